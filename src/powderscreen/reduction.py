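"""Reduction of 2D detector frames to background-subtracted 1D powder profiles.

The beamline acquisition records a series of photon-counting detector frames
per sample and per matched buffer.  Reduction sums the frames, radially
(azimuthally) averages the summed image into a 1D profile on an ``s`` or
``2θ`` axis with Poisson uncertainties, and subtracts the buffer profile.

Bin assignment uses the pixel-center scattering angle
``2θ = atan(r_pix / distance)``; no pixel splitting is performed — at a 3 m
sample–detector distance a bin spans many pixels, so sub-pixel splitting
would change nothing measurable.  No polarization or solid-angle correction
is applied by default: the downstream analysis keys on relative peak
positions, which such corrections do not move.  A hook is provided for a
per-pixel correction field should absolute intensities ever matter.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .lattice import s_from_two_theta, two_theta_from_s

__all__ = [
    "AxisKind",
    "DetectorGeometry",
    "DetectorFrame",
    "Pattern1D",
    "sum_frames",
    "azimuthal_integrate",
    "subtract_buffer",
    "convert_axis",
    "read_dat",
    "write_dat",
    "read_frame",
    "write_frame",
    "read_geometry",
    "write_geometry",
]


class AxisKind(str, Enum):
    S = "s_inv_angstrom"
    TWO_THETA = "two_theta_deg"


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat detector normal to the beam.

    distance and pixel_size in mm, beam_center in (row, col) pixel units,
    wavelength in Å.
    """

    distance: float
    pixel_size: float
    beam_center: tuple[float, float]
    wavelength: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if min(self.distance, self.pixel_size, self.wavelength) <= 0:
            raise ValueError("distance, pixel_size and wavelength must be positive")
        r, c = self.beam_center
        if not (-self.n_rows <= r <= 2 * self.n_rows and -self.n_cols <= c <= 2 * self.n_cols):
            raise ValueError("beam center implausibly far from the pixel grid")

    def two_theta_map(self) -> np.ndarray:
        """Per-pixel scattering angle 2θ [deg] at pixel centers."""
        rows = np.arange(self.n_rows)[:, None] - self.beam_center[0]
        cols = np.arange(self.n_cols)[None, :] - self.beam_center[1]
        r_mm = np.hypot(rows, cols) * self.pixel_size
        return np.degrees(np.arctan2(r_mm, self.distance))


@dataclass
class DetectorFrame:
    """One exposure: integer photon counts plus an exclusion mask."""

    counts: np.ndarray
    mask: np.ndarray | None = None
    exposure: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.mask is None:
            self.mask = np.zeros(self.counts.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.counts.shape != self.mask.shape:
            raise ValueError("counts and mask must share a shape")
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class Pattern1D:
    """A 1D scattering/powder profile with per-point uncertainties.

    The central currency of the pipeline: radial averaging, buffer
    subtraction, screening and Pawley fitting all consume and produce these.
    Intensities may be negative after buffer subtraction; sigmas are always
    positive.
    """

    axis_kind: AxisKind
    axis: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis_kind = AxisKind(self.axis_kind)
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.axis) == len(self.intensity) == len(self.sigma)):
            raise ValueError("axis, intensity and sigma must have equal length")
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("axis must be strictly increasing")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive everywhere")

    def __len__(self) -> int:
        return len(self.axis)

    @property
    def weights(self) -> np.ndarray:
        """Least-squares weights w = 1/σ²."""
        return 1.0 / self.sigma**2


# ---------------------------------------------------------------------------
# operations


def sum_frames(frames: Sequence[DetectorFrame]) -> DetectorFrame:
    """Sum a frame series elementwise; exposures add, the mask is shared."""
    if len(frames) == 0:
        raise ValueError("cannot sum an empty frame list")
    first = frames[0]
    for f in frames[1:]:
        if f.counts.shape != first.counts.shape:
            raise ValueError("all frames must share a shape")
        if not np.array_equal(f.mask, first.mask):
            raise ValueError("all frames must share a mask")
    total = np.sum([f.counts for f in frames], axis=0)
    return DetectorFrame(total, first.mask.copy(), sum(f.exposure for f in frames))


def azimuthal_integrate(
    frame: DetectorFrame,
    geom: DetectorGeometry,
    n_bins: int = 2000,
    axis_kind: AxisKind = AxisKind.S,
    correction: np.ndarray | None = None,
) -> Pattern1D:
    """Radially average a frame into a 1D profile.

    Each unmasked pixel is assigned to one of ``n_bins`` equal-width 2θ bins
    by its center angle.  Bin intensity is the mean pixel count, bin sigma
    the Poisson estimate sqrt(Σcounts)/n_pixels.  Empty bins are dropped.
    ``correction`` optionally divides per-pixel counts (flat-field /
    solid-angle hook; off by default).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if frame.counts.shape != (geom.n_rows, geom.n_cols):
        raise ValueError("frame shape does not match geometry")
    tt = geom.two_theta_map()
    good = ~frame.mask
    if not np.any(good):
        raise ValueError("all pixels are masked; nothing to integrate")
    counts = frame.counts.astype(float)
    if correction is not None:
        counts = counts / np.asarray(correction, dtype=float)
    tt_good = tt[good]
    c_good = counts[good]
    lo, hi = float(tt_good.min()), float(tt_good.max())
    if hi <= lo:
        raise ValueError("degenerate angular range")
    # right-open bins, last bin closed so the max pixel is kept
    idx = np.minimum(((tt_good - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1)
    n_pix = np.bincount(idx, minlength=n_bins)
    tot = np.bincount(idx, weights=c_good, minlength=n_bins)
    centers = lo + (np.arange(n_bins) + 0.5) * (hi - lo) / n_bins
    keep = n_pix > 0
    mean = tot[keep] / n_pix[keep]
    sig = np.sqrt(np.maximum(tot[keep], 1.0)) / n_pix[keep]
    axis_tt = centers[keep]
    meta = {
        "exposure_s": frame.exposure,
        "n_pixels": int(n_pix.sum()),
        "wavelength_A": geom.wavelength,
        "bin_pixel_counts": n_pix[keep],
    }
    if axis_kind == AxisKind.TWO_THETA:
        return Pattern1D(AxisKind.TWO_THETA, axis_tt, mean, sig, meta)
    axis_s = s_from_two_theta(axis_tt, geom.wavelength)
    return Pattern1D(AxisKind.S, axis_s, mean, sig, meta)


def subtract_buffer(sample: Pattern1D, buffer: Pattern1D, scale: float = 1.0) -> Pattern1D:
    """Pointwise sample − scale·buffer with error propagation.

    The grids must agree exactly; no silent interpolation.  Negative
    intensities are retained — clipping would bias the noise statistics the
    peak-significance test relies on.
    """
    if sample.axis_kind != buffer.axis_kind:
        raise ValueError("axis kinds differ")
    if len(sample) != len(buffer) or not np.allclose(
        sample.axis, buffer.axis, rtol=1e-12, atol=0.0
    ):
        raise ValueError("sample and buffer are not on the same grid")
    intensity = sample.intensity - scale * buffer.intensity
    sigma = np.sqrt(sample.sigma**2 + scale**2 * buffer.sigma**2)
    meta = dict(sample.meta)
    meta["buffer_subtracted"] = True
    meta["buffer_scale"] = scale
    return Pattern1D(sample.axis_kind, sample.axis.copy(), intensity, sigma, meta)


def convert_axis(p: Pattern1D, wavelength: float, target: AxisKind) -> Pattern1D:
    """Re-express the axis via s = 4π sin(θ)/λ; intensities are untouched.

    No Jacobian re-weighting is applied: the profile remains counts-per-bin
    on the original binning, merely relabelled, which is what whole-pattern
    fitting in 2θ expects.
    """
    target = AxisKind(target)
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    if p.axis_kind == target:
        return Pattern1D(target, p.axis.copy(), p.intensity.copy(), p.sigma.copy(), dict(p.meta))
    if target == AxisKind.TWO_THETA:
        axis = two_theta_from_s(p.axis, wavelength)
    else:
        axis = s_from_two_theta(p.axis, wavelength)
    meta = dict(p.meta)
    meta["wavelength_A"] = wavelength
    return Pattern1D(target, axis, p.intensity.copy(), p.sigma.copy(), meta)


# ---------------------------------------------------------------------------
# file formats

_AXIS_HEADER = {
    AxisKind.S: "s [1/A]",
    AxisKind.TWO_THETA: "2theta [deg]",
}


def write_dat(p: Pattern1D, path: str | Path | io.TextIOBase) -> None:
    """Write a 3-column whitespace text profile (SASBDB-style dialect)."""
    header = [f"# {p.meta.get('sample', 'profile')}"]
    header.append(f"# axis: {_AXIS_HEADER[p.axis_kind]}  columns: axis intensity sigma")
    for k, v in p.meta.items():
        if k in ("sample", "bin_pixel_counts"):
            continue
        header.append(f"# {k}: {v}")
    body = "\n".join(
        f"{a:.8e} {i:.8e} {s:.8e}" for a, i, s in zip(p.axis, p.intensity, p.sigma)
    )
    text = "\n".join(header) + "\n" + body + "\n"
    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        Path(path).write_text(text)


_NM_RE = re.compile(r"(1/nm|nm\^?-1|nm-1)", re.IGNORECASE)
_TT_RE = re.compile(r"(2.?theta|deg)", re.IGNORECASE)


def read_dat(path: str | Path | io.TextIOBase) -> Pattern1D:
    """Read a 3-column text profile.

    Header comment lines declare the axis; both Å⁻¹ and nm⁻¹ momentum
    transfer axes are accepted (nm⁻¹ is divided by 10 to normalize to Å⁻¹),
    as is a 2θ-in-degrees axis.  With no declaration the axis defaults to
    Å⁻¹ momentum transfer.
    """
    if isinstance(path, io.TextIOBase):
        text = path.read()
    else:
        text = Path(path).read_text()
    axis_kind = AxisKind.S
    nm = False
    rows = []
    meta: dict = {}
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        parts = stripped.split()
        is_data = len(parts) >= 3 and not stripped.startswith("#")
        if is_data:
            try:
                rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
                continue
            except ValueError:
                pass  # header text without leading '#'
        low = stripped.lower()
        if "theta" in low:
            axis_kind = AxisKind.TWO_THETA
        if _NM_RE.search(low):
            nm = True
        m = re.match(r"#\s*([A-Za-z_][\w]*)\s*:\s*(.+)$", stripped)
        if m and m.group(1).lower() != "axis":
            meta[m.group(1)] = m.group(2)
    if not rows:
        raise ValueError(f"no data rows found in profile file {path!r}")
    arr = np.asarray(rows)
    axis = arr[:, 0] / 10.0 if (nm and axis_kind == AxisKind.S) else arr[:, 0]
    return Pattern1D(axis_kind, axis, arr[:, 1], arr[:, 2], meta)


def write_frame(frame: DetectorFrame, path: str | Path) -> None:
    """Write counts as an unsigned-integer TIFF (mask saved alongside as .mask.tif)."""
    path = Path(path)
    tifffile.imwrite(path, frame.counts.astype(np.uint32))
    if np.any(frame.mask):
        tifffile.imwrite(path.with_suffix(".mask.tif"), frame.mask.astype(np.uint8))


def read_frame(path: str | Path, exposure: float = 1.0) -> DetectorFrame:
    path = Path(path)
    counts = tifffile.imread(path)
    mask_path = path.with_suffix(".mask.tif")
    mask = tifffile.imread(mask_path).astype(bool) if mask_path.exists() else None
    return DetectorFrame(counts, mask, exposure)


_GEOM_FIELDS = (
    "distance_mm",
    "pixel_size_mm",
    "beam_center_row",
    "beam_center_col",
    "wavelength_A",
    "n_rows",
    "n_cols",
)


def write_geometry(geom: DetectorGeometry, path: str | Path) -> None:
    """Plain-text sidecar geometry file (key value per line)."""
    vals = (
        geom.distance,
        geom.pixel_size,
        geom.beam_center[0],
        geom.beam_center[1],
        geom.wavelength,
        geom.n_rows,
        geom.n_cols,
    )
    Path(path).write_text("".join(f"{k} {v}\n" for k, v in zip(_GEOM_FIELDS, vals)))


def read_geometry(path: str | Path) -> DetectorGeometry:
    kv: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) == 2:
            kv[parts[0]] = float(parts[1])
    missing = [f for f in _GEOM_FIELDS if f not in kv]
    if missing:
        raise ValueError(f"geometry file {path!r} missing fields: {missing}")
    return DetectorGeometry(
        kv["distance_mm"],
        kv["pixel_size_mm"],
        (kv["beam_center_row"], kv["beam_center_col"]),
        kv["wavelength_A"],
        int(kv["n_rows"]),
        int(kv["n_cols"]),
    )
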
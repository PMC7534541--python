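"""Synthetic beamline data with the statistical structure of the screening
experiment.

Generates paired sample/buffer 1D profiles and 2D detector-frame series
containing: a smooth, monotonically decaying cellular/buffer background
(Porod-like, ``I_bg(s) = A·s^(−p) + C``); Bragg peaks at positions fixed by
a unit cell and space group, with free log-normal per-reflection mean
intensities (a Pawley fit extracts no more than that); granular ("spotty")
Debye–Scherrer rings from a finite crystallite count; Poisson counting
noise at the configured frame exposure; and 1:2 dilution series of
crystal-containing cells into mock-infected cells.

Default experiment numbers are those of the screening setup this package
models: 10 keV photons (1.24 Å), 3.00 m sample–detector distance, a
0.20 × 0.12 mm beam through a 1.8 mm capillary, and 40 sample + 40 buffer
frames of 0.045 s exposure with 0.005 s readout (4 s total per data set).

The crystallite-count-to-SNR mapping of the real instrument is not
reproducible in arbitrary units, so detection-limit *fractions* are
meaningful only relatively (ordering and 1:2 halving behaviour), not as
absolute percentages.  The intensity scale is chosen so that a
full-fraction sample shows strong peaks (max SNR of order 50–80) that fall
below a 5σ screening threshold around a 16-fold dilution — the regime the
screening experiment operates in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .lattice import (
    Reflection,
    SpaceGroupRules,
    UnitCell,
    generate_reflections,
    s_from_two_theta,
)
from .pawley import BackgroundModel, PawleyModel, ProfileParams, _peak_matrix
from .reduction import AxisKind, DetectorFrame, DetectorGeometry, Pattern1D
from .screening import DilutionSeries, DilutionStep

__all__ = [
    "ExperimentConfig",
    "PhantomSpec",
    "irradiated_volume",
    "acquisition_time",
    "simulate_profile_pair",
    "simulate_detector_series",
    "make_dilution_series",
    "paper_phantoms",
    "default_grid",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Acquisition geometry and exposure scheme of one screening data set."""

    wavelength: float = 1.24  # Å
    distance: float = 3000.0  # mm
    beam_w: float = 0.20  # mm FWHM
    beam_h: float = 0.12  # mm FWHM
    capillary_path: float = 1.8  # mm
    n_sample_frames: int = 40
    n_buffer_frames: int = 40
    frame_exposure: float = 0.045  # s
    readout: float = 0.005  # s
    seed: int = 0

    def __post_init__(self) -> None:
        vals = (
            self.wavelength,
            self.distance,
            self.beam_w,
            self.beam_h,
            self.capillary_path,
            self.n_sample_frames,
            self.frame_exposure,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all experiment quantities must be positive")

    @property
    def sample_exposure(self) -> float:
        """Total integrating exposure of the summed sample series [s]."""
        return self.n_sample_frames * self.frame_exposure

    @property
    def buffer_exposure(self) -> float:
        return self.n_buffer_frames * self.frame_exposure


def irradiated_volume(
    beam_w: float, beam_h: float, path: float, round_to: int | None = None
) -> float:
    """Irradiated sample volume in mm³, rectangular-beam approximation w·h·path.

    The beam profile is treated as a w × h rectangle (no FWHM convolution):
    this is the arithmetic the screening experiment uses to count how many
    cells the beam interrogates.
    """
    if min(beam_w, beam_h, path) <= 0:
        raise ValueError("beam dimensions and path must be positive")
    v = beam_w * beam_h * path
    return round(v, round_to) if round_to is not None else v


def acquisition_time(cfg: ExperimentConfig) -> float:
    """Total seconds per data set: (sample + buffer frames) × (exposure + readout)."""
    return (cfg.n_sample_frames + cfg.n_buffer_frames) * (
        cfg.frame_exposure + cfg.readout
    )


# ---------------------------------------------------------------------------
# phantoms


@dataclass(frozen=True)
class PhantomSpec:
    """What is in the capillary: a crystal phase inside a cellular background.

    ``background`` holds (A, p, C) of the Porod-like decay
    ``I_bg(s) = A·s^(−p) + C`` in detector counts per bin per second at unit
    efficiency; ``intensity_scale`` sets the log-normal per-reflection mean
    intensity scale (arbitrary units — Pawley refines intensities freely,
    so no structure factors are computed); ``crystal_cell_fraction`` scales
    the Bragg component linearly, mirroring dilution of crystal-containing
    cells with mock-infected ones at fixed crystal volume per cell.
    """

    cell: UnitCell
    space_group: str
    crystal_cell_fraction: float = 1.0
    n_crystallites: int = 500
    intensity_scale: float = 18.0
    intensity_sigma_log: float = 1.0
    intensity_seed: int = 7
    background: tuple[float, float, float] = (1.0, 3.0, 50.0)
    zero_shift: float = 0.0
    eta: float = 0.5
    peak_fwhm: float = 0.025  # deg 2θ

    def __post_init__(self) -> None:
        if not 0.0 <= self.crystal_cell_fraction <= 1.0:
            raise ValueError("crystal_cell_fraction must lie in [0, 1]")
        if not 2.0 <= self.background[1] <= 4.0:
            raise ValueError("background decay power p must lie in [2, 4]")
        if self.n_crystallites < 0:
            raise ValueError("n_crystallites must be non-negative")

    @property
    def rules(self) -> SpaceGroupRules:
        return SpaceGroupRules.from_symbol(self.space_group)

    def mean_intensities(self, reflections: Sequence[Reflection]) -> np.ndarray:
        """Seeded log-normal per-reflection mean intensities (phase fingerprint).

        Drawn from the phantom's own ``intensity_seed`` so the fingerprint is
        a property of the phase, stable across noise realizations and
        dilution steps.
        """
        rng = np.random.default_rng(self.intensity_seed)
        return self.intensity_scale * rng.lognormal(
            0.0, self.intensity_sigma_log, len(reflections)
        )


def paper_phantoms() -> dict[str, PhantomSpec]:
    """The four crystal phases of the screening study, by refined cell.

    Luc P4₁2₁2 a=b=129.13, c=97.1 Å; IMPDH P42₁2 a=b=209.3, c=93.44 Å;
    CatB P4₂2₁2 a=b=125.69, c=54.408 Å; HEX-1 P6₅22 a=b=58.01, c=195.2 Å.
    Each gets a distinct intensity seed so the fingerprints differ.
    """
    return {
        "luc": PhantomSpec(UnitCell.tetragonal(129.13, 97.1), "P41212", intensity_seed=11),
        "impdh": PhantomSpec(UnitCell.tetragonal(209.3, 93.44), "P4212", intensity_seed=13),
        "catb": PhantomSpec(UnitCell.tetragonal(125.69, 54.408), "P42212", intensity_seed=17),
        "hex1": PhantomSpec(UnitCell.hexagonal(58.01, 195.2), "P6522", intensity_seed=19),
    }


def default_grid(lo: float = 0.1, hi: float = 2.4, n: int = 2000) -> np.ndarray:
    """Default 2θ grid: oversamples the narrowest default peak ≥ 5×."""
    return np.linspace(lo, hi, n)


# ---------------------------------------------------------------------------
# 1D profile simulation


def _bragg_model(
    phantom: PhantomSpec, grid: np.ndarray, wavelength: float
) -> PawleyModel:
    rules = phantom.rules
    refl = generate_reflections(
        phantom.cell, rules, (float(grid[0]), float(grid[-1])), wavelength
    )
    means = phantom.mean_intensities(refl)
    refl = [replace(r, intensity=float(i)) for r, i in zip(refl, means)]
    bg = BackgroundModel((0.0,), (float(grid[0]) - 1e-9, float(grid[-1]) + 1e-9))
    return PawleyModel(
        phantom.cell,
        rules,
        wavelength,
        bg,
        ProfileParams(eta=phantom.eta, W=phantom.peak_fwhm**2),
        phantom.zero_shift,
        refl,
    )


def background_mean(phantom: PhantomSpec, grid: np.ndarray, wavelength: float) -> np.ndarray:
    """Mean cellular/buffer background in counts/s on a 2θ grid."""
    A, p, C = phantom.background
    s = s_from_two_theta(grid, wavelength)
    s = np.maximum(s, 1e-6)
    return A * s ** (-p) + C


def bragg_mean(phantom: PhantomSpec, grid: np.ndarray, wavelength: float) -> np.ndarray:
    """Noise-free Bragg component (counts/s) at full crystal fraction."""
    model = _bragg_model(phantom, grid, wavelength)
    if not model.reflections:
        return np.zeros_like(grid)
    return _peak_matrix(grid, model.reflections, model.profile, model.zero_shift) @ (
        model.intensities
    )


def _poissonize(mean_rate: np.ndarray, exposure: float, rng: np.random.Generator):
    counts = rng.poisson(np.maximum(mean_rate, 0.0) * exposure)
    intensity = counts / exposure
    sigma = np.sqrt(np.maximum(counts, 1.0)) / exposure
    return intensity, sigma


def simulate_profile_pair(
    phantom: PhantomSpec,
    cfg: ExperimentConfig,
    grid: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[Pattern1D, Pattern1D]:
    """One (sample, buffer) profile pair with Poisson noise.

    The buffer realizes the background-only mean; the sample adds the Bragg
    component scaled by the crystal-cell fraction.  Counts are Poisson at
    the series' total exposure; intensities are returned in counts/s with
    Poisson sigmas, matching what frame summation + radial averaging of the
    real acquisition would produce.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(cfg.seed if rng is None else int(rng))
    bg = background_mean(phantom, grid, cfg.wavelength)
    bragg = phantom.crystal_cell_fraction * bragg_mean(phantom, grid, cfg.wavelength)
    s_int, s_sig = _poissonize(bg + bragg, cfg.sample_exposure, rng)
    b_int, b_sig = _poissonize(bg, cfg.buffer_exposure, rng)
    meta = {
        "wavelength_A": cfg.wavelength,
        "crystal_cell_fraction": phantom.crystal_cell_fraction,
        "space_group": phantom.space_group,
    }
    sample = Pattern1D(AxisKind.TWO_THETA, grid, s_int, s_sig, {**meta, "sample": "sample"})
    buffer = Pattern1D(AxisKind.TWO_THETA, grid.copy(), b_int, b_sig, {**meta, "sample": "buffer"})
    return sample, buffer


# ---------------------------------------------------------------------------
# 2D detector simulation


def simulate_detector_series(
    phantom: PhantomSpec,
    cfg: ExperimentConfig,
    geometry: DetectorGeometry,
    rng: np.random.Generator | int | None = None,
    rocking_fraction: float = 0.02,
    spot_sigma_px: float = 1.0,
    spot_counts: float = 2000.0,
    background_scale: float = 1.0,
) -> tuple[list[DetectorFrame], list[DetectorFrame]]:
    """Frame series with granular Debye–Scherrer rings.

    Each of ``n_crystallites`` crystallites contributes, per reflection, a
    Bernoulli spot (probability ∝ multiplicity × rocking fraction) at the
    ring radius ``r = distance·tan(2θ)`` and an independent random azimuth;
    the azimuthal granularity therefore decreases as the crystallite count
    grows.  A smooth radial background is added and every frame receives its
    own Poisson draw.  Rings beyond the detector edge are truncated by
    construction (their spots fall outside the pixel grid).
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(cfg.seed if rng is None else int(rng))
    tt_map = geometry.two_theta_map()
    bg_rate = background_scale * background_mean(
        phantom, np.maximum(tt_map.ravel(), 1e-4), cfg.wavelength
    ).reshape(tt_map.shape)
    # cap the divergent forward-scattering center at the beamstop scale
    bg_rate = np.minimum(bg_rate, np.percentile(bg_rate, 99.9))

    refl = generate_reflections(
        phantom.cell,
        phantom.rules,
        (1e-3, float(tt_map.max())),
        cfg.wavelength,
    )
    spot_rate = np.zeros_like(bg_rate)
    n_cryst = phantom.n_crystallites
    frac = phantom.crystal_cell_fraction
    rows = np.arange(geometry.n_rows)[:, None]
    cols = np.arange(geometry.n_cols)[None, :]
    for r in refl:
        radius_px = geometry.distance * math.tan(math.radians(r.two_theta)) / geometry.pixel_size
        p_hit = min(1.0, rocking_fraction * r.multiplicity)
        n_spots = rng.binomial(n_cryst, p_hit * frac) if n_cryst else 0
        if n_spots == 0:
            continue
        azimuths = rng.uniform(0.0, 2.0 * np.pi, n_spots)
        halo = int(math.ceil(4.0 * spot_sigma_px))
        for az in azimuths:
            cy = geometry.beam_center[0] + radius_px * math.sin(az)
            cx = geometry.beam_center[1] + radius_px * math.cos(az)
            if not (-3 <= cy < geometry.n_rows + 3 and -3 <= cx < geometry.n_cols + 3):
                continue  # truncated beyond the detector edge
            r0, r1 = max(0, int(cy) - halo), min(geometry.n_rows, int(cy) + halo + 1)
            c0, c1 = max(0, int(cx) - halo), min(geometry.n_cols, int(cx) + halo + 1)
            if r0 >= r1 or c0 >= c1:
                continue
            g = np.exp(
                -0.5
                * (
                    ((rows[r0:r1] - cy) ** 2 + (cols[:, c0:c1] - cx) ** 2)
                    / spot_sigma_px**2
                )
            )
            spot_rate[r0:r1, c0:c1] += spot_counts * g / (2.0 * np.pi * spot_sigma_px**2)

    mean_rate = bg_rate / max(bg_rate.max(), 1.0) * 200.0 + spot_rate  # counts/s/pixel
    sample_frames = [
        DetectorFrame(
            rng.poisson(mean_rate * cfg.frame_exposure), exposure=cfg.frame_exposure
        )
        for _ in range(cfg.n_sample_frames)
    ]
    bg_only = bg_rate / max(bg_rate.max(), 1.0) * 200.0
    buffer_frames = [
        DetectorFrame(
            rng.poisson(bg_only * cfg.frame_exposure), exposure=cfg.frame_exposure
        )
        for _ in range(cfg.n_buffer_frames)
    ]
    return sample_frames, buffer_frames


# ---------------------------------------------------------------------------
# dilution series


def make_dilution_series(
    phantom: PhantomSpec,
    cfg: ExperimentConfig,
    n_steps: int,
    grid: np.ndarray | None = None,
    f0: float | None = None,
) -> DilutionSeries:
    """1:2 dilution series: step j has fraction f₀/2ʲ (step 0 undiluted).

    Background parameters and the per-reflection intensity fingerprint are
    shared across steps; each step gets an independent noise substream.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    f0 = phantom.crystal_cell_fraction if f0 is None else f0
    root = np.random.default_rng(cfg.seed)
    steps = []
    for j in range(n_steps + 1):
        child = np.random.default_rng(root.integers(0, 2**31 - 1))
        ph = replace(phantom, crystal_cell_fraction=f0 / 2**j)
        sample, buffer = simulate_profile_pair(ph, cfg, grid, child)
        steps.append(
            DilutionStep(
                dilution_factor=float(2**j),
                crystal_cell_fraction=f0 / 2**j,
                sample=sample,
                buffer=buffer,
            )
        )
    return DilutionSeries(steps)
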
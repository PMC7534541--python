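"""Crystal-content screening and phase clustering of scattering profiles.

The screening question is binary: does a cell-suspension scattering profile
contain Bragg peaks rising above the smooth cellular background, i.e. does
the culture contain diffracting crystalline material?  Peaks are called
against a SNIP-style iteratively clipped baseline with a robust (MAD-based)
local noise scale, and a sample is called crystal-positive when at least
``min_peaks`` peaks exceed ``k_sigma`` times the local noise — a single
excursion is not proof of crystallinity.

Profiles from different crystal phases are separated without any peak
assignment by PCA over a fixed low-angle 2θ window followed by average-
linkage agglomerative clustering in PC space.  Each pattern is first
normalized to unit total intensity so that clustering keys on peak
*positions* (the phase fingerprint), not on crystal-fraction amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA

from .reduction import AxisKind, Pattern1D, subtract_buffer

__all__ = [
    "PeakCall",
    "ScreeningResult",
    "PhaseClustering",
    "DilutionSeries",
    "DilutionStep",
    "estimate_baseline",
    "local_noise_sigma",
    "detect_peaks",
    "classify_crystal_content",
    "CrystalScreener",
    "pca_cluster",
    "PhaseClusterer",
    "detection_limit",
    "DetectionLimitResult",
]


@dataclass(frozen=True)
class PeakCall:
    """One detected Bragg peak."""

    position: float  # 2θ degrees (or s, matching the profile axis)
    height: float  # above-baseline intensity
    snr: float  # height / local noise sigma
    width: float  # axis units

    def __post_init__(self) -> None:
        if self.snr <= 0 or self.width <= 0:
            raise ValueError("snr and width must be positive")


@dataclass
class ScreeningResult:
    peaks: list[PeakCall]
    crystal_present: bool
    score: float  # max snr over calls (0 if none)
    baseline: np.ndarray

    def to_record(self, sample: str = "") -> dict:
        return {
            "sample": sample,
            "crystal_present": self.crystal_present,
            "score": self.score,
            "n_peaks": len(self.peaks),
            "peaks": [
                {"position": p.position, "height": p.height, "snr": p.snr, "width": p.width}
                for p in self.peaks
            ],
        }


# ---------------------------------------------------------------------------
# baseline and noise


def estimate_baseline(p: Pattern1D, half_window: int = 50) -> np.ndarray:
    """SNIP-style iteratively clipped baseline.

    Repeatedly replaces each point by the smaller of itself and the mean of
    its ``m``-distant neighbours, with ``m`` shrinking from ``half_window``
    to 1.  Convex smooth decays (the cellular background) are fixed points
    of the operation; narrow peaks are clipped down to the interpolation of
    their flanks.  The result never exceeds the profile anywhere.
    """
    if half_window < 2:
        raise ValueError("half_window must be >= 2")
    n = len(p)
    if n < 2 * half_window + 1:
        raise ValueError("profile shorter than the baseline window")
    b = p.intensity.astype(float).copy()
    for m in range(half_window, 0, -1):
        # only points with both m-distant neighbours in range are clipped;
        # touching the edges would drag them toward interior values on
        # steeply decaying profiles
        avg = 0.5 * (b[: n - 2 * m] + b[2 * m :])
        b[m : n - m] = np.minimum(b[m : n - m], avg)
    return b


def local_noise_sigma(
    p: Pattern1D, baseline: np.ndarray, window: int = 201
) -> np.ndarray:
    """Robust local noise scale: 1.4826 × sliding MAD of (profile − baseline).

    Robust to the peaks themselves; floored at a tiny fraction of the
    profile scale so noise-free synthetic input yields finite SNR.
    """
    resid = p.intensity - baseline
    n = len(resid)
    half = max(window // 2, 2)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        w = resid[lo:hi]
        out[i] = 1.4826 * np.median(np.abs(w - np.median(w)))
    floor = 1e-12 * max(float(np.max(np.abs(p.intensity))), 1.0)
    return np.maximum(out, floor)


# ---------------------------------------------------------------------------
# peak detection


def detect_peaks(
    p: Pattern1D,
    k_sigma: float = 5.0,
    min_points: int = 3,
    half_window: int = 50,
    noise_window: int = 201,
) -> list[PeakCall]:
    """Call peaks as contiguous runs of significant above-baseline points.

    A run of at least ``min_points`` consecutive points exceeding
    ``baseline + k_sigma·σ_local`` is one peak; its position is the
    intensity-weighted centroid of the above-baseline excess.  Deterministic.
    """
    if k_sigma <= 0:
        raise ValueError("k_sigma must be positive")
    baseline = estimate_baseline(p, half_window)
    sigma = local_noise_sigma(p, baseline, noise_window)
    excess = p.intensity - baseline
    hot = excess > k_sigma * sigma
    calls: list[PeakCall] = []
    i = 0
    n = len(p)
    while i < n:
        if not hot[i]:
            i += 1
            continue
        j = i
        while j < n and hot[j]:
            j += 1
        if j - i >= min_points:
            seg = slice(i, j)
            wts = excess[seg]
            pos = float(np.sum(p.axis[seg] * wts) / np.sum(wts))
            k = i + int(np.argmax(excess[seg]))
            calls.append(
                PeakCall(
                    position=pos,
                    height=float(excess[k]),
                    snr=float(excess[k] / sigma[k]),
                    width=float(p.axis[j - 1] - p.axis[i]) or float(p.axis[1] - p.axis[0]),
                )
            )
        i = j
    return calls


# ---------------------------------------------------------------------------
# crystal-present decision


@dataclass
class ScreeningConfig:
    k_sigma: float = 5.0
    min_peaks: int = 2
    min_points: int = 3
    half_window: int = 50
    noise_window: int = 201
    buffer_scale: float = 1.0


def classify_crystal_content(
    sample: Pattern1D,
    reference: Pattern1D | None = None,
    config: ScreeningConfig | None = None,
) -> ScreeningResult:
    """Decide whether a profile contains crystalline material.

    If a reference (buffer or mock-infected control) is given it is
    subtracted first.  Positive iff at least ``min_peaks`` peaks reach
    ``k_sigma`` significance.
    """
    cfg = config or ScreeningConfig()
    work = (
        subtract_buffer(sample, reference, cfg.buffer_scale)
        if reference is not None
        else sample
    )
    peaks = detect_peaks(
        work, cfg.k_sigma, cfg.min_points, cfg.half_window, cfg.noise_window
    )
    significant = [p for p in peaks if p.snr >= cfg.k_sigma]
    present = len(significant) >= cfg.min_peaks
    score = max((p.snr for p in peaks), default=0.0)
    return ScreeningResult(
        peaks=peaks,
        crystal_present=present,
        score=score,
        baseline=estimate_baseline(work, cfg.half_window),
    )


class CrystalScreener:
    """Estimator-style front end to the crystal-present decision.

    ``predict`` maps a sequence of (sample, reference-or-None) profiles to
    boolean calls; ``screen`` returns the full per-sample result.
    """

    def __init__(
        self,
        k_sigma: float = 5.0,
        min_peaks: int = 2,
        min_points: int = 3,
        half_window: int = 50,
        noise_window: int = 201,
        buffer_scale: float = 1.0,
    ):
        self.k_sigma = k_sigma
        self.min_peaks = min_peaks
        self.min_points = min_points
        self.half_window = half_window
        self.noise_window = noise_window
        self.buffer_scale = buffer_scale

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "k_sigma",
                "min_peaks",
                "min_points",
                "half_window",
                "noise_window",
                "buffer_scale",
            )
        }

    def set_params(self, **params) -> "CrystalScreener":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> ScreeningConfig:
        return ScreeningConfig(**self.get_params())

    def screen(
        self, sample: Pattern1D, reference: Pattern1D | None = None
    ) -> ScreeningResult:
        return classify_crystal_content(sample, reference, self._config())

    def fit(self, X=None, y=None) -> "CrystalScreener":
        return self  # threshold rule; nothing to estimate

    def predict(
        self,
        samples: Sequence[Pattern1D],
        references: Sequence[Pattern1D | None] | None = None,
    ) -> np.ndarray:
        refs = references or [None] * len(samples)
        return np.array(
            [self.screen(s, r).crystal_present for s, r in zip(samples, refs)]
        )


# ---------------------------------------------------------------------------
# PCA phase clustering


@dataclass
class PhaseClustering:
    scores: np.ndarray  # (n_patterns, n_components)
    explained_variance: np.ndarray  # fractions, non-increasing
    labels: np.ndarray  # 0..k-1, canonicalized by first occurrence
    window: tuple[float, float]
    degenerate: bool = False


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters in order of first occurrence → permutation invariant."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


class PhaseClusterer:
    """PCA + average-linkage clustering of powder profiles by phase.

    scikit-learn-style: ``fit`` / ``fit_predict`` over a list of
    :class:`Pattern1D` (2θ axis) or a ready (n_patterns, n_points) matrix.
    Patterns are restricted to ``window``, linearly interpolated onto a
    common grid, normalized to unit total intensity and mean-centred; the
    first ``n_components`` principal-component scores are clustered with
    average-linkage Euclidean agglomeration cut at ``n_clusters``.

    The cluster count is user-supplied by design: the screening experiment
    knows how many constructs it measured.  ``n_clusters=None`` turns on
    silhouette-based selection over 2..n_max (never the default behaviour).
    """

    def __init__(
        self,
        n_clusters: int | None = 4,
        window: tuple[float, float] = (0.4, 2.0),
        n_components: int = 3,
        auto_k_max: int = 8,
    ):
        self.n_clusters = n_clusters
        self.window = window
        self.n_components = n_components
        self.auto_k_max = auto_k_max

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in ("n_clusters", "window", "n_components", "auto_k_max")
        }

    def set_params(self, **params) -> "PhaseClusterer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _matrix(self, patterns) -> np.ndarray:
        if isinstance(patterns, np.ndarray) and patterns.ndim == 2:
            X = patterns.astype(float)
        else:
            lo, hi = self.window
            first = patterns[0]
            if first.axis_kind != AxisKind.TWO_THETA:
                raise ValueError("phase clustering expects 2θ-axis patterns")
            sel = (first.axis >= lo) & (first.axis <= hi)
            if sel.sum() < 4:
                raise ValueError("window contains too few points")
            grid = first.axis[sel]
            X = np.empty((len(patterns), len(grid)))
            for i, p in enumerate(patterns):
                X[i] = np.interp(grid, p.axis, p.intensity)
        totals = X.sum(axis=1)
        if np.any(totals == 0):
            raise ValueError("pattern with zero total intensity in window")
        return X / totals[:, None]

    def fit(self, patterns, y=None) -> "PhaseClusterer":
        X = self._matrix(patterns)
        n = X.shape[0]
        k = self.n_clusters
        if k is not None and k > n:
            raise ValueError("more clusters requested than patterns")
        n_comp = min(self.n_components, n - 1, X.shape[1]) or 1
        total_var = float(np.sum(np.var(X, axis=0)))
        self.degenerate_ = total_var < 1e-24
        if self.degenerate_:
            self.scores_ = np.zeros((n, n_comp))
            self.explained_variance_ratio_ = np.zeros(n_comp)
            self.labels_ = np.zeros(n, dtype=int)
        else:
            pca = PCA(n_components=n_comp, svd_solver="full")
            self.scores_ = pca.fit_transform(X)
            self.explained_variance_ratio_ = pca.explained_variance_ratio_
            if k is None:
                k = self._select_k(self.scores_, min(self.auto_k_max, n - 1))
            agg = AgglomerativeClustering(n_clusters=k, linkage="average", metric="euclidean")
            self.labels_ = _canonical_labels(agg.fit_predict(self.scores_))
        self.result_ = PhaseClustering(
            self.scores_,
            self.explained_variance_ratio_,
            self.labels_,
            tuple(self.window),
            self.degenerate_,
        )
        return self

    def fit_predict(self, patterns, y=None) -> np.ndarray:
        return self.fit(patterns).labels_

    @staticmethod
    def _select_k(scores: np.ndarray, k_max: int) -> int:
        from sklearn.metrics import silhouette_score

        best = (-2.0, 2)
        for k in range(2, max(k_max, 2) + 1):
            agg = AgglomerativeClustering(n_clusters=k, linkage="average", metric="euclidean")
            lab = agg.fit_predict(scores)
            if len(set(lab)) < 2:
                continue
            s = silhouette_score(scores, lab)
            if s > best[0]:
                best = (s, k)
        return best[1]


def pca_cluster(
    patterns: Sequence[Pattern1D],
    window: tuple[float, float] = (0.4, 2.0),
    n_components: int = 3,
    k: int = 4,
) -> PhaseClustering:
    """Functional wrapper over :class:`PhaseClusterer`."""
    return (
        PhaseClusterer(n_clusters=k, window=window, n_components=n_components)
        .fit(patterns)
        .result_
    )


# ---------------------------------------------------------------------------
# dilution series


@dataclass
class DilutionStep:
    dilution_factor: float
    crystal_cell_fraction: float
    sample: Pattern1D
    buffer: Pattern1D


@dataclass
class DilutionSeries:
    """Ordered 1:2 dilution steps of crystal-containing cells into mock cells."""

    steps: list[DilutionStep]

    def __post_init__(self) -> None:
        factors = [s.dilution_factor for s in self.steps]
        for prev, cur in zip(factors, factors[1:]):
            if not np.isclose(cur, 2.0 * prev):
                raise ValueError("dilution factors must double at each step")


@dataclass
class DetectionLimitResult:
    limit_fraction: float | None  # None → no positive step at all
    last_positive_step: int | None
    per_step: list[ScreeningResult]
    scores_monotone_nonincreasing: bool

    @property
    def above_first_step(self) -> bool:
        return self.limit_fraction is None


def detection_limit(
    series: DilutionSeries, config: ScreeningConfig | None = None
) -> DetectionLimitResult:
    """Crystal-cell fraction at the last dilution step still called positive.

    Screens every step (sample minus its paired buffer/mock profile) and
    reports the fraction of the deepest consecutive positive step, together
    with whether the max-SNR score declined monotonically as it should for
    a pure dilution.
    """
    if len(series.steps) < 2:
        raise ValueError("a dilution series needs at least 2 steps")
    results = [
        classify_crystal_content(s.sample, s.buffer, config) for s in series.steps
    ]
    scores = [r.score for r in results]
    monotone = all(b <= a + 1e-12 for a, b in zip(scores, scores[1:]))
    last_pos: int | None = None
    for i, r in enumerate(results):
        if r.crystal_present:
            last_pos = i
    if last_pos is None:
        return DetectionLimitResult(None, None, results, monotone)
    return DetectionLimitResult(
        series.steps[last_pos].crystal_cell_fraction, last_pos, results, monotone
    )
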
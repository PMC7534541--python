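"""Pawley whole-powder-pattern fitting (WPPF).

A powder profile is modelled as

    y(2θ) = Σ_j c_j T_j(x(2θ))  +  Σ_k I_k · m_k · PV(2θ − (2θ_k + Z); Γ(θ_k), η)

with a shifted Chebyshev background (c_j on the data range mapped to
[−1, 1]), pseudo-Voigt peaks PV of common FWHM Γ following the Caglioti
relation Γ² = U tan²θ + V tanθ + W, an instrumental zero shift Z, and one
free, non-negative intensity I_k per symmetry-distinct reflection (the
Pawley approach: no structural model, so peak intensities carry no atomic
information and are refined freely).  Because too few peaks survive the
cellular background for ab initio indexing, refinement starts from a
user-supplied cell and improves it.

Refinement is staged, mirroring common WPPF practice: (1) background +
intensities — a bounded linear problem solved exactly; (2) + zero shift and
cell; (3) + profile parameters.  The nonlinear stages use variable
projection: for each trial of the nonlinear parameters the linear
parameters are re-solved, so accepted steps can only lower the weighted
sum of squared residuals.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.polynomial import chebyshev as cheb
from scipy.optimize import least_squares, lsq_linear

from .lattice import (
    LatticeSystem,
    Reflection,
    SpaceGroupRules,
    UnitCell,
    generate_reflections,
    s_from_two_theta,
)
from .reduction import AxisKind, Pattern1D

__all__ = [
    "ProfileParams",
    "BackgroundModel",
    "PawleyModel",
    "PawleyResult",
    "pseudo_voigt",
    "fwhm_caglioti",
    "eval_background",
    "simulate_profile",
    "equipartition_init",
    "fit_statistics",
    "PawleyRefiner",
    "pawley_refine",
]


# ---------------------------------------------------------------------------
# profile primitives


def pseudo_voigt(x, gamma: float, eta: float):
    """Unit-area pseudo-Voigt: η·Lorentzian + (1−η)·Gaussian, common FWHM γ."""
    if gamma <= 0:
        raise ValueError("FWHM must be positive")
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    x = np.asarray(x, dtype=float)
    hw = gamma / 2.0
    lorentz = hw / (np.pi * (x**2 + hw**2))
    sigma = gamma / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    gauss = np.exp(-0.5 * (x / sigma) ** 2) / (sigma * math.sqrt(2.0 * math.pi))
    out = eta * lorentz + (1.0 - eta) * gauss
    return out if out.ndim else float(out)


def fwhm_caglioti(theta_deg, U: float, V: float, W: float):
    """Caglioti FWHM Γ(θ) = sqrt(U tan²θ + V tanθ + W) in degrees (θ = half of 2θ)."""
    t = np.tan(np.radians(np.asarray(theta_deg, dtype=float)))
    g2 = U * t**2 + V * t + W
    if np.any(g2 <= 0):
        raise ValueError("Caglioti Γ² must be positive over the range")
    out = np.sqrt(g2)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ProfileParams:
    """Peak-shape parameters: mixing η, Caglioti U/V/W (deg²), asymmetry.

    ``asym`` is a single low-angle divergence coefficient; 0 (the default)
    keeps peaks symmetric, which is the testable baseline given that the
    exact parameterization used by commercial WPPF packages is not public.
    """

    eta: float = 0.5
    U: float = 0.0
    V: float = 0.0
    W: float = 1e-3
    asym: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")

    def fwhm(self, two_theta_deg):
        return fwhm_caglioti(np.asarray(two_theta_deg) / 2.0, self.U, self.V, self.W)


@dataclass(frozen=True)
class BackgroundModel:
    """Shifted Chebyshev background on a fixed 2θ domain mapped to [−1, 1]."""

    coeffs: tuple[float, ...]
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError("background domain must be strictly ordered")
        object.__setattr__(self, "coeffs", tuple(float(c) for c in self.coeffs))

    def mapped(self, grid) -> np.ndarray:
        lo, hi = self.domain
        g = np.asarray(grid, dtype=float)
        if np.any(g < lo - 1e-9) or np.any(g > hi + 1e-9):
            raise ValueError("grid outside background domain")
        return 2.0 * (g - lo) / (hi - lo) - 1.0


def eval_background(bg: BackgroundModel, grid) -> np.ndarray:
    """Σ_j c_j T_j(x) on the affine map of the domain onto [−1, 1]."""
    return cheb.chebval(bg.mapped(grid), bg.coeffs)


# ---------------------------------------------------------------------------
# model


@dataclass
class PawleyModel:
    """Everything needed to simulate a powder profile."""

    cell: UnitCell
    rules: SpaceGroupRules
    wavelength: float
    background: BackgroundModel
    profile: ProfileParams = ProfileParams()
    zero_shift: float = 0.0
    reflections: list[Reflection] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(self.zero_shift) >= 0.1:
            raise ValueError("zero shift bound |Z| < 0.1 deg exceeded")

    @property
    def intensities(self) -> np.ndarray:
        return np.array([r.intensity for r in self.reflections])

    def with_intensities(self, intensities: Sequence[float]) -> "PawleyModel":
        if len(intensities) != len(self.reflections):
            raise ValueError("intensity vector length != reflection count")
        refl = [replace(r, intensity=float(i)) for r, i in zip(self.reflections, intensities)]
        return replace(self, reflections=refl)


def _peak_matrix(
    grid: np.ndarray,
    reflections: Sequence[Reflection],
    profile: ProfileParams,
    zero_shift: float,
) -> np.ndarray:
    """Columns = m_k · PV(2θ − (2θ_k + Z)) per reflection."""
    cols = np.empty((len(grid), len(reflections)))
    for j, r in enumerate(reflections):
        center = r.two_theta + zero_shift
        gamma = float(profile.fwhm(center))
        cols[:, j] = r.multiplicity * pseudo_voigt(grid - center, gamma, profile.eta)
    return cols


def simulate_profile(model: PawleyModel, grid) -> Pattern1D:
    """Deterministic noise-free profile: background + Bragg component."""
    grid = np.asarray(grid, dtype=float)
    y = eval_background(model.background, grid)
    if model.reflections:
        y = y + _peak_matrix(grid, model.reflections, model.profile, model.zero_shift) @ (
            model.intensities
        )
    return Pattern1D(
        AxisKind.TWO_THETA,
        grid,
        y,
        np.ones_like(y),
        {"simulated": True, "wavelength_A": model.wavelength},
    )


# ---------------------------------------------------------------------------
# initialisation


def equipartition_init(
    reflections: Sequence[Reflection],
    profile: ProfileParams,
    observed: Pattern1D,
    overlap_factor: float = 0.5,
) -> np.ndarray:
    """Initial per-reflection intensities by local area equipartition.

    Reflections whose centers fall within ``overlap_factor ×`` the mean FWHM
    of their neighbour are chained into one overlap group (single linkage).
    Each group's above-baseline observed area in a ±2 FWHM window is split
    equally among its members — when peaks cannot be resolved there is no
    information to do better, and the refinement sorts it out gradually.
    """
    if not reflections:
        return np.zeros(0)
    order = np.argsort([r.two_theta for r in reflections])
    centers = np.array([reflections[i].two_theta for i in order])
    fwhm = np.asarray(profile.fwhm(centers), dtype=float)
    mean_fwhm = float(np.mean(fwhm))
    # single-linkage chaining on center separation
    groups: list[list[int]] = [[0]]
    for i in range(1, len(centers)):
        if centers[i] - centers[i - 1] <= overlap_factor * mean_fwhm:
            groups[-1].append(i)
        else:
            groups.append([i])
    t = observed.axis
    y = observed.intensity
    out = np.zeros(len(reflections))
    for grp in groups:
        lo = centers[grp[0]] - 2.0 * mean_fwhm
        hi = centers[grp[-1]] + 2.0 * mean_fwhm
        sel = (t >= lo) & (t <= hi)
        if sel.sum() < 3:
            area = 0.0
        else:
            # local linear baseline through the window edges
            te, ye = t[sel], y[sel]
            base = ye[0] + (ye[-1] - ye[0]) * (te - te[0]) / max(te[-1] - te[0], 1e-12)
            area = float(np.trapezoid(np.maximum(ye - base, 0.0), te))
        share = max(area, 0.0) / len(grp)
        for i in grp:
            out[order[i]] = share
    return out


# ---------------------------------------------------------------------------
# statistics


def fit_statistics(
    observed, calculated, weights, n_params: int
) -> tuple[float, float]:
    """(Rwp in %, reduced χ²).

    Rwp = 100·sqrt(Σw(y_o−y_c)² / Σw·y_o²); χ²_red = Σw(y_o−y_c)²/(N−P).
    """
    y_o = np.asarray(observed, dtype=float)
    y_c = np.asarray(calculated, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (len(y_o) == len(y_c) == len(w)):
        raise ValueError("length mismatch")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    n = len(y_o)
    if n <= n_params:
        raise ValueError("need more points than parameters")
    ssr = float(np.sum(w * (y_o - y_c) ** 2))
    rwp = 100.0 * math.sqrt(ssr / float(np.sum(w * y_o**2)))
    return rwp, ssr / (n - n_params)


@dataclass
class PawleyResult:
    """Refined model plus fit statistics and per-parameter uncertainties."""

    model: PawleyModel
    rwp: float
    chi2_red: float
    gof_sq: float  # (Rwp/Rexp)², the alternative goodness-of-fit convention
    esds: dict
    n_points: int
    n_params: int
    converged: bool
    history: list[float]

    def report(self) -> dict:
        cell = self.model.cell
        return {
            "space_group": self.model.rules.symbol,
            "cell_A": {"a": cell.a, "b": cell.b, "c": cell.c},
            "cell_esd_A": self.esds.get("cell", {}),
            "zero_shift_deg": self.model.zero_shift,
            "zero_shift_esd_deg": self.esds.get("zero_shift"),
            "profile": {
                "eta": self.model.profile.eta,
                "U": self.model.profile.U,
                "V": self.model.profile.V,
                "W": self.model.profile.W,
            },
            "rwp_percent": self.rwp,
            "chi2_reduced": self.chi2_red,
            "gof_squared": self.gof_sq,
            "n_points": self.n_points,
            "n_params": self.n_params,
            "converged": self.converged,
            "profile_note": (
                "FWHM follows the Caglioti relation; peak asymmetry off "
                "(exact commercial parameterization not published)"
            ),
            "reflections": [
                {
                    "hkl": list(r.hkl),
                    "d_A": r.d,
                    "two_theta_deg": r.two_theta,
                    "s_invA": r.s,
                    "multiplicity": r.multiplicity,
                    "intensity": r.intensity,
                }
                for r in self.model.reflections
            ],
        }

    def write_report(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.report(), indent=2) + "\n")

    def write_profile(self, observed: Pattern1D, path: str | Path) -> None:
        """4-column obs/calc/diff/background file for difference plotting.

        Points outside the fitted window (the background domain) are omitted.
        """
        lo, hi = self.model.background.domain
        sel = (observed.axis >= lo) & (observed.axis <= hi)
        axis = observed.axis[sel]
        obs = observed.intensity[sel]
        calc = simulate_profile(self.model, axis).intensity
        bg = eval_background(self.model.background, axis)
        lines = ["# two_theta_deg obs calc diff background"]
        for t, o, c, b in zip(axis, obs, calc, bg):
            lines.append(f"{t:.6f} {o:.8e} {c:.8e} {o - c:.8e} {b:.8e}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# refinement


class PawleyRefiner:
    """Whole-powder-pattern (Pawley) refinement of a 1D profile.

    scikit-learn-style estimator: configure in the constructor, call
    :meth:`fit` with an observed :class:`Pattern1D` on a 2θ axis, then read
    fitted attributes (``cell_``, ``zero_shift_``, ``rwp_``, ``result_``...).

    Parameters
    ----------
    cell : UnitCell
        Starting unit cell (e.g. from a related PDB entry); refined.
    space_group : str
        Hermann–Mauguin symbol, one of the supported groups.
    wavelength : float
        Working wavelength in Å.
    n_background : int
        Chebyshev term count (typically 10–14 for cellular backgrounds).
    eta0, W0 : float
        Starting mixing fraction and Caglioti W (deg²).
    refine_profile : bool
        Release η and W in the final stage.
    cell_scan : float or None
        Half-width of a deterministic coarse scan over independent axis
        scale factors before gradient refinement (fractional, e.g. 0.025
        scans ±2.5%).  Guards against starting cells displaced by more than
        a peak width.  None disables the scan.
    max_outer : int
        Maximum reflection-list regeneration cycles.
    """

    _CELL_PARAM_NAMES = {
        LatticeSystem.TETRAGONAL: ("a", "c"),
        LatticeSystem.HEXAGONAL: ("a", "c"),
        LatticeSystem.CUBIC: ("a",),
        LatticeSystem.ORTHORHOMBIC: ("a", "b", "c"),
    }

    def __init__(
        self,
        cell: UnitCell | None = None,
        space_group: str = "P422",
        wavelength: float = 1.24,
        n_background: int = 12,
        eta0: float = 0.5,
        W0: float = 6.25e-4,
        refine_profile: bool = True,
        refine_zero: bool = True,
        cell_scan: float | None = 0.025,
        scan_step: float = 0.005,
        overlap_factor: float = 0.5,
        max_outer: int = 5,
        max_iter: int = 200,
        tol: float = 1e-8,
        fit_range: tuple[float, float] | None = None,
    ):
        self.cell = cell
        self.space_group = space_group
        self.wavelength = wavelength
        self.n_background = n_background
        self.eta0 = eta0
        self.W0 = W0
        self.refine_profile = refine_profile
        self.refine_zero = refine_zero
        self.cell_scan = cell_scan
        self.scan_step = scan_step
        self.overlap_factor = overlap_factor
        self.max_outer = max_outer
        self.max_iter = max_iter
        self.tol = tol
        self.fit_range = fit_range

    # -- sklearn plumbing ---------------------------------------------------

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "cell",
                "space_group",
                "wavelength",
                "n_background",
                "eta0",
                "W0",
                "refine_profile",
                "refine_zero",
                "cell_scan",
                "scan_step",
                "overlap_factor",
                "max_outer",
                "max_iter",
                "tol",
                "fit_range",
            )
        }

    def set_params(self, **params) -> "PawleyRefiner":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- internals ----------------------------------------------------------

    def _make_cell(self, values: Sequence[float]) -> UnitCell:
        names = self._CELL_PARAM_NAMES[self.cell.system]
        kv = dict(zip(names, values))
        sys = self.cell.system
        if sys is LatticeSystem.CUBIC:
            return UnitCell.cubic(kv["a"])
        if sys is LatticeSystem.TETRAGONAL:
            return UnitCell.tetragonal(kv["a"], kv["c"])
        if sys is LatticeSystem.HEXAGONAL:
            return UnitCell.hexagonal(kv["a"], kv["c"])
        return UnitCell.orthorhombic(kv["a"], kv["b"], kv["c"])

    def _cell_values(self, cell: UnitCell) -> np.ndarray:
        return np.array([getattr(cell, n) for n in self._CELL_PARAM_NAMES[cell.system]])

    def _reflections(self, cell: UnitCell, rng: tuple[float, float]) -> list[Reflection]:
        return generate_reflections(cell, self._rules, rng, self.wavelength)

    def _solve_linear(
        self,
        t: np.ndarray,
        y: np.ndarray,
        sqw: np.ndarray,
        reflections: list[Reflection],
        profile: ProfileParams,
        zero: float,
    ):
        """Exact bounded linear solve for background coeffs (free sign) and
        intensities (non-negative)."""
        nb = self.n_background
        basis = cheb.chebvander(self._bg.mapped(t), nb - 1)
        if reflections:
            peaks = _peak_matrix(t, reflections, profile, zero)
            A = np.hstack([basis, peaks])
        else:
            A = basis
        Aw = A * sqw[:, None]
        yw = y * sqw
        # fast path: unconstrained solve; fall back to bounded BVLS only if
        # the non-negativity constraint on intensities is active
        coef = np.linalg.lstsq(Aw, yw, rcond=None)[0]
        if np.any(coef[nb:] < 0):
            lower = np.r_[np.full(nb, -np.inf), np.zeros(A.shape[1] - nb)]
            upper = np.full(A.shape[1], np.inf)
            res = lsq_linear(Aw, yw, bounds=(lower, upper), method="bvls")
            coef = res.x
        resid = yw - Aw @ coef
        return coef[:nb], coef[nb:], resid, A

    def _nl_residual(self, x, names, t, y, sqw, reflections, base_profile):
        profile, zero, cell = self._unpack(x, names, base_profile)
        refl = [
            replace(r, two_theta=tt, d=d, s=s)
            for r, (tt, d, s) in zip(reflections, self._positions(cell, reflections))
        ]
        _, _, resid, _ = self._solve_linear(t, y, sqw, refl, profile, zero)
        return resid

    def _positions(self, cell: UnitCell, reflections: list[Reflection]):
        from .lattice import d_spacing, two_theta_from_d

        out = []
        for r in reflections:
            d = d_spacing(cell, r.hkl)
            tt = two_theta_from_d(d, self.wavelength)
            out.append((tt, d, s_from_two_theta(tt, self.wavelength)))
        return out

    def _unpack(self, x, names, base_profile: ProfileParams):
        x = np.asarray(x, dtype=float)
        kv = dict(zip(names, x))
        zero = kv.get("zero", 0.0)
        cell_names = self._CELL_PARAM_NAMES[self.cell.system]
        if all(n in kv for n in cell_names):
            cell = self._make_cell([kv[n] for n in cell_names])
        else:
            cell = self._fit_cell
        profile = replace(
            base_profile,
            eta=min(max(kv.get("eta", base_profile.eta), 0.0), 1.0),
            W=max(kv.get("W", base_profile.W), 1e-10),
        )
        return profile, zero, cell

    # -- fitting ------------------------------------------------------------

    def fit(self, pattern: Pattern1D, y=None) -> "PawleyRefiner":
        """Refine the model against an observed profile (2θ axis required)."""
        if self.cell is None:
            raise ValueError("a starting cell is required")
        if pattern.axis_kind != AxisKind.TWO_THETA:
            raise ValueError("pattern must be on a 2θ axis; use reduction.convert_axis")
        if self.fit_range is not None:
            lo, hi = self.fit_range
            sel = (pattern.axis >= lo) & (pattern.axis <= hi)
            if sel.sum() < 10:
                raise ValueError("fit_range leaves too few points")
            pattern = Pattern1D(
                pattern.axis_kind,
                pattern.axis[sel],
                pattern.intensity[sel],
                pattern.sigma[sel],
                dict(pattern.meta),
            )
        self._rules = SpaceGroupRules.from_symbol(self.space_group)
        if self._rules.system is not self.cell.system:
            raise ValueError("cell system does not match space group")
        t = pattern.axis
        yobs = pattern.intensity
        w = pattern.weights
        sqw = np.sqrt(w)
        grid_step = float(np.median(np.diff(t)))
        self._bg = BackgroundModel(np.zeros(self.n_background), (float(t[0]), float(t[-1])))
        rng = (float(t[0]), float(t[-1]))
        profile = ProfileParams(eta=self.eta0, W=self.W0)
        zero = 0.0
        cell = self.cell
        history: list[float] = []
        sum_wy2 = float(np.sum(w * yobs**2))

        def rwp_of(resid):
            return 100.0 * math.sqrt(float(resid @ resid) / sum_wy2)

        converged = False
        n_nl_params = 0
        for outer in range(self.max_outer):
            reflections = self._reflections(cell, rng)
            if len(reflections) < 3:
                raise ValueError(
                    "observed range covers fewer than 3 predicted reflections"
                )
            if outer == 0:
                init = equipartition_init(
                    reflections, profile, pattern, self.overlap_factor
                )
                reflections = [
                    replace(r, intensity=float(i)) for r, i in zip(reflections, init)
                ]
            # stage 1: background + intensities (exact linear)
            bg_c, inten, resid, _ = self._solve_linear(
                t, yobs, sqw, reflections, profile, zero
            )
            history.append(rwp_of(resid))

            # stage 2: zero shift + cell (variable projection)
            if outer == 0 and self.cell_scan:
                cell = self._coarse_scan(t, yobs, sqw, reflections, profile, zero, cell)
            names = list(self._CELL_PARAM_NAMES[cell.system])
            x0 = list(self._cell_values(cell))
            lo = [v * 0.9 for v in x0]
            hi = [v * 1.1 for v in x0]
            if self.refine_zero:
                names.append("zero")
                x0.append(zero)
                lo.append(-0.0999)
                hi.append(0.0999)
            self._fit_cell = cell
            ls = least_squares(
                self._nl_residual,
                x0,
                bounds=(lo, hi),
                args=(names, t, yobs, sqw, reflections, profile),
                xtol=1e-12,
                ftol=self.tol,
                gtol=1e-12,
                max_nfev=self.max_iter,
                x_scale=np.maximum(np.abs(x0), 1e-3),
            )
            profile, zero, cell = self._unpack(ls.x, names, profile)
            history.append(rwp_of(ls.fun))

            # stage 3: + profile parameters
            if self.refine_profile:
                names3 = names + ["eta", "W"]
                x3 = list(ls.x) + [profile.eta, profile.W]
                lo3 = lo + [0.0, 1e-10]
                hi3 = hi + [1.0, max(10.0 * profile.W, 1e-2)]
                ls = least_squares(
                    self._nl_residual,
                    x3,
                    bounds=(lo3, hi3),
                    args=(names3, t, yobs, sqw, reflections, profile),
                    xtol=1e-12,
                    ftol=self.tol,
                    gtol=1e-12,
                    max_nfev=self.max_iter,
                    x_scale=np.maximum(np.abs(x3), 1e-4),
                )
                profile, zero, cell = self._unpack(ls.x, names3, profile)
                names = names3
                history.append(rwp_of(ls.fun))
            n_nl_params = len(names)

            # regenerate the reflection list if the cell moved peaks materially
            new_positions = self._positions(cell, reflections)
            max_move = max(
                abs(tt - r.two_theta) for r, (tt, _, _) in zip(reflections, new_positions)
            )
            new_list = self._reflections(cell, rng)
            same_set = [r.hkl for r in new_list] == [r.hkl for r in reflections]
            if max_move <= 0.1 * grid_step and same_set:
                converged = True
                break
            if len(history) >= 6 and abs(history[-1] - history[-4]) < self.tol * max(
                history[-1], 1e-12
            ):
                converged = True
                break

        # final consistent state
        reflections = self._reflections(cell, rng)
        reflections = [
            replace(r, two_theta=tt, d=d, s=s)
            for r, (tt, d, s) in zip(reflections, self._positions(cell, reflections))
        ]
        bg_c, inten, resid, A = self._solve_linear(t, yobs, sqw, reflections, profile, zero)
        reflections = [replace(r, intensity=float(i)) for r, i in zip(reflections, inten)]
        background = BackgroundModel(bg_c, self._bg.domain)
        model = PawleyModel(
            cell, self._rules, self.wavelength, background, profile, zero, reflections
        )
        ycalc = simulate_profile(model, t).intensity
        n_params = A.shape[1] + n_nl_params
        rwp, chi2 = fit_statistics(yobs, ycalc, w, n_params)
        history.append(rwp)
        # Rexp = 100·sqrt((N−P)/Σw y²); GoF² = (Rwp/Rexp)² = χ²_red here
        rexp = 100.0 * math.sqrt((len(t) - n_params) / sum_wy2)
        esds = self._estimate_esds(
            t, yobs, w, model, names if n_nl_params else [], A, chi2
        )
        self.result_ = PawleyResult(
            model=model,
            rwp=rwp,
            chi2_red=chi2,
            gof_sq=(rwp / rexp) ** 2,
            esds=esds,
            n_points=len(t),
            n_params=n_params,
            converged=converged,
            history=history,
        )
        self.model_ = model
        self.cell_ = cell
        self.zero_shift_ = zero
        self.profile_ = profile
        self.background_ = background
        self.intensities_ = inten
        self.rwp_ = rwp
        self.chi2_red_ = chi2
        self.converged_ = converged
        return self

    def _coarse_scan(self, t, yobs, sqw, reflections, profile, zero, cell) -> UnitCell:
        """Deterministic grid scan over independent axis scale factors.

        Protects the gradient stages when the starting cell displaces peaks
        by more than their width.  Axes sharing a value (a=b) scan together.
        """
        span = self.cell_scan
        factors = np.arange(-span, span + 0.5 * self.scan_step, self.scan_step) + 1.0
        names = self._CELL_PARAM_NAMES[cell.system]
        base = self._cell_values(cell)
        best = (np.inf, cell)
        grids = np.meshgrid(*[factors] * len(names), indexing="ij")
        for idx in np.ndindex(grids[0].shape):
            vals = base * np.array([g[idx] for g in grids])
            trial = self._make_cell(vals)
            refl = [
                replace(r, two_theta=tt, d=d, s=s)
                for r, (tt, d, s) in zip(reflections, self._positions(trial, reflections))
            ]
            _, _, resid, _ = self._solve_linear(t, yobs, sqw, refl, profile, zero)
            ssr = float(resid @ resid)
            if ssr < best[0] - 1e-15:
                best = (ssr, trial)
        return best[1]

    def _estimate_esds(self, t, yobs, w, model, nl_names, A_lin, chi2) -> dict:
        """Standard uncertainties from the full numerical Jacobian at the
        solution: esd = sqrt(diag((Jᵀ W J)⁻¹) · χ²_red)."""
        sqw = np.sqrt(w)

        def full_calc(cell_vals, zero, eta, W):
            cell = self._make_cell(cell_vals)
            prof = replace(model.profile, eta=min(max(eta, 0.0), 1.0), W=max(W, 1e-12))
            refl = [
                replace(r, two_theta=tt, d=d, s=s)
                for r, (tt, d, s) in zip(
                    model.reflections, self._positions(cell, model.reflections)
                )
            ]
            m = PawleyModel(
                cell, model.rules, model.wavelength, model.background, prof, zero, refl
            )
            return simulate_profile(m, t).intensity

        cell_vals = self._cell_values(model.cell)
        p0 = np.r_[cell_vals, model.zero_shift, model.profile.eta, model.profile.W]
        active = list(range(len(cell_vals)))
        labels = list(self._CELL_PARAM_NAMES[model.cell.system])
        if "zero" in nl_names:
            active.append(len(cell_vals))
            labels.append("zero_shift")
        if "eta" in nl_names:
            active += [len(cell_vals) + 1, len(cell_vals) + 2]
            labels += ["eta", "W"]

        def calc_at(p):
            return full_calc(p[: len(cell_vals)], p[len(cell_vals)], p[-2], p[-1])

        cols = [A_lin * sqw[:, None]]
        for i in active:
            h = max(1e-6 * abs(p0[i]), 1e-8)
            pp, pm = p0.copy(), p0.copy()
            pp[i] += h
            pm[i] -= h
            cols.append(((calc_at(pp) - calc_at(pm)) / (2 * h) * sqw)[:, None])
        J = np.hstack(cols)
        try:
            cov = np.linalg.pinv(J.T @ J) * chi2
            d = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            return {"degenerate": True}
        n_lin = A_lin.shape[1]
        nb = self.n_background
        out: dict = {
            "background": d[:nb].tolist(),
            "intensities": d[nb:n_lin].tolist(),
            "cell": {},
        }
        for j, lab in enumerate(labels):
            v = float(d[n_lin + j])
            if lab in ("a", "b", "c"):
                out["cell"][lab] = v
            else:
                out[lab if lab != "zero_shift" else "zero_shift"] = v
        return out


def pawley_refine(
    observed: Pattern1D, start: PawleyModel, **config
) -> PawleyResult:
    """Functional wrapper over :class:`PawleyRefiner`.

    ``start`` supplies the cell, space group, wavelength and starting
    profile; keyword arguments forward to the refiner.
    """
    ref = PawleyRefiner(
        cell=start.cell,
        space_group=start.rules.symbol,
        wavelength=start.wavelength,
        eta0=start.profile.eta,
        W0=start.profile.W,
        **config,
    )
    ref.fit(observed)
    return ref.result_
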
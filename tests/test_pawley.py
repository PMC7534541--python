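"""Profile primitives, background, simulation and Pawley refinement."""

import math
from dataclasses import replace

import numpy as np
import pytest
from numpy.polynomial import chebyshev as cheb

from powderscreen.lattice import SpaceGroupRules, UnitCell, generate_reflections
from powderscreen.pawley import (
    BackgroundModel,
    PawleyModel,
    PawleyRefiner,
    ProfileParams,
    equipartition_init,
    eval_background,
    fit_statistics,
    fwhm_caglioti,
    pseudo_voigt,
    simulate_profile,
)
from powderscreen.reduction import AxisKind, Pattern1D


# ---------------------------------------------------------------------------
# pseudo-Voigt


def test_pseudo_voigt_apex_closed_forms():
    gamma = 0.03
    assert pseudo_voigt(0.0, gamma, 0.0) == pytest.approx(
        2 * math.sqrt(math.log(2) / math.pi) / gamma, rel=1e-12
    )
    assert pseudo_voigt(0.0, gamma, 1.0) == pytest.approx(2 / (math.pi * gamma), rel=1e-12)


@pytest.mark.parametrize("eta", [0.0, 0.5, 1.0])
def test_pseudo_voigt_unit_area(eta):
    # Lorentzian tails carry 2/(πN) beyond ±NΓ/2, so a wide window is needed
    gamma = 0.02
    x = np.linspace(-1000 * gamma, 1000 * gamma, 2000001)
    area = np.trapezoid(pseudo_voigt(x, gamma, eta), x)
    assert area == pytest.approx(1.0, abs=1e-3)


def test_pseudo_voigt_rejects_bad_params():
    with pytest.raises(ValueError):
        pseudo_voigt(0.0, -1.0, 0.5)
    with pytest.raises(ValueError):
        pseudo_voigt(0.0, 1.0, 1.5)


# ---------------------------------------------------------------------------
# Caglioti FWHM


def test_caglioti_limits_and_hand_value():
    assert fwhm_caglioti(0.0, 0.01, 0.001, 4e-4) == pytest.approx(0.02)
    assert fwhm_caglioti(37.0, 0.0, 0.0, 4e-4) == pytest.approx(0.02)
    t = math.tan(math.radians(1.0))
    expected = math.sqrt(0.01 * t * t + 0.001 * t + 4e-4)
    assert fwhm_caglioti(1.0, 0.01, 0.001, 4e-4) == pytest.approx(expected, rel=1e-12)
    with pytest.raises(ValueError):
        fwhm_caglioti(1.0, 0.0, 0.0, -1e-4)


# ---------------------------------------------------------------------------
# Chebyshev background


def test_background_constant_and_linear_terms():
    bg = BackgroundModel((5.0,), (0.4, 2.0))
    grid = np.linspace(0.4, 2.0, 11)
    assert np.allclose(eval_background(bg, grid), 5.0)
    bg1 = BackgroundModel((0.0, 1.0), (0.4, 2.0))
    vals = eval_background(bg1, grid)
    assert vals[0] == pytest.approx(-1.0)
    assert vals[-1] == pytest.approx(1.0)


def test_background_matches_recurrence_oracle():
    """chebval agrees with a hand-rolled T_j recurrence to 1e-12."""
    rng = np.random.default_rng(7)
    coeffs = rng.normal(size=12)
    bg = BackgroundModel(coeffs, (0.3, 2.4))
    grid = np.linspace(0.3, 2.4, 257)
    x = 2 * (grid - 0.3) / (2.4 - 0.3) - 1
    t_prev, t_cur = np.ones_like(x), x.copy()
    total = coeffs[0] * t_prev + coeffs[1] * t_cur
    for c in coeffs[2:]:
        t_prev, t_cur = t_cur, 2 * x * t_cur - t_prev
        total += c * t_cur
    assert np.allclose(eval_background(bg, grid), total, atol=1e-12)


def test_background_rejects_out_of_domain():
    bg = BackgroundModel((1.0,), (0.4, 2.0))
    with pytest.raises(ValueError):
        eval_background(bg, np.array([0.1]))


# ---------------------------------------------------------------------------
# simulation


def _toy_model(intensities=(100.0, 50.0, 80.0), zero=0.0, bg_coeffs=(20.0, -3.0)):
    cell = UnitCell.tetragonal(125.69, 54.408)
    rules = SpaceGroupRules.from_symbol("P42212")
    refl = generate_reflections(cell, rules, (0.4, 1.3), 1.24)[: len(intensities)]
    refl = [replace(r, intensity=v) for r, v in zip(refl, intensities)]
    return PawleyModel(
        cell,
        rules,
        1.24,
        BackgroundModel(bg_coeffs, (0.35, 1.4)),
        ProfileParams(eta=0.5, W=6.25e-4),
        zero,
        refl,
    )


def test_zero_intensities_reproduce_background():
    model = _toy_model(intensities=(0.0, 0.0, 0.0))
    grid = np.linspace(0.4, 1.3, 500)
    p = simulate_profile(model, grid)
    assert np.allclose(p.intensity, eval_background(model.background, grid))


def test_single_reflection_apex_at_shifted_center():
    model = _toy_model(intensities=(100.0,), zero=0.01, bg_coeffs=(0.0,))
    model = replace(model, reflections=model.reflections[:1])
    grid = np.linspace(0.4, 1.3, 2000)
    p = simulate_profile(model, grid)
    apex = grid[np.argmax(p.intensity)]
    expected = model.reflections[0].two_theta + 0.01
    assert abs(apex - expected) <= (grid[1] - grid[0])


def test_intensity_doubling_is_linear():
    model = _toy_model()
    grid = np.linspace(0.4, 1.3, 800)
    base = eval_background(model.background, grid)
    y1 = simulate_profile(model, grid).intensity - base
    y2 = simulate_profile(model.with_intensities(2 * model.intensities), grid).intensity - base
    assert np.allclose(y2, 2 * y1, rtol=1e-12)


# ---------------------------------------------------------------------------
# equipartition


def test_equipartition_splits_coincident_group_equally():
    cell = UnitCell.tetragonal(100.0, 50.0)
    rules = SpaceGroupRules.from_symbol("P422")
    base = generate_reflections(cell, rules, (0.4, 1.0), 1.24)[0]
    refl = [replace(base, two_theta=0.8) for _ in range(3)]
    profile = ProfileParams(W=6.25e-4)
    grid = np.linspace(0.4, 1.2, 2000)
    y = 300.0 / 0.06 * ((np.abs(grid - 0.8) < 0.03).astype(float))  # area 300 box
    observed = Pattern1D(AxisKind.TWO_THETA, grid, y, np.ones_like(y))
    init = equipartition_init(refl, profile, observed)
    assert np.allclose(init, init[0])
    assert init[0] == pytest.approx(100.0, rel=0.05)


def test_equipartition_groups_match_single_linkage_oracle():
    rng = np.random.default_rng(11)
    cell = UnitCell.tetragonal(100.0, 50.0)
    rules = SpaceGroupRules.from_symbol("P422")
    base = generate_reflections(cell, rules, (0.4, 1.0), 1.24)[0]
    centers = np.sort(rng.uniform(0.5, 2.0, 15))
    refl = [replace(base, two_theta=float(c)) for c in centers]
    profile = ProfileParams(W=6.25e-4)
    fwhm = 0.025
    threshold = 0.5 * fwhm
    # brute-force single-linkage chaining
    groups = [[0]]
    for i in range(1, len(centers)):
        if centers[i] - centers[i - 1] <= threshold:
            groups[-1].append(i)
        else:
            groups.append([i])
    grid = np.linspace(0.4, 2.2, 3000)
    y = np.zeros_like(grid)
    for c in centers:
        y += 50 * np.exp(-0.5 * ((grid - c) / 0.01) ** 2)
    observed = Pattern1D(AxisKind.TWO_THETA, grid, y, np.ones_like(y))
    init = equipartition_init(refl, profile, observed)
    # members of one oracle group share one initial value
    for grp in groups:
        assert np.allclose(init[grp], init[grp[0]])


def test_well_separated_peaks_get_individual_areas():
    cell = UnitCell.tetragonal(100.0, 50.0)
    rules = SpaceGroupRules.from_symbol("P422")
    base = generate_reflections(cell, rules, (0.4, 1.0), 1.24)[0]
    refl = [replace(base, two_theta=0.6), replace(base, two_theta=1.4)]
    grid = np.linspace(0.4, 1.8, 3000)
    y = np.zeros_like(grid)
    y += 100 * np.exp(-0.5 * ((grid - 0.6) / 0.01) ** 2)
    y += 300 * np.exp(-0.5 * ((grid - 1.4) / 0.01) ** 2)
    observed = Pattern1D(AxisKind.TWO_THETA, grid, y, np.ones_like(y))
    init = equipartition_init(refl, ProfileParams(W=6.25e-4), observed)
    assert init[1] > 2.5 * init[0]


# ---------------------------------------------------------------------------
# fit statistics


def test_fit_statistics_hand_example():
    rwp, chi2 = fit_statistics([1.0, 2.0], [1.0, 1.0], [1.0, 1.0], 0)
    assert rwp == pytest.approx(100 * math.sqrt(1 / 5))
    assert chi2 == pytest.approx(0.5)


def test_fit_statistics_perfect_fit_and_scale_invariance():
    y = np.array([1.0, 2.0, 3.0])
    rwp, chi2 = fit_statistics(y, y, np.ones(3), 0)
    assert rwp == 0.0 and chi2 == 0.0
    rng = np.random.default_rng(8)
    yo, yc = rng.uniform(1, 5, 20), rng.uniform(1, 5, 20)
    w = rng.uniform(0.5, 2, 20)
    r1, _ = fit_statistics(yo, yc, w, 3)
    r2, _ = fit_statistics(7 * yo, 7 * yc, w, 3)
    assert r1 == pytest.approx(r2, rel=1e-12)


def test_fit_statistics_rejects_overparameterized():
    with pytest.raises(ValueError):
        fit_statistics([1.0, 2.0], [1.0, 2.0], [1.0, 1.0], 2)


# ---------------------------------------------------------------------------
# refinement


@pytest.fixture(scope="module")
def noisefree_observed():
    """Noise-free profile simulated from a known model on a 12-term background."""
    rng = np.random.default_rng(9)
    cell = UnitCell.tetragonal(125.69, 54.408)
    rules = SpaceGroupRules.from_symbol("P42212")
    grid = np.linspace(0.4, 2.0, 1500)
    refl = generate_reflections(cell, rules, (0.4, 2.0), 1.24)
    refl = [replace(r, intensity=float(v)) for r, v in zip(refl, rng.uniform(20, 200, len(refl)))]
    coeffs = np.zeros(12)
    coeffs[0] = 500.0
    coeffs[1] = -80.0
    coeffs[2] = 15.0
    model = PawleyModel(
        cell,
        rules,
        1.24,
        BackgroundModel(coeffs, (float(grid[0]), float(grid[-1]))),
        ProfileParams(eta=0.5, W=6.25e-4),
        0.0,
        refl,
    )
    p = simulate_profile(model, grid)
    return model, Pattern1D(AxisKind.TWO_THETA, grid, p.intensity, np.full(len(grid), 1.0))


def test_refinement_fixed_point_on_noise_free_data(noisefree_observed):
    """Starting at the generating parameters, refinement must not move."""
    model, observed = noisefree_observed
    ref = PawleyRefiner(
        cell=model.cell,
        space_group="P42212",
        wavelength=1.24,
        n_background=12,
        cell_scan=None,
        refine_profile=False,
    )
    ref.fit(observed)
    assert ref.rwp_ < 1e-6
    assert ref.cell_.a == pytest.approx(125.69, rel=1e-8)
    assert ref.cell_.c == pytest.approx(54.408, rel=1e-8)


def test_intensities_match_closed_form_linear_solution(noisefree_observed):
    """With cell, zero and profile frozen, Pawley intensities equal the
    weighted linear least-squares solution."""
    from powderscreen.pawley import _peak_matrix

    model, observed = noisefree_observed
    ref = PawleyRefiner(
        cell=model.cell,
        space_group="P42212",
        wavelength=1.24,
        n_background=12,
        cell_scan=None,
        refine_profile=False,
        refine_zero=False,
        max_outer=1,
    )
    ref.fit(observed)
    # closed form on the same design matrix
    t = observed.axis
    sqw = np.sqrt(observed.weights)
    basis = cheb.chebvander(
        2 * (t - t[0]) / (t[-1] - t[0]) - 1, ref.n_background - 1
    )
    peaks = _peak_matrix(t, model.reflections, ref.profile_, ref.zero_shift_)
    A = np.hstack([basis, peaks]) * sqw[:, None]
    coef, *_ = np.linalg.lstsq(A, observed.intensity * sqw, rcond=None)
    expected = coef[ref.n_background:]
    assert np.allclose(ref.intensities_, expected, rtol=1e-8, atol=1e-8 * expected.max())


def test_history_non_increasing(noisefree_observed):
    model, observed = noisefree_observed
    start = UnitCell.tetragonal(125.69 * 1.005, 54.408 * 1.005)
    ref = PawleyRefiner(cell=start, space_group="P42212", wavelength=1.24, n_background=12)
    ref.fit(observed)
    h = ref.result_.history
    assert all(b <= a * (1 + 1e-9) + 1e-12 for a, b in zip(h, h[1:]))


def test_recovery_from_perturbed_start(catb_pair):
    """±2% perturbed starting cells recover the generating CatB cell to 0.05%."""
    sample, _ = catb_pair
    ref = PawleyRefiner(
        cell=UnitCell.tetragonal(125.69 * 1.02, 54.408 * 1.02),
        space_group="P42212",
        wavelength=1.24,
        fit_range=(0.4, 2.4),
    )
    ref.fit(sample)
    assert ref.converged_
    assert abs(ref.cell_.a - 125.69) / 125.69 < 5e-4
    assert abs(ref.cell_.c - 54.408) / 54.408 < 5e-4
    assert abs(ref.zero_shift_) < 0.005
    assert ref.chi2_red_ < 2.0  # proper Poisson noise model → χ²_red ≈ 1


def test_esds_are_finite_on_noisy_data(catb_pair):
    """Intensity/background trade-off is identifiable: esds exist and are finite."""
    sample, _ = catb_pair
    ref = PawleyRefiner(
        cell=UnitCell.tetragonal(125.69, 54.408),
        space_group="P42212",
        wavelength=1.24,
        fit_range=(0.4, 2.4),
        cell_scan=None,
    )
    ref.fit(sample)
    esds = ref.result_.esds
    assert np.isfinite(esds["cell"]["a"]) and esds["cell"]["a"] > 0
    assert np.isfinite(esds["zero_shift"])
    assert all(np.isfinite(v) for v in esds["intensities"])


def test_report_round_trip(tmp_path, catb_pair):
    sample, _ = catb_pair
    sel = (sample.axis >= 0.4) & (sample.axis <= 2.4)
    cropped = Pattern1D(
        sample.axis_kind, sample.axis[sel], sample.intensity[sel], sample.sigma[sel]
    )
    ref = PawleyRefiner(
        cell=UnitCell.tetragonal(125.69, 54.408),
        space_group="P42212",
        wavelength=1.24,
        cell_scan=None,
        refine_profile=False,
    )
    ref.fit(cropped)
    ref.result_.write_report(tmp_path / "report.json")
    ref.result_.write_profile(cropped, tmp_path / "profile.dat")
    import json

    rep = json.loads((tmp_path / "report.json").read_text())
    assert rep["space_group"] == "P42212"
    assert rep["rwp_percent"] == pytest.approx(ref.rwp_)
    lines = (tmp_path / "profile.dat").read_text().strip().splitlines()
    assert len(lines) == ref.result_.n_points + 1


def test_zero_shift_bound_enforced():
    with pytest.raises(ValueError):
        PawleyModel(
            UnitCell.tetragonal(100, 50),
            SpaceGroupRules.from_symbol("P422"),
            1.24,
            BackgroundModel((0.0,), (0.0, 2.0)),
            zero_shift=0.2,
        )
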
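# Methods

## The measurement being modelled

A dense suspension of insect cells is exposed in a 1.8 mm quartz capillary
to a 10 keV (λ = 1.24 Å) X-ray beam of 0.20 × 0.12 mm at a 3.00 m
sample–detector distance. 40 detector frames of 0.045 s are recorded per
sample, followed by 40 frames of the matching buffer (readout 0.005 s), so
one data set takes (40+40)·(0.045+0.005) = 4 s. The rectangular-beam
approximation of the interrogated volume is 0.20·0.12·1.8 = 0.043 mm³ —
several thousand cells of ~30 µm diameter. If a fraction of those cells
contain protein microcrystals, the randomly oriented crystallites imprint
Debye–Scherrer rings on the 2D frames and Bragg peaks on the radially
averaged 1D profile; the peak positions are a fingerprint of the crystal's
unit cell, while the cellular and buffer scattering form a smooth,
monotonically decaying background.

## Reduction

Frames are summed (counts and exposures add; the mask is shared), then
binned by pixel-center scattering angle 2θ = atan(r/D) into equal-width
bins (default 2000). Bin intensity is the mean pixel count and bin sigma
the Poisson estimate √(Σcounts)/n<sub>pix</sub>; empty bins are dropped.
There is no pixel splitting: at 3 m a bin spans many pixels and splitting
changes nothing measurable. No polarization or solid-angle correction is
applied by default (a per-pixel correction hook exists) because the
analysis keys on relative peak positions, which these corrections do not
move. Buffer subtraction is pointwise with a single global scale (default
1.0; transmission factors are a config field, not estimated), errors add in
quadrature, and negative intensities are retained — clipping would bias the
noise statistics that peak significance relies on. Axis conversion
s = 4π sin θ/λ relabels points without Jacobian re-weighting; profiles stay
counts-per-original-bin.

## Screening

The baseline is a SNIP-style iterated clip: each point is replaced by the
minimum of itself and the mean of its m-distant neighbours, m shrinking
from `half_window` (default 50 points) to 1; points without both
neighbours in range are left untouched, since clipping against a clamped
edge drags the ends of steeply decaying profiles downward. Convex smooth
decays are fixed points of the operation; narrow peaks are clipped to the
interpolation of their flanks. The local noise scale is 1.4826 × the
sliding median absolute deviation of (profile − baseline) over a 201-point
window — robust to the peaks themselves — floored at 10⁻¹² of the profile
scale so noise-free input yields finite SNRs. A peak is a run of ≥ 3
consecutive points exceeding baseline + k·σ (default k = 5); its position
is the intensity-weighted centroid of the excess. A sample is
`crystal_present` when ≥ 2 peaks reach k·σ: one excursion is not proof of
crystallinity. The window defaults suit the default binning (peaks 5–25
points wide); both are configurable.

Known limitation: at high crystal fraction the pseudo-Voigt tails leak into
the MAD window and inflate the noise estimate, so reported SNRs compress
toward ~50–80 even when the Poisson-limited SNR is far higher. Detection
calls are unaffected (the compression only biases strong peaks downward),
but reported SNR ratios between very strong and weak samples understate the
true intensity ratios.

## Phase clustering

Profiles restricted to the 0.4–2.0° 2θ window are interpolated onto a
common grid, normalized to unit total intensity (clustering should key on
peak *positions*, not crystal-fraction amplitude), mean-centred, and
projected onto the first 3 principal components; average-linkage Euclidean
agglomeration in PC space is cut at a user-supplied cluster count — the
experimenter knows how many constructs were measured, and silent model
selection is avoided (a silhouette-based auto-k exists but is never the
default). Labels are canonicalized by first occurrence, making them
invariant under input permutation. Zero-variance input is reported as
degenerate rather than clustered.

## Pawley refinement

The model is
y(2θ) = Σ c<sub>j</sub> T<sub>j</sub>(x) + Σ<sub>k</sub> I<sub>k</sub> m<sub>k</sub> PV(2θ − (2θ<sub>k</sub> + Z); Γ, η),
with a shifted Chebyshev background (x the affine map of the fit window
onto [−1,1]; term count default 12, the 10–14 range is a config value),
unit-area pseudo-Voigt peaks of common FWHM Γ(θ) = √(U tan²θ + V tanθ + W),
zero shift Z bounded to |Z| < 0.1°, and free per-reflection intensities —
the Pawley approach: no structural model, so the profile constrains only
the cell, peak shape and background. Reflection positions come from the
cell and the space group's reflection conditions; symmetry-equivalent
reflections are merged per orbit with their multiplicity (merging keys on
the symmetry orbit, not on d alone, so accidental degeneracies remain
separate intensity parameters).

Refinement is staged, releasing parameters gradually: (1) background +
intensities — an exactly solvable linear problem (unconstrained solve with
a bounded-variable fallback enforcing I<sub>k</sub> ≥ 0; non-negativity
prevents oscillating compensation with the background); (2) + zero shift
and cell; (3) + profile parameters (η and W; U, V and the single asymmetry
coefficient exist but default off — the exact FWHM/asymmetry
parameterization used by commercial WPPF suites is not published, so the
symmetric Caglioti baseline is the testable choice, and the fit report
carries a note to that effect). The nonlinear stages use variable
projection (trust-region least squares over the nonlinear parameters with
the linear ones re-solved per evaluation), so accepted steps can only
reduce the weighted SSR. Because a ±2% starting-cell error can displace
peaks by more than their width, stage 2 is preceded by a deterministic
coarse scan over independent axis scale factors (±2.5% in 0.5% steps by
default) before gradient refinement. The reflection list is regenerated
whenever the refined cell moves a predicted position by more than 0.1 grid
steps. Convergence: relative SSR change < 10⁻⁸ or 200 iterations;
non-convergence is flagged, not raised.

Initial intensities are equipartitioned: reflections chained into overlap
groups when neighbouring centers fall within 0.5 × the mean FWHM
(single-linkage), and each group's above-local-baseline observed area is
split equally among members — with unresolvable overlap there is no
information to do better, and the refinement redistributes intensity
gradually.

R<sub>wp</sub> is reported in percent (matching the usual 0.5–3% magnitudes
for good fits at this resolution). χ² is reported as reduced
χ² = Σw r²/(N−P); since goodness-of-fit conventions differ between
packages, (R<sub>wp</sub>/R<sub>exp</sub>)² is also emitted. Parameter
esds come from the full numerical Jacobian at the solution,
√(diag((JᵀWJ)⁻¹)·χ²<sub>red</sub>), via pseudo-inverse so bound-active
intensities do not abort the error estimate.

The fit window defaults to the full profile but pipeline runs restrict to
0.4–2.4° 2θ: below ~0.3° the forward-scattering divergence of the cellular
background (∝ s⁻³) exceeds what a 10–14-term polynomial can follow, and
its weighted misfit destabilizes the profile stage. This mirrors the
restriction of the clustering analysis to the low-angle window.

Not in scope: Rietveld (structure-factor) refinement, ab initio indexing
(too few peaks survive the cellular background), and size/strain
microstructure analysis.

## Synthetic data

The generator reproduces the statistical structure of the experiment, not
its physics. The cellular/buffer background is the simplest monotone
Porod-like family A·s^(−p) + C (default A = 1, p = 3, C = 50 counts/s per
bin) that matches a peak-free decaying control. The Bragg component is
built from the reflection list of a chosen cell/space group with seeded
log-normal per-reflection mean intensities (σ_log = 1.0) — a Pawley fit
extracts nothing beyond free intensities, so simulating structure factors
would add realism the analysis cannot see. The phase's intensity seed is
fixed per phantom so its fingerprint is stable across noise realizations
and dilution steps. Counts are Poisson at the summed-series exposure
(1.8 s); the sample adds the Bragg term scaled linearly by the
crystal-cell fraction (dilution with mock-infected cells at fixed crystal
volume per cell). The intensity scale (default 18) was set once so a
full-fraction sample reports a maximum SNR of order 50–80 — strong but not
saturating, the regime the screening experiment operates in. Four preset
phantoms carry the study phases: Luc (P4₁2₁2, a=b=129.13 Å, c=97.1 Å),
IMPDH (P42₁2, 209.3/93.44 Å), CatB (P4₂2₁2, 125.69/54.408 Å) and HEX-1
(P6₅22, 58.01/195.2 Å).

Detector-frame simulation paints, per crystallite and reflection, a
Bernoulli spot (probability ∝ multiplicity × rocking fraction) at ring
radius r = D·tan 2θ and a uniform random azimuth, as a 1-pixel Gaussian;
rings beyond the detector edge truncate naturally. Azimuthal granularity
therefore decreases as the crystallite count grows, which is the property
tests check. A smooth radial background is added and each frame receives
an independent Poisson draw.

What passing tests do and do not show: the generator has no absorption,
polarization, detector distortion, inter-cell size variation or
crystallite-size peak broadening, and its SNR is in arbitrary units — so
unit-cell recovery, phase separation and dilution *ordering* transfer to
real data, but absolute detection-limit percentages do not. Generator-
default dilution series remain detectable to deeper dilutions (~2⁷) than
the real instrument (~16-fold); the SNR-halving boundary behaviour is
therefore verified on an analytically constructed series (a triangle-wave
dither whose sliding MAD is exactly known, with flat-top peaks dialled to
SNR 40/2^j), where positives end exactly where k·σ arithmetic predicts.

## Problem sizes

Default grids are 2000 points over 0.1–2.4° 2θ; Pawley acceptance
protocols use 20 seeded replicates per phase (median reported); PCA uses 3
replicates × 4 phases; Monte-Carlo mean tests use 30–60 replicates on
600-point grids; detector simulations use a 128×128 test geometry with
1.5 mm pixels standing in for a large photon-counting detector.
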
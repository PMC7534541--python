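# powderscreen

SAXS/XRPD screening of protein microcrystals grown inside living insect
cells.

Recombinant proteins expressed in baculovirus-infected insect cells can
crystallize spontaneously *in cellulo*, often in only a small fraction of
cells and with crystals too small or fragile for light-microscopy scoring.
A low-background bioSAXS beamline can settle the question in seconds: a
dense cell suspension in a capillary is exposed for a few seconds, and if
crystals are present the randomly oriented crystallites produce granular
Debye–Scherrer rings — Bragg peaks in the radially averaged 1D scattering
profile at momentum transfers *s* = 4π sin θ/λ fixed by the crystal's unit
cell. `powderscreen` implements the full analysis pipeline behind that
screen:

- **reduction** — sum 2D photon-counting detector frames, radially average
  them into 1D profiles *I*(*s*) or *I*(2θ) with Poisson uncertainties, and
  subtract the matched buffer measurement;
- **screening** — call Bragg peaks against the smooth cellular background
  (SNIP-clipped baseline, robust MAD noise scale) and decide
  `crystal_present` when ≥ 2 peaks exceed *k*·σ (default 5σ);
- **phase clustering** — PCA of *I*(2θ) over the 0.4–2.0° 2θ window plus
  average-linkage agglomeration, separating crystal phases by their peak
  fingerprint without indexing;
- **pawley** — whole-powder-pattern (Pawley) fitting: pseudo-Voigt peaks
  with Caglioti FWHM Γ² = *U* tan²θ + *V* tanθ + *W*, a shifted Chebyshev
  background (~10–14 terms), an instrumental zero shift, and one free
  non-negative intensity per symmetry-distinct reflection, refining the
  unit cell and reporting R<sub>wp</sub> = 100·√(Σw(y₀−y꜀)²/Σw·y₀²) and
  reduced χ²;
- **lattice** — d-spacings, reflection-list generation and systematic
  absences for the four relevant space groups (P4₁2₁2, P42₁2, P4₂2₁2,
  P6₅22) plus translation-free primitive groups;
- **synthetic** — a seeded generator reproducing the statistical structure
  of the experiment (Porod-like cellular background, Bragg component from a
  chosen cell, granular rings from a finite crystallite count, Poisson
  noise, paired sample/buffer series, 1:2 dilution series), so the entire
  pipeline is testable without beamline data.

Fitting and clustering are exposed as scikit-learn-style estimators
(`PawleyRefiner`, `PhaseClusterer`, `CrystalScreener`) with functional
wrappers.

## Worked example

Simulate a CatB-like sample (tetragonal P4₂2₁2, a = b = 125.69 Å,
c = 54.408 Å) at the default acquisition settings (10 keV / 1.24 Å, 3 m
detector distance, 40 + 40 frames × 0.045 s), screen it, and refine the
cell starting from a +2% perturbed guess:

```python
from powderscreen import (ExperimentConfig, PawleyRefiner, UnitCell,
                          classify_crystal_content, paper_phantoms,
                          simulate_profile_pair)
from powderscreen.synthetic import default_grid

phantom = paper_phantoms()["catb"]
cfg = ExperimentConfig(seed=1)
sample, buffer = simulate_profile_pair(phantom, cfg, default_grid(), rng=1)

screen = classify_crystal_content(sample, buffer)
print(f"crystal_present={screen.crystal_present}  n_peaks={len(screen.peaks)}  "
      f"max SNR={screen.score:.1f}")

start = UnitCell.tetragonal(125.69 * 1.02, 54.408 * 1.02)
ref = PawleyRefiner(cell=start, space_group="P42212", wavelength=1.24,
                    fit_range=(0.4, 2.4)).fit(sample)
print(f"refined a = {ref.cell_.a:.3f} A  c = {ref.cell_.c:.3f} A  "
      f"zero = {ref.zero_shift_:+.4f} deg")
print(f"Rwp = {ref.rwp_:.2f} %  chi2_red = {ref.chi2_red_:.2f}  "
      f"converged = {ref.converged_}")
```

Output:

```
crystal_present=True  n_peaks=9  max SNR=39.4
refined a = 125.687 A  c = 54.407 A  zero = -0.0000 deg
Rwp = 1.30 %  chi2_red = 1.03  converged = True
```

The screen finds nine significant Bragg peaks (so the sample contains
crystalline material), and the Pawley fit pulls the 2%-off starting cell
back to the generating values within ~0.003%, with a weighted profile
residual of 1.3% and a reduced χ² of ~1 (the noise model is exact here, so
χ² ≈ 1 is the expected value for a correct fit).

The same pipeline is scriptable from the shell:

```sh
powderscreen simulate --seed 7 --out fixtures/
powderscreen screen fixtures/*.dat --out screen/
powderscreen cluster fixtures/catb.dat fixtures/hex1.dat fixtures/luc.dat \
    fixtures/impdh.dat --out cluster/ --k 4
powderscreen refine fixtures/catb.dat --space-group P42212 \
    --cell 128.2,55.5 --out refine/
powderscreen dilution --seed 2 --n-steps 5 --out dilution/
```

Every command writes a `manifest.json` (config hash, seed, version) so
deterministic stages reproduce bit-identically.

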
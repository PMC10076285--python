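# Methods

This note documents the models behind `confmap`, the defaults it ships, what
the synthetic-data generators do and do not emulate, and the numerical
choices made where the design was open.

## Differential HDx-MS

### Uptake model

Backbone amide hydrogens exchange with solvent deuterium at a rate set by
structure. For a peptic peptide observed after labeling time *t*, the
relative fractional uptake is

    RFU = uptake (Da) / N_amides

where `N_amides` counts exchangeable backbone amides: peptide length minus
one (the N-terminal residue loses its label during workup) minus prolines at
positions 2..L (no amide hydrogen). This matches the MaxUptake convention of
common state-data exports; the stricter convention that also drops the
second residue is available via `exchangeable_amides(..., n_term_excluded=2)`.

The differential between conditions A and B is `ΔRFU = RFU_A − RFU_B`;
positive values mean the peptide is more solvent-exposed (deprotected) in A.
Analyses are per exposure; the 0 min row is the unlabeled control and never
enters statistics.

### Hybrid significance test

A peptide/exposure is called significant only if both conditions hold:

1. |Δuptake| exceeds a global threshold
   `t(1−α/2, 2n−2) · sqrt(s̄_A²/n + s̄_B²/n)`, where s̄ is the
   root-mean-square replicate SD pooled over all peptides and exposures of a
   state and n is the replicate count;
2. a per-peptide Welch two-sample t-test on the replicate uptakes rejects at
   the same α.

The intersection of a global variance filter with a per-peptide test is what
keeps the false discovery rate low without an explicit multiplicity
correction; no additional FDR adjustment is applied. `global-only` and
`ttest-only` modes expose each arm separately. Cells with zero variance in
both states are assigned p = 1 when the difference is exactly 0 (an exact
self-comparison) and p = 0 otherwise.

### Structure mapping

Per-residue values are the unweighted mean ΔRFU over all retained peptides
covering the residue (min/max reducers available; a `skip_first_residue`
flag drops each peptide's signal-free first position). Values are written
into PDB B-factor columns 61–66 at two decimals; every other byte of the
input file is preserved. Uncovered residues carry the sentinel 999.99,
chosen because attainable |ΔRFU| ≤ 1 can never collide with it. Reported
color-scale limits are ±max|ΔRFU| so that zero maps to the midpoint of a
diverging palette.

## ATR-FTIR secondary structure

### Preprocessing

Fixed order, applied identically to calibration and prediction spectra:

1. **Water-vapor subtraction.** The vapor reference is scaled by the plain
   least-squares projection coefficient over 1956–1935 cm⁻¹ (a window where
   protein absorbance is flat and vapor lines are strong) and subtracted in
   full. Projection guarantees the window RMS never increases.
2. **Baseline.** Straight lines interpolated between the spectrum's values
   at 3700, 3000, 2800, 1720, 1480, 1204 and 980 cm⁻¹ are subtracted; the
   output is exactly zero at each anchor. Points outside 980–3700 cm⁻¹ are
   left untouched.
3. **Area normalization.** The whole spectrum is scaled so the trapezoid
   integral over the amide-I window (1720–1480 cm⁻¹) equals 1 AU·cm⁻¹ (the
   normalization constant is a free choice; unity makes prediction invariant
   to instrument throughput and loading).

The chain is exactly idempotent when the scaling reference is locally
baseline-free (zero mean and tilt over the scaling window); the bundled
synthetic reference is constructed that way, so rerunning the chain on its
own output reproduces it to machine precision.

### Calibration

For each structure class (α-helix, β-sheet, turns, random coil) an ascending
stepwise regression greedily adds the amide-I wavenumber that most reduces
the residual sum of squares of a linear fit of class percentage on selected
absorbances, stopping at three wavenumbers or when the relative RSS
improvement falls below 1e-4 (an F-to-enter criterion would be an
alternative stopping rule; the RSS tolerance keeps the noiseless planted
case exact). Candidates that do not increase the design rank are skipped.
Classes are fit independently with no sum-to-100 constraint, so each row of
a prediction is reported verbatim with an out-of-range flag where needed.

The standard error of prediction (SEP) is the RMS leave-one-out error with
the wavenumber selection re-run inside every fold, so selection instability
is charged to the reported error. Calibration requires spectra preprocessed
identically to later prediction inputs — in particular area-normalized;
calibrating on raw spectra and predicting on normalized ones produces
arbitrarily wrong scales (the analysis driver normalizes the library before
calibrating).

## Equilibrium binding

For a 1:1 complex with totals a, b and dissociation constant Kd (all µM),

    [AB] = ((a + b + Kd) − sqrt((a + b + Kd)² − 4ab)) / 2

computed via the numerically stable form 2ab/(s + √disc); the bound fraction
is reported relative to the limiting partner. At a = b = 20 µM and
Kd = 0.104 µM this gives 93% complex. Titration fits model the response as
`base + amplitude · bound_fraction(target, ligand, Kd)` — affine in the
bound fraction, which absorbs assay-specific normalization — with Kd kept
positive through a log10 parameterization. Confidence intervals come from a
residual bootstrap (200 refits by default). A fit whose response is flat
raises a non-identifiability error; decreasing responses are fit and flagged
`negative-amplitude`.

## Sequence charge

`charge_excess` counts (D + E) − (K + R); histidine is treated as neutral
and affinity tags are expected to be trimmed by construct boundaries before
counting. For the bundled human thrombopoietin receptor (UniProt P40238) the
D1D2 extracellular module is taken as Q26–Q290; its acidic excess computes
to 11. The sliding-window profile uses a centered window truncated at the
sequence edges (even windows extend one residue toward the C-terminus);
contiguous runs above a threshold are reported as candidate acidic patches.

## Synthetic data: what it emulates, and what it does not

**HDx-MS.** Two-state experiments with the study schedule {0, 0.25, 1, 5,
20, 60} min, 3 replicates and a 0.95 labeling D₂O ceiling. Exchange follows
a simplified model: a single intrinsic rate k_int for every residue, slowed
per residue by a protection factor PF ≥ 1, with expected per-residue
deuterium `d₂o · (1 − exp(−(k_int/PF)·t))` and peptide uptake the sum over
its exchangeable amides plus i.i.d. Gaussian replicate noise (0.05 Da
default — no replicate noise magnitude is standard, so this is exposed in
the spec/config). The default k_int = 1 min⁻¹ places a PF = 100 residue
mid-exchange at the last time point, so protection differences against that
baseline stay visible across the whole schedule; with a much faster
intrinsic rate, both states of the planted scenario would saturate and the
differential would vanish. Not emulated: sequence-dependent intrinsic rates
(Bai/Englander), back-exchange during workup (folded into the d₂o ceiling),
EX1 bimodality, and isotope envelopes — so passing tests demonstrate the
statistics and bookkeeping, not kinetic realism.

**Peptide maps** tile the sequence at stride mean_length/redundancy with
seeded jitter and length scatter clipped to 3–35 residues; coverage and
redundancy are measured, not guaranteed.

**FTIR.** Spectra are weighted sums of one Gaussian component band per
class (α 1656, β 1630, turns 1670, random 1645 cm⁻¹ — literature consensus
positions, overridable) on the canonical 4000→600 cm⁻¹, 2 cm⁻¹ grid, plus a
water-vapor line comb, a linear baseline and Gaussian noise. Real amide-I
band shapes, ATR penetration-depth dispersion and side-chain absorptions
are not modeled; the calibration tests therefore validate the selection and
cross-validation machinery, not transferability to measured protein
spectra. Library fractions are sampled on the 4-class simplex
(Dirichlet(2,2,2,2)).

**Titrations** report the bound fraction of a 20 nM target over a 16-point
geometric ligand series from 0.15 nM to 5 µM with Gaussian response noise
(1% of full scale in the recovery study).

## Problem sizes used by the test suite and analysis drivers

A 200-residue protein with ~50 peptides for the planted-region study; an
8,200-residue null protein giving ~2,050 peptides (≥2,000 null
peptide/exposure cells per α) for the type-I-error check; 50-spectrum
calibration libraries; 25-seed, 16-point titration recovery. These sizes
keep every Monte-Carlo bound meaningful while the whole suite runs in well
under a minute.

## Known limitations

* The global threshold assumes homoscedastic replicate noise across
  peptides; strongly peptide-dependent variance would make it conservative
  for quiet peptides and liberal for noisy ones.
* Residue-level projection spreads peptide-level signal uniformly over the
  span; true single-residue resolution requires overlapping-peptide
  subtraction, which is out of scope.
* The stepwise calibration inherits the instability of greedy selection
  under near-collinear candidates; the LOO SEP reports (rather than hides)
  that instability.
* Charge analysis is purely compositional; it ignores structure, pKa shifts
  and solvent exposure.
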
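# confmap

Differential conformational footprinting of proteins, as a tested, reusable
pipeline. `confmap` covers the three measurement layers used to characterize
how a mutation or a binding partner reshapes a protein — here motivated by
the calreticulin-mutant/thrombopoietin-receptor (CALR/TpoR) system:

* **HDx-MS differential uptake.** Peptide-level hydrogen–deuterium exchange
  tables are reduced to relative fractional uptake, `RFU = uptake(Da) /
  N_amides`, and compared between conditions as `ΔRFU = RFU_A − RFU_B`.
  Significance uses a hybrid rule: |Δuptake| must exceed a global
  pooled-variance threshold `t(1−α/2, 2n−2)·√(s̄_A²/n + s̄_B²/n)` **and**
  pass a per-peptide Welch t-test. Results are exported as Woods-plot tables
  and projected per residue into PDB B-factors for red–blue rendering
  (sentinel 999.99 marks uncovered residues).
* **ATR-FTIR amide-I secondary structure.** Fixed preprocessing chain
  (water-vapor subtraction scaled on 1956–1935 cm⁻¹, piecewise-linear
  baseline through 3700/3000/2800/1720/1480/1204/980 cm⁻¹, unit-area
  normalization over 1720–1480 cm⁻¹) followed by ascending stepwise
  wavenumber selection (≤3 per class) against a calibration library, with
  leave-one-out standard errors of prediction.
* **Equilibrium binding and charge.** Closed-form 1:1 complex fraction
  `[AB] = ((a+b+Kd) − √((a+b+Kd)² − 4ab))/2`, titration Kd fitting with
  bootstrap CIs, labeling-dilution arithmetic, and sliding-window acidic
  charge profiling of sequences.

Every stage is exercised end-to-end on synthetic data with known ground
truth generated in-repo (`confmap.synthetic`): two-state HDx experiments
with planted protection changes, corrupted amide-I spectra with calibration
libraries, and noisy titrations.

## Worked example

The numbered drivers under `analysis/` run the full pipeline and write their
tables under `results/`:

```
python analysis/01_simulate_hdx.py
python analysis/02_differential_uptake.py
python analysis/03_map_structure.py
python analysis/04_ftir_secondary_structure.py
python analysis/05_binding_and_charge.py
```

Output of the run recorded here:

```
simulated 50 peptides over 200 residues (100.0% coverage, redundancy 2.83)
hybrid threshold 0.351 Da at alpha 0.001
classifications at 60 min: {'not-significant': 40, 'deprotected': 10}
wrote model_delta_rfu.pdb: 200 residues colored, scale [-0.523, +0.523], sentinel 999.99
predicted fractions (mean ± SD over 5 replicates):
  alpha_helix   30.6 ±  1.5%  (truth 30.0%)
  beta_sheet    34.9 ±  1.2%  (truth 35.0%)
  turns         15.1 ±  1.2%  (truth 15.0%)
  random_coil   21.1 ±  3.2%  (truth 20.0%)
complex at 20 µM + 20 µM, Kd 104 nM: 93.0%
fitted Kd 102 nM (95% CI 98–106 nM)
TpoR D1D2 acidic excess: 11; 4 patch(es) at window-11 excess >= 3
```

Reading the numbers: the experiment plants a deprotected region (protection
factors 100 → 2) in residues 30–60 of a 200-residue synthetic protein. At
60 min all ten peptides fully inside the region are classified deprotected
and nothing outside is, at α = 0.001 with a 0.351 Da hybrid threshold; the
per-residue ΔRFU lands in the B-factor column of `model_delta_rfu.pdb` with
a symmetric ±0.523 color scale. The FTIR calibration recovers the planted
secondary-structure fractions of a 5-replicate test sample within ~1 SD.
The binding layer reproduces the equilibrium point — equimolar 20 µM
partners at Kd = 104 nM are 93% complexed — recovers the generating Kd from
a noisy 0.15 nM–5 µM titration, and counts an excess of 11 acidic residues
on the TpoR D1D2 extracellular module (Q26–Q290 of UniProt P40238).

A `confmap` CLI wraps the same functions (`confmap simulate|hdx|ftir|bind|seq …`);
see `confmap --help`.

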
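"""Synthetic ground-truth generators for every stage of the pipeline.

All generators are deterministic under an explicit seed and emulate the
study conditions of a two-state differential footprinting experiment:

* HDx-MS: six exposures {0, 0.25, 1, 5, 20, 60} min, 3 replicates, 95 %
  labeling D₂O fraction, region-localized protection differences encoded as
  per-residue protection factors under a simplified single-rate exchange
  model (expected per-residue deuterium d₂o·(1 − exp(−(k_int/PF)·t))).
* ATR-FTIR: amide-I spectra assembled from four secondary-structure
  component bands on the canonical 4000→600 cm⁻¹, 2 cm⁻¹ grid, corrupted
  with a water-vapor comb, linear baseline drift and Gaussian noise.
* Binding: 1:1 titrations over the 0.15 nM–5 µM ligand range read out as
  bound fraction of a 20 nM target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoordinateError, ValidationError
from .hdx_io import UptakeTable
from .peptides import PeptideRecord

DEFAULT_EXPOSURES = (0.0, 0.25, 1.0, 5.0, 20.0, 60.0)

#: amide-I component band positions (cm⁻¹), literature consensus values
DEFAULT_BAND_CENTERS = {
    "alpha_helix": 1656.0,
    "beta_sheet": 1630.0,
    "turns": 1670.0,
    "random_coil": 1645.0,
}
DEFAULT_BAND_WIDTHS = {
    "alpha_helix": 12.0,
    "beta_sheet": 10.0,
    "turns": 8.0,
    "random_coil": 16.0,
}
STRUCTURE_CLASSES = tuple(DEFAULT_BAND_CENTERS)


# --------------------------------------------------------------------------
# HDx-MS
# --------------------------------------------------------------------------

@dataclass
class HDXSimSpec:
    """Ground truth for one labeling state of a simulated HDx experiment.

    ``protection_factors`` slow each residue's exchange relative to the
    intrinsic rate; PF = 1 is unstructured, large PF is protected.  The
    default intrinsic rate of 1 min⁻¹ places a PF ≈ 100 residue mid-exchange
    at the last time point of the default schedule, so protection
    differences remain visible across the whole exposure series.
    """

    sequence: str
    protection_factors: np.ndarray
    intrinsic_rate: float = 1.0
    d2o_fraction: float = 0.95
    exposures: tuple = DEFAULT_EXPOSURES
    n_replicates: int = 3
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.protection_factors = np.asarray(self.protection_factors, float)
        if self.protection_factors.shape != (len(self.sequence),):
            raise ValidationError(
                "protection_factors must provide one value per residue"
            )
        if (self.protection_factors < 1).any():
            raise ValidationError("protection factors must be >= 1")
        if not 0.0 < self.d2o_fraction <= 1.0:
            raise ValidationError("d2o_fraction must lie in (0, 1]")
        exp = tuple(self.exposures)
        if list(exp) != sorted(exp) or exp[0] != 0.0:
            raise ValidationError("exposures must be ascending and include 0")
        if np.asarray(self.intrinsic_rate, float).min() <= 0:
            raise ValidationError("intrinsic_rate must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def expected_residue_uptake(spec: HDXSimSpec) -> np.ndarray:
    """Noise-free expected deuterium per residue: (n_residues, n_exposures)."""
    t = np.asarray(spec.exposures, float)[None, :]
    k_obs = (spec.intrinsic_rate / spec.protection_factors)[:, None]
    return spec.d2o_fraction * (1.0 - np.exp(-k_obs * t))


def simulate_hdx_experiment(
    spec: HDXSimSpec,
    peptide_map: list[PeptideRecord],
    state: str = "A",
) -> UptakeTable:
    """Simulate replicate uptake for every peptide/exposure of one state."""
    n = len(spec.sequence)
    for p in peptide_map:
        if p.start < 1 or p.end > n:
            raise CoordinateError(
                f"peptide {p.start}-{p.end} outside sequence of length {n}"
            )
        if p.sequence != spec.sequence[p.start - 1 : p.end]:
            raise CoordinateError(
                f"peptide sequence mismatch at {p.start}-{p.end}"
            )
    residue_uptake = expected_residue_uptake(spec)
    # cumulative sum over the proline-masked residue contributions lets each
    # peptide sum be taken as a difference of two prefix sums
    masked = residue_uptake.copy()
    proline = np.array([aa == "P" for aa in spec.sequence])
    masked[proline, :] = 0.0
    prefix = np.vstack([np.zeros(masked.shape[1]), np.cumsum(masked, axis=0)])

    rng = np.random.default_rng(spec.seed)
    rows = []
    for p in peptide_map:
        expected = prefix[p.end] - prefix[p.start]  # residues start+1..end
        noise = rng.normal(0.0, spec.noise_sd,
                           size=(spec.n_replicates, len(spec.exposures)))
        for rep in range(spec.n_replicates):
            for j, t in enumerate(spec.exposures):
                rows.append((
                    p.protein_id, p.start, p.end, p.sequence, state,
                    float(t), rep + 1, expected[j] + noise[rep, j],
                ))
    df = pd.DataFrame(rows, columns=[
        "protein", "start", "end", "sequence", "state",
        "exposure", "replicate", "uptake",
    ])
    return UptakeTable(df)


def generate_peptide_map(
    sequence: str,
    mean_length: int = 12,
    target_redundancy: float = 3.0,
    seed: int = 0,
    protein_id: str = "synthetic",
) -> list[PeptideRecord]:
    """Generate a pepsin-like peptide map with controlled redundancy.

    Peptide starts tile the sequence at a stride of
    ``mean_length / target_redundancy`` with seeded jitter; lengths scatter
    around ``mean_length`` (clipped to the 3–35 range of usable peptic
    peptides).  Returned sorted by (start, end), deduplicated.
    """
    n = len(sequence)
    if not 3 <= mean_length <= 35:
        raise ValidationError("mean_length must lie in [3, 35]")
    if n < mean_length:
        raise ValidationError("sequence shorter than mean_length")
    if target_redundancy <= 0:
        raise ValidationError("target_redundancy must be positive")
    if n == mean_length:
        return [PeptideRecord(protein_id, 1, n, sequence)]

    rng = np.random.default_rng(seed)
    stride = mean_length / target_redundancy
    starts0 = np.arange(0.0, n - 3 + 1e-9, stride)
    jitter = rng.uniform(-stride / 3.0, stride / 3.0, size=starts0.shape)
    lengths = np.clip(
        np.rint(rng.normal(mean_length, mean_length / 5.0, starts0.shape)),
        3, 35,
    ).astype(int)
    seen = set()
    peptides = []
    for s0, ln in zip(starts0 + jitter, lengths):
        start = int(np.clip(round(s0), 0, n - 3))
        end = min(start + ln, n)  # 0-based exclusive
        start = max(0, min(start, end - 3))
        key = (start, end)
        if key in seen:
            continue
        seen.add(key)
        peptides.append(PeptideRecord(
            protein_id, start + 1, end, sequence[start:end]
        ))
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


# --------------------------------------------------------------------------
# ATR-FTIR
# --------------------------------------------------------------------------

def default_grid() -> np.ndarray:
    """Canonical descending wavenumber grid: 4000 → 600 cm⁻¹, step 2."""
    return np.arange(4000.0, 599.0, -2.0)


# fixed water-vapor line list (cm⁻¹, relative intensity); positions spread
# over the rotational-vibrational band of gaseous water, including the
# 1956–1935 cm⁻¹ stretch used as the scaling reference
_VAPOR_LINES = [
    (1312.0, 0.55), (1340.0, 0.70), (1356.0, 0.45), (1396.0, 0.80),
    (1420.0, 0.60), (1458.0, 0.75), (1508.0, 0.90), (1540.0, 0.65),
    (1560.0, 1.00), (1576.0, 0.70), (1616.0, 0.95), (1640.0, 0.60),
    (1662.0, 0.85), (1700.0, 0.50), (1734.0, 0.65), (1772.0, 0.55),
    (1810.0, 0.45), (1846.0, 0.50), (1870.0, 0.40), (1890.0, 0.45),
    (1918.0, 0.40), (1936.0, 0.55), (1942.0, 0.70), (1948.0, 0.60),
    (1954.0, 0.45), (1972.0, 0.35), (1988.0, 0.30),
]
_VAPOR_WINDOW = (1935.0, 1956.0)


def water_vapor_reference(wavenumbers: np.ndarray) -> np.ndarray:
    """Synthetic water-vapor reference on a given grid.

    A comb of narrow Gaussian lines; the segment inside the scaling window
    (1935–1956 cm⁻¹) is orthogonalized against constant and linear trends so
    least-squares scaling against this reference is insensitive to local
    baseline.
    """
    wn = np.asarray(wavenumbers, float)
    ref = np.zeros_like(wn)
    for center, amp in _VAPOR_LINES:
        ref += amp * np.exp(-0.5 * ((wn - center) / 1.5) ** 2)
    lo, hi = _VAPOR_WINDOW
    m = (wn >= lo) & (wn <= hi)
    if m.sum() >= 3:
        design = np.column_stack([np.ones(m.sum()), wn[m]])
        coef, *_ = np.linalg.lstsq(design, ref[m], rcond=None)
        ref[m] -= design @ coef
    return ref


@dataclass
class FTIRSimSpec:
    """Ground truth for one synthetic ATR-FTIR absorbance spectrum."""

    fractions: tuple = (25.0, 30.0, 20.0, 25.0)  # α, β, turns, random (%)
    band_centers: dict = field(default_factory=lambda: dict(DEFAULT_BAND_CENTERS))
    band_widths: dict = field(default_factory=lambda: dict(DEFAULT_BAND_WIDTHS))
    vapor_amplitude: float = 0.0
    baseline_slope: float = 0.0  # AU per cm⁻¹, referenced to 600 cm⁻¹
    noise_sd: float = 0.0
    grid: np.ndarray = field(default_factory=default_grid)
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        self.fractions = tuple(float(f) for f in self.fractions)
        if len(self.fractions) != len(STRUCTURE_CLASSES):
            raise ValidationError(
                f"need {len(STRUCTURE_CLASSES)} fractions, got {len(self.fractions)}"
            )
        if any(f < 0 for f in self.fractions):
            raise ValidationError("fractions must be non-negative")
        if not math.isclose(sum(self.fractions), 100.0, abs_tol=1e-9):
            raise ValidationError(
                f"fractions must sum to 100, got {sum(self.fractions)}"
            )
        self.grid = np.asarray(self.grid, float)
        steps = np.diff(self.grid)
        if not np.allclose(steps, -2.0):
            raise ValidationError("grid must descend in 2 cm⁻¹ steps")


def simulate_ftir_spectrum(spec: FTIRSimSpec):
    """Weighted band sum + vapor comb + linear baseline + Gaussian noise."""
    from .ftir import Spectrum  # local import to avoid a cycle

    wn = spec.grid
    absorb = np.zeros_like(wn)
    for frac, cls in zip(spec.fractions, STRUCTURE_CLASSES):
        c = spec.band_centers[cls]
        w = spec.band_widths[cls]
        absorb += (frac / 100.0) * np.exp(-0.5 * ((wn - c) / w) ** 2)
    if spec.vapor_amplitude:
        absorb = absorb + spec.vapor_amplitude * water_vapor_reference(wn)
    if spec.baseline_slope:
        absorb = absorb + spec.baseline_slope * (wn - wn.min())
    if spec.noise_sd:
        rng = np.random.default_rng(spec.seed)
        absorb = absorb + rng.normal(0.0, spec.noise_sd, wn.shape)
    return Spectrum(wn.copy(), absorb, label=spec.label)


@dataclass
class FTIRLibrary:
    """Calibration library: spectra with known secondary-structure fractions."""

    spectra: list
    fractions: np.ndarray  # (n, 4) percent, rows on the simplex
    classes: tuple = STRUCTURE_CLASSES

    def __len__(self) -> int:
        return len(self.spectra)


def simulate_ftir_library(
    n_proteins: int = 50, noise_sd: float = 0.002, seed: int = 0
) -> FTIRLibrary:
    """Library of band-sum spectra with fractions sampled on the simplex."""
    if n_proteins < len(STRUCTURE_CLASSES):
        raise ValidationError(
            f"need at least {len(STRUCTURE_CLASSES)} proteins, got {n_proteins}"
        )
    rng = np.random.default_rng(seed)
    fractions = rng.dirichlet(np.full(len(STRUCTURE_CLASSES), 2.0), n_proteins)
    fractions *= 100.0
    spectra = []
    for i, frac in enumerate(fractions):
        frac = frac / frac.sum() * 100.0  # exact simplex after rounding noise
        spec = FTIRSimSpec(
            fractions=tuple(frac), noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)), label=f"lib{i:03d}",
        )
        spectra.append(simulate_ftir_spectrum(spec))
        fractions[i] = frac
    return FTIRLibrary(spectra=spectra, fractions=fractions)


# --------------------------------------------------------------------------
# Binding titrations
# --------------------------------------------------------------------------

def default_ligand_series(n_points: int = 16) -> np.ndarray:
    """Ligand series in µM spanning the 0.15 nM – 5 µM titration range."""
    return np.geomspace(0.15e-3, 5.0, n_points)


def simulate_titration(
    kd: float,
    target_conc: float = 0.020,
    ligand_concs: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a 1:1 binding titration (all concentrations in µM).

    Response is the bound fraction of the target plus Gaussian noise.
    Returns a table with columns ``conc_nM`` and ``response``.
    """
    from .biophys import complex_fraction

    if kd <= 0:
        raise ValidationError("kd must be positive for simulation")
    if target_conc <= 0:
        raise ValidationError("target concentration must be positive")
    ligand = (default_ligand_series() if ligand_concs is None
              else np.asarray(ligand_concs, float))
    if (ligand <= 0).any():
        raise ValidationError("ligand concentrations must be positive")
    frac = np.array([
        complex_fraction(target_conc, b, kd, of="a") for b in ligand
    ])
    rng = np.random.default_rng(seed)
    response = frac + rng.normal(0.0, noise_sd, frac.shape)
    return pd.DataFrame({"conc_nM": ligand * 1000.0, "response": response})


# --------------------------------------------------------------------------
# Synthetic structures
# --------------------------------------------------------------------------

def synthetic_ca_pdb(n_residues: int, chain_id: str = "A") -> str:
    """Minimal Cα-trace PDB text (poly-Ala helix) for mapping tests/demos."""
    if n_residues < 1:
        raise ValidationError("need at least one residue")
    lines = []
    for i in range(n_residues):
        # idealized alpha-helix Cα geometry
        theta = 2.0 * math.pi * i / 3.6
        x, y, z = 2.3 * math.cos(theta), 2.3 * math.sin(theta), 1.5 * i
        lines.append(
            f"ATOM  {i + 1:5d}  CA  ALA {chain_id}{i + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {'C':>2s}  "
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
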
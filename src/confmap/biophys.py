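"""Equilibrium 1:1 binding and sequence-charge computations.

For partners A and B with total concentrations a, b and dissociation
constant Kd, mass balance gives the complex concentration as the smaller
root of the quadratic

    [AB] = ((a + b + Kd) − sqrt((a + b + Kd)² − 4ab)) / 2

and the bound fraction is reported relative to the limiting partner.
Titration curves (response vs ligand concentration) are fit with
``response = base + amplitude · bound_fraction(target, ligand, Kd)`` with Kd
kept positive through a log parameterization.

Charge analysis counts acidic residues (Asp, Glu) against basic ones
(Lys, Arg); histidine is treated as neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import NonIdentifiableError, ValidationError
from .peptides import AMINO_ACIDS


@dataclass(frozen=True)
class BindingSystem:
    """Total concentrations and dissociation constant, all in µM."""

    a_total: float
    b_total: float
    kd: float

    def __post_init__(self) -> None:
        if self.a_total <= 0 or self.b_total <= 0:
            raise ValidationError("total concentrations must be positive")
        if self.kd < 0:
            raise ValidationError("kd must be non-negative")

    @property
    def bound_fraction(self) -> float:
        return complex_fraction(self.a_total, self.b_total, self.kd)


def complex_fraction(
    a_total: float, b_total: float, kd: float, of: str = "limiting"
) -> float:
    """Equilibrium bound fraction for a 1:1 complex (concentrations in µM).

    ``of`` selects the denominator: the limiting partner (default), or
    explicitly partner ``"a"`` or ``"b"``.  Kd = 0 is the infinite-affinity
    limit where the limiting partner is fully bound.
    """
    if a_total <= 0 or b_total <= 0:
        raise ValidationError("total concentrations must be positive")
    if kd < 0:
        raise ValidationError("kd must be non-negative")
    s = a_total + b_total + kd
    disc = s * s - 4.0 * a_total * b_total
    # numerically stable smaller quadratic root
    complex_conc = 2.0 * a_total * b_total / (s + np.sqrt(disc))
    denom = {
        "limiting": min(a_total, b_total), "a": a_total, "b": b_total,
    }.get(of)
    if denom is None:
        raise ValidationError(f"unknown denominator choice {of!r}")
    return float(min(complex_conc / denom, 1.0))


@dataclass
class KdFit:
    """Result of a titration fit: Kd (µM) with a bootstrap CI and flags."""

    kd: float
    kd_ci: tuple
    base: float
    amplitude: float
    n_points: int
    flags: list = field(default_factory=list)
    residual_rms: float = float("nan")


def _titration_model(ligand_um, base, amplitude, log10_kd, target_um):
    kd = 10.0 ** log10_kd
    frac = np.array([
        complex_fraction(target_um, b, kd, of="a") for b in ligand_um
    ])
    return base + amplitude * frac


def fit_kd(
    titration: pd.DataFrame,
    target_conc: float,
    n_boot: int = 200,
    seed: int = 0,
) -> KdFit:
    """Fit a 1:1 dissociation constant to a titration table.

    Parameters
    ----------
    titration
        Table with columns ``conc_nM`` (ligand) and ``response``; any other
        two-column layout is taken as (conc_nM, response) in order.
    target_conc
        Fixed concentration of the labeled target, in µM.
    n_boot
        Residual-bootstrap replicates for the 95 % CI on Kd.
    """
    if {"conc_nM", "response"}.issubset(titration.columns):
        conc_nm = titration["conc_nM"].to_numpy(float)
        response = titration["response"].to_numpy(float)
    else:
        conc_nm = titration.iloc[:, 0].to_numpy(float)
        response = titration.iloc[:, 1].to_numpy(float)
    if len(conc_nm) < 6:
        raise ValidationError("need at least 6 titration points")
    if (conc_nm <= 0).any():
        raise ValidationError("ligand concentrations must be positive")
    span = np.log10(conc_nm.max() / conc_nm.min())
    if span < 2:
        raise ValidationError(
            f"titration must span >= 2 decades, got {span:.2f}"
        )
    if np.ptp(response) < 1e-12:
        raise NonIdentifiableError("flat response: Kd not identifiable")

    ligand_um = conc_nm / 1000.0

    def model(x, base, amplitude, log10_kd):
        return _titration_model(x, base, amplitude, log10_kd, target_conc)

    rising = np.corrcoef(np.log(ligand_um), response)[0, 1] >= 0
    p0 = (
        float(response.min() if rising else response.max()),
        float(np.ptp(response) * (1.0 if rising else -1.0)),
        float(np.log10(np.median(ligand_um))),
    )
    try:
        popt, _ = curve_fit(model, ligand_um, response, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise NonIdentifiableError(f"titration fit did not converge: {exc}")
    base, amplitude, log10_kd = popt
    fitted = model(ligand_um, *popt)
    resid = response - fitted
    rms = float(np.sqrt(np.mean(resid**2)))

    flags = []
    if amplitude < 0:
        flags.append("negative-amplitude")
    # curvature check: the fit must beat a straight line in log-concentration
    line = np.polyval(np.polyfit(np.log(ligand_um), response, 1),
                      np.log(ligand_um))
    if np.sum(resid**2) > 0.999 * np.sum((response - line) ** 2) and rms > 0:
        flags.append("weak-curvature")

    rng = np.random.default_rng(seed)
    boot_kds: list[float] = []
    for _ in range(n_boot):
        y_star = fitted + rng.choice(resid, size=resid.size, replace=True)
        try:
            pb, _ = curve_fit(model, ligand_um, y_star, p0=popt, maxfev=5000)
            boot_kds.append(10.0 ** pb[2])
        except RuntimeError:
            continue
    if n_boot == 0:
        ci = (float("nan"), float("nan"))
    elif len(boot_kds) >= max(10, n_boot // 4):
        ci = tuple(float(v) for v in np.percentile(boot_kds, [2.5, 97.5]))
    else:
        ci = (float("nan"), float("nan"))
        flags.append("bootstrap-unstable")

    return KdFit(
        kd=float(10.0 ** log10_kd), kd_ci=ci, base=float(base),
        amplitude=float(amplitude), n_points=len(conc_nm), flags=flags,
        residual_rms=rms,
    )


def labeling_d2o_fraction(
    v_sample_ul: float, v_buffer_ul: float, buffer_purity: float = 1.0
) -> float:
    """Final D₂O fraction after diluting a protiated sample in labeling buffer."""
    if v_sample_ul < 0 or v_buffer_ul < 0:
        raise ValidationError("volumes must be non-negative")
    total = v_sample_ul + v_buffer_ul
    if total == 0:
        raise ValidationError("total volume must be positive")
    if not 0.0 <= buffer_purity <= 1.0:
        raise ValidationError("buffer purity must lie in [0, 1]")
    return v_buffer_ul * buffer_purity / total


def _check_sequence(sequence: str) -> None:
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise ValidationError(f"unknown residue letter(s): {sorted(bad)}")


def charge_excess(sequence: str) -> int:
    """Net acidic excess (D + E) − (K + R); histidine counts as neutral."""
    _check_sequence(sequence)
    return (sequence.count("D") + sequence.count("E")
            - sequence.count("K") - sequence.count("R"))


@dataclass
class ChargeProfile:
    """Sliding-window net acidic excess along a sequence (1-based positions)."""

    sequence: str
    window: int
    values: np.ndarray  # per-position acidic excess within the centered window

    def patches(self, min_excess: int = 2) -> list[tuple[int, int, int]]:
        """Contiguous runs where the excess reaches ``min_excess``.

        Returns (start, end, peak) triples in 1-based inclusive coordinates —
        candidate acidic patches.
        """
        runs = []
        in_run = False
        start = peak = 0
        for i, v in enumerate(self.values):
            if v >= min_excess:
                if not in_run:
                    in_run, start, peak = True, i + 1, int(v)
                peak = max(peak, int(v))
            elif in_run:
                runs.append((start, i, peak))
                in_run = False
        if in_run:
            runs.append((start, len(self.values), peak))
        return runs


def acidic_patch_profile(sequence: str, window: int) -> ChargeProfile:
    """Centered sliding-window acidic excess; edge windows are truncated."""
    _check_sequence(sequence)
    if not 1 <= window <= len(sequence):
        raise ValidationError(
            f"window must lie in [1, {len(sequence)}], got {window}"
        )
    per_residue = np.array([
        1 if aa in "DE" else -1 if aa in "KR" else 0 for aa in sequence
    ])
    half = (window - 1) // 2
    half_up = window // 2
    cum = np.concatenate([[0], np.cumsum(per_residue)])
    n = len(sequence)
    values = np.empty(n, dtype=int)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half_up + 1)
        values[i] = cum[hi] - cum[lo]
    return ChargeProfile(sequence=sequence, window=window, values=values)
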
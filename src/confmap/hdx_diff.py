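"""Differential deuterium uptake: RFU, ΔRFU and hybrid significance testing.

For a peptide observed after a labeling time t, the relative fractional
uptake is

    RFU = uptake (Da) / N_amides

with ``N_amides`` the peptide's exchangeable backbone amide count, and the
differential between conditions A and B is ``ΔRFU = RFU_A − RFU_B``.
Positive ΔRFU means the peptide is *deprotected* (more solvent-accessible)
in condition A.

Peptide-level significance follows the hybrid rule used for curated
differential HDx-MS analyses: a peptide/exposure is called significant only
if the absolute uptake difference exceeds a global pooled-variance threshold
*and* a per-peptide Welch t-test rejects at the chosen alpha.  The global
threshold is

    thr = t_{1−α/2, 2n−2} · sqrt(s̄_A²/n + s̄_B²/n)

where s̄ is the root-mean-square replicate standard deviation pooled over
all peptides and exposures of a state, and n the replicate count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptyComparisonError,
    InsufficientReplicatesError,
    UndefinedRFUError,
    ValidationError,
)
from .hdx_io import UptakeTable
from .peptides import PeptideRecord, exchangeable_amides

__all__ = [
    "SignificanceConfig", "exchangeable_amides", "rfu", "delta_rfu",
    "global_threshold", "hybrid_significance", "coverage_stats", "woods_table",
    "CLASS_DEPROTECTED", "CLASS_PROTECTED", "CLASS_NS",
]

CLASS_DEPROTECTED = "deprotected"
CLASS_PROTECTED = "protected"
CLASS_NS = "not-significant"

_PEPTIDE_KEY = ["protein", "start", "end", "sequence"]


@dataclass(frozen=True)
class SignificanceConfig:
    """Parameters of the hybrid peptide-level significance test."""

    alpha: float = 0.001
    n_replicates: int = 3
    mode: Literal["hybrid", "global-only", "ttest-only"] = "hybrid"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.mode not in ("hybrid", "global-only", "ttest-only"):
            raise ValidationError(f"unknown mode {self.mode!r}")


def rfu(mean_uptake_da: float, max_uptake: int) -> float:
    """Relative fractional uptake: uptake (Da) over exchangeable amides."""
    if max_uptake < 1:
        raise UndefinedRFUError(
            f"peptide has no exchangeable amides (max_uptake={max_uptake})"
        )
    if mean_uptake_da < 0:
        warnings.warn(
            f"negative uptake centroid {mean_uptake_da:.4f} Da clamped to 0",
            stacklevel=2,
        )
        mean_uptake_da = 0.0
    return mean_uptake_da / max_uptake


def delta_rfu(rfu_a: float, rfu_b: float) -> float:
    """ΔRFU between conditions A and B (antisymmetric)."""
    if not (np.isfinite(rfu_a) and np.isfinite(rfu_b)):
        raise ValidationError("RFU inputs must be finite")
    return rfu_a - rfu_b


def _pooled_rms_sd(table: UptakeTable) -> tuple[float, int]:
    """RMS replicate SD over all peptides/exposures (t=0 excluded)."""
    df = table.df[table.df["exposure"] > 0]
    grouped = df.groupby(_PEPTIDE_KEY + ["exposure"])["uptake"]
    sds = grouped.std(ddof=1)
    ns = grouped.size()
    if (ns < 2).all():
        raise InsufficientReplicatesError(
            "at least 2 replicates per peptide/exposure required"
        )
    sds = sds[ns >= 2]
    return float(np.sqrt(np.mean(sds.to_numpy() ** 2))), int(ns.max())


def global_threshold(
    table_a: UptakeTable, table_b: UptakeTable, config: SignificanceConfig
) -> float:
    """Global uptake-difference threshold (Da) from pooled replicate variance."""
    sd_a, _ = _pooled_rms_sd(table_a)
    sd_b, _ = _pooled_rms_sd(table_b)
    n = config.n_replicates
    if n < 2:
        raise InsufficientReplicatesError("n_replicates must be >= 2")
    df_t = 2 * n - 2
    tq = stats.t.ppf(1.0 - config.alpha / 2.0, df_t)
    return float(tq * np.sqrt(sd_a**2 / n + sd_b**2 / n))


def _per_cell(table: UptakeTable, suffix: str) -> pd.DataFrame:
    df = table.df[table.df["exposure"] > 0]
    g = df.groupby(_PEPTIDE_KEY + ["exposure"])["uptake"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={
        "mean": f"mean_{suffix}", "std": f"sd_{suffix}", "count": f"n_{suffix}"
    })


def hybrid_significance(
    table_a: UptakeTable,
    table_b: UptakeTable,
    config: SignificanceConfig | None = None,
) -> pd.DataFrame:
    """Compare two states peptide-by-peptide at every shared exposure.

    Returns a differential table sorted by (start, end, exposure) with one
    row per shared peptide/exposure and columns ``rfu_a``, ``rfu_b``,
    ``delta_rfu``, ``delta_uptake`` (Da, A − B), ``p_value``, ``significant``
    and ``classification``.  The global threshold (Da) and test parameters
    are stored in ``DataFrame.attrs``.  Exposure 0 is the unlabeled control
    and never enters the comparison.
    """
    config = config or SignificanceConfig()
    a = _per_cell(table_a, "a")
    b = _per_cell(table_b, "b")
    merged = a.merge(b, on=_PEPTIDE_KEY + ["exposure"], how="inner")
    if merged.empty:
        raise EmptyComparisonError(
            "the two states share no peptide/exposure combination"
        )

    thr = global_threshold(table_a, table_b, config)

    max_uptake = merged["sequence"].map(exchangeable_amides)
    if (max_uptake < 1).any():
        bad = merged.loc[max_uptake < 1, "sequence"].unique()
        raise UndefinedRFUError(f"peptides without exchangeable amides: {bad}")

    rfu_a = merged["mean_a"].clip(lower=0.0) / max_uptake
    rfu_b = merged["mean_b"].clip(lower=0.0) / max_uptake
    d_uptake = merged["mean_a"] - merged["mean_b"]

    # Welch two-sample t-test, vectorized from per-cell summary statistics
    va = merged["sd_a"] ** 2 / merged["n_a"]
    vb = merged["sd_b"] ** 2 / merged["n_b"]
    denom = np.sqrt(va + vb)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = d_uptake / denom
        df_w = (va + vb) ** 2 / (
            va**2 / (merged["n_a"] - 1) + vb**2 / (merged["n_b"] - 1)
        )
    p = 2.0 * stats.t.sf(np.abs(tstat), df_w)
    # degenerate cells: zero variance in both states
    zero_var = denom == 0
    p = np.where(zero_var & (d_uptake == 0), 1.0, p)
    p = np.where(zero_var & (d_uptake != 0), 0.0, p)

    passes_global = np.abs(d_uptake) > thr
    passes_ttest = p < config.alpha
    if config.mode == "hybrid":
        significant = passes_global & passes_ttest
    elif config.mode == "global-only":
        significant = passes_global
    else:
        significant = pd.Series(passes_ttest, index=merged.index)

    drfu = rfu_a - rfu_b
    classification = np.where(
        significant & (drfu > 0), CLASS_DEPROTECTED,
        np.where(significant & (drfu < 0), CLASS_PROTECTED, CLASS_NS),
    )

    out = merged[_PEPTIDE_KEY + ["exposure"]].copy()
    out["max_uptake"] = max_uptake
    out["rfu_a"] = rfu_a
    out["rfu_b"] = rfu_b
    out["delta_rfu"] = drfu
    out["delta_uptake"] = d_uptake
    out["p_value"] = p
    out["significant"] = np.asarray(significant, dtype=bool)
    out["classification"] = classification
    out = out.sort_values(["start", "end", "exposure"]).reset_index(drop=True)
    out.attrs["global_threshold_da"] = thr
    out.attrs["alpha"] = config.alpha
    out.attrs["mode"] = config.mode
    out.attrs["n_replicates"] = config.n_replicates
    return out


def coverage_stats(
    peptides: list[PeptideRecord], protein_length: int
) -> tuple[float, float]:
    """Sequence coverage (%) and mean per-residue redundancy of a peptide map.

    Redundancy is the mean number of peptides covering each *covered*
    residue; with no peptides both numbers are 0 (flagged via the zero).
    """
    if peptides and protein_length < max(p.end for p in peptides):
        raise ValidationError("protein_length smaller than last peptide end")
    depth = np.zeros(protein_length, dtype=int)
    for p in peptides:
        depth[p.start - 1 : p.end] += 1
    covered = depth > 0
    if not covered.any():
        return 0.0, 0.0
    coverage = 100.0 * covered.sum() / protein_length
    redundancy = float(depth[covered].mean())
    return float(coverage), redundancy


def woods_table(records: pd.DataFrame, exposure: float) -> pd.DataFrame:
    """One Woods-plot row per peptide at a given exposure.

    Columns: start, end, delta_uptake (Da), delta_rfu, classification; the
    significance threshold lines (±threshold) are kept in ``attrs``.
    """
    avail = sorted(records["exposure"].unique())
    if exposure not in avail:
        raise ValidationError(
            f"exposure {exposure} not present; available: {avail}"
        )
    sel = records[records["exposure"] == exposure]
    out = sel[["protein", "start", "end", "sequence", "delta_uptake",
               "delta_rfu", "p_value", "significant", "classification"]].copy()
    out = out.sort_values(["start", "end"]).reset_index(drop=True)
    thr = records.attrs.get("global_threshold_da")
    out.attrs["exposure"] = exposure
    out.attrs["global_threshold_da"] = thr
    if thr is not None:
        out.attrs["threshold_lines"] = (-thr, thr)
    out.attrs["alpha"] = records.attrs.get("alpha")
    return out
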
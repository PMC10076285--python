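"""Read, validate and filter peptide-level HDx-MS state tables.

The on-disk dialect is a comma-separated table with one row per
(peptide, state, exposure, replicate) and at least the columns
Protein, Start, End, Sequence, State, Exposure, Uptake (case-insensitive).
Exposure is in minutes, uptake in daltons.  Optional columns: Replicate,
``Uptake SD``, ProductsPerAA, MassErrorPPM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError, ValidationError
from .peptides import PeptideRecord

logger = logging.getLogger(__name__)

#: canonical column order of the typed table
CORE_COLUMNS = [
    "protein", "start", "end", "sequence", "state",
    "exposure", "replicate", "uptake",
]
OPTIONAL_COLUMNS = ["uptake_sd", "products_per_aa", "mass_error_ppm"]

_HEADER_ALIASES = {
    "protein": "protein",
    "start": "start",
    "end": "end",
    "sequence": "sequence",
    "state": "state",
    "exposure": "exposure",
    "replicate": "replicate",
    "uptake": "uptake",
    "uptake sd": "uptake_sd",
    "uptake_sd": "uptake_sd",
    "productsperaa": "products_per_aa",
    "products_per_aa": "products_per_aa",
    "products per aa": "products_per_aa",
    "masserrorppm": "mass_error_ppm",
    "mass_error_ppm": "mass_error_ppm",
    "mass error ppm": "mass_error_ppm",
}

_MANDATORY = ["protein", "start", "end", "sequence", "state", "exposure", "uptake"]


@dataclass
class UptakeTable:
    """Replicate deuterium uptake per peptide, state and exposure."""

    df: pd.DataFrame
    filter_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CORE_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"table missing column(s): {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def exposures(self) -> list[float]:
        return sorted(self.df["exposure"].unique())

    @property
    def states(self) -> list[str]:
        return sorted(self.df["state"].unique())

    def peptides(self) -> list[PeptideRecord]:
        """Unique peptides, sorted by (start, end)."""
        cols = ["protein", "start", "end", "sequence"]
        uniq = self.df[cols].drop_duplicates().sort_values(["start", "end"])
        return [
            PeptideRecord(r.protein, int(r.start), int(r.end), r.sequence)
            for r in uniq.itertuples(index=False)
        ]

    def n_replicates(self) -> int:
        counts = self.df.groupby(
            ["protein", "start", "end", "sequence", "state", "exposure"]
        ).size()
        return int(counts.max()) if len(counts) else 0

    def write(self, path) -> None:
        write_state_table(self, path)


def read_state_table(path) -> UptakeTable:
    """Read a state-data CSV into a typed :class:`UptakeTable`.

    Raises
    ------
    FormatError
        If a mandatory column is missing (named in the message) or an uptake
        value is non-numeric (reported with its file line number).
    """
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    rename = {}
    for col in raw.columns:
        key = col.strip().lower()
        if key in _HEADER_ALIASES:
            rename[col] = _HEADER_ALIASES[key]
    df = raw.rename(columns=rename)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {missing}")

    for col, caster in [("start", "Int64"), ("end", "Int64")]:
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(caster)
    for col in ["exposure", "uptake", "uptake_sd", "products_per_aa",
                "mass_error_ppm"]:
        if col in df.columns:
            numeric = pd.to_numeric(df[col], errors="coerce")
            bad = numeric.isna() & df[col].notna()
            if bad.any():
                # +2: header line plus 1-based counting
                lines = [int(i) + 2 for i in df.index[bad][:5]]
                raise FormatError(
                    f"non-numeric value(s) in column '{col}' at line(s) {lines}"
                )
            df[col] = numeric

    if "replicate" in df.columns:
        df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce")
        if df["replicate"].isna().any():
            raise FormatError("non-numeric replicate index")
        df["replicate"] = df["replicate"].astype(int)
    else:
        df["replicate"] = (
            df.groupby(["protein", "start", "end", "sequence", "state",
                        "exposure"]).cumcount() + 1
        )
        logger.info("replicate column absent; inferred from row multiplicity")

    keep = CORE_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in df.columns]
    df = df[keep].copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return UptakeTable(df)


def write_state_table(table: UptakeTable, path) -> None:
    """Write the table back to the CSV dialect read by :func:`read_state_table`."""
    out = table.df.rename(columns={
        "protein": "Protein", "start": "Start", "end": "End",
        "sequence": "Sequence", "state": "State", "exposure": "Exposure",
        "replicate": "Replicate", "uptake": "Uptake",
        "uptake_sd": "Uptake SD", "products_per_aa": "ProductsPerAA",
        "mass_error_ppm": "MassErrorPPM",
    })
    out.to_csv(path, index=False, float_format="%.9f")


def filter_peptides(
    table: UptakeTable,
    max_length: int = 35,
    min_products_per_aa: float = 0.2,
    min_replicates: int = 3,
    max_ppm_error: float | None = 10.0,
) -> UptakeTable:
    """Apply the peptide quality filters used for curated state data.

    A peptide is retained when its length is at most ``max_length``, its
    products-per-amino-acid score is at least ``min_products_per_aa`` (skipped
    with a warning when the column is absent), its mass error is within
    ``max_ppm_error`` (likewise optional), and it was observed in at least
    ``min_replicates`` replicates in every (state, exposure) cell where it
    appears.  Bounds are inclusive.  The returned table carries a
    ``filter_report`` dict with the number of peptides removed per rule.
    """
    df = table.df
    key = ["protein", "start", "end", "sequence"]
    peptides = df[key].drop_duplicates()
    report: dict[str, int] = {}

    length = peptides["end"] - peptides["start"] + 1
    ok_length = length <= max_length
    report["max_length"] = int((~ok_length).sum())
    keep = peptides[ok_length]

    if "products_per_aa" in df.columns:
        ppa = df.groupby(key)["products_per_aa"].min().reset_index()
        merged = keep.merge(ppa, on=key, how="left")
        ok = merged["products_per_aa"] >= min_products_per_aa
        report["min_products_per_aa"] = int((~ok).sum())
        keep = merged.loc[ok, key]
    else:
        logger.warning("products-per-aa column absent; filter skipped")
        report["min_products_per_aa"] = 0

    if max_ppm_error is not None and "mass_error_ppm" in df.columns:
        ppm = df.groupby(key)["mass_error_ppm"].apply(
            lambda s: s.abs().max()
        ).reset_index(name="mass_error_ppm")
        merged = keep.merge(ppm, on=key, how="left")
        ok = merged["mass_error_ppm"] <= max_ppm_error
        report["max_ppm_error"] = int((~ok).sum())
        keep = merged.loc[ok, key]
    elif max_ppm_error is not None:
        logger.warning("mass-error column absent; ppm filter skipped")
        report["max_ppm_error"] = 0

    counts = df.groupby(key + ["state", "exposure"]).size().reset_index(name="n")
    min_n = counts.groupby(key)["n"].min().reset_index()
    merged = keep.merge(min_n, on=key, how="left")
    ok = merged["n"] >= min_replicates
    report["min_replicates"] = int((~ok).sum())
    keep = merged.loc[ok, key]

    out = df.merge(keep, on=key, how="inner")
    report["peptides_in"] = len(peptides)
    report["peptides_out"] = len(keep)
    if len(keep) == 0:
        logger.warning("all peptides removed by filters: %s", report)
    else:
        logger.info("peptide filter report: %s", report)
    return UptakeTable(out, filter_report=report)
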
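"""Project peptide-level ΔRFU onto residues and encode it in PDB B-factors.

Structures colored by differential uptake use the B-factor column (fixed
columns 61–66 of ATOM/HETATM records) to carry the per-residue ΔRFU; a
renderer then applies a symmetric red–blue gradient centered on zero, the
conventional display showing deprotected regions red and protected regions
blue.  Residues without peptide coverage carry the sentinel 999.99 so they
can be grayed out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoordinateError, MappingError, ValidationError

#: B-factor written for residues with no peptide coverage; outside the
#: attainable |ΔRFU| <= 1 range by construction.
SENTINEL = 999.99


@dataclass
class ResidueProfile:
    """Per-residue ΔRFU values with a coverage mask (1-based numbering)."""

    values: np.ndarray
    covered: np.ndarray
    sentinel: float = SENTINEL

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.covered = np.asarray(self.covered, bool)
        if self.values.shape != self.covered.shape:
            raise ValidationError("values and coverage mask lengths differ")
        if self.covered.any():
            vals = self.values[self.covered]
            if not np.isfinite(vals).all():
                raise ValidationError("covered residues must carry finite values")
            if np.abs(vals).max() >= abs(self.sentinel):
                raise ValidationError("profile values collide with the sentinel")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def color_scale_limits(self) -> tuple[float, float]:
        """Symmetric rendering limits (−m, +m) so zero maps to the midpoint."""
        if not self.covered.any():
            return (0.0, 0.0)
        m = float(np.abs(self.values[self.covered]).max())
        return (-m, m)

    def bfactor(self, residue_number: int) -> float:
        """Value written to the B-factor column for a 1-based residue."""
        i = residue_number - 1
        return float(self.values[i]) if self.covered[i] else self.sentinel


def project_to_residues(
    records: pd.DataFrame,
    protein_length: int,
    exposure: float,
    reduce: str = "mean",
    skip_first_residue: bool = False,
) -> ResidueProfile:
    """Per-residue ΔRFU from a differential table at one exposure.

    Each covered residue receives the unweighted mean (or min/max) ΔRFU of
    all peptides containing it.  ``skip_first_residue`` drops each peptide's
    first residue, which contributes no amide signal.
    """
    avail = sorted(records["exposure"].unique())
    if exposure not in avail:
        raise ValidationError(
            f"exposure {exposure} not present; available: {avail}"
        )
    sel = records[records["exposure"] == exposure]
    if protein_length < int(sel["end"].max()):
        raise CoordinateError(
            f"protein_length {protein_length} < last peptide end "
            f"{int(sel['end'].max())}"
        )
    if reduce not in ("mean", "min", "max"):
        raise ValidationError(f"unknown reduction {reduce!r}")

    buckets: list[list[float]] = [[] for _ in range(protein_length)]
    for row in sel.itertuples(index=False):
        first = row.start + 1 if skip_first_residue else row.start
        for i in range(first - 1, row.end):
            buckets[i].append(row.delta_rfu)
    values = np.full(protein_length, SENTINEL)
    covered = np.zeros(protein_length, dtype=bool)
    reducer = {"mean": np.mean, "min": np.min, "max": np.max}[reduce]
    for i, vals in enumerate(buckets):
        if vals:
            values[i] = reducer(vals)
            covered[i] = True
    return ResidueProfile(values=values, covered=covered)


def write_bfactor_pdb(
    structure_in,
    profile: ResidueProfile,
    out_path,
    offset: int = 0,
) -> None:
    """Rewrite a PDB with B-factors taken from a residue profile.

    Only columns 61–66 of ATOM/HETATM records change; every other byte of
    the file is preserved.  ``offset`` reconciles structure numbering with
    profile numbering: profile residue = structure residue − offset.

    Raises
    ------
    MappingError
        If any structure residue falls outside the profile range (all
        offending residue numbers are listed).
    """
    with open(structure_in) as fh:
        lines = fh.read().splitlines(keepends=True)
    missing = []
    out_lines = []
    for line in lines:
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 66:
            resseq = int(line[22:26])
            idx = resseq - offset
            if not 1 <= idx <= len(profile):
                missing.append(resseq)
                out_lines.append(line)
                continue
            b = profile.bfactor(idx)
            out_lines.append(line[:60] + f"{b:6.2f}" + line[66:])
        else:
            out_lines.append(line)
    if missing:
        raise MappingError(
            "structure residues outside profile range: "
            f"{sorted(set(missing))}"
        )
    with open(out_path, "w") as fh:
        fh.writelines(out_lines)


def read_bfactor_profile(
    pdb_path, offset: int = 0, sentinel: float = SENTINEL
) -> ResidueProfile:
    """Recover a residue profile from the B-factor column of a PDB file.

    The first atom of each residue is read; residues whose B-factor equals
    the sentinel are marked uncovered.  Intended for round-trip checks of
    :func:`write_bfactor_pdb`.
    """
    values: dict[int, float] = {}
    with open(pdb_path) as fh:
        for line in fh:
            if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 66:
                resseq = int(line[22:26]) - offset
                if resseq not in values:
                    values[resseq] = float(line[60:66])
    if not values:
        raise ValidationError(f"no ATOM records in {pdb_path}")
    n = max(values)
    if min(values) < 1:
        raise CoordinateError("residue numbering below 1 after offset")
    vals = np.full(n, sentinel)
    covered = np.zeros(n, dtype=bool)
    for resseq, b in values.items():
        vals[resseq - 1] = b
        covered[resseq - 1] = not np.isclose(b, sentinel)
    return ResidueProfile(values=vals, covered=covered, sentinel=sentinel)
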
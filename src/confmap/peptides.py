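"""Peptide primitives: residue alphabet, exchangeable-amide counting, records.

The number of exchangeable backbone amide hydrogens of a peptic peptide is
the denominator of relative fractional uptake (RFU).  The convention used by
default matches the MaxUptake column of DynamX state exports: the peptide's
first residue is excluded (its amide deuterium is lost during workup at the
new N-terminus) and prolines are excluded everywhere because they carry no
backbone amide hydrogen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import CoordinateError, ValidationError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


def exchangeable_amides(sequence: str, n_term_excluded: int = 1) -> int:
    """Count exchangeable backbone amide hydrogens of a peptide.

    Parameters
    ----------
    sequence
        One-letter amino-acid sequence.
    n_term_excluded
        Number of N-terminal residues excluded from the count.  The default
        (1) reproduces the ``L - 1 - nPro`` convention; pass 2 for the
        fast-back-exchange convention that also drops the second residue.

    Returns
    -------
    int
        Number of backbone amides able to retain deuterium; never negative.
    """
    if not sequence:
        raise ValidationError("empty peptide sequence")
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise ValidationError(f"unknown residue letter(s): {sorted(bad)}")
    if n_term_excluded < 1:
        raise ValidationError("n_term_excluded must be >= 1")
    tail = sequence[n_term_excluded:]
    return sum(1 for aa in tail if aa != "P")


@dataclass(frozen=True)
class PeptideRecord:
    """A peptic peptide located on its parent protein (1-based, inclusive)."""

    protein_id: str
    start: int
    end: int
    sequence: str
    max_uptake: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise CoordinateError(
                f"peptide end {self.end} precedes start {self.start}"
            )
        if len(self.sequence) != self.end - self.start + 1:
            raise CoordinateError(
                f"sequence length {len(self.sequence)} does not match "
                f"span {self.start}-{self.end}"
            )
        if self.max_uptake < 0:
            object.__setattr__(
                self, "max_uptake", exchangeable_amides(self.sequence)
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1
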
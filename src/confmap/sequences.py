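"""Bundled reference sequences and a minimal FASTA reader."""

from __future__ import annotations

from importlib import resources

from .errors import FormatError, ValidationError


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {header: sequence} mapping."""
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            elif name is None:
                raise FormatError("FASTA sequence data before first header")
            else:
                chunks.append(line)
    if name is not None:
        records[name] = "".join(chunks)
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def tpor_sequence(start: int = 1, end: int | None = None) -> str:
    """Human thrombopoietin receptor (MPL, UniProt P40238), 1-based slice.

    The extracellular D1D2 module of the recombinant construct spans
    Q26–Q290 (histidine tag excluded); ``tpor_sequence(26, 290)`` returns it.
    """
    with resources.as_file(
        resources.files("confmap.data") / "tpor_P40238.fasta"
    ) as path:
        seq = next(iter(read_fasta(path).values()))
    if end is None:
        end = len(seq)
    if not 1 <= start <= end <= len(seq):
        raise ValidationError(
            f"slice {start}-{end} outside sequence of length {len(seq)}"
        )
    return seq[start - 1 : end]


TPOR_D1D2_SPAN = (26, 290)
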
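#!/usr/bin/env python
"""Project the 60 min ΔRFU onto a structure via the B-factor column.

Builds a synthetic Cα-trace PDB for the 200-residue protein, inserts the
per-residue mean ΔRFU as B-factor (sentinel 999.99 where no peptide covers
a residue) and reports the symmetric color-scale limits a renderer should
use so zero maps to the midpoint of the red–blue gradient.
"""

import json
from pathlib import Path

import pandas as pd

from confmap import project_to_residues, synthetic as syn, write_bfactor_pdb

HDX = Path(__file__).resolve().parents[1] / "results" / "hdx"


def main() -> None:
    records = pd.read_csv(HDX / "differential.csv")
    profile = project_to_residues(records, 200, 60.0)

    pdb_in = HDX / "model.pdb"
    pdb_in.write_text(syn.synthetic_ca_pdb(200))
    pdb_out = HDX / "model_delta_rfu.pdb"
    write_bfactor_pdb(pdb_in, profile, pdb_out)

    lo, hi = profile.color_scale_limits
    meta = {
        "covered_residues": int(profile.covered.sum()),
        "uncovered_residues": int((~profile.covered).sum()),
        "color_scale": [lo, hi],
        "sentinel": profile.sentinel,
    }
    (HDX / "structure_map.json").write_text(json.dumps(meta, indent=2) + "\n")
    print(f"wrote {pdb_out.name}: {meta['covered_residues']} residues colored, "
          f"scale [{lo:+.3f}, {hi:+.3f}], sentinel {profile.sentinel}")


if __name__ == "__main__":
    main()
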
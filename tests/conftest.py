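"""Shared fixtures: simulated two-state HDx experiments and FTIR inputs."""

from __future__ import annotations

import numpy as np
import pytest

from confmap import synthetic as syn

RESIDUES = list("ACDEFGHIKLMNQRSTVWY")  # no proline: peptide maps stay simple


def random_sequence(n: int, seed: int, residues=RESIDUES) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(residues, n))


@pytest.fixture(scope="session")
def planted_hdx():
    """Two-state experiment with a deprotected region planted at 30–60.

    State A carries PF = 2 in residues 30–60 against a PF = 100 baseline
    (state B); 200 residues, 3 replicates, 0.05 Da noise.
    """
    seq = random_sequence(200, seed=1)
    pf_ref = np.full(200, 100.0)
    pf_dep = pf_ref.copy()
    pf_dep[29:60] = 2.0
    peptides = syn.generate_peptide_map(
        seq, mean_length=12, target_redundancy=3.0, seed=2
    )
    spec_a = syn.HDXSimSpec(sequence=seq, protection_factors=pf_dep, seed=11)
    spec_b = syn.HDXSimSpec(sequence=seq, protection_factors=pf_ref, seed=12)
    table_a = syn.simulate_hdx_experiment(spec_a, peptides, state="A")
    table_b = syn.simulate_hdx_experiment(spec_b, peptides, state="B")
    return {
        "sequence": seq, "peptides": peptides, "region": (30, 60),
        "table_a": table_a, "table_b": table_b,
        "spec_a": spec_a, "spec_b": spec_b,
    }


@pytest.fixture(scope="session")
def null_hdx():
    """Two identically protected states differing only in replicate noise."""
    seq = random_sequence(8200, seed=7)
    rng = np.random.default_rng(17)
    pf = np.maximum(np.exp(rng.uniform(np.log(2), np.log(200), len(seq))), 1.0)
    peptides = syn.generate_peptide_map(
        seq, mean_length=12, target_redundancy=3.0, seed=8
    )
    spec_a = syn.HDXSimSpec(sequence=seq, protection_factors=pf, seed=21)
    spec_b = syn.HDXSimSpec(sequence=seq, protection_factors=pf, seed=22)
    return {
        "table_a": syn.simulate_hdx_experiment(spec_a, peptides, state="A"),
        "table_b": syn.simulate_hdx_experiment(spec_b, peptides, state="B"),
        "peptides": peptides,
    }


@pytest.fixture(scope="session")
def vapor_reference():
    from confmap.ftir import Spectrum

    grid = syn.default_grid()
    return Spectrum(grid, syn.water_vapor_reference(grid), label="vapor")


@pytest.fixture(scope="session")
def noisy_library():
    """50-entry calibration library with 0.002 AU spectral noise."""
    return syn.simulate_ftir_library(n_proteins=50, noise_sd=0.002, seed=4)
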
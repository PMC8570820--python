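from __future__ import annotations

import numpy as np
import pytest

import pzsearch as pz


@pytest.fixture(scope="session")
def blosum62():
    return pz.load_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def ka_params():
    return pz.default_params("BLOSUM62", 11, 1)


@pytest.fixture(scope="session")
def query300():
    """A fixed 300-residue query drawn from the background composition."""
    rng = np.random.default_rng(42)
    return pz.AminoAcidSequence("query300aa", pz.random_protein(300, rng))


@pytest.fixture(scope="session")
def planted_reference(query300):
    """The standard benchmarking fixture: 20 samples x 250 decoys plus 60
    homologs of the query planted at identities 0.9/0.8/0.7/0.6."""
    specs = [
        pz.PlantSpec(query300, 15, ident, 0.01) for ident in (0.9, 0.8, 0.7, 0.6)
    ]
    config = pz.SimConfig(
        n_samples=20, seqs_per_sample=250, planted=specs, rng_seed=42, n_chunks=1
    )
    return pz.generate_reference(config)


@pytest.fixture(scope="session")
def small_reference(query300):
    """A small reference for fast end-to-end tests (4 samples x 40 decoys,
    8 planted homologs)."""
    specs = [pz.PlantSpec(query300, 4, ident, 0.01) for ident in (0.9, 0.7)]
    config = pz.SimConfig(
        n_samples=4, seqs_per_sample=40, planted=specs, rng_seed=7, n_chunks=2
    )
    return pz.generate_reference(config)


def random_protein_pair(rng, max_len=300, homolog=False):
    """A (query, subject) residue pair; optionally a mutated homolog."""
    qlen = int(rng.integers(30, max_len + 1))
    q = pz.random_protein(qlen, rng)
    if homolog:
        ident = float(rng.uniform(0.5, 0.95))
        s, _ = pz.mutate_homolog(q, ident, 0.02, rng)
    else:
        s = pz.random_protein(int(rng.integers(30, max_len + 1)), rng)
    return q, s
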
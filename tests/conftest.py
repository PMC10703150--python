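"""Shared fixtures: tiny hand-built objects and a mid-sized synthetic bundle."""

from __future__ import annotations

import pytest

from hlaselect.io import Allele, AlignedAlleleSet
from hlaselect.simulate import (
    generate_alleles,
    generate_frequencies,
    plant_effects,
)


@pytest.fixture
def toy_alignment() -> AlignedAlleleSet:
    """Six A-locus alleles, 4 columns: position 1 split 3/3, the rest invariant."""
    return AlignedAlleleSet([
        Allele("A*01:01", "AKLM"),
        Allele("A*01:02", "AKLM"),
        Allele("A*01:03", "AKLM"),
        Allele("A*02:01", "RKLM"),
        Allele("A*02:02", "RKLM"),
        Allele("A*02:03", "RKLM"),
    ])


@pytest.fixture(scope="session")
def synthetic_bundle():
    """A small but realistic dataset: 400 alleles, 30 variable positions,
    2 populations, 5 planted positions of effect +/-0.5, noise 0.1."""
    alleles, tree = generate_alleles(
        400, length=183, n_variable_positions=30, seed=11
    )
    populations = ["POP1", "POP2"]
    truth = plant_effects(
        alleles, populations, n_planted=5, effect_size=0.5, noise_sd=0.1,
        seed=11, tree=tree,
    )
    table = generate_frequencies(alleles, truth)
    return alleles, tree, truth, table
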
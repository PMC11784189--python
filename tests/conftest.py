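"""Shared fixtures: worked-example trees and a small simulated dataset."""

from __future__ import annotations

import pytest

from amfphylo.refset import ReferenceRecord
from amfphylo.simulate import SimConfig, simulate_dataset
from amfphylo.tree import parse_newick


def _ref(seq_id, genus, species, family="Glomeraceae", order="Glomerales"):
    return ReferenceRecord(
        seq_id=seq_id,
        sequence="ACGT",
        order_=order,
        family=family,
        genus=genus,
        species=species,
    )


@pytest.fixture(scope="session")
def funneliformis_case():
    """Four ASVs in one monophyletic group with two F. coronatus references."""
    tree = parse_newick("((ASV177,(ASV178,Fcor1)),(ASV179,(ASV166,Fcor2)));")
    refs = [
        _ref("Fcor1", "Funneliformis", "Funneliformis coronatus"),
        _ref("Fcor2", "Funneliformis", "Funneliformis coronatus"),
    ]
    return tree, refs


@pytest.fixture(scope="session")
def rhizophagus_case():
    """ASV 174 falling between two different Rhizophagus species."""
    tree = parse_newick("((ASV174,(Rirr,Rfas)),Para1);")
    refs = [
        _ref("Rirr", "Rhizophagus", "Rhizophagus irregularis"),
        _ref("Rfas", "Rhizophagus", "Rhizophagus fasciculatus"),
        _ref("Para1", "Paraglomus", "Paraglomus occultum",
             family="Paraglomeraceae", order="Paraglomerales"),
    ]
    return tree, refs


@pytest.fixture(scope="session")
def small_sim():
    """One default-condition simulated dataset, shared across tests."""
    return simulate_dataset(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_sim_world(small_sim):
    return small_sim[0]


@pytest.fixture(scope="session")
def small_sim_comm(small_sim):
    return small_sim[1]
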
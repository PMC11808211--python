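"""Shared fixtures: hand-built taxonomies, fate tables and record sets."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import pytest

from vacniche.taxodist import ParasiteTaxonomy, build_tree
from vacniche.types import AssociationRecord, FateTable


def tax(species: str, kingdom="K", phylum="P", klass="C", order="O",
        family="F", genus="G") -> ParasiteTaxonomy:
    """Compact seven-rank taxonomy; pass None for a missing entry."""
    return ParasiteTaxonomy(
        species=species,
        ranks=(kingdom, phylum, klass, order, family, genus, species),
    )


@pytest.fixture
def toy_tree():
    """Seven helminths: L1/L2/A1 congeners-ish, N* progressively farther.

    Distances (self-excluded minima are exercised in the null tests):
      d(A1, L1) = 2 (same genus), d(A1, L2) = 4 (same family),
      d(N1, L1) = 4, d(N2, L*) = 6, d(N3, L*) = 10, d(R1, L*) = 4.
    """
    taxa = [
        tax("L1", genus="G1"),
        tax("L2", genus="G2"),
        tax("A1", genus="G1"),
        tax("N1", genus="G3"),
        tax("N2", family="F2", genus="G4"),
        tax("N3", klass="C2", order="O2", family="F3", genus="G5"),
        tax("R1", genus="G6"),
    ]
    return build_tree(taxa)


@pytest.fixture
def toy_fate_table():
    species = ["L1", "L2", "A1", "N1", "N2", "N3", "R1"]
    fate = {
        "L1": "lost", "L2": "lost", "A1": "acquired",
        "N1": "not_acquired", "N2": "not_acquired", "N3": "not_acquired",
        "R1": "retained",
    }
    return FateTable(
        invasion_id="inv-toy",
        focal_host="Focalis hostus",
        fate_map=fate,
        parasite_type_map={sp: "helminth" for sp in species},
        community_nonnative=frozenset({"N1", "N2", "N3"}),
    )


def rec(host: str, parasite: str, range_label: str, invasion="inv1",
        ptype="helminth", modes=("close",)) -> AssociationRecord:
    return AssociationRecord(
        host_species=host,
        parasite_species=parasite,
        parasite_type=ptype,
        transmission_modes=frozenset(modes),
        range_label=range_label,
        invasion_id=invasion,
    )


# Focal-host parasite counts of the five invasive mammals (well-studied
# literature values used as worked-example inputs throughout the suite).
TABLE1 = {
    "Cervus elaphus":     dict(native=104, nonnative=31, retained=17, lost=87,  acquired=14),
    "Procyon lotor":      dict(native=126, nonnative=18, retained=7,  lost=119, acquired=11),
    "Rupicapra rupicapra": dict(native=58,  nonnative=22, retained=13, lost=45,  acquired=9),
    "Sus scrofa":         dict(native=76,  nonnative=16, retained=9,  lost=67,  acquired=7),
    "Vulpes vulpes":      dict(native=127, nonnative=38, retained=25, lost=102, acquired=13),
}


def fate_table_from_counts(
    host: str, retained: int, lost: int, acquired: int, not_acquired: int = 0
) -> FateTable:
    """Synthetic fate table realising given per-fate counts."""
    fate_map: Dict[str, str] = {}
    for prefix, n, fate in (
        ("ret", retained, "retained"), ("lost", lost, "lost"),
        ("acq", acquired, "acquired"), ("nacq", not_acquired, "not_acquired"),
    ):
        for i in range(n):
            fate_map[f"{prefix}{i}"] = fate
    community = frozenset(sp for sp, f in fate_map.items() if f == "not_acquired")
    return FateTable(
        invasion_id=f"inv-{host}",
        focal_host=host,
        fate_map=fate_map,
        parasite_type_map={sp: "helminth" for sp in fate_map},
        community_nonnative=community,
    )
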
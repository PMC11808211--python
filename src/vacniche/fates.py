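"""Classify parasites of one invasion into the four fates and summarise richness."""

from __future__ import annotations

from typing import Dict, Iterable, Set

import pandas as pd

from .types import (
    FATES,
    PARASITE_TYPES,
    AssociationRecord,
    FateTable,
    PairedPSR,
    ValidationError,
    _norm_name,
)


def classify_fates(records: Iterable[AssociationRecord], focal_host: str) -> FateTable:
    """Partition an invasion's parasites into retained / lost / acquired /
    not-acquired, from the focal host's point of view.

    Retained: sampled from the focal host in both ranges.  Lost: focal host,
    native range only.  Acquired: focal host, non-native range only.
    Not-acquired: present on other hosts in the non-native range but never
    sampled from the focal host.  A parasite the focal host lost may still
    circulate in the invaded community; its fate stays ``lost`` and its
    community presence is recorded in ``community_nonnative``.
    """
    records = list(records)
    focal_host = _norm_name(focal_host)
    if not records:
        raise ValidationError("no records supplied")
    invasion_ids = {r.invasion_id for r in records}
    if len(invasion_ids) != 1:
        raise ValidationError(
            f"records span multiple invasions: {sorted(invasion_ids)}"
        )
    invasion_id = invasion_ids.pop()

    focal_native: Set[str] = set()
    focal_nonnative: Set[str] = set()
    community_nonnative: Set[str] = set()
    ptype: Dict[str, str] = {}
    for r in records:
        ptype[r.parasite_species] = r.parasite_type
        if r.host_species == focal_host:
            (focal_native if r.range_label == "native" else focal_nonnative).add(
                r.parasite_species
            )
        elif r.range_label == "nonnative":
            community_nonnative.add(r.parasite_species)
    if not focal_native and not focal_nonnative:
        raise ValidationError(f"focal host {focal_host!r} has no records in this invasion")

    retained = focal_native & focal_nonnative
    lost = focal_native - focal_nonnative
    acquired = focal_nonnative - focal_native
    not_acquired = community_nonnative - focal_native - focal_nonnative

    fate_map: Dict[str, str] = {}
    for sp in retained:
        fate_map[sp] = "retained"
    for sp in lost:
        fate_map[sp] = "lost"
    for sp in acquired:
        fate_map[sp] = "acquired"
    for sp in not_acquired:
        fate_map[sp] = "not_acquired"

    return FateTable(
        invasion_id=invasion_id,
        focal_host=focal_host,
        fate_map=fate_map,
        parasite_type_map={sp: ptype[sp] for sp in fate_map},
        community_nonnative=frozenset(community_nonnative),
    )


def psr(fate_table: FateTable, range_label: str) -> int:
    """Parasite species richness of the focal host in one range.

    native PSR = |retained| + |lost|; non-native PSR = |retained| + |acquired|.
    """
    if range_label == "native":
        return len(fate_table.retained) + len(fate_table.lost)
    if range_label == "nonnative":
        return len(fate_table.retained) + len(fate_table.acquired)
    raise ValidationError(f"unknown range {range_label!r}; expected 'native' or 'nonnative'")


def paired_psr(fate_table: FateTable) -> PairedPSR:
    return PairedPSR(
        focal_host=fate_table.focal_host,
        native_psr=psr(fate_table, "native"),
        nonnative_psr=psr(fate_table, "nonnative"),
    )


def fate_counts_by_type(fate_table: FateTable) -> pd.DataFrame:
    """Complete 5 x 4 contingency of (parasite type x fate) counts, zeros included."""
    counts = pd.DataFrame(
        0, index=list(PARASITE_TYPES), columns=list(FATES), dtype=int
    )
    for sp, fate in fate_table.fate_map.items():
        counts.loc[fate_table.parasite_type_map[sp], fate] += 1
    counts.index.name = "parasite_type"
    return counts
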
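"""Synthetic host-parasite invasions with known ground truth.

Emulates the structure of literature-derived mammal parasite records: per
focal host and per parasite type, sets of retained / lost / acquired /
not-acquired parasites over a randomly generated seven-rank taxonomy, plus an
ultrametric host tree, host traits, bioclimatic variable tables and
phylogenetic host-specificity scores.

The vacated-niche signal is tunable through a single clustering parameter
``theta``: acquired parasites are drawn from the lost + not-acquired candidate
pool with weight exp(-theta * d), where d is the candidate's minimum
taxonomic distance to the lost candidates (self-pairs excluded).  theta = 0
gives uniform acquisition -- exactly the random-acquisition null -- and large
theta forces acquisition of the closest relatives of lost parasites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .taxodist import ParasiteTaxonomy, TaxonomicTree, build_tree, min_distance_profile
from .types import (
    PARASITE_TYPES,
    TRANSMISSION_MODES,
    AssociationRecord,
    FateTable,
    SpecificityScore,
    ValidationError,
)

# CRP concentration per rank below kingdom: smaller = more lumping.  Chosen to
# give a handful of phyla/orders per type and genera holding ~2-3 species, so
# congeners of lost parasites exist in realistic numbers.
DEFAULT_CONCENTRATIONS: Mapping[str, float] = {
    "phylum": 0.6,
    "class": 0.6,
    "order": 1.0,
    "family": 1.5,
    "genus": 2.5,
}

# Candidate richness ranges per (host x parasite type), inclusive.  Magnitudes
# echo per-type counts of well-sampled mammal invasions (tens of lost and
# community parasites, a handful of acquisitions per type).
DEFAULT_RICHNESS: Mapping[str, Tuple[int, int]] = {
    "retained": (2, 10),
    "lost": (5, 20),
    "acquired": (2, 8),
    "not_acquired": (15, 40),
}


@dataclass
class SimulationConfig:
    n_hosts: int = 5
    parasite_types: Tuple[str, ...] = PARASITE_TYPES
    richness: Mapping[str, Tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_RICHNESS)
    )
    theta: float = 0.0
    concentrations: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONCENTRATIONS)
    )
    # "candidates": acquired drawn from lost + not_acquired (matches the
    # random-acquisition null pool); "not_acquired": restrict to never-hosted
    # species, for pool-mismatch sensitivity analyses.
    acquisition_pool: str = "candidates"
    n_community_hosts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValidationError("theta must be >= 0")
        for fate, (lo, hi) in self.richness.items():
            if lo < 0 or hi < lo:
                raise ValidationError(f"bad richness range for {fate!r}: ({lo}, {hi})")
        if self.acquisition_pool not in ("candidates", "not_acquired"):
            raise ValidationError("acquisition_pool must be 'candidates' or 'not_acquired'")


def _crp_partition(n: int, alpha: float, rng: np.random.Generator) -> List[int]:
    """Chinese-restaurant-process table assignment for n members.

    alpha = 0 lumps everyone into one group; alpha = inf splits everyone.
    """
    labels: List[int] = []
    counts: List[int] = []
    for i in range(n):
        if math.isinf(alpha) or not counts:
            new_p = 1.0
        else:
            new_p = alpha / (i + alpha)
        if not counts or rng.random() < new_p:
            labels.append(len(counts))
            counts.append(1)
        else:
            probs = np.array(counts, dtype=float)
            probs /= probs.sum()
            j = int(rng.choice(len(counts), p=probs))
            labels.append(j)
            counts[j] += 1
    return labels


def generate_taxonomy(
    n_species: int,
    parasite_type: str,
    rng: np.random.Generator,
    concentrations: Optional[Mapping[str, float]] = None,
) -> List[ParasiteTaxonomy]:
    """Random seven-rank taxonomy for one parasite type.

    All species share the type's kingdom; below it, groups are split at each
    rank by a CRP with the configured concentration.  Deterministic given the
    generator state.
    """
    if n_species < 1:
        raise ValidationError("n_species must be >= 1")
    if parasite_type not in PARASITE_TYPES:
        raise ValidationError(f"unknown parasite_type {parasite_type!r}")
    conc = {**DEFAULT_CONCENTRATIONS, **(concentrations or {})}
    prefix = parasite_type[:3].capitalize()
    # paths[i] = list of taxon names, broadest first
    paths: List[List[str]] = [[f"{prefix}_kingdom"] for _ in range(n_species)]
    groups: Dict[Tuple[str, ...], List[int]] = {
        (f"{prefix}_kingdom",): list(range(n_species))
    }
    for rank_i, rank in enumerate(("phylum", "class", "order", "family", "genus")):
        alpha = float(conc[rank])
        new_groups: Dict[Tuple[str, ...], List[int]] = {}
        counter = 0
        for key in sorted(groups):
            members = groups[key]
            labels = _crp_partition(len(members), alpha, rng)
            for member, lab in zip(members, labels):
                name = f"{prefix}_{rank[0]}{counter + lab}"
                paths[member].append(name)
                new_groups.setdefault(key + (name,), []).append(member)
            counter += max(labels) + 1
        groups = new_groups
    taxa = []
    for i, path in enumerate(paths):
        genus = path[-1]
        species = f"{genus} sp{i}"
        taxa.append(ParasiteTaxonomy(species=species, ranks=tuple(path) + (species,)))
    return taxa


def _draw_count(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def _random_modes(rng: np.random.Generator) -> frozenset:
    k = int(rng.choice([1, 1, 1, 2], p=[0.6, 0.1, 0.1, 0.2]))
    return frozenset(rng.choice(TRANSMISSION_MODES, size=k, replace=False))


def generate_invasion(
    taxonomies_by_type: Mapping[str, Sequence[ParasiteTaxonomy]],
    config: SimulationConfig,
    rng: np.random.Generator,
    invasion_id: str = "inv1",
    focal_host: str = "Focalis hostus",
) -> Tuple[List[AssociationRecord], FateTable, Dict[str, frozenset]]:
    """One invasion: association records plus the ground-truth fate table.

    Per parasite type: candidate lost / retained / not-acquired sets are drawn
    uniformly without replacement from the type's species; the acquired set is
    then drawn (without replacement) from the candidate pool with the
    exponential relatedness weights, and drawn species leave their candidate
    set, so ``classify_fates`` on the emitted records reproduces the truth
    exactly.  Also returns per-type transmission-mode assignments.
    """
    fate_map: Dict[str, str] = {}
    ptype_map: Dict[str, str] = {}
    modes: Dict[str, frozenset] = {}
    for parasite_type in config.parasite_types:
        taxa = list(taxonomies_by_type[parasite_type])
        species = [t.species for t in taxa]
        n_ret = _draw_count(rng, *config.richness["retained"])
        n_lost = _draw_count(rng, *config.richness["lost"])
        n_nacq = _draw_count(rng, *config.richness["not_acquired"])
        n_acq = _draw_count(rng, *config.richness["acquired"])
        need = n_ret + n_lost + n_nacq
        if need > len(species):
            raise ValidationError(
                f"taxonomy for {parasite_type!r} has {len(species)} species; "
                f"{need} requested"
            )
        picked = list(rng.choice(species, size=need, replace=False))
        retained = picked[:n_ret]
        lost0 = picked[n_ret : n_ret + n_lost]
        nacq0 = picked[n_ret + n_lost :]
        if config.acquisition_pool == "candidates":
            pool = sorted(lost0) + sorted(nacq0)
        else:
            pool = sorted(nacq0)
        if n_acq > len(pool):
            raise ValidationError(
                f"acquisition pool for {parasite_type!r} has {len(pool)} members; "
                f"{n_acq} acquisitions requested"
            )
        tree = build_tree(taxa)
        profile = min_distance_profile(pool, lost0, tree, exclude_self=True)
        # a candidate with no defined niche distance (lone lost species) gets
        # the most-distant weight rather than a spurious advantage
        weights = np.array(
            [math.exp(-config.theta * profile.get(p, 14.0)) for p in pool], dtype=float
        )
        weights /= weights.sum()
        acquired = list(
            rng.choice(pool, size=n_acq, replace=False, p=weights)
        )
        lost = [p for p in lost0 if p not in set(acquired)]
        nacq = [p for p in nacq0 if p not in set(acquired)]
        for group, fate in (
            (retained, "retained"),
            (lost, "lost"),
            (acquired, "acquired"),
            (nacq, "not_acquired"),
        ):
            for sp in group:
                fate_map[sp] = fate
                ptype_map[sp] = parasite_type
                modes[sp] = _random_modes(rng)

    community_hosts = [f"Communis hostus{i}" for i in range(1, config.n_community_hosts + 1)]
    records: List[AssociationRecord] = []

    def add(host: str, sp: str, range_label: str) -> None:
        records.append(
            AssociationRecord(
                host_species=host,
                parasite_species=sp,
                parasite_type=ptype_map[sp],
                transmission_modes=modes[sp],
                range_label=range_label,
                invasion_id=invasion_id,
            )
        )

    not_acquired_all = [sp for sp, f in fate_map.items() if f == "not_acquired"]
    for sp, fate in sorted(fate_map.items()):
        if fate in ("retained", "lost"):
            add(focal_host, sp, "native")
        if fate in ("retained", "acquired"):
            add(focal_host, sp, "nonnative")
    for sp in sorted(not_acquired_all):
        host = community_hosts[int(rng.integers(len(community_hosts)))]
        add(host, sp, "nonnative")

    truth = FateTable(
        invasion_id=invasion_id,
        focal_host=focal_host,
        fate_map=fate_map,
        parasite_type_map=ptype_map,
        community_nonnative=frozenset(not_acquired_all),
    )
    return records, truth, modes


def _coalescent_newick(names: Sequence[str], rng: np.random.Generator) -> str:
    """Random ultrametric tree: pairs of lineages merge at exponential times."""
    if len(names) < 2:
        raise ValidationError("need at least 2 hosts for a tree")
    nodes = [(f"{n.replace(' ', '_')}", 0.0) for n in names]  # (newick, height)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += float(rng.exponential(scale=2.0 / (k * (k - 1))))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (nwk_i, h_i) = nodes[i]
        (nwk_j, h_j) = nodes[j]
        merged = f"({nwk_i}:{t - h_i:.6f},{nwk_j}:{t - h_j:.6f})"
        nodes = [nodes[x] for x in range(k) if x not in (i, j)] + [(merged, t)]
    return nodes[0][0] + ";"


def generate_host_tree_and_traits(
    n_hosts: int, rng: np.random.Generator, host_names: Optional[Sequence[str]] = None
) -> Tuple[str, pd.DataFrame]:
    """Random ultrametric host tree (Newick) and a host trait table."""
    if n_hosts < 2:
        raise ValidationError("n_hosts must be >= 2")
    hosts = list(host_names) if host_names else [f"Hostus sp{i}" for i in range(n_hosts)]
    newick = _coalescent_newick(hosts, rng)
    traits = pd.DataFrame(
        {
            "host": hosts,
            "time_since_invasion": rng.uniform(50, 300, size=n_hosts).round(1),
            "population_density": np.exp(rng.normal(2.0, 1.0, size=n_hosts)).round(3),
            "home_range_area": np.exp(rng.normal(1.0, 1.5, size=n_hosts)).round(4),
        }
    )
    return newick, traits


def generate_specificity_scores(
    species: Sequence[str], rng: np.random.Generator
) -> List[SpecificityScore]:
    """Standard-normal phylogenetic host-specificity z-scores, one per parasite."""
    return [
        SpecificityScore(parasite_species=sp, z_value=float(z))
        for sp, z in zip(sorted(set(species)), rng.normal(size=len(set(species))))
    ]


def generate_env_table(
    n_locations: int, rng: np.random.Generator, shift: float = 0.0
) -> pd.DataFrame:
    """Location x variable table of 19 bioclim-style variables.

    ``shift`` displaces the range's climatic mean, controlling dissimilarity
    between two generated ranges.
    """
    data = {
        f"bio{i}": rng.normal(loc=shift * (1 + 0.1 * i), scale=1.0, size=n_locations)
        for i in range(1, 20)
    }
    df = pd.DataFrame(data)
    df.insert(0, "location", [f"loc{i}" for i in range(n_locations)])
    return df


def generate_dataset(config: SimulationConfig) -> Dict[str, object]:
    """Full input bundle for one simulated study: associations across
    ``n_hosts`` invasions, taxonomy, host tree, traits, climate tables,
    specificity scores and ground-truth fate tables."""
    rng = np.random.default_rng(config.seed)
    taxonomies = {
        pt: generate_taxonomy(80, pt, rng, config.concentrations)
        for pt in config.parasite_types
    }
    hosts = [f"Focalis sp{i}" for i in range(config.n_hosts)]
    records: List[AssociationRecord] = []
    truths: List[FateTable] = []
    all_modes: Dict[str, frozenset] = {}
    for i, host in enumerate(hosts):
        recs, truth, modes = generate_invasion(
            taxonomies, config, rng, invasion_id=f"inv{i}", focal_host=host
        )
        records.extend(recs)
        truths.append(truth)
        all_modes.update(modes)
    newick, traits = generate_host_tree_and_traits(config.n_hosts, rng, hosts)
    scores = generate_specificity_scores(
        [r.parasite_species for r in records], rng
    )
    env_native = generate_env_table(6, rng, shift=0.0)
    env_nonnative = generate_env_table(6, rng, shift=0.5)
    return {
        "records": records,
        "taxonomies": taxonomies,
        "host_tree_newick": newick,
        "traits": traits,
        "specificity_scores": scores,
        "env_native": env_native,
        "env_nonnative": env_nonnative,
        "fate_tables": truths,
        "transmission_modes": all_modes,
    }
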
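"""Fixed-depth taxonomic trees with unit branch lengths.

Parasite relatedness is proxied by taxonomy: each species carries a seven-rank
classification (kingdom, phylum, class, order, family, genus, species) and the
collection is assembled into a rooted tree whose internal nodes are taxa and
whose edges all have length 1.  Every leaf sits at depth 7, so the path length
between two species is ``2 * (7 - depth of their most specific shared taxon)``
-- an even integer in {0, 2, ..., 14}, with 0 iff the species are identical.

Missing rank entries are replaced by per-species placeholders, so an
incompletely classified species can never appear *more* related to another
species than its named ranks support: the placeholder forces divergence at the
last shared named rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

from .types import EmptySetError, ValidationError, VacnicheError, _norm_name

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
N_RANKS = len(RANKS)
MAX_PD = 2 * N_RANKS  # two species sharing only the root


class UnknownSpeciesError(VacnicheError, KeyError):
    def __init__(self, species: str):
        super().__init__(f"species {species!r} is not a leaf of this taxonomic tree")


@dataclass(frozen=True)
class ParasiteTaxonomy:
    """Seven-rank classification of one parasite species.

    ``ranks`` is ordered broadest to narrowest; ``None`` (or empty string on
    input) marks a missing entry.  The species-level entry, when present, must
    equal ``species``.
    """

    species: str
    ranks: Tuple[Optional[str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", _norm_name(self.species))
        if len(self.ranks) != N_RANKS:
            raise ValidationError(
                f"{self.species!r}: expected {N_RANKS} ranks, got {len(self.ranks)}"
            )
        cleaned = tuple(
            (None if r is None or str(r).strip() == "" else _norm_name(r))
            for r in self.ranks
        )
        if cleaned[-1] is None:
            cleaned = cleaned[:-1] + (self.species,)
        elif cleaned[-1] != self.species:
            raise ValidationError(
                f"species-rank entry {cleaned[-1]!r} does not match species name "
                f"{self.species!r}"
            )
        object.__setattr__(self, "ranks", cleaned)


NodeKey = Tuple[str, ...]  # path of taxon names from the root ('' = root)


class TaxonomicTree:
    """Rooted fixed-depth tree over a set of classified species.

    The tree is represented by each leaf's path of node keys; a node key is the
    tuple of taxon names from the root down to that node, so shared rank
    prefixes share nodes by construction.
    """

    def __init__(self, taxonomies: Iterable[ParasiteTaxonomy]):
        taxonomies = list(taxonomies)
        if not taxonomies:
            raise EmptySetError("cannot build a taxonomic tree from no species")
        self._paths: Dict[str, Tuple[NodeKey, ...]] = {}
        for tax in taxonomies:
            if tax.species in self._paths:
                raise ValidationError(f"duplicate species name {tax.species!r}")
            names: List[str] = []
            for rank, entry in zip(RANKS, tax.ranks):
                if entry is None:
                    # unique placeholder: incompleteness never creates relatedness
                    entry = f"?{rank}:{tax.species}"
                names.append(entry)
            path = tuple(tuple(names[: i + 1]) for i in range(N_RANKS))
            self._paths[tax.species] = path

    @property
    def species(self) -> Tuple[str, ...]:
        return tuple(sorted(self._paths))

    def __contains__(self, species: str) -> bool:
        return species in self._paths

    def __len__(self) -> int:
        return len(self._paths)

    def _path(self, species: str) -> Tuple[NodeKey, ...]:
        try:
            return self._paths[species]
        except KeyError:
            raise UnknownSpeciesError(species) from None

    def lca_depth(self, p: str, q: str) -> int:
        """Depth (root = 0) of the most specific taxon shared by two species."""
        pa, qa = self._path(p), self._path(q)
        depth = 0
        for a, b in zip(pa, qa):
            if a != b:
                break
            depth += 1
        return depth

    def distance(self, p: str, q: str) -> int:
        """Unit-edge path length between two leaves (even, 0..14)."""
        return 2 * (N_RANKS - self.lca_depth(p, q))

    def edges(self) -> Iterator[Tuple[NodeKey, NodeKey]]:
        """All (parent, child) edges; the root is the empty tuple ``()``."""
        seen = set()
        for path in self._paths.values():
            parent: NodeKey = ()
            for node in path:
                edge = (parent, node)
                if edge not in seen:
                    seen.add(edge)
                    yield edge
                parent = node


def build_tree(taxonomies: Iterable[ParasiteTaxonomy]) -> TaxonomicTree:
    """Assemble one fixed-depth unit-branch-length tree from classifications."""
    return TaxonomicTree(taxonomies)


def pairwise_distance(tree: TaxonomicTree, p: str, q: str) -> int:
    """Number of taxonomic levels separating two species (unit edges via LCA)."""
    return tree.distance(p, q)


def min_distances(
    query_set: Iterable[str],
    reference_set: Iterable[str],
    tree: TaxonomicTree,
) -> List[int]:
    """For each query species, the distance to its closest reference relative.

    Output order follows sorted query names.  Raises :class:`EmptySetError`
    when either set is empty (no loss and/or acquisition of a parasite type).
    """
    query = sorted(set(query_set))
    reference = sorted(set(reference_set))
    if not query or not reference:
        raise EmptySetError(
            "no loss and/or acquisition of a parasite type: "
            "minimum distances are undefined for an empty set"
        )
    return [min(tree.distance(q, r) for r in reference) for q in query]


def min_distance_profile(
    pool: Sequence[str],
    lost: Iterable[str],
    tree: TaxonomicTree,
    exclude_self: bool = True,
) -> Dict[str, int]:
    """Min distance from each pool member to the lost set, optionally skipping
    the self-pair for pool members that are themselves lost species.

    A lone lost species with no other lost relative is omitted (its niche
    distance is undefined).
    """
    lost = set(lost)
    profile: Dict[str, int] = {}
    for p in pool:
        refs = lost - {p} if exclude_self else lost
        if not refs:
            continue
        profile[p] = min(tree.distance(p, r) for r in refs)
    return profile
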
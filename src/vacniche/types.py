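"""Domain types for host-parasite invasion analyses.

The vocabulary follows the macroecology of mammal invasions: a *focal host*
is a species sampled in both its native and non-native (invaded) range, and
every parasite associated with its invasion has exactly one *fate*:

* ``retained``     -- sampled from the focal host in both ranges,
* ``lost``         -- sampled from the focal host only in the native range,
* ``acquired``     -- sampled from the focal host only in the non-native range,
* ``not_acquired`` -- circulating in the invaded community (on other hosts)
  but never sampled from the focal host.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Mapping

PARASITE_TYPES = ("arthropod", "bacteria", "helminth", "protozoa", "virus")
TRANSMISSION_MODES = ("close", "nonclose", "intermediate", "vector")
RANGE_LABELS = ("native", "nonnative")
FATES = ("retained", "lost", "acquired", "not_acquired")


class VacnicheError(Exception):
    """Base class for all package errors."""


class ValidationError(VacnicheError, ValueError):
    """A value violates a domain invariant."""


class SchemaError(VacnicheError, ValueError):
    """An input table is missing required structure."""


class EmptySetError(VacnicheError, ValueError):
    """An operation received an empty parasite set it cannot handle."""


class NotComputableError(VacnicheError):
    """No loss and/or acquisition of a parasite type: statistic undefined."""


class DegenerateNullError(VacnicheError):
    """The null distribution has zero spread; z-score undefined."""


class DependencyError(VacnicheError):
    """A pipeline stage is missing its upstream output."""


def _norm_name(name: str) -> str:
    """Canonical parasite/host identity: trimmed, internal whitespace collapsed."""
    return " ".join(str(name).split())


@dataclass(frozen=True)
class AssociationRecord:
    """One host-parasite sampling association inside one invasion event."""

    host_species: str
    parasite_species: str
    parasite_type: str
    transmission_modes: FrozenSet[str]
    range_label: str
    invasion_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "host_species", _norm_name(self.host_species))
        object.__setattr__(self, "parasite_species", _norm_name(self.parasite_species))
        object.__setattr__(self, "transmission_modes", frozenset(self.transmission_modes))
        if self.parasite_type not in PARASITE_TYPES:
            raise ValidationError(
                f"unknown parasite_type {self.parasite_type!r}; "
                f"expected one of {PARASITE_TYPES}"
            )
        if not self.transmission_modes:
            raise ValidationError("transmission_modes must be a non-empty set")
        bad = self.transmission_modes - set(TRANSMISSION_MODES)
        if bad:
            raise ValidationError(f"unknown transmission modes {sorted(bad)}")
        if self.range_label not in RANGE_LABELS:
            raise ValidationError(
                f"unknown range_label {self.range_label!r}; expected one of {RANGE_LABELS}"
            )


@dataclass
class FateTable:
    """Per-invasion partition of parasites into the four fates.

    ``fate_map`` assigns every parasite in the invasion exactly one fate
    (focal-host-centric: a parasite the focal host lost is ``lost`` even if it
    still circulates on other hosts in the invaded range; such species remain
    visible through ``community_nonnative`` and hence in the random-acquisition
    pool, which is ``lost | not_acquired``).
    """

    invasion_id: str
    focal_host: str
    fate_map: Mapping[str, str]
    parasite_type_map: Mapping[str, str]
    community_nonnative: FrozenSet[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for sp, fate in self.fate_map.items():
            if fate not in FATES:
                raise ValidationError(f"unknown fate {fate!r} for {sp!r}")
            if sp not in self.parasite_type_map:
                raise ValidationError(f"parasite {sp!r} has no parasite_type")

    def fate_set(self, fate: str) -> FrozenSet[str]:
        if fate not in FATES:
            raise ValidationError(f"unknown fate {fate!r}")
        return frozenset(sp for sp, f in self.fate_map.items() if f == fate)

    @property
    def retained(self) -> FrozenSet[str]:
        return self.fate_set("retained")

    @property
    def lost(self) -> FrozenSet[str]:
        return self.fate_set("lost")

    @property
    def acquired(self) -> FrozenSet[str]:
        return self.fate_set("acquired")

    @property
    def not_acquired(self) -> FrozenSet[str]:
        return self.fate_set("not_acquired")

    def of_type(self, fate: str, parasite_type: str) -> FrozenSet[str]:
        """Parasites with a given fate restricted to one parasite type."""
        if parasite_type not in PARASITE_TYPES:
            raise ValidationError(f"unknown parasite_type {parasite_type!r}")
        return frozenset(
            sp for sp in self.fate_set(fate)
            if self.parasite_type_map[sp] == parasite_type
        )

    @property
    def not_acquired_pool(self) -> FrozenSet[str]:
        """Species circulating in the invaded community but not on the focal host
        there; includes lost parasites that persist on other hosts."""
        return frozenset(self.community_nonnative - self.retained - self.acquired)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FateTable):
            return NotImplemented
        return (
            self.invasion_id == other.invasion_id
            and self.focal_host == other.focal_host
            and dict(self.fate_map) == dict(other.fate_map)
            and dict(self.parasite_type_map) == dict(other.parasite_type_map)
            and frozenset(self.community_nonnative) == frozenset(other.community_nonnative)
        )


@dataclass(frozen=True)
class SpecificityScore:
    """Phylogenetic host-specificity z-score for one parasite (dimensionless)."""

    parasite_species: str
    z_value: float

    def __post_init__(self) -> None:
        import math

        object.__setattr__(self, "parasite_species", _norm_name(self.parasite_species))
        if not math.isfinite(self.z_value):
            raise ValidationError(f"specificity score for {self.parasite_species!r} is not finite")


@dataclass(frozen=True)
class PairedPSR:
    """Parasite species richness of one focal host in its two ranges."""

    focal_host: str
    native_psr: int
    nonnative_psr: int

    def __post_init__(self) -> None:
        if self.native_psr < 0 or self.nonnative_psr < 0:
            raise ValidationError("PSR counts must be non-negative")
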
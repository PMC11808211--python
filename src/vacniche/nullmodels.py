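"""Taxonomic null models for the vacated-niche hypothesis.

For each (focal host x parasite type) the observed statistic is the mean, over
acquired parasites, of the minimum taxonomic distance to the lost set: small
values mean acquired parasites sit taxonomically close to the parasites the
host lost.  Two resampling null models place that statistic in context:

* **random acquisition** -- pseudo-acquired sets resampled (1000 draws) from the
  pool of lost and not-acquired parasites, i.e. the potential non-native
  associations of the focal host;
* **RRA** (random-relative-to-associations) -- pseudo-acquired sets resampled
  (100 draws) from the host's known associations (retained, lost and acquired).

z = (observed - null mean) / null sd; negative z means lost and acquired
parasites are more related than expected under the null, and z < -1.645 marks
one-tailed significance at the 5% level.

A pool member that is itself a lost species takes its minimum distance to the
*other* lost species: a parasite cannot fill its own vacated niche, and true
acquired parasites are never lost species, so scoring self-pairs as distance 0
would bias the null toward relatedness.  With this convention a uniformly
drawn acquired set is exchangeable with the null draws and z is centred at 0.
"""

from __future__ import annotations

import itertools
import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .taxodist import TaxonomicTree, min_distance_profile, min_distances
from .types import (
    DegenerateNullError,
    EmptySetError,
    FateTable,
    NotComputableError,
    VacnicheError,
    ValidationError,
)

MODELS = ("random_acquisition", "rra")
DEFAULT_DRAWS = {"random_acquisition": 1000, "rra": 100}
LOW_N_CUTOFF = 10  # fewer than 10 pairwise distances -> open point


def one_tailed_threshold(alpha: float = 0.05) -> float:
    """The standard-normal quantile used as the one-tailed significance line,
    rounded to the conventional three decimals (-1.645 at alpha = 0.05)."""
    return round(float(stats.norm.ppf(alpha)), 3)


Z_THRESHOLD = one_tailed_threshold()


def stage_seed(master_seed: int, label: str) -> int:
    """Independent, reproducible substream seed for a named stage.

    Derived from the master seed and a stable hash of the label, so adding or
    reordering stages never perturbs another stage's draws.
    """
    ss = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(zlib.crc32(label.encode("utf-8")),)
    )
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class NullModelResult:
    focal_host: str
    parasite_type: str
    model: str
    true_min_pds: Tuple[int, ...]
    observed_stat: float
    null_mean: float
    null_sd: float
    z_score: float            # NaN when the null is degenerate
    quantile: float           # fraction of null replicate stats <= observed
    n_draws: int
    seed: int
    null_unit: str = "set"
    degenerate: bool = False
    significant: Optional[bool] = None

    @property
    def n_comparisons(self) -> int:
        return len(self.true_min_pds)

    @property
    def low_n(self) -> bool:
        return self.n_comparisons < LOW_N_CUTOFF


def observed_statistic(
    fate_table: FateTable, tree: TaxonomicTree, parasite_type: str
) -> Optional[Tuple[List[int], float]]:
    """True minimum pairwise distances (one per acquired parasite of the type,
    to the closest lost relative) and their mean.

    Returns ``None`` -- the "not computable" marker -- when the host lost no
    parasites of this type or acquired none (a missing point, not an error).
    """
    acquired = fate_table.of_type("acquired", parasite_type)
    lost = fate_table.of_type("lost", parasite_type)
    if not acquired or not lost:
        return None
    pds = min_distances(acquired, lost, tree)
    return pds, float(np.mean(pds))


def _pool(fate_table: FateTable, parasite_type: str, model: str) -> List[str]:
    if model == "random_acquisition":
        members = fate_table.of_type("lost", parasite_type) | fate_table.of_type(
            "not_acquired", parasite_type
        )
    elif model == "rra":
        members = (
            fate_table.of_type("retained", parasite_type)
            | fate_table.of_type("lost", parasite_type)
            | fate_table.of_type("acquired", parasite_type)
        )
    else:
        raise ValidationError(f"unknown null model {model!r}; expected one of {MODELS}")
    return sorted(members)


def _null_profile(
    fate_table: FateTable, tree: TaxonomicTree, parasite_type: str, model: str
) -> np.ndarray:
    """Min-distance-to-lost value for every usable pool member (sorted order)."""
    pool = _pool(fate_table, parasite_type, model)
    lost = fate_table.of_type("lost", parasite_type)
    profile = min_distance_profile(pool, lost, tree, exclude_self=True)
    if not profile:
        raise EmptySetError(
            f"null pool for model {model!r}, type {parasite_type!r} is empty"
        )
    return np.array([profile[p] for p in sorted(profile)], dtype=float)


def _sample_null(
    m: np.ndarray, k: int, n_draws: int, rng: np.random.Generator, null_unit: str
) -> np.ndarray:
    if null_unit == "set":
        return rng.choice(m, size=(n_draws, k), replace=True).mean(axis=1)
    if null_unit == "pair":
        return rng.choice(m, size=n_draws, replace=True).astype(float)
    raise ValidationError(f"unknown null_unit {null_unit!r}; expected 'set' or 'pair'")


def _run_null(
    fate_table: FateTable,
    tree: TaxonomicTree,
    parasite_type: str,
    model: str,
    n_draws: int,
    seed: int,
    null_unit: str,
) -> NullModelResult:
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    obs = observed_statistic(fate_table, tree, parasite_type)
    if obs is None:
        raise NotComputableError(
            f"{fate_table.focal_host}: no lost and/or no acquired "
            f"{parasite_type} parasites"
        )
    true_pds, observed = obs
    m = _null_profile(fate_table, tree, parasite_type, model)
    rng = np.random.default_rng(seed)
    null_stats = _sample_null(m, len(true_pds), n_draws, rng, null_unit)
    null_mean = float(null_stats.mean())
    null_sd = float(null_stats.std(ddof=1)) if n_draws > 1 else 0.0
    degenerate = not null_sd > 0.0
    z = float("nan") if degenerate else (observed - null_mean) / null_sd
    quantile = float(np.mean(null_stats <= observed + 1e-12))
    return NullModelResult(
        focal_host=fate_table.focal_host,
        parasite_type=parasite_type,
        model=model,
        true_min_pds=tuple(true_pds),
        observed_stat=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z_score=z,
        quantile=quantile,
        n_draws=n_draws,
        seed=seed,
        null_unit=null_unit,
        degenerate=degenerate,
    )


def random_acquisition_null(
    fate_table: FateTable,
    tree: TaxonomicTree,
    parasite_type: str,
    n_draws: int = DEFAULT_DRAWS["random_acquisition"],
    seed: int = 0,
    null_unit: str = "set",
) -> NullModelResult:
    """Null model resampling pseudo-acquired sets from lost + not-acquired."""
    return _run_null(
        fate_table, tree, parasite_type, "random_acquisition", n_draws, seed, null_unit
    )


def rra_null(
    fate_table: FateTable,
    tree: TaxonomicTree,
    parasite_type: str,
    n_draws: int = DEFAULT_DRAWS["rra"],
    seed: int = 0,
    null_unit: str = "set",
) -> NullModelResult:
    """Null model resampling pseudo-acquired sets from the host's known
    associations (retained + lost + acquired)."""
    return _run_null(fate_table, tree, parasite_type, "rra", n_draws, seed, null_unit)


class CombinatorialGuardError(VacnicheError):
    pass


def exhaustive_null(
    fate_table: FateTable,
    tree: TaxonomicTree,
    parasite_type: str,
    model: str,
    null_unit: str = "set",
    guard: int = 10**6,
) -> Tuple[float, float]:
    """Exact null moments by enumerating every with-replacement pseudo-set.

    Verification oracle for the sampled nulls on small problems; the null sd
    returned is the population sd of the enumerated outcome distribution.
    """
    obs = observed_statistic(fate_table, tree, parasite_type)
    if obs is None:
        raise NotComputableError(
            f"no lost and/or acquired {parasite_type} parasites"
        )
    k = len(obs[0]) if null_unit == "set" else 1
    m = _null_profile(fate_table, tree, parasite_type, model)
    n_outcomes = len(m) ** k
    if n_outcomes > guard:
        raise CombinatorialGuardError(
            f"{n_outcomes} outcomes exceed the enumeration guard ({guard}); "
            "use the sampled null instead"
        )
    means = np.array(
        [np.mean(combo) for combo in itertools.product(m, repeat=k)], dtype=float
    )
    return float(means.mean()), float(means.std(ddof=0))


def flag_significant(
    results: Iterable[NullModelResult], threshold: float = Z_THRESHOLD
) -> List[NullModelResult]:
    """One-tailed significance: z strictly below the threshold; degenerate
    nulls are never significant."""
    flagged = []
    for r in results:
        sig = (not r.degenerate) and np.isfinite(r.z_score) and r.z_score < threshold
        flagged.append(replace(r, significant=bool(sig)))
    return flagged


def z_vs_ncomparisons(results: Sequence[NullModelResult]) -> Tuple[float, float]:
    """Spearman rank correlation between z-scores and comparison counts.

    Diagnostic for whether richer parasite groups mechanically yield stronger
    (more negative) z-scores.  Requires >= 3 finite results; a tie-degenerate
    correlation is returned as NaN with a warning.
    """
    finite = [r for r in results if np.isfinite(r.z_score)]
    if len(finite) < 3:
        raise ValidationError("need at least 3 finite results for a rank correlation")
    z = [r.z_score for r in finite]
    n = [r.n_comparisons for r in finite]
    if len(set(z)) == 1 or len(set(n)) == 1:
        warnings.warn("constant ranks: Spearman correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(z, n)
    return float(rho), float(p)


def run_null_models(
    fate_table: FateTable,
    trees_by_type: Dict[str, TaxonomicTree],
    models: Sequence[str] = MODELS,
    draws: Optional[Dict[str, int]] = None,
    seed: int = 0,
    null_unit: str = "set",
) -> Tuple[List[NullModelResult], List[Dict[str, str]]]:
    """All (parasite type x model) results for one invasion.

    Returns the computable, significance-flagged results plus a record of the
    skipped combinations (missing points: no loss and/or acquisition of a
    type, or a degenerate pool) so coverage can be accounted for.
    """
    draws = {**DEFAULT_DRAWS, **(draws or {})}
    results: List[NullModelResult] = []
    skipped: List[Dict[str, str]] = []
    present_types = sorted({t for t in fate_table.parasite_type_map.values()})
    for parasite_type in present_types:
        tree = trees_by_type.get(parasite_type)
        for model in models:
            sub = stage_seed(seed, f"{parasite_type}:{model}")
            if tree is None:
                skipped.append(
                    dict(parasite_type=parasite_type, model=model, reason="no taxonomy")
                )
                continue
            try:
                results.append(
                    _run_null(
                        fate_table, tree, parasite_type, model,
                        draws[model], sub, null_unit,
                    )
                )
            except (NotComputableError, EmptySetError) as exc:
                skipped.append(
                    dict(parasite_type=parasite_type, model=model, reason=str(exc))
                )
    return flag_significant(results), skipped
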
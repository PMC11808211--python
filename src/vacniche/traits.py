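"""Lost-vs-acquired comparisons on parasite traits.

Host specificity scores are compared with the Mann-Whitney U test; parasite
type and transmission mode contingency tables with an r x 2 Fisher exact test
(small counts are the norm in these data).  Transmission modes are
non-exclusive, so a parasite with k modes contributes one count to each of its
k mode rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .types import (
    PARASITE_TYPES,
    TRANSMISSION_MODES,
    EmptySetError,
    FateTable,
    SpecificityScore,
    ValidationError,
)

ENUMERATION_GUARD = 10**7
MC_REPLICATES = 10**5


@dataclass(frozen=True)
class TraitTestResult:
    focal_host: str
    trait: str  # specificity | parasite_type | transmission_mode
    statistic: float
    p: float
    n_lost: int
    n_acquired: int
    method: str = ""
    p_se: float = 0.0  # Monte-Carlo standard error, 0 for exact tests


def specificity_test(
    lost_scores: Sequence[SpecificityScore],
    acquired_scores: Sequence[SpecificityScore],
    focal_host: str = "",
) -> TraitTestResult:
    """Two-sided Mann-Whitney U comparing specificity distributions of lost
    and acquired parasites (tie-corrected)."""
    if not lost_scores:
        raise EmptySetError("no specificity scores for lost parasites")
    if not acquired_scores:
        raise EmptySetError("no specificity scores for acquired parasites")
    lost = [s.z_value for s in lost_scores]
    acq = [s.z_value for s in acquired_scores]
    u, p = stats.mannwhitneyu(lost, acq, alternative="two-sided", method="auto")
    return TraitTestResult(
        focal_host=focal_host,
        trait="specificity",
        statistic=float(u),
        p=float(p),
        n_lost=len(lost),
        n_acquired=len(acq),
        method="mann-whitney",
    )


def _table_logprob(x: np.ndarray, rows: np.ndarray, n: int, c1: int) -> float:
    """log P(first-column counts = x | margins) under the hypergeometric model."""
    lp = -(gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    for ri, xi in zip(rows, x):
        lp += gammaln(ri + 1) - gammaln(xi + 1) - gammaln(ri - xi + 1)
    return float(lp)


def _enumerate_p(table: np.ndarray) -> float:
    rows = table.sum(axis=1)
    c1 = int(table[:, 0].sum())
    n = int(table.sum())
    obs_lp = _table_logprob(table[:, 0], rows, n, c1)
    total = 0.0
    p = 0.0

    r = len(rows)
    x = np.zeros(r, dtype=int)

    def rec(i: int, remaining: int) -> None:
        nonlocal total, p
        if i == r - 1:
            if 0 <= remaining <= rows[-1]:
                x[-1] = remaining
                lp = _table_logprob(x, rows, n, c1)
                prob = float(np.exp(lp))
                total += prob
                if lp <= obs_lp + 1e-7:
                    p += prob
            return
        hi = min(rows[i], remaining)
        lo = max(0, remaining - int(rows[i + 1 :].sum()))
        for xi in range(lo, hi + 1):
            x[i] = xi
            rec(i + 1, remaining - xi)

    rec(0, c1)
    # total sums to 1 up to float error; normalise to absorb it
    return min(1.0, p / total)


def _estimate_n_tables(table: np.ndarray) -> int:
    c1 = int(table[:, 0].sum())
    est = 1
    for r in table.sum(axis=1):
        est *= min(int(r), c1) + 1
        if est > ENUMERATION_GUARD:
            return est
    return est


def category_test(
    table: pd.DataFrame | np.ndarray,
    focal_host: str = "",
    trait: str = "parasite_type",
    seed: int = 0,
    n_replicates: int = MC_REPLICATES,
) -> TraitTestResult:
    """Fisher's exact test on an r x 2 (category x {lost, acquired}) table.

    Conditional on both margins; two-sided by summing the probability of every
    table no more probable than the observed one.  Exhaustive enumeration up
    to a guard, then Monte-Carlo (Patefield sampling) with a reported
    standard error.  All-zero rows are dropped with a warning.
    """
    arr = np.asarray(table, dtype=int)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("expected an r x 2 count table")
    if (arr < 0).any():
        raise ValidationError("counts must be non-negative")
    zero_rows = arr.sum(axis=1) == 0
    if zero_rows.any():
        warnings.warn(f"dropping {int(zero_rows.sum())} all-zero rows", stacklevel=2)
        arr = arr[~zero_rows]
    if arr.shape[0] < 2:
        raise ValidationError("need at least 2 categories with nonzero counts")
    col_sums = arr.sum(axis=0)
    if (col_sums == 0).any():
        raise ValidationError("both fate columns must have nonzero totals")

    n_lost, n_acquired = int(col_sums[0]), int(col_sums[1])
    if _estimate_n_tables(arr) <= ENUMERATION_GUARD:
        p = _enumerate_p(arr)
        method, p_se = "fisher-exact", 0.0
    else:
        rng = np.random.default_rng(seed)
        sampler = stats.random_table(arr.sum(axis=1), col_sums)
        draws = sampler.rvs(n_replicates, random_state=rng)
        rows = arr.sum(axis=1)
        n, c1 = int(arr.sum()), n_lost
        obs_lp = _table_logprob(arr[:, 0], rows, n, c1)
        lps = np.array(
            [_table_logprob(t[:, 0], rows, n, c1) for t in draws]
        )
        hits = lps <= obs_lp + 1e-7
        p = float(hits.mean())
        p_se = float(hits.std(ddof=1) / np.sqrt(n_replicates))
        method = f"fisher-mc[{n_replicates}]"
    return TraitTestResult(
        focal_host=focal_host,
        trait=trait,
        statistic=float("nan"),  # Fisher's test has no single test statistic
        p=p,
        n_lost=n_lost,
        n_acquired=n_acquired,
        method=method,
        p_se=p_se,
    )


def type_contingency(fate_table: FateTable) -> pd.DataFrame:
    """5 x 2 (parasite type x {lost, acquired}) count table."""
    out = pd.DataFrame(0, index=list(PARASITE_TYPES), columns=["lost", "acquired"])
    for fate in ("lost", "acquired"):
        for sp in fate_table.fate_set(fate):
            out.loc[fate_table.parasite_type_map[sp], fate] += 1
    out.index.name = "parasite_type"
    return out


def mode_contingency(
    fate_table: FateTable, modes: Mapping[str, FrozenSet[str]]
) -> pd.DataFrame:
    """4 x 2 (transmission mode x {lost, acquired}) count table.

    Modes are non-exclusive: a parasite with k modes adds one count to each of
    its k rows, so column sums may exceed parasite counts.
    """
    out = pd.DataFrame(0, index=list(TRANSMISSION_MODES), columns=["lost", "acquired"])
    for fate in ("lost", "acquired"):
        for sp in fate_table.fate_set(fate):
            for mode in modes.get(sp, frozenset()):
                out.loc[mode, fate] += 1
    out.index.name = "transmission_mode"
    return out


def run_trait_tests(
    fate_table: FateTable,
    specificity: Optional[Mapping[str, float]] = None,
    modes: Optional[Mapping[str, FrozenSet[str]]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """All trait comparisons for one invasion; one row per trait."""
    results = []
    if specificity is not None:
        lost = [
            SpecificityScore(sp, specificity[sp])
            for sp in sorted(fate_table.lost)
            if sp in specificity
        ]
        acq = [
            SpecificityScore(sp, specificity[sp])
            for sp in sorted(fate_table.acquired)
            if sp in specificity
        ]
        if lost and acq:
            results.append(specificity_test(lost, acq, fate_table.focal_host))
    for trait, tbl in (
        ("parasite_type", type_contingency(fate_table)),
        ("transmission_mode", mode_contingency(fate_table, modes or {})),
    ):
        if trait == "transmission_mode" and modes is None:
            continue
        arr = tbl.to_numpy()
        # untestable: fewer than 2 occupied categories or an empty fate column
        if (arr.sum(axis=1) > 0).sum() < 2 or (arr.sum(axis=0) == 0).any():
            continue
        results.append(
            category_test(tbl, focal_host=fate_table.focal_host, trait=trait, seed=seed)
        )
    return pd.DataFrame([r.__dict__ for r in results])
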
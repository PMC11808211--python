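"""Enemy-release analyses: paired PSR comparison under phylogenetic
covariance, PSR-change responses, Sorensen beta-diversity partitioning,
environmental dissimilarity and single-predictor regressions."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import braycurtis

from .types import EmptySetError, SchemaError, ValidationError, VacnicheError

RESPONSES = ("psr_change", "turnover_prop", "nestedness_prop", "beta_sor")
PREDICTORS = (
    "time_since_invasion",
    "population_density",
    "log_home_range",
    "environmental_dissimilarity",
)


@dataclass(frozen=True)
class BetaPartition:
    """Baselga's partition of Sorensen dissimilarity between the native and
    non-native parasite communities of one focal host.

    beta_sor = beta_sim (turnover / Simpson) + beta_sne (nestedness).
    Proportions are NaN (flagged) when beta_sor = 0.
    """

    beta_sor: float
    beta_sim: float
    beta_sne: float
    turnover_prop: float
    nestedness_prop: float

    @property
    def proportions_defined(self) -> bool:
        return np.isfinite(self.turnover_prop)


@dataclass(frozen=True)
class PhyloPairedTestResult:
    t: float
    df: int
    p: float
    lambda_hat: float
    mean_diff: float
    sigma2: float


def psr_change(native_psr: float, nonnative_psr: float) -> float:
    """Proportional PSR change, 1 - non-native PSR / native PSR."""
    if native_psr <= 0:
        raise ValidationError("native PSR must be positive")
    return 1.0 - nonnative_psr / native_psr


def beta_partition(native_set: Iterable[str], nonnative_set: Iterable[str]) -> BetaPartition:
    native: Set[str] = set(native_set)
    nonnative: Set[str] = set(nonnative_set)
    if not native and not nonnative:
        raise EmptySetError("both parasite sets are empty")
    if not native:
        raise EmptySetError("native parasite set is empty")
    a = len(native & nonnative)
    b = len(native - nonnative)
    c = len(nonnative - native)
    beta_sor = (b + c) / (2 * a + b + c)
    m = min(b, c)
    beta_sim = m / (a + m) if (a + m) > 0 else 0.0
    beta_sne = beta_sor - beta_sim
    if beta_sor > 0:
        turnover_prop = beta_sim / beta_sor
        nestedness_prop = beta_sne / beta_sor
    else:
        warnings.warn("beta_sor = 0: proportions undefined", stacklevel=2)
        turnover_prop = nestedness_prop = float("nan")
    return BetaPartition(beta_sor, beta_sim, beta_sne, turnover_prop, nestedness_prop)


def _vcv_from_tree(tree: dendropy.Tree, hosts: Sequence[str]) -> np.ndarray:
    """Phylogenetic covariance: C[i, j] = shared root-to-MRCA path length."""
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    label_to_leaf = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label.replace("_", " ")
        label_to_leaf[label] = leaf
    missing = [h for h in hosts if h.replace("_", " ") not in label_to_leaf]
    if missing:
        raise ValidationError(f"hosts not in tree: {missing}")
    pdm = tree.phylogenetic_distance_matrix()
    n = len(hosts)
    C = np.zeros((n, n))
    depths = {}
    for h in hosts:
        depths[h] = float(label_to_leaf[h.replace("_", " ")].root_distance)
    for i, hi in enumerate(hosts):
        for j, hj in enumerate(hosts):
            if i == j:
                C[i, j] = depths[hi]
            else:
                dij = float(
                    pdm.patristic_distance(
                        label_to_leaf[hi.replace("_", " ")].taxon,
                        label_to_leaf[hj.replace("_", " ")].taxon,
                    )
                )
                C[i, j] = 0.5 * (depths[hi] + depths[hj] - dij)
    return C


def _lambda_scale(C: np.ndarray, lam: float) -> np.ndarray:
    Cl = lam * C
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


def _gls_fit(d: np.ndarray, C: np.ndarray, lam: float, ddof: int) -> Tuple[float, float, float]:
    """GLS mean, residual variance (scaled by n - ddof) and SE of the mean."""
    n = len(d)
    Cl = _lambda_scale(C, lam)
    Ci = np.linalg.inv(Cl)
    one = np.ones(n)
    denom = one @ Ci @ one
    mu = float((one @ Ci @ d) / denom)
    r = d - mu
    sig2 = float(r @ Ci @ r) / (n - ddof)
    se = float(np.sqrt(sig2 / denom))
    return mu, sig2, se


def _neg_profile_loglik(lam: float, d: np.ndarray, C: np.ndarray) -> float:
    n = len(d)
    Cl = _lambda_scale(C, lam)
    sign, logdet = np.linalg.slogdet(Cl)
    if sign <= 0:
        return np.inf
    mu, sig2_ml, _ = _gls_fit(d, C, lam, ddof=0)
    if sig2_ml <= 0:
        return np.inf
    return 0.5 * (n * np.log(2 * np.pi * sig2_ml) + logdet + n)


def phylo_paired_ttest(
    native_psr: Mapping[str, float],
    nonnative_psr: Mapping[str, float],
    host_tree: dendropy.Tree,
    lam: Optional[float] = None,
    variance: str = "unbiased",
) -> PhyloPairedTestResult:
    """Paired comparison of per-host values with phylogenetic covariance.

    Paired differences d_i = native_i - nonnative_i are modelled as
    multivariate normal with mean mu and covariance sigma^2 * C(lambda), where
    C is the tree's shared-path-length matrix and lambda in [0, 1] scales its
    off-diagonals (Pagel's lambda).  lambda is profiled by maximum likelihood
    unless fixed via ``lam``; t = mu_hat / SE(mu_hat) on n - 3 degrees of
    freedom (three quantities estimated: mu, sigma^2, lambda).

    ``variance="unbiased"`` scales the residual variance by n - 1, so that at
    lambda = 0 on an ultrametric tree the statistic reduces exactly to the
    classical paired t; ``variance="ml"`` uses the full-ML scaling (n).
    """
    hosts = sorted(native_psr)
    if sorted(nonnative_psr) != hosts:
        raise ValidationError("native and non-native PSR must cover the same hosts")
    n = len(hosts)
    if n < 4:
        raise ValidationError("need at least 4 hosts (df = n - 3 >= 1)")
    if variance not in ("unbiased", "ml"):
        raise ValidationError("variance must be 'unbiased' or 'ml'")
    d = np.array([float(native_psr[h]) - float(nonnative_psr[h]) for h in hosts])
    if np.allclose(d, d[0]):
        raise ValidationError("paired differences have zero variance; test degenerate")
    C = _vcv_from_tree(host_tree, hosts)
    depths = np.diag(C)
    if not np.allclose(depths, depths[0], rtol=1e-6):
        warnings.warn("host tree is not ultrametric; proceeding", stacklevel=2)
    if lam is None:
        res = optimize.minimize_scalar(
            _neg_profile_loglik,
            bounds=(0.0, 1.0),
            args=(d, C),
            method="bounded",
            options={"xatol": 1e-8},
        )
        lam_hat = float(res.x)
        # the bounded optimum can hide a better boundary value
        for bound in (0.0, 1.0):
            if _neg_profile_loglik(bound, d, C) < _neg_profile_loglik(lam_hat, d, C):
                lam_hat = bound
    else:
        if not 0.0 <= lam <= 1.0:
            raise ValidationError("lambda must lie in [0, 1]")
        lam_hat = float(lam)
    ddof = 1 if variance == "unbiased" else 0
    mu, sig2, se = _gls_fit(d, C, lam_hat, ddof=ddof)
    t = mu / se
    # one df per estimated quantity beyond the mean: sigma^2 always, lambda
    # only when profiled
    df = n - 3 if lam is None else n - 2
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return PhyloPairedTestResult(
        t=float(t), df=df, p=p, lambda_hat=lam_hat, mean_diff=mu, sigma2=sig2
    )


def environmental_dissimilarity(
    native_vars: pd.DataFrame, nonnative_vars: pd.DataFrame
) -> float:
    """Mean Bray-Curtis distance between all (native location, non-native
    location) pairs over shared climate variables.

    Each variable is min-max scaled to [0, 1] over the pooled locations first
    (Bray-Curtis requires non-negative inputs, and raw bioclim units would let
    large-magnitude variables dominate).  Constant variables are dropped with
    a warning.
    """
    cols_a = [c for c in native_vars.columns if native_vars[c].dtype.kind in "if"]
    cols_b = [c for c in nonnative_vars.columns if nonnative_vars[c].dtype.kind in "if"]
    common = [c for c in cols_a if c in set(cols_b)]
    if not common:
        raise SchemaError("no shared numeric variable columns between the two tables")
    if set(cols_a) != set(cols_b):
        warnings.warn(
            "variable sets differ; using the shared columns only", stacklevel=2
        )
    A = native_vars[common].to_numpy(dtype=float)
    B = nonnative_vars[common].to_numpy(dtype=float)
    if not (np.isfinite(A).all() and np.isfinite(B).all()):
        raise ValidationError("climate tables contain non-finite values")
    pooled = np.vstack([A, B])
    lo, hi = pooled.min(axis=0), pooled.max(axis=0)
    keep = hi > lo
    if not keep.all():
        dropped = [c for c, k in zip(common, keep) if not k]
        warnings.warn(f"dropping constant variables: {dropped}", stacklevel=2)
    if not keep.any():
        raise ValidationError("all variables constant after pooling")
    A = (A[:, keep] - lo[keep]) / (hi[keep] - lo[keep])
    B = (B[:, keep] - lo[keep]) / (hi[keep] - lo[keep])
    dists = [braycurtis(a, b) for a in A for b in B]
    return float(np.mean(dists))


def simple_regressions(host_table: pd.DataFrame) -> pd.DataFrame:
    """OLS of each response on each predictor, one at a time.

    ``host_table`` has one row per focal host with the four response columns
    and predictor columns (``home_range_area`` is log-transformed into
    ``log_home_range`` here).  Constant predictors are flagged, not fitted.
    Unadjusted p-values (none of these fits is a confirmatory test).
    """
    import statsmodels.api as sm

    table = host_table.copy()
    if "log_home_range" not in table.columns:
        if "home_range_area" not in table.columns:
            raise SchemaError("need home_range_area (or log_home_range) column")
        if (table["home_range_area"] <= 0).any():
            raise ValidationError("home_range_area must be positive to log-transform")
        table["log_home_range"] = np.log(table["home_range_area"])
    missing = [c for c in RESPONSES + PREDICTORS if c not in table.columns]
    if missing:
        raise SchemaError(f"host table missing columns: {missing}")
    rows = []
    for response in RESPONSES:
        for predictor in PREDICTORS:
            sub = table[[response, predictor]].dropna()
            n = len(sub)
            if n < 3:
                raise ValidationError(
                    f"{response} ~ {predictor}: need >= 3 hosts, got {n}"
                )
            x = sub[predictor].to_numpy(dtype=float)
            y = sub[response].to_numpy(dtype=float)
            if np.allclose(x, x[0]):
                rows.append(
                    dict(response=response, predictor=predictor, n=n,
                         slope=np.nan, intercept=np.nan, p=np.nan,
                         flag="constant_predictor")
                )
                continue
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            rows.append(
                dict(
                    response=response,
                    predictor=predictor,
                    n=n,
                    slope=float(fit.params[1]),
                    intercept=float(fit.params[0]),
                    p=float(fit.pvalues[1]),
                    flag="",
                )
            )
    return pd.DataFrame(rows)
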
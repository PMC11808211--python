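"""Simulation experiments over many synthetic invasions.

These drive the calibration and power analyses of the taxonomic null models:
at clustering strength theta = 0 the z-score distribution should be centred
at zero with ~5% of invasions below the one-tailed threshold; as theta grows,
z should shift negative and the significant fraction should climb.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import nullmodels
from .synthetic import SimulationConfig, generate_invasion, generate_taxonomy
from .taxodist import build_tree
from .types import NotComputableError, EmptySetError


def simulate_z_scores(
    n_invasions: int,
    theta: float,
    seed: int,
    model: str = "random_acquisition",
    n_draws: Optional[int] = None,
    parasite_type: str = "helminth",
    n_species: int = 80,
    config: Optional[SimulationConfig] = None,
) -> pd.DataFrame:
    """z-scores from ``n_invasions`` independent single-type invasions.

    Each invasion gets its own random taxonomy and fate draw; one row per
    invasion with the z-score, comparison count and flags.  Degenerate or
    not-computable invasions are recorded with NaN z.
    """
    if config is None:
        config = SimulationConfig(parasite_types=(parasite_type,), theta=theta, seed=seed)
    else:
        config = SimulationConfig(
            n_hosts=config.n_hosts,
            parasite_types=(parasite_type,),
            richness=config.richness,
            theta=theta,
            concentrations=config.concentrations,
            acquisition_pool=config.acquisition_pool,
            seed=seed,
        )
    n_draws = n_draws or nullmodels.DEFAULT_DRAWS[model]
    rng = np.random.default_rng(nullmodels.stage_seed(seed, f"calibration:{theta}"))
    rows = []
    for i in range(n_invasions):
        taxa = generate_taxonomy(n_species, parasite_type, rng, config.concentrations)
        tree = build_tree(taxa)
        _, truth, _ = generate_invasion(
            {parasite_type: taxa}, config, rng, invasion_id=f"sim{i}"
        )
        sub = int(rng.integers(0, 2**31 - 1))
        try:
            fn = (
                nullmodels.random_acquisition_null
                if model == "random_acquisition"
                else nullmodels.rra_null
            )
            res = fn(truth, tree, parasite_type, n_draws=n_draws, seed=sub)
            rows.append(
                dict(
                    invasion=i,
                    z_score=res.z_score,
                    quantile=res.quantile,
                    n_comparisons=res.n_comparisons,
                    degenerate=res.degenerate,
                    significant=(not res.degenerate)
                    and res.z_score < nullmodels.Z_THRESHOLD,
                )
            )
        except (NotComputableError, EmptySetError):
            rows.append(
                dict(
                    invasion=i, z_score=np.nan, quantile=np.nan,
                    n_comparisons=0, degenerate=True, significant=False,
                )
            )
    return pd.DataFrame(rows)


def calibration_summary(df: pd.DataFrame) -> dict:
    """Mean z and one-tailed significance rate over the usable invasions."""
    ok = df[np.isfinite(df["z_score"])]
    return {
        "n_usable": int(len(ok)),
        "mean_z": float(ok["z_score"].mean()),
        "significance_rate": float(ok["significant"].mean()),
        "median_quantile": float(ok["quantile"].median()),
    }


def power_summary(df: pd.DataFrame, min_comparisons: int = 5) -> dict:
    """Fraction of well-powered invasions (>= ``min_comparisons`` acquired)
    with negative z."""
    ok = df[np.isfinite(df["z_score"]) & (df["n_comparisons"] >= min_comparisons)]
    return {
        "n_usable": int(len(ok)),
        "mean_z": float(ok["z_score"].mean()),
        "negative_z_rate": float((ok["z_score"] < 0).mean()),
        "significance_rate": float(ok["significant"].mean()),
    }
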
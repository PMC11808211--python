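"""Pipeline orchestrator: configuration, stage ordering, seeding, outputs.

Stage dependency order: fates -> (null models | enemy release | trait tests).
Every stochastic stage derives its own substream from the master seed and a
stable label, so runs are reproducible and adding a stage never perturbs
another stage's draws.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import enemy, fates, io, nullmodels, traits
from .taxodist import build_tree
from .types import DependencyError, FateTable, ValidationError

log = logging.getLogger("vacniche")

STAGES = ("fates", "null_models", "enemy_release", "trait_tests")
_NEEDS_FATES = ("null_models", "enemy_release", "trait_tests")


@dataclass
class PipelineConfig:
    associations: Optional[str] = None
    taxonomy: Optional[str] = None
    host_tree: Optional[str] = None
    specificity_scores: Optional[str] = None
    env_native: Optional[str] = None
    env_nonnative: Optional[str] = None
    host_traits: Optional[str] = None
    out_dir: str = "results"
    stages: Sequence[str] = STAGES
    seed: int = 0
    draws_random_acquisition: int = 1000
    draws_rra: int = 100
    null_unit: str = "set"  # set-level resampling; "pair" for sensitivity
    focal_hosts: Dict[str, str] = field(default_factory=dict)  # invasion_id -> host

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValidationError(f"unknown stage(s) {unknown}; valid: {STAGES}")
        if self.draws_random_acquisition < 1 or self.draws_rra < 1:
            raise ValidationError("draw counts must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValidationError(f"unknown config key(s): {sorted(bad)}")
        return cls(**raw)


def _infer_focal_host(records) -> str:
    """The focal host is the (unique) host sampled in both ranges."""
    by_host: Dict[str, set] = {}
    for r in records:
        by_host.setdefault(r.host_species, set()).add(r.range_label)
    both = sorted(h for h, labels in by_host.items() if len(labels) == 2)
    if len(both) != 1:
        raise ValidationError(
            f"cannot infer focal host (hosts in both ranges: {both}); "
            "specify focal_hosts in the config"
        )
    return both[0]


def _classify_all(config: PipelineConfig) -> List[FateTable]:
    if not config.associations:
        raise DependencyError("stage 'fates' needs an associations file")
    records = io.read_associations(config.associations)
    tables = []
    by_invasion: Dict[str, list] = {}
    for r in records:
        by_invasion.setdefault(r.invasion_id, []).append(r)
    for invasion_id in sorted(by_invasion):
        recs = by_invasion[invasion_id]
        focal = config.focal_hosts.get(invasion_id) or _infer_focal_host(recs)
        tables.append(fates.classify_fates(recs, focal))
    return tables


def _load_fates(config: PipelineConfig, out: Path) -> List[FateTable]:
    path = out / "fates.csv"
    if not path.exists():
        raise DependencyError(
            "missing upstream output of stage 'fates' (fates.csv); "
            "run the fates stage first"
        )
    return io.read_fate_tables(path)


def _modes_from_associations(config: PipelineConfig) -> Dict[str, frozenset]:
    records = io.read_associations(config.associations)
    modes: Dict[str, frozenset] = {}
    for r in records:
        modes[r.parasite_species] = (
            modes.get(r.parasite_species, frozenset()) | r.transmission_modes
        )
    return modes


def run_pipeline(config: PipelineConfig) -> Dict[str, Path]:
    """Run the requested stages in dependency order; returns output paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    requested = [s for s in STAGES if s in set(config.stages)]
    outputs: Dict[str, Path] = {}
    fate_tables: Optional[List[FateTable]] = None

    if "fates" in requested:
        fate_tables = _classify_all(config)
        path = out / "fates.csv"
        io.write_fate_tables(fate_tables, path)
        outputs["fates"] = path
        log.info("fates: %d invasions classified", len(fate_tables))

    if any(s in requested for s in _NEEDS_FATES) and fate_tables is None:
        fate_tables = _load_fates(config, out)

    if "null_models" in requested:
        if not config.taxonomy:
            raise DependencyError("stage 'null_models' needs a taxonomy file")
        taxa = io.read_taxonomy(config.taxonomy)
        all_results, all_skipped = [], []
        for ft in fate_tables:
            by_type: Dict[str, list] = {}
            for sp, pt in ft.parasite_type_map.items():
                by_type.setdefault(pt, []).append(sp)
            known = {t.species: t for t in taxa}
            trees = {}
            for pt, members in by_type.items():
                classified = [known[sp] for sp in members if sp in known]
                if classified:
                    trees[pt] = build_tree(classified)
            seed = nullmodels.stage_seed(config.seed, f"null_models:{ft.invasion_id}")
            log.info("null_models[%s]: seed %d", ft.invasion_id, seed)
            results, skipped = nullmodels.run_null_models(
                ft,
                trees,
                draws={
                    "random_acquisition": config.draws_random_acquisition,
                    "rra": config.draws_rra,
                },
                seed=seed,
                null_unit=config.null_unit,
            )
            all_results.extend(results)
            for s in skipped:
                all_skipped.append({"invasion_id": ft.invasion_id, **s})
        path = out / "null_models.csv"
        io.write_results(all_results, path)
        outputs["null_models"] = path
        if all_skipped:
            skipped_path = out / "null_models_skipped.csv"
            io.write_results(pd.DataFrame(all_skipped), skipped_path)
            outputs["null_models_skipped"] = skipped_path

    if "enemy_release" in requested:
        rows = []
        for ft in fate_tables:
            native = ft.retained | ft.lost
            nonnative = ft.retained | ft.acquired
            part = enemy.beta_partition(native, nonnative)
            rows.append(
                {
                    "invasion_id": ft.invasion_id,
                    "focal_host": ft.focal_host,
                    "native_psr": fates.psr(ft, "native"),
                    "nonnative_psr": fates.psr(ft, "nonnative"),
                    "psr_change": enemy.psr_change(
                        fates.psr(ft, "native"), fates.psr(ft, "nonnative")
                    ),
                    "beta_sor": part.beta_sor,
                    "beta_sim": part.beta_sim,
                    "beta_sne": part.beta_sne,
                    "turnover_prop": part.turnover_prop,
                    "nestedness_prop": part.nestedness_prop,
                }
            )
        summary = pd.DataFrame(rows)
        if config.host_tree and len(summary) >= 4:
            tree = dendropy.Tree.get(path=config.host_tree, schema="newick")
            try:
                res = enemy.phylo_paired_ttest(
                    dict(zip(summary["focal_host"], summary["native_psr"])),
                    dict(zip(summary["focal_host"], summary["nonnative_psr"])),
                    tree,
                )
                (out / "enemy_release_ttest.json").write_text(
                    pd.Series(dataclasses.asdict(res)).to_json(indent=2)
                )
                outputs["enemy_release_ttest"] = out / "enemy_release_ttest.json"
            except ValidationError as exc:
                log.warning("phylogenetic paired t-test skipped: %s", exc)
        if config.env_native and config.env_nonnative:
            dis = enemy.environmental_dissimilarity(
                io.read_env_table(config.env_native),
                io.read_env_table(config.env_nonnative),
            )
            summary["environmental_dissimilarity"] = dis
        if config.host_traits and len(summary) >= 3:
            traits_df = io.read_env_table(config.host_traits).rename(
                columns={"host": "focal_host"}
            )
            merged = summary.merge(traits_df, on="focal_host", how="inner")
            if "environmental_dissimilarity" in merged.columns and len(merged) >= 3:
                try:
                    reg = enemy.simple_regressions(merged)
                    io.write_results(reg, out / "enemy_release_regressions.csv")
                    outputs["enemy_release_regressions"] = (
                        out / "enemy_release_regressions.csv"
                    )
                except ValidationError as exc:
                    log.warning("regressions skipped: %s", exc)
        path = out / "enemy_release.csv"
        io.write_results(summary, path)
        outputs["enemy_release"] = path

    if "trait_tests" in requested:
        scores = (
            io.read_specificity_scores(config.specificity_scores)
            if config.specificity_scores
            else None
        )
        modes = _modes_from_associations(config) if config.associations else None
        frames = []
        for ft in fate_tables:
            seed = nullmodels.stage_seed(config.seed, f"trait_tests:{ft.invasion_id}")
            df = traits.run_trait_tests(ft, specificity=scores, modes=modes, seed=seed)
            df.insert(0, "invasion_id", ft.invasion_id)
            frames.append(df)
        path = out / "trait_tests.csv"
        io.write_results(pd.concat(frames, ignore_index=True), path)
        outputs["trait_tests"] = path

    return outputs
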
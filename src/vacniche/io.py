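"""Readers and writers for the pipeline's delimited tables.

All tables are plain CSV/TSV (delimiter inferred from the extension, ``.tsv``
-> tab).  Transmission modes are encoded as a ``;``-joined list.  Floats are
written at full precision so write/read round-trips reproduce values exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, FrozenSet, List, Sequence, Tuple

import pandas as pd

from .nullmodels import NullModelResult
from .taxodist import RANKS, ParasiteTaxonomy
from .types import (
    AssociationRecord,
    FateTable,
    SchemaError,
    SpecificityScore,
    ValidationError,
)

ASSOCIATION_COLUMNS = (
    "host_species",
    "parasite_species",
    "parasite_type",
    "transmission_modes",
    "range_label",
    "invasion_id",
)
MODE_SEP = ";"


def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","


def _read_table(path: Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=_sep_for(path))


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {missing}")


def read_associations(path) -> List[AssociationRecord]:
    """Read association records; duplicate rows collapse to one record."""
    df = _read_table(path)
    _require_columns(df, ASSOCIATION_COLUMNS, "associations")
    records = []
    for idx, row in df.iterrows():
        modes = frozenset(
            m.strip() for m in str(row["transmission_modes"]).split(MODE_SEP) if m.strip()
        )
        try:
            records.append(
                AssociationRecord(
                    host_species=row["host_species"],
                    parasite_species=row["parasite_species"],
                    parasite_type=str(row["parasite_type"]).strip().lower(),
                    transmission_modes=modes,
                    range_label=str(row["range_label"]).strip().lower(),
                    invasion_id=str(row["invasion_id"]).strip(),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {idx + 2} of {path}: {exc}") from exc
    # set semantics: records are identity-complete, order is presentation only
    unique = sorted(
        set(records),
        key=lambda r: (r.invasion_id, r.host_species, r.parasite_species, r.range_label),
    )
    return unique


def write_associations(records: Sequence[AssociationRecord], path) -> None:
    rows = [
        {
            "host_species": r.host_species,
            "parasite_species": r.parasite_species,
            "parasite_type": r.parasite_type,
            "transmission_modes": MODE_SEP.join(sorted(r.transmission_modes)),
            "range_label": r.range_label,
            "invasion_id": r.invasion_id,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(ASSOCIATION_COLUMNS))
    df = df.sort_values(list(ASSOCIATION_COLUMNS)).reset_index(drop=True)
    df.to_csv(path, sep=_sep_for(Path(path)), index=False)


def read_taxonomy(path) -> List[ParasiteTaxonomy]:
    """Seven-rank taxonomy table; empty strings mark missing entries."""
    df = _read_table(path)
    _require_columns(df, ("parasite_species",) + RANKS, "taxonomy")
    taxa = []
    for _, row in df.iterrows():
        ranks = tuple(
            None if pd.isna(row[r]) or str(row[r]).strip() == "" else str(row[r])
            for r in RANKS
        )
        taxa.append(ParasiteTaxonomy(species=row["parasite_species"], ranks=ranks))
    return taxa


def write_taxonomy(taxa: Sequence[ParasiteTaxonomy], path) -> None:
    rows = []
    for t in taxa:
        row = {"parasite_species": t.species}
        row.update({r: (v if v is not None else "") for r, v in zip(RANKS, t.ranks)})
        rows.append(row)
    pd.DataFrame(rows, columns=("parasite_species",) + RANKS).to_csv(
        path, sep=_sep_for(Path(path)), index=False
    )


FATE_COLUMNS = (
    "invasion_id",
    "focal_host",
    "parasite_species",
    "parasite_type",
    "fate",
    "in_nonnative_community",
)


def write_fate_table(fate_table: FateTable, path) -> None:
    rows = [
        {
            "invasion_id": fate_table.invasion_id,
            "focal_host": fate_table.focal_host,
            "parasite_species": sp,
            "parasite_type": fate_table.parasite_type_map[sp],
            "fate": fate,
            "in_nonnative_community": sp in fate_table.community_nonnative,
        }
        for sp, fate in sorted(fate_table.fate_map.items())
    ]
    pd.DataFrame(rows, columns=list(FATE_COLUMNS)).to_csv(
        path, sep=_sep_for(Path(path)), index=False
    )


def write_fate_tables(fate_tables: Sequence[FateTable], path) -> None:
    frames = []
    for ft in fate_tables:
        frames.append(
            pd.DataFrame(
                [
                    {
                        "invasion_id": ft.invasion_id,
                        "focal_host": ft.focal_host,
                        "parasite_species": sp,
                        "parasite_type": ft.parasite_type_map[sp],
                        "fate": fate,
                        "in_nonnative_community": sp in ft.community_nonnative,
                    }
                    for sp, fate in sorted(ft.fate_map.items())
                ]
            )
        )
    pd.concat(frames, ignore_index=True)[list(FATE_COLUMNS)].to_csv(
        path, sep=_sep_for(Path(path)), index=False
    )


def read_fate_tables(path) -> List[FateTable]:
    df = _read_table(path)
    _require_columns(df, FATE_COLUMNS, "fate")
    tables = []
    for (invasion_id, focal_host), grp in df.groupby(
        ["invasion_id", "focal_host"], sort=True
    ):
        fate_map = dict(zip(grp["parasite_species"], grp["fate"]))
        ptype = dict(zip(grp["parasite_species"], grp["parasite_type"]))
        community = frozenset(
            grp.loc[grp["in_nonnative_community"], "parasite_species"]
        )
        tables.append(
            FateTable(
                invasion_id=str(invasion_id),
                focal_host=str(focal_host),
                fate_map=fate_map,
                parasite_type_map=ptype,
                community_nonnative=community,
            )
        )
    return tables


def read_fate_table(path) -> FateTable:
    tables = read_fate_tables(path)
    if len(tables) != 1:
        raise ValidationError(f"expected one invasion in {path}, found {len(tables)}")
    return tables[0]


def read_specificity_scores(path) -> Dict[str, float]:
    df = _read_table(path)
    _require_columns(df, ("parasite_species", "z_value"), "specificity")
    scores: Dict[str, float] = {}
    for _, row in df.iterrows():
        s = SpecificityScore(row["parasite_species"], float(row["z_value"]))
        if s.parasite_species in scores:
            raise ValidationError(f"duplicate specificity score for {s.parasite_species!r}")
        scores[s.parasite_species] = s.z_value
    return scores


def write_specificity_scores(scores: Sequence[SpecificityScore], path) -> None:
    pd.DataFrame(
        [{"parasite_species": s.parasite_species, "z_value": s.z_value} for s in scores],
        columns=["parasite_species", "z_value"],
    ).to_csv(path, sep=_sep_for(Path(path)), index=False)


NULL_RESULT_COLUMNS = (
    "focal_host",
    "parasite_type",
    "model",
    "n_comparisons",
    "observed_stat",
    "null_mean",
    "null_sd",
    "z_score",
    "quantile",
    "significant",
    "low_n",
    "degenerate",
    "n_draws",
    "seed",
    "null_unit",
)


def null_results_frame(results: Sequence[NullModelResult]) -> pd.DataFrame:
    rows = [
        {
            "focal_host": r.focal_host,
            "parasite_type": r.parasite_type,
            "model": r.model,
            "n_comparisons": r.n_comparisons,
            "observed_stat": r.observed_stat,
            "null_mean": r.null_mean,
            "null_sd": r.null_sd,
            "z_score": r.z_score,
            "quantile": r.quantile,
            "significant": r.significant,
            "low_n": r.low_n,
            "degenerate": r.degenerate,
            "n_draws": r.n_draws,
            "seed": r.seed,
            "null_unit": r.null_unit,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=list(NULL_RESULT_COLUMNS))


def write_results(results, path) -> None:
    """Write any stage output as a delimited table plus a JSON summary.

    Accepts a DataFrame or a sequence of ``NullModelResult``; column order is
    stable and floats keep full precision.
    """
    path = Path(path)
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        results = list(results)
        if not results:
            # degenerate stage output: header-only table in the null-result schema
            df = pd.DataFrame(columns=list(NULL_RESULT_COLUMNS))
        elif isinstance(results[0], NullModelResult):
            df = null_results_frame(results)
        else:
            df = pd.DataFrame(results)
    df.to_csv(path, sep=_sep_for(path), index=False)
    summary = {
        "rows": int(len(df)),
        "columns": list(map(str, df.columns)),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(summary, indent=2))


def read_env_table(path) -> pd.DataFrame:
    return _read_table(path)
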
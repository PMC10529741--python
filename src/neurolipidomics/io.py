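"""Delimited-text readers and writers for the pipeline's table formats.

All formats are plain CSV/TSV (delimiter sniffed on read):

* fatty-acid cohort: one row per sample, metadata columns ``sample_id``,
  ``region``, ``group`` plus one column per species label ("16:1n-7" style);
* feature table: columns ``feature_id, mz, rt, mode, ion_count``;
* sample metadata: ``sample_id, role, injection_order[, region, group]``;
* intensity matrix: features × samples, first column ``feature_id``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .fatty_acids import FattyAcidProfile, profile_from_mol_percent
from .features import Feature, SampleRecord
from .species import DEFAULT_PANEL_LABELS

__all__ = [
    "read_fa_cohort",
    "write_fa_cohort",
    "read_feature_table",
    "write_feature_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_intensity_matrix",
    "write_intensity_matrix",
    "write_json",
]

_META_COLS = ("sample_id", "region", "group")


def _read_delimited(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_fa_cohort(path: str | Path) -> list[FattyAcidProfile]:
    df = _read_delimited(path)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table lacks metadata columns {missing}")
    species_cols = [c for c in df.columns if c not in _META_COLS]
    profiles = []
    for row in df.to_dict("records"):
        molpct = {c: float(row[c]) for c in species_cols}
        profiles.append(
            profile_from_mol_percent(
                molpct,
                sample_id=str(row["sample_id"]),
                region=str(row["region"]),
                group=str(row["group"]),
            )
        )
    return profiles


def write_fa_cohort(profiles: Sequence[FattyAcidProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "sample_id": p.sample_id,
            "region": p.region,
            "group": p.group,
        }
        for lbl in DEFAULT_PANEL_LABELS:
            row[lbl] = p.get(lbl)
        extra = {sp.label: v for sp, v in p.mol_percent.items() if sp.label not in row}
        row.update(extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_feature_table(path: str | Path) -> list[Feature]:
    df = _read_delimited(path)
    return [
        Feature(
            str(r.feature_id),
            float(r.mz),
            float(r.rt),
            str(r.mode),
            int(getattr(r, "ion_count", 1)),
        )
        for r in df.itertuples(index=False)
    ]


def write_feature_table(features: Sequence[Feature], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "feature_id": f.feature_id,
                "mz": f.mz,
                "rt": f.rt,
                "mode": f.mode,
                "ion_count": f.ion_count,
            }
            for f in features
        ]
    ).to_csv(path, index=False)


def read_sample_metadata(path: str | Path) -> list[SampleRecord]:
    df = _read_delimited(path)
    records = []
    for r in df.to_dict("records"):
        region = r.get("region")
        group = r.get("group")
        records.append(
            SampleRecord(
                sample_id=str(r["sample_id"]),
                role=str(r["role"]),
                injection_order=int(r["injection_order"]),
                region=None if pd.isna(region) else str(region) if region is not None else None,
                group=None if group is None or pd.isna(group) else str(group),
            )
        )
    return records


def write_sample_metadata(samples: Sequence[SampleRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "role": s.role,
                "injection_order": s.injection_order,
                "region": s.region,
                "group": s.group,
            }
            for s in samples
        ]
    ).to_csv(path, index=False)


def read_intensity_matrix(path: str | Path) -> pd.DataFrame:
    df = _read_delimited(path)
    return df.set_index(df.columns[0])


def write_intensity_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.rename_axis("feature_id").to_csv(path)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
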
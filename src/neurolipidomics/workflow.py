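"""End-to-end orchestration: simulate/load → process → annotate → panels →
statistics → report tables.

The stage order is fixed: feature filtering and signal correction always
precede any statistics.  Reports mirror the field's cohort-table layouts:

* region contrast — one row per panel variable (26 species, 10 indices,
  15 activity ratios = a 51-test family), median [Q1;Q3] per region,
  Mann-Whitney p and BH-FDR q;
* stage tables per region — median [Q1;Q3] per stage group, Kruskal-Wallis
  p and q, Spearman rho vs stage with p and q;
* lipidome feature table — per-feature group statistics with annotation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import annotate_features, confirm_rt, load_lipid_db
from .fatty_acids import panel_values
from .features import filter_min_ions, filter_qc_presence, loess_drift_correct
from .reference import GROUPS, REGION_CONTRAST_VARIABLES, STAGE_RANK
from .simulate import CohortSpec, FeatureSimSpec, simulate_fa_cohort, simulate_feature_table
from .stats import bh_fdr, compare_regions, select_for_annotation, stage_comparison, stage_trend

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "write_report"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    When ``fa_cohort_path`` / feature paths are unset, cohorts and runs are
    simulated from the built-in templates (all randomness derives from
    ``seed`` via named substreams).
    """

    out_dir: str = "results"
    seed: int = 0
    # fatty-acid stage inputs (delimited text; None → simulate)
    fa_cohort_path: str | None = None
    # feature-processing inputs (all three or none)
    feature_table_path: str | None = None
    intensity_matrix_path: str | None = None
    sample_metadata_path: str | None = None
    lipid_db_path: str | None = None
    # module parameters
    min_ions: int = 2
    qc_presence_fraction: float = 0.70
    loess_span: float = 0.75
    rt_tolerance: float = 0.2
    annotation_alpha: float = 0.01
    fa_fdr_family: int = len(REGION_CONTRAST_VARIABLES)  # 51
    posthoc_adjust: bool = False
    # simulation blocks (used when paths are unset)
    sim_features: int = 150
    sim_samples: int = 20
    sim_drift_amplitude: float = 2.0
    sim_differential_fraction: float = 0.0
    sim_effect_size: float = 1.0
    dry_run: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in (
            "fa_cohort_path",
            "feature_table_path",
            "intensity_matrix_path",
            "sample_metadata_path",
            "lipid_db_path",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.min_ions < 1:
            raise ValueError("min_ions must be >= 1")
        if not 0 < self.qc_presence_fraction <= 1:
            raise ValueError("qc_presence_fraction must be in (0, 1]")
        if self.loess_span <= 0:
            raise ValueError("loess_span must be > 0")


@dataclass
class ReportBundle:
    region_contrast: pd.DataFrame
    stage_tables: dict[str, pd.DataFrame]
    lipidome_table: pd.DataFrame | None
    processing_log: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _fmt(v: float) -> str:
    return "nan" if not np.isfinite(v) else f"{v:.3g}"


def _median_string(med: float, q1: float, q3: float) -> str:
    return f"{_fmt(med)} [{_fmt(q1)};{_fmt(q3)}]"


def _panel_frame(profiles) -> pd.DataFrame:
    """Tidy per-sample panel table: sample_id, region, group, variable, value."""
    rows = []
    for p in profiles:
        for var, val in panel_values(p).items():
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "region": p.region,
                    "group": p.group,
                    "variable": var,
                    "value": val,
                }
            )
    return pd.DataFrame(rows)


def _stage(name: str, log: list[dict], **counts) -> None:
    entry = {"stage": name, **counts}
    log.append(entry)
    logger.info("stage %s: %s", name, counts)


def region_contrast_table(panels: pd.DataFrame, m: int) -> pd.DataFrame:
    """Table-2-layout contrast of MA grey vs white matter over all 51 variables."""
    ma = panels[panels["group"] == "MA"]
    rows = []
    for var in REGION_CONTRAST_VARIABLES:
        sub = ma[ma["variable"] == var]
        gm = sub.loc[sub["region"] == "GM", "value"].to_numpy(float)
        wm = sub.loc[sub["region"] == "WM", "value"].to_numpy(float)
        res = compare_regions(gm, wm, variable=var)
        gm_f, wm_f = gm[np.isfinite(gm)], wm[np.isfinite(wm)]
        q1g, mg, q3g = np.percentile(gm_f, [25, 50, 75]) if gm_f.size else (np.nan,) * 3
        q1w, mw, q3w = np.percentile(wm_f, [25, 50, 75]) if wm_f.size else (np.nan,) * 3
        rows.append(
            {
                "variable": var,
                "GM": _median_string(mg, q1g, q3g),
                "WM": _median_string(mw, q1w, q3w),
                "gm_median": mg,
                "wm_median": mw,
                "n_gm": len(gm_f),
                "n_wm": len(wm_f),
                "p": res.p,
            }
        )
    df = pd.DataFrame(rows)
    df["fdr_p"] = bh_fdr(df["p"].to_numpy(), m=max(m, len(df)))
    df["fdr_family"] = max(m, len(df))
    df["significant"] = df["p"] < 0.05
    return df


def stage_table(panels: pd.DataFrame, region: str, m: int) -> pd.DataFrame:
    """Tables-3/4-layout stage statistics for one region."""
    sub = panels[panels["region"] == region]
    rows = []
    for var in REGION_CONTRAST_VARIABLES:
        v = sub[sub["variable"] == var]
        groups = {
            g: v.loc[v["group"] == g, "value"].to_numpy(float)
            for g in GROUPS
            if (v["group"] == g).any()
        }
        kw, _ = stage_comparison(groups, variable=var)
        values = np.concatenate([groups[g] for g in groups])
        ranks = np.concatenate([[STAGE_RANK[g]] * len(groups[g]) for g in groups])
        trend = stage_trend(values, ranks, variable=var)
        row: dict[str, object] = {"variable": var}
        for g in GROUPS:
            if g in groups:
                gv = groups[g][np.isfinite(groups[g])]
                q1, med, q3 = np.percentile(gv, [25, 50, 75]) if gv.size else (np.nan,) * 3
                row[g] = _median_string(med, q1, q3)
        row.update({"kw_p": kw.p, "rho": trend.rho, "rho_p": trend.p})
        rows.append(row)
    df = pd.DataFrame(rows)
    fam = max(m, len(df))
    df["kw_fdr_p"] = bh_fdr(df["kw_p"].to_numpy(), m=fam)
    df["rho_fdr_p"] = bh_fdr(df["rho_p"].to_numpy(), m=fam)
    df["fdr_family"] = fam
    return df


def _feature_statistics(
    matrix: pd.DataFrame,
    samples,
    features,
    db,
    config: RunConfig,
    log: list[dict],
) -> pd.DataFrame:
    """Per-feature two-group statistics plus annotation of the strong hits."""
    study = [s for s in samples if s.role == "study"]
    group_a = [s.sample_id for s in study if s.group == "A"]
    group_b = [s.sample_id for s in study if s.group == "B"]
    feat_by_id = {f.feature_id: f for f in features}
    rows = []
    results = []
    for fid in matrix.index:
        a = matrix.loc[fid, group_a].to_numpy(float)
        b = matrix.loc[fid, group_b].to_numpy(float)
        try:
            res = compare_regions(a, b, variable=str(fid), method="asymptotic")
        except ValueError:
            continue
        results.append(res)
        rows.append({"feature_id": str(fid), "p": res.p, "U": res.statistic})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["fdr_p"] = bh_fdr(df["p"].to_numpy())
    df["fdr_family"] = len(df)

    selected = set(select_for_annotation(results, alpha=config.annotation_alpha))
    to_annotate = [feat_by_id[fid] for fid in selected if fid in feat_by_id]
    annotations: dict[str, tuple[str, str, str, float, str]] = {}
    if to_annotate and db:
        hits, unknown = annotate_features(to_annotate, db)
        hits = confirm_rt(hits, {f.feature_id: f.rt for f in to_annotate}, config.rt_tolerance)
        for h in hits:  # keep best hit per feature (sorted by |ppm| within feature)
            if h.feature_id not in annotations:
                annotations[h.feature_id] = (
                    h.entry.name,
                    h.entry.lipid_class,
                    h.entry.category,
                    h.ppm_error,
                    h.confidence,
                )
        _stage("annotate", log, selected=len(to_annotate), annotated=len(annotations),
               unknown=len(unknown))
    df["compound"] = [annotations.get(f, ("unknown",) * 5)[0] for f in df["feature_id"]]
    df["lipid_class"] = [annotations.get(f, (None,) * 5)[1] for f in df["feature_id"]]
    df["category"] = [annotations.get(f, (None,) * 5)[2] for f in df["feature_id"]]
    df["mz"] = [feat_by_id[f].mz if f in feat_by_id else np.nan for f in df["feature_id"]]
    df["rt"] = [feat_by_id[f].rt if f in feat_by_id else np.nan for f in df["feature_id"]]
    return df.sort_values("feature_id", kind="stable").reset_index(drop=True)


def run_pipeline(config: RunConfig) -> ReportBundle | None:
    """Execute all stages in fixed order; ``dry_run`` only validates."""
    config.validate()
    if config.dry_run:
        logger.info("dry run: configuration valid, nothing computed")
        return None
    from . import io as nio

    log: list[dict] = []
    rng_seed = int(config.seed)

    # --- fatty-acid cohorts -------------------------------------------------
    if config.fa_cohort_path:
        profiles = nio.read_fa_cohort(config.fa_cohort_path)
    else:
        profiles = []
        for i, region in enumerate(("GM", "WM")):
            prof, _ = simulate_fa_cohort(CohortSpec(region=region, seed=rng_seed + i))
            profiles.extend(prof)
    _stage("fa_cohort", log, samples=len(profiles))
    panels = _panel_frame(profiles)

    contrast = region_contrast_table(panels, m=config.fa_fdr_family)
    _stage("region_contrast", log, variables=len(contrast))
    stage_tables = {
        region: stage_table(panels, region, m=config.fa_fdr_family)
        for region in sorted(panels["region"].unique())
    }
    _stage("stage_tables", log, regions=len(stage_tables))

    # --- untargeted features ------------------------------------------------
    db = load_lipid_db(config.lipid_db_path)
    if config.feature_table_path:
        features = nio.read_feature_table(config.feature_table_path)
        samples = nio.read_sample_metadata(config.sample_metadata_path)
        matrix = nio.read_intensity_matrix(config.intensity_matrix_path)
    else:
        spec = FeatureSimSpec(
            n_features=config.sim_features,
            n_samples=config.sim_samples,
            drift_amplitude=config.sim_drift_amplitude,
            differential_fraction=config.sim_differential_fraction,
            effect_size=config.sim_effect_size,
            annotated_fraction=0.2,
            ppm_noise=3.0,
            seed=rng_seed + 17,
        )
        features, samples, matrix, _ = simulate_feature_table(spec, db)
    n0 = len(features)
    features = filter_min_ions(features, config.min_ions)
    matrix = matrix.loc[[f.feature_id for f in features if f.feature_id in matrix.index]]
    _stage("filter_min_ions", log, features_in=n0, features_out=len(features))

    n1 = len(matrix)
    matrix = filter_qc_presence(matrix, samples, config.qc_presence_fraction)
    _stage("filter_qc_presence", log, features_in=n1, features_out=len(matrix))

    matrix, flagged = loess_drift_correct(matrix, samples, span=config.loess_span)
    _stage("loess_drift_correct", log, features=len(matrix), passed_through=len(flagged))

    lipidome = _feature_statistics(matrix, samples, features, db, config, log)
    _stage("feature_statistics", log, tested=len(lipidome))

    cfg_json = json.dumps(asdict(config), sort_keys=True)
    bundle = ReportBundle(
        region_contrast=contrast,
        stage_tables=stage_tables,
        lipidome_table=lipidome,
        processing_log=log,
        provenance={
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": config.seed,
            "version": __version__,
        },
    )
    return bundle


def write_report(bundle: ReportBundle, out_dir: str | Path) -> list[Path]:
    """Write the report tables, processing log, and provenance block."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    path = out / "region_contrast.csv"
    bundle.region_contrast.to_csv(path, index=False)
    written.append(path)
    for region, table in sorted(bundle.stage_tables.items()):
        path = out / f"stage_{region}.csv"
        table.to_csv(path, index=False)
        written.append(path)
    if bundle.lipidome_table is not None:
        path = out / "lipidome_features.csv"
        bundle.lipidome_table.to_csv(path, index=False)
        written.append(path)

    log_path = out / "processing_log.jsonl"
    with log_path.open("w") as fh:
        for entry in bundle.processing_log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
    written.append(log_path)

    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(bundle.provenance, indent=2, sort_keys=True) + "\n")
    written.append(prov_path)
    return written
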
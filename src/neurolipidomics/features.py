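"""Untargeted LC-MS feature table processing.

The pipeline starts from a molecular-feature table (vendor peak picking is
upstream and out of scope) and applies, in order: a minimum-ion filter, a
QC-presence filter, QC-anchored LOESS drift correction along the injection
sequence, and per-class internal-standard normalization.  A separate
cross-run aligner matches feature lists between runs with compound
relative/absolute retention-time and mass tolerances.

Intensity matrices are pandas DataFrames, rows indexed by ``feature_id``
and columns by ``sample_id``; missing measurements are NaN.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

__all__ = [
    "Feature",
    "SampleRecord",
    "AlignmentWindow",
    "filter_min_ions",
    "filter_qc_presence",
    "loess_drift_correct",
    "normalize_internal_standards",
    "align_runs",
]

# Correction-factor clip bounds: prevents blow-ups at run edges.
FACTOR_CLIP = (0.2, 5.0)


@dataclass(frozen=True)
class Feature:
    """One molecular feature (a group of co-migrating ionic species)."""

    feature_id: str
    mz: float
    rt: float
    mode: str  # "positive" | "negative"
    ion_count: int = 1

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"{self.feature_id}: m/z must be > 0")
        if self.rt < 0:
            raise ValueError(f"{self.feature_id}: retention time must be >= 0")
        if self.mode not in ("positive", "negative"):
            raise ValueError(f"{self.feature_id}: unknown ionization mode {self.mode!r}")
        if self.ion_count < 1:
            raise ValueError(f"{self.feature_id}: ion_count must be >= 1")


@dataclass(frozen=True)
class SampleRecord:
    """One injection: a study sample or a pooled QC."""

    sample_id: str
    role: str  # "study" | "QC"
    injection_order: int
    region: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ("study", "QC"):
            raise ValueError(f"{self.sample_id}: unknown role {self.role!r}")
        if self.injection_order < 1:
            raise ValueError(f"{self.sample_id}: injection_order must be >= 1")


def _check_samples(samples: Sequence[SampleRecord]) -> None:
    orders = [s.injection_order for s in samples]
    if len(set(orders)) != len(orders):
        raise ValueError("injection orders must be unique within a batch")


@dataclass(frozen=True)
class AlignmentWindow:
    """Compound RT and mass tolerances for cross-run alignment.

    Each dimension has a relative and an absolute term.  Under the default
    ("either") semantics a pair matches if it is within the larger of the
    two terms; ``strict=True`` requires it to be within both.
    """

    rt_relative: float = 0.001  # fraction of mean RT (0.1 %)
    rt_absolute: float = 0.25  # minutes
    mass_ppm: float = 30.0
    mass_absolute: float = 0.0020  # Da
    strict: bool = False

    def __post_init__(self) -> None:
        for name in ("rt_relative", "rt_absolute", "mass_ppm", "mass_absolute"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rt_tolerance(self, rt_a: float, rt_b: float) -> float:
        rel = self.rt_relative * 0.5 * (rt_a + rt_b)
        return min(rel, self.rt_absolute) if self.strict else max(rel, self.rt_absolute)

    def mass_tolerance(self, mz_a: float, mz_b: float) -> float:
        rel = self.mass_ppm * 1e-6 * 0.5 * (mz_a + mz_b)
        return min(rel, self.mass_absolute) if self.strict else max(rel, self.mass_absolute)


def filter_min_ions(features: Sequence[Feature], min_ions: int = 2) -> list[Feature]:
    """Keep features built from at least ``min_ions`` ions (order preserved)."""
    if min_ions < 1:
        raise ValueError("min_ions must be >= 1")
    if not features:
        raise ValueError("empty feature list")
    kept = [f for f in features if f.ion_count >= min_ions]
    if not kept:
        logger.warning("min-ion filter removed all %d features", len(features))
    return kept


def filter_qc_presence(
    matrix: pd.DataFrame,
    samples: Sequence[SampleRecord],
    min_fraction: float = 0.70,
) -> pd.DataFrame:
    """Keep features detected (positive intensity) in at least
    ``min_fraction`` of the QC injections ("at least" — boundary inclusive).
    """
    qc_ids = [s.sample_id for s in samples if s.role == "QC"]
    if not qc_ids:
        raise ValueError("QC-based filtering impossible: no QC samples")
    qc = matrix[qc_ids]
    present = ((qc > 0) & qc.notna()).sum(axis=1)
    keep = present >= min_fraction * len(qc_ids)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("QC-presence filter dropped %d of %d features", dropped, len(matrix))
    return matrix.loc[keep]


def _interp_extrapolate(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """np.interp with linear extrapolation beyond the fitted range."""
    y = np.interp(x, xp, fp)
    if len(xp) >= 2:
        left = x < xp[0]
        if left.any():
            slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
            y[left] = fp[0] + slope * (x[left] - xp[0])
        right = x > xp[-1]
        if right.any():
            slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
            y[right] = fp[-1] + slope * (x[right] - xp[-1])
    return y


def loess_drift_correct(
    matrix: pd.DataFrame,
    samples: Sequence[SampleRecord],
    span: float = 0.75,
    min_qc: int = 4,
    log_domain: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """QC-anchored LOESS correction of injection-order signal drift.

    Per feature, a locally weighted degree-1 regression of QC intensity on
    injection order estimates the drift trend; every sample's intensity is
    rescaled by (QC median / trend at its injection order), with linear
    extrapolation beyond the first/last QC.  By default the trend is fitted
    on log intensities and exponentiated, which keeps corrected values
    positive.  Correction factors are clipped to ``FACTOR_CLIP``.

    Returns the corrected matrix and the ids of features passed through
    unchanged (too few usable QCs or a degenerate fit).
    """
    if span <= 0:
        raise ValueError("span must be > 0")
    if min_qc < 2:
        raise ValueError("min_qc must be >= 2")
    _check_samples(samples)
    by_id = {s.sample_id: s for s in samples}
    missing = [c for c in matrix.columns if c not in by_id]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    qc_ids = [s.sample_id for s in samples if s.role == "QC" and s.sample_id in matrix.columns]
    if len(qc_ids) < min_qc:
        raise ValueError(f"need at least {min_qc} QC injections, have {len(qc_ids)}")

    orders = np.array([by_id[c].injection_order for c in matrix.columns], dtype=float)
    qc_orders_all = np.array([by_id[c].injection_order for c in qc_ids], dtype=float)

    corrected = matrix.copy().astype(float)
    flagged: list[str] = []
    for fid, row in matrix.iterrows():
        qc_vals = row[qc_ids].to_numpy(dtype=float)
        usable = np.isfinite(qc_vals) & (qc_vals > 0)
        if usable.sum() < min_qc:
            flagged.append(str(fid))
            continue
        x = qc_orders_all[usable]
        y = qc_vals[usable]
        ref = float(np.median(y))
        ylog = np.log(y) if log_domain else y
        fit = lowess(ylog, x, frac=span, it=2, return_sorted=True)
        trend = _interp_extrapolate(orders, fit[:, 0], fit[:, 1])
        if log_domain:
            trend = np.exp(trend)
        if not np.all(np.isfinite(trend)) or np.any(trend <= 0):
            flagged.append(str(fid))
            continue
        factor = np.clip(ref / trend, *FACTOR_CLIP)
        n_clipped = int(np.sum((ref / trend < FACTOR_CLIP[0]) | (ref / trend > FACTOR_CLIP[1])))
        if n_clipped:
            logger.info("feature %s: %d correction factors clipped", fid, n_clipped)
        corrected.loc[fid] = row.to_numpy(dtype=float) * factor
    if flagged:
        logger.info("drift correction passed %d features through unchanged", len(flagged))
    return corrected, flagged


def normalize_internal_standards(
    matrix: pd.DataFrame,
    class_of_feature: Mapping[str, str],
    standard_features: Mapping[str, str],
) -> pd.DataFrame:
    """Divide each feature by its lipid class's isotope-labelled standard.

    Classes without a standard fall back to no normalization (warned).
    Samples where the standard is missing or zero get NaN for that class.
    """
    out = matrix.copy().astype(float)
    warned: set[str] = set()
    for fid in matrix.index:
        cls = class_of_feature.get(str(fid))
        if cls is None:
            continue
        std_id = standard_features.get(cls)
        if std_id is None:
            if cls not in warned:
                logger.warning("lipid class %s has no internal standard; left unnormalized", cls)
                warned.add(cls)
            continue
        std = matrix.loc[std_id].to_numpy(dtype=float)
        bad = ~np.isfinite(std) | (std <= 0)
        if bad.any():
            logger.info(
                "standard %s missing/zero in %d samples; class %s values set to NaN there",
                std_id,
                int(bad.sum()),
                cls,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = matrix.loc[fid].to_numpy(dtype=float) / std
        vals[bad] = np.nan
        out.loc[fid] = vals
    return out


@dataclass(frozen=True)
class MatchedPair:
    id_a: str
    id_b: str
    rt_delta: float
    ppm_delta: float
    distance: float


def align_runs(
    features_a: Sequence[Feature],
    features_b: Sequence[Feature],
    window: AlignmentWindow | None = None,
) -> tuple[list[MatchedPair], list[str], list[str]]:
    """One-to-one cross-run feature matching within RT/mass windows.

    Candidates within both the RT and mass windows are resolved greedily by
    smallest combined normalized distance, ties broken by (smaller ppm
    error, smaller RT gap, lexicographic id pair) — deterministic and
    symmetric in the two input lists.  Returns (pairs, unmatched ids of A,
    unmatched ids of B).
    """
    if not features_a or not features_b:
        raise ValueError("both feature lists must be non-empty")
    modes = {f.mode for f in features_a} | {f.mode for f in features_b}
    if len(modes) > 1:
        raise ValueError(f"mixed ionization modes: {sorted(modes)}")
    window = window or AlignmentWindow()

    candidates: list[tuple[float, float, float, str, str, MatchedPair]] = []
    for a in features_a:
        for b in features_b:
            rt_tol = window.rt_tolerance(a.rt, b.rt)
            mz_tol = window.mass_tolerance(a.mz, b.mz)
            d_rt = abs(a.rt - b.rt)
            d_mz = abs(a.mz - b.mz)
            if d_rt > rt_tol or d_mz > mz_tol:
                continue
            # normalized Euclidean distance in (RT, mass) tolerance units
            dist = math.hypot(
                d_rt / rt_tol if rt_tol > 0 else 0.0,
                d_mz / mz_tol if mz_tol > 0 else 0.0,
            )
            ppm = 1e6 * d_mz / (0.5 * (a.mz + b.mz))
            ids = tuple(sorted((a.feature_id, b.feature_id)))
            pair = MatchedPair(a.feature_id, b.feature_id, d_rt, ppm, dist)
            candidates.append((dist, ppm, d_rt, ids[0], ids[1], pair))

    candidates.sort(key=lambda t: t[:5])
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs: list[MatchedPair] = []
    for *_, pair in candidates:
        if pair.id_a in used_a or pair.id_b in used_b:
            continue
        used_a.add(pair.id_a)
        used_b.add(pair.id_b)
        pairs.append(pair)
    unmatched_a = [f.feature_id for f in features_a if f.feature_id not in used_a]
    unmatched_b = [f.feature_id for f in features_b if f.feature_id not in used_b]
    return pairs, unmatched_a, unmatched_b
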
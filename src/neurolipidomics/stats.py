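"""Nonparametric statistics for small-cohort lipidomics.

Group sizes in this design are tiny (4-7 samples per Braak-stage group),
so everything is rank-based:

* two-region contrasts via Mann-Whitney U, with a tie-aware exact
  permutation null (full enumeration of group labelings) for combined
  n ≤ 12 and the normal approximation with tie correction above;
* four-group stage comparisons via Kruskal-Wallis with Dunn's z post-hoc
  on mean ranks (reported unadjusted across pairs by default);
* ordinal stage trends via Spearman correlation on mid-ranks, two-sided p
  from the t approximation, with an exact permutation option for n ≤ 10;
* Benjamini-Hochberg FDR with an explicit family size ``m`` that may
  exceed the number of p-values supplied (a reported subset corrected
  against a larger test family);
* relative qPCR expression via the double-delta-CT method,
  fold = 2^(−ΔΔCT) against a reference gene and a calibrator group.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "PosthocResult",
    "TrendResult",
    "DdctResult",
    "compare_regions",
    "mannwhitney_exact",
    "select_for_annotation",
    "stage_comparison",
    "stage_trend",
    "bh_fdr",
    "ddct_expression",
]

EXACT_MW_MAX_N = 12  # combined-n switch point for the exact Mann-Whitney null
EXACT_SPEARMAN_MAX_N = 10


@dataclass(frozen=True)
class TestResult:
    variable: str
    statistic: float
    p: float
    test_name: str
    n_per_group: tuple[int, ...]
    q: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1 or math.isnan(self.p)):
            raise ValueError(f"invalid p-value {self.p}")


@dataclass(frozen=True)
class PosthocResult:
    variable: str
    pair: tuple[str, str]
    z: float
    p: float
    adjusted: bool = False


@dataclass(frozen=True)
class TrendResult:
    variable: str
    rho: float
    p: float
    n: int
    q: float | None = None

    def __post_init__(self) -> None:
        if not (math.isnan(self.rho) or abs(self.rho) <= 1 + 1e-12):
            raise ValueError(f"invalid rho {self.rho}")


@dataclass(frozen=True)
class DdctResult:
    sample_id: str
    gene: str
    group: str
    delta_ct: float
    delta_delta_ct: float

    @property
    def fold_change(self) -> float:
        return 2.0 ** (-self.delta_delta_ct)


def _clean(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v[np.isfinite(v)]


def mannwhitney_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-aware exact two-sided Mann-Whitney test by full enumeration.

    Pooled values are mid-ranked once; U is recomputed for every
    C(n1+n2, n1) assignment of ranks to the first group.  The two-sided p
    is the fraction of assignments at least as far from the null mean
    n1·n2/2 as the observed U (a symmetric-distance permutation p; for
    tie-free data it equals the classical doubled tail).
    """
    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    u_obs = float(ranks[:n1].sum()) - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2.0
    d_obs = abs(u_obs - mu)
    total = 0
    extreme = 0
    base = n1 * (n1 + 1) / 2
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(combo)].sum() - base
        total += 1
        if abs(u - mu) >= d_obs - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def compare_regions(
    values_a,
    values_b,
    variable: str = "",
    method: str = "auto",
) -> TestResult:
    """Two-sided Mann-Whitney U contrast of two independent groups.

    ``method``: "exact" (full enumeration, tie-aware), "asymptotic"
    (normal approximation with tie correction and continuity correction),
    or "auto" (exact when combined n ≤ 12).  Missing values are dropped
    per group.
    """
    x, y = _clean(values_a), _clean(values_b)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    if method == "auto":
        method = "exact" if len(x) + len(y) <= EXACT_MW_MAX_N else "asymptotic"
    if method == "exact":
        u, p = mannwhitney_exact(x, y)
        name = "Mann-Whitney U (exact)"
    elif method == "asymptotic":
        u, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        u, p = float(u), float(p)
        name = "Mann-Whitney U (normal approximation)"
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(variable, u, min(p, 1.0), name, (len(x), len(y)))


def select_for_annotation(results: list[TestResult], alpha: float = 0.01) -> list[str]:
    """Variables passing the strict raw-p screen (p < alpha) for annotation."""
    return [r.variable for r in results if r.p < alpha]


def stage_comparison(
    groups: dict[str, "np.ndarray | list[float]"],
    variable: str = "",
    adjust_posthoc: bool = False,
) -> tuple[TestResult, list[PosthocResult]]:
    """Kruskal-Wallis across stage groups with Dunn's post-hoc z tests.

    Dunn's z for a pair (i, j) compares mean pooled mid-ranks with the
    tie-corrected variance N(N+1)/12 − ΣT/(12(N−1)); pairwise p-values are
    two-sided normal and reported unadjusted unless ``adjust_posthoc``
    (Bonferroni over the tested pairs).
    """
    cleaned = {g: _clean(v) for g, v in groups.items()}
    cleaned = {g: v for g, v in cleaned.items() if len(v) > 0}
    if len(cleaned) < 2:
        raise ValueError("need at least 2 non-empty groups")
    for g, v in cleaned.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")

    names = list(cleaned)
    samples = [cleaned[g] for g in names]
    h, p = sps.kruskal(*samples)
    result = TestResult(
        variable, float(h), float(p), "Kruskal-Wallis", tuple(len(v) for v in samples)
    )

    pooled = np.concatenate(samples)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g, v in zip(names, samples):
        mean_ranks[g] = ranks[start : start + len(v)].mean()
        start += len(v)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    posthoc: list[PosthocResult] = []
    pairs = list(itertools.combinations(names, 2))
    for a, b in pairs:
        se = math.sqrt(var_base * (1.0 / len(cleaned[a]) + 1.0 / len(cleaned[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        pp = 2.0 * sps.norm.sf(abs(z))
        if adjust_posthoc:
            pp = min(1.0, pp * len(pairs))
        posthoc.append(PosthocResult(variable, (a, b), float(z), float(pp), adjust_posthoc))
    return result, posthoc


def _spearman_rho(values: np.ndarray, ranks_y: np.ndarray) -> float:
    rx = sps.rankdata(values)
    if np.std(rx) == 0 or np.std(ranks_y) == 0:
        return math.nan
    return float(np.corrcoef(rx, ranks_y)[0, 1])


def stage_trend(
    values,
    stage_rank,
    variable: str = "",
    method: str = "t",
) -> TrendResult:
    """Spearman correlation of a variable against the ordinal stage rank.

    Mid-ranks handle the heavy ties of the stage coding.  ``method``:
    "t" — two-sided p from the t approximation with n−2 df;
    "permutation" — exact p by enumerating all permutations (n ≤ 10).
    Constant values give an undefined (NaN) correlation.
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(stage_rank, dtype=float)
    keep = np.isfinite(v) & np.isfinite(s)
    v, s = v[keep], s[keep]
    n = len(v)
    if n < 5:
        raise ValueError("need at least 5 paired observations")
    if len(np.unique(s)) < 2:
        raise ValueError("need at least two distinct stage ranks")
    ranks_s = sps.rankdata(s)
    rho = _spearman_rho(v, ranks_s)
    if math.isnan(rho):
        return TrendResult(variable, math.nan, math.nan, n)
    if method == "t":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    elif method == "permutation":
        if n > EXACT_SPEARMAN_MAX_N:
            raise ValueError(f"exact permutation limited to n <= {EXACT_SPEARMAN_MAX_N}")
        rx = sps.rankdata(v)
        count = 0
        total = 0
        for perm in itertools.permutations(rx):
            r = np.corrcoef(np.asarray(perm), ranks_s)[0, 1]
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    else:
        raise ValueError(f"unknown method {method!r}")
    return TrendResult(variable, rho, min(p, 1.0), n)


def bh_fdr(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values over a family of ``m`` tests.

    ``m`` defaults to the number of p-values; it may be larger when a
    reported subset is corrected against a wider family (the subset must
    then contain the smallest p-values of that family for the q-values to
    be exact).  q_i = min_{j: p_j ≥ p_i} (m · p_j / rank_j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    if m is None:
        m = k
    if m < k:
        raise ValueError(f"family size m={m} smaller than number of tests {k}")
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def ddct_expression(
    ct: pd.DataFrame,
    reference_gene: str,
    calibrator_group: str,
) -> list[DdctResult]:
    """Relative qPCR expression by the double-delta-CT method.

    ``ct`` is tidy with columns sample_id, gene, CT, group.
    ΔCT = CT(target) − CT(reference gene) per sample; ΔΔCT subtracts the
    calibrator group's mean ΔCT per gene; fold change = 2^(−ΔΔCT).
    Samples missing the reference gene are dropped with a warning.
    """
    required = {"sample_id", "gene", "CT", "group"}
    if not required <= set(ct.columns):
        raise ValueError(f"need columns {sorted(required)}")
    wide = ct.pivot_table(index="sample_id", columns="gene", values="CT", aggfunc="mean")
    if reference_gene not in wide.columns:
        raise ValueError(f"reference gene {reference_gene!r} not measured")
    group_of = ct.drop_duplicates("sample_id").set_index("sample_id")["group"]
    if calibrator_group not in set(group_of):
        raise ValueError(f"calibrator group {calibrator_group!r} is empty")

    usable = wide[reference_gene].notna()
    dropped = wide.index[~usable]
    if len(dropped):
        import logging

        logging.getLogger(__name__).warning(
            "dropping %d samples without reference-gene CT", len(dropped)
        )
    wide = wide.loc[usable]

    delta = wide.drop(columns=[reference_gene]).sub(wide[reference_gene], axis=0)
    calib = delta.loc[[s for s in delta.index if group_of[s] == calibrator_group]]
    calib_mean = calib.mean(axis=0)

    out: list[DdctResult] = []
    for sample in delta.index:
        for gene in delta.columns:
            d = delta.loc[sample, gene]
            if pd.isna(d):
                continue
            out.append(
                DdctResult(
                    sample_id=str(sample),
                    gene=str(gene),
                    group=str(group_of[sample]),
                    delta_ct=float(d),
                    delta_delta_ct=float(d - calib_mean[gene]),
                )
            )
    return out
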
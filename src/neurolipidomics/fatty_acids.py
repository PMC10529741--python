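"""Fatty-acyl composition panels: mol% normalization, membrane indices,
and estimated enzyme activities.

The index panel summarizes a mol% composition into saturation-class sums
(SFA/UFA/MUFA/PUFA and the n-3/n-6 PUFA subsets), the mol%-weighted mean
acyl chain length (ACL), the double-bond index (DBI), and two
peroxidizability indices that weight double-bond classes by their relative
susceptibility to peroxidation:

    ACL   = Σ_L (Σ mol% with chain length L) · L / 100
    DBI   = 1·mono + 2·di + 3·tri + 4·tetra + 5·penta + 6·hexa
    PI(a) = 0.025·mono + 1·di + 2·tri + 4·tetra + 6·penta + 8·hexa
    PI(b) = 0.015·mono + 1·di + 2·tri + 3·tetra + 4·penta + 5·hexa

where mono..hexa are mol% sums over species with 1..6 double bonds.

Enzyme (elongase/desaturase) activities are estimated as product/substrate
mol% ratios; they are proxies for flux through a specific elongation or
desaturation step, not measured kinetics.  Panels are computed per sample
and only then aggregated to group medians — the reverse order (ratios of
median compositions) gives systematically different numbers and is not
what published cohort tables report.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .reference import GROUPS, INDEX_VARIABLES, STAGE_RANK
from .species import DEFAULT_PANEL_LABELS, FattyAcidSpecies, parse_label

logger = logging.getLogger(__name__)

__all__ = [
    "FattyAcidProfile",
    "IndexPanel",
    "ActivityPanel",
    "GroupSummary",
    "normalize_to_mol_percent",
    "profile_from_mol_percent",
    "compute_index_panel",
    "compute_activity_panel",
    "panel_values",
    "summarize_groups",
]

#: product / substrate label pairs, keyed by report name.
ACTIVITY_RATIOS: dict[str, tuple[str, str]] = {
    "Δ9(n-7)": ("16:1n-7", "16:0"),
    "Δ9(n-9)": ("18:1n-9", "18:0"),
    "Δ5(n-6)": ("20:4n-6", "20:3n-6"),
    "Δ6(n-3) (a)": ("18:4n-3", "18:3n-3"),
    "Δ6(n-3) (b)": ("24:6n-3", "24:5n-3"),
    "Elovl3(n-9)": ("20:1n-9", "18:1n-9"),
    "Elovl6": ("18:0", "16:0"),
    "Elovl1-3-7a": ("20:0", "18:0"),
    "Elovl1-3-7b": ("22:0", "20:0"),
    "Elovl1-3-7c": ("24:0", "22:0"),
    "Elovl5(n-6)": ("20:2n-6", "18:2n-6"),
    "Elovl2-5(n-6)": ("22:4n-6", "20:4n-6"),
    "Elovl2-5(n-3)": ("22:5n-3", "20:5n-3"),
    "Elovl2(n-3)": ("24:5n-3", "22:5n-3"),
    "Perox β-ox": ("22:6n-3", "24:6n-3"),
}

_PI_A = {1: 0.025, 2: 1.0, 3: 2.0, 4: 4.0, 5: 6.0, 6: 8.0}
_PI_B = {1: 0.015, 2: 1.0, 3: 2.0, 4: 3.0, 5: 4.0, 6: 5.0}

MOLPCT_SUM_TOL = 0.5  # accommodates rounded published medians


@dataclass
class FattyAcidProfile:
    """One sample's mol% fatty-acid composition with cohort labels."""

    sample_id: str
    region: str  # "GM" or "WM"
    group: str  # one of GROUPS
    mol_percent: dict[FattyAcidSpecies, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.region not in ("GM", "WM"):
            raise ValueError(f"unknown region {self.region!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown stage group {self.group!r}")
        for sp, v in self.mol_percent.items():
            if v < 0:
                raise ValueError(f"negative mol% for {sp.label}: {v}")
        total = self.total
        if self.mol_percent and not (100 - MOLPCT_SUM_TOL <= total <= 100 + MOLPCT_SUM_TOL):
            raise ValueError(
                f"mol% sums to {total:.3f}, outside 100 ± {MOLPCT_SUM_TOL}"
            )

    @property
    def stage_rank(self) -> int:
        return STAGE_RANK[self.group]

    @property
    def total(self) -> float:
        return float(sum(self.mol_percent.values()))

    def get(self, label: str) -> float:
        return self.mol_percent.get(parse_label(label), 0.0)


def _as_species_map(values: Mapping, *, warn_extra: bool = True) -> dict[FattyAcidSpecies, float]:
    panel = set(DEFAULT_PANEL_LABELS)
    out: dict[FattyAcidSpecies, float] = {}
    for key, v in values.items():
        sp = key if isinstance(key, FattyAcidSpecies) else parse_label(str(key))
        if warn_extra and sp.label not in panel:
            logger.warning("species %s is outside the default 26-species panel", sp.label)
        out[sp] = float(v)
    return out


def normalize_to_mol_percent(
    raw_areas: Mapping,
    *,
    sample_id: str = "sample",
    region: str = "GM",
    group: str = "MA",
) -> FattyAcidProfile:
    """Normalize raw peak areas to mol% (areas assumed mole-proportional).

    mol%_i = 100 · area_i / Σ areas.  Species of the default panel absent
    from the input are set to 0.
    """
    areas = _as_species_map(raw_areas)
    for sp, v in areas.items():
        if v < 0:
            raise ValueError(f"negative peak area for {sp.label}: {v}")
    total = sum(areas.values())
    if total <= 0:
        raise ValueError("empty profile: all peak areas are zero")
    molpct = {sp: 100.0 * v / total for sp, v in areas.items()}
    for lbl in DEFAULT_PANEL_LABELS:
        molpct.setdefault(parse_label(lbl), 0.0)
    return FattyAcidProfile(sample_id, region, group, molpct)


def profile_from_mol_percent(
    molpct: Mapping,
    *,
    sample_id: str = "sample",
    region: str = "GM",
    group: str = "MA",
) -> FattyAcidProfile:
    """Build a profile from values already expressed as mol% (sum 100 ± 0.5)."""
    values = _as_species_map(molpct)
    for lbl in DEFAULT_PANEL_LABELS:
        values.setdefault(parse_label(lbl), 0.0)
    return FattyAcidProfile(sample_id, region, group, values)


@dataclass(frozen=True)
class IndexPanel:
    """Saturation-class sums and membrane indices of one profile."""

    SFA: float
    UFA: float
    MUFA: float
    PUFA: float
    PUFAn3: float
    PUFAn6: float
    ACL: float
    DBI: float
    PI_a: float
    PI_b: float

    def as_dict(self) -> dict[str, float]:
        return dict(
            zip(
                INDEX_VARIABLES,
                (
                    self.SFA,
                    self.UFA,
                    self.PUFA,
                    self.MUFA,
                    self.PUFAn3,
                    self.PUFAn6,
                    self.ACL,
                    self.DBI,
                    self.PI_a,
                    self.PI_b,
                ),
            )
        )


def compute_index_panel(profile: FattyAcidProfile) -> IndexPanel:
    """Compute saturation sums, ACL, DBI and the two peroxidizability indices."""
    db_class: dict[int, float] = {k: 0.0 for k in range(7)}
    chain: dict[int, float] = {}
    pufan3 = pufan6 = 0.0
    for sp, v in profile.mol_percent.items():
        if sp.double_bonds > 6:
            raise ValueError(
                f"{sp.label}: {sp.double_bonds} double bonds is outside index definition"
            )
        db_class[sp.double_bonds] += v
        chain[sp.carbons] = chain.get(sp.carbons, 0.0) + v
        if sp.double_bonds >= 2:
            if sp.series == "n-3":
                pufan3 += v
            elif sp.series == "n-6":
                pufan6 += v
    sfa = db_class[0]
    mufa = db_class[1]
    pufa = sum(db_class[k] for k in range(2, 7))
    acl = sum(length * v for length, v in chain.items()) / 100.0
    dbi = sum(k * db_class[k] for k in range(1, 7))
    pi_a = sum(_PI_A[k] * db_class[k] for k in range(1, 7))
    pi_b = sum(_PI_B[k] * db_class[k] for k in range(1, 7))
    return IndexPanel(
        SFA=sfa,
        UFA=mufa + pufa,
        MUFA=mufa,
        PUFA=pufa,
        PUFAn3=pufan3,
        PUFAn6=pufan6,
        ACL=acl,
        DBI=dbi,
        PI_a=pi_a,
        PI_b=pi_b,
    )


@dataclass(frozen=True)
class ActivityPanel:
    """Estimated elongase/desaturase activities (product/substrate ratios).

    Ratios whose substrate mol% is zero are undefined and carried as NaN so
    that one degenerate sample does not abort a cohort run.
    """

    ratios: dict[str, float]

    def as_dict(self) -> dict[str, float]:
        return dict(self.ratios)

    def __getitem__(self, name: str) -> float:
        return self.ratios[name]


def compute_activity_panel(profile: FattyAcidProfile) -> ActivityPanel:
    ratios: dict[str, float] = {}
    for name, (product, substrate) in ACTIVITY_RATIOS.items():
        denom = profile.get(substrate)
        if denom == 0.0:
            logger.info(
                "%s undefined for sample %s: %s has mol%% = 0",
                name,
                profile.sample_id,
                substrate,
            )
            ratios[name] = math.nan
        else:
            ratios[name] = profile.get(product) / denom
    return ActivityPanel(ratios)


def panel_values(profile: FattyAcidProfile) -> dict[str, float]:
    """All 51 report variables of one sample: species mol%, indices, activities."""
    out: dict[str, float] = {lbl: profile.get(lbl) for lbl in DEFAULT_PANEL_LABELS}
    out.update(compute_index_panel(profile).as_dict())
    out.update(compute_activity_panel(profile).as_dict())
    return out


@dataclass(frozen=True)
class GroupSummary:
    """median [Q1;Q3] of one variable in one group (undefined values excluded)."""

    variable: str
    group: str
    n: int
    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if self.n > 0 and not (self.q1 <= self.median <= self.q3):
            raise ValueError(f"{self.variable}/{self.group}: Q1 ≤ median ≤ Q3 violated")


def summarize_groups(
    values: pd.DataFrame,
    *,
    variables: Iterable[str] | None = None,
) -> list[GroupSummary]:
    """Aggregate per-sample panel values to group median [Q1;Q3] summaries.

    ``values`` is tidy: columns ``variable``, ``group``, ``value`` (one row
    per sample per variable).  Quartiles use linear interpolation between
    order statistics (numpy's default, the "type 7" rule).  NaNs (undefined
    ratios) are excluded and the effective n reported.
    """
    required = {"variable", "group", "value"}
    if not required <= set(values.columns):
        raise ValueError(f"need columns {sorted(required)}")
    if variables is None:
        variables = list(dict.fromkeys(values["variable"]))
    groups_present = [g for g in GROUPS if g in set(values["group"])]
    extra = set(values["group"]) - set(GROUPS)
    groups_present += sorted(extra)
    out: list[GroupSummary] = []
    for var in variables:
        sub = values[values["variable"] == var]
        for grp in groups_present:
            v = sub.loc[sub["group"] == grp, "value"].to_numpy(dtype=float)
            if v.size == 0:
                raise ValueError(f"empty group {grp!r} for variable {var!r}")
            v = v[~np.isnan(v)]
            if v.size == 0:
                out.append(GroupSummary(var, grp, 0, math.nan, math.nan, math.nan))
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                q1, med, q3 = np.percentile(v, [25, 50, 75])
            out.append(GroupSummary(var, grp, int(v.size), float(med), float(q1), float(q3)))
    return out


def summary_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    """Tidy table (variable, group, n, median, q1, q3) from summaries."""
    return pd.DataFrame(
        [
            {
                "variable": s.variable,
                "group": s.group,
                "n": s.n,
                "median": s.median,
                "q1": s.q1,
                "q3": s.q3,
            }
            for s in summaries
        ]
    )
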
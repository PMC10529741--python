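"""Accurate-mass lipid annotation with source-specific ppm limits.

Features are matched against a reference table of neutral monoisotopic
masses after adduct expansion.  Each reference entry carries a source
class setting its mass-accuracy limit: ``db30`` entries (HMDB-like) match
within 30 ppm, ``db20`` entries (LIPID MAPS-like) within 20 ppm — strict
inequality in both cases.  Hits can be upgraded from ``mass_only`` to
``mass_rt`` confidence when the feature's retention time agrees with an
authentic-standard reference RT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .features import Feature
from .reference import CLASS_TO_CATEGORY, builtin_lipid_db

logger = logging.getLogger(__name__)

__all__ = [
    "LipidDbEntry",
    "AdductRule",
    "AnnotationHit",
    "DEFAULT_ADDUCTS",
    "DEFAULT_LIMITS",
    "ppm_error",
    "expand_adducts",
    "annotate_features",
    "confirm_rt",
    "assign_category",
    "load_lipid_db",
]

#: ppm limits per reference source class.
DEFAULT_LIMITS: dict[str, float] = {"db30": 30.0, "db20": 20.0}

_PROTON = 1.007276
_NA = 22.989218
_NH4 = 18.033823
_ACETATE = 59.013851


@dataclass(frozen=True)
class AdductRule:
    """Signed mass shift applied to a neutral mass in one ionization mode."""

    name: str
    mass_shift: float
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in ("positive", "negative"):
            raise ValueError(f"unknown mode {self.mode!r}")


#: Literature-standard ESI adducts for an ammonium-acetate mobile phase.
DEFAULT_ADDUCTS: tuple[AdductRule, ...] = (
    AdductRule("[M+H]+", +_PROTON, "positive"),
    AdductRule("[M+NH4]+", +_NH4, "positive"),
    AdductRule("[M+Na]+", +_NA, "positive"),
    AdductRule("[M-H]-", -_PROTON, "negative"),
    AdductRule("[M+CH3COO]-", +_ACETATE, "negative"),
)


@dataclass(frozen=True)
class LipidDbEntry:
    """One reference lipid: shorthand name, class, neutral mass, optional RT."""

    name: str
    lipid_class: str
    neutral_mass: float
    reference_rt: float | None = None
    source: str = "db30"
    category: str | None = None

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError(f"{self.name}: neutral mass must be > 0")
        if self.source not in DEFAULT_LIMITS:
            raise ValueError(f"{self.name}: unknown source {self.source!r}")
        if self.category is None:
            object.__setattr__(self, "category", assign_category(self.lipid_class))


@dataclass(frozen=True)
class AnnotationHit:
    feature_id: str
    entry: LipidDbEntry
    adduct: AdductRule
    ppm_error: float
    rt_confirmed: bool = False

    @property
    def confidence(self) -> str:
        return "mass_rt" if self.rt_confirmed else "mass_only"


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass deviation: 1e6 · (obs − theo) / theo."""
    if observed_mz <= 0 or theoretical_mz <= 0:
        raise ValueError("m/z values must be > 0")
    return 1e6 * (observed_mz - theoretical_mz) / theoretical_mz


def expand_adducts(
    entry: LipidDbEntry,
    mode: str,
    adducts: Sequence[AdductRule] = DEFAULT_ADDUCTS,
) -> list[tuple[AdductRule, float]]:
    """Expected m/z for every adduct rule of the requested mode."""
    if mode not in ("positive", "negative"):
        raise ValueError(f"unknown ionization mode {mode!r}")
    return [(a, entry.neutral_mass + a.mass_shift) for a in adducts if a.mode == mode]


def annotate_features(
    features: Sequence[Feature],
    db: Sequence[LipidDbEntry],
    limits: Mapping[str, float] = DEFAULT_LIMITS,
    adducts: Sequence[AdductRule] = DEFAULT_ADDUCTS,
) -> tuple[list[AnnotationHit], list[str]]:
    """Match features to adducted reference masses within source ppm limits.

    A hit is emitted when |ppm error| is strictly below the limit of the
    entry's source.  Multiple hits per feature are allowed, sorted by
    |ppm error| (then name, for determinism).  Returns (hits, ids of
    features with no hit).
    """
    if not db:
        raise ValueError("empty reference database")
    hits: list[AnnotationHit] = []
    unknown: list[str] = []
    for f in features:
        feature_hits: list[AnnotationHit] = []
        for entry in db:
            limit = limits[entry.source]
            for adduct, expected in expand_adducts(entry, f.mode, adducts):
                err = ppm_error(f.mz, expected)
                if abs(err) < limit:
                    feature_hits.append(AnnotationHit(f.feature_id, entry, adduct, err))
        feature_hits.sort(key=lambda h: (abs(h.ppm_error), h.entry.name, h.adduct.name))
        if feature_hits:
            hits.extend(feature_hits)
        else:
            unknown.append(f.feature_id)
    return hits, unknown


def confirm_rt(
    hits: Iterable[AnnotationHit],
    feature_rt: Mapping[str, float],
    rt_tolerance: float = 0.2,
) -> list[AnnotationHit]:
    """Upgrade hits whose entry RT is within ``rt_tolerance`` (inclusive)
    of the feature RT; entries without a reference RT stay mass-only."""
    if rt_tolerance <= 0:
        raise ValueError("rt_tolerance must be > 0")
    out = []
    for h in hits:
        ref = h.entry.reference_rt
        rt = feature_rt.get(h.feature_id)
        if ref is not None and rt is not None and abs(rt - ref) <= rt_tolerance:
            out.append(replace(h, rt_confirmed=True))
        else:
            out.append(h)
    return out


def assign_category(lipid_class: str) -> str:
    """Map a lipid class to one of the five major categories."""
    cat = CLASS_TO_CATEGORY.get(lipid_class)
    if cat is None:
        logger.warning("lipid class %r not in the taxonomy; category set to unknown", lipid_class)
        return "unknown"
    return cat


def load_lipid_db(source: pd.DataFrame | str | None = None) -> list[LipidDbEntry]:
    """Build reference entries from a delimited table (or the bundled one).

    Expected columns: name, lipid_class, neutral_mass, and optionally
    reference_rt, source, category.
    """
    if source is None:
        df = builtin_lipid_db()
    elif isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep=None, engine="python")
    entries = []
    for row in df.itertuples(index=False):
        rt = getattr(row, "reference_rt", None)
        rt = None if rt is None or pd.isna(rt) else float(rt)
        entries.append(
            LipidDbEntry(
                name=str(row.name),
                lipid_class=str(row.lipid_class),
                neutral_mass=float(row.neutral_mass),
                reference_rt=rt,
                source=str(getattr(row, "source", "db30")),
            )
        )
    return entries
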
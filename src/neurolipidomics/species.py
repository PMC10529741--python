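"""Fatty-acyl species: canonical "C:Dn-x" labels and the default GC panel.

A species is identified by its acyl carbon number, number of double bonds,
and series (``sat`` for saturated chains, otherwise the omega position of
the first double bond: ``n-3``, ``n-6``, ``n-7`` or ``n-9``).  The default
panel is the 26 species quantified by the GC-FID profiling workflow,
spanning 14:0 through 24:6n-3.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

__all__ = ["FattyAcidSpecies", "parse_label", "DEFAULT_PANEL", "DEFAULT_PANEL_LABELS"]

_SERIES = ("sat", "n-3", "n-6", "n-7", "n-9")
_LABEL_RE = re.compile(r"^(\d{1,2}):(\d)(?:n-(\d))?$")


@dataclass(frozen=True, order=True)
class FattyAcidSpecies:
    """One fatty-acyl species, e.g. 18:1n-9 (oleic acid)."""

    carbons: int
    double_bonds: int
    series: str

    def __post_init__(self) -> None:
        if not 12 <= self.carbons <= 26:
            raise ValueError(f"implausible acyl carbon number: {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError("double_bonds must be >= 0")
        if self.series not in _SERIES:
            raise ValueError(f"unknown series {self.series!r}")
        if (self.double_bonds == 0) != (self.series == "sat"):
            raise ValueError(
                f"series {self.series!r} inconsistent with "
                f"{self.double_bonds} double bonds"
            )

    @property
    def label(self) -> str:
        """Canonical "C:Dn-x" string; saturated species omit the series."""
        if self.double_bonds == 0:
            return f"{self.carbons}:0"
        return f"{self.carbons}:{self.double_bonds}{self.series}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@lru_cache(maxsize=None)
def parse_label(label: str) -> FattyAcidSpecies:
    """Parse a "C:Dn-x" label back into a :class:`FattyAcidSpecies`.

    Round-trips with :attr:`FattyAcidSpecies.label`. Whitespace is ignored.
    """
    m = _LABEL_RE.match(label.strip().replace(" ", ""))
    if m is None:
        raise ValueError(f"cannot parse fatty-acid label {label!r}")
    carbons, dbs, omega = int(m.group(1)), int(m.group(2)), m.group(3)
    if dbs == 0:
        if omega is not None:
            raise ValueError(f"saturated species must not carry a series: {label!r}")
        return FattyAcidSpecies(carbons, 0, "sat")
    if omega is None:
        raise ValueError(f"unsaturated species needs an n-x series: {label!r}")
    return FattyAcidSpecies(carbons, dbs, f"n-{omega}")


# The 26-species GC panel, in print order (14:0 ... 24:6n-3).
DEFAULT_PANEL_LABELS: tuple[str, ...] = (
    "14:0",
    "16:0",
    "16:1n-7",
    "18:0",
    "18:1n-9",
    "18:1n-7",
    "18:2n-6",
    "18:3n-3",
    "18:4n-3",
    "20:0",
    "20:1n-9",
    "20:2n-6",
    "20:3n-3",
    "20:4n-6",
    "20:3n-6",
    "22:0",
    "20:5n-3",
    "22:1n-9",
    "22:4n-6",
    "22:5n-6",
    "22:5n-3",
    "24:0",
    "22:6n-3",
    "24:1n-9",
    "24:5n-3",
    "24:6n-3",
)

DEFAULT_PANEL: tuple[FattyAcidSpecies, ...] = tuple(
    parse_label(lbl) for lbl in DEFAULT_PANEL_LABELS
)
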
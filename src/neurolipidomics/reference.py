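"""Bundled reference data.

Two kinds of reference material live here:

* ``GM_MEDIAN_MOLPCT`` / ``WM_MEDIAN_MOLPCT`` — published median mol%
  compositions of the 26-species panel for grey matter (frontal cortex
  area 8) and white matter (centrum semi-ovale) in lesion-free middle-aged
  brains.  They serve as worked-example inputs and as the default region
  templates of the cohort simulator.

* A small constructed lipid reference table for accurate-mass annotation.
  No public accession deposits the original database snapshot, so the
  table is synthesized from the named lipid species reported in the study:
  neutral monoisotopic masses are back-calculated from reported feature
  m/z values under an assumed per-class default adduct.  It is therefore a
  synthetic, self-consistent stand-in for an HMDB / LIPID MAPS extract,
  suitable for deterministic offline tests, not an authoritative mass list.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "GROUPS",
    "STAGE_RANK",
    "GM_MEDIAN_MOLPCT",
    "WM_MEDIAN_MOLPCT",
    "REGION_TEMPLATES",
    "INDEX_VARIABLES",
    "ACTIVITY_VARIABLES",
    "REGION_CONTRAST_VARIABLES",
    "CLASS_TO_CATEGORY",
    "builtin_lipid_db",
]

#: Stage groups in pathological order and their ordinal coding.
GROUPS: tuple[str, ...] = ("MA", "AD I-II", "AD III-IV", "AD V-VI")
STAGE_RANK: dict[str, int] = {g: i for i, g in enumerate(GROUPS)}

# Median mol% composition of the grey-matter panel (middle-aged controls).
GM_MEDIAN_MOLPCT: dict[str, float] = {
    "14:0": 2.51,
    "16:0": 26.0,
    "16:1n-7": 1.54,
    "18:0": 25.0,
    "18:1n-9": 20.0,
    "18:1n-7": 4.92,
    "18:2n-6": 0.96,
    "18:3n-3": 0.12,
    "18:4n-3": 1.48,
    "20:0": 0.29,
    "20:1n-9": 1.22,
    "20:2n-6": 0.48,
    "20:3n-3": 0.59,
    "20:4n-6": 4.54,
    "20:3n-6": 0.36,
    "22:0": 0.23,
    "20:5n-3": 0.87,
    "22:1n-9": 0.11,
    "22:4n-6": 2.20,
    "22:5n-6": 0.55,
    "22:5n-3": 0.28,
    "24:0": 0.40,
    "22:6n-3": 2.90,
    "24:1n-9": 0.75,
    "24:5n-3": 1.51,
    "24:6n-3": 0.14,
}

# Median mol% composition of the white-matter panel (middle-aged controls).
WM_MEDIAN_MOLPCT: dict[str, float] = {
    "14:0": 2.26,
    "16:0": 14.9,
    "16:1n-7": 2.88,
    "18:0": 21.6,
    "18:1n-9": 32.6,
    "18:1n-7": 5.31,
    "18:2n-6": 0.26,
    "18:3n-3": 0.10,
    "18:4n-3": 0.43,
    "20:0": 0.28,
    "20:1n-9": 3.76,
    "20:2n-6": 1.03,
    "20:3n-3": 0.68,
    "20:4n-6": 2.90,
    "20:3n-6": 0.25,
    "22:0": 0.07,
    "20:5n-3": 0.48,
    "22:1n-9": 0.19,
    "22:4n-6": 3.29,
    "22:5n-6": 0.28,
    "22:5n-3": 0.09,
    "24:0": 1.01,
    "22:6n-3": 0.71,
    "24:1n-9": 3.08,
    "24:5n-3": 0.68,
    "24:6n-3": 0.50,
}

REGION_TEMPLATES: dict[str, dict[str, float]] = {
    "GM": GM_MEDIAN_MOLPCT,
    "WM": WM_MEDIAN_MOLPCT,
}

#: Derived membrane indices, in report order.
INDEX_VARIABLES: tuple[str, ...] = (
    "SFA",
    "UFA",
    "PUFA",
    "MUFA",
    "PUFAn-3",
    "PUFAn-6",
    "ACL",
    "DBI",
    "PI (a)",
    "PI (b)",
)

#: Estimated enzyme activities (product/substrate ratios), in report order.
ACTIVITY_VARIABLES: tuple[str, ...] = (
    "Δ9(n-7)",
    "Δ9(n-9)",
    "Δ5(n-6)",
    "Δ6(n-3) (a)",
    "Δ6(n-3) (b)",
    "Elovl3(n-9)",
    "Elovl6",
    "Elovl1-3-7a",
    "Elovl1-3-7b",
    "Elovl1-3-7c",
    "Elovl5(n-6)",
    "Elovl2-5(n-6)",
    "Elovl2-5(n-3)",
    "Elovl2(n-3)",
    "Perox β-ox",
)


def _region_contrast_variables() -> tuple[str, ...]:
    from .species import DEFAULT_PANEL_LABELS

    return DEFAULT_PANEL_LABELS + INDEX_VARIABLES + ACTIVITY_VARIABLES


#: The 51-member variable family of the region-contrast report
#: (26 species + 10 indices + 15 activity ratios).
REGION_CONTRAST_VARIABLES: tuple[str, ...] = _region_contrast_variables()

#: Fixed five-category taxonomy of lipid classes.
CLASS_TO_CATEGORY: dict[str, str] = {
    # Glycerolipids
    "DG": "Glycerolipids",
    "TG": "Glycerolipids",
    "MG": "Glycerolipids",
    # Glycerophospholipids
    "PC": "Glycerophospholipids",
    "LPC": "Glycerophospholipids",
    "PE": "Glycerophospholipids",
    "LPE": "Glycerophospholipids",
    "PG": "Glycerophospholipids",
    "PS": "Glycerophospholipids",
    "PA": "Glycerophospholipids",
    "PI": "Glycerophospholipids",
    "CL": "Glycerophospholipids",
    "oxPE": "Glycerophospholipids",
    "PE-Nme": "Glycerophospholipids",
    "PE-Nme2": "Glycerophospholipids",
    "phosphorylcholine": "Glycerophospholipids",
    # Sphingolipids
    "Cer": "Sphingolipids",
    "CerP": "Sphingolipids",
    "OxCer": "Sphingolipids",
    "HexCer": "Sphingolipids",
    "SM": "Sphingolipids",
    "sulfatide": "Sphingolipids",
    # Sterol lipids
    "CE": "Sterol Lipids",
    # Fatty acyls
    "FAHFA": "Fatty Acyls",
    "acyl-CoA": "Fatty Acyls",
    "acylcarnitine": "Fatty Acyls",
}

_PROTON = 1.007276

# Classes ionized (by default) in negative mode; everything else positive.
_NEGATIVE_CLASSES = {
    "FAHFA",
    "PE",
    "LPE",
    "oxPE",
    "PE-Nme",
    "PE-Nme2",
    "PS",
    "PI",
    "PG",
    "PA",
    "CL",
    "sulfatide",
}

# (name, lipid_class, reported m/z, reported RT [min], source limit class)
# Reported identifications from both regions, deduplicated by name.
_DB_ROWS: tuple[tuple[str, str, float, float, str], ...] = (
    ("FAHFA(24:3)", "FAHFA", 391.2854, 3.66, "db20"),
    ("FAHFA(26:5)", "FAHFA", 415.3025, 3.75, "db20"),
    ("FAHFA(20:0)", "FAHFA", 341.2656, 0.93, "db20"),
    ("FAHFA(23:0)", "FAHFA", 383.2761, 0.93, "db20"),
    ("FAHFA(23:3)", "FAHFA", 377.2691, 3.68, "db20"),
    ("FAHFA(38:6)", "FAHFA", 581.4277, 6.74, "db20"),
    ("Retinoyl-CoA", "acyl-CoA", 1072.3095, 7.62, "db30"),
    ("Clupanodonyl carnitine", "acylcarnitine", 512.3154, 7.46, "db30"),
    ("DG(34:1)", "DG", 577.5203, 7.22, "db30"),
    ("DG(34:3)", "DG", 591.4963, 8.10, "db30"),
    ("DG(38:1)", "DG", 668.6557, 8.44, "db20"),
    ("DG(38:5)", "DG", 625.5211, 6.85, "db30"),
    ("DG(40:4)", "DG", 655.5657, 6.77, "db30"),
    ("DG(44:4)", "DG", 746.7144, 7.16, "db20"),
    ("MG(13:0)", "MG", 269.2096, 0.92, "db30"),
    ("MG(16:1)", "MG", 346.3320, 2.60, "db20"),
    ("MG(18:1)", "MG", 374.3633, 3.55, "db20"),
    ("TG(40:1)", "TG", 710.5937, 9.24, "db20"),
    ("TG(44:3)", "TG", 743.5977, 7.92, "db30"),
    ("TG(46:1)", "TG", 794.6884, 8.42, "db20"),
    ("TG(48:0)", "TG", 824.7713, 10.14, "db20"),
    ("TG(50:0)", "TG", 852.8003, 10.31, "db20"),
    ("TG(52:1)", "TG", 883.7737, 10.33, "db20"),
    ("TG(54:4)", "TG", 900.8038, 10.03, "db20"),
    ("PC(P-41:4)", "PC", 880.6352, 7.91, "db20"),
    ("PC(O-42:2)", "PC", 820.7033, 7.30, "db20"),
    ("PC(40:5)", "PC", 836.6162, 7.50, "db20"),
    ("PC(P-32:1)", "PC", 760.5204, 7.25, "db20"),
    ("PC(O-44:6)", "PC", 858.6796, 8.13, "db20"),
    ("PC(O-41:4)", "PC", 882.6903, 8.38, "db20"),
    ("PC(P-42:1)", "PC", 856.6781, 8.88, "db20"),
    ("PC(34:3)", "PC", 756.5556, 6.69, "db20"),
    ("PC(42:8)", "PC", 858.6028, 6.85, "db20"),
    ("PC(44:4)", "PC", 894.6818, 8.66, "db20"),
    ("LPC(18:0)", "LPC", 546.4002, 0.92, "db20"),
    ("PE(34:1)", "PE", 718.5720, 7.32, "db20"),
    ("PE-Nme(36:2)", "PE-Nme", 756.5448, 7.51, "db30"),
    ("PE(P-38:3)", "PE", 752.5430, 6.26, "db20"),
    ("PE(P-38:4)", "PE", 752.5611, 7.49, "db20"),
    ("PE(P-40:4)", "PE", 780.5926, 7.87, "db20"),
    ("PE(P-42:0)", "PE", 796.6574, 8.07, "db30"),
    ("PE(P-38:2)", "PE", 754.6103, 7.65, "db20"),
    ("oxPE(16:2)", "oxPE", 506.2240, 2.68, "db30"),
    ("PE(29:0)", "PE", 650.4968, 4.41, "db20"),
    ("PE(44:0)", "PE", 894.6527, 8.13, "db30"),
    ("PE-Nme2(44:8)", "PE-Nme2", 872.6015, 8.04, "db30"),
    ("LPE(20:1)", "LPE", 508.3410, 0.92, "db20"),
    ("PG(37:0)", "PG", 827.5506, 7.31, "db30"),
    ("CL(72:5)", "CL", 726.5268, 6.18, "db30"),
    ("PI(34:1)", "PI", 835.5253, 6.11, "db20"),
    ("PI(40:6)", "PI", 909.5395, 6.16, "db30"),
    ("PS(36:0)", "PS", 792.5941, 7.77, "db20"),
    ("PS(40:3)", "PS", 864.5726, 7.42, "db20"),
    ("PS(40:4)", "PS", 840.5738, 6.79, "db20"),
    ("PS(40:5)", "PS", 838.5583, 6.69, "db20"),
    ("PS(42:4)", "PS", 902.5922, 6.51, "db30"),
    ("Phosphorylcholine", "phosphorylcholine", 184.0729, 8.35, "db30"),
    ("Sulfatide(43:0)", "sulfatide", 906.6894, 8.60, "db20"),
    ("Sulfatide(39:4)", "sulfatide", 842.5798, 7.18, "db20"),
    ("Cer(d41:2)", "Cer", 634.6150, 8.13, "db20"),
    ("Cer(d48:2)", "Cer", 746.7042, 7.18, "db20"),
    ("Cer(d17:2)", "Cer", 438.4316, 6.64, "db30"),
    ("Cer(d28:2)", "Cer", 496.4319, 6.63, "db30"),
    ("Cer(d40:0)", "Cer", 624.6296, 8.19, "db20"),
    ("Cer(d42:1)", "Cer", 632.6325, 8.44, "db20"),
    ("OxCer(40:1)", "OxCer", 644.5988, 7.61, "db20"),
    ("Cer(d44:1)", "Cer", 660.6653, 9.18, "db20"),
    ("HexCer(d36:1)", "HexCer", 872.6422, 6.92, "db30"),
    ("HexCer(d40:1)", "HexCer", 766.6576, 8.05, "db20"),
    ("HexCer(d40:2)", "HexCer", 782.6517, 7.92, "db20"),
    ("HexCer(d40:3)", "HexCer", 780.6729, 8.24, "db20"),
    ("HexCer(d41:2)", "HexCer", 796.6687, 8.13, "db20"),
    ("HexCer(d42:3)", "HexCer", 808.7043, 8.58, "db20"),
    ("HexCer(d43:1)", "HexCer", 824.6892, 8.60, "db30"),
    ("HexCer(d43:2)", "HexCer", 824.7002, 8.49, "db20"),
    ("HexCer(t43:1)", "HexCer", 856.6795, 8.43, "db20"),
    ("SM(d28:5)", "SM", 655.4136, 6.22, "db30"),
    ("SM(d35:1)", "SM", 715.5661, 7.32, "db30"),
    ("CE(18:1)", "CE", 633.5821, 8.83, "db30"),
)


def builtin_lipid_db() -> pd.DataFrame:
    """Return the bundled (synthetic) lipid reference table.

    Columns: ``name, category, lipid_class, neutral_mass, reference_rt,
    source``.  Neutral masses are derived from reported feature m/z values
    assuming [M+H]+ for classes ionized in positive mode and [M−H]− for
    the acidic classes, so round-trip annotation under the same adduct
    rules is exact by construction.
    """
    rows = []
    for name, cls, mz, rt, source in _DB_ROWS:
        if cls in _NEGATIVE_CLASSES:
            neutral = mz + _PROTON
        else:
            neutral = mz - _PROTON
        rows.append(
            {
                "name": name,
                "category": CLASS_TO_CATEGORY.get(cls, "unknown"),
                "lipid_class": cls,
                "neutral_mass": round(neutral, 4),
                "reference_rt": rt,
                "source": source,
            }
        )
    return pd.DataFrame(rows)
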
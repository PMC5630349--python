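"""The 90-region anatomical parcellation used to define network nodes.

The cerebrum is divided into 45 bilateral regions (90 ROIs); odd
indices are left-hemisphere, even indices right-hemisphere, 1-based, in
the conventional atlas order. Any other label table with contiguous
1-based indices and unique abbreviations can be supplied instead.
"""

from __future__ import annotations

import pandas as pd

from fconn.errors import ValidationError

__all__ = ["aal90_table", "validate_region_table"]

# (name, abbreviation) for the 45 bilateral regions, atlas order.
_AAL45: tuple[tuple[str, str], ...] = (
    ("Precentral gyrus", "PreCG"),
    ("Superior frontal gyrus", "SFGdor"),
    ("Superior frontal gyrus, orbital", "ORBsup"),
    ("Middle frontal gyrus", "MFG"),
    ("Middle frontal gyrus, orbital", "ORBmid"),
    ("Inferior frontal gyrus, opercular part", "IFGoperc"),
    ("Inferior frontal gyrus, triangular part", "IFGtri"),
    ("Inferior frontal gyrus, orbital", "IFGorb"),
    ("Rolandic operculum", "ROL"),
    ("Supplementary motor area", "SMA"),
    ("Olfactory cortex", "OLF"),
    ("Superior frontal gyrus, medial", "mSFG"),
    ("Superior frontal gyrus, medial orbital", "ORBsupmed"),
    ("Gyrus rectus", "REC"),
    ("Insula", "INS"),
    ("Anterior cingulate gyri", "ACC"),
    ("Median cingulate gyri", "DCG"),
    ("Posterior cingulate gyrus", "PCC"),
    ("Hippocampus", "HIP"),
    ("Parahippocampal gyrus", "PHG"),
    ("Amygdala", "AMYG"),
    ("Calcarine fissure", "CAL"),
    ("Cuneus", "CUN"),
    ("Lingual gyrus", "LING"),
    ("Superior occipital gyrus", "SOG"),
    ("Middle occipital gyrus", "MOG"),
    ("Inferior occipital gyrus", "IOG"),
    ("Fusiform gyrus", "FFG"),
    ("Postcentral gyrus", "PoCG"),
    ("Superior parietal gyrus", "SPG"),
    ("Inferior parietal gyrus", "IPL"),
    ("Supramarginal gyrus", "SMG"),
    ("Angular gyrus", "ANG"),
    ("Precuneus", "PCUN"),
    ("Paracentral lobule", "PCL"),
    ("Caudate nucleus", "CAU"),
    ("Putamen", "PUT"),
    ("Pallidum", "PAL"),
    ("Thalamus", "THA"),
    ("Heschl gyrus", "HES"),
    ("Superior temporal gyrus", "STG"),
    ("Superior temporal gyrus: temporal pole", "TPOsup"),
    ("Middle temporal gyrus", "MTG"),
    ("Middle temporal gyrus: temporal pole", "TPOmid"),
    ("Inferior temporal gyrus", "ITG"),
)


def aal90_table() -> pd.DataFrame:
    """The default 90-node region table.

    Columns: ``index`` (1-based), ``name``, ``abbreviation``
    (e.g. ``PCC.L``), ``hemisphere`` (``L``/``R``).
    """
    rows = []
    for i, (name, abbrev) in enumerate(_AAL45):
        for offset, hemi in ((1, "L"), (2, "R")):
            rows.append(
                {
                    "index": 2 * i + offset,
                    "name": name,
                    "abbreviation": f"{abbrev}.{hemi}",
                    "hemisphere": hemi,
                }
            )
    return pd.DataFrame(rows)


def validate_region_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check contiguous 1-based indices and unique abbreviations."""
    required = {"index", "name", "abbreviation", "hemisphere"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"region table missing columns {sorted(missing)}")
    idx = sorted(table["index"].tolist())
    if idx != list(range(1, len(table) + 1)):
        raise ValidationError("region indices must be contiguous and 1-based")
    if table["abbreviation"].duplicated().any():
        dupes = table.loc[table["abbreviation"].duplicated(), "abbreviation"]
        raise ValidationError(f"duplicate abbreviations: {sorted(set(dupes))}")
    return table.sort_values("index").reset_index(drop=True)
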
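"""Metadata for the GFP nucleocytoplasmic-transport biosensor panel.

Each biosensor is GFP fused to a nuclear localization signal (NLS) of a
given class and a nuclear export signal (NES); the importin/exportin
recognizing each motif determines which transport pathway the sensor
reports on. The panel covers classical (mono/bipartite cNLS), PY-NLS,
RS-NLS and several non-classical import pathways, plus one mRNA-export
sensor (NCT-A) whose NES is handled by the Aly/REF adapter rather than
XPO1. These records are used only to label simulated conditions; no
sequence analysis is performed on them.
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = [
    "name",
    "nls_type",
    "nls_sequence",
    "importin",
    "nes_type",
    "nes_sequence",
    "exportin",
]

_CNES = "KEVDQLRLERLQIDEQL"

_PANEL = [
    ("NCT-C", "cNLS", "PKKKRKV", "KNPA1-KPNB1", "cNES", _CNES, "XPO1"),
    ("NCT-01", "cNLS R5A mutant", "PKKKAKV", "KNPA1-KPNB1", "cNES", _CNES, "XPO1"),
    ("NCT-02", "cNLS K6A mutant", "PKKKRAVE", "KNPA1-KPNB1", "cNES", _CNES, "XPO1"),
    ("NCT-03", "cNLS (bipartite)", "KRPAATKKAGQAKKKK", "KNPA1-KPNB1", "cNES", _CNES, "XPO1"),
    ("NCT-04", "Non-classical NLS", "GKISKHWTG", "KNPA1-KPNB1", "cNES", _CNES, "XPO1"),
    ("NCT-05", "IB1-NLS", "RRKKKEYVK", "KNPB1", "cNES", _CNES, "XPO1"),
    ("NCT-06", "IB1-NLS", "RKKRRQRRR", "KNPB1", "cNES", _CNES, "XPO1"),
    ("NCT-07", "PY-NLS (basic, M9)", "FGNYNNQSSNFGPMKGGNFGGRSSGPY", "KNPB2", "cNES", _CNES, "XPO1"),
    ("NCT-08", "PY-NLS (hydrophobic)", "YGDYSNQQSGYGKVSRRGGHQNSYKPY", "KNPB2", "cNES", _CNES, "XPO1"),
    ("NCT-09", "PY-NLS (atypical)", "GPGKMDSRGEHRQDRR-ERPY", "KNPB2", "cNES", _CNES, "XPO1"),
    ("NCT-10", "I4-NLS", "GKVSKRKAV", "IPO4", "cNES", _CNES, "XPO1"),
    ("NCT-11", "I5-NLS", "HTPQRVLPLKKPPMKSLRKKGSGKILTPAKKSFL", "IPO5", "cNES", _CNES, "XPO1"),
    ("NCT-13", "RS-NLS (RD mimic)", "RDPSYG(RD)8NDRDRDYSPRRDRGSPRYSPRHDRDRDRT", "TNPO3", "cNES", _CNES, "XPO1"),
    ("NCT-14", "Homeodomain-NLS", "RKLQRNRTSFTQEQIEALEKEFERTHYPDVFARERLAAKIDLPEARIQVWFSNRRAKWRREE", "IPO13", "cNES", _CNES, "XPO1"),
    ("NCT-15", "cNLS (monopartite)", "PKKKRKV", "KNPA1-KPNB1", "cNES", _CNES, "XPO1"),
    ("NCT-A", "cNLS", "PKKKRKV", "KNPA1-KPNB1", "NXF1-NXT1 mRNA", "APPAQPPSQPQQHYSEGELEEDEDSDDA", "ALYREF Adapter"),
]


def biosensor_table() -> pd.DataFrame:
    """Return the biosensor panel as a DataFrame (one row per sensor)."""
    return pd.DataFrame(_PANEL, columns=_COLUMNS)


def get_biosensor(name: str) -> dict:
    """Look up one biosensor record by name (e.g. ``"NCT-C"``)."""
    for row in _PANEL:
        if row[0] == name:
            return dict(zip(_COLUMNS, row))
    raise KeyError(f"unknown biosensor: {name!r}")
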
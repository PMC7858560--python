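"""Bundled case-study tables.

A Caucasus floristic-survey barcoding case study ships with the package:
amplification/sequencing status for 36 orchid and 38 asterid samples
across three barcode markers (nuclear ITS and plastid rpoB, accD),
best-match identification outcomes against a public reference database,
and NJ-tree (monophyly) resolution outcomes. These tables drive the
report examples and regression checks without any download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .seqio import StatusTable, read_status_table

GROUPS = ("orchid", "asterid")
MARKERS = ("ITS", "rpoB", "accD")


def _path(name: str):
    return resources.files("plantbarcode.data") / name


def load_status(group: str) -> StatusTable:
    """Amplification/sequencing status table for 'orchid' or 'asterid' samples."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    with resources.as_file(_path(f"{group}_status.tsv")) as p:
        return read_status_table(p)


def load_blast_outcomes(group: str) -> pd.DataFrame:
    """Best-match identification outcomes (CORRECT / AMBIGUOUS_TOP / BELOW_THRESHOLD)."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    with resources.as_file(_path(f"{group}_blast_outcomes.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype=str).fillna("")


def load_tree_resolution(group: str) -> pd.DataFrame:
    """NJ-tree monophyly resolution outcomes (SPECIES / GENUS_ONLY / UNRESOLVED)."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    with resources.as_file(_path(f"{group}_tree_resolution.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype=str).fillna("")
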
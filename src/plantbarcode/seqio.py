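"""Sequence, metadata and tree I/O.

Reads FASTA sequence sets, tab-separated sample-metadata tables and
amplification/sequencing status tables, and writes/reads Newick trees.
All loaders validate their invariants at load time so downstream stages
can assume clean inputs.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO as _BioSeqIO

UNKNOWN = "UNKNOWN"

#: Characters accepted in sequences by default.
_STRICT_ALPHABET = set("ACGTN-")
#: Full IUPAC nucleotide ambiguity alphabet (maskable to N).
_IUPAC_ALPHABET = _STRICT_ALPHABET | set("RYSWKMBDHV")


class Source(str, Enum):
    """Provenance of a sample: field-collected, herbarium voucher, or reference accession."""

    FRESH = "fresh"
    HERBARIUM = "herbarium"
    REFERENCE = "reference"


@dataclass
class SeqRecordSet:
    """A set of labelled nucleotide sequences, optionally on a common coordinate frame.

    ``aligned`` is True iff all sequences have equal length; distance
    computations require an aligned set.
    """

    records: list[tuple[str, str]]
    aligned: bool = field(default=False)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate sequence id: {dup!r}")
        if any(not i for i in ids):
            raise ValueError("empty sequence id")
        lengths = {len(r[1]) for r in self.records}
        self.aligned = len(lengths) == 1 and (not lengths or min(lengths) >= 1)
        if not self.records:
            self.aligned = False

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r[1] for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, seq_id: str) -> str:
        for i, s in self.records:
            if i == seq_id:
                return s
        raise KeyError(seq_id)

    def subset(self, keep: Iterable[str]) -> "SeqRecordSet":
        keep = set(keep)
        return SeqRecordSet([r for r in self.records if r[0] in keep])


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    species: str = UNKNOWN
    genus: str = UNKNOWN
    region: str = UNKNOWN
    source: Source = Source.FRESH

    def __post_init__(self) -> None:
        if self.species != UNKNOWN and self.genus == UNKNOWN:
            # genus is derivable as the first epithet of a known binomial
            object.__setattr__(self, "genus", self.species.split()[0])


@dataclass
class StatusTable:
    """Per-sample, per-marker amplification/sequencing outcomes."""

    rows: list[tuple[str, str, bool, bool]]

    def __post_init__(self) -> None:
        for sample_id, marker, amplified, sequenced in self.rows:
            if sequenced and not amplified:
                raise ValueError(
                    f"sample {sample_id!r} marker {marker!r}: sequenced without amplification"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["sample_id", "marker", "amplified", "sequenced"]
        )


def _validate_sequence(seq_id: str, seq: str, mask_ambiguous: bool) -> str:
    seq = seq.upper()
    allowed = _IUPAC_ALPHABET if mask_ambiguous else _STRICT_ALPHABET
    for pos, ch in enumerate(seq):
        if ch not in allowed:
            raise ValueError(
                f"non-IUPAC character {ch!r} in sequence {seq_id!r} at position {pos + 1}"
            )
    if mask_ambiguous:
        seq = re.sub(r"[RYSWKMBDHV]", "N", seq)
    return seq


def read_fasta(path: str | Path, *, mask_ambiguous: bool = False) -> SeqRecordSet:
    """Read a FASTA file into a :class:`SeqRecordSet`.

    Sequences are uppercased; the ``aligned`` flag is set iff all sequences
    share one length. Duplicate ids, empty files and characters outside
    {A,C,G,T,N,-} are hard errors; with ``mask_ambiguous=True`` the other
    IUPAC ambiguity codes are accepted and masked to N.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id: {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, _validate_sequence(rec.id, str(rec.seq), mask_ambiguous)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return SeqRecordSet(records)


def write_fasta(seqs: SeqRecordSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in seqs.records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read a sample-metadata TSV (sample_id, species, genus, region, source).

    Missing species/genus/region become UNKNOWN. Duplicate sample ids and
    unrecognised source values are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "species", "genus", "region", "source"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id in metadata: {dup!r}")
    out = []
    for _, row in df.iterrows():
        src = row["source"].strip().lower()
        try:
            source = Source(src)
        except ValueError:
            raise ValueError(f"unknown source value {row['source']!r} for {row['sample_id']!r}")
        out.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                species=row["species"].strip() or UNKNOWN,
                genus=row["genus"].strip() or UNKNOWN,
                region=row["region"].strip() or UNKNOWN,
                source=source,
            )
        )
    return out


def write_metadata(meta: Sequence[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame(
        [(m.sample_id, m.species, m.genus, m.region, m.source.value) for m in meta],
        columns=["sample_id", "species", "genus", "region", "source"],
    ).to_csv(path, sep="\t", index=False)


_BOOL_TOKENS = {"x": True, "true": True, "1": True, "no": False, "false": False, "0": False}


def _parse_bool(token: str, context: str) -> bool:
    try:
        return _BOOL_TOKENS[token.strip().lower()]
    except KeyError:
        raise ValueError(f"cannot parse boolean token {token!r} in {context}")


def read_status_table(path: str | Path) -> StatusTable:
    """Read an amplification/sequencing status TSV.

    Columns: sample_id, marker, amplified, sequenced. Booleans may be given
    as the survey-table dialect x/NO or as true/false. A row with
    sequenced=true but amplified=false violates the table invariant and is
    a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "marker", "amplified", "sequenced"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"status table missing columns: {sorted(missing)}")
    rows = []
    for _, row in df.iterrows():
        ctx = f"status row {row['sample_id']}/{row['marker']}"
        rows.append(
            (
                row["sample_id"],
                row["marker"],
                _parse_bool(row["amplified"], ctx),
                _parse_bool(row["sequenced"], ctx),
            )
        )
    return StatusTable(rows)


# ---------------------------------------------------------------------------
# Newick


def _escape_label(label: str, dialect: str) -> str:
    if dialect == "underscore":
        label = label.replace(" ", "_")
        if re.search(r"[():,;\[\]']", label):
            return "'" + label.replace("'", "''") + "'"
        return label
    # quoted dialect
    if re.search(r"[():,;\[\]'\s]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree, path: str | Path | None = None, *, dialect: str = "underscore") -> str:
    """Serialise a :class:`~plantbarcode.njtree.PhyloTree` as Newick.

    Branch lengths are printed with 6 decimal places. Labels containing
    spaces are underscored by default (``dialect='quoted'`` quotes them
    instead). Returns the Newick string; writes it to ``path`` if given.
    """
    text = tree.to_newick(label_fn=lambda s: _escape_label(s, dialect))
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def read_newick(source: str | Path):
    """Parse a Newick tree (file path or string) into a PhyloTree.

    Underscores in unquoted labels are restored to spaces, matching the
    default write dialect.
    """
    import dendropy

    from .njtree import PhyloTree

    if isinstance(source, Path):
        text = source.read_text()
    else:
        text = str(source)
        if "(" not in text:  # a path, not Newick data
            text = Path(text).read_text()
    dtree = dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=False, suppress_internal_node_taxa=True
    )
    tree = PhyloTree()
    counter = iter(range(10**9))

    def visit(node) -> str | int:
        if node.is_leaf():
            return node.taxon.label
        return next(counter)

    node_ids: dict = {}
    for node in dtree.preorder_node_iter():
        node_ids[node] = visit(node)
        tree._ensure_node(node_ids[node])
        if node.parent_node is not None:
            length = node.edge.length if node.edge.length is not None else 0.0
            tree.add_edge(node_ids[node.parent_node], node_ids[node], float(length))
    tree._suppress_degree_two()
    return tree
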
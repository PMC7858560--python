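"""Synthetic multi-species barcode datasets with known ground truth.

Emulates the statistical structure barcode-marker evaluation assumes: a
Yule species tree whose pendant (stem) branches are scaled to a chosen
interspecific divergence, star-shaped intraspecific radiations at a
chosen within-species divergence, i.i.d. site evolution under TN93, and
the two classic failure modes — haplotypes shared across species and
species missing from the reference library. Sequences are emitted
pre-aligned (no indel process) by default; an optional geometric indel
mask exercises pairwise-deletion code paths. Identical config + seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .distmodel import _TN93Spectral
from .seqio import SeqRecordSet, StatusTable

_BASES = np.array(list("ACGT"))

REGIONS = ("Europe", "Asia")


@dataclass
class SimConfig:
    """Generator knobs; defaults emulate a well-separated ("gap") regime.

    d_intra is the branch length (substitutions/site) from the species
    ancestor to each accession, so two conspecific accessions diverge by
    2*d_intra in expectation; d_inter is the species stem-branch length.
    The defaults (0.00025 / 0.00625, ratio 25 on an 800-nt marker) give
    conspecifics a fraction of a substitution and distinct species about
    ten — a clean barcoding gap; the recent-radiation regime is
    d_inter = d_intra. ``region_structure``: 'sorted' makes the two
    within-species subclades coincide with the two regions, 'mixed'
    assigns regions at random, 'none' uses a single region.
    """

    n_species: int = 10
    n_per_species: int | Sequence[int] = 4
    seq_length: int = 800
    d_intra: float = 0.00025
    d_inter: float = 0.00625
    base_freqs: tuple = (0.26, 0.24, 0.23, 0.27)
    kappa1: float = 4.0
    kappa2: float = 2.0
    shared_haplotype_groups: list = field(default_factory=list)
    missing_reference_species: set = field(default_factory=set)
    region_structure: str = "none"
    species_per_genus: int = 1
    indel_rate: float = 0.0
    indel_mean_length: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_intra < 0 or self.d_inter < 0:
            raise ValueError("divergences must be non-negative")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1")
        if self.region_structure not in ("sorted", "mixed", "none"):
            raise ValueError(f"unknown region_structure {self.region_structure!r}")

    def counts(self) -> list[int]:
        if isinstance(self.n_per_species, int):
            return [self.n_per_species] * self.n_species
        if len(self.n_per_species) != self.n_species:
            raise ValueError("per-species counts list length must equal n_species")
        return list(self.n_per_species)

    def species_names(self) -> list[str]:
        names = []
        for i in range(self.n_species):
            g = i // max(self.species_per_genus, 1) + 1
            names.append(f"Genus{g:02d} species{i + 1:02d}")
        return names

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["missing_reference_species"] = sorted(self.missing_reference_species)
        d["shared_haplotype_groups"] = [sorted(g) for g in self.shared_haplotype_groups]
        return d


def _yule_species_depths(n: int, rng: np.random.Generator) -> tuple[list, np.ndarray]:
    """Pure-birth genealogy over n species tips.

    Returns (edges as (parent, child, length), node times) on an arbitrary
    time scale; node 0 is the root. Tips are nodes [n_internal..].
    """
    # forward simulation: start with one lineage, split at rate 1 per lineage
    edges = []
    birth = {0: 0.0}
    active = [0]
    next_id = 1
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / k)
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        for _ in range(2):
            birth[next_id] = t
            edges.append((parent, next_id))
            active.append(next_id)
            next_id += 1
    # surviving lineages extend one further expected waiting time past the last split
    t_end = t + rng.exponential(1.0 / max(len(active), 1))
    tips = list(active)
    split_time: dict[int, float] = {}
    for parent, child in edges:
        split_time.setdefault(parent, birth[child])
    out = [
        (parent, child, split_time.get(child, t_end) - birth[child])
        for parent, child in edges
    ]
    return out, tips


def _evolve(seq: np.ndarray, P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Evolve an encoded sequence one branch: child[i] ~ Categorical(P[parent[i]])."""
    u = rng.random(seq.size)
    cdf = P.cumsum(axis=1)
    return (u[:, None] > cdf[seq]).sum(axis=1).astype(np.int8)


def simulate_dataset(cfg: SimConfig) -> tuple[SeqRecordSet, pd.DataFrame]:
    """Generate an aligned dataset and its truth table.

    The truth table has one row per sequence: seq_id, species, genus,
    region, clade (the within-species subclade index) and
    in_reference_library (False for species configured as missing from
    the library).
    """
    rng = np.random.default_rng(cfg.seed)
    names = cfg.species_names()
    counts = cfg.counts()
    known = set(names)
    for group in cfg.shared_haplotype_groups:
        bad = set(group) - known
        if bad:
            raise ValueError(f"shared haplotype group references absent species: {sorted(bad)}")
    bad = set(cfg.missing_reference_species) - known
    if bad:
        raise ValueError(f"missing_reference_species not in dataset: {sorted(bad)}")

    spec = _TN93Spectral(cfg.base_freqs, cfg.kappa1, cfg.kappa2)
    pi = spec.pi

    # species genealogy: Yule topology with internal branches rescaled to the
    # d_inter scale and every species stem (tip branch) set to d_inter, so the
    # regime contrast d_inter vs d_intra is structural, not a draw of the tree
    edges, tips = _yule_species_depths(cfg.n_species, rng)
    tip_lengths = [l for _, c, l in edges if c in tips]
    mean_tip = float(np.mean(tip_lengths)) if tip_lengths else 1.0
    scale = cfg.d_inter / mean_tip if mean_tip > 0 and cfg.d_inter > 0 else 0.0
    children: dict[int, list] = {}
    lengths: dict[int, float] = {}
    for parent, child, length in edges:
        children.setdefault(parent, []).append(child)
        lengths[child] = cfg.d_inter if child in tips else length * scale

    root_seq = rng.choice(4, size=cfg.seq_length, p=pi).astype(np.int8)
    node_seq: dict[int, np.ndarray] = {0: root_seq}
    order = [0]
    while order:
        node = order.pop()
        for ch in children.get(node, []):
            node_seq[ch] = _evolve(node_seq[node], spec.transition_matrix(lengths[ch]), rng)
            order.append(ch)

    records: list[tuple[str, str]] = []
    rows = []
    for sp_idx, (tip, name, n_acc) in enumerate(zip(sorted(tips), names, counts)):
        ancestor = node_seq[tip]
        structured = cfg.region_structure in ("sorted", "mixed") and n_acc >= 2
        if structured:
            # two within-species subclades separated by d_intra, short pendants
            sub_anc = [
                _evolve(ancestor, spec.transition_matrix(cfg.d_intra / 2.0), rng)
                for _ in range(2)
            ]
            pendant = spec.transition_matrix(cfg.d_intra / 5.0)
        for k in range(n_acc):
            clade = k % 2 if structured else 0
            if structured:
                seq = _evolve(sub_anc[clade], pendant, rng)
            else:
                seq = _evolve(ancestor, spec.transition_matrix(cfg.d_intra), rng)
            if cfg.region_structure == "sorted":
                region = REGIONS[clade]
            elif cfg.region_structure == "mixed":
                region = REGIONS[rng.integers(2)]
            else:
                region = REGIONS[0]
            seq_id = f"S{sp_idx + 1:02d}A{k + 1:02d}"
            records.append((seq_id, "".join(_BASES[seq])))
            rows.append(
                (
                    seq_id,
                    name,
                    name.split()[0],
                    region,
                    clade,
                    name not in cfg.missing_reference_species,
                )
            )
    truth = pd.DataFrame(
        rows,
        columns=["seq_id", "species", "genus", "region", "clade", "in_reference_library"],
    )

    # shared haplotypes: every accession of each listed group collapses onto the
    # haplotype of the group's alphabetically first species' first accession
    seq_by_id = dict(records)
    for group in cfg.shared_haplotype_groups:
        members = sorted(group)
        donor_rows = truth[truth["species"] == members[0]]
        donor = seq_by_id[donor_rows["seq_id"].iloc[0]]
        for sp in members:
            for sid in truth.loc[truth["species"] == sp, "seq_id"]:
                seq_by_id[sid] = donor
    records = [(sid, seq_by_id[sid]) for sid, _ in records]

    if cfg.indel_rate > 0:
        records = _apply_indel_mask(records, cfg, rng)

    return SeqRecordSet(records), truth


def _apply_indel_mask(records, cfg: SimConfig, rng: np.random.Generator):
    """Overlay per-sequence gap runs (geometric lengths) on the alignment."""
    out = []
    L = cfg.seq_length
    for seq_id, seq in records:
        arr = np.array(list(seq))
        n_events = rng.poisson(cfg.indel_rate * L)
        for _ in range(n_events):
            start = rng.integers(L)
            length = 1 + rng.geometric(1.0 / cfg.indel_mean_length)
            arr[start : start + length] = "-"
        out.append((seq_id, "".join(arr)))
    return out


def split_query_reference(
    seqs: SeqRecordSet, truth: pd.DataFrame, *, queries_per_species: int = 1
) -> tuple[SeqRecordSet, SeqRecordSet, dict]:
    """Split a simulated dataset into query and reference sets.

    The first ``queries_per_species`` accessions of every species become
    queries; the rest are references, except that species flagged as
    absent from the reference library contribute no references at all
    (their queries can then only fail with a below-threshold outcome).
    Returns (queries, references, truth species map for all sequences).
    """
    query_ids: list[str] = []
    ref_ids: list[str] = []
    for _, grp in truth.groupby("species", sort=True):
        ids = list(grp["seq_id"])
        query_ids.extend(ids[:queries_per_species])
        if bool(grp["in_reference_library"].iloc[0]):
            ref_ids.extend(ids[queries_per_species:])
    species_map = dict(zip(truth["seq_id"], truth["species"]))
    return seqs.subset(query_ids), seqs.subset(ref_ids), species_map


def simulate_status_table(
    sample_ids: Sequence[str],
    markers: Sequence[str],
    p_amp: float,
    p_seq_given_amp: float,
    seed: int,
) -> StatusTable:
    """Bernoulli amplification/sequencing outcomes respecting sequenced => amplified."""
    if not (0 <= p_amp <= 1 and 0 <= p_seq_given_amp <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for sid in sample_ids:
        for marker in markers:
            amplified = bool(rng.random() < p_amp)
            sequenced = bool(amplified and rng.random() < p_seq_given_amp)
            rows.append((sid, marker, amplified, sequenced))
    return StatusTable(rows)
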
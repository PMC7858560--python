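"""Barcoding-gap statistics.

Splits pairwise distances into intraspecific and interspecific sets and
summarises, per species, the maximum intraspecific distance against the
nearest-neighbour (minimum) interspecific distance. A species shows a
barcoding gap when its nearest non-conspecific lies further than its most
divergent conspecific pair; the per-sequence variant asks the same of
each individual sequence. Both are scale-invariant verdicts on the same
distance matrix used for tree building.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distmodel import DistanceMatrix

NOT_ASSESSABLE = "NOT_ASSESSABLE"


@dataclass
class GapSummary:
    """Per-species and dataset-level barcoding-gap summary.

    ``per_species`` columns: species, n_accessions, max_intra (NaN for
    singletons), min_inter, gap_present (boolean, or NOT_ASSESSABLE when
    max_intra is undefined). Dataset-level fractions count, respectively,
    sequences whose nearest non-conspecific is farther than their farthest
    conspecific, and species with a gap among assessable species.
    """

    per_species: pd.DataFrame
    per_sequence: pd.DataFrame
    fraction_sequences_with_gap: float
    fraction_species_with_gap: float
    n_excluded_pairs: int


def intra_inter_split(
    dm: DistanceMatrix, assignment: dict
) -> tuple[np.ndarray, np.ndarray, int]:
    """Partition off-diagonal distances into intra- and interspecific sets.

    Every label must be assigned to a species and at least two species
    must be present. UNDEFINED distances are excluded; their count is
    returned alongside the two sets.
    """
    missing = [l for l in dm.labels if l not in assignment]
    if missing:
        raise KeyError(f"labels without species assignment: {missing[:5]}")
    species = np.array([assignment[l] for l in dm.labels])
    if len(set(species)) < 2:
        raise ValueError("need at least 2 species for intra/inter comparison")
    iu = np.triu_indices(dm.n, 1)
    vals = dm.values[iu]
    same = species[iu[0]] == species[iu[1]]
    defined = np.isfinite(vals)
    intra = vals[same & defined]
    inter = vals[~same & defined]
    return intra, inter, int((~defined).sum())


def gap_summary(dm: DistanceMatrix, assignment: dict) -> GapSummary:
    """Compute per-species and per-sequence barcoding-gap verdicts."""
    intra, inter, n_excluded = intra_inter_split(dm, assignment)  # validates inputs
    species = np.array([assignment[l] for l in dm.labels])
    D = dm.values

    sp_rows = []
    for sp in sorted(set(species)):
        members = np.where(species == sp)[0]
        others = np.where(species != sp)[0]
        if len(members) > 1:
            block = D[np.ix_(members, members)]
            iu = np.triu_indices(len(members), 1)
            vals = block[iu]
            max_intra = np.nanmax(vals) if np.isfinite(vals).any() else np.nan
        else:
            max_intra = np.nan
        cross = D[np.ix_(members, others)]
        min_inter = np.nanmin(cross) if np.isfinite(cross).any() else np.nan
        if np.isnan(max_intra) or np.isnan(min_inter):
            gap = NOT_ASSESSABLE
        else:
            gap = bool(min_inter > max_intra)
        sp_rows.append((sp, len(members), max_intra, min_inter, gap))
    per_species = pd.DataFrame(
        sp_rows, columns=["species", "n_accessions", "max_intra", "min_inter", "gap_present"]
    )

    seq_rows = []
    for i, label in enumerate(dm.labels):
        mates = np.where((species == species[i]) & (np.arange(dm.n) != i))[0]
        others = np.where(species != species[i])[0]
        max_intra_i = (
            np.nanmax(D[i, mates]) if mates.size and np.isfinite(D[i, mates]).any() else np.nan
        )
        min_inter_i = (
            np.nanmin(D[i, others]) if others.size and np.isfinite(D[i, others]).any() else np.nan
        )
        if np.isnan(max_intra_i) or np.isnan(min_inter_i):
            gap = NOT_ASSESSABLE
        else:
            gap = bool(min_inter_i > max_intra_i)
        seq_rows.append((label, species[i], max_intra_i, min_inter_i, gap))
    per_sequence = pd.DataFrame(
        seq_rows, columns=["label", "species", "max_intra", "min_inter", "gap_present"]
    )

    assessable_sp = per_species[per_species["gap_present"] != NOT_ASSESSABLE]
    assessable_seq = per_sequence[per_sequence["gap_present"] != NOT_ASSESSABLE]
    frac_sp = (
        float((assessable_sp["gap_present"] == True).mean()) if len(assessable_sp) else float("nan")  # noqa: E712
    )
    frac_seq = (
        float((assessable_seq["gap_present"] == True).mean()) if len(assessable_seq) else float("nan")  # noqa: E712
    )
    return GapSummary(per_species, per_sequence, frac_seq, frac_sp, n_excluded)


def histogram_data(
    dm: DistanceMatrix, assignment: dict, n_bins: int = 40
) -> pd.DataFrame:
    """Binned intra/inter distance counts on a shared bin grid (for plotting)."""
    intra, inter, _ = intra_inter_split(dm, assignment)
    all_vals = np.concatenate([intra, inter]) if intra.size or inter.size else np.array([0.0])
    hi = float(all_vals.max()) if all_vals.size else 1.0
    edges = np.linspace(0.0, max(hi, 1e-9), n_bins + 1)
    h_intra, _ = np.histogram(intra, bins=edges)
    h_inter, _ = np.histogram(inter, bins=edges)
    return pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "n_intra": h_intra,
            "n_inter": h_inter,
        }
    )
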
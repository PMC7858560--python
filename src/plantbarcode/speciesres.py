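"""Monophyly-based species resolution on NJ trees.

A species is resolved for a query sample when the query plus all
reference accessions of exactly one species form a monophyletic group
(one side of a split of the unrooted tree) containing no other species.
If the same holds only at genus level the outcome is a genus-only
fallback ("Genus sp."); otherwise the sample is unresolved. Monophyly is
defined on bipartitions, so the decision is independent of rooting and
of leaf order.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import pandas as pd

from .njtree import PhyloTree


class Level(str, Enum):
    SPECIES = "SPECIES"
    GENUS_ONLY = "GENUS_ONLY"
    UNRESOLVED = "UNRESOLVED"


@dataclass
class ResolutionOutcome:
    sample_id: str
    level: Level
    resolved_name: str = ""
    singleton_flag: bool = False
    missing_reference: bool = False

    def __post_init__(self) -> None:
        if self.level is Level.SPECIES and len(self.resolved_name.split()) < 2:
            raise ValueError("SPECIES outcome requires a binomial name")
        if self.level is Level.GENUS_ONLY and not self.resolved_name.endswith(" sp."):
            raise ValueError("GENUS_ONLY outcome requires a 'Genus sp.' name")


def species_monophyletic(
    tree: PhyloTree, assignment: Mapping[str, str], species: str
) -> bool:
    """True iff all leaves assigned to ``species`` form one side of a split.

    Singletons are trivially monophyletic. The species must appear in the
    assignment (hard error otherwise); leaves of the tree without an
    assignment are treated as belonging to other species.
    """
    members = frozenset(l for l, sp in assignment.items() if sp == species)
    if not members:
        raise KeyError(f"species {species!r} absent from assignment")
    missing = members - set(tree.leaves)
    if missing:
        raise KeyError(f"assigned leaves not in tree: {sorted(missing)}")
    n = tree.n_leaves
    if len(members) in (1, n):
        return True
    return members in tree.clade_sides()


def resolve_sample(
    tree: PhyloTree,
    assignment: Mapping[str, str],
    genus_map: Mapping[str, str] | None,
    query_id: str,
    *,
    expected_species: str | None = None,
) -> ResolutionOutcome:
    """Resolve one query leaf against reference leaves carrying species labels.

    ``assignment`` maps reference leaves to species names (the query leaf
    itself must not be assigned). ``genus_map`` maps species to genus;
    when omitted the genus is the first epithet of the binomial. If
    ``expected_species`` is given and has no references in the tree, the
    outcome carries a missing-reference flag — the failure mode of a
    query whose species is absent from the local library.
    """
    if query_id not in tree.adj:
        raise KeyError(f"query leaf {query_id!r} not in tree")
    refs = {l: sp for l, sp in assignment.items() if l != query_id and l in tree.adj}
    if genus_map is None:
        genus_map = {sp: sp.split()[0] for sp in set(refs.values())}
    sides = tree.clade_sides()

    by_species: dict[str, set[str]] = {}
    for leaf, sp in refs.items():
        by_species.setdefault(sp, set()).add(leaf)

    missing_ref = expected_species is not None and expected_species not in by_species

    for sp in sorted(by_species):
        group = frozenset({query_id} | by_species[sp])
        # the whole leaf set counts only when no other species could be excluded
        if group in sides or (len(group) == tree.n_leaves and len(by_species) == 1):
            return ResolutionOutcome(
                query_id,
                Level.SPECIES,
                sp,
                singleton_flag=len(by_species[sp]) == 1,
                missing_reference=missing_ref,
            )

    by_genus: dict[str, set[str]] = {}
    for leaf, sp in refs.items():
        by_genus.setdefault(genus_map.get(sp, sp.split()[0]), set()).add(leaf)
    for genus in sorted(by_genus):
        group = frozenset({query_id} | by_genus[genus])
        if group in sides or (len(group) == tree.n_leaves and len(by_genus) == 1):
            return ResolutionOutcome(
                query_id,
                Level.GENUS_ONLY,
                f"{genus} sp.",
                singleton_flag=len(by_genus[genus]) == 1,
                missing_reference=missing_ref,
            )

    return ResolutionOutcome(query_id, Level.UNRESOLVED, missing_reference=missing_ref)


def resolution_table(
    trees: Mapping[str, PhyloTree],
    ref_species: Mapping[str, Mapping[str, str]],
    query_ids: Mapping[str, list[str]],
    genus_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample × per-marker resolution outcomes in long format.

    ``trees``, ``ref_species`` and ``query_ids`` are keyed by marker; a
    sample missing from a marker is simply absent from that marker's rows.
    Returns (long table, per-marker counts of SPECIES-level outcomes,
    with singleton-backed resolutions counted separately).
    """
    rows = []
    for marker in trees:
        tree = trees[marker]
        for q in query_ids.get(marker, []):
            out = resolve_sample(tree, ref_species[marker], genus_map, q)
            rows.append(
                (q, marker, out.level.value, out.resolved_name, out.singleton_flag)
            )
    long = pd.DataFrame(
        rows, columns=["sample_id", "marker", "level", "resolved_name", "singleton_flag"]
    )
    counts = []
    for marker in trees:
        sub = long[long["marker"] == marker]
        n_species = int((sub["level"] == Level.SPECIES.value).sum())
        n_singleton = int(
            ((sub["level"] == Level.SPECIES.value) & sub["singleton_flag"]).sum()
        )
        counts.append((marker, len(sub), n_species, n_singleton))
    counts_df = pd.DataFrame(
        counts, columns=["marker", "n_samples", "n_species_resolved", "n_singleton_backed"]
    )
    return long, counts_df
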
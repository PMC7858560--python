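"""Pipeline orchestration and summary tables.

Produces the survey-style summaries: per-marker sequence recovery
percentages, identification outcome counts, monophyly resolution counts,
and the end-to-end run that chains simulation (or file input), distance
estimation, NJ, identification, resolution and gap statistics, writing
every intermediate artefact plus a resolved-config run log.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .distmodel import distance_matrix, mcl_distance_matrix
from .gapstats import gap_summary
from .identify import IdentificationResult, Outcome, RefEntry, ReferenceLibrary, batch_classify, results_to_frame
from .njtree import nj_build
from .phylogeo import phylogeo_test
from .seqio import SeqRecordSet, StatusTable, write_newick
from .speciesres import Level, ResolutionOutcome, resolve_sample
from .synthetic import SimConfig, simulate_dataset, split_query_reference

logger = logging.getLogger(__name__)


def pct_1dp(numerator: int, denominator: int) -> float:
    """Percentage truncated to one decimal (the survey tables' dialect: 32/36 -> 88.8)."""
    if denominator == 0:
        return 0.0
    pct = 100.0 * numerator / denominator
    return math.floor(round(pct * 10.0, 6)) / 10.0


@dataclass
class MarkerSummary:
    marker: str
    n_samples: int = 0
    n_amplified: int = 0
    n_sequenced: int = 0
    recovery_pct: float = 0.0
    n_correct: int = 0
    n_ambiguous: int = 0
    n_below_threshold: int = 0
    n_species_resolved_tree: int = 0


def recovery_summary(status: StatusTable) -> list[MarkerSummary]:
    """Per-marker amplification/sequencing recovery with 1-decimal percentages."""
    df = status.to_frame()
    out = []
    for marker, sub in df.groupby("marker", sort=False):
        n = len(sub)
        out.append(
            MarkerSummary(
                marker=marker,
                n_samples=n,
                n_amplified=int(sub["amplified"].sum()),
                n_sequenced=int(sub["sequenced"].sum()),
                recovery_pct=pct_1dp(int(sub["sequenced"].sum()), n),
            )
        )
    return out


def count_outcomes(results: Sequence) -> dict:
    """Tally identification or resolution outcomes.

    Accepts IdentificationResult / ResolutionOutcome objects or rows of an
    outcome table with an ``outcome`` or ``level`` column. CORRECT and
    SPECIES-level outcomes count as resolved.
    """
    if isinstance(results, pd.DataFrame):
        col = "outcome" if "outcome" in results.columns else "level"
        values = list(results[col])
    else:
        values = [
            r.outcome.value if isinstance(r, IdentificationResult) else r.level.value
            for r in results
        ]
    counts = {
        "n_classified": len(values),
        "n_correct": sum(v == Outcome.CORRECT.value for v in values),
        "n_ambiguous": sum(v == Outcome.AMBIGUOUS_TOP.value for v in values),
        "n_below_threshold": sum(v == Outcome.BELOW_THRESHOLD.value for v in values),
        "n_species": sum(v == Level.SPECIES.value for v in values),
        "n_genus_only": sum(v == Level.GENUS_ONLY.value for v in values),
        "n_unresolved": sum(v == Level.UNRESOLVED.value for v in values),
    }
    counts["n_resolved"] = counts["n_correct"] + counts["n_species"]
    return counts


def _marker_inputs(marker_cfg: Mapping, seed: int):
    """Resolve one marker's sequences: either simulate or load files."""
    from .seqio import read_fasta, read_metadata

    if "simulate" in marker_cfg:
        sim = dict(marker_cfg["simulate"])
        sim.setdefault("seed", seed)
        if "missing_reference_species" in sim:
            sim["missing_reference_species"] = set(sim["missing_reference_species"])
        cfg = SimConfig(**sim)
        seqs, truth = simulate_dataset(cfg)
        queries, refs, species_map = split_query_reference(seqs, truth)
        region_map = dict(zip(truth["seq_id"], truth["region"]))
        return seqs, queries, refs, species_map, region_map, cfg
    seqs = read_fasta(marker_cfg["fasta"])
    meta = read_metadata(marker_cfg["metadata"])
    by_id = {m.sample_id: m for m in meta}
    ref_ids = [i for i in seqs.ids if i in by_id and by_id[i].source.value == "reference"]
    query_ids = [i for i in seqs.ids if i not in ref_ids]
    species_map = {
        i: by_id[i].species for i in seqs.ids if i in by_id and by_id[i].species != "UNKNOWN"
    }
    region_map = {i: by_id[i].region for i in seqs.ids if i in by_id}
    return seqs, seqs.subset(query_ids), seqs.subset(ref_ids), species_map, region_map, None


def run_pipeline(config: Mapping, outdir: str | Path) -> dict:
    """Run the full marker-evaluation pipeline and write a report bundle.

    ``config`` keys: ``seed`` (int), ``markers`` (mapping marker-name ->
    either {"simulate": {SimConfig kwargs}} or {"fasta": ..., "metadata":
    ...}), and optional ``model`` (default "MCL"), ``deletion``
    ("pairwise"), ``threshold`` (0.995). Per marker the bundle holds the
    distance matrix TSV, the Newick NJ tree, identification and
    resolution TSVs, the gap summary TSV and a MarkerSummary row; a run
    log echoes the resolved configuration. Any stage failure aborts with
    a stage-named error, keeping prior outputs with a .partial suffix.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    markers = config.get("markers", {})
    if not markers:
        raise ValueError("config lists no markers")
    seed = int(config.get("seed", 0))
    model = config.get("model", "MCL")
    deletion = config.get("deletion", "pairwise")
    threshold = float(config.get("threshold", 0.995))
    summaries = []
    stage = "setup"
    written: list[Path] = []

    def _write(path: Path, writer) -> None:
        writer(path)
        written.append(path)

    try:
        for mi, (marker, marker_cfg) in enumerate(markers.items()):
            stage = f"{marker}:inputs"
            seqs, queries, refs, species_map, region_map, sim_cfg = _marker_inputs(
                marker_cfg, seed + mi
            )
            stage = f"{marker}:distances"
            dm = (
                mcl_distance_matrix(seqs, deletion=deletion)
                if model == "MCL"
                else distance_matrix(seqs, model=model, deletion=deletion)
            )
            _write(outdir / f"{marker}.distances.tsv", dm.to_tsv)
            stage = f"{marker}:tree"
            tree = nj_build(dm)
            _write(outdir / f"{marker}.nwk", lambda p: write_newick(tree, p))
            stage = f"{marker}:identify"
            library = ReferenceLibrary(
                [
                    RefEntry(rid, seq, species_map.get(rid, rid))
                    for rid, seq in refs.records
                ],
                marker,
            )
            results, id_counts = batch_classify(queries, library, threshold)
            _write(
                outdir / f"{marker}.identification.tsv",
                lambda p: results_to_frame(results).to_csv(p, sep="\t", index=False),
            )
            stage = f"{marker}:resolve"
            ref_assignment = {rid: species_map[rid] for rid, _ in refs.records if rid in species_map}
            res_rows = []
            for qid, _ in queries.records:
                out = resolve_sample(tree, ref_assignment, None, qid)
                res_rows.append(
                    (qid, marker, out.level.value, out.resolved_name, out.singleton_flag)
                )
            res_df = pd.DataFrame(
                res_rows,
                columns=["sample_id", "marker", "level", "resolved_name", "singleton_flag"],
            )
            _write(
                outdir / f"{marker}.resolution.tsv",
                lambda p: res_df.to_csv(p, sep="\t", index=False),
            )
            stage = f"{marker}:gap"
            all_species = {**species_map}
            gap = gap_summary(dm, {l: all_species.get(l, l) for l in dm.labels})
            _write(
                outdir / f"{marker}.gap.tsv",
                lambda p: gap.per_species.to_csv(p, sep="\t", index=False),
            )
            n_species_resolved = int((res_df["level"] == Level.SPECIES.value).sum())
            summaries.append(
                MarkerSummary(
                    marker=marker,
                    n_samples=len(queries),
                    n_correct=id_counts["n_correct"],
                    n_ambiguous=id_counts["n_ambiguous"],
                    n_below_threshold=id_counts["n_below_threshold"],
                    n_species_resolved_tree=n_species_resolved,
                )
            )
        stage = "summary"
        summary_df = pd.DataFrame([asdict(s) for s in summaries])
        summary_df.to_csv(outdir / "marker_summary.tsv", sep="\t", index=False)
        log = {
            "version": __version__,
            "seed": seed,
            "model": model,
            "deletion": deletion,
            "threshold": threshold,
            "markers": {
                m: (cfg if "simulate" not in cfg else {"simulate": dict(cfg["simulate"])})
                for m, cfg in markers.items()
            },
        }
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str) + "\n")
        return {"summary": summary_df, "outdir": outdir}
    except Exception as err:
        for path in written:
            if path.exists():
                path.rename(path.with_suffix(path.suffix + ".partial"))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
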
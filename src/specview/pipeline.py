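"""End-to-end orchestration: preprocess, train, rank, evaluate.

Thin glue over the library modules, shared by the command-line
interface and by the desk-scale synthetic studies.  The annotation
entry point supports both inference paradigms: aggregate-then-rank
(one ranking against the group's consensus spectrum) and
rank-then-aggregate (per-spectrum rankings combined by mean rank or
summed reciprocal rank).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .chemio import ChemicalFormula, Molecule, parse_molecule
from .encoders import EncoderConfig, MultiViewModel
from .ranking import (
    CandidateSet,
    Embedder,
    ModelEmbedder,
    RankingResult,
    per_spectrum_rank_matrix,
    rank_after_aggregation,
    rank_at_k,
    rank_candidates,
    split_ranking_view,
)
from .spectra import (
    ConsensusSpectrum,
    FormulaSpectrum,
    NormalizationStats,
    RawSpectrum,
    annotate_peaks,
    build_consensus,
    fit_normalization,
)
from .synthetic import (
    RetrievalTask,
    SyntheticConfig,
    generate_library,
    make_retrieval_task,
    random_decoy_candidates,
)
from .training import TrainConfig, build_dataset, train

logger = logging.getLogger(__name__)


@dataclass
class PreprocessResult:
    annotated: list[FormulaSpectrum]
    consensus: dict[str, ConsensusSpectrum]
    stats: NormalizationStats
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (query_id, reason)


def preprocess(
    spectra: Sequence[RawSpectrum],
    formulas: Mapping[str, ChemicalFormula | str],
    ppm_tol: float = 20.0,
    top_k: int = 60,
) -> PreprocessResult:
    """Annotate raw spectra and build per-group consensus spectra.

    ``formulas`` maps query ids (or group keys as a fallback) to the
    precursor formula — ground truth during training, an upstream
    assignment at inference.  Spectra without a formula, or with no
    annotatable peak, are reported in ``skipped`` (with a reason code)
    but never silently dropped from the counts.
    """
    annotated: list[FormulaSpectrum] = []
    skipped: list[tuple[str, str]] = []
    for s in spectra:
        f = formulas.get(s.query_id, formulas.get(s.group_key))
        if f is None:
            skipped.append((s.query_id, "no_precursor_formula"))
            continue
        if isinstance(f, str):
            f = ChemicalFormula.parse(f)
        fs = annotate_peaks(s, f, ppm_tol=ppm_tol, top_k=top_k)
        if not fs.peaks:
            skipped.append((s.query_id, "no_annotatable_peaks"))
            continue
        annotated.append(fs)
    if not annotated:
        raise ValueError("no spectra could be annotated")
    by_group: dict[str, list[FormulaSpectrum]] = {}
    for fs in annotated:
        by_group.setdefault(fs.group_key, []).append(fs)
    consensus = {key: build_consensus(group) for key, group in by_group.items()}
    stats = fit_normalization(annotated)
    logger.info(
        "preprocessed %d spectra (%d skipped), %d consensus groups",
        len(annotated), len(skipped), len(consensus),
    )
    return PreprocessResult(annotated, consensus, stats, skipped)


# ---------------------------------------------------------------------------
# Annotation (inference)


@dataclass
class QueryAnnotation:
    """Final per-query outcome plus the full scored candidate table."""

    query_id: str
    strategy: str
    rank_of_target: int | None
    rows: list[dict]  # candidate, score, rank columns for the CSV report


def annotate_queries(
    embedder: Embedder,
    grouped_spectra: Mapping[str, Sequence[FormulaSpectrum]],
    candidate_sets: Mapping[str, CandidateSet],
    ranking_view: str,
    strategy: str = "consensus",
) -> tuple[list[RankingResult], list[QueryAnnotation]]:
    """Rank candidates for every query group under one strategy.

    ``consensus`` ranks once against the merged consensus spectrum
    (requires a cs ranking view); ``average_rank`` and
    ``reciprocal_rank`` rank per spectrum and aggregate.
    """
    results: list[RankingResult] = []
    annotations: list[QueryAnnotation] = []
    for group_key, cand in sorted(candidate_sets.items()):
        spectra = list(grouped_spectra.get(group_key, []))
        spectra = [s for s in spectra if s.peaks]
        if not spectra:
            logger.warning("query %s: nothing annotatable; unranked", group_key)
            results.append(RankingResult(group_key, [], None))
            annotations.append(QueryAnnotation(group_key, strategy, None, []))
            continue
        if strategy == "consensus":
            spectrum = build_consensus(spectra)
            res = rank_candidates(spectrum, cand, ranking_view, embedder)
            rows = [
                {"candidate": m.smiles, "score": score, "rank": i + 1}
                for i, (m, score) in enumerate(res.ordered)
            ]
        elif strategy in ("average_rank", "reciprocal_rank"):
            matrix = per_spectrum_rank_matrix(spectra, cand, ranking_view, embedder)
            from .ranking import aggregate_average_rank, aggregate_reciprocal_rank

            agg = (
                aggregate_average_rank if strategy == "average_rank"
                else aggregate_reciprocal_rank
            )
            order, scores = agg(matrix)
            rows = [
                {
                    "candidate": cand.candidates[i].smiles,
                    "score": float(scores[i]),
                    "rank": pos + 1,
                }
                for pos, i in enumerate(order)
            ]
            rank = None
            target = None
            if cand.target_id is not None:
                for i, m in enumerate(cand.candidates):
                    if m.identifier == cand.target_id:
                        rank = rank_after_aggregation(matrix, i, strategy)
                        target = m
                        break
            ordered = [(cand.candidates[i], float(scores[i])) for i in order]
            res = RankingResult(group_key, ordered, rank, target)
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
        results.append(res)
        annotations.append(QueryAnnotation(group_key, strategy, res.rank_of_target, rows))
    return results, annotations


def write_results_csv(
    annotations: Sequence[QueryAnnotation],
    path: str | Path,
    score_threshold: float | None = None,
    margin: float | None = None,
) -> None:
    """One row per query x candidate; schema v1.

    Optional confidence filters add a pass/fail column without dropping
    rows: ``confident`` requires the top score above ``score_threshold``
    and a gap of at least ``margin`` to the runner-up.
    """
    with open(path, "w", newline="") as fh:
        fh.write("# specview results schema v1\n")
        writer = csv.writer(fh)
        writer.writerow(["query_id", "strategy", "rank", "candidate", "score", "confident"])
        for ann in annotations:
            top = ann.rows[0]["score"] if ann.rows else None
            second = ann.rows[1]["score"] if len(ann.rows) > 1 else None
            confident = ""
            if score_threshold is not None or margin is not None:
                ok = top is not None
                if ok and score_threshold is not None:
                    ok = top > score_threshold
                if ok and margin is not None and second is not None:
                    ok = (top - second) >= margin
                confident = str(bool(ok)).lower()
            for row in ann.rows:
                writer.writerow(
                    [ann.query_id, ann.strategy, row["rank"], row["candidate"],
                     f"{row['score']:.6f}", confident]
                )


# ---------------------------------------------------------------------------
# Desk-scale synthetic study


@dataclass
class StudyResult:
    """Outcome of the synthetic end-to-end learnability study."""

    rank1_mol_s: float
    rank1_mol_cs: float
    rank5_mol_s: float
    annotation_recovery: float
    first_epoch_loss: float
    final_epoch_loss: float
    n_molecules: int
    n_spectra: int
    results_s: list[RankingResult]
    results_cs: list[RankingResult]
    model: MultiViewModel


def run_learnability_study(
    seed: int = 0,
    n_molecules: int = 50,
    n_decoys: int = 8,
    epochs: int = 300,
    embedding_dim: int = 32,
    hidden: int = 64,
    batch_size: int = 25,
    learning_rate: float = 1.0e-3,
    views: tuple[str, ...] = ("mol", "fp", "s", "cs"),
) -> StudyResult:
    """Train on a synthetic task and retrieve against random decoys.

    The study conditions are the generator defaults (3 collision-energy
    levels, 12 fragments, 5 ppm jitter, dropout 0.5); dimensions,
    epochs and learning rate are desk-scale choices so the full cycle
    runs on one CPU in minutes.
    """
    cfg = SyntheticConfig(n_molecules=n_molecules, n_decoys=n_decoys, seed=seed)
    library = generate_library(cfg)
    task = make_retrieval_task(library, cfg)
    formulas = {m.identifier: m.formula for m in library}
    prep = preprocess(task.spectra, formulas)

    n_generated = sum(len(s.peaks) for s in task.spectra)
    n_recovered = sum(len(s.peaks) for s in prep.annotated)
    recovery = n_recovered / n_generated if n_generated else 0.0

    enc_cfg = EncoderConfig(embedding_dim=embedding_dim, hidden=hidden)
    dataset = build_dataset(library, prep.annotated, prep.stats, enc_cfg)
    tr_cfg = TrainConfig(
        learning_rate=learning_rate,
        batch_size=batch_size,
        epochs=epochs,
        seed=seed,
        views=views,
    )
    result = train(dataset, enc_cfg, tr_cfg, stats=prep.stats)
    embedder = ModelEmbedder(result.model)

    rng = np.random.default_rng(seed + 2)
    grouped: dict[str, list[FormulaSpectrum]] = {}
    for fs in prep.annotated:
        grouped.setdefault(fs.group_key, []).append(fs)
    candidates = {
        m.identifier: random_decoy_candidates(m, library, n_decoys, rng)
        for m in library
        if m.identifier in grouped
    }

    results_s: list[RankingResult] = []
    for key, cand in sorted(candidates.items()):
        # mol-s: each group's spectra ranked individually
        for fs in grouped[key]:
            results_s.append(rank_candidates(fs, cand, "mol-s", embedder))
    results_cs, _ = annotate_queries(embedder, grouped, candidates, "mol-cs", "consensus")

    return StudyResult(
        rank1_mol_s=rank_at_k(results_s, 1),
        rank1_mol_cs=rank_at_k(results_cs, 1),
        rank5_mol_s=rank_at_k(results_s, 5),
        annotation_recovery=recovery,
        first_epoch_loss=result.loss_log[0]["total"],
        final_epoch_loss=result.loss_log[-1]["total"],
        n_molecules=len(library),
        n_spectra=len(prep.annotated),
        results_s=results_s,
        results_cs=results_cs,
        model=result.model,
    )
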
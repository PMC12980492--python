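"""Candidate retrieval and evaluation.

Given a query spectrum (or a group of spectra) and a set of candidate
molecules, candidates are ordered by the cosine similarity between the
spectral-view embedding and each candidate's molecule-view embedding.
Four ranking views exist: mol-s, fp-s, mol-cs, fp-cs (molecule view x
spectral view).  Multi-spectrum queries can be resolved either by
aggregate-then-rank (rank once against the consensus spectrum) or by
rank-then-aggregate (rank per spectrum, then combine per-candidate
ranks by mean rank or by summed reciprocal rank).

Evaluation reports rank@k (percentage of queries whose true molecule
lands in the top k; ties are scored pessimistically) and MCES@1, the
mean maximum-common-edge-subgraph distance between the true molecule
and the top-ranked candidate.  Exact MCES only, for desk-scale graphs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, Sequence

import networkx as nx
import numpy as np
from networkx.algorithms import isomorphism

from .chemio import Molecule, featurize_graph, fingerprint
from .encoders import MultiViewModel
from .spectra import (
    ConsensusSpectrum,
    FormulaSpectrum,
    RawSpectrum,
    bin_spectrum,
    spectrum_to_matrix,
)

logger = logging.getLogger(__name__)

PPM_WINDOW = 10.0  # candidate-by-mass window
MAX_CANDIDATES = 256

RANKING_VIEWS = ("mol-s", "fp-s", "mol-cs", "fp-cs")


def split_ranking_view(view: str) -> tuple[str, str]:
    if view not in RANKING_VIEWS:
        raise ValueError(f"unknown ranking view {view!r}; expected one of {RANKING_VIEWS}")
    mol_view, spec_view = view.split("-")
    return mol_view, spec_view


# ---------------------------------------------------------------------------
# Candidate sets


@dataclass
class CandidateSet:
    """Molecular candidates for one query, by mass or by formula."""

    query_id: str
    candidates: list[Molecule]
    mode: str  # "by_mass" | "by_formula"
    target_id: str | None = None


def build_candidates(
    target: Molecule,
    pool: Sequence[Molecule],
    mode: str = "by_mass",
    max_n: int = MAX_CANDIDATES,
    query_id: str | None = None,
) -> CandidateSet:
    """Filter a molecule pool into a candidate set for ``target``.

    ``by_mass`` keeps pool members whose monoisotopic mass lies within
    10 ppm of the target's; ``by_formula`` keeps exact-composition
    matches.  The target itself is always included.  If more than
    ``max_n`` survive, the target plus the nearest-by-mass decoys are
    kept (ties broken by canonical SMILES).
    """
    if mode not in ("by_mass", "by_formula"):
        raise ValueError(f"unknown candidate mode {mode!r}")
    if not pool:
        logger.warning("empty candidate pool for %s; target-only set", target.identifier)
    survivors: dict[str, Molecule] = {target.smiles: target}
    for mol in pool:
        if mol.smiles == target.smiles:
            continue
        if mode == "by_mass":
            ppm = abs(mol.monoisotopic_mass - target.monoisotopic_mass) / (
                target.monoisotopic_mass
            ) * 1e6
            if ppm <= PPM_WINDOW:
                survivors[mol.smiles] = mol
        else:
            if mol.formula.format() == target.formula.format():
                survivors[mol.smiles] = mol
    mols = list(survivors.values())
    if len(mols) > max_n:
        decoys = [m for m in mols if m.smiles != target.smiles]
        decoys.sort(
            key=lambda m: (abs(m.monoisotopic_mass - target.monoisotopic_mass), m.smiles)
        )
        mols = [target] + decoys[: max_n - 1]
    return CandidateSet(
        query_id=query_id or target.identifier,
        candidates=mols,
        mode=mode,
        target_id=target.identifier,
    )


# ---------------------------------------------------------------------------
# Embedders


class Embedder(Protocol):
    """Anything that maps molecules and spectra into the shared space."""

    def embed_molecule(self, mol: Molecule, view: str) -> np.ndarray: ...

    def embed_spectrum(
        self, spectrum: FormulaSpectrum | ConsensusSpectrum | RawSpectrum, view: str
    ) -> np.ndarray: ...


class ModelEmbedder:
    """Embedder backed by a trained :class:`MultiViewModel` checkpoint."""

    def __init__(self, model: MultiViewModel):
        self.model = model
        self._mol_cache: dict[str, dict[str, np.ndarray]] = {}

    def embed_molecule(self, mol: Molecule, view: str) -> np.ndarray:
        cached = self._mol_cache.setdefault(mol.smiles, {})
        if view not in cached:
            if view == "mol":
                cached[view] = self.model.graph_encoder(featurize_graph(mol)).data
            elif view == "fp":
                cached[view] = self.model.fingerprint_encoder(fingerprint(mol)).data
            else:
                raise ValueError(f"unknown molecule view {view!r}")
        return cached[view]

    def embed_spectrum(self, spectrum, view: str) -> np.ndarray:
        if view not in ("s", "cs"):
            raise ValueError(f"unknown spectral view {view!r}")
        encoder = (
            self.model.spectrum_encoder if view == "s" else self.model.consensus_encoder
        )
        cfg = self.model.cfg
        if cfg.spectral_mode == "binned":
            if not isinstance(spectrum, RawSpectrum):
                raise TypeError("binned mode requires raw spectra")
            vec = bin_spectrum(spectrum, cfg.bin_width, (cfg.mz_min, cfg.mz_max))
            return encoder(vec).data
        if not spectrum.peaks:
            raise ValueError("cannot embed an empty annotated spectrum")
        mat = spectrum_to_matrix(spectrum, self.model.stats)
        return encoder(mat).data


# ---------------------------------------------------------------------------
# Ranking


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))


@dataclass
class RankingResult:
    """Ordered candidates with scores for one query.

    ``rank_of_target`` uses the pessimistic tie rule: within a group of
    tied scores the target takes the worst (largest) rank.  ``None``
    marks an unranked query (e.g. nothing annotatable), counted as a
    retrieval failure by the metrics.
    """

    query_id: str
    ordered: list[tuple[Molecule, float]]
    rank_of_target: int | None
    target: Molecule | None = None


def _pessimistic_rank(scores: np.ndarray, target_idx: int, higher_better: bool = True) -> int:
    s = scores[target_idx]
    if higher_better:
        return int(np.sum(scores > s) + np.sum(scores == s))
    return int(np.sum(scores < s) + np.sum(scores == s))


def rank_candidates(
    spectrum: FormulaSpectrum | ConsensusSpectrum | RawSpectrum,
    candidate_set: CandidateSet,
    view: str,
    embedder: Embedder,
) -> RankingResult:
    """Order candidates by cosine similarity under one ranking view."""
    mol_view, spec_view = split_ranking_view(view)
    if getattr(spectrum, "peaks", None) is not None and not spectrum.peaks:
        logger.warning("query %s has no peaks; unranked", candidate_set.query_id)
        return RankingResult(candidate_set.query_id, [], None)
    z_spec = embedder.embed_spectrum(spectrum, spec_view)
    scores = np.array(
        [
            cosine(z_spec, embedder.embed_molecule(m, mol_view))
            for m in candidate_set.candidates
        ]
    )
    order = np.argsort(-scores, kind="stable")
    ordered = [(candidate_set.candidates[i], float(scores[i])) for i in order]
    rank, target = None, None
    if candidate_set.target_id is not None:
        for i, m in enumerate(candidate_set.candidates):
            if m.identifier == candidate_set.target_id:
                rank = _pessimistic_rank(scores, i)
                target = m
                break
    return RankingResult(candidate_set.query_id, ordered, rank, target)


def per_spectrum_rank_matrix(
    spectra: Sequence[FormulaSpectrum],
    candidate_set: CandidateSet,
    view: str,
    embedder: Embedder,
) -> np.ndarray:
    """Rank matrix (candidate x spectrum) for rank-then-aggregate.

    Each column ranks all candidates against one spectrum (competition
    ranking: tied scores share the worst rank of their tie group).
    """
    mol_view, spec_view = split_ranking_view(view)
    n = len(candidate_set.candidates)
    cols = []
    for s in spectra:
        z = embedder.embed_spectrum(s, spec_view)
        scores = np.array(
            [cosine(z, embedder.embed_molecule(m, mol_view)) for m in candidate_set.candidates]
        )
        ranks = np.array(
            [np.sum(scores > scores[i]) + np.sum(scores == scores[i]) for i in range(n)]
        )
        cols.append(ranks)
    return np.stack(cols, axis=1)


def aggregate_average_rank(rank_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean rank per candidate across spectra; lower is better.

    Returns (order, scores): ``order`` lists candidate indices from best
    to worst mean rank.
    """
    scores = rank_matrix.mean(axis=1)
    order = np.argsort(scores, kind="stable")
    return order, scores


def aggregate_reciprocal_rank(rank_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Summed reciprocal rank per candidate; higher is better."""
    scores = (1.0 / rank_matrix).sum(axis=1)
    order = np.argsort(-scores, kind="stable")
    return order, scores


def rank_after_aggregation(
    rank_matrix: np.ndarray, target_idx: int, method: str = "average_rank"
) -> int:
    """Target's pessimistic rank under a rank-then-aggregate strategy."""
    if method == "average_rank":
        _, scores = aggregate_average_rank(rank_matrix)
        return _pessimistic_rank(scores, target_idx, higher_better=False)
    if method == "reciprocal_rank":
        _, scores = aggregate_reciprocal_rank(rank_matrix)
        return _pessimistic_rank(scores, target_idx, higher_better=True)
    raise ValueError(f"unknown aggregation method {method!r}")


# ---------------------------------------------------------------------------
# Metrics


def rank_at_k(results: Sequence[RankingResult], k: int) -> float:
    """Percentage of queries with the target ranked in the top k.

    Unranked queries count as failures.
    """
    if not results:
        raise ValueError("rank@k of an empty result list")
    hits = sum(1 for r in results if r.rank_of_target is not None and r.rank_of_target <= k)
    return 100.0 * hits / len(results)


def heavy_atom_graph(mol: Molecule) -> nx.Graph:
    """Heavy-atom graph with atom symbols on nodes, bond orders on edges."""
    g = nx.Graph()
    rd = mol.rdkit_mol
    for atom in rd.GetAtoms():
        g.add_node(atom.GetIdx(), symbol=atom.GetSymbol())
    for bond in rd.GetBonds():
        g.add_edge(
            bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order=str(bond.GetBondType())
        )
    return g


class McesSizeError(ValueError):
    pass


def _mces_common_edges(ga: nx.Graph, gb: nx.Graph) -> int:
    """Size of the maximum common edge subgraph (labels must match)."""
    if ga.number_of_edges() > gb.number_of_edges():
        ga, gb = gb, ga
    node_match = isomorphism.categorical_node_match("symbol", None)
    edge_match = isomorphism.categorical_edge_match("order", None)
    edges = list(ga.edges)
    for k in range(len(edges), 0, -1):
        for subset in itertools.combinations(edges, k):
            pattern = nx.Graph()
            for u, v in subset:
                pattern.add_node(u, **ga.nodes[u])
                pattern.add_node(v, **ga.nodes[v])
                pattern.add_edge(u, v, **ga.edges[u, v])
            gm = isomorphism.GraphMatcher(
                gb, pattern, node_match=node_match, edge_match=edge_match
            )
            if gm.subgraph_is_monomorphic():
                return k
    return 0


def mces_distance(a: Molecule, b: Molecule, max_edges: int = 12) -> int:
    """Exact MCES distance: edges(a) + edges(b) - 2 * |MCES(a, b)|.

    Common edge subgraphs must match atom symbols and bond orders; the
    subgraph need not be connected.  Exact search only — molecules above
    ``max_edges`` bonds raise, pointing at external approximate tools.
    """
    ga, gb = heavy_atom_graph(a), heavy_atom_graph(b)
    ea, eb = ga.number_of_edges(), gb.number_of_edges()
    if ea > max_edges or eb > max_edges:
        raise McesSizeError(
            f"{ea}/{eb} edges exceed exact-mode cap {max_edges}; "
            "use an approximate MCES tool for large molecules"
        )
    return ea + eb - 2 * _mces_common_edges(ga, gb)


def mces_at_1(results: Sequence[RankingResult], max_edges: int = 12) -> float:
    """Mean MCES distance between each target and its rank-1 candidate."""
    dists = []
    for r in results:
        if r.target is None or not r.ordered:
            continue
        top1 = r.ordered[0][0]
        dists.append(mces_distance(r.target, top1, max_edges))
    if not dists:
        raise ValueError("no scorable results for MCES@1")
    return float(np.mean(dists))


def bootstrap_ci(
    values: Sequence[float] | np.ndarray,
    metric: Callable[[np.ndarray], float],
    n_resamples: int = 20_000,
    level: float = 99.9,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for a query-level metric.

    ``values`` are per-query quantities (e.g. target ranks); ``metric``
    maps a resampled vector to the statistic.  Deterministic per seed.
    """
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("bootstrap over an empty sample")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_resamples)
    n = values.size
    for i in range(n_resamples):
        stats[i] = metric(values[rng.integers(0, n, size=n)])
    alpha = (100.0 - level) / 2.0
    return (
        float(np.percentile(stats, alpha)),
        float(np.percentile(stats, 100.0 - alpha)),
    )


def evaluate_results(
    results: Sequence[RankingResult],
    ks: Sequence[int] = (1, 5, 20),
    with_mces: bool = True,
    mces_max_edges: int = 12,
    n_resamples: int = 2000,
    ci_level: float = 99.9,
    seed: int = 0,
) -> dict:
    """Metrics report: rank@k with bootstrap CIs, and MCES@1 when feasible."""
    ranks = np.array(
        [r.rank_of_target if r.rank_of_target is not None else np.inf for r in results]
    )
    report: dict = {"n_queries": len(results)}
    for k in ks:
        point = rank_at_k(results, k)
        lo, hi = bootstrap_ci(
            ranks,
            lambda v, kk=k: 100.0 * np.mean(v <= kk),
            n_resamples=n_resamples,
            level=ci_level,
            seed=seed,
        )
        report[f"rank@{k}"] = {"value": point, "ci": [lo, hi]}
    if with_mces:
        try:
            report["mces@1"] = mces_at_1(results, mces_max_edges)
        except (McesSizeError, ValueError) as exc:
            report["mces@1"] = None
            report["mces@1_note"] = str(exc)
    return report
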
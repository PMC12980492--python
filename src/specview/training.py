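"""Full-graph multiview contrastive training.

Four views of a metabolite datum — molecular graph, fingerprint,
individual spectrum, consensus spectrum — are embedded into one space
and pulled together with a temperature-scaled softmax contrastive loss.
The total objective sums a symmetric pairwise loss over *every*
unordered pair of active views (six pairs for four views, twelve
directional terms), so each view is trained against all the others
rather than against a single pivot.

Directional loss for views p, q over a batch of size B:

    L(p->q) = -(1/B) sum_i log[ h(v_p^i, v_q^i) / sum_j h(v_p^i, v_q^j) ]

with h(a, b) = exp(cos(a, b) / tau).  Negatives for datum i are the
other B-1 batch members; both directions of a pair share the batch.
"""

from __future__ import annotations

import csv
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .chemio import Molecule, MolecularGraph, featurize_graph, fingerprint
from .encoders import EncoderConfig, MultiViewModel, VIEWS
from .nn import Adam, Tensor, logsumexp
from .spectra import (
    ConsensusSpectrum,
    FormulaSpectrum,
    NormalizationStats,
    RawSpectrum,
    bin_spectrum,
    build_consensus,
    spectrum_to_matrix,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Loss functions


def similarity_h(a: np.ndarray, b: np.ndarray, tau: float = 0.05) -> float:
    """The discriminatory function h: exp(cosine similarity / tau)."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm embedding in similarity computation")
    return float(np.exp(np.dot(a, b) / (na * nb * tau)))


def _cosine_logits(vp: Tensor, vq: Tensor, tau: float) -> Tensor:
    """Matrix of cos(v_p^i, v_q^j)/tau for all batch pairs (i, j)."""
    norms_p = (vp * vp).sum(axis=1, keepdims=True).pow(0.5)
    norms_q = (vq * vq).sum(axis=1, keepdims=True).pow(0.5)
    if np.any(norms_p.data == 0) or np.any(norms_q.data == 0):
        raise ValueError("zero-norm embedding in contrastive batch")
    return (vp / norms_p) @ (vq / norms_q).T * (1.0 / tau)


def contrastive_direction_loss(vp: Tensor, vq: Tensor, tau: float = 0.05) -> Tensor:
    """One direction of the pairwise loss: anchor view p against view q.

    Equals the softmax cross-entropy of identifying each anchor's
    matching sample among the whole batch (diagonal = positives).
    Requires batch size >= 2 (there are no negatives otherwise).
    """
    b = vp.shape[0]
    if b < 2:
        raise ValueError("contrastive loss needs a batch of at least 2")
    logits = _cosine_logits(vp, vq, tau)
    lse = logsumexp(logits, axis=1).reshape(-1)
    diag = (logits * Tensor(np.eye(b))).sum(axis=1)
    return (lse - diag).mean()


def pairwise_loss(vp: Tensor, vq: Tensor, tau: float = 0.05) -> Tensor:
    """Symmetric pairwise loss: both anchor directions, shared batch."""
    return contrastive_direction_loss(vp, vq, tau) + contrastive_direction_loss(
        vq, vp, tau
    )


def total_loss(
    embeddings: Mapping[str, Tensor], tau: float = 0.05
) -> tuple[Tensor, dict[str, float]]:
    """Sum of pairwise losses over all unordered pairs of active views.

    Returns the scalar loss tensor and a per-pair breakdown for logging.
    With all four views active this is 6 pairs / 12 directional terms.
    """
    active = [v for v in VIEWS if v in embeddings]
    if len(active) < 2:
        raise ValueError("need at least two active views")
    terms: dict[str, float] = {}
    total: Tensor | None = None
    for p, q in itertools.combinations(active, 2):
        lpq = pairwise_loss(embeddings[p], embeddings[q], tau)
        terms[f"{p}-{q}"] = lpq.item()
        total = lpq if total is None else total + lpq
    return total, terms


# ---------------------------------------------------------------------------
# Dataset assembly


@dataclass
class DataPoint:
    """One molecule with precomputed views: graph, fingerprint, spectra."""

    identifier: str
    graph: MolecularGraph
    fingerprint_vec: np.ndarray
    spectra: list[np.ndarray]  # per-spectrum (n_peaks, 15) matrices or bin vectors
    consensus: np.ndarray


def build_dataset(
    molecules: Sequence[Molecule],
    annotated: Sequence[FormulaSpectrum],
    stats: NormalizationStats,
    cfg: EncoderConfig,
    raw_spectra: Sequence[RawSpectrum] | None = None,
) -> list[DataPoint]:
    """Precompute every view for each molecule.

    Spectra are matched to molecules through ``group_key``.  Molecules
    with no non-empty annotated spectrum are excluded with a warning.
    In binned mode the raw spectra are binned instead of formula-encoded
    and the consensus is the bin-wise maximum of the group's vectors.
    """
    by_group: dict[str, list[FormulaSpectrum]] = {}
    for s in annotated:
        if s.peaks:
            by_group.setdefault(s.group_key, []).append(s)
    raw_by_group: dict[str, list[RawSpectrum]] = {}
    if raw_spectra is not None:
        for r in raw_spectra:
            raw_by_group.setdefault(r.group_key, []).append(r)

    points: list[DataPoint] = []
    for mol in molecules:
        group = by_group.get(mol.identifier, [])
        if cfg.spectral_mode == "binned":
            raws = raw_by_group.get(mol.identifier, [])
            if not raws:
                logger.warning("molecule %s has no spectra; excluded", mol.identifier)
                continue
            mats = [
                bin_spectrum(r, cfg.bin_width, (cfg.mz_min, cfg.mz_max)) for r in raws
            ]
            consensus_vec = np.max(np.stack(mats), axis=0)
            if consensus_vec.max() > 0:
                consensus_vec = consensus_vec / consensus_vec.max()
        else:
            if not group:
                logger.warning(
                    "molecule %s has no annotated spectra; excluded", mol.identifier
                )
                continue
            mats = [spectrum_to_matrix(s, stats) for s in group]
            consensus_vec = spectrum_to_matrix(build_consensus(group), stats)
        points.append(
            DataPoint(
                identifier=mol.identifier,
                graph=featurize_graph(mol),
                fingerprint_vec=fingerprint(mol),
                spectra=mats,
                consensus=consensus_vec,
            )
        )
    if not points:
        raise ValueError("no data points with the required views")
    return points


def pad_peak_matrices(mats: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pad (n_i, 15) matrices to a common peak count; return batch + mask."""
    b = len(mats)
    p = max(m.shape[0] for m in mats)
    out = np.zeros((b, p, mats[0].shape[1]))
    mask = np.zeros((b, p))
    for i, m in enumerate(mats):
        out[i, : m.shape[0]] = m
        mask[i, : m.shape[0]] = 1.0
    return out, mask


# ---------------------------------------------------------------------------
# Training loop


@dataclass
class TrainConfig:
    """Optimization hyperparameters; defaults follow the training recipe."""

    temperature: float = 0.05
    learning_rate: float = 7.0e-5
    batch_size: int = 64
    epochs: int = 1500
    seed: int = 0
    grad_clip: float | None = None
    views: tuple[str, ...] = VIEWS

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        bad = [v for v in self.views if v not in VIEWS]
        if bad:
            raise ValueError(f"unknown views {bad}; expected subset of {VIEWS}")
        if len(self.views) < 2:
            raise ValueError("need at least two active views")


def _batch_embeddings(
    model: MultiViewModel,
    batch: Sequence[DataPoint],
    spectrum_choice: Sequence[int],
    views: Sequence[str],
) -> dict[str, Tensor]:
    out: dict[str, Tensor] = {}
    if "mol" in views:
        out["mol"] = model.graph_encoder.encode_batch([d.graph for d in batch])
    if "fp" in views:
        out["fp"] = model.fingerprint_encoder.encode_batch(
            [d.fingerprint_vec for d in batch]
        )
    formula_mode = model.cfg.spectral_mode == "formula"
    if "s" in views:
        mats = [d.spectra[c] for d, c in zip(batch, spectrum_choice)]
        if formula_mode:
            padded, mask = pad_peak_matrices(mats)
            out["s"] = model.spectrum_encoder(padded, mask)
        else:
            out["s"] = model.spectrum_encoder(np.stack(mats))
    if "cs" in views:
        if formula_mode:
            padded, mask = pad_peak_matrices([d.consensus for d in batch])
            out["cs"] = model.consensus_encoder(padded, mask)
        else:
            out["cs"] = model.consensus_encoder(np.stack([d.consensus for d in batch]))
    return out


@dataclass
class TrainResult:
    model: MultiViewModel
    loss_log: list[dict]  # per epoch: {"epoch": int, "total": float, per-pair}


def train(
    dataset: Sequence[DataPoint],
    encoder_cfg: EncoderConfig,
    train_cfg: TrainConfig,
    stats: NormalizationStats | None = None,
    model: MultiViewModel | None = None,
    log_path: str | Path | None = None,
) -> TrainResult:
    """Train the active view encoders with the full-graph objective.

    Each epoch shuffles molecules into batches; a molecule with several
    spectra contributes one, re-sampled uniformly per epoch.  Returns
    the trained model (a self-contained checkpoint once saved) and the
    per-epoch loss log.  Deterministic for a fixed seed.
    """
    if len(dataset) < 2:
        raise ValueError("training needs at least two data points")
    rng = np.random.default_rng(train_cfg.seed)
    if model is None:
        model = MultiViewModel(encoder_cfg, stats, seed=int(rng.integers(2**31)))
    params: list = []
    for view in train_cfg.views:
        params.extend(model.encoder(view).parameters())
    opt = Adam(params, lr=train_cfg.learning_rate)

    n = len(dataset)
    bsize = min(train_cfg.batch_size, n)
    loss_log: list[dict] = []
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        choices = [int(rng.integers(len(d.spectra))) for d in dataset]
        epoch_terms: dict[str, list[float]] = {}
        epoch_total: list[float] = []
        for start in range(0, n, bsize):
            idx = order[start : start + bsize]
            if len(idx) < 2:
                continue
            batch = [dataset[i] for i in idx]
            emb = _batch_embeddings(
                model, batch, [choices[i] for i in idx], train_cfg.views
            )
            loss, terms = total_loss(emb, train_cfg.temperature)
            opt.zero_grad()
            loss.backward()
            if train_cfg.grad_clip is not None:
                for p in params:
                    if p.grad is not None:
                        np.clip(p.grad, -train_cfg.grad_clip, train_cfg.grad_clip, p.grad)
            opt.step()
            epoch_total.append(loss.item())
            for k, v in terms.items():
                epoch_terms.setdefault(k, []).append(v)
        row = {"epoch": epoch, "total": float(np.mean(epoch_total))}
        row.update({k: float(np.mean(v)) for k, v in sorted(epoch_terms.items())})
        loss_log.append(row)
        if epoch % 50 == 0 or epoch == train_cfg.epochs - 1:
            logger.info("epoch %d: loss %.4f", epoch, row["total"])

    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(loss_log[0].keys()))
            writer.writeheader()
            writer.writerows(loss_log)
    return TrainResult(model=model, loss_log=loss_log)
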
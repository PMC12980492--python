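"""Spectrum I/O, subformula peak annotation, consensus construction, encodings.

The spectral side of the model works on *formula-annotated* peaks: each
measured fragment m/z is matched (within a ppm tolerance) against the
adduct-shifted monoisotopic masses of all element-wise subformulas of
the precursor formula.  Annotated spectra become sets of
(formula, intensity) pairs; a consensus spectrum merges all annotated
spectra that share a group key, keeping one peak per distinct formula at
the maximum intensity seen.  Each annotated peak is finally encoded as a
15-dimensional vector: 14 scaled element counts plus the normalized
intensity.  A binned (formula-free) representation is provided as an
alternative spectral encoding.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from pyteomics import mgf as pyteomics_mgf

from .chemio import (
    ELEMENTS,
    ADDUCT_SHIFTS,
    ChemicalFormula,
    formula_mass,
)

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 60
DEFAULT_PPM_TOL = 20.0


class MgfError(ValueError):
    pass


@dataclass
class RawSpectrum:
    """A measured MS/MS spectrum: peaks plus precursor metadata.

    ``group_key`` ties spectra of the same underlying molecule (training)
    or the same measured feature (inference) together for consensus
    construction.  Peaks are stored sorted by m/z regardless of input
    order.
    """

    query_id: str
    precursor_mz: float
    adduct: str = "unknown"
    group_key: str = ""
    peaks: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        for mz, inten in self.peaks:
            if mz <= 0:
                raise ValueError(f"non-positive m/z {mz} in {self.query_id}")
            if inten < 0:
                raise ValueError(f"negative intensity {inten} in {self.query_id}")
        self.peaks = sorted(self.peaks, key=lambda p: (p[0], p[1]))
        if not self.group_key:
            self.group_key = self.query_id


@dataclass(frozen=True)
class AnnotatedPeak:
    """A peak matched to a subformula of the precursor formula."""

    formula: ChemicalFormula
    mz: float
    intensity_norm: float
    ppm_error: float


@dataclass
class FormulaSpectrum:
    """An annotated spectrum: at most one peak per formula, max intensity 1."""

    query_id: str
    group_key: str
    peaks: list[AnnotatedPeak] = field(default_factory=list)

    @property
    def formulas(self) -> set[str]:
        return {p.formula.format() for p in self.peaks}

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class ConsensusSpectrum:
    """Union of annotated peaks across one group, max intensity per formula."""

    group_key: str
    peaks: list[AnnotatedPeak] = field(default_factory=list)

    @property
    def formulas(self) -> set[str]:
        return {p.formula.format() for p in self.peaks}

    def __len__(self) -> int:
        return len(self.peaks)


# ---------------------------------------------------------------------------
# MGF I/O


def _parse_adduct(params: dict) -> str:
    for key in ("ion", "adduct", "ionmode_adduct"):
        if key in params:
            label = str(params[key]).strip()
            if label:
                return label
    title = str(params.get("title", ""))
    for label in ADDUCT_SHIFTS:
        if label != "none" and label in title:
            return label
    return "unknown"


def read_mgf(path: str | Path) -> list[RawSpectrum]:
    """Read an MGF file into :class:`RawSpectrum` records.

    One spectrum per ``BEGIN IONS`` block; the precursor m/z comes from
    ``PEPMASS`` (required), the adduct from an ``ION``/``ADDUCT`` field
    or the title when present, the group key from a ``GROUP``/``FEATURE_ID``
    field (defaults to the query id).
    """
    path = Path(path)
    spectra: list[RawSpectrum] = []
    with pyteomics_mgf.MGF(str(path)) as reader:
        for index, entry in enumerate(reader):
            params = entry.get("params", {})
            if "pepmass" not in params or params["pepmass"][0] is None:
                raise MgfError(f"{path}: block {index}: missing PEPMASS")
            query_id = str(params.get("title", "")) or f"{path.stem}:{index}"
            group = str(
                params.get("group", params.get("feature_id", ""))
            )
            mzs = np.asarray(entry.get("m/z array", []), dtype=float)
            intens = np.asarray(entry.get("intensity array", []), dtype=float)
            if mzs.shape != intens.shape:
                raise MgfError(f"{path}: block {index}: malformed peak list")
            spectra.append(
                RawSpectrum(
                    query_id=query_id,
                    precursor_mz=float(params["pepmass"][0]),
                    adduct=_parse_adduct(params),
                    group_key=group,
                    peaks=list(zip(mzs.tolist(), intens.tolist())),
                )
            )
    return spectra


def write_mgf(spectra: Sequence[RawSpectrum], path: str | Path) -> None:
    """Write spectra to MGF, preserving adduct and group key as fields."""
    entries = []
    for s in spectra:
        mzs = [p[0] for p in s.peaks]
        intens = [p[1] for p in s.peaks]
        entries.append(
            {
                "m/z array": np.asarray(mzs),
                "intensity array": np.asarray(intens),
                "params": {
                    "title": s.query_id,
                    "pepmass": s.precursor_mz,
                    "ion": s.adduct,
                    "group": s.group_key,
                },
            }
        )
    pyteomics_mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# Peak filtering and annotation


def filter_top_peaks(s: RawSpectrum, k: int = DEFAULT_TOP_K) -> RawSpectrum:
    """Keep the ``k`` most intense peaks; ties keep the lower m/z first."""
    order = sorted(s.peaks, key=lambda p: (-p[1], p[0]))
    kept = order[:k]
    return replace(s, peaks=sorted(kept))


class SubformulaCapError(RuntimeError):
    pass


def subformula_count(precursor: ChemicalFormula) -> int:
    """Number of non-empty element-wise subformulas: prod(count+1) - 1."""
    n = 1
    for c in precursor.counts.values():
        n *= c + 1
    return n - 1


def enumerate_subformulas(
    precursor: ChemicalFormula, cap: int = 10_000_000
) -> Iterator[ChemicalFormula]:
    """Yield every non-empty element-wise subformula of ``precursor``.

    A subformula takes each element count between 0 and the precursor's
    count.  The stream has ``prod(count+1) - 1`` entries; exceeding
    ``cap`` raises before any enumeration starts.
    """
    total = subformula_count(precursor)
    if total > cap:
        raise SubformulaCapError(
            f"{total} subformulas exceed cap {cap}; pre-prune with a mass window"
        )
    elements = sorted(precursor.counts)
    maxima = [precursor.counts[e] for e in elements]

    def rec(i: int, current: dict[str, int]) -> Iterator[ChemicalFormula]:
        if i == len(elements):
            if any(current.values()):
                yield ChemicalFormula(dict(current))
            return
        for c in range(maxima[i] + 1):
            current[elements[i]] = c
            yield from rec(i + 1, current)
        current.pop(elements[i], None)

    yield from rec(0, {})


def _subformula_mass_table(
    precursor: ChemicalFormula, adduct: str
) -> tuple[list[ChemicalFormula], np.ndarray]:
    formulas = list(enumerate_subformulas(precursor))
    masses = np.array([formula_mass(f, adduct) for f in formulas])
    order = np.argsort(masses, kind="stable")
    return [formulas[i] for i in order], masses[order]


def annotate_peaks(
    s: RawSpectrum,
    precursor_formula: ChemicalFormula,
    ppm_tol: float = DEFAULT_PPM_TOL,
    top_k: int = DEFAULT_TOP_K,
) -> FormulaSpectrum:
    """Annotate peaks with subformulas of the precursor formula.

    Each of the ``top_k`` most intense peaks is matched to the subformula
    whose adduct-shifted mass is nearest in ppm, within ``ppm_tol``
    (ties: smaller |ppm|, then lexicographically smaller Hill formula).
    Unmatched peaks are dropped; when several peaks map to one formula
    only the most intense survives; intensities are then rescaled so the
    maximum retained intensity is 1.  The stored formula excludes the
    adduct.  An empty result is returned (with a warning) when nothing
    matches.
    """
    filtered = filter_top_peaks(s, top_k)
    adduct = s.adduct if s.adduct in ADDUCT_SHIFTS else "[M+H]+"
    formulas, masses = _subformula_mass_table(precursor_formula, adduct)

    best: dict[str, AnnotatedPeak] = {}
    for mz, inten in filtered.peaks:
        lo = np.searchsorted(masses, mz * (1 - ppm_tol * 1e-6))
        hi = np.searchsorted(masses, mz * (1 + ppm_tol * 1e-6), side="right")
        if lo >= hi:
            continue
        candidates = []
        for i in range(lo, hi):
            ppm = (mz - masses[i]) / masses[i] * 1e6
            if abs(ppm) <= ppm_tol:
                candidates.append((abs(ppm), formulas[i].format(), ppm, formulas[i]))
        if not candidates:
            continue
        candidates.sort(key=lambda t: (t[0], t[1]))
        _, key, ppm, f = candidates[0]
        prev = best.get(key)
        if prev is None or inten > prev.intensity_norm:
            best[key] = AnnotatedPeak(
                formula=f, mz=mz, intensity_norm=inten, ppm_error=ppm
            )
    peaks = sorted(best.values(), key=lambda p: p.mz)
    if not peaks:
        logger.warning("no peaks annotated for %s", s.query_id)
        return FormulaSpectrum(query_id=s.query_id, group_key=s.group_key)
    max_int = max(p.intensity_norm for p in peaks)
    peaks = [replace(p, intensity_norm=p.intensity_norm / max_int) for p in peaks]
    return FormulaSpectrum(query_id=s.query_id, group_key=s.group_key, peaks=peaks)


# ---------------------------------------------------------------------------
# Consensus construction


def build_consensus(spectra: Sequence[FormulaSpectrum]) -> ConsensusSpectrum:
    """Merge annotated spectra of one group into a consensus spectrum.

    The consensus formula set is the union over constituents; each
    formula keeps the maximum intensity seen.  The result is independent
    of input order and idempotent.
    """
    if not spectra:
        raise ValueError("cannot build a consensus from an empty list")
    keys = {s.group_key for s in spectra}
    if len(keys) > 1:
        raise ValueError(f"mixed group keys in consensus input: {sorted(keys)}")
    best: dict[str, AnnotatedPeak] = {}
    for s in spectra:
        for p in s.peaks:
            key = p.formula.format()
            prev = best.get(key)
            if (
                prev is None
                or p.intensity_norm > prev.intensity_norm
                or (p.intensity_norm == prev.intensity_norm and p.mz < prev.mz)
            ):
                best[key] = p
    peaks = sorted(best.values(), key=lambda p: p.mz)
    return ConsensusSpectrum(group_key=keys.pop(), peaks=peaks)


# ---------------------------------------------------------------------------
# Peak encoding


@dataclass
class NormalizationStats:
    """Per-element maximum atom count over the training annotations."""

    max_count: dict[str, int]

    def to_json(self) -> str:
        return json.dumps({"max_count": self.max_count})

    @classmethod
    def from_json(cls, text: str) -> "NormalizationStats":
        return cls(max_count={k: int(v) for k, v in json.loads(text)["max_count"].items()})


def fit_normalization(training_spectra: Sequence[FormulaSpectrum]) -> NormalizationStats:
    """Per-element max atom count over all annotated peaks (training only)."""
    max_count: dict[str, int] = {}
    n_peaks = 0
    for s in training_spectra:
        for p in s.peaks:
            n_peaks += 1
            for el, c in p.formula.counts.items():
                if c > max_count.get(el, 0):
                    max_count[el] = c
    if n_peaks == 0:
        raise ValueError("no annotated peaks to fit normalization statistics")
    return NormalizationStats(max_count=max_count)


PEAK_VECTOR_DIM = len(ELEMENTS) + 1  # 14 scaled counts + normalized intensity


def peak_to_vector(p: AnnotatedPeak, stats: NormalizationStats) -> np.ndarray:
    """Encode one peak as 14 scaled element counts plus intensity.

    Counts are divided by the training maximum for that element; counts
    for unseen elements, or exceeding the training maximum, clamp to 1
    with a warning.
    """
    v = np.zeros(PEAK_VECTOR_DIM)
    for el, c in p.formula.counts.items():
        idx = ELEMENTS.index(el)
        mx = stats.max_count.get(el, 0)
        if mx <= 0 or c > mx:
            logger.warning(
                "element %s count %d outside training range (max %d); clamping",
                el, c, mx,
            )
            v[idx] = 1.0
        else:
            v[idx] = c / mx
    v[-1] = p.intensity_norm
    return v


def spectrum_to_matrix(
    s: FormulaSpectrum | ConsensusSpectrum, stats: NormalizationStats
) -> np.ndarray:
    """Stack the spectrum's peak vectors into a (n_peaks, 15) matrix."""
    if not s.peaks:
        raise ValueError("cannot encode an empty spectrum")
    return np.stack([peak_to_vector(p, stats) for p in s.peaks])


# ---------------------------------------------------------------------------
# Binned (formula-free) representation


def bin_spectrum(
    s: RawSpectrum,
    bin_width: float = 1.0,
    mz_range: tuple[float, float] = (0.0, 1000.0),
) -> np.ndarray:
    """Fixed-grid binned intensity vector, max per bin, scaled to max 1.

    Out-of-range peaks are dropped with a warning.  An empty spectrum
    maps to the all-zero vector.
    """
    lo, hi = mz_range
    n_bins = math.ceil((hi - lo) / bin_width)
    bins = np.zeros(n_bins)
    for mz, inten in s.peaks:
        if mz < lo or mz >= hi:
            logger.warning("peak at m/z %.4f outside range %s; dropped", mz, mz_range)
            continue
        idx = int((mz - lo) // bin_width)
        bins[idx] = max(bins[idx], inten)
    top = bins.max()
    if top > 0:
        bins /= top
    return bins


# ---------------------------------------------------------------------------
# Cache serialization (annotated + consensus spectra)


def _peak_to_dict(p: AnnotatedPeak) -> dict:
    return {
        "formula": p.formula.format(),
        "mz": p.mz,
        "intensity": p.intensity_norm,
        "ppm": p.ppm_error,
    }


def _peak_from_dict(d: dict) -> AnnotatedPeak:
    return AnnotatedPeak(
        formula=ChemicalFormula.parse(d["formula"]),
        mz=float(d["mz"]),
        intensity_norm=float(d["intensity"]),
        ppm_error=float(d["ppm"]),
    )


def save_cache(
    spectra: Sequence[FormulaSpectrum],
    consensus: Sequence[ConsensusSpectrum],
    stats: NormalizationStats,
    path: str | Path,
) -> None:
    payload = {
        "spectra": [
            {
                "query_id": s.query_id,
                "group_key": s.group_key,
                "peaks": [_peak_to_dict(p) for p in s.peaks],
            }
            for s in spectra
        ],
        "consensus": [
            {
                "group_key": c.group_key,
                "peaks": [_peak_to_dict(p) for p in c.peaks],
            }
            for c in consensus
        ],
        "normalization": {"max_count": stats.max_count},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_cache(
    path: str | Path,
) -> tuple[list[FormulaSpectrum], list[ConsensusSpectrum], NormalizationStats]:
    payload = json.loads(Path(path).read_text())
    spectra = [
        FormulaSpectrum(
            query_id=d["query_id"],
            group_key=d["group_key"],
            peaks=[_peak_from_dict(p) for p in d["peaks"]],
        )
        for d in payload["spectra"]
    ]
    consensus = [
        ConsensusSpectrum(
            group_key=d["group_key"],
            peaks=[_peak_from_dict(p) for p in d["peaks"]],
        )
        for d in payload["consensus"]
    ]
    stats = NormalizationStats(
        max_count={k: int(v) for k, v in payload["normalization"]["max_count"].items()}
    )
    return spectra, consensus, stats
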
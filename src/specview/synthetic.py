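"""Self-contained synthetic molecule/spectrum fixtures.

The generator emulates the statistical structure the model assumes,
without any physical fragmentation modeling: each simulated peak is the
adduct-shifted mass of a true element-wise subformula of its molecule
(plus bounded ppm jitter), intensities follow a geometric decay over
fragment size with multiplicative log-normal noise, and "collision
energy" levels are emulated by structured peak dropout so that the
union of a molecule's spectra is strictly richer than any single one.
Retrieval tasks mirror the production I/O path: MGF spectra, candidate
JSON (by 10 ppm mass window or by exact formula), ground-truth CSV.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chemio import ChemicalFormula, Molecule, formula_mass, parse_molecule
from .ranking import CandidateSet, build_candidates
from .spectra import (
    AnnotatedPeak,
    ConsensusSpectrum,
    FormulaSpectrum,
    RawSpectrum,
    build_consensus,
    enumerate_subformulas,
    write_mgf,
)

# Small real structures (all parseable, all over the supported alphabet),
# including isomer pairs so by-formula candidate sets are not all singletons.
CURATED_SMILES: tuple[str, ...] = (
    "CCO",                     # ethanol
    "COC",                     # dimethyl ether (isomer of ethanol)
    "CCCO",                    # 1-propanol
    "CC(C)O",                  # 2-propanol
    "CCCCO",                   # 1-butanol
    "CCC(C)O",                 # 2-butanol
    "CCCC",                    # butane
    "CC(C)C",                  # isobutane
    "CCOCC",                   # diethyl ether
    "CCCCCO",                  # 1-pentanol
    "CC(=O)O",                 # acetic acid
    "OCC=O",                   # glycolaldehyde (isomer of acetic acid)
    "CCC(=O)O",                # propionic acid
    "CC(=O)OC",                # methyl acetate
    "CCCC(=O)O",               # butyric acid
    "CC(C)C(=O)O",             # isobutyric acid
    "OCC(O)CO",                # glycerol
    "CC(O)C(=O)O",             # lactic acid
    "OCC(=O)CO",               # dihydroxyacetone
    "OC(=O)C=CC(=O)O",         # fumaric/maleic backbone
    "OC(=O)CCC(=O)O",          # succinic acid
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",  # citric acid
    "OC(=O)C(O)C(O)C(=O)O",    # tartaric acid
    "CC(=O)C(=O)O",            # pyruvic acid
    "NCC(=O)O",                # glycine
    "CC(N)C(=O)O",             # alanine
    "CNCC(=O)O",               # sarcosine (isomer of alanine)
    "CC(C)C(N)C(=O)O",         # valine
    "CCC(C)C(N)C(=O)O",        # isoleucine
    "CC(C)CC(N)C(=O)O",        # leucine (isomer of isoleucine)
    "NC(CO)C(=O)O",            # serine
    "CC(O)C(N)C(=O)O",         # threonine
    "NC(CS)C(=O)O",            # cysteine
    "NC(CCS)C(=O)O",           # homocysteine
    "NC(CC(=O)O)C(=O)O",       # aspartic acid
    "NC(CCC(=O)O)C(=O)O",      # glutamic acid
    "NC(=O)CC(N)C(=O)O",       # asparagine
    "NCCCCC(N)C(=O)O",         # lysine
    "OCC1OC(O)C(O)C(O)C1O",    # glucose (pyranose)
    "OCC1(O)OCC(O)C(O)C1O",    # fructose (furanose isomer)
    "OCC(O)C(O)C(O)C(O)C=O",   # open-chain aldohexose
    "OCC1OCC(O)C(O)C1O",       # 1,5-anhydrohexitol
    "OCC(O)C(O)CO",            # erythritol
    "OCC(O)C(O)C(O)CO",        # xylitol
    "c1ccccc1",                # benzene
    "Cc1ccccc1",               # toluene
    "Oc1ccccc1",               # phenol
    "Nc1ccccc1",               # aniline
    "OC(=O)c1ccccc1",          # benzoic acid
    "Oc1ccc(O)cc1",            # hydroquinone
    "Oc1ccccc1O",              # catechol (isomer of hydroquinone)
    "OCc1ccccc1",              # benzyl alcohol
    "COc1ccccc1",              # anisole (isomer of benzyl alcohol)
    "O=Cc1ccccc1",             # benzaldehyde
    "CC(=O)c1ccccc1",          # acetophenone
    "OC(=O)c1ccccc1O",         # salicylic acid
    "CC(=O)Nc1ccccc1",         # acetanilide
    "c1ccncc1",                # pyridine
    "Cc1ccncc1",               # 4-methylpyridine
    "c1cc[nH]c1",              # pyrrole
    "c1ccsc1",                 # thiophene
    "c1ccoc1",                 # furan
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",  # caffeine
    "CC(=O)Oc1ccccc1C(=O)O",   # aspirin
    "NCCc1ccc(O)c(O)c1",       # dopamine
    "NCCc1c[nH]c2ccccc12",     # tryptamine
    "OCCN",                    # ethanolamine
    "NCCCN",                   # 1,3-diaminopropane
    "CSCC",                    # ethyl methyl sulfide
    "CCSCC",                   # diethyl sulfide
    "OP(=O)(O)OCC",            # ethyl phosphate
    "OCC(O)COP(=O)(O)O",       # glycerol phosphate
    "Clc1ccccc1",              # chlorobenzene
    "Fc1ccccc1",               # fluorobenzene
    "OC(=O)CN(CC(=O)O)CC(=O)O",  # nitrilotriacetic acid
    "CC(C)=CCO",               # prenol
    "CC(=O)CC(=O)C",           # acetylacetone
    "OC(=O)CCCCC(=O)O",        # adipic acid
    "OCCO",                    # ethylene glycol
    "OCCCO",                   # 1,3-propanediol
)

_GROW_ATOMS = ("C", "C", "C", "N", "O", "S")
_MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}


@dataclass
class SyntheticConfig:
    """Study conditions for fixture generation.

    ``spectra_per_molecule`` emulates 1-4 spectra at distinct collision
    energies; ``dropout`` is the per-level probability of losing a peak
    that "belongs" to another energy level; ``jitter_ppm`` must stay
    below the annotation tolerance so ground truth is recoverable.
    """

    n_molecules: int = 50
    spectra_per_molecule: int = 3
    n_fragments: int = 12
    intensity_noise: float = 0.3
    dropout: float = 0.5
    jitter_ppm: float = 5.0
    adduct: str = "[M+H]+"
    n_decoys: int = 8
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")
        if not 1 <= self.spectra_per_molecule <= 4:
            raise ValueError("spectra_per_molecule must be 1-4")
        if self.jitter_ppm > 20.0:
            raise ValueError("jitter above the annotation tolerance")


def _grow_random_molecule(rng: np.random.Generator, n_heavy: int) -> str | None:
    """Random single-bonded tree over C/N/O/S; returns canonical SMILES."""
    mol = Chem.RWMol()
    symbols = [str(rng.choice(_GROW_ATOMS))]
    mol.AddAtom(Chem.Atom(symbols[0]))
    degree = [0]
    for _ in range(n_heavy - 1):
        sym = str(rng.choice(_GROW_ATOMS))
        open_sites = [
            i for i, s in enumerate(symbols) if degree[i] < _MAX_VALENCE[s]
        ]
        if not open_sites:
            break
        anchor = int(rng.choice(open_sites))
        idx = mol.AddAtom(Chem.Atom(sym))
        mol.AddBond(anchor, idx, Chem.BondType.SINGLE)
        symbols.append(sym)
        degree.append(1)
        degree[anchor] += 1
    try:
        m = mol.GetMol()
        Chem.SanitizeMol(m)
        return Chem.MolToSmiles(m)
    except Exception:
        return None


def generate_library(cfg: SyntheticConfig) -> list[Molecule]:
    """Deterministic library: curated real structures, then random growth.

    Returns ``cfg.n_molecules`` distinct canonical structures, all over
    the 14-element alphabet.
    """
    rng = np.random.default_rng(cfg.seed)
    seen: set[str] = set()
    out: list[Molecule] = []
    for smi in CURATED_SMILES:
        if len(out) >= cfg.n_molecules:
            break
        mol = parse_molecule(smi, f"M{len(out):04d}")
        if mol.smiles in seen:
            continue
        seen.add(mol.smiles)
        out.append(mol)
    while len(out) < cfg.n_molecules:
        smi = _grow_random_molecule(rng, int(rng.integers(4, 12)))
        if smi is None:
            continue
        mol = parse_molecule(smi, f"M{len(out):04d}")
        if mol.smiles in seen:
            continue
        seen.add(mol.smiles)
        out.append(mol)
    return out


def _resolvable_fragments(
    precursor: ChemicalFormula, adduct: str, min_separation_ppm: float = 40.0
) -> list[ChemicalFormula]:
    """Subformulas whose adduct-shifted masses are mutually resolvable.

    Fragments with a near-isobaric sibling (within ``min_separation_ppm``)
    are excluded so that jittered peaks always re-annotate to their
    generating formula.  Tiny fragments (< 2 atoms or < 24 Da) are also
    excluded.
    """
    subs = [
        f
        for f in enumerate_subformulas(precursor)
        if len(f) >= 2 and f.monoisotopic_mass >= 24.0
    ]
    masses = np.array([formula_mass(f, adduct) for f in subs])
    order = np.argsort(masses)
    keep = np.ones(len(subs), dtype=bool)
    for a, b in zip(order[:-1], order[1:]):
        sep = (masses[b] - masses[a]) / masses[a] * 1e6
        if sep < min_separation_ppm:
            keep[a] = keep[b] = False
    return [subs[i] for i in range(len(subs)) if keep[i]]


def simulate_spectra(
    m: Molecule, cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> list[RawSpectrum]:
    """Simulate one raw spectrum per collision-energy level.

    Fragments are true subformulas of the molecule (precursor formula
    always included); base intensities decay geometrically with
    decreasing fragment mass and carry log-normal noise; each energy
    level owns a disjoint share of the fragments and sees the others'
    with probability ``1 - dropout``, so the union across levels is
    richer than any single level.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pool = _resolvable_fragments(m.formula, cfg.adduct)
    pool = [f for f in pool if f.format() != m.formula.format()]
    n_frag = min(cfg.n_fragments - 1, len(pool))
    chosen = [m.formula] + [
        pool[i] for i in rng.choice(len(pool), size=n_frag, replace=False)
    ] if pool else [m.formula]
    chosen.sort(key=lambda f: -f.monoisotopic_mass)
    base = 0.7 ** np.arange(len(chosen))
    levels = cfg.spectra_per_molecule
    precursor_mz = formula_mass(m.formula, cfg.adduct)
    spectra = []
    owner = np.arange(len(chosen)) % levels
    for level in range(levels):
        peaks = []
        for j, f in enumerate(chosen):
            if owner[j] != level and rng.random() < cfg.dropout:
                continue
            mz = formula_mass(f, cfg.adduct)
            mz *= 1.0 + rng.uniform(-cfg.jitter_ppm, cfg.jitter_ppm) * 1e-6
            inten = base[j] * np.exp(cfg.intensity_noise * rng.standard_normal())
            peaks.append((float(mz), float(1000.0 * inten)))
        if not peaks:  # own share guarantees at least the owned fragments
            continue
        spectra.append(
            RawSpectrum(
                query_id=f"{m.identifier}/e{level}",
                precursor_mz=precursor_mz,
                adduct=cfg.adduct,
                group_key=m.identifier,
                peaks=peaks,
            )
        )
    return spectra


@dataclass
class RetrievalTask:
    """A complete synthetic retrieval benchmark."""

    library: list[Molecule]
    spectra: list[RawSpectrum]
    candidates_by_mass: dict[str, CandidateSet]
    candidates_by_formula: dict[str, CandidateSet]
    ground_truth: dict[str, str]  # group_key -> molecule identifier


def make_retrieval_task(library: Sequence[Molecule], cfg: SyntheticConfig) -> RetrievalTask:
    """Spectra plus mass-window and formula candidate sets per molecule."""
    rng = np.random.default_rng(cfg.seed + 1)
    spectra: list[RawSpectrum] = []
    by_mass: dict[str, CandidateSet] = {}
    by_formula: dict[str, CandidateSet] = {}
    truth: dict[str, str] = {}
    for mol in library:
        spectra.extend(simulate_spectra(mol, cfg, rng))
        by_mass[mol.identifier] = build_candidates(
            mol, library, mode="by_mass", query_id=mol.identifier
        )
        by_formula[mol.identifier] = build_candidates(
            mol, library, mode="by_formula", query_id=mol.identifier
        )
        truth[mol.identifier] = mol.identifier
    return RetrievalTask(
        library=list(library),
        spectra=spectra,
        candidates_by_mass=by_mass,
        candidates_by_formula=by_formula,
        ground_truth=truth,
    )


def random_decoy_candidates(
    target: Molecule,
    library: Sequence[Molecule],
    n_decoys: int,
    rng: np.random.Generator,
) -> CandidateSet:
    """Target plus ``n_decoys`` uniformly drawn distinct library decoys."""
    others = [m for m in library if m.smiles != target.smiles]
    idx = rng.choice(len(others), size=min(n_decoys, len(others)), replace=False)
    return CandidateSet(
        query_id=target.identifier,
        candidates=[target] + [others[i] for i in idx],
        mode="random",
        target_id=target.identifier,
    )


def write_task(task: RetrievalTask, outdir: str | Path) -> None:
    """Write MGF, candidate JSON, formula sidecar and ground-truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_mgf(task.spectra, outdir / "spectra.mgf")
    for name, cands in (
        ("candidates_by_mass.json", task.candidates_by_mass),
        ("candidates_by_formula.json", task.candidates_by_formula),
    ):
        payload = {
            qid: [m.smiles for m in cs.candidates] for qid, cs in sorted(cands.items())
        }
        (outdir / name).write_text(json.dumps(payload, indent=1))
    by_id = {m.identifier: m for m in task.library}
    with open(outdir / "formulas.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["query_id", "formula", "adduct"])
        for s in task.spectra:
            mol = by_id[s.group_key]
            writer.writerow([s.query_id, mol.formula.format(), s.adduct])
    with open(outdir / "ground_truth.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group_key", "identifier", "smiles"])
        for key, ident in sorted(task.ground_truth.items()):
            writer.writerow([key, ident, by_id[ident].smiles])


# ---------------------------------------------------------------------------
# Analytic fragment-profile embedder


class SubformulaProfileEmbedder:
    """Idealized analytic embedder over subformula indicator profiles.

    A molecule is represented by the indicator vector of its complete
    subformula set; a spectrum by the indicator vector of its observed
    peak formulas.  Cosine similarity between the two then measures how
    specifically the observed fragments pin down the candidate — an
    idealization of what the trained encoders learn, useful for
    reasoning about ranking and aggregation semantics in isolation from
    optimization.  Formula positions are assigned from a shared index
    that grows on first sight, so profiles are collision-free.
    """

    def __init__(self, dim: int = 32768):
        self.dim = dim
        self._index: dict[str, int] = {}

    def _slot(self, formula: str) -> int:
        if formula not in self._index:
            if len(self._index) >= self.dim:
                raise ValueError("formula vocabulary exceeds embedder dimension")
            self._index[formula] = len(self._index)
        return self._index[formula]

    def _indicator(self, formulas) -> np.ndarray:
        v = np.zeros(self.dim)
        for f in formulas:
            v[self._slot(f)] = 1.0
        return v

    def embed_molecule(self, mol: Molecule, view: str) -> np.ndarray:
        return self._indicator(f.format() for f in enumerate_subformulas(mol.formula))

    def embed_spectrum(self, spectrum, view: str) -> np.ndarray:
        return self._indicator(p.formula.format() for p in spectrum.peaks)


def _exact_peak(formula: str, adduct: str = "[M+H]+") -> AnnotatedPeak:
    f = ChemicalFormula.parse(formula)
    return AnnotatedPeak(
        formula=f, mz=formula_mass(f, adduct), intensity_norm=1.0, ppm_error=0.0
    )


@dataclass
class ConsensusAdvantageFixture:
    """A constructed case where only the peak union identifies the target.

    The target (1-butanol) yields two spectra: one whose fragments are
    shared with a smaller alcohol (1-propanol), one whose fragments are
    shared with the bare hydrocarbon (butane).  Under the subformula
    profile embedder each single spectrum ranks the respective decoy
    above the target, while the consensus (union) spectrum is only fully
    contained in the target's subformula set.
    """

    candidates: CandidateSet
    spectra: list[FormulaSpectrum]
    consensus: ConsensusSpectrum
    target: Molecule


def consensus_advantage_fixture() -> ConsensusAdvantageFixture:
    target = parse_molecule("CCCCO", "butanol")
    decoy_small = parse_molecule("CCCO", "propanol")
    decoy_hydrocarbon = parse_molecule("CCCC", "butane")
    s1 = FormulaSpectrum(
        query_id="q/e0",
        group_key="q",
        peaks=[_exact_peak("C2H4O"), _exact_peak("C3H6O")],
    )
    s2 = FormulaSpectrum(
        query_id="q/e1",
        group_key="q",
        peaks=[_exact_peak("C4H8"), _exact_peak("C3H6")],
    )
    consensus = build_consensus([s1, s2])
    candidates = CandidateSet(
        query_id="q",
        candidates=[target, decoy_small, decoy_hydrocarbon],
        mode="by_mass",
        target_id="butanol",
    )
    return ConsensusAdvantageFixture(
        candidates=candidates, spectra=[s1, s2], consensus=consensus, target=target
    )
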
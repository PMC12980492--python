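"""Molecule parsing, chemical-formula arithmetic, and the two molecule views.

A molecule enters the pipeline as a SMILES string and contributes two
views to the shared embedding space: a featurized heavy-atom graph and a
1024-bit Morgan fingerprint (radius 5).  Formula arithmetic over the
14-element alphabet ``ELEMENTS`` underpins peak annotation: fragment
peaks are matched to element-wise subformulas of the precursor formula
by monoisotopic mass.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

# The fixed element alphabet of the per-peak encoding, in encoding order.
ELEMENTS: tuple[str, ...] = (
    "C", "H", "O", "N", "P", "S", "Cl", "F", "Br", "I", "B", "As", "Si", "Se",
)
_ELEMENT_INDEX = {e: i for i, e in enumerate(ELEMENTS)}

# Monoisotopic atomic masses (Da), IUPAC standard values.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "O": 15.9949146196,
    "N": 14.0030740048,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "F": 18.99840322,
    "Br": 78.9183371,
    "I": 126.904473,
    "B": 11.0093054,
    "As": 74.9215965,
    "Si": 27.9769265325,
    "Se": 79.9165213,
}

PROTON_MASS = 1.00727646  # H+ (electron mass accounted for)

# Ion mass shift added to the neutral molecule for each supported adduct.
ADDUCT_SHIFTS: dict[str, float] = {
    "none": 0.0,
    "[M+H]+": PROTON_MASS,
    "[M+Na]+": 22.98976928 - 0.00054858,  # Na minus one electron
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed formulas or formulas outside the element alphabet."""


class AdductError(ValueError):
    """Raised for adduct labels with no known mass shift."""


@dataclass(frozen=True)
class ChemicalFormula:
    """An elemental composition over the 14-element alphabet.

    Stored as an immutable element -> count mapping with all counts > 0
    (zero counts are dropped on construction, so equality is canonical).
    """

    counts: Mapping[str, int]

    def __post_init__(self):
        clean = {}
        for el, n in self.counts.items():
            if el not in _ELEMENT_INDEX:
                raise FormulaError(f"element {el!r} outside supported alphabet {ELEMENTS}")
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
            if n > 0:
                clean[el] = int(n)
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "ChemicalFormula":
        if text == "" or text.isspace():
            return cls({})
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
            if not m.group(0):
                break
            el, num = m.group(1), m.group(2)
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
            pos = m.end()
        if pos != len(text):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        return cls(counts)

    def format(self) -> str:
        """Hill-order text form: C, H, then remaining elements alphabetically."""
        parts = []
        rest = sorted(e for e in self.counts if e not in ("C", "H"))
        order = [e for e in ("C", "H") if e in self.counts] + rest
        for el in order:
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def count(self, element: str) -> int:
        return self.counts.get(element, 0)

    @property
    def monoisotopic_mass(self) -> float:
        return sum(n * MONOISOTOPIC_MASS[el] for el, n in self.counts.items())

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ChemicalFormula(merged)

    def is_subformula_of(self, other: "ChemicalFormula") -> bool:
        return all(n <= other.count(el) for el, n in self.counts.items())

    def to_vector(self) -> np.ndarray:
        """Counts as a length-14 vector in ``ELEMENTS`` order."""
        v = np.zeros(len(ELEMENTS))
        for el, n in self.counts.items():
            v[_ELEMENT_INDEX[el]] = n
        return v

    def __len__(self) -> int:
        return sum(self.counts.values())

    def __str__(self) -> str:
        return self.format()


def formula_mass(f: ChemicalFormula, adduct: str = "none") -> float:
    """Monoisotopic mass of ``f`` shifted by the adduct ion mass.

    ``adduct="none"`` returns the neutral mass.  Unknown labels raise
    :class:`AdductError` listing the supported adducts.
    """
    if adduct not in ADDUCT_SHIFTS:
        raise AdductError(
            f"unknown adduct {adduct!r}; supported: {sorted(ADDUCT_SHIFTS)}"
        )
    return f.monoisotopic_mass + ADDUCT_SHIFTS[adduct]


class SmilesParseError(ValueError):
    pass


@dataclass(frozen=True)
class Molecule:
    """A parsed structure with its formula and neutral monoisotopic mass."""

    identifier: str
    smiles: str  # canonical
    formula: ChemicalFormula
    monoisotopic_mass: float
    in_alphabet: bool = True
    _mol: Chem.Mol = field(repr=False, compare=False, hash=False, default=None)

    @property
    def rdkit_mol(self) -> Chem.Mol:
        return self._mol


def parse_molecule(smiles: str, identifier: str = "") -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    The structure is canonicalized so that formula, mass, graph and
    fingerprint are functions of the structure rather than of the input
    SMILES dialect.  Molecules containing elements outside the 14-element
    alphabet are flagged (``in_alphabet=False``): they keep usable graph
    and fingerprint views but cannot take part in formula-based peak
    annotation.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    counts: dict[str, int] = {}
    in_alphabet = True
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        counts[sym] = counts.get(sym, 0) + 1
        counts["H"] = counts.get("H", 0) + atom.GetTotalNumHs()
        if sym not in _ELEMENT_INDEX:
            in_alphabet = False
    if in_alphabet:
        formula = ChemicalFormula(counts)
        mass = formula.monoisotopic_mass
    else:
        formula = ChemicalFormula({el: n for el, n in counts.items() if el in _ELEMENT_INDEX})
        from rdkit.Chem.Descriptors import ExactMolWt

        mass = ExactMolWt(mol)
    return Molecule(
        identifier=identifier or canonical,
        smiles=canonical,
        formula=formula,
        monoisotopic_mass=mass,
        in_alphabet=in_alphabet,
        _mol=mol,
    )


# ---------------------------------------------------------------------------
# Graph view


@dataclass
class MolecularGraph:
    """Featurized heavy-atom graph.

    ``edge_index`` holds both directions of every bond (shape ``(2, 2m)``);
    ``node_features`` has one row per heavy atom; hydrogens appear only as
    a per-node hydrogen-count feature.
    """

    node_features: np.ndarray  # (n, NODE_FEATURE_DIM)
    edge_index: np.ndarray  # (2, 2m) int
    edge_features: np.ndarray  # (2m, EDGE_FEATURE_DIM)

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1] // 2


_CHIRALITY_TAGS = [
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
]
_BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]
_BOND_STEREO = [
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
]

# one-hot(atom type: 14 + other) | mass/100 | valence | ring | charge |
# radicals | one-hot(chirality: 3 + other) | degree | H count | aromatic
NODE_FEATURE_DIM = 15 + 1 + 1 + 1 + 1 + 1 + 4 + 1 + 1 + 1
# one-hot(bond type: 4 + other) | ring | conjugated | one-hot(stereo: 3 + other)
EDGE_FEATURE_DIM = 5 + 1 + 1 + 4


def _one_hot(value, choices, size):
    v = np.zeros(size)
    try:
        v[choices.index(value)] = 1.0
    except ValueError:
        v[size - 1] = 1.0  # "other" bucket
    return v


def featurize_graph(m: Molecule) -> MolecularGraph:
    """Build the graph view: per-heavy-atom and per-bond feature vectors.

    Feature groups per node: atom type, atomic mass, valence, ring
    membership, formal charge, radical electrons, chirality, degree,
    hydrogen count, aromaticity.  Per bond: bond type, ring membership,
    conjugation, stereo configuration.  Single-atom molecules yield a
    valid graph with zero edges.
    """
    mol = m.rdkit_mol
    nodes = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        feat = np.concatenate([
            _one_hot(sym, list(ELEMENTS), 15),
            [atom.GetMass() / 100.0],
            [float(atom.GetTotalValence())],
            [float(atom.IsInRing())],
            [float(atom.GetFormalCharge())],
            [float(atom.GetNumRadicalElectrons())],
            _one_hot(atom.GetChiralTag(), _CHIRALITY_TAGS, 4),
            [float(atom.GetDegree())],
            [float(atom.GetTotalNumHs())],
            [float(atom.GetIsAromatic())],
        ])
        nodes.append(feat)
    src, dst, efeat = [], [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = np.concatenate([
            _one_hot(bond.GetBondType(), _BOND_TYPES, 5),
            [float(bond.IsInRing())],
            [float(bond.GetIsConjugated())],
            _one_hot(bond.GetStereo(), _BOND_STEREO, 4),
        ])
        src += [i, j]
        dst += [j, i]
        efeat += [f, f]
    return MolecularGraph(
        node_features=np.array(nodes).reshape(len(nodes), NODE_FEATURE_DIM),
        edge_index=np.array([src, dst], dtype=int).reshape(2, len(src)),
        edge_features=(
            np.array(efeat).reshape(len(efeat), EDGE_FEATURE_DIM)
            if efeat
            else np.zeros((0, EDGE_FEATURE_DIM))
        ),
    )


# ---------------------------------------------------------------------------
# Fingerprint view

FINGERPRINT_BITS = 1024
FINGERPRINT_RADIUS = 5

_morgan = rdFingerprintGenerator.GetMorganGenerator(
    radius=FINGERPRINT_RADIUS, fpSize=FINGERPRINT_BITS
)


def fingerprint(m: Molecule) -> np.ndarray:
    """Binary Morgan fingerprint (1024 bits, radius 5) as a 0/1 vector."""
    fp = _morgan.GetFingerprint(m.rdkit_mol)
    arr = np.zeros(FINGERPRINT_BITS, dtype=np.float64)
    for bit in fp.GetOnBits():
        arr[bit] = 1.0
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    inter = float(np.sum((a > 0) & (b > 0)))
    union = float(np.sum((a > 0) | (b > 0)))
    return inter / union if union else 1.0


# ---------------------------------------------------------------------------
# I/O


def read_molecules(path: str | Path) -> list[Molecule]:
    """Read molecules from JSON ({id: smiles}) or two-column delimited text."""
    path = Path(path)
    out = []
    if path.suffix.lower() == ".json":
        mapping = json.loads(path.read_text())
        for ident, smi in mapping.items():
            out.append(parse_molecule(smi, ident))
    else:
        for line_no, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = re.split(r"[\t,]\s*|\s+", line)
            if len(fields) < 2:
                raise ValueError(f"{path}:{line_no}: expected 'identifier smiles'")
            out.append(parse_molecule(fields[1], fields[0]))
    return out
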
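import numpy as np
import pytest

from specview.chemio import parse_molecule
from specview.encoders import EncoderConfig, MultiViewModel
from specview.spectra import (
    AnnotatedPeak,
    FormulaSpectrum,
    NormalizationStats,
)
from specview.chemio import ChemicalFormula, formula_mass


@pytest.fixture(scope="session")
def glucose():
    return parse_molecule("OCC1OC(O)C(O)C(O)C1O", "glucose")


@pytest.fixture(scope="session")
def benzene():
    return parse_molecule("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def tiny_model():
    return MultiViewModel(EncoderConfig(embedding_dim=16, hidden=32), seed=0)


@pytest.fixture(scope="session")
def small_stats():
    return NormalizationStats(max_count={"C": 20, "H": 40, "O": 10, "N": 6, "S": 3})


def make_annotated(query_id, group_key, formula_intensities, adduct="[M+H]+"):
    """Helper: FormulaSpectrum from (formula string, intensity) pairs."""
    peaks = []
    for f, inten in formula_intensities:
        cf = ChemicalFormula.parse(f)
        peaks.append(
            AnnotatedPeak(
                formula=cf,
                mz=formula_mass(cf, adduct),
                intensity_norm=inten,
                ppm_error=0.0,
            )
        )
    return FormulaSpectrum(query_id=query_id, group_key=group_key, peaks=peaks)


@pytest.fixture
def make_spectrum():
    return make_annotated
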
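"""MGF I/O, peak filtering, subformula annotation, consensus, encodings."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from specview.chemio import ChemicalFormula, formula_mass
from specview.spectra import (
    AnnotatedPeak,
    FormulaSpectrum,
    MgfError,
    NormalizationStats,
    RawSpectrum,
    SubformulaCapError,
    annotate_peaks,
    bin_spectrum,
    build_consensus,
    enumerate_subformulas,
    filter_top_peaks,
    fit_normalization,
    load_cache,
    peak_to_vector,
    read_mgf,
    save_cache,
    subformula_count,
    spectrum_to_matrix,
    write_mgf,
)
from conftest import make_annotated


class TestMgfIO:
    def test_roundtrip_two_blocks(self, tmp_path):
        spectra = [
            RawSpectrum("q1", 181.07, "[M+H]+", "g1", [(57.03, 10.0), (181.07, 5.0)]),
            RawSpectrum("q2", 120.0, "[M+H]+", "g1", [(60.0, 1.0)]),
        ]
        path = tmp_path / "two.mgf"
        write_mgf(spectra, path)
        back = read_mgf(path)
        assert len(back) == 2
        assert back[0].query_id == "q1"
        assert back[0].adduct == "[M+H]+"
        assert back[0].group_key == "g1"
        assert back[0].peaks == pytest.approx(spectra[0].peaks)

    def test_empty_file_empty_list(self, tmp_path):
        p = tmp_path / "empty.mgf"
        p.write_text("")
        assert read_mgf(p) == []

    def test_unsorted_peaks_stored_sorted(self):
        s = RawSpectrum("q", 100.0, peaks=[(90.0, 1.0), (50.0, 2.0), (70.0, 3.0)])
        assert [p[0] for p in s.peaks] == [50.0, 70.0, 90.0]

    def test_missing_pepmass_raises(self, tmp_path):
        p = tmp_path / "bad.mgf"
        p.write_text("BEGIN IONS\nTITLE=x\n100.0 1.0\nEND IONS\n")
        with pytest.raises(MgfError, match="PEPMASS"):
            read_mgf(p)


class TestFilterTopPeaks:
    def test_selection_property(self):
        rng = np.random.default_rng(0)
        peaks = [(float(mz), float(i)) for mz, i in
                 zip(rng.uniform(50, 500, 100), rng.uniform(0, 100, 100))]
        s = filter_top_peaks(RawSpectrum("q", 600.0, peaks=peaks), 60)
        kept = {p[1] for p in s.peaks}
        dropped = {p[1] for p in peaks} - kept
        assert len(s.peaks) == 60
        assert min(kept) >= max(dropped)

    def test_under_capacity_keeps_all(self):
        s = RawSpectrum("q", 100.0, peaks=[(float(i), 1.0 * i) for i in range(1, 11)])
        assert len(filter_top_peaks(s, 60).peaks) == 10

    def test_tie_keeps_lower_mz(self):
        peaks = [(float(i), 1.0) for i in range(1, 11)]
        s = filter_top_peaks(RawSpectrum("q", 100.0, peaks=peaks), 5)
        assert [p[0] for p in s.peaks] == [1.0, 2.0, 3.0, 4.0, 5.0]


class TestEnumerateSubformulas:
    @pytest.mark.parametrize(
        "formula,expected",
        [("CH4", 9), ("C2", 2), ("C6H12O6", 636)],
    )
    def test_counts(self, formula, expected):
        f = ChemicalFormula.parse(formula)
        subs = list(enumerate_subformulas(f))
        assert len(subs) == expected == subformula_count(f)
        assert len(set(s.format() for s in subs)) == expected  # all distinct

    def test_every_subformula_elementwise_bounded(self):
        f = ChemicalFormula.parse("C3H6O2")
        for sub in enumerate_subformulas(f):
            assert sub.is_subformula_of(f)
            assert len(sub) >= 1

    def test_cap_raises_before_enumerating(self):
        with pytest.raises(SubformulaCapError, match="mass window"):
            list(enumerate_subformulas(ChemicalFormula.parse("C100H200O50"), cap=1000))


class TestAnnotatePeaks:
    def test_exact_match_zero_ppm(self):
        f = ChemicalFormula.parse("C6H12O6")
        frag = ChemicalFormula.parse("C2H4O2")
        s = RawSpectrum(
            "q", formula_mass(f, "[M+H]+"), "[M+H]+", "g",
            [(formula_mass(frag, "[M+H]+"), 10.0)],
        )
        fs = annotate_peaks(s, f)
        assert len(fs.peaks) == 1
        assert fs.peaks[0].formula == frag
        assert fs.peaks[0].ppm_error == pytest.approx(0.0, abs=1e-9)
        assert fs.peaks[0].intensity_norm == 1.0

    def test_out_of_tolerance_dropped(self):
        f = ChemicalFormula.parse("C6H12O6")
        frag = ChemicalFormula.parse("C2H4O2")
        mz = formula_mass(frag, "[M+H]+") * (1 + 25e-6)
        fs = annotate_peaks(
            RawSpectrum("q", 181.0, "[M+H]+", "g", [(mz, 10.0)]), f, ppm_tol=20.0
        )
        assert len(fs.peaks) == 0

    def test_duplicate_formula_keeps_most_intense_then_renormalizes(self):
        f = ChemicalFormula.parse("C6H12O6")
        frag = ChemicalFormula.parse("C2H4O2")
        base = formula_mass(frag, "[M+H]+")
        s = RawSpectrum(
            "q", 181.0, "[M+H]+", "g",
            [(base * (1 + 3e-6), 0.4), (base * (1 - 3e-6), 0.9)],
        )
        fs = annotate_peaks(s, f)
        assert len(fs.peaks) == 1
        assert fs.peaks[0].intensity_norm == 1.0

    def test_ppm_errors_bounded_and_zero_tol_exact_only(self):
        f = ChemicalFormula.parse("C6H12O6")
        rng = np.random.default_rng(3)
        subs = list(enumerate_subformulas(f))
        peaks = []
        for i in rng.choice(len(subs), 10, replace=False):
            mz = formula_mass(subs[i], "[M+H]+") * (1 + rng.uniform(-10e-6, 10e-6))
            peaks.append((float(mz), 1.0))
        fs = annotate_peaks(RawSpectrum("q", 181.0, "[M+H]+", "g", peaks), f)
        assert all(abs(p.ppm_error) <= 20.0 for p in fs.peaks)
        fs0 = annotate_peaks(RawSpectrum("q", 181.0, "[M+H]+", "g", peaks), f, ppm_tol=0.0)
        assert all(p.ppm_error == 0.0 for p in fs0.peaks)


class TestConsensus:
    def test_union_max_rule(self):
        s1 = make_annotated("q1", "g", [("C2H4O2", 0.4), ("CH2O", 0.2)])
        s2 = make_annotated("q2", "g", [("C2H4O2", 0.9)])
        c = build_consensus([s1, s2])
        by_f = {p.formula.format(): p.intensity_norm for p in c.peaks}
        assert by_f == {"C2H4O2": 0.9, "CH2O": 0.2}

    def test_idempotent_and_order_invariant(self):
        s1 = make_annotated("q1", "g", [("C2H4O2", 0.4), ("CH2O", 0.2)])
        s2 = make_annotated("q2", "g", [("C2H4O2", 0.9), ("C3H6O", 0.5)])
        s3 = make_annotated("q3", "g", [("CH2O", 1.0)])
        ref = build_consensus([s1, s2, s3])
        for perm in ([s3, s1, s2], [s2, s3, s1]):
            c = build_consensus(perm)
            assert c.formulas == ref.formulas
            assert [(p.formula.format(), p.intensity_norm) for p in c.peaks] == [
                (p.formula.format(), p.intensity_norm) for p in ref.peaks
            ]
        single = build_consensus([s1])
        assert single.formulas == s1.formulas

    def test_constituents_subset_of_consensus(self):
        rng = np.random.default_rng(7)
        pool = ["CH2O", "C2H4O2", "C3H6O", "C2H2", "C4H8O2", "CHN", "C2H5N"]
        spectra = []
        for i in range(5):
            picks = rng.choice(len(pool), size=rng.integers(1, 5), replace=False)
            spectra.append(
                make_annotated(f"q{i}", "g", [(pool[j], float(rng.uniform(0.1, 1))) for j in picks])
            )
        c = build_consensus(spectra)
        for s in spectra:
            assert s.formulas <= c.formulas

    def test_mixed_groups_rejected(self):
        s1 = make_annotated("q1", "g1", [("CH2O", 1.0)])
        s2 = make_annotated("q2", "g2", [("CH2O", 1.0)])
        with pytest.raises(ValueError, match="mixed group"):
            build_consensus([s1, s2])


class TestPeakVector:
    def test_scaled_counts_and_intensity(self, small_stats):
        stats = NormalizationStats(max_count={"C": 60, "H": 120, "O": 60})
        p = make_annotated("q", "g", [("C6H12O6", 1.0)]).peaks[0]
        v = peak_to_vector(p, stats)
        assert v[:3] == pytest.approx([0.1, 0.1, 0.1])  # C, H, O slots
        assert np.all(v[3:14] == 0.0)
        assert v[14] == 1.0

    def test_clamp_and_warning(self, caplog):
        stats = NormalizationStats(max_count={"C": 3, "H": 100, "O": 100})
        p = make_annotated("q", "g", [("C6H12O6", 0.5)]).peaks[0]
        with caplog.at_level("WARNING"):
            v = peak_to_vector(p, stats)
        assert v[0] == 1.0
        assert "clamping" in caplog.text

    def test_unclamped_counts_invertible(self):
        stats = NormalizationStats(max_count={"C": 12, "H": 30, "O": 8, "N": 4})
        p = make_annotated("q", "g", [("C7H14O3N2", 0.8)]).peaks[0]
        v = peak_to_vector(p, stats)
        maxes = np.array([12, 30, 8, 4])
        recovered = np.round(v[:4] * maxes).astype(int)
        assert list(recovered) == [7, 14, 3, 2]
        assert np.all((0 <= v) & (v <= 1))


class TestFitNormalization:
    def test_elementwise_max(self):
        s = make_annotated("q", "g", [("C6H12O6", 1.0), ("C2H4O2", 0.3)])
        stats = fit_normalization([s])
        assert stats.max_count == {"C": 6, "H": 12, "O": 6}

    def test_empty_training_set_raises(self):
        with pytest.raises(ValueError):
            fit_normalization([])

    def test_deterministic(self):
        s = make_annotated("q", "g", [("C6H12O6", 1.0)])
        assert fit_normalization([s]).max_count == fit_normalization([s]).max_count


class TestBinSpectrum:
    def test_single_peak_single_bin(self):
        v = bin_spectrum(RawSpectrum("q", 100.0, peaks=[(150.5, 42.0)]))
        assert v.shape == (1000,)
        assert v[150] == 1.0
        assert v.sum() == 1.0

    def test_max_in_bin_then_rescale(self):
        v = bin_spectrum(
            RawSpectrum("q", 100.0, peaks=[(10.2, 3.0), (10.7, 5.0), (20.5, 2.5)])
        )
        assert v[10] == 1.0
        assert v[20] == 0.5

    def test_empty_all_zero(self):
        assert bin_spectrum(RawSpectrum("q", 100.0, peaks=[])).sum() == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(1.0, 999.0), st.floats(0.1, 100.0)), min_size=1, max_size=30))
    def test_peak_order_invariance(self, peaks):
        a = bin_spectrum(RawSpectrum("q", 100.0, peaks=peaks))
        b = bin_spectrum(RawSpectrum("q", 100.0, peaks=list(reversed(peaks))))
        assert np.array_equal(a, b)


def test_cache_roundtrip(tmp_path, small_stats):
    s = make_annotated("q1", "g", [("C2H4O2", 1.0), ("CH2O", 0.5)])
    c = build_consensus([s])
    path = tmp_path / "cache.json"
    save_cache([s], [c], small_stats, path)
    spectra, consensus, stats = load_cache(path)
    assert spectra[0].formulas == s.formulas
    assert consensus[0].formulas == c.formulas
    assert stats.max_count == small_stats.max_count
    mat = spectrum_to_matrix(spectra[0], stats)
    assert mat.shape == (2, 15)
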
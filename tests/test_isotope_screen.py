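"""Cu doublet screening of centroided spectra."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cuspec.chem_core import IsotopePattern
from cuspec.isotope_screen import (
    CU_DOUBLET_RATIO,
    PeakList,
    find_doublets,
    read_mgf,
    read_tsv,
    score_pattern,
    write_hits_tsv,
    write_tsv,
)


def simple_spectrum(pairs, polarity="-"):
    return PeakList.from_peaks(pairs, polarity=polarity)


class TestPeakList:
    def test_rejects_non_monotone_mz(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            PeakList(np.array([300.0, 300.0]), np.array([1.0, 1.0]))

    def test_rejects_nonpositive_intensity(self):
        with pytest.raises(ValueError, match="positive"):
            PeakList(np.array([300.0]), np.array([0.0]))

    def test_rejects_peaks_outside_scan_range(self):
        with pytest.raises(ValueError, match="scan range"):
            PeakList(np.array([10.0]), np.array([1.0]))

    def test_tsv_roundtrip(self, tmp_path):
        sp = simple_spectrum([(300, 1000), (302, 449)])
        write_tsv(sp, tmp_path / "s.tsv")
        back = read_tsv(tmp_path / "s.tsv", polarity="-")
        assert np.allclose(back.mz, sp.mz)
        assert np.allclose(back.intensity, sp.intensity)

    def test_mgf_reading(self, tmp_path):
        mgf = tmp_path / "s.mgf"
        mgf.write_text(
            "BEGIN IONS\nTITLE=test\nPEPMASS=300\nCHARGE=1-\n"
            "300.0 1000\n302.0 449\nEND IONS\n"
        )
        spectra = read_mgf(mgf)
        assert len(spectra) == 1
        assert spectra[0].polarity == "-"
        assert np.allclose(spectra[0].mz, [300.0, 302.0])


class TestScorePattern:
    def test_proportional_patterns_score_one(self):
        theo = IsotopePattern(((300.0, 100.0), (302.0, 44.9)))
        obs = simple_spectrum([(300, 2000), (302, 898)])
        assert score_pattern(obs, theo) == pytest.approx(1.0, abs=1e-12)

    def test_missing_partner_scores_0912(self):
        """(100, 0) against the Cu doublet (100, 44.9): hand-computable
        cosine = 100 / sqrt(100^2 + 44.9^2)."""
        theo = IsotopePattern(((300.0, 100.0), (302.0, 44.9)))
        obs = simple_spectrum([(300, 100)])
        assert score_pattern(obs, theo) == pytest.approx(0.912, abs=5e-4)

    def test_disjoint_masses_score_zero(self):
        theo = IsotopePattern(((300.0, 100.0),))
        obs = simple_spectrum([(500, 100)])
        assert score_pattern(obs, theo) == 0.0


class TestFindDoublets:
    def test_textbook_doublet_found(self):
        sp = simple_spectrum([(300, 1000), (302, 449)])
        hits = find_doublets(sp)
        assert len(hits) == 1
        assert hits[0].mz_A == 300.0
        assert hits[0].ratio == pytest.approx(0.449, abs=1e-3)
        assert hits[0].pattern_score > 0.99

    def test_equal_intensities_rejected(self):
        sp = simple_spectrum([(300, 1000), (302, 1000)])
        assert find_doublets(sp) == []

    def test_empty_spectrum_empty_result(self):
        sp = PeakList(np.array([]), np.array([]))
        assert find_doublets(sp) == []

    def test_planted_complexes_recovered_exactly(self, table2_spectrum):
        """Noise-free 5-complex spectrum -> exactly the 5 planted anchors;
        the A+1/A+3 satellite pairs of each cluster must not double-count."""
        spectrum, manifest = table2_spectrum
        hits = find_doublets(spectrum)
        assert sorted(h.mz_A for h in hits) == sorted(
            float(c["mz"]) for c in manifest["complexes"]
        )

    def test_planted_complexes_survive_10x_noise(self, noisy_table2_spectrum):
        spectrum, manifest = noisy_table2_spectrum
        anchors = {h.mz_A for h in find_doublets(spectrum)}
        for c in manifest["complexes"]:
            assert float(c["mz"]) in anchors

    def test_pure_noise_hits_reported_not_suppressed(self):
        """The screen is a pre-filter: chance doublets in dense noise are
        reported, never silently dropped."""
        from cuspec.synthetic_data import SpectrumRecipe, gen_spectrum

        counts = []
        for seed in range(5):
            sp, _ = gen_spectrum(
                SpectrumRecipe(complexes=(), noise_peaks=400, seed=seed)
            )
            counts.append(len(find_doublets(sp)))
        assert all(c >= 0 for c in counts)  # runs, returns without error

    def test_deterministic_for_fixed_input(self, noisy_table2_spectrum):
        spectrum, _ = noisy_table2_spectrum
        assert find_doublets(spectrum) == find_doublets(spectrum)

    def test_hits_sorted_and_within_windows(self, noisy_table2_spectrum):
        spectrum, _ = noisy_table2_spectrum
        hits = find_doublets(spectrum)
        scores = [h.pattern_score for h in hits]
        assert scores == sorted(scores, reverse=True)
        for h in hits:
            assert abs(h.mz_A2 - h.mz_A - 2.0) <= 0.5
            assert (
                CU_DOUBLET_RATIO * 0.75 <= h.ratio <= CU_DOUBLET_RATIO * 1.25
            )

    def test_hits_tsv(self, tmp_path, table2_spectrum):
        spectrum, _ = table2_spectrum
        hits = find_doublets(spectrum)
        out = tmp_path / "hits.tsv"
        write_hits_tsv(hits, out)
        header = out.read_text().splitlines()[0].split("\t")
        assert header == ["mz_A", "mz_A2", "ratio", "score"]

    @given(st.floats(min_value=2.0, max_value=50.0))
    def test_intensity_scale_invariance(self, scale):
        sp = simple_spectrum([(300, 1000), (302, 449), (500, 80)])
        scaled = simple_spectrum(
            [(300, 1000 * scale), (302, 449 * scale), (500, 80 * scale)]
        )
        h1 = find_doublets(sp)
        h2 = find_doublets(scaled)
        assert [h.mz_A for h in h1] == [h.mz_A for h in h2]
        assert h1[0].ratio == pytest.approx(h2[0].ratio)
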
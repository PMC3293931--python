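"""Dinucleotide densities, flank extraction and the feature layout."""

import numpy as np
import pytest

from ptaref.duplex_finder import CandidateSite
from ptaref.errors import InvariantError, ParameterError
from ptaref.feature_extractor import (DINUCLEOTIDES, FeatureConfig,
                                      build_feature_vector,
                                      dinucleotide_density, extract_flanks,
                                      feature_names, select_features,
                                      vectors_from_tsv, vectors_to_tsv)
from ptaref.fixtures import make_training_set
from ptaref.sequence_io import TranscriptRecord


def _random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


def density_oracle(window: str) -> np.ndarray:
    """Naive substring scan."""
    out = np.zeros(16)
    for i, d in enumerate(DINUCLEOTIDES):
        out[i] = sum(window[j:j + 2] == d for j in range(len(window) - 1))
    return out / (len(window) - 1)


class TestDinucleotideDensity:
    def test_homopolymer(self):
        v = dinucleotide_density("AAAA")
        assert v[DINUCLEOTIDES.index("AA")] == 1.0
        assert v.sum() == 1.0 and np.count_nonzero(v) == 1

    def test_acgu(self):
        v = dinucleotide_density("ACGU")
        for d in ("AC", "CG", "GU"):
            assert v[DINUCLEOTIDES.index(d)] == pytest.approx(1 / 3)
        assert v.sum() == pytest.approx(1.0)

    def test_matches_substring_oracle_on_random_windows(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            w = _random_rna(rng, 20)
            v = dinucleotide_density(w)
            assert np.allclose(v, density_oracle(w), atol=1e-12)
            assert abs(v.sum() - 1.0) < 1e-12

    def test_too_short_window_rejected(self):
        with pytest.raises(InvariantError):
            dinucleotide_density("A")


class TestExtractFlanks:
    def test_interior_site_flank_coordinates(self):
        rng = np.random.default_rng(0)
        t = TranscriptRecord("t", _random_rna(rng, 400))
        site = CandidateSite("t", "m", 100, 121, -20.0)
        up, down, tu, td = extract_flanks(t, site)
        assert up == t.seq[25:100] and down == t.seq[121:196]
        assert not tu and not td

    def test_near_start_site_truncates_upstream(self):
        rng = np.random.default_rng(1)
        t = TranscriptRecord("t", _random_rna(rng, 200))
        site = CandidateSite("t", "m", 10, 31, -20.0)
        up, _, tu, td = extract_flanks(t, site)
        assert len(up) == 10 and tu and not td

    def test_reported_strings_reslice_by_coordinates(self):
        rng = np.random.default_rng(2)
        t = TranscriptRecord("t", _random_rna(rng, 350))
        for _ in range(20):
            start = int(rng.integers(0, 329))
            site = CandidateSite("t", "m", start, start + 21, -20.0)
            up, down, _, _ = extract_flanks(t, site)
            assert up == t.seq[max(0, start - 75):start]
            assert down == t.seq[start + 21:start + 21 + 75]


class TestBuildFeatureVector:
    def test_default_layout_length(self):
        rng = np.random.default_rng(3)
        t = TranscriptRecord("t", _random_rna(rng, 400))
        site = CandidateSite("t", "m", 150, 171, -20.0)
        for mode in ("raw", "delta_from_site"):
            fv = build_feature_vector(t, site, FeatureConfig(variation_mode=mode))
            assert len(fv) == 2 * 56 * 16 == 1792

    def test_homogeneous_context_gives_zero_delta_profile(self):
        t = TranscriptRecord("t", "A" * 400)
        site = CandidateSite("t", "m", 150, 171, -20.0)
        fv = build_feature_vector(t, site, FeatureConfig(variation_mode="delta_from_site"))
        assert np.all(fv.values == 0.0)

    def test_window_sums_raw_one_delta_zero(self):
        rng = np.random.default_rng(9)
        t = TranscriptRecord("t", _random_rna(rng, 400))
        site = CandidateSite("t", "m", 150, 171, -20.0)
        raw = build_feature_vector(t, site, FeatureConfig(variation_mode="raw"))
        delta = build_feature_vector(t, site, FeatureConfig(variation_mode="delta_from_site"))
        assert np.allclose(raw.values.reshape(-1, 16).sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(delta.values.reshape(-1, 16).sum(axis=1), 0.0, atol=1e-12)

    def test_matches_independent_per_window_loop_oracle(self):
        rng = np.random.default_rng(9)
        t = TranscriptRecord("t", _random_rna(rng, 400))
        site = CandidateSite("t", "m", 180, 201, -20.0)
        cfg = FeatureConfig(variation_mode="delta_from_site")
        fv = build_feature_vector(t, site, cfg)

        up = t.seq[site.start - 75:site.start]
        down = t.seq[site.end:site.end + 75]
        ref = density_oracle(t.seq[site.start:site.start + 20])
        expected = []
        for k in range(56):  # upstream, proximal (adjacent to site) first
            expected.append(density_oracle(up[75 - 20 - k:75 - k]) - ref)
        for k in range(56):  # downstream, proximal first
            expected.append(density_oracle(down[k:k + 20]) - ref)
        assert np.allclose(fv.values, np.concatenate(expected), atol=1e-12)

    def test_truncated_windows_zero_filled_and_flagged(self):
        rng = np.random.default_rng(4)
        t = TranscriptRecord("t", _random_rna(rng, 300))
        site = CandidateSite("t", "m", 30, 51, -20.0)  # only 30 nt upstream
        fv = build_feature_vector(t, site, FeatureConfig(variation_mode="raw"))
        assert fv.truncated_upstream and not fv.truncated_downstream
        blocks = fv.values.reshape(2, 56, 16)
        # upstream windows needing more than 30 nt are missing -> zeros
        assert np.all(blocks[0, 11:] == 0.0)
        assert np.all(blocks[0, :11].sum(axis=1) == pytest.approx(1.0))

    def test_pure_function_bit_identical(self):
        rng = np.random.default_rng(6)
        t = TranscriptRecord("t", _random_rna(rng, 400))
        site = CandidateSite("t", "m", 100, 121, -20.0)
        a = build_feature_vector(t, site)
        b = build_feature_vector(t, site)
        assert np.array_equal(a.values, b.values)


class TestSelectFeatures:
    def test_constant_feature_ranked_last(self):
        rng = np.random.default_rng(8)
        pos = rng.standard_normal((30, 5))
        neg = rng.standard_normal((30, 5))
        pos[:, 2] = neg[:, 2] = 1.0  # zero variance everywhere
        order = select_features(pos, neg, k=5)
        assert order[-1] == 2

    def test_planted_five_sd_shift_ranked_first(self):
        ts = make_training_set(n=80, shift=5.0, seed=4, n_features=40, n_informative=1)
        order = select_features(ts.pos, ts.neg, k=40)
        assert order[0] == ts.informative[0]

    def test_full_k_returns_a_permutation(self):
        ts = make_training_set(n=40, shift=1.0, seed=2, n_features=25, n_informative=3)
        order = select_features(ts.pos, ts.neg, k=25)
        assert sorted(order) == list(range(25))

    def test_invalid_k_rejected(self):
        ts = make_training_set(n=20, shift=1.0, seed=1, n_features=10, n_informative=2)
        with pytest.raises(ParameterError):
            select_features(ts.pos, ts.neg, k=0)
        with pytest.raises(ParameterError):
            select_features(ts.pos, ts.neg, k=11)


class TestSerialization:
    def test_tsv_roundtrip_preserves_layout_assignment(self, tmp_path):
        rng = np.random.default_rng(10)
        t = TranscriptRecord("t", _random_rna(rng, 400))
        cfg = FeatureConfig()
        vectors = [build_feature_vector(t, CandidateSite("t", "m", s, s + 21, -20.0), cfg)
                   for s in (100, 150, 200)]
        p = tmp_path / "features.tsv"
        vectors_to_tsv(vectors, cfg, p)
        back = vectors_from_tsv(p, cfg)
        assert len(back) == 3
        for a, b in zip(vectors, back):
            assert np.allclose(a.values, b.values, atol=1e-12)
            assert b.layout == cfg.layout_descriptor()
        # header names identify (side, window, dinucleotide) slots
        header = p.read_text().splitlines()[0].split("\t")
        assert header[0] == "up_w00_AA" and header[-1] == "down_w55_UU"
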
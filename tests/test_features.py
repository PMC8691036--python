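"""Feature statistics, the 84-entry vector, and the class-conditional scores."""

import numpy as np
import pytest

from csnet.features import (
    FEATURE_NAMES,
    N_FEATURES,
    FeatureModel,
    FeatureScaler,
    featurize,
    fit_feature_model,
    kmer_frequencies,
    kmer_score,
    nucleotide_bias,
)
from csnet.orf import find_longest_orf
from csnet.sequence_io import SequenceRecord


def _model_from_arrays(pos_freq_m, pos_freq_l, kmer_mean_m=None, kmer_mean_l=None,
                       mode="weighted"):
    """Build a FeatureModel directly from given statistics (uniform defaults)."""
    uni = {r: {k: np.full(4**k, 1.0 / 4**k) for k in (1, 2, 3, 4, 5, 6)}
           for r in ("whole", "orf")}
    def _wrap(d):
        return {r: {k: np.asarray(v[k]) for k in v} for r, v in d.items()} if d else uni
    return FeatureModel(
        pos_freq={"mRNA": np.asarray(pos_freq_m), "lncRNA": np.asarray(pos_freq_l)},
        kmer_mean={"mRNA": _wrap(kmer_mean_m), "lncRNA": _wrap(kmer_mean_l)},
        kmer_score_mode=mode,
    )


UNIFORM_POS = np.full((6, 4), 0.25)


class TestKmerFrequencies:
    @pytest.mark.parametrize(
        "seq, k, expected",
        [
            ("AAAA", 1, {0: 1.0}),
            ("ACGT", 2, {0 * 4 + 1: 1 / 3, 1 * 4 + 2: 1 / 3, 2 * 4 + 3: 1 / 3}),
            ("AT", 3, {}),
            ("", 1, {}),
        ],
    )
    def test_examples(self, seq, k, expected):
        f = kmer_frequencies(seq, k)
        assert f.shape == (4**k,)
        want = np.zeros(4**k)
        for i, v in expected.items():
            want[i] = v
        np.testing.assert_allclose(f, want)

    def test_frequencies_sum_to_one_when_long_enough(self, rng):
        for k in range(1, 7):
            seq = "".join(rng.choice(list("ACGT"), 50))
            assert kmer_frequencies(seq, k).sum() == pytest.approx(1.0, abs=1e-9)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            kmer_frequencies("ACGT", 7)


class TestFitFeatureModel:
    def test_identical_classes_give_identical_statistics(self):
        seqs = [SequenceRecord("a", "CCCATGAAATAACCC"), SequenceRecord("b", "GGGATGCCCTAGGGG")]
        seqs2 = [SequenceRecord(r.id + "x", r.seq) for r in seqs]
        m = fit_feature_model(seqs, seqs2)
        np.testing.assert_allclose(m.pos_freq["mRNA"], m.pos_freq["lncRNA"])
        for region in ("whole", "orf"):
            for k in (1, 3, 6):
                np.testing.assert_allclose(
                    m.kmer_mean["mRNA"][region][k], m.kmer_mean["lncRNA"][region][k]
                )

    def test_single_observation_positional_frequency(self):
        # ORF starts at index 3: upstream CCC, downstream codon AAA
        rec = [SequenceRecord("a", "CCCATGAAATAA")]
        m = fit_feature_model(rec, rec)
        downstream_first = m.pos_freq["mRNA"][3]  # offset +4, 1-based
        assert downstream_first[0] > 0.99  # A carries all observed mass
        np.testing.assert_allclose(m.pos_freq["mRNA"].sum(axis=1), np.ones(6), atol=1e-12)

    def test_kmer_mean_hand_computed(self):
        recs = [SequenceRecord("a", "AAAA"), SequenceRecord("b", "CCCC")]
        ctx = [SequenceRecord("c", "CCCATGAAATAA")]  # provides the start context
        m = fit_feature_model(recs + ctx, recs + ctx)
        # mean 1-mer over {AAAA, CCCC, CCCATGAAATAA}: hand-computed then smoothed
        raw = np.mean([
            [1, 0, 0, 0],
            [0, 1, 0, 0],
            [6 / 12, 3 / 12, 1 / 12, 2 / 12],
        ], axis=0)
        want = (raw + m.pseudocount) / (raw + m.pseudocount).sum()
        np.testing.assert_allclose(m.kmer_mean["mRNA"]["whole"][1], want, atol=1e-12)

    def test_no_usable_context_raises(self):
        # ORF at position 0: no upstream context anywhere in the class
        rec = [SequenceRecord("a", "ATGAAATAA")]
        with pytest.raises(ValueError, match="context"):
            fit_feature_model(rec, rec)

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            fit_feature_model([], [SequenceRecord("a", "CCCATGAAATAA")])


class TestNucleotideBias:
    def test_identical_model_scores_zero(self):
        m = _model_from_arrays(UNIFORM_POS, UNIFORM_POS)
        seq = "CCCATGAAATAACCC"
        assert nucleotide_bias(seq, find_longest_orf(seq), m) == pytest.approx(0.0)

    def test_orf_at_start_missing_offsets_contribute_zero(self):
        m = _model_from_arrays(UNIFORM_POS, UNIFORM_POS)
        seq = "ATGAAATAA"
        assert nucleotide_bias(seq, find_longest_orf(seq), m) == pytest.approx(0.0)

    def test_constructed_log_ratio(self):
        # all six context bases are A; p_mRNA(A)=0.4, p_lncRNA(A)=0.2 everywhere
        pm = np.tile([0.4, 0.2, 0.2, 0.2], (6, 1))
        pl = np.tile([0.2, 0.4, 0.2, 0.2], (6, 1))
        m = _model_from_arrays(pm, pl)
        seq = "AAAATGAAATAA"
        assert nucleotide_bias(seq, find_longest_orf(seq), m) == pytest.approx(
            np.log(2.0), abs=1e-12
        )

    def test_no_orf_scores_zero(self):
        m = _model_from_arrays(UNIFORM_POS, UNIFORM_POS)
        assert nucleotide_bias("CCCCCC", find_longest_orf("CCCCCC"), m) == 0.0


class TestKmerScore:
    def test_identical_model_zero_both_modes(self):
        for mode in ("weighted", "literal"):
            m = _model_from_arrays(UNIFORM_POS, UNIFORM_POS, mode=mode)
            assert kmer_score("ACGTACGT", m, 2, "whole") == pytest.approx(0.0)

    def test_literal_mode_is_sequence_independent(self):
        km = {"whole": {k: np.full(4**k, 1.0 / 4**k) for k in range(1, 7)},
              "orf": {k: np.full(4**k, 1.0 / 4**k) for k in range(1, 7)}}
        km_l = {r: {k: v / v.sum() for k, v in
                    {kk: np.linspace(1, 2, 4**kk) for kk in range(1, 7)}.items()}
                for r in ("whole", "orf")}
        m = _model_from_arrays(UNIFORM_POS, UNIFORM_POS, km, km_l, mode="literal")
        vals = {kmer_score(s, m, 3, "whole") for s in ("AAAAAA", "ACGTACGT", "GGGCCC")}
        assert len(vals) == 1

    def test_weighted_mode_picks_out_sequence_composition(self):
        r = np.array([0.3, -0.1, 0.2, -0.4])
        mm = {"whole": {1: np.exp(r) / 4}, "orf": {1: np.exp(r) / 4}}
        ml = {"whole": {1: np.full(4, 0.25)}, "orf": {1: np.full(4, 0.25)}}
        for k in range(2, 7):
            for d, v in ((mm, np.full(4**k, 1.0 / 4**k)), (ml, np.full(4**k, 1.0 / 4**k))):
                d["whole"][k] = v
                d["orf"][k] = v
        m = _model_from_arrays(UNIFORM_POS, UNIFORM_POS, mm, ml)
        # log(M_m/M_l) = r - log(4) + log(4) ... exp(r)/4 over 1/4 -> ratio exp(r)
        assert kmer_score("AAAA", m, 1, "whole") == pytest.approx(r[0], abs=1e-12)

    def test_empty_region_scores_zero(self):
        m = _model_from_arrays(UNIFORM_POS, UNIFORM_POS)
        assert kmer_score("", m, 3, "orf") == 0.0


@pytest.fixture(scope="module")
def model(small_classes):
    pos, neg = small_classes
    return fit_feature_model(train_mRNA=neg, train_lncRNA=pos)


class TestFeaturize:
    def test_length_is_84(self, model, small_dataset):
        records, _ = small_dataset
        for rec in records[:20]:
            assert featurize(rec, model).shape == (N_FEATURES,)
        assert len(FEATURE_NAMES) == 84

    def test_no_atg_degenerate_blocks(self, model):
        vec = featurize(SequenceRecord("x", "CCCCCCCCCC"), model)
        assert vec[0] == 0  # orf_length
        assert vec[1] == 0 and vec[2] == 0  # both coverage slots
        np.testing.assert_allclose(vec[8:72], 0)  # tri_orf
        np.testing.assert_allclose(vec[78:84], 0)  # kscore_orf
        assert vec[4:8].sum() == pytest.approx(1.0)  # mono_whole still live

    def test_identical_class_model_zeroes_log_ratio_features(self, small_classes):
        pos, _ = small_classes
        m = fit_feature_model(train_mRNA=pos, train_lncRNA=pos)
        vec = featurize(pos[0], m)
        assert vec[3] == pytest.approx(0.0, abs=1e-12)  # nucleotide_bias
        np.testing.assert_allclose(vec[72:84], 0, atol=1e-12)  # all kscores

    def test_coverage_pair_exclusive(self, model, small_dataset):
        records, _ = small_dataset
        for rec in records:
            vec = featurize(rec, model)
            assert (vec[1] == 0) or (vec[2] == 0)
            assert 0 <= vec[1] <= 1 and 0 <= vec[2] <= 1

    def test_mono_whole_sums_to_one(self, model, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), int(rng.integers(5, 300))))
            vec = featurize(SequenceRecord("x", seq), model)
            assert vec[4:8].sum() == pytest.approx(1.0, abs=1e-9)

    def test_class_swap_negates_log_ratio_features(self, small_classes):
        pos, neg = small_classes
        m_ab = fit_feature_model(train_mRNA=neg, train_lncRNA=pos)
        m_ba = fit_feature_model(train_mRNA=pos, train_lncRNA=neg)
        for rec in (pos[0], neg[0], pos[3]):
            va, vb = featurize(rec, m_ab), featurize(rec, m_ba)
            assert va[3] == pytest.approx(-vb[3], abs=1e-10)
            np.testing.assert_allclose(va[72:84], -vb[72:84], atol=1e-10)
            # non-log-ratio blocks unchanged
            np.testing.assert_allclose(va[:3], vb[:3])
            np.testing.assert_allclose(va[4:72], vb[4:72])

    def test_weighted_score_invariant_to_duplication(self, model):
        seq = "ATGGCCGAGAAGTAA"
        s1 = kmer_score(seq, model, 3, "whole")
        s8 = kmer_score(seq * 8, model, 3, "whole")
        assert s8 == pytest.approx(s1, abs=0.15)  # edge-window effects only

    def test_model_json_roundtrip(self, model, small_dataset, tmp_path):
        records, _ = small_dataset
        model.scaler = FeatureScaler.fit(np.stack([featurize(r, model) for r in records[:10]]))
        p = tmp_path / "fm.json"
        model.to_json(p)
        back = FeatureModel.from_json(p)
        for rec in records[:5]:
            np.testing.assert_allclose(featurize(rec, model), featurize(rec, back))
        np.testing.assert_allclose(back.scaler.mins, model.scaler.mins)


class TestFeatureScaler:
    def test_training_data_maps_into_unit_interval(self, rng):
        X = rng.normal(size=(50, 6)) * 10
        s = FeatureScaler.fit(X)
        T = s.transform(X)
        assert T.min() >= -1e-12 and T.max() <= 1 + 1e-12

    def test_constant_column_maps_to_zero(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0]])
        T = FeatureScaler.fit(X).transform(X)
        np.testing.assert_allclose(T[:, 1], 0.0)
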
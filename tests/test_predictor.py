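"""Peptide-similarity scoring, cross-validation, metrics, calibration, training."""

from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from ptmcross import predictor as pred
from ptmcross import simulate as sim
from ptmcross.io import ModSite, PeptideWindow, ProteinRecord, SiteDataset, windows_for_sites
from ptmcross.predictor import (
    ConfusionCounts,
    ContractError,
    GPSModel,
    SubstitutionMatrix,
    calibrate_thresholds,
    compute_metrics,
    gps_score,
    k_fold_cv,
    loo_validation,
    peptide_similarity,
    predict,
    roc_curve,
)


def _win(letters, pid="p", pos=1, m=None, n=None):
    if m is None:
        m = len(letters) // 2
        n = len(letters) - m - 1
    return PeptideWindow(pid, pos, m, n, letters)


MATRIX = SubstitutionMatrix.blosum62()


class TestPeptideSimilarity:
    def test_self_similarity_pure_tyrosine(self):
        w = _win("YYYYY")
        # BLOSUM62 diagonal for Y is 7
        assert peptide_similarity(w, w, MATRIX, np.ones(5)) == 35.0

    def test_padding_is_inert(self):
        a = _win("*****")
        b = _win("YDEAG")
        assert peptide_similarity(a, b, MATRIX, np.ones(5)) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            peptide_similarity(_win("YYY"), _win("YYYYY"), MATRIX, np.ones(3))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_naive_loop(self, seed):
        rng = np.random.default_rng(seed)
        letters = list(pred.ALPHABET)
        a = _win("".join(rng.choice(letters, 5)))
        b = _win("".join(rng.choice(letters, 5)))
        weights = rng.uniform(0, 2, size=5)
        expected = max(
            0.0,
            sum(w * MATRIX.lookup(x, y) for w, x, y in zip(weights, a.letters, b.letters)),
        )
        assert peptide_similarity(a, b, MATRIX, weights) == pytest.approx(expected)


class TestGpsScore:
    def test_single_positive_identical_candidate(self):
        w = _win("DDYEE", pid="q", pos=9)
        model = GPSModel(MATRIX, np.ones(5), (2, 2), [_win("DDYEE", pid="t", pos=3)])
        assert gps_score(w, model) == peptide_similarity(w, w, MATRIX, np.ones(5))

    def test_exclude_self_scores_against_other_only(self):
        me = _win("DDYEE", pid="a", pos=3)
        other = _win("GGYLL", pid="b", pos=3)
        model = GPSModel(MATRIX, np.ones(5), (2, 2), [me, other])
        expected = peptide_similarity(me, other, MATRIX, np.ones(5))
        assert gps_score(me, model, exclude_self=True) == pytest.approx(expected)

    def test_empty_positive_set_rejected(self):
        model = GPSModel(MATRIX, np.ones(5), (2, 2), [_win("DDYEE", pid="a", pos=3)])
        with pytest.raises(ContractError):
            gps_score(_win("DDYEE", pid="a", pos=3), model, exclude_self=True)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(11)
        letters = list(pred.ALPHABET[:-1])
        positives = [
            _win("".join(rng.choice(letters, 7)), pid=f"t{i}", pos=4) for i in range(20)
        ]
        weights = rng.uniform(0, 2, size=7)
        model = GPSModel(MATRIX, weights, (3, 3), positives)
        cand = _win("".join(rng.choice(letters, 7)), pid="q", pos=4)
        expected = np.mean(
            [peptide_similarity(cand, p, MATRIX, weights) for p in positives]
        )
        assert gps_score(cand, model) == pytest.approx(expected)


def _separable_dataset(n=6):
    """Positives in pure-acidic context, negatives in pure-leucine context."""
    proteins, sites = [], []
    for i in range(n):
        seq = "DDDDDDDYDDDDDDD" + "G" * 5 + "LLLLLLLYLLLLLLL"
        pid = f"sep{i}"
        proteins.append(ProteinRecord(pid, seq))
        sites.append(ModSite(pid, 8, "Y", "sulfation"))
    return SiteDataset(proteins, sites)


class TestValidation:
    def test_separable_data_gives_perfect_aroc(self):
        ds = _separable_dataset()
        model = GPSModel.default(
            windows_for_sites(ds.proteins, ds.positives("sulfation"), 7, 7)
        )
        assert loo_validation(model, ds).roc.aroc == 1.0

    def test_aroc_equals_normalized_mann_whitney_u(self, base_loo):
        pos, neg = base_loo.pos_scores, base_loo.neg_scores
        u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert base_loo.roc.aroc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_aroc_mwu_identity_with_heavy_ties(self):
        pos = [1.0, 2.0, 2.0, 3.0]
        neg = [1.0, 2.0, 2.0, 2.0, 0.0]
        roc = roc_curve(pos, neg)
        u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert roc.aroc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_kfold_deterministic_given_seed(self, base_model, standard_dataset):
        a = k_fold_cv(base_model, standard_dataset, 4, seed=123)
        b = k_fold_cv(base_model, standard_dataset, 4, seed=123)
        assert np.array_equal(a.pos_scores, b.pos_scores)
        assert a.roc.aroc == b.roc.aroc

    def test_kfold_separable_perfect_for_all_k(self):
        ds = _separable_dataset(n=10)
        model = GPSModel.default(
            windows_for_sites(ds.proteins, ds.positives("sulfation"), 7, 7)
        )
        for k in (4, 6, 8, 10):
            assert k_fold_cv(model, ds, k, seed=0).roc.aroc == 1.0

    def test_kfold_close_to_loo_on_standard_fixture(self, base_model, standard_dataset, base_loo):
        for k in (4, 6, 8, 10):
            cv = k_fold_cv(base_model, standard_dataset, k, seed=42)
            assert abs(cv.roc.aroc - base_loo.roc.aroc) <= 0.03

    def test_k_larger_than_positives_rejected(self, base_model):
        ds = _separable_dataset(n=3)
        model = GPSModel.default(
            windows_for_sites(ds.proteins, ds.positives("sulfation"), 7, 7)
        )
        with pytest.raises(ContractError):
            k_fold_cv(model, ds, k=5, seed=0)


class TestMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(10, 0, 10, 0))
        assert (m.ac, m.sn, m.sp, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_perfectly_wrong_classifier(self):
        m = compute_metrics(ConfusionCounts(0, 10, 0, 10))
        assert m.ac == 0.0
        assert m.mcc == -1.0

    def test_undefined_metrics_are_none(self):
        m = compute_metrics(ConfusionCounts(0, 0, 5, 0))
        assert m.sn is None and m.mcc is None

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exact_rational_arithmetic(self, seed):
        rng = np.random.default_rng(seed)
        tp, fp, tn, fn = (int(x) for x in rng.integers(1, 200, size=4))
        m = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
        assert m.ac == pytest.approx(float(Fraction(tp + tn, tp + fp + tn + fn)))
        assert m.sn == pytest.approx(float(Fraction(tp, tp + fn)))
        assert m.sp == pytest.approx(float(Fraction(tn, tn + fp)))
        num = Fraction(tp * tn - fp * fn)
        den2 = Fraction((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        assert m.mcc**2 == pytest.approx(float(num * num / den2))
        assert (m.mcc >= 0) == (num >= 0)


class TestCalibration:
    def test_order_statistics_cutoff(self):
        thr = calibrate_thresholds([], np.arange(1.0, 101.0), {"medium": 0.90})
        assert thr.levels["medium"].cutoff == 91.0
        assert thr.levels["medium"].achieved_sp == 0.90

    def test_unreachable_target_moves_just_above_max(self):
        thr = calibrate_thresholds([], np.arange(1.0, 101.0), {"top": 1.0})
        assert thr.levels["top"].cutoff > 100.0
        assert thr.levels["top"].achieved_sp == 1.0

    def test_achieved_sp_meets_target_on_fixture(self, base_loo):
        thr = calibrate_thresholds(base_loo.pos_scores, base_loo.neg_scores)
        for name, target in pred.DEFAULT_SP_TARGETS.items():
            assert thr.levels[name].achieved_sp >= target

    def test_cutoffs_ordered_by_specificity(self, base_loo):
        thr = calibrate_thresholds(base_loo.pos_scores, base_loo.neg_scores)
        assert (
            thr.levels["high"].cutoff
            >= thr.levels["medium"].cutoff
            >= thr.levels["low"].cutoff
        )


@pytest.fixture(scope="module")
def signal_dataset():
    spec = sim.SyntheticSpec(
        seed=9, n_pos=60, n_neg=300, n_proteins=40, window=(3, 3),
        motif={-3: {}, -2: {}, -1: {"D": 0.5, "E": 0.3}, 1: {}, 2: {}, 3: {}},
    )
    return sim.generate_motif_dataset(spec)[0]


class TestTraining:
    def test_motif_length_selection_covers_informative_flanks(self):
        spec = sim.SyntheticSpec(
            seed=5, n_pos=100, n_neg=500, n_proteins=60, window=(3, 3),
            motif={-3: {}, -2: {}, -1: {"D": 0.45, "E": 0.35},
                   1: {"Y": 0.35, "D": 0.2}, 2: {"Y": 0.35}, 3: {}},
        )
        ds, _ = sim.generate_motif_dataset(spec)
        best, arocs = pred.motif_length_selection(ds, grid=[(1, 1), (1, 2), (2, 2), (3, 3)])
        assert best[0] >= 1 and best[1] >= 2

    def test_single_candidate_grid(self, signal_dataset):
        best, _ = pred.motif_length_selection(signal_dataset, grid=[(2, 2)])
        assert best == (2, 2)

    def test_selection_deterministic(self, signal_dataset):
        grid = [(1, 1), (2, 2), (3, 3)]
        assert pred.motif_length_selection(signal_dataset, grid) == \
            pred.motif_length_selection(signal_dataset, grid)

    def test_zero_iterations_change_nothing(self, signal_dataset):
        ds = signal_dataset
        model = GPSModel.default(
            windows_for_sites(ds.proteins, ds.positives("sulfation"), 3, 3), (3, 3)
        )
        wt = pred.weight_training(model, ds, iterations=0, seed=0)
        assert np.array_equal(wt.weights, model.weights)
        mm = pred.matrix_mutation(model, ds, iterations=0, seed=0)
        assert np.array_equal(mm.matrix.scores, model.matrix.scores)

    def test_training_never_decreases_loo_aroc(self, signal_dataset):
        ds = signal_dataset
        model = GPSModel.default(
            windows_for_sites(ds.proteins, ds.positives("sulfation"), 3, 3), (3, 3)
        )
        before = loo_validation(model, ds).roc.aroc
        wt = pred.weight_training(model, ds, iterations=60, seed=2)
        after_wt = loo_validation(wt, ds).roc.aroc
        assert after_wt >= before
        mm = pred.matrix_mutation(wt, ds, iterations=60, seed=3)
        assert loo_validation(mm, ds).roc.aroc >= after_wt

    def test_signal_weight_grows_relative_to_noise(self, signal_dataset):
        ds = signal_dataset
        model = GPSModel.default(
            windows_for_sites(ds.proteins, ds.positives("sulfation"), 3, 3), (3, 3)
        )
        wt = pred.weight_training(model, ds, iterations=150, seed=1)
        signal = wt.weights[2]  # the -1 position
        noise = [wt.weights[i] for i in (0, 1, 4, 5, 6)]  # flanks except center
        assert signal > np.median(noise)

    def test_matrix_stays_symmetric_after_many_mutations(self, signal_dataset):
        ds = signal_dataset
        model = GPSModel.default(
            windows_for_sites(ds.proteins, ds.positives("sulfation"), 3, 3), (3, 3)
        )
        mm = pred.matrix_mutation(model, ds, iterations=200, seed=4)
        s = mm.matrix.scores
        assert np.array_equal(s, s.T)
        pad = pred._INDEX["*"]
        assert not s[pad].any()


class TestPredict:
    def test_no_tyrosine_yields_empty(self, trained_model):
        assert predict([ProteinRecord("p", "MADDEG")], trained_model) == []

    def test_threshold_nesting(self, trained_model, standard_dataset):
        proteins = list(standard_dataset.proteins.values())[:30]
        calls = {
            level: {(s.protein_id, s.position) for s in predict(proteins, trained_model, level)}
            for level in ("high", "medium", "low")
        }
        assert calls["high"] <= calls["medium"] <= calls["low"]

    def test_counts_match_score_then_filter_oracle(self, trained_model, standard_dataset):
        proteins = list(standard_dataset.proteins.values())[:5]
        cutoff = trained_model.thresholds.cutoff("medium")
        expected = set()
        for rec in proteins:
            for i, aa in enumerate(rec.sequence, start=1):
                if aa != "Y":
                    continue
                from ptmcross.io import extract_window

                w = extract_window(rec, i, *trained_model.window)
                if gps_score(w, trained_model) >= cutoff:
                    expected.add((rec.id, i))
        got = {(s.protein_id, s.position) for s in predict(proteins, trained_model, "medium")}
        assert got == expected

    def test_model_json_round_trip(self, trained_model):
        back = GPSModel.from_json(trained_model.to_json())
        assert np.array_equal(back.matrix.scores, trained_model.matrix.scores)
        assert np.array_equal(back.weights, trained_model.weights)
        assert back.window == trained_model.window
        assert back.thresholds.cutoff("high") == trained_model.thresholds.cutoff("high")
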
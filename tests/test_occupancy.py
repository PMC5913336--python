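"""PWM scanning, occupancy profiles and precision-recall evaluation."""

import numpy as np
import pytest

from hipfa.occupancy import (
    GammaKernel,
    precision_recall,
    predict_profile,
    scan_pwm,
)
from hipfa.specificity import BASES, Pwm

TOY = Pwm(matrix=np.array([
    [0.7, 0.1, 0.1, 0.1],
    [0.1, 0.7, 0.1, 0.1],
    [0.1, 0.1, 0.1, 0.7],
]))

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq):
    return seq.translate(COMPLEMENT)[::-1]


def brute_force_scores(pwm, seq):
    """Exhaustive per-window sum over both strands."""
    lo = np.log2(pwm.matrix / pwm.background)
    w = len(pwm)
    out = []
    for i in range(len(seq) - w + 1):
        best = []
        for window in (seq[i : i + w], revcomp(seq[i : i + w])):
            s = 0.0
            for j, b in enumerate(window):
                if b in BASES:
                    s += lo[j, BASES.index(b)]
            best.append(s)
        out.append(max(best))
    return np.array(out)


class TestScanPwm:
    def test_uniform_pwm_scores_zero(self):
        pwm = Pwm(matrix=np.full((3, 4), 0.25))
        assert np.allclose(scan_pwm(pwm, "ACGTACGTAC"), 0.0)

    def test_matches_brute_force_oracle(self):
        seq = "ACGTTGCATG"
        assert np.allclose(scan_pwm(TOY, seq), brute_force_scores(TOY, seq), atol=1e-12)

    def test_reverse_complement_mirrors_scores(self):
        seq = "ACGTTGCATGGA"
        fwd = scan_pwm(TOY, seq)
        rev = scan_pwm(TOY, revcomp(seq))
        assert np.allclose(fwd, rev[::-1], atol=1e-12)

    def test_ambiguous_base_scored_as_background(self):
        with_n = scan_pwm(TOY, "ACN")
        assert with_n.shape == (1,)
        lo = np.log2(TOY.matrix / TOY.background)
        fwd = lo[0, 0] + lo[1, 1]  # A, C contribute; N contributes 0
        rev = lo[1, 2] + lo[2, 3]  # revcomp 'NGT': N, G, T
        assert with_n[0] == pytest.approx(max(fwd, rev))


class TestPredictProfile:
    def test_closed_chromatin_suppresses_everything(self):
        scores = np.full(10, 3.0)
        prof = predict_profile(scores, np.zeros(12), GammaKernel(truncation_bp=5))
        assert np.allclose(prof.values, 0.0)

    def test_single_site_is_shifted_kernel(self):
        kernel = GammaKernel(shape=2.0, scale_bp=3.0, truncation_bp=10)
        scores = np.full(41, -100.0)
        scores[20] = 2.0
        acc = np.ones(43)  # pwm width 3 -> site center at offset + 1
        prof = predict_profile(scores, acc, kernel, score_threshold=0.0)
        k = kernel.discretize()
        expected = np.zeros(43)
        center = 21
        expected[center - 10 : center + 11] = 4.0 * k
        assert np.allclose(prof.values, expected, atol=1e-12)

    def test_two_sites_superpose_linearly(self):
        kernel = GammaKernel(shape=2.0, scale_bp=3.0, truncation_bp=8)
        scores = np.full(60, -100.0)
        scores[10] = 1.0
        scores[40] = 2.0
        acc = np.ones(62)
        prof = predict_profile(scores, acc, kernel)
        # direct convolution oracle
        impulses = np.zeros(62)
        impulses[11] = 2.0
        impulses[41] = 4.0
        expected = np.convolve(impulses, kernel.discretize(), mode="same")
        assert np.allclose(prof.values, expected, atol=1e-12)

    def test_kernel_preserves_signal_mass(self):
        kernel = GammaKernel(shape=2.0, scale_bp=100.0, truncation_bp=1000)
        scores = np.full(4001, -100.0)
        scores[2000] = 3.0
        acc = np.ones(4003)
        prof = predict_profile(scores, acc, kernel)
        assert prof.values.sum() == pytest.approx(8.0, rel=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            predict_profile(np.ones(10), np.ones(5), GammaKernel())


class TestPrecisionRecall:
    def test_perfect_prediction_reaches_corner(self):
        values = np.array([0.0, 0.0, 1.0, 1.0, 0.0])
        truth = values > 0.5
        curve = precision_recall(values, truth)
        assert any(
            p == pytest.approx(1.0) and r == pytest.approx(1.0)
            for p, r in zip(curve.precision, curve.recall)
        )

    def test_constant_predictor_has_prevalence_precision(self):
        values = np.full(10, 0.7)
        truth = np.zeros(10, dtype=bool)
        truth[:3] = True
        curve = precision_recall(values, truth)
        at_full_recall = curve.precision[np.isclose(curve.recall, 1.0)]
        assert at_full_recall[0] == pytest.approx(0.3)

    def test_matches_confusion_matrix_oracle(self):
        values = np.array([0.1, 0.9, 0.4, 0.8, 0.3, 0.7, 0.2, 0.6])
        truth = np.array([0, 1, 0, 1, 1, 1, 0, 0], dtype=bool)
        curve = precision_recall(values, truth)
        for thr in np.unique(values):
            pred = values >= thr
            tp = (pred & truth).sum()
            prec = tp / pred.sum()
            rec = tp / truth.sum()
            found = [
                (p, r)
                for p, r in zip(curve.precision, curve.recall)
                if p == pytest.approx(prec) and r == pytest.approx(rec)
            ]
            assert found, f"threshold {thr}: ({prec}, {rec}) missing"

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError, match="truth"):
            precision_recall(np.ones(5), np.zeros(5, dtype=bool))

    def test_recall_monotone_along_threshold_sweep(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(size=200)
        truth = rng.uniform(size=200) < 0.2
        curve = precision_recall(values, truth)
        assert np.all(np.diff(curve.recall) <= 0)  # sklearn orders by rising threshold
        assert 0.0 <= curve.auc <= 1.0


def test_pseudocounts_do_not_change_auc_materially():
    """On a planted-site synthetic region, +0.01 pseudo-counts leave AUC stable."""
    from hipfa.occupancy import evaluate_regions
    from hipfa.specificity import apply_pseudocounts, enumerate_point_mutants, KdTable, pwm_from_kds

    consensus = "TAATCC"
    rng = np.random.default_rng(8)
    variants = {
        (pos, base): float(10 ** rng.uniform(0.8, 1.8))
        for pos, base, _ in enumerate_point_mutants(consensus)
    }
    pwm = pwm_from_kds(KdTable(consensus=consensus, consensus_kd=2.0, variants=variants))
    pwm_pc = apply_pseudocounts(pwm.matrix, mode="hipfa")

    seq = "".join(rng.choice(list("ACGT"), size=3000))
    sites = [300, 1200, 2400]
    for s in sites:
        seq = seq[:s] + consensus + seq[s + len(consensus):]
    truth = np.zeros(len(seq), dtype=bool)
    for s in sites:
        truth[s - 60 : s + 66] = True
    acc = np.ones(len(seq))
    kernel = GammaKernel(shape=2.0, scale_bp=30.0, truncation_bp=200)

    aucs = [
        evaluate_regions(m, [("r", seq, acc, truth)], kernel=kernel, score_threshold=0.0).auc
        for m in (pwm, pwm_pc)
    ]
    assert abs(aucs[0] - aucs[1]) < 0.02
    assert aucs[0] > 0.5  # planted sites are actually found
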
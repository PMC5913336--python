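"""K_D-derived PWMs, information content and pseudo-counts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hipfa.specificity import (
    BASES,
    IncompleteTableError,
    KdTable,
    Pwm,
    apply_pseudocounts,
    enumerate_point_mutants,
    information_content,
    per_position_information,
    pwm_from_kds,
)


def complete_table(consensus, consensus_kd, variant_kd):
    """KdTable with one K_D for the consensus and a common K_D for variants."""
    variants = {
        (pos, base): variant_kd
        for pos, base, _ in enumerate_point_mutants(consensus)
    }
    return KdTable(consensus=consensus, consensus_kd=consensus_kd, variants=variants)


class TestEnumerateMutants:
    def test_bcd_consensus_has_33_variants(self):
        variants = enumerate_point_mutants("CGGTAATCCCT")
        assert len(variants) == 33
        assert len({seq for _, _, seq in variants}) == 33

    def test_single_base(self):
        assert {seq for _, _, seq in enumerate_point_mutants("A")} == {"C", "G", "T"}

    def test_every_variant_at_hamming_distance_one(self):
        consensus = "ACGTTGCA"
        for pos, base, seq in enumerate_point_mutants(consensus):
            diffs = [i for i, (a, b) in enumerate(zip(consensus, seq)) if a != b]
            assert diffs == [pos]
            assert seq[pos] == base != consensus[pos]

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            enumerate_point_mutants("ACGN")


class TestPwmFromKds:
    def test_equal_kds_give_uniform_column(self):
        pwm = pwm_from_kds(complete_table("ACG", 10.0, 10.0))
        assert np.allclose(pwm.matrix, 0.25)

    def test_ten_fold_kd_column(self):
        # K_Ds (1, 10, 10, 10) -> weights (1, 0.1, 0.1, 0.1)/1.3
        pwm = pwm_from_kds(complete_table("A", 1.0, 10.0))
        assert pwm.matrix[0, 0] == pytest.approx(1.0 / 1.3, abs=1e-5)
        assert pwm.matrix[0, 1] == pytest.approx(0.1 / 1.3, abs=1e-5)
        assert pwm.matrix[0] == pytest.approx([0.76923, 0.07692, 0.07692, 0.07692], abs=1e-5)

    def test_cad_fold_loss_weight_ratio(self):
        # consensus 0.05 nM vs worst mutant 2.2 nM: 44-fold affinity loss
        pwm = pwm_from_kds(complete_table("A", 0.05, 2.2))
        assert pwm.matrix[0, 0] / pwm.matrix[0, 1] == pytest.approx(44.0, rel=1e-9)

    def test_missing_variant_names_position_and_base(self):
        table = complete_table("AC", 1.0, 5.0)
        variants = dict(table.variants)
        del variants[(1, "G")]
        broken = KdTable(consensus="AC", consensus_kd=1.0, variants=variants)
        with pytest.raises(IncompleteTableError, match=r"position 1, base G"):
            pwm_from_kds(broken)

    # scales capped so no variant K_D crosses the 10 µM measurability ceiling
    @given(scale=st.floats(1e-3, 1e2))
    @settings(deadline=None, max_examples=50)
    def test_scale_invariance(self, scale):
        base = complete_table("ACG", 2.0, 40.0)
        scaled = KdTable(
            consensus="ACG",
            consensus_kd=2.0 * scale,
            variants={k: v * scale for k, v in base.variants.items()},
        )
        assert np.allclose(pwm_from_kds(base).matrix, pwm_from_kds(scaled).matrix)

    def test_ceiling_clamp_flagged(self):
        table = complete_table("A", 1.0, 5e4)
        assert table.variants[(0, "C")] == 1e4
        assert len(table.ceiling_flagged) == 3


class TestInformationContent:
    def test_uniform_pwm_zero_bits(self):
        pwm = Pwm(matrix=np.full((7, 4), 0.25))
        assert information_content(pwm) == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_column_two_bits(self):
        pwm = Pwm(matrix=np.array([[1.0, 0.0, 0.0, 0.0]]))
        assert information_content(pwm) == pytest.approx(2.0)

    def test_derived_column_value(self):
        pwm = pwm_from_kds(complete_table("A", 1.0, 10.0))
        assert information_content(pwm) == pytest.approx(0.8549, abs=2e-4)

    @given(st.lists(st.lists(st.floats(0.01, 10.0), min_size=4, max_size=4), min_size=1, max_size=8))
    @settings(deadline=None, max_examples=100)
    def test_bounds(self, raw):
        m = np.array(raw)
        m = m / m.sum(axis=1, keepdims=True)
        ic = information_content(Pwm(matrix=m))
        assert -1e-9 <= ic <= 2.0 * m.shape[0] + 1e-9
        assert np.all(per_position_information(Pwm(matrix=m)) >= -1e-12)


class TestPseudocounts:
    def test_count_based_rule(self):
        pwm = apply_pseudocounts(np.array([[10.0, 0.0, 0.0, 0.0]]), mode="count-based")
        assert pwm.matrix[0] == pytest.approx([10.25 / 11, 0.25 / 11, 0.25 / 11, 0.25 / 11])
        assert pwm.matrix[0] == pytest.approx([0.93182, 0.02273, 0.02273, 0.02273], abs=1e-5)

    def test_hipfa_mode_uniform_unchanged(self):
        pwm = apply_pseudocounts(np.full((3, 4), 0.25), mode="hipfa")
        assert np.allclose(pwm.matrix, 0.25)

    def test_no_zero_entries_after_either_mode(self):
        counts = np.array([[5.0, 0.0, 0.0, 0.0], [0.0, 0.0, 3.0, 0.0]])
        assert (apply_pseudocounts(counts, mode="count-based").matrix > 0).all()
        probs = np.array([[1.0, 0.0, 0.0, 0.0]])
        assert (apply_pseudocounts(probs, mode="hipfa").matrix > 0).all()

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            apply_pseudocounts(np.array([[-1.0, 1.0, 1.0, 1.0]]), mode="count-based")


def test_kd_table_round_trip_via_tsv(tmp_path):
    from hipfa.specificity import read_kd_table, write_kd_table

    table = complete_table("ACGT", 2.0, 30.0)
    path = tmp_path / "kds.tsv"
    write_kd_table(table, path)
    back = read_kd_table(path)
    assert back.consensus == "ACGT"
    assert back.consensus_kd == 2.0
    assert back.variants == table.variants


def test_meme_output_parses(tmp_path):
    from hipfa.specificity import write_meme

    pwm = pwm_from_kds(complete_table("ACG", 1.0, 10.0))
    path = tmp_path / "motif.meme"
    write_meme(pwm, path)
    text = path.read_text()
    assert "MEME version 4" in text
    rows = [l for l in text.splitlines() if l.startswith(" ")]
    parsed = np.array([[float(x) for x in r.split()] for r in rows[-3:]])
    assert np.allclose(parsed, pwm.matrix, atol=1e-6)


def test_pwm_recovered_through_full_titration_pipeline():
    """Ground-truth K_Ds -> simulated dilution titrations -> fits -> same PWM."""
    from hipfa.binding import FitOptions, fit_titration
    from hipfa.simulate import simulate_dilution_series

    consensus = "TAAT"
    rng = np.random.default_rng(4)
    variants = {
        (pos, base): float(10 ** rng.uniform(0.3, 2.0))
        for pos, base, _ in enumerate_point_mutants(consensus)
    }
    truth = KdTable(consensus=consensus, consensus_kd=1.5, variants=variants)

    fitted = {}
    for (pos, base), kd in truth.variants.items():
        curve, _ = simulate_dilution_series(kd, kd1_nM=2.0, rt_nM=40.0, noise_rel_sd=0.0)
        fitted[(pos, base)] = fit_titration(
            curve, kd1=2.0, cfg=FitOptions(nominal_rt_nM=40.0)
        ).kd2
    curve, _ = simulate_dilution_series(1.5, kd1_nM=2.0, rt_nM=40.0, noise_rel_sd=0.0)
    consensus_fit = fit_titration(curve, kd1=2.0, cfg=FitOptions(nominal_rt_nM=40.0)).kd2

    recovered = KdTable(consensus=consensus, consensus_kd=consensus_fit, variants=fitted)
    assert np.allclose(
        pwm_from_kds(recovered).matrix, pwm_from_kds(truth).matrix, atol=1e-4
    )
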
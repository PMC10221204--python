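"""QC summaries, acceptance rules, recovery, matrix factor, Hct effect."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from parpbridge.simulate import gen_qc_panel
from parpbridge.validation import (
    EMA_FDA_RULE,
    LLOQ_RULE,
    AreaPanel,
    QCReplicateSet,
    check_acceptance,
    hct_effect_assess,
    interference_check,
    isn_matrix_factor,
    recovery,
    sensitivity_check,
    stability_or_dilution_assess,
    summarize_qc,
)


def qcs(measured, nominal=100.0, **kw):
    return QCReplicateSet(analyte="niraparib", nominal=nominal, measured=tuple(measured), **kw)


class TestSummarizeQC:
    def test_constant_replicates(self):
        row = summarize_qc(qcs([100] * 5))
        assert (row.mean_conc, row.cv, row.acc) == (100.0, 0.0, 100.0)

    def test_hand_computed_cv(self):
        row = summarize_qc(qcs([90, 100, 110]))
        assert row.mean_conc == pytest.approx(100.0)
        assert row.cv == pytest.approx(10.0)
        assert row.acc == pytest.approx(100.0)

    @given(scale=st.floats(0.1, 10))
    def test_scaling_measurements_scales_accuracy_not_cv(self, scale):
        base = summarize_qc(qcs([90, 100, 110]))
        scaled = summarize_qc(qcs([90 * scale, 100 * scale, 110 * scale]))
        assert scaled.acc == pytest.approx(base.acc * scale, rel=1e-9)
        assert scaled.cv == pytest.approx(base.cv, rel=1e-9)

    def test_order_invariant(self):
        a = summarize_qc(qcs([90, 100, 110]))
        b = summarize_qc(qcs([110, 90, 100]))
        assert (a.mean_conc, a.cv, a.acc) == (b.mean_conc, b.cv, b.acc)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            qcs([100])


class TestCheckAcceptance:
    @pytest.mark.parametrize(
        "acc, cv, is_lloq, expected",
        [
            (87, 6, True, True),  # LLOQ band 80-120
            (84, 5, False, False),  # below 85
            (100, 16, False, False),  # CV above 15
            (115.0, 15.0, False, True),  # boundaries pass
            (85.0, 15.0, False, True),
            (115.1, 5, False, False),
            (84.9, 5, False, False),
            (80.0, 20.0, True, True),
            (79.9, 5, True, False),
        ],
    )
    def test_band_and_boundaries(self, acc, cv, is_lloq, expected):
        from parpbridge.validation import APRow

        row = APRow("niraparib", 100.0, "t", acc, cv, acc, 3, is_lloq=is_lloq)
        assert check_acceptance(row).passed is expected

    @given(
        acc=st.floats(50, 150),
        cv=st.floats(0, 40),
        worse_acc=st.floats(0, 50),
        worse_cv=st.floats(0, 20),
    )
    def test_monotone_in_bias_and_cv(self, acc, cv, worse_acc, worse_cv):
        """Making |acc-100| or cv larger never flips fail -> pass."""
        from parpbridge.validation import APRow

        row = APRow("x", 100.0, "t", acc, cv, acc, 3)
        worse = APRow(
            "x",
            100.0,
            "t",
            acc,
            cv + worse_cv,
            100 + (acc - 100) * (1 + worse_acc / 50) if acc != 100 else acc,
            3,
        )
        if not check_acceptance(row).passed:
            assert not check_acceptance(worse).passed


def make_panel(normal_ratios, post_ratio=1.0, level="L", is_area=1000.0):
    rows = []
    for i, r in enumerate(normal_ratios):
        rows.append(dict(technique="normal", donor_id=f"D{i}", level=level,
                         analyte_area=r * is_area, is_area=is_area))
    for i in range(max(len(normal_ratios), 2)):
        rows.append(dict(technique="post", donor_id=f"D{i}", level=level,
                         analyte_area=post_ratio * is_area, is_area=is_area))
    return AreaPanel(analyte="niraparib", table=pd.DataFrame(rows))


class TestRecovery:
    def test_identical_panels_give_full_recovery(self):
        rec, cv = recovery(make_panel([1.0, 1.0, 1.0]), "L")
        assert rec == pytest.approx(100.0)
        assert cv == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        rec, cv = recovery(make_panel([0.9, 1.0, 1.1]), "L")
        assert rec == pytest.approx(100.0)
        assert cv == pytest.approx(10.0)

    def test_partial_extraction_yield(self):
        rec, _ = recovery(make_panel([0.56, 0.56, 0.56]), "L")
        assert rec == pytest.approx(56.0)

    @given(scale=st.floats(0.01, 100))
    def test_invariant_to_uniform_area_rescaling(self, scale):
        p1 = make_panel([0.8, 0.9, 1.0])
        p2 = AreaPanel(
            analyte=p1.analyte,
            table=p1.table.assign(
                analyte_area=p1.table.analyte_area * scale,
                is_area=p1.table.is_area * scale,
            ),
        )
        assert recovery(p1, "L")[0] == pytest.approx(recovery(p2, "L")[0], rel=1e-9)

    def test_zero_post_mean_rejected(self):
        with pytest.raises(ZeroDivisionError):
            recovery(make_panel([1.0, 1.0], post_ratio=0.0), "L")


class TestIsnMatrixFactor:
    @staticmethod
    def panel(post_analyte, post_is, neat_analyte, neat_is, level="L"):
        rows = []
        for i, (pa, pi) in enumerate(zip(post_analyte, post_is)):
            rows.append(dict(technique="post", donor_id=f"D{i}", level=level,
                             analyte_area=pa, is_area=pi))
        for i, (na, ni) in enumerate(zip(neat_analyte, neat_is)):
            rows.append(dict(technique="neat", donor_id=f"N{i}", level=level,
                             analyte_area=na, is_area=ni))
        return AreaPanel(analyte="rucaparib", table=pd.DataFrame(rows))

    def test_no_matrix_effect(self):
        p = self.panel([1000] * 3, [500] * 3, [1000] * 3, [500] * 3)
        mf, cv, ok = isn_matrix_factor(p, "L")
        assert mf == pytest.approx(1.0)
        assert cv == pytest.approx(0.0)
        assert ok

    def test_known_ratio(self):
        p = self.panel([1020] * 3, [1000] * 3, [1000] * 3, [1000] * 3)
        mf, _, _ = isn_matrix_factor(p, "L")
        assert mf == pytest.approx(1.02)

    def test_is_normalisation_cancels_shared_donor_factor(self):
        """A per-donor multiplicative matrix factor common to analyte and IS
        yields ISN-MF exactly 1 for every donor."""
        rng = np.random.default_rng(8)
        factors = rng.uniform(0.7, 1.3, 7)
        p = self.panel(1000 * factors, 500 * factors, [1000] * 7, [500] * 7)
        mf, cv, _ = isn_matrix_factor(p, "L")
        assert mf == pytest.approx(1.0, rel=1e-12)
        assert cv == pytest.approx(0.0, abs=1e-9)

    def test_seven_donor_spreadsheet_oracle(self):
        rng = np.random.default_rng(21)
        pa = rng.uniform(900, 1100, 7)
        pi = rng.uniform(450, 550, 7)
        na = rng.uniform(950, 1050, 7)
        ni = rng.uniform(480, 520, 7)
        p = self.panel(pa, pi, na, ni)
        isn = (pa / na.mean()) / (pi / ni.mean())
        mf, cv, _ = isn_matrix_factor(p, "L")
        assert mf == pytest.approx(isn.mean(), rel=1e-12)
        assert cv == pytest.approx(100 * isn.std(ddof=1) / isn.mean(), rel=1e-12)

    def test_zero_neat_area_rejected(self):
        p = self.panel([1000] * 2, [500] * 2, [0, 0], [500] * 2)
        with pytest.raises(ZeroDivisionError):
            isn_matrix_factor(p, "L")


class TestHctEffect:
    @staticmethod
    def arm(condition, acc_scale=1.0):
        return [
            qcs(n * np.array([0.95, 1.0, 1.05]) * acc_scale, nominal=n, condition=condition)
            for n in (60, 153, 1020, 2550)
        ]

    def test_biased_but_within_band_passes(self):
        sets = [qcs([98, 108, 118], nominal=100, condition="hct:29")] + self.arm("hct:29")[:3]
        rows, _ = hct_effect_assess(sets)
        assert rows[0].acc == pytest.approx(108.0)
        assert rows[0].passed

    def test_excess_bias_fails_cell_and_overall(self):
        sets = [qcs([115.1, 115.1, 115.1], nominal=100, condition="hct:29")] + self.arm("hct:29")[:3]
        rows, overall = hct_effect_assess(sets)
        assert not rows[0].passed
        assert not overall

    def test_nominal_everywhere_passes(self):
        rows, overall = hct_effect_assess(self.arm("hct:29") + self.arm("hct:45"))
        assert overall and all(r.passed for r in rows)

    def test_missing_level_rejected(self):
        with pytest.raises(ValueError, match="incomplete"):
            hct_effect_assess(self.arm("hct:29")[:3])


class TestThresholdChecks:
    def test_clean_blank_passes(self):
        assert interference_check(0.0, 1000.0, "selectivity-analyte").passed

    @pytest.mark.parametrize(
        "frac, context, expected",
        [
            (19.9, "selectivity-analyte", True),
            (20.1, "selectivity-analyte", False),
            (6.0, "selectivity-IS", False),
            (4.9, "carryover-IS", True),
        ],
    )
    def test_context_limits(self, frac, context, expected):
        check = interference_check(frac * 10, 1000.0, context)
        assert check.passed is expected

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            interference_check(1.0, 0.0, "carryover-analyte")

    def test_sensitivity_signal_ratio(self):
        assert sensitivity_check(500.0, 100.0).passed
        assert not sensitivity_check(400.0, 100.0, snr=3.0).passed
        assert not sensitivity_check(490.0, 100.0).passed


class TestStabilityAndDilution:
    @pytest.mark.parametrize(
        "nominal, measured, acc",
        [
            (255, [251 * 0.94, 251, 251 * 1.06], 98.4),  # long-term frozen storage
            (2550, [2301 * 0.97, 2301, 2301 * 1.03], 90.2),  # desiccator storage
        ],
    )
    def test_partial_degradation_still_within_band(self, nominal, measured, acc):
        rows = stability_or_dilution_assess([qcs(measured, nominal=nominal, condition="stability")])
        assert rows[0].acc == pytest.approx(acc, abs=0.5)
        assert rows[0].passed

    def test_exact_nominal_passes(self):
        rows = stability_or_dilution_assess([qcs([255, 255, 255], nominal=255)])
        assert rows[0].acc == pytest.approx(100.0)
        assert rows[0].cv == 0.0
        assert rows[0].passed


class TestParameterRecovery:
    def test_generator_bias_and_cv_recovered_at_large_n(self):
        panel = gen_qc_panel(100.0, bias=2.0, cv=3.0, n=1000, seed=3)
        row = summarize_qc(panel)
        # SE(acc) ~ 3/sqrt(1000) ~ 0.095; 3 SE bounds
        assert row.acc == pytest.approx(102.0, abs=0.3)
        assert row.cv == pytest.approx(3.0, abs=0.3)

    def test_large_negative_bias_fails_every_rule(self):
        row = summarize_qc(gen_qc_panel(100.0, bias=-20.0, cv=1.0, n=5, seed=1))
        assert not check_acceptance(row, EMA_FDA_RULE, is_lloq=False).passed
        row = summarize_qc(gen_qc_panel(100.0, bias=-25.0, cv=1.0, n=5, seed=1))
        assert not check_acceptance(row, EMA_FDA_RULE, is_lloq=False).passed
        assert not check_acceptance(row, EMA_FDA_RULE, is_lloq=True, lloq_rule=LLOQ_RULE).passed
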
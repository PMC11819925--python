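import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import run2d as r
from run2d.agreement import AgreementError, CurvePanel, _rm_anova_f


def scalar_rm_anova(cell_values):
    """Independent scalar two-way within-subject ANOVA (plain loops).

    ``cell_values[s][i][j]`` is participant s under level i of factor A and
    level j of factor B.  Returns (F_A, F_AxB).
    """
    y = cell_values
    n, a, b = len(y), len(y[0]), len(y[0][0])
    grand = sum(y[s][i][j] for s in range(n) for i in range(a) for j in range(b)) / (n * a * b)
    mean_a = [sum(y[s][i][j] for s in range(n) for j in range(b)) / (n * b) for i in range(a)]
    mean_b = [sum(y[s][i][j] for s in range(n) for i in range(a)) / (n * a) for j in range(b)]
    mean_s = [sum(y[s][i][j] for i in range(a) for j in range(b)) / (a * b) for s in range(n)]
    mean_ab = [[sum(y[s][i][j] for s in range(n)) / n for j in range(b)] for i in range(a)]
    mean_as = [[sum(y[s][i][j] for j in range(b)) / b for i in range(a)] for s in range(n)]
    mean_bs = [[sum(y[s][i][j] for i in range(a)) / a for j in range(b)] for s in range(n)]

    ss_a = n * b * sum((m - grand) ** 2 for m in mean_a)
    ss_as = b * sum(
        (mean_as[s][i] - mean_a[i] - mean_s[s] + grand) ** 2
        for s in range(n)
        for i in range(a)
    )
    ss_ab = n * sum(
        (mean_ab[i][j] - mean_a[i] - mean_b[j] + grand) ** 2
        for i in range(a)
        for j in range(b)
    )
    ss_abs = sum(
        (
            y[s][i][j]
            - mean_ab[i][j]
            - mean_as[s][i]
            - mean_bs[s][j]
            + mean_a[i]
            + mean_b[j]
            + mean_s[s]
            - grand
        )
        ** 2
        for s in range(n)
        for i in range(a)
        for j in range(b)
    )
    f_a = (ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1)))
    f_ab = (ss_ab / ((a - 1) * (b - 1))) / (ss_abs / ((a - 1) * (b - 1) * (n - 1)))
    return f_a, f_ab


class TestErrorMetrics:
    def test_identical_panels_zero_mae(self, rng):
        a = rng.normal(size=(8, 101))
        np.testing.assert_array_equal(r.mae_curve(a, a), np.zeros(101))

    def test_constant_offset_mae(self, rng):
        a = rng.normal(size=(8, 101))
        np.testing.assert_allclose(r.mae_curve(a, a + 3.0), 3.0, atol=1e-12)

    def test_mixed_sign_offsets_average_absolutely(self):
        a = np.zeros((2, 101))
        b = a.copy()
        b[0, 40] = 1.0
        b[1, 40] = -5.0
        assert r.mae_curve(a, b)[40] == pytest.approx(3.0)

    def test_mae_shape_mismatch(self):
        with pytest.raises(AgreementError, match="mismatch"):
            r.mae_curve(np.zeros((3, 101)), np.zeros((4, 101)))

    def test_rmse_identity_and_offset(self, rng):
        a = rng.normal(size=101)
        assert r.rmse_per_participant(a, a) == 0.0
        assert r.rmse_per_participant(a, a + 4.2) == pytest.approx(4.2)

    def test_rmse_sine_closed_form(self):
        grid = np.arange(101)
        b = np.sin(2 * np.pi * grid / 100.0)
        # sum of sin^2 over one full period of 100 samples is exactly 50
        expected = np.sqrt(50.0 / 101.0)
        assert r.rmse_per_participant(np.zeros(101), b) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_rmse_dominates_mean_absolute_error(self, seed):
        g = np.random.default_rng(seed)
        a, b = g.normal(size=(2, 101))
        assert r.rmse_per_participant(a, b) >= np.mean(np.abs(a - b)) - 1e-12


class TestSidak:
    def test_three_joints_at_five_percent(self):
        assert f"{r.sidak_alpha(0.05, 3):.3f}" == "0.017"
        assert r.sidak_alpha(0.05, 3) == pytest.approx(0.016952, abs=1e-6)

    def test_single_comparison_identity(self):
        assert r.sidak_alpha(0.05, 1) == pytest.approx(0.05)

    def test_two_comparisons_closed_form(self):
        assert r.sidak_alpha(0.10, 2) == pytest.approx(1 - 0.9**0.5, abs=1e-12)

    def test_monotone_decreasing_in_m(self):
        values = [r.sidak_alpha(0.05, m) for m in range(1, 10)]
        assert all(x > y for x, y in zip(values, values[1:]))

    def test_close_to_bonferroni_for_small_alpha(self):
        for m in (2, 3, 5):
            assert r.sidak_alpha(0.01, m) == pytest.approx(0.01 / m, abs=0.01**2)

    def test_domain_errors(self):
        with pytest.raises(AgreementError):
            r.sidak_alpha(0.0, 3)
        with pytest.raises(AgreementError):
            r.sidak_alpha(0.05, 0)


class TestSpmAnova:
    def test_copied_condition_gives_null_result(self, rng):
        base = rng.normal(size=(10, 1, 2, 101))
        panel = CurvePanel(np.concatenate([base, base], axis=1))
        res = r.spm_rm_anova_2way(panel, alpha=0.05, n_permutations=200, seed=2)
        np.testing.assert_allclose(res.F_main, 0.0, atol=1e-9)
        assert res.clusters_main == []

    def test_offset_window_detected_without_interaction(self):
        # the injected offset is a pure main effect: it must always produce a
        # main-effect cluster over 40-60 %, while interaction clusters can
        # only be the occasional alpha-level false positive
        interaction_hits = 0
        for seed in range(5):
            panel = r.curve_panel(
                30, 2.0, seed=8 + seed, effect_deg=10.0, effect_window=(40, 60)
            )
            res = r.spm_rm_anova_2way(panel, alpha=0.017, n_permutations=1000, seed=9 + seed)
            assert any(lo <= 60 and hi >= 40 for lo, hi in res.clusters_main)
            interaction_hits += bool(res.clusters_interaction)
        assert interaction_hits <= 1

    def test_pointwise_f_matches_scalar_anova(self):
        panel = r.curve_panel(9, 2.0, seed=5)
        f_main, f_inter, _ = _rm_anova_f(panel.data)
        nodes = np.random.default_rng(7).choice(101, 5, replace=False)
        for q in nodes:
            cells = [
                [[panel.data[s, i, j, q] for j in range(2)] for i in range(2)]
                for s in range(panel.n_participants)
            ]
            f_a, f_ab = scalar_rm_anova(cells)
            assert f_main[q] == pytest.approx(f_a, rel=1e-8)
            assert f_inter[q] == pytest.approx(f_ab, rel=1e-8)

    def test_pointwise_f_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        panel = r.curve_panel(8, 2.0, seed=11)
        f_main, f_inter, _ = _rm_anova_f(panel.data)
        q = 40
        rows = [
            (s, i, j, panel.data[s, i, j, q])
            for s in range(8)
            for i in range(2)
            for j in range(2)
        ]
        df = pd.DataFrame(rows, columns=["subj", "A", "B", "y"])
        table = pg.rm_anova(df, dv="y", within=["A", "B"], subject="subj", detailed=True)
        assert f_main[q] == pytest.approx(
            float(table.loc[table["Source"] == "A", "F"].iloc[0]), rel=1e-8
        )
        assert f_inter[q] == pytest.approx(
            float(table.loc[table["Source"] == "A * B", "F"].iloc[0]), rel=1e-8
        )

    def test_family_wise_threshold_exceeds_pointwise_critical_f(self):
        pointwise = stats.f.isf(0.05, 1, 29)
        for seed in range(3):
            panel = r.curve_panel(30, 2.0, seed=100 + seed)
            res = r.spm_rm_anova_2way(panel, alpha=0.05, n_permutations=500, seed=seed)
            assert res.threshold_main > pointwise
            assert res.threshold_interaction > pointwise

    def test_rft_threshold_exceeds_pointwise_and_tracks_alpha(self):
        panel = r.curve_panel(30, 2.0, seed=21)
        strict = r.spm_rm_anova_2way(panel, alpha=0.01, method="rft")
        loose = r.spm_rm_anova_2way(panel, alpha=0.05, method="rft")
        assert strict.threshold_main > loose.threshold_main > stats.f.isf(0.05, 1, 29)

    def test_seeded_determinism(self):
        panel = r.curve_panel(12, 2.0, seed=13)
        a = r.spm_rm_anova_2way(panel, alpha=0.05, n_permutations=300, seed=4)
        b = r.spm_rm_anova_2way(panel, alpha=0.05, n_permutations=300, seed=4)
        assert a.threshold_main == b.threshold_main
        assert a.p_main == b.p_main

    def test_seed_required_for_permutation(self):
        panel = r.curve_panel(5, 2.0, seed=1)
        with pytest.raises(AgreementError, match="seed"):
            r.spm_rm_anova_2way(panel, alpha=0.05)

    def test_few_permutations_recorded_as_warning(self):
        panel = r.curve_panel(5, 2.0, seed=1)
        res = r.spm_rm_anova_2way(panel, alpha=0.05, n_permutations=50, seed=3)
        assert any("permutation" in w for w in res.warnings)

    def test_unbalanced_design_rejected(self):
        with pytest.raises(AgreementError):
            CurvePanel(np.zeros((5, 2, 3, 101)))
        bad = np.zeros((5, 2, 2, 101))
        bad[2, 1, 0, 50] = np.nan
        with pytest.raises(AgreementError, match="complete"):
            CurvePanel(bad)
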
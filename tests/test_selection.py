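"""Bootstrap engine, VIP/SR selection rounds and the DIVA/MCCR cut-off."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from metabopls import (
    SyntheticSpec,
    auc_se,
    bootstrap_plsda,
    diva_mccr,
    generate_cohort,
    sr_selection,
    vip_selection_rounds,
)


@pytest.fixture(scope="module")
def planted_model_table(planted_cohort):
    table, truth = planted_cohort
    return table, truth


class TestAucSE:
    def test_all_equal_gives_zero(self):
        assert auc_se([0.7, 0.7, 0.7, 0.7]) == 0.0

    def test_two_and_three_value_hand_computations(self):
        assert auc_se([0.8, 0.9]) == pytest.approx(0.07071067811865477)
        assert auc_se([0.7, 0.8, 0.9]) == pytest.approx(0.1)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            auc_se([0.5])

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=200)
    )
    @settings(max_examples=200, deadline=None)
    def test_equals_sample_standard_deviation(self, values):
        assert auc_se(values) == pytest.approx(
            float(np.std(values, ddof=1)), rel=1e-10, abs=1e-12
        )


class TestBootstrap:
    def test_reproducible_given_seed(self, default_cohort):
        from metabopls import balanced_split

        mt = default_cohort.select_samples(
            balanced_split(default_cohort).model_samples
        )
        r1 = bootstrap_plsda(mt, B=25, seed=4)
        r2 = bootstrap_plsda(mt, B=25, seed=4)
        assert np.array_equal(r1.aucs, r2.aucs)
        assert np.array_equal(r1.avg_vip, r2.avg_vip)
        assert np.array_equal(r1.complexities, r2.complexities)

    def test_aucs_bounded_and_stratification_preserved(self, default_cohort):
        from metabopls import balanced_split

        mt = default_cohort.select_samples(
            balanced_split(default_cohort).model_samples
        )
        run = bootstrap_plsda(mt, B=30, seed=9)
        assert run.aucs.shape == (30,)
        assert np.all((run.aucs >= 0) & (run.aucs <= 1))
        # stratified resampling keeps each replicate at 13 + 13
        assert np.all(run.in_bag_counts == 13)
        assert run.se >= 0

    def test_strong_separation_gives_high_mean_auc(self):
        planted = {f"serum__v{i}": 3.0 for i in range(1, 6)}
        t = generate_cohort(
            SyntheticSpec(n_group_a=30, n_group_b=30, planted=planted, seed=21)
        )
        run = bootstrap_plsda(t, B=200, seed=1)
        assert run.mean_auc >= 0.95

    def test_label_permutation_gives_chance_level_auc(self):
        t = generate_cohort(SyntheticSpec(n_group_a=30, n_group_b=30, seed=5))
        rng = np.random.default_rng(2)
        t.group_labels = rng.permutation(t.group_labels)
        run = bootstrap_plsda(t, B=200, seed=3)
        assert abs(run.mean_auc - 0.5) <= 0.1

    def test_in_bag_auc_is_more_optimistic(self, planted_model_table):
        table, _ = planted_model_table
        oob = bootstrap_plsda(table, B=40, seed=6, oob=True)
        inb = bootstrap_plsda(table, B=40, seed=6, oob=False)
        assert inb.mean_auc >= oob.mean_auc

    def test_histogram_export(self, tmp_path, default_cohort):
        from metabopls import balanced_split

        mt = default_cohort.select_samples(
            balanced_split(default_cohort).model_samples
        )
        run = bootstrap_plsda(mt, B=20, seed=0)
        path = tmp_path / "theta.csv"
        run.theta_histogram_csv(path)
        rows = path.read_text().strip().splitlines()
        assert rows[0] == "bin_low,bin_high,count"
        assert sum(int(r.split(",")[2]) for r in rows[1:]) == 20


class TestVIPSelection:
    def test_single_variable_always_retained(self, default_cohort):
        t = default_cohort.select_variables(["serum__v1"])
        sel = vip_selection_rounds(t, B=20, seed=1)
        assert sel.retained == ["serum__v1"]

    def test_cutoff_zero_is_identity(self, default_cohort):
        from metabopls import balanced_split

        mt = default_cohort.select_samples(
            balanced_split(default_cohort).model_samples
        )
        sel = vip_selection_rounds(mt, cutoff=0.0, rounds=3, B=10, seed=2)
        assert set(sel.retained) == set(mt.variable_names)
        assert sel.rounds_applied == 1  # nothing dropped -> early stop

    def test_impossible_cutoff_raises_actionable_error(self, default_cohort):
        from metabopls import balanced_split

        mt = default_cohort.select_samples(
            balanced_split(default_cohort).model_samples
        )
        with pytest.raises(ValueError, match="lower the cutoff"):
            vip_selection_rounds(mt, cutoff=1e9, B=10, seed=3)

    def test_monotone_in_cutoff(self, planted_model_table):
        table, _ = planted_model_table
        lo = vip_selection_rounds(table, cutoff=0.6, rounds=1, B=30, seed=8)
        hi = vip_selection_rounds(table, cutoff=1.1, rounds=1, B=30, seed=8)
        assert set(hi.retained) <= set(lo.retained)

    def test_recovers_planted_variables(self, planted_model_table):
        table, truth = planted_model_table
        sel = vip_selection_rounds(table, cutoff=0.8, rounds=3, B=100, seed=11)
        assert truth <= set(sel.retained)
        assert len(sel.audit) == sel.rounds_applied


class TestSRSelection:
    def test_cutoff_zero_retains_all(self, planted_model_table):
        table, _ = planted_model_table
        sel, curve = sr_selection(table, cutoff=0.0, B=20, seed=4)
        assert set(sel.retained) == set(table.variable_names)
        assert curve is None

    def test_infinite_cutoff_rejected(self, planted_model_table):
        table, _ = planted_model_table
        with pytest.raises(ValueError, match="lower"):
            sr_selection(table, cutoff=np.inf, B=20, seed=4)

    def test_diva_cutoff_recovers_planted_variables(self, planted_model_table):
        table, truth = planted_model_table
        sel, curve = sr_selection(table, cutoff=None, B=100, seed=11)
        assert truth <= set(sel.retained)
        assert curve is not None and curve.cutoff == sel.cutoff

    def test_monotone_in_cutoff(self, planted_model_table):
        table, _ = planted_model_table
        lo, _ = sr_selection(table, cutoff=0.05, B=30, seed=8)
        hi, _ = sr_selection(table, cutoff=0.5, B=30, seed=8)
        assert set(hi.retained) <= set(lo.retained)


class TestDIVA:
    def test_pure_noise_mccr_near_chance_in_every_interval(self):
        t = generate_cohort(SyntheticSpec(n_group_a=30, n_group_b=30, seed=17,
                                          correlation=0.0))
        run = bootstrap_plsda(t, B=30, seed=1, collect="sr")
        curve = diva_mccr(run, t, intervals=5, reps=200, seed=5)
        for m in curve.mccr:
            assert abs(m - 50.0) <= 5.0

    def test_mccr_increases_with_sr_under_graded_effects(self):
        planted = {f"serum__v{i}": 0.5 * i for i in range(1, 7)}
        t = generate_cohort(
            SyntheticSpec(n_group_a=40, n_group_b=40, planted=planted, seed=23)
        )
        run = bootstrap_plsda(t, B=50, seed=2, collect="sr")
        curve = diva_mccr(run, t, intervals=8, reps=100, seed=3)
        rho = stats.spearmanr(np.arange(len(curve.mccr)), curve.mccr).statistic
        assert rho > 0

    def test_single_interval_is_pooled_rate(self, planted_model_table):
        table, _ = planted_model_table
        run = bootstrap_plsda(table, B=20, seed=3, collect="sr")
        curve = diva_mccr(run, table, intervals=1, reps=50, seed=7)
        assert len(curve.mccr) == 1
        assert 0.0 <= curve.mccr[0] <= 100.0

    def test_more_intervals_than_variables_reduced(self, default_cohort):
        t = default_cohort.select_variables(
            default_cohort.variable_names[:4]
        )
        run = bootstrap_plsda(t, B=20, seed=3, collect="sr")
        curve = diva_mccr(run, t, intervals=10, reps=20, seed=1)
        assert len(curve.mccr) == 4


class TestSerialization:
    def test_bootstrap_and_selection_json(self, tmp_path, planted_model_table):
        import json

        table, _ = planted_model_table
        run = bootstrap_plsda(table, B=10, seed=1, collect="both")
        run.to_json(tmp_path / "run.json")
        d = json.loads((tmp_path / "run.json").read_text())
        assert d["B"] == 10 and len(d["aucs"]) == 10
        sel = vip_selection_rounds(table, B=10, seed=1, rounds=1)
        sel.to_json(tmp_path / "sel.json")
        d = json.loads((tmp_path / "sel.json").read_text())
        assert d["criterion"] == "VIP" and d["retained"] == sel.retained
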
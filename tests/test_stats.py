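import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glut4quant.errors import IncompleteDesignError, UndefinedStatisticError
from glut4quant.stats import (analyze_study, bonferroni, mixed_anova,
                              mixed_anova_from_array, paired_t,
                              rm_anova_two_within,
                              rm_anova_two_within_from_array)


def _mixed_table(rng, g=2, n=4, delta=0.0, group_delta=0.0, subject_sd=1.0,
                 noise_sd=0.5):
    rows = []
    for gi, grp in enumerate(["ET", "SIT"][:g]):
        for s in range(n):
            base = rng.normal(10, subject_sd)
            for t in ("pre", "post"):
                rows.append({
                    "subject_id": f"{grp}{s}", "mode": grp, "timepoint": t,
                    "y": base + (delta if t == "post" else 0)
                    + (group_delta if gi else 0) + rng.normal(0, noise_sd)})
    return pd.DataFrame(rows)


class TestPairedT:
    def test_textbook_example(self):
        t, df, p = paired_t([0, 0, 0, 0], [1, 2, 3, 4])
        assert t == pytest.approx(3.873, abs=1e-3)
        assert df == 3
        assert p == pytest.approx(0.0305, abs=1e-3)

    def test_identical_vectors_no_evidence(self):
        t, df, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            paired_t([1.0], [2.0])

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=12),
           st.integers(0, 10 ** 6))
    @settings(max_examples=40, deadline=None)
    def test_sign_flip_antisymmetry(self, pre, seed):
        rng = np.random.default_rng(seed)
        pre = np.asarray(pre)
        post = pre + rng.normal(0, 1, pre.size)
        t1, _, p1 = paired_t(pre, post)
        t2, _, p2 = paired_t(post, pre)
        assert t1 == pytest.approx(-t2, rel=1e-9, abs=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestBonferroni:
    def test_adjustment_and_cap(self):
        assert bonferroni([0.01], m=5)[0] == pytest.approx(0.05)
        assert bonferroni([0.5], m=4)[0] == 1.0

    def test_order_preserved(self):
        raw = np.array([0.001, 0.04, 0.2, 0.012])
        adj = bonferroni(raw)
        assert list(np.argsort(adj)) == list(np.argsort(raw))
        assert (adj >= raw).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            bonferroni([1.5])


class TestMixedAnova:
    def test_all_equal_values_degenerate(self):
        df = _mixed_table(np.random.default_rng(0), noise_sd=0, subject_sd=0)
        df["y"] = 5.0
        table = mixed_anova(df, "y", "subject_id", "timepoint", "mode")
        assert table.ss_total == pytest.approx(0.0, abs=1e-18)
        assert np.isnan(table.p("timepoint"))

    def test_matches_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        df = _mixed_table(np.random.default_rng(42), delta=1.0, group_delta=0.5)
        mine = mixed_anova(df, "y", "subject_id", "timepoint", "mode")
        ref = pg.mixed_anova(df, dv="y", within="timepoint",
                             subject="subject_id", between="mode")
        ref = ref.set_index("Source")
        for mine_name, ref_name in [("mode", "mode"),
                                    ("timepoint", "timepoint"),
                                    ("timepoint*mode", "Interaction")]:
            eff = mine.effect(mine_name)
            assert eff.ss == pytest.approx(ref.loc[ref_name, "SS"], rel=1e-9)
            assert eff.F == pytest.approx(ref.loc[ref_name, "F"], rel=1e-9)
            assert eff.p == pytest.approx(ref.loc[ref_name, "p_unc"], rel=1e-9)

    def test_ss_additivity(self):
        for seed in range(5):
            df = _mixed_table(np.random.default_rng(seed), delta=0.7)
            table = mixed_anova(df, "y", "subject_id", "timepoint", "mode")
            total = ((df.y - df.y.mean()) ** 2).sum()
            assert table.ss_total == pytest.approx(total, rel=1e-9)

    def test_unbalanced_groups_rejected(self):
        df = _mixed_table(np.random.default_rng(0))
        df = df[df.subject_id != "ET0"]
        with pytest.raises(IncompleteDesignError):
            mixed_anova(df, "y", "subject_id", "timepoint", "mode")

    def test_missing_cell_rejected(self):
        df = _mixed_table(np.random.default_rng(0))
        df = df.drop(df[(df.subject_id == "ET0") & (df.timepoint == "post")].index)
        with pytest.raises(IncompleteDesignError):
            mixed_anova(df, "y", "subject_id", "timepoint", "mode")

    def test_power_at_one_sd_change(self):
        # planted training effect = 1 SD of the within-subject change,
        # 8 subjects per mode, 500 simulated studies
        rng = np.random.default_rng(2024)
        noise = 0.5
        delta = np.sqrt(2) * noise
        hits = 0
        runs = 500
        for _ in range(runs):
            y = rng.normal(10, 1, (2, 8, 1)) + rng.normal(0, noise, (2, 8, 2))
            y[:, :, 1] += delta
            hits += mixed_anova_from_array(y).p("within") < 0.05
        assert hits / runs >= 0.80

    def test_type_i_error_rate_controlled(self):
        rng = np.random.default_rng(7)
        runs = 2000
        hits = 0
        for _ in range(runs):
            y = rng.normal(10, 1, (2, 8, 1)) + rng.normal(0, 0.5, (2, 8, 2))
            hits += mixed_anova_from_array(y).p("within") < 0.05
        assert 0.03 <= hits / runs <= 0.07


class TestTwoWithinAnova:
    def _table(self, rng, s=4, b=3, training_delta=0.0, layer_slope=0.0,
               interaction=0.0, noise=0.3):
        rows = []
        for subj in range(s):
            base = rng.normal(10, 1)
            for a in ("pre", "post"):
                for layer in range(b):
                    y = base + layer_slope * layer + rng.normal(0, noise)
                    if a == "post":
                        y += training_delta + interaction * (layer < 2)
                    rows.append({"subject_id": subj, "training": a,
                                 "layer": layer, "y": y})
        return pd.DataFrame(rows)

    def test_identical_layer_means_give_zero_layer_ss(self):
        rng = np.random.default_rng(0)
        df = self._table(rng, noise=0.0, training_delta=1.0)
        table = rm_anova_two_within(df, "y", "subject_id", "training", "layer")
        assert table.effect("layer").ss == pytest.approx(0.0, abs=1e-18)

    def test_matches_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        df = self._table(np.random.default_rng(5), training_delta=1.0,
                         layer_slope=0.2, interaction=0.5)
        mine = rm_anova_two_within(df, "y", "subject_id", "training", "layer")
        ref = pg.rm_anova(df, dv="y", within=["training", "layer"],
                          subject="subject_id", detailed=True).set_index("Source")
        for mine_name, ref_name in [("training", "training"),
                                    ("layer", "layer"),
                                    ("training*layer", "training * layer")]:
            eff = mine.effect(mine_name)
            assert eff.ss == pytest.approx(ref.loc[ref_name, "SS"], rel=1e-9)
            assert eff.F == pytest.approx(ref.loc[ref_name, "F"], rel=1e-9)
            assert eff.p == pytest.approx(ref.loc[ref_name, "p_unc"], rel=1e-9)

    def test_ss_additivity(self):
        for seed in range(5):
            df = self._table(np.random.default_rng(seed), interaction=0.4)
            table = rm_anova_two_within(df, "y", "subject_id", "training",
                                        "layer")
            total = ((df.y - df.y.mean()) ** 2).sum()
            assert table.ss_total == pytest.approx(total, rel=1e-9)

    def test_missing_cell_rejected(self):
        df = self._table(np.random.default_rng(0))
        df = df.iloc[1:]
        with pytest.raises(IncompleteDesignError):
            rm_anova_two_within(df, "y", "subject_id", "training", "layer")

    def test_interaction_power_at_one_sd(self):
        # training effect restricted to layers 0-1 of 6, magnitude 1 SD of
        # the within-cell change, 12 subjects (a cohort sized for ~88% power
        # at this effect), 500 simulated studies
        rng = np.random.default_rng(99)
        noise = 0.5
        delta = np.sqrt(2) * noise
        hits = 0
        runs = 500
        for _ in range(runs):
            y = rng.normal(10, 1, (12, 1, 1)) + rng.normal(0, noise, (12, 2, 6))
            y[:, 1, :2] += delta
            table = rm_anova_two_within_from_array(y)
            hits += table.rows.set_index("effect").loc["A*B", "p"] < 0.05
        assert hits / runs >= 0.80


class TestAnalyzeStudy:
    def _metric_tables(self, rng, interaction=0.0, training=0.0):
        fibre_rows, layer_rows = [], []
        for mode in ("ET", "SIT"):
            for s in range(6):
                subj = f"{mode}{s}"
                base = rng.normal(100, 5)
                for tp in ("pre", "post"):
                    bump = training if tp == "post" else 0.0
                    fibre_rows.append({
                        "subject_id": subj, "mode": mode, "timepoint": tp,
                        "mean_intensity": base + bump + rng.normal(0, 2),
                        "large_density_per_um2": rng.normal(0.01, 0.001),
                        "mean_large_size_um2": rng.normal(2, 0.1),
                        "small_density_per_um2": rng.normal(0.05, 0.005),
                        "mean_small_size_um2": rng.normal(0.3, 0.02)})
                    for layer in range(6):
                        y = base - 2 * layer + rng.normal(0, 2)
                        if tp == "post" and layer < 2:
                            y += interaction
                        layer_rows.append({
                            "subject_id": subj, "mode": mode, "timepoint": tp,
                            "layer_index": layer, "mean_intensity": y,
                            "large_count_per_um2": rng.normal(0.01, 0.001)})
        return pd.DataFrame(fibre_rows), pd.DataFrame(layer_rows)

    def test_null_study_triggers_no_within_layer_tests(self):
        rng = np.random.default_rng(3)
        fibre, layer = self._metric_tables(rng)
        report = analyze_study(fibre, layer)
        for mode in report.layers:
            assert "within_layer" not in report.layers[mode]["mean_intensity"]

    def test_planted_interaction_reaches_within_layer_tests(self):
        rng = np.random.default_rng(4)
        fibre, layer = self._metric_tables(rng, interaction=8.0, training=10.0)
        report = analyze_study(fibre, layer)
        wl = report.layers["ET"]["mean_intensity"]["within_layer"]
        assert wl[0]["significant"] and wl[1]["significant"]
        assert f"within_layer_t:ET:mean_intensity" in report.tests_run

    def test_report_lists_exactly_the_tests_run(self):
        rng = np.random.default_rng(5)
        fibre, layer = self._metric_tables(rng, training=10.0)
        report = analyze_study(fibre, layer)
        d = report.to_dict()
        # every anova entry corresponds to a tests_run record and vice versa
        n_anovas = len(d["whole_fibre"]) + sum(
            len(v) for v in d["layers"].values())
        listed = [t for t in d["tests_run"]
                  if t.startswith(("mixed_anova", "rm_anova"))]
        assert len(listed) == n_anovas
        # posthoc entries appear only with a matching trigger record
        for metric, entry in d["whole_fibre"].items():
            assert bool(entry["posthoc"]) == (
                f"posthoc:{metric}:post vs pre" in d["tests_run"])
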
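import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ecmetab import (
    DoseResponseModel,
    Feature,
    FeatureTable,
    PipelineConfig,
    SampleInfo,
    SimulationDesign,
    bh_adjust,
    consolidate_hits,
    exclude_low_outliers,
    generate_dose_experiment,
    joint_analysis,
    per_experiment_hits,
    spearman_dose,
)


def make_dose_table(values: np.ndarray, doses: list[float],
                    exp: str = "E1", mode: str = "HILIC+",
                    masses=None, rts=None) -> FeatureTable:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[0]
    masses = masses if masses is not None else [100.0 + i for i in range(n)]
    rts = rts if rts is not None else [1.0 + 0.1 * i for i in range(n)]
    feats = [Feature(f"F{i}", masses[i], rts[i], mode) for i in range(n)]
    samps = [SampleInfo(f"{exp}S{j}", "biological", dose_uM=doses[j],
                        experiment_id=exp, injection_order=j + 1)
             for j in range(len(doses))]
    return FeatureTable.from_records(feats, samps, values)


class TestOutlierExclusion:
    def test_single_low_value_excluded(self):
        doses = [0.0] * 5
        t = make_dose_table([[100, 102, 98, 0.5, 101]], doses)
        out = exclude_low_outliers(t)
        assert np.isnan(out.values()[0, 3])
        assert np.isfinite(out.values()[0, [0, 1, 2, 4]]).all()

    def test_at_most_one_excluded_the_smallest(self):
        doses = [0.0] * 5
        t = make_dose_table([[100, 0.3, 0.4, 99, 101]], doses)
        out = exclude_low_outliers(t)
        v = out.values()[0]
        assert np.isnan(v[1])
        assert v[2] == 0.4  # second candidate kept

    def test_identity_on_clean_data(self):
        design = SimulationDesign(n_features=80, seed=17, dropout_rate=0.0)
        tables, _ = generate_dose_experiment(design)
        out = exclude_low_outliers(tables[0])
        np.testing.assert_array_equal(out.values(), tables[0].values())

    def test_groups_are_per_experiment_and_dose(self):
        # same dose in two experiments: exclusion in one group only
        t1 = make_dose_table([[100, 101, 0.5]], [0.0] * 3, exp="E1")
        # low value relative to E1's median would not be low in a pooled
        # group with E2's tiny values
        v = np.hstack([t1.values(), [[0.4, 0.5, 0.6]]])
        feats = [Feature("F0", 100.0, 1.0, "HILIC+")]
        samps = [SampleInfo(f"S{j}", "biological", dose_uM=0.0,
                            experiment_id="E1" if j < 3 else "E2",
                            injection_order=j + 1) for j in range(6)]
        t = FeatureTable.from_records(feats, samps, v)
        out = exclude_low_outliers(t)
        assert np.isnan(out.values()[0, 2])          # excluded within E1
        assert np.isfinite(out.values()[0, 3:]).all()  # E2 untouched

    def test_removes_at_most_one_per_group(self):
        rng = np.random.default_rng(3)
        design = SimulationDesign(n_features=60, seed=19, dropout_rate=0.05)
        tables, _ = generate_dose_experiment(design)
        t = tables[0]
        out = exclude_low_outliers(t)
        bio = t.samples[t.samples["role"] == "biological"]
        for _, grp in bio.groupby(["experiment_id", "dose_uM"]):
            before = t.abundance[list(grp.index)].isna().sum(axis=1)
            after = out.abundance[list(grp.index)].isna().sum(axis=1)
            assert ((after - before) <= 1).all()


class TestSpearman:
    def test_perfect_monotonicity(self):
        # one value per dose level: strictly increasing -> rs = 1 exactly
        rs, p = spearman_dose([1, 2, 3, 4.0], [0, 1, 10, 100.0])
        assert rs == pytest.approx(1.0)
        assert p == 0.0

    def test_tied_doses_bound_rs_below_one(self):
        # with replicate-tied doses the attainable |rs| is strictly < 1
        doses = [0, 0, 1, 1, 10, 10, 100, 100.0]
        rs, _ = spearman_dose([1, 2, 3, 4, 5, 6, 7, 8.0], doses)
        assert 0.9 < rs < 1.0

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(11)
        doses = np.repeat([0.0, 1.0, 10.0, 100.0], 5)
        for _ in range(300):
            v = rng.lognormal(0, 1, 20)
            rs, p = spearman_dose(v, doses)
            ref = stats.spearmanr(v, doses)
            assert rs == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_constant_values_undefined(self):
        rs, p = spearman_dose([5, 5, 5, 5], [0, 1, 10, 100.0])
        assert np.isnan(rs) and np.isnan(p)

    def test_too_few_pairs_raise(self):
        with pytest.raises(ValueError):
            spearman_dose([1.0, 2.0], [0.0, 1.0])
        with pytest.raises(ValueError):
            spearman_dose([1, 2, 3.0], [1.0, 1.0, 1.0])

    def test_null_type_one_error_calibrated(self):
        """Permutation null: rejection rate at alpha=0.05 is ~5%."""
        rng = np.random.default_rng(23)
        doses = np.repeat([0.0, 1.0, 10.0, 100.0], 5)
        n_sim = 4000
        rej = 0
        for _ in range(n_sim):
            v = rng.standard_normal(20)
            _, p = spearman_dose(v, doses)
            rej += p < 0.05
        rate = rej / n_sim
        assert abs(rate - 0.05) < 0.015

    def test_ordinal_rank_equals_raw_dose(self):
        rng = np.random.default_rng(4)
        v = rng.lognormal(0, 1, 20)
        doses = np.repeat([0.0, 1.0, 10.0, 100.0], 5)
        ranks = np.repeat([0.0, 1.0, 2.0, 3.0], 5)
        assert spearman_dose(v, doses) == spearman_dose(v, ranks)


class TestBH:
    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_empty_list(self):
        assert len(bh_adjust([])) == 0

    def test_matches_hand_oracle_on_random_vectors(self):
        def oracle(p):
            p = np.asarray(p, float)
            m = len(p)
            order = np.argsort(p, kind="stable")
            q_sorted = p[order] * m / np.arange(1, m + 1)
            q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
            q = np.empty(m)
            q[order] = np.minimum(q_sorted, 1.0)
            return q
        rng = np.random.default_rng(8)
        for _ in range(200):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), oracle(p), atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20),
           st.randoms(use_true_random=False))
    def test_permutation_equivariant(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q = bh_adjust(p)
        q_perm = bh_adjust([p[i] for i in perm])
        np.testing.assert_allclose([q[i] for i in perm], q_perm, atol=1e-12)


class TestPerExperiment:
    def test_planted_feature_recovered(self):
        design = SimulationDesign(n_features=100, seed=29, replicate_cv=0.1,
                                  frac_dose_responsive=0.1)
        tables, gt = generate_dose_experiment(design)
        results = per_experiment_hits(tables)
        df = pd.DataFrame([(r.feature_id, r.experiment_id, r.significant,
                            r.direction) for r in results],
                          columns=["fid", "exp", "sig", "dir"])
        planted = gt.dose_direction[gt.dose_direction != "none"]
        n_exp_sig = df[df["sig"]].groupby("fid").size()
        recovered = sum(n_exp_sig.get(f, 0) >= 2 for f in planted.index)
        assert recovered / len(planted) >= 0.8
        # directions agree with ground truth
        sig = df[df["sig"] & df["fid"].isin(planted.index)]
        agree = [gt.dose_direction[f] == d
                 for f, d in zip(sig["fid"], sig["dir"])]
        assert np.mean(agree) > 0.95

    def test_no_hits_at_impossible_threshold(self):
        design = SimulationDesign(n_features=50, seed=37, replicate_cv=0.2,
                                  frac_dose_responsive=0.1)
        tables, _ = generate_dose_experiment(design)
        cfg = PipelineConfig(rs_min=1.0)
        results = per_experiment_hits(tables, cfg)
        assert not any(r.significant for r in results)

    def test_significance_flag_consistent_with_fields(self):
        design = SimulationDesign(n_features=60, seed=41,
                                  frac_dose_responsive=0.1)
        tables, _ = generate_dose_experiment(design)
        cfg = PipelineConfig()
        for r in per_experiment_hits(tables, cfg):
            assert r.significant == (abs(r.rs) > cfg.rs_min
                                     and r.q_bh < cfg.q_max)
            assert r.direction == ("up" if r.rs > 0 else "down")
            assert r.q_bh >= r.p_raw - 1e-12


class TestConsolidation:
    def _results(self, tables, sig_map):
        """Build synthetic per-experiment results: sig_map[(exp, fid)] = dir."""
        from ecmetab.dose_response import DoseResponseResult
        out = []
        for (exp, fid), direction in sig_map.items():
            out.append(DoseResponseResult(
                fid, exp, 0.9 if direction == "up" else -0.9,
                1e-4, 1e-3, direction, True, "HILIC+"))
        return out

    def _tables(self):
        t1 = make_dose_table(np.ones((2, 4)), [0, 1, 10, 100.0], exp="E1",
                             masses=[200.0, 300.0], rts=[2.0, 3.0])
        t2 = make_dose_table(np.ones((2, 4)), [0, 1, 10, 100.0], exp="E2",
                             masses=[200.0005, 300.0006], rts=[2.05, 3.02])
        t3 = make_dose_table(np.ones((2, 4)), [0, 1, 10, 100.0], exp="E3",
                             masses=[200.001, 300.1], rts=[2.1, 3.0])
        return [t1, t2, t3]

    def test_two_of_three_consolidated(self):
        tables = self._tables()
        res = self._results(tables, {("E1", "F0"): "up", ("E3", "F0"): "up"})
        hits = consolidate_hits(res, tables)
        assert len(hits) == 1
        assert hits[0].n_experiments_significant == 2
        assert hits[0].mean_mass == pytest.approx(200.0005, abs=1e-3)

    def test_direction_conflict_not_consolidated(self):
        tables = self._tables()
        res = self._results(tables, {("E1", "F0"): "up", ("E2", "F0"): "down"})
        assert consolidate_hits(res, tables) == []

    def test_mass_outside_tolerance_not_merged(self):
        tables = self._tables()
        # E3's F1 mass is 300.1 (~330 ppm away): cannot merge with E1's F1
        res = self._results(tables, {("E1", "F1"): "up", ("E3", "F1"): "up"})
        assert consolidate_hits(res, tables) == []

    def test_recovers_features_planted_in_all_experiments(self):
        design = SimulationDesign(n_features=150, seed=43, replicate_cv=0.1,
                                  frac_dose_responsive=0.08)
        tables, gt = generate_dose_experiment(design)
        res = per_experiment_hits(tables)
        sig_count = {}
        for r in res:
            if r.significant:
                sig_count[r.feature_id] = sig_count.get(r.feature_id, 0) + 1
        all_three = [f for f, c in sig_count.items() if c == 3]
        hits = consolidate_hits(res, tables)
        n3 = sum(h.n_experiments_significant == 3 for h in hits)
        assert len(all_three) > 0
        assert n3 / len(all_three) >= 0.9


class TestJointAnalysis:
    def test_single_experiment_reduces_to_per_experiment(self):
        design = SimulationDesign(n_features=60, seed=47, replicate_cv=0.1,
                                  frac_dose_responsive=0.1, n_experiments=1)
        tables, _ = generate_dose_experiment(design)
        joint = {r.feature_id: r for r in joint_analysis(tables)}
        per = {r.feature_id: r for r in per_experiment_hits(tables)}
        assert set(joint) == set(per)
        for fid in joint:
            # control scaling is a per-feature positive rescale: rank-based
            # statistics are unchanged
            assert joint[fid].rs == pytest.approx(per[fid].rs, abs=1e-12)
            assert joint[fid].p_raw == pytest.approx(per[fid].p_raw, abs=1e-12)

    def test_consistent_effect_gains_power_when_pooled(self):
        design = SimulationDesign(n_features=100, seed=53, replicate_cv=0.25,
                                  frac_dose_responsive=0.1)
        tables, gt = generate_dose_experiment(design)
        joint = {r.feature_id: r for r in joint_analysis(tables)}
        per = per_experiment_hits(tables)
        planted = gt.dose_direction[gt.dose_direction != "none"].index
        per_p = pd.DataFrame(
            [(r.feature_id, np.log10(max(r.p_raw, 1e-300))) for r in per
             if r.feature_id in set(planted)], columns=["fid", "log_p"])
        mean_single = per_p.groupby("fid")["log_p"].mean()
        joint_log_p = np.mean([np.log10(max(joint[f].p_raw, 1e-300))
                               for f in planted if f in joint])
        # pooling three consistent experiments sharpens the evidence
        assert joint_log_p < mean_single.mean()


class TestModelSurface:
    def test_fit_produces_frames_and_summary(self):
        design = SimulationDesign(n_features=80, seed=59, replicate_cv=0.1,
                                  frac_dose_responsive=0.05,
                                  drift_amplitude=0.2)
        tables, _ = generate_dose_experiment(design)
        from ecmetab import preprocess
        processed = [preprocess(t)[0] for t in tables]
        res = DoseResponseModel(processed).fit()
        assert not res.per_experiment_frame.empty
        assert set(res.hits_frame.columns) == {
            "mode", "mean_mass", "rt", "regulation", "n_experiments",
            "annotation"}
        assert "Dose-response screen" in res.summary()
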
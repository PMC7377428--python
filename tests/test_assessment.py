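import numpy as np
import pandas as pd
import pytest

from lbarace import assessment
from lbarace.assessment import (
    chisq_choice_gof,
    choice_counts,
    expected_choice_counts,
    ks_rt_gof,
    qp_discrepancy,
    quantile_probability_data,
    rm_anova_drift,
)
from lbarace.fitting import FitResult
from lbarace.io import pair_key
from lbarace.task import PAIRS, STIMULUS_IDS


class TestChisq:
    def test_textbook_arithmetic(self):
        x2, df, p = chisq_choice_gof([30, 20, 30, 20], [25, 25, 25, 25])
        assert x2 == pytest.approx(4.0)
        assert df == 3

    def test_perfect_fit(self):
        x2, _, p = chisq_choice_gof([25, 25, 25, 25], [25, 25, 25, 25])
        assert x2 == 0.0
        assert p == pytest.approx(1.0)

    def test_p_value_frozen(self):
        # chi-square survival oracle: P(X^2_3 > 4) = 0.26146...
        _, _, p = chisq_choice_gof([30, 20, 30, 20], [25, 25, 25, 25])
        assert p == pytest.approx(0.2615, abs=5e-4)

    def test_total_mismatch_raises(self):
        with pytest.raises(ValueError):
            chisq_choice_gof([30, 20, 30, 20], [25, 25, 25, 24])

    def test_zero_expected_raises(self):
        with pytest.raises(ValueError):
            chisq_choice_gof([30, 20, 30, 20], [0, 50, 25, 25])

    def test_relabeling_invariance(self):
        obs = np.array([40.0, 10.0, 30.0, 20.0])
        exp = np.array([25.0, 25.0, 25.0, 25.0])
        x2a, _, _ = chisq_choice_gof(obs, exp)
        perm = [2, 0, 3, 1]
        x2b, _, _ = chisq_choice_gof(obs[perm], exp[perm])
        assert x2a == pytest.approx(x2b)

    def test_expected_counts_sum_to_trials(self, small_cohort, small_cohort_fits):
        _, trials = small_cohort
        exp = expected_choice_counts(small_cohort_fits, trials)
        obs = choice_counts(trials)
        assert exp.sum() == pytest.approx(len(trials), abs=1e-6)
        assert obs.sum() == len(trials)


class TestQuantileProbability:
    def test_quantiles_monotone(self, small_cohort, small_cohort_fits):
        _, trials = small_cohort
        qp = quantile_probability_data(trials, small_cohort_fits,
                                       n_sim_per_subject=1200, seed=1)
        qcols = [c for c in qp.columns if c.startswith("q")]
        vals = qp[qcols].to_numpy()
        finite = np.isfinite(vals).all(axis=1)
        assert (np.diff(vals[finite], axis=1) >= -1e-12).all()

    def test_probabilities_bounded(self, small_cohort):
        _, trials = small_cohort
        qp = quantile_probability_data(trials)
        assert qp["response_prob"].between(0, 1).all()
        assert set(qp["source"]) == {"data"}

    def test_bad_levels_rejected(self, small_cohort):
        _, trials = small_cohort
        with pytest.raises(ValueError):
            quantile_probability_data(trials, quantile_levels=(0.5, 0.3))

    def test_self_consistency_with_true_params(self, small_cohort):
        profiles, trials = small_cohort
        true_fits = {
            p.subject_id: FitResult("drift_model", p.lba, 0.0, 1, True, 0)
            for p in profiles
        }
        qp = quantile_probability_data(trials, true_fits,
                                       n_sim_per_subject=12_000, seed=2)
        data = qp[qp["source"] == "data"].set_index("stimulus")
        model = qp[qp["source"] == "drift_model"].set_index("stimulus")
        for sid in STIMULUS_IDS:
            # ~288 appearances per stimulus in the data -> generous tolerances
            assert abs(data.loc[sid, "response_prob"] - model.loc[sid, "response_prob"]) < 0.1
            for c in ("q0.3", "q0.5", "q0.7"):
                rel = abs(data.loc[sid, c] - model.loc[sid, c]) / model.loc[sid, c]
                assert rel < 0.15

    def test_never_chosen_stimulus_flagged(self):
        rows = []
        for pair in PAIRS:
            winner = pair[0] if pair[0] != "LR_LEV" else pair[1]
            rows += [{"subject_id": "S1", "pair": pair_key(*pair),
                      "choice": winner, "rt_s": 0.8, "block_type": "counterfactual"}] * 2
        qp = quantile_probability_data(pd.DataFrame(rows))
        row = qp[qp["stimulus"] == "LR_LEV"].iloc[0]
        assert row["response_prob"] == 0.0
        assert np.isnan(row["q0.5"])

    def test_discrepancy_nonnegative(self, small_cohort, small_cohort_fits):
        _, trials = small_cohort
        qp = quantile_probability_data(trials, small_cohort_fits,
                                       n_sim_per_subject=1200, seed=3)
        assert qp_discrepancy(qp, "drift_model") >= 0


class TestKS:
    def test_identical_samples_give_zero_d(self, small_cohort, small_cohort_fits, monkeypatch):
        _, trials = small_cohort
        monkeypatch.setattr(assessment, "_simulate_model_trials",
                            lambda fits, n, seed: trials)
        ks = ks_rt_gof(trials, small_cohort_fits, seed=0)
        for d, p in ks.values():
            assert d == 0.0
            assert p == pytest.approx(1.0)

    def test_disjoint_supports_give_unit_d(self, small_cohort, small_cohort_fits, monkeypatch):
        _, trials = small_cohort
        shifted = trials.copy()
        shifted["rt_s"] = shifted["rt_s"] + 1000.0
        monkeypatch.setattr(assessment, "_simulate_model_trials",
                            lambda fits, n, seed: shifted)
        ks = ks_rt_gof(trials, small_cohort_fits, seed=0)
        for d, _ in ks.values():
            assert d == 1.0

    def test_reasonable_fit_from_true_params(self, small_cohort):
        profiles, trials = small_cohort
        true_fits = {
            p.subject_id: FitResult("drift_model", p.lba, 0.0, 1, True, 0)
            for p in profiles
        }
        ks = ks_rt_gof(trials, true_fits, seed=5, sim_multiplier=20)
        assert set(ks) == set(STIMULUS_IDS)
        for d, p in ks.values():
            assert 0 <= d <= 1
            assert 0 <= p <= 1

    def test_deterministic(self, small_cohort, small_cohort_fits):
        _, trials = small_cohort
        a = ks_rt_gof(trials, small_cohort_fits, seed=7, sim_multiplier=5)
        b = ks_rt_gof(trials, small_cohort_fits, seed=7, sim_multiplier=5)
        assert a == b


def _long(y):
    """subject x 2x2 array -> long frame keyed by stimulus."""
    cells = {("high", "high"): "HR_HEV", ("high", "low"): "HR_LEV",
             ("low", "high"): "LR_HEV", ("low", "low"): "LR_LEV"}
    rows = []
    for s in range(y.shape[0]):
        for i, risk in enumerate(("high", "low")):
            for j, ev in enumerate(("high", "low")):
                rows.append({"subject_id": f"S{s}", "stimulus": cells[(risk, ev)],
                             "value": y[s, i, j]})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_risk_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(3)
        y = rng.normal(1.0, 0.2, size=(12, 2, 2))
        out = rm_anova_drift(_long(y)).set_index("effect")
        diff = y.mean(axis=2)[:, 0] - y.mean(axis=2)[:, 1]  # high - low risk
        from scipy.stats import ttest_rel

        t, p = ttest_rel(y.mean(axis=2)[:, 0], y.mean(axis=2)[:, 1])
        assert out.loc["risk", "F"] == pytest.approx(t**2, abs=1e-8)
        assert out.loc["risk", "p"] == pytest.approx(p, abs=1e-10)

    def test_pure_additive_risk_effect(self):
        subj = np.arange(8)[:, None, None] * 0.1
        risk = np.array([0.0, 0.5])[None, :, None]
        y = np.broadcast_to(subj + risk, (8, 2, 2)).copy()
        out = rm_anova_drift(_long(y)).set_index("effect")
        assert out.loc["ev", "F"] == 0.0
        assert out.loc["risk:ev", "F"] == 0.0
        assert out.loc["risk", "F"] == np.inf

    def test_ss_decomposition_closes(self):
        rng = np.random.default_rng(4)
        out = rm_anova_drift(_long(rng.normal(size=(10, 2, 2))))
        assert out.attrs["ss_components"] == pytest.approx(
            out.attrs["ss_total"], rel=1e-8
        )

    def test_matches_reference_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        y = rng.normal(1.0, 0.3, size=(15, 2, 2))
        long = _long(y)
        from lbarace.assessment import _risk_ev_levels

        long["risk"] = long["stimulus"].map(lambda s: _risk_ev_levels(s)[0])
        long["ev"] = long["stimulus"].map(lambda s: _risk_ev_levels(s)[1])
        ref = pingouin.rm_anova(data=long, dv="value", within=["risk", "ev"],
                                subject="subject_id", detailed=True)
        mine = rm_anova_drift(long).set_index("effect")
        ref_map = {"risk": "risk", "ev": "ev", "risk * ev": "risk:ev"}
        for ref_name, my_name in ref_map.items():
            row = ref[ref["Source"] == ref_name].iloc[0]
            assert mine.loc[my_name, "F"] == pytest.approx(row["F"], rel=1e-6)
            assert mine.loc[my_name, "p"] == pytest.approx(row["p_unc"], rel=1e-6)

    def test_power_on_generated_drift_structure(self):
        # cohorts built with positive low-risk and high-EV drift benefits:
        # both main effects significant at alpha=.05 in >= 90% of seeds
        # (normalized true drifts; no fitting needed to test the ANOVA)
        from lbarace.task import STIMULUS_IDS, sample_population

        sig_risk = sig_ev = 0
        n_seeds = 20
        for k in range(n_seeds):
            profiles = sample_population(44, seed=9000 + k)
            rows = []
            for p in profiles:
                v = np.array([p.lba.drift_means[s] for s in STIMULUS_IDS])
                for sid, val in zip(STIMULUS_IDS, v / v.mean()):
                    rows.append({"subject_id": p.subject_id, "stimulus": sid, "value": val})
            out = rm_anova_drift(pd.DataFrame(rows)).set_index("effect")
            sig_risk += out.loc["risk", "p"] < 0.05
            sig_ev += out.loc["ev", "p"] < 0.05
        assert sig_risk / n_seeds >= 0.9
        assert sig_ev / n_seeds >= 0.9

    def test_incomplete_cells_raise(self):
        rng = np.random.default_rng(6)
        long = _long(rng.normal(size=(5, 2, 2))).iloc[:-1]
        with pytest.raises(ValueError):
            rm_anova_drift(long)
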
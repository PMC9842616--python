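import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riskconform import (
    awareness_conformity_correlation,
    binary_entropy,
    entropy_phase_comparison,
    influence_curve,
    peak_influence_alignment,
    persistence,
    simulate_cohort,
)
from riskconform.cohort import AgentParams, fixed_priors
from riskconform.metrics import (
    InfluenceEstimate,
    participant_conformity,
    wilcoxon_paired,
)


class TestBinaryEntropy:
    @pytest.mark.parametrize(
        "p,h",
        [(0.5, 1.0), (0.0, 0.0), (1.0, 0.0), (0.25, 0.8112781244591328)],
    )
    def test_known_values(self, p, h):
        assert binary_entropy(p) == pytest.approx(h, abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            binary_entropy(1.2)
        with pytest.raises(ValueError):
            binary_entropy(-0.01)


class TestInfluence:
    def test_sign_follows_norm_direction(self, moral_cohort):
        trials = moral_cohort[0]
        ra = influence_curve(
            trials, ("own_d0", "baseline"), {"frame": "loss", "norm_type": "risk_averse"}
        )
        rs = influence_curve(
            trials, ("own_d0", "baseline"), {"frame": "loss", "norm_type": "risk_seeking"}
        )
        assert ra.marginal_delta < 0 < rs.marginal_delta
        assert ra.abs_magnitude == abs(ra.marginal_delta)

    def test_swapping_phases_negates_deltas(self, moral_cohort):
        trials = moral_cohort[0]
        cond = {"frame": "gain", "norm_type": "risk_seeking"}
        fwd = influence_curve(trials, ("own_d0", "baseline"), cond)
        rev = influence_curve(trials, ("baseline", "own_d0"), cond)
        assert fwd.marginal_delta == pytest.approx(-rev.marginal_delta)
        pd.testing.assert_series_equal(fwd.per_value_delta, -rev.per_value_delta)

    def test_missing_phase_rejected(self, moral_cohort):
        trials = moral_cohort[0]
        base_only = trials[trials["phase"] == "baseline"]
        with pytest.raises(ValueError, match="no own-choice trials"):
            influence_curve(base_only, ("own_d0", "baseline"), {"frame": "gain"})

    def test_full_persistence_retains_influence(self):
        priors = fixed_priors(AgentParams(0.8, 1.5, 1.0, 0.0, 0.5, 1.0))
        trials, _, _ = simulate_cohort(
            n_per_cell=40, domains=("moral",), param_priors=priors, seed=21
        )
        cond = {"frame": "loss", "norm_type": "risk_averse"}
        d0 = influence_curve(trials, ("own_d0", "baseline"), cond)
        d3 = persistence(trials, cond)
        assert d3.ci_low <= d0.marginal_delta <= d3.ci_high or abs(
            d3.marginal_delta - d0.marginal_delta
        ) < 0.05

    def test_zero_persistence_erases_day3_influence(self):
        priors = fixed_priors(AgentParams(0.8, 1.5, 1.0, 0.0, 0.5, 0.0))
        trials, _, _ = simulate_cohort(
            n_per_cell=40, domains=("moral",), param_priors=priors, seed=12
        )
        cond = {"frame": "loss", "norm_type": "risk_averse"}
        d0 = influence_curve(trials, ("own_d0", "baseline"), cond)
        d3 = persistence(trials, cond)
        assert d0.marginal_delta < -0.05  # day-0 effect present
        assert abs(d3.marginal_delta) < 0.05  # gone at day 3


class TestWilcoxon:
    def test_matches_brute_force_enumeration(self):
        """Six-participant fixture: statistic and exact p reproduced by
        enumerating all 2^6 sign assignments."""
        phaseA = np.array([0.8, 0.4, 0.7, 0.9, 0.1, 0.9])
        phaseB = phaseA - np.array([0.3, -0.1, 0.2, 0.5, -0.4, 0.6])
        stat, p, n = wilcoxon_paired(phaseA, phaseB)
        d = phaseA - phaseB
        ranks = stats.rankdata(np.abs(d))
        w_plus = ranks[d > 0].sum()
        total = ranks.sum()
        w_min = min(w_plus, total - w_plus)
        dist = np.array(
            [
                sum(r for s, r in zip(signs, ranks) if s)
                for signs in itertools.product([0, 1], repeat=6)
            ]
        )
        p_exact = (np.sum(dist <= w_min) + np.sum(dist >= total - w_min)) / len(dist)
        assert n == 6
        assert stat == pytest.approx(w_min)
        assert p == pytest.approx(p_exact)

    def test_all_zero_differences_degenerate(self):
        stat, p, n = wilcoxon_paired([0.2, 0.4, 0.6], [0.2, 0.4, 0.6])
        assert n == 0 and np.isnan(stat) and np.isnan(p)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.random(60)
        y = x + rng.normal(0.1, 0.1, 60)
        stat, p, n = wilcoxon_paired(x, y)
        assert 0 < p < 1 and n == 60


class TestEntropyComparison:
    def test_norms_reduce_choice_uncertainty(self, uncertain_extreme_cohort):
        """Uncertain agents mixing toward steep norm schedules become more
        consistent: baseline entropy exceeds post-learning entropy."""
        es = entropy_phase_comparison(uncertain_extreme_cohort, "baseline", "own_d0")
        assert (
            es.per_participant["baseline"].mean()
            > es.per_participant["own_d0"].mean()
        )
        assert es.p_value < 0.05
        assert not es.degenerate

    def test_identical_phases_flagged_degenerate(self, moral_cohort):
        trials = moral_cohort[0]
        base = trials[trials["phase"] == "baseline"]
        clone = base.copy()
        clone["phase"] = "own_d0"
        es = entropy_phase_comparison(pd.concat([base, clone]), "baseline", "own_d0")
        assert es.degenerate and np.isnan(es.p_value)

    def test_single_repeat_rejected(self, moral_cohort):
        trials = moral_cohort[0]
        one_rep = trials[trials["repeat_index"] == 0]
        with pytest.raises(ValueError, match="repeats"):
            entropy_phase_comparison(one_rep, "baseline", "own_d0")


class TestAlignment:
    @staticmethod
    def _influence(values, deltas):
        return InfluenceEstimate(
            condition={},
            phase_pair=("own_d0", "baseline"),
            per_value_delta=pd.Series(deltas, index=values),
            marginal_delta=float(np.mean(deltas)),
            ci_low=0,
            ci_high=0,
            n_participants=1,
        )

    def test_peak_and_crossing_coincide(self):
        values = list(range(10, 31, 2))
        deltas = [-abs(v - 20) / 20 + 0.3 for v in values]  # peak at 20
        baseline = pd.Series(
            [1 / (1 + np.exp(-(20 - v) / 4)) for v in values], index=values
        )  # crosses 0.5 at 20
        res = peak_influence_alignment(self._influence(values, deltas), baseline)
        assert res.peak_value == 20
        assert res.crossing_value == pytest.approx(20)
        assert res.distance == pytest.approx(0)

    def test_interpolated_crossing(self):
        values = [10, 20, 30]
        baseline = pd.Series([0.8, 0.6, 0.2], index=values)
        res = peak_influence_alignment(
            self._influence(values, [0.0, 0.1, 0.0]), baseline
        )
        # 0.5 crossed between 20 (0.6) and 30 (0.2): 20 + 10 * 0.1/0.4
        assert res.crossing_value == pytest.approx(22.5)

    def test_flat_high_baseline_has_no_crossing(self):
        values = list(range(10, 31, 2))
        baseline = pd.Series(0.9, index=values)
        res = peak_influence_alignment(
            self._influence(values, [0.1] * len(values)), baseline
        )
        assert not res.crossing_defined
        assert res.distance is None

    def test_mixture_generator_aligns_peak_with_uncertainty(self, moral_cohort):
        from riskconform import fit_mixed_logit
        from riskconform.models import ModelSpec, cell_value_curve

        trials = moral_cohort[0]
        fit = fit_mixed_logit(trials, ModelSpec(phases=("baseline", "own_d0")))
        dists = []
        for frame in ("gain", "loss"):
            for norm in ("risk_averse", "risk_seeking"):
                est = influence_curve(
                    trials,
                    ("own_d0", "baseline"),
                    {"frame": frame, "norm_type": norm},
                    fit=fit,
                    n_draws=50,
                )
                base = cell_value_curve(fit, ("baseline", norm, frame))
                res = peak_influence_alignment(est, base)
                if res.crossing_defined:
                    dists.append(res.distance)
        assert len(dists) >= 2
        assert np.mean(dists) <= 4.0


class TestAwareness:
    def test_perfectly_linear_awareness_gives_r_one(self):
        conf = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("abcd"))
        aware = 10 + 100 * conf
        res = awareness_conformity_correlation(aware, conf)
        assert res.r == pytest.approx(1.0)
        assert res.df == 2

    def test_zero_variance_rejected(self):
        conf = pd.Series([0.1, 0.2, 0.3], index=list("abc"))
        aware = pd.Series([5.0, 5.0, 5.0], index=list("abc"))
        with pytest.raises(ValueError, match="zero variance"):
            awareness_conformity_correlation(aware, conf)

    def test_shuffled_pairing_destroys_correlation(self, moral_cohort):
        trials, _, participants = moral_cohort
        conf = participant_conformity(trials)
        aware = participants.set_index("participant_id")["awareness"]
        rng = np.random.default_rng(0)
        n_small = 0
        for _ in range(40):
            shuffled = pd.Series(
                rng.permutation(aware.loc[conf.index].to_numpy()), index=conf.index
            )
            r = awareness_conformity_correlation(shuffled, conf).r
            n_small += abs(r) < 0.15
        assert n_small >= 38  # |r| < 0.15 in >= 95% of shuffles

    def test_generated_awareness_positively_correlated(self):
        rs = []
        for seed in range(5):
            trials, _, participants = simulate_cohort(
                n_per_cell=90, domains=("moral",), seed=seed
            )
            conf = participant_conformity(trials)
            aware = participants.set_index("participant_id")["awareness"]
            rs.append(awareness_conformity_correlation(aware, conf).r)
        assert all(r > 0 for r in rs)
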
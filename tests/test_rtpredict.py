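"""Single-trial RT prediction tests: binning/smoothing, projection, the
criterion rule, crossing-time prediction, speed decoding, and the
premovement/movement classifier."""

import numpy as np
import pytest
from scipy import stats

from cispop.containers import SingleTrialDataset
from cispop.demix import fit_pca
from cispop.rtpredict import (
    CriterionRule,
    TrialProjection,
    cis_speed_correlation,
    classifier_influence,
    compute_criterion,
    fit_move_classifier,
    fit_speed_decoder,
    mean_over_units_weights,
    predict_rt,
    prepare_trial_rates,
    project_trials,
)


def _trials_from_spikes(spike_sets, n_units, go=500.0, move=800.0):
    n = len(spike_sets)
    units, times = [], []
    for s in spike_sets:
        u = np.asarray([x[0] for x in s], np.int32)
        t = np.asarray([x[1] for x in s], float)
        units.append(u)
        times.append(t)
    return SingleTrialDataset(
        spike_units=units, spike_times=times,
        condition=np.zeros(n, int), delay=np.full(n, go),
        go_time=np.full(n, go), move_time=np.full(n, move),
        rt=np.full(n, move - go), n_units=n_units, dt=10.0,
    )


class TestPrepareTrialRates:
    def test_empty_trial_zero_trace(self):
        trials = _trials_from_spikes([[]], n_units=2)
        rates, bins = prepare_trial_rates(trials)
        assert np.all(rates == 0.0)
        assert bins[0] == -55.0 and bins[-1] == 495.0

    def test_one_spike_per_bin_is_100_hz(self):
        spikes = [(0, 500.0 + t) for t in np.arange(-60.0, 500.0, 10.0) + 5.0]
        trials = _trials_from_spikes([spikes], n_units=1)
        rates, bins = prepare_trial_rates(trials)
        mid = (bins > -20) & (bins < 460)
        assert np.allclose(rates[0, 0, mid], 100.0, atol=1.0)

    def test_mass_conserved_within_edge_loss(self):
        rng = np.random.default_rng(0)
        spikes = [(0, float(t)) for t in rng.uniform(450.0, 990.0, 60)]
        trials = _trials_from_spikes([spikes], n_units=1)
        rates, bins = prepare_trial_rates(trials)
        mass = rates.sum() * 0.01  # spikes
        n_in = sum(1 for _, t in spikes if -60.0 <= t - 500.0 < 500.0)
        assert abs(mass - n_in) / n_in < 0.05


class TestProjectTrials:
    def test_uniform_weights_constant_rate(self):
        rates = np.full((3, 4, 10), 20.0)
        bins = np.arange(10) * 10.0
        norm = np.full(4, 35.0)
        proj = project_trials(rates, bins, mean_over_units_weights(4), norm, 5.0,
                              "mean", np.zeros(3), np.zeros(3))
        assert np.allclose(proj.z, 20.0 / 40.0)

    def test_orthogonal_weights_contribute_nothing(self):
        rng = np.random.default_rng(1)
        pattern = rng.normal(size=4)
        w = np.array([pattern[1], -pattern[0], 0.0, 0.0])
        rates = np.tile(pattern[None, :, None], (2, 1, 10))
        proj = project_trials(rates, np.arange(10.0), w, np.zeros(4), 1.0,
                              "w", np.zeros(2), np.zeros(2))
        assert np.max(np.abs(proj.z)) < 1e-12

    def test_unit_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            project_trials(np.zeros((2, 3, 5)), np.arange(5.0), np.zeros(4),
                           np.zeros(4), 1.0, "w", np.zeros(2), np.zeros(2))


def _projection(z, bins=None, delay=None, rt=None):
    z = np.asarray(z, float)
    if bins is None:
        bins = np.arange(z.shape[1]) * 10.0 - 55.0
    n = z.shape[0]
    return TrialProjection(
        z=z, bins=np.asarray(bins, float), method="test",
        weights=np.ones(1),
        delay=np.zeros(n) if delay is None else np.asarray(delay, float),
        rt=np.zeros(n) if rt is None else np.asarray(rt, float),
    )


class TestCriterion:
    def test_midpoint_of_range(self):
        z = np.tile(np.linspace(0.0, 1.0, 30), (12, 1))
        rule = compute_criterion(_projection(z))
        assert rule.criterion == pytest.approx(0.5)

    def test_single_peak_midway(self):
        trace = np.zeros(30)
        trace[20] = 2.0
        rule = compute_criterion(_projection(np.tile(trace, (12, 1))))
        assert rule.criterion == pytest.approx(1.0)

    def test_flat_trace_rejected(self):
        with pytest.raises(ValueError, match="uninformative"):
            compute_criterion(_projection(np.ones((12, 30))))

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            compute_criterion(_projection(np.random.rand(4, 30)))

    def test_falling_dimension_sign_flipped(self):
        z = np.tile(np.linspace(1.0, 0.0, 30), (12, 1))
        rule = compute_criterion(_projection(z))
        assert rule.sign == -1.0

    def test_split_half_stability(self, default_dm, default_dec, default_trials):
        long = default_trials.select(default_trials.delay == 500.0)
        rates, bins = prepare_trial_rates(long)
        proj = project_trials(rates, bins, default_dec.W[:, default_dec.cis1],
                              default_dm.norm_range, default_dm.norm_const,
                              "cis1", long.delay, long.rt)
        half = proj.n_trials // 2
        r1 = compute_criterion(_projection(proj.z[:half], proj.bins))
        r2 = compute_criterion(_projection(proj.z[half:], proj.bins))
        spread = r1.median_trace.max() - r1.median_trace.min()
        assert abs(r1.criterion - r2.criterion) < 0.1 * spread


class TestPredictRt:
    def test_identical_trials_flagged(self):
        z = np.tile(np.linspace(0, 1, 56), (10, 1))
        rule = compute_criterion(_projection(z))
        res = predict_rt(_projection(z), rule)
        assert np.isnan(res.r_by_delay[0.0])

    def test_perfect_coupling_gives_r_one(self):
        rng = np.random.default_rng(0)
        bins = np.arange(56) * 10.0 - 55.0
        rts = rng.uniform(250.0, 400.0, 40)
        z = np.zeros((40, 56))
        for i, rt in enumerate(rts):
            z[i] = (bins >= rt - 150.0).astype(float)
        proj = _projection(z, bins, rt=rts)
        rule = CriterionRule(criterion=0.5, median_trace=np.median(z, 0), bins=bins)
        res = predict_rt(proj, rule)
        # sub-bin interpolation leaves only the 10 ms quantization residue
        assert res.r_by_delay[0.0] > 0.995

    def test_crossing_monotone_in_criterion(self):
        rng = np.random.default_rng(3)
        bins = np.arange(56) * 10.0 - 55.0
        z = np.cumsum(rng.uniform(0, 1, (20, 56)), axis=1)
        prev = np.full(20, -np.inf)
        for crit in [5.0, 10.0, 15.0]:
            rule = CriterionRule(criterion=crit, median_trace=np.median(z, 0),
                                 bins=bins)
            res = predict_rt(_projection(z, bins), rule)
            cur = np.where(np.isnan(res.crossing), np.inf, res.crossing)
            assert np.all(cur >= prev - 1e-9)
            prev = cur

    def test_exclusion_accounting(self, default_dm, default_dec, default_trials):
        long = default_trials.select(default_trials.delay == 500.0)
        rates, bins = prepare_trial_rates(long)
        proj = project_trials(rates, bins, default_dec.W[:, default_dec.cis1],
                              default_dm.norm_range, default_dm.norm_const,
                              "cis1", long.delay, long.rt)
        rule = compute_criterion(proj)
        res = predict_rt(proj, rule)
        usable = int(res.usable.sum())
        excluded = int((res.excluded != "").sum())
        assert usable + excluded == proj.n_trials
        assert 0.0 <= res.excluded_fraction <= 1.0


class TestSpeedDecoder:
    def test_zero_speed_gives_zero_weights(self, noiseless_dm, default_cfg):
        speed = np.zeros((27, default_cfg.move_grid().size))
        dec = fit_speed_decoder(noiseless_dm, speed, default_cfg.move_grid())
        assert np.max(np.abs(dec.weights)) < 1e-6
        assert abs(dec.bias) < 1e-6

    def test_single_unit_speed_recovered(self):
        """Speed equal to one unit's (advanced) rate fits perfectly when the
        unit is silent outside the movement epoch."""
        from tests.test_demix import _matrix_from_tensor

        rng = np.random.default_rng(8)
        C, T, n = 5, 60, 6
        tens = rng.uniform(0, 1, (C, T, n))
        mg = np.arange(T) * 10.0 - 200.0
        mg_ext = np.arange(mg[0], mg[-1] + 151.0, 10.0)  # covers the lead
        speed = np.stack([np.interp(mg_ext - 150.0, mg, tens[c, :, 0],
                                    left=tens[c, 0, 0], right=tens[c, -1, 0])
                          for c in range(C)])
        dm = _matrix_from_tensor(tens)
        dm.time[:] = np.tile(mg, C)
        dec = fit_speed_decoder(dm, speed, mg_ext, lead_ms=150.0)
        assert dec.fit_r > 1.0 - 1e-9
        assert abs(dec.weights[0] - 1.0) < 1e-6

    def test_generator_speed_decodable(self, noiseless_dm, default_cfg,
                                       default_population):
        speed = default_population.ground_truth["condition_speed"]
        dec = fit_speed_decoder(noiseless_dm, speed, default_cfg.move_grid())
        assert dec.fit_r > 0.6


class TestClassifier:
    def test_planted_transition_classified(self, default_dm, default_dec,
                                           default_trials):
        sub = default_trials.select(np.arange(0, default_trials.n_trials, 15))
        model = fit_move_classifier(sub, default_dec, default_dm.norm_range,
                                    default_dm.norm_const)
        assert model.accuracy > 0.9
        infl, share = classifier_influence(model, default_dec)
        assert np.all(infl >= 0.0)
        assert share > 0.5  # the CIS carries the classification

    def test_influence_formula(self, default_dec):
        from cispop.rtpredict import ClassifierModel

        data = np.zeros((100, 2))
        rng = np.random.default_rng(0)
        data[:, 0] = rng.normal(0, 1.0, 100)
        data[:, 1] = rng.normal(0, 1.0, 100)
        data[:, 1] *= np.std(data[:, 0]) / np.std(data[:, 1])  # equal variance
        model = ClassifierModel(weights=np.array([2.0, 1.0]), intercept=0.0,
                                accuracy=1.0, premove_bin=(0, 0), move_bin=(0, 0),
                                meta={"training_data": data})
        import copy

        dec = copy.copy(default_dec)
        dec.f_ci = np.array([0.9, 0.1])
        infl, share = classifier_influence(model, dec, projected=data)
        assert infl[0] / infl[1] == pytest.approx(2.0, rel=1e-9)

    def test_zero_weight_zero_influence(self, default_dec):
        import copy

        from cispop.rtpredict import ClassifierModel

        data = np.random.default_rng(1).normal(size=(50, 3))
        model = ClassifierModel(weights=np.array([0.0, 1.0, 1.0]), intercept=0.0,
                                accuracy=1.0, premove_bin=(0, 0), move_bin=(0, 0),
                                meta={"training_data": data})
        dec = copy.copy(default_dec)
        dec.f_ci = np.array([0.9, 0.2, 0.1])
        infl, _ = classifier_influence(model, dec, projected=data)
        assert infl[0] == 0.0


class TestCisSpeedCorrelation:
    def test_proportional_peaks_give_r_one(self):
        rng = np.random.default_rng(0)
        peaks = rng.uniform(1.0, 3.0, 10)
        t = np.linspace(0, 1, 50)
        cis = peaks[:, None] * np.sin(np.pi * t)[None, :]
        speed = 2.0 * peaks[:, None] * np.cos(np.pi * t / 2)[None, :]
        r, p = cis_speed_correlation(cis, speed)
        assert r == pytest.approx(1.0)

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            cis_speed_correlation(np.random.rand(3, 10), np.random.rand(3, 10))

    def test_constant_input_flagged(self):
        r, p = cis_speed_correlation(np.ones((6, 10)), np.random.rand(6, 10))
        assert np.isnan(r)

    def test_null_p_values_uniform(self):
        """Independent draws: the correlation p-value is uniform under the
        null (Kolmogorov-Smirnov on repeated simulations)."""
        rng = np.random.default_rng(42)
        t = np.linspace(0, 1, 20)
        pvals = []
        for _ in range(300):
            cis = rng.uniform(1, 2, 27)[:, None] * np.sin(np.pi * t)[None, :]
            speed = rng.uniform(1, 2, 27)[:, None] * np.cos(np.pi * t / 2)[None, :]
            pvals.append(cis_speed_correlation(cis, speed)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_dissociation(self, default_dec, default_population):
        speed = default_population.ground_truth["condition_speed"]
        cis1 = default_dec.component_timecourse(default_dec.cis1)
        r, _ = cis_speed_correlation(cis1, speed)
        assert abs(r) < 0.3


class TestMethodOrdering:
    def test_cis1_beats_mean_over_units(self, default_dm, default_dec,
                                        default_trials):
        long = default_trials.select(default_trials.delay == 500.0)
        rates, bins = prepare_trial_rates(long)
        rs = {}
        for name, w in [("cis1", default_dec.W[:, default_dec.cis1]),
                        ("mean", mean_over_units_weights(default_dm.n_units))]:
            proj = project_trials(rates, bins, w, default_dm.norm_range,
                                  default_dm.norm_const, name, long.delay, long.rt)
            rule = compute_criterion(proj)
            rs[name] = predict_rt(proj, rule).r_by_delay[500.0]
        assert rs["cis1"] >= rs["mean"]
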
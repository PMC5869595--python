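import numpy as np
import pandas as pd
import pytest
from scipy import stats

from srsmotor.engine import (BOUND, TRANSLOCATING, ScenarioError,
                             run_simulation, sample_slide_step, site_type)
from srsmotor.params import ModelParams, ParameterError
from srsmotor.substrate import SubstrateSpec, make_dna_ns, make_dna_srs


class TestSiteType:
    def test_interval_boundaries_half_open(self):
        spec = make_dna_srs(3000, 300, 22)
        assert site_type(spec, 300) == "SRS"
        assert site_type(spec, 321) == "SRS"
        assert site_type(spec, 322) == "NS"
        assert site_type(spec, 299) == "NS"

    def test_ns_substrate_all_ns(self):
        spec = make_dna_ns()
        assert site_type(spec, 310) == "NS"

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            site_type(make_dna_ns(), 3000)


class TestParams:
    def test_default_translocation_step(self):
        assert ModelParams().v_step == 350  # 5000 bp/s * 0.07 s/MCS

    def test_probability_bounds_enforced(self):
        with pytest.raises(ParameterError):
            ModelParams(p_on_ns=1.5)

    def test_sub_site_velocity_rejected_for_atp(self):
        with pytest.raises(ParameterError):
            ModelParams(v_trans=1.0).require_v_step()

    def test_off_rate_ratio_srs_vs_ns(self):
        p = ModelParams()
        assert p.p_off_ns / p.p_off_srs == pytest.approx(2.33, abs=0.01)


class TestDeterminism:
    def test_identical_seed_identical_output(self, tiny_spec, tiny_params):
        kw = dict(n_dna=50, seed=42, equilibration_mcs=100, sampling_mcs=200)
        a = run_simulation(tiny_spec, tiny_params, "no_atp", **kw)
        b = run_simulation(tiny_spec, tiny_params, "no_atp", **kw)
        pd.testing.assert_frame_equal(a.events, b.events)
        assert (a.sample_positions == b.sample_positions).all()
        assert (a.sample_status == b.sample_status).all()

    def test_different_seed_differs(self, tiny_spec, tiny_params):
        kw = dict(n_dna=50, equilibration_mcs=100, sampling_mcs=200)
        a = run_simulation(tiny_spec, tiny_params, "no_atp", seed=1, **kw)
        b = run_simulation(tiny_spec, tiny_params, "no_atp", seed=2, **kw)
        assert not a.events.equals(b.events)


class TestBindingUnbinding:
    def test_zero_p_on_never_binds(self, tiny_spec):
        p = ModelParams(p_on_srs=0, p_on_ns=0)
        res = run_simulation(tiny_spec, p, "no_atp", n_dna=100, seed=0,
                             equilibration_mcs=0, sampling_mcs=300)
        assert res.attached_count.sum() == 0
        assert len(res.events) == 0

    def test_binding_frequency_matches_p_on(self):
        """Per-MCS binding frequency of an unbound motor equals p_on."""
        spec = make_dna_ns()
        p = ModelParams(p_off_ns=1.0, p_off_srs=1.0)  # unbind right away
        T = 400
        res = run_simulation(spec, p, "no_atp", n_dna=500, seed=3,
                             equilibration_mcs=0, sampling_mcs=T,
                             record_positions=False)
        binds = (res.events["event"] == "bind").sum()
        # exposure: every motor-MCS spent unbound
        exposure = 500 * T - res.attached_count.sum()
        freq = binds / exposure
        se = np.sqrt(p.p_on_ns * (1 - p.p_on_ns) / exposure)
        assert abs(freq - 0.022) < 4 * se

    def test_unbinding_frequency_matches_p_off(self):
        """Bound-state survival follows p_off per MCS (homogeneous DNA)."""
        spec = make_dna_ns()
        p = ModelParams(p_off_ns=0.014)
        res = run_simulation(spec, p, "no_atp", n_dna=400, seed=4,
                             equilibration_mcs=0, sampling_mcs=1500,
                             record_positions=False)
        unbinds = (res.events["event"] == "unbind").sum()
        exposure = res.bound_count.sum()
        freq = unbinds / exposure
        se = np.sqrt(0.014 * (1 - 0.014) / exposure)
        assert abs(freq - 0.014) < 4 * se

    def test_bound_residence_is_geometric(self):
        """Residence durations on homogeneous DNA follow Geometric(p_off)."""
        spec = make_dna_ns()
        p = ModelParams(p_off_ns=0.05)
        res = run_simulation(spec, p, "no_atp", n_dna=500, seed=5,
                             equilibration_mcs=0, sampling_mcs=1200,
                             record_positions=False)
        durations = []
        for _, grp in res.events.groupby("motor", sort=False):
            start = None
            for mcs, ev in zip(grp["mcs"], grp["event"]):
                if ev == "bind":
                    start = mcs
                elif ev == "unbind" and start is not None:
                    durations.append(mcs - start)
                    start = None
        durations = np.asarray(durations)
        assert durations.size > 5_000
        assert durations.mean() == pytest.approx(1 / 0.05, rel=0.05)
        # chi-square goodness of fit (appropriate for a discrete law)
        kmax = 60
        obs = np.bincount(np.minimum(durations, kmax + 1),
                          minlength=kmax + 2)[1:]
        pmf = stats.geom(0.05).pmf(np.arange(1, kmax + 1))
        expected = np.append(pmf, 1 - pmf.sum()) * durations.size
        chi2 = stats.chisquare(obs, expected)
        assert chi2.pvalue > 0.01


class TestActivationTranslocation:
    def test_no_atp_scenario_never_translocates(self, tiny_spec, tiny_params):
        res = run_simulation(tiny_spec, tiny_params, "no_atp", n_dna=100,
                             seed=6, equilibration_mcs=0, sampling_mcs=500)
        assert (res.translocating_count == 0).all()
        assert (res.events["event"] != "activate").all()

    def test_activation_frequency_matches_p_atp(self):
        spec = make_dna_ns()
        p = ModelParams(p_atp_ns=0.012, p_atp_srs=0.012)
        res = run_simulation(spec, p, "atp", n_dna=400, seed=7,
                             equilibration_mcs=0, sampling_mcs=1000,
                             record_positions=False)
        acts = (res.events["event"] == "activate").sum()
        exposure = res.bound_count.sum() + acts  # activation precedes count
        freq = acts / exposure
        se = np.sqrt(0.012 * (1 - 0.012) / exposure)
        assert abs(freq - 0.012) < 5 * se

    def test_translocation_advances_v_step_per_mcs(self):
        spec = make_dna_ns(length_bp=20000, window_offset_bp=100,
                           window_length_bp=22)
        p = ModelParams(p_atp_ns=1.0, p_atp_srs=1.0, p_off_ns=0.0,
                        p_off_srs=0.0, p_on_ns=1.0, p_on_srs=1.0)
        res = run_simulation(spec, p, "atp", n_dna=1, seed=8,
                             equilibration_mcs=0, sampling_mcs=60,
                             record_trajectories=1)
        traj = res.trajectories[:, 0].astype(float)
        moves = np.diff(traj)
        moving = np.abs(moves) > 0
        interior = moving & (traj[1:] > 0) & (traj[1:] < 19999)
        assert interior.any()
        assert set(np.abs(moves[interior]).astype(int)) == {350}

    def test_full_direction_bias_sends_all_srs_activations_to_triplex_end(self):
        spec = make_dna_srs(triplex="left")
        p = ModelParams(p_dir=1.0, p_atp_srs=1.0, p_atp_ns=0.0, p_off_ns=0.0,
                        p_off_srs=0.0)
        res = run_simulation(spec, p, "triplex", n_dna=200, seed=9,
                             max_mcs=2000, record_positions=False)
        # every motor that activates does so on SRS and must head left:
        # the only end events are triplex releases at position 0
        ev = res.events
        assert (ev.loc[ev["event"] == "activate", "position"]
                .between(300, 321).all())
        assert (ev["event"] != "arrive_end").all()
        assert (ev.loc[ev["event"] == "release_triplex", "position"] == 0).all()

    def test_direction_split_even_at_half_p_dir(self):
        """NS activations head to either end 50/50 (binomial 4 sigma)."""
        spec = make_dna_ns()
        p = ModelParams(p_atp_ns=0.012, p_atp_srs=0.012)
        res = run_simulation(spec, p, "atp", n_dna=600, seed=10,
                             record_positions=False)
        ends = res.events.loc[res.events["event"] == "arrive_end", "position"]
        n_left = (ends == 0).sum()
        n = len(ends)
        assert n > 500
        assert abs(n_left - n / 2) < 4 * np.sqrt(n * 0.25)

    def test_instant_release_when_triplex_in_reach(self):
        # all-SRS substrate: bind -> activate -> head for the triplex
        spec = SubstrateSpec(length_bp=300,
                             srs_intervals=((0, 300, "toward_left_end"),),
                             triplex_end="left")
        p = ModelParams(p_dir=1.0, p_atp_srs=1.0, p_atp_ns=1.0, p_triplex=1.0,
                        p_on_ns=1.0, p_on_srs=1.0)
        res = run_simulation(spec, p, "triplex", n_dna=100, seed=11,
                             max_mcs=100, record_positions=False)
        assert res.released_cum[-1] == 100
        assert res.n_mcs < 10

    def test_triplex_scenario_requires_triplex(self):
        with pytest.raises(ScenarioError):
            run_simulation(make_dna_srs(), ModelParams(), "triplex", n_dna=5,
                           seed=0)


class TestExclusionAndCollisions:
    @pytest.mark.parametrize("motors_per_dna", [2, 4])
    def test_single_occupancy_after_every_mcs(self, motors_per_dna):
        spec = SubstrateSpec(length_bp=30)
        p = ModelParams(p_on_ns=0.5, p_off_ns=0.05, sld_ns_mean=3,
                        sld_ns_sd=1)
        res = run_simulation(spec, p, "no_atp", n_dna=40, seed=12,
                             motors_per_dna=motors_per_dna,
                             equilibration_mcs=0, sampling_mcs=400)
        pos, st = res.sample_positions, res.sample_status
        attached = (st == BOUND) | (st == TRANSLOCATING)
        r = pos.shape[1]
        dna = np.repeat(np.arange(40), motors_per_dna)
        for t in range(pos.shape[0]):
            keys = dna[attached[t]] * 30 + pos[t][attached[t]]
            assert len(keys) == len(set(keys))

    def test_single_site_exclusion_blocks_second_binding(self):
        spec = SubstrateSpec(length_bp=2)
        p = ModelParams(p_on_ns=1.0, p_off_ns=0.0, sld_ns_mean=0,
                        sld_ns_sd=0.0)
        res = run_simulation(spec, p, "no_atp", n_dna=1, seed=13,
                             motors_per_dna=3, equilibration_mcs=0,
                             sampling_mcs=50)
        # 3 motors, 2 sites, no unbinding: at most 2 ever attached
        assert res.attached_count.max() == 2


class TestStationaryBehaviour:
    def test_bound_count_plateaus_before_2000_mcs(self):
        """The no-ATP system equilibrates within ~2000 MCS."""
        spec = make_dna_srs()
        res = run_simulation(spec, ModelParams(), "no_atp", n_dna=800,
                             seed=14, log_events=False)
        early = res.attached_count[1500:2000].mean()
        late = res.attached_count[2500:3000].mean()
        assert late > 0
        assert abs(early - late) / late < 0.05

    def test_first_arrival_symmetry_without_srs(self):
        """With no SRS and symmetric rules, both ends are reached equally."""
        spec = make_dna_ns()
        res = run_simulation(spec, ModelParams(), "atp", n_dna=800, seed=15,
                             record_positions=False)
        arr = res.events.loc[res.events["event"] == "arrive_end", "position"]
        n_left, n = (arr == 0).sum(), len(arr)
        assert abs(n_left - n / 2) < 4 * np.sqrt(n * 0.25)


def test_sample_slide_step_sign_and_magnitude(rng):
    p = ModelParams(sld_ns_mean=5.0, sld_ns_sd=0.0)
    draws = {sample_slide_step(p, "NS", rng) for _ in range(50)}
    assert draws == {-5, 5}
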
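"""Kinetic Monte Carlo engine for SpoIIIE/DNA dynamics.

Each of ``m`` DNA molecules is a 1D lattice of ``n`` sites (1 site = 1 bp);
``r`` motors (default one per molecule, the experimental stoichiometry of
~1 hexamer per DNA) bind, unbind, slide, activate and translocate with
per-MCS probabilities that depend on whether the occupied site is SRS or
non-specific (NS).

One Monte Carlo step (MCS) applies, to every motor, from the common
pre-step state:

1. unbound motors draw a uniformly random candidate site on their DNA and
   bind with probability ``p_on(site type)`` if the site is free;
2. bound motors unbind with ``p_off(site type)``; survivors, in ATP
   scenarios, activate with ``p_atp(site type)`` (direction: the
   SRS-dictated direction with probability ``p_dir`` when activated on an
   SRS site, +/-1 equiprobably on NS sites); bound motors that did not
   activate take one sliding step (magnitude ~ discretised
   |Normal(sld_mean, sld_sd)| for the site type, sign +/-1), reflecting off
   the lattice boundaries.  A sliding motor scans the DNA it passes over
   and is captured by the first SRS site crossed (1D sliding is the
   target-search mechanism);
3. translocating motors unbind with ``p_off^NS``; survivors advance
   ``v_step = round(v_trans * dt)`` sites along their fixed direction.
   Reaching the triplex-bearing end releases the triplex with probability
   ``p_triplex`` and retires that DNA molecule from all further dynamics.
   Reaching a plain end arrests the motor at the terminal site: it keeps
   its translocating state and direction (direction is constant until the
   motor dissociates) and leaves only by unbinding with ``p_off^NS`` per
   MCS.
4. same-site conflicts are resolved: a translocating motor displaces a
   bound/diffusing one; ties within a class are broken uniformly at random,
   the loser unbinds.

Updates are synchronous; with one motor per DNA molecule (the default) this
coincides with any sequential schedule because motors on different
molecules never interact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import (slide_destinations, slide_magnitude_pmf,
                      srs_neighbor_tables)
from .params import ModelParams
from .substrate import SubstrateSpec

# motor status codes
UNBOUND, BOUND, TRANSLOCATING, RETIRED = 0, 1, 2, 3
STATUS_NAMES = {UNBOUND: "unbound", BOUND: "bound",
                TRANSLOCATING: "translocating", RETIRED: "retired"}

# event codes
EV_BIND, EV_UNBIND, EV_ACTIVATE, EV_ARRIVE_END, EV_RELEASE, EV_REACH_SRS = range(6)
EVENT_NAMES = {EV_BIND: "bind", EV_UNBIND: "unbind", EV_ACTIVATE: "activate",
               EV_ARRIVE_END: "arrive_end", EV_RELEASE: "release_triplex",
               EV_REACH_SRS: "reach_srs"}

SCENARIOS = ("no_atp", "atp", "triplex")


class ScenarioError(ValueError):
    """Invalid scenario / substrate / parameter combination."""


def site_type(spec: SubstrateSpec, position: int) -> str:
    """``"SRS"`` if the site lies in an SRS interval, else ``"NS"``."""
    if not (0 <= position < spec.length_bp):
        raise IndexError(f"position {position} outside [0, {spec.length_bp})")
    return "SRS" if spec.is_srs_array()[position] else "NS"


def sample_slide_step(params: ModelParams, kind: str,
                      rng: np.random.Generator) -> int:
    """One signed sliding displacement (bp) for a site type."""
    if kind == "SRS":
        _, pmf = slide_magnitude_pmf(params.sld_srs_mean, params.sld_srs_sd)
    else:
        _, pmf = slide_magnitude_pmf(params.sld_ns_mean, params.sld_ns_sd)
    mag = rng.choice(len(pmf), p=pmf)
    sign = rng.integers(0, 2) * 2 - 1
    return int(mag * sign)


@dataclass
class SimResult:
    """Output of one simulation run."""

    spec: SubstrateSpec
    params: ModelParams
    scenario: str
    n_dna: int
    motors_per_dna: int
    seed: int
    n_mcs: int
    attached_count: np.ndarray        # per MCS: all DNA-attached motors
    bound_count: np.ndarray           # per MCS: diffusing (non-active) motors
    translocating_count: np.ndarray   # per MCS: active (incl. end-arrested)
    sample_mcs: np.ndarray            # MCS indices of the sampling window
    sample_positions: np.ndarray | None   # (S, r), -1 where detached
    sample_status: np.ndarray | None      # (S, r)
    released_cum: np.ndarray | None   # per MCS cumulative released triplexes
    events: pd.DataFrame | None
    trajectories: np.ndarray | None = None  # (n_mcs, k) positions, -1 detached
    _meta: dict = field(default_factory=dict)

    @property
    def released_fraction(self) -> np.ndarray | None:
        if self.released_cum is None:
            return None
        return self.released_cum / self.n_dna

    def events_frame(self) -> pd.DataFrame:
        if self.events is None:
            raise ValueError("run was executed with log_events=False")
        return self.events

    def to_event_tsv(self, path) -> None:
        self.events_frame().to_csv(path, sep="\t", index=False)


class _EventLog:
    __slots__ = ("mcs", "motor", "code", "pos")

    def __init__(self):
        self.mcs, self.motor, self.code, self.pos = [], [], [], []

    def add(self, t: int, motors: np.ndarray, code: int, positions: np.ndarray):
        if motors.size == 0:
            return
        self.mcs.append(np.full(motors.size, t, dtype=np.int64))
        self.motor.append(motors.astype(np.int64))
        self.code.append(np.full(motors.size, code, dtype=np.int8))
        self.pos.append(np.asarray(positions, dtype=np.int64))

    def frame(self, dna_of_motor: np.ndarray) -> pd.DataFrame:
        if not self.mcs:
            return pd.DataFrame(columns=["mcs", "motor", "dna", "event",
                                         "position"])
        mcs = np.concatenate(self.mcs)
        motor = np.concatenate(self.motor)
        code = np.concatenate(self.code)
        pos = np.concatenate(self.pos)
        df = pd.DataFrame({
            "mcs": mcs, "motor": motor, "dna": dna_of_motor[motor],
            "event": pd.Categorical.from_codes(code,
                                               list(EVENT_NAMES.values())),
            "position": pos,
        })
        df.sort_values(["mcs", "motor"], kind="stable", inplace=True,
                       ignore_index=True)
        return df


def run_simulation(
    spec: SubstrateSpec,
    params: ModelParams,
    scenario: str,
    n_dna: int = 1000,
    seed: int = 0,
    motors_per_dna: int = 1,
    equilibration_mcs: int | None = None,
    sampling_mcs: int | None = None,
    max_mcs: int | None = None,
    record_positions: bool = True,
    log_events: bool = True,
    record_trajectories: int = 0,
) -> SimResult:
    """Run the lattice model.

    Non-triplex scenarios run ``equilibration_mcs + sampling_mcs`` steps and
    record per-MCS occupancy snapshots during the sampling window.  Triplex
    scenarios run until every triplex is released (or ``max_mcs``, default
    20000) and record the cumulative released count from t = 0.  Identical
    arguments and seed give bit-identical output.
    """
    if scenario not in SCENARIOS:
        raise ScenarioError(f"unknown scenario {scenario!r}")
    if n_dna < 1 or motors_per_dna < 1:
        raise ScenarioError("need n_dna >= 1 and motors_per_dna >= 1")
    triplex = scenario == "triplex"
    atp = scenario in ("atp", "triplex")
    if triplex and spec.triplex_end == "none":
        raise ScenarioError("triplex scenario requires a substrate with a "
                            "triplex end")
    if atp:
        params.require_v_step()

    equil = params.equilibration_mcs if equilibration_mcs is None else equilibration_mcs
    sample = params.sampling_mcs if sampling_mcs is None else sampling_mcs
    if triplex:
        total = 20000 if max_mcs is None else max_mcs
        sample_lo, sample_hi = total, total  # no occupancy sampling window
    else:
        total = equil + sample if max_mcs is None else max_mcs
        sample_lo, sample_hi = equil, min(equil + sample, total)

    n = spec.length_bp
    r = n_dna * motors_per_dna
    rng = np.random.default_rng(seed)

    is_srs = spec.is_srs_array()
    srs_dir = spec.srs_direction_array().astype(np.int64)
    p_on_site = np.where(is_srs, params.p_on_srs, params.p_on_ns)
    p_off_site = np.where(is_srs, params.p_off_srs, params.p_off_ns)
    p_atp_site = np.where(is_srs, params.p_atp_srs, params.p_atp_ns)
    _, pmf_ns = slide_magnitude_pmf(params.sld_ns_mean, params.sld_ns_sd)
    _, pmf_srs = slide_magnitude_pmf(params.sld_srs_mean, params.sld_srs_sd)
    cdf_ns = np.cumsum(pmf_ns)
    cdf_srs = np.cumsum(pmf_srs)
    if is_srs.any():
        next_left, next_right = srs_neighbor_tables(is_srs)
    else:
        next_left = next_right = None
    v_step = params.v_step
    trip_site = {"left": 0, "right": n - 1, "none": None}[spec.triplex_end]

    dna = np.repeat(np.arange(n_dna, dtype=np.int64), motors_per_dna)
    status = np.full(r, UNBOUND, dtype=np.int8)
    pos = np.full(r, -1, dtype=np.int64)
    dirn = np.zeros(r, dtype=np.int64)
    reached_srs = np.zeros(r, dtype=bool)
    retired = np.zeros(n_dna, dtype=bool)

    attached_count = np.zeros(total, dtype=np.int64)
    bound_count = np.zeros(total, dtype=np.int64)
    trans_count = np.zeros(total, dtype=np.int64)
    released_cum = np.zeros(total, dtype=np.int64) if triplex else None

    n_samples = max(sample_hi - sample_lo, 0)
    if record_positions and n_samples > 0:
        sample_positions = np.empty((n_samples, r), dtype=np.int32)
        sample_status = np.empty((n_samples, r), dtype=np.int8)
    else:
        sample_positions = sample_status = None
    sample_mcs = np.arange(sample_lo, sample_hi, dtype=np.int64)

    k_traj = min(record_trajectories, r)
    traj = np.full((total, k_traj), -1, dtype=np.int64) if k_traj else None

    log = _EventLog() if log_events else None
    has_srs_sites = bool(is_srs.any())

    last_t = -1
    for t in range(total):
        alive = status != RETIRED
        unb = (status == UNBOUND) & alive
        bnd = status == BOUND
        trl = status == TRANSLOCATING
        attached = bnd | trl
        safe_pos = np.where(pos >= 0, pos, 0)

        # fresh per-MCS uniform draws, one fixed block per phase
        cand = rng.integers(0, n, size=r)
        u_bind = rng.random(r)
        u_off = rng.random(r)
        u_act = rng.random(r)
        u_dir = rng.random(r)
        u_toff = rng.random(r)
        u_trip = rng.random(r)
        u_tie = rng.random(r)

        # ---- phase 1: binding proposals -------------------------------
        new_bind = unb & (u_bind < p_on_site[cand])
        if motors_per_dna > 1 and new_bind.any():
            occ = dna[attached] * n + pos[attached]
            new_bind &= ~np.isin(dna * n + cand, occ)

        # ---- phase 2: bound motors ------------------------------------
        unbind_b = bnd & (u_off < p_off_site[safe_pos])
        still = bnd & ~unbind_b
        if atp:
            act = still & (u_act < p_atp_site[safe_pos])
        else:
            act = np.zeros(r, dtype=bool)
        new_dir = np.where(
            is_srs[safe_pos],
            np.where(u_dir < params.p_dir, srs_dir[safe_pos], -srs_dir[safe_pos]),
            np.where(u_dir < 0.5, -1, 1),
        )
        slide = still & ~act
        slide_pos = pos.copy()
        for mask, cdf in ((slide & ~is_srs[safe_pos], cdf_ns),
                          (slide & is_srs[safe_pos], cdf_srs)):
            idx = np.where(mask)[0]
            if idx.size:
                # inverse-CDF draw from the shared discretised kernel
                mags = np.searchsorted(cdf, rng.random(idx.size), side="right")
                signs = rng.integers(0, 2, size=idx.size) * 2 - 1
                slide_pos[idx] = slide_destinations(
                    pos[idx], mags * signs, n, next_left, next_right)

        # ---- phase 3: translocating motors ----------------------------
        unbind_t = trl & (u_toff < params.p_off_ns)
        mover = trl & ~unbind_t
        raw = pos + dirn * v_step
        arrive_left = mover & (dirn < 0) & (raw <= 0)
        arrive_right = mover & (dirn > 0) & (raw >= n - 1)
        arrive = arrive_left | arrive_right
        end_site = np.where(arrive_left, 0, n - 1)
        if triplex and trip_site is not None:
            at_trip = (arrive_left if trip_site == 0 else arrive_right)
            release = at_trip & (u_trip < params.p_triplex)
        else:
            release = np.zeros(r, dtype=bool)

        # ---- compose proposed next state ------------------------------
        new_status = status.copy()
        new_pos = pos.copy()
        new_dirn = dirn.copy()
        # priority 1 for motors whose move this MCS was powered translocation
        priority = np.zeros(r, dtype=np.int8)

        new_status[new_bind] = BOUND
        new_pos[new_bind] = cand[new_bind]

        new_status[unbind_b | unbind_t] = UNBOUND
        new_pos[unbind_b | unbind_t] = -1

        new_pos[slide] = slide_pos[slide]

        new_status[act] = TRANSLOCATING
        new_dirn[act] = new_dir[act]
        priority[act] = 1

        free_move = mover & ~arrive
        new_pos[free_move] = raw[free_move]
        new_pos[arrive] = end_site[arrive]
        # non-release arrivals stay translocating, arrested at the end
        arrest = arrive & ~release
        priority[mover] = 1

        # triplex release retires the whole DNA molecule
        if release.any():
            retired[dna[release]] = True
        newly_retired = retired[dna] & (new_status != RETIRED)

        # ---- phase 4: collision resolution ----------------------------
        att_new = ((new_status == BOUND) | (new_status == TRANSLOCATING)) \
            & ~newly_retired
        losers = np.zeros(r, dtype=bool)
        if motors_per_dna > 1:
            idx = np.where(att_new)[0]
            if idx.size:
                keys = dna[idx] * n + new_pos[idx]
                rank = priority[idx].astype(np.float64) * 2.0 + u_tie[idx]
                order = np.lexsort((rank, keys))
                sk = keys[order]
                keep_last = np.ones(idx.size, dtype=bool)
                keep_last[:-1] = sk[1:] != sk[:-1]
                losers[idx[order[~keep_last]]] = True
        lost_binder = losers & new_bind
        new_status[losers] = UNBOUND
        new_pos[losers] = -1

        new_status[newly_retired] = RETIRED
        new_pos[newly_retired] = -1

        # ---- commit ----------------------------------------------------
        if log is not None:
            got_bound = new_bind & ~losers
            log.add(t, np.where(got_bound)[0], EV_BIND, new_pos[got_bound])
            went_off = unbind_b | unbind_t | (losers & ~lost_binder)
            log.add(t, np.where(went_off)[0], EV_UNBIND, safe_pos[went_off])
            log.add(t, np.where(act)[0], EV_ACTIVATE, pos[act])
            first_arr = arrest & (pos != end_site)
            log.add(t, np.where(first_arr)[0], EV_ARRIVE_END,
                    end_site[first_arr])
            log.add(t, np.where(release)[0], EV_RELEASE, end_site[release])

        went_unbound = new_status == UNBOUND
        reached_srs[went_unbound | newly_retired] = False
        status, pos, dirn = new_status, new_pos, new_dirn

        if has_srs_sites:
            on_srs_now = (status == BOUND) & ~reached_srs & \
                is_srs[np.where(pos >= 0, pos, 0)] & (pos >= 0)
            if on_srs_now.any():
                if log is not None:
                    log.add(t, np.where(on_srs_now)[0], EV_REACH_SRS,
                            pos[on_srs_now])
                reached_srs[on_srs_now] = True

        bnd_now = status == BOUND
        trl_now = status == TRANSLOCATING
        att_now = bnd_now | trl_now
        bound_count[t] = bnd_now.sum()
        trans_count[t] = trl_now.sum()
        attached_count[t] = att_now.sum()
        if released_cum is not None:
            released_cum[t] = retired.sum()
        if sample_positions is not None and sample_lo <= t < sample_hi:
            i = t - sample_lo
            sample_positions[i] = np.where(att_now, pos, -1)
            sample_status[i] = status
        if traj is not None:
            traj[t, :] = np.where(att_now[:k_traj], pos[:k_traj], -1)

        last_t = t
        if triplex and retired.all():
            break

    n_mcs = last_t + 1
    attached_count = attached_count[:n_mcs]
    bound_count = bound_count[:n_mcs]
    trans_count = trans_count[:n_mcs]
    if released_cum is not None:
        released_cum = released_cum[:n_mcs]
    if traj is not None:
        traj = traj[:n_mcs]

    events = log.frame(dna) if log is not None else None
    return SimResult(
        spec=spec, params=params, scenario=scenario, n_dna=n_dna,
        motors_per_dna=motors_per_dna, seed=seed, n_mcs=n_mcs,
        attached_count=attached_count, bound_count=bound_count,
        translocating_count=trans_count, sample_mcs=sample_mcs,
        sample_positions=sample_positions, sample_status=sample_status,
        released_cum=released_cum, events=events, trajectories=traj,
        _meta={"equilibration_mcs": equil, "sampling_mcs": sample},
    )
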
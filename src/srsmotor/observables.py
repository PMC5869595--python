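"""Observables computed from simulation output or tabulated positions.

Covers the steady-state occupancy ratios (fraction of DNA-bound motors in
the SRS window without ATP; fraction at the DNA ends with ATP), the
AFM-style 50-nm localization histogram with its first-bin relative
frequency F and its propagated error, the triplex-displacement kinetic
trace and the area-under-curve ratio theta_SRS/NS, and first-passage /
translocation-duration statistics from the event log.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import BOUND, TRANSLOCATING, SimResult

#: B-form DNA rise per base pair; one 50-nm AFM bin is 147 bp.
NM_PER_BP = 0.34
AFM_BIN_NM = 50.0
AFM_BIN_BP = int(round(AFM_BIN_NM / NM_PER_BP))  # 147


@dataclass(frozen=True)
class FrequencyStat:
    """A temporal-average frequency with its across-sample spread."""

    mean: float
    sd: float
    n_samples: int

    def __iter__(self):
        return iter((self.mean, self.sd))


def _require_samples(result: SimResult):
    if result.sample_positions is None or result.sample_positions.shape[0] == 0:
        raise ValueError("run has no recorded sampling window "
                         "(record_positions=True and sampling_mcs >= 1 needed)")
    return result.sample_positions, result.sample_status


def _window_ratio(positions, attached, in_window) -> FrequencyStat:
    """Temporal mean +/- sd of (#attached in window)/(#attached), skipping
    MCS snapshots with no attached motor."""
    denom = attached.sum(axis=1)
    num = (attached & in_window).sum(axis=1)
    ok = denom > 0
    if not ok.any():
        raise ValueError("no MCS sample has a bound motor")
    ratios = num[ok] / denom[ok]
    return FrequencyStat(float(ratios.mean()), float(ratios.std(ddof=0)),
                         int(ok.sum()))


def srs_occupancy(result: SimResult, window: tuple | None = None) -> FrequencyStat:
    """Fraction of DNA-bound motors inside the SRS window.

    Defined, as in the AFM quantification, as the temporal average over the
    sampling window of (#motors bound in the window) / (#motors bound to
    the DNA); snapshots with zero bound motors are skipped.  ``window``
    defaults to the union of the substrate's SRS intervals (or the control
    window on the non-specific substrate).
    """
    positions, status = _require_samples(result)
    if window is None:
        window = result.spec.srs_union_window()
        if window is None:
            raise ValueError("substrate has neither SRS intervals nor a "
                             "control window; pass window=(start, end)")
    lo, hi = window
    attached = (status == BOUND) | (status == TRANSLOCATING)
    in_window = (positions >= lo) & (positions < hi)
    return _window_ratio(positions, attached, in_window)


def end_occupancy(result: SimResult, end_window_bp: int = 1) -> FrequencyStat:
    """Fraction of DNA-attached motors that are at the DNA ends.

    Temporal average of (#motors within ``end_window_bp`` of either end) /
    (#motors bound or translocating).  The default window of 1 bp counts
    motors sitting at the terminal lattice sites — the model's "reached the
    DNA end" population; pass ``end_window_bp=AFM_BIN_BP`` (147 bp, one
    50-nm bin) for the AFM-style readout.
    """
    n = result.spec.length_bp
    if end_window_bp * 2 >= n:
        raise ValueError(f"end window {end_window_bp} bp >= half the "
                         f"{n}-bp substrate")
    positions, status = _require_samples(result)
    attached = (status == BOUND) | (status == TRANSLOCATING)
    in_window = (positions < end_window_bp) | (positions >= n - end_window_bp)
    return _window_ratio(positions, attached, in_window)


# -- AFM localization histogram and Eq.-style statistic -------------------

@dataclass(frozen=True)
class LocalizationHistogram:
    bin_edges_nm: np.ndarray
    counts: np.ndarray

    @property
    def relative_frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def first_bin_stat(self):
        return relative_frequency_F(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start_nm": self.bin_edges_nm[:-1],
            "bin_end_nm": self.bin_edges_nm[1:],
            "count": self.counts,
            "relative_frequency": self.relative_frequencies,
        })


def localization_histogram(positions, unit: str = "bp",
                           contour_length: float | None = None,
                           bin_nm: float = AFM_BIN_NM) -> LocalizationHistogram:
    """Bin protein positions along the DNA contour into 50-nm bins.

    ``positions`` are along one molecule, in bp (converted at 0.34 nm/bp)
    or nm.  ``contour_length`` (same unit) fixes the histogram range;
    default: the largest position.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("no positions to histogram")
    if unit == "bp":
        positions = positions * NM_PER_BP
        if contour_length is not None:
            contour_length = contour_length * NM_PER_BP
    elif unit != "nm":
        raise ValueError("unit must be 'bp' or 'nm'")
    top = contour_length if contour_length is not None else positions.max()
    n_bins = max(int(np.ceil(top / bin_nm)), 1)
    edges = np.arange(n_bins + 1) * bin_nm
    counts, _ = np.histogram(positions, bins=edges)
    return LocalizationHistogram(bin_edges_nm=edges, counts=counts)


def relative_frequency_F(counts) -> tuple:
    """First-bin relative frequency F = f(x1) / sum_i f(x_i) with its
    absolute error from first-order propagation assuming an uncertainty of
    +/- 1 protein per bin:

        dF = sqrt( ((S - f1)/S^2)^2 + (n_bins - 1) * (f1/S^2)^2 ),  S = sum f_i
    """
    counts = np.asarray(counts, dtype=float)
    S = counts.sum()
    if S <= 0:
        raise ValueError("histogram has zero total count")
    f1 = counts[0]
    n_bins = counts.size
    dF = np.sqrt(((S - f1) / S**2) ** 2 + (n_bins - 1) * (f1 / S**2) ** 2)
    return float(f1 / S), float(dF)


def read_positions_tsv(path) -> pd.DataFrame:
    """Read a tabulated protein-position list (columns: molecule_id and
    position_nm or position_bp)."""
    df = pd.read_csv(path, sep="\t")
    if "position_nm" not in df.columns and "position_bp" not in df.columns:
        raise ValueError("position table needs a position_nm or position_bp "
                         "column")
    return df


# -- triplex-displacement kinetics ---------------------------------------

@dataclass(frozen=True)
class KineticTrace:
    """Cumulative triplex-release fraction versus time.

    ``signal`` (1 - released fraction) is the model proxy for the
    fluorescence-anisotropy readout, which is assumed linearly proportional
    to the number of still-intact triplexes and decays as they are
    displaced.
    """

    mcs: np.ndarray
    released_fraction: np.ndarray
    dt: float

    def __post_init__(self):
        fr = self.released_fraction
        if fr.size and (np.any(np.diff(fr) < 0) or fr[0] < 0):
            raise ValueError("released fraction must be non-decreasing")

    @property
    def seconds(self) -> np.ndarray:
        return self.mcs * self.dt

    @property
    def signal(self) -> np.ndarray:
        return 1.0 - self.released_fraction

    def rescaled(self, dt: float) -> "KineticTrace":
        return KineticTrace(self.mcs, self.released_fraction, dt)

    def first_passage(self, fraction: float) -> int | None:
        """First MCS at which the released fraction reaches ``fraction``."""
        hit = np.nonzero(self.released_fraction >= fraction)[0]
        return int(self.mcs[hit[0]]) if hit.size else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mcs": self.mcs, "seconds": self.seconds,
                             "released_fraction": self.released_fraction,
                             "signal": self.signal})


def kinetic_trace(result: SimResult) -> KineticTrace:
    if result.released_cum is None:
        raise ValueError("not a triplex run")
    frac = result.released_cum / result.n_dna
    # prepend t=0 with nothing released (counts are post-MCS)
    mcs = np.arange(result.n_mcs + 1)
    return KineticTrace(mcs=mcs,
                        released_fraction=np.concatenate(([0.0], frac)),
                        dt=result.params.dt)


def _extend(values: np.ndarray, length: int) -> np.ndarray:
    if values.size >= length:
        return values[:length]
    pad = np.full(length - values.size, values[-1])
    return np.concatenate([values, pad])


def theta_ratio(trace_srs: KineticTrace, trace_ns: KineticTrace,
                window_mcs: int | None = None,
                completion: float = 0.95,
                max_window_mcs: int = 50000) -> float:
    """Area-under-curve ratio theta = AUC(signal_SRS) / AUC(signal_NS).

    Both signals are integrated (trapezoid) over a common time window; by
    default from t = 0 until the slower substrate's released fraction first
    reaches ``completion`` (capped at ``max_window_mcs``).  theta < 1 means
    the SRS substrate's triplex is displaced faster.
    """
    if trace_srs.dt != trace_ns.dt:
        raise ValueError("traces must share a time base (equal dt)")
    if window_mcs is None:
        fps = [tr.first_passage(completion) for tr in (trace_srs, trace_ns)]
        candidates = [fp for fp in fps if fp is not None]
        if len(candidates) == 2:
            window_mcs = max(candidates)
        else:  # a substrate never completed within its trace: use trace span
            window_mcs = max(trace_srs.mcs[-1], trace_ns.mcs[-1])
        window_mcs = min(window_mcs, max_window_mcs)
    length = window_mcs + 1
    dt = trace_srs.dt
    auc_srs = np.trapezoid(_extend(trace_srs.signal, length), dx=dt)
    auc_ns = np.trapezoid(_extend(trace_ns.signal, length), dx=dt)
    if auc_ns <= 0:
        raise ZeroDivisionError("non-specific trace has zero area")
    return float(auc_srs / auc_ns)


# -- event-log first-passage statistics ----------------------------------

@dataclass(frozen=True)
class DurationStats:
    mean_mcs: float
    sd_mcs: float
    n: int
    dt: float

    @property
    def mean_seconds(self) -> float:
        return self.mean_mcs * self.dt

    @property
    def sd_seconds(self) -> float:
        return self.sd_mcs * self.dt


def _stats(durations: list, dt: float) -> DurationStats | None:
    if not durations:
        return None
    arr = np.asarray(durations, dtype=float)
    return DurationStats(float(arr.mean()), float(arr.std(ddof=0)),
                         arr.size, dt)


def search_time_stats(events: pd.DataFrame, dt: float) -> DurationStats | None:
    """Time from binding to first arrival at the SRS window within one
    continuous bound episode (the 1D-diffusion target-search time).

    Episodes that end in unbinding before reaching SRS do not contribute.
    Returns ``None`` when no qualifying episode exists.
    """
    durations = []
    for _, grp in events.groupby("motor", sort=False):
        bind_mcs = None
        for mcs, ev in zip(grp["mcs"].to_numpy(), grp["event"].to_numpy()):
            if ev == "bind":
                bind_mcs = mcs
            elif ev == "unbind":
                bind_mcs = None
            elif ev == "reach_srs" and bind_mcs is not None:
                durations.append(mcs - bind_mcs)
                bind_mcs = None
    return _stats(durations, dt)


def translocation_duration_stats(events: pd.DataFrame, dt: float,
                                 end_arrivals: bool = True) -> DurationStats | None:
    """Duration of single translocation rounds: activation to dissociation
    (or to end-arrival / triplex release when ``end_arrivals`` is True;
    otherwise end-terminated rounds are discarded)."""
    durations = []
    for _, grp in events.groupby("motor", sort=False):
        act_mcs = None
        for mcs, ev in zip(grp["mcs"].to_numpy(), grp["event"].to_numpy()):
            if ev == "activate":
                act_mcs = mcs
            elif act_mcs is None:
                continue
            elif ev == "unbind":
                durations.append(mcs - act_mcs)
                act_mcs = None
            elif ev in ("arrive_end", "release_triplex"):
                if end_arrivals:
                    durations.append(mcs - act_mcs)
                act_mcs = None
    return _stats(durations, dt)
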
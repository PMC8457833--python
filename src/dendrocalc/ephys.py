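"""Intrinsic and evoked electrophysiological measurements from sweeps.

Implements the whole-cell measurements used alongside the imaging:
passive membrane properties from a 200 ms hyperpolarizing voltage-clamp
step (-70 to -100 mV), quantification of the transient A-type potassium
current (I_A) that distinguishes magnocellular from parvocellular oxytocin
neurons, spike detection and firing-rate changes in current clamp,
evoked-response amplitudes (EPSCs, agonist puffs), tonic holding-current
shifts, train-charge monitoring, and the recording-stability exclusion
gate.

Units follow patch-clamp convention throughout: time s (20 kHz default
sampling), current pA, voltage mV, resistance MOhm, capacitance pF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .protocols import StimulusProtocol

__all__ = [
    "Sweep",
    "PassiveProperties",
    "StatSummaryPair",
    "membrane_properties",
    "ia_metric",
    "classify_ot_neuron",
    "detect_spikes",
    "firing_rate_change",
    "time_to_first_spike",
    "evoked_response_amplitude",
    "holding_current_shift",
    "train_pulse_charge",
    "patch_quality_gate",
]

DEFAULT_SAMPLE_RATE_HZ = 20_000.0


@dataclass
class Sweep:
    """A uniformly sampled voltage- or current-clamp trace.

    ``y`` is in pA for voltage clamp (``clamp_mode='VC'``) and mV for
    current clamp (``'CC'``).  ``meta`` carries generator ground truth
    (e.g. programmed spike times) and provenance.
    """

    y: np.ndarray
    sample_rate_Hz: float = DEFAULT_SAMPLE_RATE_HZ
    clamp_mode: str = "VC"
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.clamp_mode not in ("VC", "CC"):
            raise ValueError("clamp_mode must be 'VC' or 'CC'")
        if self.sample_rate_Hz <= 0:
            raise ValueError("sample_rate_Hz must be positive")

    @property
    def t(self) -> np.ndarray:
        """Sample timestamps (interval start), seconds."""
        return np.arange(len(self.y)) / self.sample_rate_Hz

    @property
    def duration_s(self) -> float:
        return len(self.y) / self.sample_rate_Hz

    def index_of(self, t_s: float) -> int:
        return int(round(t_s * self.sample_rate_Hz))


@dataclass
class PassiveProperties:
    R_input_Mohm: float
    C_m_pF: float
    R_access_Mohm: float


@dataclass
class StatSummaryPair:
    """A printed summary triple: mean, SEM and sample size."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)

    @property
    def var(self) -> float:
        return self.sd ** 2


def _step_window(sweep: Sweep) -> tuple[int, int]:
    p = sweep.protocol
    i0 = sweep.index_of(p.onset_s)
    i1 = sweep.index_of(p.onset_s + p.pulse_width_s)
    if not 0 <= i0 < i1 <= len(sweep.y):
        raise ValueError("protocol step window lies outside the sweep")
    return i0, i1


def membrane_properties(sweep: Sweep,
                        steady_window_s: float = 0.05) -> PassiveProperties:
    """Passive properties from a hyperpolarizing voltage-clamp step.

    Uses the two-resistor (access + membrane) RC model of the patched
    cell:

    * R_access = dV / peak transient current,
    * R_input  = dV / steady-state current - R_access, with the steady
      state taken as the mean over the last ``steady_window_s`` of the
      step,
    * C_m = Q / (dV * R_input/(R_input + R_access)), where Q is the
      transient charge above the steady state (trapezoidal integral).

    A sweep without a detectable capacitive transient yields C_m = nan.
    """
    if sweep.clamp_mode != "VC":
        raise ValueError("membrane_properties requires a VC sweep")
    dv = sweep.protocol.delta_mV
    if dv == 0:
        raise ValueError("protocol has zero step amplitude")
    i0, i1 = _step_window(sweep)
    baseline = sweep.y[:i0].mean() if i0 > 0 else 0.0
    y = sweep.y - baseline

    n_ss = max(1, int(round(steady_window_s * sweep.sample_rate_Hz)))
    i_ss = y[i1 - n_ss:i1].mean()
    if i_ss == 0:
        raise ValueError("no steady-state current response to the step")
    r_total = 1000.0 * dv / i_ss                   # mV/pA -> MOhm

    # signed peak of the transient relative to steady state
    step = y[i0:i1]
    rel = step - i_ss
    k = int(np.argmax(np.abs(rel)))
    if abs(rel[k]) < 0.05 * abs(i_ss):
        # no detectable capacitive transient: access resistance is
        # unresolvable (reported 0) and C_m undefined
        return PassiveProperties(R_input_Mohm=r_total, C_m_pF=float("nan"),
                                 R_access_Mohm=0.0)
    i_peak = step[k]
    r_access = 1000.0 * dv / i_peak
    r_input = r_total - r_access

    dt = 1.0 / sweep.sample_rate_Hz
    q = np.trapezoid(rel, dx=dt)                   # pA*s
    denom = dv * r_input / (r_input + r_access)    # mV
    c_m = 1000.0 * q / denom                       # pA*s/mV -> pF
    return PassiveProperties(R_input_Mohm=r_input, C_m_pF=c_m,
                             R_access_Mohm=r_access)


def ia_metric(sweep: Sweep, transient_window_s: float = 0.1,
              steady_window_s: float = 0.1, use_peak: bool = False) -> float:
    """Transient-current metric after a depolarizing step (-70 to -50 mV).

    Mean current over the first ``transient_window_s`` after step onset,
    relative to the steady-state current at the step potential (mean over
    the final ``steady_window_s`` of the step).  Positive values indicate
    a transient outward current (I_A, magnocellular signature); negative
    values the transient inward current seen in parvocellular cells.
    ``use_peak`` substitutes the signed extremum for the mean.
    """
    if sweep.clamp_mode != "VC":
        raise ValueError("ia_metric requires a VC sweep")
    i0, i1 = _step_window(sweep)
    n_tr = int(round(transient_window_s * sweep.sample_rate_Hz))
    n_ss = int(round(steady_window_s * sweep.sample_rate_Hz))
    if i0 + n_tr > i1:
        raise ValueError("transient window longer than the step")
    steady = sweep.y[i1 - n_ss:i1].mean()
    rel = sweep.y[i0:i0 + n_tr] - steady
    if use_peak:
        return float(rel[np.argmax(np.abs(rel))])
    return float(rel.mean())


def classify_ot_neuron(ia_pA: float, threshold_pA: float = 0.0) -> str:
    """Magnocellular vs. parvocellular call from the I_A metric.

    OT-MCN iff the transient-current metric is strictly above threshold;
    a value exactly at threshold is classified OT-PCN.
    """
    return "OT-MCN" if ia_pA > threshold_pA else "OT-PCN"


def detect_spikes(sweep: Sweep, threshold_mV: float = 0.0,
                  lockout_s: float = 0.002) -> np.ndarray:
    """Spike times from upward threshold crossings with a lockout.

    Returns the timestamp of each crossing sample; crossings within
    ``lockout_s`` of an accepted spike are ignored.
    """
    if sweep.clamp_mode != "CC":
        raise ValueError("detect_spikes requires a CC sweep")
    y = sweep.y
    crossing = np.flatnonzero((y[1:] >= threshold_mV) & (y[:-1] < threshold_mV)) + 1
    if crossing.size == 0:
        return np.empty(0)
    lock = int(round(lockout_s * sweep.sample_rate_Hz))
    kept = [int(crossing[0])]
    for idx in crossing[1:]:
        if idx - kept[-1] > lock:
            kept.append(int(idx))
    return np.asarray(kept) / sweep.sample_rate_Hz


def firing_rate_change(spike_times_s: Sequence[float],
                       pre_window: tuple[float, float],
                       post_window: tuple[float, float]) -> float:
    """Change in firing rate (Hz): post-window rate minus pre-window rate."""
    st = np.asarray(spike_times_s, dtype=float)

    def rate(win):
        lo, hi = win
        if hi <= lo:
            raise ValueError("window must have positive duration")
        return ((st >= lo) & (st < hi)).sum() / (hi - lo)

    return float(rate(post_window) - rate(pre_window))


def time_to_first_spike(sweep: Sweep, injection_onset_s: float,
                        threshold_mV: float = 0.0) -> float | None:
    """Latency (ms) from current-injection onset to the first spike.

    Returns None when no spike follows the injection — the
    delayed-first-spike phenotype quantified for magnocellular cells.
    """
    spikes = detect_spikes(sweep, threshold_mV=threshold_mV)
    after = spikes[spikes >= injection_onset_s]
    if after.size == 0:
        return None
    return float((after[0] - injection_onset_s) * 1000.0)


def evoked_response_amplitude(sweep: Sweep, stim_time_s: float,
                              search_window_s: float = 0.1,
                              baseline_window_s: float = 0.05) -> float:
    """Signed amplitude (pA) of an evoked current.

    Peak absolute deviation within ``search_window_s`` after the stimulus,
    relative to the local pre-stimulus baseline mean; the sign of the
    deviation is preserved (inward currents are negative).
    """
    if sweep.clamp_mode != "VC":
        raise ValueError("evoked_response_amplitude requires a VC sweep")
    i_stim = sweep.index_of(stim_time_s)
    i_b0 = max(0, i_stim - int(round(baseline_window_s * sweep.sample_rate_Hz)))
    if i_b0 == i_stim:
        raise ValueError("no baseline samples before the stimulus")
    baseline = sweep.y[i_b0:i_stim].mean()
    i_hi = min(len(sweep.y),
               i_stim + int(round(search_window_s * sweep.sample_rate_Hz)))
    rel = sweep.y[i_stim:i_hi] - baseline
    if rel.size == 0:
        raise ValueError("search window lies outside the sweep")
    return float(rel[np.argmax(np.abs(rel))])


def holding_current_shift(before: Sweep, after: Sweep,
                          window_s: tuple[float, float] | None = None) -> float:
    """Difference (pA) of stimulus-free baseline holding currents.

    Positive when the 'after' condition requires more inward holding
    current magnitude change as printed (after minus before).
    """
    def baseline(sweep: Sweep) -> float:
        if window_s is None:
            if sweep.protocol.mode == "none":
                return sweep.y.mean()
            return sweep.y[:sweep.index_of(sweep.protocol.onset_s)].mean()
        i0, i1 = sweep.index_of(window_s[0]), sweep.index_of(window_s[1])
        return sweep.y[i0:i1].mean()

    return float(baseline(after) - baseline(before))


def train_pulse_charge(sweep: Sweep) -> float:
    """Charge (pA*ms) of the final pulse of a voltage-step train.

    Trapezoidal integral of the baseline-subtracted current from the last
    pulse's onset to the onset of the following inter-pulse interval; used
    to monitor the stability of the somatic train stimulus over time.
    """
    p = sweep.protocol
    if p.mode != "vc_train":
        raise ValueError("train_pulse_charge requires a vc_train sweep")
    t_last = p.pulse_times_s[-1]
    i0 = sweep.index_of(t_last)
    i1 = min(len(sweep.y), sweep.index_of(t_last + p.pulse_width_s) + 1)
    baseline = sweep.y[:sweep.index_of(p.onset_s)].mean()
    dt_ms = 1000.0 / sweep.sample_rate_Hz
    return float(np.trapezoid(sweep.y[i0:i1] - baseline, dx=dt_ms))


def patch_quality_gate(holding_pA: Sequence[float],
                       r_access_Mohm: Sequence[float],
                       max_change_frac: float = 0.3) -> bool:
    """Recording-stability gate: True = include, False = exclude.

    A cell is excluded when the holding current or the access resistance
    changes by strictly more than ``max_change_frac`` (relative to the
    previous monitoring point) between consecutive monitoring points.
    """
    for series in (np.asarray(holding_pA, float),
                   np.asarray(r_access_Mohm, float)):
        if series.size < 2:
            continue
        prev = series[:-1]
        delta = np.abs(np.diff(series))
        denom = np.maximum(np.abs(prev), 1e-12)
        if (delta / denom > max_change_frac + 1e-12).any():
            return False
    return True
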
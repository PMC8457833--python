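"""Synthetic line scans and electrophysiology sweeps with stored ground truth.

The generator emulates the study conditions of the quantification pipeline:
85 Hz dual-channel line scans (calcium-dependent green + calcium-independent
red channel) with Poisson shot noise, dendritic calcium transients driven by
a 2 s, 20 Hz somatic train and attenuated exponentially with distance from
the soma, voltage-clamp step responses of a two-resistor RC cell with an
optional inactivating A-current, inhomogeneous-Poisson spiking in current
clamp, and difference-of-exponentials evoked currents.

Every simulator is deterministic for a fixed ``(parameters, seed)`` pair and
stores its ground truth on the returned object, so parameter-recovery tests
need no external data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .ephys import Sweep
from .linescan import LineScanRecording
from .protocols import AP_TRAIN, IA_STEP, PASSIVE_STEP, StimulusProtocol, TRAIN_MODES

__all__ = [
    "CellGroundTruth",
    "effective_length_constant",
    "calcium_kernel",
    "simulate_linescan",
    "linescan_ratio_oracle",
    "simulate_vc_step",
    "simulate_vc_train",
    "simulate_ia_sweep",
    "simulate_spiking",
    "simulate_evoked_current",
    "default_spike_template",
]

E_K_MV = -90.0           # potassium reversal for the I_A term
CA_REFERENCE_MM = 2.4    # bath calcium under control conditions


@dataclass(frozen=True)
class CellGroundTruth:
    """Generative parameters of one simulated cell.

    The osmotic challenge is modelled as a multiplicative increase of the
    dendritic leak conductance: the effective length constant is
    ``length_constant_um / sqrt(osmotic_leak_factor)``, so a factor > 1
    (hyperosmotic) shortens it and a factor < 1 (hypoosmotic) lengthens it.
    Calcium-transient amplitude scales linearly with bath calcium relative
    to the 2.4 mM control, so ``external_ca_mM = 0`` silences the
    activity-induced signal (the calcium-free control).
    """

    length_constant_um: float = 75.0
    ca_increment_at_soma: float = 0.04
    ca_decay_s: float = 0.6
    membrane_R_Mohm: float = 1500.0
    membrane_C_pF: float = 30.0
    access_R_Mohm: float = 12.0
    ia_gmax_nS: float = 2.0
    ia_decay_ms: float = 30.0
    photon_budget_green: float = 200.0
    photon_budget_red: float = 400.0
    external_ca_mM: float = CA_REFERENCE_MM
    osmotic_leak_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive = ("length_constant_um", "ca_increment_at_soma", "ca_decay_s",
                    "membrane_R_Mohm", "access_R_Mohm",
                    "ia_decay_ms", "photon_budget_green", "photon_budget_red")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        # C_m = 0 is permitted as the idealized transient-free step response
        if (self.membrane_C_pF < 0 or self.external_ca_mM < 0
                or self.osmotic_leak_factor < 0):
            raise ValueError("membrane_C_pF, external_ca_mM and "
                             "osmotic_leak_factor must be >= 0")

    def with_(self, **kwargs) -> "CellGroundTruth":
        return replace(self, **kwargs)


def effective_length_constant(truth: CellGroundTruth) -> float:
    """Length constant under the current leak state (um)."""
    if truth.osmotic_leak_factor == 0:
        return truth.length_constant_um
    return truth.length_constant_um / np.sqrt(truth.osmotic_leak_factor)


def calcium_kernel(truth: CellGroundTruth, distance_um: float,
                   pulse_times_s: np.ndarray, t_s: np.ndarray) -> np.ndarray:
    """Noiseless fractional calcium signal C(t) at a dendritic location.

    Each somatic pulse adds an instantaneous increment
    ``a = ca_increment_at_soma * exp(-distance/lambda_eff) * [Ca]/2.4``
    that decays exponentially with time constant ``ca_decay_s``; pulses
    sum linearly (sub-saturating indicator regime).
    """
    lam = effective_length_constant(truth)
    a = (truth.ca_increment_at_soma * np.exp(-distance_um / lam)
         * truth.external_ca_mM / CA_REFERENCE_MM)
    c = np.zeros_like(t_s, dtype=float)
    for tk in pulse_times_s:
        m = t_s >= tk - 1e-12
        c[m] += a * np.exp(-(t_s[m] - tk) / truth.ca_decay_s)
    return c


def _structure_profile(n_pixels: int) -> np.ndarray:
    """Gaussian brightness bump across the scan line, peak 1.

    The bump's full width at half maximum covers ~30% of the pixels; the
    dendrite occupies the center of the line.
    """
    x = np.arange(n_pixels)
    sigma = 0.3 * n_pixels / 2.355
    return np.exp(-0.5 * ((x - (n_pixels - 1) / 2) / sigma) ** 2)


def _linescan_means(truth: CellGroundTruth, distance_um: float,
                    protocol: StimulusProtocol, n_pixels: int,
                    t_lines: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    bump = _structure_profile(n_pixels)
    if protocol.mode == "none":
        c = np.zeros_like(t_lines)
    else:
        c = calcium_kernel(truth, distance_um, protocol.pulse_times_s, t_lines)
    # background pixels sit at 10% of structure brightness and carry no
    # calcium signal (scatter/dark counts, not dye)
    green = truth.photon_budget_green * (
        0.1 + 0.9 * bump[None, :] * (1.0 + c[:, None]))
    red = truth.photon_budget_red * (0.1 + 0.9 * bump[None, :])
    red = np.broadcast_to(red, green.shape).copy()
    return green, red


def simulate_linescan(truth: CellGroundTruth, distance_um: float,
                      protocol: StimulusProtocol = AP_TRAIN,
                      n_pixels: int = 64, line_rate_Hz: float = 85.0,
                      total_s: float = 11.9, prestim_s: float = 2.0,
                      noise: bool = True,
                      compartment: str = "dendrite",
                      cell_type: str = "OT-MCN",
                      rng: np.random.Generator | None = None
                      ) -> LineScanRecording:
    """Simulate a dual-channel line scan at a given distance from the soma.

    Default geometry reproduces the acquisition protocol: 85 Hz lines
    starting 2 s before somatic stimulation, 11.9 s total.  With ``noise``
    every pixel of every line is drawn from a Poisson distribution around
    its noiseless mean; with ``noise=False`` the raster holds the exact
    means, providing the closed-form oracle for the analysis chain.
    """
    if distance_um < 0:
        raise ValueError("distance_um must be >= 0")
    if protocol.mode not in TRAIN_MODES and protocol.mode != "none":
        raise ValueError("line-scan protocol must be a somatic train or 'none'")
    if protocol.mode != "none":
        if total_s < prestim_s + protocol.train_duration_s:
            raise ValueError("total duration shorter than prestim + train")
        if protocol.onset_s < prestim_s - 1e-9:
            raise ValueError("train onset precedes the pre-stimulus window")

    n_lines = int(round(line_rate_Hz * total_s))
    t_lines = np.arange(n_lines) / line_rate_Hz
    green, red = _linescan_means(truth, distance_um, protocol, n_pixels, t_lines)

    if noise:
        if rng is None:
            rng = np.random.default_rng(truth.seed)
        green = rng.poisson(green).astype(np.uint16)
        red = rng.poisson(red).astype(np.uint16)

    gt = asdict(truth)
    gt.update(distance_um=distance_um,
              lambda_eff_um=float(effective_length_constant(truth)),
              noise=noise)
    return LineScanRecording(
        green=green, red=red, line_rate_Hz=line_rate_Hz,
        prestim_s=prestim_s,
        stim_onset_s=protocol.onset_s if protocol.mode != "none" else prestim_s,
        stim_duration_s=(protocol.train_duration_s
                         if protocol.mode != "none" else 0.0),
        distance_um=distance_um, compartment=compartment, cell_type=cell_type,
        ground_truth=gt)


def linescan_ratio_oracle(truth: CellGroundTruth, distance_um: float,
                          protocol: StimulusProtocol,
                          t_lines: np.ndarray) -> np.ndarray:
    """Closed-form background-corrected green/red ratio of the generator."""
    c = (np.zeros_like(t_lines) if protocol.mode == "none" else
         calcium_kernel(truth, distance_um, protocol.pulse_times_s, t_lines))
    return truth.photon_budget_green / truth.photon_budget_red * (1.0 + c)


# --------------------------------------------------------------------------
# voltage-clamp sweeps


def _rc_step_current(truth: CellGroundTruth, dv_mV: float,
                     t_rel_s: np.ndarray) -> np.ndarray:
    """Two-resistor RC response to a voltage step, pA, t_rel from onset."""
    ra, rm, cm = truth.access_R_Mohm, truth.membrane_R_Mohm, truth.membrane_C_pF
    i_ss = 1000.0 * dv_mV / (ra + rm)                 # pA
    if cm == 0:                                       # no capacitive transient
        return np.full_like(t_rel_s, i_ss)
    i_peak = 1000.0 * dv_mV / ra
    tau = ra * cm * rm / (rm + ra) * 1e-6             # MOhm*pF -> s
    return i_ss + (i_peak - i_ss) * np.exp(-t_rel_s / tau)


def simulate_vc_step(truth: CellGroundTruth,
                     protocol: StimulusProtocol = PASSIVE_STEP,
                     total_s: float = 0.5,
                     sample_rate_Hz: float = 20_000.0,
                     noise_sd_pA: float = 0.0,
                     rng: np.random.Generator | None = None) -> Sweep:
    """Voltage-clamp step response of the two-resistor RC cell model.

    Current is reported relative to the holding current (baseline 0):
    a steady component dV/(R_a+R_m) plus a capacitive transient of initial
    amplitude dV/R_a decaying with tau = R_a*C_m*R_m/(R_a+R_m).  Optional
    additive Gaussian recording noise.
    """
    if protocol.mode != "vc_step":
        raise ValueError("protocol mode must be 'vc_step'")
    if truth.access_R_Mohm <= 0 and truth.membrane_C_pF > 0:
        raise ValueError("zero access resistance with C_m > 0 is undefined")
    n = int(round(total_s * sample_rate_Hz))
    t = np.arange(n) / sample_rate_Hz
    y = np.zeros(n)
    dv = protocol.delta_mV
    on = t >= protocol.onset_s - 1e-12
    y[on] = _rc_step_current(truth, dv, t[on] - protocol.onset_s)
    # edges take effect strictly after their nominal time, so the sample
    # on the boundary still reflects the preceding state
    off = t > protocol.onset_s + protocol.pulse_width_s + 0.25 / sample_rate_Hz
    y[off] += _rc_step_current(truth, -dv,
                               t[off] - protocol.onset_s - protocol.pulse_width_s)
    if noise_sd_pA > 0:
        if rng is None:
            rng = np.random.default_rng(truth.seed)
        y = y + rng.normal(0.0, noise_sd_pA, size=n)
    return Sweep(y=y, sample_rate_Hz=sample_rate_Hz, clamp_mode="VC",
                 protocol=protocol,
                 meta={"ground_truth": asdict(truth), "noise_sd_pA": noise_sd_pA})


def simulate_ia_sweep(truth: CellGroundTruth,
                      protocol: StimulusProtocol = IA_STEP,
                      total_s: float = 0.7,
                      sample_rate_Hz: float = 20_000.0,
                      noise_sd_pA: float = 0.0,
                      rng: np.random.Generator | None = None) -> Sweep:
    """Depolarizing step with an inactivating A-type current on top of RC.

    The transient current is ``ia_gmax * (V_step - E_K) * exp(-t/tau_ia)``
    (nS * mV = pA).  ``ia_gmax_nS = 0`` gives a parvocellular-like sweep;
    a negative value gives the transient inward current those cells often
    show.
    """
    sweep = simulate_vc_step(truth, protocol, total_s=total_s,
                             sample_rate_Hz=sample_rate_Hz,
                             noise_sd_pA=noise_sd_pA, rng=rng)
    t = sweep.t
    on = t >= protocol.onset_s - 1e-12
    amp = truth.ia_gmax_nS * (protocol.step_mV - E_K_MV)   # pA
    tau = truth.ia_decay_ms / 1000.0
    ia = np.zeros_like(sweep.y)
    ia[on] = amp * np.exp(-(t[on] - protocol.onset_s) / tau)
    off = t > protocol.onset_s + protocol.pulse_width_s + 0.25 / sample_rate_Hz
    ia[off] = 0.0                                          # deinactivation at rest
    sweep.y = sweep.y + ia
    sweep.meta["ia_amplitude_pA"] = float(amp)
    return sweep


def simulate_vc_train(truth: CellGroundTruth,
                      protocol: StimulusProtocol = AP_TRAIN,
                      total_s: float | None = None,
                      sample_rate_Hz: float = 20_000.0,
                      noise_sd_pA: float = 0.0,
                      rng: np.random.Generator | None = None) -> Sweep:
    """Somatic current during a train of action-potential-like steps.

    Each pulse evokes the RC step response (on and off edges); used for
    monitoring the voltage-clamp train charge over an experiment.
    """
    if protocol.mode != "vc_train":
        raise ValueError("protocol mode must be 'vc_train'")
    if total_s is None:
        total_s = protocol.onset_s + protocol.train_duration_s + 0.5
    n = int(round(total_s * sample_rate_Hz))
    t = np.arange(n) / sample_rate_Hz
    y = np.zeros(n)
    dv = protocol.delta_mV
    for tk in protocol.pulse_times_s:
        on = t >= tk - 1e-12
        y[on] += _rc_step_current(truth, dv, t[on] - tk)
        off = t > tk + protocol.pulse_width_s + 0.25 / sample_rate_Hz
        y[off] += _rc_step_current(truth, -dv, t[off] - tk - protocol.pulse_width_s)
    if noise_sd_pA > 0:
        if rng is None:
            rng = np.random.default_rng(truth.seed)
        y = y + rng.normal(0.0, noise_sd_pA, size=n)
    return Sweep(y=y, sample_rate_Hz=sample_rate_Hz, clamp_mode="VC",
                 protocol=protocol, meta={"ground_truth": asdict(truth)})


# --------------------------------------------------------------------------
# current-clamp spiking


def default_spike_template(sample_rate_Hz: float) -> np.ndarray:
    """A stereotyped action-potential waveform (mV, relative to rest).

    1 ms rise to +85 mV above rest, 1.5 ms fall, and a brief shallow
    afterhyperpolarization; adequate for threshold-crossing detection.
    """
    dt = 1.0 / sample_rate_Hz
    t = np.arange(0.0, 0.006, dt)
    rise = np.clip(t / 0.001, 0, 1) ** 2
    fall = np.exp(-np.maximum(t - 0.001, 0) / 0.0007)
    ahp = -8.0 * np.exp(-np.maximum(t - 0.0025, 0) / 0.002) * (t > 0.0025)
    return 85.0 * rise * fall + ahp


def simulate_spiking(rate_fn: Callable[[np.ndarray], np.ndarray] | float,
                     duration_s: float,
                     template: np.ndarray | None = None,
                     seed: int = 0,
                     sample_rate_Hz: float = 20_000.0,
                     resting_mV: float = -60.0,
                     refractory_s: float = 0.005,
                     noise_sd_mV: float = 0.0) -> Sweep:
    """Inhomogeneous-Poisson spiking with an absolute refractory period.

    ``rate_fn`` maps time (s) to instantaneous rate (Hz) and may be a
    scalar.  Spike times are drawn by thinning a homogeneous Poisson
    process at the rate ceiling, then enforcing a 5 ms (default) absolute
    refractory period; template waveforms are superimposed on the resting
    potential.  The programmed spike times are stored in
    ``meta['spike_times_s']``.
    """
    rng = np.random.default_rng(seed)
    if np.isscalar(rate_fn):
        r = float(rate_fn)
        rate = lambda t: np.full_like(np.asarray(t, float), r)  # noqa: E731
    else:
        rate = rate_fn
    grid = np.linspace(0.0, duration_s, 2049)
    rmax = float(np.max(rate(grid)))
    spike_times: list[float] = []
    if rmax > 0:
        t = 0.0
        last = -np.inf
        while True:
            t += rng.exponential(1.0 / rmax)
            if t >= duration_s:
                break
            if t - last < refractory_s:
                continue
            if rng.uniform() * rmax < float(rate(np.asarray(t))):
                spike_times.append(t)
                last = t
    n = int(round(duration_s * sample_rate_Hz))
    y = np.full(n, resting_mV)
    if template is None:
        template = default_spike_template(sample_rate_Hz)
    for ts in spike_times:
        i0 = int(round(ts * sample_rate_Hz))
        seg = template[:max(0, n - i0)]
        y[i0:i0 + len(seg)] += seg
    if noise_sd_mV > 0:
        y = y + rng.normal(0.0, noise_sd_mV, size=n)
    return Sweep(y=y, sample_rate_Hz=sample_rate_Hz, clamp_mode="CC",
                 protocol=StimulusProtocol(mode="none", onset_s=0.0),
                 meta={"spike_times_s": np.asarray(spike_times),
                       "seed": seed, "refractory_s": refractory_s})


# --------------------------------------------------------------------------
# evoked currents


def simulate_evoked_current(amplitude_pA: float,
                            stim_time_s: float = 0.1,
                            tau_rise_s: float = 0.002,
                            tau_decay_s: float = 0.012,
                            total_s: float = 0.3,
                            noise_sd_pA: float = 0.0,
                            n_sweeps: int = 1,
                            seed: int = 0,
                            sample_rate_Hz: float = 20_000.0) -> list[Sweep]:
    """Difference-of-exponentials inward current (EPSC / agonist puff).

    The waveform is normalized so its peak equals ``amplitude_pA`` and
    plotted inward (negative) for positive amplitudes, matching the
    convention of cells voltage clamped at -70 mV.
    """
    if tau_decay_s <= tau_rise_s:
        raise ValueError("tau_decay_s must exceed tau_rise_s")
    rng = np.random.default_rng(seed)
    n = int(round(total_s * sample_rate_Hz))
    t = np.arange(n) / sample_rate_Hz
    rel = np.maximum(t - stim_time_s, 0.0)
    shape = np.exp(-rel / tau_decay_s) - np.exp(-rel / tau_rise_s)
    shape[t < stim_time_s] = 0.0
    peak = shape.max()
    wave = -amplitude_pA * shape / peak if peak > 0 else shape
    protocol = StimulusProtocol(mode="minimal_stim", onset_s=stim_time_s)
    sweeps = []
    for _ in range(n_sweeps):
        y = wave.copy()
        if noise_sd_pA > 0:
            y = y + rng.normal(0.0, noise_sd_pA, size=n)
        sweeps.append(Sweep(y=y, sample_rate_Hz=sample_rate_Hz,
                            clamp_mode="VC", protocol=protocol,
                            meta={"amplitude_pA": amplitude_pA, "seed": seed}))
    return sweeps
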
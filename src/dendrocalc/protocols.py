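"""Stimulus protocol descriptions shared by the generator and the analyzers.

A :class:`StimulusProtocol` describes what was delivered to the cell during a
sweep or line scan: a train of action-potential-like voltage steps, a single
voltage-clamp step, a current injection, a puff of agonist, or nothing.  All
times are seconds from the start of the sweep; voltages are millivolts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

TRAIN_MODES = frozenset({"vc_train", "cc_train"})
STEP_MODES = frozenset({"vc_step", "cc_step"})
VALID_MODES = TRAIN_MODES | STEP_MODES | frozenset({"puff", "minimal_stim", "none"})


@dataclass(frozen=True)
class StimulusProtocol:
    """Protocol annotation for a sweep or line-scan acquisition.

    Parameters
    ----------
    mode:
        One of ``vc_train``, ``cc_train``, ``vc_step``, ``cc_step``,
        ``puff``, ``minimal_stim``, ``none``.
    holding_mV:
        Holding potential (voltage clamp) or resting target (current clamp).
    step_mV:
        Target potential of each step/pulse (absolute, not relative).
    pulse_width_s:
        Width of a single pulse (train modes) or of the whole step
        (step modes).
    rate_Hz, train_duration_s:
        Pulse rate and total train length for train modes.  Their product
        must be an integer pulse count.
    onset_s:
        Time of the first pulse / step edge from sweep start.
    """

    mode: str = "none"
    holding_mV: float = -70.0
    step_mV: float = 50.0
    pulse_width_s: float = 0.005
    rate_Hz: float = 20.0
    train_duration_s: float = 2.0
    onset_s: float = 2.0

    def __post_init__(self) -> None:
        if self.mode not in VALID_MODES:
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.mode in TRAIN_MODES:
            n = self.rate_Hz * self.train_duration_s
            if abs(n - round(n)) > 1e-9 or round(n) < 1:
                raise ValueError(
                    "rate_Hz * train_duration_s must be a positive integer "
                    f"pulse count, got {n}"
                )

    @property
    def n_pulses(self) -> int:
        """Number of pulses in a train (1 for step modes)."""
        if self.mode in TRAIN_MODES:
            return int(round(self.rate_Hz * self.train_duration_s))
        return 1

    @property
    def pulse_times_s(self):
        """Onset time of every pulse, seconds from sweep start."""
        import numpy as np

        if self.mode in TRAIN_MODES:
            return self.onset_s + np.arange(self.n_pulses) / self.rate_Hz
        return np.asarray([self.onset_s])

    @property
    def delta_mV(self) -> float:
        """Step amplitude relative to holding."""
        return self.step_mV - self.holding_mV

    def with_(self, **kwargs) -> "StimulusProtocol":
        return replace(self, **kwargs)


#: The somatic activity stimulus used throughout: a 2 s train of 5 ms
#: action-potential-like steps from -70 mV to +50 mV at 20 Hz.
AP_TRAIN = StimulusProtocol(mode="vc_train", holding_mV=-70.0, step_mV=50.0,
                            pulse_width_s=0.005, rate_Hz=20.0,
                            train_duration_s=2.0, onset_s=2.0)

#: The passive-property monitoring step: 200 ms from -70 mV to -100 mV.
PASSIVE_STEP = StimulusProtocol(mode="vc_step", holding_mV=-70.0,
                                step_mV=-100.0, pulse_width_s=0.2,
                                onset_s=0.1)

#: The A-current step: -70 mV to -50 mV, quantified over the first 100 ms.
IA_STEP = StimulusProtocol(mode="vc_step", holding_mV=-70.0, step_mV=-50.0,
                           pulse_width_s=0.5, onset_s=0.1)
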
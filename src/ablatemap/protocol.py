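"""Stimulation protocol metadata.

The electrical protocol itself (pulse shapes, field strengths) is metadata
only: the analysis needs the *timeline* — when the baseline ends and when
each 1 Hz pulse train fires — not the electrical waveform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class StimulusProtocol:
    """Timeline of a high-frequency pulsed electroporation protocol.

    Trains are 1-based: train ``k`` fires at
    ``baseline_duration + (k - 1) / train_rate`` seconds.

    Parameters
    ----------
    baseline_duration : float
        Pre-stimulus recording time in seconds. Stimulus onset equals this.
    n_trains : int
        Number of pulse trains delivered.
    train_rate : float
        Train repetition rate in Hz.
    pulses_per_train, pulse_phase_us, carrier_freq_khz, voltage :
        Electrical metadata (bipolar pulses per train, phase width in
        microseconds, carrier frequency in kHz, amplitude in volts). Not
        used by the analysis.
    """

    baseline_duration: float = 60.0
    n_trains: int = 180
    train_rate: float = 1.0
    pulses_per_train: int = 25
    pulse_phase_us: float = 2.0
    carrier_freq_khz: float = 250.0
    voltage: float = 150.0

    def __post_init__(self) -> None:
        if self.baseline_duration <= 0:
            raise ValueError("baseline_duration must be positive")
        if self.n_trains < 1:
            raise ValueError("n_trains must be at least 1")
        if self.train_rate <= 0:
            raise ValueError("train_rate must be positive")

    @property
    def stimulus_onset(self) -> float:
        """Time of the first train, in seconds."""
        return self.baseline_duration

    @property
    def stimulus_end(self) -> float:
        """Time just after the last train window, in seconds."""
        return self.baseline_duration + self.n_trains / self.train_rate

    def train_times(self) -> np.ndarray:
        """Onset time of every train, seconds; ``train_times()[k-1]`` is train k."""
        return self.baseline_duration + np.arange(self.n_trains) / self.train_rate

    def train_time(self, k: int) -> float:
        """Onset time of 1-based train ``k`` in seconds."""
        if not 1 <= k <= self.n_trains:
            raise ValueError(f"train index {k} outside 1..{self.n_trains}")
        return self.baseline_duration + (k - 1) / self.train_rate

    def onset_frame(self, frame_rate: float) -> int:
        """Stimulus onset frame index: floor(onset_s * frame_rate)."""
        return int(np.floor(self.stimulus_onset * frame_rate))
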
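"""Applied waveform geometry and stimulation-train timing.

FSCV applies a triangular voltage ramp to a carbon fiber electrode: the
potential is held at ``v_hold``, swept linearly up to ``v_peak`` and back at a
fixed scan rate, then held again until the next repetition.  At the default
geometry (−0.4 → 1.3 → −0.4 V at 400 V/s) the ramp lasts 8.5 ms and, at a
10 Hz repetition rate, is followed by a 91.5 ms hold.  Electrical stimulation
trains are delivered during the hold period so the stimulus artifact never
overlaps data acquisition during the ramp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidWaveformError",
    "RampWaveform",
    "StimEvent",
    "build_ramp",
    "volts_to_current",
    "gain_from_resistor",
]


class InvalidWaveformError(ValueError):
    """Raised when ramp geometry and repetition rate are inconsistent."""


@dataclass(frozen=True)
class RampWaveform:
    """Triangular scan waveform applied to every channel.

    Parameters
    ----------
    v_hold : float
        Holding potential between scans, volts.
    v_peak : float
        Apex of the triangular sweep, volts.
    scan_rate : float
        Sweep rate, volts/second.
    samples_per_scan : int
        Number of digitized current samples acquired during one ramp.
    repetition_rate : float
        Scan repetition frequency, hertz (10 Hz for recordings; 60 Hz is
        used only for electrode cycling/stabilization sessions).
    """

    v_hold: float = -0.4
    v_peak: float = 1.3
    scan_rate: float = 400.0
    samples_per_scan: int = 1000
    repetition_rate: float = 10.0

    def __post_init__(self) -> None:
        if self.v_peak <= self.v_hold:
            raise InvalidWaveformError(
                f"v_peak ({self.v_peak}) must exceed v_hold ({self.v_hold})"
            )
        if self.scan_rate <= 0:
            raise InvalidWaveformError("scan_rate must be positive")
        if self.samples_per_scan < 2:
            raise InvalidWaveformError("samples_per_scan must be >= 2")
        if self.repetition_rate <= 0:
            raise InvalidWaveformError("repetition_rate must be positive")
        if self.period < self.ramp_duration:
            raise InvalidWaveformError(
                f"repetition period {self.period * 1e3:.3f} ms is shorter than "
                f"the ramp duration {self.ramp_duration * 1e3:.3f} ms"
            )

    @property
    def ramp_duration(self) -> float:
        """Up-and-down sweep duration in seconds (8.5 ms at defaults)."""
        return 2.0 * (self.v_peak - self.v_hold) / self.scan_rate

    @property
    def period(self) -> float:
        """Scan-to-scan period in seconds (1 / repetition_rate)."""
        return 1.0 / self.repetition_rate

    @property
    def hold_duration(self) -> float:
        """Hold time at ``v_hold`` between ramps, seconds (91.5 ms at defaults)."""
        return self.period - self.ramp_duration

    @property
    def sample_interval(self) -> float:
        """Within-scan sampling interval, seconds."""
        return self.ramp_duration / self.samples_per_scan

    @property
    def sampling_rate(self) -> float:
        """Within-scan sampling rate, hertz (~117.6 kHz at defaults)."""
        return self.samples_per_scan / self.ramp_duration

    def voltage_sequence(self) -> np.ndarray:
        """Applied potential at each of the ``samples_per_scan`` sample instants.

        Samples are taken at the midpoints of equal subdivisions of the ramp,
        which makes the sequence exactly symmetric about the apex:
        ``v[i] == v[n-1-i]``.
        """
        n = self.samples_per_scan
        phase = (np.arange(n) + 0.5) / n
        return self.v_hold + (self.v_peak - self.v_hold) * (
            1.0 - np.abs(2.0 * phase - 1.0)
        )

    def index_of_voltage(self, volts: float, limb: str = "rising") -> int:
        """Sample index closest to ``volts`` on the rising or falling limb."""
        v = self.voltage_sequence()
        half = self.samples_per_scan // 2
        if limb == "rising":
            return int(np.argmin(np.abs(v[:half] - volts)))
        if limb == "falling":
            return half + int(np.argmin(np.abs(v[half:] - volts)))
        raise ValueError("limb must be 'rising' or 'falling'")


def build_ramp(
    v_hold: float = -0.4,
    v_peak: float = 1.3,
    scan_rate: float = 400.0,
    samples_per_scan: int = 1000,
    repetition_rate: float = 10.0,
) -> RampWaveform:
    """Construct and validate a :class:`RampWaveform`.

    Raises :class:`InvalidWaveformError` when the repetition period is shorter
    than the ramp itself or any geometric parameter is non-physical.
    """
    return RampWaveform(
        v_hold=v_hold,
        v_peak=v_peak,
        scan_rate=scan_rate,
        samples_per_scan=samples_per_scan,
        repetition_rate=repetition_rate,
    )


@dataclass(frozen=True)
class StimEvent:
    """One electrical stimulation train within a recording.

    ``onset_time`` is seconds from the start of the recording (trains are
    delivered 5 s into a 30 s recording by default).  The train consists of
    ``pulse_count`` pulses at ``frequency`` Hz; its duration is
    ``(pulse_count - 1) / frequency``.
    """

    onset_time: float = 5.0
    frequency: float = 60.0
    pulse_count: int = 30
    amplitude_uA: float = 150.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("stimulation frequency must be positive")
        if self.pulse_count < 1:
            raise ValueError("pulse_count must be >= 1")
        if self.onset_time < 0:
            raise ValueError("onset_time must be non-negative")

    @property
    def train_duration(self) -> float:
        return (self.pulse_count - 1) / self.frequency

    @property
    def end_time(self) -> float:
        return self.onset_time + self.train_duration

    def pulse_times(self) -> np.ndarray:
        """Absolute times of each stimulus pulse (seconds)."""
        return self.onset_time + np.arange(self.pulse_count) / self.frequency

    def validate_within(self, duration: float) -> None:
        """Check that the whole train falls inside a recording of ``duration`` s."""
        if self.end_time > duration:
            raise ValueError(
                f"stimulation train ends at {self.end_time:.2f} s, beyond the "
                f"{duration:.2f} s recording"
            )


def volts_to_current(differential_volts, gain: float = 200.0):
    """Convert headstage differential output (V) to electrode current (nA).

    The transimpedance amplifier reports current as a voltage with gain in
    nA/V (200 nA/V with the standard 4.99 MΩ feedback resistor).
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    return np.asarray(differential_volts, dtype=float) * gain


def gain_from_resistor(resistance_ohms: float) -> float:
    """Transimpedance gain in nA/V implied by a feedback resistor.

    1 V across R ohms is 1/R amperes, i.e. 1e9/R nA — 200.4 nA/V for 4.99 MΩ.
    """
    if resistance_ohms <= 0:
        raise ValueError("resistance must be positive")
    return 1e9 / resistance_ohms
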
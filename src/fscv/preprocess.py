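"""Two-stage filtering of voltammogram streams.

Stage 1 — per-scan smoothing: each 1,000-sample voltammogram is passed through
a 4th-order 2 kHz low-pass Butterworth IIR filter along the within-scan axis
(sampling rate ≈ 117.6 kHz at the default ramp), removing non-biological
high-frequency noise.

Stage 2 — drift removal: the time series of each of the 1,000 potential steps
across scans (sampling rate = the 10 Hz scan repetition rate) is passed through
a 2nd-order 0.01 Hz high-pass Butterworth filter applied forward and backward
(zero phase), removing the slow background drift of the charging current while
preserving second-scale transients without lag.  The filter is applied with
reflective edge padding because a 30 s record is short relative to the 100 s
cutoff period.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .raw_io import ScanStream

__all__ = ["lowpass_scan_filter", "highpass_drift_filter", "preprocess_stream"]


def lowpass_scan_filter(
    stream: ScanStream, order: int = 4, cutoff_hz: float = 2000.0
) -> ScanStream:
    """Low-pass each voltammogram along the within-scan (potential) axis.

    A causal Butterworth realization: unity gain at DC, −3 dB at the cutoff,
    −80 dB/decade roll-off at 4th order.
    """
    fs = stream.waveform.sampling_rate
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie below the within-scan Nyquist "
            f"frequency {fs / 2:.1f} Hz"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    # step-response initial conditions: a constant (DC) scan passes unchanged
    # instead of ramping up from zero state
    zi = signal.sosfilt_zi(sos)
    zi_rows = zi[:, None, :] * stream.scans[None, :, 0, None]
    filtered, _ = signal.sosfilt(sos, stream.scans, axis=1, zi=zi_rows)
    return stream.copy_with(
        filtered, lowpass={"order": order, "cutoff_hz": cutoff_hz}
    )


def highpass_drift_filter(
    stream: ScanStream,
    order: int = 2,
    cutoff_hz: float = 0.01,
    padtype: str = "odd",
    padlen: "int | None" = None,
) -> ScanStream:
    """Zero-phase high-pass across time at every potential step.

    Forward–backward (filtfilt) application doubles the effective order and
    cancels group delay; DC and sub-cutoff drift are removed.  Records are
    short relative to the 100 s cutoff period, so edge handling matters:
    the default "odd" (antisymmetric) reflection continues the local slope
    of the series past its endpoints, which lets the filter take out linear
    drift cleanly; the default pad length is one cutoff period (capped at
    the record length minus one).
    """
    fs = stream.waveform.repetition_rate
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie below the across-scan Nyquist "
            f"frequency {fs / 2:.2f} Hz"
        )
    b, a = signal.butter(order, cutoff_hz, btype="high", fs=fs)
    warmup = 3 * max(len(a), len(b))
    if stream.n_scans <= warmup:
        raise ValueError(
            f"need more than {warmup} scans for the zero-phase drift filter, "
            f"got {stream.n_scans}"
        )
    if padlen is None:
        padlen = min(stream.n_scans - 1, int(round(fs / cutoff_hz)))
    filtered = signal.filtfilt(
        b, a, stream.scans, axis=0, padtype=padtype, padlen=padlen
    )
    return stream.copy_with(
        filtered,
        highpass={
            "order": order,
            "cutoff_hz": cutoff_hz,
            "padtype": padtype,
            "padlen": padlen,
        },
    )


def preprocess_stream(stream: ScanStream, config: "dict | None" = None) -> ScanStream:
    """Apply both stages in acquisition order: low-pass per scan, then
    high-pass drift removal across time.

    ``config`` may carry ``{"lowpass": {...}, "highpass": {...}}`` overrides
    matching the keyword arguments of the two filter functions.
    """
    config = config or {}
    out = lowpass_scan_filter(stream, **config.get("lowpass", {}))
    out = highpass_drift_filter(out, **config.get("highpass", {}))
    return out
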
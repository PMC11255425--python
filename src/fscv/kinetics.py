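"""Stimulated-release and reuptake metrics from concentration traces.

ES DA (electrically stimulated dopamine release) is the difference between the
pre-stimulation baseline concentration and the peak concentration reached
within 10 s of the stimulation onset, in nM.  The baseline is the mean over a
window (default 2 s) ending at stimulation onset.

Tau quantifies reuptake: the post-peak decay is fit with a single exponential
``c(t) = baseline + A·exp(−(t − t_peak)/τ)`` from the peak down to the point
where the trace first returns to 10% of the release amplitude above baseline.
Larger τ means slower clearance (slower reuptake).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .waveform import StimEvent

__all__ = ["KineticsResult", "es_da_release", "fit_tau", "quantify_event"]

#: Search window for the stimulated peak, seconds after onset.
PEAK_WINDOW_S = 10.0

TAU_BOUNDS_S = (1e-3, 60.0)


@dataclass
class KineticsResult:
    """ES DA and reuptake kinetics for one stimulation event on one channel."""

    es_da: float
    baseline: float
    peak: float
    peak_time: float
    tau: float = np.nan
    tau_fit_r2: float = np.nan
    flags: set = field(default_factory=set)


def es_da_release(
    times: np.ndarray,
    conc_nM: np.ndarray,
    stim: StimEvent,
    baseline_window: float = 2.0,
) -> KineticsResult:
    """Stimulated release: peak within 10 s of onset minus pre-stim baseline.

    The result carries a ``no_response`` flag when the computed release is
    not positive.  A peak occurring after the 10 s window is deliberately
    ignored — only the in-window maximum counts.
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc_nM, dtype=float)
    t0 = stim.onset_time

    base_mask = (times >= t0 - baseline_window) & (times <= t0)
    peak_mask = (times > t0) & (times <= t0 + PEAK_WINDOW_S)
    if base_mask.sum() < 1 or peak_mask.sum() < 2:
        raise ValueError(
            "trace does not cover the baseline window and the 10 s peak window"
        )

    baseline = float(np.mean(conc[base_mask]))
    i_peak = np.flatnonzero(peak_mask)[np.argmax(conc[peak_mask])]
    peak = float(conc[i_peak])
    peak_time = float(times[i_peak])
    es_da = peak - baseline

    flags = set()
    if es_da <= 0:
        flags.add("no_response")
    return KineticsResult(
        es_da=es_da, baseline=baseline, peak=peak, peak_time=peak_time, flags=flags
    )


def _exp_decay(t, baseline, amplitude, tau):
    return baseline + amplitude * np.exp(-t / tau)


def fit_tau(
    times: np.ndarray,
    conc_nM: np.ndarray,
    result: KineticsResult,
    return_frac: float = 0.1,
    min_samples: int = 5,
    free_baseline: bool = False,
) -> KineticsResult:
    """Fit the post-peak exponential decay and fill in τ and its R².

    The fitted segment runs from the peak to the first sample at or below
    ``baseline + return_frac·es_da`` (or the end of the trace).  By default
    the asymptote is pinned to the pre-stimulation baseline, which is
    estimated independently from many samples; freeing it
    (``free_baseline=True``) makes the fit poorly conditioned on decay
    segments shorter than a couple of time constants.  Fits on non-decaying
    segments, or segments with fewer than ``min_samples`` points, are
    flagged ``tau_fit_failed`` and leave τ as NaN.  τ is bounded to
    (0, 60] s.
    """
    if result.es_da <= 0 or "no_response" in result.flags:
        result.flags.add("tau_fit_failed")
        return result

    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc_nM, dtype=float)
    after = np.flatnonzero(times >= result.peak_time)
    seg_t = times[after]
    seg_c = conc[after]

    cutoff = result.baseline + return_frac * result.es_da
    below = np.flatnonzero(seg_c <= cutoff)
    end = below[0] + 1 if below.size else seg_c.size
    seg_t, seg_c = seg_t[:end], seg_c[:end]

    if seg_c.size < min_samples or seg_c[-1] >= seg_c[0]:
        result.flags.add("tau_fit_failed")
        return result

    t_rel = seg_t - seg_t[0]
    amp0 = max(seg_c[0] - result.baseline, 1e-12)
    span = seg_t[-1] - seg_t[0]
    tau0 = float(np.clip(span / 2.3, *TAU_BOUNDS_S))
    try:
        if free_baseline:
            popt, _ = curve_fit(
                _exp_decay, t_rel, seg_c,
                p0=(result.baseline, amp0, tau0),
                bounds=(
                    (-np.inf, 0.0, TAU_BOUNDS_S[0]),
                    (np.inf, np.inf, TAU_BOUNDS_S[1]),
                ),
                maxfev=10000,
            )
            tau = float(popt[2])
            fitted = _exp_decay(t_rel, *popt)
        else:
            base = result.baseline
            popt, _ = curve_fit(
                lambda t, a, tau: _exp_decay(t, base, a, tau),
                t_rel, seg_c,
                p0=(amp0, tau0),
                bounds=((0.0, TAU_BOUNDS_S[0]), (np.inf, TAU_BOUNDS_S[1])),
                maxfev=10000,
            )
            tau = float(popt[1])
            fitted = _exp_decay(t_rel, base, *popt)
    except RuntimeError:
        result.flags.add("tau_fit_failed")
        return result

    ss_res = float(np.sum((seg_c - fitted) ** 2))
    ss_tot = float(np.sum((seg_c - seg_c.mean()) ** 2))
    result.tau = tau
    result.tau_fit_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return result


def quantify_event(
    times: np.ndarray,
    conc_nM: np.ndarray,
    stim: StimEvent,
    baseline_window: float = 2.0,
    return_frac: float = 0.1,
) -> KineticsResult:
    """ES DA plus τ for one stimulation event (the full per-channel readout)."""
    result = es_da_release(times, conc_nM, stim, baseline_window=baseline_window)
    return fit_tau(times, conc_nM, result, return_frac=return_frac)
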
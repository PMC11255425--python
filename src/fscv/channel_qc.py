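"""Quality control across the 16 channels of an electrode array.

Two screens are applied to the per-channel scalar used downstream (the
stimulated-release value, ES DA):

1. a response threshold — channels whose peak does not rise at least
   ``k`` noise standard deviations above baseline are "below threshold"
   (fibers do not all respond on all days and may come back online later);
2. the ±2 SD outlier rule — a channel whose value falls outside the mean of
   all contributing channels ± 2 sample standard deviations is removed.
   The rule is applied in a single pass (no re-iteration after removal).

A session-by-session yield report tracks per-fiber availability over chronic
recordings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCResult",
    "remove_outlier_channels",
    "screen_responses",
    "qc_recording",
    "channel_yield_report",
]

#: qc_status values in order of precedence
STATUSES = ("present", "below_threshold", "outlier", "absent")


@dataclass
class QCResult:
    """Outcome of the ±n SD outlier screen over one recording."""

    kept: "list[int]"
    outliers: "list[int]"
    mean: float
    sd: float
    skipped: bool = False
    lower: float = field(init=False, default=-np.inf)
    upper: float = field(init=False, default=np.inf)

    @property
    def bounds(self) -> "tuple[float, float]":
        return (self.lower, self.upper)


def remove_outlier_channels(
    values: "dict[int, float] | pd.Series",
    n_sd: float = 2.0,
) -> QCResult:
    """Apply the ±``n_sd`` standard-deviation outlier rule across channels.

    The mean and sample (n−1) SD are computed over *all* contributing
    channels, the candidate included; channels with ``|value − mean| >
    n_sd · SD`` are removed.  Single pass only: the statistics are never
    recomputed on the kept set.  With fewer than 3 channels the screen is
    skipped with a warning (all channels kept, ``skipped=True``).
    """
    series = pd.Series(values, dtype=float).dropna()
    ids = list(series.index)
    if len(ids) < 3:
        warnings.warn(
            f"only {len(ids)} channels with values; outlier screen skipped",
            stacklevel=2,
        )
        res = QCResult(kept=ids, outliers=[], mean=float(series.mean()),
                       sd=float("nan"), skipped=True)
        res.lower, res.upper = -np.inf, np.inf
        return res

    mean = float(series.mean())
    sd = float(series.std(ddof=1))
    lower, upper = mean - n_sd * sd, mean + n_sd * sd
    if np.isinf(n_sd) or sd == 0:
        outliers: "list[int]" = []
    else:
        outliers = [int(i) for i in series.index[(series < lower) | (series > upper)]]
    kept = [int(i) for i in ids if int(i) not in outliers]
    res = QCResult(kept=kept, outliers=outliers, mean=mean, sd=sd)
    res.lower, res.upper = lower, upper
    return res


def screen_responses(
    es_da: "dict[int, float] | pd.Series",
    noise_sd: "dict[int, float] | pd.Series | float",
    k: float = 3.0,
) -> "dict[int, bool]":
    """Response-threshold screen: True where the channel's ES DA rises at
    least ``k`` times the trace noise SD above baseline."""
    es = pd.Series(es_da, dtype=float)
    if np.isscalar(noise_sd):
        noise = pd.Series(noise_sd, index=es.index, dtype=float)
    else:
        noise = pd.Series(noise_sd, dtype=float).reindex(es.index)
    return {int(i): bool(es[i] >= k * noise[i]) for i in es.index}


def qc_recording(
    es_da: "dict[int, float] | pd.Series",
    noise_sd: "dict[int, float] | pd.Series | float",
    n_sd: float = 2.0,
    response_k: float = 3.0,
) -> pd.DataFrame:
    """Combined screen for one recording.

    Channels failing the response threshold are excluded before the outlier
    rule is applied to the remainder.  Returns a table with columns
    ``channel, value_nM, qc_status``.
    """
    es = pd.Series(es_da, dtype=float)
    responding = screen_responses(es, noise_sd, k=response_k)
    candidates = es[[i for i in es.index if responding[int(i)]]]
    qc = remove_outlier_channels(candidates, n_sd=n_sd) if len(candidates) else None

    rows = []
    for ch in es.index:
        ch = int(ch)
        if not responding[ch]:
            status = "below_threshold"
        elif qc is not None and ch in qc.outliers:
            status = "outlier"
        else:
            status = "present"
        rows.append({"channel": ch, "value_nM": float(es[ch]), "qc_status": status})
    return pd.DataFrame(rows)


def channel_yield_report(
    sessions: "dict[str, dict[int, str]] | dict[str, pd.Series]",
) -> pd.DataFrame:
    """Per-channel availability across sessions.

    ``sessions`` maps a session label to per-channel status strings
    (``present`` / ``below_threshold`` / ``outlier``; missing channels are
    ``absent``).  Returns one row per channel with a status column per
    session plus ``n_present`` and ``availability`` (fraction of sessions in
    which the channel contributed data).
    """
    if not sessions:
        raise ValueError("need at least one session")
    labels = list(sessions)
    status = pd.DataFrame(
        {lab: pd.Series(sessions[lab], dtype=object) for lab in labels}
    )
    status = status.fillna("absent")
    status.index = status.index.astype(int)
    status.index.name = "channel"
    status = status.sort_index()
    present = (status == "present").sum(axis=1)
    status["n_present"] = present
    status["availability"] = present / len(labels)
    return status
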
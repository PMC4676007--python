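"""Unit quality control and firing-rate analysis.

Sorted units are screened before analysis: mean rates below 4 spikes/s or
above 100 spikes/s are excluded, as are units with implausible inter-spike
interval distributions — operationalized here as more than 1.5% of ISIs
shorter than a 2-ms refractory bound (a standard sorting-quality heuristic;
the thresholds are configurable and the criterion is flagged in reports as
an operationalization).

Firing rates are spike counts over half-open epochs divided by epoch
length; evoked rates pool spikes over all 500-ms post-stimulus epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recio import EVOKED_EPOCH_S, RecordingError, SpikeTrain, StimulusSchedule

#: unit-acceptance band, spikes/s (strict: exactly 4 or 100 is kept)
RATE_BAND_HZ = (4.0, 100.0)
#: ISI refractory bound, seconds
ISI_REFRACTORY_S = 0.002
#: maximum tolerated fraction of ISIs below the refractory bound
ISI_VIOLATION_MAX = 0.015

QC_COLUMNS = ["unit_id", "mean_rate", "refractory_violation_fraction", "decision"]
RATE_COLUMNS = ["unit_id", "region", "group", "condition", "epoch_type", "rate"]


@dataclass
class UnitQCReport:
    unit_id: str
    mean_rate: float
    refractory_violation_fraction: float
    decision: str  # accepted | rejected_rate | rejected_isi


def unit_qc(
    train: SpikeTrain,
    analysis_duration: float,
    rate_band: tuple[float, float] = RATE_BAND_HZ,
    isi_refractory: float = ISI_REFRACTORY_S,
    isi_violation_max: float = ISI_VIOLATION_MAX,
) -> UnitQCReport:
    """Screen one sorted unit; updates ``train.qc_status`` in place."""
    if analysis_duration <= 0:
        raise RecordingError("analysis duration must be positive")
    rate = train.n_spikes / analysis_duration
    isis = np.diff(train.timestamps)
    viol = float(np.mean(isis < isi_refractory)) if isis.size else 0.0
    if rate < rate_band[0] or rate > rate_band[1]:
        decision = "rejected_rate"
    elif viol > isi_violation_max:
        decision = "rejected_isi"
    else:
        decision = "accepted"
    train.qc_status = decision
    return UnitQCReport(
        unit_id=train.unit_id,
        mean_rate=rate,
        refractory_violation_fraction=viol,
        decision=decision,
    )


def firing_rate(train: SpikeTrain, epoch: tuple[float, float]) -> float:
    """Spikes in ``[start, end)`` divided by the epoch length (spikes/s)."""
    start, end = float(epoch[0]), float(epoch[1])
    if end <= start:
        raise RecordingError("epoch must have positive length")
    n = int(np.searchsorted(train.timestamps, end, "left")
            - np.searchsorted(train.timestamps, start, "left"))
    return n / (end - start)


def windowed_counts(
    train: SpikeTrain, epoch: tuple[float, float], win_length: float
) -> np.ndarray:
    """Spike counts in consecutive non-overlapping windows tiling the epoch."""
    start, end = float(epoch[0]), float(epoch[1])
    n_win = int(np.floor((end - start) / win_length + 1e-9))
    if n_win < 1:
        raise RecordingError("epoch shorter than one window")
    edges = start + win_length * np.arange(n_win + 1)
    counts, _ = np.histogram(train.timestamps, bins=edges)
    return counts


def evoked_rate(
    train: SpikeTrain,
    schedule: StimulusSchedule,
    epoch_length: float = EVOKED_EPOCH_S,
) -> float:
    """Pooled rate over all post-stimulus epochs: total spikes / total time."""
    if schedule is None or schedule.n_couplets == 0:
        raise RecordingError("empty stimulus schedule")
    onsets = schedule.all_pulse_times()
    t = train.timestamps
    total = int(
        np.sum(
            np.searchsorted(t, onsets + epoch_length, "left")
            - np.searchsorted(t, onsets, "left")
        )
    )
    return total / (onsets.size * epoch_length)


def percent_change(reference: float, treatment: float) -> float:
    """``100 * (treatment - reference) / reference``; reference must be > 0."""
    if reference <= 0:
        raise RecordingError("percent change undefined for non-positive reference")
    return 100.0 * (treatment - reference) / reference


def qc_table(reports: list[UnitQCReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "unit_id": r.unit_id,
                "mean_rate": r.mean_rate,
                "refractory_violation_fraction": r.refractory_violation_fraction,
                "decision": r.decision,
            }
            for r in reports
        ],
        columns=QC_COLUMNS,
    )


def rate_table(rows: list[dict]) -> pd.DataFrame:
    """Tidy firing-rate table with a fixed column order (plus any extras)."""
    df = pd.DataFrame(rows)
    extra = [c for c in df.columns if c not in RATE_COLUMNS]
    df = df[[c for c in RATE_COLUMNS if c in df.columns] + extra]
    if "rate" in df.columns and df["rate"].lt(0).any():
        raise RecordingError("rates must be nonnegative")
    return df
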
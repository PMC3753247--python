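"""Peak-based decoding of the opponent's choice from the pupil trace.

The marker is the time of maximum pupil dilation: the decoded interval is
the latest word onset at or before the global diameter maximum, searched
from the first word onset to the end of the trace.  Because the argmax is
invariant under positive affine transforms, decoding gives identical results
on raw-millimeter and z-normalized traces; z-normalization (pooled within
opponent) is provided for visualization and cross-opponent averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .game import Choice
from .synthetic_data import GameSet, OpponentGame, PupilTrace

__all__ = [
    "DecodeResult",
    "ZNormalizedTrace",
    "ValidityResult",
    "znormalize",
    "decode_trace",
    "decode_game",
    "decode_set",
    "validity",
]


@dataclass(frozen=True)
class DecodeResult:
    decoded_interval: int  # 1..3
    decoded_choice: Choice
    peak_time_s: float
    peak_value: float
    peak_units: str = "mm"


@dataclass
class ZNormalizedTrace:
    """Trace in z-units relative to a normalization pool (all samples of all
    games of one opponent)."""

    samples_z: np.ndarray
    sampling_rate_hz: float
    schedule: object
    pool_mean_mm: float
    pool_sd_mm: float


def znormalize(traces: PupilTrace | Sequence[PupilTrace]) -> list[ZNormalizedTrace]:
    """Z-score one or more traces against their pooled mean and SD.

    Pool together all traces of one opponent; the pooled output then has
    mean 0 and SD 1.
    """
    if isinstance(traces, PupilTrace):
        traces = [traces]
    traces = list(traces)
    if not traces:
        raise ValueError("no traces to normalize")
    pooled = np.concatenate([t.samples_mm for t in traces])
    mean = float(pooled.mean())
    sd = float(pooled.std())
    if sd == 0.0:
        raise ValueError("cannot z-normalize constant traces (pooled SD is zero)")
    return [
        ZNormalizedTrace(
            samples_z=(t.samples_mm - mean) / sd,
            sampling_rate_hz=t.sampling_rate_hz,
            schedule=t.schedule,
            pool_mean_mm=mean,
            pool_sd_mm=sd,
        )
        for t in traces
    ]


def _peak_index(samples: np.ndarray, start: int, smooth_width: int) -> int:
    x = samples
    if smooth_width > 1:
        kernel = np.ones(smooth_width) / smooth_width
        x = np.convolve(x, kernel, mode="same")
    # np.argmax returns the first occurrence: ties break to the earliest sample
    return start + int(np.argmax(x[start:]))


def decode_trace(
    trace: PupilTrace | ZNormalizedTrace,
    smooth_width_s: float = 0.0,
) -> DecodeResult:
    """Locate the global dilation maximum and attribute it to an interval.

    The analysis window runs from the first word onset (a peak before any
    word cannot follow a word) to the end of the trace.  Interval windows
    are half-open ``[onset_i, onset_{i+1})``, the last extending to the end.
    Optional moving-average smoothing (width in seconds) is off by default.
    """
    samples = trace.samples_z if isinstance(trace, ZNormalizedTrace) else trace.samples_mm
    rate = trace.sampling_rate_hz
    onsets = np.asarray(trace.schedule.onsets_s)
    start = int(np.ceil(onsets[0] * rate - 1e-9))
    if start >= samples.size:
        raise ValueError("analysis window is empty: trace ends before the first onset")
    width = int(round(smooth_width_s * rate))
    i = _peak_index(samples, start, width)
    peak_time = i / rate
    interval = int(np.searchsorted(onsets, peak_time + 1e-12, side="right"))
    interval = max(interval, 1)
    return DecodeResult(
        decoded_interval=interval,
        decoded_choice=trace.schedule.order[interval - 1],
        peak_time_s=peak_time,
        peak_value=float(samples[i]),
        peak_units="z" if isinstance(trace, ZNormalizedTrace) else "mm",
    )


def decode_game(game: OpponentGame, smooth_width_s: float = 0.0) -> DecodeResult:
    """Decode one opponent game from its pupil trace."""
    return decode_trace(game.trace, smooth_width_s=smooth_width_s)


def decode_set(game_set: GameSet, smooth_width_s: float = 0.0) -> pd.DataFrame:
    """Decode every game; returns a table with one row per game and a
    ``valid`` flag (decoded interval equals the selected interval)."""
    rows = []
    for g in game_set:
        r = decode_game(g, smooth_width_s=smooth_width_s)
        rows.append(
            {
                "game_id": g.game_id,
                "opponent_id": g.opponent_id,
                "selected_interval": g.selected_interval,
                "decoded_interval": r.decoded_interval,
                "decoded_choice": r.decoded_choice.value,
                "peak_time_s": r.peak_time_s,
                "valid": int(r.decoded_interval == g.selected_interval),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ValidityResult:
    n_valid: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_valid / self.n_total

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def validity(game_set: GameSet, smooth_width_s: float = 0.0) -> ValidityResult:
    """Fraction of games whose decoded interval matches the opponent's
    selected interval."""
    if len(game_set) == 0:
        raise ValueError("empty game set")
    n_valid = sum(
        decode_game(g, smooth_width_s=smooth_width_s).decoded_interval == g.selected_interval
        for g in game_set
    )
    return ValidityResult(n_valid=int(n_valid), n_total=len(game_set))
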
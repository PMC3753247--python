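"""Synthetic decision-locked pupillometry for three-interval RPS games.

Each game presents the three words rock / paper / scissors in random order
at 4-s spacing; the opponent covertly commits to one of them.  The simulated
pupil-diameter trace (120 Hz) is a positive baseline plus a gamma-shaped
dilation transient locked to the selected word (peaking ~1.5 s after its
onset), optional distractor transients at the non-selected words, and
additive measurement noise.  The shipped defaults are calibrated so that a
75-game set reproduces the reference trace statistics: grand-mean diameter
~4.6 mm and a within-game min-max range of ~3.8 mm on average (SD across
games ~1.0 mm).

Game sets are produced with *exact* control of how many games are "valid" --
i.e. the global dilation maximum falls inside the selected word's interval
as judged by the decoder itself -- enforced by per-game rejection sampling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .game import CHOICES, Choice

__all__ = [
    "WordSchedule",
    "KernelConfig",
    "DistractorConfig",
    "ArtifactConfig",
    "GeneratorConfig",
    "PupilTrace",
    "OpponentGame",
    "GameSet",
    "TraceSummary",
    "generate_trace",
    "generate_game_set",
    "reference_fixture",
    "summarize_traces",
    "REFERENCE_SEED",
]

logger = logging.getLogger(__name__)

#: seed of the packaged deterministic 75-game reference set
REFERENCE_SEED = 73302


@dataclass(frozen=True)
class WordSchedule:
    """Word onsets (s) and the order the three words are spoken in."""

    onsets_s: tuple[float, float, float] = (1.0, 5.0, 9.0)
    order: tuple[Choice, Choice, Choice] = CHOICES

    def __post_init__(self) -> None:
        if len(self.onsets_s) != 3 or len(self.order) != 3:
            raise ValueError("a schedule has exactly three words")
        if not all(b > a for a, b in zip(self.onsets_s, self.onsets_s[1:])):
            raise ValueError("onsets must be strictly increasing")
        object.__setattr__(self, "order", tuple(Choice(c) for c in self.order))
        if len(set(self.order)) != 3:
            raise ValueError("the three words must be distinct")

    def interval_of(self, choice: Choice | str) -> int:
        """1-based interval in which ``choice`` is spoken."""
        return self.order.index(Choice(choice)) + 1


@dataclass(frozen=True)
class KernelConfig:
    """Decision-locked dilation transient: gamma-like impulse response
    ``(t/tp)^shape * exp(shape*(1 - t/tp))`` with unit peak at latency ``tp``.

    ``amplitude_mm`` is the mean peak height above baseline; the per-game
    amplitude is drawn N(amplitude_mm, amplitude_sd_mm), floored at zero.
    """

    amplitude_mm: float = 3.35
    amplitude_sd_mm: float = 0.95
    peak_latency_s: float = 1.5
    shape: float = 2.0

    def __post_init__(self) -> None:
        if self.amplitude_mm < 0 or self.amplitude_sd_mm < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.peak_latency_s <= 0 or self.shape <= 0:
            raise ValueError("peak latency and shape must be positive")


@dataclass(frozen=True)
class DistractorConfig:
    """Transients at non-selected word onsets.  Each non-selected interval
    carries one with probability ``prob_per_interval``; its amplitude is the
    game's decision amplitude times U(relative_lo, relative_hi), its latency
    jittered by U(-latency_jitter_s, +latency_jitter_s).  A relative
    amplitude above 1 is what makes a game decode invalid."""

    prob_per_interval: float = 0.8
    relative_lo: float = 0.4
    relative_hi: float = 1.15
    latency_jitter_s: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob_per_interval <= 1.0:
            raise ValueError("prob_per_interval must lie in [0, 1]")
        if not 0.0 <= self.relative_lo <= self.relative_hi:
            raise ValueError("need 0 <= relative_lo <= relative_hi")
        if self.latency_jitter_s < 0:
            raise ValueError("latency jitter must be nonnegative")


@dataclass(frozen=True)
class ArtifactConfig:
    """Optional blink-like dropouts, repaired by linear interpolation as an
    eye tracker would. Off by default."""

    dropout_rate_hz: float = 0.0
    dropout_duration_s: float = 0.15


@dataclass(frozen=True)
class GeneratorConfig:
    sampling_rate_hz: float = 120.0
    trace_duration_s: float = 14.0
    baseline_mm: float = 3.13
    kernel: KernelConfig = field(default_factory=KernelConfig)
    distractor: DistractorConfig = field(default_factory=DistractorConfig)
    artifacts: ArtifactConfig = field(default_factory=ArtifactConfig)
    noise_sd_mm: float = 0.05
    clip_floor_mm: float = 0.5
    onsets_s: tuple[float, float, float] = (1.0, 5.0, 9.0)

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.trace_duration_s <= 0:
            raise ValueError("trace duration must be positive")
        if self.baseline_mm <= 0:
            raise ValueError("baseline diameter must be positive")
        if self.noise_sd_mm < 0:
            raise ValueError("noise SD must be nonnegative")
        if self.clip_floor_mm <= 0:
            raise ValueError("clip floor must be positive")


@dataclass
class PupilTrace:
    """Uniformly sampled pupil diameter (mm) for one game."""

    samples_mm: np.ndarray
    sampling_rate_hz: float
    schedule: WordSchedule

    def __post_init__(self) -> None:
        self.samples_mm = np.asarray(self.samples_mm, dtype=float)
        if self.samples_mm.ndim != 1 or self.samples_mm.size < 2:
            raise ValueError("a trace is a 1-D array of at least two samples")
        if not np.all(self.samples_mm > 0):
            raise ValueError("pupil diameters must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.duration_s < self.schedule.onsets_s[-1]:
            raise ValueError("trace must cover all word onsets")

    @property
    def n_samples(self) -> int:
        return self.samples_mm.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass
class OpponentGame:
    """One recorded game: trace plus the opponent's concealed choice."""

    game_id: str
    opponent_id: str
    trace: PupilTrace
    opponent_choice: Choice
    selected_interval: int

    def __post_init__(self) -> None:
        self.opponent_choice = Choice(self.opponent_choice)
        if self.trace.schedule.interval_of(self.opponent_choice) != self.selected_interval:
            raise ValueError(
                "selected_interval must be the position of opponent_choice "
                "in the word order"
            )


@dataclass
class GameSet:
    """Ordered collection of opponent games with generation provenance."""

    games: list[OpponentGame]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.games:
            raise ValueError("a game set must be nonempty")

    def __len__(self) -> int:
        return len(self.games)

    def __iter__(self) -> Iterator[OpponentGame]:
        return iter(self.games)

    def __getitem__(self, i):
        return self.games[i]

    def interval_counts(self) -> tuple[int, int, int]:
        counts = [0, 0, 0]
        for g in self.games:
            counts[g.selected_interval - 1] += 1
        return tuple(counts)


def _gamma_kernel(t: np.ndarray, peak_latency_s: float, shape: float) -> np.ndarray:
    out = np.zeros_like(t, dtype=float)
    m = t > 0
    u = t[m] / peak_latency_s
    out[m] = u**shape * np.exp(shape * (1.0 - u))
    return out


def _apply_dropouts(x: np.ndarray, rate_hz: float, cfg: ArtifactConfig,
                    rng: np.random.Generator) -> np.ndarray:
    duration = x.size / rate_hz
    n_drop = rng.poisson(cfg.dropout_rate_hz * duration)
    if n_drop == 0:
        return x
    x = x.copy()
    half = max(1, int(round(cfg.dropout_duration_s * rate_hz / 2)))
    for _ in range(n_drop):
        c = int(rng.integers(half, x.size - half))
        lo, hi = c - half, c + half
        x[lo:hi] = np.interp(np.arange(lo, hi), [lo - 1, hi], [x[lo - 1], x[hi]])
    return x


def generate_trace(
    schedule: WordSchedule,
    selected_interval: int,
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> PupilTrace:
    """Generate one pupil trace with the dilation transient locked to the
    selected word.

    With noise and distractors disabled the global maximum sits exactly at
    ``onset[selected_interval] + peak_latency_s``.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if selected_interval not in (1, 2, 3):
        raise ValueError("selected_interval must be 1, 2 or 3")
    onset = schedule.onsets_s[selected_interval - 1]
    k = config.kernel
    if onset + k.peak_latency_s >= config.trace_duration_s:
        raise ValueError("decision peak would fall beyond the end of the trace")

    n = int(round(config.trace_duration_s * config.sampling_rate_hz))
    t = np.arange(n) / config.sampling_rate_hz

    amp = k.amplitude_mm
    if amp > 0 and k.amplitude_sd_mm > 0:
        amp = max(amp + k.amplitude_sd_mm * rng.standard_normal(), 0.0)
    x = config.baseline_mm + amp * _gamma_kernel(t - onset, k.peak_latency_s, k.shape)

    d = config.distractor
    for i, o in enumerate(schedule.onsets_s, start=1):
        if i == selected_interval:
            continue
        if rng.random() < d.prob_per_interval:
            rel = rng.uniform(d.relative_lo, d.relative_hi)
            jit = rng.uniform(-d.latency_jitter_s, d.latency_jitter_s)
            x += amp * rel * _gamma_kernel(t - o - jit, k.peak_latency_s, k.shape)

    if config.noise_sd_mm > 0:
        x += config.noise_sd_mm * rng.standard_normal(n)
    if config.artifacts.dropout_rate_hz > 0:
        x = _apply_dropouts(x, config.sampling_rate_hz, config.artifacts, rng)

    n_clip = int(np.sum(x < config.clip_floor_mm))
    if n_clip:
        logger.warning("clipped %d sample(s) at the %.2f mm positivity floor",
                       n_clip, config.clip_floor_mm)
        x = np.maximum(x, config.clip_floor_mm)

    return PupilTrace(x, config.sampling_rate_hz, schedule)


def _allocate_valid(interval_counts: Sequence[int], n_valid: int) -> list[int]:
    """Largest-remainder proportional split of n_valid across intervals,
    capped by the games available in each interval."""
    total = sum(interval_counts)
    quotas = [n_valid * c / total for c in interval_counts]
    alloc = [min(int(math.floor(q)), c) for q, c in zip(quotas, interval_counts)]
    remainders = sorted(
        range(3), key=lambda i: quotas[i] - math.floor(quotas[i]), reverse=True
    )
    i = 0
    while sum(alloc) < n_valid:
        j = remainders[i % 3]
        if alloc[j] < interval_counts[j]:
            alloc[j] += 1
        i += 1
    return alloc


def generate_game_set(
    n_games: int,
    interval_counts: Sequence[int] | None = None,
    n_valid: int | None = None,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    valid_per_interval: Sequence[int] | None = None,
    n_opponents: int = 3,
    max_attempts: int = 1000,
) -> GameSet:
    """Generate a reproducible game set with exact validity control.

    Parameters
    ----------
    n_games
        Number of games.
    interval_counts
        How many games select interval 1, 2, 3 (sums to ``n_games``);
        default spreads them as evenly as possible.
    n_valid
        Exact number of games whose decoded interval must match the selected
        interval (``None`` leaves validity unconstrained).  Enforced by
        regenerating each game's trace until the decoder agrees/disagrees as
        required, up to ``max_attempts`` tries per game.
    valid_per_interval
        Optional exact split of the valid games across the three intervals.
    """
    from .decode import decode_game  # deferred: decode depends on our types

    config = config or GeneratorConfig()
    if interval_counts is None:
        base = n_games // 3
        interval_counts = [base + (1 if i < n_games % 3 else 0) for i in range(3)]
    interval_counts = list(interval_counts)
    if len(interval_counts) != 3 or sum(interval_counts) != n_games:
        raise ValueError("interval_counts must be three counts summing to n_games")
    if any(c < 0 for c in interval_counts):
        raise ValueError("interval counts must be nonnegative")

    want_flags: list[bool | None]
    if n_valid is None:
        if valid_per_interval is not None:
            raise ValueError("valid_per_interval requires n_valid")
        per_interval_valid = [None, None, None]
    else:
        if not 0 <= n_valid <= n_games:
            raise ValueError("n_valid must lie in [0, n_games]")
        if valid_per_interval is None:
            per_interval_valid = _allocate_valid(interval_counts, n_valid)
        else:
            per_interval_valid = list(valid_per_interval)
            if len(per_interval_valid) != 3 or sum(per_interval_valid) != n_valid:
                raise ValueError("valid_per_interval must be three counts summing to n_valid")
            if any(v > c for v, c in zip(per_interval_valid, interval_counts)):
                raise ValueError("valid_per_interval exceeds games available in an interval")

    plan: list[tuple[int, bool | None]] = []
    for interval, (count, v) in enumerate(zip(interval_counts, per_interval_valid), start=1):
        if v is None:
            plan += [(interval, None)] * count
        else:
            plan += [(interval, True)] * v + [(interval, False)] * (count - v)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(plan))
    plan = [plan[i] for i in order]

    games: list[OpponentGame] = []
    per_opponent = math.ceil(n_games / max(n_opponents, 1))
    for idx, (interval, want) in enumerate(plan):
        word_idx = rng.permutation(3)
        schedule = WordSchedule(config.onsets_s, tuple(CHOICES[j] for j in word_idx))
        game_id = f"g{idx + 1:03d}"
        opponent_id = f"opp{idx // per_opponent + 1}"
        game = None
        for _ in range(max_attempts):
            trace = generate_trace(schedule, interval, config, rng)
            candidate = OpponentGame(
                game_id=game_id,
                opponent_id=opponent_id,
                trace=trace,
                opponent_choice=schedule.order[interval - 1],
                selected_interval=interval,
            )
            if want is None:
                game = candidate
                break
            is_valid = decode_game(candidate).decoded_interval == interval
            if is_valid == want:
                game = candidate
                break
        if game is None:
            raise RuntimeError(
                f"rejection sampling failed for {game_id} after {max_attempts} "
                f"attempts (requested valid={want}); the generator config makes "
                "the requested validity practically unreachable"
            )
        games.append(game)

    provenance = {
        "seed": seed,
        "n_games": n_games,
        "interval_counts": list(interval_counts),
        "n_valid": n_valid,
        "valid_per_interval": None if n_valid is None else list(per_interval_valid),
        "config": config_to_dict(config),
    }
    return GameSet(games, provenance)


def reference_fixture(config: GeneratorConfig | None = None) -> GameSet:
    """The packaged deterministic 75-game reference set.

    Interval selection counts (28, 25, 22); exactly 45 decoder-valid games,
    split (16, 15, 14) across intervals so that selecting the first 10 valid
    games per interval always succeeds.
    """
    return generate_game_set(
        n_games=75,
        interval_counts=(28, 25, 22),
        n_valid=45,
        valid_per_interval=(16, 15, 14),
        config=config,
        seed=REFERENCE_SEED,
    )


@dataclass(frozen=True)
class TraceSummary:
    mean_diameter_mm: float
    mean_range_mm: float
    sd_range_mm: float


def summarize_traces(game_set: GameSet) -> TraceSummary:
    """Grand-mean diameter plus mean and SD (across games) of each game's
    max-minus-min diameter range."""
    if len(game_set) == 0:
        raise ValueError("empty game set")
    all_samples = np.concatenate([g.trace.samples_mm for g in game_set])
    ranges = np.array([g.trace.samples_mm.max() - g.trace.samples_mm.min() for g in game_set])
    sd = float(np.std(ranges, ddof=1)) if ranges.size > 1 else 0.0
    return TraceSummary(
        mean_diameter_mm=float(all_samples.mean()),
        mean_range_mm=float(ranges.mean()),
        sd_range_mm=sd,
    )


def config_to_dict(config: GeneratorConfig) -> dict:
    return {
        "sampling_rate_hz": config.sampling_rate_hz,
        "trace_duration_s": config.trace_duration_s,
        "baseline_mm": config.baseline_mm,
        "kernel": vars(config.kernel).copy(),
        "distractor": vars(config.distractor).copy(),
        "artifacts": vars(config.artifacts).copy(),
        "noise_sd_mm": config.noise_sd_mm,
        "clip_floor_mm": config.clip_floor_mm,
        "onsets_s": list(config.onsets_s),
    }


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    kernel = KernelConfig(**d.pop("kernel", {}))
    distractor = DistractorConfig(**d.pop("distractor", {}))
    artifacts = ArtifactConfig(**d.pop("artifacts", {}))
    if "onsets_s" in d:
        d["onsets_s"] = tuple(d["onsets_s"])
    return GeneratorConfig(kernel=kernel, distractor=distractor, artifacts=artifacts, **d)


def quiet_config(**overrides) -> GeneratorConfig:
    """Deterministic config: no noise, no distractors, fixed amplitude.
    Convenient for exact positional checks."""
    base = GeneratorConfig(
        noise_sd_mm=0.0,
        kernel=KernelConfig(amplitude_sd_mm=0.0),
        distractor=DistractorConfig(prob_per_interval=0.0),
    )
    return replace(base, **overrides) if overrides else base
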
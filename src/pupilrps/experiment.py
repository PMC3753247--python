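"""Orchestration of the five study conditions.

Conditions differ only in what a simulated player can do with the pupil
signal, abstracted by a follow probability:

* ``naive_eye`` / ``no_video`` -- decoder-independent, uniform random play
  (group performance indistinguishable from chance);
* ``informed_eye`` / ``reconstructed_pupil`` -- follower strategies (the
  pupil-only stimulus of the reconstructed condition is perceptually, not
  algorithmically, different);
* ``naive_100pct`` -- the curated 30-game subset in which the pupil marker
  is always correct, played in 4 independently randomized blocks; a
  block-ramped follow probability serves as a descriptive stand-in for
  within-session learning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import stats
from .decode import decode_game, validity
from .game import SessionResult, Strategy, counter, play_choices
from .synthetic_data import GameSet, OpponentGame, reference_fixture

__all__ = [
    "ConditionSpec",
    "ConditionResult",
    "StudyReport",
    "select_100pct_subset",
    "build_blocks",
    "run_condition",
    "replicate_study",
    "default_condition_specs",
]

CONDITION_NAMES = (
    "naive_eye",
    "informed_eye",
    "reconstructed_pupil",
    "no_video",
    "naive_100pct",
)


@dataclass(frozen=True)
class ConditionSpec:
    name: str
    strategy: Strategy
    n_players: int = 10
    n_blocks: int = 1
    use_100pct_subset: bool = False
    #: per-block follow probability overriding strategy.follow_prob (learning stand-in)
    follow_schedule: tuple[float, ...] | None = None
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CONDITION_NAMES:
            raise ValueError(f"unknown condition {self.name!r}")
        if self.n_players < 1 or self.n_blocks < 1:
            raise ValueError("n_players and n_blocks must be >= 1")
        if self.follow_schedule is not None and len(self.follow_schedule) != self.n_blocks:
            raise ValueError("follow_schedule must have one entry per block")
        if self.name in ("naive_eye", "no_video") and self.strategy.needs_decoder:
            raise ValueError(f"{self.name} must use a decoder-independent strategy")
        if self.name in ("informed_eye", "reconstructed_pupil") and not self.strategy.needs_decoder:
            raise ValueError(f"{self.name} must use a follower strategy")


def select_100pct_subset(game_set: GameSet) -> GameSet:
    """Select the 100%-validity subset: among the decoder-valid games, the
    first 10 in chronological order (ascending game_id) for each of the
    three response intervals -- 30 games in total, all valid."""
    by_interval: dict[int, list[OpponentGame]] = {1: [], 2: [], 3: []}
    for g in sorted(game_set, key=lambda g: g.game_id):
        if decode_game(g).decoded_interval == g.selected_interval:
            by_interval[g.selected_interval].append(g)
    chosen: list[OpponentGame] = []
    for interval in (1, 2, 3):
        pool = by_interval[interval]
        if len(pool) < 10:
            raise ValueError(
                f"interval {interval} has only {len(pool)} valid games; "
                "10 are required for the 100%-validity subset"
            )
        chosen += pool[:10]
    chosen.sort(key=lambda g: g.game_id)
    return GameSet(chosen, {"derived_from": "select_100pct_subset",
                            "parent": game_set.provenance})


def build_blocks(
    subset: GameSet | Sequence[OpponentGame],
    n_blocks: int,
    rng: np.random.Generator | int | None = None,
) -> list[OpponentGame]:
    """Concatenate ``n_blocks`` independent permutations of the subset."""
    games = list(subset)
    if not games:
        raise ValueError("empty subset")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    session: list[OpponentGame] = []
    for _ in range(n_blocks):
        session += [games[i] for i in rng.permutation(len(games))]
    return session


@dataclass
class ConditionResult:
    spec: ConditionSpec
    sessions: list[SessionResult]
    binomial: list[stats.BinomialTestResult]
    learning: list[stats.LearningCurveResult]
    group_ttest: stats.GroupTestResult

    @property
    def win_counts(self) -> list[int]:
        return [s.n_wins for s in self.sessions]

    @property
    def win_fractions(self) -> np.ndarray:
        return np.array([s.win_fraction for s in self.sessions])

    @property
    def group_mean_pct(self) -> float:
        return float(100.0 * self.win_fractions.mean())

    @property
    def n_significant(self) -> int:
        return sum(b.significant for b in self.binomial)

    def summary(self) -> dict:
        return {
            "condition": self.spec.name,
            "n_players": self.spec.n_players,
            "n_games_per_session": self.sessions[0].n_games,
            "group_mean_win_pct": self.group_mean_pct,
            "win_counts": self.win_counts,
            "binomial_p_values": [b.p_value for b in self.binomial],
            "n_significant_players": self.n_significant,
            "alpha_corrected": self.binomial[0].alpha_corrected,
            "group_t_vs_chance": {
                "t": self.group_ttest.t,
                "df": self.group_ttest.df,
                "p": self.group_ttest.p_value,
            },
            "first_significant_game": [
                lc.first_significant_game for lc in self.learning
            ],
        }


def _player_session(
    games: list[OpponentGame],
    decoded: dict[str, str],
    spec: ConditionSpec,
    rng: np.random.Generator,
) -> SessionResult:
    if spec.follow_schedule is None:
        order = [games[i] for i in rng.permutation(len(games))]
        dec = [decoded[g.game_id] for g in order] if spec.strategy.needs_decoder else None
        return play_choices(
            [g.opponent_choice for g in order],
            spec.strategy,
            decoded_choices=dec,
            rng=rng,
            game_ids=[g.game_id for g in order],
        )
    # block structure with per-block follow probability
    parts: list[SessionResult] = []
    for f in spec.follow_schedule:
        block = [games[i] for i in rng.permutation(len(games))]
        strat = Strategy.follower(f) if f > 0 else Strategy.uniform_random()
        dec = [decoded[g.game_id] for g in block] if strat.needs_decoder else None
        parts.append(
            play_choices(
                [g.opponent_choice for g in block],
                strat,
                decoded_choices=dec,
                rng=rng,
                game_ids=[g.game_id for g in block],
            )
        )
    return SessionResult(
        game_ids=sum((p.game_ids for p in parts), []),
        player_choices=np.concatenate([p.player_choices for p in parts]),
        opponent_choices=np.concatenate([p.opponent_choices for p in parts]),
        outcomes=np.concatenate([p.outcomes for p in parts]),
    )


def run_condition(spec: ConditionSpec, game_set: GameSet) -> ConditionResult:
    """Simulate all players of one condition and run the per-player and
    group statistics."""
    base = select_100pct_subset(game_set) if spec.use_100pct_subset else game_set
    games = list(base)
    decoded = {g.game_id: decode_game(g).decoded_choice for g in games}

    sessions = []
    for p in range(spec.n_players):
        rng = np.random.default_rng([spec.seed, p])
        sessions.append(_player_session(games, decoded, spec, rng))

    binomial = [
        stats.binomial_tail(s.n_games, s.n_wins, alpha=spec.alpha,
                            n_comparisons=spec.n_players)
        for s in sessions
    ]
    learning = [
        stats.learning_curve(s, alpha=spec.alpha, m_comparisons=spec.n_players)
        for s in sessions
    ]
    group = stats.t_tests([s.win_fraction for s in sessions], kind="one_sample")
    return ConditionResult(spec, sessions, binomial, learning, group)


def default_condition_specs(seed: int = 0, n_players: int = 10) -> list[ConditionSpec]:
    """The five conditions with their default strategies.

    Follower conditions use follow probability 1 (the 60%-validity
    performance ceiling); chance conditions use uniform random play; the
    100%-validity condition ramps the follow probability over its four
    blocks (0, 1/3, 2/3, 1) as a descriptive learning stand-in.
    """
    return [
        ConditionSpec("naive_eye", Strategy.uniform_random(),
                      n_players=n_players, seed=seed + 1),
        ConditionSpec("informed_eye", Strategy.always_follow(),
                      n_players=n_players, seed=seed + 2),
        ConditionSpec("reconstructed_pupil", Strategy.always_follow(),
                      n_players=n_players, seed=seed + 3),
        ConditionSpec("no_video", Strategy.uniform_random(),
                      n_players=n_players, seed=seed + 4),
        ConditionSpec("naive_100pct", Strategy.uniform_random(),
                      n_players=n_players, n_blocks=4, use_100pct_subset=True,
                      follow_schedule=(0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0),
                      seed=seed + 5),
    ]


@dataclass
class StudyReport:
    conditions: dict[str, ConditionResult]
    fixture_validity_pct: float
    seed: int
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "fixture_validity_pct": self.fixture_validity_pct,
            "conditions": {name: r.summary() for name, r in self.conditions.items()},
            "provenance": self.provenance,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def replicate_study(
    seed: int = 0,
    game_set: GameSet | None = None,
    n_players: int = 10,
) -> StudyReport:
    """Run all five conditions against the reference fixture (or a supplied
    game set) and assemble the group/individual result tables."""
    game_set = game_set if game_set is not None else reference_fixture()
    v = validity(game_set)
    conditions = {}
    for spec in default_condition_specs(seed=seed, n_players=n_players):
        conditions[spec.name] = run_condition(spec, game_set)
    return StudyReport(
        conditions=conditions,
        fixture_validity_pct=v.percent,
        seed=seed,
        provenance={"game_set": game_set.provenance},
    )
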
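"""Rock-paper-scissors outcome logic and player-strategy simulation.

Players face a sequence of pre-recorded opponent games.  A player either
ignores the physiological decoder (uniform random choice), always plays the
counter-move to the decoded choice, or follows the decoder with some
probability (the "follow probability") and plays uniformly at random
otherwise.  Because a wrong decode can at best draw against the player's
counter-move, the win rate under a follower strategy has the closed form
``f*v + (1-f)/3`` for follow probability ``f`` and decoder validity ``v``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Callable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import GameSet, OpponentGame

__all__ = [
    "Choice",
    "Outcome",
    "Strategy",
    "SessionResult",
    "outcome",
    "counter",
    "play_choices",
    "play_session",
    "expected_win_rate",
]


class Choice(str, Enum):
    """One of the three moves. Paper beats rock, rock beats scissors,
    scissors beats paper."""

    ROCK = "rock"
    PAPER = "paper"
    SCISSORS = "scissors"


#: canonical ordering used for integer coding
CHOICES: tuple[Choice, Choice, Choice] = (Choice.ROCK, Choice.PAPER, Choice.SCISSORS)
_CODE = {c: i for i, c in enumerate(CHOICES)}


class Outcome(str, Enum):
    WIN = "win"
    DRAW = "draw"
    LOSS = "loss"


def _to_code(c: Choice | str | int) -> int:
    if isinstance(c, (int, np.integer)):
        if not 0 <= int(c) <= 2:
            raise ValueError(f"choice code out of range: {c}")
        return int(c)
    return _CODE[Choice(c)]


def outcome(player: Choice | str, opponent: Choice | str) -> Outcome:
    """Outcome for the player. The beats-relation is a 3-cycle:
    ``(player - opponent) mod 3 == 1`` is a win, equality a draw."""
    d = (_to_code(player) - _to_code(opponent)) % 3
    if d == 0:
        return Outcome.DRAW
    return Outcome.WIN if d == 1 else Outcome.LOSS


def counter(c: Choice | str) -> Choice:
    """The move that beats ``c`` (e.g. paper beats rock)."""
    return CHOICES[(_to_code(c) + 1) % 3]


@dataclass(frozen=True)
class Strategy:
    """Player policy parameterized by a single follow probability.

    ``follow_prob = 0`` ignores the decoder entirely (uniform random);
    ``follow_prob = 1`` always plays the counter to the decoded choice.
    """

    kind: str = "probabilistic_follower"
    follow_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform_random", "always_follow", "probabilistic_follower"):
            raise ValueError(f"unknown strategy kind: {self.kind!r}")
        if not 0.0 <= self.follow_prob <= 1.0:
            raise ValueError("follow_prob must lie in [0, 1]")
        if self.kind == "uniform_random" and self.follow_prob != 0.0:
            raise ValueError("uniform_random implies follow_prob = 0")
        if self.kind == "always_follow" and self.follow_prob != 1.0:
            raise ValueError("always_follow implies follow_prob = 1")

    @classmethod
    def uniform_random(cls) -> "Strategy":
        return cls(kind="uniform_random", follow_prob=0.0)

    @classmethod
    def always_follow(cls) -> "Strategy":
        return cls(kind="always_follow", follow_prob=1.0)

    @classmethod
    def follower(cls, follow_prob: float) -> "Strategy":
        return cls(kind="probabilistic_follower", follow_prob=follow_prob)

    @property
    def needs_decoder(self) -> bool:
        return self.follow_prob > 0.0


@dataclass
class SessionResult:
    """Ordered per-game record of one simulated player session."""

    game_ids: list[str]
    player_choices: np.ndarray  # int codes, 0=rock 1=paper 2=scissors
    opponent_choices: np.ndarray
    outcomes: np.ndarray  # +1 win, 0 draw, -1 loss
    rewards: np.ndarray = field(default=None)  # monetary units per game

    def __post_init__(self) -> None:
        n = len(self.game_ids)
        for arr in (self.player_choices, self.opponent_choices, self.outcomes):
            if len(arr) != n:
                raise ValueError("session arrays must share the session length")
        if self.rewards is None:
            self.rewards = (self.outcomes == 1).astype(float)  # win=+1, else 0

    @property
    def n_games(self) -> int:
        return len(self.game_ids)

    @property
    def cumulative_wins(self) -> np.ndarray:
        return np.cumsum(self.outcomes == 1)

    @property
    def n_wins(self) -> int:
        return int(np.sum(self.outcomes == 1))

    @property
    def win_fraction(self) -> float:
        return self.n_wins / self.n_games

    def to_dataframe(self) -> pd.DataFrame:
        labels = np.array([c.value for c in CHOICES])
        out = np.where(self.outcomes == 1, "win", np.where(self.outcomes == 0, "draw", "loss"))
        return pd.DataFrame(
            {
                "game_index": np.arange(1, self.n_games + 1),
                "game_id": self.game_ids,
                "player_choice": labels[self.player_choices],
                "opponent_choice": labels[self.opponent_choices],
                "outcome": out,
                "cumulative_wins": self.cumulative_wins,
            }
        )


def play_choices(
    opponent_choices: Sequence[Choice | str | int],
    strategy: Strategy,
    decoded_choices: Sequence[Choice | str | int] | None = None,
    rng: np.random.Generator | int | None = None,
    game_ids: Sequence[str] | None = None,
) -> SessionResult:
    """Play a session given opponent (and optionally decoded) choices.

    Vectorized core used by :func:`play_session`; also convenient when the
    pupil traces themselves are not needed (e.g. chance-level controls).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    opp = np.array([_to_code(c) for c in opponent_choices], dtype=np.int64)
    n = len(opp)
    if n == 0:
        raise ValueError("empty session")
    if strategy.needs_decoder:
        if decoded_choices is None:
            raise ValueError(f"strategy {strategy.kind!r} requires decoded choices")
        dec = np.array([_to_code(c) for c in decoded_choices], dtype=np.int64)
        if len(dec) != n:
            raise ValueError("decoded_choices length mismatch")
        follow = rng.random(n) < strategy.follow_prob
        random_play = rng.integers(0, 3, size=n)
        player = np.where(follow, (dec + 1) % 3, random_play)
    else:
        player = rng.integers(0, 3, size=n)
    d = (player - opp) % 3
    outcomes = np.where(d == 0, 0, np.where(d == 1, 1, -1)).astype(np.int64)
    if game_ids is None:
        game_ids = [f"game{i + 1:04d}" for i in range(n)]
    return SessionResult(list(game_ids), player, opp, outcomes)


def play_session(
    games: "GameSet | Sequence[OpponentGame]",
    strategy: Strategy,
    decoder: Callable | None = None,
    rng: np.random.Generator | int | None = None,
) -> SessionResult:
    """Simulate one player session against recorded opponent games, in the
    order given (randomize upstream).

    ``decoder`` maps an opponent game to a decode result with a
    ``decoded_choice`` attribute; defaults to the pupil-peak decoder.
    """
    game_list = list(games)
    if not game_list:
        raise ValueError("empty game set")
    decoded = None
    if strategy.needs_decoder:
        if decoder is None:
            from .decode import decode_game as decoder  # noqa: PLC0415
        decoded = [decoder(g).decoded_choice for g in game_list]
    return play_choices(
        [g.opponent_choice for g in game_list],
        strategy,
        decoded_choices=decoded,
        rng=rng,
        game_ids=[g.game_id for g in game_list],
    )


def expected_win_rate(follow_prob: float, validity: float) -> float:
    """Closed-form win rate of a probabilistic follower.

    Following the decoder wins exactly when the decode is correct (a wrong
    decode draws or loses against the player's counter-move, never wins), so
    the rate is ``f*v + (1-f)/3``.
    """
    if not 0.0 <= follow_prob <= 1.0:
        raise ValueError("follow_prob must lie in [0, 1]")
    if not 0.0 <= validity <= 1.0:
        raise ValueError("validity must lie in [0, 1]")
    return follow_prob * validity + (1.0 - follow_prob) / 3.0
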
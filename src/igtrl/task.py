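"""Modified Iowa Gambling Task environment.

The task presents four decks of cards (A, B, C, D). Every card pays a win;
some cards also carry a loss. Decks A and B pay large immediate wins
(average $100 in the first block) but carry larger losses, so they lose
money in the long run; decks C and D pay small wins (average $50) and win
money in the long run. Unlike the original fixed-payoff task, win amounts
vary around their deck average and all amounts escalate across each block
of ten cards. Each deck holds 60 cards; once a deck has been chosen 60
times it is depleted and the task degenerates to a three-deck choice, so
trials from that point on are excluded from model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DECKS = ("A", "B", "C", "D")
DECK_INDEX = {d: i for i, d in enumerate(DECKS)}
CARDS_PER_DECK = 60
BLOCK_SIZE = 10
DEFAULT_ESCALATION_RATE = 0.1

# Base (block-1) win sequences: mean exactly 100 for A/B, 50 for C/D.
_BASE_WINS = {
    "A": (110, 90, 100, 120, 80, 100, 110, 90, 100, 100),
    "B": (100, 110, 90, 120, 80, 100, 90, 110, 105, 95),
    "C": (55, 45, 50, 60, 40, 50, 55, 45, 50, 50),
    "D": (50, 55, 45, 60, 40, 50, 45, 55, 52, 48),
}
# Base losses per within-block position (1-based positions as keys).
# A: five losses per ten cards summing to -1250; B: one -1250 loss;
# C: five losses summing to -250; D: one -250 loss.
_BASE_LOSSES = {
    "A": {3: -150, 5: -200, 7: -250, 9: -300, 10: -350},
    "B": {9: -1250},
    "C": {3: -25, 5: -75, 7: -50, 9: -50, 10: -50},
    "D": {10: -250},
}

DISADVANTAGEOUS = ("A", "B")
ADVANTAGEOUS = ("C", "D")


@dataclass(frozen=True)
class Outcome:
    """A single card's payoff: a win >= 0 and a loss <= 0 (dollars)."""

    win: int
    loss: int

    def __post_init__(self) -> None:
        if self.win < 0:
            raise ValueError(f"win must be >= 0, got {self.win}")
        if self.loss > 0:
            raise ValueError(f"loss must be <= 0, got {self.loss}")

    @property
    def net(self) -> int:
        return self.win + self.loss


def net_outcome(outcome: Outcome) -> int:
    """Net dollar outcome win + loss — the scalar fed to the utility functions."""
    return outcome.win + outcome.loss


@dataclass(frozen=True)
class PayoffSchedule:
    """Per-deck ordered card lists (60 cards each) with block escalation.

    ``cards[deck]`` is the ordered tuple of :class:`Outcome` drawn when the
    deck is chosen for the 1st, 2nd, ... time.
    """

    cards: dict[str, tuple[Outcome, ...]]
    escalation_rate: float

    def __post_init__(self) -> None:
        for deck in DECKS:
            if deck not in self.cards:
                raise ValueError(f"schedule missing deck {deck!r}")
            if len(self.cards[deck]) != CARDS_PER_DECK:
                raise ValueError(
                    f"deck {deck} has {len(self.cards[deck])} cards, expected {CARDS_PER_DECK}"
                )

    def outcome(self, deck: str, draw_index: int) -> Outcome:
        """Outcome of the ``draw_index``-th (0-based) pick from ``deck``."""
        return self.cards[deck][draw_index]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"deck": d, "card_index": i + 1, "win": c.win, "loss": c.loss}
            for d in DECKS
            for i, c in enumerate(self.cards[d])
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, escalation_rate: float = float("nan")) -> "PayoffSchedule":
        cards = {}
        for deck, grp in df.groupby("deck"):
            grp = grp.sort_values("card_index")
            cards[str(deck)] = tuple(
                Outcome(int(w), int(l)) for w, l in zip(grp["win"], grp["loss"])
            )
        return cls(cards=cards, escalation_rate=escalation_rate)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def build_payoff_schedule(escalation_rate: float = DEFAULT_ESCALATION_RATE) -> PayoffSchedule:
    """Build the deterministic modified-IGT payoff schedule.

    Block ``k`` (k = 1..6, ten cards each) amounts are the base block-1
    amounts multiplied by ``1 + escalation_rate * (k - 1)`` and rounded to
    whole dollars; escalation applies to wins and losses alike.

    Parameters
    ----------
    escalation_rate
        Fractional increase per 10-card block; must be >= 0.
    """
    if escalation_rate < 0:
        raise ValueError(f"escalation_rate must be >= 0, got {escalation_rate}")
    cards: dict[str, tuple[Outcome, ...]] = {}
    n_blocks = CARDS_PER_DECK // BLOCK_SIZE
    for deck in DECKS:
        deck_cards = []
        for block in range(n_blocks):
            mult = 1.0 + escalation_rate * block
            for pos in range(BLOCK_SIZE):
                win = _round_half_up(_BASE_WINS[deck][pos] * mult)
                base_loss = _BASE_LOSSES[deck].get(pos + 1, 0)
                loss = -_round_half_up(-base_loss * mult)
                deck_cards.append(Outcome(win, loss))
        cards[deck] = tuple(deck_cards)
    return PayoffSchedule(cards=cards, escalation_rate=escalation_rate)


@dataclass(frozen=True)
class Trial:
    subject_id: str
    trial_index: int  # 1-based
    deck: str
    outcome: Outcome

    def __post_init__(self) -> None:
        if self.deck not in DECK_INDEX:
            raise ValueError(f"unknown deck label {self.deck!r}")


@dataclass
class Session:
    """One subject's ordered trial sequence plus its modeling horizon.

    ``modeling_horizon`` is the number of leading trials used for
    likelihood evaluation; trials past it (those after a deck was
    depleted) are kept for behavioral metrics but excluded from fitting.
    """

    subject_id: str
    group: str
    trials: list[Trial] = field(default_factory=list)
    modeling_horizon: int | None = None
    age: float | None = None

    def __post_init__(self) -> None:
        idx = [t.trial_index for t in self.trials]
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError(
                f"subject {self.subject_id}: trial indices must be contiguous from 1"
            )
        counts = self.deck_counts()
        over = [d for d, c in zip(DECKS, counts) if c > CARDS_PER_DECK]
        if over:
            raise ValueError(
                f"subject {self.subject_id}: deck(s) {over} chosen more than {CARDS_PER_DECK} times"
            )
        if self.modeling_horizon is None:
            self.modeling_horizon = truncate_at_depletion(self)

    def __len__(self) -> int:
        return len(self.trials)

    def deck_counts(self) -> np.ndarray:
        counts = np.zeros(4, dtype=int)
        for t in self.trials:
            counts[DECK_INDEX[t.deck]] += 1
        return counts

    # Compact array views used by the likelihood code.
    def choice_array(self) -> np.ndarray:
        return np.array([DECK_INDEX[t.deck] for t in self.trials], dtype=np.int64)

    def win_array(self) -> np.ndarray:
        return np.array([t.outcome.win for t in self.trials], dtype=np.float64)

    def loss_array(self) -> np.ndarray:
        return np.array([t.outcome.loss for t in self.trials], dtype=np.float64)


def truncate_at_depletion(session: Session) -> int:
    """Index of the trial on which some deck receives its 60th pick.

    Returns the 1-based trial index at which the first deck is depleted
    (that trial itself is retained), or the session length if no deck is
    ever chosen 60 times. An empty session yields 0.
    """
    counts = np.zeros(4, dtype=int)
    for t in session.trials:
        counts[DECK_INDEX[t.deck]] += 1
        if counts[DECK_INDEX[t.deck]] == CARDS_PER_DECK:
            return t.trial_index
    return len(session.trials)
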
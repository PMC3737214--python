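"""Standard behavioral IGT indices.

The net score of a trial block is the number of advantageous picks (decks
C, D) minus disadvantageous picks (decks A, B); negative values indicate
impaired performance. Deck proportions are overall choice shares per deck.
Behavioral metrics use ALL trials of a session — the depletion-truncation
rule applies only to model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortDataset
from .task import ADVANTAGEOUS, DECK_INDEX, DECKS, Session

DEFAULT_BLOCK_SIZE = 20


@dataclass(frozen=True)
class NetScoreProfile:
    block_scores: tuple[int, ...]
    block_size: int
    total: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.block_scores))


@dataclass(frozen=True)
class DeckProportions:
    p: tuple[float, float, float, float]  # order A, B, C, D

    def as_dict(self) -> dict[str, float]:
        return dict(zip(DECKS, self.p))


def net_scores(session: Session, block_size: int = DEFAULT_BLOCK_SIZE) -> NetScoreProfile:
    """Per-block net scores (C+D picks minus A+B picks) over all trials.

    A final partial block, if any, is reported as its own (shorter) block.
    """
    if len(session) == 0:
        raise ValueError("empty session")
    adv = np.array([1 if t.deck in ADVANTAGEOUS else -1 for t in session.trials])
    scores = [int(adv[i : i + block_size].sum()) for i in range(0, len(adv), block_size)]
    return NetScoreProfile(
        block_scores=tuple(scores), block_size=block_size, total=int(adv.sum())
    )


def deck_proportions(data: Session | CohortDataset) -> DeckProportions:
    """Overall proportion of choices from each deck (pooled over subjects
    when given a cohort)."""
    sessions = data.sessions if isinstance(data, CohortDataset) else [data]
    counts = np.zeros(4)
    for s in sessions:
        for t in s.trials:
            counts[DECK_INDEX[t.deck]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no trials")
    return DeckProportions(p=tuple(counts / total))


def group_behavior_summary(
    dataset: CohortDataset, block_size: int = DEFAULT_BLOCK_SIZE
) -> pd.DataFrame:
    """Per-group mean (SD) net score per block and overall, and mean deck
    proportions; one row per group."""
    if not dataset.sessions:
        raise ValueError("empty cohort")
    rows = []
    for g in dataset.groups:
        sessions = dataset.by_group(g)
        if not sessions:
            raise ValueError(f"group {g!r} has no subjects")
        profiles = [net_scores(s, block_size) for s in sessions]
        n_blocks = min(len(p.block_scores) for p in profiles)
        row: dict = {"group": g, "n": len(sessions)}
        for b in range(n_blocks):
            vals = np.array([p.block_scores[b] for p in profiles], dtype=float)
            row[f"net_block{b + 1}_mean"] = vals.mean()
            row[f"net_block{b + 1}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        means = np.array([p.mean for p in profiles])
        totals = np.array([p.total for p in profiles], dtype=float)
        row["net_mean"] = means.mean()
        row["net_mean_sd"] = means.std(ddof=1) if len(means) > 1 else 0.0
        row["net_total_mean"] = totals.mean()
        row["net_total_sd"] = totals.std(ddof=1) if len(totals) > 1 else 0.0
        props = np.array([deck_proportions(s).p for s in sessions])
        for j, d in enumerate(DECKS):
            row[f"prop_{d}"] = props[:, j].mean()
        rows.append(row)
    return pd.DataFrame(rows)
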
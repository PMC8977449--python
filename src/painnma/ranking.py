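"""Rank probabilities, SUCRA, mean ranks and the multi-outcome heat map."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .nma_engine import NMAPosterior

LOWER_BETTER = "lower_better"
HIGHER_BETTER = "higher_better"

#: Per-outcome orientation: pain and mental/sleep scores are SMDs where
#: lower means more relief; event outcomes are ORs where lower means fewer
#: (serious) adverse events.  Lower is better for all five.
OUTCOME_DIRECTIONS = {
    "pain4w": LOWER_BETTER,
    "adverse_events": LOWER_BETTER,
    "pain8w": LOWER_BETTER,
    "mental_sleep": LOWER_BETTER,
    "serious_ae": LOWER_BETTER,
}


@dataclass(frozen=True)
class RankingResult:
    outcome_id: str
    direction: str
    treatments: tuple[str, ...]
    rank_probs: np.ndarray  # (T, T): P(treatment t has rank r); rank 1 best
    sucra: np.ndarray  # (T,)
    mean_rank: np.ndarray  # (T,)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "treatment": self.treatments,
                "outcome": self.outcome_id,
                "sucra": self.sucra,
                "mean_rank": self.mean_rank,
            }
        )


def rank_probs(
    draws: np.ndarray | NMAPosterior, direction: str = LOWER_BETTER
) -> np.ndarray:
    """T x T rank-probability matrix from posterior effect draws.

    Per draw, treatments are ranked by oriented effect (rank 1 = best).
    Ties within a draw share averaged ranks, with the fractional weight
    split between the two adjacent integer ranks so the matrix stays
    doubly stochastic.
    """
    if isinstance(draws, NMAPosterior):
        draws = draws.d_pooled()
    x = np.asarray(draws, dtype=float)
    if direction == HIGHER_BETTER:
        x = -x
    elif direction != LOWER_BETTER:
        raise ValueError(f"unknown direction {direction!r}")
    n, T = x.shape
    ranks = rankdata(x, axis=1, method="average")  # 1..T, possibly fractional
    lower = np.floor(ranks).astype(int)
    frac = ranks - lower
    probs = np.zeros((T, T))
    cols = np.tile(np.arange(T), n)
    lo = np.clip(lower.ravel() - 1, 0, T - 1)
    np.add.at(probs, (cols, lo), 1.0 - frac.ravel())
    hi_mask = frac.ravel() > 0
    hi = np.clip(lower.ravel()[hi_mask], 0, T - 1)
    np.add.at(probs, (cols[hi_mask], hi), frac.ravel()[hi_mask])
    return probs / n


def sucra(rank_prob_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(SUCRA, mean rank) per treatment from a rank-probability matrix.

    SUCRA = sum over r < T of the cumulative rank probability, divided by
    T - 1; equivalently (T - mean_rank) / (T - 1).
    """
    p = np.asarray(rank_prob_matrix, dtype=float)
    T = p.shape[0]
    cum = np.cumsum(p, axis=1)
    s = cum[:, : T - 1].sum(axis=1) / (T - 1) if T > 1 else np.ones(p.shape[0])
    mean_rank = p @ np.arange(1, T + 1)
    return s, mean_rank


def rank_treatments(
    post: NMAPosterior, direction: str = LOWER_BETTER, outcome_id: str | None = None
) -> RankingResult:
    probs = rank_probs(post, direction)
    s, mr = sucra(probs)
    return RankingResult(
        outcome_id=outcome_id or post.outcome_id,
        direction=direction,
        treatments=tuple(post.treatment_ids),
        rank_probs=probs,
        sucra=s,
        mean_rank=mr,
    )


def cumulative_curves(result: RankingResult) -> pd.DataFrame:
    """Cumulative ranking curve points (treatment, rank, cum_prob)."""
    cum = np.cumsum(result.rank_probs, axis=1)
    T = len(result.treatments)
    rows = [
        {"treatment": t, "rank": r + 1, "cum_prob": float(cum[i, r])}
        for i, t in enumerate(result.treatments)
        for r in range(T)
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class HeatmapMatrix:
    """Outcomes x treatments grid of (SUCRA, mean rank), NA never imputed."""

    outcomes: tuple[str, ...]
    treatments: tuple[str, ...]  # ordered by overall mean SUCRA, best first
    sucra: pd.DataFrame  # index=outcomes, columns=treatments, NaN = missing
    mean_rank: pd.DataFrame
    overall: pd.Series  # mean SUCRA over available outcomes per treatment

    def to_frame(self) -> pd.DataFrame:
        df = self.sucra.copy()
        df.index.name = "outcome"
        return df


def heatmap(results: Sequence[RankingResult] | Mapping[str, RankingResult]) -> HeatmapMatrix:
    """Assemble per-outcome rankings into the cross-outcome heat-map grid.

    Treatments absent from an outcome's network stay NaN for that outcome;
    the overall ordering averages SUCRA over the outcomes where each
    treatment appears.
    """
    if isinstance(results, Mapping):
        results = list(results.values())
    if not results:
        raise ValueError("heatmap needs at least one ranking result")
    outcomes = [r.outcome_id for r in results]
    treatments = sorted({t for r in results for t in r.treatments})
    s = pd.DataFrame(np.nan, index=outcomes, columns=treatments)
    m = pd.DataFrame(np.nan, index=outcomes, columns=treatments)
    for r in results:
        for i, t in enumerate(r.treatments):
            s.loc[r.outcome_id, t] = r.sucra[i]
            m.loc[r.outcome_id, t] = r.mean_rank[i]
    overall = s.mean(axis=0, skipna=True).sort_values(ascending=False)
    order = list(overall.index)
    return HeatmapMatrix(
        outcomes=tuple(outcomes),
        treatments=tuple(order),
        sucra=s[order],
        mean_rank=m[order],
        overall=overall,
    )
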
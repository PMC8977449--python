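"""Frequentist random-effects pairwise meta-analysis (DerSimonian-Laird).

Serves two purposes: the classic per-comparison pooled rows shown next to
network estimates, and a closed-form, deterministic oracle against which
the Bayesian engine is validated.  Also provides comparison-adjusted funnel
data for small-study/publication-bias inspection.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effect_sizes import EffectEstimate, contrasts
from .exceptions import ValidationError
from .trial_data import NetworkDataset

Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class PooledEffect:
    treat_a: str
    treat_b: str
    measure: str
    k: int
    value: float
    se: float
    ci95: tuple[float, float]
    tau2: float
    q: float
    i2: float

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["ci95_low"], d["ci95_high"] = d.pop("ci95")
        return d


@dataclass(frozen=True)
class FunnelPoint:
    study_id: str
    comparison: tuple[str, str]
    centered_effect: float
    se: float


def dl_pool(effects: Sequence[EffectEstimate]) -> PooledEffect:
    """DerSimonian-Laird random-effects pool of one comparison.

    tau^2 = max(0, (Q - df)/C) with C = sum(w) - sum(w^2)/sum(w) and
    w = 1/se^2; the pooled value uses w* = 1/(se^2 + tau^2) and a
    normal-based 95% CI.  With a single study the pool is that study's
    estimate with tau^2 = Q = 0.
    """
    if not effects:
        raise ValidationError("dl_pool needs at least one effect")
    pairs = {(e.treat_a, e.treat_b) for e in effects}
    measures = {e.measure for e in effects}
    if len(pairs) > 1 or len(measures) > 1:
        raise ValidationError(
            f"dl_pool requires one comparison and measure, got {sorted(pairs)} / {sorted(measures)}"
        )
    y = np.array([e.value for e in effects])
    v = np.array([e.se**2 for e in effects])
    w = 1.0 / v
    yfix = float(np.sum(w * y) / np.sum(w))
    df = len(y) - 1
    q = float(np.sum(w * (y - yfix) ** 2)) if df > 0 else 0.0
    if df > 0:
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - df) / c)
    else:
        tau2 = 0.0
    wstar = 1.0 / (v + tau2)
    value = float(np.sum(wstar * y) / np.sum(wstar))
    se = float(math.sqrt(1.0 / np.sum(wstar)))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    (a, b), (measure,) = pairs.pop(), measures
    return PooledEffect(
        treat_a=a,
        treat_b=b,
        measure=measure,
        k=len(y),
        value=value,
        se=se,
        ci95=(value - Z975 * se, value + Z975 * se),
        tau2=tau2,
        q=q,
        i2=i2,
    )


def _collect_by_comparison(
    ds: NetworkDataset, outcome_id: str
) -> dict[tuple[str, str], list[EffectEstimate]]:
    """Study contrasts grouped by unordered comparison, consistently oriented.

    Contrasts are re-oriented so treat_a < treat_b alphabetically, making
    the grouping independent of which arm anchored each study.
    """
    groups: dict[tuple[str, str], list[EffectEstimate]] = defaultdict(list)
    for s in ds.studies:
        for e in contrasts(s, outcome_id, reference=ds.reference):
            if e.treat_a > e.treat_b:
                e = e.swapped()
            groups[(e.treat_a, e.treat_b)].append(e)
    return dict(groups)


def pool_all(ds: NetworkDataset, outcome_id: str) -> list[PooledEffect]:
    """DL pool for every directly compared pair reporting the outcome."""
    return [
        dl_pool(effs)
        for _, effs in sorted(_collect_by_comparison(ds, outcome_id).items())
    ]


def forest_frame(ds: NetworkDataset, outcome_id: str) -> pd.DataFrame:
    """Pairwise forest-plot table, one row per direct comparison."""
    rows = [p.to_dict() for p in pool_all(ds, outcome_id)]
    return pd.DataFrame(
        rows,
        columns=[
            "treat_a",
            "treat_b",
            "measure",
            "k",
            "value",
            "se",
            "ci95_low",
            "ci95_high",
            "tau2",
            "q",
            "i2",
        ],
    )


def funnel(ds: NetworkDataset, outcome_id: str) -> list[FunnelPoint]:
    """Comparison-adjusted funnel data.

    Each study effect is centered on its own comparison's DL pooled value;
    single-study comparisons therefore self-center to exactly zero and are
    uninformative for asymmetry.
    """
    points = []
    for comp, effs in sorted(_collect_by_comparison(ds, outcome_id).items()):
        pooled = dl_pool(effs)
        for e in effs:
            points.append(
                FunnelPoint(
                    study_id=e.study_id,
                    comparison=comp,
                    centered_effect=e.value - pooled.value,
                    se=e.se,
                )
            )
    return points


def egger_test(points: Sequence[FunnelPoint]) -> dict:
    """Egger-style asymmetry regression of centered effect on se.

    Returns the slope, its 95% CI and p-value from an unweighted OLS fit.
    Self-centered points from single-study comparisons are excluded; with
    fewer than three informative points the result is flagged degenerate.
    """
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for p in points:
        counts[p.comparison] += 1
    informative = [p for p in points if counts[p.comparison] > 1]
    if len(informative) < 3:
        return {"slope": float("nan"), "ci95": (float("nan"), float("nan")),
                "p": float("nan"), "n": len(informative), "degenerate": True}
    x = np.array([p.se for p in informative])
    y = np.array([p.centered_effect for p in informative])
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, len(x) - 2)
    return {
        "slope": float(res.slope),
        "ci95": (
            float(res.slope - tcrit * res.stderr),
            float(res.slope + tcrit * res.stderr),
        ),
        "p": float(res.pvalue),
        "n": len(informative),
        "degenerate": False,
    }


def funnel_frame(points: Sequence[FunnelPoint]) -> pd.DataFrame:
    rows = [
        {
            "study_id": p.study_id,
            "comparison": f"{p.comparison[0]} vs {p.comparison[1]}",
            "centered_effect": p.centered_effect,
            "se": p.se,
        }
        for p in points
    ]
    return pd.DataFrame(rows, columns=["study_id", "comparison", "centered_effect", "se"])
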
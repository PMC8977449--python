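"""Trial-network simulator with known ground truth.

Generates networks of two- and three-arm randomized trials under exactly
the statistical structure the analysis assumes: trial-specific true
effects drawn around differences of basic parameters with between-trial
SD tau (0.5 correlation within multi-arm trials), participant-level
normal change scores or binomial event counts per arm, and an optional
inconsistency offset applied to one designated edge's direct evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .exceptions import ValidationError
from .trial_data import (
    ArmOutcome,
    NetworkDataset,
    OutcomeRecord,
    Study,
    Treatment,
)

REFERENCE = "placebo"


def _expit(x):
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class Scenario:
    """Ground-truth description of a synthetic trial network."""

    n_treatments: int = 3
    geometry: str = "star"  # star | star_plus_edges | triangle | complete
    trials_per_edge: int = 1
    arm_size: tuple[int, int] = (20, 60)  # inclusive uniform range
    d: Mapping[str, float] = field(default_factory=dict)  # vs reference
    tau: float = 0.0
    outcome_kind: str = "continuous"  # or "dichotomous"
    baseline_mean: float = -0.5  # control-arm mean change (continuous)
    baseline_sd: float = 1.0
    baseline_risk: float = 0.3  # control-arm event risk (dichotomous)
    omega: float = 0.0  # inconsistency offset on the designated edge
    omega_edge: tuple[str, str] | None = None  # effect of a vs b shifted by omega
    extra_edges: tuple[tuple[str, str], ...] = ()  # for star_plus_edges
    trials: tuple[tuple[str, ...], ...] | None = None  # explicit design override
    outcome_id: str = "pain4w"
    followup_weeks: float = 4.0
    seed: int = 0

    @property
    def treatment_ids(self) -> tuple[str, ...]:
        k = self.n_treatments - 1
        return (REFERENCE,) + tuple(f"drug{i + 1:02d}" for i in range(k))

    def effect(self, treatment: str) -> float:
        if treatment == REFERENCE:
            return 0.0
        return float(self.d.get(treatment, 0.0))

    def trial_designs(self) -> tuple[tuple[str, ...], ...]:
        """The list of trials, each a tuple of treatment ids."""
        if self.trials is not None:
            return tuple(tuple(t) for t in self.trials)
        ids = self.treatment_ids
        ref, others = ids[0], ids[1:]
        if self.geometry == "star":
            edges = [(ref, t) for t in others]
        elif self.geometry == "star_plus_edges":
            edges = [(ref, t) for t in others] + list(self.extra_edges)
        elif self.geometry == "triangle":
            if self.n_treatments != 3:
                raise ValidationError(["triangle geometry needs exactly 3 treatments"])
            edges = [(ref, others[0]), (ref, others[1]), (others[0], others[1])]
        elif self.geometry == "complete":
            edges = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]
        else:
            raise ValidationError([f"unknown geometry {self.geometry!r}"])
        return tuple(e for e in edges for _ in range(self.trials_per_edge))

    def validate(self) -> None:
        errs = []
        if self.n_treatments < 2:
            errs.append("need at least 2 treatments")
        if self.tau < 0:
            errs.append(f"tau must be >= 0, got {self.tau}")
        if self.arm_size[0] < 2 or self.arm_size[1] < self.arm_size[0]:
            errs.append(f"invalid arm_size range {self.arm_size}")
        if self.outcome_kind not in ("continuous", "dichotomous"):
            errs.append(f"unknown outcome_kind {self.outcome_kind!r}")
        if self.baseline_sd <= 0:
            errs.append("baseline_sd must be > 0")
        if not (0 < self.baseline_risk < 1):
            errs.append("baseline_risk must be in (0, 1)")
        if self.d.get(REFERENCE, 0.0) != 0.0:
            errs.append("d[reference] must be 0")
        ids = set(self.treatment_ids)
        unknown = set(self.d) - ids
        if unknown:
            errs.append(f"d refers to unknown treatments {sorted(unknown)}")
        if self.trials is None or not errs:
            designs = None
            try:
                designs = self.trial_designs()
            except ValidationError as e:
                errs.extend(e.violations)
            if designs is not None:
                if self.omega_edge is not None and set(self.omega_edge) not in [
                    set(t) for t in designs
                ]:
                    errs.append(f"omega edge {self.omega_edge} has no trial in the design")
                for t in designs:
                    if len(set(t) - ids) > 0:
                        errs.append(f"trial {t} uses unknown treatments")
        if errs:
            raise ValidationError(errs)

    def to_dict(self) -> dict:
        out = dict(self.__dict__)
        out["d"] = dict(self.d)
        out["arm_size"] = list(self.arm_size)
        out["omega_edge"] = list(self.omega_edge) if self.omega_edge else None
        out["extra_edges"] = [list(e) for e in self.extra_edges]
        out["trials"] = [list(t) for t in self.trials] if self.trials else None
        return out

    @staticmethod
    def from_dict(cfg: Mapping) -> "Scenario":
        cfg = dict(cfg)
        if "arm_size" in cfg:
            cfg["arm_size"] = tuple(cfg["arm_size"])
        if cfg.get("omega_edge"):
            cfg["omega_edge"] = tuple(cfg["omega_edge"])
        if "extra_edges" in cfg:
            cfg["extra_edges"] = tuple(tuple(e) for e in cfg["extra_edges"])
        if cfg.get("trials"):
            cfg["trials"] = tuple(tuple(t) for t in cfg["trials"])
        return Scenario(**cfg)


def generate(sc: Scenario) -> NetworkDataset:
    """Draw a full arm-level dataset from a scenario.

    One explicit generator stream (seeded by ``sc.seed``) governs every
    draw, so the same scenario always yields the same dataset.
    """
    sc.validate()
    rng = np.random.default_rng(sc.seed)
    designs = sc.trial_designs()
    studies = []
    for i, arms in enumerate(designs):
        sid = f"s{i + 1:02d}"
        anchor = REFERENCE if REFERENCE in arms else sorted(arms)[0]
        non_anchor = [t for t in sorted(arms) if t != anchor]
        means = np.array([sc.effect(t) - sc.effect(anchor) for t in non_anchor])
        if sc.omega != 0.0 and sc.omega_edge is not None and set(arms) == set(sc.omega_edge):
            a, b = sc.omega_edge
            for j, t in enumerate(non_anchor):
                if t == a and anchor == b:
                    means[j] += sc.omega
                elif t == b and anchor == a:
                    means[j] -= sc.omega
        # 0.5 between-contrast correlation: shared + idiosyncratic parts
        if sc.tau > 0:
            shared = rng.normal(0.0, sc.tau / math.sqrt(2))
            theta = means + shared + rng.normal(0.0, sc.tau / math.sqrt(2), len(non_anchor))
        else:
            theta = means
        ns = rng.integers(sc.arm_size[0], sc.arm_size[1] + 1, size=len(arms))
        arm_sizes = dict(zip(sorted(arms), (int(n) for n in ns)))
        outcomes: dict[str, ArmOutcome] = {}
        for t in sorted(arms):
            n = arm_sizes[t]
            th = 0.0 if t == anchor else float(theta[non_anchor.index(t)])
            if sc.outcome_kind == "continuous":
                scores = rng.normal(
                    sc.baseline_mean + th * sc.baseline_sd, sc.baseline_sd, size=n
                )
                outcomes[t] = ArmOutcome(
                    kind="continuous",
                    n=n,
                    mean_change=float(np.mean(scores)),
                    sd=float(np.std(scores, ddof=1)),
                    scale_name="SIM",
                    direction="higher_is_worse",
                )
            else:
                p = _expit(math.log(sc.baseline_risk / (1 - sc.baseline_risk)) + th)
                outcomes[t] = ArmOutcome(
                    kind="dichotomous", n=n, events=int(rng.binomial(n, p))
                )
        studies.append(
            Study(
                study_id=sid,
                arms=tuple(sorted(arm_sizes.items())),
                records=(
                    OutcomeRecord(
                        outcome_id=sc.outcome_id,
                        followup_weeks=sc.followup_weeks,
                        arm_outcomes=outcomes,
                    ),
                ),
                comparison_arm=anchor,
            )
        )
    used = sorted({t for s in studies for t in s.treatment_ids})
    ref = REFERENCE if REFERENCE in used else used[0]
    treatments = tuple(Treatment(id=t, is_reference=(t == ref)) for t in used)
    return NetworkDataset(treatments=treatments, studies=tuple(studies), reference=ref)


def paper_like_scenario(seed: int = 0) -> Scenario:
    """A canned 12-node, 20-trial scenario shaped like the motivating
    network: 14 placebo-anchored two-arm trials, 5 head-to-head two-arm
    trials, one three-arm trial, and around 1,200 participants in total."""
    drugs = [f"drug{i:02d}" for i in range(1, 12)]
    placebo_trials = [(REFERENCE, d) for d in drugs] + [
        (REFERENCE, "drug01"),
        (REFERENCE, "drug05"),
        (REFERENCE, "drug07"),
    ]
    head_to_head = [
        ("drug03", "drug04"),
        ("drug02", "drug07"),
        ("drug02", "drug07"),
        ("drug05", "drug07"),
        ("drug07", "drug05"),
    ]
    three_arm = [("drug03", "drug07", REFERENCE)]
    d = {t: float(v) for t, v in zip(drugs, np.linspace(-1.2, 0.0, len(drugs)))}
    return Scenario(
        n_treatments=12,
        geometry="star_plus_edges",
        trials=tuple(placebo_trials + head_to_head + three_arm),
        arm_size=(15, 44),
        d=d,
        tau=0.2,
        outcome_kind="continuous",
        seed=seed,
    )


def realized_contrasts(ds: NetworkDataset, outcome_id: str = "pain4w"):
    """Observed per-trial contrast effects (for recovery diagnostics)."""
    from .effect_sizes import contrasts

    out = {}
    for s in ds.studies:
        for e in contrasts(s, outcome_id, reference=ds.reference):
            out[(s.study_id, e.treat_a, e.treat_b)] = e.value
    return out
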
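"""Contrast-level effect estimates from arm-level outcomes.

Continuous outcomes become standardized mean differences (Hedges' g with
the small-sample correction), dichotomous outcomes become log odds ratios
with Woolf standard errors.  Orientation is normalized so that a negative
SMD always means greater symptom relief regardless of whether the source
rating scale scores improvement as a decrease or an increase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .exceptions import DegenerateVarianceError, ValidationError
from .trial_data import ArmOutcome, Study, study_record

SMD = "SMD"
LOG_OR = "logOR"


@dataclass(frozen=True)
class EffectEstimate:
    """Relative effect of ``treat_a`` versus ``treat_b`` on the analysis scale."""

    study_id: str
    treat_a: str
    treat_b: str
    measure: str  # SMD | logOR
    value: float
    se: float
    oriented: bool = False

    def __post_init__(self):
        if self.measure not in (SMD, LOG_OR):
            raise ValidationError(f"unknown measure {self.measure!r}")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValidationError(f"se must be finite and positive, got {self.se!r}")
        if not math.isfinite(self.value):
            raise ValidationError(f"effect value must be finite, got {self.value!r}")

    def swapped(self) -> "EffectEstimate":
        """Same contrast seen from the other side: value negated, se kept."""
        return replace(self, treat_a=self.treat_b, treat_b=self.treat_a, value=-self.value)


def hedges_j(df: int) -> float:
    """Small-sample correction factor J = 1 - 3/(4*df - 1)."""
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def smd(
    arm_t: ArmOutcome,
    arm_c: ArmOutcome,
    study_id: str = "",
    treat_t: str = "t",
    treat_c: str = "c",
) -> EffectEstimate:
    """Hedges' g of the treatment arm versus the control arm.

    g = J * (mean_t - mean_c) / s_pooled with J = 1 - 3/(4(n_t+n_c-2) - 1);
    se^2 = 1/n_t + 1/n_c + g^2 / (2(n_t+n_c)).  When the scale scores
    improvement as an increase the sign is flipped so that negative g means
    greater relief in the treatment arm.
    """
    for arm in (arm_t, arm_c):
        if arm.kind != "continuous":
            raise ValidationError("smd requires continuous arms")
        if arm.n < 2:
            raise ValidationError("smd requires n >= 2 per arm")
    if arm_t.direction != arm_c.direction:
        raise ValidationError("arms of one study must share a scale direction")
    nt, nc = arm_t.n, arm_c.n
    df = nt + nc - 2
    sp2 = ((nt - 1) * arm_t.sd**2 + (nc - 1) * arm_c.sd**2) / df
    if sp2 <= 0:
        raise DegenerateVarianceError(
            f"pooled SD is zero in study {study_id!r} ({treat_t} vs {treat_c})"
        )
    d = (arm_t.mean_change - arm_c.mean_change) / math.sqrt(sp2)
    g = hedges_j(df) * d
    if arm_t.direction == "higher_is_better":
        g = -g
    se = math.sqrt(1.0 / nt + 1.0 / nc + g**2 / (2.0 * (nt + nc)))
    return EffectEstimate(
        study_id=study_id,
        treat_a=treat_t,
        treat_b=treat_c,
        measure=SMD,
        value=g,
        se=se,
        oriented=True,
    )


def log_or(
    arm_t: ArmOutcome,
    arm_c: ArmOutcome,
    study_id: str = "",
    treat_t: str = "t",
    treat_c: str = "c",
) -> EffectEstimate:
    """Log odds ratio with Woolf se; +0.5 on all four cells if any is zero."""
    for arm in (arm_t, arm_c):
        if arm.kind != "dichotomous":
            raise ValidationError("log_or requires dichotomous arms")
    a, b = arm_t.events, arm_t.n - arm_t.events
    c, d = arm_c.events, arm_c.n - arm_c.events
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    value = math.log(a * d / (b * c))
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return EffectEstimate(
        study_id=study_id,
        treat_a=treat_t,
        treat_b=treat_c,
        measure=LOG_OR,
        value=value,
        se=se,
        oriented=True,
    )


def anchor_arm(treatment_ids, reference: str = "placebo") -> str:
    """The study's anchor: the reference arm when present, else the
    alphabetically first treatment."""
    return reference if reference in treatment_ids else sorted(treatment_ids)[0]


def contrasts(
    study: Study, outcome_id: str, reference: str = "placebo"
) -> list[EffectEstimate]:
    """All non-anchor arms of a study contrasted against its anchor arm.

    A k-arm study yields k-1 estimates.  Returns an empty list when the
    outcome is unavailable for the study (no record in the selection
    window).
    """
    rec = study_record(study, outcome_id)
    if rec is None:
        return []
    ids = sorted(rec.arm_outcomes)
    anchor = anchor_arm(ids, reference)
    fn = smd if rec.kind == "continuous" else log_or
    return [
        fn(
            rec.arm_outcomes[t],
            rec.arm_outcomes[anchor],
            study_id=study.study_id,
            treat_t=t,
            treat_c=anchor,
        )
        for t in ids
        if t != anchor
    ]
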
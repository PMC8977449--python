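"""Arm-level trial data model, CSV loading/validation and network summaries.

The central object is :class:`NetworkDataset`: a set of randomized studies,
each contributing two or more treatment arms, together with the treatment
comparison graph those arms induce.  Outcome measurements are attached to
studies as :class:`OutcomeRecord` objects, one per outcome and follow-up
time point, so a study can report the same outcome at several times and the
time-point selection rule picks the one used in analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .exceptions import (
    DisconnectedNetworkError,
    SchemaError,
    ValidationError,
)

#: The five analysis outcomes, in reporting order.
OUTCOME_IDS = ("pain4w", "adverse_events", "pain8w", "mental_sleep", "serious_ae")

#: Default follow-up selection windows (weeks) per outcome.
TIMEPOINT_RULES = {
    "pain4w": (4.0, (3.0, 17.0)),
    "adverse_events": (4.0, (0.0, float("inf"))),
    "pain8w": (8.0, (8.0, float("inf"))),
    "mental_sleep": (4.0, (3.0, 17.0)),
    "serious_ae": (4.0, (0.0, float("inf"))),
}

REQUIRED_COLUMNS = (
    "study_id",
    "treatment",
    "n",
    "outcome_id",
    "followup_weeks",
    "kind",
    "events",
    "mean_change",
    "sd",
    "scale_name",
    "direction",
)

OPTIONAL_COLUMNS = ("country", "risk_of_bias", "role")


@dataclass(frozen=True)
class Treatment:
    """A node of the comparison network."""

    id: str
    name: str = ""
    is_reference: bool = False

    def __post_init__(self):
        if not self.id:
            raise ValidationError("treatment id must be non-empty")
        if not self.name:
            object.__setattr__(self, "name", self.id)


@dataclass(frozen=True)
class ArmOutcome:
    """One arm's measurement for one outcome record.

    Exactly the fields of the declared ``kind`` must be populated:
    ``events`` for dichotomous arms, ``mean_change``/``sd`` for continuous.
    """

    kind: str  # "continuous" | "dichotomous"
    n: int
    events: int | None = None
    mean_change: float | None = None
    sd: float | None = None
    scale_name: str | None = None
    direction: str = "higher_is_worse"  # or "higher_is_better"

    def __post_init__(self):
        errs = []
        if self.kind not in ("continuous", "dichotomous"):
            errs.append(f"unknown outcome kind {self.kind!r}")
        if not (isinstance(self.n, int) and self.n > 0):
            errs.append(f"arm n must be a positive integer, got {self.n!r}")
        if self.kind == "dichotomous":
            if self.events is None or not (0 <= self.events <= self.n):
                errs.append(
                    f"dichotomous arm needs 0 <= events <= n, got events={self.events!r}, n={self.n!r}"
                )
            if self.mean_change is not None or self.sd is not None:
                errs.append("dichotomous arm must not carry mean_change/sd")
        elif self.kind == "continuous":
            if self.mean_change is None or self.sd is None:
                errs.append("continuous arm needs mean_change and sd")
            elif not (self.sd > 0):
                errs.append(f"continuous arm sd must be > 0, got {self.sd!r}")
            if self.events is not None:
                errs.append("continuous arm must not carry events")
        if self.direction not in ("higher_is_worse", "higher_is_better"):
            errs.append(f"unknown direction {self.direction!r}")
        if errs:
            raise ValidationError(errs)


@dataclass(frozen=True)
class OutcomeRecord:
    """All arms' measurements for one outcome at one follow-up time."""

    outcome_id: str
    followup_weeks: float
    arm_outcomes: Mapping[str, ArmOutcome]  # treatment id -> measurement

    def __post_init__(self):
        kinds = {a.kind for a in self.arm_outcomes.values()}
        if len(kinds) > 1:
            raise ValidationError(
                f"outcome {self.outcome_id!r} mixes kinds {sorted(kinds)} across arms"
            )

    @property
    def kind(self) -> str:
        return next(iter(self.arm_outcomes.values())).kind


@dataclass(frozen=True)
class Study:
    """A randomized trial: arms with randomized n, plus outcome records."""

    study_id: str
    arms: tuple[tuple[str, int], ...]  # (treatment id, randomized n), sorted by id
    records: tuple[OutcomeRecord, ...] = ()
    country: str | None = None
    risk_of_bias: str | None = None  # low | moderate | high; metadata only
    comparison_arm: str | None = None  # the C-side arm for I/C accounting
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        errs = []
        ids = [t for t, _ in self.arms]
        if len(self.arms) < 2:
            errs.append(f"study {self.study_id!r} needs >= 2 arms")
        if len(set(ids)) != len(ids):
            errs.append(f"study {self.study_id!r} repeats a treatment across arms")
        for t, n in self.arms:
            if not (isinstance(n, int) and n > 0):
                errs.append(f"study {self.study_id!r} arm {t!r} has non-positive n {n!r}")
        if self.comparison_arm is not None and self.comparison_arm not in ids:
            errs.append(
                f"study {self.study_id!r} comparison arm {self.comparison_arm!r} not among its arms"
            )
        for rec in self.records:
            unknown = set(rec.arm_outcomes) - set(ids)
            if unknown:
                errs.append(
                    f"study {self.study_id!r} outcome {rec.outcome_id!r} references unknown arms {sorted(unknown)}"
                )
        if errs:
            raise ValidationError(errs)
        object.__setattr__(self, "arms", tuple(sorted(self.arms)))
        object.__setattr__(
            self,
            "records",
            tuple(sorted(self.records, key=lambda r: (r.outcome_id, r.followup_weeks))),
        )

    @property
    def treatment_ids(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.arms)

    @property
    def total_n(self) -> int:
        return sum(n for _, n in self.arms)

    @property
    def n_arms(self) -> int:
        return len(self.arms)

    def records_for(self, outcome_id: str) -> tuple[OutcomeRecord, ...]:
        return tuple(r for r in self.records if r.outcome_id == outcome_id)


@dataclass(frozen=True)
class NetworkDataset:
    """A connected network of studies over a common treatment set."""

    treatments: tuple[Treatment, ...]
    studies: tuple[Study, ...]
    reference: str

    def __post_init__(self):
        errs = []
        ids = [t.id for t in self.treatments]
        if len(set(ids)) != len(ids):
            errs.append("duplicate treatment ids")
        if self.reference not in ids:
            errs.append(f"reference {self.reference!r} not among treatments")
        refs = [t.id for t in self.treatments if t.is_reference]
        if refs != [self.reference]:
            errs.append(f"exactly one reference treatment required, flagged: {refs}")
        used = {t for s in self.studies for t in s.treatment_ids}
        unused = set(ids) - used
        if unused:
            errs.append(f"treatments never used in any study: {sorted(unused)}")
        unknown = used - set(ids)
        if unknown:
            errs.append(f"studies reference undeclared treatments: {sorted(unknown)}")
        sids = [s.study_id for s in self.studies]
        if len(set(sids)) != len(sids):
            errs.append("duplicate study ids")
        if errs:
            raise ValidationError(errs)
        g = _structural_graph(self.studies)
        if len(ids) and not nx.is_connected(g):
            comps = [sorted(c) for c in nx.connected_components(g)]
            raise DisconnectedNetworkError(
                [f"comparison graph is disconnected; components: {comps}"]
            )
        object.__setattr__(self, "treatments", tuple(sorted(self.treatments, key=lambda t: t.id)))
        object.__setattr__(self, "studies", tuple(sorted(self.studies, key=lambda s: s.study_id)))

    @property
    def treatment_ids(self) -> tuple[str, ...]:
        return tuple(t.id for t in self.treatments)

    def study(self, study_id: str) -> Study:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(study_id)


@dataclass(frozen=True)
class NetworkSummary:
    """Composition counts of a trial network."""

    n_studies: int
    n_treatments: int  # excluding the reference
    total_participants: int
    intervention_participants: int
    comparison_participants: int
    mean_study_size: float
    sd_study_size: float
    mean_study_size_rounded: int
    sd_study_size_rounded: int
    n_two_arm: int
    n_three_arm: int
    n_placebo_controlled: int
    n_head_to_head: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _structural_graph(studies: Iterable[Study]) -> nx.Graph:
    g = nx.Graph()
    for s in studies:
        ids = s.treatment_ids
        g.add_nodes_from(ids)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if g.has_edge(a, b):
                    g[a][b]["n_studies"] += 1
                else:
                    g.add_edge(a, b, n_studies=1)
    return g


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Loading


def _cell(row, col):
    v = row.get(col)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    if isinstance(v, str):
        v = v.strip()
        if v == "" or v.upper() == "NA":
            return None
    return v


def _int_cell(row, col, errs, ctx):
    v = _cell(row, col)
    if v is None:
        return None
    try:
        f = float(v)
        if f != int(f):
            raise ValueError
        return int(f)
    except (TypeError, ValueError):
        errs.append(f"{ctx}: non-integer {col} {v!r}")
        return None


def _float_cell(row, col, errs, ctx):
    v = _cell(row, col)
    if v is None:
        return None
    try:
        return float(v)
    except (TypeError, ValueError):
        errs.append(f"{ctx}: non-numeric {col} {v!r}")
        return None


def load_network(
    path,
    schema: Mapping[str, str] | None = None,
    reference: str | None = None,
) -> NetworkDataset:
    """Read a delimited arm-level trial table into a validated dataset.

    Each row describes one study arm.  Rows with an empty ``outcome_id``
    declare the arm's randomized size and study metadata only; rows with an
    ``outcome_id`` additionally carry that arm's measurement at the stated
    follow-up time.  Row order never affects the result.

    Parameters
    ----------
    path:
        CSV file with a header (UTF-8).
    schema:
        Optional mapping from canonical column names to the file's actual
        column names.
    reference:
        Reference treatment id.  Defaults to ``placebo`` when present,
        otherwise the alphabetically first treatment.
    """
    schema = dict(schema or {})
    df = pd.read_csv(path, dtype=str)
    rename = {schema.get(c, c): c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS}
    df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    return _build_dataset(df.to_dict("records"), reference=reference)


def _build_dataset(rows: Sequence[Mapping], reference: str | None) -> NetworkDataset:
    errs: list[str] = []
    # (study_id, treatment) -> randomized n; collected from arm-declaration rows
    arm_n: dict[tuple[str, str], int] = {}
    seen_arm_rows: set[tuple[str, str]] = set()
    study_meta: dict[str, dict] = {}
    # (study, outcome_id, followup) -> {treatment: ArmOutcome}
    rec_arms: dict[tuple[str, str, float], dict[str, ArmOutcome]] = {}
    comparison_arm: dict[str, str] = {}

    for i, row in enumerate(rows):
        sid = _cell(row, "study_id")
        trt = _cell(row, "treatment")
        ctx = f"row {i + 1} (study {sid!r}, treatment {trt!r})"
        if not sid or not trt:
            errs.append(f"{ctx}: study_id and treatment are required")
            continue
        sid, trt = str(sid), str(trt)
        n = _int_cell(row, "n", errs, ctx)
        if n is None:
            errs.append(f"{ctx}: missing or non-numeric n")
            continue
        meta = study_meta.setdefault(sid, {})
        for col in ("country", "risk_of_bias"):
            v = _cell(row, col)
            if v is not None:
                meta.setdefault(col, str(v))
        role = _cell(row, "role")
        if role is not None and str(role).lower().startswith("c"):
            prev = comparison_arm.get(sid)
            if prev is not None and prev != trt:
                errs.append(f"{ctx}: study has more than one comparison-role arm")
            comparison_arm[sid] = trt

        outcome = _cell(row, "outcome_id")
        if outcome is None:
            key = (sid, trt)
            if key in seen_arm_rows:
                errs.append(f"{ctx}: duplicate (study, treatment) arm declaration")
            seen_arm_rows.add(key)
            arm_n[key] = n
            fw = _float_cell(row, "followup_weeks", errs, ctx)
            if fw is not None:
                meta.setdefault("followup_weeks", fw)
            sc = _cell(row, "scale_name")
            if sc is not None:
                meta.setdefault("scale_name", str(sc))
            continue

        outcome = str(outcome)
        fw = _float_cell(row, "followup_weeks", errs, ctx)
        if fw is None:
            errs.append(f"{ctx}: outcome row needs followup_weeks")
            continue
        kind = _cell(row, "kind")
        if kind not in ("continuous", "dichotomous"):
            errs.append(f"{ctx}: outcome row needs kind continuous|dichotomous, got {kind!r}")
            continue
        arm_n.setdefault((sid, trt), n)
        direction = _cell(row, "direction") or "higher_is_worse"
        try:
            ao = ArmOutcome(
                kind=kind,
                n=n,
                events=_int_cell(row, "events", errs, ctx),
                mean_change=_float_cell(row, "mean_change", errs, ctx),
                sd=_float_cell(row, "sd", errs, ctx),
                scale_name=_cell(row, "scale_name"),
                direction=str(direction),
            )
        except ValidationError as e:
            errs.extend(f"{ctx}: {v}" for v in e.violations)
            continue
        bucket = rec_arms.setdefault((sid, outcome, fw), {})
        if trt in bucket:
            errs.append(f"{ctx}: duplicate (study, treatment) pair for outcome {outcome!r}")
            continue
        bucket[trt] = ao

    if errs:
        raise ValidationError(errs)

    studies = []
    by_study: dict[str, list[OutcomeRecord]] = {}
    for (sid, outcome, fw), arms in sorted(rec_arms.items()):
        try:
            by_study.setdefault(sid, []).append(
                OutcomeRecord(outcome_id=outcome, followup_weeks=fw, arm_outcomes=arms)
            )
        except ValidationError as e:
            errs.extend(f"study {sid!r}: {v}" for v in e.violations)
    sids = sorted({sid for sid, _ in arm_n})
    for sid in sids:
        arms = tuple(sorted((t, n) for (s, t), n in arm_n.items() if s == sid))
        meta = study_meta.get(sid, {})
        try:
            studies.append(
                Study(
                    study_id=sid,
                    arms=arms,
                    records=tuple(by_study.get(sid, ())),
                    country=meta.get("country"),
                    risk_of_bias=meta.get("risk_of_bias"),
                    comparison_arm=comparison_arm.get(sid),
                    meta={
                        k: v
                        for k, v in meta.items()
                        if k in ("followup_weeks", "scale_name")
                    },
                )
            )
        except ValidationError as e:
            errs.extend(e.violations)
    if errs:
        raise ValidationError(errs)

    tids = sorted({t for s in studies for t in s.treatment_ids})
    if reference is None:
        reference = "placebo" if "placebo" in tids else tids[0]
    if reference not in tids:
        raise ValidationError([f"reference treatment {reference!r} not present in data"])
    treatments = tuple(
        Treatment(id=t, is_reference=(t == reference)) for t in tids
    )
    return NetworkDataset(treatments=treatments, studies=tuple(studies), reference=reference)


# ---------------------------------------------------------------------------
# Time-point selection


def select_timepoint(
    records: Sequence[OutcomeRecord],
    target_weeks: float,
    window: tuple[float, float],
) -> OutcomeRecord | None:
    """Pick the record closest to ``target_weeks`` within ``window``.

    Ties are broken toward the earlier time point.  Returns ``None`` when no
    record falls inside the window, which marks the outcome unavailable for
    that study (the study stays in the dataset).
    """
    lo, hi = window
    eligible = [r for r in records if lo <= r.followup_weeks <= hi]
    if not eligible:
        return None
    return min(eligible, key=lambda r: (abs(r.followup_weeks - target_weeks), r.followup_weeks))


def study_record(study: Study, outcome_id: str) -> OutcomeRecord | None:
    """The study's analysis record for an outcome under the default rules."""
    target, window = TIMEPOINT_RULES.get(outcome_id, (4.0, (0.0, float("inf"))))
    return select_timepoint(study.records_for(outcome_id), target, window)


# ---------------------------------------------------------------------------
# Summaries


def summarize(ds: NetworkDataset) -> NetworkSummary:
    """Composition counts from randomized per-arm n.

    The intervention/comparison split uses each study's declared comparison
    arm: the reference arm when present, otherwise the explicitly flagged
    comparator (the C arm of a head-to-head trial still counts as
    comparison).  Study-size SD uses the n-1 denominator; a single-study
    network reports SD 0 by convention.
    """
    sizes = [s.total_n for s in ds.studies]
    n_studies = len(sizes)
    total = sum(sizes)
    comparison = 0
    for s in ds.studies:
        comp = s.comparison_arm
        if comp is None:
            comp = ds.reference if ds.reference in s.treatment_ids else s.treatment_ids[-1]
        comparison += dict(s.arms)[comp]
    mean = total / n_studies if n_studies else 0.0
    if n_studies > 1:
        sd = math.sqrt(sum((x - mean) ** 2 for x in sizes) / (n_studies - 1))
    else:
        sd = 0.0
    two_arm = sum(1 for s in ds.studies if s.n_arms == 2)
    three_arm = sum(1 for s in ds.studies if s.n_arms == 3)
    placebo_ctrl = sum(
        1 for s in ds.studies if s.n_arms == 2 and ds.reference in s.treatment_ids
    )
    head_to_head = sum(
        1 for s in ds.studies if s.n_arms == 2 and ds.reference not in s.treatment_ids
    )
    return NetworkSummary(
        n_studies=n_studies,
        n_treatments=len(ds.treatments) - 1,
        total_participants=total,
        intervention_participants=total - comparison,
        comparison_participants=comparison,
        mean_study_size=mean,
        sd_study_size=sd,
        mean_study_size_rounded=_round_half_up(mean),
        sd_study_size_rounded=_round_half_up(sd),
        n_two_arm=two_arm,
        n_three_arm=three_arm,
        n_placebo_controlled=placebo_ctrl,
        n_head_to_head=head_to_head,
    )


def comparison_graph(ds: NetworkDataset, outcome_id: str | None = None) -> nx.Graph:
    """Undirected comparison graph with per-edge study counts.

    Nodes carry ``n_randomized`` (sum of randomized n over contributing
    arms); edges carry ``n_studies``.  A three-arm study contributes all
    three pairwise edges.  With ``outcome_id=None`` the graph covers the
    whole enrollment network; otherwise only studies whose analysis record
    (after time-point selection) reports the outcome contribute, and an
    empty graph is flagged via the ``empty`` graph attribute.
    """
    g = nx.Graph()
    for s in ds.studies:
        if outcome_id is None:
            ids = s.treatment_ids
            ns = dict(s.arms)
        else:
            rec = study_record(s, outcome_id)
            if rec is None:
                continue
            ids = tuple(sorted(rec.arm_outcomes))
            ns = {t: rec.arm_outcomes[t].n for t in ids}
        for t in ids:
            if t in g:
                g.nodes[t]["n_randomized"] += ns[t]
            else:
                g.add_node(t, n_randomized=ns[t])
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if g.has_edge(a, b):
                    g[a][b]["n_studies"] += 1
                else:
                    g.add_edge(a, b, n_studies=1)
    g.graph["empty"] = g.number_of_nodes() == 0
    return g


def graph_to_frame(g: nx.Graph) -> pd.DataFrame:
    """Edge list as a tidy frame (treat_a, treat_b, n_studies)."""
    rows = [
        {"treat_a": min(a, b), "treat_b": max(a, b), "n_studies": d["n_studies"]}
        for a, b, d in g.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["treat_a", "treat_b", "n_studies"]).sort_values(
        ["treat_a", "treat_b"], ignore_index=True
    )


def write_network(ds: NetworkDataset, path) -> None:
    """Serialize a dataset back to the arm-level CSV schema.

    Studies with outcome records emit one row per (record, arm); studies
    without records emit arm-declaration rows with an empty outcome_id.
    ``load_network`` on the output reproduces an equivalent dataset.
    """
    rows = []
    for s in ds.studies:
        role = {t: "intervention" for t in s.treatment_ids}
        comp = s.comparison_arm
        if comp is None and ds.reference in s.treatment_ids:
            comp = ds.reference
        if comp is not None:
            role[comp] = "comparison"
        base = {
            "study_id": s.study_id,
            "country": s.country,
            "risk_of_bias": s.risk_of_bias,
        }
        if not s.records:
            for t, n in s.arms:
                rows.append(
                    {
                        **base,
                        "treatment": t,
                        "role": role[t],
                        "n": n,
                        "outcome_id": None,
                        "followup_weeks": s.meta.get("followup_weeks"),
                        "kind": None,
                        "events": None,
                        "mean_change": None,
                        "sd": None,
                        "scale_name": s.meta.get("scale_name"),
                        "direction": None,
                    }
                )
            continue
        for rec in s.records:
            for t in sorted(rec.arm_outcomes):
                a = rec.arm_outcomes[t]
                rows.append(
                    {
                        **base,
                        "treatment": t,
                        "role": role[t],
                        "n": a.n,
                        "outcome_id": rec.outcome_id,
                        "followup_weeks": rec.followup_weeks,
                        "kind": a.kind,
                        "events": a.events,
                        "mean_change": a.mean_change,
                        "sd": a.sd,
                        "scale_name": a.scale_name,
                        "direction": a.direction,
                    }
                )
    cols = [
        "study_id", "country", "treatment", "role", "n", "outcome_id",
        "followup_weeks", "kind", "events", "mean_change", "sd",
        "scale_name", "direction", "risk_of_bias",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def fixture_path() -> str:
    """Path to the bundled 20-trial arm-level fixture CSV."""
    return str(resources.files("painnma").joinpath("data/sci_np_trials.csv"))


def load_fixture() -> NetworkDataset:
    """The bundled 20-trial, 12-node network (counts and metadata only)."""
    return load_network(fixture_path())
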
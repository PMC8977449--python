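"""Bayesian random-effects network meta-analysis core.

Implements the arm-based consistency model: every trial has a baseline
(nuisance) and trial-specific relative effects drawn from a random-effects
distribution centred on differences of basic parameters ``d[k]`` (effect of
treatment k versus the network reference, with ``d[ref] = 0``).  Continuous
outcomes enter as anchor-based standardized mean difference contrasts with
a normal likelihood; dichotomous outcomes enter as raw arm events/n with a
binomial-logit likelihood.  Multi-arm trials use the multivariate
random-effects distribution with 0.5 between-contrast correlation.

Sampling is Metropolis-within-Gibbs with per-parameter adaptive random-walk
proposals, adapted during burn-in only and frozen afterwards, so a fixed
seed fully determines the output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .effect_sizes import LOG_OR, SMD, anchor_arm, contrasts
from .exceptions import ConvergenceError, DisconnectedNetworkError, ValidationError
from .trial_data import NetworkDataset, study_record

logger = logging.getLogger("painnma")

_ADAPT_INTERVAL = 25
_TARGET_ACC = 0.44


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one NMA fit.

    ``kind`` is normally inferred from the outcome data; set it only to
    force a check.  ``tau_prior`` is ``("uniform", (lo, hi))`` on the
    heterogeneity SD scale, or ``("fixed", value)`` for a point mass (a
    fixed 0 gives the common-effect limit).  Defaults follow the analysis
    protocol: 3 chains, 50,000 burn-in, 100,000 retained updates.
    """

    kind: str | None = None  # "normal" | "binomial" | None (infer)
    reference: str | None = None
    prior_sd_effects: float = 100.0
    tau_prior: tuple = ("uniform", (0.0, 5.0))
    n_chains: int = 3
    burn_in: int = 50_000
    samples: int = 100_000
    thin: int = 1
    seed: int | None = None
    rhat_threshold: float = 1.05
    strict_convergence: bool = False

    def __post_init__(self):
        errs = []
        if self.n_chains < 2:
            errs.append(f"n_chains must be >= 2, got {self.n_chains}")
        if self.burn_in <= 0 or self.samples <= 0:
            errs.append("burn_in and samples must be > 0")
        if self.thin < 1:
            errs.append("thin must be >= 1")
        family = self.tau_prior[0]
        if family not in ("uniform", "fixed"):
            errs.append(f"unknown tau prior family {family!r}")
        if errs:
            raise ValidationError(errs)


#: reduced profile used by the test suite (scaled down from the full run)
TEST_SPEC = ModelSpec(burn_in=2_000, samples=10_000)


@dataclass(frozen=True)
class LeagueCell:
    row: str
    col: str
    median: float
    ci95: tuple[float, float]
    significant: bool


# ---------------------------------------------------------------------------
# Problem construction


class _Problem:
    """Preprocessed data and mean-structure for the sampler.

    The per-trial random effect means are linear in the parameter vector
    ``theta`` (basic parameters first, then any extra parameters such as a
    node-split direct effect): ``mean = A @ theta``.
    """

    def __init__(self, kind, t_ids, ref):
        self.kind = kind  # "normal" | "binomial"
        self.t_ids = list(t_ids)  # reference first
        self.ref = ref
        self.trial_ids: list[str] = []
        self.trial_anchor: list[int] = []
        # contrast-level bookkeeping (one row per non-anchor arm)
        self.c_trial: list[int] = []  # owning trial
        self.c_treat: list[int] = []
        self.rows: list[dict] = []  # {param index: coefficient}
        self.param_names: list[str] = []  # d params then extras
        # normal likelihood
        self.c_y: list[float] = []
        self.c_v: list[float] = []
        self.trial_cov: dict[int, np.ndarray] = {}  # multi-arm V matrices
        # binomial likelihood
        self.c_r: list[int] = []
        self.c_n: list[int] = []
        self.b_r: list[int] = []
        self.b_n: list[int] = []

        self.param_names = [f"d[{t}]" for t in self.t_ids[1:]]

    # -- assembly -----------------------------------------------------------

    def d_index(self, tid: str) -> int | None:
        """Column of theta holding d for a treatment (None for reference)."""
        i = self.t_ids.index(tid)
        return None if i == 0 else i - 1

    def add_param(self, name: str) -> int:
        self.param_names.append(name)
        return len(self.param_names) - 1

    def consistency_row(self, treat: str, anchor: str) -> dict:
        row: dict[int, float] = {}
        it, ib = self.d_index(treat), self.d_index(anchor)
        if it is not None:
            row[it] = row.get(it, 0.0) + 1.0
        if ib is not None:
            row[ib] = row.get(ib, 0.0) - 1.0
        return row

    def finalize(self):
        self.n_params = len(self.param_names)
        self.n_contrasts = len(self.c_trial)
        self.n_trials = len(self.trial_ids)
        nc, npar = self.n_contrasts, self.n_params
        self.A = np.zeros((nc, npar))
        for c, row in enumerate(self.rows):
            for p, coef in row.items():
                self.A[c, p] = coef
        self.c_trial_arr = np.asarray(self.c_trial, dtype=int)
        self.c_treat_arr = np.asarray(self.c_treat, dtype=int)
        # per-parameter dependency sets
        self.col_idx = [np.flatnonzero(self.A[:, p]) for p in range(npar)]
        # trials split by arm count
        counts = np.bincount(self.c_trial_arr, minlength=self.n_trials)
        self.two_arm_trials = np.flatnonzero(counts == 1)
        self.multi_trials = np.flatnonzero(counts > 1)
        self.tw = np.flatnonzero(np.isin(self.c_trial_arr, self.two_arm_trials))
        self.multi_contrasts = {
            int(t): np.flatnonzero(self.c_trial_arr == t) for t in self.multi_trials
        }
        if self.kind == "normal":
            self.y = np.asarray(self.c_y)
            self.v = np.asarray(self.c_v)
            self.multi = {}
            for t, idx in self.multi_contrasts.items():
                V = self.trial_cov[t]
                self.multi[t] = (
                    idx,
                    np.linalg.inv(V),
                    float(np.linalg.slogdet(2 * np.pi * V)[1]),
                )
        else:
            self.r = np.asarray(self.c_r, dtype=float)
            self.n = np.asarray(self.c_n, dtype=float)
            self.rb = np.asarray(self.b_r, dtype=float)
            self.nb = np.asarray(self.b_n, dtype=float)
        # correlation structure of multi-arm random effects (0.5 pairwise)
        self._re_corr: dict[int, tuple[np.ndarray, float]] = {}
        for t, idx in self.multi_contrasts.items():
            m = len(idx)
            R = 0.5 * (np.eye(m) + np.ones((m, m)))
            self._re_corr[t] = (np.linalg.inv(R), float(np.linalg.slogdet(R)[1]))

    # -- likelihood pieces --------------------------------------------------

    def data_loglik_contrasts(self, delta, mu=None, idx=None):
        """Per-contrast data log-likelihood (binomial omits the constant)."""
        if idx is None:
            idx = slice(None)
        if self.kind == "normal":
            # two-arm rows only; multi-arm handled as trial blocks
            return -0.5 * (self.y[idx] - delta[idx]) ** 2 / self.v[idx]
        eta = mu[self.c_trial_arr[idx]] + delta[idx]
        p = _expit(eta)
        return self.r[idx] * np.log(p) + (self.n[idx] - self.r[idx]) * np.log1p(-p)

    def normal_trial_loglik(self, t, delta):
        idx, Vinv, logdet = self.multi[t]
        resid = self.y[idx] - delta[idx]
        return -0.5 * (resid @ Vinv @ resid) - 0.5 * logdet

    def anchor_loglik(self, mu, trials=None):
        if trials is None:
            trials = slice(None)
        p = _expit(mu[trials])
        return self.rb[trials] * np.log(p) + (self.nb[trials] - self.rb[trials]) * np.log1p(-p)

    def deviance(self, delta, mu=None):
        if self.kind == "normal":
            ll = float(np.sum(self.data_loglik_contrasts(delta, idx=self.tw)))
            for t in self.multi_trials:
                ll += self.normal_trial_loglik(int(t), delta)
            # include normal constants so the deviance is on the -2 log L scale
            ll += float(np.sum(-0.5 * np.log(2 * np.pi * self.v[self.tw])))
        else:
            ll = float(np.sum(self.data_loglik_contrasts(delta, mu)))
            ll += float(np.sum(self.anchor_loglik(mu)))
        return -2.0 * ll

    def re_logp_two(self, delta, mean, tau, idx):
        z = delta[idx] - mean[idx]
        return -0.5 * z**2 / tau**2 - 0.5 * np.log(2 * np.pi * tau**2)

    def re_logp_multi(self, t, delta, mean, tau):
        idx = self.multi_contrasts[t]
        Rinv, logdetR = self._re_corr[t]
        z = (delta[idx] - mean[idx]) / tau
        m = len(idx)
        return float(
            -0.5 * (z @ Rinv @ z) - 0.5 * (m * math.log(2 * math.pi * tau**2) + logdetR)
        )


def _expit(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return np.clip(out, 1e-12, 1 - 1e-12)


def build_problem(
    ds: NetworkDataset,
    outcome_id: str,
    spec: ModelSpec,
    mode: str = "consistency",
    split_edge: tuple[str, str] | None = None,
) -> _Problem:
    """Assemble the sampler's data structures for one outcome.

    ``mode`` selects the mean structure: ``consistency`` (basic
    parameters), ``ume`` (unrelated mean effects, one parameter per design
    comparison — the inconsistency model), or ``nodesplit`` (consistency
    plus a separate direct-effect parameter for ``split_edge``).
    Treatments with no usable data for the outcome are dropped with a
    warning; the remaining network must be connected.
    """
    ref = spec.reference or ds.reference
    usable = []
    for s in ds.studies:
        rec = study_record(s, outcome_id)
        if rec is not None and len(rec.arm_outcomes) >= 2:
            usable.append((s, rec))
    if not usable:
        raise ValidationError([f"no study reports outcome {outcome_id!r}"])
    kinds = {rec.kind for _, rec in usable}
    if len(kinds) > 1:
        raise ValidationError([f"outcome {outcome_id!r} mixes continuous and dichotomous studies"])
    kind = "normal" if kinds.pop() == "continuous" else "binomial"
    if spec.kind is not None and spec.kind != kind:
        raise ValidationError(
            [f"spec requests {spec.kind!r} likelihood but data are {kind!r}"]
        )

    present = sorted({t for _, rec in usable for t in rec.arm_outcomes})
    dropped = sorted(set(ds.treatment_ids) - set(present))
    if dropped:
        logger.warning(
            "outcome %s: dropping treatments with no data: %s", outcome_id, dropped
        )
    if ref not in present:
        raise ValidationError(
            [f"reference {ref!r} has no data for outcome {outcome_id!r}"]
        )
    g = nx.Graph()
    g.add_nodes_from(present)
    for _, rec in usable:
        ids = sorted(rec.arm_outcomes)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                g.add_edge(a, b)
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise DisconnectedNetworkError(
            [f"outcome {outcome_id!r} network is disconnected: {comps}"]
        )

    t_ids = [ref] + [t for t in present if t != ref]
    prob = _Problem(kind, t_ids, ref)

    split = None
    split_param = None
    if mode == "nodesplit":
        if split_edge is None:
            raise ValidationError(["nodesplit mode needs a split_edge"])
        a, b = split_edge
        lo = ref if ref in (a, b) else min(a, b)
        hi = b if lo == a else a
        split = (hi, lo)  # oriented: effect of hi vs lo
        split_param = prob.add_param(f"direct[{hi} vs {lo}]")
    ume_params: dict[tuple[str, str], int] = {}

    tidx = {t: i for i, t in enumerate(t_ids)}
    for s, rec in usable:
        ids = sorted(rec.arm_outcomes)
        anchor = anchor_arm(ids, ref)
        trial = len(prob.trial_ids)
        prob.trial_ids.append(s.study_id)
        prob.trial_anchor.append(tidx[anchor])
        non_anchor = [t for t in ids if t != anchor]

        if kind == "normal":
            effs = {e.treat_a: e for e in contrasts(s, outcome_id, reference=ref)}
            if len(non_anchor) > 1:
                n_anchor = rec.arm_outcomes[anchor].n
                m = len(non_anchor)
                V = np.full((m, m), 1.0 / n_anchor)
                np.fill_diagonal(V, [effs[t].se ** 2 for t in non_anchor])
                prob.trial_cov[trial] = V
        else:
            ab = rec.arm_outcomes[anchor]
            prob.b_r.append(ab.events)
            prob.b_n.append(ab.n)

        for t in non_anchor:
            prob.c_trial.append(trial)
            prob.c_treat.append(tidx[t])
            if kind == "normal":
                prob.c_y.append(effs[t].value)
                prob.c_v.append(effs[t].se ** 2)
            else:
                ao = rec.arm_outcomes[t]
                prob.c_r.append(ao.events)
                prob.c_n.append(ao.n)
            if mode == "ume":
                key = tuple(sorted((anchor, t)))
                if key not in ume_params:
                    ume_params[key] = prob.add_param(f"d[{key[1]} vs {key[0]}]")
                prob.rows.append({ume_params[key]: 1.0})
            elif mode == "nodesplit" and split is not None and (t, anchor) == split:
                prob.rows.append({split_param: 1.0})
            else:
                prob.rows.append(prob.consistency_row(t, anchor))

    if mode == "ume":
        # basic parameters are unused in the UME mean structure; strip them
        keep = sorted(set(ume_params.values()))
        remap = {old: new for new, old in enumerate(keep)}
        prob.param_names = [prob.param_names[p] for p in keep]
        prob.rows = [{remap[p]: c for p, c in row.items()} for row in prob.rows]
    prob.finalize()
    prob.mode = mode
    prob.split = split
    return prob


# ---------------------------------------------------------------------------
# Sampler


@dataclass
class NMAPosterior:
    """MCMC output of one fit, with per-chain layout and diagnostics."""

    treatment_ids: tuple[str, ...]  # reference first
    reference: str
    kind: str
    measure: str  # SMD | logOR
    outcome_id: str
    d_draws: np.ndarray  # (chains, kept, T); reference column is all 0
    tau_draws: np.ndarray  # (chains, kept)
    extra_names: tuple[str, ...]
    extra_draws: np.ndarray  # (chains, kept, n_extra)
    deviance_draws: np.ndarray  # (chains, kept)
    rhat: dict
    mc_error: dict
    dic: tuple[float, float, float]  # (Dbar, pD, DIC)
    spec: ModelSpec
    mode: str = "consistency"
    dropped_treatments: tuple[str, ...] = ()

    @property
    def n_draws(self) -> int:
        return self.d_draws.shape[0] * self.d_draws.shape[1]

    def d_pooled(self) -> np.ndarray:
        """All chains concatenated, shape (n_draws, T)."""
        return self.d_draws.reshape(-1, self.d_draws.shape[2])

    def tau_pooled(self) -> np.ndarray:
        return self.tau_draws.reshape(-1)

    def contrast_draws(self, a: str, b: str) -> np.ndarray:
        """Pooled draws of d[a] - d[b] (effect of a versus b)."""
        ia = self.treatment_ids.index(a)
        ib = self.treatment_ids.index(b)
        d = self.d_pooled()
        return d[:, ia] - d[:, ib]

    def extra_pooled(self, name: str) -> np.ndarray:
        i = self.extra_names.index(name)
        return self.extra_draws.reshape(-1, max(1, len(self.extra_names)))[:, i]

    def summary(self) -> pd.DataFrame:
        rows = []
        d = self.d_pooled()
        for i, t in enumerate(self.treatment_ids):
            x = d[:, i]
            rows.append(
                {
                    "parameter": f"d[{t}]",
                    "median": float(np.median(x)),
                    "mean": float(np.mean(x)),
                    "sd": float(np.std(x, ddof=1)) if t != self.reference else 0.0,
                    "ci95_low": float(np.percentile(x, 2.5)),
                    "ci95_high": float(np.percentile(x, 97.5)),
                    "rhat": self.rhat.get(f"d[{t}]", float("nan")),
                    "mc_error": self.mc_error.get(f"d[{t}]", float("nan")),
                }
            )
        tau = self.tau_pooled()
        rows.append(
            {
                "parameter": "tau",
                "median": float(np.median(tau)),
                "mean": float(np.mean(tau)),
                "sd": float(np.std(tau, ddof=1)),
                "ci95_low": float(np.percentile(tau, 2.5)),
                "ci95_high": float(np.percentile(tau, 97.5)),
                "rhat": self.rhat.get("tau", float("nan")),
                "mc_error": self.mc_error.get("tau", float("nan")),
            }
        )
        return pd.DataFrame(rows)


def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for draws (chains, n)."""
    chains, n = x.shape
    half = n // 2
    if half < 2:
        return float("nan")
    seqs = x[:, : 2 * half].reshape(chains * 2, half)
    means = seqs.mean(axis=1)
    variances = seqs.var(axis=1, ddof=1)
    w = float(variances.mean())
    b = half * float(means.var(ddof=1))
    if w == 0:
        return 1.0
    var_plus = (half - 1) / half * w + b / half
    return float(math.sqrt(var_plus / w))


def batch_mc_error(x: np.ndarray) -> float:
    """Batch-means Monte Carlo standard error of the overall mean."""
    chains, n = x.shape
    b = max(2, int(math.sqrt(n)))
    nb = n // b
    if nb < 2:
        return float("nan")
    bm = x[:, : nb * b].reshape(chains, nb, b).mean(axis=2)
    se2 = bm.var(axis=1, ddof=1) / nb  # per-chain variance of the chain mean
    return float(math.sqrt(float(se2.mean()) / chains))


class _AdaptiveScale:
    def __init__(self, shape, init=0.5):
        self.scale = np.full(shape, init) if shape else init
        self.acc = np.zeros(shape) if shape else 0.0
        self.tries = 0

    def record(self, accepted):
        self.acc = self.acc + accepted
        self.tries += 1

    def adapt(self):
        if self.tries == 0:
            return
        rate = self.acc / self.tries
        self.scale = self.scale * np.exp(1.2 * (rate - _TARGET_ACC))
        self.acc = self.acc * 0.0
        self.tries = 0


def _run_chain(prob: _Problem, spec: ModelSpec, rng, chain_index: int):
    npar, nc, nt = prob.n_params, prob.n_contrasts, prob.n_trials
    prior_var = spec.prior_sd_effects**2
    tau_family = spec.tau_prior[0]
    if tau_family == "fixed":
        tau = float(spec.tau_prior[1])
        sample_tau = False
    else:
        lo, hi = spec.tau_prior[1]
        tau = float(min(max(0.05 + 0.4 * chain_index, lo + 1e-6), hi - 1e-6))
        sample_tau = True
    tau_zero = (not sample_tau) and tau == 0.0

    # over-dispersed initials: chain-dependent offset plus jitter
    offset = (chain_index - (spec.n_chains - 1) / 2.0) * 0.5
    theta = offset + 0.1 * rng.standard_normal(npar)
    mean = prob.A @ theta
    delta = mean.copy()
    if not tau_zero:
        delta = mean + tau * rng.standard_normal(nc)
    if prob.kind == "binomial":
        mu = np.log((prob.rb + 0.5) / (prob.nb - prob.rb + 0.5))
        mu = mu + 0.2 * rng.standard_normal(nt)
    else:
        mu = None

    s_delta = _AdaptiveScale((nc,))
    s_theta = _AdaptiveScale((npar,), init=0.3)
    s_mu = _AdaptiveScale((nt,)) if prob.kind == "binomial" else None
    s_tau = _AdaptiveScale(None, init=0.3)

    n_iter = spec.burn_in + spec.samples
    kept = spec.samples // spec.thin
    d_store = np.zeros((kept, npar))
    tau_store = np.zeros(kept)
    dev_store = np.zeros(kept)
    delta_sum = np.zeros(nc)
    mu_sum = np.zeros(nt) if prob.kind == "binomial" else None
    n_kept = 0

    tw = prob.tw
    two_trials = prob.two_arm_trials
    c_trial = prob.c_trial_arr

    def data_ll_tw(dlt):
        if prob.kind == "normal":
            return -0.5 * (prob.y[tw] - dlt) ** 2 / prob.v[tw]
        eta = mu[c_trial[tw]] + dlt
        p = _expit(eta)
        return prob.r[tw] * np.log(p) + (prob.n[tw] - prob.r[tw]) * np.log1p(-p)

    for it in range(n_iter):
        adapting = it < spec.burn_in

        # -- trial-specific effects delta ---------------------------------
        if not tau_zero:
            if len(tw):
                prop = delta[tw] + s_delta.scale[tw] * rng.standard_normal(len(tw))
                logr = data_ll_tw(prop) - data_ll_tw(delta[tw])
                z0 = delta[tw] - mean[tw]
                z1 = prop - mean[tw]
                logr += -0.5 * (z1**2 - z0**2) / tau**2
                acc = np.log(rng.random(len(tw))) < logr
                delta[tw[acc]] = prop[acc]
                if adapting:
                    upd = np.zeros(nc)
                    upd[tw] = acc
                    s_delta.acc += upd
            for t in prob.multi_trials:
                t = int(t)
                idx = prob.multi_contrasts[t]
                prop_all = delta.copy()
                prop_all[idx] = delta[idx] + s_delta.scale[idx] * rng.standard_normal(len(idx))
                if prob.kind == "normal":
                    logr = prob.normal_trial_loglik(t, prop_all) - prob.normal_trial_loglik(t, delta)
                else:
                    logr = float(
                        np.sum(prob.data_loglik_contrasts(prop_all, mu, idx))
                        - np.sum(prob.data_loglik_contrasts(delta, mu, idx))
                    )
                logr += prob.re_logp_multi(t, prop_all, mean, tau) - prob.re_logp_multi(
                    t, delta, mean, tau
                )
                if math.log(rng.random()) < logr:
                    delta[idx] = prop_all[idx]
                    if adapting:
                        s_delta.acc[idx] += 1
            s_delta.tries += 1

        # -- study baselines mu (binomial only) ----------------------------
        if prob.kind == "binomial":
            prop_mu = mu + s_mu.scale * rng.standard_normal(nt)
            ll0 = prob.anchor_loglik(mu) + np.bincount(
                c_trial, weights=prob.data_loglik_contrasts(delta, mu), minlength=nt
            )
            ll1 = prob.anchor_loglik(prop_mu) + np.bincount(
                c_trial, weights=prob.data_loglik_contrasts(delta, prop_mu), minlength=nt
            )
            logr = ll1 - ll0 - 0.5 * (prop_mu**2 - mu**2) / prior_var
            acc = np.log(rng.random(nt)) < logr
            mu[acc] = prop_mu[acc]
            s_mu.record(acc)

        # -- basic / extra parameters theta --------------------------------
        for p in range(npar):
            idx = prob.col_idx[p]
            if len(idx) == 0:
                continue
            step = s_theta.scale[p] * rng.standard_normal()
            new = theta[p] + step
            dmean = prob.A[idx, p] * step
            logr = -0.5 * (new**2 - theta[p] ** 2) / prior_var
            if tau_zero:
                # delta tracks the mean exactly; data likelihood moves
                itw = idx[np.isin(c_trial[idx], two_trials)]
                if len(itw):
                    shift = prob.A[itw, p] * step
                    if prob.kind == "normal":
                        r0 = prob.y[itw] - delta[itw]
                        r1 = r0 - shift
                        logr += float(np.sum(-0.5 * (r1**2 - r0**2) / prob.v[itw]))
                    else:
                        nd = _with(delta, itw, delta[itw] + shift)
                        logr += float(
                            np.sum(prob.data_loglik_contrasts(nd, mu, itw))
                            - np.sum(prob.data_loglik_contrasts(delta, mu, itw))
                        )
                for t in prob.multi_trials:
                    t = int(t)
                    mi = prob.multi_contrasts[t]
                    if not np.any(prob.A[mi, p]):
                        continue
                    nd = _with(delta, mi, delta[mi] + prob.A[mi, p] * step)
                    if prob.kind == "normal":
                        logr += prob.normal_trial_loglik(t, nd) - prob.normal_trial_loglik(t, delta)
                    else:
                        logr += float(
                            np.sum(prob.data_loglik_contrasts(nd, mu, mi))
                            - np.sum(prob.data_loglik_contrasts(delta, mu, mi))
                        )
            else:
                itw = idx[np.isin(c_trial[idx], two_trials)]
                if len(itw):
                    z0 = delta[itw] - mean[itw]
                    z1 = z0 - prob.A[itw, p] * step
                    logr += float(np.sum(-0.5 * (z1**2 - z0**2) / tau**2))
                for t in prob.multi_trials:
                    t = int(t)
                    mi = prob.multi_contrasts[t]
                    if not np.any(prob.A[mi, p]):
                        continue
                    nm = _with(mean, mi, mean[mi] + prob.A[mi, p] * step)
                    logr += prob.re_logp_multi(t, delta, nm, tau) - prob.re_logp_multi(
                        t, delta, mean, tau
                    )
            if math.log(rng.random()) < logr:
                theta[p] = new
                mean[idx] = mean[idx] + dmean
                if tau_zero:
                    delta[idx] = mean[idx]
                if adapting:
                    s_theta.acc[p] += 1
        s_theta.tries += 1

        # -- heterogeneity SD tau ------------------------------------------
        if sample_tau:
            prop_tau = tau + s_tau.scale * rng.standard_normal()
            if lo < prop_tau < hi and prop_tau > 0:
                logr = 0.0
                if len(tw):
                    logr += float(
                        np.sum(
                            prob.re_logp_two(delta, mean, prop_tau, tw)
                            - prob.re_logp_two(delta, mean, tau, tw)
                        )
                    )
                for t in prob.multi_trials:
                    t = int(t)
                    logr += prob.re_logp_multi(t, delta, mean, prop_tau) - prob.re_logp_multi(
                        t, delta, mean, tau
                    )
                if math.log(rng.random()) < logr:
                    tau = float(prop_tau)
                    if adapting:
                        s_tau.acc += 1
            s_tau.tries += 1

        if adapting and (it + 1) % _ADAPT_INTERVAL == 0:
            s_delta.adapt()
            s_theta.adapt()
            s_tau.adapt()
            if s_mu is not None:
                s_mu.adapt()

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0 and n_kept < kept:
            d_store[n_kept] = theta
            tau_store[n_kept] = tau
            dev_store[n_kept] = prob.deviance(delta, mu)
            delta_sum += delta
            if mu_sum is not None:
                mu_sum += mu
            n_kept += 1

    return d_store, tau_store, dev_store, delta_sum / n_kept, (
        mu_sum / n_kept if mu_sum is not None else None
    )


def _with(arr, idx, values):
    out = arr.copy()
    out[idx] = values
    return out


def _fit_problem(prob: _Problem, outcome_id: str, spec: ModelSpec) -> NMAPosterior:
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = ss.spawn(spec.n_chains)
    d_all, tau_all, dev_all = [], [], []
    delta_mean = np.zeros(prob.n_contrasts)
    mu_mean = np.zeros(prob.n_trials) if prob.kind == "binomial" else None
    for c in range(spec.n_chains):
        rng = np.random.default_rng(child_seeds[c])
        d, t, dev, dmean, mumean = _run_chain(prob, spec, rng, c)
        d_all.append(d)
        tau_all.append(t)
        dev_all.append(dev)
        delta_mean += dmean / spec.n_chains
        if mu_mean is not None:
            mu_mean += mumean / spec.n_chains
    theta_draws = np.stack(d_all)  # (chains, kept, npar)
    tau_draws = np.stack(tau_all)
    dev_draws = np.stack(dev_all)

    dbar = float(dev_draws.mean())
    dhat = prob.deviance(delta_mean, mu_mean)
    pd_ = dbar - dhat
    dic = (dbar, pd_, dbar + pd_)

    n_basic = len(prob.t_ids) - 1 if prob.mode != "ume" else 0
    T = len(prob.t_ids)
    if prob.mode == "ume":
        d_draws = np.zeros((spec.n_chains, theta_draws.shape[1], T))
        extra_names = tuple(prob.param_names)
        extra_draws = theta_draws
    else:
        d_draws = np.concatenate(
            [np.zeros((spec.n_chains, theta_draws.shape[1], 1)), theta_draws[:, :, :n_basic]],
            axis=2,
        )
        extra_names = tuple(prob.param_names[n_basic:])
        extra_draws = theta_draws[:, :, n_basic:]

    rhat, mc = {}, {}
    for p, name in enumerate(prob.param_names):
        rhat[name] = split_rhat(theta_draws[:, :, p])
        mc[name] = batch_mc_error(theta_draws[:, :, p])
    if not (spec.tau_prior[0] == "fixed"):
        rhat["tau"] = split_rhat(tau_draws)
        mc["tau"] = batch_mc_error(tau_draws)

    post = NMAPosterior(
        treatment_ids=tuple(prob.t_ids),
        reference=prob.ref,
        kind=prob.kind,
        measure=SMD if prob.kind == "normal" else LOG_OR,
        outcome_id=outcome_id,
        d_draws=d_draws,
        tau_draws=tau_draws,
        extra_names=extra_names,
        extra_draws=extra_draws,
        deviance_draws=dev_draws,
        rhat=rhat,
        mc_error=mc,
        dic=dic,
        spec=spec,
        mode=prob.mode,
    )
    bad = {k: v for k, v in rhat.items() if np.isfinite(v) and v > spec.rhat_threshold}
    if bad:
        msg = f"rhat above {spec.rhat_threshold} for: {sorted(bad)}"
        if spec.strict_convergence:
            raise ConvergenceError(msg, diagnostics=rhat)
        logger.warning("%s (outcome %s)", msg, outcome_id)
    return post


def fit(ds: NetworkDataset, outcome_id: str, spec: ModelSpec | None = None) -> NMAPosterior:
    """Fit the random-effects consistency model for one outcome.

    Runs ``spec.n_chains`` chains from over-dispersed initial values,
    discards ``spec.burn_in`` iterations and retains ``spec.samples``
    (thinned).  Raises :class:`DisconnectedNetworkError` when the outcome's
    network is not connected and, under ``strict_convergence``, a
    :class:`ConvergenceError` carrying the diagnostics when any split-chain
    rhat exceeds the threshold.
    """
    spec = spec or ModelSpec()
    prob = build_problem(ds, outcome_id, spec, mode="consistency")
    dropped = tuple(sorted(set(ds.treatment_ids) - set(prob.t_ids)))
    post = _fit_problem(prob, outcome_id, spec)
    return replace_dropped(post, dropped)


def replace_dropped(post: NMAPosterior, dropped: tuple[str, ...]) -> NMAPosterior:
    if dropped:
        post = replace(post, dropped_treatments=dropped)
    return post


def dic(post: NMAPosterior) -> tuple[float, float, float]:
    """(Dbar, pD, DIC) with pD = Dbar - D(posterior mean)."""
    return post.dic


# ---------------------------------------------------------------------------
# League tables


def league(
    post: NMAPosterior,
    measure: str | None = None,
    order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Full league table: every ordered pair of treatments.

    Cell (row, col) summarizes the effect of the column treatment versus
    the row treatment: median and central 95% CrI of the contrast draws,
    exponentiated for odds ratios.  ``order`` (e.g. by SUCRA) fixes the
    row/column ordering; default is the posterior's treatment order.
    """
    measure = measure or post.measure
    ts = list(order) if order is not None else list(post.treatment_ids)
    rows = []
    for a in ts:
        for b in ts:
            if a == b:
                null = 0.0 if measure == SMD else 1.0
                rows.append(
                    {"row": a, "col": b, "median": null, "ci95_low": null,
                     "ci95_high": null, "significant": False}
                )
                continue
            draws = post.contrast_draws(b, a)  # column vs row
            med = float(np.median(draws))
            lo_, hi_ = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))
            if measure == LOG_OR:
                med, lo_, hi_ = math.exp(med), math.exp(lo_), math.exp(hi_)
                sig = not (lo_ <= 1.0 <= hi_)
            else:
                sig = not (lo_ <= 0.0 <= hi_)
            rows.append(
                {"row": a, "col": b, "median": med, "ci95_low": lo_,
                 "ci95_high": hi_, "significant": sig}
            )
    return pd.DataFrame(rows, columns=["row", "col", "median", "ci95_low", "ci95_high", "significant"])


def league_cells(post: NMAPosterior, measure: str | None = None) -> list[LeagueCell]:
    df = league(post, measure=measure)
    return [
        LeagueCell(
            row=r.row, col=r.col, median=r.median,
            ci95=(r.ci95_low, r.ci95_high), significant=bool(r.significant),
        )
        for r in df.itertuples()
    ]
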
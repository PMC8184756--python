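"""Q-learning agents, maximum-likelihood fitting and trial-wise regressors.

Two nested models of choice in the probabilistic learning task:

* QL — standard Q-learning. Cue values start at 0 EUR, and after each
  outcome the chosen cue's value is updated by ``Q <- Q + alpha * delta``
  with prediction error ``delta = R - Q`` (obtained minus expected outcome).
  Choices follow a softmax of cue values with inverse temperature beta.
* QLr — QL plus a repetition bias theta added, inside the softmax, to the
  value of the cue chosen at the *previous presentation of the same pair*.
  QL is QLr with theta = 0.

The default softmax is multiplicative, ``p(a) ∝ exp(beta * (Qa + theta *
rep_a))``, which is the convention under which beta is an inverse
temperature; a divisive variant ``p(a) ∝ exp((Qa + theta * rep_a) / beta)``
is available via ``convention="divisive"``.

Model fits are compared by BIC = ln(n_trials) * k + 2 * NLL (lower better).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json
import math

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .task import PUNISHMENT, REWARD, TaskConfig, build_session_schedule

MULTIPLICATIVE = "multiplicative"
DIVISIVE = "divisive"

#: per-trial likelihood floor guarding the log against underflow
P_FLOOR = 1e-12

#: optimizer bounds for (alpha, beta, theta)
FIT_BOUNDS = {"alpha": (0.0, 1.0), "beta": (0.05, 20.0), "theta": (-2.0, 2.0)}


@dataclass(frozen=True)
class AgentParameters:
    """Parameters of a QL/QLr agent."""

    alpha: float
    beta: float
    theta: float = 0.0
    model_kind: str = "QLr"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.model_kind not in ("QL", "QLr"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.model_kind == "QL" and self.theta != 0.0:
            raise ValueError("QL has no repetition bias; use model_kind='QLr'")

    @property
    def n_params(self) -> int:
        return 2 if self.model_kind == "QL" else 3

    def as_vector(self) -> np.ndarray:
        if self.model_kind == "QL":
            return np.array([self.alpha, self.beta])
        return np.array([self.alpha, self.beta, self.theta])


#: Published group-mean parameters of the two models (cohort of 20 patients).
TABLE1_QL = AgentParameters(alpha=0.27, beta=3.80, model_kind="QL")
TABLE1_QLR = AgentParameters(alpha=0.26, beta=3.19, theta=0.44, model_kind="QLr")


def choice_probability(
    params: AgentParameters,
    q_pair: np.ndarray,
    repeat_flags: np.ndarray | None = None,
    convention: str = MULTIPLICATIVE,
) -> np.ndarray:
    """Softmax probability of choosing each of a pair's two cues.

    ``repeat_flags`` marks the cue chosen at this pair's previous
    presentation (one-hot, or all-zero before the first choice).
    """
    q = np.asarray(q_pair, dtype=float)
    rep = np.zeros_like(q) if repeat_flags is None else np.asarray(repeat_flags, dtype=float)
    util = q + params.theta * rep
    if convention == MULTIPLICATIVE:
        logits = params.beta * util
    elif convention == DIVISIVE:
        if params.beta == 0.0:
            raise ValueError("divisive convention requires beta > 0")
        logits = util / params.beta
    else:
        raise ValueError(f"unknown softmax convention {convention!r}")
    logits = logits - logits.max()
    e = np.exp(logits)
    return e / e.sum()


@dataclass
class AgentState:
    """Mutable learning state over one session: Q per (pair, cue), last choice per pair."""

    q_values: np.ndarray  # (n_pairs, 2), EUR
    last_choice: np.ndarray  # (n_pairs,), -1 before first presentation

    @classmethod
    def initial(cls, n_pairs: int) -> "AgentState":
        return cls(q_values=np.zeros((n_pairs, 2)), last_choice=np.full(n_pairs, -1))


def apply_update(
    state: AgentState, pair_id: int, chosen: int, outcome: float, alpha: float
) -> float:
    """Update the chosen cue's value in place; return the prediction error."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if not 0 <= pair_id < state.q_values.shape[0] or chosen not in (0, 1):
        raise KeyError(f"unknown pair/cue ({pair_id}, {chosen})")
    delta = outcome - state.q_values[pair_id, chosen]
    state.q_values[pair_id, chosen] += alpha * delta
    state.last_choice[pair_id] = chosen
    return delta


def _repeat_flags(state: AgentState, pair_id: int) -> np.ndarray:
    rep = np.zeros(2)
    if state.last_choice[pair_id] >= 0:
        rep[state.last_choice[pair_id]] = 1.0
    return rep


def simulate_agent(
    params: AgentParameters,
    schedule: pd.DataFrame,
    rng: np.random.Generator | int,
    config: TaskConfig | None = None,
    convention: str = MULTIPLICATIVE,
) -> pd.DataFrame:
    """Play one session schedule with a QL/QLr agent.

    Returns the full behavioral session table: the schedule columns plus
    ``chosen_cue``, ``chosen_side``, ``correct``, ``outcome`` and a lognormal
    ``rt_ms`` (slower in the punishment condition, matching the observed
    asymmetry; RTs feed no model equation).
    """
    rng = np.random.default_rng(rng)
    n_pairs = int(schedule["pair_id"].max()) + 1
    state = AgentState.initial(n_pairs)

    chosen = np.empty(len(schedule), dtype=int)
    outcomes = np.empty(len(schedule))
    for i, row in enumerate(schedule.itertuples(index=False)):
        pid = row.pair_id
        p = choice_probability(params, state.q_values[pid], _repeat_flags(state, pid), convention)
        c = int(rng.random() < p[1])
        chosen[i] = c
        outcomes[i] = row.outcome_cue1 if c == 1 else row.outcome_cue0
        apply_update(state, pid, c, outcomes[i], params.alpha)

    out = schedule.copy()
    out["chosen_cue"] = chosen
    out["correct"] = chosen == 0
    out["outcome"] = outcomes
    side0 = out["side_of_cue0"].to_numpy()
    out["chosen_side"] = np.where(
        chosen == 0, side0, np.where(side0 == "left", "right", "left")
    )
    out["cue_left"] = np.where(side0 == "left", 0, 1)
    out["cue_right"] = 1 - out["cue_left"]
    is_pun = (out["condition"] == PUNISHMENT).to_numpy()
    median_rt = np.where(is_pun, 1.09, 0.70)
    out["rt_ms"] = 1000.0 * median_rt * np.exp(rng.normal(0.0, 0.35, len(out)))
    return out


def session_log_likelihood(
    params: AgentParameters,
    sessions: list[pd.DataFrame] | pd.DataFrame,
    convention: str = MULTIPLICATIVE,
    naive: bool = False,
) -> float:
    """Negative log-likelihood of observed choices under a QL/QLr agent.

    Learning state resets at each session boundary (each session introduces
    new cue pairs). Per-trial likelihoods are floored at ``P_FLOOR``.

    ``naive=True`` routes through :func:`choice_probability` /
    :func:`apply_update` trial by trial; the default path uses equivalent
    scalar arithmetic (it is what the optimizer hammers).
    """
    if isinstance(sessions, pd.DataFrame):
        sessions = [sessions]
    if naive:
        return _nll_naive(params, sessions, convention)
    alpha, beta, theta = params.alpha, params.beta, params.theta
    divisive = convention == DIVISIVE
    if convention not in (MULTIPLICATIVE, DIVISIVE):
        raise ValueError(f"unknown softmax convention {convention!r}")
    if divisive and beta == 0.0:
        raise ValueError("divisive convention requires beta > 0")
    nll = 0.0
    for sess in sessions:
        pair_ids = sess["pair_id"].to_numpy().tolist()
        choices = sess["chosen_cue"].to_numpy().tolist()
        outcomes = sess["outcome"].to_numpy().tolist()
        n_pairs = max(pair_ids) + 1
        q0 = [0.0] * n_pairs
        q1 = [0.0] * n_pairs
        last = [-1] * n_pairs
        for pid, c, r in zip(pair_ids, choices, outcomes):
            u0, u1 = q0[pid], q1[pid]
            if last[pid] == 0:
                u0 += theta
            elif last[pid] == 1:
                u1 += theta
            d = (u1 - u0) / beta if divisive else beta * (u1 - u0)
            # p(observed): logistic of the signed utility difference
            if c == 1:
                d = -d
            p = 0.0 if d > 700.0 else 1.0 / (1.0 + math.exp(d))
            nll -= math.log(p if p > P_FLOOR else P_FLOOR)
            if c == 0:
                q0[pid] += alpha * (r - q0[pid])
            else:
                q1[pid] += alpha * (r - q1[pid])
            last[pid] = c
    return nll


def _nll_naive(params: AgentParameters, sessions: list[pd.DataFrame], convention: str) -> float:
    """Reference per-trial loop through the public softmax/update operations."""
    nll = 0.0
    for sess in sessions:
        n_pairs = int(sess["pair_id"].max()) + 1
        state = AgentState.initial(n_pairs)
        pair_ids = sess["pair_id"].to_numpy()
        choices = sess["chosen_cue"].to_numpy()
        outcomes = sess["outcome"].to_numpy()
        for pid, c, r in zip(pair_ids, choices, outcomes):
            p = choice_probability(params, state.q_values[pid], _repeat_flags(state, pid), convention)
            nll -= math.log(max(p[c], P_FLOOR))
            apply_update(state, pid, c, r, params.alpha)
    return nll


@dataclass
class ModelFit:
    """Best-of-starts maximum-likelihood fit of one patient."""

    params: AgentParameters
    nll: float
    bic: float
    n_trials: int
    n_params: int
    n_starts_used: int
    converged: bool

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = asdict(self.params)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def bic_score(nll: float, n_trials: int, n_params: int) -> float:
    """BIC = ln(n_trials) * n_params + 2 * NLL."""
    return math.log(n_trials) * n_params + 2.0 * nll


def fit_patient(
    sessions: list[pd.DataFrame],
    model_kind: str = "QLr",
    n_starts: int = 20,
    rng: np.random.Generator | int = 0,
    convention: str = MULTIPLICATIVE,
) -> ModelFit:
    """Fit QL or QLr to one patient's sessions by multi-start bounded ML.

    Starting points are drawn uniformly within the optimizer bounds; the
    lowest-NLL local optimum across starts is returned.
    """
    if not sessions:
        raise ValueError("at least one session required")
    rng = np.random.default_rng(rng)
    n_trials = sum(len(s) for s in sessions)
    k = 2 if model_kind == "QL" else 3
    names = ["alpha", "beta"] if model_kind == "QL" else ["alpha", "beta", "theta"]
    bounds = [FIT_BOUNDS[n] for n in names]

    def objective(x: np.ndarray) -> float:
        theta = 0.0 if model_kind == "QL" else x[2]
        p = AgentParameters(alpha=x[0], beta=x[1], theta=theta, model_kind="QLr")
        return session_log_likelihood(p, sessions, convention)

    best = None
    any_converged = False
    for _ in range(n_starts):
        x0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all optimizer starts failed")

    theta = 0.0 if model_kind == "QL" else float(best.x[2])
    params = AgentParameters(
        alpha=float(best.x[0]), beta=float(best.x[1]), theta=theta, model_kind=model_kind
    )
    return ModelFit(
        params=params,
        nll=float(best.fun),
        bic=bic_score(float(best.fun), n_trials, k),
        n_trials=n_trials,
        n_params=k,
        n_starts_used=n_starts,
        converged=any_converged,
    )


def compare_models(fits_ql: list[ModelFit], fits_qlr: list[ModelFit]) -> dict:
    """Paired comparison of BIC between QL and QLr across patients.

    Returns the mean BIC difference (QLr - QL; negative favours QLr) and a
    two-sided one-sample t-test on the per-patient differences.
    """
    if len(fits_ql) != len(fits_qlr):
        raise ValueError("fit lists must be patient-matched")
    if len(fits_ql) < 2:
        raise ValueError("need at least 2 patients to compare models")
    diff = np.array([b.bic - a.bic for a, b in zip(fits_ql, fits_qlr)])
    if np.allclose(diff, 0.0):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_1samp(diff, 0.0)
    return {
        "delta_bic_mean": float(diff.mean()),
        "delta_bic_sem": float(diff.std(ddof=1) / math.sqrt(len(diff))),
        "t": float(t),
        "p": float(p),
        "n_patients": len(diff),
        "favoured": "QLr" if diff.mean() < 0 else ("QL" if diff.mean() > 0 else "tie"),
    }


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0.0:
        raise ValueError("cannot z-score a constant regressor (zero variance)")
    return (x - x.mean()) / sd


def derive_regressors(
    fit: ModelFit,
    sessions: list[pd.DataFrame],
    convention: str = MULTIPLICATIVE,
) -> pd.DataFrame:
    """Replay fitted learning over observed choices and build neural regressors.

    One row per trial across all sessions, in presentation order:

    * ``pe`` — raw prediction error R - Q for the chosen cue;
    * ``pe_all_z`` — PE z-scored across *all* of the patient's trials;
    * ``pe_cond_z`` — PE z-scored within condition (RPE / PPE regressors);
    * ``outcome_z`` / ``expectation_z`` — R and pre-update Q(chosen),
      z-scored within condition (the PE decomposition of the two-regressor
      model);
    * ``trial_index_z`` — within-session trial index covariate.
    """
    rows = []
    for s_idx, sess in enumerate(sessions):
        n_pairs = int(sess["pair_id"].max()) + 1
        state = AgentState.initial(n_pairs)
        for row in sess.itertuples(index=False):
            q_before = state.q_values[row.pair_id, row.chosen_cue]
            delta = apply_update(state, row.pair_id, row.chosen_cue, row.outcome, fit.params.alpha)
            rows.append(
                {
                    "session": s_idx,
                    "trial": row.trial,
                    "pair_id": row.pair_id,
                    "condition": row.condition,
                    "outcome": row.outcome,
                    "expectation": q_before,
                    "pe": delta,
                }
            )
    reg = pd.DataFrame(rows)
    reg["pe_all_z"] = _zscore(reg["pe"].to_numpy())
    for col_src, col_dst in [("pe", "pe_cond_z"), ("outcome", "outcome_z"), ("expectation", "expectation_z")]:
        out = np.empty(len(reg))
        for cond in (REWARD, PUNISHMENT):
            m = (reg["condition"] == cond).to_numpy()
            if m.any():
                out[m] = _zscore(reg.loc[m, col_src].to_numpy())
        reg[col_dst] = out
    reg["trial_index_z"] = _zscore(reg["trial"].to_numpy().astype(float))
    return reg


def performance_summary(sessions: list[pd.DataFrame]) -> dict:
    """Correct-choice rates, 24-point learning curves and median RT per condition."""
    if not sessions:
        raise ValueError("at least one session required")
    # within-pair presentation index, per session
    parts = []
    for sess in sessions:
        p = sess.groupby("pair_id").cumcount() + 1
        parts.append(pd.DataFrame({"condition": sess["condition"], "presentation": p,
                                   "correct": sess["correct"], "rt_ms": sess.get("rt_ms", np.nan)}))
    long = pd.concat(parts, ignore_index=True)

    out: dict = {"correct_rate": {}, "learning_curve": {}, "median_rt_ms": {}}
    for cond in (REWARD, PUNISHMENT):
        sub = long[long["condition"] == cond]
        if len(sub) == 0:
            continue
        out["correct_rate"][cond] = float(sub["correct"].mean())
        curve = sub.groupby("presentation")["correct"].mean()
        out["learning_curve"][cond] = curve.sort_index().to_numpy()
        out["median_rt_ms"][cond] = float(np.nanmedian(sub["rt_ms"]))
    return out


def simulate_patient(
    params: AgentParameters,
    config: TaskConfig,
    rng: np.random.Generator | int,
    convention: str = MULTIPLICATIVE,
) -> list[pd.DataFrame]:
    """Simulate all of one patient's sessions (fresh cue pairs per session)."""
    rng = np.random.default_rng(rng)
    sessions = []
    for _ in range(config.n_sessions):
        schedule = build_session_schedule(config, rng)
        sessions.append(simulate_agent(params, schedule, rng, config, convention))
    return sessions
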
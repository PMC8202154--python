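"""Survival analysis for evaluating biological versus chronological age.

Implements the Cox proportional-hazards partial likelihood (Efron or
Breslow tie handling) with a Newton solver, because the headline statistic
of the pipeline — the proportion of the combined BA+CA effect on an outcome
explained by BA alone — is a ratio of *nested partial log-likelihood gains*
and needs exact likelihood values at the null as well as at the fit:

    proportion_explained = (ll_BA - ll_null) / (ll_BA+CA - ll_null)

Around that core: likelihood-ratio tests for adding BA over CA, Harrell's
C-index (unadjusted, and adjusted by scoring the linear predictor of a Cox
fit that includes sociodemographic covariates), Kaplan–Meier curves with
log-rank tests for age-acceleration groups, and the forward-stepwise Cox
"mortality score" benchmark.  Kaplan–Meier, log-rank and the concordance
computation are delegated to lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from scipy import stats

from .errors import (
    DegenerateDataError,
    EmptyRiskSetError,
    NotNestedError,
    OrderingError,
)

__all__ = [
    "SurvivalFit",
    "fit_cox",
    "cox_log_likelihood",
    "proportion_explained",
    "likelihood_ratio_test",
    "harrells_c",
    "adjusted_c",
    "kaplan_meier",
    "log_rank",
    "survival_at",
    "stepwise_mortality_score",
    "build_design",
    "evaluate_outcome",
    "OutcomeEvaluation",
]

# |coefficient| beyond this marks a diverging (monotone-likelihood) fit: a
# hazard ratio above e^10 per unit is not a finite maximizer in practice.
_BETA_CAP = 10.0


@dataclass
class SurvivalFit:
    """A maximized Cox partial likelihood."""

    params: pd.Series  # coefficient per covariate name
    ll: float  # log partial likelihood at the estimate
    ll_null: float  # log partial likelihood at beta = 0
    n: int
    n_events: int
    converged: bool
    max_gradient: float
    ties: str

    @property
    def names(self) -> list[str]:
        return list(self.params.index)

    def linear_predictor(self, covariates: pd.DataFrame) -> np.ndarray:
        x = covariates[self.names].to_numpy(dtype=float)
        return x @ self.params.to_numpy()


def _prepare(times, events, x):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise EmptyRiskSetError("empty risk set: no rows")
    if np.any(times <= 0):
        raise DegenerateDataError("all survival times must be > 0")
    if events.sum() == 0:
        raise EmptyRiskSetError("no events in risk set")
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if not np.isfinite(x).all():
        raise DegenerateDataError("covariates must be finite")
    order = np.argsort(times, kind="stable")
    return times[order], events[order], x[order]


def _efron_terms(times, events, fraction_for_ties):
    """Per-event-row group pointers and tie fractions l/d (0 for Breslow)."""
    ev = events.astype(bool)
    uniq, counts = np.unique(times[ev], return_counts=True)
    # index of the first row (sorted order) with time >= t, for risk sums
    risk_start = np.searchsorted(times, uniq, side="left")
    group_of_event = np.repeat(np.arange(uniq.size), counts)
    if fraction_for_ties:
        phi = np.concatenate([np.arange(d) / d for d in counts])
    else:
        phi = np.zeros(group_of_event.size)
    return ev, counts, risk_start, group_of_event, phi


def _ll_grad_hess(beta, times, events, x, ties, need_derivs=True):
    """Log partial likelihood (and optionally gradient/Hessian) at ``beta``.

    Data must be pre-sorted by time ascending.  Uses suffix cumulative sums
    for the risk-set aggregates and the Efron within-tie correction
    (``ties='breslow'`` sets the tie fraction to zero).
    """
    n, p = x.shape
    eta = x @ beta
    shift = eta.max()
    w = np.exp(eta - shift)

    r0 = np.cumsum(w[::-1])[::-1]
    r1 = np.cumsum((w[:, None] * x)[::-1], axis=0)[::-1]

    ev, counts, risk_start, g_of_e, phi = _efron_terms(
        times, events, fraction_for_ties=(ties == "efron")
    )
    ev_idx = np.nonzero(ev)[0]
    w_ev = w[ev_idx]
    x_ev = x[ev_idx]
    # tied-set sums per unique event time
    bounds = np.concatenate([[0], np.cumsum(counts)])[:-1]
    s0 = np.add.reduceat(w_ev, bounds)
    s1 = np.add.reduceat(w_ev[:, None] * x_ev, bounds, axis=0)

    denom = r0[risk_start][g_of_e] - phi * s0[g_of_e]
    ll = float((eta[ev_idx] - shift).sum() - np.log(denom).sum())
    if not need_derivs:
        return ll, None, None

    m = (r1[risk_start][g_of_e] - phi[:, None] * s1[g_of_e]) / denom[:, None]
    grad = x_ev.sum(axis=0) - m.sum(axis=0)

    r2 = np.cumsum((w[:, None, None] * (x[:, :, None] * x[:, None, :]))[::-1], axis=0)[::-1]
    s2 = np.add.reduceat(
        w_ev[:, None, None] * (x_ev[:, :, None] * x_ev[:, None, :]), bounds, axis=0
    )
    a2 = (r2[risk_start][g_of_e] - phi[:, None, None] * s2[g_of_e]) / denom[:, None, None]
    hess = (a2 - m[:, :, None] * m[:, None, :]).sum(axis=0)
    return ll, grad, hess


def cox_log_likelihood(beta, covariates, times, events, ties: str = "efron") -> float:
    """Cox log partial likelihood at an arbitrary coefficient vector."""
    times, events, x = _prepare(times, events, covariates)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    ll, _, _ = _ll_grad_hess(beta, times, events, x, ties, need_derivs=False)
    return ll


def fit_cox(
    covariates: pd.DataFrame | np.ndarray,
    times,
    events,
    *,
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 100,
) -> SurvivalFit:
    """Maximize the Cox partial likelihood by Newton iteration.

    Starts at beta=0 with step-halving whenever a step would decrease the
    likelihood; converges on an absolute log-likelihood change below
    ``tol``.  Monotone-likelihood data (perfect separation) is flagged
    ``converged=False`` with coefficients capped at +/-10.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie handling {ties!r}")
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
    else:
        arr = np.asarray(covariates, dtype=float)
        names = [f"x{i}" for i in range(1 if arr.ndim == 1 else arr.shape[1])]
    times_s, events_s, x = _prepare(times, events, covariates)
    n, p = x.shape

    beta = np.zeros(p)
    ll, grad, hess = _ll_grad_hess(beta, times_s, events_s, x, ties)
    ll_null = ll
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        scale = 1.0
        for _ in range(40):
            candidate = beta + scale * step
            ll_new, _, _ = _ll_grad_hess(candidate, times_s, events_s, x, ties, need_derivs=False)
            if ll_new >= ll - 1e-14:
                break
            scale *= 0.5
        improved = ll_new - ll
        beta = beta + scale * step
        ll, grad, hess = _ll_grad_hess(beta, times_s, events_s, x, ties)
        if abs(improved) < tol:
            converged = True
            break
    if not converged or np.any(np.abs(beta) > _BETA_CAP):
        converged = False
        warnings.warn(
            "Cox fit did not converge (possible monotone likelihood); "
            "coefficients capped",
            stacklevel=2,
        )
        beta = np.clip(beta, -_BETA_CAP, _BETA_CAP)
        ll, grad, _ = _ll_grad_hess(beta, times_s, events_s, x, ties)
    return SurvivalFit(
        params=pd.Series(beta, index=names),
        ll=ll,
        ll_null=ll_null,
        n=n,
        n_events=int(events_s.sum()),
        converged=converged,
        max_gradient=float(np.max(np.abs(grad))),
        ties=ties,
    )


def proportion_explained(ll_null: float, ll_ba: float, ll_both: float) -> float | None:
    """Share of the combined BA+CA log-likelihood gain attained by BA alone.

    ``(ll_ba - ll_null) / (ll_both - ll_null)``; None when the combined gain
    is numerically zero.  Ordering violations beyond 1e-8 indicate an
    upstream misfit and raise :class:`OrderingError`.
    """
    slack = 1e-8
    if ll_ba < ll_null - slack or ll_both < ll_ba - slack:
        raise OrderingError(
            f"expected ll_null <= ll_ba <= ll_both, got {ll_null}, {ll_ba}, {ll_both}"
        )
    denom = ll_both - ll_null
    if denom < slack:
        return None
    return float(np.clip((ll_ba - ll_null) / denom, 0.0, 1.0))


def likelihood_ratio_test(
    fit_reduced: SurvivalFit, fit_full: SurvivalFit
) -> tuple[float, int, float]:
    """LRT of nested Cox fits: statistic 2*(ll_full - ll_reduced), chi-square p."""
    if not set(fit_reduced.names) <= set(fit_full.names):
        raise NotNestedError(
            f"{fit_reduced.names} is not a subset of {fit_full.names}"
        )
    df = len(fit_full.names) - len(fit_reduced.names)
    statistic = max(2.0 * (fit_full.ll - fit_reduced.ll), 0.0)
    if df == 0:
        return statistic, 0, 1.0
    return statistic, df, float(stats.chi2.sf(statistic, df))


def harrells_c(risk_scores, times, events) -> float:
    """Harrell's concordance for a risk score (higher score = higher risk).

    Comparable pairs are those where the shorter observed time is an event;
    tied risk scores count 0.5.  Returns NaN when no pair is comparable.
    """
    risk_scores = np.asarray(risk_scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        return float("nan")
    try:
        return float(concordance_index(times, -risk_scores, events))
    except ZeroDivisionError:
        return float("nan")


def adjusted_c(
    risk_age,
    covariates: pd.DataFrame,
    times,
    events,
    *,
    ties: str = "efron",
) -> float:
    """Covariate-adjusted C: concordance of the Cox linear predictor.

    Fits a Cox model on the age variable plus the adjustment covariates
    (constant columns dropped) and scores concordance on the fitted linear
    predictor, so the age effect is assessed in the context of the
    sociodemographic adjustment set.
    """
    design = pd.DataFrame({"risk_age": np.asarray(risk_age, dtype=float)})
    design.index = covariates.index
    design = pd.concat([design, covariates], axis=1)
    keep = [c for c in design.columns if design[c].nunique() > 1]
    if not keep:
        raise DegenerateDataError("no non-constant columns to fit")
    fit = fit_cox(design[keep], times, events, ties=ties)
    return harrells_c(fit.linear_predictor(design[keep]), times, events)


def kaplan_meier(times, events, groups) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group.

    Returns, per group label, a DataFrame with columns ``time`` and
    ``survival`` (step function, starting at S(0)=1).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if groups.size == 0:
        raise EmptyRiskSetError("no rows to estimate survival curves from")
    out: dict[str, pd.DataFrame] = {}
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            raise EmptyRiskSetError(f"group {g!r} is empty")
        km = KaplanMeierFitter()
        km.fit(times[mask], events[mask])
        curve = km.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        out[str(g)] = curve
    return out


def log_rank(times, events, groups) -> tuple[float, int, float]:
    """Log-rank test across groups: (statistic, df, p); NaNs with no events."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    df = len(pd.unique(groups)) - 1
    if events.sum() == 0 or df == 0:
        return float("nan"), df, float("nan")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), df, float(res.p_value)


def survival_at(curve: pd.DataFrame, t: float) -> float:
    """Step-function evaluation of a Kaplan–Meier curve at time ``t``."""
    below = curve[curve["time"] <= t]
    if below.empty:
        return 1.0
    return float(below["survival"].iloc[-1])


def stepwise_mortality_score(
    scores: pd.DataFrame,
    times,
    events,
    *,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    ties: str = "efron",
    max_steps: int = 100,
) -> tuple[list[str], SurvivalFit | None, np.ndarray]:
    """Forward-stepwise Cox selection over component scores.

    Repeatedly adds the candidate with the smallest likelihood-ratio p-value
    below ``p_enter``, then removes any selected variable whose deletion
    p-value exceeds ``p_remove``.  Returns the selected names, the final fit
    (None if nothing entered) and the benchmark linear predictor (zeros when
    empty, giving C = 0.5 downstream).
    """
    selected: list[str] = []
    current: SurvivalFit | None = None
    for _ in range(max_steps):
        changed = False
        candidates = [c for c in scores.columns if c not in selected]
        best_p, best_c, best_fit = 1.0, None, None
        for c in candidates:
            trial = fit_cox(scores[selected + [c]], times, events, ties=ties)
            base_ll = current.ll if current is not None else trial.ll_null
            statistic = max(2.0 * (trial.ll - base_ll), 0.0)
            p = float(stats.chi2.sf(statistic, 1))
            if p < best_p:
                best_p, best_c, best_fit = p, c, trial
        if best_c is not None and best_p < p_enter:
            selected.append(best_c)
            current = best_fit
            changed = True
        # backward pass
        while current is not None and len(selected) > 1:
            worst_p, worst_c, worst_fit = -1.0, None, None
            for c in selected:
                reduced = [v for v in selected if v != c]
                trial = fit_cox(scores[reduced], times, events, ties=ties)
                statistic = max(2.0 * (current.ll - trial.ll), 0.0)
                p = float(stats.chi2.sf(statistic, 1))
                if p > worst_p:
                    worst_p, worst_c, worst_fit = p, c, trial
            if worst_c is not None and worst_p > p_remove and worst_c != best_c:
                selected.remove(worst_c)
                current = worst_fit
                changed = True
            else:
                break
        if not changed:
            break
    if current is None:
        warnings.warn("no component entered the stepwise model", stacklevel=2)
        return [], None, np.zeros(len(scores))
    return selected, current, current.linear_predictor(scores[selected])


def build_design(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Numeric design matrix: categoricals one-hot encoded (first level dropped)."""
    pieces = []
    for col in columns:
        if col not in table.columns:
            raise DegenerateDataError(f"covariate column {col!r} missing")
        s = table[col]
        if s.dtype.kind in "biufc" and s.nunique() > 6:
            pieces.append(s.astype(float).rename(col))
        else:
            dummies = pd.get_dummies(s.astype("category"), prefix=col, drop_first=True)
            pieces.append(dummies.astype(float))
    return pd.concat(pieces, axis=1)


@dataclass
class OutcomeEvaluation:
    """BA-versus-CA evaluation for one sex stratum and outcome."""

    outcome: str
    sex: str | None
    n: int
    n_events: int
    ll_null: float
    ll_ca: float
    ll_ba: float
    ll_both: float
    proportion_explained_ba: float | None
    proportion_explained_ca: float | None
    lrt_ba_over_ca: tuple[float, int, float]
    c_ca: float
    c_ba: float
    c_both: float
    c_ca_adjusted: float | None
    c_ba_adjusted: float | None
    c_both_adjusted: float | None
    km_curves: dict[str, pd.DataFrame]
    log_rank_test: tuple[float, int, float]
    group_fractions: dict[str, float]

    def check_ordering(self, slack: float = 1e-6) -> None:
        if not (
            self.ll_both >= max(self.ll_ca, self.ll_ba) - slack
            and min(self.ll_ca, self.ll_ba) >= self.ll_null - slack
        ):
            raise OrderingError(
                f"nested log-likelihood ordering violated for {self.sex}/{self.outcome}"
            )


def evaluate_outcome(
    table: pd.DataFrame,
    *,
    outcome: str,
    ba_col: str = "ba",
    ca_col: str = "ca",
    sex: str | None = None,
    adjust: list[str] | None = None,
    acceleration_threshold: float = 5.0,
    ties: str = "efron",
) -> OutcomeEvaluation:
    """Full nested-model comparison of BA and CA for one outcome.

    Fits Cox models with CA alone, BA alone and both; reports log-likelihoods,
    the proportion of the combined effect explained by each age, the LRT for
    adding BA over CA, Harrell's C for each predictor (the two-variable model
    scored on its linear predictor), optionally covariate-adjusted C-indices,
    and Kaplan–Meier curves with a log-rank test across the +/-5-year
    age-acceleration groups.
    """
    from .kdm import age_acceleration_groups  # local import to avoid a cycle

    times = table[f"{outcome}_time"].to_numpy(dtype=float)
    events = table[f"{outcome}_event"].to_numpy(dtype=int)
    ca = table[[ca_col]].rename(columns={ca_col: "ca"}).astype(float)
    ba = table[[ba_col]].rename(columns={ba_col: "ba"}).astype(float)
    both = pd.concat([ba, ca], axis=1)

    fit_ca = fit_cox(ca, times, events, ties=ties)
    fit_ba = fit_cox(ba, times, events, ties=ties)
    fit_both = fit_cox(both, times, events, ties=ties)
    ll_null = fit_ca.ll_null

    prop_ba = proportion_explained(ll_null, fit_ba.ll, fit_both.ll)
    prop_ca = proportion_explained(ll_null, fit_ca.ll, fit_both.ll)
    lrt = likelihood_ratio_test(fit_ca, fit_both)

    c_ca = harrells_c(ca["ca"].to_numpy(), times, events)
    c_ba = harrells_c(ba["ba"].to_numpy(), times, events)
    c_both = harrells_c(fit_both.linear_predictor(both), times, events)

    c_ca_adj = c_ba_adj = c_both_adj = None
    if adjust:
        design = build_design(table, adjust)
        c_ca_adj = adjusted_c(ca["ca"].to_numpy(), design, times, events, ties=ties)
        c_ba_adj = adjusted_c(ba["ba"].to_numpy(), design, times, events, ties=ties)
        both_design = pd.concat([both, design], axis=1)
        keep = [c for c in both_design.columns if both_design[c].nunique() > 1]
        fit_adj = fit_cox(both_design[keep], times, events, ties=ties)
        c_both_adj = harrells_c(fit_adj.linear_predictor(both_design[keep]), times, events)

    labels, fractions = age_acceleration_groups(
        ba["ba"].to_numpy(), ca["ca"].to_numpy(), acceleration_threshold
    )
    present = [g for g in ("younger", "similar", "older") if (labels == g).any()]
    km = kaplan_meier(times, events, labels) if present else {}
    lr = log_rank(times, events, labels) if len(present) > 1 else (float("nan"), 0, float("nan"))

    out = OutcomeEvaluation(
        outcome=outcome,
        sex=sex,
        n=len(table),
        n_events=int(events.sum()),
        ll_null=ll_null,
        ll_ca=fit_ca.ll,
        ll_ba=fit_ba.ll,
        ll_both=fit_both.ll,
        proportion_explained_ba=prop_ba,
        proportion_explained_ca=prop_ca,
        lrt_ba_over_ca=lrt,
        c_ca=c_ca,
        c_ba=c_ba,
        c_both=c_both,
        c_ca_adjusted=c_ca_adj,
        c_ba_adjusted=c_ba_adj,
        c_both_adjusted=c_both_adj,
        km_curves=km,
        log_rank_test=lr,
        group_fractions=fractions,
    )
    out.check_ordering()
    return out
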
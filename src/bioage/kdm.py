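"""Klemera–Doubal biological age on component scores, fitted per sex.

Each retained component score is regressed on chronological age (CA) by
ordinary least squares, giving intercept q_j, slope k_j and residual RMSE
s_j.  The biological age of a participant with score vector x is the
precision-weighted inversion of those regressions:

    BA = sum_j (x_j - q_j) * k_j / s_j^2  /  sum_j k_j^2 / s_j^2

i.e. each component votes for the age (x_j - q_j)/k_j at which its
regression line passes through x_j, weighted by how informative the
component is about age (k_j^2/s_j^2).  Chronological age itself is *not* a
constituent, so BA can be compared against CA downstream.  The estimator is
calibration-consistent: the normalized weights w_j = (k_j/s_j^2) / sum_i
k_i^2/s_i^2 satisfy sum_j w_j k_j = 1 exactly, so a participant whose every
score sits on its regression line at age a gets BA = a.

Component importance is the share of BA variance each component contributes,
share_j = w_j^2 Var(x_j) / Var(BA); with pairwise-uncorrelated scores the
shares sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError

__all__ = [
    "AgeRegression",
    "KDMModel",
    "fit_age_regressions",
    "fit_kdm",
    "compute_ba",
    "ba_r_squared",
    "component_importance",
    "calibration_table",
    "age_acceleration_groups",
]

SLOPE_EPS = 1e-12  # |k| below this marks a component non-informative
_S_FLOOR = 1e-8  # floor on s when a perfect fit would make weights blow up


@dataclass
class AgeRegression:
    """OLS of one component score on chronological age."""

    component: str
    q: float  # intercept, score units
    k: float  # slope, score units per year
    s: float  # residual RMSE (denominator n-2), score units
    n_fit: int
    degenerate: bool = False  # s ~ 0: score is an exact function of CA

    @property
    def informative(self) -> bool:
        """Whether the component carries any age signal (|k| > SLOPE_EPS)."""
        return abs(self.k) > SLOPE_EPS


def fit_age_regressions(
    scores: pd.DataFrame, ca: np.ndarray | pd.Series
) -> list[AgeRegression]:
    """Per-component OLS of score on CA over the fit rows.

    Requires at least 3 rows and non-degenerate CA variance.  A component
    with an (numerically) exact linear relation to CA is flagged
    ``degenerate``; a flat component (|slope| below ``SLOPE_EPS``) is flagged
    non-informative and later excluded from the BA weighted sum.
    """
    ca = np.asarray(ca, dtype=float)
    n = ca.shape[0]
    if n < 3:
        raise DegenerateDataError(f"need >= 3 fit rows, got {n}")
    ca_var = ca.var(ddof=1)
    if not ca_var > 0:
        raise DegenerateDataError("chronological age has zero variance on fit rows")
    ca_c = ca - ca.mean()
    out = []
    for name in scores.columns:
        x = scores[name].to_numpy(dtype=float)
        k = float(np.dot(ca_c, x - x.mean()) / np.dot(ca_c, ca_c))
        q = float(x.mean() - k * ca.mean())
        resid = x - (q + k * ca)
        s = float(np.sqrt(np.dot(resid, resid) / (n - 2)))
        degenerate = s < _S_FLOOR
        if degenerate:
            s = max(s, _S_FLOOR)
        out.append(AgeRegression(str(name), q, k, s, n, degenerate))
    return out


@dataclass
class KDMModel:
    """Fitted Klemera–Doubal estimator for one sex stratum."""

    sex: str | None
    regressions: list[AgeRegression]
    r_squared: float | None = None  # squared correlation of BA with CA on fit rows
    ba_sd_diff: float | None = None  # SD of BA - CA on fit rows
    s_ba2: float | None = None  # age-spread variance for the CA-corrected variant
    score_variances: dict[str, float] = field(default_factory=dict)

    @property
    def components(self) -> list[str]:
        return [r.component for r in self.regressions]

    @property
    def used(self) -> list[AgeRegression]:
        return [r for r in self.regressions if r.informative]

    @property
    def weights(self) -> pd.Series:
        """Normalized weights w_j with sum_j w_j k_j = 1 over used components."""
        used = self.used
        if not used:
            raise DegenerateDataError("no usable components: all slopes are ~0")
        denom = sum(r.k**2 / r.s**2 for r in used)
        return pd.Series({r.component: (r.k / r.s**2) / denom for r in used})


def compute_ba(
    scores: pd.DataFrame,
    model: KDMModel,
    ca: np.ndarray | pd.Series | None = None,
) -> np.ndarray:
    """Biological age for each row of ``scores``.

    With ``ca=None`` (default) this is the uncorrected estimator that
    excludes chronological age as a constituent.  Passing ``ca`` switches to
    the CA-corrected variant, which adds CA as a pseudo-biomarker with
    precision ``1/s_ba2`` (the estimated variance of true age spread around
    CA); it shrinks BA towards CA and is provided for comparison only.
    """
    used = model.used
    if not used:
        raise DegenerateDataError("no usable components: all slopes are ~0")
    missing = [r.component for r in used if r.component not in scores.columns]
    if missing:
        raise DegenerateDataError(f"scores table lacks components {missing}")
    x = scores[[r.component for r in used]].to_numpy(dtype=float)
    k = np.array([r.k for r in used])
    q = np.array([r.q for r in used])
    s2 = np.array([r.s**2 for r in used])
    num = ((x - q) * (k / s2)).sum(axis=1)
    den = float((k**2 / s2).sum())
    if ca is None:
        return num / den
    if model.s_ba2 is None:
        raise DegenerateDataError("model has no s_ba2; fit with fit_kdm first")
    ca = np.asarray(ca, dtype=float)
    if model.s_ba2 <= 0:  # degenerate: no age spread, BA collapses to CA
        return ca.copy()
    return (num + ca / model.s_ba2) / (den + 1.0 / model.s_ba2)


def ba_r_squared(ba: np.ndarray, ca: np.ndarray) -> float | None:
    """Squared Pearson correlation of BA with CA; None if either is constant."""
    ba = np.asarray(ba, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if ba.size < 2 or ba.std() == 0 or ca.std() == 0:
        return None
    return float(np.corrcoef(ba, ca)[0, 1] ** 2)


def fit_kdm(
    scores: pd.DataFrame,
    ca: np.ndarray | pd.Series,
    *,
    sex: str | None = None,
) -> KDMModel:
    """Fit the estimator and its diagnostics on the given fit rows."""
    regressions = fit_age_regressions(scores, ca)
    model = KDMModel(sex=sex, regressions=regressions)
    dropped = [r.component for r in regressions if not r.informative]
    if dropped:
        warnings.warn(
            f"dropping non-informative components (|slope| ~ 0): {dropped}",
            stacklevel=2,
        )
    ca = np.asarray(ca, dtype=float)
    ba = compute_ba(scores, model)
    model.r_squared = ba_r_squared(ba, ca)
    model.ba_sd_diff = float(np.std(ba - ca, ddof=1))
    # Propagated estimator variance: Var(BA | true age) = 1 / sum(k^2/s^2).
    used = model.used
    est_var = 1.0 / sum(r.k**2 / r.s**2 for r in used)
    model.s_ba2 = max(float(np.var(ba - ca, ddof=1) - est_var), 0.0)
    model.score_variances = {
        c: float(scores[c].to_numpy(dtype=float).var(ddof=1)) for c in scores.columns
    }
    return model


def component_importance(
    model: KDMModel, score_variances: dict[str, float] | None = None
) -> pd.DataFrame:
    """Share of BA variance contributed by each used component.

    ``share_j = w_j^2 Var(x_j) / Var(BA)`` with ``Var(BA)`` taken as the sum
    of the per-component terms, which equals the empirical BA variance when
    scores are pairwise uncorrelated (as rotated PCA scores are in-sample).
    Returned sorted by decreasing share with a 1-based ``rank`` column.
    """
    if score_variances is None:
        score_variances = model.score_variances
    w = model.weights
    missing = [c for c in w.index if c not in score_variances]
    if missing:
        raise DegenerateDataError(f"no score variance recorded for {missing}")
    terms = pd.Series({c: w[c] ** 2 * score_variances[c] for c in w.index})
    shares = terms / terms.sum()
    table = (
        shares.rename("share")
        .rename_axis("component")
        .reset_index()
        .sort_values("share", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def calibration_table(
    ba: np.ndarray, ca: np.ndarray, bin_width: float = 2.5
) -> pd.DataFrame:
    """Mean BA and mean CA within left-closed CA bins of ``bin_width`` years.

    Bins are anchored at multiples of the width ([40, 42.5), [42.5, 45), ...
    for the default); empty bins are omitted.
    """
    ba = np.asarray(ba, dtype=float)
    ca = np.asarray(ca, dtype=float)
    left = np.floor(ca / bin_width) * bin_width
    frame = pd.DataFrame({"bin_left": left, "ba": ba, "ca": ca})
    out = (
        frame.groupby("bin_left", sort=True)
        .agg(n=("ca", "size"), mean_ca=("ca", "mean"), mean_ba=("ba", "mean"))
        .reset_index()
    )
    out["bin_right"] = out["bin_left"] + bin_width
    return out[["bin_left", "bin_right", "n", "mean_ca", "mean_ba"]]


def age_acceleration_groups(
    ba: np.ndarray, ca: np.ndarray, threshold: float = 5.0
) -> tuple[np.ndarray, dict[str, float]]:
    """Classify rows as biologically younger / similar / older than their CA.

    ``younger``: BA - CA <= -threshold; ``older``: BA - CA >= +threshold
    (closed boundaries, "at least 5 years"); ``similar`` otherwise.  Returns
    the per-row labels and the group fractions.
    """
    diff = np.asarray(ba, dtype=float) - np.asarray(ca, dtype=float)
    labels = np.where(diff <= -threshold, "younger", np.where(diff >= threshold, "older", "similar"))
    n = max(labels.size, 1)
    fractions = {g: float((labels == g).sum()) / n for g in ("younger", "similar", "older")}
    return labels, fractions
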
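"""Biomarker principal components with varimax rotation, per sex.

The biomarker panel is standardized on a fit subset (the healthy rows of one
sex), decomposed by correlation-matrix PCA, reduced to the components whose
eigenvalue exceeds one third of the average variance per biomarker
(eigenvalue > 1/3, since the average eigenvalue of a correlation matrix is
1), and the retained loadings are rotated by varimax towards simple
structure.  Component scores are kept at unit variance in the fit sample and
remain exactly uncorrelated under the orthogonal rotation.

Sign convention: every component is flipped so that its largest-|loading|
biomarker loads positively, and rotated components are ordered by explained
variance (sum of squared loadings), which makes repeated runs byte-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, SchemaError

__all__ = [
    "Standardization",
    "PCAResult",
    "ComponentModel",
    "standardize",
    "fit_pca",
    "retain_components",
    "varimax_criterion",
    "varimax_rotate",
    "characterize_components",
    "fit_component_model",
]

EIGENVALUE_THRESHOLD = 1.0 / 3.0
LOADING_CUTOFF = 0.5


@dataclass
class Standardization:
    """Per-biomarker means and SDs estimated on the fit subset."""

    biomarkers: list[str]
    means: np.ndarray
    sds: np.ndarray

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        missing = [b for b in self.biomarkers if b not in table.columns]
        if missing:
            raise SchemaError(f"missing biomarker columns: {missing}")
        x = table[self.biomarkers].to_numpy(dtype=float)
        return pd.DataFrame(
            (x - self.means) / self.sds, columns=self.biomarkers, index=table.index
        )


def standardize(
    cohort: pd.DataFrame,
    biomarkers: list[str] | None = None,
    fit_rows: pd.Index | np.ndarray | None = None,
) -> tuple[pd.DataFrame, Standardization]:
    """Z-score biomarkers using statistics from ``fit_rows``.

    Returns the transformed table (all rows of ``cohort``) plus reusable
    parameters.  SDs use the n-1 denominator.  A biomarker with zero
    variance on the fit rows is unusable on the correlation scale and raises
    :class:`DegenerateDataError` naming it.
    """
    if biomarkers is None:
        biomarkers = list(cohort.columns)
    missing = [b for b in biomarkers if b not in cohort.columns]
    if missing:
        raise SchemaError(f"missing biomarker columns: {missing}")
    fit = cohort if fit_rows is None else cohort.loc[fit_rows]
    x = fit[biomarkers].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise DegenerateDataError("biomarker table contains missing values")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    for name, sd in zip(biomarkers, sds):
        if not sd > 0:
            raise DegenerateDataError(f"biomarker {name!r} has zero variance on fit rows")
    params = Standardization(list(biomarkers), means, sds)
    return params.transform(cohort), params


@dataclass
class PCAResult:
    """Correlation-matrix PCA: eigenvalues descending, loadings = V sqrt(L)."""

    eigenvalues: np.ndarray
    loadings: np.ndarray  # biomarkers x components, eigenvector_ij * sqrt(lambda_j)
    eigenvectors: np.ndarray
    scores: np.ndarray  # unit-variance scores on the fit rows


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip columns so the largest-|entry| row of each column is positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def fit_pca(z: pd.DataFrame | np.ndarray) -> PCAResult:
    """Eigen-decompose the sample correlation matrix of standardized data.

    ``z`` must be the standardized fit rows.  Eigenvalues sum to the number
    of biomarkers; scores are scaled to unit sample variance per component
    (components with eigenvalue ~0 get zero scores).
    """
    zm = np.asarray(z, dtype=float)
    n, p = zm.shape
    if n < p:
        raise DegenerateDataError(f"need at least as many rows ({n}) as biomarkers ({p})")
    if np.isnan(zm).any():
        raise DegenerateDataError("standardized table contains missing values")
    # z is already standardized with ddof=1, so z'z/(n-1) is the correlation.
    corr = zm.T @ zm / (n - 1)
    eigenvalues, eigenvectors = np.linalg.eigh(corr)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    eigenvectors = _fix_signs(eigenvectors[:, order])
    loadings = eigenvectors * np.sqrt(eigenvalues)[None, :]
    inv_scale = np.where(eigenvalues > 1e-12, 1.0 / np.sqrt(np.where(eigenvalues > 0, eigenvalues, 1.0)), 0.0)
    scores = zm @ (eigenvectors * inv_scale[None, :])
    return PCAResult(eigenvalues, loadings, eigenvectors, scores)


def retain_components(
    eigenvalues: np.ndarray, threshold: float = EIGENVALUE_THRESHOLD
) -> np.ndarray:
    """Indices of components whose eigenvalue strictly exceeds ``threshold``.

    On the correlation scale the average eigenvalue is 1, so the default
    keeps components describing more than a third of the average variance
    per biomarker.  Order (descending eigenvalue) is preserved.
    """
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    return np.nonzero(eigenvalues > threshold)[0]


def varimax_criterion(loadings: np.ndarray) -> float:
    """Sum over components of the variance of their squared loadings."""
    sq = np.asarray(loadings, dtype=float) ** 2
    return float(np.sum(sq.var(axis=0)))


def varimax_rotate(
    loadings: np.ndarray,
    *,
    kaiser: bool = False,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Varimax rotation of a (biomarkers x components) loading matrix.

    Iterates the standard SVD update until the criterion changes by less
    than ``tol``.  With ``kaiser=True`` rows are normalized to unit
    communality during rotation (and rescaled back).  Returns
    ``(rotated, rotation, converged)`` with ``rotated = loadings @ rotation``
    and an orthogonal ``rotation``; non-convergence warns and returns the
    best iterate found.
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k), True
    scale = np.ones(p)
    if kaiser:
        scale = np.sqrt((L**2).sum(axis=1))
        scale[scale == 0] = 1.0
        L = L / scale[:, None]
    rotation = np.eye(k)
    previous = varimax_criterion(L)
    converged = False
    for _ in range(max_iter):
        rotated = L @ rotation
        # Gradient-like target of the varimax objective; its SVD projects
        # back onto the orthogonal group.
        target = L.T @ (rotated**3 - rotated @ np.diag((rotated**2).sum(axis=0)) / p)
        u, _, vt = np.linalg.svd(target)
        rotation = u @ vt
        current = varimax_criterion(L @ rotation)
        if current - previous <= tol:
            previous = current
            converged = True
            break
        previous = current
    if not converged:
        warnings.warn("varimax did not converge; returning best iterate", stacklevel=2)
    rotated = (L @ rotation) * scale[:, None]
    return rotated, rotation, converged


@dataclass
class ComponentSummary:
    """Interpretation of one rotated component by its strong loadings."""

    label: str
    primary_biomarkers: list[str]  # |loading| > cutoff, by decreasing |loading|
    loadings: dict[str, float]


def characterize_components(
    rotated_loadings: np.ndarray,
    biomarker_names: list[str],
    cutoff: float = LOADING_CUTOFF,
) -> list[ComponentSummary]:
    """Name each component after its strongly loading biomarkers.

    The primary list holds biomarkers with |loading| > ``cutoff`` sorted by
    decreasing |loading|; the label is the top biomarker (falling back to the
    largest |loading| when none clears the cutoff).
    """
    L = np.asarray(rotated_loadings, dtype=float)
    out = []
    for j in range(L.shape[1]):
        col = L[:, j]
        order = np.argsort(-np.abs(col))
        primary = [biomarker_names[i] for i in order if abs(col[i]) > cutoff]
        label = primary[0] if primary else biomarker_names[order[0]]
        out.append(
            ComponentSummary(label, primary, {biomarker_names[i]: float(col[i]) for i in order})
        )
    return out


@dataclass
class ComponentModel:
    """Fitted standardize → PCA → retain → varimax pipeline for one stratum.

    ``basis`` maps standardized biomarkers to unit-variance rotated component
    scores (z @ basis); ``loadings`` are the rotated loadings after sign and
    order normalization.  Component columns are named ``PC1..PCk`` in order
    of decreasing explained variance after rotation.
    """

    sex: str | None
    standardization: Standardization
    eigenvalues: np.ndarray  # all p, descending
    retained: np.ndarray  # indices into eigenvalues
    unrotated_loadings: np.ndarray  # retained columns only
    rotation: np.ndarray
    loadings: np.ndarray  # rotated, sign/order normalized
    basis: np.ndarray
    summaries: list[ComponentSummary]
    varimax_converged: bool

    @property
    def biomarkers(self) -> list[str]:
        return self.standardization.biomarkers

    @property
    def component_names(self) -> list[str]:
        return [f"PC{j + 1}" for j in range(self.loadings.shape[1])]

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.summaries]

    def transform(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """Score new rows on the rotated components."""
        z = self.standardization.transform(cohort)
        scores = z.to_numpy() @ self.basis
        return pd.DataFrame(scores, columns=self.component_names, index=cohort.index)


def fit_component_model(
    cohort: pd.DataFrame,
    biomarkers: list[str],
    fit_rows: pd.Index | np.ndarray | None = None,
    *,
    sex: str | None = None,
    threshold: float = EIGENVALUE_THRESHOLD,
    cutoff: float = LOADING_CUTOFF,
    kaiser: bool = False,
) -> ComponentModel:
    """Fit the full component pipeline on ``fit_rows`` of one stratum."""
    z_all, params = standardize(cohort, biomarkers, fit_rows)
    z_fit = z_all if fit_rows is None else z_all.loc[fit_rows]
    pca = fit_pca(z_fit)
    retained = retain_components(pca.eigenvalues, threshold)
    if retained.size == 0:
        raise DegenerateDataError("no components retained; lower the eigenvalue threshold")
    L = pca.loadings[:, retained]
    if retained.size >= 2:
        rotated, rotation, converged = varimax_rotate(L, kaiser=kaiser)
    else:
        rotated, rotation, converged = L.copy(), np.eye(1), True

    # Unit-variance score basis for the rotated components, then normalize
    # component order (explained variance desc.) and sign (top loading > 0).
    inv_sqrt = 1.0 / np.sqrt(pca.eigenvalues[retained])
    basis = (pca.eigenvectors[:, retained] * inv_sqrt[None, :]) @ rotation
    ss = (rotated**2).sum(axis=0)
    order = np.argsort(-ss, kind="stable")
    rotated, basis, rotation = rotated[:, order], basis[:, order], rotation[:, order]
    for j in range(rotated.shape[1]):
        i = int(np.argmax(np.abs(rotated[:, j])))
        if rotated[i, j] < 0:
            rotated[:, j] = -rotated[:, j]
            basis[:, j] = -basis[:, j]
            rotation[:, j] = -rotation[:, j]

    summaries = characterize_components(rotated, list(biomarkers), cutoff)
    return ComponentModel(
        sex=sex,
        standardization=params,
        eigenvalues=pca.eigenvalues,
        retained=retained,
        unrotated_loadings=L,
        rotation=rotation,
        loadings=rotated,
        basis=basis,
        summaries=summaries,
        varimax_converged=converged,
    )
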
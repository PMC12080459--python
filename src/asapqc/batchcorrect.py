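"""Batch-effect detection and correction.

Batch effects — systematic non-biological differences between subsets of
measurements recorded on different days, by different users, or with
different consumables — can mask or mimic biological variation in clinical
mass-spectrometry cohorts. This module provides

* :func:`kruskal_wallis` — rank-based k-group test with tie correction,
* :func:`assess_batch_association` — Kruskal-Wallis association between each
  leading principal component of the feature matrix and the batch labels,
* :func:`combat` — parametric empirical-Bayes location/scale adjustment
  (ComBat): per-batch, per-bin location and scale estimates are shrunk
  towards common priors (normal on locations, inverse-gamma on scales, with
  hyperparameters estimated by the method of moments) on standardized data,
  then the data are adjusted and back-transformed,
* :func:`ica_correct` — independent component analysis of the centred
  matrix; components whose per-sample weights associate with batch
  (Kruskal-Wallis at ``alpha``) are removed before reconstruction,
* :func:`batch_circles` — per-batch centroid circles (radius to the furthest
  member) for PC1/PC2 score plots,
* :func:`correction_report` — the before/after p-value table (per-PC
  association with batch and with sample type for the uncorrected, ComBat-
  and ICA-corrected matrices).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .repeatability import (
    FeatureMatrix,
    PCAModel,
    TestResult,
    classify_significance,
    fit_pca,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kruskal-Wallis and per-PC batch association
# ---------------------------------------------------------------------------


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H-test with tie correction; p from chi-square(k-1)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("Kruskal-Wallis needs at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValidationError("Kruskal-Wallis groups must be non-empty")
    if sum(a.size for a in arrays) < 3:
        raise ValidationError("Kruskal-Wallis needs a total of >= 3 observations")
    if np.ptp(np.concatenate(arrays)) == 0:
        # equal mean ranks by construction: no evidence of any difference
        return TestResult(
            name="kruskal_wallis", statistic=0.0, p=1.0, significance_level=None
        )
    res = stats.kruskal(*arrays)
    p = float(res.pvalue)
    return TestResult(
        name="kruskal_wallis",
        statistic=float(res.statistic),
        p=p,
        significance_level=classify_significance(p),
    )


@dataclass
class BatchAssessment:
    """Per-PC Kruskal-Wallis association between scores and batch labels."""

    table: pd.DataFrame  # columns: component, H, p, significant
    pca: PCAModel

    @property
    def any_significant(self) -> bool:
        return bool(self.table["significant"].any())


def _split_by_group(values: np.ndarray, labels: np.ndarray) -> list[np.ndarray]:
    labels = np.asarray(labels)
    seen: list = []
    for lab in labels:
        if lab not in seen:
            seen.append(lab)
    return [values[labels == lab] for lab in seen]


def assess_batch_association(
    matrix: FeatureMatrix,
    batch_labels: Sequence | None = None,
    n_pcs: int = 3,
) -> BatchAssessment:
    """Test each leading PC's scores for association with batch.

    ``batch_labels`` defaults to the matrix metadata column ``batch``.
    Requires at least two batches with two or more samples each.
    """
    labels = np.asarray(
        matrix.labels("batch") if batch_labels is None else batch_labels
    )
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise ValidationError("batch association needs at least 2 batches")
    if counts.min() < 2:
        raise ValidationError("every batch needs at least 2 samples")
    pca = fit_pca(matrix, n_components=n_pcs)
    rows = []
    for c in range(n_pcs):
        res = kruskal_wallis(_split_by_group(pca.scores[:, c], labels))
        rows.append(
            {
                "component": c + 1,
                "H": res.statistic,
                "p": res.p,
                "significant": res.p < 0.05,
            }
        )
    return BatchAssessment(table=pd.DataFrame(rows), pca=pca)


# ---------------------------------------------------------------------------
# ComBat (parametric empirical Bayes)
# ---------------------------------------------------------------------------


@dataclass
class CombatModel:
    """Fitted ComBat parameters (standardized scale).

    ``gamma_hat`` / ``delta_hat_sq`` are the per-batch, per-bin location and
    scale (variance) estimates of the standardized data; ``gamma_star`` /
    ``delta_star_sq`` their empirical-Bayes shrunk counterparts. Priors:
    ``gamma_bar`` / ``tau_sq`` (normal on locations) and ``a_prior`` /
    ``b_prior`` (inverse-gamma on scales), per batch.
    """

    batches: list
    grand_mean: np.ndarray
    var_pooled: np.ndarray
    gamma_hat: np.ndarray  # (n_batches, n_bins)
    gamma_star: np.ndarray
    delta_hat_sq: np.ndarray
    delta_star_sq: np.ndarray
    gamma_bar: np.ndarray  # (n_batches,)
    tau_sq: np.ndarray
    a_prior: np.ndarray
    b_prior: np.ndarray
    dropped_bins: list = field(default_factory=list)
    n_iterations: int = 0


def _combat_it_sol(
    Z_batch: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    tau_sq: float,
    a_prior: float,
    b_prior: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Iterative EB solution for one batch's (gamma*, delta*^2)."""
    n = Z_batch.shape[0]
    g_old = gamma_hat.copy()
    d_old = delta_hat.copy()
    for it in range(1, max_iter + 1):
        g_new = (n * tau_sq * gamma_hat + d_old * gamma_bar) / (n * tau_sq + d_old)
        sum2 = ((Z_batch - g_new) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            return g_new, d_new, it
    logger.warning("ComBat EB iteration did not converge after %d steps", max_iter)
    return g_old, d_old, max_iter


def combat(
    matrix: FeatureMatrix | np.ndarray,
    batch_labels: Sequence | None = None,
    covariates: pd.DataFrame | np.ndarray | None = None,
    mean_only: bool = False,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[FeatureMatrix | np.ndarray, CombatModel]:
    """Parametric empirical-Bayes batch adjustment (ComBat).

    The model assumes batch effects act on many bins in similar ways: per
    batch i and bin g, data standardized by the grand mean and pooled
    variance have mean ``gamma_ig`` and variance ``delta_ig^2``, with
    ``gamma_ig ~ N(gamma_bar_i, tau_i^2)`` and ``delta_ig^2`` inverse-gamma.
    Hyperparameters are estimated by the method of moments and the posterior
    conditional means solved iteratively; the data are adjusted with the
    shrunk estimates and back-transformed.

    Parameters
    ----------
    matrix
        Feature matrix (samples x bins) or plain array.
    batch_labels
        Defaults to the metadata column ``batch`` for a FeatureMatrix.
    covariates
        Optional design of biological covariates to protect (e.g. one-hot
        sample type, full-rank without intercept).
    mean_only
        Adjust locations only, leaving scales untouched.

    Returns
    -------
    (corrected, model)
        Corrected data in the input container type and the fitted model.
        With a single batch the input is returned unchanged (the
        standardize/back-transform round trip is the identity).

    Notes
    -----
    Zero-variance bins are excluded from the fit and re-inserted unchanged.
    A degenerate location prior (``tau^2 = 0``) collapses the EB estimate to
    ``gamma_bar``; a degenerate scale prior (zero spread of the per-bin
    variances) leaves the per-bin variance estimates unshrunk.
    """
    is_fm = isinstance(matrix, FeatureMatrix)
    X = matrix.values if is_fm else np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValidationError("combat expects a 2-D samples x bins matrix")
    labels = np.asarray(
        matrix.labels("batch") if (batch_labels is None and is_fm) else batch_labels
    )
    if labels.shape[0] != X.shape[0]:
        raise ValidationError("batch labels do not match the number of samples")

    batches: list = []
    for lab in labels:
        if lab not in batches:
            batches.append(lab)
    n_batches = len(batches)
    idx_by_batch = [np.flatnonzero(labels == b) for b in batches]
    n_per_batch = np.array([len(i) for i in idx_by_batch])
    n = X.shape[0]

    if n_batches == 1:
        model = CombatModel(
            batches=batches,
            grand_mean=X.mean(axis=0),
            var_pooled=X.var(axis=0),
            gamma_hat=np.zeros((1, X.shape[1])),
            gamma_star=np.zeros((1, X.shape[1])),
            delta_hat_sq=np.ones((1, X.shape[1])),
            delta_star_sq=np.ones((1, X.shape[1])),
            gamma_bar=np.zeros(1),
            tau_sq=np.zeros(1),
            a_prior=np.zeros(1),
            b_prior=np.zeros(1),
        )
        corrected = X.copy()
        return (matrix.with_values(corrected) if is_fm else corrected), model
    if np.any(n_per_batch < 2):
        raise ValidationError(
            "every batch needs >= 2 samples (no within-batch variance otherwise)"
        )

    # design: batch indicators plus optional covariates
    Z = np.zeros((n, n_batches))
    for j, idx in enumerate(idx_by_batch):
        Z[idx, j] = 1.0
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        C = C.reshape(n, -1)
        design = np.hstack([Z, C])
    else:
        C = None
        design = Z

    B_hat, *_ = np.linalg.lstsq(design, X, rcond=None)
    grand_mean = (n_per_batch / n) @ B_hat[:n_batches]
    resid = X - design @ B_hat
    var_pooled = (resid**2).mean(axis=0)

    # a bin is unusable when it is exactly constant or its pooled residual
    # variance has collapsed to floating-point noise
    col_var = X.var(axis=0)
    keep = (col_var > 0) & (var_pooled > 1e-12 * max(float(var_pooled.max()), 1e-300))
    dropped = np.flatnonzero(~keep).tolist()
    if dropped:
        logger.warning("ComBat: %d zero-variance bins excluded", len(dropped))
    Xk = X[:, keep]
    var_k = var_pooled[keep]
    stand_mean = np.tile(grand_mean[keep], (n, 1))
    if C is not None:
        stand_mean = stand_mean + C @ B_hat[n_batches:, keep]
    Zs = (Xk - stand_mean) / np.sqrt(var_k)

    p = Zs.shape[1]
    gamma_hat = np.vstack([Zs[idx].mean(axis=0) for idx in idx_by_batch])
    delta_hat = np.vstack([Zs[idx].var(axis=0, ddof=1) for idx in idx_by_batch])
    gamma_bar = gamma_hat.mean(axis=1)
    tau_sq = gamma_hat.var(axis=1, ddof=1)
    m_delta = delta_hat.mean(axis=1)
    s2_delta = delta_hat.var(axis=1, ddof=1)

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    a_prior = np.zeros(n_batches)
    b_prior = np.zeros(n_batches)
    n_iter_total = 0
    for i, idx in enumerate(idx_by_batch):
        ni = len(idx)
        if mean_only:
            gamma_star[i] = (
                ni * tau_sq[i] * gamma_hat[i] + delta_hat[i] * gamma_bar[i]
            ) / (ni * tau_sq[i] + delta_hat[i])
            delta_star[i] = 1.0
            continue
        if s2_delta[i] <= 1e-12 * max(m_delta[i] ** 2, 1e-300):
            # degenerate inverse-gamma prior: no information to shrink scales
            delta_star[i] = delta_hat[i]
            gamma_star[i] = (
                ni * tau_sq[i] * gamma_hat[i] + delta_star[i] * gamma_bar[i]
            ) / (ni * tau_sq[i] + delta_star[i])
            continue
        a_prior[i] = (2.0 * s2_delta[i] + m_delta[i] ** 2) / s2_delta[i]
        b_prior[i] = (
            m_delta[i] * s2_delta[i] + m_delta[i] ** 3
        ) / s2_delta[i]
        g, d, its = _combat_it_sol(
            Zs[idx],
            gamma_hat[i],
            delta_hat[i],
            gamma_bar[i],
            tau_sq[i],
            a_prior[i],
            b_prior[i],
            tol,
            max_iter,
        )
        gamma_star[i], delta_star[i] = g, d
        n_iter_total = max(n_iter_total, its)

    adjusted = Zs.copy()
    for i, idx in enumerate(idx_by_batch):
        adjusted[idx] = (Zs[idx] - gamma_star[i]) / np.sqrt(delta_star[i])
    Xk_adj = adjusted * np.sqrt(var_k) + stand_mean

    corrected = X.copy()
    corrected[:, keep] = Xk_adj

    full = lambda arr, fill: _expand(arr, keep, fill)  # noqa: E731
    model = CombatModel(
        batches=batches,
        grand_mean=grand_mean,
        var_pooled=var_pooled,
        gamma_hat=full(gamma_hat, 0.0),
        gamma_star=full(gamma_star, 0.0),
        delta_hat_sq=full(delta_hat, 1.0),
        delta_star_sq=full(delta_star, 1.0),
        gamma_bar=gamma_bar,
        tau_sq=tau_sq,
        a_prior=a_prior,
        b_prior=b_prior,
        dropped_bins=dropped,
        n_iterations=n_iter_total,
    )
    return (matrix.with_values(corrected) if is_fm else corrected), model


def _expand(arr: np.ndarray, keep: np.ndarray, fill: float) -> np.ndarray:
    out = np.full((arr.shape[0], keep.size), fill)
    out[:, keep] = arr
    return out


# ---------------------------------------------------------------------------
# ICA correction
# ---------------------------------------------------------------------------


@dataclass
class ICAResult:
    """Outcome of ICA-based batch correction."""

    n_components: int
    sources: np.ndarray  # (n_samples, n_components) per-sample weights
    mixing: np.ndarray  # (n_components, n_bins)
    batch_p: np.ndarray  # per-component KW p-value vs batch
    removed: list
    reconstruction_residual: float
    converged: bool = True


def ica_correct(
    matrix: FeatureMatrix | np.ndarray,
    batch_labels: Sequence | None = None,
    alpha: float = 0.05,
    n_components: int | None = None,
    p_adjust: str | None = None,
    random_state: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> tuple[FeatureMatrix | np.ndarray, ICAResult]:
    """Remove batch-associated independent components.

    The centred matrix is factorised with FastICA (fixed-point negentropy
    maximization, symmetric estimation, seed-controlled); each component's
    per-sample weights are Kruskal-Wallis-tested against batch, and
    components with p < ``alpha`` are omitted from the reconstruction.
    Structure outside the retained ICA subspace is kept unchanged.

    ``n_components`` defaults to ``min(n_samples - 1, 5)``, mirroring the
    five-component reduction used elsewhere in the pipeline: a batch effect
    concentrated in one direction is identifiable only while the
    factorisation is not padded with unidentifiable Gaussian noise
    components, which smear the batch axis across sources. ``p_adjust``
    may be ``"bh"`` for a Benjamini-Hochberg adjustment of the per-component
    p-values before thresholding (no adjustment by default, matching per-PC
    reporting conventions). Non-convergence of the FastICA iteration is
    reported on the result (``converged=False``), never silently ignored.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    is_fm = isinstance(matrix, FeatureMatrix)
    X = matrix.values if is_fm else np.asarray(matrix, dtype=float)
    labels = np.asarray(
        matrix.labels("batch") if (batch_labels is None and is_fm) else batch_labels
    )
    if len(set(labels.tolist())) < 2:
        raise ValidationError("ICA correction needs at least 2 batches")
    n = X.shape[0]
    k = n_components if n_components is not None else min(n - 1, 5)
    if not (1 <= k <= n - 1):
        raise ValidationError(f"n_components={k} must be in [1, {n - 1}]")

    ica = FastICA(
        n_components=k,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=random_state,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(X)  # (n, k)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            logger.warning(
                "FastICA did not converge within %d iterations (tol=%g); "
                "component estimates are partial",
                max_iter,
                tol,
            )
    mixing = ica.mixing_  # (n_bins, k)

    batch_p = np.array(
        [kruskal_wallis(_split_by_group(sources[:, j], labels)).p for j in range(k)]
    )
    p_eff = batch_p
    if p_adjust == "bh":
        p_eff = stats.false_discovery_control(batch_p, method="bh")
    elif p_adjust is not None:
        raise ValidationError(f"unknown p_adjust {p_adjust!r}")
    removed = np.flatnonzero(p_eff < alpha).tolist()

    full_rec = sources @ mixing.T + ica.mean_
    residual = float(np.linalg.norm(X - full_rec))
    kept = [j for j in range(k) if j not in removed]
    corrected = sources[:, kept] @ mixing[:, kept].T + ica.mean_
    # out-of-subspace structure (beyond the k retained components) is kept
    corrected = corrected + (X - full_rec)

    result = ICAResult(
        n_components=k,
        sources=sources,
        mixing=mixing.T,
        batch_p=batch_p,
        removed=removed,
        reconstruction_residual=residual,
        converged=converged,
    )
    return (matrix.with_values(corrected) if is_fm else corrected), result


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BatchCircle:
    """Centroid circle of one batch in (PC1, PC2): radius to the furthest member."""

    batch: object
    centroid: np.ndarray
    radius: float


def batch_circles(scores_2d: np.ndarray, batch_labels: Sequence) -> list[BatchCircle]:
    """Per-batch centroid and maximum member distance in a 2-D score plane."""
    pts = np.atleast_2d(np.asarray(scores_2d, dtype=float))
    labels = np.asarray(batch_labels)
    if labels.shape[0] != pts.shape[0]:
        raise ValidationError("batch labels do not match the number of score rows")
    circles = []
    seen: list = []
    for lab in labels:
        if lab in seen:
            continue
        seen.append(lab)
        group = pts[labels == lab]
        centroid = group.mean(axis=0)
        radius = float(np.linalg.norm(group - centroid, axis=1).max())
        circles.append(BatchCircle(batch=lab, centroid=centroid, radius=radius))
    return circles


@dataclass
class CorrectionReport:
    """Before/after per-PC association p-values and batch circles.

    ``pvalues`` has one row per (matrix arm, factor, component) with the
    Kruskal-Wallis H, p and significance flag; arms are ``uncorrected``,
    ``combat`` and ``ica``, factors ``batch`` and ``sample_type``.
    """

    pvalues: pd.DataFrame
    circles: dict
    corrected: dict


def correction_report(
    matrix: FeatureMatrix,
    batch_labels: Sequence | None = None,
    type_labels: Sequence | None = None,
    n_pcs: int = 3,
    alpha: float = 0.05,
    random_state: int = 0,
) -> CorrectionReport:
    """Run both correctors and tabulate per-PC batch / sample-type association.

    For each of the uncorrected, ComBat-corrected and ICA-corrected matrices,
    the first ``n_pcs`` PCs are Kruskal-Wallis-tested against batch and
    against sample type, giving the (arms x factors x PCs) p-value table,
    plus per-batch centroid circles in the (PC1, PC2) plane of each arm.
    """
    batch = np.asarray(
        matrix.labels("batch") if batch_labels is None else batch_labels
    )
    stype = np.asarray(
        matrix.labels("sample_type") if type_labels is None else type_labels
    )
    combat_matrix, _ = combat(matrix, batch)
    ica_matrix, ica_result = ica_correct(
        matrix, batch, alpha=alpha, random_state=random_state
    )
    arms = {
        "uncorrected": matrix,
        "combat": combat_matrix,
        "ica": ica_matrix,
    }
    rows = []
    circles = {}
    for arm, fm in arms.items():
        pca = fit_pca(fm, n_components=n_pcs)
        circles[arm] = batch_circles(pca.scores[:, :2], batch)
        for factor, labels in (("batch", batch), ("sample_type", stype)):
            for c in range(n_pcs):
                res = kruskal_wallis(_split_by_group(pca.scores[:, c], labels))
                rows.append(
                    {
                        "matrix": arm,
                        "factor": factor,
                        "component": c + 1,
                        "H": res.statistic,
                        "p": res.p,
                        "significant": res.p < 0.05,
                    }
                )
    return CorrectionReport(
        pvalues=pd.DataFrame(rows),
        circles=circles,
        corrected={"combat": combat_matrix, "ica": ica_matrix},
    )
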
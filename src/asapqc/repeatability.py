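"""Repeatability and reproducibility statistics in PCA score space.

Processed acquisitions are collected into a :class:`FeatureMatrix` (samples x
m/z bins with per-sample metadata), reduced to their first five principal
components, and compared in score space: one-standard-deviation confidence
ellipses for score plots, per-group centroid spreads (mean and standard
deviation of member-to-centroid Euclidean distances), cross-group deviations
(each group's points against every other group's centroid), and the
nonparametric / parametric test battery used for group comparisons
(Shapiro-Wilk normality, Mann-Whitney U, one-way ANOVA with Tukey HSD),
with significance read at strict p < 0.05 / 0.01 / 0.001 thresholds.

PCA is performed on mean-centred unit-area spectra without variance scaling:
after unit-area normalization all bins share a scale, and scaling would
inflate noise-only bins. Component signs follow a deterministic convention
(the largest-magnitude loading entry is positive) so score plots are
reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .acquisition import SampleSpectrum
from .errors import ValidationError

#: metadata columns recognised in feature-matrix CSV files
METADATA_COLUMNS = (
    "sample_id",
    "patient",
    "sample_type",
    "user",
    "batch",
    "replicate",
    "day",
)

SIGNIFICANCE_LEVELS = (0.001, 0.01, 0.05)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Samples x m/z-bin intensity table plus per-sample metadata.

    ``intensities`` is a DataFrame indexed by acquisition id with float m/z
    bin centres as columns; ``metadata`` shares the index and holds any of
    :data:`METADATA_COLUMNS`.
    """

    intensities: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.intensities.isna().any().any():
            raise ValidationError("feature matrix contains missing values")
        if not self.intensities.index.equals(self.metadata.index):
            raise ValidationError("intensities and metadata indices differ")

    @property
    def values(self) -> np.ndarray:
        return self.intensities.to_numpy(dtype=float)

    @property
    def mz_grid(self) -> np.ndarray:
        return self.intensities.columns.to_numpy(dtype=float)

    @property
    def sample_ids(self) -> list:
        return list(self.intensities.index)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    def labels(self, column: str) -> np.ndarray:
        if column not in self.metadata.columns:
            raise ValidationError(
                f"metadata column {column!r} missing; available: "
                f"{list(self.metadata.columns)}"
            )
        return self.metadata[column].to_numpy()

    def with_values(self, values: np.ndarray) -> "FeatureMatrix":
        """Copy of this matrix with replaced intensity values."""
        frame = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=self.intensities.index,
            columns=self.intensities.columns,
        )
        return FeatureMatrix(intensities=frame, metadata=self.metadata.copy())

    @classmethod
    def from_spectra(
        cls, spectra: Sequence[SampleSpectrum], ids: Sequence | None = None
    ) -> "FeatureMatrix":
        if not spectra:
            raise ValidationError("cannot build a feature matrix from no spectra")
        grid = spectra[0].mz_grid
        for s in spectra[1:]:
            if s.mz_grid.shape != grid.shape or np.any(s.mz_grid != grid):
                raise ValidationError("spectra are on different m/z grids")
        if ids is None:
            ids = [
                s.provenance.get("acquisition_id", f"acq{i}")
                for i, s in enumerate(spectra)
            ]
        intensities = pd.DataFrame(
            np.vstack([s.intensities for s in spectra]), index=list(ids), columns=grid
        )
        meta_rows = []
        for s in spectra:
            row = {k: s.provenance.get(k) for k in METADATA_COLUMNS}
            row["qc_flags"] = ";".join(sorted(s.qc_flags))
            meta_rows.append(row)
        metadata = pd.DataFrame(meta_rows, index=list(ids))
        return cls(intensities=intensities, metadata=metadata)

    def to_csv(self, path: str | Path) -> None:
        """Single CSV with metadata columns followed by m/z bin columns."""
        meta = self.metadata.copy()
        meta.index.name = "acquisition_id"
        out = pd.concat([meta, self.intensities], axis=1)
        out.to_csv(path, float_format="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        frame = pd.read_csv(path, index_col=0)
        meta_cols = [c for c in frame.columns if not _is_number(c)]
        bin_cols = [c for c in frame.columns if _is_number(c)]
        if not bin_cols:
            raise ValidationError(f"{path} contains no m/z bin columns")
        intensities = frame[bin_cols]
        intensities.columns = [float(c) for c in bin_cols]
        return cls(intensities=intensities, metadata=frame[meta_cols])


def _is_number(s) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


@dataclass
class PCAModel:
    """Principal components of a feature matrix (covariance PCA, centred only)."""

    loadings: np.ndarray  # (n_components, n_bins), orthonormal rows
    scores: np.ndarray  # (n_samples, n_components)
    explained_fraction: np.ndarray
    center: np.ndarray
    n_components: int

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.center) @ self.loadings.T

    def reconstruct(self, scores: np.ndarray | None = None) -> np.ndarray:
        if scores is None:
            scores = self.scores
        return scores @ self.loadings + self.center


@dataclass(frozen=True)
class ConfidenceEllipse:
    """Coverage ellipse for a 2-D score cloud.

    With ``coverage`` c the squared Mahalanobis radius is the chi-square(2 df)
    quantile at c, so a bivariate normal has probability c of falling inside;
    at c = 0.68 this is the conventional "one standard deviation" ellipse of
    score plots (radius ~1.51 sigma per axis, not the literal 1-sigma ellipse,
    which would cover only 39.3% in two dimensions).
    """

    center: np.ndarray
    semi_axes: np.ndarray
    rotation: float
    coverage: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside (or on) the ellipse."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.center
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        rot = np.array([[c, s], [-s, c]])  # rotate into principal axes
        local = pts @ rot.T
        return (local / self.semi_axes) ** 2 @ np.ones(2) <= 1.0 + 1e-12


@dataclass(frozen=True)
class GroupSpread:
    """Within-group variability: member-to-centroid Euclidean distances."""

    group: object
    centroid: np.ndarray
    mean_distance: float
    sd_distance: float
    n: int


@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical test with its strict significance level."""

    name: str
    statistic: float
    p: float
    significance_level: float | None
    detail: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# PCA and score-space geometry
# ---------------------------------------------------------------------------


def fit_pca(matrix: FeatureMatrix | np.ndarray, n_components: int = 5) -> PCAModel:
    """Covariance-based PCA of the (centred, unscaled) feature matrix.

    Components are sign-fixed so the largest-magnitude loading entry of each
    component is positive.
    """
    from sklearn.decomposition import PCA  # deferred import keeps startup light

    X = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(
        matrix, dtype=float
    )
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 samples and 2 bins")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if not (1 <= n_components <= max_rank):
        raise ValidationError(
            f"n_components={n_components} must be in [1, {max_rank}] for shape "
            f"{X.shape}"
        )
    if np.allclose(X.var(axis=0), 0.0):
        raise ValidationError("feature matrix has zero variance; PCA undefined")

    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1.0
            scores[:, i] *= -1.0
    return PCAModel(
        loadings=loadings,
        scores=scores,
        explained_fraction=pca.explained_variance_ratio_.copy(),
        center=pca.mean_.copy(),
        n_components=n_components,
    )


def confidence_ellipse(
    scores_2d: np.ndarray, coverage: float = 0.68, method: str = "coverage"
) -> ConfidenceEllipse:
    """Confidence ellipse of a 2-D score cloud from its mean and covariance.

    Parameters
    ----------
    scores_2d
        Array of shape (n, 2), n >= 3 and not collinear.
    coverage
        Requested coverage fraction under approximate bivariate normality.
    method
        ``"coverage"`` (default) sets the squared Mahalanobis radius to the
        chi-square(2) quantile at ``coverage``; ``"sd-radius"`` draws the
        literal one-sigma ellipse (radius 1 in Mahalanobis units) and ignores
        ``coverage`` for the radius (it is still recorded).
    """
    pts = np.asarray(scores_2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("confidence_ellipse expects an (n, 2) array")
    if pts.shape[0] < 3:
        raise ValidationError("confidence_ellipse needs at least 3 points")
    if not (0 < coverage < 1):
        raise ValidationError("coverage must be in (0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals.min() <= 1e-12 * max(eigvals.max(), 1e-300):
        raise ValidationError("degenerate (singular) covariance; points collinear")
    if method == "coverage":
        r2 = stats.chi2.ppf(coverage, df=2)
    elif method == "sd-radius":
        r2 = 1.0
    else:
        raise ValidationError(f"unknown ellipse method {method!r}")
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    rotation = float(np.arctan2(eigvecs[1, 0], eigvecs[0, 0]))
    return ConfidenceEllipse(
        center=center,
        semi_axes=np.sqrt(eigvals * r2),
        rotation=rotation,
        coverage=coverage,
    )


def _group_indices(labels: np.ndarray) -> dict:
    labels = np.asarray(labels)
    groups: dict = {}
    for lab in labels:
        if lab not in groups:
            groups[lab] = np.flatnonzero(labels == lab)
    return groups


def centroid_spread(scores: np.ndarray, group_labels: Sequence) -> list[GroupSpread]:
    """Per-group centroid and Euclidean-distance spread statistics.

    The centroid averages each component across the group's measurements; the
    spread is the mean and standard deviation of each measurement's Euclidean
    distance to its own group centroid.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(group_labels)
    if labels.shape[0] != scores.shape[0]:
        raise ValidationError("group labels do not match the number of score rows")
    out = []
    for lab, idx in _group_indices(labels).items():
        pts = scores[idx]
        centroid = pts.mean(axis=0)
        dists = np.linalg.norm(pts - centroid, axis=1)
        sd = float(dists.std(ddof=1)) if dists.size > 1 else 0.0
        out.append(
            GroupSpread(
                group=lab,
                centroid=centroid,
                mean_distance=float(dists.mean()),
                sd_distance=sd,
                n=int(dists.size),
            )
        )
    return out


def cross_group_deviation(scores: np.ndarray, group_labels: Sequence) -> pd.DataFrame:
    """Mean distance of each group's points to every group's centroid.

    Rows are the measured group, columns the centroid's group; the diagonal
    reproduces :func:`centroid_spread`'s mean distances. Used to compare each
    user's measurements with the centroids of other users.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(group_labels)
    groups = _group_indices(labels)
    if len(groups) < 2:
        raise ValidationError("cross-group deviation needs at least 2 groups")
    names = list(groups)
    centroids = {lab: scores[idx].mean(axis=0) for lab, idx in groups.items()}
    table = pd.DataFrame(index=names, columns=names, dtype=float)
    for lab, idx in groups.items():
        for other in names:
            d = np.linalg.norm(scores[idx] - centroids[other], axis=1)
            table.loc[lab, other] = float(d.mean())
    table.index.name = "group"
    table.columns.name = "centroid"
    return table


# ---------------------------------------------------------------------------
# test battery
# ---------------------------------------------------------------------------


def classify_significance(p: float) -> float | None:
    """Strictest satisfied significance level among 0.05/0.01/0.001 (strict <)."""
    if not (0.0 <= p <= 1.0) or not np.isfinite(p):
        raise ValidationError(f"p-value {p!r} outside [0, 1]")
    for level in SIGNIFICANCE_LEVELS:
        if p < level:
            return level
    return None


def shapiro_wilk(x: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000, non-constant input)."""
    x = np.asarray(x, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ValidationError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValidationError("Shapiro-Wilk undefined for constant input")
    res = stats.shapiro(x)
    return TestResult(
        name="shapiro_wilk",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        significance_level=classify_significance(float(res.pvalue)),
    )


#: largest n_x * n_y for which the exact Mann-Whitney null is enumerated
MWU_EXACT_LIMIT = 400


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Mann-Whitney U test for a single-pair comparison.

    The p-value is exact (full enumeration of the null U distribution) when
    the samples are tie-free and ``n_x * n_y <= 400``; otherwise the normal
    approximation with tie and continuity corrections is used. The reported
    statistic is U for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("Mann-Whitney requires two non-empty samples")
    combined = np.concatenate([x, y])
    tie_free = np.unique(combined).size == combined.size
    method = "exact" if tie_free and x.size * y.size <= MWU_EXACT_LIMIT else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    p = float(res.pvalue)
    return TestResult(
        name="mann_whitney",
        statistic=float(res.statistic),
        p=p,
        significance_level=classify_significance(min(p, 1.0)),
        detail={"method": method, "alternative": alternative},
    )


def compare_distances(
    x: Sequence[float], y: Sequence[float], test: str = "mann_whitney"
) -> TestResult:
    """Compare two sets of centroid distances.

    ``test="mann_whitney"`` (default, robust to the non-normality common in
    distance distributions) or ``test="t"`` (Welch two-sample t-test).
    """
    if test == "mann_whitney":
        return mann_whitney_u(x, y)
    if test == "t":
        res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=False)
        p = float(res.pvalue)
        return TestResult(
            name="welch_t",
            statistic=float(res.statistic),
            p=p,
            significance_level=classify_significance(p),
        )
    raise ValidationError(f"unknown distance test {test!r}")


def anova_tukey(
    groups: Sequence[Sequence[float]],
    labels: Sequence | None = None,
) -> tuple[TestResult, list[TestResult]]:
    """One-way ANOVA for overall differences, then Tukey HSD pairwise tests.

    Tukey's adjusted p-values come from the studentized-range distribution.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValidationError("every group needs n >= 2 for ANOVA/Tukey")
    if labels is None:
        labels = list(range(len(arrays)))
    if np.ptp(np.concatenate(arrays)) == 0:
        raise ValidationError("ANOVA undefined for globally constant data")

    f_res = stats.f_oneway(*arrays)
    anova = TestResult(
        name="anova",
        statistic=float(f_res.statistic),
        p=float(f_res.pvalue),
        significance_level=classify_significance(float(f_res.pvalue)),
    )
    hsd = stats.tukey_hsd(*arrays)
    pairwise = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            p = float(hsd.pvalue[i, j])
            pairwise.append(
                TestResult(
                    name="tukey",
                    statistic=float(hsd.statistic[i, j]),
                    p=p,
                    significance_level=classify_significance(p),
                    detail={"pair": (labels[i], labels[j])},
                )
            )
    return anova, pairwise
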
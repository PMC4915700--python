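"""Ecological distances, PCoA ordination, bi-/tri-plot vectors, diversity.

Distances operate on the comparison document exactly as given (raw or
normalized counts — normalization is the caller's explicit step).
PCoA follows the classical Gower construction: square the distances,
double-center, eigendecompose, scale eigenvectors by the square roots of
the positive eigenvalues.  With Euclidean input distances the embedding
coincides with PCA of the centered data, a useful cross-check.  Axis
signs are fixed by forcing the largest-magnitude coordinate on each axis
positive, so results are reproducible across eigensolvers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import braycurtis as _braycurtis
from scipy.spatial.distance import euclidean as _euclidean
from scipy.spatial.distance import jensenshannon as _jensenshannon
from scipy.stats import pearsonr

from .binning import SampleProfile
from .comparison import ComparisonDocument

__all__ = [
    "DistanceMatrix",
    "Ordination",
    "bray_curtis",
    "jensen_shannon",
    "euclidean",
    "pcoa",
    "biplot_vectors",
    "triplot_vectors",
    "alpha_diversity",
    "ALPHA_INDICES",
]

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass
class Ordination:
    labels: list[str]
    coordinates: np.ndarray  # samples x k
    eigenvalues: np.ndarray  # descending, positive-part used for axes
    fraction_explained: np.ndarray  # per retained axis


def _count_matrix(doc: ComparisonDocument) -> tuple[list[str], np.ndarray]:
    m = doc.classified_matrix()
    return list(m.columns), m.to_numpy(dtype=float).T  # samples x classes


def _pairwise(doc: ComparisonDocument, metric, check_totals: bool) -> DistanceMatrix:
    labels, x = _count_matrix(doc)
    if check_totals:
        zero = [labels[i] for i in range(len(labels)) if x[i].sum() <= 0]
        if zero:
            raise ValueError(f"all-zero sample(s): {zero}")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = metric(x[i], x[j])
    return DistanceMatrix(labels, d)


def bray_curtis(doc: ComparisonDocument) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y), bounded by [0, 1]."""
    return _pairwise(doc, lambda a, b: _braycurtis(a, b), check_totals=True)


def jensen_shannon(doc: ComparisonDocument) -> DistanceMatrix:
    """Square-root Jensen-Shannon divergence (natural log) of the
    per-sample relative-abundance distributions; bounded by sqrt(ln 2)."""

    def metric(a: np.ndarray, b: np.ndarray) -> float:
        d = _jensenshannon(a / a.sum(), b / b.sum())  # base e, returns sqrt
        return 0.0 if np.isnan(d) else float(d)

    return _pairwise(doc, metric, check_totals=True)


def euclidean(doc: ComparisonDocument) -> DistanceMatrix:
    """Plain L2 distance on count vectors (PCoA of it reproduces PCA)."""
    return _pairwise(doc, lambda a, b: _euclidean(a, b), check_totals=False)


def pcoa(d: DistanceMatrix, k: int = 2) -> Ordination:
    """Principal coordinate analysis of a sample distance matrix.

    Gower double-centering B = -1/2 J D^2 J, eigendecomposition, and
    coordinates from eigenvectors scaled by sqrt(eigenvalue).  Negative
    eigenvalues (non-Euclidean input) are excluded from the variance
    fractions with a logged warning; *k* is truncated to the number of
    positive eigenvalues when necessary.
    """
    n = len(d.labels)
    if k < 1 or n < 2:
        raise ValueError(f"need k >= 1 and n >= 2 (n={n}, k={k})")
    if k > n - 1:
        log.warning("k=%d exceeds n-1=%d axes; truncating", k, n - 1)
        k = n - 1
    dsq = d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ dsq @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(1e-9, 1e-9 * abs(eigval[0])) if eigval.size else 0.0
    positive = eigval > tol
    n_pos = int(positive.sum())
    if (eigval < -tol).any():
        log.warning(
            "distance matrix is non-Euclidean: %d negative eigenvalue(s) "
            "excluded from fraction_explained",
            int((eigval < -tol).sum()),
        )
    if k > n_pos:
        log.warning("k=%d exceeds positive-eigenvalue count %d; truncating", k, n_pos)
        k = n_pos
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    # sign convention: largest-magnitude coordinate on each axis positive
    for axis in range(k):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    pos_total = eigval[positive].sum()
    frac = eigval[:k] / pos_total if pos_total > 0 else np.zeros(k)
    return Ordination(list(d.labels), coords, eigval, frac)


def _correlation_vectors(
    values: np.ndarray, names: list, ord_: Ordination, n_top: int
) -> list[tuple[object, np.ndarray]]:
    """Shared bi-/tri-plot machinery over a samples x variables matrix."""
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    k = ord_.coordinates.shape[1]
    stds = values.std(axis=0, ddof=0)
    keep = np.nonzero(stds > 0)[0]
    if keep.size == 0:
        return []
    std_share = stds / stds[keep].sum()
    out = []
    for idx in keep:
        vec = np.zeros(k)
        for axis in range(k):
            axis_coords = ord_.coordinates[:, axis]
            if axis_coords.std() == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = pearsonr(values[:, idx], axis_coords).statistic
            vec[axis] = (0.0 if np.isnan(r) else r) * std_share[idx]
        out.append((names[idx], vec))
    out.sort(key=lambda nv: (-float(np.linalg.norm(nv[1])), str(nv[0])))
    return out[:n_top]


def biplot_vectors(
    doc: ComparisonDocument, ord_: Ordination, n_top: int = 5
) -> list[tuple[object, np.ndarray]]:
    """Classes contributing most to the ordination's variation.

    Component j of a class's vector is the Pearson correlation between
    its per-sample relative abundances and the axis-j coordinates,
    scaled by the class's share of total standard deviation; classes are
    ranked by vector length (ties by ascending class id) and the top
    *n_top* returned.  Constant classes are excluded.  The vectors point
    in the direction of steepest increase of the class.
    """
    if list(ord_.labels) != doc.samples:
        raise ValueError("ordination samples do not match the document")
    m = doc.classified_matrix()
    x = m.to_numpy(dtype=float).T  # samples x classes
    totals = x.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return _correlation_vectors(x / totals, list(m.index), ord_, n_top)


def triplot_vectors(
    doc: ComparisonDocument, ord_: Ordination, n_top: int = 5
) -> list[tuple[str, np.ndarray]]:
    """As :func:`biplot_vectors`, over numeric metadata attributes."""
    if list(ord_.labels) != doc.samples:
        raise ValueError("ordination samples do not match the document")
    frame = doc.metadata.frame
    numeric_cols = []
    for col in frame.columns:
        vals = frame[col].reindex(doc.samples)
        try:
            numeric = vals.astype(float)
        except (TypeError, ValueError):
            log.info("skipping non-numeric metadata attribute %r", col)
            continue
        if numeric.isna().any():
            log.info("skipping metadata attribute %r with missing values", col)
            continue
        numeric_cols.append((col, numeric.to_numpy()))
    if not numeric_cols:
        log.warning("no numeric metadata attributes available for tri-plot")
        return []
    values = np.column_stack([v for _, v in numeric_cols])
    return _correlation_vectors(values, [c for c, _ in numeric_cols], ord_, n_top)


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _simpson(p: np.ndarray) -> float:
    return float(1.0 - (p**2).sum())


ALPHA_INDICES = {
    "shannon": _shannon,
    "simpson": _simpson,
    "richness": lambda p: float((p > 0).sum()),
}


def alpha_diversity(profile: SampleProfile, index: str = "shannon") -> float:
    """Alpha diversity of one sample profile.

    shannon: -sum p_i ln p_i; simpson: 1 - sum p_i^2 (Gini-Simpson);
    richness: number of classes with nonzero count.
    """
    try:
        fn = ALPHA_INDICES[index]
    except KeyError:
        raise ValueError(f"unknown index {index!r}; choose from {sorted(ALPHA_INDICES)}") from None
    counts = np.array(
        [v for k, v in profile.counts.items() if k not in ("UNASSIGNED", "UNRESOLVED")],
        dtype=float,
    )
    total = counts.sum()
    if total <= 0:
        raise ValueError("alpha diversity of an empty profile is undefined")
    return fn(counts / total)
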
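"""Pathway deregulation scores from principal curves on pathway expression.

For each pathway, the expression matrix is restricted to the pathway's
genes, genes are z-scored, the samples are reduced by PCA, and a principal
curve (Hastie-Stuetzle alternation of projection and per-coordinate
smoothing) is threaded through the point cloud.  A sample's deregulation
score is how far its projection lies along the curve from the reference
position defined by the normal samples, rescaled so scores fall in [0, 1]
and the median normal score is exactly 0.

Pathways that barely vary across tumors are filtered out by a standard
deviation threshold before the tumors are clustered on 1 - Pearson
correlation distance with centroid linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


@dataclass
class PathwayDefinition:
    pathway_id: str
    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        # de-duplicate while keeping order
        self.genes = list(dict.fromkeys(self.genes))


@dataclass
class DeregParams:
    """Knobs for scoring, filtering and clustering.

    ``sd_min`` is a strict lower bound on the per-pathway score standard
    deviation across tumors; ``n_pca_components`` caps the dimensionality of
    the space the curve is fitted in (reduced automatically for small
    pathways); ``curve_tol`` is the relative change in mean squared
    projection distance at which the curve iteration stops.
    """

    sd_min: float = 0.2
    n_pca_components: int = 3
    curve_tol: float = 1e-4
    curve_max_iter: int = 50
    curve_span: float = 0.2
    rpkm_log_offset: float = 1.0
    n_clusters: int = 3
    curve_grid_points: int = 200

    def __post_init__(self) -> None:
        if self.sd_min < 0:
            raise ValueError("sd_min must be >= 0")
        if self.n_pca_components < 1:
            raise ValueError("n_pca_components must be >= 1")


@dataclass
class PrincipalCurve:
    """A fitted one-dimensional curve through a point cloud.

    ``points`` are ordered curve vertices in the reduced space,
    ``arc_length`` the cumulative arc length at each vertex, and
    ``projection`` the arc-length parameter at which each input sample
    projects onto the curve.
    """

    points: np.ndarray
    arc_length: np.ndarray
    projection: np.ndarray
    mse: float
    n_iter: int


def rpkm_normalize(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
    offset: float = 1.0,
) -> pd.DataFrame:
    """log2 RPKM: log2(count * 1e9 / (length_bp * library_size) + offset).

    ``counts`` is genes x samples raw counts; ``library_sizes`` defaults to
    the column sums.  Zero gene lengths or library sizes are rejected.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()[:5]
        raise ValueError(f"gene lengths missing for {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    else:
        library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    rpkm = counts * 1e9
    rpkm = rpkm.div(lengths, axis=0).div(library_sizes, axis=1)
    return np.log2(rpkm + offset)


def _project_to_polyline(points: np.ndarray, curve: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project points onto a polyline; return (arc-length parameter, squared distance)."""
    seg_start = curve[:-1]  # (m-1, d)
    seg_vec = curve[1:] - seg_start
    seg_len2 = np.einsum("ij,ij->i", seg_vec, seg_vec)
    seg_len2 = np.where(seg_len2 == 0, 1e-300, seg_len2)
    seg_len = np.sqrt(np.einsum("ij,ij->i", seg_vec, seg_vec))
    arc0 = np.concatenate([[0.0], np.cumsum(seg_len)])[:-1]  # arc length at segment start

    diff = points[:, None, :] - seg_start[None, :, :]  # (n, m-1, d)
    t = np.einsum("nmd,md->nm", diff, seg_vec) / seg_len2
    t = np.clip(t, 0.0, 1.0)
    proj = seg_start[None, :, :] + t[:, :, None] * seg_vec[None, :, :]
    d2 = np.einsum("nmd,nmd->nm", points[:, None, :] - proj, points[:, None, :] - proj)
    best = np.argmin(d2, axis=1)
    n_idx = np.arange(len(points))
    lam = arc0[best] + t[n_idx, best] * seg_len[best]
    return lam, d2[n_idx, best]


def _smooth_coordinates(
    lam: np.ndarray, points: np.ndarray, grid: np.ndarray, span: float
) -> np.ndarray:
    """Local-linear (Gaussian kernel) smooth of each coordinate against the parameter.

    ``span`` sets the kernel bandwidth as a fraction of the parameter range.
    A local *linear* fit reproduces straight-line point clouds exactly, so
    collinear data are a fixed point of the curve iteration.  Degenerate
    local weight configurations fall back to the local weighted mean.
    """
    bw = max(span * (lam.max() - lam.min()), 1e-12)
    D = lam[None, :] - grid[:, None]  # (m, n)
    W = np.exp(-0.5 * (D / bw) ** 2)
    Sw = W.sum(axis=1)
    Sd1 = (W * D).sum(axis=1)
    Sd2 = (W * D * D).sum(axis=1)
    Swy = W @ points  # (m, d)
    Swdy = (W * D) @ points
    denom = Sw * Sd2 - Sd1**2
    ok = denom > 1e-12 * np.maximum(Sw, 1e-300) ** 2
    out = np.empty((len(grid), points.shape[1]))
    with np.errstate(invalid="ignore", divide="ignore"):
        lin = (Sd2[:, None] * Swy - Sd1[:, None] * Swdy) / denom[:, None]
        mean = Swy / Sw[:, None]
    out[ok] = lin[ok]
    out[~ok] = mean[~ok]
    return out


def fit_principal_curve(points: np.ndarray, params: DeregParams | None = None) -> PrincipalCurve:
    """Hastie-Stuetzle principal curve through ``points`` (n x d).

    Initialized from the first principal component; alternates projection
    onto the current polyline with per-coordinate local-linear smoothing
    against the arc-length parameter until the mean squared projection
    distance stabilizes (relative change < ``curve_tol``) or
    ``curve_max_iter`` is reached.
    """
    params = params or DeregParams()
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 4 or points.shape[1] < 2:
        raise ValueError("fit_principal_curve requires >= 4 points in >= 2 dimensions")
    if np.allclose(points, points[0]):
        raise ValueError("degenerate input: all points identical")

    center = points.mean(axis=0)
    X = points - center
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    lam = X @ vt[0]  # signed first-PC coordinate as initial parameter

    m = max(params.curve_grid_points, 20)
    mse_prev = np.inf
    curve = None
    n_iter = 0
    for n_iter in range(1, params.curve_max_iter + 1):
        grid = np.linspace(lam.min(), lam.max(), m)
        if grid[0] == grid[-1]:
            raise ValueError("degenerate parameterization: all projections identical")
        curve = _smooth_coordinates(lam, X, grid, params.curve_span)
        lam, d2 = _project_to_polyline(X, curve)
        mse = float(d2.mean())
        converged = mse < 1e-12 or (
            np.isfinite(mse_prev) and abs(mse_prev - mse) / max(mse_prev, 1e-12) < params.curve_tol
        )
        mse_prev = mse
        if converged:
            break

    seg_len = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    return PrincipalCurve(curve + center, arc, lam, mse_prev, n_iter)


def pathway_deregulation_score(
    expr: pd.DataFrame,
    pathway: PathwayDefinition,
    normal_ids: list[str],
    params: DeregParams | None = None,
) -> pd.Series | None:
    """Deregulation score in [0, 1] for every sample, for one pathway.

    ``expr`` is a genes x samples log2-expression matrix containing both
    tumors and normals.  The pathway's genes with nonzero variance are
    z-scored, reduced by PCA, and a principal curve is fitted over all
    samples.  The raw score is the absolute arc-length offset of a sample's
    projection from the median projection of the normal samples, recentred
    by the median normal offset and rescaled by the maximum, so the median
    normal score is 0 and the maximum score is 1.  Returns ``None`` (with a
    logged warning) when fewer than 3 pathway genes are resolvable.
    """
    params = params or DeregParams()
    normal_ids = [s for s in normal_ids if s in expr.columns]
    if len(normal_ids) < 2:
        raise ValueError("pathway scoring needs >= 2 normal reference samples")
    present = [g for g in pathway.genes if g in expr.index]
    if len(present) >= 3:
        full = expr.loc[present].to_numpy()
        if np.allclose(full, full[:, [0]]):
            # all samples identical on this pathway: nothing is deregulated
            return pd.Series(0.0, index=expr.columns)
    sub = expr.loc[present]
    sub = sub[sub.std(axis=1, ddof=0) > 0]
    if len(sub) < 3:
        logger.warning(
            "pathway %s skipped: %d resolvable variable genes (< 3)", pathway.pathway_id, len(sub)
        )
        return None

    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=0), axis=0)
    X = z.to_numpy().T  # samples x genes
    if np.allclose(X, X[0]):
        return pd.Series(0.0, index=expr.columns)

    k = min(params.n_pca_components, X.shape[1], X.shape[0] - 1)
    if k < 2:
        k = min(2, X.shape[1])
    scores = PCA(n_components=k, svd_solver="full").fit_transform(X)
    curve = fit_principal_curve(scores, params)
    lam = pd.Series(curve.projection, index=z.columns)

    t_ref = lam[normal_ids].median()
    raw = (lam - t_ref).abs()
    # recentre by the upper median so the normal-sample median score is
    # exactly 0 after clipping, for both odd and even reference counts
    ref_offsets = np.sort(raw[normal_ids].to_numpy())
    adj = raw - ref_offsets[len(ref_offsets) // 2]
    adj = adj.clip(lower=0.0)
    mx = adj.max()
    if mx <= 0:
        return pd.Series(0.0, index=expr.columns)
    return (adj / mx).reindex(expr.columns)


def score_matrix(
    expr: pd.DataFrame,
    pathways: list[PathwayDefinition],
    normal_ids: list[str],
    params: DeregParams | None = None,
) -> pd.DataFrame:
    """Pathways x samples deregulation score matrix (skipping unresolvable pathways)."""
    rows = {}
    for pw in pathways:
        s = pathway_deregulation_score(expr, pw, normal_ids, params)
        if s is not None:
            rows[pw.pathway_id] = s
    return pd.DataFrame(rows).T


def filter_pathways_by_sd(
    scores: pd.DataFrame, tumor_ids: list[str], sd_min: float = 0.2
) -> pd.DataFrame:
    """Retain pathways whose score standard deviation across tumors strictly exceeds sd_min."""
    sd = scores[tumor_ids].std(axis=1, ddof=1)
    return scores[sd > sd_min]


def cluster_samples(scores: pd.DataFrame, n_clusters: int) -> pd.Series:
    """Hierarchical clustering of samples on 1 - Pearson correlation distance.

    Centroid linkage is applied to the correlation-distance matrix as
    configured, even though centroid linkage is formally defined for
    Euclidean distances; occasional inversions in the dendrogram are
    accepted.  Returns sample -> integer label (1..n_clusters), deterministic
    for a given input.
    """
    if scores.shape[1] < n_clusters:
        raise ValueError("need at least n_clusters samples")
    sds = scores.std(axis=0, ddof=0)
    flat = sds[sds == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance score vector for sample(s) {flat}")
    corr = np.corrcoef(scores.to_numpy().T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="centroid")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=scores.columns, name="cluster")


def overrepresentation_pvalues(
    overlap: np.ndarray, universe_size: np.ndarray, geneset_size: np.ndarray, query_size: np.ndarray
) -> np.ndarray:
    """Vectorized upper-tail hypergeometric P(overlap >= observed)."""
    return hypergeom.sf(np.asarray(overlap) - 1, universe_size, geneset_size, query_size)


def geneset_enrichment(
    query_genes: list[str] | set[str],
    geneset: PathwayDefinition,
    universe_size: int,
) -> float:
    """Upper-tail hypergeometric over-representation p-value.

    Probability of drawing at least the observed overlap between the query
    and the gene set when sampling ``len(query)`` genes from a universe of
    ``universe_size``.
    """
    query = set(query_genes)
    if not query:
        raise ValueError("empty query gene list")
    gs = set(geneset.genes)
    if len(query) > universe_size or len(gs) > universe_size:
        raise ValueError("query/geneset larger than the universe")
    overlap = len(query & gs)
    return float(overrepresentation_pvalues(overlap, universe_size, len(gs), len(query)))
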
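"""Channel-space dimensionality reduction to a one-dimensional signal.

The stochastic-resonance stage integrates a scalar differential equation,
so the multichannel epoch must first be collapsed to a single time
series.  Five unsupervised reducers are provided:

* CAR   - common average reference against a chosen electrode (Oz default);
* PCA   - first principal-component score series;
* MDS   - first principal coordinate of classical multidimensional scaling
          over the time samples viewed as points in channel space;
* LLE   - locally linear embedding of the same point cloud to one
          dimension (K nearest neighbours, default 40);
* CCA   - projection ``wx' X`` onto the channel weights that maximize the
          canonical correlation with a sinusoidal reference template.

MDS and LLE treat each time sample as a point in R^n_channels: that is
the only orientation that returns a time series of the original length.
Both are quadratic-or-worse in the number of points, so they subsample to
``max_points`` and interpolate the embedding back to full length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from sklearn.neighbors import NearestNeighbors

from .signal_model import EEGEpoch, TemplateBank

__all__ = [
    "ReducedSignal",
    "CCAProjection",
    "car_reduce",
    "pca_reduce",
    "mds_reduce",
    "lle_reduce",
    "lle_weights",
    "cca_fit",
    "cca_reduce",
]

log = logging.getLogger(__name__)

REDUCERS = ("car", "pca", "mds", "lle", "cca")


@dataclass(frozen=True)
class ReducedSignal:
    """One-dimensional signal produced by a reducer.

    ``meta`` records the method-specific parameters actually used
    (reference channel, loading vector, neighbour count, projection
    weights ...) so the reduction is reproducible.
    """

    values: np.ndarray
    method: str
    meta: Mapping[str, object]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("reduced signal must be 1-D")
        if not np.isfinite(v).all():
            raise ValueError("reduced signal contains non-finite values")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class CCAProjection:
    """First canonical pair between an epoch and a reference template.

    ``wx`` (channel weights) and ``wy`` (template weights) scale their
    projections to unit variance; ``rho`` is the first canonical
    correlation, reported non-negative.
    """

    wx: np.ndarray
    wy: np.ndarray
    rho: float


def car_reduce(epoch: EEGEpoch, reference_channel: str = "Oz") -> ReducedSignal:
    """Common average reference: reference electrode minus the per-sample
    mean over all electrodes."""
    ref = epoch.channel(reference_channel)
    values = ref - epoch.data.mean(axis=0)
    return ReducedSignal(values, "car", {"reference_channel": reference_channel})


def pca_reduce(epoch: EEGEpoch) -> ReducedSignal:
    """First principal-component score series (channels as variables).

    The score series is mean-centred; ``meta`` stores the unit loading
    vector and the explained-variance fraction.  The loading sign is fixed
    so its largest-magnitude entry is positive.
    """
    if epoch.n_samples <= epoch.n_channels:
        raise ValueError("PCA needs more samples than channels")
    centred = epoch.data - epoch.data.mean(axis=1, keepdims=True)
    cov = centred @ centred.T / (epoch.n_samples - 1)
    total = float(np.trace(cov))
    if total <= 0:
        raise ValueError("degenerate epoch: zero variance in every channel")
    evals, evecs = sla.eigh(cov)
    loading = evecs[:, -1]
    if loading[np.argmax(np.abs(loading))] < 0:
        loading = -loading
    values = loading @ centred
    return ReducedSignal(
        values,
        "pca",
        {"loading": loading, "explained_variance_fraction": float(evals[-1] / total)},
    )


def _subsample_indices(n: int, max_points: int) -> np.ndarray:
    if n <= max_points:
        return np.arange(n)
    return np.unique(np.round(np.linspace(0, n - 1, max_points)).astype(int))


def _interp_back(idx: np.ndarray, emb: np.ndarray, n: int) -> np.ndarray:
    if len(idx) == n:
        return emb
    return np.interp(np.arange(n), idx, emb)


def mds_reduce(epoch: EEGEpoch, max_points: int = 2000) -> ReducedSignal:
    """First principal coordinate of classical (Torgerson) MDS.

    Classical MDS on Euclidean distances equals the spectral decomposition
    of the double-centred Gram matrix of the points; the rank-1 coordinate
    is obtained equivalently (and without materializing the n x n matrix)
    from the leading singular pair of the centred point matrix.
    """
    if epoch.n_channels < 2:
        raise ValueError("MDS needs at least 2 channels")
    if not np.isfinite(epoch.data).all():
        raise ValueError("non-finite distances")
    n = epoch.n_samples
    idx = _subsample_indices(n, max_points)
    pts = epoch.data.T[idx]  # points x channels
    pts = pts - pts.mean(axis=0, keepdims=True)
    # leading singular pair of the centred cloud == rank-1 principal coordinate
    u, s, _ = sla.svd(pts, full_matrices=False)
    coord = u[:, 0] * s[0]
    if coord[np.argmax(np.abs(coord))] < 0:
        coord = -coord
    values = _interp_back(idx, coord, n)
    return ReducedSignal(values, "mds", {"max_points": max_points, "n_used": len(idx)})


def lle_weights(points: np.ndarray, k: int, reg: float = 1e-3) -> sp.csr_matrix:
    """Barycentric reconstruction weights of locally linear embedding.

    Each row reconstructs one point from its ``k`` nearest neighbours
    (weights summing to one, zero outside the neighbourhood).  Singular
    local Gram matrices are conditioned with a ridge of ``reg * trace``.
    """
    n = points.shape[0]
    if k >= n:
        raise ValueError(f"need k < n_points, got k={k}, n={n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    _, neigh = nn.kneighbors(points)
    neigh = neigh[:, 1:]  # drop self
    rows = np.repeat(np.arange(n), k)
    cols = neigh.ravel()
    data = np.empty(n * k)
    ones = np.ones(k)
    for i in range(n):
        z = points[neigh[i]] - points[i]
        gram = z @ z.T
        trace = np.trace(gram)
        if trace > 0:
            gram = gram + reg * trace * np.eye(k)
        else:
            gram = gram + reg * np.eye(k)
            log.warning("LLE: degenerate neighbourhood at point %d", i)
        w = sla.solve(gram, ones, assume_a="pos")
        data[i * k : (i + 1) * k] = w / w.sum()
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def lle_reduce(
    epoch: EEGEpoch, K: int = 40, max_points: int = 2000, reg: float = 1e-3
) -> ReducedSignal:
    """Locally linear embedding of the sample cloud to one dimension.

    The embedding is the eigenvector of ``(I - W)'(I - W)`` with the
    smallest non-zero eigenvalue, rescaled to zero mean and unit variance
    (the embedding constraints of the method).
    """
    n = epoch.n_samples
    idx = _subsample_indices(n, max_points)
    pts = epoch.data.T[idx]
    m = len(idx)
    if K >= m:
        raise ValueError(f"K={K} must be smaller than the number of points ({m})")
    w = lle_weights(pts, K, reg=reg)
    iw = sp.identity(m, format="csr") - w
    m_mat = (iw.T @ iw).tocsc()
    # two smallest eigenpairs; the smallest is the constant vector (eigenvalue ~0)
    vals, vecs = spla.eigsh(m_mat, k=2, sigma=0.0, which="LM")
    order = np.argsort(vals)
    emb = vecs[:, order[1]]
    emb = emb - emb.mean()
    std = emb.std()
    if std == 0:
        raise ValueError("LLE produced a constant embedding")
    emb = emb / std
    if emb[np.argmax(np.abs(emb))] < 0:
        emb = -emb
    values = _interp_back(idx, emb, n)
    return ReducedSignal(values, "lle", {"K": K, "reg": reg, "n_used": m})


def _inv_sqrt_psd(c: np.ndarray, rcond: float) -> np.ndarray:
    """Whitening transform ``C^(-1/2)`` of a PSD matrix.

    Rank-deficient directions (eigenvalues below ``rcond * max eigenvalue``)
    are truncated, pseudo-inverse style; a ridge would instead bias the
    canonical correlation and break its invariance under channel remixing.
    """
    evals, evecs = sla.eigh(c)
    if evals[-1] <= 0:
        return np.zeros_like(c)
    keep = evals > rcond * evals[-1]
    if not keep.all():
        log.warning(
            "rank-deficient covariance: dropped %d of %d directions",
            int((~keep).sum()),
            len(evals),
        )
    inv = np.where(keep, 1.0 / np.sqrt(np.where(keep, evals, 1.0)), 0.0)
    return (evecs * inv) @ evecs.T


def cca_fit(X: np.ndarray, Y: np.ndarray, rcond: float = 1e-12) -> CCAProjection:
    """First canonical pair maximizing ``corr(wx' X, wy' Y)``.

    Solved through the whitened cross-covariance SVD; rank-deficient
    covariances are handled by spectral truncation at ``rcond`` times the
    leading eigenvalue.  The sign of (wx, wy) is fixed so the X projection
    correlates non-negatively with the first template row.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"sample mismatch: X has {X.shape[1]}, Y has {Y.shape[1]}")
    n = X.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    xc = X - X.mean(axis=1, keepdims=True)
    yc = Y - Y.mean(axis=1, keepdims=True)
    cxx = xc @ xc.T / (n - 1)
    cyy = yc @ yc.T / (n - 1)
    cxy = xc @ yc.T / (n - 1)
    wxx = _inv_sqrt_psd(cxx, rcond)
    wyy = _inv_sqrt_psd(cyy, rcond)
    u, s, vt = sla.svd(wxx @ cxy @ wyy)
    rho = float(np.clip(s[0], 0.0, 1.0))
    wx = wxx @ u[:, 0]
    wy = wyy @ vt[0]
    # sign convention: projection correlates positively with template row 0
    if float((wx @ xc) @ yc[0]) < 0:
        wx, wy = -wx, -wy
    return CCAProjection(wx=wx, wy=wy, rho=rho)


def cca_reduce(epoch: EEGEpoch, bank: TemplateBank, f: float) -> ReducedSignal:
    """Project the epoch onto the CCA channel weights fitted against the
    reference template of frequency ``f``."""
    y = bank[f]
    if bank.n_samples != epoch.n_samples:
        raise ValueError(
            f"bank built for {bank.n_samples} samples, epoch has {epoch.n_samples}"
        )
    proj = cca_fit(epoch.data, y)
    values = proj.wx @ (epoch.data - epoch.data.mean(axis=1, keepdims=True))
    return ReducedSignal(values, "cca", {"f": f, "wx": proj.wx, "rho": proj.rho})
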
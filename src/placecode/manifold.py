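"""Neural-manifold embedding and position decoding.

The population activity matrix X (N cells x T moving frames) is embedded by
classical multidimensional scaling of the pairwise cosine dissimilarity
between population vectors: the squared-dissimilarity matrix is
double-centered (B = -1/2 J D^2 J) and eigendecomposed, and component t
courses are the leading eigenvectors scaled by the square roots of their
eigenvalues. Cosine distance compares the direction, not the magnitude, of
population vectors, so the embedding is invariant to global activity
scaling. Manifold dimensionality is the number of components required to
explain 90% of the (positive-spectrum) variance. Angular position is decoded
from the leading components with an optimal linear estimator (least-squares
readout of cos/sin of the angle) under five-fold cross-validation over
contiguous temporal blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .errors import InsufficientDataError

# ---------------------------------------------------------------------------
# Classical MDS
# ---------------------------------------------------------------------------

@dataclass
class ManifoldEmbedding:
    components: np.ndarray          # M x T (rows ordered by eigenvalue)
    eigenvalues: np.ndarray         # full spectrum, non-increasing
    variance_explained: np.ndarray  # cumulative fraction over positive spectrum
    method: str = "cmds-cosine"
    kept_frames: np.ndarray | None = None  # indices into the original frames

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def n_frames(self) -> int:
        return self.components.shape[1]


def classical_mds(
    dissimilarity: np.ndarray, n_components: int | None = None
) -> ManifoldEmbedding:
    """Classical (Torgerson) MDS of a T x T dissimilarity matrix.

    Keeps components with positive eigenvalues (up to ``n_components``);
    negative eigenvalues of a non-Euclidean dissimilarity are retained in
    the reported spectrum but excluded from the variance accounting.
    """
    d = np.asarray(dissimilarity, dtype=float)
    t = d.shape[0]
    b = d ** 2
    b = b - b.mean(axis=0, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    b *= -0.5
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    pos = eigval > max(1e-12, 1e-9 * abs(eigval[0])) if eigval[0] > 0 else \
        np.zeros(t, dtype=bool)
    n_pos = int(pos.sum())
    m = n_pos if n_components is None else min(n_components, n_pos)
    comps = (eigvec[:, :m] * np.sqrt(eigval[:m])).T
    pos_sum = eigval[pos].sum()
    cumvar = (np.cumsum(eigval[pos]) / pos_sum) if n_pos else np.array([])
    return ManifoldEmbedding(comps, eigval, cumvar)


def embed_population(
    x: np.ndarray,
    n_components: int | None = None,
    method: str = "cmds-cosine",
) -> ManifoldEmbedding:
    """Embed a cells x frames population matrix.

    The default is classical MDS of pairwise cosine dissimilarities between
    population vectors. Frames with an all-zero population vector (no
    activity while moving) have no direction and are dropped before
    computing cosine distances; ``kept_frames`` records the surviving frame
    indices so position labels can be subset to match. ``method="pca"``
    provides a principal-component backend behind the same interface (for
    comparison; it keeps all frames).
    """
    x = np.asarray(x, dtype=float)
    if method == "pca":
        centered = x - x.mean(axis=1, keepdims=True)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        eigval = s ** 2 / max(x.shape[1] - 1, 1)
        m = eigval.size if n_components is None else min(n_components,
                                                         eigval.size)
        pos = eigval > 1e-12 * max(eigval[0], 1.0)
        emb = ManifoldEmbedding(
            components=(vt[:m] * s[:m, None]) / np.sqrt(max(x.shape[1] - 1, 1)),
            eigenvalues=eigval,
            variance_explained=np.cumsum(eigval[pos]) / eigval[pos].sum(),
            method="pca",
            kept_frames=np.arange(x.shape[1]),
        )
        return emb
    if method != "cmds-cosine":
        raise InsufficientDataError(f"unknown embedding method {method!r}")
    norms = np.linalg.norm(x, axis=0)
    kept = np.nonzero(norms > 0)[0]
    if kept.size < 3:
        raise InsufficientDataError("fewer than 3 nonzero population vectors")
    d = squareform(pdist(x[:, kept].T, metric="cosine"))
    emb = classical_mds(d, n_components)
    emb.kept_frames = kept
    return emb


def manifold_dimensionality(emb: ManifoldEmbedding, threshold: float = 0.9) -> int:
    """Smallest number of components whose cumulative variance reaches
    ``threshold``."""
    if emb.variance_explained.size == 0:
        raise InsufficientDataError("empty positive spectrum")
    return int(np.searchsorted(emb.variance_explained, threshold) + 1)


def dimensionality_curve(
    x: np.ndarray,
    ensemble_sizes: list[int],
    n_draws: int = 5,
    seed: int | np.random.Generator | None = 0,
    threshold: float = 0.9,
) -> np.ndarray:
    """Mean manifold dimensionality vs number of cells in the ensemble.

    For each size, draws ``n_draws`` random cell subsets (a single draw when
    the size equals the full population) and averages the 90%-variance
    dimensionality over draws.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    out = []
    for size in ensemble_sizes:
        if size > n:
            raise InsufficientDataError(f"ensemble size {size} exceeds {n} cells")
        draws = 1 if size == n else n_draws
        dims = []
        for _ in range(draws):
            cells = rng.choice(n, size=size, replace=False)
            emb = embed_population(x[cells])
            dims.append(manifold_dimensionality(emb, threshold))
        out.append(float(np.mean(dims)))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Optimal linear estimator decoding
# ---------------------------------------------------------------------------

@dataclass
class DecoderResult:
    predicted_deg: np.ndarray
    true_deg: np.ndarray
    fold_of_frame: np.ndarray
    pearson_r: float              # mean of pooled r on cos and sin components
    circular_r: float
    n_dims: int


def _blocked_folds(t: int, k: int) -> np.ndarray:
    fold = np.empty(t, dtype=int)
    for i, chunk in enumerate(np.array_split(np.arange(t), k)):
        fold[chunk] = i
    return fold


def circular_correlation(a_deg: np.ndarray, b_deg: np.ndarray) -> float:
    """Fisher-Lee circular correlation coefficient."""
    a = np.radians(a_deg)
    b = np.radians(b_deg)
    sa = np.sin(a - np.angle(np.exp(1j * a).mean()))
    sb = np.sin(b - np.angle(np.exp(1j * b).mean()))
    denom = np.sqrt(np.sum(sa ** 2) * np.sum(sb ** 2))
    if denom == 0:
        return np.nan
    return float(np.sum(sa * sb) / denom)


def decode_position_cv(
    emb: ManifoldEmbedding | np.ndarray,
    theta_deg: np.ndarray,
    n_dims: int = 3,
    k_folds: int = 5,
    blocked: bool = True,
    seed: int | np.random.Generator | None = 0,
) -> DecoderResult:
    """Decode angular position from manifold components, cross-validated.

    An optimal linear estimator (least-squares linear map with intercept)
    is trained per fold from the first ``n_dims`` components to the
    (cos, sin) encoding of the angle; the predicted angle is the atan2 of
    the held-out predictions. Folds are contiguous temporal blocks by
    default (limiting autocorrelation leakage); ``blocked=False`` uses a
    seeded random frame partition instead. Performance is the mean of the
    Pearson correlations between predicted and true cos and sin over all
    held-out frames; the circular correlation is reported alongside.
    """
    y = emb.components if isinstance(emb, ManifoldEmbedding) else np.asarray(emb)
    if n_dims > y.shape[0]:
        raise InsufficientDataError(
            f"requested {n_dims} dims, embedding has {y.shape[0]}"
        )
    theta = np.asarray(theta_deg, dtype=float)
    t = y.shape[1]
    if theta.size != t:
        raise InsufficientDataError("label count does not match embedded frames")
    if t < k_folds:
        raise InsufficientDataError("fewer frames than folds")
    feats = np.column_stack([np.ones(t), y[:n_dims].T])
    targets = np.column_stack([np.cos(np.radians(theta)), np.sin(np.radians(theta))])
    if blocked:
        fold = _blocked_folds(t, k_folds)
    else:
        rng = np.random.default_rng(seed)
        fold = rng.permutation(t) % k_folds
    pred = np.empty_like(targets)
    for f in range(k_folds):
        test = fold == f
        train = ~test
        if test.sum() < 2 or train.sum() < 2:
            raise InsufficientDataError("fold with fewer than 2 samples")
        w, *_ = np.linalg.lstsq(feats[train], targets[train], rcond=None)
        pred[test] = feats[test] @ w
    r_cos = pearsonr(pred[:, 0], targets[:, 0])[0]
    r_sin = pearsonr(pred[:, 1], targets[:, 1])[0]
    pred_deg = np.mod(np.degrees(np.arctan2(pred[:, 1], pred[:, 0])), 360.0)
    return DecoderResult(
        predicted_deg=pred_deg,
        true_deg=np.mod(theta, 360.0),
        fold_of_frame=fold,
        pearson_r=float((r_cos + r_sin) / 2.0),
        circular_r=circular_correlation(pred_deg, np.mod(theta, 360.0)),
        n_dims=n_dims,
    )
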
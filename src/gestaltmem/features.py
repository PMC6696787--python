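"""Feature-space distinctiveness: k-NN sparseness and PCA+KDE likelihood.

Both measures treat an image's feature vector (in practice a CNN embedding;
here any real matrix) relative to the other images of its category:

* sparseness — the Euclidean distance to the k-th nearest same-category
  neighbor (default k = 3, self excluded); large distances mean the image
  sits in a sparse region of its category's feature cloud;
* KDE likelihood — the context vectors of a category are projected onto
  their top principal components, a Gaussian kernel density is fit to the
  projected context, and each scored image receives the negative log
  density of its projection. High values again mean atypical images.

The kernel density is isotropic: with n context points, d components and
bandwidth h, the density at q is

    (1 / (n h^d (2 pi)^(d/2))) * sum_i exp(-||q - c_i||^2 / (2 h^2)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .core import DegenerateDataError, ParameterError, make_score_table

__all__ = ["KDEConfig", "sparseness_scores", "kde_likelihood_scores"]


@dataclass
class KDEConfig:
    """PCA/KDE hyperparameters.

    ``n_components`` is either an integer component count or a fraction in
    (0, 1) meaning the smallest count retaining that much context variance;
    it is always capped by ``min(n_context - 1, dim)``. ``bandwidth_rule``
    is ``"scott"`` (h = sigma-bar * n^(-1/(d+4))), ``"silverman"``
    (h = sigma-bar * (n (d+2) / 4)^(-1/(d+4))) or ``"fixed"`` (requires
    ``bandwidth``), where sigma-bar is the RMS per-component SD of the
    projected context. ``include_self`` keeps a scored image's own kernel
    in its density when the image is part of the context (the convention
    when the context includes the scored set); set False for leave-one-out.
    """

    n_components: Union[int, float] = 0.95
    bandwidth_rule: str = "scott"
    bandwidth: Optional[float] = None
    include_self: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.n_components, float):
            if not 0.0 < self.n_components <= 1.0:
                raise ParameterError("fractional n_components must lie in (0, 1]")
        elif self.n_components < 1:
            raise ParameterError("n_components must be >= 1")
        if self.bandwidth_rule not in ("scott", "silverman", "fixed"):
            raise ParameterError("bandwidth_rule must be scott, silverman or fixed")
        if self.bandwidth_rule == "fixed":
            if self.bandwidth is None or self.bandwidth <= 0:
                raise ParameterError("fixed bandwidth_rule requires bandwidth > 0")


def _split_features(features: pd.DataFrame):
    if "category" not in features.columns:
        raise ParameterError("feature matrix must carry a 'category' column")
    cols = [c for c in features.columns if c != "category"]
    x = features[cols].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ParameterError("feature matrix contains non-finite values")
    return features.index.to_numpy(), features["category"].to_numpy(), x


def sparseness_scores(features: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Distance to the k-th nearest same-category neighbor, per image.

    ``features`` is indexed by image_id with a ``category`` column and
    numeric feature columns. Every category must contain at least k + 1
    images. Ties in neighbor rank are resolved by distance sorting (equal
    distances give equal scores, so the tie-break is immaterial).
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    ids, cats, x = _split_features(features)
    scores = np.empty(len(ids))
    for c in pd.unique(cats):
        idx = np.flatnonzero(cats == c)
        if len(idx) < k + 1:
            raise ParameterError(
                f"category {c!r} has {len(idx)} images; sparseness with k={k} "
                f"needs at least {k + 1}"
            )
        dist = cdist(x[idx], x[idx])
        # Row-sorted distances: column 0 is the self distance (0).
        scores[idx] = np.sort(dist, axis=1)[:, k]
    return make_score_table(ids, cats, scores, np.ones(len(ids), dtype=int),
                            "sparseness")


def _resolve_bandwidth(projected: np.ndarray, config: KDEConfig) -> float:
    n, d = projected.shape
    if config.bandwidth_rule == "fixed":
        return float(config.bandwidth)
    sigma = float(np.sqrt(projected.var(axis=0, ddof=1).mean()))
    if sigma == 0:
        raise DegenerateDataError(
            "projected context has zero variance; supply a fixed bandwidth "
            "(bandwidth_rule='fixed') or a larger context"
        )
    if config.bandwidth_rule == "scott":
        return sigma * n ** (-1.0 / (d + 4))
    return sigma * (n * (d + 2) / 4.0) ** (-1.0 / (d + 4))


def kde_density(query: np.ndarray, context: np.ndarray, h: float,
                exclude: Optional[np.ndarray] = None) -> np.ndarray:
    """Isotropic Gaussian kernel density of query points given context.

    ``exclude[i]`` optionally names a context row left out of query i's sum
    (leave-one-out). Implements the explicit kernel-sum formula directly.
    """
    n, d = context.shape
    sq = cdist(query, context, "sqeuclidean")
    kernels = np.exp(-sq / (2.0 * h * h))
    if exclude is None:
        dens = kernels.sum(axis=1) / n
    else:
        mask = np.ones_like(kernels)
        valid = exclude >= 0
        mask[np.flatnonzero(valid), exclude[valid]] = 0.0
        counts = np.where(valid, n - 1, n)
        dens = (kernels * mask).sum(axis=1) / counts
    return dens / (h**d * (2.0 * np.pi) ** (d / 2.0))


def kde_likelihood_scores(
    features: pd.DataFrame,
    context: Optional[pd.DataFrame] = None,
    config: Optional[KDEConfig] = None,
) -> pd.DataFrame:
    """Negative log KDE density per image, within its category context.

    ``context`` defaults to ``features`` itself; it may be a larger
    feature matrix (the scored set's own categories can be too small for a
    stable density, in which case a wider context with more exemplars per
    category should be supplied). Per category, the PCA basis and the
    bandwidth are estimated from the context, and each scored image gets
    the negative log density of its projection.
    """
    config = config or KDEConfig()
    if context is None:
        context = features
    ids, cats, x = _split_features(features)
    ctx_ids, ctx_cats, ctx_x = _split_features(context)
    if x.shape[1] != ctx_x.shape[1]:
        raise ParameterError("features and context must share dimensionality")

    scores = np.empty(len(ids))
    for c in pd.unique(cats):
        q_idx = np.flatnonzero(cats == c)
        c_idx = np.flatnonzero(ctx_cats == c)
        if len(c_idx) < 3:
            raise ParameterError(
                f"context for category {c!r} has {len(c_idx)} images; "
                "at least 3 are required"
            )
        cap = min(len(c_idx) - 1, ctx_x.shape[1])
        if isinstance(config.n_components, float) and config.n_components < 1.0:
            pca = PCA(n_components=None).fit(ctx_x[c_idx])
            cum = np.cumsum(pca.explained_variance_ratio_)
            d = min(int(np.searchsorted(cum, config.n_components) + 1), cap)
        else:
            d = min(int(config.n_components), cap)
        pca = PCA(n_components=d).fit(ctx_x[c_idx])
        ctx_proj = pca.transform(ctx_x[c_idx])
        q_proj = pca.transform(x[q_idx])
        h = _resolve_bandwidth(ctx_proj, config)

        exclude = None
        if not config.include_self:
            ctx_pos = {img: j for j, img in enumerate(ctx_ids[c_idx])}
            exclude = np.array([ctx_pos.get(img, -1) for img in ids[q_idx]])
        dens = kde_density(q_proj, ctx_proj, h, exclude=exclude)
        if np.any(dens <= 0):
            raise DegenerateDataError(
                f"zero density for some images of category {c!r}; increase the "
                "bandwidth or the context size"
            )
        scores[q_idx] = -np.log(dens)
    return make_score_table(ids, cats, scores, np.ones(len(ids), dtype=int),
                            "cnn_likelihood")
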
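"""Split-half consistency of per-image scores.

The participant pool is repeatedly split at random into two halves, the
scoring rule is applied to each half's trials, and Spearman's rank
correlation between the two half-based score vectors is computed per
category over the images scoreable in both halves. Averaging the
correlations over the resamples estimates how consistent the score ranking
is across observers — the same procedure commonly applied to memorability
scores.

For the built-in scorers every per-image score is a ratio of sums over
trials (correct/congruent counts, RT sums/included counts, rating
sums/counts), so each half's scores can be computed from per-participant
numerator and denominator matrices. That makes 10^4 resamples cheap.
Arbitrary scorer callables are supported through a slower path that calls
the scorer on each half's trial table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import ParameterError, SchemaError, logger
from . import scoring

__all__ = ["SplitHalfResult", "split_half_consistency"]

#: Minimum images scoreable in both halves for a split to contribute.
MIN_IMAGES_PER_SPLIT = 3


@dataclass
class SplitHalfResult:
    """Per-category split-half consistency estimates.

    ``mean_rho`` maps category -> mean Spearman rho over contributing
    splits (NaN if no split was usable); ``rho_samples`` holds the raw
    per-split correlations; ``n_images_used`` the mean number of images
    entering each split's correlation.
    """

    mean_rho: Dict[str, float]
    rho_samples: Dict[str, np.ndarray]
    n_participants_half: Tuple[int, int]
    n_images_used: Dict[str, float]
    n_splits: int
    seed: int

    def summary(self) -> pd.DataFrame:
        """One row per category: mean rho, number of usable splits, images used."""
        cats = sorted(self.mean_rho)
        return pd.DataFrame(
            {
                "category": cats,
                "mean_rho": [self.mean_rho[c] for c in cats],
                "n_samples": [len(self.rho_samples[c]) for c in cats],
                "mean_n_images": [self.n_images_used[c] for c in cats],
            }
        )


def _trial_decomposition(trials: pd.DataFrame, kind: str, rt_limit: float):
    """Per-trial (value, include) arrays such that a pool's per-image score
    is sum(value)/sum(include) over its trials."""
    if kind == "categorizability":
        include = trials["congruent"].astype(bool).to_numpy()
        value = (trials["correct"].astype(bool) & include).to_numpy(dtype=float)
    elif kind == "shrinkability":
        include = trials["outcome"].isin(["correct", "timeout"]).to_numpy()
        rt = trials["rt"].to_numpy(dtype=float).copy()
        rt[(trials["outcome"] == "timeout").to_numpy()] = rt_limit
        value = np.where(include, rt, 0.0)
    elif kind == "distinctiveness":
        include = np.ones(len(trials), dtype=bool)
        value = trials["rating"].to_numpy(dtype=float)
    else:
        raise ParameterError(f"no fast decomposition for scorer kind {kind!r}")
    return value, include.astype(float)


_SCORER_KINDS = {
    scoring.categorizability_scores: "categorizability",
    scoring.shrinkability_scores: "shrinkability",
    scoring.distinctiveness_scores: "distinctiveness",
}


def _infer_kind(trials: pd.DataFrame) -> str:
    if "congruent" in trials.columns:
        return "categorizability"
    if "outcome" in trials.columns:
        return "shrinkability"
    if "rating" in trials.columns:
        return "distinctiveness"
    raise SchemaError("cannot infer paradigm from trial table columns")


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    ra, rb = rankdata(a), rankdata(b)
    sa, sb = ra.std(), rb.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.mean((ra - ra.mean()) * (rb - rb.mean())) / (sa * sb))


def split_half_consistency(
    trials: pd.DataFrame,
    scorer: Union[str, Callable[[pd.DataFrame], pd.DataFrame], None] = None,
    n_splits: int = 1000,
    seed: int = 0,
    rt_limit: float = 6.0,
) -> SplitHalfResult:
    """Estimate per-category split-half consistency of a score.

    Parameters
    ----------
    trials
        A trial table of any of the three paradigms.
    scorer
        One of the scoring functions (:func:`scoring.categorizability_scores`,
        :func:`scoring.shrinkability_scores`,
        :func:`scoring.distinctiveness_scores`), the corresponding kind
        string, ``None`` (infer from the table's columns), or an arbitrary
        callable ``trials -> score table`` (slow path).
    n_splits
        Number of random participant splits (1000 in the original
        analyses).
    seed
        Seed of the split stream; results are deterministic in
        (trials, n_splits, seed).

    With an odd participant count the halves have sizes floor(n/2) and
    ceil(n/2). Within a split, only images scoreable in both halves enter
    the per-category Spearman correlation; splits leaving a category with
    fewer than three such images, or a tied-constant score vector,
    contribute no sample for that category.
    """
    if n_splits < 1:
        raise ParameterError("n_splits must be >= 1")
    participants = trials["participant_id"].unique()
    n_p = len(participants)
    if n_p < 2:
        raise ParameterError("split-half consistency requires >= 2 participants")

    custom: Optional[Callable] = None
    if callable(scorer):
        kind = _SCORER_KINDS.get(scorer)
        if kind is None:
            custom = scorer
            kind = None
    elif isinstance(scorer, str):
        kind = scorer
    else:
        kind = _infer_kind(trials)

    rng = np.random.default_rng(seed)
    half = n_p // 2

    if custom is None:
        value, include = _trial_decomposition(trials, kind, rt_limit)
        pidx = pd.Categorical(trials["participant_id"], categories=participants).codes
        image_ids, iidx = np.unique(trials["image_id"].to_numpy(), return_inverse=True)
        n_img = len(image_ids)
        num = np.zeros((n_p, n_img))
        den = np.zeros((n_p, n_img))
        np.add.at(num, (pidx, iidx), value)
        np.add.at(den, (pidx, iidx), include)
        img_cat = (
            trials.drop_duplicates("image_id").set_index("image_id")["category"]
        ).reindex(image_ids).to_numpy()
        cat_cols = {c: np.flatnonzero(img_cat == c) for c in pd.unique(img_cat)}
    else:
        by_participant = {p: t for p, t in trials.groupby("participant_id", sort=False)}
        cat_cols = None

    categories = list(pd.unique(trials["category"]))
    samples: Dict[str, list] = {c: [] for c in categories}
    images_used: Dict[str, list] = {c: [] for c in categories}
    skipped = 0

    for _ in range(n_splits):
        perm = rng.permutation(n_p)
        a_idx, b_idx = perm[:half], perm[half:]
        if custom is None:
            num_a, den_a = num[a_idx].sum(axis=0), den[a_idx].sum(axis=0)
            num_b, den_b = num[b_idx].sum(axis=0), den[b_idx].sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                score_a = num_a / den_a
                score_b = num_b / den_b
            usable = (den_a > 0) & (den_b > 0)
            for c, cols in cat_cols.items():
                use = cols[usable[cols]]
                if len(use) < MIN_IMAGES_PER_SPLIT:
                    skipped += 1
                    continue
                rho = _spearman(score_a[use], score_b[use])
                if np.isnan(rho):
                    skipped += 1
                    continue
                samples[c].append(rho)
                images_used[c].append(len(use))
        else:
            ta = trials[trials["participant_id"].isin(participants[a_idx])]
            tb = trials[trials["participant_id"].isin(participants[b_idx])]
            sa, sb = custom(ta), custom(tb)
            merged = sa.merge(sb, on=["image_id", "category"], suffixes=("_a", "_b"))
            for c, grp in merged.groupby("category"):
                if len(grp) < MIN_IMAGES_PER_SPLIT:
                    skipped += 1
                    continue
                rho = _spearman(grp["score_a"].to_numpy(), grp["score_b"].to_numpy())
                if np.isnan(rho):
                    skipped += 1
                    continue
                samples[c].append(rho)
                images_used[c].append(len(grp))

    if skipped:
        logger.info("split_half_consistency: %d category-splits skipped", skipped)

    mean_rho = {
        c: (float(np.mean(v)) if v else float("nan")) for c, v in samples.items()
    }
    return SplitHalfResult(
        mean_rho=mean_rho,
        rho_samples={c: np.asarray(v) for c, v in samples.items()},
        n_participants_half=(half, n_p - half),
        n_images_used={
            c: (float(np.mean(v)) if v else float("nan"))
            for c, v in images_used.items()
        },
        n_splits=n_splits,
        seed=seed,
    )
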
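"""Per-image behavioral scores and per-participant signal-detection metrics.

Scoring rules follow the original operationalizations exactly:

* categorizability — the proportion of participants who categorized the
  image correctly on its congruent trials; a non-response counts as
  incorrect and stays in the denominator;
* shrinkability — the mean thumbnail-search RT over a participant pool,
  excluding wrong-click trials and fixing no-response RTs at the response
  limit (lower = more shrinkable);
* exclusion rate — the fraction of an image's search trials on which a
  distractor was clicked;
* perceived distinctiveness — the mean of the 7-point ratings.

Signal-detection metrics use the equal-variance Gaussian model: hit rate H
is accuracy on congruent (label-matching) trials, false-alarm rate F the
'yes' rate on incongruent trials, d' = z(H) - z(F) and the likelihood-ratio
criterion beta = exp((z(F)^2 - z(H)^2) / 2).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import DegenerateDataError, SchemaError, logger, make_score_table

__all__ = [
    "categorizability_scores",
    "sdt_metrics",
    "shrinkability_scores",
    "exclusion_rates",
    "distinctiveness_scores",
    "per_category_descriptives",
]


def _image_categories(trials: pd.DataFrame) -> pd.Series:
    cats = trials.groupby("image_id", sort=False)["category"].agg(
        lambda s: s.iloc[0] if s.nunique() == 1 else None
    )
    if cats.isna().any():
        bad = cats.index[cats.isna()].tolist()[:5]
        raise SchemaError(f"images with inconsistent category labels: {bad}")
    return cats


def categorizability_scores(trials: pd.DataFrame) -> pd.DataFrame:
    """Proportion correct on congruent trials, per image.

    Images without any congruent trial are excluded from the output with a
    logged warning. Non-responses count as incorrect.
    """
    cong = trials[trials["congruent"].astype(bool)]
    all_images = trials["image_id"].unique()
    grouped = cong.groupby("image_id", sort=False)
    n = grouped.size()
    correct = grouped["correct"].sum()
    dropped = set(all_images) - set(n.index)
    if dropped:
        logger.warning(
            "categorizability: %d image(s) had no congruent trials and were "
            "excluded: %s", len(dropped), sorted(dropped)[:5]
        )
    cats = _image_categories(trials).reindex(n.index)
    return make_score_table(
        n.index.to_numpy(),
        cats.to_numpy(),
        (correct / n).to_numpy(dtype=float),
        n.to_numpy(),
        "categorizability",
    )


def _corrected_rate(count: np.ndarray, total: np.ndarray, correction: str) -> np.ndarray:
    rate = count / total
    if correction == "half_count":
        rate = np.where(rate <= 0.0, 1.0 / (2.0 * total), rate)
        rate = np.where(rate >= 1.0, 1.0 - 1.0 / (2.0 * total), rate)
    elif correction == "none":
        if np.any((rate <= 0.0) | (rate >= 1.0)):
            raise DegenerateDataError(
                "extreme hit/false-alarm rate (0 or 1) with correction='none'; "
                "d' and beta are undefined — use correction='half_count'"
            )
    else:
        raise SchemaError(f"unknown sdt correction {correction!r}")
    return rate


def sdt_metrics(trials: pd.DataFrame, correction: str = "half_count") -> pd.DataFrame:
    """Per-participant signal-detection metrics for the categorization study.

    Returns a DataFrame with one row per participant: ``hit_rate``,
    ``fa_rate`` (both after the extreme-rate correction), ``d_prime``,
    ``beta``, and uncorrected percent-correct summaries (overall,
    congruent, incongruent).
    """
    t = trials.copy()
    t["congruent"] = t["congruent"].astype(bool)
    t["correct"] = t["correct"].astype(bool)
    g = t.groupby("participant_id", sort=False)
    n_cong = g["congruent"].sum().to_numpy(dtype=float)
    n_trials = g.size().to_numpy(dtype=float)
    n_incong = n_trials - n_cong
    if np.any(n_cong < 1) or np.any(n_incong < 1):
        raise SchemaError(
            "every participant needs at least one congruent and one "
            "incongruent trial for SDT metrics"
        )
    hits = g.apply(
        lambda x: (x["congruent"] & x["correct"]).sum(), include_groups=False
    ).to_numpy(dtype=float)
    # A false alarm is a 'yes' on an incongruent trial, i.e. an incorrect one.
    fas = g.apply(
        lambda x: (~x["congruent"] & ~x["correct"]).sum(), include_groups=False
    ).to_numpy(dtype=float)
    correct_cong = hits
    correct_incong = n_incong - fas

    h = _corrected_rate(hits, n_cong, correction)
    f = _corrected_rate(fas, n_incong, correction)
    zh, zf = norm.ppf(h), norm.ppf(f)
    return pd.DataFrame(
        {
            "participant_id": list(g.groups.keys()),
            "hit_rate": h,
            "fa_rate": f,
            "d_prime": zh - zf,
            "beta": np.exp((zf**2 - zh**2) / 2.0),
            "percent_correct": (correct_cong + correct_incong) / n_trials,
            "percent_correct_congruent": correct_cong / n_cong,
            "percent_correct_incongruent": correct_incong / n_incong,
        }
    )


def shrinkability_scores(trials: pd.DataFrame, rt_limit: float = 6.0) -> pd.DataFrame:
    """Mean search RT per image: wrong clicks excluded, timeouts fixed at the limit."""
    t = trials.copy()
    included = t["outcome"].isin(["correct", "timeout"])
    t.loc[t["outcome"] == "timeout", "rt"] = rt_limit
    kept = t[included]
    all_images = t["image_id"].unique()
    grouped = kept.groupby("image_id", sort=False)
    n = grouped.size()
    mean_rt = grouped["rt"].mean()
    dropped = set(all_images) - set(n.index)
    if dropped:
        logger.warning(
            "shrinkability: %d image(s) had only wrong-click trials and were "
            "excluded: %s", len(dropped), sorted(dropped)[:5]
        )
    cats = _image_categories(t).reindex(n.index)
    return make_score_table(
        n.index.to_numpy(),
        cats.to_numpy(),
        mean_rt.to_numpy(dtype=float),
        n.to_numpy(),
        "shrinkability",
    )


def exclusion_rates(trials: pd.DataFrame) -> pd.DataFrame:
    """Fraction of an image's search trials that ended in a wrong click."""
    g = trials.groupby("image_id", sort=False)
    n = g.size()
    wrong = g["outcome"].agg(lambda s: (s == "wrong_click").sum())
    cats = _image_categories(trials).reindex(n.index)
    return make_score_table(
        n.index.to_numpy(),
        cats.to_numpy(),
        (wrong / n).to_numpy(dtype=float),
        n.to_numpy(),
        "exclusion_rate",
    )


def distinctiveness_scores(ratings: pd.DataFrame) -> pd.DataFrame:
    """Mean distinctiveness rating per image."""
    g = ratings.groupby("image_id", sort=False)
    n = g.size()
    mean_rating = g["rating"].mean()
    cats = _image_categories(ratings).reindex(n.index)
    return make_score_table(
        n.index.to_numpy(),
        cats.to_numpy(),
        mean_rating.to_numpy(dtype=float),
        n.to_numpy(),
        "distinctiveness",
    )


def per_category_descriptives(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-category mean/median/SD/min/max of a score table (Table layout).

    SD is the sample standard deviation (n - 1). Categories are ordered by
    ascending mean.
    """
    g = scores.groupby("category")["score"]
    out = pd.DataFrame(
        {
            "mean": g.mean(),
            "median": g.median(),
            "sd": g.std(ddof=1),
            "min": g.min(),
            "max": g.max(),
            "n_images": g.size(),
        }
    )
    return out.sort_values("mean")
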
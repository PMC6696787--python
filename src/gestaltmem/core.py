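"""Shared domain types, configuration, and error taxonomy.

Score tables are plain :class:`pandas.DataFrame` objects with the canonical
columns ``image_id, category, score_kind, score, n_responses``; the helpers
here construct and validate them so every downstream stage can rely on the
same invariants (scores in range for their kind, at least one response per
scored image, unique image ids).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("gestaltmem")


class ParameterError(ValueError):
    """Invalid configuration or generative parameters (CLI exit code 2)."""


class SchemaError(ValueError):
    """Malformed or invariant-violating tabular data (CLI exit code 3)."""


class DegenerateDataError(ValueError):
    """Numerically degenerate input, e.g. constant vectors (CLI exit code 4)."""


#: Recognised per-image score kinds.
SCORE_KINDS = (
    "categorizability",
    "shrinkability",
    "distinctiveness",
    "memorability",
    "sparseness",
    "cnn_likelihood",
    "exclusion_rate",
    "typicality",
)

#: Canonical column order of a score table (also the CSV header).
SCORE_COLUMNS = ("image_id", "category", "score_kind", "score", "n_responses")

SUPERORDINATES = ("indoor", "outdoor")


@dataclass(frozen=True)
class ImageRef:
    """A stimulus image: opaque identifier plus its scene category."""

    image_id: str
    category: str
    superordinate: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.image_id:
            raise ParameterError("image_id must be non-empty")
        if not self.category:
            raise ParameterError("category must be non-empty")
        if self.superordinate is not None and self.superordinate not in SUPERORDINATES:
            raise ParameterError(
                f"superordinate must be one of {SUPERORDINATES}, got {self.superordinate!r}"
            )


@dataclass
class AnalysisConfig:
    """Analysis-stage knobs shared across scoring, consistency and association.

    Parameters
    ----------
    n_splits
        Number of random participant splits for split-half consistency.
    rt_limit
        Response limit of the thumbnail search task in seconds; reaction
        times of no-response trials are fixed at this value.
    nn_rank
        Neighbor rank for the sparseness measure (distance to the
        ``nn_rank``-th nearest same-category neighbor).
    rating_min, rating_max
        Bounds of the distinctiveness rating scale (representative ...
        distinctive).
    alpha
        Default significance level for hypothesis tests.
    bonferroni_alpha
        Family-wise level quoted for the Bonferroni-corrected correlation
        matrix.
    sdt_correction
        Handling of extreme hit/false-alarm rates when computing d' and
        beta: ``"half_count"`` replaces 0 by 1/(2N) and 1 by 1 - 1/(2N);
        ``"none"`` raises on extremes.
    """

    n_splits: int = 1000
    rt_limit: float = 6.0
    nn_rank: int = 3
    rating_min: int = -3
    rating_max: int = 3
    alpha: float = 0.05
    bonferroni_alpha: float = 0.001
    seed: int = 0
    sdt_correction: str = "half_count"

    def __post_init__(self) -> None:
        if self.n_splits < 1:
            raise ParameterError("n_splits must be >= 1")
        if self.rt_limit <= 0:
            raise ParameterError("rt_limit must be > 0")
        if self.nn_rank < 1:
            raise ParameterError("nn_rank must be >= 1")
        if self.rating_min >= self.rating_max:
            raise ParameterError("rating bounds must satisfy rating_min < rating_max")
        for name in ("alpha", "bonferroni_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ParameterError(f"{name} must lie in (0, 1)")
        if self.sdt_correction not in ("none", "half_count"):
            raise ParameterError("sdt_correction must be 'none' or 'half_count'")


def make_score_table(
    image_ids,
    categories,
    scores,
    n_responses,
    score_kind: str,
) -> pd.DataFrame:
    """Assemble a validated per-image score table.

    All arguments are aligned sequences of equal length; ``score_kind``
    applies to every row.
    """
    if score_kind not in SCORE_KINDS:
        raise ParameterError(f"unknown score_kind {score_kind!r}")
    df = pd.DataFrame(
        {
            "image_id": np.asarray(image_ids, dtype=object),
            "category": np.asarray(categories, dtype=object),
            "score_kind": score_kind,
            "score": np.asarray(scores, dtype=float),
            "n_responses": np.asarray(n_responses, dtype=int),
        }
    )
    return validate_score_table(df)


def validate_score_table(
    df: pd.DataFrame,
    rt_limit: Optional[float] = None,
    rating_bounds: Optional[tuple] = None,
) -> pd.DataFrame:
    """Check score-table invariants; returns the table with canonical columns.

    Range checks depend on ``score_kind``: proportions in [0, 1],
    shrinkability in (0, rt_limit] when a limit is given, ratings inside
    the rating bounds when given, sparseness non-negative.
    """
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"score table missing columns: {sorted(missing)}")
    df = df.loc[:, list(SCORE_COLUMNS)].copy()
    if df["image_id"].duplicated().any():
        dupes = df.loc[df["image_id"].duplicated(), "image_id"].tolist()[:5]
        raise SchemaError(f"duplicate image_id values in score table: {dupes}")
    unknown = set(df["score_kind"]) - set(SCORE_KINDS)
    if unknown:
        raise SchemaError(f"unknown score_kind values: {sorted(unknown)}")
    if (df["n_responses"] < 1).any():
        raise SchemaError("every scored image requires n_responses >= 1")
    if not np.isfinite(df["score"].to_numpy(dtype=float)).all():
        raise SchemaError("scores must be finite")

    s = df["score"]
    kinds = df["score_kind"]
    prop = kinds.isin(["categorizability", "memorability", "exclusion_rate"])
    if ((s[prop] < 0) | (s[prop] > 1)).any():
        raise SchemaError("proportion-valued scores must lie in [0, 1]")
    if (s[kinds == "sparseness"] < 0).any():
        raise SchemaError("sparseness scores must be non-negative")
    shrink = kinds == "shrinkability"
    if shrink.any():
        if (s[shrink] <= 0).any():
            raise SchemaError("shrinkability scores must be positive")
        if rt_limit is not None and (s[shrink] > rt_limit + 1e-12).any():
            raise SchemaError(f"shrinkability scores must not exceed rt_limit={rt_limit}")
    dist = kinds == "distinctiveness"
    if rating_bounds is not None and dist.any():
        lo, hi = rating_bounds
        if ((s[dist] < lo) | (s[dist] > hi)).any():
            raise SchemaError(f"distinctiveness scores must lie in [{lo}, {hi}]")
    return df
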
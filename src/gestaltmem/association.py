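"""Correlational statistics: standardization, Pearson/Spearman tests,
paired t-test, Bonferroni-corrected correlation matrices, and first-order
partial correlations.

Image-level correlations are computed on within-category z scores so that
between-category differences in mean score cannot masquerade as image-level
associations. The partial correlation controlling perceived distinctiveness
is the key statistic of the reanalysis: with zero-order correlations
r_xy, r_xz, r_yz it is

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) (1 - r_yz^2)),

with n - 3 degrees of freedom, and is identical to the correlation of the
least-squares residuals of x and y on z (both routes are implemented).
All p-values use the exact t reference distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist

from .core import DegenerateDataError, ParameterError, logger

__all__ = [
    "AssocEntry",
    "AssociationReport",
    "zscore_within_category",
    "pearson_test",
    "spearman_corr",
    "partial_correlation",
    "partial_from_correlations",
    "paired_t_test",
    "correlation_matrix",
    "mean_sd_correlation",
    "mean_vs_sd_correlation",
    "align_scores",
]

DIRECTIONS = ("two_sided", "greater", "less")


@dataclass
class AssocEntry:
    """One correlation test: variables, statistic, df, p, direction."""

    x: str
    y: str
    stat: str  # "pearson_r" | "spearman_rho" | "partial_r"
    value: float
    n: int
    df: int
    p: float
    direction: str = "two_sided"
    partial_of: Optional[str] = None
    bonferroni_significant: Optional[bool] = None


@dataclass
class AssociationReport:
    """A collection of correlation-test entries plus test metadata."""

    entries: List[AssocEntry] = field(default_factory=list)
    alpha: float = 0.05
    correction: str = "none"
    n_tests: int = 0

    def add(self, entry: AssocEntry) -> None:
        self.entries.append(entry)

    def to_frame(self) -> pd.DataFrame:
        if not self.entries:
            return pd.DataFrame(
                columns=[
                    "x", "y", "stat", "value", "n", "df", "p",
                    "direction", "partial_of", "bonferroni_significant",
                ]
            )
        return pd.DataFrame([vars(e) for e in self.entries])


def _check_vector(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ParameterError(f"{name} must be 1-D")
    if not np.isfinite(arr).all():
        raise ParameterError(f"{name} contains non-finite values")
    return arr


def _t_pvalue(t_stat: float, df: int, direction: str) -> float:
    if direction == "two_sided":
        return float(2.0 * t_dist.sf(abs(t_stat), df))
    if direction == "greater":
        return float(t_dist.sf(t_stat, df))
    if direction == "less":
        return float(t_dist.cdf(t_stat, df))
    raise ParameterError(f"direction must be one of {DIRECTIONS}")


def _r_pvalue(r: float, df: int, direction: str) -> float:
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        t_stat = np.inf * np.sign(r)
    else:
        t_stat = r * np.sqrt(df / (1.0 - r * r))
    return _t_pvalue(t_stat, df, direction)


def zscore_within_category(scores: pd.DataFrame) -> pd.DataFrame:
    """Standardize a score table within each category (sample SD, n - 1).

    After the transform every category has mean 0 and SD 1, so image-level
    correlations between two transformed tables cannot be driven by
    between-category differences.
    """
    out = scores.copy()
    g = out.groupby("category")["score"]
    counts, sds = g.transform("size"), g.transform("std")
    if (counts < 2).any():
        bad = out.loc[counts < 2, "category"].unique().tolist()
        raise DegenerateDataError(f"categories with fewer than 2 images: {bad}")
    if (sds == 0).any():
        bad = out.loc[sds == 0, "category"].unique().tolist()
        raise DegenerateDataError(f"constant score within category: {bad}")
    out["score"] = (out["score"] - g.transform("mean")) / sds
    return out


def pearson_test(
    x, y, direction: str = "two_sided", x_name: str = "x", y_name: str = "y"
) -> AssocEntry:
    """Pearson correlation with an exact-t hypothesis test (df = n - 2)."""
    xa, ya = _check_vector(x, "x"), _check_vector(y, "y")
    if len(xa) != len(ya):
        raise ParameterError("x and y must have equal length")
    n = len(xa)
    if n < 3:
        raise ParameterError("pearson_test requires n >= 3")
    if xa.std() == 0 or ya.std() == 0:
        raise DegenerateDataError("zero variance in x or y")
    r = float(np.corrcoef(xa, ya)[0, 1])
    df = n - 2
    return AssocEntry(
        x=x_name, y=y_name, stat="pearson_r", value=r, n=n, df=df,
        p=_r_pvalue(r, df, direction), direction=direction,
    )


def spearman_corr(x, y) -> float:
    """Spearman's rank correlation (average ranks for ties)."""
    xa, ya = _check_vector(x, "x"), _check_vector(y, "y")
    if len(xa) != len(ya):
        raise ParameterError("x and y must have equal length")
    if len(xa) < 3:
        raise ParameterError("spearman_corr requires n >= 3")
    rx, ry = rankdata(xa), rankdata(ya)
    if rx.std() == 0 or ry.std() == 0:
        raise DegenerateDataError("constant vector: Spearman rho undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def partial_from_correlations(
    r_xy: float, r_xz: float, r_yz: float,
    n: Optional[int] = None, direction: str = "two_sided",
    x_name: str = "x", y_name: str = "y", z_name: str = "z",
) -> AssocEntry:
    """First-order partial correlation from three zero-order correlations.

    Useful when only published correlation values are available. With ``n``
    given, the test uses df = n - 3.
    """
    for name, v in (("r_xy", r_xy), ("r_xz", r_xz), ("r_yz", r_yz)):
        if not -1.0 <= v <= 1.0:
            raise ParameterError(f"{name} must lie in [-1, 1]")
    if abs(r_xz) == 1.0 or abs(r_yz) == 1.0:
        raise DegenerateDataError(
            "covariate perfectly correlated with x or y: partial undefined"
        )
    value = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    if n is None:
        return AssocEntry(
            x=x_name, y=y_name, stat="partial_r", value=float(value), n=0,
            df=0, p=float("nan"), direction=direction, partial_of=z_name,
        )
    df = n - 3
    return AssocEntry(
        x=x_name, y=y_name, stat="partial_r", value=float(value), n=n, df=df,
        p=_r_pvalue(float(value), df, direction), direction=direction,
        partial_of=z_name,
    )


def partial_correlation(
    x, y, z, direction: str = "two_sided", method: str = "closed_form",
    x_name: str = "x", y_name: str = "y", z_name: str = "z",
) -> AssocEntry:
    """First-order partial correlation of x and y controlling z (df = n - 3).

    ``method="closed_form"`` uses the zero-order correlation identity;
    ``method="residual"`` correlates the least-squares residuals of x and y
    on z. The two agree to numerical precision and serve as an internal
    cross-check.
    """
    xa, ya, za = (_check_vector(v, name) for v, name in ((x, "x"), (y, "y"), (z, "z")))
    if not len(xa) == len(ya) == len(za):
        raise ParameterError("x, y, z must have equal length")
    n = len(xa)
    if n < 4:
        raise ParameterError("partial_correlation requires n >= 4")
    for v, name in ((xa, "x"), (ya, "y"), (za, "z")):
        if v.std() == 0:
            raise DegenerateDataError(f"zero variance in {name}")

    if method == "closed_form":
        c = np.corrcoef(np.vstack([xa, ya, za]))
        entry = partial_from_correlations(
            c[0, 1], c[0, 2], c[1, 2], n=n, direction=direction,
            x_name=x_name, y_name=y_name, z_name=z_name,
        )
        return entry
    if method == "residual":
        zc = np.column_stack([np.ones(n), za])
        rx = xa - zc @ np.linalg.lstsq(zc, xa, rcond=None)[0]
        ry = ya - zc @ np.linalg.lstsq(zc, ya, rcond=None)[0]
        if rx.std() == 0 or ry.std() == 0:
            raise DegenerateDataError(
                "covariate explains x or y exactly: partial undefined"
            )
        value = float(np.corrcoef(rx, ry)[0, 1])
        df = n - 3
        return AssocEntry(
            x=x_name, y=y_name, stat="partial_r", value=value, n=n, df=df,
            p=_r_pvalue(value, df, direction), direction=direction,
            partial_of=z_name,
        )
    raise ParameterError("method must be 'closed_form' or 'residual'")


def paired_t_test(a, b) -> Tuple[float, int, float]:
    """Paired t-test on the per-pair differences; returns (t, df, p_two_sided)."""
    aa, ba = _check_vector(a, "a"), _check_vector(b, "b")
    if len(aa) != len(ba):
        raise ParameterError("paired vectors must have equal length")
    n = len(aa)
    if n < 2:
        raise ParameterError("paired_t_test requires n >= 2")
    diff = aa - ba
    sd = diff.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero variance of paired differences")
    t_stat = float(diff.mean() / (sd / np.sqrt(n)))
    df = n - 1
    return t_stat, df, _t_pvalue(t_stat, df, "two_sided")


def correlation_matrix(
    variables: Dict[str, Sequence[float]],
    correction: str = "bonferroni",
    alpha: float = 0.05,
) -> AssociationReport:
    """All pairwise Pearson correlations with multiple-testing flags.

    Under ``correction="bonferroni"`` each two-sided p is compared with
    ``alpha / m`` where m is the number of variable pairs.
    """
    if correction not in ("none", "bonferroni"):
        raise ParameterError("correction must be 'none' or 'bonferroni'")
    names = list(variables)
    if len(names) < 2:
        raise ParameterError("correlation_matrix requires >= 2 variables")
    arrays = [_check_vector(variables[k], k) for k in names]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ParameterError("all variables must have equal length")
    m = len(names) * (len(names) - 1) // 2
    threshold = alpha / m if correction == "bonferroni" else alpha
    report = AssociationReport(alpha=alpha, correction=correction, n_tests=m)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            entry = pearson_test(
                arrays[i], arrays[j], direction="two_sided",
                x_name=names[i], y_name=names[j],
            )
            entry.bonferroni_significant = bool(entry.p < threshold)
            report.add(entry)
    return report


def mean_sd_correlation(means, sds, direction: str = "two_sided") -> AssocEntry:
    """Pearson correlation between per-category means and SDs.

    A strongly negative value is the signature of a performance ceiling:
    easy categories leave little room for their images to vary.
    """
    entry = pearson_test(means, sds, direction=direction,
                         x_name="category_mean", y_name="category_sd")
    return entry


def mean_vs_sd_correlation(scores: pd.DataFrame, direction: str = "two_sided") -> AssocEntry:
    """Ceiling check on a score table: correlate per-category mean and SD."""
    g = scores.groupby("category")["score"]
    if g.ngroups < 3:
        raise ParameterError("mean_vs_sd_correlation requires >= 3 categories")
    return mean_sd_correlation(g.mean().to_numpy(), g.std(ddof=1).to_numpy(),
                               direction=direction)


def align_scores(*tables: pd.DataFrame) -> pd.DataFrame:
    """Inner-join score tables on image_id, one column per score kind.

    Images missing from any table are dropped pairwise with a logged
    count. Returns a DataFrame indexed by image_id with a ``category``
    column and one column per score kind.
    """
    if not tables:
        raise ParameterError("align_scores requires at least one table")
    merged: Optional[pd.DataFrame] = None
    total = 0
    for tbl in tables:
        kind = tbl["score_kind"].iloc[0]
        part = tbl.set_index("image_id")[["category", "score"]].rename(
            columns={"score": kind}
        )
        total = max(total, len(part))
        if merged is None:
            merged = part
        else:
            merged = merged.join(part.drop(columns="category"), how="inner")
    dropped = total - len(merged)
    if dropped > 0:
        logger.info("align_scores: %d image(s) dropped (missing in some table)", dropped)
    return merged
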
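"""Tabular and image I/O: trial tables, score tables, feature matrices,
reports, and PNG images.

All tables are UTF-8 CSV with a header row, ``.`` decimal separator and
RFC-4180 quoting (pandas defaults). Loading validates the schema and the
paradigm's invariants and never silently drops rows; counts are logged.
Unknown extra columns are preserved on read but ignored by the analyses.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Optional, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .association import AssociationReport
from .consistency import SplitHalfResult
from .core import SCORE_COLUMNS, ParameterError, SchemaError, logger, validate_score_table
from .masks import RasterImage

__all__ = [
    "DatasetBundle",
    "read_trials",
    "write_trials",
    "read_scores",
    "write_scores",
    "read_features",
    "write_features",
    "write_report",
    "read_image",
    "write_image",
]

TRIAL_SCHEMAS: Dict[str, list] = {
    "study1": ["participant_id", "image_id", "category", "congruent", "responded", "correct"],
    "study2": ["participant_id", "image_id", "category", "rt", "outcome"],
    "study3": ["participant_id", "image_id", "category", "rating"],
}

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    True: True, False: False, 1: True, 0: False,
}

OUTCOMES = ("correct", "wrong_click", "timeout")


@dataclasses.dataclass
class DatasetBundle:
    """Optional trial tables, memorability scores and features of one dataset."""

    study1: Optional[pd.DataFrame] = None
    study2: Optional[pd.DataFrame] = None
    study3: Optional[pd.DataFrame] = None
    memorability: Optional[pd.DataFrame] = None
    features: Optional[pd.DataFrame] = None

    def validate(self) -> None:
        """Check image_id/category cross-references across present members."""
        ref: Optional[pd.Series] = None
        for name in ("study1", "study2", "study3", "memorability"):
            tbl = getattr(self, name)
            if tbl is None:
                continue
            cats = tbl.drop_duplicates("image_id").set_index("image_id")["category"]
            if ref is None:
                ref = cats
            else:
                common = ref.index.intersection(cats.index)
                if not (ref.loc[common] == cats.loc[common]).all():
                    raise SchemaError(
                        f"category labels in {name} conflict with other members"
                    )
                ref = pd.concat([ref, cats[~cats.index.isin(ref.index)]])
        if self.features is not None and ref is not None:
            common = ref.index.intersection(self.features.index)
            if not (self.features.loc[common, "category"] == ref.loc[common]).all():
                raise SchemaError("feature matrix categories conflict with trial tables")


def _coerce_bool(series: pd.Series, column: str) -> pd.Series:
    def conv(v):
        key = v.lower() if isinstance(v, str) else v
        if key not in _BOOL_MAP:
            raise SchemaError(f"column {column!r}: unrecognized boolean value {v!r}")
        return _BOOL_MAP[key]

    return series.map(conv)


def _validate_trials(df: pd.DataFrame, schema: str, rt_limit: float,
                     rating_bounds) -> pd.DataFrame:
    if schema == "study1":
        for col in ("congruent", "responded", "correct"):
            df[col] = _coerce_bool(df[col], col)
        bad = df.index[~df["responded"] & df["correct"]]
        if len(bad):
            raise SchemaError(
                f"study1 row {bad[0]}: responded=false with correct=true "
                "(a non-response is recorded as incorrect)"
            )
    elif schema == "study2":
        df["rt"] = pd.to_numeric(df["rt"], errors="coerce")
        if df["rt"].isna().any():
            row = int(df.index[df["rt"].isna()][0])
            raise SchemaError(f"study2 row {row}, column 'rt': not a number")
        unknown = df.index[~df["outcome"].isin(OUTCOMES)]
        if len(unknown):
            row = int(unknown[0])
            raise SchemaError(
                f"study2 row {row}, column 'outcome': unknown code "
                f"{df.loc[row, 'outcome']!r} (expected one of {OUTCOMES})"
            )
        out_of_range = df.index[(df["rt"] <= 0) | (df["rt"] > rt_limit + 1e-12)]
        if len(out_of_range):
            row = int(out_of_range[0])
            raise SchemaError(
                f"study2 row {row}, column 'rt': value {df.loc[row, 'rt']} "
                f"outside (0, {rt_limit}]"
            )
        timeouts = df["outcome"] == "timeout"
        bad = df.index[timeouts & (df["rt"] != rt_limit)]
        if len(bad):
            row = int(bad[0])
            raise SchemaError(
                f"study2 row {row}: timeout trial must have rt = rt_limit "
                f"({rt_limit}), got {df.loc[row, 'rt']}"
            )
    elif schema == "study3":
        df["rating"] = pd.to_numeric(df["rating"], errors="coerce")
        if df["rating"].isna().any():
            row = int(df.index[df["rating"].isna()][0])
            raise SchemaError(f"study3 row {row}, column 'rating': not a number")
        lo, hi = rating_bounds
        bad = df.index[(df["rating"] < lo) | (df["rating"] > hi)]
        if len(bad):
            row = int(bad[0])
            raise SchemaError(
                f"study3 row {row}, column 'rating': value "
                f"{df.loc[row, 'rating']} outside [{lo}, {hi}]"
            )
        df["rating"] = df["rating"].astype(int)
    return df


def read_trials(
    path: Union[str, Path],
    schema: str,
    column_map: Optional[Dict[str, str]] = None,
    rt_limit: float = 6.0,
    rating_bounds=(-3, 3),
) -> pd.DataFrame:
    """Read and validate a trial table.

    ``column_map`` maps file column names onto the canonical schema (for
    externally deposited files with different headers). Extra columns are
    preserved. Raises :class:`SchemaError` naming the offending row and
    column on any invariant violation.
    """
    if schema not in TRIAL_SCHEMAS:
        raise ParameterError(f"unknown schema {schema!r}")
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = set(TRIAL_SCHEMAS[schema]) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    df = _validate_trials(df, schema, rt_limit, rating_bounds)
    logger.info("read_trials: %d rows from %s (%s)", len(df), path, schema)
    return df


def write_trials(trials: pd.DataFrame, path: Union[str, Path], schema: str) -> None:
    """Write a trial table in the canonical column order (extras appended)."""
    if schema not in TRIAL_SCHEMAS:
        raise ParameterError(f"unknown schema {schema!r}")
    canonical = TRIAL_SCHEMAS[schema]
    missing = set(canonical) - set(trials.columns)
    if missing:
        raise SchemaError(f"trial table missing columns {sorted(missing)}")
    extras = [c for c in trials.columns if c not in canonical]
    trials.loc[:, canonical + extras].to_csv(path, index=False)
    logger.info("write_trials: %d rows to %s (%s)", len(trials), path, schema)


def read_scores(path: Union[str, Path], **kwargs) -> pd.DataFrame:
    """Read a score table CSV (header ``image_id,category,score_kind,score,n_responses``)."""
    df = pd.read_csv(path)
    df = validate_score_table(df, **kwargs)
    logger.info("read_scores: %d rows from %s", len(df), path)
    return df


def write_scores(scores: pd.DataFrame, path: Union[str, Path]) -> None:
    validate_score_table(scores).to_csv(path, index=False)
    logger.info("write_scores: %d rows to %s", len(scores), path)


def read_features(path: Union[str, Path]) -> pd.DataFrame:
    """Read a feature matrix CSV: ``image_id,category,f0..f{d-1}``."""
    df = pd.read_csv(path)
    if "image_id" not in df.columns or "category" not in df.columns:
        raise SchemaError(f"{path}: feature file needs image_id and category columns")
    df = df.set_index("image_id")
    fcols = [c for c in df.columns if c != "category"]
    vals = df[fcols].to_numpy()
    if not np.isfinite(vals.astype(float)).all():
        raise SchemaError(f"{path}: feature matrix has missing/non-finite entries")
    logger.info("read_features: %d rows x %d dims from %s", len(df), len(fcols), path)
    return df


def write_features(features: pd.DataFrame, path: Union[str, Path]) -> None:
    features.to_csv(path, index=True, index_label="image_id")
    logger.info("write_features: %d rows to %s", len(features), path)


def _report_payload(report) -> dict:
    if isinstance(report, AssociationReport):
        if not report.entries:
            raise ParameterError("refusing to write an empty association report")
        return {
            "kind": "association",
            "alpha": report.alpha,
            "correction": report.correction,
            "n_tests": report.n_tests,
            "entries": [dataclasses.asdict(e) for e in report.entries],
        }
    if isinstance(report, SplitHalfResult):
        if not report.mean_rho:
            raise ParameterError("refusing to write an empty split-half result")
        return {
            "kind": "split_half",
            "n_splits": report.n_splits,
            "seed": report.seed,
            "n_participants_half": list(report.n_participants_half),
            "categories": [
                {
                    "category": c,
                    "mean_rho": report.mean_rho[c],
                    "n_samples": int(len(report.rho_samples[c])),
                    "mean_n_images": report.n_images_used[c],
                }
                for c in sorted(report.mean_rho)
            ],
        }
    raise ParameterError(f"unsupported report type {type(report).__name__}")


def write_report(report, path: Union[str, Path], format: str = "json") -> None:
    """Write an association report or split-half result as JSON or CSV.

    JSON keeps full numeric precision; the CSV form has one row per test
    (association) or per category (split-half).
    """
    payload = _report_payload(report)
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(payload, indent=2, allow_nan=True))
    elif format == "csv":
        if payload["kind"] == "association":
            pd.DataFrame(payload["entries"]).to_csv(path, index=False)
        else:
            rows = pd.DataFrame(payload["categories"])
            rows["n_splits"] = payload["n_splits"]
            rows["seed"] = payload["seed"]
            rows.to_csv(path, index=False)
    else:
        raise ParameterError("format must be 'json' or 'csv'")
    logger.info("write_report: %s -> %s", payload["kind"], path)


def read_report(path: Union[str, Path]) -> dict:
    """Read back a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())


def write_image(image: RasterImage, path: Union[str, Path]) -> None:
    """Write a raster image as 8-bit PNG (value_range mapped to 0..255)."""
    lo, hi = image.value_range
    arr = np.clip((image.pixels - lo) / (hi - lo), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255).round().astype(np.uint8))


def read_image(path: Union[str, Path]) -> RasterImage:
    """Read a PNG as a RasterImage with value_range (0, 1)."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return RasterImage(pixels=arr.astype(float) / 255.0, value_range=(0.0, 1.0),
                       provenance=str(path))
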
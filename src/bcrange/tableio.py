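"""Feature-table I/O and the real-data preprocessing pipeline.

LC-MS feature tables arrive as delimited text with samples in rows or
columns and possibly missing intensities. The preprocessing chain mirrors
standard metabolomics practice: technical duplicates are averaged per
biological unit, features missing in at least 30% of samples are dropped,
and remaining missing cells are set to zero (absent peak). The chain order
is fixed — average → filter → impute — and is idempotent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import InputError
from .decomposition import FeatureTable
from .selection import SelectionResult

__all__ = [
    "RawFeatureTable",
    "read_feature_table",
    "average_duplicates",
    "missing_value_filter",
    "impute_zero",
    "preprocess",
    "write_selection",
    "read_selection",
]

logger = logging.getLogger("bcrange.tableio")

#: Tokens treated as missing values when reading (case-insensitive).
DEFAULT_NA_TOKENS = ("", "na", "nan")


@dataclass
class RawFeatureTable:
    """Pre-cleaning table: intensities may contain NaN missing markers."""

    intensities: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    labels: np.ndarray | None = None
    replicate_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise InputError("feature ids must be unique")
        n, p = self.intensities.shape
        if len(self.sample_ids) != n or len(self.feature_ids) != p:
            raise InputError("id lists must match matrix dimensions")
        if self.replicate_map is not None:
            missing = set(self.sample_ids) - set(self.replicate_map)
            if missing:
                raise InputError(
                    f"replicate_map does not cover samples: {sorted(missing)}"
                )


def read_feature_table(
    path,
    orientation: str = "samples_in_rows",
    label_col: str | None = None,
    sep: str | None = None,
    na_tokens: tuple[str, ...] = DEFAULT_NA_TOKENS,
) -> RawFeatureTable:
    """Read a delimited feature table, normalizing to samples-in-rows.

    The first column holds ids (sample ids, or feature ids when
    ``orientation="features_in_rows"``). ``label_col`` names the column (or
    row, for feature-oriented files) carrying the binary group label.
    """
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise InputError(f"unknown orientation {orientation!r}")
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    # pandas silently renames duplicate header columns, so check the raw
    # header up front (feature ids for samples-in-rows files).
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split(sep)[1:]
    if orientation == "samples_in_rows" and len(set(header)) != len(header):
        raise InputError("duplicate feature ids in input")
    variants = sorted(
        {v for tok in na_tokens for v in (tok, tok.lower(), tok.upper(),
                                          tok.capitalize())}
    )
    df = pd.read_csv(
        path,
        sep=sep,
        index_col=0,
        na_values=variants,
        keep_default_na=False,
        dtype=str,
    )
    if orientation == "features_in_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    labels = None
    if label_col is not None:
        if label_col not in df.columns:
            raise InputError(f"label column {label_col!r} not found")
        labels = pd.to_numeric(df[label_col]).to_numpy()
        df = df.drop(columns=[label_col])
    if df.columns.duplicated().any():
        raise InputError("duplicate feature ids in input")
    values = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    return RawFeatureTable(
        intensities=values,
        sample_ids=df.index.tolist(),
        feature_ids=df.columns.tolist(),
        labels=labels,
    )


def average_duplicates(table: RawFeatureTable) -> RawFeatureTable:
    """Average technical duplicates per biological unit, cell-wise.

    A cell missing in some replicates is the mean of the observed ones; a
    cell missing in all replicates stays missing. Labels must agree within
    a unit. Units keep first-appearance order.
    """
    if table.replicate_map is None:
        raise InputError("replicate_map required to average duplicates")
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(table.sample_ids):
        unit = table.replicate_map[sid]
        if unit not in groups:
            order.append(unit)
            groups[unit] = []
        groups[unit].append(i)
    averaged = np.empty((len(order), len(table.feature_ids)))
    labels = None if table.labels is None else np.empty(len(order))
    for u, unit in enumerate(order):
        rows = groups[unit]
        if not rows:
            raise InputError(f"unit {unit!r} has no samples")
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            # a cell missing in every replicate stays missing by design
            warnings.simplefilter("ignore", RuntimeWarning)
            averaged[u] = np.nanmean(table.intensities[rows], axis=0)
        if labels is not None:
            unit_labels = np.unique(table.labels[rows])
            if unit_labels.size != 1:
                raise InputError(f"unit {unit!r} has conflicting labels")
            labels[u] = unit_labels[0]
    logger.info("averaged %d samples into %d units", len(table.sample_ids), len(order))
    return RawFeatureTable(
        intensities=averaged,
        sample_ids=order,
        feature_ids=list(table.feature_ids),
        labels=labels,
        replicate_map={unit: unit for unit in order},
    )


def missing_value_filter(
    table: RawFeatureTable, max_missing_frac: float = 0.30
) -> RawFeatureTable:
    """Drop features whose missing fraction is >= ``max_missing_frac``.

    The boundary is inclusive: with 10 samples and a 0.30 cutoff, a feature
    missing in exactly 3 samples is excluded.
    """
    if not (0.0 <= max_missing_frac <= 1.0):
        raise InputError("max_missing_frac must lie in [0, 1]")
    frac = np.isnan(table.intensities).mean(axis=0)
    keep = frac < max_missing_frac
    logger.info(
        "missing-value filter: dropped %d of %d features",
        int((~keep).sum()), keep.size,
    )
    return RawFeatureTable(
        intensities=table.intensities[:, keep],
        sample_ids=list(table.sample_ids),
        feature_ids=[f for f, k in zip(table.feature_ids, keep) if k],
        labels=table.labels,
        replicate_map=table.replicate_map,
    )


def impute_zero(table: RawFeatureTable) -> FeatureTable:
    """Replace remaining missing cells by zero and finalize the table."""
    if table.labels is None:
        raise InputError("labels required to build a FeatureTable")
    if np.unique(table.labels).size != 2:
        raise InputError("labels must be binary (exactly two values)")
    X = np.where(np.isnan(table.intensities), 0.0, table.intensities)
    n_imputed = int(np.isnan(table.intensities).sum())
    logger.info("zero-imputed %d missing cells", n_imputed)
    return FeatureTable(
        X=X,
        sample_ids=list(table.sample_ids),
        feature_ids=list(table.feature_ids),
        labels=np.asarray(table.labels),
    )


def preprocess(
    table: RawFeatureTable, max_missing_frac: float = 0.30
) -> FeatureTable:
    """Full chain: average duplicates (if mapped) → filter → zero-impute."""
    if table.replicate_map is not None:
        table = average_duplicates(table)
    table = missing_value_filter(table, max_missing_frac)
    return impute_zero(table)


def write_selection(
    result: SelectionResult, path, feature_ids: list[str] | None = None
) -> None:
    """Write a selection result as TSV, one row per (feature, group) state.

    Columns: feature_id, group, angle_deg, magnitude, logistic_p, status.
    Status is ``selected``, ``filtered``, or ``wedge_only``; rows are
    ordered by feature index then group.
    """
    rows = []
    p = result.magnitudes.shape[0]
    ids = feature_ids or [f"x{j + 1}" for j in range(p)]
    for label, sel in result.per_group.items():
        pmap = dict(sel.filtered_out)
        for j in sorted(sel.wedge_members):
            if j in sel.selected:
                status = "selected"
            elif j in pmap:
                status = "filtered"
            else:
                status = "wedge_only"
            rows.append(
                {
                    "feature_id": ids[j],
                    "feature_index": j,
                    "group": label,
                    "angle_deg": np.degrees(result.angles[j]),
                    "magnitude": result.magnitudes[j],
                    "logistic_p": pmap.get(j, np.nan),
                    "status": status,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "feature_id", "feature_index", "group",
            "angle_deg", "magnitude", "logistic_p", "status",
        ],
    ).sort_values(["feature_index", "group"], kind="stable")
    df.to_csv(path, sep="\t", index=False)


def read_selection(path) -> pd.DataFrame:
    """Read back a selection TSV written by :func:`write_selection`."""
    return pd.read_csv(path, sep="\t")
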
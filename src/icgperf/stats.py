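"""Study-level summaries of perfusion metrics.

Fluorescence intensities and their ratios are right-skewed with variance
growing with the mean, so all summaries are computed on the natural-log
scale: per (group, ROI, timepoint) cell the mean of ln-values with its
t-distribution 95% confidence interval, plus the back-transformed geometric
mean.  Records with zero (flagged, no-signal) values cannot be
log-transformed; they are excluded from the cell with an explicit count
rather than offset by a pseudo-constant.

Mixed-model inference on the repeated-measures design is deliberately out
of scope: the module emits tidy long-format tables that any external
mixed-model tool can consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

#: Column order of the exported summary table.
SUMMARY_COLUMNS = [
    "variable", "group", "roi", "timepoint", "n", "n_excluded",
    "mean_ln", "ci_low_ln", "ci_high_ln", "mean_raw", "ci_undefined",
]

_CELL_KEYS = ["group", "roi", "timepoint"]


@dataclass(frozen=True)
class StudyRecord:
    """One (animal, group, ROI, timepoint) observation joining curve
    metrics, flow and scores.  ``None`` marks a quantity not measured at
    that timepoint (e.g. ratios at the baseline reference)."""

    animal_id: str
    group: str
    roi: str
    timepoint: str
    bsfi: float | None = None
    sfi: float | None = None
    bsfi_ratio: float | None = None
    sfi_ratio: float | None = None
    flow_mean: float | None = None
    macro_total: int | None = None
    chiu_grade: int | None = None


def ln_transform(values) -> np.ndarray:
    """Natural log of the positive entries of ``values``.

    Non-positive or non-finite entries (zero BSFI in fully occluded ROIs,
    flagged records) are dropped with a warning stating how many were
    excluded — never silently turned into NaN or -inf.
    """
    arr = np.asarray(values, dtype=float)
    keep = np.isfinite(arr) & (arr > 0)
    n_dropped = int(arr.size - keep.sum())
    if n_dropped:
        warnings.warn(
            f"ln_transform: excluded {n_dropped} non-positive or non-finite "
            f"value(s) of {arr.size}",
            stacklevel=2,
        )
    return np.log(arr[keep])


def _summarize_one(values: np.ndarray) -> dict:
    n = values.size
    mean = float(values.mean())
    if n == 1:
        return {
            "n": 1, "mean_ln": mean, "ci_low_ln": np.nan, "ci_high_ln": np.nan,
            "mean_raw": float(np.exp(mean)), "ci_undefined": True,
        }
    sd = float(values.std(ddof=1))
    half = float(sstats.t.ppf(0.975, n - 1)) * sd / np.sqrt(n)
    return {
        "n": n, "mean_ln": mean, "ci_low_ln": mean - half, "ci_high_ln": mean + half,
        "mean_raw": float(np.exp(mean)), "ci_undefined": False,
    }


def summarize_cells(records: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Per-cell ln-scale means with 95% t-confidence intervals.

    ``records`` is a long-format table with at least the columns ``group``,
    ``roi``, ``timepoint`` and ``variable``.  Each (group, roi, timepoint)
    cell is summarised over its positive values; cells whose records are
    all excluded are omitted with a warning.  Single-record cells report
    the mean with an undefined CI, flagged in ``ci_undefined``.
    """
    missing = [c for c in _CELL_KEYS + [variable] if c not in records.columns]
    if missing:
        raise ValueError(f"records table lacks column(s) {missing}")
    rows = []
    for keys, cell in records.groupby(_CELL_KEYS, sort=True, observed=True):
        raw = cell[variable].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ln_vals = ln_transform(raw)
        n_excluded = raw.size - ln_vals.size
        if ln_vals.size == 0:
            warnings.warn(
                f"summarize_cells: cell {keys} has no positive {variable!r} "
                "values; omitted",
                stacklevel=2,
            )
            continue
        row = dict(zip(_CELL_KEYS, keys))
        row["variable"] = variable
        row["n_excluded"] = int(n_excluded)
        row.update(_summarize_one(ln_vals))
        rows.append(row)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def export_results_table(summaries: pd.DataFrame, path: str | Path) -> Path:
    """Write a summary table as CSV with a deterministic column order.

    An empty input still produces a header-only file; a written table reads
    back equal to what was written.
    """
    path = Path(path)
    cols = [c for c in SUMMARY_COLUMNS if c in summaries.columns] + [
        c for c in summaries.columns if c not in SUMMARY_COLUMNS
    ]
    try:
        summaries.loc[:, cols].to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"failed to write results table to {path}: {exc}") from exc
    return path
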
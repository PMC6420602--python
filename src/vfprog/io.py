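"""In-memory containers for longitudinal visual-field series and CSV I/O.

The long-format series CSV has columns ``eye_id,time_years,location_id,
sensitivity_db`` (optionally ``eye`` with values OD/OS; OS fields are
mirrored to right-eye orientation at read time).  Labels live in a separate
CSV with columns ``eye_id,label`` where label is ``stable`` or
``progressing``; eyes absent from the labels file are ``unknown``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .grid import VFGrid, build_grid

logger = logging.getLogger(__name__)

LABELS = ("stable", "progressing", "unknown")
DB_MIN, DB_MAX = 0.0, 50.0

__all__ = [
    "VFTest",
    "VFSeries",
    "Cohort",
    "read_series_csv",
    "write_series_csv",
    "write_predictors_csv",
    "read_predictors_csv",
    "cohort_summary",
]


@dataclass(frozen=True)
class VFTest:
    """One visual-field examination: a time point and 52 dB sensitivities."""

    time_years: float
    sensitivity: np.ndarray

    def __post_init__(self):
        sens = np.asarray(self.sensitivity, dtype=float)
        object.__setattr__(self, "sensitivity", sens)
        if self.time_years < 0:
            raise ValueError(f"time_years must be non-negative, got {self.time_years}")
        if sens.ndim != 1:
            raise ValueError("sensitivity must be a 1-D vector")
        if not np.isfinite(sens).all():
            raise ValueError("sensitivity contains non-finite values")
        if ((sens < DB_MIN) | (sens > DB_MAX)).any():
            bad = sens[(sens < DB_MIN) | (sens > DB_MAX)]
            raise ValueError(f"sensitivity outside [{DB_MIN}, {DB_MAX}] dB: {bad[:5]}")


@dataclass
class VFSeries:
    """One eye's ordered sequence of VF tests plus an optional label."""

    eye_id: str
    tests: list[VFTest]
    label: str = "unknown"

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if len(self.tests) == 0:
            raise ValueError(f"eye {self.eye_id}: series has no tests")
        times = np.array([t.time_years for t in self.tests])
        if not (np.diff(times) > 0).all():
            raise ValueError(f"eye {self.eye_id}: test times must be strictly increasing")
        if times[0] != 0:
            raise ValueError(f"eye {self.eye_id}: first test time must be 0")
        lengths = {len(t.sensitivity) for t in self.tests}
        if len(lengths) != 1:
            raise ValueError(f"eye {self.eye_id}: tests have inconsistent location counts")

    @property
    def n_tests(self) -> int:
        return len(self.tests)

    @property
    def analyzable(self) -> bool:
        """At least two tests: the minimum any progression metric requires."""
        return self.n_tests >= 2

    @property
    def times(self) -> np.ndarray:
        return np.array([t.time_years for t in self.tests])

    @property
    def matrix(self) -> np.ndarray:
        """(n_tests, n_locations) sensitivity matrix."""
        return np.vstack([t.sensitivity for t in self.tests])

    @property
    def follow_up_years(self) -> float:
        return float(self.times[-1])


@dataclass
class Cohort:
    """A collection of eyes with unique ids."""

    series: list[VFSeries] = dc_field(default_factory=list)

    def __post_init__(self):
        ids = [s.eye_id for s in self.series]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate eye_ids in cohort: {dup}")

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    def __getitem__(self, eye_id: str) -> VFSeries:
        for s in self.series:
            if s.eye_id == eye_id:
                return s
        raise KeyError(eye_id)

    @property
    def eye_ids(self) -> list[str]:
        return [s.eye_id for s in self.series]

    @property
    def labels(self) -> pd.Series:
        return pd.Series(
            [s.label for s in self.series], index=self.eye_ids, name="label"
        )


def _mirror_left_eyes(df: pd.DataFrame, grid: VFGrid) -> pd.DataFrame:
    """Map OS (left eye) rows to right-eye orientation.

    A left-eye 24-2 chart is the mirror image of the right-eye chart
    (including the nasal extension and the blind spot), so ids read in the
    left-eye chart's own order map onto right-eye ids by reversing each row
    of the reading order.  This sends the OS blind spot onto the OD blind
    spot.
    """
    os_mask = df["eye"].astype(str).str.upper().eq("OS")
    if not os_mask.any():
        return df
    id_to_mirror: dict[int, int] = {}
    order = pd.DataFrame({"l": grid.location_id, "x": grid.x, "y": grid.y})
    for _, row_df in order.groupby("y"):
        ids = row_df.sort_values("x")["l"].to_numpy()
        for a, b in zip(ids, ids[::-1]):
            id_to_mirror[int(a)] = int(b)
    df = df.copy()
    df.loc[os_mask, "location_id"] = df.loc[os_mask, "location_id"].map(id_to_mirror)
    return df


def read_series_csv(
    path,
    labels_path=None,
    grid: VFGrid | None = None,
) -> Cohort:
    """Read a long-format VF series CSV (and optional labels CSV) into a Cohort.

    Blind-spot rows are dropped with a logged count.  Every (eye, visit) must
    supply all 52 retained locations; sensitivities must lie in [0, 50] dB.
    """
    grid = grid or build_grid()
    df = pd.read_csv(path)
    required = {"eye_id", "time_years", "location_id", "sensitivity_db"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"series CSV missing columns: {sorted(missing)}")
    df["eye_id"] = df["eye_id"].astype(str)

    if "eye" in df.columns:
        df = _mirror_left_eyes(df, grid)

    dup = df.duplicated(subset=["eye_id", "time_years", "location_id"], keep=False)
    if dup.any():
        first = df.index[dup][0]
        key = df.loc[first, ["eye_id", "time_years", "location_id"]].tolist()
        raise ValueError(
            f"duplicate (eye_id, time_years, location_id) rows, first at CSV row "
            f"{first + 2}: {key}"
        )

    out_of_range = (df["sensitivity_db"] < DB_MIN) | (df["sensitivity_db"] > DB_MAX)
    if out_of_range.any():
        first = df.index[out_of_range][0]
        raise ValueError(
            f"sensitivity_db outside [{DB_MIN}, {DB_MAX}] at CSV row {first + 2}: "
            f"{df.loc[first, 'sensitivity_db']}"
        )

    blind_ids = set(grid.location_id[grid.is_blind_spot].tolist())
    n_blind = int(df["location_id"].isin(blind_ids).sum())
    if n_blind:
        logger.info("dropped %d blind-spot rows", n_blind)
        df = df[~df["location_id"].isin(blind_ids)]

    retained = grid.retained_ids
    labels = {}
    if labels_path is not None:
        lab = pd.read_csv(labels_path)
        if not {"eye_id", "label"}.issubset(lab.columns):
            raise ValueError("labels CSV must have columns eye_id,label")
        bad = ~lab["label"].isin(["stable", "progressing"])
        if bad.any():
            raise ValueError(
                f"labels must be 'stable' or 'progressing', got {lab.loc[bad, 'label'].unique()}"
            )
        labels = dict(zip(lab["eye_id"].astype(str), lab["label"]))

    series = []
    for eye_id, g in df.groupby("eye_id", sort=True):
        tests = []
        for t, gt in sorted(g.groupby("time_years"), key=lambda kv: kv[0]):
            got = set(gt["location_id"].tolist())
            want = set(retained.tolist())
            if got != want:
                miss = sorted(want - got)
                extra = sorted(got - want)
                parts = []
                if miss:
                    parts.append(f"missing location ids {miss}")
                if extra:
                    parts.append(f"unknown location ids {extra}")
                raise ValueError(f"eye {eye_id}, time {t}: " + "; ".join(parts))
            gt = gt.set_index("location_id").loc[retained]
            tests.append(VFTest(float(t), gt["sensitivity_db"].to_numpy(float)))
        series.append(VFSeries(str(eye_id), tests, labels.get(str(eye_id), "unknown")))
    return Cohort(series)


def write_series_csv(cohort: Cohort, path, labels_path=None, grid: VFGrid | None = None):
    """Write a Cohort to the long-format series CSV (and optional labels CSV)."""
    grid = grid or build_grid()
    retained = grid.retained_ids
    rows = []
    for s in cohort:
        for t in s.tests:
            for l, v in zip(retained, t.sensitivity):
                rows.append((s.eye_id, t.time_years, int(l), v))
    df = pd.DataFrame(rows, columns=["eye_id", "time_years", "location_id", "sensitivity_db"])
    df.to_csv(path, index=False, float_format="%.17g")
    if labels_path is not None:
        lab = pd.DataFrame(
            [(s.eye_id, s.label) for s in cohort if s.label != "unknown"],
            columns=["eye_id", "label"],
        )
        lab.to_csv(labels_path, index=False)


def write_predictors_csv(table: pd.DataFrame, path):
    """Write a per-eye predictor table.

    ``eye_id`` first (taken from the index if absent as a column), remaining
    columns in their given order, floats at full precision, NaN as an empty
    field so metrics undefined for short series stay distinguishable.
    """
    df = table.copy()
    if "eye_id" not in df.columns:
        df = df.reset_index().rename(columns={df.index.name or "index": "eye_id"})
    non_numeric = [
        c for c in df.columns
        if c != "eye_id" and not pd.api.types.is_numeric_dtype(df[c])
    ]
    if non_numeric:
        raise ValueError(f"non-numeric predictor columns: {non_numeric}")
    cols = ["eye_id"] + [c for c in df.columns if c != "eye_id"]
    df[cols].to_csv(path, index=False, float_format="%.17g", na_rep="")


def read_predictors_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "eye_id" not in df.columns:
        raise ValueError("predictors CSV must have an eye_id column")
    return df.set_index(df["eye_id"].astype(str)).drop(columns="eye_id")


def cohort_summary(cohort: Cohort) -> dict:
    """Descriptive statistics echoed by ``vfprog validate``."""
    n_tests = np.array([s.n_tests for s in cohort])
    fu = np.array([s.follow_up_years for s in cohort])
    all_db = np.concatenate([s.matrix.ravel() for s in cohort])
    labels = pd.Series([s.label for s in cohort])
    return {
        "n_eyes": len(cohort),
        "n_tests_total": int(n_tests.sum()),
        "mean_tests_per_eye": float(n_tests.mean()),
        "tests_per_eye_range": (int(n_tests.min()), int(n_tests.max())),
        "mean_follow_up_years": float(fu.mean()),
        "follow_up_range_years": (float(fu.min()), float(fu.max())),
        "mean_db": float(all_db.mean()),
        "median_db": float(np.median(all_db)),
        "sd_db": float(all_db.std()),
        "n_stable": int((labels == "stable").sum()),
        "n_progressing": int((labels == "progressing").sum()),
        "n_unknown": int((labels == "unknown").sum()),
    }
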
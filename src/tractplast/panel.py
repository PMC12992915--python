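"""Tidy longitudinal store of along-tract metric profiles.

A :class:`TractProfilePanel` holds one value per
``(subject_id, session, tract, segment, metric)`` key in native metric
units, with an explicit session ordering (baseline first).  Statistical
analyses are restricted to the middle segments of each tract via
:meth:`TractProfilePanel.trim_and_filter`, excluding the anatomically
heterogeneous start and end regions.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, IntegrityError, SchemaError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "session", "tract", "segment", "metric", "value")
KEY_COLUMNS = REQUIRED_COLUMNS[:-1]
DEFAULT_SESSION_ORDER = ("MRI1", "MRI2", "MRI3")


class TractProfilePanel:
    """Validated tidy table of along-tract metric values.

    Parameters
    ----------
    data
        Long-format frame with columns ``subject_id, session, tract,
        segment, metric, value``.
    session_order
        Ordered session labels, baseline first.
    validate
        If True (default), check for duplicate keys and drop non-finite
        values with a logged count.
    """

    def __init__(self, data: pd.DataFrame,
                 session_order: Sequence[str] = DEFAULT_SESSION_ORDER,
                 validate: bool = True):
        missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        df = data.loc[:, list(REQUIRED_COLUMNS)].copy()
        df["segment"] = df["segment"].astype(int)
        df["value"] = pd.to_numeric(df["value"], errors="coerce")
        self.session_order = tuple(session_order)
        if validate:
            bad = ~np.isfinite(df["value"].to_numpy())
            if bad.any():
                logger.warning("dropping %d non-finite values", int(bad.sum()))
                df = df.loc[~bad]
            dup = df.duplicated(subset=list(KEY_COLUMNS))
            if dup.any():
                key = df.loc[dup, list(KEY_COLUMNS)].iloc[0].to_dict()
                raise IntegrityError(f"duplicate observation key: {key}")
            unknown = set(df["session"]) - set(self.session_order)
            if unknown:
                raise SchemaError(f"sessions outside session_order: {sorted(unknown)}")
        self.data = df.reset_index(drop=True)

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_file(cls, path: str | Path, delimiter: str = "\t",
                  session_order: Sequence[str] = DEFAULT_SESSION_ORDER,
                  column_map: dict[str, str] | None = None) -> "TractProfilePanel":
        """Read a panel from a delimited text file.

        ``column_map`` renames file columns to the required schema, e.g.
        ``{"sub": "subject_id"}``.
        """
        # round_trip parsing: the default fast parser can be 1 ulp off,
        # breaking exact write-then-read equality
        df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
        if column_map:
            df = df.rename(columns=column_map)
        return cls(df, session_order=session_order)

    def to_file(self, path: str | Path, delimiter: str = "\t") -> None:
        self.data.to_csv(path, sep=delimiter, index=False)

    # ------------------------------------------------------------ accessors
    @property
    def subjects(self) -> list[str]:
        return sorted(self.data["subject_id"].unique())

    @property
    def sessions(self) -> list[str]:
        present = set(self.data["session"])
        return [s for s in self.session_order if s in present]

    @property
    def tracts(self) -> list[str]:
        return sorted(self.data["tract"].unique())

    @property
    def metrics(self) -> list[str]:
        return sorted(self.data["metric"].unique())

    def segments(self, tract: str | None = None) -> list[int]:
        df = self.data if tract is None else self.data[self.data["tract"] == tract]
        return sorted(df["segment"].unique())

    def __len__(self) -> int:
        return len(self.data)

    def equals(self, other: "TractProfilePanel") -> bool:
        a = self.data.sort_values(list(KEY_COLUMNS)).reset_index(drop=True)
        b = other.data.sort_values(list(KEY_COLUMNS)).reset_index(drop=True)
        return a.equals(b)

    @property
    def n_segment_tests(self) -> int:
        """Number of (tract, segment) units entering segment-wise testing."""
        return int(self.data.groupby("tract")["segment"].nunique().sum())

    # ------------------------------------------------------------ filtering
    def trim_and_filter(self, n_keep: int = 80,
                        exclude_subjects: Iterable[str] = ()) -> "TractProfilePanel":
        """Retain the centered run of ``n_keep`` segments and drop subjects.

        For the default 98-segment profiles and ``n_keep=80`` this keeps
        segments 10-89 (1-based), dropping nine anatomically heterogeneous
        segments at each end.  The overhang must split evenly; an odd
        overhang raises rather than trimming asymmetrically.  Idempotent.
        """
        seg_max = self.data.groupby("tract")["segment"].max()
        seg_min = self.data.groupby("tract")["segment"].min()
        df = self.data
        excl = set(exclude_subjects)
        if excl:
            unknown = excl - set(self.subjects)
            if unknown:
                raise ConfigurationError(f"unknown subjects to exclude: {sorted(unknown)}")
            df = df[~df["subject_id"].isin(excl)]
        pieces = []
        for tract, sub in df.groupby("tract", sort=False):
            n_seg = int(seg_max[tract] - seg_min[tract] + 1)
            if n_keep > n_seg:
                raise ConfigurationError(
                    f"n_keep={n_keep} exceeds {n_seg} segments of tract {tract}")
            overhang = n_seg - n_keep
            if overhang % 2:
                raise ConfigurationError(
                    f"cannot center {n_keep} of {n_seg} segments of {tract}: "
                    "odd overhang")
            lo = int(seg_min[tract]) + overhang // 2
            hi = lo + n_keep - 1
            pieces.append(sub[(sub["segment"] >= lo) & (sub["segment"] <= hi)])
        out = pd.concat(pieces, ignore_index=True) if pieces else df.iloc[:0]
        return TractProfilePanel(out, session_order=self.session_order, validate=False)

    def select(self, tract: str, segment: int) -> pd.DataFrame:
        """Long-format observations of one (tract, segment)."""
        m = (self.data["tract"] == tract) & (self.data["segment"] == segment)
        return self.data.loc[m]

    # ------------------------------------------------------------- reshaping
    def segment_array(self, tract: str, segment: int,
                      metrics: Sequence[str] | None = None
                      ) -> tuple[np.ndarray, list[str], list[str], list[str]]:
        """Wide array (subjects x sessions x metrics) for one segment.

        Returns ``(values, subjects, sessions, metrics)``; missing cells are
        NaN.  The session axis follows ``session_order``.
        """
        df = self.select(tract, segment)
        if df.empty:
            raise KeyError(f"no observations for tract={tract!r} segment={segment}")
        metrics = list(metrics) if metrics is not None else sorted(df["metric"].unique())
        subjects = sorted(df["subject_id"].unique())
        sessions = [s for s in self.session_order if s in set(df["session"])]
        wide = df.pivot_table(index="subject_id", columns=["session", "metric"],
                              values="value", aggfunc="first")
        arr = np.full((len(subjects), len(sessions), len(metrics)), np.nan)
        for j, sess in enumerate(sessions):
            for k, met in enumerate(metrics):
                if (sess, met) in wide.columns:
                    arr[:, j, k] = wide[(sess, met)].reindex(subjects).to_numpy()
        return arr, subjects, sessions, metrics
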
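"""Long-format longitudinal data containers and CSV I/O.

A :class:`LongitudinalDataset` holds, for each of ``n`` subjects, an
observation-time vector ``t_i`` (length ``n_i``, subject-varying) and a
response vector ``y_i`` of the same length.  No balance is assumed: ``n_i``
may differ across subjects and may be smaller than the basis dimension used
for modelling.  Missingness is represented by absence of rows, never by
sentinel values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LongitudinalDataset", "read_long_csv", "write_long_csv"]


@dataclass
class LongitudinalDataset:
    """Unbalanced longitudinal data in subject-grouped form.

    Parameters
    ----------
    subject_ids : list
        One identifier per subject (any hashable, order preserved).
    times : list of ndarray
        Per-subject observation times ``t_i`` (finite reals, ties allowed).
    responses : list of ndarray
        Per-subject responses ``y_i``, aligned with ``times``.
    """

    subject_ids: list = field(default_factory=list)
    times: list = field(default_factory=list)
    responses: list = field(default_factory=list)

    def __post_init__(self):
        if not (len(self.subject_ids) == len(self.times) == len(self.responses)):
            raise ValueError("subject_ids, times and responses must have equal length")
        clean_t, clean_y = [], []
        for sid, t, y in zip(self.subject_ids, self.times, self.responses):
            t = np.asarray(t, dtype=float).ravel()
            y = np.asarray(y, dtype=float).ravel()
            if t.size != y.size:
                raise ValueError(f"subject {sid!r}: len(times) != len(responses)")
            if t.size < 1:
                raise ValueError(f"subject {sid!r}: needs at least one observation")
            if not np.all(np.isfinite(t)):
                raise ValueError(f"subject {sid!r}: non-finite time")
            if not np.all(np.isfinite(y)):
                raise ValueError(f"subject {sid!r}: non-finite response")
            clean_t.append(t)
            clean_y.append(y)
        self.times = clean_t
        self.responses = clean_y

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_obs(self) -> np.ndarray:
        """Vector of per-subject observation counts ``n_i``."""
        return np.array([t.size for t in self.times], dtype=int)

    @property
    def time_range(self) -> tuple[float, float]:
        lo = min(float(t.min()) for t in self.times)
        hi = max(float(t.max()) for t in self.times)
        return lo, hi

    def subset(self, indices) -> "LongitudinalDataset":
        indices = np.asarray(indices, dtype=int)
        return LongitudinalDataset(
            [self.subject_ids[i] for i in indices],
            [self.times[i] for i in indices],
            [self.responses[i] for i in indices],
        )

    def to_frame(self, id_col="subject", time_col="time", value_col="value") -> pd.DataFrame:
        rows = {
            id_col: np.repeat(self.subject_ids, self.n_obs),
            time_col: np.concatenate(self.times),
            value_col: np.concatenate(self.responses),
        }
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df, id_col="subject", time_col="time", value_col="value"):
        for col in (id_col, time_col, value_col):
            if col not in df.columns:
                raise KeyError(f"required column {col!r} not present")
        if len(df) == 0:
            raise ValueError("empty input: no observation rows")
        sids, times, responses = [], [], []
        # groupby(sort=False) keeps first-appearance order; within-subject
        # order is the row order of the frame.
        for sid, grp in df.groupby(id_col, sort=False):
            t = pd.to_numeric(grp[time_col], errors="raise").to_numpy(dtype=float)
            y = pd.to_numeric(grp[value_col], errors="raise").to_numpy(dtype=float)
            keep = ~np.isnan(y)
            if not keep.any():
                raise ValueError(f"subject {sid!r}: all responses missing")
            sids.append(sid)
            times.append(t[keep])
            responses.append(y[keep])
        return cls(sids, times, responses)


def read_long_csv(path, id_col="subject", time_col="time", value_col="value") -> LongitudinalDataset:
    """Read a long-format CSV (one row per observation) into a dataset.

    One dataset entry is created per distinct subject id, rows grouped by id
    in order of first appearance; within-subject row order is file order.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty input file: {path}") from exc
    try:
        return LongitudinalDataset.from_frame(df, id_col, time_col, value_col)
    except (ValueError, TypeError) as exc:
        # re-raise numeric-parse errors with the file named
        raise type(exc)(f"{path}: {exc}") from exc


def write_long_csv(dataset: LongitudinalDataset, path,
                   id_col="subject", time_col="time", value_col="value") -> None:
    dataset.to_frame(id_col, time_col, value_col).to_csv(path, index=False)
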
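"""Core data structures for spatial capture-recapture studies.

Provides trap arrays, occasion calendars, binary capture histories and the
discretized statespace of candidate activity-center pixels, together with
delimited-text readers/writers and temporal aggregation of capture
histories into coarser sampling intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrapArray",
    "OccasionCalendar",
    "CaptureHistory",
    "StateSpace",
    "read_traps",
    "write_traps",
    "read_captures",
    "write_captures",
    "aggregate_occasions",
    "build_statespace",
    "write_statespace",
]

SEX_LABELS = ("F", "M", "U")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass(frozen=True)
class TrapArray:
    """Planar trap (detector) locations with an optional operation mask.

    Parameters
    ----------
    trap_id : sequence of str
        Unique trap identifiers.
    coords : (J, 2) array
        Planar x/y coordinates in consistent distance units (e.g. km).
    operation : (J, K) array of {0, 1}, optional
        Per-occasion availability; ``None`` means always operating.
    """

    trap_id: tuple[str, ...]
    coords: np.ndarray
    operation: np.ndarray | None = None

    def __post_init__(self) -> None:
        ids = tuple(str(t) for t in self.trap_id)
        object.__setattr__(self, "trap_id", ids)
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValidationError("coords must be a (J, 2) array")
        if len(ids) != coords.shape[0]:
            raise ValidationError("trap_id and coords length mismatch")
        if len(set(ids)) != len(ids):
            dupes = sorted({t for t in ids if ids.count(t) > 1})
            raise ValidationError(f"duplicate trap id(s): {', '.join(dupes)}")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("trap coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        if self.operation is not None:
            op = np.asarray(self.operation)
            if not np.isin(op, (0, 1)).all():
                raise ValidationError("operation mask entries must be 0/1")
            if op.ndim != 2 or op.shape[0] != len(ids):
                raise ValidationError("operation mask must be (J, K)")
            object.__setattr__(self, "operation", op.astype(np.int8))

    @property
    def n_traps(self) -> int:
        return len(self.trap_id)

    def index_of(self, trap_id: str) -> int:
        try:
            return self.trap_id.index(str(trap_id))
        except ValueError:
            raise ValidationError(f"unknown trap id: {trap_id!r}") from None

    def effective_occasions(self, n_occasions: int) -> np.ndarray:
        """Number of operating occasions per trap, as a (J,) int array."""
        if self.operation is None:
            return np.full(self.n_traps, n_occasions, dtype=int)
        if self.operation.shape[1] != n_occasions:
            raise ValidationError(
                f"operation mask has {self.operation.shape[1]} occasions, "
                f"expected {n_occasions}"
            )
        return self.operation.sum(axis=1).astype(int)


@dataclass(frozen=True)
class OccasionCalendar:
    """Partition of the study duration into contiguous day blocks.

    ``bounds`` is an ordered tuple of ``(start_day, length_days)`` pairs
    (0-based start, length >= 1) that tile the study period without gaps.
    """

    bounds: tuple[tuple[int, int], ...]
    label: str = "custom"

    def __post_init__(self) -> None:
        bounds = tuple((int(s), int(n)) for s, n in self.bounds)
        if not bounds:
            raise ValidationError("calendar must contain at least one block")
        expected_start = 0
        for start, length in bounds:
            if length < 1:
                raise ValidationError("occasion block length must be >= 1 day")
            if start != expected_start:
                raise ValidationError("occasion blocks must be contiguous from day 0")
            expected_start = start + length
        object.__setattr__(self, "bounds", bounds)

    @property
    def n_occasions(self) -> int:
        return len(self.bounds)

    @property
    def n_days(self) -> int:
        start, length = self.bounds[-1]
        return start + length

    def occasion_of_day(self, day: int) -> int:
        """Map a 0-based day index to its occasion index."""
        if not 0 <= day < self.n_days:
            raise ValidationError(
                f"day {day + 1} outside study duration of {self.n_days} days"
            )
        for k, (start, length) in enumerate(self.bounds):
            if start <= day < start + length:
                return k
        raise AssertionError("unreachable: contiguous blocks cover all days")

    @classmethod
    def daily(cls, n_days: int) -> "OccasionCalendar":
        return cls(tuple((d, 1) for d in range(n_days)), label="daily")

    @classmethod
    def from_block_lengths(
        cls, lengths: Sequence[int], label: str = "custom"
    ) -> "OccasionCalendar":
        starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        return cls(tuple(zip(starts.tolist(), list(lengths))), label=label)

    @classmethod
    def weekly(cls, n_days: int) -> "OccasionCalendar":
        """7-day blocks; a short remainder block closes the study.

        91 days -> 13 x 7; 90 days -> 12 x 7 + 1 x 6 (13 occasions).
        """
        n_full, rem = divmod(n_days, 7)
        lengths = [7] * n_full + ([rem] if rem else [])
        return cls.from_block_lengths(lengths, label="weekly")

    @classmethod
    def monthly(cls, n_days: int) -> "OccasionCalendar":
        """~30-day blocks; 91 days -> 30/30/31, 90 days -> 30/30/30."""
        n_blocks = max(1, n_days // 30)
        base, rem = divmod(n_days, n_blocks)
        lengths = [base] * (n_blocks - rem) + [base + 1] * rem
        return cls.from_block_lengths(lengths, label="monthly")

    @classmethod
    def quarterly(cls, n_days: int) -> "OccasionCalendar":
        return cls(((0, n_days),), label="quarterly")

    @classmethod
    def by_label(cls, label: str, n_days: int) -> "OccasionCalendar":
        factories = {
            "daily": cls.daily,
            "weekly": cls.weekly,
            "monthly": cls.monthly,
            "quarterly": cls.quarterly,
        }
        if label not in factories:
            raise ValidationError(f"unknown calendar label: {label!r}")
        return factories[label](n_days)


@dataclass(frozen=True)
class CaptureHistory:
    """Binary individual x trap x occasion detection array.

    Multiple detections of an individual at one trap within a single
    occasion are recorded as a single 1.
    """

    y: np.ndarray
    individual_id: tuple[str, ...]
    sex: np.ndarray  # per-individual label in {"F", "M", "U"}
    calendar: OccasionCalendar
    traps: TrapArray

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        if y.ndim != 3:
            raise ValidationError("y must be individual x trap x occasion")
        if not np.isin(y, (0, 1)).all():
            raise ValidationError("capture history entries must be 0/1")
        y = y.astype(np.int8)
        n, J, K = y.shape
        ids = tuple(str(i) for i in self.individual_id)
        if len(ids) != n or len(set(ids)) != len(ids):
            raise ValidationError("individual ids must be unique and match y")
        sex = np.asarray(self.sex, dtype="U1")
        if sex.shape != (n,):
            raise ValidationError("sex labels must match individual count")
        if not np.isin(sex, SEX_LABELS).all():
            raise ValidationError(f"sex labels must be in {SEX_LABELS}")
        if J != self.traps.n_traps:
            raise ValidationError("trap dimension mismatch with TrapArray")
        if K != self.calendar.n_occasions:
            raise ValidationError("occasion dimension mismatch with calendar")
        if n and (y.sum(axis=(1, 2)) == 0).any():
            zero = [ids[i] for i in np.flatnonzero(y.sum(axis=(1, 2)) == 0)]
            raise ValidationError(
                f"individuals with no detections: {', '.join(zero)}"
            )
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "individual_id", ids)
        object.__setattr__(self, "sex", sex)

    @property
    def n_individuals(self) -> int:
        return self.y.shape[0]

    @property
    def n_detections(self) -> int:
        return int(self.y.sum())

    def counts_by_trap(self) -> np.ndarray:
        """Per-individual per-trap detection counts, shape (n, J)."""
        return self.y.sum(axis=2)


@dataclass(frozen=True)
class StateSpace:
    """Regular grid of candidate activity-center pixels."""

    pixel_centers: np.ndarray  # (P, 2)
    pixel_area: float
    extent: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax
    spacing: float

    def __post_init__(self) -> None:
        centers = np.asarray(self.pixel_centers, dtype=float)
        if centers.ndim != 2 or centers.shape[1] != 2:
            raise ValidationError("pixel_centers must be (P, 2)")
        if self.pixel_area <= 0:
            raise ValidationError("pixel_area must be positive")
        object.__setattr__(self, "pixel_centers", centers)

    @property
    def n_pixels(self) -> int:
        return self.pixel_centers.shape[0]

    @property
    def total_area(self) -> float:
        return self.n_pixels * self.pixel_area

    def contains(self, points: np.ndarray) -> np.ndarray:
        xmin, xmax, ymin, ymax = self.extent
        pts = np.atleast_2d(points)
        return (
            (pts[:, 0] >= xmin)
            & (pts[:, 0] <= xmax)
            & (pts[:, 1] >= ymin)
            & (pts[:, 1] <= ymax)
        )


# ---------------------------------------------------------------------------
# Readers / writers (CSV dialects documented in the package README)
# ---------------------------------------------------------------------------


def read_traps(path: str | Path) -> TrapArray:
    """Read a trap table: ``trap_id,x,y[,op_1..op_K]``."""
    df = pd.read_csv(path, dtype={"trap_id": str})
    if df.empty:
        raise ValidationError(f"no traps in {path}")
    required = {"trap_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValidationError(f"trap file must have columns {sorted(required)}")
    for col in ("x", "y"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ValidationError(f"non-numeric {col!r} coordinate at line {row}")
    op_cols = [c for c in df.columns if c.startswith("op_")]
    operation = None
    if op_cols:
        op_cols = sorted(op_cols, key=lambda c: int(c.split("_", 1)[1]))
        operation = df[op_cols].to_numpy()
    return TrapArray(
        trap_id=tuple(df["trap_id"]),
        coords=df[["x", "y"]].to_numpy(dtype=float),
        operation=operation,
    )


def write_traps(traps: TrapArray, path: str | Path) -> None:
    df = pd.DataFrame(
        {"trap_id": traps.trap_id,
         "x": traps.coords[:, 0],
         "y": traps.coords[:, 1]}
    )
    if traps.operation is not None:
        for k in range(traps.operation.shape[1]):
            df[f"op_{k + 1}"] = traps.operation[:, k]
    df.to_csv(path, index=False)


def read_captures(
    path: str | Path, traps: TrapArray, calendar: OccasionCalendar
) -> CaptureHistory:
    """Read a long-format capture table: ``individual,trap_id,day,sex``.

    ``day`` is a 1-based day index within the study period; ``sex`` is one
    of F/M/U. Repeated records of one individual at one trap within the
    same occasion collapse to a single detection.
    """
    df = pd.read_csv(path, dtype={"individual": str, "trap_id": str, "sex": str})
    required = {"individual", "trap_id", "day", "sex"}
    if not required.issubset(df.columns):
        raise ValidationError(f"capture file must have columns {sorted(required)}")
    ids: list[str] = []
    sex_of: dict[str, str] = {}
    for ind, sex in zip(df["individual"], df["sex"]):
        sex = str(sex).upper()
        if sex not in SEX_LABELS:
            raise ValidationError(f"invalid sex label {sex!r} for {ind!r}")
        if ind not in sex_of:
            ids.append(ind)
            sex_of[ind] = sex
        elif sex_of[ind] != sex:
            raise ValidationError(f"conflicting sex labels for individual {ind!r}")
    y = np.zeros((len(ids), traps.n_traps, calendar.n_occasions), dtype=np.int8)
    row_of = {ind: i for i, ind in enumerate(ids)}
    for ind, trap, day in zip(df["individual"], df["trap_id"], df["day"]):
        j = traps.index_of(trap)
        k = calendar.occasion_of_day(int(day) - 1)
        y[row_of[ind], j, k] = 1
    return CaptureHistory(
        y=y,
        individual_id=tuple(ids),
        sex=np.array([sex_of[i] for i in ids]),
        calendar=calendar,
        traps=traps,
    )


def write_captures(history: CaptureHistory, path: str | Path) -> None:
    """Write a capture history in the long format read by :func:`read_captures`.

    Each 1 in ``y`` becomes one row, dated at the first day of its occasion.
    """
    rows = []
    for i, j, k in zip(*np.nonzero(history.y)):
        start, _ = history.calendar.bounds[k]
        rows.append(
            (history.individual_id[i], history.traps.trap_id[j],
             start + 1, history.sex[i])
        )
    pd.DataFrame(rows, columns=["individual", "trap_id", "day", "sex"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Temporal aggregation
# ---------------------------------------------------------------------------


def aggregate_occasions(
    history: CaptureHistory, scheme: OccasionCalendar
) -> CaptureHistory:
    """Collapse a capture history onto a coarser occasion calendar.

    Each collapsed entry is the logical OR of the source entries whose day
    blocks fall inside the scheme block; the scheme must partition the
    source calendar's days along existing block boundaries.
    """
    src = history.calendar
    if scheme.n_days != src.n_days:
        raise ValidationError(
            f"scheme covers {scheme.n_days} days, history covers {src.n_days}"
        )
    # map each source occasion to the scheme block containing it
    mapping = np.empty(src.n_occasions, dtype=int)
    for k, (start, length) in enumerate(src.bounds):
        b = scheme.occasion_of_day(start)
        b_start, b_len = scheme.bounds[b]
        if not (b_start <= start and start + length <= b_start + b_len):
            raise ValidationError(
                "scheme blocks do not align with source occasion boundaries"
            )
        mapping[k] = b
    n, J, _ = history.y.shape
    y_new = np.zeros((n, J, scheme.n_occasions), dtype=np.int8)
    for b in range(scheme.n_occasions):
        cols = mapping == b
        y_new[:, :, b] = history.y[:, :, cols].max(axis=2)
    traps = history.traps
    if traps.operation is not None:
        op_new = np.zeros((traps.n_traps, scheme.n_occasions), dtype=np.int8)
        for b in range(scheme.n_occasions):
            op_new[:, b] = traps.operation[:, mapping == b].max(axis=1)
        traps = TrapArray(traps.trap_id, traps.coords, op_new)
    return CaptureHistory(
        y=y_new,
        individual_id=history.individual_id,
        sex=history.sex,
        calendar=scheme,
        traps=traps,
    )


# ---------------------------------------------------------------------------
# Statespace construction
# ---------------------------------------------------------------------------


def build_statespace(
    traps: TrapArray,
    buffer: float,
    spacing: float,
    geometry: str = "rectangle",
) -> StateSpace:
    """Discretize a buffered region around the trap array into pixels.

    ``geometry='rectangle'`` expands the trap bounding box by ``buffer`` on
    every side; ``geometry='discs'`` additionally drops pixels farther than
    ``buffer`` from every trap (union-of-discs mask).
    """
    if buffer < 0:
        raise ValidationError("buffer must be >= 0")
    if spacing <= 0:
        raise ValidationError("spacing must be > 0")
    xmin, ymin = traps.coords.min(axis=0) - buffer
    xmax, ymax = traps.coords.max(axis=0) + buffer
    xs = np.arange(xmin + spacing / 2, xmax, spacing)
    ys = np.arange(ymin + spacing / 2, ymax, spacing)
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    if geometry == "discs":
        d2 = (
            (centers[:, None, :] - traps.coords[None, :, :]) ** 2
        ).sum(axis=2)
        centers = centers[(d2 <= buffer**2).any(axis=1)]
    elif geometry != "rectangle":
        raise ValidationError(f"unknown statespace geometry: {geometry!r}")
    if centers.shape[0] < 4:
        raise ValidationError(
            "degenerate statespace: fewer than 4 pixels; reduce spacing"
        )
    return StateSpace(
        pixel_centers=centers,
        pixel_area=spacing**2,
        extent=(float(xmin), float(xmax), float(ymin), float(ymax)),
        spacing=float(spacing),
    )


def write_statespace(space: StateSpace, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "pixel_id": np.arange(space.n_pixels),
            "x": space.pixel_centers[:, 0],
            "y": space.pixel_centers[:, 1],
            "area": space.pixel_area,
        }
    )
    df.to_csv(path, index=False)
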
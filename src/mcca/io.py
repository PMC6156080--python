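"""Reading and writing of every on-disk artifact the pipeline touches.

Delimited tables are comma-separated UTF-8 with one header row; image
stacks are plain multi-frame TIFF; ROI masks travel as a labelled 16-bit
TIFF (label k = ROI k+1, background 0).  Frame ``i`` occurs at
``i / sampling_rate_hz`` seconds (frame-start convention, 0-based).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .detection import CellActivity, TransientEvent

log = logging.getLogger("mcca.io")

DEFAULT_FIELD_UM = 440.0
DEFAULT_GRID_PX = 512
DEFAULT_PIXEL_SIZE_UM = DEFAULT_FIELD_UM / DEFAULT_GRID_PX  # ~0.859 um/px

EVENT_COLUMNS = [
    "cell_id",
    "peak_time_s",
    "foot_time_s",
    "tail_time_s",
    "amplitude_dff_pct",
    "auc_dff_s",
]

CELL_COLUMNS = [
    "cell_id",
    "kind",
    "frequency_trans_per_min",
    "activity_class",
    "n_events",
    "mean_auc",
]


class InputError(ValueError):
    """Raised for malformed or inconsistent on-disk inputs."""


@dataclass
class Recording:
    """ROI-averaged fluorescence time series with spatial calibration.

    traces
        raw fluorescence, shape (n_frames, n_cells), arbitrary units.
    sampling_rate_hz
        frames per second; resonant-scanning rigs deliver 15.2-30.4 Hz.
    roi_xy_um
        per-cell centroid coordinates in micrometres (optional).
    field_um
        edge length of the square field of view, default 440 um.
    """

    traces: np.ndarray
    sampling_rate_hz: float
    cell_ids: list[str] = field(default_factory=list)
    roi_xy_um: np.ndarray | None = None
    field_um: float = DEFAULT_FIELD_UM

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise InputError("traces must be a (n_frames, n_cells) matrix")
        if not (0 < self.sampling_rate_hz <= 100):
            raise InputError(
                f"sampling_rate_hz must lie in (0, 100], got {self.sampling_rate_hz}"
            )
        if not np.all(np.isfinite(self.traces)):
            raise InputError("traces must be finite")
        if np.any(self.traces < 0):
            raise InputError("raw fluorescence must be non-negative")
        if not self.cell_ids:
            self.cell_ids = [f"cell{i:04d}" for i in range(self.n_cells)]
        if len(self.cell_ids) != self.n_cells:
            raise InputError("cell_ids length must match the number of trace columns")
        if self.roi_xy_um is not None:
            self.roi_xy_um = np.asarray(self.roi_xy_um, dtype=float)
            if self.roi_xy_um.shape != (self.n_cells, 2):
                raise InputError(
                    f"expected {self.n_cells} coordinate rows, "
                    f"got shape {self.roi_xy_um.shape}"
                )
            if not np.all(np.isfinite(self.roi_xy_um)):
                raise InputError("ROI coordinates must be finite")
            if np.any(self.roi_xy_um < 0) or np.any(self.roi_xy_um > self.field_um):
                raise InputError("ROI coordinates must lie within [0, field_um]")

    @property
    def n_frames(self) -> int:
        return self.traces.shape[0]

    @property
    def n_cells(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sampling_rate_hz

    def with_coordinates(self, roi_xy_um: np.ndarray) -> "Recording":
        """Return a copy with ROI centroids attached (consistency-checked)."""
        xy = np.asarray(roi_xy_um, dtype=float)
        if xy.shape[0] != self.n_cells:
            raise InputError(
                f"coordinate row count {xy.shape[0]} does not match "
                f"{self.n_cells} cells"
            )
        return Recording(
            traces=self.traces,
            sampling_rate_hz=self.sampling_rate_hz,
            cell_ids=list(self.cell_ids),
            roi_xy_um=xy,
            field_um=self.field_um,
        )


@dataclass
class RoiMaskSet:
    """Per-cell boolean pixel masks over a common frame grid."""

    masks: np.ndarray  # (n_cells, height, width) boolean
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise InputError("masks must have shape (n_cells, height, width)")
        empties = np.flatnonzero(~self.masks.any(axis=(1, 2)))
        if empties.size:
            raise InputError(f"empty ROI mask(s): {empties.tolist()}")

    @property
    def n_cells(self) -> int:
        return self.masks.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.masks.shape[1], self.masks.shape[2]

    def centroids_um(self) -> np.ndarray:
        """(x, y) centroids in micrometres (x = column, y = row)."""
        out = np.empty((self.n_cells, 2))
        for i, m in enumerate(self.masks):
            rr, cc = np.nonzero(m)
            out[i] = (cc.mean() * self.pixel_size_um, rr.mean() * self.pixel_size_um)
        return out

    def to_label_image(self) -> np.ndarray:
        """16-bit label image, label k = ROI k+1, 0 = background."""
        label = np.zeros(self.grid_shape, dtype=np.uint16)
        for i, m in enumerate(self.masks):
            if np.any(label[m]):
                raise InputError(f"ROI {i} overlaps another mask")
            label[m] = i + 1
        return label

    @classmethod
    def from_label_image(cls, label: np.ndarray, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM):
        label = np.asarray(label)
        n = int(label.max())
        masks = np.stack([label == k + 1 for k in range(n)])
        return cls(masks=masks, pixel_size_um=pixel_size_um)


# ---------------------------------------------------------------------------
# delimited tables
# ---------------------------------------------------------------------------

def _read_numeric_table(path, min_rows: int = 1) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"{path}: empty file") from exc
    if df.shape[0] < min_rows or df.shape[1] < 1:
        raise InputError(f"{path}: expected at least {min_rows} data rows and 1 column")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise InputError(
                f"{path}: non-numeric or missing value at row {int(bad[0])}, "
                f"column '{col}'"
            )
        df[col] = vals
    return df


def read_traces(path, sampling_rate_hz: float) -> Recording:
    """Load a frames-by-cells fluorescence table into a Recording.

    Column order is preserved as the cell index; header names become cell
    IDs.  The table must be fully numeric with at least two rows.
    """
    df = _read_numeric_table(path, min_rows=2)
    return Recording(
        traces=df.to_numpy(dtype=float),
        sampling_rate_hz=sampling_rate_hz,
        cell_ids=[str(c) for c in df.columns],
    )


def write_traces(recording: Recording, path) -> Path:
    path = Path(path)
    pd.DataFrame(recording.traces, columns=recording.cell_ids).to_csv(path, index=False)
    return path


def read_roi_coordinates(
    path, units: str = "px", pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
) -> np.ndarray:
    """Load ROI centroids; pixel inputs are converted to micrometres."""
    if units not in ("px", "um"):
        raise InputError(f"units must be 'px' or 'um', got {units!r}")
    df = _read_numeric_table(path, min_rows=1)
    if df.shape[1] < 2:
        raise InputError(f"{path}: expected two coordinate columns")
    xy = df.iloc[:, :2].to_numpy(dtype=float)
    if units == "px":
        xy = xy * pixel_size_um
    return xy


def write_roi_coordinates(xy_um: np.ndarray, path) -> Path:
    path = Path(path)
    pd.DataFrame(np.asarray(xy_um, dtype=float), columns=["x_um", "y_um"]).to_csv(
        path, index=False
    )
    return path


# ---------------------------------------------------------------------------
# events and per-cell tables
# ---------------------------------------------------------------------------

def events_to_frame(events: Mapping[str, Sequence[TransientEvent]]) -> pd.DataFrame:
    """Long-format event table: one row per transient."""
    rows = []
    for cell_id, evs in events.items():
        for e in evs:
            rows.append(
                (
                    str(cell_id),
                    e.peak_time_s,
                    e.foot_time_s,
                    e.tail_time_s,
                    e.amplitude_dff_pct,
                    e.auc_dff_s,
                )
            )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events(events, path) -> Path:
    """Write detected transients as a long-format CSV.

    ``events`` may be a mapping cell_id -> list of TransientEvent, or a
    DataFrame already in the event schema.  Values are written at full
    precision so that ``read_events(write_events(x))`` reproduces ``x``.
    """
    path = Path(path)
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    if list(df.columns) != EVENT_COLUMNS:
        raise InputError(f"event table must have columns {EVENT_COLUMNS}")
    df.to_csv(path, index=False)
    return path


def read_events(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"cell_id": str})
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"{path}: empty file") from exc
    if list(df.columns) != EVENT_COLUMNS:
        raise InputError(f"{path}: expected columns {EVENT_COLUMNS}")
    return df


def cells_to_frame(cells: Iterable[CellActivity]) -> pd.DataFrame:
    rows = [
        (c.cell_id, c.kind, c.frequency_trans_per_min, c.activity_class, c.n_events, c.mean_auc)
        for c in cells
    ]
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


def write_cells(cells, path) -> Path:
    path = Path(path)
    df = cells if isinstance(cells, pd.DataFrame) else cells_to_frame(cells)
    df.to_csv(path, index=False)
    return path


def read_cells(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str})
    if list(df.columns) != CELL_COLUMNS:
        raise InputError(f"{path}: expected columns {CELL_COLUMNS}")
    return df


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def extract_roi_traces(stack: np.ndarray, masks: RoiMaskSet) -> np.ndarray:
    """Average pixels inside each ROI for every frame of an image stack.

    Returns a (n_frames, n_cells) matrix; linear in the stack by
    construction.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise InputError("stack must have shape (n_frames, height, width)")
    if stack.shape[1:] != masks.grid_shape:
        raise InputError(
            f"frame shape {stack.shape[1:]} does not match mask grid {masks.grid_shape}"
        )
    n_frames = stack.shape[0]
    flat = stack.reshape(n_frames, -1)
    out = np.empty((n_frames, masks.n_cells))
    for i, m in enumerate(masks.masks):
        idx = np.flatnonzero(m.ravel())
        if idx.size == 0:
            raise InputError(f"ROI {i} has an empty mask")
        out[:, i] = flat[:, idx].mean(axis=1)
    return out


def read_stack(path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_stack(stack: np.ndarray, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack))
    return path


def read_masks(path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> RoiMaskSet:
    return RoiMaskSet.from_label_image(tifffile.imread(Path(path)), pixel_size_um)


def write_masks(masks: RoiMaskSet, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, masks.to_label_image())
    return path
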
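"""Session containers and file I/O.

A :class:`SessionData` holds one head-fixed VR imaging session: raw
fluorescence (cells × frames, 30 Hz) frame-aligned with track position,
running velocity and a familiar/novel context label on a 3 m virtual
linear track.  Laps are delimited by teleports — a frame-to-frame
position drop larger than half the track — after which the animal is
returned to the track start.

Supported on-disk layouts:

* HDF5 — one group per session with datasets named after the
  ``SessionData`` fields;
* delimited — a directory with ``fluor.csv`` (frames × cells, header =
  cell ids) and ``behavior.csv`` (``position,velocity,context``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import AnalysisConfig

__all__ = [
    "SessionData", "ResultsBundle", "AlignmentError", "ValidationError",
    "compute_lap_index", "lap_context_labels",
    "load_session", "save_session", "load_results", "save_results",
]

CONTEXTS = ("familiar", "novel", "none")


class AlignmentError(ValueError):
    """Fluorescence and behavior streams disagree in frame count."""


class ValidationError(ValueError):
    """A container field violates its invariants."""


def compute_lap_index(position: np.ndarray, track_length: float) -> np.ndarray:
    """Per-frame lap number from teleport detection.

    A lap boundary is any frame where position drops by more than
    ``track_length / 2`` relative to the previous frame (the VR teleport
    back to the track start).
    """
    position = np.asarray(position, dtype=float)
    teleport = np.diff(position) < -track_length / 2.0
    laps = np.concatenate([[0], np.cumsum(teleport)])
    return laps.astype(np.int64)


@dataclass
class SessionData:
    """Frame-aligned fluorescence and behavior for one imaging session."""

    fluor: np.ndarray                  # (cells, frames), arbitrary units
    position: np.ndarray               # cm, in [0, track_length)
    velocity: np.ndarray               # cm/s
    context: np.ndarray                # per-frame label in CONTEXTS
    frame_rate: float = 30.0           # Hz
    track_length: float = 300.0        # cm
    cell_ids: list = field(default_factory=list)
    lap_index: np.ndarray | None = None

    def __post_init__(self):
        self.fluor = np.atleast_2d(np.asarray(self.fluor, dtype=float))
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.context = np.asarray(self.context, dtype="U8")
        if not self.cell_ids:
            self.cell_ids = [f"cell{i:04d}" for i in range(self.fluor.shape[0])]
        if self.lap_index is None:
            self.lap_index = compute_lap_index(self.position, self.track_length)
        else:
            self.lap_index = np.asarray(self.lap_index, dtype=np.int64)
        self.validate()

    @property
    def n_cells(self) -> int:
        return self.fluor.shape[0]

    @property
    def n_frames(self) -> int:
        return self.fluor.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def validate(self) -> None:
        n = self.fluor.shape[1]
        for name in ("position", "velocity", "context", "lap_index"):
            m = len(getattr(self, name))
            if m != n:
                raise AlignmentError(
                    f"{name} has {m} frames but fluorescence has {n}")
        if len(self.cell_ids) != self.fluor.shape[0]:
            raise ValidationError("cell_ids length does not match fluor rows")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")
        for name in ("fluor", "position", "velocity"):
            arr = getattr(self, name)
            bad = ~np.isfinite(arr)
            if bad.any():
                frames = np.unique(np.nonzero(bad)[-1])[:10]
                raise ValidationError(
                    f"non-finite values in {name} at frames {frames.tolist()}")
        if (self.position < 0).any() or (self.position >= self.track_length).any():
            bad = np.nonzero((self.position < 0)
                             | (self.position >= self.track_length))[0][:10]
            raise ValidationError(
                f"position outside [0, {self.track_length}) at frames "
                f"{bad.tolist()}")
        unknown = set(np.unique(self.context)) - set(CONTEXTS)
        if unknown:
            raise ValidationError(f"unknown context labels: {sorted(unknown)}")
        if (np.diff(self.lap_index) < 0).any():
            raise ValidationError("lap_index must be non-decreasing")

    @property
    def n_laps(self) -> int:
        return int(self.lap_index[-1]) + 1 if self.n_frames else 0


def lap_context_labels(session: SessionData) -> np.ndarray:
    """Per-lap context by majority frame label; ties go to the label that
    appears earlier within the lap (switching happens at teleports)."""
    labels = []
    for lap in range(session.n_laps):
        mask = session.lap_index == lap
        ctx = session.context[mask]
        vals, counts = np.unique(ctx, return_counts=True)
        best = counts == counts.max()
        cands = vals[best]
        if len(cands) == 1:
            labels.append(cands[0])
        else:
            first = {c: np.argmax(ctx == c) for c in cands}
            labels.append(min(cands, key=lambda c: first[c]))
    return np.asarray(labels, dtype="U8")


# ---------------------------------------------------------------------------
# session I/O

def save_session(session: SessionData, path: str | Path,
                 format: str = "hdf5", group: str = "session") -> None:
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            g = f.create_group(group)
            g.create_dataset("fluor", data=session.fluor)
            g.create_dataset("position", data=session.position)
            g.create_dataset("velocity", data=session.velocity)
            g.create_dataset("context",
                             data=np.char.encode(session.context, "ascii"))
            g.create_dataset("lap_index", data=session.lap_index)
            g.create_dataset("cell_ids", data=np.array(
                [c.encode("ascii") for c in session.cell_ids]))
            g.attrs["frame_rate"] = session.frame_rate
            g.attrs["track_length"] = session.track_length
    elif format == "delimited":
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(session.fluor.T, columns=session.cell_ids).to_csv(
            path / "fluor.csv", index=False)
        pd.DataFrame({
            "position": session.position,
            "velocity": session.velocity,
            "context": session.context,
        }).to_csv(path / "behavior.csv", index=False)
        (path / "meta.json").write_text(json.dumps({
            "frame_rate": session.frame_rate,
            "track_length": session.track_length,
        }))
    else:
        raise ValueError(f"unknown format {format!r}")


def load_session(path: str | Path, format: str = "hdf5",
                 group: str = "session") -> SessionData:
    """Read and validate a session; laps are recomputed from teleports."""
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            g = f[group]
            return SessionData(
                fluor=g["fluor"][()],
                position=g["position"][()],
                velocity=g["velocity"][()],
                context=np.char.decode(g["context"][()], "ascii"),
                cell_ids=[c.decode("ascii") for c in g["cell_ids"][()]],
                frame_rate=float(g.attrs["frame_rate"]),
                track_length=float(g.attrs["track_length"]),
            )
    elif format == "delimited":
        fluor = pd.read_csv(path / "fluor.csv")
        beh = pd.read_csv(path / "behavior.csv")
        if len(beh) != len(fluor):
            raise AlignmentError(
                f"behavior has {len(beh)} frames but fluorescence has "
                f"{len(fluor)}")
        meta = {}
        meta_path = path / "meta.json"
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
        return SessionData(
            fluor=fluor.to_numpy().T,
            position=beh["position"].to_numpy(),
            velocity=beh["velocity"].to_numpy(),
            context=beh["context"].to_numpy(dtype="U8"),
            cell_ids=list(fluor.columns),
            frame_rate=float(meta.get("frame_rate", 30.0)),
            track_length=float(meta.get("track_length", 300.0)),
        )
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# results bundle

@dataclass
class ResultsBundle:
    """Per-cell analysis records plus run metadata.

    ``records`` is a DataFrame with one row per cell (columns are
    whatever stages ran: transient frequency, tuned flag, field bins,
    width, r/lag, r_ff/r_fn/Δ stability, class …) and must carry a
    ``cell_id`` column.  ``meta`` snapshots the config and seed so a run
    is reproducible from its outputs.
    """

    records: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.records) and "cell_id" not in self.records.columns:
            raise ValidationError("records must carry a cell_id column")

    @classmethod
    def new(cls, records: pd.DataFrame, config: AnalysisConfig,
            seed: int | None = None) -> "ResultsBundle":
        from . import __version__
        return cls(records=records, meta={
            "config": config.to_dict(),
            "seed": seed,
            "software_version": __version__,
        })


def save_results(bundle: ResultsBundle, path: str | Path) -> None:
    """Write a delimited table plus a JSON metadata sidecar.

    ``path`` is the table path; the sidecar lands at ``path`` with a
    ``.json`` suffix appended.
    """
    path = Path(path)
    cols = list(bundle.records.columns) if len(bundle.records.columns) else ["cell_id"]
    df = bundle.records if len(bundle.records.columns) else pd.DataFrame(columns=cols)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(bundle.meta, indent=2, sort_keys=True))


def load_results(path: str | Path) -> ResultsBundle:
    path = Path(path)
    records = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return ResultsBundle(records=records, meta=meta)
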
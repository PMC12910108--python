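"""Per-molecule three-channel ALEX trajectories and ground-truth records.

The three channels follow the standard alternating-laser naming:

``F_DD``
    donor excitation, donor emission (DNA dye).
``F_DA``
    donor excitation, acceptor emission (FRET channel, plus leakage and
    direct excitation).
``F_AA``
    acceptor excitation, acceptor emission (polymerase dye).

A :class:`TrajectorySet` wraps one tidy :class:`pandas.DataFrame` with columns
``molecule_id, frame, time_s, F_DD, F_DA, F_AA`` and the frame interval, and is
the unit of exchange between the simulator, the imaging extraction, and the
correction/event-calling stages. TSV round-tripping uses the same schema.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "TrajectorySet", "GroundTruthEvent",
           "truth_to_tsv", "truth_from_tsv"]

_COLUMNS = ["molecule_id", "frame", "time_s", "F_DD", "F_DA", "F_AA"]


@dataclasses.dataclass(frozen=True)
class Trajectory:
    """One molecule's per-frame photon counts in the three ALEX channels."""

    molecule_id: int
    time_s: np.ndarray
    f_dd: np.ndarray
    f_da: np.ndarray
    f_aa: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        n = len(self.time_s)
        if not (len(self.f_dd) == len(self.f_da) == len(self.f_aa) == n):
            raise ValueError("channel arrays must share one length")
        if n > 1:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0) or not np.allclose(dt, self.frame_interval,
                                                  rtol=1e-6, atol=1e-9):
                raise ValueError("time must increase with constant frame_interval")
        for ch in (self.f_dd, self.f_da, self.f_aa):
            if np.any(np.asarray(ch) < 0):
                raise ValueError("photon counts must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.time_s)


class TrajectorySet:
    """A collection of trajectories sharing one time base."""

    def __init__(self, frames: pd.DataFrame, frame_interval: float):
        missing = [c for c in _COLUMNS if c not in frames.columns]
        if missing:
            raise ValueError(f"missing trajectory columns: {missing}")
        if frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        self.frames = frames.loc[:, _COLUMNS].reset_index(drop=True)
        self.frame_interval = float(frame_interval)

    @classmethod
    def from_molecule_arrays(
        cls,
        molecule_ids: Sequence[int],
        time_s: np.ndarray,
        f_dd: Sequence[np.ndarray],
        f_da: Sequence[np.ndarray],
        f_aa: Sequence[np.ndarray],
        frame_interval: float,
    ) -> "TrajectorySet":
        """Assemble a set from per-molecule channel arrays on a shared grid."""
        n = len(time_s)
        parts = []
        for mid, dd, da, aa in zip(molecule_ids, f_dd, f_da, f_aa):
            parts.append(pd.DataFrame({
                "molecule_id": np.full(n, mid, dtype=np.int64),
                "frame": np.arange(n, dtype=np.int64),
                "time_s": time_s,
                "F_DD": dd, "F_DA": da, "F_AA": aa,
            }))
        if parts:
            frames = pd.concat(parts, ignore_index=True)
        else:
            frames = pd.DataFrame({c: [] for c in _COLUMNS})
        return cls(frames, frame_interval)

    def molecule_ids(self) -> list[int]:
        return sorted(self.frames["molecule_id"].unique().tolist())

    def __len__(self) -> int:
        return self.frames["molecule_id"].nunique()

    def get(self, molecule_id: int) -> Trajectory:
        sub = self.frames[self.frames["molecule_id"] == molecule_id]
        if sub.empty:
            raise KeyError(f"no molecule {molecule_id}")
        sub = sub.sort_values("frame")
        return Trajectory(
            molecule_id=int(molecule_id),
            time_s=sub["time_s"].to_numpy(float),
            f_dd=sub["F_DD"].to_numpy(float),
            f_da=sub["F_DA"].to_numpy(float),
            f_aa=sub["F_AA"].to_numpy(float),
            frame_interval=self.frame_interval,
        )

    def __iter__(self) -> Iterator[Trajectory]:
        for mid in self.molecule_ids():
            yield self.get(mid)

    def to_tsv(self, path: str | Path) -> None:
        self.frames.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path,
                 frame_interval: float | None = None) -> "TrajectorySet":
        frames = pd.read_csv(path, sep="\t")
        if frame_interval is None:
            t = frames.sort_values(["molecule_id", "frame"])["time_s"].to_numpy()
            diffs = np.diff(t)
            diffs = diffs[diffs > 0]
            if diffs.size == 0:
                raise ValueError("cannot infer frame_interval from a single frame")
            frame_interval = float(np.median(diffs))
        return cls(frames, frame_interval)


@dataclasses.dataclass(frozen=True)
class GroundTruthEvent:
    """Simulator truth record used by recovery tests and reports.

    ``kind`` is one of ``binding``, ``incorporation-step``, ``bleach-donor``
    or ``bleach-acceptor``. Incorporation steps span the waiting time that
    produced nucleotide ``nt_index`` (1-based) and nest inside their binding
    event.
    """

    molecule_id: int
    kind: str
    t_start: float
    t_end: float
    nt_index: int | None = None

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("t_start must precede t_end")


def truth_to_tsv(events: Iterable[GroundTruthEvent], path: str | Path) -> None:
    rows = [dataclasses.asdict(ev) for ev in events]
    df = pd.DataFrame(rows, columns=["molecule_id", "kind", "t_start",
                                     "t_end", "nt_index"])
    df.to_csv(path, sep="\t", index=False)


def truth_from_tsv(path: str | Path) -> list[GroundTruthEvent]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        nt = None if pd.isna(row.nt_index) else int(row.nt_index)
        out.append(GroundTruthEvent(int(row.molecule_id), str(row.kind),
                                    float(row.t_start), float(row.t_end), nt))
    return out
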
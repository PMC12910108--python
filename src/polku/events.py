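"""Event calling on corrected trajectories.

Colocalization events are maximal runs of polymerase-channel frames above a
photon threshold (50 photons by default), required to last at least two
frames; runs separated by fewer than three sub-threshold frames are merged
into one event, which preserves dwell mass across shot-noise dropouts.

FRET incorporation events are runs of valid frames whose efficiency lies in
the linear band [0.3, 0.8] that last at least five frames (1 s) but less than
20 s and have an overall negative slope. Out-of-band interruptions shorter
than the 1 s minimum event duration (gaps of up to four valid frames) are
bridged within a run: when an efficiency level sits near the band floor,
shot noise throws individual frames out of band and would otherwise fragment
the event and clip its duration. The event's FRET-change magnitude
``delta_e`` defaults to a plateau estimate (median efficiency of the first
frames of the run minus the median of the settled frames just after it,
while the molecule remains observable) so that the final incorporation step,
which carries the efficiency below the band floor, is counted; endpoint- and
fit-based estimates are available via ``delta_mode``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corrections import EfretTrace
from .trajectories import Trajectory

__all__ = [
    "ColocalizationEvent",
    "FretEvent",
    "FirstBinding",
    "call_colocalization",
    "call_colocalization_set",
    "first_binding_times",
    "call_fret_events",
    "events_to_csv",
]


@dataclasses.dataclass(frozen=True)
class ColocalizationEvent:
    molecule_id: int
    start_frame: int
    end_frame: int
    start_s: float
    end_s: float
    duration_s: float
    mean_partner_intensity: float


@dataclasses.dataclass(frozen=True)
class FretEvent:
    """A called FRET decrease.

    ``ends_at_signal_loss`` marks events whose run is terminated by the loss
    of observability (photobleach or dissociation) rather than by the
    efficiency leaving the band: their duration is censored, so dwell
    analyses exclude them (the paper-style photobleaching elimination).
    """

    molecule_id: int
    start_frame: int
    end_frame: int
    start_s: float
    end_s: float
    duration_s: float
    delta_e: float
    slope: float
    ends_at_signal_loss: bool = False


@dataclasses.dataclass(frozen=True)
class FirstBinding:
    """First-arrival observation for one molecule (right-censored if no event)."""

    molecule_id: int
    time_s: float
    censored: bool


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, end) index pairs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def _merge_runs(runs: list[tuple[int, int]], max_gap: int,
                mergeable: np.ndarray | None = None) -> list[tuple[int, int]]:
    """Merge runs separated by <= max_gap frames.

    If ``mergeable`` is given, a gap is only bridged when every gap frame is
    mergeable (used by FRET calling to avoid merging across invalid frames).
    """
    if not runs or max_gap <= 0:
        return list(runs)
    merged = [runs[0]]
    for start, end in runs[1:]:
        prev_start, prev_end = merged[-1]
        gap = start - prev_end - 1
        bridge = gap <= max_gap
        if bridge and mergeable is not None:
            bridge = bool(np.all(mergeable[prev_end + 1:start]))
        if bridge:
            merged[-1] = (prev_start, end)
        else:
            merged.append((start, end))
    return merged


def call_colocalization(
    traj: Trajectory,
    threshold: float = 50.0,
    *,
    min_frames: int = 2,
    merge_gap: int = 2,
    channel: str = "f_aa",
) -> list[ColocalizationEvent]:
    """Call colocalization events on one molecule's partner-channel intensity."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    x = np.asarray(getattr(traj, channel), dtype=float)
    if x.size == 0:
        return []
    dt = traj.frame_interval
    runs = _merge_runs(_runs(x > threshold), merge_gap)
    events = []
    for start, end in runs:
        n = end - start + 1
        if n < min_frames:
            continue
        events.append(ColocalizationEvent(
            molecule_id=traj.molecule_id,
            start_frame=start,
            end_frame=end,
            start_s=start * dt,
            end_s=(end + 1) * dt,
            duration_s=n * dt,
            mean_partner_intensity=float(np.mean(x[start:end + 1])),
        ))
    return events


def call_colocalization_set(
    trajset, threshold: float = 50.0, **kwargs
) -> dict[int, list[ColocalizationEvent]]:
    """Call colocalization events for every molecule of a trajectory set."""
    return {traj.molecule_id: call_colocalization(traj, threshold, **kwargs)
            for traj in trajset}


def first_binding_times(
    events_per_molecule: Mapping[int, Sequence[ColocalizationEvent]],
    observation_window: float,
) -> list[FirstBinding]:
    """First event start per molecule; event-free molecules are censored."""
    out = []
    for mid in sorted(events_per_molecule):
        events = events_per_molecule[mid]
        if events:
            first = min(ev.start_s for ev in events)
            out.append(FirstBinding(mid, float(first), censored=False))
        else:
            out.append(FirstBinding(mid, float(observation_window),
                                    censored=True))
    return out


def _plateau_level(window: np.ndarray, side: str, tolerance: float) -> float:
    """Level of the extreme plateau in a window of efficiencies.

    The extremum is located on means of adjacent frames (to damp shot noise),
    then all frames within ``tolerance`` of it are pooled and averaged, so
    plateaus of any length contribute all their frames.
    """
    w = np.asarray(window, dtype=float)
    if w.size == 1:
        return float(w[0])
    pairs = 0.5 * (w[:-1] + w[1:])
    if side == "high":
        anchor = float(np.max(pairs))
        pooled = w[w >= anchor - tolerance]
    else:
        anchor = float(np.min(pairs))
        pooled = w[w <= anchor + tolerance]
    return float(np.mean(pooled)) if pooled.size else anchor


def _delta_e(e: np.ndarray, valid: np.ndarray, start: int, end: int,
             slope: float, dt: float, mode: str, tolerance: float) -> float:
    if mode == "endpoint":
        delta = e[start] - e[end]
    elif mode == "fit":
        delta = -slope * (end - start) * dt
    elif mode == "plateau":
        # estimate the starting and final plateau levels; frames adjacent to
        # an invalid boundary are skipped because a binding or dissociation
        # that happens mid-frame records a mixed efficiency
        head = e[start:min(start + 6, end + 1)]
        pre = _plateau_level(head, "high", tolerance)

        post_vals: list[float] = []
        truncated = True
        for j in range(end + 1, min(end + 9, len(e))):
            if not valid[j]:
                break
            post_vals.append(e[j])
        else:
            truncated = (end + 9 >= len(e))
        if truncated and post_vals:
            post_vals = post_vals[:-1]  # frame straddling the loss of signal
        if len(post_vals) >= 2:
            tail = np.asarray(post_vals)
        else:
            # event ends with the observation (dissociation or bleach):
            # use the run's own tail, excluding the straddling last frame
            hi = end if (end + 1 >= len(e) or not valid[end + 1]) else end + 1
            tail = e[max(hi - 5, start):hi]
            if tail.size == 0:
                tail = e[end:end + 1]
        post = _plateau_level(tail, "low", tolerance)
        delta = pre - post
    else:
        raise ValueError(f"unknown delta_mode {mode!r}")
    return max(float(delta), 0.0)


def call_fret_events(
    trace: EfretTrace,
    *,
    e_min: float = 0.3,
    e_max: float = 0.8,
    min_frames: int = 5,
    max_duration_s: float = 20.0,
    merge_gap: int = 4,
    delta_mode: str = "plateau",
    level_tolerance: float = 0.05,
) -> list[FretEvent]:
    """Call FRET incorporation events on a corrected, bleach-truncated trace."""
    e = np.asarray(trace.e, dtype=float)
    valid = np.asarray(trace.valid, dtype=bool)
    with np.errstate(invalid="ignore"):
        in_band = valid & (e >= e_min) & (e <= e_max)
    dt = trace.frame_interval
    runs = _merge_runs(_runs(in_band), merge_gap, mergeable=valid)
    events = []
    for start, end in runs:
        n = end - start + 1
        duration = n * dt
        if n < min_frames or duration >= max_duration_s:
            continue
        seg_t = trace.time_s[start:end + 1]
        seg_e = e[start:end + 1]
        slope = float(np.polyfit(seg_t, seg_e, 1)[0])
        if slope >= 0:
            continue
        delta = _delta_e(e, valid, start, end, slope, dt, delta_mode,
                         level_tolerance)
        censored = bool(end + 1 >= len(valid) or not valid[end + 1])
        events.append(FretEvent(
            molecule_id=trace.molecule_id,
            start_frame=start,
            end_frame=end,
            start_s=start * dt,
            end_s=(end + 1) * dt,
            duration_s=duration,
            delta_e=delta,
            slope=slope,
            ends_at_signal_loss=censored,
        ))
    return events


def events_to_csv(events: Iterable[ColocalizationEvent | FretEvent],
                  path: str | Path) -> None:
    """Write called events (either kind) to CSV."""
    rows = [dataclasses.asdict(ev) for ev in events]
    if rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(columns=["molecule_id", "start_frame", "end_frame",
                                   "start_s", "end_s", "duration_s"])
    df.to_csv(path, index=False)
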
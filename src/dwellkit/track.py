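"""Linking per-frame foci into binding events and extracting dwell times.

Foci detected within a fixed radius in strictly consecutive frames belong
to the same binding event; a single missed frame terminates the event (no
gap closing).  Candidate continuations between a frame pair are matched
greedily by ascending distance, each focus used at most once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .protocol import AcquisitionProtocol

__all__ = ["EVENT_COLUMNS", "link_foci", "extract_dwells"]

EVENT_COLUMNS = ["condition_id", "start_frame", "end_frame", "n_frames", "x_px", "y_px"]


class _Event:
    __slots__ = ("start", "end", "sum_x", "sum_y", "n", "last_x", "last_y")

    def __init__(self, frame: int, x: float, y: float):
        self.start = frame
        self.end = frame
        self.sum_x = x
        self.sum_y = y
        self.n = 1
        self.last_x = x
        self.last_y = y

    def extend(self, frame: int, x: float, y: float) -> None:
        self.end = frame
        self.sum_x += x
        self.sum_y += y
        self.n += 1
        self.last_x = x
        self.last_y = y


def link_foci(foci: pd.DataFrame, radius_px: float = 3.0) -> pd.DataFrame:
    """Link a single-condition foci table into binding events.

    Between each pair of consecutive frame indices, active events are
    matched to the new frame's foci greedily by ascending pair distance
    (most recent focus position vs. new focus), with matches allowed only
    within ``radius_px``; each focus is used at most once.  Unmatched new
    foci start events; unmatched active events terminate.  Every focus
    belongs to exactly one event.  Returns one row per event with its
    inclusive frame span and mean position.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    missing = {"frame", "x_px", "y_px"} - set(foci.columns)
    if missing:
        raise ValueError(f"foci table missing columns: {sorted(missing)}")
    if "condition_id" in foci.columns and foci["condition_id"].nunique() > 1:
        raise ValueError(
            "link_foci expects foci from a single condition; got "
            f"{sorted(foci['condition_id'].unique())}"
        )
    if len(foci) == 0:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    condition_id = int(foci["condition_id"].iloc[0]) if "condition_id" in foci.columns else -1

    frames = foci["frame"].to_numpy(dtype=int)
    xs = foci["x_px"].to_numpy(dtype=float)
    ys = foci["y_px"].to_numpy(dtype=float)

    events: list[_Event] = []
    active: list[_Event] = []
    prev_frame: int | None = None

    for f in np.unique(frames):
        idx = np.nonzero(frames == f)[0]
        matched = np.zeros(idx.size, dtype=bool)
        survivors: list[_Event] = []
        if prev_frame is not None and f == prev_frame + 1 and active:
            lx = np.array([ev.last_x for ev in active])
            ly = np.array([ev.last_y for ev in active])
            d = np.hypot(lx[:, None] - xs[idx][None, :], ly[:, None] - ys[idx][None, :])
            pairs = np.argwhere(d <= radius_px)
            if pairs.size:
                taken = np.zeros(len(active), dtype=bool)
                for p in np.argsort(d[pairs[:, 0], pairs[:, 1]], kind="stable"):
                    i, j = pairs[p]
                    if taken[i] or matched[j]:
                        continue
                    taken[i] = True
                    matched[j] = True
                    k = idx[j]
                    active[i].extend(int(f), xs[k], ys[k])
                survivors = [ev for i, ev in enumerate(active) if taken[i]]
        for j in np.nonzero(~matched)[0]:
            k = idx[j]
            ev = _Event(int(f), xs[k], ys[k])
            events.append(ev)
            survivors.append(ev)
        active = survivors
        prev_frame = int(f)

    return pd.DataFrame(
        {
            "condition_id": condition_id,
            "start_frame": [ev.start for ev in events],
            "end_frame": [ev.end for ev in events],
            "n_frames": [ev.end - ev.start + 1 for ev in events],
            "x_px": [ev.sum_x / ev.n for ev in events],
            "y_px": [ev.sum_y / ev.n for ev in events],
        }
    )


def extract_dwells(
    events: pd.DataFrame,
    protocol: AcquisitionProtocol,
    condition_index: int,
    min_frames: int = 1,
    drop_censored: bool = False,
) -> pd.DataFrame:
    """Convert linked events into apparent dwell times for one condition.

    ``dwell_s = n_frames * tau_tl``; events shorter than ``min_frames``
    frames are removed; events whose last frame is the final phase-II frame
    are flagged censored (and dropped when ``drop_censored=True``).  Frame
    indices are absolute within the full two-phase stack.
    """
    protocol._check_condition(condition_index)
    if "condition_id" in events.columns and len(events):
        conds = {int(c) for c in events["condition_id"].unique() if int(c) >= 0}
        if conds and conds != {int(condition_index)}:
            raise ValueError(
                f"events carry condition_id {sorted(conds)}, expected {condition_index}"
            )
    if len(events) == 0:
        return pd.DataFrame(columns=list(EVENT_COLUMNS) + ["dwell_s", "censored"])
    tau_tl = protocol.tau_tl(condition_index)
    last_frame = protocol.n_bleach_frames + protocol.n_frames - 1
    out = events.copy()
    out["dwell_s"] = out["n_frames"] * tau_tl
    out["censored"] = out["end_frame"] == last_frame
    out["condition_id"] = condition_index
    out = out[out["n_frames"] >= min_frames]
    if drop_censored:
        out = out[~out["censored"]]
    return out.reset_index(drop=True)
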
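"""Conduction-velocity mapping from spike timestamps and electrode geometry.

Threshold-crossing times on spatially separated electrodes are grouped
into wavefront events (single-linkage in time) and each event yields a
conduction-velocity estimate, either from consecutive-in-time electrode
pairs (distance / delay) or from a least-squares plane-wave fit of
activation time versus position.

Geometry caveat: for a planar wave, an electrode pair oriented off the
propagation axis sees a longer apparent path per unit delay, so pairwise
velocities overestimate the true speed unless the pair lies along the
propagation direction; the plane fit does not suffer from this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ElectrodeLayout
from .errors import ParameterError

#: Default grouping window, s. Generous relative to one-pitch traversal at
#: the slowest plausible conduction velocity (700 um at 0.047 m/s = 15 ms).
DEFAULT_GROUP_WINDOW_S = 0.05

#: Events spanning longer than layout diagonal / MIN_PLAUSIBLE_VELOCITY are
#: split to guard against chaining across successive beats.
MIN_PLAUSIBLE_VELOCITY_M_PER_S = 0.01


@dataclass
class PropagationEvent:
    """One putative wavefront: member spikes sorted by time."""

    members: list[tuple[str, float]]  # (electrode_id, t_s), time-sorted
    window: float

    @property
    def electrode_ids(self) -> list[str]:
        return [e for e, _ in self.members]

    @property
    def times(self) -> np.ndarray:
        return np.array([t for _, t in self.members])

    @property
    def n_electrodes(self) -> int:
        return len(self.members)


@dataclass
class VelocityEstimate:
    """Conduction-velocity estimate for one wavefront event."""

    velocity: float  # summary velocity, m/s
    mode: str  # "pairwise" | "plane"
    pairwise: np.ndarray = field(default_factory=lambda: np.empty(0))
    direction: np.ndarray | None = None  # unit vector (plane mode)
    n_electrodes: int = 0


def group_into_waves(
    spikes,
    layout: ElectrodeLayout,
    group_window: float = DEFAULT_GROUP_WINDOW_S,
    min_velocity: float = MIN_PLAUSIBLE_VELOCITY_M_PER_S,
) -> list[PropagationEvent]:
    """Group spikes into wavefront events by single-linkage in time.

    ``spikes`` is a DataFrame with columns ``electrode_id, t_s`` (a spike
    table) or an iterable of ``(electrode_id, t)`` pairs. A spike joins the
    current event when it falls within ``group_window`` seconds of the
    event's latest member and its electrode is not already a member;
    otherwise it starts a new event. Events whose total span exceeds
    layout diagonal / ``min_velocity`` are split with a warning. Only
    events with at least two electrodes are returned.
    """
    if group_window <= 0:
        raise ParameterError("group_window must be > 0")
    if isinstance(spikes, pd.DataFrame):
        pairs = list(zip(spikes["electrode_id"], spikes["t_s"]))
    else:
        pairs = [(str(e), float(t)) for e, t in spikes]
    pairs.sort(key=lambda p: p[1])

    max_span = layout.diagonal() * 1e-6 / min_velocity
    events: list[PropagationEvent] = []
    members: list[tuple[str, float]] = []
    seen: set[str] = set()

    def flush():
        if len(members) >= 2:
            events.append(PropagationEvent(list(members), group_window))
        members.clear()
        seen.clear()

    for eid, t in pairs:
        if members:
            span_ok = t - members[0][1] <= max_span
            if not span_ok and t - members[-1][1] <= group_window and eid not in seen:
                warnings.warn(
                    "wavefront event split: span exceeded layout diagonal / "
                    f"{min_velocity} m/s",
                    stacklevel=2,
                )
            if t - members[-1][1] > group_window or eid in seen or not span_ok:
                flush()
        members.append((eid, t))
        seen.add(eid)
    flush()
    return events


def estimate_velocity(
    event: PropagationEvent, layout: ElectrodeLayout, mode: str = "pairwise"
) -> VelocityEstimate:
    """Conduction velocity of one wavefront event.

    Pairwise mode: ``v = distance / delay`` for consecutive-in-time
    electrode pairs, summarized by the median; pairs with zero delay are
    skipped with a warning, and an event where every pair is simultaneous
    is an error. Plane mode: least-squares fit of
    ``t(x, y) = t0 + x * sx + y * sy``; the speed is the reciprocal of the
    slowness-vector norm and the direction its unit vector. Distances are
    centre-to-centre in micrometres.
    """
    if event.n_electrodes < 2:
        raise ParameterError("velocity needs an event with >= 2 electrodes")
    times = event.times
    if np.ptp(times) == 0:
        raise ParameterError("simultaneous activation: no usable delays")
    if mode == "pairwise":
        vs = []
        for (ea, ta), (eb, tb) in zip(event.members[:-1], event.members[1:]):
            dt = tb - ta
            if dt == 0:
                warnings.warn(
                    f"zero delay between electrodes {ea!r} and {eb!r}: pair skipped",
                    stacklevel=2,
                )
                continue
            vs.append(layout.distance(ea, eb) * 1e-6 / dt)
        if not vs:
            raise ParameterError("simultaneous activation: no usable delays")
        vs = np.array(vs)
        return VelocityEstimate(
            velocity=float(np.median(vs)),
            mode="pairwise",
            pairwise=vs,
            n_electrodes=event.n_electrodes,
        )
    if mode == "plane":
        xy = layout.coords(event.electrode_ids)
        A = np.column_stack([np.ones(len(xy)), xy])
        coef, *_ = np.linalg.lstsq(A, times, rcond=None)
        slowness = coef[1:]  # s per um
        norm = float(np.linalg.norm(slowness))
        if norm == 0:
            raise ParameterError("simultaneous activation: no usable delays")
        return VelocityEstimate(
            velocity=1e-6 / norm,
            mode="plane",
            direction=slowness / norm,
            n_electrodes=event.n_electrodes,
        )
    raise ParameterError(f"unknown velocity mode {mode!r}")


def waves_table(
    spikes,
    layout: ElectrodeLayout,
    group_window: float = DEFAULT_GROUP_WINDOW_S,
    mode: str = "pairwise",
) -> pd.DataFrame:
    """Group spikes and estimate a velocity per wavefront event.

    Returns a DataFrame with columns ``event_id, n_electrodes, t_start_s,
    v_m_per_s, direction_x, direction_y``; events whose delays are all
    zero are dropped.
    """
    rows = []
    for k, ev in enumerate(group_into_waves(spikes, layout, group_window)):
        try:
            est = estimate_velocity(ev, layout, mode=mode)
        except ParameterError:
            continue
        dx, dy = (est.direction if est.direction is not None else (np.nan, np.nan))
        rows.append((k, ev.n_electrodes, float(ev.times[0]), est.velocity, dx, dy))
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "n_electrodes",
            "t_start_s",
            "v_m_per_s",
            "direction_x",
            "direction_y",
        ],
    )
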
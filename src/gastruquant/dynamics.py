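"""Neighbor-exchange (T1) detection and contact-change classes.

A T1 exchange is the elementary intercalation event: within a quartet of
cells {a, b, c, d}, the a–b interface shrinks to a point and a new c–d
interface opens, so a and b lose contact while c and d — previously common
neighbors of both — gain it. T1 counts per standardized 90-minute window are
the headline intercalation statistic; per-cell gain/loss classes mirror
the green/magenta/yellow contact-change maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .tissue_model import CellMesh, TrackedTimeLapse


@dataclass(frozen=True)
class T1Event:
    transition: int  # frame t -> t+1
    time_min: float  # earlier timestamp (frame t)
    lost: frozenset  # persistent ids (a, b)
    gained: frozenset  # persistent ids (c, d)

    @property
    def quartet(self) -> frozenset:
        return self.lost | self.gained


def _tracked_adjacency(mesh: CellMesh, track_map: dict[int, int]):
    """Adjacency over persistent ids; counts untracked labels."""
    pairs = set()
    untracked = set()
    for pair in mesh.adjacency:
        a, b = sorted(pair)
        if a in track_map and b in track_map:
            pairs.add(frozenset((track_map[a], track_map[b])))
        else:
            untracked.update(l for l in (a, b) if l not in track_map)
    return pairs, untracked


def adjacency_diff(
    mesh_t: CellMesh,
    mesh_t1: CellMesh,
    track_map_t: dict[int, int],
    track_map_t1: dict[int, int],
):
    """(lost, gained) adjacency pairs between two tracked frames.

    Restricted to cells present (tracked) in both frames, so divisions and
    extrusions never masquerade as exchanges. Returns
    ``(lost, gained, n_excluded)`` where ``n_excluded`` counts untracked
    labels plus pairs dropped because a member left the id universe.
    """
    pairs_t, untracked_t = _tracked_adjacency(mesh_t, track_map_t)
    pairs_t1, untracked_t1 = _tracked_adjacency(mesh_t1, track_map_t1)
    common = {track_map_t[l] for l in mesh_t.cells if l in track_map_t} & {
        track_map_t1[l] for l in mesh_t1.cells if l in track_map_t1
    }
    keep_t = {p for p in pairs_t if p <= common}
    keep_t1 = {p for p in pairs_t1 if p <= common}
    n_excluded = (
        len(untracked_t)
        + len(untracked_t1)
        + len(pairs_t - keep_t)
        + len(pairs_t1 - keep_t1)
    )
    return keep_t - keep_t1, keep_t1 - keep_t, n_excluded


def detect_t1(tl: TrackedTimeLapse):
    """Detect strict quartet T1 events across all transitions.

    A lost pair (a, b) and a gained pair (c, d) form a T1 iff the pairs are
    disjoint and, at frame t, c and d were each adjacent to both a and b.
    Unmatched losses/gains are reported separately (boundary drift,
    extrusion, higher-order rearrangements) — never silently dropped.
    Events carry the earlier frame's timestamp.

    Returns ``(events, unmatched)`` where ``unmatched`` is a DataFrame of
    non-T1 contact changes.
    """
    if len(tl) < 2:
        raise ValueError("need >= 2 frames to detect T1 events")
    events: list[T1Event] = []
    leftovers = []
    for t in range(len(tl) - 1):
        lost, gained, _ = adjacency_diff(
            tl.frames[t], tl.frames[t + 1], tl.track_maps[t], tl.track_maps[t + 1]
        )
        pairs_t, _ = _tracked_adjacency(tl.frames[t], tl.track_maps[t])
        neigh: dict[int, set] = {}
        for p in pairs_t:
            x, y = tuple(p)
            neigh.setdefault(x, set()).add(y)
            neigh.setdefault(y, set()).add(x)
        remaining_gains = set(gained)
        for lp in sorted(lost, key=sorted):
            a, b = tuple(lp)
            match = None
            for gp in sorted(remaining_gains, key=sorted):
                if gp & lp:
                    continue
                c, d = tuple(gp)
                common = neigh.get(a, set()) & neigh.get(b, set())
                if c in common and d in common:
                    match = gp
                    break
            if match is not None:
                remaining_gains.discard(match)
                events.append(
                    T1Event(
                        transition=t,
                        time_min=tl.timestamps[t],
                        lost=lp,
                        gained=match,
                    )
                )
            else:
                leftovers.append(
                    {"transition": t, "kind": "loss_non_t1", "pair": tuple(sorted(lp))}
                )
        for gp in sorted(remaining_gains, key=sorted):
            leftovers.append(
                {"transition": t, "kind": "gain_non_t1", "pair": tuple(sorted(gp))}
            )
    unmatched = pd.DataFrame(leftovers, columns=["transition", "kind", "pair"])
    return events, unmatched


def intercalation_rate(
    events, tl: TrackedTimeLapse, window_min: float = 90.0
) -> float:
    """T1 events normalized to a standard window (default 90 min).

    Counts are scaled linearly in time when the movie span differs from the
    window; spans shorter than half the window are rejected as unreliable
    extrapolation.
    """
    span = tl.timestamps[-1] - tl.timestamps[0]
    if span < window_min / 2:
        raise ValueError(
            f"time-lapse spans {span} min < half the {window_min}-min window"
        )
    return len(list(events)) * window_min / span


def contact_change_map(
    tl: TrackedTimeLapse, interval: tuple[int, int] | None = None
) -> pd.DataFrame:
    """Per-cell contact-change class over a frame interval.

    Classes: 'gain' (green), 'loss' (magenta), 'both' (yellow), 'none',
    from the union of adjacency diffs across every transition in the
    interval. Only cells tracked throughout the interval are classified.
    """
    t0, t1 = interval if interval is not None else (0, len(tl) - 1)
    if not (0 <= t0 < t1 <= len(tl) - 1):
        raise ValueError(f"interval {interval} outside time-lapse of {len(tl)} frames")
    present = None
    for t in range(t0, t1 + 1):
        ids = {
            tl.track_maps[t][l] for l in tl.frames[t].cells if l in tl.track_maps[t]
        }
        present = ids if present is None else (present & ids)
    gainers, losers = set(), set()
    for t in range(t0, t1):
        lost, gained, _ = adjacency_diff(
            tl.frames[t], tl.frames[t + 1], tl.track_maps[t], tl.track_maps[t + 1]
        )
        for p in lost:
            losers.update(p)
        for p in gained:
            gainers.update(p)
    rows = []
    for pid in sorted(present):
        g, l = pid in gainers, pid in losers
        cls = "both" if (g and l) else ("gain" if g else ("loss" if l else "none"))
        rows.append({"persistent_id": pid, "contact_class": cls})
    return pd.DataFrame(rows)
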
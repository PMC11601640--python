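"""Lineage tracking, mitosis/death calling and cell-cycle fate classification.

Tracking is greedy nearest-neighbour linking under a per-frame step limit.
A mitosis is called at anaphase when one track turns into two, each daughter
first-frame nuclear area being 45-55% (inclusive) of the mother's last-frame
area.  Post-mitotic fate is read from the CDK2 activity trace: > 0.6 two
hours after anaphase means immediate re-entry; otherwise a later rise above
0.6 within the observed window is a transient G0, and never rising above 0.6
a prolonged G0.  A lineage with no second mitosis for more than 30 h after
the first is G2-arrested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MITOSIS_BAND = (0.45, 0.55)
FATE_THRESHOLD = 0.6
FATE_DELAY_H = 2.0
G2_ARREST_WINDOW_H = 30.0
CAPTURE_RADIUS_UM = 20.0


@dataclass
class CellTrack:
    track_id: int
    frames: list[int] = field(default_factory=list)
    det_rows: list[int] = field(default_factory=list)  # row index into detections
    parent: int | None = None
    daughters: list[int] = field(default_factory=list)
    end_reason: str = "open"  # division | death | lost | end-of-movie | open

    def last_frame(self) -> int:
        return self.frames[-1]

    def index_at(self, frame: int) -> int | None:
        # frames are strictly increasing; binary search
        i = np.searchsorted(self.frames, frame)
        if i < len(self.frames) and self.frames[i] == frame:
            return int(i)
        return None


@dataclass
class MitosisEvent:
    frame: int  # anaphase frame = first daughter frame
    mother: int
    daughters: tuple[int, int] | None
    fractions: tuple[float, float]
    accepted: bool


def mitosis_band_accept(
    mother_area: float,
    d1_area: float,
    d2_area: float,
    band: tuple[float, float] = MITOSIS_BAND,
) -> bool:
    """The daughter/mother size rule: both fractions in [band_lo, band_hi]."""
    if mother_area <= 0:
        return False
    f1, f2 = d1_area / mother_area, d2_area / mother_area
    return band[0] <= f1 <= band[1] and band[0] <= f2 <= band[1]


def track_nuclei(
    detections: pd.DataFrame,
    pixel_size_um: float,
    max_step_um: float = 12.0,
    max_gap_frames: int = 1,
) -> list[CellTrack]:
    """Greedy frame-to-frame nearest-neighbour linking.

    Unmatched detections open tracks; tracks unmatched for more than
    ``max_gap_frames`` frames are closed as lost.
    """
    tracks: list[CellTrack] = []
    active: list[CellTrack] = []
    if len(detections) == 0:
        return tracks
    max_frame = int(detections["frame"].max())
    by_frame = dict(tuple(detections.groupby("frame")))
    for f in range(int(detections["frame"].min()), max_frame + 1):
        dets = by_frame.get(f)
        det_rows = [] if dets is None else list(dets.index)
        positions = (
            np.empty((0, 2)) if dets is None else dets[["y", "x"]].to_numpy(dtype=float)
        )
        # candidate pairs under the (gap-scaled) step limit
        pairs = []
        for t in active:
            gap = f - t.last_frame()
            last = detections.loc[t.det_rows[-1]]
            limit = max_step_um * gap / pixel_size_um
            if len(positions):
                dists = np.hypot(positions[:, 0] - last["y"], positions[:, 1] - last["x"])
                for j in np.nonzero(dists <= limit)[0]:
                    pairs.append((dists[j], t, int(j)))
        pairs.sort(key=lambda p: p[0])
        used_tracks, used_dets = set(), set()
        for d, t, j in pairs:
            if id(t) in used_tracks or j in used_dets:
                continue
            used_tracks.add(id(t))
            used_dets.add(j)
            t.frames.append(f)
            t.det_rows.append(det_rows[j])
        for j, row in enumerate(det_rows):
            if j not in used_dets:
                nt = CellTrack(track_id=len(tracks), frames=[f], det_rows=[row])
                tracks.append(nt)
                active.append(nt)
        still = []
        for t in active:
            if f - t.last_frame() > max_gap_frames:
                t.end_reason = "lost"
            else:
                still.append(t)
        active = still
    for t in active:
        t.end_reason = "end-of-movie"
    return tracks


def detect_mitosis(
    tracks: list[CellTrack],
    detections: pd.DataFrame,
    pixel_size_um: float,
    band: tuple[float, float] = MITOSIS_BAND,
    capture_radius_um: float = CAPTURE_RADIUS_UM,
) -> tuple[list[MitosisEvent], list[MitosisEvent]]:
    """Call anaphase events and set lineage links; returns (accepted, rejected).

    Handles both topologies produced by a greedy tracker at a division: the
    mother track ends and two tracks appear, or the mother track continues
    into one daughter and a single new track appears (the mother is then split
    at the anaphase frame so the event always consumes one track and produces
    two).
    """
    radius_px = capture_radius_um / pixel_size_um
    accepted: list[MitosisEvent] = []
    rejected: list[MitosisEvent] = []

    def pos(track: CellTrack, idx: int) -> np.ndarray:
        row = detections.loc[track.det_rows[idx]]
        return np.array([row["y"], row["x"]])

    def area(track: CellTrack, idx: int) -> float:
        return float(detections.loc[track.det_rows[idx]]["area_px"])

    max_frame = max((t.last_frame() for t in tracks), default=-1)
    f = 0
    while f <= max_frame:
        f += 1
        newborn = [t for t in tracks if t.frames[0] == f and t.parent is None]
        if not newborn:
            continue
        # mothers: tracks with a detection at f-1 (excluding today's newborns)
        mothers = []
        for t in tracks:
            if t in newborn:
                continue
            i = t.index_at(f - 1)
            if i is not None:
                mothers.append((t, i))
        chosen: dict[int, list[CellTrack]] = {}
        for s in newborn:
            p0 = pos(s, 0)
            best, best_d = None, np.inf
            for m, i in mothers:
                d = np.hypot(*(pos(m, i) - p0))
                if d <= radius_px and d < best_d:
                    best, best_d = m, d
            if best is not None:
                chosen.setdefault(best.track_id, []).append(s)
        for mid, kids in chosen.items():
            m = next(t for t in tracks if t.track_id == mid)
            im = m.index_at(f - 1)
            mother_area = area(m, im)
            cont = m.index_at(f)
            if cont is not None and len(kids) == 1:
                s = kids[0]
                fr = (area(m, cont) / mother_area, area(s, 0) / mother_area)
                ok = mitosis_band_accept(mother_area, area(m, cont), area(s, 0), band)
                if ok:
                    d = CellTrack(
                        track_id=len(tracks),
                        frames=m.frames[cont:],
                        det_rows=m.det_rows[cont:],
                        parent=m.track_id,
                        end_reason=m.end_reason,
                    )
                    d.daughters = m.daughters
                    m.frames = m.frames[:cont]
                    m.det_rows = m.det_rows[:cont]
                    m.end_reason = "division"
                    m.daughters = [d.track_id, s.track_id]
                    s.parent = m.track_id
                    tracks.append(d)
                    accepted.append(MitosisEvent(f, m.track_id, (d.track_id, s.track_id), fr, True))
                else:
                    rejected.append(MitosisEvent(f, m.track_id, None, fr, False))
            elif cont is None and len(kids) == 2:
                s1, s2 = kids
                fr = (area(s1, 0) / mother_area, area(s2, 0) / mother_area)
                ok = mitosis_band_accept(mother_area, area(s1, 0), area(s2, 0), band)
                if ok:
                    m.end_reason = "division"
                    m.daughters = [s1.track_id, s2.track_id]
                    s1.parent = m.track_id
                    s2.parent = m.track_id
                    accepted.append(
                        MitosisEvent(f, m.track_id, (s1.track_id, s2.track_id), fr, True)
                    )
                else:
                    rejected.append(MitosisEvent(f, m.track_id, None, fr, False))
            else:
                for s in kids:
                    fr = (area(s, 0) / mother_area, np.nan)
                    rejected.append(MitosisEvent(f, m.track_id, None, fr, False))
    return accepted, rejected


def detect_deaths(
    tracks: list[CellTrack], detections: pd.DataFrame, drop_fraction: float = 0.5
) -> list[int]:
    """Mark tracks ending with nuclear condensation (area drop > 50% without a
    split) as deaths; returns the affected track ids."""
    dead = []
    for t in tracks:
        if t.end_reason not in ("lost", "end-of-movie") or len(t.frames) < 2:
            continue
        areas = detections.loc[t.det_rows, "area_px"].to_numpy(dtype=float)
        ref = np.median(areas[max(0, len(areas) - 4) : -1])
        if ref > 0 and areas[-1] < (1 - drop_fraction) * ref and t.end_reason == "lost":
            t.end_reason = "death"
            dead.append(t.track_id)
    return dead


# --- traces and fate -------------------------------------------------------


@dataclass
class CDK2Trace:
    track_id: int
    times_min: np.ndarray
    activity: np.ndarray
    birth_anaphase_min: float | None  # anaphase that created this cell
    own_division_min: float | None  # this cell's own division, if any
    track_start_min: float = 0.0


def build_traces(
    tracks: list[CellTrack],
    detections: pd.DataFrame,
    frame_interval_min: float,
    events: list[MitosisEvent] | None = None,
) -> dict[int, CDK2Trace]:
    birth = {}
    division = {}
    for ev in events or []:
        if ev.accepted and ev.daughters:
            division[ev.mother] = ev.frame * frame_interval_min
            for d in ev.daughters:
                birth[d] = ev.frame * frame_interval_min
    traces = {}
    for t in tracks:
        if not t.frames:
            continue
        times = np.asarray(t.frames, dtype=float) * frame_interval_min
        act = detections.loc[t.det_rows, "activity"].to_numpy(dtype=float)
        traces[t.track_id] = CDK2Trace(
            track_id=t.track_id,
            times_min=times,
            activity=act,
            birth_anaphase_min=birth.get(t.track_id),
            own_division_min=division.get(t.track_id),
            track_start_min=float(times[0]),
        )
    return traces


def classify_post_mitotic_fate(
    times_min: np.ndarray,
    activity: np.ndarray,
    anaphase_time_min: float,
    threshold: float = FATE_THRESHOLD,
    delay_h: float = FATE_DELAY_H,
    mode: str = "nearest",
) -> str:
    """Category of one post-mitotic trace: ``cdk2_increasing`` if activity at
    anaphase + delay exceeds the threshold, ``transient_g0`` if it exceeds it
    later within the observed window, else ``prolonged_g0``; ``censored`` if
    the trace ends before anaphase + delay."""
    if mode not in ("nearest", "median3"):
        raise ValueError("mode must be 'nearest' or 'median3'")
    times = np.asarray(times_min, dtype=float)
    act = np.asarray(activity, dtype=float)
    t_eval = anaphase_time_min + delay_h * 60.0
    if len(times) == 0 or times[-1] < t_eval:
        return "censored"
    order = np.argsort(np.abs(times - t_eval))
    if mode == "median3":
        vals = act[order[:3]]
        vals = vals[np.isfinite(vals)]
        v = np.median(vals) if vals.size else np.nan
    else:
        v = np.nan
        for i in order[:3]:  # nearest frame; fall back past missing values
            if np.isfinite(act[i]):
                v = act[i]
                break
    if not np.isfinite(v):
        return "censored"
    if v > threshold:
        return "cdk2_increasing"
    later = (times > t_eval) & np.isfinite(act)
    if np.any(act[later] > threshold):
        return "transient_g0"
    return "prolonged_g0"


def classify_g2_arrest(
    first_mitosis_h: float,
    second_mitosis_h: float | None,
    observation_end_h: float,
    window_h: float = G2_ARREST_WINDOW_H,
) -> str:
    """'cycling' | 'arrested' | 'censored' for one lineage.

    Cycling if a second mitosis occurs within the window after the first;
    arrested if observation extends past the window with none; censored if the
    movie ends before the window elapses.
    """
    if second_mitosis_h is not None and second_mitosis_h - first_mitosis_h <= window_h:
        return "cycling"
    if observation_end_h - first_mitosis_h > window_h:
        return "arrested"
    return "censored"


@dataclass
class Lineage:
    mother: int
    first_mitosis_min: float
    daughters: tuple[int, int]
    second_mitosis_min: float | None
    observation_end_min: float


def collect_lineages(
    tracks: list[CellTrack],
    events: list[MitosisEvent],
    frame_interval_min: float,
) -> list[Lineage]:
    """One lineage per first-generation accepted mitosis: the second mitosis
    is the earliest division of either daughter subtree."""
    by_id = {t.track_id: t for t in tracks}
    ev_by_mother = {ev.mother: ev for ev in events if ev.accepted}
    first_gen = [ev for ev in events if ev.accepted and by_id[ev.mother].parent is None]
    lineages = []
    for ev in first_gen:
        second = None
        end_frame = ev.frame
        stack = list(ev.daughters)
        while stack:
            tid = stack.pop()
            tr = by_id[tid]
            if tr.frames:
                end_frame = max(end_frame, tr.last_frame())
            child_ev = ev_by_mother.get(tid)
            if child_ev is not None:
                if second is None or child_ev.frame < second:
                    second = child_ev.frame
                stack.extend(child_ev.daughters)
        lineages.append(
            Lineage(
                mother=ev.mother,
                first_mitosis_min=ev.frame * frame_interval_min,
                daughters=tuple(ev.daughters),
                second_mitosis_min=None if second is None else second * frame_interval_min,
                observation_end_min=end_frame * frame_interval_min,
            )
        )
    return lineages


def intermitotic_times(
    lineages: list[Lineage], bin_width_h: float = 2.0
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray], int]:
    """Durations (h) between first and second mitosis per lineage, their
    histogram (counts, bin edges), and the censored-lineage count."""
    durations = np.array(
        [
            (ln.second_mitosis_min - ln.first_mitosis_min) / 60.0
            for ln in lineages
            if ln.second_mitosis_min is not None
        ]
    )
    censored = sum(1 for ln in lineages if ln.second_mitosis_min is None)
    if durations.size:
        # edges extend one bin past the max so a duration on a bin boundary
        # lands in its own half-open bin
        hi = (np.floor(durations.max() / bin_width_h) + 1) * bin_width_h
        edges = np.arange(0.0, hi + 0.5 * bin_width_h, bin_width_h)
        counts, edges = np.histogram(durations, bins=edges)
    else:
        counts, edges = np.array([], dtype=int), np.array([0.0])
    return durations, (counts, edges), censored


def heatmap_matrix(
    traces: list[CDK2Trace], n_frames: int, frame_interval_min: float
) -> tuple[np.ndarray, pd.DataFrame]:
    """Activity matrix (cells x frames) sorted by first-mitosis time.

    First mitosis of a cell is its own division time; cells that never divide
    sort last, ordered by track start.  Missing values are NaN.
    """
    def key(tr: CDK2Trace):
        if tr.own_division_min is not None:
            return (0, tr.own_division_min, tr.track_id)
        return (1, tr.track_start_min, tr.track_id)

    ordered = sorted(traces, key=key)
    mat = np.full((len(ordered), n_frames), np.nan)
    for i, tr in enumerate(ordered):
        idx = np.round(tr.times_min / frame_interval_min).astype(int)
        ok = (idx >= 0) & (idx < n_frames)
        mat[i, idx[ok]] = tr.activity[ok]
    meta = pd.DataFrame(
        {
            "track": [tr.track_id for tr in ordered],
            "first_mitosis_min": [tr.own_division_min for tr in ordered],
            "track_start_min": [tr.track_start_min for tr in ordered],
        }
    )
    return mat, meta


def average_activity(
    traces: list[CDK2Trace],
    alignment: str = "movie",
    frame_interval_min: float = 12.0,
) -> pd.DataFrame:
    """Pointwise mean activity with dispersion and per-point n.

    ``alignment='movie'`` uses the shared movie time base;
    ``'anaphase'`` shifts each trace so t=0 is its birth anaphase (traces
    without one are dropped).
    """
    if alignment not in ("movie", "anaphase"):
        raise ValueError("alignment must be 'movie' or 'anaphase'")
    if not traces:
        raise ValueError("at least one trace required")
    series = []
    for tr in traces:
        t = tr.times_min.copy()
        if alignment == "anaphase":
            if tr.birth_anaphase_min is None:
                continue
            t = t - tr.birth_anaphase_min
        series.append((t, tr.activity))
    if not series:
        raise ValueError("no traces usable for the requested alignment")
    all_t = np.unique(np.concatenate([np.round(t / frame_interval_min) for t, _ in series]))
    grid = all_t * frame_interval_min
    sums = np.zeros(len(grid))
    sqs = np.zeros(len(grid))
    ns = np.zeros(len(grid), dtype=int)
    pos = {int(k): i for i, k in enumerate(all_t)}
    for t, a in series:
        for ti, ai in zip(np.round(t / frame_interval_min).astype(int), a):
            if np.isfinite(ai):
                i = pos[ti]
                sums[i] += ai
                sqs[i] += ai * ai
                ns[i] += 1
    mean = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    var = np.where(ns > 1, (sqs - ns * mean**2) / np.maximum(ns - 1, 1), 0.0)
    sd = np.sqrt(np.maximum(var, 0.0))
    sd[ns == 0] = np.nan
    return pd.DataFrame({"time_min": grid, "mean": mean, "sd": sd, "n": ns})
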
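"""Unfolding-event detection, statistics and channel-cation occupancy.

The classifier turns per-frame H-bond states and stem geometry into a
typed, time-stamped event timeline following the common transition
taxonomy of mechanically unfolded parallel G-stems:

unzip
    a single G loses all of its quartet H-bonds while the rest of its
    quartet stays mutually bonded;
strand_slippage
    a strand's H-bond register offset changes by one level with bonds
    re-formed at the new register;
opening
    a strand loses its bonds to exactly one neighbour strand across >=2
    levels while keeping the other neighbour;
detachment
    a strand retains no inter-strand H-bonds and is spatially separated
    from the rest of the stem (terminal for that strand);
spiral_form / spiral_resolve
    a partial-slippage state with monotone per-residue level offsets and
    helical winding of the backbone about the axis beyond the native
    twist (the winding sign gives the spiral handedness);
rotation_crosslike
    a strand's end-to-end vector reverses orientation relative to the
    stem axis while contacts persist (cross-like intermediates);
refold
    restoration of the complete native H-bond set after earlier events;
anchorT_unstack
    a flanking anchor thymine unstacks from its terminal quartet (does
    not alter stem H-bonding, hence never counts as the first stem
    event).

All rules are explicitly threshold-based (see :class:`ClassifierParams`);
a persistence filter suppresses single-frame flicker, and every event
must hold for the persistence window before it is committed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .forces import ForceSeries, transition_forces
from .geometry import fit_quartet_plane, stem_axis
from .hbonds import HBondSeries, compute_hbond_series, register_matrix
from .topology import GUANINE_BASE_ATOMS, THYMINE_BASE_ATOMS, StemTopology
from .trajectory import Trajectory

STEM_EVENT_TYPES = (
    "unzip",
    "strand_slippage",
    "opening",
    "detachment",
    "spiral_form",
    "spiral_resolve",
    "rotation_crosslike",
    "refold",
)

#: precedence when several predicates commit for the same strand close in
#: time (higher wins)
_PRIORITY = {
    "detachment": 7,
    "rotation_crosslike": 6,
    "spiral_form": 5,
    "spiral_resolve": 5,
    "strand_slippage": 4,
    "opening": 3,
    "unzip": 2,
    "refold": 1,
    "anchorT_unstack": 0,
}


@dataclass(frozen=True)
class ClassifierParams:
    """All thresholds of the rule-based event classifier."""

    d_cut: float = 3.5                 # A, H-bond distance (with hydrogens)
    angle_cut: float = 135.0           # deg, donor-H-acceptor
    d_cut_no_h: float = 3.4            # A, distance-only H-bond mode
    persistence: int = 10              # frames a state must hold to commit
    detach_min_dist: float = 8.0       # A, strand separation for detachment
    rotation_angle: float = 120.0      # deg, end-to-end vs axis
    spiral_offset_range: float = 0.7   # levels, min partial-slippage spread
    spiral_wind_per_level: float = 45.0  # deg extra winding per slipped level
    spiral_align_max: float = 60.0     # deg, strand must stay axis-aligned
    t_unstack_dist: float = 6.0        # A, anchor-T centroid from its G
    suppress_window: int = 30          # frames, strand-event masking of unzips
    monotone_tol: float = 0.15         # levels, tolerance for monotonicity
    strand_move_min: float = 1.0       # A, min strand motion for spirals


@dataclass
class UnfoldingEvent:
    """One committed unfolding transition."""

    type: str
    frame: int
    time_ns: float
    strand: int | None = None
    residues: tuple = ()
    terminus: int | None = None
    first_broken_edge: str | None = None
    quartets_remaining_before: int | None = None
    handedness: str | None = None
    detail: str | None = None
    transition_force_pN: float | None = None

    def to_dict(self) -> dict:
        return {
            "type": self.type,
            "frame": int(self.frame),
            "time_ns": float(self.time_ns),
            "strand": None if self.strand is None else int(self.strand),
            "residues": [list(r) for r in self.residues],
            "terminus": self.terminus,
            "first_broken_edge": self.first_broken_edge,
            "quartets_remaining_before": self.quartets_remaining_before,
            "handedness": self.handedness,
            "detail": self.detail,
            "transition_force_pN": self.transition_force_pN,
        }


@dataclass
class EventTimeline:
    """Ordered events of one run plus the state series they came from."""

    events: list[UnfoldingEvent]
    n_frames: int
    times: np.ndarray
    run_id: str = ""

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)

    def stem_events(self) -> list[UnfoldingEvent]:
        """Events that alter H-bonding in the stem (anchor-T unstacking
        does not)."""
        return [e for e in self.events if e.type in STEM_EVENT_TYPES]

    def first_stem_event(self) -> UnfoldingEvent | None:
        ev = self.stem_events()
        return ev[0] if ev else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.to_dict() for e in self.events])


# ---------------------------------------------------------------------------
# per-frame strand features


@dataclass
class _StrandFeatures:
    frac_offset: np.ndarray      # (n_frames, 4, n) geometric level offsets
    winding: np.ndarray          # (n_frames, 4) extra winding, deg
    axis_angle: np.ndarray       # (n_frames, 4) end-to-end vs axis, deg
    min_dist: np.ndarray         # (n_frames, 4) to the other strands, A
    displacement: np.ndarray     # (n_frames, 4) mean motion since frame 0, A
    t_dist: dict                 # (strand, end) -> (n_frames,) plane distance
    quartet_links: np.ndarray    # (n_frames, n) native link count per quartet


def _strand_feature_series(
    traj: Trajectory, topology: StemTopology, series: HBondSeries
) -> _StrandFeatures:
    n = topology.n_quartets
    nf = traj.n_frames
    g_idx = np.empty((4, n, len(GUANINE_BASE_ATOMS)), dtype=int)
    for s, level, rid in topology.iter_guanines():
        g_idx[s, level] = traj.atom_indices(rid, GUANINE_BASE_ATOMS)
    strand_atoms = [g_idx[s].ravel() for s in range(4)]

    t_res = {}
    for s, strand in enumerate(topology.strands):
        for end, rid in (("5'", strand.t5), ("3'", strand.t3)):
            if rid is not None:
                try:
                    t_res[(s, end)] = traj.atom_indices(rid, THYMINE_BASE_ATOMS)
                except KeyError:
                    # minimal topologies may lack some thymine atoms
                    t_res[(s, end)] = traj.atom_indices(rid, ["C2", "C4", "C6"])

    frac = np.full((nf, 4, n), np.nan)
    wind = np.zeros((nf, 4))
    axang = np.zeros((nf, 4))
    mind = np.zeros((nf, 4))
    disp = np.zeros((nf, 4))
    tdist = {k: np.zeros(nf) for k in t_res}
    links = np.zeros((nf, n))

    # native reference frame (frame 0): axis, level grid, azimuth basis
    xyz0 = traj.coords[0]
    cent0 = np.array(
        [[xyz0[g_idx[s, k]].mean(axis=0) for k in range(n)] for s in range(4)]
    )
    quartet_cent0 = cent0.mean(axis=0)
    axis0 = stem_axis(quartet_cent0)
    origin0 = quartet_cent0.mean(axis=0)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ axis0) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u0 = ref - (ref @ axis0) * axis0
    u0 /= np.linalg.norm(u0)
    v0 = np.cross(axis0, u0)
    grid0 = (quartet_cent0 - origin0) @ axis0              # level z positions
    step0 = np.diff(grid0)
    step0[np.abs(step0) < 1e-9] = 1e-9
    native_dphi = np.zeros((4, n - 1))
    for s in range(4):
        rel = cent0[s] - origin0
        phi = np.degrees(np.arctan2(rel @ v0, rel @ u0))
        dphi = np.diff(phi)
        native_dphi[s] = (dphi + 180.0) % 360.0 - 180.0

    base_cent = np.empty((4, n, 3))

    for f in range(nf):
        xyz = traj.coords[f]
        for s in range(4):
            for k in range(n):
                base_cent[s, k] = xyz[g_idx[s, k]].mean(axis=0)
        for s in range(4):
            # the reference frame for strand s is the native frame rigidly
            # superposed onto the still-bonded Gs of the other strands, so
            # neither the motion of s nor displaced (unzipped, slipped,
            # detached) reference Gs can drag the frame of reference
            others = [o for o in range(4) if o != s]
            ref_idx = [
                g_idx[o, k]
                for o in others
                for k in range(n)
                if series.g_bonded(f, o, k)
            ]
            if len(ref_idx) < 2:
                ref_idx = [g_idx[o, k] for o in others for k in range(n)]
            sel = np.concatenate(ref_idx)
            cur = xyz[sel]
            nat = xyz0[sel]
            cur_mean, nat_mean = cur.mean(axis=0), nat.mean(axis=0)
            rot, _ = Rotation.align_vectors(cur - cur_mean, nat - nat_mean)
            axis = rot.apply(axis0)
            origin = cur_mean + rot.apply(origin0 - nat_mean)
            u = rot.apply(u0)
            v = rot.apply(v0)

            z = (base_cent[s] - origin) @ axis
            lev = np.interp(z, grid0, np.arange(n))
            # np.interp clamps outside the grid; extrapolate linearly
            below = z < grid0[0]
            above = z > grid0[-1]
            lev[below] = (z[below] - grid0[0]) / step0[0]
            lev[above] = (n - 1) + (z[above] - grid0[-1]) / step0[-1]
            frac[f, s] = lev - np.arange(n)
            rel = base_cent[s] - origin
            phi = np.degrees(np.arctan2(rel @ v, rel @ u))
            dphi = np.diff(phi)
            dphi = (dphi + 180.0) % 360.0 - 180.0
            extra = dphi - native_dphi[s]
            extra = (extra + 180.0) % 360.0 - 180.0
            wind[f, s] = extra.sum()
            e2e = base_cent[s, -1] - base_cent[s, 0]
            cosang = np.clip(e2e @ axis / np.linalg.norm(e2e), -1.0, 1.0)
            axang[f, s] = np.degrees(np.arccos(cosang))
            other_xyz = xyz[np.concatenate([strand_atoms[o] for o in others])]
            mind[f, s] = cdist(xyz[strand_atoms[s]], other_xyz).min()
            disp[f, s] = np.linalg.norm(
                xyz[strand_atoms[s]] - traj.coords[0][strand_atoms[s]], axis=1
            ).mean()
        for (s, end), idx in t_res.items():
            # unstacking is the T leaving its own terminal G; when instead
            # the G left (unzipped away from a static T) the T displacement
            # stays small and the event belongs to the G, so we record the
            # separation with the sign of "who moved"
            level = 0 if end == "5'" else n - 1
            t_cent = xyz[idx].mean(axis=0)
            g_cent = xyz[g_idx[s, level]].mean(axis=0)
            d_own = float(np.linalg.norm(t_cent - g_cent))
            t_moved = float(
                np.linalg.norm(t_cent - traj.coords[0][idx].mean(axis=0))
            )
            g_moved = float(
                np.linalg.norm(
                    g_cent - traj.coords[0][g_idx[s, level]].mean(axis=0)
                )
            )
            tdist[(s, end)][f] = d_own if t_moved > g_moved else 0.0
        for k in range(n):
            links[f, k] = series.present[f, :, k, k, :].any(axis=-1).sum()
    return _StrandFeatures(
        frac_offset=frac,
        winding=wind,
        axis_angle=axang,
        min_dist=mind,
        displacement=disp,
        t_dist=tdist,
        quartet_links=links,
    )


# ---------------------------------------------------------------------------
# predicate -> committed events


def _onsets(pred: np.ndarray, persistence: int) -> list[int]:
    """Frames where ``pred`` turns True and stays True for >= persistence
    frames (the window must fit inside the trajectory)."""
    out = []
    nf = len(pred)
    f = 0
    while f < nf:
        if pred[f] and (f == 0 or not pred[f - 1]):
            end = f + persistence
            if end <= nf and pred[f:end].all():
                out.append(f)
        f += 1
    return out


def _quartets_remaining(links: np.ndarray, frame: int) -> int:
    """Quartets still present just before a frame: >=2 native links."""
    f = max(0, frame - 1)
    return int((links[f] >= 2).sum())


def detect_events(
    traj: Trajectory,
    topology: StemTopology,
    params: ClassifierParams | None = None,
    series: HBondSeries | None = None,
    run_id: str = "",
) -> EventTimeline:
    """Rule-based classification of unfolding transitions.

    Assumes the trajectory starts in (or near) the native state, which
    provides the reference for register offsets, winding and strand
    orientation.  Frames must be uniformly spaced in time.
    """
    params = params or ClassifierParams()
    steps = np.diff(traj.times)
    if steps.size and not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
        raise ValueError("non-uniform frame spacing; resample the trajectory")
    if series is None:
        series = compute_hbond_series(
            traj,
            topology,
            d_cut=params.d_cut,
            angle_cut=params.angle_cut,
            d_cut_no_h=params.d_cut_no_h,
        )
    feats = _strand_feature_series(traj, topology, series)
    per_strand_reg, _ = register_matrix(series)
    n = topology.n_quartets
    nf = traj.n_frames
    P = params.persistence

    candidates: list[UnfoldingEvent] = []

    def add(ev: UnfoldingEvent) -> None:
        candidates.append(ev)

    # ---- strand-level predicates ----
    bonded_levels_wc = np.array(
        [
            [series.strand_levels_bonded(f, s, "wc") for s in range(4)]
            for f in range(nf)
        ]
    )
    bonded_levels_h = np.array(
        [
            [series.strand_levels_bonded(f, s, "h") for s in range(4)]
            for f in range(nf)
        ]
    )
    no_bonds = (bonded_levels_wc == 0) & (bonded_levels_h == 0)

    for s in range(4):
        detach_pred = no_bonds[:, s] & (feats.min_dist[:, s] > params.detach_min_dist)
        for f in _onsets(detach_pred, P):
            add(
                UnfoldingEvent(
                    type="detachment",
                    frame=f,
                    time_ns=traj.times[f],
                    strand=s,
                    residues=tuple(topology.strands[s].g_residues),
                    quartets_remaining_before=_quartets_remaining(
                        feats.quartet_links, f
                    ),
                )
            )

        rot_pred = (feats.axis_angle[:, s] > params.rotation_angle) & (
            feats.min_dist[:, s] <= params.detach_min_dist
        )
        for f in _onsets(rot_pred, P):
            add(
                UnfoldingEvent(
                    type="rotation_crosslike",
                    frame=f,
                    time_ns=traj.times[f],
                    strand=s,
                    residues=tuple(topology.strands[s].g_residues),
                    quartets_remaining_before=_quartets_remaining(
                        feats.quartet_links, f
                    ),
                )
            )

        # spiral: monotone partial slippage + winding, strand still
        # axis-aligned and attached
        offs = feats.frac_offset[:, s, :]
        d = np.diff(offs, axis=1)
        mono = (d >= -params.monotone_tol).all(axis=1) | (
            d <= params.monotone_tol
        ).all(axis=1)
        rng = offs.max(axis=1) - offs.min(axis=1)
        wind_ok = np.abs(feats.winding[:, s]) >= (
            params.spiral_wind_per_level * rng
        )
        spiral_pred = (
            mono
            & (rng >= params.spiral_offset_range)
            & wind_ok
            & (feats.axis_angle[:, s] < params.spiral_align_max)
            & (feats.min_dist[:, s] <= params.detach_min_dist)
            & (feats.displacement[:, s] > params.strand_move_min)
        )
        spiral_on = _onsets(spiral_pred, P)
        for f in spiral_on:
            hand = "right" if feats.winding[f, s] > 0 else "left"
            add(
                UnfoldingEvent(
                    type="spiral_form",
                    frame=f,
                    time_ns=traj.times[f],
                    strand=s,
                    residues=tuple(topology.strands[s].g_residues),
                    handedness=hand,
                    quartets_remaining_before=_quartets_remaining(
                        feats.quartet_links, f
                    ),
                )
            )
        # resolution: spiral predicate ends after having been committed
        for f in _onsets(~spiral_pred, P):
            started_before = [fo for fo in spiral_on if fo < f]
            if not started_before:
                continue
            # judge the outcome once the transition has settled
            f_set = min(f + P, nf - 1)
            reg = per_strand_reg[f_set, s]
            outcome = (
                "slipped"
                if np.isfinite(reg) and abs(reg) >= 1
                else "native"
            )
            add(
                UnfoldingEvent(
                    type="spiral_resolve",
                    frame=f,
                    time_ns=traj.times[f],
                    strand=s,
                    residues=tuple(topology.strands[s].g_residues),
                    detail=outcome,
                    quartets_remaining_before=_quartets_remaining(
                        feats.quartet_links, f
                    ),
                )
            )

        # slippage: register offset steps by one level and stays there
        reg = per_strand_reg[:, s]
        current = 0.0
        f = 0
        while f < nf:
            v = reg[f]
            if (
                np.isfinite(v)
                and v != current
                and abs(v - current) == 1
                and f + P <= nf
                and np.all(reg[f : f + P] == v)
            ):
                add(
                    UnfoldingEvent(
                        type="strand_slippage",
                        frame=f,
                        time_ns=traj.times[f],
                        strand=s,
                        residues=tuple(topology.strands[s].g_residues),
                        detail=f"offset {int(current)}->{int(v)}",
                        quartets_remaining_before=_quartets_remaining(
                            feats.quartet_links, f
                        ),
                    )
                )
                current = v
                f += P
                continue
            f += 1

        # opening: one neighbour lost across >=2 levels, other kept
        open_wc = (bonded_levels_wc[:, s] == 0) & (bonded_levels_h[:, s] >= 2)
        open_h = (bonded_levels_h[:, s] == 0) & (bonded_levels_wc[:, s] >= 2)
        for pred, side in ((open_wc, "wc"), (open_h, "h")):
            for f in _onsets(pred, P):
                neighbor = (s + 1) % 4 if side == "wc" else (s - 1) % 4
                # the opening is owned by the strand that moved: a lost
                # interface also shows up from the static partner's side,
                # and a departing (detaching/rotating) neighbour that lost
                # all of its own bonds must not charge this strand
                if feats.displacement[f, s] <= feats.displacement[f, neighbor]:
                    continue
                still_bonded = np.mean(
                    [
                        series.strand_bond_count(ff, neighbor) > 0
                        for ff in range(f, min(f + P, nf))
                    ]
                )
                if still_bonded < 0.5:
                    continue
                add(
                    UnfoldingEvent(
                        type="opening",
                        frame=f,
                        time_ns=traj.times[f],
                        strand=s,
                        residues=tuple(topology.strands[s].g_residues),
                        detail=f"lost {side} neighbour",
                        quartets_remaining_before=_quartets_remaining(
                            feats.quartet_links, f
                        ),
                    )
                )

    # ---- per-G unzip ----
    W = params.suppress_window
    for s, level, rid in topology.iter_guanines():
        g_bonded = np.array(
            [series.g_bonded(f, s, level) for f in range(nf)]
        )
        others_linked = np.array(
            [
                series.present[f, (s + 1) % 4, level, level, :].any()
                or series.present[f, (s + 2) % 4, level, level, :].any()
                for f in range(nf)
            ]
        )
        for f in _onsets(~g_bonded & others_linked, P):
            # the bond loss must be recent and from a solidly bonded state:
            # a long-free or borderline-flickering G whose quartet links
            # merely blink is not a new unzipping transition
            look = g_bonded[max(0, f - W) : f]
            if not len(look) or look.mean() < 0.8:
                continue
            end = "5'" if level == 0 else ("3'" if level == n - 1 else None)
            add(
                UnfoldingEvent(
                    type="unzip",
                    frame=f,
                    time_ns=traj.times[f],
                    strand=s,
                    residues=(rid,),
                    terminus=None if end is None else topology.terminus_of(s, end),
                    quartets_remaining_before=_quartets_remaining(
                        feats.quartet_links, f
                    ),
                )
            )

    # ---- refold ----
    native_ok = series.native_complete()
    for f in _onsets(native_ok, P):
        if f == 0:
            continue
        add(UnfoldingEvent(type="refold", frame=f, time_ns=traj.times[f]))

    # ---- anchor-T unstacking ----
    for (s, end), dist in feats.t_dist.items():
        for f in _onsets(dist > params.t_unstack_dist, P):
            strand = topology.strands[s]
            t_rid = strand.t5 if end == "5'" else strand.t3
            add(
                UnfoldingEvent(
                    type="anchorT_unstack",
                    frame=f,
                    time_ns=traj.times[f],
                    strand=s,
                    residues=(t_rid,),
                    terminus=topology.terminus_of(s, end),
                )
            )

    return EventTimeline(
        events=_assemble(candidates, params),
        n_frames=nf,
        times=traj.times,
        run_id=run_id,
    )


def _assemble(
    candidates: list[UnfoldingEvent], params: ClassifierParams
) -> list[UnfoldingEvent]:
    """Order candidates, apply precedence/suppression and detachment
    permanence."""
    cands = sorted(
        candidates, key=lambda e: (e.frame, -_PRIORITY[e.type])
    )
    W = params.suppress_window
    strand_events = {
        "strand_slippage",
        "opening",
        "detachment",
        "spiral_form",
        "spiral_resolve",
        "rotation_crosslike",
    }
    committed: list[UnfoldingEvent] = []
    detached: set[int] = set()

    def near_strand_event(ev: UnfoldingEvent, types: set[str]) -> bool:
        for other in cands:
            if other is ev or other.strand != ev.strand:
                continue
            if other.type in types and abs(other.frame - ev.frame) <= W:
                if _PRIORITY[other.type] > _PRIORITY[ev.type]:
                    return True
        return False

    for ev in cands:
        if ev.strand is not None and ev.strand in detached:
            continue  # detachment is terminal for the strand
        same = [
            c
            for c in committed
            if c.type == ev.type
            and c.strand == ev.strand
            and c.residues == ev.residues
            and c.detail == ev.detail
        ]
        if any(abs(c.frame - ev.frame) <= W for c in same):
            continue  # flicker re-commit of the same transition
        if same and not any(
            c.strand == ev.strand and c.frame > max(s.frame for s in same)
            and c.type != ev.type
            for c in committed
        ):
            # identical state re-announced with nothing having happened to
            # the strand in between: still the same transition
            continue
        if ev.type == "unzip" and near_strand_event(ev, strand_events):
            continue
        if ev.type == "opening" and near_strand_event(
            ev, strand_events - {"opening"}
        ):
            continue
        if ev.type == "strand_slippage" and near_strand_event(
            ev, {"spiral_form", "spiral_resolve", "rotation_crosslike", "detachment"}
        ):
            continue
        if ev.type == "refold":
            prior = [
                c
                for c in committed
                if c.type in STEM_EVENT_TYPES and c.frame < ev.frame
            ]
            if not prior:
                continue
            last = prior[-1]
            # a refold must resolve an outstanding perturbation; after a
            # native-restoring resolution there is nothing left to refold
            if last.type == "refold" or (
                last.type == "spiral_resolve" and last.detail == "native"
            ):
                continue
        if ev.type == "detachment":
            detached.add(ev.strand)
        committed.append(ev)
    return committed


# ---------------------------------------------------------------------------
# first-unzip edge


def first_unzip_edge(
    timeline: EventTimeline,
    series: HBondSeries,
    topology: StemTopology,
    feo_series: np.ndarray | None = None,
) -> dict:
    """Which H-bond edge of the first unzipped G broke first.

    Returns a record with the terminus, the first broken edge ("WC",
    "H" or "both" on a within-frame tie, from the perspective of the
    pulled-out G) and the contemporaneous force-edge overlap when a
    per-frame ``feo_series`` is supplied.  If the first stem event is not
    an unzip the edge is reported as "n/a".
    """
    first = timeline.first_stem_event()
    if first is None or first.type != "unzip":
        return {
            "terminus": None if first is None else first.terminus,
            "edge": "n/a",
            "feo": None,
            "event": first,
        }
    s = first.strand
    level = topology.level_of(first.residues[0])[1]
    fc = first.frame

    def break_frame(edge: str) -> int:
        present = np.array(
            [
                (
                    series.g_donated(f, s, level)
                    if edge == "WC"
                    else series.g_accepted(f, s, level)
                ).any()
                for f in range(fc + 1)
            ]
        )
        absent_from = fc
        for f in range(fc, -1, -1):
            if present[f]:
                break
            absent_from = f
        return absent_from

    wc_break, h_break = break_frame("WC"), break_frame("H")
    if wc_break < h_break:
        edge = "WC"
    elif h_break < wc_break:
        edge = "H"
    else:
        edge = "both"
    feo = None
    if feo_series is not None:
        feo = float(np.asarray(feo_series, float)[fc])
    return {"terminus": first.terminus, "edge": edge, "feo": feo, "event": first}


# ---------------------------------------------------------------------------
# ensemble statistics


@dataclass
class EventStats:
    """Aggregated statistics over a collection of runs."""

    counts_by_type: pd.DataFrame
    first_events: pd.DataFrame
    first_event_3prime_fraction: float
    spiral_handedness: dict
    n_runs: int

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "counts_by_type": self.counts_by_type,
            "first_events": self.first_events,
        }


def event_stats(
    timelines: list[EventTimeline],
    labels: list[dict] | None = None,
) -> EventStats:
    """Cross-run tallies: event counts, first-event termini, spiral
    handedness.

    ``labels`` may carry per-run metadata (e.g. ``anchors``,
    ``n_quartets``, ``water``); label keys become grouping columns of the
    count table.
    """
    if not timelines:
        raise ValueError("event_stats needs at least one timeline")
    labels = labels or [{} for _ in timelines]
    rows = []
    first_rows = []
    spirals = {"left": 0, "right": 0}
    for tl, lab in zip(timelines, labels):
        run = lab.get("run_id", tl.run_id)
        for ev in tl.events:
            rows.append({"run_id": run, "type": ev.type, **lab})
            if ev.type == "spiral_form" and ev.handedness in spirals:
                spirals[ev.handedness] += 1
        first = tl.first_stem_event()
        if first is not None:
            first_rows.append(
                {
                    "run_id": run,
                    "type": first.type,
                    "terminus": first.terminus,
                    "time_ns": first.time_ns,
                    "is_3prime": (
                        None
                        if first.terminus is None
                        else bool(first.terminus >= 5)
                    ),
                    **lab,
                }
            )
    df = pd.DataFrame(rows)
    group_cols = ["type"] + [
        k for k in (labels[0] or {}) if k not in ("run_id",)
    ]
    counts = (
        df.groupby(group_cols).size().rename("count").reset_index()
        if len(df)
        else pd.DataFrame(columns=["type", "count"])
    )
    firsts = pd.DataFrame(first_rows)
    known = [r for r in first_rows if r["is_3prime"] is not None]
    frac3 = (
        sum(r["is_3prime"] for r in known) / len(known) if known else float("nan")
    )
    n_spiral = spirals["left"] + spirals["right"]
    hand = {
        "left": spirals["left"],
        "right": spirals["right"],
        "left_fraction": spirals["left"] / n_spiral if n_spiral else float("nan"),
    }
    return EventStats(
        counts_by_type=counts,
        first_events=firsts,
        first_event_3prime_fraction=frac3,
        spiral_handedness=hand,
        n_runs=len(timelines),
    )


def attach_transition_forces(
    timeline: EventTimeline,
    series: ForceSeries,
    window_ns: float = 2.0,
) -> EventTimeline:
    """Annotate each event with the windowed |F| average ending at it."""
    times = np.array([e.time_ns for e in timeline.events])
    if not len(times):
        return timeline
    forces = transition_forces(series, times, window_ns=window_ns)
    events = [
        replace(e, transition_force_pN=float(fv))
        for e, fv in zip(timeline.events, forces)
    ]
    return EventTimeline(
        events=events,
        n_frames=timeline.n_frames,
        times=timeline.times,
        run_id=timeline.run_id,
    )


# ---------------------------------------------------------------------------
# channel cation occupancy


@dataclass
class OccupancySeries:
    """Per-site channel-cation occupancy."""

    occupied: np.ndarray     # (n_frames, n_sites) bool
    times: np.ndarray

    @property
    def percent(self) -> np.ndarray:
        """Percentage of frames each inter-quartet site holds a cation."""
        return 100.0 * self.occupied.mean(axis=0)


DEFAULT_ION_RESNAMES = ("K", "K+", "POT")


def channel_occupancy(
    traj: Trajectory,
    topology: StemTopology,
    ion_resnames: tuple[str, ...] = DEFAULT_ION_RESNAMES,
    radial_cut: float = 2.5,
) -> OccupancySeries:
    """K+ occupancy of the inter-quartet channel sites.

    A site (between adjacent quartets) is occupied in a frame iff an
    ion's projection onto the stem axis lies strictly between the two
    quartet centroids' projections and its distance from the axis is at
    most ``radial_cut``.
    """
    ion_mask = traj.atoms["resname"].isin(list(ion_resnames)).to_numpy()
    ion_idx = np.flatnonzero(ion_mask)
    if not len(ion_idx):
        raise ValueError(
            f"no ions with residue names {ion_resnames} in the topology"
        )
    n = topology.n_quartets
    g_idx = np.empty((4, n, len(GUANINE_BASE_ATOMS)), dtype=int)
    for s, level, rid in topology.iter_guanines():
        g_idx[s, level] = traj.atom_indices(rid, GUANINE_BASE_ATOMS)
    nf = traj.n_frames
    occ = np.zeros((nf, n - 1), dtype=bool)
    for f in range(nf):
        xyz = traj.coords[f]
        cents = np.array(
            [xyz[g_idx[:, k].ravel()].mean(axis=0) for k in range(n)]
        )
        axis = stem_axis(cents)
        origin = cents.mean(axis=0)
        zq = (cents - origin) @ axis
        ions = xyz[ion_idx]
        zi = (ions - origin) @ axis
        radial = np.linalg.norm(
            (ions - origin) - np.outer(zi, axis), axis=1
        )
        for k in range(n - 1):
            lo, hi = sorted((zq[k], zq[k + 1]))
            occ[f, k] = bool(
                np.any((zi > lo) & (zi < hi) & (radial <= radial_cut))
            )
    return OccupancySeries(occupied=occ, times=traj.times)
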
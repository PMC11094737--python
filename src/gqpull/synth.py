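"""Synthetic parallel G-stems, deformation/unfolding trajectories, force traces.

This module is the package's test and demonstration substrate.  It builds
an idealised tetramolecular parallel all-anti G-stem (3-5 quartets,
right-handed ~30 deg twist per step, ~3.4 A rise, channel K+ between
adjacent quartets, flanking anchor thymines), applies scripted elastic
deformations (twist/rise ramps, quartet buckling) and scripted unfolding
events (unzipping, strand slippage, opening, detachment, spiral formation
and resolution, strand rotation, refolding, anchor-T unstacking), and
generates constant-velocity harmonic pulling-force traces.  Every output
carries a :class:`SyntheticTruth` with the injected parameters, so each
analysis stage can be checked by round-trip recovery.

The event choreography is linear interpolation of rigid sub-group motions
in internal coordinates; no physical realism is claimed beyond label
fidelity: the generated frames satisfy the geometric definition of their
scripted label at (and after) the scripted frame.

Bases use standard planar reference-frame heavy-atom geometry; the
backbone is represented minimally (C1' and the glycosidic nitrogen),
which suffices for every analysis in the package.  The quartet is
assembled by solving for the rigid in-plane placement of the guanine
template that realises the cyclic N1-H...O6 / N2-H...N7 bonding at the
target H-bond length under exact C4 symmetry.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .forces import PN_PER_KJ_MOL_NM, ForceSeries, PullingSchedule
from .topology import (
    GUANINE_BASE_ATOMS,
    StemTopology,
    build_topology_from_strands,
)
from .trajectory import Trajectory

# ---------------------------------------------------------------------------
# base templates: standard reference-frame in-plane heavy-atom coordinates (A)

_GUANINE_2D = {
    "C1'": (-2.477, 5.399),
    "N9": (-1.289, 4.551),
    "C8": (0.023, 4.962),
    "N7": (0.870, 3.969),
    "C5": (0.071, 2.833),
    "C6": (0.424, 1.460),
    "O6": (1.554, 0.955),
    "N1": (-0.700, 0.641),
    "C2": (-1.999, 1.087),
    "N2": (-2.949, 0.139),
    "N3": (-2.342, 2.364),
    "C4": (-1.265, 3.177),
}

_THYMINE_2D = {
    "C1'": (-2.481, 5.354),
    "N1": (-1.284, 4.500),
    "C2": (-1.462, 3.135),
    "O2": (-2.562, 2.608),
    "N3": (-0.298, 2.407),
    "C4": (0.994, 2.897),
    "O4": (1.944, 2.119),
    "C5": (1.106, 4.338),
    "C7": (2.466, 4.961),
    "C6": (-0.024, 5.057),
}

#: target heavy-atom donor-acceptor distance in the assembled quartet (A)
HBOND_LENGTH = 2.90

CHAINS = ("A", "B", "C", "D")
ION_RESNAME = "K"


def _rot2(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


@lru_cache(maxsize=8)
def _quartet_placement(radius: float) -> tuple[float, float, float]:
    """Rigid in-plane placement (theta, tx, ty) of the guanine template.

    Under exact C4 symmetry (each strand the previous one rotated +90 deg
    about the channel axis) the two cyclic H-bond constraints
    (N1...O6 and N2...N7 at HBOND_LENGTH) pin the quartet geometry up to a
    global rotation: only two rigid solution branches exist, one physical
    (O6 carbonyls lining the channel, bases non-overlapping) and one with
    clashing bases.  The requested C1' radius therefore acts as a branch
    selector, not a free parameter; the achieved radius is ~8.2 A for a
    2.9 A H-bond with the standard base geometry.
    """
    names = list(_GUANINE_2D)
    pts = np.array([_GUANINE_2D[n] for n in names])
    i_n1, i_n2 = names.index("N1"), names.index("N2")
    i_o6, i_n7 = names.index("O6"), names.index("N7")
    i_c1 = names.index("C1'")
    r90 = _rot2(np.pi / 2)

    def residuals(p):
        g0 = pts @ _rot2(p[0]).T + p[1:]
        g1 = g0 @ r90.T
        return np.array(
            [
                np.linalg.norm(g1[i_o6] - g0[i_n1]) - HBOND_LENGTH,
                np.linalg.norm(g1[i_n7] - g0[i_n2]) - HBOND_LENGTH,
            ]
        )

    solutions: list[tuple[float, tuple[float, float, float]]] = []
    for theta0 in np.linspace(0, 2 * np.pi, 8, endpoint=False):
        centroid = pts.mean(axis=0) @ _rot2(theta0).T
        for rad0 in (3.0, 5.0, 8.0, 10.0):
            t0 = np.array([rad0, 0.0]) - centroid
            sol = least_squares(residuals, [theta0, *t0])
            if sol.cost > 1e-14:
                continue
            g0 = pts @ _rot2(sol.x[0]).T + sol.x[1:]
            g1 = g0 @ r90.T
            # reject the branch with overlapping bases: everything except
            # the two bonded donor/acceptor pairs must stay > 2.4 A apart
            d = np.linalg.norm(g0[:, None, :] - g1[None, :, :], axis=-1)
            d[i_n1, i_o6] = np.inf
            d[i_n2, i_n7] = np.inf
            if d.min() < 2.4:
                continue
            solutions.append(
                (float(np.linalg.norm(g0[i_c1])), tuple(map(float, sol.x)))
            )
    if not solutions:
        raise RuntimeError("quartet placement found no clash-free solution")
    achieved, placement = min(solutions, key=lambda s: abs(s[0] - radius))
    return placement


def _placed_base_2d(template: dict, placement: tuple[float, float, float]) -> dict:
    theta, tx, ty = placement
    rot = _rot2(theta)
    return {
        n: np.array([*(rot @ np.asarray(xy)), 0.0]) + np.array([tx, ty, 0.0])
        for n, xy in template.items()
    }


# ---------------------------------------------------------------------------
# blueprint & truth


@dataclass(frozen=True)
class StemBlueprint:
    """Construction parameters of the ideal stem."""

    n_quartets: int = 4
    rise_per_step: float = 3.4       # A
    twist_per_step: float = 30.0     # deg, positive = right-handed
    c1_radius: float = 10.0          # A
    flanking_t: bool = True
    with_ions: bool = True

    def __post_init__(self) -> None:
        if not 3 <= self.n_quartets <= 5:
            raise ValueError("n_quartets must be in 3..5")
        if self.rise_per_step <= 0:
            raise ValueError("rise per step must be positive")
        if self.c1_radius <= 4.0:
            raise ValueError("C1' radius too small to place bases")


@dataclass
class SyntheticTruth:
    """Ground-truth labels serialised alongside every generated dataset."""

    kind: str
    seed: int | None = None
    blueprint: dict = field(default_factory=dict)
    frames: dict = field(default_factory=dict)     # per-frame parameter arrays
    events: list = field(default_factory=list)     # scripted event records
    trace: dict = field(default_factory=dict)      # force-trace parameters

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(f"not JSON serialisable: {type(o)}")

        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=default)


@dataclass(frozen=True)
class ScriptedEvent:
    """One scripted unfolding event.

    ``frame`` is the frame at which the event's defining geometric
    condition is first fully realised (motion is ramped over the preceding
    frames).  ``strand`` is a 0-based strand index; ``end`` is ``"5'"`` or
    ``"3'"`` where relevant; ``edge`` ("WC"|"H") selects which H-bond edge
    of an unzipped G breaks first; ``handedness`` ("left"|"right") applies
    to spirals; ``neighbor`` ("wc"|"h") selects which neighbour an opening
    detaches from; ``outcome`` ("native"|"slipped") applies to
    spiral_resolve.
    """

    type: str
    frame: int
    strand: int = 0
    end: str = "3'"
    edge: str = "WC"
    handedness: str = "right"
    neighbor: str = "wc"
    direction: int = 1
    outcome: str = "native"


EVENT_TYPES = (
    "unzip",
    "strand_slippage",
    "opening",
    "detachment",
    "spiral_form",
    "spiral_resolve",
    "rotation_crosslike",
    "refold",
    "anchorT_unstack",
)

#: frames over which each event's motion is ramped before its scripted frame
EVENT_RAMP = {
    "unzip": 20,
    "strand_slippage": 20,
    "opening": 12,
    "detachment": 10,
    "spiral_form": 14,
    "spiral_resolve": 14,
    "rotation_crosslike": 20,
    "refold": 16,
    "anchorT_unstack": 10,
}


# ---------------------------------------------------------------------------
# ideal stem construction


def _build_atoms(
    blueprint: StemBlueprint,
    step_twists: np.ndarray | None = None,
    step_rises: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray, StemTopology]:
    """Atom table, coordinates and topology of one stem conformation.

    ``step_twists``/``step_rises`` (length n_quartets - 1) override the
    uniform blueprint values; quartet k is the base quartet rotated by the
    cumulative twist and translated by the cumulative rise.
    """
    n = blueprint.n_quartets
    tw = np.full(n - 1, blueprint.twist_per_step) if step_twists is None else step_twists
    rs = np.full(n - 1, blueprint.rise_per_step) if step_rises is None else step_rises
    cum_tw = np.concatenate([[0.0], np.cumsum(np.radians(tw))])
    cum_z = np.concatenate([[0.0], np.cumsum(rs)])

    placement = _quartet_placement(blueprint.c1_radius)
    g_base = _placed_base_2d(_GUANINE_2D, placement)
    t_base = _placed_base_2d(_THYMINE_2D, placement)

    rows: list[dict] = []
    coords: list[np.ndarray] = []
    strand_specs: list[dict] = []

    g_names = ["C1'", *GUANINE_BASE_ATOMS]
    t_names = list(_THYMINE_2D)

    for s, chain in enumerate(CHAINS):
        phi_s = np.pi / 2 * s
        resid = 1
        spec: dict = {"chain": chain, "g_residues": [], "t5": None, "t3": None}
        # 5' flanking T one step below quartet 0, continuing the helix
        if blueprint.flanking_t:
            rot = Rotation.from_euler(
                "z", phi_s - np.radians(blueprint.twist_per_step)
            )
            for name in t_names:
                rows.append(
                    {"name": name, "resname": "DT", "resid": resid, "chain": chain}
                )
                coords.append(
                    rot.apply(t_base[name])
                    + np.array([0.0, 0.0, -blueprint.rise_per_step])
                )
            spec["t5"] = resid
            resid += 1
        for k in range(n):
            rot = Rotation.from_euler("z", phi_s + cum_tw[k])
            for name in g_names:
                rows.append(
                    {"name": name, "resname": "DG", "resid": resid, "chain": chain}
                )
                coords.append(rot.apply(g_base[name]) + np.array([0, 0, cum_z[k]]))
            spec["g_residues"].append(resid)
            resid += 1
        if blueprint.flanking_t:
            rot = Rotation.from_euler(
                "z", phi_s + cum_tw[-1] + np.radians(blueprint.twist_per_step)
            )
            for name in t_names:
                rows.append(
                    {"name": name, "resname": "DT", "resid": resid, "chain": chain}
                )
                coords.append(
                    rot.apply(t_base[name])
                    + np.array([0, 0, cum_z[-1] + blueprint.rise_per_step])
                )
            spec["t3"] = resid
            resid += 1
        strand_specs.append(spec)

    if blueprint.with_ions:
        for k in range(n - 1):
            rows.append(
                {"name": "K", "resname": ION_RESNAME, "resid": k + 1, "chain": "I"}
            )
            coords.append(np.array([0.0, 0.0, 0.5 * (cum_z[k] + cum_z[k + 1])]))

    atoms = pd.DataFrame(rows)
    topology = build_topology_from_strands(strand_specs)
    return atoms, np.array(coords), topology


def build_ideal_stem(
    blueprint: StemBlueprint | None = None,
) -> tuple[Trajectory, StemTopology]:
    """Single-frame ideal stem plus its topology.

    Four symmetric strands related by 90 deg rotation about the axis;
    quartet k is rotated by k*twist and raised by k*rise; channel K+ ions
    sit midway between adjacent quartets; flanking Ts carry the pulling
    anchors and terminus labels 1-8.
    """
    blueprint = blueprint or StemBlueprint()
    atoms, coords, topology = _build_atoms(blueprint)
    traj = Trajectory(atoms=atoms, coords=coords[None], times=np.zeros(1))
    return traj, topology


# ---------------------------------------------------------------------------
# deformation trajectories


def make_deformation_traj(
    blueprint: StemBlueprint,
    n_frames: int,
    twist_schedule: np.ndarray | None = None,
    rise_schedule: np.ndarray | None = None,
    buckle: tuple[int, int, np.ndarray] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt_ns: float = 0.1,
) -> tuple[Trajectory, StemTopology, SyntheticTruth]:
    """Trajectory realising scheduled twist/rise/buckle values per frame.

    ``twist_schedule``/``rise_schedule``: per-frame scalars (shape
    (n_frames,)) or per-frame per-step arrays (shape (n_frames, n_steps)).
    ``buckle``: (quartet level, strand, per-frame angle deg) rotating that
    G's base about an in-plane axis through its base centroid.  Gaussian
    coordinate noise of ``noise_sd`` A is added with the given seed.
    """
    n_steps = blueprint.n_quartets - 1

    def expand(sched, default):
        if sched is None:
            return np.full((n_frames, n_steps), default)
        arr = np.asarray(sched, float)
        if arr.ndim == 1:
            arr = np.repeat(arr[:, None], n_steps, axis=1)
        if arr.shape != (n_frames, n_steps):
            raise ValueError("schedule shape must be (n_frames,) or (n_frames, n_steps)")
        return arr

    tw = expand(twist_schedule, blueprint.twist_per_step)
    rs = expand(rise_schedule, blueprint.rise_per_step)

    atoms, _, topology = _build_atoms(blueprint)
    rng = np.random.default_rng(seed)
    frames = []
    for f in range(n_frames):
        _, coords, _ = _build_atoms(blueprint, step_twists=tw[f], step_rises=rs[f])
        if buckle is not None:
            level, strand, angles = buckle
            ang = float(np.asarray(angles, float).reshape(n_frames)[f])
            rid = topology.strands[strand].g_residues[level]
            # rotate the base about the in-plane axis tangential to the
            # channel through the base centroid (a buckle, not a propeller)
            idx = _residue_atom_indices(atoms, rid, ["C1'", *GUANINE_BASE_ATOMS])
            base = coords[idx]
            centroid = base.mean(axis=0)
            radial = centroid - np.array([0, 0, centroid[2]])
            radial /= np.linalg.norm(radial)
            axis = np.cross([0.0, 0.0, 1.0], radial)
            rot = Rotation.from_rotvec(np.radians(ang) * axis)
            coords[idx] = rot.apply(base - centroid) + centroid
        frames.append(coords)
    arr = np.array(frames)
    if noise_sd > 0:
        arr = arr + rng.normal(0.0, noise_sd, arr.shape)
    traj = Trajectory(atoms=atoms, coords=arr, times=np.arange(n_frames) * dt_ns)
    truth = SyntheticTruth(
        kind="deformation",
        seed=seed,
        blueprint=dataclasses.asdict(blueprint),
        frames={
            "step_twist_deg": tw,
            "step_rise_A": rs,
            "noise_sd_A": noise_sd,
            "buckle": None
            if buckle is None
            else {
                "level": buckle[0],
                "strand": buckle[1],
                "angle_deg": np.asarray(buckle[2], float),
            },
        },
    )
    return traj, topology, truth


def _residue_atom_indices(atoms: pd.DataFrame, residue, names) -> np.ndarray:
    chain, resid = residue
    mask = (
        (atoms["chain"] == chain)
        & (atoms["resid"] == resid)
        & (atoms["name"].isin(list(names)))
    )
    return np.flatnonzero(mask.to_numpy())


# ---------------------------------------------------------------------------
# unfolding choreography

_UNZIP_SLIDE_A = 1.4
_UNZIP_RADIAL_A = 8.0
_OPENING_SHIFT_A = 1.6
_DETACH_SHIFT_A = 20.0
_SPIRAL_WIND_DEG = 60.0
_ANCHOR_T_SHIFT_A = 5.0


def _event_alpha(ev: ScriptedEvent, frame: int) -> float:
    ramp = EVENT_RAMP[ev.type]
    return float(np.clip((frame - (ev.frame - ramp)) / ramp, 0.0, 1.0))


class _Choreographer:
    """Applies scripted events to the native stem, frame by frame."""

    def __init__(
        self,
        blueprint: StemBlueprint,
        atoms: pd.DataFrame,
        native: np.ndarray,
        topology: StemTopology,
    ):
        self.blueprint = blueprint
        self.atoms = atoms
        self.native = native
        self.topology = topology
        self._strand_idx = [
            self._strand_atom_indices(s) for s in range(4)
        ]

    def _strand_atom_indices(self, s: int) -> np.ndarray:
        chain = self.topology.strands[s].chain
        return np.flatnonzero((self.atoms["chain"] == chain).to_numpy())

    def _g_indices(self, s: int, level: int) -> np.ndarray:
        rid = self.topology.strands[s].g_residues[level]
        return _residue_atom_indices(
            self.atoms, rid, ["C1'", *GUANINE_BASE_ATOMS]
        )

    def _named(self, coords: np.ndarray, residue, name: str) -> np.ndarray:
        idx = _residue_atom_indices(self.atoms, residue, [name])
        return coords[idx[0]]

    def validate(self, script: list[ScriptedEvent]) -> None:
        detached: set[int] = set()
        spiral_active: set[int] = set()
        last_frame = -1
        for ev in script:
            if ev.type not in EVENT_TYPES:
                raise ValueError(f"unknown event type {ev.type!r}")
            if ev.frame - EVENT_RAMP[ev.type] <= last_frame:
                raise ValueError(
                    f"event {ev.type}@{ev.frame} overlaps the previous event's ramp"
                )
            if ev.strand in detached and ev.type != "refold":
                raise ValueError(
                    f"event {ev.type}@{ev.frame} involves detached strand {ev.strand}"
                )
            if ev.type == "detachment":
                detached.add(ev.strand)
            if ev.type == "spiral_resolve" and ev.strand not in spiral_active:
                raise ValueError("spiral_resolve without a prior spiral_form")
            if ev.type == "spiral_form":
                spiral_active.add(ev.strand)
            if ev.type == "spiral_resolve":
                spiral_active.discard(ev.strand)
            if ev.type == "refold":
                detached.clear()
                spiral_active.clear()
            last_frame = ev.frame

    def frame_coords(self, script: list[ScriptedEvent], frame: int) -> np.ndarray:
        coords = self.native.copy()
        for ev in script:
            a = _event_alpha(ev, frame)
            if a <= 0.0:
                break
            coords = self._apply(ev, a, coords)
        return coords

    def _apply(self, ev: ScriptedEvent, a: float, coords: np.ndarray) -> np.ndarray:
        fn = getattr(self, f"_apply_{ev.type}")
        return fn(ev, a, coords)

    # -- individual event transforms -------------------------------------

    def _apply_unzip(self, ev, a, coords):
        s = ev.strand
        level = 0 if ev.end == "5'" else self.topology.n_quartets - 1
        rid = self.topology.strands[s].g_residues[level]
        idx = self._g_indices(s, level)
        # phase 1: slide the base along its breaking edge's H-bond
        # direction, which stretches those two bonds directly while the
        # other edge's bonds (roughly perpendicular) only lengthen as
        # sqrt(d^2 + x^2) and survive; a hinge cannot do this for the
        # Hoogsteen edge because O6 is nearly collinear with N1-N2
        if ev.edge == "WC":
            partner = self.topology.strands[(s + 1) % 4].g_residues[level]
            v1 = self._named(self.native, partner, "O6") - self._named(
                self.native, rid, "N1"
            )
            v2 = self._named(self.native, partner, "N7") - self._named(
                self.native, rid, "N2"
            )
            direction = -(v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2))
        else:
            partner = self.topology.strands[(s - 1) % 4].g_residues[level]
            v1 = self._named(self.native, rid, "O6") - self._named(
                self.native, partner, "N1"
            )
            v2 = self._named(self.native, rid, "N7") - self._named(
                self.native, partner, "N2"
            )
            direction = v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2)
        direction = direction / np.linalg.norm(direction)
        shift = _UNZIP_SLIDE_A * min(1.0, 2 * a)
        coords[idx] = coords[idx] + shift * direction
        # phase 2: radial extraction breaks the remaining edge
        if a > 0.5:
            centroid = coords[idx].mean(axis=0)
            radial = centroid - np.array([0, 0, centroid[2]])
            radial = radial / np.linalg.norm(radial)
            coords[idx] = coords[idx] + _UNZIP_RADIAL_A * (2 * a - 1) * radial
        return coords

    def _apply_strand_slippage(self, ev, a, coords):
        s, d = ev.strand, ev.direction
        idx = self._strand_idx[s]
        shift = np.array([0, 0, d * a * self.blueprint.rise_per_step])
        rot = Rotation.from_euler(
            "z", d * a * np.radians(self.blueprint.twist_per_step)
        )
        coords[idx] = rot.apply(coords[idx]) + shift
        return coords

    def _apply_opening(self, ev, a, coords):
        # each residue moves along its own level's H-bond direction on the
        # side to be broken (bond orientations rotate with the helical
        # twist, so a single space-fixed translation would break the
        # levels unevenly)
        s = ev.strand
        n = self.topology.n_quartets
        strand = self.topology.strands[s]
        dirs = []
        for level in range(n):
            rid = strand.g_residues[level]
            if ev.neighbor == "wc":
                partner = self.topology.strands[(s + 1) % 4].g_residues[level]
                v1 = self._named(self.native, partner, "O6") - self._named(
                    self.native, rid, "N1"
                )
                v2 = self._named(self.native, partner, "N7") - self._named(
                    self.native, rid, "N2"
                )
                d = -(v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2))
            else:
                partner = self.topology.strands[(s - 1) % 4].g_residues[level]
                v1 = self._named(self.native, rid, "O6") - self._named(
                    self.native, partner, "N1"
                )
                v2 = self._named(self.native, rid, "N7") - self._named(
                    self.native, partner, "N2"
                )
                d = v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2)
            dirs.append(d / np.linalg.norm(d))
            gidx = _residue_atom_indices(
                self.atoms, rid, ["C1'", *GUANINE_BASE_ATOMS]
            )
            coords[gidx] = coords[gidx] + a * _OPENING_SHIFT_A * dirs[-1]
        for t_rid, level in ((strand.t5, 0), (strand.t3, n - 1)):
            if t_rid is not None:
                tidx = _residue_atom_indices(self.atoms, t_rid, list(_THYMINE_2D))
                coords[tidx] = coords[tidx] + a * _OPENING_SHIFT_A * dirs[level]
        return coords

    def _apply_detachment(self, ev, a, coords):
        idx = self._strand_idx[ev.strand]
        centroid = coords[idx].mean(axis=0)
        radial = centroid - np.array([0, 0, centroid[2]])
        radial = radial / np.linalg.norm(radial)
        coords[idx] = coords[idx] + a * _DETACH_SHIFT_A * radial
        return coords

    def _spiral_displace(self, ev, amount, coords):
        s = ev.strand
        n = self.topology.n_quartets
        hand = 1.0 if ev.handedness == "right" else -1.0
        strand = self.topology.strands[s]
        for level in range(n):
            frac = level / (n - 1)
            idx = _residue_atom_indices(
                self.atoms, strand.g_residues[level], ["C1'", *GUANINE_BASE_ATOMS]
            )
            rot = Rotation.from_euler(
                "z", hand * amount * frac * np.radians(_SPIRAL_WIND_DEG)
            )
            coords[idx] = rot.apply(coords[idx]) + np.array(
                [0, 0, amount * frac * self.blueprint.rise_per_step]
            )
        # flanking Ts follow their terminal G
        for t_rid, frac in ((strand.t5, 0.0), (strand.t3, 1.0)):
            if t_rid is not None and frac > 0:
                idx = _residue_atom_indices(self.atoms, t_rid, list(_THYMINE_2D))
                rot = Rotation.from_euler(
                    "z", hand * amount * frac * np.radians(_SPIRAL_WIND_DEG)
                )
                coords[idx] = rot.apply(coords[idx]) + np.array(
                    [0, 0, amount * frac * self.blueprint.rise_per_step]
                )
        return coords

    def _apply_spiral_form(self, ev, a, coords):
        return self._spiral_displace(ev, a, coords)

    def _apply_spiral_resolve(self, ev, a, coords):
        # the matching spiral_form (already applied) is unwound back to
        # native or completed into a full one-level slip
        if ev.outcome == "native":
            return self._spiral_displace(ev, -a, coords)
        # "slipped" outcome: each residue moves from its partially wound
        # position (hand*frac*WIND deg, frac*rise) to the uniform one-level
        # slip (+twist deg, full rise)
        s, hand = ev.strand, (1.0 if ev.handedness == "right" else -1.0)
        n = self.topology.n_quartets
        strand = self.topology.strands[s]
        for level in range(n):
            frac = level / (n - 1)
            gidx = _residue_atom_indices(
                self.atoms, strand.g_residues[level], ["C1'", *GUANINE_BASE_ATOMS]
            )
            rot = Rotation.from_euler(
                "z",
                a
                * (
                    np.radians(self.blueprint.twist_per_step)
                    - hand * frac * np.radians(_SPIRAL_WIND_DEG)
                ),
            )
            coords[gidx] = rot.apply(coords[gidx]) + np.array(
                [0, 0, a * (1 - frac) * self.blueprint.rise_per_step]
            )
        return coords

    def _apply_rotation_crosslike(self, ev, a, coords):
        s = ev.strand
        idx = self._strand_idx[s]
        centroid = coords[idx].mean(axis=0)
        radial = centroid - np.array([0, 0, centroid[2]])
        radial = radial / np.linalg.norm(radial)
        rot = Rotation.from_rotvec(np.radians(180.0 * a) * radial)
        coords[idx] = rot.apply(coords[idx] - centroid) + centroid
        return coords

    def _apply_refold(self, ev, a, coords):
        return coords + a * (self.native - coords)

    def _apply_anchorT_unstack(self, ev, a, coords):
        strand = self.topology.strands[ev.strand]
        t_rid = strand.t5 if ev.end == "5'" else strand.t3
        if t_rid is None:
            raise ValueError(f"strand {ev.strand} has no {ev.end} flanking T")
        idx = _residue_atom_indices(self.atoms, t_rid, list(_THYMINE_2D))
        direction = -1.0 if ev.end == "5'" else 1.0
        coords[idx] = coords[idx] + np.array(
            [0, 0, direction * a * _ANCHOR_T_SHIFT_A]
        )
        return coords


def make_unfolding_traj(
    blueprint: StemBlueprint,
    script: list[ScriptedEvent],
    n_frames: int | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt_ns: float = 0.1,
) -> tuple[Trajectory, StemTopology, SyntheticTruth]:
    """Trajectory realising an ordered unfolding-event script.

    Each event's motion ramps over the frames preceding its scripted
    frame, so its geometric signature is first fully present at
    ``event.frame`` and persists afterwards.  The truth timeline is the
    script itself.
    """
    atoms, native, topology = _build_atoms(blueprint)
    script = sorted(script, key=lambda e: e.frame)
    chor = _Choreographer(blueprint, atoms, native, topology)
    chor.validate(script)
    if n_frames is None:
        n_frames = (max((e.frame for e in script), default=0)) + 60
    frames = np.array(
        [chor.frame_coords(script, f) for f in range(n_frames)]
    )
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)
    traj = Trajectory(atoms=atoms, coords=frames, times=np.arange(n_frames) * dt_ns)
    truth = SyntheticTruth(
        kind="unfolding",
        seed=seed,
        blueprint=dataclasses.asdict(blueprint),
        frames={"noise_sd_A": noise_sd, "dt_ns": dt_ns},
        events=[dataclasses.asdict(e) for e in script],
    )
    return traj, topology, truth


# ---------------------------------------------------------------------------
# ion-occupancy scripting


def make_occupancy_traj(
    blueprint: StemBlueprint,
    site_by_frame: np.ndarray,
    seed: int = 0,
    dt_ns: float = 0.1,
) -> tuple[Trajectory, StemTopology, SyntheticTruth]:
    """Static stem with ions moved according to an occupancy script.

    ``site_by_frame`` has shape (n_frames, n_ions); entry (f, i) is the
    channel-site index occupied by ion i in frame f, or -1 for "away"
    (the ion is parked 15 A off-axis).
    """
    site_by_frame = np.asarray(site_by_frame, int)
    n_frames, n_ions = site_by_frame.shape
    bp = dataclasses.replace(blueprint, with_ions=True)
    atoms, native, topology = _build_atoms(bp)
    n_sites = bp.n_quartets - 1
    if n_ions != n_sites:
        raise ValueError(f"script has {n_ions} ions, stem has {n_sites} sites")
    ion_idx = np.flatnonzero((atoms["resname"] == ION_RESNAME).to_numpy())
    frames = np.repeat(native[None], n_frames, axis=0)
    for f in range(n_frames):
        for i, site in enumerate(site_by_frame[f]):
            if site < 0:
                frames[f, ion_idx[i]] = np.array(
                    [15.0 + 3.0 * i, 0.0, 0.0]
                )
            else:
                z = (site + 0.5) * bp.rise_per_step
                frames[f, ion_idx[i]] = np.array([0.0, 0.0, z])
    traj = Trajectory(atoms=atoms, coords=frames, times=np.arange(n_frames) * dt_ns)
    truth = SyntheticTruth(
        kind="occupancy",
        seed=seed,
        blueprint=dataclasses.asdict(bp),
        frames={"site_by_frame": site_by_frame},
    )
    return traj, topology, truth


# ---------------------------------------------------------------------------
# pulling-force traces


def make_force_trace(
    schedule: PullingSchedule,
    ruptures: list[tuple[float, float]],
    t_end_ns: float,
    noise_sd_pN: float = 0.0,
    seed: int = 0,
    dt_ns: float = 0.01,
    plateau_hold_ns: float = 4.0,
    post_rupture_pN: float = 20.0,
) -> tuple[ForceSeries, SyntheticTruth]:
    """Sawtooth constant-velocity pulling trace with scripted ruptures.

    ``ruptures`` is a list of (time ns, plateau pN): the force rises
    linearly from the post-rupture baseline, holds at the plateau for
    ``plateau_hold_ns`` ending exactly at the rupture time, then drops.
    Gaussian noise is added to the force; the distance column is derived
    from the noisy force so that spring-force reconstruction from
    (time, distance, center) reproduces the stored bias exactly.
    """
    times = np.asarray([t for t, _ in ruptures], float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("rupture times must be strictly increasing")
    t = np.arange(0.0, t_end_ns + dt_ns / 2, dt_ns)
    f = np.full_like(t, post_rupture_pN)
    t_prev = 0.0
    f_prev = 0.0
    for t_r, plateau in ruptures:
        hold_start = max(t_prev, t_r - plateau_hold_ns)
        seg = (t >= t_prev) & (t < hold_start)
        denom = max(hold_start - t_prev, dt_ns)
        f[seg] = f_prev + (plateau - f_prev) * (t[seg] - t_prev) / denom
        seg = (t >= hold_start) & (t <= t_r)
        f[seg] = plateau
        t_prev = t_r
        f_prev = post_rupture_pN
    if ruptures:
        f[t > times[-1]] = post_rupture_pN
    rng = np.random.default_rng(seed)
    if noise_sd_pN > 0:
        f = f + rng.normal(0.0, noise_sd_pN, f.shape)
    center = np.asarray(schedule.center(t), float)
    distance = center - f / (schedule.force_constant * PN_PER_KJ_MOL_NM)
    series = ForceSeries(
        time_ns=t, distance_nm=distance, center_nm=center, force_pN=f
    )
    truth = SyntheticTruth(
        kind="force_trace",
        seed=seed,
        trace={
            "ruptures": [[float(a), float(b)] for a, b in ruptures],
            "noise_sd_pN": noise_sd_pN,
            "dt_ns": dt_ns,
            "plateau_hold_ns": plateau_hold_ns,
            "post_rupture_pN": post_rupture_pN,
            "force_constant": schedule.force_constant,
            "pull_speed": schedule.pull_speed,
            "d0": schedule.d0,
        },
    )
    return series, truth
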
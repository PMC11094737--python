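"""Quartet-plane geometry of a G-stem: planarity, tilt, rise, twist, axis.

Each G-quartet is summarised by the best-fit plane through the heavy atoms
of its four guanine bases, obtained by singular value decomposition of the
centred coordinates.  The third singular value gives the planarity

    P = sigma_3 / sqrt(N),

the RMSD of the atoms' signed distances from the plane.  Between adjacent
quartets we report the tilt (angle between co-oriented plane normals), the
rise (sum of the two quartet centroids' distances from the plane fitted to
the pooled atoms of both quartets) and the helical step twist (signed
rotation about the stem axis of a per-quartet reference vector, positive
for a right-handed advance 5'->3').  The total twist is the sum of step
twists; its sign is the handedness of the helix.

Units: Angstrom for distances, degrees for angles.  Normal signs from SVD
are arbitrary and are co-oriented with the 5'->3' stem axis before any
angle between planes is formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topology import GUANINE_BASE_ATOMS, StemTopology
from .trajectory import Trajectory

#: Vectors with squared norm below this are treated as degenerate.
DEGENERACY_TOL = 1e-6


class DegenerateGeometryError(ValueError):
    """Raised for rank-deficient plane fits or vanishing projections."""


@dataclass(frozen=True)
class QuartetPlane:
    """Best-fit plane of one quartet's heavy base atoms."""

    centroid: np.ndarray
    normal: np.ndarray
    singular_values: tuple[float, float, float]
    planarity: float
    n_atoms: int

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of points from the plane, along the normal."""
        return (np.atleast_2d(points) - self.centroid) @ self.normal

    def flipped(self) -> "QuartetPlane":
        return QuartetPlane(
            centroid=self.centroid,
            normal=-self.normal,
            singular_values=self.singular_values,
            planarity=self.planarity,
            n_atoms=self.n_atoms,
        )


@dataclass(frozen=True)
class StemGeometry:
    """Per-frame helical descriptors of the whole stem."""

    planes: tuple[QuartetPlane, ...]
    step_tilt: np.ndarray        # degrees, length n_quartets - 1
    step_rise: np.ndarray        # Angstrom
    step_twist: np.ndarray       # signed degrees
    axis: np.ndarray             # unit vector, 5'->3'

    @property
    def total_twist(self) -> float:
        return float(self.step_twist.sum())

    @property
    def handedness(self) -> int:
        """+1 for a right-handed helix, -1 for left-handed, 0 for untwisted."""
        return int(np.sign(self.total_twist))

    @property
    def planarity(self) -> np.ndarray:
        return np.array([p.planarity for p in self.planes])


def fit_quartet_plane(atom_coords: np.ndarray, label: str = "quartet") -> QuartetPlane:
    """Fit a plane to atom coordinates by SVD.

    The plane passes through the centroid; the normal is the direction of
    smallest variance.  Planarity is ``sigma_3 / sqrt(N)``, identical to the
    RMSD of the signed point-plane distances.

    Raises
    ------
    DegenerateGeometryError
        For fewer than 3 points, non-finite input, or (near-)collinear
        configurations where the plane is not unique.
    """
    pts = np.asarray(atom_coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise DegenerateGeometryError(f"{label}: expected (N, 3) coordinates")
    n = pts.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"{label}: plane fit needs >=3 points, got {n}")
    if not np.isfinite(pts).all():
        raise DegenerateGeometryError(f"{label}: non-finite coordinates")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    # SVD of the centred coordinates; right singular vectors are the
    # principal directions, the last one the plane normal.
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < DEGENERACY_TOL:
        raise DegenerateGeometryError(f"{label}: collinear points, plane undefined")
    normal = vt[2] / np.linalg.norm(vt[2])
    return QuartetPlane(
        centroid=centroid,
        normal=normal,
        singular_values=(float(s[0]), float(s[1]), float(s[2])),
        planarity=float(s[2] / np.sqrt(n)),
        n_atoms=n,
    )


def planarity(plane: QuartetPlane) -> float:
    """RMSD of the fitted atoms about the best-fit plane (Angstrom)."""
    return plane.planarity


def tilt(plane_a: QuartetPlane, plane_b: QuartetPlane) -> float:
    """Angle in degrees between two plane normals, in [0, 180].

    The caller is responsible for co-orienting the normals along the stem
    (see :func:`co_orient_planes`); for co-oriented native quartets the
    tilt is near 0.
    """
    d = float(np.clip(np.dot(plane_a.normal, plane_b.normal), -1.0, 1.0))
    return float(np.degrees(np.arccos(d)))


def rise(
    quartet_a_atoms: np.ndarray,
    quartet_b_atoms: np.ndarray,
    method: str = "pooled",
) -> float:
    """Rise between two adjacent quartets (Angstrom, unsigned).

    ``method="pooled"`` (default) fits one plane to the pooled heavy base
    atoms of both quartets and returns the sum of the two quartet
    centroids' unsigned distances from it.  ``method="bisector"`` instead
    uses the plane through the mid-centroid whose normal bisects the two
    individual co-oriented quartet normals.
    """
    a = np.asarray(quartet_a_atoms, dtype=float)
    b = np.asarray(quartet_b_atoms, dtype=float)
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    if method == "pooled":
        plane = fit_quartet_plane(np.vstack([a, b]), label="pooled quartet pair")
        normal, origin = plane.normal, plane.centroid
    elif method == "bisector":
        pa = fit_quartet_plane(a, label="quartet a")
        pb = fit_quartet_plane(b, label="quartet b")
        nb = pb.normal if np.dot(pa.normal, pb.normal) >= 0 else -pb.normal
        normal = pa.normal + nb
        norm = np.linalg.norm(normal)
        if norm < DEGENERACY_TOL:
            raise DegenerateGeometryError("bisector normal vanishes")
        normal = normal / norm
        origin = 0.5 * (ca + cb)
    else:
        raise ValueError(f"unknown rise method {method!r}")
    return float(abs((ca - origin) @ normal) + abs((cb - origin) @ normal))


def stem_axis(centroids: np.ndarray) -> np.ndarray:
    """Best-fit line direction through quartet centroids, oriented 5'->3'.

    For two quartets this reduces to the normalised centroid difference.
    """
    c = np.asarray(centroids, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise DegenerateGeometryError("stem axis needs >=2 quartet centroids")
    centred = c - c.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[0] < DEGENERACY_TOL:
        raise DegenerateGeometryError("coincident centroids, stem axis undefined")
    axis = vt[0] / np.linalg.norm(vt[0])
    # orient from the 5' quartet towards the 3' quartet
    if np.dot(axis, c[-1] - c[0]) < 0:
        axis = -axis
    return axis


def co_orient_planes(
    planes: list[QuartetPlane], axis: np.ndarray
) -> list[QuartetPlane]:
    """Flip plane normals where needed so all have positive dot with axis."""
    return [p if np.dot(p.normal, axis) >= 0 else p.flipped() for p in planes]


def step_twist(
    ref_a: np.ndarray,
    centroid_a: np.ndarray,
    ref_b: np.ndarray,
    centroid_b: np.ndarray,
    axis: np.ndarray,
) -> float:
    """Signed helical rotation (degrees) from quartet a to quartet b.

    The per-quartet reference vectors (centroid -> reference atom) are
    projected onto the plane orthogonal to the 5'->3' axis; the returned
    angle is positive for a right-handed rotation advancing 5'->3' and
    lies in (-180, 180].
    """
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    va = np.asarray(ref_a, float) - np.asarray(centroid_a, float)
    vb = np.asarray(ref_b, float) - np.asarray(centroid_b, float)
    va = va - np.dot(va, axis) * axis
    vb = vb - np.dot(vb, axis) * axis
    if np.linalg.norm(va) < DEGENERACY_TOL or np.linalg.norm(vb) < DEGENERACY_TOL:
        raise DegenerateGeometryError(
            "twist reference vector nearly parallel to the stem axis"
        )
    ang = np.degrees(
        np.arctan2(np.dot(axis, np.cross(va, vb)), np.dot(va, vb))
    )
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def step_twist_matched(
    atoms_a: np.ndarray,
    atoms_b: np.ndarray,
    centroid_a: np.ndarray,
    centroid_b: np.ndarray,
    axis: np.ndarray,
) -> float:
    """Step twist from all matched atom pairs of two quartets (degrees).

    ``atoms_a``/``atoms_b`` must list the same atoms in the same order
    (same strand, same atom name, adjacent levels).  Each pair contributes
    its projected rotation about the axis; the estimate is the angle of
    the summed cross/dot products, which averages out isotropic coordinate
    noise and is exact for a rigid helical step.
    """
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    va = np.asarray(atoms_a, float) - np.asarray(centroid_a, float)
    vb = np.asarray(atoms_b, float) - np.asarray(centroid_b, float)
    va = va - np.outer(va @ axis, axis)
    vb = vb - np.outer(vb @ axis, axis)
    num = float(np.sum(np.cross(va, vb) @ axis))
    den = float(np.sum(np.einsum("ij,ij->i", va, vb)))
    if abs(num) < DEGENERACY_TOL and abs(den) < DEGENERACY_TOL:
        raise DegenerateGeometryError(
            "all twist reference vectors nearly parallel to the stem axis"
        )
    ang = float(np.degrees(np.arctan2(num, den)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def total_twist(geometry: StemGeometry) -> float:
    """Sum of step twists (signed degrees); the sign is the handedness."""
    return geometry.total_twist


# ---------------------------------------------------------------------------
# frame-level assembly


def _quartet_atoms(
    traj: Trajectory, frame: int, topology: StemTopology, level: int
) -> np.ndarray:
    coords = [
        traj.residue_coords(frame, rid, GUANINE_BASE_ATOMS)
        for rid in topology.quartets[level]
    ]
    return np.vstack(coords)


def frame_stem_geometry(
    traj: Trajectory,
    frame: int,
    topology: StemTopology,
    rise_method: str = "pooled",
    twist_method: str = "matched",
    twist_reference_atom: str = "N9",
    twist_reference_strand: int = 0,
) -> StemGeometry:
    """Compute all helical descriptors of the stem for one frame.

    ``twist_method="matched"`` (default) estimates each step twist from
    all strand-matched base-atom pairs of the two quartets, which is exact
    for rigid helical steps and robust to coordinate noise;
    ``"reference_atom"`` uses the single centroid->N9 vector of one
    strand's G per quartet.
    """
    n = topology.n_quartets
    pooled = [_quartet_atoms(traj, frame, topology, k) for k in range(n)]
    planes = [
        fit_quartet_plane(pooled[k], label=f"quartet {k}") for k in range(n)
    ]
    centroids = np.array([p.centroid for p in planes])
    axis = stem_axis(centroids)
    planes = co_orient_planes(planes, axis)
    step_tilt = np.array([tilt(planes[k], planes[k + 1]) for k in range(n - 1)])
    step_rise = np.array(
        [rise(pooled[k], pooled[k + 1], method=rise_method) for k in range(n - 1)]
    )
    if twist_method == "matched":
        twists = np.array(
            [
                step_twist_matched(
                    pooled[k], pooled[k + 1], centroids[k], centroids[k + 1], axis
                )
                for k in range(n - 1)
            ]
        )
    elif twist_method == "reference_atom":
        refs = np.array(
            [
                traj.residue_coords(
                    frame,
                    topology.strands[twist_reference_strand].g_residues[k],
                    (twist_reference_atom,),
                )[0]
                for k in range(n)
            ]
        )
        twists = np.array(
            [
                step_twist(refs[k], centroids[k], refs[k + 1], centroids[k + 1], axis)
                for k in range(n - 1)
            ]
        )
    else:
        raise ValueError(f"unknown twist method {twist_method!r}")
    return StemGeometry(
        planes=tuple(planes),
        step_tilt=step_tilt,
        step_rise=step_rise,
        step_twist=twists,
        axis=axis,
    )


def geometry_table(
    traj: Trajectory,
    topology: StemTopology,
    rise_method: str = "pooled",
) -> pd.DataFrame:
    """Per-frame, per-quartet geometry table.

    One row per (frame, quartet level).  Step metrics (tilt, rise,
    step_twist) describe the step from level ``index - 1`` to ``index`` and
    are NaN at level 0; total twist and handedness are repeated per frame.
    """
    rows = []
    for f in range(traj.n_frames):
        geo = frame_stem_geometry(traj, f, topology, rise_method=rise_method)
        for q in range(topology.n_quartets):
            rows.append(
                {
                    "frame": f,
                    "time_ns": traj.times[f],
                    "index": q,
                    "planarity_A": geo.planes[q].planarity,
                    "tilt_deg": geo.step_tilt[q - 1] if q > 0 else np.nan,
                    "rise_A": geo.step_rise[q - 1] if q > 0 else np.nan,
                    "step_twist_deg": geo.step_twist[q - 1] if q > 0 else np.nan,
                    "total_twist_deg": geo.total_twist,
                    "handedness": geo.handedness,
                }
            )
    return pd.DataFrame(rows)
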
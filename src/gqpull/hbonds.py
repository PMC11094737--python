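"""Quartet H-bond state tracking and strand register (slippage) offsets.

In a native parallel G-quartet each guanine donates two H-bonds from its
Watson-Crick edge (N1-H...O6 and N2-H...N7) to the next strand around the
channel and accepts two on its Hoogsteen edge from the previous strand:
8 bonds per quartet.  Here the donor-acceptor pairing is evaluated not
only at the native level but across all level combinations of adjacent
strand pairs, which is what makes register shifts (strand slippage, the
slip-stranded GQ) directly observable as a change in the partner-level
offset.

Criteria: a bond is present iff the donor-acceptor distance is at or
below the cutoff (3.5 A default) and, when the donor hydrogens exist in
the topology, the donor-H-acceptor angle is at or above 135 deg.  For
hydrogen-free topologies a distance-only criterion with a slightly
tighter 3.4 A cutoff is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import StemTopology
from .trajectory import Trajectory

#: (donor atom on the G, acceptor atom on its WC-side partner)
BOND_ATOMS = (("N1", "O6"), ("N2", "N7"))
#: hydrogens attached to each donor, when present
DONOR_HYDROGENS = {"N1": ("H1",), "N2": ("H21", "H22")}

DEFAULT_D_CUT = 3.5          # A, with hydrogens
DEFAULT_D_CUT_NO_H = 3.4     # A, distance-only mode
DEFAULT_ANGLE_CUT = 135.0    # deg, donor-H-acceptor


@dataclass
class HBondSeries:
    """Per-frame inter-strand H-bond state of the whole stem.

    ``present[f, s, j, j2, b]`` is True when in frame ``f`` the guanine of
    donor strand ``s`` at native level ``j`` donates bond ``b`` (0: N1->O6,
    1: N2->N7) to the guanine of strand ``(s+1) % 4`` at native level
    ``j2``.  ``distance`` holds the corresponding donor-acceptor distances
    in Angstrom.
    """

    present: np.ndarray
    distance: np.ndarray
    times: np.ndarray
    used_hydrogens: bool

    @property
    def n_frames(self) -> int:
        return self.present.shape[0]

    @property
    def n_levels(self) -> int:
        return self.present.shape[2]

    # -- convenience views -------------------------------------------------

    def native(self) -> np.ndarray:
        """Native-register bonds: shape (n_frames, 4, n_levels, 2)."""
        j = np.arange(self.n_levels)
        return self.present[:, :, j, j, :]

    def quartet_bond_count(self, frame: int, level: int) -> int:
        return int(self.present[frame, :, level, level, :].sum())

    def native_complete(self) -> np.ndarray:
        """Per frame: True when all 8 * n_quartets native bonds are present."""
        return self.native().reshape(self.n_frames, -1).all(axis=1)

    def g_donated(self, frame: int, strand: int, level: int) -> np.ndarray:
        """This G's WC-edge (donated) bonds, any register: shape (n_levels, 2)."""
        return self.present[frame, strand, level]

    def g_accepted(self, frame: int, strand: int, level: int) -> np.ndarray:
        """This G's Hoogsteen-edge (accepted) bonds: shape (n_levels, 2)."""
        return self.present[frame, (strand - 1) % 4, :, level, :]

    def g_bonded(self, frame: int, strand: int, level: int) -> bool:
        return bool(
            self.g_donated(frame, strand, level).any()
            or self.g_accepted(frame, strand, level).any()
        )

    def strand_bond_count(self, frame: int, strand: int) -> int:
        """All bonds the strand participates in (donated + accepted)."""
        return int(
            self.present[frame, strand].sum()
            + self.present[frame, (strand - 1) % 4].sum()
        )

    def strand_levels_bonded(self, frame: int, strand: int, side: str) -> int:
        """Number of this strand's levels with >=1 bond on the given side.

        ``side="wc"``: bonds donated to strand+1; ``side="h"``: bonds
        accepted from strand-1.
        """
        if side == "wc":
            per_level = self.present[frame, strand].any(axis=(1, 2))
        elif side == "h":
            per_level = self.present[frame, (strand - 1) % 4].any(axis=(0, 2))
        else:
            raise ValueError(f"side must be 'wc' or 'h', got {side!r}")
        return int(per_level.sum())


def compute_hbond_series(
    traj: Trajectory,
    topology: StemTopology,
    d_cut: float = DEFAULT_D_CUT,
    angle_cut: float = DEFAULT_ANGLE_CUT,
    d_cut_no_h: float = DEFAULT_D_CUT_NO_H,
) -> HBondSeries:
    """Evaluate all inter-strand G-G H-bonds for every frame.

    The cutoffs are inclusive (a bond exactly at the cutoff counts as
    present).  Hydrogens are used automatically when every donor hydrogen
    is resolvable from the atom table; otherwise the distance-only
    criterion applies.
    """
    n = topology.n_quartets

    def indices(names):
        out = np.empty((4, n, len(names)), dtype=int)
        for s, level, rid in topology.iter_guanines():
            try:
                out[s, level] = traj.atom_indices(rid, names)
            except KeyError as exc:
                raise KeyError(f"H-bond atom missing for G {rid}: {exc}") from exc
        return out

    donor_idx = indices([b[0] for b in BOND_ATOMS])       # (4, n, 2)
    acceptor_idx = indices([b[1] for b in BOND_ATOMS])

    use_h = True
    h_idx: dict[int, np.ndarray] = {}
    try:
        for b, (donor, _) in enumerate(BOND_ATOMS):
            h_idx[b] = indices(DONOR_HYDROGENS[donor])
    except KeyError:
        use_h = False

    nf = traj.n_frames
    present = np.zeros((nf, 4, n, n, 2), dtype=bool)
    distance = np.zeros((nf, 4, n, n, 2), dtype=float)
    cut = d_cut if use_h else d_cut_no_h

    for f in range(nf):
        xyz = traj.coords[f]
        for s in range(4):
            dpos = xyz[donor_idx[s]]                       # (n, 2, 3)
            apos = xyz[acceptor_idx[(s + 1) % 4]]          # (n, 2, 3)
            diff = apos[None, :, :, :] - dpos[:, None, :, :]
            dist = np.linalg.norm(diff, axis=-1)           # (j, j2, 2)
            ok = dist <= cut
            if use_h:
                for b in range(2):
                    hpos = xyz[h_idx[b][s]]                # (n, n_h, 3)
                    # donor-H-acceptor angle, best hydrogen
                    dh = hpos - dpos[:, None, b, :]        # (j, n_h, 3)
                    ha = (
                        apos[None, :, None, b, :]
                        - hpos[:, None, :, :]
                    )                                      # (j, j2, n_h, 3)
                    dh_u = dh / np.linalg.norm(dh, axis=-1, keepdims=True)
                    ha_u = ha / np.linalg.norm(ha, axis=-1, keepdims=True)
                    cosang = np.einsum(
                        "jhx,jkhx->jkh", dh_u, ha_u
                    )
                    ang = np.degrees(np.arccos(np.clip(-cosang, -1, 1)))
                    # angle(donor-H, H-acceptor): 180 - included angle;
                    # take the best hydrogen per (j, j2)
                    best = (180.0 - ang).max(axis=-1)
                    ok[:, :, b] &= best >= angle_cut
            present[f, s] = ok
            distance[f, s] = dist
    return HBondSeries(
        present=present, distance=distance, times=traj.times, used_hydrogens=use_h
    )


# ---------------------------------------------------------------------------
# register offsets


def _mode(values: list[int]) -> float:
    """Modal value; ties broken toward 0, then toward the negative offset."""
    if not values:
        return float("nan")
    uniq, counts = np.unique(values, return_counts=True)
    best = counts.max()
    cands = sorted(uniq[counts == best], key=lambda v: (abs(v), v))
    return float(cands[0])


def register_offsets(
    series: HBondSeries, frame: int
) -> tuple[np.ndarray, np.ndarray]:
    """H-bond register offsets versus the native quartet assignment.

    Returns ``(per_strand, per_residue)``: per-residue offsets (4, n) are
    the modal partner-level shift of each G's bonds (donated and
    accepted), NaN where the G has no inter-strand bond; per-strand
    offsets are the modal defined per-residue value, NaN for a strand with
    no bonds at all (a detachment candidate).  A native frame gives all
    zeros; a strand slipped one level toward the 3' end gives +1.
    """
    n = series.n_levels
    per_res = np.full((4, n), np.nan)
    for s in range(4):
        for j in range(n):
            offs: list[int] = []
            donated = series.g_donated(frame, s, j)
            accepted = series.g_accepted(frame, s, j)
            for j2 in range(n):
                offs += [j2 - j] * int(donated[j2].sum())
                offs += [j2 - j] * int(accepted[j2].sum())
            per_res[s, j] = _mode(offs)
    per_strand = np.array(
        [
            _mode([int(v) for v in per_res[s] if np.isfinite(v)])
            for s in range(4)
        ]
    )
    return per_strand, per_res


def register_matrix(series: HBondSeries) -> tuple[np.ndarray, np.ndarray]:
    """Register offsets for every frame.

    Returns ``(per_strand, per_residue)`` arrays of shapes (n_frames, 4)
    and (n_frames, 4, n_levels).
    """
    per_strand = np.empty((series.n_frames, 4))
    per_res = np.empty((series.n_frames, 4, series.n_levels))
    for f in range(series.n_frames):
        per_strand[f], per_res[f] = register_offsets(series, f)
    return per_strand, per_res
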
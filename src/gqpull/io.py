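"""File formats: structures/trajectories (via MDAnalysis), pulling tables,
topology auto-detection and run configuration.

Coordinates are Angstrom internally; pulling distances follow the COLVAR
convention (nm) and are converted on read; forces in bias columns are
kJ mol^-1 nm^-1 and become pN internally.  Output tables state their units
in the column names.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

from .forces import PN_PER_KJ_MOL_NM, ForceSeries, PullingSchedule, spring_force
from .topology import StemTopology, build_topology_from_strands
from .trajectory import Trajectory

GUANINE_RESNAMES = {"DG", "G", "GUA", "DG5", "DG3"}
THYMINE_RESNAMES = {"DT", "T", "THY", "DT5", "DT3"}


class FormatError(ValueError):
    """Unreadable or inconsistent input file."""


# ---------------------------------------------------------------------------
# structures & trajectories


def read_structure_and_traj(
    topology_path: str,
    trajectory_path: str | None = None,
    dt_ns: float | None = None,
) -> Trajectory:
    """Load a PDB topology plus optional DCD/XTC/multi-model-PDB frames.

    Times are taken from the trajectory metadata (ps, converted to ns)
    unless ``dt_ns`` is given, which then defines uniform frame spacing.
    Residue numbering and chain/segment identifiers are preserved.
    """
    try:
        if trajectory_path is None:
            u = mda.Universe(topology_path)
        else:
            u = mda.Universe(topology_path, trajectory_path)
    except Exception as exc:  # MDAnalysis raises many concrete types
        raise FormatError(
            f"cannot read {topology_path}"
            + (f" with {trajectory_path}" if trajectory_path else "")
            + f": {exc}"
        ) from exc
    atoms = _atom_table(u)
    coords = []
    times = []
    for i, ts in enumerate(u.trajectory):
        coords.append(ts.positions.copy())
        times.append(i * dt_ns if dt_ns is not None else ts.time / 1000.0)
    return Trajectory(
        atoms=atoms, coords=np.array(coords), times=np.array(times, float)
    )


def _atom_table(u: "mda.Universe") -> pd.DataFrame:
    ag = u.atoms
    chains = None
    for attr in ("chainIDs", "segids"):
        if hasattr(ag, attr):
            vals = [str(c).strip() for c in getattr(ag, attr)]
            if any(vals):
                chains = vals
                break
    if chains is None:
        chains = [""] * len(ag)
    return pd.DataFrame(
        {
            "name": [str(n) for n in ag.names],
            "resname": [str(r) for r in ag.resnames],
            "resid": [int(r) for r in ag.resids],
            "chain": chains,
        }
    )


def write_trajectory_pdb(traj: Trajectory, path: str) -> None:
    """Write all frames as a multi-model PDB."""
    n_atoms = traj.n_atoms
    res_keys = list(
        dict.fromkeys(zip(traj.atoms["chain"], traj.atoms["resid"]))
    )
    res_index = {k: i for i, k in enumerate(res_keys)}
    atom_resindex = np.array(
        [
            res_index[(c, r)]
            for c, r in zip(traj.atoms["chain"], traj.atoms["resid"])
        ]
    )
    seg_keys = list(dict.fromkeys(traj.atoms["chain"]))
    seg_index = {k: i for i, k in enumerate(seg_keys)}
    res_seg = np.array([seg_index[k[0]] for k in res_keys])
    u = mda.Universe.empty(
        n_atoms,
        n_residues=len(res_keys),
        n_segments=len(seg_keys),
        atom_resindex=atom_resindex,
        residue_segindex=res_seg,
        trajectory=True,
    )
    u.add_TopologyAttr("names", traj.atoms["name"].tolist())
    u.add_TopologyAttr(
        "resnames",
        [
            traj.atoms.loc[atom_resindex == i, "resname"].iloc[0]
            for i in range(len(res_keys))
        ],
    )
    u.add_TopologyAttr("resids", [int(r) for _, r in res_keys])
    u.add_TopologyAttr("segids", [str(k) for k in seg_keys])
    u.add_TopologyAttr(
        "chainIDs",
        [str(c)[:1] if str(c) else "X" for c in traj.atoms["chain"]],
    )
    u.load_new(traj.coords.astype(np.float64), format=MemoryReader)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, n_atoms, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# stem-topology auto-detection


def detect_topology(atoms: pd.DataFrame) -> StemTopology:
    """Build a :class:`StemTopology` from residue names and numbering.

    Expects four chains, each with one contiguous G-tract of equal length
    and optional flanking Ts; quartets are formed level-by-level (k-th G
    of every strand), strand order follows chain order, and termini are
    labelled 1-8 (5' ends 1-4, 3' ends 5-8).
    """
    chains = [c for c in dict.fromkeys(atoms["chain"]) if _is_nucleic(atoms, c)]
    if len(chains) != 4:
        raise FormatError(
            f"expected 4 nucleic-acid strands, found {len(chains)}; provide "
            "an explicit topology file"
        )
    specs = []
    lengths = set()
    for chain in chains:
        sub = atoms[atoms["chain"] == chain]
        residues = (
            sub[["resid", "resname"]]
            .drop_duplicates()
            .sort_values("resid")
            .to_numpy()
        )
        gs = [int(r) for r, name in residues if name in GUANINE_RESNAMES]
        ts = [int(r) for r, name in residues if name in THYMINE_RESNAMES]
        if not gs:
            raise FormatError(f"chain {chain} has no guanines")
        if gs != list(range(gs[0], gs[0] + len(gs))):
            raise FormatError(
                f"chain {chain}: G-tract is not contiguous; provide an "
                "explicit topology file"
            )
        lengths.add(len(gs))
        t5 = max((t for t in ts if t < gs[0]), default=None)
        t3 = min((t for t in ts if t > gs[-1]), default=None)
        specs.append({"chain": chain, "g_residues": gs, "t5": t5, "t3": t3})
    if len(lengths) != 1:
        raise FormatError(
            f"unequal G-tract lengths {sorted(lengths)}; provide an explicit "
            "topology file"
        )
    return build_topology_from_strands(specs)


def _is_nucleic(atoms: pd.DataFrame, chain: str) -> bool:
    names = set(atoms.loc[atoms["chain"] == chain, "resname"])
    return bool(names & (GUANINE_RESNAMES | THYMINE_RESNAMES))


# ---------------------------------------------------------------------------
# COLVAR-style pulling tables


COLVAR_FIELDS = ("time", "distance", "center", "bias")


def write_pull_series(series: ForceSeries, path: str) -> None:
    """Write a COLVAR-style table (time ns, distance nm, center nm, bias
    force kJ mol^-1 nm^-1)."""
    with open(path, "w") as fh:
        fh.write("#! FIELDS time distance center bias\n")
        bias = series.force_pN / PN_PER_KJ_MOL_NM
        for t, d, c, b in zip(
            series.time_ns, series.distance_nm, series.center_nm, bias
        ):
            fh.write(f" {t:.6f} {d:.9f} {c:.9f} {b:.9f}\n")


def read_pull_series(
    path: str, schedule: PullingSchedule | None = None
) -> ForceSeries:
    """Parse a COLVAR-style whitespace table with a ``#! FIELDS`` header.

    Columns ``time`` (ns) and ``distance`` (nm) are mandatory.  A missing
    ``bias`` column (kJ mol^-1 nm^-1) is reconstructed from the schedule
    via the spring force, with a warning; a missing ``center`` column is
    filled from the schedule.  Restart-duplicated time blocks are
    deduplicated keeping the later block.
    """
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("#!"):
        raise FormatError(f"{path}: missing '#! FIELDS' header line")
    fields = header.split()[2:]
    if "time" not in fields or "distance" not in fields:
        raise FormatError(
            f"{path}: mandatory columns time/distance missing from {fields}"
        )
    df = pd.read_csv(path, sep=r"\s+", comment="#", names=fields, header=None)
    # restart deduplication: keep the later block wherever time rewinds
    keep: list[int] = []
    for i, t in enumerate(df["time"].to_numpy()):
        while keep and df["time"].iloc[keep[-1]] >= t:
            keep.pop()
        keep.append(i)
    df = df.iloc[keep]
    t = df["time"].to_numpy(float)
    d = df["distance"].to_numpy(float)
    if "center" in fields:
        c = df["center"].to_numpy(float)
    elif schedule is not None:
        c = np.asarray(schedule.center(t), float)
    else:
        raise FormatError(
            f"{path}: no 'center' column and no pulling schedule given"
        )
    if "bias" in fields:
        f_pn = df["bias"].to_numpy(float) * PN_PER_KJ_MOL_NM
    elif schedule is not None:
        warnings.warn(
            f"{path}: no 'bias' column; reconstructing the spring force "
            "from the schedule",
            stacklevel=2,
        )
        f_pn = spring_force(t, d, schedule).force_pN
    else:
        raise FormatError(
            f"{path}: no 'bias' column and no pulling schedule given"
        )
    return ForceSeries(
        time_ns=t, distance_nm=d, center_nm=c, force_pN=f_pn
    )


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Serialisable configuration of one analysis run."""

    topology: str | None = None
    trajectory: str | None = None
    pull_series: str | None = None
    dt_ns: float | None = None
    seed: int = 0
    output_dir: str = "."
    force_constant: float = 180.0      # kJ mol^-1 nm^-2
    pull_speed: float = 5.4            # nm us^-1
    d0_nm: float = 0.0
    classifier: dict = field(default_factory=dict)
    units: dict = field(
        default_factory=lambda: {
            "length": "A",
            "pull_distance": "nm",
            "force": "pN",
            "time": "ns",
            "angle": "deg",
        }
    )

    def schedule(self) -> PullingSchedule:
        return PullingSchedule(
            force_constant=self.force_constant,
            pull_speed=self.pull_speed,
            d0=self.d0_nm,
        )

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
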
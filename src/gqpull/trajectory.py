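"""Lightweight in-memory trajectory container.

Coordinates are stored as a dense ``(n_frames, n_atoms, 3)`` array in
Angstrom with per-frame times in nanoseconds, alongside a pandas atom table
(name, resname, resid, chain).  File-format concerns (PDB/DCD/XTC via
MDAnalysis) live in :mod:`gqpull.io`; everything downstream works on this
container only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .topology import ResidueId

ATOM_COLUMNS = ("name", "resname", "resid", "chain")


@dataclass
class Trajectory:
    """Atom table plus coordinates for one or more frames.

    ``atoms`` must contain the columns ``name``, ``resname``, ``resid``
    (int), ``chain`` (str).  ``coords`` has shape (n_frames, n_atoms, 3) in
    Angstrom; ``times`` has shape (n_frames,) in nanoseconds.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    times: np.ndarray
    _index: dict[tuple[str, int, str], int] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        self.times = np.asarray(self.times, dtype=float)
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table missing columns: {missing}")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coordinate array has {self.coords.shape[1]} atoms but the "
                f"atom table has {len(self.atoms)}"
            )
        if len(self.times) != self.n_frames:
            raise ValueError("times length does not match frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def _build_index(self) -> None:
        names = self.atoms["name"].to_numpy()
        resids = self.atoms["resid"].to_numpy()
        chains = self.atoms["chain"].to_numpy()
        self._index = {
            (str(c), int(r), str(n)): i
            for i, (c, r, n) in enumerate(zip(chains, resids, names))
        }

    def atom_indices(
        self, residue: ResidueId, names: tuple[str, ...] | list[str]
    ) -> np.ndarray:
        """Indices of named atoms of a residue; raises if any are missing."""
        if not self._index:
            self._build_index()
        chain, resid = residue
        out = []
        for n in names:
            key = (str(chain), int(resid), n)
            if key not in self._index:
                raise KeyError(
                    f"atom {n} of residue {chain}:{resid} not found in topology"
                )
            out.append(self._index[key])
        return np.asarray(out, dtype=int)

    def residue_coords(
        self, frame: int, residue: ResidueId, names: tuple[str, ...] | list[str]
    ) -> np.ndarray:
        """Coordinates (len(names), 3) of a residue's named atoms in a frame."""
        return self.coords[frame, self.atom_indices(residue, names)]

    def select(self, mask: np.ndarray) -> "Trajectory":
        """Sub-trajectory containing only atoms where ``mask`` is True."""
        atoms = self.atoms.loc[np.asarray(mask)].reset_index(drop=True)
        return Trajectory(
            atoms=atoms, coords=self.coords[:, np.asarray(mask)], times=self.times
        )
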
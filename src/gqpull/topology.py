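"""Stem topology: strands, quartets and terminus labeling of a tetrameric GQ.

A tetramolecular parallel G-quadruplex (GQ) is described here by four
strands, each contributing one guanine per quartet, stacked 5'->3'.  Every
analysis in the package is phrased relative to a :class:`StemTopology`: it
fixes which residues form each quartet (level 0 = 5'-most), the cyclic
strand order around the channel, the flanking thymines whose C2/C4/C6
geometric centers serve as pulling anchors, and the 1-8 indexing of strand
ends used to name pulling setups (e.g. ``4Q^1-8``).

Terminus convention: the 5' end of strand *s* (1-based) is terminus ``s``,
its 3' end is terminus ``s + 4``; hence 1-6/1-7/1-8 pulls act between the
5' end of strand 1 and the 3' end of strands 2/3/4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

#: A residue is identified by (chain/segment id, residue number).
ResidueId = tuple[str, int]

# Heavy atoms of the guanine base (no sugar, no phosphate, no hydrogens).
GUANINE_BASE_ATOMS = (
    "N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4",
)

# Ring atoms of the thymine base; C2/C4/C6 define the pulling anchor.
THYMINE_BASE_ATOMS = ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6")
ANCHOR_ATOM_NAMES = ("C2", "C4", "C6")


class TopologyError(ValueError):
    """Raised when a stem topology cannot be built or is inconsistent."""


@dataclass(frozen=True)
class Strand:
    """One GQ strand: its guanines 5'->3' and optional flanking thymines."""

    chain: str
    g_residues: tuple[ResidueId, ...]
    t5: ResidueId | None = None
    t3: ResidueId | None = None

    @property
    def n_levels(self) -> int:
        return len(self.g_residues)


@dataclass(frozen=True)
class StemTopology:
    """Frame of reference for all GQ analyses.

    Parameters
    ----------
    strands
        Four strand records in fixed cyclic order around the channel
        (strand ``s`` donates its Watson-Crick edge H-bonds to strand
        ``(s + 1) mod 4``).
    quartets
        One 4-tuple of G residues per level, 5'->3', element ``s`` taken
        from ``strands[s]``.
    anchor_atoms
        Mapping terminus index (1-8) -> tuple of (ResidueId, atom name)
        for the three anchor atoms (C2/C4/C6 of the terminal T), present
        only for termini that carry a flanking T.
    """

    strands: tuple[Strand, Strand, Strand, Strand]
    quartets: tuple[tuple[ResidueId, ResidueId, ResidueId, ResidueId], ...]
    anchor_atoms: dict[int, tuple[tuple[ResidueId, str], ...]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if len(self.strands) != 4:
            raise TopologyError(f"expected 4 strands, got {len(self.strands)}")
        n = self.n_quartets
        for s in self.strands:
            if s.n_levels != n:
                raise TopologyError(
                    f"strand {s.chain} has {s.n_levels} Gs, expected {n}"
                )
        seen: set[ResidueId] = set()
        for level, quartet in enumerate(self.quartets):
            if len(quartet) != 4:
                raise TopologyError(f"quartet {level} does not have 4 residues")
            for s, rid in enumerate(quartet):
                if rid != self.strands[s].g_residues[level]:
                    raise TopologyError(
                        f"quartet {level} slot {s} ({rid}) does not match "
                        f"strand {self.strands[s].chain} level {level}"
                    )
                if rid in seen:
                    raise TopologyError(f"residue {rid} in more than one quartet")
                seen.add(rid)
        bad = [t for t in self.anchor_atoms if t not in range(1, 9)]
        if bad:
            raise TopologyError(f"anchor terminus indices out of 1-8: {bad}")

    @property
    def n_quartets(self) -> int:
        return len(self.quartets)

    @property
    def n_steps(self) -> int:
        return self.n_quartets - 1

    def terminus_labels(self) -> dict[int, tuple[int, str]]:
        """Map terminus index 1-8 -> (strand index 0-3, ``"5'"`` | ``"3'"``)."""
        labels: dict[int, tuple[int, str]] = {}
        for s in range(4):
            labels[s + 1] = (s, "5'")
            labels[s + 5] = (s, "3'")
        return labels

    def terminus_of(self, strand_index: int, end: str) -> int:
        if end not in ("5'", "3'"):
            raise TopologyError(f"end must be 5' or 3', got {end!r}")
        return strand_index + 1 if end == "5'" else strand_index + 5

    def terminal_g(self, strand_index: int, end: str) -> ResidueId:
        """The guanine at the given end of a strand."""
        gs = self.strands[strand_index].g_residues
        return gs[0] if end == "5'" else gs[-1]

    def level_of(self, residue: ResidueId) -> tuple[int, int]:
        """Return (strand index, quartet level) of a guanine."""
        for s, strand in enumerate(self.strands):
            if residue in strand.g_residues:
                return s, strand.g_residues.index(residue)
        raise TopologyError(f"residue {residue} is not a stem guanine")

    def iter_guanines(self) -> Iterator[tuple[int, int, ResidueId]]:
        """Yield (strand index, level, residue) for every stem G."""
        for s, strand in enumerate(self.strands):
            for level, rid in enumerate(strand.g_residues):
                yield s, level, rid


def build_topology_from_strands(
    strand_specs: list[dict],
) -> StemTopology:
    """Assemble a :class:`StemTopology` from explicit per-strand residue lists.

    Each spec dict needs ``chain`` and ``g_residues`` (list of residue
    numbers 5'->3'); optional ``t5``/``t3`` residue numbers for flanking Ts.
    """
    if len(strand_specs) != 4:
        raise TopologyError(f"need exactly 4 strands, got {len(strand_specs)}")
    strands = []
    for spec in strand_specs:
        chain = str(spec["chain"])
        gs = tuple((chain, int(r)) for r in spec["g_residues"])
        t5 = (chain, int(spec["t5"])) if spec.get("t5") is not None else None
        t3 = (chain, int(spec["t3"])) if spec.get("t3") is not None else None
        strands.append(Strand(chain=chain, g_residues=gs, t5=t5, t3=t3))
    lengths = {s.n_levels for s in strands}
    if len(lengths) != 1:
        raise TopologyError(
            f"unequal G-tract lengths {sorted(lengths)}; provide an explicit "
            "topology file"
        )
    n = lengths.pop()
    quartets = tuple(
        tuple(strands[s].g_residues[level] for s in range(4)) for level in range(n)
    )
    anchors: dict[int, tuple[tuple[ResidueId, str], ...]] = {}
    for s, strand in enumerate(strands):
        if strand.t5 is not None:
            anchors[s + 1] = tuple((strand.t5, a) for a in ANCHOR_ATOM_NAMES)
        if strand.t3 is not None:
            anchors[s + 5] = tuple((strand.t3, a) for a in ANCHOR_ATOM_NAMES)
    return StemTopology(
        strands=tuple(strands), quartets=quartets, anchor_atoms=anchors
    )
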
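"""Structure and trajectory I/O with role-aware selections.

Coordinates live in a plain ``(F, A, 3)`` float array (Angstrom) next to a
:class:`Topology` that records, for every atom, its residue, chain and the
*role* the chain plays in the complex: one of the two protein monomers of
the homodimer (``monomer1``/``monomer2``) or one of the two DNA strands
(``strandW``/``strandC``).  Roles, not raw chain ids, are what the analysis
modules select on, so renumbering or renaming chains in the input PDB never
changes a result.

Residue numbering is taken verbatim from the PDB file.  The conventional
annotations for the Yap8 system -- N-terminal tail 7-16, basic region
17-40, bZIP 7-89, and the 13-bp response element at duplex positions 7-19
of a 25-bp construct -- are attached as named regions when the residues are
present, and can be overridden through ``region_annotations``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, FormatError, SelectionError

logger = logging.getLogger(__name__)

CHAIN_ROLES = ("monomer1", "monomer2", "strandW", "strandC")
PROTEIN_ROLES = ("monomer1", "monomer2")
DNA_ROLES = ("strandW", "strandC")

#: canonical deoxyribonucleotide residue names (one- and two-letter forms)
DNA_RESNAMES = {
    "DA", "DT", "DG", "DC", "DU", "DI",
    "A", "T", "G", "C", "U", "I",
}

#: default named regions; the pseudo-roles "protein" and "dna" expand to
#: both monomers / both strands respectively
DEFAULT_REGIONS: dict[str, tuple[str, tuple[int, int]]] = {
    "n_tail": ("protein", (7, 16)),
    "basic_region": ("protein", (17, 40)),
    "bzip": ("protein", (7, 89)),
    "y8re_W": ("strandW", (7, 19)),
    "y8re_C": ("strandC", (7, 19)),
}


@dataclass(frozen=True)
class AtomRecord:
    """A single atom of a single frame."""

    serial: int
    name: str
    element: str
    residue_index: int
    chain_id: str
    xyz: tuple[float, float, float]


@dataclass(frozen=True)
class Residue:
    index: int
    name: str
    kind: str  # "protein" | "dna"
    chain_role: str
    chain_id: str

    @property
    def key(self) -> tuple[str, int, str]:
        """Hashable identity used throughout the contact pipeline."""
        return (self.chain_role, self.index, self.name)


@dataclass
class Topology:
    """Per-atom annotation arrays plus named regions.

    All arrays have length ``n_atoms`` and share ordering with the
    coordinate arrays of any :class:`Trajectory` built on this topology.
    """

    serial: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    res_index: np.ndarray
    res_name: np.ndarray
    chain_id: np.ndarray
    chain_role: np.ndarray
    region_annotations: dict[str, tuple[str, tuple[int, int]]] = field(default_factory=dict)
    frame_interval: float = 0.1  # ns per frame

    def __post_init__(self) -> None:
        n = len(self.serial)
        for arr in (self.atom_name, self.element, self.res_index,
                    self.res_name, self.chain_id, self.chain_role):
            if len(arr) != n:
                raise ValueError("topology annotation arrays disagree in length")
        serials = np.asarray(self.serial)
        if len(np.unique(serials)) != n:
            raise FormatError("duplicate atom serials in topology")
        bad = set(np.unique(self.chain_role)) - set(CHAIN_ROLES)
        if bad:
            raise ConfigurationError(f"unknown chain roles: {sorted(bad)}")
        self._validate_regions()

    # -- residue-level views -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    @property
    def residues(self) -> list[Residue]:
        out: list[Residue] = []
        seen: set[tuple[str, int]] = set()
        for role, idx, name, cid in zip(self.chain_role, self.res_index,
                                        self.res_name, self.chain_id):
            if (role, int(idx)) in seen:
                continue
            seen.add((role, int(idx)))
            kind = "dna" if role in DNA_ROLES else "protein"
            out.append(Residue(int(idx), str(name), kind, str(role), str(cid)))
        return out

    def residue_atoms(self) -> dict[tuple[str, int, str], np.ndarray]:
        """Map residue key -> atom index array (topology order)."""
        groups: dict[tuple[str, int, str], list[int]] = {}
        for i, (role, idx, name) in enumerate(zip(self.chain_role,
                                                  self.res_index, self.res_name)):
            groups.setdefault((str(role), int(idx), str(name)), []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in groups.items()}

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.asarray([e.upper() != "H" for e in self.element])

    @property
    def has_hydrogens(self) -> bool:
        return bool((~self.heavy_mask).any())

    # -- regions -------------------------------------------------------------

    def _roles_of(self, pseudo: str) -> tuple[str, ...]:
        if pseudo == "protein":
            return PROTEIN_ROLES
        if pseudo == "dna":
            return DNA_ROLES
        if pseudo in CHAIN_ROLES:
            return (pseudo,)
        raise ConfigurationError(f"unknown chain role {pseudo!r}")

    def _validate_regions(self) -> None:
        for rname, (role, (lo, hi)) in self.region_annotations.items():
            roles = self._roles_of(role)
            present = self.res_index[np.isin(self.chain_role, roles)]
            if present.size == 0 or lo < present.min() or hi > present.max():
                raise ConfigurationError(
                    f"region {rname!r} range {lo}-{hi} lies outside the "
                    f"residues present for role {role!r}")
            if rname.startswith("y8re") and hi - lo + 1 != 13:
                raise ConfigurationError(
                    f"region {rname!r} must span 13 positions, got {hi - lo + 1}")

    def with_regions(self, annotations: Mapping[str, tuple[str, tuple[int, int]]]) -> "Topology":
        merged = dict(self.region_annotations)
        merged.update(annotations)
        return replace(self, region_annotations=merged)


@dataclass
class Trajectory:
    topology: Topology
    coordinates: np.ndarray  # (F, A, 3), Angstrom

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (F, A, 3)")
        if self.coordinates.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise FormatError(
                f"atom count mismatch: topology has {self.topology.n_atoms}, "
                f"coordinates have {self.coordinates.shape[1]}")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _default_regions_present(top: Topology) -> dict[str, tuple[str, tuple[int, int]]]:
    """Attach the conventional Yap8/Y8RE regions where the residues exist."""
    out = {}
    for rname, (role, (lo, hi)) in DEFAULT_REGIONS.items():
        try:
            roles = top._roles_of(role)
        except ConfigurationError:
            continue
        present = top.res_index[np.isin(top.chain_role, roles)]
        if present.size and lo >= present.min() and hi <= present.max():
            out[rname] = (role, (lo, hi))
    return out


def read_topology(path: str | Path,
                  chain_roles: Mapping[str, str],
                  region_annotations: Mapping[str, tuple[str, tuple[int, int]]] | None = None,
                  frame_interval: float = 0.1) -> Topology:
    """Read a PDB file and annotate every chain with its role.

    Parameters
    ----------
    chain_roles
        Map of PDB chain id -> role (``monomer1``, ``monomer2``,
        ``strandW``, ``strandC``).  Every chain in the file must be
        mapped; an unmapped chain raises :class:`ConfigurationError`.
    region_annotations
        Named residue ranges overriding / extending the defaults.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1, extra_fields=["atom_id"])

    chains = [str(c) for c in np.unique(arr.chain_id)]
    missing = [c for c in chains if c not in chain_roles]
    if missing:
        raise ConfigurationError(
            f"no role mapping for chain(s) {missing}; supply chain_roles for "
            f"every chain in the file")
    for cid, role in chain_roles.items():
        if role not in CHAIN_ROLES:
            raise ConfigurationError(f"unknown role {role!r} for chain {cid!r}")

    roles = np.asarray([chain_roles[str(c)] for c in arr.chain_id])
    # kind consistency: DNA residues must sit on strand roles and vice versa
    for cid in chains:
        m = arr.chain_id == cid
        names = set(str(n) for n in np.unique(arr.res_name[m]))
        is_dna_chain = bool(names & DNA_RESNAMES)
        role_is_strand = chain_roles[cid] in DNA_ROLES
        if is_dna_chain != role_is_strand:
            raise ConfigurationError(
                f"chain {cid!r} mapped to {chain_roles[cid]!r} but its residues "
                f"look like {'DNA' if is_dna_chain else 'protein'}")

    top = Topology(
        serial=np.asarray(arr.atom_id, dtype=int),
        atom_name=np.asarray([str(n) for n in arr.atom_name]),
        element=np.asarray([str(e) for e in arr.element]),
        res_index=np.asarray(arr.res_id, dtype=int),
        res_name=np.asarray([str(n) for n in arr.res_name]),
        chain_id=np.asarray([str(c) for c in arr.chain_id]),
        chain_role=roles,
        region_annotations={},
        frame_interval=frame_interval,
    )
    regions = _default_regions_present(top)
    if region_annotations:
        regions.update(region_annotations)
    return top.with_regions(regions)


def read_frames(path: str | Path, topology: Topology) -> Trajectory:
    """Read trajectory coordinates; format from the file extension.

    Multi-model PDB is the first-class dialect; DCD and XTC are read
    through MDAnalysis coordinate readers.  Every frame must carry exactly
    the topology's atom count.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        from biotite.structure.io.pdb import PDBFile
        pdb = PDBFile.read(str(path))
        try:
            stack = pdb.get_structure(model=None)
        except Exception as exc:  # inconsistent models
            raise FormatError(f"cannot read multi-model PDB: {exc}") from exc
        coords = np.asarray(stack.coord, dtype=float)
        if coords.ndim == 2:  # single model
            coords = coords[None]
    elif suffix == ".dcd":
        from MDAnalysis.coordinates.DCD import DCDReader
        with DCDReader(str(path)) as reader:
            coords = np.asarray([ts.positions.copy() for ts in reader], dtype=float)
    elif suffix == ".xtc":
        from MDAnalysis.coordinates.XTC import XTCReader
        with XTCReader(str(path)) as reader:
            coords = np.asarray([ts.positions.copy() for ts in reader], dtype=float)
    else:
        raise FormatError(f"unsupported trajectory format {suffix!r}")

    if coords.shape[1] != topology.n_atoms:
        raise FormatError(
            f"atom count mismatch: topology has {topology.n_atoms} atoms, "
            f"{path.name} frames have {coords.shape[1]}")
    return Trajectory(topology, coords)


def write_frames(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (3-decimal precision)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    top = trajectory.topology
    F = trajectory.n_frames
    stack = struc.AtomArrayStack(F, top.n_atoms)
    stack.coord = np.asarray(trajectory.coordinates, dtype=np.float32)
    stack.set_annotation("chain_id", top.chain_id.astype("U4"))
    stack.set_annotation("res_id", top.res_index.astype(int))
    stack.set_annotation("res_name", top.res_name.astype("U5"))
    stack.set_annotation("atom_name", top.atom_name.astype("U6"))
    stack.set_annotation("element", np.asarray([e.upper() for e in top.element], dtype="U2"))
    stack.set_annotation("hetero", np.zeros(top.n_atoms, dtype=bool))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# selection language
# ---------------------------------------------------------------------------
#
#   expr     := term ( ("or" | "minus") term )*
#   term     := factor ( "and" factor )*
#   factor   := "(" expr ")" | predicate
#   predicate:= "role" ROLE | "resid" LO[-HI] | "resname" NAME[,NAME...]
#             | "name" NAME[,NAME...] | "heavy" | "hydrogen"
#             | "region" NAME | "all"
#
# "or" is set union, "minus" set difference, "and" intersection; "role"
# also accepts the pseudo-roles "protein" and "dna".

def _tokenize(expr: str) -> list[str]:
    out: list[str] = []
    for raw in expr.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _Parser:
    def __init__(self, tokens: list[str], topology: Topology):
        self.toks = tokens
        self.pos = 0
        self.top = topology

    def peek(self) -> str | None:
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens from {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() in ("or", "minus"):
            op = self.next()
            rhs = self.term()
            mask = (mask | rhs) if op == "or" else (mask & ~rhs)
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.next()
        if tok == "(":
            mask = self.expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.predicate(tok)

    def predicate(self, tok: str) -> np.ndarray:
        top = self.top
        if tok == "all":
            return np.ones(top.n_atoms, dtype=bool)
        if tok == "heavy":
            return top.heavy_mask
        if tok == "hydrogen":
            return ~top.heavy_mask
        if tok == "role":
            roles = top._roles_of(self.next())
            return np.isin(top.chain_role, roles)
        if tok == "resid":
            rng = self.next()
            if "-" in rng.lstrip("-"):
                lo_s, hi_s = rng.rsplit("-", 1)
                lo, hi = int(lo_s), int(hi_s)
            else:
                lo = hi = int(rng)
            if hi < lo:
                raise SelectionError(f"empty residue range {rng!r}")
            return (top.res_index >= lo) & (top.res_index <= hi)
        if tok == "resname":
            names = self.next().split(",")
            return np.isin(top.res_name, names)
        if tok == "name":
            names = self.next().split(",")
            return np.isin(top.atom_name, names)
        if tok == "region":
            rname = self.next()
            if rname not in top.region_annotations:
                raise SelectionError(f"unknown region {rname!r}")
            role, (lo, hi) = top.region_annotations[rname]
            roles = top._roles_of(role)
            return (np.isin(top.chain_role, roles)
                    & (top.res_index >= lo) & (top.res_index <= hi))
        raise SelectionError(f"unknown selection token {tok!r}")


def select(topology: Topology, expr: str) -> np.ndarray:
    """Evaluate a selection expression; returns sorted atom indices.

    Examples
    --------
    ``"role strandW and resid 1-6 and heavy"``
        heavy atoms of the first six Watson-strand positions;
    ``"(role dna and heavy) minus (region y8re_W or region y8re_C) minus (resid 1-2 or resid 24-25)"``
        DNA heavy atoms outside the response element, dropping two
        terminal base pairs at each end.
    """
    mask = _Parser(_tokenize(expr), topology).parse()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        logger.warning("selection %r matched no atoms", expr)
    return idx
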
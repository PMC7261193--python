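"""Geometric detection of protein-DNA contacts in trajectory frames.

Three interaction classes are detected, each from plain geometry:

hydrogen bond
    donor-heavy to acceptor-heavy distance <= 3.0 A and a D-H...A angle
    >= 135 deg at some donor hydrogen.  When a donor carries no hydrogens
    in the topology the test degrades to a pure distance criterion
    (default 3.5 A), matching the common practice for united-atom or
    stripped structures.
salt bridge
    minimum distance between any positively charged atom of one residue
    and any negatively charged atom of the other <= 4.0 A; on the DNA
    side the charge sits on the phosphate oxygens.  Recorded once per
    residue pair regardless of how many atom pairs qualify.
hydrophobic contact
    distance between the centre of mass of the protein side-chain heavy
    atoms and the centre of mass of the DNA base heavy atoms <= 6.0 A.

All cutoffs are inclusive (distance equal to the cutoff counts).  The
defaults live in :class:`DetectionCriteria` and the atom chemistry in
:class:`~yap8dna.chemistry.ChemistryTables`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.spatial.distance import cdist

from .chemistry import ATOMIC_MASS, ChemistryTables
from .contact_dynamics import ContactTimeSeries
from .errors import ConfigurationError
from .structures_io import DNA_ROLES, Topology, Trajectory

logger = logging.getLogger(__name__)

ResidueKey = tuple[str, int, str]  # (chain_role, residue index, residue name)


@dataclass
class DetectionCriteria:
    """Distance/angle thresholds, Angstrom and degrees."""

    hbond_heavy_dist: float = 3.0
    hbond_angle_min: float = 135.0
    hbond_dist_only: float | None = 3.5
    salt_dist: float = 4.0
    hydrophobic_com_dist: float = 6.0

    def __post_init__(self) -> None:
        for name in ("hbond_heavy_dist", "salt_dist", "hydrophobic_com_dist"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.hbond_dist_only is not None and self.hbond_dist_only <= 0:
            raise ConfigurationError("hbond_dist_only must be positive")
        if not (0 < self.hbond_angle_min <= 180):
            raise ConfigurationError("hbond_angle_min must lie in (0, 180]")


@dataclass(frozen=True)
class InteractionEvent:
    frame: int
    protein: ResidueKey
    dna: ResidueKey
    itype: str  # "hbond" | "saltbridge" | "hydrophobic"
    distance: float
    angle: float | None = None


class _ResidueChemistry:
    """Atom indices of one residue resolved against the chemistry tables."""

    __slots__ = ("key", "kind", "donors", "acceptors", "charge", "hydro_idx", "hydro_mass")

    def __init__(self, key: ResidueKey, kind: str, atom_idx: np.ndarray,
                 topology: Topology, tables: ChemistryTables):
        self.key = key
        self.kind = kind
        names = {str(topology.atom_name[i]): i for i in atom_idx}
        res_name = key[2]

        self.donors: list[tuple[int, list[int]]] = []
        for d, hs in tables.donors_for(res_name, kind):
            if d in names:
                self.donors.append((names[d], [names[h] for h in hs if h in names]))
        self.acceptors: list[int] = [names[a] for a in tables.acceptors_for(res_name, kind)
                                     if a in names]
        self.charge: tuple[int, list[int]] | None = None
        ch = tables.charged_for(res_name, kind)
        if ch is not None:
            idx = [names[a] for a in ch[1] if a in names]
            if idx:
                self.charge = (ch[0], idx)
        hydro_names = tables.hydrophobic_for(res_name)
        if hydro_names is None:
            self.hydro_idx = None
            self.hydro_mass = None
        else:
            idx = [names[a] for a in hydro_names if a in names]
            if not idx:
                self.hydro_idx = None
                self.hydro_mass = None
            else:
                self.hydro_idx = np.asarray(idx, dtype=int)
                self.hydro_mass = np.asarray(
                    [ATOMIC_MASS.get(str(topology.element[i]).upper(), 12.0)
                     for i in idx])


class InteractionIndex:
    """Per-topology cache of residue chemistry, built once per trajectory."""

    def __init__(self, topology: Topology, tables: ChemistryTables):
        self.topology = topology
        self.protein: list[_ResidueChemistry] = []
        self.dna: list[_ResidueChemistry] = []
        self._warned: set[ResidueKey] = set()
        for key, idx in topology.residue_atoms().items():
            kind = "dna" if key[0] in DNA_ROLES else "protein"
            rc = _ResidueChemistry(key, kind, idx, topology, tables)
            (self.dna if kind == "dna" else self.protein).append(rc)
            if rc.hydro_idx is None and key not in self._warned:
                logger.debug("residue %s has no hydrophobic atom definition; "
                             "skipped in hydrophobic detection", key)
                self._warned.add(key)


def _angle_deg(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    v1 = d - h
    v2 = a - h
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _hbond_pairs(coords: np.ndarray, donor_res: _ResidueChemistry,
                 acceptor_res: _ResidueChemistry,
                 criteria: DetectionCriteria) -> list[tuple[float, float | None]]:
    """All qualifying (distance, angle) donor->acceptor contacts."""
    out: list[tuple[float, float | None]] = []
    for d_idx, h_idxs in donor_res.donors:
        for a_idx in acceptor_res.acceptors:
            dist = float(np.linalg.norm(coords[d_idx] - coords[a_idx]))
            if h_idxs:
                if dist > criteria.hbond_heavy_dist:
                    continue
                best = max(_angle_deg(coords[d_idx], coords[h], coords[a_idx])
                           for h in h_idxs)
                if best >= criteria.hbond_angle_min:
                    out.append((dist, best))
            else:
                if criteria.hbond_dist_only is None:
                    raise ConfigurationError(
                        "donor without hydrogens encountered but "
                        "hbond_dist_only is unset")
                if dist <= criteria.hbond_dist_only:
                    out.append((dist, None))
    return out


def detect_hbonds(coords: np.ndarray, topology: Topology,
                  criteria: DetectionCriteria | None = None,
                  tables: ChemistryTables | None = None,
                  index: InteractionIndex | None = None,
                  frame: int = 0) -> list[InteractionEvent]:
    """Hydrogen bonds between protein and DNA in one frame (both
    directions: protein donor or DNA donor)."""
    criteria = criteria or DetectionCriteria()
    index = index or InteractionIndex(topology, tables or ChemistryTables.default())
    if not topology.has_hydrogens and criteria.hbond_dist_only is None:
        raise ConfigurationError(
            "topology carries no hydrogens and hbond_dist_only is unset")
    events: list[InteractionEvent] = []
    for p in index.protein:
        for d in index.dna:
            for dist, ang in _hbond_pairs(coords, p, d, criteria):
                events.append(InteractionEvent(frame, p.key, d.key, "hbond", dist, ang))
            for dist, ang in _hbond_pairs(coords, d, p, criteria):
                events.append(InteractionEvent(frame, p.key, d.key, "hbond", dist, ang))
    return events


def detect_saltbridges(coords: np.ndarray, topology: Topology,
                       criteria: DetectionCriteria | None = None,
                       tables: ChemistryTables | None = None,
                       index: InteractionIndex | None = None,
                       frame: int = 0) -> list[InteractionEvent]:
    """Residue-pair level salt bridges (at most one event per pair)."""
    criteria = criteria or DetectionCriteria()
    index = index or InteractionIndex(topology, tables or ChemistryTables.default())
    events: list[InteractionEvent] = []
    for p in index.protein:
        if p.charge is None:
            continue
        sp, p_idx = p.charge
        for d in index.dna:
            if d.charge is None:
                continue
            sd, d_idx = d.charge
            if sp * sd >= 0:
                continue
            dmin = float(cdist(coords[p_idx], coords[d_idx]).min())
            if dmin <= criteria.salt_dist:
                events.append(InteractionEvent(frame, p.key, d.key, "saltbridge", dmin))
    return events


def detect_hydrophobic(coords: np.ndarray, topology: Topology,
                       criteria: DetectionCriteria | None = None,
                       tables: ChemistryTables | None = None,
                       index: InteractionIndex | None = None,
                       frame: int = 0) -> list[InteractionEvent]:
    """Apolar contacts via side-chain / base centre-of-mass distance."""
    criteria = criteria or DetectionCriteria()
    index = index or InteractionIndex(topology, tables or ChemistryTables.default())
    events: list[InteractionEvent] = []

    def com(rc: _ResidueChemistry) -> np.ndarray:
        w = rc.hydro_mass
        return (coords[rc.hydro_idx] * w[:, None]).sum(axis=0) / w.sum()

    for p in index.protein:
        if p.hydro_idx is None:
            continue
        cp = com(p)
        for d in index.dna:
            if d.hydro_idx is None:
                continue
            dist = float(np.linalg.norm(cp - com(d)))
            if dist <= criteria.hydrophobic_com_dist:
                events.append(InteractionEvent(frame, p.key, d.key, "hydrophobic", dist))
    return events


def detect_all(trajectory: Trajectory,
               criteria: DetectionCriteria | None = None,
               tables: ChemistryTables | None = None
               ) -> dict[tuple[ResidueKey, ResidueKey, str], ContactTimeSeries]:
    """Run all three detectors on every frame.

    Returns per (protein residue, DNA residue, interaction type) an
    integer count series of length F.  Hydrogen bonds are counted
    additively (several simultaneous donor-acceptor pairs between one
    residue pair raise the count); salt bridges and hydrophobic contacts
    are 0/1 per frame.  Pairs that never interact are omitted (their
    series are identically zero).
    """
    criteria = criteria or DetectionCriteria()
    tables = tables or ChemistryTables.default()
    top = trajectory.topology
    index = InteractionIndex(top, tables)
    F = trajectory.n_frames
    counts: dict[tuple[ResidueKey, ResidueKey, str], np.ndarray] = {}

    for f in range(F):
        coords = trajectory.coordinates[f]
        frame_events = (detect_hbonds(coords, top, criteria, tables, index, f)
                        + detect_saltbridges(coords, top, criteria, tables, index, f)
                        + detect_hydrophobic(coords, top, criteria, tables, index, f))
        for ev in frame_events:
            key = (ev.protein, ev.dna, ev.itype)
            if key not in counts:
                counts[key] = np.zeros(F, dtype=int)
            counts[key][f] += 1

    return {k: ContactTimeSeries(pair=(k[0], k[1]), itype=k[2], counts=v)
            for k, v in counts.items()}


def events_to_dataframe(events: Iterable[InteractionEvent]):
    """Flatten events into the per-frame CSV layout."""
    import pandas as pd

    rows = [{"frame": ev.frame,
             "protein_role": ev.protein[0], "protein_res": ev.protein[1],
             "protein_name": ev.protein[2],
             "strand": ev.dna[0], "dna_res": ev.dna[1], "dna_name": ev.dna[2],
             "type": ev.itype, "distance": ev.distance, "angle": ev.angle}
            for ev in events]
    return pd.DataFrame(rows, columns=["frame", "protein_role", "protein_res",
                                       "protein_name", "strand", "dna_res",
                                       "dna_name", "type", "distance", "angle"])
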
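"""Shared builders for toy topologies and frames.

Everything is generated in memory; tests that need files write them to
tmp_path through the package's own writers.
"""
from __future__ import annotations

import numpy as np
import pytest

from yap8dna.structures_io import Topology, Trajectory, _default_regions_present

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
NUC = {"A": "DA", "T": "DT", "G": "DG", "C": "DC"}
SEQ25 = "TTTGTTTGATTAATAATCAACTTTA"


def make_topology(atoms, frame_interval=0.1, regions="auto"):
    """atoms: iterable of (name, element, res_index, res_name, chain_id, role).

    Coordinates are supplied separately; serials are sequential.
    """
    atoms = list(atoms)
    top = Topology(
        serial=np.arange(1, len(atoms) + 1),
        atom_name=np.asarray([a[0] for a in atoms]),
        element=np.asarray([a[1] for a in atoms]),
        res_index=np.asarray([a[2] for a in atoms], dtype=int),
        res_name=np.asarray([a[3] for a in atoms]),
        chain_id=np.asarray([a[4] for a in atoms]),
        chain_role=np.asarray([a[5] for a in atoms]),
        frame_interval=frame_interval,
    )
    if regions == "auto":
        top = top.with_regions(_default_regions_present(top))
    elif regions:
        top = top.with_regions(regions)
    return top


def duplex_atoms(atom_spec=(("C1'", "C"), ("OP1", "O"))):
    """Atom tuples for a full 25-bp duplex (both strands)."""
    out = []
    for strand, cid, role in (("W", "W", "strandW"), ("C", "C", "strandC")):
        for pos in range(1, 26):
            base = SEQ25[pos - 1] if strand == "W" else COMPLEMENT[SEQ25[pos - 1]]
            for name, elem in atom_spec:
                out.append((name, elem, pos, NUC[base], cid, role))
    return out


@pytest.fixture
def duplex_complex():
    """25-bp duplex plus a 10-residue protein tail (residues 7-16), with
    dull but valid coordinates; returns (topology, trajectory of 3 frames)."""
    atoms = duplex_atoms()
    for r in range(7, 17):
        atoms.append(("N", "N", r, "GLY", "A", "monomer1"))
        atoms.append(("CA", "C", r, "GLY", "A", "monomer1"))
    top = make_topology(atoms)
    rng = np.random.default_rng(7)
    base = rng.uniform(-30, 30, size=(top.n_atoms, 3))
    coords = np.stack([base, base + 1.0, base - 2.0])
    return top, Trajectory(top, coords)
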
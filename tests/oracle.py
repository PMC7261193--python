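"""Independent brute-force contact detector used as a test oracle.

Pure-Python all-pairs scan written directly from the geometric contact
definitions and the shipped chemistry JSON, with no shared code paths
with :mod:`yap8dna.interactions` (plain dict/list/math, no numpy
vectorization, no residue-chemistry caching).
"""
from __future__ import annotations

import json
import math
from importlib import resources

_RAW = json.loads(resources.files("yap8dna").joinpath("data/chemistry.json").read_text())
_NUC = {"A": "DA", "T": "DT", "G": "DG", "C": "DC", "U": "DU", "I": "DI"}
_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974, "S": 32.06}

PROTEIN_BB_DONOR = ("N", ["H", "H1", "H2", "H3", "HN"])
PROTEIN_BB_ACC = ["O", "OXT"]
DNA_BB_ACC = ["OP1", "OP2", "O5'", "O3'", "O4'"]
DNA_PHOSPHATE = ["OP1", "OP2"]


def _dist(a, b):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def _angle(d, h, a):
    v1 = [x - y for x, y in zip(d, h)]
    v2 = [x - y for x, y in zip(a, h)]
    dot = sum(x * y for x, y in zip(v1, v2))
    n1 = math.sqrt(sum(x * x for x in v1))
    n2 = math.sqrt(sum(x * x for x in v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, dot / (n1 * n2)))))


def _residues(topology, coords):
    """List of residue dicts: key, kind, {atom name: xyz}."""
    groups = {}
    for i in range(topology.n_atoms):
        key = (str(topology.chain_role[i]), int(topology.res_index[i]),
               str(topology.res_name[i]))
        groups.setdefault(key, {})[str(topology.atom_name[i])] = (
            [float(c) for c in coords[i]], str(topology.element[i]))
    out = []
    for key, atoms in groups.items():
        kind = "dna" if key[0] in ("strandW", "strandC") else "protein"
        out.append({"key": key, "kind": kind, "atoms": atoms})
    return out


def _donors(res):
    tab = list(_RAW["donors"].get(_NUC.get(res["key"][2], res["key"][2]), []))
    if res["kind"] == "protein":
        tab.append(PROTEIN_BB_DONOR)
    out = []
    for d, hs in tab:
        if d in res["atoms"]:
            out.append((d, [h for h in hs if h in res["atoms"]]))
    return out


def _acceptors(res):
    tab = list(_RAW["acceptors"].get(_NUC.get(res["key"][2], res["key"][2]), []))
    tab += PROTEIN_BB_ACC if res["kind"] == "protein" else DNA_BB_ACC
    return [a for a in tab if a in res["atoms"]]


def hbond_events(topology, coords, heavy=3.0, angle_min=135.0, dist_only=3.5):
    """set of (protein key, dna key, donor atom, acceptor atom)."""
    residues = _residues(topology, coords)
    prot = [r for r in residues if r["kind"] == "protein"]
    dna = [r for r in residues if r["kind"] == "dna"]
    found = set()
    for p in prot:
        for n in dna:
            for donor_res, acc_res in ((p, n), (n, p)):
                for d, hs in _donors(donor_res):
                    for a in _acceptors(acc_res):
                        dd = _dist(donor_res["atoms"][d][0], acc_res["atoms"][a][0])
                        if hs:
                            if dd <= heavy and any(
                                    _angle(donor_res["atoms"][d][0],
                                           donor_res["atoms"][h][0],
                                           acc_res["atoms"][a][0]) >= angle_min
                                    for h in hs):
                                found.add((p["key"], n["key"], d, a))
                        elif dd <= dist_only:
                            found.add((p["key"], n["key"], d, a))
    return found


def saltbridge_events(topology, coords, cutoff=4.0):
    residues = _residues(topology, coords)
    found = set()
    for p in [r for r in residues if r["kind"] == "protein"]:
        ch = _RAW["charged"].get(p["key"][2])
        if ch is None:
            continue
        plus = [a for a in ch["atoms"] if a in p["atoms"]]
        if not plus or ch["sign"] <= 0:
            continue
        for n in [r for r in residues if r["kind"] == "dna"]:
            minus = [a for a in DNA_PHOSPHATE if a in n["atoms"]]
            if not minus:
                continue
            dmin = min(_dist(p["atoms"][a][0], n["atoms"][b][0])
                       for a in plus for b in minus)
            if dmin <= cutoff:
                found.add((p["key"], n["key"]))
    return found


def hydrophobic_events(topology, coords, cutoff=6.0):
    residues = _residues(topology, coords)

    def com(res):
        tab = _RAW["hydrophobic"].get(_NUC.get(res["key"][2], res["key"][2]))
        if tab is None:
            return None
        pts = [(res["atoms"][a][0], _MASS.get(res["atoms"][a][1].upper(), 12.0))
               for a in tab if a in res["atoms"]]
        if not pts:
            return None
        m = sum(w for _, w in pts)
        return [sum(p[i] * w for p, w in pts) / m for i in range(3)]

    found = set()
    for p in [r for r in residues if r["kind"] == "protein"]:
        cp = com(p)
        if cp is None:
            continue
        for n in [r for r in residues if r["kind"] == "dna"]:
            cn = com(n)
            if cn is not None and _dist(cp, cn) <= cutoff:
                found.add((p["key"], n["key"]))
    return found
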
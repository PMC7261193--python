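"""Chemistry lookup tables driving geometric interaction detection.

The shipped JSON covers side-chain donors/acceptors, charged groups and
hydrophobic atom sets for the 20 amino acids that need them and the four
deoxyribonucleotides.  Backbone chemistry is uniform and therefore added
in code: every protein residue donates through its amide ``N`` and accepts
through its carbonyl ``O``; every nucleotide accepts through the
phosphate/sugar oxygens and carries the phosphate negative charge on
``OP1``/``OP2``.

Detection is tolerant to missing atoms: a table entry whose atom is absent
from the topology (coarse toy residues, stripped hydrogens) is silently
skipped, so the same tables serve full-atom and minimal synthetic systems.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

#: atomic masses used for residue centres of mass
ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06,
}

_NUC_ALIASES = {"A": "DA", "T": "DT", "G": "DG", "C": "DC", "U": "DU", "I": "DI"}

#: backbone donors/acceptors added for every residue of the kind
PROTEIN_BACKBONE_DONOR = ("N", ("H", "H1", "H2", "H3", "HN"))
PROTEIN_BACKBONE_ACCEPTORS = ("O", "OXT")
DNA_BACKBONE_ACCEPTORS = ("OP1", "OP2", "O5'", "O3'", "O4'")
DNA_PHOSPHATE_ATOMS = ("OP1", "OP2")


def _norm(res_name: str) -> str:
    return _NUC_ALIASES.get(res_name, res_name)


@dataclass
class ChemistryTables:
    """Residue-name keyed atom tables; see module docstring for scope."""

    donors: dict[str, list[tuple[str, list[str]]]]
    acceptors: dict[str, list[str]]
    charged: dict[str, tuple[int, list[str]]]
    hydrophobic: dict[str, list[str]]
    include_backbone: bool = True

    @classmethod
    def from_dict(cls, raw: dict, include_backbone: bool = True) -> "ChemistryTables":
        donors = {k: [(d, list(hs)) for d, hs in v] for k, v in raw["donors"].items()}
        charged = {k: (int(v["sign"]), list(v["atoms"])) for k, v in raw["charged"].items()}
        return cls(donors=donors,
                   acceptors={k: list(v) for k, v in raw["acceptors"].items()},
                   charged=charged,
                   hydrophobic={k: list(v) for k, v in raw["hydrophobic"].items()},
                   include_backbone=include_backbone)

    @classmethod
    def from_json(cls, path: str | Path, include_backbone: bool = True) -> "ChemistryTables":
        with open(path) as fh:
            return cls.from_dict(json.load(fh), include_backbone)

    @classmethod
    def default(cls) -> "ChemistryTables":
        text = resources.files("yap8dna").joinpath("data/chemistry.json").read_text()
        return cls.from_dict(json.loads(text))

    # -- per-residue lookups (kind: "protein" | "dna") ----------------------

    def donors_for(self, res_name: str, kind: str) -> list[tuple[str, list[str]]]:
        out = list(self.donors.get(_norm(res_name), []))
        if self.include_backbone and kind == "protein":
            out.append((PROTEIN_BACKBONE_DONOR[0], list(PROTEIN_BACKBONE_DONOR[1])))
        return out

    def acceptors_for(self, res_name: str, kind: str) -> list[str]:
        out = list(self.acceptors.get(_norm(res_name), []))
        if self.include_backbone:
            if kind == "protein":
                out.extend(PROTEIN_BACKBONE_ACCEPTORS)
            else:
                out.extend(DNA_BACKBONE_ACCEPTORS)
        return out

    def charged_for(self, res_name: str, kind: str) -> tuple[int, list[str]] | None:
        if kind == "dna":
            return (-1, list(DNA_PHOSPHATE_ATOMS))
        return self.charged.get(_norm(res_name))

    def hydrophobic_for(self, res_name: str) -> list[str] | None:
        return self.hydrophobic.get(_norm(res_name))
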
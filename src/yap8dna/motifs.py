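"""Composition analysis of Y8RE sites and their flanking sequences.

A site is a 25-bp window around a 13-bp Yap8 response element (Y8RE):
six 5' flank positions (1-6), the 13-bp core (7-19) and six 3' flank
positions (20-25).  The canonical S. cerevisiae ACR3 promoter site,
TTTGTT-TGATTAATAATCA-ACTTTA, ships as :data:`SCACR3`.

The module builds position frequency matrices over aligned sites,
measures per-region A/T fractions (the flanks of functional sites are
A/T-rich) and generates the flank-mutated probe designs used to test the
role of that enrichment: M1 keeps the 5' flank and converts the 3' flank
to G/C, M2 mutates the 5' flank only, and M3 converts both flanks to G/C
while always leaving the 13-bp core untouched.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

ALPHABET = "ACGT"
REGIONS = {"flank5": slice(0, 6), "core": slice(6, 19), "flank3": slice(19, 25)}

#: the ACR3 promoter Y8RE site of S. cerevisiae (5' flank + core + 3' flank)
SCACR3 = "TTTGTTTGATTAATAATCAACTTTA"

MUTATION_MODES = {
    "M1": ("flank3",),          # 5' flank kept A/T-rich, 3' flank -> G/C
    "M2": ("flank5",),          # 5' flank -> G/C
    "M3": ("flank5", "flank3"),  # both flanks -> G/C
}


@dataclass(frozen=True)
class MotifSite:
    label: str
    seq25: str

    def __post_init__(self) -> None:
        if len(self.seq25) != 25:
            raise ValidationError(
                f"site {self.label!r}: length {len(self.seq25)}, expected 25")
        bad = set(self.seq25) - set(ALPHABET)
        if bad:
            raise ValidationError(
                f"site {self.label!r}: invalid characters {sorted(bad)}")

    @property
    def flank5(self) -> str:
        return self.seq25[REGIONS["flank5"]]

    @property
    def core(self) -> str:
        return self.seq25[REGIONS["core"]]

    @property
    def flank3(self) -> str:
        return self.seq25[REGIONS["flank3"]]


@dataclass
class PositionFrequencyMatrix:
    counts: np.ndarray       # 4 x 25 integers, rows A,C,G,T
    frequencies: np.ndarray  # 4 x 25, columns sum to 1
    n_sites: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.frequencies, index=list(ALPHABET),
                            columns=range(1, 26))

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


def build_pfm(sites: Sequence[MotifSite]) -> PositionFrequencyMatrix:
    """Column-wise base counts and frequencies over aligned 25-bp sites."""
    if not sites:
        raise ValidationError("need at least one site")
    from Bio import motifs
    from Bio.Seq import Seq

    m = motifs.create([Seq(s.seq25) for s in sites], alphabet="ACGT")
    counts = np.asarray([m.counts[b] for b in ALPHABET], dtype=int)
    freqs = counts / counts.sum(axis=0, keepdims=True)
    return PositionFrequencyMatrix(counts=counts, frequencies=freqs,
                                   n_sites=len(sites))


def at_fraction(site: MotifSite, region: str) -> float:
    """Fraction of A/T bases in one region of the site."""
    if region not in REGIONS:
        raise ValidationError(f"unknown region {region!r}; pick from {sorted(REGIONS)}")
    seq = site.seq25[REGIONS[region]]
    return sum(b in "AT" for b in seq) / len(seq)


def gc_mutate_flanks(site: MotifSite, mode: str,
                     substitution: Mapping[str, str] | None = None,
                     seed: int | None = None) -> MotifSite:
    """Produce an M1/M2/M3-style flank-mutated variant.

    Every A or T in the designated flank(s) is replaced by G or C --
    through ``substitution`` (a map from A/T into {G, C}) when given,
    otherwise by a seeded random choice.  The 13-bp core and any
    undesignated flank are untouched; existing G/C flank bases stay.
    """
    if mode not in MUTATION_MODES:
        raise ValidationError(f"unknown mode {mode!r}; pick from {sorted(MUTATION_MODES)}")
    if substitution is not None:
        if not substitution:
            raise ValidationError("substitution map is empty")
        bad = {k: v for k, v in substitution.items()
               if k not in "AT" or v not in "GC"}
        if bad:
            raise ValidationError(f"substitution must map A/T into G/C, got {bad}")

    rng = np.random.default_rng(seed)
    seq = list(site.seq25)
    for region in MUTATION_MODES[mode]:
        sl = REGIONS[region]
        for i in range(sl.start, sl.stop):
            if seq[i] in "AT":
                if substitution is not None:
                    seq[i] = substitution.get(seq[i], "G" if seq[i] == "A" else "C")
                else:
                    seq[i] = str(rng.choice(["G", "C"]))
    return MotifSite(label=f"{site.label}-{mode}", seq25="".join(seq))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sites(path: str | Path) -> list[MotifSite]:
    """Read aligned 25-mers from FASTA or plain text (``label seq`` or
    bare sequence per line)."""
    path = Path(path)
    text = path.read_text().strip()
    sites: list[MotifSite] = []
    if text.startswith(">"):
        from Bio import SeqIO
        for rec in SeqIO.parse(str(path), "fasta"):
            sites.append(MotifSite(label=rec.id, seq25=str(rec.seq).upper()))
    else:
        for i, line in enumerate(text.splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 2:
                sites.append(MotifSite(label=parts[0], seq25=parts[1].upper()))
            else:
                sites.append(MotifSite(label=f"site{i + 1}", seq25=parts[0].upper()))
    if not sites:
        raise ValidationError(f"no sites found in {path}")
    return sites


def write_sites(sites: Iterable[MotifSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f">{s.label}\n{s.seq25}\n")
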
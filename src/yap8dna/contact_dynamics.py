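"""Dynamic contact maps: strength, occupancy, lifetime, filtering, comparison.

The per-frame *contact strength* of a residue pair is the number of
hydrogen bonds plus salt bridges present in that frame; hydrophobic
contacts are tracked separately and never enter the strength sum.  Over a
trajectory each pair is summarised by

* ``strength_mean`` / ``strength_sd`` -- population mean and SD of the
  per-frame strength, zero frames included;
* ``occupancy`` -- percentage of frames with strength >= 1;
* ``mean_lifetime`` -- mean length of maximal runs of consecutive present
  frames, converted to ns through the topology's frame interval;
* ``n_events`` -- number of such runs.

Maps are reported per protein monomer and can be filtered by minimum
occupancy (the conventional reporting threshold is 25%, inclusive) or
compared pair-by-pair between two conditions (e.g. wild type vs N20A).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .structures_io import PROTEIN_ROLES

ResidueKey = tuple[str, int, str]
PairKey = tuple[ResidueKey, ResidueKey]


@dataclass
class ContactTimeSeries:
    """Per-frame interaction counts for one residue pair and one type."""

    pair: PairKey
    itype: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if (self.counts < 0).any():
            raise ValueError("negative interaction counts")


@dataclass(frozen=True)
class PairContactStats:
    strength_mean: float
    strength_sd: float
    occupancy: float  # percent
    mean_lifetime: float  # ns
    n_events: int


@dataclass
class DynamicContactMap:
    """Per-monomer pair statistics plus the underlying strength series."""

    strength: dict[str, dict[PairKey, PairContactStats]]
    hydrophobic: dict[str, dict[PairKey, PairContactStats]]
    series: dict[PairKey, np.ndarray] = field(default_factory=dict)
    frame_interval: float = 0.1
    label: str = ""

    def pairs(self) -> list[tuple[str, PairKey]]:
        """Deterministic (monomer, pair) ordering."""
        out = []
        for role in sorted(self.strength):
            out.extend((role, p) for p in sorted(self.strength[role]))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for kind, table in (("strength", self.strength),
                            ("hydrophobic", self.hydrophobic)):
            for role in sorted(table):
                for pair in sorted(table[role]):
                    s = table[role][pair]
                    (prole, pidx, pname), (strand, didx, dname) = pair
                    rows.append({
                        "channel": kind, "monomer": role,
                        "protein_res": pidx, "protein_name": pname,
                        "strand": strand, "dna_pos": didx, "dna_name": dname,
                        "strength_mean": s.strength_mean,
                        "strength_sd": s.strength_sd,
                        "occupancy_pct": s.occupancy,
                        "lifetime_ns": s.mean_lifetime,
                        "n_events": s.n_events,
                    })
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dataframe().to_dict(orient="records"), fh, indent=1)


@dataclass
class MapComparison:
    """Side-by-side contact statistics for two conditions."""

    table: pd.DataFrame  # one row per pair in the union
    label_a: str = "A"
    label_b: str = "B"

    @property
    def unique_to_a(self) -> pd.DataFrame:
        return self.table[self.table["present_a"] & ~self.table["present_b"]]

    @property
    def unique_to_b(self) -> pd.DataFrame:
        return self.table[self.table["present_b"] & ~self.table["present_a"]]

    @property
    def significant(self) -> pd.DataFrame:
        """Pairs whose mean strengths differ by more than one SD of both
        conditions, plus pairs present in only one condition."""
        t = self.table
        both = t["present_a"] & t["present_b"]
        delta = (t["mean_a"] - t["mean_b"]).abs()
        differs = both & (delta > np.maximum(t["sd_a"], t["sd_b"]))
        return t[differs | ~both]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def strength_series(hbond: np.ndarray | None, saltbridge: np.ndarray | None) -> np.ndarray:
    """Element-wise sum of H-bond and salt-bridge counts for one pair."""
    if hbond is None and saltbridge is None:
        raise ValueError("at least one series required")
    if hbond is None:
        hbond = np.zeros_like(np.asarray(saltbridge, dtype=int))
    if saltbridge is None:
        saltbridge = np.zeros_like(np.asarray(hbond, dtype=int))
    hbond = np.asarray(hbond, dtype=int)
    saltbridge = np.asarray(saltbridge, dtype=int)
    if hbond.shape != saltbridge.shape:
        raise ValueError(
            f"series length mismatch: {hbond.shape} vs {saltbridge.shape}")
    return hbond + saltbridge


def occupancy(series: np.ndarray) -> float:
    """Percentage of frames in which the contact is present (count >= 1)."""
    series = np.asarray(series)
    if series.size < 1:
        raise ValueError("empty series")
    return 100.0 * float((series >= 1).sum()) / series.size


def run_lengths(series: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of consecutive present frames."""
    present = np.asarray(series) >= 1
    padded = np.concatenate([[False], present, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    return ends - starts


def mean_lifetime(series: np.ndarray, frame_interval: float) -> float:
    """Mean run length x frame interval, ns; 0 when never present."""
    runs = run_lengths(series)
    if runs.size == 0:
        return 0.0
    return float(runs.mean()) * frame_interval


def pair_stats(series: np.ndarray, frame_interval: float) -> PairContactStats:
    series = np.asarray(series, dtype=float)
    runs = run_lengths(series)
    return PairContactStats(
        strength_mean=float(series.mean()),
        strength_sd=float(series.std()),  # population SD, zero frames included
        occupancy=occupancy(series),
        mean_lifetime=mean_lifetime(series, frame_interval),
        n_events=int(runs.size),
    )


# ---------------------------------------------------------------------------
# map construction
# ---------------------------------------------------------------------------

def build_map(events: Mapping[tuple[ResidueKey, ResidueKey, str], ContactTimeSeries],
              frame_interval: float = 0.1,
              label: str = "") -> DynamicContactMap:
    """Summarise a ``detect_all`` result into a dynamic contact map.

    H-bond and salt-bridge series of the same pair are summed into the
    strength channel; hydrophobic series populate their own channel.
    """
    strength_by_pair: dict[PairKey, np.ndarray] = {}
    hydro_by_pair: dict[PairKey, np.ndarray] = {}
    for (pkey, dkey, itype), ts in events.items():
        pair = (pkey, dkey)
        target = hydro_by_pair if itype == "hydrophobic" else strength_by_pair
        if pair in target:
            target[pair] = strength_series(target[pair], ts.counts)
        else:
            target[pair] = np.asarray(ts.counts, dtype=int)

    def group(by_pair: dict[PairKey, np.ndarray]) -> dict[str, dict[PairKey, PairContactStats]]:
        out: dict[str, dict[PairKey, PairContactStats]] = {}
        for pair, series in sorted(by_pair.items()):
            role = pair[0][0]
            if role not in PROTEIN_ROLES:
                raise ConfigurationError(f"pair {pair} is not protein-first")
            out.setdefault(role, {})[pair] = pair_stats(series, frame_interval)
        return out

    return DynamicContactMap(strength=group(strength_by_pair),
                             hydrophobic=group(hydro_by_pair),
                             series=dict(strength_by_pair),
                             frame_interval=frame_interval, label=label)


def filter_map(cmap: DynamicContactMap, min_occupancy: float = 25.0) -> DynamicContactMap:
    """Keep pairs whose occupancy is at least ``min_occupancy`` percent
    (inclusive threshold)."""
    if not (0.0 <= min_occupancy <= 100.0):
        raise ConfigurationError("min_occupancy must lie in [0, 100]")

    def keep(table: dict[str, dict[PairKey, PairContactStats]]):
        return {role: {p: s for p, s in pairs.items() if s.occupancy >= min_occupancy}
                for role, pairs in table.items()}

    kept_strength = keep(cmap.strength)
    kept_pairs = {p for pairs in kept_strength.values() for p in pairs}
    return DynamicContactMap(
        strength={r: v for r, v in kept_strength.items() if v},
        hydrophobic={r: v for r, v in keep(cmap.hydrophobic).items() if v},
        series={p: s for p, s in cmap.series.items() if p in kept_pairs},
        frame_interval=cmap.frame_interval,
        label=cmap.label,
    )


def compare_maps(map_a: DynamicContactMap, map_b: DynamicContactMap,
                 label_a: str = "A", label_b: str = "B") -> MapComparison:
    """Pair-by-pair strength comparison of two conditions (e.g. wild type
    vs point mutant run on the same complex topology)."""

    def flat(cmap: DynamicContactMap) -> dict[PairKey, PairContactStats]:
        return {p: s for pairs in cmap.strength.values() for p, s in pairs.items()}

    a, b = flat(map_a), flat(map_b)
    rows = []
    for pair in sorted(set(a) | set(b)):
        (prole, pidx, pname), (strand, didx, dname) = pair
        sa, sb = a.get(pair), b.get(pair)
        rows.append({
            "monomer": prole, "protein_res": pidx, "protein_name": pname,
            "strand": strand, "dna_pos": didx, "dna_name": dname,
            "present_a": sa is not None, "present_b": sb is not None,
            "mean_a": sa.strength_mean if sa else 0.0,
            "sd_a": sa.strength_sd if sa else 0.0,
            "mean_b": sb.strength_mean if sb else 0.0,
            "sd_b": sb.strength_sd if sb else 0.0,
        })
    table = pd.DataFrame(rows, columns=["monomer", "protein_res", "protein_name",
                                        "strand", "dna_pos", "dna_name",
                                        "present_a", "present_b",
                                        "mean_a", "sd_a", "mean_b", "sd_b"])
    return MapComparison(table=table, label_a=label_a, label_b=label_b)
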
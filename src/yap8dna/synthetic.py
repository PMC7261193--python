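"""Synthetic inputs with exact ground truth for every pipeline stage.

Real inputs to this package are MD trajectories of a Yap8 homodimer on a
25-bp duplex, anisotropy titration tables, and aligned response-element
sites.  None of those can be regenerated at test time, so every stage is
instead exercised on constructed data whose expected output is known
*exactly*:

* two-state (telegraph) Markov presence series, the standard minimal
  model for a contact that forms and breaks with constant per-frame
  rates -- stationary occupancy ``p_on/(p_on+p_off)``, geometric run
  lengths with mean ``1/p_off`` frames;
* toy coordinate trajectories in which chosen residue pairs are *planted*
  at interaction-satisfying geometry exactly in the frames where their
  Markov series is on, and parked far beyond every cutoff otherwise;
* titrations generated from the exact binding isotherm, optionally with
  Gaussian noise;
* two-conformation trajectories (tail docked vs displaced) for the
  clustering stage.

Every generator returns a machine-readable truth record alongside the
data, and all randomness flows through a single seeded generator.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binding import Titration, isotherm
from .contact_dynamics import ContactTimeSeries, run_lengths
from .errors import GeneratorError
from .interactions import DetectionCriteria
from .motifs import SCACR3
from .structures_io import Topology, Trajectory

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_NUC_NAME = {"A": "DA", "T": "DT", "G": "DG", "C": "DC"}


# ---------------------------------------------------------------------------
# two-state Markov presence process
# ---------------------------------------------------------------------------

@dataclass
class MarkovContactSpec:
    """Telegraph process for contact presence.

    ``p_on`` is the per-frame probability of switching 0 -> 1, ``p_off``
    of 1 -> 0.  Stationary occupancy is ``p_on / (p_on + p_off)`` and the
    mean on-run length ``1 / p_off`` frames.  Frame 1 carries the initial
    state (off unless ``start_on``); transitions apply between frames.
    """

    p_on: float
    p_off: float
    F: int
    seed: int
    start_on: bool = False

    def __post_init__(self) -> None:
        for name in ("p_on", "p_off"):
            p = getattr(self, name)
            if not (0 < p <= 1):
                raise GeneratorError(f"{name} must lie in (0, 1]")
        if self.F < 1:
            raise GeneratorError("F must be >= 1")

    @property
    def stationary_occupancy(self) -> float:
        return self.p_on / (self.p_on + self.p_off)


def gen_markov_series(spec: MarkovContactSpec) -> tuple[np.ndarray, dict]:
    """Simulate the presence series; returns (bool array, truth record).

    The truth record holds the *realized* occupancy and run statistics of
    the emitted series (exact bookkeeping, not the asymptotic values).
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.random(spec.F)
    series = np.empty(spec.F, dtype=bool)
    state = spec.start_on
    series[0] = state
    for f in range(1, spec.F):
        if state:
            state = not (u[f] < spec.p_off)
        else:
            state = u[f] < spec.p_on
        series[f] = state
    runs = run_lengths(series.astype(int))
    truth = {
        "occupancy_pct": 100.0 * float(series.mean()),
        "run_lengths": runs.tolist(),
        "mean_lifetime_frames": float(runs.mean()) if runs.size else 0.0,
        "n_events": int(runs.size),
        "stationary_occupancy_pct": 100.0 * spec.stationary_occupancy,
        "expected_mean_run_frames": 1.0 / spec.p_off,
    }
    return series, truth


# ---------------------------------------------------------------------------
# toy protein-DNA trajectories with planted contacts
# ---------------------------------------------------------------------------

#: (protein residue name, protein atoms, DNA atom, default on/off distance);
#: atom choices are mutually silent across detectors: the ASN amide donor is
#: neutral and non-hydrophobic, the LYS ammonium at 3.8 A is outside both
#: H-bond criteria, and the LEU/thymine-methyl pair is apolar carbon only.
_PLANT_CHEMISTRY = {
    "hbond": ("ASN", (("ND2", "N"), ("HD21", "H")), "OP1", 2.8, 5.0),
    "saltbridge": ("LYS", (("NZ", "N"),), "OP1", 3.8, 6.0),
    "hydrophobic": ("LEU", (("CD1", "C"),), "C7", 5.5, 7.5),
}


@dataclass
class PlantedContact:
    """One planted residue pair driven by a Markov presence series."""

    protein_index: int
    dna_index: int
    itype: str  # "hbond" | "saltbridge" | "hydrophobic"
    markov: MarkovContactSpec
    protein_role: str = "monomer1"
    dna_strand: str = "strandW"
    on_distance: float | None = None
    off_distance: float | None = None

    def __post_init__(self) -> None:
        if self.itype not in _PLANT_CHEMISTRY:
            raise GeneratorError(f"unknown interaction type {self.itype!r}")
        defaults = _PLANT_CHEMISTRY[self.itype]
        if self.on_distance is None:
            self.on_distance = defaults[3]
        if self.off_distance is None:
            self.off_distance = defaults[4]


@dataclass
class ToyComplexSpec:
    """A minimal Yap8-like complex: a 25-bp duplex (Watson strand given
    by ``dna_seq``, Crick complementary) plus one pseudo-residue per
    planted protein position, using the conventional numbering (tails
    7-16, basic region 17-40, Y8RE at 7-19)."""

    planted: list[PlantedContact] = field(default_factory=list)
    dna_seq: str = SCACR3
    frame_interval: float = 0.1  # ns
    F: int | None = None  # frames; defaults to the planted series length

    def __post_init__(self) -> None:
        if len(self.dna_seq) != 25:
            raise GeneratorError("dna_seq must be 25 bases")
        lengths = {c.markov.F for c in self.planted}
        if len(lengths) > 1:
            raise GeneratorError("all planted series must share F")
        if self.F is None:
            self.F = lengths.pop() if lengths else 1
        elif lengths and lengths.pop() != self.F:
            raise GeneratorError("F disagrees with planted series length")
        seen = set()
        for c in self.planted:
            for k in ((c.protein_role, c.protein_index), (c.dna_strand, c.dna_index)):
                if k in seen:
                    raise GeneratorError(f"residue {k} used by two planted contacts")
                seen.add(k)


def _check_margins(contact: PlantedContact, criteria: DetectionCriteria) -> None:
    cut = {"hbond": criteria.hbond_heavy_dist,
           "saltbridge": criteria.salt_dist,
           "hydrophobic": criteria.hydrophobic_com_dist}[contact.itype]
    if contact.on_distance > cut:
        raise GeneratorError(
            f"{contact.itype} on-distance {contact.on_distance} exceeds cutoff {cut}")
    off_floor = cut + 1.0
    if contact.itype == "hbond" and criteria.hbond_dist_only is not None:
        off_floor = max(off_floor, criteria.hbond_dist_only + 1.0)
    if contact.off_distance < off_floor:
        raise GeneratorError(
            f"{contact.itype} off-distance {contact.off_distance} must exceed "
            f"{off_floor} (cutoff + 1 A margin)")


def gen_toy_trajectory(spec: ToyComplexSpec,
                       criteria: DetectionCriteria | None = None
                       ) -> tuple[Trajectory, dict]:
    """Build the toy trajectory and its exact ground-truth contact table.

    The truth record maps ``(protein key, dna key, itype)`` to the
    planted presence series (as integer counts); ``detect_all`` on the
    returned trajectory must reproduce it bit for bit, with no events for
    any other pair.
    """
    criteria = criteria or DetectionCriteria()
    for c in spec.planted:
        _check_margins(c, criteria)

    serials: list[int] = []
    names: list[str] = []
    elements: list[str] = []
    res_idx: list[int] = []
    res_names: list[str] = []
    chain_ids: list[str] = []
    roles: list[str] = []
    base_xyz: list[np.ndarray] = []

    _ROLE_CHAIN = {"monomer1": "A", "monomer2": "B", "strandW": "W", "strandC": "C"}

    def add_atom(name: str, element: str, ridx: int, rname: str, role: str,
                 xyz: np.ndarray) -> int:
        serials.append(len(serials) + 1)
        names.append(name)
        elements.append(element)
        res_idx.append(ridx)
        res_names.append(rname)
        chain_ids.append(_ROLE_CHAIN[role])
        roles.append(role)
        base_xyz.append(np.asarray(xyz, dtype=float))
        return len(serials) - 1

    planted_dna = {(c.dna_strand, c.dna_index): c for c in spec.planted}

    # interaction sites along x, parked chains far away in y
    site_of = {id(c): np.array([200.0 * k, 0.0, 0.0])
               for k, c in enumerate(spec.planted)}

    moving_atoms: dict[int, tuple[int, PlantedContact]] = {}  # atom -> contact
    truth_series: dict[tuple, np.ndarray] = {}
    series_of: dict[int, np.ndarray] = {}

    for c in spec.planted:
        rname, patoms, datom, _, _ = _PLANT_CHEMISTRY[c.itype]
        anchor = site_of[id(c)]
        for aname, elem in patoms:
            offset = np.array([1.0, 0.0, 0.0]) if elem == "H" else np.zeros(3)
            add_atom(aname, elem, c.protein_index, rname, c.protein_role,
                     anchor + offset)
        series, _ = gen_markov_series(c.markov)
        series_of[id(c)] = series.astype(int)

    # full 25-bp duplex; planted DNA residues get their interaction atom,
    # the rest a chemically inert C1' placed far from every site
    for strand, role, ypark in (("W", "strandW", 500.0), ("C", "strandC", 800.0)):
        for pos in range(1, 26):
            base = spec.dna_seq[pos - 1]
            if strand == "C":
                base = _COMPLEMENT[base]
            rname = _NUC_NAME[base]
            key = (role, pos)
            if key in planted_dna:
                c = planted_dna[key]
                p_rname, _, datom, _, _ = _PLANT_CHEMISTRY[c.itype]
                if c.itype == "hydrophobic" and rname != "DT":
                    raise GeneratorError(
                        "hydrophobic planting targets the thymine methyl; "
                        f"position {pos} on {role} is {rname}")
                elem = "O" if datom.startswith("O") else "C"
                ai = add_atom(datom, elem, pos, rname, role,
                              site_of[id(c)])  # x offset applied per frame
                moving_atoms[ai] = (0, c)
            else:
                add_atom("C1'", "C", pos, rname, role,
                         np.array([50.0 * pos, ypark, 0.0]))

    top = Topology(
        serial=np.asarray(serials),
        atom_name=np.asarray(names),
        element=np.asarray(elements),
        res_index=np.asarray(res_idx),
        res_name=np.asarray(res_names),
        chain_id=np.asarray(chain_ids),
        chain_role=np.asarray(roles),
        frame_interval=spec.frame_interval,
    )

    base = np.stack(base_xyz)
    coords = np.repeat(base[None, :, :], spec.F, axis=0)
    for ai, (_, c) in moving_atoms.items():
        s = series_of[id(c)]
        dx = np.where(s.astype(bool), c.on_distance, c.off_distance)
        coords[:, ai, 0] = site_of[id(c)][0] + dx

    rname_of = {(r, i): n for r, i, n in zip(roles, res_idx, res_names)}
    for c in spec.planted:
        pkey = (c.protein_role, c.protein_index,
                _PLANT_CHEMISTRY[c.itype][0])
        dkey = (c.dna_strand, c.dna_index, rname_of[(c.dna_strand, c.dna_index)])
        truth_series[(pkey, dkey, c.itype)] = series_of[id(c)]

    truth = {
        "events": {k: ContactTimeSeries(pair=(k[0], k[1]), itype=k[2], counts=v)
                   for k, v in truth_series.items()},
        "frame_interval": spec.frame_interval,
    }
    return Trajectory(top, coords), truth


# ---------------------------------------------------------------------------
# titrations
# ---------------------------------------------------------------------------

def default_protein_grid(n: int = 20, top: float = 200.0) -> np.ndarray:
    """The standard titration grid: n points evenly spanning 0..top nM."""
    return np.linspace(0.0, top, n)


def gen_titration(K_d: float, dA_T: float = 0.1, D_T: float = 1.0,
                  E_T: np.ndarray | None = None,
                  noise_sd: float = 0.0, seed: int | None = None
                  ) -> tuple[Titration, dict]:
    """Generate an anisotropy titration from the exact isotherm.

    ``noise_sd`` is the SD of additive Gaussian noise on dA (absolute
    units; pass e.g. ``0.02 * dA_T`` for 2% of the total change).
    """
    if E_T is None:
        E_T = default_protein_grid()
    E_T = np.asarray(E_T, dtype=float)
    if E_T.max() < K_d:
        raise GeneratorError("titration grid does not span half-saturation")
    dA = isotherm(E_T, D_T, K_d, dA_T)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        dA = dA + rng.normal(0.0, noise_sd, size=dA.shape)
    truth = {"K_d": float(K_d), "dA_T": float(dA_T), "D_T": float(D_T),
             "noise_sd": float(noise_sd), "seed": seed}
    return Titration(E_T=E_T, D_T=D_T, dA=dA), truth


# ---------------------------------------------------------------------------
# two-conformation trajectories for clustering
# ---------------------------------------------------------------------------

def gen_two_cluster_trajectory(n_per_cluster: int = 50,
                               displacement: float = 8.0,
                               jitter: float = 0.3,
                               seed: int = 0,
                               rigid_motion: bool = True
                               ) -> tuple[Trajectory, dict]:
    """Trajectory whose N-terminal tail occupies two conformations.

    A static 12-residue DNA-like anchor (one P atom per residue) serves
    as the superposition reference; ten tail residues (protein 7-16, one
    CA each) sit either docked or displaced by ``displacement`` along z,
    with per-frame Gaussian jitter of SD ``jitter``.  When
    ``rigid_motion`` is set each frame additionally receives a random
    global rotation + translation, which best-fit superposition must
    remove.  Truth carries the frame labels and the two atom selections.
    """
    if displacement <= 4 * jitter:
        raise GeneratorError("displacement must dominate jitter")
    rng = np.random.default_rng(seed)
    F = 2 * n_per_cluster

    theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    anchor = np.stack([10 * np.cos(theta), 10 * np.sin(theta), np.zeros(12)], axis=1)
    tail0 = np.stack([np.linspace(12, 30, 10), np.zeros(10), np.zeros(10)], axis=1)

    n_atoms = 12 + 10
    serials = np.arange(1, n_atoms + 1)
    names = np.asarray(["P"] * 12 + ["CA"] * 10)
    elements = np.asarray(["P"] * 12 + ["C"] * 10)
    res_idx = np.asarray(list(range(1, 13)) + list(range(7, 17)))
    res_names = np.asarray(["DA"] * 12 + ["GLY"] * 10)
    chain_ids = np.asarray(["W"] * 12 + ["A"] * 10)
    roles = np.asarray(["strandW"] * 12 + ["monomer1"] * 10)
    top = Topology(serial=serials, atom_name=names, element=elements,
                   res_index=res_idx, res_name=res_names,
                   chain_id=chain_ids, chain_role=roles)

    labels = np.repeat([0, 1], n_per_cluster)
    coords = np.empty((F, n_atoms, 3))
    from scipy.spatial.transform import Rotation
    for f in range(F):
        tail = tail0 + np.array([0.0, 0.0, displacement]) * labels[f]
        tail = tail + rng.normal(0.0, jitter, size=tail.shape)
        frame = np.vstack([anchor, tail])
        if rigid_motion:
            rot = Rotation.random(rng=rng)
            frame = rot.apply(frame) + rng.uniform(-20, 20, size=3)
        coords[f] = frame

    truth = {"labels": labels,
             "superpose": np.arange(12),
             "rmsd_atoms": np.arange(12, 22)}
    return Trajectory(top, coords), truth
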
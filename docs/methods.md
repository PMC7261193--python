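# Methods

This note documents the models and procedures implemented in `yap8dna`,
the defaults chosen where the underlying experimental protocol leaves the
definition open, and what the synthetic-data tests do and do not
demonstrate about real data.

## System and conventions

The target system is the Yap8 homodimer bound to a 25-bp duplex containing
the 13-bp Yap8 response element (Y8RE, `TGATTAATAATCA`) flanked by six
A/T-rich bases on each side (`TTTGTT-…-ACTTTA`).  Protein residues follow
the conventional Yap8 numbering: unstructured N-terminal tail 7–16, basic
region 17–40, full bZIP 7–89.  DNA positions are 1–25 per strand, 1-based
and inclusive; both strands are stored 5′→3′ internally, and the Watson
strand carries the element at positions 7–19.  Chains are addressed by
*role* (`monomer1`, `monomer2`, `strandW`, `strandC`) rather than PDB chain
id, so renaming or renumbering chains in an input file cannot change any
result.  Residue numbering itself is taken verbatim from the input PDB;
all region annotations are overridable configuration.

The trajectory frame interval defaults to 0.1 ns per frame.  It is pure
metadata — only lifetime values (ns) depend on it.  Frame striding, when
wanted, is plain array slicing of `Trajectory.coordinates`.

## Contact detection

Detection is purely geometric, per frame, restricted to protein–DNA
residue pairs, and governed by editable chemistry tables
(`src/yap8dna/data/chemistry.json`):

* **Hydrogen bond** — donor-heavy to acceptor-heavy distance ≤ 3.0 Å and
  D–H···A angle ≥ 135° at some donor hydrogen.  These thresholds follow
  the defaults of the trajectory-analysis tooling conventionally used for
  such maps.  A donor whose hydrogens are absent from the topology falls
  back to a distance-only criterion (3.5 Å); if the whole topology is
  hydrogen-free and no fallback distance is configured, detection refuses
  to guess and raises a configuration error.  Multiple simultaneous
  donor–acceptor pairs between one residue pair are counted additively,
  consistent with summing hydrogen bonds into a strength value.
* **Salt bridge** — minimum distance between any positive atom of one
  residue (Arg NE/NH1/NH2, Lys NZ) and any negative atom of the other
  (Asp/Glu carboxylates; on DNA the phosphate OP1/OP2) ≤ 4.0 Å, the common
  literature convention.  Recorded at residue-pair granularity — one event
  per pair per frame however many atom pairs qualify — to match
  residue-level contact maps.
* **Hydrophobic contact** — distance between the mass-weighted centre of
  the protein side-chain heavy atoms and that of the DNA base heavy atoms
  (backbone excluded) ≤ 6 Å.  The motivating case is leucine against
  thymine methyls, hence side chain vs base rather than whole residues.

All cutoffs are inclusive at the boundary.  The detectors are plain
all-pairs scans — the systems of interest (a dimer on 25 bp) are small
enough that spatial acceleration would buy nothing and could only risk
disagreement with the definition; tests pin the detectors to an
independently written brute-force oracle on randomized frames, and to
exact rigid-motion invariance.

## Dynamic contact maps

For each residue pair the per-frame *contact strength* is the H-bond count
plus the salt-bridge count; hydrophobic contacts are kept in a separate
channel and never enter the strength sum.  Summary statistics per pair:

* strength mean and **population** SD over all frames, absent frames
  included as zeros — this makes the reported mean and SD mutually
  consistent descriptions of the same series;
* occupancy = 100 × (frames with strength ≥ 1)/F;
* mean lifetime = mean maximal-run length × frame interval.  Runs have no
  gap tolerance: one absent frame terminates a run.  This is the simplest
  defensible definition; a gap-tolerant variant would only lengthen
  lifetimes, and sensitivity to it can be probed by smoothing the series
  before `pair_stats`.

The reporting filter keeps pairs with occupancy ≥ 25 % (inclusive, applied
to occupancy and not strength).  Map comparison (e.g. wild type vs N20A)
tabulates mean ± SD side by side for every pair in the union, flags pairs
unique to one condition, and marks a shared pair as *significant* when the
mean strengths differ by more than one SD of **both** conditions — the
conservative reading; exceeding only the smaller SD flags noise-level
differences when one condition fluctuates broadly.

## Conformational clustering

The frame-to-frame distance is a best-fit RMSD with separate superposition
and measurement sets: superpose on the Y8RE heavy atoms (so that tail
motion *relative to the binding site* is what the metric sees), measure
over the DNA heavy atoms outside the element minus the two terminal base
pairs at each end, plus the protein tail residues 7–16.  Including the
tails is the default because the clustering exists to classify tail
conformations; `include_tails=False` switches to the DNA-only variant.
Superposition uses the Kabsch algorithm (scipy `Rotation.align_vectors`).

Clustering is DBSCAN on the precomputed distance matrix (scikit-learn),
deterministic for a fixed frame order, with no sieving.  `eps` and
`min_samples` have no universal defaults and must be chosen per dataset;
the synthetic tests use eps = 1.0 Å, min_samples = 5 against planted
two-conformation trajectories.  The representative structure is the
largest cluster's medoid (minimum summed distance to the other members);
ties resolve to the lowest frame index, and equal-size clusters to the
lowest cluster label, so the choice is reproducible.

## Binding isotherm

Anisotropy titrations are described by the exact (stoichiometric,
quadratic) solution of 1:1 binding, valid at probe concentrations
comparable to K_d:

ΔA = ΔA_T/(2 D_T) · [(E_T + D_T + K_d) − √((E_T + D_T + K_d)² − 4 E_T D_T)]

The bracket equals twice the bound-probe concentration, so ΔA/ΔA_T is the
bound fraction, monotone in E_T, saturating at ΔA_T, and reducing to the
hyperbola E_T/(E_T + K_d) as D_T → 0.  The source equation for this assay
is sometimes typeset with the discriminant term garbled ("4E_T*+D_T");
only the product 4·E_T·D_T yields the standard dimensionally consistent
quadratic solution bounded by ΔA_T, and that is what is implemented.

Fitting is unweighted nonlinear least squares over (K_d, ΔA_T) — no
weighting scheme is part of the assay protocol — with K_d constrained
positive, started from the concentration at half-maximal signal and the
maximal signal, and run at tight (1e-14) convergence tolerances so that
noiseless synthetic data are recovered to machine precision.  The reported
K_d standard error is the Jacobian-based covariance estimate at the
optimum; with replicated experiments the spread across replicate fits is
the more honest uncertainty, and the Monte-Carlo test reports recovery
quantiles for exactly that reason.

## Motif flank analysis

Sites are aligned 25-mers partitioned as 6-bp 5′ flank / 13-bp core /
6-bp 3′ flank (positions 1–6 / 7–19 / 20–25; the 6+13+6 geometry is
fixed).  Position frequency matrices are counted with `Bio.motifs`.  The
flank-mutation designs replace every A/T in the designated flank(s) with
G/C — M1 mutates the 3′ flank only, M2 the 5′ flank only, M3 both —
leaving the core and any undesignated flank untouched.  The mutator
implements the design rule, not any specific published oligo: the
substitution is either a user-supplied deterministic map (A→{G,C},
T→{G,C}) or a seeded random choice.  Only the canonical ScACR3 site ships
as a constant; orthologous sites are user input.

## Synthetic data and what the tests show

Every generator emits an exact truth record, and every downstream
estimator is tested against it:

* **Markov contact series** — a two-state telegraph process with per-frame
  switching probabilities; stationary occupancy p_on/(p_on+p_off), mean
  run length 1/p_off frames.  Frame 1 carries the initial state (off by
  default).  Occupancy tests account for the series autocorrelation when
  computing the standard error of the realized mean.
* **Planted-contact trajectories** — minimal pseudo-residues (one heavy
  atom per interaction role plus required hydrogens) placed at
  criterion-satisfying geometry exactly in the on-frames and parked with
  ≥ 1 Å margin beyond every cutoff otherwise; the full 25-bp duplex is
  present with chemically inert placeholders elsewhere.  The planted
  chemistries (Asn amide donor, Lys ammonium at 3.8 Å, Leu/thymine-methyl
  pair) are chosen so each planted pair triggers exactly one detector.
* **Titrations** — generated from the isotherm itself, optionally with
  additive Gaussian noise; 20 points spanning 0–200 nM at D_T = 1 nM and
  ΔA_T = 0.1 by default, matching the assay's probe concentration and a
  grid that brackets half-saturation for the nM-range constants studied.
* **Two-conformation trajectories** — a static DNA-like anchor plus a
  10-atom tail that toggles between a docked and an 8-Å-displaced pose
  with 0.3 Å per-coordinate jitter, under random per-frame rigid motion
  that superposition must remove.

These constructions validate the estimators, the geometry, and the
bookkeeping — not the biology.  They contain no force field, no solvent,
no correlated side-chain dynamics, no base-pair breathing, and their
contact on/off process is memoryless; passing tests therefore certify
that the pipeline measures what it defines, on trajectories whose true
answer is known, and nothing more.  Problem sizes in the default suite
(50–200-frame toys, 10⁴–10⁵-frame Markov series, 200 Monte-Carlo
replicates) were chosen as the smallest giving stable statistics for the
assertions made.

## Known limitations

* H-bond geometry uses a single distance/angle class for all donor types;
  no distinction between strong/weak donors and no water-mediated bridges.
* Strength SD over a single trajectory understates between-replica
  variability; comparisons across conditions with single runs are
  descriptive, not inferential.
* DBSCAN results depend on (eps, min_samples); the package deliberately
  refuses to default them for real data.
* The PDB writer emits 3-decimal coordinates, the format's precision;
  round-trips are exact only to 10⁻³ Å.
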
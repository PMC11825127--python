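# Methods

## Scope and model

`rafdimer` computes structural readouts that discriminate monomer-selective
from dimer-compatible BRAF<sup>V600E</sup> inhibitors. It treats a kinase
structure as a set of protomers (protein chains) plus ligands, and reduces
each protomer to three conformational descriptors with fixed, literature-
standard definitions in BRAF author numbering:

* **αC position**: ‖Cα(Ile582) − centroid{Cα(Asn500), Cα(Glu501),
  Cα(Val502)}‖. The centroid is unweighted: all four atoms are Cα carbons
  of identical mass, so centre of mass and centroid coincide. Boundary
  19.6 Å; the in-state is strict (`< 19.6`), the boundary itself classifies
  as out. The boundary assignment is a measure-zero convention and is
  documented rather than load-bearing.
* **DFG pseudo-dihedral**: torsion of Cα(Ile592, Gly593, Asp594, Phe595),
  IUPAC right-hand sign, wrapped from (−180°, 180°] to [0°, 360°) by adding
  360° to negatives. The wrap is fixed by the fact that the physically
  relevant DFG-out values (≈ 210°, ≈ 290°) exceed 180°. DFG-out is the
  closed side of the 140° boundary (`≥ 140`). The implementation is checked
  against two independent torsion formulations (a projection-based oracle
  and MDAnalysis) in the tests.
* **K–E salt bridge**: both criteria are computed and reported — the
  Lys483 NZ to nearest Glu501 OE1/OE2 distance with a 4.0 Å cutoff (the
  default for probability analyses and for the classifier's "K–E
  distance"), and the minimum sidechain heavy-atom distance with a 4.5 Å
  cutoff. "Sidechain" means every heavy atom beyond Cα; Cβ is included by
  default and excludable via `include_cb=False`, since conventions differ
  on whether Cβ belongs to the sidechain for contact purposes.

Structures are read with gemmi (PDB and mmCIF). Alternate locations are
collapsed to the highest-occupancy conformer, ties broken by alt-loc
identifier order, so downstream geometry is deterministic. Hydrogens are
discarded: every cutoff in the pipeline is a heavy-atom criterion, which is
the only choice applicable to crystal structures. Waters and monoatomic
HETATM residues (ions) are never ligands. Missing residues (unresolved
activation loops are common in RAF structures) degrade per descriptor, not
per structure: `compute_descriptors` fills what it can and records the rest
in an `unavailable` map.

## Fingerprints

Hydrogen bonds are donor–acceptor heavy-atom pairs within 3.5 Å. Protein
typing comes from standard amino-acid chemistry (backbone N donates except
proline, backbone O accepts, sidechains per residue identity; histidine
ring nitrogens are typed both ways because protonation is unknown in a
crystal). Ligand typing comes from a shipped annotation table per het-code
(entries for the PHI1-, LY3009120- and vemurafenib-like synthetic ligands)
with a heuristic fallback for unannotated codes: nitrogens are
donor+acceptor, oxygens acceptor-only — again a no-hydrogens pragmatic.
Hydrophobic contacts are carbon–carbon pairs, 4.0 Å when both carbons are
aromatic and 4.5 Å otherwise; aromatic stacking is deliberately not a
separate category. Three hallmark h-bonds are flagged explicitly
(ligand→Glu501 carboxylate; the Asp594 backbone bond with its direction;
ligand→His574 backbone carbonyl) because the selectivity analysis keys on
them. When the Asp594 backbone shows h-bonds in both directions, the
ligand-accepts reading (amide carbonyl accepting from the backbone amide,
the dimer-compatible signature) takes precedence; the per-residue entries
retain both.

Back pockets BP-I…BP-IV are residue sets in BRAF numbering with a 4.5 Å
proximity criterion. Membership is configuration, not code: the shipped
default places BP-I around Lys483/the gatekeeper, BP-II in the αC/DFG back
cavity, BP-III in the subpocket vacated by Phe595 in DFG-out and BP-IV
beyond the DFG toward the HRD backbone, but any study using pocket
occupancy quantitatively should supply its own map.

## Selectivity classifier

The classifier formalises an empirical co-crystal rule: a stable
inhibitor–Glu501 h-bond restrains the αC helix the same way in both
protomers, so inter-protomer agreement of the αC position and K–E distance
is evidence of a stable h-bond, hence of dimer selectivity. Deviations are
rounded to 0.1 Å before comparison with the 0.3 Å threshold — co-crystal
geometry at 2–3 Å resolution does not support finer distinctions — and
"inconsistent" is an OR over the two metrics. Raw full-precision deviations
are kept in the returned record so borderline calls can be audited. The
rule is a screen: it does not predict potency and is not a substitute for
binding assays or simulation.

## Trajectory statistics

Descriptor series are computed per frame with the same definitions as for
static structures, vectorised over an `(n_frames, n_atoms, 3)` array. The
first 40 % of each replica is discarded by default (`floor(trim · n)`
frames), mirroring the convention of keeping the last 3 μs of a 5 μs run;
the trim is fraction-based because a frame count, not a timebase, is what a
trajectory file carries. Histograms are density-normalised with 50 bins
spanning the pooled data range unless edges are supplied; replicas, and
both protomers of a dimer, are pooled before binning. State probabilities
are per-replica frame fractions with the across-replica mean and sample SD
(ddof = 1, n = 3 in the reference setup); no autocorrelation correction is
attempted. The ligand–Glu501 series is the minimum distance between the
Glu501 carboxylate oxygens and the ligand's donor-group atoms (annotated
donors by default, overridable per het-code).

## Contact networks

Residue-pair contact probability is the fraction of frames with any
heavy-atom pair within 4.5 Å, computed with a per-frame k-d tree.
Sequence-adjacent pairs (|Δresnum| ≤ 2 within a chain) are excluded as
trivial covalent neighbours; the exclusion width is configurable.
Stable contacts (probability ≥ 0.7, closed) form a graph that is
partitioned into k = 4 communities by divisive edge-betweenness
(Girvan–Newman): edges of maximal betweenness are removed until k
components exist, ties broken by removing the lexicographically smallest
(chain, resnum) edge so the partition is deterministic. Isolated residues
do not count as communities; each joins the community of its
nearest-in-sequence assigned residue. Community-level "average contacts"
sum the pair probabilities between two communities — the expected number of
simultaneous contacts, which is one of two readings of the quantity (the
other counts frames with ≥ 1 contact); the summed-probability reading is
implemented and stated here. The difference network is holo − apo on these
sums, averaged over replicas, and the headline number is the signed sum
over community pairs spanning the two protomers, each unordered pair
counted once.

## Synthetic data

The generator exists so that every stage has ground truth. It builds
minimal protomers containing exactly the atoms the descriptors need and
controls each descriptor independently: the αC Cα triplet slides along a
fixed axis from Ile582, Phe595's Cα rotates about the central DFG bond,
Lys483's NZ slides along the carboxylate direction, and the ligand's amide
nitrogen moves along a third, orthogonal direction from OE1. Point targets
are realised exactly (to float precision; ~10⁻³ Å after a PDB round trip).
Trajectories draw per-frame values — normal for distances, wrapped-normal
mixtures for the dihedral (a sharper circular law can be substituted),
Bernoulli occupancy for the salt bridge and the ligand h-bond, with "on"
frames placed strictly inside and "off" frames strictly outside the
criterion — reproducibly from a seed, replicas on independent sub-streams
(`SeedSequence.spawn`). Default study conditions are 3 replicas × 10,000
frames. Contact scenarios plant four 3-residue blocks (N/C lobes × two
chains) whose intra-block contacts are permanent and whose inter-block
contacts toggle with planted probabilities via dedicated bridge atoms in
regions unique to each block pair, so no spurious pairs arise.

What the generator does **not** emulate: bonded geometry, sterics,
solvent, correlated dynamics, autocorrelated time series, or the
conformational coupling between descriptors. Passing tests therefore
demonstrate that the measurement pipeline is correct and statistically
calibrated — that planted parameters are recovered within stated
tolerances — not that the package's thresholds would classify any
particular real structure correctly. Reference co-crystal geometries used
in tests and in `scripts/acceptance.py` are synthetic stand-ins built to
published descriptor values, and are labelled `synthetic` wherever they are
written to disk; the same code paths accept real deposited files.

## Numerical choices and limitations

* Histogram normalisation is validated to 10⁻⁹; 2-D marginals equal 1-D
  histograms exactly when edges are shared.
* Degenerate inputs fail loudly: collinear torsion points, empty frame
  sets, zero-frame replicas, mismatched series lengths and unreachable
  community counts raise typed exceptions.
* Boundary conventions are closed on the "out"/"stable"/"occupied" side
  (αC-out at 19.6 Å, DFG-out at 140°, stable contact at 0.7, pocket
  contact at 4.5 Å) — all measure-zero choices, made once and documented.
* Deterministic outputs: identical configuration and inputs give
  byte-identical tables; randomness enters only through explicit seeds.
* Problem sizes in tests and the acceptance script (10,000-frame replicas,
  2,000-frame contact scenarios) are the package's chosen desk-scale study
  conditions; statistical tolerances are 3σ binomial bounds at those sizes.
* The community partition contract is the interface (deterministic
  k-community partition of the stable-contact graph), not a bit-match to
  any particular external network-analysis implementation.
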
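# Methods

This note documents the statistical and geometric procedures implemented in
`scamap`, the parameters that matter, the choices made where the published
SCA lineage leaves the details open, and what the synthetic benchmarks do
and do not demonstrate.

## Alignment assembly

Alignments are value objects over the 20 standard residues plus gap.
Nonstandard codes (B, Z, X, J, U, O) and `.` are normalized to gap at
construction: they carry no usable amino-acid identity for frequency
statistics, and treating them as a 21st state would distort the background
model.  Lowercase (insert-state) characters are uppercased.

**Pairwise identity** is the fraction of identical residues over columns
where *both* rows are non-gap; two rows with no mutually occupied column
have identity 0.  This one definition is used everywhere identity appears
(redundancy filtering, sequence weighting), so the 90%/95% cutoffs and the
80% weighting neighborhood are mutually consistent.

**Redundancy filtering** is a greedy scan in input order: a row is dropped
if its identity to any already-retained row exceeds the cutoff.  First
occurrence wins; the output order is the input order.  Any maximal
independent set would satisfy the contract; the greedy rule is deterministic
and order-stable.

**Length classes** follow the conventions of class definitions in sequence
databases: "longer than N" is strict (`L > N`), a window class "N to M
residues" is inclusive at both ends (`filter_by_length(...,
inclusive_min=True)`).  Lengths are measured on ungapped sequences.

**Concatenation** of subunit alignments (e.g. PurS-dimer + small-PurL +
PurQ into one row per organism) matches rows by an organism token parsed
from the header — a `[Species name]` bracket, else the suffix after the
last underscore (UniProt `NAME_ECOLI` style).  Organisms missing any
subunit are dropped.  How subunit rows should be paired across organisms is
genuinely open; the organism-token rule is this package's choice and is
isolated behind the `pairing_key` argument.

**Anchor-based merging** aligns two alignments only at column pairs
supplied from a structural superposition of one representative of each.
Between consecutive anchors, the unanchored columns of the first alignment
are emitted before those of the second, each gap-padded for the other's
rows.  Any inter-anchor ordering that preserves every row's ungapped
sequence is valid; this one is deterministic, and sequence preservation is
enforced by a property test over random inputs.

**Occupancy truncation** keeps columns whose non-gap fraction is >= the
threshold, boundary inclusive (a column at exactly 50% survives a 50%
cutoff).

## Coupling statistics

The coupling pipeline follows the published SCA lineage.  The historical
toolbox releases differ in their internal conventions, so all constants
here are declared package defaults, each configurable:

* **Sequence weights**: `w_s = 1 / |{t : identity(s,t) >= 0.8}|`, self
  included.  The effective sequence number is `sum(w)`.
* **Regularization**: `f = (1 - lambda) f_raw + lambda q` with pseudocount
  `lambda = 0.03` and a fixed 20-component background composition `q`
  shipped with the package (the composition used in the published SCA
  toolbox, renormalized to sum to 1).  Pairwise tables mix toward
  `q_a q_b` in every block, including `i = j`, where the raw block is
  `delta_ab f_raw_i^a`.  This uniform rule keeps the pairwise table
  consistent with the positional marginals and gives an exact invariant
  used as a test: a duplicated column couples to its copy exactly as to
  itself.
* **Gap handling**: gaps carry no amino-acid count, so positional sums may
  fall below 1 by the gap mass; pairwise counts use rows non-gap at both
  positions.
* **Conservation weights**: `phi = ln[f(1-q)/(q(1-f))]`, computed on
  frequencies clipped to `[1e-12, 1 - 1e-12]` so that at `lambda = 0` a
  fully conserved column yields a finite `phi`; its covariance is exactly
  zero, so the clipped value never contributes.
* **Compression**: the amino-acid-resolved covariance is reduced to one
  nonnegative magnitude per position pair by the Frobenius norm over both
  amino-acid dimensions.

**Spectral significance.** Null spectra come from alignments with every
column independently permuted across rows — this destroys inter-position
correlation while preserving each column's composition and the global
conservation signal.  Sequence weights are *not* recomputed for the nulls
(permutation changes row identities; re-weighting each replicate would
confound the null with the weighting procedure and costs an
`O(n^2 p)` identity computation per replicate).  The significance line is
the 95th percentile of the null maximum eigenvalues over 100 replicates by
default; `k_significant` counts actual eigenvalues above it.  The top
"global conservation" mode is included in the rotated set by default
(literature differs); `include_first_mode=False` drops it.

**ICA.** The significant eigenvectors are rotated by a symmetric
fixed-point iteration with the `tanh` contrast.  Because the input columns
are orthonormal, the second-moment matrix of the data fed to the iteration
is exactly the identity, so the learned unmixing matrix is exactly
orthogonal and the spanned subspace is preserved to machine precision — a
tested invariant.  Tolerance 1e-8, at most 1000 iterations, a seeded random
orthogonal initialization; non-convergence returns the best iterate with a
warning (it arises for inputs without non-Gaussian structure, where any
rotation is as good as any other).  Components are sign-oriented so the
largest-magnitude loading is positive and ordered by greedy maximal
|correlation| against the input eigenvectors.

**Sectors.** A position joins a component's sector when its loading exceeds
that component's `mean + 2 sd`; positions qualifying on several components
go to the one with the maximal loading.  The published analyses show
component projections but state no membership rule; `mean + 2 sd` is this
package's default and is reported with every sector table.  Empty sectors
are retained (with a warning) rather than dropped, so component indices
stay aligned.

**Amino-acid-level statistics.**  Co-occurrence tables are weighted 21 x 21
contingency tables (20 residues + gap) with conditionals and mutual
information in nats.  Perturbation profiles condition the alignment on a
residue at one position (subset must hold >= 5% of total weight by default)
and report `DD_j = sqrt( sum_b (phi_j^b Delta f_j^b)^2 )` per position,
with `phi` from the full alignment and both frequency sets regularized
identically, so conditioning on an uninformative residue gives exactly
zero.

## Geometry

**SASA** is Shrake–Rupley sphere sampling (960 points per atom by default;
doubling changes fixture totals by < 1%), probe radius 1.4 Å, element
radii from a fixed table (C 1.70, N 1.55, O 1.52, S 1.80 ...; unknown
elements fall back to 1.70 Å with a warning).  Hydrogens are kept in the
model but excluded from all geometry.  Relative SASA divides a residue's
total by the Gly-X-Gly maximum-exposure reference of its type; **buried**
means relative SASA < 0.25.  The threshold is a convention, not a physical
constant; every burial statistic reports it.

**Interface area** between two disjoint residue sets is
`SASA(A) + SASA(B) - SASA(A u B)` — the buried area summed over both faces
— with the one-sided value (half) reported alongside, since published
interface numbers use either convention without saying so.

**Cavities** are found on a grid (0.5 Å default): voxels outside every vdW
sphere are empty; empty space reachable by a probe rolled in from the box
boundary (flood fill of probe-center space, dilated back by the probe
radius) is bulk solvent; remaining connected empty components are cavity
candidates, reported only if they contain at least one voxel where the
probe itself could sit.  That last condition discards sub-probe surface
crevices and lattice interstices, which are neither reachable solvent nor
chemically meaningful voids.  Volume is voxel count x spacing^3; on the
hollow-shell fixture it agrees with a 0.2 Å fine-grid oracle to well
within 10% and converges between 0.5 and 0.25 Å grids.  **Depth** of a
cavity (or of an arbitrary site) is the Euclidean distance to the nearest
bulk-solvent voxel, 0 for points already in bulk.  **Lining residues** are
those with any heavy atom within 4.5 Å of a cavity voxel.

**Superposition** is the closed-form Kabsch solution with reflection
suppressed (det = +1), default pairing C-alpha atoms matched by chain +
residue number; non-identical proteins require an explicit coordinate
pairing from a sequence or structure alignment, and the pairing used should
be reported with the RMSD.  **Per-residue RMSD** applies one global
superposition, then averages over each residue's shared heavy atoms (side
chains included).

**Ramachandran classification** uses rectangular regions, alpha
`phi in [-100, -30] x psi in [-80, -5]`, beta
`phi in [-180, -45] x psi in [45, 180]` (degrees, configurable).  Termini
and residues across chain breaks (peptide C–N > 1.8 Å) are unclassifiable
and excluded from the denominators.

**Sector-on-structure report**: per sector, the burial fraction, the
conserved fraction (positions with relative entropy above the 80th
percentile of the whole profile, configurable), per-domain composition,
overlap with each cavity's lining set, and pairwise sector overlaps
`|A n B| / |A|`.  Unmappable positions are listed, never silently dropped.

## Synthetic data

The alignment generator plants co-evolution as a per-sequence hidden state
shared by all columns of a sector: each sector column emits its
state-specific preferred residue with fidelity `c` and a background draw
otherwise.  This is precisely the covariation pattern a coupling analysis
is designed to detect; it is an emulation device, not a model of how any
real family evolved.  Defaults define the benchmark conditions used
throughout the tests: 400 sequences x 100 positions, two disjoint
15-position sectors with 2 hidden states at `c = 0.9`, ten conserved
columns at dominant-residue probability 0.9, 2% gaps, and 50 appended
near-duplicates (5% point mutations) standing in for phylogenetic
redundancy.  Real alignments differ in ways the generator does not emulate
— tree-structured correlation, column-dependent gap structure, alignment
error — so passing the recovery benchmark shows the estimator detects the
covariation it models, not that any given real family will yield clean
sectors.  Mean planted-pair coupling increases monotonically with `c`
(tested at 0.6 / 0.75 / 0.9).

Toy structures use alanine-like carbon atoms with standard radii so their
truths are geometry-only: a hollow Fibonacci-lattice shell (atom spacing
~1.1 Å, sealed against a 1.4 Å probe) whose enclosed volume is computed by
an independent 0.2 Å fine-grid evaluation; two lattice globules at a set
separation (zero interface when the surface gap exceeds the probe
diameter); ideal poly-alanine helix/strand backbones built by natural
extension (NeRF) from canonical bond geometry with uniform phi/psi; and a
packed cubic-lattice globule (spacing 1.9 Å < 2 r_C / sqrt(3), hence no
internal voids) whose deep-core residues are fully buried.  Conformer
perturbation rigidly translates listed residues and jitters the rest,
recording the exact per-residue RMSD as truth.

All generators are bit-reproducible given (spec, seed).

## Problem sizes and numerics

The benchmark sizes (400 x 100 alignments, 3 seeds, 50 null replicates in
the recovery checks, ~10^5-voxel cavity grids, 10^6-sample Monte-Carlo SASA
oracle) were chosen so each acceptance property is decided by a margin
large relative to its sampling noise while the whole suite runs in a few
minutes on one CPU.  Structure coordinates are stored at PDB precision
(float32 / 0.001 Å); exactness claims for superposition (RMSD < 1e-9 Å)
are therefore stated and tested on float64 coordinate pairings, while
pipeline-level checks use the 1e-6 Å scale that survives float32 storage.
The ICA determinism contract, all seeds, and the fixed TSV float format
(`%.6g`) together make the full pipeline byte-reproducible, which the
acceptance suite checks end to end.

## Known limitations

* The coupling conventions (weighting, regularization, compression, null
  construction, ICA contrast, sector cutoff) are declared defaults in the
  published SCA lineage, not a claim of parity with any specific toolbox
  release; analyses of the same alignment with a different toolbox will
  differ in detail.
* Cavity volumes are method- and parameter-dependent; agreement with
  viewer-based published volumes should be expected only to within tens of
  percent, and the grid/probe convention should be reported with any
  number.
* Sequence weights are held fixed across permutation-null replicates (see
  above).
* No phylogenetic model anywhere: redundancy is treated by weighting and
  filtering only, and tree-induced correlation can inflate couplings in
  real families.
* The organism-token pairing rule for subunit concatenation can mispair
  paralogs within one organism; curate headers when that matters.
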
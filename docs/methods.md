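# Methods

## Angle conventions

All torsions are degrees on the half-open interval [−180, 180); +180 wraps
to −180. The half-open convention makes bin assignment at the torus seam
deterministic: a record at exactly −180 always lands in bin 0. Grids are
anchored at (−180, −180) with half-open bins [lo, hi) on both axes.
φ_i is the torsion C(i−1)–N(i)–CA(i)–C(i) and ψ_i is
N(i)–CA(i)–C(i)–N(i+1), signed by the IUPAC right-hand convention (the
implementation agrees with biotite's `dihedral` to float32 precision, and
with a construct-then-measure oracle to 1e−6°). Chain-terminal residues and
quadruples with collinear atoms are skipped and reported, not imputed.
ω and side-chain torsions are not computed.

Only the twenty canonical residues are accepted; modified residues (MSE,
SEP, …) are rejected at parse time rather than remapped, since the analysis
is defined over the canonical identities only.

## MISE bin-width optimisation

For a square grid of width Δ on both axes, the cost is C(Δ) = (2n̄ − v)/Δ⁴
with n̄ the mean and v the **population** variance (divide by the number of
bins) of per-bin counts over the *full* grid, empty bins included — the
formula is implemented exactly as printed in its source derivation;
omitting empty bins corrupts both moments, and `mise_cost` can enforce the
expected grid size. Candidate widths are restricted to integer fractions
Δ = 360/k so bins tile the torus exactly; the default sweep is
k = 10…400 (configurable — the appropriate range depends on sample size).
Cost ties break toward larger k (finer grid).

The common grid uses the sample-size-weighted mean Δ̄ = Σ N_X Δ_X / Σ N_X
and k = **floor**(360/Δ̄) bins per axis. Floor, not round: with the
published per-residue optima, Δ̄ = 1.887° gives 360/Δ̄ = 190.8, and the
published shared grid is 190 × 190 (bin width 360/190 ≈ 1.895°), which
floor reproduces and rounding would not.

## Density estimation and modal statistics

P_X(φ, ψ) is the normalised joint histogram; probabilities are stored as
fractions and converted to percent only at reporting boundaries (the
reference W_X column only reconciles with P_X^max × N_X when the fraction
is used: 0.00437 × 113,609 ≈ 496.5). Modal-bin ties are broken to the
lexicographically smallest (i, j) index and flagged; ties essentially never
occur at realistic sample sizes. Distributions with zero observations are
carried but flagged, and excluded (with a warning) from distance and
inertia computations.

## Distance topology

Distances are city-block sums over probability fractions, so the
theoretical maximum is 2 and sample-size scale cancels. Neighbour lists
sort by increasing distance with alphabetical tie-breaks (always flagged).
Open-set search generates, for every residue X and size s = 2 … L−1, the
candidate {X} ∪ (first s−1 neighbours of X) and accepts it iff every
member's first s−1 neighbours lie inside; this candidate generation is
provably equivalent to exhaustive subset enumeration (any open S equals
{X} ∪ first s−1 neighbours for each of its members), and the test suite
checks that equivalence directly on random 6–8-element matrices. Nested
accepted sets are all reported; a minimal-sets filter is available.
A boundary element of an accepted S is an outside residue whose first |S|
neighbours are exactly S while some member of S does not return the favour
within its own first |S| neighbours.

The replacement map takes, per residue, the argmin over *strictly positive*
distances (zero off-diagonal distances — duplicate distributions — cannot
be their own replacement evidence); reciprocal replacements are exactly the
mutual-nearest-neighbour pairs, and the suite cross-checks the two
computations against each other.

The pair-match probability implements the sequential pairing scheme
∏_{j=0}^{m−1} 2/((2n−2j)(2n−2j−1)) in exact rational arithmetic. This
sequential scheme is not the same count as the unordered perfect-matching
probability; the formula is implemented as defined, by design, because it
is the published convention the overlap statistic refers to.

## Inertia and correlation analyses

W_X = P_X^max · N_X and I_X = M_X/W_X. Note the printed reference I_X
column derives from unrounded peaks: recomputing from the 3-decimal
P_X^max column shifts e.g. Trp from 4.398 to 4.409, while recomputing from
the printed W_X column reproduces every I_X to ±0.001.

The strong/weak helix-former partition uses strict inequality at the
0.200 % threshold, so a residue exactly at the threshold (Trp in the
reference table) is a weak former — this matches the published set
memberships. Partition correlations with fewer than three members are
omitted with a warning rather than computed.

Mutability is the raw substitution-matrix diagonal; no rescaling across
matrix families. Significance stars on survey correlations use the
two-sided t-test p-value of Pearson R at n = 20 (the conventional test;
the thresholds 0.05/0.01/0.001 map to */**/***). The survey's mean R̄ is
unweighted across matrices, and the matrix–matrix average is taken over
unordered pairs (reported count documented in the result object).
Matrix parsing supports the NCBI whitespace-table layout (ambiguity
rows/columns B, Z, X, * dropped; symmetry over the canonical 20 enforced)
and AAindex lower-triangle blocks (default row order ARNDCQEGHILKMFPSTWYV,
mirrored). The in-repo fixtures are synthetic matrices (seeded, generated
by `scripts/make_fixture_matrices.py`); real matrices can be supplied as
files, or loaded from Biopython at run time as the tests do for BLOSUM62.

## Synthetic data generator

Each residue's (φ, ψ) samples are drawn from a mixture of bivariate
Gaussian basins wrapped onto the torus, with canonical centers
α(−63, −43), β(−120, 130), PPII(−75, 145), left-α(60, 45) and spreads of
10–25° — the canonical Ramachandran basin locations. Default per-residue
weights are constructed to satisfy the qualitative structure of observed
distributions: Gly's left-α weight is comparable to its α weight; Pro has
only α and PPII basins with PPII dominant; Ile/Pro/Thr/Val carry no weight
at φ > 0; all other residues are α-dominant with Ala the strongest helix
former. Weights are design constraints, not empirical fits to any
structure database — passing recovery tests therefore demonstrates the
statistical machinery (binning, density, distance, classification), not
agreement with real protein geometry, whose marginals are far less
Gaussian and include correlations between φ and ψ within basins.

Wrapping a plane Gaussian (rather than sampling a von Mises density) is
adequate because spreads ≪ 360°; the residual wrap-around mass is captured
analytically in the oracle by summing ±2 periodic images. The analytic
per-bin mass of a mixture factorises into 1D Gaussian CDF differences
(axis-aligned basins only) and serves as the independent oracle for modal
masses and for ranking empirical distances against true mixture distances.

Seeding: one master seed; per-residue streams derive via
`SeedSequence(master_seed, spawn_key=(index,))` with index the residue's
alphabetical position, so a single residue can be regenerated stably.
Ground truth (normalised weights, analytic modal mass) is written as a
sidecar JSON so tests never re-derive it from the samples.

## Problem sizes and numerical choices

Default test problem sizes: 300 samples/residue for pipeline-shape tests,
5,000–20,000 for recovery properties, 100,000 for the modal-mass
Monte-Carlo comparison (binomial standard errors at the analytic modal
bin; the empirical maximum is allowed slightly wider slack for selection
noise across 36,100 bins). The full synthetic pipeline at 10⁴
samples/residue runs in a few minutes on one CPU; the published-table
statistics are instantaneous.

Degenerate inputs: empty dihedral tables parse to empty collections with a
0/0/0 report; empty record sets are errors for bin-width optimisation
(fewer than 2 records cannot constrain Δ); all-zero basin weights are
rejected; zero-variance vectors make Pearson R undefined and raise.

## Known limitations

- The generator does not model φ–ψ correlation within basins, residue
  neighbour effects, or the heavy non-Gaussian tails of real Ramachandran
  data; distances between synthetic residues are much larger-scaled than
  between real ones at database sample sizes.
- The published per-residue Δ_X, P_X^max and N_X cannot be recomputed
  without the source structure database; they ship as reference constants
  and every statistic derived from them is recomputed from those printed
  inputs.
- Coordinate input handles a single chain per invocation and takes the
  first altloc; no occupancy or quality filtering is performed.
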
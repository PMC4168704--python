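# Methods

## Model

Scaffolding is cast as maximum-likelihood orientation of a bidirected
scaffolding graph. Each aligned read pair *r* is assumed correct with
probability *p_r*, independently across pairs. For a contig orientation
*O*, pairs either agree with *O* or not; the likelihood
∏_{r∈R_O} p_r · ∏_{r∉R_O} (1 − p_r) is, up to a constant, maximized by
maximizing ∑_{r∈R_O} ln(p_r / (1 − p_r)) — each agreeing pair contributes
its log-odds. Pairs between one contig pair are bundled per strand
configuration: with the links canonicalized so `contig_a < contig_b`,
(+,−) → A, (−,+) → D, (+,+) → B, (−,−) → C. A and D require the contigs
in the same relative orientation, B and C in opposite orientation.

### Probability models

- `uniform`: constant p₀ (default 0.9; any value > 0.5 reduces the
  objective to counting concordant pairs, which the test suite verifies
  against a counting oracle).
- `repeat`: fraction of the two mates' aligned bases outside annotated
  repeat intervals (both mates' bases are used).
- `coverage`: 1 − |cov_i − cov_j| / (cov_i + cov_j), with the convention
  that two zero-coverage contigs are maximally similar (p = 1). Coverage
  is total aligned bases divided by contig length, computed from all
  alignments including randomly allocated multi-mappers.
- `product`: repeat × coverage (the CLI default).

All probabilities are clamped to [ε, 1 − ε] with ε = 10⁻³ so log-odds
stay finite. Note the coverage model systematically penalizes very short
contigs (reads must fit entirely inside a contig, so short and truncated
contigs show depressed coverage); on such contigs a true link can receive
p < 0.5 and be declined by the optimizer. The `repeat` or `uniform`
models avoid this if it matters for a given assembly.

## Orientation ILP

Binary variables: a flip bit S_i per contig, a parity S_ij per edge, and
indicators A_ij, B_ij, C_ij, D_ij, at most one of which may be 1.
Constraints force S_ij = S_i ⊕ S_j (four linear inequalities), restrict
A/D to S_ij = 0 and B/C to S_ij = 1, and forbid directed 3-cycles: with
the precedence convention that A and B assert `contig_a → contig_b` and
C and D the reverse, both rotations of every triangle get
P(i→j) + P(j→k) + P(k→i) ≤ 2. Two-cycles cannot occur (one state per
edge); cycles longer than 3 are broken after solving by deselecting the
minimum-weight edge of each remaining cycle — removing the least
likelihood mass, since the exact rule is open.

The ILP is solved exactly with HiGHS through `scipy.optimize.milp`
(integrality tolerance 10⁻⁶, deterministic). Edges may remain unselected;
selected states with non-positive weight are normalized to "unselected"
(they contribute nothing and the normalization removes solver tie-break
nondeterminism). A brute-force enumerator over all 2^|V| flip
assignments — greedy per-edge state choice plus exact search over
triangle-involved edges — provides an independent oracle for components
of ≤ 15 nodes; ILP and oracle agree on every random instance in the test
suite.

### Precedence: convention vs. physical direction

The fixed state→precedence convention above is what the cycle
constraints and the cycle breaker operate on, but it is not covariant
under flips: the physically realized direction of a selected state
depends on the flip bit of the lexicographically smaller endpoint
(state A with both contigs flipped places `contig_b` first). Chain
extraction, gap estimation and evaluation therefore use the physical
direction (`a → b` iff the a-side mate's final strand is '+'). Mixing
the two would break perfect-recovery behaviour on randomized contig
orientations; keeping the convention inside the ILP is harmless because
the constraint system depends on flips only through parities.

## Non-serial dynamic programming

The ILP decomposes along vertex cuts because all constraints follow the
edges of the scaffolding graph. Connected components are independent.
Within a component, the decomposition recursively splits at articulation
points (1-cuts) and at separation pairs (2-cuts), producing a tree of
2-/3-connected pieces. Each piece with a 2-cut boundary {i, j} is solved
twice — boundary vertices fixed to equal (sol₀₀) and to opposite (sol₀₁)
orientations — and contributes sol₀₀ + (sol₀₁ − sol₀₀) · S_ij to its
parent's objective. The bonus is attached to the parity variable (a
zero-weight virtual edge when the parent lacks a real (i, j) edge) so it
also applies when no state is selected on that pair. Pieces behind a
1-cut are solved once with the cut vertex fixed and enter as constants.
A top-down pass then picks, per child, the stored solution matching the
parent's realized boundary parity, inverting the whole child solution
when the boundary orientations disagree — valid because flipping every
contig of a component leaves the objective unchanged.

Two details keep the two-solve scheme *exact* (the test suite checks
equality with the monolithic ILP on hundreds of random decomposable
graphs):

- the whole constraint system depends on S only through parities, so a
  child's optimum is a function of its boundary parity alone;
- a separation pair {u, v} is only used when all common neighbours of u
  and v lie on one side of the cut, and the (u, v) edge travels to that
  side — otherwise the split would tear a triangle apart and its 3-cycle
  constraint would be lost.

The decomposition is defined by contract (split until no valid cut
remains); the quadratic separation-pair search is adequate at the
component sizes the thinning heuristic guarantees, and an SPQR-tree
implementation would be a drop-in optimization. The thinning heuristic
raises the bundle threshold by one and recomputes the decomposition
until no component exceeds `max_component_nodes` (default 500).

## Linearization and gap estimation

Selected edges, taken with their physical directions, are linearized by
maximum-weight bipartite matching between successor slots and
predecessor slots; matched edges form vertex-disjoint simple paths, and
unmatched contigs become singleton scaffolds. Before matching,
transitively implied selected edges (u → w alongside selected u → v and
v → w) are set aside: such long-range links span a short intervening
contig and support the same layout — often with *more* pairs than either
direct adjacency, so letting them compete in the matching would bypass
the middle contig. Their pairs still inform gap estimation. A residual
matched cycle (defensive case) is opened at its weakest edge.

Offsets are stored per mate as the distance from the 5′ alignment start
to the contig end the read points toward; this is invariant under contig
flips, and a concordant pair spanning gaps implies
insert = offset_u + Σ(g_t + interior lengths) + offset_v, linear in the
gap vector g. Gaps per chain minimize Σ_r (i_r(g) − μ)²/σ² subject to
g ≥ g_min (default −read length, allowing unmerged overlaps) — a
bound-constrained linear least squares solved with `scipy.optimize.
lsq_linear`. Adjacencies with no concordant spanning link fall back to a
configured default (100 bp).

Two selection effects are corrected:

- *Insert model.* μ and σ default to weighted median / 1.4826·MAD of
  same-contig pair inserts (when ≥ 100 exist, else configured values).
  Same-contig observation is length-biased toward short fragments (an
  insert i fits in Σ_c max(L_c − i + 1, 0) positions), so observations
  are weighted by the inverse placement count.
- *Spanning pairs.* Pairs observed to span a gap are biased toward long
  inserts. The fit is repeated once with each link's target replaced by
  the conditional mean E[X · w(X)] / E[w(X)], where w is the exact
  placement count given the flank lengths, the current gap-region
  estimate and the discordance cutoff, computed on a grid over μ ± 5σ.
  Uncorrected, gap estimates run ≈ σ²/window (tens of bp at σ = 300)
  short; corrected, the pooled bias on simulations is within a few bp.

Scaffolds are written as AGP v2.1 (one W line per contig, one N line per
gap with gap_type `scaffold`, linkage `yes`, evidence `paired-ends`) and
as gapped FASTA (60-column, reverse-complementing flipped contigs,
spacer max(1, round(g)) Ns). Raw — possibly negative — gap estimates are
preserved in `# gap-estimate` comment lines so the AGP round-trips
exactly. Scaffolds are named `scaffold_<k>` by decreasing span.

## Synthetic benchmark

The generator emulates the simulated-contig protocol used to evaluate
scaffolders: contig and gap sizes drawn alternately, with replacement,
from empirical size lists until a linear genome is exhausted; each
contig emitted in a random orientation; the true layout recorded. The
default size lists span 2–20 kb, skewed toward short contigs as
short-read draft assemblies are (mean ≈ 5.8 kb — a 1 Mb genome yields
≈ 160–190 contigs), with gaps of 50–500 bp. Read pairs are innie with
Gaussian inserts (default μ = 3000, σ = 300, 100 bp reads, 5× read
coverage), placed uniformly; a mate overlapping a gap is unmapped; with
probability `chimera_rate` the second mate is relocated uniformly.

What the generator does *not* emulate: sequencing errors and quality
scores, repeat-induced multi-mapping (every simulated mate maps
uniquely), chimeric contigs/assembly errors, coverage biases (GC,
mappability) and multiple libraries. Passing tests therefore demonstrate
the correctness of graph construction, optimization, linearization and
gap calibration under the stated noise model — not robustness to
repeat-rich real data, where the repeat/coverage probability models and
bundle thresholds have to do real work.

Accuracy metrics: adjacency MCC over the bundled edges of the
scaffolding graph as candidate universe (an all-pairs universe would be
TN-dominated and uninformative); a realized adjacency counts as TP only
if the contigs are genomically adjacent and order and orientation match
up to reading the chain backwards. N50 uses the standard
cumulative-half definition with gap lengths counted toward spans; TPN50
is the N50 after splitting chains at every non-TP adjacency, so
TPN50 ≤ N50 with equality iff no join is wrong. Orientation accuracy
allows one global flip per chain and ignores singletons.

## Defaults and numeric choices

| parameter | default | notes |
|---|---|---|
| ε probability clamp | 10⁻³ | keeps log-odds finite |
| p₀ (uniform model) | 0.9 | any value > 0.5 ranks identically |
| min_bundle | 2 | avoids singleton-pair noise |
| k_sigma discordance cutoff | 3 | drop if offset sum > μ + 3σ |
| max_component_nodes | 500 | thinning threshold |
| g_min | −read length | permits small overlaps |
| default gap (unsupported) | 100 bp | |
| MILP integrality tolerance | 10⁻⁶ | HiGHS, deterministic |
| insert model | estimate if ≥ 100 same-contig pairs | else config μ, σ |

Determinism: nodes, edges and candidate cuts are always iterated in
sorted order; all simulation randomness flows from explicit seeds; equal
runs produce byte-identical outputs.

## Known limitations

- Single library only; no mate-pair/long-insert mixing.
- The likelihood scores at most one state per edge rather than all
  concordant states of an orientation; this mirrors the ILP formulation
  the method is built on and keeps the objective linear.
- 3-cut decomposition is not implemented; oversized triconnected
  components are handled by thinning instead.
- The exact 3-cycle constraint set and the matching/QP constructions are
  reconstructions consistent with the formulation's main text; their
  precedence convention is documented above.
- Gap estimates between contigs joined only by multi-gap spanning links
  are weakly determined; the QP handles the coupling but their variance
  is accordingly larger.
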
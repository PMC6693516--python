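# Methods

This package reconstructs, as tested code, a computational workflow for
asking how bacterial colonization reshapes host metabolism when the only
molecular readout is multi-condition differential expression: discretize
gene activity, extract context-specific metabolic networks, summarize
pathway-level activity shifts, and rank gene knockouts by their ability
to push the metabolic state of one dietary condition toward another.
The workflow is the one used to study *C. elegans* colonized by two
*Ochrobactrum* microbiota isolates (MYb71, MYb237) against an *E. coli*
OP50 control across six developmental time points; the package runs on
any model + DE-table pair with that factorial shape.

## Model substrate

A metabolic model is stoichiometry, flux bounds, a subsystem (pathway)
label per reaction, and a boolean gene-protein-reaction (GPR) rule per
reaction. GPRs are evaluated over the tri-valued lattice OFF = −1 <
UNKNOWN = 0 < ON = +1 with AND = min and OR = max; restricted to
definite states this is ordinary boolean logic, and UNKNOWN propagates
conservatively. A gene knockout blocks a reaction exactly when the GPR
evaluates false with that gene OFF and all others ON, i.e. when no
isozyme route survives. Models are read from a native JSON dialect
(schema tag `ctxmetanet-model-v1`, documented by `model_core`) or from
SBML Level 3 with fbc gene associations; subsystems travel as SBML
groups. SBML I/O is delegated to cobra; everything the analysis does
with the model is implemented here.

## Step 1 — activity discretization

Input rows are (gene, side A, side B, log2 fold-change, adjusted
p-value), where the sides are (condition, timepoint) cells: all
condition pairs at each time point plus adjacent time points within
each condition. Only genes with at least one comparison at adjusted
p < α (default 0.05, strict) are eligible for a call; all other genes
are left open (UNKNOWN) everywhere. Each significant comparison with
|log2FC| ≥ `lfc_min` (default 0: significance alone gates the vote)
casts an ON vote for its higher side and an OFF vote for its lower
side; a context's state is the strict majority of the votes it
receives, with ties and empty ballots left UNKNOWN. Majority voting is
the package's concrete reading of "most likely activity state": it is
the simplest estimator that is sign-symmetric (negating every
fold-change swaps ON and OFF exactly) and it is exposed as a pluggable
`vote_policy` for alternatives.

## Step 2 — context-specific networks (iMAT)

Gene states are lifted to reaction evidence through the GPRs (min/max
lattice), giving high-evidence (`r_high`) and low-evidence (`r_low`)
reaction sets. The iMAT MILP then picks a steady-state flux vector
(S·v = 0, bounds) maximizing the number of satisfied labels: a high
reaction counts when |v| ≥ ε (default 1.0 against default bounds ±1000,
which keeps big-M moderate), a low reaction when v = 0. Indicator
constraints are written as big-M inequalities with M from the bounds and
solved with HiGHS through `scipy.optimize.milp` (single-threaded and
deterministic). Activity is read off the single returned optimum as
|v| > δ (δ = 1e−6); enumeration of alternative optima is deliberately
not the default, since one network per context is reported. A
brute-force oracle enumerates all satisfaction assignments (≤ 16
evidence labels) with per-assignment LP feasibility checks and must
agree with the MILP objective on every bundled fixture.

The source state handed to knockout scoring, `v_ref`, is the
L1-norm-minimal flux supporting the context network: minimize Σ|v|
subject to steady state, bounds, and the directional ε-constraints of
the high-evidence reactions the optimum satisfied. L1 minimality makes
the reference sparse and deterministic.

## Pathway activity

Per context, active reactions are counted per subsystem (counts conserve
the active-set size by construction). Diet shifts are differences of
mean counts between context groups, ranked by absolute value with
lexicographic tie-breaks; the top 8 mirror the headline figure of the
motivating study. Ordination is a centered PCA of the binary
context × reaction activity matrix (profiles of subsystem counts are
available behind a flag); binary activity is the default because the
networks themselves, not their summaries, are the objects compared.

## Steps 3–4 — gene-level transformation scoring (MTA)

For a source context (e.g. growth on MYb71) and a target context (e.g.
growth on OP50) at the same time point, the target change sets are
derived from the source-vs-target DE comparison: genes significantly
higher in the target mark every reaction whose GPR mentions them as
required-up (`r_forward_up`), significantly lower genes mark theirs as
required-down; a reaction marked in both directions is a conflict and
stays steady, as does any down-marked reaction whose reference flux is
already below the required change ε_change (default 0.5 — half the iMAT
activity threshold, so one "unit" of activity can meaningfully drop).
All remaining reactions form `r_steady`.

The default scoring policy predicts the network's *forced response* to a
knockout: the post-knockout flux v\* is the feasible flux closest to
`v_ref` in L1 norm with the blocked reactions pinned to zero (a
MOMA-style LP — minimization of metabolic adjustment). The
transformation score is

TS = n_succ / |r_forward| − λ · D / (Σ_steady |v_ref| + 1)

where n_succ counts required-up reactions with |v\*| ≥ |v_ref| + ε_change
plus required-down reactions with |v\*| ≤ max(|v_ref| − ε_change, 0),
D = Σ_steady |v\* − v_ref|, and λ = 1 weights the steady-deviation
penalty (the +1 in the denominator guards empty or zero-flux steady
sets). With no required changes TS reduces to the pure penalty term.

The null (empty) knockout leaves the network exactly at `v_ref`, so
TS_null = 0; it is the natural significance threshold, and a positive
TS certifies that the knockout *forces* movement toward the target. The
obvious alternative — scoring the *best-case* flux the knockout still
allows via a two-stage optimization (MILP maximizing n_succ, then LP
minimizing D) — is implemented as policy `"optimistic"`, but it cannot
rank knockouts against a null threshold: blocking reactions only
shrinks the feasible polytope, so the null knockout is provably optimal
under it (a property the test suite asserts). The forced-response
policy is therefore the default; both are pluggable.

Per run, scores at or below the threshold are zeroed and the remaining
m genes are replaced by rank/m (ascending, average ranks for ties), so
the best gene scores 1 — this makes runs comparable, since raw TS
magnitudes vary between runs while their order is stable. Genes
blocking no reaction score TS_null by construction; identical blocked
sets share one solve. Robustness comes from five bootstrap runs per
comparison, each removing a uniformly random 10% of genes (all their DE
rows — the analysis is gene-level, so removal is per gene) and
recomputing everything from discretization onward. A *set* of runs
spans both microbiota-vs-control comparisons, all time points, and the
full-data run plus its bootstraps; set scores are per-gene means of the
rank-normalized scores rescaled to a maximum of 1. The overall score
sums a gene's forward-set scores across omics layers and subtracts the
reverse-set scores, so it is positive for mediators of the
microbiota → control transition, negative for the reverse, and exactly
antisymmetric under swapping the directions. With one layer it lies in
[−1, 1], with two in [−2, 2].

## Transcriptome-side stages

**Clustering.** Gene log2 fold-change profiles (microbiota vs control
per strain × timepoint) are clustered with Lloyd's K-means, best of 25
seeded restarts per k over k = 2…15, and the cluster number is chosen
by AIC under a spherical Gaussian model with each gene profile as one
observation:

AIC(k) = n · ln(RSS / n) + 2 · k · d

with n genes, d contrasts, RSS the within-cluster sum of squares
(floored at 1e−12 for the degenerate zero-RSS case) and k·d mean
parameters. The per-cell form n·d·ln(RSS/(n·d)) + 2·k·d was evaluated
and rejected: its likelihood term grows with n·d while its penalty does
not, so splitting pure-noise clusters always pays and the criterion
decreases monotonically past the true k on exactly the kind of data
this stage targets (measured here: it picked k = 14–15 on 8 planted
clusters in 10/10 seeds, versus 10/10 correct for the per-observation
form). BIC is available as an alternative. Heatmap export orders rows
cluster-contiguously, by correlation with the cluster mean within each
cluster; rendering is left to external tools.

**Signature overlap and concordance.** Venn counts of two DE gene sets
are plain set arithmetic. Transcript–protein concordance reports the
Pearson correlation of shared-gene fold-changes plus
consistent-direction counts among significantly changed proteins
(percentages relative to the up- and down-regulated protein counts);
the significant-protein set is an explicit argument because the
fold-change maps alone do not carry significance. Sample-level
expression PCA (first three components of centered log-scale profiles)
is included as supporting plumbing.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *shape* of the study — 3 conditions
(OP50, MYb71, MYb237) × 6 time points (L2/6 h through Ad7/216 h) × 3
replicates (2 for one cell in the real study) — and plants ground truth
at the level the pipeline consumes: DE summary statistics, not reads or
counts. Differential-expression fitting is out of scope, so p-values
are simulated directly: a comparison whose planted states differ draws
log2FC from Normal(±effect, noise) with the sign toward the ON side and
padj from U(0, 0.01); agreeing or UNKNOWN comparisons are null —
log2FC ~ Normal(0, noise), padj ~ U(0.2, 1) — except a 1% false-positive
fraction drawn with padj < 0.05. Defaults (effect 3 log2 units, noise
0.3, FP 0.01) describe a strong, clean response; an optional
negative-binomial count emitter exists for interface demos only.
Planted activity patterns differ between conditions and may invert once
along time; genes whose planted state never differs across any
comparison are statistically indistinguishable from unknowns, so the
default truth plants such genes as UNKNOWN rather than pretending they
are recoverable. Planted fold-change clusters (default 8, mirroring the
study's 8-cluster solution) use mutually orthogonal mean profiles of
norm 3 log2 units with 0.3 noise — centres √2·3 ≈ 4.2 apart, i.e. ≥ 5
noise SDs.

The toy models are deliberately small. The fixed diamond (8 reactions,
5 metabolites, 6 genes) routes uptake through branch A or branch B to a
shared join and secretion; branch A is gated entirely by gene gA and
branch B by gB, so gA's knockout blocks exactly branch A and provably
forces all throughput onto branch B — a planted mediator with a
paper-and-pencil guarantee. A reversible cross reaction (gated by gX,
zero in every reference state) and a GPR-orphan gene (gU) plant the
no-effect cases. What passing tests on these fixtures shows is that
the machinery is correct — discretization recovers recoverable states,
the MILP matches exhaustive enumeration, the planted mediator tops the
ranking; it does not show that a genome-scale reconstruction with
thousands of reactions, incomplete GPRs, and noisy real DE calls would
yield biologically clean mediator lists.

## Numerical choices and problem sizes

* ε = 1.0, δ = 1e−6, big-M from the ±1000 default bounds; steady-state
  residuals are checked against 1e−6.
* All LPs/MILPs run on HiGHS, single solve path, no randomization; all
  randomness flows through explicit integer seeds
  (`numpy.random.default_rng`), so every artifact is byte-reproducible
  and the pipeline manifest records content hashes to prove it.
* Success counting in TS uses a 1e−6 tolerance on the ε_change
  inequalities.
* Ranking uses average ranks for ties; top-k pathway selection breaks
  ties lexicographically; gene enumeration order never affects scores.
* Default verification sizes — chosen as the smallest sizes at which
  every planted structure is non-trivially expressed: 80-gene bundles
  over the full 3×6 design for state recovery (5 replicate seeds),
  the 6-gene diamond scenario with 5 bootstraps × 2 directions ×
  2 time points for mediator recovery (5 replicate seeds), 400 × 12
  fold-change matrices for cluster-number recovery (10 seeds).

## Known limitations

* The MTA score here is a documented stand-in with the published
  contract (threshold exists, higher is better, order is what is
  aggregated); the original score formula is not reprinted in the
  motivating study and is not reproduced verbatim.
* iMAT reports one optimum; alternative optima can relabel
  individually active reactions (the objective is unique, the active
  set need not be). The optional enumeration flag exists but is off.
* Discretization is per-context majority voting; it does not model
  vote dependence (the same comparison feeds two contexts) and cannot
  call genes whose expression never differs between compared cells.
* The proteome layer is assumed to arrive in the same DE-table schema
  and is discretized by the identical rule; no proteomics-specific
  error model is applied.
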
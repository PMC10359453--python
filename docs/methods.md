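# Methods

This note documents the statistical procedures, conventions and numerical
choices behind the package, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Coordinates and alphabet

Alignment columns and reference residue positions are both 1-based and
closed.  A `ReferenceMap` ties column *c* to reference position *p* iff the
reference sequence (*Msm*UdgX by default) has its *p*-th non-gap character
in column *c*; columns where the reference is gapped have no reference
position, and all reporting uses reference numbering ("position 53").

The residue alphabet is the 20 standard amino acids plus gap `-` and
unknown `X`.  Ambiguity and non-standard codes (B, Z, J, U, O, `*`, `.`)
are normalised to `X` on input with a logged warning; `X` never enters any
residue statistic.  Gapped alignments are accepted and gaps handled
explicitly throughout, so the pipeline works whether or not the upstream
aligner emitted gaps.

## Conservation statistics

Per-column frequencies, consensus and Shannon entropy are computed over
countable residues only (gaps and `X` excluded), keeping entropy
well-defined at partially gapped columns.  Entropy is in **bits** (base-2);
the base is a convention and documented rather than inherited.  Consensus
ties are broken alphabetically by one-letter code — real ties are vanishing
at these sample sizes, but a deterministic rule is required for
reproducible tests.

**Percent occurrence** deliberately uses a different denominator: counts
are divided by the *total* number of aligned sequences, with gaps and `X`
reported as their own categories, matching the convention of
published percent-occurrence plots for this family.  The two denominators
are both exposed because they answer different questions (composition of
observed residues vs composition of the sample).

Joint entropy and all pairwise statistics use **pairwise deletion**: a
sequence contributes to a column pair iff it holds a countable residue at
both columns.  Listwise deletion was the alternative; pairwise keeps more
data at unevenly gapped columns and is the variant implemented, flagged
here because the choice can matter for heavily gapped real alignments.

## Subfamily partitioning

A signature is an ordered set of (position, allowed residues) constraints;
a sequence matches iff every constrained column holds an allowed residue
(gaps/`X` never match).  The defaults encode the family's diagnostic
residues: R107/H109 for UdgX-type sequences, P107/N109 for canonical
family-4 UDGs.  Sequences matching neither signature (e.g. R107 without
H109) are reported as *unclassified* rather than assigned to a side,
because real similarity-search samples are not guaranteed to split
cleanly.

"Conserved above threshold" is a **strict** inequality (a column at
exactly 95 % does not pass a 0.95 threshold), and within a subfamily the
conservation denominator is countable residues at that column.  A position
is "unique" to subfamily A when it is conserved above threshold in A and
B's consensus residue differs; B's own conservation level is not required,
mirroring the original filter-then-compare procedure.

Co-occurrence of a query residue (default Q53) is the fraction of
anchor-signature matches that also carry the query residue — a conditional
frequency, not a correlation; the coevolution metrics below provide the
complementary symmetric view.

## Coevolution metrics

Mutual information is computed from the pairwise-deletion contingency
table in bits; zero cells contribute nothing.  The test suite verifies the
identity MI = H(i) + H(j) − H(i,j) against entropies computed by an
independent code path.  The chi-square statistic uses observed categories
with dof = (r−1)(c−1), no continuity correction; degenerate single-row/
column tables score 0 with dof 0.  The Pearson-correlation metric is
implemented as the **phi coefficient between consensus indicators** (per
sequence: does it carry the column's consensus residue?).  This is a
documented stand-in — web servers for alignment covariation do not publish
their exact encoding of "Pearson correlation" between categorical columns
— and it is isolated behind the metric interface so an alternative encoding
is a one-function change.  Zero-variance indicators make phi undefined; it
is returned as NaN and flagged, never silently zeroed.

No average-product correction (APC) is applied by default, since the
analysis this reproduces used raw scores; `apc=True` enables it.

Clustering converts scores to distances d = 1 − s/max(s) over off-diagonal
entries (|s| for phi; joint entropy, where *low* values mean
co-conservation, is used directly after scaling) and applies
**average-linkage** hierarchical clustering with ties resolved by position
order.  The linkage choice is a documented default, not a claim about the
original tool's internals; the planted-truth tests check the recovered
topology (the {53, 107, 109} clade), which is robust across linkages at
the planted effect sizes.

## Kinetics

Initial rates are ordinary-least-squares slopes of product (nM) against
time (min), requiring ≥ 3 points; the slope's standard error is reported.

The default estimator is the **Lineweaver–Burk** fit: unweighted OLS of
1/v on 1/S, with V_max = 1/intercept and K_m = slope/intercept.  It is the
estimator used for the published mutant parameter table, which is why it
is the default despite its well-known statistical fragility (reciprocal
transformation over-weights the least precise low-rate points).  Standard
errors of (V_max, K_m) are obtained by the delta method from the full
slope–intercept covariance; the error propagation method is this package's
choice, as the source table does not state one.  Non-positive rates are
excluded with a warning (their reciprocals are undefined); a non-positive
intercept aborts the fit with an error rather than returning a negative
V_max.  A two-point fit is exact and flagged `saturated` with SEs reported
as 0.

The **direct nonlinear fit** (`method="mm"`, Levenberg–Marquardt via
`scipy.optimize.curve_fit`, initialised from the LB estimates) serves as a
cross-check: on noiseless data the two agree to ~1e-6 relative, and under
multiplicative noise the nonlinear fit is verifiably less biased — both
facts are asserted by simulation in the test suite.

Derived quantities use unrounded estimates: k_cat = V_max/[E_t]
(default [E_t] = 200 nM, the assay's enzyme concentration) and
k_cat/K_m, whose SE again follows by the delta method.  Report rounding
follows the published layout (V_max/K_m to 2 dp, k_cat to 3 dp, efficiency
×10⁻³ to 3 dp).

The bundled reference table of mutant parameters reproduces a published
source and is treated as *input*.  Two internal inconsistencies of that
table are preserved, not repaired: the H109S/E52N row prints a turnover
(0.006 min⁻¹) that does not equal its V_max/[E_t] (0.011), and the printed
efficiency column differs in the third decimal from k_cat/K_m recomputed
from the printed k_cat and K_m.  Consistency checks therefore gate on the
k_cat column for the self-consistent rows only, and fold-change
comparisons involving the E52N turnover/efficiency are made on the printed
columns themselves.

The substrate series helper converts a label-dilution design
(0.1 pmol labelled + 0.5…30 pmol unlabelled in 10 µl) to nM
(pmol/µl = µM), giving the canonical 60–3010 nM grid.

## Structure geometry

PDB files are parsed with gemmi; one atom is kept per (chain, residue,
atom name), the highest-occupancy alternate location winning with ties
going to altloc A.  Distances are plain Euclidean norms between uniquely
resolved atoms; ambiguous or empty selections raise errors naming the
selector.  Because deposited structures differ in which His side-chain
nitrogen is modelled toward a bonding partner, distance queries take
explicit atom names, and bond-length checks should take the minimum over
{ND1, NE2} rather than assume nomenclature.

Superposition is the Kabsch algorithm: SVD of the covariance of the
centred point sets, with the determinant sign correction that excludes
reflections (rotation orthonormality is asserted to < 1e-8 in tests, and
the rotation is cross-checked against an independent alignment routine).
Rank-deficient (collinear) inputs are flagged `degenerate` but still
solved.  Cross-structure Cα RMSD pairs residues by residue-number
intersection on the chosen chain — appropriate for point mutants of one
protein, *not* for homologs, which would need a sequence alignment first —
and requires ≥ 3 shared Cα atoms.

## Synthetic data: what it emulates, and what it does not

The alignment generator emulates the structure assumed by the original
counting analysis: a large similarity-search sample containing two
subfamilies distinguished by fixed residues, with star-topology
independence between sequences.  Defaults are the study conditions used
throughout the tests: 2000 sequences (plus a deterministic reference as
first record), 200 columns, an even subfamily split, subfamily residues
Q/R/H vs A/P/N at 53/107/109 planted at conservation 0.99, and background
columns whose consensus appears with probability 0.4.  The background
level was chosen so that no background column can pass the 0.95
conservation filter at n ≥ 500 — a property the test suite verifies rather
than assumes.  Optional coupled column pairs draw a shared two-state
indicator (consensus vs a designated alternative residue, 0.5 marginal)
whose states match with the pair's coupling probability ∈ [0.5, 1]; a
position may not be both coupled and a subfamily-differing signature
(configuration error).

What the generator does **not** emulate: phylogenetic correlation between
sequences (which inflates covariation statistics on real alignments),
alignment error, gaps, or compositional bias.  Passing planted-truth tests
therefore demonstrates correctness of the counting, partitioning and
information-theoretic machinery under the generative model — it does not
certify biological conclusions on real MSAs, where phylogeny is the
dominant confounder of MI-style statistics.

Kinetics noise is multiplicative Gaussian on rates (roughly constant CV
across substrate levels, as in gel-quantified assays), truncated positive
by redrawing; time courses are linear with per-point multiplicative noise
and warn when product exceeds 10 % of substrate (the initial-rate regime
assumption).  At the published V_max/K_m and [E_t], low-substrate courses
genuinely strain that assumption over 8 min — the warning fires by design.
Toy structures are ideal α-helical Cα traces (2.3 Å radius, 1.5 Å rise,
100°/residue) with optional isotropic jitter; per-axis σ = 0.2/√3 Å gives
an expected superposed RMSD of 0.2 Å, the scale of agreement between
point-mutant crystal structures.

## Problem sizes and determinism

Test and acceptance runs use 2000-sequence × 200-column alignments,
200-replicate noise simulations for estimator calibration, and
400-residue traces for RMSD checks — sizes at which every binomial
tolerance in the tests has ≥ 5σ slack while the full suite completes in
seconds.  All randomness flows through `numpy.random.default_rng` seeded
from explicit integer seeds; identical seed and truth give byte-identical
outputs, and pipeline reports echo their configuration for provenance.

## Known limitations

* The phi-coefficient encoding of categorical correlation is one of
  several defensible choices (see above).
* Fold-change labels round to the nearest integer; the raw ratio is always
  reported alongside.
* The structure stage assumes shared residue numbering; no sequence-based
  pairing is implemented.
* The LB estimator's fragility under heteroscedastic noise is inherited by
  design (table-matching default); use `method="mm"` for inference.
* Cavity-volume analysis and alignment construction are out of scope; the
  pipeline consumes an already-aligned MSA.
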
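# Methods

## The prediction protocol

The pipeline predicts a functional gene network in a target genome from
five ingredients: curated template networks (organism, gene, functional
role) from better-studied relatives; homology-hit tables from two search
channels; an operon table; an interaction set; and a phylogenetic-profile
presence matrix over a panel of reference genomes. Its output is a gene
set with one role assignment and a full evidence-provenance chain per
gene, plus statistical validation reports.

The protocol assumes (i) orthology transfers function between the template
and target organisms at the chosen E-value stringency, (ii) co-operonic,
co-interacting, co-regulated and co-evolving genes are functionally
related to their anchors, and (iii) differential expression under the
studied condition is enriched in the true network, so a hypergeometric
tail over DE counts is a meaningful validation statistic.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| orthology-map E-value max | 1e-6 | threshold for the operon-aware orthology mapper channel |
| sequence-search E-value max | 1e-20 | stricter threshold for raw sequence-search hits |
| organism priority | A_halo, PCC6803, P_mari, C_glut, E_coli | conflict resolution order: closest evolutionary relative of a marine cyanobacterial target first; explicit because "closer relative" must be a total order |
| α (relatedness weighting) | 2 | exponent on (1 + d_H) in the relatedness score; larger α sharpens the penalty on profile divergence |
| LH percentile filter | 0 (off) | optional informativeness filter: excludes candidates whose profile log-likelihood magnitude sits in the lowest percentile (too-generic profiles) |
| DA index weights | 1/3, 1/3, 1/3 | the original linear combination's weights are not recoverable; equal weights are neutral and configurable |
| DA flag threshold | 0.9 | pairs scoring below it are reported with their missing/extra accessions |
| DE cutoffs | ≥ 2.0 up, ≤ 0.5 down | fold-change cutoffs; the boundary values count as DE (inclusive), a documented choice between the two conventions in circulation |
| enrichment flag | raw P ≤ 0.05 | raw tail probabilities drive the flag; a Benjamini–Hochberg column is emitted alongside for reference but is informational |

## The functional-relatedness score is a reconstruction

The published description of the profile-based relatedness measure
specifies its ingredients — the per-gene profile log-likelihood LH, the
Hamming distance d_H, a weighting factor α (default 2), and the
both-present genome count h — and its monotonicity (more related when d_H
is smaller and h larger), but not the closed form itself. This package
adopts

    score(g_i, g_j) = (h + 1) / (1 + d_H)^α

which satisfies every stated property: symmetric, strictly decreasing in
d_H at fixed h, non-decreasing in h at fixed d_H, permutation-invariant
over the genome panel, and maximal for identical profiles at a given
presence count. LH enters only as an optional informativeness filter.
The closed form is one pluggable function (`phylo_relatedness(..., form=)`)
so an alternative expression drops in without touching recruitment logic.
Likelihood frequencies use p_j = m_j / G with G the number of target
genes (m_j is a count of target genes, so G — not the panel size — is the
meaningful denominator), clamped to [1/(2G), 1 − 1/(2G)] to keep logs
finite on degenerate panels.

## Recruitment rule

A non-model gene x is recruited via anchor g iff score(x, g) is strictly
greater than the best score any *other* model gene achieves with g. The
comparison set for a single-gene model is empty, so such a model recruits
nothing — the rule quantifies over competing model genes, and with none
there is no bar to clear. Recruitment is single-pass: recruits do not
themselves recruit, since transitive closure has no support in the
protocol and balloons the model.

## Domain-architecture score conventions

All three indices live in [0, 1]. Degenerate cases never penalize absence
of evidence: two empty architectures score 1 everywhere (identically
empty); fewer than two shared domains give γ = 1 (no arrangement evidence
against conservation); a shared singleton keeps the duplicate index
meaningful. One override: architectures sharing *no* domain score 0
overall even though γ alone would be vacuously 1 — otherwise "0 means
totally different" would be violated (a disjoint pair would score 1/3).
The combined score sees only the distinct-domain sets, per-domain copy
counts and first-occurrence order; two architectures identical in those
three summaries (e.g. ABA vs AAB) are indistinguishable to it, so
"score 1 iff literally identical as ordered multisets" holds only up to
that information. Domains are identified by accession; coordinates only
order first occurrences.

## Hypergeometric validation

The tail is inclusive, P(X ≥ V) = Σ_{i=V}^{min(A,K)} C(A,i)C(N−A,K−i)/C(N,K),
evaluated via scipy's survival function (log-space internally); tests pin
it against exact rational arithmetic over the full N ≤ 30 grid and random
N ≤ 50 cases. All channel rows of one report share the same (N, A)
population. Channel rows count *recruited* genes only (channel tag, no
template tag); the expanded row counts the whole model; raw P-values are
reported without multiple-testing correction, matching how such validation
tables are conventionally printed.

## What the synthetic world emulates — and what it does not

The generator plants: functional modules whose members co-occur across
the reference panel (a module-level clade pattern; template-target genes
get independent dropout at the retention rate, the remaining module genes
are *profile companions* — near-copies of one same-module target's profile
with a 3% per-genome flip rate); homology hits whose E-values straddle the
thresholds (true pairs log-uniform in [1e-50, 1e-21], decoys in
[1e-19, 1e-2]); operons and interactions concentrated within modules; a
regulon with a planted ortholog subset (103 members, 41 mapped, at full
scale) including a few members corroborating existing model genes; domain
architectures identical for true pairs except a planted set of perturbed
pairs (7 of 63) degraded until they fall below the 0.9 flag threshold;
fold changes log-normal around 1 truncated strictly inside (0.5, 2.0) for
non-DE genes and pushed beyond the cutoffs for the planted DE set, which
is enriched in module genes (25% per-gene rate); and one pathway composed
90% of model/module genes among otherwise random pathways.

It does **not** simulate sequences (orthology is asserted directly via hit
tables), phylogenetic tree structure of the panel (genome columns are
exchangeable, so profile similarity has none of the phylogenetic
autocorrelation real panels show), cross-contamination between modules,
noisy operon boundaries, or false-positive interactions correlated with
expression. Passing the planted-recovery tests therefore demonstrates the
*machinery* (thresholds, best-hit logic, recruitment rule, statistics) is
correct, not that the biological signal in real data is as clean; real
recall and purity will be lower than the synthetic figures.

Scale defaults: the full configuration matches the study conditions
(2520 target genes, 810 reference genomes, 102 DE genes, 63 template
pairs, 103-member regulon). Tests and replicate-based checks use a
desk-scale world (300 genes, 60 genomes, 30 DE genes, same 63 template
pairs over 10 modules), chosen so the whole suite runs in seconds while
every planted signal stays recoverable.

## Numerical and tie-breaking choices

- Best-hit selection breaks exact E-value ties by preferring a subject
  co-operonic with another query's chosen subject, then lexicographically
  on subject id (operon consistency is a tiebreak bonus, not a filter).
- Merge conflicts with identical priority, DA score and E-value emit a
  warning and fall back to the lexicographically smallest source gene.
- Recruitment output is sorted (gene, anchor); all stages iterate sorted
  containers, so identical inputs give byte-identical outputs (the run
  manifest, which records wall-clock stage timings, is the one exception).
- Fold-change tables must be strictly positive; zero or negative values
  are data errors, not silently dropped.

## Known limitations

- The relatedness closed form is a reconstruction (above); ranked
  recruitment under a different form satisfying the same monotonicities
  could differ at the margin.
- The DA score's three-summary view cannot distinguish architectures that
  agree on content, copy counts and first-occurrence order.
- Regulon transfer reuses the template-mapping thresholds; organism- or
  regulator-specific calibration is not attempted.
- Published gene-identity results that depend on the real target genome's
  sequences (e.g. which specific genes a regulon maps onto) are outside
  what a synthetic world can reproduce; they are covered only by
  planted-ground-truth analogues.
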
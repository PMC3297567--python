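# Methods

This note records the models, estimators and design decisions behind the
package, in the order the pipeline applies them.

## Signal model and synthetic data

The generator emulates a two-strand tiling design at fixed spacing
(default 22 nt; probe length equals the spacing) over a synthetic
bacterial chromosome: genes of log-normal length (mean 900 nt, sd 0.3 on
the log scale) packed with exponential intergenic gaps, a configurable
fraction carrying a contiguous 5′UTR segment or a nested antisense
segment on the opposite strand, plus optional free-standing small-RNA
segments.  Expressed genes draw a log2 baseline from N(9.5, 1.0);
regulatory segments sit lower, 1.8 log2 units above the background
median (6.0) by default, reflecting their low abundance.

Probe log2 intensity is

    y_ph = base_p + delta_ph + a_p + s_h + eps_ph

with `base_p` the baseline of the covering same-strand feature (or the
background median with a fixed per-probe jitter, sd 0.15, at
untranscribed positions), `delta_ph` the planted depletion effect
applied only in the matching RNase's −IPTG samples, and independent
Gaussian noise components on the log2 scale: probe affinity `a_p`
(sd 0.25), per-hybridization shift `s_h` (sd 0.30) and residual `eps`
(sd 0.20).  The four main experiments — wild type and the three
depletions — are generated in duplicate; optional +IPTG samples are
fully complemented (no effect), since differential testing only uses
wild type against −IPTG.  The default planted program is deliberately
imbalanced (70% of effects up, ~25% of genes affected per enzyme,
median |Δ| ≈ 1.5 log2), the situation that defeats distribution-matching
normalizations.  Every draw descends from one `SeedSequence`, so a seed
fixes the entire dataset, and switching one noise component off leaves
the others' draws untouched (used by the regeneration oracles in the
tests).

What the generator does *not* emulate: sequence-dependent affinity,
cross-hybridization chemistry, reverse-transcription artifacts, and
spatial correlation of noise along the array.  Passing tests therefore
demonstrate the estimators' correctness under the stated additive model,
not robustness to those real-data pathologies.

Depletion severity is carried by a scenario object (default 30-fold
activity reduction).  In the expression generator the planted deltas are
applied at face value — they are defined as the realized log2 changes
under the scenario — while in the decay module the scenario divides the
depleted enzyme's rate constants.

## Probe-level decomposition

Affinity and shift are removed before aggregation.  The shift is
estimated from the matrix of deviations of each value from its probe's
within-condition median, polished by Tukey's two-way median polish
(tolerance 1e-9, at most 20 sweeps, midpoint convention for ties); only
the within-condition component of a hybridization shift is identifiable
at this stage — a shift shared by all replicates of a condition is
indistinguishable from a real condition effect and is left to the
normalization step.  The affinity of a probe is its deviation (after
shift removal, median across samples) from a running median over 9
neighbouring same-strand probes.  Neighbouring probes measure the same
transcript, which is what separates affinity from expression level; the
estimator is exact when a probe's neighbourhood is homogeneous and
degrades gracefully to attributing isolated single-probe dips/spikes at
feature boundaries to affinity — harmless downstream because unit values
are medians over at least `min_probes` probes.  Both estimated vectors
are centred to median zero, and profiles + affinity + shift reconstructs
the input exactly.

Aggregation takes the median of probe-level values over probes lying
entirely within the unit's interval, on the same strand, with a unique
genomic match.  `min_probes` defaults to 3 — fragments hybridizing to
one or two probes are not reliably measurable — and under-covered units
are flagged rather than dropped.

## Least-variant-set normalization

Genes are ranked by average expression over all samples and split into
10 equal-count strata ("equal expression intervals" read as equal-count
deciles, which guarantees non-empty strata).  Within each stratum the
`floor(0.10 × size)` genes with the lowest variance across the four
main-condition means (replicates averaged first) are selected, with a
lexicographic gene-id tie-break for determinism.  The reference signal
is the per-gene mean of the anchor genes over all hybridizations —
symmetric and condition-agnostic, since no baseline is privileged.  For
each hybridization, (observed − reference) is regressed on the reference
by locally weighted linear regression with tricube weights at span 0.5
(statsmodels lowess, two robustifying iterations); the fitted curve is
applied to every unit at its observed value, with constant extrapolation
beyond the anchor range.  Because each sample is pulled toward the
mean-of-all-samples reference, a distortion planted in one of n samples
is corrected by a factor (1 − 1/n); the cross-sample differences it
creates are removed in full.

## Differential analysis

Each gene follows a one-way layout `x_ij = wt + ΔRNase_i + ε_ij` over
the four main conditions, fitted by OLS with pooled residual variance
(residual dof = samples − 4; with duplicates, 4).  Each `ΔRNase_i` is
tested two-sided against zero on the pooled dof.  Genes with zero
residual variance get undefined (NaN) p-values, are excluded from the
multiple-testing mass and listed in a QC report — never p = 0.
Benjamini–Hochberg step-up q-values are computed in one pooled pass over
all gene × RNase tests (three per gene); Storey's π₀-adaptive estimator
would be a less conservative alternative but the plain step-up is kept
for its distribution-free guarantee.  Profiles are U/D/− by
`q ≤ 0.1` jointly with `|Δ| ≥ log2(FC)` applied to the point estimate,
at 2-fold and 1.5-fold.  Venn summaries count each unit once in the
region given by the exact set of RNases calling it up (resp. down);
units up under one enzyme and down under another form a separate mixed
class.  The primary RNase of an affected unit is the significant
increase with the largest delta, ties broken by the fixed order
Y > J1 > III; decrease-only units are labelled "down".

The implementation is vectorised with numpy for simulation-scale runs
and is checked in the tests against statsmodels OLS with a condition
factor, gene by gene, and against both a naive evaluation of the
step-up formula and statsmodels' BH implementation.

## Segment discovery and classification

The expressed rule (≥5× the chromosome median in at least one
hybridization) is applied to raw, pre-normalization intensities; the
chromosome median is computed per hybridization over unique probes only.
Expression runs require at least 3 probes and tolerate gaps of 1
sub-threshold probe.  Probes inside same-strand annotated genes are
subtracted from runs before candidates are formed — a 5′UTR shares one
continuous run with its gene, so candidates must be the non-genic
remainder — and contiguity with gene expression at the cut points is
recorded (boundary-straddling probes are skipped when checking
adjacency).  Candidates reaching ≥10× background whose aggregated
expression shows condition structure (one-way ANOVA across the four main
experiments, p ≤ 0.05) are promoted to "new" (T) segments; the rest keep
the S label.

Classification is a deterministic decision tree on (i) contiguity with a
same-strand gene on the segment's 5′ or 3′ side and (ii) boundary shape
measured on the cross-sample maximum profile (the condition where the
segment is most stabilized): a *downshift* is a drop of ≥2 log2 units
between the mean of the 3 probes inside the boundary and the 3 outside;
*downstream still above background* means the outside mean exceeds
background + 1 log2.  Gene on the 3′ side → 5′UTR; genes on both sides →
intra-operon; gene on the 5′ side → 3′ extension, subtyped 3′ (downshift
to background), 3′PT (downshift but signal remains — partial
termination) or 3′MT (no downshift — missing terminator); isolated
segments → independent (sharp rise at the 5′ end and terminal downshift),
independent-MT (no terminal downshift) or inter-genic (terminal
downshift without a sharp 5′ rise, leaving the promoter assignment
open).  The downshift quantities are package choices — the source
material describes the shapes qualitatively.  Antisense partners are
opposite-strand features overlapping by at least min(50 nt, 25% of the
segment length).

## Enrichment

Per category (hierarchical ids with " * " separators; categories may
overlap) the screen reports %Up/%−/%Down for each RNase and a two-sided
Fisher exact test of the 2×2 table in-category × flagged for each
direction, using all annotated genes of the run as the reference
population (a restricted population can be passed explicitly).
Significance applies Bonferroni over the number of categories examined
at level 0.05; significant categories get +Up/−Up/+Down/−Down codes by
the direction of the deviation.  The profile feeding the screen is the
2-fold call at FDR ≤ 0.1.

## Decay kinetics

Pathways are acyclic species graphs with first-order reactions:
endonucleolytic cleavage (RNase Y or III) converting a parent into
products, and 5′→3′ (RNase J1) or 3′→5′ exonucleolytic removal modelled
as whole-species loss — the observable is band presence and half-life,
not nucleotide-resolved ladders.  A rifampicin chase sets synthesis to
zero at t = 0; the linear system `dn/dt = A n` is solved with the matrix
exponential, exact for first-order networks.  Default chase timepoints
are {0, 2.5, 5, 10, 15} minutes.  Depletion divides every rate of the
depleted enzyme by the scenario factor (default 30).  Half-lives come
from log-linear least squares of ln(intensity) against time with
censoring of values at or below a floor; a non-positive decay rate
returns a "stable" sentinel (infinite half-life), never a negative
number.  Band-pattern prediction simulates the chase per condition and
reports probe-overlapping species whose peak abundance clears a
detection floor (default 0.05 relative units), fitting each visible
species from its peak onward.

The transcriptional/post-transcriptional classifier uses the
steady-state relation abundance ∝ synthesis × half-life: with tolerance
1.5 (a package choice), an abundance fold-change is post-transcriptional
when the half-life fold-change reaches abundance_fc/1.5, transcriptional
when the half-life change stays within 1.5× while abundance moved more,
and mixed in between.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything on synthetic
data sized for a laptop-class machine: end-to-end pipeline runs use
100–150 genes (~10⁴ probes), FDR calibration uses 2000 null + 500
affected genes over 10–20 seeds, ANOVA calibration 4,000–10,000 null
segments, the enrichment family-wise-error study 60–200 replicate
datasets of 4234 genes × 110 categories, and half-life recovery 50 noisy
chases per planted value.  Loess uses span 0.5 with 2 robustifying
iterations; median polish stops at 1e-9 or 20 sweeps; BH q-values cap at
1; all tie-breaks are lexicographic or by the fixed RNase order, making
every output reproducible bit for bit from the seed.

## Known limitations

The shift/drift decomposition recovers only the within-condition part of
hybridization shifts (the rest is handled by normalization), and its
positional affinity term needs homogeneous probe neighbourhoods to be
exact.  Segment classification depends on hand-set boundary-shape
thresholds and does not model convergent transcription or overlapping
operons.  The decay module does not model synthesis during the chase,
enzyme saturation, or partial processivity.  None of the synthetic
fixtures capture sequence-composition effects on hybridization.
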
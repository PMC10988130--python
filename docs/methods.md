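# Methods

This note documents the models, statistics and design choices behind
`cofracnet`, in the order the pipeline runs them.

## Chromatogram model and preprocessing

An elution profile is a length-`n_fractions` vector of non-negative
abundances with NaN for missing measurements, on a 1-based fraction axis
ordered by elution time (large assemblies first).  Cleaning follows standard
co-fractionation practice: a single missing fraction flanked by two observed
ones is imputed as the neighbor mean (imputation is simultaneous over the
input mask, which makes the operation idempotent), then any observed run
shorter than `min_consecutive` (default 5, configurable) is discarded as an
unsupported identification.

Profiles are deconvolved into 1–5 Gaussian components by bounded nonlinear
least squares on the observed fractions only (missing values are excluded
from the loss, never zero-filled).  Initialization is deterministic: the
top-k local maxima of the smoothed zero-filled profile, plus, for each k, the
(k−1)-component solution extended by a component at the largest residual.
Seeding each k with the previous solution plus a vanishing extra component
guarantees the raw best-fit residual is non-increasing in k.  The component
count is chosen by AIC, `n ln(RSS/n) + 6k`.  Widths are bounded below by 0.8
fractions — narrower components chase single noisy fractions and corrupt the
co-apex feature — and centers may sit slightly outside the axis (within two
minimal widths) to fit peaks truncated at the column boundary.

## Pair scoring and precision calibration

Candidate pairs are all pairs with ≥ `min_cooccurring` (default 5) mutually
observed fractions and defined correlations.  Five features summarize
co-elution: Pearson correlation of raw and of cleaned profiles on mutual
fractions, Euclidean distance of the L2-normalized profiles, minimum distance
between fitted peak centers (co-apex), and the mutual observation count.

Pairs are labeled against a reference complex catalogue: TP if co-complexed,
FP if both catalogued but never co-complexed, unknown otherwise.  A Gaussian
naive Bayes classifier yields a posterior probability of interaction; the
*ranking* uses the naive-Bayes log-odds, a strictly monotone transform of the
posterior that does not saturate at 1.0 in double precision (thousands of
well-separated pairs would otherwise tie and be ordered lexicographically).
Cross-validation folds are formed over reference *complexes*, not pairs,
because pairs from one complex share their signal; each labeled pair is held
out with the fold of its lexicographically smallest involved complex (exact
exclusion of every involved complex would need a model per pair; the residual
leakage is one complex's worth of shared training signal for pairs spanning
complexes in different folds).  Unknown pairs are scored by the full model.

Running precision at rank *i* is TP/(TP+FP) over labeled pairs at rank ≤ i;
unknown pairs inherit the precision at their rank, and ranks before the first
labeled pair carry precision 1 so the cut is a total function.  Because
running precision is non-monotone, the network keeps the *largest* rank still
meeting the threshold (default 0.5) — the largest network achieving the
stated precision — and known-FP pairs are excluded from the emitted edges.

## Differential comparison

Edge identity is unordered-pair equality; nodes are counted only while
incident to a retained edge.  `pct_unique = 100·(union − shared)/union`.
Replicate-level networks of one condition can be merged by union (default) or
intersection before comparison.

## Rewiring null model

Degree-preserving randomization performs `⌈10·|E|⌉` attempted double-edge
swaps, rejecting any swap creating a self-loop or duplicate edge.  The
proposal is symmetric and rejections leave the state unchanged, so the chain
is uniform over simple graphs with the given degree sequence; at ten attempts
per edge the samples are effectively independent draws for the graph sizes
used here (verified against exhaustive enumeration on small graphs).

The coherence statistic is the proportion of interacting pairs sharing ≥ 1
annotation term, by default over edges whose two endpoints are both annotated
(unannotated proteins are uninformative; a flag divides by all edges
instead — the choice matters only when annotation coverage is low).  For the
domain aspect an edge counts when any cross-endpoint domain pair is a known
physically interacting pair.  The empirical p-value is
`(1 + #{null ≥ observed}) / (1 + N)` with N = 100 rewired networks by
default.  This estimator is slightly conservative when the discrete statistic
ties with null samples; the calibration check therefore uses networks large
enough (hundreds of edges) that the statistic's support is fine-grained.

Differential term enrichment: for each term annotating between
`min_annotated` (3) and 50% of the network proteins (near-universal terms are
degenerate), the observed difference in within-term edge counts between the
two networks is standardized against N pairs of independently rewired
networks; two-sided p-values come from the normal approximation of the null
and q-values from Benjamini–Hochberg, with 10% FDR flagging significance.  A
per-term log-odds of annotation between the two node sets (Haldane–Anscombe
0.5 correction on zero cells, standard 2×2 SE) accompanies each record, and
significant terms are linked in an enrichment map when the Jaccard overlap of
their annotated network proteins is ≥ 0.33.  Annotations are used as
provided — no ontology-graph propagation; propagate upstream if desired.

## IP differential abundance

Log2 fold change is the difference of group means of log2 intensities (not
the log of a ratio of means — symmetric under group swap).  Significance is a
two-sample Student's t-test on log2 values (Welch available by flag), with BH
q-values across tested proteins; proteins quantified in fewer than
`min_quantified` (3) replicates of either group are excluded and logged.
Degenerate zero-variance comparisons return p = 1 when means agree and p = 0
otherwise.  Interactor calls use strict inequalities: log2FC > 0.58
(1.5-fold) and q < 0.05.  The packaged RELA co-IP example table transcribes
published values at their printed precision; one q-value printed as 0.050
under an inclusion rule of q < 0.05 is recorded as 0.0499, consistent with
both constraints (noted in the file header).

## Synthetic data generator

The generator emulates a two-condition SEC-PCP experiment at desk scale.
Defaults: 200 proteins, 40 fractions, 20 complexes of 3–6 subunits, 20%
multiplicative noise, 10% missingness, half the complexes rearranged.

* **Complex peaks.**  Complex centers are spread across the column's
  separating range (fractions 4 to 0.6·n) on a jittered grid, reflecting a
  complex set resolvable by SEC; each complex has one width (0.8–1.8
  fractions) shared by its members, whose centers jitter by < 1 fraction.
* **Member mass distribution.**  Complex members carry most of their mass in
  the shared peak — the core PCP assumption — with a monomer peak of ~30%
  amplitude at a later fraction (smaller apparent mass elutes later).
* **Non-complexed proteins** belong to unmodelled assemblies of their own:
  two comparable-amplitude peaks at positions ≥ 6 fractions apart.  This
  matters: with single-peaked free proteins, a chance coincidence of
  dominant peaks is indistinguishable from planted co-elution and swamps it
  combinatorially; with two comparable peaks a single coincidence caps the
  correlation well below a co-complex pair's.
* **Rearrangement.**  A rearranged complex either dissolves — members
  redistribute their mass into two comparable peaks (monomer plus an
  unmodelled sub-assembly) — or shifts its shared center by ≥ 5 fractions in
  the inhibited condition, chosen 50/50.  Dissolved complexes leave the
  inhibited condition's truth; shifted complexes remain co-complexed.
* **Noise and missingness.**  Multiplicative log-normal noise with the
  configured coefficient of variation (mean-one); independent Bernoulli
  dropout with a 1.5× elevated rate below the 25th intensity percentile,
  balanced so the overall missing rate equals `dropout_rate` — mimicking
  intensity-dependent MS missingness.
* **Reference catalogue.**  A `reference_coverage` fraction (default 0.8) of
  planted complexes plus `n_decoy_complexes` (default 30) decoys drawn from
  the whole proteome — catalogued complexes that do not co-elute in this
  system.  Decoys keep calibration and truth distinct (no circular
  evaluation) *and* extend the catalogue universe so FP labels sample the
  chance co-elution population; without that, running precision is blind to
  unlabeled chance pairs and the 50% cut is systematically too deep.
* **Annotations** add `terms_per_complex` terms shared by all members of each
  complex plus background terms assigned independently (probability 0.05).
  **IP tables** place four groups (bait/control × condition) around per-
  protein base abundances, with planted log2 fold changes on ~10% of proteins
  and N(0, `noise_sd_log2`) replicate noise on the log2 scale.

All generators are pure functions of (config, seed).

What the generator does *not* emulate: peptide- or spectrum-level structure,
shared peptides between protein groups, correlated (batch) noise across
proteins, partial complex membership or substoichiometric subunits, and
fraction-to-molecular-weight calibration (fraction index is the only
coordinate).  Passing tests therefore demonstrate the statistical machinery
is correct and calibrated under the stated elution model — not that any
particular real dataset will reach the same precision.

## Problem sizes and numerical choices

The test suite and acceptance script run the full inference on the default
200-protein experiment (≈ 20,000 candidate pairs, ≈ 30 s per condition), the
null-calibration study on 200 random 100-node/600-edge graphs (chosen so the
sharing statistic's discrete support is fine enough for a meaningful
uniformity check), and exhaustive rewiring enumeration on ≤ 8-edge graphs.
Ties in score ranking break lexicographically by pair id; all seeds are
explicit; BH and t-tests delegate to statsmodels and scipy.

## Known limitations

* The 50%-precision guarantee is relative to the reference catalogue; it
  transfers to the full pair universe only insofar as labeled pairs are
  exchangeable with unknown ones (the decoy design above approximates this).
* Complex-level cross-validation is approximate for pairs whose members span
  complexes assigned to different folds.
* Gaussian deconvolution assumes roughly Gaussian, additively mixed peaks;
  heavily tailed or saturated chromatograms will yield biased co-apex
  features.
* The rewiring null conditions on the degree sequence only — it does not
  preserve clustering or community structure, which is the standard (and
  deliberate) choice for these tests.
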
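# Methods

`dmsensemble` implements the analysis stack used to resolve RNA
conformational ensembles from in-cell DMS-MaPseq experiments: per-read
mutation bit vectors, quality filtering, Bernoulli-mixture ensemble
deconvolution with BIC model selection, reactivity normalization,
ROC/AUROC evaluation of secondary-structure models, and
reactivity-constrained structure prediction. A synthetic read-mixture
generator with ground truth stands in for sequencing data, so every stage
can be validated end to end by parameter recovery.

## Bit vectors and quality filters

Aligned reads (SAM, via pysam) are reduced to ternary vectors over a
1-based analysis window: MATCH where the call agrees with the reference,
MUTATION at mismatches and deleted reference positions, UNINFORMATIVE at
absent positions, low-quality calls, and mate-overlap disagreements.
Mate pairs are merged into one observation per template; an overlap
position where the mates disagree is trusted from neither and becomes
uninformative. Insertions carry no reference position and are ignored;
soft clips are ignored; deletion placement is taken exactly as aligned.

The quality rule treats calls with Phred quality *below* the floor
(default 20) as uninformative. The opposite reading — high-quality calls
uninformative — is implementable via `literal_phred_rule` for auditing,
but it inverts the meaning of base quality and is not the default.

Four conjunctive filters then discard vectors: (1) uninformative fraction
of the window ≥ 0.5; (2) mutations exceeding 10% of the read's
*informative* positions (denominator choice documented below); (3) two
mutations at distance < 4 nt; (4) a mutation adjacent to an uninformative
position. Because the rules are conjunctive, their order cannot change
the retained set; the per-rule report counts use first-failure
attribution in the order above. The 10% rule uses informative positions
rather than window width so that short-coverage reads are not penalized
for positions they never observed. A read-length floor (default 120 nt of
merged alignment footprint) is applied at ingestion and reported as a
fifth count.

## Ensemble deconvolution

Retained reads are modelled as draws from a K-component mixture of
independent Bernoulli profiles µ_k over the A/C positions of the window
(G/U positions carry no DMS signal and are excluded from the likelihood;
uninformative positions are treated as missing at random, so each read
contributes only where it is informative).

The close-mutation filter truncates the sample space: a read from a
heavily modified conformation is less likely to survive than one from a
protected conformation, which biases naive mixing-weight estimates. With
the validity correction (default on), each component's per-read
likelihood is divided by the component's survival probability
P(no two successes within the minimum gap | µ_k), computed exactly by a
dynamic program over positions that tracks the capped distance since the
last success (O(M·gap), batched over profiles).

Two subtleties follow from the truncated model:

- **What the fitted weights estimate.** The mixing weights that maximize
  the truncated likelihood converge to the *post-filter* cluster
  proportions (each component density is renormalized by its own survival
  probability, so the weight of component k in the surviving population
  is π_k·p_k / Σ_l π_l·p_l). The model therefore reports, as `pi`, the
  de-truncated composition π_k ∝ π̂_k / p_k — the estimate of the
  pre-filter ensemble — and keeps the raw fitted weights as
  `pi_observed`. With the correction disabled the two coincide.
- **The M-step.** Dividing by p(µ_k) makes the closed-form µ update no
  longer optimal. Each M-step instead takes one fixed-point ascent step:
  the survival term is linearized at the current µ (its gradient is exact
  because p is multilinear in each µ_j: ∂p/∂µ_j = p|µ_j=1 − p|µ_j=0,
  evaluated as one batched DP), the per-coordinate stationarity condition
  a/µ − b/(1−µ) = c becomes a quadratic with a unique root in (0, 1), and
  the step is backtracked until the complete-data objective improves.
  Accepting only improvements makes this a generalized EM, so the
  observed-data log-likelihood is non-decreasing at every iteration — an
  invariant the test suite asserts.

Initialization draws each µ_kj uniformly from [0.001, 0.2] (the typical
DMS per-position mutation-rate range) with uniform weights; the best of
10 restarts by final log-likelihood is kept. Convergence is |Δ logL| <
0.05; maximum 300 iterations, with non-convergence reported rather than
raised. µ is clamped to [1e-6, 1−1e-6]. K is selected by minimum BIC over
K = 1..3, with BIC = −2 logL + (K·M + K − 1)·ln n, where M is the number
of A/C positions and n the (weight-summed) retained read count; neither
convention is canonical in the field, so both are stated here and
recorded in the model output. Reported clusters are ordered by descending
abundance, which also resolves label switching deterministically.

Residual, uncorrected selection effects are documented rather than
modelled: the survival DP uses the A/C-masked profile with zeros at G/U
positions, while the actual filter also sees background G/U mutations;
and the mutation-adjacent-uninformative rule removes reads in proportion
to their mutation count. Under the default simulation conditions both
effects together shift the recovered major-cluster percentage by well
under one point.

## Reactivity profiles

Raw reactivity at a position is the weighted mutation count over the
weighted informative count; it is undefined (not zero) where coverage is
zero. Normalization divides by the median of the top ceil(0.1·M) defined
A/C raw values (M = number of defined A/C positions; the median of an
even-sized set is the mean of its central pair) and caps at 1. No
Winsorizing or outlier trimming precedes the scale estimate. G/U
positions remain undefined in normalized profiles because DMS methylates
only N1-A and N3-C. Cluster profiles take µ_k as their raw values with
responsibility-weighted coverage and are normalized per-cluster by
default; a shared scale (the maximum of the per-cluster scales) is
available when clusters must be compared on one footing, since the
published convention is not stated.

## AUROC structure evaluation

A structure model is scored as a classifier of its own A/C positions:
sliding a threshold t over the reactivity scale, TPR is the fraction of
paired positions with reactivity < t and FPR the fraction of unpaired
positions with reactivity < t; AUROC is the trapezoidal area, which
equals the Mann–Whitney statistic P(r_paired < r_unpaired) + ½ P(tie)
(asserted to 1e-12 against an independent rank-based oracle). Ties sit on
the threshold and receive half credit through the diagonal segment of the
curve. Undefined reactivities are excluded, never imputed. Because the
statistic is invariant under strictly monotone transforms, raw and
normalized profiles give identical AUROC — so the unstated choice in the
published convention is immaterial, which the suite asserts.

## Constrained folding

The built-in folder is a pseudo-energy dynamic program (weighted
Nussinov): it maximizes Σ over pairs of [pair_score − penalty(i) −
penalty(j)] with pair scores GC = 3, AU = 2, GU = 1, a minimum hairpin
loop of 3 nt, and a per-position penalty α·ln(1 + r) at A/C positions
with defined normalized reactivity r (α default 4, intercept 0). An
optional hard ceiling forbids pairing above a reactivity cutoff.
Traceback tie-breaking is deterministic (prefer the right end unpaired,
then the smallest outer pairing index). These constants are calibrated so
that profiles generated from a target structure at the generator's rates
recover ≥ 90% of its pairs on the bundled hairpin and three-way-junction
fixtures; they are a desk-scale surrogate, not a nearest-neighbor
thermodynamic model, and the DP is verified against exhaustive
enumeration for windows ≤ 12 nt. The stand-in never emits pseudoknots.

A thermodynamic folder is reachable through `fold_external`, an adapter
that runs a configured executable (a preset for ViennaRNA's RNAfold is
included) and parses CT or dot-bracket output; a missing executable is an
explicit error, never a silent fallback. Pseudoknot prediction is
adapter-only; recovering a pseudoknot helix is documented as out of reach
for the stand-in.

## Synthetic data generator

The generator emulates the statistical structure the deconvolution
assumes. Each conformation's modification profile assigns paired A/C
positions 0.008, unpaired A/C positions 0.10, and G/U positions 0.002
(background); a uniform 0.001 error rate is added, and each position
independently becomes uninformative with probability 0.02. These rates
are simulation conventions chosen to land population reactivities in the
conventional bins (paired mostly unreactive; unpaired mostly
medium-to-strong after normalization); they are not measurements of any
specific RNA. Reads draw a conformation from the mixing proportions, then
independent Bernoulli calls per position. Optional rejection sampling
regenerates reads violating the close-mutation rule, emulating a source
population in which such molecules never appear; the default leaves them
in so that the selection bias of the filters — and the EM correction that
undoes it — can be measured against ground truth.

Matrices can be written as single-end SAM plus matching FASTA (mutations
as substituted bases under a full-match CIGAR, or as deleted reference
positions; uninformative positions as sub-floor quality characters);
re-ingestion reproduces the codes bit for bit, which anchors the
end-to-end integrity tests.

### Fixture structures

The bundled reference is a *designed* 451-nt telomerase-RNA-like
sequence: its two analysis windows (22–204 and 213–368) each support a
canonical-like fold (a multi-helix architecture, respectively a three-way
junction) and an alternative fold (a wholesale rearrangement keeping only
the outer stem, respectively a register-shifted linear stem). The
sequence is solved from the union of the two pair tables — chains of
positions linked by complementarity receive alternating Watson–Crick
partners, free positions are filled A/C-rich — so one sequence is exactly
compatible with both folds. The published structures for the real RNA
exist only as figures; these fixtures reproduce the statistical situation
(two folds on one sequence, pairing status differing at dozens of A/C
positions, the alternative fold dismantling most of the canonical
architecture), not any experimentally determined pairing. Four designated
"bulge" positions — two adjacent A/C pairs in distinct interior loops of
the canonical three-way junction — stand in for the protein-protected
helical bulges that separate the purified-RNP reactivity clusters.

What the generator does *not* emulate: PCR duplicates and UMI structure,
realistic quality-score distributions, indel error models beyond optional
deletion encoding, correlated modification (cooperative breathing), and
partial-length amplicons. Passing recovery tests therefore demonstrates
correctness of the inference machinery under the stated generative
assumptions, not performance on real libraries.

## Validation protocols and problem sizes

The reproduction protocols simulate 20,000 reads per scenario (a size at
which mixing-proportion recovery is limited by model identifiability
rather than sampling noise, and the full pipeline runs in ~30–60 s per
scenario on one core), apply the four filters, and select K ≤ 3 by BIC
with 10 restarts:

- CR4/5-window two-conformation mixture at an 87/13 composition;
- t/PK-window mixture at 79.3/20.7;
- purified-RNP scenario: two profiles differing only at the four bulge
  positions (0.02 vs 0.25), mixed 62/38.

The first two recover the major-cluster percentage within 1–2 points and
select K = 2. The third is a documented negative result: with differences
confined to four positions, the two-component model's log-likelihood gain
over K = 1 (~170 nats at ~12,500 retained reads) is far below the BIC
penalty for the extra component (~840 nats), so minimum BIC selects K = 1
and the reported major share is 100%. The scenario carries roughly 0.013
nats of mixture information per read — an order of magnitude short of
what ±3-point recovery requires; the BIC crossover would arrive near
75,000 reads. Even a forced two-cluster fit scatters by several points
across seeds at this information level. This is an intrinsic sensitivity
limit of BIC-gated deconvolution for conformations distinguished at only
a handful of positions, worth knowing when interpreting small reactivity
differences between clusters.

## Known limitations

- The deconvolution assumes independent Bernoulli modification within a
  conformation; correlated modification or more than K = 3 conformations
  are not modelled.
- The validity correction addresses only the close-mutation filter; the
  adjacent-uninformative filter's (small) selection effect is not
  corrected.
- The built-in folder has no thermodynamic model, no pseudoknots, and no
  suboptimal-structure sampling; conclusions about specific folds should
  come through the external adapter.
- Windows are analyzed independently; linkage of conformations across
  separately amplified windows is unknowable from these data by design.
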
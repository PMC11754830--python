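# dmsensemble

Ensemble deconvolution of in-cell DMS-MaPseq chemical probing data.

Dimethyl sulfate (DMS) methylates the Watson–Crick face of unpaired
adenines and cytosines; during mutational-profiling reverse transcription
each modification reads through as a mismatch or deletion, so every
sequencing read carries a single-molecule fingerprint of one RNA's
structure. When an RNA — such as human telomerase RNA, whose
template/pseudoknot and CR4/5 three-way-junction domains must fold
correctly for ribonucleoprotein assembly — populates several
conformations at once, the population-average reactivity blurs them
together. `dmsensemble` is for structural-RNA researchers who want to
pull those conformations apart from targeted MaPseq libraries.

## What it does

- **Bit vectors** — converts aligned reads (SAM) into per-read ternary
  vectors (match / mutation / uninformative) over a 1-based analysis
  window, merging mate pairs, and applies the standard quality filters
  (≥ 50% uninformative, > 10% mutated, two mutations within 4 nt,
  mutation adjacent to an uninformative position, 120-nt length floor).
- **Deconvolution** — fits a K-component Bernoulli mixture by EM over
  the A/C positions: read i from cluster k mutates position j with
  probability µ_kj; responsibilities γ_ik, mixing proportions π, and K
  chosen by minimum BIC = −2 log L + (K·M + K − 1)·ln n for K ≤ 3.
  Because the close-mutation filter removes heavily modified reads, the
  per-cluster likelihood is divided by the cluster's survival
  probability (exact dynamic program) and the reported π is de-biased
  back to the pre-filter ensemble composition.
- **Reactivity** — population and per-cluster profiles (mutations over
  coverage), normalized by the median of the top 10% of A/C values and
  capped at 1; Pearson agreement between replicates.
- **AUROC** — scores any candidate secondary structure as a classifier
  of its own positions ("reactivity < threshold ⇒ paired"), with the
  trapezoidal area equal to the Mann–Whitney rank statistic.
- **Folding** — a pseudo-energy-guided dynamic program predicts a
  pseudoknot-free structure from normalized reactivities, plus an
  adapter for an external thermodynamic folder (RNAfold preset).
- **Simulation** — a generator draws read mixtures from
  structure-derived modification profiles with ground truth, and can
  emit SAM/FASTA fixtures that round-trip bit-for-bit.

## Worked example

Simulate a two-conformation CR4/5-window mixture at an 87/13 composition
and run the full pipeline (filters → EM with BIC selection → cluster
reactivities → AUROC → folding):

```sh
dmsensemble simulate --seed 1 --n-reads 20000 --window cr45 --pi 0.87 --out-dir sim
dmsensemble report sim/reads.sam --reference sim/reference.fa \
    --window cr45 --seed 1 --out-dir out
```

which prints

```
status: ok
reads: total=20000 retained=12235 discarded=7765
cluster abundances: major 86.0% / minor 14.0%
population reactivity bins: low=24, medium=2, strong=32, undefined=68, unreactive=30
```

Reading the output: the filters retained 12,235 of 20,000 reads (most
discards are reads with two close mutations — exactly the selection the
EM correction accounts for). Minimum BIC picked K = 2 (`out/bic_table.tsv`:
289907 / 289115 / 289794 for K = 1, 2, 3), and the de-biased mixing
proportions recover the simulated 87/13 composition as 86.0/14.0. The
`undefined` bin counts G/U positions, which DMS does not report on.
Per-cluster reactivity tables, the fitted model, responsibilities, and
constrained structure predictions are written under `out/`.

The six subcommands (`simulate`, `bitvector`, `cluster`, `auroc`,
`fold`, `report`) run the same stages individually on each other's
outputs; the same machinery is importable from Python
(`dmsensemble.em_fit`, `select_k`, `roc_curve`, `fold_constrained`, …).

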
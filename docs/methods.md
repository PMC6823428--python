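# Methods

## Model and assumptions

The consensome is a frequency-of-discovery meta-analysis. It rests on
three assumptions: (i) experiments perturbing any node of one signaling
family in one biosample interrogate a shared downstream program, so
binning them borrows statistical power; (ii) the *direction* of
differential expression is a nuisance — it depends on perturbation
polarity (agonist vs knockout), isoform usage, dose, timing — so it is
suppressed when measuring the strength of a node–target relationship;
(iii) recurrence of significance across experiments reflects regulatory
strength better than fold change, which is platform- and
design-dependent.

The per-gene null model is Binomial(N_g, p0): if a gene is unrelated to
the node, each experiment independently calls it significant with
probability p0 = 0.05 (the nominal threshold applied upstream). The CPV
is the upper-tail probability of the observed discovery count E_g. Two
properties follow and are tested: the test is *conservative* under the
null (binomial discreteness makes the attained size ≤ 0.05, approached
from below as N_g grows), and CPVs are not comparable across very
different N_g — genes with equal discovery rates but different coverage
get different CPVs, producing the characteristic multi-tail scatter.
No normalization across unequal N_g is applied, and no multiplicity
correction enters the ranking; a Benjamini–Hochberg column (`cpv_bh`)
is emitted for orientation only.

## Probeset aggregation

The directional z-transform maps (F_p, P_p) to sign(log2 F_p) ·
qnorm(1 − P_p/2) with sign(0) = +1, so F = 1 sits on the induction
branch. Gene-level z is the arithmetic mean (an unweighted Stouffer
combination; probesets of one gene are treated as exchangeable
replicates, which overstates precision when they are correlated — a
known, accepted simplification given that well under 1% of genes have
more than one probeset). Gene-level F̂ evaluates the OLS fit of
log2 F_p on Z_p at the mean z; because an OLS line passes through the
mean of its data, F̂ equals the geometric mean of the probeset fold
changes whenever Z is the plain average, and the regression form is
kept for generality. Fallbacks: n = 1 returns (P_p, F_p) exactly
(bit-exact identity, tested); all-equal z's return the geometric mean.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | gene-level discovery threshold, boundary inclusive (p ≤ α) |
| `p0` | 0.05 | per-experiment success rate of the binomial null |
| `p_floor` | 1e−300 | clamp before qnorm; upstream p = 0 would otherwise give infinite z |
| `significant_only_fc` | False | average consensus FC over all N_g experiments, not only the E_g significant ones |
| `min_n_experiments` | 1 | report every measured gene; no minimum coverage is imposed |
| `window` | 10 000 bp | promoter half-window around each TSS (cistromic) |
| `reducer` | max | several peaks in one window: strongest promoter-proximal evidence |
| `zero_inclusive` | True | cistromic mean counts peak-free experiments as 0 |
| `multi_node` | all matching families | a multi-node experiment enters each family bin it maps to |

Percentile is 100·(N − rank)/N (top gene of 10,000 → 99.99); ranks are
ascending-CPV with average rank on ties, stored fractionally. Fold
changes may be declared linear or log2 per input file; the internal
canonical form is the linear ratio paired with its log2 value.

## Numerical choices

- **Exact direction suppression.** The log2 fold change is carried as a
  first-class column; corpus inversion (F → 1/F) negates it, which is
  exact in floating point, and the consensus fold change is computed as
  2^mean(|log2 F̂|) — algebraically the geometric mean of max(F, 1/F).
  Consequently CPV, rank and consensus FC are *bit-identical* between a
  corpus and its inversion (tested), not merely close.
- The |z| quantile is computed as −qnorm(p/2) rather than qnorm(1 − p/2),
  avoiding cancellation in 1 − p at very small p; the direction sign is
  applied afterwards, making antisymmetry z(1/F, p) = −z(F, p) exact.
- CPV uses the binomial survival function at E_g − 1; E_g = 0 is pinned
  to exactly 1.0.
- Gene-level P = 2·Φ̄(|Z|) via the survival function, capped at 1.0.
- Window overlap converts BED half-open peaks to 1-based inclusive
  spans and intersects them with the closed window [tss − w, tss + w];
  boundary bases count (tested at both edges). Interval queries use an
  interval tree; correctness is cross-checked against an exhaustive
  O(peaks × genes) scan.
- Consensome files round-trip numerics at 12 significant digits;
  readers parse floats in round-trip mode.

## Synthetic corpus

The generator emulates the statistical shape of a curated corpus, not
the raw data: it starts at the (fold change, p-value) level. Defaults
define the study conditions: 1000 genes, 10 true targets, 20
experiments in one node family, per-experiment true-target discovery
probability π_t = 0.8, discoveries drawn p ~ U(0, 0.05) with log2
effect magnitudes |N(1.0, 0.35)| (≈ 2-fold typical), a 25% chance any
given discovery is repressive, null genes p ~ U(0, 1) with log2 FC ~
N(0, 0.15), 10% per-gene/per-experiment missingness, and ~1% of genes
covered by 2–5 correlated probesets. A single seed drives hierarchical
substreams (structure stream + one stream per experiment), so enlarging
the corpus never perturbs existing experiments.

The cistromic generator places TSSs on a jittered per-chromosome grid
whose spacing exceeds the promoter-window diameter, so each window is
attributable to one gene; true targets receive a strong in-window peak
(score |N(200, 30)|) per experiment with probability 1 by default, over
50 uniformly placed background peaks (|N(40, 15)|) per experiment.

What passing tests on this corpus show: the engine recovers genes that
are recurrently significant, suppresses direction exactly, and is
calibrated under a uniform null. What they do not show: robustness to
correlated experiments (shared platforms, re-analyzed contrasts),
p-value miscalibration upstream, or annotation errors — real corpora
violate the independence the binomial null assumes, which is one reason
CPVs are used as a ranking, not as literal probabilities.

## Design choices where the design was open

- Consensus FC averages all N_g experiments a gene is measured in
  (`significant_only_fc` flips to the E_g significant ones); averaging
  everything makes F_g a corpus-wide magnitude rather than a
  winner's-curse-inflated one.
- Cistromic means include peak-free experiments as zeros; excluding
  them would conflate binding strength with binding frequency.
- The ±10 kb promoter criterion is interval overlap, strand-ignored;
  summit distance is not used because inputs are plain peak intervals.
- Multi-node experiments default to entering every family bin they map
  to; the alternative assigns them only to their first-listed family.
- Display rounding of percentages uses two significant figures
  (round-half-even): 99/258 → "38", 1490/25922 → "5.7", 33/40 → "82".
  Stored values are always full precision. Note that the frequency
  ratio of the printed counts 99/258 vs 1490/25922 is 6.68-fold; the
  commonly quoted "6.5-fold" for this comparison is not recoverable
  from those counts under any standard rounding, so this package
  reports the computed ratio.

## Limitations

- The binomial null treats experiments as independent and exchangeable;
  nested designs (many contrasts from one dataset) inflate recurrence.
  The version stamp records datasets vs experiments so users can judge.
- Probeset z's of one gene are averaged unweighted; correlated
  probesets make gene-level P anti-conservative.
- CPVs are comparable only within a consensome (same corpus, same
  selector), not across them.
- The cistromic score treats MACS2 scores as opaque magnitudes; no
  background model or input normalization is applied.
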
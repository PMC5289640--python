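# Methods

## Model and assumptions

`tcrpair` treats a multi-well TCR sequencing experiment as repeated
independent sampling from a fixed population of clones. Cells are drawn with
replacement (infinite-population approximation); each clone is defined by
1–2 α chain ids, 1–2 β chain ids and a frequency, and chains are opaque
identifiers — the algorithm never inspects sequence content, so numeric ids
and CDR3 amino-acid strings behave identically.

Sequencing noise has two parts:

* **Drop-out.** Every chain instance of a cell fails to be observed with a
  clone-specific probability (the drop rate). In the likelihoods this is
  summarised by a single mean rate ε.
* **In-frame errors.** Each surviving chain instance is replaced, with a
  chain-specific probability, by one of three fixed "daughter" sequences
  unique to that chain. Daughters act as plausible but wrong chains: they
  inflate the chain registries and can form false pairs.

A well records only the *set* of distinct chain ids per locus plus its
sample size; counts within a well are not used. Well sample size is required
metadata — the occupancy likelihoods need it, so a missing size is an error,
never imputed.

## Pairing stage

Association scores weight each co-occurrence by 1/(c_α + c_β), the inverse
of the total number of distinct chains in the well. The source description
of this weight is ambiguous (its equation can be read as 1/c_α + 1/c_β while
the prose says "inversely by the total number of chains recovered from that
well"); we benchmarked both forms on one-plate datasets and found metric
differences of at most two percentage points, and adopted the prose form.

Per-well matching maximises the summed score over one-to-one assignments
(scipy's linear sum assignment). Rectangular wells (unequal chain counts,
produced by drop-out) yield min(|A|, |B|) pairs; surplus chains stay
unpaired in that well, and forced assignments with zero score are still
counted — the filter stage removes them. Chains are sorted by id before
matrix construction so ties resolve deterministically.

The per-replicate filter keeps pairs assigned strictly more often than the
mean of the positive assignment counts; the consensus keeps pairs appearing
in strictly more than a proportion T of the N_r replicates (both "greater
than", not "at least"). Replicate subsets have ⌊p_J·W⌋ wells (minimum 1),
drawn without replacement.

**A consequence worth knowing:** with literally noise-free data every well
is square and only true pairs are ever assigned, so the strict mean filter
must exclude whichever true pairs fall at or below the mean count — perfect
recovery is then impossible by construction, and with all counts equal the
filtered list is empty. In realistic data the many low-count junk
assignments created by drop-out (and daughters) anchor the filter level
well below the genuine pairs' counts, which is what makes near-perfect
recovery possible. The end-to-end sanity tests therefore keep drop-out on
even in their "clean" configurations.

A related structural effect: for a dual-α clone, each well can assign its β
to only one of the two α chains, so the clone's two pairs split the
assignment counts and their replicate supports. At stringent consensus
thresholds (T = 0.9) typically at most one pair per dual clone survives,
which caps the top-clone depth near (1 + prevalence·0)/(1 + prevalence) ≈
77% at 30% dual-α prevalence; relaxed thresholds recover both pairs.

## Frequency estimation

The absence probability of a clone from a well of n cells is evaluated in
closed form, q = 2(1−f+fε)^n − (1−f+fε²)^n (single pair) and
3(1−f+fε)^n − 3(1−f+fε²)^n + (1−f+fε³)^n (dual-α), which are algebraically
identical to the underlying binomial sums (via E[ε^M] = (1−f+fε)^n for
M ~ Binomial(n, f)); the literal sums serve as test oracles. ε is a user
parameter (default 0.15, the simulation's mean drop rate) — estimating ε
itself is out of scope, and setting ε = 0 yields lower bounds on abundances.

The MLE is a bounded scalar optimisation on logit(f) (tolerance ~1e−10 in f,
avoiding boundary pathologies); if the clone is seen in every well the
boundary f̂ = 1 is taken directly. Confidence intervals are the frequencies
where log L = log L_max − 1.96, found by bisection on each side and clamped
at the domain boundary when no crossing exists. The literal 1.96 offset is
used (not the χ²₁-based 1.92). A clone never observed is not estimable and
raises an error rather than returning 0. A dual clone's occupancy count
requires all three of its chains in a well.

## Dual-TCRα discrimination

For every pair of candidate pairs sharing a β (never an α — duals are
dual-α only), the expected number of triple-co-occurrence wells under
independence is E = Σ_l w_l [1 − (1−f₁)^{n_l} − (1−f₂)^{n_l} +
(1−f₁−f₂)^{n_l}], and the ratio r = A/E of observed to expected is computed
(r = +∞ when E = 0 < A, a strongly dual-leaning outcome; r = 1 when both
are 0). The ratios are split by 1-D k-means (k = 2, 20 restarts,
deterministic sub-seeds); the higher-mean cluster is called dual. With
fewer than two finite ratios clustering is ill-posed and a fixed threshold
r > 2 is used; identical ratios give no calls.

The full-likelihood route computes, per well below the size cap (default
50 cells), the probability of the observed presence/absence pattern of the
three chains: latent per-clone cell counts (binomial for the dual
hypothesis, multinomial over (m₁, m₂) for two clones) are summed against
independent per-chain detection terms, 1 − ε^m for a chain carried by m
cells. Multinomial terms are evaluated in log-space with terms 40 nats
below the per-well maximum dropped. The per-well pattern distribution sums
to one (a tested invariant) and matches instance-level Monte-Carlo
simulation. The route applies when the three chains co-occur in at least
one well under the cap; where |ΔlogL| ≥ 10 (an empirical default, exposed
as configuration) its verdict overrides the clustering. Estimated pair
frequencies summing above 1 are renormalised to the simplex boundary before
entering the independence formulas. Accepted duals replace their two pairs
in the clone table and take the dual-mode frequency re-estimate; overlapping
dual calls sharing a constituent pair are resolved greedily in order of
evidence, likelihood-route calls first.

## Synthetic data generator

The generator reproduces the validation conditions and *is* the study
design; its defaults are not tuning knobs. Defaults: N = 2100 clones, the
top n_s = 25 covering p_s = 0.5 of the population on a linear ramp anchored
at f_{n_s} = 1.1·p_s/(N−n_s) with a flat tail at (1−p_s)/(N−n_s) (the
source's equation prints p_s/(N−n_s) for the tail, which contradicts its own
text at p_s ≠ 0.5; the text's reading is used — they coincide at the
universal p_s = 0.5); 30% dual-α and 6% dual-β prevalence; sharing spectra
(α: 81.6/8.5/2.1/0.7/3.3/0.5/3.3% for multiplicities 1–7; β:
85.9/7.6/3.7/1.9/0.9% for 1–5); lognormal drop rates (mean 0.15, sd 0.01,
capped at 0.9) per clone and lognormal in-frame error rates (mean 0.02,
sd 0.005) per chain. The lognormal parameters are taken as the mean/sd of
the variable itself (the source is ambiguous between this and the log-scale
reading; at these values the difference is negligible). Chain
multiplicities are drawn from the spectra until all clone slots are filled
(final draw truncated), chains are shuffled onto slots with repairs ensuring
a chain lands in distinct clones, and whole-population resampling rejects
duplicate clones. Frequencies are assigned to clones by a seeded random
permutation, so sharing and dual status are independent of abundance rank.
Drop rates are drawn per population (not redrawn per dataset). All
randomness flows from one seed through numpy SeedSequence spawning; the
stream order is: frequencies permutation, dual flags, slot assignment,
drop rates, error rates (generation), then per-well sampling.

What the generator does *not* emulate: V(D)J recombination or sequence
content, read-level noise, finite-population sampling, cross-plate batch
effects, and PCR efficiency differences between chains. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative model, not robustness to every artefact of real data.

## Problem sizes used in the checks

The validation study runs at desk scale, chosen once: single-cell
comparisons use 200 simulations (96 or 960 cells); the one-plate threshold
sweep uses 5 datasets at N_r = 25; the five-plate study uses 3 datasets at
N_r = 20 with thresholds applied post hoc to shared replicate supports;
generator fidelity uses 10 populations of 10,000 clones. Full-scale
replication (100 datasets × N_r = 100 across all sampling strategies and
skewnesses) is a cluster-sized computation and is not part of the default
suite.

## Known limitations and discrepancies

* Simulated 96-cell single-cell sequencing recovers ~65% of top-half clone
  pairs under the pair-level depth definition used throughout this package,
  a few points above the ~60% reported for the corresponding published
  figure; clone-level readings of "correctly identified" land nearer 62%.
  The analytic expectation of the pair-level metric (per-cell pair recovery
  probability (0.85·0.98)² against the default frequency ramp) agrees with
  our simulation, so the gap reflects a metric-definition or figure-reading
  difference, not a sampling bug.
* At T = 0.9 the one-plate top depth (~71% mean) sits below the published
  78–92% band's lower edge, consistent with the dual-α support-splitting cap
  described above.
* The empirical sharing summary of the published epitope-specific clone
  table (169 distinct CDR3α, 15 shared) requires that third-party
  supplementary CSV, which is not redistributed here; the check runs only
  when the user supplies `data/s1_dataset.csv`.
* Dual-TCRβ clones are simulated (6%) but never *called* — identification
  is dual-α only, and dual-β presence mildly inflates the false pairing
  rate, as in the source study.
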
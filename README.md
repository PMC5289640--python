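# tcrpair

Frequency-based pairing of TCRα and TCRβ chains from multi-well bulk
sequencing, with maximum-likelihood estimation of clonal frequencies and
discrimination of dual-TCRα clones from β-sharing clone pairs.

## The problem

The αβ T-cell receptor is a heterodimer, but standard multiplex sequencing of
the hypervariable CDR3 regions reads the α and β chains separately and loses
the pairing. Sorting many small samples (10–300 cells) of an antigen-specific
population into 96-well plates and bulk-sequencing each well preserves
statistical pairing information: chains of the same clone co-occur across
wells. Recovering the pairs is hard in practice because epitope-specific
populations share CDR3α and CDR3β sequences across clones, 10–30% of T cells
carry two productive α chains (and ~6% two β chains), and sequencing suffers
chain drop-out and in-frame errors. `tcrpair` implements a pairing pipeline
built for exactly these conditions, and — because it models well occupancy
explicitly — also returns each clone's frequency in the parent population
with a confidence interval.

## The method

**Association and assignment.** For α chain *i* and β chain *j*, the
association score over a set of wells is

    S_ij = Σ_k δ_ijk / (c_α^k + c_β^k)

where δ_ijk = 1 if both chains appear in well *k* and c_α^k, c_β^k are the
numbers of distinct chains in the well. Within each well, α chains are
matched one-to-one to β chains by maximising Σ S_ij (a linear sum assignment
problem). Per replicate, pairs assigned more often than the mean of the
positive assignment counts are kept; a pseudo-jackknife (N_r random subsets
of a proportion p_J = 0.75 of wells) retains pairs appearing in more than a
threshold proportion *T* of replicates.

**Frequency estimation.** For a candidate pair with per-well-size occupancy
counts k_l out of w_l wells of n_l cells, the likelihood of clone frequency
*f* is a product of binomials in 1 − q_l, where the absence probability

    q_l = 2(1 − f + fε)^{n_l} − (1 − f + fε²)^{n_l}

accounts for a per-chain-instance drop rate ε (for a three-chain dual-α
clone the analogous form is 3g(ε) − 3g(ε²) + g(ε³)). The MLE is found by
bounded scalar optimisation; 95% CIs are the frequencies where log L falls
1.96 below its maximum.

**Dual-TCRα discrimination.** Candidate pairs sharing a β chain are examined
two ways: the ratio of observed to expected (under independence) three-way
co-occurrence wells, clustered by 1-D 2-means into dual vs two-clone groups;
and, for chains seen together in small wells (< 50 cells), an exact
occupancy-pattern likelihood under both hypotheses, summing over latent
per-clone cell counts. A log-likelihood difference ≥ 10 overrides the
clustering verdict. Called duals replace their two pairs and get a dual-mode
frequency re-estimate.

The package also ships the full synthetic validation machinery: skewed
clone-size distributions (n_s clones covering a proportion p_s of the
population over a linear ramp, flat tail below), published α/β sharing
spectra, dual-α/dual-β prevalences, lognormal clone drop rates and
per-sequence in-frame error rates, the published mixed plate layouts, and
simulated single-cell sequencing for comparison.

## Worked example

```python
from tcrpair import simdata
from tcrpair.model import TCRPairingModel

pop = simdata.generate_population(N=500, n_s=10, seed=11)   # ground truth
plan = simdata.build_sampling_plan("high-mixed", 1)          # one 96-well plate
wells, _ = simdata.sample_wells(pop, plan, seed=12)

res = TCRPairingModel(wells, n_r=50, threshold=0.6, seed=13).fit()
print(res.summary(max_rows=8))
```

```
TCR alpha/beta pairing results
==============================
wells: 96   p_J=0.75  N_r=50  T=0.6  eps=0.15
candidate pairs: 279   clones: 276 (3 dual-alpha)

top clones (of 276):
clone_id alpha_ids beta_id  dual_flag   f_hat  ci_low  ci_high  support
      c0      a289    b018      False 0.10957 0.07197  0.16356  0.92000
      c1      a087    b372      False 0.09984 0.06603  0.14801  0.92000
      c2      a228    b324      False 0.09171 0.06099  0.13528  0.82000
      c3      a080    b163      False 0.06163 0.04206  0.08889  0.96000
      ...
```

Each row is a recovered clone: its chain ids, whether it was called
dual-TCRα, the frequency MLE with its 95% CI, and the proportion of jackknife
replicates supporting the pairing. Here the most abundant true clone
(`a289`/`b018`, true frequency 0.099) is recovered with `f̂ = 0.110`
(CI 0.072–0.164), and the true frequency lies inside the interval.

The same pipeline is scriptable from the shell:

```sh
tcrpair simulate --n-clones 500 --n-top 10 --seed 11 --out sim/
tcrpair pair --input sim/wells.tsv --nr 50 --threshold 0.6 --seed 13 --out pairs.tsv
tcrpair estimate-freq --input sim/wells.tsv --pairs pairs.tsv --eps 0.15 --out freqs.tsv
tcrpair call-duals --input sim/wells.tsv --pairs pairs.tsv --out clones.tsv
tcrpair run-all --out run/          # everything, plus metrics vs ground truth
```

Input well tables are TSV with columns `well_id, sample_size, locus, chain_id`
(one row per distinct chain per well); chain identifiers are opaque strings,
so CDR3 amino-acid sequences pass through untouched.

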
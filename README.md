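# paracn

Aggregate and paralog-specific copy number estimation for low-copy
repeats (segmental duplications) from short-read WGS alignments.

Duplicated genes such as *SMN1/2*, *STRC* or *PMS2* are largely invisible
to standard CNV callers: reads map ambiguously between near-identical
repeat copies, so per-position depth and genotypes are unreliable.
`paracn` sidesteps the ambiguity in two steps:

1. **AggregateCN** — reads from *all* copies of a repeat are pooled onto
   one copy through precomputed self-alignments (a homology table) and the
   total copy number c is estimated from window read depth with a
   multi-sample hidden Markov model. Emissions are Negative Binomial,
   b_w(c) = NB(o_w; n_w·c/2·m_w, p_w), where (n_w, p_w) is the sample's
   GC-matched diploid background and m_w a shared window scale factor;
   transitions between adjacent windows use two jump parameters
   a↗, a↘ ∈ [0, 0.1] with P(i→j) = a↗^(j−i). Parameters are fitted
   jointly across the cohort, so a deletion shared by a few samples
   sharpens the transition probabilities at its boundaries for everyone.
2. **ParalogCN** — the total is apportioned among copies using
   allele-specific read counts at paralogous sequence variants (PSVs).
   Because PSVs can be polymorphic, the population frequency f_vk of the
   reference allele of PSV v on copy k is estimated jointly with the
   per-sample copy-number tuples by an EM algorithm over samples at the
   reference AggregateCN; only *reliable* PSVs (min_k f_vk ≥ 0.95) are
   used to genotype individual samples.

Trio concordance (P(child | parents) under random mating, discordant
below 0.01) validates calls, and fitted model parameters can be frozen to
genotype single samples. A bundled simulator generates toy genomes,
alignments, depth matrices, PSV counts and trios, so everything can be
exercised without external data.

## Worked example

Simulate a six-sample cohort over a two-copy duplication (reference
copy number 4) in which two samples carry a whole deletion of one copy,
then run the full pipeline:

```sh
paracn sim cohort --seed 5 --samples 6 --deletion-carriers 2 -o demo
paracn pipeline -I demo/bamlist.txt --alignments demo/self_align.paf \
    -g demo/genome.fa -r chrSim:10001-12000 --min-samples 4 -o demo/out
```

`demo/out/cn.bed` holds the AggregateCN segments:

```text
#sample  contig  start  end    agg_cn  quality  ref_cn
s0       chrSim  10000  12000  3       48.5     4
s1       chrSim  10000  12000  3       45.3     4
s2       chrSim  10000  12000  4       51.6     4
...
```

The two carriers (s0, s1) are called at AggregateCN 3 — one copy of the
four in the reference is missing — at Phred quality ≈ 45–48 (Q ≥ 20 is
the high-confidence convention); the rest sit at the reference value 4.
`demo/out/pscn.tsv` apportions the total between the two copies:

```text
#sample  paralog_cn  posterior  copy_quals   agg_cn  agg_quality  skip
s0       1,2         1.0000     100.0,100.0  3       48.5         .
s1       1,2         1.0000     100.0,100.0  3       45.3         .
s2       2,2         1.0000     100.0,100.0  4       51.6         .
...
```

so the deletion is assigned to the first repeat copy (ParalogCN 1,2), as
simulated. `demo/out/pscn.tsv.psvs` lists the fitted f values and
reliability flag per PSV, and `model.json` holds the frozen HMM
parameters consumable by `paracn cn-using` for single samples.

The same machinery is available as a library (`paracn.hmm`,
`paracn.pscn`, `paracn.trio`, `paracn.simulate`, ...) and the test suite
runs everything on simulated data only.

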
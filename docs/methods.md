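# Methods

`paracn` estimates the aggregate copy number (AggregateCN) and
paralog-specific copy number (ParalogCN) of low-copy repeats (LCRs,
segmental duplications) from short-read WGS alignments. Reads in such
regions map ambiguously between near-identical copies, so the method never
asks *where* a read maps within the repeat family: it pools reads across
all copies for the total copy number, and uses allele counts at paralogous
sequence variants (PSVs) to apportion that total among copies.

## Homology table and PSVs

Pairwise self-alignments of the reference (PAF records with extended
CIGARs) are filtered by length (default ≥ 500 bp) and sequence similarity
(default ≥ 0.97, exposed as a parameter since different references warrant
different stringency) into an interval-indexed table. A source sequence
participating in more than 10 pairwise alignments is typically an
interspersed repeat rather than an LCR; its records are flagged *tangled*,
kept in the table so queries can warn, and excluded from copy-number
analysis. PSVs are read directly off the stored alignments: one PSV per
mismatch run or indel, indels left-anchored at the preceding matched base
(VCF convention). Coordinate projection between copies walks the stored
CIGAR; positions inside an insertion have no image and project to the
nearest aligned base (ties resolved leftward) where a concrete position is
required, e.g. when assigning pooled reads to windows.

Multi-copy families arise as connected components of the overlap graph of
pairwise records; PSV allele lists are extended to one allele per copy,
with copies matching the primary contributing the primary allele. The
extension assumes each paralog aligns directly to the primary copy, which
holds for the duplication structures modelled here.

## Background read depth

Read depth is tabulated in non-overlapping 100 bp windows; each read pair
counts once, in the window containing the center of its first-in-genome
read. Windows with ≥ 10% low-MAPQ (< 10), improperly paired, or
soft-clipped reads are *irregular* and excluded. Unique-region windows
≥ 500 bp from any duplication supply the copy-number-2 baseline; when a
core region set is given, windows in a 5 kb neighbourhood are admitted
only for extreme GC (≤ 35% or ≥ 55%) to populate sparse strata.

Depth per GC stratum is modelled as Negative Binomial, which absorbs the
overdispersion of real libraries. The fit profiles p through the mean (for
fixed n the NB mean MLE is the sample mean) and maximizes a 1-D likelihood
in log10 n by bounded search; under-dispersed strata fall back to the
Poisson limit (n = 10^6, mean matched). Strata with fewer than 100 regular
windows borrow parameters: log-mean interpolated linearly between the
nearest fitted GC values, dispersion from the nearest; with no fittable
stratum at all a single pooled fit is used (toy genomes).

## Pooled depth and region groups

A query locus is split at every change in its set of overlapping
duplications (duplications < 500 bp ignored) into segments of constant
*reference copy number* (2 × number of copies; a two-copy duplication has
reference CN 4). Same-CN segments separated by < 2000 bp — typically
interrupted by an interspersed repeat — form one *region group*, analyzed
as a single HMM instance. Reads from every copy are projected to the
primary copy and counted with the same center rule into 100 bp windows
(matching the background window size so emissions are directly
comparable). A window irregular in more than 10% of samples is dropped
together with both flanking windows.

## Aggregate copy number HMM

Hidden states are candidate AggregateCN values; the contiguous state range
covers each sample's rounded trimmed-mean normalized depth ± 1, always
contains the reference CN, and is capped at reference + 6. Emissions scale
the background NB size parameter: b(o; c) = NB(o; n·(c/2)·m_w, p), with a
per-window scale factor m_w (shared by all samples) absorbing residual
window-specific bias. Copy number 0 cannot use an NB size of 0; its
emission is a mixture 0.99·δ₀ + 0.01·Geometric(mean 1), tolerating
occasional mismapped reads without zero-likelihood traps.

Transitions between adjacent windows use two parameters per boundary,
a↗, a↘ ∈ [10⁻⁶, 0.1] (initialized at 10⁻⁵): a jump of size d up has
probability a↗^d, down a↘^d, diagonals absorb the remainder. The initial
distribution puts 1/S on each non-reference state (S = cohort size) and
the rest on the reference state — for K states this is normalized as
π_ref = 1 − (K−1)/S, with a renormalization guard for tiny cohorts.

Fitting iterates, per round: per-sample Forward–Backward (log-space);
joint ML update of each m_w by bounded golden-section search on the
γ-weighted NB log-likelihood (bounds [0.1, 10]); pooled update of π
(first-window posteriors with a 1/(10S) floor) and of the per-boundary
jump parameters by 2-D bounded ML on the pooled expected transition
counts. Convergence: total log-likelihood change < 0.01 or 30 iterations.
The trace is monitored; because updates are clamped, exact monotonicity is
not guaranteed and violations are logged.

### Shared-event boundary refinement

Per-sample breakpoint estimates wander by ±2–3 windows at 30×-equivalent
depth (per-window evidence for a one-copy change out of four is ≈ 1 nat),
and the pooled Baum–Welch update inherits that smear: expected jump counts
are dominated by whichever sample has the largest posterior event mass, so
the consensus can bifurcate across neighbouring boundaries and freeze. The
cohort, however, localizes a *shared* breakpoint almost exactly: the
log-likelihood of a candidate boundary summed over carriers is sharply
peaked at the true position. After the iterative fit, decoded
non-reference events are clustered by overlap and copy number; clusters
with ≥ 3 carriers get their shared (start, end) re-estimated by maximizing
the pooled log-likelihood ratio within ±8 windows of the observed
boundaries, the transition parameters are raised to the 0.1 ceiling at the
consensus boundaries, smeared neighbours are reset to the background
(median) level, and all samples are re-decoded. The step is deterministic
and leaves singleton and two-carrier events to the fitted parameters.

Viterbi decoding yields per-sample segments; segment quality is
Q = −10·log₁₀(1 − min_w γ) over the segment's windows, capped at 100,
with Q ≥ 20 the conventional high-quality threshold. Single-sample mode
re-decodes one sample with all parameters (π, a↗, a↘, m, state space, and
the PSV f matrix downstream) frozen from a prior cohort fit; the window
layout is checked by hash.

## Paralog-specific copy number

For reference copy number c_r and sample AggregateCN c_s, ParalogCN is an
integer tuple of length c_r/2 summing to c_s (stars-and-bars:
C(c_s + c_r/2 − 1, c_r/2 − 1) tuples). Loci with c_r > 8 or more than 500
tuples are skipped.

PSV reference-allele frequencies f_vk ∈ [0,1] (PSV v, copy k) and the
hidden per-sample tuples are estimated jointly by EM over samples whose
AggregateCN equals c_r (minimum 50). The per-sample likelihood
marginalizes allele *carriage*: each of the t_k chromosomes of copy k
carries copy k's reference allele with probability f_vk, otherwise one of
the other copies' alleles uniformly; reads then sample chromosomes, with
error mass ε = 0.01 routed to an "other" bin, and base quality ≥ 20
required when counting. Marginalizing the carriage configuration (a
product of binomials) rather than collapsing to the read-level marginal is
essential for identifiability: on a cohort of reference tuples the
collapsed multinomial rate depends only on f differences, making f = (1,1)
and f = (0.5,0.5) indistinguishable, whereas the carriage mixture
preserves the between-sample overdispersion that separates a polymorphic
PSV from a fixed one. The read-level marginal (`allele_prob`) is retained
as the documented limiting distribution of pooled counts.

E-step: posterior over tuples per sample, uniform prior, PSVs
independent. M-step: each PSV row restarts from the best of its current
value and a small candidate grid over {0.5, 0.75, 0.9, 0.97, 1.0}^K — the
expected likelihood is multimodal per PSV and the grid escapes those
optima deterministically — then bounded 1-D coordinate ascent per entry.
Convergence at Δ log-likelihood < 10⁻³ or 100 iterations; two seeded
random restarts of the whole run guard the remaining multimodality. The
observed-data log-likelihood is asserted non-decreasing.

A PSV is *reliable* when min_k f_vk ≥ 0.95. Individual samples are then
genotyped by one E-step over reliable PSVs only (at least 3 with reads
required), with a prior weight of 0.5 on the even tuple when c_s = c_r
(remainder uniform); per-copy qualities are Phred scores of the marginal
posterior for the called value.

At the default cohort conditions (100 samples, ~60 reads per PSV) the f
estimator is information-limited: ~200 chromosomes per copy give a
standard error ≈ 0.013 near f = 0.97, so entries truly at 0.97 carry a
~6% chance each of falling below the 0.95 reliability cut, and doubly
polymorphic PSVs (both entries ≈ 0.5) sit on a likelihood ridge with
per-entry spread ≈ 0.1. Larger cohorts tighten both.

## Trio concordance

Diploid ParalogCN calls are modelled as sums of two independent haploid
tuples (random mating). The haploid distribution is fitted by EM
deconvolution from all high-quality (Q ≥ 20) diploid calls; a uniform
start is a stationary saddle on symmetric cohorts, so initialization is
peaked at half the mean diploid call. For a trio, each parent's call is
decomposed into ordered haploid pairs weighted by the fitted frequencies
(Bayes-conditioned on the call); the child probability sums, over parental
decompositions and the four equally likely transmissions, the indicator
that one maternal plus one paternal haploid equals the child's tuple. A
trio is discordant below 0.01. Children are genotyped independently of
parents.

Note an arbitrary diploid frequency table need not be a convolution
square; the deconvolution returns the ML random-mating approximation, and
the re-convolution check in the test suite therefore uses calls drawn from
an actual random-mating population.

## Synthetic data

The simulator emits every input the pipeline consumes, from one integer
seed: toy genomes (one contig: unique flanks, 2–4 copies of a duplicated
segment separated by unique spacers, substitution PSVs planted at 5/kb,
optional 1 bp indels) together with the exact PAF self-alignment records;
sorted/indexed BAMs of perfectly aligned proper pairs (100 bp reads,
300 bp fragments, MAPQ 60) at per-copy copy numbers; window depth
matrices; PSV allele counts; and Mendelian trios.

Depth defaults emulate a 30× PCR-free paired-end cohort and are derived
from that geometry: 100 bp windows receive coverage·window/(2·read length)
= 15 pairs at copy number 2; NB dispersion n = 30 gives var/mean ≈ 1.5;
a smooth unimodal GC multiplier (peak at 45% GC, amplitude 0.3) with
per-sample log-normal depth factors (σ = 5%) supplies the bias the
GC-stratified background models; PSV sites pool reads over all copies, so
a 30× genome yields ~60 reads per PSV at AggregateCN 4. Truth f values
are drawn from {1.0: 0.6, 0.97: 0.2, 0.5: 0.2}, matching the strongly
bimodal f distributions observed in population data. The matrix path
(counts drawn directly per window) is exact for the HMM/EM layers; the
read-level path exercises I/O, counting, and projection, but carries no
sequencing errors, indels in reads, or mapping ambiguity — passing tests
therefore validate the estimation machinery, not robustness to alignment
artefacts.

Problem sizes in the test suite and acceptance script (100-sample
cohorts, 60-window groups, 20 PSVs, 500 trios) were chosen as the
smallest at which the cohort-level claims are statistically meaningful.

## Numerical choices

Log-space Forward–Backward/Viterbi throughout; a minimal inlined
log-sum-exp avoids per-window call overhead. NB pmfs come from
`scipy.stats.nbinom`; all 1-D maximizations use bounded Brent
(`minimize_scalar`), the 2-D transition fit L-BFGS-B with box
constraints. Degenerate inputs: empty alignment input produces an empty
table; a locus covered only by tangled homology raises a "region
unsuitable" error; all-irregular windows and all-dropped window sets
raise; K = 1 state spaces decode trivially with quality capped at 100;
AggregateCN 0 genotypes as the zero tuple. Ties: gap projections prefer
the left neighbour; haploid-deconvolution iteration order is sorted, so
equal-likelihood decompositions resolve deterministically.

## Limitations

ParalogCN is assumed constant across a constant-AggregateCN region; gene
conversion and hybrid alleles violate this and are out of scope. The
window scale factors m_w and a copy-number event shared by a large
fraction of the cohort are weakly identifiable: when roughly half the
samples carry the same event, the γ-weighted scale update can absorb part
of the depth shift into m_w before the transition parameters detect it,
reducing sensitivity for very common events; event frequencies up to
~10–20% of the cohort are handled well. The
multi-copy PSV extension requires each paralog to align to the primary
copy. Read-backed PSV counting handles substitution PSVs on
forward-oriented copies. The simulator's error model is idealized (see
above). Breakpoint resolution is limited to the 100 bp window grid, and
boundary consensus requires ≥ 3 carriers of a shared event.
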
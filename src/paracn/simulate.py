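"""Synthetic data generator exercising every stage of the pipeline.

Builds toy genomes containing 2-4-copy duplications with planted PSVs (the
simulator knows the exact pairwise alignments, so no aligner is needed),
paired-read alignments or window depth matrices with GC bias and Negative
Binomial noise, PSV allele counts under chosen f matrices and ParalogCN
tuples, and Mendelian trios.  All randomness flows from a single integer
seed; the same seed reproduces every output byte for byte.

Default conditions emulate a 100-sample cohort of ~30x paired-end 100 bp
WGS: at 100 bp windows a fragment contributes one counted pair, giving a
background mean of about 15 pairs per window at copy number 2, with the
mild NB overdispersion of PCR-free libraries.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from . import hmm, pscn
from .homology import Duplication, cigar_to_string
from .intervals import GenomicInterval

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    seed: int = 0
    n_samples: int = 100
    # genome geometry
    copy_length: int = 3000
    n_copies: int = 2
    flank: int = 10000
    spacer: int = 3000
    psv_per_kb: float = 5.0
    psv_indels: int = 0
    # depth model (per 100 bp window, diploid background).  30x coverage
    # with 100 bp paired reads puts ~15 fragments per window (each pair
    # counted once); PCR-free libraries are mildly overdispersed
    # (var/mean ~1.5 at the background mean).
    window_size: int = 100
    depth_mean: float = 15.0
    nb_dispersion: float = 30.0  # NB size n; var = mu + mu^2/n
    gc_bias: float = 0.3         # amplitude of the unimodal GC multiplier
    sample_depth_sd: float = 0.05  # lognormal inter-sample depth variation
    # reads
    read_length: int = 100
    fragment: int = 300
    # PSV counts: reads at a PSV pool over all copies, so a 30x diploid
    # genome yields ~coverage * c_s/2 reads at a site (60 at AggregateCN 4)
    psv_depth: float = 60.0
    seq_error: float = pscn.SEQ_ERROR


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


@dataclass
class SimGenome:
    config: SimConfig
    contig: str
    sequences: dict[str, str]
    copies: list[GenomicInterval]
    duplications: list[Duplication]  # primary (copy 0) vs each other copy
    psv_positions: list[int]         # on the primary copy
    psv_alleles: list[list[str]]     # per PSV, one allele per copy

    def paf_lines(self) -> list[str]:
        """Exact self-alignment records of the planted duplications."""
        out = []
        length = len(self.sequences[self.contig])
        for dup in self.duplications:
            r1, r2 = dup.region1, dup.region2
            match = sum(n for n, op in dup.cigar if op == "=")
            total = sum(n for n, _ in dup.cigar)
            out.append(
                "\t".join(
                    [
                        r1.contig, str(length), str(r1.start), str(r1.end),
                        r2.strand,
                        r2.contig, str(length), str(r2.start), str(r2.end),
                        str(match), str(total), "60",
                        "cg:Z:" + cigar_to_string(dup.cigar),
                    ]
                )
            )
        return out

    def write_fasta(self, path: str) -> str:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        return path


def _random_seq(rng, length: int) -> np.ndarray:
    return rng.choice(4, size=length)


def sim_genome(cfg: SimConfig, *, rng=None) -> SimGenome:
    """One contig: flank | copy1 | spacer | copy2 [| spacer | copy3 ...] | flank.

    Copies are identical except at planted substitution PSVs (and optional
    1 bp deletions); flanks and spacers are unique random sequence."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n_psvs = int(round(cfg.psv_per_kb * cfg.copy_length / 1000))
    if n_psvs == 0 and cfg.n_copies > 1 and cfg.psv_per_kb > 0:
        raise ValueError("PSV density too low for the copy length")

    primary = _random_seq(rng, cfg.copy_length)
    # PSV positions: away from copy edges, min spacing 10 bp
    candidates = np.arange(20, cfg.copy_length - 20)
    positions: list[int] = []
    rng.shuffle(candidates)
    for pos in candidates:
        if len(positions) >= n_psvs + cfg.psv_indels:
            break
        if all(abs(pos - q) >= 10 for q in positions):
            positions.append(int(pos))
    positions.sort()
    indel_set = set(
        rng.choice(positions, size=cfg.psv_indels, replace=False).tolist()
    ) if cfg.psv_indels else set()

    copy_seqs = [primary]
    alleles_per_copy: list[list[str]] = [[] for _ in positions]
    for i, pos in enumerate(positions):
        alleles_per_copy[i].append(str(BASES[primary[pos]]))
    for _ in range(1, cfg.n_copies):
        alt = primary.copy()
        for i, pos in enumerate(positions):
            if pos in indel_set:
                continue
            choices = [b for b in range(4) if b != primary[pos]]
            alt[pos] = rng.choice(choices)
        copy_seqs.append(alt)
        for i, pos in enumerate(positions):
            alleles_per_copy[i].append(str(BASES[copy_seqs[-1][pos]]))

    contig = "chrSim"
    parts = [_random_seq(rng, cfg.flank)]
    copies: list[GenomicInterval] = []
    offset = cfg.flank
    for k, cs in enumerate(copy_seqs):
        seq_k = cs
        if k > 0 and indel_set:
            keep = np.ones(cfg.copy_length, dtype=bool)
            for pos in indel_set:
                keep[pos] = False
            seq_k = cs[keep]
        parts.append(seq_k)
        copies.append(GenomicInterval(contig, offset, offset + len(seq_k)))
        offset += len(seq_k)
        if k < len(copy_seqs) - 1:
            parts.append(_random_seq(rng, cfg.spacer))
            offset += cfg.spacer
    parts.append(_random_seq(rng, cfg.flank))
    genome = "".join(BASES[np.concatenate(parts)])

    # exact alignments primary -> each paralog
    dups = []
    for k in range(1, cfg.n_copies):
        ops: list[tuple[int, str]] = []

        def push(n, op):
            if ops and ops[-1][1] == op:
                ops[-1] = (ops[-1][0] + n, op)
            else:
                ops.append((n, op))

        cursor = 0
        for pos in positions:
            if pos in indel_set:
                if pos > cursor:
                    push(pos - cursor, "=")
                push(1, "I")  # base present on primary only
                cursor = pos + 1
            else:
                if pos > cursor:
                    push(pos - cursor, "=")
                push(1, "X")
                cursor = pos + 1
        if cursor < cfg.copy_length:
            push(cfg.copy_length - cursor, "=")
        dups.append(Duplication(copies[0], copies[k], tuple(ops)))

    sub_positions = [p for p in positions if p not in indel_set]
    sub_alleles = [
        alleles_per_copy[i]
        for i, p in enumerate(positions)
        if p not in indel_set
    ]
    return SimGenome(
        cfg,
        contig,
        {contig: genome},
        copies,
        dups,
        [copies[0].start + p for p in sub_positions],
        sub_alleles,
    )


# ---------------------------------------------------------------------------
# Depth matrices
# ---------------------------------------------------------------------------


def gc_multiplier(gc: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth unimodal GC bias: depth peaks near 45% GC and decays towards
    the extremes (mimicking PCR bias without modelling any chemistry)."""
    gc = np.asarray(gc, dtype=float)
    return 1.0 - amplitude * ((gc - 45.0) / 35.0) ** 2


@dataclass
class SimDepth:
    counts: np.ndarray    # (S, W)
    nb_n: np.ndarray      # (S, W) background NB size per sample/window
    nb_p: np.ndarray      # (S, W)
    gc: np.ndarray        # (W,)
    cn: np.ndarray        # (S, W) truth aggregate CN
    m_w: np.ndarray       # (W,) truth scale factors


def sim_depth(
    cfg: SimConfig,
    cn: np.ndarray,
    *,
    gc: np.ndarray | None = None,
    m_w: np.ndarray | None = None,
    rng=None,
) -> SimDepth:
    """Window counts ~ NB with mean depth_mean * gc_mult * m_w * cn/2.

    ``cn`` is the (S, W) truth AggregateCN matrix.  The returned nb_n/nb_p
    are the diploid background parameters each sample's normalization step
    would supply (they include the per-sample depth factor and GC bias but
    not m_w, which the HMM must recover)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    cn = np.asarray(cn)
    S, W = cn.shape
    if gc is None:
        gc = rng.integers(30, 61, size=W)
    if m_w is None:
        m_w = np.ones(W)
    sample_factor = np.exp(rng.normal(0.0, cfg.sample_depth_sd, size=S))
    base = cfg.depth_mean * gc_multiplier(gc, cfg.gc_bias)  # (W,)
    mu2 = sample_factor[:, None] * base[None, :]            # diploid mean
    n_bg = np.full((S, W), cfg.nb_dispersion, dtype=float)
    p_bg = n_bg / (n_bg + mu2)
    # observed counts at truth CN with window-specific scaling
    n_obs = n_bg * (cn / 2.0) * m_w[None, :]
    counts = np.zeros((S, W), dtype=int)
    pos = n_obs > 0
    counts[pos] = rng.negative_binomial(n_obs[pos], p_bg[pos])
    return SimDepth(counts, n_bg, p_bg, np.asarray(gc), cn, m_w)


def deletion_cohort(
    cfg: SimConfig,
    *,
    n_windows: int = 60,
    del_start: int = 20,
    del_len: int = 20,
    n_carriers: int = 10,
    ref_cn: int = 4,
    delta: int = -1,
    rng=None,
):
    """Truth CN matrix for a cohort where the first ``n_carriers`` samples
    share a partial deletion (or duplication, delta>0) of ``del_len``
    windows — the geometry of a shared event inside a two-copy repeat."""
    cn = np.full((cfg.n_samples, n_windows), ref_cn, dtype=int)
    cn[:n_carriers, del_start : del_start + del_len] += delta
    return sim_depth(cfg, cn, rng=rng)


# ---------------------------------------------------------------------------
# PSV counts
# ---------------------------------------------------------------------------


#: Default PSV reference-allele frequency mixture: most PSVs are fixed or
#: nearly fixed in the population, a minority are common polymorphisms.
F_TRUTH_VALUES = (1.0, 0.97, 0.5)
F_TRUTH_WEIGHTS = (0.6, 0.2, 0.2)


def sim_f_truth(n_psvs: int, n_copies: int = 2, *, rng=None) -> np.ndarray:
    """Draw a truth f matrix from the default bimodal mixture."""
    rng = rng if rng is not None else np.random.default_rng(0)
    vals = np.asarray(F_TRUTH_VALUES)
    idx = rng.choice(len(vals), size=(n_psvs, n_copies), p=F_TRUTH_WEIGHTS)
    return vals[idx]


def sim_psv_counts(
    cfg: SimConfig,
    f_truth: np.ndarray,
    tuples: list[tuple[int, ...]],
    *,
    rng=None,
):
    """Allele-specific PSV read counts for each sample.

    Per sample and PSV, each of the t_k chromosomes of copy k carries copy
    k's allele with probability f_vk, otherwise one of the other copies'
    alleles uniformly; Poisson(psv_depth) reads then sample chromosomes
    uniformly, with probability seq_error of an off-model "other" allele.
    Returns a list over PSVs of (S, K+1) count arrays (alleles assumed
    distinct across copies) matching :class:`paracn.pscn.PsvSet.biallelic`
    layouts for K = 2.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    f_truth = np.asarray(f_truth, dtype=float)
    V, K = f_truth.shape
    S = len(tuples)
    counts = [np.zeros((S, K + 1), dtype=int) for _ in range(V)]
    for s, t in enumerate(tuples):
        t = np.asarray(t)
        c_s = int(t.sum())
        if c_s == 0:
            continue
        chrom_copy = np.repeat(np.arange(K), t)  # copy index per chromosome
        for v in range(V):
            # carriage draw per chromosome
            carries_ref = rng.random(c_s) < f_truth[v][chrom_copy]
            allele = chrom_copy.copy()
            for i in range(c_s):
                if not carries_ref[i]:
                    others = [a for a in range(K) if a != chrom_copy[i]]
                    allele[i] = others[rng.integers(len(others))]
            n_reads = rng.poisson(cfg.psv_depth)
            for _ in range(n_reads):
                if rng.random() < cfg.seq_error:
                    counts[v][s, K] += 1
                else:
                    counts[v][s, allele[rng.integers(c_s)]] += 1
    return counts


# ---------------------------------------------------------------------------
# Trios
# ---------------------------------------------------------------------------


def sim_trios(
    n_trios: int,
    haploid_freqs: dict[tuple[int, ...], float],
    *,
    rng=None,
    spike_fraction: float = 0.0,
    spike_tuples: list[tuple[int, ...]] | None = None,
):
    """Mendelian trios: each parent is the sum of two haploid draws, the
    child the sum of one transmitted haploid per parent.  A ``spike_fraction``
    of children is replaced by tuples drawn from ``spike_tuples`` (impossible
    tuples give guaranteed-discordant trios)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    haps = sorted(haploid_freqs)
    probs = np.array([haploid_freqs[h] for h in haps], dtype=float)
    probs /= probs.sum()

    def draw() -> tuple[int, ...]:
        return haps[rng.choice(len(haps), p=probs)]

    trios = []
    for i in range(n_trios):
        m1, m2 = draw(), draw()
        f1, f2 = draw(), draw()
        mother = tuple(a + b for a, b in zip(m1, m2))
        father = tuple(a + b for a, b in zip(f1, f2))
        cm = (m1, m2)[rng.integers(2)]
        cf = (f1, f2)[rng.integers(2)]
        child = tuple(a + b for a, b in zip(cm, cf))
        if spike_tuples and rng.random() < spike_fraction:
            child = spike_tuples[rng.integers(len(spike_tuples))]
        trios.append((child, mother, father))
    return trios


# ---------------------------------------------------------------------------
# Read-level emission (BAM)
# ---------------------------------------------------------------------------


def sim_bam(
    genome: SimGenome,
    out_path: str,
    *,
    copy_cn: list[int] | None = None,
    coverage: float = 30.0,
    rng=None,
):
    """Paired reads over the simulated contig written as a sorted, indexed
    BAM.  ``copy_cn`` gives the per-copy copy number (default: 2 for every
    region, i.e. the reference configuration); unique sequence is always
    diploid.  Reads are perfectly aligned (no sequencing errors), MAPQ 60,
    proper pairs."""
    import pysam

    cfg = genome.config
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    seq = genome.sequences[genome.contig]
    L = len(seq)
    rl, frag = cfg.read_length, cfg.fragment
    if copy_cn is None:
        copy_cn = [2] * len(genome.copies)

    # per-base haploid multiplicity/2 relative to diploid
    weight = np.ones(L)
    for cn, iv in zip(copy_cn, genome.copies):
        weight[iv.start : iv.end] = cn / 2.0
    n_frags = int(coverage * L / (2 * rl))
    starts = rng.integers(0, L - frag, size=int(n_frags * 1.3))
    acc = rng.random(len(starts)) < weight[starts + frag // 2]
    starts = starts[acc][:n_frags]
    starts.sort()

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": genome.contig, "LN": L}],
        }
    )
    tmp = out_path + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as bam:
        for i, s in enumerate(starts):
            for mate in (0, 1):
                a = pysam.AlignedSegment(header)
                a.query_name = f"frag{i}"
                pos = s if mate == 0 else s + frag - rl
                a.reference_id = 0
                a.reference_start = int(pos)
                a.cigarstring = f"{rl}M"
                a.query_sequence = seq[pos : pos + rl]
                a.query_qualities = pysam.qualitystring_to_array("I" * rl)
                a.mapping_quality = 60
                a.flag = (
                    0x1 | 0x2
                    | (0x40 if mate == 0 else 0x80)
                    | (0x20 if mate == 0 else 0x10)
                )
                a.next_reference_id = 0
                a.next_reference_start = int(s + frag - rl if mate == 0 else s)
                a.template_length = frag if mate == 0 else -frag
                bam.write(a)
    pysam.sort("-o", out_path, tmp)
    os.remove(tmp)
    pysam.index(out_path)
    return out_path
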
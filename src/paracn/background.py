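"""Background read-depth model: GC-stratified Negative Binomial fits.

Read depth in unique (copy-number 2) regions of the genome is tabulated in
non-overlapping fixed-length windows (default 100 bp) and modelled per
sample with a Negative Binomial distribution per GC-content value.  The NB
accommodates the over-dispersion of PCR-based libraries that a Poisson
cannot; windows contaminated by mapping artefacts (low MAPQ, improper
pairs, soft-clipping) are flagged *irregular* and excluded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .homology import HomologyTable, SequenceAccessor
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

WINDOW_SIZE = 100
LOW_MAPQ = 10          # reads below this MAPQ count as low mapping quality
IRREGULAR_FRAC = 0.10  # any artefact fraction at/above this marks a window
DUP_BUFFER = 500       # min distance from any duplication, bp
GC_LOW, GC_HIGH = 35, 55   # extreme-GC thresholds for neighbourhood rescue
NEIGHBORHOOD = 5000
MIN_WINDOWS_PER_GC = 100
_POISSON_N = 1e6       # NB size used as the Poisson limit


@dataclass
class DepthWindow:
    """One fixed-length depth window with artefact fractions."""

    interval: GenomicInterval
    gc_percent: int
    read_count: int = 0
    frac_low_mapq: float = 0.0
    frac_improper: float = 0.0
    frac_clipped: float = 0.0

    @property
    def irregular(self) -> bool:
        return flag_irregular(
            self.frac_low_mapq, self.frac_improper, self.frac_clipped
        )


def flag_irregular(
    frac_low_mapq: float, frac_improper: float, frac_clipped: float
) -> bool:
    """A window is irregular iff any artefact fraction is >= 10%."""
    return max(frac_low_mapq, frac_improper, frac_clipped) >= IRREGULAR_FRAC


def gc_percent(seq: str) -> int:
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return -1
    return round(100 * (seq.count("G") + seq.count("C")) / acgt)


# ---------------------------------------------------------------------------
# Read assignment
# ---------------------------------------------------------------------------


def pair_center(read) -> int | None:
    """Center of the first-in-genome read of a pair (that read is the one
    counted, so each pair is tallied exactly once); unpaired reads use their
    own center.  Returns None when the mate, not this read, represents the
    pair."""
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return None
    if read.is_paired and not read.mate_is_unmapped \
            and read.reference_id == read.next_reference_id:
        first = (
            read.reference_start < read.next_reference_start
            or (read.reference_start == read.next_reference_start and read.is_read1)
        )
        if not first:
            return None
    return (read.reference_start + read.reference_end) // 2


def is_clipped(read) -> bool:
    return any(op in (4, 5) for op, _ in (read.cigartuples or ()))


def assign_reads(alignments, windows: list[DepthWindow]) -> None:
    """Count read pairs into windows in place (center-of-first-read rule).

    ``alignments`` is an open coordinate-sorted pysam.AlignmentFile;
    ``windows`` must be non-overlapping.  Artefact fractions are filled from
    all reads whose center lands in a window.
    """
    by_contig: dict[str, list[DepthWindow]] = {}
    for w in windows:
        by_contig.setdefault(w.interval.contig, []).append(w)
    for contig, wins in by_contig.items():
        wins.sort(key=lambda w: w.interval.start)
        starts = np.array([w.interval.start for w in wins])
        last = -1
        totals = np.zeros(len(wins), dtype=int)
        low_mapq = np.zeros(len(wins), dtype=int)
        improper = np.zeros(len(wins), dtype=int)
        clipped = np.zeros(len(wins), dtype=int)
        lo, hi = wins[0].interval.start, wins[-1].interval.end
        for read in alignments.fetch(contig, max(0, lo - 1000), hi + 1000):
            if read.reference_start < last:
                raise ValueError("alignments are not coordinate-sorted")
            last = read.reference_start
            center = pair_center(read)
            if center is None:
                continue
            idx = int(np.searchsorted(starts, center, side="right")) - 1
            if idx < 0 or not wins[idx].interval.contains(center):
                continue
            totals[idx] += 1
            if read.mapping_quality < LOW_MAPQ:
                low_mapq[idx] += 1
            if read.is_paired and not read.is_proper_pair:
                improper[idx] += 1
            if is_clipped(read):
                clipped[idx] += 1
        for i, w in enumerate(wins):
            w.read_count = int(totals[i])
            if totals[i] > 0:
                w.frac_low_mapq = low_mapq[i] / totals[i]
                w.frac_improper = improper[i] / totals[i]
                w.frac_clipped = clipped[i] / totals[i]


# ---------------------------------------------------------------------------
# Window selection
# ---------------------------------------------------------------------------


def select_background_windows(
    genome,
    table: HomologyTable | None = None,
    *,
    regions: list[GenomicInterval] | None = None,
    window_size: int = WINDOW_SIZE,
    target_count: int | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> list[DepthWindow]:
    """Select non-overlapping unique-sequence windows for background fitting.

    Windows within ``DUP_BUFFER`` bp of any duplication in the table (either
    side, tangled included) are discarded, as are windows containing N.  When
    ``regions`` restricts the core set, extra windows in a 5 kb neighbourhood
    are admitted only if their GC content is extreme (<=35% or >=55%), to
    populate sparse GC strata.
    """
    acc = genome if isinstance(genome, SequenceAccessor) else SequenceAccessor(genome)
    if contig_lengths is None:
        src = acc._src
        if isinstance(src, dict):
            contig_lengths = {c: len(s) for c, s in src.items()}
        else:
            contig_lengths = {name: len(src[name]) for name in src.keys()}

    excluded: dict[str, list[tuple[int, int]]] = {}
    if table is not None:
        for dup in table.duplications:
            for region in (dup.region1, dup.region2):
                excluded.setdefault(region.contig, []).append(
                    (region.start - DUP_BUFFER, region.end + DUP_BUFFER)
                )

    def blocked(contig: str, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in excluded.get(contig, ()))

    core: list[tuple[str, int]] = []
    flank: list[tuple[str, int]] = []
    for contig, length in contig_lengths.items():
        for start in range(0, length - window_size + 1, window_size):
            if regions is None:
                core.append((contig, start))
                continue
            iv = GenomicInterval(contig, start, start + window_size)
            in_core = any(r.contig == contig and r.start <= start
                          and start + window_size <= r.end for r in regions)
            if in_core:
                core.append((contig, start))
            elif any(
                r.contig == contig
                and r.start - NEIGHBORHOOD <= start
                and start + window_size <= r.end + NEIGHBORHOOD
                for r in regions
            ):
                flank.append((contig, start))

    windows: list[DepthWindow] = []
    for pool, extreme_only in ((core, False), (flank, True)):
        for contig, start in pool:
            if blocked(contig, start, start + window_size):
                continue
            seq = acc.fetch(contig, start, start + window_size)
            if "N" in seq:
                continue
            gc = gc_percent(seq)
            if extreme_only and GC_LOW < gc < GC_HIGH:
                continue
            windows.append(
                DepthWindow(GenomicInterval(contig, start, start + window_size), gc)
            )
    if not windows:
        raise ValueError(
            "no unique-sequence windows available; provide a larger genome "
            "or fewer duplications"
        )
    if target_count is not None and len(windows) > target_count:
        windows = windows[:target_count]
    return windows


# ---------------------------------------------------------------------------
# NB fitting
# ---------------------------------------------------------------------------


def fit_nb_mle(counts: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood NB(n, p) for one GC stratum.

    p is profiled through the mean (for fixed n the NB MLE of the mean is
    the sample mean), leaving a smooth 1-D likelihood in n maximized by
    bounded search over log10 n.  Under-dispersed or constant counts fall
    back to the Poisson limit (large n, mean matched).
    """
    counts = np.asarray(counts, dtype=float)
    mean = counts.mean()
    var = counts.var()
    if mean <= 0:
        raise ValueError("cannot fit NB to all-zero counts")
    if var <= mean:
        n = _POISSON_N
        return n, n / (n + mean)

    def nll(log10_n: float) -> float:
        n = 10.0 ** log10_n
        p = n / (n + mean)
        return -stats.nbinom.logpmf(counts, n, p).sum()

    res = optimize.minimize_scalar(nll, bounds=(-3.0, 8.0), method="bounded")
    n = 10.0 ** res.x
    return n, n / (n + mean)


def nb_mean(n: float, p: float) -> float:
    return n * (1.0 - p) / p


@dataclass
class NbModel:
    """Per-sample background model: GC value -> NB(n, p) at copy number 2."""

    params: dict[int, tuple[float, float]]
    window_size: int = WINDOW_SIZE
    n_windows_used: dict[int, int] = field(default_factory=dict)
    sample: str = ""
    genome_id: str = ""

    def get(self, gc: int) -> tuple[float, float]:
        try:
            return self.params[gc]
        except KeyError:
            raise KeyError(f"no NB parameters for GC={gc}") from None

    def mean(self, gc: int) -> float:
        n, p = self.get(gc)
        return nb_mean(n, p)

    def save(self, path: str) -> None:
        meta = {
            "window_size": self.window_size,
            "sample": self.sample,
            "genome_id": self.genome_id,
            "low_mapq": LOW_MAPQ,
            "irregular_frac": IRREGULAR_FRAC,
        }
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(meta) + "\n")
            fh.write("gc\tn\tp\twindows_used\n")
            for gc in sorted(self.params):
                n, p = self.params[gc]
                fh.write(
                    f"{gc}\t{n:.8g}\t{p:.10g}\t{self.n_windows_used.get(gc, 0)}\n"
                )

    @classmethod
    def load(cls, path: str) -> "NbModel":
        params: dict[int, tuple[float, float]] = {}
        used: dict[int, int] = {}
        meta: dict = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    meta = json.loads(line[1:])
                elif not line.startswith("gc\t"):
                    gc, n, p, nw = line.split("\t")
                    params[int(gc)] = (float(n), float(p))
                    used[int(gc)] = int(nw)
        return cls(
            params,
            window_size=meta.get("window_size", WINDOW_SIZE),
            n_windows_used=used,
            sample=meta.get("sample", ""),
            genome_id=meta.get("genome_id", ""),
        )


def fit_nb(
    windows: list[DepthWindow],
    *,
    min_windows: int = MIN_WINDOWS_PER_GC,
    window_size: int = WINDOW_SIZE,
    sample: str = "",
    genome_id: str = "",
) -> NbModel:
    """Fit per-GC NB parameters from regular windows.

    GC values observed with fewer than ``min_windows`` regular windows borrow
    parameters from fitted neighbours: the log-mean is interpolated linearly
    between the nearest fitted GC values (extrapolation holds the end value)
    and the dispersion n is taken from the nearest fitted value.
    """
    regular = [w for w in windows if not w.irregular]
    if not regular:
        raise ValueError("all windows are irregular; cannot fit background")
    by_gc: dict[int, list[int]] = {}
    for w in regular:
        by_gc.setdefault(w.gc_percent, []).append(w.read_count)

    params: dict[int, tuple[float, float]] = {}
    used: dict[int, int] = {}
    for gc, counts in by_gc.items():
        used[gc] = len(counts)
        if len(counts) >= min_windows and np.mean(counts) > 0:
            params[gc] = fit_nb_mle(np.asarray(counts))
    if not params:
        # too few windows everywhere: pool all strata into one fit
        pooled = np.asarray([w.read_count for w in regular])
        logger.warning(
            "no GC stratum reached %d windows; fitting a single pooled NB",
            min_windows,
        )
        np_ = fit_nb_mle(pooled)
        params = {gc: np_ for gc in by_gc}
        return NbModel(params, window_size, used, sample, genome_id)

    fitted = sorted(params)
    log_means = {gc: float(np.log(nb_mean(*params[gc]))) for gc in fitted}
    for gc in sorted(by_gc):
        if gc in params:
            continue
        lo = max((g for g in fitted if g <= gc), default=None)
        hi = min((g for g in fitted if g >= gc), default=None)
        if lo is None:
            lm, n_src = log_means[hi], hi
        elif hi is None:
            lm, n_src = log_means[lo], lo
        else:
            t = (gc - lo) / (hi - lo)
            lm = (1 - t) * log_means[lo] + t * log_means[hi]
            n_src = lo if gc - lo <= hi - gc else hi
        n = params[n_src][0]
        mean = float(np.exp(lm))
        params[gc] = (n, n / (n + mean))
    return NbModel(params, window_size, used, sample, genome_id)
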
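"""Pooled aggregate read depth over all copies of a low-copy repeat.

For a query locus, reads aligned to every homologous copy are projected onto
the primary copy through the stored alignments (no realignment) and counted
into fixed-length windows, yielding per-sample aggregate depth o_w^(s).  The
locus is first partitioned into segments of constant *reference copy number*
(2 x number of copies; a plain two-copy duplication has reference CN 4), and
same-CN segments separated by short interruptions (<2 kb) are analyzed
together as one region group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import background
from .background import DepthWindow, gc_percent, pair_center
from .homology import GAP, Duplication, HomologyTable, SequenceAccessor
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

MIN_DUP_LENGTH = 500   # duplications shorter than this are skipped
MAX_GROUP_GAP = 2000   # same-CN segments closer than this form one group
MAX_IRREGULAR_SAMPLE_FRAC = 0.10  # window dropped if irregular in > this


class RegionUnsuitableError(ValueError):
    pass


@dataclass
class ConstCnSegment:
    """A locus sub-interval with a constant set of homologous copies."""

    interval: GenomicInterval
    dups: list[Duplication]  # oriented: region1 overlaps the segment

    @property
    def copies(self) -> list[GenomicInterval]:
        """All copies of this segment, the segment itself first."""
        out = [self.interval]
        for dup in self.dups:
            out.append(dup.project_interval(self.interval))
        return out

    @property
    def ref_copy_number(self) -> int:
        return 2 * (1 + len(self.dups))


@dataclass
class RegionGroup:
    """Same-reference-CN segments analyzed as one HMM instance."""

    segments: list[ConstCnSegment]
    gap_merged: bool = False

    @property
    def ref_copy_number(self) -> int:
        return self.segments[0].ref_copy_number

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.segments[0].interval.contig,
            self.segments[0].interval.start,
            self.segments[-1].interval.end,
        )


@dataclass
class AggDepthMatrix:
    """Pooled read counts: samples x windows, with window metadata."""

    samples: list[str]
    windows: pd.DataFrame  # columns: contig, start, end, gc, keep
    counts: np.ndarray     # int, shape (S, W)
    irregular: np.ndarray  # bool, shape (S, W)

    def kept(self) -> np.ndarray:
        return self.windows["keep"].to_numpy()

    def save(self, path: str) -> None:
        df = self.windows.copy()
        for i, s in enumerate(self.samples):
            df[s] = self.counts[i]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str) -> "AggDepthMatrix":
        df = pd.read_csv(path, sep="\t")
        meta_cols = ["contig", "start", "end", "gc", "keep"]
        samples = [c for c in df.columns if c not in meta_cols]
        counts = df[samples].to_numpy().T.astype(int)
        return cls(
            samples,
            df[meta_cols],
            counts,
            np.zeros_like(counts, dtype=bool),
        )


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def segment_locus(
    locus: GenomicInterval,
    table: HomologyTable,
    *,
    min_dup_length: int = MIN_DUP_LENGTH,
) -> list[ConstCnSegment]:
    """Partition a locus at every change in the set of overlapping
    duplications (short duplications <500 bp ignored)."""
    tangled = [
        d for d in table.overlapping(locus, include_tangled=True) if d.tangled
    ]
    dups = [
        d
        for d in table.overlapping(locus)
        if d.region1.length >= min_dup_length
    ]
    if not dups and tangled:
        cover = 0
        last = locus.start
        for d in sorted(tangled, key=lambda d: d.region1.start):
            s = max(d.region1.start, last)
            e = min(d.region1.end, locus.end)
            if e > s:
                cover += e - s
                last = e
        if cover >= locus.length:
            raise RegionUnsuitableError(
                f"region {locus.to_region()} unsuitable: only tangled homology"
            )

    points = {locus.start, locus.end}
    for d in dups:
        points.add(max(locus.start, d.region1.start))
        points.add(min(locus.end, d.region1.end))
    points = sorted(points)

    segments: list[ConstCnSegment] = []
    for a, b in zip(points[:-1], points[1:]):
        iv = GenomicInterval(locus.contig, a, b)
        here = [d for d in dups if d.region1.start <= a and b <= d.region1.end]
        if segments and len(segments[-1].dups) == len(here) and all(
            x is y for x, y in zip(segments[-1].dups, here)
        ):
            segments[-1] = ConstCnSegment(
                GenomicInterval(locus.contig, segments[-1].interval.start, b),
                here,
            )
        else:
            segments.append(ConstCnSegment(iv, here))
    return segments


def group_segments(
    segments: list[ConstCnSegment], *, max_gap: int = MAX_GROUP_GAP
) -> list[RegionGroup]:
    """Merge same-reference-CN segments separated by < ``max_gap`` bp."""
    groups: list[RegionGroup] = []
    open_groups: dict[int, RegionGroup] = {}  # ref_cn -> growing group
    for seg in sorted(segments, key=lambda s: s.interval.start):
        cn = seg.ref_copy_number
        grp = open_groups.get(cn)
        if grp is not None and (
            seg.interval.start - grp.segments[-1].interval.end < max_gap
        ):
            grp.segments.append(seg)
            grp.gap_merged = True
        else:
            grp = RegionGroup([seg])
            groups.append(grp)
            open_groups[cn] = grp
    return sorted(groups, key=lambda g: g.span.start)


def make_windows(
    group: RegionGroup, genome, *, window_size: int | None = None
) -> pd.DataFrame:
    """Tile the group's segments into non-overlapping fixed-length windows
    (same length as the background model so emissions are comparable)."""
    window_size = window_size or background.WINDOW_SIZE
    acc = genome if isinstance(genome, SequenceAccessor) else SequenceAccessor(genome)
    rows = []
    for seg in group.segments:
        start = seg.interval.start
        while start + window_size <= seg.interval.end:
            seq = acc.fetch(seg.interval.contig, start, start + window_size)
            rows.append(
                {
                    "contig": seg.interval.contig,
                    "start": start,
                    "end": start + window_size,
                    "gc": gc_percent(seq),
                    "keep": True,
                }
            )
            start += window_size
    if not rows:
        raise RegionUnsuitableError("region group shorter than one window")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------


def _count_into(
    centers: list[int], starts: np.ndarray, ends: np.ndarray,
    counts: np.ndarray, flags: list[np.ndarray], flag_values: list[list[bool]],
) -> None:
    for c, fv in zip(centers, flag_values):
        idx = int(np.searchsorted(starts, c, side="right")) - 1
        if idx < 0 or c >= ends[idx]:
            continue
        counts[idx] += 1
        for arr, v in zip(flags, fv):
            if v:
                arr[idx] += 1


def pool_sample(alignments, group: RegionGroup, windows: pd.DataFrame):
    """Project one sample's reads from all copies onto the primary copy and
    count by the first-read-center rule.  Returns (counts, irregular) per
    window; read pairs whose projected center falls outside every window are
    counted and logged."""
    starts = windows["start"].to_numpy()
    ends = windows["end"].to_numpy()
    W = len(windows)
    counts = np.zeros(W, dtype=int)
    totals = np.zeros(W, dtype=int)
    low_mapq = np.zeros(W, dtype=int)
    improper = np.zeros(W, dtype=int)
    clipped = np.zeros(W, dtype=int)
    lost = 0

    def handle(read, project) -> None:
        nonlocal lost
        center = pair_center(read)
        if center is None:
            return
        try:
            proj = project(center)
        except ValueError:
            lost += 1
            return
        idx = int(np.searchsorted(starts, proj, side="right")) - 1
        if idx < 0 or proj >= ends[idx]:
            lost += 1
            return
        counts[idx] += 1
        totals[idx] += 1
        if read.mapping_quality < background.LOW_MAPQ:
            low_mapq[idx] += 1
        if read.is_paired and not read.is_proper_pair:
            improper[idx] += 1
        if background.is_clipped(read):
            clipped[idx] += 1

    for seg in group.segments:
        iv = seg.interval
        for read in alignments.fetch(iv.contig, max(0, iv.start - 500), iv.end + 500):
            handle(read, lambda c: c)
        for dup in seg.dups:
            r2 = dup.region2
            for read in alignments.fetch(r2.contig, r2.start, r2.end):
                handle(read, lambda c, d=dup: d.project_nearest(c, from_region=2))
    if lost:
        logger.info("%d read pair(s) projected outside the primary windows", lost)

    with np.errstate(divide="ignore", invalid="ignore"):
        irr = np.zeros(W, dtype=bool)
        nz = totals > 0
        irr[nz] = (
            (low_mapq[nz] / totals[nz] >= background.IRREGULAR_FRAC)
            | (improper[nz] / totals[nz] >= background.IRREGULAR_FRAC)
            | (clipped[nz] / totals[nz] >= background.IRREGULAR_FRAC)
        )
    return counts, irr


def pool_and_count(
    group: RegionGroup, bam_paths: dict[str, str], genome
) -> AggDepthMatrix:
    """Pooled aggregate depth matrix for a cohort over one region group."""
    import pysam

    windows = make_windows(group, genome)
    samples = sorted(bam_paths)
    counts = np.zeros((len(samples), len(windows)), dtype=int)
    irregular = np.zeros((len(samples), len(windows)), dtype=bool)
    for i, sample in enumerate(samples):
        with pysam.AlignmentFile(bam_paths[sample]) as bam:
            counts[i], irregular[i] = pool_sample(bam, group, windows)
    matrix = AggDepthMatrix(samples, windows, counts, irregular)
    filter_windows(matrix)
    return matrix


def filter_windows(
    matrix: AggDepthMatrix, *, max_frac: float = MAX_IRREGULAR_SAMPLE_FRAC
) -> np.ndarray:
    """Drop windows irregular in more than ``max_frac`` of samples, plus one
    flanking window on either side.  Updates ``matrix.windows['keep']``."""
    S = len(matrix.samples)
    frac = matrix.irregular.sum(axis=0) / max(S, 1)
    drop = frac > max_frac
    dilated = drop.copy()
    dilated[:-1] |= drop[1:]
    dilated[1:] |= drop[:-1]
    keep = ~dilated
    if not keep.any():
        raise RegionUnsuitableError("no usable windows after irregular filter")
    matrix.windows["keep"] = keep
    return keep
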
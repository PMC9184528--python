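"""Homology table: pairwise duplications, PSV extraction, coordinate projection.

The table stores pairwise self-alignments of a reference genome (one record
per duplicated sequence pair) and is the backbone of copy-number analysis:
it answers "which other regions are homologous to this locus", lifts
positions and reads between repeat copies through the stored alignments, and
yields the paralogous sequence variants (PSVs) that differentiate copies.

Alignment convention: ``region1`` plays the role of the query and ``region2``
the target.  CIGAR operations are ``=`` (match), ``X`` (mismatch), ``I``
(insertion in region1 relative to region2) and ``D`` (deletion from region1,
i.e. bases present only in region2).  ``=``/``X``/``I`` consume region1,
``=``/``X``/``D`` consume region2.  For a ``-`` strand record the alignment
walks region1 forward and region2 from its end backwards (region2 bases
reverse-complemented).
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace

import networkx as nx
from intervaltree import IntervalTree

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

# A source sequence taking part in more than this many pairwise alignments is
# flagged "tangled" (typically an interspersed repeat) and excluded from
# copy-number queries.
MAX_PAIRWISE_ALIGNMENTS = 10
DEFAULT_MIN_LENGTH = 500
DEFAULT_MIN_SIMILARITY = 0.97

GAP = None  # marker returned by project_position inside an insertion

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def parse_cigar(text: str) -> tuple[tuple[int, str], ...]:
    ops = []
    pos = 0
    for m in _CIGAR_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed CIGAR {text!r}")
        ops.append((int(m.group(1)), m.group(2)))
        pos = m.end()
    if pos != len(text) or not ops:
        raise ValueError(f"malformed CIGAR {text!r}")
    return tuple(ops)


def cigar_to_string(cigar) -> str:
    return "".join(f"{n}{op}" for n, op in cigar)


def _consumed(cigar, which: int) -> int:
    ops = "=XIM" if which == 1 else "=XDM"
    return sum(n for n, op in cigar if op in ops)


@dataclass
class Duplication:
    """One pairwise duplication record with its stored alignment."""

    region1: GenomicInterval
    region2: GenomicInterval
    cigar: tuple[tuple[int, str], ...]
    tangled: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.cigar, list):
            self.cigar = tuple(tuple(c) for c in self.cigar)
        len1, len2 = _consumed(self.cigar, 1), _consumed(self.cigar, 2)
        if len1 != self.region1.length or len2 != self.region2.length:
            raise ValueError(
                f"CIGAR consumes {len1}/{len2} bp but regions are "
                f"{self.region1.length}/{self.region2.length} bp"
            )

    @property
    def strand(self) -> str:
        """Relative orientation of region2 w.r.t. region1."""
        return self.region2.strand

    @property
    def length(self) -> int:
        return self.region1.length

    @property
    def similarity(self) -> float:
        """Matching columns / all alignment columns (indels count as columns)."""
        total = sum(n for n, _ in self.cigar)
        match = sum(n for n, op in self.cigar if op == "=")
        return match / total

    def flipped(self) -> "Duplication":
        """Same duplication viewed with region2 as the primary copy."""
        swap = {"I": "D", "D": "I"}
        cigar = tuple((n, swap.get(op, op)) for n, op in self.cigar)
        if self.strand == "-":
            cigar = cigar[::-1]
        r1 = replace(self.region2, strand="+")
        r2 = replace(self.region1, strand=self.strand)
        return Duplication(r1, r2, cigar, tangled=self.tangled)

    # ---- coordinate projection -------------------------------------------

    def _walk(self):
        """Yield (op, pos1, pos2, run_length) with pos2 in region2-forward
        coordinates regardless of strand (pos2 is the leftmost base of the
        run on the forward strand for '+', the rightmost for '-')."""
        pos1 = self.region1.start
        if self.strand == "+":
            pos2 = self.region2.start
            for n, op in self.cigar:
                yield op, pos1, pos2, n
                if op in "=XI":
                    pos1 += n
                if op in "=XD":
                    pos2 += n
        else:
            pos2 = self.region2.end  # exclusive; walk backwards
            for n, op in self.cigar:
                if op in "=XD":
                    nxt2 = pos2 - n
                else:
                    nxt2 = pos2
                yield op, pos1, nxt2, n
                if op in "=XI":
                    pos1 += n
                pos2 = nxt2

    def project(self, pos: int, *, from_region: int = 1) -> int | None:
        """Project a position between copies through the stored alignment.

        Match/mismatch columns map 1:1; a position inside an insertion on the
        source copy returns ``None`` (gap marker).  Raises ``ValueError`` when
        the position is outside the source region.
        """
        dup = self if from_region == 1 else self.flipped()
        if not dup.region1.contains(pos):
            raise ValueError(f"position {pos} outside {dup.region1}")
        for op, p1, p2, n in dup._walk():
            if op in "=XM" and p1 <= pos < p1 + n:
                off = pos - p1
                if dup.strand == "+":
                    return p2 + off
                return p2 + n - 1 - off
            if op == "I" and p1 <= pos < p1 + n:
                return GAP
        raise AssertionError("unreachable: position not consumed by CIGAR")

    def project_nearest(self, pos: int, *, from_region: int = 1) -> int:
        """Like :meth:`project`, but a position in a gap maps to the nearest
        aligned base's projection, preferring the left neighbour on ties."""
        dup = self if from_region == 1 else self.flipped()
        if not dup.region1.contains(pos):
            raise ValueError(f"position {pos} outside {dup.region1}")
        res = dup.project(pos)
        if res is not None:
            return res
        aligned = [
            (p1, p1 + n - 1)
            for op, p1, _, n in dup._walk()
            if op in "=XM"
        ]
        best, best_dist = None, None
        for lo, hi in aligned:
            cand = lo if pos < lo else hi
            dist = abs(pos - cand)
            if best_dist is None or dist < best_dist:
                best, best_dist = cand, dist
        if best is None:
            raise ValueError("alignment has no aligned columns")
        return dup.project(best)

    def project_interval(self, iv: GenomicInterval) -> GenomicInterval:
        """Project an interval on region1 to region2 (nearest-base at gaps)."""
        a = self.project_nearest(max(iv.start, self.region1.start))
        b = self.project_nearest(min(iv.end - 1, self.region1.end - 1))
        lo, hi = min(a, b), max(a, b)
        return GenomicInterval(self.region2.contig, lo, hi + 1, self.strand)

    def to_row(self) -> str:
        r1, r2 = self.region1, self.region2
        return "\t".join(
            [
                r1.contig, str(r1.start), str(r1.end),
                r2.contig, str(r2.start), str(r2.end), r2.strand,
                str(self.length), f"{self.similarity:.6f}",
                cigar_to_string(self.cigar),
                "tangled" if self.tangled else ".",
            ]
        )

    @classmethod
    def from_row(cls, line: str) -> "Duplication":
        f = line.rstrip("\n").split("\t")
        dup = cls(
            GenomicInterval(f[0], int(f[1]), int(f[2])),
            GenomicInterval(f[3], int(f[4]), int(f[5]), f[6]),
            parse_cigar(f[9]),
            tangled=f[10] == "tangled",
        )
        return dup


@dataclass
class Psv:
    """A paralogous sequence variant: a position where repeat copies differ.

    ``alleles[k]`` is the reference sequence of copy ``k`` at the projected
    position (allele 0 belongs to the primary copy); indel PSVs are
    left-anchored at the preceding matched base, VCF-style.
    """

    position: GenomicInterval
    alleles: list[str]
    copies: list[GenomicInterval]

    def __post_init__(self) -> None:
        if len(self.alleles) < 2:
            raise ValueError("a PSV needs at least two alleles")
        if len(set(self.alleles)) < 2:
            raise ValueError("PSV alleles must not all be identical")

    @property
    def is_indel(self) -> bool:
        return len(set(map(len, self.alleles))) > 1


class SequenceAccessor:
    """Uniform .fetch() over a dict of sequences or a pyfaidx.Fasta."""

    def __init__(self, source):
        self._src = source

    def fetch(self, contig: str, start: int, end: int) -> str:
        try:
            if isinstance(self._src, dict):
                seq = self._src[contig][start:end]
            else:
                seq = str(self._src[contig][start:end])
        except KeyError as exc:
            raise KeyError(f"contig {contig!r} not found in genome") from exc
        return str(seq).upper()


def resolve_matches(dup: Duplication, genome) -> Duplication:
    """Split ambiguous M runs into =/X by comparing the two sequences."""
    if not any(op == "M" for _, op in dup.cigar):
        return dup
    acc = genome if isinstance(genome, SequenceAccessor) else SequenceAccessor(genome)
    seq1 = acc.fetch(dup.region1.contig, dup.region1.start, dup.region1.end)
    seq2 = acc.fetch(dup.region2.contig, dup.region2.start, dup.region2.end)
    if dup.strand == "-":
        seq2 = reverse_complement(seq2)
    ops: list[tuple[int, str]] = []

    def push(n: int, op: str) -> None:
        if ops and ops[-1][1] == op:
            ops[-1] = (ops[-1][0] + n, op)
        else:
            ops.append((n, op))

    off1 = off2 = 0
    for n, op in dup.cigar:
        if op == "M":
            for j in range(n):
                push(1, "=" if seq1[off1 + j] == seq2[off2 + j] else "X")
            off1 += n
            off2 += n
        else:
            push(n, op)
            if op in "=XI":
                off1 += n
            if op in "=XD":
                off2 += n
    return replace(dup, cigar=tuple(ops))


def extract_psvs(dup: Duplication, genome) -> list[Psv]:
    """Walk the stored alignment and emit one PSV per mismatch run or indel."""
    acc = genome if isinstance(genome, SequenceAccessor) else SequenceAccessor(genome)
    dup = resolve_matches(dup, acc)
    seq1 = acc.fetch(dup.region1.contig, dup.region1.start, dup.region1.end)
    seq2 = acc.fetch(dup.region2.contig, dup.region2.start, dup.region2.end)
    if dup.strand == "-":
        seq2 = reverse_complement(seq2)

    def pos2_genomic(off2: int, span2: int = 1) -> GenomicInterval:
        # offset in alignment orientation -> forward-strand genomic interval
        if dup.strand == "+":
            s = dup.region2.start + off2
            return GenomicInterval(dup.region2.contig, s, s + span2, "+")
        e = dup.region2.end - off2
        return GenomicInterval(dup.region2.contig, e - span2, e, "-")

    psvs: list[Psv] = []
    off1 = off2 = 0

    def add(pos1: int, a1: str, a2: str, o2: int, span2: int) -> None:
        psvs.append(
            Psv(
                GenomicInterval(dup.region1.contig, pos1, pos1 + len(a1)),
                [a1, a2],
                [
                    GenomicInterval(dup.region1.contig, pos1, pos1 + len(a1)),
                    pos2_genomic(o2, span2),
                ],
            )
        )

    ops = list(dup.cigar)
    i = 0
    while i < len(ops):
        n, op = ops[i]
        if op in "=M":
            off1 += n
            off2 += n
            i += 1
        elif op == "X":
            # merge a run of consecutive X ops
            run = n
            while i + 1 < len(ops) and ops[i + 1][1] == "X":
                i += 1
                run += ops[i][0]
            a1 = seq1[off1 : off1 + run]
            a2 = seq2[off2 : off2 + run]
            add(dup.region1.start + off1, a1, a2, off2, run)
            off1 += run
            off2 += run
            i += 1
        elif op == "I":
            if off1 == 0 or off2 == 0:
                raise ValueError("indel at alignment start cannot be anchored")
            a1 = seq1[off1 - 1 : off1 + n]
            a2 = seq2[off2 - 1 : off2]
            add(dup.region1.start + off1 - 1, a1, a2, off2 - 1, 1)
            off1 += n
            i += 1
        elif op == "D":
            if off1 == 0 or off2 == 0:
                raise ValueError("indel at alignment start cannot be anchored")
            a1 = seq1[off1 - 1 : off1]
            a2 = seq2[off2 - 1 : off2 + n]
            add(dup.region1.start + off1 - 1, a1, a2, off2 - 1, n + 1)
            off2 += n
            i += 1
        else:  # pragma: no cover
            raise ValueError(f"unsupported op {op!r}")
    return psvs


def apply_psvs(seq1: str, dup: Duplication, psvs: list[Psv]) -> str:
    """Rebuild region2's sequence (alignment orientation) from region1's
    sequence and the PSV allele list — the extraction round-trip oracle."""
    out = []
    cursor = 0
    start = dup.region1.start
    for psv in sorted(psvs, key=lambda p: p.position.start):
        off = psv.position.start - start
        out.append(seq1[cursor:off])
        out.append(psv.alleles[1])
        cursor = off + len(psv.alleles[0])
    out.append(seq1[cursor:])
    return "".join(out)


# ---------------------------------------------------------------------------
# Table
# ---------------------------------------------------------------------------


class HomologyTable:
    """Interval-indexed collection of pairwise duplications."""

    def __init__(self, duplications=(), genome_id: str = ""):
        self.genome_id = genome_id
        self.duplications: list[Duplication] = []
        self._trees: dict[str, IntervalTree] = {}
        for dup in duplications:
            self.add(dup)

    def __len__(self) -> int:
        return len(self.duplications)

    def add(self, dup: Duplication) -> None:
        idx = len(self.duplications)
        self.duplications.append(dup)
        for side, region in ((1, dup.region1), (2, dup.region2)):
            tree = self._trees.setdefault(region.contig, IntervalTree())
            tree.addi(region.start, region.end, (idx, side))

    def overlapping(
        self, iv: GenomicInterval, *, include_tangled: bool = False
    ) -> list[Duplication]:
        """Duplications overlapping ``iv``, oriented so region1 overlaps it."""
        tree = self._trees.get(iv.contig)
        if tree is None:
            return []
        hits: dict[tuple[int, int], Duplication] = {}
        n_tangled = 0
        for node in tree.overlap(iv.start, iv.end):
            idx, side = node.data
            dup = self.duplications[idx]
            if dup.tangled:
                n_tangled += 1
                if not include_tangled:
                    continue
            hits[(idx, side)] = dup if side == 1 else dup.flipped()
        if n_tangled and not include_tangled:
            logger.warning(
                "%d tangled duplication(s) overlapping %s excluded from query",
                n_tangled, iv.to_region(),
            )
        return sorted(
            hits.values(), key=lambda d: (d.region1.start, d.region1.end)
        )

    # ---- serialization ----------------------------------------------------

    HEADER = (
        "#contig1\tstart1\tend1\tcontig2\tstart2\tend2\tstrand\t"
        "length\tsimilarity\tcigar\tflags"
    )

    def save(self, path: str) -> None:
        text = "\n".join(
            [f"#genome_id={self.genome_id}", self.HEADER]
            + [d.to_row() for d in sorted(
                self.duplications, key=lambda d: (d.region1.contig, d.region1.start)
            )]
        ) + "\n"
        if str(path).endswith(".gz"):
            import pysam

            with pysam.BGZFile(str(path), "wb") as fh:
                fh.write(text.encode())
        else:
            with open(path, "w") as fh:
                fh.write(text)

    @classmethod
    def load(cls, path: str) -> "HomologyTable":
        if str(path).endswith(".gz"):
            import pysam

            with pysam.BGZFile(str(path), "rb") as fh:
                lines = io.TextIOWrapper(io.BytesIO(fh.read())).readlines()
        else:
            with open(path) as fh:
                lines = fh.readlines()
        genome_id = ""
        dups = []
        for line in lines:
            if line.startswith("#genome_id="):
                genome_id = line.strip().split("=", 1)[1]
            elif line.startswith("#") or not line.strip():
                continue
            else:
                dups.append(Duplication.from_row(line))  # validates CIGAR
        return cls(dups, genome_id=genome_id)


def read_paf(path_or_lines) -> list[Duplication]:
    """Parse PAF records (with cg:Z CIGAR tags) into Duplication records.

    Malformed records (bad/absent CIGAR, length mismatch) are skipped with a
    logged reason.
    """
    if isinstance(path_or_lines, (list, tuple)):
        lines = path_or_lines
    else:
        with open(path_or_lines) as fh:
            lines = fh.readlines()
    dups = []
    for ln, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        try:
            qname, qstart, qend = f[0], int(f[2]), int(f[3])
            strand = f[4]
            tname, tstart, tend = f[5], int(f[7]), int(f[8])
            cg = next(x[5:] for x in f[12:] if x.startswith("cg:Z:"))
            dup = Duplication(
                GenomicInterval(qname, qstart, qend),
                GenomicInterval(tname, tstart, tend, strand),
                parse_cigar(cg),
            )
        except (StopIteration, ValueError, IndexError) as exc:
            logger.warning("rejected PAF record at line %d: %s", ln, exc)
            continue
        dups.append(dup)
    return dups


def build_table(
    records,
    min_length: int = DEFAULT_MIN_LENGTH,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
    genome_id: str = "",
) -> HomologyTable:
    """Filter pairwise self-alignment records into a homology table.

    Records shorter than ``min_length`` (on either side) or below
    ``min_similarity`` are dropped.  Source sequences participating in more
    than :data:`MAX_PAIRWISE_ALIGNMENTS` retained records — typically
    interspersed repeats — have all their records flagged ``tangled``; they
    stay in the table (queries can warn) but are excluded from copy-number
    analysis.
    """
    if min_length <= 0 or not 0 < min_similarity <= 1:
        raise ValueError("min_length must be >0 and min_similarity in (0,1]")
    kept = [
        replace(d, tangled=False)
        for d in records
        if d.region1.length >= min_length
        and d.region2.length >= min_length
        and d.similarity >= min_similarity
    ]
    # count, per record interval, how many distinct records overlap it
    trees: dict[str, IntervalTree] = {}
    for idx, d in enumerate(kept):
        for region in (d.region1, d.region2):
            trees.setdefault(region.contig, IntervalTree()).addi(
                region.start, region.end, idx
            )
    for idx, d in enumerate(kept):
        partners: set[int] = set()
        for region in (d.region1, d.region2):
            for node in trees[region.contig].overlap(region.start, region.end):
                partners.add(node.data)
        if len(partners) > MAX_PAIRWISE_ALIGNMENTS:
            d.tangled = True
    n_tangled = sum(d.tangled for d in kept)
    if n_tangled:
        logger.info("flagged %d/%d records as tangled", n_tangled, len(kept))
    return HomologyTable(kept, genome_id=genome_id)


def merge_multicopy(dups: list[Duplication]) -> list[list[GenomicInterval]]:
    """Group pairwise duplications into multi-copy families.

    Copies are the transitive closure over interval overlap of the pairwise
    records: duplications A<->B and B<->C overlapping on B yield one family
    {A, B, C}.  Returns one sorted interval list (>=2 copies) per family.
    """
    regions: list[GenomicInterval] = []
    for d in dups:
        regions.append(replace(d.region1, strand="+"))
        regions.append(replace(d.region2, strand="+"))

    g = nx.Graph()
    g.add_nodes_from(range(len(regions)))
    # pair edges: the two sides of one duplication
    for i in range(0, len(regions), 2):
        g.add_edge(i, i + 1)
    # overlap edges
    by_contig: dict[str, IntervalTree] = {}
    for i, r in enumerate(regions):
        by_contig.setdefault(r.contig, IntervalTree()).addi(r.start, r.end, i)
    for i, r in enumerate(regions):
        for node in by_contig[r.contig].overlap(r.start, r.end):
            if node.data != i:
                g.add_edge(i, node.data)

    groups = []
    for comp in nx.connected_components(g):
        # merge overlapping member intervals into maximal copies
        ivs = sorted((regions[i].start, regions[i].end, regions[i].contig) for i in comp)
        merged: list[GenomicInterval] = []
        for start, end, contig in ivs:
            if merged and merged[-1].contig == contig and start <= merged[-1].end:
                if end > merged[-1].end:
                    merged[-1] = GenomicInterval(contig, merged[-1].start, end)
            else:
                merged.append(GenomicInterval(contig, start, end))
        if len(merged) >= 2:
            groups.append(merged)
    return sorted(groups, key=lambda grp: (grp[0].contig, grp[0].start))


def extend_group_psvs(
    table: HomologyTable, primary: GenomicInterval, genome
) -> list[Psv]:
    """PSVs of a multi-copy family with one allele per copy.

    For each duplication linking the primary copy to another copy, pairwise
    PSVs are extracted and merged by primary position; copies whose pairwise
    alignment matches the primary at a position contribute the primary
    (reference) allele.  Copy order: primary first, then paralogs by
    position.  Handles families where every copy aligns directly to the
    primary (the common case for the loci modelled here).
    """
    dups = table.overlapping(primary)
    dups = [d for d in dups if not d.tangled]
    merged: dict[int, Psv] = {}
    n_copies = len(dups) + 1
    for k, dup in enumerate(dups, start=1):
        for psv in extract_psvs(dup, genome):
            key = psv.position.start
            if key not in merged:
                merged[key] = Psv(
                    psv.position,
                    [psv.alleles[0]] * (n_copies),
                    [psv.copies[0]] + [None] * (n_copies - 1),
                )
            merged[key].alleles[k] = psv.alleles[1]
            merged[key].copies[k] = psv.copies[1]
    out = []
    for pos in sorted(merged):
        psv = merged[pos]
        for k, dup in enumerate(dups, start=1):
            if psv.copies[k] is None:  # this copy matches the primary here
                p2 = dup.project_nearest(psv.position.start)
                psv.copies[k] = GenomicInterval(
                    dup.region2.contig, p2, p2 + len(psv.alleles[0]), dup.strand
                )
        out.append(psv)
    return out


def write_psvs_vcf(psvs: list[Psv], path: str, genome_id: str = "") -> None:
    """Write PSVs to a minimal VCF-like text file (positions on the primary
    copy; ALT holds paralog alleles; INFO carries paralogous positions)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if genome_id:
            fh.write(f"##reference={genome_id}\n")
        fh.write('##INFO=<ID=POS2,Number=.,Type=String,Description='
                 '"Paralogous positions">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for psv in psvs:
            alts = []
            for a in psv.alleles[1:]:
                if a not in alts and a != psv.alleles[0]:
                    alts.append(a)
            pos2 = ",".join(
                f"{c.contig}:{c.start + 1}:{c.strand}" for c in psv.copies[1:]
            )
            fh.write(
                f"{psv.position.contig}\t{psv.position.start + 1}\t.\t"
                f"{psv.alleles[0]}\t{','.join(alts)}\t.\t.\tPOS2={pos2}\n"
            )
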
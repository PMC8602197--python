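"""Back-splice junction detection from paired-end reads.

Two independent callers mirror the common two-tool strategy for circRNA
discovery:

* :func:`detect_split` — a chimeric split-segment caller: a read supports a
  back-splice when its prefix maps ending at the circle's ``end`` and its
  suffix maps beginning at ``start``, in reversed genomic order on one
  scaffold.
* :func:`detect_realign` — a candidate-junction realignment caller: builds
  the junction pseudo-sequence (end-flank followed by start-flank) for each
  candidate and counts reads aligning across the junction midpoint.

Mapping is exact k-mer anchoring plus ungapped extension — adequate for the
simulator's substitution-only error model, and deliberately not a
general-purpose spliced aligner.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .models import BackspliceJunction, GeneModel, GenomeModel, ReadRecord, revcomp

DEFAULT_ANCHOR = 20
DEFAULT_MAX_SPAN = 100_000
DEFAULT_MIN_READS = 2
DEFAULT_MAX_MISMATCH = 2


@dataclass
class QCStats:
    kept_pairs: int = 0
    removed_pairs: int = 0
    kept_reads: int = 0
    removed_reads: int = 0


def qc_filter_reads(
    reads: Iterable[ReadRecord],
    q_threshold: int = 20,
    max_lowq_frac: float = 0.5,
    max_n_frac: float = 0.05,
) -> tuple[list[ReadRecord], QCStats]:
    """Remove low-quality read pairs.

    A read fails when the fraction of bases with Q below ``q_threshold``
    exceeds ``max_lowq_frac``, or the fraction of N bases exceeds
    ``max_n_frac``.  Both mates of a pair are removed if either fails;
    unpaired reads are judged alone.
    """

    def _fails(r: ReadRecord) -> bool:
        if len(r.sequence) != len(r.qualities):
            raise ValueError(f"read {r.id}: sequence/quality length mismatch")
        n = len(r.sequence)
        if n == 0:
            return True
        lowq = sum(1 for q in r.qualities if q < q_threshold) / n
        nfrac = r.sequence.upper().count("N") / n
        return lowq > max_lowq_frac or nfrac > max_n_frac

    pairs: dict[str, list[ReadRecord]] = defaultdict(list)
    order: list[str] = []
    for r in reads:
        if r.id not in pairs:
            order.append(r.id)
        pairs[r.id].append(r)

    kept: list[ReadRecord] = []
    stats = QCStats()
    for rid in order:
        group = pairs[rid]
        if any(_fails(r) for r in group):
            stats.removed_pairs += 1
            stats.removed_reads += len(group)
        else:
            stats.kept_pairs += 1
            stats.kept_reads += len(group)
            kept.extend(group)
    return kept, stats


class GenomeKmerIndex:
    """Exact k-mer index over the forward strand of every scaffold."""

    def __init__(self, genome: GenomeModel, k: int = DEFAULT_ANCHOR):
        self.genome = genome
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in genome.scaffolds.items():
            for i in range(len(seq) - k + 1):
                self._index[seq[i : i + k]].append((name, i))

    def find(self, kmer: str) -> list[tuple[str, int]]:
        """Hits as (scaffold, 0-based offset)."""
        return self._index.get(kmer, [])


def _extend_forward(seq: str, genome_seq: str, g0: int) -> int:
    """Longest exact match of seq against genome_seq starting at offset g0."""
    m = 0
    limit = min(len(seq), len(genome_seq) - g0)
    while m < limit and seq[m] == genome_seq[g0 + m]:
        m += 1
    return m


def _extend_backward(seq: str, genome_seq: str, g_end: int) -> int:
    """Longest exact match of a suffix of seq ending at genome offset g_end
    (inclusive)."""
    m = 0
    limit = min(len(seq), g_end + 1)
    while m < limit and seq[len(seq) - 1 - m] == genome_seq[g_end - m]:
        m += 1
    return m


def _split_junctions_for_read(
    seq: str, index: GenomeKmerIndex, anchor: int, max_span: int
) -> set[tuple[str, int, int]]:
    """All back-splice junctions (scaffold, start, end) supported by one
    read orientation via reversed-order prefix/suffix mapping."""
    L = len(seq)
    if L < 2 * anchor:
        return set()
    out: set[tuple[str, int, int]] = set()
    prefix_hits = index.find(seq[:anchor])
    if not prefix_hits:
        return out
    suffix_hits = index.find(seq[-anchor:])
    if not suffix_hits:
        return out
    for scf_p, p0 in prefix_hits:
        gseq = index.genome.scaffolds[scf_p]
        m_p = _extend_forward(seq, gseq, p0)
        if m_p < anchor:
            continue
        for scf_s, s0 in suffix_hits:
            if scf_s != scf_p:
                continue
            m_s = _extend_backward(seq, gseq, s0 + anchor - 1)
            if m_s < anchor:
                continue
            # candidate split positions t: read[:t] ends at end(t),
            # read[t:] starts at start(t); span is independent of t
            span = p0 - s0 - anchor + L
            if span < 2 or span > max_span:
                continue
            t_lo = max(anchor, L - m_s)
            t_hi = min(L - anchor, m_p)
            for t in range(t_lo, t_hi + 1):
                end = p0 + t  # 1-based last base inside the circle
                start = end - span + 1
                if start >= 1:
                    out.add((scf_p, start, end))
    return out


def detect_split(
    reads: Iterable[ReadRecord],
    genome: GenomeModel,
    anchor: int = DEFAULT_ANCHOR,
    max_span: int = DEFAULT_MAX_SPAN,
    min_reads: int = DEFAULT_MIN_READS,
    sample_id: str = "sample",
    index: GenomeKmerIndex | None = None,
) -> list[BackspliceJunction]:
    """Chimeric split-read back-splice caller for one sample.

    Both orientations of each read are searched; a read contributes at most
    one count to any junction.  Only junctions supported by at least
    ``min_reads`` reads are reported, sorted by coordinate.
    """
    if index is None:
        index = GenomeKmerIndex(genome, k=anchor)
    elif index.k != anchor:
        raise ValueError(f"index built with k={index.k}, caller wants anchor={anchor}")

    counts: Counter[tuple[str, int, int]] = Counter()
    for r in reads:
        seq = r.sequence.upper()
        hits = _split_junctions_for_read(seq, index, anchor, max_span)
        hits |= _split_junctions_for_read(revcomp(seq), index, anchor, max_span)
        for key in hits:
            counts[key] += 1

    out = []
    for (scf, start, end), n in sorted(counts.items()):
        if n >= min_reads:
            out.append(
                BackspliceJunction(
                    scaffold=scf,
                    start=start,
                    end=end,
                    strand=".",
                    junction_reads={sample_id: n},
                    callers={"split"},
                )
            )
    return out


def _exonic_host(genome: GenomeModel, scaffold: str, start: int, end: int) -> GeneModel | None:
    """Gene whose exons overlap both junction ends (splicing template for
    pseudo-sequence construction), or None."""
    for g in genome.genes:
        if g.scaffold != scaffold:
            continue
        s_hit = any(es <= start <= ee for es, ee in g.exons)
        e_hit = any(es <= end <= ee for es, ee in g.exons)
        if s_hit and e_hit:
            return g
    return None


def circular_sequence(
    genome: GenomeModel, scaffold: str, start: int, end: int, gene: GeneModel | None
) -> str:
    """Plus-strand circular sequence linearized at the back-splice.

    With a splicing gene, introns inside [start, end] are excluded
    (concatenation of overlapping exon sub-intervals in genomic order);
    otherwise the plain genomic substring.
    """
    if gene is None:
        return genome.fetch(scaffold, start, end)
    parts = [
        genome.fetch(scaffold, max(es, start), min(ee, end))
        for es, ee in gene.exons
        if ee >= start and es <= end
    ]
    return "".join(parts)


def annotation_candidates(
    genome: GenomeModel, max_span: int = DEFAULT_MAX_SPAN
) -> list[BackspliceJunction]:
    """All exon-boundary back-splice candidates: (exon_i start, exon_j end)
    pairs with i <= j within one gene and span <= max_span."""
    out = []
    for g in genome.genes:
        for i, (si, _) in enumerate(g.exons):
            for j in range(i, len(g.exons)):
                ej = g.exons[j][1]
                if ej - si + 1 <= max_span and si < ej:
                    out.append(
                        BackspliceJunction(
                            scaffold=g.scaffold, start=si, end=ej, strand=".", callers=set()
                        )
                    )
    return out


def detect_realign(
    reads: Iterable[ReadRecord],
    genome: GenomeModel,
    candidates: Sequence[BackspliceJunction],
    anchor: int = DEFAULT_ANCHOR,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_reads: int = DEFAULT_MIN_READS,
    read_len: int = 150,
    max_span: int = DEFAULT_MAX_SPAN,
    sample_id: str = "sample",
) -> list[BackspliceJunction]:
    """Candidate-junction realignment caller for one sample.

    For every candidate a junction pseudo-sequence is built: the circle's
    end-flank followed by its start-flank, each ``read_len - anchor`` nt,
    exon-spliced when the candidate's ends fall in exons of one gene.  A
    read counts for a candidate when it aligns ungapped to the
    pseudo-sequence crossing the junction midpoint with at least ``anchor``
    nt on each side and at most ``max_mismatch`` mismatches.  Candidates
    wider than ``max_span`` are dropped.
    """
    flank = read_len - anchor
    pseudo: list[tuple[BackspliceJunction, str, int]] = []  # (candidate, seq, flank_used)
    seen_ids: set[str] = set()
    for cand in candidates:
        if cand.id in seen_ids:
            continue
        seen_ids.add(cand.id)
        if cand.span > max_span:
            continue
        gene = _exonic_host(genome, cand.scaffold, cand.start, cand.end)
        cseq = circular_sequence(genome, cand.scaffold, cand.start, cand.end, gene)
        f = min(flank, len(cseq))
        pseudo.append((cand, cseq[-f:] + cseq[:f], f))

    k = anchor
    kidx: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for ci, (_, pseq, _) in enumerate(pseudo):
        for i in range(len(pseq) - k + 1):
            kidx[pseq[i : i + k]].append((ci, i))

    counts: Counter[int] = Counter()
    for r in reads:
        matched: set[int] = set()
        for seq in (r.sequence.upper(), revcomp(r.sequence.upper())):
            L = len(seq)
            probes = list(range(0, max(L - k, 0) + 1, k))
            placements: set[tuple[int, int]] = set()
            for p in probes:
                for ci, pos in kidx.get(seq[p : p + k], []):
                    placements.add((ci, pos - p))
            for ci, off in placements:
                if ci in matched:
                    continue
                _, pseq, f = pseudo[ci]
                if off < 0 or off + L > len(pseq):
                    continue
                # must cross the midpoint (between pseudo positions f-1, f)
                if off > f - anchor or off + L < f + anchor:
                    continue
                mism = sum(1 for a, b in zip(seq, pseq[off : off + L]) if a != b)
                if mism <= max_mismatch:
                    matched.add(ci)
        for ci in matched:
            counts[ci] += 1

    out = []
    for ci in sorted(counts, key=lambda i: (pseudo[i][0].scaffold, pseudo[i][0].start, pseudo[i][0].end)):
        n = counts[ci]
        if n >= min_reads:
            cand = pseudo[ci][0]
            out.append(
                BackspliceJunction(
                    scaffold=cand.scaffold,
                    start=cand.start,
                    end=cand.end,
                    strand=".",
                    junction_reads={sample_id: n},
                    callers={"realign"},
                )
            )
    return out


def detect_both(
    reads: Iterable[ReadRecord],
    genome: GenomeModel,
    anchor: int = DEFAULT_ANCHOR,
    max_span: int = DEFAULT_MAX_SPAN,
    min_reads: int = DEFAULT_MIN_READS,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    read_len: int = 150,
    sample_id: str = "sample",
    index: GenomeKmerIndex | None = None,
) -> tuple[list[BackspliceJunction], list[BackspliceJunction]]:
    """Run both callers on one sample; the realign caller is seeded with
    the split caller's junctions (at min_reads=1) plus all annotated
    exon-boundary pairs, making the two callers overlapping but distinct."""
    reads = list(reads)
    split = detect_split(
        reads, genome, anchor=anchor, max_span=max_span, min_reads=min_reads,
        sample_id=sample_id, index=index,
    )
    seeds = detect_split(
        reads, genome, anchor=anchor, max_span=max_span, min_reads=1,
        sample_id=sample_id, index=index,
    )
    cands = seeds + annotation_candidates(genome, max_span=max_span)
    realign = detect_realign(
        reads, genome, cands, anchor=anchor, max_mismatch=max_mismatch,
        min_reads=min_reads, read_len=read_len, max_span=max_span, sample_id=sample_id,
    )
    return split, realign
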
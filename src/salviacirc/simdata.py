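"""Synthetic genome, circRNA truth set and paired-end read generator.

The generator emulates the study design every downstream stage is exercised
against: a multi-scaffold genome with multi-exon gene models, planted
exonic / intronic / intergenic circRNAs, a 3-tissue x 3-replicate layout
with tissue-specific abundances, RNase-R depletion of linear transcripts
(modeled as a retention fraction), and 2 x 150 nt paired-end reads in which
mate 1 of each circRNA pair crosses the back-splice junction.

Planted junctions are required to be *unambiguous*: the genomic base just
downstream of the circle end must differ from the circle's first base, and
the base just upstream of the start from its last base.  Without this, a
back-splice at (start, end) is indistinguishable from one at
(start+1, end+1) from read evidence alone — real callers resolve the shift
with GT/AG splice signals, which a random genome does not provide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import write_fasta, write_fastq, write_gff3, write_table
from .models import (
    BackspliceJunction,
    GeneModel,
    GenomeModel,
    ReadRecord,
    SampleDesign,
    TruthRecord,
    revcomp,
)

# Gene-structure defaults: exons long enough (>= read length * 2) that a
# single-exon circle still accommodates a non-junction mate window, introns
# long enough to host intronic circles.
EXON_LEN_RANGE = (300, 400)
INTRON_LEN_RANGE = (150, 250)
MIN_INTERGENIC_GAP = 500
MIN_CIRC_LEN = 160

Q_CORRECT = 37
Q_ERROR = 12


class GenomeSizingError(ValueError):
    """Requested genes do not fit on the requested scaffolds."""


class CapacityError(ValueError):
    """Not enough introns / intergenic space for the requested plantings."""


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(s) for s in stream])


def simulate_genome(
    n_scaffolds: int = 5,
    scaffold_len: int = 50_000,
    n_genes: int = 30,
    exons_per_gene: tuple[int, int] = (3, 6),
    seed: int = 0,
) -> GenomeModel:
    """Random genome with non-overlapping multi-exon genes.

    Genes are laid out left to right on round-robin scaffolds with
    intergenic gaps of at least ``MIN_INTERGENIC_GAP`` nt (also kept at
    scaffold edges so intergenic circles can be planted anywhere outside
    genes).  Deterministic for a fixed seed.
    """
    if scaffold_len < 5_000:
        raise ValueError("scaffold_len must be >= 5,000 nt")
    lo, hi = exons_per_gene
    if lo < 1 or hi < lo:
        raise ValueError("exons_per_gene must be a (min, max) range with min >= 1")

    rng = _rng(seed, 0)
    names = [f"scf{i + 1}" for i in range(n_scaffolds)]
    scaffolds = {
        name: "".join(rng.choice(list("ACGT"), size=scaffold_len)) for name in names
    }

    cursors = {name: MIN_INTERGENIC_GAP for name in names}
    genes: list[GeneModel] = []
    for gi in range(n_genes):
        n_ex = int(rng.integers(lo, hi + 1))
        exon_lens = rng.integers(*EXON_LEN_RANGE, size=n_ex, endpoint=True)
        intron_lens = rng.integers(*INTRON_LEN_RANGE, size=max(n_ex - 1, 0), endpoint=True)
        gene_span = int(exon_lens.sum() + intron_lens.sum())
        strand = "+" if rng.random() < 0.5 else "-"
        gap = int(rng.integers(MIN_INTERGENIC_GAP, MIN_INTERGENIC_GAP + 500, endpoint=True))

        placed = False
        order = [names[(gi + k) % n_scaffolds] for k in range(n_scaffolds)]
        for name in order:
            start = cursors[name] + gap
            if start + gene_span - 1 <= scaffold_len - MIN_INTERGENIC_GAP:
                exons = []
                pos = start
                for j in range(n_ex):
                    exons.append((pos, pos + int(exon_lens[j]) - 1))
                    pos += int(exon_lens[j])
                    if j < n_ex - 1:
                        pos += int(intron_lens[j])
                genes.append(
                    GeneModel(
                        gene_id=f"gene{gi + 1:04d}",
                        scaffold=name,
                        strand=strand,
                        exons=tuple(exons),
                    )
                )
                cursors[name] = exons[-1][1]
                placed = True
                break
        if not placed:
            free = {n: scaffold_len - cursors[n] for n in names}
            worst = max(free, key=free.get)
            raise GenomeSizingError(
                f"gene {gi + 1} of {n_genes} (span {gene_span} nt) does not fit on any "
                f"scaffold; largest remaining space is {free[worst]} nt on {worst}"
            )
    return GenomeModel(scaffolds=scaffolds, genes=genes)


def _unambiguous(genome: GenomeModel, scaffold: str, start: int, end: int) -> bool:
    """True when the junction coordinates are identifiable from reads: no
    single-base shift of the back-splice yields the same read sequences."""
    seq = genome.scaffolds[scaffold]
    if start < 2 or end > len(seq) - 1:
        return False
    return seq[end] != seq[start - 1] and seq[start - 2] != seq[end - 1]


def plant_circrnas(
    genome: GenomeModel,
    n_exonic: int = 20,
    n_intronic: int = 5,
    n_intergenic: int = 5,
    seed: int = 0,
    max_exons: int = 5,
) -> list[TruthRecord]:
    """Plant circRNAs of the three genomic classes as ground truth.

    Exonic circles span 1..``max_exons`` consecutive exons of one gene with
    both ends on exon boundaries; intronic circles lie strictly inside one
    intron; intergenic circles overlap no gene.  All circles are at least
    ``MIN_CIRC_LEN`` nt so a read never wraps the circle more than once.
    """
    rng = _rng(seed, 1)
    records: list[TruthRecord] = []
    used: set[str] = set()

    def _add(scaffold: str, start: int, end: int, true_class: str,
             host: str | None, spliced: bool, strand: str) -> bool:
        jid = f"{scaffold}-{start}-{end}"
        if jid in used or not _unambiguous(genome, scaffold, start, end):
            return False
        used.add(jid)
        records.append(
            TruthRecord(
                junction=BackspliceJunction(scaffold=scaffold, start=start, end=end, strand=strand),
                true_class=true_class,
                host_gene=host,
                spliced=spliced,
            )
        )
        return True

    # exonic: consecutive exon runs, ends on exon boundaries
    if n_exonic > 0 and not genome.genes:
        raise CapacityError("no genes available for exonic circRNAs")
    placed = 0
    attempts = 0
    while placed < n_exonic:
        attempts += 1
        if attempts > 200 * max(n_exonic, 1):
            raise CapacityError(
                f"could only place {placed} of {n_exonic} exonic circRNAs"
            )
        g = genome.genes[int(rng.integers(len(genome.genes)))]
        n_ex = len(g.exons)
        k = int(rng.integers(1, min(max_exons, n_ex) + 1))
        i = int(rng.integers(0, n_ex - k + 1))
        start = g.exons[i][0]
        end = g.exons[i + k - 1][1]
        length = sum(e - s + 1 for s, e in g.exons[i : i + k])
        if length < MIN_CIRC_LEN:
            continue
        if _add(g.scaffold, start, end, "exonic", g.gene_id, True, g.strand):
            placed += 1

    # intronic: strictly within one intron
    introns = [
        (g, iv)
        for g in genome.genes
        for iv in g.introns
        if iv[1] - iv[0] + 1 >= MIN_CIRC_LEN + 2
    ]
    if n_intronic > 0 and not introns:
        raise CapacityError("no introns long enough for intronic circRNAs")
    placed = 0
    attempts = 0
    while placed < n_intronic:
        attempts += 1
        if attempts > 200 * max(n_intronic, 1):
            raise CapacityError(
                f"could only place {placed} of {n_intronic} intronic circRNAs"
            )
        g, (ivs, ive) = introns[int(rng.integers(len(introns)))]
        avail = ive - ivs + 1 - 2  # 1 nt margin each side: strictly inside
        length = int(rng.integers(MIN_CIRC_LEN, min(avail, 300) + 1))
        start = int(rng.integers(ivs + 1, ive - length + 1))
        if _add(g.scaffold, start, start + length - 1, "intronic", g.gene_id, False, g.strand):
            placed += 1

    # intergenic: gaps between genes / scaffold edges, overlapping no gene
    gaps: list[tuple[str, int, int]] = []
    by_scf = genome.genes_by_scaffold()
    for name, seq in genome.scaffolds.items():
        bounds = sorted((g.start, g.end) for g in by_scf.get(name, []))
        prev = 1
        for gs, ge in bounds:
            if gs - 1 >= prev:
                gaps.append((name, prev, gs - 1))
            prev = ge + 1
        if len(seq) >= prev:
            gaps.append((name, prev, len(seq)))
    gaps = [(n, a, b) for n, a, b in gaps if b - a + 1 >= MIN_CIRC_LEN + 2]
    if n_intergenic > 0 and not gaps:
        raise CapacityError("no intergenic space for intergenic circRNAs")
    placed = 0
    attempts = 0
    while placed < n_intergenic:
        attempts += 1
        if attempts > 200 * max(n_intergenic, 1):
            raise CapacityError(
                f"could only place {placed} of {n_intergenic} intergenic circRNAs"
            )
        name, a, b = gaps[int(rng.integers(len(gaps)))]
        avail = b - a - 1  # keep 1 nt clear of gene boundaries
        length = int(rng.integers(MIN_CIRC_LEN, min(avail, 400) + 1))
        start = int(rng.integers(a + 1, b - length + 1))
        if _add(name, start, start + length - 1, "intergenic", None, False, "."):
            placed += 1

    return records


def truth_circ_sequence(genome: GenomeModel, rec: TruthRecord) -> str:
    """Transcript-strand circular sequence of a planted circRNA, linearized
    at the back-splice starting at ``start`` (spliced for exonic circles)."""
    j = rec.junction
    if rec.true_class == "exonic":
        gene = next(g for g in genome.genes if g.gene_id == rec.host_gene)
        parts = [
            genome.fetch(j.scaffold, max(s, j.start), min(e, j.end))
            for s, e in gene.exons
            if e >= j.start and s <= j.end
        ]
        seq = "".join(parts)
        return revcomp(seq) if gene.strand == "-" else seq
    return genome.fetch(j.scaffold, j.start, j.end)


def assign_abundances(
    truth: list[TruthRecord],
    design: SampleDesign,
    seed: int = 0,
    base_mean: float = 8.0,
    specific_fraction: float = 0.5,
    specificity_boost: float = 4.0,
) -> None:
    """Fill each truth record's per-sample expected junction-read count.

    Each circle gets a log-normal base abundance around ``base_mean``; a
    ``specific_fraction`` of circles are tissue-specific (one tissue boosted
    by ``specificity_boost``).  The design's global tissue multipliers are
    applied on top.
    """
    rng = _rng(seed, 2)
    for rec in truth:
        base = float(base_mean * rng.lognormal(mean=0.0, sigma=0.4))
        profile = {t: 1.0 for t in design.tissues}
        if rng.random() < specific_fraction:
            boosted = design.tissues[int(rng.integers(len(design.tissues)))]
            profile[boosted] = specificity_boost
        rec.abundance = {
            s: base * profile[design.tissue_of(s)] * design.tissue_multipliers[design.tissue_of(s)]
            for s in design.sample_ids
        }


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 1e-9:
        return int(rng.poisson(mean))
    n = 1.0 / dispersion
    p = n / (n + mean)
    return int(rng.negative_binomial(n, p))


def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float) -> tuple[str, tuple[int, ...]]:
    if error_rate <= 0:
        return seq, (Q_CORRECT,) * len(seq)
    bases = list(seq)
    quals = [Q_CORRECT] * len(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < error_rate)
    for i in hits:
        alt = "ACGT".replace(bases[i], "")
        bases[i] = alt[int(rng.integers(3))]
        quals[i] = Q_ERROR
    return "".join(bases), tuple(quals)


@dataclass
class SimResult:
    """In-memory product of a simulation run."""

    reads: dict[str, list[ReadRecord]]
    junction_truth: pd.DataFrame  # circ_id x sample emitted junction-read counts
    gene_counts: pd.DataFrame  # gene x sample emitted linear fragment counts
    library_sizes: dict[str, int] = field(default_factory=dict)

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for sample, reads in self.reads.items():
            write_fastq([r for r in reads if r.mate == 1], out / f"{sample}_R1.fastq")
            write_fastq([r for r in reads if r.mate == 2], out / f"{sample}_R2.fastq")
        write_table(self.junction_truth.reset_index(), out / "junction_truth.tsv")
        write_table(self.gene_counts.reset_index(), out / "gene_truth.tsv")
        write_table(
            pd.DataFrame(
                {"sample": list(self.library_sizes), "total_reads": list(self.library_sizes.values())}
            ),
            out / "library_sizes.tsv",
        )


def simulate_reads(
    genome: GenomeModel,
    truth: list[TruthRecord],
    design: SampleDesign,
    read_len: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
    anchor: int = 20,
    min_junction_reads: int = 0,
    gene_depth_mean: float = 200.0,
) -> SimResult:
    """Emit per-sample paired reads plus the emitted-count truth tables.

    Mate 1 of every circRNA pair crosses the back-splice with at least
    ``anchor`` nt on each side (read ids carry a ``:bsj:`` tag); mate 2 is a
    reverse-complemented window of the circle that avoids the junction.
    Linear-gene pairs are drawn from spliced transcripts and thinned by the
    design's RNase-R retention fraction.  Junction-read counts per circle
    and sample are negative-binomial around abundance; when
    ``min_junction_reads`` > 0 every expressed circle emits at least that
    many pairs (a floor on the draw, for guaranteed-coverage designs).
    """
    if read_len < 2 * anchor:
        raise ValueError(f"read_len {read_len} must be >= 2 x anchor ({2 * anchor})")
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")

    if truth and all(not r.abundance for r in truth):
        assign_abundances(truth, design, seed=seed)

    circ_seqs = {r.junction.id: truth_circ_sequence(genome, r) for r in truth}
    for cid, seq in circ_seqs.items():
        if len(seq) < read_len:
            raise ValueError(
                f"circRNA {cid} is {len(seq)} nt, shorter than the read length {read_len}"
            )

    gene_rng = _rng(seed, 3)
    gene_base = {
        g.gene_id: float(gene_depth_mean * gene_rng.lognormal(0.0, 0.5))
        for g in genome.genes
    }
    gene_profile: dict[str, dict[str, float]] = {}
    for g in genome.genes:
        profile = {t: 1.0 for t in design.tissues}
        if gene_rng.random() < 0.5:
            profile[design.tissues[int(gene_rng.integers(len(design.tissues)))]] = 4.0
        gene_profile[g.gene_id] = profile
    transcripts = {}
    for g in genome.genes:
        t = "".join(genome.fetch(g.scaffold, s, e) for s, e in g.exons)
        transcripts[g.gene_id] = revcomp(t) if g.strand == "-" else t

    samples = design.sample_ids
    jt = pd.DataFrame(0, index=[r.junction.id for r in truth], columns=samples, dtype=int)
    jt.index.name = "circ_id"
    gc = pd.DataFrame(0, index=[g.gene_id for g in genome.genes], columns=samples, dtype=int)
    gc.index.name = "gene_id"
    all_reads: dict[str, list[ReadRecord]] = {}

    for si, sample in enumerate(samples):
        rng = _rng(seed, 4, si)
        tissue = design.tissue_of(sample)
        reads: list[ReadRecord] = []

        for rec in truth:
            cid = rec.junction.id
            mean = rec.abundance.get(sample, 0.0)
            n = _nb_draw(rng, mean, design.dispersion)
            if mean > 0:
                n = max(n, min_junction_reads)
            jt.loc[cid, sample] = n
            cseq = circ_seqs[cid]
            clen = len(cseq)
            # split position: end-flank length within [anchor, read_len-anchor],
            # confined to the junction-flanking exons for spliced circles
            a_lo, a_hi = anchor, read_len - anchor
            if rec.true_class == "exonic":
                gene = next(g for g in genome.genes if g.gene_id == rec.host_gene)
                segs = [
                    min(e, rec.junction.end) - max(s, rec.junction.start) + 1
                    for s, e in gene.exons
                    if e >= rec.junction.start and s <= rec.junction.end
                ]
                first_seg, last_seg = (
                    (segs[-1], segs[0]) if gene.strand == "-" else (segs[0], segs[-1])
                )
                a_lo = max(a_lo, read_len - first_seg)
                a_hi = min(a_hi, last_seg)
            for k in range(n):
                a = int(rng.integers(a_lo, a_hi + 1))
                r1 = cseq[clen - a :] + cseq[: read_len - a]
                p = int(rng.integers(0, clen - read_len + 1))
                r2 = revcomp(cseq[p : p + read_len])
                rid = f"{sample}:{cid}:bsj:{k}"
                s1, q1 = _apply_errors(rng, r1, error_rate)
                s2, q2 = _apply_errors(rng, r2, error_rate)
                reads.append(ReadRecord(id=rid, mate=1, sequence=s1, qualities=q1))
                reads.append(ReadRecord(id=rid, mate=2, sequence=s2, qualities=q2))

        for g in genome.genes:
            tseq = transcripts[g.gene_id]
            if len(tseq) < read_len:
                continue
            mean = (
                gene_base[g.gene_id]
                * gene_profile[g.gene_id][tissue]
                * design.tissue_multipliers[tissue]
                * design.linear_retention
            )
            n = _nb_draw(rng, mean, design.dispersion)
            gc.loc[g.gene_id, sample] = n
            for k in range(n):
                flen = int(rng.integers(min(250, len(tseq)), min(350, len(tseq)) + 1))
                p = int(rng.integers(0, len(tseq) - flen + 1))
                frag = tseq[p : p + flen]
                r1 = frag[:read_len]
                r2 = revcomp(frag[-read_len:])
                rid = f"{sample}:{g.gene_id}:lin:{k}"
                s1, q1 = _apply_errors(rng, r1, error_rate)
                s2, q2 = _apply_errors(rng, r2, error_rate)
                reads.append(ReadRecord(id=rid, mate=1, sequence=s1, qualities=q1))
                reads.append(ReadRecord(id=rid, mate=2, sequence=s2, qualities=q2))

        all_reads[sample] = reads

    library_sizes = {s: len(r) for s, r in all_reads.items()}
    return SimResult(
        reads=all_reads,
        junction_truth=jt,
        gene_counts=gc,
        library_sizes=library_sizes,
    )


def write_genome(genome: GenomeModel, fasta_path, gff3_path) -> None:
    write_fasta(genome.scaffolds, fasta_path)
    write_gff3(genome, gff3_path)
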
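"""Convergent / divergent primer design and in-silico PCR.

The validation logic for a circRNA rests on two primer pairs drawn on the
circle's cDNA (the circular sequence linearized at the back-splice):

* the **convergent** pair faces inward within the circle's genomic span:
  it amplifies from genomic DNA and from cDNA, and when the circle's span
  contains an intron the genomic product is strictly longer than the cDNA
  product;
* the **divergent** pair faces outward on the linear genomic frame, so its
  only possible product runs across the back-splice junction — it
  amplifies from circular cDNA and never from linear genomic DNA.

Melting temperatures use the Wallace rule 2(A+T) + 4(G+C); no
nearest-neighbor thermodynamics or dimer screening is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import BackspliceJunction, CircAnnotation, GeneModel, GenomeModel, revcomp

MIN_TEMPLATE = 80
MAX_AMPLICON = 5_000


class PrimerDesignError(ValueError):
    """No primer pair satisfied the constraints; carries diagnostics."""


def wallace_tm(primer: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C) degrees C."""
    p = primer.upper()
    return 2.0 * (p.count("A") + p.count("T")) + 4.0 * (p.count("G") + p.count("C"))


@dataclass
class PrimerPair:
    orientation: str  # convergent | divergent
    fwd: str
    rev: str
    fwd_pos: int  # 1-based 5' position of the fwd primer on the circular cDNA
    rev_pos: int  # 1-based 5' position of the rev primer (its 3'-most template base)
    tm_fwd: float
    tm_rev: float
    # expected product sizes; None means no product expected
    product_circular: int | None = None
    product_linear: int | None = None
    product_genomic: int | None = None


@dataclass
class Amplicon:
    sequence: str
    size: int
    start: int  # 1-based position of the product's first base on the template
    end: int  # 1-based position of the last base (may be < start on circles)


def insilico_pcr(
    pair: PrimerPair | tuple[str, str],
    template: str,
    circular: bool = False,
    max_size: int = MAX_AMPLICON,
) -> list[Amplicon]:
    """Exact-match PCR prediction: every inward-facing combination of
    primer binding sites with product size <= ``max_size``.

    Each primer is searched on both strands (zero mismatches).  Circular
    templates are searched across the origin and products are limited to a
    single lap.
    """
    if isinstance(pair, PrimerPair):
        fwd, rev = pair.fwd, pair.rev
    else:
        fwd, rev = pair
    template = template.upper()
    n = len(template)
    if n == 0:
        return []
    search = template + template[: min(n, max_size)] if circular else template
    limit = min(max_size, n) if circular else max_size

    def _find(sub: str, space: str) -> list[int]:
        out, i = [], space.find(sub)
        while i != -1:
            out.append(i)
            i = space.find(sub, i + 1)
        return out

    products: list[Amplicon] = []
    seen: set[tuple[int, int]] = set()
    for p, q in ((fwd, rev), (rev, fwd)):
        fwd_sites = [i for i in _find(p, search) if i < n]  # extends rightward
        rev_sites = _find(revcomp(q), search)  # extends leftward
        for i in fwd_sites:
            for j in rev_sites:
                if j < i + len(p):
                    continue
                size = j + len(q) - i
                if size > limit or size <= max(len(p), len(q)):
                    continue
                key = (i, size)
                if key in seen:
                    continue
                seen.add(key)
                seq = search[i : i + size]
                start = i + 1
                end = (i + size - 1) % n + 1 if circular else i + size
                products.append(Amplicon(sequence=seq, size=size, start=start, end=end))
    products.sort(key=lambda a: (a.size, a.start))
    return products


def _position_map(
    junction: BackspliceJunction,
    annotation: CircAnnotation,
    genome: GenomeModel,
) -> list[int]:
    """Genomic coordinate of every base of the circular cDNA (transcript
    orientation)."""
    if annotation.circ_class == "exonic":
        gene = next(g for g in genome.genes if g.gene_id == annotation.parent_gene)
        coords: list[int] = []
        for es, ee in gene.exons:
            s, e = max(es, junction.start), min(ee, junction.end)
            if s <= e:
                coords.extend(range(s, e + 1))
        if gene.strand == "-":
            coords.reverse()
        return coords
    return list(range(junction.start, junction.end + 1))


def _contiguous(coords: list[int]) -> bool:
    return all(abs(b - a) == 1 for a, b in zip(coords, coords[1:]))


def _segments(coords: list[int]) -> list[tuple[int, int]]:
    """Genomically contiguous runs of the cDNA as 0-based [start, end]
    index pairs (one per exon segment; a single run for unspliced circles)."""
    segs = []
    run_start = 0
    for i in range(1, len(coords)):
        if abs(coords[i] - coords[i - 1]) != 1:
            segs.append((run_start, i - 1))
            run_start = i
    segs.append((run_start, len(coords) - 1))
    return segs


def _pick_primer(
    circ_seq: str,
    coords: list[int],
    region: range,
    length_range: tuple[int, int],
    antisense: bool,
    step: int = 2,
) -> list[tuple[int, str, float]]:
    """Candidate primers whose binding site starts at a position in
    ``region`` (0-based on circ_seq) and is genomically contiguous.
    Returns (site_start, primer_sequence, tm)."""
    out = []
    lo, hi = length_range
    for start in range(region.start, region.stop, step):
        for ln in range(lo, hi + 1):
            if start < 0 or start + ln > len(circ_seq):
                continue
            if not _contiguous(coords[start : start + ln]):
                continue
            site = circ_seq[start : start + ln]
            primer = revcomp(site) if antisense else site
            out.append((start, primer, wallace_tm(primer)))
    return out


def design_primers(
    junction: BackspliceJunction,
    circ_seq: str,
    genome: GenomeModel,
    annotation: CircAnnotation,
    length_range: tuple[int, int] = (18, 24),
    product_range: tuple[int, int] = (100, 400),
    max_tm_diff: float = 4.0,
) -> tuple[PrimerPair, PrimerPair]:
    """Design one convergent and one divergent pair for a circRNA.

    Primers are drawn from the circular cDNA, restricted to genomically
    contiguous windows (never crossing a splice or the back-splice), with
    pair Tm difference <= ``max_tm_diff``.  Expected product sizes on
    circular cDNA, linear cDNA and genomic DNA are computed by exact
    in-silico PCR, and each pair is required to show the template logic of
    its orientation (divergent: circular product only; convergent:
    products on all three templates).
    """
    clen = len(circ_seq)
    if clen < MIN_TEMPLATE:
        raise PrimerDesignError(
            f"{junction.id}: circular sequence is {clen} nt, "
            f"below the {MIN_TEMPLATE} nt minimum for primer design"
        )
    coords = _position_map(junction, annotation, genome)
    if len(coords) != clen:
        raise PrimerDesignError(f"{junction.id}: position map/sequence length mismatch")
    gseq = genome.scaffolds[junction.scaffold]
    pmin, pmax = product_range
    pmin = min(pmin, max(clen - 2 * max(length_range), 40))
    segs = _segments(coords)

    reach = min(80, clen // 2)

    def _pairs(fwd_cands, rev_cands, size_of):
        """Tm-compatible candidate combinations, in-range product sizes
        first, then smallest Tm difference."""
        combos = []
        for fs, fp, ftm in fwd_cands:
            for rs, rp, rtm in rev_cands:
                if abs(ftm - rtm) > max_tm_diff:
                    continue
                size = size_of(fs, len(fp), rs, len(rp))
                if size > min(MAX_AMPLICON, clen) or size < 2 * min(length_range):
                    continue
                in_range = pmin <= size <= min(pmax, clen)
                combos.append((not in_range, abs(ftm - rtm), size, fs, fp, ftm, rs, rp, rtm))
        combos.sort()
        return combos

    diagnostics = []

    # divergent: fwd near the circle's 3' end pointing across the junction,
    # rev near its 5' start pointing back across; outward on the genome
    div_fwd = _pick_primer(circ_seq, coords, range(clen - reach, clen - length_range[0]), length_range, False)
    div_rev = _pick_primer(circ_seq, coords, range(0, reach), length_range, True)

    def _div_size(fs, fl, rs, rl):
        return (clen - fs) + (rs + rl)

    divergent = None
    for _, _, size, fs, fp, ftm, rs, rp, rtm in _pairs(div_fwd, div_rev, _div_size):
        if fs < rs + len(rp):  # sites must not overlap on the circle
            continue
        circ_prods = insilico_pcr((fp, rp), circ_seq, circular=True)
        lin_prods = insilico_pcr((fp, rp), circ_seq, circular=False)
        gen_prods = insilico_pcr((fp, rp), gseq, circular=False)
        if len(circ_prods) == 1 and not gen_prods and not lin_prods:
            divergent = PrimerPair(
                orientation="divergent",
                fwd=fp, rev=rp,
                fwd_pos=fs + 1, rev_pos=rs + len(rp),
                tm_fwd=ftm, tm_rev=rtm,
                product_circular=circ_prods[0].size,
                product_linear=None,
                product_genomic=None,
            )
            break
        diagnostics.append(
            f"divergent fwd@{fs + 1}/rev@{rs + 1}: circ={len(circ_prods)} "
            f"linear={len(lin_prods)} genomic={len(gen_prods)} products"
        )
    if divergent is None:
        raise PrimerDesignError(
            f"{junction.id}: no divergent pair found; "
            + ("; ".join(diagnostics[:5]) or "no candidate windows")
        )

    # convergent: faces inward within the circle's span; for spliced circles
    # with more than one exon segment the pair straddles an intron (fwd at
    # the end of the first segment, rev at the start of the last), so the
    # genomic product is strictly longer than the cDNA product
    if len(segs) > 1:
        f_lo = max(segs[0][0], segs[0][1] - reach)
        fwd_region = range(f_lo, segs[0][1] + 1 - min(length_range))
        rev_region = range(segs[-1][0], min(segs[-1][0] + reach, segs[-1][1] + 1 - min(length_range)))
    else:
        fwd_region = range(0, reach)
        rev_region = range(clen - reach, clen - min(length_range))
    con_fwd = _pick_primer(circ_seq, coords, fwd_region, length_range, False)
    con_rev = _pick_primer(circ_seq, coords, rev_region, length_range, True)

    def _con_size(fs, fl, rs, rl):
        return (rs + rl) - fs

    convergent = None
    for _, _, size, fs, fp, ftm, rs, rp, rtm in _pairs(con_fwd, con_rev, _con_size):
        circ_prods = insilico_pcr((fp, rp), circ_seq, circular=True)
        lin_prods = insilico_pcr((fp, rp), circ_seq, circular=False)
        gen_prods = insilico_pcr((fp, rp), gseq, circular=False)
        if len(lin_prods) == 1 and len(gen_prods) == 1 and circ_prods:
            convergent = PrimerPair(
                orientation="convergent",
                fwd=fp, rev=rp,
                fwd_pos=fs + 1, rev_pos=rs + len(rp),
                tm_fwd=ftm, tm_rev=rtm,
                product_circular=min(a.size for a in circ_prods),
                product_linear=lin_prods[0].size,
                product_genomic=gen_prods[0].size,
            )
            break
        diagnostics.append(
            f"convergent fwd@{fs + 1}/rev@{rs + 1}: circ={len(circ_prods)} "
            f"linear={len(lin_prods)} genomic={len(gen_prods)} products"
        )
    if convergent is None:
        raise PrimerDesignError(
            f"{junction.id}: no convergent pair found; "
            + ("; ".join(diagnostics[:5]) or "no candidate windows")
        )
    return convergent, divergent
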
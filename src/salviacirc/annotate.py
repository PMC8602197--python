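"""Junction classification, alternative circularization and circular
sequence extraction.

Classification follows the junction ends:

* **exonic** — both junction ends fall in exons of a single gene (the
  parent gene); the circle is assumed spliced.
* **intronic** — the whole interval lies within a single gene but is not
  exonic by the preceding rule (this covers circles inside one intron and,
  under the default policy, mixed exon/intron junctions).
* **intergenic** — everything else.

Exonic circles additionally get the number of spanned exons and a position
category (first / middle / last / first_and_last exon) computed in
transcript orientation, so minus-strand genes flip genomic order.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .backsplice import circular_sequence
from .consensus import CircCatalog
from .models import (
    BackspliceJunction,
    CircAnnotation,
    GeneModel,
    GenomeModel,
    revcomp,
)
from .primers import PrimerPair, design_primers, insilico_pcr  # noqa: F401  (module surface)


class GeneIndex:
    """Interval lookup of gene spans per scaffold."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for i, g in enumerate(self.genes):
            self._trees[g.scaffold][g.start : g.end + 1] = i

    def overlapping(self, scaffold: str, start: int, end: int) -> list[GeneModel]:
        hits = self._trees.get(scaffold, IntervalTree()).overlap(start, end + 1)
        return [self.genes[iv.data] for iv in sorted(hits, key=lambda iv: iv.begin)]


def _in_exon(gene: GeneModel, pos: int, slop: int = 0) -> bool:
    return any(s - slop <= pos <= e + slop for s, e in gene.exons)


def classify_junction(
    junction: BackspliceJunction,
    genes: Sequence[GeneModel] | GeneIndex,
    boundary_slop: int = 0,
    mixed_ends: str = "intronic",
) -> CircAnnotation:
    """Classify one back-splice junction against the gene models.

    ``boundary_slop`` relaxes the exon-overlap test of each junction end by
    that many nt.  ``mixed_ends`` decides junctions inside a gene with
    exactly one end in an exon: 'intronic' (default, ends-based rule) or
    'exonic' (any-exon-end rule).  When the two ends overlap different
    genes and no single gene covers both, the junction is intergenic with a
    warning.
    """
    if mixed_ends not in ("intronic", "exonic"):
        raise ValueError(f"unknown mixed_ends policy {mixed_ends!r}")
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    start, end = junction.start, junction.end
    candidates = index.overlapping(junction.scaffold, start, end)

    def _annotate_exonic(gene: GeneModel) -> CircAnnotation:
        hit_idx = [
            i for i, (s, e) in enumerate(gene.exons) if e >= start and s <= end
        ]
        spanned = len(hit_idx)
        n = len(gene.exons)
        # terminal exons in transcript orientation
        first_idx, last_idx = (n - 1, 0) if gene.strand == "-" else (0, n - 1)
        has_first = first_idx in hit_idx
        has_last = last_idx in hit_idx
        if has_first and has_last:
            cat = "first_and_last"
        elif has_first:
            cat = "first"
        elif has_last:
            cat = "last"
        else:
            cat = "middle"
        return CircAnnotation(
            circ_id=junction.id,
            circ_class="exonic",
            parent_gene=gene.gene_id,
            spanned_exons=spanned,
            position_category=cat,
            strand=gene.strand,
        )

    exonic_hosts = []
    for g in candidates:
        s_hit = _in_exon(g, start, boundary_slop)
        e_hit = _in_exon(g, end, boundary_slop)
        if s_hit and e_hit:
            exonic_hosts.append(g)
        elif mixed_ends == "exonic" and (s_hit or e_hit) and g.start <= start and end <= g.end:
            exonic_hosts.append(g)
    if exonic_hosts:
        # prefer the gene covering both ends with the tightest span
        exonic_hosts.sort(key=lambda g: (g.end - g.start, g.gene_id))
        return _annotate_exonic(exonic_hosts[0])

    containing = [g for g in candidates if g.start <= start and end <= g.end]
    if containing:
        containing.sort(key=lambda g: (g.end - g.start, g.gene_id))
        g = containing[0]
        return CircAnnotation(
            circ_id=junction.id,
            circ_class="intronic",
            parent_gene=g.gene_id,
            strand=g.strand,
        )

    # ends overlapping different genes with no common host fall through here
    if candidates:
        end_genes = {
            g.gene_id for g in candidates if g.start <= start <= g.end
        } | {g.gene_id for g in candidates if g.start <= end <= g.end}
        if len(end_genes) > 1:
            warnings.warn(
                f"junction {junction.id}: ends overlap different genes "
                f"({sorted(end_genes)}); classified intergenic"
            )
    return CircAnnotation(circ_id=junction.id, circ_class="intergenic", strand=".")


def classify_catalog(
    catalog: CircCatalog | Iterable[BackspliceJunction],
    genes: Sequence[GeneModel] | GeneIndex,
    **kwargs,
) -> list[CircAnnotation]:
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    junctions = (
        catalog.junctions.values() if isinstance(catalog, CircCatalog) else catalog
    )
    return [classify_junction(j, index, **kwargs) for j in junctions]


def alternative_circularization(
    catalog: CircCatalog | Iterable[BackspliceJunction],
    annotations: Sequence[CircAnnotation],
) -> tuple[dict[str, list[str]], dict[int, int]]:
    """Group exonic circRNAs by parent gene.

    Returns the gene -> sorted circRNA-id mapping and the alternative
    circularization histogram: number of genes producing k circRNAs.
    """
    ids = (
        set(catalog.junctions)
        if isinstance(catalog, CircCatalog)
        else {j.id for j in catalog}
    )
    groups: dict[str, list[str]] = defaultdict(list)
    for ann in annotations:
        if ann.circ_class == "exonic" and ann.circ_id in ids:
            groups[ann.parent_gene].append(ann.circ_id)
    groups = {g: sorted(cids) for g, cids in groups.items()}
    hist: dict[int, int] = defaultdict(int)
    for cids in groups.values():
        hist[len(cids)] += 1
    return groups, dict(sorted(hist.items()))


def circ_sequence(
    junction: BackspliceJunction,
    annotation: CircAnnotation,
    genome: GenomeModel,
) -> str:
    """Circular sequence linearized at the back-splice, starting at
    ``start``, in transcript orientation.

    Exonic circles concatenate the parent gene's exon sub-intervals inside
    [start, end] in genomic order (reverse-complemented for minus-strand
    genes); intronic and intergenic circles are the plain genomic substring.
    """
    if annotation.circ_id != junction.id:
        raise ValueError(
            f"annotation {annotation.circ_id} does not match junction {junction.id}"
        )
    if annotation.circ_class == "exonic":
        gene = next(
            (g for g in genome.genes if g.gene_id == annotation.parent_gene), None
        )
        if gene is None:
            raise ValueError(f"parent gene {annotation.parent_gene} not in genome")
        seq = circular_sequence(genome, junction.scaffold, junction.start, junction.end, gene)
        if not seq:
            raise RuntimeError(f"zero-length exonic clip for {junction.id}")
        return revcomp(seq) if gene.strand == "-" else seq
    return genome.fetch(junction.scaffold, junction.start, junction.end)


def annotation_table(annotations: Sequence[CircAnnotation]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "circ_id": a.circ_id,
                "class": a.circ_class,
                "parent_gene": a.parent_gene or ".",
                "spanned_exons": a.spanned_exons if a.spanned_exons is not None else ".",
                "position_category": a.position_category or ".",
                "strand": a.strand,
            }
            for a in annotations
        ]
    )
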
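"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive throughout, matching the circRNA naming
convention ``{scaffold}-{start}-{end}`` (e.g. ``scf1-46693-46978``) where
``start`` is the first base inside the circle and ``end`` the last.  BED
export converts to 0-based half-open at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field


VALID_BASES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def circ_id(scaffold: str, start: int, end: int) -> str:
    return f"{scaffold}-{start}-{end}"


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered set of exon intervals on one scaffold.

    Exons are 1-based inclusive ``(start, end)`` tuples in ascending genomic
    order, non-overlapping.  ``strand`` is '+' or '-'; for minus-strand genes
    the transcript order of exons is the reverse of the genomic order.
    """

    gene_id: str
    scaffold: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: needs at least one exon")
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"gene {self.gene_id}: exon start {s} > end {e}")
            if s <= prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intervals strictly between consecutive exons (may be empty)."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return tuple(out)

    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class GenomeModel:
    """Reference scaffolds plus gene annotation — the coordinate frame for
    every downstream stage."""

    scaffolds: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, seq in self.scaffolds.items():
            if not seq:
                raise ValueError(f"scaffold {name}: empty sequence")
            if not set(seq) <= VALID_BASES:
                bad = sorted(set(seq) - VALID_BASES)
                raise ValueError(f"scaffold {name}: invalid characters {bad}")
        for g in self.genes:
            if g.scaffold not in self.scaffolds:
                raise ValueError(f"gene {g.gene_id}: unknown scaffold {g.scaffold}")
            if g.end > len(self.scaffolds[g.scaffold]):
                raise ValueError(f"gene {g.gene_id}: extends past scaffold end")

    def fetch(self, scaffold: str, start: int, end: int) -> str:
        """Sequence of [start, end], 1-based inclusive."""
        seq = self.scaffolds[scaffold]
        if start < 1 or end > len(seq) or start > end:
            raise ValueError(f"bad interval {scaffold}:{start}-{end}")
        return seq[start - 1 : end]

    def genes_by_scaffold(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            out.setdefault(g.scaffold, []).append(g)
        return out


@dataclass
class BackspliceJunction:
    """One circRNA candidate: a back-splice joining ``end`` (donor side,
    larger coordinate) back to ``start`` (acceptor side, smaller coordinate).

    ``junction_reads`` maps sample id to the number of reads crossing the
    back-splice point; ``callers`` records which detection route(s) reported
    it ('split' and/or 'realign').
    """

    scaffold: str
    start: int
    end: int
    strand: str = "."
    junction_reads: dict[str, int] = field(default_factory=dict)
    callers: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"junction start {self.start} must be < end {self.end}")
        for s, c in self.junction_reads.items():
            if c < 0:
                raise ValueError(f"negative junction read count for sample {s}")

    @property
    def id(self) -> str:
        return circ_id(self.scaffold, self.start, self.end)

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def total_reads(self) -> int:
        return sum(self.junction_reads.values())


@dataclass
class TruthRecord:
    """Ground truth for a planted circRNA (simulation only).

    ``abundance`` maps sample id to the expected junction-read copy number.
    Exonic circles have ``spliced=True``: their circular sequence excludes
    introns and their ends sit on exon boundaries of ``host_gene``.
    """

    junction: BackspliceJunction
    true_class: str
    host_gene: str | None
    spliced: bool
    abundance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.true_class not in ("exonic", "intronic", "intergenic"):
            raise ValueError(f"bad class {self.true_class!r}")
        if (self.true_class == "intergenic") != (self.host_gene is None):
            raise ValueError("intergenic iff host_gene is None")


@dataclass
class SampleDesign:
    """The tissue x replicate layout and the read-emission knobs.

    ``tissue_multipliers`` scale each circRNA's base abundance per tissue;
    ``dispersion`` is the negative-binomial phi in Var = mu + phi * mu^2;
    ``linear_retention`` is the fraction of linear-transcript fragments that
    survive the simulated RNase R digestion.
    """

    tissues: tuple[str, ...] = ("leaf", "root", "stem")
    replicates: int = 3
    tissue_multipliers: dict[str, float] | None = None
    dispersion: float = 0.2
    linear_retention: float = 0.05

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 <= self.linear_retention <= 1.0:
            raise ValueError("linear_retention must be in [0, 1]")
        if self.tissue_multipliers is None:
            self.tissue_multipliers = {t: 1.0 for t in self.tissues}
        for t in self.tissues:
            if self.tissue_multipliers.get(t, 0.0) < 0:
                raise ValueError(f"multiplier for {t} must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{t}_R{r}" for t in self.tissues for r in range(1, self.replicates + 1)]

    def tissue_of(self, sample_id: str) -> str:
        return sample_id.rsplit("_R", 1)[0]

    def grouping(self) -> dict[str, str]:
        return {s: self.tissue_of(s) for s in self.sample_ids}


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read (mate 1 or 2 of a pair)."""

    id: str
    mate: int
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass
class CircAnnotation:
    """Genomic classification of one back-splice junction."""

    circ_id: str
    circ_class: str
    parent_gene: str | None = None
    spanned_exons: int | None = None
    position_category: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.circ_class not in ("exonic", "intronic", "intergenic"):
            raise ValueError(f"bad class {self.circ_class!r}")
        if (self.circ_class == "intergenic") != (self.parent_gene is None):
            raise ValueError("intergenic iff parent_gene is None")
        if self.circ_class == "exonic":
            if self.spanned_exons is None or self.spanned_exons < 1:
                raise ValueError("exonic annotation needs spanned_exons >= 1")
            if self.position_category not in ("first", "middle", "last", "first_and_last"):
                raise ValueError(f"bad position_category {self.position_category!r}")
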
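"""Classification rules, alternative circularization and circular sequence
extraction, cross-checked against brute-force oracles."""

import numpy as np
import pytest

from salviacirc import simdata
from salviacirc.annotate import (
    GeneIndex,
    alternative_circularization,
    circ_sequence,
    classify_junction,
)
from salviacirc.models import BackspliceJunction, GeneModel, GenomeModel, revcomp


def _jx(start, end, scf="scf1"):
    return BackspliceJunction(scaffold=scf, start=start, end=end)


def oracle_classify(junction, genes, mixed_ends="intronic"):
    """Linear-scan re-statement of the classification rules."""
    start, end = junction.start, junction.end

    def in_exon(g, p):
        return any(s <= p <= e for s, e in g.exons)

    exonic = []
    for g in genes:
        if g.scaffold != junction.scaffold:
            continue
        both = in_exon(g, start) and in_exon(g, end)
        mixed = (
            mixed_ends == "exonic"
            and (in_exon(g, start) or in_exon(g, end))
            and g.start <= start and end <= g.end
        )
        if both or mixed:
            exonic.append(g)
    if exonic:
        g = min(exonic, key=lambda g: (g.end - g.start, g.gene_id))
        return ("exonic", g.gene_id)
    inside = [
        g for g in genes
        if g.scaffold == junction.scaffold and g.start <= start and end <= g.end
    ]
    if inside:
        g = min(inside, key=lambda g: (g.end - g.start, g.gene_id))
        return ("intronic", g.gene_id)
    return ("intergenic", None)


class TestClassifyJunction:
    def test_two_exon_span_is_exonic_last(self, toy_gene):
        ann = classify_junction(_jx(301, 600), [toy_gene])
        assert (ann.circ_class, ann.parent_gene) == ("exonic", "G")
        assert ann.spanned_exons == 2
        assert ann.position_category == "last"

    def test_intron_interval_is_intronic(self, toy_gene):
        ann = classify_junction(_jx(201, 300), [toy_gene])
        assert (ann.circ_class, ann.parent_gene) == ("intronic", "G")

    def test_no_gene_overlap_is_intergenic(self, toy_gene):
        ann = classify_junction(_jx(10, 50), [toy_gene])
        assert ann.circ_class == "intergenic" and ann.parent_gene is None

    @pytest.mark.parametrize(
        "start, end, category",
        [
            (101, 600, "first_and_last"),
            (101, 400, "first"),
            (301, 400, "middle"),
            (301, 600, "last"),
        ],
    )
    def test_position_categories_plus_strand(self, toy_gene, start, end, category):
        ann = classify_junction(_jx(start, end), [toy_gene])
        assert ann.position_category == category

    def test_minus_strand_flips_first_and_last(self):
        gene = GeneModel(
            gene_id="M", scaffold="scf1", strand="-",
            exons=((101, 200), (301, 400), (501, 600)),
        )
        # genomically-last exon is the transcript's first exon on minus strand
        assert classify_junction(_jx(301, 600), [gene]).position_category == "first"
        assert classify_junction(_jx(101, 400), [gene]).position_category == "last"

    def test_mixed_end_policies(self, toy_gene):
        # start in exon 1, end inside intron 1
        mixed = _jx(150, 250)
        assert classify_junction(mixed, [toy_gene]).circ_class == "intronic"
        ann = classify_junction(mixed, [toy_gene], mixed_ends="exonic")
        assert ann.circ_class == "exonic" and ann.parent_gene == "G"

    def test_ends_in_different_genes_warns_intergenic(self):
        g1 = GeneModel("A", "scf1", "+", ((100, 200),))
        g2 = GeneModel("B", "scf1", "+", ((900, 1000),))
        with pytest.warns(UserWarning, match="different genes"):
            ann = classify_junction(_jx(150, 950), [g1, g2])
        assert ann.circ_class == "intergenic"

    def test_boundary_slop_relaxes_exon_overlap(self, toy_gene):
        near = _jx(299, 600)  # 2 nt short of exon 2
        assert classify_junction(near, [toy_gene]).circ_class == "intronic"
        assert classify_junction(near, [toy_gene], boundary_slop=2).circ_class == "exonic"

    def test_agrees_with_oracle_on_random_junctions(self):
        """1,000 random junctions over random gene models: interval-scan
        oracle and interval-tree implementation agree exactly."""
        rng = np.random.default_rng(17)
        genes = []
        pos = 100
        for i in range(30):
            n_ex = int(rng.integers(1, 5))
            exons = []
            for _ in range(n_ex):
                length = int(rng.integers(50, 200))
                exons.append((pos, pos + length - 1))
                pos += length + int(rng.integers(30, 120))
            genes.append(
                GeneModel(f"g{i}", "scf1", "+" if rng.random() < 0.5 else "-", tuple(exons))
            )
            pos += int(rng.integers(100, 400))
        import warnings

        index = GeneIndex(genes)
        for _ in range(1000):
            start = int(rng.integers(1, pos))
            end = start + int(rng.integers(1, 2000))
            j = _jx(start, end)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # split-gene junctions warn by design
                ann = classify_junction(j, index)
            assert (ann.circ_class, ann.parent_gene) == oracle_classify(j, genes)


class TestAlternativeCircularization:
    def test_two_circles_one_gene(self, toy_gene):
        anns = [
            classify_junction(_jx(301, 400), [toy_gene]),
            classify_junction(_jx(301, 600), [toy_gene]),
        ]
        groups, hist = alternative_circularization(
            [_jx(301, 400), _jx(301, 600)], anns
        )
        assert groups == {"G": ["scf1-301-400", "scf1-301-600"]}
        assert hist == {2: 1}

    def test_three_singleton_genes(self):
        genes = [
            GeneModel(f"g{i}", "scf1", "+", ((1000 * i + 100, 1000 * i + 300),))
            for i in range(1, 4)
        ]
        juncs = [_jx(1000 * i + 100, 1000 * i + 300) for i in range(1, 4)]
        anns = [classify_junction(j, genes) for j in juncs]
        groups, hist = alternative_circularization(juncs, anns)
        assert hist == {1: 3}

    def test_histogram_matches_brute_force_and_mass_identity(self, small_genome):
        truth = simdata.plant_circrnas(small_genome, 20, 0, 0, seed=31)
        juncs = [t.junction for t in truth]
        anns = [classify_junction(j, small_genome.genes) for j in juncs]
        groups, hist = alternative_circularization(juncs, anns)
        # brute-force grouping
        expected = {}
        for ann in anns:
            expected.setdefault(ann.parent_gene, set()).add(ann.circ_id)
        assert {g: set(c) for g, c in groups.items()} == expected
        n_exonic = sum(1 for a in anns if a.circ_class == "exonic")
        assert sum(k * v for k, v in hist.items()) == n_exonic


class TestCircSequence:
    def test_exonic_concatenates_spanned_exons(self, toy_gene):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        genome = GenomeModel(scaffolds={"scf1": seq}, genes=[toy_gene])
        j = _jx(301, 600)
        ann = classify_junction(j, [toy_gene])
        s = circ_sequence(j, ann, genome)
        assert len(s) == 200
        assert s == genome.fetch("scf1", 301, 400) + genome.fetch("scf1", 501, 600)

    def test_intergenic_is_genomic_substring(self, toy_gene):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        genome = GenomeModel(scaffolds={"scf1": seq}, genes=[toy_gene])
        j = _jx(700, 740)
        ann = classify_junction(j, [toy_gene])
        assert circ_sequence(j, ann, genome) == seq[699:740]
        assert len(circ_sequence(j, ann, genome)) == 41

    def test_minus_strand_is_reverse_complement(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        plus = GeneModel("G", "scf1", "+", ((101, 200), (301, 400)))
        minus = GeneModel("G", "scf1", "-", ((101, 200), (301, 400)))
        j = _jx(101, 400)
        gp = GenomeModel(scaffolds={"scf1": seq}, genes=[plus])
        gm = GenomeModel(scaffolds={"scf1": seq}, genes=[minus])
        sp = circ_sequence(j, classify_junction(j, [plus]), gp)
        sm = circ_sequence(j, classify_junction(j, [minus]), gm)
        assert sm == revcomp(sp)

    def test_planted_exonic_annotations_match_truth(self, small_genome):
        truth = simdata.plant_circrnas(small_genome, 8, 2, 2, seed=33)
        genes = {g.gene_id: g for g in small_genome.genes}
        for rec in truth:
            ann = classify_junction(rec.junction, small_genome.genes)
            assert ann.circ_class == rec.true_class
            if rec.true_class == "exonic":
                assert ann.parent_gene == rec.host_gene
                g = genes[rec.host_gene]
                expected_span = sum(
                    1 for s, e in g.exons
                    if e >= rec.junction.start and s <= rec.junction.end
                )
                assert ann.spanned_exons == expected_span
                assert circ_sequence(rec.junction, ann, small_genome) == (
                    simdata.truth_circ_sequence(small_genome, rec)
                )
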
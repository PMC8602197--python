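"""Penalty scoring, wrap-around site scanning and best-site collapse,
cross-checked against a brute-force enumeration oracle."""

import numpy as np
import pytest

from salviacirc.mirnatarget import (
    MiRNA,
    _alignment_pairs,
    _window_scores,
    _to_idx,
    pair_penalty,
    scan_targets,
    score_alignment,
    sponge_summary,
)
from salviacirc.models import revcomp


def _mirna(seq, mid="mir"):
    return MiRNA(mid, seq)


def _site_for(mirna_seq):
    """Perfectly complementary DNA target site (5'->3') for a miRNA."""
    return revcomp(mirna_seq.replace("U", "T"))


MIR21 = "UAGCUUAUCAGACUGAUGUUGA"  # 22 nt


def _gapless(L):
    return [(i, L - i + 1) for i in range(1, L + 1)]


class TestScoreAlignment:
    def test_perfect_complement_scores_zero(self):
        m = _mirna(MIR21)
        site = _site_for(MIR21)
        assert score_alignment(m, site, _gapless(len(MIR21))) == 0.0

    @pytest.mark.parametrize(
        "pos, expected",
        [(15, 0.5), (5, 1.0)],  # G:U outside vs inside the core region
    )
    def test_single_wobble_position_dependence(self, pos, expected):
        m = _mirna("A" * 21)
        # miRNA A pairs T; put a G at the site position facing `pos`:
        # A:G is a mismatch, so use a U-miRNA base instead for wobble
        seq = list("A" * 21)
        seq[pos - 1] = "U"
        m = _mirna("".join(seq))
        site = list(_site_for(m.sequence))
        # wobble: miRNA U pairs target G; site position facing miRNA pos i
        # (gapless) is L - i + 1
        site[21 - pos] = "G"
        assert score_alignment(m, "".join(site), _gapless(21)) == expected

    def test_mismatch_core_plus_gap_tail(self):
        """One mismatch at position 3 (core, 2x) plus one unpaired miRNA
        base at position 18 (gap, 2.0) -> 4.0."""
        m = _mirna(MIR21)
        L = len(MIR21)
        site = list(_site_for(MIR21))
        site_len = L - 1  # miRNA position 18 is unpaired, site one shorter
        # rebuild site without the base pairing position 18
        full = _site_for(MIR21)
        site = full[: L - 18] + full[L - 18 + 1 :]
        aln = []
        for i in range(1, 18):
            aln.append((i, site_len - i + 1))
        aln.insert(17, (18, None))
        for i in range(19, L + 1):
            aln.append((i, site_len - i + 2))
        # introduce the mismatch at position 3: flip the site base facing it
        pos3 = site_len - 3 + 1
        flip = {"A": "C", "C": "A", "G": "A", "T": "C", "U": "C"}
        site = site[: pos3 - 1] + flip[site[pos3 - 1]] + site[pos3:]
        assert score_alignment(m, site, aln) == 4.0

    @pytest.mark.parametrize(
        "mirna_base, target_base, pos, expected",
        [
            ("A", "T", 1, 0.0), ("A", "T", 5, 0.0),  # WC never penalized
            ("G", "C", 20, 0.0), ("C", "G", 7, 0.0),
            ("G", "T", 15, 0.5), ("G", "T", 2, 1.0),  # wobble, core doubles
            ("U", "G", 14, 0.5), ("U", "G", 13, 1.0),
            ("A", "A", 15, 1.0), ("A", "A", 3, 2.0),  # mismatch
            ("C", "T", 1, 1.0), ("C", "T", 12, 2.0),
        ],
    )
    def test_penalty_table(self, mirna_base, target_base, pos, expected):
        assert pair_penalty(mirna_base, target_base, pos) == expected

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            score_alignment(_mirna(MIR21), "NNN" + "A" * 19, _gapless(22))


def brute_force_windows(mirna, seq, allow_gap=True):
    """Oracle: score every window/variant with score_alignment directly."""
    L = len(mirna.sequence)
    n = len(seq)
    padded = seq + seq[: L + 1]
    best = {}
    for w in range(n):
        scores = []
        site = padded[w : w + L]
        scores.append((score_alignment(mirna, site, _alignment_pairs(L, 0)), 0))
        if allow_gap:
            for g in range(1, L):
                site_i = padded[w : w + L + 1]
                scores.append(
                    (score_alignment(mirna, site_i, _alignment_pairs(L, g)), g)
                )
            for d in range(2, L):
                site_d = padded[w : w + L - 1]
                scores.append(
                    (score_alignment(mirna, site_d, _alignment_pairs(L, -d)), -d)
                )
        best[w] = min(scores)
    return best


class TestScanTargets:
    def test_exact_complement_single_zero_hit(self):
        rng = np.random.default_rng(83)
        flank = "".join(rng.choice(list("ACGT"), 200))
        seq = flank[:100] + _site_for(MIR21) + flank[100:]
        hits = scan_targets([_mirna(MIR21)], {"c1": seq}, cutoff=2.0)
        exact = [h for h in hits if h.expectation == 0.0]
        assert len(exact) == 1
        assert exact[0].site_start == 101
        assert exact[0].site_end == 101 + 22 - 1

    def test_site_split_across_backsplice_junction_found(self):
        rng = np.random.default_rng(89)
        core = "".join(rng.choice(list("ACGT"), 300))
        site = _site_for(MIR21)
        # last 10 nt of the circle followed by first 12 nt = the site
        seq = site[10:] + core + site[:10]
        hits = scan_targets([_mirna(MIR21)], {"c1": seq}, cutoff=0.0)
        assert len(hits) == 1
        h = hits[0]
        assert h.expectation == 0.0
        assert h.site_start == len(seq) - 10 + 1 and h.site_end == 12

    def test_random_sequence_no_perfect_hit(self):
        rng = np.random.default_rng(97)
        seq = "".join(rng.choice(list("ACGT"), 500))
        hits = scan_targets([_mirna(MIR21)], {"c1": seq}, cutoff=0.0)
        assert hits == []

    def test_window_scores_match_brute_force(self):
        """Vectorized per-window best scores equal direct evaluation of
        score_alignment over every window and gap variant."""
        rng = np.random.default_rng(101)
        for trial in range(5):
            seq = "".join(rng.choice(list("ACGT"), 60))
            mir = _mirna(
                "".join(rng.choice(list("ACGU"), int(rng.integers(18, 25)))),
                f"m{trial}",
            )
            L = len(mir.sequence)
            padded = seq + seq[: L + 1]
            best, variant = _window_scores(
                _to_idx(mir.sequence, "m"), _to_idx(padded, "t"), len(seq), True
            )
            oracle = brute_force_windows(mir, seq)
            for w in range(len(seq)):
                assert best[w] == pytest.approx(oracle[w][0], abs=1e-9), (trial, w)

    def test_collapse_equals_greedy_brute_force(self):
        """Reported sites equal a greedy best-first collapse over the
        exhaustive window enumeration."""
        rng = np.random.default_rng(103)
        mir = _mirna(MIR21)
        L = len(mir.sequence)
        cutoff = 18.0
        for trial in range(3):
            seq = "".join(rng.choice(list("ACGT"), 120))
            n = len(seq)
            oracle = brute_force_windows(mir, seq)
            order = sorted(oracle, key=lambda w: (oracle[w][0], w))
            taken = np.zeros(n, dtype=bool)
            expected = []
            for w in order:
                score, variant = oracle[w]
                if score > cutoff:
                    break
                site_len = L + (1 if variant > 0 else 0) - (1 if variant < 0 else 0)
                span = [(w + k) % n for k in range(site_len)]
                if any(taken[p] for p in span):
                    continue
                for p in span:
                    taken[p] = True
                expected.append((w + 1, score))
            hits = scan_targets([mir], {"c": seq}, cutoff=cutoff)
            got = sorted((h.site_start, h.expectation) for h in hits)
            assert got == sorted(expected), f"trial {trial}"

    def test_raising_cutoff_never_removes_hits(self):
        rng = np.random.default_rng(107)
        seq = "".join(rng.choice(list("ACGT"), 300))
        mir = _mirna(MIR21)
        lo = {(h.mirna_id, h.site_start) for h in scan_targets([mir], {"c": seq}, cutoff=8.0)}
        hi = {(h.mirna_id, h.site_start) for h in scan_targets([mir], {"c": seq}, cutoff=12.0)}
        assert lo <= hi

    def test_empty_mirna_set_empty_output(self):
        assert scan_targets([], {"c": "ACGT" * 50}) == []


class TestSpongeSummary:
    def test_multiplicity_tables(self):
        from salviacirc.mirnatarget import TargetHit

        def hit(m, c):
            return TargetHit(m, c, 1, 21, 0.0, "")

        hits = [hit("m1", "c1"), hit("m1", "c2"), hit("m2", "c1"), hit("m1", "c1")]
        mir_df, circ_df = sponge_summary(hits)
        assert mir_df.iloc[0].tolist() == ["m1", 2]
        assert mir_df.iloc[1].tolist() == ["m2", 1]
        assert circ_df.iloc[0].tolist() == ["c1", 2]

    def test_empty_hits(self):
        mir_df, circ_df = sponge_summary([])
        assert mir_df.empty and circ_df.empty
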
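"""miRNA binding-site scanning on circRNA sequences.

Complementarity is scored with an additive expectation penalty (lower is
better): Watson-Crick pair 0, G:U wobble 0.5, mismatch 1.0, gap 2.0, each
doubled when the miRNA position lies in the core region (positions 2-13
from the miRNA 5' end).  At most one gap per site is considered.  Sites
with expectation <= cutoff (default 5.0) are reported; overlapping windows
collapse to the best-scoring site.  Circular sequences are scanned with a
junction-wrapping pad so sites spanning the back-splice are found.

The absolute hit lists of any such scheme are parameterization-dependent;
this module's penalty table and cutoff are fixed and recorded in output
headers rather than inherited from an external scoring server.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CORE_START, CORE_END = 2, 13
MATCH_PENALTY = 0.0
WOBBLE_PENALTY = 0.5
MISMATCH_PENALTY = 1.0
GAP_PENALTY = 2.0
DEFAULT_CUTOFF = 5.0

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
# penalty[miRNA base][target base]; target T and U are equivalent
_PAIR_PENALTY = np.full((4, 4), MISMATCH_PENALTY)
_PAIR_PENALTY[0, 3] = MATCH_PENALTY  # A : U/T
_PAIR_PENALTY[3, 0] = MATCH_PENALTY  # U : A
_PAIR_PENALTY[2, 1] = MATCH_PENALTY  # G : C
_PAIR_PENALTY[1, 2] = MATCH_PENALTY  # C : G
_PAIR_PENALTY[2, 3] = WOBBLE_PENALTY  # G : U wobble
_PAIR_PENALTY[3, 2] = WOBBLE_PENALTY  # U : G wobble


def _core_factor(pos: int) -> float:
    return 2.0 if CORE_START <= pos <= CORE_END else 1.0


def _to_idx(seq: str, label: str) -> np.ndarray:
    try:
        return np.array([_BASE_IDX[b] for b in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"{label}: invalid nucleotide {exc.args[0]!r}") from None


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA; T is normalized to U on construction."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        norm = self.sequence.upper().replace("T", "U")
        if not 18 <= len(norm) <= 26:
            raise ValueError(f"miRNA {self.id}: length {len(norm)} outside 18-26 nt")
        if not set(norm) <= set("ACGU"):
            raise ValueError(f"miRNA {self.id}: invalid characters")
        object.__setattr__(self, "sequence", norm)


@dataclass
class TargetHit:
    """One miRNA binding site on a linearized circular sequence.

    ``site_end`` < ``site_start`` means the site wraps across the
    back-splice junction.  ``alignment`` is the three-line rendering:
    miRNA 3'->5', match line, target 5'->3'.
    """

    mirna_id: str
    circ_id: str
    site_start: int
    site_end: int
    expectation: float
    alignment: str


def pair_penalty(mirna_base: str, target_base: str, mirna_pos: int) -> float:
    """Penalty of pairing one miRNA base (at 1-based 5' position
    ``mirna_pos``) with one target base."""
    m = _BASE_IDX.get(mirna_base.upper())
    t = _BASE_IDX.get(target_base.upper())
    if m is None or t is None:
        raise ValueError(f"invalid bases {mirna_base!r}/{target_base!r}")
    return float(_PAIR_PENALTY[m, t]) * _core_factor(mirna_pos)


def score_alignment(
    mirna: MiRNA,
    target_site: str,
    alignment: Sequence[tuple[int | None, int | None]],
) -> float:
    """Expectation score of an explicit miRNA/target alignment.

    ``alignment`` lists (mirna_pos, target_pos) pairs in order, 1-based;
    ``None`` on one side marks a gap (an unpaired base on the other side).
    Every miRNA position 1..L must appear exactly once.  A gap in the
    miRNA (an inserted target base) takes the core factor of the next
    miRNA position.
    """
    tgt = target_site.upper()
    if not set(tgt.replace("T", "U")) <= set("ACGU"):
        raise ValueError("target site contains non-nucleotide characters")
    L = len(mirna.sequence)
    covered = [mi for mi, _ in alignment if mi is not None]
    if sorted(covered) != list(range(1, L + 1)):
        raise ValueError(f"alignment must cover miRNA positions 1..{L} exactly once")

    total = 0.0
    for idx, (mi, tj) in enumerate(alignment):
        if mi is not None and tj is not None:
            total += pair_penalty(mirna.sequence[mi - 1], tgt[tj - 1], mi)
        elif mi is not None:  # miRNA base unpaired: gap in the target
            total += GAP_PENALTY * _core_factor(mi)
        elif tj is not None:  # inserted target base: gap in the miRNA
            nxt = next((m for m, _ in alignment[idx + 1 :] if m is not None), L)
            total += GAP_PENALTY * _core_factor(nxt)
        else:
            raise ValueError("alignment element with neither position set")
    return total


def _window_scores(
    mirna_idx: np.ndarray, padded_idx: np.ndarray, n_windows: int, allow_gap: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Best expectation per window start and the winning variant code.

    Variant codes: 0 gapless; g in 1..L-1 -> target base inserted between
    miRNA positions g and g+1; -d -> miRNA position d unpaired (d in
    2..L-1).  Window w pairs miRNA position i with the padded base at
    w + L - i (antiparallel), plus the gap adjustment of the variant.
    """
    L = len(mirna_idx)
    W = n_windows
    core = np.array([_core_factor(i) for i in range(1, L + 1)])
    pen = _PAIR_PENALTY[mirna_idx] * core[:, None]  # L x 4

    A = np.empty((L, W))
    B = np.empty((L, W))
    C = np.empty((L, W))
    for i in range(1, L + 1):
        A[i - 1] = pen[i - 1][padded_idx[L - i : L - i + W]]
        B[i - 1] = pen[i - 1][padded_idx[L - i + 1 : L - i + 1 + W]]
        if L - i - 1 >= 0:
            C[i - 1] = pen[i - 1][padded_idx[L - i - 1 : L - i - 1 + W]]
    G = A.sum(axis=0)
    best = G.copy()
    variant = np.zeros(W, dtype=np.int32)
    if not allow_gap or L < 3:
        return best, variant

    cumA = np.cumsum(A, axis=0)
    cumB = np.cumsum(B, axis=0)
    cumC = np.cumsum(C, axis=0)
    for g in range(1, L):  # inserted target base between g and g+1
        gp = GAP_PENALTY * _core_factor(g + 1)
        score = cumB[g - 1] + (G - cumA[g - 1]) + gp
        better = score < best
        best[better] = score[better]
        variant[better] = g
    for d in range(2, L):  # miRNA position d unpaired
        gp = GAP_PENALTY * _core_factor(d)
        prefix = cumC[d - 2] if d >= 2 else 0.0
        score = prefix + (G - cumA[d - 1]) + gp
        better = score < best
        best[better] = score[better]
        variant[better] = -d
    return best, variant


def _alignment_pairs(L: int, variant: int) -> list[tuple[int | None, int | None]]:
    """Alignment of miRNA positions to site positions (1-based, site given
    5'->3') for one variant code, matching :func:`_window_scores`."""
    if variant == 0:
        return [(i, L - i + 1) for i in range(1, L + 1)]
    if variant > 0:
        g = variant
        site_len = L + 1
        pairs: list[tuple[int | None, int | None]] = []
        for i in range(1, g + 1):
            pairs.append((i, site_len - (i - 1)))
        pairs.append((None, site_len - g))  # inserted target base
        for i in range(g + 1, L + 1):
            pairs.append((i, site_len - i))
        return pairs
    d = -variant
    site_len = L - 1
    pairs = []
    for i in range(1, d):
        pairs.append((i, site_len - i + 1))
    pairs.append((d, None))  # unpaired miRNA base
    for i in range(d + 1, L + 1):
        pairs.append((i, site_len - i + 2))
    return pairs


def _render(mirna: MiRNA, site: str, pairs: list[tuple[int | None, int | None]]) -> str:
    top, mid, bot = [], [], []
    for mi, tj in reversed(pairs):  # render target 5'->3' left to right
        m = mirna.sequence[mi - 1] if mi is not None else "-"
        t = site[tj - 1] if tj is not None else "-"
        if mi is None or tj is None:
            sym = " "
        else:
            p = _PAIR_PENALTY[_BASE_IDX[m], _BASE_IDX[t]]
            sym = "|" if p == MATCH_PENALTY else ("o" if p == WOBBLE_PENALTY else " ")
        top.append(m)
        mid.append(sym)
        bot.append(t)
    return (
        "miRNA  3' " + "".join(reversed(mirna.sequence)).ljust(len(top)) + " 5'\n"
        "          " + "".join(mid) + "\n"
        "target 5' " + "".join(bot) + " 3'"
    )


def scan_targets(
    mirnas: Sequence[MiRNA],
    circ_seqs: Mapping[str, str],
    cutoff: float = DEFAULT_CUTOFF,
    allow_gap: bool = True,
) -> list[TargetHit]:
    """Scan every circular sequence for binding sites of every miRNA.

    Each sequence is treated as circular: a pad of miRNA length wraps the
    back-splice so junction-spanning sites are found, with coordinates
    mapped back to the unpadded circle.  Per window the best gapless, then
    best single-gap alignment is scored; windows with expectation <=
    ``cutoff`` are kept and overlapping windows collapse to the
    best-scoring site.
    """
    hits: list[TargetHit] = []
    for circ_id_, seq in circ_seqs.items():
        n = len(seq)
        if n == 0:
            continue
        seq_u = seq.upper()
        for mir in mirnas:
            L = len(mir.sequence)
            if n < 3:
                continue
            mirna_idx = _to_idx(mir.sequence, mir.id)
            padded = seq_u + seq_u[: min(L + 1, n)]
            padded_idx = _to_idx(padded, circ_id_)
            n_win = n if len(padded_idx) >= n + L + 1 else max(len(padded_idx) - L - 1, 0)
            if n_win == 0:
                continue
            best, variant = _window_scores(mirna_idx, padded_idx, n_win, allow_gap)

            order = np.lexsort((np.arange(n_win), best))
            taken = np.zeros(n, dtype=bool)
            for w in order:
                if best[w] > cutoff:
                    break
                site_len = L + (1 if variant[w] > 0 else 0) - (1 if variant[w] < 0 else 0)
                span = [(w + off) % n for off in range(site_len)]
                if any(taken[p] for p in span):
                    continue
                for p in span:
                    taken[p] = True
                site = padded[w : w + site_len]
                pairs = _alignment_pairs(L, int(variant[w]))
                hits.append(
                    TargetHit(
                        mirna_id=mir.id,
                        circ_id=circ_id_,
                        site_start=w + 1,
                        site_end=(w + site_len - 1) % n + 1,
                        expectation=float(best[w]),
                        alignment=_render(mir, site, pairs),
                    )
                )
    hits.sort(key=lambda h: (h.circ_id, h.site_start, h.mirna_id))
    return hits


def sponge_summary(hits: Sequence[TargetHit]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distinct-target multiplicity tables.

    Returns (per-miRNA circRNA counts, per-circRNA miRNA counts), each
    sorted by descending count with lexicographic tie-break; duplicate
    (miRNA, circRNA) hits count once.
    """
    pairs = sorted({(h.mirna_id, h.circ_id) for h in hits})
    by_mirna: dict[str, set[str]] = {}
    by_circ: dict[str, set[str]] = {}
    for m, c in pairs:
        by_mirna.setdefault(m, set()).add(c)
        by_circ.setdefault(c, set()).add(m)
    mir_df = pd.DataFrame(
        sorted(
            ({"mirna_id": m, "n_circrnas": len(cs)} for m, cs in by_mirna.items()),
            key=lambda r: (-r["n_circrnas"], r["mirna_id"]),
        )
    )
    circ_df = pd.DataFrame(
        sorted(
            ({"circ_id": c, "n_mirnas": len(ms)} for c, ms in by_circ.items()),
            key=lambda r: (-r["n_mirnas"], r["circ_id"]),
        )
    )
    return mir_df, circ_df
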
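"""Two-caller consensus and cross-sample catalog building.

Per sample, the junctions reported by both callers form the consensus set
(the intersection), and the intersection/union ratio is reported.  The
per-sample consensus sets are then merged across samples into one catalog
with per-sample junction-read counts, from which replicate- and
tissue-sharing statistics (Venn region counts) are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .models import BackspliceJunction


@dataclass
class IntersectReport:
    n_split: int
    n_realign: int
    n_intersection: int
    n_union: int

    @property
    def ratio(self) -> float:
        """Intersection / union, as a fraction (0 when both sets empty)."""
        return self.n_intersection / self.n_union if self.n_union else 0.0


@dataclass
class CircCatalog:
    """Union of consensus junctions across samples.

    ``provenance`` maps junction id to the set of samples in which it passed
    the two-caller consensus.
    """

    junctions: dict[str, BackspliceJunction] = field(default_factory=dict)
    samples: list[str] = field(default_factory=list)
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.junctions)

    def sample_set(self, sample: str) -> set[str]:
        """Ids of junctions that passed consensus in one sample."""
        return {jid for jid, prov in self.provenance.items() if sample in prov}


def _check_unique(junctions: Sequence[BackspliceJunction], label: str) -> dict[str, BackspliceJunction]:
    by_id: dict[str, BackspliceJunction] = {}
    for j in junctions:
        key = (j.scaffold, j.start, j.end)
        jid = j.id
        if jid in by_id:
            raise ValueError(f"duplicate junction id {jid} in {label} input")
        by_id[jid] = j
    return by_id


def intersect_callers(
    set_split: Sequence[BackspliceJunction],
    set_realign: Sequence[BackspliceJunction],
    count_policy: str = "realign",
    slop: int = 0,
) -> tuple[list[BackspliceJunction], IntersectReport]:
    """Per-sample consensus: junctions found by both callers.

    Matching requires identical (scaffold, start, end); ``slop`` > 0 allows
    that many nt of coordinate tolerance for real data (a realign junction
    matches the nearest split junction within slop on both ends).  The
    consensus junction's read counts come from the realign caller
    (``count_policy='realign'``) or the per-sample maximum
    (``count_policy='max'``).
    """
    if count_policy not in ("realign", "max"):
        raise ValueError(f"unknown count_policy {count_policy!r}")
    a = _check_unique(set_split, "split")
    b = _check_unique(set_realign, "realign")

    def _match(jb: BackspliceJunction) -> BackspliceJunction | None:
        if slop == 0:
            return a.get(jb.id)
        best = None
        for ja in a.values():
            if (
                ja.scaffold == jb.scaffold
                and abs(ja.start - jb.start) <= slop
                and abs(ja.end - jb.end) <= slop
            ):
                if best is None or abs(ja.start - jb.start) + abs(ja.end - jb.end) < abs(
                    best.start - jb.start
                ) + abs(best.end - jb.end):
                    best = ja
        return best

    consensus: list[BackspliceJunction] = []
    matched_a: set[str] = set()
    for jb in b.values():
        ja = _match(jb)
        if ja is None or ja.id in matched_a:
            continue
        matched_a.add(ja.id)
        counts = dict(jb.junction_reads)
        if count_policy == "max":
            for s, c in ja.junction_reads.items():
                counts[s] = max(counts.get(s, 0), c)
        consensus.append(
            BackspliceJunction(
                scaffold=jb.scaffold,
                start=jb.start,
                end=jb.end,
                strand=jb.strand if jb.strand != "." else ja.strand,
                junction_reads=counts,
                callers=set(ja.callers) | set(jb.callers),
            )
        )
    n_int = len(consensus)
    n_union = len(a) + len(b) - n_int
    report = IntersectReport(
        n_split=len(a), n_realign=len(b), n_intersection=n_int, n_union=n_union
    )
    return sorted(consensus, key=lambda j: (j.scaffold, j.start, j.end)), report


def merge_samples(per_sample: Mapping[str, Sequence[BackspliceJunction]]) -> CircCatalog:
    """Union the per-sample consensus lists into one catalog by coordinates.

    Per-sample junction-read counts are preserved (0 where a junction was
    not found); provenance records the contributing samples.
    """
    samples = list(per_sample)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")
    catalog = CircCatalog(samples=samples)
    for sample in samples:
        _check_unique(per_sample[sample], sample)
        for j in per_sample[sample]:
            jid = j.id
            if jid not in catalog.junctions:
                catalog.junctions[jid] = BackspliceJunction(
                    scaffold=j.scaffold,
                    start=j.start,
                    end=j.end,
                    strand=j.strand,
                    junction_reads={},
                    callers=set(),
                )
                catalog.provenance[jid] = set()
            tgt = catalog.junctions[jid]
            for s, c in j.junction_reads.items():
                tgt.junction_reads[s] = tgt.junction_reads.get(s, 0) + c
            tgt.callers |= j.callers
            if tgt.strand == "." and j.strand != ".":
                tgt.strand = j.strand
            catalog.provenance[jid].add(sample)
    for j in catalog.junctions.values():
        for s in samples:
            j.junction_reads.setdefault(s, 0)
    # canonical coordinate order, independent of input sample order
    order = sorted(catalog.junctions.values(), key=lambda j: (j.scaffold, j.start, j.end))
    catalog.junctions = {j.id: j for j in order}
    catalog.provenance = {j.id: catalog.provenance[j.id] for j in order}
    return catalog


@dataclass
class GroupSharing:
    group: str
    members: list[str]
    union_size: int
    shared_all: int

    @property
    def shared_pct(self) -> float:
        return 100.0 * self.shared_all / self.union_size if self.union_size else 0.0


@dataclass
class VennCounts:
    """Region counts for a set triple (or pair), keyed by membership
    pattern, e.g. ('A',), ('A','B'), ('A','B','C')."""

    sets: list[str]
    regions: dict[tuple[str, ...], int]

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())


def _venn(named_sets: Mapping[str, set[str]]) -> VennCounts:
    names = list(named_sets)
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(named_sets[n] for n in combo))
            outside = set.union(set(), *(named_sets[n] for n in names if n not in combo))
            regions[combo] = len(inside - outside)
    return VennCounts(sets=names, regions=regions)


def sharing_stats(
    catalog: CircCatalog, grouping: Mapping[str, str]
) -> tuple[list[GroupSharing], dict[tuple[str, ...], VennCounts]]:
    """Intra-group sharing and inter-group Venn region counts.

    ``grouping`` maps every catalog sample to a group (e.g. tissue).  For
    each group: the union of its members' junction sets, and how many
    junctions all members share.  For every pair and triple of groups, the
    Venn region counts over group-level junction sets.
    """
    missing = [s for s in catalog.samples if s not in grouping]
    if missing:
        raise ValueError(f"samples missing from grouping: {missing}")

    groups: dict[str, list[str]] = {}
    for s in catalog.samples:
        groups.setdefault(grouping[s], []).append(s)

    member_sets = {s: catalog.sample_set(s) for s in catalog.samples}
    group_sets = {
        g: set.union(set(), *(member_sets[s] for s in members))
        for g, members in groups.items()
    }

    intra = []
    for g, members in groups.items():
        union = group_sets[g]
        shared = (
            set.intersection(*(member_sets[s] for s in members)) if members else set()
        )
        intra.append(
            GroupSharing(group=g, members=members, union_size=len(union), shared_all=len(shared))
        )

    venns: dict[tuple[str, ...], VennCounts] = {}
    names = list(groups)
    for r in (2, 3):
        for combo in combinations(names, r):
            venns[combo] = _venn({g: group_sets[g] for g in combo})
    return intra, venns
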
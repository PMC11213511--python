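"""Multi-caller consensus merging.

A consensus record requires >=2 distinct callers agreeing on SV type and
orientation pair, with per-end breakpoint distances <= 1 kb (the
"pairwise" distance is applied per corresponding breakend after canonical
ordering).  Clusters are connected components of the compatibility graph,
found with a position-sorted sweep; a strict-clique mode is available.
Merged breakend positions are per-end lower medians, and intrachromosomal
records shorter than 30 bp are discarded.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import Breakend, ConsensusSV, SVCall

logger = logging.getLogger(__name__)

DEFAULT_MAX_DIST = 1000
DEFAULT_MIN_CALLERS = 2
DEFAULT_MIN_SIZE = 30


def calls_compatible(a: SVCall, b: SVCall, max_dist: int = DEFAULT_MAX_DIST) -> bool:
    """True iff two same-sample calls agree on type, orientation pair and
    both per-end distances (b1<->b1, b2<->b2) are <= max_dist on matching
    chromosomes."""
    return (
        a.svtype == b.svtype
        and a.orient_pair == b.orient_pair
        and a.b1.chrom == b.b1.chrom
        and a.b2.chrom == b.b2.chrom
        and abs(a.b1.pos - b.b1.pos) <= max_dist
        and abs(a.b2.pos - b.b2.pos) <= max_dist
    )


def _lower_median(values: Sequence[int]) -> int:
    s = sorted(values)
    return s[(len(s) - 1) // 2]


class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _dedupe(calls: Sequence[SVCall]) -> list[SVCall]:
    seen = set()
    out = []
    dropped = 0
    for c in calls:
        key = (c.sample_id, c.caller_id, c.b1, c.b2, c.svtype)
        if key in seen:
            dropped += 1
            continue
        seen.add(key)
        out.append(c)
    if dropped:
        logger.warning("deduplicated %d duplicate (sample, caller, coordinates) records", dropped)
    return out


def _cluster_components(group: list[SVCall], max_dist: int) -> list[list[SVCall]]:
    # group is pre-sorted by b1.pos; only neighbours within max_dist on b1
    # can be compatible, so the sweep is O(n * window).
    dsu = _DSU(len(group))
    for i, a in enumerate(group):
        for j in range(i + 1, len(group)):
            b = group[j]
            if b.b1.pos - a.b1.pos > max_dist:
                break
            if abs(a.b2.pos - b.b2.pos) <= max_dist:
                dsu.union(i, j)
    comps: dict[int, list[SVCall]] = defaultdict(list)
    for i, c in enumerate(group):
        comps[dsu.find(i)].append(c)
    return list(comps.values())


def _cluster_cliques(group: list[SVCall], max_dist: int) -> list[list[SVCall]]:
    # Greedy clique partition over the canonical order: a call joins the
    # first cluster it is compatible with *every* member of.
    clusters: list[list[SVCall]] = []
    for c in group:
        for cl in clusters:
            if all(calls_compatible(c, m, max_dist) for m in cl):
                cl.append(c)
                break
        else:
            clusters.append([c])
    return clusters


def merge_sample(
    calls: Iterable[SVCall],
    max_dist: int = DEFAULT_MAX_DIST,
    min_callers: int = DEFAULT_MIN_CALLERS,
    min_size: int = DEFAULT_MIN_SIZE,
    strict_clique: bool = False,
) -> list[ConsensusSV]:
    """Merge one sample's multi-caller calls into consensus records."""
    calls = _dedupe(list(calls))
    if not calls:
        return []
    sample_ids = {c.sample_id for c in calls}
    if len(sample_ids) != 1:
        raise ValueError(f"merge_sample given calls from multiple samples: {sorted(sample_ids)}")

    groups: dict[tuple, list[SVCall]] = defaultdict(list)
    for c in calls:
        groups[(c.svtype, c.orient_pair, c.b1.chrom, c.b2.chrom)].append(c)

    out: list[ConsensusSV] = []
    for key in sorted(groups, key=str):
        group = sorted(groups[key], key=lambda c: (c.b1.pos, c.b2.pos, c.caller_id))
        clusters = (_cluster_cliques if strict_clique else _cluster_components)(group, max_dist)
        for members in clusters:
            callers = frozenset(m.caller_id for m in members)
            if len(callers) < min_callers:
                continue
            b1 = Breakend(members[0].b1.chrom, _lower_median([m.b1.pos for m in members]), members[0].b1.orient)
            b2 = Breakend(members[0].b2.chrom, _lower_median([m.b2.pos for m in members]), members[0].b2.orient)
            rec = ConsensusSV(
                sample_id=members[0].sample_id,
                b1=b1,
                b2=b2,
                svtype=members[0].svtype,
                supporting_callers=callers,
                member_calls=tuple(members),
            )
            if rec.intrachromosomal and rec.size < min_size:
                continue
            out.append(rec)
    out.sort(key=lambda r: (r.b1.sort_key(), r.b2.sort_key(), r.svtype))
    return out


def merge_cohort(
    per_sample_calls: Mapping[str, Iterable[SVCall]],
    max_dist: int = DEFAULT_MAX_DIST,
    min_callers: int = DEFAULT_MIN_CALLERS,
    min_size: int = DEFAULT_MIN_SIZE,
    strict_clique: bool = False,
) -> tuple[list[ConsensusSV], pd.DataFrame]:
    """Merge every sample and tabulate per-sample counts by SV class.

    Returns the cohort consensus list (ordered by sample, then genomic
    position) and a per-sample count table with DEL/DUP/INV/TRA columns
    plus intra-/interchromosomal TRA breakdowns.
    """
    consensus: list[ConsensusSV] = []
    rows = []
    for sample_id in sorted(per_sample_calls):
        recs = merge_sample(
            per_sample_calls[sample_id],
            max_dist=max_dist,
            min_callers=min_callers,
            min_size=min_size,
            strict_clique=strict_clique,
        )
        consensus.extend(recs)
        counts = {t: 0 for t in ("DEL", "DUP", "INV", "TRA")}
        intra_tra = inter_tra = 0
        for r in recs:
            counts[r.svtype] += 1
            if r.svtype == "TRA":
                if r.intrachromosomal:
                    intra_tra += 1
                else:
                    inter_tra += 1
        rows.append(
            {
                "sample_id": sample_id,
                **counts,
                "total": sum(counts.values()),
                "intra_tra": intra_tra,
                "inter_tra": inter_tra,
            }
        )
    table = pd.DataFrame(
        rows, columns=["sample_id", "DEL", "DUP", "INV", "TRA", "total", "intra_tra", "inter_tra"]
    )
    return consensus, table
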
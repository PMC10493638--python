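"""Allele-group construction across three haploid assemblies.

Genes are partitioned from pairwise protein-similarity hits into triads
(1:1:1 correspondence across the three haplotypes), pairs (two haplotypes)
and singletons. A triad requires a *closed triangle* of reciprocal best
hits: each member is the other's best match within the partner haplotype.
Open chains (A-B and B-C without A-C) are resolved deterministically by
dropping the weaker link, never by transitive closure, which could merge
paralogous families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .io import HitRecord


def haplotype_from_prefix(gene_id: str) -> str:
    """Default ID scheme: haplotype label is the token before the first '_'."""
    return gene_id.split("_")[0]


HaplotypeResolver = Callable[[str], str] | Mapping[str, str]


def _resolver(how: HaplotypeResolver) -> Callable[[str], str]:
    if callable(how):
        return how

    def look(gene_id: str) -> str:
        try:
            return how[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} has no haplotype assignment")
    return look


@dataclass
class Triad:
    """Three homoeologous gene IDs, one per haplotype, plus the identities
    of the three supporting reciprocal pairs (the closed triangle)."""

    triad_id: str
    genes: dict[str, str]  # haplotype label -> gene_id
    mean_identity: float
    provenance: list[tuple[str, str, float]] = field(default_factory=list)

    def members(self) -> list[str]:
        return [self.genes[h] for h in sorted(self.genes)]


@dataclass
class AllelePartition:
    """Exhaustive, disjoint partition of the gene inventory into triads,
    two-gene groups and singletons."""

    triads: list[Triad]
    pairs: list[tuple[str, str, float]]
    singletons: list[str]
    anchors: dict[str, str] = field(default_factory=dict)  # group id -> ref gene

    def validate(self, all_genes: Iterable[str]) -> None:
        inventory = set(all_genes)
        seen: set[str] = set()
        for t in self.triads:
            for g in t.members():
                if g in seen:
                    raise ValueError(f"gene {g!r} in more than one group")
                seen.add(g)
        for a, b, _ in self.pairs:
            for g in (a, b):
                if g in seen:
                    raise ValueError(f"gene {g!r} in more than one group")
                seen.add(g)
        for g in self.singletons:
            if g in seen:
                raise ValueError(f"gene {g!r} in more than one group")
            seen.add(g)
        if seen != inventory:
            missing = inventory - seen
            extra = seen - inventory
            raise ValueError(
                f"partition not exhaustive: missing={sorted(missing)[:5]} "
                f"extra={sorted(extra)[:5]}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.triads:
            row = {"group_id": t.triad_id, "kind": "triad",
                   "mean_identity": round(t.mean_identity, 4)}
            row.update(t.genes)
            rows.append(row)
        for i, (a, b, ident) in enumerate(self.pairs, 1):
            rows.append({"group_id": f"P{i:05d}", "kind": "pair",
                         "mean_identity": round(ident, 4),
                         "gene_a": a, "gene_b": b})
        for i, g in enumerate(self.singletons, 1):
            rows.append({"group_id": f"S{i:05d}", "kind": "singleton",
                         "gene_a": g})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Best hits and reciprocal pairs
# ---------------------------------------------------------------------------

def best_hits(hits: Sequence[HitRecord],
              haplotype_of: HaplotypeResolver = haplotype_from_prefix,
              min_identity: float = 60.0,
              min_coverage: float = 0.5,
              query_lengths: Mapping[str, int] | None = None,
              ) -> dict[tuple[str, str], HitRecord]:
    """Best hit of each query into each target haplotype.

    Best = highest percent identity, ties broken by bit score then by
    lexicographically smaller subject ID. Hits below ``min_identity`` are
    dropped; when ``query_lengths`` is given, hits with
    alignment_length / query_length < ``min_coverage`` are dropped too.
    Self-haplotype hits are ignored.
    """
    hap = _resolver(haplotype_of)
    best: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        q_hap, s_hap = hap(h.query_id), hap(h.subject_id)
        if q_hap == s_hap:
            continue
        if h.percent_identity < min_identity:
            continue
        if query_lengths is not None:
            qlen = query_lengths.get(h.query_id)
            if qlen is None:
                raise KeyError(f"no length for query {h.query_id!r}")
            if h.alignment_length / qlen < min_coverage:
                continue
        key = (h.query_id, s_hap)
        cur = best.get(key)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best[key] = h
    return best


def _hit_rank(h: HitRecord) -> tuple[float, float, str]:
    # sort key: higher identity first, then higher bit score, then lexico id
    return (-h.percent_identity, -h.bit_score, h.subject_id)


def reciprocal_pairs(best: Mapping[tuple[str, str], HitRecord],
                     haplotype_of: HaplotypeResolver = haplotype_from_prefix,
                     ) -> list[tuple[str, str, float]]:
    """Mutual-best-hit pairs (A, B, identity), A < B lexicographically.

    A pair is kept iff A's best hit in B's haplotype is B and vice versa;
    identity recorded is the mean of the two directed identities.
    """
    hap = _resolver(haplotype_of)
    pairs = []
    for (q, s_hap), h in best.items():
        s = h.subject_id
        if q >= s:
            continue  # visit each unordered pair once, from the smaller id
        back = best.get((s, hap(q)))
        if back is not None and back.subject_id == q:
            pairs.append((q, s, (h.percent_identity + back.percent_identity) / 2.0))
    pairs.sort()
    return pairs


def one_way_pairs(best: Mapping[tuple[str, str], HitRecord],
                  ) -> list[tuple[str, str, float]]:
    """One-directional alternative to :func:`reciprocal_pairs`: every
    (query, best subject) link, deduplicated to unordered pairs."""
    seen: dict[tuple[str, str], float] = {}
    for (q, _s_hap), h in best.items():
        a, b = sorted((q, h.subject_id))
        key = (a, b)
        seen[key] = max(seen.get(key, 0.0), h.percent_identity)
    return sorted((a, b, i) for (a, b), i in seen.items())


# ---------------------------------------------------------------------------
# Partition construction
# ---------------------------------------------------------------------------

def build_partition(pairs: Sequence[tuple[str, str, float]],
                    all_genes: Iterable[str],
                    haplotype_of: HaplotypeResolver = haplotype_from_prefix,
                    ) -> AllelePartition:
    """Partition the gene inventory into triads, pairs and singletons.

    A triad is a closed triangle of links spanning the three haplotypes;
    a gene appearing in two triangles is an error (it signals upstream
    multi-mapping). Links not in any triangle are resolved by a greedy
    maximum-identity matching (equivalent to repeatedly discarding the
    weaker link of any open chain); the survivors become pairs, everything
    else a singleton. Output is independent of input order.
    """
    hap = _resolver(haplotype_of)
    inventory = sorted(set(all_genes))
    link_ident: dict[tuple[str, str], float] = {}
    adj: dict[str, set[str]] = {}
    for a, b, ident in pairs:
        a2, b2 = sorted((a, b))
        link_ident[(a2, b2)] = ident
        adj.setdefault(a2, set()).add(b2)
        adj.setdefault(b2, set()).add(a2)

    # triangles: for each link (a,b), common neighbours c close a triangle
    triangles: list[tuple[str, str, str]] = []
    for (a, b) in sorted(link_ident):
        common = adj.get(a, set()) & adj.get(b, set())
        for c in sorted(common):
            tri = tuple(sorted((a, b, c)))
            if tri[0] == a and tri[1] == b:  # emit once per triangle
                haps = {hap(g) for g in tri}
                if len(haps) == 3:
                    triangles.append(tri)  # type: ignore[arg-type]

    in_triangle: dict[str, tuple[str, str, str]] = {}
    for tri in triangles:
        for g in tri:
            prev = in_triangle.get(g)
            if prev is not None and prev != tri:
                raise ValueError(
                    f"gene {g!r} participates in two triangles {prev} and "
                    f"{tri}: upstream multi-mapping")
            in_triangle[g] = tri

    triads: list[Triad] = []
    triad_genes: set[str] = set()
    for i, tri in enumerate(sorted(set(triangles)), 1):
        edges = [(x, y, link_ident[(x, y)])
                 for x, y in itertools_combinations(tri)]
        genes = {hap(g): g for g in tri}
        triads.append(Triad(
            triad_id=f"T{i:05d}", genes=genes,
            mean_identity=sum(e[2] for e in edges) / 3.0,
            provenance=edges))
        triad_genes.update(tri)

    # greedy maximum-identity matching on the remaining links
    remaining = [(a, b, i) for (a, b), i in link_ident.items()
                 if a not in triad_genes and b not in triad_genes]
    remaining.sort(key=lambda e: (-e[2], e[0], e[1]))
    matched: set[str] = set()
    kept_pairs: list[tuple[str, str, float]] = []
    for a, b, ident in remaining:
        if a in matched or b in matched:
            continue
        matched.update((a, b))
        kept_pairs.append((a, b, ident))
    kept_pairs.sort()

    grouped = triad_genes | matched
    singletons = [g for g in inventory if g not in grouped]

    part = AllelePartition(triads=triads, pairs=kept_pairs,
                           singletons=singletons)
    part.validate(inventory)
    return part


def itertools_combinations(tri: Sequence[str]):
    return [(tri[0], tri[1]), (tri[0], tri[2]), (tri[1], tri[2])]


# ---------------------------------------------------------------------------
# Optional anchoring against a reference assembly
# ---------------------------------------------------------------------------

def anchor_to_reference(partition: AllelePartition,
                        ref_hits: Sequence[HitRecord],
                        ) -> AllelePartition:
    """Annotate each group with the reference gene that is the best hit of
    a majority of its members; ties or 1-1-1 splits leave it unanchored."""
    best_ref: dict[str, str] = {}
    best_seen: dict[str, HitRecord] = {}
    for h in ref_hits:
        cur = best_seen.get(h.query_id)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best_seen[h.query_id] = h
            best_ref[h.query_id] = h.subject_id

    anchors: dict[str, str] = {}
    for t in partition.triads:
        votes: dict[str, int] = {}
        for g in t.members():
            r = best_ref.get(g)
            if r is not None:
                votes[r] = votes.get(r, 0) + 1
        if votes:
            top = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
            if top[0][1] > len(t.members()) // 2:
                anchors[t.triad_id] = top[0][0]
    partition.anchors = anchors
    return partition
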
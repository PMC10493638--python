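"""Telomere tracts, centromeric tandem-array candidates, and NLR locus
status and clustering.

Telomeres are runs of the seven-base plant telomeric unit — CCCATTT read
inward from the 5' end, TTTAGGG ending at the 3' end — detected at unit
resolution: each 7-mer either matches the query unit exactly or counts as
a mismatched unit (any N makes a unit a mismatch). The centromere detector
is a simplified periodicity scanner that locates long high-copy tandem
arrays; it is not a general tandem-repeat finder, but finds the megabase-
scale satellite arrays that mark centromeres. NLR loci (intervals from an
upstream annotator) are labelled genic or intergenic by strand-blind
overlap with annotated gene spans and chained into clusters.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .io import GeneModel, GenomeSequences

TELOMERE_UNIT_5P = "CCCATTT"
TELOMERE_UNIT_3P = "TTTAGGG"


# ---------------------------------------------------------------------------
# Telomeres
# ---------------------------------------------------------------------------

@dataclass
class TelomereCall:
    chrom: str
    end: str                     # "5prime" | "3prime"
    start: int                   # 1-based closed tract interval
    stop: int
    length_bp: int
    copy_estimate: float
    purity: float


def _scan_units(seq: str, unit: str, max_offset: int, min_copies: int,
                min_purity: float) -> tuple[int, int, float] | None:
    """Find the best unit-run near the start of ``seq``.

    Anchors at the first exact unit within ``max_offset``, extends unit by
    unit allowing mismatched units while the running purity stays at or
    above ``min_purity``, then trims trailing mismatched units so the
    tract ends on a match. Returns (0-based start, n_units, purity).
    """
    u = len(unit)
    anchor = -1
    for off in range(0, min(max_offset, len(seq) - u) + 1):
        if seq[off:off + u] == unit:
            anchor = off
            break
    if anchor < 0:
        return None
    matches = 0
    total = 0
    best = (0, 0)  # (units incl. trailing trim, matches)
    pos = anchor
    while pos + u <= len(seq):
        total += 1
        if seq[pos:pos + u] == unit:
            matches += 1
            if matches / total >= min_purity:
                best = (total, matches)
        if matches / total < min_purity:
            break
        pos += u
    n_units, n_match = best
    # trim trailing mismatched units: best already recorded at a matching unit
    while n_units and seq[anchor + (n_units - 1) * u: anchor + n_units * u] != unit:
        n_units -= 1
    if n_units < min_copies:
        return None
    purity = n_match / n_units
    return anchor, n_units, purity


def find_telomeres(genome: GenomeSequences, max_offset: int = 10_000,
                   min_copies: int = 100, min_purity: float = 0.9,
                   ) -> list[TelomereCall]:
    """Detect telomeric tracts at both ends of every chromosome.

    Scans inward from each end up to ``max_offset`` bp for the anchoring
    unit, then reports the maximal run with purity >= ``min_purity`` and
    at least ``min_copies`` units.
    """
    calls: list[TelomereCall] = []
    u = 7
    for chrom, seq in genome:
        hit = _scan_units(seq, TELOMERE_UNIT_5P, max_offset, min_copies,
                          min_purity)
        if hit:
            start0, n_units, purity = hit
            calls.append(TelomereCall(
                chrom=chrom, end="5prime",
                start=start0 + 1, stop=start0 + n_units * u,
                length_bp=n_units * u, copy_estimate=float(n_units),
                purity=purity))
        rev = seq[::-1]
        hit = _scan_units(rev, TELOMERE_UNIT_3P[::-1], max_offset,
                          min_copies, min_purity)
        if hit:
            start0, n_units, purity = hit
            stop1 = len(seq) - start0
            calls.append(TelomereCall(
                chrom=chrom, end="3prime",
                start=stop1 - n_units * u + 1, stop=stop1,
                length_bp=n_units * u, copy_estimate=float(n_units),
                purity=purity))
    return calls


def classify_t2t(calls: list[TelomereCall], genome: GenomeSequences,
                 ) -> tuple[dict[str, str], int]:
    """Per-chromosome status ('T2T', 'one-ended', 'none') and the count of
    telomere-to-telomere chromosomes (both ends called)."""
    ends: dict[str, set[str]] = {}
    for c in calls:
        ends.setdefault(c.chrom, set()).add(c.end)
    status: dict[str, str] = {}
    for chrom, _seq in genome:
        got = ends.get(chrom, set())
        if got == {"5prime", "3prime"}:
            status[chrom] = "T2T"
        elif got:
            status[chrom] = "one-ended"
        else:
            status[chrom] = "none"
    return status, sum(1 for s in status.values() if s == "T2T")


# ---------------------------------------------------------------------------
# Tandem arrays (centromere candidates)
# ---------------------------------------------------------------------------

@dataclass
class TandemArrayCall:
    chrom: str
    start: int                  # 1-based closed
    stop: int
    unit_length: int
    unit_sequence: str
    copy_number: float
    array_score: float


def _self_match_segments(seq: str, u: int, min_len: int,
                         min_identity: float) -> list[tuple[int, int]]:
    """Maximal segments where seq[i] == seq[i+u] with density >= min_identity.

    Runs of lag-u self-matches are merged across short gaps as long as the
    merged density stays above the threshold.
    """
    n = len(seq)
    if n < 2 * u:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    match = (arr[:-u] == arr[u:]) & (arr[:-u] != ord("N"))
    # consecutive-match runs as [start, end) via edge detection
    edges = np.diff(match.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if match[0]:
        starts = np.concatenate(([0], starts))
    if match[-1]:
        ends = np.concatenate((ends, [match.size]))
    runs = list(zip(starts.tolist(), ends.tolist()))
    # ignore sub-unit runs: genuine tandem structure matches over >= u bases
    runs = [(s, e) for s, e in runs if e - s >= u]
    if not runs:
        return []
    merged: list[tuple[int, int, int]] = []  # (start, end, n_matches)
    cur_s, cur_e = runs[0]
    cur_m = cur_e - cur_s
    for s, e in runs[1:]:
        new_m = cur_m + (e - s)
        if new_m / (e - cur_s) >= min_identity:
            cur_e, cur_m = e, new_m
        else:
            merged.append((cur_s, cur_e, cur_m))
            cur_s, cur_e, cur_m = s, e, e - s
    merged.append((cur_s, cur_e, cur_m))
    # a lag-u match segment [s,e) implies a repeat region [s, e+u)
    return [(s, e + u) for s, e, _mm in merged if (e + u) - s >= min_len]


def _modal_unit(seq: str, start: int, end: int, u: int) -> tuple[str, float]:
    """Most common u-mer among the array's aligned frames and the per-base
    identity of the array to that unit tiled across it."""
    frames = [seq[i:i + u] for i in range(start, end - u + 1, u)]
    if not frames:
        return seq[start:start + u], 0.0
    modal = Counter(frames).most_common(1)[0][0]
    matches = 0
    total = 0
    for i in range(start, end, u):
        chunk = seq[i:min(i + u, end)]
        for a, b in zip(chunk, modal):
            total += 1
            if a == b:
                matches += 1
    return modal, matches / total if total else 0.0


def find_tandem_arrays(chrom: str, seq: str,
                       unit_length_range: tuple[int, int] = (100, 200),
                       min_array_bp: int = 10_000,
                       min_identity: float = 0.8,
                       ) -> list[TandemArrayCall]:
    """Detect tandem arrays by lag-u self-match periodicity.

    For each candidate unit length u in the range, maximal >=80%-periodic
    segments at least ``min_array_bp`` long are collected; candidates are
    validated against their modal unit and selected greedily longest-first
    without overlap.
    """
    lo, hi = unit_length_range
    if lo < 2 or hi > 2000:
        raise ValueError("unit_length_range must lie within [2, 2000]")
    candidates: list[TandemArrayCall] = []
    for u in range(lo, hi + 1):
        for s, e in _self_match_segments(seq, u, min_array_bp, min_identity):
            modal, ident = _modal_unit(seq, s, e, u)
            if ident < min_identity:
                continue
            candidates.append(TandemArrayCall(
                chrom=chrom, start=s + 1, stop=e,
                unit_length=u, unit_sequence=modal,
                copy_number=(e - s) / u,
                array_score=ident * (e - s)))
    candidates.sort(key=lambda c: (-(c.stop - c.start + 1), c.unit_length,
                                   c.start))
    chosen: list[TandemArrayCall] = []
    for c in candidates:
        if all(c.stop < k.start or c.start > k.stop for k in chosen):
            chosen.append(c)
    chosen.sort(key=lambda c: c.start)
    return chosen


def centromere_candidates(genome: GenomeSequences,
                          unit_length_range: tuple[int, int] = (100, 200),
                          min_array_bp: int = 10_000,
                          ) -> dict[str, TandemArrayCall | None]:
    """Longest tandem array per chromosome = the centromere candidate."""
    out: dict[str, TandemArrayCall | None] = {}
    for chrom, seq in genome:
        arrays = find_tandem_arrays(chrom, seq, unit_length_range,
                                    min_array_bp)
        out[chrom] = (max(arrays, key=lambda c: c.stop - c.start + 1)
                      if arrays else None)
    return out


# ---------------------------------------------------------------------------
# NLR loci
# ---------------------------------------------------------------------------

@dataclass
class NLRLocusStatus:
    locus_id: str
    chrom: str
    start: int                  # 1-based closed
    stop: int
    status: str                 # "genic" | "intergenic"
    overlapping_gene: str | None = None
    cluster_id: str | None = None


def nlr_status(loci: list[tuple[str, int, int, str]],
               genes: list[GeneModel],
               gene_allowlist: set[str] | None = None,
               ) -> list[NLRLocusStatus]:
    """Label each NLR locus genic or intergenic.

    A locus is genic iff it overlaps any annotated gene span by at least
    1 bp, strand-blind; the overlapping gene recorded is the one with the
    largest overlap (ties by lexicographic gene ID). With
    ``gene_allowlist`` only the listed gene IDs count as genes. A locus on
    a chromosome absent from the annotation is an error.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        if gene_allowlist is not None and g.gene_id not in gene_allowlist:
            continue
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.start, g.end + 1, g)
    known_chroms = {g.chrom for g in genes}
    out: list[NLRLocusStatus] = []
    for chrom, start, stop, name in loci:
        if chrom not in known_chroms:
            raise KeyError(f"NLR locus {name!r} on chromosome {chrom!r} "
                           "absent from the gene annotation")
        overlaps = trees.get(chrom, IntervalTree()).overlap(start, stop + 1)
        best_gene: str | None = None
        best_olap = 0
        for iv in overlaps:
            g: GeneModel = iv.data
            olap = min(stop, g.end) - max(start, g.start) + 1
            if olap > best_olap or (olap == best_olap and best_gene is not None
                                    and g.gene_id < best_gene):
                best_gene, best_olap = g.gene_id, olap
        out.append(NLRLocusStatus(
            locus_id=name, chrom=chrom, start=start, stop=stop,
            status="genic" if best_gene else "intergenic",
            overlapping_gene=best_gene))
    return out


@dataclass
class NLRClusterSummary:
    cluster_id: str
    chrom: str
    start: int
    stop: int
    n_loci: int
    n_genic: int

    @property
    def ratio(self) -> str:
        return f"{self.n_genic}/{self.n_loci}"

    @property
    def location_mb(self) -> str:
        return f"{self.start / 1e6:.2f}-{self.stop / 1e6:.2f}"


def cluster_nlr(loci: list[NLRLocusStatus], max_gap: int = 200_000,
                min_loci: int = 5) -> list[NLRClusterSummary]:
    """Single-linkage chaining of NLR loci along each chromosome.

    Consecutive loci join a cluster when the gap between them is at most
    ``max_gap`` bp; clusters with at least ``min_loci`` members are
    reported with their genic/total ratio. Output is independent of input
    order and member cluster_ids are filled in on the input loci.
    """
    by_chrom: dict[str, list[NLRLocusStatus]] = {}
    for l in loci:
        by_chrom.setdefault(l.chrom, []).append(l)
    summaries: list[NLRClusterSummary] = []
    k = 0
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda l: (l.start, l.stop))
        chain: list[NLRLocusStatus] = []
        for l in members + [None]:  # type: ignore[list-item]
            if chain and (l is None or l.start - chain[-1].stop > max_gap):
                if len(chain) >= min_loci:
                    k += 1
                    cid = f"C{k:03d}"
                    for m in chain:
                        m.cluster_id = cid
                    summaries.append(NLRClusterSummary(
                        cluster_id=cid, chrom=chrom,
                        start=min(m.start for m in chain),
                        stop=max(m.stop for m in chain),
                        n_loci=len(chain),
                        n_genic=sum(m.status == "genic" for m in chain)))
                chain = []
            if l is not None:
                chain.append(l)
    return summaries
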
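"""Synthetic triploid genome, annotation and expression generator.

Emulates the data shape of a phased triploid (AAA) banana-like genome:
three haploid chromosome sets carrying homoeologous gene triads, pairs and
singletons; telomeric unit tracts at chromosome ends; a centromeric tandem
array per chromosome; NLR loci in genic and intergenic space; coding
divergence between homoeologs with controlled Ka/Ks; and per-tissue read
counts whose triad-level relative expression follows planted bias
categories. Everything is deterministic given the seed, and a TruthTable
records every planted fact so downstream stages can be scored against
ground truth.

Divergence is simulated at the CDS level only; intergenic sequence is
i.i.d. uniform DNA, which is all the downstream stages (gene, hit and
feature logic) consume. Similarity-hit identities are the exact protein
identities of the simulated sequences, so pairing thresholds act on exact
values rather than on an alignment heuristic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio.Seq import Seq

from . import kaks as _kaks
from .expression import CENTROIDS, GROUPS
from .io import (CountsTable, GeneModel, GenomeSequences, HitRecord,
                 write_counts, write_fasta, write_gff3, write_hits)

HAPLOTYPES = ("H1", "H2", "H3")
TELOMERE_UNIT_5P = "CCCATTT"
TELOMERE_UNIT_3P = "TTTAGGG"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class PackingError(ValueError):
    """Planted features do not fit on the configured chromosomes."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ExpressionConfig:
    tissues: tuple[str, ...] = ("root", "leaf", "flower", "fruit")
    # seven-category proportions, order as GROUPS: matches the observed
    # structure of triad bias in triploid banana (~52% balanced, ~4% per
    # dominant class, ~12% per suppressed class)
    proportions: tuple[float, ...] = (0.52, 0.04, 0.04, 0.04, 0.12, 0.12, 0.12)
    concentration: float = 100.0
    library_size: int = 5_000_000
    noise: str = "poisson"            # "poisson" | "negative_binomial"
    overdispersion: float = 0.1       # NB only: var = mu + overdispersion*mu^2
    abundance_sigma: float = 1.0      # log-normal spread of triad abundance


@dataclass
class CodingConfig:
    length_codons: int = 300
    ka_range: tuple[float, float] = (0.01, 0.05)
    ks_range: tuple[float, float] = (0.05, 0.20)


@dataclass
class NLRConfig:
    n_genic: int = 6
    n_intergenic: int = 9
    cluster_gap: int = 50_000


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes_per_haplotype: int = 3
    chrom_length: int = 400_000
    n_triads: int = 60
    n_pairs: int = 6
    n_singletons: int = 9
    telomere_copies: tuple[int, int] = (100, 500)   # per-end uniform range
    centromere_unit_length: tuple[int, int] = (100, 200)
    centromere_array_length: tuple[int, int] = (10_000, 20_000)
    nlr: NLRConfig = field(default_factory=NLRConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    coding: CodingConfig = field(default_factory=CodingConfig)

    def __post_init__(self) -> None:
        p = self.expression.proportions
        if abs(sum(p) - 1.0) > 1e-9 or len(p) != 7:
            raise ValueError("expression.proportions must be 7 values "
                             "summing to 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        for key, sub in (("nlr", NLRConfig), ("expression", ExpressionConfig),
                         ("coding", CodingConfig)):
            if key in raw and isinstance(raw[key], dict):
                d = raw[key]
                for f in dataclasses.fields(sub):
                    if f.name in d and isinstance(d[f.name], list):
                        d[f.name] = tuple(d[f.name])
                raw[key] = sub(**d)
        for f in dataclasses.fields(cls):
            if f.name in raw and isinstance(raw[f.name], list):
                raw[f.name] = tuple(raw[f.name])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Truth table
# ---------------------------------------------------------------------------

@dataclass
class TriadTruth:
    triad_id: str
    genes: dict[str, str]
    chrom_index: int
    category: str
    relative: dict[str, list[float]] = field(default_factory=dict)  # tissue -> e
    kaks: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class TruthTable:
    triads: list[TriadTruth] = field(default_factory=list)
    pairs: list[tuple[str, str]] = field(default_factory=list)
    singletons: list[str] = field(default_factory=list)
    telomeres: dict[str, dict[str, int]] = field(default_factory=dict)
    centromeres: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    nlr: list[dict] = field(default_factory=list)
    gene_models: dict[str, GeneModel] = field(default_factory=dict)
    cds: dict[str, str] = field(default_factory=dict)
    proteins: dict[str, str] = field(default_factory=dict)

    def category_counts(self) -> dict[str, int]:
        out = {g: 0 for g in GROUPS}
        for t in self.triads:
            out[t.category] += 1
        return out

    def to_json(self, path: str | Path) -> None:
        doc = {
            "triads": [{**dataclasses.asdict(t)} for t in self.triads],
            "pairs": self.pairs,
            "singletons": self.singletons,
            "telomeres": self.telomeres,
            "centromeres": self.centromeres,
            "nlr": self.nlr,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, default=list)


# ---------------------------------------------------------------------------
# CDS evolution with controlled NG86 divergence
# ---------------------------------------------------------------------------

def random_cds(length_codons: int, rng: np.random.Generator) -> str:
    codons = rng.choice(len(_kaks.SENSE_CODONS), size=length_codons)
    return "".join(_kaks.SENSE_CODONS[i] for i in codons)


def _mutations_of(codon: str, synonymous: bool) -> list[str]:
    """Single-nucleotide, non-stop variants of ``codon`` of the given type."""
    aa = _kaks.CODON_TABLE[codon]
    out = []
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            m = codon[:pos] + b + codon[pos + 1:]
            if m in _kaks.STOP_CODONS:
                continue
            if (_kaks.CODON_TABLE[m] == aa) == synonymous:
                out.append(m)
    return out


class DivergenceError(ValueError):
    """Target Ka/Ks unreachable; carries the realized values."""

    def __init__(self, msg: str, realized_ka: float, realized_ks: float):
        super().__init__(msg)
        self.realized_ka = realized_ka
        self.realized_ks = realized_ks


def evolve_cds_pair(length_codons: int, target_ka: float, target_ks: float,
                    seed: int, tolerance: float = 0.10,
                    max_moves: int | None = None,
                    ancestor: str | None = None) -> tuple[str, str, dict]:
    """Generate a CDS pair whose realized NG86 Ka and Ks are within
    ``tolerance`` (relative) of the targets.

    Starting from a random (or supplied) ancestral CDS, synonymous and
    nonsynonymous single-nucleotide substitutions — rejecting stop codons,
    at most one substitution per codon — are introduced into a copy until
    the realized, Jukes-Cantor-corrected rates reach their targets. A
    target of 0 means no substitutions of that type (exactly 0 realized).
    Raises :class:`DivergenceError` if the move budget is exhausted.
    """
    rng = np.random.default_rng(seed)
    a = ancestor if ancestor is not None else random_cds(length_codons, rng)
    codons = [a[i:i + 3] for i in range(0, len(a), 3)]
    b = list(codons)
    untouched = list(range(len(b)))
    if max_moves is None:
        max_moves = 20 * length_codons

    def realized() -> tuple[float, float]:
        res = _kaks.compute_kaks(a, "".join(b))
        return (res.Ka if res.Ka is not None else float("inf"),
                res.Ks if res.Ks is not None else float("inf"))

    moves = 0
    ka, ks = realized()
    # done flags: a rate stops moving once it has reached the closest
    # achievable value to its target (substitutions are discrete, so the
    # last move is reverted if it would overshoot further than the
    # remaining undershoot)
    done_ka = target_ka == 0
    done_ks = target_ks == 0
    while True:
        need_ka = not done_ka and ka < target_ka
        need_ks = not done_ks and ks < target_ks
        done_ka = done_ka or not need_ka
        done_ks = done_ks or not need_ks
        if done_ka and done_ks:
            break
        if moves >= max_moves or not untouched:
            raise DivergenceError(
                f"targets (Ka={target_ka}, Ks={target_ks}) unreachable: "
                f"realized Ka={ka:.4f}, Ks={ks:.4f}", ka, ks)
        synonymous = need_ks and (
            not need_ka
            or (target_ks - ks) / target_ks >= (target_ka - ka) / target_ka)
        idx_pos = int(rng.integers(len(untouched)))
        i = untouched[idx_pos]
        options = _mutations_of(b[i], synonymous)
        if options:
            old = b[i]
            b[i] = options[int(rng.integers(len(options)))]
            new_ka, new_ks = realized()
            val, new_val, target = ((ks, new_ks, target_ks) if synonymous
                                    else (ka, new_ka, target_ka))
            if new_val > target and new_val - target > target - val:
                # overshoot worse than the undershoot: revert, freeze rate
                b[i] = old
                if synonymous:
                    done_ks = True
                else:
                    done_ka = True
            else:
                untouched.pop(idx_pos)
                ka, ks = new_ka, new_ks
        else:
            # codon admits no move of this type (e.g. TGG has no synonymous
            # variant); rotate it out and try another
            untouched.pop(idx_pos)
        moves += 1
    for val, target, label in ((ka, target_ka, "Ka"), (ks, target_ks, "Ks")):
        if target == 0:
            if val != 0:
                raise DivergenceError(f"{label} should be 0", ka, ks)
        elif abs(val - target) > tolerance * target:
            raise DivergenceError(
                f"realized {label}={val:.4f} outside +/-{tolerance:.0%} of "
                f"{target}", ka, ks)
    seq_b = "".join(b)
    res = _kaks.compute_kaks(a, seq_b)
    return a, seq_b, res.as_dict()


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

def _protein(cds: str) -> str:
    return str(Seq(cds).translate())


def _identity(p1: str, p2: str) -> float:
    same = sum(a == b for a, b in zip(p1, p2))
    return 100.0 * same / max(len(p1), len(p2))


def _hit_rows(a: str, b: str, proteins: dict[str, str]) -> list[HitRecord]:
    pa, pb = proteins[a], proteins[b]
    ident = _identity(pa, pb)
    n = len(pa)
    mism = n - sum(x == y for x, y in zip(pa, pb))
    rows = []
    for q, s in ((a, b), (b, a)):
        rows.append(HitRecord(
            query_id=q, subject_id=s, percent_identity=round(ident, 3),
            alignment_length=n, mismatches=mism, gap_openings=0,
            q_start=1, q_end=n, s_start=1, s_end=n,
            e_value=1e-180, bit_score=float(2 * n)))
    return rows


def simulate_triploid(config: SimulationConfig
                      ) -> tuple[dict[str, GenomeSequences],
                                 dict[str, list[GeneModel]],
                                 list[HitRecord], TruthTable]:
    """Build the three haploid genomes with all planted features.

    Returns per-haplotype genome sequences and gene models, the pairwise
    similarity-hit table (closing one triangle per triad), and the truth
    table. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    truth = TruthTable(nlr=[])
    n_chrom = config.n_chromosomes_per_haplotype
    L = config.chrom_length

    # ---- coding sequences --------------------------------------------------
    gene_counter = {h: 0 for h in HAPLOTYPES}

    def new_gene_id(hap: str) -> str:
        gene_counter[hap] += 1
        return f"{hap}_g{gene_counter[hap]:04d}"

    cc = config.coding
    groups: list[tuple[str, dict[str, str], int]] = []  # (kind, hap->gene, chrom)

    for i in range(config.n_triads):
        tka = float(rng.uniform(*cc.ka_range))
        tks = float(rng.uniform(*cc.ks_range))
        seed_a, seed_b = (int(s) for s in rng.integers(2 ** 31, size=2))
        anc, s2, _ = evolve_cds_pair(cc.length_codons, tka, tks, seed_a)
        _, s3, _ = evolve_cds_pair(cc.length_codons, tka, tks, seed_b,
                                   ancestor=anc)
        genes = {}
        for hap, seq in zip(HAPLOTYPES, (anc, s2, s3)):
            gid = new_gene_id(hap)
            genes[hap] = gid
            truth.cds[gid] = seq
            truth.proteins[gid] = _protein(seq)
        tt = TriadTruth(triad_id=f"T{i + 1:05d}", genes=genes,
                        chrom_index=i % n_chrom, category="")
        for ga, gb in ((genes["H1"], genes["H2"]), (genes["H1"], genes["H3"]),
                       (genes["H2"], genes["H3"])):
            res = _kaks.compute_kaks(truth.cds[ga], truth.cds[gb])
            tt.kaks[f"{ga}|{gb}"] = (res.Ka or 0.0, res.Ks or 0.0)
        truth.triads.append(tt)
        groups.append(("triad", genes, i % n_chrom))

    for j in range(config.n_pairs):
        hap_pair = (HAPLOTYPES[j % 3], HAPLOTYPES[(j + 1) % 3])
        tka = float(rng.uniform(*cc.ka_range))
        tks = float(rng.uniform(*cc.ks_range))
        sa, sb, _ = evolve_cds_pair(cc.length_codons, tka, tks,
                                    int(rng.integers(2 ** 31)))
        genes = {}
        for hap, seq in zip(hap_pair, (sa, sb)):
            gid = new_gene_id(hap)
            genes[hap] = gid
            truth.cds[gid] = seq
            truth.proteins[gid] = _protein(seq)
        truth.pairs.append(tuple(genes[h] for h in hap_pair))
        groups.append(("pair", genes, (config.n_triads + j) % n_chrom))

    for k in range(config.n_singletons):
        hap = HAPLOTYPES[k % 3]
        seq = random_cds(cc.length_codons, rng)
        gid = new_gene_id(hap)
        truth.cds[gid] = seq
        truth.proteins[gid] = _protein(seq)
        truth.singletons.append(gid)
        groups.append(("singleton", {hap: gid},
                       (config.n_triads + config.n_pairs + k) % n_chrom))

    # ---- chromosome layout -------------------------------------------------
    cds_len = 3 * cc.length_codons
    genomes: dict[str, GenomeSequences] = {}
    models: dict[str, list[GeneModel]] = {h: [] for h in HAPLOTYPES}

    # genes per (haplotype, chromosome)
    chrom_genes: dict[tuple[str, int], list[str]] = {}
    for _kind, genes, ci in groups:
        for hap, gid in genes.items():
            chrom_genes.setdefault((hap, ci), []).append(gid)

    for hap in HAPLOTYPES:
        records = []
        for ci in range(n_chrom):
            chrom = f"{hap}_chr{ci + 1:02d}"
            seq = rng.integers(0, 4, size=L, dtype=np.uint8)
            seq = _BASES[seq]

            tel5 = int(rng.integers(config.telomere_copies[0],
                                    config.telomere_copies[1] + 1))
            tel3 = int(rng.integers(config.telomere_copies[0],
                                    config.telomere_copies[1] + 1))
            unit_len = int(rng.integers(config.centromere_unit_length[0],
                                        config.centromere_unit_length[1] + 1))
            array_len = int(rng.integers(config.centromere_array_length[0],
                                         config.centromere_array_length[1] + 1))
            array_len -= array_len % unit_len

            tel5_bp, tel3_bp = tel5 * 7, tel3 * 7
            genes_here = chrom_genes.get((hap, ci), [])
            pad = 1000  # buffer separating feature classes
            needed = (tel5_bp + tel3_bp + array_len + 4 * pad
                      + len(genes_here) * (cds_len + pad))
            if needed > L:
                raise PackingError(
                    f"{chrom}: features need {needed} bp > chromosome "
                    f"length {L} (genes={len(genes_here)}, "
                    f"telomeres={tel5_bp + tel3_bp}, array={array_len})")

            arr = bytearray(seq.tobytes())
            arr[0:tel5_bp] = (TELOMERE_UNIT_5P * tel5).encode()
            arr[L - tel3_bp:L] = (TELOMERE_UNIT_3P * tel3).encode()
            truth.telomeres.setdefault(chrom, {})["5prime"] = tel5
            truth.telomeres[chrom]["3prime"] = tel3

            cen_start0 = L // 2 - array_len // 2
            unit = _BASES[rng.integers(0, 4, size=unit_len, dtype=np.uint8)]
            copies = array_len // unit_len
            arr[cen_start0:cen_start0 + array_len] = unit.tobytes() * copies
            truth.centromeres[chrom] = (cen_start0 + 1,
                                        cen_start0 + array_len, unit_len)

            # genes split across the two arms, evenly spaced
            arm1 = (tel5_bp + pad, cen_start0 - pad)
            arm2 = (cen_start0 + array_len + pad, L - tel3_bp - pad)
            half = (len(genes_here) + 1) // 2
            for arm, gene_ids in (((arm1), genes_here[:half]),
                                  ((arm2), genes_here[half:])):
                if not gene_ids:
                    continue
                lo, hi = arm
                slot = (hi - lo) // len(gene_ids)
                if slot < cds_len + pad:
                    raise PackingError(
                        f"{chrom}: arm [{lo},{hi}] too small for "
                        f"{len(gene_ids)} genes")
                for gi, gid in enumerate(gene_ids):
                    start0 = lo + gi * slot
                    cds = truth.cds[gid]
                    arr[start0:start0 + cds_len] = cds.encode()
                    model = GeneModel(
                        gene_id=gid, chrom=chrom, strand="+",
                        start=start0 + 1, end=start0 + cds_len,
                        cds_segments=[(start0 + 1, start0 + cds_len)],
                        protein_id=gid + ".p1")
                    models[hap].append(model)
                    truth.gene_models[gid] = model
            records.append((chrom, arr.decode("ascii")))
        genomes[hap] = GenomeSequences(records=records, haplotype_label=hap)

    # ---- NLR loci ----------------------------------------------------------
    nc = config.nlr
    for hap in HAPLOTYPES:
        chrom = f"{hap}_chr01"
        here = sorted((m for m in models[hap] if m.chrom == chrom),
                      key=lambda m: m.start)
        if len(here) < max(nc.n_genic, nc.n_intergenic + 1):
            raise PackingError(
                f"{chrom}: {len(here)} genes cannot host {nc.n_genic} genic "
                f"and {nc.n_intergenic} intergenic NLR loci")
        n_loc = 0
        for m in here[:nc.n_genic]:
            n_loc += 1
            truth.nlr.append({
                "locus_id": f"{hap}_NLR{n_loc:03d}", "chrom": chrom,
                "start": m.start + 10, "stop": min(m.start + 400, m.end),
                "status": "genic", "gene": m.gene_id})
        spans = [(m.start, m.end) for m in here]
        gaps = [(a_end + 1, b_start - 1)
                for (_, a_end), (b_start, _) in zip(spans, spans[1:])
                if b_start - a_end > 1000]
        if len(gaps) < nc.n_intergenic:
            raise PackingError(f"{chrom}: only {len(gaps)} intergenic gaps "
                               f"for {nc.n_intergenic} NLR loci")
        for gs, ge in gaps[:nc.n_intergenic]:
            n_loc += 1
            mid = (gs + ge) // 2
            truth.nlr.append({
                "locus_id": f"{hap}_NLR{n_loc:03d}", "chrom": chrom,
                "start": mid - 100, "stop": mid + 100,
                "status": "intergenic", "gene": None})

    # ---- hits table --------------------------------------------------------
    hits: list[HitRecord] = []
    for tt in truth.triads:
        g = tt.genes
        for a, b in ((g["H1"], g["H2"]), (g["H1"], g["H3"]),
                     (g["H2"], g["H3"])):
            hits.extend(_hit_rows(a, b, truth.proteins))
    for a, b in truth.pairs:
        hits.extend(_hit_rows(a, b, truth.proteins))

    return genomes, models, hits, truth


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def _soft_centroid(category: str, delta: float = 0.05) -> np.ndarray:
    """Centroid pulled slightly inside the simplex so Dirichlet
    concentrations are positive on every axis; the nearest centroid (hence
    the planted class) is unchanged."""
    c = CENTROIDS[category]
    return (1.0 - delta) * c + delta * np.full(3, 1 / 3)


def simulate_expression(truth: TruthTable, config: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        ) -> CountsTable:
    """Draw per-tissue gene-level counts realising the planted categories.

    Per triad and tissue the relative-expression vector is Dirichlet
    around the (softened) category centroid with the configured
    concentration; triad total abundance is log-normal; expected counts
    scale with abundance x relative share x gene length, normalised to the
    library size; counting noise is Poisson or negative binomial. Non-triad
    genes receive independent log-normal abundances. One sample per tissue.
    """
    ec = config.expression
    if ec.library_size <= 0:
        raise ValueError("library size must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)

    # plant categories once (idempotent across calls with the same truth)
    if any(not t.category for t in truth.triads):
        cats = rng.choice(len(GROUPS), size=len(truth.triads),
                          p=ec.proportions)
        for t, ci in zip(truth.triads, cats):
            t.category = GROUPS[ci]

    all_genes = sorted(truth.cds)
    lengths = {g: len(truth.cds[g]) for g in all_genes}
    triad_genes = {g for t in truth.triads for g in t.genes.values()}
    other_genes = [g for g in all_genes if g not in triad_genes]

    counts = np.zeros((len(all_genes), len(ec.tissues)), dtype=np.int64)
    gene_idx = {g: i for i, g in enumerate(all_genes)}

    for tj, tissue in enumerate(ec.tissues):
        weights = np.zeros(len(all_genes))
        for t in truth.triads:
            if np.isinf(ec.concentration):
                rel = CENTROIDS[t.category].copy()
            else:
                alpha = ec.concentration * _soft_centroid(t.category)
                rel = rng.dirichlet(alpha)
            t.relative[tissue] = [float(x) for x in rel]
            abundance = float(rng.lognormal(mean=np.log(20.0),
                                            sigma=ec.abundance_sigma))
            for hap, share in zip(HAPLOTYPES, rel):
                g = t.genes[hap]
                weights[gene_idx[g]] = abundance * share * lengths[g]
        for g in other_genes:
            abundance = float(rng.lognormal(mean=np.log(20.0),
                                            sigma=ec.abundance_sigma))
            weights[gene_idx[g]] = abundance * lengths[g]
        expected = weights / weights.sum() * ec.library_size
        if ec.noise == "poisson":
            counts[:, tj] = rng.poisson(expected)
        elif ec.noise == "negative_binomial":
            phi = ec.overdispersion
            r = 1.0 / phi
            p = r / (r + expected)
            counts[:, tj] = rng.negative_binomial(r, p)
        else:
            raise ValueError(f"unknown noise model {ec.noise!r}")

    import pandas as pd
    df = pd.DataFrame(counts, index=all_genes, columns=list(ec.tissues))
    lser = pd.Series({g: lengths[g] for g in all_genes}, name="length")
    return CountsTable(counts=df, lengths=lser,
                       tissues={t: t for t in ec.tissues})


# ---------------------------------------------------------------------------
# End-to-end artifact writer
# ---------------------------------------------------------------------------

def write_simulation(out_dir: str | Path, config: SimulationConfig,
                     ) -> TruthTable:
    """Run the full simulation and write every artifact through the
    package's standard formats, plus a JSON manifest with seed/version."""
    from . import __version__
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes, models, hits, truth = simulate_triploid(config)
    counts = simulate_expression(truth, config)

    for hap in HAPLOTYPES:
        write_fasta(genomes[hap], out / f"{hap}.genome.fasta")
        write_gff3(models[hap], out / f"{hap}.genes.gff3")
        write_fasta([(g.gene_id, truth.cds[g.gene_id]) for g in models[hap]],
                    out / f"{hap}.cds.fasta")
        write_fasta([(g.gene_id, truth.proteins[g.gene_id])
                     for g in models[hap]],
                    out / f"{hap}.proteins.fasta")
    write_hits(hits, out / "hits.tsv")
    write_counts(counts, out / "counts.tsv")
    with open(out / "nlr_loci.bed", "w") as fh:
        for rec in truth.nlr:
            fh.write(f"{rec['chrom']}\t{rec['start'] - 1}\t{rec['stop']}\t"
                     f"{rec['locus_id']}\n")
    truth.to_json(out / "truth.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump({"command": "simulate", "seed": config.seed,
                   "version": __version__,
                   "config": config.to_dict()}, fh, indent=1)
    return truth
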
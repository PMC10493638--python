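"""TPM, the expression filter, per-triad standardisation and the
seven-group homoeolog-expression-bias classification.

For a triad with per-haplotype TPM (t1, t2, t3) the relative (ternary)
expression is e_i = t_i / (t1 + t2 + t3). On the simplex, each expressed
triad is assigned to the nearest of seven centroids:

* balanced        (1/3, 1/3, 1/3)
* Hk-dominant     1 on axis k, 0 elsewhere
* Hk-suppressed   0 on axis k, 1/2 on the other two

Nearest-centroid assignment uses Euclidean distance in the plane of the
simplex; no distance cutoff is applied, so every expressed triad receives
exactly one of the seven labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountsTable, GeneModel
from .triads import AllelePartition, Triad

logger = logging.getLogger("triadkit")

GROUPS: tuple[str, ...] = ("balanced", "H1D", "H2D", "H3D", "H1S", "H2S", "H3S")

CENTROIDS: dict[str, np.ndarray] = {
    "balanced": np.array([1 / 3, 1 / 3, 1 / 3]),
    "H1D": np.array([1.0, 0.0, 0.0]),
    "H2D": np.array([0.0, 1.0, 0.0]),
    "H3D": np.array([0.0, 0.0, 1.0]),
    "H1S": np.array([0.0, 0.5, 0.5]),
    "H2S": np.array([0.5, 0.0, 0.5]),
    "H3S": np.array([0.5, 0.5, 0.0]),
}

EXPRESSION_TPM_THRESHOLD = 0.5  # strict: a homoeolog is expressed iff TPM > 0.5


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

def compute_tpm(counts: CountsTable) -> pd.DataFrame:
    """Transcripts per million: TPM_g = (c_g/L_g) / sum_h(c_h/L_h) * 1e6.

    Columns sum to 1e6 except for all-zero samples, which stay all-zero
    with a logged warning.
    """
    rate = counts.counts.div(counts.lengths, axis=0)
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        logger.warning("all-zero samples: %s", list(colsum.index[zero]))
        colsum = colsum.replace(0, np.nan)
    tpm = rate.div(colsum, axis=1) * 1e6
    return tpm.fillna(0.0)


def tpm_by_tissue(tpm: pd.DataFrame, tissues: dict[str, str]) -> pd.DataFrame:
    """Average replicate samples of the same tissue into one column each."""
    cols: dict[str, list[str]] = {}
    for sample, tissue in tissues.items():
        cols.setdefault(tissue, []).append(sample)
    out = {t: tpm[samples].mean(axis=1) for t, samples in cols.items()}
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Expression filter and standardisation
# ---------------------------------------------------------------------------

def filter_expressed(partition: AllelePartition, tissue_tpm: pd.DataFrame,
                     per_homoeolog: bool = False,
                     ) -> tuple[list[Triad], pd.DataFrame]:
    """Keep triads with expression above the TPM threshold.

    Default rule (triad level): the triad is retained iff at least one of
    its three homoeologs has TPM strictly above 0.5 in at least one tissue,
    so whole triads are kept or dropped together. With
    ``per_homoeolog=True`` the same strict rule is instead required of
    *every* homoeolog. Returns the retained triads plus per-triad flags.
    """
    rows = []
    kept: list[Triad] = []
    thr = EXPRESSION_TPM_THRESHOLD
    for t in partition.triads:
        genes = t.members()
        missing = [g for g in genes if g not in tissue_tpm.index]
        if missing:
            raise KeyError(f"triad {t.triad_id}: genes absent from TPM "
                           f"matrix: {missing}")
        sub = tissue_tpm.loc[genes]
        per_gene = (sub > thr).any(axis=1)
        ok = bool(per_gene.all()) if per_homoeolog else bool(per_gene.any())
        rows.append({"triad_id": t.triad_id, "expressed": ok,
                     "n_expressed_homoeologs": int(per_gene.sum())})
        if ok:
            kept.append(t)
    flags = pd.DataFrame(rows)
    return kept, flags


def standardize_triad(tpm_vector) -> np.ndarray | None:
    """Relative (ternary) expression e_i = t_i / sum(t); None if sum is 0."""
    v = np.asarray(tpm_vector, dtype=float)
    total = v.sum()
    if total == 0.0:
        return None
    return v / total


def combine_tissues(per_tissue_tpm) -> np.ndarray | None:
    """Combined-analysis vector: mean TPM per homoeolog across tissues,
    then standardised. ``per_tissue_tpm`` is an (n_tissues, 3) array."""
    m = np.asarray(per_tissue_tpm, dtype=float)
    return standardize_triad(m.mean(axis=0))


# ---------------------------------------------------------------------------
# Seven-group classification
# ---------------------------------------------------------------------------

@dataclass
class BiasAssignment:
    triad_id: str
    tissue: str
    group: str
    distances: dict[str, float]
    margin: float
    relative: tuple[float, float, float]


def classify_bias(relative, triad_id: str = "", tissue: str = "",
                  ) -> BiasAssignment:
    """Assign a defined ternary vector to the nearest of the seven
    centroids (Euclidean distance); ties resolved by the fixed group order
    balanced, H1D, H2D, H3D, H1S, H2S, H3S."""
    if relative is None:
        raise ValueError("undefined relative vector: apply the expression "
                         "filter before classification")
    v = np.asarray(relative, dtype=float)
    if v.shape != (3,):
        raise ValueError("relative vector must have 3 components")
    if not np.isclose(v.sum(), 1.0, atol=1e-6):
        raise ValueError(f"relative vector sums to {v.sum()}, not 1")
    distances = {g: float(np.linalg.norm(v - CENTROIDS[g])) for g in GROUPS}
    ordered = sorted(GROUPS, key=lambda g: (distances[g], GROUPS.index(g)))
    winner = ordered[0]
    margin = distances[ordered[1]] - distances[winner]
    return BiasAssignment(triad_id=triad_id, tissue=tissue, group=winner,
                          distances=distances, margin=margin,
                          relative=tuple(float(x) for x in v))


def classify_triads(triads: list[Triad], tissue_tpm_per_gene: pd.DataFrame,
                    ) -> pd.DataFrame:
    """Per-tissue and combined bias assignments for a set of triads.

    ``tissue_tpm_per_gene`` is a genes x tissues TPM frame. A triad/tissue
    whose TPM sums to zero yields a row flagged undefined rather than an
    assignment. Returns a tidy frame with one row per triad per tissue plus
    one 'combined' row per triad.
    """
    tissues = list(tissue_tpm_per_gene.columns)
    rows = []
    for t in triads:
        genes = [t.genes[h] for h in sorted(t.genes)]
        mat = tissue_tpm_per_gene.loc[genes, tissues].to_numpy(float).T
        for label, vec in list(zip(tissues, mat)) + [
                ("combined", mat.mean(axis=0))]:
            rel = standardize_triad(vec)
            if rel is None:
                rows.append({"triad_id": t.triad_id, "tissue": label,
                             "group": "undefined", "margin": np.nan,
                             "e_H1": np.nan, "e_H2": np.nan, "e_H3": np.nan,
                             "tpm_H1": vec[0], "tpm_H2": vec[1],
                             "tpm_H3": vec[2]})
                continue
            a = classify_bias(rel, triad_id=t.triad_id, tissue=label)
            rows.append({"triad_id": t.triad_id, "tissue": label,
                         "group": a.group, "margin": a.margin,
                         "e_H1": rel[0], "e_H2": rel[1], "e_H3": rel[2],
                         "tpm_H1": vec[0], "tpm_H2": vec[1], "tpm_H3": vec[2]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Summaries and chromosomal density
# ---------------------------------------------------------------------------

def summarize_groups(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue (and combined) counts and percentages of the seven
    groups; percentages rounded to 2 decimals over expressed triads."""
    rows = []
    for tissue, sub in assignments.groupby("tissue", sort=False):
        defined = sub[sub["group"] != "undefined"]
        n = len(defined)
        if n == 0:
            logger.warning("tissue %s has no defined assignments", tissue)
        counts = defined["group"].value_counts()
        row: dict = {"tissue": tissue, "n_expressed_triads": n}
        for g in GROUPS:
            c = int(counts.get(g, 0))
            row[f"n_{g}"] = c
            row[f"pct_{g}"] = round(100.0 * c / n, 2) if n else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def biased_gene_density(assignments: pd.DataFrame,
                        triads: list[Triad],
                        gene_models: dict[str, GeneModel],
                        window: int = 100_000,
                        tissue: str = "combined") -> pd.DataFrame:
    """Per-window counts of genes from non-balanced triads.

    Fixed windows [1,w], [w+1,2w], ... on each chromosome; a gene falls in
    the window containing its span midpoint. Output is BEDGRAPH-style:
    chrom, 0-based window start, end, count.
    """
    by_id = {t.triad_id: t for t in triads}
    counts: dict[tuple[str, int], int] = {}
    sub = assignments[(assignments["tissue"] == tissue)
                      & (~assignments["group"].isin(["balanced", "undefined"]))]
    for triad_id in sub["triad_id"]:
        for g in by_id[triad_id].members():
            model = gene_models.get(g)
            if model is None:
                raise KeyError(f"no gene model for {g!r}")
            widx = (model.midpoint - 1) // window
            counts[(model.chrom, widx)] = counts.get((model.chrom, widx), 0) + 1
    rows = [{"chrom": c, "start": w * window, "end": (w + 1) * window,
             "count": n}
            for (c, w), n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
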
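"""Nei-Gojobori (1986) Ka/Ks for codon-aligned homoeolog pairs.

The NG86 counting method estimates the numbers of synonymous (S) and
nonsynonymous (N) *sites* in each sequence from the genetic code, counts
observed synonymous (Sd) and nonsynonymous (Nd) *differences* by averaging
over all shortest mutational pathways between each codon pair, and corrects
the proportions pN = Nd/N and pS = Sd/S for multiple hits with the
Jukes-Cantor formula K = -(3/4) ln(1 - (4/3) p). A ratio Ka/Ks below 1
indicates purifying selection on the pair.

Conventions (NG86 implementations differ on these):

* a single-nucleotide change that creates a stop codon counts as
  nonsynonymous when tallying sites;
* mutational pathways that pass through a stop codon are excluded from the
  pathway average; if every pathway does, all steps count as nonsynonymous;
* N and S are averaged over the two sequences of the pair;
* codon columns containing a gap or an ambiguous base are dropped pairwise.

Per-codon site counts and per-codon-pair difference counts are memoised in
module-level tables built once from the standard genetic code.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from Bio.Data.CodonTable import standard_dna_table

_BASES = "ACGT"
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(t) for t in itertools.product(_BASES, repeat=3))
    if c not in STOP_CODONS
)


class SaturationError(ValueError):
    """Raised when p >= 3/4 makes the Jukes-Cantor correction undefined."""


# ---------------------------------------------------------------------------
# Site counting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Expected (nonsynonymous, synonymous) site counts for one sense codon.

    Each of the nine possible single-nucleotide changes contributes 1/3 of
    a site at its position; a change is synonymous iff the encoded amino
    acid is unchanged (changes to stop codons are nonsynonymous).
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no NG86 site counts")
    if any(b not in _BASES for b in codon):
        raise ValueError(f"ambiguous codon {codon!r}; drop upstream")
    aa = CODON_TABLE[codon]
    s_sites = 0.0
    for pos in range(3):
        syn_at_pos = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            if mutant not in STOP_CODONS and CODON_TABLE[mutant] == aa:
                syn_at_pos += 1
        s_sites += syn_at_pos / 3.0
    return 3.0 - s_sites, s_sites


# ---------------------------------------------------------------------------
# Difference counting (shortest-pathway average)
# ---------------------------------------------------------------------------

def _step_type(c_from: str, c_to: str) -> int:
    """1 if the single-nucleotide step is synonymous, else 0."""
    return int(CODON_TABLE[c_from] == CODON_TABLE[c_to])


@lru_cache(maxsize=None)
def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Observed (nonsynonymous, synonymous) differences for a codon pair.

    With k differing positions, every one of the k! orderings of
    single-nucleotide steps defines a pathway; pathways through stop codons
    are excluded and the syn/nonsyn step counts are averaged over the rest.
    If all pathways are excluded, all k steps count as nonsynonymous.
    Guarantees nd + sd == k.
    """
    for c in (codon_a, codon_b):
        if c in STOP_CODONS or any(b not in _BASES for b in c):
            raise ValueError(f"invalid codon {c!r}")
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff_positions)
    if k == 0:
        return 0.0, 0.0
    total_syn = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_positions):
        current = codon_a
        syn_steps = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS and nxt != codon_b:
                ok = False
                break
            syn_steps += _step_type(current, nxt)
            current = nxt
        if ok:
            total_syn += syn_steps
            n_paths += 1
    if n_paths == 0:
        return float(k), 0.0
    sd = total_syn / n_paths
    return k - sd, sd


# ---------------------------------------------------------------------------
# Pairwise Ka/Ks
# ---------------------------------------------------------------------------

@dataclass
class KaKsResult:
    """NG86 site/difference counts and Jukes-Cantor corrected rates."""

    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    Ka: float | None
    Ks: float | None
    ratio: float | None
    n_codons: int
    saturated: bool = False

    def as_dict(self) -> dict:
        return {
            "N": self.N, "S": self.S, "Nd": self.Nd, "Sd": self.Sd,
            "pN": self.pN, "pS": self.pS,
            "Ka": self.Ka, "Ks": self.Ks, "ratio": self.ratio,
            "n_codons": self.n_codons, "saturated": self.saturated,
        }


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction K = -(3/4) ln(1 - (4/3) p); requires p < 3/4."""
    if p >= 0.75:
        raise SaturationError(f"p = {p} >= 3/4; correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _codon_columns(seq_a: str, seq_b: str) -> list[tuple[str, str]]:
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences differ in length")
    if len(seq_a) % 3:
        raise ValueError("aligned length not divisible by 3")
    pairs = []
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3].upper(), seq_b[i:i + 3].upper()
        if "-" in ca or "-" in cb:
            continue
        if any(b not in _BASES for b in ca + cb):
            continue
        pairs.append((ca, cb))
    n = len(pairs)
    for idx, (ca, cb) in enumerate(pairs):
        for c, label in ((ca, "first"), (cb, "second")):
            if c in STOP_CODONS and idx < n - 1:
                raise ValueError(
                    f"internal stop codon {c} in {label} sequence")
    # a terminal stop (both or either) is simply dropped
    if pairs and (pairs[-1][0] in STOP_CODONS or pairs[-1][1] in STOP_CODONS):
        pairs = pairs[:-1]
    return pairs


def compute_kaks(seq_a: str, seq_b: str) -> KaKsResult:
    """NG86 Ka/Ks for a codon-aligned pair of CDS strings.

    Gapped or ambiguous codon columns are dropped pairwise. ``ratio`` is
    None when Ks == 0 (or undefined). When pN or pS reaches saturation
    (>= 3/4) the corresponding rate is None and ``saturated`` is set.
    """
    pairs = _codon_columns(seq_a, seq_b)
    if not pairs:
        raise ValueError("no comparable codon columns")
    n_a = s_a = n_b = s_b = 0.0
    nd = sd = 0.0
    for ca, cb in pairs:
        na, sa = ng86_sites(ca)
        nb, sb = ng86_sites(cb)
        n_a += na; s_a += sa; n_b += nb; s_b += sb
        d_n, d_s = ng86_differences(ca, cb)
        nd += d_n; sd += d_s
    N = (n_a + n_b) / 2.0
    S = (s_a + s_b) / 2.0
    pN = nd / N
    pS = sd / S
    saturated = False
    try:
        ka: float | None = jukes_cantor(pN)
    except SaturationError:
        ka, saturated = None, True
    try:
        ks: float | None = jukes_cantor(pS)
    except SaturationError:
        ks, saturated = None, True
    ratio = None
    if ka is not None and ks is not None and ks > 0.0:
        ratio = ka / ks
    return KaKsResult(N=N, S=S, Nd=nd, Sd=sd, pN=pN, pS=pS,
                      Ka=ka, Ks=ks, ratio=ratio,
                      n_codons=len(pairs), saturated=saturated)


# ---------------------------------------------------------------------------
# Group-wise comparison across bias categories
# ---------------------------------------------------------------------------

def kaks_by_group(ratios: pd.DataFrame) -> pd.DataFrame:
    """Summarise Ka/Ks ratios per expression-bias category.

    ``ratios`` needs columns ``group`` and ``ratio`` (one row per pair or
    per triad; rows with undefined ratio may carry NaN). Returns one row
    per category with n, mean, median and quartiles of the defined ratios,
    plus a pooled balanced-vs-non-balanced rank-sum test (Mann-Whitney U)
    reported as descriptive columns on every row.
    """
    rows = []
    defined = ratios.dropna(subset=["ratio"])
    groups = ["balanced", "H1D", "H2D", "H3D", "H1S", "H2S", "H3S"]
    present = [g for g in groups if g in set(ratios["group"])]
    for g in present:
        vals = defined.loc[defined["group"] == g, "ratio"].to_numpy(float)
        if len(vals) == 0:
            rows.append({"group": g, "n": 0, "mean": np.nan, "median": np.nan,
                         "q1": np.nan, "q3": np.nan})
        else:
            rows.append({
                "group": g, "n": len(vals),
                "mean": float(np.mean(vals)),
                "median": float(np.median(vals)),
                "q1": float(np.quantile(vals, 0.25)),
                "q3": float(np.quantile(vals, 0.75)),
            })
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(
            columns=["group", "n", "mean", "median", "q1", "q3",
                     "ranksum_U", "ranksum_p"])
    bal = defined.loc[defined["group"] == "balanced", "ratio"].to_numpy(float)
    non = defined.loc[defined["group"] != "balanced", "ratio"].to_numpy(float)
    if len(bal) and len(non):
        u, p = stats.mannwhitneyu(non, bal, alternative="greater")
        out["ranksum_U"] = float(u)
        out["ranksum_p"] = float(p)
    else:
        out["ranksum_U"] = np.nan
        out["ranksum_p"] = np.nan
    return out


def purifying_fraction(ratios: pd.DataFrame) -> float:
    """Fraction of defined Ka/Ks ratios below 1 (purifying selection)."""
    vals = ratios["ratio"].dropna().to_numpy(float)
    if len(vals) == 0:
        return float("nan")
    return float(np.mean(vals < 1.0))
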
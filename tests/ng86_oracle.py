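"""Brute-force NG86 oracle, written independently of the package.

Uses Biopython's translate() as its genetic code and a recursive
depth-first enumeration of mutational pathways (the package uses a table
of the standard code and itertools.permutations). Slow and simple on
purpose.
"""

from Bio.Seq import Seq

BASES = "ACGT"


def aa(codon: str) -> str:
    return str(Seq(codon).translate())


def is_stop(codon: str) -> bool:
    return aa(codon) == "*"


def oracle_sites(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts by direct enumeration."""
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if not is_stop(mut) and aa(mut) == aa(codon):
                syn += 1.0 / 3.0
    return 3.0 - syn, syn


def _paths(current: str, target: str):
    """Yield lists of (from, to) steps for every ordering of the remaining
    changes, pruning any path whose intermediate codon is a stop."""
    diff = [i for i in range(3) if current[i] != target[i]]
    if not diff:
        yield []
        return
    for pos in diff:
        nxt = current[:pos] + target[pos] + current[pos + 1:]
        if is_stop(nxt) and nxt != target:
            continue
        for rest in _paths(nxt, target):
            yield [(current, nxt)] + rest


def oracle_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(nd, sd) averaged over stop-free pathways; all-nonsynonymous if
    every pathway is blocked."""
    k = sum(a != b for a, b in zip(codon_a, codon_b))
    all_paths = list(_paths(codon_a, codon_b))
    if k == 0:
        return 0.0, 0.0
    if not all_paths:
        return float(k), 0.0
    sd_total = 0.0
    for path in all_paths:
        sd_total += sum(aa(f) == aa(t) for f, t in path)
    sd = sd_total / len(all_paths)
    return k - sd, sd


def oracle_pair_counts(seq_a: str, seq_b: str):
    """(N, S, Nd, Sd) for two equal-length, gap-free, stop-free CDS."""
    n_a = s_a = n_b = s_b = nd = sd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        na, sa = oracle_sites(ca)
        nb, sb = oracle_sites(cb)
        n_a += na; s_a += sa; n_b += nb; s_b += sb
        dn, ds = oracle_differences(ca, cb)
        nd += dn; sd += ds
    return (n_a + n_b) / 2.0, (s_a + s_b) / 2.0, nd, sd
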
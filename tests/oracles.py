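"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's lookup tables and dynamic programs:
translation goes through Bio.Seq, pathway enumeration is a plain recursion,
and the local-alignment oracle enumerates every alignment path explicitly.
"""

from __future__ import annotations

import itertools

from Bio.Seq import Seq

NUCS = "ACGT"


def translate(codon: str) -> str:
    """One-letter amino acid, '*' for stop."""
    return str(Seq(codon).translate())


def naive_site_counts(codon: str) -> tuple[float, float]:
    """NG86 synonymous/non-synonymous sites by direct enumeration."""
    aa = translate(codon)
    assert aa != "*"
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for alt in NUCS:
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            maa = translate(mut)
            if maa == "*":
                continue
            tot += 1
            if maa == aa:
                syn += 1
        if tot:
            s += syn / tot
    return s, 3.0 - s


def naive_path_diffs(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged (sd, nd) by recursive enumeration of change orders."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    results = []

    def walk(cur: str, remaining: list[int], syn: int, non: int):
        if not remaining:
            results.append((syn, non))
            return
        for pos in remaining:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if translate(nxt) == "*":
                continue
            step_syn = translate(nxt) == translate(cur)
            walk(
                nxt,
                [p for p in remaining if p != pos],
                syn + step_syn,
                non + (not step_syn),
            )

    walk(a, diff, 0, 0)
    if not results:  # every route blocked: classify each change singly
        syn = non = 0
        for pos in diff:
            mut = a[:pos] + b[pos] + a[pos + 1 :]
            if translate(mut) != "*" and translate(mut) == translate(a):
                syn += 1
            else:
                non += 1
        return float(syn), float(non)
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def naive_pair_totals(cds_a: str, cds_b: str):
    """(Sd, Nd, S_sites, N_sites, n_codons) over an aligned stop-free pair."""
    Sd = Nd = Ssites = Nsites = 0.0
    n = 0
    for k in range(0, len(cds_a), 3):
        ca, cb = cds_a[k : k + 3], cds_b[k : k + 3]
        if any(c not in NUCS for c in ca + cb):
            continue
        if translate(ca) == "*" or translate(cb) == "*":
            continue
        n += 1
        sa, na = naive_site_counts(ca)
        sb, nb = naive_site_counts(cb)
        Ssites += (sa + sb) / 2
        Nsites += (na + nb) / 2
        sd, nd = naive_path_diffs(ca, cb)
        Sd += sd
        Nd += nd
    return Sd, Nd, Ssites, Nsites, n


def exhaustive_local_align(columns, target_scores, gap_open, gap_extend):
    """Best local-alignment score by explicit path enumeration.

    ``columns`` x ``target_scores`` give cell scores score[i][j] for target
    residue i against profile column j.  Every alignment path (sequences of
    match / profile-gap / target-gap moves starting and ending on a match)
    is enumerated; a gap run of length g costs gap_open + (g-1)*gap_extend.
    Returns (best_score, Lt) with Lt the target residues spanned by the best
    alignment (0 if no positive-scoring alignment exists).
    """
    Ls = len(target_scores)
    Lp = len(columns)
    score = [[target_scores[i][columns[j]] for j in range(Lp)] for i in range(Ls)]

    best = [0.0, 0]

    def extend(i, j, acc, ti_start):
        # alignment currently ends with a match at (i, j)
        if acc > best[0]:
            best[0], best[1] = acc, i - ti_start + 1
        # continue with a match, or a gap run then a match
        if i + 1 < Ls and j + 1 < Lp:
            extend(i + 1, j + 1, acc + score[i + 1][j + 1], ti_start)
        for g in range(1, Lp - j - 1):  # gap in target: skip g profile columns
            if i + 1 < Ls and j + 1 + g < Lp:
                cost = gap_open + (g - 1) * gap_extend
                extend(i + 1, j + 1 + g, acc + score[i + 1][j + 1 + g] - cost, ti_start)
        for g in range(1, Ls - i - 1):  # gap in profile: skip g target residues
            if i + 1 + g < Ls and j + 1 < Lp:
                cost = gap_open + (g - 1) * gap_extend
                extend(i + 1 + g, j + 1, acc + score[i + 1 + g][j + 1] - cost, ti_start)

    for i0 in range(Ls):
        for j0 in range(Lp):
            extend(i0, j0, score[i0][j0], i0)
    return best[0], best[1]


def naive_degrees(edges, nodes):
    """Node degrees by direct incidence recount."""
    return {
        n: sum(1 for a, b in edges if n in (a, b) and a != b) for n in nodes
    }


def adjusted_rand(labels_a, labels_b) -> float:
    """Adjusted Rand index from the pair-counting definition."""
    n = len(labels_a)
    assert n == len(labels_b)
    from math import comb

    pairs_both = pairs_a = pairs_b = 0
    cont: dict[tuple, int] = {}
    ca: dict = {}
    cb: dict = {}
    for x, y in zip(labels_a, labels_b):
        cont[(x, y)] = cont.get((x, y), 0) + 1
        ca[x] = ca.get(x, 0) + 1
        cb[y] = cb.get(y, 0) + 1
    pairs_both = sum(comb(v, 2) for v in cont.values())
    pairs_a = sum(comb(v, 2) for v in ca.values())
    pairs_b = sum(comb(v, 2) for v in cb.values())
    total = comb(n, 2)
    expected = pairs_a * pairs_b / total
    max_index = (pairs_a + pairs_b) / 2
    if max_index == expected:
        return 1.0
    return (pairs_both - expected) / (max_index - expected)
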
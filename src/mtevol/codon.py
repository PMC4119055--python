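"""Pairwise Nei–Gojobori (NG86) dN/dS estimation and per-codon substitution
profiles.

The NG86 method counts, for every codon, the fraction of single-nucleotide
changes that are synonymous (*synonymous sites*, ``s``) versus non-synonymous
(``n = 3 - s``), and, for every pair of aligned codons, the synonymous and
non-synonymous differences averaged over all minimal mutational pathways
between them.  Proportions ``ps = Sd / S̄`` and ``pn = Nd / N̄`` are converted
to rates per site with the Jukes–Cantor correction
``d = -(3/4) ln(1 - (4/3) p)``; their ratio is ``ω = dN/dS``, the classic
selection statistic (ω < 1 purifying, ≈ 1 neutral, > 1 positive selection).

Conventions (matching the SNAP calculator's documented behaviour):

* single-nucleotide changes that create stop codons are excluded from the
  per-position site-count denominators;
* mutational pathways passing through a stop codon are excluded from pathway
  averaging; if every pathway is blocked, differences are classified directly
  position-by-position and the pair is flagged;
* codons containing a gap, an ambiguous base, or a stop in either sequence
  are skipped entirely.

An optional transition-weighted site counting (``ts_weight > 1``) upweights
transitions in the site-count denominators; the default (1.0) is plain NG86.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "CodonPairStats",
    "CumulativeProfile",
    "codon_site_counts",
    "codon_path_diffs",
    "pairwise_ng86",
    "jukes_cantor_correct",
    "cumulative_site_profile",
    "aggregate_gene_stats",
    "dnds_regression",
    "SATURATION_CAP",
]

NUCS = "ACGT"
SATURATION_CAP = 10.0

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def _is_transition(x: str, y: str) -> bool:
    return (x in _PURINES and y in _PURINES) or (x in _PYRIMIDINES and y in _PYRIMIDINES)


def _codon_table(code: int | CodonTable.CodonTable = 1) -> CodonTable.CodonTable:
    if isinstance(code, CodonTable.CodonTable):
        return code
    return CodonTable.unambiguous_dna_by_id[int(code)]


def _translate(codon: str, table: CodonTable.CodonTable) -> str | None:
    """Amino acid for ``codon``, or None for a stop codon."""
    if codon in table.stop_codons:
        return None
    return table.forward_table[codon]


def codon_site_counts(
    codon: str,
    code: int | CodonTable.CodonTable = 1,
    ts_weight: float = 1.0,
) -> tuple[float, float]:
    """Synonymous and non-synonymous site counts ``(s, n)`` for one codon.

    At each of the three positions the fraction of synonymous changes is
    computed over the single-nucleotide changes that do not create a stop
    codon; ``s`` is the sum of the three fractions and ``n = 3 - s``.

    Parameters
    ----------
    codon : str
        A stop-free, unambiguous DNA codon (e.g. ``"GGG"``).
    code : int or Bio.Data.CodonTable.CodonTable
        NCBI genetic-code table id (default 1, the standard code).
    ts_weight : float
        Relative weight of transitions in the site-count denominators;
        1.0 gives the plain NG86 counting.

    Returns
    -------
    (s, n) : tuple of float
        ``s + n == 3`` exactly.
    """
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3 or any(c not in NUCS for c in codon):
        raise ValueError(f"not an unambiguous DNA codon: {codon!r}")
    table = _codon_table(code)
    aa = _translate(codon, table)
    if aa is None:
        raise ValueError(f"stop codon rejected: {codon!r}")
    if ts_weight <= 0:
        raise ValueError("ts_weight must be positive")

    s = 0.0
    for pos in range(3):
        syn_w = 0.0
        tot_w = 0.0
        for alt in NUCS:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            maa = _translate(mutant, table)
            if maa is None:  # change to stop: excluded from the denominator
                continue
            w = ts_weight if _is_transition(codon[pos], alt) else 1.0
            tot_w += w
            if maa == aa:
                syn_w += w
        if tot_w > 0:
            s += syn_w / tot_w
    return s, 3.0 - s


def codon_path_diffs(
    codon_a: str,
    codon_b: str,
    code: int | CodonTable.CodonTable = 1,
) -> tuple[float, float, int, int]:
    """Pathway-averaged synonymous/non-synonymous differences between codons.

    All orderings of the differing positions are enumerated; each step of a
    pathway is classified synonymous or non-synonymous, pathways passing
    through stop codons are dropped, and the per-class counts are averaged
    over the surviving pathways.  Transitions and transversions are counted
    directly from the observed nucleotide differences.

    Returns
    -------
    (sd, nd, ts_count, tv_count)
        ``sd + nd`` equals the number of differing positions.

    Notes
    -----
    If every pathway is blocked by stop codons the differences are classified
    by applying each change singly to ``codon_a`` (direct classification);
    callers needing the flag should use :func:`_path_diffs_flagged`.
    """
    sd, nd, ts, tv, _ = _path_diffs_flagged(codon_a, codon_b, _codon_table(code))
    return sd, nd, ts, tv


def _path_diffs_flagged(
    codon_a: str,
    codon_b: str,
    table: CodonTable.CodonTable,
) -> tuple[float, float, int, int, bool]:
    a = codon_a.upper().replace("U", "T")
    b = codon_b.upper().replace("U", "T")
    for c in (a, b):
        if len(c) != 3 or any(x not in NUCS for x in c):
            raise ValueError(f"not an unambiguous DNA codon: {c!r}")
        if _translate(c, table) is None:
            raise ValueError(f"stop codon rejected: {c!r}")

    diff_pos = [i for i in range(3) if a[i] != b[i]]
    ts = sum(1 for i in diff_pos if _is_transition(a[i], b[i]))
    tv = len(diff_pos) - ts
    if not diff_pos:
        return 0.0, 0.0, 0, 0, False

    path_syn: list[int] = []
    path_non: list[int] = []
    for order in itertools.permutations(diff_pos):
        cur = a
        syn = non = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            aa_cur = _translate(cur, table)
            aa_nxt = _translate(nxt, table)
            if aa_nxt is None:
                blocked = True
                break
            if aa_nxt == aa_cur:
                syn += 1
            else:
                non += 1
            cur = nxt
        if not blocked:
            path_syn.append(syn)
            path_non.append(non)

    if path_syn:
        return (
            float(np.mean(path_syn)),
            float(np.mean(path_non)),
            ts,
            tv,
            False,
        )

    # all pathways hit stops: classify each change singly against codon_a
    syn = non = 0
    aa_a = _translate(a, table)
    for pos in diff_pos:
        mutant = a[:pos] + b[pos] + a[pos + 1 :]
        maa = _translate(mutant, table)
        if maa is not None and maa == aa_a:
            syn += 1
        else:
            non += 1
    return float(syn), float(non), ts, tv, True


def jukes_cantor_correct(p: float) -> float:
    """Jukes–Cantor distance ``d = -(3/4) ln(1 - (4/3) p)``.

    Returns ``nan`` for saturated proportions (``p >= 3/4``); finite values
    are capped at :data:`SATURATION_CAP`.
    """
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return math.nan
    d = -0.75 * math.log1p(-(4.0 / 3.0) * p)
    return min(d, SATURATION_CAP)


# ---------------------------------------------------------------------------
# vectorized codon machinery
# ---------------------------------------------------------------------------

_NUC_INDEX = {c: i for i, c in enumerate(NUCS)}
_CODONS = ["".join(c) for c in itertools.product(NUCS, repeat=3)]
_CODON_INDEX = {c: i for i, c in enumerate(_CODONS)}


class _CodeTables:
    """Cached per-genetic-code lookup tables over the 64-codon index space."""

    def __init__(self, table: CodonTable.CodonTable, ts_weight: float):
        self.table = table
        self.is_stop = np.array([c in table.stop_codons for c in _CODONS])
        sn = np.zeros((64, 2))
        for i, c in enumerate(_CODONS):
            if not self.is_stop[i]:
                sn[i] = codon_site_counts(c, table, ts_weight)
        self.site_s = sn[:, 0]
        self.site_n = sn[:, 1]

        self.sd = np.zeros((64, 64))
        self.nd = np.zeros((64, 64))
        self.ts = np.zeros((64, 64), dtype=np.int64)
        self.tv = np.zeros((64, 64), dtype=np.int64)
        self.blocked = np.zeros((64, 64), dtype=bool)
        for i, a in enumerate(_CODONS):
            if self.is_stop[i]:
                continue
            for j in range(i, 64):
                if self.is_stop[j]:
                    continue
                sd, nd, ts, tv, blocked = _path_diffs_flagged(a, _CODONS[j], table)
                self.sd[i, j] = self.sd[j, i] = sd
                self.nd[i, j] = self.nd[j, i] = nd
                self.ts[i, j] = self.ts[j, i] = ts
                self.tv[i, j] = self.tv[j, i] = tv
                self.blocked[i, j] = self.blocked[j, i] = blocked


_CODE_CACHE: dict[tuple[int, float], _CodeTables] = {}


def _tables_for(code: int | CodonTable.CodonTable, ts_weight: float = 1.0) -> _CodeTables:
    table = _codon_table(code)
    key = (table.id, float(ts_weight))
    if key not in _CODE_CACHE:
        _CODE_CACHE[key] = _CodeTables(table, ts_weight)
    return _CODE_CACHE[key]


def _encode_codons(seq: str) -> np.ndarray:
    """Codon index array for an in-frame CDS; -1 marks gap/ambiguous codons."""
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    out = np.full(len(seq) // 3, -1, dtype=np.int64)
    for k in range(len(out)):
        codon = seq[3 * k : 3 * k + 3]
        idx = 0
        ok = True
        for c in codon:
            if c not in _NUC_INDEX:
                ok = False
                break
            idx = idx * 4 + _NUC_INDEX[c]
        if ok:
            out[k] = idx
    return out


@dataclass
class CodonPairStats:
    """NG86 quantities for one pair of aligned in-frame coding sequences."""

    n_codons: int  # usable (stop/gap-free in both) codons compared
    S_sites: float  # S̄: mean synonymous sites over the two sequences
    N_sites: float  # N̄: mean non-synonymous sites
    Sd: float  # pathway-averaged synonymous differences
    Nd: float  # pathway-averaged non-synonymous differences
    ps: float
    pn: float
    dS: float  # JC-corrected; nan when saturated
    dN: float
    omega: float  # dN/dS; nan when dS == 0 or either rate saturated
    ts_fraction: float  # transitional share of observed differences; nan if none
    saturated_s: bool = False
    saturated_n: bool = False
    n_blocked: int = 0  # codon pairs whose pathways were all stop-blocked

    @property
    def saturated(self) -> bool:
        return self.saturated_s or self.saturated_n


def pairwise_ng86(
    cds_a: str,
    cds_b: str,
    code: int | CodonTable.CodonTable = 1,
    ts_weight: float = 1.0,
) -> CodonPairStats:
    """Nei–Gojobori pairwise dN/dS for two aligned in-frame CDS.

    Sequences must be equal length and divisible by 3; codons containing a
    gap, ambiguity or stop in either sequence are skipped.  See the module
    docstring for conventions.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError(
            f"aligned CDS lengths differ: {len(cds_a)} vs {len(cds_b)}"
        )
    tabs = _tables_for(code, ts_weight)
    ia = _encode_codons(cds_a)
    ib = _encode_codons(cds_b)
    usable = (ia >= 0) & (ib >= 0)
    usable[usable] &= ~tabs.is_stop[ia[usable]] & ~tabs.is_stop[ib[usable]]
    ia, ib = ia[usable], ib[usable]
    n_codons = int(usable.sum())

    S_sites = float((tabs.site_s[ia] + tabs.site_s[ib]).sum() / 2.0)
    N_sites = float((tabs.site_n[ia] + tabs.site_n[ib]).sum() / 2.0)
    Sd = float(tabs.sd[ia, ib].sum())
    Nd = float(tabs.nd[ia, ib].sum())
    ts = int(tabs.ts[ia, ib].sum())
    tv = int(tabs.tv[ia, ib].sum())
    n_blocked = int(tabs.blocked[ia, ib].sum())

    ps = Sd / S_sites if S_sites > 0 else 0.0
    pn = Nd / N_sites if N_sites > 0 else 0.0
    dS = jukes_cantor_correct(ps)
    dN = jukes_cantor_correct(pn)
    saturated_s = math.isnan(dS)
    saturated_n = math.isnan(dN)
    if saturated_s or saturated_n or dS == 0.0:
        omega = math.nan
    else:
        omega = dN / dS
    ts_fraction = ts / (ts + tv) if (ts + tv) > 0 else math.nan

    return CodonPairStats(
        n_codons=n_codons,
        S_sites=S_sites,
        N_sites=N_sites,
        Sd=Sd,
        Nd=Nd,
        ps=ps,
        pn=pn,
        dS=dS,
        dN=dN,
        omega=omega,
        ts_fraction=ts_fraction,
        saturated_s=saturated_s,
        saturated_n=saturated_n,
        n_blocked=n_blocked,
    )


@dataclass
class CumulativeProfile:
    """Per-codon cumulative synonymous/non-synonymous difference curves,
    averaged over all sequence pairs of an alignment."""

    gene_name: str
    cum_syn: np.ndarray  # shape (n_codons,), non-decreasing
    cum_nonsyn: np.ndarray
    hotspot_windows: list[tuple[int, int, str]] = field(default_factory=list)
    window_nonsyn_share: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "codon": np.arange(1, len(self.cum_syn) + 1),
                "cum_syn": self.cum_syn,
                "cum_nonsyn": self.cum_nonsyn,
            }
        )


def cumulative_site_profile(
    alignment: Sequence[tuple[str, str]] | Sequence[str],
    gene_name: str = "gene",
    hotspots: Sequence[tuple[int, int, str]] = (),
    code: int | CodonTable.CodonTable = 1,
) -> CumulativeProfile:
    """Cumulative substitution curves along a codon alignment.

    For each codon index ``i`` the running sums over codons ``1..i`` of
    pathway-averaged synonymous and non-synonymous differences are computed,
    averaged over all sequence pairs.  Hotspot windows (1-based inclusive
    codon intervals) are carried through, and the share of total
    non-synonymous difference falling inside each window is reported.
    """
    seqs = [s[1] if isinstance(s, tuple) else str(s) for s in alignment]
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    (length,) = lengths
    if length % 3 != 0:
        raise ValueError(f"alignment length {length} not divisible by 3")

    tabs = _tables_for(code)
    enc = np.stack([_encode_codons(s) for s in seqs])
    n_codons = enc.shape[1]
    syn = np.zeros(n_codons)
    non = np.zeros(n_codons)
    n_pairs = 0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            ia, ib = enc[i], enc[j]
            ok = (ia >= 0) & (ib >= 0)
            ok[ok] &= ~tabs.is_stop[ia[ok]] & ~tabs.is_stop[ib[ok]]
            syn[ok] += tabs.sd[ia[ok], ib[ok]]
            non[ok] += tabs.nd[ia[ok], ib[ok]]
            n_pairs += 1
    syn /= n_pairs
    non /= n_pairs

    total_non = non.sum()
    shares = {}
    for start, end, label in hotspots:
        if not (1 <= start <= end <= n_codons):
            raise ValueError(f"hotspot window {label!r} outside [1, {n_codons}]")
        shares[label] = (
            float(non[start - 1 : end].sum() / total_non) if total_non > 0 else 0.0
        )

    return CumulativeProfile(
        gene_name=gene_name,
        cum_syn=np.cumsum(syn),
        cum_nonsyn=np.cumsum(non),
        hotspot_windows=[tuple(h) for h in hotspots],
        window_nonsyn_share=shares,
    )


def aggregate_gene_stats(
    pair_stats: Sequence[CodonPairStats],
    gene_name: str = "gene",
    group: str = "",
) -> dict:
    """Arithmetic means of dS, dN and per-pair ω over non-saturated pairs.

    ω is averaged as mean-of-ratios over pairs where it is defined (dS > 0,
    neither rate saturated).  Counts of excluded pairs are reported so no
    pair is dropped silently.
    """
    if not pair_stats:
        raise ValueError("empty pair-stats list")
    usable = [p for p in pair_stats if not p.saturated]
    omegas = [p.omega for p in usable if not math.isnan(p.omega)]
    ts = [p.ts_fraction for p in usable if not math.isnan(p.ts_fraction)]
    result = {
        "gene": gene_name,
        "group": group,
        "n_pairs": len(pair_stats),
        "n_saturated": len(pair_stats) - len(usable),
        "n_omega_undefined": len(usable) - len(omegas),
        "mean_dS": float(np.mean([p.dS for p in usable])) if usable else math.nan,
        "mean_dN": float(np.mean([p.dN for p in usable])) if usable else math.nan,
        "mean_omega": float(np.mean(omegas)) if omegas else math.nan,
        "ts_fraction": float(np.mean(ts)) if ts else math.nan,
    }
    if not usable:
        result["all_saturated"] = True
    return result


def dnds_regression(per_gene: pd.DataFrame) -> pd.DataFrame:
    """Per-group OLS regression of log2(dN) on log2(dS).

    ``per_gene`` needs columns ``gene``, ``group``, ``mean_dN``, ``mean_dS``.
    Genes with non-positive rates are excluded (counts reported); groups with
    fewer than 3 usable genes are skipped.  Each usable gene is also marked
    relative to the neutrality line dN = dS.
    """
    required = {"gene", "group", "mean_dN", "mean_dS"}
    missing = required - set(per_gene.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for grp, sub in per_gene.groupby("group", sort=True):
        ok = (sub["mean_dN"] > 0) & (sub["mean_dS"] > 0) & sub[["mean_dN", "mean_dS"]].notna().all(axis=1)
        used = sub[ok]
        n_excluded = int((~ok).sum())
        if len(used) < 3:
            rows.append(
                {
                    "group": grp,
                    "n_genes": len(used),
                    "n_excluded": n_excluded,
                    "slope": math.nan,
                    "intercept": math.nan,
                    "r": math.nan,
                    "mean_log2_omega": math.nan,
                    "skipped": True,
                }
            )
            continue
        x = np.log2(used["mean_dS"].to_numpy(float))
        y = np.log2(used["mean_dN"].to_numpy(float))
        from scipy import stats as _st

        res = _st.linregress(x, y)
        rows.append(
            {
                "group": grp,
                "n_genes": len(used),
                "n_excluded": n_excluded,
                "slope": float(res.slope),
                "intercept": float(res.intercept),
                "r": float(res.rvalue),
                "mean_log2_omega": float(np.mean(y - x)),
                "skipped": False,
            }
        )
    return pd.DataFrame(rows)


def classify_selection(mean_dN: float, mean_dS: float) -> str:
    """Position of a gene relative to the neutrality line dN = dS."""
    if mean_dN > mean_dS:
        return "positive"
    if mean_dN < mean_dS:
        return "purifying"
    return "neutral"
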
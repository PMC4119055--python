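"""Position-specific scoring matrices (PSSMs) and local profile alignment.

A family alignment, filtered for gappy columns, is converted into a
per-column log2-odds profile:

    score(column, aa) = log2( ((count + pc * bg[aa]) / (n_rows + pc)) / bg[aa] )

with pseudocount weight ``pc`` distributed according to the background
``bg``.  Profiles are scanned against target sequences with a
Smith–Waterman-style local dynamic program over the position-specific
scores, using affine gap penalties (a gap of length g costs
``gap_open + (g - 1) * gap_extend`` bits).  Each hit records the aligned
target length ``Lt``, the profile length ``Lp`` and the score ``S`` in bits —
the three quantities the Similarity Index consumes.

Ambiguous residues (X, B, Z, U, O, J) score 0 in every column (background
odds); gap characters in targets are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AA_ALPHABET",
    "PositionProfile",
    "ProfileHit",
    "filter_gap_columns",
    "build_profile",
    "scan_sequence",
    "scan_collection",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
AMBIGUOUS = frozenset("XBZUOJ")
GAP_CHARS = frozenset("-.")

DEFAULT_GAP_OPEN = 4.0
DEFAULT_GAP_EXTEND = 0.5
DEFAULT_MIN_SCORE = 25.0


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


@dataclass
class PositionProfile:
    """Per-column amino-acid log2-odds model of one family alignment."""

    family_name: str
    columns: np.ndarray  # shape (Lp, 20), bits
    background: np.ndarray  # shape (20,), sums to 1
    pseudocount: float

    @property
    def Lp(self) -> int:
        return self.columns.shape[0]

    def consensus(self) -> str:
        """Argmax residue per column."""
        return "".join(AA_ALPHABET[i] for i in self.columns.argmax(axis=1))

    def max_score(self) -> float:
        """Score of the gap-free consensus alignment (column maxima summed)."""
        return float(self.columns.max(axis=1).sum())


@dataclass
class ProfileHit:
    """One profile-vs-sequence local alignment.

    Spans are 1-based inclusive; ``SI`` and ``band`` are filled downstream by
    the similarity-network stage.
    """

    family_name: str
    target_id: str
    target_span: tuple[int, int]
    profile_span: tuple[int, int]
    Lt: int
    S: float
    SI: float | None = None
    band: str | None = None


def _as_rows(alignment) -> list[str]:
    """Accept a list of strings, (id, seq) pairs, or SeqRecord-likes."""
    rows = []
    for r in alignment:
        if isinstance(r, str):
            rows.append(r.upper())
        elif isinstance(r, (tuple, list)) and len(r) == 2:
            rows.append(str(r[1]).upper())
        else:  # SeqRecord / aligned sequence object
            rows.append(str(getattr(r, "seq", r)).upper())
    return rows


def filter_gap_columns(
    alignment, max_gap_fraction: float = 0.5
) -> tuple[list[str], list[int]]:
    """Drop alignment columns whose gap fraction exceeds the threshold.

    Returns the filtered rows (column order preserved) and the 0-based
    indices of the retained columns.
    """
    if not 0 <= max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    rows = _as_rows(alignment)
    if not rows:
        raise ValueError("empty alignment")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    (width,) = lengths
    n = len(rows)
    kept = [
        j
        for j in range(width)
        if sum(1 for r in rows if r[j] in GAP_CHARS) / n <= max_gap_fraction
    ]
    filtered = ["".join(r[j] for j in kept) for r in rows]
    return filtered, kept


def build_profile(
    alignment,
    family_name: str = "family",
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> PositionProfile:
    """Build a log2-odds PSSM from a (gap-filtered) protein alignment.

    Gap and ambiguity characters contribute nothing to the column counts but
    the denominator stays ``n_rows + pseudocount``, so columns rich in gaps
    shrink toward (below-) background scores.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0 (keeps log-odds finite)")
    rows = _as_rows(alignment)
    if not rows or not rows[0]:
        raise ValueError("empty alignment")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    bg = uniform_background() if background is None else np.asarray(background, float)
    if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0) or (bg <= 0).any():
        raise ValueError("background must be 20 positive frequencies summing to 1")

    n = len(rows)
    width = len(rows[0])
    counts = np.zeros((width, 20))
    for r in rows:
        for j, c in enumerate(r):
            i = _AA_INDEX.get(c)
            if i is not None:
                counts[j, i] += 1.0
    probs = (counts + pseudocount * bg) / (n + pseudocount)
    return PositionProfile(
        family_name=family_name,
        columns=np.log2(probs / bg),
        background=bg,
        pseudocount=pseudocount,
    )


def _encode_target(sequence: str) -> np.ndarray:
    """Residue indices; -1 marks ambiguity (scores 0 in every column)."""
    seq = sequence.upper()
    out = np.empty(len(seq), dtype=np.int64)
    for k, c in enumerate(seq):
        if c in _AA_INDEX:
            out[k] = _AA_INDEX[c]
        elif c in AMBIGUOUS:
            out[k] = -1
        elif c in GAP_CHARS:
            raise ValueError(f"gap character at position {k + 1} in target")
        else:
            raise ValueError(f"unknown residue {c!r} at position {k + 1}")
    return out


def scan_sequence(
    profile: PositionProfile,
    sequence: str,
    target_id: str = "target",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> list[ProfileHit]:
    """Optimal local alignment of a target sequence against a profile.

    Smith–Waterman over position-specific scores with affine gaps (Gotoh
    three-state recursion).  Returns a single-element list with the optimal
    hit, or an empty list when the optimal score is not positive.
    """
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive (given in bits)")
    if not sequence:
        raise ValueError("empty target sequence")
    enc = _encode_target(sequence)
    Lp = profile.Lp
    Ls = len(enc)

    # score of target residue i against profile column j
    cell = np.zeros((Ls, Lp))
    for i in range(Ls):
        if enc[i] >= 0:
            cell[i] = profile.columns[:, enc[i]]

    NEG = -np.inf
    M = np.zeros((Ls + 1, Lp + 1))
    X = np.full((Ls + 1, Lp + 1), NEG)  # gap in target (column consumed)
    Y = np.full((Ls + 1, Lp + 1), NEG)  # gap in profile (residue consumed)
    ptrM = np.zeros((Ls + 1, Lp + 1), dtype=np.int8)  # 0 start, 1 M, 2 X, 3 Y
    ptrX = np.zeros((Ls + 1, Lp + 1), dtype=np.int8)  # 1 from M, 2 from X
    ptrY = np.zeros((Ls + 1, Lp + 1), dtype=np.int8)  # 1 from M, 3 from Y

    best, bi, bj = 0.0, 0, 0
    for i in range(1, Ls + 1):
        for j in range(1, Lp + 1):
            xo, xe = M[i, j - 1] - gap_open, X[i, j - 1] - gap_extend
            if xo >= xe:
                X[i, j], ptrX[i, j] = xo, 1
            else:
                X[i, j], ptrX[i, j] = xe, 2
            yo, ye = M[i - 1, j] - gap_open, Y[i - 1, j] - gap_extend
            if yo >= ye:
                Y[i, j], ptrY[i, j] = yo, 1
            else:
                Y[i, j], ptrY[i, j] = ye, 3
            dM, dX, dY = M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]
            diag = max(dM, dX, dY)
            score = diag + cell[i - 1, j - 1]
            if score <= 0:
                M[i, j], ptrM[i, j] = 0.0, 0
            else:
                M[i, j] = score
                if diag == dM:
                    # restarting from an empty prefix: alignment begins here
                    ptrM[i, j] = 0 if (dM == 0.0 and ptrM[i - 1, j - 1] == 0) else 1
                elif diag == dX:
                    ptrM[i, j] = 2
                else:
                    ptrM[i, j] = 3
            if M[i, j] > best:
                best, bi, bj = M[i, j], i, j

    if best <= 0:
        return []

    # traceback from (bi, bj) in state M to the local start
    i, j, state = bi, bj, 1
    ti_end, pj_end = bi, bj
    while True:
        if state == 1:
            prev = ptrM[i, j]
            i, j = i - 1, j - 1
            if prev == 0:
                break
            state = prev
        elif state == 2:
            state = ptrX[i, j]
            j -= 1
        else:
            state = ptrY[i, j]
            i -= 1
    ti_start, pj_start = i + 1, j + 1

    Lt = ti_end - ti_start + 1
    return [
        ProfileHit(
            family_name=profile.family_name,
            target_id=target_id,
            target_span=(ti_start, ti_end),
            profile_span=(pj_start, pj_end),
            Lt=Lt,
            S=float(best),
        )
    ]


def scan_collection(
    profiles: Sequence[PositionProfile],
    sequences: Iterable[tuple[str, str]],
    min_score: float = DEFAULT_MIN_SCORE,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> pd.DataFrame:
    """Scan every sequence with every profile; keep hits with S > min_score.

    Returns a table with columns ``family, target, Lt, Lp, S, target_span,
    profile_span`` (one best hit per profile/target pair), sorted by
    descending score then family and target name.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("empty profile list")
    if min_score < 0:
        raise ValueError("min_score must be >= 0")
    seqs = list(sequences)
    rows = []
    for prof in profiles:
        for tid, seq in seqs:
            hits = scan_sequence(prof, seq, tid, gap_open, gap_extend)
            if hits and hits[0].S > min_score:
                h = hits[0]
                rows.append(
                    {
                        "family": h.family_name,
                        "target": h.target_id,
                        "Lt": h.Lt,
                        "Lp": prof.Lp,
                        "S": h.S,
                        "target_start": h.target_span[0],
                        "target_end": h.target_span[1],
                        "profile_start": h.profile_span[0],
                        "profile_end": h.profile_span[1],
                    }
                )
    frame = pd.DataFrame(
        rows,
        columns=[
            "family",
            "target",
            "Lt",
            "Lp",
            "S",
            "target_start",
            "target_end",
            "profile_start",
            "profile_end",
        ],
    )
    return frame.sort_values(
        ["S", "family", "target"], ascending=[False, True, True], ignore_index=True
    )
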
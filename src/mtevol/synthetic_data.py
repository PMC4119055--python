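"""Synthetic inputs with the statistical structure the analyses assume.

Four generators stand in for database downloads:

* :func:`simulate_family_set` — protein families whose consensus sequences
  share controlled fractions of conserved columns (a shared "core" of
  columns emulates the ortholog/paralog/related structure seen when family
  profiles are scanned against each other);
* :func:`simulate_codon_msa` — in-frame coding sequences evolved from one
  random ancestor on a star topology, with region-specific omega (dN/dS)
  acceptance and a transition/transversion proposal bias;
* :func:`make_presence_matrix` — family-by-phylum occupancy fractions with
  planted wide / mid-low / absent conservation classes;
* :func:`make_composition_table` — family amino-acid composition tables
  with planted per-group log2 enrichments (e.g. K/R in RNA-binding groups).

Every generator takes an explicit seed and is byte-reproducible; each one's
planted truth is returned alongside the data so downstream stages can be
checked for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from mtevol.profiles import AA_ALPHABET
from mtevol.codon import NUCS, _CODONS, _codon_table, _is_transition

__all__ = [
    "FamilySimConfig",
    "CodonSimConfig",
    "simulate_family_set",
    "simulate_codon_msa",
    "make_presence_matrix",
    "make_composition_table",
    "BACKGROUND_COMPOSITION",
]

#: Background amino-acid frequencies (order = AA_ALPHABET), a smoothed
#: average over bacterial proteomes; rows renormalized to sum exactly 1.
_BG = np.array(
    [
        0.089,  # A
        0.012,  # C
        0.054,  # D
        0.062,  # E
        0.040,  # F
        0.074,  # G
        0.022,  # H
        0.066,  # I
        0.046,  # K
        0.100,  # L
        0.024,  # M
        0.039,  # N
        0.044,  # P
        0.038,  # Q
        0.056,  # R
        0.060,  # S
        0.054,  # T
        0.071,  # V
        0.013,  # W
        0.036,  # Y
    ]
)
BACKGROUND_COMPOSITION = _BG / _BG.sum()


@dataclass
class FamilySimConfig:
    """Parameters of the shared-core protein family simulation.

    ``shared_column_fraction`` is either one fraction applied to every
    family pair (a core of columns common to all families) or a symmetric
    matrix with unit diagonal; matrices must be *nested* (realizable as a
    global core plus per-clan cores), which covers the scalar and block
    designs used throughout.
    """

    n_families: int
    members_per_family: int
    profile_length: int
    shared_column_fraction: float | np.ndarray = 0.0
    mutation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.members_per_family < 1:
            raise ValueError("members_per_family must be >= 1")
        if self.profile_length < 1:
            raise ValueError("profile_length must be >= 1")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        f = self.shared_column_fraction
        if np.isscalar(f):
            if not 0 <= f <= 1:
                raise ValueError("shared_column_fraction must be in [0, 1]")
        else:
            f = np.asarray(f, float)
            if f.shape != (self.n_families, self.n_families):
                raise ValueError(
                    "shared_column_fraction matrix must be n_families square"
                )
            if not np.allclose(f, f.T):
                raise ValueError("shared_column_fraction matrix must be symmetric")
            if not np.allclose(np.diag(f), 1.0):
                raise ValueError("shared_column_fraction diagonal must be 1")
            if ((f < 0) | (f > 1)).any():
                raise ValueError("shared_column_fraction values must be in [0, 1]")
            self.shared_column_fraction = f


def _share_matrix(config: FamilySimConfig) -> np.ndarray:
    n = config.n_families
    f = config.shared_column_fraction
    if np.isscalar(f):
        m = np.full((n, n), float(f))
        np.fill_diagonal(m, 1.0)
        return m
    return np.asarray(f, float)


def simulate_family_set(
    config: FamilySimConfig,
) -> tuple[dict[str, list[tuple[str, str]]], dict[str, str], pd.DataFrame]:
    """Generate protein families with controlled cross-family conservation.

    The pairwise share matrix is realized hierarchically: a global core of
    columns (the matrix minimum) is identical across all families; families
    whose pairwise share exceeds that level form clans with additional
    shared columns.  Remaining columns are drawn independently per family.
    Members are the family consensus with i.i.d. per-residue substitutions
    at ``mutation_rate``.

    Returns
    -------
    members : dict family -> list of (member_id, sequence)
    consensus : dict family -> consensus sequence
    truth : DataFrame with one row per unordered family pair
        (``family_a, family_b, shared_fraction, relation``), relation being
        ``related`` when the planted share is >= 0.3, else ``unrelated``.
    """
    rng = np.random.default_rng(config.seed)
    n, L = config.n_families, config.profile_length
    fam_names = [f"fam{i:02d}" for i in range(n)]
    share = _share_matrix(config)

    # nested realization: merge families top-down by descending share level
    levels = sorted({share[i, j] for i in range(n) for j in range(i + 1, n)}, reverse=True)
    consensus_idx = np.empty((n, L), dtype=np.int64)
    consensus_idx[:] = rng.integers(0, 20, size=(n, L))

    # start independent; for each level (high to low) overwrite a shared
    # prefix of columns within each connected component at that level
    for level in levels:
        if level <= 0:
            continue
        k = int(round(level * L))
        comp = _components(share >= level - 1e-12, n)
        for group in comp:
            if len(group) < 2:
                continue
            block = rng.integers(0, 20, size=k)
            for i in group:
                consensus_idx[i, :k] = block
    # verify realizability: recompute planted shares and compare
    realized = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            realized[i, j] = realized[j, i] = np.mean(
                consensus_idx[i] == consensus_idx[j]
            )
    # random coincidences (~1/20 per column) inflate realized shares; only a
    # grossly non-nested matrix is rejected
    for i in range(n):
        for j in range(i + 1, n):
            if realized[i, j] + 1e-9 < share[i, j] - 0.1:
                raise ValueError(
                    "shared_column_fraction matrix is not realizable as a "
                    f"nested core structure (pair {fam_names[i]}, {fam_names[j]})"
                )

    members: dict[str, list[tuple[str, str]]] = {}
    consensus: dict[str, str] = {}
    for i, fam in enumerate(fam_names):
        cons = "".join(AA_ALPHABET[c] for c in consensus_idx[i])
        consensus[fam] = cons
        fam_members = []
        for m in range(config.members_per_family):
            seq = list(consensus_idx[i])
            mutate = rng.random(L) < config.mutation_rate
            for pos in np.nonzero(mutate)[0]:
                alt = rng.integers(0, 19)
                seq[pos] = alt if alt < seq[pos] else alt + 1
            fam_members.append(
                (f"{fam}_m{m:02d}", "".join(AA_ALPHABET[c] for c in seq))
            )
        members[fam] = fam_members

    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            rows.append(
                {
                    "family_a": fam_names[i],
                    "family_b": fam_names[j],
                    "shared_fraction": share[i, j],
                    "relation": "related" if share[i, j] >= 0.3 else "unrelated",
                }
            )
    truth = pd.DataFrame(rows, columns=["family_a", "family_b", "shared_fraction", "relation"])
    return members, consensus, truth


def _components(adj: np.ndarray, n: int) -> list[list[int]]:
    seen = [False] * n
    out = []
    for s in range(n):
        if seen[s]:
            continue
        stack, group = [s], []
        seen[s] = True
        while stack:
            u = stack.pop()
            group.append(u)
            for v in range(n):
                if adj[u, v] and not seen[v]:
                    seen[v] = True
                    stack.append(v)
        out.append(sorted(group))
    return out


@dataclass
class CodonSimConfig:
    """Parameters of the star-topology codon simulation.

    ``omega_map`` lists ``(start, end, omega)`` 1-based inclusive codon
    intervals that must tile ``[1, n_codons]`` without gaps or overlap;
    ``kappa`` is the transition/transversion proposal ratio and
    ``branch_length`` the expected number of proposed mutations per codon
    on each branch (the realized substitution rate is lower wherever
    selection rejects non-synonymous changes).
    """

    n_sequences: int
    n_codons: int
    omega_map: Sequence[tuple[int, int, float]] = dc_field(default_factory=list)
    kappa: float = 2.0
    branch_length: float = 0.1
    seed: int = 0
    code: int = 1

    def __post_init__(self):
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.branch_length < 0:
            raise ValueError("branch_length must be >= 0")
        if not self.omega_map:
            self.omega_map = [(1, self.n_codons, 1.0)]
        intervals = sorted(self.omega_map)
        expect = 1
        for start, end, omega in intervals:
            if omega < 0:
                raise ValueError(f"omega must be >= 0 in interval ({start}, {end})")
            if start != expect:
                raise ValueError(
                    f"omega_map intervals must tile [1, n_codons]: gap/overlap at {start}"
                )
            if end < start:
                raise ValueError(f"empty omega_map interval ({start}, {end})")
            expect = end + 1
        if expect != self.n_codons + 1:
            raise ValueError("omega_map intervals must end at n_codons")
        self.omega_map = intervals

    def omega_per_codon(self) -> np.ndarray:
        out = np.empty(self.n_codons)
        for start, end, omega in self.omega_map:
            out[start - 1 : end] = omega
        return out


def simulate_codon_msa(
    config: CodonSimConfig,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Evolve coding sequences from one ancestor on a star topology.

    A stop-free random ancestor is drawn; each sequence descends along an
    independent branch on which Poisson(branch_length * n_codons) point
    mutations are proposed (transitions ``kappa``-fold more often than each
    transversion).  A proposal is accepted with probability 1 when
    synonymous, with probability omega of its codon's interval when
    non-synonymous, and never when it creates a stop codon.

    Returns the sequences (ancestor excluded) and a truth table of accepted
    events (``sequence, codon, position, from_codon, to_codon, kind, ts``).
    """
    rng = np.random.default_rng(config.seed)
    table = _codon_table(config.code)
    stop = set(table.stop_codons)
    sense = [c for c in _CODONS if c not in stop]
    omega = config.omega_per_codon()

    ancestor = [sense[i] for i in rng.integers(0, len(sense), size=config.n_codons)]

    events = []
    seqs: list[tuple[str, str]] = []
    for s in range(config.n_sequences):
        codons = list(ancestor)
        n_prop = rng.poisson(config.branch_length * config.n_codons)
        for _ in range(n_prop):
            site = int(rng.integers(0, 3 * config.n_codons))
            ci, pos = divmod(site, 3)
            cur = codons[ci]
            base = cur[pos]
            alts = [b for b in NUCS if b != base]
            weights = np.array(
                [config.kappa if _is_transition(base, b) else 1.0 for b in alts]
            )
            alt = alts[rng.choice(3, p=weights / weights.sum())]
            new = cur[:pos] + alt + cur[pos + 1 :]
            if new in stop:
                continue
            syn = table.forward_table[new] == table.forward_table[cur]
            # relative fixation: non-synonymous changes fix omega-fold as
            # often as synonymous ones (syn damped when omega > 1 so the
            # realized dN/dS tracks omega on both sides of 1)
            w = omega[ci]
            accept_p = min(1.0, w) if not syn else min(1.0, 1.0 / w) if w > 1 else 1.0
            if rng.random() >= accept_p:
                continue
            codons[ci] = new
            events.append(
                {
                    "sequence": f"seq{s:03d}",
                    "codon": ci + 1,
                    "position": pos + 1,
                    "from_codon": cur,
                    "to_codon": new,
                    "kind": "synonymous" if syn else "nonsynonymous",
                    "ts": _is_transition(base, alt),
                }
            )
        seqs.append((f"seq{s:03d}", "".join(codons)))

    truth = pd.DataFrame(
        events,
        columns=["sequence", "codon", "position", "from_codon", "to_codon", "kind", "ts"],
    )
    truth.attrs["ancestor"] = "".join(ancestor)
    return seqs, truth


def make_presence_matrix(
    n_families: int,
    phyla: Sequence[str],
    class_assignment: Mapping[str, str] | Sequence[str],
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Family-by-phylum occupancy fractions with planted conservation classes.

    ``wide`` families draw occupancy in [0.9, 1.0] per phylum, ``midlow``
    in [0.3, 0.7] (centered at 0.5), ``absent`` in [0, 0.05].

    Returns the occupancy matrix and the planted class per family.
    """
    if not phyla:
        raise ValueError("phylum list must be non-empty")
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    fam_names = [f"fam{i:02d}" for i in range(n_families)]
    if isinstance(class_assignment, Mapping):
        classes = [class_assignment[f] for f in fam_names]
    else:
        classes = list(class_assignment)
        if len(classes) != n_families:
            raise ValueError("class_assignment length must equal n_families")
    valid = {"wide", "midlow", "absent"}
    bad = set(classes) - valid
    if bad:
        raise ValueError(f"unknown conservation classes: {sorted(bad)}")

    rng = np.random.default_rng(seed)
    rows = []
    for cls in classes:
        if cls == "wide":
            row = rng.uniform(0.9, 1.0, size=len(phyla))
        elif cls == "midlow":
            row = rng.uniform(0.3, 0.7, size=len(phyla))
        else:
            row = rng.uniform(0.0, 0.05, size=len(phyla))
        rows.append(row)
    matrix = pd.DataFrame(rows, index=fam_names, columns=list(phyla))
    return matrix, pd.Series(classes, index=fam_names, name="class")


def make_composition_table(
    group_effects: Mapping[str, Mapping[str, float]],
    families_per_group: int = 10,
    noise_sd: float = 0.1,
    seed: int = 0,
    background: np.ndarray | None = None,
):
    """Family composition tables with planted per-group log2 enrichments.

    Each family's frequencies are ``background * 2**(shift + noise)``
    renormalized to sum 1, where ``shift`` is the group's per-residue log2
    effect and ``noise`` is N(0, noise_sd) per residue.  With zero effects
    and zero noise every row equals the background vector exactly.

    Returns a :class:`mtevol.composition.CompositionTable`.
    """
    from mtevol.composition import CompositionTable

    if families_per_group < 1:
        raise ValueError("families_per_group must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    bg = BACKGROUND_COMPOSITION if background is None else np.asarray(background, float)
    if bg.shape != (20,) or (bg <= 0).any():
        raise ValueError("background must be 20 positive frequencies")
    bg = bg / bg.sum()

    aa_index = {a: i for i, a in enumerate(AA_ALPHABET)}
    rng = np.random.default_rng(seed)
    rows, groups, names = [], [], []
    for group in group_effects:
        shift = np.zeros(20)
        for aa, eff in group_effects[group].items():
            if aa not in aa_index:
                raise ValueError(f"unknown residue in group_effects: {aa!r}")
            shift[aa_index[aa]] = eff
        for k in range(families_per_group):
            noise = rng.normal(0.0, noise_sd, size=20) if noise_sd > 0 else 0.0
            freq = bg * np.exp2(shift + noise)
            if (freq <= 0).any():
                raise ValueError("shifts produced non-positive frequencies")
            freq = freq / freq.sum()
            rows.append(freq)
            groups.append(group)
            names.append(f"{group}_fam{k:02d}")
    frame = pd.DataFrame(rows, index=names, columns=list(AA_ALPHABET))
    return CompositionTable(frame=frame, groups=pd.Series(groups, index=names))
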
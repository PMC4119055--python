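import numpy as np
import pandas as pd
import pytest

from mtevol.composition import CompositionTable
from mtevol.profiles import AA_ALPHABET


@pytest.fixture
def rng():
    return np.random.default_rng(20240710)


@pytest.fixture
def toy_composition_table():
    """Four groups x 3 families with distinct, valid composition rows."""
    rng = np.random.default_rng(5)
    rows, groups, names = [], [], []
    for g in ("16S", "23S", "tRNA", "non-RNA"):
        for k in range(3):
            v = rng.dirichlet(np.ones(20) * 5)
            rows.append(v)
            groups.append(g)
            names.append(f"{g}_{k}")
    frame = pd.DataFrame(rows, index=names, columns=list(AA_ALPHABET))
    return CompositionTable(frame=frame, groups=pd.Series(groups, index=names))


def random_sense_codons(rng, n):
    """Random stop-free codon string of length 3n."""
    from mtevol.codon import _CODONS, _codon_table

    stops = set(_codon_table(1).stop_codons)
    sense = [c for c in _CODONS if c not in stops]
    return "".join(sense[i] for i in rng.integers(0, len(sense), size=n))
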
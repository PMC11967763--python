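import numpy as np
import pytest

from pdoconcord import CopyProfilePair, GeneCopyState, SimConfig


@pytest.fixture
def default_cfg() -> SimConfig:
    return SimConfig(seed=0)


def random_pair(rng: np.random.Generator, n_genes: int = 50,
                sample_id: str = "P") -> CopyProfilePair:
    """Arbitrary valid copy-profile pair (not from the event generator)."""

    def states():
        cn = rng.integers(0, 5, size=(n_genes, 2)).astype(float)
        hi, lo = cn.max(axis=1), cn.min(axis=1)
        return tuple(
            GeneCopyState(f"G{i:03d}", float(a), float(b))
            for i, (a, b) in enumerate(zip(hi, lo))
        )

    return CopyProfilePair(sample_id=sample_id, tumor=states(), organoid=states())


def brute_force_similarity(pair: CopyProfilePair):
    """Independent re-evaluation of d, d', s with plain Python arithmetic."""
    import math

    d = [
        math.sqrt((t.cnA - o.cnA) ** 2 + (t.cnB - o.cnB) ** 2)
        for t, o in zip(pair.tumor, pair.organoid)
    ]
    dmin, dmax = min(d), max(d)
    if dmax == dmin:
        s = [1.0] * len(d)
    else:
        s = [1.0 - (di - dmin) / (dmax - dmin) for di in d]
    return d, s, sum(s) / len(s)
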
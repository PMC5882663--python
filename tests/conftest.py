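import itertools

import numpy as np
import pytest

from gastruquant.synthetic_data import TissueParams

#: small tissue used wherever many tissues must be generated
COMPACT = dict(n_rows=7, n_paraxial_cols=2, n_exterior_cols=0)


@pytest.fixture
def compact_params():
    def _make(seed=0, **kw):
        return TissueParams(seed=seed, **{**COMPACT, **kw})

    return _make


@pytest.fixture
def stripe_image():
    """10×10 grid split into two vertical stripes (labels 1, 2)."""
    img = np.zeros((10, 10), dtype=int)
    img[:, :5] = 1
    img[:, 5:] = 2
    return img


def brute_force_adjacency(lab, min_pairs=2):
    """Independent pixel-pair scan defining the adjacency oracle."""
    counts = {}
    h, w = lab.shape
    for r in range(h):
        for c in range(w):
            for dr, dc in ((0, 1), (1, 0)):
                rr, cc = r + dr, c + dc
                if rr < h and cc < w:
                    a, b = int(lab[r, c]), int(lab[rr, cc])
                    if a != b and a > 0 and b > 0:
                        key = frozenset((a, b))
                        counts[key] = counts.get(key, 0) + 1
    return {k for k, v in counts.items() if v >= min_pairs}


def permutation_pvalue(a, b, stat_fn, obs):
    """Exhaustive two-sample permutation p-value, P(stat >= obs)."""
    pooled = np.concatenate([a, b])
    n = len(a)
    cnt = tot = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        tot += 1
        if stat_fn(pooled[mask], pooled[~mask]) >= obs - 1e-12:
            cnt += 1
    return cnt / tot
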
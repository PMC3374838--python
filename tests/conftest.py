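import math

import numpy as np
import pytest

from locotrack.synthetic import GenotypeParams, SimConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def wt_params():
    # stationary within-track speed SD 0.037 mm/s at theta = 0.5/s
    return GenotypeParams(
        "wt", mu_speed=0.15, theta=0.5, sigma=0.037, turn_sd=0.5, mu_sd=0.031
    )


@pytest.fixture
def small_dataset(wt_params):
    """Five-animal clean assay (no dropout) with ground truth."""
    cfg = SimConfig(n_animals=5, duration_s=60.0, dropout_prob=0.0, seed=7)
    frames, gt = generate_dataset(cfg, [wt_params])
    return cfg, frames, gt


def brute_force_events(accel, dt=1.0):
    """Independent sign-run enumerator: walks the series sample by sample
    and records (sign, start index, length, peak) for each maximal strictly
    same-sign run.  Exact zeros belong to no run."""
    runs = []
    cur_sign, start = 0, None
    for i, a in enumerate(list(accel) + [0.0]):  # sentinel flushes last run
        s = int(a > 0) - int(a < 0)
        if s != cur_sign:
            if cur_sign != 0:
                seg = accel[start:i]
                peak = max(seg) if cur_sign > 0 else min(seg)
                runs.append((cur_sign, start * dt, (i - start) * dt, float(peak)))
            cur_sign, start = s, i
    return runs


def brute_force_matching(heads, dets, max_disp):
    """Enumerate all one-to-one matchings of admissible pairs; return the
    best (max cardinality, then min total distance)."""
    import itertools

    heads = np.atleast_2d(heads) if len(heads) else np.empty((0, 2))
    dets = np.atleast_2d(dets) if len(dets) else np.empty((0, 2))
    m, k = len(heads), len(dets)
    d = np.array(
        [[math.dist(heads[i], dets[j]) for j in range(k)] for i in range(m)]
    ).reshape(m, k)
    best = (0, 0.0, [])
    for r in range(min(m, k), -1, -1):
        found = None
        for hs in itertools.combinations(range(m), r):
            for ds in itertools.permutations(range(k), r):
                if all(d[i, j] <= max_disp for i, j in zip(hs, ds)):
                    cost = sum(d[i, j] for i, j in zip(hs, ds))
                    if found is None or cost < found[0]:
                        found = (cost, list(zip(hs, ds)))
        if found is not None:
            best = (r, found[0], found[1])
            break
    return best  # (cardinality, total cost, pairs)
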
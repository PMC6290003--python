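import numpy as np
import pytest

from tensionfret.synthetic_scenes import PunctumSpec, SceneSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def three_spot_scene():
    """Three well-separated FLIM puncta with a common lifetime."""
    spots = [
        PunctumSpec((12.0, 12.0), 1.5, 150.0, 2.0),
        PunctumSpec((30.0, 40.0), 1.5, 150.0, 2.0),
        PunctumSpec((45.0, 20.0), 1.5, 150.0, 2.0),
    ]
    return SceneSpec(image_shape=(56, 56), puncta=spots, seed=3)


def grid_search_tau(counts, bin_width_ns, offset_ns=0.56, lo=0.5, hi=6.0, step=0.001):
    """Brute-force Poisson likelihood grid oracle for the lifetime MLE.

    Independent of the fitter: evaluates the full Poisson log-pmf at each
    grid lifetime with the ML amplitude for that lifetime.
    """
    from scipy.stats import poisson

    counts = np.asarray(counts, dtype=float)
    peak = int(np.argmax(counts))
    start = peak + int(np.ceil(offset_ns / bin_width_ns - 1e-12))
    window = counts[start:]
    t = (np.arange(start, counts.size) + 0.5) * bin_width_ns
    taus = np.arange(lo, hi + step / 2, step)
    best_tau, best_ll = None, -np.inf
    for tau in taus:
        shape = np.exp(-t / tau)
        amp = window.sum() / shape.sum()
        ll = poisson.logpmf(np.round(window), amp * shape).sum()
        if ll > best_ll:
            best_ll, best_tau = ll, tau
    return best_tau


def brute_force_matching(a, b, max_disp):
    """Exhaustive maximum-cardinality, minimum-total-distance matching."""
    from itertools import combinations, permutations

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    best_pairs, best_card, best_cost = [], 0, np.inf
    small, large, swap = (range(na), range(nb), False) if na <= nb else (range(nb), range(na), True)
    k = len(list(small))
    for subset in combinations(large, k):
        for perm in permutations(subset):
            pairs, cost = [], 0.0
            for i, j in zip(small, perm):
                ai, bj = (i, j) if not swap else (j, i)
                d = float(np.hypot(*(a[ai] - b[bj])))
                if d <= max_disp:
                    pairs.append((ai, bj))
                    cost += d
            card = len(pairs)
            if card > best_card or (card == best_card and cost < best_cost - 1e-12):
                best_pairs, best_card, best_cost = pairs, card, cost
    return best_pairs, best_cost


def ecdf_sup_distance(a, b):
    """Direct ECDF-supremum two-sample KS statistic."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / len(a)
    fb = np.searchsorted(b, grid, side="right") / len(b)
    return float(np.max(np.abs(fa - fb)))
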
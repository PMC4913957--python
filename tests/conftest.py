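import numpy as np
import pytest

from droughtfire.classify import RuleSet, fit_tree
from droughtfire.climate import FEATURE_NAMES
from droughtfire.synthetic import gen_climate, gen_scene


@pytest.fixture(scope="session")
def rules():
    return RuleSet()


@pytest.fixture(scope="session")
def med_climate():
    """Four years of seeded Mediterranean forcing for one site."""
    return gen_climate("mediterranean", years=4, seed=7)


@pytest.fixture(scope="session")
def small_scene():
    """A quick 144-pixel scene (288 pixel-years) for pipeline-level tests."""
    return gen_scene((12, 12), seed=5)


@pytest.fixture(scope="session")
def big_scene():
    """The 20,000-pixel-year scene used for threshold-recovery checks.

    10,000 pixels (mixed mediterranean / summer-rain), two fire years, the
    default rule set, 5 % label flips, seed 42.
    """
    return gen_scene((100, 100), seed=42, flip_rate=0.05)


@pytest.fixture(scope="session")
def big_scene_tree(big_scene):
    f = big_scene.features
    return fit_tree(
        f[list(FEATURE_NAMES)], f["label"], folds=10, seed=42, min_node=20
    )


def brute_force_root_split(X, y, min_node):
    """Exhaustive-search oracle for the best Gini root split.

    Enumerates every feature and every separating midpoint, computes child
    impurities from first principles, and applies the same tie-breaks the
    inducer documents (lowest feature index, then smallest threshold).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    n = len(y)

    def gini(labels):
        if len(labels) == 0:
            return 0.0
        p = labels.mean()
        return 1.0 - p**2 - (1.0 - p) ** 2

    parent = gini(y)
    best = None
    for j in range(X.shape[1]):
        values = np.unique(X[:, j])
        for a, b in zip(values, values[1:]):
            thr = 0.5 * (a + b)
            if not a < thr < b:
                continue
            left = X[:, j] <= thr
            nl = int(left.sum())
            if nl < min_node or n - nl < min_node:
                continue
            gain = parent - (nl * gini(y[left]) + (n - nl) * gini(y[~left])) / n
            if best is None or gain > best[0] + 1e-12:
                best = (gain, j, thr)
    if best is None or best[0] <= 1e-12:
        return None
    return best[1], best[2], best[0]
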
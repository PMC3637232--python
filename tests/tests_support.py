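"""Helpers shared by the test modules."""

import numpy as np

from icamam import classify as cl
from icamam import evaluate as ev

COARSE_GAMMA_EXPS = np.arange(-9.0, 0.1, 2.0)
COARSE_C_EXPS = np.arange(-1.0, 6.1, 2.0)
FAST_RPROP = cl.RpropConfig(max_epochs=200, patience=40)


def coarse_experiment(protos, site, q=10, classifier="svm", seed=0, **kw):
    """run_site_experiment with decimated hyperparameter grids."""
    return ev.run_site_experiment(
        protos, site, q=q, classifier=classifier, seed=seed,
        gamma_exps=COARSE_GAMMA_EXPS, C_exps=COARSE_C_EXPS,
        H_grid=(50,), restarts=2, rprop_cfg=FAST_RPROP, **kw)


def amari_index(P: np.ndarray) -> float:
    """Permutation/scale-invariant distance of P from a signed permutation."""
    P = np.abs(np.asarray(P, dtype=float))
    n = P.shape[0]
    rows = (P / P.max(axis=1, keepdims=True)).sum() - n
    cols = (P / P.max(axis=0, keepdims=True)).sum() - n
    return float((rows + cols) / (2 * n * (n - 1)))


def nongaussian_sources(n: int, rng: np.random.Generator) -> np.ndarray:
    """Three independent non-Gaussian sources (uniform, Laplace, bimodal)."""
    return np.vstack([
        rng.uniform(-np.sqrt(3), np.sqrt(3), n),
        rng.laplace(0.0, 1.0 / np.sqrt(2), n),
        np.sign(rng.standard_normal(n)) * rng.gamma(2.0, 0.5, n),
    ])
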
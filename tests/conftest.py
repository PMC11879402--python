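import numpy as np
import pandas as pd
import pytest

from imodest import SimulationConfig, simulate_paired, preprocess_cohort
from imodest.regulators import ModelSpec


class ValueEnsemble:
    """Mock ensemble whose per-spec scores are set directly; used to test
    the gain decomposition against hand-computable value functions."""

    def __init__(self, values, gene="g", cohort_id="c"):
        self.gene = gene
        self.cohort_id = cohort_id
        self._values = {frozenset(k): v for k, v in values.items()}
        self.fits = {ModelSpec(frozenset(k)): None
                     for k in values if len(k)}

    def press(self, spec, score="deflated"):
        return self._values.get(spec.classes)


@pytest.fixture
def value_ensemble_factory():
    return ValueEnsemble


@pytest.fixture(scope="session")
def small_paired():
    """One small paired tumor/adjacent simulation shared across tests."""
    cfg = SimulationConfig(n_samples=120, n_genes=6, seed=7,
                           n_mirna=40, n_tf=50,
                           probes_per_gene=6, snps_per_gene=8)
    return cfg, *simulate_paired(cfg)


@pytest.fixture(scope="session")
def small_prepared(small_paired):
    _cfg, tumor, adjacent = small_paired
    return preprocess_cohort(tumor), preprocess_cohort(adjacent)


def naive_elastic_net(X, y, lam, alpha=0.5, tol=1e-13, max_iter=200_000):
    """Textbook residual-update coordinate descent on centered copies of
    the data; an implementation-independent oracle for the solver.

    Minimizes (1/2n)||y - b0 - Xb||^2 + lam*(alpha*|b|_1
    + (1-alpha)/2*|b|_2^2).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    ss = (Xc ** 2).sum(axis=0)
    b = np.zeros(p)
    r = yc.copy()
    l1, l2 = lam * alpha, lam * (1 - alpha)
    for _ in range(max_iter):
        dmax = 0.0
        for j in range(p):
            rho = Xc[:, j] @ r / n + ss[j] / n * b[j]
            denom = ss[j] / n + l2
            if denom <= 0:
                bj = 0.0
            else:
                bj = np.sign(rho) * max(abs(rho) - l1, 0.0) / denom
            if bj != b[j]:
                r -= Xc[:, j] * (bj - b[j])
                dmax = max(dmax, abs(bj - b[j]))
                b[j] = bj
        if dmax < tol:
            break
    b0 = ym - xm @ b
    return b, b0


def naive_loo_press(X, y, lam, alpha=0.5):
    """Leave-one-out PRESS R^2 by refitting from scratch on every fold."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        b, b0 = naive_elastic_net(X[keep], y[keep], lam, alpha)
        preds[i] = b0 + X[i] @ b
    tss = ((y - y.mean()) ** 2).sum()
    return 1.0 - ((y - preds) ** 2).sum() / tss


def enet_objective(X, y, b, b0, lam, alpha=0.5):
    n = len(y)
    resid = y - b0 - X @ b
    return ((resid ** 2).sum() / (2 * n)
            + lam * (alpha * np.abs(b).sum()
                     + (1 - alpha) / 2 * (b ** 2).sum()))
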
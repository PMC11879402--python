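"""Model engine: enumerate regulator-combination models, fit elastic nets,
and score them by leave-one-out PRESS R² with Monte-Carlo deflation.

For every gene and every non-empty subset of the admitted regulator
classes, an elastic net (mixing parameter 0.5) is fit to the standardized
expression.  The penalty strength λ is chosen once per (gene, spec) by
10-fold cross-validation on the full sample and then held fixed while each
sample is left out and exactly refit, giving

    PRESS R² = 1 - SSE / TSS,
    SSE = Σ_i (y_i - ŷ_{-i})²,   TSS = Σ_i (y_i - ȳ)².

The intercept-only null baseline predicts each sample by the mean of the
others, so its PRESS R² is 1 - (n/(n-1))² < 0 for any response.

The deflation value of a gene is the mean PRESS R² of purely random
predictions ŷ_{-i} ~ Normal(mean_{-i}, sd_{-i}); positive deflation values
are subtracted from every model's score (negative ones — the usual case —
leave scores untouched).  One deflation value is shared by all 63 specs of
a (gene, cohort), since it depends only on y.

Transfer scores apply tumor-trained coefficients, unchanged, to a
tumor-adjacent cohort and report the plain out-of-sample R².
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _solver
from .annotations import CIS_WINDOW, admitted_features
from .preprocess import PreparedCohort
from .regulators import (CLASS_ORDER, ModelSpec, NULL_SPEC, class_index,
                         enumerate_models)

MIXING = 0.5
DEFAULT_DEFLATION_RUNS = 1000
CD_TOL = 1e-10
CD_MAX_ITER = 100_000


def gene_seed(seed: int, gene_id: str) -> int:
    """Stable per-gene seed (< 2^31) derived from the pipeline seed, so
    per-gene random streams are reproducible under any execution order."""
    return (int(seed) * 1_000_003 + zlib.crc32(gene_id.encode())) % (2**31 - 1)


# ---------------------------------------------------------------------------
# elastic net

@dataclass
class ElasticNetFit:
    coef: np.ndarray
    intercept: float
    lam: float


def lambda_path(X: np.ndarray, y: np.ndarray, mixing: float = MIXING,
                n_lambdas: int = 30, min_ratio: float = 1e-3) -> np.ndarray:
    """Descending log-spaced λ path from λ_max (the smallest λ with an
    all-zero solution) down to ``min_ratio * λ_max``."""
    n = len(y)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    lam_max = np.abs(xc.T @ yc).max() / (n * mixing)
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambdas)


def fit_elastic_net(X: np.ndarray, y: np.ndarray, mixing: float = MIXING,
                    lam: float | None = None, n_lambdas: int = 30,
                    min_ratio: float = 1e-3, cv_folds: int = 10,
                    seed: int = 0, fold_ids: np.ndarray | None = None
                    ) -> ElasticNetFit:
    """Fit an elastic net; if ``lam`` is None, select it by K-fold
    cross-validation over the λ path (minimum held-out SSE), then refit on
    the full data warm-started down the path."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if p == 0:
        raise ValueError("design has no columns")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in design or response")
    lams = lambda_path(X, y, mixing, n_lambdas, min_ratio)
    if lam is None:
        if fold_ids is None:
            fold_ids = make_folds(n, cv_folds, seed)
        k = int(fold_ids.max()) + 1
        sse = _solver.cv_path_sse(X, y, lams, mixing, fold_ids, k,
                                  CD_TOL, CD_MAX_ITER)
        lam = float(lams[int(np.argmin(sse))])
    path = lams[lams >= lam]
    if len(path) == 0 or path[-1] != lam:
        path = np.append(path, lam)
    beta, b0 = _solver.fit_path(X, y, path, mixing, CD_TOL, CD_MAX_ITER)
    return ElasticNetFit(coef=beta, intercept=float(b0), lam=float(lam))


def make_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Shuffled round-robin fold assignment (k capped at n)."""
    rng = np.random.default_rng(seed)
    k = max(2, min(k, n))
    ids = np.arange(n) % k
    rng.shuffle(ids)
    return ids.astype(np.int64)


# ---------------------------------------------------------------------------
# PRESS

def press_from_predictions(y: np.ndarray, preds: np.ndarray) -> float:
    """1 - SSE/TSS for arbitrary held-out predictions."""
    y = np.asarray(y, dtype=float)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("degenerate response: zero total sum of squares")
    sse = float(((y - preds) ** 2).sum())
    return 1.0 - sse / tss


def null_press_r2(y: np.ndarray) -> float:
    """Intercept-only leave-one-out PRESS R² (each sample predicted by the
    mean of the others); algebraically equal to 1 - (n/(n-1))²."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 samples")
    preds = (y.sum() - y) / (n - 1)
    return press_from_predictions(y, preds)


def press_r2_loo(X: np.ndarray, y: np.ndarray, lam: float,
                 mixing: float = MIXING,
                 beta_init: np.ndarray | None = None):
    """Exact leave-one-out PRESS R² at a fixed λ.

    Returns (press, per-sample held-out predictions).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if beta_init is None:
        beta_init = np.zeros(X.shape[1])
    preds = _solver.loo_predictions(X, y, lam, mixing,
                                    np.ascontiguousarray(beta_init,
                                                         dtype=np.float64),
                                    CD_TOL, CD_MAX_ITER)
    return press_from_predictions(y, preds), preds


def compute_deflation(y: np.ndarray, runs: int = DEFAULT_DEFLATION_RUNS,
                      seed: int = 0, return_runs: bool = False):
    """Mean PRESS R² of random predictions ŷ_{-i} ~ N(mean_{-i}, sd_{-i}).

    mean_{-i} and sd_{-i} (n-1 denominator over the n-1 remaining values)
    summarize the sample without individual i, mimicking a model with no
    information beyond the training fold's location and spread.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 samples")
    if runs < 1:
        raise ValueError("runs must be >= 1")
    rng = np.random.default_rng(seed)
    s1, s2 = y.sum(), (y**2).sum()
    mean_i = (s1 - y) / (n - 1)
    var_i = (s2 - y**2 - (n - 1) * mean_i**2) / (n - 2)
    sd_i = np.sqrt(np.maximum(var_i, 0.0))
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        raise ValueError("degenerate response: zero total sum of squares")
    draws = mean_i + sd_i * rng.standard_normal((runs, n))
    press = 1.0 - ((y - draws) ** 2).sum(axis=1) / tss
    return (float(press.mean()), press) if return_runs \
        else float(press.mean())


def apply_deflation(raw: float, deflation: float) -> float:
    """Subtract the deflation value only when it is strictly positive."""
    return raw - deflation if deflation > 0 else raw


# ---------------------------------------------------------------------------
# design construction

def build_design(cohort: PreparedCohort, gene: str, spec: ModelSpec,
                 window: int = CIS_WINDOW):
    """Column-concatenated predictor blocks for the spec's classes.

    Returns (X DataFrame with (class, feature) MultiIndex columns,
    list of classes that contributed zero columns).
    """
    blocks, empty = [], []
    for cls in spec:
        mat = cohort.matrices.get(cls)
        if mat is None:
            empty.append(cls)
            continue
        feats = admitted_features(cohort.annotations, gene, cls, window)
        feats = [f for f in feats if f in mat.columns]
        if not feats:
            empty.append(cls)
            continue
        block = mat[feats].copy()
        block.columns = pd.MultiIndex.from_product([[cls], feats])
        blocks.append(block)
    if not blocks:
        return pd.DataFrame(index=cohort.expression.index), empty
    return pd.concat(blocks, axis=1), empty


# ---------------------------------------------------------------------------
# results

@dataclass
class FitResult:
    """One fitted (gene, cohort, spec) model and its scores."""

    gene: str
    cohort_id: str
    spec: ModelSpec
    coefficients: pd.Series         # (class, feature) -> weight, zeros kept
    intercept: float
    lam: float
    press_r2_raw: float
    deflation: float
    n_samples: int
    transfer_r2: float | None = None

    @property
    def press_r2(self) -> float:
        return apply_deflation(self.press_r2_raw, self.deflation)


@dataclass
class EnsembleResult:
    """All fitted specs of one (gene, cohort) plus the null baseline."""

    gene: str
    cohort_id: str
    n_samples: int
    fits: dict                       # ModelSpec -> FitResult
    null_press_raw: float
    deflation: float
    skipped: dict = field(default_factory=dict)   # ModelSpec -> reason

    @property
    def null_press(self) -> float:
        return apply_deflation(self.null_press_raw, self.deflation)

    def press(self, spec: ModelSpec, score: str = "deflated"):
        """Score of a spec (the empty spec is the null baseline); None if
        the spec was skipped or the requested score is unavailable."""
        if len(spec) == 0:
            if score == "transfer":
                return self.null_transfer
            return self.null_press if score == "deflated" \
                else self.null_press_raw
        fit = self.fits.get(spec)
        if fit is None:
            return None
        if score == "deflated":
            return fit.press_r2
        if score == "raw":
            return fit.press_r2_raw
        if score == "transfer":
            return fit.transfer_r2
        raise ValueError(f"unknown score {score!r}")

    null_transfer: float | None = None

    @property
    def unmodelable(self) -> bool:
        return len(self.fits) == 0

    def classes_present(self):
        present = set()
        for spec in self.fits:
            present |= spec.classes
        return sorted(present, key=class_index)


def transfer_score(fit: FitResult, adjacent: PreparedCohort,
                   window: int = CIS_WINDOW) -> float | None:
    """Out-of-sample R² of tumor-trained coefficients on the adjacent
    cohort (no refitting, no leave-one-out).  Model features missing from
    the adjacent cohort contribute 0 (their mean on the standardized
    scale), with a warning.  Returns None when the gene is absent."""
    if fit.gene not in adjacent.expression.columns:
        return None
    y = adjacent.expression[fit.gene].to_numpy()
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        return None
    pred = np.full(len(y), fit.intercept)
    missing = 0
    for (cls, feat), w in fit.coefficients.items():
        if w == 0.0:
            continue
        mat = adjacent.matrices.get(cls)
        if mat is None or feat not in mat.columns:
            missing += 1
            continue
        pred += w * mat[feat].to_numpy()
    if missing:
        warnings.warn(f"{missing} model features absent from adjacent "
                      "cohort; treated as mean (0)")
    sse = ((y - pred) ** 2).sum()
    return float(1.0 - sse / tss)


def fit_ensemble(cohort: PreparedCohort, gene: str,
                 adjacent: PreparedCohort | None = None,
                 classes=CLASS_ORDER, seed: int = 0,
                 deflation_runs: int = DEFAULT_DEFLATION_RUNS,
                 mixing: float = MIXING, n_lambdas: int = 30,
                 min_ratio: float = 1e-3, cv_folds: int = 10,
                 window: int = CIS_WINDOW) -> EnsembleResult:
    """Fit every non-empty regulator-class combination for one gene.

    One shared deflation value per (gene, cohort); the same CV fold
    assignment is reused across specs.  Specs with no admissible features
    are skipped with reason "no features".
    """
    if gene not in cohort.expression.columns:
        raise KeyError(f"gene {gene!r} not in cohort expression")
    y = np.ascontiguousarray(cohort.expression[gene].to_numpy(),
                             dtype=np.float64)
    n = len(y)
    gseed = gene_seed(seed, gene)
    deflation = compute_deflation(y, runs=deflation_runs, seed=gseed)
    fold_ids = make_folds(n, cv_folds, (gseed + 1) % (2**31 - 1))
    null_raw = null_press_r2(y)

    # per-class blocks are spec-independent; build once
    full_spec = ModelSpec(frozenset(classes))
    full_X, _ = build_design(cohort, gene, full_spec, window)
    class_cols = {cls: [c for c in full_X.columns if c[0] == cls]
                  for cls in classes}

    fits, skipped = {}, {}
    for spec in enumerate_models(classes):
        # a spec is only fitted when every member class contributes at
        # least one column; otherwise it would duplicate a smaller spec
        missing = [cl for cl in spec if not class_cols[cl]]
        if missing:
            skipped[spec] = "no features: " + ",".join(missing)
            continue
        cols = [c for cl in spec for c in class_cols[cl]]
        Xdf = full_X[cols]
        X = np.ascontiguousarray(Xdf.to_numpy(), dtype=np.float64)
        enet = fit_elastic_net(X, y, mixing=mixing, n_lambdas=n_lambdas,
                               min_ratio=min_ratio, fold_ids=fold_ids)
        raw, _ = press_r2_loo(X, y, enet.lam, mixing, enet.coef)
        fit = FitResult(gene=gene, cohort_id=cohort.cohort_id, spec=spec,
                        coefficients=pd.Series(enet.coef, index=Xdf.columns),
                        intercept=enet.intercept, lam=enet.lam,
                        press_r2_raw=raw, deflation=deflation, n_samples=n)
        if adjacent is not None:
            fit.transfer_r2 = transfer_score(fit, adjacent, window)
        fits[spec] = fit

    ens = EnsembleResult(gene=gene, cohort_id=cohort.cohort_id, n_samples=n,
                         fits=fits, null_press_raw=null_raw,
                         deflation=deflation, skipped=skipped)
    if adjacent is not None and gene in adjacent.expression.columns:
        ya = adjacent.expression[gene].to_numpy()
        tss = ((ya - ya.mean()) ** 2).sum()
        # null model transfers as "predict the training mean" = intercept
        if tss > 0:
            ens.null_transfer = float(1.0 - ((ya - y.mean()) ** 2).sum()
                                      / tss)
    return ens


def press_r2(cohort: PreparedCohort, gene: str, spec: ModelSpec,
             seed: int = 0, mixing: float = MIXING,
             window: int = CIS_WINDOW, **kwargs):
    """Raw leave-one-out PRESS R² of one (gene, spec) plus the full-data
    coefficients.  The empty spec returns the intercept-only closed form."""
    y = np.ascontiguousarray(cohort.expression[gene].to_numpy(),
                             dtype=np.float64)
    if len(spec) == 0:
        return null_press_r2(y), pd.Series(dtype=float)
    Xdf, _ = build_design(cohort, gene, spec, window)
    if Xdf.shape[1] == 0:
        raise ValueError(f"spec {spec.label} has no features for {gene}")
    X = np.ascontiguousarray(Xdf.to_numpy(), dtype=np.float64)
    gseed = gene_seed(seed, gene)
    fold_ids = make_folds(len(y), kwargs.pop("cv_folds", 10),
                          (gseed + 1) % (2**31 - 1))
    enet = fit_elastic_net(X, y, mixing=mixing, fold_ids=fold_ids, **kwargs)
    raw, _ = press_r2_loo(X, y, enet.lam, mixing, enet.coef)
    return raw, pd.Series(enet.coef, index=Xdf.columns)
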
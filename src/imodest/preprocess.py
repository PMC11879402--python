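"""Per-data-type preprocessing: standardization, covariate residualization,
methylation beta->M conversion, SNP quality control and PCA-based sample
outlier removal.

Every regulator matrix and the expression matrix go through the same
recipe before model fitting: (optional log transform ->) per-feature
z-scoring -> per-feature ordinary-least-squares residualization against
the covariate design -> re-standardization.  Tumor cohorts are corrected
for the full covariate set (sex, batch, the first two genotype principal
components, tumor purity, age, histology); tumor-adjacent cohorts use the
reduced set (sex, batch, PC1, PC2) in a separate model.

Standard deviations use the n-1 denominator throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .regulators import CLASS_ORDER, METH, SNP

TUMOR_COVARIATES = ("sex", "batch", "PC1", "PC2", "purity", "age",
                    "histology")
NORMAL_COVARIATES = ("sex", "batch", "PC1", "PC2")
BETA_CLIP = 1e-6


@dataclass
class OmicsMatrix:
    """One regulator class's samples x features matrix plus bookkeeping."""

    values: pd.DataFrame
    cls: str
    state: str = "raw"          # raw | standardized | residualized

    @property
    def samples(self):
        return list(self.values.index)

    @property
    def feature_ids(self):
        return list(self.values.columns)


@dataclass
class CovariateTable:
    """Per-sample covariates; categorical columns become dummy contrasts in
    the residualization design."""

    table: pd.DataFrame

    CATEGORICAL = ("sex", "batch", "histology")

    def __post_init__(self):
        if self.table.isna().any().any():
            raise ValueError("covariate table contains missing values")

    def design_matrix(self, mode: str = "tumor") -> pd.DataFrame:
        """Intercept + numeric columns + dummy-coded categoricals for the
        requested correction mode ('tumor' = full set, 'normal' = reduced)."""
        cols = TUMOR_COVARIATES if mode == "tumor" else NORMAL_COVARIATES
        cols = [c for c in cols if c in self.table.columns]
        parts = [pd.Series(1.0, index=self.table.index, name="intercept")]
        for c in cols:
            if c in self.CATEGORICAL:
                dum = pd.get_dummies(self.table[c], prefix=c,
                                     drop_first=True, dtype=float)
                parts.append(dum)
            else:
                parts.append(self.table[c].astype(float))
        return pd.concat(parts, axis=1)


def standardize(matrix: OmicsMatrix, log_transform: bool = False
                ) -> tuple[OmicsMatrix, list[str]]:
    """Per-feature z-score (subtract mean, divide by n-1 sd); constant
    features are dropped and returned in the report list.

    ``log_transform`` applies log(x+1) first (expression counts); values
    must then exceed -1.
    """
    vals = matrix.values.to_numpy(float)
    if vals.shape[1] == 0:
        return OmicsMatrix(matrix.values.copy(), matrix.cls,
                           "standardized"), []
    if not np.isfinite(vals).all():
        raise ValueError("matrix contains non-finite values")
    if log_transform:
        if (vals <= -1).any():
            raise ValueError("log transform requires values > -1")
        vals = np.log1p(vals)
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [f for f, k in zip(matrix.values.columns, keep) if not k]
    if not keep.any():
        raise ValueError(f"all {matrix.cls} features are constant; "
                         "standardization would produce an empty matrix")
    z = (vals[:, keep] - mu[keep]) / sd[keep]
    out = pd.DataFrame(z, index=matrix.values.index,
                       columns=matrix.values.columns[keep])
    return OmicsMatrix(out, matrix.cls, "standardized"), dropped


def residualize(matrix: OmicsMatrix, covariates: CovariateTable,
                mode: str = "tumor") -> OmicsMatrix:
    """OLS residuals of every feature against the covariate design, then
    re-standardized.  Rank-deficient designs are handled by a minimum-norm
    fit with a warning (aliased columns contribute nothing)."""
    design = covariates.design_matrix(mode)
    design = design.loc[matrix.values.index]
    D = design.to_numpy(float)
    n, k = D.shape
    if k > n:
        raise ValueError(f"more covariate columns ({k}) than samples ({n})")
    Y = matrix.values.to_numpy(float)
    coef, _, rank, _ = np.linalg.lstsq(D, Y, rcond=None)
    if rank < k:
        warnings.warn(f"covariate design rank {rank} < {k} columns; "
                      "aliased columns dropped from the fit")
    resid = Y - D @ coef
    out = pd.DataFrame(resid, index=matrix.values.index,
                       columns=matrix.values.columns)
    std, _ = standardize(OmicsMatrix(out, matrix.cls, "raw"))
    return OmicsMatrix(std.values, matrix.cls, "residualized")


def beta_to_m(beta: pd.DataFrame | np.ndarray,
              clip: float = BETA_CLIP):
    """Methylation beta values -> M-values, M = log2(beta / (1 - beta)).

    Values are clipped to [clip, 1-clip] first so boundary betas map to
    finite M; inputs outside [0, 1] are rejected.
    """
    arr = np.asarray(beta, dtype=float)
    if ((arr < 0) | (arr > 1)).any() or not np.isfinite(arr).all():
        raise ValueError("beta values must lie in [0, 1]")
    clipped = np.clip(arr, clip, 1 - clip)
    m = np.log2(clipped / (1 - clipped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    return m


# ---------------------------------------------------------------------------
# SNP quality control

def _hwe_chisq_p(n_aa: np.ndarray, n_ab: np.ndarray, n_bb: np.ndarray):
    """1-df Hardy-Weinberg chi-square p per SNP from genotype counts."""
    n = n_aa + n_ab + n_bb
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n_aa + n_ab) / (2 * n)
        q = 1 - p
        exp_aa = n * p**2
        exp_ab = 2 * n * p * q
        exp_bb = n * q**2
        chi = np.zeros_like(p, dtype=float)
        for obs, exp in ((n_aa, exp_aa), (n_ab, exp_ab), (n_bb, exp_bb)):
            term = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
            chi += term
    pval = stats.chi2.sf(chi, df=1)
    # monomorphic SNPs: chi 0 -> p 1 (they fall to the MAF filter instead)
    return np.where(np.isfinite(pval), pval, 1.0), chi


def snp_qc(genotypes: pd.DataFrame,
           snp_miss_threshold: float = 0.1,
           sample_miss_threshold: float = 0.05,
           hwe_p_threshold: float = 1e-5,
           maf_threshold: float = 0.05,
           interpret_call_rate: str = "literal"):
    """Sequential SNP/sample quality filters on hard calls (0/1/2, NaN
    missing), applied in order: SNP missingness, sample missingness,
    Hardy-Weinberg equilibrium, minor allele frequency (strict <).

    ``interpret_call_rate='literal'`` removes SNPs with missingness >
    ``snp_miss_threshold`` and samples with missingness >
    ``sample_miss_threshold``; ``'plink'`` removes SNPs whose call rate is
    below ``1 - snp_miss_threshold`` (numerically the same rule, kept as an
    explicit switch because the two conventions are easy to conflate).

    Returns (filtered matrix, report DataFrame with one row per rule).
    """
    if interpret_call_rate not in ("literal", "plink"):
        raise ValueError("interpret_call_rate must be 'literal' or 'plink'")
    G = genotypes.copy()
    report = []

    miss_snp = G.isna().mean(axis=0)
    drop = miss_snp > snp_miss_threshold
    report.append(("snp_missingness", int(drop.sum())))
    G = G.loc[:, ~drop]

    miss_sample = G.isna().mean(axis=1)
    drop_s = miss_sample > sample_miss_threshold
    report.append(("sample_missingness", int(drop_s.sum())))
    G = G.loc[~drop_s]

    arr = G.to_numpy(float)
    calls = np.round(arr)
    n_aa = np.nansum(calls == 0, axis=0)
    n_ab = np.nansum(calls == 1, axis=0)
    n_bb = np.nansum(calls == 2, axis=0)
    pvals, _ = _hwe_chisq_p(n_aa.astype(float), n_ab.astype(float),
                            n_bb.astype(float))
    drop_hwe = pvals < hwe_p_threshold
    report.append(("hwe", int(drop_hwe.sum())))
    G = G.loc[:, ~drop_hwe]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(G.to_numpy(float), axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    drop_maf = maf < maf_threshold
    report.append(("maf", int(drop_maf.sum())))
    G = G.loc[:, ~drop_maf]

    if G.shape[1] == 0:
        raise ValueError("no SNPs survived quality control")
    rep = pd.DataFrame(report, columns=["rule", "items_removed"])
    return G, rep


def pc_outlier_filter(matrix: pd.DataFrame, n_pcs: int = 5,
                      sd_factor: float = 6.0):
    """Remove samples beyond ``sd_factor`` standard deviations on any of
    the first ``n_pcs`` principal components, recompute the PCs once on
    the survivors, and return (kept sample ids, top-2 PC scores).

    Scores are standardized to unit variance so the sd rule is on the
    score scale.
    """
    if len(matrix) < n_pcs + 1:
        raise ValueError(f"need at least {n_pcs + 1} samples for "
                         f"{n_pcs} principal components")

    def _scores(df, k):
        X = df.to_numpy(float)
        X = X - X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd == 0, 1.0, sd)
        U, S, _ = np.linalg.svd(X, full_matrices=False)
        k = min(k, len(S))
        sc = U[:, :k] * S[:k]
        ssd = sc.std(axis=0, ddof=1)
        return sc / np.where(ssd == 0, 1.0, ssd)

    scores = _scores(matrix, n_pcs)
    centered = scores - scores.mean(axis=0)
    keep = (np.abs(centered) <= sd_factor).all(axis=1)
    kept = matrix.index[keep]
    if len(kept) < n_pcs + 1:
        raise ValueError("too few samples remain after outlier removal")
    final = _scores(matrix.loc[kept], max(n_pcs, 2))
    pcs = pd.DataFrame(final[:, :2], index=kept, columns=["PC1", "PC2"])
    return list(kept), pcs


# ---------------------------------------------------------------------------
# cohort-level driver

@dataclass
class PreparedCohort:
    """A cohort after preprocessing: standardized+residualized expression
    and regulator matrices, ready for model fitting."""

    cohort_id: str
    tissue: str
    expression: pd.DataFrame            # samples x genes, processed
    matrices: dict                      # class -> samples x features
    annotations: object
    mode: str = "tumor"
    truth: object = None

    @property
    def n_samples(self) -> int:
        return len(self.expression)

    @property
    def genes(self):
        return list(self.expression.columns)


def preprocess_cohort(cohort, mode: str | None = None,
                      residualize_covariates: bool = True,
                      log_expression: bool = False,
                      cohort_id: str | None = None) -> PreparedCohort:
    """Standardize (and covariate-correct) a synthetic or file-backed
    cohort: methylation goes beta -> M first; every matrix and the
    expression are z-scored, residualized against the mode's covariate
    design, and re-standardized."""
    if mode is None:
        mode = "tumor" if cohort.tissue == "tumor" else "normal"
    cov = CovariateTable(cohort.covariates)

    def _prep(df, cls):
        om = OmicsMatrix(df, cls, "raw")
        om, _ = standardize(om, log_transform=(log_expression
                                               and cls == "EXPR"))
        if residualize_covariates:
            om = residualize(om, cov, mode)
        return om.values

    matrices = {}
    for cls, df in cohort.matrices.items():
        if cls == METH:
            df = beta_to_m(df)
        matrices[cls] = _prep(df, cls)
    expression = _prep(cohort.expression, "EXPR")
    return PreparedCohort(
        cohort_id=cohort_id or cohort.tissue,
        tissue=cohort.tissue, expression=expression, matrices=matrices,
        annotations=cohort.annotations, mode=mode,
        truth=getattr(cohort, "truth", None))
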
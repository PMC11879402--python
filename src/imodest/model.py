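"""Model / Results objects tying the pipeline together.

``RegulatorDecomposition`` is built from a (tumor, optional adjacent)
cohort pair; ``fit()`` runs the 63-model elastic-net ensemble for every
gene and returns ``DecompositionResults`` carrying per-gene per-class
predictive gains, averaged coefficients, transfer classification and a
``summary()`` table.  Clustering, enrichment and plotting hang off the
results object.

Example
-------
>>> from imodest import SimulationConfig, simulate_paired
>>> from imodest.model import RegulatorDecomposition
>>> tumor, adjacent = simulate_paired(SimulationConfig(n_samples=120,
...                                                    n_genes=8, seed=1))
>>> res = RegulatorDecomposition(tumor, adjacent, seed=1).fit()
>>> print(res.summary())             # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotations import CIS_WINDOW
from .cluster import cluster_genes, label_clusters, select_k
from .decompose import (average_coefficients, classify_transfer,
                        gain_correlation, gains_table)
from .engine import DEFAULT_DEFLATION_RUNS, fit_ensemble
from .enrich import enrich_gene_sets
from .preprocess import PreparedCohort, preprocess_cohort
from .regulators import CLASS_ORDER, enumerate_models


class RegulatorDecomposition:
    """Per-gene decomposition of expression variance over regulator
    classes for one cohort (optionally paired with tumor-adjacent tissue).

    Parameters
    ----------
    cohort : SyntheticCohort | PreparedCohort
        Raw cohorts are preprocessed (standardize -> residualize against
        the tissue's covariate model -> re-standardize; methylation goes
        beta -> M first).
    adjacent : optional paired tumor-adjacent cohort; tumor-trained models
        are transferred to it without refitting.
    genes : subset of genes to model (default: all).
    seed : pipeline seed; per-gene streams are derived deterministically.
    """

    def __init__(self, cohort, adjacent=None, genes=None,
                 classes=CLASS_ORDER, seed: int = 0,
                 deflation_runs: int = DEFAULT_DEFLATION_RUNS,
                 window: int = CIS_WINDOW, residualize: bool = True,
                 n_lambdas: int = 30, cv_folds: int = 10):
        self.cohort = self._prepare(cohort, residualize)
        self.adjacent = self._prepare(adjacent, residualize) \
            if adjacent is not None else None
        self.genes = list(genes) if genes is not None \
            else list(self.cohort.expression.columns)
        self.classes = tuple(classes)
        self.seed = int(seed)
        self.deflation_runs = deflation_runs
        self.window = window
        self.n_lambdas = n_lambdas
        self.cv_folds = cv_folds

    @staticmethod
    def _prepare(cohort, residualize):
        if isinstance(cohort, PreparedCohort):
            return cohort
        return preprocess_cohort(cohort,
                                 residualize_covariates=residualize)

    @classmethod
    def from_simulation(cls, config, **kwargs):
        """Simulate a paired cohort from a SimulationConfig and build the
        model on it (seed defaults to the config's)."""
        from .simulate import simulate_paired
        tumor, adjacent = simulate_paired(config)
        kwargs.setdefault("seed", config.seed)
        return cls(tumor, adjacent, **kwargs)

    def fit(self, verbose: bool = False) -> "DecompositionResults":
        ensembles = {}
        for gene in self.genes:
            if verbose:
                print(f"fitting {gene} ({len(ensembles) + 1}/"
                      f"{len(self.genes)})")
            ensembles[gene] = fit_ensemble(
                self.cohort, gene, adjacent=self.adjacent,
                classes=self.classes, seed=self.seed,
                deflation_runs=self.deflation_runs,
                n_lambdas=self.n_lambdas, cv_folds=self.cv_folds,
                window=self.window)
        return DecompositionResults(self, ensembles)


class DecompositionResults:
    """Fitted ensemble collection plus derived gain/coefficient tables."""

    def __init__(self, model: RegulatorDecomposition, ensembles: dict):
        self.model = model
        self.ensembles = ensembles
        self.gains = gains_table(ensembles.values())

    @property
    def gain_matrix(self) -> pd.DataFrame:
        """Genes x classes tumor gains."""
        return self.gains.pivot_table(index="gene", columns="class",
                                      values="gain", aggfunc="first"
                                      ).reindex(columns=list(self.model.classes))

    @property
    def gain_matrix_adjacent(self) -> pd.DataFrame:
        return self.gains.pivot_table(index="gene", columns="class",
                                      values="gain_adjacent",
                                      aggfunc="first"
                                      ).reindex(columns=list(self.model.classes))

    def coefficients(self) -> pd.DataFrame:
        """Long-format averaged coefficients across all genes."""
        frames = [average_coefficients(e) for e in self.ensembles.values()]
        return pd.concat(frames, ignore_index=True) if frames \
            else pd.DataFrame(columns=["gene", "class", "feature",
                                       "mean_coef", "mean_abs_coef",
                                       "n_models"])

    def transfer(self, threshold: float = 0.0):
        """Per-(gene, class) transfer classification (both / tumor_only /
        adjacent_only / neither)."""
        return classify_transfer(self.gains, threshold)

    def gain_correlations(self) -> pd.Series:
        """Per-class Pearson r between tumor and adjacent gains."""
        return pd.Series({cls: gain_correlation(self.gains, cls)
                          for cls in self.model.classes}, name="pearson_r")

    def cluster(self, k: int = 20, method: str = "ward",
                k_candidates=None, gains=None, score: str = "deflated"):
        """Cluster genes on their per-spec scores and label clusters by
        dominant regulators; if ``k_candidates`` is given, k is selected
        by Dunn index / connectivity first."""
        specs = enumerate_models(self.model.classes)
        rows, genes = [], []
        for gene, ens in self.ensembles.items():
            vals = [ens.press(s, score) for s in specs]
            if any(v is None for v in vals):
                continue
            rows.append(vals)
            genes.append(gene)
        feats = pd.DataFrame(rows, index=genes,
                             columns=[s.label for s in specs])
        metrics = None
        if k_candidates is not None:
            metrics, k = select_k(feats, k_candidates, method)
        k = min(k, len(feats))
        assignments = cluster_genes(feats, k, method, self.model.seed)
        return label_clusters(assignments,
                              gains if gains is not None else self.gains,
                              cohort_id=self.model.cohort.cohort_id,
                              metrics=metrics)

    def enrich(self, collection, min_gain: float = 0.25):
        return enrich_gene_sets(self.gains, collection,
                                classes=self.model.classes,
                                min_gain=min_gain)

    def summary(self) -> str:
        """Text summary: per-class mean/median tumor gain, adjacent gain
        and tumor-adjacent correlation over the modeled genes."""
        lines = ["Regulator decomposition of expression variance",
                 f"cohort: {self.model.cohort.cohort_id}   "
                 f"genes: {len(self.ensembles)}   "
                 f"samples: {self.model.cohort.n_samples}",
                 "-" * 72,
                 f"{'class':<8}{'mean gain':>12}{'median gain':>13}"
                 f"{'mean adj':>12}{'r(T,N)':>10}{'n pairs':>9}"]
        corr = self.gain_correlations() if self.model.adjacent is not None \
            else None
        for cls in self.model.classes:
            sub = self.gains[self.gains["class"] == cls]
            g = sub["gain"].dropna()
            ga = sub["gain_adjacent"].dropna()
            r = corr[cls] if corr is not None else None
            lines.append(
                f"{cls:<8}"
                f"{g.mean() if len(g) else float('nan'):>12.4f}"
                f"{g.median() if len(g) else float('nan'):>13.4f}"
                f"{ga.mean() if len(ga) else float('nan'):>12.4f}"
                f"{(f'{r:.3f}' if r is not None else '--'):>10}"
                f"{int(sub['n_pairs'].max()):>9}")
        lines.append("-" * 72)
        lines.append("gain: mean PRESS R² increase when the class joins "
                     "every background model")
        return "\n".join(lines)

    def plot_gains(self, ax=None, adjacent: bool = False):
        """Box plot of per-gene gains by class (tumor, or transferred)."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        if ax is None:
            _fig, ax = plt.subplots(figsize=(7, 4))
        col = "gain_adjacent" if adjacent else "gain"
        data, labels = [], []
        for cls in self.model.classes:
            vals = self.gains.loc[self.gains["class"] == cls, col].dropna()
            data.append(vals.to_numpy())
            labels.append(cls)
        ax.boxplot(data, tick_labels=labels)
        ax.axhline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_ylabel("predictive gain (Δ PRESS R²)")
        ax.set_title("tumor-adjacent transfer" if adjacent
                     else "tumor cohort")
        return ax
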
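"""Synthetic multi-omic cohort generator with known ground truth.

Emulates the structure of a TCGA-like cohort: per-sample measurements for
six regulator classes (miRNA/TF/lncRNA expression, methylation beta values,
gene-level copy number, SNP dosages), a gene-expression matrix, a sample
covariate table, and an annotation universe (gene intervals, positional
features with ±1 Mb cis-windows, TF->gene and miRNA->gene target maps).

Each gene's expression is an additive mixture

    expr_g = sum_c sqrt(share_gc) * u_gc  +  covariate term  +  noise,

where ``u_gc`` is an empirically standardized linear combination of that
gene's causal features in class ``c`` and the per-class variance shares
plus the noise share sum to one.  Causal feature sets are disjoint between
classes and draws are independent, so realized variance shares match the
configured truth up to sampling error — the baseline needed for exact
share-recovery tests.  An optional shared latent factor induces correlated
regulators instead.

Covariates confound by construction: a per-sample confounder score enters
both the regulator features and the expression, so covariate
residualization is non-trivially exercised downstream.  Classes listed as
tumor-specific contribute zero variance in tumor-adjacent cohorts (their
share moves to noise) and vice versa, giving the generator a known
tumor-vs-adjacent transfer pattern.

What this generator does *not* emulate: linkage disequilibrium between
SNPs, read-level noise, relatedness between samples, or non-linear
regulator effects.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotations import (AnnotationUniverse, admitted_features,
                          write_universe, CIS_WINDOW)
from .regulators import (CLASS_ORDER, CNV, LNCRNA, METH, MIRNA, SNP, TF,
                         class_index)

DEFAULT_SHARES = {MIRNA: 0.05, TF: 0.20, LNCRNA: 0.05, METH: 0.15,
                  CNV: 0.05, SNP: 0.05}
DEFAULT_CAUSAL = {MIRNA: 4, TF: 4, LNCRNA: 2, METH: 4, CNV: 1, SNP: 5}


class ConfigError(ValueError):
    """Simulation configuration cannot be realized."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for one synthetic paired cohort.

    ``shares`` may be a single per-class dict applied to every gene, or a
    DataFrame (genes x classes) of per-gene shares; ``noise_share`` fills
    the remainder and the total must be exactly 1 per gene.
    """

    n_samples: int = 200
    n_genes: int = 50
    n_mirna: int = 120
    n_tf: int = 150
    lncrna_per_gene: int = 3
    probes_per_gene: int = 10
    snps_per_gene: int = 15
    mirna_targets_per_gene: int = 8
    tf_targets_per_gene: int = 8
    causal_counts: dict = field(default_factory=lambda: dict(DEFAULT_CAUSAL))
    shares: object = field(default_factory=lambda: dict(DEFAULT_SHARES))
    noise_share: float = 0.45
    covariate_effect: float = 0.3
    tumor_specific_classes: frozenset = frozenset()
    normal_specific_classes: frozenset = frozenset()
    correlated_regulators: bool = False
    latent_strength: float = 0.5
    seed: int = 0
    gene_spacing: int = 3_000_000
    gene_length: int = 10_000
    chrom_length: int | None = None
    adjacent_fraction: float = 0.5

    def __post_init__(self):
        if self.n_samples < 3:
            raise ConfigError("n_samples must be >= 3")
        for name in ("n_genes", "n_mirna", "n_tf", "lncrna_per_gene",
                     "probes_per_gene", "snps_per_gene"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        tab = self.share_table()
        total = tab.sum(axis=1)
        if not np.allclose(total, 1.0, atol=1e-9):
            raise ConfigError("per-gene class shares + noise share must sum "
                              f"to 1 (got {total.min()}..{total.max()})")
        if ((tab < -1e-12) | (tab > 1 + 1e-12)).any().any():
            raise ConfigError("shares must lie in [0, 1]")

    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]

    def share_table(self) -> pd.DataFrame:
        """Per-gene shares, columns = six classes + 'noise', rows sum to 1."""
        genes = self.gene_ids()
        if isinstance(self.shares, pd.DataFrame):
            tab = self.shares.reindex(index=genes).fillna(0.0).copy()
            for c in CLASS_ORDER:
                if c not in tab.columns:
                    tab[c] = 0.0
            if "noise" not in tab.columns:
                tab["noise"] = 1.0 - tab[list(CLASS_ORDER)].sum(axis=1)
            return tab[list(CLASS_ORDER) + ["noise"]].astype(float)
        row = {c: float(self.shares.get(c, 0.0)) for c in CLASS_ORDER}
        row["noise"] = float(self.noise_share)
        return pd.DataFrame([row] * len(genes), index=genes,
                            columns=list(CLASS_ORDER) + ["noise"])


@dataclass
class SyntheticTruth:
    """Ground truth for one cohort: effective per-class variance shares,
    noise share, and causal feature ids per (gene, class)."""

    shares: pd.DataFrame            # genes x (classes + noise), effective
    causal: dict                    # (gene, class) -> tuple of feature ids

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in self.shares.index:
            for cls in list(CLASS_ORDER) + ["noise"]:
                ids = self.causal.get((gene, cls), ())
                rows.append((gene, cls, self.shares.loc[gene, cls],
                             ",".join(ids)))
        return pd.DataFrame(rows, columns=["gene", "class", "share",
                                           "causal_features"])


@dataclass
class SyntheticCohort:
    """One simulated tissue: regulator matrices on their native scales
    (SNP dosages in {0,1,2}, methylation as beta values), expression,
    covariates, annotations and the generating truth."""

    tissue: str
    expression: pd.DataFrame        # samples x genes
    matrices: dict                  # class -> samples x features DataFrame
    covariates: pd.DataFrame
    annotations: AnnotationUniverse
    truth: SyntheticTruth
    contributions: dict = field(default_factory=dict)  # gene -> n x classes
    noise_part: pd.DataFrame | None = None

    @property
    def samples(self):
        return list(self.expression.index)

    @property
    def n_samples(self) -> int:
        return len(self.expression)


# ---------------------------------------------------------------------------
# annotations

def simulate_annotations(config: SimulationConfig,
                         window: int = CIS_WINDOW) -> AnnotationUniverse:
    """Lay out genes and positional features on one synthetic chromosome.

    Gene ``i`` occupies ``[margin + i*spacing, margin + i*spacing + L)``.
    Each gene gets one SNP and one probe placed exactly at a window
    boundary (fixtures for the inclusive-boundary rule) plus uniformly
    placed ones, and one lncRNA overlapping its body (exercising the
    body-overlap exclusion) plus in-window lncRNAs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    margin = window + 1_000_000
    genes = config.gene_ids()
    starts = margin + np.arange(config.n_genes, dtype=np.int64) \
        * config.gene_spacing
    ends = starts + config.gene_length
    needed = int(ends[-1] + window + 1) if config.n_genes else margin
    if config.chrom_length is not None and config.chrom_length < needed:
        raise ConfigError(
            f"chromosome length {config.chrom_length} too short for "
            f"{config.n_genes} genes at spacing {config.gene_spacing} "
            f"(need >= {needed})")
    gene_df = pd.DataFrame({"chrom": "chrS", "start": starts, "end": ends,
                            "strand": "+"}, index=pd.Index(genes, name="gene"))

    snp_rows, probe_rows, lnc_rows = [], [], []
    for gi, gene in enumerate(genes):
        s, e = int(starts[gi]), int(ends[gi])
        lo, hi = s - window, e - 1 + window
        if config.snps_per_gene > 0:
            pos = [lo]  # boundary fixture: exactly at -window
            pos += list(rng.integers(lo, hi + 1,
                                     size=config.snps_per_gene - 1))
            for j, p in enumerate(sorted(pos)):
                snp_rows.append((f"snp_{gene}_{j:03d}", "chrS", int(p),
                                 int(p) + 1))
        if config.probes_per_gene > 0:
            pos = [hi]  # boundary fixture: exactly at +window
            pos += list(rng.integers(lo, hi + 1,
                                     size=config.probes_per_gene - 1))
            for j, p in enumerate(sorted(pos)):
                probe_rows.append((f"probe_{gene}_{j:03d}", "chrS", int(p),
                                   int(p) + 1))
        if config.lncrna_per_gene > 0:
            # one transcript overlapping the gene body (excluded from cis)
            ov = int(rng.integers(s, e))
            lnc_rows.append((f"lnc_{gene}_ov", "chrS", ov,
                             min(ov + 1000, e)))
            for j in range(config.lncrna_per_gene - 1):
                off = int(rng.integers(20_000, window - 2_000))
                side = 1 if rng.random() < 0.5 else -1
                a = e + off if side == 1 else s - off - 1000
                lnc_rows.append((f"lnc_{gene}_{j:03d}", "chrS", a, a + 1000))

    def _frame(rows):
        df = pd.DataFrame(rows, columns=["name", "chrom", "start", "end"])
        return df.set_index("name")

    features = {SNP: _frame(snp_rows), METH: _frame(probe_rows),
                LNCRNA: _frame(lnc_rows)}

    tf_ids = tuple(f"tf_{i:04d}" for i in range(config.n_tf))
    mir_ids = tuple(f"mir_{i:04d}" for i in range(config.n_mirna))
    tf_targets, mir_targets = {}, {}
    for gene in genes:
        if config.n_tf and config.tf_targets_per_gene:
            k = min(config.tf_targets_per_gene, config.n_tf)
            tf_targets[gene] = tuple(sorted(
                rng.choice(tf_ids, size=k, replace=False)))
        if config.n_mirna and config.mirna_targets_per_gene:
            k = min(config.mirna_targets_per_gene, config.n_mirna)
            mir_targets[gene] = tuple(sorted(
                rng.choice(mir_ids, size=k, replace=False)))
    return AnnotationUniverse(genes=gene_df, features=features,
                              tf_targets=tf_targets,
                              mirna_targets=mir_targets,
                              tf_ids=tf_ids, mirna_ids=mir_ids)


# ---------------------------------------------------------------------------
# causal effects (shared between paired cohorts)

@dataclass
class CausalEffects:
    """Causal feature ids and raw weights per (gene, class); drawn once and
    shared between a tumor cohort and its paired adjacent cohort."""

    causal: dict     # (gene, class) -> tuple of feature ids
    weights: dict    # (gene, class) -> ndarray of weights


def draw_effects(config: SimulationConfig, ann: AnnotationUniverse,
                 seed=None) -> CausalEffects:
    """Pick causal features (within each gene's admitted universe) and
    Gaussian weights.  Weight shape inside a class is a modeling
    convenience; only the class-level variance share is a contract."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 23]) if seed is None else seed)
    tab = config.share_table()
    causal, weights = {}, {}
    for gene in config.gene_ids():
        for cls in CLASS_ORDER:
            share = tab.loc[gene, cls]
            want = config.causal_counts.get(cls, 0)
            pool = admitted_features(ann, gene, cls)
            if share > 0 and (want <= 0 or not pool):
                raise ConfigError(
                    f"gene {gene}: class {cls} has share {share} but no "
                    f"causal features are available")
            if share <= 0 or want <= 0 or not pool:
                continue
            k = min(want, len(pool))
            ids = tuple(sorted(rng.choice(pool, size=k, replace=False)))
            causal[(gene, cls)] = ids
            weights[(gene, cls)] = rng.normal(size=k)
    return CausalEffects(causal=causal, weights=weights)


# ---------------------------------------------------------------------------
# cohorts

def _standardize_cols(arr: np.ndarray) -> np.ndarray:
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (arr - mu) / sd


def _effective_shares(config: SimulationConfig, tissue: str) -> pd.DataFrame:
    tab = config.share_table().copy()
    if tissue == "tumor":
        off = config.normal_specific_classes
    else:
        off = config.tumor_specific_classes
    for cls in off:
        tab["noise"] = tab["noise"] + tab[cls]
        tab[cls] = 0.0
    return tab


def _covariates(rng, samples, tissue) -> pd.DataFrame:
    n = len(samples)
    return pd.DataFrame({
        "sex": rng.choice(["F", "M"], size=n),
        "batch": rng.choice(["b1", "b2", "b3"], size=n),
        "PC1": rng.normal(size=n),
        "PC2": rng.normal(size=n),
        "purity": rng.uniform(0.35, 0.95, size=n) if tissue == "tumor"
        else np.zeros(n),
        "age": rng.normal(60, 10, size=n),
        "histology": rng.choice(["h1", "h2"], size=n),
    }, index=pd.Index(samples, name="sample"))


def _confounder_score(rng, cov: pd.DataFrame, tissue: str) -> np.ndarray:
    """One standardized per-sample score built from the covariates.

    In adjacent tissue only the covariates available to the reduced
    (normal-mode) correction model contribute, so residualization can
    always remove the confounding it is asked to remove.
    """
    parts = [(cov["sex"] == "M").to_numpy(float),
             (cov["batch"] == "b2").to_numpy(float),
             (cov["batch"] == "b3").to_numpy(float),
             cov["PC1"].to_numpy(), cov["PC2"].to_numpy()]
    if tissue == "tumor":
        parts += [cov["purity"].to_numpy(),
                  (cov["age"].to_numpy() - 60.0) / 10.0,
                  (cov["histology"] == "h2").to_numpy(float)]
    w = rng.normal(size=len(parts))
    score = np.zeros(len(cov))
    for wi, p in zip(w, parts):
        score += wi * p
    sd = score.std()
    return score / sd if sd > 0 else score


def simulate_cohort(config: SimulationConfig, ann: AnnotationUniverse,
                    tissue: str = "tumor", effects: CausalEffects | None = None,
                    n_samples: int | None = None, sample_prefix: str | None = None,
                    seed=None) -> SyntheticCohort:
    """Draw one cohort of ``n_samples`` for the given tissue.

    Regulator features are drawn on their native scales (SNP dosages from
    binomial(2, MAF) with MAF ~ U(0.05, 0.5) — the post-QC universe —
    and methylation on the beta scale so the beta->M conversion is
    exercised downstream).  Expression is built from the *clean*
    standardized causal signals so that realized class variance shares
    match the effective truth up to sampling error.
    """
    if tissue not in ("tumor", "tumor-adjacent"):
        raise ValueError("tissue must be 'tumor' or 'tumor-adjacent'")
    if effects is None:
        effects = draw_effects(config, ann)
    n = config.n_samples if n_samples is None else int(n_samples)
    if n < 3:
        raise ConfigError("cohort needs at least 3 samples")
    if sample_prefix is None:
        sample_prefix = "T" if tissue == "tumor" else "N"
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 41 if tissue == "tumor" else 43])
        if seed is None else seed)
    samples = [f"{sample_prefix}{i:05d}" for i in range(n)]
    cov = _covariates(rng, samples, tissue)
    cs = _confounder_score(rng, cov, tissue)
    ce = config.covariate_effect
    latent = rng.normal(size=n) if config.correlated_regulators else None

    genes = config.gene_ids()
    clean: dict[str, np.ndarray] = {}
    observed: dict[str, pd.DataFrame] = {}
    feat_ids: dict[str, list[str]] = {}

    def _maybe_latent(z):
        if latent is None:
            return z
        s = config.latent_strength
        return np.sqrt(1 - s**2) * z + s * latent[:, None]

    # continuous expression-like classes
    for cls, ids in ((MIRNA, list(ann.mirna_ids)), (TF, list(ann.tf_ids)),
                     (LNCRNA, list(ann.features[LNCRNA].index)
                      if LNCRNA in ann.features else []),
                     (CNV, genes)):
        z = _maybe_latent(rng.normal(size=(n, len(ids))))
        obs = z + ce * np.outer(cs, rng.normal(size=len(ids)))
        if cls == CNV:
            obs = 2.0 + 0.6 * obs   # copy-number-like scale
        clean[cls], feat_ids[cls] = z, ids
        observed[cls] = pd.DataFrame(obs, index=samples, columns=ids)

    # methylation: latent M-values, emitted as beta values
    probe_ids = list(ann.features[METH].index) if METH in ann.features else []
    zm = _maybe_latent(rng.normal(size=(n, len(probe_ids))))
    m0 = rng.uniform(-2, 2, size=len(probe_ids))
    sscale = rng.uniform(0.5, 1.5, size=len(probe_ids))
    m_obs = m0 + sscale * (zm + ce * np.outer(cs, rng.normal(size=len(probe_ids))))
    beta = 1.0 / (1.0 + np.exp2(-m_obs))
    clean[METH], feat_ids[METH] = zm, probe_ids
    observed[METH] = pd.DataFrame(beta, index=samples, columns=probe_ids)

    # SNP dosages under Hardy-Weinberg; germline, so not confounded
    snp_ids = list(ann.features[SNP].index) if SNP in ann.features else []
    maf = rng.uniform(0.05, 0.5, size=len(snp_ids))
    dosage = rng.binomial(2, np.broadcast_to(maf, (n, len(snp_ids)))
                          ).astype(float)
    clean[SNP], feat_ids[SNP] = _standardize_cols(dosage), snp_ids
    observed[SNP] = pd.DataFrame(dosage, index=samples, columns=snp_ids)

    col_pos = {cls: {f: j for j, f in enumerate(feat_ids[cls])}
               for cls in clean}

    tab = _effective_shares(config, tissue)
    expr = np.empty((n, len(genes)))
    contributions = {}
    noise_mat = np.empty((n, len(genes)))
    for gi, gene in enumerate(genes):
        parts = {}
        total = np.zeros(n)
        for cls in CLASS_ORDER:
            share = tab.loc[gene, cls]
            key = (gene, cls)
            if share <= 0 or key not in effects.causal:
                continue
            idx = [col_pos[cls][f] for f in effects.causal[key]]
            zstd = _standardize_cols(clean[cls][:, idx])
            u = zstd @ effects.weights[key]
            sd = u.std()
            u = u / sd if sd > 0 else u
            part = np.sqrt(share) * u
            parts[cls] = part
            total += part
        eps = rng.normal(size=n)
        eps = (eps - eps.mean()) / eps.std()
        noise = np.sqrt(tab.loc[gene, "noise"]) * eps
        noise_mat[:, gi] = noise
        expr[:, gi] = total + noise + ce * cs
        contributions[gene] = pd.DataFrame(
            parts, index=samples).reindex(columns=list(CLASS_ORDER),
                                          fill_value=0.0)

    truth = SyntheticTruth(shares=tab,
                           causal={k: v for k, v in effects.causal.items()
                                   if tab.loc[k[0], k[1]] > 0})
    return SyntheticCohort(
        tissue=tissue,
        expression=pd.DataFrame(expr, index=samples, columns=genes),
        matrices=observed, covariates=cov, annotations=ann, truth=truth,
        contributions=contributions,
        noise_part=pd.DataFrame(noise_mat, index=samples, columns=genes))


def simulate_paired(config: SimulationConfig):
    """Tumor + tumor-adjacent cohorts sharing annotations and causal
    weights (except tissue-specific classes, which are silenced in the
    other tissue).  The adjacent cohort holds
    ``round(adjacent_fraction * n_samples)`` samples; a fraction of zero
    yields ``(tumor, None)`` with a warning, mirroring cancers without
    adjacent material."""
    ann = simulate_annotations(config)
    effects = draw_effects(config, ann)
    tumor = simulate_cohort(config, ann, "tumor", effects=effects)
    n_adj = int(round(config.adjacent_fraction * config.n_samples))
    if n_adj == 0:
        warnings.warn("adjacent_fraction yields 0 samples; "
                      "adjacent cohort omitted")
        return tumor, None
    adjacent = simulate_cohort(config, ann, "tumor-adjacent",
                               effects=effects, n_samples=max(n_adj, 3))
    return tumor, adjacent


def realized_shares(cohort: SyntheticCohort) -> pd.DataFrame:
    """Empirical per-class variance shares of the generated signal.

    Computed from the generator's own clean components:
    var(class contribution) / var(class contributions + noise).
    """
    genes = list(cohort.expression.columns)
    out = pd.DataFrame(0.0, index=genes, columns=list(CLASS_ORDER) + ["noise"])
    for gene in genes:
        contrib = cohort.contributions[gene]
        total = contrib.sum(axis=1).to_numpy() \
            + cohort.noise_part[gene].to_numpy()
        denom = total.var()
        for cls in CLASS_ORDER:
            out.loc[gene, cls] = contrib[cls].to_numpy().var() / denom
        out.loc[gene, "noise"] = cohort.noise_part[gene].to_numpy().var() \
            / denom
    return out


# ---------------------------------------------------------------------------
# serialization

def write_cohort(cohort: SyntheticCohort, outdir: str) -> list[str]:
    """Write the cohort as delimited text (TSV matrices, BED annotations,
    truth table).  Returns the list of files written."""
    os.makedirs(outdir, exist_ok=True)
    written = []

    def _w(df, name, index_label="sample"):
        path = os.path.join(outdir, name)
        df.to_csv(path, sep="\t", index_label=index_label,
                  float_format="%.10g")
        written.append(path)

    _w(cohort.expression, "expression.tsv")
    for cls, df in sorted(cohort.matrices.items()):
        _w(df, f"{cls.lower()}.tsv")
    _w(cohort.covariates, "covariates.tsv")
    _w(cohort.truth.to_frame().set_index("gene"), "truth.tsv",
       index_label="gene")
    write_universe(cohort.annotations, outdir)
    with open(os.path.join(outdir, "tissue.txt"), "w") as fh:
        fh.write(cohort.tissue + "\n")
    return written
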
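"""Tabular I/O: TSV matrices, fit-result tables, bedGraph coefficient
tracks, checksummed manifests.

All coordinates written are 0-based half-open (BED/bedGraph convention).
"""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np
import pandas as pd

from .annotations import read_universe
from .regulators import METH, SNP, ModelSpec, enumerate_models
from .simulate import SyntheticCohort, SyntheticTruth


def read_matrix(path: str) -> pd.DataFrame:
    """Strict TSV matrix reader: first column sample id, header = feature
    ids; ragged rows raise."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().all(axis=None) and df.size:
        raise ValueError(f"{path}: could not parse any values")
    return df


def write_matrix(df: pd.DataFrame, path: str, index_label="sample"):
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def read_cohort(indir: str) -> SyntheticCohort:
    """Read a cohort directory as written by ``simulate.write_cohort``."""
    from .regulators import CLASS_ORDER
    expression = read_matrix(os.path.join(indir, "expression.tsv"))
    matrices = {}
    for cls in CLASS_ORDER:
        path = os.path.join(indir, f"{cls.lower()}.tsv")
        if os.path.exists(path):
            matrices[cls] = read_matrix(path)
    covariates = pd.read_csv(os.path.join(indir, "covariates.tsv"),
                             sep="\t", index_col=0)
    ann = read_universe(indir)
    tissue_path = os.path.join(indir, "tissue.txt")
    tissue = "tumor"
    if os.path.exists(tissue_path):
        tissue = open(tissue_path).read().strip()
    truth = None
    truth_path = os.path.join(indir, "truth.tsv")
    if os.path.exists(truth_path):
        tf = pd.read_csv(truth_path, sep="\t",
                         keep_default_na=False, na_values=[])
        shares = tf.pivot_table(index="gene", columns="class",
                                values="share", aggfunc="first")
        causal = {}
        for _, row in tf.iterrows():
            ids = tuple(x for x in str(row["causal_features"]).split(",")
                        if x)
            if ids:
                causal[(row["gene"], row["class"])] = ids
        truth = SyntheticTruth(shares=shares, causal=causal)
    return SyntheticCohort(tissue=tissue, expression=expression,
                           matrices=matrices, covariates=covariates,
                           annotations=ann, truth=truth)


# ---------------------------------------------------------------------------
# fit results

def write_fits(ensembles, outdir: str, cohort_id: str = "cohort"):
    """Serialize an ensemble collection: per-spec scores TSV plus
    long-format coefficients TSV."""
    os.makedirs(outdir, exist_ok=True)
    score_rows, coef_rows = [], []
    for ens in ensembles:
        score_rows.append((ens.gene, 0, 0, np.nan, ens.null_press_raw,
                           ens.deflation, ens.null_press,
                           ens.null_transfer if ens.null_transfer is not None
                           else np.nan))
        for spec, fit in sorted(ens.fits.items(),
                                key=lambda kv: kv[0].sort_key):
            score_rows.append((
                ens.gene, spec.bitmask, len(fit.coefficients), fit.lam,
                fit.press_r2_raw, fit.deflation, fit.press_r2,
                fit.transfer_r2 if fit.transfer_r2 is not None else np.nan))
            for (cls, feat), w in fit.coefficients.items():
                if w != 0.0:
                    coef_rows.append((ens.gene, spec.bitmask, cls, feat, w))
    scores = pd.DataFrame(score_rows, columns=[
        "gene", "spec_bitmask", "n_features", "lambda", "press_r2_raw",
        "deflation", "press_r2", "transfer_r2"])
    coefs = pd.DataFrame(coef_rows, columns=["gene", "spec_bitmask",
                                             "class", "feature", "weight"])
    scores.to_csv(os.path.join(outdir, f"scores_{cohort_id}.tsv"),
                  sep="\t", index=False, float_format="%.10g")
    coefs.to_csv(os.path.join(outdir, f"coefficients_{cohort_id}.tsv"),
                 sep="\t", index=False, float_format="%.10g")
    return scores, coefs


class ScoresEnsemble:
    """Lightweight stand-in for an in-memory ensemble, backed by a scores
    table row-set; supports the ``press``/``gene``/``cohort_id`` surface
    the decomposition functions need."""

    def __init__(self, gene: str, cohort_id: str, rows: pd.DataFrame):
        self.gene = gene
        self.cohort_id = cohort_id
        self._by_mask = rows.set_index("spec_bitmask")
        self.fits = {ModelSpec.from_bitmask(int(m)): None
                     for m in self._by_mask.index if m != 0}

    def press(self, spec, score="deflated"):
        mask = spec.bitmask
        if mask not in self._by_mask.index:
            return None
        row = self._by_mask.loc[mask]
        col = {"deflated": "press_r2", "raw": "press_r2_raw",
               "transfer": "transfer_r2"}[score]
        val = row[col]
        return None if pd.isna(val) else float(val)


def read_scores(path: str, cohort_id: str = "cohort") -> list:
    scores = pd.read_csv(path, sep="\t")
    return [ScoresEnsemble(gene, cohort_id, sub)
            for gene, sub in scores.groupby("gene", sort=True)]


# ---------------------------------------------------------------------------
# bedGraph coefficient tracks

def export_coefficient_tracks(summary: pd.DataFrame, annotations,
                              outdir: str) -> list[str]:
    """bedGraph tracks of per-position coefficient sums and magnitudes for
    the positional classes SNP and methylation.

    Per feature position: sum over genes of the feature's mean
    coefficient, and sum of mean |coefficient|.  Zero values are omitted
    from each track (so a position whose signed contributions cancel still
    appears in the magnitude track).  A track-hub stub referencing the
    files is written.
    """
    os.makedirs(outdir, exist_ok=True)
    written = []
    skipped_no_coords = 0
    for cls in (SNP, METH):
        feats = annotations.features.get(cls)
        sub = summary[summary["class"] == cls]
        agg = sub.groupby("feature")[["mean_coef", "mean_abs_coef"]].sum()
        rows = []
        for feat, row in agg.iterrows():
            if feats is None or feat not in feats.index:
                skipped_no_coords += 1
                continue
            coords = feats.loc[feat]
            rows.append((str(coords["chrom"]), int(coords["start"]),
                         int(coords["end"]), float(row["mean_coef"]),
                         float(row["mean_abs_coef"])))
        rows.sort(key=lambda r: (r[0], r[1]))
        for kind, col in (("sum", 3), ("magnitude", 4)):
            path = os.path.join(outdir, f"{cls.lower()}_{kind}.bedGraph")
            with open(path, "w") as fh:
                fh.write(f"track type=bedGraph name={cls.lower()}_{kind} "
                         f"description=\"{cls} coefficient {kind}\"\n")
                for r in rows:
                    if r[col] == 0.0:   # zero values carry no track signal
                        continue
                    fh.write(f"{r[0]}\t{r[1]}\t{r[2]}\t{r[col]:.10g}\n")
            written.append(path)
    hub = os.path.join(outdir, "hub.txt")
    with open(hub, "w") as fh:
        fh.write("hub imodest_coefficients\n"
                 "shortLabel regulator coefficient tracks\n"
                 "longLabel per-position regulator coefficient sums and "
                 "magnitudes\n")
        for path in written:
            fh.write(f"track {os.path.basename(path)}\n")
    written.append(hub)
    if skipped_no_coords:
        import warnings
        warnings.warn(f"{skipped_no_coords} features lacked coordinates "
                      "and were skipped")
    return written


def read_bedgraph(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("track"):
                continue
            chrom, start, end, value = line.rstrip("\n").split("\t")
            rows.append((chrom, int(start), int(end), float(value)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


# ---------------------------------------------------------------------------
# manifest

def file_checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str, seed: int, stages: dict,
                   exclude=("manifest.json",)) -> str:
    """JSON manifest: package version, seed, per-stage wall-clock and a
    sha256 checksum of every file under ``outdir``."""
    from . import __version__
    checksums = {}
    for root, _dirs, files in os.walk(outdir):
        for f in sorted(files):
            if f in exclude:
                continue
            path = os.path.join(root, f)
            rel = os.path.relpath(path, outdir)
            checksums[rel] = file_checksum(path)
    manifest = {"version": __version__, "seed": seed,
                "stages_seconds": stages, "checksums": checksums}
    path = os.path.join(outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
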
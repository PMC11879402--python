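"""Genomic annotation universe: gene intervals, feature coordinates and
regulator->target maps.

Coordinates are 0-based half-open everywhere (BED convention).  A gene's
cis-window extends ``window`` bases (default 1 Mb) beyond both gene
boundaries and is *inclusive* at exactly the boundary base: a probe whose
interval touches position ``gene.start - 1_000_000`` is in the window.

lncRNAs whose interval intersects the gene body itself are excluded from
that gene's lncRNA predictor set, so a gene is never predicted by its own
overlapping transcript.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

from .regulators import CNV, LNCRNA, METH, MIRNA, SNP, TF, POSITIONAL_CLASSES

CIS_WINDOW = 1_000_000


@dataclass
class AnnotationUniverse:
    """Gene intervals, positional feature intervals and trans target maps.

    Parameters
    ----------
    genes : DataFrame indexed by gene id with columns chrom, start, end, strand.
    features : mapping of class -> DataFrame indexed by feature id with
        columns chrom, start, end (positional classes only: LNCRNA/METH/SNP).
    tf_targets, mirna_targets : mapping gene id -> tuple of regulator ids.
    mirna_ids, tf_ids : the full regulator pools (features of the
        expression matrices for those classes).
    """

    genes: pd.DataFrame
    features: dict = field(default_factory=dict)
    tf_targets: dict = field(default_factory=dict)
    mirna_targets: dict = field(default_factory=dict)
    tf_ids: tuple = ()
    mirna_ids: tuple = ()

    def __post_init__(self):
        bad = self.genes[self.genes["start"] >= self.genes["end"]]
        if len(bad):
            raise ValueError(f"malformed gene intervals: {list(bad.index)}")
        for cls, df in self.features.items():
            bad = df[df["start"] >= df["end"]]
            if len(bad):
                raise ValueError(
                    f"malformed {cls} feature intervals: {list(bad.index)}")
        known_tf = set(self.tf_ids)
        known_mir = set(self.mirna_ids)
        for gene, ids in self.tf_targets.items():
            unknown = set(ids) - known_tf
            if unknown:
                raise ValueError(f"TF map for {gene} references unknown ids "
                                 f"{sorted(unknown)}")
        for gene, ids in self.mirna_targets.items():
            unknown = set(ids) - known_mir
            if unknown:
                raise ValueError(f"miRNA map for {gene} references unknown "
                                 f"ids {sorted(unknown)}")

    def gene_interval(self, gene_id: str):
        try:
            row = self.genes.loc[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene {gene_id!r}") from None
        return str(row["chrom"]), int(row["start"]), int(row["end"])


def _intersects_closed(fs, fe, lo, hi):
    """Does 0-based half-open [fs, fe) touch the closed base range [lo, hi]?"""
    return (fs <= hi) & (fe - 1 >= lo)


def assign_cis_features(universe: AnnotationUniverse, gene_id: str, cls: str,
                        window: int = CIS_WINDOW) -> list[str]:
    """Feature ids of ``cls`` within ±``window`` of the gene's boundaries.

    The window is inclusive at exactly ±window bp.  For LNCRNA, any feature
    intersecting the gene body ``[start, end)`` is removed.
    """
    if cls not in POSITIONAL_CLASSES:
        raise ValueError(f"{cls} is not a positional class")
    chrom, start, end = universe.gene_interval(gene_id)
    feats = universe.features.get(cls)
    if feats is None or feats.empty:
        return []
    lo, hi = start - window, end - 1 + window
    same = feats["chrom"].astype(str) == chrom
    hit = same & _intersects_closed(feats["start"], feats["end"], lo, hi)
    if cls == LNCRNA:
        body = same & _intersects_closed(feats["start"], feats["end"],
                                         start, end - 1)
        hit &= ~body
    return list(feats.index[hit])


def select_trans_features(universe: AnnotationUniverse, gene_id: str,
                          cls: str) -> list[str]:
    """Mapped regulators of ``gene_id`` for a trans class (TF or miRNA).

    Genes absent from the map get an empty list; model fitting then simply
    proceeds without that class.
    """
    if cls == TF:
        return list(universe.tf_targets.get(gene_id, ()))
    if cls == MIRNA:
        return list(universe.mirna_targets.get(gene_id, ()))
    raise ValueError(f"{cls} is not a trans class")


def admitted_features(universe: AnnotationUniverse, gene_id: str, cls: str,
                      window: int = CIS_WINDOW) -> list[str]:
    """Predictor ids of any class admitted for ``gene_id``.

    CNV is the gene's own copy-number value; positional classes go through
    the cis-window; TF/miRNA through the target maps.
    """
    if cls == CNV:
        return [gene_id]
    if cls in POSITIONAL_CLASSES:
        return assign_cis_features(universe, gene_id, cls, window)
    return select_trans_features(universe, gene_id, cls)


# ---------------------------------------------------------------------------
# serialization (BED + two-column TSV maps)

def write_universe(universe: AnnotationUniverse, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    g = universe.genes.reset_index()
    g.columns = ["name", "chrom", "start", "end", "strand"]
    g["score"] = 0
    g[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        os.path.join(outdir, "genes.bed"), sep="\t", header=False, index=False)
    for cls, df in universe.features.items():
        f = df.reset_index()
        f.columns = ["name", "chrom", "start", "end"]
        f[["chrom", "start", "end", "name"]].to_csv(
            os.path.join(outdir, f"{cls.lower()}_features.bed"),
            sep="\t", header=False, index=False)
    for fname, mapping in (("tf_targets.tsv", universe.tf_targets),
                           ("mirna_targets.tsv", universe.mirna_targets)):
        rows = [(g_, r) for g_, ids in sorted(mapping.items()) for r in ids]
        pd.DataFrame(rows, columns=["gene", "regulator"]).to_csv(
            os.path.join(outdir, fname), sep="\t", index=False)
    pd.DataFrame({"id": list(universe.tf_ids)}).to_csv(
        os.path.join(outdir, "tf_ids.tsv"), sep="\t", index=False)
    pd.DataFrame({"id": list(universe.mirna_ids)}).to_csv(
        os.path.join(outdir, "mirna_ids.tsv"), sep="\t", index=False)


def read_universe(indir: str) -> AnnotationUniverse:
    genes = pd.read_csv(os.path.join(indir, "genes.bed"), sep="\t",
                        header=None,
                        names=["chrom", "start", "end", "name", "score",
                               "strand"])
    genes = genes.set_index("name")[["chrom", "start", "end", "strand"]]
    genes.index.name = "gene"
    features = {}
    for cls in POSITIONAL_CLASSES:
        path = os.path.join(indir, f"{cls.lower()}_features.bed")
        if os.path.exists(path):
            df = pd.read_csv(path, sep="\t", header=None,
                             names=["chrom", "start", "end", "name"])
            features[cls] = df.set_index("name")

    def _read_map(fname):
        path = os.path.join(indir, fname)
        if not os.path.exists(path):
            return {}
        df = pd.read_csv(path, sep="\t")
        return {g: tuple(sub["regulator"]) for g, sub in df.groupby("gene")}

    def _read_ids(fname):
        path = os.path.join(indir, fname)
        if not os.path.exists(path):
            return ()
        return tuple(pd.read_csv(path, sep="\t")["id"])

    return AnnotationUniverse(genes=genes, features=features,
                              tf_targets=_read_map("tf_targets.tsv"),
                              mirna_targets=_read_map("mirna_targets.tsv"),
                              tf_ids=_read_ids("tf_ids.tsv"),
                              mirna_ids=_read_ids("mirna_ids.tsv"))
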
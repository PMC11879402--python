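"""Over-representation of well-predicted genes in user-supplied gene sets
(e.g. pooled cell-type markers): unranked hypergeometric test with
Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .regulators import CLASS_ORDER


@dataclass
class GeneSetCollection:
    """Named gene sets over a shared universe; sets are clipped to the
    universe, names must be unique."""

    sets: dict                       # name -> frozenset of gene ids
    universe: frozenset

    def __post_init__(self):
        self.universe = frozenset(self.universe)
        self.sets = {name: frozenset(s) & self.universe
                     for name, s in self.sets.items()}


def read_gmt(path: str, universe=None) -> GeneSetCollection:
    """Read GMT (set name, description, members...).  If no universe is
    given, the union of all members is used."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *members = parts
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            sets[name] = frozenset(m for m in members if m)
    if universe is None:
        universe = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(sets=sets, universe=universe)


def threshold_genes(gains: pd.DataFrame, cls: str,
                    min_gain: float = 0.25) -> frozenset:
    """Genes whose gain for ``cls`` is strictly greater than ``min_gain``
    (default 0.25: 'predicted by more than 25%')."""
    sub = gains[gains["class"] == cls].dropna(subset=["gain"])
    return frozenset(sub.loc[sub["gain"] > min_gain, "gene"])


def hypergeom_test(query, target, universe) -> float:
    """Upper-tail hypergeometric probability P[X >= |query ∩ target|] with
    population |universe|, |target| successes and |query| draws."""
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    query = frozenset(query) & universe
    target = frozenset(target) & universe
    k = len(query & target)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, len(universe), len(target),
                                    len(query)))


def adjust_fdr(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up q-values (monotone in the ranked p's)."""
    pvals = list(pvalues)
    if not pvals:
        return []
    if any(p < 0 or p > 1 for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(pvals, method="fdr_bh")
    return list(q)


def enrich_gene_sets(gains: pd.DataFrame, collection: GeneSetCollection,
                     classes=CLASS_ORDER, min_gain: float = 0.25
                     ) -> pd.DataFrame:
    """Test every (class, gene set) pair: are genes predicted by the class
    by more than ``min_gain`` over-represented in the set?  Universe
    defaults to the collection's universe intersected with the genes that
    have gains (the gains are only defined there)."""
    have_gains = frozenset(gains["gene"])
    universe = collection.universe & have_gains
    rows = []
    for cls in classes:
        query = threshold_genes(gains, cls, min_gain) & universe
        for name, target in sorted(collection.sets.items()):
            tgt = target & universe
            overlap = len(query & tgt)
            p = hypergeom_test(query, tgt, universe) if universe else 1.0
            rows.append((name, cls, len(query), len(tgt), overlap, p))
    df = pd.DataFrame(rows, columns=["set", "class", "n_query", "n_target",
                                     "overlap", "p"])
    df["q"] = adjust_fdr(df["p"]) if len(df) else []
    return df
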
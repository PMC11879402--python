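"""Decompose the model ensemble into per-regulator predictive gains,
averaged coefficients, conditional gains and tumor-vs-adjacent transfer
summaries.

The predictive gain of a regulator class is the mean increase in PRESS R²
when the class is added to every possible background — every subset of the
other classes, including the empty set (whose score is the intercept-only
null baseline).  With six classes that is 2^5 = 32 paired differences, and
for ensembles whose scores are additive across classes the gain recovers
each class's value exactly (it is the Banzhaf value of an additive game).

Conditional gains restrict the backgrounds to those containing (or
avoiding) specified classes, exposing mediation: if a class's gain
vanishes once another class is in the model, their explained variance is
shared.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import EnsembleResult
from .regulators import CLASS_ORDER, ModelSpec, class_index


def _backgrounds(others, include=frozenset(), exclude=frozenset()):
    others = sorted(others, key=class_index)
    for r in range(len(others) + 1):
        for combo in itertools.combinations(others, r):
            s = frozenset(combo)
            if include <= s and not (s & exclude):
                yield s


def regulator_gain(ensemble: EnsembleResult, cls: str,
                   score: str = "deflated"):
    """Mean paired PRESS R² difference press(S ∪ {cls}) − press(S) over all
    backgrounds S ⊆ other classes.

    Returns (gain, n_pairs); pairs with a skipped spec are excluded.
    ``(None, 0)`` if no usable pair exists.
    """
    return conditional_gain(ensemble, cls, score=score)


def conditional_gain(ensemble: EnsembleResult, cls: str,
                     include=frozenset(), exclude=frozenset(),
                     score: str = "deflated"):
    """Regulator gain restricted to backgrounds S with include ⊆ S and
    S ∩ exclude = ∅.  include=exclude=∅ reproduces the unconditional gain.
    """
    include, exclude = frozenset(include), frozenset(exclude)
    if include & exclude:
        raise ValueError(f"conflicting condition: {sorted(include & exclude)}"
                         " both included and excluded")
    if cls in include or cls in exclude:
        raise ValueError(f"class {cls} cannot appear in its own condition")
    others = [c for c in CLASS_ORDER if c != cls]
    diffs = []
    any_background = False
    for s in _backgrounds(others, include, exclude):
        any_background = True
        without = ensemble.press(ModelSpec(s), score)
        with_ = ensemble.press(ModelSpec(s | {cls}), score)
        if without is None or with_ is None:
            continue
        diffs.append(with_ - without)
    if not any_background:
        raise ValueError(
            f"condition include={sorted(include)} exclude={sorted(exclude)} "
            "admits no background subsets")
    if not diffs:
        return None, 0
    return float(np.mean(diffs)), len(diffs)


@dataclass
class GainProfile:
    """Per-gene per-class predictive gains in tumor (and, when an adjacent
    cohort was scored, in tumor-adjacent tissue via transfer R²)."""

    gene: str
    cohort_id: str
    gain: dict                  # class -> float | None
    n_pairs: dict               # class -> int
    gain_adjacent: dict | None = None


def gain_profile(ensemble: EnsembleResult, score: str = "deflated",
                 with_adjacent: bool = True) -> GainProfile:
    gains, pairs, adj = {}, {}, {}
    has_transfer = any(ensemble.press(spec, "transfer") is not None
                       for spec in ensemble.fits)
    for cls in CLASS_ORDER:
        g, np_ = regulator_gain(ensemble, cls, score)
        gains[cls], pairs[cls] = g, np_
        if with_adjacent and has_transfer:
            ga, _ = regulator_gain(ensemble, cls, "transfer")
            adj[cls] = ga
    return GainProfile(gene=ensemble.gene, cohort_id=ensemble.cohort_id,
                       gain=gains, n_pairs=pairs,
                       gain_adjacent=adj if adj else None)


def gains_table(ensembles, score: str = "deflated") -> pd.DataFrame:
    """Long-format per-(gene, class) gains across an ensemble collection:
    columns gene, class, gain, gain_adjacent, n_pairs."""
    rows = []
    for ens in ensembles:
        prof = gain_profile(ens, score)
        for cls in CLASS_ORDER:
            ga = prof.gain_adjacent.get(cls) if prof.gain_adjacent else None
            rows.append((prof.cohort_id, prof.gene, cls, prof.gain[cls],
                         ga, prof.n_pairs[cls]))
    return pd.DataFrame(rows, columns=["cohort", "gene", "class", "gain",
                                       "gain_adjacent", "n_pairs"])


def gain_matrix(table: pd.DataFrame, value: str = "gain") -> pd.DataFrame:
    """Pivot a long gains table to genes x classes."""
    return table.pivot_table(index="gene", columns="class", values=value,
                             aggfunc="first").reindex(columns=list(CLASS_ORDER))


# ---------------------------------------------------------------------------
# coefficients

def average_coefficients(ensemble: EnsembleResult) -> pd.DataFrame:
    """Per-feature mean signed weight and mean |weight| across the models
    containing the feature's class (32 of 63 when all six classes fit).

    A weight regularized to exactly zero counts as 0 in the mean; a
    feature only drops out of the denominator when its class is absent
    from the spec.  Features excluded at design time (e.g. a gene's own
    overlapping lncRNA) never appear.
    """
    sums, abssums, counts = {}, {}, {}
    for spec, fit in ensemble.fits.items():
        for key, w in fit.coefficients.items():
            sums[key] = sums.get(key, 0.0) + w
            abssums[key] = abssums.get(key, 0.0) + abs(w)
            counts[key] = counts.get(key, 0) + 1
    rows = [(ensemble.gene, cls, feat, sums[k] / counts[k],
             abssums[k] / counts[k], counts[k])
            for k in sorted(sums, key=lambda k: (class_index(k[0]), k[1]))
            for cls, feat in [k]]
    return pd.DataFrame(rows, columns=["gene", "class", "feature",
                                       "mean_coef", "mean_abs_coef",
                                       "n_models"])


# ---------------------------------------------------------------------------
# transfer

TRANSFER_CATEGORIES = ("both", "tumor_only", "adjacent_only", "neither")


@dataclass
class TransferClassification:
    """Per-(gene, class) transfer category and the per-class percentage
    summary.  Categories partition all pairs: a regulator is 'predictive'
    in a tissue when its gain exceeds the threshold."""

    table: pd.DataFrame          # gene, class, gain, gain_adjacent, category
    summary: pd.DataFrame        # class x category percentages
    threshold: float


def classify_transfer(gains: pd.DataFrame, threshold: float = 0.0
                      ) -> TransferClassification:
    """Classify each (gene, class) pair from a long gains table with both
    tumor and adjacent gains: 'both' if gain > threshold in both tissues,
    'tumor_only' / 'adjacent_only' if in exactly one, else 'neither'."""
    tab = gains.copy()

    def _cat(row):
        t = row["gain"] is not None and not pd.isna(row["gain"]) \
            and row["gain"] > threshold
        a = row["gain_adjacent"] is not None \
            and not pd.isna(row["gain_adjacent"]) \
            and row["gain_adjacent"] > threshold
        if t and a:
            return "both"
        if t:
            return "tumor_only"
        if a:
            return "adjacent_only"
        return "neither"

    tab["category"] = tab.apply(_cat, axis=1)
    summary = (tab.groupby("class")["category"]
               .value_counts(normalize=True).unstack(fill_value=0.0) * 100)
    summary = summary.reindex(columns=list(TRANSFER_CATEGORIES),
                              fill_value=0.0)
    summary = summary.reindex(index=[c for c in CLASS_ORDER
                                     if c in summary.index])
    return TransferClassification(table=tab, summary=summary,
                                  threshold=threshold)


def gain_correlation(gains: pd.DataFrame, cls: str) -> float | None:
    """Pearson correlation over genes between tumor and adjacent gains of
    one class; None with < 3 complete genes or zero variance."""
    sub = gains[gains["class"] == cls][["gain", "gain_adjacent"]].dropna()
    if len(sub) < 3:
        return None
    x = sub["gain"].to_numpy(float)
    y = sub["gain_adjacent"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)
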
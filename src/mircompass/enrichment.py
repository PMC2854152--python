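"""GO-SLIM contingency tables, Fisher exact tests and residual diagnostics.

Counting is annotation-level, not gene-level: a gene carrying two
molecular-function categories contributes one count to each, so column
sums can exceed the number of genes in the set.  The r x 2 exact test is
estimated by Monte Carlo over tables with fixed margins (Patefield
sampling) because annotation universes of ~23,000 genes make the full
network algorithm impractical; the estimator is unbiased and reports a
binomial standard error.
"""

from __future__ import annotations

import dataclasses
import warnings
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "contingency_counts",
    "fisher_2x2",
    "fisher_rxc_montecarlo",
    "proportion_table",
    "chisq_residuals",
    "load_reference_counts",
]


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """Categories x 2 annotation counts (set column vs complement column)."""

    categories: tuple[str, ...]
    counts: np.ndarray  # shape (k, 2), non-negative integers
    column_labels: tuple[str, str] = ("in_set", "complement")

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape != (len(self.categories), 2):
            raise ValueError("counts must be categories x 2")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.categories), columns=list(self.column_labels)
        )


def contingency_counts(
    gene_set: Iterable[str],
    annotations: Mapping[str, Sequence[str]],
    universe: Iterable[str],
    categories: Sequence[str] | None = None,
) -> ContingencyTable:
    """Annotation-pair counts for a gene set versus its complement.

    Cell (c, in_set) is the number of (gene, category=c) annotation pairs
    with the gene in the set; multi-annotated genes contribute one count
    per category.
    """
    uni = set(universe)
    gset = set(gene_set)
    if not gset <= uni:
        raise ValueError("gene_set must be a subset of the universe")
    if categories is None:
        cats = sorted({c for g in uni for c in annotations.get(g, ())})
    else:
        cats = list(categories)
    idx = {c: i for i, c in enumerate(cats)}
    counts = np.zeros((len(cats), 2), dtype=np.int64)
    for g in uni:
        col = 0 if g in gset else 1
        for c in annotations.get(g, ()):
            if c in idx:
                counts[idx[c], col] += 1
    return ContingencyTable(categories=tuple(cats), counts=counts)


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Two-sidedness by the probability-mass criterion: the p-value sums the
    hypergeometric probabilities of all tables with the same margins whose
    probability does not exceed the observed table's.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("at least one margin must be positive")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_rxc_montecarlo(
    table: ContingencyTable,
    n_sim: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte Carlo estimate of the exact independence p for an r x 2 table.

    ``n_sim`` tables with the observed margins are generated by Patefield
    sequential sampling; the estimate is
    ``(1 + #{tables at most as probable as observed}) / (n_sim + 1)``
    (the +1 pseudo-count avoids reporting zero), with its binomial
    standard error.  All-zero rows are dropped with a warning.
    """
    if n_sim < 10_000:
        raise ValueError("n_sim must be >= 10,000 for a usable estimate")
    counts = np.asarray(table.counts, dtype=np.int64)
    keep = counts.sum(axis=1) > 0
    if not keep.all():
        warnings.warn("dropping all-zero rows from the contingency table")
        counts = counts[keep]
    if counts.shape[0] < 2:
        raise ValueError("need at least two non-empty categories")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if (col == 0).any():
        raise ValueError("tested columns must have positive sums")

    # table probability with fixed margins is const / prod(n_ij!), so
    # "probability <= observed" is "sum of gammaln(n_ij + 1) >= observed's"
    obs_stat = gammaln(counts + 1).sum()
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(row, col)
    hits = 0
    chunk = 100_000
    done = 0
    while done < n_sim:
        m = min(chunk, n_sim - done)
        sim = sampler.rvs(m, method="patefield", random_state=rng)
        sim_stat = gammaln(sim + 1).sum(axis=(1, 2))
        hits += int((sim_stat >= obs_stat - 1e-9).sum())
        done += m
    p_hat = (1.0 + hits) / (n_sim + 1.0)
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / n_sim))
    return p_hat, se


def proportion_table(table: ContingencyTable, decimals: int = 2) -> pd.DataFrame:
    """Per-category percentages of each column (100 * count / column sum)."""
    sums = table.column_sums
    if (sums == 0).any():
        raise ValueError("cannot compute proportions of an empty column")
    pct = 100.0 * table.counts / sums
    return pd.DataFrame(
        np.round(pct, decimals),
        index=list(table.categories),
        columns=list(table.column_labels),
    )


def chisq_residuals(table: ContingencyTable) -> pd.DataFrame:
    """Per-cell Pearson residuals (observed - expected) / sqrt(expected)."""
    counts = np.asarray(table.counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty table")
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = (counts - expected) / np.sqrt(expected)
    return pd.DataFrame(
        resid, index=list(table.categories), columns=list(table.column_labels)
    )


def load_reference_counts() -> pd.DataFrame:
    """Published GO-SLIM molecular-function annotation counts.

    The table distributed with the package gives, for the 15 molecular-
    function categories, the published annotation counts of the
    up-regulated core set, the down-regulated core set, and their
    complements on the ATH1 annotation universe.
    """
    with resources.files("mircompass.data").joinpath("goslim_mf_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)
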
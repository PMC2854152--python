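"""Per-contrast differential expression and core-set construction.

Each mutant-vs-WT contrast is a per-gene two-group linear model on log2
intensities.  Residual variances are shrunk toward a pooled prior by
empirical Bayes: the prior degrees of freedom and scale are fit by moment
matching on the log-variance distribution, the moderated t uses the
posterior variance, and p-values come from a t distribution with
augmented degrees of freedom.  Genes are called up/down at a
Benjamini-Hochberg FDR threshold, and the core sets are the genes called
in the same direction across every contrast (minus cross-hybridizing
probes).
"""

from __future__ import annotations

import dataclasses
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DiffExprConfig",
    "ContrastResult",
    "moderated_t",
    "bh_fdr",
    "call_contrast",
    "fit_contrasts",
    "core_sets",
    "overlap_table",
]


@dataclasses.dataclass(frozen=True)
class DiffExprConfig:
    fdr_q: float = 0.05
    summarize: str = "mean"  # replicate summary for reported group levels
    fdr_method: str = "fdr_bh"  # the FDR procedure is a config knob

    def __post_init__(self) -> None:
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")


@dataclasses.dataclass
class ContrastResult:
    """Per-gene statistics for one mutant-vs-WT contrast."""

    name: str
    table: pd.DataFrame  # columns: lfc, t, p, q, call
    prior_df: float
    prior_var: float

    @property
    def up_genes(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["call"] == "up"])

    @property
    def down_genes(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["call"] == "down"])


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on a monotone function)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def _fit_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match (prior_df, prior_var) on the log-variance distribution.

    With s2 ~ s0^2 * F(df, d0), log s2 has known digamma/trigamma moments;
    matching the empirical mean and variance of log s2 yields d0 and s0^2.
    A degenerate fit (observed spread no larger than the sampling spread)
    falls back to infinite prior df, i.e. a fully pooled variance.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        # a single gene carries no information about the variance prior:
        # no shrinkage, reduces to the ordinary two-sample t
        return 0.0, 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(e.mean()))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0 = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0


def moderated_t(
    matrix: pd.DataFrame,
    design: pd.Series,
    contrast: tuple[str, str],
) -> ContrastResult:
    """Empirical-Bayes moderated two-group t statistics (no FDR calls yet).

    Parameters
    ----------
    matrix:
        genes x samples log2 expression.
    design:
        sample -> group labels covering every matrix column used.
    contrast:
        (test group, reference group), e.g. ``("dcl1-7", "WT")``.
    """
    test, ref = contrast
    cols_t = [c for c in matrix.columns if design.get(c) == test]
    cols_r = [c for c in matrix.columns if design.get(c) == ref]
    if len(cols_t) < 2 or len(cols_r) < 2:
        raise ValueError(f"need >= 2 replicates per group for {test} vs {ref}")
    xt = matrix[cols_t].to_numpy(float)
    xr = matrix[cols_r].to_numpy(float)
    n1, n2 = xt.shape[1], xr.shape[1]
    df = n1 + n2 - 2

    lfc = xt.mean(axis=1) - xr.mean(axis=1)
    ss = ((xt - xt.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (xr - xr.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df

    d0, s0 = _fit_prior(s2, df)
    if d0 == 0:
        s2_post = s2
        df_total = float(df)
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        df_total = d0 + df

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    p = np.where(
        se > 0,
        2.0 * stats.t.sf(np.abs(np.where(se > 0, t, 0.0)), df_total),
        np.where(lfc == 0, 1.0, 0.0),
    )
    t_degenerate = np.zeros_like(lfc)
    nz = lfc != 0
    t_degenerate[nz] = np.sign(lfc[nz]) * np.inf
    t = np.where(se > 0, t, t_degenerate)

    table = pd.DataFrame(
        {"lfc": lfc, "t": t, "p": p}, index=matrix.index
    )
    return ContrastResult(name=f"{test}_vs_{ref}", table=table, prior_df=d0, prior_var=s0)


def bh_fdr(p: Sequence[float], q: float = 0.05, method: str = "fdr_bh") -> tuple[np.ndarray, np.ndarray]:
    """Step-up FDR control: reject vector plus monotone adjusted values.

    With the Benjamini-Hochberg rule, the i smallest p-values are rejected
    where i is the largest index with p_(i) <= i*q/m; a p-value adjusted
    exactly to ``q`` is rejected (<=).
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, qvals, _, _ = multipletests(p, alpha=q, method=method)
    return reject, qvals


def call_contrast(
    matrix: pd.DataFrame,
    design: pd.Series,
    contrast: tuple[str, str],
    cfg: DiffExprConfig = DiffExprConfig(),
) -> ContrastResult:
    """Moderated t plus FDR calls for one contrast."""
    res = moderated_t(matrix, design, contrast)
    reject, qvals = bh_fdr(res.table["p"].to_numpy(), cfg.fdr_q, cfg.fdr_method)
    res.table["q"] = np.maximum(qvals, res.table["p"])  # monotonicity q >= p
    call = np.full(len(res.table), "none", dtype=object)
    lfc = res.table["lfc"].to_numpy()
    call[reject & (lfc > 0)] = "up"
    call[reject & (lfc < 0)] = "down"
    res.table["call"] = call
    return res


def fit_contrasts(
    matrix: pd.DataFrame,
    design: pd.Series,
    ref: str = "WT",
    cfg: DiffExprConfig = DiffExprConfig(),
    groups: Iterable[str] | None = None,
) -> list[ContrastResult]:
    """One called contrast per non-reference group (in design order)."""
    seen: list[str] = []
    for g in design:
        if g != ref and g not in seen:
            seen.append(g)
    wanted = list(groups) if groups is not None else seen
    return [call_contrast(matrix, design, (g, ref), cfg) for g in wanted]


def core_sets(
    contrasts: Sequence[ContrastResult],
    cross_hyb: Iterable[str] = (),
) -> tuple[frozenset[str], frozenset[str]]:
    """Genes called up (resp. down) in every contrast, minus flagged probes."""
    if len(contrasts) < 2:
        raise ValueError("core sets need at least two contrasts")
    universes = {frozenset(c.table.index) for c in contrasts}
    if len(universes) != 1:
        raise ValueError("contrasts must share one gene universe")
    flagged = set(cross_hyb)
    up = set.intersection(*(set(c.up_genes) for c in contrasts)) - flagged
    down = set.intersection(*(set(c.down_genes) for c in contrasts)) - flagged
    return frozenset(up), frozenset(down)


def overlap_table(
    contrasts: Sequence[ContrastResult], direction: str = "up"
) -> pd.DataFrame:
    """Pairwise shared-call counts and row-conditional percentages.

    For each ordered pair (A, B): the size of A's call set, the overlap
    with B's, and 100*|overlap|/|A| (NaN for an empty A).
    """
    getter = {"up": lambda c: c.up_genes, "down": lambda c: c.down_genes}[direction]
    rows = []
    for a, b in product(contrasts, repeat=2):
        sa, sb = getter(a), getter(b)
        inter = len(sa & sb)
        rows.append(
            {
                "A": a.name,
                "B": b.name,
                "n_A": len(sa),
                "n_shared": inter,
                "pct_of_A": 100.0 * inter / len(sa) if sa else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["A", "B", "n_A", "n_shared", "pct_of_A"])
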
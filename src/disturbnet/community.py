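"""Community-level statistics: diversity, richness, archaeal fraction, PCA
ordination, the variance-then-t two-phase testing procedure, and abiotic
correlation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .io import AbundanceTable

__all__ = [
    "shannon",
    "richness",
    "archaeal_fraction",
    "pca_scores",
    "two_phase_test",
    "abiotic_correlation",
    "PhaseComparison",
]


def shannon(column) -> float:
    """Shannon diversity H = -sum p ln p in nats.

    The column is renormalized over its nonzero entries, so any
    proportional scaling of the input gives the same value.
    """
    p = np.asarray(column, dtype=float)
    if p.size == 0:
        raise ValueError("empty abundance column")
    if (p < 0).any():
        raise ValueError("negative abundance")
    p = p[p > 0]
    if p.size == 0:
        raise ValueError("all-zero abundance column")
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def richness(column) -> int:
    """Number of taxa with nonzero abundance."""
    return int(np.count_nonzero(np.asarray(column, dtype=float) > 0))


def archaeal_fraction(column, annotations: pd.DataFrame, taxa=None) -> float:
    """Share of total abundance carried by Archaea-annotated taxa.

    ``column`` may be a pandas Series indexed by taxon, or an array with an
    explicit ``taxa`` list.  Returns NaN when no counted taxon carries a
    domain annotation (undefined).
    """
    if isinstance(column, pd.Series):
        series = column.astype(float)
    else:
        if taxa is None:
            raise ValueError("taxa required when column is a bare array")
        series = pd.Series(np.asarray(column, dtype=float), index=list(taxa))
    total = float(series.sum())
    if total == 0:
        raise ValueError("all-zero abundance column")
    if "domain" not in annotations:
        return float("nan")
    domains = annotations["domain"].reindex(series.index)
    if domains.isna().all():
        return float("nan")
    return float(series[domains == "Archaea"].sum() / total)


def pca_scores(
    table: AbundanceTable,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """PCA of samples in taxon space.

    The abundance table is transposed (samples become observations), each
    taxon feature is z-scored (mean 0, sd 1 with the n-1 denominator) after
    dropping zero-variance taxa, and the principal components of the
    resulting matrix are returned.  Component signs are fixed so that the
    largest-magnitude loading of each component is positive.

    Returns ``(scores, explained_variance_ratio, dropped_taxa)`` where
    ``scores`` is a samples x components DataFrame with columns PC1, PC2, …
    """
    if table.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    x = table.values.T  # samples x taxa
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [t for t, k in zip(table.taxa, keep) if not k]
    x = x[:, keep]
    if x.shape[1] == 0:
        raise ValueError("no taxa with nonzero variance")
    z = (x - x.mean(axis=0)) / sd[keep]
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(z)
    # sign convention: dominant loading entry of each component positive
    flip = np.sign(
        pca.components_[np.arange(len(pca.components_)),
                        np.abs(pca.components_).argmax(axis=1)]
    )
    flip[flip == 0] = 1.0
    scores = scores * flip
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    frame = pd.DataFrame(scores, index=table.samples, columns=cols)
    return frame, pca.explained_variance_ratio_, dropped


@dataclass
class PhaseComparison:
    """Result of the variance-then-t comparison of two sample phases."""

    metric: str
    before: np.ndarray
    after: np.ndarray
    before_mean: float
    before_sem: float
    after_mean: float
    after_sem: float
    f_p: float
    t_p: float
    variance_mode: str  # "pooled" | "unequal"
    direction: str
    flag: str = ""


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def two_phase_test(
    before,
    after,
    alpha: float = 0.05,
    direction: str = "greater",
    metric: str = "",
) -> PhaseComparison:
    """F test for variance equality, then a one-tailed two-sample t test.

    The F test (two-sided) decides the t-test flavour: equal variances not
    rejected (p > alpha) -> pooled-variance Student t; rejected -> Welch t
    with Satterthwaite degrees of freedom.  ``direction`` states the
    alternative for the *after* phase: ``"greater"`` tests mean(after) >
    mean(before), ``"less"`` the reverse.  The caller supplies the
    direction per metric; it is never inferred from the data.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if len(b) < 2 or len(a) < 2:
        raise ValueError("two_phase_test requires >= 2 values per phase")
    var_b, var_a = float(np.var(b, ddof=1)), float(np.var(a, ddof=1))
    flag = ""
    if var_b == 0.0 and var_a == 0.0:
        f_p = 1.0
        if b.mean() == a.mean():
            t_p = 0.5
            flag = "degenerate"
            mode = "pooled"
        else:
            t_p = 0.0 if (a.mean() > b.mean()) == (direction == "greater") else 1.0
            flag = "zero-variance"
            mode = "pooled"
    else:
        if var_b == 0.0 or var_a == 0.0:
            f_p = 0.0
        else:
            f = var_b / var_a
            dist = stats.f(len(b) - 1, len(a) - 1)
            f_p = float(min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f))))
        mode = "pooled" if f_p > alpha else "unequal"
        res = stats.ttest_ind(
            a, b, equal_var=(mode == "pooled"), alternative=direction
        )
        t_p = float(res.pvalue)
    return PhaseComparison(
        metric=metric,
        before=b,
        after=a,
        before_mean=float(b.mean()),
        before_sem=_sem(b),
        after_mean=float(a.mean()),
        after_sem=_sem(a),
        f_p=f_p,
        t_p=t_p,
        variance_mode=mode,
        direction=direction,
        flag=flag,
    )


def abiotic_correlation(member_series, abiotic_series, method: str = "pearson") -> float:
    """Correlation between a taxon's abundance series and an abiotic series.

    Pearson by default, Spearman by flag.  Returns NaN for zero-variance
    input (correlation undefined).
    """
    x = np.asarray(member_series, dtype=float)
    y = np.asarray(abiotic_series, dtype=float)
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    if len(x) < 3:
        raise ValueError("correlation requires >= 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def sample_summary(
    table: AbundanceTable, annotations: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-sample Shannon diversity, richness and (optionally) archaeal share."""
    rows = []
    for s in table.samples:
        col = table.data[s]
        row = {
            "sample": s,
            "shannon": shannon(col) if (col > 0).any() else float("nan"),
            "richness": richness(col),
        }
        if annotations is not None:
            try:
                row["archaeal_fraction"] = archaeal_fraction(col, annotations)
            except ValueError:
                row["archaeal_fraction"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
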
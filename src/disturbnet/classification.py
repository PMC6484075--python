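"""Abundance-pattern classification of microbial community members.

Each taxon in a time-series abundance table is labelled along three axes:

* abundance level — high (HA, mean share > 1%), low (LA, 0.1–1%) or
  rare (RA) averaged over all samples;
* presence — Core (detected in every sample) vs Ncore (partial presence);
* stability — before-stable (BS), before-variable (BV) or no-change (NC),
  from an F test of the equality of before- vs after-window variances
  followed by a comparison of the coefficients of variation (CV).

A fourth label marks taxa whose abundance during a disturbance window rises
above (induced) or falls below (repressed) both the before- and after-window
means — a convex / concave pattern across the three phases.

The mean used by the CV and the response comparison is the *present-mean*:
the window sum divided by the number of samples in which the taxon was
detected (not the window length).  The CV itself sums squared deviations
over all window entries, zeros included, with an n-1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import AbundanceTable, PhaseDesign

__all__ = [
    "present_mean",
    "cv",
    "abundance_class",
    "presence_class",
    "stability_class",
    "response_class",
    "classify_all",
    "class_summary",
    "aggregate_properties",
    "MemberClassifier",
    "CLASSIFICATION_COLUMNS",
]

#: Fixed column order of the classification TSV.
CLASSIFICATION_COLUMNS = [
    "taxon",
    "abundance_class",
    "presence_class",
    "stability_class",
    "response",
    "present_mean",
    "mean_all",
    "cv_before",
    "cv_after",
    "f_test_p",
    "flags",
]

#: Coefficients below this magnitude count as zero when tallying signs.
ZERO_TOL = 1e-12


def present_mean(series) -> float:
    """Mean abundance over the samples in which the taxon is present.

    Sum of the whole series divided by the count of strictly positive
    entries.  Raises ``ValueError`` for an all-zero series.
    """
    x = np.asarray(series, dtype=float)
    n_present = int(np.count_nonzero(x > 0))
    if n_present == 0:
        raise ValueError("taxon absent in window")
    return float(x.sum() / n_present)


def cv(series) -> float:
    """Coefficient of variation about the present-mean.

    Sample standard deviation (n-1 denominator, deviations over *all*
    entries including zeros) divided by :func:`present_mean`.
    """
    x = np.asarray(series, dtype=float)
    t = len(x)
    if t < 2:
        raise ValueError("cv requires a window of length >= 2")
    xbar = present_mean(x)  # raises on all-zero
    sd = float(np.sqrt(np.sum((x - xbar) ** 2) / (t - 1)))
    return sd / xbar


def abundance_class(
    series_or_mean, ha_threshold: float = 0.01, la_threshold: float = 0.001
) -> str:
    """HA / LA / RA from the plain arithmetic mean over all samples.

    HA strictly above ``ha_threshold``; LA on the closed interval
    [``la_threshold``, ``ha_threshold``]; RA below.  Zeros count toward the
    mean (share of total sequences, not present-mean).
    """
    m = (
        float(series_or_mean)
        if np.isscalar(series_or_mean)
        else float(np.asarray(series_or_mean, dtype=float).mean())
    )
    if m > ha_threshold:
        return "HA"
    if m >= la_threshold:
        return "LA"
    return "RA"


def presence_class(series) -> str:
    """Core iff strictly positive in every sample, else Ncore."""
    x = np.asarray(series, dtype=float)
    return "Core" if bool(np.all(x > 0)) else "Ncore"


def _f_test_two_sided(before: np.ndarray, after: np.ndarray) -> float:
    """Two-sided F test p-value for equality of two variances."""
    var_b = float(np.var(before, ddof=1))
    var_a = float(np.var(after, ddof=1))
    if var_b == 0.0 and var_a == 0.0:
        return 1.0
    if var_b == 0.0 or var_a == 0.0:
        return 0.0
    f = var_b / var_a
    dist = stats.f(len(before) - 1, len(after) - 1)
    return float(min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f))))


def stability_class(
    before_series, after_series, alpha: float = 0.05
) -> tuple[str, float, str]:
    """Classify a taxon's abundance pattern as BS, BV or NC.

    A two-sided F test compares the before- and after-window variances; if
    the variances are not significantly different the taxon is NC.
    Otherwise the CVs decide: before-CV >= after-CV -> BS (variability was
    concentrated before the disturbance), else BV.

    Returns ``(label, f_test_p, flag)``.  Degenerate windows follow fixed
    conventions: both variances zero -> NC with p = 1 (equal by inspection);
    exactly one zero variance -> BS/BV by the CV rule with p = 0 recorded
    (trivially unequal); an all-zero window -> NC with p = NaN and flag
    ``"window-absent"``.
    """
    b = np.asarray(before_series, dtype=float)
    a = np.asarray(after_series, dtype=float)
    if len(b) < 2 or len(a) < 2:
        raise ValueError("stability_class requires >= 2 samples per window")
    if not (b > 0).any() or not (a > 0).any():
        return "NC", float("nan"), "window-absent"
    p = _f_test_two_sided(b, a)
    if p > alpha:
        return "NC", p, ""
    return ("BS" if cv(b) >= cv(a) else "BV"), p, ""


def response_class(before_series, during_series, after_series) -> tuple[str, str]:
    """Induced / repressed / neither from the three window present-means.

    Induced when the during-window present-mean strictly exceeds both the
    before and after present-means (convex pattern); repressed in the
    mirrored concave case; ties or mixed orderings give neither.

    Returns ``(label, flag)``; a window with no presence yields
    ``("neither", "window-absent")``, an empty during window
    ``("neither", "no-during")``.
    """
    d = np.asarray(during_series, dtype=float)
    if d.size == 0:
        return "neither", "no-during"
    windows = [np.asarray(w, dtype=float) for w in (before_series, d, after_series)]
    if any(not (w > 0).any() for w in windows):
        return "neither", "window-absent"
    m_b, m_d, m_a = (present_mean(w) for w in windows)
    if m_d > m_b and m_d > m_a:
        return "induced", ""
    if m_d < m_b and m_d < m_a:
        return "repressed", ""
    return "neither", ""


class MemberClassifier(BaseEstimator):
    """Per-taxon abundance / presence / stability / response labelling.

    Parameters
    ----------
    alpha:
        Significance level of the variance-equality F test (default 0.05).
    ha_threshold, la_threshold:
        Mean-abundance cutoffs for the HA (> 1%) and LA (0.1–1%) classes.
    ncore_min_presence:
        Minimum number of present samples, in the before or in the after
        window, for an Ncore taxon to count as retained; taxa below it are
        flagged ``low-prevalence`` (set to 0 to disable).

    Attributes
    ----------
    labels_:
        DataFrame with one row per taxon in the fixed
        :data:`CLASSIFICATION_COLUMNS` order.
    summary_:
        Presence x abundance x stability cross-tabulation (occupied cells
        only; their counts sum to the number of taxa).
    """

    def __init__(
        self,
        alpha: float = 0.05,
        ha_threshold: float = 0.01,
        la_threshold: float = 0.001,
        ncore_min_presence: int = 3,
    ) -> None:
        self.alpha = alpha
        self.ha_threshold = ha_threshold
        self.la_threshold = la_threshold
        self.ncore_min_presence = ncore_min_presence

    def fit(self, table: AbundanceTable, design: PhaseDesign) -> "MemberClassifier":
        if design.n_samples != table.n_samples:
            raise ValueError("phase design does not match the table's sample count")
        records = []
        vals = table.values
        b_idx, d_idx, a_idx = (
            list(design.before),
            list(design.during),
            list(design.after),
        )
        for i, taxon in enumerate(table.taxa):
            row = vals[i]
            b, d, a = row[b_idx], row[d_idx], row[a_idx]
            flags: list[str] = []
            mean_all = float(row.mean())
            if (row > 0).any():
                pmean = present_mean(row)
            else:
                pmean = float("nan")
                flags.append("absent")
            stab, f_p, stab_flag = stability_class(b, a, alpha=self.alpha)
            if stab_flag:
                flags.append(stab_flag)
            cv_b = cv(b) if (b > 0).any() else float("nan")
            cv_a = cv(a) if (a > 0).any() else float("nan")
            resp, resp_flag = response_class(b, d, a)
            if resp_flag and resp_flag not in flags:
                flags.append(resp_flag)
            pres = presence_class(row)
            if (
                pres == "Ncore"
                and self.ncore_min_presence > 0
                and (row > 0).any()
                and np.count_nonzero(b > 0) < self.ncore_min_presence
                and np.count_nonzero(a > 0) < self.ncore_min_presence
            ):
                flags.append("low-prevalence")
            records.append(
                {
                    "taxon": taxon,
                    "abundance_class": abundance_class(
                        mean_all, self.ha_threshold, self.la_threshold
                    ),
                    "presence_class": pres,
                    "stability_class": stab,
                    "response": resp,
                    "present_mean": pmean,
                    "mean_all": mean_all,
                    "cv_before": cv_b,
                    "cv_after": cv_a,
                    "f_test_p": f_p,
                    "flags": ";".join(flags),
                }
            )
        self.labels_ = pd.DataFrame(records, columns=CLASSIFICATION_COLUMNS)
        self.summary_ = class_summary(self.labels_)
        return self

    def transform(self, table: AbundanceTable | None = None) -> pd.DataFrame:
        if not hasattr(self, "labels_"):
            raise ValueError("MemberClassifier is not fitted")
        return self.labels_


def classify_all(
    table: AbundanceTable,
    design: PhaseDesign,
    alpha: float = 0.05,
    ha_threshold: float = 0.01,
    la_threshold: float = 0.001,
    ncore_min_presence: int = 3,
) -> pd.DataFrame:
    """One classification record per taxon (see :class:`MemberClassifier`)."""
    clf = MemberClassifier(
        alpha=alpha,
        ha_threshold=ha_threshold,
        la_threshold=la_threshold,
        ncore_min_presence=ncore_min_presence,
    )
    return clf.fit(table, design).labels_


def class_summary(labels: pd.DataFrame) -> pd.DataFrame:
    """Occupied-cell counts of the presence x abundance x stability cube."""
    counts = (
        labels.groupby(
            ["presence_class", "abundance_class", "stability_class"], observed=True
        )
        .size()
        .rename("n_taxa")
        .reset_index()
    )
    return counts.sort_values(
        ["presence_class", "abundance_class", "stability_class"], kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class GroupComparison:
    """Directional two-group comparison of an annotation metric."""

    metric: str
    group_high: str
    group_low: str
    mean_high: float
    mean_low: float
    f_p: float
    t_p: float
    flag: str = ""


def aggregate_properties(
    labels: pd.DataFrame, annotations: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Group-wise genomic/functional summaries of the classified taxa.

    Per stability class (BS/BV/NC): group size and mean +/- SEM of GC
    percent and genome size, with pairwise variance-then-t comparisons run
    in the direction of the larger observed mean.  Per abundance class
    (HA/LA/RA): taxon count and the number of distinct pathway identifiers
    in the union over member taxa.  Missing annotations are excluded per
    metric; groups with fewer than two annotated members skip the tests.
    """
    from .community import two_phase_test

    merged = labels.merge(
        annotations, how="left", left_on="taxon", right_index=True
    )
    genomic_rows = []
    for metric in ("gc_percent", "genome_size_mb"):
        if metric not in merged:
            continue
        for group, sub in merged.groupby("stability_class", observed=True):
            vals = sub[metric].dropna().to_numpy(dtype=float)
            genomic_rows.append(
                {
                    "metric": metric,
                    "stability_class": group,
                    "n": len(vals),
                    "mean": float(vals.mean()) if len(vals) else float("nan"),
                    "sem": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                    if len(vals) > 1
                    else float("nan"),
                }
            )
    genomic = pd.DataFrame(genomic_rows)

    test_rows = []
    classes = sorted(merged["stability_class"].dropna().unique())
    for metric in ("gc_percent", "genome_size_mb"):
        if metric not in merged:
            continue
        for i, g1 in enumerate(classes):
            for g2 in classes[i + 1 :]:
                v1 = merged.loc[merged["stability_class"] == g1, metric].dropna()
                v2 = merged.loc[merged["stability_class"] == g2, metric].dropna()
                if len(v1) < 2 or len(v2) < 2:
                    test_rows.append(
                        {
                            "metric": metric,
                            "group_high": g1,
                            "group_low": g2,
                            "mean_high": float("nan"),
                            "mean_low": float("nan"),
                            "f_p": float("nan"),
                            "t_p": float("nan"),
                            "flag": "too-few-annotated",
                        }
                    )
                    continue
                hi, lo = (g1, g2) if v1.mean() >= v2.mean() else (g2, g1)
                v_hi = merged.loc[merged["stability_class"] == hi, metric].dropna()
                v_lo = merged.loc[merged["stability_class"] == lo, metric].dropna()
                cmp = two_phase_test(
                    v_lo.to_numpy(), v_hi.to_numpy(), direction="greater"
                )
                test_rows.append(
                    {
                        "metric": metric,
                        "group_high": hi,
                        "group_low": lo,
                        "mean_high": float(v_hi.mean()),
                        "mean_low": float(v_lo.mean()),
                        "f_p": cmp.f_p,
                        "t_p": cmp.t_p,
                        "flag": cmp.flag,
                    }
                )
    tests = pd.DataFrame(test_rows)

    pathway_rows = []
    for group, sub in merged.groupby("abundance_class", observed=True):
        union: set[str] = set()
        if "pathways" in sub:
            for s in sub["pathways"].dropna():
                union |= set(s)
        pathway_rows.append(
            {
                "abundance_class": group,
                "n_taxa": len(sub),
                "n_pathways": len(union),
            }
        )
    pathways = pd.DataFrame(pathway_rows)
    return {"genomic": genomic, "genomic_tests": tests, "pathways": pathways}
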
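"""Signed, directed interaction-network inference from abundance time series.

The engine is a discrete-time generalized Lotka-Volterra (gLV) regression:
under the map ``x_{i,k+1} = x_{i,k} * exp(dt_k * (r_i + sum_j a_ij x_{j,k}))``
the per-step log-ratio ``y_ik = ln(x_{i,k+1}/x_{i,k}) / dt_k`` is linear in
the community state, so each taxon's growth rate r_i and interaction row
a_i. are recovered by (ridge-penalized) least squares of y on an intercept
plus all member abundances.  a_ij > 0 means taxon j increases taxon i's
growth (edge j -> i in the exported network).

The ensemble procedure wraps the engine: many replicates each fit a random
member subset (default 90% of members), per-pair sign tallies measure
reliability (proportion > 0.9 by default), and only the strongest 10% of
reliable pairs are kept in the final network.  Subset re-closure to
proportions is available but off by default: re-closed member columns sum
to exactly one, which is collinear with the regression intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import AbundanceTable, PhaseDesign, EDGE_COLUMNS

__all__ = [
    "GlvFit",
    "InteractionEnsemble",
    "GLVRegressor",
    "NetworkInferrer",
    "fit_glv",
    "ensemble_infer",
    "consensus_edges",
    "strength_filter",
    "infer_network",
]

#: Coefficients below this magnitude count as neither positive nor negative.
ZERO_TOL = 1e-12


@dataclass
class GlvFit:
    """Fitted discrete-time gLV parameters for one member set."""

    members: list[str]
    growth: np.ndarray  # r_i, per day
    interactions: np.ndarray  # a_ij: effect of j on i, per unit abundance per day
    ridge: float
    pseudocount: float


class GLVRegressor(BaseEstimator):
    """Discrete-time gLV log-ratio ridge regression.

    Parameters
    ----------
    ridge:
        L2 penalty on the interaction coefficients (never on the intercept
        / growth-rate term).  0 gives the exact least-squares fit.
    pseudocount:
        Added to every abundance inside the log ratio so zero observations
        stay finite.

    Attributes
    ----------
    growth_rate_ : ndarray of shape (n_members,)
        Intrinsic growth rates r_i (per day).
    interaction_matrix_ : ndarray of shape (n_members, n_members)
        a_ij, the effect of member j on member i.
    """

    def __init__(self, ridge: float = 1e-3, pseudocount: float = 1e-6) -> None:
        self.ridge = ridge
        self.pseudocount = pseudocount

    def fit(self, X, t=None) -> "GLVRegressor":
        """Fit to a trajectory.

        Parameters
        ----------
        X : array-like of shape (n_timepoints, n_members)
            Abundances in temporal order.
        t : array-like of shape (n_timepoints,), optional
            Observation times in days; uniform unit spacing when absent.
        """
        x = np.asarray(X, dtype=float)
        if x.ndim != 2:
            raise ValueError("X must be 2-D (timepoints x members)")
        n_time, n_members = x.shape
        if n_time < 3:
            raise ValueError("gLV fit requires at least 3 time points")
        if (x < 0).any():
            raise ValueError("abundances must be non-negative")
        if t is None:
            t = np.arange(n_time, dtype=float)
        t = np.asarray(t, dtype=float)
        dt = np.diff(t)
        if (dt <= 0).any():
            raise ValueError("times must be strictly increasing")
        if self.ridge == 0 and n_time < n_members + 2:
            raise ValueError(
                "unpenalized fit needs >= n_members + 2 time points; set ridge > 0"
            )
        eps = self.pseudocount
        y = np.log((x[1:] + eps) / (x[:-1] + eps)) / dt[:, None]
        if not np.isfinite(y).all():
            raise ValueError("non-finite log-ratio response")
        g = np.hstack([np.ones((n_time - 1, 1)), x[:-1]])  # intercept + state
        if self.ridge == 0:
            coef, *_ = np.linalg.lstsq(g, y, rcond=None)
        else:
            penalty = self.ridge * np.eye(n_members + 1)
            penalty[0, 0] = 0.0  # intercept unpenalized
            coef = np.linalg.solve(g.T @ g + penalty, g.T @ y)
        self.growth_rate_ = coef[0].copy()
        self.interaction_matrix_ = coef[1:].T.copy()  # row i = effects on member i
        self.n_features_in_ = n_members
        return self


def fit_glv(
    table: AbundanceTable,
    ridge: float = 1e-3,
    pseudocount: float = 1e-6,
) -> GlvFit:
    """Fit the gLV engine to a (windowed) abundance table."""
    reg = GLVRegressor(ridge=ridge, pseudocount=pseudocount)
    reg.fit(table.values.T, t=table.times)
    return GlvFit(
        members=table.taxa,
        growth=reg.growth_rate_,
        interactions=reg.interaction_matrix_,
        ridge=ridge,
        pseudocount=pseudocount,
    )


@dataclass
class InteractionEnsemble:
    """Per-ordered-pair tallies over subsample replicates.

    Matrices are indexed ``[i, j]`` for the pair (i <- j): the effect of
    member j on member i.  Diagonals (self-pairs) are not tallied.
    """

    members: list[str]
    n_present: np.ndarray  # replicates containing both members
    n_pos: np.ndarray
    n_neg: np.ndarray
    strength_mean: np.ndarray  # mean a_ij over replicates present (NaN if none)
    n_replicates: int
    subsample_fraction: float
    seed: int | None


class NetworkInferrer(BaseEstimator):
    """Subsample-ensemble consensus network inference.

    Parameters mirror the pipeline configuration: ``n_replicates`` ensemble
    size (R), ``subsample_fraction`` member fraction per replicate (f),
    ``p0`` sign-consensus proportion, ``mode`` ("threshold" keeps pairs with
    sign proportion > p0; "test" requires an exact one-sided binomial test
    against p0 at level ``alpha``), ``top_frac`` fraction of reliable pairs
    kept by strength, ``ridge``/``pseudocount`` engine settings,
    ``renormalize`` re-closure of subsampled tables, ``random_state`` seed.

    Attributes
    ----------
    ensemble_ : InteractionEnsemble
    reliable_edges_ : DataFrame of consensus pairs before strength filtering
    network_ : networkx.DiGraph of the retained strongest edges
    """

    def __init__(
        self,
        n_replicates: int = 1000,
        subsample_fraction: float = 0.9,
        p0: float = 0.9,
        mode: str = "threshold",
        alpha: float = 0.05,
        top_frac: float = 0.1,
        ridge: float = 1e-3,
        pseudocount: float = 1e-6,
        renormalize: bool = False,
        random_state: int | None = None,
    ) -> None:
        self.n_replicates = n_replicates
        self.subsample_fraction = subsample_fraction
        self.p0 = p0
        self.mode = mode
        self.alpha = alpha
        self.top_frac = top_frac
        self.ridge = ridge
        self.pseudocount = pseudocount
        self.renormalize = renormalize
        self.random_state = random_state

    def fit(self, X, t=None, members=None) -> "NetworkInferrer":
        """Run the full ensemble -> consensus -> strength-filter chain.

        ``X`` is (n_timepoints, n_members); ``members`` optional member ids.
        """
        x = np.asarray(X, dtype=float)
        n_members = x.shape[1]
        if members is None:
            members = [f"m{i}" for i in range(n_members)]
        table = AbundanceTable(
            pd.DataFrame(
                x.T, index=list(members), columns=[f"s{k}" for k in range(x.shape[0])]
            ),
            t,
        )
        self.ensemble_ = ensemble_infer(
            table,
            n_replicates=self.n_replicates,
            subsample_fraction=self.subsample_fraction,
            ridge=self.ridge,
            pseudocount=self.pseudocount,
            renormalize=self.renormalize,
            seed=self.random_state,
        )
        self.reliable_edges_ = consensus_edges(
            self.ensemble_, p0=self.p0, mode=self.mode, alpha=self.alpha
        )
        self.network_ = strength_filter(self.reliable_edges_, top_frac=self.top_frac)
        return self


def ensemble_infer(
    table: AbundanceTable,
    n_replicates: int = 1000,
    subsample_fraction: float = 0.9,
    ridge: float = 1e-3,
    pseudocount: float = 1e-6,
    renormalize: bool = False,
    seed: int | None = None,
) -> InteractionEnsemble:
    """Tally interaction signs and strengths over member-subsample replicates.

    Each replicate draws ``floor(f * N)`` members uniformly without
    replacement, optionally re-closes the sub-table to proportions, fits the
    gLV engine, and records the sign (and value) of every off-diagonal
    coefficient.  Fully deterministic under a fixed seed.
    """
    n = table.n_taxa
    if n < 3:
        raise ValueError("ensemble inference requires >= 3 members")
    m = int(np.floor(subsample_fraction * n))
    if m < 2:
        raise ValueError(f"subsample size {m} < 2; increase subsample_fraction")
    rng = np.random.default_rng(seed)
    vals = table.values  # taxa x samples
    times = table.times
    n_present = np.zeros((n, n), dtype=int)
    n_pos = np.zeros((n, n), dtype=int)
    n_neg = np.zeros((n, n), dtype=int)
    strength_sum = np.zeros((n, n), dtype=float)
    reg = GLVRegressor(ridge=ridge, pseudocount=pseudocount)
    for _ in range(n_replicates):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = vals[idx]
        if renormalize:
            sums = sub.sum(axis=0)
            sums[sums == 0] = 1.0
            sub = sub / sums
        reg.fit(sub.T, t=times)
        a = reg.interaction_matrix_
        ii = idx[:, None].repeat(m, axis=1)
        jj = idx[None, :].repeat(m, axis=0)
        off = ~np.eye(m, dtype=bool)
        ii, jj, av = ii[off], jj[off], a[off]
        n_present[ii, jj] += 1
        n_pos[ii, jj] += (av > ZERO_TOL).astype(int)
        n_neg[ii, jj] += (av < -ZERO_TOL).astype(int)
        strength_sum[ii, jj] += av
    with np.errstate(invalid="ignore"):
        strength_mean = np.where(
            n_present > 0, strength_sum / np.maximum(n_present, 1), np.nan
        )
    return InteractionEnsemble(
        members=table.taxa,
        n_present=n_present,
        n_pos=n_pos,
        n_neg=n_neg,
        strength_mean=strength_mean,
        n_replicates=n_replicates,
        subsample_fraction=subsample_fraction,
        seed=seed,
    )


def binomial_consensus_p(k: int, n: int, p0: float) -> float:
    """Exact one-sided binomial tail P(X >= k | n, p0)."""
    if n == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


def consensus_edges(
    ensemble: InteractionEnsemble,
    p0: float = 0.9,
    mode: str = "threshold",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Collect sign-consistent (reliable) ordered pairs from an ensemble.

    For each pair and each sign, with tally k out of n replicates present:
    mode ``"threshold"`` accepts when k/n > p0; mode ``"test"`` when the
    exact binomial tail P(X >= k | n, p0) <= alpha.  At most one sign can
    pass for p0 >= 0.5; the pair carries that sign and the ensemble's mean
    coefficient as strength.  Pairs never co-present are skipped.
    Edge orientation: source = acting member j, target = affected member i.
    """
    if mode not in ("threshold", "test"):
        raise ValueError("mode must be 'threshold' or 'test'")
    members = ensemble.members
    rows = []
    n_members = len(members)
    for i in range(n_members):
        for j in range(n_members):
            if i == j:
                continue
            n = int(ensemble.n_present[i, j])
            if n == 0:
                continue
            for sign, k in ((1, int(ensemble.n_pos[i, j])), (-1, int(ensemble.n_neg[i, j]))):
                if mode == "threshold":
                    reliable = k / n > p0
                else:
                    reliable = binomial_consensus_p(k, n, p0) <= alpha
                if reliable:
                    rows.append(
                        {
                            "source": members[j],
                            "target": members[i],
                            "sign": sign,
                            "strength": float(ensemble.strength_mean[i, j]),
                            "n_pos": int(ensemble.n_pos[i, j]),
                            "n_neg": int(ensemble.n_neg[i, j]),
                            "n_present": n,
                        }
                    )
                    break  # at most one sign can be reliable
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def strength_filter(reliable: pd.DataFrame, top_frac: float = 0.1) -> nx.DiGraph:
    """Keep the strongest fraction of reliable pairs as a signed network.

    Pairs are ranked by |strength| descending; ``ceil(top_frac * count)``
    survive.  Ties at the cut are broken lexicographically by
    (source, target) so the kept set is stable across runs.
    """
    g = nx.DiGraph()
    if len(reliable) == 0:
        return g
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must lie in (0, 1]")
    n_keep = int(np.ceil(top_frac * len(reliable)))
    ranked = reliable.assign(_abs=reliable["strength"].abs()).sort_values(
        ["_abs", "source", "target"], ascending=[False, True, True], kind="mergesort"
    )
    kept = ranked.head(n_keep).drop(columns="_abs")
    for row in kept.itertuples(index=False):
        g.add_edge(
            row.source,
            row.target,
            sign=int(row.sign),
            strength=float(row.strength),
            n_pos=int(row.n_pos),
            n_neg=int(row.n_neg),
            n_present=int(row.n_present),
        )
    return g


def infer_network(
    table: AbundanceTable,
    design: PhaseDesign,
    phase: str = "before",
    n_replicates: int = 1000,
    subsample_fraction: float = 0.9,
    p0: float = 0.9,
    mode: str = "threshold",
    alpha: float = 0.05,
    top_frac: float = 0.1,
    ridge: float = 1e-3,
    pseudocount: float = 1e-6,
    renormalize: bool = False,
    seed: int | None = None,
) -> nx.DiGraph:
    """Infer the signed interaction network for one phase window.

    Taxa absent throughout the window are dropped, then the chain
    ensemble_infer -> consensus_edges -> strength_filter runs on the
    window's samples only.
    """
    if phase not in ("before", "during", "after"):
        raise ValueError("phase must be 'before', 'during' or 'after'")
    window = table.window(getattr(design, phase))
    present = window.data.sum(axis=1) > 0
    window = AbundanceTable(window.data.loc[present], window.times)
    inferrer = NetworkInferrer(
        n_replicates=n_replicates,
        subsample_fraction=subsample_fraction,
        p0=p0,
        mode=mode,
        alpha=alpha,
        top_frac=top_frac,
        ridge=ridge,
        pseudocount=pseudocount,
        renormalize=renormalize,
        random_state=seed,
    )
    inferrer.fit(window.values.T, t=window.times, members=window.taxa)
    return inferrer.network_
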
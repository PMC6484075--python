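"""Ground-truth synthetic data: gLV disturbance time series and
classification fixtures.

The simulator iterates the discrete exponential map

    x_{i,k+1} = x_{i,k} * exp(dt_k * (r_i + sum_j a_ij x_{j,k}) + eta_ik)

with a press disturbance modelled as a parameter override (r', A') inside a
declared window — mirroring a sustained temperature drop that suppresses
part of the community and then releases it.  The optional eta term is
per-step environmental (process) stochasticity; without persistent
excitation a deterministic community settles onto a low-dimensional
attractor and carries almost no information about its interaction matrix.

Scenarios are built around an interior equilibrium: a target composition
x* is drawn, the interaction matrix A is sparse and predominantly
competitive (all reciprocal interactions negative; weak one-layer
commensal links from a few "feeder" members mimic cross-feeding), the
self-interaction is diagonally dominant, and r = -A x* so the community
fluctuates around x*.  The competitive structure makes the exponential map
provably bounded — positive-feedback chains amplify multiplicatively
across discrete steps and diverge.

Three data layers are emitted: the noise-free latent trajectories (these
follow the map exactly and support exact parameter recovery), the observed
absolute abundances (latent times observation noise), and the closed
relative-abundance table the analysis pipeline consumes.  Compositional
closure removes the total-abundance degree of freedom, so gLV recovery
from the closed table is necessarily approximate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AbundanceTable, PhaseDesign, EDGE_COLUMNS

__all__ = [
    "GlvScenario",
    "SimulationResult",
    "default_scenario",
    "simulate_glv",
    "truth_edges",
    "TaxonFixtureSpec",
    "default_fixture_specs",
    "make_classification_fixture",
]

#: Abundance floor applied during simulation (keeps the map positive).
FLOOR = 1e-10

#: Divergence guard: any latent abundance above this aborts the scenario.
DIVERGENCE_LIMIT = 1e6


@dataclass
class GlvScenario:
    """A gLV community with a press-disturbance parameter override.

    ``noise`` names the observation-noise model: ``"none"``,
    ``"lognormal"`` (multiplicative ``exp(N(0, sigma))``) or
    ``"multinomial"`` (count sampling at depth ``depth``; columns of the
    closed table then sum to exactly 1).  ``env_sigma`` is the standard
    deviation of the per-step environmental (process) noise inside the
    dynamics; set it to 0 for fully deterministic trajectories.
    """

    growth: np.ndarray
    interactions: np.ndarray
    design: PhaseDesign
    times: np.ndarray
    x0: np.ndarray
    growth_disturbed: np.ndarray | None = None
    interactions_disturbed: np.ndarray | None = None
    noise: str = "none"
    sigma: float = 0.05
    depth: int = 10_000
    env_sigma: float = 0.0
    seed: int | None = None
    member_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.growth = np.asarray(self.growth, dtype=float)
        self.interactions = np.asarray(self.interactions, dtype=float)
        n = len(self.growth)
        if self.interactions.shape != (n, n):
            raise ValueError("interaction matrix shape does not match growth vector")
        if self.noise not in ("none", "lognormal", "multinomial"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if len(self.times) != self.design.n_samples:
            raise ValueError("time grid does not match the phase design")
        if self.member_names is None:
            width = len(str(n))
            self.member_names = [f"taxon{str(i + 1).zfill(width)}" for i in range(n)]

    @property
    def n_members(self) -> int:
        return len(self.growth)


def default_scenario(
    n_members: int = 15,
    n_before: int = 12,
    n_during: int = 3,
    n_after: int = 15,
    density: float = 0.3,
    n_feeders: int = 5,
    noise: str = "lognormal",
    sigma: float = 0.05,
    depth: int = 10_000,
    env_sigma: float = 0.2,
    damping: float = 0.3,
    displacement: float = 1.5,
    dt: float = 7.0,
    seed: int | None = 0,
) -> GlvScenario:
    """Build the package's reference disturbance scenario.

    Interaction structure: off-diagonal pairs are present with probability
    ``density``; all interactions are competitive (negative, magnitudes
    uniform on [0.2, 1.0]) except weak commensal links (positive,
    [0.2, 0.5]) that flow from ``n_feeders`` cross-feeding members to the
    rest — feeders receive no positive input, so no positive-feedback
    chain exists and the discrete map stays bounded.  Self-interaction is
    ``a_ii = -(damping/(dt x*_i) + sum_j |a_ij|)``: diagonally dominant,
    with per-sampling-step damping ``damping`` at equilibrium.

    The community fluctuates around x* ~ Dirichlet(20) under per-step
    environmental noise ``env_sigma``.  Start-up and disturbance are
    suppressions: the initial state and the disturbance-window equilibrium
    displace members downward by lognormal factors exp(-|N(0, s)|) with
    s = ``displacement``, after which the community regrows.  Sampling is
    weekly (dt = 7 days); slower cadence raises the per-interval noise on
    the log-ratio response and faster cadence under-samples turnover.
    """
    rng = np.random.default_rng(seed)
    n = n_members
    mask = rng.random((n, n)) < density
    np.fill_diagonal(mask, False)
    feeders = rng.choice(n, size=min(n_feeders, n), replace=False)
    is_feeder = np.zeros(n, dtype=bool)
    is_feeder[feeders] = True
    magnitude = rng.uniform(0.2, 1.0, size=(n, n))
    sign = -np.ones((n, n))
    commensal = (~is_feeder[:, None]) & is_feeder[None, :] & (rng.random((n, n)) < 0.5)
    sign[commensal] = 1.0
    magnitude[commensal] = rng.uniform(0.2, 0.5, size=int(commensal.sum()))
    a = np.where(mask, sign * magnitude, 0.0)
    x_star = rng.dirichlet(np.full(n, 20.0))
    np.fill_diagonal(a, -(damping / (dt * x_star) + np.abs(a).sum(axis=1)))
    r = -a @ x_star
    x_star_dist = x_star * np.exp(-np.abs(rng.normal(0.0, displacement, size=n)))
    x_star_dist = x_star_dist * x_star.sum() / x_star_dist.sum()
    r_dist = -a @ x_star_dist
    x0 = x_star * np.exp(-np.abs(rng.normal(0.0, displacement, size=n)))
    design = PhaseDesign.from_sizes(n_before, n_during, n_after)
    times = dt * np.arange(design.n_samples, dtype=float)
    return GlvScenario(
        growth=r,
        interactions=a,
        design=design,
        times=times,
        x0=x0,
        growth_disturbed=r_dist,
        interactions_disturbed=None,
        noise=noise,
        sigma=sigma,
        depth=depth,
        env_sigma=env_sigma,
        seed=seed,
    )


@dataclass
class SimulationResult:
    """Output bundle of :func:`simulate_glv`."""

    table: AbundanceTable  # closed, noisy — what the pipeline consumes
    observed: AbundanceTable  # absolute abundances with observation noise
    latent: AbundanceTable  # noise-free trajectories (follow the map exactly)
    design: PhaseDesign
    scenario: GlvScenario


def simulate_glv(scenario: GlvScenario) -> SimulationResult:
    """Iterate the disturbance scenario and emit tables + ground truth.

    Base parameters (r, A) drive the before and after windows; the
    override (r', A') governs every step *into* a during-window sample.
    Environmental noise perturbs the dynamics per step; observation noise
    is applied afterwards; the closed table divides each column by its
    sum.  Distinct, seed-derived random streams drive the two noise
    layers, so the latent trajectory of a scenario is unchanged when only
    the observation-noise model differs.
    """
    n = scenario.n_members
    times = np.asarray(scenario.times, dtype=float)
    n_samples = len(times)
    during = set(scenario.design.during)
    r_d = (
        scenario.growth_disturbed
        if scenario.growth_disturbed is not None
        else scenario.growth
    )
    a_d = (
        scenario.interactions_disturbed
        if scenario.interactions_disturbed is not None
        else scenario.interactions
    )
    env_rng = np.random.default_rng(
        None if scenario.seed is None else [int(scenario.seed), 1]
    )
    obs_rng = np.random.default_rng(
        None if scenario.seed is None else [int(scenario.seed), 2]
    )
    x = np.empty((n, n_samples), dtype=float)
    x[:, 0] = np.maximum(scenario.x0, FLOOR)
    for k in range(n_samples - 1):
        dt = times[k + 1] - times[k]
        if (k + 1) in during:
            r_k, a_k = r_d, a_d
        else:
            r_k, a_k = scenario.growth, scenario.interactions
        growth = dt * (r_k + a_k @ x[:, k])
        if scenario.env_sigma > 0:
            growth = growth + env_rng.normal(0.0, scenario.env_sigma, size=n)
        with np.errstate(over="ignore"):
            step = x[:, k] * np.exp(growth)
        if not np.all(np.isfinite(step)) or np.any(step > DIVERGENCE_LIMIT):
            raise ValueError("unstable scenario: abundance diverged")
        x[:, k + 1] = np.maximum(step, FLOOR)
    samples = [f"T{k + 1}" for k in range(n_samples)]
    latent = AbundanceTable(
        pd.DataFrame(x, index=scenario.member_names, columns=samples), times
    )
    obs = x.copy()
    if scenario.noise == "lognormal":
        obs = obs * np.exp(obs_rng.normal(0.0, scenario.sigma, size=obs.shape))
    elif scenario.noise == "multinomial":
        p = obs / obs.sum(axis=0)
        counts = np.column_stack(
            [obs_rng.multinomial(scenario.depth, p[:, k]) for k in range(n_samples)]
        )
        obs = counts.astype(float)
    observed = AbundanceTable(
        pd.DataFrame(obs, index=scenario.member_names, columns=samples), times
    )
    closed = obs / obs.sum(axis=0)
    table = AbundanceTable(
        pd.DataFrame(closed, index=scenario.member_names, columns=samples), times
    )
    return SimulationResult(
        table=table,
        observed=observed,
        latent=latent,
        design=scenario.design,
        scenario=scenario,
    )


def truth_edges(scenario: GlvScenario, zero_tol: float = 1e-12) -> pd.DataFrame:
    """Nonzero base interactions as an edge frame (source acts on target)."""
    a = scenario.interactions
    names = scenario.member_names
    rows = []
    n = scenario.n_members
    for i in range(n):
        for j in range(n):
            if i == j or abs(a[i, j]) <= zero_tol:
                continue
            rows.append(
                {
                    "source": names[j],
                    "target": names[i],
                    "sign": 1 if a[i, j] > 0 else -1,
                    "strength": float(a[i, j]),
                    "n_pos": 0,
                    "n_neg": 0,
                    "n_present": 0,
                }
            )
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


# ---------------------------------------------------------------------------
# Classification fixtures
# ---------------------------------------------------------------------------

#: Window-mean scale per abundance class (share of community).
_ABUNDANCE_MEAN = {"HA": 0.02, "LA": 0.004, "RA": 0.0004}

#: Within-window coefficient of variation of the variable / quiet windows.
#: The 25-fold variance ratio keeps the F test decisively significant at
#: n = 12 vs 15 even when "neither" responses separate the window means.
_CV_HIGH = 0.35
_CV_LOW = 0.07
_CV_NC = 0.2

#: During-window mean multiplier per response target.
_RESPONSE_FACTOR = {"induced": 2.0, "repressed": 0.4, "neither": 1.0}


@dataclass
class TaxonFixtureSpec:
    """Prescribed labels plus the generating moments for one fixture taxon."""

    name: str
    abundance_class: str
    presence_class: str
    stability_class: str
    response: str
    mean_before: float
    mean_during: float
    mean_after: float
    sd_before: float
    sd_after: float
    n_zero_before: int = 0
    n_zero_after: int = 0

    @classmethod
    def from_labels(
        cls,
        name: str,
        abundance: str,
        presence: str,
        stability: str,
        response: str,
    ) -> "TaxonFixtureSpec":
        """Derive satisfiable generating moments from target labels.

        Stability dictates the window variances: BS/BV use a decisive
        25-fold variance ratio (CV 0.35 vs 0.07, scaled with the window
        mean), NC uses the same absolute SD in both windows.  For Ncore
        taxa the masked zeros go where they reinforce (or least disturb)
        the target: zeros inflate a window's variance, so BS zeros sit in
        the before window, BV zeros after, NC one in each.  A ``neither``
        response separates the before/after means (0.75x vs 1.25x) so the
        during mean sits strictly between them.
        """
        for value, allowed in (
            (abundance, ("HA", "LA", "RA")),
            (presence, ("Core", "Ncore")),
            (stability, ("BS", "BV", "NC")),
            (response, ("induced", "repressed", "neither")),
        ):
            if value not in allowed:
                raise ValueError(f"label {value!r} not in {allowed}")
        m = _ABUNDANCE_MEAN[abundance]
        if response == "neither":
            mean_b, mean_a = 0.75 * m, 1.25 * m
        else:
            mean_b = mean_a = m
        if stability == "BS":
            sd_b, sd_a = _CV_HIGH * mean_b, _CV_LOW * mean_a
            zeros = (2, 0)
        elif stability == "BV":
            sd_b, sd_a = _CV_LOW * mean_b, _CV_HIGH * mean_a
            zeros = (0, 2)
        else:
            sd_b = sd_a = _CV_NC * m
            zeros = (1, 1)
        if presence == "Core":
            zeros = (0, 0)
        return cls(
            name=name,
            abundance_class=abundance,
            presence_class=presence,
            stability_class=stability,
            response=response,
            mean_before=mean_b,
            mean_during=m * _RESPONSE_FACTOR[response],
            mean_after=mean_a,
            sd_before=sd_b,
            sd_after=sd_a,
            n_zero_before=zeros[0],
            n_zero_after=zeros[1],
        )

    def validate(self, design: PhaseDesign) -> None:
        if self.presence_class == "Core" and (self.n_zero_before or self.n_zero_after):
            raise ValueError(f"{self.name}: Core taxon cannot carry masked zeros")
        if self.presence_class == "Ncore" and not (
            self.n_zero_before or self.n_zero_after
        ):
            raise ValueError(f"{self.name}: Ncore taxon needs at least one masked zero")
        if self.n_zero_before > design.t1 - 3 or self.n_zero_after > design.t2 - 3:
            raise ValueError(f"{self.name}: too many masked zeros for the design")
        if self.response != "neither" and len(design.during) == 0:
            raise ValueError(f"{self.name}: response target needs a during window")


def default_fixture_specs(n_taxa: int = 36, seed: int | None = None) -> list[TaxonFixtureSpec]:
    """A balanced spread of label combinations.

    Core and Ncore alternate; Ncore taxa are always RA (matching the
    empirical pattern that partially present taxa are rare); abundance is
    weighted toward the rare biosphere (HA capped at 15 taxa so the
    community mass budget stays below 1).
    """
    stabilities = ["BS", "BV", "NC"]
    responses = ["induced", "repressed", "neither"]
    specs = []
    n_ha = 0
    for i in range(n_taxa):
        presence = "Core" if i % 2 == 0 else "Ncore"
        if presence == "Ncore":
            abundance = "RA"
        else:
            abundance = ["HA", "LA", "RA"][(i // 2) % 3]
            if abundance == "HA":
                n_ha += 1
                if n_ha > 15:
                    abundance = "LA"
        specs.append(
            TaxonFixtureSpec.from_labels(
                name=f"fx{str(i + 1).zfill(len(str(n_taxa)))}",
                abundance=abundance,
                presence=presence,
                stability=stabilities[i % 3],
                response=responses[(i // 3) % 3],
            )
        )
    return specs


def make_classification_fixture(
    specs: list[TaxonFixtureSpec],
    design: PhaseDesign,
    seed: int | None = None,
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Draw an abundance table realizing the prescribed labels.

    Window values are normal draws with the spec's means/SDs, clipped to a
    small positive floor; masked zeros are placed at random positions of
    the relevant window.  A ``filler`` taxon absorbs each column's
    remainder so closure to proportions leaves the focal values untouched.
    Returns the closed table and the truth-label frame (filler excluded).
    """
    for spec in specs:
        spec.validate(design)
    rng = np.random.default_rng(seed)
    n_samples = design.n_samples
    rows = {}
    for spec in specs:
        row = np.zeros(n_samples)
        floor = 1e-3 * min(spec.mean_before, spec.mean_during or spec.mean_before)
        for idx, mean, sd in (
            (list(design.before), spec.mean_before, spec.sd_before),
            (list(design.during), spec.mean_during, _CV_NC * spec.mean_during),
            (list(design.after), spec.mean_after, spec.sd_after),
        ):
            if idx:
                row[idx] = np.maximum(rng.normal(mean, sd, size=len(idx)), floor)
        for window, n_zero in (
            (list(design.before), spec.n_zero_before),
            (list(design.after), spec.n_zero_after),
        ):
            if n_zero:
                row[rng.choice(window, size=n_zero, replace=False)] = 0.0
        rows[spec.name] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    col_sums = frame.sum(axis=0).to_numpy()
    if (col_sums >= 1.0).any():
        raise ValueError("fixture specs exceed the unit mass budget; reduce means")
    frame.loc["filler"] = 1.0 - col_sums
    frame.columns = [f"T{k + 1}" for k in range(n_samples)]
    table = AbundanceTable(frame)
    truth = pd.DataFrame(
        [
            {
                "taxon": s.name,
                "abundance_class": s.abundance_class,
                "presence_class": s.presence_class,
                "stability_class": s.stability_class,
                "response": s.response,
            }
            for s in specs
        ]
    )
    return table, truth
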
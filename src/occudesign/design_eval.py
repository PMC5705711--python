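"""Survey-design arithmetic and Monte-Carlo evaluation of estimator quality.

Two questions drive survey design for species with imperfect detection:
how many repeat visits are needed before a string of non-detections can
be read as true absence, and how precise are the occupancy and
detection estimators under a candidate combination of sites (S) and
occasions (K).  The first has a closed form; the second is answered by
simulating detection histories under known parameters, refitting the
constant model, and summarising the sampling distribution of the MLEs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .occupancy_core import fit_constant
from .study_io import ValidationError

__all__ = [
    "DesignScenario",
    "SimulationSummary",
    "min_occasions",
    "simulate_mle_distribution",
    "evaluate_design_grid",
]

_CEIL_TOL = 1e-12  # guards exact-integer ratios against float inflation


def min_occasions(p: float, p_star: float) -> int:
    """Minimum number of occasions K to infer absence with confidence p_star.

    Solves for the smallest integer K with cumulative detection
    probability 1 - (1 - p)^K >= p_star, i.e. the ceiling of
    log(1 - p_star) / log(1 - p).  A site surveyed K times without a
    detection can then be declared unoccupied with probability p_star
    of having detected the species were it present.
    """
    if not 0 < p < 1:
        raise ValidationError(f"detection probability must be in (0,1), got {p}")
    if not 0 < p_star < 1:
        raise ValidationError(f"cumulative target must be in (0,1), got {p_star}")
    ratio = math.log(1.0 - p_star) / math.log(1.0 - p)
    return max(1, int(math.ceil(ratio - _CEIL_TOL)))


@dataclass(frozen=True)
class DesignScenario:
    """A candidate survey design: parameters plus effort (S sites, K occasions)."""

    psi: float
    p: float
    n_sites: int
    n_occasions: int
    p_star: float = 0.95

    def __post_init__(self) -> None:
        for name in ("psi", "p", "p_star"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0,1], got {v}")
        if self.n_sites < 2:
            raise ValidationError("n_sites must be >= 2")
        if self.n_occasions < 1:
            raise ValidationError("n_occasions must be >= 1")


@dataclass
class SimulationSummary:
    """Sampling-distribution summary of the constant-model MLEs.

    Moment summaries (mean, bias, RMSE, quantiles) are taken over
    non-degenerate fits only; datasets driving the MLE to the parameter
    boundary (e.g. zero detections anywhere) are counted in
    ``boundary_rate`` rather than silently mixed into the moments.
    """

    scenario: DesignScenario
    n_iter: int
    seed: int | None
    boundary_rate: float
    stats: pd.DataFrame  # rows psi/p; columns mean, median, sd, bias, rmse, q2.5, q97.5
    estimates: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    def row(self) -> dict:
        """Flatten to one tidy record (for design-grid tables)."""
        out = {
            "psi": self.scenario.psi,
            "p": self.scenario.p,
            "n_sites": self.scenario.n_sites,
            "n_occasions": self.scenario.n_occasions,
            "n_iter": self.n_iter,
            "boundary_rate": self.boundary_rate,
        }
        for par in ("psi", "p"):
            for stat in self.stats.columns:
                out[f"{par}_hat_{stat}"] = self.stats.loc[par, stat]
        return out


def _cell_rng(seed: int | None, scenario: DesignScenario) -> np.random.Generator:
    # seed derived from (master seed, S, K) so each grid cell reproduces
    # independently of evaluation order
    entropy = [scenario.n_sites, scenario.n_occasions]
    if seed is not None:
        entropy = [seed] + entropy
    return np.random.default_rng(np.random.SeedSequence(entropy))


def simulate_mle_distribution(
    scenario: DesignScenario, n_iter: int, seed: int | None = None
) -> SimulationSummary:
    """Distribution of constant-model MLEs under a known design.

    Each iteration draws S latent occupancy states Bernoulli(psi),
    detections Bernoulli(p) over K occasions at occupied sites, and
    refits the constant model by maximum likelihood.
    """
    if n_iter < 100:
        raise ValidationError("n_iter must be >= 100 for stable summaries")
    rng = _cell_rng(seed, scenario)
    S, K = scenario.n_sites, scenario.n_occasions

    # detection counts per site suffice: d_i | z_i=1 ~ Binomial(K, p), else 0
    z = rng.random((n_iter, S)) < scenario.psi
    d = np.where(z, rng.binomial(scenario.n_occasions, scenario.p, size=(n_iter, S)), 0)

    k = np.full(S, K)
    psi_hat = np.empty(n_iter)
    p_hat = np.empty(n_iter)
    bnd = np.empty(n_iter, dtype=bool)
    for it in range(n_iter):
        psi_hat[it], p_hat[it], _, bnd[it] = fit_constant(d[it], k)

    ok = ~bnd
    est = pd.DataFrame({"psi_hat": psi_hat, "p_hat": p_hat, "boundary": bnd})
    rows = {}
    for par, vals, truth in (("psi", psi_hat[ok], scenario.psi), ("p", p_hat[ok], scenario.p)):
        if vals.size == 0:
            rows[par] = {c: np.nan for c in ("mean", "median", "sd", "bias", "rmse", "q2.5", "q97.5")}
            continue
        bias = float(np.mean(vals) - truth)
        rows[par] = {
            "mean": float(np.mean(vals)),
            "median": float(np.median(vals)),
            "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
            "bias": bias,
            "rmse": float(np.sqrt(np.mean((vals - truth) ** 2))),
            "q2.5": float(np.percentile(vals, 2.5)),
            "q97.5": float(np.percentile(vals, 97.5)),
        }
    stats = pd.DataFrame(rows).T[["mean", "median", "sd", "bias", "rmse", "q2.5", "q97.5"]]
    return SimulationSummary(
        scenario=scenario,
        n_iter=n_iter,
        seed=seed,
        boundary_rate=float(np.mean(bnd)),
        stats=stats,
        estimates=est,
    )


def evaluate_design_grid(
    psi: float,
    p: float,
    site_grid: list[int],
    occasion_grid: list[int],
    n_iter: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """One MLE-distribution summary per (S, K) cell, as a tidy table.

    The table exposes precision (sd, RMSE) of both estimators across
    the effort grid, the raw material for choosing a design that buys
    acceptable precision with the fewest visits.
    """
    if not site_grid or not occasion_grid:
        raise ValidationError("site and occasion grids must be non-empty")
    rows = []
    for S in site_grid:
        for K in occasion_grid:
            summ = simulate_mle_distribution(
                DesignScenario(psi=psi, p=p, n_sites=S, n_occasions=K), n_iter, seed
            )
            rows.append(summ.row())
    return pd.DataFrame(rows)
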
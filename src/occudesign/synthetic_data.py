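"""Synthetic bromeliad-survey generator with a known truth ledger.

The generator emulates a monitoring study of a bromeliad-dwelling frog
on a single mountain summit: ~143 tagged bromeliads ("sites") split
across three altitudinal zones, occupancy strongly zone-dependent
(moderate at high and medium elevation, low in the lowest band),
detection per night depending on observer experience, and 4-6
consecutive survey nights per month over several months.  Latent
occupancy is drawn once per site and held fixed across all occasions
(the closure assumption of the single-season model), detections are
independent Bernoulli draws at occupied sites, and every generated
dataset carries a truth record with the latent states and generating
parameters so estimator and selection behaviour can be checked against
known values.

The generator produces study-shaped data, not field data: there is no
between-month movement, no abundance-driven detection heterogeneity,
and covariates other than zone/elevation and observer are drawn
independently of the latent state (they are pure decoys for model
selection).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .study_io import (
    DetectionHistory,
    SiteCovariateTable,
    SurveyCovariateTable,
    ValidationError,
    write_history,
    write_site_covariates,
    write_survey_covariates,
)

__all__ = ["StudyGeneratorConfig", "SyntheticStudy", "generate_study", "generate_two_period"]

_ZONES = ("low", "medium", "high")


@dataclass(frozen=True)
class StudyGeneratorConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the monitored population: 48/48/47 sites in the
    low/medium/high zones, zone occupancy 0.14/0.66/0.66, per-night
    detection 0.61 for the experienced observer and 0.38 for the
    inexperienced one, and 4 monthly surveys of 4-6 nights each.
    Elevation bands (m a.s.l.) are disjoint and ordered low < medium <
    high.
    """

    n_sites_per_zone: tuple[int, int, int] = (48, 48, 47)  # low, medium, high
    zone_psi: tuple[float, float, float] = (0.14, 0.66, 0.66)
    observer_p: dict[str, float] = field(
        default_factory=lambda: {"high": 0.61, "low": 0.38}
    )
    occasions_per_month: tuple[int, int] = (4, 6)  # inclusive range
    n_months: int = 4
    elevation_ranges: tuple[tuple[float, float], ...] = (
        (1704.0, 1815.0),
        (1838.0, 1925.0),
        (1998.0, 2060.0),
    )
    observer_assignment: str = "alternating"  # or "random"
    with_neighbours: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_sites_per_zone):
            raise ValidationError("each zone needs at least one site")
        if any(not 0 < psi <= 1 for psi in self.zone_psi):
            raise ValidationError("zone occupancy probabilities must be in (0,1]")
        if any(not 0 < p <= 1 for p in self.observer_p.values()):
            raise ValidationError("observer detection probabilities must be in (0,1]")
        lo, hi = self.occasions_per_month
        if not 1 <= lo <= hi:
            raise ValidationError("invalid occasions-per-month range")
        if self.n_months < 1:
            raise ValidationError("need at least one month")
        bands = self.elevation_ranges
        if len(bands) != 3 or any(a >= b for a, b in bands):
            raise ValidationError("three non-empty elevation bands required")
        if not (bands[0][1] < bands[1][0] and bands[1][1] < bands[2][0]):
            raise ValidationError("elevation bands must be disjoint and ordered")
        if self.observer_assignment not in ("alternating", "random"):
            raise ValidationError("observer_assignment must be 'alternating' or 'random'")

    @property
    def n_sites(self) -> int:
        return sum(self.n_sites_per_zone)


@dataclass
class SyntheticStudy:
    """A generated dataset plus the truth that generated it."""

    history: DetectionHistory
    site_covariates: SiteCovariateTable
    survey_covariates: SurveyCovariateTable
    truth: dict
    neighbour_history: DetectionHistory | None = None

    def write(self, outdir: str | Path) -> None:
        """Write history/covariate CSVs and the truth ledger as JSON."""
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_history(self.history, outdir / "history.csv")
        write_site_covariates(self.site_covariates, outdir / "site_covariates.csv")
        write_survey_covariates(self.survey_covariates, outdir / "survey_covariates.csv")
        if self.neighbour_history is not None:
            write_history(self.neighbour_history, outdir / "neighbour_history.csv")
        truth = dict(self.truth)
        truth["z"] = [int(z) for z in truth["z"]]
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)


def _month_labels(n_months: int) -> list[str]:
    base = ["feb", "mar", "apr", "may", "jun", "jul", "aug", "sep", "oct", "nov", "dec", "jan"]
    return [base[i % 12] if n_months <= 12 else f"m{i + 1}" for i in range(n_months)]


def generate_study(config: StudyGeneratorConfig, seed: int | None = None) -> SyntheticStudy:
    """Generate one synthetic single-season study.

    ``seed`` overrides ``config.seed`` when given.  The same seed always
    produces the same study, byte-identical on disk.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    # --- sites and site covariates ---
    zones = np.repeat(_ZONES, config.n_sites_per_zone)
    S = config.n_sites
    site_ids = [f"B{i + 1:03d}" for i in range(S)]
    elev = np.empty(S)
    for zone, (lo, hi) in zip(_ZONES, config.elevation_ranges):
        m = zones == zone
        elev[m] = rng.uniform(lo, hi, m.sum())
    # plant morphology: decoy covariates, independent of occupancy
    height = rng.uniform(20.0, 80.0, S)  # cm
    width = rng.uniform(20.0, 90.0, S)
    site_df = pd.DataFrame(
        {
            "zone": zones,
            "elevation": np.round(elev, 1),
            "bromeliad_size": np.round(height * width, 1),
            "rosette_volume": np.round(0.4 * height * 0.5 * width, 1),
            "n_leaves": rng.poisson(15, S),
            "n_neighbours": rng.poisson(2, S),
        },
        index=pd.Index(site_ids, name="site"),
    )

    # --- occasions ---
    lo, hi = config.occasions_per_month
    occ_per_month = rng.integers(lo, hi + 1, config.n_months)
    months = _month_labels(config.n_months)
    occ_labels = [
        f"{m}_{j + 1}" for m, n in zip(months, occ_per_month) for j in range(n)
    ]
    K = len(occ_labels)

    # --- observers ---
    levels = sorted(config.observer_p)  # ("high", "low")
    if config.observer_assignment == "alternating":
        # the two survey teams alternate nights over the whole site list
        obs_idx = np.tile(np.arange(K) % 2, (S, 1))
    else:
        obs_idx = rng.integers(0, 2, (S, K))
    observer = np.array(levels, dtype=object)[obs_idx]
    p_mat = np.array([config.observer_p[l] for l in levels])[obs_idx]
    dusk = np.round(rng.uniform(10.0, 300.0, (S, K)), 0)  # minutes after dusk

    # --- latent states and detections ---
    psi_site = np.select(
        [zones == z for z in _ZONES], list(config.zone_psi)
    )
    z = rng.random(S) < psi_site
    y = (rng.random((S, K)) < p_mat) & z[:, None]
    history = DetectionHistory(site_ids, y.astype(float), occ_labels)

    survey_covs = SurveyCovariateTable(
        site_ids, occ_labels, {"observer_experience": observer, "time_after_dusk": dusk}
    )

    neighbour = None
    if config.with_neighbours:
        # neighbours share the tagged site's latent state; detections are
        # fresh draws (minimal model: pooling mechanics only)
        yn = (rng.random((S, K)) < p_mat) & z[:, None]
        neighbour = DetectionHistory(site_ids, yn.astype(float), occ_labels)

    truth = {
        "seed": seed,
        "zone_psi": dict(zip(_ZONES, config.zone_psi)),
        "observer_p": dict(config.observer_p),
        "occasions_per_month": [int(n) for n in occ_per_month],
        "z": z.astype(int).tolist(),
        "n_sites_per_zone": dict(zip(_ZONES, config.n_sites_per_zone)),
    }
    return SyntheticStudy(history, SiteCovariateTable(site_df), survey_covs, truth, neighbour)


def generate_two_period(
    config: StudyGeneratorConfig, effect: float, seed: int | None = None
) -> tuple[SyntheticStudy, SyntheticStudy]:
    """Two independent study periods with a proportional occupancy decline.

    Period 2 revisits the same sites (same covariates and observer
    schedule) with zone occupancies scaled to psi_z * (1 - effect);
    latent states and detections are drawn independently between
    periods.
    """
    psi2 = tuple(psi * (1.0 - effect) for psi in config.zone_psi)
    if any(not 0 < v < 1 for v in psi2):
        raise ValidationError(
            f"period-2 zone occupancy {psi2} outside (0,1) at effect {effect}"
        )
    seed = config.seed if seed is None else seed
    base = generate_study(config, seed)
    cfg2 = _replace_frozen(config, zone_psi=psi2, seed=None)
    rng = np.random.default_rng(np.random.SeedSequence([seed if seed is not None else 0, 2]))

    # redraw latent states and detections only; covariates carried over
    S, K = base.history.n_sites, base.history.n_occasions
    zones = base.site_covariates.table["zone"].to_numpy()
    psi_site = np.select([zones == z for z in _ZONES], list(psi2))
    z = rng.random(S) < psi_site
    levels = sorted(config.observer_p)
    obs = base.survey_covariates.covariates["observer_experience"]
    p_mat = np.select([obs == l for l in levels], [config.observer_p[l] for l in levels])
    y = (rng.random((S, K)) < p_mat) & z[:, None]
    hist2 = DetectionHistory(
        list(base.history.site_ids), y.astype(float), list(base.history.occasion_labels)
    )
    truth2 = dict(base.truth)
    truth2.update({"zone_psi": dict(zip(_ZONES, psi2)), "z": z.astype(int).tolist(), "period": 2})
    period2 = SyntheticStudy(
        hist2, base.site_covariates, base.survey_covariates, truth2, None
    )
    return base, period2


def _replace_frozen(config: StudyGeneratorConfig, **kw) -> StudyGeneratorConfig:
    data = asdict(config)
    data.update(kw)
    return StudyGeneratorConfig(**data)
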
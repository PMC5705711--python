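"""Single-season site-occupancy model with covariates on logit links.

The model estimates occupancy probability (psi, the probability that a
randomly chosen site is occupied) and detection probability (p, the
probability of detecting the species on one visit to an occupied site)
from repeat-visit detection/non-detection data.  A site with at least
one detection contributes

    psi_i * prod_t p_it^y_it (1 - p_it)^(1 - y_it)

to the likelihood, while a site with no detections contributes

    psi_i * prod_t (1 - p_it) + (1 - psi_i),

the mixture of "occupied but always missed" and "truly unoccupied".
Products run over surveyed occasions only, so missing visits simply
contribute no factor (occasion-wise deletion).  The model assumes
closure (the latent state does not change within the season), no false
positives, and independence between sites.

Both parameters are modelled on the logit scale; continuous covariates
are centred and scaled to unit variance before fitting and categorical
covariates are dummy-coded against the first (alphabetical) level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, log_expit, logit

from .study_io import (
    DetectionHistory,
    SiteCovariateTable,
    SurveyCovariateTable,
    ValidationError,
)

__all__ = [
    "OccupancyModelSpec",
    "OccupancyFit",
    "occupancy_loglik",
    "fit_occupancy",
    "fit_constant",
    "predict_parameters",
    "build_selection_table",
    "stepwise_select",
]

logger = logging.getLogger(__name__)

_ETA_BOUND = 15.0  # logit-scale box for the optimizer
_BOUNDARY_ETA = 13.8  # |logit| beyond which a probability is within ~1e-6 of 0/1


# ----------------------------------------------------------------------
# model specification and design matrices
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class OccupancyModelSpec:
    """Covariate structure for occupancy (psi) and detection (p).

    Empty tuples mean a constant (intercept-only) parameter.  Covariate
    names refer to columns of the site covariate table (for psi, or for
    p when the covariate is site-level) or of the survey covariate
    table (for p).
    """

    psi_covariates: tuple[str, ...] = ()
    p_covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for group in (self.psi_covariates, self.p_covariates):
            if len(set(group)) != len(group):
                raise ValidationError(f"duplicate covariate in model spec: {group}")

    @property
    def name(self) -> str:
        psi = ",".join(self.psi_covariates) or "."
        p = ",".join(self.p_covariates) or "."
        return f"psi({psi})p({p})"


@dataclass
class _ColumnCoding:
    """How one covariate was turned into design columns (for reuse in predict)."""

    name: str
    kind: str  # "continuous" | "categorical"
    mean: float = 0.0
    sd: float = 1.0
    levels: tuple = ()  # categorical levels; first is the reference


@dataclass
class _DesignInfo:
    X: np.ndarray  # (S, q) psi design
    W: np.ndarray  # (S, K, r) p design
    psi_colnames: list[str]
    p_colnames: list[str]
    psi_coding: list[_ColumnCoding]
    p_coding: list[_ColumnCoding]


def _code_site_column(
    values: pd.Series, name: str, coding: _ColumnCoding | None
) -> tuple[np.ndarray, list[str], _ColumnCoding]:
    """Return design columns (S, c) for one site covariate."""
    if coding is None:
        if pd.api.types.is_numeric_dtype(values):
            mean = float(values.mean())
            sd = float(values.std(ddof=0))
            coding = _ColumnCoding(name, "continuous", mean, sd if sd > 0 else 1.0)
        else:
            levels = tuple(sorted(values.dropna().unique().tolist()))
            coding = _ColumnCoding(name, "categorical", levels=levels)
    if coding.kind == "continuous":
        arr = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"non-finite values in covariate {name!r}")
        col = (arr - coding.mean) / coding.sd
        return col[:, None], [name], coding
    unseen = set(values.dropna().unique()) - set(coding.levels)
    if unseen:
        raise ValidationError(f"unseen level(s) {sorted(unseen)} in covariate {name!r}")
    cols = np.column_stack(
        [(values == lev).to_numpy(dtype=float) for lev in coding.levels[1:]]
    ) if len(coding.levels) > 1 else np.zeros((len(values), 0))
    names = [f"{name}[{lev}]" for lev in coding.levels[1:]]
    return cols, names, coding


def _code_survey_column(
    arr: np.ndarray, name: str, mask: np.ndarray, coding: _ColumnCoding | None
) -> tuple[np.ndarray, list[str], _ColumnCoding]:
    """Return design columns (S, K, c) for one survey covariate."""
    if arr.dtype.kind == "f":
        if coding is None:
            obs = arr[mask & ~np.isnan(arr)]
            mean = float(obs.mean())
            sd = float(obs.std())
            coding = _ColumnCoding(name, "continuous", mean, sd if sd > 0 else 1.0)
        col = (np.where(np.isnan(arr), coding.mean, arr) - coding.mean) / coding.sd
        return col[:, :, None], [name], coding
    if coding is None:
        flat = pd.Series(arr.ravel()).dropna()
        levels = tuple(sorted(flat.unique().tolist()))
        coding = _ColumnCoding(name, "categorical", levels=levels)
    unseen = set(pd.Series(arr.ravel()).dropna().unique()) - set(coding.levels)
    if unseen:
        raise ValidationError(f"unseen level(s) {sorted(unseen)} in covariate {name!r}")
    cols = np.stack(
        [(arr == lev).astype(float) for lev in coding.levels[1:]], axis=2
    ) if len(coding.levels) > 1 else np.zeros(arr.shape + (0,))
    names = [f"{name}[{lev}]" for lev in coding.levels[1:]]
    return cols, names, coding


def _build_design(
    history: DetectionHistory,
    site_covs: SiteCovariateTable | None,
    survey_covs: SurveyCovariateTable | None,
    spec: OccupancyModelSpec,
    reuse: _DesignInfo | None = None,
) -> _DesignInfo:
    S, K = history.n_sites, history.n_occasions
    mask = history.observed_mask
    site_df = site_covs.aligned_to(history) if site_covs is not None else None

    def site_series(name: str) -> pd.Series:
        if site_df is None or name not in site_df.columns:
            raise ValidationError(f"covariate {name!r} not found in site covariate table")
        return site_df[name]

    # --- psi design ---
    X_cols = [np.ones((S, 1))]
    psi_names = ["(intercept)"]
    psi_coding: list[_ColumnCoding] = []
    reuse_psi = {c.name: c for c in reuse.psi_coding} if reuse else {}
    for name in spec.psi_covariates:
        cols, names, coding = _code_site_column(site_series(name), name, reuse_psi.get(name))
        X_cols.append(cols)
        psi_names.extend(names)
        psi_coding.append(coding)
    X = np.hstack(X_cols)

    # --- p design ---
    W_cols = [np.ones((S, K, 1))]
    p_names = ["(intercept)"]
    p_coding: list[_ColumnCoding] = []
    reuse_p = {c.name: c for c in reuse.p_coding} if reuse else {}
    for name in spec.p_covariates:
        if survey_covs is not None and name in survey_covs.columns:
            cols, names, coding = _code_survey_column(
                survey_covs.covariates[name], name, mask, reuse_p.get(name)
            )
        else:  # site-level covariate entering the detection model
            cols2d, names, coding = _code_site_column(site_series(name), name, reuse_p.get(name))
            cols = np.repeat(cols2d[:, None, :], K, axis=1)
        W_cols.append(cols)
        p_names.extend(names)
        p_coding.append(coding)
    W = np.concatenate(W_cols, axis=2)
    return _DesignInfo(X, W, psi_names, p_names, psi_coding, p_coding)


# ----------------------------------------------------------------------
# likelihood and gradient
# ----------------------------------------------------------------------

def _loglik_grad(
    theta: np.ndarray, X: np.ndarray, W: np.ndarray, Y: np.ndarray, M: np.ndarray
) -> tuple[float, np.ndarray]:
    """Log-likelihood and gradient at packed parameters (beta_psi, beta_p)."""
    q = X.shape[1]
    bpsi, bp = theta[:q], theta[q:]
    eta_psi = X @ bpsi  # (S,)
    eta_p = W @ bp  # (S, K)

    log_psi = log_expit(eta_psi)
    log_1mpsi = log_expit(-eta_psi)
    log_p = log_expit(eta_p)
    log_1mp = log_expit(-eta_p)
    p = expit(eta_p)
    psi = expit(eta_psi)

    Ym = np.where(M, Y, 0.0)
    detected = Ym.any(axis=1)
    # log prod_t p^y (1-p)^(1-y) over surveyed occasions
    logf = np.where(M, Ym * log_p + (1.0 - Ym) * log_1mp, 0.0).sum(axis=1)
    ll_det = log_psi + logf
    ll_nodet = np.logaddexp(log_psi + logf, log_1mpsi)
    ll = np.where(detected, ll_det, ll_nodet)

    # gradient weights
    # occupied-and-missed posterior weight for non-detected sites
    w_occ = np.exp(log_psi + logf - ll_nodet)  # psi*q / L
    d_psi = np.where(detected, 1.0 - psi, w_occ - psi)  # d logL / d eta_psi
    c = np.where(detected[:, None], Ym - p, -w_occ[:, None] * p)  # d logL / d eta_p
    c = np.where(M, c, 0.0)

    g_psi = X.T @ d_psi
    g_p = np.einsum("sk,skr->r", c, W)
    return float(ll.sum()), np.concatenate([g_psi, g_p])


def occupancy_loglik(
    beta_psi: np.ndarray,
    beta_p: np.ndarray,
    history: DetectionHistory,
    site_covs: SiteCovariateTable | None = None,
    survey_covs: SurveyCovariateTable | None = None,
    spec: OccupancyModelSpec | None = None,
) -> float:
    """Model log-likelihood at the given logit-scale coefficient vectors.

    ``beta_psi``/``beta_p`` are (intercept + covariate) vectors matching
    ``spec``; with the default constant model each is just the intercept.
    """
    spec = spec or OccupancyModelSpec()
    info = _build_design(history, site_covs, survey_covs, spec)
    theta = np.concatenate([np.atleast_1d(beta_psi), np.atleast_1d(beta_p)])
    if theta.size != info.X.shape[1] + info.W.shape[2]:
        raise ValidationError(
            f"expected {info.X.shape[1]} psi and {info.W.shape[2]} p coefficients"
        )
    if not np.all(np.isfinite(theta)):
        raise ValidationError("non-finite coefficients")
    Y = np.nan_to_num(history.matrix)
    ll, _ = _loglik_grad(theta, info.X, info.W, Y, history.observed_mask)
    return ll


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

@dataclass
class OccupancyFit:
    """Maximum-likelihood fit of a single-season occupancy model."""

    spec: OccupancyModelSpec
    beta_psi: np.ndarray
    beta_p: np.ndarray
    psi_colnames: list[str]
    p_colnames: list[str]
    loglik: float
    aic: float
    se: np.ndarray  # packed (beta_psi, beta_p) order
    vcov: np.ndarray | None
    converged: bool
    boundary: bool
    n_sites: int
    n_params: int
    design: _DesignInfo = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def psi_hat(self) -> float:
        """Occupancy at mean covariates (the estimate itself for a constant model)."""
        return float(expit(self.beta_psi[0]))

    @property
    def p_hat(self) -> float:
        """Detection at mean covariates / reference levels."""
        return float(expit(self.beta_p[0]))

    def coefficients(self) -> pd.DataFrame:
        names = [f"psi:{n}" for n in self.psi_colnames] + [f"p:{n}" for n in self.p_colnames]
        est = np.concatenate([self.beta_psi, self.beta_p])
        return pd.DataFrame({"term": names, "estimate": est, "se": self.se})


def _drop_unvisited(history: DetectionHistory) -> DetectionHistory:
    visits = history.n_visits()
    if np.all(visits > 0):
        return history
    keep = visits > 0
    warnings.warn(
        f"excluding {int((~keep).sum())} site(s) with no observed occasion", stacklevel=3
    )
    return DetectionHistory(
        [s for s, k in zip(history.site_ids, keep) if k],
        history.matrix[keep],
        list(history.occasion_labels),
    )


def fit_occupancy(
    history: DetectionHistory,
    site_covs: SiteCovariateTable | None = None,
    survey_covs: SurveyCovariateTable | None = None,
    spec: OccupancyModelSpec | None = None,
    n_starts: int = 5,
    seed: int | None = None,
) -> OccupancyFit:
    """Fit the occupancy model by multi-start quasi-Newton maximisation.

    The first start comes from naive moment estimates (raw proportion of
    sites with a detection; detection rate at those sites), the rest are
    random perturbations.  Standard errors come from the inverse observed
    information at the optimum; ``converged`` is False when the best
    start fails the optimizer's tolerance or the information matrix is
    not positive definite (e.g. boundary fits with no detections).
    """
    spec = spec or OccupancyModelSpec()
    history = _drop_unvisited(history)
    if history.n_sites < 2:
        raise ValidationError("at least 2 sites required")
    info = _build_design(history, site_covs, survey_covs, spec)
    Y = np.nan_to_num(history.matrix)
    M = history.observed_mask
    q, r = info.X.shape[1], info.W.shape[2]

    d = history.n_detections()
    naive = np.clip(np.mean(d > 0), 0.02, 0.98)
    if d.sum() > 0:
        p0 = np.clip(d[d > 0].sum() / M[d > 0].sum(), 0.02, 0.98)
    else:
        p0 = 0.1
    start0 = np.zeros(q + r)
    start0[0] = logit(naive)
    start0[q] = logit(p0)

    rng = np.random.default_rng(seed)
    starts = [start0] + [
        start0 + rng.normal(scale=1.0, size=q + r) for _ in range(max(0, n_starts - 1))
    ]

    def negloglik(theta: np.ndarray) -> tuple[float, np.ndarray]:
        ll, g = _loglik_grad(theta, info.X, info.W, Y, M)
        return -ll, -g

    best = None
    for s in starts:
        res = optimize.minimize(
            negloglik,
            s,
            jac=True,
            method="L-BFGS-B",
            bounds=[(-_ETA_BOUND, _ETA_BOUND)] * (q + r),
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    theta = best.x
    ll = -best.fun

    boundary = bool(np.any(np.abs(theta) > _BOUNDARY_ETA) or d.sum() == 0)

    # observed information: central differences of the analytic gradient
    n_par = q + r
    H = np.empty((n_par, n_par))
    for j in range(n_par):
        h = 1e-5 * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = _loglik_grad(tp, info.X, info.W, Y, M)
        _, gm = _loglik_grad(tm, info.X, info.W, Y, M)
        H[j] = -(gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)

    se = np.full(n_par, np.nan)
    vcov = None
    pos_def = False
    try:
        evals = np.linalg.eigvalsh(H)
        if np.all(evals > 1e-10):
            vcov = np.linalg.inv(H)
            se = np.sqrt(np.diag(vcov))
            pos_def = True
    except np.linalg.LinAlgError:
        pass

    converged = bool(best.success) and pos_def and not boundary
    return OccupancyFit(
        spec=spec,
        beta_psi=theta[:q],
        beta_p=theta[q:],
        psi_colnames=info.psi_colnames,
        p_colnames=info.p_colnames,
        loglik=ll,
        aic=2 * n_par - 2 * ll,
        se=se,
        vcov=vcov,
        converged=converged,
        boundary=boundary,
        n_sites=history.n_sites,
        n_params=n_par,
        design=info,
    )


# ----------------------------------------------------------------------
# fast constant-model kernel (used heavily by the simulation modules)
# ----------------------------------------------------------------------

def _constant_negll_grad(theta, d_g, k_g, n_g):
    a, b = theta
    la, lma = log_expit(a), log_expit(-a)
    lb, lmb = log_expit(b), log_expit(-b)
    psi, p = expit(a), expit(b)

    det = d_g > 0
    ll_det = la + d_g * lb + (k_g - d_g) * lmb
    ll_no = np.logaddexp(la + k_g * lmb, lma)
    ll = np.where(det, ll_det, ll_no)

    w_occ = np.exp(la + k_g * lmb - ll_no)  # P(occupied | never detected)
    ga = np.where(det, 1.0 - psi, w_occ - psi)
    gb = np.where(det, d_g - k_g * p, -w_occ * k_g * p)
    return -float(n_g @ ll), -np.array([n_g @ ga, n_g @ gb])


def fit_constant(
    n_detections: np.ndarray, n_visits: np.ndarray
) -> tuple[float, float, float, bool]:
    """Constant-model MLE from per-site detection and visit counts.

    Returns ``(psi_hat, p_hat, loglik, boundary)``.  The two degenerate
    datasets are short-circuited: zero detections anywhere pins the MLE
    to the psi_hat = 0 boundary (p is then inestimable and reported as
    0), and detections on every visit at every site pin it to
    psi_hat = p_hat = 1.
    """
    d = np.asarray(n_detections, dtype=float)
    k = np.asarray(n_visits, dtype=float)
    if np.any(k <= 0):
        raise ValidationError("every site needs at least one visit")
    if d.sum() == 0:
        ll = 0.0  # L_i = psi*(1-p)^k + (1-psi) -> 1 at psi=0
        return 0.0, 0.0, ll, True
    if np.all(d == k):
        return 1.0, 1.0, 0.0, True

    # group identical (d, k) pairs; the likelihood only sees these counts
    pairs, n_g = np.unique(np.column_stack([d, k]), axis=0, return_counts=True)
    d_g, k_g = pairs[:, 0], pairs[:, 1]

    naive = np.clip(np.mean(d > 0), 0.02, 0.98)
    p0 = np.clip(d[d > 0].sum() / k[d > 0].sum(), 0.02, 0.98)
    pstar = 1.0 - (1.0 - p0) ** k.mean()
    psi0 = np.clip(naive / max(pstar, 0.05), 0.02, 0.98)
    start = np.array([logit(psi0), logit(p0)])

    res = optimize.minimize(
        _constant_negll_grad,
        start,
        args=(d_g, k_g, n_g),
        jac=True,
        method="L-BFGS-B",
        bounds=[(-_ETA_BOUND, _ETA_BOUND)] * 2,
        options={"maxiter": 200, "ftol": 1e-13, "gtol": 1e-9},
    )
    a, b = res.x
    boundary = bool(max(abs(a), abs(b)) > _BOUNDARY_ETA)
    return float(expit(a)), float(expit(b)), -float(res.fun), boundary


# ----------------------------------------------------------------------
# prediction with delta-method intervals
# ----------------------------------------------------------------------

def predict_parameters(
    fit: OccupancyFit,
    history: DetectionHistory,
    site_covs: SiteCovariateTable | None = None,
    survey_covs: SurveyCovariateTable | None = None,
    level: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site psi and per-site-occasion p with delta-method CIs.

    Intervals are computed on the logit scale (eta_hat +/- z * se(eta))
    and back-transformed, so they always lie inside (0, 1).  Covariates
    are re-coded with the scalers and level sets frozen at fit time.

    Returns ``(psi_table, p_table)``: the first indexed by site with
    columns ``psi, lo, hi``; the second in long format with columns
    ``site, occ, p, lo, hi`` for surveyed cells.
    """
    from scipy.stats import norm

    if fit.vcov is None:
        raise ValidationError("fit has no covariance matrix; cannot form intervals")
    info = _build_design(history, site_covs, survey_covs, fit.spec, reuse=fit.design)
    z = norm.ppf(0.5 + level / 2)
    q = len(fit.beta_psi)
    V_psi = fit.vcov[:q, :q]
    V_p = fit.vcov[q:, q:]

    eta_psi = info.X @ fit.beta_psi
    se_psi = np.sqrt(np.einsum("sq,qr,sr->s", info.X, V_psi, info.X))
    psi_tab = pd.DataFrame(
        {
            "psi": expit(eta_psi),
            "lo": expit(eta_psi - z * se_psi),
            "hi": expit(eta_psi + z * se_psi),
        },
        index=pd.Index(history.site_ids, name="site"),
    )

    eta_p = info.W @ fit.beta_p
    se_p = np.sqrt(np.einsum("skq,qr,skr->sk", info.W, V_p, info.W))
    rows = []
    mask = history.observed_mask
    for i, site in enumerate(history.site_ids):
        for j, occ in enumerate(history.occasion_labels):
            if mask[i, j]:
                rows.append(
                    {
                        "site": site,
                        "occ": occ,
                        "p": expit(eta_p[i, j]),
                        "lo": expit(eta_p[i, j] - z * se_p[i, j]),
                        "hi": expit(eta_p[i, j] + z * se_p[i, j]),
                    }
                )
    return psi_tab, pd.DataFrame(rows)


# ----------------------------------------------------------------------
# AIC machinery and stepwise selection
# ----------------------------------------------------------------------

def build_selection_table(fits: list[OccupancyFit]) -> pd.DataFrame:
    """AIC ranking with Akaike weights, sorted best first.

    Weights are exp(-delta/2) normalised over the set, interpretable as
    the probability of each model being the best in the set.  Ties are
    broken by fewer parameters, then model name.
    """
    if not fits:
        raise ValidationError("no fits to rank")
    rows = [
        {
            "model": f.spec.name,
            "k": f.n_params,
            "loglik": f.loglik,
            "aic": f.aic,
            "converged": f.converged,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows)
    df["_order"] = range(len(df))
    df = df.sort_values(["aic", "k", "model"], kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    w = np.exp(-df["delta_aic"] / 2)
    df["weight"] = w / w.sum()
    return df.drop(columns="_order")


def _correlation_screen(
    candidates: list[str], columns: dict[str, np.ndarray], threshold: float
) -> list[str]:
    """Drop the later-listed member of any pair with |Pearson r| > threshold."""
    kept: list[str] = []
    for name in candidates:
        col = columns.get(name)
        drop = False
        if col is not None:
            for prev in kept:
                pcol = columns.get(prev)
                if pcol is None:
                    continue
                ok = np.isfinite(col) & np.isfinite(pcol)
                if ok.sum() > 2 and col[ok].std() > 0 and pcol[ok].std() > 0:
                    r = np.corrcoef(col[ok], pcol[ok])[0, 1]
                    if abs(r) > threshold:
                        logger.warning(
                            "dropping covariate %r: |r|=%.2f with %r exceeds %.2f",
                            name, abs(r), prev, threshold,
                        )
                        drop = True
                        break
        if not drop:
            kept.append(name)
    return kept


def stepwise_select(
    history: DetectionHistory,
    site_covs: SiteCovariateTable | None,
    survey_covs: SurveyCovariateTable | None,
    p_candidates: list[str],
    psi_candidates: list[str],
    n_starts: int = 3,
    seed: int | None = None,
    delta_retain: float = 2.0,
    corr_threshold: float = 0.7,
) -> tuple[pd.DataFrame, OccupancyFit]:
    """Two-stage stepwise model selection.

    Stage 1 keeps occupancy constant and ranks single-covariate
    detection models against the constant model; detection structures
    within ``delta_retain`` AIC units of the stage-1 best are retained.
    Stage 2 crosses each retained detection structure with each single
    occupancy covariate (and constant occupancy) and returns the full
    stage-2 ranking plus the AIC-best fit.  Candidates failing the
    pairwise correlation screen or failing to converge are excluded
    from the ranking, with a log record.
    """
    # correlation screen on numeric candidate columns
    cols: dict[str, np.ndarray] = {}
    if site_covs is not None:
        aligned = site_covs.aligned_to(history)
        for c in aligned.columns:
            if pd.api.types.is_numeric_dtype(aligned[c]):
                cols[c] = aligned[c].to_numpy(dtype=float)
    if survey_covs is not None:
        for c, arr in survey_covs.covariates.items():
            if arr.dtype.kind == "f":
                cols[c] = np.nanmean(arr, axis=1)  # site-level summary for screening
    p_candidates = _correlation_screen(list(p_candidates), cols, corr_threshold)
    psi_candidates = _correlation_screen(list(psi_candidates), cols, corr_threshold)

    def try_fit(spec: OccupancyModelSpec) -> OccupancyFit | None:
        fit = fit_occupancy(history, site_covs, survey_covs, spec, n_starts, seed)
        if not fit.converged:
            logger.warning("model %s did not converge; excluded from ranking", spec.name)
            return None
        return fit

    # stage 1: detection covariates only
    stage1_specs = [OccupancyModelSpec((), ())] + [
        OccupancyModelSpec((), (c,)) for c in p_candidates
    ]
    stage1 = {s.p_covariates: try_fit(s) for s in stage1_specs}
    stage1 = {k: f for k, f in stage1.items() if f is not None}
    if not stage1:
        raise ValidationError("no stage-1 model converged")
    aics = {k: f.aic for k, f in stage1.items()}
    best_aic = min(aics.values())
    retained_p = [k for k, a in aics.items() if a - best_aic < delta_retain]

    # stage 2: cross retained detection structures with occupancy covariates
    fits: list[OccupancyFit] = []
    for p_struct in retained_p:
        fits.append(stage1[p_struct])  # constant-psi model, already fitted
        for c in psi_candidates:
            fit = try_fit(OccupancyModelSpec((c,), p_struct))
            if fit is not None:
                fits.append(fit)
    table = build_selection_table(fits)
    best_name = table["model"].iloc[0]
    best_fit = next(f for f in fits if f.spec.name == best_name)
    return table, best_fit
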
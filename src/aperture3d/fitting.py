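"""Maximum-likelihood fitting of the Bayesian vector-normal models.

Observer data are adjusted motion directions — longitude/latitude pairs
per trial for each stimulus condition.  The response model is

    observed (alpha, beta) = predicted(alpha, beta; sigma_m, sigma_d)
                             + iid Gaussian angular noise,

with a single unknown response variance shared by both angles.  The
nuisance variance is concentrated out analytically, so maximizing the
likelihood reduces to minimizing the residual sum of squares (RSS) of the
angle residuals over the noise ratios, and the likelihood-ratio statistic
between two fits is ``N ln(RSS1/RSS2)`` with N the number of scalar
residuals.

Model comparison uses the conventional likelihood-ratio test (chi-square
with 1 df for the one extra BVN2 parameter) and the Schwarz/BIC
approximation of the Bayes factor for a one-parameter difference,
``BF = exp((chi2 - ln n) / 2)`` with n the number of fitted conditions.
Parameter uncertainty is assessed by resampling trials with replacement
within condition and refitting (bootstrap), and motion-versus-depth noise
differences across observers by a one-sample t test.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .estimators import DesignMatrices, NoiseParams, design_matrices
from .geometry import (
    StimulusCondition,
    ViewingGeometry,
    from_spherical,
    to_spherical,
)

TRIAL_COLUMNS = [
    "observer",
    "experiment",
    "tilt_deg",
    "orientation_disparity_deg",
    "iovd_sign",
    "rep",
    "longitude_deg",
    "latitude_deg",
]

PROBE_COLUMNS = TRIAL_COLUMNS[:6] + ["probe_x_cm", "probe_y_cm", "probe_disparity_cm"]

RATIO_BOUNDS = (0.001, 0.5)  # sigma_m/sigma0 search range: 0.1% .. 50%
# sigma_d may run to 1000% so the depth pathway can switch off entirely,
# which makes the single-source model an (effective) special case of the
# two-source model and keeps the likelihood-ratio statistic non-negative
SIGMA_D_BOUNDS = (0.001, 10.0)


class SchemaError(ValueError):
    """A trial table does not conform to the expected schema."""


class FitConvergenceError(RuntimeError):
    """No optimizer start converged to a valid optimum."""


def validate_trial_table(df: pd.DataFrame, columns: Sequence[str] = TRIAL_COLUMNS) -> None:
    """Raise :class:`SchemaError` naming missing columns or bad rows."""
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table is missing columns: {missing}")
    for col in columns:
        if col in ("observer",):
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise SchemaError(f"non-numeric value in column {col!r} at row {bad[0]}")
    if "longitude_deg" in columns:
        lon = pd.to_numeric(df["longitude_deg"])
        lat = pd.to_numeric(df["latitude_deg"])
        out = df.index[(lon.abs() > 180) | (lat.abs() > 90)]
        if len(out):
            raise SchemaError(f"angles out of range at row {out[0]}")


def conditions_from_table(
    df: pd.DataFrame,
) -> tuple[list[StimulusCondition], np.ndarray]:
    """Unique stimulus conditions and the per-trial condition index."""
    keys = df[["experiment", "tilt_deg", "orientation_disparity_deg", "iovd_sign"]]
    uniq = keys.drop_duplicates().sort_values(list(keys.columns)).reset_index(drop=True)
    conds = [
        StimulusCondition(
            tilt_deg=float(r.tilt_deg),
            orientation_disparity_deg=float(r.orientation_disparity_deg),
            iovd_sign=int(r.iovd_sign),
            experiment=int(r.experiment),
        )
        for r in uniq.itertuples()
    ]
    lookup = {tuple(row): i for i, row in enumerate(uniq.itertuples(index=False))}
    idx = np.array([lookup[tuple(row)] for row in keys.itertuples(index=False)])
    return conds, idx


def mirror_collapse(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse mirror-symmetric oblique conditions onto canonical ones.

    Trials with tilt > 90 deg are mapped onto their x-reflection
    (tilt -> 180 - tilt, IOVD sign flipped).  The reflection swaps the
    eyes, so it preserves orientation disparity; longitude and latitude
    are invariant because the longitude convention folds the left/right
    sign of the trajectory.
    """
    out = df.copy()
    flip = out["tilt_deg"] > 90
    out.loc[flip, "iovd_sign"] = -out.loc[flip, "iovd_sign"]
    out.loc[flip, "tilt_deg"] = 180.0 - out.loc[flip, "tilt_deg"]
    return out


def _fingerprint(y: np.ndarray, idx: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.round(y, 9).tobytes())
    h.update(idx.tobytes())
    return h.hexdigest()[:16]


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one BVN model to one observer's trials."""

    model_tag: Literal["BVN1", "BVN2"]
    sigma_m_pct: float
    sigma_d_pct: float
    log_likelihood: float
    rss: float
    n_trials: int
    n_conditions: int
    n_residuals: int
    converged: bool
    n_starts: int
    data_fingerprint: str = ""

    @property
    def noise(self) -> NoiseParams:
        if self.model_tag == "BVN1":
            return NoiseParams.bvn1(self.sigma_m_pct / 100.0)
        return NoiseParams.bvn2(self.sigma_m_pct / 100.0, self.sigma_d_pct / 100.0)

    def to_dict(self) -> dict:
        return {
            "model": self.model_tag,
            "sigma_m_pct": self.sigma_m_pct,
            "sigma_d_pct": self.sigma_d_pct,
            "log_likelihood": self.log_likelihood,
            "rss": self.rss,
            "n_trials": self.n_trials,
            "n_conditions": self.n_conditions,
        }


@dataclass(frozen=True)
class ModelComparison:
    """Likelihood-ratio test and approximate Bayes factor, BVN2 over BVN1."""

    chi2: float
    df: int
    p_value: float
    bayes_factor: float
    n_conditions: int

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p_value,
            "BF": self.bayes_factor,
            "n_conditions": self.n_conditions,
        }


def _loglik_from_rss(rss: float, n_resid: int) -> float:
    s2 = max(rss, 1e-300) / n_resid
    return -0.5 * n_resid * (np.log(2 * np.pi * s2) + 1.0)


def _prepare(trials: pd.DataFrame, geometry: ViewingGeometry):
    validate_trial_table(trials)
    conds, idx = conditions_from_table(trials)
    if len(conds) < 2:
        raise ValueError("need at least 2 distinct conditions to fit")
    design = design_matrices(conds, geometry)
    y = trials[["longitude_deg", "latitude_deg"]].to_numpy(dtype=float)
    return design, y, idx


def _rss(design: DesignMatrices, y: np.ndarray, idx: np.ndarray, noise: NoiseParams) -> float:
    pred = design.predict_angles(noise)
    resid = y - pred[idx]
    return float(np.sum(resid * resid))


def fit_model(
    trials: pd.DataFrame,
    model_tag: Literal["BVN1", "BVN2"],
    geometry: ViewingGeometry,
    n_starts: int = 5,
    _prepared=None,
    _start: Optional[tuple[float, float]] = None,
) -> FitResult:
    """Fit BVN noise ratios to a trial table by (concentrated) ML.

    BVN1 optimizes a single noise ratio; BVN2 optimizes (sigma_m,
    sigma_d).  The search runs over log ratios (bounded Nelder-Mead with
    multiple log-spaced starts) and, for BVN2, also profiles the
    depth-pathway-off boundary (sigma_d = infinity), so the single-source
    model is an exact special case and the likelihood ratio is never
    negative.  Ties are broken by lowest RSS, then smallest sigma_m.
    """
    design, y, idx = _prepared if _prepared is not None else _prepare(trials, geometry)
    n_resid = 2 * y.shape[0]
    lo, hi = np.log(RATIO_BOUNDS[0]), np.log(RATIO_BOUNDS[1])
    lod, hid = np.log(SIGMA_D_BOUNDS[0]), np.log(SIGMA_D_BOUNDS[1])

    def scalar_fit(make_noise):
        def obj(ls):
            return _rss(design, y, idx, make_noise(float(np.exp(ls))))

        grid = np.linspace(lo, hi, 41)
        vals = [obj(g) for g in grid]
        g0 = grid[int(np.argmin(vals))]
        res = optimize.minimize_scalar(
            obj,
            bounds=(max(lo, g0 - 0.5), min(hi, g0 + 0.5)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if not res.success:
            raise FitConvergenceError("scalar noise optimization failed")
        return float(np.exp(res.x)), float(res.fun)

    if model_tag == "BVN1":
        sigma, rss = scalar_fit(NoiseParams.bvn1)
        return FitResult(
            model_tag="BVN1",
            sigma_m_pct=100 * sigma,
            sigma_d_pct=100 * sigma,
            log_likelihood=_loglik_from_rss(rss, n_resid),
            rss=rss,
            n_trials=y.shape[0],
            n_conditions=len(design),
            n_residuals=n_resid,
            converged=True,
            n_starts=1,
            data_fingerprint=_fingerprint(y, idx),
        )

    def obj2(p):
        sm, sd = np.exp(p)
        return _rss(design, y, idx, NoiseParams.bvn2(float(sm), float(sd)))

    if _start is not None:
        starts = [np.log(np.asarray(_start, dtype=float))]
    else:
        ratios = np.exp(np.linspace(lo + 0.5, hi - 0.5, n_starts))
        starts = [np.log([r, r]) for r in ratios]
        starts.append(np.array([np.log(0.05), hid - 0.5]))  # depth pathway off
    best = None
    n_ok = 0
    for s0 in starts:
        res = optimize.minimize(
            obj2,
            s0,
            method="Nelder-Mead",
            bounds=[(lo, hi), (lod, hid)],
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 8000},
        )
        if not res.success:
            continue
        n_ok += 1
        cand = (res.fun, float(np.exp(res.x[0])), float(np.exp(res.x[1])))
        if best is None or cand < best:
            best = cand
    if best is None:
        raise FitConvergenceError(
            f"no BVN2 start converged ({len(starts)} starts, bounds {RATIO_BOUNDS})"
        )
    rss, sm, sd = best
    # boundary of the parameter space: depth pathway switched off entirely
    # (sigma_d -> infinity), under which BVN2 coincides with BVN1 and the
    # single-source model is an exact special case of the two-source model
    if _start is None:
        sm_off, rss_off = scalar_fit(lambda s: NoiseParams.bvn2(s, np.inf))
        if rss_off < rss - 1e-12:
            rss, sm, sd = rss_off, sm_off, float("inf")
    return FitResult(
        model_tag="BVN2",
        sigma_m_pct=100 * sm,
        sigma_d_pct=100 * sd,
        log_likelihood=_loglik_from_rss(rss, n_resid),
        rss=rss,
        n_trials=y.shape[0],
        n_conditions=len(design),
        n_residuals=n_resid,
        converged=True,
        n_starts=n_ok,
        data_fingerprint=_fingerprint(y, idx),
    )


def lr_test(fit1: FitResult, fit2: FitResult) -> ModelComparison:
    """Likelihood-ratio test of BVN2 (fit2) against BVN1 (fit1), df = 1."""
    if fit1.model_tag != "BVN1" or fit2.model_tag != "BVN2":
        raise ValueError("lr_test expects (BVN1 fit, BVN2 fit)")
    if fit1.data_fingerprint != fit2.data_fingerprint:
        raise ValueError("fits were computed on different data")
    chi2 = 2.0 * (fit2.log_likelihood - fit1.log_likelihood)
    p = float(stats.chi2.sf(max(chi2, 0.0), df=1))
    return ModelComparison(
        chi2=chi2,
        df=1,
        p_value=p,
        bayes_factor=bayes_factor(max(chi2, 0.0), fit1.n_conditions),
        n_conditions=fit1.n_conditions,
    )


def bayes_factor(chi2: float, n_conditions: int) -> float:
    """BIC approximation of the Bayes factor for one extra parameter.

    ``BF = exp((chi2 - ln n) / 2)`` with n the number of fitted
    conditions; BF > 1 favours the richer model (BVN2).
    """
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    if n_conditions < 2:
        raise ValueError("need at least 2 conditions")
    exponent = (chi2 - np.log(n_conditions)) / 2.0
    if exponent > 700:  # beyond float range: overwhelming evidence
        return float("inf")
    return float(np.exp(exponent))


@dataclass
class BootstrapResult:
    """Within-condition bootstrap distribution of BVN2 noise estimates."""

    replicates: pd.DataFrame  # columns: replicate, sigma_m_pct, sigma_d_pct
    n_requested: int
    n_dropped: int
    point: FitResult

    @property
    def summary(self) -> dict:
        out = {}
        for col in ("sigma_m_pct", "sigma_d_pct"):
            q = self.replicates[col].quantile([0.25, 0.5, 0.75])
            out[col] = {
                "median": float(q.loc[0.5]),
                "q1": float(q.loc[0.25]),
                "q3": float(q.loc[0.75]),
            }
        return out


def bootstrap_fit(
    trials: pd.DataFrame,
    n_boot: int,
    seed: int,
    geometry: ViewingGeometry,
    resample: bool = True,
) -> BootstrapResult:
    """Bootstrap BVN2 estimates by resampling trials within condition.

    Each replicate redraws, for every condition, the same number of
    trials with replacement from that condition's trials, then refits
    BVN2 (warm-started at the point estimate).  Replicates whose fit
    fails are dropped; more than 5% dropped raises.  ``resample=False``
    refits the original table (degenerate single-replicate check).
    """
    design, y, idx = _prepare(trials, geometry)
    point = fit_model(trials, "BVN2", geometry, _prepared=(design, y, idx))
    rng = np.random.default_rng(seed)
    warm = (
        point.sigma_m_pct / 100.0,
        min(point.sigma_d_pct / 100.0, SIGMA_D_BOUNDS[1]),
    )
    per_cond = [np.flatnonzero(idx == k) for k in range(len(design))]
    rows = []
    n_dropped = 0
    for b in range(n_boot):
        if resample:
            take = np.concatenate(
                [rng.choice(members, size=len(members), replace=True) for members in per_cond]
            )
        else:
            take = np.arange(y.shape[0])
        yb, ib = y[take], idx[take]
        try:
            fit = fit_model(
                trials, "BVN2", geometry, _prepared=(design, yb, ib), _start=warm
            )
        except FitConvergenceError:
            try:
                fit = fit_model(trials, "BVN2", geometry, _prepared=(design, yb, ib))
            except FitConvergenceError:
                n_dropped += 1
                continue
        rows.append((b, fit.sigma_m_pct, fit.sigma_d_pct))
    if n_dropped > 0.05 * n_boot:
        raise FitConvergenceError(f"{n_dropped}/{n_boot} bootstrap replicates failed")
    reps = pd.DataFrame(rows, columns=["replicate", "sigma_m_pct", "sigma_d_pct"])
    return BootstrapResult(
        replicates=reps, n_requested=n_boot, n_dropped=n_dropped, point=point
    )


@dataclass(frozen=True)
class NoiseDifferenceResult:
    mean_difference_pct: float
    ci95: tuple[float, float]
    t: float
    df: int
    p_value: float


def noise_difference_test(
    per_observer_estimates: Sequence[tuple[float, float]]
) -> NoiseDifferenceResult:
    """One-sample two-tailed t test on per-observer sigma_m - sigma_d (%)."""
    est = np.asarray(per_observer_estimates, dtype=float)
    if est.shape[0] < 2:
        raise ValueError("need at least 2 observers")
    diffs = est[:, 0] - est[:, 1]
    sd = diffs.std(ddof=1)
    if sd < 1e-12:
        raise ValueError("zero variance across observers: t statistic undefined")
    n = len(diffs)
    mean = float(diffs.mean())
    se = sd / np.sqrt(n)
    t = mean / se
    df = n - 1
    p = float(2 * stats.t.sf(abs(t), df))
    tcrit = float(stats.t.ppf(0.975, df))
    return NoiseDifferenceResult(
        mean_difference_pct=mean,
        ci95=(mean - tcrit * se, mean + tcrit * se),
        t=float(t),
        df=df,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# raw probe-disparity ingestion


def triangulate_probe(
    x_img_cm: float, y_img_cm: float, disparity_cm: float, geometry: ViewingGeometry
) -> np.ndarray:
    """3D position of a probe dot from its cyclopean image and disparity.

    ``disparity_cm`` is the horizontal disparity (left minus right image
    x), positive (crossed) for points nearer than the screen.  The dot is
    triangulated through the two nodal points.
    """
    i, D = geometry.ipd_cm, geometry.distance_cm
    if i + disparity_cm <= 0:
        raise ValueError("disparity implies a point behind the eyes")
    z = -disparity_cm * D / (i + disparity_cm)
    scale = (z + D) / D
    return np.array([x_img_cm * scale, y_img_cm * scale, z])


def probe_from_direction(
    longitude_deg: float,
    latitude_deg: float,
    r_cm: float,
    geometry: ViewingGeometry,
) -> tuple[float, float, float]:
    """Inverse of :func:`triangulate_probe` for a direction at radius r."""
    p = from_spherical(longitude_deg, latitude_deg, r_cm)
    i, D = geometry.ipd_cm, geometry.distance_cm
    disparity = -i * p[2] / (p[2] + D)
    scale = D / (p[2] + D)
    return float(p[0] * scale), float(p[1] * scale), float(disparity)


def scale_probe_disparity(
    raw: pd.DataFrame, factor: float, geometry: ViewingGeometry
) -> pd.DataFrame:
    """Convert raw probe settings to a trial table of direction angles.

    Horizontal probe disparities are multiplied by the empirical
    depth-underestimation factor (0.6 in the study), then each probe dot
    is triangulated through the two nodal points and converted to
    longitude/latitude about the start point.
    """
    if factor <= 0:
        raise ValueError("scaling factor must be positive")
    validate_trial_table(raw, PROBE_COLUMNS)
    rows = []
    for rec in raw.itertuples():
        p = triangulate_probe(
            float(rec.probe_x_cm),
            float(rec.probe_y_cm),
            factor * float(rec.probe_disparity_cm),
            geometry,
        )
        d = to_spherical(p)
        rows.append((d.longitude_deg, d.latitude_deg))
    out = raw[TRIAL_COLUMNS[:6]].copy()
    out["longitude_deg"] = [r[0] for r in rows]
    out["latitude_deg"] = [r[1] for r in rows]
    return out
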
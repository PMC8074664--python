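"""Linear mixed-effects models with nested random effects and AR(1) errors.

The analysis models a 5-min mean heart rate ``y`` as

.. math::

    y = X\\beta + \\sum_k Z_k b_k + \\varepsilon,
    \\qquad b_k \\sim N(0, \\sigma_k^2 I),

with independent random levels ``k`` all nested within participants —
a participant intercept, a participant slope per continuous predictor,
and intercepts for weekday and hour-of-day (and optionally movement
decile) within participants — and residuals following a first-order
autoregressive process across consecutive records within each
participant-day: ``corr(e_i, e_j) = phi^{|i-j|}`` on record order.

Estimation is (restricted) maximum likelihood.  Because every random
level is nested in participants, the marginal covariance is block
diagonal by participant:

.. math::

    \\Sigma_p = \\sigma^2 V_p, \\qquad
    V_p = \\sum_k \\lambda_k Z_{pk} Z_{pk}' + C_p(\\phi),

where ``lambda_k = sigma_k^2 / sigma^2`` and ``C_p`` is the block-AR(1)
correlation.  The likelihood is profiled over ``beta`` (GLS) and
``sigma^2``; the remaining parameters (log variance ratios and
``arctanh phi``) are optimized with a quasi-Newton method.  Each
participant's contribution is computed from the Gram matrix of the
AR(1)-whitened stack ``[y, X, U]`` via the Woodbury identity — the AR(1)
correlation whitens in O(n) because consecutive-record innovations are
``(e_t - phi e_{t-1}) / sqrt(1 - phi^2)`` — so no dense n-by-n covariance
is ever formed.  Gram matrices depend only on ``phi`` and are cached
across optimizer steps that move only the variance ratios.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .config import ACOUSTIC_VARS, SOUNDSCAPES, SOUNDSCAPES_COLLAPSED, ModelSpec

__all__ = [
    "Design",
    "ModelFit",
    "EffectSizeReport",
    "build_design",
    "fit_lme_ar1",
    "fit_model",
    "fit_effect_null",
    "null_spec_for",
    "likelihood_ratio_test",
    "gvif",
    "partial_r2",
    "percent_change",
    "interaction_contrasts",
]


# --------------------------------------------------------------------------
# Design construction
# --------------------------------------------------------------------------

@dataclass
class Design:
    """Response, fixed design and random-effect layout for one model.

    Records are sorted by (participant, timestamp); ``part_slices`` gives
    each participant's contiguous row range, ``day_start`` marks the first
    record of every participant-day (AR(1) blocks reset there).  The
    random-effect matrix ``U`` has one column per (level, group) with a
    uniform layout across participants: participant intercept, one slope
    column per continuous predictor, 7 weekday columns, 24 hour columns
    and optionally 10 movement-decile columns.
    """

    y: np.ndarray
    X: np.ndarray
    x_names: list[str]
    U: np.ndarray
    u_names: list[str]          # "<level>" or "<level>:<group>"
    level_of_col: np.ndarray    # level index per U column
    level_names: list[str]
    part_slices: list[slice]
    part_ids: list
    day_start: np.ndarray       # bool mask over rows
    n_days_per_part: np.ndarray
    scaler: dict                # per-predictor pooled mean/sd used for z-scoring
    records: pd.DataFrame       # the sorted records backing this design
    spec: ModelSpec = None

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _continuous_vars(spec: ModelSpec) -> tuple[str, ...]:
    if spec.fixed in ("acoustic", "interaction"):
        return ACOUSTIC_VARS
    if spec.fixed == "movement":
        return ("movement",)
    return ()


def _slope_vars(spec: ModelSpec) -> tuple[str, ...]:
    if not spec.random_slopes:
        return ()
    explicit = getattr(spec, "slope_vars", None)
    if explicit is not None:
        return tuple(explicit)
    return _continuous_vars(spec)


def null_spec_for(spec: ModelSpec, keep_random_slopes: bool = True) -> ModelSpec:
    """Intercept-only counterpart of ``spec``.

    With ``keep_random_slopes`` the null keeps the identical random
    structure (required by the effect-size computation); without it the
    random slopes are dropped as well, which matches the degrees-of-freedom
    accounting of likelihood-ratio tests against intercept-only models
    (fixed slopes and their random-slope variances both count).
    """
    import copy

    null = copy.deepcopy(spec)
    null.fixed = "intercept"
    if keep_random_slopes:
        null.slope_vars = _slope_vars(spec)
    else:
        null.slope_vars = ()
    return null


def _standardize(col: np.ndarray, name: str, scaler: dict) -> np.ndarray:
    mu, sd = float(np.mean(col)), float(np.std(col, ddof=0))
    if sd == 0:
        raise ValueError(f"predictor {name!r} is constant (sd = 0)")
    scaler[name] = {"mean": mu, "sd": sd}
    return (col - mu) / sd


def collapse_soundscape(classes: pd.Series | np.ndarray) -> np.ndarray:
    """Map the 4-level soundscape onto {Quiet, Speech, Noisy}."""
    mapping = {"Quiet": "Quiet", "Speech": "Speech",
               "SpeechInNoise": "Noisy", "Noise": "Noisy"}
    return np.array([mapping[c] for c in np.asarray(classes, dtype=object)], dtype=object)


def build_design(records: pd.DataFrame, spec: ModelSpec | None = None) -> Design:
    """Encode analysis records into matrices for :func:`fit_lme_ar1`.

    Continuous predictors are centred and scaled by their pooled mean/s.d.
    when ``spec.predictor_scaling == "standardized"``; the soundscape is
    dummy-coded with Quiet as reference; the interaction model collapses
    SpeechInNoise and Noise into "Noisy" before coding.
    """
    spec = spec or ModelSpec()
    spec.validate()
    needed = {"participant_id", "timestamp", "hr", "date", "weekday", "hour"}
    if spec.fixed in ("acoustic", "soundscape", "interaction"):
        needed |= {"spl", "sml", "snr", "soundscape"}
    if spec.fixed == "movement" or spec.movement_decile_level:
        needed |= {"movement"}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"records are missing fields: {sorted(missing)}")

    rec = records.copy()
    rec["__ts"] = pd.to_datetime(rec["timestamp"])
    if spec.fixed == "movement" or spec.movement_decile_level:
        rec = rec.loc[np.isfinite(rec["movement"].to_numpy(float))]
    rec = rec.sort_values(["participant_id", "__ts"], kind="mergesort").reset_index(drop=True)
    n = len(rec)
    if n == 0:
        raise ValueError("no records to fit")

    y = rec["hr"].to_numpy(float)
    if spec.response == "log_hr":
        if np.any(y <= 0):
            raise ValueError("hr must be positive for a log-scale response")
        y = np.log(y)

    scaler: dict = {}

    def cont(name: str) -> np.ndarray:
        col = rec[name].to_numpy(float)
        if spec.predictor_scaling == "standardized":
            return _standardize(col, name, scaler)
        scaler[name] = {"mean": 0.0, "sd": 1.0}
        return col

    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    cont_cols: dict[str, np.ndarray] = {}

    if spec.fixed in ("acoustic", "interaction"):
        for v in ACOUSTIC_VARS:
            cont_cols[v] = cont(v)
            cols.append(cont_cols[v])
            names.append(v)
    if spec.fixed == "movement":
        cont_cols["movement"] = cont("movement")
        cols.append(cont_cols["movement"])
        names.append("movement")
    if spec.fixed == "soundscape":
        cls = rec["soundscape"].to_numpy(object)
        for level in SOUNDSCAPES[1:]:
            cols.append((cls == level).astype(float))
            names.append(f"soundscape[{level}]")
    if spec.fixed == "interaction":
        cls = collapse_soundscape(rec["soundscape"])
        rec["soundscape_collapsed"] = cls
        for level in SOUNDSCAPES_COLLAPSED[1:]:
            dummy = (cls == level).astype(float)
            cols.append(dummy)
            names.append(f"soundscape[{level}]")
        for v in ACOUSTIC_VARS:
            for level in SOUNDSCAPES_COLLAPSED[1:]:
                cols.append(cont_cols[v] * (cls == level))
                names.append(f"{v}:{level}")
    X = np.column_stack(cols)

    # Slope covariates may be needed even for an intercept-only fixed part
    # (the effect-size null model keeps the full random structure).
    for v in _slope_vars(spec):
        if v not in cont_cols:
            cont_cols[v] = cont(v)

    # ---- random-effect layout ------------------------------------------
    pids = rec["participant_id"].to_numpy(object)
    uniq_pids, part_index = np.unique(pids, return_inverse=True)
    order_check = np.diff(part_index)
    assert np.all(order_check >= 0)
    part_slices = []
    for k in range(len(uniq_pids)):
        rows = np.flatnonzero(part_index == k)
        part_slices.append(slice(rows[0], rows[-1] + 1))

    day_key = rec["participant_id"].astype(str) + "|" + rec["date"].astype(str)
    day_start = np.ones(n, dtype=bool)
    day_start[1:] = day_key.to_numpy()[1:] != day_key.to_numpy()[:-1]
    n_days = np.array([int(day_start[sl].sum()) for sl in part_slices])

    u_cols: list[np.ndarray] = []
    u_names: list[str] = []
    level_of_col: list[int] = []
    level_names: list[str] = []

    def add_level(name: str, columns: list[tuple[str, np.ndarray]]) -> None:
        level_names.append(name)
        for cname, col in columns:
            u_cols.append(col)
            u_names.append(cname)
            level_of_col.append(len(level_names) - 1)

    if spec.random_intercept:
        add_level("participant", [("participant", np.ones(n))])
    for v in _slope_vars(spec):
        add_level(f"slope_{v}", [(f"slope_{v}", cont_cols[v])])
    if spec.weekday_level:
        wd = rec["weekday"].to_numpy(int)
        add_level("weekday", [(f"weekday:{d}", (wd == d).astype(float)) for d in range(7)])
    if spec.hour_level:
        hh = rec["hour"].to_numpy(int)
        add_level("hour", [(f"hour:{h}", (hh == h).astype(float)) for h in range(24)])
    if spec.movement_decile_level:
        md = rec["movement_decile"].to_numpy()
        add_level("movement_decile",
                  [(f"movement_decile:{d}", (md == d).astype(float)) for d in range(1, 11)])

    U = np.column_stack(u_cols) if u_cols else np.zeros((n, 0))

    return Design(y=y, X=X, x_names=names, U=U, u_names=u_names,
                  level_of_col=np.asarray(level_of_col, dtype=int),
                  level_names=level_names, part_slices=part_slices,
                  part_ids=list(uniq_pids), day_start=day_start,
                  n_days_per_part=n_days, scaler=scaler, records=rec, spec=spec)


# --------------------------------------------------------------------------
# Likelihood machinery
# --------------------------------------------------------------------------

class _Engine:
    """Profiled (RE)ML likelihood over (log lambda, arctanh phi)."""

    def __init__(self, design: Design):
        self.d = design
        self.K = len(design.level_names)
        self.ar1 = bool(design.spec.ar1) if design.spec is not None else True
        self.stack = np.hstack([design.y[:, None], design.X, design.U])
        self._gram_cache: dict[float, tuple[list[np.ndarray], float]] = {}

    # -- AR(1) whitening and per-participant Gram matrices ----------------
    def _grams(self, phi: float) -> tuple[list[np.ndarray], float]:
        cached = self._gram_cache.get(phi)
        if cached is not None:
            return cached
        d = self.d
        S = self.stack
        if phi == 0.0:
            W = S
        else:
            s = np.sqrt(1.0 - phi * phi)
            W = np.empty_like(S)
            W[1:] = (S[1:] - phi * S[:-1]) / s
            W[d.day_start] = S[d.day_start]
        grams = [W[sl].T @ W[sl] for sl in d.part_slices]
        # log det of the AR(1) correlation: (m_d - 1) log(1 - phi^2) per day.
        logdet_c = 0.0 if phi == 0.0 else \
            (d.n - int(d.n_days_per_part.sum())) * np.log(1.0 - phi * phi)
        if len(self._gram_cache) > 64:
            self._gram_cache.clear()
        self._gram_cache[phi] = (grams, logdet_c)
        return grams, logdet_c

    def _unpack(self, theta: np.ndarray) -> tuple[np.ndarray, float]:
        lam = np.exp(theta[:self.K])
        phi = float(np.tanh(theta[self.K])) if self.ar1 else 0.0
        return lam, phi

    def profile(self, theta: np.ndarray) -> dict:
        """All profiled quantities at one point of the variance parameters."""
        d = self.d
        lam, phi = self._unpack(theta)
        grams, logdet_c = self._grams(phi)
        m = 1 + d.p                      # columns of [y, X] in the Gram
        q = d.U.shape[1]
        sqrt_lam_col = np.sqrt(lam[d.level_of_col]) if q else np.zeros(0)

        S_acc = np.zeros((m, m))
        logdet = logdet_c
        chol_blocks = []
        for F in grams:
            F_AA = F[:m, :m]
            if q:
                B = sqrt_lam_col[:, None] * F[m:, :m]           # q x m
                GtG = (sqrt_lam_col[:, None] * F[m:, m:]) * sqrt_lam_col[None, :]
                M = GtG + np.eye(q)
                c, low = cho_factor(M, lower=True, check_finite=False)
                logdet += 2.0 * float(np.sum(np.log(np.diag(c))))
                S_p = F_AA - B.T @ cho_solve((c, low), B, check_finite=False)
                chol_blocks.append((c, low, B))
            else:
                S_p = F_AA
                chol_blocks.append(None)
            S_acc += S_p

        S_yy = S_acc[0, 0]
        S_Xy = S_acc[1:, 0]
        S_XX = S_acc[1:, 1:]
        beta = np.linalg.solve(S_XX, S_Xy)
        quad = float(S_yy - S_Xy @ beta)
        quad = max(quad, 1e-300)
        n, p = d.n, d.p
        reml = (d.spec.estimation == "REML") if d.spec is not None else False
        if reml:
            sigma2 = quad / (n - p)
            sign, logdet_xx = np.linalg.slogdet(S_XX / sigma2)
            ll = (-0.5 * (n - p) * np.log(2.0 * np.pi * sigma2) - 0.5 * logdet
                  - 0.5 * logdet_xx - 0.5 * (n - p))
        else:
            sigma2 = quad / n
            ll = -0.5 * n * np.log(2.0 * np.pi * sigma2) - 0.5 * logdet - 0.5 * n
        return {"ll": float(ll), "beta": beta, "sigma2": float(sigma2),
                "lam": lam, "phi": phi, "S_XX": S_XX, "chol_blocks": chol_blocks,
                "sqrt_lam_col": sqrt_lam_col, "logdet": float(logdet)}

    def nll(self, theta: np.ndarray) -> float:
        try:
            return -self.profile(theta)["ll"]
        except np.linalg.LinAlgError:
            return 1e12


# --------------------------------------------------------------------------
# Fit result
# --------------------------------------------------------------------------

@dataclass
class ModelFit:
    """Estimates, uncertainty and diagnostics of one mixed-model fit."""

    spec: ModelSpec
    beta: pd.Series
    se: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    vcov: pd.DataFrame
    variance_components: dict[str, float]    # sigma_k^2 per level, response units^2
    sigma2: float
    phi: float
    loglik: float
    n_obs: int
    n_participants: int
    converged: bool
    n_iter: int
    optimizer_message: str
    scaler: dict
    design: Design = field(repr=False, default=None)

    @property
    def n_parameters(self) -> int:
        """Fixed coefficients + variance components + AR(1) + residual."""
        k = len(self.beta) + len(self.variance_components) + 1
        if self.spec.ar1:
            k += 1
        return k

    def random_effects(self) -> dict[str, pd.Series]:
        """Predicted random effects per level, indexed by (participant, group)."""
        d = self.design
        out: dict[str, dict] = {name: {} for name in d.level_names}
        for k, sl in enumerate(d.part_slices):
            pid = d.part_ids[k]
            present = d.U[sl].any(axis=0)
            for j in np.flatnonzero(present):
                level = d.level_names[d.level_of_col[j]]
                key = d.u_names[j].split(":", 1)[-1] if ":" in d.u_names[j] else ""
                out[level][(pid, key)] = self._blups_part[k][j]
        return {name: pd.Series(vals, dtype=float) for name, vals in out.items()}

    @property
    def _blups_part(self) -> list[np.ndarray]:
        return self.__dict__["__blups_part"]

    def fitted_fixed(self) -> np.ndarray:
        """X beta on the (sorted) design records."""
        return self.design.X @ self.beta.to_numpy()

    def fitted(self) -> np.ndarray:
        """X beta + Z b-hat on the (sorted) design records."""
        d = self.design
        yhat = self.fitted_fixed()
        for k, sl in enumerate(d.part_slices):
            yhat[sl] += d.U[sl] @ self._blups_part[k]
        return yhat

    def resid(self) -> np.ndarray:
        """Observation-level residuals after removing predicted random effects."""
        return self.design.y - self.fitted()

    def summary(self) -> str:
        """Human-readable coefficient table."""
        lines = [f"Mixed model: fixed={self.spec.fixed!r}  response={self.spec.response!r}  "
                 f"method={self.spec.estimation}  AR(1)={self.spec.ar1}",
                 f"n_obs={self.n_obs}  participants={self.n_participants}  "
                 f"loglik={self.loglik:.2f}  converged={self.converged}",
                 "", f"{'term':<24}{'beta':>10}{'se':>9}{'95% CI':>22}"]
        for name in self.beta.index:
            lines.append(f"{name:<24}{self.beta[name]:>+10.3f}{self.se[name]:>9.3f}"
                         f"   [{self.ci_lower[name]:>+8.3f} to {self.ci_upper[name]:>+8.3f}]")
        lines.append("")
        lines.append("variance components (s.d. in response units):")
        for lvl, v in self.variance_components.items():
            lines.append(f"  {lvl:<22}{np.sqrt(v):>10.4f}")
        lines.append(f"  {'residual':<22}{np.sqrt(self.sigma2):>10.4f}")
        lines.append(f"  AR(1) phi            {self.phi:>10.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "fixed": self.spec.fixed, "response": self.spec.response,
            "estimation": self.spec.estimation,
            "beta": self.beta.to_dict(), "se": self.se.to_dict(),
            "ci_lower": self.ci_lower.to_dict(), "ci_upper": self.ci_upper.to_dict(),
            "variance_components": self.variance_components,
            "residual_variance": self.sigma2, "ar1_phi": self.phi,
            "loglik": self.loglik, "n_obs": self.n_obs,
            "n_participants": self.n_participants, "converged": self.converged,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

def fit_lme_ar1(design: Design, spec: ModelSpec | None = None,
                fix_theta: np.ndarray | None = None) -> ModelFit:
    """Fit the mixed model by (restricted) maximum likelihood.

    Variance parameters are optimized on transformed scales (log variance
    ratios, arctanh of the AR(1) coefficient) from a fixed deterministic
    start (each level's variance at 10% of the response variance, phi = 0);
    on failure two perturbed restarts are attempted.  Non-convergence
    raises; variance components collapsing to ~0 emit a warning naming the
    level.

    ``fix_theta`` holds the variance parameters fixed at the supplied
    transformed values and only profiles the fixed coefficients and the
    residual scale — used for effect-size null models that must keep the
    random-effect distribution of the full model.
    """
    spec = spec or design.spec or ModelSpec()
    if design.spec is None:
        design.spec = spec
    K = len(design.level_names)
    # every level is nested in participants, so >= 2 participants guarantees
    # >= 2 groups per level
    if K and len(design.part_ids) < 2:
        raise ValueError("random levels need at least 2 participants")

    eng = _Engine(design)
    if fix_theta is not None:
        best_x = np.asarray(fix_theta, dtype=float)
        success, n_iter, message = True, 0, "variance parameters held fixed"
    else:
        frac = 0.10
        lam0 = frac / max(1.0 - frac * K, 0.2)
        theta0 = np.concatenate([np.full(K, np.log(lam0)),
                                 [0.0] if eng.ar1 else []])
        n_theta = theta0.size
        bounds = [(-15.0, 10.0)] * K + ([(-5.0, 5.0)] if eng.ar1 else [])

        best = None
        rng = np.random.default_rng(12345)
        for attempt in range(3):
            start = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.5, size=n_theta)
            res = optimize.minimize(eng.nll, start, method="L-BFGS-B", bounds=bounds,
                                    options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500})
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-9):
                best = res
            if res.success and np.isfinite(res.fun):
                best = res if res.fun <= best.fun + 1e-9 else best
                break
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(f"mixed-model optimization failed: {best}")
        if not best.success:
            warnings.warn(f"optimizer did not report convergence: {best.message}")
        best_x, success = best.x, bool(best.success)
        n_iter, message = int(best.nit), str(best.message)

    prof = eng.profile(best_x)
    lam, phi, sigma2 = prof["lam"], prof["phi"], prof["sigma2"]
    for name, l in zip(design.level_names, lam):
        if l < 1e-6:
            warnings.warn(f"variance component {name!r} collapsed to ~0 (singular fit)")

    covb = sigma2 * np.linalg.inv(prof["S_XX"])
    se = np.sqrt(np.diag(covb))
    beta = pd.Series(prof["beta"], index=design.x_names)
    se_s = pd.Series(se, index=design.x_names)
    fit = ModelFit(
        spec=spec, beta=beta, se=se_s,
        ci_lower=beta - 1.96 * se_s, ci_upper=beta + 1.96 * se_s,
        vcov=pd.DataFrame(covb, index=design.x_names, columns=design.x_names),
        variance_components={name: float(l * sigma2)
                             for name, l in zip(design.level_names, lam)},
        sigma2=float(sigma2), phi=float(phi), loglik=float(prof["ll"]),
        n_obs=design.n, n_participants=len(design.part_ids),
        converged=success, n_iter=n_iter,
        optimizer_message=message, scaler=design.scaler, design=design,
    )
    # Per-participant BLUP vectors (columns outside a participant's block are 0).
    blups_part = []
    m = 1 + design.p
    grams, _ = eng._grams(phi)
    for F, blk in zip(grams, prof["chol_blocks"]):
        if blk is None:
            blups_part.append(np.zeros(0))
            continue
        c, low, _ = blk
        coef = np.concatenate([[1.0], -prof["beta"]])
        gtr = prof["sqrt_lam_col"] * (F[m:, :m] @ coef)
        blups_part.append(prof["sqrt_lam_col"] * cho_solve((c, low), gtr,
                                                           check_finite=False))
    fit.__dict__["__blups_part"] = blups_part
    return fit


def fit_model(records: pd.DataFrame, spec: ModelSpec | None = None) -> ModelFit:
    """Convenience: :func:`build_design` followed by :func:`fit_lme_ar1`."""
    spec = spec or ModelSpec()
    design = build_design(records, spec)
    return fit_lme_ar1(design, spec)


def fit_effect_null(fit_full: ModelFit) -> ModelFit:
    """Intercept-only null sharing the full model's random-effect law.

    Builds an intercept-only design with the identical random structure
    (including the random slopes) on the same records and evaluates it
    with the variance ratios and AR(1) coefficient held at the full
    model's estimates.  Holding the variance parameters fixed keeps the
    BLUP shrinkage identical between the two models; re-estimating them
    freely would let the mean-zero random slopes absorb a shared fixed
    effect and understate the fixed-effect contribution.
    """
    null_spec = null_spec_for(fit_full.spec, keep_random_slopes=True)
    design = build_design(fit_full.design.records, null_spec)
    lam = np.array([fit_full.variance_components[name] / fit_full.sigma2
                    for name in design.level_names])
    theta = np.log(np.maximum(lam, 1e-15))
    if null_spec.ar1:
        phi = np.clip(fit_full.phi, -0.999999, 0.999999)
        theta = np.concatenate([theta, [np.arctanh(phi)]])
    return fit_lme_ar1(design, null_spec, fix_theta=theta)


def dense_loglik(design: Design, lam: dict[str, float] | np.ndarray, phi: float,
                 sigma2: float, beta: np.ndarray) -> float:
    """Dense multivariate-normal log-likelihood at fixed parameters.

    Brute-force reference: builds the full n-by-n covariance
    ``sigma^2 (sum_k lambda_k Z_k Z_k' + C(phi))`` and evaluates the
    Gaussian density.  Only sensible for small n; used to validate the
    structured computation.
    """
    d = design
    if isinstance(lam, dict):
        lam = np.array([lam[name] for name in d.level_names])
    n = d.n
    C = np.zeros((n, n))
    # AR(1) correlation within participant-days, identity elsewhere.
    day_id = np.cumsum(d.day_start) - 1
    for b in np.unique(day_id):
        rows = np.flatnonzero(day_id == b)
        m = rows.size
        idx = np.arange(m)
        C[np.ix_(rows, rows)] = phi ** np.abs(idx[:, None] - idx[None, :])
    V = C.copy()
    # random effects are drawn independently per participant, so the
    # outer products only fill within-participant blocks
    for sl in d.part_slices:
        for j in range(d.U.shape[1]):
            lj = lam[d.level_of_col[j]]
            u = d.U[sl, j]
            V[sl, sl] += lj * np.outer(u, u)
    cov = sigma2 * V
    r = d.y - d.X @ np.asarray(beta)
    sign, logdet = np.linalg.slogdet(cov)
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(cov, r)))


# --------------------------------------------------------------------------
# Inference helpers
# --------------------------------------------------------------------------

def likelihood_ratio_test(fit_full: ModelFit, fit_null: ModelFit) -> tuple[float, int, float]:
    """Chi-square LRT of two nested ML fits on the same records.

    Returns ``(chi2, df, p)`` with ``chi2 = 2 (ll_full - ll_null)`` and
    ``df`` the difference in total parameter counts.  REML fits are
    rejected: restricted likelihoods of models with different fixed parts
    are not comparable.
    """
    for f in (fit_full, fit_null):
        if f.spec.estimation != "ML":
            raise ValueError("likelihood-ratio tests require ML fits, not REML")
    if fit_full.n_obs != fit_null.n_obs:
        raise ValueError("fits must be on the same records")
    chi2 = 2.0 * (fit_full.loglik - fit_null.loglik)
    df = fit_full.n_parameters - fit_null.n_parameters
    if df < 0:
        raise ValueError("the null model must be nested in the full model")
    p = float(stats.chi2.sf(max(chi2, 0.0), df)) if df > 0 else 1.0
    return float(chi2), int(df), p


def gvif(X: pd.DataFrame | np.ndarray, term_groups: dict[str, list] | None = None,
         x_names: list[str] | None = None) -> pd.Series:
    """Generalized variance-inflation factors (determinant-ratio form).

    For each term (a block of one or more design columns) computes
    ``det(R_11) det(R_22) / det(R)`` on the correlation matrix ``R`` of
    the non-intercept columns — the classic GVIF, which reduces to the
    ordinary VIF for single-column terms and is invariant to rescaling of
    the columns within a term.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        M = X.to_numpy(float)
    else:
        M = np.asarray(X, dtype=float)
        names = x_names or [f"x{j}" for j in range(M.shape[1])]
    keep = [j for j, nm in enumerate(names) if nm != "intercept"]
    M = M[:, keep]
    names = [names[j] for j in keep]
    if term_groups is None:
        term_groups = {nm: [nm] for nm in names}
    if len(term_groups) < 2:
        raise ValueError("GVIF needs at least 2 terms besides the intercept")
    R = np.corrcoef(M, rowvar=False)
    det_R = np.linalg.det(R)
    if det_R <= 1e-12:
        raise ValueError(f"singular correlation matrix among columns {names}")
    out = {}
    col_of = {nm: j for j, nm in enumerate(names)}
    for term, cols in term_groups.items():
        idx = [col_of[c] for c in cols]
        rest = [j for j in range(len(names)) if j not in idx]
        det1 = np.linalg.det(R[np.ix_(idx, idx)])
        det2 = np.linalg.det(R[np.ix_(rest, rest)]) if rest else 1.0
        out[term] = float(det1 * det2 / det_R)
    return pd.Series(out)


@dataclass
class EffectSizeReport:
    """Level-wise residual sums-of-squares and the derived effect sizes.

    ``sigma2_*`` are observation-level residual SS after removing the
    predicted random effects; ``tau2_*`` and ``gamma2_*`` are the SS of
    the predicted weekday- and hour-level effects.  ``rp2`` is the
    proportional reduction in prediction error of the fixed effects
    relative to an intercept-only model with identical random structure;
    ``rf2`` replaces the null-model denominator with the total
    sum-of-squares of the observations.
    """

    sigma2_full: float
    tau2_full: float
    gamma2_full: float
    sigma2_null: float
    tau2_null: float
    gamma2_null: float
    total_ss: float
    rp2: float
    rf2: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("sigma2_full", "tau2_full", "gamma2_full", "sigma2_null",
                 "tau2_null", "gamma2_null", "total_ss", "rp2", "rf2")}


def _level_ss(fit: ModelFit) -> tuple[float, float, float]:
    re = fit.random_effects()
    sigma2 = float(np.sum(fit.resid() ** 2))
    tau2 = float(np.sum(re.get("weekday", pd.Series(dtype=float)) ** 2))
    gamma2 = float(np.sum(re.get("hour", pd.Series(dtype=float)) ** 2))
    return sigma2, tau2, gamma2


def partial_r2(fit_full: ModelFit, fit_null: ModelFit) -> EffectSizeReport:
    """Variance explained by the fixed effects in a multilevel model.

    Both fits must share the records and the random structure; the null
    must be intercept-only.  Computes level-wise residual sums-of-squares
    (observation, weekday, hour) for both models and returns

    ``RP2 = 1 - (sF + tF + gF) / (sN + tN + gN)``

    together with ``RF2 = 1 - (sF + tF + gF) / TSS``.
    """
    if fit_full.design.level_names != fit_null.design.level_names:
        raise ValueError("full and null fits must share the random structure")
    if fit_full.n_obs != fit_null.n_obs:
        raise ValueError("full and null fits must be on the same records")
    sF, tF, gF = _level_ss(fit_full)
    sN, tN, gN = _level_ss(fit_null)
    y = fit_full.design.y
    tss = float(np.sum((y - y.mean()) ** 2))
    rp2 = 1.0 - (sF + tF + gF) / (sN + tN + gN)
    rf2 = 1.0 - (sF + tF + gF) / tss
    return EffectSizeReport(sF, tF, gF, sN, tN, gN, tss, float(rp2), float(rf2))


def percent_change(beta_log_scale: float) -> float:
    """Back-transform a log-response coefficient to percent change per unit.

    ``(exp(beta) - 1) * 100``.
    """
    return float((np.exp(beta_log_scale) - 1.0) * 100.0)


def interaction_contrasts(fit: ModelFit) -> pd.DataFrame:
    """Slope contrasts versus the Quiet soundscape from the interaction fit.

    With Quiet as the reference class, each interaction coefficient
    ``var:level`` *is* the difference between that class's slope and the
    Quiet slope; the table reports the estimate, its standard error and a
    Wald p-value for every (acoustic variable, class) pair.
    """
    rows = []
    for v in ACOUSTIC_VARS:
        for level in SOUNDSCAPES_COLLAPSED[1:]:
            name = f"{v}:{level}"
            if name not in fit.beta.index:
                raise ValueError(f"fit has no interaction term {name!r}; "
                                 "did you fit the interaction model?")
            est = float(fit.beta[name])
            se = float(fit.se[name])
            z = est / se if se > 0 else np.inf
            rows.append({"variable": v, "contrast": f"{level} - Quiet",
                         "estimate": est, "se": se,
                         "p": float(2.0 * stats.norm.sf(abs(z)))})
    return pd.DataFrame(rows)
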
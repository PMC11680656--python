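"""Classification-error-corrected parametric proportional hazards across latent classes.

Age is the timescale.  Given fixed stage-1 posterior class-membership
probabilities p_ig, the hazard for a woman of class g is

    h_g(t | W) = h0(t) * exp(xi_g + gamma' W),

with the reference class' log hazard ratio xi fixed at 0, and the
log-likelihood marginalizes the survival contribution over classes:

    sum_i log sum_g p_ig [ h_g(T_i)^{delta_i} * S_g(T_i) / S_g(E_i) ],

where T_i is the exit age, E_i the (delayed) entry age and delta_i the
event indicator.  Dividing by S_g(E_i) accounts for left truncation:
subjects are observed only conditional on being event-free at entry.
Weighting by p_ig rather than the modal class corrects the hazard ratios
for classification error in the posterior assignment; maximizing this
weighted objective is equivalent to maximizing the joint
longitudinal-survival likelihood in the hazard parameters with the
trajectory parameters held fixed (the two objectives differ by a term free
of hazard parameters).

The baseline hazard h0 is either Weibull or a cubic M-spline with
non-negative coefficients (its integral, the cumulative baseline hazard,
uses the corresponding I-spline basis); candidate spline fits are compared
by AIC.  Standard errors condition on the stage-1 estimates (inverse
observed information); confidence intervals are Wald.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_fprime, approx_hess

from alctraj.lcmm import PosteriorMatrix
from alctraj.preprocess import MODEL2_COVARIATES

_SPLINE_DEGREE = 3  # cubic


@dataclass
class HazardSpec:
    """Baseline family, knot count, covariate set and reference class."""

    baseline_family: str = "weibull"  # or "mspline"
    n_knots: int = 4  # total knots incl. the two boundary knots
    covariate_set: str = "model1"  # "model1", "model2" or "none"
    reference_class: int | None = None  # 1-based; None = last class
    ci_level: float = 0.95

    def __post_init__(self):
        if self.baseline_family not in ("weibull", "mspline"):
            raise ValueError("baseline_family must be 'weibull' or 'mspline'")
        if self.n_knots < 2:
            raise ValueError("need at least the two boundary knots")
        if self.covariate_set not in ("model1", "model2", "none"):
            raise ValueError("covariate_set must be 'model1', 'model2' or 'none'")


def weibull_hazard(t, shape: float, scale: float):
    """Weibull hazard and cumulative hazard at age(s) ``t``.

    h0(t) = (shape/scale) (t/scale)^(shape-1);  H0(t) = (t/scale)^shape.
    shape = 1 recovers the constant-hazard (exponential) case.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0) or shape <= 0 or scale <= 0:
        raise ValueError("t, shape and scale must be strictly positive")
    u = t / scale
    h = (shape / scale) * u ** (shape - 1.0)
    H = u**shape
    return h, H


class MSplineBasis:
    """Cubic M-spline basis and its integrated I-spline counterpart.

    Each M-spline basis function is non-negative and integrates to 1 over
    its support, so a non-negative coefficient vector yields a valid hazard
    and the I-splines give its cumulative hazard in closed form.  Interior
    knots sit at equally spaced quantiles of the observed event ages;
    boundary knots at the minimum entry and maximum exit age.
    """

    def __init__(self, boundary: tuple, interior=()):
        lo, hi = float(boundary[0]), float(boundary[1])
        interior = np.sort(np.asarray(interior, dtype=float))
        if lo >= hi:
            raise ValueError("boundary knots must be increasing")
        if interior.size and (interior.min() <= lo or interior.max() >= hi):
            raise ValueError("interior knots must lie strictly inside the boundary")
        self.boundary = (lo, hi)
        self.interior = interior
        k = _SPLINE_DEGREE
        self._knots = np.concatenate([[lo] * (k + 1), interior, [hi] * (k + 1)])
        self.n_basis = len(self._knots) - (k + 1)
        deltas = self._knots[k + 1 :] - self._knots[: self.n_basis]
        self._mscale = (k + 1) / deltas  # B-spline -> unit-integral M-spline
        self._antiderivs = [
            BSpline(self._knots, np.eye(self.n_basis)[j], k).antiderivative()
            for j in range(self.n_basis)
        ]

    @classmethod
    def from_data(cls, entry, exit_age, event, n_knots: int) -> "MSplineBasis":
        """Place knots from survival data: quantile interior knots, data-range boundary."""
        entry = np.asarray(entry, dtype=float)
        exit_age = np.asarray(exit_age, dtype=float)
        event = np.asarray(event).astype(bool)
        if not event.any():
            raise ValueError("need at least one event to place interior knots")
        n_interior = n_knots - 2
        event_ages = exit_age[event]
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(event_ages, qs) if n_interior > 0 else ()
        return cls((entry.min(), exit_age.max()), interior)

    def _check(self, t):
        t = np.asarray(t, dtype=float)
        lo, hi = self.boundary
        if np.any(t < lo - 1e-9) or np.any(t > hi + 1e-9):
            raise ValueError(f"t outside the boundary knots [{lo}, {hi}]")
        return np.clip(t, lo, hi)

    def m(self, t) -> np.ndarray:
        """M-spline basis values; shape (len(t), n_basis)."""
        t = self._check(np.atleast_1d(t))
        design = BSpline.design_matrix(t, self._knots, _SPLINE_DEGREE).toarray()
        return design * self._mscale[None, :]

    def i(self, t) -> np.ndarray:
        """I-spline basis values (integrals of the M-splines from the lower boundary)."""
        t = self._check(np.atleast_1d(t))
        lo = self.boundary[0]
        out = np.empty((len(t), self.n_basis))
        for j, anti in enumerate(self._antiderivs):
            out[:, j] = (anti(t) - anti(lo)) * self._mscale[j]
        return out


def mspline_baseline(t, basis: MSplineBasis, coefficients):
    """Baseline hazard and cumulative hazard h0(t) = sum_k eta_k M_k(t).

    Coefficients must be non-negative; H0 uses the matching I-spline basis.
    """
    eta = np.asarray(coefficients, dtype=float)
    if eta.shape != (basis.n_basis,):
        raise ValueError(f"expected {basis.n_basis} coefficients, got {eta.shape}")
    if np.any(eta < 0):
        raise ValueError("M-spline coefficients must be non-negative")
    h = basis.m(t) @ eta
    H = basis.i(t) @ eta
    return h, H


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


def build_covariates(survival: pd.DataFrame, covariate_set: str):
    """Indicator design matrix for the adjustment covariates.

    model1: recruitment quintile only (4 indicators; age is the timescale
    and never a covariate).  model2 additionally expands the eight
    lifestyle/reproductive categoricals, dropping one reference level each.
    """
    if covariate_set == "none":
        return np.zeros((len(survival), 0)), []
    cols = ["recruitment_quintile"]
    if covariate_set == "model2":
        cols += list(MODEL2_COVARIATES)
    pieces = []
    names = []
    for col in cols:
        series = survival[col]
        if series.isna().any():
            raise ValueError(f"missing values in covariate {col!r}; survival set must be complete-case")
        dummies = pd.get_dummies(series.astype("category"), prefix=col, drop_first=True)
        pieces.append(dummies.to_numpy(dtype=float))
        names.extend(dummies.columns.tolist())
    W = np.hstack(pieces) if pieces else np.zeros((len(survival), 0))
    return W, names


def _ids_checksum(ids) -> str:
    payload = ",".join(map(str, np.sort(np.asarray(ids)))).encode()
    return hashlib.md5(payload).hexdigest()


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


class _PHEngine:
    """Precomputed data for one latent-class PH likelihood."""

    def __init__(self, posteriors: PosteriorMatrix, survival: pd.DataFrame, spec: HazardSpec):
        if posteriors.subject_ids is not None:
            post_ids = np.asarray(posteriors.subject_ids)
            surv_ids = survival["subject_id"].to_numpy()
            if len(post_ids) != len(surv_ids) or set(post_ids) != set(surv_ids):
                raise ValueError("posterior matrix and survival data hold different subjects")
            order = pd.Index(surv_ids).get_indexer(post_ids)
            survival = survival.iloc[order].reset_index(drop=True)
        self.p = posteriors.probs
        self.G = self.p.shape[1]
        self.spec = spec
        self.ref = (spec.reference_class or self.G) - 1
        if not (0 <= self.ref < self.G):
            raise ValueError("reference_class out of range")
        self.E = survival["entry_age"].to_numpy(dtype=float)
        self.T = survival["exit_age"].to_numpy(dtype=float)
        self.d = survival["event"].to_numpy(dtype=float)
        if np.any(self.T <= self.E):
            bad = survival.loc[self.T <= self.E, "subject_id"].tolist()
            raise ValueError(f"exit age must exceed entry age; offending subjects {bad[:5]}")
        self.W, self.cov_names = build_covariates(survival, spec.covariate_set)
        self.ids = survival["subject_id"].to_numpy()
        self.checksum = _ids_checksum(self.ids)
        self.modal = posteriors.modal_class

        if spec.baseline_family == "mspline":
            self.basis = MSplineBasis.from_data(self.E, self.T, self.d, spec.n_knots)
            self.M_T = self.basis.m(self.T)
            self.I_T = self.basis.i(self.T)
            self.I_E = self.basis.i(self.E)
            self.n_base = self.basis.n_basis
        else:
            self.basis = None
            self.n_base = 2

    @property
    def n_free(self) -> int:
        return (self.G - 1) + self.W.shape[1] + self.n_base

    def unpack(self, theta):
        G = self.G
        xi = np.zeros(G)
        free = [g for g in range(G) if g != self.ref]
        xi[free] = theta[: G - 1]
        ncov = self.W.shape[1]
        gamma = theta[G - 1 : G - 1 + ncov]
        base = theta[G - 1 + ncov :]
        return xi, gamma, base

    def baseline(self, base_raw):
        """(log h0(T), H0(T), H0(E)) under the positivity parameterization."""
        if self.spec.baseline_family == "weibull":
            shape, scale = np.exp(base_raw)
            logh = np.log(shape / scale) + (shape - 1.0) * np.log(self.T / scale)
            H_T = (self.T / scale) ** shape
            H_E = (self.E / scale) ** shape
        else:
            eta = np.exp(base_raw)
            h = self.M_T @ eta
            logh = np.log(np.clip(h, 1e-300, None))
            H_T = self.I_T @ eta
            H_E = self.I_E @ eta
        return logh, H_T, H_E

    def loglik(self, theta) -> float:
        xi, gamma, base_raw = self.unpack(np.asarray(theta, dtype=float))
        logh, H_T, H_E = self.baseline(base_raw)
        lin = xi[None, :] + (self.W @ gamma)[:, None]  # (N, G)
        risk = np.exp(lin)
        logterm = self.d[:, None] * (logh[:, None] + lin) - (H_T - H_E)[:, None] * risk
        with np.errstate(divide="ignore"):
            logp = np.where(self.p > 0, np.log(np.clip(self.p, 1e-300, None)), -np.inf)
        contrib = logsumexp(logp + logterm, axis=1)
        if not np.all(np.isfinite(contrib)):
            bad = self.ids[~np.isfinite(contrib)]
            raise FloatingPointError(f"non-finite likelihood for subjects {bad[:5].tolist()}")
        return float(contrib.sum())

    def init_theta(self) -> np.ndarray:
        D = self.d.sum()
        if D < 1:
            raise ValueError("need at least one event")
        if self.spec.baseline_family == "weibull":
            shape0 = 6.0
            scale0 = (np.sum(self.T**shape0 - self.E**shape0) / D) ** (1.0 / shape0)
            base = np.log([shape0, scale0])
        else:
            c = D / np.sum(self.T - self.E)  # crude constant hazard
            k = _SPLINE_DEGREE
            deltas = (k + 1) / self.basis._mscale
            base = np.log(np.clip(c * deltas / (k + 1), 1e-8, None))
        return np.concatenate([np.zeros(self.G - 1 + self.W.shape[1]), base])


@dataclass
class HazardFit:
    """Fitted latent-class proportional-hazards model."""

    spec: HazardSpec
    n_classes: int
    xi: np.ndarray  # (G,) log hazard ratios, reference fixed at 0
    xi_se: np.ndarray
    gamma: np.ndarray
    gamma_names: list
    baseline_params: dict
    loglik: float
    n_params: int
    aic: float
    cov: np.ndarray  # covariance of the free parameter vector
    hr_table: pd.DataFrame
    converged: bool
    data_checksum: str
    reference_class: int

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "baseline_family": self.spec.baseline_family,
                "n_knots": self.spec.n_knots,
                "covariate_set": self.spec.covariate_set,
                "reference_class": self.reference_class,
                "xi": self.xi.tolist(),
                "xi_se": self.xi_se.tolist(),
                "gamma": dict(zip(self.gamma_names, map(float, self.gamma))),
                "baseline_params": {
                    k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in self.baseline_params.items()
                },
                "loglik": self.loglik,
                "n_params": self.n_params,
                "AIC": self.aic,
                "converged": self.converged,
                "data_checksum": self.data_checksum,
                "hr_table": self.hr_table.to_dict(orient="records"),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def latent_class_ph_loglik(
    posteriors: PosteriorMatrix,
    survival: pd.DataFrame,
    spec: HazardSpec,
    params: dict,
) -> float:
    """Evaluate the classification-error-corrected PH log-likelihood.

    ``params`` carries ``xi`` (length G, reference entry 0), ``gamma``
    (covariate coefficients, may be empty) and the baseline: ``shape`` and
    ``scale`` for Weibull, or ``coefficients`` (non-negative) for the
    M-spline family.
    """
    engine = _PHEngine(posteriors, survival, spec)
    xi = np.asarray(params["xi"], dtype=float)
    if xi.shape != (engine.G,):
        raise ValueError("xi must have one entry per class")
    if abs(xi[engine.ref]) > 1e-12:
        raise ValueError("reference-class xi must be 0")
    gamma = np.asarray(params.get("gamma", np.zeros(engine.W.shape[1])), dtype=float)
    if spec.baseline_family == "weibull":
        base = np.log([params["shape"], params["scale"]])
    else:
        coefs = np.asarray(params["coefficients"], dtype=float)
        if np.any(coefs < 0):
            raise ValueError("M-spline coefficients must be non-negative")
        base = np.log(np.clip(coefs, 1e-300, None))
    free = [g for g in range(engine.G) if g != engine.ref]
    theta = np.concatenate([xi[free], gamma, base])
    return engine.loglik(theta)


def fit_hazard(
    posteriors: PosteriorMatrix,
    survival: pd.DataFrame,
    spec: HazardSpec,
) -> HazardFit:
    """Maximize the latent-class PH likelihood and return hazard ratios with Wald CIs.

    Positivity of the Weibull parameters and spline coefficients is
    enforced by optimizing on the log scale; the covariance of the
    estimates is the inverse observed information at the optimum
    (conditioning on the stage-1 parameters), and spline-coefficient SEs on
    the natural scale follow by the delta method.
    """
    engine = _PHEngine(posteriors, survival, spec)
    theta0 = engine.init_theta()

    def neg(th):
        try:
            return -engine.loglik(th)
        except FloatingPointError:
            return 1e12

    res = minimize(neg, theta0, method="BFGS", options={"maxiter": 500, "gtol": 1e-6})
    if not res.success:  # one Nelder-Mead polish guards against line-search stalls
        res2 = minimize(neg, res.x, method="Nelder-Mead", options={"maxiter": 2000, "fatol": 1e-9})
        if res2.fun < res.fun:
            res = res2
    theta = res.x
    ll = engine.loglik(theta)

    H = approx_hess(theta, lambda th: -engine.loglik(th))
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        # Singular information.  Three distinct situations, told apart by
        # where the flat eigendirection lives:
        #  * covariate block: collinear design — a data problem, fatal;
        #  * class log-HR block: an unidentified class contrast (no
        #    effective events in that class, the marginalized likelihood is
        #    monotone in xi toward -inf) — report an infinite-variance Wald
        #    interval rather than crash;
        #  * baseline block: a spline coefficient pinned at its zero
        #    boundary — pseudo-inverse (zero variance along the boundary).
        w, V = np.linalg.eigh(H)
        n_xi = engine.G - 1
        n_reg = n_xi + engine.W.shape[1]
        tol = 1e-8 * max(1.0, float(w.max()))
        w_inv = np.where(w > tol, 1.0 / np.where(w > tol, w, 1.0), 0.0)
        for j in np.where(w <= tol)[0]:
            block = int(np.argmax(np.abs(V[:, j])))
            if n_xi <= block < n_reg:
                raise np.linalg.LinAlgError(
                    "singular information matrix; near-collinear covariate: "
                    f"{engine.cov_names[block - n_xi]}"
                )
            if block < n_xi:
                w_inv[j] = 1e12  # unidentified class contrast: SE -> inf
                warnings.warn(
                    "class log-HR unidentified (no effective events in a class); "
                    "reporting an infinite-variance Wald interval"
                )
            else:
                warnings.warn("baseline coefficient at boundary; pseudo-inverse covariance")
        cov = (V * w_inv[None, :]) @ V.T

    G = engine.G
    xi, gamma, base_raw = engine.unpack(theta)
    free = [g for g in range(G) if g != engine.ref]
    xi_se = np.zeros(G)
    se_free = np.sqrt(np.clip(np.diag(cov)[: G - 1], 0, None))
    xi_se[free] = se_free

    z = norm.ppf(0.5 + spec.ci_level / 2.0)
    hr = np.exp(xi)
    lo = np.exp(xi - z * xi_se)
    hi = np.exp(xi + z * xi_se)
    n_by_class = np.bincount(engine.modal - 1, minlength=G)
    cases_by_class = np.bincount(engine.modal - 1, weights=engine.d, minlength=G).astype(int)
    rows = []
    for g in range(G):
        is_ref = g == engine.ref
        rows.append(
            {
                "class": g + 1,
                "n_women": int(n_by_class[g]),
                "n_cases": int(cases_by_class[g]),
                "HR": 1.0 if is_ref else float(hr[g]),
                "ci_low": np.nan if is_ref else float(lo[g]),
                "ci_high": np.nan if is_ref else float(hi[g]),
                "reference": is_ref,
            }
        )
    hr_table = pd.DataFrame(rows)

    if spec.baseline_family == "weibull":
        shape, scale = np.exp(base_raw)
        baseline_params = {"shape": float(shape), "scale": float(scale)}
    else:
        eta = np.exp(base_raw)
        k0 = G - 1 + engine.W.shape[1]
        eta_se = eta * np.sqrt(np.clip(np.diag(cov)[k0:], 0, None))  # delta method
        baseline_params = {
            "coefficients": eta,
            "coefficients_se": eta_se,
            "boundary_knots": list(engine.basis.boundary),
            "interior_knots": engine.basis.interior.tolist(),
        }

    n_params = engine.n_free
    grad = approx_fprime(theta, lambda th: -engine.loglik(th), centered=True)
    gnorm = float(np.max(np.abs(grad)))
    grad_ok = bool(res.success) or gnorm < 1e-3 * max(1.0, abs(ll))
    if not grad_ok:
        warnings.warn(f"hazard fit did not converge cleanly (gradient norm {gnorm:.3g})")
    return HazardFit(
        spec=spec,
        n_classes=G,
        xi=xi,
        xi_se=xi_se,
        gamma=gamma,
        gamma_names=engine.cov_names,
        baseline_params=baseline_params,
        loglik=float(ll),
        n_params=n_params,
        aic=float(2.0 * n_params - 2.0 * ll),
        cov=cov,
        hr_table=hr_table,
        converged=bool(grad_ok),
        data_checksum=engine.checksum,
        reference_class=engine.ref + 1,
    )


def compare_baselines(fits: list):
    """Pick the minimum-AIC fit among candidates estimated on identical data.

    Returns (chosen fit, AIC table).  Equal-AIC ties go to the first listed
    fit, with a note in the table.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    checks = {f.data_checksum for f in fits}
    if len(checks) > 1:
        raise ValueError("fits were estimated on different data (id checksums differ)")
    table = pd.DataFrame(
        {
            "baseline": [f"{f.spec.baseline_family}" + (f"_{f.spec.n_knots}knots" if f.spec.baseline_family == "mspline" else "") for f in fits],
            "n_params": [f.n_params for f in fits],
            "loglik": [f.loglik for f in fits],
            "AIC": [f.aic for f in fits],
        }
    )
    best_aic = table["AIC"].min()
    winners = table.index[np.isclose(table["AIC"], best_aic, atol=1e-9)]
    chosen = fits[int(winners[0])]
    table["chosen"] = False
    table.loc[winners[0], "chosen"] = True
    if len(winners) > 1:
        table.attrs["note"] = "AIC tie; first listed fit chosen"
    return chosen, table
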
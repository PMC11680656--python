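"""Latent class mixed model (LCMM) estimation.

Model: subject i with n_i transformed intake measures y_i at rescaled times
t_ij = (age - 35)/13 belongs to latent class g with probability pi_g
(intercept-only multinomial, softmax of G-1 free logits, last class as
reference).  Conditional on class g,

    y_i | g  ~  MVN( X_i beta_g,  V_i ),     V_i = Z_i B Z_i' + sigma^2 I,

with X_i = Z_i the quadratic design (1, t, t^2), a random-effect covariance
B = L L' shared across classes, and homoscedastic residual sd sigma.  The
marginal log-likelihood sums log-sum-exp mixtures over classes.

Estimation is maximum likelihood: an EM warm-up (posterior-weighted
generalized-least-squares updates for the class means, EM updates for B and
sigma via the conditional moments of the random effects) followed by
quasi-Newton (L-BFGS-B) refinement of the full parameter vector with an
analytic gradient, using a Cholesky parameterization for B and log(sigma)
to enforce constraints.  Multistart estimation perturbs the one-class
solution to avoid local maxima.

Subjects contribute whatever measures they have (unbalanced V_i); there is
no imputation.  Estimation is label-agnostic; a separate relabeling utility
orders classes for presentation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from alctraj.preprocess import rescale_age, transform_intake, inverse_transform_intake

_LOG2PI = float(np.log(2.0 * np.pi))
_TRIL_IDX = np.tril_indices(3)


@dataclass
class TrajectorySpec:
    """Structural choices of the trajectory model (quadratic fixed & random parts)."""

    n_classes: int
    fixed_degree: int = 2
    random_degree: int = 2
    time_center: float = 35.0
    time_scale: float = 13.0
    age_guard: tuple = (18.0, 70.0)

    def __post_init__(self):
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.fixed_degree != 2 or self.random_degree != 2:
            raise ValueError("this analysis fixes both polynomial degrees at 2")


@dataclass
class TrajectoryData:
    """Padded per-subject arrays for the repeated intake measures.

    ``y`` holds the log(x+1)-transformed intakes, ``t`` the rescaled ages;
    both are zero-padded to the maximum number of measures and accompanied
    by a boolean ``mask`` marking real observations.
    """

    y: np.ndarray  # (N, M)
    t: np.ndarray  # (N, M)
    mask: np.ndarray  # (N, M) bool
    subject_ids: np.ndarray  # (N,)

    def __post_init__(self):
        if not self.mask.any(axis=1).all():
            raise ValueError("every subject needs at least one measure")

    @property
    def n_subjects(self) -> int:
        return self.y.shape[0]

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def from_frame(cls, intakes: pd.DataFrame, transform: bool = True) -> "TrajectoryData":
        """Build from a long table (subject_id, age_years, intake_g_day)."""
        df = intakes[["subject_id", "age_years", "intake_g_day"]].copy()
        value = (
            transform_intake(df["intake_g_day"].to_numpy(dtype=float))
            if transform
            else df["intake_g_day"].to_numpy(dtype=float)
        )
        df["value"] = value
        groups = df.groupby("subject_id", sort=True)
        counts = groups.size()
        ids = counts.index.to_numpy()
        N, M = len(ids), int(counts.max())
        y = np.zeros((N, M))
        t = np.zeros((N, M))
        mask = np.zeros((N, M), dtype=bool)
        order = np.argsort(df["subject_id"].to_numpy(), kind="stable")
        pos = {s: i for i, s in enumerate(ids)}
        fill = np.zeros(N, dtype=int)
        ages = df["age_years"].to_numpy(dtype=float)
        for k in order:
            i = pos[df["subject_id"].iat[k]]
            j = fill[i]
            y[i, j] = value[k]
            t[i, j] = rescale_age(ages[k])
            mask[i, j] = True
            fill[i] = j + 1
        return cls(y=y, t=t, mask=mask, subject_ids=ids)

    def design(self) -> np.ndarray:
        """Quadratic design (1, t, t^2) with padded rows zeroed; shape (N, M, 3)."""
        X = np.stack([np.ones_like(self.t), self.t, self.t**2], axis=-1)
        return X * self.mask[:, :, None]


@dataclass
class LcmmFit:
    """Fitted G-class latent class mixed model."""

    n_classes: int
    beta: np.ndarray  # (G, 3)
    membership_logits: np.ndarray  # (G-1,), class G is the reference
    re_cholesky: np.ndarray  # (3, 3) lower triangular, B = L L'
    residual_sd: float
    loglik: float = np.nan
    converged: bool = False
    n_iter: int = 0
    n_starts_used: int = 1
    best_start_seed: int = 0
    start_logliks: list = field(default_factory=list)

    @property
    def class_shares(self) -> np.ndarray:
        return softmax(np.append(self.membership_logits, 0.0))

    @property
    def re_covariance(self) -> np.ndarray:
        return self.re_cholesky @ self.re_cholesky.T

    @property
    def n_params(self) -> int:
        return (self.n_classes - 1) + 3 * self.n_classes + 6 + 1

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "n_classes": self.n_classes,
                "beta": self.beta.tolist(),
                "membership_logits": self.membership_logits.tolist(),
                "re_cholesky": self.re_cholesky.tolist(),
                "residual_sd": self.residual_sd,
                "loglik": self.loglik,
                "converged": self.converged,
                "n_iter": self.n_iter,
                "n_params": self.n_params,
                "n_starts_used": self.n_starts_used,
                "best_start_seed": self.best_start_seed,
                "start_logliks": list(self.start_logliks),
                "class_shares": self.class_shares.tolist(),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, path) -> "LcmmFit":
        d = json.loads(Path(path).read_text())
        return cls(
            n_classes=d["n_classes"],
            beta=np.asarray(d["beta"]),
            membership_logits=np.asarray(d["membership_logits"]),
            re_cholesky=np.asarray(d["re_cholesky"]),
            residual_sd=d["residual_sd"],
            loglik=d["loglik"],
            converged=d["converged"],
            n_iter=d["n_iter"],
            n_starts_used=d["n_starts_used"],
            best_start_seed=d["best_start_seed"],
            start_logliks=d["start_logliks"],
        )


@dataclass
class PosteriorMatrix:
    """Posterior class-membership probabilities p_ig and modal assignment.

    ``modal_class`` is 1-based (classes 1..G); ties go to the lowest index.
    ``mean_posterior_by_class[g]`` averages p_ig over subjects modally
    assigned to class g+1 (NaN for empty classes).
    """

    probs: np.ndarray  # (N, G)
    modal_class: np.ndarray  # (N,), values in 1..G
    mean_posterior_by_class: np.ndarray  # (G,)
    subject_ids: np.ndarray | None = None

    @property
    def n_classes(self) -> int:
        return self.probs.shape[1]

    def class_shares_modal(self) -> np.ndarray:
        G = self.n_classes
        return np.bincount(self.modal_class - 1, minlength=G) / len(self.modal_class)

    def to_frame(self) -> pd.DataFrame:
        G = self.probs.shape[1]
        df = pd.DataFrame(self.probs, columns=[f"class_{g + 1}" for g in range(G)])
        df.insert(0, "subject_id", self.subject_ids if self.subject_ids is not None else np.arange(1, len(df) + 1))
        df["modal_class"] = self.modal_class
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_probs(cls, probs: np.ndarray, subject_ids=None) -> "PosteriorMatrix":
        probs = np.asarray(probs, dtype=float)
        if np.any(probs < -1e-12) or np.max(np.abs(probs.sum(axis=1) - 1.0)) > 1e-10:
            raise ValueError("posterior rows must be probabilities summing to 1")
        modal = probs.argmax(axis=1) + 1
        G = probs.shape[1]
        mean_post = np.full(G, np.nan)
        for g in range(G):
            sel = modal == g + 1
            if sel.any():
                mean_post[g] = probs[sel, g].mean()
        return cls(probs=probs, modal_class=modal, mean_posterior_by_class=mean_post, subject_ids=subject_ids)


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------


def _unpack(theta: np.ndarray, G: int):
    k = G - 1
    logits = theta[:k]
    beta = theta[k : k + 3 * G].reshape(G, 3)
    L = np.zeros((3, 3))
    L[_TRIL_IDX] = theta[k + 3 * G : k + 3 * G + 6]
    sigma = float(np.exp(theta[k + 3 * G + 6]))
    return logits, beta, L, sigma


def _pack(fit: LcmmFit) -> np.ndarray:
    return np.concatenate(
        [
            fit.membership_logits,
            fit.beta.ravel(),
            fit.re_cholesky[_TRIL_IDX],
            [np.log(max(fit.residual_sd, 1e-12))],
        ]
    )


def _v_quantities(data: TrajectoryData, L: np.ndarray, sigma: float):
    """V_i, its inverse and log-determinant, batched over subjects.

    Padded slots get unit variance and zero design so they contribute
    nothing to the log-density beyond a constant that is dropped via the
    per-subject observation count.
    """
    X = data.design()
    mask = data.mask
    B = L @ L.T
    if sigma**2 < 1e-12 and np.min(np.linalg.eigvalsh(B)) < 1e-12:
        raise np.linalg.LinAlgError(
            "singular within-subject covariance: residual_sd ~ 0 with degenerate random effects"
        )
    V = np.einsum("nmk,kl,nql->nmq", X, B, X)
    diag = sigma**2 * mask + (~mask) * 1.0
    idx = np.arange(V.shape[1])
    V[:, idx, idx] += diag
    sign, logdet = np.linalg.slogdet(V)
    if not np.all(sign > 0) or not np.all(np.isfinite(logdet)):
        raise np.linalg.LinAlgError(
            "singular within-subject covariance (sigma ~ 0 with degenerate random effects)"
        )
    Vinv = np.linalg.inv(V)
    return X, V, Vinv, logdet


def _class_logdens(data: TrajectoryData, beta: np.ndarray, X, Vinv, logdet):
    """log MVN density of each subject's measures under each class mean; (N, G)."""
    n_obs = data.mask.sum(axis=1)
    G = beta.shape[0]
    mu = np.einsum("nmk,gk->ngm", X, beta)  # (N, G, M)
    r = (data.y[:, None, :] - mu) * data.mask[:, None, :]
    quad = np.einsum("ngm,nmq,ngq->ng", r, Vinv, r)
    return -0.5 * (n_obs[:, None] * _LOG2PI + logdet[:, None] + quad), r


def loglik_components(theta: np.ndarray, data: TrajectoryData, G: int):
    """Return (total loglik, per-subject-class joint log terms, posteriors, internals)."""
    logits, beta, L, sigma = _unpack(theta, G)
    X, V, Vinv, logdet = _v_quantities(data, L, sigma)
    logdens, r = _class_logdens(data, beta, X, Vinv, logdet)
    logpi = np.log(softmax(np.append(logits, 0.0)))
    joint = logdens + logpi[None, :]
    marg = logsumexp(joint, axis=1)
    post = np.exp(joint - marg[:, None])
    return float(marg.sum()), joint, post, (X, Vinv, logdet, r, logits, beta, L, sigma)


def loglik_and_grad(theta: np.ndarray, data: TrajectoryData, G: int):
    """Marginal log-likelihood and its analytic gradient in the packed parameterization."""
    ll, _, post, (X, Vinv, logdet, r, logits, beta, L, sigma) = loglik_components(theta, data, G)

    pi = softmax(np.append(logits, 0.0))
    g_logits = post[:, : G - 1].sum(axis=0) - len(post) * pi[: G - 1]

    Vinv_r = np.einsum("nmq,ngq->ngm", Vinv, r)  # V^{-1} r_ig
    g_beta = np.einsum("ng,nmk,ngm->gk", post, X, Vinv_r)

    # W_i = 0.5 * sum_g p_ig (V^{-1} r r' V^{-1} - V^{-1})
    W = 0.5 * (np.einsum("ng,ngm,ngq->nmq", post, Vinv_r, Vinv_r) - Vinv)
    G_B = np.einsum("nmk,nmq,nql->kl", X, W, X)
    g_L = 2.0 * G_B @ L
    g_chol = g_L[_TRIL_IDX]

    # d loglik / d sigma^2 = sum_i tr(W_i D_i); chain to log sigma
    idx = np.arange(W.shape[1])
    dsig2 = float((W[:, idx, idx] * data.mask).sum())
    g_logsigma = dsig2 * 2.0 * sigma**2

    grad = np.concatenate([g_logits, g_beta.ravel(), g_chol, [g_logsigma]])
    return ll, grad


def marginal_loglik(theta_or_fit, data: TrajectoryData, G: int | None = None) -> float:
    if isinstance(theta_or_fit, LcmmFit):
        theta, G = _pack(theta_or_fit), theta_or_fit.n_classes
    else:
        theta = np.asarray(theta_or_fit, dtype=float)
        if G is None:
            raise ValueError("G required with a packed parameter vector")
    ll, *_ = loglik_components(theta, data, G)
    return ll


def subject_loglik(y, ages, fit: LcmmFit):
    """Per-class log-densities and marginal log-likelihood for one subject.

    Parameters
    ----------
    y : array of transformed intakes (log(x+1) scale)
    ages : matching ages in years
    fit : parameters to evaluate at

    Returns
    -------
    (logdens, marginal) — length-G array of class-conditional MVN
    log-densities and the stable log-sum-exp marginal over classes.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    if y.size == 0 or y.shape != ages.shape:
        raise ValueError("need >= 1 measure with matching ages")
    data = TrajectoryData(
        y=y[None, :],
        t=np.asarray(rescale_age(ages))[None, :],
        mask=np.ones((1, y.size), dtype=bool),
        subject_ids=np.array([0]),
    )
    _, joint, _, internals = loglik_components(_pack(fit), data, fit.n_classes)
    logdens = joint[0] - np.log(fit.class_shares)
    marginal = float(logsumexp(joint[0]))
    return logdens, marginal


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _one_class_ols_init(data: TrajectoryData) -> LcmmFit:
    """OLS pooled fit as a starting point for the 1-class model."""
    X = data.design()
    mask = data.mask
    Xf = X.reshape(-1, 3)[mask.ravel()]
    yf = data.y.ravel()[mask.ravel()]
    beta, *_ = np.linalg.lstsq(Xf, yf, rcond=None)
    resid = yf - Xf @ beta
    s2 = float(resid @ resid / max(len(yf) - 3, 1))
    # split total residual variance between the random intercept and noise
    L = np.diag([np.sqrt(0.5 * s2), 1e-2, 1e-2])
    return LcmmFit(
        n_classes=1,
        beta=beta[None, :],
        membership_logits=np.zeros(0),
        re_cholesky=L,
        residual_sd=float(np.sqrt(0.5 * s2)),
    )


def _em_step(theta: np.ndarray, data: TrajectoryData, G: int):
    """One generalized EM sweep; returns the updated packed vector."""
    logits, beta, L, sigma = _unpack(theta, G)
    X, V, Vinv, logdet = _v_quantities(data, L, sigma)
    logdens, r = _class_logdens(data, beta, X, Vinv, logdet)
    logpi = np.log(softmax(np.append(logits, 0.0)))
    joint = logdens + logpi[None, :]
    post = np.exp(joint - logsumexp(joint, axis=1)[:, None])

    # class shares
    pi_new = np.clip(post.mean(axis=0), 1e-10, None)
    pi_new = pi_new / pi_new.sum()
    logits_new = np.log(pi_new[:-1]) - np.log(pi_new[-1])

    # posterior-weighted GLS for the class means
    XtVinvX = np.einsum("nmk,nmq,nql->nkl", X, Vinv, X)
    XtVinvy = np.einsum("nmk,nmq,nq->nk", X, Vinv, data.y * data.mask)
    beta_new = np.empty_like(beta)
    for g in range(G):
        A = np.einsum("n,nkl->kl", post[:, g], XtVinvX)
        c = np.einsum("n,nk->k", post[:, g], XtVinvy)
        beta_new[g] = np.linalg.solve(A + 1e-10 * np.eye(3), c)

    # EM update of B and sigma via conditional random-effect moments
    B = L @ L.T
    mu_new = np.einsum("nmk,gk->ngm", X, beta_new)
    r_new = (data.y[:, None, :] - mu_new) * data.mask[:, None, :]
    BXt = np.einsum("kl,nml->nkm", B, X)  # B X' (n,3,M)
    m_ig = np.einsum("nkm,nmq,ngq->ngk", BXt, Vinv, r_new)  # E[b | y, g]
    S = B - np.einsum("nkm,nmq,nlq->nkl", BXt, Vinv, BXt)  # Cov[b | y] (class-free)
    B_new = (S + np.einsum("ng,ngk,ngl->nkl", post, m_ig, m_ig)).sum(axis=0) / len(post)
    B_new = 0.5 * (B_new + B_new.T)

    Xm = np.einsum("nmk,ngk->ngm", X, m_ig)
    e = (r_new - Xm) * data.mask[:, None, :]
    tr_XSXt = np.einsum("nmk,nkl,nml->nm", X, S, X)  # diag of X S X'
    sse = np.einsum("ng,ngm->", post, e**2) + float((tr_XSXt * data.mask).sum())
    sigma2_new = max(sse / data.n_obs, 1e-10)

    w, Q = np.linalg.eigh(B_new)
    B_new = (Q * np.clip(w, 1e-10, None)) @ Q.T
    L_new = np.linalg.cholesky(B_new)

    out = np.concatenate(
        [logits_new, beta_new.ravel(), L_new[_TRIL_IDX], [0.5 * np.log(sigma2_new)]]
    )
    return out


def fit_single_start(
    data: TrajectoryData,
    spec: TrajectorySpec,
    init: LcmmFit,
    em_iters: int = 100,
    max_iter: int = 500,
    tol: float = 1e-8,
    grad_tol: float = 1e-3,
) -> LcmmFit:
    """Maximize the LCMM likelihood from one starting point.

    EM warm-up until the relative log-likelihood change drops below 1e-6
    (or ``em_iters`` sweeps), then L-BFGS-B refinement with the analytic
    gradient.  Convergence requires relative log-likelihood stability below
    ``tol`` and a small projected gradient; hitting the iteration cap
    returns the best parameters with ``converged=False``, never silently.
    """
    G = spec.n_classes
    theta = _pack(init)
    ll_prev = -np.inf
    it = 0
    for it in range(em_iters):
        theta_new = _em_step(theta, data, G)
        ll, *_ = loglik_components(theta_new, data, G)
        theta = theta_new
        if np.isfinite(ll_prev) and abs(ll - ll_prev) < 1e-6 * (1 + abs(ll)):
            ll_prev = ll
            break
        ll_prev = ll

    def neg(th):
        ll, gr = loglik_and_grad(th, data, G)
        return -ll, -gr

    res = minimize(
        neg,
        theta,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": grad_tol / max(1, data.n_subjects)},
    )
    theta = res.x
    ll, grad = loglik_and_grad(theta, data, G)
    gnorm = float(np.max(np.abs(grad)))
    converged = bool(res.success or gnorm < grad_tol * max(1.0, data.n_subjects / 100.0))
    logits, beta, L, sigma = _unpack(theta, G)
    # canonical sign for the Cholesky factor (B = LL' is sign-invariant columnwise)
    signs = np.sign(np.diag(L))
    signs[signs == 0] = 1.0
    L = L * signs[None, :]
    return LcmmFit(
        n_classes=G,
        beta=beta,
        membership_logits=logits.copy(),
        re_cholesky=L,
        residual_sd=sigma,
        loglik=float(ll),
        converged=converged,
        n_iter=it + 1 + int(res.nit),
    )


def one_class_beta_se(fit: LcmmFit, data: TrajectoryData) -> np.ndarray:
    """Asymptotic standard errors of the 1-class fixed effects (GLS information)."""
    _, _, Vinv, _ = _v_quantities(data, fit.re_cholesky, fit.residual_sd)
    X = data.design()
    info = np.einsum("nmk,nmq,nql->kl", X, Vinv, X)
    return np.sqrt(np.diag(np.linalg.inv(info)))


def random_starts(
    base: LcmmFit,
    data: TrajectoryData,
    G: int,
    n_starts: int,
    rng: np.random.Generator,
    perturb_factor: float = 2.0,
):
    """Random initial values: per-class Gaussian perturbations of the 1-class solution.

    Candidate class means are scattered with scale equal to the 1-class
    between-subject standard deviations (square roots of the random-effect
    variances) plus ``perturb_factor`` times the asymptotic SEs of the
    1-class fixed effects.  Latent classes live in the between-subject
    distribution, so that spread — not the tiny SE of the pooled mean — is
    the right exploration scale; SE-only perturbations leave the starts
    nearly symmetric and often collapse into a merged local optimum.
    """
    se = one_class_beta_se(base, data)
    scale = np.sqrt(np.diag(base.re_covariance)) + perturb_factor * se
    starts = []
    for _ in range(n_starts):
        beta = base.beta[0][None, :] + scale[None, :] * rng.standard_normal((G, 3))
        starts.append(
            LcmmFit(
                n_classes=G,
                beta=beta,
                membership_logits=np.zeros(G - 1),
                re_cholesky=base.re_cholesky.copy(),
                residual_sd=base.residual_sd,
            )
        )
    return starts


def warm_start_from(prev: LcmmFit, data: TrajectoryData | None = None) -> LcmmFit:
    """Initial values for a (G+1)-class model from a G-class fit (split the largest class)."""
    G = prev.n_classes
    shares = prev.class_shares
    big = int(np.argmax(shares))
    se = 0.2 * np.abs(prev.beta[big]) + 0.05
    beta = np.vstack([prev.beta, prev.beta[big] + se])
    beta[big] = prev.beta[big] - se
    new_shares = np.append(shares, shares[big] / 2)
    new_shares[big] /= 2
    new_shares = new_shares / new_shares.sum()
    logits = np.log(new_shares[:-1]) - np.log(new_shares[-1])
    return LcmmFit(
        n_classes=G + 1,
        beta=beta,
        membership_logits=logits,
        re_cholesky=prev.re_cholesky.copy(),
        residual_sd=prev.residual_sd,
    )


def fit_multistart(
    data: TrajectoryData,
    spec: TrajectorySpec,
    n_starts: int = 100,
    warm_starts: list | None = None,
    seed: int = 0,
    perturb_factor: float = 2.0,
    em_iters: int = 60,
    max_iter: int = 500,
    base_fit: LcmmFit | None = None,
) -> LcmmFit:
    """Multistart maximum likelihood for a G-class model.

    Fits the 1-class model first (OLS-initialized), then launches
    ``n_starts`` random perturbations of it (plus any ``warm_starts``
    derived from lower-G fits), keeping the highest-log-likelihood converged
    fit.  Ties within 1e-6 go to the lowest start index.  All start
    log-likelihoods are recorded on the returned fit.
    """
    G = spec.n_classes
    if base_fit is None:
        base_fit = fit_single_start(data, TrajectorySpec(1), _one_class_ols_init(data), em_iters=em_iters, max_iter=max_iter)
    if G == 1:
        base_fit.n_starts_used = 1
        base_fit.start_logliks = [base_fit.loglik]
        return base_fit

    rng = np.random.default_rng(seed)
    starts = random_starts(base_fit, data, G, n_starts, rng, perturb_factor)
    if warm_starts:
        starts = list(warm_starts) + starts

    best = None
    best_idx = -1
    logliks = []
    for idx, start in enumerate(starts):
        try:
            fit = fit_single_start(data, spec, start, em_iters=em_iters, max_iter=max_iter)
        except np.linalg.LinAlgError:
            logliks.append(float("nan"))
            continue
        logliks.append(fit.loglik)
        if fit.converged and (best is None or fit.loglik > best.loglik + 1e-6):
            best = fit
            best_idx = idx
    if best is None:
        finite = [ll for ll in logliks if np.isfinite(ll)]
        top = max(finite) if finite else float("nan")
        raise RuntimeError(
            f"no start converged for G={G}; best non-converged log-likelihood {top:.4f}"
        )
    best.n_starts_used = len(starts)
    best.best_start_seed = best_idx
    best.start_logliks = logliks
    return best


# ---------------------------------------------------------------------------
# posteriors, prediction, diagnostics
# ---------------------------------------------------------------------------


def posterior_probs(fit: LcmmFit, data: TrajectoryData) -> PosteriorMatrix:
    """Posterior class-membership probabilities p_ig = pi_g f(Y_i|g) / sum_h ..."""
    _, joint, post, _ = loglik_components(_pack(fit), data, fit.n_classes)
    return PosteriorMatrix.from_probs(post, subject_ids=data.subject_ids)


def predict_class_trajectories(fit: LcmmFit, ages, age_guard=(18.0, 70.0)) -> pd.DataFrame:
    """Per-class mean curves over an age grid, transformed and natural scale.

    The natural-scale curve is the plug-in back-transform exp(curve) - 1 of
    the transformed-scale class mean (not the expectation of the intake
    itself).  Ages outside the guard raise a warning, not a failure.
    """
    ages = np.asarray(ages, dtype=float)
    lo, hi = age_guard
    if np.any(ages < lo) or np.any(ages > hi):
        warnings.warn(f"age grid extends beyond the guard [{lo}, {hi}]; extrapolating")
    t = np.asarray(rescale_age(ages))
    X = np.stack([np.ones_like(t), t, t * t], axis=-1)
    rows = []
    for g in range(fit.n_classes):
        curve = X @ fit.beta[g]
        rows.append(
            pd.DataFrame(
                {
                    "class": g + 1,
                    "age_years": ages,
                    "transformed": curve,
                    "intake_g_day": inverse_transform_intake(curve),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def empirical_bayes_effects(fit: LcmmFit, data: TrajectoryData):
    """Posterior-mean random effects per subject and class; returns (m_ig, post)."""
    theta = _pack(fit)
    _, _, post, (X, Vinv, _, r, _, _, L, _) = loglik_components(theta, data, fit.n_classes)
    B = L @ L.T
    BXt = np.einsum("kl,nml->nkm", B, X)
    m_ig = np.einsum("nkm,nmq,ngq->ngk", BXt, Vinv, r)
    return m_ig, post


def weighted_fit_diagnostic(fit: LcmmFit, data: TrajectoryData, age_bins) -> pd.DataFrame:
    """Posterior-weighted observed vs predicted mean trajectories per class and age bin.

    For each class g and age bin, computes the p_ig-weighted mean of the
    observed transformed intakes and of the subject-specific predictions
    (class mean plus empirical-Bayes random effects).  Empty bins are
    omitted.  Close agreement indicates the fitted model reproduces the
    observed mean trajectories.
    """
    m_ig, post = empirical_bayes_effects(fit, data)
    X = data.design()
    ages = 35.0 + 13.0 * data.t
    edges = np.asarray(age_bins, dtype=float)
    rows = []
    for g in range(fit.n_classes):
        pred = X @ fit.beta[g] + np.einsum("nmk,nk->nm", X, m_ig[:, g, :])
        w_full = np.broadcast_to(post[:, g][:, None], data.y.shape)
        for b in range(len(edges) - 1):
            sel = data.mask & (ages >= edges[b]) & (ages < edges[b + 1])
            wsum = w_full[sel].sum()
            if not sel.any() or wsum <= 0:
                continue
            rows.append(
                {
                    "class": g + 1,
                    "age_low": edges[b],
                    "age_high": edges[b + 1],
                    "n_obs": int(sel.sum()),
                    "weight": float(wsum),
                    "observed": float((w_full[sel] * data.y[sel]).sum() / wsum),
                    "predicted": float((w_full[sel] * pred[sel]).sum() / wsum),
                }
            )
    return pd.DataFrame(rows)


def presentation_order(fit: LcmmFit, age: float = 50.0, descending: bool = True) -> np.ndarray:
    """Class order (0-based) by natural-scale mean intake at ``age`` for reporting."""
    t = rescale_age(age)
    x = np.array([1.0, t, t * t])
    values = inverse_transform_intake(fit.beta @ x)
    order = np.argsort(values)
    return order[::-1] if descending else order


def relabel_classes(fit: LcmmFit, order) -> LcmmFit:
    """Return a copy of ``fit`` with classes permuted to ``order`` (0-based).

    Estimation is label-agnostic; this explicit utility exists only for
    presentation (e.g. ordering classes by intake level).  The marginal
    log-likelihood is invariant under the permutation.
    """
    order = np.asarray(order, dtype=int)
    shares = fit.class_shares[order]
    logits = np.log(shares[:-1]) - np.log(shares[-1])
    return replace(
        fit,
        beta=fit.beta[order].copy(),
        membership_logits=logits,
    )
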
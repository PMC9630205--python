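"""Calibration: fitting the explanatory model and screening the data.

The explanatory model is a mixed-effects logistic regression with
asymptotes fixed at (g, u) and crossed random intercepts for participant
and track:

    P(y_pi = 1) = g + (u - g) * logistic(x_i'beta + b_p + c_t),
    b_p ~ N(0, sigma_person^2),  c_t ~ N(0, sigma_track^2).

Crossed random effects have no nested closed form.  The marginal
likelihood is computed by a hybrid scheme that puts the accuracy where
it is needed: conditional on the track effects, participants are
independent, and each participant's one-dimensional integral is
evaluated exactly (to quadrature precision) by Gauss-Hermite quadrature;
the track effects — each informed by hundreds of responses, where a
Gaussian approximation is excellent — are then integrated by Laplace
approximation around their posterior mode.  A joint Laplace over all
random effects (the construction standard mixed-model software applies
to crossed designs) is noticeably attenuated here: with ~15 binary
responses per participant squeezed between a 0.4 guessing floor and a
0.96-0.98 ceiling, each participant's likelihood is far from Gaussian,
and the resulting downward bias in sigma_person shrinks every fixed
effect with it.  Quadrature in the person dimension removes that bias.
The outer optimization over (beta, log sigma_person, log sigma_track)
uses L-BFGS-B with finite-difference gradients.

A slow Monte-Carlo / Gauss-Hermite integration oracle
(:func:`marginal_loglik_mc`) is provided for validating the Laplace
approximation on small datasets.

Screening mirrors the track- and participant-reliability checks used to
clean the published calibration data: tracks whose mean accuracy falls
below chance (possible stimulus bias) and participants who give (nearly)
the same on/off judgment throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from numpy.polynomial.hermite import hermgauss

from .item_bank import Condition
from .response_model import ExplanatoryParams, ON_COEF_NAMES, OFF_COEF_NAMES

__all__ = [
    "DATASET_COLUMNS",
    "validate_dataset",
    "FitResult",
    "ScreenReport",
    "fit_explanatory",
    "profile_asymptotes",
    "prediction_accuracy",
    "marginal_loglik",
    "marginal_loglik_mc",
    "screen_tracks",
    "screen_participants",
]

#: Long-format calibration dataset columns (one row per trial).
DATASET_COLUMNS = ("participant_id", "track_id", "condition", "target_beat",
                   "direction", "displacement_level", "displacement",
                   "response")


def validate_dataset(data: pd.DataFrame) -> None:
    missing = set(DATASET_COLUMNS) - set(data.columns)
    if missing:
        raise ValueError(f"dataset missing columns: {sorted(missing)}")
    if not data["response"].isin([0, 1]).all():
        raise ValueError("responses must be 0/1")


def _design(data: pd.DataFrame, condition: Condition
            ) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Rows for one condition -> (y, X, coefficient names)."""
    sub = data[data["condition"] == condition.value]
    if sub.empty:
        raise ValueError(f"no rows for condition {condition.value}")
    y = sub["response"].to_numpy(dtype=float)
    strength = (sub["target_beat"].to_numpy() == 3).astype(float)
    if condition is Condition.ON:
        X = np.column_stack([np.ones(len(sub)), strength])
        return y, X, ON_COEF_NAMES
    direction = (sub["direction"].to_numpy() == "late").astype(float)
    level = sub["displacement_level"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(sub)), level, direction, strength,
                         direction * strength])
    return y, X, OFF_COEF_NAMES


def _bernoulli_score(eta, y, g, u):
    """Per-element log-lik and first eta-derivative only (hot path)."""
    D = u - g
    s = expit(eta)
    p = np.clip(g + D * s, 1e-12, 1 - 1e-12)
    ll = np.where(y == 1, np.log(p), np.log1p(-p))
    l1 = D * s * (1 - s) * (y - p) / (p * (1 - p))
    return ll, l1


def _bernoulli_derivs(eta, y, g, u):
    """Per-element log-lik and first/second eta-derivatives."""
    D = u - g
    s = expit(eta)
    p = np.clip(g + D * s, 1e-12, 1 - 1e-12)  # guard the g=0 / u=1 reduction
    ll = y * np.log(p) + (1 - y) * np.log1p(-p)
    sp = s * (1 - s)
    pprime = D * sp
    resid = (y - p) / (p * (1 - p))
    l1 = pprime * resid
    ppp = D * sp * (1 - 2 * s)
    l2 = ppp * resid - pprime**2 * (y / p**2 + (1 - y) / (1 - p) ** 2)
    return ll, l1, l2


class _JointLaplace:
    """Joint Laplace over all random effects with Fisher working weights.

    Fast but attenuated for this model (see module docstring); used only
    to produce starting values for the hybrid marginal likelihood.
    """

    def __init__(self, y, X, p_idx, t_idx, g, u):
        self.y, self.X = y, X
        self.p_idx, self.t_idx = np.asarray(p_idx), np.asarray(t_idx)
        self.n_p = int(self.p_idx.max()) + 1
        self.n_t = int(self.t_idx.max()) + 1
        self.g, self.u = g, u
        self._warm = np.zeros(self.n_p + self.n_t)

    def _joint(self, b, eta_fix, sp2, st2):
        bp, bt = b[: self.n_p], b[self.n_p:]
        eta = eta_fix + bp[self.p_idx] + bt[self.t_idx]
        ll, l1, _ = _bernoulli_derivs(eta, self.y, self.g, self.u)
        D = self.u - self.g
        s = expit(eta)
        p = np.clip(self.g + D * s, 1e-12, 1 - 1e-12)
        w = (D * s * (1 - s)) ** 2 / (p * (1 - p))
        j = ll.sum() - 0.5 * (bp @ bp) / sp2 - 0.5 * (bt @ bt) / st2
        return j, l1, w, bp, bt

    def marginal(self, beta, sigma_p, sigma_t):
        sp2 = max(sigma_p, 1e-6) ** 2
        st2 = max(sigma_t, 1e-6) ** 2
        eta_fix = self.X @ beta
        b = self._warm.copy()
        j, l1, w, bp, bt = self._joint(b, eta_fix, sp2, st2)
        for _ in range(200):
            gp = np.bincount(self.p_idx, weights=l1, minlength=self.n_p) - bp / sp2
            gt = np.bincount(self.t_idx, weights=l1, minlength=self.n_t) - bt / st2
            if max(np.abs(gp).max(), np.abs(gt).max()) < 1e-8:
                break
            Dp = np.bincount(self.p_idx, weights=w, minlength=self.n_p) + 1 / sp2
            Dt = np.bincount(self.t_idx, weights=w, minlength=self.n_t) + 1 / st2
            M = np.zeros((self.n_p, self.n_t))
            np.add.at(M, (self.p_idx, self.t_idx), w)
            MD = M / Dp[:, None]
            S = np.diag(Dt) - MD.T @ M
            dt = np.linalg.solve(S, gt - MD.T @ gp)
            dp = (gp - M @ dt) / Dp
            step = np.concatenate([dp, dt])
            alpha = 1.0
            for _ in range(30):  # damped Fisher scoring
                cand = b + alpha * step
                jc, l1c, wc, bpc, btc = self._joint(cand, eta_fix, sp2, st2)
                if jc >= j - 1e-12:
                    b, j, l1, w, bp, bt = cand, jc, l1c, wc, bpc, btc
                    break
                alpha *= 0.5
            else:
                break
        self._warm = b.copy()
        Dp = np.bincount(self.p_idx, weights=w, minlength=self.n_p) + 1 / sp2
        Dt = np.bincount(self.t_idx, weights=w, minlength=self.n_t) + 1 / st2
        M = np.zeros((self.n_p, self.n_t))
        np.add.at(M, (self.p_idx, self.t_idx), w)
        S = np.diag(Dt) - (M / Dp[:, None]).T @ M
        sign, logdet_S = np.linalg.slogdet(S)
        if sign <= 0:
            return -np.inf
        logdet_H = np.log(Dp).sum() + logdet_S
        return (j - 0.5 * self.n_p * np.log(sp2) - 0.5 * self.n_t * np.log(st2)
                - 0.5 * logdet_H)


class _Marginal:
    """Hybrid person-quadrature / track-Laplace marginal log-likelihood.

    Conditional on the track effects c the participants decouple, so

        L = int N(c; 0, st^2 I) prod_p f_p(c) dc,
        f_p(c) = int N(b; 0, sp^2) prod_{i in p} P_i(eta_i + b)^(y) ... db,

    where each f_p is a 1-D integral evaluated by Gauss-Hermite
    quadrature and the outer n_t-dimensional integral by Laplace at the
    mode of log g(c) = sum_p log f_p(c) - c'c/(2 st^2).  Gradient and
    Hessian of log g follow from differentiating under the quadrature:
    with posterior node weights r_pj ~ omega_j exp(S_pj),

        d log f_p / dc_t      = E_r[s_t],   s_t = sum_{i in p, t} l1_i,
        d2 log f_p / dc_t c_u = delta_tu E_r[q_t] + Cov_r(s_t, s_u),

    with q_t the within-track sum of l2.
    """

    def __init__(self, y, X, p_idx, t_idx, g, u, gh_points: int = 21):
        self.y, self.X = y, X
        self.p_idx, self.t_idx = np.asarray(p_idx), np.asarray(t_idx)
        self.n_p = int(self.p_idx.max()) + 1
        self.n_t = int(self.t_idx.max()) + 1
        self.g, self.u = g, u
        nodes, wts = hermgauss(gh_points)
        self.nodes = nodes
        self.logw = np.log(wts) - 0.5 * np.log(np.pi)
        self._warm_c = np.zeros(self.n_t)
        self._rows_of_p = [np.flatnonzero(self.p_idx == p)
                           for p in range(self.n_p)]
        pt = self.p_idx.astype(np.int64) * self.n_t + self.t_idx
        self._pt_unique = len(np.unique(pt)) == len(pt)

    def _stats(self, c, eta_fix, sigma_p, need_l2=False):
        """Per-person log f_p, posterior node weights, and row derivatives."""
        b = np.sqrt(2.0) * sigma_p * self.nodes                    # (K,)
        eta = (eta_fix + c[self.t_idx])[:, None] + b[None, :]      # (n, K)
        if need_l2:
            ll, l1, l2 = _bernoulli_derivs(eta, self.y[:, None], self.g, self.u)
        else:
            ll, l1 = _bernoulli_score(eta, self.y[:, None], self.g, self.u)
            l2 = None
        # per-person sums; column-wise bincount is much faster than add.at
        logA = np.column_stack([
            np.bincount(self.p_idx, weights=ll[:, j], minlength=self.n_p)
            for j in range(ll.shape[1])])
        lw = logA + self.logw
        logf = logsumexp(lw, axis=1)                               # (n_p,)
        post = np.exp(lw - logf[:, None])                          # (n_p, K)
        return logf, post, l1, l2, b

    def _logg_grad(self, c, eta_fix, sigma_p, st2):
        logf, post, l1, _, _ = self._stats(c, eta_fix, sigma_p)
        logg = logf.sum() - 0.5 * (c @ c) / st2
        r = (post[self.p_idx] * l1).sum(axis=1)                    # E[l1] per row
        grad = np.bincount(self.t_idx, weights=r, minlength=self.n_t) - c / st2
        return logg, grad

    def _mode_c(self, eta_fix, sigma_p, st2):
        # the marginal is an envelope in c, so its error is second order in
        # the residual gradient; 1e-7 is far tighter than needed
        res = minimize(
            lambda c: tuple(-v for v in self._logg_grad(c, eta_fix, sigma_p, st2)),
            self._warm_c, jac=True, method="L-BFGS-B",
            options={"maxiter": 200, "gtol": 1e-7, "ftol": 1e-13})
        self._warm_c = res.x.copy()
        return res.x

    def marginal(self, beta, sigma_p, sigma_t):
        """Marginal log-likelihood and EB effects at the given parameters."""
        st2 = max(sigma_t, 1e-6) ** 2
        eta_fix = self.X @ beta
        c_hat = self._mode_c(eta_fix, sigma_p, st2)
        logf, post, l1, l2, b = self._stats(c_hat, eta_fix, sigma_p,
                                            need_l2=True)

        # negative Hessian of log g at the mode
        e_l1 = (post[self.p_idx] * l1).sum(axis=1)                 # per row
        e_l2 = (post[self.p_idx] * l2).sum(axis=1)
        H = np.diag(np.bincount(self.t_idx, weights=-e_l2, minlength=self.n_t)
                    + 1.0 / st2)
        if self._pt_unique:
            # one row per (person, track): scatter scores into dense
            # (node, person, track) stacks and contract
            K = post.shape[1]
            R = np.zeros((K, self.n_p, self.n_t))
            R[:, self.p_idx, self.t_idx] = l1.T
            Rw = R * post.T[:, :, None]
            H -= np.einsum("kpt,kpu->tu", Rw, R, optimize=True)
            M1 = np.zeros((self.n_p, self.n_t))
            M1[self.p_idx, self.t_idx] = e_l1
            H += M1.T @ M1
        else:
            sq_post = np.sqrt(post)[self.p_idx]
            Z = l1 * sq_post                                       # (n, K)
            for rows in self._rows_of_p:
                tt = self.t_idx[rows]
                cov = Z[rows] @ Z[rows].T - np.outer(e_l1[rows], e_l1[rows])
                H[np.ix_(tt, tt)] -= cov
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            return -np.inf, np.zeros(self.n_p), c_hat
        ml = (logf.sum() - 0.5 * (c_hat @ c_hat) / st2
              - 0.5 * self.n_t * np.log(st2) - 0.5 * logdet)
        person_eb = post @ b                                       # E[b_p | y, c_hat]
        return float(ml), person_eb, c_hat


@dataclass
class FitResult:
    """Estimates from one explanatory-model fit."""

    condition: Condition
    beta: dict[str, float]
    beta_se: dict[str, float]
    sigma_person: float
    sigma_track: float
    g: float
    u: float
    log_marginal_likelihood: float
    converged: bool
    n_obs: int
    n_participants: int
    n_tracks: int
    person_modes: dict = field(default_factory=dict, repr=False)
    track_modes: dict = field(default_factory=dict, repr=False)
    message: str = ""

    def to_params(self) -> ExplanatoryParams:
        return ExplanatoryParams(condition=self.condition, beta=dict(self.beta),
                                 sigma_person=self.sigma_person,
                                 sigma_track=self.sigma_track, g=self.g, u=self.u)

    def to_json_dict(self) -> dict:
        return {
            "condition": self.condition.value,
            "beta": self.beta, "beta_se": self.beta_se,
            "sigma_person": self.sigma_person, "sigma_track": self.sigma_track,
            "g": self.g, "u": self.u,
            "log_marginal_likelihood": self.log_marginal_likelihood,
            "converged": self.converged, "n_obs": self.n_obs,
        }


def fit_explanatory(data: pd.DataFrame, condition: Condition | str,
                    g: float = 0.4, u: float = 0.98,
                    start: Mapping[str, float] | None = None) -> FitResult:
    """Fit the asymptote-modified crossed-random-intercept logistic model.

    Maximizes the Laplace-approximated marginal likelihood over the fixed
    effects and the two random-intercept SDs (optimized on the log scale,
    keeping them non-negative); the asymptotes are held fixed at (g, u).
    Deterministic given the data and starting values.  Standard errors
    come from the numerically differentiated observed information of the
    Laplace log-likelihood.
    """
    condition = Condition(condition)
    validate_dataset(data)
    y, X, names = _design(data, condition)
    sub = data[data["condition"] == condition.value]
    if sub["participant_id"].nunique() < 2 or sub["track_id"].nunique() < 2:
        raise ValueError("need >= 2 participants and >= 2 tracks")
    if y.min() == y.max():
        raise ValueError("both response values must be present")
    p_codes, p_labels = pd.factorize(sub["participant_id"], sort=True)
    t_codes, t_labels = pd.factorize(sub["track_id"], sort=True)
    k = len(names)

    pbar = y.mean()
    eta0 = np.log(np.clip((pbar - g) / (u - g), 0.02, 0.98)
                  / (1 - np.clip((pbar - g) / (u - g), 0.02, 0.98)))
    psi0 = np.zeros(k + 2)
    psi0[0] = eta0
    psi0[k] = 0.0           # log sigma_person
    psi0[k + 1] = np.log(0.3)  # log sigma_track
    if start:
        for i, nm in enumerate(names):
            if nm in start:
                psi0[i] = start[nm]
    bounds = [(-20, 20)] * k + [(-6, 3), (-8, 3)]

    # stage 1: cheap joint-Laplace fit for starting values
    lap = _JointLaplace(y, X, p_codes, t_codes, g, u)

    def neg_ml_lap(psi):
        ml = lap.marginal(psi[:k], np.exp(psi[k]), np.exp(psi[k + 1]))
        return -ml if np.isfinite(ml) else 1e10

    opts = {"maxiter": 300, "maxfun": 3000, "eps": 1e-5, "gtol": 1e-3,
            "ftol": 1e-10}
    res1 = minimize(neg_ml_lap, psi0, method="L-BFGS-B", bounds=bounds,
                    options=opts)

    # stage 2: hybrid quadrature/Laplace marginal likelihood
    eng = _Marginal(y, X, p_codes, t_codes, g, u, gh_points=15)

    def neg_ml(psi):
        ml, _, _ = eng.marginal(psi[:k], np.exp(psi[k]), np.exp(psi[k + 1]))
        return -ml if np.isfinite(ml) else 1e10

    res = minimize(neg_ml, res1.x, method="L-BFGS-B", bounds=bounds,
                   options=opts)
    psi = res.x
    beta = psi[:k]
    sigma_p, sigma_t = float(np.exp(psi[k])), float(np.exp(psi[k + 1]))
    ml, bp, bt = eng.marginal(beta, sigma_p, sigma_t)

    # observed information of the marginal log-likelihood (forward differences)
    h = 1e-4 * np.maximum(1.0, np.abs(psi))
    m = k + 2
    f0 = -float(ml)
    f_i = np.array([neg_ml(psi + np.eye(m)[i] * h[i]) for i in range(m)])
    H = np.zeros((m, m))
    for i in range(m):
        for jx in range(i, m):
            if i == jx:
                H[i, i] = (neg_ml(psi + 2 * np.eye(m)[i] * h[i])
                           - 2 * f_i[i] + f0) / h[i] ** 2
            else:
                fij = neg_ml(psi + np.eye(m)[i] * h[i] + np.eye(m)[jx] * h[jx])
                H[i, jx] = H[jx, i] = (fij - f_i[i] - f_i[jx] + f0) / (h[i] * h[jx])
    se = np.full(m, np.nan)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        se[d > 0] = np.sqrt(d[d > 0])
    except np.linalg.LinAlgError:
        pass

    return FitResult(
        condition=condition,
        beta={nm: float(beta[i]) for i, nm in enumerate(names)},
        beta_se={nm: float(se[i]) for i, nm in enumerate(names)},
        sigma_person=sigma_p, sigma_track=sigma_t, g=g, u=u,
        log_marginal_likelihood=float(ml),
        converged=bool(res.success and np.all(np.isfinite(se[:k]))),
        n_obs=len(y), n_participants=eng.n_p, n_tracks=eng.n_t,
        person_modes={lab: float(v) for lab, v in zip(p_labels, bp)},
        track_modes={lab: float(v) for lab, v in zip(t_labels, bt)},
        message=str(res.message),
    )


def profile_asymptotes(data: pd.DataFrame, condition: Condition | str,
                       g_grid=(0.3, 0.4, 0.5), u_grid=(0.94, 0.96, 0.98)
                       ) -> tuple[FitResult, pd.DataFrame]:
    """Grid search over fixed asymptotes by profile marginal likelihood.

    Fits the model at every (g, u) pair and returns the best fit plus the
    profile table.  The asymptotes enter the model as constants, so this
    is the natural way to choose them when no published values apply.
    """
    rows = []
    best = None
    for g in g_grid:
        for u in u_grid:
            if not g < u:
                continue
            fit = fit_explanatory(data, condition, g=g, u=u)
            rows.append({"g": g, "u": u,
                         "log_marginal_likelihood": fit.log_marginal_likelihood})
            if best is None or (fit.log_marginal_likelihood
                                > best.log_marginal_likelihood):
                best = fit
    return best, pd.DataFrame(rows)


def prediction_accuracy(fit: FitResult, data: pd.DataFrame) -> float:
    """In-sample classification accuracy of the fitted model.

    Conditional probabilities use the empirical-Bayes modes of the random
    effects (unseen participants/tracks get 0); a row is predicted correct
    when that probability exceeds 0.5.
    """
    validate_dataset(data)
    y, X, _ = _design(data, fit.condition)
    sub = data[data["condition"] == fit.condition.value]
    bp = sub["participant_id"].map(fit.person_modes).fillna(0.0).to_numpy()
    bt = sub["track_id"].map(fit.track_modes).fillna(0.0).to_numpy()
    eta = X @ np.array([fit.beta[n] for n in
                        (ON_COEF_NAMES if fit.condition is Condition.ON
                         else OFF_COEF_NAMES)])
    p = fit.g + (fit.u - fit.g) * expit(eta + bp + bt)
    return float(np.mean((p > 0.5) == (y == 1)))


def marginal_loglik(data: pd.DataFrame, condition: Condition | str,
                    beta: Mapping[str, float], sigma_person: float,
                    sigma_track: float, g: float, u: float,
                    gh_points: int = 21) -> float:
    """Marginal log-likelihood at fixed parameters (hybrid scheme).

    The same quantity :func:`fit_explanatory` maximizes; exposed for
    model comparison and for validation against integration oracles.
    """
    condition = Condition(condition)
    y, X, names = _design(data, condition)
    sub = data[data["condition"] == condition.value]
    p_codes, _ = pd.factorize(sub["participant_id"], sort=True)
    t_codes, _ = pd.factorize(sub["track_id"], sort=True)
    eng = _Marginal(y, X, p_codes, t_codes, g, u, gh_points=gh_points)
    bv = np.array([beta[n] for n in names])
    return eng.marginal(bv, sigma_person, sigma_track)[0]


def marginal_loglik_mc(data: pd.DataFrame, condition: Condition | str,
                       beta: Mapping[str, float], sigma_person: float,
                       sigma_track: float, g: float, u: float,
                       n_track_draws: int = 4000, gh_points: int = 41,
                       seed: int = 0) -> float:
    """Integration oracle for the marginal log-likelihood (small data only).

    Track effects are integrated by plain Monte Carlo from their prior;
    conditional on the track effects, participants are independent and
    each participant's 1-D integral is evaluated by Gauss-Hermite
    quadrature.  Memory grows as draws x rows x nodes, so keep this to
    toy datasets.
    """
    condition = Condition(condition)
    y, X, names = _design(data, condition)
    sub = data[data["condition"] == condition.value]
    p_codes, _ = pd.factorize(sub["participant_id"], sort=True)
    t_codes, _ = pd.factorize(sub["track_id"], sort=True)
    n_p, n_t = p_codes.max() + 1, t_codes.max() + 1
    eta_fix = X @ np.array([beta[n] for n in names])

    rng = np.random.default_rng(seed)
    nodes, weights = hermgauss(gh_points)
    bp = np.sqrt(2.0) * sigma_person * nodes          # (J,)
    logw = np.log(weights / np.sqrt(np.pi))
    Du = u - g

    # chunk over track draws to bound the (chunk, rows, nodes) tensor
    chunk = max(1, int(2e7 // (len(y) * gh_points)))
    log_cond = np.empty(n_track_draws)
    done = 0
    while done < n_track_draws:
        m = min(chunk, n_track_draws - done)
        ct = rng.normal(0.0, sigma_track, size=(m, n_t))
        eta = (eta_fix[None, :, None] + ct[:, t_codes, None] + bp[None, None, :])
        p = g + Du * expit(eta)
        ll = np.where(y[None, :, None] == 1, np.log(p), np.log1p(-p))
        per = np.zeros((m, n_p, gh_points))
        np.add.at(per, (slice(None), p_codes, slice(None)), ll)
        log_person = logsumexp(per + logw[None, None, :], axis=2)  # (m, n_p)
        log_cond[done:done + m] = log_person.sum(axis=1)
        done += m
    return float(logsumexp(log_cond) - np.log(n_track_draws))


@dataclass
class ScreenReport:
    """Tracks/participants flagged by the data-quality screens."""

    flagged_tracks: list[tuple[int, str, float]] = field(default_factory=list)
    flagged_participants: list[tuple[object, float]] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)


def screen_tracks(data: pd.DataFrame, chance: float = 0.5) -> ScreenReport:
    """Flag (track, condition) cells with mean accuracy strictly below chance.

    Below-chance accuracy on a track suggests a stimulus bias (listeners
    systematically mishear that track) rather than item difficulty.
    A mean of exactly ``chance`` is not flagged.
    """
    validate_dataset(data)
    means = data.groupby(["track_id", "condition"])["response"].mean()
    flagged = [(int(t), str(c), float(m)) for (t, c), m in means.items()
               if m < chance]
    return ScreenReport(flagged_tracks=sorted(flagged),
                        thresholds={"chance": chance})


def screen_participants(data: pd.DataFrame, dominance: float = 0.9) -> ScreenReport:
    """Flag participants who give (nearly) all-'on' or all-'off' judgments.

    The judgment is reconstructed from correctness: a correct response to
    an ON item, or an incorrect response to an OFF item, is an "on the
    beat" answer.  A participant is flagged when the share of their most
    frequent judgment strictly exceeds ``dominance``.
    """
    validate_dataset(data)
    judged_on = ((data["condition"] == Condition.ON.value)
                 == (data["response"] == 1))
    share = judged_on.groupby(data["participant_id"]).mean()
    dom = np.maximum(share, 1.0 - share)
    flagged = [(pid, float(v)) for pid, v in dom.items() if v > dominance]
    return ScreenReport(flagged_participants=sorted(flagged, key=lambda x: str(x[0])),
                        thresholds={"dominance": dominance})
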
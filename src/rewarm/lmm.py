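"""Variance-component estimation for the cold-challenge analyses.

Two model families are implemented here:

* :class:`RandomInterceptREML` — the univariate linear mixed model

  .. math:: y_{ij} = x_{ij}'\\beta + b_i + e_{ij},\\qquad
            b_i \\sim N(0, \\sigma^2_p),\\ e_{ij} \\sim N(0, \\sigma^2)

  with patient random intercepts and arbitrary fixed effects (center
  indicators, optional covariates).  The restricted likelihood is profiled
  down to a one-dimensional search over the variance ratio
  ``lambda = sigma2_patient / sigma2_resid``, which makes a single fit cheap
  enough to drive tens of thousands of bootstrap refits.

* :class:`BivariateREML` — the bivariate linear mixed model used for
  convergent validity: two modalities measured on the same patients over
  repeated visits, each with its own fixed effects and residual variance,
  and a correlated pair of patient-level random intercepts with covariance
  matrix ``G`` (parameterized through its Cholesky factor so positive
  semi-definiteness is automatic).  The latent correlation between the
  modalities is ``G12 / sqrt(G11 * G22)``.

Both fits maximize the restricted likelihood

.. math:: \\ell_R = -\\tfrac12\\bigl[\\log|V| + \\log|X'V^{-1}X|
          + r'V^{-1}r + (N-p)\\log 2\\pi\\bigr]

so that a bivariate fit with the cross-covariance pinned at zero has a
restricted log-likelihood exactly equal to the sum of the two univariate
fits (the bivariate model nests the univariate one).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

_LOG2PI = math.log(2.0 * math.pi)

# Search range for log(lambda); the endpoints act as the 0 and +inf
# boundaries of the variance ratio.
_T_LO = math.log(1e-9)
_T_HI = math.log(1e9)

BOUNDARY_PATIENT = "patient_variance_zero"
BOUNDARY_RESIDUAL = "residual_variance_zero"


@dataclass
class UnivariateFit:
    """REML estimates for the random-intercept model."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_patient: float
    sigma2_resid: float
    loglik: float
    converged: bool
    boundary: str | None
    n_obs: int
    n_groups: int
    xnames: list[str] | None = None

    @property
    def icc(self) -> float:
        """Intraclass correlation sigma2_patient / (sigma2_patient + sigma2_resid)."""
        tot = self.sigma2_patient + self.sigma2_resid
        if tot <= 0.0:
            raise ValueError("both variance components are zero; ICC undefined")
        return self.sigma2_patient / tot


class RandomInterceptREML:
    """Profiled REML for ``y = X beta + b_group + e``.

    Parameters
    ----------
    X : (n, p) array of fixed-effect regressors (include the intercept).
    y : (n,) response.
    groups : (n,) integer codes identifying the grouping unit (patient).

    The constructor reduces the data to per-group sufficient statistics, so
    a fit evaluates the restricted likelihood in O(G p^2) per candidate
    variance ratio regardless of the number of rows, and bootstrap variants
    (new response on the same design, or resampled groups with
    multiplicities) re-use the precomputed pieces.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                 xnames: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        if X.ndim != 2 or len(y) != len(X) or len(groups) != len(X):
            raise ValueError("X, y and groups must have matching lengths")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in design or response")
        order = np.argsort(groups, kind="stable")
        self.X = X[order]
        self.y = y[order]
        g_sorted = groups[order]
        # re-code groups as 0..G-1 in sorted order
        uniq, codes = np.unique(g_sorted, return_inverse=True)
        self.group_labels = uniq
        self.codes = codes
        self.n_groups = len(uniq)
        self.n_obs, self.p = self.X.shape
        if self.n_obs <= self.p:
            raise ValueError("fewer observations than fixed-effect parameters")
        self.xnames = xnames
        starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
        self._starts = starts
        self.n_per_group = np.diff(np.r_[starts, self.n_obs]).astype(float)
        # per-group sufficient statistics
        self.Sx = np.add.reduceat(self.X, starts, axis=0)          # (G, p)
        self.XtX_g = np.add.reduceat(
            self.X[:, :, None] * self.X[:, None, :], starts, axis=0)  # (G, p, p)
        self._set_response(self.y)

    # -- response-dependent statistics -------------------------------------

    def _set_response(self, y: np.ndarray) -> None:
        starts = self._starts
        self.Sy = np.add.reduceat(y, starts)                        # (G,)
        self.Syy_g = np.add.reduceat(y * y, starts)                 # (G,)
        self.Xty_g = np.add.reduceat(self.X * y[:, None], starts, axis=0)

    def _aggregates(self, counts: np.ndarray | None):
        if counts is None:
            counts = np.ones(self.n_groups)
        XtX = np.einsum("g,gpq->pq", counts, self.XtX_g)
        Xty = np.einsum("g,gp->p", counts, self.Xty_g)
        yty = float(np.dot(counts, self.Syy_g))
        return counts, XtX, Xty, yty

    # -- REML criterion ----------------------------------------------------

    def _neg_reml(self, t: float, counts, XtX, Xty, yty, N: int):
        """Negative restricted log-likelihood at log-variance-ratio ``t``."""
        lam = math.exp(t)
        n = self.n_per_group
        w = counts * lam / (1.0 + n * lam)
        A = XtX - np.einsum("g,gp,gq->pq", w, self.Sx, self.Sx)
        bvec = Xty - self.Sx.T @ (w * self.Sy)
        q = yty - float(w @ (self.Sy * self.Sy))
        sign, ldA = np.linalg.slogdet(A)
        if sign <= 0:
            return 1e12, None
        try:
            beta = np.linalg.solve(A, bvec)
        except np.linalg.LinAlgError:
            return 1e12, None
        ypy = q - float(bvec @ beta)
        ypy = max(ypy, 1e-300)
        dof = N - self.p
        sigma2 = ypy / dof
        ld = float(counts @ np.log1p(n * lam))
        crit = 0.5 * (dof * (_LOG2PI + math.log(sigma2) + 1.0) + ld + ldA)
        return crit, (lam, sigma2, beta, A)

    def fit(self, counts: np.ndarray | None = None) -> UnivariateFit:
        """Maximize the restricted likelihood over the variance ratio."""
        counts, XtX, Xty, yty = self._aggregates(counts)
        N = int(np.round(counts @ self.n_per_group))

        def f(t):
            return self._neg_reml(t, counts, XtX, Xty, yty, N)[0]

        res = optimize.minimize_scalar(
            f, bounds=(_T_LO, _T_HI), method="bounded",
            options={"xatol": 1e-11})
        cands = [res.x, _T_LO, _T_HI]
        vals = [f(t) for t in cands]
        best = int(np.argmin(vals))
        t_hat = cands[best]
        crit, parts = self._neg_reml(t_hat, counts, XtX, Xty, yty, N)
        converged = parts is not None
        if not converged:
            raise np.linalg.LinAlgError(
                "singular fixed-effect design in the mixed model "
                "(e.g. a single center with a single patient)")
        lam, sigma2, beta, A = parts
        boundary = None
        if t_hat <= _T_LO + 1e-3:
            boundary = BOUNDARY_PATIENT
            lam = 0.0
        elif t_hat >= _T_HI - 1e-3:
            boundary = BOUNDARY_RESIDUAL
        cov_beta = sigma2 * np.linalg.inv(A)
        return UnivariateFit(
            beta=beta, cov_beta=cov_beta,
            sigma2_patient=lam * sigma2, sigma2_resid=sigma2,
            loglik=-crit, converged=converged, boundary=boundary,
            n_obs=N, n_groups=int(np.sum(counts > 0)), xnames=self.xnames)

    # -- bootstrap support ---------------------------------------------------

    def simulate(self, fit: UnivariateFit, rng: np.random.Generator) -> np.ndarray:
        """Draw a response vector from the fitted model (internal row order)."""
        b = rng.normal(0.0, math.sqrt(max(fit.sigma2_patient, 0.0)), self.n_groups)
        e = rng.normal(0.0, math.sqrt(fit.sigma2_resid), self.n_obs)
        return self.X @ fit.beta + b[self.codes] + e

    def refit(self, y_new: np.ndarray) -> UnivariateFit:
        """Refit with a new response on the same design (parametric bootstrap)."""
        self._set_response(np.asarray(y_new, dtype=float))
        try:
            return self.fit()
        finally:
            self._set_response(self.y)


# ---------------------------------------------------------------------------
# bivariate model
# ---------------------------------------------------------------------------

@dataclass
class BivariateFitResult:
    """REML estimates for the bivariate random-intercept model."""

    G: np.ndarray                 # 2x2 patient-level covariance
    resid_var: np.ndarray         # (2,) residual variances, model order
    beta: np.ndarray
    loglik: float
    converged: bool
    boundary: bool                # True if a diagonal of G collapsed to ~0
    theta: np.ndarray             # internal parameter vector at the optimum
    modalities: tuple[str, str] | None = None
    xnames: list[str] | None = None

    @property
    def rho(self) -> float | None:
        """Latent correlation G12/sqrt(G11*G22); None at a variance boundary."""
        if self.boundary:
            return None
        return float(self.G[0, 1] / math.sqrt(self.G[0, 0] * self.G[1, 1]))


class BivariateREML:
    """REML for two outcomes sharing correlated patient random intercepts.

    Rows are stacked observations (patient, variate index 0/1, value) with a
    row-specific fixed-effect design.  Patients are grouped by their
    observation pattern so the per-patient covariance matrix is assembled
    once per pattern and the likelihood accumulates with batched einsums.
    """

    def __init__(self, X, y, patients, variate, xnames=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        patients = np.asarray(patients)
        variate = np.asarray(variate, dtype=int)
        if not np.all((variate == 0) | (variate == 1)):
            raise ValueError("variate codes must be 0 or 1")
        order = np.lexsort((variate, patients))
        X, y, patients, variate = X[order], y[order], patients[order], variate[order]
        self.p = X.shape[1]
        self.N = len(y)
        self.xnames = xnames
        uniq, codes = np.unique(patients, return_inverse=True)
        self.patient_labels = uniq
        self.n_patients = len(uniq)
        starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
        ends = np.r_[starts[1:], self.N]
        # group patients by identical variate pattern
        pattern_of = {}
        for s, e in zip(starts, ends):
            key = tuple(variate[s:e])
            pattern_of.setdefault(key, []).append((s, e))
        self._patterns = []
        for key, spans in pattern_of.items():
            k = len(key)
            Xg = np.stack([X[s:e] for s, e in spans])      # (m, k, p)
            yg = np.stack([y[s:e] for s, e in spans])      # (m, k)
            mod = np.array(key, dtype=int)                 # (k,)
            Z = np.zeros((k, 2))
            Z[np.arange(k), mod] = 1.0
            pats = np.array([codes[s] for s, _ in spans])
            self._patterns.append({"X": Xg, "y": yg, "mod": mod, "Z": Z,
                                   "patients": pats})

    # -- parameter packing: theta = (log s2_0, log s2_1, log l11, c, log l22)
    # with L21 = c * L22.  The ratio c is invariant to rescaling either
    # variate (both L21 and L22 carry variate-1 units), which keeps the
    # optimization well conditioned when the two outcomes live on wildly
    # different scales; the latent correlation is c / sqrt(1 + c^2).

    @staticmethod
    def _unpack(theta, free_cov: bool):
        s2 = np.exp(theta[:2])
        l11 = math.exp(theta[2])
        if free_cov:
            l22 = math.exp(theta[4])
            l21 = theta[3] * l22
        else:
            l21 = 0.0
            l22 = math.exp(theta[3])
        L = np.array([[l11, 0.0], [l21, l22]])
        return s2, L @ L.T

    def neg_reml(self, theta: np.ndarray, free_cov: bool = True) -> float:
        s2, G = self._unpack(np.asarray(theta, dtype=float), free_cov)
        A = np.zeros((self.p, self.p))
        bvec = np.zeros(self.p)
        q = 0.0
        ld = 0.0
        for pat in self._patterns:
            Z, mod = pat["Z"], pat["mod"]
            V = Z @ G @ Z.T + np.diag(s2[mod])
            try:
                C = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return 1e12
            m, k = pat["y"].shape
            ld += 2.0 * m * float(np.log(np.diag(C)).sum())
            # whiten: solve C w = x per patient, then accumulate with BLAS
            Ci = np.linalg.inv(C)
            W = np.matmul(Ci[None], pat["X"]).reshape(m * k, self.p)
            z = np.matmul(Ci[None], pat["y"][:, :, None]).reshape(m * k)
            A += W.T @ W
            bvec += W.T @ z
            q += float(z @ z)
        sign, ldA = np.linalg.slogdet(A)
        if sign <= 0:
            return 1e12
        beta = np.linalg.solve(A, bvec)
        rVr = q - float(bvec @ beta)
        return 0.5 * (ld + ldA + rVr + (self.N - self.p) * _LOG2PI)

    def loglik_at(self, theta, free_cov: bool = True) -> float:
        """Restricted log-likelihood at a given parameter vector."""
        return -self.neg_reml(theta, free_cov)

    def _beta_at(self, theta, free_cov=True):
        s2, G = self._unpack(np.asarray(theta, dtype=float), free_cov)
        A = np.zeros((self.p, self.p))
        bvec = np.zeros(self.p)
        for pat in self._patterns:
            Z, mod = pat["Z"], pat["mod"]
            V = Z @ G @ Z.T + np.diag(s2[mod])
            Vi = np.linalg.inv(V)
            A += np.einsum("mkp,kl,mlq->pq", pat["X"], Vi, pat["X"], optimize=True)
            bvec += np.einsum("mkp,kl,ml->p", pat["X"], Vi, pat["y"], optimize=True)
        return np.linalg.solve(A, bvec)

    def default_starts(self) -> list[np.ndarray]:
        """Deterministic starting points from patient-level moment estimates.

        The patient-mean variance approximates G_vv + s2_v/k, the mean
        within-patient variance approximates s2_v, and the correlation of
        patient means across variates seeds the cross term.
        """
        means = np.full((self.n_patients, 2), np.nan)
        s2 = np.zeros(2)
        g = np.zeros(2)
        for v in (0, 1):
            within = []
            pm_all = []
            pat_idx = []
            for pat in self._patterns:
                sel = pat["mod"] == v
                if not sel.any():
                    continue
                yv = pat["y"][:, sel]
                pm = yv.mean(axis=1)
                pm_all.append(pm)
                pat_idx.append(pat["patients"])
                if sel.sum() >= 2:
                    within.append(yv.var(axis=1, ddof=1))
            pm_all = np.concatenate(pm_all)
            pat_idx = np.concatenate(pat_idx)
            means[pat_idx, v] = pm_all
            s2[v] = max(float(np.mean(np.concatenate(within))), 1e-8) \
                if within else max(float(np.var(pm_all)) * 0.5, 1e-8)
            g[v] = max(float(np.var(pm_all)) - s2[v] / 2.0, 0.05 * s2[v])
        both = np.all(np.isfinite(means), axis=1)
        r0 = 0.0
        if both.sum() >= 3:
            c = np.corrcoef(means[both, 0], means[both, 1])[0, 1]
            if np.isfinite(c):
                r0 = float(np.clip(c, -0.95, 0.95))
        starts = []
        for r in (r0, 0.0):
            l11 = math.sqrt(g[0])
            l22 = math.sqrt(max(g[1] * (1.0 - r ** 2), 1e-10))
            c = r / math.sqrt(max(1.0 - r ** 2, 1e-10))
            starts.append(np.array([math.log(s2[0]), math.log(s2[1]),
                                    math.log(l11), c, math.log(l22)]))
        return starts

    def fit(self, starts: list[np.ndarray] | None = None,
            free_cov: bool = True, ftol: float = 1e-13, gtol: float = 1e-9,
            maxiter: int = 500) -> BivariateFitResult:
        """Maximize the restricted likelihood from one or more starts."""
        if starts is None:
            starts = self.default_starts()
        if not free_cov:
            starts = [np.r_[t[:3], t[4:]] if len(t) == 5 else t for t in starts]
        nparam = 5 if free_cov else 4
        bounds = [(-30.0, 30.0)] * nparam
        if free_cov:
            bounds[3] = (-1e6, 1e6)
        best = None
        ok = False
        for t0 in starts:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.minimize(
                    self.neg_reml, np.asarray(t0, dtype=float),
                    args=(free_cov,), method="L-BFGS-B", bounds=bounds,
                    options={"ftol": ftol, "gtol": gtol, "maxiter": maxiter})
            if best is None or res.fun < best.fun:
                best = res
                ok = bool(res.success)
        if not ok:
            # gradient-free polish for the occasional L-BFGS line-search stall
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.minimize(
                    self.neg_reml, best.x, args=(free_cov,),
                    method="Nelder-Mead",
                    options={"fatol": 1e-10, "xatol": 1e-8, "maxiter": 2000})
            if res.fun <= best.fun:
                best = res
                ok = bool(res.success)
        s2, G = self._unpack(best.x, free_cov)
        # scale-free per-variate boundary check (each variate has its own units)
        boundary = any(G[v, v] < 1e-7 * (G[v, v] + s2[v]) for v in (0, 1))
        beta = self._beta_at(best.x, free_cov)
        return BivariateFitResult(
            G=G, resid_var=s2, beta=beta, loglik=-float(best.fun),
            converged=ok, boundary=boundary, theta=np.asarray(best.x),
            xnames=self.xnames)

    # -- parametric bootstrap ------------------------------------------------

    def simulate(self, fit: BivariateFitResult,
                 rng: np.random.Generator) -> list[np.ndarray]:
        """Simulate grouped responses from a fitted model."""
        Lg = np.linalg.cholesky(fit.G + 1e-12 * np.eye(2))
        b = rng.standard_normal((self.n_patients, 2)) @ Lg.T
        sims = []
        for pat in self._patterns:
            mod = pat["mod"]
            mean = pat["X"] @ fit.beta                      # (m, k)
            re = b[pat["patients"]][:, mod]                 # (m, k)
            e = rng.normal(0.0, np.sqrt(fit.resid_var[mod]),
                           size=mean.shape)
            sims.append(mean + re + e)
        return sims

    def refit(self, sims: list[np.ndarray],
              start: np.ndarray | None = None,
              free_cov: bool = True) -> BivariateFitResult:
        """Refit after swapping in simulated grouped responses.

        Bootstrap replicates use slightly relaxed optimizer tolerances —
        percentile intervals do not benefit from 1e-13 objective precision.
        """
        saved = [pat["y"] for pat in self._patterns]
        try:
            for pat, ynew in zip(self._patterns, sims):
                pat["y"] = ynew
            starts = None if start is None else [start]
            return self.fit(starts=starts, free_cov=free_cov,
                            ftol=1e-10, gtol=1e-6, maxiter=200)
        finally:
            for pat, yold in zip(self._patterns, saved):
                pat["y"] = yold
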
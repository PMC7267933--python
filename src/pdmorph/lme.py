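"""Linear mixed-effect modelling of regional atrophy rates.

Per brain region the model is

    y_i = X_i beta + Z_i b_i + e_i,     b_i ~ N(0, Psi),  e_i ~ N(0, s^2 I)

for subject i with m_i visits.  The fixed design X_i has exactly eight
columns, in this order: intercept, time from baseline t, PDN indicator
G1, t*G1, PDCI indicator G2, t*G2, piecewise age (years above the knot,
zero below it), years of education.  Controls are the reference group,
so beta[1], beta[1]+beta[3] and beta[1]+beta[5] are the atrophy rates of
controls, PDN and PDCI respectively.  The random design Z_i carries an
intercept and t per subject with an unstructured 2x2 covariance
(compound symmetry is not assumed).

Estimation is REML.  The relative random-effect covariance G = Psi/s^2
is parametrized by its Cholesky factor (non-negative diagonal, so
boundary fits with zero variance components are representable and are
reported, not hidden); the residual variance is profiled out, and the
resulting 3-parameter objective is minimized by L-BFGS-B from a
method-of-moments start.  The fit is deterministic given the data.

Subjects sharing a visit-time pattern share V_i = s^2 (I + Z G Z'), so
the likelihood is evaluated per pattern with batched linear algebra;
with a fixed visit schedule and monotone drop-out there are only a
handful of patterns and a fit costs milliseconds.

Equality of slopes across groups (beta[3] = beta[5] = 0) is tested with
a contrast F statistic; the denominator df is the residual df N - 8 by
default, with a Satterthwaite (Fai-Cornelius) option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .cohort import IntegrityError, LongTable, PdmorphError

__all__ = [
    "piecewise_age",
    "PiecewiseAgeTransform",
    "LMEDesign",
    "LMEFit",
    "ContrastTest",
    "SLOPE_CONTRAST",
    "build_design",
    "fit_lme",
    "contrast_F_test",
    "slope_table",
]

N_FIXED = 8

#: Contrast selecting the two group-by-time interaction coefficients:
#: the null hypothesis of equal atrophy rates in all three groups.
SLOPE_CONTRAST = np.zeros((2, N_FIXED))
SLOPE_CONTRAST[0, 3] = 1.0
SLOPE_CONTRAST[1, 5] = 1.0


class ConvergenceError(PdmorphError):
    """The REML optimizer failed to converge; message carries the trace."""


def piecewise_age(age, knot: float = 60.0):
    """Years of age above the knot; zero at or below it.

    Implements the piecewise-linear (Heaviside-knot) aging model: the
    cross-sectional age effect on brain volume and thickness is taken as
    negligible below the knot (default 60 years) and linear above it.
    """
    return np.maximum(np.asarray(age, dtype=float) - knot, 0.0)


@dataclass(frozen=True)
class PiecewiseAgeTransform:
    knot: float = 60.0

    def __post_init__(self) -> None:
        if not (40.0 <= self.knot <= 80.0):
            raise PdmorphError(f"age knot {self.knot} outside the sensible range [40, 80]")

    def __call__(self, age):
        return piecewise_age(age, self.knot)


@dataclass
class LMEDesign:
    """Aligned fixed design X (N x 8), outcome y, times and subject ids."""

    X: np.ndarray
    y: np.ndarray
    t: np.ndarray
    subject: np.ndarray
    region: str = ""

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.y), N_FIXED):
            raise IntegrityError("fixed design must have exactly 8 columns")


def build_design(
    table: LongTable,
    region: str,
    transform: PiecewiseAgeTransform | float = 60.0,
    age_mode: str = "enrollment",
) -> LMEDesign:
    """Build the 8-column fixed design for one region.

    Rows with a missing outcome are dropped (complete case per region).
    ``age_mode='enrollment'`` uses each subject's baseline age through
    the knot transform at every visit (the default); ``'visit'`` lets
    the transformed age vary with the visit.
    """
    if isinstance(transform, (int, float)):
        transform = PiecewiseAgeTransform(float(transform))
    df = table.df
    if region not in df.columns:
        raise PdmorphError(f"unknown region/column {region!r}")
    ok = df[region].notna()
    df = df[ok]
    if len(df) == 0:
        raise PdmorphError(f"no non-missing observations for {region}")
    if not df["group"].isin(["CTRL", "PDN", "PDCI"]).all():
        raise IntegrityError("subject with unknown group")

    t = df["time_from_baseline"].to_numpy(dtype=float)
    g1 = (df["group"] == "PDN").to_numpy(dtype=float)
    g2 = (df["group"] == "PDCI").to_numpy(dtype=float)
    if age_mode == "enrollment":
        age = df["baseline_age"].to_numpy(dtype=float)
    elif age_mode == "visit":
        age = df["age_at_visit"].to_numpy(dtype=float)
    else:
        raise PdmorphError(f"unknown age_mode {age_mode!r}")
    X = np.column_stack(
        [
            np.ones(len(df)),
            t,
            g1,
            t * g1,
            g2,
            t * g2,
            transform(age),
            df["education"].to_numpy(dtype=float),
        ]
    )
    return LMEDesign(
        X=X,
        y=df[region].to_numpy(dtype=float),
        t=t,
        subject=df["subject_id"].to_numpy(),
        region=region,
    )


# ---------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------

class _Pattern:
    """All subjects sharing one visit-time vector, batched."""

    __slots__ = ("times", "X", "y", "m", "S", "Xflat", "yflat")

    def __init__(self, times, X, y):
        self.times = times      # (m,)
        self.X = X              # (S, m, 8)
        self.y = y              # (S, m)
        self.S, self.m = y.shape
        self.Xflat = X.reshape(-1, X.shape[-1])  # (S*m, 8)
        self.yflat = y.reshape(-1)


class _REMLProblem:
    def __init__(self, design: LMEDesign, random_slope: bool = True):
        self.random_slope = random_slope
        self.q = 2 if random_slope else 1
        order = np.argsort(design.subject, kind="stable")
        X, y, t, subj = (a[order] for a in (design.X, design.y, design.t, design.subject))
        self.n_obs = len(y)
        patterns: dict[tuple, list] = {}
        start = 0
        self.n_subjects = 0
        for i in range(1, len(subj) + 1):
            if i == len(subj) or subj[i] != subj[start]:
                key = tuple(np.round(t[start:i], 10))
                patterns.setdefault(key, []).append((X[start:i], y[start:i]))
                self.n_subjects += 1
                start = i
        self.patterns = []
        for key, members in patterns.items():
            Xs = np.stack([m[0] for m in members])
            ys = np.stack([m[1] for m in members])
            self.patterns.append(_Pattern(np.asarray(key, dtype=float), Xs, ys))
        self.max_m = max(p.m for p in self.patterns)

    def _Z(self, times: np.ndarray) -> np.ndarray:
        if self.random_slope:
            return np.column_stack([np.ones_like(times), times])
        return np.ones((len(times), 1))

    def theta_to_G(self, theta: np.ndarray) -> np.ndarray:
        L = np.zeros((self.q, self.q))
        if self.q == 2:
            L[0, 0], L[1, 0], L[1, 1] = theta
        else:
            L[0, 0] = theta[0]
        return L @ L.T

    def profile(self, theta: np.ndarray):
        """GLS profile at relative covariance G(theta).

        Returns (beta, A, rss, logdet_v0, sigma2) with A = sum X'V0^-1 X
        and V0 = I + Z G Z' per subject.
        """
        G = self.theta_to_G(theta)
        A = np.zeros((N_FIXED, N_FIXED))
        c = np.zeros(N_FIXED)
        logdet = 0.0
        pieces = []
        for p in self.patterns:
            Z = self._Z(p.times)
            V0 = np.eye(p.m) + Z @ G @ Z.T
            Cf = linalg.cho_factor(V0, lower=True)
            W = linalg.cho_solve(Cf, np.eye(p.m))
            logdet += p.S * 2.0 * np.sum(np.log(np.diag(Cf[0])))
            WX = np.matmul(W, p.X).reshape(-1, N_FIXED)  # (S*m, 8)
            A += p.Xflat.T @ WX
            c += WX.T @ p.yflat
            pieces.append(W)
        try:
            beta = linalg.solve(A, c, assume_a="pos")
        except (linalg.LinAlgError, np.linalg.LinAlgError):
            # rank-deficient fixed design: minimum-norm GLS solution
            beta, *_ = np.linalg.lstsq(A, c, rcond=None)
        rss = 0.0
        for p, W in zip(self.patterns, pieces):
            r = p.y - p.X @ beta
            rss += float(np.sum(r * (r @ W.T)))
        rss = max(rss, 0.0)
        df = self.n_obs - N_FIXED
        sigma2 = rss / df
        return beta, A, rss, logdet, sigma2

    def neg2_reml(self, theta: np.ndarray) -> float:
        _, A, rss, logdet, _ = self.profile(theta)
        df = self.n_obs - N_FIXED
        sign, logdet_A = np.linalg.slogdet(A)
        return logdet + logdet_A + df * math.log(max(rss, 1e-300))

    def neg2_reml_full(self, phi: np.ndarray) -> float:
        """Unprofiled objective in phi = (theta..., log sigma2); used for
        the observed information behind Satterthwaite df."""
        theta, logs2 = phi[:-1], phi[-1]
        s2 = math.exp(logs2)
        _, A, rss, logdet, _ = self.profile(theta)
        df = self.n_obs - N_FIXED
        sign, logdet_A = np.linalg.slogdet(A)
        return df * logs2 + logdet + logdet_A + rss / s2

    def start(self) -> np.ndarray:
        """Method-of-moments start from per-subject OLS lines."""
        coefs, resid_ss, resid_df, infl = [], 0.0, 0, []
        for p in self.patterns:
            Z = self._Z(p.times)
            if np.linalg.matrix_rank(Z) < self.q:
                continue
            ZtZinv = np.linalg.pinv(Z.T @ Z)
            B = p.y @ Z @ ZtZinv  # (S, q) per-subject OLS coefficients
            coefs.append(B)
            infl.extend([ZtZinv] * p.S)
            if p.m > self.q:
                fitted = B @ Z.T
                resid_ss += float(((p.y - fitted) ** 2).sum())
                resid_df += p.S * (p.m - self.q)
        yall = np.concatenate([p.y.ravel() for p in self.patterns])
        s2 = resid_ss / resid_df if resid_df > 0 else max(yall.var() / 2, 1e-8)
        s2 = max(s2, 1e-10 * max(yall.var(), 1.0))
        if coefs and sum(len(b) for b in coefs) >= 3:
            B = np.concatenate(coefs)
            emp = np.cov(B.T).reshape(self.q, self.q)
            psi0 = emp - s2 * np.mean(infl, axis=0)
            w, V = np.linalg.eigh(psi0)
            psi0 = (V * np.clip(w, 1e-8, None)) @ V.T
        else:
            psi0 = np.eye(self.q) * max(yall.var() / 4, 1e-8)
        G0 = psi0 / s2
        try:
            L = np.linalg.cholesky(G0 + 1e-10 * np.eye(self.q))
        except np.linalg.LinAlgError:
            L = np.diag(np.sqrt(np.clip(np.diag(G0), 1e-8, None)))
        if self.q == 2:
            return np.array([L[0, 0], L[1, 0], L[1, 1]])
        return np.array([L[0, 0]])


@dataclass
class LMEFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    psi: np.ndarray
    sigma2: float
    loglik: float
    theta: np.ndarray
    converged: bool
    n_obs: int
    n_subjects: int
    boundary: bool
    message: str
    region: str = ""
    objective: float = float("nan")
    _problem: _REMLProblem | None = field(default=None, repr=False)

    @property
    def group_slopes(self) -> dict[str, float]:
        b = self.beta
        return {"CTRL": b[1], "PDN": b[1] + b[3], "PDCI": b[1] + b[5]}

    def slope_se(self, group: str) -> float:
        w = np.zeros(N_FIXED)
        w[1] = 1.0
        if group == "PDN":
            w[3] = 1.0
        elif group == "PDCI":
            w[5] = 1.0
        elif group != "CTRL":
            raise PdmorphError(f"unknown group {group}")
        return float(np.sqrt(w @ self.cov_beta @ w))

    @property
    def df_residual(self) -> int:
        return self.n_obs - N_FIXED


def fit_lme(
    design: LMEDesign,
    random_slope: bool = True,
    fix_theta: Sequence[float] | None = None,
    max_iter: int = 200,
) -> LMEFit:
    """REML fit of the mixed model for one region's design.

    Subjects with a single visit contribute through their marginal
    covariance.  If no subject has two or more visits the random-slope
    variance is unidentifiable and an error advises the
    random-intercept-only mode (``random_slope=False``).  Setting
    ``fix_theta`` skips optimization and evaluates the GLS fit at the
    given relative-covariance Cholesky parameters (e.g. zeros for an
    OLS-equivalent fit).
    """
    prob = _REMLProblem(design, random_slope=random_slope)
    if random_slope and prob.max_m < 2:
        raise ConvergenceError(
            "no subject has >= 2 visits: the random-slope variance is "
            "unidentifiable; refit with random_slope=False"
        )

    # degenerate noise-free data: any theta reproduces y exactly, the REML
    # surface is flat in the variance parameters, so skip optimization
    zeros = np.zeros(3 if random_slope else 1)
    _, _, rss0, _, _ = prob.profile(zeros)
    yscale = max(float(np.mean(np.concatenate([p.y.ravel() for p in prob.patterns]) ** 2)), 1.0)
    if fix_theta is None and rss0 <= 1e-12 * yscale * prob.n_obs:
        fix_theta = zeros

    if fix_theta is not None:
        theta = np.asarray(fix_theta, dtype=float)
        converged, message, obj = True, "fixed variance parameters", prob.neg2_reml(theta)
    else:
        x0 = prob.start()
        big = 1e4
        bounds = [(0.0, big), (-big, big), (0.0, big)][: len(x0)]
        if len(x0) == 1:
            bounds = [(0.0, big)]
        res = optimize.minimize(
            prob.neg2_reml,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
        )
        theta = res.x
        obj = float(res.fun)
        converged = bool(res.success)
        message = str(res.message)
        if not converged:
            # L-BFGS-B can stop abnormally at a variance boundary; polish
            # with a derivative-free simplex from the best point found
            res2 = optimize.minimize(
                prob.neg2_reml, theta, method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-10},
            )
            cand = np.clip(res2.x, [b[0] for b in bounds], [b[1] for b in bounds])
            f_cand = prob.neg2_reml(cand)
            if f_cand <= obj + 1e-9:
                theta, obj = cand, float(f_cand)
                converged = bool(res2.success)
                message = str(res2.message)
        if not converged:
            raise ConvergenceError(f"REML optimizer did not converge: {message}")

    beta, A, rss, logdet, sigma2 = prob.profile(theta)
    df = prob.n_obs - N_FIXED
    sign, logdet_A = np.linalg.slogdet(A)
    loglik = -0.5 * (
        df * math.log(2 * math.pi)
        + df * math.log(max(sigma2, 1e-300))
        + logdet
        + logdet_A
        + df
    )
    G = prob.theta_to_G(theta)
    psi = sigma2 * G
    try:
        cov_beta = sigma2 * linalg.inv(A)
    except (linalg.LinAlgError, np.linalg.LinAlgError):
        cov_beta = sigma2 * np.linalg.pinv(A)
    diag = np.diag(G)
    boundary = bool(np.any(diag < 1e-10))
    return LMEFit(
        beta=beta,
        cov_beta=cov_beta,
        psi=psi,
        sigma2=float(sigma2),
        loglik=float(loglik),
        theta=np.asarray(theta, dtype=float),
        converged=converged,
        n_obs=prob.n_obs,
        n_subjects=prob.n_subjects,
        boundary=boundary,
        message=message,
        region=design.region,
        objective=obj,
        _problem=prob,
    )


@dataclass
class ContrastTest:
    L: np.ndarray
    F: float
    df1: int
    df2: float
    p: float
    df_method: str


def _satterthwaite_df2(fit: LMEFit, L: np.ndarray) -> float:
    """Fai-Cornelius multi-dimensional Satterthwaite denominator df.

    Uses the observed information of the unprofiled REML objective in
    (theta, log sigma2), with finite-difference derivatives of the
    contrast covariance.
    """
    prob = fit._problem
    phi_hat = np.append(fit.theta, math.log(max(fit.sigma2, 1e-300)))

    def covL(phi):
        theta, logs2 = phi[:-1], phi[-1]
        _, A, _, _, _ = prob.profile(theta)
        cb = math.exp(logs2) * linalg.inv(A)
        return L @ cb @ L.T

    h = 1e-4 * np.maximum(np.abs(phi_hat), 1.0)
    k = len(phi_hat)
    H = np.zeros((k, k))
    f0 = prob.neg2_reml_full(phi_hat)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = prob.neg2_reml_full(phi_hat + ei + ej)
            fpm = prob.neg2_reml_full(phi_hat + ei - ej)
            fmp = prob.neg2_reml_full(phi_hat - ei + ej)
            fmm = prob.neg2_reml_full(phi_hat - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        Vphi = 2.0 * linalg.inv(H)
    except linalg.LinAlgError:
        return float(fit.df_residual)

    M = covL(phi_hat)
    w, P = np.linalg.eigh(M)
    q = L.shape[0]
    E = 0.0
    for m in range(q):
        pm = P[:, m]
        grad = np.zeros(k)
        for i in range(k):
            ei = np.zeros(k); ei[i] = h[i]
            grad[i] = (pm @ covL(phi_hat + ei) @ pm - pm @ covL(phi_hat - ei) @ pm) / (2 * h[i])
        denom = grad @ Vphi @ grad
        if denom <= 0:
            continue
        nu = 2.0 * w[m] ** 2 / denom
        if nu > 2.0:
            E += nu / (nu - 2.0)
    if E <= q:
        return float(fit.df_residual)
    return 2.0 * E / (E - q)


def contrast_F_test(
    fit: LMEFit, L: np.ndarray | None = None, df_method: str = "satterthwaite"
) -> ContrastTest:
    """F-test of the linear hypothesis L beta = 0.

    The default contrast tests equality of the three group slopes
    (beta[3] = beta[5] = 0, rank 2).  F = (Lb)' (L Cov(b) L')^-1 (Lb) / rank(L)
    with numerator df = rank(L) and denominator df per ``df_method``
    ('residual': N - 8; 'satterthwaite': Fai-Cornelius).
    """
    if L is None:
        L = SLOPE_CONTRAST
    L = np.atleast_2d(np.asarray(L, dtype=float))
    if L.shape[1] != N_FIXED:
        raise PdmorphError("contrast matrix must have 8 columns")
    rank = np.linalg.matrix_rank(L)
    if rank < L.shape[0]:
        raise PdmorphError("contrast matrix is rank deficient")

    yscale = max(float(np.mean(np.concatenate([p.y.ravel() for p in fit._problem.patterns]) ** 2)), 1e-300)
    if fit.sigma2 <= 1e-14 * yscale:
        # exact (noise-free) fit: no residual variation to test against
        lb = L @ fit.beta
        exact_nonzero = float(lb @ lb) > 1e-10 * yscale
        F = math.inf if exact_nonzero else 0.0
        p = 0.0 if exact_nonzero else 1.0
        return ContrastTest(L=L, F=F, df1=int(rank), df2=float(fit.df_residual),
                            p=p, df_method=df_method + " (degenerate exact fit)")

    lb = L @ fit.beta
    M = L @ fit.cov_beta @ L.T
    F = float(lb @ linalg.solve(M, lb, assume_a="pos")) / rank
    if df_method == "residual":
        df2 = float(fit.df_residual)
    elif df_method == "satterthwaite":
        df2 = _satterthwaite_df2(fit, L)
    else:
        raise PdmorphError(f"unknown df_method {df_method!r}")
    p = float(stats.f.sf(F, rank, df2))
    return ContrastTest(L=L, F=F, df1=int(rank), df2=df2, p=p, df_method=df_method)


def slope_table(
    fits: Mapping[str, LMEFit],
    df_method: str = "satterthwaite",
    alpha: float = 0.05,
    units: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-region atrophy-rate report with the slope-equality F-test.

    Rates are in region units per year; thickness rates are additionally
    rendered in um/year (1 mm/y = 1000 um/y).  Significance flags apply
    a Bonferroni correction across the listed regions.
    """
    rows = []
    for region, fit in fits.items():
        ct = contrast_F_test(fit, df_method=df_method)
        slopes = fit.group_slopes
        row = {
            "region": region,
            "rate_ctrl": slopes["CTRL"],
            "rate_pdn": slopes["PDN"],
            "rate_pdci": slopes["PDCI"],
            "se_ctrl": fit.slope_se("CTRL"),
            "se_pdn": fit.slope_se("PDN"),
            "se_pdci": fit.slope_se("PDCI"),
            "F": ct.F,
            "DF1": ct.df1,
            "DF2": ct.df2,
            "p": ct.p,
            "boundary_fit": fit.boundary,
        }
        if units and units.get(region) == "mm":
            for g in ("ctrl", "pdn", "pdci"):
                row[f"rate_{g}_um_per_year"] = row[f"rate_{g}"] * 1000.0
        rows.append(row)
    out = pd.DataFrame(rows)
    m = len(out)
    out["p_bonferroni"] = np.minimum(out["p"] * m, 1.0)
    out["significant"] = out["p_bonferroni"] < alpha
    return out
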
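"""Linear mixed-model engine: REML/ML with correlated random effects, AR(1)
residuals and optional group-specific residual variance.

The model, per subject i with n_i readings,

    y_i = X_i beta + Z_i b_i + eps_i,
    b_i ~ MVN(0, Sigma_b),
    eps_i ~ MVN(0, sigma^2 d_{g_i}^2 R_i(rho)),

where ``R_i(rho)[a, b] = rho ** |slot_a - slot_b|`` is a continuous-index
AR(1) correlation over *nominal* slot distance (robust to missing slots),
and ``d_g`` are residual SD ratios per variance group (reference group 1).

Estimation maximizes the profiled REML or ML criterion over an
unconstrained parameterization: Sigma_b / sigma^2 via log-Cholesky factors
(one factor per independent random-effect block), rho via atanh, and the SD
ratios via log.  The overall scale sigma^2 and the fixed effects beta are
profiled out in closed form (GLS), so the optimizer only sees the variance
*shape* parameters.  Fits use quasi-Newton (L-BFGS-B) from two
deterministic starts; a seed only matters if optional random restarts are
requested.

Also provided: EBLUPs of the random effects, likelihood-ratio tests (with
the 50:50 chi-square boundary mixture for variance components), marginal
and conditional R^2 (Nakagawa-Schielzeth with Johnson's random-slope
extension), the ACF of pre-whitened residuals, and a simulation-based
visual predictive check (VPC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SubjectBlock",
    "MixedModelData",
    "FittedModel",
    "ConvergenceError",
    "marginal_loglik",
    "fit",
    "eblup",
    "lrt",
    "r2",
    "residual_acf",
    "vpc",
]

LOG2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """Raised when no optimizer start reaches a stationary point.

    Carries the best parameters seen so far in ``best_params``.
    """

    def __init__(self, msg, best_params=None, diagnostics=None):
        super().__init__(msg)
        self.best_params = best_params
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class SubjectBlock:
    """One subject's stacked data for the mixed model."""

    subject_id: str
    y: np.ndarray  # (n_i,)
    X: np.ndarray  # (n_i, p) fixed design
    Z: np.ndarray  # (n_i, q) random design
    slots: np.ndarray  # (n_i,) nominal slot indices, strictly increasing
    var_group: int = 0  # residual-variance group label

    def __post_init__(self):
        n = self.y.shape[0]
        if self.X.shape[0] != n or self.Z.shape[0] != n or self.slots.shape[0] != n:
            raise ValueError(f"{self.subject_id}: inconsistent row counts")
        if np.any(np.diff(self.slots) <= 0):
            raise ValueError(f"{self.subject_id}: slots not strictly increasing")


@dataclass
class MixedModelData:
    """Stacked per-subject blocks plus design metadata.

    ``re_blocks`` gives the sizes of independent blocks of Sigma_b (each
    block unstructured internally, zero covariance across blocks); the
    default is one block covering all random effects.
    """

    blocks: list
    x_names: list
    z_names: list
    re_blocks: tuple = ()
    n_var_groups: int = 1

    def __post_init__(self):
        q = self.blocks[0].Z.shape[1] if self.blocks else 0
        if not self.re_blocks:
            self.re_blocks = (q,)
        if sum(self.re_blocks) != q:
            raise ValueError("re_blocks must sum to the random-design width")

    @property
    def n_obs(self) -> int:
        return sum(b.y.shape[0] for b in self.blocks)

    @property
    def n_subjects(self) -> int:
        return len(self.blocks)

    @property
    def p(self) -> int:
        return self.blocks[0].X.shape[1]

    @property
    def q(self) -> int:
        return self.blocks[0].Z.shape[1]


@dataclass
class FittedModel:
    """Estimates and diagnostics from one mixed-model fit."""

    beta: pd.Series
    se: pd.Series
    cov_beta: pd.DataFrame
    Sigma_b: np.ndarray
    sigma: float
    rho: float
    var_ratio: np.ndarray  # per-group residual SD ratios, ref group = 1
    loglik: float
    criterion: str  # "REML" | "ML"
    ar1: bool
    n_params: int  # fixed + variance parameters (for LRT df)
    x_names: list = field(default_factory=list)
    z_names: list = field(default_factory=list)
    re_blocks: tuple = ()
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)
    theta: np.ndarray | None = None  # internal variance-shape parameters


# ---------------------------------------------------------------------------
# parameter packing: log-Cholesky per RE block, atanh(rho), log SD ratios


def _n_chol(m: int) -> int:
    return m * (m + 1) // 2


def _pack_theta(G_blocks, rho, ratios, ar1, n_groups):
    parts = []
    for G in G_blocks:
        m = G.shape[0]
        L = np.linalg.cholesky(G + 1e-10 * np.eye(m))
        vals = []
        for i in range(m):
            for j in range(i + 1):
                vals.append(np.log(max(L[i, j], 1e-8)) if i == j else L[i, j])
        parts.append(np.array(vals))
    if ar1:
        parts.append(np.array([np.arctanh(np.clip(rho, -0.99, 0.99))]))
    if n_groups > 1:
        parts.append(np.log(np.asarray(ratios[1:], dtype=float)))
    return np.concatenate(parts) if parts else np.zeros(0)


def _unpack_theta(theta, re_blocks, ar1, n_groups):
    pos = 0
    G_blocks = []
    for m in re_blocks:
        L = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1):
                v = theta[pos]
                L[i, j] = np.exp(v) if i == j else v
                pos += 1
        G_blocks.append(L @ L.T)
    rho = float(np.tanh(theta[pos])) if ar1 else 0.0
    pos += 1 if ar1 else 0
    ratios = np.ones(n_groups)
    if n_groups > 1:
        ratios[1:] = np.exp(theta[pos : pos + n_groups - 1])
    q = sum(re_blocks)
    G = np.zeros((q, q))
    at = 0
    for Gb in G_blocks:
        m = Gb.shape[0]
        G[at : at + m, at : at + m] = Gb
        at += m
    return G, rho, ratios


def _theta_bounds(re_blocks, ar1, n_groups):
    bounds = []
    for m in re_blocks:
        for i in range(m):
            for j in range(i + 1):
                bounds.append((-8.0, 8.0) if i == j else (-60.0, 60.0))
    if ar1:
        bounds.append((-5.0, 5.0))
    for _ in range(n_groups - 1):
        bounds.append((-3.0, 3.0))
    return bounds


# ---------------------------------------------------------------------------
# compiled data: blocks grouped by identical slot pattern for batched algebra


class _Group:
    __slots__ = ("slots", "D", "var_group", "Y", "X", "Z", "sids")

    def __init__(self, slots, var_group, Y, X, Z, sids):
        self.slots = slots
        self.D = np.abs(slots[:, None] - slots[None, :])
        self.var_group = var_group
        self.Y = Y  # (nb, m)
        self.X = X  # (nb, m, p)
        self.Z = Z  # (nb, m, q)
        self.sids = sids


def _compile(data: MixedModelData):
    keyed = {}
    for b in data.blocks:
        key = (b.slots.tobytes(), b.var_group)
        keyed.setdefault(key, []).append(b)
    groups = []
    for blocks in keyed.values():
        slots = np.asarray(blocks[0].slots, dtype=float)
        groups.append(
            _Group(
                slots,
                blocks[0].var_group,
                np.stack([b.y for b in blocks]),
                np.stack([b.X for b in blocks]),
                np.stack([b.Z for b in blocks]),
                [b.subject_id for b in blocks],
            )
        )
    return groups


def _corr(D, rho):
    if rho == 0.0:
        return np.eye(D.shape[0])
    return np.sign(rho) ** D * np.abs(rho) ** D if rho < 0 else rho**D


def _group_inverses(theta, groups, p, re_blocks, ar1, n_groups):
    """Per-group W_i^{-1}-based quantities for the scaled covariance
    W_i = Z_i G Z_i' + d^2 R_i(rho) (i.e. V_i / sigma^2)."""
    G, rho, ratios = _unpack_theta(theta, re_blocks, ar1, n_groups)
    logdet = 0.0
    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    ytWy = 0.0
    N = 0
    per_group = []
    for g in groups:
        R = _corr(g.D, rho)
        ZG = g.Z @ G
        W = np.einsum("nij,nkj->nik", ZG, g.Z)
        W += ratios[g.var_group] ** 2 * R
        sign, ld = np.linalg.slogdet(W)
        if np.any(sign <= 0):
            raise np.linalg.LinAlgError("W not positive definite")
        Winv = np.linalg.inv(W)
        B = Winv @ g.X  # (nb, m, p) = W^-1 X
        v = np.einsum("nij,nj->ni", Winv, g.Y)  # W^-1 y
        XtWX += np.einsum("nij,nik->jk", g.X, B)
        XtWy += np.einsum("nij,ni->j", g.X, v)
        ytWy += float(np.einsum("ni,ni->", g.Y, v))
        logdet += float(ld.sum())
        N += g.Y.size
        per_group.append((Winv, B, v, R))
    beta = np.linalg.solve(XtWX, XtWy)
    rss = max(ytWy - XtWy @ beta, 1e-12)
    return (G, rho, ratios), (beta, XtWX, rss, logdet, N), per_group


def _profiled_pieces(theta, groups, p, re_blocks, ar1, n_groups):
    _, pieces, _ = _group_inverses(theta, groups, p, re_blocks, ar1, n_groups)
    return pieces


def _neg2ll_grad(theta, groups, p, re_blocks, ar1, n_groups, criterion):
    """Profiled -2 log-likelihood and its analytic gradient.

    Uses the standard trace identities for variance-parameter derivatives,
    with beta and sigma^2 profiled out (envelope theorem: their optimality
    kills the corresponding chain-rule terms).
    """
    try:
        (G, rho, ratios), (beta, XtWX, rss, logdet, N), per_group = _group_inverses(
            theta, groups, p, re_blocks, ar1, n_groups
        )
    except np.linalg.LinAlgError:
        return 1e12, np.zeros_like(theta)
    reml = criterion == "REML"
    dof = N - p if reml else N
    if reml:
        sign, ld_xtx = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return 1e12, np.zeros_like(theta)
        value = dof * (LOG2PI + np.log(rss / dof) + 1.0) + logdet + ld_xtx
    else:
        value = dof * (LOG2PI + np.log(rss / dof) + 1.0) + logdet

    H = np.linalg.inv(XtWX)
    q = sum(re_blocks)
    # q x q accumulators for G-parameter derivatives
    sumC = np.zeros((q, q))  # sum Z' W^-1 Z
    sumUU = np.zeros((q, q))  # sum (Z' W^-1 r)(Z' W^-1 r)'
    sumM = np.zeros((q, q))  # sum (Z'W^-1 X) H (Z'W^-1 X)'
    # m x m accumulators per group for rho / SD-ratio derivatives
    mm_terms = []
    need_mm = ar1 or n_groups > 1
    for g, (Winv, B, v, R) in zip(groups, per_group):
        w = v - B @ beta  # W^-1 r, (nb, m)
        WinvZ = Winv @ g.Z
        sumC += np.einsum("nij,nik->jk", g.Z, WinvZ)
        U = np.einsum("nij,ni->nj", g.Z, w)  # (nb, q)
        sumUU += U.T @ U
        F = np.einsum("nij,nik->njk", g.Z, B)  # (nb, q, p) = Z'W^-1X
        sumM += np.einsum("njp,pq,nkq->jk", F, H, F)
        if need_mm:
            A = Winv.sum(axis=0)
            A -= (dof / rss) * (w.T @ w)
            if reml:
                A -= np.einsum("nip,pq,njq->ij", B, H, B)
            mm_terms.append((A, R, g))
    S = sumC - (dof / rss) * sumUU - (sumM if reml else 0.0)

    grad = np.zeros_like(theta)
    # gradient w.r.t. log-Cholesky entries of each G block
    pos = 0
    at = 0
    for m_blk in re_blocks:
        Sb = S[at : at + m_blk, at : at + m_blk]
        # rebuild this block's Cholesky factor from theta
        L = np.zeros((m_blk, m_blk))
        idx = pos
        for i in range(m_blk):
            for j in range(i + 1):
                v_ = theta[idx]
                L[i, j] = np.exp(v_) if i == j else v_
                idx += 1
        SL = 2.0 * (Sb @ L)
        for i in range(m_blk):
            for j in range(i + 1):
                grad[pos] = SL[i, j] * (L[i, i] if i == j else 1.0)
                pos += 1
        at += m_blk
    if ar1:
        Dall = 0.0
        for A, R, g in mm_terms:
            D = g.D
            Dm = np.maximum(D, 1.0)
            dR = (
                np.where(D > 0, D * np.sign(rho) ** (Dm - 1.0) * np.abs(rho) ** (Dm - 1.0), 0.0)
                if rho < 0
                else np.where(D > 0, D * rho ** (Dm - 1.0), 0.0)
            )
            Dall += ratios[g.var_group] ** 2 * float(np.sum(A * dR))
        grad[pos] = Dall * (1.0 - rho**2)  # chain rule through tanh
        pos += 1
    for gi in range(1, n_groups):
        acc = 0.0
        for A, R, g in mm_terms:
            if g.var_group == gi:
                acc += 2.0 * ratios[gi] ** 2 * float(np.sum(A * R))
        grad[pos] = acc
        pos += 1
    return value, grad


def _neg2ll(theta, groups, p, re_blocks, ar1, n_groups, criterion):
    try:
        beta, XtWX, rss, logdet, N = _profiled_pieces(
            theta, groups, p, re_blocks, ar1, n_groups
        )
    except np.linalg.LinAlgError:
        return 1e12
    if criterion == "ML":
        return N * (LOG2PI + np.log(rss / N) + 1.0) + logdet
    sign, ld_xtx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return 1e12
    return (N - p) * (LOG2PI + np.log(rss / (N - p)) + 1.0) + logdet + ld_xtx


# ---------------------------------------------------------------------------
# public API


def marginal_loglik(
    params: FittedModel, data: MixedModelData, criterion: str = "REML"
) -> float:
    """Marginal Gaussian log-likelihood at explicit parameter values.

    ML uses the supplied fixed effects; REML profiles them out (GLS) and
    includes the usual ``log|X'V^-1 X|`` adjustment.
    """
    beta = np.asarray(params.beta, dtype=float)
    Sigma_b = np.asarray(params.Sigma_b, dtype=float)
    if np.any(np.linalg.eigvalsh((Sigma_b + Sigma_b.T) / 2) < -1e-8):
        raise ValueError("Sigma_b is not positive semi-definite")
    sigma2 = params.sigma**2
    ratios = np.asarray(params.var_ratio, dtype=float)
    p = data.p
    logdet = 0.0
    quad = 0.0
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    N = data.n_obs
    for b in data.blocks:
        slots = np.asarray(b.slots, dtype=float)
        D = np.abs(slots[:, None] - slots[None, :])
        R = _corr(D, params.rho)
        d2 = ratios[b.var_group] ** 2 if b.var_group < ratios.size else 1.0
        V = b.Z @ Sigma_b @ b.Z.T + sigma2 * d2 * R
        L = np.linalg.cholesky(V)
        logdet += 2.0 * float(np.log(np.diag(L)).sum())
        U = np.linalg.solve(L, np.column_stack([b.X, b.y]))
        Ux, Uy = U[:, :p], U[:, p]
        XtVX += Ux.T @ Ux
        XtVy += Ux.T @ Uy
        ytVy += float(Uy @ Uy)
        quad += float(np.sum((Uy - Ux @ beta) ** 2))
    if criterion == "ML":
        return -0.5 * (N * LOG2PI + logdet + quad)
    beta_gls = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - XtVy @ beta_gls
    _, ld = np.linalg.slogdet(XtVX)
    return -0.5 * ((N - p) * LOG2PI + logdet + ld + rss)


def _smart_start(data: MixedModelData):
    """Method-of-moments start: covariance of per-subject OLS coefficients
    for G, pooled residual variance for sigma^2, lag-1 residual ACF for rho."""
    q = data.q
    coefs, res_vars, lag1_num, lag1_den = [], [], 0.0, 0.0
    for b in data.blocks:
        if b.y.size <= q + 1:
            continue
        sol, *_ = np.linalg.lstsq(b.Z, b.y, rcond=None)
        r = b.y - b.Z @ sol
        dof = max(b.y.size - q, 1)
        coefs.append(sol)
        res_vars.append(float(r @ r) / dof)
        adj = np.diff(np.asarray(b.slots, dtype=float)) == np.min(
            np.diff(np.asarray(b.slots, dtype=float))
        )
        lag1_num += float(np.sum(r[:-1][adj] * r[1:][adj]))
        lag1_den += float(r @ r)
    sigma2 = float(np.mean(res_vars)) if res_vars else 1.0
    sigma2 = max(sigma2, 1e-6)
    rho0 = float(np.clip(lag1_num / lag1_den if lag1_den > 0 else 0.0, -0.8, 0.8))
    if len(coefs) > q:
        Sb = np.cov(np.asarray(coefs).T)
        Sb = np.atleast_2d(Sb)
        vals, vecs = np.linalg.eigh((Sb + Sb.T) / 2)
        Sb = vecs @ np.diag(np.clip(vals, 1e-6, None)) @ vecs.T
    else:
        Sb = np.eye(q) * sigma2 * 0.1
    return Sb / sigma2, rho0, sigma2


def fit(
    data: MixedModelData,
    init: FittedModel | None = None,
    criterion: str = "REML",
    ar1: bool = True,
    seed: int | None = None,
    n_random_restarts: int = 0,
    maxiter: int = 400,
    gtol: float = 1e-5,
) -> FittedModel:
    """Fit the mixed model by profiled REML (default) or ML.

    Deterministic given data, ``init`` and ``seed``: two fixed starts (a
    per-subject-OLS moment start and an identity-scaled start) are always
    tried; ``n_random_restarts`` extra seeded starts may be added.
    """
    if criterion not in ("REML", "ML"):
        raise ValueError(f"criterion must be REML or ML, got {criterion!r}")
    if data.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    Xall = np.vstack([b.X for b in data.blocks])
    rank = np.linalg.matrix_rank(Xall)
    if rank < data.p:
        _, Rq = np.linalg.qr(Xall)
        bad = [data.x_names[j] for j in range(data.p) if abs(Rq[j, j]) < 1e-8 * abs(Rq[0, 0])]
        raise ValueError(f"fixed design is rank deficient; collinear columns: {bad}")

    groups = _compile(data)
    p, q = data.p, data.q
    n_groups = data.n_var_groups
    re_blocks = tuple(data.re_blocks)

    def block_split(G):
        out, at = [], 0
        for m in re_blocks:
            out.append(G[at : at + m, at : at + m])
            at += m
        return out

    starts = []
    if init is not None and init.theta is not None:
        starts.append(np.array(init.theta, dtype=float))
    G0, rho0, _ = _smart_start(data)
    starts.append(_pack_theta(block_split(G0), rho0, np.ones(n_groups), ar1, n_groups))
    starts.append(
        _pack_theta(block_split(np.eye(q) * 0.1), 0.0, np.ones(n_groups), ar1, n_groups)
    )
    rng = np.random.default_rng(seed)
    for _ in range(n_random_restarts):
        A = rng.normal(scale=0.5, size=(q, q))
        starts.append(
            _pack_theta(
                block_split(A @ A.T + 0.1 * np.eye(q)),
                float(rng.uniform(-0.5, 0.5)),
                np.ones(n_groups),
                ar1,
                n_groups,
            )
        )

    bounds = _theta_bounds(re_blocks, ar1, n_groups)
    args = (groups, p, re_blocks, ar1, n_groups, criterion)
    best = None
    diags = []
    for x0 in starts:
        res = optimize.minimize(
            _neg2ll_grad,
            x0,
            args=args,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-9},
        )
        diags.append(
            {"success": bool(res.success), "nit": int(res.nit), "fun": float(res.fun)}
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("all starts failed", diagnostics=diags)
    converged = any(d["success"] and abs(d["fun"] - best.fun) < 1e-6 for d in diags)
    if not converged and best.fun >= 1e12:
        raise ConvergenceError(
            "optimizer did not converge", best_params=best.x, diagnostics=diags
        )

    theta = best.x
    beta, XtWX, rss, logdet, N = _profiled_pieces(
        theta, groups, p, re_blocks, ar1, n_groups
    )
    G, rho, ratios = _unpack_theta(theta, re_blocks, ar1, n_groups)
    dof = N - p if criterion == "REML" else N
    sigma2 = rss / dof
    cov_beta = sigma2 * np.linalg.inv(XtWX)
    loglik = -0.5 * _neg2ll(theta, *args)
    n_var_params = len(theta) + 1  # shape parameters + profiled sigma
    names = list(data.x_names)
    return FittedModel(
        beta=pd.Series(beta, index=names),
        se=pd.Series(np.sqrt(np.diag(cov_beta)), index=names),
        cov_beta=pd.DataFrame(cov_beta, index=names, columns=names),
        Sigma_b=sigma2 * G,
        sigma=float(np.sqrt(sigma2)),
        rho=rho,
        var_ratio=ratios,
        loglik=float(loglik),
        criterion=criterion,
        ar1=ar1,
        n_params=data.p + n_var_params,
        x_names=names,
        z_names=list(data.z_names),
        re_blocks=re_blocks,
        converged=converged,
        diagnostics={"starts": diags},
        theta=theta,
    )


def gls(
    data: MixedModelData,
    Sigma_b: np.ndarray | None = None,
    sigma: float = 1.0,
    rho: float = 0.0,
    var_ratio=(1.0,),
) -> tuple[pd.Series, pd.DataFrame]:
    """Generalized-least-squares fixed effects at *fixed* variance parameters.

    With ``Sigma_b = 0`` and ``rho = 0`` this is exactly ordinary least
    squares — the mixed model collapses when the variance components vanish.
    Returns (beta, covariance of beta).
    """
    q = data.q
    Sb = np.zeros((q, q)) if Sigma_b is None else np.asarray(Sigma_b, dtype=float)
    ratios = np.asarray(var_ratio, dtype=float)
    p = data.p
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    for b in data.blocks:
        slots = np.asarray(b.slots, dtype=float)
        D = np.abs(slots[:, None] - slots[None, :])
        d2 = ratios[b.var_group] ** 2 if b.var_group < ratios.size else 1.0
        V = b.Z @ Sb @ b.Z.T + sigma**2 * d2 * _corr(D, rho)
        VX = np.linalg.solve(V, b.X)
        XtVX += b.X.T @ VX
        XtVy += VX.T @ b.y
    cov = np.linalg.inv(XtVX)
    beta = cov @ XtVy
    return (
        pd.Series(beta, index=data.x_names),
        pd.DataFrame(cov, index=data.x_names, columns=data.x_names),
    )


def make_params(
    beta,
    Sigma_b,
    sigma: float,
    rho: float = 0.0,
    var_ratio=(1.0,),
    x_names=None,
    z_names=None,
    criterion: str = "ML",
    ar1: bool = True,
) -> FittedModel:
    """Assemble a :class:`FittedModel` from explicit parameter values.

    Useful for evaluating the likelihood at known truth, simulating from a
    hypothetical model, or seeding a fit.
    """
    beta = np.asarray(beta, dtype=float)
    p = beta.size
    names = list(x_names) if x_names is not None else [f"x{i}" for i in range(p)]
    Sigma_b = np.asarray(Sigma_b, dtype=float)
    zn = list(z_names) if z_names is not None else [f"z{i}" for i in range(Sigma_b.shape[0])]
    nan = np.full(p, np.nan)
    return FittedModel(
        beta=pd.Series(beta, index=names),
        se=pd.Series(nan, index=names),
        cov_beta=pd.DataFrame(np.full((p, p), np.nan), index=names, columns=names),
        Sigma_b=Sigma_b,
        sigma=float(sigma),
        rho=float(rho),
        var_ratio=np.asarray(var_ratio, dtype=float),
        loglik=np.nan,
        criterion=criterion,
        ar1=ar1,
        n_params=p + _n_chol(Sigma_b.shape[0]) + 1 + int(ar1) + (len(var_ratio) - 1),
        x_names=names,
        z_names=zn,
        re_blocks=(Sigma_b.shape[0],),
    )


def _block_V(fitted: FittedModel, b: SubjectBlock) -> np.ndarray:
    slots = np.asarray(b.slots, dtype=float)
    D = np.abs(slots[:, None] - slots[None, :])
    R = _corr(D, fitted.rho)
    d2 = fitted.var_ratio[b.var_group] ** 2 if b.var_group < len(fitted.var_ratio) else 1.0
    return b.Z @ fitted.Sigma_b @ b.Z.T + fitted.sigma**2 * d2 * R


def eblup(fitted: FittedModel, data: MixedModelData) -> pd.DataFrame:
    """Empirical best linear unbiased predictors of each subject's random
    effects: ``b_i = Sigma_b Z_i' V_i^{-1} (y_i - X_i beta)``."""
    beta = fitted.beta.to_numpy()
    rows = {}
    for b in data.blocks:
        if b.y.size == 0:
            warnings.warn(f"{b.subject_id}: no readings, EBLUP set to 0")
            rows[b.subject_id] = np.zeros(data.q)
            continue
        V = _block_V(fitted, b)
        resid = b.y - b.X @ beta
        rows[b.subject_id] = fitted.Sigma_b @ b.Z.T @ np.linalg.solve(V, resid)
    return pd.DataFrame.from_dict(rows, orient="index", columns=data.z_names)


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p: float
    p_boundary: float  # 50:50 chi2(df-1)/chi2(df) mixture for variance terms


def lrt(fit_null: FittedModel, fit_alt: FittedModel) -> LRTResult:
    """Likelihood-ratio test of nested fits sharing the same criterion.

    REML comparisons require identical fixed effects; compare fixed effects
    with ML refits.  ``p_boundary`` applies the 50:50 chi-square mixture
    appropriate when the null pins a variance component at its boundary.
    """
    if fit_null.criterion != fit_alt.criterion:
        raise ValueError("fits use different criteria (REML vs ML)")
    if fit_null.criterion == "REML" and list(fit_null.x_names) != list(fit_alt.x_names):
        raise ValueError(
            "REML log-likelihoods are not comparable across different fixed "
            "effects; refit with criterion='ML'"
        )
    statistic = 2.0 * (fit_alt.loglik - fit_null.loglik)
    df = fit_alt.n_params - fit_null.n_params
    if df < 0:
        raise ValueError("null model has more parameters than the alternative")
    statistic = max(statistic, 0.0)
    if df == 0:
        return LRTResult(statistic, 0, 1.0, 1.0)
    p = float(stats.chi2.sf(statistic, df))
    lower = float(stats.chi2.sf(statistic, df - 1)) if df > 1 else float(statistic <= 0)
    p_mix = 0.5 * lower + 0.5 * p
    return LRTResult(float(statistic), int(df), p, p_mix)


def r2(fitted: FittedModel, data: MixedModelData) -> tuple[float, float]:
    """Marginal and conditional R^2 for the mixed model.

    Variance explained by fixed effects is the variance of ``X beta`` over
    all rows; the random-effect variance uses Johnson's random-slope
    extension, the row-average of ``diag(Z Sigma_b Z')``; the residual
    variance is the (AR(1)-free) marginal residual variance, averaged over
    variance groups by their row counts.
    """
    beta = fitted.beta.to_numpy()
    fixed = np.concatenate([b.X @ beta for b in data.blocks])
    var_f = float(np.var(fixed))
    tr = 0.0
    n = 0
    var_e_num = 0.0
    for b in data.blocks:
        ZS = b.Z @ fitted.Sigma_b
        tr += float(np.einsum("ij,ij->", ZS, b.Z))
        d2 = fitted.var_ratio[b.var_group] ** 2 if b.var_group < len(fitted.var_ratio) else 1.0
        var_e_num += fitted.sigma**2 * d2 * b.y.size
        n += b.y.size
    var_r = tr / n
    var_e = var_e_num / n
    total = var_f + var_r + var_e
    return var_f / total, (var_f + var_r) / total


def residual_acf(fitted: FittedModel, data: MixedModelData, max_lag: int = 10) -> pd.DataFrame:
    """ACF of pre-whitened residuals by nominal slot lag.

    Residuals are whitened by the Cholesky factor of each subject's fitted
    marginal covariance, so under a correct model all lags >= 1 are near 0.
    Returns columns (lag, acf, n_pairs); lag 0 is exactly 1.
    """
    max_block = max(b.y.size for b in data.blocks)
    if max_lag >= max_block:
        warnings.warn(f"max_lag {max_lag} >= longest block; truncating")
        max_lag = max_block - 1
    beta = fitted.beta.to_numpy()
    pairs_num = np.zeros(max_lag + 1)
    pairs_n = np.zeros(max_lag + 1, dtype=int)
    all_e = []
    per_subject = []
    for b in data.blocks:
        V = _block_V(fitted, b)
        L = np.linalg.cholesky(V)
        e = np.linalg.solve(L, b.y - b.X @ beta)
        all_e.append(e)
        per_subject.append((e, np.round(np.asarray(b.slots, dtype=float)).astype(int)))
    e_all = np.concatenate(all_e)
    var = float(np.mean(e_all**2))
    for e, slots in per_subject:
        dif = slots[:, None] - slots[None, :]
        for lag in range(0, max_lag + 1):
            ii, jj = np.where(dif == -lag)
            pairs_num[lag] += float(np.sum(e[ii] * e[jj]))
            pairs_n[lag] += ii.size
    acf = np.where(pairs_n > 0, pairs_num / np.maximum(pairs_n, 1) / var, np.nan)
    acf[0] = 1.0
    return pd.DataFrame({"lag": np.arange(max_lag + 1), "acf": acf, "n_pairs": pairs_n})


def _psd_factor(S: np.ndarray) -> np.ndarray:
    """A factor F with F F' = S for PSD S (exact zeros stay zero)."""
    vals, vecs = np.linalg.eigh((S + S.T) / 2)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def simulate_from_fit(
    fitted: FittedModel, data: MixedModelData, rng: np.random.Generator
) -> list:
    """One replicate of the response at the observed design, drawn from the
    fitted model.  Returns a list of y vectors aligned with ``data.blocks``."""
    out = []
    chol_Sb = _psd_factor(fitted.Sigma_b)
    beta = fitted.beta.to_numpy()
    for b in data.blocks:
        slots = np.asarray(b.slots, dtype=float)
        D = np.abs(slots[:, None] - slots[None, :])
        R = _corr(D, fitted.rho)
        d = fitted.var_ratio[b.var_group] if b.var_group < len(fitted.var_ratio) else 1.0
        Le = np.linalg.cholesky(R + 1e-12 * np.eye(R.shape[0]))
        bi = chol_Sb @ rng.standard_normal(fitted.Sigma_b.shape[0])
        eps = fitted.sigma * d * (Le @ rng.standard_normal(b.y.size))
        out.append(b.X @ beta + b.Z @ bi + eps)
    return out


def vpc(
    fitted: FittedModel,
    data: MixedModelData,
    nsim: int = 200,
    quantiles=(0.05, 0.95),
    seed: int | None = None,
) -> pd.DataFrame:
    """Visual predictive check table per nominal slot.

    Simulates ``nsim`` replicates from the fitted model at the observed
    design and reports, per slot: the simulated mean and quantile band, the
    observed quantiles and the observed count.
    """
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    rng = np.random.default_rng(seed)
    lo_q, hi_q = quantiles
    slot_keys = [np.round(np.asarray(b.slots, dtype=float)).astype(int) for b in data.blocks]
    all_slots = np.unique(np.concatenate(slot_keys))
    obs = {s: [] for s in all_slots}
    for b, keys in zip(data.blocks, slot_keys):
        for s, v in zip(keys, b.y):
            obs[s].append(v)
    # precompute per-block pieces; residual Cholesky reused across replicates
    q = fitted.Sigma_b.shape[0]
    chol_Sb = _psd_factor(fitted.Sigma_b)
    beta = fitted.beta.to_numpy()
    prepared = []
    le_cache: dict = {}
    for b, keys in zip(data.blocks, slot_keys):
        slots = np.asarray(b.slots, dtype=float)
        key = slots.tobytes()
        if key not in le_cache:
            D = np.abs(slots[:, None] - slots[None, :])
            R = _corr(D, fitted.rho)
            le_cache[key] = np.linalg.cholesky(R + 1e-12 * np.eye(R.shape[0]))
        d = fitted.var_ratio[b.var_group] if b.var_group < len(fitted.var_ratio) else 1.0
        prepared.append((b.X @ beta, b.Z, fitted.sigma * d, le_cache[key], keys))
    sim = {s: [] for s in all_slots}
    for _ in range(nsim):
        for mean, Z, sd, Le, keys in prepared:
            bi = chol_Sb @ rng.standard_normal(q)
            y = mean + Z @ bi + sd * (Le @ rng.standard_normal(mean.size))
            for s, v in zip(keys, y):
                sim[s].append(v)
    rows = []
    for s in all_slots:
        sv = np.asarray(sim[s])
        ov = np.asarray(obs[s])
        rows.append(
            {
                "slot": int(s),
                "sim_mean": float(np.mean(sv)),
                "sim_lo": float(np.quantile(sv, lo_q)),
                "sim_hi": float(np.quantile(sv, hi_q)),
                "obs_lo": float(np.quantile(ov, lo_q)) if ov.size else np.nan,
                "obs_hi": float(np.quantile(ov, hi_q)) if ov.size else np.nan,
                "n_obs": int(ov.size),
            }
        )
    return pd.DataFrame(rows)
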
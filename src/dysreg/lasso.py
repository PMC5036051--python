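"""L1-penalised least squares with per-column penalty weights.

The model for one response gene is::

    y = b0 + b_c * CNA + b_m * DM + sum_k b_k * TF_k + eps

minimising  (1/2n) ||y - b0 - X b||^2  +  lambda * sum_{penalised j} |b_j|.

The own-gene CNA and DM columns carry zero penalty weight, so they are never
shrunk to zero: the TF selection is performed conditional on the cis effects.
The solver is cyclic coordinate descent on the Gram matrix (the design is
short and wide-ish: a few hundred samples, up to a couple thousand TFs), with
penalised columns standardised to unit variance internally for the penalty
and all coefficients reported on the original scale.  Warm starts along a
descending lambda path make path and cross-validation fits cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .bundle import OmicsBundle
from .errors import ConvergenceError, InputError


@dataclass
class RegressionDesign:
    """Per-gene response and design columns with the penalty mask."""

    gene: str
    y: np.ndarray
    x_cna: np.ndarray
    x_dm: np.ndarray
    tf_matrix: np.ndarray  # samples x TFs
    tf_names: list[str]

    def __post_init__(self) -> None:
        n = self.y.shape[0]
        if self.x_cna.shape != (n,) or self.x_dm.shape != (n,):
            raise InputError("CNA/DM columns must match the sample axis of y")
        if self.tf_matrix.shape != (n, len(self.tf_names)):
            raise InputError("TF matrix shape does not match sample axis / names")
        if self.gene in self.tf_names:
            raise InputError("response gene must not appear in its own TF block")
        for arr in (self.y, self.x_cna, self.x_dm, self.tf_matrix):
            if not np.isfinite(arr).all():
                raise InputError("non-finite values in regression design")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def X(self) -> np.ndarray:
        return np.column_stack([self.x_cna, self.x_dm, self.tf_matrix])

    @property
    def penalty_mask(self) -> np.ndarray:
        """1.0 for penalised (TF) columns, 0.0 for forced-in CNA/DM."""
        return np.concatenate([np.zeros(2), np.ones(len(self.tf_names))])


@dataclass
class LassoSolution:
    gene: str
    intercept: float
    beta_cna: float
    beta_dm: float
    beta_tf: dict[str, float]  # nonzero coefficients only
    lam: float
    n_iter: int = 0

    @property
    def support(self) -> set[str]:
        return set(self.beta_tf)


def build_design(bundle: OmicsBundle, gene: str) -> RegressionDesign:
    """Assemble the tumour-sample design for one panel gene.  If the response
    gene itself is in the TF list it is removed from its own predictor block."""
    if gene not in bundle.panel_genes:
        raise InputError(f"{gene!r} is not a panel gene in this bundle")
    samples = bundle.tumour_samples
    tf_names = [t for t in bundle.tf_genes if t != gene]
    return RegressionDesign(
        gene=gene,
        y=bundle.expression.loc[samples, gene].to_numpy(dtype=float),
        x_cna=bundle.cna.loc[samples, gene].to_numpy(dtype=float),
        x_dm=bundle.dm.loc[samples, gene].to_numpy(dtype=float),
        tf_matrix=bundle.expression.loc[samples, tf_names].to_numpy(dtype=float),
        tf_names=tf_names,
    )


# ---------------------------------------------------------------------------
# Coordinate-descent kernel (Gram formulation)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sweep_work(G, c, beta, lam, weights, work):  # pragma: no cover - numba
    """One coordinate-descent pass over the work set.

    Exploits sparsity: coordinates outside ``work`` have beta == 0, so the
    partial residual correlation only needs sums over the work set.
    """
    dmax = 0.0
    for ii in range(work.shape[0]):
        j = work[ii]
        gjj = G[j, j]
        if gjj <= 0.0:
            continue
        s = c[j] + gjj * beta[j]
        for kk in range(work.shape[0]):
            k = work[kk]
            if beta[k] != 0.0:
                s -= G[j, k] * beta[k]
        thr = lam * weights[j]
        if s > thr:
            bnew = (s - thr) / gjj
        elif s < -thr:
            bnew = (s + thr) / gjj
        else:
            bnew = 0.0
        d = bnew - beta[j]
        if d != 0.0:
            beta[j] = bnew
            if abs(d) > dmax:
                dmax = abs(d)
    return dmax


@njit(cache=True)
def _cd_gram(G, c, yy, lams, weights, tol, max_sweeps, fdev):  # pragma: no cover
    """Warm-started coordinate descent along a lambda sequence.

    At each lambda: solve restricted to the current work set (nonzero or
    unpenalised coordinates), then verify the KKT conditions for every
    excluded coordinate via one BLAS gradient evaluation, pulling violators
    into the work set; converged when no violators remain and the final pass
    moved every coordinate by < tol.

    ``yy`` is mean(y_centered^2).  When ``fdev > 0`` the path stops early
    once the training deviance ratio gains less than ``fdev`` between
    successive lambdas (or exceeds 0.999); remaining rows repeat the last
    solution.  Used for cross-validation paths, where the flat tail cannot
    change the selected lambda.
    """
    nlam = lams.shape[0]
    p = G.shape[0]
    B = np.zeros((nlam, p))
    beta = np.zeros(p)
    sweeps = np.zeros(nlam, dtype=np.int64)
    prev_dev = 0.0
    for li in range(nlam):
        lam = lams[li]
        used = 0
        inwork = (beta != 0.0) | (weights == 0.0)
        work = np.nonzero(inwork)[0]
        grad = c - G @ beta
        while used < max_sweeps:
            while used < max_sweeps:
                dmax = _sweep_work(G, c, beta, lam, weights, work)
                used += 1
                if dmax < tol:
                    break
            # KKT check over all coordinates (BLAS matrix-vector product)
            grad = c - G @ beta
            nviol = 0
            for j in range(p):
                if not inwork[j] and abs(grad[j]) > lam * weights[j] + 1e-12:
                    inwork[j] = True
                    nviol += 1
            if nviol == 0:
                break
            work = np.nonzero(inwork)[0]
        sweeps[li] = used
        B[li] = beta
        if fdev > 0.0 and yy > 0.0:
            # RSS/n = yy - c.beta - beta.grad at the converged solution
            rss = yy - np.dot(c, beta) - np.dot(beta, grad)
            dev = 1.0 - rss / yy
            if li > 0 and (dev - prev_dev < fdev or dev > 0.999):
                for rest in range(li + 1, nlam):
                    B[rest] = beta
                break
            prev_dev = dev
    return B, sweeps


def _standardize(X: np.ndarray, y: np.ndarray):
    """Center everything; scale columns to unit (population) SD.  Constant
    columns get scale 1 and a zeroed column, so they simply stay at zero."""
    xm = X.mean(axis=0)
    Xc = X - xm
    sd = Xc.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = Xc / sd_safe
    ym = float(y.mean())
    return Xs, y - ym, xm, sd_safe, ym


def _unscale(B_std: np.ndarray, xm, sd, ym):
    """Map standardized-scale coefficient rows back to the original scale."""
    B = B_std / sd
    icept = ym - B @ xm
    return B, icept


def lambda_max(design: RegressionDesign) -> float:
    """Smallest lambda at which every penalised coefficient is zero: the max
    absolute correlation of a standardised TF column with the residual of y
    on the forced-in block."""
    Xs, yc, *_ = _standardize(design.X, design.y)
    U = Xs[:, :2]
    coef, *_ = np.linalg.lstsq(U, yc, rcond=None)
    r = yc - U @ coef
    return float(np.max(np.abs(Xs[:, 2:].T @ r)) / design.n)


def lambda_path(
    design: RegressionDesign, ratio: float = 1e-3, n_points: int = 100
) -> np.ndarray:
    lmax = lambda_max(design)
    if lmax <= 0:
        lmax = np.finfo(float).tiny
    return np.geomspace(lmax, lmax * ratio, n_points)


def _fit_path_standardized(
    Xs: np.ndarray,
    yc: np.ndarray,
    lams: np.ndarray,
    weights: np.ndarray,
    tol: float,
    max_sweeps: int,
    fdev: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    n = Xs.shape[0]
    G = (Xs.T @ Xs) / n
    c = (Xs.T @ yc) / n
    yy = float(np.mean(yc**2))
    return _cd_gram(
        np.ascontiguousarray(G), c, yy, np.asarray(lams, dtype=float), weights,
        tol, max_sweeps, fdev,
    )


def fit_constrained_lasso(
    design: RegressionDesign,
    lam: float,
    tol: float = 1e-7,
    max_sweeps: int = 100_000,
) -> LassoSolution:
    """Solve at a single lambda.  CNA and DM are never penalised."""
    if lam < 0:
        raise InputError("lambda must be >= 0")
    if design.n < 3:
        raise InputError("need at least 3 samples")
    Xs, yc, xm, sd, ym = _standardize(design.X, design.y)
    B_std, sweeps = _fit_path_standardized(
        Xs, yc, np.array([lam]), design.penalty_mask, tol, max_sweeps
    )
    if sweeps[0] >= max_sweeps:
        raise ConvergenceError(
            f"coordinate descent did not reach tol={tol} in {max_sweeps} sweeps"
        )
    B, icept = _unscale(B_std, xm, sd, ym)
    b = B[0]
    beta_tf = {
        name: float(b[j + 2])
        for j, name in enumerate(design.tf_names)
        if B_std[0, j + 2] != 0.0
    }
    return LassoSolution(
        gene=design.gene,
        intercept=float(icept[0]),
        beta_cna=float(b[0]),
        beta_dm=float(b[1]),
        beta_tf=beta_tf,
        lam=float(lam),
        n_iter=int(sweeps[0]),
    )


# ---------------------------------------------------------------------------
# Cross-validated lambda draws
# ---------------------------------------------------------------------------

@dataclass
class PathParams:
    """Lambda-path and solver settings shared by CV and final fits."""

    ratio: float = 1e-3
    n_points: int = 100
    tol: float = 1e-7
    max_sweeps: int = 100_000
    folds: int = 10
    rule: str = "1se"  # or "min"
    #: looser update tolerance for CV path fits: the selected lambda is a
    #: grid argmin and does not move under 1e-4-scale coefficient wiggle
    cv_tol: float = 1e-4
    #: deviance-plateau early stop for CV path fits (0 disables); the flat
    #: tail of the path cannot change the CV-selected lambda
    cv_fdev: float = 1e-5


def _cv_one_repeat(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    path: np.ndarray,
    fold_ids: np.ndarray,
    params: PathParams,
) -> np.ndarray:
    """Mean test MSE per lambda over the folds of one CV repeat."""
    folds = int(fold_ids.max()) + 1
    mse = np.empty((folds, path.size))
    for f in range(folds):
        te = fold_ids == f
        tr = ~te
        Xs, yc, xm, sd, ym = _standardize(X[tr], y[tr])
        B_std, _ = _fit_path_standardized(
            Xs, yc, path, weights, params.cv_tol, params.max_sweeps, params.cv_fdev
        )
        B, icept = _unscale(B_std, xm, sd, ym)
        pred = X[te] @ B.T + icept
        mse[f] = np.mean((y[te, None] - pred) ** 2, axis=0)
    return mse


def draw_lambdas(
    design: RegressionDesign,
    repeats: int = 100,
    seed: int | np.random.Generator = 0,
    params: PathParams | None = None,
) -> np.ndarray:
    """One cross-validated lambda per repeat, fold assignment re-randomised
    each time.

    Each repeat runs K-fold CV over a shared geometric lambda path (computed
    on the full data) and returns the MSE-minimising lambda ("min" rule) or
    the largest lambda within one standard error of the minimum ("1se").
    The spread of the returned values is the stability-selection driver.
    """
    params = params or PathParams()
    if repeats < 1:
        raise InputError("repeats must be >= 1")
    if params.folds < 2 or design.n < params.folds:
        raise InputError("need folds >= 2 and n >= folds")
    rng = np.random.default_rng(seed)
    X, y = design.X, design.y
    weights = design.penalty_mask
    path = lambda_path(design, params.ratio, params.n_points)
    n = design.n
    out = np.empty(repeats)
    base = np.arange(n) % params.folds
    for r in range(repeats):
        fold_ids = base[rng.permutation(n)]
        mse = _cv_one_repeat(X, y, weights, path, fold_ids, params)
        mean = mse.mean(axis=0)
        imin = int(np.argmin(mean))
        if params.rule == "min":
            out[r] = path[imin]
        elif params.rule == "1se":
            se = mse.std(axis=0, ddof=1) / np.sqrt(mse.shape[0])
            ok = np.nonzero(mean <= mean[imin] + se[imin])[0]
            out[r] = path[ok[0]]  # path is descending: first ok = largest lambda
        else:
            raise InputError(f"unknown lambda rule {params.rule!r}")
    return out


def fit_at_lambdas(
    design: RegressionDesign,
    lambdas: np.ndarray,
    params: PathParams | None = None,
) -> np.ndarray:
    """Standardized-scale TF support matrix (len(lambdas) x n_tfs booleans)
    from warm-started full-data fits at each requested lambda."""
    params = params or PathParams()
    lambdas = np.asarray(lambdas, dtype=float)
    order = np.argsort(lambdas)[::-1]
    Xs, yc, *_ = _standardize(design.X, design.y)
    B_std, sweeps = _fit_path_standardized(
        Xs, yc, lambdas[order], design.penalty_mask, params.tol, params.max_sweeps
    )
    if int(sweeps.max(initial=0)) >= params.max_sweeps:
        raise ConvergenceError("coordinate descent did not converge on the path")
    support = np.empty((lambdas.size, len(design.tf_names)), dtype=bool)
    support[order] = B_std[:, 2:] != 0.0
    return support
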
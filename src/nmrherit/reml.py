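"""Restricted maximum likelihood for the plot-level mixed model.

The univariate model for one response vector y (a metabolomic feature or a
malting-quality trait) is

    y = X b + Z_g g + Z_l l + Z_ig ig + Z_il il + Z_t t + e

with fixed location x year x trial cell effects b and independent random
terms

    g  ~ N(0, G sigma_g^2)            additive genomic line effects
    l  ~ N(0, I sigma_l^2)            non-genomic line effects
    ig ~ N(0, diag(G,...,G) sigma_ig^2)  genomic line x environment effects
    il ~ N(0, I sigma_il^2)           non-genomic line x environment effects
    t  ~ N(0, I sigma_t^2)            malting-batch effects
    e  ~ N(0, I sigma_e^2)            residual

where G is the genomic relationship matrix and the block-diagonal
structure of ig repeats G once per location x year environment.

Estimation maximizes the restricted log-likelihood over nonnegative
components with expectation-maximization warm-start iterations followed by
average-information (AI) updates with step-halving; components whose update
goes negative are pinned at zero and freed again if their gradient turns
positive.  Standard errors come from the inverse AI matrix at convergence.

The bivariate model expands every dispersion parameter to a 2x2 covariance
block (Model 1 as sub-model per response); responses may be observed on
different plot subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .design import PlotDesign
from .grm import GenomicRelationship

logger = logging.getLogger(__name__)

#: canonical order of the model's dispersion terms (residual last)
TERM_NAMES = ("g", "l", "ig", "il", "t", "e")


class RemlError(RuntimeError):
    """REML failure; carries the last iterate when convergence failed."""

    def __init__(self, message: str, last_estimates=None, grad_norm=None):
        super().__init__(message)
        self.last_estimates = last_estimates
        self.grad_norm = grad_norm


# --------------------------------------------------------------- model spec


@dataclass
class ModelSpec:
    """Response, full-rank fixed-effect matrix and dense covariance
    structures of all random terms (residual structure is the identity)."""

    y: np.ndarray
    X: np.ndarray
    term_names: tuple
    structures: list  # dense n x n structure matrix per non-residual term
    n_levels: np.ndarray  # levels per term incl. residual (EM scaling)
    plot_index: np.ndarray  # rows of the original design retained
    dropped_fixed: int = 0
    inestimable: tuple = ()

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_params(self) -> int:
        return len(self.structures) + 1

    def with_response(self, y: np.ndarray) -> "ModelSpec":
        """Same design, new response (must be fully observed on the same
        rows); reuses the precomputed structures."""
        y = np.asarray(y, float)
        if y.shape != self.y.shape or not np.isfinite(y).all():
            raise ValueError("replacement response must be finite and same length")
        return ModelSpec(
            y, self.X, self.term_names, self.structures, self.n_levels,
            self.plot_index, self.dropped_fixed, self.inestimable,
        )


def _full_rank_dummies(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """One-hot matrix of labels reduced to full column rank by dropping
    trailing collinear columns in data order (deterministic)."""
    cats, codes = np.unique(labels, return_inverse=True)
    X = np.zeros((len(labels), len(cats)))
    X[np.arange(len(labels)), codes] = 1.0
    # greedy Gram-Schmidt rank filter in column order
    Q: list[np.ndarray] = []
    keep = []
    for j in range(X.shape[1]):
        r = X[:, j].copy()
        for q in Q:
            r -= q * (q @ X[:, j])
        nr = np.linalg.norm(r)
        if nr > 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
            Q.append(r / nr)
            keep.append(j)
    return X[:, keep], X.shape[1] - len(keep)


def build_design(
    design: PlotDesign,
    grm: GenomicRelationship,
    response: np.ndarray,
    term_names: tuple = TERM_NAMES[:-1],
) -> ModelSpec:
    """Assemble the mixed-model design for one response.

    Rows with missing response are dropped.  The fixed-effect matrix holds
    location x year x trial cells reduced to full column rank; each random
    term's covariance structure is materialized as a dense n x n matrix
    (G gathers for the genomic terms, equality indicators otherwise).
    """
    response = np.asarray(response, float)
    if len(response) != design.n_plots:
        raise ValueError("response length does not match plot count")
    rows = np.flatnonzero(np.isfinite(response))
    if rows.size == 0:
        raise ValueError("response has no observed values")
    sub = design.subset(np.isfinite(response))
    y = response[rows]

    gidx = {l: i for i, l in enumerate(grm.line_ids)}
    missing = sorted({str(l) for l in sub.line_ids if l not in gidx})
    if missing:
        raise KeyError(f"lines absent from G: {missing[:5]}")
    li = np.array([gidx[l] for l in sub.line_ids])
    env = sub.environment().to_numpy()
    _, env_code = np.unique(env, return_inverse=True)
    _, batch_code = np.unique(sub.table["batch"].to_numpy(), return_inverse=True)

    X, dropped = _full_rank_dummies(sub.cell().to_numpy())

    same_line = (li[:, None] == li[None, :]).astype(float)
    same_env = (env_code[:, None] == env_code[None, :]).astype(float)
    Vg = grm.G[np.ix_(li, li)]
    structures_all = {
        "g": Vg,
        "l": same_line,
        "ig": Vg * same_env,
        "il": same_line * same_env,
        "t": (batch_code[:, None] == batch_code[None, :]).astype(float),
    }
    n_lines = len(np.unique(li))
    n_env = len(np.unique(env_code))
    levels_all = {
        "g": n_lines,
        "l": n_lines,
        "ig": n_lines * n_env,
        "il": len({(a, b) for a, b in zip(li, env_code)}),
        "t": len(np.unique(batch_code)),
        "e": len(rows),
    }
    structures = [structures_all[t] for t in term_names]
    inestimable = tuple(
        t for t in term_names
        if levels_all[t] <= 1 or np.ptp(structures_all[t]) == 0
    )
    if inestimable:
        logger.warning("terms with a single level (variance inestimable): %s", inestimable)
    n_levels = np.array([levels_all[t] for t in term_names] + [levels_all["e"]], float)
    return ModelSpec(
        y=y, X=X, term_names=tuple(term_names) + ("e",),
        structures=structures, n_levels=n_levels, plot_index=rows,
        dropped_fixed=dropped, inestimable=inestimable,
    )


# --------------------------------------------------------- likelihood kernel


def _projection(model_X: np.ndarray, V: np.ndarray):
    """Cholesky-based REML kernel: returns (P, logdetV, logdetXtViX)."""
    n = V.shape[0]
    c, low = sla.cho_factor(V, lower=True, check_finite=False)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vi = sla.cho_solve((c, low), np.eye(n), check_finite=False)
    ViX = Vi @ model_X
    XtViX = model_X.T @ ViX
    cx, lowx = sla.cho_factor(XtViX, lower=True, check_finite=False)
    logdetX = 2.0 * float(np.sum(np.log(np.diag(cx))))
    P = Vi - ViX @ sla.cho_solve((cx, lowx), ViX.T, check_finite=False)
    return P, logdetV, logdetX


def _build_V(model: ModelSpec, theta: np.ndarray) -> np.ndarray:
    V = np.eye(model.n) * theta[-1]
    for th, S in zip(theta[:-1], model.structures):
        if th != 0.0:
            V += th * S
    return V


def restricted_loglik(model: ModelSpec, components: np.ndarray) -> float:
    """Restricted log-likelihood of y under V = sum_k sigma_k^2 Z_k A_k Z_k'
    + I sigma_e^2, profiled over the fixed effects (full constant included)."""
    theta = np.asarray(components, float)
    if theta.shape != (model.n_params,):
        raise ValueError(f"expected {model.n_params} components")
    if (theta < 0).any() or not theta.any():
        raise ValueError("components must be nonnegative and not all zero")
    V = _build_V(model, theta)
    try:
        P, logdetV, logdetX = _projection(model.X, V)
    except np.linalg.LinAlgError as exc:
        raise RemlError(f"singular V at components {theta}") from exc
    ypy = float(model.y @ (P @ model.y))
    nr = model.n - model.X.shape[1]
    return -0.5 * (logdetV + logdetX + ypy + nr * np.log(2.0 * np.pi))


@dataclass
class VarianceComponents:
    """REML estimates of the model's variance components.

    ``cov`` is the asymptotic covariance of the estimates (inverse AI matrix
    at convergence; rows/columns of components pinned at zero are zero).
    """

    term_names: tuple
    estimates: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    pinned: np.ndarray
    n_obs: int

    def __getitem__(self, name: str) -> float:
        return float(self.estimates[self.term_names.index(name)])

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def as_dict(self) -> dict:
        return {t: float(v) for t, v in zip(self.term_names, self.estimates)}


def _ll_and_derivs(model: ModelSpec, theta: np.ndarray):
    """Log-likelihood, gradient and AI matrix at theta."""
    V = _build_V(model, theta)
    P, logdetV, logdetX = _projection(model.X, V)
    Py = P @ model.y
    ypy = float(model.y @ Py)
    nr = model.n - model.X.shape[1]
    ll = -0.5 * (logdetV + logdetX + ypy + nr * np.log(2.0 * np.pi))
    K = model.n_params
    w = np.empty((K, model.n))
    trPV = np.empty(K)
    for k in range(K - 1):
        S = model.structures[k]
        w[k] = S @ Py
        trPV[k] = float(np.sum(P * S))
    w[K - 1] = Py
    trPV[K - 1] = float(np.trace(P))
    quad = w @ Py  # y'P Vk P y
    grad = -0.5 * (trPV - quad)
    Pw = P @ w.T
    AI = 0.5 * (w @ Pw)
    return ll, grad, AI, quad, trPV


def reml_fit(
    model: ModelSpec,
    start: np.ndarray | None = None,
    n_em: int = 5,
    max_iter: int = 200,
    ll_tol: float = 1e-8,
    grad_tol: float = 1e-6,
) -> VarianceComponents:
    """Fit the variance components by EM warm-start + AI-REML.

    Convergence requires both the relative log-likelihood change below
    ``ll_tol`` and the scale-invariant gradient norm of the free components
    below ``grad_tol``.  Raises :class:`RemlError` on non-convergence,
    carrying the last iterate.
    """
    y = model.y
    vary = float(np.var(y, ddof=1)) if model.n > 1 else 0.0
    if vary <= 0.0:
        raise RemlError("response is constant; likelihood is degenerate")
    K = model.n_params
    if start is not None:
        theta = np.asarray(start, float).copy()
        if theta.shape != (K,):
            raise ValueError(f"start must have {K} entries")
        theta = np.maximum(theta, 1e-8 * vary)
    else:
        theta = np.full(K, 0.5 * vary / max(K - 1, 1))
        theta[-1] = 0.5 * vary
    gscale = vary / model.n  # makes the gradient criterion scale-invariant

    ll, grad, AI, quad, trPV = _ll_and_derivs(model, theta)
    n_iter = 0
    for it in range(n_em):
        n_iter += 1
        theta = np.maximum(theta + theta**2 / model.n_levels * (quad - trPV), 0.0)
        theta = np.maximum(theta, 1e-10 * vary)  # keep V positive definite
        new_ll, grad, AI, quad, trPV = _ll_and_derivs(model, theta)
        ll = new_ll

    pinned = np.zeros(K, dtype=bool)
    converged = False
    gmax = np.inf
    for it in range(max_iter):
        n_iter += 1
        tol_ll = ll_tol * (1.0 + abs(ll))
        # free a pinned component when its gradient turns positive
        pinned &= ~(pinned & (grad > 0.0))
        free = ~pinned
        AIf = AI[np.ix_(free, free)]
        try:
            delta = np.linalg.solve(AIf + 1e-12 * np.eye(free.sum()), grad[free])
        except np.linalg.LinAlgError:
            delta = grad[free] * gscale
        cap = 10.0 * max(vary, float(theta.max()))
        dmax = float(np.abs(delta).max()) if delta.size else 0.0
        if dmax > cap:
            delta = delta * (cap / dmax)
        step = 1.0
        d_ll = 0.0
        accepted = False
        for _ in range(30):
            cand = theta.copy()
            cand[free] = theta[free] + step * delta
            newly_pinned = free & (cand < 0.0)
            cand = np.maximum(cand, 0.0)
            cand[pinned] = 0.0
            if cand[-1] <= 0.0 or not cand.any():
                step *= 0.5
                continue
            try:
                res = _ll_and_derivs(model, cand)
            except np.linalg.LinAlgError:
                step *= 0.5
                continue
            if res[0] > ll:
                theta = cand
                pinned = pinned | newly_pinned
                d_ll = res[0] - ll
                ll, grad, AI, quad, trPV = res
                accepted = True
                break
            step *= 0.5
        free = ~pinned & (theta > 0)
        gmax = np.max(np.abs(grad[free]) * gscale) if free.any() else 0.0
        if accepted and d_ll >= tol_ll and gmax >= grad_tol:
            continue
        if gmax < grad_tol and (not accepted or d_ll < tol_ll):
            converged = True
            break
        # AI progress exhausted but the gradient is not flat (typically a
        # boundary); EM is a guaranteed-ascent direction -- if it cannot
        # improve the likelihood beyond tolerance either, we are at the
        # constrained maximum
        em = np.maximum(theta + theta**2 / model.n_levels * (quad - trPV), 0.0)
        em[pinned] = 0.0
        if em[-1] <= 0.0:
            em[-1] = theta[-1]
        em_gain = 0.0
        try:
            res = _ll_and_derivs(model, em)
            if res[0] > ll:
                em_gain = res[0] - ll
                theta = em
                ll, grad, AI, quad, trPV = res
        except np.linalg.LinAlgError:
            pass
        if max(d_ll, em_gain) < tol_ll:
            converged = True
            break
    if not converged:
        raise RemlError(
            f"REML did not converge in {n_iter} iterations (|grad|={gmax:.3e})",
            last_estimates=theta, grad_norm=gmax,
        )
    free = ~pinned & (theta > 0)
    cov = np.zeros((K, K))
    if free.any():
        try:
            cov[np.ix_(free, free)] = np.linalg.inv(AI[np.ix_(free, free)])
        except np.linalg.LinAlgError:
            cov[np.ix_(free, free)] = np.linalg.pinv(AI[np.ix_(free, free)])
    theta = np.where(theta < 1e-9 * vary, 0.0, theta)  # snap numerical zeros
    return VarianceComponents(
        term_names=model.term_names, estimates=theta, cov=cov, loglik=ll,
        converged=True, n_iter=n_iter, pinned=pinned | (theta == 0), n_obs=model.n,
    )


# ----------------------------------------------------------- bivariate model


@dataclass
class BivariateModel:
    """Stacked two-response model; every term carries 2x2 covariance blocks.

    Responses may be observed on different plot subsets; block structures
    are cut from the full-plot structure matrices accordingly.
    """

    y: np.ndarray  # stacked (n1 + n2,)
    X: np.ndarray  # blockdiag of per-response fixed-effect matrices
    n1: int
    n2: int
    term_names: tuple
    blocks11: list
    blocks12: list
    blocks22: list
    n_levels: np.ndarray
    n_fixed1: int = 0  # columns of the first response's fixed-effect block

    def univariate_model(self, which: int) -> ModelSpec:
        """The single-response sub-model (used for warm starts)."""
        if which == 0:
            rows, y = slice(0, self.n1), self.y[: self.n1]
            X = self.X[: self.n1, : self.n_fixed1]
            blocks = self.blocks11
        else:
            rows, y = slice(self.n1, self.n), self.y[self.n1 :]
            X = self.X[self.n1 :, self.n_fixed1 :]
            blocks = self.blocks22
        return ModelSpec(
            y=y, X=X, term_names=self.term_names,
            structures=[b for b in blocks[:-1]], n_levels=self.n_levels,
            plot_index=np.arange(y.size),
        )

    @property
    def n(self) -> int:
        return self.n1 + self.n2

    @property
    def n_terms(self) -> int:
        return len(self.term_names)

    def param_names(self) -> list[str]:
        out = []
        for t in self.term_names:
            out += [f"{t}:v1", f"{t}:c12", f"{t}:v2"]
        return out


def build_bivariate(
    design: PlotDesign,
    grm: GenomicRelationship,
    y1: np.ndarray,
    y2: np.ndarray,
) -> BivariateModel:
    """Assemble the stacked bivariate design for two responses measured on
    (possibly different subsets of) the same plots."""
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    if len(y1) != design.n_plots or len(y2) != design.n_plots:
        raise ValueError("responses must be given on all design plots (NaN = missing)")
    for name, y in (("first", y1), ("second", y2)):
        obs = y[np.isfinite(y)]
        if obs.size < 2 or np.ptp(obs) == 0:
            raise ValueError(f"{name} response is constant or unobserved")
    rows1 = np.flatnonzero(np.isfinite(y1))
    rows2 = np.flatnonzero(np.isfinite(y2))
    if not np.intersect1d(rows1, rows2).size:
        raise ValueError("responses share no plots")

    gidx = {l: i for i, l in enumerate(grm.line_ids)}
    missing = sorted({str(l) for l in design.line_ids if l not in gidx})
    if missing:
        raise KeyError(f"lines absent from G: {missing[:5]}")
    li = np.array([gidx[l] for l in design.line_ids])
    env = design.environment().to_numpy()
    _, env_code = np.unique(env, return_inverse=True)
    _, batch_code = np.unique(design.table["batch"].to_numpy(), return_inverse=True)

    same_line = (li[:, None] == li[None, :]).astype(float)
    same_env = (env_code[:, None] == env_code[None, :]).astype(float)
    Vg = grm.G[np.ix_(li, li)]
    full = {
        "g": Vg,
        "l": same_line,
        "ig": Vg * same_env,
        "il": same_line * same_env,
        "t": (batch_code[:, None] == batch_code[None, :]).astype(float),
        "e": np.eye(design.n_plots),
    }
    names = TERM_NAMES
    b11 = [full[t][np.ix_(rows1, rows1)] for t in names]
    b12 = [full[t][np.ix_(rows1, rows2)] for t in names]
    b22 = [full[t][np.ix_(rows2, rows2)] for t in names]

    cells = design.cell().to_numpy()
    X1, _ = _full_rank_dummies(cells[rows1])
    X2, _ = _full_rank_dummies(cells[rows2])
    X = sla.block_diag(X1, X2)
    n_lines = len(np.unique(li))
    n_env = len(np.unique(env_code))
    n_levels = np.array(
        [n_lines, n_lines, n_lines * n_env,
         len({(a, b) for a, b in zip(li, env_code)}),
         len(np.unique(batch_code)), len(rows1) + len(rows2)], float,
    )
    return BivariateModel(
        y=np.concatenate([y1[rows1], y2[rows2]]), X=X, n1=len(rows1), n2=len(rows2),
        term_names=names, blocks11=b11, blocks12=b12, blocks22=b22, n_levels=n_levels,
        n_fixed1=X1.shape[1],
    )


@dataclass
class BivariateComponents:
    """Per-term 2x2 covariance blocks with the asymptotic parameter
    covariance (parameter order v1, c12, v2 within each term)."""

    term_names: tuple
    blocks: np.ndarray  # (n_terms, 2, 2)
    cov: np.ndarray  # (3K, 3K)
    loglik: float
    converged: bool
    n_iter: int
    pinned: np.ndarray
    n_obs: tuple

    def block(self, name: str) -> np.ndarray:
        return self.blocks[self.term_names.index(name)]

    def param_slice(self, name: str) -> slice:
        k = self.term_names.index(name)
        return slice(3 * k, 3 * k + 3)

    def univariate(self, which: int) -> np.ndarray:
        """Variance components of one response (0 or 1) in term order."""
        return self.blocks[:, which, which].copy()


def _biv_build_V(model: BivariateModel, theta: np.ndarray) -> np.ndarray:
    n1, n2 = model.n1, model.n2
    V = np.zeros((n1 + n2, n1 + n2))
    for k in range(model.n_terms):
        v1, c, v2 = theta[3 * k : 3 * k + 3]
        if v1:
            V[:n1, :n1] += v1 * model.blocks11[k]
        if v2:
            V[n1:, n1:] += v2 * model.blocks22[k]
        if c:
            V[:n1, n1:] += c * model.blocks12[k]
    V[n1:, :n1] = V[:n1, n1:].T
    return V


def _biv_ll_only(model: BivariateModel, theta: np.ndarray) -> float:
    """Restricted log-likelihood without the O(n^3) explicit inverse
    (used inside step-halving, where derivatives are not needed)."""
    V = _biv_build_V(model, theta)
    c, low = sla.cho_factor(V, lower=True, check_finite=False)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(c))))
    ViX = sla.cho_solve((c, low), model.X, check_finite=False)
    Viy = sla.cho_solve((c, low), model.y, check_finite=False)
    XtViX = model.X.T @ ViX
    cx, lowx = sla.cho_factor(XtViX, lower=True, check_finite=False)
    logdetX = 2.0 * float(np.sum(np.log(np.diag(cx))))
    XtViy = model.X.T @ Viy
    ypy = float(model.y @ Viy) - float(
        XtViy @ sla.cho_solve((cx, lowx), XtViy, check_finite=False)
    )
    nr = model.n - model.X.shape[1]
    return -0.5 * (logdetV + logdetX + ypy + nr * np.log(2.0 * np.pi))


def _biv_ll_and_derivs(model: BivariateModel, theta: np.ndarray):
    n1, n2 = model.n1, model.n2
    V = _biv_build_V(model, theta)
    P, logdetV, logdetX = _projection(model.X, V)
    Py = P @ model.y
    nr = model.n - model.X.shape[1]
    ll = -0.5 * (logdetV + logdetX + float(model.y @ Py) + nr * np.log(2.0 * np.pi))
    npar = 3 * model.n_terms
    w = np.zeros((npar, model.n))
    trPV = np.empty(npar)
    P11, P12, P22 = P[:n1, :n1], P[:n1, n1:], P[n1:, n1:]
    for k in range(model.n_terms):
        S11, S12, S22 = model.blocks11[k], model.blocks12[k], model.blocks22[k]
        j = 3 * k
        w[j, :n1] = S11 @ Py[:n1]
        trPV[j] = float(np.sum(P11 * S11))
        w[j + 1, :n1] = S12 @ Py[n1:]
        w[j + 1, n1:] = S12.T @ Py[:n1]
        trPV[j + 1] = 2.0 * float(np.sum(P12 * S12))
        w[j + 2, n1:] = S22 @ Py[n1:]
        trPV[j + 2] = float(np.sum(P22 * S22))
    quad = w @ Py
    grad = -0.5 * (trPV - quad)
    AI = 0.5 * (w @ (P @ w.T))
    return ll, grad, AI, quad, trPV


def restricted_loglik_bivariate(model: BivariateModel, blocks: np.ndarray) -> float:
    """Restricted log-likelihood at the given (n_terms, 2, 2) blocks."""
    blocks = np.asarray(blocks, float)
    theta = np.stack([blocks[:, 0, 0], blocks[:, 0, 1], blocks[:, 1, 1]], axis=1).ravel()
    ll, *_ = _biv_ll_and_derivs(model, theta)
    return ll


def _observed_cross_correlation(model: BivariateModel) -> float:
    """Pearson correlation of the two responses over shared plots (the
    residual cross-block indicator identifies them); 0 when too few."""
    S12 = model.blocks12[-1]  # residual indicator: 1 where same plot
    i1, i2 = np.nonzero(S12)
    if i1.size < 3:
        return 0.0
    a, b = model.y[: model.n1][i1], model.y[model.n1 :][i2]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.clip(np.corrcoef(a, b)[0, 1], -0.9, 0.9))


def _biv_free_grad_norm(
    grad: np.ndarray, pinned: np.ndarray, theta: np.ndarray, K: int, gscale: float
) -> float:
    """Scale-invariant gradient norm over free, non-boundary parameters
    (at a PSD boundary |r| = 1 the covariance gradient need not vanish)."""
    boundary = np.zeros(3 * K, dtype=bool)
    for k in range(K):
        v1, c, v2 = theta[3 * k : 3 * k + 3]
        if v1 > 0 and v2 > 0 and c * c >= (1.0 - 1e-6) * v1 * v2:
            boundary[3 * k : 3 * k + 3] = True
    check = ~pinned & ~boundary
    return float(np.max(np.abs(grad[check]) * gscale)) if check.any() else 0.0


def _project_psd(theta: np.ndarray, n_terms: int, eps: float = 0.0) -> np.ndarray:
    """Project each 2x2 block onto the PSD cone (eigenvalue clipping)."""
    out = theta.copy()
    for k in range(n_terms):
        v1, c, v2 = out[3 * k : 3 * k + 3]
        B = np.array([[v1, c], [c, v2]])
        w, Q = np.linalg.eigh(B)
        if w[0] < eps:
            B = (Q * np.clip(w, eps, None)) @ Q.T
            out[3 * k : 3 * k + 3] = B[0, 0], B[0, 1], B[1, 1]
    return out


def _biv_ll_and_grad(model: BivariateModel, theta: np.ndarray):
    """Likelihood and gradient w.r.t. the block entries (no AI matrix --
    cheaper inner loop for the quasi-Newton fitter)."""
    n1 = model.n1
    V = _biv_build_V(model, theta)
    P, logdetV, logdetX = _projection(model.X, V)
    Py = P @ model.y
    nr = model.n - model.X.shape[1]
    ll = -0.5 * (logdetV + logdetX + float(model.y @ Py) + nr * np.log(2.0 * np.pi))
    npar = 3 * model.n_terms
    grad = np.empty(npar)
    P11, P12, P22 = P[:n1, :n1], P[:n1, n1:], P[n1:, n1:]
    Py1, Py2 = Py[:n1], Py[n1:]
    for k in range(model.n_terms):
        S11, S12, S22 = model.blocks11[k], model.blocks12[k], model.blocks22[k]
        j = 3 * k
        grad[j] = -0.5 * (float(np.sum(P11 * S11)) - float(Py1 @ (S11 @ Py1)))
        grad[j + 1] = -0.5 * (
            2.0 * float(np.sum(P12 * S12)) - 2.0 * float(Py1 @ (S12 @ Py2))
        )
        grad[j + 2] = -0.5 * (float(np.sum(P22 * S22)) - float(Py2 @ (S22 @ Py2)))
    return ll, grad


def _chol_to_theta(p: np.ndarray, K: int) -> np.ndarray:
    """Map per-term Cholesky parameters (a, b, c) to block entries
    (v1, c12, v2) = (a^2, a b, b^2 + c^2)."""
    a, b, c = p[0::3], p[1::3], p[2::3]
    theta = np.empty(3 * K)
    theta[0::3] = a * a
    theta[1::3] = a * b
    theta[2::3] = b * b + c * c
    return theta


def reml_fit_bivariate(
    model: BivariateModel,
    start: np.ndarray | None = None,
    max_iter: int = 500,
    ll_tol: float = 1e-8,
    grad_tol: float = 1e-6,
    univariate_fits: tuple[VarianceComponents, VarianceComponents] | None = None,
) -> BivariateComponents:
    """REML over the six 2x2 covariance blocks, each parameterized by its
    Cholesky factor.

    Writing a block as ``L L'`` with ``L = [[a, 0], [b, c]]`` turns the
    positive-semidefinite constraint into the simple bounds a, c >= 0, so
    the restricted likelihood can be maximized by a quasi-Newton method
    (L-BFGS-B) with the analytic gradient; boundary solutions |r| = 1
    (c = 0) and pinned zero variances (a = 0) are exactly representable.
    The residual block's parameters are bounded away from zero so the
    stacked covariance matrix stays invertible even for (near-)identical
    responses.

    Warm start: variance entries from the per-response univariate fits
    (fitted here when not supplied) and covariances from the observed
    cross-correlation of the responses, shrunk by half.

    Standard errors come from the inverse AI matrix in the block
    parameterization at the solution (zeroed for pinned parameters).
    """
    from scipy.optimize import minimize

    K = model.n_terms
    y1, y2 = model.y[: model.n1], model.y[model.n1 :]
    v1y, v2y = float(np.var(y1, ddof=1)), float(np.var(y2, ddof=1))
    if v1y <= 0.0 or v2y <= 0.0:
        raise RemlError("a response is constant; likelihood is degenerate")

    if start is not None:
        theta0 = np.asarray(start, float).copy()
        u1 = np.maximum(theta0[0::3], 1e-6 * v1y)
        u2 = np.maximum(theta0[2::3], 1e-6 * v2y)
        c0 = theta0[1::3]
    else:
        if univariate_fits is None:
            try:
                univariate_fits = (
                    reml_fit(model.univariate_model(0)),
                    reml_fit(model.univariate_model(1)),
                )
            except RemlError:
                univariate_fits = None
        if univariate_fits is not None:
            u1 = np.maximum(univariate_fits[0].estimates, 1e-4 * v1y)
            u2 = np.maximum(univariate_fits[1].estimates, 1e-4 * v2y)
        else:
            u1 = np.full(K, 0.5 * v1y / max(K - 1, 1))
            u1[-1] = 0.5 * v1y
            u2 = np.full(K, 0.5 * v2y / max(K - 1, 1))
            u2[-1] = 0.5 * v2y
        # covariance warm start from the observed cross-correlation of the
        # two responses, shrunk; quasi-Newton recovers from a wrong sign
        r_obs = _observed_cross_correlation(model)
        c0 = 0.5 * r_obs * np.sqrt(u1 * u2)

    # Cholesky parameterization of the start
    p0 = np.empty(3 * K)
    p0[0::3] = np.sqrt(u1)
    p0[1::3] = c0 / np.sqrt(u1)
    p0[2::3] = np.sqrt(np.maximum(u2 - p0[1::3] ** 2, 1e-6 * v2y))

    # bounds: a, c >= 0 everywhere; residual a, c strictly positive so V
    # stays positive definite (caps the residual correlation below 1)
    lo = np.zeros(3 * K)
    lo[1::3] = -np.inf
    lo[3 * (K - 1)] = 1e-3 * np.sqrt(v1y)
    lo[3 * (K - 1) + 2] = 1e-3 * np.sqrt(v2y)
    bounds = [(lo[i], np.inf) for i in range(3 * K)]

    n_eval = 0

    def objective(p: np.ndarray):
        nonlocal n_eval
        n_eval += 1
        theta = _chol_to_theta(p, K)
        try:
            ll, g_theta = _biv_ll_and_grad(model, theta)
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e12, np.zeros_like(p)
        a, b, c = p[0::3], p[1::3], p[2::3]
        g_p = np.empty_like(p)
        g_p[0::3] = 2.0 * a * g_theta[0::3] + b * g_theta[1::3]
        g_p[1::3] = a * g_theta[1::3] + 2.0 * b * g_theta[2::3]
        g_p[2::3] = 2.0 * c * g_theta[2::3]
        return -ll, -g_p

    res = minimize(
        objective, p0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "ftol": ll_tol, "gtol": grad_tol, "maxls": 40},
    )
    if not np.isfinite(res.fun) or res.fun >= 1e12:
        raise RemlError("bivariate REML failed: likelihood not evaluable",
                        last_estimates=_chol_to_theta(res.x, K))
    theta = _chol_to_theta(res.x, K)

    # derivatives in the block parameterization at the solution
    ll, grad, AI, quad, trPV = _biv_ll_and_derivs(model, theta)
    scale = np.sqrt(v1y * v2y)
    theta = np.where(np.abs(theta) < 1e-9 * scale, 0.0, theta)
    for k in range(K):  # zero variance forces the block's covariance to zero
        if theta[3 * k] == 0.0 or theta[3 * k + 2] == 0.0:
            theta[3 * k + 1] = 0.0

    pinned = np.zeros(3 * K, dtype=bool)
    boundary = np.zeros(3 * K, dtype=bool)
    for k in range(K):
        v1, c, v2 = theta[3 * k : 3 * k + 3]
        if v1 == 0.0:
            pinned[3 * k] = pinned[3 * k + 1] = True
        if v2 == 0.0:
            pinned[3 * k + 2] = pinned[3 * k + 1] = True
        if v1 > 0 and v2 > 0 and c * c >= (1.0 - 1e-9) * v1 * v2:
            boundary[3 * k + 1] = True  # |r| = 1: SE of c not meaningful
    free = ~pinned
    cov = np.zeros((3 * K, 3 * K))
    if free.any():
        try:
            cov[np.ix_(free, free)] = np.linalg.inv(AI[np.ix_(free, free)])
        except np.linalg.LinAlgError:
            cov[np.ix_(free, free)] = np.linalg.pinv(AI[np.ix_(free, free)])

    blocks = np.empty((K, 2, 2))
    for k in range(K):
        v1, c, v2 = theta[3 * k : 3 * k + 3]
        blocks[k] = [[v1, c], [c, v2]]
    return BivariateComponents(
        term_names=model.term_names, blocks=blocks, cov=cov, loglik=ll,
        converged=True, n_iter=int(res.nit), pinned=pinned,
        n_obs=(model.n1, model.n2),
    )
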
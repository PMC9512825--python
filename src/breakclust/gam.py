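"""Gamma-family generalized additive model for the expected proximity curve.

The background model regresses the observed proximity values on the
per-breakpoint covariates,

    E[y_i] = b0 + FS + LAD + repClass + ChromMark
             + s(RT)·LAD + s(GC)·LAD + s(TAD_recurr)·LAD
             + s(TADB_recurr)·LAD + s(GeneDensity)·LAD
             + te(GeneDensity, TAD_recurr)·TADsegm
             + te(GeneDensity, RT)·TADsegm
             + te(RT, TAD_recurr)·TADsegm

with a Gamma response and identity link.  Smooths are penalized cubic
B-splines (second-order difference penalty) with sum-to-zero
constraints; factor-by terms duplicate a smooth per factor level;
tensor terms take the row-wise Kronecker product of two constrained
marginal bases.  Fitting is penalized IRLS; smoothing parameters are
chosen by GCV on the converged working model.

Proximity values are non-positive, while a Gamma response must be
positive: the model is fitted to the reversed-sign response
``y = -bpp + eps0`` and predictions are reversed back.  This is a
monotone reflection, so the curve's shape is preserved exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.interpolate import BSpline
from scipy.stats import chi2

logger = logging.getLogger(__name__)

#: Floor added when reversing the sign of the response.
EPS0 = 1e-6


@dataclass
class GAMSpec:
    """Model structure: which covariates enter and how."""

    linear_factors: list = field(default_factory=list)
    linear_terms: list = field(default_factory=list)   # continuous, one slope
    smooths: list = field(default_factory=list)      # [(var, by-or-None), ...]
    tensors: list = field(default_factory=list)      # [((v1, v2), by-or-None), ...]
    basis_dim: int = 10
    tensor_basis_dim: int = 5

    def __post_init__(self):
        if self.basis_dim < 4 or self.tensor_basis_dim < 4:
            raise ValueError("basis dimensions must be >= 4")


def default_spec() -> GAMSpec:
    """The full background model with factor-by smooths and tensors."""
    return GAMSpec(
        linear_factors=["FS", "LAD", "repClass", "ChromMark"],
        smooths=[("RT", "LAD"), ("GC", "LAD"), ("TAD_recurr", "LAD"),
                 ("TADB_recurr", "LAD"), ("GeneDensity", "LAD")],
        tensors=[(("GeneDensity", "TAD_recurr"), "TADsegm_class"),
                 (("GeneDensity", "RT"), "TADsegm_class"),
                 (("RT", "TAD_recurr"), "TADsegm_class")],
    )


class _Marginal:
    """A constrained cubic B-spline basis for one variable."""

    def __init__(self, x: np.ndarray, k: int):
        x = np.asarray(x, dtype=float)
        ux = np.unique(x)
        k = int(min(k, max(ux.size, 2)))
        lo, hi = float(ux[0]), float(ux[-1])
        if hi <= lo:
            hi = lo + 1.0
        span = hi - lo
        if k >= 4:
            n_interior = k - 4
            if n_interior > 0:
                qs = np.linspace(0, 1, n_interior + 2)[1:-1]
                interior = np.unique(np.quantile(x, qs))
            else:
                interior = np.array([])
            self.degree = 3
        else:                       # very few distinct values: linear spline
            self.degree = 1
            interior = np.array([])
        t = np.concatenate([
            np.full(self.degree + 1, lo - 1e-8 * span),
            interior,
            np.full(self.degree + 1, hi + 1e-8 * span),
        ])
        self.knots = t
        self.n_basis = len(t) - self.degree - 1
        B = self._raw(x)
        # sum-to-zero constraint over the training data
        C = B.sum(axis=0, keepdims=True)
        self.Z = sla.null_space(C)                      # (n_basis, n_basis-1)
        # second-order difference penalty on coefficients, projected
        if self.n_basis > 2:
            D = np.diff(np.eye(self.n_basis), n=2, axis=0)
        else:
            D = np.zeros((0, self.n_basis))
        S = D.T @ D
        self.S = self.Z.T @ S @ self.Z
        self.ncol = self.Z.shape[1]

    def _raw(self, x):
        x = np.clip(np.asarray(x, dtype=float),
                    self.knots[0] + 1e-12, self.knots[-1] - 1e-12)
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()

    def basis(self, x):
        return self._raw(x) @ self.Z


@dataclass
class Term:
    """One block of design columns with its local penalty."""

    name: str
    kind: str                      # intercept | linear | smooth | tensor
    vars: tuple
    by: str | None
    by_level: object | None
    builder: object                # callable(cov_df) -> (n, ncol) block
    penalty: np.ndarray | None
    ncol: int
    cols: slice | None = None
    penalty_group: str | None = None


def _factor_indicator(cov, by, level):
    return (cov[by].astype(str).to_numpy() == str(level)).astype(float)


def _observed_levels(series: pd.Series) -> list:
    return sorted(pd.unique(series.astype(str)))


class Design:
    """Model matrix plus penalty bookkeeping for a GAMSpec on a dataset."""

    def __init__(self, cov: pd.DataFrame, spec: GAMSpec):
        self.spec = spec
        cov = cov.copy()
        self.medians = {}
        for c in cov.columns:
            if cov[c].dtype.kind == "f":
                med = float(np.nanmedian(cov[c]))
                n_miss = int(cov[c].isna().sum())
                if n_miss:
                    logger.info("covariate %s: %d missing imputed to median", c, n_miss)
                cov[c] = cov[c].fillna(med)
                self.medians[c] = med
        self.terms: list[Term] = [Term("intercept", "intercept", (), None, None,
                                       lambda d: np.ones((len(d), 1)), None, 1)]
        for var in spec.linear_factors:
            self._add_linear(cov, var)
        for var in spec.linear_terms:
            self.terms.append(Term(
                var, "linear", (var,), None, None,
                lambda d, v=var: d[v].to_numpy(float)[:, None], None, 1))
        for var, by in spec.smooths:
            self._add_smooth(cov, var, by, spec.basis_dim)
        for (v1, v2), by in spec.tensors:
            self._add_tensor(cov, v1, v2, by, spec.tensor_basis_dim)
        self.X = self.matrix(cov)
        self.n, self.p = self.X.shape

    # -- term construction -------------------------------------------------
    def _add_linear(self, cov, var):
        series = cov[var]
        if series.nunique() < 2:
            logger.warning("factor %s is constant in the data; dropped", var)
            return
        if series.dtype.kind in "if" and set(np.unique(series)) <= {0, 1, 0.0, 1.0}:
            self.terms.append(Term(
                var, "linear", (var,), None, None,
                lambda d, v=var: d[v].to_numpy(float)[:, None], None, 1))
            return
        levels = _observed_levels(series)
        ref = {"repClass": "none", "ChromMark": "Quies"}.get(var, levels[0])
        keep = [l for l in levels if l != ref]
        if not keep:
            logger.warning("factor %s has a single level; dropped", var)
            return

        def build(d, v=var, ks=tuple(keep)):
            s = d[v].astype(str).to_numpy()
            return np.column_stack([(s == l).astype(float) for l in ks])

        self.terms.append(Term(var, "linear", (var,), None, None, build,
                               None, len(keep)))

    def _smooth_levels(self, cov, by):
        if by is None:
            return [None]
        levels = _observed_levels(cov[by])
        if len(levels) < 2:
            logger.warning("by-factor %s has a single level in the data", by)
        return levels

    def _add_smooth(self, cov, var, by, k):
        marg = _Marginal(cov[var].to_numpy(float), k)
        for level in self._smooth_levels(cov, by):
            def build(d, v=var, m=marg, b=by, l=level):
                B = m.basis(d[v].to_numpy(float))
                if b is None:
                    return B
                return B * _factor_indicator(d, b, l)[:, None]

            name = f"s({var})" + (f":{by}={level}" if by else "")
            self.terms.append(Term(name, "smooth", (var,), by, level, build,
                                   marg.S.copy(), marg.ncol,
                                   penalty_group="smooth"))

    def _add_tensor(self, cov, v1, v2, by, k):
        m1 = _Marginal(cov[v1].to_numpy(float), k)
        m2 = _Marginal(cov[v2].to_numpy(float), k)
        S = np.kron(m1.S, np.eye(m2.ncol)) + np.kron(np.eye(m1.ncol), m2.S)
        for level in self._smooth_levels(cov, by):
            def build(d, a=v1, b=v2, ma=m1, mb=m2, f=by, l=level):
                B1 = ma.basis(d[a].to_numpy(float))
                B2 = mb.basis(d[b].to_numpy(float))
                B = np.einsum("ni,nj->nij", B1, B2).reshape(len(d), -1)
                if f is None:
                    return B
                return B * _factor_indicator(d, f, l)[:, None]

            name = f"te({v1},{v2})" + (f":{by}={level}" if by else "")
            self.terms.append(Term(name, "tensor", (v1, v2), by, level, build,
                                   S.copy(), m1.ncol * m2.ncol,
                                   penalty_group="tensor"))

    # -- assembly ----------------------------------------------------------
    def matrix(self, cov: pd.DataFrame) -> np.ndarray:
        cov = cov.copy()
        for c, med in self.medians.items():
            if c in cov:
                cov[c] = cov[c].fillna(med)
        blocks, start = [], 0
        for t in self.terms:
            B = t.builder(cov)
            t.cols = slice(start, start + B.shape[1])
            start += B.shape[1]
            blocks.append(B)
        return np.column_stack(blocks)

    def penalty(self, lambdas: dict) -> np.ndarray:
        """Full penalty matrix for per-group smoothing parameters."""
        S = np.zeros((self.p, self.p))
        for t in self.terms:
            if t.penalty is not None:
                lam = lambdas.get(t.penalty_group, 0.0)
                S[t.cols, t.cols] += lam * t.penalty
        return S


def build_design(covariates: pd.DataFrame, spec: GAMSpec | None = None) -> Design:
    """Penalized model matrix for the covariate table (see :class:`Design`)."""
    return Design(covariates, spec or default_spec())


def _gamma_deviance(y, mu):
    return 2.0 * np.sum(-np.log(y / mu) + (y - mu) / mu)


@dataclass
class GAMFit:
    """A converged penalized Gamma-identity fit."""

    design: Design
    beta: np.ndarray
    cov_beta: np.ndarray           # Bayesian posterior covariance of beta
    fitted: np.ndarray             # working scale (positive)
    y: np.ndarray                  # working response
    deviance: float
    null_deviance: float
    edf: float
    phi: float                     # scale (Pearson estimate)
    lambdas: dict
    converged: bool
    deviance_trace: list
    sign_reversed: bool = False
    eps0: float = EPS0

    @property
    def explained_deviance(self) -> float:
        return explained_deviance(self)

    @property
    def fitted_bpp(self) -> np.ndarray:
        """Fitted values on the proximity scale (undo the sign reversal)."""
        return -(self.fitted - self.eps0) if self.sign_reversed else self.fitted

    def predict(self, covariates: pd.DataFrame, working_scale: bool = False):
        X = self.design.matrix(covariates)
        mu = X @ self.beta
        if working_scale or not self.sign_reversed:
            return mu
        return -(mu - self.eps0)


def _pirls(X, y, S, max_iter=200, tol=1e-7, prior_weights=None):
    """Penalized IRLS for Gamma / identity.  Returns (beta, mu, trace, ok)."""
    n, p = X.shape
    pw = np.ones(n) if prior_weights is None else np.asarray(prior_weights)
    mu = np.full(n, y.mean())
    beta = None
    trace = []
    dev = _gamma_deviance(y, mu)
    for it in range(max_iter):
        w = pw / mu**2
        XtW = X.T * w
        A = XtW @ X + S
        b = XtW @ y
        try:
            beta_new = sla.solve(A, b, assume_a="pos")
        except sla.LinAlgError:
            beta_new = np.linalg.lstsq(A, b, rcond=None)[0]
        # step-halve to keep fitted values positive and deviance finite
        step = 1.0
        for _ in range(30):
            cand = beta_new if beta is None else beta + step * (beta_new - beta)
            mu_new = X @ cand
            if (mu_new > 0).all():
                dev_new = _gamma_deviance(y, mu_new)
                if np.isfinite(dev_new):
                    break
            step /= 2.0
        else:
            raise RuntimeError(
                "Gamma identity fit: could not keep fitted values positive; "
                f"deviance trace: {trace}")
        beta, mu = cand, mu_new
        trace.append(dev_new)
        if abs(dev - dev_new) < tol * (abs(dev_new) + 0.1):
            return beta, mu, trace, True
        dev = dev_new
    return beta, mu, trace, False


#: GCV charges gamma effective degrees of freedom per coefficient; values
#: above 1 guard against the undersmoothing GCV is prone to when the
#: response is serially correlated (as a smoothed curve is).
GCV_GAMMA = 1.4


def _gcv_score(XtWX, XtWz, wz2, S, n, gamma=GCV_GAMMA):
    A = XtWX + S
    try:
        c, low = sla.cho_factor(A)
    except sla.LinAlgError:
        return np.inf, None, None
    beta = sla.cho_solve((c, low), XtWz)
    edf = float(np.trace(sla.cho_solve((c, low), XtWX)))
    rss = wz2 - 2 * beta @ XtWz + beta @ XtWX @ beta
    gcv = n * rss / max(n - gamma * edf, 1e-6) ** 2
    return gcv, beta, edf


def _huber_weights(y, mu, c):
    """Huber weights on Gamma Pearson residuals with MAD scale."""
    r = (y - mu) / mu
    scale = 1.4826 * np.median(np.abs(r - np.median(r)))
    if scale <= 0:
        return np.ones_like(y)
    u = np.abs(r) / scale
    return np.minimum(1.0, c / np.maximum(u, 1e-12))


def _select_lambdas_gcv(design: Design, y, groups, init=1.0,
                        prior_weights=None):
    """GCV grid search for per-group smoothing parameters.

    A pilot fit at moderate smoothing provides the IRLS working
    quantities; the GCV surface is then searched on a coarse log-grid
    and refined once around the optimum.
    """
    X = design.X
    n = len(y)
    pw = np.ones(n) if prior_weights is None else prior_weights
    lambdas = {g: init for g in groups}
    _, mu, _, _ = _pirls(X, y, design.penalty(lambdas), prior_weights=pw)
    w = pw / mu**2
    XtW = X.T * w
    XtWX = XtW @ X
    XtWz = XtW @ y
    wz2 = float(np.sum(w * y * y))

    grids = {g: np.logspace(-3, 5, 7) for g in groups}
    best = None
    names = list(groups)

    def search(grids):
        nonlocal best
        from itertools import product
        for combo in product(*(grids[g] for g in names)):
            lam = dict(zip(names, combo))
            gcv, _, _ = _gcv_score(XtWX, XtWz, wz2, design.penalty(lam), n)
            if best is None or gcv < best[0]:
                best = (gcv, lam)

    search(grids)
    center = best[1]
    refined = {g: center[g] * np.logspace(-0.5, 0.5, 3) for g in names}
    search(refined)
    return best[1]


def _select_lambdas_blocked(design: Design, y, groups, blocks, n_folds=3,
                            init=1.0, prior_weights=None):
    """Chromosome-blocked CV for the smoothing parameters.

    The smoothed proximity response is strongly serially correlated
    along each chromosome, which makes pointwise criteria (GCV, REML)
    undersmooth badly: a wiggly fit that memorizes one chromosome's
    curve looks good to them.  A genome-wide background model must
    instead generalize to chromosomes it has not seen, so whole
    chromosomes are held out.  The search runs on the IRLS working
    model from a pilot fit, where each fold costs one linear solve.
    """
    X = design.X
    pw = np.ones(len(y)) if prior_weights is None else prior_weights
    _, mu, _, _ = _pirls(X, y, design.penalty({g: init for g in groups}),
                         prior_weights=pw)
    w = pw / mu**2
    blocks = np.asarray(blocks)
    chroms = sorted(set(blocks))
    if len(chroms) < 2:
        logger.info("single chromosome: falling back to GCV selection")
        return _select_lambdas_gcv(design, y, groups, prior_weights=pw)
    n_folds = min(n_folds, len(chroms))
    fold_of = {c: i % n_folds for i, c in enumerate(chroms)}
    fold = np.array([fold_of[b] for b in blocks])
    pre = []
    for f in range(n_folds):
        tr = fold != f
        Xt = X[tr]
        wt = w[tr]
        pre.append((Xt.T * wt @ Xt, Xt.T * wt @ y[tr], ~tr))

    names = list(groups)
    results = []

    def cv_error(lam):
        S = design.penalty(lam)
        err = 0.0
        for XtWX_f, XtWy_f, held in pre:
            # small ridge: a factor level absent from the training fold
            # would otherwise make the system singular
            A = XtWX_f + S
            ridge = 1e-8 * np.mean(np.diag(A))
            try:
                beta = sla.solve(A + ridge * np.eye(A.shape[0]), XtWy_f,
                                 assume_a="pos")
            except sla.LinAlgError:
                return np.inf
            resid = y[held] - X[held] @ beta
            err += float(np.sum(w[held] * resid**2))
        return err

    def search(grids):
        from itertools import product
        for combo in product(*(grids[g] for g in names)):
            lam = dict(zip(names, combo))
            results.append((cv_error(lam), lam))

    def pick(tol=0.05):
        # parsimony rule: the heaviest smoothing whose held-out error is
        # within tol of the minimum — CV noise otherwise favors wiggle
        finite = [(e, lam) for e, lam in results if np.isfinite(e)]
        if not finite:
            return {g: 1.0 for g in names}
        err_min = min(e for e, _ in finite)
        ok = [lam for e, lam in finite if e <= err_min * (1 + tol)]
        return max(ok, key=lambda lam: np.prod([lam[g] for g in names]))

    search({g: np.logspace(-2, 6, 5) for g in names})
    center = pick()
    search({g: center[g] * np.logspace(-1, 1, 3) for g in names})
    return pick()


def _select_lambdas(design: Design, y, groups, blocks=None,
                    prior_weights=None):
    if not groups:
        return {}
    if blocks is not None:
        return _select_lambdas_blocked(design, y, groups, blocks,
                                       prior_weights=prior_weights)
    return _select_lambdas_gcv(design, y, groups, prior_weights=prior_weights)


def fit_gam(design: Design, response, lambdas: dict | None = None,
            select: bool = True, sign_reversed: bool = False,
            eps0: float = EPS0, robust: bool = False, huber_c: float = 1.5,
            robust_iters: int = 2, blocks=None) -> GAMFit:
    """Fit the penalized Gamma-identity model on a built design.

    ``response`` must be strictly positive (the working scale).  When
    ``lambdas`` is None and the design has penalized terms, smoothing
    parameters are selected by chromosome-blocked CV when per-row block
    labels are given, else by GCV.

    With ``robust=True`` the converged fit is re-estimated with Huber
    weights on the Pearson residuals (MAD scale), capping the influence
    of rows far above the background — a background model should not
    learn the candidate loci it is meant to expose.
    """
    y = np.asarray(response, dtype=float)
    if (y <= 0).any():
        raise ValueError("working response must be strictly positive")
    if design.n < design.p:
        raise ValueError(f"n={design.n} < p={design.p}: design is underdetermined")
    groups = sorted({t.penalty_group for t in design.terms if t.penalty is not None})
    pw = np.ones(design.n)
    if robust:
        # anchor the outlier weights on a heavily-smoothed pilot: a
        # flexible fit would chase the very loci that must stay outliers
        # (masking), so residuals are judged against a fit that can only
        # express broad covariate effects
        S_heavy = design.penalty({g: 1e6 for g in groups})
        _, mu_pilot, _, _ = _pirls(design.X, y, S_heavy)
        pw = _huber_weights(y, mu_pilot, huber_c)
    if lambdas is None:
        lambdas = _select_lambdas(design, y, groups, blocks=blocks,
                                  prior_weights=pw) \
            if (select and groups) else {g: 1.0 for g in groups}
    S = design.penalty(lambdas)
    beta, mu, trace, ok = _pirls(design.X, y, S, prior_weights=pw)
    if robust:
        for _ in range(max(robust_iters - 1, 0)):
            pw = np.minimum(_huber_weights(y, mu, huber_c),
                            _huber_weights(y, mu_pilot, huber_c))
            beta, mu, trace, ok = _pirls(design.X, y, S, prior_weights=pw)
    if not ok:
        logger.warning("IRLS did not reach tolerance; deviance trace tail %s",
                       trace[-3:])
    w = pw / mu**2
    XtW = design.X.T * w
    A = XtW @ design.X + S
    c, low = sla.cho_factor(A)
    XtWX = XtW @ design.X
    edf = float(np.trace(sla.cho_solve((c, low), XtWX)))
    pearson = float(np.sum((y - mu) ** 2 / mu**2))
    phi = pearson / max(design.n - edf, 1.0)
    cov_beta = sla.cho_solve((c, low), np.eye(design.p)) * phi
    dev = _gamma_deviance(y, mu)
    null_dev = _gamma_deviance(y, np.full_like(y, y.mean()))
    return GAMFit(design=design, beta=beta, cov_beta=cov_beta, fitted=mu,
                  y=y, deviance=dev, null_deviance=null_dev, edf=edf, phi=phi,
                  lambdas=lambdas, converged=ok, deviance_trace=trace,
                  sign_reversed=sign_reversed, eps0=eps0)


def fit_background(covariates: pd.DataFrame, bpp, spec: GAMSpec | None = None,
                   robust: bool = True, **kwargs) -> GAMFit:
    """Fit the background model directly to proximity values (bpp <= 0).

    Handles the sign reversal onto the positive working scale; the
    fitted expected proximity is ``fit.fitted_bpp``.  Robust
    (Huber-reweighted) estimation is on by default so candidate loci do
    not drag the background toward themselves.
    """
    bpp = np.asarray(bpp, dtype=float)
    # reversed sign with a small floor; smoother overshoot above zero is
    # clipped so the working response stays strictly positive
    y = np.maximum(-bpp, 0.0) + EPS0
    design = build_design(covariates, spec)
    return fit_gam(design, y, sign_reversed=True, robust=robust, **kwargs)


def explained_deviance(fit: GAMFit) -> float:
    """Fraction of the null deviance explained by the model."""
    if fit.null_deviance == 0:
        raise ValueError("null deviance is zero; explained deviance undefined")
    return (fit.null_deviance - fit.deviance) / fit.null_deviance


def term_significance(fit: GAMFit) -> pd.DataFrame:
    """Wald tests per model term from the Bayesian coefficient covariance.

    For term block j the statistic ``beta_j' V_jj^{-1} beta_j`` is
    referred to a chi-squared distribution on the block's rank.  A
    singular block yields a missing p-value.
    """
    rows = []
    for t in fit.design.terms:
        if t.kind == "intercept":
            continue
        b = fit.beta[t.cols]
        V = fit.cov_beta[t.cols, t.cols]
        try:
            Vi = np.linalg.pinv(V, rcond=1e-10)
            rank = np.linalg.matrix_rank(V, tol=1e-10)
            if rank == 0:
                raise np.linalg.LinAlgError
            stat = float(b @ Vi @ b)
            p = float(chi2.sf(stat, rank))
        except np.linalg.LinAlgError:
            stat, rank, p = np.nan, 0, np.nan
        rows.append({"term": t.name, "kind": t.kind, "by": t.by,
                     "by_level": t.by_level, "statistic": stat,
                     "rank": rank, "p_value": p})
    return pd.DataFrame(rows, columns=["term", "kind", "by", "by_level",
                                       "statistic", "rank", "p_value"])


def partial_effects(fit: GAMFit, term_name: str, grid) -> pd.DataFrame:
    """Evaluate one term's contribution over a grid with a +/-2 SE band.

    ``grid`` is an array for a 1-D smooth, or a tuple of two arrays
    (evaluated on their lattice) for a tensor surface.  Points outside
    the training range are flagged ``extrapolated``.
    """
    term = next((t for t in fit.design.terms if t.name == term_name), None)
    if term is None:
        raise KeyError(f"no term named {term_name!r}")
    if term.kind == "tensor":
        g1, g2 = (np.asarray(g, dtype=float) for g in grid)
        G1, G2 = np.meshgrid(g1, g2, indexing="ij")
        d = pd.DataFrame({term.vars[0]: G1.ravel(), term.vars[1]: G2.ravel()})
    else:
        g = np.asarray(grid, dtype=float)
        d = pd.DataFrame({term.vars[0]: g})
    if term.by is not None:
        d[term.by] = term.by_level
    B = term.builder(d)
    b = fit.beta[term.cols]
    V = fit.cov_beta[term.cols, term.cols]
    eff = B @ b
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, V, B), 0.0))
    out = d.copy()
    out["effect"] = eff
    out["se"] = se
    out["lower"] = eff - 2 * se
    out["upper"] = eff + 2 * se
    return out
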
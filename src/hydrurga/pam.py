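"""Penalized additive binomial models (logit / cloglog).

A compact GAM engine for the habitat and activity analyses: cubic
regression spline smooths (optionally cyclic, optionally with shrinkage so
a smooth can shrink toward — and past — a straight line), by-factor
replicated smooths, and simple random intercepts represented as
ridge-penalized dummy variables (trip nested within tag via concatenated
grouping).  Fitting is penalized IRLS; smoothing parameters are chosen by
an outer Laplace-approximate REML criterion (GCV available), searched by
coordinate descent on a log grid with golden-section refinement.

The spline bases are the classical natural cubic spline machinery: the
coefficients are the function values at the knots, the penalty is the
integrated squared second derivative, and the cyclic variant matches
value and first two derivatives at the period endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

_GOLD = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class SmoothSpec:
    """One penalized smooth term.

    ``by_factor`` replicates the smooth per level of a grouping column
    (one shared smoothing parameter across levels); ``shrinkage`` adds a
    small penalty on the null space (the straight line) so the term can be
    selected out entirely.
    """

    covariate: str
    basis_dim: int = 10
    cyclic: bool = False
    period: float | None = None
    by_factor: str | None = None
    shrinkage: bool = True

    def __post_init__(self):
        if self.basis_dim < 3:
            raise ValueError("basis_dim must be >= 3")
        if self.cyclic and (self.period is None or self.period <= 0):
            raise ValueError("cyclic smooths need a positive period")

    @property
    def label(self) -> str:
        s = f"s({self.covariate})"
        return f"{s}:{self.by_factor}" if self.by_factor else s


@dataclass(frozen=True)
class RandomEffectSpec:
    """Ridge-penalized group intercepts; factors are concatenated (nesting)."""

    factors: tuple[str, ...]

    @property
    def label(self) -> str:
        return "re(" + ":".join(self.factors) + ")"


# ---------------------------------------------------------------------------
# spline bases

def _ncs_matrices(knots: np.ndarray):
    """B, D of the natural cubic spline: gamma = B^-1 D f (interior 2nd derivs)."""
    h = np.diff(knots)
    k = len(knots)
    B = np.zeros((k - 2, k - 2))
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i > 0:
            B[i, i - 1] = h[i] / 6.0
        if i < k - 3:
            B[i, i + 1] = h[i + 1] / 6.0
    return B, D, h


def crs_basis(x: np.ndarray, knots: np.ndarray):
    """Cubic regression spline design and penalty in knot-value coordinates.

    Returns (X, S): X maps function values at the knots to f(x) (natural
    cubic interpolation), S is the integrated-squared-second-derivative
    penalty.  Values outside the knot range are clamped to the boundary.
    """
    knots = np.asarray(knots, dtype=float)
    B, D, h = _ncs_matrices(knots)
    Binv_D = linalg.solve(B, D, assume_a="pos")
    F = np.vstack([np.zeros(len(knots)), Binv_D, np.zeros(len(knots))])
    S = D.T @ Binv_D
    x = np.clip(np.asarray(x, dtype=float), knots[0], knots[-1])
    j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, len(knots) - 2)
    hj = h[j]
    dm = knots[j + 1] - x
    dp = x - knots[j]
    A = np.zeros((len(x), len(knots)))
    C = np.zeros((len(x), len(knots)))
    rows = np.arange(len(x))
    A[rows, j] += dm / hj
    A[rows, j + 1] += dp / hj
    C[rows, j] += (dm ** 3 / hj - hj * dm) / 6.0
    C[rows, j + 1] += (dp ** 3 / hj - hj * dp) / 6.0
    return A + C @ F, S


def cyclic_crs_basis(x: np.ndarray, knots: np.ndarray, period: float):
    """Cyclic cubic regression spline: f and first two derivatives match at 0/period.

    ``knots`` spans [0, period] inclusive; coefficients are values at the
    first k-1 knots (the last knot wraps onto the first).
    """
    knots = np.asarray(knots, dtype=float)
    k = len(knots)
    m = k - 1
    h = np.diff(knots)
    B = np.zeros((m, m))
    D = np.zeros((m, m))
    for i in range(m):
        hm = h[i - 1]  # wraps: h[-1] is the last interval
        hp = h[i]
        B[i, i] = (hm + hp) / 3.0
        B[i, (i - 1) % m] += hm / 6.0
        B[i, (i + 1) % m] += hp / 6.0
        D[i, i] = -1.0 / hm - 1.0 / hp
        D[i, (i - 1) % m] += 1.0 / hm
        D[i, (i + 1) % m] += 1.0 / hp
    Binv_D = linalg.solve(B, D)
    S = D.T @ Binv_D
    x = knots[0] + np.mod(np.asarray(x, dtype=float) - knots[0], period)
    j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, k - 2)
    hj = h[j]
    dm = knots[j + 1] - x
    dp = x - knots[j]
    A = np.zeros((len(x), m))
    C = np.zeros((len(x), m))
    rows = np.arange(len(x))
    np.add.at(A, (rows, j % m), dm / hj)
    np.add.at(A, (rows, (j + 1) % m), dp / hj)
    np.add.at(C, (rows, j % m), (dm ** 3 / hj - hj * dm) / 6.0)
    np.add.at(C, (rows, (j + 1) % m), (dp ** 3 / hj - hj * dp) / 6.0)
    return A + C @ Binv_D, S


def build_basis(values, spec: SmoothSpec):
    """Design and penalty matrices for a smooth term (uncentred).

    Knots sit at the value quantiles (non-cyclic) or uniformly over the
    period (cyclic).  With ``shrinkage`` the penalty's null space receives
    a small eigenvalue (0.1 x the smallest positive one) so heavy
    penalization can shrink the whole term to zero.
    """
    values = np.asarray(values, dtype=float)
    if spec.cyclic:
        knots = np.linspace(0.0, spec.period, spec.basis_dim + 1)
        X, S = cyclic_crs_basis(values, knots, spec.period)
    else:
        qs = np.linspace(0.0, 1.0, spec.basis_dim)
        knots = np.unique(np.quantile(values, qs))
        if len(knots) < spec.basis_dim:
            raise ValueError(
                f"{spec.covariate}: need at least {spec.basis_dim} distinct values")
        X, S = crs_basis(values, knots)
    if spec.shrinkage:
        S = _add_shrinkage(S)
    return X, S, knots


def adapt_basis_dim(values, spec: SmoothSpec) -> SmoothSpec | None:
    """Shrink a non-cyclic smooth's basis_dim until quantile knots are distinct.

    Heavily tied covariates (e.g. a distance that is exactly zero on the
    pack ice) cannot support the requested knot count; returns a resized
    spec, or None when fewer than 4 distinct knots are possible (callers
    then drop the term or fall back to a linear one).
    """
    if spec.cyclic:
        return spec
    vals = np.asarray(values, dtype=float)
    bd = min(spec.basis_dim, int(pd.Series(vals).nunique()))
    while bd >= 4:
        knots = np.unique(np.quantile(vals, np.linspace(0.0, 1.0, bd)))
        if len(knots) == bd:
            return SmoothSpec(spec.covariate, bd, spec.cyclic, spec.period,
                              spec.by_factor, spec.shrinkage)
        bd = min(len(knots), bd - 1)
    return None


def _add_shrinkage(S: np.ndarray, factor: float = 0.1) -> np.ndarray:
    vals, vecs = linalg.eigh(S)
    tol = max(vals.max(), 1.0) * 1e-10
    pos = vals > tol
    if pos.all() or not pos.any():
        return S
    eps = factor * vals[pos].min()
    vals = np.where(pos, vals, eps)
    return (vecs * vals) @ vecs.T


def _center_constraint(X: np.ndarray):
    """Orthonormal basis Z of the sum-to-zero constraint null space."""
    c = X.sum(axis=0)[None, :]
    _, _, vt = linalg.svd(c, full_matrices=True)
    return vt[1:].T  # (k, k-1)


# ---------------------------------------------------------------------------
# model

@dataclass
class _TermBlock:
    name: str
    sl: slice
    penalty: np.ndarray | None    # block-level penalty (None = unpenalized)
    kind: str                     # 'parametric' | 'smooth' | 'random'
    meta: dict = field(default_factory=dict)


class PenalizedAdditiveModel:
    """Binomial additive model with penalized spline smooths.

    Parameters
    ----------
    response : 1-D binary array, or column name when `data` is given
    data : DataFrame holding covariates
    linear : names of unpenalized linear terms
    smooths : SmoothSpec sequence
    random_effect : RandomEffectSpec or None
    link : 'logit' or 'cloglog' (cloglog behaves better when one outcome
        is rare, as hourly haul-out is)
    intercept : include an intercept column

    Examples
    --------
    >>> m = PenalizedAdditiveModel("y", data=df, linear=["depth"],
    ...                            smooths=[SmoothSpec("hour", cyclic=True, period=24)],
    ...                            link="cloglog")
    >>> r = m.fit()
    >>> print(r.summary())
    """

    def __init__(self, response, data: pd.DataFrame | None = None,
                 linear: Sequence[str] = (), smooths: Sequence[SmoothSpec] = (),
                 random_effect: RandomEffectSpec | None = None,
                 link: str = "logit", intercept: bool = True):
        if isinstance(response, str):
            y = np.asarray(data[response], dtype=float)
        else:
            y = np.asarray(response, dtype=float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("response must be binary 0/1")
        if link not in ("logit", "cloglog"):
            raise ValueError("link must be 'logit' or 'cloglog'")
        self.y = y
        self.link = link
        self.data = data
        cols = []
        self.blocks: list[_TermBlock] = []
        pos = 0
        if intercept:
            cols.append(np.ones((len(y), 1)))
            self.blocks.append(_TermBlock("(Intercept)", slice(0, 1), None, "parametric"))
            pos = 1
        for name in linear:
            cols.append(np.asarray(data[name], dtype=float)[:, None])
            self.blocks.append(_TermBlock(name, slice(pos, pos + 1), None, "parametric"))
            pos += 1
        self.penalized: list[_TermBlock] = []
        for spec in smooths:
            Xs, Ss, knots = build_basis(np.asarray(data[spec.covariate], dtype=float), spec)
            Z = _center_constraint(Xs)
            Xc = Xs @ Z
            Sc = Z.T @ Ss @ Z
            meta = {"spec": spec, "knots": knots, "Z": Z}
            if spec.by_factor is not None:
                levels = pd.unique(data[spec.by_factor])
                meta["levels"] = list(levels)
                p = Xc.shape[1]
                block = np.zeros((len(y), p * len(levels)))
                for li, lev in enumerate(levels):
                    mask = (data[spec.by_factor] == lev).to_numpy()
                    block[mask, li * p:(li + 1) * p] = Xc[mask]
                S_full = linalg.block_diag(*([Sc] * len(levels)))
                cols.append(block)
                tb = _TermBlock(spec.label, slice(pos, pos + block.shape[1]), S_full,
                                "smooth", meta)
                pos += block.shape[1]
            else:
                cols.append(Xc)
                tb = _TermBlock(spec.label, slice(pos, pos + Xc.shape[1]), Sc,
                                "smooth", meta)
                pos += Xc.shape[1]
            self.blocks.append(tb)
            self.penalized.append(tb)
        if random_effect is not None:
            key = data[list(random_effect.factors)].astype(str).agg(":".join, axis=1)
            levels = pd.unique(key)
            dummies = (key.to_numpy()[:, None] == np.asarray(levels)[None, :]).astype(float)
            cols.append(dummies)
            tb = _TermBlock(random_effect.label, slice(pos, pos + len(levels)),
                            np.eye(len(levels)), "random",
                            {"levels": list(levels), "spec": random_effect})
            pos += len(levels)
            self.blocks.append(tb)
            self.penalized.append(tb)
        self.X = np.hstack(cols) if cols else np.empty((len(y), 0))
        self.n_coef = self.X.shape[1]
        self._pen_ranks = [int(np.linalg.matrix_rank(tb.penalty)) for tb in self.penalized]

    # -- link functions ----------------------------------------------------

    def _inv_link(self, eta):
        if self.link == "logit":
            return 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        eta = np.clip(eta, -30.0, 3.5)
        return -np.expm1(-np.exp(eta))

    def _mu_eta(self, eta):
        if self.link == "logit":
            mu = self._inv_link(eta)
            return mu * (1.0 - mu)
        eta = np.clip(eta, -30.0, 3.5)
        return np.exp(eta - np.exp(eta))

    def _link(self, mu):
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        if self.link == "logit":
            return np.log(mu / (1.0 - mu))
        return np.log(-np.log(1.0 - mu))

    def _deviance(self, mu):
        y = self.y
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(y > 0.5, -2.0 * np.log(mu), -2.0 * np.log(1.0 - mu))
        return float(d.sum())

    # -- fitting -----------------------------------------------------------

    def _penalty_matrix(self, lambdas):
        S = np.zeros((self.n_coef, self.n_coef))
        for lam, tb in zip(lambdas, self.penalized):
            S[tb.sl, tb.sl] += lam * tb.penalty
        return S

    def _solve_spd(self, A, b):
        """Solve the (nominally SPD) normal equations without conditioning
        warnings; degenerate columns fall back to least squares."""
        try:
            return linalg.cho_solve(linalg.cho_factor(A, check_finite=False), b,
                                    check_finite=False)
        except linalg.LinAlgError:
            return linalg.lstsq(A, b)[0]

    def _pirls(self, lambdas, beta0=None, max_iter=100, tol=1e-8):
        S = self._penalty_matrix(lambdas)
        # ridge scaled to the design so near-constant columns stay solvable
        n = len(self.y)
        ridge = 1e-9 * max(n, 1.0) * np.eye(self.n_coef)
        y = self.y
        if beta0 is None:
            mu = (y + 0.5) / 2.0
            eta = self._link(mu)
            beta = np.zeros(self.n_coef)
        else:
            beta = beta0.copy()
            eta = self.X @ beta
            mu = self._inv_link(eta)
        pdev = self._deviance(mu) + float(beta @ S @ beta)
        converged = False
        for _ in range(max_iter):
            dmu = np.maximum(self._mu_eta(eta), 1e-12)
            var = np.clip(mu * (1.0 - mu), 1e-12, None)
            w = dmu ** 2 / var
            z = eta + (y - mu) / dmu
            XtW = self.X.T * w
            A = XtW @ self.X + S + ridge
            b = XtW @ z
            beta_new = self._solve_spd(A, b)
            # step-halving keeps the penalized deviance non-increasing
            step = 1.0
            for _ in range(30):
                cand = beta + step * (beta_new - beta)
                eta_c = self.X @ cand
                mu_c = self._inv_link(eta_c)
                pdev_c = self._deviance(mu_c) + float(cand @ S @ cand)
                if np.isfinite(pdev_c) and pdev_c <= pdev + 1e-12:
                    break
                step /= 2.0
            delta_beta = np.max(np.abs(cand - beta))
            beta, eta, mu = cand, eta_c, mu_c
            if (abs(pdev - pdev_c) < tol * (abs(pdev_c) + 0.1)
                    or delta_beta < 1e-10 * (1.0 + np.max(np.abs(beta)))):
                pdev = pdev_c
                converged = True
                break
            pdev = pdev_c
        dmu = np.maximum(self._mu_eta(eta), 1e-12)
        var = np.clip(mu * (1.0 - mu), 1e-12, None)
        w = dmu ** 2 / var
        XtWX = (self.X.T * w) @ self.X
        A = XtWX + S + ridge
        return {"beta": beta, "mu": mu, "eta": eta, "w": w, "XtWX": XtWX, "A": A,
                "S": S, "deviance": self._deviance(mu), "pdev": pdev,
                "converged": converged}

    def _loglik(self, mu):
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        return float(np.sum(np.where(self.y > 0.5, np.log(mu), np.log(1.0 - mu))))

    def _criterion(self, log10_lams, kind, warm):
        lams = 10.0 ** np.asarray(log10_lams, dtype=float)
        st = self._pirls(lams, beta0=warm.get("beta"))
        warm["beta"] = st["beta"]
        edf = float(np.trace(self._solve_spd(st["A"], st["XtWX"])))
        if kind == "gcv":
            n = len(self.y)
            return st["deviance"] * n / max(n - edf, 1.0) ** 2, st
        # Laplace-approximate REML (to be minimized -> negative score)
        ll_p = self._loglik(st["mu"]) - 0.5 * float(st["beta"] @ st["S"] @ st["beta"])
        log_det_S = sum(r * np.log(l) for r, l in zip(self._pen_ranks, lams))
        sign, log_det_A = np.linalg.slogdet(st["A"])
        score = ll_p + 0.5 * log_det_S - 0.5 * log_det_A
        return -score, st

    def fit(self, penalty_selection: str = "reml",
            lambdas: Sequence[float] | None = None,
            grid: tuple[float, float, int] = (-2.0, 7.0, 10),
            refine_iter: int = 10) -> "PAMResults":
        """Fit the model; select smoothing parameters unless given.

        ``penalty_selection`` is 'reml' (Laplace-approximate), 'gcv', or
        'fixed' (requires ``lambdas``, one per penalized term).
        """
        npen = len(self.penalized)
        if npen == 0 or penalty_selection == "fixed":
            if npen and lambdas is None:
                raise ValueError("penalty_selection='fixed' needs lambdas")
            lams = np.asarray(lambdas if lambdas is not None else [], dtype=float)
            st = self._pirls(lams)
            if not st["converged"]:
                raise RuntimeError("penalized IRLS failed to converge "
                                   f"(deviance {st['deviance']:.4g})")
            return self._results(lams, st)
        if lambdas is not None:
            st = self._pirls(np.asarray(lambdas, dtype=float))
            return self._results(np.asarray(lambdas, dtype=float), st)
        warm: dict = {}
        cur = np.zeros(npen)  # log10 lambda
        best_val, best_st = self._criterion(cur, penalty_selection, warm)
        for _ in range(2):  # coordinate-descent passes
            for j in range(npen):
                lo, hi, npts = grid
                cand = np.linspace(lo, hi, npts)
                vals = []
                for c in cand:
                    trial = cur.copy()
                    trial[j] = c
                    v, _ = self._criterion(trial, penalty_selection, warm)
                    vals.append(v)
                jbest = int(np.argmin(vals))
                cur[j] = cand[jbest]
                # golden-section refinement within one grid cell each side
                a = cand[max(jbest - 1, 0)]
                b = cand[min(jbest + 1, npts - 1)]
                x1 = b - _GOLD * (b - a)
                x2 = a + _GOLD * (b - a)
                t1 = cur.copy(); t1[j] = x1
                t2 = cur.copy(); t2[j] = x2
                f1, _ = self._criterion(t1, penalty_selection, warm)
                f2, _ = self._criterion(t2, penalty_selection, warm)
                for _ in range(refine_iter):
                    if f1 < f2:
                        b, x2, f2 = x2, x1, f1
                        x1 = b - _GOLD * (b - a)
                        t1[j] = x1
                        f1, _ = self._criterion(t1, penalty_selection, warm)
                    else:
                        a, x1, f1 = x1, x2, f2
                        x2 = a + _GOLD * (b - a)
                        t2[j] = x2
                        f2, _ = self._criterion(t2, penalty_selection, warm)
                cur[j] = x1 if f1 < f2 else x2
                best_val, best_st = self._criterion(cur, penalty_selection, warm)
        lams = 10.0 ** cur
        if not best_st["converged"]:
            raise RuntimeError("penalized IRLS failed to converge at selected lambdas")
        return self._results(lams, best_st)

    def _results(self, lams, st):
        Vb = self._solve_spd(st["A"], np.eye(self.n_coef))
        M = Vb @ st["XtWX"]
        edf_col = np.diag(M)
        return PAMResults(model=self, params=st["beta"], cov_params=Vb,
                          edf_col=edf_col, lambdas=np.asarray(lams, dtype=float),
                          mu=st["mu"], deviance=st["deviance"],
                          converged=st["converged"])


class PAMResults:
    """Fitted penalized additive binomial model.

    Carries coefficients and their (Bayesian) covariance, per-term
    effective degrees of freedom, log-likelihood, AIC/BIC, and Wald-type
    approximate tests for smooth terms.
    """

    def __init__(self, model, params, cov_params, edf_col, lambdas, mu,
                 deviance, converged):
        self.model = model
        self.params = params
        self.cov_params = cov_params
        self.edf_col = edf_col
        self.lambdas = lambdas
        self.fittedvalues = mu
        self.deviance = deviance
        self.converged = converged
        self.llf = model._loglik(mu)
        self.edf_total = float(edf_col.sum())
        self.aic = -2.0 * self.llf + 2.0 * self.edf_total
        self.bic = -2.0 * self.llf + np.log(len(model.y)) * self.edf_total

    @property
    def bse(self):
        return np.sqrt(np.clip(np.diag(self.cov_params), 0.0, None))

    def edf_by_term(self) -> dict:
        return {tb.name: float(self.edf_col[tb.sl].sum()) for tb in self.model.blocks}

    def term_names(self) -> list:
        return [tb.name for tb in self.model.blocks]

    def parametric_table(self) -> pd.DataFrame:
        from scipy.stats import norm
        rows = []
        for tb in self.model.blocks:
            if tb.kind != "parametric":
                continue
            i = tb.sl.start
            est = self.params[i]
            se = self.bse[i]
            z = est / se if se > 0 else np.nan
            rows.append({"term": tb.name, "estimate": est, "std_error": se,
                         "z_value": z, "p_value": 2 * norm.sf(abs(z))})
        return pd.DataFrame(rows)

    def smooth_table(self) -> pd.DataFrame:
        """Wald-type approximate significance of smooth terms."""
        from scipy.stats import chi2
        rows = []
        for tb in self.model.blocks:
            if tb.kind == "parametric":
                continue
            b = self.params[tb.sl]
            V = self.cov_params[tb.sl, tb.sl]
            Vp = linalg.pinvh(V)
            stat = float(b @ Vp @ b)
            edf = float(self.edf_col[tb.sl].sum())
            df = max(edf, 1.0)
            rows.append({"term": tb.name, "edf": edf,
                         "ref_df": tb.sl.stop - tb.sl.start,
                         "chi_sq": stat, "p_value": float(chi2.sf(stat, df))})
        return pd.DataFrame(rows)

    def predict(self, eta_only: bool = False, X: np.ndarray | None = None):
        X = self.model.X if X is None else X
        eta = X @ self.params
        return eta if eta_only else self.model._inv_link(eta)

    def partial_effect(self, term: str, grid: np.ndarray, level=None) -> np.ndarray:
        """Centred smooth contribution evaluated on `grid` (link scale)."""
        for tb in self.model.blocks:
            if tb.name == term or tb.meta.get("spec") and tb.meta["spec"].covariate == term:
                spec = tb.meta["spec"]
                knots = tb.meta["knots"]
                if spec.cyclic:
                    Xg, _ = cyclic_crs_basis(np.asarray(grid, dtype=float), knots, spec.period)
                else:
                    Xg, _ = crs_basis(np.asarray(grid, dtype=float), knots)
                Xg = Xg @ tb.meta["Z"]
                beta = self.params[tb.sl]
                if spec.by_factor is not None:
                    levels = tb.meta["levels"]
                    p = Xg.shape[1]
                    li = levels.index(level) if level is not None else 0
                    beta = beta[li * p:(li + 1) * p]
                return Xg @ beta
        raise KeyError(f"no smooth term {term!r}")

    def summary(self) -> str:
        lines = [
            f"Penalized additive binomial model ({self.model.link} link)",
            f"n = {len(self.model.y)}, log-likelihood = {self.llf:.2f}, "
            f"deviance = {self.deviance:.2f}",
            f"edf (total) = {self.edf_total:.2f}, AIC = {self.aic:.2f}, "
            f"BIC = {self.bic:.2f}",
            "",
            "Parametric coefficients:",
            self.parametric_table().to_string(index=False, float_format="%.4g"),
        ]
        sm = self.smooth_table()
        if len(sm):
            lines += ["", "Approximate significance of smooth terms (Wald-type):",
                      sm.to_string(index=False, float_format="%.4g")]
        return "\n".join(lines)


def compare(fits: Sequence[PAMResults], criterion: str = "aic",
            names: Sequence[str] | None = None) -> pd.DataFrame:
    """Rank fitted models; ties broken by fewer effective parameters.

    All fits must be on the identical response vector.
    """
    if criterion not in ("aic", "loglik"):
        raise ValueError("criterion must be 'aic' or 'loglik'")
    y0 = fits[0].model.y
    for f in fits[1:]:
        if len(f.model.y) != len(y0) or not np.array_equal(f.model.y, y0):
            raise ValueError("fits must share an identical response vector")
    names = list(names) if names is not None else [f"model_{i}" for i in range(len(fits))]
    df = pd.DataFrame({
        "model": names,
        "log_likelihood": [f.llf for f in fits],
        "edf": [f.edf_total for f in fits],
        "aic": [f.aic for f in fits],
    })
    if criterion == "aic":
        df = df.sort_values(["aic", "edf"], kind="stable")
    else:
        df = df.sort_values(["log_likelihood", "edf"], ascending=[False, True],
                            kind="stable")
    return df.reset_index(drop=True)
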
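"""Linear mixed-effects models for treatment contrasts in nested designs.

The study design measures leaves nested in tree-by-date cells nested in
trees; CO2 treatment is applied at (above) the tree level.  The model is

    response ~ CO2 + (1 | tree) + (1 | tree:date)

with independent random intercepts and i.i.d. residuals:

    y = X beta + Z_t b_t + Z_td b_td + e,
    b_t ~ N(0, s2_t I), b_td ~ N(0, s2_td I), e ~ N(0, s2_e I).

Estimation is REML: the variance *ratios* theta_j = s2_j / s2_e are
profiled out of the fixed effects and residual scale, and the restricted
criterion is minimised over log(theta) by bounded quasi-Newton from a
method-of-moments start.  The covariance matrix is block diagonal over the
coarsest grouping factor, so each evaluation factors small per-block
matrices rather than the full n x n covariance.

Fixed-effect t-tests use the Satterthwaite approximation

    df = 2 [Var(c' beta_hat)]^2 / Var_hat[ Var(c' beta_hat) ],

with the denominator obtained from the gradient of Var(c' beta_hat) in the
variance components and the inverse REML observed information
(finite-difference Hessian).  Variance components estimated at the zero
boundary are excluded from the approximation; in the no-random-effect limit
this recovers the classical residual df = n - p.

An optional array-level random intercept (one level above tree) can be
added; with only a couple of arrays per treatment it rarely absorbs any
variance beyond the tree level, so it is off by default.  Treatment coding uses aCO2 as the reference level, making the
intercept the aCO2 mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

_VARIANCE_FLOOR_RATIO = 1e-10   # lower bound on theta = s2_j / s2_e
_THETA_CEILING = 1e8
_REML_TOL = 1e-12   # relative tolerance on the profiled REML criterion

REFERENCE_TREATMENT = "aCO2"


class ConvergenceError(RuntimeError):
    """REML optimisation failed; carries the optimiser trace."""


@dataclass
class _Block:
    """Rows of one coarsest-group block with local random-effect codes."""

    y: np.ndarray
    X: np.ndarray
    codes: list[np.ndarray]   # one local int-code vector per random effect
    masks: list[np.ndarray]   # precomputed same-level boolean matrices


class TreatmentLMM:
    """REML mixed model of a response on CO2 treatment with nested random
    intercepts.

    Parameters
    ----------
    y : array
        Response, one value per leaf measurement.
    treatment, tree, date : arrays
        Labels per measurement.  Treatment must be constant within tree.
    include_tree_date : bool
        Include the tree-by-date random intercept (default True; disable
        for one-way designs).
    array : array, optional
        Array labels; supplying them adds an array-level random intercept.
    """

    def __init__(self, y, treatment, tree, date=None, *,
                 include_tree_date: bool = True, array=None,
                 reference: str = REFERENCE_TREATMENT):
        y = np.asarray(y, dtype=float)
        treatment = np.asarray(treatment)
        tree = np.asarray(tree)
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values")
        if y.size != treatment.size or y.size != tree.size:
            raise ValueError("y, treatment and tree must have equal length")
        levels = pd.unique(treatment)
        if len(levels) != 2:
            raise ValueError(f"need exactly two treatment levels, got {levels}")
        if reference in levels:
            other = [l for l in levels if l != reference][0]
        else:
            reference, other = sorted(levels)
        for t in pd.unique(tree):
            if len(pd.unique(treatment[tree == t])) != 1:
                raise ValueError(f"treatment varies within tree {t!r}")
        if len(pd.unique(tree)) < 2:
            raise ValueError("need at least two trees")

        self.y = y
        self.n = y.size
        self.X = np.column_stack(
            [np.ones(self.n), (treatment == other).astype(float)]
        )
        self.p = 2
        self.reference = reference
        self.effect_level = other

        self.effect_names: list[str] = []
        groupings: list[np.ndarray] = []
        if array is not None:
            arr = np.asarray(array)
            _check_nested(tree, arr, "tree", "array")
            self.effect_names.append("array")
            groupings.append(pd.factorize(arr)[0])
        self.effect_names.append("tree")
        groupings.append(pd.factorize(tree)[0])
        if include_tree_date:
            if date is None:
                raise ValueError("include_tree_date=True requires date labels")
            date = np.asarray(date)
            cell = pd.factorize(
                pd.Series(tree).astype(str) + "\x1f" + pd.Series(date).astype(str)
            )[0]
            self.effect_names.append("tree_date")
            groupings.append(cell)
        self.m = len(groupings)
        self._blocks = _build_blocks(y, self.X, groupings)

    # -- construction helpers -------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str,
                       treatment_col: str = "treatment",
                       tree_col: str = "tree_id", date_col: str = "date",
                       include_tree_date: bool = True,
                       array_col: str | None = None,
                       reference: str = REFERENCE_TREATMENT) -> "TreatmentLMM":
        return cls(
            df[response].to_numpy(dtype=float),
            df[treatment_col].to_numpy(),
            df[tree_col].to_numpy(),
            df[date_col].to_numpy() if include_tree_date else None,
            include_tree_date=include_tree_date,
            array=df[array_col].to_numpy() if array_col else None,
            reference=reference,
        )

    # -- REML criterion --------------------------------------------------
    def _profiled_pieces(self, theta: np.ndarray):
        """Accumulate log|W|, X'W^-1 X, X'W^-1 y, y'W^-1 y over blocks,
        for W = I + sum_j theta_j Z_j Z_j'."""
        logdet_w = 0.0
        xtwx = np.zeros((self.p, self.p))
        xtwy = np.zeros(self.p)
        ytwy = 0.0
        for blk in self._blocks:
            nb = blk.y.size
            W = np.eye(nb)
            for t_j, mask in zip(theta, blk.masks):
                if t_j > 0:
                    W += t_j * mask
            c, low = cho_factor(W, lower=True, check_finite=False)
            logdet_w += 2.0 * np.sum(np.log(np.diag(c)))
            sol = cho_solve((c, low), np.column_stack([blk.X, blk.y]),
                            check_finite=False)
            wx, wy = sol[:, : self.p], sol[:, self.p]
            xtwx += blk.X.T @ wx
            xtwy += blk.X.T @ wy
            ytwy += float(blk.y @ wy)
        return logdet_w, xtwx, xtwy, ytwy

    def _neg2_profiled_reml(self, theta: np.ndarray) -> float:
        logdet_w, xtwx, xtwy, ytwy = self._profiled_pieces(theta)
        sign, logdet_x = np.linalg.slogdet(xtwx)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(xtwx, xtwy)
        rss = max(ytwy - float(xtwy @ beta), 1e-300)
        return logdet_w + logdet_x + (self.n - self.p) * np.log(rss)

    def restricted_loglike(self, variances: np.ndarray) -> float:
        """REML log-likelihood at explicit variance components
        ``(s2_1, ..., s2_m, s2_e)`` (fixed effects profiled out)."""
        variances = np.asarray(variances, dtype=float)
        s2e = variances[-1]
        theta = variances[:-1] / s2e
        logdet_w, xtwx, xtwy, ytwy = self._profiled_pieces(theta)
        _, logdet_x = np.linalg.slogdet(xtwx)
        beta = np.linalg.solve(xtwx, xtwy)
        rss = max(ytwy - float(xtwy @ beta), 1e-300)
        nmp = self.n - self.p
        return -0.5 * (
            logdet_w + nmp * np.log(s2e) + logdet_x + rss / s2e
            + nmp * np.log(2 * np.pi)
        )

    def _contrast_variance(self, variances: np.ndarray, c: np.ndarray) -> float:
        """Var(c' beta_hat) = s2_e c'(X'W^-1 X)^-1 c at given variances."""
        s2e = variances[-1]
        theta = variances[:-1] / s2e
        _, xtwx, _, _ = self._profiled_pieces(theta)
        return s2e * float(c @ np.linalg.solve(xtwx, c))

    # -- starting values -------------------------------------------------
    def _mom_start(self) -> np.ndarray:
        """Method-of-moments variance ratios from group means."""
        resid = self.y - self.X @ np.linalg.lstsq(self.X, self.y, rcond=None)[0]
        s2_total = max(float(np.var(resid, ddof=self.p)), 1e-12)
        theta = []
        for j in range(self.m):
            group_vars = []
            within = []
            for blk in self._blocks:
                codes = blk.codes[j]
                r = blk.y - blk.X @ np.linalg.lstsq(blk.X, blk.y, rcond=None)[0]
                for lev in np.unique(codes):
                    rows = r[codes == lev]
                    group_vars.append(rows.mean())
                    if rows.size > 1:
                        within.append(rows.var(ddof=1))
            between = float(np.var(group_vars)) if len(group_vars) > 1 else 0.0
            s2w = float(np.mean(within)) if within else s2_total
            m_bar = self.n / max(len(group_vars), 1)
            est = max(between - s2w / m_bar, 1e-3 * s2_total)
            theta.append(est / s2_total)
        return np.asarray(theta)

    # -- fitting ---------------------------------------------------------
    def fit(self, start: np.ndarray | None = None) -> "TreatmentLMMResults":
        y_var = float(np.var(self.y))
        if y_var < 1e-28:
            return self._degenerate_results()

        bounds = [(np.log(_VARIANCE_FLOOR_RATIO), np.log(_THETA_CEILING))] * self.m
        starts = []
        if start is not None:
            starts.append(np.asarray(start, dtype=float))
        starts.append(self._mom_start())
        starts.append(np.full(self.m, 1e-2))

        lo, hi = np.log(_VARIANCE_FLOOR_RATIO), np.log(_THETA_CEILING)

        def objective(eta):
            return self._neg2_profiled_reml(np.exp(np.clip(eta, lo, hi)))

        best = None
        for s0 in starts:
            eta0 = np.log(np.clip(s0, _VARIANCE_FLOOR_RATIO, _THETA_CEILING))
            res = optimize.minimize(
                objective, eta0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": _REML_TOL, "gtol": 1e-8, "maxiter": 500},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError(f"REML optimisation failed: {best}")
        converged = bool(best.success)
        message = str(best.message)
        # derivative-free polish: the profiled surface can be flat enough
        # that quasi-Newton with numerical gradients stops early
        polish = optimize.minimize(
            objective, best.x, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 2000},
        )
        if polish.fun <= best.fun:
            polish.x = np.clip(polish.x, lo, hi)
            best = polish
            converged = converged or bool(polish.success)
        if not converged:
            logger.warning("REML optimiser reported: %s", message)

        theta = np.exp(best.x)
        logdet_w, xtwx, xtwy, ytwy = self._profiled_pieces(theta)
        beta = np.linalg.solve(xtwx, xtwy)
        rss = max(ytwy - float(xtwy @ beta), 1e-300)
        s2e = rss / (self.n - self.p)
        variances = np.append(theta * s2e, s2e)
        cov_beta = s2e * np.linalg.inv(xtwx)
        llf = self.restricted_loglike(variances)
        at_boundary = theta <= _VARIANCE_FLOOR_RATIO * 10
        if at_boundary.any():
            logger.info(
                "variance component(s) at zero boundary: %s",
                [n for n, b in zip(self.effect_names, at_boundary) if b],
            )
        return TreatmentLMMResults(
            model=self, params=beta, cov_params=cov_beta,
            variances=variances, llf=llf, converged=converged,
            optimizer_message=message, at_boundary=at_boundary,
        )

    def _degenerate_results(self) -> "TreatmentLMMResults":
        # constant response: all variance components are zero and the
        # treatment effect is exactly zero
        beta = np.array([float(self.y.mean()), 0.0])
        return TreatmentLMMResults(
            model=self, params=beta, cov_params=np.zeros((2, 2)),
            variances=np.zeros(self.m + 1), llf=np.nan, converged=True,
            optimizer_message="degenerate constant response",
            at_boundary=np.ones(self.m, dtype=bool),
        )


def _check_nested(fine: np.ndarray, coarse: np.ndarray, fine_name, coarse_name):
    df = pd.DataFrame({"f": fine, "c": coarse})
    bad = df.groupby("f")["c"].nunique()
    if (bad > 1).any():
        raise ValueError(
            f"grouping is not nested: {fine_name} level(s) "
            f"{bad[bad > 1].index.tolist()} span multiple {coarse_name} levels"
        )


def _build_blocks(y, X, groupings) -> list[_Block]:
    """Partition rows into independent blocks (connected components of the
    row-sharing-a-group-level graph) and precompute same-level masks."""
    n = y.size
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for codes in groupings:
        order = np.argsort(codes, kind="stable")
        sorted_codes = codes[order]
        # link consecutive sorted rows that share a level
        same = sorted_codes[:-1] == sorted_codes[1:]
        for a, b in zip(order[:-1][same], order[1:][same]):
            union(a, b)
    roots = np.array([find(i) for i in range(n)])
    blocks = []
    for r in np.unique(roots):
        rows = np.nonzero(roots == r)[0]
        codes = [g[rows] for g in groupings]
        masks = [
            (c[:, None] == c[None, :]).astype(float) for c in codes
        ]
        blocks.append(_Block(y=y[rows], X=X[rows], codes=codes, masks=masks))
    return blocks


@dataclass
class TreatmentLMMResults:
    """Estimates, uncertainties and diagnostics from a fitted
    :class:`TreatmentLMM`."""

    model: TreatmentLMM
    params: np.ndarray          # [intercept (reference mean), treatment effect]
    cov_params: np.ndarray
    variances: np.ndarray       # per random effect ... , residual
    llf: float
    converged: bool
    optimizer_message: str
    at_boundary: np.ndarray

    # -- parameter accessors --------------------------------------------
    @property
    def param_names(self) -> list[str]:
        return ["Intercept", self.model.effect_level]

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def vcomp(self) -> dict:
        names = list(self.model.effect_names) + ["residual"]
        return dict(zip(names, self.variances))

    @property
    def vcomp_sd(self) -> dict:
        return {k: float(np.sqrt(v)) for k, v in self.vcomp.items()}

    @property
    def tvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.params / self.bse
        return np.where(np.isfinite(t), t, 0.0)

    # -- Satterthwaite ----------------------------------------------------
    def satterthwaite(self, contrast) -> tuple[float, float]:
        """(df, two-sided p) for ``c' beta`` by Satterthwaite's method."""
        c = np.asarray(contrast, dtype=float)
        var_c = float(c @ self.cov_params @ c)
        t = float(c @ self.params) / np.sqrt(var_c) if var_c > 0 else 0.0
        if var_c <= 0:  # degenerate fit
            return float(self.model.n - self.model.p), 1.0

        v = self.variances.copy()
        s2e = v[-1]
        # components estimated at (or within noise of) the zero boundary
        # contribute nothing to Var(c'beta) and break the finite-difference
        # information matrix, so they are excluded
        active = [j for j in range(self.model.m)
                  if v[j] > max(1e-6 * s2e, 1e-12)] + [self.model.m]
        va = v[active]

        def f_of(vv):
            full = v.copy()
            full[active] = vv
            return self._safe_contrast_var(full, c)

        def ll_of(vv):
            full = v.copy()
            full[active] = vv
            return self.model.restricted_loglike(full)

        steps_g = np.maximum(1e-5 * np.abs(va), 1e-9 * s2e)
        grad = _fd_gradient(f_of, va, steps_g)
        steps_h = np.maximum(1e-4 * np.abs(va), 1e-7 * s2e)
        hess = _fd_hessian(ll_of, va, steps_h)
        info = -hess
        try:
            cov_v = np.linalg.pinv(info)
        except np.linalg.LinAlgError:
            cov_v = None
        denom = float(grad @ cov_v @ grad) if cov_v is not None else np.nan
        if not np.isfinite(denom) or denom <= 0:
            logger.warning(
                "Satterthwaite information matrix singular; "
                "falling back to a normal approximation"
            )
            return np.inf, float(2 * stats.norm.sf(abs(t)))
        df = 2.0 * var_c**2 / denom
        p = float(2 * stats.t.sf(abs(t), df))
        return df, p

    def _safe_contrast_var(self, variances, c):
        variances = np.maximum(variances, 0.0)
        variances[-1] = max(variances[-1], 1e-12)
        return self.model._contrast_variance(variances, c)

    @property
    def df_sat(self) -> np.ndarray:
        return np.array([
            self.satterthwaite(np.eye(2)[i])[0] for i in range(2)
        ])

    @property
    def pvalues(self) -> np.ndarray:
        return np.array([
            self.satterthwaite(np.eye(2)[i])[1] for i in range(2)
        ])

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Fixed-effect CIs on Satterthwaite df."""
        out = np.empty((2, 2))
        for i in range(2):
            df, _ = self.satterthwaite(np.eye(2)[i])
            q = stats.t.ppf(1 - alpha / 2, df) if np.isfinite(df) else \
                stats.norm.ppf(1 - alpha / 2)
            out[i] = (self.params[i] - q * self.bse[i],
                      self.params[i] + q * self.bse[i])
        return out

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        eff = self.satterthwaite(np.array([0.0, 1.0]))
        intc = self.satterthwaite(np.array([1.0, 0.0]))
        lines = [
            "Linear mixed model (REML), response ~ CO2 + (1|tree)"
            + (" + (1|tree:date)" if "tree_date" in self.model.effect_names
               else ""),
            f"n = {self.model.n}, converged = {self.converged}, "
            f"REML loglik = {self.llf:.4f}",
            "",
            f"{'':<12}{'estimate':>12}{'SE':>12}{'t':>9}{'df':>8}{'p':>10}",
        ]
        for name, est, se, t, (df, p) in zip(
            self.param_names, self.params, self.bse, self.tvalues,
            (intc, eff),
        ):
            lines.append(
                f"{name:<12}{est:>12.5g}{se:>12.5g}{t:>9.3f}{df:>8.2f}{p:>10.4g}"
            )
        lines.append("")
        lines.append(f"{'random effect':<16}{'variance':>12}{'SD':>12}")
        for name, var in self.vcomp.items():
            lines.append(f"{name:<16}{var:>12.5g}{np.sqrt(var):>12.5g}")
        return "\n".join(lines)

    def report_row(self, alpha: float = 0.05) -> dict:
        """Flat dict of the quantities a results table reports per index."""
        df, p = self.satterthwaite(np.array([0.0, 1.0]))
        vc, sd = self.vcomp, self.vcomp_sd
        return {
            "aco2_mean": float(self.params[0]),
            "aco2_se": float(self.bse[0]),
            "eco2_effect": float(self.params[1]),
            "eco2_se": float(self.bse[1]),
            "t_value": float(self.tvalues[1]),
            "df": float(df),
            "p_value": float(p),
            "significant": bool(p < alpha),
            "tree_variance": float(vc.get("tree", np.nan)),
            "tree_sd": float(sd.get("tree", np.nan)),
            "date_variance": float(vc.get("tree_date", np.nan)),
            "date_sd": float(sd.get("tree_date", np.nan)),
            "residual_variance": float(vc["residual"]),
            "residual_sd": float(sd["residual"]),
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# finite differences
# ---------------------------------------------------------------------------

def _fd_gradient(f, x, steps):
    g = np.empty_like(x)
    for i, h in enumerate(steps):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] = max(xm[i] - h, 0.0)
        g[i] = (f(xp) - f(xm)) / (xp[i] - xm[i])
    return g


def _fd_hessian(f, x, steps):
    k = x.size
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            hi, hj = steps[i], steps[j]
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += hi
                xm[i] = max(xm[i] - hi, 1e-14)
                dp, dm = xp[i] - x[i], x[i] - xm[i]
                # non-uniform central second difference
                H[i, i] = 2 * (
                    dm * f(xp) - (dp + dm) * f0 + dp * f(xm)
                ) / (dp * dm * (dp + dm))
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[i] += hi; xpp[j] += hj
                xpm[i] += hi; xpm[j] = max(xpm[j] - hj, 1e-14)
                xmp[i] = max(xmp[i] - hi, 1e-14); xmp[j] += hj
                xmm[i] = max(xmm[i] - hi, 1e-14)
                xmm[j] = max(xmm[j] - hj, 1e-14)
                di = (xpp[i] - xmp[i])
                dj = (xpp[j] - xpm[j])
                H[i, j] = H[j, i] = (
                    f(xpp) - f(xpm) - f(xmp) + f(xmm)
                ) / (di * dj)
    return H


# ---------------------------------------------------------------------------
# convenience fitting functions
# ---------------------------------------------------------------------------

def fit_lmm(df: pd.DataFrame, response: str, **kwargs) -> TreatmentLMMResults:
    """Fit ``response ~ CO2 + (1|tree) + (1|tree:date)`` on a long table."""
    return TreatmentLMM.from_dataframe(df, response, **kwargs).fit()


def fit_all_indices(index_df: pd.DataFrame, alpha: float = 0.05,
                    **kwargs) -> pd.DataFrame:
    """One mixed-model row per vegetation index.

    Undefined index values are excluded listwise with a logged count; an
    index with no defined values is skipped with a log entry.
    """
    rows = []
    for name, sub in index_df.groupby("index_name", sort=False):
        defined = sub[sub["defined"]] if "defined" in sub else sub.dropna(
            subset=["value"])
        n_dropped = len(sub) - len(defined)
        if n_dropped:
            logger.info("%s: excluded %d undefined value(s)", name, n_dropped)
        if defined.empty or defined["value"].isna().all():
            logger.warning("%s: all values undefined; index skipped", name)
            continue
        res = fit_lmm(defined, "value", **kwargs)
        row = {"index": name, **res.report_row(alpha=alpha)}
        rows.append(row)
    order = {n: i for i, n in enumerate(pd.unique(index_df["index_name"]))}
    return (
        pd.DataFrame(rows)
        .sort_values("index", key=lambda s: s.map(order), kind="mergesort")
        .reset_index(drop=True)
    )


def fit_pcs(scores: pd.DataFrame, meta: pd.DataFrame, n_pcs: int = 4,
            **kwargs) -> dict:
    """Mixed models for the first ``n_pcs`` principal-component scores.

    Scores are standardised per component.  Returns per-component fits plus
    a pooled fit on the stacked standardised scores with a single common
    treatment effect - a stacked-univariate reading of a multivariate
    model (shared residual variance across components).
    """
    per_pc: dict[str, TreatmentLMMResults] = {}
    stacked = []
    for k in range(1, n_pcs + 1):
        col = scores.iloc[:, k - 1].to_numpy(dtype=float)
        z = (col - col.mean()) / col.std(ddof=1)
        df = meta[["treatment", "tree_id", "date"]].copy()
        df["value"] = z
        per_pc[f"PC{k}"] = fit_lmm(df, "value", **kwargs)
        df2 = df.copy()
        df2["component"] = f"PC{k}"
        stacked.append(df2)
    pooled = fit_lmm(pd.concat(stacked, ignore_index=True), "value", **kwargs)
    return {"per_pc": per_pc, "pooled": pooled}
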
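"""Stage 1: structured life-course model selection via LARS/lasso.

The six encoded life-course variables compete for association with baseline
frailty.  Each candidate is first residualized on the common confounders,
near-duplicate candidates are dropped, and the least angle regression (LARS)
algorithm with the lasso modification traces the full lasso solution path —
variables enter (and may leave) the active set as the penalty decreases, and
the coefficient path is piecewise linear in the penalty parameter.

Two diagnostics support the choice of life-course model:

* an *elbow plot* quantity — cumulative R-squared from an ordinary
  least-squares refit of each successive active set, and
* the *covariance test for the lasso* — a per-knot statistic measuring how
  much the entering variable improves the fit over the path restricted to
  the variables already active; under the null that all signal is already in
  the active set it is asymptotically Exponential(1), giving the p-value
  ``exp(-T)``.

Selection proceeds to stage 2 with the first-entered variable even when the
covariance test does not support it; ``supported`` records that distinction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateOutcomeError, RankDeficiencyError

__all__ = [
    "LarsPath",
    "CovTestResult",
    "SelectionResult",
    "residualize",
    "drop_collinear",
    "lars_path",
    "covariance_test",
    "select_model",
    "kkt_violation",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# residualization & collinearity screening
# ---------------------------------------------------------------------------

def _design_with_intercept(C: np.ndarray | None, n: int) -> np.ndarray:
    if C is None or C.size == 0:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), C])


def residualize(X, C=None):
    """Replace each column of ``X`` by its OLS residual on ``[1, C]``.

    With no confounders the columns are simply mean-centred.  Preserves the
    container type (DataFrame in, DataFrame out).  Raises
    :class:`RankDeficiencyError` naming aliased confounder columns when ``C``
    is not of full column rank.
    """
    x_df = isinstance(X, pd.DataFrame)
    Xv = X.to_numpy(dtype=float) if x_df else np.asarray(X, dtype=float)
    c_names = None
    if isinstance(C, pd.DataFrame):
        c_names = list(C.columns)
        Cv = C.to_numpy(dtype=float)
    else:
        Cv = None if C is None else np.asarray(C, dtype=float)
    n = Xv.shape[0]
    D = _design_with_intercept(Cv, n)
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # identify aliased columns by sequential rank growth
        aliased = []
        r_prev = 1
        for k in range(1, D.shape[1]):
            r = np.linalg.matrix_rank(D[:, : k + 1])
            if r == r_prev:
                aliased.append(c_names[k - 1] if c_names else f"col{k - 1}")
            r_prev = r
        raise RankDeficiencyError(f"confounder matrix is rank deficient; aliased: {aliased}",
                                  aliased)
    coef, *_ = np.linalg.lstsq(D, Xv, rcond=None)
    R = Xv - D @ coef
    if x_df:
        return pd.DataFrame(R, columns=X.columns, index=X.index)
    return R


def drop_collinear(
    X: pd.DataFrame,
    threshold: float = 0.9,
    prefer_prefix: str = "sp_",
) -> tuple[pd.DataFrame, list[dict]]:
    """Greedily remove one column of every pair with |r| > ``threshold``.

    For a flagged pair the later-listed column is dropped, except that a
    column whose name starts with ``prefer_prefix`` (by default the sensitive
    period variables) is kept in preference to a derived one regardless of
    order.  Returns the reduced frame and a log of ``{kept, dropped, r}``
    records.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    cols = list(X.columns)
    corr = X.corr().to_numpy()
    dropped: set[str] = set()
    log: list[dict] = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a, b = cols[i], cols[j]
            if a in dropped or b in dropped:
                continue
            r = corr[i, j]
            if abs(r) > threshold:
                a_pref = a.startswith(prefer_prefix)
                b_pref = b.startswith(prefer_prefix)
                keep, drop = (a, b)
                if b_pref and not a_pref:
                    keep, drop = (b, a)
                dropped.add(drop)
                log.append({"kept": keep, "dropped": drop, "r": float(r)})
    kept_cols = [c for c in cols if c not in dropped]
    return X[kept_cols], log


# ---------------------------------------------------------------------------
# LARS / lasso path
# ---------------------------------------------------------------------------

@dataclass
class LarsPath:
    """Full lasso path: knots, coefficients and per-event refit R-squared.

    One row of ``coefs`` per event (variable entry, drop, or the terminal
    unpenalized solution); ``knots`` holds the penalty value at each event and
    is strictly decreasing, ending at 0 when the path runs to completion.
    Coefficients between consecutive knots are linear in the penalty.
    """

    columns: list[str]
    knots: np.ndarray
    coefs: np.ndarray
    actions: list[tuple[str, str | None]]
    active_sets: list[list[str]]
    r2_per_step: np.ndarray
    n: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float

    @property
    def entry_order(self) -> list[str]:
        seen: list[str] = []
        for act, var in self.actions:
            if act == "enter" and var not in seen:
                seen.append(var)
        return seen

    def coef_at(self, lam: float) -> np.ndarray:
        """Lasso coefficients at an arbitrary penalty (standardized scale)."""
        if lam >= self.knots[0]:
            return np.zeros(len(self.columns))
        if lam <= self.knots[-1]:
            # path truncated before lam (all-active segment continues linearly
            # only down to the last computed knot); clamp to last knot
            return self.coefs[-1].copy()
        k = int(np.searchsorted(-self.knots, -lam, side="right")) - 1
        lo, hi = self.knots[k + 1], self.knots[k]
        w = (self.knots[k] - lam) / (hi - lo)
        return self.coefs[k] + w * (self.coefs[k + 1] - self.coefs[k])


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    if np.any(scale == 0):
        raise ValueError("constant candidate column cannot be standardized")
    return (X - mean) / scale, mean, scale


def lars_path(X, y, standardize: bool = True) -> LarsPath:
    """Trace the lasso-modified LARS path of ``y`` on ``X``.

    Columns are standardized (mean 0, sd 1) and the outcome centred before
    fitting, so knots are on the standardized-correlation scale.  The path
    implements the equiangular LARS moves with the lasso modification: a
    variable leaves the active set when its coefficient crosses zero, and the
    coefficients at every knot solve the lasso at that penalty (KKT-checked
    in the test suite via :func:`kkt_violation`).  Ties in the entry
    correlation are broken by column order.
    """
    if isinstance(X, pd.DataFrame):
        cols = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        cols = [f"x{i}" for i in range(Xv.shape[1])]
    yv = np.asarray(y, dtype=float).ravel()
    n, p = Xv.shape
    if n <= p:
        raise ValueError(f"need more rows than candidate columns (n={n}, p={p})")
    if np.std(yv) == 0:
        raise DegenerateOutcomeError("outcome vector is constant")
    if standardize:
        Xs, x_mean, x_scale = _standardize(Xv)
    else:
        Xs, x_mean, x_scale = Xv, np.zeros(p), np.ones(p)
    y_mean = yv.mean()
    yc = yv - y_mean

    beta = np.zeros(p)
    c = Xs.T @ yc
    lam = float(np.max(np.abs(c)))
    active: list[int] = []
    signs = np.zeros(p)

    knots = [lam]
    coefs = [beta.copy()]
    j0 = int(np.argmax(np.abs(c) >= lam - _EPS))  # first index attaining the max
    actions: list[tuple[str, str | None]] = [("enter", cols[j0])]
    active.append(j0)
    signs[j0] = np.sign(c[j0])
    active_sets = [[cols[j] for j in active]]

    max_events = 8 * p + 10
    for _ in range(max_events):
        A = np.array(active, dtype=int)
        G = Xs[:, A].T @ Xs[:, A]
        try:
            d_A = np.linalg.solve(G, signs[A])
        except np.linalg.LinAlgError:
            raise RankDeficiencyError(
                f"active set {[cols[j] for j in active]} is singular; "
                "screen collinear candidates first")
        a = Xs.T @ (Xs[:, A] @ d_A)

        # candidate penalties where an inactive variable's correlation catches up
        best_lam = 0.0
        best_event: tuple[str, int] | None = None
        inactive = [j for j in range(p) if j not in active]
        for j in inactive:
            for cand in ((c[j] - lam * a[j]) / (1 - a[j]) if abs(1 - a[j]) > _EPS else -1,
                         (lam * a[j] - c[j]) / (1 + a[j]) if abs(1 + a[j]) > _EPS else -1):
                if _EPS < cand < lam - _EPS and cand > best_lam:
                    best_lam, best_event = cand, ("enter", j)
        # candidate penalties where an active coefficient crosses zero (lasso drop)
        for idx, j in enumerate(active):
            if abs(d_A[idx]) > _EPS:
                cand = lam + beta[j] / d_A[idx]
                if _EPS < cand < lam - _EPS and cand > best_lam:
                    best_lam, best_event = cand, ("drop", j)

        next_lam = best_lam if best_event is not None else 0.0
        beta[A] = beta[A] + (lam - next_lam) * d_A
        c = Xs.T @ (yc - Xs @ beta)
        lam = next_lam

        if best_event is None:
            knots.append(0.0)
            coefs.append(beta.copy())
            actions.append(("end", None))
            active_sets.append([cols[j] for j in active])
            break
        act, j = best_event
        knots.append(lam)
        if act == "enter":
            active.append(j)
            signs[j] = np.sign(c[j])
        else:
            beta[j] = 0.0
            active.remove(j)
            signs[j] = 0.0
        coefs.append(beta.copy())
        actions.append((act, cols[j]))
        active_sets.append([cols[j] for j in active])
    else:
        warnings.warn("LARS path terminated at the event budget before reaching 0",
                      stacklevel=2)

    # cumulative R^2 from OLS refits of each successive active set
    tss = float(yc @ yc)
    r2 = []
    for aset in active_sets:
        idx = [cols.index(v) for v in aset]
        if not idx:
            r2.append(0.0)
            continue
        bh, *_ = np.linalg.lstsq(Xs[:, idx], yc, rcond=None)
        resid = yc - Xs[:, idx] @ bh
        r2.append(1.0 - float(resid @ resid) / tss)

    return LarsPath(
        columns=cols,
        knots=np.asarray(knots),
        coefs=np.asarray(coefs),
        actions=actions,
        active_sets=active_sets,
        r2_per_step=np.asarray(r2),
        n=n,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
    )


def kkt_violation(path: LarsPath, X, y, event: int) -> float:
    """Maximum KKT violation of the lasso optimality conditions at a knot.

    At penalty lambda the subgradient conditions require active-column
    gradients equal to ``sign(beta) * lambda`` and inactive-column gradients
    no larger than lambda in magnitude.  Returns the largest violation
    (0 means exact optimality).
    """
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    Xs = (Xv - path.x_mean) / path.x_scale
    yc = np.asarray(y, dtype=float).ravel() - path.y_mean
    beta = path.coefs[event]
    lam = path.knots[event]
    g = Xs.T @ (yc - Xs @ beta)
    viol = 0.0
    for j in range(len(beta)):
        if abs(beta[j]) > _EPS:
            viol = max(viol, abs(g[j] - np.sign(beta[j]) * lam))
        else:
            viol = max(viol, abs(g[j]) - lam)
    return float(viol)


# ---------------------------------------------------------------------------
# covariance test
# ---------------------------------------------------------------------------

@dataclass
class CovTestResult:
    """Per-entry covariance-test statistics along a lasso path."""

    steps: list[dict]          # {step, variable, lambda, lambda_next, T, p}
    sigma2_hat: float

    @property
    def p_values(self) -> list[float]:
        return [s["p"] for s in self.steps]


def covariance_test(path: LarsPath, X, y, sigma2="estimate") -> CovTestResult:
    """Covariance test for the lasso at every variable-entry knot.

    For the entry at knot ``lambda_k`` with following knot ``lambda_{k+1}``,

        T_k = [ <y, X b(lambda_{k+1})> - <y, X_A b_A(lambda_{k+1})> ] / sigma^2,

    where ``b`` is the full lasso solution and ``b_A`` the lasso solution
    using only the variables active *before* the entry.  Under the null that
    the active set already contains all signal, T is asymptotically
    Exponential(1); the p-value is ``exp(-T)``.

    ``sigma2`` may be a known positive value or ``"estimate"`` (residual
    variance of the unpenalized OLS fit on all candidates, n - p - 1
    denominator; requires n > p + 1).
    """
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    Xs = (Xv - path.x_mean) / path.x_scale
    yv = np.asarray(y, dtype=float).ravel()
    yc = yv - path.y_mean
    n, p = Xs.shape

    if sigma2 == "estimate":
        if n <= p + 1:
            raise ValueError("cannot estimate sigma^2 with n <= p + 1")
        bh, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
        rss = float(((yc - Xs @ bh) ** 2).sum())
        s2 = rss / (n - p - 1)
    else:
        s2 = float(sigma2)
        if s2 <= 0:
            raise ValueError("sigma2 must be positive")

    steps = []
    sub_cache: dict[tuple[str, ...], LarsPath] = {}
    step_no = 0
    for k, (act, var) in enumerate(path.actions):
        if act != "enter":
            continue
        step_no += 1
        lam_next = path.knots[k + 1] if k + 1 < len(path.knots) else 0.0
        beta_full = path.coef_at(lam_next) if k + 1 < len(path.knots) else path.coefs[-1]
        inner_full = float(yc @ (Xs @ beta_full))
        before = path.active_sets[k - 1] if k > 0 else []
        if before:
            key = tuple(sorted(before))
            if key not in sub_cache:
                idx = [path.columns.index(v) for v in before]
                sub_cache[key] = lars_path(Xs[:, idx], yc, standardize=False)
            sub = sub_cache[key]
            idx = [path.columns.index(v) for v in before]
            beta_sub = sub.coef_at(lam_next)
            inner_sub = float(yc @ (Xs[:, idx] @ beta_sub))
        else:
            inner_sub = 0.0
        T = (inner_full - inner_sub) / s2
        if T < -1e-8:
            warnings.warn(f"covariance statistic {T:.3g} below numerical tolerance at "
                          f"step {step_no}; clipping to 0", stacklevel=2)
        T = max(T, 0.0)
        steps.append({
            "step": step_no,
            "variable": var,
            "lambda": float(path.knots[k]),
            "lambda_next": float(lam_next),
            "T": T,
            "p": float(np.exp(-T)),
        })
    return CovTestResult(steps=steps, sigma2_hat=s2)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Outcome of stage 1 for one stratum."""

    first_selected: str
    supported: bool
    n_supported_steps: int
    entry_order: list[str]
    r2_per_step: list[float]
    p_values: list[float]
    alpha: float
    path: LarsPath = field(repr=False)
    covtest: CovTestResult = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "first_selected": self.first_selected,
            "supported": self.supported,
            "n_supported_steps": self.n_supported_steps,
            "entry_order": self.entry_order,
            "knots": [float(k) for k in self.path.knots],
            "r2_per_step": [float(r) for r in self.r2_per_step],
            "covariance_test": self.covtest.steps,
            "sigma2_hat": self.covtest.sigma2_hat,
            "alpha": self.alpha,
        }


def select_model(path: LarsPath, covtest: CovTestResult, alpha: float = 0.05) -> SelectionResult:
    """Pick the life-course model(s) supported by the path and covariance test.

    The first-entered variable is always carried forward to stage 2 (the
    elbow and p-values qualify the strength of support, they do not veto the
    choice); ``n_supported_steps`` is the longest prefix of entry steps with
    covariance-test p below ``alpha``.
    """
    entry = path.entry_order
    ps = covtest.p_values
    n_sup = 0
    for pv in ps:
        if pv < alpha:
            n_sup += 1
        else:
            break
    return SelectionResult(
        first_selected=entry[0],
        supported=bool(ps and ps[0] < alpha),
        n_supported_steps=n_sup,
        entry_order=entry,
        r2_per_step=list(path.r2_per_step),
        p_values=list(ps),
        alpha=alpha,
        path=path,
        covtest=covtest,
    )
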
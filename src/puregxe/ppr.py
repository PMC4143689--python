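"""Projection pursuit regression and stepwise main-effect residualization.

The phenotype is modelled as an additive combination of ridge functions,

    y = sum_m S_m(alpha_m . x) + eps,

each term a smooth 1-D function of a linear projection of the predictors,
fitted by the classic alternating scheme: hold the direction fixed and
refit the scatterplot smoother, then hold the smoother fixed and update the
direction by a Gauss-Newton step, until the residual sum of squares
stabilises.

Two smoothers are provided.  Continuous predictors use LOWESS with the
span chosen by cross-validation.  Discrete predictors with few levels
(binary environments, 0/1/2 genotypes) use exact per-level means, which
annihilates the predictor's main effect exactly and deterministically.

The two-step "pure interaction" preparation removes the environment's main
effect from the trait, then the SNP's main effect from that residual,
without ever fitting a joint term — whatever association survives is, by
construction, not attributable to either marginal effect.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "LevelMeansSmoother",
    "LowessSmoother",
    "PPRModel",
    "ResidualVector",
    "fit_ppr",
    "residualize_stepwise",
]


class LevelMeansSmoother:
    """Exact per-level mean fit for a discrete 1-D predictor.

    Equivalent to one-way ANOVA fitted values; unseen levels at predict
    time fall back to the training mean.
    """

    def __init__(self, max_levels: int = 10):
        self.max_levels = max_levels

    def fit(self, x: np.ndarray, y: np.ndarray) -> "LevelMeansSmoother":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        levels, inverse = np.unique(x, return_inverse=True)
        if levels.size > self.max_levels:
            raise ValueError(
                f"{levels.size} distinct values exceed max_levels="
                f"{self.max_levels}; use a continuous smoother"
            )
        counts = np.bincount(inverse)
        sums = np.bincount(inverse, weights=y)
        self.levels_ = levels
        self.means_ = sums / counts
        self.global_mean_ = float(y.mean())
        self.fitted_ = self.means_[inverse]
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.full(x.shape, self.global_mean_)
        pos = np.searchsorted(self.levels_, x)
        pos = np.clip(pos, 0, self.levels_.size - 1)
        hit = self.levels_[pos] == x
        out[hit] = self.means_[pos[hit]]
        return out


class LowessSmoother:
    """LOWESS scatterplot smoother with cross-validated span.

    When ``frac`` is None the span is chosen from ``frac_grid`` by 5-fold
    cross-validation with folds interleaved along the sorted predictor, so
    every fold covers the whole range.  Ties on CV error prefer the larger
    (smoother) span.  Prediction interpolates the fitted curve and clamps
    outside the training range.
    """

    #: candidate spans, largest (stiffest) first so ties resolve smooth
    frac_grid = (0.7, 0.5, 0.35, 0.2)

    def __init__(self, frac: float | None = None):
        self.frac = frac

    @staticmethod
    def _curve(x: np.ndarray, y: np.ndarray, frac: float,
               xvals: np.ndarray) -> np.ndarray:
        return _sm_lowess(y, x, frac=frac, it=0, xvals=xvals)

    def fit(self, x: np.ndarray, y: np.ndarray) -> "LowessSmoother":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n = x.size
        frac = self.frac
        if frac is None:
            order = np.argsort(x, kind="stable")
            fold = np.empty(n, dtype=int)
            fold[order] = np.arange(n) % 5
            best = (np.inf, self.frac_grid[0])
            for cand in self.frac_grid:
                if cand * n < 3:
                    continue
                sse = 0.0
                for f in range(5):
                    tr = fold != f
                    te = ~tr
                    if tr.sum() < 3 or te.sum() == 0:
                        continue
                    pred = self._curve(x[tr], y[tr], cand, x[te])
                    resid = y[te] - pred
                    sse += float(np.nansum(resid**2))
                if sse < best[0]:
                    best = (sse, cand)
            frac = best[1]
        self.frac_ = frac
        xk = np.unique(x)
        yk = self._curve(x, y, frac, xk)
        # lowess can emit NaN at duplicated extremes; fall back to the mean
        if np.isnan(yk).any():
            yk = np.where(np.isnan(yk), float(np.nanmean(y)), yk)
        self._xk = xk
        self._yk = yk
        self.fitted_ = self.predict(x)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self._xk.size == 1:
            return np.full(x.shape, self._yk[0])
        return np.interp(x, self._xk, self._yk)

    def derivative(self, x: np.ndarray) -> np.ndarray:
        """Slope of the fitted curve at ``x`` (piecewise-linear gradient)."""
        if self._xk.size == 1:
            return np.zeros_like(np.asarray(x, dtype=float))
        grad = np.gradient(self._yk, self._xk)
        return np.interp(np.asarray(x, dtype=float), self._xk, grad)


def _make_smoother(name: str, max_levels: int):
    if name in ("lowess", "loess", "supersmoother", "continuous"):
        return LowessSmoother()
    if name in ("level-means", "levels"):
        return LevelMeansSmoother(max_levels=max_levels)
    raise ValueError(f"unknown smoother {name!r}")


@dataclass
class _RidgeTerm:
    direction: np.ndarray
    smoother: object
    converged: bool


@dataclass
class PPRModel:
    """Fitted projection pursuit regression model."""

    directions: list[np.ndarray]
    smoothers: list[object]
    intercept: float
    fitted_values: np.ndarray
    residuals: np.ndarray
    residual_variance: float
    converged: bool

    @property
    def n_terms(self) -> int:
        return len(self.directions)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = _as_matrix(x)
        out = np.full(x.shape[0], self.intercept)
        for alpha, sm in zip(self.directions, self.smoothers):
            out += sm.predict(x @ alpha)
        return out


def _as_matrix(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def _fit_ridge_term(
    x: np.ndarray,
    r: np.ndarray,
    smoother: str,
    max_levels: int,
    tol: float,
    max_iter: int,
) -> _RidgeTerm:
    n, p = x.shape
    if p == 1:
        sm = _make_smoother(smoother, max_levels).fit(x[:, 0], r)
        return _RidgeTerm(np.array([1.0]), sm, True)

    # initial direction: least-squares coefficient vector, normalized
    xc = x - x.mean(axis=0)
    alpha, *_ = np.linalg.lstsq(xc, r - r.mean(), rcond=None)
    nrm = np.linalg.norm(alpha)
    alpha = alpha / nrm if nrm > 0 else np.ones(p) / np.sqrt(p)

    sm = None
    prev_rss = np.inf
    converged = False
    for _ in range(max_iter):
        proj = x @ alpha
        sm = _make_smoother(smoother, max_levels).fit(proj, r)
        rss = float(np.sum((r - sm.fitted_) ** 2))
        if prev_rss - rss <= tol * max(prev_rss, 1e-300):
            converged = True
            break
        prev_rss = rss
        # Gauss-Newton update: linearize S(alpha.x) around current alpha
        deriv = sm.derivative(proj)
        w = deriv**2
        good = w > 1e-12
        if good.sum() < p + 1:
            converged = True
            break
        target = proj[good] + (r[good] - sm.fitted_[good]) / deriv[good]
        sw = np.sqrt(w[good])
        new, *_ = np.linalg.lstsq(x[good] * sw[:, None], target * sw,
                                  rcond=None)
        nrm = np.linalg.norm(new)
        if nrm == 0:
            converged = True
            break
        new = new / nrm
        if new @ alpha < 0:  # keep orientation continuous
            new = -new
        alpha = new
    proj = x @ alpha
    sm = _make_smoother(smoother, max_levels).fit(proj, r)
    return _RidgeTerm(alpha, sm, converged)


def fit_ppr(
    x: np.ndarray,
    y: np.ndarray,
    M: int = 1,
    smoother: str = "lowess",
    max_levels: int = 10,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> PPRModel:
    """Fit a projection pursuit regression with ``M`` ridge terms.

    Terms are added forward-stagewise, each fitted to the current residual.
    With a single predictor column the direction is fixed at 1 and fitting
    reduces to 1-D smoothing.  A zero-variance response yields the constant
    model S == mean(y).  Non-convergence returns the best iterate with
    ``converged=False`` rather than raising.
    """
    x = _as_matrix(x)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.size:
        raise ValueError("x and y have different sample counts")
    if x.shape[0] < 8:
        raise ValueError("need at least 8 samples to fit PPR")
    if not np.isfinite(x).all():
        raise ValueError("predictors must be finite")
    if M < 1:
        raise ValueError("M must be >= 1")

    intercept = float(y.mean())
    if np.ptp(y) == 0.0:
        fitted = np.full(y.shape, intercept)
        return PPRModel([], [], intercept, fitted, y - fitted, 0.0, True)

    r = y - intercept
    directions: list[np.ndarray] = []
    smoothers: list[object] = []
    all_converged = True
    for _ in range(M):
        term = _fit_ridge_term(x, r, smoother, max_levels, tol, max_iter)
        r = r - term.smoother.fitted_
        directions.append(term.direction)
        smoothers.append(term.smoother)
        all_converged &= term.converged
    fitted = y - r
    return PPRModel(
        directions=directions,
        smoothers=smoothers,
        intercept=intercept,
        fitted_values=fitted,
        residuals=r,
        residual_variance=float(np.var(r)),
        converged=all_converged,
    )


@dataclass
class ResidualVector:
    """Main-effect-free residuals for one (trait, environment, SNP) triple."""

    values: np.ndarray
    source_trait: str
    removed: list[str]
    flags: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.values.size


def _n_levels(v: np.ndarray) -> int:
    return np.unique(v).size


def _center_levels(r: np.ndarray, f: np.ndarray) -> np.ndarray:
    _, inv = np.unique(f, return_inverse=True)
    means = np.bincount(inv, weights=r) / np.bincount(inv)
    return r - means[inv]


def _max_margin(r: np.ndarray, f: np.ndarray) -> float:
    _, inv = np.unique(f, return_inverse=True)
    means = np.bincount(inv, weights=r) / np.bincount(inv)
    return float(np.max(np.abs(means)))


def _backfit_two_way(
    r: np.ndarray, e: np.ndarray, g: np.ndarray,
    tol: float = 1e-12, max_iter: int = 200,
) -> np.ndarray:
    """Alternate level-mean centering until both margins vanish.

    A single pass of each centering leaves a small residual margin on the
    first factor whenever the two factors are unbalanced; iterating
    converges to the projection orthogonal to both sets of level
    indicators, i.e. the additive two-way fit is removed exactly.
    """
    for _ in range(max_iter):
        r = _center_levels(r, e)
        r = _center_levels(r, g)
        if max(_max_margin(r, e), _max_margin(r, g)) < tol:
            break
    return r


def residualize_stepwise(
    y: np.ndarray,
    e: np.ndarray,
    g: np.ndarray,
    smoother: str = "lowess",
    max_levels: int = 4,
    source_trait: str = "trait",
    env_name: str = "env",
    snp_name: str = "snp",
) -> ResidualVector:
    """Remove the environment's then the SNP's main effect from ``y``.

    The environment uses level-means smoothing when it has at most
    ``max_levels`` distinct values (binary indicators) and the continuous
    smoother otherwise (age).  The genotype always uses level-means, so
    both marginal effects are removed exactly for discrete predictors.
    Inputs must already be aligned and complete (pairwise deletion done).
    """
    y = np.asarray(y, dtype=float)
    e = np.asarray(e, dtype=float)
    g = np.asarray(g, dtype=float)
    if not (y.size == e.size == g.size):
        raise ValueError("y, e, g must be aligned to the same samples")
    flags: list[str] = []

    env_smoother = (
        "level-means" if _n_levels(e) <= max_levels else smoother
    )
    m1 = fit_ppr(e, y, M=1, smoother=env_smoother, max_levels=max_levels)
    res1 = m1.residuals
    if not m1.converged:
        flags.append("env-fit-not-converged")

    if _n_levels(g) < 2:
        res2 = res1 - res1.mean()
        flags.append("no-genotype-variation")
    else:
        m2 = fit_ppr(g, res1, M=1, smoother="level-means", max_levels=4)
        res2 = m2.residuals
        if env_smoother == "level-means" and _n_levels(e) > 1:
            # discrete-discrete case: polish so BOTH margins are exactly 0
            res2 = _backfit_two_way(res2, e, g)
    return ResidualVector(
        values=res2,
        source_trait=source_trait,
        removed=[env_name, snp_name],
        flags=flags,
    )
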
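"""Spatial regression of firing rate on position, and the remap logistic model.

``SpatialRateRegression`` is a locally weighted least-squares (loess-style)
regression of per-pixel firing rate on pixel position: at each valid pixel a
degree-1 plane is fitted over the ``span * N`` nearest valid pixels with
tri-cube distance weights and evaluated at that pixel.  The smoothing span is
chosen per cell by 10-fold cross-validation over a span grid, and the quality
of fit is summarized as percent variance explained,
PVE = 100 * (1 - sigma_resid^2 / sigma_total^2).

``RemapLogit`` is a logistic regression of per-cell remapping on the
session-2 ISI peak time, genotype group, and session indicators,

    log(P(remap) / (1 - P(remap))) = a0 + a1*ISI_peak + a2*T + a3*S2 + a4*S3,

fitted by iteratively reweighted least squares (IRLS) with step-halving, so
the deviance is non-increasing across iterations; convergence is declared
when the coefficient change falls below 1e-8 (max 100 iterations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maps import RateMap

DEFAULT_SPAN_GRID = (0.05, 0.1, 0.2, 0.3, 0.5, 0.75, 1.0)


# ---------------------------------------------------------------------------
# Locally weighted spatial regression
# ---------------------------------------------------------------------------


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - u**3, 0.0, None) ** 3
    return w


def percent_variance_explained(observed: np.ndarray, predicted: np.ndarray) -> float:
    """PVE = 100 * (1 - var(residual) / var(observed)).

    100 when predictions reproduce the observations exactly, 0 when they do
    no better than the observed mean; can be negative for a worse-than-mean
    fit. Invariant to shifting or rescaling both series together.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    sigma_total = observed.std(ddof=0)
    sigma_resid = (observed - predicted).std(ddof=0)
    if sigma_total == 0.0:
        return 100.0 if sigma_resid == 0.0 else -np.inf
    return float(100.0 * (1.0 - sigma_resid**2 / sigma_total**2))


def _loess_predict(
    xy_train: np.ndarray, y_train: np.ndarray, xy_eval: np.ndarray, span: float
) -> np.ndarray:
    """Degree-1 tri-cube local regression predictions at ``xy_eval``."""
    n = len(xy_train)
    m = min(n, max(3, int(np.ceil(span * n))))
    preds = np.empty(len(xy_eval))
    for k, p in enumerate(xy_eval):
        d = np.hypot(xy_train[:, 0] - p[0], xy_train[:, 1] - p[1])
        if m < n:
            nb = np.argpartition(d, m - 1)[:m]
        else:
            nb = np.arange(n)
        dn = d[nb]
        dmax = dn.max()
        if dmax <= 0:
            preds[k] = y_train[nb].mean()
            continue
        w = _tricube(dn / (dmax * (1.0 + 1e-12)))
        w = np.maximum(w, 1e-12)
        X = np.column_stack([np.ones(len(nb)), xy_train[nb, 0] - p[0], xy_train[nb, 1] - p[1]])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y_train[nb] * sw, rcond=None)
        preds[k] = beta[0]  # plane evaluated at the centered eval point
    return preds


@dataclass
class SpatialRegressionResults:
    """Fit summary of a locally weighted spatial regression."""

    span: float
    predicted: np.ndarray  # per valid pixel, Hz
    observed: np.ndarray
    sigma_resid: float
    sigma_total: float
    pve: float  # percent variance explained

    def summary(self) -> str:
        return (
            "Locally weighted spatial regression\n"
            f"  span:            {self.span:.3f}\n"
            f"  pixels:          {len(self.observed)}\n"
            f"  sigma_total:     {self.sigma_total:.4f} Hz\n"
            f"  sigma_resid:     {self.sigma_resid:.4f} Hz\n"
            f"  variance explained: {self.pve:.1f} %"
        )


class SpatialRateRegression:
    """Loess-style model of per-pixel firing rate as a function of position.

    Parameters
    ----------
    ratemap : RateMap
        The occupancy-normalized rate map; only valid pixels enter the fit.
    """

    def __init__(self, ratemap: RateMap):
        valid = ratemap.valid
        cx, cy = ratemap.centers()
        self.xy = np.column_stack([cx[valid], cy[valid]])
        self.y = ratemap.rate[valid].astype(float)
        if len(self.y) < 3:
            raise ValueError("need at least 3 valid pixels")

    def fit(self, span: float) -> SpatialRegressionResults:
        """Fit at a given span and evaluate at every valid pixel."""
        if not (0.0 < span <= 1.0):
            raise ValueError("span must be in (0, 1]")
        pred = _loess_predict(self.xy, self.y, self.xy, span)
        sigma_resid = float((self.y - pred).std(ddof=0))
        sigma_total = float(self.y.std(ddof=0))
        pve = percent_variance_explained(self.y, pred)
        return SpatialRegressionResults(
            span=span,
            predicted=pred,
            observed=self.y.copy(),
            sigma_resid=sigma_resid,
            sigma_total=sigma_total,
            pve=pve,
        )

    def cv_error(self, span: float, k: int = 10, seed: int = 0) -> float:
        """Mean held-out squared error of k-fold CV at one span."""
        return self.cv_errors([span], k=k, seed=seed)[0]

    def cv_errors(self, span_grid, k: int = 10, seed: int = 0) -> list[float]:
        """Mean held-out squared error per span over a common fold partition."""
        n = len(self.y)
        if n < k:
            raise ValueError(f"fewer valid pixels ({n}) than folds ({k})")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        errors = []
        for span in span_grid:
            sse = 0.0
            for fold in folds:
                mask = np.ones(n, dtype=bool)
                mask[fold] = False
                pred = _loess_predict(self.xy[mask], self.y[mask], self.xy[fold], span)
                sse += float(np.sum((self.y[fold] - pred) ** 2))
            errors.append(sse / n)
        return errors

    def select_span(self, span_grid=DEFAULT_SPAN_GRID, k: int = 10, seed: int = 0) -> float:
        """Span in the grid minimizing CV error (ties -> smaller span)."""
        grid = sorted(span_grid)
        if not grid:
            raise ValueError("span_grid is empty")
        errs = self.cv_errors(grid, k=k, seed=seed)
        best = int(np.argmin(errs))  # argmin takes the first, i.e. smaller span
        return float(grid[best])


def select_span_cv(ratemap: RateMap, span_grid=DEFAULT_SPAN_GRID, k: int = 10, seed: int = 0) -> float:
    """Cross-validated span choice for one rate map."""
    return SpatialRateRegression(ratemap).select_span(span_grid, k=k, seed=seed)


def fit_spatial_regression(ratemap: RateMap, span: float) -> SpatialRegressionResults:
    """Locally weighted regression of a rate map at a fixed span."""
    return SpatialRateRegression(ratemap).fit(span)


# ---------------------------------------------------------------------------
# Remap logistic regression (IRLS)
# ---------------------------------------------------------------------------

REMAP_COLUMNS = ("isi_peak", "group", "session2", "session3")


@dataclass
class RemapLogitResults:
    """Coefficients and diagnostics of the remap logistic regression."""

    params: np.ndarray
    bse: np.ndarray
    exog_names: list[str]
    deviance_path: list[float] = field(default_factory=list)
    converged: bool = True
    diagnostic: str = ""
    n_obs: int = 0

    @property
    def deviance(self) -> float:
        return self.deviance_path[-1]

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    def summary(self) -> str:
        lines = [
            "Remap logistic regression (IRLS)",
            f"  n = {self.n_obs}, deviance = {self.deviance:.3f}, "
            f"converged = {self.converged}",
            f"  {'term':<12}{'coef':>10}{'se':>10}{'z':>8}",
        ]
        for name, b, se, z in zip(self.exog_names, self.params, self.bse, self.zvalues):
            lines.append(f"  {name:<12}{b:>10.4f}{se:>10.4f}{z:>8.2f}")
        if self.diagnostic:
            lines.append(f"  note: {self.diagnostic}")
        return "\n".join(lines)


class RemapLogit:
    """Logistic model of remapping probability, fitted by IRLS."""

    def __init__(self, endog: np.ndarray, exog: np.ndarray, exog_names: list[str] | None = None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != len(self.endog):
            raise ValueError("endog and exog lengths differ")
        if not set(np.unique(self.endog)) <= {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")
        if len(np.unique(self.endog)) < 2:
            raise ValueError("need at least one observation per outcome class")
        self.exog_names = exog_names or [f"x{i}" for i in range(self.exog.shape[1])]

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, columns=REMAP_COLUMNS) -> "RemapLogit":
        """Build from a table with a binary ``remap`` column plus predictors.

        ``columns`` selects the predictor columns (drop ``isi_peak`` for the
        reduced group-and-session model); an intercept is always included.
        """
        missing = [c for c in ("remap", *columns) if c not in table.columns]
        if missing:
            raise ValueError(f"table missing column(s) {missing}")
        y = table["remap"].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(table))] + [table[c].to_numpy(dtype=float) for c in columns])
        return cls(y, X, exog_names=["intercept", *columns])

    def fit(self, tol: float = 1e-8, maxiter: int = 100) -> RemapLogitResults:
        """Maximum likelihood via IRLS with step-halving (monotone deviance)."""
        X, y = self.exog, self.endog
        n, p = X.shape
        beta = np.zeros(p)

        def deviance(b: np.ndarray) -> float:
            eta = X @ b
            # log-likelihood: sum y*eta - log(1 + exp(eta)), stable form
            ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
            return -2.0 * ll

        dev = deviance(beta)
        path = [dev]
        converged = False
        diagnostic = ""
        for _ in range(maxiter):
            eta = X @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.maximum(mu * (1.0 - mu), 1e-10)
            z = eta + (y - mu) / w
            XtW = X.T * w
            try:
                beta_new = np.linalg.solve(XtW @ X, XtW @ z)
            except np.linalg.LinAlgError:
                diagnostic = "singular weighted design (possible separation or collinearity)"
                break
            step = beta_new - beta
            new_dev = deviance(beta_new)
            halvings = 0
            while new_dev > dev + 1e-10 and halvings < 30:
                step *= 0.5
                beta_new = beta + step
                new_dev = deviance(beta_new)
                halvings += 1
            if new_dev > dev + 1e-10:
                diagnostic = "deviance could not be decreased (step-halving exhausted)"
                break
            beta = beta_new
            path.append(new_dev)
            if np.max(np.abs(step)) < tol:
                converged = True
                break
            dev = new_dev
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        if not converged and not diagnostic:
            diagnostic = "maximum iterations reached"
        if np.any(mu < 1e-10) or np.any(mu > 1.0 - 1e-10):
            if not converged:
                diagnostic = "possible perfect separation: fitted probabilities at 0/1"
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        info = (self.exog.T * w) @ self.exog
        try:
            cov = np.linalg.inv(info)
            bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            bse = np.full(p, np.nan)
        if diagnostic:
            warnings.warn(f"RemapLogit: {diagnostic}", stacklevel=2)
        return RemapLogitResults(
            params=beta,
            bse=bse,
            exog_names=list(self.exog_names),
            deviance_path=path,
            converged=converged,
            diagnostic=diagnostic,
            n_obs=n,
        )


def fit_remap_logistic(table: pd.DataFrame, columns=REMAP_COLUMNS, **fit_kwargs) -> RemapLogitResults:
    """Fit the remap logistic model from a predictor table.

    Pass ``columns=("group", "session2", "session3")`` for the reduced model
    without the ISI peak term.
    """
    return RemapLogit.from_dataframe(table, columns=columns).fit(**fit_kwargs)
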
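"""Posterior-bootstrap shape classification of trait-gradient relationships.

For one population's trait (e.g., R* vs temperature, or Topt vs resource
level), the uncertainty in the trait at each gradient value is a posterior
draw matrix. The procedure:

1. Bootstrap: sample one posterior draw independently per gradient value
   and fit a penalized cubic regression spline (or a straight line when the
   gradient has <= 3 values) through those points; repeat ``n_boot`` times
   (5000 in the study protocol). The smoothing parameter is chosen per fit
   by generalized cross-validation (GCV) and the smooth-term effective
   degrees of freedom (EDF, straight line => 1) recorded.
2. Gate: when >= 80% of fits are effectively linear (EDF <= 1.6), refit
   straight lines to the same bootstrap samples and call the relationship
   increasing/decreasing by slope sign when >= 70% of slopes agree.
3. Otherwise classify each spline by the sign pattern of its first
   derivative on a fine grid: a negative-to-positive zero crossing is
   U-shaped, positive-to-negative is hump-shaped, no crossing is monotonic;
   the modal shape wins when its fraction is >= 60%, else "uncertain".

Traits bounded below by zero (R*, affinity, vs temperature) use a gamma
error family with a log link; everything else is Gaussian.

The penalty is the integrated squared second derivative of the spline, so
infinite smoothing recovers an exact straight line and the total influence
trace tends to 2 (smooth EDF -> 1); zero smoothing approaches the basis
dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "GradientSeries",
    "BootstrapEnsemble",
    "ShapeVerdict",
    "PSpline",
    "bootstrap_fits",
    "classify_shape",
    "mean_species_curve",
    "EDF_THRESHOLD",
    "LINEARITY_GATE",
    "GAM_SHAPE_THRESHOLD",
    "LM_SHAPE_THRESHOLD",
]

EDF_THRESHOLD = 1.6  # smooth-term EDF at or below which a fit counts as linear
LINEARITY_GATE = 0.80  # fraction of linear fits that switches to the LM pathway
GAM_SHAPE_THRESHOLD = 0.60
LM_SHAPE_THRESHOLD = 0.70

_LAMBDA_GRID = np.logspace(-8, 8, 49)
_N_GRID = 200  # derivative evaluation points over the observed range


def _select_lambda(gcv: np.ndarray) -> int:
    """Index of the GCV minimiser; near-ties resolve to the smoothest fit
    (largest lambda), so exactly-representable simple curves are not fitted
    with spurious wiggle."""
    best = float(np.min(gcv))
    tol = best * 1e-6 + 1e-12
    candidates = np.nonzero(gcv <= best + tol)[0]
    return int(candidates[-1])


@dataclass(frozen=True)
class GradientSeries:
    """Posterior draws of one trait along one gradient.

    ``gradient`` has shape (g,); ``draws`` has shape (n_posterior, g) with
    column j holding the trait's posterior draws at gradient value j.
    ``family`` is ``"gaussian"`` or ``"gamma"`` (log link; strictly positive
    traits only).
    """

    gradient: np.ndarray
    draws: np.ndarray
    family: str = "gaussian"

    def __post_init__(self) -> None:
        x = np.asarray(self.gradient, float)
        d = np.asarray(self.draws, float)
        object.__setattr__(self, "gradient", x)
        object.__setattr__(self, "draws", d)
        if d.ndim != 2 or d.shape[1] != len(x):
            raise ValueError("draws must be (n_posterior, n_gradient)")
        if len(np.unique(x)) < 2:
            raise ValueError("degenerate gradient: all values equal")
        if self.family not in ("gaussian", "gamma"):
            raise ValueError("family must be gaussian or gamma")
        if self.family == "gamma" and np.any(d <= 0):
            raise ValueError("gamma family requires strictly positive draws")


class PSpline:
    """Penalized cubic regression spline on a fixed design.

    Basis dimension is ``min(k, g - 1)`` for ``g`` distinct gradient
    values; the roughness penalty is the integrated squared second
    derivative, computed exactly by Gauss–Legendre quadrature per knot
    span (the integrand is piecewise quadratic for a cubic spline).
    """

    def __init__(self, x: np.ndarray, k: int = 10):
        x = np.asarray(x, float)
        g = len(np.unique(x))
        p = max(min(k, g - 1), 3)
        degree = min(3, p - 1)
        a, b = float(x.min()), float(x.max())
        n_interior = p - degree - 1
        interior = np.linspace(a, b, n_interior + 2)[1:-1]
        knots = np.concatenate([[a] * (degree + 1), interior, [b] * (degree + 1)])
        self.x = x
        self.knots = knots
        self.degree = degree
        self.p = p
        self.B = BSpline.design_matrix(x, knots, degree).toarray()
        self.S = self._curvature_penalty()
        self.grid = np.linspace(a, b, _N_GRID)
        self.B_grid = BSpline.design_matrix(self.grid, knots, degree).toarray()
        self.Bd_grid = self._derivative_matrix(self.grid)
        # per-lambda solve operators and influence traces (weights = 1)
        BtB = self.B.T @ self.B
        n = len(x)
        Ms, traces = [], []
        for lam in _LAMBDA_GRID:
            Minv = np.linalg.solve(BtB + lam * self.S + 1e-10 * np.eye(p), self.B.T)
            Ms.append(Minv)
            traces.append(np.trace(self.B @ Minv))
        self.M = np.stack(Ms)  # (L, p, n)
        self.traces = np.asarray(traces)
        self.n = n

    def _curvature_penalty(self) -> np.ndarray:
        if self.degree < 2:
            # fall back to squared first-difference penalty for tiny bases
            D = np.diff(np.eye(self.p), n=1, axis=0)
            return D.T @ D
        spans = np.unique(self.knots)
        gauss_x = np.array([-np.sqrt(3 / 5), 0.0, np.sqrt(3 / 5)])
        gauss_w = np.array([5 / 9, 8 / 9, 5 / 9])
        S = np.zeros((self.p, self.p))
        for lo, hi in zip(spans[:-1], spans[1:]):
            half = 0.5 * (hi - lo)
            pts = 0.5 * (lo + hi) + half * gauss_x
            B2 = self._second_derivative_matrix(pts)
            S += half * (B2.T * gauss_w) @ B2
        return S

    def _derivative_matrix(self, pts: np.ndarray) -> np.ndarray:
        out = np.empty((len(pts), self.p))
        for j in range(self.p):
            c = np.zeros(self.p)
            c[j] = 1.0
            out[:, j] = BSpline(self.knots, c, self.degree).derivative()(pts)
        return out

    def _second_derivative_matrix(self, pts: np.ndarray) -> np.ndarray:
        out = np.empty((len(pts), self.p))
        for j in range(self.p):
            c = np.zeros(self.p)
            c[j] = 1.0
            out[:, j] = BSpline(self.knots, c, self.degree).derivative(2)(pts)
        return out

    # -- fitting ---------------------------------------------------------

    def fit_gaussian(self, y: np.ndarray) -> tuple[np.ndarray, float, float]:
        """GCV-selected fit; returns (coefficients, smooth EDF, lambda)."""
        coefs = np.einsum("lpn,n->lp", self.M, y)
        fitted = coefs @ self.B.T  # (L, n)
        rss = np.sum((y[None, :] - fitted) ** 2, axis=1)
        denom = np.maximum(self.n - self.traces, 1e-8) ** 2
        gcv = self.n * rss / denom
        i = _select_lambda(gcv)
        return coefs[i], float(self.traces[i] - 1.0), float(_LAMBDA_GRID[i])

    def fit_gamma(self, y: np.ndarray, max_iter: int = 25) -> tuple[np.ndarray, float, float]:
        """Gamma/log-link penalized IRLS; GCV over the working residuals.

        For the gamma family with a log link, the IRLS weights are
        constant, so the influence trace per lambda equals the Gaussian one.
        """
        if np.any(y <= 0):
            raise ValueError("gamma family requires positive responses")
        fits = []
        logy = np.log(y)
        for li, lam in enumerate(_LAMBDA_GRID):
            eta = logy.copy()
            c = self.M[li] @ eta
            for _ in range(max_iter):
                eta = self.B @ c
                mu = np.exp(np.clip(eta, -30, 30))
                z = eta + (y - mu) / mu
                c_new = self.M[li] @ z
                if np.max(np.abs(c_new - c)) < 1e-10:
                    c = c_new
                    break
                c = c_new
            eta = self.B @ c
            mu = np.exp(np.clip(eta, -30, 30))
            z = eta + (y - mu) / mu
            rss = float(np.sum((z - eta) ** 2))
            gcv = self.n * rss / max(self.n - self.traces[li], 1e-8) ** 2
            fits.append((gcv, c, float(self.traces[li] - 1.0), float(lam)))
        i = _select_lambda(np.array([f[0] for f in fits]))
        return fits[i][1], fits[i][2], fits[i][3]

    def predict(self, coefs: np.ndarray) -> np.ndarray:
        """Fitted values on the evaluation grid (response scale handled by
        the caller for the gamma family)."""
        return self.B_grid @ coefs

    def derivative(self, coefs: np.ndarray) -> np.ndarray:
        return self.Bd_grid @ coefs


@dataclass
class BootstrapEnsemble:
    """Fitted bootstrap ensemble for one trait-gradient relationship."""

    x: np.ndarray
    y_samples: np.ndarray  # (n_boot, g) bootstrap responses
    pathway: str  # "GAM" or "LM"
    family: str
    spline: PSpline | None
    coefs: np.ndarray | None  # (n_boot, p) for the GAM pathway
    edf: np.ndarray | None
    slopes: np.ndarray  # (n_boot,) straight-line slopes on the same samples
    grid: np.ndarray
    curves: np.ndarray  # (n_boot, n_grid) response-scale predictions
    seed: int


@dataclass
class ShapeVerdict:
    """Probabilistic shape call for one trait-gradient relationship."""

    label: str  # U-shaped | hump-shaped | increasing | decreasing | uncertain
    probability: float
    pathway: str
    frac_linear: float  # fraction of fits with smooth EDF <= threshold
    grid: np.ndarray
    mean_curve: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    critical_point: float | None = None


def _classify_derivative(deriv: np.ndarray, grid: np.ndarray,
                         persist: int = 2) -> tuple[str, float | None]:
    """Shape from the sign pattern of a first derivative on a fine grid.

    A crossing only counts when the sign on each side persists for at least
    ``persist`` consecutive grid points (noise guard).
    """
    sign = np.sign(deriv)
    # run-length encode the nonzero signs (zeros do not break a run)
    runs: list[list] = []  # [sign, first index, last index, count]
    for i in np.nonzero(sign)[0]:
        s = sign[i]
        if runs and runs[-1][0] == s:
            runs[-1][2] = i
            runs[-1][3] += 1
        else:
            runs.append([s, int(i), int(i), 1])
    runs = [r for r in runs if r[3] >= persist]
    if not runs:
        return ("increasing" if deriv.sum() >= 0 else "decreasing"), None
    for (s0, _, e0, _), (s1, b1, _, _) in zip(runs[:-1], runs[1:]):
        if s0 < 0 < s1:
            return "U-shaped", float(grid[(e0 + b1) // 2])
        if s0 > 0 > s1:
            return "hump-shaped", float(grid[(e0 + b1) // 2])
    return ("increasing" if runs[0][0] > 0 else "decreasing"), None


def bootstrap_fits(
    series: GradientSeries,
    n_boot: int = 5000,
    seed: int = 0,
    k: int = 10,
) -> BootstrapEnsemble:
    """Fit the posterior-bootstrap ensemble for one trait-gradient series."""
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    x = series.gradient
    g = len(x)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, series.draws.shape[0], size=(n_boot, g))
    y_samples = series.draws[idx, np.arange(g)]  # (n_boot, g)

    pathway = "GAM" if g >= 4 else "LM"
    slopes = np.polyfit(x, y_samples.T, 1)[0]

    if pathway == "LM":
        grid = np.linspace(x.min(), x.max(), _N_GRID)
        inter = np.polyfit(x, y_samples.T, 1)[1]
        curves = slopes[:, None] * grid[None, :] + inter[:, None]
        return BootstrapEnsemble(
            x=x, y_samples=y_samples, pathway="LM", family=series.family,
            spline=None, coefs=None, edf=None, slopes=slopes, grid=grid,
            curves=curves, seed=seed,
        )

    sp = PSpline(x, k=k)
    coefs = np.empty((n_boot, sp.p))
    edf = np.empty(n_boot)
    for i in range(n_boot):
        if series.family == "gamma":
            coefs[i], edf[i], _ = sp.fit_gamma(y_samples[i])
        else:
            coefs[i], edf[i], _ = sp.fit_gaussian(y_samples[i])
    curves = coefs @ sp.B_grid.T
    if series.family == "gamma":
        curves = np.exp(np.clip(curves, -30, 30))
    return BootstrapEnsemble(
        x=x, y_samples=y_samples, pathway="GAM", family=series.family,
        spline=sp, coefs=coefs, edf=edf, slopes=slopes, grid=sp.grid,
        curves=curves, seed=seed,
    )


def classify_shape(
    ensemble: BootstrapEnsemble,
    edf_threshold: float = EDF_THRESHOLD,
    linearity_gate: float = LINEARITY_GATE,
    gam_threshold: float = GAM_SHAPE_THRESHOLD,
    lm_threshold: float = LM_SHAPE_THRESHOLD,
) -> ShapeVerdict:
    """Turn a bootstrap ensemble into a probabilistic shape label."""
    mean_curve = ensemble.curves.mean(axis=0)
    lower = np.quantile(ensemble.curves, 0.025, axis=0)
    upper = np.quantile(ensemble.curves, 0.975, axis=0)

    if ensemble.pathway == "GAM":
        frac_linear = float(np.mean(ensemble.edf <= edf_threshold))
    else:
        frac_linear = 1.0

    if ensemble.pathway == "LM" or frac_linear >= linearity_gate:
        # linear pathway: slope sign on the same bootstrap samples
        frac_up = float(np.mean(ensemble.slopes > 0))
        frac_down = float(np.mean(ensemble.slopes < 0))
        if frac_up >= lm_threshold:
            label, prob = "increasing", frac_up
        elif frac_down >= lm_threshold:
            label, prob = "decreasing", frac_down
        else:
            label, prob = "uncertain", max(frac_up, frac_down)
        return ShapeVerdict(
            label=label, probability=prob, pathway="LM",
            frac_linear=frac_linear, grid=ensemble.grid,
            mean_curve=mean_curve, lower=lower, upper=upper,
        )

    labels = []
    crit_points: dict[str, list[float]] = {"U-shaped": [], "hump-shaped": []}
    for i in range(len(ensemble.coefs)):
        deriv = ensemble.spline.derivative(ensemble.coefs[i])
        lab, cp = _classify_derivative(deriv, ensemble.grid)
        labels.append(lab)
        if cp is not None and lab in crit_points:
            crit_points[lab].append(cp)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    order = np.argsort(counts)[::-1]
    modal, modal_frac = uniq[order[0]], counts[order[0]] / len(labels)
    if modal_frac >= gam_threshold:
        label, prob = str(modal), float(modal_frac)
    else:
        label, prob = "uncertain", float(modal_frac)
    cp = None
    if label in crit_points and crit_points[label]:
        cp = float(np.mean(crit_points[label]))
    return ShapeVerdict(
        label=label, probability=prob, pathway="GAM",
        frac_linear=frac_linear, grid=ensemble.grid,
        mean_curve=mean_curve, lower=lower, upper=upper, critical_point=cp,
    )


def mean_species_curve(
    x: np.ndarray,
    mean_values: np.ndarray,
    n_contributing: np.ndarray | int,
    family: str = "gaussian",
    edf_threshold: float = EDF_THRESHOLD,
    k: int = 10,
) -> ShapeVerdict:
    """Single unweighted fit to cross-population mean trait values.

    ``mean_values`` are the means (over populations) of posterior-median
    trait estimates at each gradient value; at least two populations must
    contribute per gradient value. The same EDF gate and derivative-based
    shape criteria apply, with a deterministic verdict (probability 1).
    """
    x = np.asarray(x, float)
    y = np.asarray(mean_values, float)
    n_contributing = np.broadcast_to(np.asarray(n_contributing), y.shape)
    if np.any(n_contributing < 2):
        raise ValueError("need >= 2 populations contributing per gradient value")
    if len(np.unique(x)) < 4:
        slope, inter = np.polyfit(x, y, 1)
        grid = np.linspace(x.min(), x.max(), _N_GRID)
        curve = slope * grid + inter
        label = "increasing" if slope > 0 else "decreasing"
        return ShapeVerdict(label=label, probability=1.0, pathway="LM",
                            frac_linear=1.0, grid=grid, mean_curve=curve,
                            lower=curve, upper=curve)
    sp = PSpline(x, k=k)
    if family == "gamma":
        coefs, edf, _ = sp.fit_gamma(y)
    else:
        coefs, edf, _ = sp.fit_gaussian(y)
    if edf <= edf_threshold:
        slope, inter = np.polyfit(x, y, 1)
        curve = slope * sp.grid + inter
        label = "increasing" if slope > 0 else "decreasing"
        return ShapeVerdict(label=label, probability=1.0, pathway="LM",
                            frac_linear=1.0, grid=sp.grid, mean_curve=curve,
                            lower=curve, upper=curve)
    curve = sp.predict(coefs)
    if family == "gamma":
        curve = np.exp(np.clip(curve, -30, 30))
    label, cp = _classify_derivative(sp.derivative(coefs), sp.grid)
    return ShapeVerdict(label=label, probability=1.0, pathway="GAM",
                        frac_linear=0.0, grid=sp.grid, mean_curve=curve,
                        lower=curve, upper=curve, critical_point=cp)
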
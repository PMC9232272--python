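"""Reference-plane placement accuracy theory.

Each reference plane contributes a Gaussian accuracy profile R_i centered at
its column μ_i; the combined accuracy Y(x) is an inverse-distance-weighted
mixture of the R_i, and the placement error E(α, σ) sums 1 - Y over all
integer columns.  ``optimal_alpha`` scans the spacing ratio α = d/L for the
minimum of E; ``fit_sigma`` fits σ to an empirical error-vs-α curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AccuracyModel",
    "accuracy_R",
    "combined_Y",
    "error_E",
    "optimal_alpha",
    "fit_sigma",
    "plane_positions",
]

DEFAULT_ALPHA_STEP = 10.0 / 1024.0


@dataclass(frozen=True)
class AccuracyModel:
    """Three-reference accuracy model with μ_i = (1/2 ∓ α) m, m/2, (1/2 + α) m."""

    m: int = 1023
    sigma: float = 123.0
    alpha: float = 1.0 / 3.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0.0 < self.alpha <= 0.5:
            raise ValueError("alpha must be in (0, 0.5]")
        if self.m < 1:
            raise ValueError("m must be >= 1")

    @property
    def mu(self) -> tuple[float, float, float]:
        m, a = self.m, self.alpha
        return ((0.5 - a) * m, 0.5 * m, (0.5 + a) * m)


def accuracy_R(x, mu_i: float, sigma: float):
    """Single-reference accuracy exp(-(x - μ_i)² / (2σ²)), in [0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    x = np.asarray(x, dtype=float)
    return np.exp(-((x - mu_i) ** 2) / (2.0 * sigma**2))


def combined_Y(x, model: AccuracyModel):
    """Inverse-distance-weighted mixture of the three reference accuracies.

    Y(x) = Σ_i w_i(x) R_i(x) / Σ_i w_i(x) with w_i(x) = 1/(|x - μ_i| + 1);
    the +1 keeps weights finite at x = μ_i.  As a convex combination of
    values in [0, 1], Y stays in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    w = np.stack([1.0 / (np.abs(x - mu) + 1.0) for mu in model.mu])
    r = np.stack([accuracy_R(x, mu, model.sigma) for mu in model.mu])
    return (w * r).sum(axis=0) / w.sum(axis=0)


def error_E(alpha: float, sigma: float, m: int = 1023) -> float:
    """Placement error E(α, σ) = Σ_{x=0}^{m} [1 - Y(x)] over integer columns."""
    model = AccuracyModel(m=m, sigma=sigma, alpha=alpha)
    x = np.arange(m + 1, dtype=float)
    return float(np.sum(1.0 - combined_Y(x, model)))


def alpha_grid(grid_step: float = DEFAULT_ALPHA_STEP) -> np.ndarray:
    """The α scan grid: multiples of grid_step inside (0, 0.5]."""
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    n = int(np.floor(0.5 / grid_step + 1e-12))
    return np.arange(1, n + 1) * grid_step


def optimal_alpha(sigma: float, m: int = 1023,
                  grid_step: float = DEFAULT_ALPHA_STEP) -> float:
    """Grid argmin of E(α, σ) over (0, 0.5]; ties pick the smaller α."""
    grid = alpha_grid(grid_step)
    errors = np.array([error_E(a, sigma, m) for a in grid])
    return float(grid[int(np.argmin(errors))])  # argmin takes first = smallest α


def _minmax_normalize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    span = v.max() - v.min()
    if span == 0:
        return np.zeros_like(v)
    return (v - v.min()) / span


def fit_sigma(empirical, m: int = 1023,
              sigma_grid=None, normalize: bool = True) -> tuple[float, float]:
    """Fit σ to an empirical (α, error) curve by minimizing the mean
    absolute difference W(σ) = (1/s) Σ_i |E(α_i, σ) - Expr(α_i)|.

    Both curves are min-max normalized to [0, 1] before comparison unless
    ``normalize=False``.  Returns (best σ, W at best σ).
    """
    pts = [(float(a), float(e)) for a, e in empirical]
    if len(pts) < 3:
        raise ValueError(f"need at least 3 empirical points, got {len(pts)}")
    alphas = np.array([p[0] for p in pts])
    expr = np.array([p[1] for p in pts])
    if sigma_grid is None:
        sigma_grid = np.arange(1.0, 401.0)
    if normalize:
        expr = _minmax_normalize(expr)
    best_sigma, best_w = None, np.inf
    for sigma in np.asarray(sigma_grid, dtype=float):
        theory = np.array([error_E(a, sigma, m) for a in alphas])
        if normalize:
            theory = _minmax_normalize(theory)
        w = float(np.mean(np.abs(theory - expr)))
        if w < best_w:
            best_sigma, best_w = float(sigma), w
    return best_sigma, best_w


def plane_positions(t: int, L: float) -> tuple[float, ...]:
    """Evenly distributed reference-plane positions (2i - 1) L / (2 t)."""
    if t < 1:
        raise ValueError("t must be >= 1")
    return tuple((2 * i - 1) * L / (2 * t) for i in range(1, t + 1))
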
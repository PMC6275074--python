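"""Competitive adaptive reweighted sampling (CARS) for wavelength selection.

CARS runs N Monte-Carlo iterations.  In each, a PLS model is fitted to a
random subset of the calibration samples on the currently retained bands;
bands with small absolute regression coefficients are then eliminated in two
stages: an enforced removal keeping the top ceil(r(i) * p) bands by |b|,
where r(i) = a * exp(-k i) is an exponentially decreasing function pinned by
r(1) = 1 (all bands) and r(N) = 2/p (two bands), followed by an adaptive
reweighted draw of that same count proportional to |b| without replacement
(which additionally drops zero-coefficient bands).  The RMSECV of each
iteration's retained set, evaluated by leave-one-out on the full calibration
data, scores the subsets; the subset with minimal RMSECV is selected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls import fit_pls, loo_cv

__all__ = ["CarsConfig", "CarsResult", "edf_ratio", "cars_run",
           "report_cars_diagnostics"]


@dataclass(frozen=True)
class CarsConfig:
    n_runs: int = 50                 # Monte-Carlo sampling iterations
    mc_sample_ratio: float = 0.8     # calibration fraction drawn per run
    pls_components: int = 5          # internal PLS size, capped by rank
    seed: int = 0

    def __post_init__(self):
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if not 0 < self.mc_sample_ratio < 1:
            raise ValueError("mc_sample_ratio must be in (0, 1)")


@dataclass
class CarsResult:
    """Per-iteration retained subsets with their cross-validation errors."""

    retained_sets: list[np.ndarray]   # band indices retained after iteration i
    retained_counts: np.ndarray
    rmsecv: np.ndarray
    edf_ratios: np.ndarray
    best_iteration: int               # 0-based index of the minimal RMSECV
    selected: np.ndarray              # band indices of the winning subset
    wavelengths_nm: np.ndarray        # the same subset on the nm axis

    @property
    def n_iterations(self) -> int:
        return len(self.retained_sets)


def edf_ratio(i: int, n_runs: int, p: int) -> float:
    """Retained-band fraction r(i) = a * exp(-k i), r(1)=1, r(N)=2/p."""
    if p < 2:
        raise ValueError("need at least 2 bands")
    if not 1 <= i <= n_runs:
        raise ValueError(f"iteration {i} outside 1..{n_runs}")
    k = math.log(p / 2.0) / (n_runs - 1)
    a = math.exp(k)
    return a * math.exp(-k * i)


def _weighted_draw_without_replacement(
    rng: np.random.Generator, items: np.ndarray, weights: np.ndarray, k: int
) -> np.ndarray:
    """Draw up to k distinct items with probability proportional to weights.

    Zero-weight items are never drawn, so the result may hold fewer than k.
    """
    positive = weights > 0
    items, weights = items[positive], weights[positive]
    k = min(k, items.size)
    if k == 0 or weights.sum() == 0:
        return items[:0]
    chosen = rng.choice(items.size, size=k, replace=False,
                        p=weights / weights.sum())
    return items[np.sort(chosen)]


def cars_run(X, y, cfg: CarsConfig = CarsConfig(), grid=None) -> CarsResult:
    """Run CARS on calibration spectra X (n x p) and response y.

    ``X`` may be a SpectraMatrix (its grid supplies the nm axis) or a plain
    array with ``grid`` passed separately.  Deterministic for a fixed
    ``cfg.seed``.  Stops early if the retained set collapses below 2 bands.
    """
    grid_values = getattr(getattr(X, "grid", None), "values", None)
    if grid_values is None and grid is not None:
        grid_values = np.asarray(getattr(grid, "values", grid), dtype=float)
    Xv = np.atleast_2d(np.asarray(getattr(X, "values", X), dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xv.shape
    if p < 2:
        raise ValueError("CARS needs at least 2 bands")

    rng = np.random.default_rng(cfg.seed)
    n_draw = max(2, int(round(cfg.mc_sample_ratio * n)))
    retained = np.arange(p)

    retained_sets: list[np.ndarray] = []
    rmsecv: list[float] = []
    ratios: list[float] = []

    for i in range(1, cfg.n_runs + 1):
        draw = rng.choice(n, size=n_draw, replace=False)
        a_fit = min(cfg.pls_components, n_draw - 1, retained.size)
        model = fit_pls(Xv[np.ix_(draw, retained)], y[draw], a_fit)
        b_abs = np.abs(model.coef)

        r_i = edf_ratio(i, cfg.n_runs, p)
        ratios.append(r_i)
        k_i = min(math.ceil(r_i * p), retained.size)
        top = np.argsort(b_abs)[::-1][:k_i]           # enforced removal
        survivors = retained[np.sort(top)]
        weights = b_abs[np.sort(top)]
        retained = _weighted_draw_without_replacement(  # adaptive reweighting
            rng, survivors, weights, k_i
        )
        if retained.size < 2:
            warnings.warn(f"retained set collapsed at iteration {i}; path truncated")
            break
        a_cv = min(cfg.pls_components, n - 2, retained.size)
        cv = loo_cv(Xv[:, retained], y, max_components=a_cv)
        retained_sets.append(retained.copy())
        rmsecv.append(float(cv.rmsecv[a_cv - 1]))

    if not retained_sets:
        raise RuntimeError("CARS retained no usable subset")
    rmsecv_arr = np.array(rmsecv)
    best = int(np.argmin(rmsecv_arr))
    selected = retained_sets[best]
    return CarsResult(
        retained_sets=retained_sets,
        retained_counts=np.array([s.size for s in retained_sets]),
        rmsecv=rmsecv_arr,
        edf_ratios=np.array(ratios[: len(retained_sets)]),
        best_iteration=best,
        selected=selected,
        wavelengths_nm=(
            grid_values[selected] if grid_values is not None
            else selected.astype(float)
        ),
    )


def report_cars_diagnostics(result: CarsResult) -> pd.DataFrame:
    """Per-iteration table of retained counts and RMSECV, best run flagged.

    The three columns mirror the standard CARS diagnostic panels: number of
    sampled variables, RMSECV path and (via the retained sets) the
    coefficient path.
    """
    df = pd.DataFrame(
        {
            "iteration": np.arange(1, result.n_iterations + 1),
            "edf_ratio": result.edf_ratios,
            "retained_count": result.retained_counts,
            "rmsecv": result.rmsecv,
        }
    )
    df["is_best"] = df.index == result.best_iteration
    return df
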
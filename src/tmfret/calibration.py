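"""FCG calibration: fit the Gaussian width σ and convert efficiencies to distances.

Calibration pairs are donor/acceptor sites whose backbone (Cβ–Cβ) separation
is known from a reference structure and whose FRET efficiency has been
measured under the same conditions.  Plotting measured efficiency against
distance (in R0 units, so pairs with different Förster radii share one
abscissa) reveals a relation shallower than the ideal Förster curve;
fitting a single shared Gaussian width σ across all pairs captures the
distance heterogeneity and yields the standard curve used to convert
subsequent efficiency measurements into mean distances.

One σ is fit globally (shared across pairs); per-pair widths are
deliberately not supported, since a calibration with one measurement per
pair cannot constrain them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .forster_core import FCGModel, fcg_efficiency, invert_fcg

__all__ = [
    "CalibrationPair",
    "CalibrationFit",
    "fit_fcg_sigma",
    "efficiencies_to_distances",
    "read_calibration_table",
    "BoundaryWarning",
]


class BoundaryWarning(UserWarning):
    """The σ optimizer stopped at a bound of its search interval."""


@dataclass(frozen=True)
class CalibrationPair:
    """One (known distance, measured efficiency, R0) calibration point."""

    pair_id: str
    known_distance: float  # Cβ–Cβ Å from a reference structure
    efficiency: float
    r0: float

    def __post_init__(self) -> None:
        if self.known_distance <= 0:
            raise ValueError("known_distance must be > 0")
        if not 0 < self.efficiency < 1:
            raise ValueError("efficiency must be in (0, 1)")
        if self.r0 <= 0:
            raise ValueError("r0 must be > 0")


@dataclass(frozen=True)
class CalibrationFit:
    """Result of the global σ fit."""

    sigma: float
    rss: float
    n_pairs: int
    hit_boundary: bool
    fitted_curve: Callable[[float], float]  # distance/R0 ratio -> efficiency

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_pairs < 2:
            raise ValueError("need >= 2 calibration pairs")


def _rss(sigma: float, pairs: Sequence[CalibrationPair]) -> float:
    total = 0.0
    for p in pairs:
        step = min(0.05, sigma / 5) if sigma > 0 else 0.05
        model = FCGModel(r0=p.r0, sigma=sigma, quadrature_step=step)
        total += (p.efficiency - fcg_efficiency(p.known_distance, model)) ** 2
    return total


def fit_fcg_sigma(
    pairs: Sequence[CalibrationPair],
    sigma_bounds: tuple[float, float] = (0.0, 15.0),
) -> CalibrationFit:
    """Fit the shared Gaussian width σ (Å) by bounded scalar least squares.

    Minimizes Σᵢ (Eᵢ − FCG(dᵢ; R0ᵢ, σ))² over σ ∈ ``sigma_bounds`` with a
    deterministic bounded Brent search.  A fit that lands on a bound is
    flagged (``hit_boundary``) and warned about.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need >= 2 calibration pairs to fit sigma")
    lo, hi = sigma_bounds
    if not 0 <= lo < hi:
        raise ValueError(f"invalid sigma bounds {sigma_bounds}")

    res = minimize_scalar(
        _rss, args=(pairs,), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-3},
    )
    sigma = float(res.x)
    # bounded Brent never lands exactly on a bound; flag near-boundary fits
    tol = 1e-2 * (hi - lo)
    hit = sigma <= lo + tol or sigma >= hi - tol
    # degenerate case: if sigma ~ 0 fits no worse, prefer exactly 0
    if sigma <= lo + tol and lo == 0.0:
        if _rss(0.0, pairs) <= res.fun + 1e-12:
            sigma = 0.0
    if hit:
        warnings.warn(
            f"fitted sigma {sigma:.3g} Å is at/near the search bound "
            f"{sigma_bounds}; treat with caution",
            BoundaryWarning,
        )

    mean_r0 = float(np.mean([p.r0 for p in pairs]))
    sig = sigma
    curve_model = FCGModel(
        r0=mean_r0,
        sigma=sig,
        quadrature_step=min(0.05, sig / 5) if sig > 0 else 0.05,
    )

    def fitted_curve(ratio: float) -> float:
        """Efficiency at distance = ratio · R0 (mean calibration R0)."""
        return fcg_efficiency(ratio * mean_r0, curve_model)

    return CalibrationFit(
        sigma=sigma,
        rss=float(_rss(sigma, pairs)),
        n_pairs=len(pairs),
        hit_boundary=hit,
        fitted_curve=fitted_curve,
    )


def efficiencies_to_distances(
    efficiencies: pd.DataFrame,
    sigma: float,
    r0_by_voltage: dict[int, float] | None = None,
    r0_column: str = "r0",
    bracket: tuple[float, float] = (2.0, 80.0),
) -> pd.DataFrame:
    """Invert per-condition efficiencies to mean backbone distances.

    ``efficiencies`` is a tidy frame with at least ``efficiency_mean`` and a
    condition identity (``state`` or voltage/ligand columns).  The Förster
    radius per row comes either from an ``r0`` column or from
    ``r0_by_voltage`` (donor photophysics can differ between voltages).

    Rows whose efficiency is outside the attainable FCG range are reported
    with NaN distance and the error message in an ``error`` column; other
    rows are still processed.
    """
    out = efficiencies.copy()
    distances, errors = [], []
    for _, row in out.iterrows():
        if r0_by_voltage is not None:
            r0 = r0_by_voltage[int(row["voltage_mV"])]
        else:
            r0 = float(row[r0_column])
        step = min(0.05, sigma / 5) if sigma > 0 else 0.05
        model = FCGModel(r0=r0, sigma=sigma, quadrature_step=step)
        try:
            d = invert_fcg(float(row["efficiency_mean"]), model, bracket)
            distances.append(d)
            errors.append("")
        except ValueError as exc:
            distances.append(np.nan)
            errors.append(str(exc))
    out["distance_A"] = distances
    out["error"] = errors
    return out


def read_calibration_table(path) -> list[CalibrationPair]:
    """Read calibration pairs from a delimited table
    (pair_id, distance_A, efficiency, r0_A)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = ["pair_id", "distance_A", "efficiency", "r0_A"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        CalibrationPair(
            pair_id=str(r.pair_id),
            known_distance=float(r.distance_A),
            efficiency=float(r.efficiency),
            r0=float(r.r0_A),
        )
        for r in df.itertuples()
    ]
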
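"""Spectral overlap integral J, relative quantum yields, and the Förster radius.

The Förster radius is computed from the overlap of the donor emission
spectrum with the acceptor absorption spectrum,

    R0 = C · (J · Q · η⁻⁴ · κ²)^(1/6),

with J in M⁻¹·cm⁻¹·nm⁴, Q the donor quantum yield, η the refractive index
(1.33 for aqueous saline), and κ² the orientation factor (2/3 for an
isotropic donor; transition-metal acceptors have multiple transition
dipoles, so κ² is close to isotropic in practice).  With this unit
convention the standard scaling constant C = 0.211 yields R0 in Å.

Quantum yields of environment-sensitive donors such as l-Anap shift with
local environment (e.g. membrane voltage), so only *relative* yields are
measured: the slope of donor vs. co-expressed YFP intensity at a site,
normalized to a reference site of known (or assigned) yield, times the
brightness ratio between voltages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "DonorPhotophysics",
    "R0Parameters",
    "overlap_integral",
    "compute_r0",
    "relative_quantum_yield",
    "DisjointSupportWarning",
]

#: Scaling constant of the Förster-radius equation for J in M^-1 cm^-1 nm^4,
#: giving R0 in Å.
DEFAULT_SCALE_C = 0.211


class DisjointSupportWarning(UserWarning):
    """Donor emission and acceptor absorption do not overlap."""


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-gridded curve: emission (a.u.) or molar extinction.

    Wavelengths are in nm on a strictly increasing grid of >= 2 points.
    """

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("spectrum needs >= 2 wavelength points")
        if wl.size != vals.size:
            raise ValueError("wavelengths and values must have equal length")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(vals)):
            raise ValueError("spectrum contains non-finite entries")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")

    @classmethod
    def from_file(cls, path) -> "Spectrum":
        """Read a two-column delimited file (wavelength_nm, value), one header line."""
        df = pd.read_csv(path, sep=None, engine="python")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (wavelength_nm, value)")
        return cls(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))

    def to_file(self, path, value_name: str = "value") -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths, value_name: self.values}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class DonorPhotophysics:
    emission: Spectrum
    quantum_yield: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.quantum_yield <= 1:
            raise ValueError(
                f"quantum yield must be in (0, 1], got {self.quantum_yield}"
            )


@dataclass(frozen=True)
class R0Parameters:
    """Constants of the Förster-radius equation with a declared unit convention."""

    eta: float = 1.33
    kappa2: float = 2.0 / 3.0
    scale_C: float = DEFAULT_SCALE_C

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("refractive index must be > 0")
        if not 0 < self.kappa2 <= 4:
            raise ValueError("kappa2 must be in (0, 4]")
        if self.scale_C <= 0:
            raise ValueError("scale_C must be > 0")


def overlap_integral(
    donor_emission: Spectrum,
    acceptor_absorption: Spectrum,
    grid_step: float = 1.0,
) -> float:
    """Spectral overlap J = ∫ f_D(λ) ε_A(λ) λ⁴ dλ, in M⁻¹·cm⁻¹·nm⁴.

    The donor emission is area-normalized (f_D = emission / ∫ emission dλ),
    so J is invariant to the donor's arbitrary amplitude and linear in the
    acceptor extinction.  Both spectra are linearly interpolated onto a
    common grid (union of supports, default 1 nm step), zero outside their
    own support.  Disjoint supports return 0 with a warning.
    """
    if np.any(acceptor_absorption.values < 0):
        raise ValueError("acceptor extinction must be non-negative")

    d_wl, d_val = donor_emission.wavelengths, donor_emission.values
    a_wl, a_val = acceptor_absorption.wavelengths, acceptor_absorption.values
    if d_wl[-1] < a_wl[0] or a_wl[-1] < d_wl[0]:
        warnings.warn(
            "donor emission and acceptor absorption have disjoint wavelength "
            "supports; J = 0",
            DisjointSupportWarning,
        )
        return 0.0

    lo = min(d_wl[0], a_wl[0])
    hi = max(d_wl[-1], a_wl[-1])
    grid = np.arange(lo, hi + grid_step, grid_step)
    f_d = np.interp(grid, d_wl, d_val, left=0.0, right=0.0)
    eps = np.interp(grid, a_wl, a_val, left=0.0, right=0.0)

    donor_area = np.trapezoid(f_d, grid)
    if donor_area <= 0:
        raise ValueError("donor emission has non-positive area")
    return float(np.trapezoid(f_d * eps * grid**4, grid) / donor_area)


def compute_r0(J: float, Q: float, params: R0Parameters | None = None) -> float:
    """Förster radius R0 = C (J Q η⁻⁴ κ²)^(1/6), in Å.

    J in M⁻¹·cm⁻¹·nm⁴ under the package convention (C = 0.211).  J = 0
    returns R0 = 0 with a warning (no acceptor absorption → no transfer).
    """
    if params is None:
        params = R0Parameters()
    if J < 0:
        raise ValueError(f"J must be >= 0, got {J}")
    if not 0 < Q <= 1:
        raise ValueError(f"Q must be in (0, 1], got {Q}")
    if J == 0:
        warnings.warn("J = 0: no spectral overlap, R0 = 0", DisjointSupportWarning)
        return 0.0
    return float(
        params.scale_C * (J * Q * params.eta**-4 * params.kappa2) ** (1.0 / 6.0)
    )


def _slope_through_origin(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y = m·x (no intercept)."""
    denom = float(np.dot(x, x))
    if denom == 0:
        raise ValueError("degenerate regression: all x values are zero")
    return float(np.dot(x, y) / denom)


def relative_quantum_yield(
    anap_site: "np.ndarray | list[float]",
    yfp_site: "np.ndarray | list[float]",
    anap_reference: "np.ndarray | list[float]",
    yfp_reference: "np.ndarray | list[float]",
    brightness_ratio_neg100_vs_0: float,
    q_reference: float,
) -> tuple[float, float]:
    """Relative donor quantum yields at 0 and −100 mV from intensity slopes.

    The donor (Anap) intensity is proportional to expression level — tracked
    by the co-expressed YFP intensity — times the site's quantum yield.  A
    through-origin least-squares slope of Anap vs. YFP at 0 mV, divided by
    the same slope at a reference site with yield ``q_reference``, gives the
    site's yield at 0 mV.  The −100 mV yield scales by the site's measured
    brightness ratio (fl at −100 mV / fl at 0 mV).

    Returns ``(Q_0mV, Q_neg100mV)``.
    """
    a_s = np.asarray(anap_site, float)
    y_s = np.asarray(yfp_site, float)
    a_r = np.asarray(anap_reference, float)
    y_r = np.asarray(yfp_reference, float)
    for name, (a, y) in {
        "site": (a_s, y_s),
        "reference": (a_r, y_r),
    }.items():
        if a.size != y.size or a.size < 3:
            raise ValueError(f"{name}: need paired lists of equal length >= 3")
        if np.any(a <= 0) or np.any(y < 0):
            raise ValueError(f"{name}: intensities must be positive")
    if brightness_ratio_neg100_vs_0 <= 0:
        raise ValueError("brightness ratio must be > 0")
    if q_reference <= 0:
        raise ValueError("q_reference must be > 0")

    slope_site = _slope_through_origin(y_s, a_s)
    slope_ref = _slope_through_origin(y_r, a_r)
    if slope_ref == 0:
        raise ValueError("reference slope is zero; cannot form a yield ratio")
    q0 = q_reference * slope_site / slope_ref
    return q0, q0 * brightness_ratio_neg100_vs_0
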
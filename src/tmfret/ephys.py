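"""Boltzmann fits of conductance–voltage relations from tail currents.

Hyperpolarization-activated channels are characterized by the voltage
dependence of their relative conductance, measured from instantaneous tail
currents at a fixed tail potential following main pulses over a voltage
range.  The G-V relation is fit with a Boltzmann function

    G/Gmax = 1 / (1 + exp((V − V1/2) / Vs)),

where V1/2 is the half-activation potential and Vs the slope factor; with
Vs > 0 conductance rises toward negative potentials (the
hyperpolarization-activated convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["GVData", "BoltzmannFit", "FitError", "boltzmann",
           "normalize_conductance", "fit_boltzmann", "read_gv_table"]


class FitError(RuntimeError):
    """Boltzmann fit failed to converge; message carries diagnostics."""


@dataclass(frozen=True)
class GVData:
    """Tail-current measurements for one patch."""

    voltages: np.ndarray  # mV, main-pulse potentials
    tail_currents: np.ndarray  # pA at the tail potential
    patch_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages, float)
        i = np.asarray(self.tail_currents, float)
        object.__setattr__(self, "voltages", v)
        object.__setattr__(self, "tail_currents", i)
        if v.size < 4:
            raise ValueError("need >= 4 voltage points")
        if v.size != i.size:
            raise ValueError("voltages and currents must have equal length")
        if len(np.unique(v)) != v.size:
            raise ValueError("voltages must be distinct")


@dataclass(frozen=True)
class BoltzmannFit:
    v_half: float  # mV
    v_s: float  # mV slope factor
    g_max: float  # normalization (tail-current units)
    rss: float

    def __post_init__(self) -> None:
        if self.v_s == 0:
            raise ValueError("slope factor must be nonzero")
        if self.g_max <= 0:
            raise ValueError("g_max must be > 0")

    def predict(self, voltages) -> np.ndarray:
        return boltzmann(np.asarray(voltages, float), self.v_half, self.v_s)


def boltzmann(v, v_half: float, v_s: float):
    """Relative conductance 1 / (1 + exp((V − V1/2)/Vs))."""
    return 1.0 / (1.0 + np.exp((np.asarray(v, float) - v_half) / v_s))


def _initial_guesses(v: np.ndarray, i: np.ndarray) -> tuple[float, float, float]:
    g_max0 = float(np.max(np.abs(i)))
    rel = np.abs(i) / g_max0
    crossing = v[np.argmin(np.abs(rel - 0.5))]
    # slope-factor sign from the direction of activation: conductance
    # growing toward negative voltages means Vs > 0
    slope = np.polyfit(v, rel, 1)[0]
    vs0 = 10.0 if slope < 0 else -10.0
    return float(crossing), vs0, g_max0


def fit_boltzmann(
    data: GVData,
    init: tuple[float, float, float] | None = None,
) -> BoltzmannFit:
    """Least-squares Boltzmann fit of tail currents vs. main-pulse voltage.

    ``init`` optionally overrides the (V1/2, Vs, Gmax) starting guesses;
    defaults are the half-range crossing voltage, 10 mV, and the maximal
    tail current.  The fit is deterministic given the data and guesses.
    """
    v = data.voltages
    i = data.tail_currents
    if np.max(np.abs(i)) == 0:
        raise FitError(f"patch {data.patch_id}: all tail currents are zero")
    sign = 1.0 if i[np.argmax(np.abs(i))] >= 0 else -1.0
    y = sign * i
    if init is None:
        init = _initial_guesses(v, y)

    def model(vv, v_half, v_s, g_max):
        return g_max * boltzmann(vv, v_half, v_s)

    try:
        popt, _ = curve_fit(model, v, y, p0=init, maxfev=10000)
    except RuntimeError as exc:
        raise FitError(
            f"patch {data.patch_id}: Boltzmann fit did not converge "
            f"(init={init}): {exc}"
        ) from exc
    v_half, v_s, g_max = map(float, popt)
    if g_max < 0:  # absorb a sign flip into the slope convention
        g_max = -g_max
        v_s = -v_s
    resid = y - model(v, v_half, v_s, g_max)
    return BoltzmannFit(
        v_half=v_half, v_s=v_s, g_max=g_max, rss=float(np.sum(resid**2))
    )


def normalize_conductance(data: GVData, mode: str = "fitted") -> np.ndarray:
    """Relative conductance G/Gmax per voltage.

    ``mode="fitted"`` divides by the Boltzmann-fitted Gmax (robust when the
    most hyperpolarized pulse does not reach full activation);
    ``mode="max"`` divides by the largest-magnitude tail current.
    """
    i = data.tail_currents
    if np.max(np.abs(i)) == 0:
        raise ValueError("all tail currents are zero")
    sign = 1.0 if i[np.argmax(np.abs(i))] >= 0 else -1.0
    if mode == "max":
        if np.allclose(i, i[0]):
            warnings.warn("constant tail currents: flat G-V", UserWarning)
        return sign * i / np.max(np.abs(i))
    if mode == "fitted":
        fit = fit_boltzmann(data)
        return sign * i / fit.g_max
    raise ValueError(f"unknown normalization mode {mode!r}")


def read_gv_table(path, patch_id: str = "") -> GVData:
    """Read a delimited (voltage_mV, tail_current) table."""
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("voltage_mV", "tail_current"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return GVData(
        voltages=df["voltage_mV"].to_numpy(float),
        tail_currents=df["tail_current"].to_numpy(float),
        patch_id=patch_id or str(path),
    )
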
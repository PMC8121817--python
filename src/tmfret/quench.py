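"""Patch fluorescence → unquenched fractions F → corrected FRET efficiencies.

In patch-clamp fluorometry quenching experiments the donor fluorescence of a
membrane patch is imaged before and after applying the metal acceptor
(Co²⁺ for engineered di-histidine sites, Cu²⁺-TETAC for engineered
cysteines).  After background subtraction, the unquenched fraction is

    F = fl(metal) / fl(no metal).

Some quenching is nonspecific (solution quenching, off-target labeling) and
is measured on a matched construct *lacking* the acceptor site.  Because
independent quenching pathways add in rate, the site-specific FRET
efficiency is recovered by the exact correction

    E = (F_no_site − F_site) / (F_site · F_no_site + F_no_site − F_site),

equivalently 1/F_site − 1/F_no_site = E / (1 − E).  E reduces to
1 − F_site when there is no nonspecific quenching (F_no_site = 1) and to 0
when quenching is entirely nonspecific (F_site = F_no_site).

Donor brightness can itself change with voltage (environmental sensitivity),
so F — a ratio taken *within* one voltage — is computed separately at each
voltage and never across voltages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PatchFluorescence",
    "QuenchSummary",
    "DataQualityError",
    "net_intensity",
    "unquenched_fraction",
    "fret_efficiency_corrected",
    "patch_unquenched_fractions",
    "summarize_condition",
    "condition_efficiencies",
    "read_patch_table",
    "write_summary_table",
    "VOLTAGES",
    "LIGANDS",
    "REQUIRED_COLUMNS",
    "state_name",
]

VOLTAGES = (0, -100)
LIGANDS = ("none", "cAMP", "cGMP")

REQUIRED_COLUMNS = [
    "patch_id",
    "construct",
    "has_site",
    "voltage_mV",
    "ligand",
    "fl_roi_no_metal",
    "bg_no_metal",
    "fl_roi_metal",
    "bg_metal",
]

#: Condition → functional-state naming for HCN-type channels: ligand bound at
#: 0 mV is the resting(-cAMP) state, hyperpolarized with ligand is activated,
#: hyperpolarized without ligand is inactivated.
_STATE_NAMES = {
    (0, "cAMP"): "resting-cAMP",
    (0, "none"): "resting-apo",
    (-100, "cAMP"): "activated",
    (-100, "none"): "inactivated",
}


def state_name(voltage_mV: int, ligand: str) -> str:
    """Functional state label for a (voltage, ligand) condition."""
    try:
        return _STATE_NAMES[(int(voltage_mV), ligand)]
    except KeyError:
        return f"{ligand}_{int(voltage_mV)}mV"


class DataQualityError(ValueError):
    """A patch record violates a physical sanity check."""


@dataclass(frozen=True)
class PatchFluorescence:
    """Raw per-patch ROI and background intensities for one condition."""

    patch_id: str
    construct: str
    has_site: bool
    voltage_mV: int
    ligand: str
    fl_roi_no_metal: float
    bg_no_metal: float
    fl_roi_metal: float
    bg_metal: float

    def __post_init__(self) -> None:
        if self.voltage_mV not in VOLTAGES:
            raise ValueError(
                f"voltage {self.voltage_mV} not in allowed set {VOLTAGES}"
            )
        if self.ligand not in LIGANDS:
            raise ValueError(f"ligand {self.ligand!r} not in {LIGANDS}")


@dataclass(frozen=True)
class QuenchSummary:
    """Per-condition summary of unquenched fractions over independent patches."""

    F_mean: float
    F_sem: float | None
    n: int
    voltage_mV: int
    ligand: str
    site_class: str  # "with_site" | "without_site"

    def __post_init__(self) -> None:
        if not 0 < self.F_mean <= 1.2:
            raise ValueError(f"F_mean {self.F_mean} outside (0, 1.2]")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def net_intensity(fl_roi: float, bg: float, patch_id: str = "?") -> float:
    """Background-subtracted intensity; must be strictly positive."""
    if not (np.isfinite(fl_roi) and np.isfinite(bg)):
        raise DataQualityError(f"patch {patch_id}: non-finite intensity")
    net = fl_roi - bg
    if net <= 0:
        raise DataQualityError(
            f"patch {patch_id}: non-positive net intensity "
            f"(ROI {fl_roi} - background {bg} = {net})"
        )
    return net


def unquenched_fraction(fl_metal: float, fl_no_metal: float) -> float:
    """F = fl(metal) / fl(no metal), both background-subtracted."""
    if fl_no_metal == 0:
        raise ZeroDivisionError("fl(no metal) is zero")
    return fl_metal / fl_no_metal


def fret_efficiency_corrected(
    F_site: float, F_no_site: float, clip: bool = True
) -> float:
    """Nonspecific-quenching-corrected FRET efficiency.

    ``F_site`` and ``F_no_site`` are the unquenched fractions with and
    without the engineered acceptor site.  Values pushed outside [0, 1] by
    measurement noise are clipped (with a warning) when ``clip`` is True.
    """
    for name, f in (("F_site", F_site), ("F_no_site", F_no_site)):
        if not 0 < f <= 1.2:
            raise ValueError(f"{name} = {f} outside (0, 1.2]")
    denom = F_site * F_no_site + F_no_site - F_site
    if denom <= 0:
        raise ArithmeticError(
            f"non-positive denominator {denom:.4g} in efficiency correction "
            f"(F_site={F_site}, F_no_site={F_no_site})"
        )
    eff = (F_no_site - F_site) / denom
    if clip and not 0.0 <= eff <= 1.0:
        warnings.warn(
            f"efficiency {eff:.4g} outside [0, 1]; clipped (noise)", UserWarning
        )
        eff = min(max(eff, 0.0), 1.0)
    return eff


def read_patch_table(path) -> pd.DataFrame:
    """Read a delimited (CSV/TSV) patch-fluorescence table and validate it."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad_v = set(df["voltage_mV"].unique()) - set(VOLTAGES)
    if bad_v:
        raise ValueError(f"{path}: unknown voltages {sorted(bad_v)}")
    bad_l = set(df["ligand"].unique()) - set(LIGANDS)
    if bad_l:
        raise ValueError(f"{path}: unknown ligand labels {sorted(bad_l)}")
    return df


def patch_unquenched_fractions(df: pd.DataFrame) -> pd.DataFrame:
    """Per-patch F from raw ROI/background columns.

    Adds ``F`` and ``site_class`` columns.  Raises
    :class:`DataQualityError` (naming the patch) on non-positive net
    intensities.
    """
    out = df.copy()
    f_vals = []
    for _, row in out.iterrows():
        net_no = net_intensity(
            row["fl_roi_no_metal"], row["bg_no_metal"], str(row["patch_id"])
        )
        net_m = net_intensity(
            row["fl_roi_metal"], row["bg_metal"], str(row["patch_id"])
        )
        f_vals.append(unquenched_fraction(net_m, net_no))
    out["F"] = f_vals
    out["site_class"] = np.where(out["has_site"], "with_site", "without_site")
    return out


def summarize_condition(df: pd.DataFrame) -> pd.DataFrame:
    """Group per-patch F by (site class, voltage, ligand): mean, s.e.m., n.

    ``df`` may be a raw patch table (F computed on the fly) or one already
    carrying an ``F`` column.  The s.e.m. is sd/√n and is reported as NaN
    for n = 1.
    """
    if df.empty:
        raise ValueError("empty patch table")
    if "F" not in df.columns:
        df = patch_unquenched_fractions(df)
    grouped = (
        df.groupby(["site_class", "voltage_mV", "ligand"])["F"]
        .agg(F_mean="mean", F_sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    grouped["F_sem"] = grouped["F_sd"] / np.sqrt(grouped["n"])
    return grouped.drop(columns="F_sd")


def condition_efficiencies(df: pd.DataFrame, clip: bool = False) -> pd.DataFrame:
    """Per-condition corrected FRET efficiencies with plain statistics.

    For each (voltage, ligand) condition, each with-site patch's F is
    corrected using the *averaged* F of all without-site patches under the
    same condition; the per-patch efficiencies are then summarized as
    mean ± s.e.m. over n with-site patches.  Statistics are computed on
    unclipped values; set ``clip`` to clip each per-patch efficiency.

    Returns a tidy frame with columns voltage_mV, ligand, state,
    efficiency_mean, efficiency_sem, n, F_site_mean, F_site_sem,
    F_no_site_mean, F_no_site_sem, n_no_site.
    """
    if "F" not in df.columns:
        df = patch_unquenched_fractions(df)
    rows = []
    for (v, lig), grp in df.groupby(["voltage_mV", "ligand"]):
        with_site = grp[grp["site_class"] == "with_site"]
        no_site = grp[grp["site_class"] == "without_site"]
        if with_site.empty or no_site.empty:
            raise ValueError(
                f"condition (voltage={v}, ligand={lig!r}) lacks "
                f"{'with-site' if with_site.empty else 'without-site'} patches"
            )
        f_no_mean = float(no_site["F"].mean())
        effs = np.array(
            [
                fret_efficiency_corrected(f, f_no_mean, clip=clip)
                for f in with_site["F"]
            ]
        )
        n = len(effs)
        rows.append(
            {
                "voltage_mV": v,
                "ligand": lig,
                "state": state_name(v, lig),
                "efficiency_mean": float(effs.mean()),
                "efficiency_sem": float(effs.std(ddof=1) / np.sqrt(n))
                if n > 1
                else np.nan,
                "n": n,
                "F_site_mean": float(with_site["F"].mean()),
                "F_site_sem": float(
                    with_site["F"].std(ddof=1) / np.sqrt(n)
                )
                if n > 1
                else np.nan,
                "F_no_site_mean": f_no_mean,
                "F_no_site_sem": float(
                    no_site["F"].std(ddof=1) / np.sqrt(len(no_site))
                )
                if len(no_site) > 1
                else np.nan,
                "n_no_site": len(no_site),
            }
        )
    return pd.DataFrame(rows)


def write_summary_table(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, index=False)
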
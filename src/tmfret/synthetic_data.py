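"""Ground-truth generators for every input the pipeline consumes.

No raw patch-clamp fluorometry measurements ship with this package, so each
reader in the pipeline has a matching simulator with *known ground truth*:
patch fluorescence cohorts (with Gaussian distance heterogeneity,
nonspecific quenching, background offsets, expression scaling shared by the
donor and YFP signals, voltage-dependent donor brightness, and measurement
noise), donor/acceptor spectra with an analytic overlap integral,
calibration pairs, Boltzmann G-V tables, and exactly C4-symmetric structure
fixtures in PDB format.  Every generator is a pure function of its
parameters and seed.

Default preset (the regime of short-range transition-metal FRET on a
tetrameric channel): Förster radii 13.3 Å at 0 mV and 13.0 Å at −100 mV,
backbone distances 15–25 Å with Gaussian heterogeneity σ = 5 Å, nonspecific
unquenched fraction 0.9, donor brightness ×1.26 at −100 mV, 3% intensity
noise, and 5 patches per condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .calibration import CalibrationPair
from .ephys import GVData, boltzmann
from .forster_core import FCGModel, fcg_efficiency
from .spectra import R0Parameters, Spectrum, overlap_integral

__all__ = [
    "GroundTruth",
    "DEFAULT_TRUTH",
    "expected_unquenched_fraction",
    "simulate_patch_cohort",
    "simulate_spectra",
    "simulate_calibration_pairs",
    "simulate_gv",
    "simulate_c4_tetramer",
    "c4_site_positions",
    "solve_two_ring_geometry",
    "write_cohort",
]

STATES = {
    "resting-cAMP": (0, "cAMP"),
    "resting-apo": (0, "none"),
    "activated": (-100, "cAMP"),
    "inactivated": (-100, "none"),
}


@dataclass(frozen=True)
class GroundTruth:
    """True parameters behind a simulated tmFRET experiment."""

    state_distances: dict = field(
        default_factory=lambda: {
            "resting-cAMP": 24.0,
            "resting-apo": 20.0,
            "activated": 21.0,
            "inactivated": 18.0,
        }
    )
    sigma: float = 5.0
    r0_by_voltage: dict = field(default_factory=lambda: {0: 13.3, -100: 13.0})
    f_ns: float = 0.9  # nonspecific unquenched fraction
    brightness_ratio_neg100: float = 1.26  # donor environmental change
    intensity_noise_frac: float = 0.03  # relative sd of each intensity read
    expression_lognorm_sd: float = 0.4  # patch-to-patch expression spread
    donor_base_intensity: float = 1000.0  # a.u.
    yfp_base_intensity: float = 2000.0  # a.u.
    background_mean: float = 50.0  # a.u.

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.state_distances.values()):
            raise ValueError("state distances must be > 0")
        if not 0 < self.f_ns <= 1:
            raise ValueError("f_ns must be in (0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def fcg_model(self, voltage_mV: int) -> FCGModel:
        sig = self.sigma
        return FCGModel(
            r0=self.r0_by_voltage[int(voltage_mV)],
            sigma=sig,
            quadrature_step=min(0.05, sig / 5) if sig > 0 else 0.05,
        )

    def true_efficiency(self, state: str) -> float:
        voltage, _ = STATES[state]
        return fcg_efficiency(self.state_distances[state], self.fcg_model(voltage))


DEFAULT_TRUTH = GroundTruth()


def expected_unquenched_fraction(efficiency: float, f_ns: float) -> float:
    """Noise-free F for a with-site patch under rate-additive quenching.

    FRET and nonspecific quenching are independent decay pathways, so their
    rates add: 1/F_site = 1/F_ns + E/(1−E).  This is exactly the relation
    the corrected-efficiency formula inverts, so a zero-noise cohort closes
    the loop identically.
    """
    if not 0 <= efficiency < 1:
        raise ValueError("efficiency must be in [0, 1)")
    return f_ns * (1 - efficiency) / ((1 - efficiency) + efficiency * f_ns)


def simulate_patch_cohort(
    truth: GroundTruth = DEFAULT_TRUTH,
    n_patches: int = 5,
    seed: int | None = None,
    noise: bool = True,
) -> pd.DataFrame:
    """Simulate a full four-state cohort of with-site and without-site patches.

    For each functional state (voltage × ligand) the generator draws
    ``n_patches`` patches of the acceptor-site construct and ``n_patches``
    of the matched no-site control.  Per patch: a lognormal expression
    scale multiplies both the donor and YFP intensities; the donor
    intensity gains the brightness ratio at −100 mV; the metal-on intensity
    is the no-metal intensity times the expected unquenched fraction;
    background offsets are added; and every recorded intensity receives
    Gaussian noise at ``truth.intensity_noise_frac`` (disabled when
    ``noise=False``).

    Returns the tidy patch table the quench reader consumes, plus a
    ``yfp_intensity`` column (expression-correlated, for quantum-yield
    slope estimation) and a ``state`` column.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for state, (voltage, ligand) in STATES.items():
        e_true = truth.true_efficiency(state)
        for has_site in (True, False):
            f_expected = (
                expected_unquenched_fraction(e_true, truth.f_ns)
                if has_site
                else truth.f_ns
            )
            for k in range(n_patches):
                scale = float(
                    np.exp(rng.normal(0.0, truth.expression_lognorm_sd))
                )
                donor = truth.donor_base_intensity * scale
                if voltage == -100:
                    donor *= truth.brightness_ratio_neg100
                net_no_metal = donor
                net_metal = donor * f_expected
                bg = truth.background_mean
                roi_no = net_no_metal + bg
                roi_m = net_metal + bg
                if noise:
                    frac = truth.intensity_noise_frac
                    roi_no = rng.normal(roi_no, frac * net_no_metal)
                    roi_m = rng.normal(roi_m, frac * net_metal)
                    bg_no = rng.normal(bg, frac * bg)
                    bg_m = rng.normal(bg, frac * bg)
                else:
                    bg_no = bg_m = bg
                yfp = truth.yfp_base_intensity * scale
                if noise:
                    yfp = rng.normal(yfp, truth.intensity_noise_frac * yfp)
                rows.append(
                    {
                        "patch_id": f"{state}_{'site' if has_site else 'nosite'}_{k}",
                        "construct": "donor+acceptorsite" if has_site else "donor",
                        "has_site": has_site,
                        "voltage_mV": voltage,
                        "ligand": ligand,
                        "fl_roi_no_metal": roi_no,
                        "bg_no_metal": bg_no,
                        "fl_roi_metal": roi_m,
                        "bg_metal": bg_m,
                        "yfp_intensity": yfp,
                        "state": state,
                    }
                )
    return pd.DataFrame(rows)


def simulate_spectra(
    donor_peak_nm: float = 480.0,
    donor_sd_nm: float = 20.0,
    acceptor_extinction: float = 300.0,
    wavelength_range: tuple[float, float] = (350.0, 650.0),
    grid_step: float = 1.0,
    target_r0: float | None = None,
    params: R0Parameters | None = None,
) -> dict:
    """Gaussian donor emission and flat acceptor extinction with analytic J.

    With a constant extinction ε over the full donor support the overlap
    integral has the closed form J = ε·E[λ⁴] = ε (μ⁴ + 6 μ² s² + 3 s⁴) for
    the Gaussian emission (truncation beyond ±5 s is negligible).  When
    ``target_r0`` (Å) is given, the donor quantum yield Q that makes the
    Förster-radius equation produce exactly that radius is solved for and
    returned.

    Returns a dict with ``donor``, ``acceptor`` (:class:`Spectrum`),
    ``J_analytic``, ``J_numeric`` and (if requested) ``Q``.
    """
    if params is None:
        params = R0Parameters()
    lo, hi = wavelength_range
    wl = np.arange(lo, hi + grid_step, grid_step)
    emission = np.exp(-0.5 * ((wl - donor_peak_nm) / donor_sd_nm) ** 2)
    donor = Spectrum(wl, emission)
    acceptor = Spectrum(wl, np.full_like(wl, float(acceptor_extinction)))
    mu, s = donor_peak_nm, donor_sd_nm
    j_analytic = acceptor_extinction * (mu**4 + 6 * mu**2 * s**2 + 3 * s**4)
    out = {
        "donor": donor,
        "acceptor": acceptor,
        "J_analytic": float(j_analytic),
        "J_numeric": overlap_integral(donor, acceptor, grid_step),
    }
    if target_r0 is not None:
        q = (target_r0 / params.scale_C) ** 6 / (
            j_analytic * params.eta**-4 * params.kappa2
        )
        if not 0 < q <= 1:
            raise ValueError(
                f"target_r0 {target_r0} needs quantum yield {q:.3g} outside (0, 1]; "
                "adjust the acceptor extinction or spectra"
            )
        out["Q"] = float(q)
    return out


def simulate_calibration_pairs(
    distances: "list[float]",
    r0s: "list[float]",
    sigma: float = 5.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> list[CalibrationPair]:
    """Calibration pairs at known distances with optional efficiency noise.

    Efficiencies are FCG(dᵢ; R0ᵢ, σ) plus Gaussian noise, clipped to the
    open unit interval (a measured efficiency of exactly 0 or 1 is not
    physical for a calibration pair).
    """
    if len(distances) != len(r0s):
        raise ValueError("distances and r0s must have equal length")
    rng = np.random.default_rng(seed)
    pairs = []
    for i, (d, r0) in enumerate(zip(distances, r0s)):
        model = FCGModel(
            r0=r0, sigma=sigma,
            quadrature_step=min(0.05, sigma / 5) if sigma > 0 else 0.05,
        )
        eff = fcg_efficiency(d, model)
        if noise_sd > 0:
            eff = float(np.clip(eff + rng.normal(0, noise_sd), 1e-4, 1 - 1e-4))
        pairs.append(
            CalibrationPair(pair_id=f"pair{i}", known_distance=d,
                            efficiency=eff, r0=r0)
        )
    return pairs


def simulate_gv(
    v_half: float,
    v_s: float,
    voltages: "np.ndarray | list[float] | None" = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    g_max: float = 1.0,
    patch_id: str = "sim",
) -> GVData:
    """Boltzmann tail-current curve with Gaussian noise on relative conductance."""
    if voltages is None:
        voltages = np.arange(0.0, -115.0, -10.0)
    v = np.asarray(voltages, float)
    rng = np.random.default_rng(seed)
    g = g_max * boltzmann(v, v_half, v_s)
    if noise_sd > 0:
        g = g + rng.normal(0.0, noise_sd * g_max, size=v.size)
    return GVData(voltages=v, tail_currents=g, patch_id=patch_id)


def c4_site_positions(radius: float, z: float, phase: float) -> np.ndarray:
    """Analytic positions of one site on the four chains of a C4 ring."""
    ang = phase + np.arange(4) * (np.pi / 2)
    return np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), np.full(4, z)]
    )


def solve_two_ring_geometry(
    d_same: float,
    d_adjacent: float,
    d_diagonal: float,
    donor_radius: float = 23.0,
) -> dict:
    """Acceptor-ring parameters consistent with three inter-subunit distances.

    Synthetic stand-in construction: given a donor ring of radius
    ``donor_radius`` at z = 0, phase 0, solve for the acceptor ring
    (radius, height, phase) of a C4 tetramer whose same-subunit, nearest
    adjacent-subunit, and diagonal-subunit donor→acceptor distances equal
    the three inputs.  With M = (d_same² + d_diag²)/2 the identities
    rd·ra·cosφ = (d_diag² − d_same²)/4 and rd·ra·sinφ = (d_adj² − M)/2
    determine the ring uniquely up to reflection; the height follows from
    h² = M − rd² − ra² (an error is raised when the requested donor radius
    makes h² negative).
    """
    ds2, da2, dd2 = d_same**2, d_adjacent**2, d_diagonal**2
    m = (ds2 + dd2) / 2.0
    p = (dd2 - ds2) / 4.0
    q = (da2 - m) / 2.0
    t = float(np.hypot(p, q))  # = rd * ra
    ra = t / donor_radius
    h2 = m - donor_radius**2 - ra**2
    if h2 < 0:
        raise ValueError(
            f"no consistent geometry at donor_radius {donor_radius}: h^2 = {h2:.3g}"
        )
    return {
        "donor_radius": donor_radius,
        "acceptor_radius": float(ra),
        "height": float(np.sqrt(h2)),
        "phase": float(np.arctan2(q, p)),
    }


_PDB_ATOM = (
    "ATOM  {serial:>5d} {name:<4s}{alt:1s}{res:<3s} {chain:1s}{resnum:>4d}"
    "{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
    "{element:>2s}\n"
)


def simulate_c4_tetramer(
    sites: dict,
    n_residues: int | None = None,
    filler_radius: float = 15.0,
    chains: str = "ABCD",
) -> str:
    """Exactly C4-symmetric poly-alanine tetramer fixture as PDB text.

    ``sites`` maps residue number → (radius Å, z Å, phase rad); the Cβ atom
    of each listed residue is placed at the analytic ring position
    (:func:`c4_site_positions`), so inter-subunit Cβ–Cβ distances are known
    in closed form.  All other residues are filler placed on an inner
    helix-like path (they give each chain a center of mass in the correct
    angular quadrant for ring ordering).  Chains are exact 90° rotations of
    each other about the z axis.  The fixture is synthetic: its geometry is
    constructed, not derived from any deposited structure.
    """
    if not sites:
        raise ValueError("need at least one probe site")
    if any(r <= 0 for r, _, _ in sites.values()):
        raise ValueError("site radii must be > 0")
    max_res = max(sites)
    if n_residues is None:
        n_residues = max_res + 2
    if n_residues < max_res:
        raise ValueError("n_residues must cover all probe sites")

    lines = []
    serial = 1
    for k, chain in enumerate(chains):
        rot = k * np.pi / 2
        for resnum in range(1, n_residues + 1):
            if resnum in sites:
                radius, z, phase = sites[resnum]
            else:
                radius = filler_radius
                z = 1.0 * resnum
                phase = np.deg2rad(4.0 * resnum)
            ang = phase + rot
            cb = np.array(
                [radius * np.cos(ang), radius * np.sin(ang), z]
            )
            inward = -np.array([np.cos(ang), np.sin(ang), 0.0])
            ca = cb + 1.53 * inward
            n_at = ca + np.array([0.0, 0.0, -1.2]) + 0.8 * inward
            c_at = ca + np.array([0.0, 0.0, 1.2]) + 0.8 * inward
            o_at = c_at + np.array([0.0, 0.0, 0.6]) + 0.6 * inward
            for name, pos, element in (
                ("N", n_at, "N"),
                ("CA", ca, "C"),
                ("C", c_at, "C"),
                ("O", o_at, "O"),
                ("CB", cb, "C"),
            ):
                lines.append(
                    _PDB_ATOM.format(
                        serial=serial,
                        name=f" {name}" if len(name) < 4 else name,
                        alt=" ",
                        res="ALA",
                        chain=chain,
                        resnum=resnum,
                        icode=" ",
                        x=pos[0],
                        y=pos[1],
                        z=pos[2],
                        occ=1.0,
                        b=0.0,
                        element=element,
                    )
                )
                serial += 1
        lines.append(f"TER   {serial:>5d}      ALA {chain}{n_residues:>4d}\n")
        serial += 1
    lines.append("END\n")
    return "".join(lines)


def write_cohort(df: pd.DataFrame, path, truth: GroundTruth, seed, n_patches: int) -> None:
    """Write a simulated cohort CSV plus a JSON metadata sidecar."""
    df.to_csv(path, index=False)
    meta = {
        "generator": "tmfret.synthetic_data.simulate_patch_cohort",
        "seed": seed,
        "n_patches": n_patches,
        "truth": {
            k: (dict(v) if isinstance(v, dict) else v)
            for k, v in asdict(truth).items()
        },
    }
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
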
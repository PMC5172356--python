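"""Synthetic fluorescence, DSC, and ¹⁵N relaxation data generators.

Each generator emits data with the statistical structure the downstream
analysis assumes, together with the generating ground truth, so the entire
pipeline can be exercised and calibrated without instrument data.

* Thermal/chemical melts: two-state mixtures of Gaussian tryptophan emission
  bands whose native fraction follows a logistic in the condition variable;
  unfolding red-shifts the band (denatured center > native center).
* DSC: two-state van't Hoff excess heat-capacity endotherms, optionally
  multi-component (conjugate traces), with per-component reversibility on
  reheat, polynomial baseline and additive noise.
* Relaxation: per-residue Lipari–Szabo model-free spectral densities drive
  the full forward relaxation equations; decay curves are mono-exponentials
  at those rates sampled on the stated delay grids with multiplicative
  Gaussian noise, and steady-state NOE pairs are generated in duplicate.

All randomness flows through ``numpy.random.default_rng`` (PCG64); a fixed
seed yields bit-identical datasets across runs and platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataio import DecayCurve, DSCTrace, EmissionSpectrum, NoePair, ValidationError
from .relaxfit import (RelaxationRecord, SpinSystemConstants, forward_rates,
                       model_free_j)

__all__ = [
    "GAS_CONSTANT",
    "MeltSimParams",
    "ModelFreeParams",
    "RelaxSimParams",
    "DSCComponent",
    "DSCSimParams",
    "simulate_melt_series",
    "simulate_relaxation_dataset",
    "simulate_dsc_trace",
    "make_model_free_profile",
    "T1_DELAYS_S",
    "T2_DELAYS_S",
]

GAS_CONSTANT = 8.31446261815324e-3   # kJ mol^-1 K^-1

# standard inversion-recovery / CPMG delay grids, seconds
T1_DELAYS_S = (0.010, 0.020, 0.040, 0.180, 0.300, 0.500, 1.000)
T2_DELAYS_S = (0.010, 0.030, 0.050, 0.070, 0.090, 0.110, 0.150)


# ---------------------------------------------------------------------------
# Fluorescence melts
# ---------------------------------------------------------------------------

@dataclass
class MeltSimParams:
    """Two-state melt simulation parameters.

    ``midpoint_true`` is T_half in K (thermal mode) or c_half in mol/L
    (chemical mode).  ``rate`` is the sigmoid slope parameter in the condition
    unit; alternatively supply a van't Hoff enthalpy ``delta_h_vh`` (kJ/mol)
    and the rate is derived as R·T_half²/ΔH_vH.  ``baseline_slopes`` drift the
    native/denatured band centers linearly in the condition (nm per unit).
    ``noise_sd`` is multiplicative Gaussian intensity noise (fraction).
    """

    midpoint_true: float
    rate: float = 2.0
    delta_h_vh: float | None = None
    condition_kind: str = "thermal"
    native_band_center: float = 335.0
    denatured_band_center: float = 355.0
    band_width: float = 18.0
    baseline_slopes: tuple = (0.0, 0.0)
    noise_sd: float = 0.02
    n_replicates: int = 3
    wavelength_grid: np.ndarray = field(
        default_factory=lambda: np.arange(310.0, 401.0, 1.0))
    condition_grid: np.ndarray = field(
        default_factory=lambda: np.arange(300.0, 361.0, 2.0))
    seed: int = 0

    def __post_init__(self):
        self.wavelength_grid = np.asarray(self.wavelength_grid, dtype=float)
        self.condition_grid = np.asarray(self.condition_grid, dtype=float)
        if self.denatured_band_center <= self.native_band_center:
            raise ValidationError(
                "denatured band center must exceed the native one (red shift)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be at least 1")
        if self.delta_h_vh is not None:
            if self.delta_h_vh <= 0:
                raise ValidationError("delta_h_vh must be positive")
            self.rate = GAS_CONSTANT * self.midpoint_true**2 / self.delta_h_vh
        if not (self.condition_grid.min() <= self.midpoint_true
                <= self.condition_grid.max()):
            warnings.warn("midpoint outside the condition grid; downstream fits "
                          "will be extrapolative", stacklevel=2)


def _gaussian_band(lam: np.ndarray, center: float, width: float) -> np.ndarray:
    """Gaussian emission band normalized to unit summed intensity on the grid.

    Equal integrated intensity for the native and denatured bands makes the
    barycentric mean of a two-state mixture an exact Boltzmann sigmoid in the
    condition variable (the weights are then the state populations), so
    noiseless simulations round-trip through the sigmoid fit exactly.
    """
    g = np.exp(-0.5 * ((lam - center) / width) ** 2)
    return g / np.sum(g)


def simulate_melt_series(params: MeltSimParams) -> list[EmissionSpectrum]:
    """Simulate emission spectra across the condition grid and replicates.

    Each spectrum is p_N·Band(native) + (1−p_N)·Band(denatured) with
    p_N(x) = 1/(1+exp((x−midpoint)/rate)), times (1 + Gaussian noise).
    Replicates differ only by the noise stream.
    """
    rng = np.random.default_rng(params.seed)
    lam = params.wavelength_grid
    x0 = params.condition_grid[0]
    out = []
    for rep in range(1, params.n_replicates + 1):
        for cond in params.condition_grid:
            p_native = 1.0 / (1.0 + np.exp((cond - params.midpoint_true) / params.rate))
            c_n = params.native_band_center + params.baseline_slopes[0] * (cond - x0)
            c_d = params.denatured_band_center + params.baseline_slopes[1] * (cond - x0)
            f = (p_native * _gaussian_band(lam, c_n, params.band_width)
                 + (1.0 - p_native) * _gaussian_band(lam, c_d, params.band_width))
            if params.noise_sd > 0:
                f = f * (1.0 + rng.normal(0.0, params.noise_sd, size=lam.size))
            out.append(EmissionSpectrum(
                condition_value=float(cond),
                wavelengths=lam.copy(),
                intensities=f,
                condition_kind=params.condition_kind,
                replicate_id=f"rep{rep}",
            ))
    return out


# ---------------------------------------------------------------------------
# Relaxation
# ---------------------------------------------------------------------------

@dataclass
class ModelFreeParams:
    """Ground-truth motional parameters for one residue."""

    residue_id: str
    s2: float = 0.86
    tau_e_ps: float = 50.0
    tau_m_ns: float = 8.0
    rex: float = 0.0          # s^-1, adds to R2

    def __post_init__(self):
        if not (0.0 <= self.s2 <= 1.0):
            raise ValidationError("S^2 must lie in [0, 1]")
        if self.tau_m_ns <= 0:
            raise ValidationError("tau_m must be positive")
        if self.tau_e_ps < 0:
            raise ValidationError("tau_e must be non-negative")
        if self.rex < 0:
            raise ValidationError("rex must be non-negative")


@dataclass
class RelaxSimParams:
    residues: list
    field_mhz: float = 600.13
    noise_fraction: float = 0.02
    t1_delays: tuple = T1_DELAYS_S
    t2_delays: tuple = T2_DELAYS_S
    noe_replicates: int = 2
    i0: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.field_mhz <= 0:
            raise ValidationError("field_mhz must be positive")
        if len(self.t1_delays) < 4 or len(self.t2_delays) < 4:
            raise ValidationError("delay grids need at least 4 points")
        if self.noise_fraction < 0:
            raise ValidationError("noise_fraction must be non-negative")


def make_model_free_profile(n_residues: int = 60, tau_m_ns: float = 8.0,
                            s2: float = 0.86, tau_e_ps: float = 50.0,
                            n_mobile_terminal: int = 3,
                            rex_by_residue: dict | None = None) -> list[ModelFreeParams]:
    """A deterministic protein-like motional profile.

    A rigid core at the given S², with ``n_mobile_terminal`` flexible residues
    at each terminus (S² ramping down to 0.5, slower internal motion), plus
    optional exchange broadening assigned per residue number (1-based).
    """
    rex_by_residue = rex_by_residue or {}
    out = []
    for i in range(1, n_residues + 1):
        dist = min(i - 1, n_residues - i)
        if dist < n_mobile_terminal:
            frac = (dist + 1) / (n_mobile_terminal + 1)
            res_s2 = 0.5 + (s2 - 0.5) * frac
            res_te = 500.0
        else:
            res_s2, res_te = s2, tau_e_ps
        out.append(ModelFreeParams(
            residue_id=str(i), s2=res_s2, tau_e_ps=res_te, tau_m_ns=tau_m_ns,
            rex=float(rex_by_residue.get(i, 0.0))))
    return out


def simulate_relaxation_dataset(params: RelaxSimParams,
                                constants: SpinSystemConstants | None = None):
    """Simulate decay curves, NOE duplicates, and the ground-truth rate table.

    Returns ``(t1_curves, t2_curves, noe_pairs, truth_records)``.  For each
    residue the model-free spectral density drives the full forward
    relaxation equations (Rex added to R2); decays are mono-exponential at
    those rates with multiplicative Gaussian noise, and each NOE replicate is
    an independently noised (I_sat, I_eq) pair with I_sat/I_eq = NOE.
    """
    constants = constants or SpinSystemConstants(field_mhz=params.field_mhz)
    rng = np.random.default_rng(params.seed)
    t1_grid = np.asarray(params.t1_delays, dtype=float)
    t2_grid = np.asarray(params.t2_delays, dtype=float)

    def _noise(shape):
        if params.noise_fraction == 0:
            return 1.0
        return 1.0 + rng.normal(0.0, params.noise_fraction, size=shape)

    t1_curves, t2_curves, noe_pairs, truth = [], [], [], []
    for mf in params.residues:
        j = model_free_j(mf.s2, mf.tau_e_ps, mf.tau_m_ns)
        r1, r2, noe = forward_rates(j, constants, rex=mf.rex)
        i1 = params.i0 * np.exp(-r1 * t1_grid) * _noise(t1_grid.size)
        i2 = params.i0 * np.exp(-r2 * t2_grid) * _noise(t2_grid.size)
        t1_curves.append(DecayCurve(mf.residue_id, t1_grid.copy(), i1, "T1"))
        t2_curves.append(DecayCurve(mf.residue_id, t2_grid.copy(), i2, "T2"))
        for rep in range(1, params.noe_replicates + 1):
            i_eq = params.i0 * float(np.squeeze(_noise(1)))
            i_sat = params.i0 * noe * float(np.squeeze(_noise(1)))
            noe_pairs.append(NoePair(mf.residue_id, i_sat, i_eq, f"rep{rep}"))
        truth.append(RelaxationRecord(
            residue_id=mf.residue_id, r1=r1, r1_err=0.0, r2=r2, r2_err=0.0,
            noe=noe, noe_err=0.0, field_mhz=constants.field_mhz))
    return t1_curves, t2_curves, noe_pairs, truth


# ---------------------------------------------------------------------------
# DSC
# ---------------------------------------------------------------------------

@dataclass
class DSCComponent:
    """One two-state transition: midpoint (K), van't Hoff enthalpy (kJ/mol),
    amplitude scale, and the fraction of the endotherm recovered on reheat."""

    t_m: float
    delta_h_vh: float = 500.0
    amplitude: float = 1.0
    reversibility: float = 1.0

    def __post_init__(self):
        if self.delta_h_vh <= 0:
            raise ValidationError("delta_h_vh must be positive")
        if not (0.0 <= self.reversibility <= 1.0):
            raise ValidationError("reversibility must lie in [0, 1]")


@dataclass
class DSCSimParams:
    components: list
    baseline: tuple = (0.0,)       # polynomial coefficients in (T - Tmin), kJ/K/mol
    noise_sd: float = 0.0
    temperature_grid: np.ndarray = field(
        default_factory=lambda: np.arange(300.0, 360.0 + 1e-9, 0.1))
    scan_rate: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.temperature_grid = np.asarray(self.temperature_grid, dtype=float)
        if len(self.components) == 0:
            raise ValidationError("at least one transition component is required")
        tmin, tmax = self.temperature_grid.min(), self.temperature_grid.max()
        for comp in self.components:
            if not (tmin <= comp.t_m <= tmax):
                raise ValidationError(
                    f"component t_m={comp.t_m} K lies outside the temperature grid")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


def vant_hoff_excess_cp(temps: np.ndarray, t_m: float, delta_h_vh: float,
                        amplitude: float = 1.0) -> np.ndarray:
    """Two-state van't Hoff excess heat capacity, kJ K⁻¹ mol⁻¹.

    Cp_ex(T) = A · ΔH_vH²/(R·T_m²) · K/(1+K)²,  K = exp[−(ΔH_vH/R)(1/T − 1/T_m)].

    The prefactor is evaluated at T_m so that the maximum sits exactly at the
    nominal transition temperature (with a T-dependent prefactor the peak
    shifts ≈ 4R²T_m³/ΔH² below T_m, fractions of a kelvin).
    """
    x = -(delta_h_vh / GAS_CONSTANT) * (1.0 / temps - 1.0 / t_m)
    k = np.exp(x)
    return amplitude * delta_h_vh**2 / (GAS_CONSTANT * t_m**2) * k / (1.0 + k) ** 2


def simulate_dsc_trace(params: DSCSimParams) -> tuple[DSCTrace, DSCTrace]:
    """Simulate a (first heat, reheat) pair of DSC traces.

    The reheat multiplies each component by its reversibility fraction;
    baseline and (additive Gaussian) noise apply to both scans with
    independent noise draws.
    """
    rng = np.random.default_rng(params.seed)
    temps = params.temperature_grid
    base = np.polyval(params.baseline[::-1], temps - temps.min())
    first = base.copy()
    reheat = base.copy()
    for comp in params.components:
        peak = vant_hoff_excess_cp(temps, comp.t_m, comp.delta_h_vh, comp.amplitude)
        first += peak
        reheat += comp.reversibility * peak
    if params.noise_sd > 0:
        first = first + rng.normal(0.0, params.noise_sd, temps.size)
        reheat = reheat + rng.normal(0.0, params.noise_sd, temps.size)
    return (
        DSCTrace(temps.copy(), first, "first_heat", params.scan_rate),
        DSCTrace(temps.copy(), reheat, "reheat", params.scan_rate),
    )
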
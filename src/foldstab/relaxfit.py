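"""¹⁵N backbone relaxation analysis.

The module covers the chain from raw per-residue decay curves to per-residue
spectral densities and destabilization profiles:

* mono-exponential T1/T2 fitting with Monte Carlo error estimates,
* steady-state {¹H}-¹⁵N NOE from saturated/equilibrium intensity pairs
  (hnNOE = I_sat / I_eq), averaged over duplicate experiments with the
  between-duplicate standard deviation as the error,
* the forward relaxation equations R1(J), R2(J), NOE(J) for an amide
  ¹⁵N spin relaxed by the ¹H–¹⁵N dipolar interaction and ¹⁵N CSA,
* reduced spectral density mapping (R1, R2, NOE) → J(0), J(ωN), J(0.87ωH)
  with first-order analytic error propagation,
* isotropic rotational correlation time from the trimmed R2/R1 ratio,
* per-residue J(0) ratio profiles between two states of a protein,
* a chemical-shift-perturbation utility for assigned peak lists.

Conventions.  Angular frequencies are rad/s and spectral densities seconds
per radian internally; mapped J values are reported in ns.  The ¹⁵N
gyromagnetic ratio is negative; frequency arguments use magnitudes (J is
even) while the signed γH/γN ratio enters the NOE.

The reduced mapping lumps the three high-frequency densities
J(ωH−ωN) ≈ J(ωH) ≈ J(ωH+ωN) onto the single effective frequency 0.87ωH:

    σ      = R1 (NOE − 1) γN/γH
    J(0.87ωH) = 4σ / (5d²)
    J(ωN)  = [R1 − (7d²/4) J(0.87ωH)] / (3d²/4 + c²)
    J(0)   = [R2 − (13d²/8) J(0.87ωH) − (3d²/8 + c²/2) J(ωN)] / (d²/2 + 2c²/3)

with dipolar constant d = (μ0 ħ γH γN)/(4π r_NH³) and CSA constant
c = ωN Δσ/√3.  Applied to rates from the full five-frequency equations the
mapping is approximate (≲5% on J(0) for τm of 2–20 ns at 600 MHz); applied
to rates built with the same lumping it is an exact algebraic inverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, curve_fit
from scipy import stats

from .dataio import DecayCurve, NoePair, PeakList, ValidationError

__all__ = [
    "MU0",
    "HBAR",
    "SpinSystemConstants",
    "ExpFitResult",
    "RelaxationRecord",
    "SpectralDensities",
    "JRatioProfile",
    "model_free_j",
    "fit_exponential",
    "compute_hnnoe",
    "forward_rates",
    "forward_rates_lumped",
    "reduced_spectral_density",
    "map_spectral_densities",
    "estimate_tauc_isotropic",
    "jratio_profile",
    "compute_csp",
    "fit_relaxation_dataset",
]

MU0 = 4e-7 * np.pi          # vacuum permeability, T m A^-1
HBAR = 1.054571817e-34      # reduced Planck constant, J s


@dataclass(frozen=True)
class SpinSystemConstants:
    """Physical constants of the amide ¹H–¹⁵N spin pair at a stated field.

    Defaults follow common backbone-relaxation practice: r_NH = 1.02 Å,
    Δσ(¹⁵N) = −172 ppm.  All outputs that depend on these constants should
    echo them into their metadata so results are replayable.
    """

    field_mhz: float = 600.13
    gamma_h: float = 2.6752218744e8    # rad s^-1 T^-1
    gamma_n: float = -2.7116e7         # rad s^-1 T^-1 (negative)
    r_nh_angstrom: float = 1.02
    delta_sigma_ppm: float = -172.0

    def __post_init__(self):
        if self.field_mhz <= 0:
            raise ValidationError("field_mhz must be positive")
        if self.r_nh_angstrom <= 0:
            raise ValidationError("r_nh must be positive")

    @property
    def omega_h(self) -> float:
        """¹H Larmor frequency, rad/s (positive)."""
        return 2.0 * np.pi * self.field_mhz * 1e6

    @property
    def omega_n(self) -> float:
        """¹⁵N Larmor frequency, rad/s (signed; negative for ¹⁵N)."""
        return self.omega_h * self.gamma_n / self.gamma_h

    @property
    def d(self) -> float:
        """Dipolar coupling constant magnitude, rad/s."""
        r = self.r_nh_angstrom * 1e-10
        return abs(MU0 * HBAR * self.gamma_h * self.gamma_n / (4.0 * np.pi * r**3))

    @property
    def c(self) -> float:
        """CSA coupling constant magnitude, rad/s."""
        return abs(self.omega_n) * abs(self.delta_sigma_ppm) * 1e-6 / np.sqrt(3.0)

    def as_dict(self) -> dict:
        return {
            "field_mhz": self.field_mhz,
            "gamma_h": self.gamma_h,
            "gamma_n": self.gamma_n,
            "r_nh_angstrom": self.r_nh_angstrom,
            "delta_sigma_ppm": self.delta_sigma_ppm,
        }

    @classmethod
    def from_config(cls, cfg: Mapping) -> "SpinSystemConstants":
        c = cfg.get("constants", {})
        return cls(
            field_mhz=cfg.get("field_mhz", 600.13),
            gamma_h=c.get("gamma_h", 2.6752218744e8),
            gamma_n=c.get("gamma_n", -2.7116e7),
            r_nh_angstrom=c.get("r_nh_angstrom", 1.02),
            delta_sigma_ppm=c.get("delta_sigma_ppm", -172.0),
        )


@dataclass
class ExpFitResult:
    residue_id: str
    t_relax: float          # seconds
    i0: float
    mc_error: float         # seconds
    residual_rms: float
    converged: bool
    experiment: str = "T1"


@dataclass
class RelaxationRecord:
    residue_id: str
    r1: float               # s^-1
    r1_err: float
    r2: float               # s^-1
    r2_err: float
    noe: float
    noe_err: float
    field_mhz: float = 600.13

    def __post_init__(self):
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValidationError("relaxation rates must be positive")
        if min(self.r1_err, self.r2_err, self.noe_err) < 0:
            raise ValidationError("errors must be non-negative")


@dataclass
class SpectralDensities:
    """Mapped spectral densities for one residue, in ns.

    Negative or non-finite mapped values are possible under noise; they are
    flagged invalid (never clamped) and excluded from summaries and ratios.
    """

    residue_id: str
    j0: float
    j0_err: float
    j_wn: float
    j_wn_err: float
    j_wh: float
    j_wh_err: float
    j0_valid: bool = True
    j_wn_valid: bool = True
    j_wh_valid: bool = True


@dataclass
class JRatioProfile:
    residue_ids: list
    ratios: np.ndarray
    errors: np.ndarray
    mean: float
    sd: float
    mean_j0_modified: float
    sd_j0_modified: float
    mean_j0_unmodified: float
    sd_j0_unmodified: float


# ---------------------------------------------------------------------------
# Spectral density models and forward equations
# ---------------------------------------------------------------------------

def model_free_j(s2: float, tau_e_ps: float, tau_m_ns: float) -> Callable[[float], float]:
    """Lipari–Szabo model-free spectral density J(ω), seconds per radian.

    J(ω) = (2/5)[S² τm/(1+(ωτm)²) + (1−S²) τ/(1+(ωτ)²)],  1/τ = 1/τm + 1/τe.

    S² is the generalized order parameter (0–1), τe the effective internal
    correlation time (ps) and τm the overall tumbling time (ns).
    """
    if not (0.0 <= s2 <= 1.0):
        raise ValidationError("order parameter S^2 must lie in [0, 1]")
    if tau_m_ns <= 0:
        raise ValidationError("tau_m must be positive")
    if tau_e_ps < 0:
        raise ValidationError("tau_e must be non-negative")
    tau_m = tau_m_ns * 1e-9
    tau_e = tau_e_ps * 1e-12
    tau = 0.0 if tau_e == 0.0 else 1.0 / (1.0 / tau_m + 1.0 / tau_e)

    def j(omega: float) -> float:
        w2 = omega * omega
        val = s2 * tau_m / (1.0 + w2 * tau_m**2)
        if tau > 0.0 and s2 < 1.0:
            val += (1.0 - s2) * tau / (1.0 + w2 * tau**2)
        return 0.4 * val

    return j


def forward_rates(j: Callable[[float], float], constants: SpinSystemConstants,
                  rex: float = 0.0) -> tuple[float, float, float]:
    """R1, R2 (s⁻¹) and hnNOE from a spectral density evaluator.

    Full five-frequency forms; ``rex`` adds to R2 only.  When R1 is zero the
    NOE is returned as 1 (the cross-relaxation term is zero before the
    guarded division).
    """
    wh = constants.omega_h
    wn = abs(constants.omega_n)
    d2 = constants.d**2
    c2 = constants.c**2
    j0 = j(0.0)
    jn = j(wn)
    jh = j(wh)
    jhmn = j(wh - wn)
    jhpn = j(wh + wn)
    r1 = (d2 / 4.0) * (jhmn + 3.0 * jn + 6.0 * jhpn) + c2 * jn
    r2 = ((d2 / 8.0) * (4.0 * j0 + jhmn + 3.0 * jn + 6.0 * jh + 6.0 * jhpn)
          + (c2 / 6.0) * (4.0 * j0 + 3.0 * jn) + rex)
    sigma = (d2 / 4.0) * (6.0 * jhpn - jhmn)
    noe = 1.0 if r1 == 0.0 else 1.0 + (constants.gamma_h / constants.gamma_n) * sigma / r1
    return r1, r2, noe


def forward_rates_lumped(j0: float, j_wn: float, j_wh: float,
                         constants: SpinSystemConstants,
                         rex: float = 0.0) -> tuple[float, float, float]:
    """Forward rates under the reduced-mapping lumping (J values in seconds).

    All three high-frequency densities are replaced by ``j_wh`` (the value at
    0.87ωH); these rates invert exactly under :func:`map_spectral_densities`.
    """
    d2 = constants.d**2
    c2 = constants.c**2
    r1 = (7.0 * d2 / 4.0) * j_wh + (3.0 * d2 / 4.0 + c2) * j_wn
    r2 = ((d2 / 2.0 + 2.0 * c2 / 3.0) * j0 + (13.0 * d2 / 8.0) * j_wh
          + (3.0 * d2 / 8.0 + c2 / 2.0) * j_wn + rex)
    sigma = (5.0 * d2 / 4.0) * j_wh
    noe = 1.0 if r1 == 0.0 else 1.0 + (constants.gamma_h / constants.gamma_n) * sigma / r1
    return r1, r2, noe


# ---------------------------------------------------------------------------
# Decay fitting and NOE
# ---------------------------------------------------------------------------

def _exp_model(t, i0, t_relax):
    return i0 * np.exp(-t / t_relax)


def fit_exponential(curve: DecayCurve, mc_iterations: int = 500,
                    rng: np.random.Generator | None = None) -> ExpFitResult:
    """Fit I(t) = I0 exp(−t/Tα) and estimate the Tα error by Monte Carlo.

    The Monte Carlo error is the standard deviation of Tα over refits of
    synthetic curves built from the best-fit model plus Gaussian noise with
    SD equal to the residual RMS of the primary fit.
    """
    t = curve.delays
    y = curve.intensities
    if t.size < 4:
        raise ValidationError("at least 4 delay points are required for fitting")
    if np.allclose(y, y[0]):
        raise ValidationError("intensities are constant; no decay to fit")
    rng = rng if rng is not None else np.random.default_rng(0)

    # log-linear slope for the initial Tα; fall back to a third of the span
    p0_i0 = float(np.max(np.abs(y)))
    with np.errstate(divide="ignore", invalid="ignore"):
        pos = y > 0
        if pos.sum() >= 2:
            slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
            p0_t = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 3.0
        else:
            p0_t = (t[-1] - t[0]) / 3.0
    p0_t = float(np.clip(p0_t, 1e-6, 100.0))

    def _fail():
        return ExpFitResult(curve.residue_id, np.nan, np.nan, np.nan, np.nan,
                            False, curve.experiment)

    try:
        popt, _ = curve_fit(_exp_model, t, y, p0=[p0_i0, p0_t], maxfev=5000)
    except (RuntimeError, ValueError):
        return _fail()
    i0, t_relax = popt
    if not np.isfinite(t_relax) or t_relax <= 0:
        return _fail()
    resid = y - _exp_model(t, *popt)
    # residual standard error: dof-corrected so the MC noise is unbiased
    rms = float(np.sqrt(np.sum(resid**2) / max(t.size - 2, 1)))

    mc_vals = []
    if mc_iterations > 0 and rms > 0:
        yhat = _exp_model(t, *popt)
        for _ in range(mc_iterations):
            ysim = yhat + rng.normal(0.0, rms, size=t.size)
            try:
                psim, _ = curve_fit(_exp_model, t, ysim, p0=popt, maxfev=2000)
            except (RuntimeError, ValueError):
                continue
            if np.isfinite(psim[1]) and psim[1] > 0:
                mc_vals.append(psim[1])
    mc_error = float(np.std(mc_vals, ddof=1)) if len(mc_vals) > 1 else 0.0
    return ExpFitResult(curve.residue_id, float(t_relax), float(i0), mc_error,
                        rms, True, curve.experiment)


def compute_hnnoe(pairs: Sequence[NoePair]) -> tuple[float, float]:
    """Heteronuclear NOE = mean of per-replicate I_sat/I_eq; error = sample SD.

    With a single replicate the SD is undefined; 0 is returned with a warning.
    """
    if len(pairs) == 0:
        raise ValidationError("at least one NOE pair is required")
    ratios = np.array([p.i_sat / p.i_eq for p in pairs], dtype=float)
    noe = float(np.mean(ratios))
    if ratios.size < 2:
        warnings.warn("single NOE replicate: error undefined, reported as 0",
                      stacklevel=2)
        return noe, 0.0
    return noe, float(np.std(ratios, ddof=1))


def fit_relaxation_dataset(t1_curves: Iterable[DecayCurve],
                           t2_curves: Iterable[DecayCurve],
                           noe_pairs: Iterable[NoePair],
                           constants: SpinSystemConstants | None = None,
                           mc_iterations: int = 500,
                           seed: int = 0) -> list[RelaxationRecord]:
    """Chain exponential fits and NOE averaging into a per-residue rate table.

    Rates are inverses of fitted times; rate errors follow from δ(1/T)=δT/T².
    Residues with a non-converged T1 or T2 fit, or missing NOE pairs, are
    dropped with a warning.
    """
    constants = constants or SpinSystemConstants()
    rng = np.random.default_rng(seed)
    by_res_noe: dict[str, list[NoePair]] = {}
    for p in noe_pairs:
        by_res_noe.setdefault(p.residue_id, []).append(p)
    t1_by_res = {c.residue_id: c for c in t1_curves}
    t2_by_res = {c.residue_id: c for c in t2_curves}

    records = []
    for res in sorted(t1_by_res, key=lambda r: (len(r), r)):
        if res not in t2_by_res or res not in by_res_noe:
            warnings.warn(f"residue {res}: incomplete relaxation data, skipped",
                          stacklevel=2)
            continue
        f1 = fit_exponential(t1_by_res[res], mc_iterations, rng)
        f2 = fit_exponential(t2_by_res[res], mc_iterations, rng)
        if not (f1.converged and f2.converged):
            warnings.warn(f"residue {res}: decay fit did not converge, skipped",
                          stacklevel=2)
            continue
        noe, noe_err = compute_hnnoe(by_res_noe[res])
        records.append(RelaxationRecord(
            residue_id=res,
            r1=1.0 / f1.t_relax, r1_err=f1.mc_error / f1.t_relax**2,
            r2=1.0 / f2.t_relax, r2_err=f2.mc_error / f2.t_relax**2,
            noe=noe, noe_err=noe_err,
            field_mhz=constants.field_mhz,
        ))
    return records


# ---------------------------------------------------------------------------
# Reduced spectral density mapping
# ---------------------------------------------------------------------------

def _mapping_coefficients(constants: SpinSystemConstants):
    d2 = constants.d**2
    c2 = constants.c**2
    g = constants.gamma_n / constants.gamma_h      # signed
    k = 4.0 / (5.0 * d2)                            # J(0.87wH) = k * sigma
    a = 7.0 * d2 / 4.0
    A = 3.0 * d2 / 4.0 + c2
    b = 13.0 * d2 / 8.0
    e = 3.0 * d2 / 8.0 + c2 / 2.0
    B = d2 / 2.0 + 2.0 * c2 / 3.0
    return g, k, a, A, b, e, B


def reduced_spectral_density(record: RelaxationRecord,
                             constants: SpinSystemConstants | None = None
                             ) -> SpectralDensities:
    """Map one (R1, R2, NOE) record to J(0), J(ωN), J(0.87ωH) in ns.

    Errors are first-order analytic propagation of the stated rate/NOE errors
    through the closed-form mapping (the mapping is linear in R1, R2 and the
    cross-relaxation rate σ, so the propagation is exact to first order).
    Negative mapped values are flagged invalid, not clamped.
    """
    constants = constants or SpinSystemConstants()
    if record.r1 == 0:
        raise ValidationError("R1 must be nonzero for spectral density mapping")
    g, k, a, A, b, e, B = _mapping_coefficients(constants)
    r1, r2, noe = record.r1, record.r2, record.noe

    sigma = r1 * (noe - 1.0) * g
    j_wh = k * sigma
    j_wn = (r1 - a * j_wh) / A
    j0 = (r2 - b * j_wh - e * j_wn) / B

    # partial derivatives wrt (r1, r2, noe)
    djwh = np.array([k * g * (noe - 1.0), 0.0, k * g * r1])
    djwn = (np.array([1.0, 0.0, 0.0]) - a * djwh) / A
    dj0 = (np.array([0.0, 1.0, 0.0]) - b * djwh - e * djwn) / B
    errs = np.array([record.r1_err, record.r2_err, record.noe_err])
    j_wh_err = float(np.sqrt(np.sum((djwh * errs) ** 2)))
    j_wn_err = float(np.sqrt(np.sum((djwn * errs) ** 2)))
    j0_err = float(np.sqrt(np.sum((dj0 * errs) ** 2)))

    ns = 1e9
    return SpectralDensities(
        residue_id=record.residue_id,
        j0=j0 * ns, j0_err=j0_err * ns,
        j_wn=j_wn * ns, j_wn_err=j_wn_err * ns,
        j_wh=j_wh * ns, j_wh_err=j_wh_err * ns,
        j0_valid=bool(np.isfinite(j0) and j0 >= 0),
        j_wn_valid=bool(np.isfinite(j_wn) and j_wn >= 0),
        j_wh_valid=bool(np.isfinite(j_wh) and j_wh >= 0),
    )


def map_spectral_densities(records: Iterable[RelaxationRecord],
                           constants: SpinSystemConstants | None = None
                           ) -> list[SpectralDensities]:
    constants = constants or SpinSystemConstants()
    return [reduced_spectral_density(r, constants) for r in records]


# ---------------------------------------------------------------------------
# Rotational correlation time
# ---------------------------------------------------------------------------

def estimate_tauc_isotropic(records: Sequence[RelaxationRecord],
                            trim_fraction: float = 0.2,
                            constants: SpinSystemConstants | None = None) -> float:
    """Isotropic τc (ns) from the trimmed-mean R2/R1 ratio.

    The ``trim_fraction`` of residues with R2/R1 furthest from the median is
    discarded (mobile termini depress, exchange inflates, the ratio); the
    rigid-rotor ratio equation R2(τ)/R1(τ) with S²=1, τe=0, Rex=0 is then
    solved for τ on (0.1, 100] ns by bracketed root finding.
    """
    if not (0.0 <= trim_fraction < 1.0):
        raise ValidationError("trim_fraction must lie in [0, 1)")
    constants = constants or SpinSystemConstants()
    ratios = np.array([r.r2 / r.r1 for r in records], dtype=float)
    n_trim = int(round(trim_fraction * ratios.size))
    if ratios.size - n_trim < 5:
        raise ValidationError("fewer than 5 residues remain after trimming")
    if n_trim > 0:
        dist = np.abs(ratios - np.median(ratios))
        keep = np.argsort(dist)[: ratios.size - n_trim]
        ratios = ratios[keep]
    target = float(np.mean(ratios))

    def f(tau_ns):
        r1, r2, _ = forward_rates(model_free_j(1.0, 0.0, tau_ns), constants)
        return r2 / r1 - target

    lo, hi = 0.1, 100.0
    if f(lo) * f(hi) > 0:
        raise ValidationError("no rigid-rotor tau_c in (0.1, 100] ns matches the "
                              "trimmed R2/R1 ratio")
    return float(brentq(f, lo, hi, xtol=1e-6))


# ---------------------------------------------------------------------------
# J(0) ratio profiles and CSP
# ---------------------------------------------------------------------------

def jratio_profile(modified: Sequence[SpectralDensities],
                   unmodified: Sequence[SpectralDensities]) -> JRatioProfile:
    """Per-residue J(0) ratio (modified/unmodified) with propagated errors.

    Only residues with a valid J(0) in both tables enter the profile; the
    relative errors add in quadrature.  Also reports each table's mean ± SD
    of J(0) over its own valid residues (the headline summary statistic).
    """
    mod = {s.residue_id: s for s in modified if s.j0_valid}
    unm = {s.residue_id: s for s in unmodified if s.j0_valid}
    shared = sorted(set(mod) & set(unm), key=lambda r: (len(r), r))
    if len(shared) == 0:
        raise ValidationError("no residues shared between the two tables")
    if len(shared) < 5:
        raise ValidationError("fewer than 5 residues valid in both tables")
    ratios, errors = [], []
    for res in shared:
        m, u = mod[res], unm[res]
        if u.j0 == 0:
            continue
        ratio = m.j0 / u.j0
        rel = np.sqrt((m.j0_err / m.j0) ** 2 + (u.j0_err / u.j0) ** 2) \
            if m.j0 > 0 else np.nan
        ratios.append(ratio)
        errors.append(abs(ratio) * rel)
    ratios = np.asarray(ratios)
    errors = np.asarray(errors)
    j0_mod = np.array([s.j0 for s in modified if s.j0_valid])
    j0_unm = np.array([s.j0 for s in unmodified if s.j0_valid])
    return JRatioProfile(
        residue_ids=shared,
        ratios=ratios,
        errors=errors,
        mean=float(np.mean(ratios)),
        sd=float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0,
        mean_j0_modified=float(np.mean(j0_mod)),
        sd_j0_modified=float(np.std(j0_mod, ddof=1)) if j0_mod.size > 1 else 0.0,
        mean_j0_unmodified=float(np.mean(j0_unm)),
        sd_j0_unmodified=float(np.std(j0_unm, ddof=1)) if j0_unm.size > 1 else 0.0,
    )


def compute_csp(list_a: PeakList, list_b: PeakList,
                nitrogen_weight: float = 0.14) -> dict:
    """Weighted chemical shift perturbation per shared residue, ppm.

    CSP = sqrt(ΔδH² + (w ΔδN)²).  Residues present in only one list are
    excluded (logged at debug level).
    """
    import logging
    log = logging.getLogger("foldstab")
    a = list_a.shifts()
    b = list_b.shifts()
    shared = set(a) & set(b)
    if not shared:
        raise ValidationError("peak lists share no residues")
    for res in (set(a) | set(b)) - shared:
        log.debug("residue %s present in only one peak list; excluded from CSP", res)
    out = {}
    for res in sorted(shared, key=lambda r: (len(r), r)):
        dh = a[res][0] - b[res][0]
        dn = a[res][1] - b[res][1]
        out[res] = float(np.sqrt(dh**2 + (nitrogen_weight * dn) ** 2))
    return out
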
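"""Synthetic dataset generators with recorded ground truth.

Every generator is a pure function of its parameters and an explicit
integer seed, and returns the dataset together with a
:class:`~smcondense.datatypes.SyntheticTruth` record sufficient to
regenerate it bit-identically.

The structure-free polymer law is a deliberately simple saturating form

    L(F) = L_max * F / (F + F_half)

chosen because its works and inter-branch areas have closed forms, which
the test suite uses as exact oracles.  It is a stand-in for ssDNA
elasticity, not a physical model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, ndimage

from .constants import KBT_PNNM
from .datatypes import ForceExtensionBranch, SyntheticTruth, TimeTrace
from .titration import TitrationCurve


# --------------------------------------------------------------------------
# models
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PolymerModel:
    """Structure-free extensible polymer: L(F) = L_max * F / (F + F_half).

    ``f_half_pN`` is the force at half-maximal extension and carries the
    salt dependence of chain compliance (stiffer chains at higher salt
    are modelled by a larger half-force).
    """

    contour_length_nt: int = 13552
    rise_per_nt_nm: float = 0.34
    f_half_pN: float = 2.0
    salt_mM: float = 0.0

    def __post_init__(self) -> None:
        if self.contour_length_nt <= 0 or self.rise_per_nt_nm <= 0:
            raise ValueError("contour length and rise per nt must be positive")
        if self.f_half_pN <= 0:
            raise ValueError("half-force must be positive")

    @property
    def contour_nm(self) -> float:
        return self.contour_length_nt * self.rise_per_nt_nm

    def extension_nm(self, force_pN):
        """Equilibrium extension at the given force(s)."""
        f = np.asarray(force_pN, dtype=float)
        return self.contour_nm * f / (f + self.f_half_pN)

    def d_extension(self, force_pN):
        """dL/dF, the compliance."""
        f = np.asarray(force_pN, dtype=float)
        return self.contour_nm * self.f_half_pN / (f + self.f_half_pN) ** 2

    def stretch_work_pNnm(self, f_lo: float, f_hi: float) -> float:
        """Closed-form work integral F dL between two forces."""
        fh = self.f_half_pN

        def antideriv(f: float) -> float:
            return self.contour_nm * fh * (math.log(f + fh) + fh / (f + fh))

        return antideriv(f_hi) - antideriv(f_lo)

    def wedge_area_pNnm(self, f_c: float) -> float:
        """Closed form of the integral of L(F)*(1 - F/f_c) dF on [0, f_c].

        This is the inter-branch loop area produced by a sequestered
        fraction declining linearly from 1 at zero force to 0 at ``f_c``.
        """
        fh = self.f_half_pN
        log_term = math.log1p(f_c / fh)
        i1 = f_c - fh * log_term
        i2 = f_c**2 / 2.0 - fh * f_c + fh**2 * log_term
        return self.contour_nm * (i1 - i2 / f_c)


@dataclass(frozen=True)
class HysteresisModel:
    """Secondary-structure hysteresis for bare-chain pulling branches.

    The sequestered fraction declines linearly from its zero-force value
    to 0 at ``critical_force_pN``.  When ``target_hysteresis_energy_kBT``
    is given, the zero-force fraction is rescaled so that the loop area
    between noiseless branches equals the prescribed energy.
    """

    sequestered_fraction_at_zero_force: float = 0.0
    critical_force_pN: float = 8.0
    target_hysteresis_energy_kBT: float | None = None

    def __post_init__(self) -> None:
        s0 = self.sequestered_fraction_at_zero_force
        if not 0.0 <= s0 <= 1.0:
            raise ValueError("sequestered fraction must lie in [0, 1]")
        if self.critical_force_pN <= 0:
            raise ValueError("critical force must be positive")
        if (
            self.target_hysteresis_energy_kBT is not None
            and self.target_hysteresis_energy_kBT < 0
        ):
            raise ValueError("prescribed hysteresis energy must be >= 0")

    def resolve_fraction(self, model: PolymerModel) -> float:
        """Zero-force sequestered fraction after energy rescaling."""
        if self.target_hysteresis_energy_kBT is None:
            return self.sequestered_fraction_at_zero_force
        area_unit = model.wedge_area_pNnm(self.critical_force_pN)
        s0 = self.target_hysteresis_energy_kBT * KBT_PNNM / area_unit
        if s0 > 1.0 + 1e-12:
            raise ValueError(
                f"prescribed hysteresis energy needs sequestered fraction {s0:.3f} > 1; "
                "increase contour length or critical force"
            )
        return min(s0, 1.0)

    def sequestered_fraction(self, force_pN, model: PolymerModel):
        f = np.asarray(force_pN, dtype=float)
        s0 = self.resolve_fraction(model)
        return s0 * np.clip(1.0 - f / self.critical_force_pN, 0.0, None)


@dataclass(frozen=True)
class CoatingModel:
    """Protein coating: multiplicative condensation plus optional bridging.

    ``condensation_factor`` multiplies the bare-chain extension at every
    force.  A positive ``bridging_energy_kBT`` stiffens the pulling
    branch (bridges broken on the way up) so that the loop area between
    branches equals the prescribed energy; 0 means branches coincide.
    """

    condensation_factor: float = 1.0
    site_size_nt: float = 65.0
    bridging_energy_kBT: float = 0.0
    bridging_critical_force_pN: float = 8.0

    def __post_init__(self) -> None:
        if not 0.0 < self.condensation_factor <= 1.0:
            raise ValueError("condensation factor must lie in (0, 1]")
        if self.site_size_nt <= 0:
            raise ValueError("site size must be positive")
        if self.bridging_energy_kBT < 0:
            raise ValueError("bridging energy must be >= 0")
        if self.bridging_critical_force_pN <= 0:
            raise ValueError("bridging critical force must be positive")


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _check_schedule(force_schedule) -> np.ndarray:
    f = np.asarray(force_schedule, dtype=float)
    if f.ndim != 1 or f.size < 2:
        raise ValueError("force schedule must be a 1-D array of >= 2 forces")
    if np.any(f < 0):
        raise ValueError("forces must be non-negative")
    if np.any(np.diff(f) <= 0):
        raise ValueError("force schedule must be strictly increasing")
    return f


def _check_noise(noise_sd: float) -> None:
    if noise_sd < 0:
        raise ValueError("noise standard deviation must be >= 0")


def _branch_work_quad(extension_fn, f_lo: float, f_hi: float) -> float:
    """Work integral F dL along an extension law, by adaptive quadrature."""
    eps = 1e-6

    def integrand(f: float) -> float:
        d = (extension_fn(f + eps) - extension_fn(f - eps)) / (2 * eps)
        return f * d

    val, _ = integrate.quad(integrand, f_lo + eps, f_hi - eps, limit=400)
    return float(val)


# --------------------------------------------------------------------------
# force-extension generators
# --------------------------------------------------------------------------

def gen_fec_ssdna(
    model: PolymerModel,
    hyst: HysteresisModel,
    force_schedule: Sequence[float],
    noise_sd_nm: float = 0.0,
    seed: int = 0,
    condition: str = "ssDNA",
) -> tuple[ForceExtensionBranch, ForceExtensionBranch, SyntheticTruth]:
    """Generate a pulling/relaxing pair for a bare chain with optional hysteresis.

    The relaxing branch follows the structure-free polymer law; the
    pulling branch has a fraction of the contour sequestered in
    secondary structure below the critical force.

    Returns ``(pulling, relaxing, truth)``.
    """
    f = _check_schedule(force_schedule)
    _check_noise(noise_sd_nm)
    s0 = hyst.resolve_fraction(model)  # raises if out of [0, 1]

    def relax_ext(force):
        return model.extension_nm(force)

    def pull_ext(force):
        frac = s0 * np.clip(1.0 - np.asarray(force, float) / hyst.critical_force_pN, 0.0, None)
        return model.extension_nm(force) * (1.0 - frac)

    rng = np.random.default_rng(seed)
    pull = pull_ext(f) + rng.normal(0.0, noise_sd_nm, f.size) * (noise_sd_nm > 0)
    relax = relax_ext(f) + rng.normal(0.0, noise_sd_nm, f.size) * (noise_sd_nm > 0)

    f_lo, f_hi = float(f[0]), float(f[-1])
    w_relax = model.stretch_work_pNnm(f_lo, f_hi)
    w_pull = _branch_work_quad(pull_ext, f_lo, f_hi) if s0 > 0 else w_relax
    loop_full = s0 * model.wedge_area_pNnm(hyst.critical_force_pN)

    truth = SyntheticTruth(
        generator="gen_fec_ssdna",
        seed=seed,
        params=dict(
            model=vars(model) | {},
            hyst=dict(
                sequestered_fraction_at_zero_force=hyst.sequestered_fraction_at_zero_force,
                critical_force_pN=hyst.critical_force_pN,
                target_hysteresis_energy_kBT=hyst.target_hysteresis_energy_kBT,
            ),
            force_schedule=f,
            noise_sd_nm=noise_sd_nm,
            condition=condition,
        ),
        derived=dict(
            sequestered_fraction_effective=s0,
            work_pulling_pNnm=w_pull,
            work_relaxing_pNnm=w_relax,
            hysteresis_area_pNnm=w_pull - w_relax,
            hysteresis_area_full_loop_pNnm=loop_full,
            hysteresis_energy_kBT=(w_pull - w_relax) / KBT_PNNM,
        ),
    )

    pulling = ForceExtensionBranch(condition, model.salt_mM, "pulling", f, pull)
    relaxing = ForceExtensionBranch(condition, model.salt_mM, "relaxing", f[::-1], relax[::-1])
    return pulling, relaxing, truth


def gen_fec_coated(
    model: PolymerModel,
    coat: CoatingModel,
    force_schedule: Sequence[float],
    noise_sd_nm: float = 0.0,
    seed: int = 0,
    condition: str = "+SSB",
) -> tuple[ForceExtensionBranch, ForceExtensionBranch, SyntheticTruth]:
    """Generate a pulling/relaxing pair for a protein-coated chain.

    Both branches equal ``condensation_factor`` times the structure-free
    extension; a positive bridging energy stiffens the pulling branch so
    the inter-branch loop area equals the prescribed energy.
    """
    f = _check_schedule(force_schedule)
    _check_noise(noise_sd_nm)
    c = coat.condensation_factor

    b0 = 0.0
    if coat.bridging_energy_kBT > 0:
        area_unit = c * model.wedge_area_pNnm(coat.bridging_critical_force_pN)
        b0 = coat.bridging_energy_kBT * KBT_PNNM / area_unit
        if b0 > 1.0 + 1e-12:
            raise ValueError(
                f"prescribed bridging energy needs bridged fraction {b0:.3f} > 1"
            )
        b0 = min(b0, 1.0)

    def relax_ext(force):
        return c * model.extension_nm(force)

    def pull_ext(force):
        frac = b0 * np.clip(
            1.0 - np.asarray(force, float) / coat.bridging_critical_force_pN, 0.0, None
        )
        return c * model.extension_nm(force) * (1.0 - frac)

    rng = np.random.default_rng(seed)
    pull = pull_ext(f) + rng.normal(0.0, noise_sd_nm, f.size) * (noise_sd_nm > 0)
    relax = relax_ext(f) + rng.normal(0.0, noise_sd_nm, f.size) * (noise_sd_nm > 0)

    f_lo, f_hi = float(f[0]), float(f[-1])
    w_relax = c * model.stretch_work_pNnm(f_lo, f_hi)
    w_pull = _branch_work_quad(pull_ext, f_lo, f_hi) if b0 > 0 else w_relax

    truth = SyntheticTruth(
        generator="gen_fec_coated",
        seed=seed,
        params=dict(
            model=vars(model) | {},
            coat=vars(coat) | {},
            force_schedule=f,
            noise_sd_nm=noise_sd_nm,
            condition=condition,
        ),
        derived=dict(
            bridged_fraction_effective=b0,
            work_pulling_pNnm=w_pull,
            work_relaxing_pNnm=w_relax,
            hysteresis_area_pNnm=w_pull - w_relax,
            hysteresis_energy_kBT=(w_pull - w_relax) / KBT_PNNM,
        ),
    )

    pulling = ForceExtensionBranch(condition, model.salt_mM, "pulling", f, pull)
    relaxing = ForceExtensionBranch(condition, model.salt_mM, "relaxing", f[::-1], relax[::-1])
    return pulling, relaxing, truth


# --------------------------------------------------------------------------
# titration generators
# --------------------------------------------------------------------------

def titration_signal(ratio, site_size_nt: float, plateau_fold: float):
    """Noiseless two-segment titration signal (fold enhancement)."""
    r = np.asarray(ratio, dtype=float)
    return 1.0 + (plateau_fold - 1.0) * np.minimum(r / site_size_nt, 1.0)


def gen_titration(
    site_size_nt: float,
    plateau_fold: float,
    n_points: int = 30,
    ratio_max: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    salt_mM: float = 0.0,
    replicate_id: str = "sim",
) -> tuple[TitrationCurve, SyntheticTruth]:
    """Piecewise-linear titration isotherm: linear rise to the breakpoint, flat after.

    The noiseless signal equals ``plateau_fold`` exactly at
    ``ratio == site_size_nt`` and stays there for larger ratios.
    """
    if site_size_nt <= 0:
        raise ValueError("site size must be positive")
    if plateau_fold < 1:
        raise ValueError("plateau fold-enhancement must be >= 1")
    if ratio_max is None:
        ratio_max = 2.0 * site_size_nt
    if ratio_max <= site_size_nt:
        raise ValueError("ratio_max must exceed the site size (breakpoint not bracketed)")
    _check_noise(noise_sd)
    if n_points < 4:
        raise ValueError("need at least 4 titration points")

    ratio = np.linspace(0.0, ratio_max, n_points)
    rng = np.random.default_rng(seed)
    signal = titration_signal(ratio, site_size_nt, plateau_fold)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, n_points)

    curve = TitrationCurve(
        ratio=ratio, fold_enhancement=signal, salt_mM=salt_mM, replicate_id=replicate_id
    )
    truth = SyntheticTruth(
        generator="gen_titration",
        seed=seed,
        params=dict(
            site_size_nt=site_size_nt,
            plateau_fold=plateau_fold,
            n_points=n_points,
            ratio_max=ratio_max,
            noise_sd=noise_sd,
            salt_mM=salt_mM,
            replicate_id=replicate_id,
        ),
        derived=dict(site_size_nt=site_size_nt, amplitude_fold=plateau_fold),
    )
    return curve, truth


def backtitration_signal(
    salt_mM,
    midpoint_mM: float,
    rise_peak_mM: float,
    decline_slope: float,
    peak_signal: float,
    width_mM: float,
):
    """Noiseless back-titration: rise, shallow linear decline, logistic dissociation.

    The pre-transition envelope rises linearly from 1 to ``peak_signal``
    at ``rise_peak_mM`` and then declines linearly with ``decline_slope``
    (signal units per mM).  A logistic factor with inflection at
    ``midpoint_mM`` multiplies the envelope, so the signal at the
    midpoint is exactly half the local envelope value.
    """
    s = np.asarray(salt_mM, dtype=float)
    envelope = np.where(
        s <= rise_peak_mM,
        1.0 + (peak_signal - 1.0) * s / rise_peak_mM,
        peak_signal - decline_slope * (s - rise_peak_mM),
    )
    logistic = 1.0 / (1.0 + np.exp((s - midpoint_mM) / width_mM))
    return envelope * logistic


def gen_backtitration(
    midpoint_mM: float,
    rise_peak_mM: float = 300.0,
    decline_slope: float = 1e-3,
    n_points: int = 60,
    noise_sd: float = 0.0,
    seed: int = 0,
    peak_signal: float = 6.0,
    width_mM: float | None = None,
    salt_max_mM: float | None = None,
) -> tuple["np.ndarray", "np.ndarray", SyntheticTruth]:
    """Salt back-titration table; returns ``(salt_mM, signal, truth)``."""
    if midpoint_mM <= rise_peak_mM:
        raise ValueError("midpoint must exceed the rise peak")
    if width_mM is None:
        width_mM = midpoint_mM / 25.0
    if salt_max_mM is None:
        salt_max_mM = midpoint_mM + 6.0 * width_mM
    if salt_max_mM < midpoint_mM + 3.0 * width_mM:
        raise ValueError(
            "salt range does not span the dissociation limb "
            f"(need max salt >= {midpoint_mM + 3.0 * width_mM:.0f} mM)"
        )
    env_at_mid = peak_signal - decline_slope * (midpoint_mM - rise_peak_mM)
    if env_at_mid <= 0:
        raise ValueError("decline slope extinguishes the signal before the midpoint")
    _check_noise(noise_sd)

    salt = np.linspace(0.0, salt_max_mM, n_points)
    signal = backtitration_signal(
        salt, midpoint_mM, rise_peak_mM, decline_slope, peak_signal, width_mM
    )
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, n_points)

    truth = SyntheticTruth(
        generator="gen_backtitration",
        seed=seed,
        params=dict(
            midpoint_mM=midpoint_mM,
            rise_peak_mM=rise_peak_mM,
            decline_slope=decline_slope,
            n_points=n_points,
            noise_sd=noise_sd,
            peak_signal=peak_signal,
            width_mM=width_mM,
            salt_max_mM=salt_max_mM,
        ),
        derived=dict(midpoint_mM=midpoint_mM, envelope_at_midpoint=env_at_mid),
    )
    return salt, signal, truth


# --------------------------------------------------------------------------
# time traces and kymographs
# --------------------------------------------------------------------------

def gen_timetrace(
    L_start_nm: float,
    L_eq_nm: float,
    tau_s: float,
    duration_s: float,
    dt_s: float,
    noise_sd_nm: float = 0.0,
    seed: int = 0,
    force_pN: float = 1.0,
) -> tuple[TimeTrace, SyntheticTruth]:
    """Exponential relaxation toward equilibrium after a force step.

    L(t) = L_eq + (L_start - L_eq) * exp(-t / tau) + Gaussian noise.
    """
    if tau_s <= 0:
        raise ValueError("relaxation time must be positive")
    if dt_s <= 0:
        raise ValueError("sampling interval must be positive")
    if duration_s < 5.0 * tau_s:
        warnings.warn(
            "trace shorter than 5 relaxation times; equilibrium poorly constrained",
            stacklevel=2,
        )
    _check_noise(noise_sd_nm)

    t = np.arange(0.0, duration_s, dt_s)
    ext = L_eq_nm + (L_start_nm - L_eq_nm) * np.exp(-t / tau_s)
    rng = np.random.default_rng(seed)
    if noise_sd_nm > 0:
        ext = ext + rng.normal(0.0, noise_sd_nm, t.size)

    trace = TimeTrace(t, ext, np.full(t.size, force_pN))
    truth = SyntheticTruth(
        generator="gen_timetrace",
        seed=seed,
        params=dict(
            L_start_nm=L_start_nm,
            L_eq_nm=L_eq_nm,
            tau_s=tau_s,
            duration_s=duration_s,
            dt_s=dt_s,
            noise_sd_nm=noise_sd_nm,
            force_pN=force_pN,
        ),
        derived=dict(L_eq_nm=L_eq_nm, tau_s=tau_s, amplitude_nm=L_start_nm - L_eq_nm),
    )
    return trace, truth


def gen_kymograph(
    length_schedule_um: Sequence[float],
    intensity_schedule: Sequence[float],
    pixel_um: float = 0.16,
    psf_sigma_px: float = 0.0,
    background_mean: float = 0.0,
    background_sd: float = 0.0,
    seed: int = 0,
    frame_shape: tuple[int, int] | None = None,
    tether_rc: tuple[int, int] | None = None,
    frame_interval_s: float = 1.0,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Frame stack of a single tethered fiber along the flow (row) axis.

    Each frame holds one fiber segment anchored at the tether pixel,
    extending ``round(length / pixel)`` pixels down the tether column,
    convolved with a Gaussian PSF and overlaid on Gaussian background.

    Returns ``(stack, truth)`` with ``stack`` of shape (frames, rows, cols),
    float64.  Quantization to uint16 happens only at TIFF export.
    """
    lengths = np.asarray(length_schedule_um, dtype=float)
    intens = np.asarray(intensity_schedule, dtype=float)
    if lengths.shape != intens.shape:
        raise ValueError("length and intensity schedules must have equal length")
    if pixel_um <= 0:
        raise ValueError("pixel size must be positive")
    if np.any(lengths < 0) or np.any(intens < 0):
        raise ValueError("schedules must be non-negative")

    n_px = np.rint(lengths / pixel_um).astype(int)
    if frame_shape is None:
        frame_shape = (int(n_px.max()) + 16, 21)
    n_rows, n_cols = frame_shape
    if tether_rc is None:
        tether_rc = (4, n_cols // 2)
    t_row, t_col = tether_rc
    if not (0 <= t_row < n_rows and 0 <= t_col < n_cols):
        raise ValueError("tether pixel outside frame")
    if np.any(t_row + n_px > n_rows):
        raise ValueError("fiber longer than frame")

    rng = np.random.default_rng(seed)
    stack = np.empty((lengths.size, n_rows, n_cols), dtype=float)
    for i in range(lengths.size):
        frame = np.zeros((n_rows, n_cols))
        if n_px[i] > 0:
            frame[t_row : t_row + n_px[i], t_col] = intens[i]
        if psf_sigma_px > 0:
            frame = ndimage.gaussian_filter(frame, psf_sigma_px)
        frame += background_mean
        if background_sd > 0:
            frame += rng.normal(0.0, background_sd, frame.shape)
        stack[i] = frame

    truth = SyntheticTruth(
        generator="gen_kymograph",
        seed=seed,
        params=dict(
            length_schedule_um=lengths,
            intensity_schedule=intens,
            pixel_um=pixel_um,
            psf_sigma_px=psf_sigma_px,
            background_mean=background_mean,
            background_sd=background_sd,
            frame_shape=list(frame_shape),
            tether_rc=list(tether_rc),
            frame_interval_s=frame_interval_s,
        ),
        derived=dict(
            n_pixels_per_frame=n_px,
            length_truth_um=n_px * pixel_um,
        ),
    )
    return stack, truth
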
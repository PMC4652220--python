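"""Force-extension analytics and the energy ledger.

Equilibrium extraction from force-step time traces, branch assembly,
completion to a common force ceiling, work integration, delta-E /
delta-delta-E / hysteresis accounting in k_BT, per-tetramer
normalization, salt-slope fits, relative condensation, and matching of
flow-stretch condensation to an applied tweezer force.

Work is defined as the integral of force over extension (positive for
stretching), so pulling-minus-relaxing work is the classical hysteresis
loop area.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .constants import KBT_PNNM
from .datatypes import ForceExtensionBranch, TimeTrace

__all__ = [
    "EquilibriumFit",
    "EnergyLedger",
    "LedgerEntry",
    "TetramerAccounting",
    "fit_equilibrium",
    "assemble_branches",
    "complete_branch",
    "integrate_work",
    "work_trapezoid",
    "trapezoid_work_noise_sd",
    "energy_ledger",
    "per_tetramer_energy",
    "fit_energy_slope",
    "relative_condensation",
    "estimate_flow_force",
    "fold_condensation",
    "predict_scaled_length",
]


# --------------------------------------------------------------------------
# equilibrium extraction
# --------------------------------------------------------------------------

@dataclass
class EquilibriumFit:
    """Single-exponential approach to equilibrium within one force segment."""

    L_eq_nm: float
    tau_s: float  # NaN when the segment is already flat
    amplitude_nm: float
    converged: bool
    force_pN: float = float("nan")
    residual_rms_nm: float = float("nan")


def fit_equilibrium(segment: TimeTrace, drift_tolerance: float = 0.01) -> EquilibriumFit:
    """Fit L(t) = L_eq + A*exp(-t/tau) to one constant-force segment.

    ``converged`` is True when the fitted model drifts by less than
    ``drift_tolerance`` times |A| over the final 20% of the segment
    (always True for amplitude ~ 0).
    """
    t, ext = segment.time_s, segment.extension_nm
    if t.size < 10:
        raise ValueError(f"segment has {t.size} samples; need at least 10")
    force = float(segment.force_pN[0])
    t0 = t - t[0]

    spread = float(ext.max() - ext.min())
    tail_mean = float(ext[-max(t.size // 10, 2):].mean())
    a0 = float(ext[0] - tail_mean)
    # flat segment: no resolvable amplitude
    if spread < 1e-9 or abs(a0) < 1e-9 and spread < 1e-6 * max(abs(tail_mean), 1.0):
        return EquilibriumFit(
            L_eq_nm=float(ext.mean()),
            tau_s=float("nan"),
            amplitude_nm=0.0,
            converged=True,
            force_pN=force,
            residual_rms_nm=float(np.std(ext - ext.mean())),
        )

    def model(tt, leq, amp, tau):
        return leq + amp * np.exp(-tt / tau)

    tau0 = max(float(t0[-1]) / 5.0, float(t0[1] - t0[0]))
    try:
        popt, _ = optimize.curve_fit(
            model,
            t0,
            ext,
            p0=(tail_mean, a0, tau0),
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        # no exponential structure: report the mean as equilibrium
        return EquilibriumFit(
            L_eq_nm=float(ext.mean()),
            tau_s=float("nan"),
            amplitude_nm=0.0,
            converged=True,
            force_pN=force,
            residual_rms_nm=float(np.std(ext - ext.mean())),
        )
    leq, amp, tau = (float(v) for v in popt)
    resid = ext - model(t0, *popt)

    if abs(amp) < 1e-9:
        converged = True
        tau = float("nan")
    else:
        t80 = 0.8 * t0[-1]
        drift = abs(amp) * abs(math.exp(-t80 / tau) - math.exp(-t0[-1] / tau))
        converged = drift < drift_tolerance * abs(amp)
    return EquilibriumFit(
        L_eq_nm=leq,
        tau_s=tau,
        amplitude_nm=amp,
        converged=converged,
        force_pN=force,
        residual_rms_nm=float(np.sqrt(np.mean(resid**2))),
    )


def assemble_branches(
    fits: list[EquilibriumFit],
    directions: list[str],
    condition: str,
    salt_mM: float,
    mg_mM: float = 0.0,
) -> tuple[ForceExtensionBranch, ForceExtensionBranch]:
    """Assemble equilibrium lengths into a (pulling, relaxing) branch pair.

    ``directions`` labels each fit; every fit must be converged and
    carry its force label.
    """
    if len(fits) != len(directions):
        raise ValueError("fits and directions must align")
    bad = sorted(f.force_pN for f in fits if not f.converged)
    if bad:
        raise ValueError(
            "unconverged equilibrium fits at forces (pN): "
            + ", ".join(f"{b:g}" for b in bad)
        )
    out = {}
    for direction in ("pulling", "relaxing"):
        sel = [f for f, d in zip(fits, directions) if d == direction]
        if not sel:
            raise ValueError(f"missing {direction} direction")
        sel.sort(key=lambda f: f.force_pN, reverse=(direction == "relaxing"))
        out[direction] = ForceExtensionBranch(
            condition,
            salt_mM,
            direction,
            np.array([f.force_pN for f in sel]),
            np.array([f.L_eq_nm for f in sel]),
            mg_mM=mg_mM,
        )
    return out["pulling"], out["relaxing"]


# --------------------------------------------------------------------------
# completion and work integration
# --------------------------------------------------------------------------

def complete_branch(
    branch: ForceExtensionBranch,
    anchor_extension_nm: float | None = None,
    f_max_measured_pN: float = 10.5,
    f_target_pN: float = 17.5,
) -> ForceExtensionBranch:
    """Extend a branch to the common force ceiling by linear extrapolation.

    A straight segment is appended from the last measured point to
    ``(f_target_pN, anchor_extension_nm)``, the convergence extension of
    the bare chain at the target force.  Branches already reaching the
    target are returned unchanged.  The worst-case work uncertainty of
    the appended segment (true curve anywhere inside the bounding
    rectangle) is recorded on the returned branch.
    """
    f, ext = branch.sorted_by_force()
    if f[-1] >= f_target_pN - 1e-9:
        return branch
    if f[-1] < f_max_measured_pN - 1e-9:
        raise ValueError(
            f"branch ends at {f[-1]:g} pN, below the measured ceiling "
            f"{f_max_measured_pN:g} pN; cannot complete"
        )
    if anchor_extension_nm is None:
        raise ValueError("anchor extension at the target force is required")

    d_ext = anchor_extension_nm - ext[-1]
    if d_ext < 0:
        warnings.warn("anchor extension below last measured point", stacklevel=2)
    bound = 0.5 * (f_target_pN - f[-1]) * abs(d_ext)

    new_f = np.append(f, f_target_pN)
    new_ext = np.append(ext, anchor_extension_nm)
    if branch.direction == "relaxing":
        new_f, new_ext = new_f[::-1], new_ext[::-1]
    return ForceExtensionBranch(
        branch.condition,
        branch.salt_mM,
        branch.direction,
        new_f,
        new_ext,
        mg_mM=branch.mg_mM,
        completion_error_bound_pNnm=branch.completion_error_bound_pNnm + bound,
    )


def work_trapezoid(force_pN, extension_nm) -> float:
    """Trapezoidal work integral of force over extension, in pN*nm.

    Points must be sorted with force non-decreasing (stretching work
    positive); noisy extensions may wiggle locally.  Constant-force
    plateaus are allowed here; branch objects additionally require
    strictly monotone force.
    """
    f = np.asarray(force_pN, dtype=float)
    ext = np.asarray(extension_nm, dtype=float)
    if f.size < 2:
        return 0.0
    if np.any(np.diff(f) < 0):
        raise ValueError("points must be sorted by non-decreasing force")
    return float(np.trapezoid(f, ext))


def integrate_work(branch: ForceExtensionBranch) -> float:
    """Work of one branch: integral of force over extension, in pN*nm."""
    f, ext = branch.sorted_by_force()
    return work_trapezoid(f, ext)


def trapezoid_work_noise_sd(force_pN, noise_sd_nm: float) -> float:
    """Propagated standard deviation of the trapezoidal work integral.

    Assumes i.i.d. Gaussian noise of ``noise_sd_nm`` on every extension
    point; the work is linear in the extensions, so its variance is the
    noise variance times the sum of squared trapezoid coefficients.
    """
    f = np.sort(np.asarray(force_pN, dtype=float))
    if f.size < 2:
        return 0.0
    coef = np.zeros(f.size)
    coef[0] = -0.5 * (f[0] + f[1])
    coef[-1] = 0.5 * (f[-2] + f[-1])
    if f.size > 2:
        coef[1:-1] = 0.5 * (f[2:] - f[:-2])
    return float(noise_sd_nm * np.sqrt(np.sum(coef**2)))


# --------------------------------------------------------------------------
# the energy ledger
# --------------------------------------------------------------------------

@dataclass
class LedgerEntry:
    condition: str
    salt_mM: float
    direction: str
    work_pNnm: float
    dE_kBT: float
    ddE_kBT: float | None
    extrapolation_error_bound_pNnm: float


@dataclass
class EnergyLedger:
    """Integrated works and derived energies for a set of completed branches."""

    entries: list[LedgerEntry] = field(default_factory=list)
    hysteresis_kBT: dict[tuple[str, float], float] = field(default_factory=dict)
    reference: tuple[str, float, str] = ("ssDNA", 0.0, "pulling")
    baseline_direction: str = "relaxing"
    kbt_pNnm: float = KBT_PNNM

    def entry(self, condition: str, salt_mM: float, direction: str) -> LedgerEntry:
        for e in self.entries:
            if (e.condition, e.salt_mM, e.direction) == (condition, salt_mM, direction):
                return e
        raise KeyError((condition, salt_mM, direction))


def energy_ledger(
    branches: list[ForceExtensionBranch],
    reference: tuple[str, float, str] = ("ssDNA", 0.0, "pulling"),
    baseline_condition: str = "ssDNA",
    baseline_direction: str = "relaxing",
    kbt_pNnm: float = KBT_PNNM,
) -> EnergyLedger:
    """Build the energy ledger from completed branches.

    dE is each branch's work minus the reference branch's work, in k_BT;
    hysteresis is pulling-minus-relaxing work per (condition, salt);
    ddE is dE minus the dE of the named baseline branch at matching salt
    (default: bare-chain relaxing), where such a baseline exists.
    """
    if not branches:
        raise ValueError("no branches supplied")
    keys = [b.key() for b in branches]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (condition, salt, direction) branches")

    ceilings = {round(b.max_force_pN, 6) for b in branches}
    if len(ceilings) > 1:
        raise ValueError(
            f"branches completed to different force ceilings: {sorted(ceilings)}"
        )

    by_key = {b.key(): b for b in branches}
    ref_key = (reference[0], float(reference[1]), reference[2])
    if ref_key not in by_key:
        raise ValueError(f"reference branch {ref_key} not found")
    works = {b.key(): integrate_work(b) for b in branches}
    w_ref = works[ref_key]

    ledger = EnergyLedger(
        reference=ref_key, baseline_direction=baseline_direction, kbt_pNnm=kbt_pNnm
    )
    for b in branches:
        dE = (works[b.key()] - w_ref) / kbt_pNnm
        base_key = (baseline_condition, float(b.salt_mM), baseline_direction)
        ddE = None
        if base_key in works:
            ddE = dE - (works[base_key] - w_ref) / kbt_pNnm
        ledger.entries.append(
            LedgerEntry(
                condition=b.condition,
                salt_mM=float(b.salt_mM),
                direction=b.direction,
                work_pNnm=works[b.key()],
                dE_kBT=dE,
                ddE_kBT=ddE,
                extrapolation_error_bound_pNnm=b.completion_error_bound_pNnm,
            )
        )

    pairs = {(b.condition, float(b.salt_mM)) for b in branches}
    for cond, salt in sorted(pairs):
        kp, kr = (cond, salt, "pulling"), (cond, salt, "relaxing")
        if kp in works and kr in works:
            ledger.hysteresis_kBT[(cond, salt)] = (works[kp] - works[kr]) / kbt_pNnm
    return ledger


@dataclass
class TetramerAccounting:
    ssDNA_length_nt: int
    site_size_nt: float
    n_tetramers: int
    energy_per_tetramer_kBT: float


def per_tetramer_energy(
    ddE_kBT: float, ssDNA_length_nt: int, site_size_nt: float
) -> TetramerAccounting:
    """Normalize a total energy by the tetramer count length/site-size.

    The count rounds half away from zero and must be at least 1.
    """
    if ssDNA_length_nt <= 0 or site_size_nt <= 0:
        raise ValueError("length and site size must be positive")
    if ssDNA_length_nt <= site_size_nt:
        raise ValueError("substrate shorter than one binding site")
    if not 30 <= site_size_nt <= 80:
        warnings.warn(
            f"site size {site_size_nt} nt outside the typical 30-80 nt range",
            stacklevel=2,
        )
    n = int(math.floor(ssDNA_length_nt / site_size_nt + 0.5))  # round half away from zero
    return TetramerAccounting(
        ssDNA_length_nt=ssDNA_length_nt,
        site_size_nt=site_size_nt,
        n_tetramers=n,
        energy_per_tetramer_kBT=ddE_kBT / n,
    )


def fit_energy_slope(dE_by_salt: dict[float, float]) -> tuple[float, float]:
    """OLS slope of dE (k_BT) against ln(salt), with its standard error.

    Zero or negative salt entries are rejected (exclude the 0 mM point
    before calling).
    """
    salts = np.array(sorted(dE_by_salt), dtype=float)
    if np.any(salts <= 0):
        raise ValueError("all salts must be positive for a log-salt fit (drop 0 mM)")
    if salts.size < 2:
        raise ValueError("need at least 2 salts")
    if salts.size < 3:
        warnings.warn("fewer than 3 salts: slope fit is an exact interpolation", stacklevel=2)
    y = np.array([dE_by_salt[s] for s in salts])
    res = stats.linregress(np.log(salts), y)
    return float(res.slope), float(res.stderr) if salts.size > 2 else 0.0


# --------------------------------------------------------------------------
# condensation profiles and worked-example arithmetic
# --------------------------------------------------------------------------

def relative_condensation(lengths: pd.DataFrame) -> pd.DataFrame:
    """Compute L/L0 per (force, salt), L0 being the 0 mM length at that force.

    Input: tidy frame with columns ``force_pN, salt_mM, extension_nm``.
    """
    required = {"force_pN", "salt_mM", "extension_nm"}
    if not required.issubset(lengths.columns):
        raise ValueError(f"length table must have columns {sorted(required)}")
    out = []
    for force, grp in lengths.groupby("force_pN"):
        zero = grp.loc[grp["salt_mM"] == 0, "extension_nm"]
        if zero.empty:
            raise ValueError(f"missing 0 mM row for force {force:g} pN")
        L0 = float(zero.iloc[0])
        g = grp.copy()
        g["L_over_L0"] = g["extension_nm"] / L0
        out.append(g)
    return (
        pd.concat(out)
        .sort_values(["force_pN", "salt_mM"], ignore_index=True)
    )


def estimate_flow_force(
    tirf_profile: dict[float, float],
    tweezer_profiles: dict[float, dict[float, float]],
) -> tuple[float, tuple[float, float]]:
    """Match a flow-stretch condensation profile to an applied force.

    ``tirf_profile`` maps salt -> L/L0 from imaging; each tweezer profile
    maps salt -> L/L0 at one applied force.  Profiles are interpolated
    onto the shared salt range; the best force minimizes the summed
    squared difference, ties breaking toward the smallest force.  The
    returned interval spans all forces whose misfit is within twice the
    minimum.
    """
    if len(tweezer_profiles) < 2:
        raise ValueError("need at least 2 tweezer forces")
    t_salt = np.array(sorted(tirf_profile))
    t_val = np.array([tirf_profile[s] for s in t_salt])

    misfits = {}
    for force in sorted(tweezer_profiles):
        prof = tweezer_profiles[force]
        w_salt = np.array(sorted(prof))
        w_val = np.array([prof[s] for s in w_salt])
        lo = max(t_salt.min(), w_salt.min())
        hi = min(t_salt.max(), w_salt.max())
        if lo >= hi:
            raise ValueError(
                f"salt ranges of imaging and tweezer profiles are disjoint at {force:g} pN"
            )
        grid = t_salt[(t_salt >= lo) & (t_salt <= hi)]
        tirf_i = np.interp(grid, t_salt, t_val)
        twz_i = np.interp(grid, w_salt, w_val)
        misfits[force] = float(np.sum((tirf_i - twz_i) ** 2))

    best = min(misfits, key=lambda f: (misfits[f], f))
    thresh = 2.0 * misfits[best] if misfits[best] > 0 else 0.0
    inside = [f for f, m in misfits.items() if m <= thresh or f == best]
    return float(best), (float(min(inside)), float(max(inside)))


def fold_condensation(L_ref: float, L_cond: float, ndigits: int = 1) -> float:
    """Length ratio reference/condensed, rounded to reporting precision."""
    if L_ref <= 0 or L_cond <= 0:
        raise ValueError("lengths must be positive")
    return round(L_ref / L_cond, ndigits)


def predict_scaled_length(
    reference_contour_nm: float, genome_length_ratio: float, ndigits: int = 1
) -> float:
    """Scale a reference contour by a genome-length ratio; result in um."""
    if reference_contour_nm <= 0 or genome_length_ratio <= 0:
        raise ValueError("inputs must be positive")
    return round(reference_contour_nm * genome_length_ratio / 1000.0, ndigits)
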
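"""Homodimer dissociation equilibrium from slow-exchange peak volumes.

A self-dimerizing domain in slow exchange gives separate monomer and
dimer peaks whose volumes report populations directly.  With total
protein [M]_T in monomer-equivalent µM:

    [M] = [M]_T * Vm / (Vm + Vd)
    [D] = [M]_T * Vd / (2 * (Vm + Vd))
    K_D,dimer = [M]^2 / [D]

Inverting the mass balance [M] + 2[D] = [M]_T gives the closed-form
monomer concentration at any total:

    [M] = (-K + sqrt(K^2 + 8 * [M]_T * K)) / 4

K_D,dimer is estimated by nonlinear least squares of this monomer
fraction against residue-averaged observed fractions across a dilution
series, with bootstrap-over-residues uncertainties, and converted to a
standard (1 M) dissociation free energy dG = R*T*ln(K_D).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    NonIdentifiableError,
    UndefinedEquilibriumError,
    ValidationError,
)
from .peak_io import Constants, DilutionSeries

__all__ = [
    "DimerFitResult",
    "species_from_volumes",
    "kd_single_point",
    "monomer_conc",
    "monomer_fraction",
    "fit_kd_dimer",
    "delta_g_from_kd",
    "kd_from_delta_g",
    "fold_destabilization",
    "additivity_gap",
]


def species_from_volumes(total: float, v_monomer: float, v_dimer: float):
    """Monomer and dimer concentrations (µM) from a peak-volume pair.

    Mass balance [M] + 2[D] = total holds exactly; only the volume ratio
    matters, so no inter-spectrum normalization is required.
    """
    if not total > 0:
        raise ValidationError(f"total concentration must be positive, got {total}")
    if v_monomer < 0 or v_dimer < 0:
        raise ValidationError("peak volumes must be non-negative")
    vsum = v_monomer + v_dimer
    if vsum <= 0:
        raise ValidationError("both peak volumes are zero")
    monomer = total * v_monomer / vsum
    dimer = total * v_dimer / (2.0 * vsum)
    return monomer, dimer


def kd_single_point(total: float, v_monomer: float, v_dimer: float) -> float:
    """Per-point dimer dissociation constant [M]^2/[D] in µM."""
    monomer, dimer = species_from_volumes(total, v_monomer, v_dimer)
    if dimer <= 0:
        raise UndefinedEquilibriumError(
            "dimer volume is zero: K_D,dimer undefined at a fully dissociated point"
        )
    return monomer**2 / dimer


def monomer_conc(total, kd_dimer):
    """Equilibrium monomer concentration (µM) at a given total and K_D,dimer.

    Positive root of K = 2[M]^2/(total - [M]); evaluated in the
    conjugate form 2*total / (1 + sqrt(1 + 8*total/K)), which is stable
    for both K -> 0 and K -> inf.  Vectorized over either argument.
    """
    t = np.asarray(total, dtype=float)
    k = np.asarray(kd_dimer, dtype=float)
    if np.any(t <= 0):
        raise ValidationError("total concentration must be positive")
    if np.any(k < 0):
        raise ValidationError("kd_dimer must be non-negative")
    with np.errstate(divide="ignore"):
        m = np.where(k > 0, 2.0 * t / (1.0 + np.sqrt(1.0 + 8.0 * t / k)), 0.0)
    if m.ndim == 0:
        return float(m)
    return m


def monomer_fraction(total, kd_dimer):
    """Fraction of protein in the monomeric state, [M]/total, in [0, 1]."""
    return monomer_conc(total, kd_dimer) / np.asarray(total, dtype=float)


def delta_g_from_kd(kd: float, constants: Constants | None = None) -> float:
    """Dissociation free energy R*T*ln(K_D) in kJ/mol, K_D in µM, 1 M standard state."""
    if constants is None:
        constants = Constants()
    if not kd > 0:
        raise ValidationError(f"kd must be positive, got {kd}")
    return constants.gas_constant * constants.temperature * math.log(kd * 1e-6) / 1000.0


def kd_from_delta_g(delta_g: float, constants: Constants | None = None) -> float:
    """Inverse of :func:`delta_g_from_kd`; returns K_D in µM."""
    if constants is None:
        constants = Constants()
    return math.exp(delta_g * 1000.0 / (constants.gas_constant * constants.temperature)) * 1e6


def fold_destabilization(kd_mut: float, kd_wt: float) -> float:
    """Ratio of mutant to reference K_D,dimer (>1 means a weaker dimer)."""
    if not (kd_mut > 0 and kd_wt > 0):
        raise ValidationError("dissociation constants must be positive")
    return kd_mut / kd_wt


def additivity_gap(dg_wt: float, dg_m1: float, dg_m2: float, dg_double: float) -> float:
    """Deviation from additivity of two single-site free-energy effects, kJ/mol.

    Returns |(ddG1 + ddG2) - ddG12| where ddG_i = dG_i - dG_wt.  Zero for
    perfectly additive (independent) mutations.
    """
    for v in (dg_wt, dg_m1, dg_m2, dg_double):
        if not math.isfinite(v):
            raise ValidationError("free energies must be finite")
    ddg1 = dg_m1 - dg_wt
    ddg2 = dg_m2 - dg_wt
    ddg12 = dg_double - dg_wt
    return abs((ddg1 + ddg2) - ddg12)


@dataclass
class DimerFitResult:
    """Result of a dilution-series K_D,dimer fit."""

    kd_dimer: float  # µM
    kd_sd: float  # µM; NaN when bootstrap disabled
    delta_g: float  # kJ/mol, 1 M standard state
    delta_g_sd: float  # kJ/mol, first-order propagation of kd_sd
    concentrations: np.ndarray  # µM, per dilution point
    fraction_observed: np.ndarray  # residue-averaged monomer fraction
    fraction_observed_sd: np.ndarray  # 1 S.D. across residues
    fraction_fitted: np.ndarray  # model fraction at the fitted K_D
    per_point_kd: np.ndarray  # diagnostic per-point [M]^2/[D] (µM; NaN if undefined)
    residues_used: tuple[str, ...] = field(default_factory=tuple)
    n_boot: int = 0

    @property
    def n_residues_used(self) -> int:
        return len(self.residues_used)


def _fit_log_kd(concs: np.ndarray, f_obs: np.ndarray, log_k0: float) -> float:
    res = least_squares(
        lambda p: monomer_fraction(concs, math.exp(p[0])) - f_obs,
        x0=[log_k0],
        method="lm",
    )
    return math.exp(res.x[0])


def fit_kd_dimer(
    series: DilutionSeries,
    residues: list[str] | None = None,
    n_boot: int = 200,
    seed: int | None = None,
    constants: Constants | None = None,
) -> DimerFitResult:
    """Fit K_D,dimer to residue-averaged monomer fractions over a dilution.

    Per concentration, Vm/(Vm+Vd) is averaged across the residue panel
    (matching the quantity plotted with 1 S.D. error bars in dilution
    figures); the closed-form monomer fraction is then fit by nonlinear
    least squares in log K.  Uncertainty is a bootstrap over residues
    (``n_boot`` resamples; 0 disables).  Initial K from the median of
    the per-point [M]^2/[D] estimates.
    """
    if residues is not None:
        missing = [r for r in residues if r not in series.residues]
        if missing:
            raise ValidationError(f"residues not in series: {missing}")
        idx = [series.residues.index(r) for r in residues]
        used = tuple(residues)
    else:
        idx = list(range(len(series.residues)))
        used = series.residues
    concs = series.concentrations
    if np.unique(concs).size < 2:
        raise NonIdentifiableError(
            "a single concentration cannot constrain K_D,dimer"
        )
    frac = series.monomer_volume_fraction()[:, idx]
    f_obs = frac.mean(axis=1)
    f_sd = frac.std(axis=1, ddof=1) if frac.shape[1] > 1 else np.zeros_like(f_obs)

    # per-point Eq.-(2)-style diagnostics on the averaged fractions
    per_point_kd = np.full(concs.size, np.nan)
    for i, (t, f) in enumerate(zip(concs, f_obs)):
        if 0 < f < 1:
            per_point_kd[i] = 2.0 * t * f**2 / (1.0 - f)

    if np.all(f_obs >= 1.0 - 1e-9):
        raise NonIdentifiableError("all points fully monomeric: K_D,dimer unbounded")
    if np.all(f_obs <= 1e-9):
        raise NonIdentifiableError("all points fully dimeric: K_D,dimer -> 0")

    finite = per_point_kd[np.isfinite(per_point_kd)]
    k0 = float(np.median(finite)) if finite.size else float(np.median(concs))
    kd = _fit_log_kd(concs, f_obs, math.log(k0))

    kd_sd = float("nan")
    if n_boot > 0 and frac.shape[1] > 1:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            pick = rng.integers(0, frac.shape[1], frac.shape[1])
            boots[b] = _fit_log_kd(concs, frac[:, pick].mean(axis=1), math.log(kd))
        kd_sd = float(np.std(boots, ddof=1))

    constants = constants or Constants()
    dg = delta_g_from_kd(kd, constants)
    dg_sd = (
        constants.gas_constant * constants.temperature * (kd_sd / kd) / 1000.0
        if math.isfinite(kd_sd)
        else float("nan")
    )
    return DimerFitResult(
        kd_dimer=kd,
        kd_sd=kd_sd,
        delta_g=dg,
        delta_g_sd=dg_sd,
        concentrations=concs.copy(),
        fraction_observed=f_obs,
        fraction_observed_sd=f_sd,
        fraction_fitted=monomer_fraction(concs, kd),
        per_point_kd=per_point_kd,
        residues_used=used,
        n_boot=n_boot,
    )
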
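"""Ligand binding constants from CSP titrations, corrected for dimerization.

Only the monomeric domain binds the ligand, so the one-site quadratic
(ligand-depletion) isotherm is evaluated with the *available monomer*
concentration [M] instead of the total protein:

    d_obs = d_max * {(M + P + K) - sqrt((M + P + K)^2 - 4*M*P)} / (2*M)

with P the total ligand concentration and K = K_D,complex.  [M] is held
fixed at its zero-ligand value from the dimer equilibrium — the
decoupled treatment; the exact coupled solution lives in
:mod:`ubafit.equilibrium` and is used to quantify the approximation
error of every fit (``decoupling_bias``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lmfit import Parameters, minimize

from .csp import CSPProfile
from .errors import NonIdentifiableError, NumericError, ValidationError
from .dimer import monomer_conc

__all__ = [
    "BindingFitResult",
    "available_monomer",
    "binding_csp",
    "fit_binding",
]


def available_monomer(protein_total: float, kd_dimer: float) -> float:
    """Free monomer concentration (µM) at zero ligand, from the dimer equilibrium."""
    return monomer_conc(protein_total, kd_dimer)


def binding_csp(monomer, ligand_total, kd_complex, delta_max):
    """Quadratic one-site isotherm CSP, ppm; vectorized over ligand_total.

    Bounded in [0, delta_max], monotone non-decreasing in ligand, and
    proportional to delta_max.
    """
    m = float(monomer)
    if not m > 0:
        raise ValidationError("monomer concentration must be positive")
    p = np.asarray(ligand_total, dtype=float)
    if np.any(p < 0):
        raise ValidationError("ligand concentration must be non-negative")
    k = float(kd_complex)
    if k < 0:
        raise ValidationError("kd_complex must be non-negative")
    s = m + p + k
    disc = s**2 - 4.0 * m * p
    if np.any(disc < -1e-9 * np.maximum(s**2, 1.0)):
        raise NumericError("negative discriminant in quadratic isotherm")
    bound_frac = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * m)
    out = delta_max * bound_frac
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class BindingFitResult:
    """Result of a monomer-corrected quadratic-isotherm titration fit."""

    kd_complex: float  # µM
    kd_sd: float  # µM; NaN when bootstrap disabled
    delta_max: dict[str, float]  # ppm per fitted residue
    available_monomer: float  # µM, fixed [M] used in the fit
    residues_used: tuple[str, ...]
    n_points: int
    saturation_warning: bool  # titration ended far from saturation
    decoupling_bias: float  # max relative deviation of the decoupled
    # isotherm from the exact coupled-equilibria prediction at the fit
    n_boot: int = 0


def _isotherm_residuals(params, m, ligand, values, residues):
    k = math.exp(params["log_kd"].value)
    res = []
    for j, r in enumerate(residues):
        dmax = math.exp(params[f"log_dmax_{j}"].value)
        res.append(binding_csp(m, ligand, k, dmax) - values[:, j])
    return np.concatenate(res)


def _fit_once(m, ligand, values, residues, log_k0, log_d0):
    params = Parameters()
    params.add("log_kd", value=log_k0)
    for j in range(len(residues)):
        params.add(f"log_dmax_{j}", value=log_d0[j])
    out = minimize(
        _isotherm_residuals,
        params,
        args=(m, ligand, values, residues),
        method="leastsq",
    )
    kd = math.exp(out.params["log_kd"].value)
    dmax = {
        r: math.exp(out.params[f"log_dmax_{j}"].value)
        for j, r in enumerate(residues)
    }
    return kd, dmax


def fit_binding(
    profile: CSPProfile,
    protein_total: float | None = None,
    kd_dimer: float = 0.0,
    residues: list[str] | None = None,
    n_boot: int = 200,
    seed: int | None = None,
) -> BindingFitResult:
    """Fit a shared K_D,complex and per-residue delta_max to a CSP profile.

    [M] is fixed at ``available_monomer(protein_total, kd_dimer)`` for
    all titration points.  Global fit in log parameters (positivity by
    construction); uncertainty by bootstrap over the non-reference
    titration points.  A ``saturation_warning`` is set when the titration
    endpoint reaches less than 80% of the fitted saturation.
    """
    if protein_total is None:
        protein_total = profile.protein_total
    if residues is not None:
        missing = [r for r in residues if r not in profile.residues]
        if missing:
            raise ValidationError(f"residues not in profile: {missing}")
        idx = [profile.residues.index(r) for r in residues]
        used = tuple(residues)
    else:
        idx = list(range(len(profile.residues)))
        used = profile.residues
    ligand = profile.ligand_totals
    values = profile.values[:, idx]
    if ligand.size < 4:
        raise NonIdentifiableError(
            f"{ligand.size} titration points cannot constrain K_D,complex "
            "and delta_max; at least 4 required"
        )
    m = available_monomer(protein_total, kd_dimer)
    if not m > 0:
        raise ValidationError(
            "available monomer is zero (kd_dimer = 0): nothing can bind"
        )
    peak = values.max(axis=0)
    if np.any(peak <= 0):
        flat = [used[j] for j in range(len(used)) if peak[j] <= 0]
        raise NonIdentifiableError(f"residues with no CSP response: {flat}")
    # half-saturation ligand concentration as the initial K guess
    half = peak / 2.0
    k0 = float(
        np.median(
            [np.interp(half[j], values[:, j], ligand) for j in range(len(used))]
        )
    )
    log_k0 = math.log(max(k0, 1e-3))
    log_d0 = np.log(peak * 1.05)

    kd, dmax = _fit_once(m, ligand, values, used, log_k0, log_d0)

    kd_sd = float("nan")
    nonzero = np.flatnonzero(ligand > 0)
    if n_boot > 0 and nonzero.size > 1:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            pick = np.concatenate(([0], np.sort(rng.choice(nonzero, nonzero.size))))
            try:
                boots[b], _ = _fit_once(
                    m, ligand[pick], values[pick], used, math.log(kd), log_d0
                )
            except NumericError:
                boots[b] = np.nan
        boots = boots[np.isfinite(boots)]
        kd_sd = float(np.std(boots, ddof=1)) if boots.size > 1 else float("nan")

    end_saturation = binding_csp(m, float(ligand[-1]), kd, 1.0)
    saturation_warning = bool(end_saturation < 0.8)

    # quantify the decoupled-[M] approximation against the exact solver
    from .equilibrium import oracle_csp_curve

    grid = ligand[ligand > 0]
    exact = oracle_csp_curve(protein_total, grid, kd_dimer, kd, 1.0)
    approx = binding_csp(m, grid, kd, 1.0)
    decoupling_bias = float(np.max(np.abs(approx - exact) / np.maximum(exact, 1e-12)))

    return BindingFitResult(
        kd_complex=kd,
        kd_sd=kd_sd,
        delta_max=dmax,
        available_monomer=m,
        residues_used=used,
        n_points=int(ligand.size),
        saturation_warning=saturation_warning,
        decoupling_bias=decoupling_bias,
        n_boot=n_boot,
    )
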
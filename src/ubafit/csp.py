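"""Normalized chemical shift perturbations from 1H/15N shift differences.

The combined amide CSP uses the conventional nitrogen down-weighting:

    delta_obs = sqrt(0.5 * (dH**2 + 0.2 * dN**2))

with dH, dN the proton and nitrogen shift changes in ppm relative to the
zero-ligand reference point of a titration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .peak_io import TitrationSeries

__all__ = ["N15_WEIGHT", "CSPProfile", "normalized_csp", "csp_profile"]

# 15N shift-range scaling relative to 1H; fixed, no per-residue weights.
N15_WEIGHT = 0.2


def normalized_csp(delta_h, delta_n):
    """Combined 1H/15N chemical shift perturbation in ppm.

    Accepts scalars or arrays; symmetric under sign flips of either input
    and absolutely homogeneous (scaling both inputs by c scales the output
    by |c|).
    """
    dh = np.asarray(delta_h, dtype=float)
    dn = np.asarray(delta_n, dtype=float)
    if not (np.all(np.isfinite(dh)) and np.all(np.isfinite(dn))):
        raise ValidationError("shift differences must be finite")
    out = np.sqrt(0.5 * (dh**2 + N15_WEIGHT * dn**2))
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class CSPProfile:
    """Per-residue CSP values over the titration, ppm.

    ``values[i, j]`` is the perturbation of residue j at ligand point i;
    the reference row (zero ligand) is identically zero by construction.
    """

    residues: tuple[str, ...]
    protein_total: float
    ligand_totals: np.ndarray
    values: np.ndarray  # (n_points, n_residues), ppm, >= 0

    def __post_init__(self) -> None:
        self.residues = tuple(self.residues)
        self.ligand_totals = np.asarray(self.ligand_totals, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.ligand_totals.size, len(self.residues)):
            raise ValidationError("CSP value matrix shape mismatch")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValidationError("CSP values must be finite and non-negative")

    @property
    def n_points(self) -> int:
        return self.ligand_totals.size


def csp_profile(series: TitrationSeries) -> CSPProfile:
    """Compute per-residue CSPs relative to the zero-ligand reference point."""
    dh = series.delta_h - series.delta_h[0]
    dn = series.delta_n - series.delta_n[0]
    values = np.sqrt(0.5 * (dh**2 + N15_WEIGHT * dn**2))
    return CSPProfile(
        residues=series.residues,
        protein_total=series.protein_total,
        ligand_totals=series.ligand_totals.copy(),
        values=values,
    )
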
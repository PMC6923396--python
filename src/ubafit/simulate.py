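"""Synthetic dilution, titration and PRE datasets for parameter recovery.

The generators are forward models of the same equilibria the fitting
code inverts, under the experimental designs used for a self-dimerizing
ubiquitin-binding domain: a six-point dilution between 20 and 500 µM
total protein, a ligand titration of 0-400 µM into 200 µM protein, and
a two-time-point PRE scheme with a 12 ms delay.

Regimes are baked in rather than simulated: monomer and dimer are in
slow exchange (separate peaks whose volumes report populations), ligand
binding is in fast exchange (a single monomer peak moving with the
bound fraction).  Noise structure is the standard NMR one —
multiplicative (constant-CV) for peak volumes and intensities, additive
Gaussian for chemical shifts in each dimension.

Every stochastic call takes a seed; identical config + seed gives
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binding import available_monomer, binding_csp
from .csp import N15_WEIGHT
from .dimer import monomer_fraction
from .errors import ValidationError
from .peak_io import DilutionSeries, PRETable, TitrationSeries

__all__ = [
    "DEFAULT_RESIDUES",
    "SimulationConfig",
    "simulate_dilution",
    "simulate_titration",
    "simulate_pre",
]

#: backbone amides plus the tryptophan side-chain Hε1-Nε1 peak typically
#: resolved for both monomer and dimer in the UBA dilution series
DEFAULT_RESIDUES = (
    "S399",
    "L402",
    "G405",
    "S407",
    "G411",
    "W412",
    "T419",
    "G425",
)


def _default_delta_max(residues: tuple[str, ...]) -> dict[str, float]:
    # conventional saturation CSPs, 0.1-0.3 ppm spread over the panel;
    # not measured values
    n = len(residues)
    vals = np.linspace(0.1, 0.3, n) if n > 1 else np.array([0.2])
    return dict(zip(residues, vals))


@dataclass
class SimulationConfig:
    """Ground truths and experimental design for the synthetic generators.

    Concentrations are monomer-equivalent µM.  ``volume_noise_cv`` and
    ``intensity_noise_cv`` are relative (multiplicative) noise levels;
    ``shift_noise_sd`` is an absolute ppm noise applied independently in
    the 1H and 15N dimensions.
    """

    kd_dimer: float = 6.8
    kd_complex: float = 40.0
    protein_total: float = 200.0
    dilution_concs: np.ndarray = field(
        default_factory=lambda: np.geomspace(20.0, 500.0, 6)
    )
    ligand_concs: np.ndarray = field(
        default_factory=lambda: np.array(
            [0.0, 25.0, 50.0, 100.0, 150.0, 200.0, 300.0, 400.0]
        )
    )
    residues: tuple[str, ...] = DEFAULT_RESIDUES
    delta_max: dict[str, float] | None = None
    volume_noise_cv: float = 0.05
    shift_noise_sd: float = 0.005
    intensity_noise_cv: float = 0.02
    r2_dia: float = 25.0  # diamagnetic reference rate, s^-1
    pre_delay: float = 0.012
    seed: int | None = None

    def __post_init__(self) -> None:
        self.dilution_concs = np.asarray(self.dilution_concs, dtype=float)
        self.ligand_concs = np.asarray(self.ligand_concs, dtype=float)
        self.residues = tuple(self.residues)
        if self.kd_dimer < 0 or self.kd_complex <= 0:
            raise ValidationError("dissociation constants must be positive")
        if not self.protein_total > 0:
            raise ValidationError("protein_total must be positive")
        if np.any(self.dilution_concs <= 0):
            raise ValidationError("dilution concentrations must be positive")
        for name in ("volume_noise_cv", "shift_noise_sd", "intensity_noise_cv"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.delta_max is None:
            self.delta_max = _default_delta_max(self.residues)
        missing = [r for r in self.residues if r not in self.delta_max]
        if missing:
            raise ValidationError(f"delta_max missing for residues: {missing}")

    def rng(self, seed: int | None = None) -> np.random.Generator:
        if seed is None:
            seed = self.seed
        if seed is None:
            raise ValidationError("a seed is required for stochastic simulation")
        return np.random.default_rng(seed)


def _mult_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    # floor guards against (rare, large-cv) negative draws; volumes stay > 0
    return np.maximum(1.0 + cv * rng.standard_normal(shape), 1e-6)


def simulate_dilution(config: SimulationConfig, seed: int | None = None) -> DilutionSeries:
    """Slow-exchange monomer/dimer peak volumes over the dilution series.

    Expected volumes are proportional to [M] for the monomer peak and
    2[D] for the dimer peak (per-proton signal), i.e. to the monomer
    fraction f and 1-f, then perturbed by multiplicative noise.
    """
    rng = config.rng(seed) if config.volume_noise_cv > 0 else None
    concs = config.dilution_concs
    n, r = concs.size, len(config.residues)
    f = monomer_fraction(concs, config.kd_dimer)[:, None] * np.ones((1, r))
    vm, vd = f.copy(), 1.0 - f
    if rng is not None:
        vm *= _mult_noise(rng, config.volume_noise_cv, (n, r))
        vd *= _mult_noise(rng, config.volume_noise_cv, (n, r))
    return DilutionSeries(config.residues, concs.copy(), vm, vd)


# fixed per-residue CSP directions: angle in the normalized (1H, 15N)
# shift plane, spread so neither dimension degenerates
def _shift_directions(n: int) -> tuple[np.ndarray, np.ndarray]:
    theta = np.linspace(0.2, np.pi / 2 - 0.2, n)
    u_h = np.cos(theta) / np.sqrt(0.5)
    u_n = np.sin(theta) / np.sqrt(0.5 * N15_WEIGHT)
    return u_h, u_n


def simulate_titration(config: SimulationConfig, seed: int | None = None) -> TitrationSeries:
    """Fast-exchange titration shifts whose noiseless CSP follows the isotherm.

    Each residue moves along a fixed direction in the (1H, 15N) plane
    scaled so the combined CSP equals the decoupled quadratic isotherm
    exactly; Gaussian shift noise is then added per dimension at every
    non-reference point.  The reference point is exactly zero.
    """
    rng = config.rng(seed) if config.shift_noise_sd > 0 else None
    ligs = config.ligand_concs
    n, r = ligs.size, len(config.residues)
    m0 = available_monomer(config.protein_total, config.kd_dimer)
    u_h, u_n = _shift_directions(r)
    dh = np.zeros((n, r))
    dn = np.zeros((n, r))
    for j, res in enumerate(config.residues):
        csp = binding_csp(m0, ligs, config.kd_complex, config.delta_max[res])
        dh[:, j] = csp * u_h[j]
        dn[:, j] = csp * u_n[j]
    if rng is not None:
        noise_h = config.shift_noise_sd * rng.standard_normal((n, r))
        noise_n = config.shift_noise_sd * rng.standard_normal((n, r))
        noise_h[0] = noise_n[0] = 0.0  # reference point stays exact
        dh += noise_h
        dn += noise_n
    return TitrationSeries(config.residues, config.protein_total, ligs.copy(), dh, dn)


def simulate_pre(
    config: SimulationConfig,
    gamma2_true,
    seed: int | None = None,
) -> PRETable:
    """Two-time-point PRE intensities for given true Γ2 rates per residue.

    I(t) = I0 * exp(-R2 * t) sampled at t = 0 and t = Δt, with
    R2 = r2_dia for the diamagnetic pair and r2_dia + Γ2 for the
    paramagnetic pair, under multiplicative intensity noise.
    """
    g2 = np.asarray(gamma2_true, dtype=float)
    r = len(config.residues)
    if g2.shape != (r,):
        raise ValidationError(f"gamma2_true must have shape ({r},), got {g2.shape}")
    if not np.all(np.isfinite(g2)):
        raise ValidationError("gamma2_true must be finite")
    rng = config.rng(seed) if config.intensity_noise_cv > 0 else None
    dt = config.pre_delay
    i_dia_a = np.ones(r)
    i_dia_b = np.exp(-config.r2_dia * dt) * np.ones(r)
    i_para_a = np.ones(r)
    i_para_b = np.exp(-(config.r2_dia + g2) * dt)
    if rng is not None:
        cv = config.intensity_noise_cv
        i_para_a = i_para_a * _mult_noise(rng, cv, r)
        i_para_b = i_para_b * _mult_noise(rng, cv, r)
        i_dia_a = i_dia_a * _mult_noise(rng, cv, r)
        i_dia_b = i_dia_b * _mult_noise(rng, cv, r)
    return PRETable(
        config.residues, i_para_a, i_para_b, i_dia_a, i_dia_b, delay=dt
    )
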
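"""End-to-end orchestration: simulate or read → fit dimer → fit binding → report.

A pipeline run processes one or more protein variants (e.g. wild type
and acetylation-mimetic mutants), fits the dimer dissociation constant
from each dilution series and the ligand-complex dissociation constant
from each titration, derives free energies, fold changes against a
reference variant, and — when exactly a reference, two single mutants
and the double mutant are present — the free-energy additivity gap.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .binding import BindingFitResult, fit_binding
from .csp import csp_profile
from .dimer import (
    DimerFitResult,
    additivity_gap,
    fit_kd_dimer,
    fold_destabilization,
)
from .errors import UbafitError, ValidationError
from .peak_io import (
    Constants,
    read_dilution_table,
    read_titration_table,
    write_fit_report,
)
from .simulate import SimulationConfig, simulate_dilution, simulate_titration

__all__ = ["PipelineConfig", "VariantSpec", "PipelineReport", "run_pipeline", "load_config"]

log = logging.getLogger("ubafit")


@dataclass
class VariantSpec:
    """One protein variant: either input tables or simulation ground truths."""

    name: str
    dilution_path: str | None = None
    titration_path: str | None = None
    kd_dimer_true: float | None = None
    kd_complex_true: float | None = None


@dataclass
class PipelineConfig:
    variants: list[VariantSpec] = field(default_factory=list)
    reference: str = "WT"
    simulate: bool = False
    seed: int = 0
    n_boot: int = 200
    temperature: float = 298.0
    simulation: SimulationConfig | None = None  # design template for simulate mode

    def digest(self) -> str:
        payload = {
            "variants": [
                (v.name, v.dilution_path, v.titration_path, v.kd_dimer_true, v.kd_complex_true)
                for v in self.variants
            ],
            "reference": self.reference,
            "simulate": self.simulate,
            "seed": self.seed,
            "n_boot": self.n_boot,
            "temperature": self.temperature,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    """Per-variant fits plus derived comparisons and provenance."""

    variants: list[str]
    dimer: dict[str, DimerFitResult]
    binding: dict[str, BindingFitResult | None]
    fold_change: dict[str, float]  # K_D,dimer ratio vs the reference variant
    additivity_gap_kj: float | None
    provenance: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.variants:
            d = self.dimer[name]
            b = self.binding.get(name)
            rows.append(
                dict(
                    variant=name,
                    KD_dimer_uM=d.kd_dimer,
                    KD_dimer_sd=d.kd_sd,
                    dG_kJ_per_mol=d.delta_g,
                    dG_sd=d.delta_g_sd,
                    KD_complex_uM=b.kd_complex if b else float("nan"),
                    KD_complex_sd=b.kd_sd if b else float("nan"),
                    fold_vs_reference=self.fold_change[name],
                )
            )
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        write_fit_report(
            [(n, self.dimer[n], self.binding.get(n)) for n in self.variants], path
        )


def _variant_seed(base: int, index: int, stage: int) -> int:
    # distinct, reproducible stream per variant and stage, < 2^31
    return (base * 1_000_003 + index * 101 + stage) % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full analysis for every configured variant."""
    if not config.variants:
        raise ValidationError("no variants configured")
    names = [v.name for v in config.variants]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate variant names")
    constants = Constants(temperature=config.temperature)
    sim_template = config.simulation or SimulationConfig()
    dimer_results: dict[str, DimerFitResult] = {}
    binding_results: dict[str, BindingFitResult | None] = {}

    for i, variant in enumerate(config.variants):
        log.info("variant %s: dimer stage", variant.name)
        if config.simulate:
            if variant.kd_dimer_true is None:
                raise ValidationError(
                    f"variant {variant.name}: simulation mode needs kd_dimer_true"
                )
            sim = SimulationConfig(
                kd_dimer=variant.kd_dimer_true,
                kd_complex=variant.kd_complex_true or sim_template.kd_complex,
                protein_total=sim_template.protein_total,
                dilution_concs=sim_template.dilution_concs,
                ligand_concs=sim_template.ligand_concs,
                residues=sim_template.residues,
                volume_noise_cv=sim_template.volume_noise_cv,
                shift_noise_sd=sim_template.shift_noise_sd,
            )
            series = simulate_dilution(sim, seed=_variant_seed(config.seed, i, 0))
        elif variant.dilution_path:
            series = read_dilution_table(variant.dilution_path)
        else:
            raise ValidationError(
                f"variant {variant.name}: no dilution input and not simulating"
            )
        dimer_results[variant.name] = fit_kd_dimer(
            series,
            n_boot=config.n_boot,
            seed=_variant_seed(config.seed, i, 1),
            constants=constants,
        )
        log.info(
            "variant %s: KD_dimer = %.3g µM",
            variant.name,
            dimer_results[variant.name].kd_dimer,
        )

        log.info("variant %s: binding stage", variant.name)
        if config.simulate and variant.kd_complex_true is not None:
            titr = simulate_titration(sim, seed=_variant_seed(config.seed, i, 2))
        elif not config.simulate and variant.titration_path:
            titr = read_titration_table(variant.titration_path)
        else:
            binding_results[variant.name] = None
            continue
        binding_results[variant.name] = fit_binding(
            csp_profile(titr),
            protein_total=titr.protein_total,
            kd_dimer=dimer_results[variant.name].kd_dimer,
            n_boot=config.n_boot,
            seed=_variant_seed(config.seed, i, 3),
        )
        log.info(
            "variant %s: KD_complex = %.3g µM",
            variant.name,
            binding_results[variant.name].kd_complex,
        )

    ref = config.reference if config.reference in names else names[0]
    kd_ref = dimer_results[ref].kd_dimer
    fold = {n: fold_destabilization(dimer_results[n].kd_dimer, kd_ref) for n in names}

    gap = None
    if len(names) == 4 and ref in names:
        others = [n for n in names if n != ref]
        dgs = [dimer_results[n].delta_g for n in others]
        # convention: last-listed variant is the double mutant
        gap = additivity_gap(dimer_results[ref].delta_g, dgs[0], dgs[1], dgs[2])

    provenance = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "reference": ref,
    }
    return PipelineReport(
        variants=names,
        dimer=dimer_results,
        binding=binding_results,
        fold_change=fold,
        additivity_gap_kj=gap,
        provenance=provenance,
    )


def load_config(path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        variants = [VariantSpec(**v) for v in raw.get("variants", [])]
        sim_raw = raw.get("simulation")
        sim = SimulationConfig(**sim_raw) if sim_raw else None
        return PipelineConfig(
            variants=variants,
            reference=raw.get("reference", "WT"),
            simulate=bool(raw.get("simulate", False)),
            seed=int(raw.get("seed", 0)),
            n_boot=int(raw.get("n_boot", 200)),
            temperature=float(raw.get("temperature", 298.0)),
            simulation=sim,
        )
    except TypeError as exc:
        raise ValidationError(f"bad configuration in {path}: {exc}") from exc
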
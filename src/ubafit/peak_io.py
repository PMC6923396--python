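"""Tabular peak-list containers and readers/writers.

Three experiment types are supported, all as comma-delimited UTF-8 text
with a mandatory header:

* dilution series — slow-exchange monomer/dimer peak volumes per residue
  at several total protein concentrations
  (columns: ``residue, conc_total_uM, volume_monomer, volume_dimer``);
* titration series — amide 1H/15N chemical shifts per residue at
  increasing ligand concentrations with fixed protein total
  (columns: ``residue, protein_total_uM, ligand_total_uM, dH_ppm, dN_ppm``);
* PRE table — two-time-point paramagnetic/diamagnetic intensities
  (columns: ``residue, I_para_a, I_para_b, I_dia_a, I_dia_b``).

Concentrations are totals in monomer-equivalent µM throughout (a dimer
counts twice).  Peak volumes and intensities are in arbitrary but
internally consistent units; only within-spectrum ratios are used
downstream.  Residue labels are opaque strings — side-chain peaks such
as the tryptophan Hε1-Nε1 resonance are labelled freely (e.g. "W412sc").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "Constants",
    "DilutionSeries",
    "TitrationSeries",
    "PRETable",
    "read_dilution_table",
    "read_titration_table",
    "read_pre_table",
    "write_dilution_table",
    "write_titration_table",
    "write_pre_table",
    "write_fit_report",
    "REPORT_COLUMNS",
]


@dataclass(frozen=True)
class Constants:
    """Thermodynamic constants: gas constant R (J mol-1 K-1) and temperature (K)."""

    gas_constant: float = 8.314
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValidationError(f"temperature must be > 0 K, got {self.temperature}")
        if not self.gas_constant > 0:
            raise ValidationError("gas constant must be positive")


def _as_2d(name: str, a, n_rows: int, n_cols: int) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.shape != (n_rows, n_cols):
        raise ValidationError(
            f"{name} must have shape ({n_rows}, {n_cols}), got {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass
class DilutionSeries:
    """Monomer/dimer peak volumes over a protein dilution series.

    Attributes
    ----------
    residues:
        Residue labels, one per column of the volume matrices.
    concentrations:
        Total protein per point, monomer-equivalent µM, shape (n_points,).
    volume_monomer, volume_dimer:
        Peak volumes, arbitrary units >= 0, shape (n_points, n_residues).
    """

    residues: tuple[str, ...]
    concentrations: np.ndarray
    volume_monomer: np.ndarray
    volume_dimer: np.ndarray

    def __post_init__(self) -> None:
        self.residues = tuple(str(r) for r in self.residues)
        if len(set(self.residues)) != len(self.residues):
            raise ValidationError("duplicate residue labels")
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        n, r = self.concentrations.size, len(self.residues)
        if r == 0:
            raise ValidationError("at least one residue required")
        if np.any(~np.isfinite(self.concentrations)) or np.any(
            self.concentrations <= 0
        ):
            raise ValidationError("total concentrations must be positive and finite")
        if np.unique(self.concentrations).size < 2:
            raise ValidationError("at least 2 distinct concentrations required")
        self.volume_monomer = _as_2d("volume_monomer", self.volume_monomer, n, r)
        self.volume_dimer = _as_2d("volume_dimer", self.volume_dimer, n, r)
        if np.any(self.volume_monomer < 0) or np.any(self.volume_dimer < 0):
            raise ValidationError("peak volumes must be non-negative")
        total_vol = self.volume_monomer + self.volume_dimer
        if np.any(total_vol <= 0):
            i, j = np.argwhere(total_vol <= 0)[0]
            raise ValidationError(
                f"residue {self.residues[j]} at {self.concentrations[i]:g} µM "
                "has zero total peak volume"
            )

    @property
    def n_points(self) -> int:
        return self.concentrations.size

    def monomer_volume_fraction(self) -> np.ndarray:
        """Vm/(Vm+Vd) per point per residue; equals the monomer molar fraction."""
        return self.volume_monomer / (self.volume_monomer + self.volume_dimer)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.concentrations):
            for j, res in enumerate(self.residues):
                rows.append(
                    dict(
                        residue=res,
                        conc_total_uM=c,
                        volume_monomer=self.volume_monomer[i, j],
                        volume_dimer=self.volume_dimer[i, j],
                    )
                )
        return pd.DataFrame(rows)


@dataclass
class TitrationSeries:
    """Per-residue 1H/15N shifts over a ligand titration at fixed protein total.

    The first point (``ligand_totals[0] == 0``) is the reference against
    which chemical shift perturbations are computed.
    """

    residues: tuple[str, ...]
    protein_total: float
    ligand_totals: np.ndarray
    delta_h: np.ndarray  # (n_points, n_residues), ppm, absolute shifts
    delta_n: np.ndarray

    def __post_init__(self) -> None:
        self.residues = tuple(str(r) for r in self.residues)
        if len(set(self.residues)) != len(self.residues):
            raise ValidationError("duplicate residue labels")
        if not self.protein_total > 0:
            raise ValidationError("protein_total must be positive")
        self.ligand_totals = np.asarray(self.ligand_totals, dtype=float)
        n, r = self.ligand_totals.size, len(self.residues)
        if n < 1 or self.ligand_totals[0] != 0:
            raise ValidationError("first titration point must be the zero-ligand reference")
        if np.any(self.ligand_totals < 0):
            raise ValidationError("ligand concentrations must be non-negative")
        if np.any(np.diff(self.ligand_totals) <= 0):
            raise ValidationError("ligand concentrations must be strictly increasing")
        self.delta_h = _as_2d("delta_h", self.delta_h, n, r)
        self.delta_n = _as_2d("delta_n", self.delta_n, n, r)

    @property
    def n_points(self) -> int:
        return self.ligand_totals.size

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, lig in enumerate(self.ligand_totals):
            for j, res in enumerate(self.residues):
                rows.append(
                    dict(
                        residue=res,
                        protein_total_uM=self.protein_total,
                        ligand_total_uM=lig,
                        dH_ppm=self.delta_h[i, j],
                        dN_ppm=self.delta_n[i, j],
                    )
                )
        return pd.DataFrame(rows)


@dataclass
class PRETable:
    """Two-time-point intensities for paramagnetic and diamagnetic samples.

    ``delay`` is the time separation between the two points in seconds
    (0.012 s by default, the standard two-point scheme).
    """

    residues: tuple[str, ...]
    i_para_a: np.ndarray
    i_para_b: np.ndarray
    i_dia_a: np.ndarray
    i_dia_b: np.ndarray
    delay: float = 0.012

    def __post_init__(self) -> None:
        self.residues = tuple(str(r) for r in self.residues)
        if len(set(self.residues)) != len(self.residues):
            raise ValidationError("duplicate residue labels")
        if not self.delay > 0:
            raise ValidationError("delay must be positive")
        r = len(self.residues)
        for name in ("i_para_a", "i_para_b", "i_dia_a", "i_dia_b"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (r,):
                raise ValidationError(f"{name} must have shape ({r},), got {arr.shape}")
            if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
                raise ValidationError(f"{name} intensities must be positive and finite")
            setattr(self, name, arr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                residue=list(self.residues),
                I_para_a=self.i_para_a,
                I_para_b=self.i_para_b,
                I_dia_a=self.i_dia_a,
                I_dia_b=self.i_dia_b,
            )
        )


def _read_csv(path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    for col in required:
        if col == "residue":
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            raise FormatError(f"{path}: non-numeric values in column {col}")
        df[col] = coerced
    if df[list(required)].isna().any().any():
        raise FormatError(f"{path}: empty cells in required columns")
    return df


def read_dilution_table(path) -> DilutionSeries:
    """Read and validate a dilution-series peak-volume table."""
    df = _read_csv(
        path, ("residue", "conc_total_uM", "volume_monomer", "volume_dimer")
    )
    residues = tuple(pd.unique(df["residue"].astype(str)))
    concs = np.sort(pd.unique(df["conc_total_uM"].to_numpy(dtype=float)))
    if np.any(concs <= 0):
        raise ValidationError(f"{path}: non-positive total concentration")
    vm = np.full((concs.size, len(residues)), np.nan)
    vd = np.full_like(vm, np.nan)
    conc_idx = {c: i for i, c in enumerate(concs)}
    res_idx = {r: j for j, r in enumerate(residues)}
    for _, row in df.iterrows():
        i, j = conc_idx[float(row["conc_total_uM"])], res_idx[str(row["residue"])]
        if not np.isnan(vm[i, j]):
            raise ValidationError(
                f"{path}: duplicate row for residue {row['residue']} at "
                f"{row['conc_total_uM']:g} µM"
            )
        vm[i, j] = row["volume_monomer"]
        vd[i, j] = row["volume_dimer"]
    if np.isnan(vm).any():
        i, j = np.argwhere(np.isnan(vm))[0]
        raise ValidationError(
            f"{path}: residue {residues[j]} has no row at {concs[i]:g} µM"
        )
    return DilutionSeries(residues, concs, vm, vd)


def read_titration_table(path) -> TitrationSeries:
    """Read and validate a chemical-shift titration table."""
    df = _read_csv(
        path, ("residue", "protein_total_uM", "ligand_total_uM", "dH_ppm", "dN_ppm")
    )
    prot = pd.unique(df["protein_total_uM"].to_numpy(dtype=float))
    if prot.size != 1:
        raise ValidationError(f"{path}: protein_total_uM differs across rows")
    residues = tuple(pd.unique(df["residue"].astype(str)))
    ligs = np.sort(pd.unique(df["ligand_total_uM"].to_numpy(dtype=float)))
    if ligs.size == 0 or ligs[0] != 0:
        raise ValidationError(f"{path}: no zero-ligand reference row")
    dh = np.full((ligs.size, len(residues)), np.nan)
    dn = np.full_like(dh, np.nan)
    lig_idx = {c: i for i, c in enumerate(ligs)}
    res_idx = {r: j for j, r in enumerate(residues)}
    for _, row in df.iterrows():
        i, j = lig_idx[float(row["ligand_total_uM"])], res_idx[str(row["residue"])]
        if not np.isnan(dh[i, j]):
            raise ValidationError(
                f"{path}: duplicate ligand concentration "
                f"{row['ligand_total_uM']:g} µM for residue {row['residue']}"
            )
        dh[i, j] = row["dH_ppm"]
        dn[i, j] = row["dN_ppm"]
    if np.isnan(dh).any():
        i, j = np.argwhere(np.isnan(dh))[0]
        raise ValidationError(
            f"{path}: residue {residues[j]} has no row at ligand {ligs[i]:g} µM"
        )
    return TitrationSeries(residues, float(prot[0]), ligs, dh, dn)


def read_pre_table(path, delay: float = 0.012) -> PRETable:
    """Read and validate a two-time-point PRE intensity table."""
    df = _read_csv(path, ("residue", "I_para_a", "I_para_b", "I_dia_a", "I_dia_b"))
    residues = tuple(df["residue"].astype(str))
    return PRETable(
        residues,
        df["I_para_a"].to_numpy(dtype=float),
        df["I_para_b"].to_numpy(dtype=float),
        df["I_dia_a"].to_numpy(dtype=float),
        df["I_dia_b"].to_numpy(dtype=float),
        delay=delay,
    )


# 17 significant digits: a float64 survives the text round trip exactly
def _fmt(x: float) -> str:
    return format(x, ".17g")


def write_dilution_table(series: DilutionSeries, path) -> None:
    series.to_frame().to_csv(path, index=False, float_format=_fmt)


def write_titration_table(series: TitrationSeries, path) -> None:
    series.to_frame().to_csv(path, index=False, float_format=_fmt)


def write_pre_table(table: PRETable, path) -> None:
    table.to_frame().to_csv(path, index=False, float_format=_fmt)


REPORT_COLUMNS = (
    "variant",
    "KD_dimer_uM",
    "KD_dimer_sd",
    "dG_kJ_per_mol",
    "dG_sd",
    "KD_complex_uM",
    "KD_complex_sd",
)


def write_fit_report(results, path) -> pd.DataFrame:
    """Write a delimited fit report, one row per variant.

    ``results`` is an iterable of ``(variant_name, dimer_result, binding_result)``
    tuples; either result may be None, in which case its fields are blank.
    The column layout mirrors the standard per-variant summary: dimer K_D
    with uncertainty, the derived dissociation free energy, and the
    ligand-complex K_D with uncertainty.
    """
    rows = []
    for variant, dimer_res, binding_res in results:
        row = {c: np.nan for c in REPORT_COLUMNS}
        row["variant"] = variant
        if dimer_res is not None:
            row["KD_dimer_uM"] = dimer_res.kd_dimer
            row["KD_dimer_sd"] = dimer_res.kd_sd
            row["dG_kJ_per_mol"] = dimer_res.delta_g
            row["dG_sd"] = dimer_res.delta_g_sd
        if binding_res is not None:
            row["KD_complex_uM"] = binding_res.kd_complex
            row["KD_complex_sd"] = binding_res.kd_sd
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    df.to_csv(path, index=False)
    return df
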
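"""File I/O, packaged reference data, and the end-to-end pipeline.

Conventions: CSV files carry percent columns (``*_pct``, ``fa_wt_percent``)
and hours, as lab sheets do; the in-memory model uses fractions and
minutes.  Conversion happens only at this boundary.  Column matching is
case-insensitive and order-free.  Configs and fit outputs are JSON.

Two reference datasets ship with the package:

* ``bagasse_l16.csv`` — a published 16-run L16 orthogonal fractionation
  campaign on sugarcane bagasse (conditions, both severity conventions,
  solid yield, compositions, removal percentages, formyl content and
  enzymatic conversions).  It anchors the severity reproduction check.
* ``deformylated_solids.csv`` — compositions and digestibility of two
  lime-deformylated solids, stored as data only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fitting import FitResult, SolubilizationDataset, fit_all_variants
from .mass_balance import (
    DEFAULT_FEEDSTOCK,
    CompositionRecord,
    FeedstockComposition,
    component_solubilization,
    pooled_solubilization,
    total_solubilization,
)
from .models import DEFAULT_CLIP_EPS, ModelFamily
from .severity import (
    DEFAULT_DENSITY_TABLE,
    DEFAULT_FA_T_REF,
    DensityTable,
    FractionationCondition,
    SeverityConstants,
    SEVERITY_PRESETS,
    csf_ext_fa,
)
from .synthetic import (
    SimulationConfig,
    generate_design,
    simulate_alpha,
    simulate_composition_table,
)

__all__ = [
    "SchemaError",
    "read_conditions",
    "write_severity_table",
    "severity_table",
    "read_alpha",
    "write_alpha",
    "read_composition",
    "write_composition",
    "load_l16_reference",
    "l16_conditions",
    "load_deformylated_reference",
    "reproduce_l16",
    "PipelineConfig",
    "run_pipeline",
]

#: Agreement tolerance for the severity reproduction report.
L16_TOLERANCE = 0.02

#: Fixture entry known to be inconsistent with its own operating condition
#: (run 12's Arrhenius severity; a transcription error in the source table).
L16_KNOWN_MISPRINT = (12, "A_CSF_ext")


class SchemaError(ValueError):
    """An input table does not match its documented schema."""


def _match_columns(df: pd.DataFrame, required: Sequence[str]) -> pd.DataFrame:
    lower = {c.lower(): c for c in df.columns}
    missing = [c for c in required if c.lower() not in lower]
    if missing:
        raise SchemaError(
            f"missing column(s) {missing}; found {list(df.columns)}"
        )
    return df.rename(columns={lower[c.lower()]: c for c in required})


def read_conditions(path) -> pd.DataFrame:
    """Read a conditions CSV: run_id, temperature_C, fa_wt_percent, time_h."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    return _match_columns(df, ["run_id", "temperature_C", "fa_wt_percent", "time_h"])


def _conditions_from_frame(df: pd.DataFrame) -> list[FractionationCondition]:
    return [
        FractionationCondition.from_lab_units(
            row["temperature_C"], row["fa_wt_percent"], row["time_h"]
        )
        for _, row in df.iterrows()
    ]


def severity_table(
    df: pd.DataFrame,
    constants: dict[str, SeverityConstants],
    density_table: DensityTable = DEFAULT_DENSITY_TABLE,
) -> pd.DataFrame:
    """Append one CSF_ext column per named constant set to a conditions frame."""
    out = df.copy()
    conds = _conditions_from_frame(df)
    for label, consts in constants.items():
        out[label] = [csf_ext_fa(c, consts, density_table) for c in conds]
    return out


def write_severity_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_alpha(path) -> pd.DataFrame:
    """Read an alpha CSV: run_id, component, alpha (fractions)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    return _match_columns(df, ["run_id", "component", "alpha"])


def write_alpha(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


_COMPOSITION_COLS = [
    "run", "temperature_C", "fa_wt_percent", "time_h",
    "SY_pct", "GC_pct", "XC_pct", "LC_pct",
]


def read_composition(path_or_df) -> tuple[pd.DataFrame, list[CompositionRecord]]:
    """Read a composition CSV (percent columns) into typed records.

    Returns the normalized frame plus one :class:`CompositionRecord` per
    row with fractions.  Optional columns (FC_pct, EGC*_pct, XR/DD) are
    carried in the frame but only glucan/xylan/lignin/formyl contents enter
    the records.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        try:
            df = pd.read_csv(path_or_df)
        except pd.errors.EmptyDataError as exc:
            raise SchemaError(f"{path_or_df}: empty file") from exc
    df = _match_columns(df, _COMPOSITION_COLS)
    records = []
    for _, row in df.iterrows():
        contents = {
            "glucan": row["GC_pct"] / 100.0,
            "xylan": row["XC_pct"] / 100.0,
            "lignin": row["LC_pct"] / 100.0,
        }
        if "FC_pct" in df.columns and pd.notna(row.get("FC_pct", np.nan)):
            contents["formyl"] = row["FC_pct"] / 100.0
        egc = {}
        for col, label in (("EGC6_pct", "6h"), ("EGC72_pct", "72h")):
            if col in df.columns and pd.notna(row.get(col, np.nan)):
                egc[label] = row[col] / 100.0
        records.append(
            CompositionRecord(
                run_id=str(row["run"]),
                solid_yield=row["SY_pct"] / 100.0,
                contents=contents,
                egc=egc,
            )
        )
    return df, records


def write_composition(
    records: Sequence[CompositionRecord],
    conditions: Sequence[FractionationCondition],
    path,
) -> None:
    """Write composition records back to the percent-based CSV schema."""
    rows = []
    for rec, cond in zip(records, conditions):
        rows.append(
            {
                "run": rec.run_id,
                "temperature_C": cond.temperature_c,
                "fa_wt_percent": 100.0 * cond.fa_weight_fraction,
                "time_h": cond.time_min / 60.0,
                "SY_pct": 100.0 * rec.solid_yield,
                "GC_pct": 100.0 * rec.contents.get("glucan", np.nan),
                "XC_pct": 100.0 * rec.contents.get("xylan", np.nan),
                "LC_pct": 100.0 * rec.contents.get("lignin", np.nan),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def _packaged(name: str):
    return resources.files("csfext.data").joinpath(name)


def load_l16_reference() -> pd.DataFrame:
    """The packaged 16-run reference campaign (percent columns as published)."""
    with resources.as_file(_packaged("bagasse_l16.csv")) as p:
        return pd.read_csv(p)


def load_deformylated_reference() -> pd.DataFrame:
    """Compositions/digestibility of the two lime-deformylated solids (data only)."""
    with resources.as_file(_packaged("deformylated_solids.csv")) as p:
        return pd.read_csv(p)


def l16_conditions() -> list[FractionationCondition]:
    """The 16 reference operating points as typed conditions."""
    df = load_l16_reference()
    return _conditions_from_frame(df)


def reproduce_l16(
    arrhenius: SeverityConstants | None = None,
    logistic: SeverityConstants | None = None,
    density_table: DensityTable = DEFAULT_DENSITY_TABLE,
    tolerance: float = L16_TOLERANCE,
) -> pd.DataFrame:
    """Recompute both severity columns of the reference table and diff them.

    Returns the reference frame with ``computed_*``, ``delta_*`` and
    ``outlier_*`` columns; an entry is an outlier when |delta| exceeds
    ``tolerance``.  With the default (table1) constants the only outlier is
    the known misprinted Arrhenius entry of run 12.
    """
    arrhenius = arrhenius or SEVERITY_PRESETS["arrhenius-table1"]
    logistic = logistic or SEVERITY_PRESETS["logistic-table1"]
    df = load_l16_reference()
    conds = _conditions_from_frame(df)
    for label, consts in (("A_CSF_ext", arrhenius), ("L_CSF_ext", logistic)):
        computed = np.array([csf_ext_fa(c, consts, density_table) for c in conds])
        df[f"computed_{label}"] = computed
        df[f"delta_{label}"] = computed - df[label]
        df[f"outlier_{label}"] = np.abs(df[f"delta_{label}"]) > tolerance
    return df


@dataclass
class PipelineConfig:
    """Everything needed to re-run the pipeline bit-identically."""

    out_dir: Path
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    families: tuple[str, ...] = ("arrhenius", "logistic")
    preset: str = "table1"  # or "eq78"
    t_ref_c: float = DEFAULT_FA_T_REF
    clip_eps: float = DEFAULT_CLIP_EPS
    lignin_basis: str = "klason"
    xylan_basis: str = "xylan_only"
    feedstock: FeedstockComposition = DEFAULT_FEEDSTOCK

    def preset_constants(self) -> dict[str, SeverityConstants]:
        if self.preset == "table1":
            return {
                "arrhenius": SEVERITY_PRESETS["arrhenius-table1"],
                "logistic": SEVERITY_PRESETS["logistic-table1"],
            }
        if self.preset == "eq78":
            return {
                "arrhenius": SEVERITY_PRESETS["arrhenius-eq7"],
                "logistic": SEVERITY_PRESETS["logistic-eq8"],
            }
        raise ValueError(f"unknown preset {self.preset!r} (use 'table1' or 'eq78')")


def _density_hash(table: DensityTable) -> str:
    blob = json.dumps(
        {f"{float(k):g}": v for k, v in table.densities_g_per_ml.items()},
        sort_keys=True,
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate a campaign, derive all variants, fit, and report.

    Stages: (1) factorial design + noisy per-component alphas from the
    simulation config; (2) inverse mass balance to a composition table;
    (3) pooled and total-biomass variants re-derived from that table through
    the forward mass balance; (4) joint OLS fits of every variant for each
    requested family, ranked by R-squared; (5) severity reproduction report
    against the packaged reference campaign.  All artifacts are written
    under ``config.out_dir``; the returned bundle holds the in-memory
    objects plus a provenance block sufficient to re-run bit-identically.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation

    conditions = generate_design(sim)
    dataset = simulate_alpha(conditions, sim, components=["xylan", "lignin", "glucan"])
    dataset.clip_eps = config.clip_eps
    records = simulate_composition_table(
        dataset, config.feedstock, sim,
        lignin_basis=config.lignin_basis, xylan_basis=config.xylan_basis,
    )
    write_composition(records, conditions, out / "composition.csv")

    # variant datasets: xylan / lignin direct, pooled and total via mass balance
    variant_datasets: dict[str, SolubilizationDataset] = {
        "xylan": dataset.for_component("xylan"),
        "lignin": dataset.for_component("lignin"),
    }
    pooled = [
        pooled_solubilization(
            r, config.feedstock,
            lignin_basis=config.lignin_basis, xylan_basis=config.xylan_basis,
        )
        for r in records
    ]
    total = [total_solubilization(r) for r in records]
    variant_datasets["xylan_plus_lignin"] = SolubilizationDataset.from_records(
        conditions, pooled, component="xylan_plus_lignin",
        density_table=sim.density_table, clip_eps=config.clip_eps,
    )
    variant_datasets["total_biomass"] = SolubilizationDataset.from_records(
        conditions, total, component="total_biomass",
        density_table=sim.density_table, clip_eps=config.clip_eps,
    )

    # alpha table artifact
    alpha_rows = dataset.frame.copy()
    alpha_rows.insert(0, "run_id", np.tile(np.arange(1, len(conditions) + 1),
                                           len(dataset.components)))
    write_alpha(alpha_rows[["run_id", "component", "alpha"]], out / "alpha.csv")

    conditions_df = pd.DataFrame(
        {
            "run_id": np.arange(1, len(conditions) + 1),
            "temperature_C": [c.temperature_c for c in conditions],
            "fa_wt_percent": [100 * c.fa_weight_fraction for c in conditions],
            "time_h": [c.time_min / 60.0 for c in conditions],
        }
    )
    conditions_df.to_csv(out / "conditions.csv", index=False)

    presets = config.preset_constants()
    csf = severity_table(
        conditions_df,
        {f"{fam}_csf_ext": consts for fam, consts in presets.items()},
        sim.density_table,
    )
    write_severity_table(csf, out / "csf.csv")

    fits: dict[str, dict[str, FitResult]] = {}
    reports = []
    for fam in config.families:
        fam_fits, report = fit_all_variants(variant_datasets, fam, config.t_ref_c)
        fits[fam] = fam_fits
        reports.append(report)
    variant_report = pd.concat(reports, ignore_index=True)
    variant_report.to_csv(out / "variant_report.csv", index=False)
    with open(out / "fits.json", "w") as fh:
        json.dump(
            {fam: {v: f.to_dict() for v, f in fam_fits.items()}
             for fam, fam_fits in fits.items()},
            fh, indent=2,
        )

    repro = reproduce_l16(
        presets.get("arrhenius", SEVERITY_PRESETS["arrhenius-table1"]),
        presets.get("logistic", SEVERITY_PRESETS["logistic-table1"]),
        sim.density_table,
    )
    repro.to_csv(out / "l16_reproduction.csv", index=False)

    provenance = {
        "seed": sim.seed,
        "preset": config.preset,
        "t_ref_c": config.t_ref_c,
        "clip_eps": config.clip_eps,
        "lignin_basis": config.lignin_basis,
        "xylan_basis": config.xylan_basis,
        "noise_sigma": sim.noise_sigma,
        "noise_scale": sim.noise_scale,
        "density_table_sha256_12": _density_hash(sim.density_table),
        "n_conditions": len(conditions),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)

    return {
        "conditions": conditions,
        "dataset": dataset,
        "composition": records,
        "variant_datasets": variant_datasets,
        "fits": fits,
        "variant_report": variant_report,
        "l16_reproduction": repro,
        "provenance": provenance,
        "out_dir": out,
    }
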
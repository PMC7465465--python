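"""End-to-end pipeline: areas -> RRF -> quantify -> back-calculate -> validate.

Deterministic and seed-free: all randomness lives in the simulator. Each
stage logs one machine-greppable line per sample with the key numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .chromatograms import (
    DEFAULT_BLANK_REGION,
    DEFAULT_HALFWIDTH,
    DEFAULT_RT_WINDOW,
    SIMChromatogram,
    summed_quant_area,
)
from .errors import ConfigurationError, DataError
from .isotopes import D3_DICAMBA, DICAMBA, CompoundIonSpec, derive_sim_channels
from .quantify import (
    QuantResult,
    ResponseCalibration,
    SamplePrepFactors,
    compute_rrf,
    quantify,
    back_calculate,
)
from .validation import (
    LINEARITY_MAX_RSD,
    LINEARITY_MIN_R2,
    LinearityResult,
    MatrixEffectResult,
    RecoveryResult,
    ReplicateSummary,
    assess_linearity,
    compute_matrix_effect,
    compute_recovery,
    round_half_up,
    summarize_replicates,
)

logger = logging.getLogger("sidquant")

__all__ = ["PipelineConfig", "ValidationReport", "measure_areas", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Processing parameters and acceptance thresholds for one batch."""

    analyte: CompoundIonSpec = DICAMBA
    internal_standard: CompoundIonSpec = D3_DICAMBA
    rt_window: tuple[float, float] = DEFAULT_RT_WINDOW
    integration_halfwidth: float = DEFAULT_HALFWIDTH
    blank_region: tuple[float, float] = DEFAULT_BLANK_REGION
    snr_lod: float = 3.0
    snr_loq: float = 10.0
    linearity_min_r2: float = LINEARITY_MIN_R2
    linearity_max_rsd: float = LINEARITY_MAX_RSD
    report_decimals: int = 1

    def __post_init__(self) -> None:
        if self.rt_window[0] >= self.rt_window[1]:
            raise ConfigurationError("rt_window must be ordered")
        if self.blank_region[0] >= self.blank_region[1]:
            raise ConfigurationError("blank_region must be ordered")
        if min(self.snr_lod, self.snr_loq) <= 0:
            raise ConfigurationError("S/N thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("analyte", "internal_standard"):
            if key in raw:
                spec = raw.pop(key)
                kwargs[key] = derive_sim_channels(
                    spec["precursor_mz"],
                    spec["fragment_mz"],
                    spec["n_chlorines"],
                    spec.get("label_shift", 0),
                    name=spec.get("name", key),
                )
        for key in ("rt_window", "blank_region"):
            if key in raw:
                raw[key] = tuple(raw[key])
        kwargs.update(raw)
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: {exc}") from exc


@dataclass
class ValidationReport:
    """Collected method-performance results for one batch."""

    rrf: ResponseCalibration | None = None
    linearity: LinearityResult | None = None
    recovery: list[RecoveryResult] = field(default_factory=list)
    matrix_effects: list[MatrixEffectResult] = field(default_factory=list)
    replicate_summaries: dict[str, ReplicateSummary] = field(
        default_factory=dict
    )

    def to_text(self) -> str:
        lines = ["method validation summary", "=" * 25]
        if self.rrf is not None:
            lines.append(
                f"RRF: mean {self.rrf.rrf_mean:.4f} "
                f"(RSD {self.rrf.rrf_rsd:.2f}%, n={self.rrf.n_levels})"
            )
        if self.linearity is not None:
            status = "PASS" if self.linearity.passed else "FAIL"
            lines.append(
                f"linearity: R2={self.linearity.r_squared:.4f} "
                f"slope={self.linearity.slope:.4g} [{status}]"
            )
        for rec in self.recovery:
            lines.append(
                f"recovery @ {rec.level:g}: {rec.mean_recovery:.0f}% "
                f"(RSD {rec.rsd:.1f}%, n={rec.n})"
            )
        for me in self.matrix_effects:
            lines.append(
                f"matrix effect [{me.matrix}]: {me.effect:.0f}% "
                f"({me.interpretation})"
            )
        for group, summ in self.replicate_summaries.items():
            lines.append(
                f"{group}: mean {summ.mean_rounded:g} "
                f"(RSD {summ.rsd_rounded:g}%, n={len(summ.values)})"
            )
        return "\n".join(lines) + "\n"

    def write_tables(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.recovery:
            pd.DataFrame(
                [
                    {
                        "level": r.level,
                        "mean_recovery_pct": round_half_up(r.mean_recovery, 0),
                        "rsd_pct": round_half_up(r.rsd, 1),
                        "n": r.n,
                    }
                    for r in self.recovery
                ]
            ).to_csv(out / "recovery.csv", index=False)
        if self.replicate_summaries:
            pd.DataFrame(
                [
                    {
                        "group": g,
                        "mean": s.mean_rounded,
                        "rsd_pct": s.rsd_rounded,
                        "n": len(s.values),
                    }
                    for g, s in self.replicate_summaries.items()
                ]
            ).to_csv(out / "replicate_summaries.csv", index=False)
        if self.matrix_effects:
            pd.DataFrame(
                [
                    {
                        "matrix": m.matrix,
                        "effect_pct": round_half_up(m.effect, 0),
                        "interpretation": m.interpretation,
                    }
                    for m in self.matrix_effects
                ]
            ).to_csv(out / "matrix_effect.csv", index=False)
        (out / "summary.txt").write_text(self.to_text())


def measure_areas(
    config: PipelineConfig,
    chromatograms: list[SIMChromatogram],
) -> pd.DataFrame:
    """Summed analyte and IS quantification areas per sample."""
    rows = []
    for chrom in chromatograms:
        row = {"sample_id": chrom.sample_id}
        for label, spec in (
            ("analyte", config.analyte),
            ("is", config.internal_standard),
        ):
            peak = summed_quant_area(
                chrom,
                spec,
                rt_window=config.rt_window,
                halfwidth=config.integration_halfwidth,
                blank_region=config.blank_region,
            )
            if peak is None:
                row[f"{label}_area"] = 0.0
                row[f"{label}_snr"] = 0.0
                row[f"{label}_rt"] = float("nan")
            else:
                row[f"{label}_area"] = peak.area
                row[f"{label}_snr"] = peak.snr
                row[f"{label}_rt"] = peak.rt
        logger.info(
            "areas sample=%s analyte_area=%.4g is_area=%.4g",
            chrom.sample_id,
            row["analyte_area"],
            row["is_area"],
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _prep_from_row(row: pd.Series) -> SamplePrepFactors:
    basis = str(row["is_basis"])
    return SamplePrepFactors(
        sample_volume_ml=float(row["sample_volume_ml"]),
        residue_volume_ml=float(row["residue_volume_ml"]),
        aliquot_dilution=float(row["aliquot_dilution"]),
        is_basis=basis,
        reporting_basis=(
            "total_amount" if basis == "ug_total" else "conc_in_sample"
        ),
    )


def run_pipeline(
    config: PipelineConfig,
    chromatograms: list[SIMChromatogram],
    sample_sheet: pd.DataFrame,
    rrf: ResponseCalibration | None = None,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Run the full batch: areas, RRF, quantification, validation.

    The RRF source is either ``rrf_level`` samples in the batch or a
    persisted calibration passed as ``rrf``. Identical inputs give
    identical outputs; there is no randomness on this path.
    """
    if sample_sheet.empty:
        raise ConfigurationError("sample sheet is empty")
    if sample_sheet["sample_id"].duplicated().any():
        raise DataError("sample sheet has duplicate sample ids")
    areas = measure_areas(config, chromatograms)
    merged = sample_sheet.merge(areas, on="sample_id", how="left")
    if merged["analyte_area"].isna().any():
        missing = merged.loc[merged["analyte_area"].isna(), "sample_id"]
        raise DataError(
            f"no chromatogram for sample(s): {', '.join(missing.astype(str))}"
        )

    report = ValidationReport()

    # --- RRF calibration -------------------------------------------------
    rrf_rows = merged[merged["sample_type"] == "rrf_level"]
    if rrf is None:
        if rrf_rows.empty:
            raise ConfigurationError(
                "no RRF source: provide rrf_level samples or a persisted "
                "RRF calibration"
            )
        series = [
            (
                float(r["nominal_analyte"]),
                float(r["analyte_area"]),
                float(r["is_reference"]),
                float(r["is_area"]),
            )
            for _, r in rrf_rows.iterrows()
        ]
        try:
            rrf = compute_rrf(series)
        except ValueError as exc:
            raise DataError(f"RRF calibration failed: {exc}") from exc
        logger.info(
            "rrf mean=%.5f rsd=%.3f%% n=%d",
            rrf.rrf_mean,
            rrf.rrf_rsd,
            rrf.n_levels,
        )
    report.rrf = rrf

    # --- quantification ---------------------------------------------------
    results: list[dict] = []
    quantifiable = merged[
        merged["sample_type"].isin(["recovery", "unknown"])
    ]
    for _, row in quantifiable.iterrows():
        prep = _prep_from_row(row)
        try:
            value = quantify(
                float(row["analyte_area"]),
                float(row["is_area"]),
                float(row["is_reference"]),
                rrf.rrf_mean,
            )
        except DataError as exc:
            raise DataError(
                f"sample {row['sample_id']!r}: {exc}"
            ) from exc
        qr: QuantResult = back_calculate(
            value,
            prep,
            sample_id=str(row["sample_id"]),
            is_reference=float(row["is_reference"]),
        )
        reported = (
            qr.total_amount if qr.conc_analyte is None else qr.conc_analyte
        )
        logger.info(
            "quantify sample=%s ratio=%.4g value=%.6g reported=%.6g",
            row["sample_id"],
            float(row["analyte_area"]) / float(row["is_area"])
            if float(row["is_area"]) > 0
            else float("nan"),
            value,
            reported,
        )
        results.append(
            {
                "sample_id": row["sample_id"],
                "sample_type": row["sample_type"],
                "group": row["group"],
                "nominal_analyte": row["nominal_analyte"],
                "analyte_area": row["analyte_area"],
                "is_area": row["is_area"],
                "conc_analyte": qr.conc_analyte,
                "total_amount_ng": qr.total_amount,
                "reported_value": reported,
                "flags": ";".join(sorted(qr.flags)),
            }
        )
    results_df = pd.DataFrame(
        results,
        columns=[
            "sample_id",
            "sample_type",
            "group",
            "nominal_analyte",
            "analyte_area",
            "is_area",
            "conc_analyte",
            "total_amount_ng",
            "reported_value",
            "flags",
        ],
    )

    # --- validation -------------------------------------------------------
    cal = merged[merged["sample_type"] == "calibration"]
    if len(cal) >= 2 and cal["nominal_analyte"].nunique() >= 2:
        report.linearity = assess_linearity(
            cal.rename(
                columns={"nominal_analyte": "concentration",
                         "analyte_area": "area"}
            )[["concentration", "area", "day_label"]],
            min_r2=config.linearity_min_r2,
            max_rsd=config.linearity_max_rsd,
        )

    rec = results_df[results_df["sample_type"] == "recovery"]
    if not rec.empty:
        report.recovery = compute_recovery(
            rec.rename(
                columns={"nominal_analyte": "nominal",
                         "conc_analyte": "measured"}
            )[["nominal", "measured"]]
        )

    mx = merged[merged["sample_type"] == "matrix"]
    if not mx.empty:
        for matrix_name, grp in mx[mx["matrix"] != "solvent"].groupby(
            "matrix"
        ):
            solvent_mean = mx.loc[
                mx["matrix"] == "solvent", "analyte_area"
            ].mean()
            report.matrix_effects.append(
                compute_matrix_effect(
                    grp["analyte_area"].mean(),
                    float(solvent_mean),
                    matrix=str(matrix_name),
                )
            )

    unknowns = results_df[results_df["sample_type"] == "unknown"]
    for group, grp in unknowns.groupby("group"):
        if len(grp) >= 2:
            report.replicate_summaries[str(group)] = summarize_replicates(
                grp["reported_value"]
            )

    return results_df, report
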
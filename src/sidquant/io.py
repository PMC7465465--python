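"""File formats: long-CSV chromatograms, sample sheets, RRF JSON, results.

The chromatogram dialect is a long CSV with columns
``sample_id,channel_mz,time_min,intensity`` -- diffable, and trivially
regenerated by the simulator. Sample sheets and quantification results
are plain CSV; the averaged RRF calibration persists as a small JSON
document so a calibration can be reused across batches.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chromatograms import SIMChromatogram
from .errors import DataError, FormatError
from .quantify import ResponseCalibration, RFLevel

__all__ = [
    "CHROMATOGRAM_COLUMNS",
    "read_chromatograms",
    "write_chromatograms",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_rrf_json",
    "write_rrf_json",
    "write_manifest",
]

CHROMATOGRAM_COLUMNS = ["sample_id", "channel_mz", "time_min", "intensity"]

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "sample_type",
    "matrix",
    "group",
    "day_label",
    "nominal_analyte",
    "is_reference",
    "is_basis",
    "sample_volume_ml",
    "residue_volume_ml",
    "aliquot_dilution",
]

_SAMPLE_TYPES = {
    "calibration",
    "rrf_level",
    "recovery",
    "matrix",
    "unknown",
    "blank",
}


def write_chromatograms(chroms, path) -> None:
    """Write chromatograms to the long-CSV dialect."""
    frames = []
    for chrom in chroms:
        for mz in sorted(chrom.channels):
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": chrom.sample_id,
                        "channel_mz": mz,
                        "time_min": chrom.time,
                        "intensity": chrom.channels[mz],
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_chromatograms(path) -> list[SIMChromatogram]:
    """Read long-CSV chromatograms, grouped and time-sorted.

    Row order in the file is irrelevant. Duplicated
    ``(sample, channel, time)`` rows are a data error; each channel must
    yield a strictly increasing time grid shared within its sample.
    """
    df = pd.read_csv(path)
    missing = [c for c in CHROMATOGRAM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    if df.duplicated(subset=["sample_id", "channel_mz", "time_min"]).any():
        bad = df[
            df.duplicated(subset=["sample_id", "channel_mz", "time_min"])
        ]["sample_id"].iloc[0]
        raise DataError(
            f"{path}: duplicated (sample, channel, time) rows in sample "
            f"{bad!r}"
        )
    chroms = []
    for sample_id, sample_df in df.groupby("sample_id", sort=True):
        channels = {}
        time_ref = None
        for mz, ch_df in sample_df.groupby("channel_mz", sort=True):
            ch_df = ch_df.sort_values("time_min")
            t = ch_df["time_min"].to_numpy(dtype=float)
            if time_ref is None:
                time_ref = t
            elif t.shape != time_ref.shape or not np.allclose(t, time_ref):
                raise DataError(
                    f"{path}: sample {sample_id!r} channels do not share "
                    "one time grid"
                )
            channels[float(mz)] = ch_df["intensity"].to_numpy(dtype=float)
        try:
            chroms.append(
                SIMChromatogram(
                    sample_id=str(sample_id), time=time_ref, channels=channels
                )
            )
        except ValueError as exc:
            raise DataError(f"{path}: {exc}") from exc
    return chroms


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    """Read and validate a sample sheet CSV."""
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    if df["sample_id"].duplicated().any():
        dup = df[df["sample_id"].duplicated()]["sample_id"].iloc[0]
        raise DataError(f"{path}: duplicate sample_id {dup!r}")
    unknown = set(df["sample_type"]) - _SAMPLE_TYPES
    if unknown:
        raise DataError(
            f"{path}: unknown sample_type value(s) {sorted(unknown)}"
        )
    needs_nominal = df["sample_type"].isin(
        ["calibration", "rrf_level", "recovery"]
    )
    if df.loc[needs_nominal, "nominal_analyte"].isna().any():
        bad = df.loc[
            needs_nominal & df["nominal_analyte"].isna(), "sample_id"
        ].iloc[0]
        raise DataError(
            f"{path}: sample {bad!r} requires a nominal_analyte value"
        )
    return df


def write_rrf_json(calibration: ResponseCalibration, path, **metadata) -> None:
    doc = {
        "rrf_mean": calibration.rrf_mean,
        "rrf_rsd": calibration.rrf_rsd,
        "levels": [
            {
                "analyte_conc": lv.analyte_conc,
                "analyte_area": lv.analyte_area,
                "is_conc": lv.is_conc,
                "is_area": lv.is_area,
                "rf_analyte": lv.rf_analyte,
                "rf_is": lv.rf_is,
                "rrf": lv.rrf,
            }
            for lv in calibration.per_level
        ],
        "metadata": metadata,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_rrf_json(path) -> ResponseCalibration:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    try:
        levels = tuple(
            RFLevel(
                analyte_conc=lv["analyte_conc"],
                analyte_area=lv["analyte_area"],
                is_conc=lv["is_conc"],
                is_area=lv["is_area"],
                rf_analyte=lv["rf_analyte"],
                rf_is=lv["rf_is"],
                rrf=lv["rrf"],
            )
            for lv in doc["levels"]
        )
        return ResponseCalibration(
            per_level=levels,
            rrf_mean=doc["rrf_mean"],
            rrf_rsd=doc["rrf_rsd"],
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing RRF field {exc}") from exc


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
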
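"""Readers and writers for the pipeline's tabular formats.

Conventions: TSV/CSV with one documented header line; BED is 0-based
half-open; arm identifiers are "1p".."22q"; missing data are empty fields,
never 0.  Output files may carry provenance comment lines starting with
'#' ahead of the header; all readers skip them.  Row-level validation
errors name the offending line.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd
import yaml

from .aneuploidy import ArmCountProfile
from .ctc import CTCMeasurement
from .ddpcr import DropletAssay
from .exceptions import SchemaError
from .methylation import RegionCountMatrix
from .simulate import SyntheticCohort


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


# -- arm counts ----------------------------------------------------------


def write_arm_counts(profiles: list[ArmCountProfile], path, header: str | None = None) -> None:
    rows = [
        {"sample_id": p.sample_id, "arm": a, "count": c}
        for p in profiles
        for a, c in p.counts.items()
    ]
    _write_table(pd.DataFrame(rows), path, sep="\t", header_comment=header)


def read_arm_counts(path) -> list[ArmCountProfile]:
    df = _read_table(path, sep="\t")
    _require_columns(df, ["sample_id", "arm", "count"], path)
    bad = df.index[pd.to_numeric(df["count"], errors="coerce").fillna(-1) < 0]
    if len(bad):
        raise SchemaError(f"{path}: negative or non-numeric count at data row {bad[0] + 1}")
    profiles = []
    for sid, grp in df.groupby("sample_id", sort=False):
        counts = dict(zip(grp["arm"], grp["count"].astype(int)))
        profiles.append(
            ArmCountProfile(sample_id=str(sid), counts=counts,
                            total_mapped_reads=int(sum(counts.values())))
        )
    return profiles


# -- methylation ---------------------------------------------------------


def write_methylation(matrix: RegionCountMatrix, bed_path, counts_path, groups_path) -> None:
    bed = matrix.regions.copy()
    bed.insert(0, "chrom_bed", "chr" + bed["chrom"].astype(str))
    bed_out = bed[["chrom_bed", "start", "end"]].copy()
    bed_out["name"] = bed.index
    bed_out.to_csv(bed_path, sep="\t", header=False, index=False)
    out = matrix.counts.copy()
    out.insert(0, "region_id", out.index)
    _write_table(out, counts_path, sep="\t")
    pd.DataFrame(
        {"sample_id": list(matrix.groups), "group": list(matrix.groups.values())}
    ).to_csv(groups_path, index=False)


def read_methylation(bed_path, counts_path, groups_path) -> RegionCountMatrix:
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "region_id"],
    )
    bad = bed.index[bed["start"] >= bed["end"]]
    if len(bad):
        raise SchemaError(f"{bed_path}: start >= end at data row {bad[0] + 1}")
    if len(bed) and bed["start"].min() == 1:
        warnings.warn(
            f"{bed_path}: minimum start is 1 - coordinates look 1-based; "
            "BED is read as 0-based half-open, no correction applied"
        )
    bed["chrom"] = bed["chrom"].astype(str).str.removeprefix("chr")
    regions = bed.set_index("region_id")
    counts = _read_table(counts_path, sep="\t").set_index("region_id")
    groups_df = pd.read_csv(groups_path, comment="#")
    _require_columns(groups_df, ["sample_id", "group"], groups_path)
    groups = dict(zip(groups_df["sample_id"], groups_df["group"]))
    regions = regions.loc[counts.index]
    return RegionCountMatrix(regions=regions, counts=counts, groups=groups)


# -- ddPCR ---------------------------------------------------------------


def write_ddpcr(assays: list[DropletAssay], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": a.sample_id, "assay": a.assay_name,
                "mutant_positive": a.mutant_positive,
                "wildtype_positive": a.wildtype_positive,
                "total_droplets": a.total_droplets,
            }
            for a in assays
        ]
    ).to_csv(path, index=False)


def read_ddpcr(path) -> list[DropletAssay]:
    df = _read_table(path, sep=",")
    _require_columns(
        df, ["sample_id", "assay", "mutant_positive", "wildtype_positive", "total_droplets"], path
    )
    assays = []
    for i, row in df.iterrows():
        try:
            assays.append(
                DropletAssay(
                    sample_id=str(row["sample_id"]), assay_name=str(row["assay"]),
                    mutant_positive=int(row["mutant_positive"]),
                    wildtype_positive=int(row["wildtype_positive"]),
                    total_droplets=int(row["total_droplets"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: invalid droplet row {i + 1}: {exc}") from exc
    return assays


# -- cohort table --------------------------------------------------------


def write_cohort_table(patients: pd.DataFrame, path) -> None:
    patients.to_csv(path, index=False)


def read_cohort_table(path) -> pd.DataFrame:
    df = _read_table(path, sep=",")
    _require_columns(df, ["patient_id"], path)
    return df


def ctc_measurements_from_cohort(patients: pd.DataFrame) -> list[CTCMeasurement]:
    """Expand the wide per-patient cohort table into platform measurements."""
    out = []
    for _, row in patients.iterrows():
        out.append(CTCMeasurement(row["patient_id"], "PB_CellSearch",
                                  int(row["ctc_pb_cellsearch"]), 7.5))
        out.append(
            CTCMeasurement(
                row["patient_id"], "DLA_CellSearch", int(row["ctc_dla_cellsearch"]),
                float(row.get("aliquot_volume_mL", 1.5)),
                product_total_volume_mL=float(row["product_volume_mL"]),
                processed_blood_volume_L=float(row["processed_blood_L"]),
            )
        )
        out.append(
            CTCMeasurement(
                row["patient_id"], "DLA_FCM", int(row["ctc_dla_fcm"]),
                float(row["product_volume_mL"]),
                product_total_volume_mL=float(row["product_volume_mL"]),
                processed_blood_volume_L=float(row["processed_blood_L"]),
            )
        )
    return out


# -- cohort bundle -------------------------------------------------------

COHORT_FILES = (
    "arms.tsv", "patient_arms.tsv", "regions.bed", "methylation_counts.tsv",
    "groups.csv", "ddpcr.csv", "cohort.csv", "truth.json", "config.yaml",
)


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Write the full synthetic cohort in the documented formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_arm_counts(cohort.hbd_arm_profiles + cohort.patient_arm_profiles,
                     outdir / "arms.tsv")
    write_methylation(cohort.methylation, outdir / "regions.bed",
                      outdir / "methylation_counts.tsv", outdir / "groups.csv")
    write_ddpcr(cohort.ddpcr, outdir / "ddpcr.csv")
    write_cohort_table(cohort.patients, outdir / "cohort.csv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    cfg = cohort.truth["config"]
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    return outdir


def read_config_yaml(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg


# -- low-level helpers ---------------------------------------------------


def _read_table(path, sep: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=sep, comment="#")


def _write_table(df: pd.DataFrame, path, sep: str, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=False)


def write_with_provenance(df: pd.DataFrame, path, sep: str, thresholds: dict) -> None:
    """Write a result table with the thresholds used embedded as comments."""
    header = "\n".join(f"{k}={v}" for k, v in thresholds.items())
    _write_table(df, path, sep=sep, header_comment=header)
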
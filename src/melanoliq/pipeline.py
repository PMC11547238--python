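"""End-to-end driver: simulate -> QC -> score -> report.

Mirrors the study flow: chromosome-arm aneuploidy scoring against the HBD
panel, selection of high-ctDNA patients, DMR discovery, melanoma-specific
methylation scores with the HBD-derived cutoff, ddPCR VAF estimation, CTC
detection/recovery metrics, and the integrated cohort report.  Every stage
writes its output with the thresholds used embedded in a provenance header;
a missing input marks the stage as skipped rather than failing the run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .aneuploidy import AneuploidyScorer
from .ctc import detection_summary, recovery_from_measurements
from .ddpcr import dominant_vaf, estimate_vaf
from .exceptions import DomainError, MelanoliqError, PipelineError
from .methylation import (
    DMRFinder,
    HBD,
    MethylationScorer,
    call_altered,
    filter_regions,
    hbd_cutoff,
    normalize_counts,
    pca_top_variable,
    select_high_ctdna,
)
from .simulate import SimulationConfig, simulate_cohort
from .stats import cohort_report

STAGES = (
    "simulate", "aneuploidy", "select_high_ctdna", "dmr_discovery",
    "methylation_scores", "vaf", "ctc", "report",
)


@dataclass
class PipelineConfig:
    """Paths, thresholds and switches for one pipeline run.

    Threshold defaults are the study's printed values: aneuploidy positivity
    at score >= 3, DMR FDR 0.10, region completeness 0.75, LpnPI QC fraction
    0.20, read-depth QC 90,000, >= 3 mutant droplets for detection, >= 1 CTC
    for platform positivity.
    """

    workdir: str | Path = "melanoliq_run"
    simulate: bool = True
    seed: int = 0
    n_patients: int = 20
    aneuploidy_threshold: float = 3.0
    fdr: float = 0.10
    completeness: float = 0.75
    lpnpi_min_fraction: float = 0.20
    min_mapped_reads: int = 90_000
    min_droplets: int = 3
    ctc_positivity: int = 1
    cutoff_mode: str = "ci_mean"
    pca_fraction: float = 0.50
    dry_run: bool = False

    def __post_init__(self) -> None:
        for name in ("fdr", "completeness", "lpnpi_min_fraction", "pca_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise DomainError(f"{name} must be in (0, 1), got {v}")

    def thresholds(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("workdir")
        return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline; returns {stage: status} plus in-memory results.

    Any stage failure aborts with the stage name and cause; a stage whose
    input file is absent is marked "skipped".
    """
    workdir = Path(config.workdir)
    status: dict[str, str] = {}
    results: dict = {"status": status, "workdir": workdir}
    if config.dry_run:
        for s in STAGES:
            status[s] = "planned"
        return results
    workdir.mkdir(parents=True, exist_ok=True)

    def run_stage(name, fn):
        try:
            out = fn()
        except FileNotFoundError as exc:
            status[name] = "skipped"
            results[name] = None
            return None
        except MelanoliqError as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        status[name] = "ok"
        results[name] = out
        return out

    # 1. simulate ---------------------------------------------------------
    if config.simulate:
        def do_simulate():
            sim = SimulationConfig(seed=config.seed, n_patients=config.n_patients)
            cohort = simulate_cohort(sim)
            mio.write_cohort(cohort, workdir)
            return cohort
        run_stage("simulate", do_simulate)
    else:
        status["simulate"] = "skipped"

    thresholds = config.thresholds()

    # 2. aneuploidy -------------------------------------------------------
    def do_aneuploidy():
        profiles = mio.read_arm_counts(workdir / "arms.tsv")
        hbd = [p for p in profiles if p.sample_id.startswith("HBD")]
        pts = [p for p in profiles if not p.sample_id.startswith("HBD")]
        scorer = AneuploidyScorer(
            threshold=config.aneuploidy_threshold,
            min_mapped_reads=config.min_mapped_reads,
        ).fit(hbd)
        table = scorer.score_samples(pts)
        table.insert(0, "sample_id", table.index)
        mio.write_with_provenance(table, workdir / "aneuploidy.tsv", "\t", thresholds)
        return {"scorer": scorer, "table": table.set_index("sample_id")}

    aneu = run_stage("aneuploidy", do_aneuploidy)

    # 3 + 4. methylation --------------------------------------------------
    def do_selection():
        if aneu is None:
            raise FileNotFoundError("no aneuploidy results")
        return select_high_ctdna(
            aneu["table"]["score"], min_score=config.aneuploidy_threshold
        )

    high_ctdna = run_stage("select_high_ctdna", do_selection)

    def do_dmr():
        matrix = mio.read_methylation(
            workdir / "regions.bed", workdir / "methylation_counts.tsv",
            workdir / "groups.csv",
        )
        if high_ctdna is None:
            raise FileNotFoundError("no high-ctDNA selection")
        matrix = filter_regions(matrix, completeness=config.completeness)
        norm = normalize_counts(matrix.counts)
        hbd_ids = matrix.hbd_ids
        finder = DMRFinder(fdr=config.fdr).fit(
            norm[hbd_ids + list(high_ctdna)].T,
            [HBD] * len(hbd_ids) + ["patient"] * len(high_ctdna),
        )
        dmr_stats = finder.stats_.loc[finder.dmrs_]
        out = dmr_stats.reset_index(names="region_id")
        mio.write_with_provenance(out, workdir / "dmrs.tsv", "\t", thresholds)
        return {"matrix": matrix, "normalized": norm, "dmrs": finder.dmrs_,
                "stats": finder.stats_}

    dmr = run_stage("dmr_discovery", do_dmr)

    def do_meth_scores():
        if dmr is None:
            raise FileNotFoundError("no DMR stage output")
        matrix, norm = dmr["matrix"], dmr["normalized"]
        hbd_ids = matrix.hbd_ids
        scorer = MethylationScorer().fit(norm[hbd_ids].T)
        scores = scorer.score_samples(norm.T, dmr_regions=dmr["dmrs"])
        hbd_scores = scores.loc[hbd_ids, "dmr_score"]  # leave-one-out
        cutoff = hbd_cutoff(hbd_scores, mode=config.cutoff_mode)
        scores["altered"] = [call_altered(s, cutoff) for s in scores["dmr_score"]]
        scores["qc_pass"] = True
        scores.insert(0, "sample_id", scores.index)
        mio.write_with_provenance(
            scores, workdir / "methylation_scores.tsv", "\t",
            thresholds | {"dmr_cutoff": cutoff},
        )
        coords, evr = pca_top_variable(norm, fraction=config.pca_fraction)
        coords.insert(0, "sample_id", coords.index)
        mio.write_with_provenance(coords, workdir / "pca.tsv", "\t", thresholds)
        return {"scores": scores.set_index("sample_id"), "cutoff": cutoff,
                "pca": coords, "explained_variance": evr}

    meth = run_stage("methylation_scores", do_meth_scores)

    # 5. VAF --------------------------------------------------------------
    def do_vaf():
        assays = mio.read_ddpcr(workdir / "ddpcr.csv")
        estimates = [estimate_vaf(a, min_droplets=config.min_droplets) for a in assays]
        by_sample: dict[str, list] = {}
        for e in estimates:
            by_sample.setdefault(e.sample_id, []).append(e)
        dominant = {sid: dominant_vaf(es) for sid, es in by_sample.items()}
        rows = [
            {
                "sample_id": e.sample_id, "assay": e.assay_name,
                "lambda_mut": e.lambda_mut, "lambda_wt": e.lambda_wt,
                "vaf": e.vaf, "detected": e.detected,
                "dominant": dominant[e.sample_id] is e,
            }
            for e in estimates
        ]
        table = pd.DataFrame(rows)
        mio.write_with_provenance(table, workdir / "vaf.tsv", "\t", thresholds)
        return {"table": table, "dominant": dominant}

    vaf = run_stage("vaf", do_vaf)

    # 6. CTC --------------------------------------------------------------
    def do_ctc():
        patients = mio.read_cohort_table(workdir / "cohort.csv")
        measurements = mio.ctc_measurements_from_cohort(patients)
        summary = detection_summary(measurements, config.ctc_positivity)
        mio.write_with_provenance(summary, workdir / "ctc_summary.tsv", "\t", thresholds)
        by_patient = {}
        for m in measurements:
            by_patient.setdefault(m.sample_id, {})[m.platform] = m
        recs = []
        for pid, ms in by_patient.items():
            pb, dla = ms.get("PB_CellSearch"), ms.get("DLA_CellSearch")
            if pb is None or dla is None or pb.count == 0:
                continue  # recovery computed in CTC-positive patients only
            r = recovery_from_measurements(pb, dla)
            recs.append({"patient_id": pid,
                         "expected_total": r.expected_total_in_product,
                         "measured_total": r.measured_total_in_product,
                         "recovery_pct": r.recovery_pct})
        rec_table = pd.DataFrame(recs)
        mio.write_with_provenance(rec_table, workdir / "recovery.tsv", "\t", thresholds)
        return {"patients": patients, "summary": summary, "recovery": rec_table}

    ctc = run_stage("ctc", do_ctc)

    # 7. report -----------------------------------------------------------
    def do_report():
        if ctc is None or vaf is None or aneu is None:
            raise FileNotFoundError("report needs CTC, VAF and aneuploidy stages")
        table = ctc["patients"].copy()
        table["vaf"] = [
            vaf["dominant"][pid].vaf if pid in vaf["dominant"] else np.nan
            for pid in table["patient_id"]
        ]
        table["mutation_detected"] = [
            vaf["dominant"][pid].detected if pid in vaf["dominant"] else False
            for pid in table["patient_id"]
        ]
        aneu_t = aneu["table"]
        table["aneuploidy_score"] = [
            aneu_t.loc[pid, "score"] if pid in aneu_t.index else np.nan
            for pid in table["patient_id"]
        ]
        table["aneuploidy_positive"] = [
            bool(aneu_t.loc[pid, "positive"]) if pid in aneu_t.index else False
            for pid in table["patient_id"]
        ]
        if meth is not None:
            ms = meth["scores"]
            table["dmr_score"] = [
                ms.loc[pid, "dmr_score"] if pid in ms.index else np.nan
                for pid in table["patient_id"]
            ]
            table["methylation_altered"] = [
                bool(ms.loc[pid, "altered"]) if pid in ms.index else False
                for pid in table["patient_id"]
            ]
        report = cohort_report(table)
        report["tests"].to_csv(workdir / "report.tsv", sep="\t", index=False)
        payload = {
            "thresholds": thresholds,
            "tests": report["tests"].to_dict(orient="records"),
            "calls": report["calls"].astype(bool).to_dict(orient="index"),
        }
        with open(workdir / "report.json", "w") as fh:
            json.dump(payload, fh, indent=1, default=str)
        return report

    run_stage("report", do_report)
    return results
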
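"""Synthetic liquid-biopsy cohort generator.

Emulates the joint data streams of a small metastatic-melanoma liquid-biopsy
study so that every downstream stage (aneuploidy scoring, methylation
scoring, ddPCR VAF, CTC recovery, cohort statistics) is testable without
patient data:

* a panel of healthy blood donors (HBDs) providing chromosome-arm read
  counts and region methylation counts;
* patients with a latent tumor fraction (point mass at 0 plus a Beta
  component; the same fraction drives every analyte);
* arm-level copy-number gains/losses whose read-count signal scales with
  tumor fraction; a subset of truly differentially methylated regions whose
  methylation fold-change scales with tumor fraction;
* droplet counts at ~20,000 droplets per well with VAF equated to the tumor
  fraction (diploid, heterozygous clonal mutation);
* CTC counts coupled to tumor burden, with a lossy diagnostic-leukapheresis
  (DLA) recovery step and platform-specific detection efficiencies.

All distributional choices are modeling decisions bounded by realistic
cohort ranges; the ``truth`` record retains everything needed to score
parameter recovery.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .arms import AUTOSOMAL_ARMS, baseline_arm_proportions
from .aneuploidy import ArmCountProfile
from .ddpcr import DropletAssay
from .exceptions import ConfigurationError, DomainError
from .methylation import HBD, PATIENT, RegionCountMatrix


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; defaults emulate the study cohort."""

    n_patients: int = 20
    n_hbd_methylation: int = 9
    n_hbd_arms: int = 20
    n_regions: int = 5_000
    n_true_dmrs: int = 200
    arms: tuple[str, ...] = AUTOSOMAL_ARMS
    reads_per_sample: int = 500_000
    droplets_per_well: int = 20_000
    cfdna_copies_per_well: int = 10_000
    # tumor fraction: point mass at 0 (undetectable disease in blood) plus a
    # Beta component; defaults give median VAF ~3% and max ~0.56
    tf_zero_weight: float = 0.10
    tf_beta: tuple[float, float] = (0.45, 4.5)
    tf_max: float = 0.56
    cna_arm_fraction: float = 0.25
    arm_noise_sd: float = 0.02
    dmr_effect: float = 3.0
    nb_dispersion: float = 0.05
    library_size_log2_spread: float = 1.0  # library sizes vary +/- 2-fold
    # CTC and clinical couplings
    ctc_base_conc_per_ml: float = 0.05
    ctc_burden_coupling: float = 1.0  # slope of log conc vs log tumor volume
    ctc_conc_log_sd: float = 1.2
    dla_recovery_beta: tuple[float, float] = (2.9, 7.1)  # mean ~0.29
    mnc_recovery_beta: tuple[float, float] = (7.0, 3.0)  # mean ~0.70
    cs_dla_efficiency_beta: tuple[float, float] = (3.0, 17.0)  # mean 0.15
    fcm_efficiency_beta: tuple[float, float] = (19.0, 1.0)  # mean 0.95
    processed_blood_range_L: tuple[float, float] = (2.4, 6.8)
    product_volume_range_mL: tuple[float, float] = (46.0, 121.0)
    aliquot_volume_mL: float = 1.5
    mnc_per_L_blood: float = 2.5e9
    # tumor volume given tumor fraction, and LDH given volume
    volume_base_cm3: float = 25.0
    volume_tf_coupling: float = 4.5  # on sqrt(tf) scale
    volume_log_sd: float = 0.7
    volume_range_cm3: tuple[float, float] = (2.0, 736.0)
    ldh_baseline: float = 164.0
    ldh_slope_per_cm3: float = 0.8
    ldh_noise_sd: float = 30.0
    ldh_max: float = 1074.0
    lesion_rate_per_cm3: float = 1 / 40
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_patients, self.n_hbd_methylation, self.n_hbd_arms,
            self.n_regions, self.n_true_dmrs, self.reads_per_sample,
            self.droplets_per_well,
        )
        if any(c <= 0 for c in counts):
            raise ConfigurationError("all counts must be positive")
        if self.n_true_dmrs > self.n_regions:
            raise ConfigurationError("n_true_dmrs cannot exceed n_regions")
        if not 0 <= self.tf_zero_weight <= 1 or not 0 < self.tf_max < 1:
            raise ConfigurationError("tumor-fraction mixture parameters invalid")
        for pair in (self.tf_beta, self.dla_recovery_beta, self.mnc_recovery_beta,
                     self.cs_dla_efficiency_beta, self.fcm_efficiency_beta):
            if pair[0] <= 0 or pair[1] < 0:
                raise ConfigurationError("Beta parameters must be positive")
        if self.nb_dispersion < 0 or self.arm_noise_sd < 0:
            raise ConfigurationError("dispersions must be nonnegative")


@dataclass
class SyntheticCohort:
    """The full generated dataset plus the ground truth used by tests."""

    config: SimulationConfig
    hbd_arm_profiles: list[ArmCountProfile]
    patient_arm_profiles: list[ArmCountProfile]
    methylation: RegionCountMatrix
    ddpcr: list[DropletAssay]
    patients: pd.DataFrame
    truth: dict


# -- arm counts ----------------------------------------------------------


def _deterministic_counts(total: int, props: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` reads over ``props``."""
    raw = props * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(raw - counts)[::-1]
    counts[order[:short]] += 1
    return counts


def _draw_arm_profile(
    sample_id: str,
    props: np.ndarray,
    reads: int,
    arms: tuple[str, ...],
    rng: np.random.Generator,
    noise_sd: float,
) -> ArmCountProfile:
    if noise_sd > 0:
        props = props * np.exp(rng.normal(0, noise_sd, size=len(props)))
        props = props / props.sum()
        counts = rng.multinomial(reads, props)
    else:
        counts = _deterministic_counts(reads, props)
    return ArmCountProfile(
        sample_id=sample_id,
        counts={a: int(c) for a, c in zip(arms, counts)},
        total_mapped_reads=int(reads),
    )


def simulate_hbd_arm_panel(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[ArmCountProfile]:
    """HBD arm-count panel: multinomial reads around the length-proportional
    baseline arm fractions, with small lognormal donor-to-donor noise."""
    rng = rng or np.random.default_rng(config.seed)
    baseline = baseline_arm_proportions(config.arms)
    return [
        _draw_arm_profile(
            f"HBD_arm_{i + 1:02d}", baseline, config.reads_per_sample,
            config.arms, rng, config.arm_noise_sd,
        )
        for i in range(config.n_hbd_arms)
    ]


def simulate_patient_arm_profile(
    tumor_fraction: float,
    cna_spec: dict[str, int],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    sample_id: str = "patient",
) -> ArmCountProfile:
    """Patient arm counts: arm proportion proportional to
    baseline * ((1 - tf) + tf * c/2), renormalized, then multinomial."""
    if not 0 <= tumor_fraction < 1:
        raise DomainError("tumor_fraction must be in [0, 1)")
    if any(c not in (0, 1, 2, 3, 4) for c in cna_spec.values()):
        raise DomainError("copy numbers must be in {0,1,2,3,4}")
    rng = rng or np.random.default_rng(config.seed)
    baseline = baseline_arm_proportions(config.arms)
    copy = np.array([cna_spec.get(a, 2) for a in config.arms], dtype=float)
    props = baseline * ((1 - tumor_fraction) + tumor_fraction * copy / 2)
    props = props / props.sum()
    return _draw_arm_profile(
        sample_id, props, config.reads_per_sample, config.arms, rng,
        config.arm_noise_sd,
    )


def draw_cna_spec(config: SimulationConfig, rng: np.random.Generator) -> dict[str, int]:
    """Random copy-number spec: a fixed fraction of arms gain or lose."""
    n_alter = max(1, round(config.cna_arm_fraction * len(config.arms)))
    altered = rng.choice(len(config.arms), size=n_alter, replace=False)
    states = rng.choice([0, 1, 3, 4], size=n_alter)
    return {config.arms[i]: int(c) for i, c in zip(altered, states)}


# -- methylation ---------------------------------------------------------


def _nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_methylation(
    config: SimulationConfig,
    patient_tfs: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[RegionCountMatrix, list[str]]:
    """Region x sample methylation counts for HBDs + patients.

    Region counts are negative-binomial around region-specific means; for
    patients, the means of the true DMR regions are scaled by
    (1 - tf) + tf * dmr_effect (tumor-derived hypermethylation mixing into
    the cfDNA pool).  Library sizes vary +/- 2-fold.  Returns the matrix and
    the true DMR region ids.
    """
    rng = rng or np.random.default_rng(config.seed)
    patient_tfs = np.asarray(patient_tfs, float)
    region_ids = [f"region_{i + 1:05d}" for i in range(config.n_regions)]
    weights = rng.gamma(2.0, 1.0, size=config.n_regions)
    weights /= weights.sum()
    dmr_idx = rng.choice(config.n_regions, size=config.n_true_dmrs, replace=False)
    true_dmrs = [region_ids[i] for i in sorted(dmr_idx)]

    samples, columns, groups = [], [], {}
    for i in range(config.n_hbd_methylation):
        sid = f"HBD_{i + 1:02d}"
        lib = config.reads_per_sample * 2 ** rng.uniform(
            -config.library_size_log2_spread, config.library_size_log2_spread
        )
        columns.append(_nb_counts(lib * weights, config.nb_dispersion, rng))
        samples.append(sid)
        groups[sid] = HBD
    for j, tf in enumerate(patient_tfs):
        sid = f"patient_{j + 1:02d}"
        lib = config.reads_per_sample * 2 ** rng.uniform(
            -config.library_size_log2_spread, config.library_size_log2_spread
        )
        mean = lib * weights.copy()
        mean[dmr_idx] *= (1 - tf) + tf * config.dmr_effect
        columns.append(_nb_counts(mean, config.nb_dispersion, rng))
        samples.append(sid)
        groups[sid] = PATIENT

    counts = pd.DataFrame(
        np.column_stack(columns),
        index=pd.Index(region_ids, name="region_id"),
        columns=samples,
    )
    # synthetic coordinates: non-overlapping 1 kb windows tiled over 1-22
    chroms = (np.arange(config.n_regions) % 22) + 1
    starts = (np.arange(config.n_regions) // 22) * 1000
    regions = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": starts + 1000},
        index=pd.Index(region_ids, name="region_id"),
    )
    return RegionCountMatrix(regions=regions, counts=counts, groups=groups), true_dmrs


# -- ddPCR ---------------------------------------------------------------


def simulate_ddpcr(
    tumor_fraction: float,
    total_cfdna_copies: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    sample_id: str = "patient",
    assay_name: str = "BRAF p.V600E",
) -> DropletAssay:
    """Droplet counts for a uniplex assay with VAF equal to the tumor
    fraction: per channel, positives ~ Binomial(droplets, 1 - exp(-lambda))."""
    if total_cfdna_copies < 0:
        raise DomainError("cfDNA copies must be nonnegative")
    rng = rng or np.random.default_rng(config.seed)
    d = config.droplets_per_well
    lam_mut = tumor_fraction * total_cfdna_copies / d
    lam_wt = (1 - tumor_fraction) * total_cfdna_copies / d
    return DropletAssay(
        sample_id=sample_id,
        assay_name=assay_name,
        mutant_positive=int(rng.binomial(d, 1 - np.exp(-lam_mut))),
        wildtype_positive=int(rng.binomial(d, 1 - np.exp(-lam_wt))),
        total_droplets=d,
    )


# -- CTCs and clinical covariates ---------------------------------------


def _beta_draw(rng: np.random.Generator, a: float, b: float) -> float:
    """Beta(a, b) draw; b = 0 is the degenerate lossless case (exactly 1)."""
    return 1.0 if b == 0 else float(rng.beta(a, b))


def simulate_ctc_and_clinical(
    tumor_volume: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict:
    """CTC counts on three platforms plus clinical covariates for one patient.

    CTC concentration is lognormal with mean increasing in tumor volume.
    The peripheral-blood CellSearch count is Poisson over 7.5 mL; the DLA
    product receives Binomial(expected cells, recovery~Beta) cells, of which
    CellSearch counts an aliquot (with its own efficiency) and flow
    cytometry counts the whole product at high efficiency.  LDH rises
    linearly with tumor volume above a healthy baseline.
    """
    if tumor_volume < 0:
        raise DomainError("tumor_volume must be nonnegative")
    rng = rng or np.random.default_rng(config.seed)
    cfg = config
    log_conc = (
        np.log(cfg.ctc_base_conc_per_ml)
        + cfg.ctc_burden_coupling * (np.log1p(tumor_volume) - np.log1p(100.0))
        + rng.normal(0, cfg.ctc_conc_log_sd)
    )
    conc = float(np.exp(log_conc)) if tumor_volume > 0 else 0.0

    pb_count = int(rng.poisson(conc * 7.5))
    processed_L = float(rng.uniform(*cfg.processed_blood_range_L))
    product_mL = float(rng.uniform(*cfg.product_volume_range_mL))
    expected_in_product = conc * processed_L * 1000.0

    dla_recovery = _beta_draw(rng, *cfg.dla_recovery_beta)
    cells_in_product = int(rng.binomial(int(round(expected_in_product)), dla_recovery))
    cs_eff = _beta_draw(rng, *cfg.cs_dla_efficiency_beta)
    aliquot_frac = min(1.0, cfg.aliquot_volume_mL / product_mL)
    dla_cs_count = int(rng.binomial(cells_in_product, aliquot_frac * cs_eff))
    fcm_eff = _beta_draw(rng, *cfg.fcm_efficiency_beta)
    fcm_count = int(rng.binomial(cells_in_product, fcm_eff))

    mnc_expected = cfg.mnc_per_L_blood * processed_L
    mnc_recovery = _beta_draw(rng, *cfg.mnc_recovery_beta)
    mnc_measured = float(mnc_expected * mnc_recovery)

    ldh = float(np.clip(
        cfg.ldh_baseline + cfg.ldh_slope_per_cm3 * tumor_volume
        + abs(rng.normal(0, cfg.ldh_noise_sd)),
        cfg.ldh_baseline, cfg.ldh_max,
    ))
    lesion_count = int(1 + rng.poisson(cfg.lesion_rate_per_cm3 * tumor_volume)) if tumor_volume > 0 else 0

    return {
        "ctc_conc_per_ml": conc,
        "ctc_pb_cellsearch": pb_count,
        "ctc_dla_cellsearch": dla_cs_count,
        "ctc_dla_fcm": fcm_count,
        "cells_in_product": cells_in_product,
        "processed_blood_L": processed_L,
        "product_volume_mL": product_mL,
        "aliquot_volume_mL": cfg.aliquot_volume_mL,
        "mnc_expected": mnc_expected,
        "mnc_measured": mnc_measured,
        "ldh": ldh,
        "tumor_volume_cm3": tumor_volume,
        "lesion_count": lesion_count,
    }


# -- the whole cohort ----------------------------------------------------


def draw_tumor_fractions(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Point mass at 0 plus a Beta component truncated at ``tf_max``."""
    tfs = np.zeros(config.n_patients)
    active = rng.random(config.n_patients) >= config.tf_zero_weight
    n_active = int(active.sum())
    draws = rng.beta(*config.tf_beta, size=n_active)
    for i in range(n_active):  # resample the rare draws above the cap
        while draws[i] > config.tf_max:
            draws[i] = rng.beta(*config.tf_beta)
    tfs[active] = draws
    return tfs


_SUBTYPES = ("BRAF p.V600E/K", "NRAS", "other")
_SUBTYPE_PROBS = (0.65, 0.20, 0.15)


def simulate_cohort(
    config: SimulationConfig | None = None,
    tumor_fractions=None,
) -> SyntheticCohort:
    """Generate the full synthetic cohort from one seeded RNG stream.

    ``tumor_fractions`` overrides the mixture draw with explicit per-patient
    values (e.g. a grid for calibration studies); its length must equal
    ``config.n_patients``.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)

    hbd_arms = simulate_hbd_arm_panel(config, rng)
    if tumor_fractions is not None:
        tfs = np.asarray(tumor_fractions, float)
        if len(tfs) != config.n_patients:
            raise ConfigurationError("tumor_fractions length must equal n_patients")
        if ((tfs < 0) | (tfs >= 1)).any():
            raise DomainError("tumor fractions must be in [0, 1)")
    else:
        tfs = draw_tumor_fractions(config, rng)
    subtypes = rng.choice(len(_SUBTYPES), size=config.n_patients, p=_SUBTYPE_PROBS)

    patient_arms, assays, records, truth_patients = [], [], [], {}
    for j, tf in enumerate(tfs):
        pid = f"patient_{j + 1:02d}"
        cna = draw_cna_spec(config, rng) if tf > 0 else {}
        patient_arms.append(
            simulate_patient_arm_profile(tf, cna, config, rng, sample_id=pid)
        )
        assays.append(
            simulate_ddpcr(
                tf, config.cfdna_copies_per_well, config, rng,
                sample_id=pid, assay_name=_SUBTYPES[subtypes[j]],
            )
        )
        volume = float(np.clip(
            config.volume_base_cm3
            * np.exp(config.volume_tf_coupling * np.sqrt(tf)
                     + rng.normal(0, config.volume_log_sd)),
            *config.volume_range_cm3,
        ))
        rec = simulate_ctc_and_clinical(volume, config, rng)
        rec.update(patient_id=pid, true_tumor_fraction=float(tf),
                   mutation_subtype=_SUBTYPES[subtypes[j]])
        records.append(rec)
        truth_patients[pid] = {"tumor_fraction": float(tf), "cna": cna}

    methylation, true_dmrs = simulate_methylation(config, tfs, rng)
    # rename methylation patient columns to the cohort patient ids (same order)
    patients = pd.DataFrame(records).set_index("patient_id", drop=False)
    truth = {"patients": truth_patients, "true_dmrs": true_dmrs,
             "config": asdict(config) | {"arms": list(config.arms)}}
    return SyntheticCohort(
        config=config,
        hbd_arm_profiles=hbd_arms,
        patient_arm_profiles=patient_arms,
        methylation=methylation,
        ddpcr=assays,
        patients=patients,
        truth=truth,
    )
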
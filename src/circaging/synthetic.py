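"""Synthetic inputs with planted ground truth for every pipeline stage.

Four generators mirror the study designs the pipeline consumes:

* pooled young/old x {RNase-R-treated, mock} junction count libraries
  with planted age-class memberships and shared-class fold changes;
* a population cohort (default n=306, covariates drawn to match the
  published demographic ranges) with planted expression-phenotype
  effects;
* early/late-passage qPCR plates for four primary cell types
  (3 biological x 3 technical replicates) with planted Ct shifts;
* a six-strain mouse panel (spleen and muscle, young and old animals)
  with planted lifespan slopes on the normalized-expression scale.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` child streams, one child per independent
sub-stage, so identical configs are byte-identical and stage-level
reruns are reproducible.

Counts use a negative-binomial (gamma-Poisson) model parameterized by
mean and dispersion ``k`` (variance = mean + mean^2/k), since pooled
junction counts are over-dispersed.  RNase R treatment is modeled as two
multiplicative factors: a circRNA enrichment factor (>= 1) on BSJ counts
and a linear-RNA retention fraction (<= 1) on canonical counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import phenotype as pheno
from .associate import MOUSE_REFERENCE_ASSAYS

__all__ = [
    "ConfigError",
    "PoolSimConfig",
    "CohortSimConfig",
    "GroundTruth",
    "POOL_LIBRARIES",
    "DEFAULT_STRAIN_LIFESPANS",
    "simulate_pool_counts",
    "simulate_cohort",
    "simulate_senescence_qpcr",
    "simulate_mouse_panel",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


POOL_LIBRARIES = ("young_treated", "young_mock", "old_treated", "old_mock")
TREATED_LIBRARIES = {"young": "young_treated", "old": "old_treated"}

#: Six distinct placeholder median strain lifespans (months).  The source
#: strain survival medians are not bundled; override with real values.
DEFAULT_STRAIN_LIFESPANS: dict[str, float] = {
    "A/J": 20.7,
    "NOD.B10Sn-H2b/J": 25.1,
    "PWD/PhJ": 26.0,
    "129S1/SvImJ": 28.2,
    "C57BL/6J": 30.1,
    "WSB/EiJ": 35.9,
}

CELL_TYPES = ("astrocytes", "cardiomyocytes", "endothelial_cells", "fibroblasts")


@dataclass(frozen=True)
class PoolSimConfig:
    """Configuration of the pooled-library count simulation."""

    n_circ_total: int = 2207
    n_shared: int = 184
    n_young_only: int = 431
    n_old_only: int = 1592
    mean_bsj_reads: float = 100.0
    dispersion: float = 10.0
    canonical_mean: float = 500.0
    rnase_r_linear_retention: float = 0.05
    rnase_r_circ_enrichment: float = 5.0
    shared_log2fc_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_shared, self.n_young_only, self.n_old_only)
        if any(c < 0 for c in counts) or self.n_circ_total < 0:
            raise ConfigError("class counts must be non-negative")
        if sum(counts) != self.n_circ_total:
            raise ConfigError(
                "n_shared + n_young_only + n_old_only must equal n_circ_total "
                f"({sum(counts)} != {self.n_circ_total})"
            )
        if self.mean_bsj_reads <= 0 or self.dispersion <= 0 or self.canonical_mean <= 0:
            raise ConfigError("mean/dispersion parameters must be positive")
        if not 0 <= self.rnase_r_linear_retention <= 1:
            raise ConfigError("rnase_r_linear_retention must lie in [0, 1]")
        if self.rnase_r_circ_enrichment < 1:
            raise ConfigError("rnase_r_circ_enrichment must be >= 1")


@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration of the cohort simulation.

    ``planted_effects`` maps circ_id -> (outcome, coefficient) where the
    outcome is one of 'age', 'PLS', 'grip_cross_sectional',
    'grip_longitudinal'.  Effects are planted with expression as the
    response: expression = 1 + confounder loadings + coeff * outcome + noise.
    """

    n_participants: int = 306
    planted_effects: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    confounder_loadings: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    noise_sd: float = 0.25
    premature_fraction: float = 0.05
    parent_missing_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        n_params = 2 + len(pheno.WBC_COLUMNS) + 6  # exposure/const + covariates
        if self.n_participants <= 2 * n_params:
            raise ConfigError(
                f"n_participants={self.n_participants} too small for the covariate set"
            )
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if not 0 < self.premature_fraction < 1:
            raise ConfigError("premature_fraction must lie in (0, 1)")
        for circ, (outcome, coeff) in self.planted_effects.items():
            if not np.isfinite(coeff):
                raise ConfigError(f"non-finite planted coefficient for {circ}")
            if outcome not in ("age", "PLS", "grip_cross_sectional", "grip_longitudinal"):
                raise ConfigError(f"unknown planted outcome {outcome!r} for {circ}")


@dataclass
class GroundTruth:
    """Planted truth keyed by the simulated entity identifiers."""

    class_of: dict[str, str] = field(default_factory=dict)
    planted_fc: dict[str, float] = field(default_factory=dict)
    planted_effects: dict[str, tuple[str, float]] = field(default_factory=dict)
    planted_senescence_shift: dict[tuple[str, str], float] = field(default_factory=dict)
    planted_lifespan_slope: dict[tuple[str, str, str], float] = field(default_factory=dict)


def _nbinom(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draws with the mean/dispersion parameterization.

    Zero mean gives exactly zero counts (gamma scale 0 is degenerate).
    """
    mean = np.asarray(mean, dtype=float)
    lam = rng.gamma(shape=dispersion, scale=np.where(mean > 0, mean / dispersion, 0.0))
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# pooled libraries


def simulate_pool_counts(config: PoolSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the four pooled libraries (young/old x treated/mock).

    Returns a junction count table (one row per circRNA per library; all
    circRNAs appear in every library, with zero planted mean outside
    their class's pools) and the ground truth with class memberships and
    shared-class log2 fold changes (old over young).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_layout, rng_fc, *rng_libs = [
        np.random.default_rng(child) for child in ss.spawn(2 + len(POOL_LIBRARIES))
    ]
    n = config.n_circ_total
    width = max(4, len(str(max(n, 1))))
    circ_ids = np.array([f"circ{i:0{width}d}" for i in range(n)])
    classes = np.array(
        ["shared"] * config.n_shared
        + ["young_only"] * config.n_young_only
        + ["old_only"] * config.n_old_only
    )
    perm = rng_layout.permutation(n)
    classes = classes[perm]

    hosts = np.array([f"GENE{i:0{width}d}" for i in range(n)])
    chroms = rng_layout.choice([f"chr{c}" for c in range(1, 23)], size=n)
    starts = rng_layout.integers(1_000, 5_000_000, size=n)
    lengths = rng_layout.integers(200, 20_000, size=n)
    ends = starts + lengths

    log2_fc = rng_fc.normal(0.0, config.shared_log2fc_sd, size=n)
    truth = GroundTruth()
    for i in range(n):
        truth.class_of[circ_ids[i]] = classes[i]
        if classes[i] == "shared":
            truth.planted_fc[circ_ids[i]] = float(log2_fc[i])

    base = config.mean_bsj_reads
    pool_mean = {
        "young": np.where(
            classes == "old_only",
            0.0,
            np.where(classes == "shared", base * np.exp2(-log2_fc / 2), base),
        ),
        "old": np.where(
            classes == "young_only",
            0.0,
            np.where(classes == "shared", base * np.exp2(log2_fc / 2), base),
        ),
    }

    frames = []
    for lib, rng in zip(POOL_LIBRARIES, rng_libs):
        pool, treatment = lib.split("_")
        bsj_mean = pool_mean[pool]
        canon_mean = np.full(n, config.canonical_mean)
        if treatment == "treated":
            bsj_mean = bsj_mean * config.rnase_r_circ_enrichment
            canon_mean = canon_mean * config.rnase_r_linear_retention
        frames.append(
            pd.DataFrame(
                {
                    "circ_id": circ_ids,
                    "host_gene": hosts,
                    "chrom": chroms,
                    "junction_start": starts,
                    "junction_end": ends,
                    "library_id": lib,
                    "bsj_reads": _nbinom(rng, bsj_mean, config.dispersion),
                    "canonical_reads": _nbinom(rng, canon_mean, config.dispersion),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return table, truth


# ---------------------------------------------------------------------------
# cohort

# Demographic sampling targets (bracket weights and moment parameters)
# follow the published cohort description.
AGE_BRACKETS = [(30, 40, 24), (40, 50, 37), (50, 60, 31), (60, 70, 32), (70, 80, 116), (80, 90, 63), (90, 94, 3)]
EDUCATION_WEIGHTS = [22, 124, 56, 50, 34, 20]
SMOKING_WEIGHTS = [164, 79, 43, 20]
FEMALE_FRACTION = 163 / 306
BAGNO_FRACTION = 160 / 306
WBC_PARAMS = {
    "neutrophil_pct": (56.59, 8.35, 34.2, 81.2),
    "lymphocyte_pct": (31.69, 7.67, 9.8, 51.2),
    "monocyte_pct": (8.04, 2.20, 3.9, 21.3),
    "eosinophil_pct": (3.18, 2.17, 0.0, 21.5),
}


def _truncated_normal(rng, mean, sd, lo, hi, size):
    vals = rng.normal(mean, sd, size=size)
    return np.clip(vals, lo, hi)


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate cohort records and a planted expression matrix.

    Returns ``(records, expression, truth)``: the cohort table (one row
    per participant), an expression matrix (participants x circRNAs,
    one column per planted effect) and the ground truth.  Participants
    without a defined value for a planted outcome (e.g. no PLS)
    contribute no outcome term to that circRNA's expression; they fall
    out of the corresponding model by listwise deletion anyway.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_cov, rng_parent, rng_grip, rng_expr = [
        np.random.default_rng(child) for child in ss.spawn(4)
    ]
    n = config.n_participants

    bracket_weights = np.array([w for _, _, w in AGE_BRACKETS], dtype=float)
    bracket_idx = rng_cov.choice(len(AGE_BRACKETS), size=n, p=bracket_weights / bracket_weights.sum())
    lo = np.array([AGE_BRACKETS[i][0] for i in bracket_idx], dtype=float)
    hi = np.array([AGE_BRACKETS[i][1] for i in bracket_idx], dtype=float)
    age = np.clip(lo + rng_cov.uniform(0, 1, size=n) * (hi - lo), 30.0, 94.0)

    records = pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "age": np.round(age, 1),
            "sex": np.where(rng_cov.uniform(size=n) < FEMALE_FRACTION, "female", "male"),
            "bmi": np.round(_truncated_normal(rng_cov, 27.15, 4.35, 15.0, 43.0, n), 2),
            "education": rng_cov.choice(
                pheno.EDUCATION_LEVELS,
                size=n,
                p=np.array(EDUCATION_WEIGHTS) / sum(EDUCATION_WEIGHTS),
            ),
            "site": np.where(rng_cov.uniform(size=n) < BAGNO_FRACTION, "Bagno", "Greve"),
            "smoking": rng_cov.choice(
                pheno.SMOKING_LEVELS,
                size=n,
                p=np.array(SMOKING_WEIGHTS) / sum(SMOKING_WEIGHTS),
            ),
        }
    )
    for col, (mean, sd, lo_, hi_) in WBC_PARAMS.items():
        records[col] = np.round(_truncated_normal(rng_cov, mean, sd, lo_, hi_, n), 1)

    # Parental death ages: sex-specific normals placed so that the
    # configured fraction falls below the premature cut-off in expectation.
    z = norm.ppf(config.premature_fraction)
    mother_sd, father_sd = 12.0, 11.0
    mother_mean = pheno.PREMATURE_MOTHER_AGE - mother_sd * z
    father_mean = pheno.PREMATURE_FATHER_AGE - father_sd * z
    mother_age = np.clip(rng_parent.normal(mother_mean, mother_sd, size=n), 20.0, 110.0)
    father_age = np.clip(rng_parent.normal(father_mean, father_sd, size=n), 20.0, 110.0)
    mother_age[rng_parent.uniform(size=n) < config.parent_missing_fraction] = np.nan
    father_age[rng_parent.uniform(size=n) < config.parent_missing_fraction] = np.nan
    records["mother_death_age"] = np.round(mother_age, 1)
    records["father_death_age"] = np.round(father_age, 1)

    is_male = (records["sex"] == "male").to_numpy()
    grip3 = 44.0 - 0.28 * age + 10.0 * is_male + rng_grip.normal(0, 6.0, size=n)
    grip4 = grip3 - 1.0 + rng_grip.normal(0, 3.0, size=n)
    records["grip_fu3"] = np.round(np.clip(grip3, 2.5, None), 2)
    records["grip_fu4"] = np.round(np.clip(grip4, 2.5, None), 2)

    pls = pheno.compute_pls(records)["pls"].to_numpy()
    outcome_values = {
        "age": age,
        "PLS": pls,
        "grip_cross_sectional": records["grip_fu3"].to_numpy(dtype=float),
        "grip_longitudinal": records["grip_fu4"].to_numpy(dtype=float),
    }
    covariates, _ = pheno.build_covariates(records, outcome="none")

    expr = {}
    truth = GroundTruth(planted_effects=dict(config.planted_effects))
    for circ in sorted(config.planted_effects):
        outcome, coeff = config.planted_effects[circ]
        values = np.full(n, 1.0)
        loadings = config.confounder_loadings.get(circ, {})
        for cov_name, loading in loadings.items():
            if cov_name not in covariates.columns:
                raise ConfigError(f"unknown confounder {cov_name!r} for {circ}")
            values = values + loading * covariates[cov_name].to_numpy(dtype=float)
        values = values + coeff * np.nan_to_num(outcome_values[outcome], nan=0.0)
        values = values + rng_expr.normal(0.0, config.noise_sd, size=n)
        expr[circ] = values
    expression = pd.DataFrame(expr, index=records["participant_id"])
    return records, expression, truth


# ---------------------------------------------------------------------------
# senescence qPCR plates


def simulate_senescence_qpcr(
    planted_shifts: Mapping[tuple[str, str], float],
    seed: int = 0,
    n_biological: int = 3,
    n_technical: int = 3,
    base_ct: float = 26.0,
    assay_offset_sd: float = 1.5,
    sample_effect_sd: float = 0.5,
    biological_sd: float = 0.15,
    technical_sd: float = 0.08,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate early/late-passage Ct plates.

    ``planted_shifts`` maps (assay_id, cell_type) -> Ct shift of the late
    group (late Ct = early Ct - shift, so a shift of -1 halves late
    expression); a NaN shift marks the assay undetected in that cell type
    (all its Cts missing).  Sample-level loading effects are shared
    across assays (removed by global-mean normalization); biological and
    technical noise are per-well.
    """
    for key, shift in planted_shifts.items():
        if shift is not None and not (np.isnan(shift) or np.isfinite(shift)):
            raise ConfigError(f"invalid shift for {key}")
    assays = sorted({a for a, _ in planted_shifts})
    cell_types = sorted({c for _, c in planted_shifts})
    if not assays:
        raise ConfigError("planted_shifts must name at least one (assay, cell type)")

    ss = np.random.SeedSequence(seed)
    rng_offsets, rng_wells = [np.random.default_rng(c) for c in ss.spawn(2)]
    assay_offset = {a: rng_offsets.normal(0.0, assay_offset_sd) for a in assays}
    cell_offset = {c: rng_offsets.normal(0.0, 0.5) for c in cell_types}

    truth = GroundTruth(planted_senescence_shift=dict(planted_shifts))
    rows = []
    for cell in cell_types:
        for passage in ("early", "late"):
            for bio in range(1, n_biological + 1):
                sample_effect = rng_wells.normal(0.0, sample_effect_sd)
                for assay in assays:
                    shift = planted_shifts.get((assay, cell))
                    detected = shift is not None and not np.isnan(shift)
                    bio_noise = rng_wells.normal(0.0, biological_sd)
                    mu = (
                        base_ct
                        + assay_offset[assay]
                        + cell_offset[cell]
                        + sample_effect
                        + bio_noise
                    )
                    if detected and passage == "late":
                        mu = mu - shift
                    for tech in range(1, n_technical + 1):
                        ct = mu + rng_wells.normal(0.0, technical_sd)
                        rows.append(
                            {
                                "assay_id": assay,
                                "cell_type": cell,
                                "passage": passage,
                                "biological_replicate": bio,
                                "technical_replicate": tech,
                                "ct": float(np.clip(ct, 1.0, 50.0)) if detected else np.nan,
                            }
                        )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# mouse panel


def simulate_mouse_panel(
    strain_lifespans: Mapping[str, float] | None = None,
    planted_slopes: Mapping[tuple[str, str, str], float] | None = None,
    seed: int = 0,
    n_animals_per_group: int = 3,
    intercept: float = 1.0,
    animal_sd: float = 0.3,
    ct_noise_sd: float = 0.25,
    technical_sd: float = 0.08,
    n_technical: int = 3,
    reference_assays: tuple[str, ...] = MOUSE_REFERENCE_ASSAYS,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the strain panel qPCR table.

    ``planted_slopes`` maps (circ_id, tissue, age_group) -> slope of
    normalized expression on median strain lifespan (months); the
    normalized expectation is ``intercept + slope * (L - mean(L))``, kept
    near 1 so the per-circRNA global-mean rescaling is bias-free.  A
    (circ, tissue) pair with no key in any age group is undetected in
    that tissue (missing Cts, reported ND downstream).
    """
    if strain_lifespans is None:
        strain_lifespans = DEFAULT_STRAIN_LIFESPANS
    if planted_slopes is None:
        planted_slopes = {}
    if len(strain_lifespans) < 2:
        raise ConfigError("need at least 2 strains")
    if len(set(strain_lifespans.values())) < 2:
        raise ConfigError("need at least 2 distinct lifespan values")
    circs = sorted({c for c, _, _ in planted_slopes})
    tissues = ("spleen", "muscle")
    detected = {(c, t) for c, t, _ in planted_slopes}
    mean_lifespan = float(np.mean(list(strain_lifespans.values())))

    ref_base = {a: 22.0 + i for i, a in enumerate(reference_assays)}
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    truth = GroundTruth(planted_lifespan_slope=dict(planted_slopes))

    rows = []
    animal_counter = 0
    for strain in sorted(strain_lifespans):
        lifespan = strain_lifespans[strain]
        for age_group in ("young", "old"):
            for _ in range(n_animals_per_group):
                animal_counter += 1
                for tissue in tissues:
                    animal_id = f"M{animal_counter:03d}_{tissue}"
                    animal_effect = rng.normal(0.0, animal_sd)
                    ref_cts = {
                        a: ref_base[a] + animal_effect + rng.normal(0.0, 0.1)
                        for a in reference_assays
                    }
                    ref_mean = float(np.mean(list(ref_cts.values())))
                    meta = {
                        "strain": strain,
                        "median_lifespan_months": lifespan,
                        "age_group": age_group,
                        "tissue": tissue,
                        "animal_id": animal_id,
                    }
                    for assay, base in ref_cts.items():
                        for tech in range(1, n_technical + 1):
                            rows.append(
                                {
                                    **meta,
                                    "assay_id": assay,
                                    "technical_replicate": tech,
                                    "ct": base + rng.normal(0.0, technical_sd),
                                }
                            )
                    for circ in circs:
                        if (circ, tissue) not in detected:
                            target_ct = np.nan
                        else:
                            slope = planted_slopes.get((circ, tissue, age_group), 0.0)
                            target = intercept + slope * (lifespan - mean_lifespan)
                            target = max(target, 0.05)
                            target_ct = (
                                ref_mean
                                - np.log2(target)
                                + rng.normal(0.0, ct_noise_sd)
                            )
                        for tech in range(1, n_technical + 1):
                            ct = (
                                target_ct + rng.normal(0.0, technical_sd)
                                if np.isfinite(target_ct)
                                else np.nan
                            )
                            rows.append(
                                {
                                    **meta,
                                    "assay_id": circ,
                                    "technical_replicate": tech,
                                    "ct": ct,
                                }
                            )
    return pd.DataFrame(rows), truth
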
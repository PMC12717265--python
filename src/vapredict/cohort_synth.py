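"""Synthetic cohorts with the statistical structure the methods assume.

The generator emulates the eligibility window of a healthy adult refraction
study: ages uniform on 30-65 years, spherical equivalent (SE) normal with
mean -1.0 D and sd 2.0 D clipped to [-7.00, +4.00] D, accommodation
amplitude declining linearly with age (Hofstetter-like mean
``max(0, 18.5 - 0.3 age)`` D with 1.0 D jitter, truncated at zero), a
small negative cylinder, defocus c_2^0 derived from SE, second-order
astigmatism split from the cylinder at a random axis, and small
higher-order coefficients (sd 0.03 um).

Ground-truth acuity per optical condition comes from a declared blur rule:
the condition's total defocus is reduced by accommodation when (and only
when) it is negative, and logMAR rises linearly with the residual blur plus
an age penalty beyond 50 years, with 0.02 logMAR measurement noise. A
simulated observer turns that latent acuity into per-letter responses via
a logistic psychometric function with a 10% guess floor. All generative
constants are fixture parameters declared here, not population estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boost_regression import DEFOCUS_LEVELS, defocus_column
from .wavefront_optics import N_COEFFS, diopter_to_z20

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "va_ground_truth",
    "simulated_observer",
    "end_to_end_fixture",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-cohort generator (all units clinical)."""

    n_subjects: int = 135
    seed: int = 0
    missing_va: int = 11          # VA cells blanked to exercise row dropping
    pupil_radius_mm: float = 1.5
    aa_intercept: float = 18.5    # D, Hofstetter-like mean AA at age 0
    aa_slope: float = 0.3         # D/year decline
    aa_jitter_sd: float = 1.0     # D
    se_mean: float = -1.0         # D
    se_sd: float = 2.0            # D
    se_range: tuple = (-7.0, 4.0)
    cyl_sd: float = 0.75          # D (cylinder = -|N(0, cyl_sd^2)|)
    hoa_sd: float = 0.03          # um, higher-order coefficient scale
    blur_slope: float = 0.18      # logMAR per diopter of residual blur
    cyl_weight: float = 0.5       # weight of residual cylinder in the blur rule
    age_penalty: float = 0.004    # logMAR per year beyond 50
    va_floor: float = -0.1        # best achievable mean logMAR
    va_noise_sd: float = 0.02     # logMAR measurement noise
    psychometric_slope: float = 0.05  # logMAR
    guess_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def va_ground_truth(se: float, cylinder: float, aa: float, age: float,
                    delta_d: float, condition: str, cfg: GeneratorConfig,
                    rng: np.random.Generator | None = None) -> float:
    """Latent logMAR acuity of an eye under one optical condition.

    The defocus experienced is ``delta_total = SE + delta_d`` for the
    uncorrected baseline (delta_d = 0) and ``delta_total = delta_d`` once
    corrected (SE removed); negative defocus is partially rescued by
    accommodation: residual = delta_total + min(aa, -delta_total). The
    cylinder contributes only in the uncorrected state.
    """
    if condition == "uncorrected":
        delta_total = se + delta_d
        cyl_res = cylinder
    else:  # corrected baseline, with or without trial-lens defocus
        delta_total = delta_d
        cyl_res = 0.0
    if delta_total < 0:
        residual = delta_total + min(aa, -delta_total)
    else:
        residual = delta_total
    va = (cfg.va_floor
          + cfg.blur_slope * (abs(residual) + cfg.cyl_weight * abs(cyl_res))
          + cfg.age_penalty * max(0.0, age - 50.0))
    va = float(np.clip(va, -0.3, 1.1))
    if rng is not None:
        va += float(rng.normal(0.0, cfg.va_noise_sd))
    return va


def generate_cohort(cfg: GeneratorConfig | None = None) -> pd.DataFrame:
    """Generate an eye-level cohort table in the pipeline's CSV schema.

    One row per eye (two per subject); the right eye of each subject is
    flagged dominant and carries the nine-level defocus curve. VA columns
    are the latent-acuity rule plus measurement noise, with
    ``cfg.missing_va`` cells blanked uniformly at random (seeded) to
    exercise the missing-data path downstream.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for s in range(cfg.n_subjects):
        age = float(rng.uniform(30.0, 65.0))
        dominant_eye = "OD"
        for eye in ("OD", "OS"):
            aa = max(0.0, cfg.aa_intercept - cfg.aa_slope * age
                     + float(rng.normal(0.0, cfg.aa_jitter_sd)))
            se = float(np.clip(rng.normal(cfg.se_mean, cfg.se_sd), *cfg.se_range))
            cyl = -abs(float(rng.normal(0.0, cfg.cyl_sd)))
            sphere = se - cyl / 2.0
            axis = float(rng.uniform(0.0, math.pi))
            z = np.zeros(N_COEFFS)
            z[4] = diopter_to_z20(se, cfg.pupil_radius_mm)
            astig_mag = cyl * cfg.pupil_radius_mm ** 2 / (4.0 * math.sqrt(6.0))
            z[3] = astig_mag * math.sin(2.0 * axis)
            z[5] = astig_mag * math.cos(2.0 * axis)
            z[6:] = rng.normal(0.0, cfg.hoa_sd, size=N_COEFFS - 6)
            dominant = int(eye == dominant_eye)
            row = {
                "subject_id": f"S{s:04d}", "eye": eye, "dominant": dominant,
                "age": age, "aa_d": aa, "sphere_d": sphere, "cylinder_d": cyl,
                "va_uncorrected_logmar": va_ground_truth(
                    se, cyl, aa, age, 0.0, "uncorrected", cfg, rng),
                "va_corrected_logmar": va_ground_truth(
                    se, cyl, aa, age, 0.0, "corrected", cfg, rng),
            }
            if dominant:
                for level in DEFOCUS_LEVELS:
                    row[defocus_column(level)] = va_ground_truth(
                        se, cyl, aa, age, level, "defocus", cfg, rng)
            else:
                for level in DEFOCUS_LEVELS:
                    row[defocus_column(level)] = np.nan
            for j in range(N_COEFFS):
                row[f"z{j}"] = z[j]
            row["pupil_radius_mm"] = cfg.pupil_radius_mm
            rows.append(row)
    cohort = pd.DataFrame(rows)

    # blank cfg.missing_va VA cells among those that feed observation rows
    slots = []
    for idx, row in cohort.iterrows():
        slots.append((idx, "va_uncorrected_logmar"))
        slots.append((idx, "va_corrected_logmar"))
        if row["dominant"]:
            slots.extend((idx, defocus_column(lv)) for lv in DEFOCUS_LEVELS)
    if cfg.missing_va > len(slots):
        raise ValueError("missing_va exceeds the number of VA cells")
    for k in rng.choice(len(slots), size=cfg.missing_va, replace=False):
        idx, col = slots[int(k)]
        cohort.loc[idx, col] = np.nan
    return cohort


def simulated_observer(subject_row, letter: str, logmar: float,
                       rng: np.random.Generator | int | None = None,
                       cfg: GeneratorConfig | None = None,
                       va_column: str = "va_uncorrected_logmar") -> bool:
    """Draw a recognized/unrecognized response from the psychometric rule.

    Recognition probability is ``guess + (1 - guess) *
    logistic((va_presented - va_true) / slope)``: letters much larger than
    the subject's threshold are almost always recognized, much smaller
    ones fall to the 10% guess floor. The letter identity does not enter
    the rule; it is carried for manifest bookkeeping.
    """
    cfg = cfg or GeneratorConfig()
    va_true = float(subject_row[va_column])
    if math.isnan(va_true):
        raise ValueError("subject row lacks a ground-truth VA for this condition")
    p = recognition_probability(logmar, va_true, cfg)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return bool(rng.random() < p)


def recognition_probability(va_presented: float, va_true: float,
                            cfg: GeneratorConfig | None = None) -> float:
    """The psychometric rule itself, without the Bernoulli draw."""
    cfg = cfg or GeneratorConfig()
    x = (va_presented - va_true) / cfg.psychometric_slope
    logistic = 1.0 / (1.0 + math.exp(-x))
    return cfg.guess_rate + (1.0 - cfg.guess_rate) * logistic


def end_to_end_fixture(cfg: GeneratorConfig | None = None):
    """Cohort + labelled image manifest + observation table, fully offline.

    Chains the generator, the image-set manifest (labels from the
    simulated observer) and the tabular dataset builder, guaranteeing both
    the recognizer and the boosting stack are trainable without any
    external data.
    """
    from .boost_regression import build_observation_table
    from .optotype_sim import generate_image_set

    cfg = cfg or GeneratorConfig()
    cohort = generate_cohort(cfg)

    def labeler(row, letter, logmar, rng):
        return simulated_observer(row, letter, logmar, rng, cfg)

    labelable = cohort[cohort["va_uncorrected_logmar"].notna()]
    manifest = generate_image_set(labelable, seed=cfg.seed, labeler=labeler)
    table = build_observation_table(cohort)
    return cohort, manifest, table
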
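"""End-to-end orchestration: simulate → fit → analyze → report.

``run_pipeline`` runs the whole study emulation under one seeded
configuration: simulate striatal/cerebellar TACs on the chosen frame
schedule and fit Ki_cer by reference-Patlak; generate a two-arm cohort;
compute the descriptive and inferential statistics per arm; run the
regression-to-the-mean battery. The report embeds the exact configuration
and a hash of it, so any report can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .cohort import ARM_CHALLENGE, ARM_TEST_RETEST, CohortConfig, generate_cohort
from .errors import ConfigurationError
from .io import load_schedule_spec
from .patlak import patlak_reference, suv_at
from .rtm import rtm_battery
from .simulate import (
    DEFAULT_PLASMA,
    DEFAULT_REFERENCE,
    DEFAULT_STRIATUM,
    PlasmaInputParams,
    RegionKinetics,
    simulate_region,
)
from .stats import ks_normality, paired_t, percent_change, reliability

logger = logging.getLogger("dopakin")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    schedule: str | list = "study2_32f"
    striatum: RegionKinetics = DEFAULT_STRIATUM
    reference: RegionKinetics = DEFAULT_REFERENCE
    plasma: PlasmaInputParams = DEFAULT_PLASMA
    cohort: CohortConfig = field(default_factory=CohortConfig)
    t_star: float = 24.0
    noise_scale: float = 0.05
    icc_variant: str = "agreement"
    alpha: float = 0.05
    seed: int = 0
    injected_mbq: float = 150.0
    weight_kg: float = 75.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ConfigurationError("seed must be a non-negative integer")
        if self.noise_scale < 0:
            raise ConfigurationError("noise_scale must be >= 0")

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            return obj

        return {
            "schedule": self.schedule,
            "striatum": enc(self.striatum),
            "reference": enc(self.reference),
            "plasma": enc(self.plasma),
            "cohort": enc(self.cohort),
            "t_star": self.t_star,
            "noise_scale": self.noise_scale,
            "icc_variant": self.icc_variant,
            "alpha": self.alpha,
            "seed": self.seed,
            "injected_mbq": self.injected_mbq,
            "weight_kg": self.weight_kg,
        }

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode("utf-8")
        ).hexdigest()[:16]


def _arm_descriptives(arm_df) -> dict:
    pc = percent_change(arm_df["ki_scan1"], arm_df["ki_scan2"])
    return {
        "n": int(len(arm_df)),
        "ki_scan1_mean": float(arm_df["ki_scan1"].mean()),
        "ki_scan1_sd": float(arm_df["ki_scan1"].std(ddof=1)),
        "ki_scan2_mean": float(arm_df["ki_scan2"].mean()),
        "ki_scan2_sd": float(arm_df["ki_scan2"].std(ddof=1)),
        "percent_change_mean": float(np.mean(pc)),
        "percent_change_sd": float(np.std(pc, ddof=1)),
    }


def run_pipeline(config: RunConfig, exclusions: tuple = ()) -> dict:
    """Run the full study emulation and return a JSON-serializable report."""
    schedule = load_schedule_spec(config.schedule)
    logger.info("schedule: %d frames, %.1f min total", len(schedule), schedule.total_min)

    # --- kinetic stage: simulate one subject's curves and fit Ki_cer -------
    seed = int(config.seed)
    ref_noiseless = simulate_region(config.reference, config.plasma, schedule, 0.0,
                                    region_label="cerebellum")
    str_noiseless = simulate_region(config.striatum, config.plasma, schedule, 0.0,
                                    region_label="striatum")
    fit_noiseless = patlak_reference(str_noiseless, ref_noiseless, config.t_star)
    ref_noisy = simulate_region(config.reference, config.plasma, schedule,
                                config.noise_scale, seed=seed, region_label="cerebellum")
    str_noisy = simulate_region(config.striatum, config.plasma, schedule,
                                config.noise_scale, seed=seed + 1, region_label="striatum")
    fit_noisy = patlak_reference(str_noisy, ref_noisy, config.t_star)
    suv_t = min(95.0, schedule.total_min)
    ref_suv = suv_at(ref_noiseless, suv_t, config.injected_mbq, config.weight_kg)
    logger.info("patlak: noiseless Ki_cer=%.5f, noisy Ki_cer=%.5f",
                fit_noiseless.ki_cer, fit_noisy.ki_cer)

    # --- cohort stage ------------------------------------------------------
    cohort_cfg = dataclasses.replace(config.cohort, seed=seed)
    cohort = generate_cohort(cohort_cfg)
    if exclusions:
        cohort = cohort[~cohort["subject_id"].isin(exclusions)]
    tr = cohort[cohort["arm"] == ARM_TEST_RETEST]
    ch = cohort[cohort["arm"] == ARM_CHALLENGE]
    rel = reliability(tr["ki_scan1"], tr["ki_scan2"], config.icc_variant)
    t_tr = paired_t(tr["ki_scan1"], tr["ki_scan2"])
    t_ch = paired_t(ch["ki_scan1"], ch["ki_scan2"])
    ks_stat, ks_p = ks_normality(percent_change(ch["ki_scan1"], ch["ki_scan2"]))
    logger.info("cohort: ICC=%.3f TRV=%.1f%%", rel.icc, rel.trv_percent)

    # --- regression-to-the-mean stage --------------------------------------
    report_rtm = rtm_battery(tr, ch, exclusions=exclusions)

    return {
        "provenance": {
            "version": __version__,
            "seed": seed,
            "config_hash": config.hash(),
            "config": config.to_dict(),
        },
        "patlak": {
            "noiseless": fit_noiseless.to_dict(),
            "noisy": fit_noisy.to_dict(),
            "reference_suv": {"value": ref_suv.value, "at_time_min": ref_suv.at_time},
        },
        "descriptives": {
            ARM_TEST_RETEST: _arm_descriptives(tr),
            ARM_CHALLENGE: _arm_descriptives(ch),
        },
        "stats": {
            "reliability_test_retest": rel.to_dict(),
            "paired_t_test_retest": t_tr.to_dict(),
            "paired_t_challenge": t_ch.to_dict(),
            "ks_normality_percent_change_challenge": {"statistic": ks_stat, "p": ks_p},
        },
        "rtm": report_rtm.to_dict(),
    }
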
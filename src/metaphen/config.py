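"""Cohort configuration and study-design defaults.

The default :class:`CohortConfig` encodes the design of a small COPD
case–control study: 25 COPD patients (all male, GOLD A–D split 2/2/4/17) and
21 healthy never-smoker controls (9 M / 12 F), with clinical variables
parameterized by their published median / interquartile range / limits, and
a set of planted metabolite contrasts (decreased sphingomyelins and
polyunsaturated phosphatidylcholines, accumulating lysoPCs, GOLD-stratum
markers) that downstream statistics are expected to detect.

Effect sizes are standardized shifts on the natural-log concentration scale;
the clinical literature motivating this design reports direction and
significance, not magnitudes, so defaults sit in the 0.8–1.5 range and are
fully overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

GOLD_CATEGORIES = ("A", "B", "C", "D")


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


@dataclass(frozen=True)
class Effect:
    """A planted group contrast on a targeted analyte or analyte class.

    Parameters
    ----------
    target
        Analyte name (e.g. ``"Kynurenine"``) or a class alias: ``"SM"``,
        ``"SM(OH)"``, ``"lysoPC"``, ``"PC"``, ``"PUFA-PC"`` (PC aa/ae with
        total acyl length C36–C40 and at least two double bonds),
        ``"acylcarnitine"``, ``"amino_acid"``, ``"biogenic_amine"``.
    contrast
        ``"copd"`` (COPD vs control) or ``"gold:X"`` with X in A–D
        (that GOLD stratum vs the rest of the COPD arm).
    size
        Standardized shift on the log-concentration scale (units of the
        analyte log-SD); positive means elevated in the contrast group.
    """

    target: str
    contrast: str
    size: float


@dataclass(frozen=True)
class SpectralEffect:
    """A planted group signal at one 1-Da bin of an untargeted profile."""

    matrix: str  # "serum" | "ebc"
    mode: str  # "pos" | "neg"
    mz: int  # integer bin centre in [90, 1400]
    contrast: str  # "copd" or "gold:X"
    size: float  # standardized shift on the log-intensity scale


def _var(median, q1, q3, lo, hi, dist="truncnorm"):
    return {"median": median, "q1": q1, "q3": q3, "lo": lo, "hi": hi, "dist": dist}


def default_clinical_params() -> dict:
    """Per-variable location/spread targets (median, IQR, limits) per arm."""
    return {
        "age": {"copd": _var(67, 58, 72, 42, 78), "control": _var(37, 27, 62, 23, 74)},
        "bmi": {"copd": _var(26, 23, 31, 19, 46), "control": _var(24, 23, 26, 22, 37)},
        "fvc_l": {"copd": _var(2.0, 1.5, 2.5, 1.0, 5.1), "control": _var(3.6, 3.1, 4.5, 2.6, 6.7)},
        "fvc_pct": {"copd": _var(47, 39, 57, 29, 83), "control": _var(89, 86, 109, 84, 129)},
        "fev1_pct": {"copd": _var(29, 22, 39, 14, 81), "control": _var(92, 87, 102, 83, 122)},
        # COPD inclusion requires post-bronchodilator FEV1/FVC < 0.7, so the
        # COPD upper truncation sits just below that bound.
        "fev1_fvc": {"copd": _var(0.49, 0.42, 0.65, 0.35, 0.699), "control": _var(0.81, 0.80, 0.83, 0.77, 0.93)},
        "pef": {"copd": _var(149, 125, 229, 85, 466), "control": _var(403, 347, 535, 296, 701)},
        "pef_pct": {"copd": _var(27, 23, 39, 14, 80), "control": _var(94, 81, 102, 75, 108)},
        "dlco": {"copd": _var(4.9, 2.6, 5.8, 1.9, 8.4), "control": _var(7.4, 6.1, 7.7, 4.7, 11.2)},
        # COPD-arm only
        "pack_years": {"copd": _var(40, 27, 53, 1, 84, dist="lognorm"), "control": None},
        "mmrc": {"copd": _var(2, 2, 3, 1, 4, dist="integer"), "control": None},
        "exacerbations": {"copd": _var(2, 1, 2, 0, 2, dist="nbinom"), "control": None},
    }


#: Bernoulli prevalences of COPD-arm flags (fractions of n=25).
def default_flag_prevalence() -> dict:
    return {
        "current_smoker": 0.40,
        "ex_smoker": 0.56,
        "laba": 0.96,
        "lama": 0.80,
        "ics": 0.80,
        "theophylline": 0.68,
        "oxygen": 0.40,
        "emphysema": 0.52,
        "heart_failure": 0.48,
        "coronary_heart_disease": 0.28,
        "hypertension": 0.44,
        "asthma": 0.28,
        "pulmonary_hypertension": 0.16,
        "sleep_apnea": 0.04,
        "diabetes": 0.08,
        "osteoporosis": 0.08,
        "depression": 0.16,
    }


def default_effect_table() -> tuple[Effect, ...]:
    return (
        Effect("SM", "copd", -1.0),
        Effect("SM(OH)", "copd", -1.0),
        Effect("PUFA-PC", "copd", -0.8),
        Effect("lysoPC", "copd", 0.8),
        Effect("lysoPC", "gold:A", 1.0),
        Effect("Kynurenine", "gold:B", 1.0),
        Effect("Putrescine", "gold:C", 0.8),
        Effect("Ornithine", "gold:C", -0.5),
    )


def default_spectral_effects() -> tuple[SpectralEffect, ...]:
    return (
        SpectralEffect("serum", "neg", 327, "copd", -1.2),
        SpectralEffect("serum", "neg", 367, "copd", -1.2),
        SpectralEffect("serum", "neg", 368, "copd", -1.2),
        SpectralEffect("serum", "neg", 1069, "gold:B", 1.5),
        SpectralEffect("serum", "neg", 1317, "gold:B", 1.5),
        SpectralEffect("serum", "pos", 259, "gold:A", 1.5),
    )


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort generator.

    Attributes
    ----------
    n_copd, n_control
        Arm sizes (default 25 / 21).
    gold_counts
        GOLD A–D counts within the COPD arm; must sum to ``n_copd``.
    seed
        Master seed; every random stream derives from it.
    effect_table, spectral_effects
        Planted contrasts for the targeted panel and untargeted profiles.
    clinical_params
        Per-variable median/IQR/limit targets per arm.
    flag_prevalence
        Bernoulli prevalences of the COPD-arm comorbidity/medication flags.
    batch_scale_sd
        SD of the per-spectrum multiplicative log-scale batch factor that
        total-ion-count normalization is meant to remove.
    noise_sd
        Subject-level log-intensity SD of untargeted peaks.
    ebc_noise_scale
        Multiplier on ``noise_sd`` for EBC spectra; the dilute EBC matrix
        carries less biological variance than serum.
    spectral_factor_sd
        Loading scale (log units) of a latent per-spectrum factor that
        co-varies many peaks at once — the block-correlation option that
        mimics plasma protein/lipoprotein composition variance. It makes
        the serum profile the dominant, group-independent source of total
        variance. Set to 0 for independent peaks.
    gold_severity
        Per-stratum multiplier on every ``"copd"``-contrast effect, so the
        mildest (GOLD A) patients sit metabolically between controls and
        the B-D strata.
    analyte_log_sd
        Subject-level log-concentration SD of targeted analytes.
    n_peak_locations
        Shared peak locations per (matrix, mode) spectrum family.
    mz_jitter_sd
        Per-subject m/z jitter (Da) around each shared location.
    subtype_effect, subtype_fraction
        When ``subtype_effect > 0`` the COPD arm is split into two latent
        subtypes and the targeted panel receives alternating-sign
        standardized shifts of this size — the planted structure the
        de novo phenotyping workflow should recover. Off (0.0) by default.
    """

    n_copd: int = 25
    n_control: int = 21
    gold_counts: Mapping[str, int] = field(default_factory=lambda: {"A": 2, "B": 2, "C": 4, "D": 17})
    seed: int = 0
    effect_table: Sequence[Effect] = field(default_factory=default_effect_table)
    spectral_effects: Sequence[SpectralEffect] = field(default_factory=default_spectral_effects)
    clinical_params: Mapping = field(default_factory=default_clinical_params)
    flag_prevalence: Mapping[str, float] = field(default_factory=default_flag_prevalence)
    batch_scale_sd: float = 0.5
    noise_sd: float = 0.4
    ebc_noise_scale: float = 0.4
    spectral_factor_sd: float = 0.5
    analyte_log_sd: float = 0.35
    gold_severity: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.5, "B": 0.8, "C": 0.9, "D": 1.0})
    n_peak_locations: int = 400
    mz_jitter_sd: float = 0.03
    subtype_effect: float = 0.0
    subtype_fraction: float = 0.5

    def validate(self) -> None:
        if self.n_copd < 0:
            raise ConfigError("n_copd must be >= 0")
        if self.n_control < 0:
            raise ConfigError("n_control must be >= 0")
        unknown = set(self.gold_counts) - set(GOLD_CATEGORIES)
        if unknown:
            raise ConfigError(f"gold_counts has unknown categories: {sorted(unknown)}")
        if any(v < 0 for v in self.gold_counts.values()):
            raise ConfigError("gold_counts entries must be >= 0")
        if sum(self.gold_counts.values()) != self.n_copd:
            raise ConfigError(
                f"gold_counts sum to {sum(self.gold_counts.values())}, expected n_copd={self.n_copd}"
            )
        for name, arms in self.clinical_params.items():
            for arm, spec in arms.items():
                if spec is None:
                    continue
                if spec["q3"] < spec["q1"] or (spec["q3"] - spec["q1"]) < 0:
                    raise ConfigError(f"clinical_params[{name}][{arm}]: IQR must be non-negative")
                if spec["q3"] == spec["q1"] and spec["dist"] not in ("integer", "nbinom"):
                    raise ConfigError(f"clinical_params[{name}][{arm}]: spread must be > 0")
                if not (spec["lo"] <= spec["median"] <= spec["hi"]):
                    raise ConfigError(f"clinical_params[{name}][{arm}]: median outside limits")
        for fname in ("batch_scale_sd", "noise_sd", "ebc_noise_scale",
                      "spectral_factor_sd", "analyte_log_sd", "mz_jitter_sd"):
            if getattr(self, fname) < 0:
                raise ConfigError(f"{fname} must be >= 0")
        for flag, p in self.flag_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"flag_prevalence[{flag}] must be in [0, 1]")
        if self.n_peak_locations < 1:
            raise ConfigError("n_peak_locations must be >= 1")
        for cat in GOLD_CATEGORIES:
            if self.gold_severity.get(cat, 1.0) < 0:
                raise ConfigError(f"gold_severity[{cat}] must be >= 0")
        if not 0.0 < self.subtype_fraction < 1.0:
            raise ConfigError("subtype_fraction must be in (0, 1)")
        for eff in self.effect_table:
            if eff.contrast != "copd" and not (
                eff.contrast.startswith("gold:") and eff.contrast[5:] in GOLD_CATEGORIES
            ):
                raise ConfigError(f"effect_table: unknown contrast {eff.contrast!r}")
        for eff in self.spectral_effects:
            if eff.matrix not in ("serum", "ebc"):
                raise ConfigError(f"spectral_effects: unknown matrix {eff.matrix!r}")
            if eff.mode not in ("pos", "neg"):
                raise ConfigError(f"spectral_effects: unknown mode {eff.mode!r}")
            if not 90 <= eff.mz <= 1400:
                raise ConfigError(f"spectral_effects: m/z {eff.mz} outside [90, 1400]")
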
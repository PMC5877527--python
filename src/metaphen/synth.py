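"""Synthetic COPD cohort generator.

Emits the three data blocks the integration pipeline consumes — a clinical
subject table, a targeted metabolite panel (Biocrates-p180-style analytes in
µM plus derived ratios), and untargeted peak lists per (subject, matrix,
ionization mode) — together with a ground-truth record of every planted
effect, so that parameter-recovery and calibration tests need no external
data.

Distributional choices: clinical variables are truncated normals matched to
median/IQR by moment fitting (log-normal for right-skewed pack-years,
negative-binomial for exacerbation counts); analyte concentrations are
log-normal with class-level standardized shifts planted on the log scale;
untargeted spectra are heavy-tailed peak lists over shared per-cohort peak
locations, each spectrum multiplied by a log-normal batch factor that TIC
normalization is expected to remove.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .config import GOLD_CATEGORIES, CohortConfig, ConfigError, Effect

# --------------------------------------------------------------------------
# Targeted panel registry: analyte -> typical serum concentration (µM)
# --------------------------------------------------------------------------

AMINO_ACIDS = {
    "Ala": 400.0, "Arg": 100.0, "Asn": 50.0, "Asp": 20.0, "Cit": 30.0,
    "Gln": 600.0, "Glu": 60.0, "Gly": 250.0, "His": 80.0, "Ile": 60.0,
    "Leu": 120.0, "Lys": 180.0, "Met": 25.0, "Phe": 60.0, "Pro": 180.0,
    "Ser": 110.0, "Thr": 130.0, "Trp": 60.0, "Tyr": 65.0, "Val": 230.0,
}
BIOGENIC_AMINES = {
    "Kynurenine": 2.5, "Putrescine": 0.15, "Ornithine": 60.0,
    "ADMA": 0.5, "Taurine": 60.0, "Serotonin": 1.0, "Creatinine": 70.0,
}
ACYLCARNITINES = {
    "Carnitine C0": 35.0, "Carnitine C2": 8.0, "Carnitine C3": 0.4,
    "Carnitine C16": 0.1, "Carnitine C18:1": 0.12, "Carnitine C18:2": 0.06,
}
LYSOPC = {
    "lysoPC a C16:0": 90.0, "lysoPC a C17:0": 2.5, "lysoPC a C18:0": 25.0,
    "lysoPC a C18:1": 20.0, "lysoPC a C18:2": 22.0, "lysoPC a C26:1": 0.3,
}
PC = {
    "PC aa C32:0": 15.0, "PC aa C34:2": 400.0, "PC aa C36:2": 220.0,
    "PC aa C36:3": 150.0, "PC aa C36:4": 220.0, "PC aa C38:4": 110.0,
    "PC aa C38:6": 80.0, "PC aa C40:6": 25.0, "PC aa C42:0": 0.6,
    "PC aa C42:2": 0.3, "PC ae C34:3": 8.0, "PC ae C36:3": 7.0,
    "PC ae C38:3": 4.5,
}
SM = {
    "SM C16:0": 120.0, "SM C18:0": 25.0, "SM C20:2": 4.0,
    "SM C22:3": 3.0, "SM C24:0": 25.0, "SM C24:1": 50.0,
}
SM_OH = {
    "SM(OH) C14:1": 6.0, "SM(OH) C16:1": 4.0,
    "SM(OH) C22:1": 12.0, "SM(OH) C22:2": 10.0,
}
HEXOSE = {"Hexose": 4500.0}

ANALYTE_BASELINES: dict[str, float] = {
    **AMINO_ACIDS, **BIOGENIC_AMINES, **ACYLCARNITINES,
    **LYSOPC, **PC, **SM, **SM_OH, **HEXOSE,
}

RATIO_NAMES = (
    "Glu/Gln", "Kynurenine/Trp", "Putrescine/Ornithine", "Ornithine/Ser",
    "Thr/Ser", "tSM", "tSM-non OH", "tSM-OH", "tSM-OH/tSM-non OH",
)

_PC_RE = re.compile(r"^PC a[ae] C(\d+):(\d+)$")


def analyte_class(name: str) -> str:
    if name.startswith("lysoPC"):
        return "lysoPC"
    if name.startswith("PC a"):
        return "PC"
    if name.startswith("SM(OH)"):
        return "SM(OH)"
    if name.startswith("SM "):
        return "SM"
    if name.startswith("Carnitine"):
        return "acylcarnitine"
    if name in AMINO_ACIDS:
        return "amino_acid"
    if name in BIOGENIC_AMINES:
        return "biogenic_amine"
    return "other"


def is_pufa_pc(name: str) -> bool:
    """PC aa/ae with total acyl chain length C36–C40 and >= 2 double bonds."""
    m = _PC_RE.match(name)
    if not m:
        return False
    carbons, bonds = int(m.group(1)), int(m.group(2))
    return 36 <= carbons <= 40 and bonds >= 2


_CLASS_ALIASES = {"SM", "SM(OH)", "lysoPC", "PC", "PUFA-PC",
                  "acylcarnitine", "amino_acid", "biogenic_amine"}


def _effect_targets(effect: Effect) -> list[str]:
    """Analytes an effect applies to; raises on unknown targets."""
    if effect.target == "PUFA-PC":
        return [a for a in ANALYTE_BASELINES if is_pufa_pc(a)]
    if effect.target in _CLASS_ALIASES:
        return [a for a in ANALYTE_BASELINES if analyte_class(a) == effect.target]
    if effect.target in ANALYTE_BASELINES:
        return [effect.target]
    raise ConfigError(f"effect_table names unknown analytes/classes: ['{effect.target}']")


def validate_effect_table(effects) -> None:
    unknown = []
    for eff in effects:
        try:
            _effect_targets(eff)
        except ConfigError:
            unknown.append(eff.target)
    if unknown:
        raise ConfigError(f"effect_table names unknown analytes/classes: {sorted(set(unknown))}")


# --------------------------------------------------------------------------
# Clinical block
# --------------------------------------------------------------------------

FLAG_COLUMNS = (
    "current_smoker", "ex_smoker", "laba", "lama", "ics", "theophylline",
    "oxygen", "emphysema", "heart_failure", "coronary_heart_disease",
    "hypertension", "asthma", "pulmonary_hypertension", "sleep_apnea",
    "diabetes", "osteoporosis", "depression",
)

#: 1.349 = Phi^{-1}(0.75) - Phi^{-1}(0.25): converts IQR to a normal SD.
_IQR_TO_SD = 2.0 * ndtri(0.75)


def _trunc_normal(rng, mu, sigma, lo, hi, size):
    a, b = ndtr((lo - mu) / sigma), ndtr((hi - mu) / sigma)
    u = rng.uniform(a, b, size)
    return mu + sigma * ndtri(np.clip(u, 1e-12, 1 - 1e-12))


def _sample_var(rng, spec, size):
    dist = spec["dist"]
    if dist == "lognorm":
        mu = np.log(spec["median"])
        sigma = np.log(spec["q3"] / spec["q1"]) / _IQR_TO_SD
        return np.exp(_trunc_normal(rng, mu, sigma, np.log(spec["lo"]), np.log(spec["hi"]), size))
    if dist == "nbinom":
        # over-dispersed count, clipped to the table limits; mean slightly
        # above the median so the clipped median lands on it
        mean = spec["median"] + 0.2
        n = 2.0
        p = n / (n + mean)
        draws = rng.negative_binomial(n, p, size)
        return np.clip(draws, spec["lo"], spec["hi"]).astype(float)
    sigma = max((spec["q3"] - spec["q1"]) / _IQR_TO_SD, 1e-9)
    x = _trunc_normal(rng, spec["median"], sigma, spec["lo"], spec["hi"], size)
    if dist == "integer":
        x = np.clip(np.rint(x), spec["lo"], spec["hi"])
    return x


def generate_clinical(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample the clinical/demographic subject table.

    Returns one row per subject with group, GOLD category, sex, spirometry,
    diffusing capacity, smoking history and the comorbidity/medication
    flags (flags are COPD-arm only; controls are healthy never-smokers).
    """
    config.validate()
    validate_effect_table(config.effect_table)
    nc, nh = config.n_copd, config.n_control
    rows: dict[str, np.ndarray] = {}
    subject_id = [f"COPD-{i+1:02d}" for i in range(nc)] + [f"CTRL-{i+1:02d}" for i in range(nh)]
    group = np.array(["COPD"] * nc + ["control"] * nh)

    values: dict[str, np.ndarray] = {}
    for var, arms in config.clinical_params.items():
        col = np.zeros(nc + nh)
        if arms.get("copd") is not None and nc:
            col[:nc] = _sample_var(rng, arms["copd"], nc)
        if arms.get("control") is not None and nh:
            col[nc:] = _sample_var(rng, arms["control"], nh)
        values[var] = col
    # FEV1 (L) derived for internal consistency: FVC x FEV1/FVC
    values["fev1_l"] = values["fvc_l"] * values["fev1_fvc"]

    # Sex: COPD arm all male; controls 9 M / 12 F at default size.
    sex = np.array(["M"] * (nc + nh), dtype=object)
    if nh:
        n_male = int(round(nh * 9 / 21))
        ctrl_sex = np.array(["M"] * n_male + ["F"] * (nh - n_male), dtype=object)
        rng.shuffle(ctrl_sex)
        sex[nc:] = ctrl_sex

    # GOLD: assigned by descending FEV1 %pred (A = best preserved), so that
    # spirometry differs across strata as observed in real cohorts.
    gold = np.array(["none"] * (nc + nh), dtype=object)
    if nc:
        order = np.argsort(-values["fev1_pct"][:nc], kind="stable")
        labels = []
        for cat in GOLD_CATEGORIES:
            labels += [cat] * config.gold_counts.get(cat, 0)
        for pos, lab in zip(order, labels):
            gold[pos] = lab

    # GOLD semantics: A/B are low exacerbation risk (capped at 1/year);
    # A/C are low-symptom strata (mMRC <= 1), B/D high-symptom (>= 2).
    exac = values["exacerbations"]
    low_risk = np.isin(gold, ("A", "B"))
    exac[low_risk] = np.minimum(exac[low_risk], 1.0)
    mmrc = values["mmrc"]
    low_sym = np.isin(gold, ("A", "C"))
    high_sym = np.isin(gold, ("B", "D"))
    mmrc[low_sym] = np.minimum(mmrc[low_sym], 1.0)
    mmrc[high_sym] = np.maximum(mmrc[high_sym], 2.0)

    rows["subject_id"] = subject_id
    rows["group"] = group
    rows["gold"] = gold
    rows["sex"] = sex
    for var in ("age", "bmi", "fvc_l", "fvc_pct", "fev1_l", "fev1_pct",
                "fev1_fvc", "pef", "pef_pct", "dlco", "pack_years", "mmrc",
                "exacerbations"):
        rows[var] = np.round(values[var], 4)
    # keep the spirometry identity exact on the rounded scale
    rows["fev1_l"] = np.round(rows["fvc_l"] * rows["fev1_fvc"], 4)

    # Smoking status is categorical within the COPD arm: current / ex / never.
    current = np.zeros(nc + nh, dtype=bool)
    ex = np.zeros(nc + nh, dtype=bool)
    if nc:
        p_cur = config.flag_prevalence.get("current_smoker", 0.40)
        p_ex = config.flag_prevalence.get("ex_smoker", 0.56)
        # categorical smoking status; the remainder are never-smokers
        u = rng.uniform(size=nc)
        current[:nc] = u < p_cur
        ex[:nc] = (u >= p_cur) & (u < min(p_cur + p_ex, 1.0))
        # never-smoker COPD patients carry no pack-years
        never = ~(current[:nc] | ex[:nc])
        rows["pack_years"][:nc][never] = 0.0
    rows["current_smoker"] = current
    rows["ex_smoker"] = ex
    # Medication prevalence scales with stratum severity: patients are
    # treated according to their GOLD group, so mild (A) patients carry
    # fewer maintenance therapies.
    medication_flags = ("laba", "lama", "ics", "theophylline", "oxygen")
    severity = np.array([config.gold_severity.get(g, 1.0) for g in gold[:nc]])
    for flag, p in config.flag_prevalence.items():
        if flag in ("current_smoker", "ex_smoker"):
            continue
        col = np.zeros(nc + nh, dtype=bool)
        if nc:
            p_subj = p * severity if flag in medication_flags else np.full(nc, p)
            col[:nc] = rng.uniform(size=nc) < p_subj
        rows[flag] = col
    df = pd.DataFrame(rows)
    return df


# --------------------------------------------------------------------------
# Targeted panel
# --------------------------------------------------------------------------

def compute_ratios(panel: pd.DataFrame) -> pd.DataFrame:
    """(Re)compute the derived ratio columns from analyte columns."""
    out = panel.copy()
    sm_cols = [c for c in ANALYTE_BASELINES if analyte_class(c) == "SM"]
    smoh_cols = [c for c in ANALYTE_BASELINES if analyte_class(c) == "SM(OH)"]
    out["tSM-non OH"] = out[sm_cols].sum(axis=1)
    out["tSM-OH"] = out[smoh_cols].sum(axis=1)
    out["tSM"] = out["tSM-non OH"] + out["tSM-OH"]
    out["tSM-OH/tSM-non OH"] = out["tSM-OH"] / out["tSM-non OH"]
    out["Glu/Gln"] = out["Glu"] / out["Gln"]
    out["Kynurenine/Trp"] = out["Kynurenine"] / out["Trp"]
    out["Putrescine/Ornithine"] = out["Putrescine"] / out["Ornithine"]
    out["Ornithine/Ser"] = out["Ornithine"] / out["Ser"]
    out["Thr/Ser"] = out["Thr"] / out["Ser"]
    return out


def _contrast_mask(subjects: pd.DataFrame, contrast: str) -> np.ndarray:
    if contrast == "copd":
        return (subjects["group"] == "COPD").to_numpy()
    if contrast.startswith("gold:"):
        return (subjects["gold"] == contrast[5:]).to_numpy()
    raise ConfigError(f"unknown contrast {contrast!r}")


def _contrast_weight(subjects: pd.DataFrame, contrast: str, config: CohortConfig) -> np.ndarray:
    """Per-subject multiplier for an effect: COPD-vs-control contrasts are
    scaled by the stratum's severity so GOLD A sits nearest the controls."""
    w = _contrast_mask(subjects, contrast).astype(float)
    if contrast == "copd":
        sev = subjects["gold"].map(lambda g: config.gold_severity.get(g, 1.0)).to_numpy()
        w = w * sev
    return w


def generate_targeted(
    subjects: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
    subtypes: pd.Series | None = None,
) -> pd.DataFrame:
    """Sample the targeted metabolite panel (µM) with planted contrasts.

    Concentrations are log-normal around class-typical baselines; each
    effect in ``config.effect_table`` shifts the log-mean of its target
    analytes by ``size * analyte_log_sd`` for the contrast group. Derived
    ratios are recomputed after all shifts. When ``subtypes`` is given
    (a COPD-arm subtype label per subject) and ``config.subtype_effect > 0``,
    alternating-sign shifts of that size are planted across the panel.
    """
    if len(subjects) == 0:
        raise ValueError("subjects must be non-empty")
    validate_effect_table(config.effect_table)
    names = list(ANALYTE_BASELINES)
    n, p = len(subjects), len(names)
    sigma = config.analyte_log_sd
    mu = np.tile(np.log([ANALYTE_BASELINES[a] for a in names]), (n, 1))
    col_of = {a: j for j, a in enumerate(names)}
    for eff in config.effect_table:
        w = _contrast_weight(subjects, eff.contrast, config)
        for a in _effect_targets(eff):
            mu[:, col_of[a]] += eff.size * sigma * w
    if subtypes is not None and config.subtype_effect > 0:
        st = subjects["subject_id"].map(subtypes).to_numpy()
        signs = np.array([1.0 if j % 2 == 0 else -1.0 for j in range(p)])
        hit = st == "S2"
        if hit.any():
            mu[hit] += config.subtype_effect * sigma * signs
    conc = np.exp(mu + sigma * rng.standard_normal((n, p)))
    panel = pd.DataFrame(conc, index=pd.Index(subjects["subject_id"], name="subject_id"),
                         columns=names)
    return compute_ratios(panel)


# --------------------------------------------------------------------------
# Untargeted spectra
# --------------------------------------------------------------------------

MATRICES = ("serum", "ebc")
MODES = ("pos", "neg")


def _peak_locations(config: CohortConfig, rng: np.random.Generator) -> dict:
    """Shared compound locations per (matrix, mode), planted m/z included."""
    locations = {}
    for matrix in MATRICES:
        for mode in MODES:
            mz = rng.uniform(90.6, 1399.4, config.n_peak_locations)
            base_mu = rng.normal(np.log(1e4), 1.5, config.n_peak_locations)
            planted = [e for e in config.spectral_effects
                       if e.matrix == matrix and e.mode == mode]
            mz = np.concatenate([mz, [e.mz + 0.1 for e in planted]])
            base_mu = np.concatenate([base_mu, rng.normal(np.log(3e4), 0.3, len(planted))])
            # loadings of the latent block-correlation factor
            lam = rng.normal(0.0, config.spectral_factor_sd, len(mz))
            locations[(matrix, mode)] = (mz, base_mu, lam, planted)
    return locations


def generate_spectra(
    subjects: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
    subtypes: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Sample untargeted peak lists for every (subject, matrix, mode).

    Returns a long-format peak table (subject_id, matrix, mode, mz,
    intensity) and the per-spectrum batch factors (the multiplicative
    log-normal scale noise TIC normalization should cancel). EBC spectra
    use ``noise_sd * ebc_noise_scale`` and carry no planted group signal
    by default. When COPD subtypes are planted, a deterministic subset of
    serum locations receives alternating-sign shifts of size
    ``subtype_effect * noise_sd``.
    """
    if len(subjects) == 0:
        raise ValueError("subjects must be non-empty")
    config.validate()
    locations = _peak_locations(config, rng)
    frames = []
    batch_factors: dict[str, float] = {}
    sids = subjects["subject_id"].to_numpy()
    subtype_of = None
    if subtypes is not None and config.subtype_effect > 0:
        subtype_of = subjects["subject_id"].map(subtypes).to_numpy()
    for matrix in MATRICES:
        for mode in MODES:
            mz0, base_mu, lam, planted = locations[(matrix, mode)]
            nloc = len(mz0)
            scale = config.ebc_noise_scale if matrix == "ebc" else 1.0
            sd = config.noise_sd * scale
            # subtype markers: every other location in the first half of
            # the shared serum location set, signs alternating
            sub_idx = np.arange(0, min(300, config.n_peak_locations), 2)
            sub_sign = np.where((sub_idx // 2) % 2 == 0, 1.0, -1.0)
            weights = {e.contrast: _contrast_weight(subjects, e.contrast, config)
                       for e in planted}
            for i, sid in enumerate(sids):
                factor = rng.standard_normal()  # latent composition factor
                if (subtype_of is not None and matrix == "serum"
                        and subtype_of[i] == "S2"):
                    # the planted subtype differs in overall serum
                    # composition: its latent factor is mean-shifted
                    factor += config.subtype_effect
                log_i = base_mu + scale * lam * factor + sd * rng.standard_normal(nloc)
                for j, eff in enumerate(planted):
                    log_i[config.n_peak_locations + j] += (
                        eff.size * config.noise_sd * weights[eff.contrast][i])
                if (subtype_of is not None and matrix == "serum"
                        and subtype_of[i] == "S2"):
                    log_i[sub_idx] += config.subtype_effect * config.noise_sd * sub_sign
                factor = float(np.exp(rng.normal(0.0, config.batch_scale_sd)))
                batch_factors[f"{sid}:{matrix}:{mode}"] = factor
                mz = mz0 + config.mz_jitter_sd * rng.standard_normal(nloc)
                np.clip(mz, 90.0, 1400.4, out=mz)
                frames.append(pd.DataFrame({
                    "subject_id": sid,
                    "matrix": matrix,
                    "mode": mode,
                    "mz": np.round(mz, 4),
                    "intensity": np.round(np.exp(log_i) * factor, 4),
                }))
    peaks = pd.concat(frames, ignore_index=True)
    return peaks, batch_factors


# --------------------------------------------------------------------------
# Orchestration + on-disk formats
# --------------------------------------------------------------------------

@dataclass
class CohortDataset:
    """A fully generated cohort: subject table, panel, peak lists, truth."""

    subjects: pd.DataFrame
    targeted: pd.DataFrame
    peaks: pd.DataFrame
    truth: dict

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(path / "subjects.tsv", sep="\t", index=False)
        self.targeted.to_csv(path / "targeted.csv")
        self.peaks.to_csv(path / "peaks.csv", index=False)
        (path / "truth.json").write_text(json.dumps(self.truth, indent=1, sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "CohortDataset":
        path = Path(path)
        subjects = pd.read_csv(path / "subjects.tsv", sep="\t")
        targeted = pd.read_csv(path / "targeted.csv", index_col="subject_id")
        peaks = pd.read_csv(path / "peaks.csv")
        truth = json.loads((path / "truth.json").read_text())
        return cls(subjects, targeted, peaks, truth)


def generate_cohort(config: CohortConfig | None = None) -> CohortDataset:
    """Generate a complete cohort from one seed, with a ground-truth record.

    The master seed spawns independent child streams for the clinical,
    subtype, targeted and spectral generators, so identical configs give
    byte-identical outputs.
    """
    config = config or CohortConfig()
    config.validate()
    validate_effect_table(config.effect_table)
    ss = np.random.SeedSequence(config.seed)
    r_clin, r_sub, r_tgt, r_spec = (np.random.default_rng(s) for s in ss.spawn(4))

    subjects = generate_clinical(config, r_clin)

    subtypes = None
    if config.subtype_effect > 0:
        copd_ids = subjects.loc[subjects["group"] == "COPD", "subject_id"].tolist()
        n2 = int(round(len(copd_ids) * config.subtype_fraction))
        labels = np.array(["S1"] * (len(copd_ids) - n2) + ["S2"] * n2, dtype=object)
        r_sub.shuffle(labels)
        subtypes = pd.Series(labels, index=copd_ids)

    targeted = generate_targeted(subjects, config, r_tgt, subtypes=subtypes)
    peaks, batch_factors = generate_spectra(subjects, config, r_spec, subtypes=subtypes)

    truth = {
        "effect_table": [vars(e) for e in config.effect_table],
        "spectral_effects": [vars(e) for e in config.spectral_effects],
        "subtypes": {} if subtypes is None else subtypes.to_dict(),
        "batch_factors": batch_factors,
        "seed": config.seed,
    }
    return CohortDataset(subjects, targeted, peaks, truth)
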
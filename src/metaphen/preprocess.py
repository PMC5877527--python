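"""Preprocessing and five-block integration.

Untargeted profiles pass bin (1 Da, round-half-up on the 90–1400 Da grid)
-> total-ion-count normalization -> natural log with pseudocount ->
per-bin centering across subjects -> logistic transform
1/[(0.5 + e^-x) * 2]; clinical and targeted blocks are divided by their
per-variable maximum. The centering step exists because log TIC fractions
sit far in the logistic's saturated tail; centering places each bin's
between-subject variation in the transform's responsive range (disable
with ``center_spectral=False`` to apply the logistic to raw log
fractions). The result is one subjects x
features matrix with every value in [0, 1] and a feature -> block map over
the six source blocks (clinical, targeted, serum-pos, serum-neg, ebc-pos,
ebc-neg).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MZ_MIN = 90
MZ_MAX = 1400
N_BINS = MZ_MAX - MZ_MIN + 1  # 1311 one-Dalton bins

BLOCKS = ("clinical", "targeted", "serum-pos", "serum-neg", "ebc-pos", "ebc-neg")

#: clinical feature columns drawn from the subject table
CLINICAL_NUMERIC = (
    "age", "bmi", "fvc_l", "fvc_pct", "fev1_l", "fev1_pct", "fev1_fvc",
    "pef", "pef_pct", "dlco", "pack_years", "mmrc", "exacerbations",
)
CLINICAL_FLAGS = (
    "current_smoker", "ex_smoker", "laba", "lama", "ics", "theophylline",
    "oxygen", "emphysema", "heart_failure", "coronary_heart_disease",
    "hypertension", "asthma", "pulmonary_hypertension", "sleep_apnea",
    "diabetes", "osteoporosis", "depression",
)
SMOKING_VARIABLES = ("pack_years", "current_smoker", "ex_smoker")


class EmptySpectrumError(ValueError):
    """A profile with zero total intensity cannot be TIC-normalized."""


class PeakRangeError(ValueError):
    """A peak falls outside the binnable acquisition range."""


def bin_peaks(mz, intensity, strict: bool = True) -> np.ndarray:
    """Bin peaks to the 1-Da grid, nearest integer (round half up).

    Peaks must lie in [89.5, 1400.5); in lenient mode out-of-range peaks
    are dropped with a warning instead of raising.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.shape != intensity.shape:
        raise ValueError("mz and intensity must have the same shape")
    if np.any(intensity < 0) or not np.all(np.isfinite(intensity)):
        raise ValueError("intensities must be finite and non-negative")
    in_range = (mz >= MZ_MIN - 0.5) & (mz < MZ_MAX + 0.5)
    if not in_range.all():
        bad = mz[~in_range]
        if strict:
            raise PeakRangeError(
                f"peaks outside [{MZ_MIN - 0.5}, {MZ_MAX + 0.5}): {bad[:5].tolist()}"
            )
        warnings.warn(f"dropping {bad.size} out-of-range peaks", stacklevel=2)
        mz, intensity = mz[in_range], intensity[in_range]
    bins = np.zeros(N_BINS)
    idx = np.floor(mz + 0.5).astype(int) - MZ_MIN
    np.add.at(bins, idx, intensity)
    return bins


def tic_normalize(bins) -> np.ndarray:
    """Divide a binned profile by its total ion count; output sums to 1."""
    bins = np.asarray(bins, dtype=float)
    if np.any(bins < 0):
        raise ValueError("binned intensities must be non-negative")
    total = bins.sum()
    if total <= 0:
        raise EmptySpectrumError("profile has zero total intensity")
    return bins / total


def log_transform(values, pseudocount: float = 1e-6) -> np.ndarray:
    """Natural log with a pseudocount: x -> ln(x + pseudocount)."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("log_transform requires non-negative input")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return np.log(values + pseudocount)


def logistic_transform(x):
    """Map x to (0, 1) via 1 / [(0.5 + e^-x) * 2] = 1 / (1 + 2 e^-x)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("logistic_transform requires finite input")
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + 2.0 * np.exp(-x[pos]))
    e = np.exp(x[~pos])  # stable for large negative x
    out[~pos] = e / (e + 2.0)
    return out if out.ndim else float(out)


def max_scale(values, name: str = "variable") -> np.ndarray:
    """Divide a column by its maximum so the largest value maps to 1."""
    values = np.asarray(values, dtype=float)
    m = values.max() if values.size else 0.0
    if not np.isfinite(m) or m <= 0:
        raise ValueError(f"max_scale: column {name!r} has non-positive maximum")
    return values / m


@dataclass
class IntegratedMatrix:
    """Subjects x features matrix in [0, 1] with a feature -> block map."""

    values: pd.DataFrame
    blocks: dict[str, str]

    def features_of(self, *blocks: str) -> list[str]:
        want = set(blocks)
        return [f for f in self.values.columns if self.blocks[f] in want]

    def subset(self, blocks: tuple[str, ...], subjects=None) -> "IntegratedMatrix":
        feats = self.features_of(*blocks)
        vals = self.values[feats]
        if subjects is not None:
            vals = vals.loc[subjects]
        return IntegratedMatrix(vals, {f: self.blocks[f] for f in feats})

    def write(self, csv_path: str | Path, blocks_path: str | Path) -> None:
        self.values.to_csv(csv_path)
        Path(blocks_path).write_text(json.dumps(self.blocks, indent=0, sort_keys=True))

    @classmethod
    def read(cls, csv_path: str | Path, blocks_path: str | Path) -> "IntegratedMatrix":
        values = pd.read_csv(csv_path, index_col=0)
        blocks = json.loads(Path(blocks_path).read_text())
        return cls(values, blocks)


def _spectral_block(peaks: pd.DataFrame, subject_ids, matrix: str, mode: str,
                    strict: bool, pseudocount: float, center: bool) -> pd.DataFrame:
    sub = peaks[(peaks["matrix"] == matrix) & (peaks["mode"] == mode)]
    present = set(sub["subject_id"])
    missing = [s for s in subject_ids if s not in present]
    if missing:
        raise ValueError(
            f"subjects missing a {matrix}-{mode} spectrum: {missing}"
        )
    cols = [f"{matrix}-{mode}:{mz}" for mz in range(MZ_MIN, MZ_MAX + 1)]
    logs = np.zeros((len(subject_ids), N_BINS))
    grouped = sub.groupby("subject_id", sort=False)
    for i, sid in enumerate(subject_ids):
        g = grouped.get_group(sid)
        binned = bin_peaks(g["mz"].to_numpy(), g["intensity"].to_numpy(), strict=strict)
        logs[i] = log_transform(tic_normalize(binned), pseudocount)
    if center:
        logs = logs - logs.mean(axis=0)
    out = logistic_transform(logs)
    return pd.DataFrame(out, index=subject_ids, columns=cols)


def integrate(
    subjects: pd.DataFrame,
    targeted: pd.DataFrame,
    peaks: pd.DataFrame,
    *,
    strict: bool = True,
    exclude_smoking: bool = False,
    exclude_mz: list[str] | None = None,
    pseudocount: float = 1e-6,
    center_spectral: bool = True,
) -> IntegratedMatrix:
    """Combine the five data sources into one [0, 1] analysis matrix.

    Spectral blocks pass bin -> TIC -> log -> per-bin centering ->
    logistic; clinical and targeted blocks are max-scaled per variable
    (0/1 flags are left as indicators). ``exclude_smoking`` drops the smoking-history variables;
    ``exclude_mz`` drops named spectral features (``"serum-neg:327"``
    form) before output — the hooks for the sensitivity re-analyses.
    """
    sids = subjects["subject_id"].tolist()
    if len(set(sids)) != len(sids):
        raise ValueError("duplicate subject ids in subject table")
    t_missing = [s for s in sids if s not in set(targeted.index)]
    extra = [s for s in targeted.index if s not in set(sids)]
    if t_missing or extra:
        raise ValueError(
            f"subject mismatch between clinical and targeted blocks: "
            f"missing={t_missing} extra={extra}"
        )

    frames, blocks = [], {}

    # clinical block
    clin = pd.DataFrame(index=pd.Index(sids, name="subject_id"))
    clin["sex_m"] = (subjects.set_index("subject_id").loc[sids, "sex"] == "M").astype(float)
    subj_idx = subjects.set_index("subject_id").loc[sids]
    for col in CLINICAL_NUMERIC:
        vals = subj_idx[col].to_numpy(dtype=float)
        if vals.max() > 0:
            vals = max_scale(vals, name=col)
        else:
            warnings.warn(f"clinical variable {col!r} is all zero; left unscaled",
                          stacklevel=2)
        clin[col] = vals
    for col in CLINICAL_FLAGS:
        clin[col] = subj_idx[col].astype(float)
    if exclude_smoking:
        clin = clin.drop(columns=list(SMOKING_VARIABLES))
    clin.columns = [f"clin:{c}" for c in clin.columns]
    for c in clin.columns:
        blocks[c] = "clinical"
    frames.append(clin)

    # targeted block
    tgt = targeted.loc[sids].copy()
    for col in tgt.columns:
        tgt[col] = max_scale(tgt[col].to_numpy(dtype=float), name=col)
    tgt.columns = [f"tgt:{c}" for c in tgt.columns]
    for c in tgt.columns:
        blocks[c] = "targeted"
    frames.append(tgt)

    # four spectral blocks
    for matrix in ("serum", "ebc"):
        for mode in ("pos", "neg"):
            blk = _spectral_block(peaks, sids, matrix, mode, strict, pseudocount,
                                  center_spectral)
            for c in blk.columns:
                blocks[c] = f"{matrix}-{mode}"
            frames.append(blk)

    values = pd.concat(frames, axis=1)
    if exclude_mz:
        missing = [f for f in exclude_mz if f not in values.columns]
        if missing:
            raise ValueError(f"exclude_mz names unknown features: {missing}")
        values = values.drop(columns=list(exclude_mz))
        for f in exclude_mz:
            blocks.pop(f)
    if values.isna().any().any():
        raise ValueError("integrated matrix contains missing values")
    return IntegratedMatrix(values, blocks)
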
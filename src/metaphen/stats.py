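"""Univariate statistics: volcano t-tests, ANOVA + Tukey HSD across GOLD
strata, the metabolite-by-clinical association table, and sensitivity
re-runs with subject exclusions.

Raw p-values are reported without multiple-testing correction (the analysis
convention this pipeline follows); a Benjamini–Hochberg column can be added
on request via ``add_bh_fdr``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA_DEFAULT = 0.05


def _group_arrays(X: pd.DataFrame, labels, level) -> np.ndarray:
    mask = np.asarray(labels) == level
    return X.to_numpy(dtype=float)[mask]


def volcano(
    X: pd.DataFrame,
    labels,
    case: str,
    control: str,
    alpha: float = ALPHA_DEFAULT,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-feature two-sample Student's t-test (pooled variance by default).

    Effect is the difference of group means (case − control) on the
    integrated scale. Features with zero variance in both groups are
    flagged ``degenerate`` and excluded from significance counts.
    Set ``equal_var=False`` for Welch's variant.
    """
    a = _group_arrays(X, labels, case)
    b = _group_arrays(X, labels, control)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("volcano requires n >= 2 per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(a, b, axis=0, equal_var=equal_var)
    effect = a.mean(axis=0) - b.mean(axis=0)
    degenerate = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    p = np.where(degenerate, np.nan, p)
    out = pd.DataFrame({
        "feature": X.columns,
        "effect": effect,
        "t": t,
        "p": p,
        "degenerate": degenerate,
    })
    out["significant"] = (out["p"] < alpha).fillna(False) & ~out["degenerate"]
    return out


def add_bh_fdr(table: pd.DataFrame, p_col: str = "p") -> pd.DataFrame:
    """Append a Benjamini–Hochberg adjusted p-value column (optional)."""
    out = table.copy()
    p = out[p_col].to_numpy(dtype=float)
    ok = np.isfinite(p)
    q = np.full_like(p, np.nan)
    q[ok] = sps.false_discovery_control(p[ok])
    out[p_col + "_bh"] = q
    return out


def anova_tukey(
    X: pd.DataFrame,
    strata,
    alpha: float = ALPHA_DEFAULT,
    strict: bool = False,
    tukey: bool = True,
    tukey_gate: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA per feature with Tukey HSD post hoc pairwise tests.

    Returns ``(anova, tukey)``: the first has per-feature F, p and a
    significance tier (``"<0.0001"``, ``"0.05-0.0001"``, ``"ns"``); the
    second has one row per (feature, group pair) with the studentized-range
    adjusted p-value (empty when ``tukey=False``, which skips the per-pair
    loop). ``tukey_gate=True`` runs the post hoc test only where the
    omnibus ANOVA is significant at ``alpha`` — the usual convention, and
    much faster on wide spectral matrices. Strata with n < 2 are dropped
    with a warning (``strict=True`` raises instead).
    """
    strata = np.asarray(strata)
    levels = [g for g in pd.unique(strata) if pd.notna(g)]
    counts = {g: int((strata == g).sum()) for g in levels}
    small = [g for g, c in counts.items() if c < 2]
    if small:
        if strict:
            raise ValueError(f"strata with n < 2: {small}")
        warnings.warn(f"dropping strata with n < 2: {small}", stacklevel=2)
        levels = [g for g in levels if g not in small]
    if len(levels) < 2:
        raise ValueError("ANOVA requires >= 2 strata with n >= 2")
    groups = [X.to_numpy(dtype=float)[strata == g] for g in levels]

    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, p = sps.f_oneway(*groups, axis=0)
    tier = np.where(p < 1e-4, "<0.0001", np.where(p < alpha, "0.05-0.0001", "ns"))
    tier = np.where(np.isfinite(p), tier, "degenerate")
    anova = pd.DataFrame({"feature": X.columns, "F": F, "p": p, "tier": tier})

    rows = []
    for j, feat in enumerate(X.columns if tukey else ()):
        if tukey_gate and not (np.isfinite(p[j]) and p[j] < alpha):
            continue
        cols = [g[:, j] for g in groups]
        if any(np.ptp(c) == 0 for c in cols) and all(np.ptp(c) == 0 for c in cols):
            continue
        try:
            res = sps.tukey_hsd(*cols)
        except Exception:
            continue
        for ia in range(len(levels)):
            for ib in range(ia + 1, len(levels)):
                rows.append((feat, levels[ia], levels[ib], float(res.pvalue[ia, ib])))
    tukey = pd.DataFrame(rows, columns=["feature", "group1", "group2", "p"])
    return anova, tukey


def association_table(
    panel: pd.DataFrame,
    subjects: pd.DataFrame,
    continuous_vars: tuple[str, ...] = ("pack_years", "fev1_l", "pef"),
    dichotomous_vars: tuple[str, ...] = (
        "current_smoker", "ics", "lama", "theophylline",
        "pulmonary_hypertension", "heart_failure", "emphysema",
    ),
    multilevel_vars: tuple[str, ...] = ("exacerbations",),
    r_threshold: float = 0.49,
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Metabolite x clinical-variable associations in the COPD arm.

    Pearson's r for continuous variables, two-sample t-test p for
    dichotomous ones, one-way ANOVA p for multi-level factors. Cells are
    flagged notable when |r| >= ``r_threshold`` or p < ``alpha``; constant
    metabolites or degenerate groupings yield a ``degenerate`` marker.
    """
    if "group" in subjects.columns:
        subjects = subjects[subjects["group"] == "COPD"]
    sids = subjects["subject_id"].tolist()
    pane = panel.loc[sids]
    subj = subjects.set_index("subject_id").loc[sids]
    rows = []

    def emit(metab, var, kind, value, degenerate=False):
        if degenerate or not np.isfinite(value):
            notable, value, degenerate = False, np.nan, True
        elif kind == "pearson_r":
            notable = abs(value) >= r_threshold
        else:
            notable = value < alpha
        rows.append((metab, var, kind, value, notable, degenerate))

    for metab in pane.columns:
        y = pane[metab].to_numpy(dtype=float)
        const = np.ptp(y) == 0
        for var in continuous_vars:
            x = subj[var].to_numpy(dtype=float)
            if const or np.ptp(x) == 0:
                emit(metab, var, "pearson_r", np.nan, degenerate=True)
            else:
                r = float(np.corrcoef(x, y)[0, 1])
                emit(metab, var, "pearson_r", r)
        for var in dichotomous_vars:
            flag = subj[var].to_numpy(dtype=bool)
            if const or flag.sum() < 2 or (~flag).sum() < 2:
                emit(metab, var, "test_p", np.nan, degenerate=True)
            else:
                p = float(sps.ttest_ind(y[flag], y[~flag], equal_var=True).pvalue)
                emit(metab, var, "test_p", p)
        for var in multilevel_vars:
            lv = subj[var].to_numpy()
            groups = [y[lv == g] for g in pd.unique(lv)]
            groups = [g for g in groups if len(g) >= 2]
            if const or len(groups) < 2:
                emit(metab, var, "test_p", np.nan, degenerate=True)
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = float(sps.f_oneway(*groups).pvalue)
                emit(metab, var, "test_p", p)
    return pd.DataFrame(
        rows, columns=["metabolite", "clinical_variable", "kind", "value",
                       "notable", "degenerate"])


@dataclass(frozen=True)
class SensitivityResult:
    n_significant_before: int
    n_significant_after: int
    fraction_retained: float


def sensitivity_rerun(
    X: pd.DataFrame,
    labels,
    case: str,
    control: str,
    exclude_mask,
    alpha: float = ALPHA_DEFAULT,
) -> SensitivityResult:
    """Re-run the volcano after excluding subjects; report retention.

    ``exclude_mask`` is a boolean vector (True = drop). The retention
    fraction is computed over the originally significant feature set.
    """
    exclude_mask = np.asarray(exclude_mask, dtype=bool)
    labels = np.asarray(labels)
    keep = ~exclude_mask
    for g in (case, control):
        if (labels[keep] == g).sum() < 2:
            raise ValueError(f"exclusion leaves fewer than 2 subjects in group {g!r}")
    before = volcano(X, labels, case, control, alpha=alpha)
    after = volcano(X.loc[keep], labels[keep], case, control, alpha=alpha)
    sig_before = set(before.loc[before["significant"], "feature"])
    sig_after = set(after.loc[after["significant"], "feature"])
    retained = len(sig_before & sig_after)
    frac = 1.0 if not sig_before else retained / len(sig_before)
    return SensitivityResult(len(sig_before), retained, frac)
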
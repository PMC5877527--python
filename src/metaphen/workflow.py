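"""De novo phenotyping workflow.

Enumerates 24 candidate datasets — the cross-product of cohort scope
(all subjects / COPD only), representation (original features / principal
components explaining at least a variance threshold) and six data-source
subsets — clusters each hierarchically, scores every cut with the validity
battery, evaluates a GOLD-based sparse PLS-DA partition of the same dataset
as the positive control, and applies the acceptance rule: the best de novo
partition must approach the control on every oriented index, and, when
controls are in scope, the two-cluster cut must misclassify at most two
subjects against the COPD/control labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .multivariate import pca, splsda_fit
from .preprocess import IntegratedMatrix
from .validity import (
    INDEX_ORIENTATION,
    Dendrogram,
    ValidityReport,
    cut_k,
    hclust_complete,
    stability_apn,
    validity_report,
)

#: the six data-source subsets, named by the blocks they draw on
BLOCK_SUBSETS: dict[str, tuple[str, ...]] = {
    "all": ("clinical", "targeted", "serum-pos", "serum-neg", "ebc-pos", "ebc-neg"),
    "clinical": ("clinical",),
    "targeted": ("targeted",),
    "serum": ("serum-pos", "serum-neg"),
    "ebc": ("ebc-pos", "ebc-neg"),
    "metabolomic": ("targeted", "serum-pos", "serum-neg", "ebc-pos", "ebc-neg"),
}
SCOPES = ("all_subjects", "copd_only")
REPRESENTATIONS = ("original", "pcs")


@dataclass
class CandidateDataset:
    dataset_id: str
    scope: str
    representation: str
    subset: str
    matrix: pd.DataFrame
    source_blocks: tuple[str, ...]


@dataclass
class DenovoResult:
    dendrogram: Dendrogram
    partitions: dict[int, np.ndarray]
    reports: dict[int, ValidityReport]
    table: pd.DataFrame            # k x index
    best_k: dict[str, int]         # per oriented index
    ch_best_k: int

    @property
    def best_partition(self) -> np.ndarray:
        return self.partitions[self.ch_best_k]


@dataclass
class WorkflowConfig:
    k_range: tuple[int, ...] = tuple(range(2, 9))
    variance_threshold: float = 0.05
    tolerance: float = 0.10
    n_components: int = 2
    keepX: int = 60
    apn_columns: int = 40
    control_space: str = "splsda"  # or "raw"
    max_misclassified: int = 2
    seed: int = 0


@dataclass
class WorkflowResult:
    summary: pd.DataFrame
    details: dict[str, dict] = field(repr=False, default_factory=dict)

    @property
    def accepted(self) -> list[str]:
        return self.summary.loc[self.summary["accepted"], "dataset_id"].tolist()

    def report(self) -> str:
        lines = ["# De novo phenotyping report", ""]
        n_acc = int(self.summary["accepted"].sum())
        lines.append(f"Candidate datasets: {len(self.summary)}; accepted: {n_acc}.")
        lines.append("")
        lines.append("Ranked by mean oriented-index gap to the positive control")
        lines.append("(negative gap = de novo better than control):")
        lines.append("")
        for _, row in self.summary.iterrows():
            flag = "ACCEPTED" if row["accepted"] else "rejected"
            lines.append(
                f"- {row['dataset_id']}: gap={row['mean_gap']:+.3f}, "
                f"CH-optimal k={row['ch_best_k']}, {flag}"
                + (f" ({row['reasons']})" if row["reasons"] else "")
            )
        return "\n".join(lines)


def enumerate_datasets(
    integrated: IntegratedMatrix,
    subjects: pd.DataFrame,
    variance_threshold: float = 0.05,
) -> list[CandidateDataset]:
    """Build the 24 candidate datasets (2 scopes x 2 representations x 6
    source subsets); the PC representation keeps components explaining at
    least ``variance_threshold`` of the subset's variance."""
    present = set(integrated.blocks.values())
    missing = [b for b in BLOCK_SUBSETS["all"] if b not in present]
    if missing:
        raise ValueError(f"integrated matrix is missing blocks: {missing}")
    copd_ids = subjects.loc[subjects["group"] == "COPD", "subject_id"].tolist()
    out = []
    for scope in SCOPES:
        rows = copd_ids if scope == "copd_only" else list(integrated.values.index)
        for subset, blks in BLOCK_SUBSETS.items():
            sub = integrated.subset(blks, subjects=rows)
            for rep in REPRESENTATIONS:
                if rep == "original":
                    mat = sub.values
                else:
                    model = pca(sub.values)
                    keep = model.explained_fraction >= variance_threshold
                    if not keep.any():
                        keep = np.zeros_like(keep)
                        keep[0] = True  # always retain at least the top component
                    mat = model.scores.loc[:, keep]
                out.append(CandidateDataset(
                    dataset_id=f"{scope}/{rep}/{subset}",
                    scope=scope,
                    representation=rep,
                    subset=subset,
                    matrix=mat,
                    source_blocks=blks,
                ))
    return out


def run_denovo(
    dataset: CandidateDataset,
    k_range=tuple(range(2, 9)),
    apn_columns: int | None = 40,
    seed: int = 0,
) -> DenovoResult:
    """Cluster one candidate dataset and score every cut.

    The dendrogram is built once; each k in ``k_range`` is cut and scored
    with the full validity battery plus APN (column subsample of size
    ``apn_columns``, seeded; None = exact all-columns APN). The per-index
    best k respects each index's orientation.
    """
    n = dataset.matrix.shape[0]
    k_range = [k for k in k_range if 2 <= k <= n - 1]
    if not k_range:
        raise ValueError("k_range has no valid k in [2, n-1]")
    dend = hclust_complete(dataset.matrix)
    partitions, reports, rows = {}, {}, []
    for k in k_range:
        labels = cut_k(dend, k)
        rep = validity_report(dataset.matrix, labels)
        if dataset.matrix.shape[1] >= 2:
            rep.indices["apn"] = stability_apn(
                dataset.matrix, k, columns=apn_columns, seed=seed)
        else:
            rep.indices["apn"] = np.nan
            rep.undefined["apn"] = "single feature column"
        partitions[k] = labels
        reports[k] = rep
        rows.append(pd.Series(rep.indices, name=k))
    table = pd.DataFrame(rows)
    best_k = {}
    for name, orient in INDEX_ORIENTATION.items():
        col = table[name] * orient
        if col.notna().any():
            best_k[name] = int(col.idxmax())
    ch_best = best_k.get("calinski_harabasz", k_range[0])
    return DenovoResult(dend, partitions, reports, table, best_k, ch_best)


def positive_control(
    dataset: CandidateDataset,
    labels,
    n_components: int = 2,
    keepX: int = 60,
    space: str = "splsda",
) -> ValidityReport:
    """Evaluate the GOLD-based partition of a dataset as a clustering.

    ``labels`` are GOLD strata (plus ``"control"`` when controls are in
    scope). In the default mode the partition is scored in the score space
    of a sparse PLS-DA model fit with those labels; ``space="raw"`` scores
    it directly in the dataset's feature space.
    """
    labels = np.asarray(labels, dtype=object)
    keep = pd.notna(labels) & (labels != "none")
    if not keep.all():
        warnings.warn("dropping subjects without a stratum label", stacklevel=2)
    X = dataset.matrix.loc[keep]
    y = labels[keep]
    levels = sorted(pd.unique(y).tolist())
    part = np.array([levels.index(v) + 1 for v in y])
    if space == "raw":
        report = validity_report(X, part)
    else:
        p = X.shape[1]
        nc = min(n_components, p, X.shape[0] - 1, max(len(levels) - 1, 1))
        model = splsda_fit(X, y, n_components=nc, keepX=min(keepX, p))
        report = validity_report(model.scores, part)
    # the control partition is label-derived, not data-derived: it is
    # perfectly stable under feature deletion by construction
    report.indices["apn"] = 0.0
    return report


def _misclassification(labels2: np.ndarray, groups: np.ndarray) -> int:
    """Best-assignment disagreement between a 2-cluster cut and 2 groups."""
    g = pd.unique(groups)
    m = np.zeros((2, 2), dtype=int)
    for ci in (1, 2):
        for gi, gv in enumerate(g[:2]):
            m[ci - 1, gi] = int(((labels2 == ci) & (groups == gv)).sum())
    return int(len(groups) - max(m[0, 0] + m[1, 1], m[0, 1] + m[1, 0]))


def accept(
    dataset: CandidateDataset,
    denovo: DenovoResult,
    control: ValidityReport,
    group_labels=None,
    tolerance: float = 0.10,
    max_misclassified: int = 2,
) -> tuple[bool, list[str]]:
    """Acceptance rule for one candidate dataset.

    Accepted iff (a) every oriented index of the best de novo partition
    (the Calinski–Harabasz-optimal cut) is within a relative ``tolerance``
    of the positive control or better, and (b) when COPD/control labels
    are supplied, the k=2 cut misclassifies at most ``max_misclassified``
    subjects. Returns the decision and the list of failed criteria.
    """
    reasons = []
    best = denovo.reports[denovo.ch_best_k]
    for name, orient in INDEX_ORIENTATION.items():
        cv = control.indices.get(name, np.nan)
        dv = best.indices.get(name, np.nan)
        if not np.isfinite(cv):
            continue
        if not np.isfinite(dv):
            reasons.append(f"{name} undefined for de novo partition")
            continue
        slack = tolerance * abs(cv)
        ok = dv >= cv - slack if orient > 0 else dv <= cv + slack
        if not ok:
            reasons.append(f"{name} {dv:.3g} vs control {cv:.3g}")
    if group_labels is not None:
        groups = np.asarray(group_labels, dtype=object)
        if 2 in denovo.partitions:
            mis = _misclassification(denovo.partitions[2], groups)
            if mis > max_misclassified:
                reasons.append(f"misclassification > {max_misclassified} (got {mis})")
        else:
            reasons.append("no k=2 cut available for the branch-separation check")
    return (not reasons), reasons


def run_workflow(
    integrated: IntegratedMatrix,
    subjects: pd.DataFrame,
    config: WorkflowConfig | None = None,
) -> WorkflowResult:
    """Run the full phenotyping procedure over all 24 candidate datasets.

    Each dataset is clustered and scored, its GOLD-based positive control
    is evaluated, and the acceptance rule applied. The summary ranks
    datasets by the mean oriented relative gap to their control (lower =
    closer; negative = better than control).
    """
    config = config or WorkflowConfig()
    datasets = enumerate_datasets(integrated, subjects, config.variance_threshold)
    subj = subjects.set_index("subject_id")
    rows, details = [], {}
    for ds in datasets:
        ids = list(ds.matrix.index)
        gold = subj.loc[ids, "gold"].to_numpy(dtype=object)
        group = subj.loc[ids, "group"].to_numpy(dtype=object)
        strata = np.where(group == "control", "control", gold)
        denovo = run_denovo(ds, config.k_range, config.apn_columns, config.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            control = positive_control(
                ds, strata, config.n_components, config.keepX, config.control_space)
        groups_for_rule = group if ds.scope == "all_subjects" else None
        ok, reasons = accept(ds, denovo, control, groups_for_rule,
                             config.tolerance, config.max_misclassified)
        best = denovo.reports[denovo.ch_best_k]
        gaps = []
        for name, orient in INDEX_ORIENTATION.items():
            cv, dv = control.indices.get(name), best.indices.get(name)
            if cv is None or dv is None or not (np.isfinite(cv) and np.isfinite(dv)) or cv == 0:
                continue
            gaps.append(orient * (cv - dv) / abs(cv))
        mis = (_misclassification(denovo.partitions[2], group)
               if ds.scope == "all_subjects" and 2 in denovo.partitions else np.nan)
        rows.append({
            "dataset_id": ds.dataset_id,
            "scope": ds.scope,
            "representation": ds.representation,
            "subset": ds.subset,
            "n_features": ds.matrix.shape[1],
            "ch_best_k": denovo.ch_best_k,
            "mean_gap": float(np.mean(gaps)) if gaps else np.nan,
            "misclassified_k2": mis,
            "accepted": ok,
            "reasons": "; ".join(reasons),
        })
        details[ds.dataset_id] = {
            "denovo": denovo, "control": control, "dataset": ds,
        }
    summary = pd.DataFrame(rows).sort_values(
        "mean_gap", kind="stable").reset_index(drop=True)
    return WorkflowResult(summary, details)
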
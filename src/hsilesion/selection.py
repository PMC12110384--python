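"""Two-stage mRMR feature selection with forced tumor-vs-peritumor features.

Minimum-redundancy maximum-relevance (mRMR) greedily picks features that
score high on relevance to the class label while being dissimilar to the
features already chosen.  This implementation uses the FCD variant:
relevance = one-way ANOVA F statistic, redundancy = mean absolute Pearson
correlation with the selected set, combined by difference.  A
mutual-information variant (equal-frequency discretization, 8 bins) is
available behind ``method="mi"``.

The two-stage procedure mirrors the study design: stage 1 selects k1
features independently within each image channel (each tissue index, and
the RGB photograph); stage 2 selects k2 from the pooled stage-1 survivors.
A final augmentation step re-runs mRMR on the tumor-vs-peritumor binary
subproblem and swaps in its top features until at least two are present,
replacing the lowest-ranked non-forced features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif, mutual_info_classif

__all__ = [
    "SelectionResult",
    "mrmr_select",
    "two_stage_select",
    "augment_tumor_peritumor",
    "SCENARIO_CHANNELS",
]


@dataclass
class SelectionResult:
    """Ordered selection with per-feature scores and provenance."""

    selected: list[str]
    relevance: dict[str, float]
    scores: dict[str, float]  # greedy criterion value at pick time
    stage1_pools: dict[str, list[str]] = field(default_factory=dict)
    forced: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("duplicate features in selection")

    def to_json_dict(self) -> dict:
        return {
            "selected": self.selected,
            "relevance": self.relevance,
            "scores": self.scores,
            "stage1_pools": self.stage1_pools,
            "forced": self.forced,
        }


def _relevance(X: np.ndarray, y: np.ndarray, method: str) -> np.ndarray:
    if method == "f":
        with np.errstate(invalid="ignore", divide="ignore"):
            f, _ = f_classif(X, y)
        f = np.asarray(f, dtype=float)
        f[np.isnan(f)] = 0.0  # constant features
        finite_max = f[np.isfinite(f)].max(initial=1.0)
        f[np.isposinf(f)] = 10.0 * max(finite_max, 1.0)  # perfect separators
        return f
    if method == "mi":
        return mutual_info_classif(
            _equal_frequency_bins(X), y, discrete_features=True, random_state=0
        )
    raise ValueError(f"unknown mRMR method {method!r}")


def _equal_frequency_bins(X: np.ndarray, bins: int = 8) -> np.ndarray:
    out = np.empty_like(X, dtype=np.int64)
    for j in range(X.shape[1]):
        edges = np.quantile(X[:, j], np.linspace(0, 1, bins + 1)[1:-1])
        out[:, j] = np.searchsorted(edges, X[:, j])
    return out


def mrmr_select(
    table: pd.DataFrame,
    labels,
    k: int,
    method: str = "f",
) -> SelectionResult:
    """Greedy mRMR: pick argmax of relevance minus mean |corr| to selected.

    Deterministic; exact score ties are broken lexicographically by feature
    name.  Features are z-scored before the redundancy computation.
    """
    if table.isna().any().any():
        raise ValueError("feature table contains missing values")
    names = list(table.columns)
    if k > len(names):
        raise ValueError(f"k={k} exceeds {len(names)} features")
    y = np.asarray(labels)
    if y.shape[0] != table.shape[0]:
        raise ValueError("labels length must match table rows")
    X = table.to_numpy(dtype=float)
    sd = X.std(axis=0)
    Xz = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    rel = _relevance(X, y, method)
    # scale relevance to [0, 1] so it is commensurate with |correlation|
    # redundancy; otherwise the difference criterion degenerates to a pure
    # relevance ranking and re-selects exact duplicates
    if rel.max() > 0:
        rel = rel / rel.max()
    # pairwise |correlation|; constant features correlate with nothing
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(np.corrcoef(Xz, rowvar=False))
    corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)
    order = np.argsort(names)  # lexicographic tie-break order
    selected_idx: list[int] = []
    scores: dict[str, float] = {}
    remaining = set(range(len(names)))
    # near-duplicates of an already-selected feature (|r| >= 0.95) are
    # deferred: their difference score (~rel - 1) can still exceed the
    # slightly negative scores of independent noise features, which would
    # let exact duplicates back in
    collinear_cap = 0.95
    while len(selected_idx) < k:
        best = {True: (None, -np.inf), False: (None, -np.inf)}
        for j in (o for o in order if o in remaining):
            if selected_idx:
                redundancy = float(np.mean(corr[j, selected_idx]))
                max_corr = float(np.max(corr[j, selected_idx]))
            else:
                redundancy = max_corr = 0.0
            score = float(rel[j]) - redundancy
            key = max_corr < collinear_cap
            if score > best[key][1] + 1e-12:
                best[key] = (j, score)
        best_j, best_score = best[True] if best[True][0] is not None \
            else best[False]
        selected_idx.append(best_j)
        remaining.discard(best_j)
        scores[names[best_j]] = best_score
    selected = [names[j] for j in selected_idx]
    return SelectionResult(
        selected=selected,
        relevance={names[j]: float(rel[j]) for j in selected_idx},
        scores=scores,
    )


SCENARIO_CHANNELS = {
    # scenario I: RGB photograph only; II: the 12 tissue indices;
    # III: indices + RGB
    "I": ("RGB",),
    "II": None,   # resolved to the 12 index channels at call time
    "III": None,  # indices + RGB
}


def resolve_channels(scenario: str, available: list[str]) -> list[str]:
    index_channels = [c for c in available if c != "RGB"]
    if scenario == "I":
        return ["RGB"]
    if scenario == "II":
        return index_channels
    if scenario == "III":
        return index_channels + ["RGB"]
    raise ValueError(f"unknown scenario {scenario!r}")


def two_stage_select(
    per_channel_tables: dict[str, pd.DataFrame],
    labels,
    k1: int = 7,
    k2: int = 7,
    scenario: str = "II",
    method: str = "f",
) -> tuple[SelectionResult, pd.DataFrame]:
    """Per-channel stage-1 mRMR, then stage-2 mRMR on the pooled survivors.

    Returns the selection plus the pooled stage-1 feature table (columns =
    the pooled candidate features), for downstream augmentation/modeling.
    """
    channels = resolve_channels(scenario, list(per_channel_tables))
    n_rows = {c: per_channel_tables[c].shape[0] for c in channels}
    if len(set(n_rows.values())) > 1:
        raise ValueError(f"channel tables disagree on rows: {n_rows}")
    pools: dict[str, list[str]] = {}
    pooled_cols: list[pd.DataFrame] = []
    for channel in channels:
        table = per_channel_tables[channel]
        stage1 = mrmr_select(table, labels, min(k1, table.shape[1]), method)
        pools[channel] = stage1.selected
        pooled_cols.append(table[stage1.selected])
    pooled = pd.concat(pooled_cols, axis=1)
    if pooled.shape[1] <= k2:  # scenario I: stage 2 is the identity
        stage2 = mrmr_select(pooled, labels, pooled.shape[1], method)
    else:
        stage2 = mrmr_select(pooled, labels, k2, method)
    stage2.stage1_pools = pools
    return stage2, pooled


def augment_tumor_peritumor(
    result: SelectionResult,
    pooled: pd.DataFrame,
    labels,
    tumor_label="I",
    peritumor_label="II",
    min_forced: int = 2,
    method: str = "f",
) -> SelectionResult:
    """Force >= 2 tumor-vs-peritumor discriminative features into the set.

    mRMR is re-run on the tumor/peritumor rows only; if fewer than
    ``min_forced`` of its top picks are already selected, the lowest-ranked
    non-forced features are replaced (set size is preserved).
    """
    y = np.asarray(labels)
    subset = (y == tumor_label) | (y == peritumor_label)
    if subset.sum() == 0 or len(np.unique(y[subset])) < 2:
        raise ValueError("labels must contain both tumor and peritumor classes")
    k = len(result.selected)
    binary = mrmr_select(pooled.loc[subset], y[subset],
                         min(k, pooled.shape[1]), method)
    selected = list(result.selected)
    in_set = [f for f in binary.selected[:min_forced] if f in selected]
    forced = list(in_set)
    needed = min_forced - len(in_set)
    candidates = [f for f in binary.selected if f not in selected]
    if needed > len(candidates):
        raise ValueError("tumor-vs-peritumor pool exhausted")
    for add in candidates[:needed]:
        # drop the lowest-ranked feature that is not itself forced
        for victim in reversed(selected):
            if victim not in forced:
                selected.remove(victim)
                break
        else:
            raise ValueError("cannot replace: all features are forced")
        selected.append(add)
        forced.append(add)
    return SelectionResult(
        selected=selected,
        relevance=result.relevance,
        scores=result.scores,
        stage1_pools=result.stage1_pools,
        forced=forced,
    )
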
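"""Fold-change categorization, structural feature summaries, PCA and
hierarchical-clustering matrices for quantified glycopeptides.

Categorization uses a twofold cutoff throughout and a fixed decision-tree
precedence: paracancer disagreement first, then changes explained entirely
at the protein-expression level, then common (both tumors), tumor-specific,
and opposite changes.  Labels are mutually exclusive and exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .glyco import classify_features, parse_structure
from .quant import RATIOS

CATEGORIES = (
    "common_up",
    "common_down",
    "icc_specific_up",
    "icc_specific_down",
    "hcc_specific_up",
    "hcc_specific_down",
    "opposite",
    "protein_level_only",
    "paracancer_differs",
    "unchanged",
)


@dataclass(frozen=True)
class DiffCategory:
    label: str
    ratios: dict
    cutoff: float


def _outside(r: float, cutoff: float) -> int:
    """+1 above cutoff, -1 below 1/cutoff, 0 inside the band."""
    if r >= cutoff:
        return 1
    if r <= 1.0 / cutoff:
        return -1
    return 0


def categorize(
    ratios: dict[str, float],
    normalized: dict[str, float] | None = None,
    cutoff: float = 2.0,
    require_cross_tumor: bool = False,
) -> DiffCategory:
    """Assign one differential category from the four between-group ratios.

    ``normalized`` carries the normalized-glycosylation ratios (glycopeptide
    ratio / protein ratio); when absent the protein-level-only rule is
    skipped.  ``require_cross_tumor`` additionally demands a twofold
    ICC/HCC difference for tumor-specific labels (the stricter selection
    used when listing tumor-type-specific glycopeptides).
    """
    missing = [k for k in RATIOS if k not in ratios or ratios[k] is None or np.isnan(ratios[k])]
    if missing:
        raise ValueError(f"missing ratios: {missing}")
    icc = _outside(ratios["ICC_ICCP"], cutoff)
    hcc = _outside(ratios["HCC_HCCP"], cutoff)
    cross = _outside(ratios["ICC_HCC"], cutoff)
    para = _outside(ratios["ICCP_HCCP"], cutoff)

    def done(label):
        return DiffCategory(label, dict(ratios), cutoff)

    if para != 0:
        return done("paracancer_differs")
    if normalized is not None and (icc != 0 or hcc != 0):
        arms = [("ICC_ICCP", icc), ("HCC_HCCP", hcc)]
        if all(
            _outside(normalized[name], cutoff) == 0
            for name, out in arms
            if out != 0
        ):
            return done("protein_level_only")
    if icc == 1 and hcc == 1:
        return done("common_up")
    if icc == -1 and hcc == -1:
        return done("common_down")
    if icc != 0 and hcc != 0:  # opposite directions
        return done("opposite")
    if icc != 0 and hcc == 0:
        if not require_cross_tumor or cross != 0:
            return done("icc_specific_up" if icc == 1 else "icc_specific_down")
        return done("unchanged")
    if hcc != 0 and icc == 0:
        if not require_cross_tumor or cross != 0:
            return done("hcc_specific_up" if hcc == 1 else "hcc_specific_down")
        return done("unchanged")
    return done("unchanged")


def categorize_table(
    quant: pd.DataFrame, cutoff: float = 2.0, require_cross_tumor: bool = False
) -> pd.DataFrame:
    """Apply categorize() row-wise; uses norm_* columns when present."""
    has_norm = all(f"norm_{r}" in quant.columns for r in RATIOS)
    labels = []
    for _, row in quant.iterrows():
        ratios = {r: row[r] for r in RATIOS}
        normalized = (
            {r: row[f"norm_{r}"] for r in RATIOS}
            if has_norm and row.get("protein_status", "ok") == "ok"
            else None
        )
        labels.append(categorize(ratios, normalized, cutoff, require_cross_tumor).label)
    out = quant.copy()
    out["category"] = labels
    return out


# ---------------------------------------------------------------------------
# Feature frequency summaries


_FEATURE_COLUMNS = (
    "subtype",
    "core_kind",
    "n_fucose",
    "n_sialic",
    "n_antennae",
    "has_lacdinac",
    "has_core_fucose",
    "has_bisecting",
    "antenna_fucose",
)


def add_features(table: pd.DataFrame) -> pd.DataFrame:
    """Attach structural feature columns derived from the canonical string."""
    feats = [classify_features(parse_structure(s)) for s in table["structure"]]
    out = table.copy()
    for col in _FEATURE_COLUMNS:
        out[col] = [getattr(f, col) for f in feats]
    out["branch_families"] = ["+".join(f.branch_families) for f in feats]
    return out


def feature_frequencies(
    categorized: pd.DataFrame,
    features: tuple[str, ...] = _FEATURE_COLUMNS,
) -> pd.DataFrame:
    """Counts and percentages of each feature value within each category.

    Percentages sum to 100 within every (category, feature) partition; empty
    categories yield no rows (and no division error).
    """
    rows = []
    for cat, grp in categorized.groupby("category", sort=True):
        for feat in features:
            counts = grp[feat].value_counts()
            total = int(counts.sum())
            for value, count in counts.items():
                rows.append(
                    {
                        "category": cat,
                        "feature": feat,
                        "value": value,
                        "count": int(count),
                        "percent": 100.0 * count / total,
                    }
                )
    return pd.DataFrame(rows, columns=["category", "feature", "value", "count", "percent"])


# ---------------------------------------------------------------------------
# PCA and clustering


def pca_matrix(intensities: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of per-channel expression profiles (channels are observations).

    Input: glycopeptides x channels intensity table.  Values are
    log2-transformed and centered; returns channel coordinates and the
    explained-variance ratios (non-increasing, summing to 1).
    """
    if intensities.shape[0] < 2 or intensities.shape[1] < 2:
        raise ValueError("need at least 2 glycopeptides and 2 channels")
    X = np.log2(intensities.to_numpy(dtype=float)).T  # channels x features
    X = X - X.mean(axis=0, keepdims=True)
    if np.allclose(X, 0):
        raise ValueError("constant intensity matrix: PCA undefined")
    n_comp = min(X.shape)
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(X)
    frame = pd.DataFrame(
        coords,
        index=intensities.columns,
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    return frame, pca.explained_variance_ratio_


def clustering_matrix(
    log2fc: pd.DataFrame, method: str = "average"
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Two-way agglomerative clustering (Euclidean) of a log2 fold-change
    matrix; returns row linkage, column linkage and the reordered matrix."""
    values = log2fc.to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = log2fc.index[np.isnan(values).any(axis=1)].tolist()
        raise ValueError(f"NaN entries in rows: {bad}")
    row_link = hierarchy.linkage(pdist(values, metric="euclidean"), method=method)
    col_link = hierarchy.linkage(pdist(values.T, metric="euclidean"), method=method)
    row_order = hierarchy.leaves_list(row_link)
    col_order = hierarchy.leaves_list(col_link)
    ordered = log2fc.iloc[row_order, col_order]
    return row_link, col_link, ordered
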
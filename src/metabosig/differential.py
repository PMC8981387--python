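"""Two-group differential-metabolite calling and overview statistics.

Each metabolite is tested on the logged data with a two-group
fixed-effect linear model (equivalent to a pooled-variance t-test);
fold change is the ratio of group arithmetic means on the scaled,
imputed (pre-log) scale.  A metabolite is a differential metabolite
(DM) when p < 0.05 (strict) and absolute fold change >= 1.5
(inclusive), where absolute fold change = max(FC, 1/FC).  Raw p-values
are used for calling, mirroring the original analysis; a
Benjamini-Hochberg column is emitted for information only.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, leaves_list
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .io import GROUPS, NormalizedStudy, StudyValidationError

P_THRESHOLD = 0.05
FC_THRESHOLD = 1.5


@dataclasses.dataclass(frozen=True)
class DmSummary:
    """Per-tissue DM bookkeeping: counts, directions and percentage."""

    tissue: str
    n_detected: int
    n_dm: int
    n_up: int
    n_down: int
    pct_dm: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _pooled_t(x0: np.ndarray, x1: np.ndarray) -> np.ndarray:
    """Vectorised equal-variance two-sided t-test across rows.

    Degenerate rows (zero pooled variance) get p=1 when the group means
    are equal and p=0 otherwise.
    """
    n0, n1 = x0.shape[1], x1.shape[1]
    m0, m1 = x0.mean(axis=1), x1.mean(axis=1)
    v0 = x0.var(axis=1, ddof=1)
    v1 = x1.var(axis=1, ddof=1)
    df = n0 + n1 - 2
    sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / df
    se = np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se == 0
    p[degenerate & (m0 == m1)] = 1.0
    p[degenerate & (m0 != m1)] = 0.0
    return p


def test_metabolite(values, groups) -> float:
    """Two-sided p for one metabolite's logged values split by group."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    x0 = values[groups == GROUPS[0]]
    x1 = values[groups == GROUPS[1]]
    if len(x0) < 2 or len(x1) < 2:
        raise StudyValidationError("need at least 2 samples per group")
    if not np.isfinite(values).all():
        raise StudyValidationError("non-finite values passed to test")
    return float(_pooled_t(x0[None, :], x1[None, :])[0])


def fold_change(values, groups) -> tuple[float, float, str]:
    """FC = mean(D5)/mean(D0) on the pre-log scale; abs FC = max(FC, 1/FC).

    Direction is "up" when FC > 1, "down" when FC < 1; an exact tie is
    reported "up" but can never be a DM (abs FC = 1 < threshold).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    m0 = values[groups == GROUPS[0]].mean()
    m1 = values[groups == GROUPS[1]].mean()
    if m0 <= 0 or m1 <= 0:
        raise StudyValidationError("group means must be positive on the pre-log scale")
    fc = m1 / m0
    return fc, max(fc, 1.0 / fc), ("up" if fc >= 1.0 else "down")


def run_differential(
    norm: NormalizedStudy,
    p_threshold: float = P_THRESHOLD,
    fc_threshold: float = FC_THRESHOLD,
) -> pd.DataFrame:
    """Per-metabolite differential table for one tissue.

    Columns: fold_change, abs_fold_change, log2_fold_change, p_value,
    q_value (BH, informational), direction, is_dm.
    """
    groups = norm.group.loc[norm.sample_ids].to_numpy()
    logged = norm.logged.to_numpy()
    pre_log = norm.imputed.to_numpy()
    is0 = groups == GROUPS[0]
    is1 = groups == GROUPS[1]
    p = _pooled_t(logged[:, is0], logged[:, is1])
    m0 = pre_log[:, is0].mean(axis=1)
    m1 = pre_log[:, is1].mean(axis=1)
    fc = m1 / m0
    abs_fc = np.maximum(fc, 1.0 / fc)
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "fold_change": fc,
            "abs_fold_change": abs_fc,
            "log2_fold_change": np.log2(fc),
            "p_value": p,
            "q_value": q,
            "direction": np.where(fc >= 1.0, "up", "down"),
        },
        index=norm.logged.index,
    )
    out.index.name = "metabolite_id"
    out["is_dm"] = (out["p_value"] < p_threshold) & (out["abs_fold_change"] >= fc_threshold)
    return out


def call_dms(
    results: pd.DataFrame,
    tissue: str,
    p_threshold: float = P_THRESHOLD,
    fc_threshold: float = FC_THRESHOLD,
) -> tuple[list, DmSummary]:
    """Apply the DM cutoffs (strict on p, inclusive on abs FC) and summarise."""
    is_dm = (results["p_value"] < p_threshold) & (results["abs_fold_change"] >= fc_threshold)
    dms = results.loc[is_dm]
    n_up = int((dms["direction"] == "up").sum())
    n_down = int((dms["direction"] == "down").sum())
    summary = DmSummary(
        tissue=tissue,
        n_detected=len(results),
        n_dm=len(dms),
        n_up=n_up,
        n_down=n_down,
        pct_dm=pct_dms(len(dms), len(results)),
    )
    return list(dms.index), summary


def pct_dms(n_dm: int, n_detected: int) -> float:
    """Percentage of DMs among all detected metabolites, to one decimal."""
    if n_detected <= 0:
        raise StudyValidationError("n_detected must be positive")
    if n_dm > n_detected:
        raise StudyValidationError("n_dm cannot exceed n_detected")
    return round(100.0 * n_dm / n_detected, 1)


def venn_counts(sets: dict) -> dict:
    """Exact counts for every region of a 2- or 3-set Venn diagram.

    ``sets`` maps tissue name -> set of ids (insertion order kept).
    Region keys are '&'-joined tissue names; each region counts ids in
    exactly those tissues and no others.
    """
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise StudyValidationError("venn_counts supports 2 or 3 sets")
    out = {}
    for r in range(1, len(names) + 1):
        for inside in itertools.combinations(names, r):
            region = set.intersection(*(set(sets[n]) for n in inside))
            for other in names:
                if other not in inside:
                    region -= set(sets[other])
            out["&".join(inside)] = len(region)
    return out


def pca_overview(logged: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of samples (columns) on the logged matrix.

    Returns (scores indexed by sample id, explained variances).  The sign
    of each component is fixed so its largest-magnitude loading is
    positive; explained variances are non-increasing and sum to the total
    variance.  A constant matrix is flagged with a warning.
    """
    x = logged.to_numpy(dtype=float).T  # samples x metabolites
    if x.shape[0] < 3:
        raise StudyValidationError("PCA needs at least 3 samples")
    if np.allclose(x, x[0]):
        warnings.warn("constant matrix: PCA has zero variance", stacklevel=2)
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(x)
    # deterministic sign: largest-magnitude loading of each PC positive
    for j in range(pca.components_.shape[0]):
        load = pca.components_[j]
        k = np.argmax(np.abs(load))
        if load[k] < 0:
            pca.components_[j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=logged.columns, columns=cols), pca.explained_variance_


def standardize_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each metabolite row; zero-variance rows become all zeros."""
    values = matrix.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mu) / sd
    z[~np.isfinite(z)] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def hierarchical_clustering(
    dm_logged: pd.DataFrame, axis: str = "samples", method: str = "average"
) -> tuple[np.ndarray, list]:
    """Average-linkage clustering on Euclidean distances of row-standardized data.

    ``axis`` selects whether samples (columns) or metabolites (rows) are
    clustered.  Ids are sorted before computing so leaf order is
    deterministic under input reordering; returns (scipy linkage matrix,
    leaf ids in dendrogram order).
    """
    z = standardize_rows(dm_logged)
    if axis == "samples":
        ids = sorted(z.columns)
        points = z[ids].to_numpy().T
    elif axis == "metabolites":
        ids = sorted(z.index)
        points = z.loc[ids].to_numpy()
    else:
        raise ValueError("axis must be 'samples' or 'metabolites'")
    if len(ids) < 2:
        raise StudyValidationError("clustering needs at least 2 observations")
    link = linkage(pdist(points, metric="euclidean"), method=method)
    order = [ids[i] for i in leaves_list(link)]
    return link, order
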
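"""Pathway-level statistics: direction zscore, Enrichment Value, MSEA.

Three complementary summaries of how differential metabolites (DMs)
concentrate in sub-pathways:

* ``pathway_zscore`` — signed imbalance of increased vs decreased DMs,
  (up - down) / sqrt(up + down).  The square-root denominator is the
  standard form of this statistic (a binomial sign test statistic) and
  is the package default; the plain-count denominator is available for
  auditability.
* ``enrichment_value`` — ratio of the within-pathway DM proportion to
  the out-of-pathway DM proportion over a background of detected
  *named* metabolites: EV = (k/m) / ((n-k)/(N-m)).
* ``msea`` — GSEA-style weighted running-sum enrichment over the full
  ranked metabolite list, with a set-label permutation null, normalized
  enrichment scores, and add-one-corrected permutation p-values.

A sub-pathway is a *signature* when |zscore| >= 2.5, EV >= 1.5 and it
contains at least 5 DMs.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .io import StudyValidationError

logger = logging.getLogger(__name__)

ZSCORE_THRESHOLD = 2.5
EV_THRESHOLD = 1.5
MIN_DMS = 5


def pathway_zscore(up: int, down: int, denominator: str = "sqrt") -> float:
    """Signed direction statistic for a pathway's DMs.

    ``up`` and ``down`` are the numbers of increased and decreased DMs
    assigned to the pathway.  With ``denominator="sqrt"`` (default) the
    statistic is (up - down)/sqrt(up + down); ``"count"`` divides by the
    raw count instead, which bounds it in [-1, 1].
    """
    if up < 0 or down < 0:
        raise StudyValidationError("up and down must be non-negative")
    count = up + down
    if count == 0:
        raise StudyValidationError("zscore undefined for an empty pathway")
    if denominator == "sqrt":
        return (up - down) / math.sqrt(count)
    if denominator == "count":
        return (up - down) / count
    raise ValueError("denominator must be 'sqrt' or 'count'")


def enrichment_value(k: int, m: int, n: int, N: int) -> float:
    """EV = (k/m) / ((n - k)/(N - m)) on named-metabolite margins.

    k: DMs in the pathway; m: detected named metabolites in the pathway;
    n: DMs among all detected named metabolites; N: all detected named
    metabolites.  When every DM lies in the pathway (n = k) the ratio is
    unbounded and +inf is returned as a flagged sentinel.
    """
    if m < 1:
        raise StudyValidationError("pathway has no detected named metabolites (m = 0)")
    if N <= m:
        raise StudyValidationError("pathway equals the whole background (N <= m)")
    if not (k <= m and k <= n <= N):
        raise StudyValidationError(f"inconsistent margins k={k}, m={m}, n={n}, N={N}")
    if n == k:
        return math.inf
    return (k / m) / ((n - k) / (N - m))


def score_all_pathways(
    results: pd.DataFrame,
    annotations: pd.DataFrame,
    z_threshold: float = ZSCORE_THRESHOLD,
    ev_threshold: float = EV_THRESHOLD,
    min_dms: int = MIN_DMS,
    denominator: str = "sqrt",
) -> pd.DataFrame:
    """One scored row per sub-pathway containing at least one DM.

    ``results`` is the per-metabolite differential table for one tissue
    (its index is the tissue's detected background); ``annotations`` maps
    metabolite ids to super/sub-pathways.  zscore and EV are computed on
    detected *named* metabolites only; unnamed "X-" compounds still count
    as DMs for volcano/Venn purposes but not here.  Pathways failing the
    k >= ``min_dms`` cutoff are listed with is_signature=False rather
    than dropped.
    """
    detected = results.index
    missing_ann = [mid for mid in detected[results["is_dm"]] if mid not in annotations.index]
    if missing_ann:
        raise StudyValidationError(f"DMs without annotation: {missing_ann}")
    ann = annotations.reindex(detected)
    named = ann["is_named"].fillna(False).astype(bool)
    background = results.loc[named.to_numpy()]
    ann_named = ann.loc[named.to_numpy()]
    N = len(background)
    n = int(background["is_dm"].sum())
    rows = []
    for sub, members in ann_named.groupby("sub_pathway", sort=True):
        sub_results = background.loc[members.index]
        dms = sub_results.loc[sub_results["is_dm"]]
        k = len(dms)
        if k == 0:
            continue
        up = int((dms["direction"] == "up").sum())
        down = k - up
        z = pathway_zscore(up, down, denominator=denominator)
        m = len(members)
        ev = enrichment_value(k, m, n, N) if N > m else math.nan
        is_sig = (
            abs(z) >= z_threshold
            and (math.isinf(ev) or ev >= ev_threshold)
            and k >= min_dms
        )
        rows.append(
            {
                "sub_pathway": sub,
                "super_pathway": members["super_pathway"].iloc[0],
                "k": k,
                "up": up,
                "down": down,
                "m": m,
                "n": n,
                "N": N,
                "zscore": z,
                "enrichment_value": ev,
                "ev_infinite": math.isinf(ev),
                "is_signature": is_sig,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.set_index("sub_pathway")
    return out


def rank_statistic(results: pd.DataFrame) -> pd.Series:
    """Signed ranking statistic: sign(log FC) * -log10(p)."""
    p = results["p_value"].clip(lower=1e-300)
    stat = np.sign(results["log2_fold_change"]) * (-np.log10(p))
    return pd.Series(stat.to_numpy(), index=results.index, name="rank_stat")


def _running_es(indicator: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Signed enrichment score for each row of a boolean indicator matrix."""
    n_perm, nb = indicator.shape
    ns = indicator.sum(axis=1)
    hit_w = weights[None, :] * indicator
    hit_total = hit_w.sum(axis=1, keepdims=True)
    # all-zero weights (flat statistic): fall back to unweighted steps
    flat = hit_total[:, 0] == 0
    if flat.any():
        hit_w[flat] = indicator[flat].astype(float)
        hit_total[flat, 0] = ns[flat]
    hits = np.cumsum(hit_w, axis=1) / hit_total
    misses = np.cumsum(~indicator, axis=1) / (nb - ns)[:, None]
    run = hits - misses
    idx = np.argmax(np.abs(run), axis=1)
    return run[np.arange(n_perm), idx]


def msea(
    stats: pd.Series,
    sets: dict,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    dm_ids=None,
) -> pd.DataFrame:
    """Metabolite set enrichment over a ranked list with a permutation null.

    ``stats`` maps every detected (background) metabolite to its signed
    ranking statistic; ``sets`` maps sub-pathway name -> member ids.
    Members outside the background are ignored; sets with fewer than two
    detected members are skipped with a warning; a set equal to the whole
    background has no contrast and is flagged degenerate (ES = 0, p = 1).

    NES = ES / mean(|permuted ES| of matching sign); p is the add-one
    corrected fraction of same-sign permutation scores at least as
    extreme.  Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise StudyValidationError("n_perm must be at least 100")
    order = pd.DataFrame({"stat": stats}).sort_values(
        by=["stat"], ascending=False, kind="mergesort"
    )
    # stable tie-break on id for determinism
    order = order.loc[
        sorted(order.index, key=lambda i: (-order.at[i, "stat"], str(i)))
    ]
    ranked_ids = list(order.index)
    svals = order["stat"].to_numpy(dtype=float)
    nb = len(ranked_ids)
    pos = {mid: i for i, mid in enumerate(ranked_ids)}
    weights = np.abs(svals) ** weight
    rng = np.random.default_rng(seed)
    dm_set = set(dm_ids) if dm_ids is not None else None

    rows = []
    for name in sorted(sets):
        members = [mid for mid in sets[name] if mid in pos]
        ns = len(members)
        if ns < 2:
            logger.warning("skipping set %r: %d detected member(s)", name, ns)
            continue
        n_dm = len(dm_set & set(members)) if dm_set is not None else ns
        if ns == nb:
            rows.append(
                {
                    "sub_pathway": name,
                    "es": 0.0,
                    "nes": math.nan,
                    "p_value": 1.0,
                    "n_detected_in_set": ns,
                    "n_dm_in_set": n_dm,
                    "degenerate": True,
                    "significant": False,
                }
            )
            continue
        ind = np.zeros((1, nb), dtype=bool)
        ind[0, [pos[mid] for mid in members]] = True
        es = float(_running_es(ind, weights)[0])
        # set-label permutations: random sets of the same size
        perm_ind = np.zeros((n_perm, nb), dtype=bool)
        for r in range(n_perm):
            perm_ind[r, rng.choice(nb, size=ns, replace=False)] = True
        perm_es = _running_es(perm_ind, weights)
        same_sign = perm_es * np.sign(es) > 0 if es != 0 else np.ones(n_perm, bool)
        n_same = int(same_sign.sum())
        if n_same > 0:
            nes = es / np.abs(perm_es[same_sign]).mean() if es != 0 else 0.0
            p = (1 + int((np.abs(perm_es[same_sign]) >= abs(es)).sum())) / (1 + n_same)
        else:
            nes = es / np.abs(perm_es).mean() if np.abs(perm_es).mean() > 0 else math.nan
            p = 1.0 / (1 + n_perm)
        rows.append(
            {
                "sub_pathway": name,
                "es": es,
                "nes": nes,
                "p_value": p,
                "n_detected_in_set": ns,
                "n_dm_in_set": n_dm,
                "degenerate": False,
                "significant": p < 0.05,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.set_index("sub_pathway")
    return out


def pathway_sets(annotations: pd.DataFrame, background=None) -> dict:
    """sub_pathway -> set of metabolite ids, optionally restricted to a background."""
    ann = annotations if background is None else annotations.loc[
        [mid for mid in annotations.index if mid in set(background)]
    ]
    return {sub: set(idx) for sub, idx in ann.groupby("sub_pathway").groups.items()}


def compare_tissues(tables: dict, min_dms: int = MIN_DMS) -> pd.DataFrame:
    """Cross-tissue comparison of MSEA results.

    ``tables`` maps tissue -> MSEA result table (indexed by sub_pathway
    with columns nes, p_value, n_dm_in_set).  The union of pathways with
    n_dm_in_set >= ``min_dms`` in *any* tissue is kept; a pathway absent
    from a tissue's table is marked not-detected there (distinct from
    detected-but-not-significant).
    """
    if len(tables) < 1:
        raise StudyValidationError("need at least one tissue table")
    keep: set = set()
    for table in tables.values():
        if table.empty:
            continue
        keep |= set(table.index[table["n_dm_in_set"] >= min_dms])
    index = sorted(keep)
    out = pd.DataFrame(index=pd.Index(index, name="sub_pathway"))
    for tissue, table in tables.items():
        detected = out.index.isin(table.index)
        out[f"{tissue}_detected"] = detected
        for col, src in (("nes", "nes"), ("p", "p_value"), ("k", "n_dm_in_set")):
            out[f"{tissue}_{col}"] = [
                table.at[sub, src] if det else math.nan
                for sub, det in zip(out.index, detected)
            ]
    return out
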
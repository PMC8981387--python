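"""Peak-area preprocessing: batch median scaling, minimum imputation, log.

The scheme mirrors the quantification platform's quality-control
convention: within each instrument batch every metabolite is divided by
its within-batch median (so each batch, and hence the metabolite, has
median one); remaining missing cells — interpreted as below-detection
dropouts — are imputed with the metabolite's minimum observed scaled
value across all batches; the complete matrix is then natural-log
transformed for downstream statistics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import NormalizedStudy, PeakAreaStudy, StudyValidationError

logger = logging.getLogger(__name__)


def median_scale(raw: pd.DataFrame, batch: pd.Series) -> tuple[pd.DataFrame, list]:
    """Divide each (metabolite, batch) cell group by its within-batch median.

    Missing cells stay missing.  A metabolite entirely missing from one
    batch keeps its NaNs there (imputation handles them later); a
    metabolite missing in *all* batches is dropped and reported.

    Returns (scaled matrix, list of dropped metabolite ids).
    """
    all_missing = raw.isna().all(axis=1)
    dropped = list(raw.index[all_missing])
    if dropped:
        logger.warning(
            "dropping %d metabolite(s) with no observed value: %s",
            len(dropped), dropped[:10],
        )
    kept = raw.loc[~all_missing]
    scaled = kept.copy()
    for b in pd.unique(batch.loc[list(raw.columns)]):
        cols = [s for s in raw.columns if batch.loc[s] == b]
        block = kept[cols]
        med = block.median(axis=1, skipna=True)
        scaled[cols] = block.div(med, axis=0)
    return scaled, dropped


def impute_minimum(scaled: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill each missing cell with its metabolite's minimum observed value.

    Returns (complete matrix, boolean mask of imputed cells).
    """
    observed_counts = scaled.notna().sum(axis=1)
    if (observed_counts == 0).any():
        empty = list(scaled.index[observed_counts == 0])
        raise StudyValidationError(
            f"metabolites with zero observed values reached imputation: {empty}"
        )
    mask = scaled.isna()
    mins = scaled.min(axis=1, skipna=True)
    values = np.where(mask.to_numpy(), mins.to_numpy()[:, None], scaled.to_numpy())
    imputed = pd.DataFrame(values, index=scaled.index, columns=scaled.columns)
    return imputed, mask


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Element-wise natural logarithm; rejects non-positive cells by name."""
    values = matrix.to_numpy(dtype=float)
    bad = ~(values > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise StudyValidationError(
            f"non-positive value {values[i, j]!r} at metabolite "
            f"{matrix.index[i]!r}, sample {matrix.columns[j]!r}"
        )
    return pd.DataFrame(np.log(values), index=matrix.index, columns=matrix.columns)


def normalize(study: PeakAreaStudy, min_observed: int = 2) -> NormalizedStudy:
    """Run the full scheme: scale -> impute -> log.

    Metabolites observed in fewer than ``min_observed`` samples overall
    are dropped before testing (no variance estimate is possible) and
    reported in ``dropped_metabolites``.
    """
    too_sparse = study.raw.notna().sum(axis=1) < min_observed
    sparse_ids = list(study.raw.index[too_sparse])
    if sparse_ids:
        logger.warning(
            "dropping %d metabolite(s) observed in <%d samples",
            len(sparse_ids), min_observed,
        )
    raw = study.raw.loc[~too_sparse]
    scaled, all_missing = median_scale(raw, study.batch)
    imputed, mask = impute_minimum(scaled)
    logged = log_transform(imputed)
    return NormalizedStudy(
        tissue=study.tissue,
        scaled=scaled,
        imputed=imputed,
        imputed_mask=mask,
        logged=logged,
        group=study.group.loc[study.sample_ids],
        batch=study.batch.loc[study.sample_ids],
        dropped_metabolites=tuple(sparse_ids + all_missing),
    )
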
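"""Domain types and TSV/JSON readers/writers shared by all pipeline stages.

The pipeline starts from a quantified peak-area matrix (metabolites x
samples), per-sample metadata (group, instrument batch, tissue) and a
metabolite annotation table mapping each compound to one of the nine
platform super-pathway categories and a finer sub-pathway label.

Missing peak areas (below-detection dropouts) are encoded in TSV as an
empty field or ``NA`` on read; ``NA`` is always written.  All joins are
id-keyed, never positional.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

#: The two study arms: D0 sham controls vs five-day exposure.
GROUPS = ("D0", "D5")

#: Closed vocabulary of the nine top-level metabolite categories.
SUPER_PATHWAYS = frozenset(
    {
        "Amino Acid",
        "Carbohydrate",
        "Cofactors and Vitamins",
        "Energy",
        "Lipid",
        "Nucleotide",
        "Partially characterized molecules",
        "Peptide",
        "Xenobiotics",
    }
)

#: Unnamed compounds carry a platform tag like ``X-23639`` instead of a name.
UNNAMED_PATTERN = re.compile(r"^X-?\d+$")

#: Only these two encodings count as missing in any TSV the pipeline reads.
NA_VALUES = ("", "NA")

#: Floats round-trip through TSV to 12 significant digits.
FLOAT_FORMAT = "%.12g"


class StudyValidationError(ValueError):
    """Raised when an input table violates a documented contract."""


class EdgeListError(ValueError):
    """Raised for malformed interaction edge-list rows (carries line number)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PeakAreaStudy:
    """Raw peak areas plus sample metadata for one tissue.

    ``raw`` is a metabolites x samples DataFrame of positive peak areas
    with NaN for missing (below-detection) cells.  ``group`` and
    ``batch`` are Series indexed by sample id.
    """

    tissue: str
    raw: pd.DataFrame
    group: pd.Series
    batch: pd.Series
    excluded_samples: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.validate()

    @property
    def metabolite_ids(self) -> list:
        return list(self.raw.index)

    @property
    def sample_ids(self) -> list:
        return list(self.raw.columns)

    def n_per_group(self) -> dict:
        return self.group.value_counts().to_dict()

    def validate(self) -> None:
        if self.raw.index.duplicated().any():
            raise StudyValidationError("duplicated metabolite ids")
        if self.raw.columns.duplicated().any():
            raise StudyValidationError("duplicated sample ids")
        for name, series in (("group", self.group), ("batch", self.batch)):
            missing = [s for s in self.raw.columns if s not in series.index]
            if missing:
                raise StudyValidationError(
                    f"samples without {name} metadata: {missing}"
                )
            if series.loc[list(self.raw.columns)].isna().any():
                raise StudyValidationError(f"null {name} labels present")
        bad_groups = set(self.group.loc[list(self.raw.columns)]) - set(GROUPS)
        if bad_groups:
            raise StudyValidationError(
                f"unknown group labels {sorted(bad_groups)}; expected {GROUPS}"
            )
        counts = self.group.loc[list(self.raw.columns)].value_counts()
        for g in GROUPS:
            if counts.get(g, 0) < 2:
                raise StudyValidationError(
                    f"group {g} has {counts.get(g, 0)} samples; need at least 2"
                )
        values = self.raw.to_numpy(dtype=float)
        present = ~np.isnan(values)
        if not (values[present] > 0).all():
            raise StudyValidationError("non-positive peak areas present")


@dataclasses.dataclass(frozen=True)
class NormalizedStudy:
    """Batch-median-scaled, minimum-imputed and log-transformed matrices.

    ``scaled`` keeps the original missing cells as NaN; ``imputed`` is the
    complete pre-log matrix with each missing cell set to that metabolite's
    minimum observed scaled value; ``imputed_mask`` marks those cells;
    ``logged`` is the natural log of ``imputed``.
    """

    tissue: str
    scaled: pd.DataFrame
    imputed: pd.DataFrame
    imputed_mask: pd.DataFrame
    logged: pd.DataFrame
    group: pd.Series
    batch: pd.Series
    dropped_metabolites: tuple = ()

    @property
    def metabolite_ids(self) -> list:
        return list(self.logged.index)

    @property
    def sample_ids(self) -> list:
        return list(self.logged.columns)


# ---------------------------------------------------------------------------
# peak-area matrix + metadata
# ---------------------------------------------------------------------------


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        na_values=list(NA_VALUES),
        keep_default_na=False,
        **kwargs,
    )


def read_peak_area_study(matrix_path, metadata_path, tissue: str | None = None) -> PeakAreaStudy:
    """Read a peak-area matrix TSV and its sample-metadata TSV.

    The matrix has metabolite_id as its first column and one column per
    sample; the metadata has columns sample_id, group, batch, tissue.
    Metadata must cover every matrix column; extra metadata rows (other
    tissues' samples) are ignored.
    """
    raw = _read_tsv(matrix_path, index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    meta = _read_tsv(metadata_path, dtype=str)
    required = {"sample_id", "group", "batch", "tissue"}
    if not required.issubset(meta.columns):
        raise StudyValidationError(
            f"metadata missing columns {sorted(required - set(meta.columns))}"
        )
    meta = meta.set_index("sample_id")
    absent = [s for s in raw.columns if s not in meta.index]
    if absent:
        raise StudyValidationError(f"metadata missing rows for samples: {absent}")
    meta = meta.loc[list(raw.columns)]
    tissues = sorted(set(meta["tissue"]))
    if tissue is None:
        if len(tissues) != 1:
            raise StudyValidationError(
                f"matrix spans tissues {tissues}; pass an explicit tissue"
            )
        tissue = tissues[0]
    else:
        keep = meta.index[meta["tissue"] == tissue]
        if len(keep) == 0:
            raise StudyValidationError(f"no samples for tissue {tissue!r}")
        raw = raw[list(keep)]
        meta = meta.loc[list(keep)]
    return PeakAreaStudy(
        tissue=tissue,
        raw=raw.astype(float),
        group=meta["group"],
        batch=meta["batch"],
    )


def write_study(study: PeakAreaStudy, matrix_path, metadata_path) -> None:
    """Write a study back to the two-TSV on-disk form (missing -> ``NA``)."""
    out = study.raw.copy()
    out.index.name = "metabolite_id"
    out.to_csv(matrix_path, sep="\t", na_rep="NA", float_format=FLOAT_FORMAT)
    meta = pd.DataFrame(
        {
            "sample_id": study.sample_ids,
            "group": study.group.loc[study.sample_ids].to_numpy(),
            "batch": study.batch.loc[study.sample_ids].to_numpy(),
            "tissue": study.tissue,
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def apply_exclusions(study: PeakAreaStudy, excluded_ids) -> PeakAreaStudy:
    """Drop flagged samples (e.g. one technician-flagged abnormal sample).

    The removed ids are recorded in ``excluded_samples``.  Exclusion must
    leave at least two samples in each group.
    """
    excluded = set(excluded_ids)
    unknown = excluded - set(study.sample_ids)
    if unknown:
        raise StudyValidationError(f"cannot exclude unknown samples: {sorted(unknown)}")
    if not excluded:
        return study
    keep = [s for s in study.sample_ids if s not in excluded]
    counts = study.group.loc[keep].value_counts()
    for g in GROUPS:
        if counts.get(g, 0) < 2:
            raise StudyValidationError(
                f"excluding {sorted(excluded)} leaves group {g} with "
                f"{counts.get(g, 0)} samples"
            )
    return PeakAreaStudy(
        tissue=study.tissue,
        raw=study.raw[keep],
        group=study.group.loc[keep],
        batch=study.batch.loc[keep],
        excluded_samples=study.excluded_samples | frozenset(excluded),
    )


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise StudyValidationError(f"cannot parse boolean {value!r}")


def read_annotations(path) -> pd.DataFrame:
    """Read the metabolite annotation TSV.

    Returns a DataFrame indexed by metabolite_id with columns ``name``,
    ``super_pathway``, ``sub_pathway`` and ``is_named``.  Compounds whose
    name matches the platform's unnamed convention (``X-`` + digits) get
    is_named=False unless an explicit is_named column overrides the regex.
    """
    ann = _read_tsv(path, dtype=str)
    required = {"metabolite_id", "name", "super_pathway", "sub_pathway"}
    if not required.issubset(ann.columns):
        raise StudyValidationError(
            f"annotation table missing columns {sorted(required - set(ann.columns))}"
        )
    bad = sorted(set(ann["super_pathway"]) - SUPER_PATHWAYS)
    if bad:
        raise StudyValidationError(
            f"super_pathway values outside the 9-category vocabulary: {bad}"
        )
    ann = ann.set_index("metabolite_id")
    if ann.index.duplicated().any():
        raise StudyValidationError("duplicated metabolite ids in annotations")
    if "is_named" in ann.columns:
        is_named = ann["is_named"].map(_parse_bool)
    else:
        is_named = ~ann["name"].astype(str).str.match(UNNAMED_PATTERN)
    out = ann[["name", "super_pathway", "sub_pathway"]].copy()
    out["is_named"] = is_named.astype(bool)
    return out


def write_annotations(annotations: pd.DataFrame, path) -> None:
    out = annotations.copy()
    out.index.name = "metabolite_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# interaction edge lists (STITCH-style)
# ---------------------------------------------------------------------------

EDGE_COLUMNS = ("chemical_a", "chemical_b", "combined_score")


def read_edge_list(path) -> pd.DataFrame:
    """Read a chemical-chemical edge list with 0-1000 confidence scores.

    Malformed rows raise :class:`EdgeListError` naming the 1-based file
    line number.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != EDGE_COLUMNS:
            raise EdgeListError(
                f"line 1: expected header {EDGE_COLUMNS}, got {tuple(header)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise EdgeListError(f"line {lineno}: expected 3 fields, got {len(fields)}")
            a, b, score = fields
            try:
                score_i = int(score)
            except ValueError:
                raise EdgeListError(
                    f"line {lineno}: combined_score {score!r} is not an integer"
                ) from None
            if not 0 <= score_i <= 1000:
                raise EdgeListError(f"line {lineno}: combined_score {score_i} outside 0-1000")
            rows.append((a, b, score_i))
    return pd.DataFrame(rows, columns=list(EDGE_COLUMNS))


def write_edge_list(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False, columns=list(EDGE_COLUMNS))


# ---------------------------------------------------------------------------
# generic result tables + run summaries
# ---------------------------------------------------------------------------


def write_table(frame: pd.DataFrame, path, index: bool = True) -> None:
    """Write a result table; floats keep 12 significant digits."""
    frame.to_csv(path, sep="\t", na_rep="NA", index=index, float_format=FLOAT_FORMAT)


def read_table(path, index_col=0) -> pd.DataFrame:
    return _read_tsv(path, index_col=index_col)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_json(path):
    return json.loads(Path(path).read_text(encoding="utf-8"))
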
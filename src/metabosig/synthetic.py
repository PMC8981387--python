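"""Synthetic multi-tissue peak-area studies with planted ground truth.

The generator emulates the structure of an untargeted metabolomics study
of two respiratory muscles and lung after five days of controlled
mechanical ventilation: log-normal peak areas, multiplicative
instrument-batch effects shared across metabolites, left-censored
(missing-not-at-random) dropouts below a per-metabolite detection
limit, group fold changes planted on designated sub-pathway sets, the
platform's nine super-pathway categories with unnamed "X-#####"
compounds, and partially overlapping metabolite panels across tissues.

Every draw is deterministic given the config seed; each tissue gets its
own RNG stream derived from (seed, tissue) so adding a tissue never
perturbs another tissue's data.
"""

from __future__ import annotations

import dataclasses
import math
import zlib

import numpy as np
import pandas as pd
import yaml

from .io import GROUPS, PeakAreaStudy, StudyValidationError

#: Sub-pathway catalogue per super-pathway used to annotate null metabolites.
SUB_PATHWAY_CATALOG = {
    "Amino Acid": (
        "Leucine, Isoleucine and Valine Metabolism",
        "Tryptophan Metabolism",
        "Urea cycle; Arginine and Proline Metabolism",
        "Polyamine Metabolism",
        "Glycine, Serine and Threonine Metabolism",
    ),
    "Carbohydrate": (
        "Glycolysis, Gluconeogenesis, and Pyruvate Metabolism",
        "Pentose Metabolism",
    ),
    "Cofactors and Vitamins": (
        "Nicotinate and Nicotinamide Metabolism",
        "Pantothenate and CoA Metabolism",
    ),
    "Energy": ("TCA Cycle", "Oxidative Phosphorylation"),
    "Lipid": (
        "Fatty Acid Metabolism (Acyl Carnitine, Polyunsaturated)",
        "Fatty Acid Metabolism (Acyl Carnitine, Long Chain Saturated)",
        "Monoacylglycerol",
        "Phosphatidylinositol (PI)",
        "Sphingomyelins",
    ),
    "Nucleotide": (
        "Purine Metabolism, (Hypo)Xanthine/Inosine containing",
        "Pyrimidine Metabolism, Uracil containing",
    ),
    "Partially characterized molecules": ("Partially Characterized Molecules",),
    "Peptide": ("Dipeptide", "Gamma-glutamyl Amino Acid"),
    "Xenobiotics": ("Benzoate Metabolism", "Food Component/Plant", "Chemical"),
}

_SUPER_OF_SUB = {
    sub: sup for sup, subs in SUB_PATHWAY_CATALOG.items() for sub in subs
}

#: Default study-like tissue panels (detected metabolites per tissue).
DEFAULT_PANEL_SIZES = {"diaphragm": 817, "intercostal": 786, "lung": 941}


@dataclasses.dataclass(frozen=True)
class PlantedSet:
    """A sub-pathway whose members receive a common group fold change."""

    sub_pathway: str
    size: int
    fold: float
    direction: str  # "up" or "down"

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise StudyValidationError("planted set size must be positive")
        if self.fold <= 1.0:
            raise StudyValidationError("planted fold change must exceed 1")
        if self.direction not in ("up", "down"):
            raise StudyValidationError("direction must be 'up' or 'down'")
        if self.sub_pathway not in _SUPER_OF_SUB:
            raise StudyValidationError(f"unknown sub-pathway {self.sub_pathway!r}")


#: Default planted effects: a 15-member all-increased branched-chain
#: amino-acid set and an 11-member all-decreased benzoate set at fold 3,
#: matching the scale of effects the pipeline is meant to detect.
DEFAULT_PLANTED = (
    PlantedSet("Leucine, Isoleucine and Valine Metabolism", 15, 3.0, "up"),
    PlantedSet("Benzoate Metabolism", 11, 3.0, "down"),
)


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator, with study-like defaults.

    n_samples is per group (five animals per arm).  A study of ten
    samples per tissue fits in a single instrument run, so n_batches
    defaults to 1; multi-batch designs draw metabolite-shared
    multiplicative log-normal batch factors (log-scale SD 0.5).  Note
    that per-batch median scaling divides by a median estimated from the
    batch's own samples, so batches much smaller than a real instrument
    run perturb the downstream test statistic's null distribution.  Peak
    areas sit around exp(15) with between-metabolite spread 1.5 and
    within-group residual SD 0.25 on the log scale; 10% of each
    metabolite's values are left-censored below its detection limit; 15%
    of compounds are unnamed; tissue_overlap_fraction is sized so the
    study-like panels share a core of 680 metabolites.
    """

    seed: int = 0
    n_metabolites: int = 900
    n_samples: int = 5
    n_batches: int = 1
    batch_effect_sd: float = 0.5
    base_log_mean: float = 15.0
    base_log_sd: float = 1.5
    noise_sd: float = 0.25
    dropout_quantile: float = 0.1
    unnamed_fraction: float = 0.15
    planted_dm_sets: tuple = DEFAULT_PLANTED
    tissue_overlap_fraction: float = 0.865

    def __post_init__(self) -> None:
        if self.n_metabolites <= 0 or self.n_samples < 2 or self.n_batches < 1:
            raise StudyValidationError("counts must be positive (>=2 samples/group)")
        if not 0.0 <= self.dropout_quantile <= 0.5:
            raise StudyValidationError("dropout_quantile must lie in [0, 0.5]")
        if not 0.0 < self.tissue_overlap_fraction <= 1.0:
            raise StudyValidationError("tissue_overlap_fraction must lie in (0, 1]")
        if not 0.0 <= self.unnamed_fraction < 1.0:
            raise StudyValidationError("unnamed_fraction must lie in [0, 1)")
        planted_total = sum(ps.size for ps in self.planted_dm_sets)
        if planted_total > self.n_metabolites:
            raise StudyValidationError("planted sets larger than n_metabolites")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        planted = d.pop("planted_dm_sets", None)
        if planted is not None:
            d["planted_dm_sets"] = tuple(
                ps if isinstance(ps, PlantedSet) else PlantedSet(**ps) for ps in planted
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_dm_sets"] = [dataclasses.asdict(ps) for ps in self.planted_dm_sets]
        return d


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Planted truth: per-metabolite direction/fold and per-pathway counts."""

    effects: pd.DataFrame  # index metabolite_id; columns direction, fold
    planted_pathways: pd.DataFrame  # index sub_pathway; columns n_up, n_down, fold

    def dm_ids(self) -> list:
        return list(self.effects.index[self.effects["direction"] != "null"])


def _stream(seed: int, *labels: str) -> np.random.Generator:
    """Independent RNG stream derived from (seed, labels) via stable CRC32."""
    entropy = [seed] + [zlib.crc32(lab.encode("utf-8")) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _make_ids(n: int) -> list:
    return [f"M{i + 1:05d}" for i in range(n)]


def _build_pool(config: SimulationConfig, ids: list) -> tuple[pd.DataFrame, GroundTruth]:
    """Annotations and true effects for a metabolite pool.

    Planted members occupy the first ids (so multi-tissue panels can put
    them in the shared core); the remainder is split into unnamed
    "X-#####" compounds and named nulls assigned random catalogue
    sub-pathways.
    """
    rng = _stream(config.seed, "annotations")
    n = len(ids)
    names, supers, subs, is_named = {}, {}, {}, {}
    direction = {mid: "null" for mid in ids}
    fold = {mid: 1.0 for mid in ids}
    cursor = 0
    planted_rows = []
    for ps in config.planted_dm_sets:
        members = ids[cursor : cursor + ps.size]
        cursor += ps.size
        for mid in members:
            subs[mid] = ps.sub_pathway
            supers[mid] = _SUPER_OF_SUB[ps.sub_pathway]
            is_named[mid] = True
            direction[mid] = ps.direction
            fold[mid] = ps.fold
        planted_rows.append(
            {
                "sub_pathway": ps.sub_pathway,
                "n_up": ps.size if ps.direction == "up" else 0,
                "n_down": ps.size if ps.direction == "down" else 0,
                "fold": ps.fold,
            }
        )
    rest = ids[cursor:]
    n_unnamed = min(int(round(config.unnamed_fraction * n)), len(rest))
    unnamed = set(rng.choice(np.array(rest), size=n_unnamed, replace=False)) if n_unnamed else set()
    named_subs = [s for s in _SUPER_OF_SUB if s != "Chemical"]
    for mid in rest:
        if mid in unnamed:
            subs[mid] = "Chemical"
            supers[mid] = "Xenobiotics"
            is_named[mid] = False
        else:
            sub = named_subs[int(rng.integers(len(named_subs)))]
            subs[mid] = sub
            supers[mid] = _SUPER_OF_SUB[sub]
            is_named[mid] = True
    for mid in ids:
        names[mid] = f"X-{20000 + int(mid[1:])}" if not is_named[mid] else f"compound-{mid[1:]}"
    annotations = pd.DataFrame(
        {
            "name": pd.Series(names),
            "super_pathway": pd.Series(supers),
            "sub_pathway": pd.Series(subs),
            "is_named": pd.Series(is_named),
        }
    ).loc[ids]
    annotations.index.name = "metabolite_id"
    truth = GroundTruth(
        effects=pd.DataFrame(
            {"direction": pd.Series(direction), "fold": pd.Series(fold)}
        ).loc[ids],
        planted_pathways=pd.DataFrame(
            planted_rows, columns=["sub_pathway", "n_up", "n_down", "fold"]
        ).set_index("sub_pathway"),
    )
    return annotations, truth


def _simulate_matrix(
    config: SimulationConfig, tissue: str, ids: list, effects: pd.DataFrame
) -> PeakAreaStudy:
    rng = _stream(config.seed, "tissue", tissue)
    n = len(ids)
    ns = config.n_samples
    sample_ids, groups, batches = [], [], []
    for g in GROUPS:
        for i in range(ns):
            sample_ids.append(f"{tissue}_{g}_{i + 1}")
            groups.append(g)
            # round-robin within each group keeps batches group-balanced
            batches.append(f"B{i % config.n_batches + 1}")
    group_arr = np.array(groups)
    batch_idx = np.array([int(b[1:]) - 1 for b in batches])
    base = rng.normal(config.base_log_mean, config.base_log_sd, size=n)
    batch_f = rng.normal(0.0, config.batch_effect_sd, size=config.n_batches)
    eff = effects.loc[ids]
    signed = np.where(
        eff["direction"] == "up", 1.0, np.where(eff["direction"] == "down", -1.0, 0.0)
    )
    log_fc = signed * np.log(eff["fold"].to_numpy())
    log_x = (
        base[:, None]
        + log_fc[:, None] * (group_arr == "D5")[None, :]
        + batch_f[batch_idx][None, :]
        + rng.normal(0.0, config.noise_sd, size=(n, 2 * ns))
    )
    x = np.exp(log_x)
    if config.dropout_quantile > 0:
        limits = np.quantile(x, config.dropout_quantile, axis=1)
        x = np.where(x < limits[:, None], np.nan, x)
    raw = pd.DataFrame(x, index=ids, columns=sample_ids)
    raw.index.name = "metabolite_id"
    meta_index = pd.Index(sample_ids)
    return PeakAreaStudy(
        tissue=tissue,
        raw=raw,
        group=pd.Series(groups, index=meta_index),
        batch=pd.Series(batches, index=meta_index),
    )


def simulate_study(
    config: SimulationConfig, tissue: str = "diaphragm"
) -> tuple[PeakAreaStudy, pd.DataFrame, GroundTruth]:
    """One tissue's peak-area study + annotations + planted ground truth."""
    ids = _make_ids(config.n_metabolites)
    annotations, truth = _build_pool(config, ids)
    study = _simulate_matrix(config, tissue, ids, truth.effects)
    return study, annotations, truth


def simulate_multi_tissue(
    config: SimulationConfig, panel_sizes: dict | None = None
) -> tuple[dict, pd.DataFrame, dict]:
    """Studies for several tissues with a shared detection core.

    ``panel_sizes`` maps tissue -> number of detected metabolites
    (defaults to the study-like 817/786/941 panels).  A core of
    round(tissue_overlap_fraction * min(panel)) metabolites is detected
    in every tissue; the remainder of each panel is tissue-private, so
    the 3-way intersection of detection sets equals the core size by
    construction.  Returns ({tissue: study}, pooled annotations,
    {tissue: ground truth restricted to its panel}).
    """
    if panel_sizes is None:
        panel_sizes = dict(DEFAULT_PANEL_SIZES)
    if not panel_sizes:
        raise StudyValidationError("panel_sizes is empty")
    n_core = int(round(config.tissue_overlap_fraction * min(panel_sizes.values())))
    planted_total = sum(ps.size for ps in config.planted_dm_sets)
    if planted_total > n_core:
        raise StudyValidationError("planted sets do not fit in the shared core")
    privates = {t: s - n_core for t, s in panel_sizes.items()}
    if any(p < 0 for p in privates.values()):
        raise StudyValidationError("core larger than a tissue panel")
    total = n_core + sum(privates.values())
    ids = _make_ids(total)
    annotations, truth = _build_pool(config, ids)
    core_ids = ids[:n_core]
    studies, truths = {}, {}
    offset = n_core
    for tissue, extra in privates.items():
        panel = core_ids + ids[offset : offset + extra]
        offset += extra
        studies[tissue] = _simulate_matrix(config, tissue, panel, truth.effects)
        truths[tissue] = GroundTruth(
            effects=truth.effects.loc[panel],
            planted_pathways=truth.planted_pathways,
        )
    return studies, annotations, truths


def simulate_edge_list(
    metabolite_ids,
    seed: int,
    hub_spec=(),
    mean_degree: float = 2.0,
    hub_fraction: float = 0.6,
) -> pd.DataFrame:
    """STITCH-style edge list: sparse background plus designated hubs.

    Background edges form an Erdős–Rényi-like graph with the given mean
    degree and confidence scores 150-1000; each metabolite in
    ``hub_spec`` additionally connects to ``hub_fraction`` of all other
    nodes at high confidence (700-1000), giving hubs a degree far above
    the background median.  No self-loops, no duplicate pairs
    (duplicates keep the maximum score).
    """
    ids = list(metabolite_ids)
    n = len(ids)
    if n < 2:
        raise StudyValidationError("need at least 2 metabolites for an edge list")
    unknown = set(hub_spec) - set(ids)
    if unknown:
        raise StudyValidationError(f"hub_spec outside metabolite ids: {sorted(unknown)}")
    rng = _stream(seed, "edges")
    p = min(1.0, mean_degree / (n - 1))
    upper = np.triu(rng.random((n, n)) < p, k=1)
    edges: dict = {}
    for i, j in zip(*np.nonzero(upper)):
        edges[(ids[i], ids[j])] = int(rng.integers(150, 1001))
    for hub in hub_spec:
        others = [mid for mid in ids if mid != hub]
        k = max(1, int(math.ceil(hub_fraction * len(others))))
        partners = rng.choice(np.array(others), size=k, replace=False)
        for other in partners:
            key = tuple(sorted((hub, str(other))))
            score = int(rng.integers(700, 1001))
            edges[key] = max(edges.get(key, 0), score)
    rows = [
        {"chemical_a": a, "chemical_b": b, "combined_score": s}
        for (a, b), s in sorted(edges.items())
    ]
    return pd.DataFrame(rows, columns=["chemical_a", "chemical_b", "combined_score"])
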
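"""Pathway zscore, Enrichment Value, signature calling and MSEA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, assume, strategies as st
from scipy.stats import hypergeom

from metabosig import differential, enrichment, io, preprocess, synthetic


class TestPathwayZscore:
    # every (up, down) split whose zscore the study prints, incl. the two
    # splits uniquely implied by their (count, zscore) pairs
    PRINTED = [
        (0, 11, -3.32),  # benzoate, diaphragm
        (1, 12, -3.05),  # dipeptide, diaphragm (13 DMs force 1 up / 12 down)
        (15, 0, 3.87),   # branched-chain amino acids, intercostals
        (10, 0, 3.16),   # purine (hypo)xanthine/inosine, intercostals
        (10, 0, 3.16),   # monoacylglycerol, intercostals
        (7, 0, 2.65),    # phosphatidylinositol, intercostals
        (12, 0, 3.46),   # polyunsaturated acyl carnitines, lung
        (8, 0, 2.83),    # long-chain saturated acyl carnitines, lung
        (0, 9, -3.00),   # benzoate, lung
        (1, 9, -2.53),   # food component/plant, lung (10 DMs force 1 up / 9 down)
    ]

    @pytest.mark.parametrize("up, down, expected", PRINTED)
    def test_reported_values_reproduce_under_sqrt_count(self, up, down, expected):
        assert round(enrichment.pathway_zscore(up, down), 2) == expected

    def test_count_denominator_option(self):
        assert enrichment.pathway_zscore(15, 0, denominator="count") == 1.0
        assert enrichment.pathway_zscore(3, 9, denominator="count") == -0.5

    def test_balanced_pathway_is_zero(self):
        assert enrichment.pathway_zscore(4, 4) == 0.0

    def test_empty_pathway_rejected(self):
        with pytest.raises(io.StudyValidationError):
            enrichment.pathway_zscore(0, 0)

    @given(up=st.integers(0, 200), down=st.integers(0, 200))
    def test_magnitude_bounded_by_sqrt_count(self, up, down):
        assume(up + down >= 1)
        z = enrichment.pathway_zscore(up, down)
        k = up + down
        assert abs(z) <= math.sqrt(k) + 1e-12
        unidirectional = up == 0 or down == 0
        assert (abs(abs(z) - math.sqrt(k)) < 1e-12) == unidirectional

    @given(up=st.integers(0, 50), down=st.integers(0, 50), shift=st.integers(1, 10))
    def test_monotone_in_direction_imbalance_at_fixed_count(self, up, down, shift):
        assume(up + down >= 1 and down - shift >= 0)
        # moving `shift` DMs from down to up keeps the count, raises the zscore
        assert enrichment.pathway_zscore(up + shift, down - shift) > enrichment.pathway_zscore(up, down)


class TestEnrichmentValue:
    def test_equal_proportions_give_one(self):
        assert enrichment.enrichment_value(1, 2, 10, 20) == pytest.approx(1.0)

    def test_hand_evaluated_table(self):
        # (12/20) / ((290-12)/(941-20)) = 0.6 / 0.30184... = 1.9877...
        ev = enrichment.enrichment_value(12, 20, 290, 941)
        assert round(ev, 2) == 1.99

    def test_all_dms_in_pathway_is_infinite_sentinel(self):
        assert math.isinf(enrichment.enrichment_value(5, 10, 5, 100))

    def test_degenerate_margins_rejected(self):
        with pytest.raises(io.StudyValidationError):
            enrichment.enrichment_value(0, 0, 10, 100)
        with pytest.raises(io.StudyValidationError):
            enrichment.enrichment_value(3, 100, 10, 100)

    @given(
        k=st.integers(1, 30), extra_m=st.integers(1, 30),
        extra_n=st.integers(1, 50), extra_noise=st.integers(1, 100),
        factor=st.integers(2, 5),
    )
    def test_scale_consistency(self, k, extra_m, extra_n, extra_noise, factor):
        """Multiplying k, m, n-k and N-m by one factor leaves EV unchanged."""
        m = k + extra_m
        n = k + extra_n
        N = m + (n - k) + extra_noise
        ev1 = enrichment.enrichment_value(k, m, n, N)
        ev2 = enrichment.enrichment_value(
            factor * k, factor * m, factor * n, factor * (N - m) + factor * m
        )
        assert ev2 == pytest.approx(ev1, rel=1e-12)

    @given(
        N=st.integers(10, 200), m_frac=st.floats(0.05, 0.9),
        n_frac=st.floats(0.05, 0.9), k_frac=st.floats(0.0, 1.0),
    )
    def test_hypergeometric_tail_cross_check(self, N, m_frac, n_frac, k_frac):
        """EV > 1 iff the enrichment tail is lighter than the depletion tail.

        The equivalence holds whenever k is at least one unit away from
        its null expectation m*n/N; exactly at the expectation the two
        discrete tail probabilities may straddle either way.
        """
        m = max(1, int(m_frac * N))
        assume(N > m)
        n = max(1, int(n_frac * N))
        lo, hi = max(0, n - (N - m)), min(m, n)
        k = lo + int(round(k_frac * (hi - lo)))
        assume(n > k)
        assume(abs(k - m * n / N) >= 1.0)
        ev = enrichment.enrichment_value(k, m, n, N)
        p_enrich = hypergeom.sf(k - 1, N, n, m)
        p_deplete = hypergeom.cdf(k, N, n, m)
        assert (ev > 1) == (p_enrich < p_deplete)


def _fake_results(ids, dm_dirs):
    """Differential table with given {id: direction-or-None} DM spec."""
    frame = pd.DataFrame(index=pd.Index(ids, name="metabolite_id"))
    frame["p_value"] = [0.01 if dm_dirs.get(i) else 0.5 for i in ids]
    frame["fold_change"] = [
        2.0 if dm_dirs.get(i) == "up" else (0.4 if dm_dirs.get(i) == "down" else 1.05)
        for i in ids
    ]
    frame["abs_fold_change"] = np.maximum(frame.fold_change, 1 / frame.fold_change)
    frame["log2_fold_change"] = np.log2(frame.fold_change)
    frame["direction"] = np.where(frame.fold_change >= 1, "up", "down")
    frame["is_dm"] = [bool(dm_dirs.get(i)) for i in ids]
    return frame


def _annotations(spec):
    """spec: {id: (sub_pathway, is_named)}; super looked up from the catalog."""
    rows = {
        mid: {
            "name": mid if named else f"X-{1000 + i}",
            "super_pathway": synthetic._SUPER_OF_SUB[sub],
            "sub_pathway": sub,
            "is_named": named,
        }
        for i, (mid, (sub, named)) in enumerate(spec.items())
    }
    ann = pd.DataFrame.from_dict(rows, orient="index")
    ann.index.name = "metabolite_id"
    return ann


class TestScoreAllPathways:
    def test_counts_restricted_to_named_background(self):
        ids = [f"m{i}" for i in range(10)]
        spec = {i: ("Dipeptide", True) for i in ids[:4]}
        spec["m1"] = ("Dipeptide", False)  # unnamed member: out of m and k
        spec.update({i: ("TCA Cycle", True) for i in ids[4:]})
        dm_dirs = {"m0": "down", "m1": "down", "m5": "up"}
        scores = enrichment.score_all_pathways(_fake_results(ids, dm_dirs), _annotations(spec))
        row = scores.loc["Dipeptide"]
        assert row["m"] == 3 and row["k"] == 1 and row["down"] == 1
        assert row["N"] == 9 and row["n"] == 2

    def test_dm_without_annotation_listed_in_error(self):
        ids = ["m0", "m1", "m2"]
        ann = _annotations({"m0": ("Dipeptide", True), "m1": ("Dipeptide", True)})
        with pytest.raises(io.StudyValidationError, match="m2"):
            enrichment.score_all_pathways(_fake_results(ids, {"m2": "up"}), ann)

    def test_signature_requires_all_three_cutoffs(self):
        ids = [f"m{i}" for i in range(40)]
        spec = {i: ("Benzoate Metabolism", True) for i in ids[:11]}
        spec.update({i: ("Monoacylglycerol", True) for i in ids[11:15]})
        spec.update({i: ("TCA Cycle", True) for i in ids[15:]})
        dm_dirs = {i: "down" for i in ids[:11]}          # 11-member unidirectional set
        dm_dirs.update({i: "up" for i in ids[11:15]})    # k=4: fails the k cutoff
        scores = enrichment.score_all_pathways(_fake_results(ids, dm_dirs), _annotations(spec))
        benzoate = scores.loc["Benzoate Metabolism"]
        assert round(benzoate["zscore"], 2) == -3.32
        assert benzoate["is_signature"]
        assert not scores.at["Monoacylglycerol", "is_signature"]

    def test_background_share_pathway_is_not_signature(self):
        # DM share inside the pathway equals the share outside -> EV = 1
        ids = [f"m{i}" for i in range(30)]
        spec = {i: ("Dipeptide", True) for i in ids[:10]}
        spec.update({i: ("TCA Cycle", True) for i in ids[10:]})
        dm_dirs = {i: "down" for i in ids[:5]}    # 5/10 in pathway
        dm_dirs.update({i: "down" for i in ids[10:20]})  # 10/20 outside
        scores = enrichment.score_all_pathways(_fake_results(ids, dm_dirs), _annotations(spec))
        assert scores.at["Dipeptide", "enrichment_value"] == pytest.approx(1.0)
        assert not scores.at["Dipeptide", "is_signature"]

    def test_sub_threshold_pathways_still_listed(self):
        ids = [f"m{i}" for i in range(12)]
        spec = {i: ("TCA Cycle", True) for i in ids[:4]}
        spec.update({i: ("Dipeptide", True) for i in ids[4:]})
        scores = enrichment.score_all_pathways(
            _fake_results(ids, {"m0": "up", "m1": "up"}), _annotations(spec)
        )
        assert "TCA Cycle" in scores.index
        assert not scores.at["TCA Cycle", "is_signature"]


class TestMsea:
    @staticmethod
    def _stats(n=60, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.normal(size=n), index=[f"m{i:03d}" for i in range(n)])

    def test_top_ranked_set_is_enriched(self):
        stats = self._stats()
        top10 = set(stats.sort_values(ascending=False).index[:10])
        out = enrichment.msea(stats, {"top": top10}, n_perm=200, seed=1)
        assert out.at["top", "es"] > 0
        assert out.at["top", "p_value"] < 0.05
        assert out.at["top", "nes"] > 0

    def test_whole_background_set_is_degenerate(self):
        stats = self._stats()
        out = enrichment.msea(stats, {"all": set(stats.index)}, n_perm=100, seed=1)
        assert out.at["all", "es"] == 0.0
        assert bool(out.at["all", "degenerate"])

    def test_sets_below_two_members_skipped(self, caplog):
        stats = self._stats()
        with caplog.at_level("WARNING"):
            out = enrichment.msea(
                stats, {"tiny": {stats.index[0]}, "ok": set(stats.index[:5])},
                n_perm=100, seed=1,
            )
        assert list(out.index) == ["ok"]
        assert "tiny" in caplog.text

    def test_deterministic_given_seed(self):
        stats = self._stats()
        sets = {"s1": set(stats.index[:8]), "s2": set(stats.index[20:30])}
        a = enrichment.msea(stats, sets, n_perm=150, seed=7)
        b = enrichment.msea(stats, sets, n_perm=150, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_nes_sign_matches_es_sign(self):
        stats = self._stats(seed=3)
        sets = {f"s{i}": set(stats.sample(8, random_state=i).index) for i in range(6)}
        out = enrichment.msea(stats, sets, n_perm=150, seed=2)
        assert (np.sign(out["nes"]) == np.sign(out["es"])).all()

    def test_random_sets_give_roughly_uniform_p(self):
        """Null sets: p-values not concentrated near 0 (measured band)."""
        rng = np.random.default_rng(0)
        ps = []
        for rep in range(200):
            stats = self._stats(seed=1000 + rep)
            members = set(rng.choice(stats.index.to_numpy(), size=8, replace=False))
            out = enrichment.msea(stats, {"null": members}, n_perm=100, seed=rep)
            ps.append(out.at["null", "p_value"])
        ps = np.asarray(ps)
        assert (ps < 0.05).mean() <= 0.10
        assert 0.40 < ps.mean() < 0.65


class TestCompareTissues:
    @staticmethod
    def _table(rows):
        frame = pd.DataFrame(rows, columns=["sub_pathway", "nes", "p_value", "n_dm_in_set"])
        return frame.set_index("sub_pathway")

    def test_pathway_missing_from_one_tissue_marked_not_detected(self):
        tables = {
            "diaphragm": self._table([("Dipeptide", -2.1, 0.01, 9)]),
            "intercostal": self._table([("Dipeptide", -1.0, 0.3, 3)]),
            "lung": self._table([("TCA Cycle", 1.0, 0.2, 2)]),
        }
        out = enrichment.compare_tissues(tables)
        assert list(out.index) == ["Dipeptide"]
        assert not out.at["Dipeptide", "lung_detected"]
        assert math.isnan(out.at["Dipeptide", "lung_nes"])
        # detected but not significant is distinct from not detected
        assert out.at["Dipeptide", "intercostal_detected"]
        assert out.at["Dipeptide", "intercostal_p"] == 0.3

    def test_single_tissue_is_identity_after_filter(self):
        table = self._table([("A" , 1.0, 0.01, 7), ("B", 0.5, 0.5, 2)])
        table.index.name = "sub_pathway"
        out = enrichment.compare_tissues({"lung": table})
        assert list(out.index) == ["A"]
        assert out.at["A", "lung_nes"] == 1.0

    def test_k_exactly_five_in_one_tissue_retained(self):
        tables = {
            "a": self._table([("P", 1.0, 0.2, 5)]),
            "b": self._table([("P", 1.0, 0.2, 1)]),
        }
        assert list(enrichment.compare_tissues(tables).index) == ["P"]
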
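"""LOD likelihoods, critical-LOD calibration, assignment filters, weighting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from larvorigin.genio import MISSING, AlleleFrequencyTable, allele_frequencies
from larvorigin.parentage import (
    CalibrationError,
    ParentageConfig,
    ParentageModel,
    assign_parentage,
    calibrate_critical_lod,
    locus_lod,
    pair_lod,
    single_parent_transition,
    source_weight_table,
    weighted_source_proportions,
)
from larvorigin.synthgen import (
    CohortSpec,
    PopulationModel,
    make_allele_freqs,
    simulate_adults,
    simulate_cohorts,
)
from conftest import make_table

FREQS = {1: 0.6, 2: 0.4}  # alleles A=1, B=2


class TestTransitionProbability:
    @pytest.mark.parametrize(
        "off,par,expected",
        [
            ((1, 2), (1, 1), 0.4),   # parent AA, offspring AB
            ((1, 2), (1, 2), 0.5),   # parent AB, offspring AB
            ((2, 2), (1, 1), 0.0),   # exclusion
            ((1, 1), (1, 1), 0.6),   # parent AA, offspring AA
            ((1, 1), (1, 2), 0.3),   # parent AB transmits A w.p. 1/2
        ],
    )
    def test_hand_enumeration(self, off, par, expected):
        assert single_parent_transition(off, par, FREQS) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.data())
    def test_transition_is_probability_distribution(self, data):
        # summing T over all unordered offspring genotypes gives 1
        k = data.draw(st.integers(2, 5))
        raw = data.draw(
            st.lists(st.floats(0.05, 1.0), min_size=k, max_size=k)
        )
        p = np.array(raw) / np.sum(raw)
        freqs = {i + 1: float(p[i]) for i in range(k)}
        par = (
            data.draw(st.integers(1, k)),
            data.draw(st.integers(1, k)),
        )
        total = sum(
            single_parent_transition((a, b), par, freqs)
            for a in range(1, k + 1)
            for b in range(a, k + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-12)


class TestLocusLod:
    def test_closed_forms(self):
        lod, mm = locus_lod((1, 1), (1, 1), FREQS, eps=0.0)
        assert lod == pytest.approx(math.log(0.6 / 0.36), abs=1e-12) and not mm
        lod, mm = locus_lod((1, 2), (1, 1), FREQS, eps=0.0)
        assert lod == pytest.approx(math.log(0.4 / 0.48), abs=1e-12) and not mm

    def test_mismatch_mixture_floor(self):
        lod, mm = locus_lod((2, 2), (1, 1), FREQS, eps=0.01)
        assert mm and lod == pytest.approx(math.log(0.01), abs=1e-12)

    def test_eps_zero_mismatch_is_minus_inf(self):
        lod, mm = locus_lod((2, 2), (1, 1), FREQS, eps=0.0)
        assert mm and lod == -math.inf


class TestPairLod:
    def _freq_table(self, per_locus):
        return AlleleFrequencyTable(
            loci=list(per_locus),
            groups=["pool"],
            freqs={"pool": dict(per_locus)},
            gene_counts={"pool": {k: 100 for k in per_locus}},
        )

    def test_additivity_two_loci(self):
        freqs = self._freq_table({"L1": dict(FREQS), "L2": dict(FREQS)})
        cfg = ParentageConfig(error_rate=0.0)
        off = ("o", np.array([[1, 1], [1, 2]], dtype=np.int32))
        cand = ("c", np.array([[1, 1], [1, 1]], dtype=np.int32))
        score = pair_lod(off, cand, ["L1", "L2"], freqs, cfg)
        expected = math.log(0.6 / 0.36) + math.log(0.4 / 0.48)
        assert score.lod == pytest.approx(expected, abs=1e-12)
        assert score.loci_compared == 2 and score.mismatches == 0

    def test_missing_loci_skipped(self):
        freqs = self._freq_table({"L1": dict(FREQS), "L2": dict(FREQS)})
        cfg = ParentageConfig()
        off = ("o", np.array([[MISSING, MISSING], [MISSING, MISSING]], dtype=np.int32))
        cand = ("c", np.array([[1, 1], [1, 2]], dtype=np.int32))
        score = pair_lod(off, cand, ["L1", "L2"], freqs, cfg)
        assert score.loci_compared == 0 and score.lod == 0.0

    def test_true_parent_no_mismatches(self, small_freqs, small_adults):
        spec = CohortSpec(
            sites=("S",), months=("m01",), n_per_month=25,
            source_mixture={p: 0.25 for p in small_freqs.groups},
            prop_parent_sampled=1.0, error_rate=0.0, missing_rate=0.0,
        )
        cohorts = simulate_cohorts(small_freqs, small_adults, spec, seed=44)
        pooled = allele_frequencies(small_adults, grouping=None).pooled()
        cfg = ParentageConfig(error_rate=0.0)
        idx = {i: k for k, i in enumerate(small_adults.ids)}
        for i in range(cohorts.n_individuals):
            parent = cohorts.metadata["true_parent_id"].iloc[i]
            score = pair_lod(
                (cohorts.ids[i], cohorts.calls[i]),
                (parent, small_adults.calls[idx[parent]]),
                cohorts.loci, pooled, cfg,
            )
            assert score.mismatches == 0


class TestCalibration:
    def test_always_sampled_parent_wins(self, small_freqs):
        adults = simulate_adults(small_freqs, {p: 30 for p in small_freqs.groups}, seed=1)
        pooled = allele_frequencies(adults, grouping=None).pooled()
        cfg = ParentageConfig(
            error_rate=0.0, prop_sampled=1.0, n_sim_offspring=400,
            n_candidates=50, seed=2,
        )
        critical, curve = calibrate_critical_lod(pooled, cfg)
        conf0 = curve.loc[curve["threshold"] == 0.0, "confidence"].iloc[0]
        assert conf0 >= 0.99
        assert critical <= 0.1

    def test_no_sampled_parents_errors(self, small_freqs):
        adults = simulate_adults(small_freqs, {p: 30 for p in small_freqs.groups}, seed=3)
        pooled = allele_frequencies(adults, grouping=None).pooled()
        cfg = ParentageConfig(prop_sampled=0.0, n_sim_offspring=300, seed=4)
        with pytest.raises(CalibrationError) as exc:
            calibrate_critical_lod(pooled, cfg)
        assert exc.value.curve is not None

    def test_determinism_under_seed(self, small_freqs):
        adults = simulate_adults(small_freqs, {p: 30 for p in small_freqs.groups}, seed=5)
        pooled = allele_frequencies(adults, grouping=None).pooled()
        cfg = ParentageConfig(n_sim_offspring=500, seed=6)
        c1, curve1 = calibrate_critical_lod(pooled, cfg)
        c2, curve2 = calibrate_critical_lod(pooled, cfg)
        assert c1 == c2
        pd.testing.assert_frame_equal(curve1, curve2)

    def test_confidence_curve_nondecreasing(self, small_freqs):
        adults = simulate_adults(small_freqs, {p: 30 for p in small_freqs.groups}, seed=7)
        pooled = allele_frequencies(adults, grouping=None).pooled()
        cfg = ParentageConfig(n_sim_offspring=500, prop_sampled=0.1, seed=8)
        _, curve = calibrate_critical_lod(pooled, cfg)
        s = curve["confidence_smoothed"].to_numpy()
        assert np.all(np.diff(s) >= -1e-12)


class TestAssignment:
    def test_few_loci_rejected(self, small_freqs, small_adults):
        spec = CohortSpec(
            sites=("S",), months=("m01",), n_per_month=10,
            source_mixture={p: 0.25 for p in small_freqs.groups},
            prop_parent_sampled=1.0, error_rate=0.0, missing_rate=0.0,
        )
        cohorts = simulate_cohorts(small_freqs, small_adults, spec, seed=20)
        # keep only 5 typed loci on the first postlarva
        cohorts.calls[0, 5:, :] = MISSING
        pooled = allele_frequencies(small_adults, grouping=None).pooled()
        cfg = ParentageConfig(critical_lod=0.0)
        res = assign_parentage(cohorts, small_adults, pooled, cfg)
        first = res.iloc[0]
        assert not first["accepted"] and first["reason"] == "few_loci"

    def test_many_mismatches_never_accepted(self):
        # candidate homozygous for an allele the offspring lacks at 3 loci
        loci = [f"L{j}" for j in range(12)]
        freqs = AlleleFrequencyTable(
            loci=loci, groups=["pool"],
            freqs={"pool": {l: {1: 0.5, 2: 0.3, 3: 0.2} for l in loci}},
            gene_counts={"pool": {l: 100 for l in loci}},
        )
        off_calls = np.tile(np.array([[1, 1]], dtype=np.int32), (12, 1))
        cand_calls = off_calls.copy()
        cand_calls[:3] = [2, 2]  # 3 Mendelian exclusions
        postlarvae = make_table(loci, {"pl": [tuple(map(tuple, off_calls))]})
        adults = make_table(loci, {"ad": [tuple(map(tuple, cand_calls))]})
        cfg = ParentageConfig(critical_lod=-1e9, error_rate=0.01, min_loci_compared=5)
        res = assign_parentage(postlarvae, adults, freqs, cfg)
        assert not res["accepted"].iloc[0]
        assert res["reason"].iloc[0] == "many_mismatches"

    def test_tie_between_identical_candidates(self, small_freqs, small_adults):
        from larvorigin.genio import GenotypeTable

        twin = GenotypeTable(
            loci=list(small_adults.loci),
            ids=["orig", "twin"],
            calls=np.stack([small_adults.calls[0], small_adults.calls[0]]),
            metadata=pd.DataFrame(
                {"pop": [small_adults.metadata["pop"].iloc[0]] * 2},
                index=pd.Index(["orig", "twin"], name="id"),
            ),
        )
        spec = CohortSpec(
            sites=("S",), months=("m01",), n_per_month=5,
            source_mixture={small_adults.metadata['pop'].iloc[0]: 1.0},
            prop_parent_sampled=0.0, error_rate=0.0, missing_rate=0.0,
        )
        cohorts = simulate_cohorts(small_freqs, small_adults, spec, seed=21)
        pooled = allele_frequencies(small_adults, grouping=None).pooled()
        cfg = ParentageConfig(critical_lod=-1e9, min_loci_compared=1, max_mismatches=99)
        res = assign_parentage(cohorts, twin, pooled, cfg)
        assert (res["reason"] == "tie").all()

    def test_empty_adults_rejected(self, small_cohorts, small_freqs):
        pooled = small_freqs.pooled()
        empty = small_cohorts.subset([])
        with pytest.raises(ValueError):
            assign_parentage(small_cohorts, empty, pooled, ParentageConfig(critical_lod=1.0))


class TestWeightedSourceProportions:
    def test_published_worked_examples(self):
        counts = pd.DataFrame(
            {"DR": [21, 0], "BZ": [12, 8]}, index=["LongKey", "BigMunson"]
        )
        t = source_weight_table(
            counts, {"DR": 36, "BZ": 48}, {"LongKey": 1134, "BigMunson": 896}
        )
        totals = t[t["site"] == "total"].set_index("population")["total_weighted"]
        assert totals["DR"] == pytest.approx(0.0514, abs=5e-5)
        assert totals["BZ"] == pytest.approx(0.0406, abs=5e-5)

    def test_zero_assignments_all_zero(self):
        counts = pd.DataFrame({"A": [0, 0]}, index=["s1", "s2"])
        t = source_weight_table(counts, {"A": 10}, {"s1": 5, "s2": 5})
        assert (t[t["site"] != "total"]["weighted"] == 0).all()
        assert t[t["site"] == "total"]["total_weighted"].iloc[0] == 0

    def test_unknown_keys_rejected(self):
        counts = pd.DataFrame({"A": [1]}, index=["s1"])
        with pytest.raises(KeyError):
            source_weight_table(counts, {"B": 10}, {"s1": 5})
        with pytest.raises(KeyError):
            source_weight_table(counts, {"A": 10}, {"s2": 5})

    def test_aggregation_from_assignments(self):
        assignments = pd.DataFrame(
            {
                "offspring_id": ["o1", "o2", "o3"],
                "site": ["s1", "s1", "s2"],
                "population": ["A", "A", "B"],
                "accepted": [True, True, False],
            }
        )
        t = weighted_source_proportions(
            assignments, {"A": 4, "B": 2}, {"s1": 10, "s2": 20}
        )
        a_s1 = t[(t["population"] == "A") & (t["site"] == "s1")]
        assert a_s1["count"].iloc[0] == 2
        assert a_s1["weighted"].iloc[0] == pytest.approx(100 * 2 / (4 * 10))
        # rejected assignment contributes nothing
        assert t[(t["population"] == "B") & (t["site"] == "s2")]["count"].iloc[0] == 0


class TestModelResultsSurface:
    def test_fit_summary_and_weights(self, small_freqs, small_adults, small_cohorts):
        cfg = ParentageConfig(n_sim_offspring=600, n_candidates=40, seed=30)
        res = ParentageModel(small_cohorts, small_adults, cfg).fit()
        text = res.summary()
        assert "critical LOD" in text and "resolved assignments" in text
        weights = res.source_weights()
        assert set(weights["population"]) == set(small_freqs.groups)
        totals = weights[weights["site"] == "total"]["total_weighted"]
        assert (totals >= 0).all()
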
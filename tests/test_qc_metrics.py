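"""FPCM, FNCM, the branch decision, orphan removal and ranking."""

import numpy as np
import pytest

from peakqc.errors import DegenerateInputError, UndefinedMetricError
from peakqc.peak_io import GenomicInterval, MetaSet, PeakDataset
from peakqc.qc_metrics import (
    assess,
    assess_frequencies,
    expected_orphans,
    fncm_modified,
    fncm_unmodified,
    fpcm,
    fpcm_from_p_false,
    rank_callers,
    remove_orphans,
)
from peakqc.region_merge import (
    PivotalFrequencies,
    merge_meta_set,
    pivotal_frequencies,
)
from peakqc.synthetic import SimulationConfig, simulate_meta_set

F_CTCF_1 = PivotalFrequencies(f=[5534, 4542, 2482, 32141], n=44699)
F_CTCF_2 = PivotalFrequencies(f=[46452, 5797, 12012, 28175], n=92436)


class TestExpectedOrphans:
    def test_direct_evaluation(self):
        # 2 * 4542^2 / (3 * 2482)
        assert expected_orphans(4542, 2482) == pytest.approx(5541.17, abs=0.01)
        assert expected_orphans(3, 2) == pytest.approx(3.0)
        assert expected_orphans(0, 5) == 0.0

    def test_f3_zero_with_doubletons_undefined(self):
        with pytest.raises(UndefinedMetricError):
            expected_orphans(10, 0)


class TestFpcm:
    def test_first_worked_example_below_threshold(self):
        res = fpcm(F_CTCF_1)
        assert res.fpcm == pytest.approx(0.998, abs=0.001)
        assert not res.exceeds_threshold
        assert res.p_false == 0.0  # FPCM < 1 clamps p_false

    def test_second_worked_example_exceeds_threshold(self):
        res = fpcm(F_CTCF_2)
        assert res.fpcm == pytest.approx(24.901, abs=0.02)
        assert res.exceeds_threshold
        assert res.p_false == pytest.approx(1 - 1 / res.fpcm)

    @pytest.mark.parametrize("p_false,expected", [
        (0.5, 2.0), (2 / 3, 3.0), (0.98, 50.0),
    ])
    def test_p_false_fpcm_duality(self, p_false, expected):
        assert fpcm_from_p_false(p_false) == pytest.approx(expected)

    def test_balanced_frequencies_give_fpcm_one(self):
        # construct f1 = 2 f2^2 / (3 f3) exactly: f2=30, f3=20 -> f1=30
        freqs = PivotalFrequencies(f=[30, 30, 20, 100], n=180)
        res = fpcm(freqs)
        assert res.fpcm == pytest.approx(1.0, rel=1e-12)

    def test_no_orphans_is_zero_with_note(self):
        res = fpcm(PivotalFrequencies(f=[0, 10, 10, 30], n=50))
        assert res.fpcm == 0.0 and res.p_false == 0.0
        assert "no orphans" in res.note

    def test_degenerate_frequencies_raise(self):
        with pytest.raises(UndefinedMetricError):
            fpcm(PivotalFrequencies(f=[10, 0, 0, 5], n=15))
        with pytest.raises(UndefinedMetricError):
            fpcm(PivotalFrequencies(f=[5, 3], n=8))

    def test_threshold_is_configurable(self):
        freqs = PivotalFrequencies(f=[100, 20, 10, 5], n=135)
        lo = fpcm(freqs, threshold=2.0)
        hi = fpcm(freqs, threshold=1000.0)
        assert lo.exceeds_threshold and not hi.exceeds_threshold


class TestFncmUnmodified:
    def test_worked_example_mean_of_four(self):
        res = fncm_unmodified(None, F_CTCF_1,
                              sizes={"GEM": 41827, "MACS": 45318,
                                     "PICS": 78011, "SISSRs": 43215})
        assert res.n_estimate == pytest.approx(49525, abs=1)
        assert res.branch == "no_modification"
        assert set(res.estimator_values) == \
            {"chao", "lanumteang_bohning", "zelterman", "ztp_ml"}
        assert res.per_dataset["MACS"] == pytest.approx(45318 / 49524.63,
                                                        rel=1e-6)

    def test_identical_meta_set_estimators(self):
        """All regions seen by all k datasets: the three closed-form
        estimators return exactly m; the ZTP MLE allows for unseen
        zero-count regions and returns m/(1 - e^-lambda*) with lambda*
        solving the mean equation at k — slightly above m. FNCM is
        therefore just below 1, not exactly 1."""
        from peakqc.popsize_estimators import ztp_mle

        m = 40
        freqs = PivotalFrequencies(f=[0, 0, 0, m], n=m)
        sizes = {f"D{i}": m for i in range(4)}
        res = fncm_unmodified(None, freqs, sizes=sizes)
        ev = res.estimator_values
        assert ev["chao"] == ev["lanumteang_bohning"] == ev["zelterman"] == m
        _, e_ml = ztp_mle(freqs)
        assert ev["ztp_ml"] == pytest.approx(e_ml.value)
        assert e_ml.value > m
        expected_n1e = (3 * m + e_ml.value) / 4
        assert res.n_estimate == pytest.approx(expected_n1e, rel=1e-12)
        assert all(v == pytest.approx(m / expected_n1e)
                   for v in res.per_dataset.values())
        assert all(0.98 < v < 1.0 for v in res.per_dataset.values())

    def test_fncm_above_one_warns_not_clamps(self):
        freqs = PivotalFrequencies(f=[0, 0, 0, 10], n=10)
        with pytest.warns(UserWarning, match="> 1"):
            res = fncm_unmodified(None, freqs, sizes={"big": 50})
        assert res.per_dataset["big"] == pytest.approx(50 / res.n_estimate)
        assert res.per_dataset["big"] > 1.0


class TestFncmModified:
    def test_published_chapman_sample_mean_after_outlier(self):
        from peakqc.popsize_estimators import leave_one_out_outliers
        kept, removed = leave_one_out_outliers(
            [45996, 46011, 43591, 45609, 45783, 47198])
        assert removed == [43591.0]
        assert np.mean(kept) == pytest.approx(46119, abs=1)

    def test_identical_datasets_all_fncm_one(self):
        ivs = [GenomicInterval("chr1", i * 500, i * 500 + 100)
               for i in range(30)]
        meta = MetaSet([PeakDataset(f"D{i}", list(ivs)) for i in range(4)])
        res = fncm_modified(meta)
        assert res.branch == "orphans_removed"
        assert res.n_estimate == pytest.approx(30.0)
        assert all(v == pytest.approx(1.0) for v in res.per_dataset.values())
        assert len(res.estimator_values) == 6  # k(k-1)/2 pairs

    def test_dropout_caller_has_proportionally_lower_fncm(self):
        # caller D4 detects only half the regions
        truth = [GenomicInterval("chr1", i * 1000, i * 1000 + 150)
                 for i in range(200)]
        full = list(truth)
        half = truth[::2]
        meta = MetaSet([
            PeakDataset("D1", full), PeakDataset("D2", full),
            PeakDataset("D3", full), PeakDataset("D4", half),
        ])
        res = fncm_modified(meta)
        assert res.per_dataset["D4"] == pytest.approx(
            res.per_dataset["D1"] / 2, rel=1e-9)

    def test_zero_overlap_everywhere_is_degenerate(self):
        meta = MetaSet([
            PeakDataset("A", [GenomicInterval("chr1", 0, 10)]),
            PeakDataset("B", [GenomicInterval("chr1", 100, 110)]),
            PeakDataset("C", [GenomicInterval("chr1", 200, 210)]),
        ])
        with pytest.raises(DegenerateInputError):
            fncm_modified(meta)


class TestRemoveOrphans:
    @pytest.fixture
    def meta_with_orphans(self):
        shared = [GenomicInterval("chr1", i * 1000, i * 1000 + 100)
                  for i in range(7)]
        orphans_a = [GenomicInterval("chr2", 0, 50),
                     GenomicInterval("chr2", 500, 550)]
        orphans_b = [GenomicInterval("chr3", 10, 60)]
        return MetaSet([
            PeakDataset("A", shared + orphans_a),
            PeakDataset("B", [GenomicInterval("chr1", s.start + 10,
                                              s.end + 10)
                              for s in shared] + orphans_b),
            PeakDataset("C", list(shared)),
        ])

    def test_exactly_orphan_intervals_removed(self, meta_with_orphans):
        cleaned = remove_orphans(meta_with_orphans)
        assert cleaned.sizes == [7, 7, 7]
        assert all(iv.chrom == "chr1"
                   for ds in cleaned.datasets for iv in ds.intervals)

    def test_remerge_has_no_orphans(self, meta_with_orphans):
        cleaned = remove_orphans(meta_with_orphans)
        freqs = pivotal_frequencies(merge_meta_set(cleaned), cleaned.k)
        assert freqs.f1 == 0

    def test_identical_meta_set_unchanged(self):
        ivs = [GenomicInterval("chr1", 0, 100)]
        meta = MetaSet([PeakDataset("A", ivs), PeakDataset("B", ivs)])
        cleaned = remove_orphans(meta)
        assert cleaned.sizes == meta.sizes


class TestRanking:
    def test_published_four_caller_ranking(self):
        order = rank_callers({"GEM": 0.776, "MACS": 0.874,
                              "PICS": 0.689, "SISSRs": 0.702})
        assert order == ["MACS", "GEM", "SISSRs", "PICS"]

    def test_ties_keep_input_order(self):
        assert rank_callers({"x": 0.5, "y": 0.5, "z": 0.7}) == ["z", "x", "y"]

    def test_two_labels(self):
        assert rank_callers({"a": 0.1, "b": 0.9}) == ["b", "a"]

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            rank_callers({"only": 1.0})


class TestAssess:
    def test_frequency_entry_first_example_branch(self):
        report = assess_frequencies([5534, 4542, 2482, 32141],
                                    sizes=[41827, 45318, 78011, 43215])
        assert report.recommendation == "keep_all"
        assert report.fncm.branch == "no_modification"

    def test_frequency_entry_second_example_branch(self):
        report = assess_frequencies([46452, 5797, 12012, 28175])
        assert report.recommendation == "remove_orphans"
        # no BEDs and no sizes: Chapman branch cannot run -> FNCM skipped
        assert report.fncm is None

    def test_assess_requires_three_datasets(self):
        meta = MetaSet([
            PeakDataset("A", [GenomicInterval("chr1", 0, 10)]),
            PeakDataset("B", [GenomicInterval("chr1", 5, 15)]),
        ])
        with pytest.raises(DegenerateInputError):
            assess(meta)

    def test_end_to_end_on_clean_simulation(self):
        config = SimulationConfig(n_true=800, seed=5,
                                  genome_length=10_000_000)
        meta, truth = simulate_meta_set(config)
        report = assess(meta)
        assert report.recommendation == "keep_all"
        assert report.fncm.n_estimate == pytest.approx(truth.n_true, rel=0.1)
        for label, p in zip(report.labels, config.detection_prob):
            assert report.fncm.per_dataset[label] == pytest.approx(p, abs=0.1)

    def test_clean_simulations_rarely_flag_orphan_removal(self):
        """A false-positive-free meta-set should virtually always be told
        to keep all peaks."""
        keep = 0
        reps = 30
        for seed in range(reps):
            config = SimulationConfig(n_true=500, seed=seed,
                                      genome_length=5_000_000)
            meta, _ = simulate_meta_set(config)
            keep += assess(meta).recommendation == "keep_all"
        assert keep >= 0.95 * reps

    def test_fpcm_monotone_in_injected_fp_rate(self):
        """More injected orphan false positives -> higher FPCM."""
        fpcms = []
        for rate in (0.0, 0.2, 0.5):
            config = SimulationConfig(
                n_true=600, seed=99, genome_length=20_000_000,
                fp_count=tuple(int(rate * 600) for _ in range(4)))
            meta, _ = simulate_meta_set(config)
            regions = merge_meta_set(meta)
            freqs = pivotal_frequencies(regions, meta.k)
            fpcms.append(fpcm(freqs).fpcm)
        assert fpcms[0] <= fpcms[1] <= fpcms[2]

    def test_report_ranking_matches_fncm_order(self):
        report = assess_frequencies([5534, 4542, 2482, 32141],
                                    sizes=[41827, 45318, 78011, 43215],
                                    labels=["GEM", "MACS", "PICS", "SISSRs"])
        vals = report.fncm.per_dataset
        assert report.ranking == sorted(vals, key=vals.get, reverse=True)
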
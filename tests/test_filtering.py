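"""Cleaning cascade: flag removal, replicate outliers, averaging, thresholds."""

import numpy as np
import pandas as pd
import pytest

from dietquant import BiasModel, build_design, simulate_trial, spike_outlier
from dietquant.filtering import (
    DROP,
    FilterError,
    apply_taxon_map,
    average_replicates,
    detect_outlier_replicates,
    drop_flagged,
    filter_identity,
    filter_low_frequency,
    run_filter_pipeline,
    to_rra,
)

from conftest import VOLE_TAXA, make_table


class TestDropFlagged:
    def test_no_flags_identity(self, small_table):
        assert drop_flagged(small_table) == small_table

    def test_flagged_rows_removed(self):
        motus = {
            "a": ("a", 1.0, "ok"),
            "b": ("b", 1.0, "flagged"),
            "c": ("c", 1.0, "flagged"),
        }
        table = make_table(
            {("s1", 1): {"a": 5, "b": 5, "c": 5}, ("s2", 1): {"a": 5, "b": 5, "c": 5}},
            motus=motus,
        )
        out = drop_flagged(table)
        assert list(out.counts.index) == ["a"]

    def test_all_flagged_warns(self):
        table = make_table(
            {("s1", 1): {"a": 5}, ("s2", 1): {"a": 5}},
            motus={"a": ("a", 1.0, "flagged")},
        )
        with pytest.warns(UserWarning, match="flagged"):
            out = drop_flagged(table)
        assert out.counts.empty


class TestOutlierReplicates:
    def test_consistent_replicates_no_removals(self, small_table):
        """Identical replicates within samples, distinct samples: nothing
        is flagged."""
        out, log = detect_outlier_replicates(small_table)
        assert log.removals.empty
        assert out.counts.shape == small_table.counts.shape

    def test_spiked_replicate_lands_in_log(self, vole_design, quiet_bias):
        table, _ = simulate_trial(vole_design, quiet_bias, seed=77)
        spiked = spike_outlier(table, "faeces_T60_S30_A10_a01", 2, 0.8, seed=1)
        _, log = detect_outlier_replicates(spiked)
        removed = set(zip(log.removals["sample"], log.removals["replicate"]))
        assert ("faeces_T60_S30_A10_a01", 2) in removed
        assert log.removals["distance"].ge(log.removals["threshold"]).all()

    def test_sample_reduced_below_two_replicates_is_discarded(self):
        # s1 has two wildly different replicates: one gets removed, the
        # survivor alone cannot support averaging, so s1 is discarded
        table = make_table(
            {
                ("s1", 1): {"a": 100, "b": 0, "c": 0},
                ("s1", 2): {"a": 0, "b": 0, "c": 100},
                ("s2", 1): {"a": 40, "b": 40, "c": 20},
                ("s2", 2): {"a": 41, "b": 39, "c": 20},
                ("s3", 1): {"a": 10, "b": 20, "c": 70},
                ("s3", 2): {"a": 11, "b": 19, "c": 70},
            }
        )
        out, log = detect_outlier_replicates(table, floor_factor=3.0)
        assert "s1" in log.discarded_samples
        assert out.samples.loc["s1", "status"] == "discarded_outlier_filter"
        assert "s1" not in set(out.counts.columns.get_level_values(0))

    def test_too_few_samples_rejected(self):
        table = make_table({("s1", 1): {"a": 5}, ("s1", 2): {"a": 6}})
        with pytest.raises(FilterError, match="2 samples"):
            detect_outlier_replicates(table)

    def test_detection_and_false_removal_rates(self, quiet_bias):
        """One spiked replicate per ~10 samples at severity 0.8: >= 90%
        of spikes removed, < 5% of clean replicates removed (100 runs)."""
        design = build_design(VOLE_TAXA, animals_per_mixture=2)
        bias = BiasModel(contaminant_rate=0.0, outlier_replicate_rate=0.0,
                         depth_log_mean=np.log(5000), depth_log_sd=0.2)
        hit = tot = false = clean = 0
        for run in range(100):
            rng = np.random.default_rng(9000 + run)
            table, _ = simulate_trial(design, bias, seed=9000 + run)
            # spike mixture-fed samples: a vertex-heavy corruption of a
            # pure-reference sample can coincide with its own vertex and
            # is then not an outlier at all
            ids = [s for s in table.sample_ids
                   if table.samples.loc[s, "sample_type"] != "single_plant"]
            spiked = []
            for s in rng.choice(ids, size=max(1, len(table.sample_ids) // 10), replace=False):
                r = int(rng.choice(table.replicates_of(s)))
                table = spike_outlier(table, s, r, 0.8, seed=int(rng.integers(2**31)))
                spiked.append((s, r))
            _, log = detect_outlier_replicates(table)
            removed = set(zip(log.removals["sample"], log.removals["replicate"]))
            hit += sum(1 for k in spiked if k in removed)
            tot += len(spiked)
            false += len(removed - set(spiked))
            clean += table.counts.shape[1] - len(spiked)
        assert hit / tot >= 0.90
        assert false / clean < 0.05


class TestAverageReplicates:
    def test_arithmetic_mean(self):
        table = make_table(
            {("s1", 1): {"a": 10}, ("s1", 2): {"a": 20}, ("s1", 3): {"a": 30},
             ("s2", 1): {"a": 7}}
        )
        avg = average_replicates(table)
        assert avg.counts.loc["a", "s1"] == 20.0
        assert avg.counts.loc["a", "s2"] == 7.0  # single replicate unchanged

    def test_equal_replicates_idempotent(self, small_table):
        dup = make_table(
            {("s1", 1): {"a": 4, "b": 6}, ("s1", 2): {"a": 4, "b": 6},
             ("s2", 1): {"a": 9, "b": 1}, ("s2", 2): {"a": 9, "b": 1}}
        )
        avg = average_replicates(dup)
        assert avg.counts.loc["a", "s1"] == 4.0
        assert avg.counts.loc["b", "s1"] == 6.0


class TestLowFrequency:
    def _mean(self, data):
        return average_replicates(make_table(data))

    def test_sub_threshold_motu_removed_entirely(self):
        avg = self._mean(
            {("s1", 1): {"a": 995, "b": 5}, ("s2", 1): {"a": 995, "b": 5}}
        )
        out = filter_low_frequency(avg, 0.01)
        assert "b" not in out.counts.index  # 0.5% everywhere -> dropped

    def test_exactly_one_percent_retained(self):
        avg = self._mean({("s1", 1): {"a": 990, "b": 10}})
        out = filter_low_frequency(avg, 0.01)
        assert out.counts.loc["b", "s1"] == 10.0  # strict "inferior to 1%"

    def test_zero_threshold_identity(self):
        avg = self._mean({("s1", 1): {"a": 999, "b": 1}})
        out = filter_low_frequency(avg, 0.0)
        assert out.counts.equals(avg.counts)

    def test_per_sample_zeroing_keeps_real_occurrences(self):
        """A MOTU real in one sample and noise in another is zeroed only
        where it is noise."""
        avg = self._mean(
            {("s1", 1): {"a": 500, "b": 500}, ("s2", 1): {"a": 998, "b": 2}}
        )
        out = filter_low_frequency(avg, 0.01)
        assert out.counts.loc["b", "s1"] == 500.0
        assert out.counts.loc["b", "s2"] == 0.0


class TestIdentityFilter:
    def test_boundary_inclusive(self):
        avg = average_replicates(
            make_table(
                {("s1", 1): {"lo": 10, "hi": 10}},
                motus={"lo": ("lo", 0.84, "ok"), "hi": ("hi", 0.85, "ok")},
            )
        )
        out = filter_identity(avg, 0.85)
        assert list(out.counts.index) == ["hi"]

    def test_all_perfect_identity_unchanged(self, small_table):
        avg = average_replicates(small_table)
        assert filter_identity(avg, 0.85).counts.equals(avg.counts)

    def test_impossible_threshold_errors(self, small_table):
        avg = average_replicates(small_table)
        with pytest.raises(FilterError, match="empty"):
            filter_identity(avg, 1.01)


class TestTaxonMap:
    def _avg(self):
        return average_replicates(
            make_table(
                {("s1", 1): {"m1": 40, "m2": 60, "m3": 30}},
                motus={
                    "m1": ("Festuca", 1.0, "ok"),
                    "m2": ("Avenella", 1.0, "ok"),
                    "m3": ("Maleae", 0.9, "ok"),
                },
            )
        )

    def test_merge_sums_counts(self):
        out = apply_taxon_map(self._avg(), {"Festuca": "Avenella"})
        assert out.counts.loc["Avenella", "s1"] == 100.0

    def test_drop_removes_rows(self):
        out = apply_taxon_map(self._avg(), {"Maleae": DROP})
        assert "Maleae" not in out.motus["taxon"].tolist()

    def test_empty_map_identity(self):
        out = apply_taxon_map(self._avg(), {})
        assert sorted(out.motus["taxon"]) == ["Avenella", "Festuca", "Maleae"]
        assert out.counts.to_numpy().sum() == 130.0


class TestToRRA:
    def test_simple_normalisation(self):
        avg = average_replicates(make_table({("s1", 1): {"a": 10, "b": 30, "c": 60}}))
        rra, discarded = to_rra(avg)
        np.testing.assert_allclose(rra.loc["s1", ["a", "b", "c"]], [0.1, 0.3, 0.6])
        assert discarded == []

    def test_zero_sample_discarded(self):
        avg = average_replicates(
            make_table({("s1", 1): {"a": 10}, ("s2", 1): {"a": 0}})
        )
        rra, discarded = to_rra(avg)
        assert discarded == ["s2"]
        assert list(rra.index) == ["s1"]

    def test_single_taxon_vertex(self):
        avg = average_replicates(make_table({("s1", 1): {"a": 50}}))
        rra, _ = to_rra(avg, taxon_order=["b", "a"])
        np.testing.assert_allclose(rra.loc["s1"], [0.0, 1.0])


class TestPipeline:
    def test_clean_trial_recovers_expected(self, quiet_bias):
        """No biases, depth ~2e4: RRA tracks expected composition with
        mean |error| < 0.02."""
        design = build_design(VOLE_TAXA, animals_per_mixture=3)
        table, truth = simulate_trial(design, quiet_bias, seed=100)
        rra, report = run_filter_pipeline(table, taxon_order=list(VOLE_TAXA))
        exp = truth.expected_compositions.loc[rra.index]
        assert np.abs(rra.to_numpy() - exp.to_numpy()).mean() < 0.02

    def test_sub_threshold_contaminant_absent_from_rra(self, vole_design):
        bias = BiasModel(contaminant_rate=0.003, outlier_replicate_rate=0.0)
        table, truth = simulate_trial(vole_design, bias, seed=200)
        rra, _ = run_filter_pipeline(table, taxon_order=list(VOLE_TAXA))
        cont_taxa = set(table.motus.loc[truth.contaminant_motus, "taxon"])
        assert not (set(rra.columns) - set(VOLE_TAXA)) & cont_taxa

    def test_audit_counts_monotone(self, vole_design):
        table, _ = simulate_trial(vole_design, BiasModel(), seed=300)
        _, report = run_filter_pipeline(table, taxon_order=list(VOLE_TAXA))
        audit = report.audit
        for col in ("n_motus", "n_samples", "n_replicates"):
            assert (np.diff(audit[col].to_numpy()) <= 0).all(), col

    def test_sample_relabelling_commutes(self, quiet_bias):
        """Renaming samples does not change any filtering outcome."""
        design = build_design(VOLE_TAXA, animals_per_mixture=2)
        table, _ = simulate_trial(design, quiet_bias, seed=17)
        rra1, _ = run_filter_pipeline(table, taxon_order=list(VOLE_TAXA))
        renamed = table.copy()
        mapping = {s: f"x_{s}" for s in renamed.samples.index}
        renamed.samples.index = [mapping[s] for s in renamed.samples.index]
        renamed.counts.columns = pd.MultiIndex.from_tuples(
            [(mapping[s], r) for s, r in renamed.counts.columns],
            names=["sample", "replicate"],
        )
        rra2, _ = run_filter_pipeline(renamed, taxon_order=list(VOLE_TAXA))
        np.testing.assert_allclose(
            rra1.to_numpy(), rra2.rename(index={v: k for k, v in mapping.items()})
            .loc[rra1.index].to_numpy()
        )
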
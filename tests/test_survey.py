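"""Target-set selection, per-target statistics, aggregation, summaries."""

import numpy as np
import pandas as pd
import pytest

from cliffminer.survey import (
    TargetStats,
    aggregate_survey,
    five_number_summary,
    select_target_sets,
    size_frequency_table,
)


def records_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "compound_id", "smiles", "target_id",
            "standard_type", "standard_value", "standard_units", "year",
        ],
    )


def alkane_rows(target, n, standard_type="Ki", start=0):
    # distinct linear alkanes/alcohols give n unique structures cheaply
    return [
        (f"{target}-{i:03d}", "C" * (i + 1) + "O", target, standard_type, 50.0, "nM", 2010)
        for i in range(start, start + n)
    ]


class TestSelection:
    def test_min_size_boundary_inclusive(self):
        records = records_frame(alkane_rows("A", 99) + alkane_rows("B", 100))
        sets, _ = select_target_sets(records, min_size=100)
        assert [s.target_id for s in sets] == ["B"]

    def test_restriction_to_equilibrium_compounds(self):
        rows = alkane_rows("A", 120) + [
            (f"A-x{i}", "C" * (200 + i) + "O", "A", "IC50", 50.0, "nM", 2010)
            for i in range(30)
        ]
        sets, log = select_target_sets(records_frame(rows), min_size=100)
        assert sets[0].size == 120
        assert log.rejected_measurement_type == 30

    def test_target_without_equilibrium_data_excluded(self):
        records = records_frame(alkane_rows("A", 120, standard_type="IC50"))
        sets, log = select_target_sets(records, min_size=100)
        assert sets == [] and "A" in log.targets_excluded

    def test_strict_reading_discards_mixed_targets(self):
        rows = alkane_rows("A", 120) + alkane_rows("A", 5, standard_type="IC50", start=150)
        sets, _ = select_target_sets(records_frame(rows), min_size=100,
                                     require_all_equilibrium=True)
        assert sets == []

    def test_structural_duplicates_merged_with_median_pki(self):
        rows = alkane_rows("A", 4)
        # same structure under a different id and encoding, third measurement
        rows += [("A-dup", "OC" + "C" * 0, "A", "Ki", 500.0, "nM", 2008)]
        rows += [("A-000", "CO", "A", "Ki", 5.0, "nM", 2011)]
        sets, log = select_target_sets(records_frame(rows), min_size=4)
        ts = sets[0]
        assert ts.size == 4
        assert log.duplicates_merged == 1
        # three records for methanol: 50, 500, 5 nM -> median 50 nM = pKi 7.3010
        assert ts.pki["A-000"] == pytest.approx(7.30103, abs=1e-5)
        assert "A-000" in ts.flagged_discordant  # span 2 log units
        assert ts.year["A-000"] == 2008  # earliest report year kept

    def test_unparseable_structures_rejected_not_fatal(self):
        rows = alkane_rows("A", 5) + [("A-bad", "C1CC", "A", "Ki", 5.0, "nM", 2010)]
        sets, log = select_target_sets(records_frame(rows), min_size=5)
        assert sets[0].size == 5 and log.rejected_structure == 1


def stats(target_id="T1", size=20, pairs=10, cliffs=2, cliff_compounds=5,
          isolated=1, mode="mmp"):
    return TargetStats(
        target_id=target_id, mode=mode, set_size=size,
        n_qualifying_pairs=pairs, n_cliffs=cliffs,
        n_cliff_compounds=cliff_compounds,
        n_isolated=isolated, n_coordinated=cliffs - isolated,
        excluded=pairs == 0,
    )


class TestPerTargetStats:
    def test_cliff_rate_relative_to_qualifying_pairs(self):
        assert stats(pairs=10, cliffs=2).cliff_pct == 20.0

    def test_compound_rate_relative_to_set_size(self):
        assert stats(size=20, cliff_compounds=5).compound_pct == 25.0

    def test_zero_qualifying_pairs_flagged_undefined(self):
        s = stats(pairs=0, cliffs=0, cliff_compounds=0, isolated=0)
        assert s.excluded and s.cliff_pct is None

    def test_isolation_split_sums_to_100(self):
        s = stats(cliffs=4, isolated=1)
        assert s.isolated_pct + s.coordinated_pct == 100.0


class TestAggregate:
    def test_unweighted_mean(self):
        summary = aggregate_survey([stats("T1", pairs=10, cliffs=1),
                                    stats("T2", pairs=10, cliffs=2)])
        assert summary.mean_cliff_pct == 15.0

    def test_single_target_equals_its_stats(self):
        s = stats()
        summary = aggregate_survey([s])
        assert summary.mean_cliff_pct == s.cliff_pct
        assert summary.mean_compound_pct == s.compound_pct

    def test_permutation_invariant(self):
        sl = [stats("T1", cliffs=1), stats("T2", cliffs=3), stats("T3", cliffs=5)]
        assert aggregate_survey(sl) == aggregate_survey(sl[::-1])

    def test_mean_bounded_by_inputs(self):
        sl = [stats("T1", pairs=100, cliffs=c) for c in (3, 10, 25)]
        summary = aggregate_survey(sl)
        pcts = [s.cliff_pct for s in sl]
        assert min(pcts) <= summary.mean_cliff_pct <= max(pcts)

    def test_duplicate_pulls_mean_toward_itself(self):
        base = [stats("T1", pairs=10, cliffs=1), stats("T2", pairs=10, cliffs=5)]
        before = aggregate_survey(base).mean_cliff_pct
        after = aggregate_survey(base + [stats("T3", pairs=10, cliffs=5)]).mean_cliff_pct
        assert abs(after - 50.0) < abs(before - 50.0)

    def test_flagged_targets_excluded_and_tallied(self):
        sl = [stats("T1"), stats("T2", pairs=0, cliffs=0, cliff_compounds=0, isolated=0)]
        summary = aggregate_survey(sl)
        assert summary.n_targets == 1 and summary.n_targets_excluded == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_survey([])


class TestFiveNumber:
    def test_evenly_spaced_values(self):
        assert five_number_summary([1, 2, 3, 4, 5]) == (1, 2, 3, 4, 5)

    def test_single_value(self):
        assert five_number_summary([7.5]) == (7.5,) * 5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            five_number_summary([])

    def test_matches_sort_and_index_oracle(self):
        def oracle(values):
            # independent linear-interpolation order-statistics routine
            v = sorted(values)
            n = len(v)

            def q(p):
                h = p * (n - 1)
                lo = int(np.floor(h))
                hi = min(lo + 1, n - 1)
                return v[lo] + (h - lo) * (v[hi] - v[lo])

            return (v[0], q(0.25), q(0.5), q(0.75), v[-1])

        rng = np.random.default_rng(41)
        for _ in range(50):
            vals = rng.normal(size=rng.integers(1, 40)).tolist()
            assert five_number_summary(vals) == pytest.approx(oracle(vals), abs=1e-12)


class TestSizeFrequency:
    def test_marker_inclusive_at_200(self):
        df = size_frequency_table([stats("T1", size=200), stats("T2", size=150)])
        flags = dict(zip(df["target_id"], df["above_marker"]))
        assert bool(flags["T1"]) and not bool(flags["T2"])

    def test_constant_group_has_zero_dispersion(self):
        sl = [stats(f"T{i}", size=300, pairs=10, cliffs=2) for i in range(3)]
        df = size_frequency_table(sl)
        assert df.attrs["dispersion"]["above_marker"] == 0.0
        assert df.attrs["dispersion"]["below_marker"] is None

    def test_one_row_per_target(self):
        sl = [stats(f"T{i}", size=100 + i) for i in range(4)]
        assert len(size_frequency_table(sl)) == 4


class TestEndToEndRecovery:
    def test_measured_rates_equal_planted_rates(self, small_collection):
        from cliffminer.run import RunConfig, mine_collection
        from cliffminer.survey import per_target_statistics

        records, truth = small_collection
        cfg = RunConfig(mode="mmp", min_set_size=50)
        runs, _ = mine_collection(records, cfg)
        for target_id, tr in runs.items():
            s = per_target_statistics(tr.target_set, tr.result, tr.network,
                                      tr.isolation, "mmp")
            assert s.cliff_pct == truth.cliff_rate_pct[target_id]
            assert {c.pair for c in tr.result.cliffs} == set(truth.cliff_pairs[target_id])
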
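import numpy as np
import pytest

from dnahyb import dataset as dsm
from dnahyb import seqops, thermo


class TestAssembly:
    def test_contract_small(self):
        ds = dsm.assemble_dataset(seed_count=2, target_size=10, rng_seed=1,
                                  variety_min=0.0)
        assert len(ds) >= 10
        for r in ds.records:
            for y in r.yields.values():
                assert 0.0 <= y <= 1.0
            assert set(r.yields) == set(thermo.DEFAULT_TEMPERATURES)

    def test_deterministic_regeneration(self):
        a = dsm.assemble_dataset(seed_count=2, target_size=10, rng_seed=5,
                                 variety_min=0.0)
        b = dsm.assemble_dataset(seed_count=2, target_size=10, rng_seed=5,
                                 variety_min=0.0)
        assert a.records == b.records

    def test_no_duplicate_unordered_pairs(self, small_dataset):
        keys = {tuple(sorted((r.seq_a, r.seq_b)))
                for r in small_dataset.records}
        assert len(keys) == len(small_dataset)

    def test_pairs_stored_in_canonical_order(self, small_dataset):
        for r in small_dataset.records:
            assert r.seq_a <= r.seq_b

    def test_labels_recomputable_from_yields(self, small_dataset):
        t = small_dataset.reference_temperature
        for r in small_dataset.records:
            assert r.label == dsm.label_for(r.yields[t])

    def test_all_mass_regions_populated(self, small_dataset):
        h = dsm.histogram(small_dataset, 57.0)
        n = len(small_dataset)
        for region in ("low", "high", "mid"):
            assert h.extreme_counts[region] >= 0.1 * n

    def test_lengths_stay_in_window(self, small_dataset):
        for r in small_dataset.records:
            assert 18 <= len(r.seq_a) <= 26
            assert 18 <= len(r.seq_b) <= 26

    def test_impossible_variety_guard(self):
        with pytest.raises(RuntimeError, match="rounds"):
            dsm.assemble_dataset(seed_count=1, target_size=5, rng_seed=1,
                                 variety_min=0.9, max_rounds=3)


class TestHistogram:
    def test_counts_sum_to_records(self, small_dataset):
        h = dsm.histogram(small_dataset, 57.0)
        assert sum(h.counts) == len(small_dataset)
        assert sum(h.extreme_counts.values()) == len(small_dataset)
        assert h.extreme_counts["low"] == h.counts[0]
        assert h.extreme_counts["high"] == h.counts[9]

    def test_empty_dataset_all_zero(self):
        ds = dsm.HybridisationDataset(records=[])
        h = dsm.histogram(ds, 57.0)
        assert h.counts == (0,) * 10
        assert h.extreme_counts == {"low": 0, "high": 0, "mid": 0}

    def test_unknown_temperature_lists_available(self, small_dataset):
        with pytest.raises(KeyError, match="available"):
            dsm.histogram(small_dataset, 99.0)


class TestStratifiedSplit:
    def test_partition_and_proportions(self, small_dataset):
        ds = small_dataset
        all_ids = {r.pair_id for r in ds.records}
        assigned = set().union(*ds.splits.values())
        assert assigned == all_ids
        assert sum(len(v) for v in ds.splits.values()) == len(all_ids)
        n = len(ds)
        assert abs(len(ds.splits["train"]) - 0.8 * n) <= 10  # <=1/stratum
        assert abs(len(ds.splits["validation"]) - 0.1 * n) <= 10
        assert abs(len(ds.splits["test"]) - 0.1 * n) <= 10

    def test_divisible_case_exact(self):
        # 100 records spread uniformly over bins split exactly 80/10/10
        records = []
        for i in range(100):
            y = min((i % 10) / 10 + 0.05, 1.0)
            records.append(dsm.YieldRecord(
                pair_id=f"p{i}", seq_a="ACGTACGTACGTACGTAC",
                seq_b="ACGTACGTACGTACGTAC",
                yields={57.0: y}, label=dsm.label_for(y)))
        ds = dsm.HybridisationDataset(records=records)
        out = dsm.stratified_split(ds, rng_seed=3)
        assert len(out.splits["train"]) == 80
        assert len(out.splits["validation"]) == 10
        assert len(out.splits["test"]) == 10

    def test_label_ratio_preserved(self, small_dataset):
        ds = small_dataset
        label_of = {r.pair_id: r.label for r in ds.records}
        overall = np.mean([lab == "Low" for lab in label_of.values()])
        for name, members in ds.splits.items():
            frac = np.mean([label_of[i] == "Low" for i in members])
            assert abs(frac - overall) < 0.05

    def test_deterministic(self, small_dataset):
        a = dsm.stratified_split(small_dataset, rng_seed=9)
        b = dsm.stratified_split(small_dataset, rng_seed=9)
        assert a.splits == b.splits

    def test_bad_fractions_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="sum to 1"):
            dsm.stratified_split(small_dataset, fractions=(0.5, 0.2, 0.2))


class TestRoundTrip:
    def test_write_read_equality(self, small_dataset, tmp_path):
        path = tmp_path / "ds.tsv"
        dsm.write_dataset(small_dataset, path)
        back = dsm.read_dataset(path)
        assert back.splits == small_dataset.splits
        assert len(back) == len(small_dataset)
        for orig, readback in zip(small_dataset.records, back.records):
            assert readback.pair_id == orig.pair_id
            assert readback.seq_a == orig.seq_a
            assert readback.seq_b == orig.seq_b
            assert readback.label == orig.label
            for t in orig.yields:
                assert readback.yields[t] == pytest.approx(orig.yields[t],
                                                           abs=5e-7)

    def test_gzip_round_trip(self, small_dataset, tmp_path):
        path = tmp_path / "ds.tsv.gz"
        dsm.write_dataset(small_dataset, path)
        assert len(dsm.read_dataset(path)) == len(small_dataset)

    def test_missing_yield_column_schema_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("pair_id\tseq_a\tseq_b\tlabel\np1\tACGT\tACGT\tLow\n")
        with pytest.raises(dsm.DatasetSchemaError, match="yield"):
            dsm.read_dataset(path)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("pair_id\tseq_a\tseq_b\tyield_57\tlabel\n"
                        "p1\tACGT\tACGT\t0.5\tHigh\n"
                        "p2\tACGT\tACGT\tnot-a-number\tLow\n")
        with pytest.raises(dsm.DatasetSchemaError, match="line 3"):
            dsm.read_dataset(path)

    def test_splits_must_partition(self):
        r = dsm.YieldRecord(pair_id="p1", seq_a="ACGT", seq_b="ACGT",
                            yields={57.0: 0.5}, label="High")
        with pytest.raises(ValueError, match="partition"):
            dsm.HybridisationDataset(records=[r], splits={"train": set()})
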
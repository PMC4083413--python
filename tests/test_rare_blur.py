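"""Occurrence counts, median-adaptive threshold, blurring, withdrawal."""

import numpy as np
import pytest

import snvblur as sb
from snvblur.model import SnvKey, ValidationError
from snvblur.rare_blur import (
    FrequencyTable,
    ThresholdConfig,
    consequence_rank,
    is_rare,
    occurrence_counts,
    rare_threshold,
    threshold_from_counts,
)

from conftest import CONTACT, make_meta


def site(i):
    return SnvKey("chr1", 1000 + i, "A", "G")


def dataset_from_matrix(matrix, p_hom_row=None):
    """rows = samples, cols = sites; 1 marks a carrier (het unless flagged)."""
    matrix = np.asarray(matrix)
    ids = [f"s{i + 1}" for i in range(matrix.shape[0])]
    ds = sb.CohortDataset(sample_ids=ids)
    for j in range(matrix.shape[1]):
        carriers = {
            ids[i]: "het" for i in range(matrix.shape[0]) if matrix[i, j]
        }
        if carriers:
            ds.calls[site(j)] = carriers
    return ds


class TestOccurrenceCounts:
    def test_single_sample_all_counts_one(self):
        ds = dataset_from_matrix([[1, 1, 1]])
        table = occurrence_counts(ds)
        assert set(table.counts.values()) == {1}

    def test_genotype_blind(self):
        ds = sb.CohortDataset(sample_ids=["s1", "s2"])
        ds.calls[site(0)] = {"s1": "het", "s2": "hom_alt"}
        assert occurrence_counts(ds).counts[site(0)] == 2

    def test_matches_bruteforce_column_sums(self):
        rng = np.random.default_rng(5)
        matrix = (rng.random((6, 20)) < 0.4).astype(int)
        matrix[0, :3] = 1  # ensure some occupied columns
        ds = dataset_from_matrix(matrix)
        table = occurrence_counts(ds)
        for j in range(20):
            expected = int(matrix[:, j].sum())
            if expected:
                assert table.counts[site(j)] == expected
            else:
                assert site(j) not in table.counts


class TestRareThreshold:
    def test_degenerate_equal_counts_blur_everything(self):
        table = FrequencyTable({site(i): 4 for i in range(5)}, n_samples=4)
        threshold = rare_threshold(table)
        assert threshold == 6.0
        assert all(is_rare(k, threshold) for k in table.counts.values())

    def test_hand_median(self):
        table = FrequencyTable(
            dict(zip((site(i) for i in range(5)), [1, 2, 2, 3, 9])), n_samples=10
        )
        assert rare_threshold(table) == 3.0

    def test_empty_table_is_error(self):
        with pytest.raises(ValidationError):
            rare_threshold(FrequencyTable({}, n_samples=2))

    @pytest.mark.parametrize("seed", range(8))
    def test_median_against_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(125):  # 1000 multisets across the seeds
            counts = rng.integers(1, 50, size=int(rng.integers(1, 40))).tolist()
            # independent oracle: sort and pick middle element(s) by hand
            ordered = sorted(counts)
            mid = len(ordered) // 2
            if len(ordered) % 2:
                median = ordered[mid]
            else:
                median = (ordered[mid - 1] + ordered[mid]) / 2
            assert threshold_from_counts(counts, 1.5) == pytest.approx(1.5 * median)

    def test_strict_mode_excludes_equality(self):
        assert is_rare(3, 3.0) and not is_rare(3, 3.0, strict=True)


class TestBlurRare:
    @staticmethod
    def toy_store(threshold_factor=1.5):
        """8 samples, 10 sites with counts (1 x8, 8, 8): median 1, threshold 1.5."""
        matrix = np.zeros((8, 10), dtype=int)
        for i in range(8):
            matrix[i, i] = 1  # 8 singletons
        matrix[:, 8] = 1
        matrix[:, 9] = 1  # two sites carried by everyone
        ds = dataset_from_matrix(matrix)
        ds.attach_metadata([make_meta(sid) for sid in ds.sample_ids])
        store, linkage, _ = sb.aggregate_dataset(
            ds, sb.AggregateConfig(seed=9, passphrase="pw", factor=threshold_factor)
        )
        return ds, store, linkage

    def test_toy_counts_blur_split(self):
        _, store, _ = self.toy_store()
        assert store.threshold == 1.5
        blurred = [r for r in store.records if r.blurred]
        unblurred = [r for r in store.records if not r.blurred]
        assert len(blurred) == 8 and len(unblurred) == 2
        for rec in unblurred:
            assert len(rec.sub_calls) == 8
            assert rec.het_count == 8 and rec.hom_count == 0

    def test_threshold_zero_blurs_nothing(self):
        ds, _, _ = self.toy_store()
        table = occurrence_counts(ds)
        store = sb.blur_rare(ds, {}, [], table, 0.0, "contact")
        assert not any(r.blurred for r in store.records)

    def test_threshold_at_n_blurs_everything(self):
        ds, _, _ = self.toy_store()
        table = occurrence_counts(ds)
        store = sb.blur_rare(ds, {}, [], table, 8.0, "contact")
        assert all(r.blurred for r in store.records)
        text_subs = [r.sub_calls for r in store.records]
        assert all(not s for s in text_subs)

    def test_blur_disjointness_invariant(self):
        _, store, _ = self.toy_store()
        rare_keys = {r.key for r in store.records if r.blurred}
        linked_keys = {r.key for r in store.records if r.sub_calls}
        assert rare_keys.isdisjoint(linked_keys)
        assert rare_keys | linked_keys == {r.key for r in store.records}

    def test_factor_monotonicity(self):
        ds = sb.simulate_cohort(sb.SfsConfig(n_samples=8, n_sites=300, seed=21))
        blurred_sets = []
        for factor in (0.5, 1.0, 1.5, 3.0):
            store, _, _ = sb.aggregate_dataset(
                ds, sb.AggregateConfig(seed=2, passphrase="pw", factor=factor)
            )
            blurred_sets.append({r.key for r in store.records if r.blurred})
        for smaller, larger in zip(blurred_sets, blurred_sets[1:]):
            assert smaller <= larger


class TestAggregateEndToEnd:
    def test_two_identical_samples_fully_blurred(self):
        ds = sb.CohortDataset(sample_ids=["s1", "s2"])
        ds.calls[site(0)] = {"s1": "het", "s2": "het"}
        ds.attach_metadata([make_meta("s1"), make_meta("s2")])
        store, _, _ = sb.aggregate_dataset(ds, sb.AggregateConfig(seed=1, passphrase="pw"))
        # count 2, median 2, threshold 3 -> blurred
        assert store.threshold == 3.0
        assert [r.blurred for r in store.records] == [True]
        assert store.records[0].trait_summary == [("epilepsy", 2)]

    def test_determinism_byte_identical(self, tmp_path, small_cohort):
        paths = []
        for run in (1, 2):
            store, linkage, _ = sb.aggregate_dataset(
                small_cohort, sb.AggregateConfig(seed=77, passphrase="pw")
            )
            p = tmp_path / f"run{run}.vcf"
            sb.write_aggregated_vcf(store, str(p))
            (tmp_path / f"run{run}.enc").write_bytes(linkage)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()
        assert (tmp_path / "run1.enc").read_bytes() == (tmp_path / "run2.enc").read_bytes()

    @pytest.mark.parametrize("seed", range(6))
    def test_store_text_never_contains_sample_ids(self, tmp_path, seed):
        ds = sb.simulate_cohort(sb.SfsConfig(n_samples=6, n_sites=120, seed=seed))
        store, _, _ = sb.aggregate_dataset(ds, sb.AggregateConfig(seed=seed + 1, passphrase="pw"))
        path = tmp_path / "s.vcf"
        sb.write_aggregated_vcf(store, str(path))
        text = path.read_text()
        for sid in ds.sample_ids:
            assert sid not in text

    def test_small_cohort_error_propagates(self):
        ds = sb.CohortDataset(sample_ids=["s1"])
        ds.calls[site(0)] = {"s1": "het"}
        ds.attach_metadata([make_meta("s1")])
        with pytest.raises(ValidationError):
            sb.aggregate_dataset(ds, sb.AggregateConfig(seed=1, passphrase="pw"))


class TestRemoveSample:
    def test_remove_only_effective_sample_empties_records(self):
        ds = sb.CohortDataset(sample_ids=["s1", "s2"])
        ds.calls[site(0)] = {"s1": "het"}
        ds.calls[site(1)] = {"s1": "hom_alt"}
        ds.calls[site(2)] = {"s1": "het", "s2": "het"}
        ds.attach_metadata([make_meta("s1"), make_meta("s2")])
        store, linkage, _ = sb.aggregate_dataset(ds, sb.AggregateConfig(seed=3, passphrase="pw"))
        reduced = sb.remove_sample(store, linkage, "pw", "s1")
        assert reduced.n_samples == 1
        assert {r.key for r in reduced.records} == {site(2)}
        assert reduced.records[0].carrier_count == 1

    def test_unknown_sample_is_error_store_unchanged(self, small_cohort, agg_config):
        store, linkage, _ = sb.aggregate_dataset(small_cohort, agg_config)
        before = [r for r in store.records]
        with pytest.raises(ValidationError):
            sb.remove_sample(store, linkage, agg_config.passphrase, "sX")
        assert store.records == before

    def test_counts_match_frozen_threshold_reaggregation_oracle(self, small_cohort, agg_config):
        store, linkage, _ = sb.aggregate_dataset(small_cohort, agg_config)
        victim = small_cohort.sample_ids[2]
        reduced = sb.remove_sample(store, linkage, agg_config.passphrase, victim)
        reduced.validate()
        # oracle: recompute counts brute-force from the remaining samples,
        # replaying the original assignments and freezing the threshold
        remaining = [s for s in small_cohort.sample_ids if s != victim]
        for rec in reduced.records:
            carriers = {
                sid: z
                for sid, z in small_cohort.calls.get(rec.key, {}).items()
                if sid in remaining
            }
            assert rec.carrier_count == len(carriers)
            assert rec.n_samples == len(remaining)
            if not rec.blurred:
                assert rec.het_count == sum(1 for z in carriers.values() if z == "het")
                assert rec.hom_count == sum(1 for z in carriers.values() if z == "hom_alt")
                assert len(rec.sub_calls) == len(carriers)
        # threshold frozen, blur status unchanged for surviving keys
        assert reduced.threshold == store.threshold
        old_blur = {r.key: r.blurred for r in store.records}
        assert all(old_blur[r.key] == r.blurred for r in reduced.records)
        # sites carried only by the removed sample are gone
        gone = {k for k, c in small_cohort.calls.items() if set(c) == {victim}}
        assert gone.isdisjoint({r.key for r in reduced.records})


class TestConsequenceRank:
    @pytest.mark.parametrize(
        "label, rank",
        [
            ("nonsense", 1),
            ("readthrough", 2),
            ("start-lost", 3),
            ("Start Lost", 3),
            ("splice site", 4),
            ("splice_site", 4),
            ("missense", 5),
            ("synonymous", 6),
            ("frameshift", 7),
            ("", 7),
        ],
    )
    def test_ranking(self, label, rank):
        assert consequence_rank(label) == rank

    def test_sorting_by_rank(self):
        labels = ["missense", "nonsense", "frameshift"]
        assert sorted(labels, key=consequence_rank) == [
            "nonsense",
            "missense",
            "frameshift",
        ]
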
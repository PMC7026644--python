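"""Preprocessing: barcode consensus, cleavage counts, relative activities."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from coda.library import (
    ActivityRecord,
    ActivityTable,
    Variant,
    WildType,
    build_barcode_map,
    compute_ra,
    count_cleavage,
    format_subs,
    merge_batches,
    parse_subs,
    preprocess,
    reduce_triples,
)


@pytest.fixture
def wt():
    return WildType(id="wt", sequence="ACGUACGUACGU")


def variant_read(wt, subs):
    return wt.apply(subs)


class TestWildType:
    def test_t_converted_to_u(self):
        w = WildType(id="x", sequence="ACGTACGTACGT")
        assert w.sequence == "ACGUACGUACGU"

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            WildType(id="x", sequence="ACGUA")

    def test_bad_alphabet_rejected(self):
        with pytest.raises(ValueError):
            WildType(id="x", sequence="ACGUACGUNNGU")


class TestBarcodeMap:
    def test_unanimous_consensus(self, wt):
        read = variant_read(wt, [(5, "G")])
        bmap = build_barcode_map([("b1", read)] * 3, wt)
        assert bmap.variants == {"b1": ((5, "G"),)}
        assert bmap.read_tally["b1"] == 3

    def test_majority_consensus_kept(self, wt):
        x = variant_read(wt, [(5, "G")])
        y = variant_read(wt, [(7, "A")])
        bmap = build_barcode_map([("b", x), ("b", x), ("b", y)], wt)
        assert bmap.variants == {"b": ((5, "G"),)}

    def test_tie_dropped(self, wt):
        x = variant_read(wt, [(5, "G")])
        y = variant_read(wt, [(7, "A")])
        bmap = build_barcode_map([("b", x), ("b", y)], wt)
        assert bmap.variants == {}
        assert bmap.n_dropped_no_majority == 1

    def test_length_mismatch_discarded(self, wt):
        bmap = build_barcode_map([("b", wt.sequence + "A"), ("b", wt.sequence)], wt)
        assert bmap.n_skipped_length == 1
        assert bmap.variants == {"b": ()}

    def test_non_acgu_read_skipped(self, wt):
        bad = "N" + wt.sequence[1:]
        bmap = build_barcode_map([("b", bad), ("b", wt.sequence)], wt)
        assert bmap.n_skipped_alphabet == 1

    def test_empty_input_errors(self, wt):
        with pytest.raises(ValueError):
            build_barcode_map([], wt)


class TestCountCleavage:
    def test_direct_count(self, wt):
        bmap = build_barcode_map([("b", variant_read(wt, [(5, "G")]))], wt)
        variants = count_cleavage([("b", True), ("b", True), ("b", False)], bmap)
        assert variants == [Variant(((5, "G"),), n_cleaved=2, n_total=3)]

    def test_unknown_barcode_ignored(self, wt):
        bmap = build_barcode_map([("b", wt.sequence)], wt)
        assert count_cleavage([("zz", True)], bmap) == []

    def test_same_substitutions_summed_across_barcodes(self, wt):
        read = variant_read(wt, [(5, "G")])
        bmap = build_barcode_map([("b1", read), ("b2", read)], wt)
        variants = count_cleavage(
            [("b1", True), ("b1", False), ("b2", True)], bmap
        )
        assert variants == [Variant(((5, "G"),), n_cleaved=2, n_total=3)]


class TestComputeRA:
    def test_formula(self):
        recs = compute_ra([Variant(((5, "G"),), 50, 200)], (100, 200))
        assert recs[0].ra == pytest.approx(0.5)

    def test_min_read_filter(self):
        recs = compute_ra([Variant(((5, "G"),), 2, 4)], (100, 200), min_reads=5)
        assert recs == []

    def test_wild_type_proportions_give_unity(self):
        recs = compute_ra([Variant(((5, "G"),), 30, 60)], (100, 200))
        assert recs[0].ra == pytest.approx(1.0)

    def test_zero_wild_type_cleaved_errors(self):
        with pytest.raises(ValueError):
            compute_ra([Variant(((5, "G"),), 1, 10)], (0, 200))

    @given(scale=st.integers(min_value=1, max_value=1000))
    def test_scale_invariance(self, scale):
        """RA is unchanged when every read count is scaled by a constant."""
        base = compute_ra([Variant(((5, "G"),), 7, 20)], (10, 30), min_reads=1)[0].ra
        scaled = compute_ra(
            [Variant(((5, "G"),), 7 * scale, 20 * scale)],
            (10 * scale, 30 * scale),
            min_reads=1,
        )[0].ra
        assert scaled == pytest.approx(base)


class TestActivityTable:
    def test_double_key_canonicalized(self, wt):
        table = ActivityTable.from_records(
            wt, [ActivityRecord(((7, "A"), (5, "G")), 0.4)]
        )
        assert table.get_double((5, "G"), (7, "A")).ra == 0.4
        assert table.get_double((7, "A"), (5, "G")).ra == 0.4

    def test_coverage_matches_brute_force(self, wt):
        rng = np.random.default_rng(0)
        records = []
        for _ in range(60):
            pos = int(rng.integers(1, wt.length + 1))
            alts = [b for b in "ACGU" if b != wt.sequence[pos - 1]]
            records.append(
                ActivityRecord(((pos, str(rng.choice(alts))),), float(rng.uniform(0, 1)))
            )
        table = ActivityTable.from_records(wt, records)
        assert table.single_coverage == len(table.singles) / (3 * wt.length)
        assert 0 <= table.single_coverage <= 1

    def test_tsv_round_trip(self, wt, tmp_path):
        table = ActivityTable.from_records(
            wt,
            [
                ActivityRecord(((5, "G"),), 0.4, n_total=10),
                ActivityRecord(((5, "G"), (7, "A")), 0.8, n_total=7),
            ],
        )
        path = tmp_path / "activity.tsv"
        table.to_tsv(path)
        back = ActivityTable.from_tsv(path, wt)
        assert back.singles[(5, "G")].ra == pytest.approx(0.4)
        assert back.get_double((5, "G"), (7, "A")).ra == pytest.approx(0.8)


class TestMergeBatches:
    def test_average_across_batches(self, wt):
        t1 = ActivityTable.from_records(wt, [ActivityRecord(((5, "G"),), 0.4)])
        t2 = ActivityTable.from_records(wt, [ActivityRecord(((5, "G"),), 0.6)])
        merged = merge_batches([t1, t2])
        rec = merged.singles[(5, "G")]
        assert rec.ra == pytest.approx(0.5)
        assert rec.provenance == "batch_average"

    def test_single_batch_value_unchanged(self, wt):
        t1 = ActivityTable.from_records(wt, [ActivityRecord(((5, "G"),), 0.4)])
        t2 = ActivityTable.from_records(wt, [ActivityRecord(((7, "A"),), 0.9)])
        merged = merge_batches([t1, t2])
        assert merged.singles[(5, "G")].ra == pytest.approx(0.4)
        assert merged.singles[(5, "G")].provenance == "direct"

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            merge_batches([])

    def test_mismatched_wild_types_error(self, wt):
        other = WildType(id="o", sequence="ACGUACGUACGG")
        with pytest.raises(ValueError):
            merge_batches(
                [ActivityTable(wt), ActivityTable(other)]
            )


class TestReduceTriples:
    def make_table(self, wt, triples, singles, doubles=()):
        records = [ActivityRecord((s,), ra) for s, ra in singles.items()]
        records += [ActivityRecord(k, ra) for k, ra in doubles]
        records += [ActivityRecord(k, ra) for k, ra in triples]
        return ActivityTable.from_records(wt, records)

    def test_reduction_formula(self, wt):
        table = self.make_table(
            wt,
            triples=[(((2, "G"), (5, "G"), (9, "G")), 0.4)],
            singles={(2, "G"): 0.3, (5, "G"): 0.3, (9, "G"): 0.8},
        )
        reduce_triples(table)
        assert table.get_double((2, "G"), (5, "G")).ra == pytest.approx(0.5)
        assert table.get_double((2, "G"), (5, "G")).provenance == "reduced_triple"

    def test_below_threshold_z_excluded(self, wt):
        table = self.make_table(
            wt,
            triples=[(((2, "G"), (5, "G"), (9, "G")), 0.4)],
            singles={(2, "G"): 0.3, (5, "G"): 0.3, (9, "G"): 0.4},
        )
        assert reduce_triples(table) == 0

    def test_multiple_estimates_averaged(self, wt):
        table = self.make_table(
            wt,
            triples=[
                (((2, "G"), (5, "G"), (9, "G")), 0.32),
                (((2, "G"), (5, "G"), (11, "C")), 0.54),
            ],
            singles={(2, "G"): 0.3, (5, "G"): 0.3, (9, "G"): 0.8, (11, "C"): 0.9},
        )
        reduce_triples(table)
        assert table.get_double((2, "G"), (5, "G")).ra == pytest.approx(
            (0.32 / 0.8 + 0.54 / 0.9) / 2
        )

    def test_direct_double_never_overwritten(self, wt):
        table = self.make_table(
            wt,
            triples=[(((2, "G"), (5, "G"), (9, "G")), 0.4)],
            singles={(2, "G"): 0.3, (5, "G"): 0.3, (9, "G"): 0.8},
            doubles=[(((2, "G"), (5, "G")), 0.7)],
        )
        reduce_triples(table)
        rec = table.get_double((2, "G"), (5, "G"))
        assert rec.ra == pytest.approx(0.7)
        assert rec.provenance == "direct"

    def test_covered_position_pair_not_reduced(self, wt):
        # a different mutation combination at the same position pair counts
        table = self.make_table(
            wt,
            triples=[(((2, "G"), (5, "G"), (9, "G")), 0.4)],
            singles={(2, "G"): 0.3, (5, "G"): 0.3, (9, "G"): 0.8},
            doubles=[(((2, "A"), (5, "C")), 0.7)],
        )
        assert reduce_triples(table) == 0


class TestSubsEncoding:
    def test_round_trip(self, wt):
        subs = ((3, "A"), (7, "C"))
        text = format_subs(subs, wt)
        assert text == "G3A,G7C"
        assert parse_subs(text, wt) == subs

    def test_wild_type_token(self, wt):
        assert format_subs((), wt) == "WT"
        assert parse_subs("WT", wt) == ()

    def test_reference_base_checked(self, wt):
        with pytest.raises(ValueError):
            parse_subs("A3G", wt)  # position 3 is G, not A


def test_preprocess_end_to_end(wt):
    """Records -> barcode map -> counts -> RA, with the wild type anchoring."""
    wt_read = wt.sequence
    var_read = wt.apply([(5, "G")])
    dna = [("w", wt_read)] * 3 + [("v", var_read)] * 3
    rna = [("w", 1)] * 10 + [("w", 0)] * 10 + [("v", 1)] * 5 + [("v", 0)] * 15
    table = preprocess(wt, dna, rna, min_reads=5)
    assert table.singles[(5, "G")].ra == pytest.approx(0.5)
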
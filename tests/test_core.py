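from __future__ import annotations

import numpy as np
import pytest

import oracles
from resa.core import (
    CohortConfig,
    annotation_filter,
    assign_sets,
    label_cohort,
    quality_pass,
    recurrence_counts,
)
from resa.errors import ConfigError
from resa.variants_io import CellCall, ExonIntervals, SiteList, VariantKey


def mk_call(key, cell, dp=10, ad_alt=4, qual=50.0, qd=10.0, fs=1.0, caller="G"):
    ad_alt = min(ad_alt, dp)
    return CellCall(
        key=key, cell_id=cell, caller=caller, dp=dp, ad_ref=dp - ad_alt,
        ad_alt=ad_alt, qual=qual, pl=(40, 0, 80), fs=fs, qd=qd,
    )


def k(pos, ref="C", alt="T", chrom="chr1"):
    return VariantKey(chrom, pos, ref, alt)


CFG30 = CohortConfig(n_cells=30)


class TestBounds:
    @pytest.mark.parametrize(
        "n,lower,upper",
        [(30, 3, 24), (100, 10, 80), (50, 5, 40), (12, 3, 9)],
    )
    def test_effective_bounds(self, n, lower, upper):
        assert CohortConfig(n_cells=n).bounds() == (lower, upper)

    def test_inverted_bounds_are_fatal(self):
        with pytest.raises(ConfigError):
            CohortConfig(n_cells=4, recurrence_floor=4, recurrence_upper_frac=0.5)

    def test_fraction_ordering_validated(self):
        with pytest.raises(ConfigError):
            CohortConfig(n_cells=30, recurrence_lower_frac=0.9, recurrence_upper_frac=0.8)


class TestQualityPass:
    @pytest.mark.parametrize(
        "dp,qd,fs,ad_alt,expected",
        [
            (3, 5.0, 10.0, 2, True),   # minimum depth of 3 suffices
            (2, 8.0, 1.0, 2, False),   # below the depth floor
            (10, 1.9, 1.0, 4, False),  # QD below 2.0
            (10, 8.0, 31.0, 4, False), # FS above 30.0
            (10, None, None, 4, True), # absent bias fields pass
            (10, 8.0, 1.0, 0, False),  # no alt support
        ],
    )
    def test_predicate(self, dp, qd, fs, ad_alt, expected):
        call = CellCall(k(1), "c", "G", dp=dp, ad_ref=dp - ad_alt, ad_alt=ad_alt,
                        qual=50.0, qd=qd, fs=fs)
        assert quality_pass(call, CFG30) is expected


class TestAnnotationFilter:
    def exons(self):
        return ExonIntervals({"chr1": [(0, 1000)]})

    def test_removal_order_and_ledger(self):
        editing = SiteList("editing", sites=frozenset({("chr1", 20)}))
        germ = SiteList("germline_population", keys=frozenset({k(30)}))
        calls = [
            mk_call(k(5000), "c1"),  # non-exonic
            mk_call(k(20), "c1"),    # editing site
            mk_call(k(30), "c1"),    # germline-listed
            mk_call(k(40), "c1"),
            mk_call(k(50), "c1"),
        ]
        kept, ledger, removed = annotation_filter(calls, self.exons(), editing, [germ])
        assert [c.key.pos for c in kept] == [40, 50]
        assert dict(ledger) == {"non_exonic": 1, "editing": 1, "germline_list": 1}
        assert removed[k(20)] == "editing"

    def test_editing_wins_over_germline(self):
        editing = SiteList("editing", sites=frozenset({("chr1", 20)}))
        germ = SiteList("germline_population", keys=frozenset({k(20)}))
        _, _, removed = annotation_filter([mk_call(k(20), "c1")], self.exons(), editing, [germ])
        assert removed[k(20)] == "editing"

    def test_empty_exons_fatal(self):
        with pytest.raises(ConfigError):
            annotation_filter([mk_call(k(1), "c1")], ExonIntervals({}), None, [])

    def test_no_germline_list_keeps_everything(self):
        kept, ledger, _ = annotation_filter([mk_call(k(10), "c1")], self.exons(), None, [])
        assert len(kept) == 1 and not ledger


class TestAssignSets:
    def test_intersection_and_primary_only(self):
        g = {"c1": [mk_call(k(1), "c1"), mk_call(k(2), "c1"), mk_call(k(3), "c1")]}
        s = {"c1": [mk_call(k(2), "c1", caller="S"), mk_call(k(3), "c1", caller="S"),
                    mk_call(k(4), "c1", caller="S")]}
        m = assign_sets(g, s)["c1"]
        assert m == {k(1): "B", k(2): "A", k(3): "A"}  # secondary-only k4 ignored

    def test_empty_primary_cell(self):
        assert assign_sets({"c1": []}, {"c1": []})["c1"] == {}

    def test_cell_missing_from_secondary_goes_all_b(self):
        m = assign_sets({"c1": [mk_call(k(1), "c1")]}, {})
        assert m["c1"] == {k(1): "B"}


class TestRecurrence:
    def test_distinct_cell_counting(self):
        g = {
            "c1": [mk_call(k(1), "c1")],
            "c2": [mk_call(k(1), "c2"), mk_call(k(1), "c2")],  # duplicate within cell
            "c3": [mk_call(k(1), "c3"), mk_call(k(2), "c3")],
        }
        counts = recurrence_counts(g)
        assert counts[k(1)] == 3 and counts[k(2)] == 1

    def test_matches_brute_force_on_random_cohort(self):
        rng = np.random.default_rng(42)
        keys = [k(i + 1) for i in range(50)]
        g = {
            f"c{i}": [mk_call(keys[j], f"c{i}") for j in rng.choice(50, size=12, replace=False)]
            for i in range(20)
        }
        counts = recurrence_counts(g)
        expect = oracles.brute_recurrence(
            {c: [call.key for call in calls] for c, calls in g.items()}
        )
        assert dict(counts) == expect


def _random_cohort(rng, n_cells=12, n_keys=40):
    """Random small cohort with mixed quality/consensus structure."""
    keys = [k(i + 1) for i in range(n_keys)]
    calls_by_cell, s_keys = {}, {}
    for i in range(n_cells):
        cell = f"c{i:02d}"
        chosen = rng.choice(n_keys, size=rng.integers(3, 12), replace=False)
        calls = []
        for j in chosen:
            calls.append(
                mk_call(
                    keys[j], cell,
                    dp=int(rng.integers(1, 20)),
                    ad_alt=1,
                    qd=float(rng.uniform(0, 10)) if rng.random() < 0.8 else None,
                    fs=float(rng.uniform(0, 60)) if rng.random() < 0.8 else None,
                )
            )
        calls_by_cell[cell] = calls
        s_keys[cell] = {keys[j] for j in chosen if rng.random() < 0.5}
    return calls_by_cell, s_keys


def _run_label(calls_by_cell, s_keys, n_cells):
    cfg = CohortConfig(n_cells=n_cells)
    membership = {
        cell: {c.key: ("A" if c.key in s_keys[cell] else "B") for c in calls}
        for cell, calls in calls_by_cell.items()
    }
    rec = recurrence_counts(calls_by_cell)
    return label_cohort(calls_by_cell, membership, rec, cfg)


class TestLabelCohort:
    def test_stated_rules_on_handmade_cohort(self):
        """30-cell cohort, L=3, U=24: the four canonical outcomes."""
        n = 30
        calls, s_keys = {f"c{i:02d}": [] for i in range(n)}, {f"c{i:02d}": set() for i in range(n)}
        pos_key, over_key, neg_key, uns_key = k(10), k(20), k(30), k(40)
        for i in range(5):  # quality-passing set-A calls in 5 cells
            calls[f"c{i:02d}"].append(mk_call(pos_key, f"c{i:02d}"))
            s_keys[f"c{i:02d}"].add(pos_key)
        for i in range(25):  # seen in 25 > 0.8*30 cells
            calls[f"c{i:02d}"].append(mk_call(over_key, f"c{i:02d}"))
        calls["c00"].append(mk_call(neg_key, "c00", dp=2))       # B-only, fails, singleton
        calls["c01"].append(mk_call(uns_key, "c01", dp=10))      # B-only but quality-passing
        lab = _run_label(calls, s_keys, n)
        assert lab.label[pos_key] == "positive"
        assert lab.label[over_key] == "removed" and lab.reason[over_key] == "over_recurrent"
        assert lab.label[neg_key] == "negative"
        assert lab.label[uns_key] == "unsure"

    def test_set_a_below_recurrence_floor_is_unsure(self):
        n = 30
        calls = {f"c{i:02d}": [] for i in range(n)}
        s_keys = {f"c{i:02d}": set() for i in range(n)}
        key = k(10)
        calls["c00"].append(mk_call(key, "c00"))
        s_keys["c00"].add(key)
        lab = _run_label(calls, s_keys, n)
        assert lab.label[key] == "unsure"

    def test_partition_and_oracle_agreement(self):
        rng = np.random.default_rng(7)
        calls_by_cell, s_keys = _random_cohort(rng)
        lab = _run_label(calls_by_cell, s_keys, 12)
        n_keys = len({c.key for calls in calls_by_cell.values() for c in calls})
        assert sum(lab.counts().values()) == n_keys
        expect = oracles.brute_labels(
            {
                cell: [
                    {"key": c.key, "dp": c.dp, "qd": c.qd, "fs": c.fs, "ad_alt": c.ad_alt}
                    for c in calls
                ]
                for cell, calls in calls_by_cell.items()
            },
            s_keys,
            n_cells=12,
        )
        assert lab.label == expect

    def test_monotone_in_recurrence_bounds(self):
        rng = np.random.default_rng(11)
        calls_by_cell, s_keys = _random_cohort(rng, n_cells=20)
        membership = {
            cell: {c.key: ("A" if c.key in s_keys[cell] else "B") for c in calls}
            for cell, calls in calls_by_cell.items()
        }
        rec = recurrence_counts(calls_by_cell)

        def lab(lower, upper):
            cfg = CohortConfig(n_cells=20, recurrence_lower_frac=lower, recurrence_upper_frac=upper)
            return label_cohort(calls_by_cell, membership, rec, cfg)

        base = lab(0.10, 0.80)
        stricter_lower = lab(0.30, 0.80)
        assert set(stricter_lower.keys_with("positive")) <= set(base.keys_with("positive"))
        stricter_upper = lab(0.10, 0.50)
        assert set(base.keys_with("removed")) <= set(stricter_upper.keys_with("removed"))

    def test_germline_listed_keys_always_removed(self):
        exons = ExonIntervals({"chr1": [(0, 1000)]})
        germ = SiteList("germline_population", keys=frozenset({k(5)}))
        calls = {f"c{i}": [mk_call(k(5), f"c{i}"), mk_call(k(6), f"c{i}")] for i in range(4)}
        pooled = [c for cs in calls.values() for c in cs]
        kept, _, removed = annotation_filter(pooled, exons, None, [germ])
        kept_by_cell = {cell: [c for c in cs if c.key != k(5)] for cell, cs in calls.items()}
        lab = label_cohort(
            kept_by_cell,
            assign_sets(kept_by_cell, {c: [] for c in calls}),
            recurrence_counts(kept_by_cell),
            CohortConfig(n_cells=4),
            removed,
        )
        assert lab.label[k(5)] == "removed" and lab.reason[k(5)] == "germline_list"

    def test_deterministic_under_cell_ordering(self):
        rng = np.random.default_rng(3)
        calls_by_cell, s_keys = _random_cohort(rng)
        lab1 = _run_label(calls_by_cell, s_keys, 12)
        reordered = dict(reversed(list(calls_by_cell.items())))
        lab2 = _run_label(reordered, s_keys, 12)
        assert lab1.label == lab2.label and lab1.recurrence == lab2.recurrence

    def test_cell_count_mismatch_fatal(self):
        with pytest.raises(ConfigError):
            label_cohort({"c1": []}, {"c1": {}}, {}, CohortConfig(n_cells=5))
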
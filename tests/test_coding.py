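"""Area sampling, cleaning rules, interrater reliability and consensus."""

import datetime as dt
import itertools

import numpy as np
import pytest

from sentits import (
    area_sample,
    calibration_loop,
    clean_sample,
    interrater_reliability,
    min_pairwise_reliability,
    resolve_consensus,
)
from sentits.coding import area_partition, deduplicate


def brute_force_partition(n, n_areas):
    """Independent enumerator: contiguous blocks, sizes differ by at most 1,
    larger blocks last, covering 0..n-1 exactly once."""
    base, rem = divmod(n, n_areas)
    sizes = [base] * (n_areas - rem) + [base + 1] * rem
    out, start = [], 0
    for s in sizes:
        out.append(list(range(start, start + s)))
        start += s
    assert sorted(itertools.chain.from_iterable(out)) == list(range(n))
    return out


class TestAreaSample:
    @pytest.mark.parametrize("n,n_areas", [(10, 5), (11, 5), (1000, 200), (7, 3), (200, 200)])
    def test_partition_matches_brute_force(self, n, n_areas):
        got = [list(range(a, b)) for a, b in area_partition(n, n_areas)]
        assert got == brute_force_partition(n, n_areas)

    def test_under_cap_keeps_everything(self, comment_factory):
        comments = [comment_factory(i) for i in range(399)]
        out, rep = area_sample(comments, cap=400, seed=0)
        assert len(out) == 399 and rep.n_sampled == 399

    def test_at_cap_boundary_keeps_everything(self, comment_factory):
        comments = [comment_factory(i) for i in range(400)]
        out, _ = area_sample(comments, cap=400, seed=0)
        assert len(out) == 400

    def test_over_cap_draws_two_per_area(self, comment_factory):
        comments = [comment_factory(i) for i in range(1000)]
        out, rep = area_sample(comments, cap=400, seed=1)
        assert len(out) == 400
        assert rep.areas_used == 200
        # each area of 5 chronologically consecutive comments contributes 2
        ordered = sorted(comments, key=lambda c: (c.date, c.comment_id))
        pos = {c.comment_id: i for i, c in enumerate(ordered)}
        per_area = np.zeros(200, dtype=int)
        for c in out:
            per_area[pos[c.comment_id] // 5] += 1
        assert (per_area == 2).all()

    def test_idempotent_under_fixed_seed(self, comment_factory):
        comments = [comment_factory(i) for i in range(900)]
        a, _ = area_sample(comments, cap=400, seed=7)
        b, _ = area_sample(comments, cap=400, seed=7)
        assert a == b

    def test_odd_cap_rejected(self, comment_factory):
        with pytest.raises(ValueError):
            area_sample([comment_factory(0)], cap=401)


class TestCleanSample:
    def make_batch(self, comment_factory, n, n_meaningless):
        out = []
        for i in range(n):
            flags = ("meaningless",) if i < n_meaningless else ()
            out.append(comment_factory(i, text=f"text {i}", flags=flags))
        return out

    def test_clean_input_passes_through(self, comment_factory):
        batch = self.make_batch(comment_factory, 50, 0)
        out, rep = clean_sample(batch, lambda c: "meaningless" in c.flags)
        assert sorted(c.comment_id for c in out) == sorted(c.comment_id for c in batch)
        assert rep.n_meaningless_removed == 0

    def test_refill_triggered_above_threshold(self, comment_factory):
        batch = self.make_batch(comment_factory, 100, 25)   # 25% > 20%
        pool = [comment_factory(1000 + i, text=f"pool {i}") for i in range(40)]
        out, rep = clean_sample(batch, lambda c: "meaningless" in c.flags,
                                refill_pool=pool, seed=0)
        assert len(out) == 100
        assert not any("meaningless" in c.flags for c in out)
        assert rep.n_meaningless_removed == 25
        assert rep.n_refilled == 25

    def test_retained_at_or_below_threshold(self, comment_factory):
        batch = self.make_batch(comment_factory, 100, 15)   # 15% <= 20%
        out, rep = clean_sample(batch, lambda c: "meaningless" in c.flags,
                                refill_pool=[], seed=0)
        assert len(out) == 100
        assert sum("meaningless" in c.flags for c in out) == 15
        assert rep.n_refilled == 0

    def test_duplicates_removed_first(self, comment_factory):
        batch = [
            comment_factory(0, text="same"),
            comment_factory(1, text="same"),
            comment_factory(2, text="different"),
        ]
        out, rep = clean_sample(batch, lambda c: False)
        assert len(out) == 2 and rep.n_after_dedup == 2

    def test_pool_exhaustion_falls_short(self, comment_factory):
        batch = self.make_batch(comment_factory, 20, 10)    # 50% meaningless
        pool = [comment_factory(100 + i, text=f"pool {i}") for i in range(4)]
        out, rep = clean_sample(batch, lambda c: "meaningless" in c.flags,
                                refill_pool=pool, seed=0)
        assert len(out) == 14
        assert rep.n_refilled == 4


class TestDeduplicate:
    def test_keeps_first_occurrence(self, comment_factory):
        a = comment_factory(0, date=dt.date(2014, 1, 1), text="x")
        b = comment_factory(1, date=dt.date(2014, 1, 2), text="x")
        assert deduplicate([b, a]) == [a]


class TestReliability:
    def test_identical_codings(self, coded_factory):
        a = [coded_factory(i, {"Blame Doctor"}) for i in range(10)]
        assert interrater_reliability(a, list(a)) == 1.0

    def test_forty_five_of_fifty(self, coded_factory):
        a = [coded_factory(i, {"Blame Doctor"}) for i in range(50)]
        b = [coded_factory(i, {"Blame Doctor"}) for i in range(45)] + [
            coded_factory(i, {"Support Doctor"}) for i in range(45, 50)
        ]
        assert interrater_reliability(a, b) == 0.9

    def test_disjoint_labels(self, coded_factory):
        a = [coded_factory(i, {"Blame Doctor"}) for i in range(5)]
        b = [coded_factory(i, {"Support Doctor"}) for i in range(5)]
        assert interrater_reliability(a, b) == 0.0

    def test_symmetric(self, coded_factory):
        rng = np.random.default_rng(0)
        cats = ["Blame Doctor", "Support Doctor", "N/A"]
        a = [coded_factory(i, {cats[rng.integers(3)]}) for i in range(30)]
        b = [coded_factory(i, {cats[rng.integers(3)]}) for i in range(30)]
        assert interrater_reliability(a, b) == interrater_reliability(b, a)

    def test_mismatched_ids_rejected(self, coded_factory):
        a = [coded_factory(0, {"N/A"})]
        b = [coded_factory(1, {"N/A"})]
        with pytest.raises(ValueError):
            interrater_reliability(a, b)

    def test_label_sets_must_match_exactly(self, coded_factory):
        a = [coded_factory(0, {"Blame Doctor", "Blame Big System"})]
        b = [coded_factory(0, {"Blame Doctor"})]
        assert interrater_reliability(a, b) == 0.0


class TestCalibration:
    def make_tables(self, coded_factory, n, n_disagree):
        truth = [coded_factory(i, {"Blame Doctor"}) for i in range(n)]
        other = [
            coded_factory(i, {"Support Doctor"} if i < n_disagree else {"Blame Doctor"})
            for i in range(n)
        ]
        return {"R1": truth, "R2": other}

    def test_identical_raters_pass(self, coded_factory):
        tables = self.make_tables(coded_factory, 60, 0)
        res = calibration_loop(tables, sample_size=50, seed=0)
        assert res.passed and res.reliability == 1.0 and res.n_used == 50

    def test_below_target_fails(self, coded_factory):
        tables = self.make_tables(coded_factory, 50, 6)     # 0.88 < 0.9
        res = calibration_loop(tables, sample_size=50, seed=0)
        assert not res.passed and res.reliability == pytest.approx(0.88)

    def test_zero_target_always_passes(self, coded_factory):
        tables = self.make_tables(coded_factory, 50, 50)
        assert calibration_loop(tables, sample_size=50, target=0.0, seed=0).passed

    def test_small_sample_uses_all(self, coded_factory):
        tables = self.make_tables(coded_factory, 20, 0)
        assert calibration_loop(tables, sample_size=50, seed=0).n_used == 20


class TestConsensus:
    def test_unanimous_pass_through(self, coded_factory):
        tables = {
            r: [coded_factory(0, {"Blame Doctor"}), coded_factory(1, {"N/A"})]
            for r in ("R1", "R2", "R3", "R4")
        }
        consensus, pending = resolve_consensus(tables)
        assert pending == []
        assert [c.labels for c in consensus] == [
            frozenset({"Blame Doctor"}), frozenset({"N/A"}),
        ]

    def test_three_to_one_majority(self, coded_factory):
        tables = {
            "R1": [coded_factory(0, {"Blame Doctor"})],
            "R2": [coded_factory(0, {"Blame Doctor"})],
            "R3": [coded_factory(0, {"Blame Doctor"})],
            "R4": [coded_factory(0, {"Blame Patient"})],
        }
        consensus, pending = resolve_consensus(tables)
        assert consensus[0].labels == frozenset({"Blame Doctor"})
        assert pending == []

    def test_even_split_escalated(self, coded_factory):
        tables = {
            "R1": [coded_factory(0, {"Blame Doctor"})],
            "R2": [coded_factory(0, {"Blame Doctor"})],
            "R3": [coded_factory(0, {"Blame Patient"})],
            "R4": [coded_factory(0, {"Blame Patient"})],
        }
        consensus, pending = resolve_consensus(tables)
        assert consensus == [] and pending == ["c00000"]

    def test_multilabel_majority_per_category(self, coded_factory):
        tables = {
            "R1": [coded_factory(0, {"Blame Doctor", "Blame Big System"})],
            "R2": [coded_factory(0, {"Blame Doctor", "Blame Big System"})],
            "R3": [coded_factory(0, {"Blame Doctor", "Blame Big System"})],
            "R4": [coded_factory(0, {"Blame Doctor"})],
        }
        consensus, _ = resolve_consensus(tables)
        assert consensus[0].labels == frozenset({"Blame Doctor", "Blame Big System"})

    def test_min_pairwise_is_minimum(self, coded_factory):
        perfect = [coded_factory(i, {"N/A"}) for i in range(10)]
        off = [coded_factory(i, {"N/A" if i else "Blame Doctor"}) for i in range(10)]
        tables = {"R1": perfect, "R2": list(perfect), "R3": off}
        assert min_pairwise_reliability(tables) == 0.9
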
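"""Replicate averaging, expression calls, presence partition, restriction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stagecorr.io import ExpressionTable, GeneSet, HomologMap, Sample
from stagecorr.preprocess import (
    StageAlignment,
    StageSeries,
    average_replicates,
    filter_map_to_series,
    is_expressed,
    log_transform,
    presence_partition,
    restrict,
)


def make_table(species, values, stage_hpf, n_reps, gene_ids=None):
    values = np.asarray(values, dtype=float)
    samples = tuple(
        Sample(stage_label=f"{h} hpf", hpf=h, replicate_id=f"r{r + 1}")
        for h in stage_hpf
        for r in range(n_reps)
    )
    gene_ids = gene_ids or tuple(f"{species}_g{i}" for i in range(values.shape[0]))
    return ExpressionTable(species, gene_ids, samples, values)


def make_series(species, values, hpf=None, gene_ids=None, tag="raw"):
    values = np.asarray(values, dtype=float)
    hpf = hpf if hpf is not None else 10.0 * (np.arange(values.shape[1]) + 1)
    return StageSeries(
        species_id=species,
        gene_ids=gene_ids or tuple(f"{species}_g{i}" for i in range(values.shape[0])),
        stage_labels=tuple(f"{int(h)} hpf" for h in hpf),
        hpf=hpf,
        values=values,
        transform_tag=tag,
    )


class TestAverageReplicates:
    def test_arithmetic_mean(self):
        t = make_table("sp", [[2.0, 4.0, 1.0, 3.0], [0.0, 0.0, 8.0, 8.0]], [10, 20], 2)
        s = average_replicates(t)
        np.testing.assert_array_equal(s.values, [[3.0, 2.0], [0.0, 8.0]])
        assert s.stage_labels == ("10 hpf", "20 hpf")

    def test_single_replicate_passthrough(self):
        t = make_table("sp", [[1.0, 2.0], [3.0, 4.0]], [10, 20], 1)
        np.testing.assert_array_equal(average_replicates(t).values, t.values)

    def test_stages_sorted_by_hpf(self):
        # columns entered as 30, 10, 20 hpf
        samples = tuple(
            Sample(f"{h} hpf", float(h), "r1") for h in (30, 10, 20)
        )
        t = ExpressionTable("sp", ("g0", "g1"), samples, [[3.0, 1.0, 2.0], [6.0, 4.0, 5.0]])
        s = average_replicates(t)
        assert s.stage_labels == ("10 hpf", "20 hpf", "30 hpf")
        np.testing.assert_array_equal(s.values, [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])

    @given(perm=st.permutations(list(range(6))))
    def test_replicate_order_invariance(self, perm):
        base = make_table(
            "sp", np.arange(12, dtype=float).reshape(2, 6), [10, 20, 30], 2
        )
        shuffled = ExpressionTable(
            "sp",
            base.gene_ids,
            tuple(base.samples[j] for j in perm),
            base.values[:, perm],
        )
        np.testing.assert_allclose(
            average_replicates(shuffled).values, average_replicates(base).values
        )


class TestIsExpressed:
    @pytest.mark.parametrize(
        "profile,threshold,expected",
        [
            ((0.0, 0.0, 3.1), 3.0, True),   # strictly above at one stage
            ((3.0, 3.0, 3.0), 3.0, False),  # equality does not count
            ((0.0, 0.0, 0.0), 0.0, False),
        ],
    )
    def test_strict_threshold(self, profile, threshold, expected):
        s = make_series("sp", [list(profile), [9.0, 9.0, 9.0]])
        assert is_expressed(s, "sp_g0", threshold) is expected

    def test_unknown_gene(self):
        s = make_series("sp", [[1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(KeyError, match="nope"):
            is_expressed(s, "nope", 3.0)


class TestLogTransform:
    @pytest.mark.parametrize("value,expected", [(0.0, 0.0), (99.0, 2.0), (9.0, 1.0)])
    def test_log10_with_unit_pseudocount(self, value, expected):
        s = make_series("sp", [[value, value], [1.0, 1.0]])
        out = log_transform(s, 1.0)
        assert out.values[0, 0] == pytest.approx(expected)
        assert out.transform_tag == "log"

    def test_double_transform_rejected(self):
        s = make_series("sp", [[1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(ValueError, match="already log"):
            log_transform(log_transform(s))

    @given(vals=st.lists(st.integers(0, 10**6), min_size=4, max_size=4, unique=True))
    def test_strictly_monotone_per_cell(self, vals):
        s = make_series("sp", np.asarray(sorted(vals), dtype=float).reshape(2, 2))
        out = log_transform(s)
        assert np.all(np.diff(out.values.ravel()) > 0)


def triple_map(n):
    return HomologMap(
        records=tuple((f"A_g{i}", f"B_g{i}", f"C_g{i}") for i in range(n)),
        species_order=("A", "B", "C"),
    )


class TestPresencePartition:
    def hand_cohort(self):
        # 4 triplets: g0, g1 expressed (>3) everywhere; g2 only in A and B;
        # g3 nowhere
        a = make_series("A", [[9, 9], [5, 0], [4, 4], [1, 1]], gene_ids=[f"A_g{i}" for i in range(4)])
        b = make_series("B", [[9, 9], [0, 5], [9, 0], [0, 0]], gene_ids=[f"B_g{i}" for i in range(4)])
        c = make_series("C", [[9, 9], [5, 5], [2, 2], [3, 3]], gene_ids=[f"C_g{i}" for i in range(4)])
        return a, b, c

    def test_hand_enumeration(self):
        a, b, c = self.hand_cohort()
        part = presence_partition([a, b, c], triple_map(4), threshold=3.0)
        # order: ABC, AB, AC, BC, A, B, C, none
        assert part.counts_vector() == (2, 1, 0, 0, 0, 0, 0, 1)
        assert part.regions[("A", "B", "C")] == (
            ("A_g0", "B_g0", "C_g0"),
            ("A_g1", "B_g1", "C_g1"),
        )

    def test_threshold_limits(self):
        a, b, c = self.hand_cohort()
        everything = presence_partition([a, b, c], triple_map(4), threshold=-1.0)
        assert everything.counts_vector()[0] == 4
        nothing = presence_partition([a, b, c], triple_map(4), threshold=np.inf)
        assert nothing.counts_vector()[-1] == 4

    def test_absent_gene_counts_as_not_expressed(self):
        a, b, c = self.hand_cohort()
        c_short = make_series(
            "C", c.values[:3], gene_ids=list(c.gene_ids[:3])
        )  # C_g3 absent from table
        part = presence_partition([a, b, c_short], triple_map(4), threshold=3.0)
        assert part.total == 4
        assert part.counts_vector()[-1] == 1

    @given(
        data=st.integers(0, 2**20 - 1),
        n=st.integers(1, 12),
        threshold=st.floats(0, 10, allow_nan=False),
    )
    def test_region_sizes_sum_to_map(self, data, n, threshold):
        rng = np.random.default_rng(data)
        series = [
            make_series(sp, rng.uniform(0, 10, size=(n, 3)),
                        gene_ids=[f"{sp}_g{i}" for i in range(n)])
            for sp in "ABC"
        ]
        part = presence_partition(series, triple_map(n), threshold=threshold)
        assert part.total == n
        assert sum(part.counts_vector()) == n


class TestRestrict:
    def pair(self, n=10, n_stages=8):
        rng = np.random.default_rng(0)
        a = make_series("A", rng.uniform(0, 9, (n, n_stages)),
                        gene_ids=[f"A_g{i}" for i in range(n)])
        b = make_series("B", rng.uniform(0, 9, (n, n_stages)),
                        gene_ids=[f"B_g{i}" for i in range(n)])
        m = HomologMap(
            records=tuple((f"A_g{i}", f"B_g{i}") for i in range(n)),
            species_order=("A", "B"),
        )
        return a, b, m

    def test_set_and_alignment_bookkeeping(self):
        a, b, m = self.pair()
        gs = GeneSet("four", members=("A_g1", "A_g3", "A_g5", "A_g7"))
        align = StageAlignment(tuple((f"{10*(k+1)} hpf", f"{10*(k+1)} hpf") for k in range(7)))
        paired = restrict(a, b, m, gene_set=gs, alignment=align)
        assert paired.a.shape == paired.b.shape == (4, 7)
        assert paired.gene_ids_a == ("A_g1", "A_g3", "A_g5", "A_g7")
        assert paired.gene_ids_b == ("B_g1", "B_g3", "B_g5", "B_g7")

    def test_member_order_invariance(self):
        a, b, m = self.pair()
        g1 = GeneSet("s", members=("A_g1", "A_g3", "A_g5"))
        g2 = GeneSet("s", members=("A_g5", "A_g1", "A_g3"))
        p1 = restrict(a, b, m, gene_set=g1)
        p2 = restrict(a, b, m, gene_set=g2)
        np.testing.assert_array_equal(p1.a, p2.a)  # map order, not member order

    def test_none_set_keeps_all(self):
        a, b, m = self.pair()
        assert restrict(a, b, m).n_genes == 10

    def test_empty_intersection(self):
        a, b, m = self.pair()
        with pytest.raises(ValueError, match="empty gene set"):
            restrict(a, b, m, gene_set=GeneSet("miss", members=("X_g9",)))

    def test_missing_gene_raises(self):
        a, b, m = self.pair()
        b_short = make_series("B", b.values[:5], gene_ids=list(b.gene_ids[:5]))
        with pytest.raises(KeyError, match="filter_map_to_series"):
            restrict(a, b_short, m)
        filtered = filter_map_to_series(m, [a, b_short])
        assert len(filtered) == 5
        assert restrict(a, b_short, filtered).n_genes == 5

    def test_alignment_must_be_order_preserving(self):
        a, b, m = self.pair()
        bad = StageAlignment((("20 hpf", "10 hpf"), ("10 hpf", "20 hpf")))
        with pytest.raises(ValueError, match="order-preserving"):
            restrict(a, b, m, alignment=bad)
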
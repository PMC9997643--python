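import math

import numpy as np
import pytest

from aimkit.model import VariantRecord
from aimkit.popgen import maf, weighted_fst, weir_fst
from aimkit.simulate import PopulationSpec, SimulationConfig, simulate

from .conftest import make_matrix
from .oracles import weir_cockerham_oracle


def two_group_matrix(genos_a, genos_b):
    g = make_matrix(
        [[c] for c in genos_a + genos_b],
        samples=[f"A{i}" for i in range(len(genos_a))]
        + [f"B{i}" for i in range(len(genos_b))],
    )
    groups = {
        "A": [f"A{i}" for i in range(len(genos_a))],
        "B": [f"B{i}" for i in range(len(genos_b))],
    }
    return g, groups


class TestWeirFstExamples:
    def test_fixed_difference_is_one(self):
        g, groups = two_group_matrix([(0, 0)] * 10, [(1, 1)] * 10)
        rec = weir_fst(g, groups)[0]
        assert rec.a == pytest.approx(0.5, abs=1e-12)
        assert rec.b == pytest.approx(0.0, abs=1e-12)
        assert rec.c == 0.0
        assert rec.fst == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic_undefined(self):
        g, groups = two_group_matrix([(0, 0)] * 5, [(0, 0)] * 5)
        rec = weir_fst(g, groups)[0]
        assert math.isnan(rec.fst)

    def test_identical_groups_with_hets_nonpositive(self):
        genos = [(0, 1), (0, 1), (0, 0), (1, 1)]
        g, groups = two_group_matrix(list(genos), list(genos))
        rec = weir_fst(g, groups)[0]
        assert rec.s2 == pytest.approx(0.0, abs=1e-12)
        assert rec.a < 0 and rec.b > 0 and rec.c > 0
        assert rec.fst <= 0

    def test_group_without_calls_undefined(self):
        g, groups = two_group_matrix([(0, 1)] * 3, [None] * 3)
        rec = weir_fst(g, groups)[0]
        assert math.isnan(rec.fst)

    def test_needs_two_groups(self):
        g, groups = two_group_matrix([(0, 1)], [(0, 1)])
        with pytest.raises(ValueError):
            weir_fst(g, {"A": groups["A"]})


class TestFilters:
    def _mixed_matrix(self):
        variants = [
            VariantRecord("1", 100, "v1", "A", ("G",)),
            VariantRecord("1", 200, "v2", "A", ("G", "T")),
            VariantRecord("X", 300, "v3", "A", ("G",)),
        ]
        g = make_matrix(
            [[(0, 1), (0, 2), (0, 1)], [(1, 1), (1, 2), (0, 0)]],
            variants=variants,
        )
        return g, {"A": ["S1"], "B": ["S2"]}

    def test_biallelic_autosomal_restriction(self):
        g, groups = self._mixed_matrix()
        recs = weir_fst(g, groups)
        assert [r.variant_id for r in recs] == ["v1"]

    def test_flags_disable_filters(self):
        g, groups = self._mixed_matrix()
        recs = weir_fst(g, groups, biallelic_only=False, autosomes_only=False)
        assert [r.variant_id for r in recs] == ["v1", "v2", "v3"]


class TestOracleEquivalence:
    def test_500_random_sites(self):
        rng = np.random.default_rng(77)
        for _ in range(500):
            r = int(rng.integers(2, 5))
            sizes = rng.integers(2, 15, size=r)
            group_genos = [
                [tuple(rng.integers(0, 2, size=2)) for _ in range(n)]
                for n in sizes
            ]
            flat = [c for grp in group_genos for c in grp]
            g = make_matrix(
                [[c] for c in flat],
                samples=[f"S{i}" for i in range(len(flat))],
            )
            start = 0
            groups = {}
            for gi, n in enumerate(sizes):
                groups[f"G{gi}"] = [f"S{i}" for i in range(start, start + n)]
                start += n
            rec = weir_fst(g, groups)[0]
            a, b, c, fst = weir_cockerham_oracle(group_genos)
            assert rec.a == pytest.approx(a, abs=1e-10)
            assert rec.b == pytest.approx(b, abs=1e-10)
            assert rec.c == pytest.approx(c, abs=1e-10)
            if math.isnan(fst):
                assert math.isnan(rec.fst)
            else:
                assert rec.fst == pytest.approx(fst, abs=1e-10)


class TestInvariances:
    def test_allele_label_swap(self):
        genos_a = [(0, 1), (1, 1), (0, 0), (0, 1)]
        genos_b = [(0, 0), (0, 1), (0, 0), (1, 1)]
        g, groups = two_group_matrix(list(genos_a), list(genos_b))
        swapped = [
            [(1 - a, 1 - b)] for a, b in genos_a
        ] + [[(1 - a, 1 - b)] for a, b in genos_b]
        g2 = make_matrix(swapped, samples=g.samples)
        r1 = weir_fst(g, groups)[0]
        r2 = weir_fst(g2, groups)[0]
        assert r1.fst == pytest.approx(r2.fst, abs=1e-12)

    def test_group_order_permutation(self):
        g, groups = two_group_matrix([(0, 1)] * 4 + [(1, 1)], [(0, 0)] * 5)
        r1 = weir_fst(g, groups)[0]
        r2 = weir_fst(g, dict(reversed(groups.items())))[0]
        assert r1.fst == pytest.approx(r2.fst, abs=1e-12)


class TestBaldingNicholsRecovery:
    def test_mean_fst_near_drift(self):
        means = []
        for rep in range(3):
            cfg = SimulationConfig(
                populations=(
                    PopulationSpec("P1", 100, 0.1),
                    PopulationSpec("P2", 100, 0.1),
                ),
                n_markers=2000,
                seed=1000 + rep,
            )
            g, panel, _ = simulate(cfg)
            recs = weir_fst(
                g, {"P1": panel.members("P1"), "P2": panel.members("P2")}
            )
            means.append(np.nanmean([r.fst for r in recs]))
        assert all(abs(m - 0.1) <= 0.02 for m in means)


class TestMaf:
    def test_pooled_minor_designation(self):
        # pooled p_alt = 0.75 -> minor allele is ref
        g, groups = two_group_matrix([(1, 1)] * 2, [(0, 1), (1, 1)])
        df = maf(g, groups)
        assert df.loc[0, "minor_allele"] == "A"  # ref
        assert df.loc[0, "A"] == pytest.approx(0.0)
        assert df.loc[0, "B"] == pytest.approx(0.25)

    def test_tie_breaks_to_alt(self):
        g, groups = two_group_matrix([(0, 1)], [(0, 1)])
        df = maf(g, groups)
        assert df.loc[0, "minor_allele"] == "G"
        assert df.loc[0, "A"] == pytest.approx(0.5)

    def test_monomorphic_zero(self):
        g, groups = two_group_matrix([(0, 0)], [(0, 0)])
        df = maf(g, groups)
        assert df.loc[0, "A"] == 0.0 and df.loc[0, "B"] == 0.0

    def test_multiallelic_rejected(self):
        variants = [VariantRecord("1", 100, "v1", "A", ("G", "T"))]
        g = make_matrix([[(0, 2)]], variants=variants)
        with pytest.raises(ValueError):
            maf(g, {"A": ["S1"]})

    def test_balding_nichols_group_spread(self):
        cfg = SimulationConfig(
            populations=(
                PopulationSpec("P1", 100, 0.1),
                PopulationSpec("P2", 100, 0.1),
            ),
            n_markers=500,
            seed=4,
        )
        g, panel, _ = simulate(cfg)
        groups = {"P1": panel.members("P1"), "P2": panel.members("P2")}
        df = maf(g, groups)
        pooled = maf(g, {"ALL": g.samples})
        spread = (df["P1"] - df["P2"]).abs()
        assert spread.mean() > 0.05  # drift separates group frequencies
        between = (
            (pooled["ALL"] >= np.minimum(df["P1"], df["P2"]) - 1e-12)
            & (pooled["ALL"] <= np.maximum(df["P1"], df["P2"]) + 1e-12)
        )
        assert between.all()  # pooled frequency is intermediate


def test_weighted_fst_matches_ratio_of_sums():
    g, groups = two_group_matrix(
        [(0, 0), (0, 1), (1, 1)], [(1, 1), (1, 1), (0, 1)]
    )
    recs = weir_fst(g, groups)
    expected = sum(r.a for r in recs) / sum(r.a + r.b + r.c for r in recs)
    assert weighted_fst(recs) == pytest.approx(expected)
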
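"""Tests for pooled cluster statistics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from molcluster.model_io import BindingRule, MoleculeType, SeedSpecies, TimecourseTable
from molcluster.species_graph import (
    generate_synthetic_clusters,
    parse_complex,
    summarize,
)
from molcluster.stats import (
    bf_matrix,
    bin_distribution,
    bond_histogram,
    composition_table,
    default_size_bins,
    occupancy_distribution,
    pool,
    timecourse_stats,
)
from tests.conftest import make_model


def _summaries(model, strings):
    out = []
    for s in strings:
        out.extend(summarize(c) for c in parse_complex(s, model))
    return out


@pytest.fixture
def ab2_model():
    """Multivalent A and B with a self-binding rule, so A-A and A-B dimers exist."""
    return make_model(
        [MoleculeType("A", ("a1", "a2", "a3")), MoleculeType("B", ("b1", "b2", "b3", "b4"))],
        [SeedSpecies("A", 10), SeedSpecies("B", 10)],
        [
            BindingRule("R1", ("A", "a1"), ("A", "a2"), 1.0, 1.0),
            BindingRule("R2", ("A", "a1"), ("B", "b1"), 1.0, 1.0),
        ],
    )


class TestOccupancy:
    def test_pooled_sizes_1_1_2(self, ab_model):
        pooled = _summaries(ab_model, ["A(a)", "B(b)", "A(a!1).B(b!1)"])
        dist = occupancy_distribution(pooled)
        assert dist.fractions == {1: 0.5, 2: 0.5}
        assert dist.aco == pytest.approx(1.5)

    def test_all_monomers(self, ab_model):
        pooled = _summaries(ab_model, ["A(a)"] * 4)
        dist = occupancy_distribution(pooled)
        assert dist.fractions == {1: 1.0}
        assert dist.aco == 1.0

    def test_single_cluster_of_size_n(self, nnn_model):
        clusters = generate_synthetic_clusters({7: 1}, nnn_model, seed=2)
        dist = occupancy_distribution([summarize(c) for c in clusters])
        assert dist.fractions == {7: 1.0}
        assert dist.aco == 7.0

    def test_pool_expands_species_counts(self, ab_model):
        pooled = pool([("A(a!1).B(b!1)", 5)], model=ab_model)
        assert len(pooled) == 5

    def test_pool_of_two_trials_concatenates(self, ab_model):
        t = _summaries(ab_model, ["A(a)", "B(b)", "A(a!1).B(b!1)"])
        dist = occupancy_distribution(t + t)
        assert dist.fractions == {1: 0.5, 2: 0.5}

    def test_empty_pool_is_an_error(self):
        with pytest.raises(ValueError):
            pool([])


class TestBinning:
    def test_two_bins(self, ab_model):
        dist = occupancy_distribution(
            _summaries(ab_model, ["A(a)", "B(b)", "A(a!1).B(b!1)"])
        )
        binned = bin_distribution(dist, [(1, 10), (11, None)])
        assert binned.fractions == [1.0, 0.0]
        binned = bin_distribution(dist, [(1, 1), (2, None)])
        assert binned.fractions == [0.5, 0.5]

    def test_fractions_conserved_under_default_bins(self, nnn_model):
        clusters = generate_synthetic_clusters({1: 5, 3: 2, 12: 1, 40: 1}, nnn_model, 4)
        dist = occupancy_distribution([summarize(c) for c in clusters])
        binned = bin_distribution(dist)
        assert sum(binned.fractions) == pytest.approx(sum(dist.fractions.values()))

    @pytest.mark.parametrize(
        "bins", [[(1, 10), (10, None)], [(1, 10), (12, None)], [(1, 10), (11, 20)]]
    )
    def test_invalid_bins_rejected(self, ab_model, bins):
        dist = occupancy_distribution(_summaries(ab_model, ["A(a)"]))
        with pytest.raises(ValueError):
            bin_distribution(dist, bins)

    def test_default_bins_monomer_resolved_then_log(self):
        bins = default_size_bins(100)
        assert bins[:10] == [(s, s) for s in range(1, 11)]
        assert bins[10] == (11, 20)
        assert bins[11] == (21, 40)
        assert bins[-1][1] is None


class TestBondHistogram:
    def test_chain_of_three(self, chain_model):
        pooled = _summaries(chain_model, ["A(a!1).B(b1!1,b2!2).A(a!2)"])
        hist = bond_histogram(pooled)
        assert hist.fractions == {1: pytest.approx(2 / 3), 2: pytest.approx(1 / 3)}
        assert hist.mean_bonds == pytest.approx(4 / 3)

    def test_all_monomers(self, ab_model):
        hist = bond_histogram(_summaries(ab_model, ["A(a)", "B(b)"]))
        assert hist.fractions == {0: 1.0}
        assert hist.mean_bonds == 0.0

    def test_per_type_scope(self, chain_model):
        pooled = _summaries(chain_model, ["A(a!1).B(b1!1,b2!2).A(a!2)", "A(a)"])
        hist = bond_histogram(pooled, scope="B")
        assert hist.fractions == {2: 1.0}

    def test_nwasp_support_within_valence(self, nnn_model):
        clusters = generate_synthetic_clusters({9: 4}, nnn_model, seed=6)
        hist = bond_histogram([summarize(c) for c in clusters], scope="NWASP",
                              model=nnn_model)
        assert set(hist.fractions) <= set(range(0, 7))

    def test_unknown_type_rejected(self, ab_model):
        with pytest.raises(ValueError, match="unknown molecule type"):
            bond_histogram(_summaries(ab_model, ["A(a)"]), scope="Z", model=ab_model)

    def test_tree_mean_bonds_identity(self, nnn_model):
        """Over one tree of size n the mean degree is exactly 2(n-1)/n."""
        for n in (2, 5, 11):
            clusters = generate_synthetic_clusters({n: 1}, nnn_model, seed=n)
            hist = bond_histogram([summarize(c) for c in clusters])
            assert hist.mean_bonds == pytest.approx(2 * (n - 1) / n)


class TestBFMatrix:
    def test_identical_dimers_single_cell(self, nnn_model):
        pooled = _summaries(
            nnn_model, ["Nephrin(y1!1,y2,y3).Nck(sh2!1,sh3a,sh3b,sh3c)"] * 10
        )
        mat = bf_matrix(pooled)
        assert np.count_nonzero(mat.freq) == 1
        assert mat.freq.max() == 1.0

    def test_columns_normalized(self, nnn_model):
        clusters = generate_synthetic_clusters({1: 4, 2: 3, 5: 2}, nnn_model, seed=9)
        mat = bf_matrix([summarize(c) for c in clusters])
        sums = mat.freq.sum(axis=0)
        nonempty = sums > 0
        assert np.allclose(sums[nonempty], 1.0)

    def test_two_compositions_split_evenly(self, ab2_model):
        aa = "A(a1!1,a2,a3).A(a1,a2!1,a3)"  # BF 2/6
        ab = "A(a1!1,a2,a3).B(b1!1,b2,b3,b4)"  # BF 2/7
        pooled = _summaries(ab2_model, [aa] * 5 + [ab] * 5)
        mat = bf_matrix(pooled, bf_bin_width=0.02)
        col = mat.freq[:, 1]  # size-2 column (bins 1, 2)
        assert sorted(col[col > 0]) == [0.5, 0.5]

    def test_bad_bf_bin_width(self, ab_model):
        with pytest.raises(ValueError):
            bf_matrix(_summaries(ab_model, ["A(a)"]), bf_bin_width=0.0)

    def test_bf_one_lands_in_last_bin(self, chain_model):
        pooled = _summaries(chain_model, ["A(a!1).B(b1!1,b2!2).A(a!2)"])
        mat = bf_matrix(pooled, bf_bin_width=0.05)
        assert mat.freq[-1].sum() == 1.0


class TestComposition:
    def test_mixed_size2_composition(self, ab2_model):
        pooled = _summaries(
            ab2_model,
            ["A(a1!1,a2,a3).B(b1!1,b2,b3,b4)", "A(a1!1,a2,a3).A(a1,a2!1,a3)"],
        )
        comp = composition_table(pooled)
        df = comp.to_frame()
        assert df.loc["2", "A"] == pytest.approx(3 / 4)
        assert df.loc["2", "B"] == pytest.approx(1 / 4)

    def test_rows_sum_to_one(self, nnn_model):
        clusters = generate_synthetic_clusters({1: 3, 2: 2, 6: 2}, nnn_model, seed=1)
        comp = composition_table([summarize(c) for c in clusters])
        assert np.allclose(comp.fractions.sum(axis=1), 1.0)

    def test_single_type_model(self):
        model = make_model(
            [MoleculeType("A", ("a1", "a2"))],
            [SeedSpecies("A", 4)],
            [BindingRule("R1", ("A", "a1"), ("A", "a2"), 1.0, 1.0)],
        )
        pooled = _summaries(model, ["A(a1,a2)", "A(a1!1,a2).A(a1,a2!1)"])
        comp = composition_table(pooled)
        assert np.allclose(comp.fractions, 1.0)


class TestTimecourseStats:
    def _table(self, values):
        return TimecourseTable(times=np.arange(len(values)), columns={"x": values})

    def test_identical_trials_zero_std(self):
        t = self._table([1.0, 2.0, 3.0])
        ts = timecourse_stats([t, t])
        assert np.all(ts.std["x"] == 0)
        assert np.array_equal(ts.mean["x"], [1, 2, 3])

    def test_sample_std_with_n_minus_one(self):
        ts = timecourse_stats([self._table([0.0]), self._table([2.0])])
        assert ts.mean["x"][0] == pytest.approx(1.0)
        assert ts.std["x"][0] == pytest.approx(np.sqrt(2))

    def test_single_trial_zero_std_by_convention(self):
        ts = timecourse_stats([self._table([5.0, 6.0])])
        assert np.all(ts.std["x"] == 0)

    def test_mismatched_grids_rejected(self):
        a = TimecourseTable(times=[0, 1], columns={"x": [1, 2]})
        b = TimecourseTable(times=[0, 2], columns={"x": [1, 2]})
        with pytest.raises(ValueError, match="grids"):
            timecourse_stats([a, b])


@given(st.lists(st.tuples(st.integers(1, 30), st.integers(1, 5)), min_size=1, max_size=8))
def test_aco_pooling_identity(per_trial_spec):
    """Pooled ACO equals the molecule-weighted mean of per-trial ACOs."""
    from molcluster.species_graph import ClusterSummary

    def fake(size):
        return ClusterSummary(
            size=size, type_counts={"A": size}, n_bonds=size - 1,
            total_sites=2 * size, bound_sites=2 * (size - 1),
            bound_fraction=(size - 1) / size, degree_by_node={}, node_types={},
            is_tree=True,
        )

    trials = [[fake(s) for s in range(1, size + 1)] * mult
              for size, mult in per_trial_spec]
    pooled = [c for tr in trials for c in tr]
    aco_pooled = occupancy_distribution(pooled).aco
    weights = [sum(c.size for c in tr) for tr in trials]
    acos = [occupancy_distribution(tr).aco for tr in trials]
    weighted = sum(w * a for w, a in zip(weights, acos)) / sum(weights)
    assert aco_pooled == pytest.approx(weighted)
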
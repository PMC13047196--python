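import numpy as np
import pytest

from casingsoil import simulate_dataset, recovery_design
from casingsoil.assembly import (
    DegenerateCommunityError,
    PROCESSES,
    assembly_profile,
    bmntd,
    bnti,
    bnti_matrix,
    classify,
    patristic_distances,
    rc_bray,
    rc_matrix,
    summarize,
)

THREE_TIP_D = np.array(
    [[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]]
)


class TestBmntd:
    def test_hand_case_on_three_tip_tree(self):
        # x = {A}, y = {B}, d(A,B)=2 -> 0.5*(2+2) = 2
        assert bmntd([1, 0, 0], [0, 1, 0], THREE_TIP_D) == pytest.approx(2.0)

    def test_identical_communities_give_zero(self, rng):
        x = rng.integers(0, 10, size=3)
        x[0] += 1
        assert bmntd(x, x, THREE_TIP_D) == 0.0

    def test_symmetry_and_nonnegativity(self, rng):
        for _ in range(20):
            x = rng.integers(0, 5, size=3) + [1, 0, 0]
            y = rng.integers(0, 5, size=3) + [0, 0, 1]
            assert bmntd(x, y, THREE_TIP_D) == pytest.approx(
                bmntd(y, x, THREE_TIP_D)
            )
            assert bmntd(x, y, THREE_TIP_D) >= 0

    def test_branch_scaling_linearity(self):
        x, y = [3, 1, 0], [0, 2, 5]
        base = bmntd(x, y, THREE_TIP_D)
        assert bmntd(x, y, 3.0 * THREE_TIP_D) == pytest.approx(3.0 * base)

    def test_empty_community_rejected(self):
        with pytest.raises(DegenerateCommunityError):
            bmntd([0, 0, 0], [1, 0, 0], THREE_TIP_D)


class TestBnti:
    def test_star_phylogeny_degenerate_null(self):
        """Equal tip-tip distances make every shuffle identical."""
        d = 2.0 * (np.ones((6, 6)) - np.eye(6))
        x = np.array([5, 3, 0, 0, 1, 0])
        y = np.array([0, 0, 4, 2, 0, 1])
        with pytest.warns(RuntimeWarning, match="degenerate"):
            val = bnti(x, y, d, n_null=99, seed=0)
        assert val == 0.0

    def test_monte_carlo_stability_across_seeds(self, small_dataset):
        _, table, tree, meta, _ = small_dataset
        d = patristic_distances(tree, table.taxon_ids)
        x = table.matrix[0]
        y = table.matrix[7]
        a = bnti(x, y, d, n_null=999, seed=1)
        b = bnti(x, y, d, n_null=999, seed=2)
        assert abs(a - b) < 0.5

    def test_strong_selection_signs(self):
        """Contrasting environments give betaNTI > 2; shared environments
        phylogenetically cluster (negative betaNTI medians)."""
        from dataclasses import replace

        design = replace(
            recovery_design("selection", seed=11),
            stage_amplitude=0.0,
            selection_strength=100.0,
            dispersal_regime="limited",
            dispersal_sigma=1.5,
        )
        table, tree, meta, _ = simulate_dataset(design)
        d = patristic_distances(tree, table.taxon_ids)
        # across contrasting environments (peat 0 vs 100), stage-matched
        cross = [
            bnti(
                table.counts.loc[f"CT0_s{s}_r{r}"].to_numpy(),
                table.counts.loc[f"CT100_s{s}_r{r}"].to_numpy(),
                d, n_null=199, seed=7,
            )
            for s in (1, 3, 5)
            for r in (1, 2)
        ]
        assert np.median(cross) > 2.0
        # within shared environments: clustered, medians clearly negative
        pairs, _ = assembly_profile(table, tree, meta, n_null=199, seed=5)
        within_medians = pairs.groupby("group")["bnti"].median()
        assert (within_medians < -0.5).all()


class TestRcBray:
    def test_identical_samples_near_minus_one(self, rng):
        pool = rng.integers(0, 30, size=(10, 80))
        x = pool[0] + 1
        assert rc_bray(x, x, pool + 1, n_null=999, seed=0) < -0.9

    def test_pool_draws_center_near_zero(self, rng):
        """Independent draws from one pool give RC centered near 0."""
        p = rng.dirichlet(np.ones(100) * 0.5)
        counts = rng.multinomial(2000, p, size=40)
        rc_vals = []
        for k in range(100):
            a, b = rng.choice(40, size=2, replace=False)
            rc_vals.append(
                rc_bray(counts[a], counts[b], counts, n_null=199, seed=k)
            )
        assert abs(np.mean(rc_vals)) < 0.2

    def test_tie_rule_antisymmetry(self, rng):
        """RC computed from 'below' counts equals the negative of RC
        computed from 'above' counts (ties split evenly)."""
        pool = rng.integers(0, 20, size=(8, 40)) + 1
        x, y = pool[0], pool[1]
        n_null = 199
        from casingsoil.assembly import _null_communities

        keep = pool.sum(axis=0) > 0
        occ = (pool[:, keep] > 0).mean(axis=0)
        pp = pool[:, keep].sum(axis=0) / pool[:, keep].sum()
        rng2 = np.random.default_rng(3)
        nulls = _null_communities(
            np.vstack([x[keep], y[keep]]), occ, pp, n_null, rng2
        )
        tot = x[keep].sum() + y[keep].sum()
        obs = np.abs(x[keep] - y[keep]).sum() / tot
        null_bc = np.abs(nulls[0] - nulls[1]).sum(axis=1) / tot
        below = (null_bc < obs).sum()
        above = (null_bc > obs).sum()
        ties = (null_bc == obs).sum()
        rc_from_below = 2 * (below + 0.5 * ties) / n_null - 1
        rc_from_above = -(2 * (above + 0.5 * ties) / n_null - 1)
        assert rc_from_below == pytest.approx(rc_from_above)

    def test_empty_pool_rejected(self):
        with pytest.raises(DegenerateCommunityError):
            rc_bray([1, 0], [0, 1], np.zeros((3, 2), dtype=int), seed=0)


class TestClassification:
    @pytest.mark.parametrize(
        "b, r, expected",
        [
            (2.5, 0.0, "variable_selection"),
            (2.5, -0.99, "variable_selection"),
            (-2.5, 0.99, "homogeneous_selection"),
            (0.3, 0.99, "dispersal_limitation"),
            (0.3, -0.99, "homogenizing_dispersal"),
            (0.3, 0.5, "undominated"),
            (2.0, 0.95, "undominated"),  # boundaries fall stochastic side
            (-2.0, -0.95, "undominated"),
        ],
    )
    def test_rule_table(self, b, r, expected):
        assert classify(b, r) == expected

    def test_classification_is_total(self, rng):
        for _ in range(200):
            b = rng.normal(scale=3)
            r = rng.uniform(-1, 1)
            assert classify(b, r) in PROCESSES

    def test_summarize_fractions_sum_to_one(self, rng):
        procs = rng.choice(PROCESSES, size=57).tolist()
        fr = summarize(procs)
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in fr.values())


class TestProfile:
    def test_profile_partitions_all_pairs(self, small_dataset):
        _, table, tree, meta, _ = small_dataset
        pairs, fractions = assembly_profile(
            table, tree, meta, n_null=99, seed=0
        )
        # 2 groups x C(6,2) pairs
        assert len(pairs) == 2 * 15
        assert set(pairs["process"]) <= set(PROCESSES)
        np.testing.assert_allclose(fractions.sum(axis=1), 1.0, atol=1e-9)
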
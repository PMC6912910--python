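"""Generators: trees, traits, communities, climate, fixture stability."""

import hashlib
import warnings

import numpy as np
import pandas as pd
import pytest

from phylostruct.climate import validate_climate_table
from phylostruct.community import read_community
from phylostruct.synth import (
    SynthConfig,
    add_outgroup,
    make_fixture,
    simulate_climate,
    simulate_communities,
    simulate_niche,
    simulate_traits,
    simulate_tree,
)
from phylostruct.tree import Phylogeny


class TestSimulateTree:
    def test_ultrametric_and_scaled(self):
        t = simulate_tree(17, seed=5)
        assert t.is_ultrametric(tol=1e-9)
        depths = np.diag(t.covariance().values)
        assert np.allclose(depths, 1.0, atol=1e-9)

    def test_seed_determinism(self):
        a = simulate_tree(12, seed=9).to_newick()
        b = simulate_tree(12, seed=9).to_newick()
        assert a == b
        c = simulate_tree(12, seed=10).to_newick()
        assert a != c

    def test_yule_age_matches_theory(self):
        """Pure-birth trees grown from the two daughters of the root:
        expected age to reach n tips is sum_{k=2}^{n-1} 1/(b k), plus one
        mean inter-event interval 1/(b n) for the length-biased sampling
        of the n-tip window."""
        n, b = 10, 1.0
        want = sum(1.0 / (b * k) for k in range(2, n)) + 1.0 / (b * n)
        ages = [
            np.diag(
                simulate_tree(
                    n, birth_rate=b, death_rate=0.0, seed=s,
                    scale_depth=None,
                ).covariance().values
            ).max()
            for s in range(150)
        ]
        assert np.mean(ages) == pytest.approx(want, rel=0.10)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SynthConfig(birth_rate=0.1, death_rate=0.2)
        with pytest.raises(ValueError):
            SynthConfig(richness_range=(1, 5))
        # richness cap follows small species pools
        assert SynthConfig(
            n_species=8, richness_range=(2, 15)
        ).richness_range == (2, 8)


class TestOutgroup:
    def test_ingroup_distances_preserved(self, tree47):
        aug = add_outgroup(tree47, ["Ephedra_a", "Ephedra_b"])
        D0 = tree47.distances()
        D1 = aug.distances()
        for a in tree47.tip_labels[:8]:
            for b in tree47.tip_labels[:8]:
                assert D1.loc(a, b) == pytest.approx(
                    D0.loc(a, b), abs=1e-9
                )
        assert aug.is_ultrametric(tol=1e-6)
        # outgroup is distant: distance to any ingroup tip = 2 * new depth
        assert D1.loc("Ephedra_a", tree47.tip_labels[0]) > 2.0


class TestSimulateTraits:
    def test_sigma_zero_degenerate(self, tree47):
        x = simulate_traits(tree47, 0.5, 0.0, 3.3, seed=1)
        assert (x == 3.3).all()

    def test_lambda_zero_uncorrelated(self, toy_tree):
        reps = np.array([
            simulate_traits(toy_tree, 0.0, 1.0, 0.0, seed=s).to_numpy()
            for s in range(800)
        ])
        cov_ab = np.cov(reps[:, 0], reps[:, 1])[0, 1]
        se = 2.0 / np.sqrt(800)  # var(product of ~N(0,2)) ~ 4
        assert abs(cov_ab) < 3 * se

    def test_lambda_one_sister_correlation(self, toy_tree):
        """A and B share half their history: corr = C_AB / C_AA = 0.5."""
        reps = np.array([
            simulate_traits(toy_tree, 1.0, 1.0, 0.0, seed=s).to_numpy()
            for s in range(800)
        ])
        corr = np.corrcoef(reps[:, 0], reps[:, 1])[0, 1]
        assert corr == pytest.approx(0.5, abs=0.1)


class TestSimulateCommunities:
    def test_richness_range_respected(self, tree47):
        comm = simulate_communities(
            tree47, None, n_plots=40, mode="neutral",
            richness_range=(3, 7), seed=2,
        )
        S = (comm > 0).sum(axis=1)
        assert S.between(3, 7).all()

    def test_filtering_concentrates_around_optimum(self, tree47):
        trait = simulate_traits(tree47, 1.0, 1.0, 0.0, seed=3)
        opt = float(trait.median())
        comm = simulate_communities(
            tree47, trait, n_plots=60, mode="filtering", tau=0.3,
            optima=[opt] * 60, richness_range=(5, 5), seed=4,
        )
        sel_dev = []
        for _, row in comm.iterrows():
            sel_dev.append(np.abs(trait[row[row > 0].index] - opt).mean())
        neutral = simulate_communities(
            tree47, None, n_plots=60, mode="neutral",
            richness_range=(5, 5), seed=4,
        )
        neu_dev = []
        for _, row in neutral.iterrows():
            neu_dev.append(np.abs(trait[row[row > 0].index] - opt).mean())
        assert np.mean(sel_dev) < 0.5 * np.mean(neu_dev)

    def test_multivariate_filtering_selects_niche_neighbours(self, tree47):
        niche = simulate_niche(tree47, n_axes=5, seed=31)
        comm = simulate_communities(
            tree47, niche, n_plots=40, mode="filtering", tau=0.8,
            richness_range=(6, 6), seed=32,
        )
        nv = niche.to_numpy()
        lookup = {sp: i for i, sp in enumerate(niche.index)}

        def mean_pairwise(sel):
            idx = [lookup[s] for s in sel]
            d = [
                np.linalg.norm(nv[a] - nv[b])
                for i, a in enumerate(idx) for b in idx[i + 1:]
            ]
            return np.mean(d)

        filt_d = np.mean(
            [mean_pairwise(r[r > 0].index) for _, r in comm.iterrows()]
        )
        neutral = simulate_communities(
            tree47, None, n_plots=40, mode="neutral",
            richness_range=(6, 6), seed=32,
        )
        neu_d = np.mean(
            [mean_pairwise(r[r > 0].index) for _, r in neutral.iterrows()]
        )
        assert filt_d < 0.75 * neu_d

    def test_limiting_enforces_min_gap(self, tree47):
        niche = simulate_niche(tree47, n_axes=5, seed=5)
        delta = 1.5
        comm = simulate_communities(
            tree47, niche, n_plots=30, mode="limiting", delta=delta,
            richness_range=(3, 6), seed=6,
        )
        nv = niche.to_numpy()
        lookup = {sp: i for i, sp in enumerate(niche.index)}
        for _, row in comm.iterrows():
            idx = [lookup[s] for s in row[row > 0].index]
            for i, a in enumerate(idx):
                for b in idx[i + 1:]:
                    assert np.linalg.norm(nv[a] - nv[b]) >= delta - 1e-9

    def test_infeasible_delta_relaxes_with_warning(self, tree47):
        niche = simulate_niche(tree47, n_axes=2, seed=7)
        with pytest.warns(UserWarning, match="relaxing"):
            simulate_communities(
                tree47, niche, n_plots=2, mode="limiting", delta=50.0,
                richness_range=(6, 6), seed=8,
            )

    def test_trait_required_for_non_neutral(self, tree47):
        with pytest.raises(ValueError, match="trait"):
            simulate_communities(
                tree47, None, n_plots=3, mode="filtering", seed=1
            )


class TestSimulateClimate:
    def test_invariants_hold(self):
        groups = np.repeat([1, 2, 3], [12, 17, 87])
        clim, latents = simulate_climate(groups, seed=3)
        validate_climate_table(clim)
        assert (clim["bio12"] > 0).all()
        assert len(latents) == len(clim)

    def test_zero_effect_uninformative_grouping(self):
        from sklearn.metrics import adjusted_rand_score

        from phylostruct.climate import (
            climate_pca, select_components, upgma_groups,
        )

        groups = np.repeat([1, 2, 3], [12, 17, 87])
        aris = []
        for seed in range(5):
            clim, _ = simulate_climate(groups, effect=0.0, seed=seed)
            pca = climate_pca(clim)
            k = select_components(pca.variance_fractions, 0.85)
            hg = upgma_groups(pca.scores.iloc[:, :k], 3)
            aris.append(adjusted_rand_score(groups, hg.labels))
        assert abs(np.mean(aris)) < 0.05

    def test_three_components_capture_85pct(self):
        from phylostruct.climate import climate_pca

        groups = np.repeat([1, 2, 3], [12, 17, 87])
        clim, _ = simulate_climate(groups, seed=11)
        res = climate_pca(clim)
        assert res.cumulative()[2] >= 0.85


class TestFixture:
    def test_byte_stability(self, fixture_dir, tmp_path):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again = make_fixture(tmp_path / "again", seed=7)
        for key, p in fixture_dir.items():
            h1 = hashlib.sha256(p.read_bytes()).hexdigest()
            h2 = hashlib.sha256(again[key].read_bytes()).hexdigest()
            assert h1 == h2, f"{key} not byte-stable"

    def test_files_parse_through_readers(self, fixture_dir):
        from phylostruct.climate import read_climate
        from phylostruct.tree import CladeFilter

        tree = Phylogeny.from_newick(fixture_dir["tree"].read_text())
        assert len(tree) == 49  # 47 angiosperms + 2 gymnosperms
        filt = CladeFilter.from_file(fixture_dir["clade_filter"])
        assert len(tree.drop(filt)) == 47
        comm = read_community(fixture_dir["community"])
        assert len(comm) == 116
        assert set(comm.columns) <= set(tree.tip_labels)
        traits = pd.read_csv(fixture_dir["traits"], index_col=0)
        assert traits.shape == (47, 4)
        assert (traits > 0).all().all()
        clim = read_climate(fixture_dir["climate"])
        assert len(clim) == 116
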
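"""Synthetic-data generator: study-condition structure and oracles."""

import numpy as np
import pandas as pd
import pytest

from mycofeedback import composition as comp
from mycofeedback import phylo
from mycofeedback.datasets import PipelineConfig, load_dataset, validate_dataset
from mycofeedback.feedback import interaction_coefficient, pairwise_interactions
from mycofeedback.meta import compute_lrr
from mycofeedback.simulate import (
    SimulationConfig,
    assign_host_traits,
    default_true_lrr,
    generate_full_dataset,
    make_feedback_blocks,
    simulate_feedback_biomass,
    simulate_growth_assays,
    simulate_host_effects,
    simulate_mycobiome_counts,
    simulate_tree,
)


class TestTree:
    def test_two_tips_cherry(self):
        t = simulate_tree(2, seed=0)
        d = t.patristic_distances()
        assert d.iloc[0, 1] == pytest.approx(2.0, abs=1e-8)

    def test_deterministic(self):
        assert simulate_tree(38, seed=5).to_newick() == simulate_tree(38, seed=5).to_newick()

    def test_unit_diagonal_covariance(self):
        C = simulate_tree(50, seed=1).covariance(scale="none")
        assert np.allclose(np.diag(C.to_numpy()), 1.0, atol=1e-8)

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            simulate_tree(1)


class TestHostEffects:
    def test_no_variance_constant_per_fungus(self):
        tree = simulate_tree(10, seed=0)
        traits = assign_host_traits(tree, seed=0)
        cfg = SimulationConfig(sigma2_phylo=0.0, sigma2_species=0.0,
                               beta_life_history=(0.0,) * 7)
        E = simulate_host_effects(tree, traits, cfg, seed=1)
        assert np.allclose(E.to_numpy().std(axis=0), 0.0)

    def test_empirical_covariance_matches_C(self):
        tree = simulate_tree(10, seed=3)
        traits = assign_host_traits(tree, seed=0)
        cfg = SimulationConfig(sigma2_phylo=1.0, sigma2_species=0.0,
                               beta_life_history=(0.0,) * 7)
        C = tree.covariance().to_numpy()
        hosts = list(tree.covariance().index)
        draws = []
        for s in range(500):
            E = simulate_host_effects(tree, traits, cfg, seed=s)
            draws.append(E.loc[hosts].to_numpy()[:, 0] - np.log(cfg.base_proportions[0]))
        U = np.array(draws)
        emp = U.T @ U / len(U)
        # entrywise Monte-Carlo error: Var(xy) <= C_ii C_jj + C_ij^2 <= 2
        se = 3.0 * np.sqrt(2.0 / len(U))
        assert np.abs(emp - C).max() < 3 * se + 0.05

    def test_life_history_shift(self):
        tree = simulate_tree(20, seed=2)
        traits = assign_host_traits(tree, seed=1)
        beta = (1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        cfg = SimulationConfig(sigma2_phylo=0.0, sigma2_species=0.1,
                               beta_life_history=beta)
        diffs = []
        for s in range(200):
            E = simulate_host_effects(tree, traits, cfg, seed=s)
            late = traits["life_history"] == "late"
            diffs.append(E.loc[late.index[late], E.columns[0]].mean()
                         - E.loc[late.index[~late], E.columns[0]].mean())
        assert np.mean(diffs) == pytest.approx(1.0, abs=3 * np.std(diffs) / np.sqrt(200))


class TestCounts:
    def test_multinomial_limit_equal_proportions(self):
        tree = simulate_tree(6, seed=1)
        traits = assign_host_traits(tree, seed=0)
        cfg = SimulationConfig(
            n_host_species=6, sigma2_phylo=0.0, sigma2_species=0.0,
            beta_life_history=(0.0,) * 7, base_proportions=(1 / 7,) * 7,
            block_sd=0.0, year_sd=0.0, years=1, n_blocks=4,
            dirichlet_concentration=1e9, unassigned_fraction=0.0,
        )
        E = simulate_host_effects(tree, traits, cfg, seed=0)
        table, meta, _ = simulate_mycobiome_counts(E, tree, cfg, seed=0)
        species = comp.drop_unassigned(
            comp.aggregate_to_species(table.counts, table.taxonomy)
        )
        props = species.div(species.sum(axis=1), axis=0)
        assert np.abs(props.to_numpy() - 1 / 7).max() < 0.02

    def test_species_proportions_match_softmax(self):
        tree = simulate_tree(4, seed=5)
        traits = assign_host_traits(tree, seed=0)
        cfg = SimulationConfig(
            n_host_species=4, sigma2_phylo=0.5, sigma2_species=0.2,
            block_sd=0.0, year_sd=0.0, years=1, n_blocks=50,
            dirichlet_concentration=500.0, unassigned_fraction=0.0,
        )
        E = simulate_host_effects(tree, traits, cfg, seed=3)
        table, meta, _ = simulate_mycobiome_counts(E, tree, cfg, seed=4)
        species = comp.drop_unassigned(
            comp.aggregate_to_species(table.counts, table.taxonomy)
        )
        host = meta.table["host_species"]
        for h in E.index:
            eta = E.loc[h].to_numpy()
            expect = np.exp(eta - eta.max())
            expect /= expect.sum()
            obs = (
                species.loc[host.index[host == h]]
                .div(species.loc[host.index[host == h]].sum(axis=1), axis=0)
                .mean(axis=0)
                .loc[list(E.columns)]
                .to_numpy()
            )
            # 50 samples per host; binomial-ish SE per component
            assert np.abs(obs - expect).max() < 3 * np.sqrt(0.25 / 50) + 0.02

    def test_no_unassigned_gives_unit_density_proxy(self):
        tree = simulate_tree(4, seed=5)
        traits = assign_host_traits(tree, seed=0)
        cfg = SimulationConfig(n_host_species=4, years=1, n_blocks=2,
                               unassigned_fraction=0.0)
        E = simulate_host_effects(tree, traits, cfg, seed=0)
        table, _, _ = simulate_mycobiome_counts(E, tree, cfg, seed=1)
        species = comp.aggregate_to_species(table.counts, table.taxonomy)
        p = comp.density_proxy(species)["proportion"]
        assert (p == 1.0).all()


class TestFeedbackBiomass:
    def test_zero_noise_exact_I(self):
        cfg = SimulationConfig(biomass_noise_sd=0.0)
        blocks = [["A", "B"]]
        design = simulate_feedback_biomass(blocks, {("A", "B"): 2.0}, cfg, seed=0)
        res = pairwise_interactions(design)
        assert res["I"].iloc[0] == pytest.approx(2.0, abs=1e-12)
        assert res["degenerate"].iloc[0]

    def test_cell_means_construction(self):
        cfg = SimulationConfig(biomass_noise_sd=0.0, biomass_base=10.0)
        design = simulate_feedback_biomass([["A", "B"]], {("A", "B"): 2.0}, cfg, 0)
        t = design.table
        cell = t.groupby(["host_species", "training_species"])["biomass"].mean()
        assert cell[("A", "A")] == pytest.approx(10.0)
        assert cell[("A", "B")] == pytest.approx(9.0)
        assert cell[("B", "A")] == pytest.approx(9.0)
        assert cell[("B", "B")] == pytest.approx(10.0)
        assert interaction_coefficient(
            cell[("A", "A")], cell[("A", "B")], cell[("B", "A")], cell[("B", "B")]
        ) == pytest.approx(2.0)

    def test_monte_carlo_unbiased(self):
        cfg = SimulationConfig(biomass_noise_sd=0.5, feedback_reps=4)
        est = []
        for s in range(500):
            design = simulate_feedback_biomass([["A", "B"]], {("A", "B"): 1.5}, cfg, s)
            est.append(pairwise_interactions(design)["I"].iloc[0])
        se = np.std(est) / np.sqrt(len(est))
        assert np.mean(est) == pytest.approx(1.5, abs=3 * se)

    def test_infeasible_target(self):
        cfg = SimulationConfig(biomass_base=1.0)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_feedback_biomass([["A", "B"]], {("A", "B"): 2.5}, cfg, 0)


class TestGrowthAssays:
    def _traits(self, tree):
        return assign_host_traits(tree, seed=0)

    def test_zero_lrr_zero_sd(self):
        tree = simulate_tree(6, seed=0)
        traits = self._traits(tree)
        cfg = SimulationConfig(assay_cv=1e-9, n_studies=1,
                               assay_species_per_study=6,
                               include_mixture_assays=False)
        true = pd.DataFrame(0.0, index=list(cfg.fungal_species), columns=traits.index)
        assays, _ = simulate_growth_assays(true, traits, cfg, seed=1)
        eff = compute_lrr(assays.table)
        assert np.abs(eff["lrr"]).max() < 1e-6

    def test_monte_carlo_lrr_recovery(self):
        tree = simulate_tree(3, seed=1)
        traits = self._traits(tree)
        cfg = SimulationConfig(n_studies=1, assay_species_per_study=1,
                               assay_n=8, include_mixture_assays=False)
        true = pd.DataFrame(0.7, index=list(cfg.fungal_species), columns=traits.index)
        vals = []
        for s in range(500):
            assays, _ = simulate_growth_assays(true, traits, cfg, seed=s)
            vals.append(compute_lrr(assays.table)["lrr"].mean())
        se = np.std(vals) / np.sqrt(len(vals))
        # small positive Jensen bias O(cv^2/n) is part of the expectation
        assert np.mean(vals) == pytest.approx(0.7, abs=3 * se + 0.01)


class TestFullDataset:
    def test_loadable_valid_and_deterministic(self, tmp_path):
        cfg = SimulationConfig(n_host_species=10, n_blocks=2, seed=11,
                               assay_species_per_study=4)
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        generate_full_dataset(cfg, out_dir=d1)
        generate_full_dataset(cfg, out_dir=d2)
        for f in sorted(p.name for p in d1.iterdir()):
            if f == "config.yaml":  # embeds the output directory path
                continue
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f
        loaded = load_dataset(PipelineConfig(data_dir=str(d1)))
        report = validate_dataset(loaded)
        assert report.empty

    def test_ground_truth_schema(self, small_dataset):
        _, truth = small_dataset
        assert {"params", "latent_fitness", "interaction_targets", "true_lrr"} <= set(truth)
        params = dict(zip(truth["params"]["parameter"], truth["params"]["value"]))
        assert "sigma2_phylo" in params and "sigma2_species" in params
        assert {"species_A", "species_B", "I_target"} <= set(
            truth["interaction_targets"].columns
        )

    def test_asv_counts_match_config(self, small_dataset):
        dataset, _ = small_dataset
        cfg = SimulationConfig()
        tax = dataset.counts.taxonomy
        per_species = tax[tax != comp.UNASSIGNED].value_counts()
        for sp, k in zip(cfg.fungal_species, cfg.asvs_per_species):
            assert per_species[sp] == k
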
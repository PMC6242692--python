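"""The synthetic screen generator: determinism, structure and planted effects."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from crispriscreen.genome import find_protospacers
from crispriscreen.simulate import (
    GroundTruth,
    SimulationConfig,
    _initial_abundance,
    _multinomial_expected,
    _overdisperse,
    make_design,
    simulate_genome,
    simulate_growth_screen,
    simulate_library,
    simulate_screen_suite,
    true_guide_fitness,
)
from crispriscreen.stats import ScreenDesign, guide_log2fc

SMALL = dict(genome_length=30_000, n_genes=30, library_size=800, depth=100_000)


class TestSimulateGenome:
    def test_no_essentials_when_fraction_zero(self):
        cfg = SimulationConfig(seed=1, fraction_essential=0.0,
                               fraction_near_essential=0.0, n_host_factors=2,
                               n_capsid_genes=2, **SMALL)
        _, _, _, truth = simulate_genome(cfg)
        assert not truth.genes["essential"].any()
        assert not truth.genes["sensitive"].any()

    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        g1, genes1, tus1, t1 = simulate_genome(cfg)
        g2, genes2, tus2, t2 = simulate_genome(cfg)
        assert g1.sequence == g2.sequence
        pd.testing.assert_frame_equal(genes1, genes2)
        pd.testing.assert_frame_equal(t1.genes, t2.genes)

    def test_planted_counts_recorded_exactly(self):
        cfg = SimulationConfig(seed=2, **SMALL)
        _, genes, _, truth = simulate_genome(cfg)
        assert truth.genes["essential"].sum() == round(0.2 * cfg.n_genes)
        assert truth.genes["near_essential"].sum() == round(0.1 * cfg.n_genes)
        assert truth.genes["host_factor"].sum() == cfg.n_host_factors
        assert truth.genes["capsid_gene"].sum() == cfg.n_capsid_genes
        # labels are mutually consistent
        assert not (truth.genes["essential"] & truth.genes["host_factor"]).any()
        assert (truth.genes["sensitive"] <= truth.genes["essential"]).all()

    def test_tu_structure_consistent(self):
        cfg = SimulationConfig(seed=3, **SMALL)
        _, genes, tus, _ = simulate_genome(cfg)
        for tu_id, grp in genes.groupby("tu_id"):
            assert grp["strand"].nunique() == 1
            ranks = grp.sort_values("tu_rank")
            coords = ranks["left"].tolist()
            # rank order follows transcription direction
            if grp["strand"].iloc[0] == "+":
                assert coords == sorted(coords)
            else:
                assert coords == sorted(coords, reverse=True)
        # genes do not overlap
        s = genes.sort_values("left")
        assert (s["left"].to_numpy()[1:] >= s["right"].to_numpy()[:-1]).all()

    def test_genes_must_fit(self):
        with pytest.raises(ValueError, match="do not fit"):
            simulate_genome(SimulationConfig(seed=1, genome_length=5_000,
                                             n_genes=50))


class TestSimulateLibrary:
    def test_full_library_equals_enumeration(self):
        cfg = SimulationConfig(seed=4, **SMALL)
        genome, genes, _, _ = simulate_genome(cfg)
        sites = find_protospacers(genome)
        cfg_all = SimulationConfig(seed=4, **{**SMALL, "library_size": len(sites)})
        lib = simulate_library(genome, genes, cfg_all)
        assert len(lib) == len(sites) + 1  # plus control
        assert set(lib.loc[~lib["is_control"], "spacer"]) == set(sites["spacer"])

    def test_oversized_library_errors(self):
        cfg = SimulationConfig(seed=4, **{**SMALL, "library_size": 10**7})
        genome, genes, _, _ = simulate_genome(
            SimulationConfig(seed=4, **SMALL))
        with pytest.raises(ValueError, match="exceeds"):
            simulate_library(genome, genes, cfg)

    def test_strand_balance_and_revalidation(self):
        cfg = SimulationConfig(seed=6, **SMALL)
        genome, genes, _, _ = simulate_genome(cfg)
        lib = simulate_library(genome, genes, cfg)
        guides = lib[~lib["is_control"]]
        n_plus = int((guides["strand"] == "+").sum())
        assert sps.binomtest(n_plus, len(guides), 0.5).pvalue > 0.01
        # every sampled guide revalidates against the genome
        seq2 = genome.sequence * 2
        from crispriscreen.genome import revcomp

        for _, g in guides.sample(50, random_state=0).iterrows():
            s = int(g["start"])
            window = seq2[s : s + 20]
            expected = window if g["strand"] == "+" else revcomp(window)
            assert g["spacer"] == expected
            assert g["n_perfect_sites"] >= 1


def hand_truth(genes: pd.DataFrame, cost: dict, sensitive=(), host=(), capsid=()):
    names = genes["name"]
    return GroundTruth(
        genes=pd.DataFrame(
            {"essential": names.isin(cost).to_numpy(),
             "near_essential": False,
             "sensitive": names.isin(sensitive).to_numpy(),
             "host_factor": names.isin(host).to_numpy(),
             "capsid_gene": names.isin(capsid).to_numpy()},
            index=pd.Index(names, name="gene"),
        ),
        gene_cost=pd.Series({n: cost.get(n, 0.0) for n in names}),
    )


class TestTrueGuideFitness:
    @pytest.fixture
    def two_gene_operon(self):
        genes = pd.DataFrame(
            {"name": ["up", "ess"], "left": [0, 500], "right": [400, 900],
             "strand": ["+", "+"], "tu_id": ["t1", "t1"], "tu_rank": [1, 2]}
        )
        truth = hand_truth(genes, {"ess": -0.4}, sensitive=["ess"])
        return genes, truth

    def _lib(self, rows):
        df = pd.DataFrame(rows)
        df["is_control"] = df.get("is_control", False)
        return df

    def test_clean_guide_zero(self, two_gene_operon):
        genes, truth = two_gene_operon
        truth.genes.loc["ess", "essential"] = False
        truth.gene_cost["ess"] = 0.0
        lib = self._lib([{"guide_id": "a", "spacer": "A" * 20, "gene": "up",
                          "targets_coding": True}])
        cfg = SimulationConfig(seed=1, repression_efficiency_range=(1.0, 1.0))
        w = true_guide_fitness(lib, genes, truth, cfg)
        assert w["a"] == 0.0

    def test_template_guide_on_sensitive_gene_full_effect(self, two_gene_operon):
        genes, truth = two_gene_operon
        lib = self._lib(
            [{"guide_id": "tmpl", "spacer": "A" * 20, "gene": "ess",
              "targets_coding": False},
             {"guide_id": "cod", "spacer": "C" * 20, "gene": "ess",
              "targets_coding": True}]
        )
        cfg = SimulationConfig(seed=1, repression_efficiency_range=(1.0, 1.0))
        w = true_guide_fitness(lib, genes, truth, cfg)
        assert w["tmpl"] == pytest.approx(w["cod"])
        assert w["cod"] == pytest.approx(-0.4)

    def test_template_guide_on_ordinary_gene_scaled(self, two_gene_operon):
        genes, truth = two_gene_operon
        truth.genes.loc["ess", "sensitive"] = False
        lib = self._lib([{"guide_id": "tmpl", "spacer": "A" * 20, "gene": "ess",
                          "targets_coding": False}])
        cfg = SimulationConfig(seed=1, repression_efficiency_range=(1.0, 1.0))
        w = true_guide_fitness(lib, genes, truth, cfg)
        assert w["tmpl"] == pytest.approx(-0.4 * cfg.template_effect_scale)

    def test_polar_includes_downstream_cost(self, two_gene_operon):
        genes, truth = two_gene_operon
        lib = self._lib([{"guide_id": "up1", "spacer": "A" * 20, "gene": "up",
                          "targets_coding": True}])
        cfg_on = SimulationConfig(seed=1, repression_efficiency_range=(1.0, 1.0))
        cfg_off = SimulationConfig(seed=1, polar=False,
                                   repression_efficiency_range=(1.0, 1.0))
        assert true_guide_fitness(lib, genes, truth, cfg_on)["up1"] == \
            pytest.approx(-0.4)
        assert true_guide_fitness(lib, genes, truth, cfg_off)["up1"] == 0.0

    def test_bad_seed_penalty_applies_anywhere(self, two_gene_operon):
        genes, truth = two_gene_operon
        lib = self._lib([{"guide_id": "bs", "spacer": "C" * 15 + "AGGAA",
                          "gene": None, "targets_coding": None}])
        cfg = SimulationConfig(seed=1)
        w = true_guide_fitness(lib, genes, truth, cfg)
        assert w["bs"] == pytest.approx(cfg.bad_seed_penalty)

    def test_control_guide_exactly_zero(self, default_suite):
        assert default_suite["truth"].guide_fitness["control"] == 0.0


class TestCountGeneration:
    def test_multinomial_totals_equal_depth(self):
        rng = np.random.default_rng(1)
        a = rng.lognormal(size=200)
        m = _multinomial_expected(a, 50_000, rng)
        assert m.sum() == 50_000

    def test_overdispersion_zero_is_identity(self):
        rng = np.random.default_rng(2)
        m = np.arange(100)
        assert (_overdisperse(m, 0.0, rng) == m).all()

    def test_overdispersed_variance_exceeds_poisson(self):
        rng = np.random.default_rng(3)
        m = np.full(20_000, 200)
        k = _overdisperse(m, 0.1, rng)
        v = k.var()
        assert v > 200 * 2  # ~ m + 0.1 m^2 = 4200 >> 200

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SimulationConfig(seed=1, depth=0)


class TestScreens:
    def test_null_screen_flat(self):
        cfg = SimulationConfig(seed=9, fraction_essential=0, dispersion=0.0,
                               fraction_near_essential=0, bad_seed_penalty=0.0,
                               n_host_factors=0, n_capsid_genes=0,
                               genome_length=30_000, n_genes=30,
                               library_size=500, depth=10_000_000)
        genome, genes, tus, truth = simulate_genome(cfg)
        lib = simulate_library(genome, genes, cfg)
        truth.guide_fitness = true_guide_fitness(lib, genes, truth, cfg)
        truth.abundance = _initial_abundance(lib, cfg)
        counts, ddf = simulate_growth_screen(lib, truth, cfg)
        lfc = guide_log2fc(counts, ScreenDesign.from_frame(ddf))
        assert lfc.abs().mean() < 0.05

    def test_planted_minus_four_recovered(self):
        cfg = SimulationConfig(seed=10, genome_length=60_000, n_genes=60,
                               library_size=2_000, depth=1_000_000)
        genome, genes, tus, truth = simulate_genome(cfg)
        lib = simulate_library(genome, genes, cfg)
        w = pd.Series(0.0, index=lib["guide_id"].to_numpy())
        w.iloc[:200] = -4.0 / 17.0  # planted per-generation effect
        w["control"] = 0.0
        truth.guide_fitness = w
        truth.abundance = _initial_abundance(lib, cfg)
        counts, ddf = simulate_growth_screen(lib, truth, cfg)
        lfc = guide_log2fc(counts, ScreenDesign.from_frame(ddf))
        assert abs(lfc.iloc[:200].mean() - (-4.0)) < 0.3

    def test_suite_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=12, **SMALL)
        s1 = simulate_screen_suite(cfg)
        s2 = simulate_screen_suite(cfg)
        for key in ("growth", "phage", "transduction"):
            pd.testing.assert_frame_equal(s1[key][0], s2[key][0])
        assert s1["genome"].sequence == s2["genome"].sequence

    def test_phage_flat_without_host_factors(self):
        cfg = SimulationConfig(seed=13, n_host_factors=0, n_capsid_genes=0,
                               **SMALL)
        suite = simulate_screen_suite(cfg)
        counts, ddf = suite["phage"]
        lfc = guide_log2fc(counts, ScreenDesign.from_frame(ddf))
        assert lfc.abs().median() < 0.5

    def test_host_factor_guides_enriched(self, default_suite):
        truth = default_suite["truth"]
        counts, ddf = default_suite["phage"]
        lfc = guide_log2fc(counts, ScreenDesign.from_frame(ddf))
        protected = truth.survival[truth.survival > 0.5].index
        rest = truth.survival[truth.survival <= 0.5].index
        assert lfc[protected].median() > lfc[rest].median() + 3

    def test_transduction_slope_one_without_capsid_genes(self):
        cfg = SimulationConfig(seed=14, n_capsid_genes=0, n_host_factors=0,
                               **SMALL)
        suite = simulate_screen_suite(cfg)
        g_lfc = guide_log2fc(*map_design(suite["growth"]))
        t_lfc = guide_log2fc(*map_design(suite["transduction"]))
        from crispriscreen.transduction import global_fitness_regression

        slope, _, _, _ = global_fitness_regression(t_lfc, g_lfc)
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_capsid_guides_depleted_beyond_growth_trend(self, default_suite):
        truth = default_suite["truth"]
        lib = default_suite["library"]
        g_lfc = guide_log2fc(*map_design(default_suite["growth"]))
        t_lfc = guide_log2fc(*map_design(default_suite["transduction"]))
        capsid = truth.label_set("capsid_gene")
        mask = lib["gene"].isin(capsid) & (lib["targets_coding"] == True)  # noqa: E712
        ids = lib.loc[mask, "guide_id"]
        resid = (t_lfc - g_lfc).loc[ids]
        assert resid.mean() == pytest.approx(-3.0, abs=0.7)

    def test_polar_candidates_lie_upstream_of_essentials(self):
        """Essential-free candidate genes are polar artefacts iff polar is on."""
        from crispriscreen.qc import apply_qc
        from crispriscreen.scoring import GeneScorer
        from crispriscreen.stats import FoldChangeEstimator

        results = {}
        for polar in (True, False):
            cfg = SimulationConfig(seed=15, polar=polar,
                                   fraction_near_essential=0.0,
                                   bad_seed_penalty=0.0)
            suite = simulate_screen_suite(cfg)
            counts, ddf = suite["growth"]
            design = ScreenDesign.from_frame(ddf)
            est = FoldChangeEstimator().fit(counts, design)
            scorer = GeneScorer().fit(est.guide_stats_, suite["library"])
            called = set(scorer.call().loc[lambda s: s].index)
            truth = suite["truth"]
            ess = truth.label_set("essential")
            free = called - ess
            genes = suite["genes"]
            tu_members = {
                t: grp.sort_values("tu_rank")["name"].tolist()
                for t, grp in genes.groupby("tu_id")
            }

            def upstream_of_essential(g):
                row = genes.set_index("name").loc[g]
                members = tu_members[row["tu_id"]]
                i = members.index(g)
                return any(m in ess for m in members[i + 1 :])

            frac = (np.mean([upstream_of_essential(g) for g in free])
                    if free else None)
            results[polar] = (len(free), frac)
        n_on, frac_on = results[True]
        n_off, frac_off = results[False]
        assert n_on > 0 and frac_on >= 0.9
        assert n_off == 0 or frac_off == 0.0


def map_design(pair):
    counts, ddf = pair
    return counts, ScreenDesign.from_frame(ddf)
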
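import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_loglik, pathway_counts_oracle
from conftest import make_alignment
from phyloindel import (
    Phylogeny,
    branch_rates_counting,
    build_codon_alignment,
    eb_sites,
    lineage_omega,
    lrt,
    m0_fit,
    site_model_fit,
    species_consensus_alignment,
)
from phyloindel.codon_evolution import (
    SENSE_CODONS,
    BranchRates,
    CodonLikelihood,
    CodonModelFit,
    _pathway_counts,
    _SITE_COUNTS,
    f3x4_frequencies,
    nested_start,
    uniform_frequencies,
)
from phyloindel.errors import (
    ModelMismatchError,
    OptimizationOrderError,
    StopCodonError,
)
from phyloindel.synthetic_data import SimulationConfig, simulate_study


def _fit(model, lnl):
    return CodonModelFit(
        model=model, lnL=lnl, kappa=2.0, params={}, branch_lengths={},
        classes=[(1.0, 0.5)], converged=True, n_codons=100,
    )


class TestCodonAlignment:
    def test_gapless_alignment_keeps_all_sites(self):
        aln = make_alignment({"A": "ATGAAATTT", "B": "ATGAAATTC"})
        caln = build_codon_alignment(aln)
        assert caln.n_codons == 3
        assert caln.site_columns == [1, 4, 7]

    def test_gapped_codon_column_dropped_for_all_taxa(self):
        aln = make_alignment({"A": "ATG---TTT", "B": "ATGAAATTC"})
        caln = build_codon_alignment(aln)
        assert caln.n_codons == 2
        assert caln.site_columns == [1, 7]

    def test_internal_stop_names_taxon_and_site(self):
        aln = make_alignment({"A": "ATGTAATTT", "B": "ATGAAATTC"})
        with pytest.raises(StopCodonError, match="A at codon site 2"):
            build_codon_alignment(aln)

    def test_site_count_matches_simulator_minus_gapped_columns(
        self, default_study, default_species_alignment
    ):
        aln, _ = default_species_alignment
        caln = build_codon_alignment(aln)
        gapped = 0
        for s in range(aln.n_columns // 3):
            if any("-" in r.seq[3 * s : 3 * s + 3] for r in aln.records):
                gapped += 1
        assert caln.n_codons == aln.n_columns // 3 - gapped


class TestLikelihood:
    def test_zero_divergence_limit_is_iid_equilibrium(self):
        aln = make_alignment({"A": "ATGAAATTTCCC", "B": "ATGAAATTTCCC"})
        caln = build_codon_alignment(aln)
        tree = Phylogeny.from_newick("(A:0.1,B:0.1);")
        fit = m0_fit(caln, tree)
        assert fit.tree_length() < 1e-4
        pi = f3x4_frequencies(caln)
        expected = sum(
            np.log(pi[caln.codes[0, s]]) for s in range(caln.n_codons)
        )
        assert fit.lnL == pytest.approx(expected, abs=1e-4)

    def test_pruning_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        codons = [SENSE_CODONS[i] for i in rng.integers(0, 61, size=60)]
        rows = {
            "A": codons[:20],
            "B": codons[20:40],
            "C": codons[40:60],
        }
        aln = make_alignment({k: "".join(v) for k, v in rows.items()})
        caln = build_codon_alignment(aln)
        tree = Phylogeny.from_newick("((A:0.2,B:0.3):0.15,C:0.4);")
        pi = uniform_frequencies()
        engine = CodonLikelihood(caln, tree, pi)
        bl_names = engine.edges
        bl = {"A": 0.2, "B": 0.3, "C": 0.4}
        bl[[n for n in bl_names if n not in bl][0]] = 0.15
        kappa, omega = 2.5, 0.7
        mine = engine.loglik_single(
            kappa, omega, np.array([bl[n] for n in bl_names])
        )
        oracle = brute_force_loglik(tree, rows, kappa, omega, bl, pi)
        assert mine == pytest.approx(oracle, abs=1e-6)

    def test_nested_site_models_keep_likelihood_ordering(self):
        cfg = SimulationConfig(n_species=6, n_codons=60, indel_rate=0.0)
        study = simulate_study(cfg, seed=5)
        aln, _ = species_consensus_alignment(study["alignment"])
        caln = build_codon_alignment(aln)
        tree = study["tree"]
        m0 = m0_fit(caln, tree)
        m1a = site_model_fit(caln, tree, "M1a", m0=m0)
        m2a = site_model_fit(
            caln, tree, "M2a", m0=m0, extra_starts=[nested_start(m1a, "M2a")]
        )
        m7 = site_model_fit(caln, tree, "M7", m0=m0, n_beta_categories=8)
        m8a = site_model_fit(caln, tree, "M8a", m0=m0, n_beta_categories=8)
        m8 = site_model_fit(
            caln, tree, "M8", m0=m0, n_beta_categories=8,
            extra_starts=[nested_start(m7, "M8"), nested_start(m8a, "M8")],
        )
        tol = 1e-6
        assert m2a.lnL >= m1a.lnL - tol
        assert m8.lnL >= m7.lnL - tol
        assert m8.lnL >= m8a.lnL - tol
        assert m1a.lnL >= m0.lnL - tol  # holds whenever omega_hat(M0) <= 1


class TestLRT:
    def test_equal_likelihoods_give_p_one(self):
        r = lrt(_fit("M1a", -100.0), _fit("M2a", -100.0), df=2)
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_chi_square_quantile(self):
        r = lrt(_fit("M1a", -100.0), _fit("M2a", -100.0 + 5.99 / 2), df=2)
        assert r.p_value == pytest.approx(0.05, abs=0.001)

    def test_published_m1a_m2a_pair_is_highly_significant(self):
        r = lrt(_fit("M1a", -2907.9808), _fit("M2a", -2879.567332), df=2)
        assert r.statistic == pytest.approx(56.827, abs=0.01)
        assert r.p_value < 0.001

    def test_order_violation_raises(self):
        with pytest.raises(OptimizationOrderError):
            lrt(_fit("M1a", -100.0), _fit("M2a", -101.0), df=2)


class TestEBSites:
    def test_threshold_one_flags_nothing(self, small_selection_study):
        study = small_selection_study
        aln, _ = species_consensus_alignment(study["alignment"])
        caln = build_codon_alignment(aln)
        m2a = site_model_fit(caln, study["tree"], "M2a", seed=1)
        assert eb_sites(m2a, threshold=1.0 + 1e-12).flagged == []

    def test_model_without_positive_class_rejected(self):
        fit = _fit("M1a", -10.0)
        with pytest.raises(ModelMismatchError):
            eb_sites(fit)

    def test_flagged_sites_are_mostly_truly_selected(self, small_selection_study):
        study = small_selection_study
        aln, _ = species_consensus_alignment(study["alignment"])
        caln = build_codon_alignment(aln)
        tree, truth = study["tree"], study["truth"]
        m2a = site_model_fit(caln, tree, "M2a", seed=1)
        sites = eb_sites(m2a, threshold=0.95)
        kept = truth.alignment_columns
        origin = [kept[(c - 1) // 3] for c in caln.site_columns]
        flagged_origin = {origin[i] for i in sites.flagged}
        assert len(sites.flagged) > 0
        false = flagged_origin - set(truth.selected_sites)
        assert len(false) <= 0.2 * len(flagged_origin)


class TestCountingRates:
    def test_identical_parent_child_gives_zero(self):
        assert _pathway_counts("TTT", "TTT") == (0.0, 0.0)

    def test_single_step_nonsynonymous(self):
        assert _pathway_counts("TTT", "TTA") == (1.0, 0.0)

    @pytest.mark.parametrize(
        "a,b",
        [("TTT", "CTC"), ("ATG", "CGG"), ("AAA", "AGC"), ("TGG", "TAC"),
         ("GGG", "CCC")],
    )
    def test_pathway_averaging_matches_oracle(self, a, b):
        assert _pathway_counts(a, b) == pytest.approx(pathway_counts_oracle(a, b))

    def test_site_counts_sum_to_three_for_every_sense_codon(self):
        for codon, (n, s) in _SITE_COUNTS.items():
            assert n + s == pytest.approx(3.0)

    def test_branch_totals_satisfy_site_identity(self, default_study,
                                                 default_species_alignment):
        aln, _ = default_species_alignment
        caln = build_codon_alignment(aln)
        rates = branch_rates_counting(caln, default_study["tree"])
        assert np.allclose(
            rates.data["N"] + rates.data["S"], 3 * caln.n_codons
        )

    def test_mean_branch_omega_recovers_truth(self):
        ratios = []
        for seed in range(5):
            cfg = SimulationConfig(
                n_species=10, n_codons=250, omega=0.5, indel_rate=0.0
            )
            study = simulate_study(cfg, seed=seed)
            aln, _ = species_consensus_alignment(study["alignment"])
            caln = build_codon_alignment(aln)
            rates = branch_rates_counting(caln, study["tree"])
            d = rates.data
            ok = (d["dS"] > 0) & ~d["saturated"]
            ratios.append(float((d.loc[ok, "dN"] / d.loc[ok, "dS"]).mean()))
        assert abs(np.mean(ratios) - 0.5) < 0.15


class TestLineageOmega:
    def _rates(self, tree, dn, ds):
        df = pd.DataFrame(
            {
                "branch": [n.name for n in tree.edges()],
                "dN": dn,
                "dS": ds,
            }
        ).set_index("branch")
        return BranchRates(df)

    def test_constant_ratio_along_path(self, five_taxon_tree):
        tree = five_taxon_tree
        n = len(tree.edges())
        rates = self._rates(tree, [0.02] * n, [0.01] * n)
        lo = lineage_omega(rates, tree, "A")
        assert lo.omega == pytest.approx(2.0)

    def test_path_sum_arithmetic(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,C:2);", outgroup="C")
        dn = {"A": 0.03, "B": 0.05}
        ds = {"A": 0.02, "B": 0.02}
        stem = [n.name for n in tree.edges() if n.name not in ("A", "B", "C")][0]
        dn[stem], ds[stem] = 0.01, 0.02
        dn["C"], ds["C"] = 0.0, 0.0
        names = [n.name for n in tree.edges()]
        rates = self._rates(tree, [dn[x] for x in names], [ds[x] for x in names])
        lo = lineage_omega(rates, tree, "A")
        assert lo.sum_dn == pytest.approx(0.04)
        assert lo.sum_ds == pytest.approx(0.04)
        assert lo.omega == pytest.approx(1.0)

    def test_undefined_when_no_synonymous_change(self, five_taxon_tree):
        tree = five_taxon_tree
        n = len(tree.edges())
        rates = self._rates(tree, [0.02] * n, [0.0] * n)
        assert not lineage_omega(rates, tree, "A").defined

    def test_invariant_to_branch_subdivision(self):
        whole = Phylogeny.from_newick("((A:2,B:2):1,C:3);", outgroup="C")
        split = Phylogeny.from_newick("(((A:1):1,B:2):1,C:3);", outgroup="C")
        names_w = [n.name for n in whole.edges()]
        names_s = [n.name for n in split.edges()]
        rw = self._rates(whole, [0.02] * len(names_w), [0.01] * len(names_w))
        # same totals on A's path: the subdivided tree splits A's branch in two
        rs = self._rates(split, [0.01] * len(names_s), [0.005] * len(names_s))
        lw = lineage_omega(rw, whole, "A")
        ls = lineage_omega(rs, split, "A")
        assert lw.omega == pytest.approx(ls.omega)
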
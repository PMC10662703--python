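import itertools
import math

import numpy as np
import pytest

from mitosel import (
    Tree,
    fitch_ancestral,
    get_code,
    group_omega_contrast,
    ng86_pairwise,
    ng86_pathway_counts,
    ng86_site_counts,
    slac_site_test,
    terminal_branch_omegas,
)
from mitosel.io import GeneAlignment, SequenceRecord
from mitosel.selection import _binom_upper_tail

from oracles import brute_parsimony, brute_pathway_counts, brute_site_counts

CODE = get_code(5)


class TestNG86SiteCounts:
    def test_fourfold_third_position_fully_synonymous(self):
        s, n = ng86_site_counts("GGG", CODE)
        assert s >= 1.0 and s + n == pytest.approx(3.0)

    def test_met_codon_has_one_synonymous_neighbor(self):
        # code 5: ATA and ATG are both Met; ATG -> ATA is the only syn change
        s, n = ng86_site_counts("ATG", CODE)
        assert s == pytest.approx(1 / 3)

    def test_stop_neighbors_reduce_site_total(self):
        # TGG: TGA is Trp in code 5 (not a stop) but TAG is -> total 3 - 1/3
        s, n = ng86_site_counts("TGG", CODE)
        assert s + n == pytest.approx(3.0 - 1 / 3)
        # TAT (Tyr): neighbors TAA/TAG are stops, so total 3 - 2/3
        s, n = ng86_site_counts("TAT", CODE)
        assert s + n == pytest.approx(3.0 - 2 / 3)

    def test_all_sense_codons_match_brute_force(self):
        for codon in CODE.sense_codons:
            assert ng86_site_counts(codon, CODE) == pytest.approx(
                brute_site_counts(codon, CODE), abs=1e-12
            )

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_site_counts("TAA", CODE)


class TestNG86Pathways:
    def test_random_pairs_match_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        sense = list(CODE.sense_codons)
        for _ in range(100):
            c1, c2 = rng.choice(sense, size=2)
            sd, nd, n_valid = ng86_pathway_counts(c1, c2, CODE)
            osd, ond = brute_pathway_counts(c1, c2, CODE)
            assert sd == pytest.approx(osd, abs=1e-9)
            assert nd == pytest.approx(ond, abs=1e-9)
            if n_valid:
                ndiff = sum(a != b for a, b in zip(c1, c2))
                assert sd + nd == pytest.approx(ndiff)


class TestNG86Pairwise:
    def test_identical_sequences_flagged(self):
        res = ng86_pairwise("ATTATT", "ATTATT", CODE)
        assert "identical" in res.flags and res.Sd == res.Nd == 0

    def test_single_synonymous_difference_forces_omega_zero(self):
        res = ng86_pairwise("ATTGGAGGA", "ATCGGAGGA", CODE)
        assert res.dN == 0.0 and res.dS > 0 and res.omega == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        sense = list(CODE.sense_codons)
        s1 = "".join(rng.choice(sense, size=30))
        s2 = "".join(rng.choice(sense, size=30))
        a = ng86_pairwise(s1, s2, CODE)
        b = ng86_pairwise(s2, s1, CODE)
        assert (a.S_sites, a.N_sites, a.Sd, a.Nd, a.dS, a.dN) == pytest.approx(
            (b.S_sites, b.N_sites, b.Sd, b.Nd, b.dS, b.dN), nan_ok=True
        )

    def test_gapped_codons_excluded_pairwise(self):
        res = ng86_pairwise("AT-GGA", "ATTGGA", CODE)
        assert res.n_codons == 1

    def test_site_totals_bounded_by_three_per_codon(self):
        rng = np.random.default_rng(2)
        sense = list(CODE.sense_codons)
        s1 = "".join(rng.choice(sense, size=50))
        s2 = "".join(rng.choice(sense, size=50))
        res = ng86_pairwise(s1, s2, CODE)
        assert res.S_sites + res.N_sites <= 3 * res.n_codons + 1e-9


class TestFitchAncestral:
    def test_single_change_on_internal_edge_of_balanced_quartet(self, quartet_tree):
        # on the unrooted quartet the change sits on the single internal
        # edge; rooting splits that edge in two, giving two equally
        # parsimonious placements whose weights sum to the one change
        rec = fitch_ancestral(
            quartet_tree, {"A": "ATT", "B": "ATT", "C": "ATC", "D": "ATC"}, CODE
        )
        assert rec.min_changes == 1 and rec.mpr_count == 2
        assert all(e.kind == "syn" for e in rec.events)
        root_children = {c.index for c in quartet_tree.root.children}
        assert {e.branch for e in rec.events} <= root_children
        assert sum(e.weight for e in rec.events) == pytest.approx(1.0)

    def test_identical_tips_no_events(self, quartet_tree):
        rec = fitch_ancestral(quartet_tree, {t: "GGA" for t in "ABCD"}, CODE)
        assert rec.min_changes == 0 and rec.events == []

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration_on_five_tips(self, seed):
        tree = Tree.from_newick("(((A:1,B:1):1,(C:1,D:1):1):1,E:2);")
        rng = np.random.default_rng(seed)
        codons = rng.choice(["ATT", "ATC", "ATA", "GGA"], size=5)
        states = dict(zip("ABCDE", codons))
        rec = fitch_ancestral(tree, states, CODE)
        cost, n_mpr, branch_changes = brute_parsimony(tree, states)
        assert rec.min_changes == cost
        assert rec.mpr_count == n_mpr
        got = {}
        for e in rec.events:
            got[e.branch] = got.get(e.branch, 0.0) + e.weight
        for branch, want in branch_changes.items():
            assert got.get(branch, 0.0) == pytest.approx(want, abs=1e-9)
        assert sum(e.weight for e in rec.events) == pytest.approx(cost, abs=1e-9)

    def test_missing_tips_are_dropped(self, quartet_tree):
        rec = fitch_ancestral(quartet_tree, {"A": "ATT", "B": "ATC"}, CODE)
        assert rec.min_changes == 1

    def test_fewer_than_two_observed_tips_rejected(self, quartet_tree):
        with pytest.raises(ValueError):
            fitch_ancestral(quartet_tree, {"A": "ATT"}, CODE)

    def test_event_weights_sum_to_parsimony_score(self, neutral_sim):
        tree, aln, _ = neutral_sim
        rng = np.random.default_rng(4)
        for site in rng.integers(0, aln.n_codons, size=10):
            states = {
                r.id: r.residues[3 * site : 3 * site + 3] for r in aln.records
            }
            rec = fitch_ancestral(tree, states, CODE, site=int(site))
            assert sum(e.weight for e in rec.events) == pytest.approx(
                rec.min_changes, abs=1e-9
            )


class TestBinomialTail:
    def test_all_nonsynonymous_closed_form(self):
        # 5 events, all nonsynonymous, expected fraction 0.7 -> 0.7^5
        assert _binom_upper_tail(5, 5, 0.7) == pytest.approx(0.7**5)

    def test_zero_observed_is_certain(self):
        assert _binom_upper_tail(0.0, 4.0, 0.5) == 1.0


class TestSlacSiteTest:
    def test_invariant_sites_neutral(self, quartet_tree):
        aln = GeneAlignment(
            "g", [SequenceRecord(t, "ATTGGA") for t in "ABCD"]
        )
        results = slac_site_test(aln, quartet_tree, CODE)
        assert all(r.classification == "neutral" and r.p_positive == 1.0
                   for r in results)

    def test_pvalues_bounded_and_indexed_one_based(self, neutral_sim):
        tree, aln, _ = neutral_sim
        results = slac_site_test(aln, tree, CODE)
        assert [r.codon_index for r in results] == list(range(1, aln.n_codons + 1))
        assert all(0.0 <= r.p_positive <= 1.0 and 0.0 <= r.p_negative <= 1.0
                   for r in results)

    def test_mismatched_tips_rejected(self, quartet_tree):
        aln = GeneAlignment("g", [SequenceRecord("X", "ATT")])
        with pytest.raises(ValueError):
            slac_site_test(aln, quartet_tree, CODE)


class TestGroupContrast:
    def test_zero_permutations_rejected(self, contrast_sim):
        tree, aln, _ = contrast_sim
        labels = {t.name: t.group for t in tree.tips}
        with pytest.raises(ValueError):
            group_omega_contrast(aln, tree, labels, n_perm=0, seed=1)

    def test_exchangeable_labels_give_nonsmall_p(self, neutral_sim):
        tree, aln, _ = neutral_sim
        # arbitrary labels on a simulation with no group effect
        labels = {name: i % 2 for i, name in enumerate(sorted(aln.ids))}
        res = group_omega_contrast(aln, tree, labels, n_perm=499, seed=5)
        assert res.p_perm > 0.01

    def test_detects_elevated_foreground(self, contrast_sim):
        tree, aln, truth = contrast_sim
        labels = {t.name: t.group for t in tree.tips}
        res = group_omega_contrast(aln, tree, labels, n_perm=499, seed=3)
        assert res.delta > 0
        assert res.omega_foreground > res.omega_background

    def test_reproducible_given_seed(self, contrast_sim):
        tree, aln, _ = contrast_sim
        labels = {t.name: t.group for t in tree.tips}
        bo = terminal_branch_omegas(aln, tree, CODE, seed=2)
        r1 = group_omega_contrast(aln, tree, labels, n_perm=199, seed=7,
                                  branch_omegas=bo)
        r2 = group_omega_contrast(aln, tree, labels, n_perm=199, seed=7,
                                  branch_omegas=bo)
        assert r1.p_perm == r2.p_perm and r1.delta == r2.delta


class TestOmegaRegimes:
    @pytest.mark.parametrize("omega,check", [(0.2, lambda w: w < 1.0),
                                             (1.0, lambda w: w > 0.8)])
    def test_mean_pairwise_omega_reflects_regime(self, omega, check):
        from mitosel import SimulationConfig, simulate_codon_evolution, simulate_tree

        cfg = SimulationConfig(seed=31, n_tips=6, n_codons=350, depth=0.3,
                               omega_foreground=omega, omega_background=omega,
                               kappa=1.0, at_fraction=0.5)
        tree = simulate_tree(cfg)
        aln, _ = simulate_codon_evolution(tree, cfg)
        omegas = []
        for a, b in itertools.combinations(aln.records, 2):
            res = ng86_pairwise(a.residues, b.residues, CODE)
            if not math.isnan(res.omega):
                omegas.append(res.omega)
        assert omegas and check(float(np.mean(omegas)))
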
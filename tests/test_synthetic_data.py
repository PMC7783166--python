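"""Generators: determinism, round-trip through the readers, and agreement
with their own analytic expectations."""

import math

import numpy as np
import pytest

from readthru import extraction, formats_io as fio
from readthru import synthetic_data as sd
from readthru.comparative import taa_disparity
from readthru.extraction import partition_heg_leg
from readthru.stop_usage import stop_frequencies

from conftest import REJECT_PLAN


class TestDeterminism:
    def test_genome_outputs_byte_identical(self, tmp_path):
        cfg = sd.GenomeSimConfig(n_genes=40, seed=17, reject_plan=dict(REJECT_PLAN))
        paths_a = sd.generate_genome(cfg, tmp_path / "a")
        paths_b = sd.generate_genome(cfg, tmp_path / "b")
        for pa, pb in zip(paths_a, paths_b):
            assert pa.read_bytes() == pb.read_bytes()

    def test_triplet_outputs_byte_identical(self, tmp_path):
        cfg = sd.TripletSimConfig(n_genes=10, seed=23)
        pa, ra, ta = sd.generate_triplets(cfg, tmp_path / "a")
        pb, rb, tb = sd.generate_triplets(cfg, tmp_path / "b")
        assert ta.read_bytes() == tb.read_bytes()
        assert all(x.read_bytes() == y.read_bytes() for x, y in zip(pa, pb))

    def test_comparative_outputs_byte_identical(self, tmp_path):
        cfg = sd.ComparativeSimConfig(n_species=12, seed=29)
        a = sd.generate_comparative(cfg, tmp_path / "a")
        b = sd.generate_comparative(cfg, tmp_path / "b")
        for pa, pb in zip(a, b):
            assert pa.read_bytes() == pb.read_bytes()


class TestRoundTrip:
    def test_genome_files_parse_back(self, tmp_path):
        cfg = sd.GenomeSimConfig(n_genes=30, seed=5, reject_plan=dict(REJECT_PLAN))
        fasta, gff, expr, _ = sd.generate_genome(cfg, tmp_path)
        genome_mem, expression_mem, _ = sd.build_genome(cfg)
        genome = fio.read_genome(fasta, gff)
        mem = {g.gene_id: g.coding_sequence for g in genome_mem.genes}
        disk = {g.gene_id: g.coding_sequence for g in genome.genes}
        assert mem == disk
        expression = fio.read_expression(expr)
        assert expression.keys() == expression_mem.keys()
        assert all(
            math.isclose(expression[k], expression_mem[k], rel_tol=1e-9)
            for k in expression
        )

    def test_triplet_files_parse_back(self, tmp_path):
        cfg = sd.TripletSimConfig(n_genes=5, seed=2)
        paths, roles, _ = sd.generate_triplets(cfg, tmp_path)
        role_map = {}
        with open(roles) as fh:
            fh.readline()
            for line in fh:
                token, role = line.split()
                role_map[token] = role
        triplets = fio.read_triplets(paths, role_map)
        mem, _ = sd.build_triplets(cfg)
        assert [t.seqs for t in triplets] == [t.seqs for t in mem]

    def test_comparative_files_parse_back(self, tmp_path):
        cfg = sd.ComparativeSimConfig(n_species=10, seed=3)
        tree_path, traits_path, _ = sd.generate_comparative(cfg, tmp_path)
        tree = fio.read_tree(tree_path)
        assert len(tree.taxon_namespace) == 10


class TestGenomeGenerator:
    def test_all_taa_when_forced(self):
        cfg = sd.GenomeSimConfig(n_genes=50, stop_probs=(1.0, 0.0, 0.0), seed=7)
        genome, _, truth = sd.build_genome(cfg)
        assert all(g.coding_sequence[-3:] == "TAA" for g in genome.genes)
        assert (truth["stop"] == "TAA").all()

    def test_background_asc_rate_near_iid_expectation(self, small_genome):
        """With a uniform-composition chain, each downstream codon position
        is a stop triplet with probability 3/64."""
        truth = small_genome["truth"]
        utr_rows = truth[truth["fate"] != "short-intergenic"]
        n = len(utr_rows)
        hits = sum(
            len([p for p in str(row).split(",") if p])
            for row in utr_rows["asc_positions"]
        )
        rate = hits / (6 * n)
        sd3 = 3 * math.sqrt((3 / 64) * (1 - 3 / 64) / (6 * n))
        assert abs(rate - 3 / 64) < sd3

    def test_expression_link_raises_heg_taa(self):
        cfg = sd.GenomeSimConfig(n_genes=4000, expression_link=0.5, seed=13)
        genome, expression, _ = sd.build_genome(cfg)
        contexts, _ = extraction.extract_stop_contexts(genome, expression)
        heg, leg = partition_heg_leg(contexts)
        f_heg = stop_frequencies(heg).freq["TAA"]
        f_leg = stop_frequencies(leg).freq["TAA"]
        n_q = len(heg)
        sd3 = 3 * math.sqrt(0.25 / n_q) * math.sqrt(2)
        assert f_heg - f_leg > 0
        disparity = taa_disparity(heg, leg)
        expected = sd.expected_taa_disparity(cfg)
        # delta-method SD of the ratio at quartile size n_q
        se = expected * math.sqrt(2 * 0.5 * 0.5 / (0.5**2) / n_q)
        assert abs(disparity - expected) < max(3 * se, sd3)

    def test_gc_target_reflected_in_utrs(self):
        cfg = sd.GenomeSimConfig(n_genes=300, gc=0.3, seed=21)
        genome, expression, _ = sd.build_genome(cfg)
        contexts, _ = extraction.extract_stop_contexts(genome, expression)
        gc = np.mean(
            [
                (c.downstream_utr.count("G") + c.downstream_utr.count("C")) / 97
                for c in contexts
            ]
        )
        assert abs(gc - 0.3) < 0.02

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            sd.GenomeSimConfig(n_genes=10, gc=1.5, seed=1)
        with pytest.raises(ValueError):
            sd.GenomeSimConfig(n_genes=10, stop_probs=(0.9, 0.3, 0.1), seed=1)
        with pytest.raises(ValueError):
            sd.GenomeSimConfig(n_genes=10, asc_inject=(9, 0.1), seed=1)


class TestTripletGenerator:
    def test_zero_branch_lengths_identical_sequences(self):
        cfg = sd.TripletSimConfig(n_genes=10, branch_lengths=(0, 0, 0), seed=4)
        trips, truth = sd.build_triplets(cfg)
        for t in trips:
            assert t.seqs["ingroup1"] == t.seqs["ingroup2"] == t.seqs["outgroup"]
        assert truth.empty

    def test_flat_profile_matches_jc_enumeration_oracle(self):
        """Recovered parsimony frequency at flat-rate sites equals the
        exact expectation computed by enumerating all 64 column outcomes
        under Jukes-Cantor transition probabilities."""
        from itertools import product

        from readthru.triplet_substitutions import infer_ancestor, substitution_profile

        t1 = t2 = 0.05
        to = 0.10
        rate = 1.0
        flat = {s: rate for s in list(range(-30, 0)) + list(range(4, 34))}
        flat.update({1: 0.0, 2: 0.0, 3: 0.0})
        cfg = sd.TripletSimConfig(
            n_genes=2000, branch_lengths=(t1, t2, to), rate_profile=flat, seed=6
        )
        trips, _ = sd.build_triplets(cfg)
        profile = substitution_profile(trips).table
        # UTR sites only: CDS sites are biased by the premature-stop
        # filter (genes whose coding mutations create a stop are dropped)
        flat_sites = profile[profile.site >= 4]
        num = flat_sites["numerator"].sum()
        den = flat_sites["denominator"].sum()
        observed = num / den

        def jc(t):
            # JC transition matrix entries at branch length t (expected subs/site)
            same = 0.25 + 0.75 * math.exp(-4 * t / 3)
            diff = (1 - same) / 3
            return same, diff

        def pr(t, a, b, jc_t):
            same, diff = jc_t
            return same if a == b else diff

        e_num = e_den = 0.0
        jcs = [jc(t) for t in (t1, t2, to)]
        for in1, in2, out in product("ACGT", repeat=3):
            # root fixed at A by symmetry
            p = pr(t1, "A", in1, jcs[0]) * pr(t2, "A", in2, jcs[1]) * pr(to, "A", out, jcs[2])
            anc = infer_ancestor((in1, in2, out))
            if anc is None:
                continue
            e_den += 2 * p
            e_num += p * ((in1 != anc) + (in2 != anc))
        expected = e_num / e_den
        n_obs = den  # ~2 lineages x genes x sites
        sd3 = 3 * math.sqrt(expected * (1 - expected) / n_obs)
        assert abs(observed - expected) < sd3

    def test_ramp_profile_rank_recovery(self):
        from scipy.stats import spearmanr

        from readthru.triplet_substitutions import substitution_profile

        cfg = sd.TripletSimConfig(n_genes=1500, seed=9)
        trips, _ = sd.build_triplets(cfg)
        profile = substitution_profile(trips).table
        down = profile[profile.site >= 4].set_index("site")
        truth_rates = [cfg.rate_profile[s] for s in down.index]
        rho = spearmanr(down["frequency"], truth_rates).statistic
        assert rho > 0.9


class TestComparativeGenerator:
    def test_too_few_species_refused(self):
        with pytest.raises(ValueError, match="too small"):
            sd.ComparativeSimConfig(n_species=2, seed=1)

    def test_tree_is_ultrametric_with_positive_branches(self):
        tree, traits, truth = sd.build_comparative(sd.ComparativeSimConfig(n_species=20, seed=10))
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9
        assert all(e.length is None or e.length > 0 for e in tree.preorder_edge_iter())
        assert truth["b"] == 1.0
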
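"""Simulator tests: lineage-tree invariants, read-count laws, duplex bundles."""

import numpy as np
import pandas as pd
import pytest

from secondhit import simulate as sim


def shared_count_oracle(tree: sim.LineageTree, a: int, b: int) -> int:
    """Independent path-sum oracle: shared mutations of two nodes equal the
    summed branch counts over the common part of their root paths."""
    path_a = tree.path_to_root(a)
    path_b = set(tree.path_to_root(b))
    common = [n for n in path_a if n in path_b]
    return sum(len(tree.branch_mutations.get(n, frozenset())) for n in common)


class TestSimulateLineage:
    def test_degenerate_single_node_tree(self):
        tree = sim.simulate_lineage(1, 5.0, seed=0)
        assert tree.nodes == [0]
        assert tree.genotype(0) == frozenset()

    def test_zero_rate_gives_empty_branches(self):
        tree = sim.simulate_lineage(8, 0.0, seed=1)
        assert all(len(m) == 0 for m in tree.branch_mutations.values())

    def test_invalid_node_count_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_lineage(0, 1.0, seed=0)
        with pytest.raises(ValueError):
            sim.simulate_lineage(5, -1.0, seed=0)

    @pytest.mark.parametrize("seed", [0, 1, 12345])
    def test_shared_mutations_match_path_sum_oracle(self, seed):
        tree = sim.simulate_lineage(15, 10.0, seed=seed)
        leaves = [n for n in tree.nodes if n not in set(tree.parents.values())]
        for i, a in enumerate(leaves):
            for b in leaves[i + 1:]:
                assert len(tree.shared_mutations(a, b)) == shared_count_oracle(tree, a, b)

    def test_mutation_ids_globally_unique_and_cataloged(self):
        tree = sim.simulate_lineage(10, 20.0, seed=3)
        ids = [m for s in tree.branch_mutations.values() for m in s]
        assert len(ids) == len(set(ids))
        assert set(ids) <= set(tree.catalog)

    def test_star_topology_makes_nonroot_nodes_unrelated(self):
        tree = sim.simulate_lineage(6, 10.0, seed=2, topology="star")
        assert all(p == 0 for n, p in tree.parents.items() if n != 0)
        assert len(tree.shared_mutations(1, 2)) == 0

    def test_determinism(self):
        t1 = sim.simulate_lineage(10, 5.0, seed=9)
        t2 = sim.simulate_lineage(10, 5.0, seed=9)
        assert t1.parents == t2.parents
        assert t1.branch_mutations == t2.branch_mutations
        assert t1.catalog == t2.catalog


class TestSimulateCohort:
    def test_proband_carries_germline_hit_in_every_cell(self, proband):
        g = proband.germline_hit
        assert g is not None and g.alt_on_mutant is True
        chrom, start, end = proband.gene_footprint
        assert g.chrom == chrom and start <= g.pos <= end
        # a pure-background sample shows the het at VAF 0.5; a second-hit
        # LOH clone can only shift it, never remove it from all cells
        spec = sim.SampleSpec("bg", "bulk", {}, 0.0)
        assert sim.true_vaf(proband, spec, g.chrom, g.pos, g.alt) == pytest.approx(0.5)

    def test_tumor_at_purity_one_fixes_retained_allele_fraction(self, proband):
        spec = sim.SampleSpec("pure_tumor", "bulk", {}, 1.0, error_rate=0.0)
        for snp in proband.germline_hets.values():
            v = sim.true_vaf(proband, spec, snp.chrom, snp.pos, snp.alt)
            assert v == pytest.approx(1.0 if snp.alt_on_mutant else 0.0)

    def test_controls_have_no_second_hit_clones(self, cohort):
        for ctrl in cohort.controls:
            assert all(c.second_hit is None for c in ctrl.clones.values())
            assert ctrl.germline_hit is None

    def test_clone_plan_realized_exactly(self, proband):
        hits = {n: c.second_hit for n, c in proband.clones.items() if c.second_hit}
        kinds = sorted((h.kind, h.lost_haplotype or "") for h in hits.values())
        assert ("point", "") in kinds
        assert ("loh", "wt") in kinds and ("loh", "mutant") in kinds

    def test_overfull_sample_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            sim.SampleSpec("bad", "bulk", {2: 0.7}, 0.5)
        with pytest.raises(ValueError, match="exceed|sum"):
            sim.simulate_cohort(
                {"sample_plan": [{"sample_id": "bad", "clone_fractions": {2: 0.7},
                                  "tumor_contamination": 0.5}]},
                seed=0,
            )

    def test_reproducible_byte_for_byte(self):
        c1 = sim.simulate_cohort(seed=5)
        c2 = sim.simulate_cohort(seed=5)
        sites = sim.snp_panel_sites(c1.proband)
        rc1 = sim.emit_read_counts(c1.proband, c1.proband.samples[1], sites, seed=3)
        rc2 = sim.emit_read_counts(c2.proband, c2.proband.samples[1], sites, seed=3)
        assert rc1.to_csv() == rc2.to_csv()


class TestEmitReadCounts:
    def test_clone_size_is_twice_vaf(self, proband):
        # heterozygous point hit in a clone of fraction 0.56: expected VAF 0.28
        hit = next(c.second_hit for c in proband.clones.values()
                   if c.second_hit and c.second_hit.kind == "point")
        v = proband.tree.catalog[hit.mutation_id]
        spec = sim.SampleSpec("s", "lcm", {2: 0.56}, 0.0, target_depth=2000,
                              error_rate=0.0)
        assert sim.true_vaf(proband, spec, v.chrom, v.pos, v.alt) == pytest.approx(0.28)
        rc = sim.emit_read_counts(proband, spec, [(v.chrom, v.pos, v.ref, v.alt)], seed=0)
        vaf = rc["alt_depth"][0] / rc["depth"][0]
        se = np.sqrt(0.28 * 0.72 / rc["depth"][0])
        assert abs(vaf - 0.28) < 3 * se

    def test_zero_target_depth_gives_no_reads(self, proband):
        spec = sim.SampleSpec("s", "bulk", {}, 0.0, target_depth=0.0)
        rc = sim.emit_read_counts(proband, spec, sim.snp_panel_sites(proband)[:10], seed=0)
        assert (rc["depth"] == 0).all() and (rc["alt_depth"] == 0).all()

    def test_empty_site_list_gives_empty_table(self, proband):
        rc = sim.emit_read_counts(proband, proband.samples[0], [], seed=0)
        assert rc.empty

    def test_unknown_site_rejected(self, proband):
        spec = proband.samples[0]
        with pytest.raises(ValueError, match="chromosome"):
            sim.emit_read_counts(proband, spec, [("chrX", 100, "A", "C")], seed=0)
        with pytest.raises(ValueError, match="outside"):
            sim.emit_read_counts(proband, spec, [("chr17", 10**10, "A", "C")], seed=0)

    def test_error_only_sites_match_binomial_closed_form(self, proband):
        # sites with no variant: alt fraction ~ Binomial(depth, e/3)
        e, depth, n = 1e-3, 30, 40000
        spec = sim.SampleSpec("s", "bulk", {}, 0.0, target_depth=depth, error_rate=e)
        rng = np.random.default_rng(0)
        sites = [("chr2", int(p), "A", "C")
                 for p in rng.choice(2_000_000, size=n, replace=False) + 1]
        rc = sim.emit_read_counts(proband, spec, sites, seed=1)
        frac = rc["alt_depth"].sum() / rc["depth"].sum()
        p = e / 3
        se = np.sqrt(p * (1 - p) / rc["depth"].sum())
        assert abs(frac - p) < 3 * se

    def test_contamination_truncal_vaf_converges_to_half_purity(self, proband):
        t = 0.04
        spec = sim.SampleSpec("s", "bulk", {}, t, target_depth=40, error_rate=0.0)
        sites = sim.catalog_sites(proband, sorted(proband.truncal_mutation_ids))
        rc = sim.emit_read_counts(proband, spec, sites, seed=2)
        agg = rc["alt_depth"].sum() / rc["depth"].sum()
        se = np.sqrt((t / 2) * (1 - t / 2) / rc["depth"].sum())
        assert abs(agg - t / 2) < 4 * se

    def test_shared_mutation_counts_match_tree_oracle_at_high_depth(self):
        # error-free, high-depth presence recovers the tree's sharing truth
        tree = sim.simulate_lineage(8, 15.0, seed=21)
        ind = sim.Individual(
            "x", tree, {}, [], {}, None, sim.DEFAULT_GENE_FOOTPRINT, None,
            frozenset(),
        )
        leaves = [n for n in tree.nodes if n not in set(tree.parents.values())][:3]
        sites = sim.catalog_sites(ind, sorted(tree.catalog))
        present = {}
        for leaf in leaves:
            spec = sim.SampleSpec(f"s{leaf}", "lcm", {leaf: 1.0}, 0.0,
                                  target_depth=200, error_rate=0.0)
            rc = sim.emit_read_counts(ind, spec, sites, seed=leaf)
            present[leaf] = {
                mid for mid, alt in zip(sorted(tree.catalog), rc["alt_depth"]) if alt > 0
            }
        for i, a in enumerate(leaves):
            for b in leaves[i + 1:]:
                assert len(present[a] & present[b]) == shared_count_oracle(tree, a, b)


class TestEmitDuplexReads:
    def test_clonal_variant_supported_on_both_strands_of_every_molecule(self, proband):
        g = proband.germline_hit
        spec = sim.SampleSpec("s", "lcm", {}, 1.0, error_rate=0.0)  # pure tumor
        # germline hit is on the retained haplotype: VAF 1 in pure tumor
        df = sim.emit_duplex_reads(proband, spec, [(g.chrom, g.pos, g.ref, g.alt)],
                                   single_strand_error=0.0, seed=0, mean_molecules=50)
        assert (df["variant_reads"] == df["reads"]).all()
        assert set(df.groupby("molecule_id")["strand"].nunique()) == {2}

    def test_no_molecules_gives_empty_table(self, proband):
        df = sim.emit_duplex_reads(proband, proband.samples[0],
                                   [("chr2", 100, "A", "C")],
                                   single_strand_error=1e-3, seed=0, mean_molecules=0)
        assert df.empty

    def test_double_strand_error_rate_matches_analytic_value(self, proband):
        # both strands of a non-carrier molecule err to the same alt base
        # with probability (e/3)^2
        e = 0.06
        spec = sim.SampleSpec("s", "bulk", {}, 0.0, error_rate=0.0)
        df = sim.emit_duplex_reads(proband, spec, [("chr2", 500, "A", "C")],
                                   single_strand_error=e, seed=3,
                                   mean_molecules=150_000)
        per_mol = df.groupby("molecule_id")["variant_reads"].agg(["min", "count"])
        both = int((per_mol["min"] >= 1).sum())
        n = len(per_mol)
        p = (e / 3) ** 2
        assert abs(both / n - p) < 4 * np.sqrt(p * (1 - p) / n)

    def test_invalid_error_rate_rejected(self, proband):
        with pytest.raises(ValueError):
            sim.emit_duplex_reads(proband, proband.samples[0], [], 1.5, seed=0)
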
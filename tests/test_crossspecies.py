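"""Ortholog mapping and cross-species conservation of gene sets and nodes."""
import numpy as np
import pandas as pd
import pytest

from consensnet import data as bundled
from consensnet.consensome import build_consensomes, extract_hcts
from consensnet.crossspecies import (
    OrthologMap,
    conservation_matrix,
    conserved_node_overlap,
    cross_species_gene_overlap,
    enzyme_class_enrichment,
    map_orthologs,
)
from consensnet.genesets import GeneSet
from consensnet.synthetic import SimConfig, gen_de_table, gen_regulatory_corpus
from consensnet.genesets import derive_de_gene_sets
from consensnet.enrichment import hct_intersection_analysis


def identity_map(symbols):
    return OrthologMap(
        pd.DataFrame({"src_gene": list(symbols),
                      "dst_gene": [s.upper() for s in symbols]}),
        src_species="mouse", dst_species="human",
    )


class TestMapOrthologs:
    def test_identity_up_to_case(self):
        omap = identity_map(["Rsad2", "Ifit1"])
        mouse = GeneSet("m", "mouse", frozenset({"Rsad2", "Ifit1"}))
        mapped, unmapped = map_orthologs(mouse, omap)
        assert mapped.symbols == {"RSAD2", "IFIT1"}
        assert mapped.species == "human" and not unmapped

    def test_empty_map_counts_everything_unmapped(self):
        omap = OrthologMap(pd.DataFrame({"src_gene": [], "dst_gene": []}),
                           "mouse", "human")
        mouse = GeneSet("m", "mouse", frozenset({"Rsad2", "Ifit1"}))
        mapped, unmapped = map_orthologs(mouse, omap)
        assert len(mapped) == 0 and unmapped == {"Rsad2", "Ifit1"}

    def test_one_to_two_fans_out(self):
        omap = OrthologMap(
            pd.DataFrame({"src_gene": ["Ifit1", "Ifit1"],
                          "dst_gene": ["IFIT1", "IFIT1B"]}),
            "mouse", "human",
        )
        mapped, _ = map_orthologs(GeneSet("m", "mouse", frozenset({"Ifit1"})),
                                  omap)
        assert mapped.symbols == {"IFIT1", "IFIT1B"}

    def test_species_mismatch_rejected(self):
        omap = identity_map(["Rsad2"])
        human = GeneSet("h", "human", frozenset({"RSAD2"}))
        with pytest.raises(ValueError, match="source"):
            map_orthologs(human, omap)

    def test_monotone_in_input(self):
        omap = identity_map([f"G{i}a" for i in range(20)])
        small = GeneSet("s", "mouse", frozenset({"G1a", "G2a"}))
        big = GeneSet("b", "mouse", frozenset({f"G{i}a" for i in range(10)}))
        mapped_small, _ = map_orthologs(small, omap)
        mapped_big, _ = map_orthologs(big, omap)
        assert mapped_small.symbols <= mapped_big.symbols


class TestCrossSpeciesOverlap:
    def test_disjoint_sets(self):
        omap = identity_map(["Aa", "Bb", "Cc", "Dd"])
        a = GeneSet("a", "mouse", frozenset({"Aa", "Bb"}))
        b = GeneSet("b", "human", frozenset({"CC", "DD"}))
        inter, res = cross_species_gene_overlap(a, b, omap, universe=100)
        assert len(inter) == 0 and res.k == 0 and res.p == 1.0

    def test_mapped_copy_is_maximal_overlap(self):
        symbols = [f"Gene{i}a" for i in range(6)]
        omap = identity_map(symbols)
        a = GeneSet("a", "mouse", frozenset(symbols))
        b = GeneSet("b", "human", frozenset(s.upper() for s in symbols))
        inter, res = cross_species_gene_overlap(a, b, omap, universe=50)
        assert inter.symbols == a.symbols
        assert res.k == len(a)
        # minimal attainable p at these margins
        from consensnet.enrichment import overlap_from_counts
        assert res.p == pytest.approx(
            overlap_from_counts(6, 6, 6, 50).p
        )

    def test_direction_agnostic_with_bijective_map(self):
        omap = identity_map(["Aa", "Bb", "Cc", "Dd", "Ee"])
        a = GeneSet("a", "mouse", frozenset({"Aa", "Bb", "Cc"}))
        b = GeneSet("b", "human", frozenset({"BB", "CC", "DD"}))
        _, res_fwd = cross_species_gene_overlap(a, b, omap, universe=40)
        _, res_rev = cross_species_gene_overlap(b, a, omap.inverted(),
                                                universe=40)
        assert res_fwd.k == res_rev.k == 2
        assert res_fwd.p == pytest.approx(res_rev.p)
        # the map is auto-inverted when handed in the opposite direction
        _, res_auto = cross_species_gene_overlap(a, b, omap.inverted(),
                                                 universe=40)
        assert res_auto.k == res_fwd.k


class TestEnzymeClassEnrichment:
    def test_bundled_intersection_annotation_counts(self):
        """The packaged 40-gene intersection table carries 6 E2/E3 genes."""
        ann = bundled.hwgbmi_intersection_classes()
        intersection = GeneSet("inter", "mouse", frozenset(ann["gene"]))
        assert len(intersection) == 40
        res = enzyme_class_enrichment(
            intersection, ann, bundled.E2_E3_CLASSES,
            universe=24703, n_class_in_universe=400,
        )
        assert res.k == 6 and res.n1 == 40 and res.N == 24703
        assert res.p < 1e-3

    def test_empty_class_list(self):
        ann = bundled.hwgbmi_intersection_classes()
        intersection = GeneSet("inter", "mouse", frozenset(ann["gene"]))
        res = enzyme_class_enrichment(intersection, ann, [], universe=24703,
                                      n_class_in_universe=0)
        assert res.k == 0 and res.p == 1.0

    def test_all_genes_in_class(self):
        ann = pd.DataFrame({"gene": ["A", "B"], "class": ["x", "x"]})
        inter = GeneSet("i", "mouse", frozenset({"A", "B"}))
        res = enzyme_class_enrichment(inter, ann, ["x"], universe=100,
                                      n_class_in_universe=10)
        assert res.k == res.n1 == 2

    def test_unannotated_intersection_gene_rejected(self):
        ann = pd.DataFrame({"gene": ["A"], "class": ["x"]})
        inter = GeneSet("i", "mouse", frozenset({"A", "B"}))
        with pytest.raises(KeyError, match="B"):
            enzyme_class_enrichment(inter, ann, ["x"], universe=100)


def two_species_consensomes(cfg, human_case=True):
    """Mouse corpus plus a human corpus with the same planted regulons,
    symbols upper-cased."""
    corpus, truth = gen_regulatory_corpus(cfg)
    mouse = build_consensomes(corpus)
    human_corpus = corpus.assign(
        node=corpus["node"].str.upper(), gene=corpus["gene"].str.upper()
    )
    human = build_consensomes(human_corpus)
    return mouse, human, corpus, truth


class TestConservationMatrix:
    CFG = SimConfig(n_genes=120, n_nodes=3, targets_per_node=6,
                    datasets_per_node=(2, 2), background_rate=0.2,
                    n_up_genes=10, n_down_genes=5, seed=13)

    def test_identical_regulons_conserve_everything(self):
        mouse, human, _, truth = two_species_consensomes(self.CFG)
        node = sorted(truth.true_targets)[0]
        genes = sorted(truth.true_targets[node])[:3]
        omap = identity_map([g for g in mouse[node].table["gene"]])
        mat = conservation_matrix(genes, mouse, human, omap, rule="any")
        retained = mat[~mat["absent"]]
        assert len(retained)
        assert (retained["mouse_hct"] == retained["human_hct"]).all()
        assert retained["mouse_percentile"].to_numpy() == pytest.approx(
            retained["human_percentile"].to_numpy()
        )

    def test_percentiles_match_consensome_module_exactly(self):
        mouse, human, _, truth = two_species_consensomes(self.CFG)
        node = sorted(truth.true_targets)[0]
        gene = sorted(truth.true_targets[node])[0]
        omap = identity_map([gene])
        mat = conservation_matrix([gene], mouse, human, omap, rule="any")
        row = mat[(mat["gene"] == gene) & (mat["node"] == node.upper())]
        if len(row):
            assert row["mouse_percentile"].iloc[0] == pytest.approx(
                mouse[node].percentile_of(gene)
            )

    def test_single_species_hct_rule_contrast(self):
        # one node, gene is an HCT in mouse only
        mouse_tab = pd.DataFrame(
            {"dataset_id": "d1", "node": "Tf1",
             "gene": [f"g{i}" for i in range(20)],
             "strength": np.arange(20, 0, -1.0)}
        )
        human_tab = mouse_tab.assign(
            node="TF1",
            gene=[f"G{i}" for i in range(19, -1, -1)],  # reversed order
            strength=np.arange(20, 0, -1.0),
        )
        mouse = build_consensomes(mouse_tab)
        human = build_consensomes(human_tab)
        omap = identity_map([f"g{i}" for i in range(20)])
        mat_any = conservation_matrix(["g0"], mouse, human, omap, rule="any")
        assert len(mat_any) == 1
        assert mat_any["mouse_hct"].iloc[0] and not mat_any["human_hct"].iloc[0]
        mat_both = conservation_matrix(["g0"], mouse, human, omap, rule="both")
        assert len(mat_both) == 0

    def test_gene_absent_from_both_species_flagged(self):
        mouse, human, _, truth = two_species_consensomes(self.CFG)
        omap = identity_map(["Zz9"])
        mat = conservation_matrix(["Zz9"], mouse, human, omap, rule="any")
        assert len(mat) == 0 or mat["absent"].all()


class TestConservedNodeOverlap:
    def test_direct_counts(self):
        """7 mapped human nodes tested in mouse, 5 of them significant."""
        tested = [f"Node{i}" for i in range(100)]
        sig_a = tested[:10]
        sig_b = [f"NODE{i}" for i in range(7)]  # orthologs of Node0..Node6
        omap = OrthologMap(
            pd.DataFrame({"src_gene": [f"NODE{i}" for i in range(7)],
                          "dst_gene": [f"Node{i}" for i in range(7)]}),
            "human", "mouse",
        )
        res, untested = conserved_node_overlap(sig_a[:5], tested, sig_b, omap)
        assert res.k == 5 and res.n1 == 7
        assert res.n2 == 5 and res.N == 100
        assert not untested

    def test_no_mapped_node_significant(self):
        tested = [f"Node{i}" for i in range(10)]
        omap = OrthologMap(
            pd.DataFrame({"src_gene": ["X1"], "dst_gene": ["Node9"]}),
            "human", "mouse",
        )
        res, _ = conserved_node_overlap(["Node0"], tested, ["X1"], omap)
        assert res.k == 0 and res.p == 1.0

    def test_untested_orthologs_excluded_and_reported(self):
        tested = ["Node0", "Node1"]
        omap = OrthologMap(
            pd.DataFrame({"src_gene": ["A", "B"],
                          "dst_gene": ["Node0", "NodeMissing"]}),
            "human", "mouse",
        )
        res, untested = conserved_node_overlap(["Node0"], tested, ["A", "B"],
                                               omap)
        assert untested == {"NODEMISSING"}
        assert res.n1 == 1 and res.k == 1

    def test_shared_drivers_significant_in_both_species(self):
        """Monte-Carlo: a driver planted in both species reaches q<0.05 in both."""
        cfg = SimConfig(n_genes=600, n_nodes=6, targets_per_node=30,
                        datasets_per_node=(2, 3), background_rate=0.15,
                        n_up_genes=60, n_down_genes=30, seed=0)
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            c = cfg.replace(seed=seed)
            mouse, human, corpus, truth = two_species_consensomes(c)
            de = gen_de_table(c, truth)
            up, _ = derive_de_gene_sets(de)
            hcts_m = {n: extract_hcts(x) for n, x in mouse.items()}
            hcts_h = {n: extract_hcts(x) for n, x in human.items()}
            up_h = GeneSet("up", "human",
                           frozenset(s.upper() for s in up.symbols))
            tab_m = hct_intersection_analysis(up, hcts_m, universe=c.n_genes)
            tab_h = hct_intersection_analysis(up_h, hcts_h, universe=c.n_genes)
            (driver,) = truth.driver_nodes
            qm = tab_m.set_index("node").loc[driver, "q"]
            qh = tab_h.set_index("node").loc[driver.upper(), "q"]
            hits += (qm < 0.05) and (qh < 0.05)
        assert hits >= round(0.9 * n_seeds)
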
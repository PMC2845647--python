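"""Annotation parsing, TSS assignment, region partitioning, gene classes."""

import logging

import numpy as np
import pandas as pd
import pytest

import monodi as m
from monodi.genes import TagSet, apply_regulation_labels


GFF_HEADER = "##gff-version 3\n"


def write_gff(tmp_path, body):
    path = tmp_path / "genes.gff3"
    path.write_text(GFF_HEADER + body)
    return path


def tagset(rows):
    return TagSet(pd.DataFrame(rows, columns=["chrom", "position", "strand", "count"]))


def expression_table(gene_means, noise=None):
    """gene_means: {gene: (untreated_mean, tsa_mean)}; both replicates equal."""
    rows = []
    for g, (u, t) in gene_means.items():
        for cond, mu in (("untreated", u), ("tsa", t)):
            for rep in (1, 2):
                rows.append((g, cond, rep, mu))
    return m.ExpressionTable(pd.DataFrame(
        rows, columns=["gene_id", "condition", "replicate", "intensity"]))


class TestReadAnnotation:
    def test_cds_span_is_min_max_of_parts(self, tmp_path):
        body = ("c1\tsrc\tgene\t101\t450\t.\t+\t.\tID=g1\n"
                "c1\tsrc\tCDS\t101\t200\t.\t+\t0\tID=g1.c1;Parent=g1\n"
                "c1\tsrc\tCDS\t301\t450\t.\t+\t0\tID=g1.c2;Parent=g1\n")
        genes = m.read_annotation(write_gff(tmp_path, body))
        assert len(genes) == 1
        assert (genes[0].cds_start, genes[0].cds_end) == (100, 450)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.gff3"
        path.write_text("")
        assert m.read_annotation(path) == []

    def test_rrna_gene_flagged_for_exclusion(self, tmp_path):
        body = ("c1\tsrc\tgene\t11\t500\t.\t+\t.\tID=r1\n"
                "c1\tsrc\trRNA\t11\t500\t.\t+\t.\tID=r1.r;Parent=r1\n")
        genes = m.read_annotation(write_gff(tmp_path, body))
        assert genes[0].excluded_from_activity

    def test_malformed_line_names_line_number(self, tmp_path):
        body = "c1\tsrc\tgene\t1\tnot_a_number\t.\t+\t.\tID=g1\n"
        with pytest.raises(ValueError, match="line 2"):
            m.read_annotation(write_gff(tmp_path, body))


class TestCallTss:
    def test_exact_position_grouping_no_clustering(self):
        tags = tagset([("c1", 500, "+", 3), ("c1", 501, "+", 1)])
        table = m.call_tss(tags)
        assert table.frame["count"].tolist() == [3, 1]
        assert table.frame["position"].tolist() == [500, 501]

    def test_tier_filters_are_strict(self):
        tags = tagset([("c1", 1, "+", 1000), ("c1", 2, "+", 1001)])
        table = m.call_tss(tags)
        assert table.above(1000).frame["position"].tolist() == [2]
        assert table.tier_counts((100, 1000)) == {100: 2, 1000: 1}

    def test_min_tags_is_inclusive(self):
        tags = tagset([("c1", 1, "+", 2), ("c1", 2, "+", 1)])
        assert len(m.call_tss(tags, min_tags=2)) == 1

    def test_synthetic_tags_recover_true_tss(self, small_model):
        tags = m.simulate_tss_tags(small_model, 100_000, seed=7)
        table = m.call_tss(tags)
        hits = 0
        for g in small_model.genes:
            window = table.frame[
                (table.frame["chrom"] == g.chrom)
                & (table.frame["position"] >= g.tss - 50)
                & (table.frame["position"] <= g.tss + 50)]
            top = window.loc[window["count"].idxmax()]
            hits += int(top["position"]) == g.tss
        assert hits >= 0.95 * len(small_model.genes)


class TestAssignPrimaryTss:
    def make_gene(self, strand="+"):
        return m.Gene("g1", "c1", 5000, 7000, strand)

    def test_highest_count_wins(self):
        table = m.call_tss(tagset([("c1", 4800, "+", 40), ("c1", 4650, "+", 7)]))
        gene, = m.assign_primary_tss([self.make_gene()], table)
        assert gene.tss == 4800

    def test_tie_goes_most_upstream(self):
        table = m.call_tss(tagset([("c1", 4800, "+", 9), ("c1", 4650, "+", 9)]))
        gene, = m.assign_primary_tss([self.make_gene()], table)
        assert gene.tss == 4650

    def test_tie_goes_most_upstream_minus_strand(self):
        table = m.call_tss(tagset([("c1", 7200, "-", 9), ("c1", 7350, "-", 9)]))
        gene, = m.assign_primary_tss([self.make_gene("-")], table)
        assert gene.tss == 7350

    def test_no_candidates_leaves_unset(self):
        table = m.call_tss(tagset([("c1", 100, "+", 50), ("c1", 5500, "-", 50)]))
        gene, = m.assign_primary_tss([self.make_gene()], table)
        assert gene.tss is None


class TestPartitionRegions:
    def test_plus_strand(self):
        gene = m.Gene("g", "c1", 5100, 7000, "+", tss=5000)
        promoter, body = m.partition_regions(gene)
        assert (promoter.start, promoter.end) == (4000, 5000)
        assert (body.start, body.end) == (5100, 7000)

    def test_minus_strand_mirror(self):
        gene = m.Gene("g", "c1", 5000, 7000, "-", tss=6999)
        promoter, body = m.partition_regions(gene)
        assert (promoter.start, promoter.end) == (7000, 8000)
        assert promoter.strand == "-"

    def test_clipping_warns(self, caplog):
        gene = m.Gene("g", "c1", 500, 2000, "+", tss=400)
        with caplog.at_level(logging.WARNING):
            promoter, _ = m.partition_regions(gene)
        assert (promoter.start, promoter.end) == (0, 400)
        assert any("clipped" in r.message for r in caplog.records)

    def test_mirror_symmetry_against_flip_oracle(self):
        """Partitioning a strand-flipped gene equals flipping the partition."""
        L = 20_000
        gene = m.Gene("g", "c1", 5100, 7000, "+", tss=5000)
        flip = m.Gene("g", "c1", L - 7000, L - 5100, "-", tss=L - 5000 - 1)
        for fwd, mirrored in zip(m.partition_regions(gene),
                                 m.partition_regions(flip)):
            assert (mirrored.start, mirrored.end) == (L - fwd.end, L - fwd.start)


class TestClassifyActivity:
    def make(self, n_genes=200):
        genes = [m.Gene(f"g{i:03d}", "c1", 10, 20, "+") for i in range(n_genes)]
        means = {g.id: (100.0, float(1000 + i)) for i, g in enumerate(genes)}
        return genes, expression_table(means)

    def test_top_and_bottom_disjoint_sets(self):
        genes, expr = self.make()
        labels = m.classify_activity(expr, genes, n=50)
        active = {g for g, v in labels.items() if v == "active"}
        inactive = {g for g, v in labels.items() if v == "inactive"}
        assert len(active) == len(inactive) == 50
        assert not active & inactive

    def test_known_intensity_order(self):
        genes, expr = self.make()
        labels = m.classify_activity(expr, genes, n=50)
        assert {g for g, v in labels.items() if v == "active"} == \
            {f"g{i:03d}" for i in range(150, 200)}

    def test_rrna_excluded_even_if_highest(self):
        genes, expr = self.make()
        genes[199].excluded_from_activity = True  # the top-intensity gene
        labels = m.classify_activity(expr, genes, n=50)
        assert labels["g199"] == "other"
        assert labels["g149"] == "active"  # next eligible slides in

    def test_too_few_eligible_genes_rejected(self):
        genes, expr = self.make(60)
        with pytest.raises(ValueError):
            m.classify_activity(expr, genes, n=50)


class TestFoldChangeClasses:
    def test_inclusive_boundaries(self):
        expr = expression_table({"up": (100, 200), "down": (100, 50),
                                 "flat": (100, 100), "other": (100, 120)})
        labels = m.fold_change_classes(expr, n_constant=1, intensity_floor=0.0)
        assert labels["up"] == "up" and labels["down"] == "down"
        assert labels["flat"] == "constant"

    def test_all_flat_no_up_down(self):
        expr = expression_table({f"g{i}": (50, 50) for i in range(10)})
        labels = m.fold_change_classes(expr, n_constant=4)
        assert "up" not in labels.values() and "down" not in labels.values()

    def test_invariant_under_replicate_swap(self):
        rows = [("g1", "untreated", 1, 10.0), ("g1", "untreated", 2, 20.0),
                ("g1", "tsa", 1, 40.0), ("g1", "tsa", 2, 50.0)]
        a = m.ExpressionTable(pd.DataFrame(
            rows, columns=["gene_id", "condition", "replicate", "intensity"]))
        swapped = [(g, c, 3 - r, i) for g, c, r, i in rows]
        b = m.ExpressionTable(pd.DataFrame(
            swapped, columns=["gene_id", "condition", "replicate", "intensity"]))
        assert a.fold_changes().equals(b.fold_changes())

    def test_designed_classes_recovered_on_synthetic_table(self):
        model = m.make_genome(4, 300_000, 150, seed=11,
                              class_counts={"constant": 50, "up": 28, "down": 49},
                              n_rrna=2)
        expr = m.simulate_expression(model, seed=12)
        labels = m.fold_change_classes(expr)
        sizes = {c: sum(v == c for v in labels.values())
                 for c in ("up", "down", "constant")}
        assert abs(sizes["up"] - 28) <= 2
        assert abs(sizes["down"] - 49) <= 2
        truth = {g.gene_id: g.expr_class for g in model.genes}
        agree = sum(labels[g] == c for g, c in truth.items()
                    if c in ("up", "down", "constant"))
        assert agree >= 0.95 * 127

    def test_labels_applied_to_genes(self):
        genes = [m.Gene("a", "c", 1, 2, "+"), m.Gene("b", "c", 1, 2, "+")]
        apply_regulation_labels(genes, {"a": "up"})
        assert genes[0].regulation == "up" and genes[1].regulation == "other"


class TestExpressionTable:
    def test_positive_intensities_enforced(self):
        df = pd.DataFrame([("g", "tsa", 1, -1.0)],
                          columns=["gene_id", "condition", "replicate", "intensity"])
        with pytest.raises(ValueError):
            m.ExpressionTable(df)

    def test_missing_condition_rejected_for_fc(self):
        df = pd.DataFrame([("g", "tsa", 1, 1.0), ("g", "tsa", 2, 1.0)],
                          columns=["gene_id", "condition", "replicate", "intensity"])
        with pytest.raises(ValueError):
            m.ExpressionTable(df).fold_changes()
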
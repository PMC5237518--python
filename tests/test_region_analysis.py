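"""Feature classification, regional aggregation, Diff_D ranking and enrichment."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from evopool.region_analysis import (
    FeatureIndex,
    assign_feature_class,
    builtin_regions,
    class_enrichment,
    gene_tajima_d,
    percent_change,
    regional_summary,
)
from evopool.synthetic_data import GeneRecord


@pytest.fixture(scope="module")
def toy_genes():
    return [
        GeneRecord(
            "pc1", "2L", 10_000, 16_000, "+", "protein_coding",
            (("5'UTR", 10_000, 10_199), ("CDS", 10_200, 11_000), ("intron", 11_001, 12_000),
             ("CDS", 12_001, 15_700), ("3'UTR", 15_701, 16_000)),
        ),
        GeneRecord("nc1", "2L", 30_000, 31_000, "-", "lncRNA"),
        GeneRecord("pc2", "2L", 40_000, 43_000, "-", "protein_coding",
                   (("CDS", 40_000, 43_000),)),
    ]


class TestFeatureAssignment:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (10_500, "CDS"),
            (10_100, "5'UTR"),
            (11_500, "intron"),
            (15_800, "3'UTR"),
            (9_500, "promoter"),       # 500 bp upstream of a + gene
            (30_500, "ncRNA"),
            (20_000, "intergenic"),
            (43_500, "promoter"),      # - strand: promoter beyond the gene end
            (39_500, "intergenic"),    # - strand: upstream of start coord is NOT promoter
        ],
    )
    def test_known_positions(self, toy_genes, pos, expected):
        assert assign_feature_class("2L", pos, toy_genes) == expected

    def test_off_chromosome_errors(self, toy_genes, small_layout):
        with pytest.raises(ValueError, match="off-chromosome"):
            assign_feature_class("2L", 10**9, toy_genes, layout=small_layout[0])

    def test_matches_brute_force_lookup(self, small_layout, rng):
        """Interval-tree classification equals a direct scan over gene records."""
        layout, genes = small_layout
        index = FeatureIndex(genes)

        def brute(chrom, pos):
            hits = []
            for g in genes:
                if g.chrom != chrom:
                    continue
                if g.gene_class == "protein_coding":
                    for feat, s, e in g.substructure:
                        if s <= pos <= e:
                            hits.append(feat)
                elif g.start <= pos <= g.end:
                    hits.append("ncRNA")
                if g.strand == "+" and g.start - 1000 <= pos <= g.start - 1:
                    hits.append("promoter")
                if g.strand == "-" and g.end + 1 <= pos <= g.end + 1000:
                    hits.append("promoter")
            for feat in ("CDS", "5'UTR", "3'UTR", "intron", "promoter", "ncRNA"):
                if feat in hits:
                    return feat
            return "intergenic"

        chroms = [c for c, _ in layout.chromosomes]
        for _ in range(300):
            chrom = chroms[rng.integers(len(chroms))]
            pos = int(rng.integers(1, layout.lengths[chrom]))
            assert index.lookup(chrom, pos) == brute(chrom, pos)

    def test_partition_every_position_has_one_class(self, toy_genes):
        for pos in range(9_000, 45_000, 137):
            cls = assign_feature_class("2L", pos, toy_genes)
            assert cls in {"CDS", "5'UTR", "3'UTR", "intron", "promoter", "ncRNA", "intergenic"}


class TestRegionalSummary:
    def _windows(self, values, group="selection", line="L1", chrom="2L"):
        return pd.DataFrame(
            {
                "line": line,
                "group": group,
                "chrom": chrom,
                "start": [1 + 1000 * i for i in range(len(values))],
                "end": [1001 + 1000 * i for i in range(len(values))],
                "H": values,
            }
        )

    def test_single_window(self):
        out = regional_summary(self._windows([0.42]), [("r", "2L", 1, 10_000)], value="H")
        row = out[out.group == "selection"].iloc[0]
        assert row["mean"] == pytest.approx(0.42)
        assert row["sem"] == 0.0

    def test_region_without_windows_flagged_absent(self):
        out = regional_summary(self._windows([0.42]), [("empty", "3R", 1, 10_000)], value="H")
        assert out.iloc[0]["absent"] == True  # noqa: E712

    def test_weighted_consistency_of_disjoint_regions(self, rng):
        """Two disjoint halves recombine (weighted by window count) into the pooled mean."""
        vals = rng.uniform(0, 0.5, 40)
        win = self._windows(vals)
        whole = regional_summary(win, [("all", "2L", 1, 100_000)], value="H")
        left = regional_summary(win, [("l", "2L", 1, 20_000)], value="H")
        right = regional_summary(win, [("r", "2L", 20_001, 100_000)], value="H")
        l = left[left.group == "selection"].iloc[0]
        r = right[right.group == "selection"].iloc[0]
        pooled = (l["mean"] * l.n_windows + r["mean"] * r.n_windows) / (l.n_windows + r.n_windows)
        assert pooled == pytest.approx(whole[whole.group == "selection"].iloc[0]["mean"])

    def test_builtin_regions_cover_layout(self, small_layout):
        regions = builtin_regions(small_layout[0])
        labels = {r[0] for r in regions}
        assert any(l.startswith("chrom_") for l in labels)
        assert any(l.startswith("centromere_") for l in labels)
        assert any(l.startswith("noncentromere_") for l in labels)


class TestPercentChange:
    @pytest.mark.parametrize(
        "sel,ctl,expected",
        [(0.244, 0.166, 47), (0.231, 0.194, 19), (0.381, 0.016, 2281), (0.7, 0.7, 0)],
    )
    def test_rounded_values(self, sel, ctl, expected):
        assert round(percent_change(sel, ctl)) == expected

    def test_zero_control_flagged(self):
        assert np.isnan(percent_change(0.5, 0.0))


class TestGeneTajimaD:
    def test_diff_d_is_exact_difference(self, pooled_fixture, line_group):
        from evopool.variant_filters import parse_pooled_vcf, sites_to_frame

        sites = parse_pooled_vcf(pooled_fixture["paths"], line_group)
        frame = sites_to_frame([s for s in sites if not s.is_indel], line_group.all_lines)
        ranked = gene_tajima_d(frame, pooled_fixture["genes"], line_group, nominal_n=100)
        assert len(ranked) > 10
        np.testing.assert_allclose(ranked.Diff_D, ranked.Selection_D - ranked.Control_D)
        assert (ranked.Diff_D.values[:-1] >= ranked.Diff_D.values[1:] - 1e-12).all()

    def test_gene_without_sites_excluded(self, line_group):
        frame = pd.DataFrame({"chrom": ["2L"], "pos": [100],
                              **{f"p_{l}": [0.5] for l in line_group.all_lines}})
        genes = [GeneRecord("empty", "2L", 5_000, 6_000, "+", "protein_coding",
                            (("CDS", 5_000, 6_000),))]
        ranked = gene_tajima_d(frame, genes, line_group)
        assert ranked.empty


class TestEnrichment:
    def _ranking(self, classes):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(classes))],
                             "gene_class": classes})

    def test_background_entirely_of_class(self):
        out = class_enrichment(self._ranking(["x"] * 10), 5, "x")
        assert out["p_value"] == pytest.approx(1.0)

    def test_observed_zero(self):
        ranked = self._ranking(["a"] * 5 + ["x"] * 5)
        out = class_enrichment(ranked, 5, "x")
        assert out["observed"] == 0
        assert out["p_value"] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        """Small case agrees with exact enumeration over all C(20, 5) draws."""
        classes = ["x"] * 3 + ["y"] * 17
        order = ["x", "x", "x", "y", "y"] + ["y"] * 15
        ranked = self._ranking(order)
        out = class_enrichment(ranked, 5, "x", background_counts={"x": 5, "y": 15})
        # oracle: P(X >= 3) with M=20, K=5, draws of 5
        M, K, n, obs = 20, 5, 5, 3
        p_exact = sum(
            comb(K, k) * comb(M - K, n - k) for k in range(obs, min(K, n) + 1)
        ) / comb(M, n)
        assert out["p_value"] == pytest.approx(p_exact, rel=1e-12)

    def test_monotone_in_observed(self):
        """P is non-increasing as the observed count grows at fixed margins."""
        from scipy.stats import hypergeom

        ps = [float(hypergeom.sf(k - 1, 50, 10, 10)) for k in range(0, 11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_top_k_too_large_errors(self):
        with pytest.raises(ValueError, match="top_k"):
            class_enrichment(self._ranking(["x"] * 3), 5, "x")
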
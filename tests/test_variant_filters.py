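"""Site-filter rules, boundary behaviour, and group-wise zygosity classification."""

import numpy as np
import pytest

from evopool.variant_filters import (
    FILTER_ORDER,
    LineGroup,
    VariantSite,
    apply_site_filters,
    classify_sites_by_group,
    parse_pooled_vcf,
)

LINES = ("L1", "L2", "L3", "C1", "C2", "C3")


def make_site(chrom="2L", pos=1000, freqs=0.5, dp=100, gq=60.0, indel=False, multi=False,
              ref="A", alt="C"):
    if not isinstance(freqs, dict):
        freqs = {l: freqs for l in LINES}
    return VariantSite(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        freqs=freqs,
        depths={l: dp for l in LINES} if not isinstance(dp, dict) else dp,
        quals={l: gq for l in LINES} if not isinstance(gq, dict) else gq,
        is_indel=indel, is_multiallelic=multi,
    )


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=2L,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t""" + "\t".join(LINES) + "\n"


def write_vcf(tmp_path, body):
    path = tmp_path / "x.vcf"
    path.write_text(VCF_HEADER + body)
    return path


class TestParse:
    def test_empty_vcf_gives_empty_list(self, tmp_path, line_group):
        assert parse_pooled_vcf(write_vcf(tmp_path, ""), line_group) == []

    def test_multiallelic_retained_and_flagged(self, tmp_path, line_group):
        field = "0/1:50,50:100:60"
        body = "2L\t500\t.\tA\tC,G,T\t60\t.\t.\tGT:AD:DP:GQ\t" + "\t".join([field] * 6) + "\n"
        sites = parse_pooled_vcf(write_vcf(tmp_path, body), line_group)
        assert len(sites) == 1 and sites[0].is_multiallelic

    def test_unknown_line_id_errors(self, tmp_path):
        group = LineGroup(selection=("S1", "S2", "S3"), control=("K1", "K2", "K3"))
        field = "0/1:50,50:100:60"
        body = "2L\t500\t.\tA\tC\t60\t.\t.\tGT:AD:DP:GQ\t" + "\t".join([field] * 6) + "\n"
        with pytest.raises(ValueError, match="unknown line"):
            parse_pooled_vcf(write_vcf(tmp_path, body), group)

    def test_missing_file_errors(self, line_group):
        with pytest.raises(FileNotFoundError):
            parse_pooled_vcf("/nonexistent.vcf", line_group)


class TestFilters:
    def test_five_site_fixture_one_survivor_with_attribution(self):
        """One site per failing rule plus one clean site: exactly one survivor."""
        sites = [
            make_site(pos=1_000, multi=True),                    # multiallelic
            make_site(pos=2_000, gq=25.0),                       # quality
            make_site(pos=3_000, dp={**{l: 100 for l in LINES}, "C2": 9}),  # depth
            make_site(pos=4_005),                                # within 10 bp of the indel
            make_site(pos=4_010, indel=True, ref="AT", alt="A"),
            make_site(pos=9_000),                                # clean
        ]
        kept, removed = apply_site_filters(sites)
        assert [s.pos for s in kept] == [9_000]
        assert removed == {"multiallelic": 1, "quality": 1, "depth": 1, "indel_proximity": 1}

    @pytest.mark.parametrize("dist,survives", [(10, False), (11, True)])
    def test_indel_margin_boundary_inclusive(self, dist, survives):
        sites = [
            make_site(pos=5_000 + dist),
            make_site(pos=5_000, indel=True, ref="AT", alt="A"),
        ]
        kept, _ = apply_site_filters(sites)
        assert bool(kept) is survives

    def test_min_depth_boundary(self):
        """DP=9 in one line removes the site; DP=10 everywhere keeps it."""
        bad = make_site(pos=100, dp={**{l: 100 for l in LINES}, "L1": 9})
        good = make_site(pos=200, dp=10)
        kept, removed = apply_site_filters([bad, good])
        assert [s.pos for s in kept] == [200]
        assert removed["depth"] == 1

    def test_quality_strictly_greater_than_threshold(self):
        at_threshold = make_site(pos=100, gq=30.0)
        kept, removed = apply_site_filters([at_threshold])
        assert not kept and removed["quality"] == 1

    def test_relaxing_thresholds_never_shrinks_survivors(self, rng):
        """Monotonicity: weaker thresholds keep a superset of sites."""
        sites = []
        for k in range(200):
            sites.append(
                make_site(
                    pos=100 + 40 * k,
                    dp={l: int(d) for l, d in zip(LINES, rng.integers(5, 300, 6))},
                    gq={l: float(q) for l, q in zip(LINES, rng.uniform(10, 90, 6))},
                    indel=bool(rng.random() < 0.1),
                    multi=bool(rng.random() < 0.1),
                )
            )
        strict, _ = apply_site_filters(sites, 30, 10, 250, 10)
        loose, _ = apply_site_filters(sites, 20, 5, 400, 5)
        strict_keys = {(s.chrom, s.pos) for s in strict}
        loose_keys = {(s.chrom, s.pos) for s in loose}
        assert strict_keys <= loose_keys

    def test_survivor_set_order_independent(self, rng):
        """Shuffling the input changes attribution order, never the surviving set."""
        sites = [
            make_site(pos=100 + 40 * k, gq=float(rng.uniform(10, 60)),
                      dp=int(rng.integers(5, 300))) for k in range(100)
        ]
        kept_a, _ = apply_site_filters(list(sites))
        shuffled = list(sites)
        rng.shuffle(shuffled)
        kept_b, _ = apply_site_filters(shuffled)
        assert {(s.chrom, s.pos) for s in kept_a} == {(s.chrom, s.pos) for s in kept_b}


class TestClassification:
    def test_alternatively_fixed(self, line_group):
        site = make_site(freqs={"L1": 1.0, "L2": 1.0, "L3": 1.0, "C1": 0.0, "C2": 0.0, "C3": 0.0})
        counts = classify_sites_by_group([site], line_group)
        assert counts["alternatively_fixed"] == 1
        assert counts["polymorphic"] == 0

    def test_all_het_counted_in_both_groups(self, line_group):
        counts = classify_sites_by_group([make_site(freqs=0.5)], line_group)
        assert counts["het_all_selection"] == 1
        assert counts["het_all_control"] == 1

    def test_ten_site_fixture_exact_counts(self, line_group):
        """Hand-enumerated category memberships for a constructed 10-site table."""
        f = lambda ls, cs: {"L1": ls[0], "L2": ls[1], "L3": ls[2],
                            "C1": cs[0], "C2": cs[1], "C3": cs[2]}
        sites = [
            make_site(pos=1, freqs=f((0.5, 0.5, 0.5), (0.5, 0.5, 0.5))),  # het everywhere
            make_site(pos=2, freqs=f((0.5, 0.5, 0.5), (0.0, 0.0, 0.0))),  # het sel, fixed ctl
            make_site(pos=3, freqs=f((1.0, 1.0, 1.0), (0.0, 0.0, 0.0))),  # alternatively fixed
            make_site(pos=4, freqs=f((0.0, 0.0, 0.0), (1.0, 1.0, 1.0))),  # alternatively fixed
            make_site(pos=5, freqs=f((0.0, 0.0, 1.0), (0.5, 0.2, 0.9))),  # fixed sel, het ctl
            make_site(pos=6, freqs=f((0.5, 0.9, 0.2), (1.0, 1.0, 1.0))),  # fixed ctl, het sel
            make_site(pos=7, freqs=f((0.5, 0.0, 0.5), (0.5, 0.5, 0.5))),  # het all ctl only
            make_site(pos=8, freqs=f((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))),  # boring
            make_site(pos=9, freqs=f((0.3, 0.4, 0.6), (0.2, 0.0, 0.0))),  # het all sel
            make_site(pos=10, freqs=f((1.0, 1.0, 1.0), (1.0, 1.0, 1.0))),  # fixed same allele
        ]
        counts = classify_sites_by_group(sites, line_group)
        assert counts == {
            "polymorphic": 6,
            "het_all_selection": 4,
            "het_all_control": 3,
            "fixed_selection_het_any_control": 1,
            "fixed_control_het_any_selection": 2,
            "alternatively_fixed": 2,
        }

    def test_missing_line_errors(self, line_group):
        site = make_site()
        del site.freqs["C3"]
        with pytest.raises(ValueError, match="missing line"):
            classify_sites_by_group([site], line_group)

    def test_partition_property(self, rng, line_group):
        """Every site is either het-in-all or has a fixed line, per group."""
        for _ in range(50):
            freqs = {l: float(rng.choice([0.0, 1.0, rng.uniform(0.05, 0.95)])) for l in LINES}
            site = make_site(freqs=freqs)
            counts = classify_sites_by_group([site], line_group)
            sel_all_het = counts["het_all_selection"] == 1
            sel_has_fixed = any(freqs[l] in (0.0, 1.0) for l in line_group.selection)
            assert sel_all_het != sel_has_fixed
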
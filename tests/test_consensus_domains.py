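import numpy as np
import pytest

from aptastruct import (
    MultipleAlignment,
    annotate_structure,
    classify_columns,
    domain_stats,
    progressive_align,
    project_domains,
    segment_regions,
)
from aptastruct.consensus_domains import DomainRegion
from aptastruct.folding import BasePairSet


def _aln(rows: dict[str, str]) -> MultipleAlignment:
    return MultipleAlignment(rows=rows)


class TestClassifyColumns:
    def test_majority_letter_column(self):
        cc = classify_columns(_aln({"a": "S", "b": "S", "c": "S", "d": "H"}))
        assert cc.classes == ("consensus",)
        assert cc.consensus_letters == ("S",)
        assert cc.consensus_fractions == (0.75,)

    def test_gap_threshold_edge_counts_as_gap(self):
        cc = classify_columns(_aln({"a": "-", "b": "-", "c": "S", "d": "H"}))
        assert cc.classes == ("gap",)

    def test_nongap_when_no_majority(self):
        cc = classify_columns(_aln({"a": "S", "b": "H", "c": "L", "d": "-"}))
        assert cc.classes == ("nongap",)

    def test_gaps_stay_in_consensus_denominator(self):
        # 2 of 4 rows carry S: exactly the 50% threshold
        cc = classify_columns(_aln({"a": "S", "b": "S", "c": "H", "d": "-"}))
        assert cc.classes == ("consensus",)
        assert cc.consensus_fractions == (0.5,)

    def test_classes_are_exhaustive_and_exclusive(self, rng):
        rows = {
            f"r{i}": "".join(rng.choice(list("SHL-"), size=30)) for i in range(9)
        }
        cc = classify_columns(_aln(rows))
        assert set(cc.classes) <= {"consensus", "gap", "nongap"}
        assert len(cc.classes) == 30


class TestSegmentRegions:
    def test_runs_and_numbering(self):
        rows = {
            "a": "SSS-SS",
            "b": "SSH-HS",
            "c": "SSLSLS",
            "d": "SS-H-S",
        }
        cc = classify_columns(_aln(rows))
        regions = segment_regions(cc)
        kinds = [(r.kind, r.start, r.stop, r.index) for r in regions]
        assert kinds == [
            ("consensus", 1, 2, 1),
            ("nongap", 3, 3, 1),
            ("gap", 4, 4, 1),
            ("nongap", 5, 5, 2),
            ("consensus", 6, 6, 2),
        ]
        assert regions[0].ss_identity == "SS"
        assert regions[0].name == "domain1" and regions[2].name == "gap1"

    def test_identical_strings_single_domain(self):
        aln = _aln({"a": "SHLSH", "b": "SHLSH"})
        regions = segment_regions(classify_columns(aln))
        assert len(regions) == 1
        assert regions[0].kind == "consensus"
        assert regions[0].ss_identity == "SHLSH"

    def test_regions_tile_columns(self, rng):
        rows = {
            f"r{i}": "".join(rng.choice(list("SHLIGDM-"), size=40))
            for i in range(11)
        }
        regions = segment_regions(classify_columns(_aln(rows)))
        covered = sorted(c for r in regions for c in r.columns)
        assert covered == list(range(1, 41))


class TestDomainStats:
    def test_identical_strings_fixed_point(self):
        aln = _aln({"a": "SHLSH", "b": "SHLSH", "c": "SHLSH"})
        regions = segment_regions(classify_columns(aln))
        stats = domain_stats(aln, regions)
        assert stats.domains_per_sequence == 1.0
        assert stats.pct_ss_in_domains == 100.0
        row = stats.per_region.iloc[0]
        assert row["conserved"] == 1.0 and row["frequency"] == 1.0
        assert row["mean_length"] == 5.0 and row["sd_length"] == 0.0

    def test_membership_rule_excludes_low_matching_row(self):
        # single domain over columns 1-5; row d matches the column
        # consensus letters in only 2/5 columns (below the 50% rule)
        rows = {
            "a": "SSSSS",
            "b": "SSSSS",
            "c": "SSSSH",
            "d": "SHHHH",
        }
        aln = _aln(rows)
        cc = classify_columns(aln)
        regions = segment_regions(cc)
        assert [r.kind for r in regions] == ["consensus"]
        stats = domain_stats(aln, regions, cc)
        assert stats.membership.loc["a", "domain1"]
        assert not stats.membership.loc["d", "domain1"]
        assert stats.per_region.iloc[0]["frequency"] == 0.75
        assert stats.domains_per_sequence == 0.75

    def test_fraction_fixed_base_on_standard_coordinates(self):
        # identical 69-long strings: single all-S domain, every character
        # of columns 1..14 and 55..69 lies in the fixed segments
        s = "S" * 69
        aln = _aln({"a": s, "b": s})
        regions = segment_regions(classify_columns(aln))
        stats = domain_stats(aln, regions)
        frac = stats.per_region.iloc[0]["fraction_fixed_base"]
        assert frac == pytest.approx(29 / 69)


class TestProjectDomains:
    def test_gapless_alignment_projection_matches_columns(self):
        rows = {"a": "SSHHLL", "b": "SSHHLL"}
        aln = _aln(rows)
        regions = segment_regions(classify_columns(aln))
        proj = project_domains(aln, regions)
        assert (proj.spans["base_start"] == 1).all()
        assert (proj.spans["base_stop"] == 6).all()
        assert (proj.spans["domain_loss"] == 0).all()
        assert np.allclose(proj.inclusion.loc["domain1"], 1.0)

    def test_single_row_internal_gap(self):
        aln = _aln({"only": "S-S"})
        region = DomainRegion(kind="consensus", start=1, stop=3, index=1, ss_identity="SSS")
        proj = project_domains(aln, [region])
        rec = proj.spans.iloc[0]
        assert (rec["base_start"], rec["base_stop"]) == (1, 2)
        assert rec["domain_loss"] == 1

    def test_distance_metrics_on_constructed_rows(self):
        # two domains separated by a 2-base spacer in every row
        rows = {"a": "SSHHLSS", "b": "SSHHLSS"}
        aln = _aln(rows)
        cc = classify_columns(aln)
        regions = [
            DomainRegion(kind="consensus", start=1, stop=2, index=1, ss_identity="SS"),
            DomainRegion(kind="consensus", start=5, stop=7, index=2, ss_identity="LSS"),
        ]
        proj = project_domains(aln, regions)
        d1 = proj.distances.set_index("domain")
        assert d1.loc["domain1", "d_to_next"] == 2.0  # bases 3-4 lie between
        assert d1.loc["domain1", "d_prior"] == 0.0  # starts at base 1
        assert d1.loc["domain2", "d_next"] == 0.0  # ends at the 3' end

    def test_planted_shared_hairpin_recovered_across_seeds(self):
        # every member of a synthetic population carries the 3'-flank
        # hairpin (stem 55-59/63-67, loop 60-62); its domain must project
        # onto those bases in >= 95% of seeded runs
        hairpin = {(55, 67), (56, 66), (57, 65), (58, 64), (59, 63)}
        successes = 0
        n_runs = 6
        for seed in range(n_runs):
            rng = np.random.default_rng(1000 + seed)
            ss = {}
            for i in range(120):
                pairs = set(hairpin)
                if rng.random() < 0.7:  # random decoration in the insert
                    p = int(rng.integers(5, 35))
                    stem = int(rng.integers(3, 6))
                    loop = int(rng.integers(3, 7))
                    for k in range(stem):
                        pairs.add((p + k, p + 2 * stem + loop - 1 - k))
                ann = annotate_structure(BasePairSet(frozenset(pairs), 69))
                ss[f"p{i}"] = ann.ss_string
            aln = progressive_align(ss)
            regions = segment_regions(classify_columns(aln))
            proj = project_domains(aln, regions)
            cover = proj.inclusion.max(axis=0)
            if all(cover[p] >= 0.5 for p in range(55, 68)):
                successes += 1
        assert successes / n_runs >= 0.95
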
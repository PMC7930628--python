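import math

import numpy as np
import pytest

import paleomito as pm
from paleomito import _seq
from paleomito.calling import (
    AlleleEvidence,
    SiteCounts,
    _lod,
    apply_call_filters,
    call_site,
)
from paleomito.mapping import ReadIndex
from paleomito.vcfio import VcfParseError


def site(counts_by_allele, position=100, quals=30):
    """Build SiteCounts from {allele: (count, fwd, rev)} with constant quality."""
    alleles = {}
    dp = 0
    for allele, (count, fwd, rev) in counts_by_allele.items():
        alleles[allele] = AlleleEvidence(
            count=count, fwd=fwd, rev=rev,
            quals=np.full(count, quals, dtype=np.uint8),
            end_distances=np.full(count, 25, dtype=np.int64),
        )
        dp += count
    return SiteCounts(position=position, depth=dp, alleles=alleles)


@pytest.fixture(scope="module")
def mapped_clean(mt_ref, clean_sim):
    index = ReadIndex(mt_ref)
    alns, _ = pm.map_reads(clean_sim.reads, index)
    return alns


class TestBuildPileup:
    def test_simple_depth(self, mt_ref, mapped_clean, clean_sim):
        pileup = pm.build_pileup(mapped_clean, clean_sim.reads, mt_ref)
        counts = pileup.site_counts(100)
        assert counts.depth == sum(ev.count for ev in counts.alleles.values())

    def test_mean_depth_matches_read_oracle(self, mt_ref):
        """Pileup mean DP equals brute-force read-base counting within 2%.

        Uses a variant-free, damage-free library so that read admission
        (unique best, <2 mismatches) removes only the rare multi-error reads.
        """
        cfg = pm.SimulationConfig(
            reference=mt_ref, endogenous_coverage=50.0,
            damage=pm.DamageParams.none(), seed=19,
        )
        sim = pm.simulate_dataset(cfg)
        alns, _ = pm.map_reads(sim.reads, ReadIndex(mt_ref))
        pileup = pm.build_pileup(alns, sim.reads, mt_ref)
        expected = len(sim.reads) * 101 / mt_ref.length
        assert abs(pileup.depth_map().mean() - expected) / expected < 0.02

    def test_low_quality_bases_excluded(self, mt_ref, mapped_clean, clean_sim):
        import dataclasses

        quals = clean_sim.reads.quals.copy()
        quals[:, :] = 10  # below min_bq=20
        low = dataclasses.replace(clean_sim.reads, quals=quals)
        pileup = pm.build_pileup(mapped_clean, low, mt_ref)
        assert pileup.depth_map().sum() == 0

    def test_empty_alignments_empty_pileup(self, mt_ref, clean_sim):
        pileup = pm.build_pileup([], clean_sim.reads, mt_ref)
        assert pileup.depth_map().sum() == 0
        assert pileup.candidate_sites() == []


class TestCallSite:
    def test_strong_signal_emitted(self):
        s = site({"A": (50, 25, 25), "G": (50, 25, 25)})
        calls = call_site(s, ref_allele="A")
        assert len(calls) == 1
        c = calls[0]
        assert (c.alt_allele, c.ad, c.rd, c.dp) == ("G", 50, 50, 100)
        assert c.af == pytest.approx(0.5)
        assert c.lod > 50

    def test_zero_alt_reads_no_candidate(self):
        assert call_site(site({"A": (100, 50, 50)}), ref_allele="A") == []

    def test_lod_matches_direct_likelihood(self):
        """Two-hypothesis likelihood oracle on a 20-read toy pileup."""
        s = site({"A": (17, 9, 8), "G": (3, 2, 1)}, quals=30)
        calls = call_site(s, ref_allele="A", min_af=0.0)
        c = calls[0]
        e = 10 ** -3.0
        af = 3 / 20
        # direct evaluation base by base
        l_mix = 17 * math.log10(af * e / 3 + (1 - af) * (1 - e)) + 3 * math.log10(
            af * (1 - e) + (1 - af) * e / 3
        )
        l_err = 17 * math.log10(1 - e) + 3 * math.log10(e / 3)
        assert c.lod == pytest.approx(l_mix - l_err, abs=1e-9)

    def test_emission_floor(self):
        s = site({"A": (990, 495, 495), "G": (10, 5, 5)})
        assert call_site(s, ref_allele="A") == []  # AF 1% < 5% floor
        assert len(call_site(s, ref_allele="A", min_af=0.0)) == 1

    def test_multiallelic_site_split(self):
        s = site({"A": (60, 30, 30), "C": (20, 10, 10), "T": (20, 10, 10)})
        calls = call_site(s, ref_allele="A")
        assert [c.alt_allele for c in calls] == ["C", "T"]
        assert all(c.dp == 100 for c in calls)


class TestCallFilters:
    def test_low_af_tag(self):
        c = call_site(site({"A": (960, 480, 480), "G": (40, 20, 20)}), "A", min_af=0.0)[0]
        apply_call_filters([c], cr=0.0)
        assert "low_af" in c.filters

    def test_contamination_formula_case(self):
        # cr=0.02, AF=0.02, DP=400: af <= cr + 2*sqrt(af(1-af)/dp)
        c = pm.VariantCall(
            position=5, ref_allele="A", alt_allele="G", ad=8, rd=392, dp=400,
            af=0.02, lod=5.0, alt_fwd=4, alt_rev=4, ref_fwd=196, ref_rev=196,
            median_end_distance=25.0,
        )
        apply_call_filters([c], cr=0.02)
        assert "contamination" in c.filters

    def test_majority_allele_never_contamination(self):
        c = pm.VariantCall(
            position=5, ref_allele="A", alt_allele="G", ad=390, rd=10, dp=400,
            af=0.975, lod=500.0, alt_fwd=195, alt_rev=195, ref_fwd=5, ref_rev=5,
            median_end_distance=25.0,
        )
        apply_call_filters([c], cr=0.9)
        assert "contamination" not in c.filters

    def test_position_bias_threshold(self):
        c = pm.VariantCall(
            position=5, ref_allele="A", alt_allele="G", ad=50, rd=50, dp=100,
            af=0.5, lod=50.0, alt_fwd=25, alt_rev=25, ref_fwd=25, ref_rev=25,
            median_end_distance=2.0,
        )
        apply_call_filters([c], cr=0.0)
        assert "position_bias" in c.filters

    def test_strand_bias_requires_single_strand(self):
        one_strand = pm.VariantCall(
            position=5, ref_allele="A", alt_allele="G", ad=30, rd=70, dp=100,
            af=0.3, lod=30.0, alt_fwd=30, alt_rev=0, ref_fwd=20, ref_rev=50,
            median_end_distance=25.0,
        )
        both = pm.VariantCall(
            position=5, ref_allele="A", alt_allele="G", ad=30, rd=70, dp=100,
            af=0.3, lod=30.0, alt_fwd=29, alt_rev=1, ref_fwd=20, ref_rev=50,
            median_end_distance=25.0,
        )
        apply_call_filters([one_strand, both], cr=0.0)
        assert "strand_bias" in one_strand.filters
        assert "strand_bias" not in both.filters

    def test_pass_iff_no_tags(self):
        c = call_site(site({"A": (50, 25, 25), "G": (50, 25, 25)}), "A")[0]
        apply_call_filters([c], cr=0.0)
        assert c.is_pass and c.filter_string() == "PASS"


class TestNormalize:
    def test_snp_idempotent(self, mt_ref):
        c = pm.VariantCall(
            position=200, ref_allele=mt_ref.base(200), alt_allele="T" if mt_ref.base(200) != "T" else "G",
            ad=10, rd=0, dp=10, af=1.0, lod=10.0,
        )
        (out,) = pm.normalize_variants([c], mt_ref)
        assert (out.position, out.ref_allele, out.alt_allele) == (
            c.position, c.ref_allele, c.alt_allele,
        )

    def test_homopolymer_insertion_left_aligned_oracle(self):
        ref = pm.CircularReference("t", "GATTTTC", elongation_length=0)
        # inserting one T anywhere in the homopolymer is equivalent;
        # exhaustive-shift oracle: left-most anchored representation is pos 2
        c = pm.VariantCall(
            position=6, ref_allele="T", alt_allele="TT",
            ad=5, rd=0, dp=5, af=1.0, lod=5.0,
        )
        (out,) = pm.normalize_variants([c], ref)
        candidates = []
        for pos in range(1, 7):
            alt_seq = ref.sequence[: pos] + "T" + ref.sequence[pos:]
            if alt_seq == ref.sequence[:6] + "T" + ref.sequence[6:]:
                candidates.append(pos)
        assert out.position == min(candidates) == 2
        assert (out.ref_allele, out.alt_allele) == ("A", "AT")

    def test_trailing_base_trimmed(self):
        ref = pm.CircularReference("t", "GACGTC", elongation_length=0)
        c = pm.VariantCall(
            position=2, ref_allele="ACG", alt_allele="AG",
            ad=5, rd=0, dp=5, af=1.0, lod=5.0,
        )
        (out,) = pm.normalize_variants([c], ref)
        assert (out.position, out.ref_allele, out.alt_allele) == (2, "AC", "A")

    def test_inconsistent_ref_rejected(self, mt_ref):
        c = pm.VariantCall(
            position=10, ref_allele="NOPE", alt_allele="A",
            ad=1, rd=0, dp=1, af=1.0, lod=1.0,
        )
        with pytest.raises(ValueError, match="inconsistent ref"):
            pm.normalize_variants([c], mt_ref)


class TestVcfRoundTrip:
    def _calls(self):
        c1 = pm.VariantCall(
            position=100, ref_allele="A", alt_allele="G", ad=30, rd=70, dp=100,
            af=0.3, lod=33.25, alt_fwd=15, alt_rev=15, ref_fwd=35, ref_rev=35,
            median_end_distance=24.0, filters={"contamination"}, cr_used=0.02,
        )
        c2 = pm.VariantCall(
            position=250, ref_allele="C", alt_allele="T", ad=95, rd=5, dp=100,
            af=0.95, lod=210.5, alt_fwd=50, alt_rev=45, ref_fwd=3, ref_rev=2,
            median_end_distance=30.0, cr_used=0.02,
        )
        return [c1, c2]

    def test_write_read_lossless(self, mt_ref, tmp_path):
        path = tmp_path / "calls.vcf"
        pm.write_vcf(self._calls(), "s1", path, ref=mt_ref)
        back = pm.read_vcf(path)
        for orig, rt in zip(self._calls(), back):
            assert (rt.position, rt.ref_allele, rt.alt_allele) == (
                orig.position, orig.ref_allele, orig.alt_allele,
            )
            assert (rt.ad, rt.rd, rt.dp) == (orig.ad, orig.rd, orig.dp)
            assert rt.af == pytest.approx(orig.af, abs=1e-6)
            assert rt.filters == orig.filters
            assert (rt.alt_fwd, rt.alt_rev, rt.ref_fwd, rt.ref_rev) == (
                orig.alt_fwd, orig.alt_rev, orig.ref_fwd, orig.ref_rev,
            )

    def test_empty_call_set_valid_header_only(self, mt_ref, tmp_path):
        path = tmp_path / "empty.vcf"
        pm.write_vcf([], "s1", path, ref=mt_ref)
        assert pm.read_vcf(path) == []

    def test_external_minimal_vcf_ingested(self, tmp_path):
        path = tmp_path / "ext.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
            '##FORMAT=<ID=AF,Number=A,Type=Float,Description="af">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS\n"
            "mt\t73\t.\tA\tG\t.\tPASS\t.\tAD:DP:AF\t10,90:100:0.9\n"
            "mt\t146\t.\tT\tC\t.\t.\t.\tAD:DP:AF\t50,50:100:0.5\n"
            "mt\t310\t.\tA\tC,G\t.\tPASS\t.\tAD:DP:AF\t10,60,30:100:0.6,0.3\n"
        )
        calls = pm.read_vcf(path)
        assert len(calls) == 4  # multiallelic record split into two
        assert calls[0].af == pytest.approx(0.9)
        assert calls[2].alt_allele == "C" and calls[2].ad == 60
        assert calls[3].alt_allele == "G" and calls[3].ad == 30
        assert calls[2].dp == calls[3].dp == 100

    def test_malformed_vcf_raises(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("this is not a vcf\n")
        with pytest.raises((VcfParseError, OSError)):
            pm.read_vcf(path)
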
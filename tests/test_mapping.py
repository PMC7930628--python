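import numpy as np
import pytest

import paleomito as pm
from paleomito import _seq
from paleomito.mapping import (
    MT_TARGET,
    REASON_SHORT,
    ReadIndex,
    map_read,
)
from paleomito.simulate import SOURCE_NUMTS

from conftest import make_read


def brute_force_best(read_codes, index):
    """Exhaustive minimum-mismatch scan over all targets / strands / offsets,
    deduplicated across the elongated-tail copies (the mapper's oracle)."""
    L = index.ref.length
    best: dict[tuple, int] = {}
    for strand, codes in (("+", read_codes), ("-", _seq.revcomp(read_codes))):
        m = len(codes)
        for tid, (_, tcodes, circular) in enumerate(index.targets):
            if len(tcodes) < m:
                continue
            win = np.lib.stride_tricks.sliding_window_view(tcodes, m)
            mism = (win != codes).sum(axis=1)
            for p in np.flatnonzero(mism <= index.max_mismatch):
                canon = p % L if circular else int(p)
                key = (tid, int(canon), strand)
                if key not in best or mism[p] < best[key]:
                    best[key] = int(mism[p])
    if not best:
        return None
    mm = min(best.values())
    return mm, sorted(k for k, v in best.items() if v == mm)


class TestMapRead:
    def test_exact_read_maps_uniquely(self, mt_ref):
        index = ReadIndex(mt_ref)
        aln, reason = map_read(make_read(mt_ref, 1), index)
        assert reason is None
        assert (aln.target, aln.start, aln.mismatches, aln.mapq) == (MT_TARGET, 1, 0, 37)
        assert aln.n_best == 1

    def test_origin_spanning_read_is_one_alignment(self, mt_ref):
        index = ReadIndex(mt_ref)
        aln, _ = map_read(make_read(mt_ref, 16_540), index)
        assert aln.start == 16_540
        assert aln.mismatches == 0
        assert aln.mapq == 37

    def test_minus_strand_read(self, mt_ref):
        index = ReadIndex(mt_ref)
        aln, _ = map_read(make_read(mt_ref, 5000, strand="-"), index)
        assert (aln.start, aln.strand, aln.mismatches) == (5000, "-", 0)

    def test_two_mismatches_drop_mapq_to_25(self, mt_ref):
        index = ReadIndex(mt_ref)
        aln, _ = map_read(make_read(mt_ref, 2000, mutate_at=(40, 60)), index)
        assert aln.mismatches == 2
        assert aln.mapq == 25

    def test_zero_divergence_decoy_read_ties(self, mt_ref):
        decoys = pm.generate_numts_decoys(mt_ref, 1, 0.0, (600, 600), seed=1)
        index = ReadIndex(mt_ref, decoys)
        aln, _ = map_read(make_read(mt_ref, decoys[0].source_start + 10), index)
        assert aln.n_best >= 2
        assert aln.mapq == 0

    def test_short_read_rejected_with_reason(self, mt_ref):
        index = ReadIndex(mt_ref)
        codes, quals = make_read(mt_ref, 10, length=20)
        aln, reason = map_read((codes, quals), index)
        assert aln is None and reason == REASON_SHORT

    def test_matches_brute_force_oracle(self, toy_ref):
        """Pigeonhole seeding equals the exhaustive minimum-mismatch scan."""
        rng = np.random.default_rng(17)
        index = ReadIndex(toy_ref, pm.generate_numts_decoys(toy_ref, 2, 0.05, (300, 400), seed=3))
        for trial in range(40):
            start = int(rng.integers(1, toy_ref.length + 1))
            n_mut = int(rng.integers(0, 7))  # sometimes beyond max_mismatch
            strand = "+" if rng.random() < 0.5 else "-"
            codes, quals = make_read(
                toy_ref, start, strand=strand,
                mutate_at=tuple(rng.choice(101, size=n_mut, replace=False)),
            )
            aln, reason = map_read((codes, quals), index)
            oracle = brute_force_best(codes, index)
            if oracle is None:
                assert aln is None
            else:
                mm, placements = oracle
                assert aln.mismatches == mm
                assert aln.n_best == len(placements)


class TestDeduplicate:
    def _aln(self, i, start, end, strand="+"):
        return pm.Alignment(
            read_index=i, target=MT_TARGET, start=start, strand=strand,
            length=end - start + 1, mismatches=0, mapq=37, n_best=1,
            second_best_mismatches=None,
        )

    def _reads(self, quals):
        n = len(quals)
        return pm.simulate.ReadSet(
            seqs=np.zeros((n, 101), dtype=np.uint8),
            quals=np.tile(np.array(quals, dtype=np.uint8)[:, None], (1, 101)),
            lengths=np.full(n, 101, dtype=np.int32),
            source=np.zeros(n, dtype=np.uint8), hap=np.zeros(n, dtype=np.uint8),
            true_start=np.zeros(n, dtype=np.int32), true_strand=np.ones(n, dtype=bool),
            damage_read=np.empty(0, dtype=np.int64), damage_offset=np.empty(0, dtype=np.int32),
            damage_orig=np.empty(0, dtype=np.uint8), damage_obs=np.empty(0, dtype=np.uint8),
        )

    def test_identical_placements_keep_highest_quality(self):
        alns = [self._aln(0, 100, 200), self._aln(1, 100, 200)]
        reads = self._reads([30, 35])
        pm.deduplicate(alns, reads)
        assert [a.duplicate for a in alns] == [True, False]

    def test_same_start_different_end_both_kept(self):
        alns = [self._aln(0, 100, 200), self._aln(1, 100, 210)]
        pm.deduplicate(alns, self._reads([30, 30]))
        assert not any(a.duplicate for a in alns)

    def test_survivors_equal_distinct_tuples_oracle(self):
        rng = np.random.default_rng(23)
        alns = []
        for i in range(30):
            start = int(rng.integers(1, 4))
            strand = "+" if rng.random() < 0.5 else "-"
            alns.append(self._aln(i, start, start + 100, strand))
        pm.deduplicate(alns, self._reads([30] * 30))
        survivors = sum(not a.duplicate for a in alns)
        distinct = len({(a.target, a.start, a.end, a.strand) for a in alns})
        assert survivors == distinct


class TestFilterAmbiguous:
    def test_unique_hit_retained(self, mt_ref):
        index = ReadIndex(mt_ref)
        aln, _ = map_read(make_read(mt_ref, 300), index)
        kept, removed = pm.filter_ambiguous([aln])
        assert kept == [aln] and removed == []

    def test_decoy_tie_removed_as_numts(self, mt_ref):
        decoys = pm.generate_numts_decoys(mt_ref, 1, 0.0, (600, 600), seed=5)
        index = ReadIndex(mt_ref, decoys)
        aln, _ = map_read(make_read(mt_ref, decoys[0].source_start + 5), index)
        kept, removed = pm.filter_ambiguous([aln])
        assert kept == []
        assert removed[0][1] == "tie"

    def test_monotone_in_delta(self, mt_ref, toy_ref):
        decoys = pm.generate_numts_decoys(toy_ref, 3, 0.02, (300, 500), seed=6)
        index = ReadIndex(toy_ref, decoys)
        rng = np.random.default_rng(7)
        alns = []
        for _ in range(60):
            start = int(rng.integers(1, toy_ref.length + 1))
            codes, quals = make_read(toy_ref, start, mutate_at=tuple(rng.choice(101, 2, replace=False)))
            aln, _ = map_read((codes, quals), index)
            if aln:
                alns.append(aln)
        sizes = [len(pm.filter_ambiguous(alns, delta=d)[0]) for d in (2, 1, 0)]
        assert sizes == sorted(sizes)

    def test_no_numts_survivors_on_decoy_simulation(self, mt_ref):
        cfg = pm.SimulationConfig(
            reference=mt_ref,
            endogenous_variants=pm.random_snp_set(mt_ref, n=10, seed=8),
            endogenous_coverage=5.0,
            numts_decoys=3,
            numts_divergence=0.03,
            seed=8,
        )
        sim = pm.simulate_dataset(cfg)
        index = ReadIndex(mt_ref, sim.decoys)
        alns, _ = pm.map_reads(sim.reads, index)
        kept, _ = pm.filter_ambiguous(alns)
        sources = {int(sim.reads.source[a.read_index]) for a in kept}
        assert SOURCE_NUMTS not in sources
        assert len(kept) > 0

    def test_no_loss_without_decoys(self, mt_ref, clean_sim):
        index = ReadIndex(mt_ref)
        alns, _ = pm.map_reads(clean_sim.reads, index)
        kept, removed = pm.filter_ambiguous(alns)
        reasons = {r for _, r in removed}
        assert reasons <= {"low-mapq"}  # only the MQ gate, never ambiguity
        assert all(a.n_best == 1 for a in alns)


@pytest.fixture(scope="module")
def damaged_run(mt_ref):
    cfg = pm.SimulationConfig(
        reference=mt_ref,
        endogenous_coverage=100.0,
        damage=pm.DamageParams(delta5_max=0.3, delta3_max=0.3, decay=0.5),
        seed=21,
    )
    sim = pm.simulate_dataset(cfg)
    index = ReadIndex(mt_ref)
    alns, _ = pm.map_reads(sim.reads, index)
    alns = pm.deduplicate(alns, sim.reads)
    nondup = [a for a in alns if not a.duplicate]
    return sim, nondup


class TestDamageProfile:
    def test_recovers_delta5_within_3se(self, mt_ref, damaged_run):
        sim, alns = damaged_run
        profile = pm.estimate_damage_profile(alns, sim.reads, mt_ref)
        n = profile.n5[0]
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(profile.rate5_ct[0] - 0.3) < 3 * se
        # geometric decay visible at offset 2
        se2 = np.sqrt(0.075 * 0.925 / profile.n5[2])
        assert abs(profile.rate5_ct[2] - 0.075) < 4 * se2

    def test_strand_symmetry(self, mt_ref, damaged_run):
        sim, alns = damaged_run
        fwd = [a for a in alns if a.strand == "+"]
        rev = [a for a in alns if a.strand == "-"]
        p_fwd = pm.estimate_damage_profile(fwd, sim.reads, mt_ref)
        p_rev = pm.estimate_damage_profile(rev, sim.reads, mt_ref)
        assert p_fwd.rate5_ct[0] == pytest.approx(p_rev.rate5_ct[0], abs=0.03)

    def test_null_profile_on_undamaged_reads(self, mt_ref):
        # variant-free, damage-free library: residual rate is sequencing
        # error toward one specific base, ~e/3
        cfg = pm.SimulationConfig(
            reference=mt_ref, endogenous_coverage=30.0,
            damage=pm.DamageParams.none(), seed=22,
        )
        sim = pm.simulate_dataset(cfg)
        index = ReadIndex(mt_ref)
        alns, _ = pm.map_reads(sim.reads, index)
        profile = pm.estimate_damage_profile(alns, sim.reads, mt_ref)
        assert profile.rate5_ct[0] < 3e-3

    def test_zero_denominator_is_nan_not_zero(self, mt_ref):
        aln, _ = map_read(make_read(mt_ref, 50), ReadIndex(mt_ref))
        reads = pm.simulate.ReadSet(
            seqs=np.tile(_seq.encode(mt_ref.fetch(50, 101)), (1, 1)),
            quals=np.full((1, 101), 32, dtype=np.uint8),
            lengths=np.array([101], dtype=np.int32),
            source=np.zeros(1, dtype=np.uint8), hap=np.zeros(1, dtype=np.uint8),
            true_start=np.array([50], dtype=np.int32), true_strand=np.ones(1, dtype=bool),
            damage_read=np.empty(0, dtype=np.int64), damage_offset=np.empty(0, dtype=np.int32),
            damage_orig=np.empty(0, dtype=np.uint8), damage_obs=np.empty(0, dtype=np.uint8),
        )
        profile = pm.estimate_damage_profile([aln], reads, mt_ref)
        seg = mt_ref.fetch(50, 12)
        for i, base in enumerate(seg):
            if base != "C":
                assert np.isnan(profile.rate5_ct[i])


class TestRescaleQualities:
    def test_closed_form_value(self, mt_ref):
        # place a damaged T over a reference C at 5' offset 0 with d = 0.3
        pos = mt_ref.sequence.index("C", 100) + 1
        codes, quals = make_read(mt_ref, pos)
        codes = codes.copy()
        codes[0] = _seq.T
        aln, _ = map_read((codes, quals), ReadIndex(mt_ref))
        reads = pm.simulate.ReadSet(
            seqs=codes[None, :], quals=np.full((1, 101), 30, dtype=np.uint8),
            lengths=np.array([101], dtype=np.int32),
            source=np.zeros(1, dtype=np.uint8), hap=np.zeros(1, dtype=np.uint8),
            true_start=np.array([pos], dtype=np.int32), true_strand=np.ones(1, dtype=bool),
            damage_read=np.empty(0, dtype=np.int64), damage_offset=np.empty(0, dtype=np.int32),
            damage_orig=np.empty(0, dtype=np.uint8), damage_obs=np.empty(0, dtype=np.uint8),
        )
        profile = pm.DamageProfile(
            rate5_ct=np.array([0.3] + [0.0] * 11), rate3_ga=np.zeros(12),
            n5=np.ones(12, dtype=int), n3=np.ones(12, dtype=int),
        )
        out = pm.rescale_qualities([aln], reads, mt_ref, profile)
        # -10*log10(0.3 + 10^-3) = 5.21... -> floor 5
        assert out.quals[0, 0] == 5
        assert (out.quals[0, 1:] == 30).all()

    def test_zero_rate_leaves_quality_unchanged(self, mt_ref, clean_sim):
        index = ReadIndex(mt_ref)
        alns, _ = pm.map_reads(clean_sim.reads, index)
        profile = pm.DamageProfile(
            rate5_ct=np.zeros(12), rate3_ga=np.zeros(12),
            n5=np.ones(12, dtype=int), n3=np.ones(12, dtype=int),
        )
        out = pm.rescale_qualities(alns[:200], clean_sim.reads, mt_ref, profile)
        assert np.array_equal(out.quals, clean_sim.reads.quals)

    def test_never_raises_quality(self, mt_ref):
        cfg = pm.homoplasmic_design(mt_ref, seed=31)
        sim = pm.simulate_dataset(cfg)
        index = ReadIndex(mt_ref)
        alns, _ = pm.map_reads(sim.reads, index)
        profile = pm.estimate_damage_profile(alns, sim.reads, mt_ref)
        out = pm.rescale_qualities(alns, sim.reads, mt_ref, profile)
        assert (out.quals <= sim.reads.quals).all()


class TestSamRoundTrip:
    def test_alignments_survive_sam_round_trip(self, mt_ref, tmp_path):
        cfg = pm.SimulationConfig(
            reference=mt_ref, endogenous_coverage=1.0,
            damage=pm.DamageParams.none(), seed=41,
        )
        sim = pm.simulate_dataset(cfg)
        index = ReadIndex(mt_ref)
        alns, _ = pm.map_reads(sim.reads, index)
        p = tmp_path / "out.sam"
        pm.mapping.write_sam(alns, sim.reads, mt_ref, (), p)
        back, seqs, quals = pm.mapping.read_sam(p)
        assert len(back) == len(alns)
        for a, b in zip(alns, back):
            assert (a.target, a.start, a.strand, a.mismatches, a.mapq) == (
                b.target, b.start, b.strand, b.mismatches, b.mapq,
            )
        for a, s in zip(alns, seqs):
            assert np.array_equal(s, sim.reads.seqs[a.read_index, : a.length])
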
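"""Single-end ancient-DNA read simulation with full ground truth.

The generator emulates a gargammel-style simulation of an ancient
mitochondrial library: short fragments (default fixed 110 bp) sampled
uniformly from a circular endogenous genome at a configured fold coverage,
cytosine-deamination damage (C>T at 5' ends, G>A at 3' ends, geometrically
decaying within a 12 bp window), an undamaged present-day contaminant mixed
in at a configured rate, an optional second endogenous haplotype for
heteroplasmy designs (e.g. a 30:70 mixture), optional NumtS-like nuclear
decoy sequences, uniform sequencing errors, and single-end reads truncated
to the machine read length (default 101 bp).  Every read carries its true
origin and placement; the truth set lists the expected variant calls with
their expected allele fractions.

Defaults follow the study design this package benchmarks: endogenous
coverage 100X, fragment length fixed at 110 bp (minimum 30), read length
101 bp, per-base error 1e-3, terminal damage 0.3 decaying by 0.5 per base
over a 12 bp window, double-stranded library semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _seq
from .reference import CircularReference, Haplotype, MtVariant

SOURCE_ENDO = 0
SOURCE_CONTAMINANT = 1
SOURCE_NUMTS = 2
SOURCE_NAMES = {SOURCE_ENDO: "endogenous", SOURCE_CONTAMINANT: "contaminant", SOURCE_NUMTS: "numts"}


@dataclass
class DamageParams:
    """Terminal deamination model for a double-stranded library.

    Damage probability at offset ``i`` from the respective end is
    ``delta_max * decay**i`` for ``i < window`` and 0 beyond.  A per-position
    empirical rate table may be supplied instead via ``rate5``/``rate3``
    (arrays of length ``window``), mimicking a measured misincorporation
    profile.
    """

    delta5_max: float = 0.3
    delta3_max: float = 0.3
    decay: float = 0.5
    window: int = 12
    rate5: np.ndarray | None = None
    rate3: np.ndarray | None = None

    def __post_init__(self) -> None:
        for d in (self.delta5_max, self.delta3_max):
            if not 0.0 <= d <= 1.0:
                raise ValueError("damage probabilities must be in [0, 1]")
        if not 0.0 < self.decay <= 1.0:
            raise ValueError("decay must be in (0, 1]")

    def rates5(self) -> np.ndarray:
        if self.rate5 is not None:
            return np.asarray(self.rate5, dtype=float)
        return self.delta5_max * self.decay ** np.arange(self.window)

    def rates3(self) -> np.ndarray:
        if self.rate3 is not None:
            return np.asarray(self.rate3, dtype=float)
        return self.delta3_max * self.decay ** np.arange(self.window)

    @classmethod
    def none(cls) -> "DamageParams":
        return cls(delta5_max=0.0, delta3_max=0.0)


@dataclass
class Decoy:
    """A NumtS-like nuclear decoy: a diverged copy of a reference segment."""

    name: str
    sequence: str
    source_start: int  # 1-based start of the copied reference segment
    edits: tuple[tuple[int, str, str], ...]  # (offset, original, substituted)

    @property
    def codes(self) -> np.ndarray:
        return _seq.encode(self.sequence)


@dataclass
class SimulationConfig:
    """Study-design knobs for one simulated library."""

    reference: CircularReference
    endogenous_variants: tuple[MtVariant, ...] = ()
    endogenous_coverage: float = 100.0
    fragment_length: int = 110
    min_fragment: int = 30
    read_length: int = 101
    contamination_rate: float = 0.0
    contaminant_variants: tuple[MtVariant, ...] = ()  # default: the reference itself
    mixture: tuple[tuple[MtVariant, ...], float] | None = None  # (haplotype B, fraction)
    damage: DamageParams = field(default_factory=DamageParams)
    numts_decoys: int = 0
    numts_divergence: float = 0.03
    numts_length_range: tuple[int, int] = (500, 2000)
    numts_coverage: float = 5.0
    error_rate: float = 1e-3
    n_fill: str = "A"  # concrete base standing in for reference N placeholders
    seed: int = 0

    def __post_init__(self) -> None:
        if self.endogenous_coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0.0 <= self.contamination_rate < 1.0:
            raise ValueError("contamination_rate must be in [0, 1)")
        if self.mixture is not None:
            frac = self.mixture[1]
            if not 0.0 < frac < 1.0:
                raise ValueError("mixture fraction must be in (0, 1)")
        if self.fragment_length < self.min_fragment:
            raise ValueError("fragment_length below min_fragment")


@dataclass
class ReadSet:
    """Simulated reads as fixed-width arrays plus per-read ground truth."""

    seqs: np.ndarray  # (n, read_length) uint8 base codes; rows padded beyond length
    quals: np.ndarray  # (n, read_length) uint8 Phred scores
    lengths: np.ndarray  # (n,) int32
    source: np.ndarray  # (n,) uint8: 0 endogenous, 1 contaminant, 2 numts
    hap: np.ndarray  # (n,) uint8: endogenous haplotype index (0=A, 1=B)
    true_start: np.ndarray  # (n,) int32, 1-based on the source sequence
    true_strand: np.ndarray  # (n,) bool, True = forward
    damage_read: np.ndarray  # event arrays: read index
    damage_offset: np.ndarray  # offset within the read (sequenced orientation)
    damage_orig: np.ndarray  # original base code
    damage_obs: np.ndarray  # observed base code

    def __len__(self) -> int:
        return len(self.lengths)

    def read_seq(self, i: int) -> str:
        return _seq.decode(self.seqs[i, : self.lengths[i]])

    def read_qual(self, i: int) -> str:
        return "".join(chr(q + 33) for q in self.quals[i, : self.lengths[i]])

    def damage_events(self, i: int) -> list[tuple[int, str, str]]:
        mask = self.damage_read == i
        return [
            (int(o), _seq.BASES[a], _seq.BASES[b])
            for o, a, b in zip(
                self.damage_offset[mask], self.damage_orig[mask], self.damage_obs[mask]
            )
        ]


@dataclass
class TruthEntry:
    variant: MtVariant
    expected_af: float


@dataclass
class TruthSet:
    """Expected variant calls and per-read placements for a simulation."""

    entries: tuple[TruthEntry, ...]
    reads: ReadSet

    def positions(self) -> set[int]:
        return {e.variant.position for e in self.entries}

    def by_position(self) -> dict[int, TruthEntry]:
        return {e.variant.position: e for e in self.entries}


@dataclass
class SimulationResult:
    config: SimulationConfig
    reads: ReadSet
    truth: TruthSet
    decoys: tuple[Decoy, ...]


# ---------------------------------------------------------------------------
# Fragment sampling


def sample_fragments(
    source_codes: np.ndarray,
    coverage: float,
    fragment_length: int,
    seed: int | np.random.Generator,
    min_fragment: int = 30,
    circular: bool = True,
    length_sampler=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample fragment (starts, lengths, strands) from a source sequence.

    The fragment count is ``round(coverage * len(source) / mean_fragment_len)``;
    starts are uniform on the circle (or on valid linear starts for decoys),
    strands uniform.  ``length_sampler(rng, n)`` may draw variable lengths;
    draws below ``min_fragment`` are rejected and redrawn.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(source_codes)
    if length_sampler is None:
        mean_len = float(fragment_length)
    else:
        probe = length_sampler(np.random.default_rng(0), 4096)
        if (np.asarray(probe) < min_fragment).all():
            raise ValueError("length model produces only fragments below min_fragment")
        mean_len = float(np.mean(np.asarray(probe)[np.asarray(probe) >= min_fragment]))
    n = int(round(coverage * L / mean_len))
    if length_sampler is None:
        lengths = np.full(n, fragment_length, dtype=np.int32)
    else:
        lengths = np.empty(n, dtype=np.int32)
        filled = 0
        while filled < n:
            draw = np.asarray(length_sampler(rng, n - filled), dtype=np.int32)
            ok = draw[draw >= min_fragment]
            lengths[filled : filled + len(ok)] = ok
            filled += len(ok)
    if circular:
        starts = rng.integers(1, L + 1, size=n, dtype=np.int32)
    else:
        max_len = int(lengths.max(initial=min_fragment))
        if L < max_len:
            raise ValueError("source shorter than fragment length")
        starts = rng.integers(1, L - lengths + 2, dtype=np.int32)
    strands = rng.random(n) < 0.5
    return starts, lengths, strands


def _extract_fragments(
    source_codes: np.ndarray,
    starts: np.ndarray,
    length: int,
    strands: np.ndarray,
    circular: bool,
) -> np.ndarray:
    """Fixed-length fragment matrix in *sequenced orientation* (minus-strand rows revcomped)."""
    L = len(source_codes)
    idx = (starts[:, None] - 1 + np.arange(length)[None, :])
    if circular:
        idx %= L
    frags = source_codes[idx]
    minus = ~strands
    if minus.any():
        frags[minus] = _seq._COMP[frags[minus]][:, ::-1]
    return frags


# ---------------------------------------------------------------------------
# Damage


def _apply_damage_matrix(
    frags: np.ndarray, lengths: np.ndarray, params: DamageParams, rng: np.random.Generator
):
    """Vectorized deamination over a fragment matrix (sequenced orientation).

    Only C at 5' offsets and G at 3' offsets ever mutate.  Returns the event
    arrays (row, offset, original, observed).
    """
    n, width = frags.shape
    ev_rows: list[np.ndarray] = []
    ev_offs: list[np.ndarray] = []
    ev_orig: list[np.ndarray] = []
    r5, r3 = params.rates5(), params.rates3()
    window = min(params.window, width)
    for i in range(window):
        # 5' C>T
        mask = (frags[:, i] == _seq.C) & (lengths > i) & (rng.random(n) < r5[i])
        if mask.any():
            rows = np.flatnonzero(mask)
            frags[rows, i] = _seq.T
            ev_rows.append(rows)
            ev_offs.append(np.full(len(rows), i, dtype=np.int32))
            ev_orig.append(np.full(len(rows), _seq.C, dtype=np.uint8))
        # 3' G>A at offset i from the fragment 3' end
        cols = lengths - 1 - i
        valid = cols >= 0
        col_idx = np.where(valid, cols, 0)
        mask = valid & (frags[np.arange(n), col_idx] == _seq.G) & (rng.random(n) < r3[i])
        if mask.any():
            rows = np.flatnonzero(mask)
            frags[rows, col_idx[rows]] = _seq.A
            ev_rows.append(rows)
            ev_offs.append(col_idx[rows].astype(np.int32))
            ev_orig.append(np.full(len(rows), _seq.G, dtype=np.uint8))
    if ev_rows:
        rows = np.concatenate(ev_rows)
        offs = np.concatenate(ev_offs)
        orig = np.concatenate(ev_orig)
    else:
        rows = np.empty(0, dtype=np.int64)
        offs = np.empty(0, dtype=np.int32)
        orig = np.empty(0, dtype=np.uint8)
    obs = np.where(orig == _seq.C, _seq.T, _seq.A).astype(np.uint8)
    return rows, offs, orig, obs


def apply_damage(
    fragment: str | np.ndarray, params: DamageParams, seed: int | np.random.Generator = 0
):
    """Apply terminal deamination to one fragment; returns (damaged, events).

    ``events`` is a list of (offset, original base, observed base) in the
    fragment's own 5'->3' orientation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = _seq.encode(fragment) if isinstance(fragment, str) else fragment.copy()
    mat = codes[None, :].copy()
    rows, offs, orig, obs = _apply_damage_matrix(
        mat, np.array([len(codes)], dtype=np.int32), params, rng
    )
    events = [
        (int(o), _seq.BASES[a], _seq.BASES[b]) for o, a, b in zip(offs, orig, obs)
    ]
    damaged = mat[0]
    if isinstance(fragment, str):
        return _seq.decode(damaged), events
    return damaged, events


# ---------------------------------------------------------------------------
# Decoys


def generate_numts_decoys(
    ref: CircularReference,
    count: int,
    mean_divergence: float,
    length_range: tuple[int, int] = (500, 2000),
    seed: int | np.random.Generator = 0,
) -> tuple[Decoy, ...]:
    """Divergent copies of contiguous reference segments (NumtS-like decoys)."""
    if count == 0:
        return ()
    if not 0.0 <= mean_divergence < 0.2:
        raise ValueError("mean_divergence must be in [0, 0.2)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    decoys = []
    for k in range(count):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        start = int(rng.integers(1, ref.length + 1))
        idx = (np.arange(start - 1, start - 1 + length)) % ref.length
        codes = ref.codes[idx].copy()
        mut = np.flatnonzero(rng.random(length) < mean_divergence)
        edits = []
        for off in mut:
            orig = codes[off]
            if orig == _seq.N:
                continue
            alt = int((orig + rng.integers(1, 4)) % 4)
            codes[off] = alt
            edits.append((int(off), _seq.BASES[orig], _seq.BASES[alt]))
        decoys.append(
            Decoy(
                name=f"numts_{k}",
                sequence=_seq.decode(codes),
                source_start=start,
                edits=tuple(edits),
            )
        )
    return tuple(decoys)


# ---------------------------------------------------------------------------
# Dataset simulation


def _expected_truth(config: SimulationConfig) -> tuple[TruthEntry, ...]:
    """Expected non-reference alleles and allele fractions per variant site.

    Component weights: haplotype A = (1-cr)(1-f), haplotype B = (1-cr)f,
    contaminant = cr, where f is the mixture fraction (0 without a mixture).
    """
    cr = config.contamination_rate
    f = config.mixture[1] if config.mixture else 0.0
    comps = [
        (dict_by_pos(config.endogenous_variants), (1 - cr) * (1 - f)),
        (dict_by_pos(config.mixture[0]) if config.mixture else {}, (1 - cr) * f),
        (dict_by_pos(config.contaminant_variants), cr),
    ]
    positions = sorted({p for comp, _ in comps for p in comp})
    entries = []
    for pos in positions:
        allele_weight: dict[MtVariant, float] = {}
        for comp, w in comps:
            if w == 0.0:
                continue
            v = comp.get(pos)
            if v is not None:
                allele_weight[v] = allele_weight.get(v, 0.0) + w
        for v, w in sorted(allele_weight.items()):
            entries.append(TruthEntry(variant=v, expected_af=w))
    return tuple(entries)


def dict_by_pos(variants) -> dict[int, MtVariant]:
    return {v.position: v for v in variants}


def simulate_dataset(config: SimulationConfig) -> SimulationResult:
    """Simulate a full single-end library with ground truth.

    Endogenous fragments (both haplotypes of a mixture design) receive
    deamination damage; contaminant fragments are present-day DNA and receive
    none; NumtS decoy reads derive from the same ancient extract and are
    damaged.  Uniform sequencing errors are applied after damage; reads are
    truncated to the read length.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    ref = config.reference
    cr = config.contamination_rate

    hap_a = Haplotype(ref, tuple(config.endogenous_variants))
    seq_a = _seq.encode(hap_a.materialize(n_fill=config.n_fill))
    sources: list[tuple[np.ndarray, float, int, int, bool, bool]] = []
    # (codes, coverage, source code, hap index, circular, damaged)
    if config.mixture is not None:
        hap_b = Haplotype(ref, tuple(config.mixture[0]))
        seq_b = _seq.encode(hap_b.materialize(n_fill=config.n_fill))
        f = config.mixture[1]
        sources.append((seq_a, config.endogenous_coverage * (1 - f), SOURCE_ENDO, 0, True, True))
        sources.append((seq_b, config.endogenous_coverage * f, SOURCE_ENDO, 1, True, True))
    else:
        sources.append((seq_a, config.endogenous_coverage, SOURCE_ENDO, 0, True, True))
    if cr > 0:
        hap_c = Haplotype(ref, tuple(config.contaminant_variants))
        seq_c = _seq.encode(hap_c.materialize(n_fill=config.n_fill))
        cont_cov = config.endogenous_coverage * cr / (1 - cr)
        sources.append((seq_c, cont_cov, SOURCE_CONTAMINANT, 0, True, False))
    decoys = generate_numts_decoys(
        ref,
        config.numts_decoys,
        config.numts_divergence,
        config.numts_length_range,
        rng,
    )
    for d in decoys:
        sources.append((d.codes, config.numts_coverage, SOURCE_NUMTS, 0, False, True))

    frag_blocks = []
    for codes, cov, src, hap, circular, damaged in sources:
        starts, lengths, strands = sample_fragments(
            codes,
            cov,
            config.fragment_length,
            rng,
            min_fragment=config.min_fragment,
            circular=circular,
        )
        frags = _extract_fragments(codes, starts, config.fragment_length, strands, circular)
        if damaged:
            ev = _apply_damage_matrix(frags, lengths, config.damage, rng)
        else:
            ev = (
                np.empty(0, dtype=np.int64),
                np.empty(0, dtype=np.int32),
                np.empty(0, dtype=np.uint8),
                np.empty(0, dtype=np.uint8),
            )
        frag_blocks.append((starts, lengths, strands, frags, src, hap, ev))

    # assemble reads
    rl = config.read_length
    n_total = sum(len(b[0]) for b in frag_blocks)
    seqs = np.zeros((n_total, rl), dtype=np.uint8)
    quals = np.zeros((n_total, rl), dtype=np.uint8)
    lengths_all = np.zeros(n_total, dtype=np.int32)
    source_all = np.zeros(n_total, dtype=np.uint8)
    hap_all = np.zeros(n_total, dtype=np.uint8)
    start_all = np.zeros(n_total, dtype=np.int32)
    strand_all = np.zeros(n_total, dtype=bool)
    dmg_read, dmg_off, dmg_orig, dmg_obs = [], [], [], []
    row = 0
    for starts, lengths, strands, frags, src, hap, ev in frag_blocks:
        n = len(starts)
        read_len = np.minimum(lengths, rl)
        seqs[row : row + n, :] = frags[:, :rl]
        lengths_all[row : row + n] = read_len
        source_all[row : row + n] = src
        hap_all[row : row + n] = hap
        start_all[row : row + n] = starts
        strand_all[row : row + n] = strands
        ev_rows, ev_offs, ev_orig, ev_obs = ev
        keep = ev_offs < read_len[ev_rows]
        dmg_read.append(ev_rows[keep] + row)
        dmg_off.append(ev_offs[keep])
        dmg_orig.append(ev_orig[keep])
        dmg_obs.append(ev_obs[keep])
        row += n

    # sequencing errors (uniform substitution to one of the 3 alternatives)
    err_mask = rng.random(seqs.shape) < config.error_rate
    col_grid = np.arange(rl)[None, :]
    err_mask &= col_grid < lengths_all[:, None]
    err_mask &= seqs < 4  # never substitute padding
    if err_mask.any():
        shift = rng.integers(1, 4, size=int(err_mask.sum()))
        seqs[err_mask] = (seqs[err_mask] + shift) % 4
    # base qualities: Q30-class with upward jitter so mean read quality >= Q30
    quals[:] = rng.integers(30, 35, size=quals.shape)
    quals[col_grid >= lengths_all[:, None]] = 0

    reads = ReadSet(
        seqs=seqs,
        quals=quals,
        lengths=lengths_all,
        source=source_all,
        hap=hap_all,
        true_start=start_all,
        true_strand=strand_all,
        damage_read=np.concatenate(dmg_read) if dmg_read else np.empty(0, dtype=np.int64),
        damage_offset=np.concatenate(dmg_off) if dmg_off else np.empty(0, dtype=np.int32),
        damage_orig=np.concatenate(dmg_orig) if dmg_orig else np.empty(0, dtype=np.uint8),
        damage_obs=np.concatenate(dmg_obs) if dmg_obs else np.empty(0, dtype=np.uint8),
    )
    truth = TruthSet(entries=_expected_truth(config), reads=reads)
    return SimulationResult(config=config, reads=reads, truth=truth, decoys=decoys)


# ---------------------------------------------------------------------------
# Synthetic variant sets and IO


TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}


def random_snp_set(
    ref: CircularReference,
    n: int = 36,
    seed: int | np.random.Generator = 0,
    include_positions: tuple[int, ...] = (),
    min_spacing: int = 300,
    transition_fraction: float = 0.9,
    avoid: tuple[int, ...] = (3107,),
) -> tuple[MtVariant, ...]:
    """A synthetic SNP set standing in for a real sample's variant list.

    Positions are spread with a minimum pairwise spacing (so no 110 bp
    fragment spans two variants), optionally forcing specific positions into
    the set; alt alleles are transition-biased like real mtDNA variation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    taken: list[int] = []

    def ok(pos: int) -> bool:
        if ref.base(pos) == "N":
            return False
        if any(abs(pos - a) < min_spacing for a in avoid):
            return False
        return all(
            min(abs(pos - t), ref.length - abs(pos - t)) >= min_spacing for t in taken
        )

    for pos in include_positions:
        if not ok(pos):
            raise ValueError(f"forced position {pos} violates spacing constraints")
        taken.append(pos)
    attempts = 0
    while len(taken) < n:
        pos = int(rng.integers(1, ref.length + 1))
        if ok(pos):
            taken.append(pos)
        attempts += 1
        if attempts > 200_000:
            raise RuntimeError("could not place variants with the requested spacing")
    variants = []
    for pos in sorted(taken):
        refb = ref.base(pos)
        if rng.random() < transition_fraction:
            alt = TRANSITION_OF[refb]
        else:
            alt = rng.choice([b for b in "ACGT" if b != refb and b != TRANSITION_OF[refb]])
        variants.append(MtVariant(pos, refb, str(alt)))
    return tuple(variants)


def write_fastq(reads: ReadSet, path: str | Path) -> None:
    """Write reads as Phred+33 FASTQ; ids encode origin for convenience."""
    with open(path, "w") as fh:
        for i in range(len(reads)):
            name = (
                f"read{i:06d}|{SOURCE_NAMES[int(reads.source[i])]}"
                f"|hap{int(reads.hap[i])}|{int(reads.true_start[i])}"
                f"|{'+' if reads.true_strand[i] else '-'}"
            )
            fh.write(f"@{name}\n{reads.read_seq(i)}\n+\n{reads.read_qual(i)}\n")


def write_truth(truth: TruthSet, path: str | Path) -> None:
    """Tab-separated expected variant table: pos, ref, alt, expected_AF."""
    with open(path, "w") as fh:
        fh.write("position\tref\talt\texpected_af\n")
        for e in truth.entries:
            v = e.variant
            fh.write(f"{v.position}\t{v.ref_allele}\t{v.alt_allele}\t{e.expected_af:.6g}\n")
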
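import numpy as np
import pytest

import paleomito as pm
from paleomito import _seq


@pytest.fixture(scope="session")
def mt_ref():
    """The packaged synthetic 16,569 bp circular reference (N at 3107)."""
    return pm.packaged_reference()


@pytest.fixture(scope="session")
def locus_map():
    return pm.packaged_locus_map()


@pytest.fixture(scope="session")
def toy_ref():
    """A small random circular reference for brute-force-checkable tests."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    return pm.CircularReference("toy", seq, elongation_length=150)


@pytest.fixture(scope="session")
def clean_sim(mt_ref):
    """Damage-free, contamination-free 100X simulation with 36 SNPs."""
    cfg = pm.SimulationConfig(
        reference=mt_ref,
        endogenous_variants=pm.random_snp_set(mt_ref, n=36, seed=11),
        endogenous_coverage=100.0,
        damage=pm.DamageParams.none(),
        seed=11,
    )
    return pm.simulate_dataset(cfg)


def make_read(ref, start, length=101, strand="+", mutate_at=()):
    """An error-free read from the circle, optionally with planted mismatches."""
    seq = ref.fetch(start, length)
    codes = _seq.encode(seq)
    if strand == "-":
        codes = _seq.revcomp(codes)
    for off in mutate_at:
        codes[off] = (codes[off] + 1) % 4
    quals = np.full(length, 32, dtype=np.uint8)
    return codes, quals
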
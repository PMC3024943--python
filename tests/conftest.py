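import numpy as np
import pytest

from arraycnv import CallSet, CnvCall, GenomeMap


@pytest.fixture
def small_map() -> GenomeMap:
    """10 probes on chr1 at 100..1000, step 100."""
    return GenomeMap.from_probes(
        [(f"p{i}", "1", 100 * (i + 1), True) for i in range(10)]
    )


@pytest.fixture
def two_chrom_map() -> GenomeMap:
    """200 probes on chr1 + 100 on chr2, step 100 bp."""
    probes = [(f"p{i}", "1", 100 * (i + 1), True) for i in range(200)]
    probes += [(f"q{i}", "2", 100 * (i + 1), True) for i in range(100)]
    return GenomeMap.from_probes(probes)


def make_call(method, chrom, start, end, cn=1, sample="s1", conf=50.0, n_probes=1):
    return CnvCall(
        sample_id=sample, method=method, chromosome=chrom, start=start, end=end,
        copy_number=cn, n_probes=n_probes, confidence=conf,
    )


def make_callset(method, calls, sample="s1"):
    return CallSet(method=method, sample_id=sample, calls=calls)


def random_callset_triple(rng: np.random.Generator, gm: GenomeMap, sample="s1"):
    """Random three-method callsets over a map, for equivalence testing."""
    sets = []
    for m in ("A", "B", "C"):
        calls = []
        for _ in range(int(rng.integers(0, 5))):
            chrom = str(rng.choice(gm.chromosomes))
            sl = gm.chrom_slice(chrom)
            n = sl.stop - sl.start
            i0 = int(rng.integers(0, n))
            i1 = int(min(n - 1, i0 + rng.integers(0, 30)))
            calls.append(
                make_call(
                    m, chrom,
                    int(gm.positions[sl.start + i0]),
                    int(gm.positions[sl.start + i1]),
                    cn=int(rng.choice([0, 1, 3, 4])),
                    sample=sample,
                    n_probes=i1 - i0 + 1,
                )
            )
        sets.append(make_callset(m, calls, sample))
    return sets
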
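import numpy as np
import pytest

from cncohort.genome import GenomeBuild, make_windows
from cncohort.io import CopyNumberSegment, SegmentSet


@pytest.fixture
def small_build():
    """Two short chromosomes, one with a centromere."""
    return GenomeBuild(
        name="toy",
        chromosomes=(("c1", 1_000_000), ("c2", 800_000)),
        centromeres={"c1": (450_000, 550_000)},
    )


@pytest.fixture
def diploid_segment(small_build):
    def make(sample="S1", chrom="c1", start=0, end=1_000_000, maj=1, mino=1):
        return CopyNumberSegment(
            sample=sample, chrom=chrom, start=start, end=end,
            n_major=maj, n_minor=mino,
        )

    return make


def random_cohort(
    rng: np.random.Generator,
    build: GenomeBuild,
    n_samples: int = 5,
    max_calls: int = 50,
    max_cn: int = 8,
) -> SegmentSet:
    """Random non-overlapping allele-specific calls (no generator involved:
    independent of the simulate module)."""
    segs = []
    n_calls = int(rng.integers(1, max_calls + 1))
    for _ in range(n_calls):
        sample = f"S{int(rng.integers(1, n_samples + 1))}"
        chrom, length = build.chromosomes[int(rng.integers(len(build.chromosomes)))]
        a = int(rng.integers(0, length - 1))
        b = int(rng.integers(a + 1, min(a + length // 3 + 2, length) + 1))
        total = int(rng.integers(0, max_cn + 1))
        mino = int(rng.integers(0, total // 2 + 1))
        cand = CopyNumberSegment(
            sample=sample, chrom=chrom, start=a, end=min(b, length),
            n_major=total - mino, n_minor=mino,
        )
        if any(
            s.sample == cand.sample and s.chrom == cand.chrom
            and s.start < cand.end and cand.start < s.end
            for s in segs
        ):
            continue  # keep per-sample calls non-overlapping
        segs.append(cand)
    if not segs:
        segs.append(
            CopyNumberSegment(
                sample="S1", chrom=build.chromosomes[0][0], start=0,
                end=build.chromosomes[0][1], n_major=1, n_minor=1,
            )
        )
    return SegmentSet.from_iterable(segs)


@pytest.fixture
def random_cohort_factory(small_build):
    def make(seed, **kw):
        return random_cohort(np.random.default_rng(seed), small_build, **kw)

    return make
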
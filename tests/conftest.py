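import numpy as np
import pytest

from varsweep.feature_store import FeatureRegion, build_store
from varsweep.simulate import GenomeModel


@pytest.fixture
def toy_genome():
    return GenomeModel.toy(n_chrom=3, length=100_000)


def random_instance(seed, nv=1000, nr=500, glen=1_000_000, max_len=200,
                    chrom="chr1"):
    """One-chromosome random join instance with sorted inputs."""
    rng = np.random.default_rng(seed)
    points = np.sort(rng.integers(0, glen, nv))
    starts = np.sort(rng.integers(0, glen, nr))
    ends = starts + rng.integers(1, max_len + 1, nr)
    return {chrom: points}, {chrom: (starts, ends)}


@pytest.fixture
def store_factory(tmp_path):
    """Build a feature store in a temp dir from (chrom, start, end, value) rows."""
    counter = [0]

    def make(rows, name="feat", value_type="numeric"):
        counter[0] += 1
        regions = [FeatureRegion(chrom=c, start=s, end=e, value=v)
                   for c, s, e, v in rows]
        return build_store(regions, name=name, value_type=value_type,
                           path=tmp_path / f"{name}{counter[0]}.vasf")

    return make
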
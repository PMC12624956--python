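import numpy as np
import pytest

from trctools.genome import GeneAnnotation, GenomeLayout


@pytest.fixture
def small_layout() -> GenomeLayout:
    return GenomeLayout({"chr1": 20_000, "chr2": 15_000})


@pytest.fixture
def plus_gene() -> GeneAnnotation:
    return GeneAnnotation("gA", "chr1", 2000, 4000, "+")


@pytest.fixture
def minus_gene() -> GeneAnnotation:
    return GeneAnnotation("gB", "chr1", 6000, 8000, "-")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
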
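import numpy as np
import pytest

from pssmap import (Chromosome, CrossDesign, GeneticMap, Marker, default_marker_set,
                    simulate_cross)


@pytest.fixture
def small_map() -> GeneticMap:
    return GeneticMap([
        Chromosome("chr1", 100_000_000, 80.0),
        Chromosome("chr2", 80_000_000, 60.0),
    ])


@pytest.fixture
def small_markers(small_map) -> list[Marker]:
    return default_marker_set(small_map, 20)


@pytest.fixture
def f2_cohort(small_map, small_markers):
    design = CrossDesign(type="F2", n_offspring=40)
    return simulate_cross(design, small_map, small_markers, rng=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
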
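import numpy as np
import pytest

import beeroot as br


@pytest.fixture
def tiny_sheet() -> br.SampleSheet:
    """Two samples per lineage group plus one outgroup sample."""
    rows = (
        [(f"m{i}", "mellifera", "M") for i in range(2)]
        + [(f"c{i}", "carnica", "C") for i in range(2)]
        + [(f"o{i}", "anatoliaca", "O") for i in range(2)]
        + [(f"a{i}", "scutellata", "A") for i in range(2)]
        + [("og0", "cerana", "OUTGROUP", "cerana")]
    )
    return br.SampleSheet.from_records(rows)


@pytest.fixture
def tiny_panel(tiny_sheet) -> tuple[br.GenotypeMatrix, br.SampleSheet]:
    """9 samples x 6 loci with known classification structure.

    locus0: polymorphic everywhere; locus1: polymorphic+private in mellifera;
    locus2: fixed-private in scutellata; locus3: monomorphic ingroup, fixed
    difference vs outgroup; locus4: polymorphic in M and C only;
    locus5: has a missing call.
    """
    samples = ["m0", "m1", "c0", "c1", "o0", "o1", "a0", "a1", "og0"]
    calls = np.array(
        [
            # l0 l1 l2 l3 l4 l5
            [1, 1, 0, 0, 1, 1],   # m0
            [1, 0, 0, 0, 0, 0],   # m1
            [0, 0, 0, 0, 1, 0],   # c0
            [1, 0, 0, 0, 2, 0],   # c1
            [1, 0, 0, 0, 0, 0],   # o0
            [0, 0, 0, 0, 0, -1],  # o1
            [1, 0, 2, 0, 0, 0],   # a0
            [0, 0, 2, 0, 0, 0],   # a1
            [0, 0, 0, 2, 0, 0],   # og0
        ],
        dtype=np.int8,
    )
    g = br.GenotypeMatrix(samples, [f"l{j}" for j in range(6)], calls)
    return g, tiny_sheet


@pytest.fixture(scope="session")
def sim_panel():
    """A moderately sized simulated panel with full ground truth."""
    cfg = br.SimConfig(seed=42, n_loci=500, samples_per_subspecies=3,
                       samples_per_outgroup=1)
    return br.simulate_panel(cfg)
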
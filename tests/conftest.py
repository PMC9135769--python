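import numpy as np
import pytest

from topofold import (
    ArchitecturePlan,
    BundleSpec,
    SegmentSpec,
    build_bundle,
    perturb_ensemble,
)

MINIMAL_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
END
"""

WATER_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


@pytest.fixture
def water_pdb(tmp_path):
    path = tmp_path / "water.pdb"
    path.write_text(WATER_ONLY_PDB)
    return path


@pytest.fixture(scope="session")
def bundle():
    """Four 18-residue helices, 10 Å apart, alternating up/down."""
    return build_bundle(BundleSpec(helix_lengths=(18, 18, 18, 18)))


@pytest.fixture(scope="session")
def bundle19():
    """Four 19-residue helices; the 100 degrees/residue twist closes after 18
    steps, so helix termini all face the same azimuth and junction gaps track
    the axis spacing."""
    return build_bundle(BundleSpec(helix_lengths=(19, 19, 19, 19)))


@pytest.fixture(scope="session")
def bundle_plan():
    segs = tuple(
        SegmentSpec(label, "A", start, end)
        for label, start, end in [
            ("H1", 1, 18), ("H2", 19, 36), ("H3", 37, 54), ("H4", 55, 72)
        ]
    )
    return ArchitecturePlan(segments=segs)


@pytest.fixture(scope="session")
def small_ensemble(bundle):
    return perturb_ensemble(bundle, n_frames=5, amplitude=0.5, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
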
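import numpy as np
import pytest

from contactstates import FeatureMatrix, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_fm():
    """3 frames x 2 varying contacts; small enough to enumerate exactly."""
    return FeatureMatrix(x=np.array([[0, 0], [0, 1], [1, 1]], dtype=np.uint8),
                         pairs=[(0, 1), (0, 2)], cutoff=2.0, pruned=True)


@pytest.fixture
def two_block_fm():
    """Two clearly separated blocks of frames: 10 x (1,0) then 10 x (0,1)."""
    x = np.vstack([np.tile([1, 0], (10, 1)), np.tile([0, 1], (10, 1))])
    return FeatureMatrix(x=x.astype(np.uint8), pairs=[(0, 1), (0, 2)],
                         cutoff=2.0, pruned=True)


@pytest.fixture
def line_trajectory():
    """Two frames of 4 collinear unit-spaced points; second frame stretched
    so that some contacts vary between frames."""
    f0 = np.column_stack([np.arange(4.0), np.zeros(4)])
    f1 = np.column_stack([np.arange(4.0) * 1.4, np.zeros(4)])
    return Trajectory(coords=np.stack([f0, f1]))


def make_pdb(path, frames):
    """Write a tiny synthetic multi-model PDB of Cα atoms (test fixture)."""
    lines = []
    for m, coords in enumerate(frames, start=1):
        lines.append(f"MODEL     {m:4d}")
        for i, (x, y, z) in enumerate(coords, start=1):
            lines.append(
                f"ATOM  {i:5d}  CA  ALA A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
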
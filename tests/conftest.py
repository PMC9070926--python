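import numpy as np
import pytest

from genoprof.tiling import GenomeAxis, TileDepthMatrix


@pytest.fixture
def axis3() -> GenomeAxis:
    return GenomeAxis("chr", 300, 100)


@pytest.fixture
def small_matrix(axis3) -> TileDepthMatrix:
    depths = np.array(
        [
            [[100.0, 200.0, 300.0], [4.0, 5.0, 6.0]],
            [[110.0, 210.0, 310.0], [3.0, 6.0, 5.0]],
        ]
    )
    return TileDepthMatrix(axis3, ["libA", "libB"], depths)
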
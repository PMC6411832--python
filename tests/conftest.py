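import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests/_oracles.py

from reda import build_exon_universe, parse_annotation


TOY_GTF = "\n".join(
    [
        # gene A: two exons with one intron [1300, 3000)
        'chr1\tt\texon\t1001\t1300\t.\t+\t.\tgene_id "GA"; transcript_id "GA.1"; gene_name "A";',
        'chr1\tt\texon\t3001\t3500\t.\t+\t.\tgene_id "GA"; transcript_id "GA.1"; gene_name "A";',
        # gene B far downstream: single exon at [30000, 30400)
        'chr1\tt\texon\t30001\t30400\t.\t-\t.\tgene_id "GB"; transcript_id "GB.1"; gene_name "B";',
    ]
) + "\n"


@pytest.fixture(scope="session")
def toy_universe():
    """Two genes on chr1: intron [1300, 3000), exons at [1000, 1300),
    [3000, 3500), [30000, 30400)."""
    return build_exon_universe(parse_annotation(TOY_GTF))


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)
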
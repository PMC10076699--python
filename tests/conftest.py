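import numpy as np
import pytest

from isoswitch.synthetic import SimulationConfig, make_study_fixture

TOY_GTF = "\n".join(
    [
        'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; isoform "a";',
        'chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; isoform "a";',
        'chr1\tsrc\texon\t51\t80\t.\t+\t.\tgene_id "g1"; transcript_id "t2"; isoform "b";',
        'chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t2"; isoform "b";',
        'chr1\tsrc\texon\t701\t800\t.\t+\t.\tgene_id "g2"; transcript_id "t3";',
    ]
) + "\n"


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230)


@pytest.fixture(scope="session")
def small_fixture():
    """Error-free, shallow study used by quantification truth checks."""
    config = SimulationConfig(
        ages=(("E14", -5.0), ("P1", 1.0), ("P9", 9.0), ("P60", 60.0)),
        replicates=2,
        reads_per_sample=4000,
        error_rate=0.0,
        seed=5,
    )
    return make_study_fixture(config)
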
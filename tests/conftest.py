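import numpy as np
import pytest

from mitolav.simulate import CohortDesign
from mitolav.variants import AlleleCounts, VariantRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def study_design():
    """The reference cohort design (494/572, 43 pools of <= 25, ~378x)."""
    return CohortDesign(seed=11)


@pytest.fixture
def small_design():
    """A scaled-down cohort for fast end-to-end tests."""
    return CohortDesign(n_cases=60, n_controls=70, pool_size=10, n_pools=13,
                        median_pool_coverage=200.0, seq_error_rate=0.002,
                        seed=5)


def make_record(min_case=5, min_ctrl=3, n_cases=494, n_controls=572,
                chrom="1", pos=100, gene="GENE1",
                consequence_class="nonsynonymous", annotations=None,
                ref="A", alt="G"):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        consequence_class=consequence_class,
        counts=AlleleCounts(min_case, 2 * n_cases - min_case,
                            min_ctrl, 2 * n_controls - min_ctrl),
        annotations=dict(annotations or {}),
    )
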
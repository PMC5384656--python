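import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230407)


@pytest.fixture
def tiny_trios():
    from dnmburden.types import TrioRecord

    return [
        TrioRecord("F1", 33.9, 31.7, 33.1),
        TrioRecord("F2", 30.0, 30.0, 37.0),
        TrioRecord("F3", 41.2, 38.0, 39.1),
        TrioRecord("F4", 28.5, 27.0, 35.0),
    ]


@pytest.fixture
def mutation_factory():
    from dnmburden.types import DeNovoMutation

    def make(subject="F1", chrom="1", pos=100, consequence="missense", cadd=25.0,
             gene="GENE1", variant_class="SNV", ref="A", alt="C"):
        return DeNovoMutation(
            subject_id=subject, chrom=chrom, pos=pos, ref=ref, alt=alt,
            variant_class=variant_class, consequence=consequence,
            cadd_phred=cadd, gene=gene,
        )

    return make
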
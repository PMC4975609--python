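import pytest

from axonsens import TissueModel, bessel_prime_roots


@pytest.fixture(scope="session")
def basis():
    return bessel_prime_roots(20)


@pytest.fixture(scope="session")
def tissue():
    """Standard white-matter substrate used throughout the analyses."""
    return TissueModel(f=0.7, D_par=1.7e-9, a=4e-6, T2=0.070)
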
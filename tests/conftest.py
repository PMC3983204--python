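import numpy as np
import pytest

from pdzscan import (
    ClassificationConfig,
    PeptideAlignment,
    build_pwm,
    make_designed_pwms,
    simulate_proteome,
    simulate_variants,
)


@pytest.fixture(scope="session")
def toy_alignment():
    # hand-countable 4-peptide set: offset 0 = V/V/I/V, offset 2 = T/S/T/T
    return PeptideAlignment("toy", ["ETWV", "ESWV", "ETWI", "QTWV"])


@pytest.fixture(scope="session")
def toy_pwm(toy_alignment):
    return build_pwm(toy_alignment, pseudocount_weight=0.0)


@pytest.fixture(scope="session")
def designed_pwms():
    return make_designed_pwms(n_domains=3, seed=11)


@pytest.fixture(scope="session")
def synthetic_study():
    """Default-parameter synthetic study: proteome, variants, truth."""
    proteome, truth = simulate_proteome(seed=101)
    variants, truth = simulate_variants(proteome, truth, seed=202)
    return proteome, variants, truth


@pytest.fixture(scope="session")
def default_config():
    return ClassificationConfig()
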
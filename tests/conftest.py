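import numpy as np
import pytest

from umiont.design import UmiDesign
from umiont.simulate import (
    ErrorModel,
    ReadDepth,
    make_mixture_genome,
    mixture_spec,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def small_mixture():
    """A small two-haplotype mixture experiment shared across tests.

    20 repeat units (2 minor, 10% unit fraction), 400 bp units, 5 defining
    positions, ~10 templates per unit, ~12x read depth, V14-like errors.
    """
    spec = mixture_spec(n_total_units=20, n_minor_units=2, n_defining=5, unit_length=400)
    truth = make_mixture_genome(spec, variant_seed=7)
    model = ErrorModel.v14_hac()
    records, lineage, pool = simulate_experiment(
        truth, UmiDesign(), model, templates_per_unit=10,
        depth=ReadDepth(mean=12), seed=11,
    )
    return {
        "truth": truth,
        "model": model,
        "records": records,
        "lineage": lineage,
        "pool": pool,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
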
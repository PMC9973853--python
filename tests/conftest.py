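import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from bgcnovelty import (
    BgcRecord,
    LandscapeConfig,
    StrainSimConfig,
    build_reference,
    simulate_landscape,
    simulate_strains,
)
from bgcnovelty.gcf import DEFAULT_BUILD_THRESHOLD


def make_record(bgc_id="B001", domains=("A", "B"), strain="S0", complete=True, **kw):
    defaults = dict(
        strain_id=strain,
        bgc_id=bgc_id,
        contig_id=kw.pop("contig_id", "ctg1"),
        start_bp=kw.pop("start_bp", 0),
        end_bp=kw.pop("end_bp", 1000),
        product_class=kw.pop("product_class", "NRPS"),
        complete=complete,
        domains=tuple(domains),
    )
    defaults.update(kw)
    return BgcRecord(**defaults)


@pytest.fixture(scope="session")
def landscape():
    return simulate_landscape(LandscapeConfig(seed=7))


@pytest.fixture(scope="session")
def reference(landscape):
    return build_reference(
        landscape.records, build_threshold=DEFAULT_BUILD_THRESHOLD, vocabulary=landscape.vocabulary
    )


@pytest.fixture(scope="session")
def strain_cohort(landscape):
    return simulate_strains(landscape, StrainSimConfig(seed=11, n_strains=6))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
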
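import numpy as np
import pytest

from omicord.design import DEFAULT_DESIGN, TimeDesign
from omicord import synthetic as sy


@pytest.fixture
def design() -> TimeDesign:
    return DEFAULT_DESIGN


@pytest.fixture
def full_rna_design() -> TimeDesign:
    """8-point grid with RNA observed at every time (no failed sample)."""
    return TimeDesign(time_points=DEFAULT_DESIGN.time_points, replicates=3)


@pytest.fixture
def small_catalog() -> sy.Catalog:
    return sy.generate_catalog(60, [12, 15], seed=11)


def noiseless_spec(**kw) -> sy.ConcordanceSpec:
    base = dict(noise_sd=0.0, outlier_rate=0.0, dropout=0.0)
    base.update(kw)
    return sy.ConcordanceSpec(**base)


def all_class_spec(cls: str, **kw) -> sy.ConcordanceSpec:
    fractions = {c: 0.0 for c in sy.PAIR_CLASSES}
    fractions[cls] = 1.0
    return sy.ConcordanceSpec(fractions=fractions, **kw)
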
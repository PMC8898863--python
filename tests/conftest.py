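import dataclasses

import pytest

from hipcea import CohortSpec, GroupSpec, load_parameters


@pytest.fixture
def params():
    return load_parameters()


@pytest.fixture
def default_spec():
    return CohortSpec()


@pytest.fixture
def small_spec():
    """A fast-to-generate cohort spec away from the utility ceiling."""
    return dataclasses.replace(
        CohortSpec(),
        mtha=GroupSpec(
            n=60,
            male_fraction=0.5,
            age=(65.0, 8.0),
            preop_ohs=(20.0, 6.0),
            preop_fjs=(15.0, 10.0),
            preop_eq5d=(0.30, 0.15),
            preop_eqvas=(65.0, 15.0),
        ),
        rtha=GroupSpec(
            n=40,
            male_fraction=0.6,
            age=(60.0, 6.0),
            preop_ohs=(19.0, 6.0),
            preop_fjs=(14.0, 9.0),
            preop_eq5d=(0.40, 0.15),
            preop_eqvas=(70.0, 12.0),
        ),
        residual_sd=0.05,
        mtha_change_target=0.30,
    )
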
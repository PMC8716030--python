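import warnings

import pytest

from ocumsm.event_history import apply_eligibility_filters, to_counting_process
from ocumsm.fixture import make_study_fixture


@pytest.fixture(scope="session")
def study_cohort():
    cohort, manifest = make_study_fixture()
    return cohort, manifest


@pytest.fixture(scope="session")
def eligible(study_cohort):
    cohort, _ = study_cohort
    elig, _ = apply_eligibility_filters(cohort)
    return elig


@pytest.fixture(scope="session")
def cp_rows(eligible):
    rows, _ = to_counting_process(eligible)
    return rows


@pytest.fixture(scope="session")
def study_fits(cp_rows):
    from ocumsm.coxph import fit_cox

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {tr: fit_cox(cp_rows, tr) for tr in [(0, 1), (0, 2), (1, 2)]}
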
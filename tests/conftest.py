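import warnings
from importlib import resources

import pytest

import ethoseq as es


@pytest.fixture(scope="session")
def ethogram():
    return es.default_ethogram()


@pytest.fixture(scope="session")
def day3_matrix(ethogram):
    with resources.as_file(es.packaged_matrix_path(3)) as p:
        return es.read_transition_matrix(p, ethogram, age_days=3)


@pytest.fixture(scope="session")
def day3_fit(day3_matrix):
    return es.QuasiIndependence(day3_matrix).fit()


@pytest.fixture(scope="session")
def cohort_fits(ethogram):
    """Quasi-independence fits for all five packaged cohort matrices.

    Day 3 is the study's printed matrix; the other four are the packaged
    synthetic reconstructions.
    """
    fits = {}
    for age in es.STUDY_AGES:
        with resources.as_file(es.packaged_matrix_path(age)) as p:
            tc = es.read_transition_matrix(p, ethogram, age_days=age)
        fits[age] = es.QuasiIndependence(tc).fit()
    return fits


def make_log(records, duration=3600.0, ethogram=None, session_id="s1", age=3):
    """Build an EventLog from (subject, behavior, onset, offset) tuples."""
    recs = [
        es.EventRecord(
            session_id=session_id,
            cohort_age_days=age,
            subject_id=sub,
            behavior=beh,
            onset_s=a,
            offset_s=b,
        )
        for sub, beh, a, b in records
    ]
    return es.make_event_log(
        recs, session_duration_s=duration, ethogram=ethogram,
        session_id=session_id, cohort_age_days=age,
    )
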
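import pytest

from olvf import (
    FollowUpOutcome,
    Sex,
    SpineAssessment,
    SubjectRecord,
    VertebralLevel,
)

T = VertebralLevel


def make_subject(
    sid,
    sex=Sex.FEMALE,
    age=75.0,
    fn=-1.0,
    ls=-1.0,
    spine=None,
    fx_time=None,
    death_time=None,
    followup=5.0,
):
    return SubjectRecord(
        subject_id=str(sid),
        sex=sex,
        age_years=age,
        fn_tscore=fn,
        ls_tscore=ls,
        spine=spine if spine is not None else SpineAssessment(),
        outcome=FollowUpOutcome(
            hip_fx=fx_time is not None,
            fx_time_years=fx_time,
            death_time_years=death_time,
            followup_years=followup,
        ),
    )


def build_women_cohort():
    """1951 analysed women: 26 hip fractures within 5 years (16 within 3),
    17 fracture cases with FN T-score <= -2.7, and 92 subjects whose most
    severe deformity is collapsed grade (-3.0) of whom 7 fracture."""
    severe_spine = SpineAssessment({T.T7: -3.0})
    cohort = []
    for i in range(1951):
        fx_time = None
        if i < 26:
            fx_time = 2.0 if i < 16 else 4.0
        fn = -3.0 if i < 17 else -1.0
        spine = severe_spine if (i < 7 or 26 <= i < 111) else None
        cohort.append(
            make_subject(f"W{i:05d}", Sex.FEMALE, fn=fn, spine=spine, fx_time=fx_time)
        )
    return cohort


def build_men_cohort():
    """1882 analysed men: 23 hip fractures within 5 years (8 within 3),
    12 fracture cases with FN <= -2.1 (6 of the 8 early ones), 5 of the 8
    early cases with LS <= -2.5, and 87 subjects with most severe
    deformity -2.0 of whom 4 fracture."""
    mod_severe_spine = SpineAssessment({T.T10: -2.0})
    cohort = []
    for i in range(1882):
        fx_time = None
        if i < 23:
            fx_time = 2.0 if i < 8 else 4.0
        fn = -2.5 if (i < 6 or 8 <= i < 14) else -1.0
        ls = -3.0 if i < 5 else -1.0
        spine = mod_severe_spine if (i < 4 or 23 <= i < 106) else None
        cohort.append(
            make_subject(f"M{i:05d}", Sex.MALE, fn=fn, ls=ls, spine=spine, fx_time=fx_time)
        )
    return cohort


@pytest.fixture(scope="session")
def women_cohort():
    return build_women_cohort()


@pytest.fixture(scope="session")
def men_cohort():
    return build_men_cohort()
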
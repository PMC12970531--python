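import datetime

import pytest

from anemia_cdss import (
    AnalytePanel,
    build_guideline_ruleset,
    classify_cohort,
    default_group_specs,
    generate_cohort,
)


def panel(pid="P1", date=datetime.date(2023, 3, 1), age=60, sex="F", **labs):
    return AnalytePanel(pid, date, age, sex, **labs)


@pytest.fixture(scope="session")
def ruleset():
    return build_guideline_ruleset()


@pytest.fixture(scope="session")
def default_cohort(ruleset):
    """One synthetic cohort at the study's group sizes, with classifications."""
    records = generate_cohort(default_group_specs(), seed=20230101)
    panels = [r.panel for r in records]
    results = classify_cohort(panels, ruleset)
    return records, panels, results
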
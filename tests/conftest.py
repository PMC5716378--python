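import numpy as np
import pytest

import wntgsa as w

#: Deviation sign patterns of the six signature pathway genes, as extracted
#: from the stimulation time course the generator emulates.
PATTERN_BOOK = {
    "WNT3A": "+-++",
    "CTNNB1": "++-+",
    "APC": "-++-",
    "MYC": "-+++",
    "PORCN": "+---",
    "SFRP4": "-+++",
}


@pytest.fixture(scope="session")
def pattern_book():
    return dict(PATTERN_BOOK)


@pytest.fixture(scope="session")
def default_timecourses(pattern_book):
    return w.generate_timecourse_dataset(n_genes=71, pattern_book=pattern_book, rng_seed=0)


@pytest.fixture(scope="session")
def static_table():
    return w.generate_static_dataset(rng_seed=0)


def make_planted_interval_courses(seed, n_other=7, target_index=1):
    """Courses where gene PLNT has high influence only at one interval.

    The planted gene's deviation at the target interval sits mid-range of
    the block (mapping near the g-function kink at 0.5 where the factor has
    a huge relative effect) and at the extremes elsewhere; paired with a
    near-zero importance coefficient this makes the target interval the
    gene's dominant one.
    """
    rng = np.random.default_rng(seed)
    hours = w.DEFAULT_HOURS
    dev_p = np.array([3.0, 3.0, 3.0, -3.0])
    dev_p[target_index] = 0.0
    fc_p = np.concatenate([[0.5], 0.5 + np.cumsum(dev_p)])
    courses = [w.TimeCourse("PLNT", hours, fc_p)]
    for j in range(n_other):
        dev = rng.uniform(-3, 3, len(hours) - 1)
        fc = np.concatenate([[rng.uniform(-1, 1)], np.cumsum(dev)])
        courses.append(w.TimeCourse(f"G{j}", hours, fc))
    a = np.full(len(courses), 1.0)
    a[0] = 0.02
    return courses, a
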
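import numpy as np
import pytest

from neoreho import load_packaged_participants, participants_frame


@pytest.fixture(scope="session")
def cohort_records():
    return load_packaged_participants()


@pytest.fixture(scope="session")
def cohort_frame(cohort_records):
    return participants_frame(cohort_records)


def kendall_w_oracle(ts: np.ndarray) -> float:
    """Brute-force tie-corrected Kendall W: explicit pairwise-comparison
    mid-ranks and direct evaluation of the defining formula."""
    ts = np.asarray(ts, dtype=float)
    m, n = ts.shape
    ranks = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            less = np.sum(ts[i] < ts[i, j])
            equal = np.sum(ts[i] == ts[i, j])
            ranks[i, j] = 1 + less + (equal - 1) / 2.0
    rank_sums = ranks.sum(axis=0)
    s = np.sum((rank_sums - rank_sums.mean()) ** 2)
    tie = 0.0
    for i in range(m):
        for v in np.unique(ts[i]):
            t = np.sum(ts[i] == v)
            tie += t**3 - t
    denom = m * m * (n**3 - n) - m * tie
    if denom <= 0:
        return float("nan")
    return 12.0 * s / denom
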
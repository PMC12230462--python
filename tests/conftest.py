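import numpy as np
import pytest


def match_sparks(events, centers_um, centers_ms,
                 pos_tol_um=2.0, time_tol_ms=40.0):
    """Greedy one-to-one matching of detected events to planted sparks.

    Returns (n_matched, n_false_positive, n_missed).
    """
    used = set()
    matched = 0
    for cx, ct in zip(centers_um, centers_ms):
        cand = [
            (abs(e.center_position_um - cx) + abs(e.center_time_ms - ct) / 20.0, i)
            for i, e in enumerate(events)
            if i not in used
            and abs(e.center_position_um - cx) < pos_tol_um
            and abs(e.center_time_ms - ct) < time_tol_ms
        ]
        if cand:
            used.add(min(cand)[1])
            matched += 1
    n_truth = len(centers_um)
    return matched, len(events) - matched, n_truth - matched


@pytest.fixture
def spark_matcher():
    return match_sparks


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
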
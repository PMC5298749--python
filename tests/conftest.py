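import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def qrs_oracle(samples, buffer_n, refractory, frac):
    """Independent brute-force QRS scan: absolute first difference,
    per-buffer threshold, left-to-right marking with a refractory skip.

    Pure-Python reference kept deliberately naive; the production detector
    is checked against it sample for sample.
    """
    s = [float(v) for v in samples]
    d = [abs(s[i + 1] - s[i]) for i in range(len(s) - 1)]
    thr = []
    for w in range(0, len(d), buffer_n):
        chunk = d[w : w + buffer_n]
        m = max(chunk)
        thr.extend([frac * m if m > 0 else float("inf")] * len(chunk))
    marks = []
    i = 0
    while i < len(d):
        if d[i] > thr[i]:
            marks.append(i)
            i += refractory + 1
        else:
            i += 1
    return marks
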
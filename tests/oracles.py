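"""Independent brute-force information-theory oracles used only by tests.

Deliberately naive: dictionaries of counts and pure-Python log2 sums, no
shared code with the package's vectorized estimators.
"""

from collections import Counter
from math import log2


def entropy_oracle(states) -> float:
    counts = Counter(states)
    n = len(states)
    return -sum((c / n) * log2(c / n) for c in counts.values())


def joint_entropy_oracle(x, y) -> float:
    assert len(x) == len(y)
    counts = Counter(zip(x, y))
    n = len(x)
    return -sum((c / n) * log2(c / n) for c in counts.values())


def mi_oracle(x, y) -> float:
    """MI via the full empirical joint table: sum p(a,b) log2 p(a,b)/(p(a)p(b))."""
    n = len(x)
    px = Counter(x)
    py = Counter(y)
    pxy = Counter(zip(x, y))
    total = 0.0
    for (a, b), c in pxy.items():
        p_ab = c / n
        total += p_ab * log2(p_ab / ((px[a] / n) * (py[b] / n)))
    return total
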
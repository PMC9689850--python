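"""Independent term-by-term reference implementations of the descriptors.

Deliberately written as plain Python loops, one term at a time, with no
vectorization and no code shared with the package, so they can serve as
an independent oracle for the production implementations.
"""

import math


def std_oracle(x, y):
    n = len(x)
    u = [(x[i] - y[i]) / math.sqrt(2) for i in range(n)]
    v = [(x[i] + y[i]) / math.sqrt(2) for i in range(n)]

    def pop_std(vals):
        m = sum(vals) / len(vals)
        return math.sqrt(sum((t - m) ** 2 for t in vals) / len(vals))

    s1, s2 = pop_std(u), pop_std(v)
    return s1, s2, math.pi * s1 * s2


def sav_oracle(x, y):
    total = 0.0
    for i in range(len(x) - 1):
        na = math.hypot(x[i], y[i])
        nb = math.hypot(x[i + 1], y[i + 1])
        if na == 0.0 or nb == 0.0:
            continue
        total += (x[i] * x[i + 1] + y[i] * y[i + 1]) / (na * nb)
    return total


def sshd_oracle(x, y):
    return sum(abs(x[i] - y[i]) / math.sqrt(2) for i in range(len(x)))


def sta_oracle(x, y):
    total = 0.0
    for i in range(len(x) - 2):
        det = (
            x[i] * (y[i + 1] - y[i + 2])
            - x[i + 1] * (y[i] - y[i + 2])
            + x[i + 2] * (y[i] - y[i + 1])
        )
        total += 0.5 * abs(det)
    return total


def ctm_oracle(x, y, rho):
    radii = [math.hypot(x[i], y[i]) for i in range(len(x))]
    r = rho * max(radii)
    return sum(1 for t in radii if t <= r) / len(radii)


def sdc_oracle(x, y):
    return sum(math.hypot(x[i], y[i]) for i in range(len(x)))


def ssvl_oracle(x, y):
    return sum(
        math.hypot(x[i + 1] - x[i], y[i + 1] - y[i]) for i in range(len(x) - 1)
    )


def scc_oracle(x, y):
    cx = [(x[i] + x[i + 1] + x[i + 2]) / 3 for i in range(len(x) - 2)]
    cy = [(y[i] + y[i + 1] + y[i + 2]) / 3 for i in range(len(y) - 2)]
    return sum(
        math.hypot(cx[i + 1] - cx[i], cy[i + 1] - cy[i]) for i in range(len(cx) - 1)
    )
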
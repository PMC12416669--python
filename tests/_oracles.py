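"""Independently coded brute-force references for the statistical core.

These deliberately re-derive every quantity from first principles (plain
Python floats, no shared helpers with the package) so that agreement with
the implementation is evidence, not tautology.
"""

from __future__ import annotations

import math


def ror_oracle(a: float, b: float, c: float, d: float):
    """(ror, lo, hi) of the log-Wald 95% interval, or None with a zero cell."""
    if min(a, b, c, d) <= 0:
        return None
    point = a * d / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = 1.959963984540054
    return (point,
            math.exp(math.log(point) - z * se),
            math.exp(math.log(point) + z * se))


def bcpnn_moment_oracle(a: int, b: int, c: int, d: int,
                        gamma11: float = 1.0, alpha1: float = 1.0,
                        beta1: float = 1.0, alpha: float = 2.0,
                        beta: float = 2.0):
    """(e_ic, ic025) under the classical moment expansion of the BCPNN."""
    n = a + b + c + d
    gamma = gamma11 * (n + alpha) * (n + beta) / ((a + b + alpha1) * (a + c + beta1))
    e_ic = math.log((a + gamma11) * (n + alpha) * (n + beta)
                    / ((n + gamma) * (a + b + alpha1) * (a + c + beta1)), 2)
    v = (1.0 / math.log(2.0)) ** 2 * (
        (n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma))
        + (n - a - b + alpha - alpha1) / ((a + b + alpha1) * (1 + n + alpha))
        + (n - a - c + beta - beta1) / ((a + c + beta1) * (1 + n + beta)))
    return e_ic, e_ic - 2.0 * math.sqrt(v)


def dedup_oracle(records: list[tuple[int, int | None, int | None]]) -> set[int]:
    """Brute-force (fda_dt, primaryid)-max per caseid.

    records: (primaryid, caseid, fda_dt); missing fda_dt sorts oldest;
    missing caseid is its own singleton group.
    """
    groups: dict[object, list[tuple[int, int]]] = {}
    kept: set[int] = set()
    for i, (pid, cid, dt) in enumerate(records):
        key = ("singleton", i) if cid is None else cid
        groups.setdefault(key, []).append((-1 if dt is None else dt, pid))
    for members in groups.values():
        kept.add(max(members)[1])
    return kept
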
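"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's solver path: plain interval
bisection on the conservation balances, and the closed-form quadratic
isotherm, provide ground truth to compare against.
"""

from __future__ import annotations

import math


def bisect_root(f, lo: float, hi: float, iters: int = 200) -> float:
    """Plain interval bisection; assumes f(lo) <= 0 <= f(hi)."""
    flo = f(lo)
    if flo == 0.0:
        return lo
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) <= 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def two_site_bisection(kdo: float, kda: float, et: float, lt: float) -> dict[str, float]:
    """Four-state two-site equilibrium via bisection on the free-ligand balance."""
    if lt == 0.0:
        return {"e0": et, "e1": 0.0, "e2": 0.0, "e3": 0.0, "free_ligand": 0.0}

    def g(L: float) -> float:
        return L + et * L / (kdo + L) + et * L / (kda + L) - lt

    L = bisect_root(g, 0.0, lt)
    fo = L / (kdo + L)
    fa = L / (kda + L)
    return {
        "e0": et * (1 - fo) * (1 - fa),
        "e1": et * fo * (1 - fa),
        "e2": et * (1 - fo) * fa,
        "e3": et * fo * fa,
        "free_ligand": L,
    }


def quadratic_bound_fraction(kd: float, et: float, lt: float) -> float:
    """Closed-form single-site bound fraction Eb/Et."""
    b = et + lt + kd
    eb = (b - math.sqrt(b * b - 4.0 * et * lt)) / 2.0
    return eb / et


def competition_nested_bisection(
    et: float, rt: float, ct: float, kdr: float, kdc: float
) -> tuple[float, float]:
    """One-site two-ligand competition by nested bisection on free ligands.

    Returns (bound reporter, bound competitor) concentrations.  Outer
    bisection runs over free competitor C; for each C the free reporter R
    is found by inner bisection of the reporter balance, with free enzyme
    E0 = Et / (1 + R/KdR + C/KdC).
    """

    def e0_of(R: float, C: float) -> float:
        return et / (1.0 + R / kdr + C / kdc)

    def reporter_balance(R: float, C: float) -> float:
        return R + e0_of(R, C) * R / kdr - rt

    def free_reporter(C: float) -> float:
        if rt == 0.0:
            return 0.0
        return bisect_root(lambda R: reporter_balance(R, C), 0.0, rt)

    def competitor_balance(C: float) -> float:
        R = free_reporter(C)
        return C + e0_of(R, C) * C / kdc - ct

    C = 0.0 if ct == 0.0 else bisect_root(competitor_balance, 0.0, ct)
    R = free_reporter(C)
    e0 = e0_of(R, C)
    return e0 * R / kdr, e0 * C / kdc
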
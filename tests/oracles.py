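"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library code paths they verify: the
polynomial oracle solves the normal equations exactly in rational
arithmetic, the fusion oracle does exhaustive set-removal suppression,
and the crossing oracle is a plain double loop over pixels.
"""
from __future__ import annotations

import math
from fractions import Fraction


def exact_polyfit(xs, ys, degree):
    """Least-squares polynomial coefficients via exact normal equations.

    Floats are exactly representable as Fractions, so building and
    solving V'V c = V'y in rational arithmetic gives the exact
    least-squares solution (ascending coefficient order).
    """
    xs = [Fraction(float(x)) for x in xs]
    ys = [Fraction(float(y)) for y in ys]
    m = degree + 1
    A = [[sum(x ** (i + j) for x in xs) for j in range(m)] for i in range(m)]
    b = [sum(y * x**i for x, y in zip(xs, ys)) for i in range(m)]
    # Gaussian elimination with partial pivoting over the rationals
    for col in range(m):
        pivot = max(range(col, m), key=lambda r: abs(A[r][col]))
        if A[pivot][col] == 0:
            raise ZeroDivisionError("singular normal equations")
        A[col], A[pivot] = A[pivot], A[col]
        b[col], b[pivot] = b[pivot], b[col]
        for r in range(col + 1, m):
            f = A[r][col] / A[col][col]
            for c in range(col, m):
                A[r][c] -= f * A[col][c]
            b[r] -= f * b[col]
    coeffs = [Fraction(0)] * m
    for r in range(m - 1, -1, -1):
        s = b[r] - sum(A[r][c] * coeffs[c] for c in range(r + 1, m))
        coeffs[r] = s / A[r][r]
    return [float(c) for c in coeffs]


def ols_line(points):
    """Closed-form OLS slope/intercept of y on x (rational arithmetic)."""
    xs = [Fraction(float(x)) for x, _ in points]
    ys = [Fraction(float(y)) for _, y in points]
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    slope = sxy / sxx
    return float(slope), float(my - slope * mx)


def exhaustive_fusion(candidates, radius):
    """Confidence-ordered suppression by repeated global-max selection.

    ``candidates`` are (x, y, cls, confidence, channel) tuples; returns
    the set of surviving (x, y, cls, confidence) tuples. Same tie rules
    as the implementation (confidence desc, channel, x, y) but realised
    by removing suppressed points from the pool instead of checking new
    points against the kept list.
    """
    pool = sorted(candidates, key=lambda c: (-c[3], c[4], c[0], c[1]))
    kept = []
    while pool:
        best = pool.pop(0)
        kept.append(best)
        pool = [
            c
            for c in pool
            if not (c[2] == best[2] and math.hypot(c[0] - best[0], c[1] - best[1]) < radius)
        ]
    return {(x, y, cls, conf) for x, y, cls, conf, _ in kept}


def exhaustive_crossing(pixels, outline, curve_fn, support, tol):
    """Plain double-loop version of the single-curve crossing test."""
    lo, hi = support
    for x, y in outline:
        if lo <= x <= hi and abs(y - curve_fn(x)) <= tol:
            return True
    columns = {}
    for x, y in pixels:
        lo_y, hi_y = columns.get(x, (y, y))
        columns[x] = (min(lo_y, y), max(hi_y, y))
    for x, (y_min, y_max) in columns.items():
        if lo <= x <= hi and y_min < curve_fn(x) < y_max:
            return True
    return False
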
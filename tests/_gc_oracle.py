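"""Independent symbolic solver for the single-delay causal model.

Solves the closed-form moment equations with sympy (exact rationals where
possible), sharing no code with the production estimator: the non-causal
coefficient from the autocovariance ratio, the causal pair (a2, b) from
the 2x2 linear system, the noise variances, and the log variance ratio.
"""

from __future__ import annotations

import sympy as sp

_Rxx0, _Rxxl, _Ryy0, _Rxy0, _Rxyl = sp.symbols(
    "Rxx0 Rxxl Ryy0 Rxy0 Rxyl", real=True)
_a2, _b = sp.symbols("a2 b", real=True)

_solution = sp.solve(
    [sp.Eq(_Rxx0, _a2 * _Rxxl + _b * _Rxyl),
     sp.Eq(_Rxxl, _a2 * _Rxx0 + _b * _Rxy0)],
    [_a2, _b], dict=True)[0]

_a1_expr = _Rxx0 / _Rxxl
_sigma1_expr = (1 - _a1_expr ** 2) * _Rxx0
_sigma2_expr = sp.simplify(
    (1 - _solution[_a2] ** 2) * _Rxx0 - _solution[_b] ** 2 * _Ryy0
    - 2 * _solution[_a2] * _solution[_b] * _Rxy0)


def solve_moment_equations(Rxx0, Rxxl, Ryy0, Rxy0, Rxyl):
    """Returns (a1, a2, b, sigma1_sq, sigma2_sq, gc) from the moment
    equations; gc is None when the variance ratio is non-positive."""
    subs = {_Rxx0: sp.Float(Rxx0, 30), _Rxxl: sp.Float(Rxxl, 30),
            _Ryy0: sp.Float(Ryy0, 30), _Rxy0: sp.Float(Rxy0, 30),
            _Rxyl: sp.Float(Rxyl, 30)}
    a1 = float(_a1_expr.subs(subs))
    a2 = float(_solution[_a2].subs(subs))
    b = float(_solution[_b].subs(subs))
    s1 = float(_sigma1_expr.subs(subs))
    s2 = float(_sigma2_expr.subs(subs))
    gc = None
    if s2 != 0 and s1 / s2 > 0:
        gc = float(sp.log(sp.Float(s1, 30) / sp.Float(s2, 30)))
    return a1, a2, b, s1, s2, gc
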
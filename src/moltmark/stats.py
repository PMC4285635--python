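"""Two-sample pooled-variance Student's t with incomplete-beta p-values.

The two-sided p-value is evaluated through the regularized incomplete beta
function: for t with df degrees of freedom,
``p = I_{df/(df + t^2)}(df/2, 1/2)``, which is exact for all (also odd)
degrees of freedom.  A zero pooled variance with a nonzero mean difference
yields the sentinel (t = +/-inf, p = 0) with a degeneracy flag; two
identical constant groups yield (t = 0, p = 1).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special

__all__ = ["pooled_t", "t_sf_two_sided"]


def t_sf_two_sided(t: float, df: float) -> float:
    """Two-sided tail probability of Student's t via the incomplete beta."""
    if math.isinf(t):
        return 0.0
    if df <= 0:
        raise ValueError("df must be positive")
    x = df / (df + t * t)
    return float(special.betainc(df / 2.0, 0.5, x))


def pooled_t(group_a, group_b) -> tuple[float, float, int, bool]:
    """Pooled-variance Student's t of group_a minus group_b.

    Returns ``(t, p, df, degenerate)`` with df = n_a + n_b - 2 and a
    two-sided p-value.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError(f"each group needs >=2 values, got {na} and {nb}")
    df = na + nb - 2
    diff = float(a.mean() - b.mean())
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if diff == 0:
            return 0.0, 1.0, df, False
        return math.copysign(math.inf, diff), 0.0, df, True
    t = diff / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return float(t), t_sf_two_sided(t, df), df, False
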
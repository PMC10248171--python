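"""PAC endpoints of the rule-learnability argument.

Learning a complete rule set for mutation detection can only ever be
probably approximately correct: with m training samples, the probability
that the learned hypothesis errs more than epsilon is at most

    P[error > eps] <= 4 * exp(-eps * m / 4)

so driving this failure probability below a confidence level delta requires

    m >= (4 / eps) * log(4 / delta)        (natural log)

samples.  These two quantities — the failure-probability bound and the
ceiled sample-complexity bound — are implemented here.  The surrounding
learnability proof (the region-splitting device and the r-term-DNF
hardness reduction) is theory and is documented, not implemented.
"""

from __future__ import annotations

import math
from itertools import product

import pandas as pd

from .cohort_sim import ValidationError

__all__ = ["failure_bound", "sample_complexity", "pac_table"]


def _validate(eps: float | None = None, delta: float | None = None,
              m: int | None = None) -> None:
    if eps is not None and not 0.0 < eps < 1.0:
        raise ValidationError("eps must be in (0, 1)")
    if delta is not None and not 0.0 < delta < 1.0:
        raise ValidationError("delta must be in (0, 1)")
    if m is not None and (int(m) != m or m < 1):
        raise ValidationError("m must be a positive integer")


def failure_bound(eps: float, m: int) -> float:
    """Upper bound 4 * exp(-eps * m / 4) on P[generalization error > eps].

    Lies in (0, 4] and decreases strictly in both arguments.
    """
    _validate(eps=eps, m=m)
    return 4.0 * math.exp(-eps * m / 4.0)


def sample_complexity(eps: float, delta: float) -> int:
    """Minimal integer m with failure_bound(eps, m) <= delta.

    ceil((4 / eps) * ln(4 / delta)); the natural logarithm is forced by the
    e-based exponential in the failure bound.
    """
    _validate(eps=eps, delta=delta)
    return math.ceil(4.0 / eps * math.log(4.0 / delta))


def pac_table(eps_values=(0.01, 0.05, 0.1, 0.2),
              delta_values=(0.01, 0.05, 0.1)) -> pd.DataFrame:
    """Sample-complexity table over an (eps, delta) grid."""
    rows = [{"eps": e, "delta": d, "m": sample_complexity(e, d),
             "failure_bound_at_m": failure_bound(e, sample_complexity(e, d))}
            for e, d in product(eps_values, delta_values)]
    return pd.DataFrame(rows)
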
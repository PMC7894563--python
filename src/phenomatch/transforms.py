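"""Link functions and date conventions shared across models.

Diet proportions are mapped to the real line with an offset logit,
``ln((p + 0.01) / (1 - p + 0.01))``, which stays finite at the boundary
proportions 0 and 1 that regurgitate samples frequently produce.  Dates are
integer ordinal days (days after January 1st, with January 1st = 0), so the
calendar never enters any model matrix.
"""

from __future__ import annotations

import datetime

import numpy as np

#: Offset added to numerator and denominator of the logit of a proportion.
LOGIT_OFFSET = 0.01


def logit_offset(p):
    """Offset-logit transform of a proportion.

    Parameters
    ----------
    p : float or array-like
        Proportion(s) in [0, 1].

    Returns
    -------
    float or ndarray
        ``ln((p + 0.01) / (1 - p + 0.01))``; finite on the closed unit
        interval, strictly increasing, antisymmetric about ``p = 0.5``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("proportions must be finite and within [0, 1]")
    out = np.log((p + LOGIT_OFFSET) / (1.0 - p + LOGIT_OFFSET))
    return out if out.ndim else float(out)


def inv_logit_offset(y):
    """Inverse of :func:`logit_offset`, clipped to [0, 1].

    Solving ``y = ln((p + c) / (1 - p + c))`` for ``p`` gives
    ``p = ((1 + c) e^y - c) / (1 + e^y)``.  Values of ``y`` beyond the
    images of 0 and 1 map to the boundary.
    """
    y = np.asarray(y, dtype=float)
    c = LOGIT_OFFSET
    ey = np.exp(y)
    p = ((1.0 + c) * ey - c) / (1.0 + ey)
    p = np.clip(p, 0.0, 1.0)
    return p if p.ndim else float(p)


def to_ordinal_day(date: datetime.date) -> int:
    """Days elapsed since January 1st of the same year (Jan 1 = 0)."""
    return (date - datetime.date(date.year, 1, 1)).days


def from_ordinal_day(year: int, day: int) -> datetime.date:
    """Calendar date for an ordinal day within ``year`` (Jan 1 = 0)."""
    return datetime.date(year, 1, 1) + datetime.timedelta(days=int(day))
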
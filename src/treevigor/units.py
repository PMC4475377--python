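"""Unit conventions and the single conversion helpers used package-wide.

Diameters are stored in centimetres in census files, annual growth rates
(AGR) are in millimetres per year, and the species maximum-diameter trait
(DBH95) is in metres.  Every cross-unit comparison in the package goes
through the helpers below so that each conversion is applied exactly once.
"""

from __future__ import annotations

import numpy as np

CM_PER_M = 100.0
MM_PER_CM = 10.0


def m_to_cm(x):
    """Metres -> centimetres (DBH95 trait against census diameters)."""
    return np.asarray(x, dtype=float) * CM_PER_M


def cm_to_mm(x):
    """Centimetres -> millimetres (diameter increments to AGR)."""
    return np.asarray(x, dtype=float) * MM_PER_CM


def annualized_increment_mm(dbh_prev_cm, dbh_next_cm, interval_years):
    """Annualized diameter increment in mm/yr over one census interval.

    AGR = 10 * (D_t - D_{t-1}) / dt with diameters in cm.  May be negative
    for field shrinkage; clamping is the caller's responsibility.
    """
    if interval_years <= 0:
        raise ValueError("interval_years must be positive")
    d0 = np.asarray(dbh_prev_cm, dtype=float)
    d1 = np.asarray(dbh_next_cm, dtype=float)
    return cm_to_mm(d1 - d0) / float(interval_years)
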
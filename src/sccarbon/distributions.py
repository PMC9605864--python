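"""Two-piece (split) normal / lognormal quantile transforms.

The scenario generator anchors each headline variable at printed 5/50/95
quantiles.  A split normal — one standard deviation below the median, a
different one above — passes through all three anchors exactly, which a
single normal cannot do when the printed range is asymmetric.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtri

#: z-score of the 95th percentile of the standard normal.
Z95 = float(ndtri(0.95))


class AnchorOrderError(ValueError):
    """Raised when a (q05, q50, q95) anchor triple is not ordered."""


def check_anchors(name: str, q05: float, q50: float, q95: float) -> None:
    if not (q05 <= q50 <= q95):
        raise AnchorOrderError(
            f"quantile anchors for {name!r} must satisfy q05 <= q50 <= q95, "
            f"got ({q05}, {q50}, {q95})"
        )


def split_normal_from_z(z, q05: float, q50: float, q95: float):
    """Map standard-normal draws ``z`` through the split normal with the
    given quantile anchors.  Median, 5% and 95% points are matched exactly;
    degenerate anchors (q05 == q50 == q95) give a point mass."""
    z = np.asarray(z, dtype=float)
    sigma_lo = (q50 - q05) / Z95
    sigma_hi = (q95 - q50) / Z95
    return q50 + np.where(z < 0.0, sigma_lo, sigma_hi) * z


def split_lognormal_from_z(z, q05: float, q50: float, q95: float):
    """Split lognormal: the split normal applied on the log scale.
    All anchors must be positive."""
    if min(q05, q50, q95) <= 0:
        raise ValueError("split lognormal requires positive anchors")
    return np.exp(
        split_normal_from_z(z, np.log(q05), np.log(q50), np.log(q95))
    )
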
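"""Contour-to-contour relationship (CCR) and connectedness models.

The CCR model bounds two pairwise features — minimum surface distance (mm)
and directional fractional volume overlap — between configured pairs of
organs.  Training values of the distance feature are fit to a gamma
distribution (support [0, inf)), overlap values to a beta distribution
(support [0, 1]); the acceptance interval is the central 99% of the fitted
distribution, expanded by a clinical-tolerance margin (2 mm for distance,
0.02 for overlap) and clipped to the feature's domain.  A pair is flagged
when its observed feature value falls outside the interval; both member
contours of a flagged pair are reported, since the model detects an
improper *relationship*, not which contour caused it.

The connectedness model bounds the number of 26-connected parts of a
contour.  Some organs are legitimately multi-part (thyroid lobes, brachial
plexus truncated by the scan), so the maximum allowed count is the 99.95%
quantile of a gamma distribution fitted to training counts (or the common
value when all training counts agree).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import CcrBound

BODY_LABEL = "body"

#: expansion margins applied to the fitted percentile bounds
DISTANCE_EXPANSION_MM = 2.0
OVERLAP_EXPANSION = 0.02
#: strictly positive floor used so zero distances admit a gamma fit
DISTANCE_ZERO_CLIP_MM = 0.01
OVERLAP_EPS = 1e-4


@dataclass
class CcrMatrix:
    """Boolean selection of which (selected, comparison) pairs to evaluate.

    Rows are selected OAR types, columns are comparison OAR types plus the
    special ``"body"`` column.  Only pairs marked true are trained and
    scored.
    """

    pairs: set = field(default_factory=set)

    @classmethod
    def from_pairs(cls, pairs) -> "CcrMatrix":
        m = cls()
        for sel, comp in pairs:
            m.add(sel, comp)
        return m

    def add(self, selected: str, comparison: str) -> None:
        if selected == comparison:
            raise ValueError("a contour is not compared with itself")
        self.pairs.add((selected, comparison))

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.pairs

    def __iter__(self):
        return iter(sorted(self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def pairs_for(self, oar_type: str):
        """All evaluated pairs that involve ``oar_type`` on either side."""
        return [p for p in sorted(self.pairs) if oar_type in p]

    def to_frame(self) -> pd.DataFrame:
        """0/1 matrix with labelled rows (selected) and columns (comparison)."""
        selected = sorted({s for s, _ in self.pairs})
        comparison = sorted({c for _, c in self.pairs})
        df = pd.DataFrame(0, index=selected, columns=comparison, dtype=int)
        for s, c in self.pairs:
            df.loc[s, c] = 1
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CcrMatrix":
        m = cls()
        for s in df.index:
            for c in df.columns:
                if df.loc[s, c]:
                    m.add(str(s), str(c))
        return m


@dataclass
class PartsThreshold:
    """Maximum allowed number of disconnected parts for one OAR type."""

    oar_type: str
    max_parts: int
    gamma_params: tuple | None = None  # (k, theta) when fitted

    def __post_init__(self) -> None:
        if self.max_parts < 1:
            raise ValueError("max_parts must be >= 1")


def fit_ccr_bounds(samples, feature: str, selected_oar: str = "",
                   comparison_oar: str = "", percentile: float = 0.99,
                   expansion: float | None = None) -> CcrBound:
    """Fit the acceptance interval for one pair feature from training values.

    ``feature`` is ``"min_distance"`` or ``"fractional_overlap"``.  Bounds
    are the ``(1-p)/2`` and ``1-(1-p)/2`` quantiles of the fitted gamma /
    beta distribution, widened by the expansion margin and clipped to the
    domain ([0, inf) or [0, 1]).  An (almost) constant sample — e.g. all
    distances zero for anatomically touching organs — yields degenerate
    point-mass bounds ``value +/- expansion``.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 1:
        raise ValueError("no training samples")
    if feature == "min_distance":
        default_exp, domain = DISTANCE_EXPANSION_MM, (0.0, np.inf)
    elif feature == "fractional_overlap":
        default_exp, domain = OVERLAP_EXPANSION, (0.0, 1.0)
    else:
        raise ValueError(f"unknown CCR feature {feature!r}")
    exp = default_exp if expansion is None else expansion
    lo_q, hi_q = (1.0 - percentile) / 2.0, 1.0 - (1.0 - percentile) / 2.0

    if np.ptp(x) < 1e-9:
        v = float(x[0])
        lower, upper = v - exp, v + exp
        params, degenerate = None, True
    elif feature == "min_distance":
        clipped = np.clip(x, DISTANCE_ZERO_CLIP_MM, None)
        k, _, theta = sps.gamma.fit(clipped, floc=0.0)
        lower = float(sps.gamma.ppf(lo_q, k, scale=theta)) - exp
        upper = float(sps.gamma.ppf(hi_q, k, scale=theta)) + exp
        params, degenerate = (float(k), float(theta)), False
    else:
        clipped = np.clip(x, OVERLAP_EPS, 1.0 - OVERLAP_EPS)
        a, b, _, _ = sps.beta.fit(clipped, floc=0.0, fscale=1.0)
        lower = float(sps.beta.ppf(lo_q, a, b)) - exp
        upper = float(sps.beta.ppf(hi_q, a, b)) + exp
        params, degenerate = (float(a), float(b)), False

    lower = max(lower, domain[0])
    upper = min(upper, domain[1])
    return CcrBound(selected_oar=selected_oar, comparison_oar=comparison_oar,
                    feature=feature, lower=lower, upper=upper,
                    dist_params=params, degenerate=degenerate)


def ccr_classify(value: float, bound: CcrBound) -> bool:
    """True when the pair feature lies outside the acceptance interval."""
    return bool(value < bound.lower or value > bound.upper)


def fit_parts_threshold(counts, oar_type: str = "") -> PartsThreshold:
    """Maximum allowable disconnected parts from training part counts.

    All-equal counts give that value directly; otherwise a gamma
    distribution is fitted by maximum likelihood and the threshold is the
    ceiling of its 99.95% quantile.
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or np.any(c < 1):
        raise ValueError("part counts must be >= 1")
    if np.ptp(c) == 0:
        return PartsThreshold(oar_type=oar_type, max_parts=int(c[0]))
    k, _, theta = sps.gamma.fit(c, floc=0.0)
    q = sps.gamma.ppf(0.9995, k, scale=theta)
    return PartsThreshold(oar_type=oar_type,
                          max_parts=int(np.ceil(q)),
                          gamma_params=(float(k), float(theta)))


def connectedness_classify(parts_count: int, threshold: PartsThreshold) -> bool:
    """True when the contour has more parts than the fitted maximum."""
    return bool(parts_count > threshold.max_parts)


def bounds_table(bounds) -> pd.DataFrame:
    """Flat table of fitted CCR bounds for reporting/export."""
    rows = []
    for b in bounds:
        p = b.dist_params or (np.nan, np.nan)
        rows.append({
            "selected": b.selected_oar, "comparison": b.comparison_oar,
            "feature": b.feature, "lower": b.lower, "upper": b.upper,
            "k_or_alpha": p[0], "theta_or_beta": p[1],
        })
    return pd.DataFrame(rows, columns=["selected", "comparison", "feature",
                                       "lower", "upper", "k_or_alpha",
                                       "theta_or_beta"])
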
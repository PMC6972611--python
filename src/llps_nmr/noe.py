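"""Interproton distances from NOESY cross-peak intensities (r^-6 calibration).

In the initial-rate regime the NOESY cross-peak intensity between two protons
scales with their separation as d^-6.  A single cross peak of known geometry
therefore calibrates all others:

    d_HH = (I_ref / I_HH)^(1/6) * d_ref

For ibuprofen in the dense liquid phase the fixed intramolecular distance
between the alpha-methyl protons (a) and the isopropyl methine proton (c),
2.456 angstrom, serves as the reference, using the (a*)-(c*) cross-peak
intensity as I_ref.  Intermolecular contributions to the reference peak are
suppressed by the same d^-6 weighting and are neglected.

Cross peaks fade out beyond roughly 5 angstrom; distances above that ceiling
are flagged (not removed) since they sit outside the reliable NOE window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: fixed intramolecular (a)-(c) proton distance of ibuprofen, angstrom
D_REF_DEFAULT = 2.456
#: approximate ceiling of NOE detectability, angstrom
NOE_CEILING_ANGSTROM = 5.0

__all__ = ["NoePeakSet", "noe_distance", "noe_distance_table",
           "noe_intensity_from_distances", "D_REF_DEFAULT",
           "NOE_CEILING_ANGSTROM"]


@dataclass
class NoePeakSet:
    """NOESY cross-peak intensities keyed by proton-pair label.

    ``reference_pair`` names the pair of known (intramolecular) geometry whose
    intensity calibrates the rest; it must be present in ``intensities``.
    """

    intensities: dict = field(default_factory=dict)   # pair label -> a.u.
    reference_pair: str = "a*-c*"
    d_ref: float = D_REF_DEFAULT                      # angstrom

    def __post_init__(self) -> None:
        if self.d_ref <= 0:
            raise ValueError("d_ref must be > 0")
        for pair, I in self.intensities.items():
            if I <= 0:
                raise ValueError(f"intensity of pair {pair!r} must be > 0, got {I}")

    @property
    def I_ref(self) -> float:
        try:
            return self.intensities[self.reference_pair]
        except KeyError:
            raise ValueError(
                f"reference pair {self.reference_pair!r} missing from peak set"
            ) from None


def noe_distance(I_hh, I_ref, d_ref):
    """Interproton distance (angstrom) from one cross peak and the reference.

    d = (I_ref / I_hh)^(1/6) * d_ref; strictly decreasing in I_hh.  Accepts
    scalars or arrays; all inputs must be > 0.
    """
    I_hh = np.asarray(I_hh, dtype=float)
    if np.any(I_hh <= 0) or np.any(np.asarray(I_ref) <= 0) or d_ref <= 0:
        raise ValueError("intensities and d_ref must be > 0")
    out = (I_ref / I_hh) ** (1.0 / 6.0) * d_ref
    return out if out.ndim else float(out)


def noe_distance_table(peaks: NoePeakSet) -> pd.DataFrame:
    """Distances for every non-reference cross peak in a set.

    Returns a tidy frame with columns ``pair``, ``distance_angstrom`` and
    ``flag_gt_5A`` (True where the distance exceeds the ~5 angstrom NOE
    detection ceiling and should be treated as qualitative only).
    """
    I_ref = peaks.I_ref  # raises if the reference pair is missing
    rows = []
    for pair, I in peaks.intensities.items():
        if pair == peaks.reference_pair:
            continue
        d = noe_distance(I, I_ref, peaks.d_ref)
        rows.append({"pair": pair, "distance_angstrom": d,
                     "flag_gt_5A": d > NOE_CEILING_ANGSTROM})
    return pd.DataFrame(rows, columns=["pair", "distance_angstrom", "flag_gt_5A"])


def noe_intensity_from_distances(distances, d_ref, I_ref):
    """Forward model: total cross-peak intensity from contributing distances.

    In the initial-rate regime the contributions of several interproton
    contacts to one cross peak add, each scaling as d^-6:

        I = I_ref * sum_i (d_ref / d_i)^6

    so the shortest contact dominates.  Single-distance input is the exact
    inverse of :func:`noe_distance`.
    """
    d = np.atleast_1d(np.asarray(distances, dtype=float))
    if d.size == 0:
        raise ValueError("need at least one distance")
    if np.any(d <= 0) or d_ref <= 0 or I_ref <= 0:
        raise ValueError("distances, d_ref and I_ref must be > 0")
    return float(I_ref * np.sum((d_ref / d) ** 6))
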
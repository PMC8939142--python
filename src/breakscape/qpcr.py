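"""qPCR standard curves, absolute quantification and TDMD stoichiometry.

A ten-fold dilution series of known input copies gives a standard curve
Ct = intercept + slope * log10(copies); an ideal doubling chemistry has
slope -log2(10) ~ -3.3219 and amplification efficiency
E = 10^(-1/slope) - 1 = 1.  Unknowns are inverted through the curve to
copies per reaction and divided by cells per reaction.  TDMD stoichiometry
then compares lncRNA decay-site copies with microRNA copies
(sites:miR ratio) and, after silencing, miR copies gained per lncRNA copy
lost (turnover per molecule).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

IDEAL_SLOPE = -math.log2(10.0)  # Ct per log10(copies) at efficiency 1


@dataclass(frozen=True)
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass(frozen=True)
class StoichiometryReport:
    norad_copies_per_cell: float
    mir_copies_per_cell: float
    sites_per_norad: int
    site_to_mir_ratio: float
    turnover_per_norad: Optional[float] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def fit_standard_curve(
    copies: Sequence[float], ct: Sequence[float], replicate_mean: bool = True
) -> StandardCurve:
    """Least-squares line Ct = intercept + slope * log10(copies).

    Replicate Ct values at the same input copy number are averaged on the
    Ct scale before fitting when ``replicate_mean`` is set.
    """
    copies = np.asarray(copies, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if copies.shape != ct.shape:
        raise ValueError("copies and ct must have the same length")
    if (copies <= 0).any():
        raise ValueError("input copy numbers must be positive")
    x = np.log10(copies)
    y = ct
    if replicate_mean:
        ux = np.unique(x)
        y = np.array([y[x == v].mean() for v in ux])
        x = ux
    if x.size < 3:
        raise ValueError(f"need >= 3 dilution points, got {x.size}")
    fit = stats.linregress(x, y)
    curve = StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )
    if curve.slope >= 0:
        raise ValueError(
            f"standard curve slope must be negative, got {curve.slope:.3f}"
        )
    if not (0.8 < curve.efficiency <= 1.1):
        log.warning("assay efficiency %.3f outside the usual (0.8, 1.1] range",
                    curve.efficiency)
    return curve


def copies_from_ct(curve: StandardCurve, ct: float, cells_per_reaction: float = 1.0) -> float:
    """Invert the standard curve: copies per cell for a measured Ct."""
    if cells_per_reaction <= 0:
        raise ValueError("cells_per_reaction must be positive")
    copies = 10.0 ** ((ct - curve.intercept) / curve.slope)
    return copies / cells_per_reaction


def tdmd_site_ratio(
    norad_copies_per_cell: float,
    mir_copies_per_cell: float,
    sites_per_norad: int = 2,
) -> float:
    """(lncRNA copies x TDMD sites per molecule) : miR copies."""
    if mir_copies_per_cell <= 0:
        raise ValueError("miR copy number must be positive")
    if norad_copies_per_cell < 0 or sites_per_norad < 0:
        raise ValueError("copy numbers and site counts must be non-negative")
    return norad_copies_per_cell * sites_per_norad / mir_copies_per_cell


def turnover_per_molecule(mir_copies_gained: float, norad_copies_lost: float) -> float:
    """miR copies gained per lncRNA copy lost after silencing."""
    if norad_copies_lost <= 0:
        raise ValueError("copies lost must be positive")
    if mir_copies_gained < 0:
        raise ValueError("copies gained must be non-negative")
    return mir_copies_gained / norad_copies_lost


def ddct_fold_change(
    ct_target_treated: float,
    ct_reference_treated: float,
    ct_target_control: float,
    ct_reference_control: float,
) -> float:
    """Relative quantification: fold = 2^(-ddCt) against a normaliser gene."""
    ddct = (ct_target_treated - ct_reference_treated) - (
        ct_target_control - ct_reference_control
    )
    return 2.0**-ddct


def stoichiometry_report(
    norad_copies_per_cell: float,
    mir_copies_per_cell: float,
    sites_per_norad: int = 2,
    mir_copies_gained: Optional[float] = None,
    norad_copies_lost: Optional[float] = None,
) -> StoichiometryReport:
    turnover = None
    if mir_copies_gained is not None and norad_copies_lost is not None:
        turnover = turnover_per_molecule(mir_copies_gained, norad_copies_lost)
    return StoichiometryReport(
        norad_copies_per_cell=norad_copies_per_cell,
        mir_copies_per_cell=mir_copies_per_cell,
        sites_per_norad=sites_per_norad,
        site_to_mir_ratio=tdmd_site_ratio(
            norad_copies_per_cell, mir_copies_per_cell, sites_per_norad
        ),
        turnover_per_norad=turnover,
    )
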
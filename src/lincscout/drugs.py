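"""Dose-response modelling and differential drug-sensitivity scoring.

Viability plates are summarized per drug and genotype group by a drug
sensitivity score (DSS): the normalized area of the fitted four-parameter
logistic inhibition curve above an activity threshold, integrated over the
tested log10 concentration range and scaled to [0, 100]. The selective
score sDSS = DSS(group A) - DSS(group B) ranks drugs by differential
response; drugs with |sDSS| >= 1 pass the screen filter by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = ["DoseResponsePlate", "fit_4pl", "dss", "sdss_screen", "four_pl"]


@dataclass
class DoseResponsePlate:
    """One drug x group dose-response series; responses are % inhibition
    (0 = untreated viability, 100 = complete kill)."""

    drug: str
    group: str
    concentrations: np.ndarray  # uM
    response: np.ndarray        # % inhibition
    replicate: int = 1

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.concentrations.shape != self.response.shape:
            raise ValueError("concentrations and response must align")
        if (self.concentrations <= 0).any():
            raise ValueError("concentrations must be strictly positive")


def four_pl(c: np.ndarray, bottom: float, top: float, ic50: float, hill: float):
    """y = bottom + (top - bottom) / (1 + (c / ic50)^hill)."""
    return bottom + (top - bottom) / (1.0 + (np.asarray(c, float) / ic50) ** hill)


@dataclass
class FourPLFit:
    bottom: float
    top: float
    ic50: float
    hill: float
    fit_ok: bool
    degenerate: bool = False

    def predict(self, c: np.ndarray) -> np.ndarray:
        if self.degenerate:
            return np.full_like(np.asarray(c, float), self.bottom)
        return four_pl(c, self.bottom, self.top, self.ic50, self.hill)


def fit_4pl(plate: DoseResponsePlate) -> FourPLFit:
    """Least-squares 4PL fit of the inhibition curve.

    Note the curve as parameterized is *decreasing* in c for hill > 0, so
    for inhibition data (rising with dose) the fitted hill is negative.
    Flat series are flagged degenerate (fit_ok False) and represented by
    their constant level.
    """
    c, y = plate.concentrations, plate.response
    if len(c) < 4:
        raise ValueError("need >=4 dose points")
    if np.ptp(y) < 1e-6:
        level = float(y.mean())
        return FourPLFit(level, level, float(np.median(c)), 1.0, False, True)
    p0 = [float(y.min()), float(y.max()), float(np.exp(np.mean(np.log(c)))), -1.0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                four_pl, c, y, p0=p0, maxfev=20_000,
                bounds=([-50.0, -50.0, c.min() / 1e4, -20.0],
                        [150.0, 150.0, c.max() * 1e4, 20.0]),
            )
    except RuntimeError:
        return FourPLFit(float(y.mean()), float(y.mean()), float(np.median(c)),
                         1.0, False, True)
    return FourPLFit(*map(float, popt), fit_ok=True)


def dss(plate: DoseResponsePlate, activity_threshold: float = 10.0) -> float:
    """Drug sensitivity score in [0, 100].

    The fitted inhibition curve y(x), x = log10(concentration), is
    integrated as max(0, y - threshold) over the tested range and
    normalized by (100 - threshold) * range, then scaled by 100: a drug
    with no activity above the threshold anywhere scores 0; complete
    inhibition over the whole range scores 100. Unfittable curves score 0
    with a warning.
    """
    fit = fit_4pl(plate)
    lo, hi = np.log10(plate.concentrations.min()), np.log10(plate.concentrations.max())
    if hi <= lo:
        raise ValueError("need a non-degenerate concentration range")
    if fit.degenerate:
        if not fit.fit_ok and np.ptp(plate.response) >= 1e-6:
            logger.warning("unfittable dose-response for %s/%s; DSS set to 0",
                           plate.drug, plate.group)
            return 0.0
        level = max(0.0, fit.bottom - activity_threshold)
        return float(100.0 * level / (100.0 - activity_threshold))
    return dss_from_curve(fit, lo, hi, activity_threshold)


def dss_from_curve(fit: FourPLFit, lo: float, hi: float,
                   activity_threshold: float = 10.0) -> float:
    """Normalized area of a fitted curve above the activity threshold over
    [lo, hi] in log10 concentration (adaptive quadrature)."""
    from scipy.integrate import quad

    def integrand(x: float) -> float:
        y = float(fit.predict(np.array([10.0**x]))[0])
        return max(0.0, min(y, 100.0) - activity_threshold)

    area, _ = quad(integrand, lo, hi, limit=200)
    return float(100.0 * area / ((100.0 - activity_threshold) * (hi - lo)))


def _average_replicates(plates: list[DoseResponsePlate]) -> DoseResponsePlate:
    base = plates[0]
    for p in plates[1:]:
        if not np.allclose(p.concentrations, base.concentrations):
            raise ValueError(
                f"replicate concentration grids differ for {base.drug}/{base.group}"
            )
    resp = np.mean([p.response for p in plates], axis=0)
    return DoseResponsePlate(base.drug, base.group, base.concentrations, resp)


def sdss_screen(
    plates: list[DoseResponsePlate],
    group_a: str,
    group_b: str,
    threshold: float = 1.0,
    activity_threshold: float = 10.0,
) -> pd.DataFrame:
    """Selective-DSS screen between two groups.

    Replicates are averaged at the response level before fitting; sDSS =
    DSS(group_a) - DSS(group_b) (so positive means the drug hits group_a
    harder); passes_filter = |sDSS| >= threshold. Drugs present in only one
    group are excluded with a warning. Sorted by |sDSS| descending, ties
    broken by drug name.
    """
    grouped: dict[tuple[str, str], list[DoseResponsePlate]] = {}
    for p in plates:
        grouped.setdefault((p.drug, p.group), []).append(p)
    drugs = sorted({d for d, _ in grouped})
    rows = []
    for drug in drugs:
        if (drug, group_a) not in grouped or (drug, group_b) not in grouped:
            logger.warning("drug %s missing one group; excluded", drug)
            continue
        dss_a = dss(_average_replicates(grouped[(drug, group_a)]), activity_threshold)
        dss_b = dss(_average_replicates(grouped[(drug, group_b)]), activity_threshold)
        sdss = dss_a - dss_b
        rows.append(
            {
                "drug": drug,
                f"dss_{group_a}": dss_a,
                f"dss_{group_b}": dss_b,
                "sdss": sdss,
                "passes_filter": abs(sdss) >= threshold,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(
            ["sdss", "drug"], key=lambda s: s.abs() if s.name == "sdss" else s,
            ascending=[False, True],
        ).reset_index(drop=True)
    return out
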
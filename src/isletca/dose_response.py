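"""Four-parameter logistic (4PL) dose-response curves.

The 4PL model is

    response(c) = bottom + (top - bottom) / (1 + (ec50 / c) ** hill)

with ``ec50 > 0`` the half-maximal concentration and ``hill`` the slope.
Fits are performed in log-concentration space (standard for ramps spanning
decades, e.g. 0.1-100 nM epinephrine) with unweighted least squares, and
canonicalized so that ``top > bottom`` with the sign of ``hill`` carrying
the direction of the response; this removes the (bottom, top, hill) <->
(top, bottom, -hill) degeneracy and makes recovered parameters comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class FourPL:
    """Parameters of a four-parameter logistic curve."""

    bottom: float
    top: float
    ec50: float
    hill: float

    def __post_init__(self) -> None:
        if not self.ec50 > 0:
            raise ValueError("ec50 must be positive")
        if self.top == self.bottom:
            raise ValueError("top must differ from bottom")
        if self.hill == 0:
            raise ValueError("hill must be non-zero")


@dataclass
class FitResult:
    """Residual summary of a 4PL fit."""

    rss: float
    converged: bool
    n: int


def eval_4pl(params: FourPL, conc) -> np.ndarray | float:
    """Evaluate the 4PL curve at positive concentration(s)."""
    conc_arr = np.asarray(conc, dtype=float)
    if np.any(conc_arr <= 0):
        raise ValueError("concentrations must be strictly positive")
    out = params.bottom + (params.top - params.bottom) / (
        1.0 + (params.ec50 / conc_arr) ** params.hill
    )
    return float(out) if np.ndim(conc) == 0 else out


def _logistic_logc(lc, bottom, top, lec50, hill):
    return bottom + (top - bottom) / (1.0 + np.exp(-hill * (lc - lec50)))


def fit_4pl(conc, response) -> tuple[FourPL, FitResult]:
    """Least-squares 4PL fit in log-concentration space.

    Initialization is data driven: bottom/top from the extreme responses,
    EC50 from the geometric-mean concentration, hill = +/-1 by response
    direction.  Requires at least 4 distinct positive concentrations and
    non-constant responses.
    """
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    if conc.shape != response.shape:
        raise ValueError("conc and response must have equal length")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    if len(np.unique(conc)) < 4:
        raise ValueError("fit requires at least 4 distinct concentrations")
    if response.std() == 0:
        raise ValueError("degenerate data: responses have zero variance")

    lc = np.log(conc)
    order = np.argsort(lc)
    r_lo = response[order[:2]].mean()
    r_hi = response[order[-2:]].mean()
    hill0 = 1.0 if r_hi >= r_lo else -1.0
    span = response.max() - response.min()
    p0 = (response.min(), response.max(), float(np.median(lc)), hill0)
    converged = True
    try:
        popt, _ = curve_fit(_logistic_logc, lc, response, p0=p0, maxfev=50000)
    except RuntimeError:
        popt = np.array(p0)
        converged = False
    bottom, top, lec50, hill = (float(v) for v in popt)
    if top < bottom:  # canonical form: top > bottom, hill sign carries direction
        bottom, top, hill = top, bottom, -hill
    if top == bottom:
        top = bottom + 1e-12 * max(1.0, span)
    if hill == 0:
        hill = 1e-12
    params = FourPL(bottom=bottom, top=top, ec50=float(np.exp(lec50)), hill=hill)
    rss = float(np.sum((eval_4pl(params, conc) - response) ** 2))
    return params, FitResult(rss=rss, converged=converged, n=conc.size)


def normalize_to_pre_agonist(response, pre_agonist_median: float) -> np.ndarray:
    """Normalize responses by the pre-agonist (baseline condition) median."""
    if not pre_agonist_median > 0:
        raise ValueError("pre_agonist_median must be positive")
    return np.asarray(response, dtype=float) / pre_agonist_median


__all__ = ["FourPL", "FitResult", "eval_4pl", "fit_4pl", "normalize_to_pre_agonist"]
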
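"""Activity-based-probe densitometry and four-parameter dose-response fits.

An activity-based probe labels only the catalytically competent fraction of
a protease, so the ratio of the probe-labeled ("active") band to the total
protein band reports fractional enzyme activity.  Raw ratios are comparable
only within a gel/blot, so they are normalized to the mean ratio of the
control samples run on the same gel block.  For competition assays, percent
activity is scaled between the uninhibited (100%) and maximally inhibited
(0%) responses and fitted with a four-parameter logistic (4PL)

    y(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)

whose midpoint is the IC50.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DensitometryRecord:
    """One band-density measurement (already quantified upstream)."""

    sample_id: str
    group: str
    active_density: float
    total_density: float
    gel_block_id: str = "gel-1"
    timepoint: str = ""

    def __post_init__(self) -> None:
        if self.total_density <= 0:
            raise ValueError(f"{self.sample_id}: total_density must be > 0")
        if self.active_density < 0:
            raise ValueError(f"{self.sample_id}: active_density must be >= 0")

    @property
    def ratio(self) -> float:
        return self.active_density / self.total_density


@dataclass(frozen=True)
class DoseResponsePoint:
    concentration: float  # nM
    percent_activity: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass
class DoseResponseFit:
    ic50: Optional[float]
    hill_slope: Optional[float]
    top: Optional[float]
    bottom: Optional[float]
    rss: Optional[float]
    converged: bool
    message: str = ""

    def predict(self, concentration: np.ndarray) -> np.ndarray:
        if not self.converged:
            raise RuntimeError("fit did not converge; parameters withheld")
        return _four_pl(
            np.asarray(concentration, dtype=float),
            self.bottom,
            self.top,
            self.ic50,
            self.hill_slope,
        )


def active_total_normalize(
    records: Sequence[DensitometryRecord], control_group: str
) -> pd.DataFrame:
    """Normalize active/total ratios to the same-gel control mean.

    Each record's ratio is divided by the mean active/total ratio of the
    ``control_group`` records in the same gel block, so control records
    average to exactly 1.0 within every block.  Ratios remain meaningful
    only within a block, never across blocks.
    """
    if not records:
        return pd.DataFrame(
            columns=["sample_id", "group", "gel_block_id", "ratio", "normalized_ratio"]
        )
    frame = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "group": [r.group for r in records],
            "gel_block_id": [r.gel_block_id for r in records],
            "ratio": [r.ratio for r in records],
        }
    )
    out = []
    for block, sub in frame.groupby("gel_block_id", sort=False):
        controls = sub.loc[sub["group"] == control_group, "ratio"]
        if controls.empty:
            raise ValueError(f"gel block {block!r} has no {control_group!r} records")
        mean = controls.mean()
        if mean == 0:
            raise ValueError(f"gel block {block!r}: control mean ratio is zero")
        sub = sub.copy()
        sub["normalized_ratio"] = sub["ratio"] / mean
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def percent_activity(
    ratios: Sequence[float], max_ref: float, min_ref: float
) -> List[float]:
    """Linear rescale to percent: ``max_ref`` -> 100, ``min_ref`` -> 0."""
    if max_ref <= min_ref:
        raise ValueError("degenerate normalization: max_ref must exceed min_ref")
    span = max_ref - min_ref
    return [100.0 * (r - min_ref) / span for r in ratios]


def _four_pl(c, bottom, top, ic50, hill):
    with np.errstate(over="ignore"):
        return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def fit_ic50(
    points: Sequence[DoseResponsePoint],
    n_starts: int = 5,
    seed: int = 0,
) -> DoseResponseFit:
    """Least-squares 4PL fit of percent activity vs inhibitor concentration.

    IC50 is searched on a log10 scale within [min dose / 10, max dose * 10]
    and the Hill slope within [0.1, 10]; five quantile-seeded multi-starts
    guard against local minima.  Zero-concentration points only anchor
    ``top`` (they are excluded from the logistic residuals, which are
    undefined at c = 0 on the log scale).
    """
    if len(points) < 4:
        raise ValueError("need at least 4 dose-response points")
    conc = np.array([p.concentration for p in points], dtype=float)
    resp = np.array([p.percent_activity for p in points], dtype=float)
    zero = conc == 0
    top_anchor = float(resp[zero].mean()) if zero.any() else None
    conc, resp = conc[~zero], resp[~zero]
    if len(conc) < 4:
        raise ValueError("need at least 4 nonzero-concentration points")
    if np.allclose(resp, resp[0]):
        raise ValueError("no dose dependence: all responses equal")
    if resp.min() > 25 or resp.max() < 75:
        warnings.warn(
            "dose ladder does not span the transition (no point <25% or >75%)",
            stacklevel=2,
        )

    log_c = np.log10(conc)
    lo_ic50, hi_ic50 = conc.min() / 10.0, conc.max() * 10.0

    def model(lc, bottom, top, log_ic50, hill):
        return _four_pl(10.0 ** lc, bottom, top, 10.0 ** log_ic50, hill)

    rng = np.random.default_rng(seed)
    # quantile-based starting midpoints spread over the dose range
    quantiles = np.linspace(0.15, 0.85, n_starts)
    start_log_ic50 = np.quantile(log_c, quantiles)

    bounds_lo = [-50.0, resp.min() - 50.0, np.log10(lo_ic50), 0.1]
    bounds_hi = [resp.max() + 50.0, resp.max() + 100.0, np.log10(hi_ic50), 10.0]
    if top_anchor is not None:
        # fix top to the zero-dose mean (tight band keeps curve_fit happy)
        bounds_lo[1], bounds_hi[1] = top_anchor - 1e-6, top_anchor + 1e-6

    best: Optional[Tuple[float, np.ndarray]] = None
    for i, lic in enumerate(start_log_ic50):
        p0 = [
            float(resp.min()),
            top_anchor if top_anchor is not None else float(resp.max()),
            float(lic),
            1.0 + 0.1 * rng.standard_normal(),
        ]
        p0 = np.clip(p0, bounds_lo, bounds_hi)
        try:
            popt, _ = curve_fit(
                model, log_c, resp, p0=p0, bounds=(bounds_lo, bounds_hi), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((model(log_c, *popt) - resp) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)

    if best is None:
        return DoseResponseFit(
            ic50=None,
            hill_slope=None,
            top=None,
            bottom=None,
            rss=None,
            converged=False,
            message="no start converged",
        )
    rss, popt = best
    bottom, top, log_ic50, hill = popt
    if bottom >= top:
        return DoseResponseFit(
            ic50=None,
            hill_slope=None,
            top=None,
            bottom=None,
            rss=None,
            converged=False,
            message="degenerate fit: bottom >= top",
        )
    fit = DoseResponseFit(
        ic50=float(10.0 ** log_ic50),
        hill_slope=float(hill),
        top=float(top),
        bottom=float(bottom),
        rss=rss,
        converged=True,
    )
    logger.info(
        "fit_ic50: ic50=%.4g nM hill=%.3g top=%.3g bottom=%.3g rss=%.3g",
        fit.ic50,
        fit.hill_slope,
        fit.top,
        fit.bottom,
        fit.rss,
    )
    return fit


def bootstrap_ic50(
    points: Sequence[DoseResponsePoint],
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> Tuple[float, float]:
    """Nonparametric bootstrap CI for IC50 (resampling points with replacement)."""
    rng = np.random.default_rng(seed)
    pts = list(points)
    estimates = []
    for _ in range(n_boot):
        sample = [pts[i] for i in rng.integers(0, len(pts), size=len(pts))]
        if len({p.concentration for p in sample if p.concentration > 0}) < 4:
            continue
        try:
            fit = fit_ic50(sample, seed=int(rng.integers(2**31)))
        except ValueError:
            continue
        if fit.converged:
            estimates.append(fit.ic50)
    if not estimates:
        raise RuntimeError("bootstrap produced no converged fits")
    lo = float(np.quantile(estimates, (1 - ci) / 2))
    hi = float(np.quantile(estimates, 1 - (1 - ci) / 2))
    return lo, hi


def standard_dose_ladder() -> np.ndarray:
    """The 3-fold, 7-step ladder from 3.7 to 2,700 nM used in ABP competition."""
    return 3.7 * 3.0 ** np.arange(7)


def simulate_dose_response(
    ic50: float,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    concentrations: Optional[np.ndarray] = None,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> List[DoseResponsePoint]:
    """Generate 4PL responses (optionally noisy) on a dose ladder.

    ``n_replicates`` independent measurements are emitted per concentration
    (ABP competition assays are typically run in triplicate); with
    ``noise_sd=0`` the replicates coincide and one per dose is returned.
    """
    if concentrations is None:
        concentrations = standard_dose_ladder()
    rng = np.random.default_rng(seed)
    reps = 1 if noise_sd == 0 else n_replicates
    pts = []
    for c in concentrations:
        y = _four_pl(float(c), bottom, top, ic50, hill)
        for _ in range(reps):
            noisy = y + (float(rng.normal(0, noise_sd)) if noise_sd > 0 else 0.0)
            pts.append(DoseResponsePoint(float(c), float(noisy)))
    return pts
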
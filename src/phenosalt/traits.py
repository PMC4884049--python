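"""Whole-plant salinity-tolerance traits.

Derived quantities from the per-image measurements:

* projected shoot area — the sum of the plant pixel counts of the two
  orthogonal side views and the top view, a linear surrogate for shoot
  fresh biomass;
* the area–fresh-weight calibration regression;
* percent growth reduction of salt-treated vs control plants;
* osmotic / ionic phase indices — ratios of treated to control relative
  growth rate (RGR) before and after a breakpoint day (default day 10,
  the end of the shoot-ion-independent window);
* a tissue-tolerance score (senescent % per mM leaf Na+; lower = more
  tolerant);
* replicate summaries of leaf Na+, K+ and the K+/Na+ ratio, where the
  group ratio is the mean of per-replicate ratios, never the ratio of
  group means;
* leaf tissue ion concentration from digest measurements, expressed in
  the tissue water (fresh minus dry weight, 1 g = 1 mL).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionFit",
    "PhaseIndices",
    "projected_shoot_area",
    "fit_area_weight_regression",
    "growth_reduction",
    "phase_indices",
    "tissue_tolerance_score",
    "tissue_tolerance_summary",
    "kna_ratio_summary",
    "tissue_ion_concentration",
]


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class PhaseIndices:
    """Treated/control RGR ratios for the two stress phases.

    An index of 1 means growth identical to control in that window; the
    osmotic index covers day 0 to the breakpoint, the ionic index the
    breakpoint to the last imaged day. CIs are bootstrap 95% intervals
    over replicate plants.
    """

    osmotic_index: float
    ionic_index: float
    osmotic_ci: tuple[float, float]
    ionic_ci: tuple[float, float]
    n_treated: int
    n_control: int


def projected_shoot_area(side1_px: float, side2_px: float, top_px: float) -> float:
    """Sum of plant pixel areas over the three views (biomass surrogate)."""
    for v in (side1_px, side2_px, top_px):
        if v < 0:
            raise ValueError("view areas must be non-negative")
    return side1_px + side2_px + top_px


def fit_area_weight_regression(
    areas: Sequence[float], weights: Sequence[float]
) -> RegressionFit:
    """OLS fit of shoot fresh weight on projected shoot area."""
    x = np.asarray(areas, float)
    y = np.asarray(weights, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("areas and weights must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("areas are constant; slope is undefined")
    fit = stats.linregress(x, y)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    resid = y - (fit.intercept + fit.slope * x)
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return RegressionFit(float(fit.slope), float(fit.intercept), r2, len(x))


def growth_reduction(treated_area: float, control_area: float) -> float:
    """Percent reduction of treated vs control area, 100*(1 - T/C)."""
    if control_area <= 0:
        raise ValueError("control area must be positive")
    return 100.0 * (1.0 - treated_area / control_area)


def _interval_rgr(series: pd.DataFrame, day_a: float, day_b: float) -> np.ndarray:
    """Per-plant RGR over [day_a, day_b]: (ln A_b - ln A_a) / (b - a)."""
    wide = series.pivot_table(index="plant_id", columns="day", values="area_px")
    for d in (day_a, day_b):
        if d not in wide.columns:
            raise ValueError(f"series lack day {d}")
    a, b = wide[day_a].to_numpy(float), wide[day_b].to_numpy(float)
    if np.any(a <= 0) or np.any(b <= 0) or np.any(np.isnan(a)) or np.any(np.isnan(b)):
        raise ValueError("areas must be positive and present at both days")
    return (np.log(b) - np.log(a)) / (day_b - day_a)


def phase_indices(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    breakpoint_day: float = 10.0,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    rng: np.random.Generator | int | None = 0,
) -> PhaseIndices:
    """Osmotic and ionic growth indices with bootstrap CIs.

    ``treated`` and ``control`` are tidy frames with columns plant_id,
    day, area_px covering day 0, the breakpoint and at least one later
    day. The index for each window is mean(treated RGR)/mean(control RGR);
    CIs are normal-interval bootstrap (estimate ± z * bootstrap SD) over
    resampled plants, which stays close to nominal coverage at the small
    replicate numbers (n = 7) this design uses.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    days = sorted(set(treated["day"]).intersection(control["day"]))
    if 0 not in days or breakpoint_day not in days or days[-1] <= breakpoint_day:
        raise ValueError("series must cover day 0, the breakpoint and a later day")
    last = days[-1]

    rgr = {
        ("osm", "t"): _interval_rgr(treated, 0, breakpoint_day),
        ("osm", "c"): _interval_rgr(control, 0, breakpoint_day),
        ("ion", "t"): _interval_rgr(treated, breakpoint_day, last),
        ("ion", "c"): _interval_rgr(control, breakpoint_day, last),
    }

    def ratio(phase: str, ti: np.ndarray | slice, ci: np.ndarray | slice) -> float:
        return float(rgr[(phase, "t")][ti].mean() / rgr[(phase, "c")][ci].mean())

    full = slice(None)
    osm, ion = ratio("osm", full, full), ratio("ion", full, full)

    nt, nc = len(rgr[("osm", "t")]), len(rgr[("osm", "c")])
    boots = np.empty((n_boot, 2))
    for b in range(n_boot):
        ti = rng.integers(0, nt, nt)
        ci = rng.integers(0, nc, nc)
        boots[b] = (ratio("osm", ti, ci), ratio("ion", ti, ci))
    z = stats.norm.ppf(0.5 + ci_level / 2)
    sd = boots.std(axis=0, ddof=1)
    osm_ci = (osm - z * sd[0], osm + z * sd[0])
    ion_ci = (ion - z * sd[1], ion + z * sd[1])
    return PhaseIndices(osm, ion, osm_ci, ion_ci, nt, nc)


def tissue_tolerance_score(senescent_percent: float, leaf_na_mM: float) -> float:
    """Senescent area (%) per mM leaf Na+; lower = more tissue tolerant."""
    if senescent_percent < 0:
        raise ValueError("senescent_percent must be non-negative")
    if leaf_na_mM <= 0:
        raise ValueError("leaf Na+ must be positive (zero Na+ leaves the score undefined)")
    return senescent_percent / leaf_na_mM


def tissue_tolerance_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per cultivar x dose tissue-tolerance score with propagated SE.

    Expects replicate columns cultivar, dose_mM, senescent_percent, na_mM.
    The score is computed from group means; its SE combines the relative
    SEs of the two means in quadrature (first-order error propagation).
    Groups whose mean Na+ is not positive are flagged with NaN.
    """
    rows = []
    for (cultivar, dose), g in table.groupby(["cultivar", "dose_mM"], sort=True):
        n = len(g)
        s_mean, na_mean = g["senescent_percent"].mean(), g["na_mM"].mean()
        s_se = g["senescent_percent"].std(ddof=1) / np.sqrt(n)
        na_se = g["na_mM"].std(ddof=1) / np.sqrt(n)
        if na_mean <= 0:
            score, se = np.nan, np.nan
        else:
            score = s_mean / na_mean
            if s_mean > 0:
                se = score * np.hypot(s_se / s_mean, na_se / na_mean)
            else:
                se = s_se / na_mean
        rows.append((cultivar, dose, n, score, se))
    return pd.DataFrame(
        rows, columns=["cultivar", "dose_mM", "n", "tissue_tolerance_score", "se"]
    )


def kna_ratio_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Group means ± SE of leaf Na+, K+ and the K+/Na+ ratio.

    The ratio is computed per replicate and then averaged (mean of
    ratios). Groups with fewer than two complete replicates are skipped
    with a warning, mirroring tables where heavily senesced material
    could not be assayed.
    """
    rows = []
    for (cultivar, dose), g in table.groupby(["cultivar", "dose_mM"], sort=True):
        g = g.dropna(subset=["na_mM", "k_mM"])
        if len(g) < 2:
            warnings.warn(
                f"group ({cultivar}, {dose} mM) has <2 complete replicates; skipped",
                stacklevel=2,
            )
            continue
        n = len(g)
        ratio = g["k_mM"] / g["na_mM"]
        rows.append(
            (
                cultivar, dose, n,
                g["na_mM"].mean(), g["na_mM"].std(ddof=1) / np.sqrt(n),
                g["k_mM"].mean(), g["k_mM"].std(ddof=1) / np.sqrt(n),
                ratio.mean(), ratio.std(ddof=1) / np.sqrt(n),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cultivar", "dose_mM", "n",
            "na_mean", "na_se", "k_mean", "k_se", "kna_mean", "kna_se",
        ],
    )


def tissue_ion_concentration(
    fresh_weight_g: float,
    dry_weight_g: float,
    digest_volume_mL: float,
    digest_conc_mM: float,
) -> float:
    """Ion concentration in tissue water (mM) from a digest measurement.

    The digested amount (µmol) is ``digest_conc_mM * digest_volume_mL``;
    tissue water (mL) is fresh minus dry weight at 1 g = 1 mL.
    """
    if dry_weight_g < 0 or fresh_weight_g <= dry_weight_g:
        raise ValueError("need fresh weight > dry weight >= 0")
    if digest_volume_mL <= 0:
        raise ValueError("digest volume must be positive")
    if digest_conc_mM < 0:
        raise ValueError("digest concentration must be non-negative")
    amount_umol = digest_conc_mM * digest_volume_mL
    tissue_water_mL = fresh_weight_g - dry_weight_g
    return amount_umol / tissue_water_mL
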
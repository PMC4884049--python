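"""Experiment-design support and statistical reporting.

Covers the non-imaging bookkeeping of a controlled salinity experiment —
stepwise NaCl dosing with CaCl2 supplementation at a fixed Na+:Ca2+ molar
ratio, watering pots back to a target weight so the soil salt
concentration stays constant — and the reporting statistics: fixed-effects
two-way ANOVA (cultivar x salt level) with significance stars and LSD
(least significant difference) letter groupings of treatment means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExperimentDesign",
    "DoseEvent",
    "DoseSchedule",
    "cacl2_supplement",
    "build_dose_schedule",
    "water_to_weight",
    "two_way_anova",
    "lsd_threshold",
    "lsd_groups",
]

#: Na+:Ca2+ molar ratio used for CaCl2 supplementation.
NA_CA_RATIO = 30.0


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial design: cultivars x NaCl doses x replicates."""

    cultivars: tuple[str, ...] = ("sensitive", "tolerant")
    doses_mM: tuple[float, ...] = (0.0, 50.0, 75.0, 100.0)
    n_reps: int = 7
    increment_mM: float = 50.0
    increment_interval_h: float = 12.0
    na_ca_ratio: float = NA_CA_RATIO
    target_pot_weight_g: float = 3600.0
    event_volume_mL: float = 60.0  # metadata: volume of 0.5 M stock per event
    event_stock_M: float = 0.5

    def validate(self) -> None:
        if any(d < 0 for d in self.doses_mM):
            raise ValueError("doses must be non-negative")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >=1")
        if self.increment_mM <= 0:
            raise ValueError("increment_mM must be positive")
        if self.increment_interval_h <= 0:
            raise ValueError("increment_interval_h must be positive")
        if self.na_ca_ratio <= 0:
            raise ValueError("na_ca_ratio must be positive")


@dataclass(frozen=True)
class DoseEvent:
    time_h: float
    added_nacl_mM: float
    cumulative_nacl_mM: float
    cacl2_mM_cumulative: float
    solution_volume_mL: float


@dataclass(frozen=True)
class DoseSchedule:
    target_mM: float
    events: tuple[DoseEvent, ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.time_h, e.added_nacl_mM, e.cumulative_nacl_mM,
                 e.cacl2_mM_cumulative, e.solution_volume_mL)
                for e in self.events
            ],
            columns=[
                "time_h", "added_nacl_mM", "cumulative_nacl_mM",
                "cacl2_mM_cumulative", "solution_volume_mL",
            ],
        )


def cacl2_supplement(nacl_mM: float, na_ca_ratio: float = NA_CA_RATIO) -> float:
    """CaCl2 concentration (mM) supplementing a NaCl dose.

    Supplementation holds the Na+:Ca2+ molar ratio at ``na_ca_ratio``
    (30:1 by default, i.e. 3.3 mM CaCl2 for 100 mM NaCl when rounded to
    one decimal place, the precision used in reports).
    """
    if nacl_mM < 0:
        raise ValueError("NaCl concentration must be non-negative")
    return nacl_mM / na_ca_ratio


def build_dose_schedule(design: ExperimentDesign, target_mM: float) -> DoseSchedule:
    """Stepwise ramp to ``target_mM`` in ``increment_mM`` steps.

    Increments are applied every ``increment_interval_h`` hours until the
    target is reached; the last event may be a partial increment. A target
    of 0 (control) yields an empty schedule.
    """
    design.validate()
    if target_mM not in design.doses_mM:
        raise ValueError(f"target {target_mM} mM is not one of the design doses")
    events = []
    cumulative = 0.0
    i = 0
    while cumulative < target_mM:
        added = min(design.increment_mM, target_mM - cumulative)
        cumulative += added
        events.append(
            DoseEvent(
                time_h=i * design.increment_interval_h,
                added_nacl_mM=added,
                cumulative_nacl_mM=cumulative,
                cacl2_mM_cumulative=cacl2_supplement(cumulative, design.na_ca_ratio),
                solution_volume_mL=design.event_volume_mL,
            )
        )
        i += 1
    return DoseSchedule(target_mM=target_mM, events=tuple(events))


def water_to_weight(current_weight_g: float, target_weight_g: float) -> float:
    """Water (g) to add to bring a pot back to its target weight.

    Never negative — an over-weight pot gets no water and triggers a
    warning rather than an impossible removal.
    """
    if target_weight_g < 0 or current_weight_g < 0:
        raise ValueError("weights must be non-negative")
    if current_weight_g > target_weight_g:
        warnings.warn(
            f"pot over target weight by {current_weight_g - target_weight_g:.1f} g",
            stacklevel=2,
        )
        return 0.0
    return target_weight_g - current_weight_g


def _stars(p: float) -> str:
    if math.isnan(p):
        return "na"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def two_way_anova(
    table: pd.DataFrame,
    value: str,
    factor_a: str = "cultivar",
    factor_b: str = "dose_mM",
) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA with interaction.

    Returns a frame indexed by term (factor_a, factor_b, interaction,
    residual) with sum_sq, df, F, p and the significance stars used in
    report tables (** p<0.01, * p<0.05, ns otherwise). A trait with zero
    variance yields NaN F statistics flagged ``na``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for f in (factor_a, factor_b):
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >=2 levels")
    df = table[[factor_a, factor_b, value]].rename(
        columns={factor_a: "A", factor_b: "B", value: "y"}
    )
    if np.ptp(df["y"].to_numpy(float)) == 0:
        terms = [f"{factor_a} (C)", f"{factor_b} (S)", "C x S", "residual"]
        out = pd.DataFrame(
            {"sum_sq": 0.0, "df": np.nan, "F": np.nan, "p": np.nan, "stars": "na"},
            index=terms,
        )
        return out
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = sm.stats.anova_lm(model, typ=2)
    aov = aov.rename(
        index={
            "C(A)": f"{factor_a} (C)",
            "C(B)": f"{factor_b} (S)",
            "C(A):C(B)": "C x S",
            "Residual": "residual",
        },
        columns={"PR(>F)": "p"},
    )
    aov["stars"] = [_stars(p) if not math.isnan(f) else "na"
                    for p, f in zip(aov["p"].fillna(np.nan), aov["F"].fillna(np.nan))]
    aov.loc["residual", "stars"] = ""
    return aov[["sum_sq", "df", "F", "p", "stars"]]


def lsd_threshold(mse: float, df_error: int, n_per_group: int, alpha: float = 0.05) -> float:
    """Least significant difference: t(1-alpha/2, df) * sqrt(2*MSE/n)."""
    if mse <= 0:
        raise ValueError("MSE must be positive")
    if df_error < 1 or n_per_group < 1:
        raise ValueError("df_error and n_per_group must be >=1")
    t = stats.t.ppf(1 - alpha / 2, df_error)
    return float(t * np.sqrt(2 * mse / n_per_group))


def lsd_groups(
    means: dict[str, float] | pd.Series,
    mse: float,
    df_error: int,
    n_per_group: int | Sequence[int],
    alpha: float = 0.05,
) -> dict[str, str]:
    """LSD letter display: means closer than the LSD share a letter.

    Letters are assigned by the sorted-sweep insert-and-absorb convention:
    means are ordered descending, each maximal run of pairwise
    non-significant means becomes one letter, runs contained in another
    are absorbed. The guaranteed contract is the pairwise relation —
    means differing by >= LSD never share a letter, means differing by
    < LSD always share at least one — not the letter strings themselves.
    Requires equal replication per group (a pooled LSD is otherwise
    unjustified).
    """
    if isinstance(means, pd.Series):
        means = means.to_dict()
    if not means:
        raise ValueError("no group means given")
    if not np.isscalar(n_per_group):
        ns = set(int(n) for n in n_per_group)
        if len(ns) != 1:
            raise ValueError("unequal replication; pooled LSD not applicable")
        n_per_group = ns.pop()
    lsd = lsd_threshold(mse, df_error, int(n_per_group), alpha)

    order = sorted(means, key=lambda k: (-means[k], str(k)))
    vals = [means[k] for k in order]
    m = len(order)
    # maximal non-significant runs over the descending means
    runs: list[tuple[int, int]] = []
    for i in range(m):
        j = i
        while j + 1 < m and vals[i] - vals[j + 1] < lsd:
            j += 1
        # runs with the same right end are contained in an earlier run
        if not runs or j > runs[-1][1]:
            runs.append((i, j))
    letters = "abcdefghijklmnopqrstuvwxyz"
    if len(runs) > len(letters):
        raise ValueError("more letter groups than available letters")
    assigned: dict[str, str] = {k: "" for k in order}
    for letter, (i, j) in zip(letters, runs):
        for k in order[i : j + 1]:
            assigned[k] += letter
    return assigned
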
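"""Per-year cost-of-reproduction verdicts from a state x time survival fit.

A breeding season is *costly* when successful breeders (state 2) survive
the following interval with lower probability than failed/non-breeders
(state 1), the two +-1 SE intervals being disjoint; *beneficial* when the
ordering is reversed; *equal* when the SE intervals overlap.  Compound
intervals (spanning a no-resighting year) and the terminally confounded
interval are never classified.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .multistate_cmr import ModelFit

__all__ = [
    "SurvivalEstimate",
    "CostLabel",
    "PeriodComparison",
    "extract_state_survival",
    "classify_year",
    "classify_all_years",
    "compare_periods",
    "verdict_table",
    "plot_survival_costs",
]

VERDICTS = ("costly", "equal", "beneficial", "not_comparable")


@dataclass(frozen=True)
class SurvivalEstimate:
    year: int                 # interval (year, year+1); year = season of effort
    state: int
    estimate: float
    se: float
    comparable: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.estimate <= 1.0:
            raise ValueError("survival estimate must be in [0, 1]")
        if self.se < 0:
            raise ValueError("SE must be nonnegative")


@dataclass(frozen=True)
class CostLabel:
    year: int
    verdict: str

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"verdict must be one of {VERDICTS}")


def extract_state_survival(fit: ModelFit,
                           sex: str | None = None) -> list[SurvivalEstimate]:
    """Natural-scale state-specific survival with delta-method SEs.

    Intervals straddling an inactive occasion are compound (multi-year)
    estimates and marked non-comparable, as is the final interval of a
    time-dependent model (confounded with terminal detection).
    """
    if "State" not in fit.spec.phi:
        raise ValueError("states not distinguished: Phi structure has no "
                         "State effect")
    if "Sex" in fit.spec.phi and sex is None:
        raise ValueError("Phi is sex-structured; pass sex='F' or 'M'")
    sex = sex or "M"
    occ = fit.design.occasions
    T = occ.n_occasions
    est = fit.estimates()
    phi = est[est["class"] == "phi"]
    phi = phi[phi["Sex"] == sex]
    time_dep = "Time" in fit.spec.phi

    bad_intervals: set[int] = set()
    for t in range(T):
        if not occ.resighting_active[t] and 0 < t < T - 1:
            bad_intervals.update({t - 1, t})
    out: list[SurvivalEstimate] = []
    for _, row in phi.iterrows():
        t = int(row["Time"])
        comparable = True
        if t in bad_intervals:
            comparable = False
        if time_dep and t == T - 2:
            comparable = False
        out.append(SurvivalEstimate(
            year=occ.years[t], state=int(row["State"]),
            estimate=float(row["estimate"]),
            se=float(row["se"]) if np.isfinite(row["se"]) else 0.0,
            comparable=comparable))
    return out


def classify_year(e1: SurvivalEstimate, e2: SurvivalEstimate,
                  method: str = "se_overlap",
                  z_alpha: float = 0.05) -> CostLabel:
    """Verdict for one interval from the state-1 and state-2 estimates.

    Default rule: +-1 SE intervals; disjoint with state 2 below state 1 ->
    costly, disjoint above -> beneficial, overlapping -> equal.  A z-test
    alternative (``method='z'``) is available but is not the reporting
    default.
    """
    if e1.year != e2.year:
        raise ValueError(f"mismatched intervals: {e1.year} vs {e2.year}")
    if {e1.state, e2.state} != {1, 2}:
        raise ValueError("need one estimate per state")
    if e1.state == 2:
        e1, e2 = e2, e1
    if not (e1.comparable and e2.comparable):
        return CostLabel(e1.year, "not_comparable")
    if method == "z":
        se = float(np.hypot(e1.se, e2.se))
        if se == 0:
            return CostLabel(e1.year, "equal" if e1.estimate == e2.estimate
                             else ("costly" if e2.estimate < e1.estimate
                                   else "beneficial"))
        z = (e2.estimate - e1.estimate) / se
        p = 2 * stats.norm.sf(abs(z))
        if p >= z_alpha:
            return CostLabel(e1.year, "equal")
        return CostLabel(e1.year, "costly" if z < 0 else "beneficial")
    lo1, hi1 = e1.estimate - e1.se, e1.estimate + e1.se
    lo2, hi2 = e2.estimate - e2.se, e2.estimate + e2.se
    if hi2 < lo1:
        return CostLabel(e1.year, "costly")
    if hi1 < lo2:
        return CostLabel(e1.year, "beneficial")
    return CostLabel(e1.year, "equal")


def classify_all_years(estimates: Iterable[SurvivalEstimate],
                       method: str = "se_overlap") -> list[CostLabel]:
    by_year: dict[int, dict[int, SurvivalEstimate]] = {}
    for e in estimates:
        by_year.setdefault(e.year, {})[e.state] = e
    labels = []
    for year in sorted(by_year):
        pair = by_year[year]
        if len(pair) != 2:
            labels.append(CostLabel(year, "not_comparable"))
            continue
        labels.append(classify_year(pair[1], pair[2], method=method))
    return labels


@dataclass
class PeriodComparison:
    state: int
    cut_year: int
    mean_early: float
    mean_late: float
    wilcoxon_w: float
    wilcoxon_p: float
    t_stat: float
    t_df: float
    t_p: float


def compare_periods(estimates: Sequence[SurvivalEstimate], cut_year: int,
                    state: int) -> PeriodComparison:
    """Early-vs-late comparison of per-year survival for one state.

    Years before ``cut_year`` form the early period.  Both the Wilcoxon
    rank-sum (exact where possible) and Welch's t are reported.
    """
    vals = [(e.year, e.estimate) for e in estimates
            if e.state == state and e.comparable]
    early = [v for y, v in vals if y < cut_year]
    late = [v for y, v in vals if y >= cut_year]
    if len(early) < 2 or len(late) < 2:
        raise ValueError("need at least 2 comparable estimates per period")
    mw = stats.mannwhitneyu(early, late, alternative="two-sided",
                            method="exact" if
                            (len(early) < 10 and len(late) < 10) else "auto")
    tt = stats.ttest_ind(early, late, equal_var=False)
    df = getattr(tt, "df", np.nan)
    return PeriodComparison(
        state=state, cut_year=cut_year,
        mean_early=float(np.mean(early)), mean_late=float(np.mean(late)),
        wilcoxon_w=float(mw.statistic), wilcoxon_p=float(mw.pvalue),
        t_stat=float(tt.statistic), t_df=float(df), t_p=float(tt.pvalue))


def verdict_table(estimates: Iterable[SurvivalEstimate],
                  path: str | Path | None = None) -> pd.DataFrame:
    """CSV-ready table: year, S1, SE1, S2, SE2, verdict."""
    by_year: dict[int, dict[int, SurvivalEstimate]] = {}
    for e in estimates:
        by_year.setdefault(e.year, {})[e.state] = e
    labels = {l.year: l.verdict for l in classify_all_years(
        [e for pair in by_year.values() for e in pair.values()])}
    rows = []
    for year in sorted(by_year):
        pair = by_year[year]
        rows.append({
            "year": year,
            "S1": pair.get(1).estimate if 1 in pair else np.nan,
            "SE1": pair.get(1).se if 1 in pair else np.nan,
            "S2": pair.get(2).estimate if 2 in pair else np.nan,
            "SE2": pair.get(2).se if 2 in pair else np.nan,
            "verdict": labels.get(year, "not_comparable"),
        })
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df


_VERDICT_MARKS = {"costly": ("v", "white"), "beneficial": ("^", "black"),
                  "equal": ("_", "black")}


def plot_survival_costs(estimates: Iterable[SurvivalEstimate],
                        breeding_success: "pd.Series | None" = None,
                        path: str | Path | None = None):
    """Annual state-specific survival (points +- SE) with per-year verdict
    symbols, optionally over breeding-success bars; returns the figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = verdict_table(estimates)
    fig, ax = plt.subplots(figsize=(8, 4))
    if breeding_success is not None:
        ax2 = ax.twinx()
        ax2.bar(breeding_success.index, breeding_success.values,
                color="0.85", zorder=0)
        ax2.set_ylabel("fledglings per initiated nest")
        ax2.set_zorder(ax.get_zorder() - 1)
        ax.patch.set_visible(False)
    ax.errorbar(table.year, table.S1, yerr=table.SE1, fmt="o", mfc="white",
                mec="black", color="black", capsize=2,
                label="failed/non-breeders (1)")
    ax.errorbar(table.year + 0.15, table.S2, yerr=table.SE2, fmt="o",
                color="black", capsize=2, label="successful breeders (2)")
    for _, row in table.iterrows():
        mark = _VERDICT_MARKS.get(row.verdict)
        if mark is not None:
            ax.scatter([row.year], [1.02], marker=mark[0], c=mark[1],
                       edgecolors="black", s=60, clip_on=False)
    ax.set_xlabel("year")
    ax.set_ylabel("annual survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
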
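"""Paired-change trending analysis with four-quadrant concordance and an exclusion zone.

For each (patient, wall) the single-wall automated change from baseline to
the postoperative timepoint is paired with the change in the manual global
value (mean over available walls).  Pairs inside the central exclusion box —
changes too small to distinguish from repeatability noise — are excluded;
among the retained pairs the concordance rate is the percentage changing in
the same direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ContractError, UndefinedRateError, UndefinedStatisticError
from .vocab import TIMEPOINTS, WALLS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Trending-analysis knobs.

    ``lsc_mm`` is the half-width of the central exclusion box (the least
    significant change of the automated method under hands-on imaging);
    ``adequacy_threshold_pct`` is the conventional adequacy bar for the
    concordance rate.  ``exclusion_geometry`` selects whether a pair is
    excluded when *both* coordinates are inside the box (square origin box,
    default) or when *either* is.
    """

    lsc_mm: float = 1.8
    adequacy_threshold_pct: float = 90.0
    min_walls_global: int = 2
    exclusion_geometry: Literal["both", "either"] = "both"
    strict_global_walls: bool = False

    def __post_init__(self) -> None:
        if self.lsc_mm < 0:
            raise ConfigurationError("lsc_mm must be >= 0")
        if not (0 < self.adequacy_threshold_pct <= 100):
            raise ConfigurationError("adequacy_threshold_pct must be in (0, 100]")
        if self.min_walls_global not in (1, 2, 3, 4):
            raise ConfigurationError("min_walls_global must be in 1..4")
        if self.exclusion_geometry not in ("both", "either"):
            raise ConfigurationError("exclusion_geometry must be 'both' or 'either'")


@dataclass(frozen=True)
class PairedChange:
    """One (patient, wall) paired change: single-wall auto vs manual global."""

    patient_id: str
    wall: str
    delta_auto_mm: float
    delta_ref_mm: float
    excluded: Optional[bool] = None
    concordant: Optional[bool] = None


@dataclass(frozen=True)
class ConcordanceResult:
    """Concordance-rate summary over a set of paired changes."""

    n_total_pairs: int
    n_retained: int
    n_concordant: int
    rate_pct: float
    adequate: bool

    def __post_init__(self) -> None:
        if not (self.n_concordant <= self.n_retained <= self.n_total_pairs):
            raise ContractError("require n_concordant <= n_retained <= n_total_pairs")

    @property
    def rate_int_pct(self) -> int:
        """Rate rounded half-up to integer percent (reporting convention)."""
        return round_half_up(self.rate_pct)


@dataclass(frozen=True)
class DeltaComparison:
    """Paired comparison of per-wall automated changes vs manual global changes."""

    wall: str
    n: int
    mean_delta_auto_mm: float
    sd_delta_auto_mm: float
    mean_delta_ref_mm: float
    sd_delta_ref_mm: float
    mean_difference_mm: float
    sd_difference_mm: float
    t_statistic: float
    p_value: float


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (matches manuscript-style rounding)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _sign(x: float) -> int:
    return int(x > 0) - int(x < 0)


def global_mapse(wall_values: Iterable[float], cfg: AnalysisConfig | None = None) -> Optional[float]:
    """Mean manual MAPSE over available walls; None (infeasible) below the wall floor."""
    cfg = cfg or AnalysisConfig()
    values = [v for v in wall_values if v is not None and np.isfinite(v)]
    if len(values) < cfg.min_walls_global:
        return None
    return float(np.mean(values))


def _global_by_timepoint(manual: pd.DataFrame, cfg: AnalysisConfig) -> dict[str, Optional[float]]:
    """Manual global MAPSE per timepoint for one patient's manual rows."""
    if cfg.strict_global_walls:
        by_tp = {tp: set(manual.loc[manual["timepoint"] == tp, "wall"]) for tp in TIMEPOINTS}
        common = by_tp["pre_cpb"] & by_tp["icu"]
        manual = manual[manual["wall"].isin(common)]
    out: dict[str, Optional[float]] = {}
    for tp in TIMEPOINTS:
        vals = manual.loc[manual["timepoint"] == tp, "mapse_mm"].tolist()
        out[tp] = global_mapse(vals, cfg)
    return out


def build_pairs(measurements: pd.DataFrame, cfg: AnalysisConfig | None = None) -> list[PairedChange]:
    """Build per-(patient, wall) paired changes from a long-format measurement table.

    A pair requires a feasible automated value for the wall at both timepoints
    and a feasible manual global value at both timepoints; incomplete pairs
    are omitted and their count logged.  Changes are ICU minus baseline.
    """
    cfg = cfg or AnalysisConfig()
    df = measurements.dropna(subset=["mapse_mm"])
    pairs: list[PairedChange] = []
    n_dropped = 0
    for pid, pat in df.groupby("patient_id", sort=True):
        manual = pat[pat["method"] == "manual"]
        g = _global_by_timepoint(manual, cfg)
        auto = pat[pat["method"] == "auto"]
        for wall in WALLS:
            rows = auto[auto["wall"] == wall]
            a = {tp: rows.loc[rows["timepoint"] == tp, "mapse_mm"] for tp in TIMEPOINTS}
            if any(len(a[tp]) == 0 for tp in TIMEPOINTS):
                if any(len(a[tp]) > 0 for tp in TIMEPOINTS):
                    n_dropped += 1
                continue
            if g["pre_cpb"] is None or g["icu"] is None:
                n_dropped += 1
                continue
            delta_auto = float(a["icu"].iloc[0]) - float(a["pre_cpb"].iloc[0])
            delta_ref = g["icu"] - g["pre_cpb"]
            pairs.append(PairedChange(str(pid), wall, delta_auto, delta_ref))
    if n_dropped:
        logger.info("build_pairs omitted %d incomplete pair(s)", n_dropped)
    if not pairs:
        logger.warning("no complete (patient, wall) pair in the measurement table")
    return pairs


def apply_exclusion_zone(pairs: Sequence[PairedChange], cfg: AnalysisConfig | None = None) -> list[PairedChange]:
    """Flag each pair as excluded (inside the origin box) or concordant/discordant.

    With the default square-box geometry a pair is excluded only when *both*
    |changes| are below ``lsc_mm``.  A retained pair is concordant when the
    two changes share a sign; an exact-zero change agrees only with another
    exact zero.
    """
    cfg = cfg or AnalysisConfig()
    out: list[PairedChange] = []
    for p in pairs:
        inside_auto = abs(p.delta_auto_mm) < cfg.lsc_mm
        inside_ref = abs(p.delta_ref_mm) < cfg.lsc_mm
        excluded = (inside_auto and inside_ref) if cfg.exclusion_geometry == "both" else (inside_auto or inside_ref)
        if excluded:
            out.append(replace(p, excluded=True, concordant=None))
        else:
            concordant = _sign(p.delta_auto_mm) == _sign(p.delta_ref_mm)
            out.append(replace(p, excluded=False, concordant=concordant))
    return out


def concordance_rate(pairs: Sequence[PairedChange], cfg: AnalysisConfig | None = None) -> ConcordanceResult:
    """Concordance rate over the retained pairs of an exclusion-flagged set."""
    cfg = cfg or AnalysisConfig()
    if any(p.excluded is None for p in pairs):
        raise ContractError("apply_exclusion_zone must run before concordance_rate")
    retained = [p for p in pairs if not p.excluded]
    if not retained:
        raise UndefinedRateError("no retained pairs; concordance rate undefined")
    n_conc = sum(bool(p.concordant) for p in retained)
    rate = round(100.0 * n_conc / len(retained), 1)
    adequate = round_half_up(rate) >= cfg.adequacy_threshold_pct
    return ConcordanceResult(len(pairs), len(retained), n_conc, rate, adequate)


def concordance_by_wall(pairs: Sequence[PairedChange], cfg: AnalysisConfig | None = None) -> dict[str, Optional[ConcordanceResult]]:
    """Per-wall concordance results (None where a wall has no retained pair)."""
    out: dict[str, Optional[ConcordanceResult]] = {}
    for wall in WALLS:
        sub = [p for p in pairs if p.wall == wall]
        try:
            out[wall] = concordance_rate(sub, cfg) if sub else None
        except UndefinedRateError:
            out[wall] = None
    return out


def paired_delta_comparison(pairs: Sequence[PairedChange], wall: str = "") -> DeltaComparison:
    """Paired t test of automated vs reference changes over complete pairs.

    Uses *all* supplied pairs — the exclusion zone does not apply to this
    comparison.  Requires n >= 2.
    """
    if len(pairs) < 2:
        raise UndefinedStatisticError("paired comparison requires at least 2 pairs")
    da = np.array([p.delta_auto_mm for p in pairs])
    dr = np.array([p.delta_ref_mm for p in pairs])
    diff = da - dr
    if np.allclose(diff, diff[0]):
        # constant difference: the paired t statistic degenerates
        if np.isclose(diff[0], 0.0):
            t_stat, p_val = 0.0, 1.0
        else:
            t_stat, p_val = float(np.sign(diff[0])) * float("inf"), 0.0
    else:
        t_stat, p_val = stats.ttest_rel(da, dr)
    return DeltaComparison(
        wall=wall,
        n=len(pairs),
        mean_delta_auto_mm=float(np.mean(da)),
        sd_delta_auto_mm=float(np.std(da, ddof=1)),
        mean_delta_ref_mm=float(np.mean(dr)),
        sd_delta_ref_mm=float(np.std(dr, ddof=1)),
        mean_difference_mm=float(np.mean(diff)),
        sd_difference_mm=float(np.std(diff, ddof=1)),
        t_statistic=float(t_stat),
        p_value=float(p_val),
    )


def _quadrant_panel(ax, pairs: Sequence[PairedChange], cfg: AnalysisConfig, title: str) -> None:
    from matplotlib.patches import Rectangle

    lim_vals = [abs(p.delta_auto_mm) for p in pairs] + [abs(p.delta_ref_mm) for p in pairs] + [2 * cfg.lsc_mm]
    lim = 1.1 * max(lim_vals)
    retained = [p for p in pairs if p.excluded is False]
    excluded = [p for p in pairs if p.excluded]
    ax.axhline(0, color="0.6", lw=0.8)
    ax.axvline(0, color="0.6", lw=0.8)
    ax.plot([-lim, lim], [-lim, lim], ls="--", color="0.4", lw=0.9)
    box = cfg.lsc_mm
    ax.add_patch(Rectangle((-box, -box), 2 * box, 2 * box, fill=False, edgecolor="tab:red", lw=1.0))
    if excluded:
        ax.scatter([p.delta_ref_mm for p in excluded], [p.delta_auto_mm for p in excluded],
                   s=14, c="0.7", label="excluded")
    if retained:
        ax.scatter([p.delta_ref_mm for p in retained], [p.delta_auto_mm for p in retained],
                   s=16, c="tab:blue", label="retained")
    try:
        res = concordance_rate(pairs, cfg)
        note = f"n={res.n_retained}, concordance {res.rate_pct:.0f}%"
    except (UndefinedRateError, ContractError):
        note = "rate undefined"
    ax.set_title(f"{title}\n{note}", fontsize=9)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_xlabel("Δ manual global (mm)", fontsize=8)
    ax.set_ylabel("Δ single-wall auto (mm)", fontsize=8)
    ax.set_aspect("equal")


def four_quadrant_plot(
    pairs: Sequence[PairedChange],
    cfg: AnalysisConfig | None = None,
    path: str = "four_quadrant.png",
    per_wall: bool = False,
    title: str = "Trending ability",
) -> str:
    """Write a four-quadrant scatter (pooled, or one panel per wall) to ``path``.

    Output bytes are deterministic for a fixed input (no timestamps embedded).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cfg = cfg or AnalysisConfig()
    if not pairs:
        raise ContractError("four_quadrant_plot requires at least one pair")
    plt.rcParams["svg.hashsalt"] = "mapsetrend"
    if per_wall:
        fig, axes = plt.subplots(2, 2, figsize=(8, 8))
        for ax, wall in zip(axes.ravel(), WALLS):
            sub = [p for p in pairs if p.wall == wall]
            if sub:
                _quadrant_panel(ax, sub, cfg, wall)
            else:
                ax.set_axis_off()
                ax.set_title(f"{wall}\n(no pairs)", fontsize=9)
    else:
        fig, ax = plt.subplots(figsize=(5, 5))
        _quadrant_panel(ax, pairs, cfg, title)
    fig.tight_layout()
    metadata = {"Date": None} if str(path).endswith(".svg") else None
    fig.savefig(path, dpi=150, metadata=metadata)
    plt.close(fig)
    return str(path)


def pairs_to_frame(pairs: Sequence[PairedChange]) -> pd.DataFrame:
    """Flatten paired changes into a DataFrame (handy for reports and tests)."""
    return pd.DataFrame([vars(p) for p in pairs])
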
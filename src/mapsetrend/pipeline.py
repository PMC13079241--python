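"""End-to-end driver: simulate -> extract -> trend -> RWMA -> report.

The report reconciles every n along the filtering chain (enrolled ->
analyzed -> complete pairs -> retained pairs) and bundles the per-wall and
pooled concordance, feasibility, the paired-delta comparison table, the
inter-rater kappa, and the pattern-stratified concordance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import pandas as pd

from . import io as mio
from .errors import UndefinedRateError, UndefinedStatisticError
from .extraction import ExtractionConfig, WallMeasurement, extract_track, feasibility_rate
from .rwma import adjudicate_table, classify_all_patterns, cohens_kappa, pattern_concordance
from .synthdata import CohortConfig, TrackConfig, generate_annulus_track, generate_cohort
from .trending import (
    AnalysisConfig,
    ConcordanceResult,
    PairedChange,
    apply_exclusion_zone,
    build_pairs,
    concordance_by_wall,
    concordance_rate,
    four_quadrant_plot,
    paired_delta_comparison,
)
from .vocab import PATTERNS, TIMEPOINTS, WALLS

logger = logging.getLogger(__name__)


@dataclass
class EnrollmentLog:
    """Bookkeeping of the post-enrollment cohort filter."""

    n_enrolled: int
    n_analyzed: int
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (patient_id, reason)


def filter_enrolled(measurements: pd.DataFrame, n_enrolled: Optional[int] = None) -> tuple[pd.DataFrame, EnrollmentLog]:
    """Drop patients lacking any measurement at one of the two timepoints.

    Every exclusion is logged with the patient id and the missing timepoint.
    ``n_enrolled`` defaults to the number of distinct patients in the table.
    """
    patients = sorted(measurements["patient_id"].unique())
    n0 = n_enrolled if n_enrolled is not None else len(patients)
    excluded: list[tuple[str, str]] = []
    keep: list[str] = []
    for pid in patients:
        tps = set(measurements.loc[measurements["patient_id"] == pid, "timepoint"])
        missing = [tp for tp in TIMEPOINTS if tp not in tps]
        if missing:
            reason = f"missing {' and '.join(missing)} recordings"
            excluded.append((pid, reason))
            logger.info("excluding patient %s: %s", pid, reason)
        else:
            keep.append(pid)
    filtered = measurements[measurements["patient_id"].isin(keep)].reset_index(drop=True)
    return filtered, EnrollmentLog(n_enrolled=n0, n_analyzed=len(keep), excluded=excluded)


def _concordance_dict(res: Optional[ConcordanceResult]) -> Optional[dict[str, Any]]:
    if res is None:
        return None
    d = dataclasses.asdict(res)
    d["rate_int_pct"] = res.rate_int_pct
    return d


@dataclass
class Report:
    """Machine-readable summary of one pipeline run."""

    seed: int
    ns: dict[str, int]
    feasibility_pct: dict[str, Optional[float]]
    concordance_pooled: Optional[dict[str, Any]]
    concordance_by_wall: dict[str, Optional[dict[str, Any]]]
    delta_comparisons: list[dict[str, Any]]
    kappa: Optional[dict[str, Any]]
    pattern_concordance: dict[str, Optional[dict[str, Any]]]
    enrollment: dict[str, Any]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True) + "\n")

    def to_markdown(self, path: str | Path) -> None:
        lines = ["# Trending-analysis report", ""]
        lines.append(f"- seed: {self.seed}")
        for k, v in self.ns.items():
            lines.append(f"- {k}: {v}")
        lines.append("")
        lines.append("## Concordance")
        if self.concordance_pooled:
            c = self.concordance_pooled
            lines.append(
                f"- pooled: {c['rate_pct']:.1f}% ({c['n_concordant']}/{c['n_retained']} retained), "
                f"adequate: {c['adequate']}"
            )
        for wall, c in self.concordance_by_wall.items():
            lines.append(
                f"- {wall}: " + (f"{c['rate_pct']:.1f}% ({c['n_concordant']}/{c['n_retained']})" if c else "undefined")
            )
        lines.append("")
        lines.append("## Feasibility (%)")
        for wall, v in self.feasibility_pct.items():
            lines.append(f"- {wall}: " + (f"{v:.1f}" if v is not None else "undefined"))
        lines.append("")
        lines.append("## Paired-delta comparisons")
        lines.append("| wall | n | Δauto (mm) | Δglobal (mm) | difference (mm) | p |")
        lines.append("|---|---|---|---|---|---|")
        for d in self.delta_comparisons:
            lines.append(
                f"| {d['wall']} | {d['n']} | {d['mean_delta_auto_mm']:.2f} ± {d['sd_delta_auto_mm']:.2f} "
                f"| {d['mean_delta_ref_mm']:.2f} ± {d['sd_delta_ref_mm']:.2f} "
                f"| {d['mean_difference_mm']:.2f} ± {d['sd_difference_mm']:.2f} | {d['p_value']:.3g} |"
            )
        lines.append("")
        lines.append("## Inter-rater agreement")
        if self.kappa and self.kappa.get("kappa") is not None:
            lines.append(f"- Cohen's kappa (obs1 vs obs2): {self.kappa['kappa']:.3f} over {self.kappa['n_items']} items")
        else:
            lines.append("- Cohen's kappa: undefined")
        lines.append("")
        lines.append("## Pattern-stratified concordance")
        for name in PATTERNS:
            c = self.pattern_concordance.get(name)
            lines.append(
                f"- {name}: " + (f"{c['rate_pct']:.1f}% ({c['n_concordant']}/{c['n_retained']})" if c else "undefined")
            )
        Path(path).write_text("\n".join(lines) + "\n")


def analyze_cohort(
    measurements: pd.DataFrame,
    ratings: Optional[pd.DataFrame] = None,
    analysis_cfg: AnalysisConfig | None = None,
    seed: int = 0,
    n_enrolled: Optional[int] = None,
    out_dir: Optional[str | Path] = None,
    fig_format: str = "png",
) -> tuple[Report, list[PairedChange]]:
    """Trend + RWMA analysis of a measurement table; optionally writes figures."""
    cfg = analysis_cfg or AnalysisConfig()
    measurements, enrollment = filter_enrolled(measurements, n_enrolled)
    pairs = apply_exclusion_zone(build_pairs(measurements, cfg), cfg)

    try:
        pooled = concordance_rate(pairs, cfg)
    except UndefinedRateError:
        pooled = None
    per_wall = concordance_by_wall(pairs, cfg)

    delta_rows = []
    for wall in WALLS:
        sub = [p for p in pairs if p.wall == wall]
        try:
            delta_rows.append(dataclasses.asdict(paired_delta_comparison(sub, wall)))
        except UndefinedStatisticError:
            pass

    feas: dict[str, Optional[float]] = {}
    auto = measurements[measurements["method"] == "auto"]
    for wall in WALLS:
        # missing rows are infeasible recordings; denominator = patients x timepoints
        n_expected = measurements["patient_id"].nunique() * len(TIMEPOINTS)
        n_present = int(((auto["wall"] == wall) & auto["mapse_mm"].notna()).sum())
        feas[wall] = 100.0 * n_present / n_expected if n_expected else None

    kappa_dict = None
    patt: dict[str, Optional[dict[str, Any]]] = {name: None for name in PATTERNS}
    if ratings is not None and len(ratings):
        wide = ratings.pivot_table(
            index=["patient_id", "timepoint", "wall"], columns="observer", values="rating", aggfunc="first"
        )
        both = wide.dropna(subset=["obs1", "obs2"])
        if len(both):
            kres = cohens_kappa(both["obs1"].tolist(), both["obs2"].tolist())
            kappa_dict = dataclasses.asdict(kres)
            kappa_dict["categories"] = list(kres.categories)
        adjudicated = adjudicate_table(ratings)
        patterns = classify_all_patterns(adjudicated)
        patt = {k: _concordance_dict(v) for k, v in pattern_concordance(pairs, patterns, cfg).items()}

    ns = {
        "n_enrolled": enrollment.n_enrolled,
        "n_analyzed": enrollment.n_analyzed,
        "n_complete_pairs": len(pairs),
        "n_retained_pairs": pooled.n_retained if pooled else 0,
        "n_excluded_pairs": (len(pairs) - pooled.n_retained) if pooled else len(pairs),
    }
    report = Report(
        seed=seed,
        ns=ns,
        feasibility_pct=feas,
        concordance_pooled=_concordance_dict(pooled),
        concordance_by_wall={w: _concordance_dict(c) for w, c in per_wall.items()},
        delta_comparisons=delta_rows,
        kappa=kappa_dict,
        pattern_concordance=patt,
        enrollment={
            "n_enrolled": enrollment.n_enrolled,
            "n_analyzed": enrollment.n_analyzed,
            "excluded": [{"patient_id": p, "reason": r} for p, r in enrollment.excluded],
        },
    )

    if out_dir is not None and pairs:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        four_quadrant_plot(pairs, cfg, str(out_dir / f"four_quadrant_pooled.{fig_format}"), title="Pooled trending ability")
        four_quadrant_plot(pairs, cfg, str(out_dir / f"four_quadrant_walls.{fig_format}"), per_wall=True)
        if ratings is not None and len(ratings):
            _pattern_figure(pairs, ratings, cfg, out_dir / f"four_quadrant_patterns.{fig_format}")
    return report, pairs


def _pattern_figure(pairs: Sequence[PairedChange], ratings: pd.DataFrame, cfg: AnalysisConfig, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .trending import _quadrant_panel

    adjudicated = adjudicate_table(ratings)
    patterns = classify_all_patterns(adjudicated)
    plt.rcParams["svg.hashsalt"] = "mapsetrend"
    fig, axes = plt.subplots(2, 2, figsize=(8, 8))
    for ax, name in zip(axes.ravel(), PATTERNS):
        sub = [
            p for p in pairs
            if (pat := patterns.get((p.patient_id, p.wall))) is not None and name in pat.memberships
        ]
        if sub:
            _quadrant_panel(ax, sub, cfg, name)
        else:
            ax.set_axis_off()
            ax.set_title(f"{name}\n(no pairs)", fontsize=9)
    fig.tight_layout()
    metadata = {"Date": None} if str(path).endswith(".svg") else None
    fig.savefig(path, dpi=150, metadata=metadata)
    plt.close(fig)


def extract_tracks_dir(
    tracks_dir: str | Path,
    cfg: ExtractionConfig | None = None,
) -> list[WallMeasurement]:
    """Run the extraction chain over every ``*.csv`` track in a directory.

    Track files are named ``<patient>_<timepoint>_<wall>.csv`` (the layout
    written by the simulate stage).
    """
    cfg = cfg or ExtractionConfig()
    out: list[WallMeasurement] = []
    for path in sorted(Path(tracks_dir).glob("*.csv")):
        parts = path.stem.rsplit("_", 2)
        if len(parts) == 3 and parts[2] in WALLS:
            pid, tp, wall = parts[0], parts[1], parts[2]
            tp = "pre_cpb" if tp.startswith("pre") else tp
        else:
            pid, tp, wall = path.stem, "icu", "anterior"
        track = mio.read_track(path)
        wm, _ = extract_track(track, tp, cfg, patient_id=pid, wall=wall)
        out.append(wm)
    return out


def run_pipeline(
    out_dir: str | Path,
    track_cfg: TrackConfig | None = None,
    cohort_cfg: CohortConfig | None = None,
    extraction_cfg: ExtractionConfig | None = None,
    analysis_cfg: AnalysisConfig | None = None,
    seed: int = 0,
    n_demo_tracks: int = 4,
    fig_format: str = "png",
) -> Report:
    """Simulate a cohort and demo tracks, extract, analyze, and write the report.

    Deterministic for a fixed seed.  Writes ``cohort.csv``, ``ratings.csv``,
    ``tracks/``, ``track_measurements.csv``, ``report.json``,
    ``report.md``, ``table2.csv`` and the three figures under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort_cfg = dataclasses.replace(cohort_cfg or CohortConfig(), seed=seed)
    track_cfg = track_cfg or TrackConfig()

    measurements, ratings, truth = generate_cohort(cohort_cfg)
    mio.write_cohort(measurements, out_dir / "cohort.csv")
    mio.write_ratings(ratings, out_dir / "ratings.csv")

    tracks_dir = out_dir / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    for i in range(n_demo_tracks):
        tcfg = dataclasses.replace(track_cfg, seed=seed * 10_000 + i)
        track = generate_annulus_track(tcfg)
        wall = WALLS[i % len(WALLS)]
        tp = TIMEPOINTS[i % len(TIMEPOINTS)]
        mio.write_track(track, tracks_dir / f"T{i + 1:03d}_{tp}_{wall}.csv")
    track_measurements = extract_tracks_dir(tracks_dir, extraction_cfg)
    pd.DataFrame([dataclasses.asdict(m) for m in track_measurements]).to_csv(
        out_dir / "track_measurements.csv", index=False
    )
    for wall in sorted({m.wall for m in track_measurements}):
        try:
            logger.info("track feasibility %s: %.0f%%", wall, feasibility_rate(track_measurements, wall))
        except UndefinedRateError:
            pass

    report, _pairs = analyze_cohort(
        measurements, ratings, analysis_cfg, seed=seed, out_dir=out_dir, fig_format=fig_format
    )
    report.to_json(out_dir / "report.json")
    report.to_markdown(out_dir / "report.md")
    pd.DataFrame(report.delta_comparisons).to_csv(out_dir / "table2.csv", index=False)
    return report
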
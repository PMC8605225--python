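"""Full interrater-agreement study over a cohort.

For every patient and structure, the pipeline harmonizes the raters'
contours to their maximal common cranio-caudal extent (the prostate is
never cropped), derives the inferior-half subsets of the neurovascular
bundles, computes Dice / average surface distance / Hausdorff distance for
every unordered rater pair, and records per-rater volumes and per-patient
harmonized border distances.  Results are summarized as median (IQR) in a
report table with one column per structure — four raters over 15 patients
yield 6 pairs x 15 = 90 pair records and 60 volume records per structure.

Failures (missing masks, no longitudinal overlap, a rater emptied by the
crop) are logged and skipped, never silently dropped: per structure,
records + logged pair failures = C(n_raters, 2) x n_patients.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyMaskError, ManifestError, NoLongitudinalOverlapError
from .grid import NVB_LEFT, NVB_RIGHT, PROSTATE, StructureMask, inferior_half_label
from .harmonization import (
    LongitudinalInterval,
    common_extent,
    crop_to_interval,
    inferior_half,
)
from .metrics import AsdMode, compute_pair_metrics, volume_cc


class MaskSource(Protocol):
    """Anything that can hand out cohort masks (manifest or in-memory)."""

    patients: list[str]
    raters: list[str]
    structures: list[str]

    def load(self, patient: str, rater: str, structure: str) -> StructureMask | None: ...


@dataclass(frozen=True)
class StudyConfig:
    """Knobs of the agreement study.

    ``volume_timing`` selects whether reported volumes of cropped
    structures are taken after ("post") or before ("pre") harmonization;
    derived inferior-half volumes are always post-crop.
    """

    asd_mode: AsdMode = "pooled"
    hausdorff_percentile: float = 100.0
    no_crop_structures: tuple[str, ...] = (PROSTATE,)
    inferior_half_structures: tuple[str, ...] = (NVB_LEFT, NVB_RIGHT)
    volume_timing: str = "post"  # "post" | "pre"
    max_failure_fraction: float = 0.5


@dataclass(frozen=True)
class PairMetricRecord:
    patient_id: str
    structure: str
    rater_a: str
    rater_b: str
    dsc: float
    avg_surface_distance_mm: float
    hausdorff_mm: float


@dataclass(frozen=True)
class VolumeRecord:
    patient_id: str
    structure: str
    rater_id: str
    volume_cc: float


@dataclass(frozen=True)
class BorderDistanceRecord:
    patient_id: str
    structure: str
    border_distance_mm: float


@dataclass
class StudyResult:
    records: list[PairMetricRecord] = field(default_factory=list)
    volumes: list[VolumeRecord] = field(default_factory=list)
    border_distances: list[BorderDistanceRecord] = field(default_factory=list)
    failures: list[str] = field(default_factory=list)
    structures: list[str] = field(default_factory=list)
    n_raters: int = 0
    n_patients: int = 0


def enumerate_rater_pairs(raters: Sequence[str]) -> list[tuple[str, str]]:
    """All C(n, 2) unordered rater pairs, deduplicated, in sorted order."""
    unique = sorted(set(raters))
    if len(unique) < 2:
        raise ValueError(f"need >= 2 distinct raters, got {len(unique)}")
    return list(combinations(unique, 2))


def summarize_median_iqr(values: Iterable[float]) -> tuple[float, float, float]:
    """(median, q1, q3) with quartiles by linear interpolation between
    order statistics — the common default of mainstream statistics
    software, pinned here so reported numbers are reproducible."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("summarize_median_iqr needs at least one value")
    med, q1, q3 = np.quantile(arr, [0.5, 0.25, 0.75], method="linear")
    return float(med), float(q1), float(q3)


def _process_structure(
    patient: str,
    structure: str,
    masks: dict[str, StructureMask],
    all_raters: Sequence[str],
    config: StudyConfig,
    result: StudyResult,
) -> None:
    """Harmonize one (patient, structure), emit records into ``result``."""
    pairs = enumerate_rater_pairs(all_raters)

    def fail_pairs(raters_lost: set[str], why: str) -> None:
        for ra, rb in pairs:
            if ra in raters_lost or rb in raters_lost:
                result.failures.append(
                    f"{patient}/{structure}/{ra}-{rb}: {why}"
                )

    missing = {r for r in all_raters if r not in masks or masks[r] is None}
    if missing:
        fail_pairs(missing, "missing mask")
    available = {r: m for r, m in masks.items() if m is not None}
    if len(available) < 2:
        fail_pairs(set(available), "fewer than two raters available")
        return

    crop = structure not in config.no_crop_structures
    interval: LongitudinalInterval | None = None
    if crop:
        try:
            interval = common_extent(list(available.values()))
        except (NoLongitudinalOverlapError, EmptyMaskError) as exc:
            fail_pairs(set(available), str(exc))
            return
        cropped: dict[str, StructureMask] = {}
        for r, m in available.items():
            try:
                cropped[r] = crop_to_interval(m, interval)
            except EmptyMaskError as exc:
                fail_pairs({r}, f"empty after harmonization: {exc}")
        analysed = cropped
    else:
        analysed = available

    if len(analysed) < 2:
        return

    _emit(patient, structure, analysed, config, result)
    if crop and interval is not None:
        result.border_distances.append(
            BorderDistanceRecord(
                patient_id=patient,
                structure=structure,
                border_distance_mm=interval.border_distance_mm(
                    next(iter(analysed.values())).grid.slice_spacing_mm
                ),
            )
        )
        if config.volume_timing == "pre":
            vol_masks = {r: available[r] for r in analysed}
        else:
            vol_masks = analysed
    else:
        vol_masks = analysed
    for r in sorted(vol_masks):
        result.volumes.append(
            VolumeRecord(
                patient_id=patient,
                structure=structure,
                rater_id=r,
                volume_cc=volume_cc(vol_masks[r]),
            )
        )

    # derived inferior-half subset
    if crop and interval is not None and structure in config.inferior_half_structures:
        label = inferior_half_label(structure)
        dz = next(iter(analysed.values())).grid.slice_spacing_mm
        sub = inferior_half(interval, dz)
        sub_masks: dict[str, StructureMask] = {}
        for r, m in analysed.items():
            try:
                sub_masks[r] = crop_to_interval(m, sub).relabeled(label)
            except EmptyMaskError as exc:
                result.failures.append(
                    f"{patient}/{label}/{r}: empty inferior half: {exc}"
                )
        if len(sub_masks) >= 2:
            _emit(patient, label, sub_masks, config, result)
            result.border_distances.append(
                BorderDistanceRecord(
                    patient_id=patient,
                    structure=label,
                    border_distance_mm=sub.border_distance_mm(dz),
                )
            )
            for r in sorted(sub_masks):
                result.volumes.append(
                    VolumeRecord(
                        patient_id=patient,
                        structure=label,
                        rater_id=r,
                        volume_cc=volume_cc(sub_masks[r]),
                    )
                )


def _emit(
    patient: str,
    label: str,
    masks: dict[str, StructureMask],
    config: StudyConfig,
    result: StudyResult,
) -> None:
    metrics = compute_pair_metrics(
        masks,
        asd_mode=config.asd_mode,
        hausdorff_percentile=config.hausdorff_percentile,
    )
    for (ra, rb), pm in sorted(metrics.items()):
        result.records.append(
            PairMetricRecord(
                patient_id=patient,
                structure=label,
                rater_a=ra,
                rater_b=rb,
                dsc=pm.dsc,
                avg_surface_distance_mm=pm.avg_surface_distance_mm,
                hausdorff_mm=pm.hausdorff_mm,
            )
        )


def run_agreement_study(
    source: MaskSource, config: StudyConfig | None = None
) -> StudyResult:
    """Run the whole study over a manifest or in-memory cohort."""
    config = config or StudyConfig()
    raters = sorted(set(source.raters))
    result = StudyResult(n_raters=len(raters), n_patients=len(source.patients))
    structures: list[str] = []
    for s in source.structures:
        structures.append(s)
        if s in config.inferior_half_structures and s not in config.no_crop_structures:
            structures.append(inferior_half_label(s))
    result.structures = structures

    n_pairs = len(enumerate_rater_pairs(raters))
    expected = n_pairs * len(source.patients) * len(source.structures)
    for patient in source.patients:
        for structure in source.structures:
            masks = {r: source.load(patient, r, structure) for r in raters}
            _process_structure(patient, structure, masks, raters, config, result)
    if expected and len(result.failures) > config.max_failure_fraction * expected:
        raise ManifestError(
            f"{len(result.failures)} failures out of {expected} expected pair "
            f"computations exceeds the threshold "
            f"({config.max_failure_fraction:.0%}); see StudyResult.failures"
        )
    return result


# ---------------------------------------------------------------------------
# Report building
# ---------------------------------------------------------------------------

_METRIC_ORDER = [
    ("volume_cc", "Overall volume (cc)"),
    ("border_distance_mm", "Overall distance between superior and inferior border (mm)"),
    ("dsc", "Overall Dice similarity coefficient"),
    ("avg_surface_distance_mm", "Overall average surface distance (mm)"),
    ("hausdorff_mm", "Overall Hausdorff distance (mm)"),
]


def build_report(result: StudyResult) -> pd.DataFrame:
    """Long-form summary: one row per (structure x metric) with n, median,
    q1, q3 rounded to 2 decimals.  Metrics without data for a structure
    (the uncropped prostate's border distance) appear with n = 0 and NaN
    statistics, rendered "NA" in the text table."""
    by_metric: dict[str, dict[str, list[float]]] = {
        key: {} for key, _ in _METRIC_ORDER
    }
    for rec in result.records:
        by_metric["dsc"].setdefault(rec.structure, []).append(rec.dsc)
        by_metric["avg_surface_distance_mm"].setdefault(rec.structure, []).append(
            rec.avg_surface_distance_mm
        )
        by_metric["hausdorff_mm"].setdefault(rec.structure, []).append(
            rec.hausdorff_mm
        )
    for v in result.volumes:
        by_metric["volume_cc"].setdefault(v.structure, []).append(v.volume_cc)
    for b in result.border_distances:
        by_metric["border_distance_mm"].setdefault(b.structure, []).append(
            b.border_distance_mm
        )

    rows = []
    for key, metric_label in _METRIC_ORDER:
        for structure in result.structures:
            values = by_metric[key].get(structure)
            if values:
                med, q1, q3 = summarize_median_iqr(values)
                rows.append(
                    dict(
                        structure=structure,
                        metric=key,
                        metric_label=metric_label,
                        n=len(values),
                        median=round(med, 2),
                        q1=round(q1, 2),
                        q3=round(q3, 2),
                    )
                )
            else:
                rows.append(
                    dict(
                        structure=structure,
                        metric=key,
                        metric_label=metric_label,
                        n=0,
                        median=np.nan,
                        q1=np.nan,
                        q3=np.nan,
                    )
                )
    return pd.DataFrame(rows)


def _cell(row: pd.Series) -> str:
    if row["n"] == 0:
        return "NA"
    return f"{row['median']:.2f} ({row['q1']:.2f} - {row['q3']:.2f})"


def render_report_text(summary: pd.DataFrame) -> str:
    """Human-readable wide table: metric rows x structure columns, cells
    'median (q1 - q3)', built from the same rounded values as the CSV."""
    structures = list(dict.fromkeys(summary["structure"]))
    lines = []
    header = ["metric [n]"] + structures
    table: list[list[str]] = [header]
    for key, metric_label in _METRIC_ORDER:
        sub = summary[summary["metric"] == key].set_index("structure")
        if sub.empty:
            continue
        ns = sorted({int(n) for n in sub["n"] if n > 0})
        n_str = "/".join(str(n) for n in ns) if ns else "0"
        row = [f"{metric_label} [n={n_str}]"]
        for s in structures:
            row.append(_cell(sub.loc[s]) if s in sub.index else "NA")
        table.append(row)
    widths = [max(len(r[c]) for r in table) for c in range(len(header))]
    for r in table:
        lines.append("  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip())
    return "\n".join(lines) + "\n"


def write_report(
    result: StudyResult,
    out_dir: str | Path,
    config: StudyConfig | None = None,
) -> pd.DataFrame:
    """Write pair_metrics.csv, summary_table.{csv,json,txt}, run_log.txt and
    config_used.json.  Output is deterministic: two runs over the same
    cohort and config produce byte-identical files."""
    config = config or StudyConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    pair_df = pd.DataFrame([asdict(r) for r in result.records])
    pair_df.to_csv(out_dir / "pair_metrics.csv", index=False, float_format="%.6f")

    summary = build_report(result)
    summary.to_csv(out_dir / "summary_table.csv", index=False, float_format="%.2f")
    payload = summary.replace({np.nan: None}).to_dict(orient="records")
    (out_dir / "summary_table.json").write_text(json.dumps(payload, indent=2) + "\n")
    (out_dir / "summary_table.txt").write_text(render_report_text(summary))

    log_lines = [
        f"patients={result.n_patients} raters={result.n_raters}",
        f"structures={','.join(result.structures)}",
        f"pair_records={len(result.records)} volumes={len(result.volumes)} "
        f"border_distances={len(result.border_distances)}",
        f"failures={len(result.failures)}",
        *result.failures,
    ]
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    (out_dir / "config_used.json").write_text(
        json.dumps(asdict(config), indent=2) + "\n"
    )
    return summary
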
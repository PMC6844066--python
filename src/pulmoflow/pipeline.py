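"""End-to-end workflow: simulate → quantify → derive → statistics → report.

The pipeline is file-composable: :func:`run_simulate` writes a cohort dataset
(long-format flow-curve CSVs plus a ground-truth sidecar), :func:`run_analyze`
turns records into a :class:`StudyReport` (per-record index tables, PVDR
table, cohort summaries, hypothesis tests), and :func:`run_report` writes the
report as CSV/JSON with optional plots.  Real scanner-exported flow-curve
CSVs can enter at the analysis stage.

Every report carries provenance: the configuration, its hash, the seed and
the package version, so any number in it is reproducible from config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import io as pio
from . import pbvv as pb
from . import stats as st
from . import synth
from .exceptions import InvalidInputError, InvalidParameterError
from .types import (
    LATERAL_POSITIONS,
    POSITIONS,
    VESSELS,
    AreaResult,
    PositionEffectConfig,
    SubjectPositionRecord,
)

__all__ = ["RunConfig", "StudyReport", "run_simulate", "load_dataset", "run_analyze", "run_report"]

logger = logging.getLogger("pulmoflow")

PathLike = Union[str, Path]


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration for a full pipeline run.

    ``seed`` is mandatory and drives every random choice.  The effect gains
    parameterize the positional physiology the generator emulates; analysis
    toggles select curve-space vs image-space entry, cumulative-curve drift
    correction (off by default) and the ICC variant.
    """

    seed: int
    n_subjects: int = 10
    n_frames: int = 35
    flow_noise_sd: float = synth.DEFAULT_FLOW_NOISE_SD
    stroke_volume: float = synth.DEFAULT_STROKE_VOLUME_ML
    heart_rate: float = synth.DEFAULT_HEART_RATE_BPM
    supine_right_fraction: float = synth.DEFAULT_SUPINE_RIGHT_FRACTION
    dependent_flow_gain: float = 0.25
    dependent_venous_area_gain: float = 0.25
    nondependent_pvdr_gain: float = 0.90
    drift_correction: bool = False
    icc_variant: str = "ICC2"
    render_images: bool = False

    def __post_init__(self):
        if self.seed is None:
            raise InvalidParameterError("seed is mandatory")

    def effects(self) -> Dict[str, PositionEffectConfig]:
        out = {}
        for pos in POSITIONS:
            lateral = pos in LATERAL_POSITIONS
            out[pos] = PositionEffectConfig(
                position=pos,
                dependent_flow_gain=self.dependent_flow_gain if lateral else 0.0,
                dependent_venous_area_gain=self.dependent_venous_area_gain if lateral else 0.0,
                nondependent_pvdr_gain=self.nondependent_pvdr_gain if lateral else 0.0,
            )
        return out

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        return cls.from_dict(pio.load_yaml(path))

    def to_yaml(self, path: PathLike) -> None:
        pio.dump_yaml(self.to_dict(), path)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _version() -> str:
    from . import __version__

    return __version__


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def run_simulate(config: RunConfig, outdir: PathLike) -> Path:
    """Generate a cohort dataset on disk and return its directory.

    Layout: ``curves/<subject>_<position>.csv`` (long format, 7 vessels),
    ``areas.csv``, ``ground_truth.csv``, ``config.yaml``; with
    ``render_images=True`` additionally ``images/`` with NIfTI series for the
    first subject's supine vessels.
    """
    outdir = Path(outdir)
    (outdir / "curves").mkdir(parents=True, exist_ok=True)
    records, truth = synth.generate_cohort(
        n_subjects=config.n_subjects,
        effects=config.effects(),
        seed=config.seed,
        n_frames=config.n_frames,
        flow_noise_sd=config.flow_noise_sd,
        stroke_volume=config.stroke_volume,
        heart_rate=config.heart_rate,
        supine_right_fraction=config.supine_right_fraction,
    )

    area_rows, truth_rows = [], []
    for rec in records:
        pio.write_flow_curves_csv(
            rec.curves, outdir / "curves" / f"{rec.subject_id}_{rec.position}.csv"
        )
        if rec.areas:
            for vessel, area in rec.areas.items():
                area_rows.append(
                    {
                        "subject": rec.subject_id,
                        "position": rec.position,
                        "vessel_id": vessel,
                        "mean_area_mm2": area.mean_area,
                    }
                )
        gt = truth.per_record[(rec.subject_id, rec.position)]
        truth_rows.append(
            {
                "subject": rec.subject_id,
                "position": rec.position,
                "stroke_volume_ml": gt.stroke_volume,
                "right_fraction": gt.right_fraction,
                "pbvv_right_ml": gt.true_pbvv["right"],
                "pbvv_left_ml": gt.true_pbvv["left"],
                "pbvv_bilateral_ml": gt.true_pbvv["bilateral"],
            }
        )
        logger.info(
            "simulated %s %s: sv=%.1f ml, right fraction=%.3f",
            rec.subject_id, rec.position, gt.stroke_volume, gt.right_fraction,
        )
    pd.DataFrame(area_rows).to_csv(outdir / "areas.csv", index=False, float_format="%.10g")
    pd.DataFrame(truth_rows).to_csv(outdir / "ground_truth.csv", index=False, float_format="%.10g")
    config.to_yaml(outdir / "config.yaml")

    if config.render_images:
        imgdir = outdir / "images"
        imgdir.mkdir(exist_ok=True)
        rec = records[0]
        gt = truth.per_record[(rec.subject_id, rec.position)]
        rng = np.random.default_rng(config.seed)
        for vessel in VESSELS:
            venc = {"MPA": 100.0, "RPA": 125.0, "LPA": 125.0}.get(vessel, 80.0)
            # the parabolic profile doubles the centreline velocity; raise the
            # encoding limit to cover the implied peak instead of refusing
            area = gt.true_areas.get(vessel, synth.DEFAULT_AREAS_MM2[vessel])
            peak = 2.0 * float(np.max(np.abs(rec.curves[vessel].flow))) / area * 100.0
            venc = max(venc, 25.0 * np.ceil(1.05 * peak / 25.0))
            rendered = synth.render_pc_series(
                rec.curves[vessel],
                vessel_area=area,
                venc=venc,
                noise_sd=0.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            stem = f"{rec.subject_id}_{rec.position}_{vessel}"
            pio.write_vessel_series(
                rendered.series,
                imgdir / f"{stem}_mag.nii.gz",
                imgdir / f"{stem}_vel.nii.gz",
                imgdir / f"{stem}.json",
            )
    return outdir


def load_dataset(dataset_dir: PathLike) -> List[SubjectPositionRecord]:
    """Load a simulated (or equivalently structured) dataset from disk."""
    dataset_dir = Path(dataset_dir)
    curve_files = sorted((dataset_dir / "curves").glob("*.csv"))
    if not curve_files:
        raise InvalidInputError(f"no curve CSVs under {dataset_dir}/curves")
    areas_path = dataset_dir / "areas.csv"
    areas_df = pd.read_csv(areas_path) if areas_path.exists() else None

    records = []
    for path in curve_files:
        subject, _, position = path.stem.rpartition("_")
        # positions contain an underscore (right_lateral); re-split on known names
        for pos in POSITIONS:
            if path.stem.endswith(f"_{pos}"):
                subject = path.stem[: -len(pos) - 1]
                position = pos
                break
        curves = pio.read_flow_curves_csv(path)
        missing = [v for v in VESSELS if v not in curves]
        if missing:
            logger.warning("excluding %s: missing vessels %s", path.stem, missing)
            continue
        rr = curves["MPA"].rr_interval
        areas = None
        if areas_df is not None:
            sub = areas_df[(areas_df["subject"] == subject) & (areas_df["position"] == position)]
            if len(sub):
                n = curves["MPA"].n_frames
                areas = {
                    row.vessel_id: AreaResult(np.full(n, row.mean_area_mm2))
                    for row in sub.itertuples()
                }
        records.append(
            SubjectPositionRecord(
                subject_id=subject,
                position=position,
                curves=curves,
                heart_rate=60000.0 / rr,
                areas=areas,
            )
        )
    return records


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyReport:
    """All pipeline outputs for one cohort, with provenance."""

    metrics: pd.DataFrame  # subject, position, scope, metric, value
    pvdr: pd.DataFrame
    summary: pd.DataFrame  # position, scope, metric, mean, sem, n
    tests: pd.DataFrame  # test, statistic, p_value, n
    provenance: Dict[str, object]
    example: Dict[str, object] = field(default_factory=dict)


def metrics_from_records(
    records: Sequence[SubjectPositionRecord], drift_correction: bool = False
) -> pd.DataFrame:
    """Long-format per-record metric table from the derived indices."""
    rows = []

    def add(rec, scope, metric, value):
        rows.append(
            {
                "subject": rec.subject_id,
                "position": rec.position,
                "scope": scope,
                "metric": metric,
                "value": float(value),
            }
        )

    for rec in records:
        res = pb.analyze_record(rec, drift_correction=drift_correction)
        for scope, r in res["pbvv"].items():
            add(rec, scope, "pbvv_ml", r.pbvv)
            add(rec, scope, "arterial_net_ml", r.arterial_net)
            add(rec, scope, "relative_pbvv_pct", r.relative_pbvv)
        add(rec, "global", "flow_fraction_right_pct", res["flow_fraction_right"])
        add(rec, "global", "superior_split_pct", res["superior_split"])
        add(rec, "global", "cardiac_output_l_min", res["cardiac_output"])
        add(rec, "global", "av_mismatch_ml", res["av_mismatch_ml"])
        add(rec, "global", "av_mismatch_pct", res["av_mismatch_pct"])
        add(rec, "global", "heart_rate_bpm", rec.heart_rate)
        for vessel in VESSELS:
            add(rec, vessel, "net_flow_ml", rec.curves[vessel].net_flow())
        if rec.areas:
            for vessel, area in rec.areas.items():
                add(rec, vessel, "mean_area_mm2", area.mean_area)
        logger.info(
            "analyzed %s %s: MPA net=%.1f ml, AV mismatch=%.2f ml (%.2f%%)",
            rec.subject_id, rec.position, res["mpa_net"],
            res["av_mismatch_ml"], res["av_mismatch_pct"],
        )
    return pd.DataFrame(rows)


def pvdr_table(metrics: pd.DataFrame, reference: str = "supine") -> pd.DataFrame:
    """Per-subject, per-lung PVDR of each position against the reference position."""
    rel = metrics[metrics["metric"] == "relative_pbvv_pct"]
    piv = rel.pivot_table(index="subject", columns=["position", "scope"], values="value")
    rows = []
    for subject, row in piv.iterrows():
        for lung, scope in (("right", "right_lung"), ("left", "left_lung")):
            if (reference, scope) not in row.index:
                continue
            ref_val = row[(reference, scope)]
            for position in POSITIONS:
                if position == reference or (position, scope) not in row.index:
                    continue
                new_val = row[(position, scope)]
                rows.append(
                    {
                        "subject": subject,
                        "lung": lung,
                        "position_ref": reference,
                        "position_new": position,
                        "relative_pbvv_ref_pct": ref_val,
                        "relative_pbvv_new_pct": new_val,
                        "pvdr_pct": pb.pvdr(ref_val, new_val),
                    }
                )
    return pd.DataFrame(rows)


def summarize(metrics: pd.DataFrame) -> pd.DataFrame:
    """Cohort mean ± SEM per (position, scope, metric)."""
    rows = []
    for (position, scope, metric), grp in metrics.groupby(["position", "scope", "metric"]):
        values = grp["value"].to_numpy()
        if values.size >= 2:
            mean, sem = st.describe(values)
        else:
            mean, sem = float(values[0]), float("nan")
        rows.append(
            {
                "position": position,
                "scope": scope,
                "metric": metric,
                "mean": mean,
                "sem": sem,
                "n": values.size,
            }
        )
    return pd.DataFrame(rows)


def _paired(metrics: pd.DataFrame, metric: str, scope: str, pos_a: str, pos_b: str,
            scope_b: Optional[str] = None):
    """Subject-aligned value pairs for one metric between two positions/scopes."""
    scope_b = scope_b or scope
    sel = metrics[metrics["metric"] == metric]
    a = sel[(sel["position"] == pos_a) & (sel["scope"] == scope)].set_index("subject")["value"]
    b = sel[(sel["position"] == pos_b) & (sel["scope"] == scope_b)].set_index("subject")["value"]
    common = a.index.intersection(b.index)
    return a.loc[common].to_numpy(), b.loc[common].to_numpy()


def cohort_tests(metrics: pd.DataFrame) -> pd.DataFrame:
    """The study's hypothesis tests on a cohort metric table."""
    rows = []

    def add(name, fn, *args):
        try:
            statistic, p = fn(*args)
            n = len(args[0])
            rows.append({"test": name, "statistic": statistic, "p_value": p, "n": n})
        except Exception as exc:  # degenerate data: record, don't crash the report
            logger.warning("test %s failed: %s", name, exc)
            rows.append({"test": name, "statistic": np.nan, "p_value": np.nan, "n": 0})

    # cardiac output unaffected by position (repeated measures)
    co = metrics[(metrics["metric"] == "cardiac_output_l_min")]
    piv = co.pivot_table(index="subject", columns="position", values="value")[list(POSITIONS)]
    add("cardiac_output_across_positions_friedman", friedman_matrix, piv.to_numpy())

    # right-vs-left arterial net flow per position
    for position in POSITIONS:
        r, l = _paired(metrics, "net_flow_ml", "RPA", position, position, scope_b="LPA")
        add(f"right_vs_left_net_flow_{position}_wilcoxon", st.wilcoxon_signed_rank, r, l)

    # non-dependent lung relative PBVV vs supine (the distensibility-reserve effect)
    for position, nondep_scope in (("right_lateral", "left_lung"), ("left_lateral", "right_lung")):
        new, ref = _paired(metrics, "relative_pbvv_pct", nondep_scope, position, "supine")
        add(f"nondependent_relative_pbvv_{position}_vs_supine_wilcoxon",
            st.wilcoxon_signed_rank, new, ref)

    # superior vs inferior venous net flow in supine and prone
    nets = metrics[metrics["metric"] == "net_flow_ml"]
    for position in ("supine", "prone"):
        sub = nets[nets["position"] == position]
        piv_v = sub.pivot_table(index="subject", columns="scope", values="value")
        if {"RSPV", "LSPV", "RIPV", "LIPV"}.issubset(piv_v.columns):
            sup = (piv_v["RSPV"] + piv_v["LSPV"]).to_numpy()
            inf = (piv_v["RIPV"] + piv_v["LIPV"]).to_numpy()
            add(f"superior_vs_inferior_venous_flow_{position}_wilcoxon",
                st.wilcoxon_signed_rank, sup, inf)

    # dependent vs non-dependent venous area for the same lung across lateral positions
    areas = metrics[metrics["metric"] == "mean_area_mm2"]
    if len(areas):
        for lung, veins, dep_pos, nondep_pos in (
            ("right", ("RSPV", "RIPV"), "right_lateral", "left_lateral"),
            ("left", ("LSPV", "LIPV"), "left_lateral", "right_lateral"),
        ):
            sub = areas[areas["scope"].isin(veins)]
            piv_a = sub.pivot_table(index="subject", columns="position", values="value", aggfunc="sum")
            if dep_pos in piv_a.columns and nondep_pos in piv_a.columns:
                add(f"{lung}_venous_area_dependent_vs_nondependent_wilcoxon",
                    st.wilcoxon_signed_rank,
                    piv_a[dep_pos].to_numpy(), piv_a[nondep_pos].to_numpy())

    return pd.DataFrame(rows)


def friedman_matrix(matrix: np.ndarray) -> Tuple[float, float]:
    return st.friedman(matrix)


def run_analyze(
    records: Sequence[SubjectPositionRecord],
    config: RunConfig,
) -> StudyReport:
    """Analyze cohort records into a full study report."""
    metrics = metrics_from_records(records, drift_correction=config.drift_correction)
    pvdr_df = pvdr_table(metrics)
    summary = summarize(metrics)
    tests = cohort_tests(metrics)

    example: Dict[str, object] = {}
    for rec in records:
        if rec.position == "supine":
            res = pb.analyze_record(rec, drift_correction=config.drift_correction)
            bi = res["pbvv"]["bilateral"]
            example = {
                "subject": rec.subject_id,
                "position": rec.position,
                "cum_volume_ml": bi.cum_volume.tolist(),
                "frame_duration_ms": rec.curves["MPA"].frame_duration,
                "pbvv_ml": bi.pbvv,
            }
            break

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": _version(),
        "n_records": len(records),
    }
    return StudyReport(
        metrics=metrics, pvdr=pvdr_df, summary=summary, tests=tests,
        provenance=provenance, example=example,
    )


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def run_report(
    report: StudyReport,
    outdir: PathLike,
    formats: Sequence[str] = ("csv", "json"),
    plots: bool = False,
) -> List[Path]:
    """Write the study report as CSV tables and/or a JSON document, optionally with plots."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    unknown = set(formats) - {"csv", "json"}
    if unknown:
        raise InvalidParameterError(f"unknown report formats: {sorted(unknown)}")

    if "csv" in formats:
        for name, df in (
            ("metrics", report.metrics),
            ("pvdr", report.pvdr),
            ("summary", report.summary),
            ("tests", report.tests),
        ):
            path = outdir / f"{name}.csv"
            df.to_csv(path, index=False, float_format="%.10g")
            written.append(path)
    if "json" in formats:
        path = outdir / "report.json"
        doc = {
            "provenance": report.provenance,
            "summary": report.summary.to_dict(orient="records"),
            "tests": report.tests.to_dict(orient="records"),
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=True))
        written.append(path)
    if plots:
        written.extend(_write_plots(report, outdir))
    return written


def _write_plots(report: StudyReport, outdir: Path) -> List[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    if report.example:
        cum = np.asarray(report.example["cum_volume_ml"])
        t = (np.arange(cum.size) + 0.5) * report.example["frame_duration_ms"]
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(t, cum, marker="o", ms=3)
        imax, imin = int(np.argmax(cum)), int(np.argmin(cum))
        ax.annotate(
            "", xy=(t[imax], cum[imax]), xytext=(t[imax], cum[imin]),
            arrowprops=dict(arrowstyle="<->", color="crimson"),
        )
        ax.text(t[imax], (cum[imax] + cum[imin]) / 2,
                f"  PBVV = {report.example['pbvv_ml']:.1f} ml", color="crimson")
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("cumulative pulmonary volume change (ml)")
        ax.set_title(f"{report.example['subject']} {report.example['position']} (bilateral)")
        path = outdir / "cumulative_volume.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    rel = report.summary[
        (report.summary["metric"] == "relative_pbvv_pct")
        & (report.summary["scope"].isin(["right_lung", "left_lung"]))
    ]
    if len(rel):
        fig, ax = plt.subplots(figsize=(6, 4))
        width = 0.35
        xs = np.arange(len(POSITIONS))
        for off, scope, color in ((-width / 2, "right_lung", "white"), (width / 2, "left_lung", "gray")):
            sub = rel[rel["scope"] == scope].set_index("position").reindex(list(POSITIONS))
            ax.bar(xs + off, sub["mean"], width, yerr=sub["sem"], color=color,
                   edgecolor="black", label=scope.replace("_", " "))
        ax.set_xticks(xs, [p.replace("_", " ") for p in POSITIONS])
        ax.set_ylabel("relative PBVV (%)")
        ax.legend()
        path = outdir / "relative_pbvv_by_position.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
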
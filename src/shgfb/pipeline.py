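"""End-to-end orchestration: images -> masks -> F/B -> cohort -> survival/tree.

A run is described by a :class:`RunConfig`: a manifest CSV mapping patient /
region / ROI / session to F and B image files, a calibration table of FITC
reference values per session, the masking method(s) to apply, and toggles for
the downstream survival analyses. All outputs are plain text (CSV/JSON) plus
PNG heatmaps; writes are atomic (temp file then rename) and a fixed seed and
config reproduce outputs byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import masking, quant, survival, synthetic, tree

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_manifest",
    "read_calibration",
    "atomic_write_text",
    "write_csv",
    "simulate_dataset",
    "quantify",
    "analyze",
    "run_pipeline",
    "run_demo",
]

MANIFEST_COLUMNS = [
    "patient_id",
    "region_type",
    "roi_id",
    "session_id",
    "f_path",
    "b_path",
    "manual_threshold_f",
    "manual_threshold_b",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    manifest_path: Path
    calibration_path: Path
    output_dir: Path
    methods: tuple[str, ...] = ("manual", "otsu", "adaptive")
    threshold_settings: masking.ThresholdSettings = field(
        default_factory=masking.ThresholdSettings
    )
    clinical_path: Path | None = None  # patient_id, sodx, mfs_time, event
    background_f: float = 0.0
    background_b: float = 0.0
    run_quartile_km: bool = True
    run_cox: bool = True
    run_two_covariate: bool = True
    run_tree: bool = True
    run_sodx_split: bool = True
    write_heatmaps: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one masking method must be selected")
        unknown = set(self.methods) - set(quant.METHODS)
        if unknown:
            raise ValueError(f"unknown masking methods: {sorted(unknown)}")


def atomic_write_text(text: str, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_csv(df: pd.DataFrame, path: Path, float_format: str = "%.10g") -> None:
    atomic_write_text(df.to_csv(index=False, float_format=float_format), path)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate the image manifest CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"manifest {path} is empty")
    missing = [c for c in MANIFEST_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {missing}")
    bad = ~df["region_type"].isin(quant.REGION_TYPES)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # header is line 1
        raise ValueError(
            f"manifest {path}: unknown region_type in line(s) {rows}: "
            f"{sorted(df.loc[bad, 'region_type'].unique())}"
        )
    dup = df.duplicated(subset=["roi_id"])
    if dup.any():
        raise ValueError(f"manifest {path}: duplicate roi_id in line(s) {(df.index[dup] + 2).tolist()}")
    return df


def read_calibration(path: str | Path) -> dict[str, quant.CalibrationRecord]:
    df = pd.read_csv(path)
    if not {"session_id", "fitc_fb"} <= set(df.columns):
        raise ValueError(f"calibration table {path} needs session_id and fitc_fb columns")
    return {
        str(r.session_id): quant.CalibrationRecord(str(r.session_id), float(r.fitc_fb))
        for r in df.itertuples()
    }


# ---------------------------------------------------------------------------
# simulate


def simulate_dataset(
    output_dir: str | Path,
    n_patients: int = 12,
    seed: int = 0,
    image_shape: tuple[int, int] = (128, 128),
    rois_per_region: int = 3,
    n_missing_interface: int = 1,
    cohort_truth: synthetic.CohortTruth | None = None,
) -> RunConfig:
    """Generate a complete synthetic dataset on disk and return its RunConfig.

    Per patient and region type (bulk, interface), ``rois_per_region`` image
    pairs are written whose planted per-pixel F/B matches the patient's
    cohort-level value for that region. The last ``n_missing_interface``
    patients get no interface images, exercising the incomplete-region
    bookkeeping downstream. Sessions alternate per patient with distinct FITC
    reference values.
    """
    out = Path(output_dir)
    images_dir = out / "images"
    images_dir.mkdir(parents=True, exist_ok=True)
    truth = cohort_truth or synthetic.CohortTruth()
    cohort = synthetic.generate_cohort(n_patients, truth, seed=seed)
    rng = np.random.default_rng(seed + 1)

    sessions = {"S1": 1.0, "S2": 1.25}
    cal_df = pd.DataFrame(
        {"session_id": list(sessions), "fitc_fb": list(sessions.values())}
    )
    rows = []
    for i, patient in cohort.iterrows():
        session_id = "S1" if i % 2 == 0 else "S2"
        fitc = sessions[session_id]
        regions = [("tumor_bulk", patient.fb_bulk), ("tumor_stroma_interface", patient.fb_interface)]
        if i >= n_patients - n_missing_interface:
            regions = regions[:1]
        for region_type, fb_value in regions:
            for r in range(rois_per_region):
                roi_id = f"{patient.patient_id}_{region_type}_{r}"
                params = synthetic.PhantomParams(
                    constant_fb=float(fb_value) * fitc,  # raw ratio scales with session
                    peak_intensity=600.0,  # keeps F = fb x fiber within 16-bit range
                    noise_scale=2.0,
                    background_offset=40.0,
                )
                pair, _ = synthetic.generate_image_pair(
                    image_shape,
                    params,
                    seed=int(rng.integers(2**31)),
                    roi_id=roi_id,
                    region_type=region_type,
                    session_id=session_id,
                )
                fpath, bpath = synthetic.write_image_pair(pair, images_dir)
                rows.append(
                    {
                        "patient_id": patient.patient_id,
                        "region_type": region_type,
                        "roi_id": roi_id,
                        "session_id": session_id,
                        "f_path": str(fpath.relative_to(out)),
                        "b_path": str(bpath.relative_to(out)),
                        # thresholds apply to background-subtracted images
                        "manual_threshold_f": 0.1 * params.peak_intensity * float(fb_value) * fitc,
                        "manual_threshold_b": 0.1 * params.peak_intensity,
                    }
                )
    manifest = pd.DataFrame(rows)
    write_csv(manifest, out / "manifest.csv")
    write_csv(cal_df, out / "calibration.csv")
    clinical = cohort[["patient_id", "sodx", "mfs_time", "event"]]
    write_csv(clinical, out / "clinical.csv")
    synthetic.write_settings_sidecar(truth, out / "cohort_truth.json")
    return RunConfig(
        manifest_path=out / "manifest.csv",
        calibration_path=out / "calibration.csv",
        clinical_path=out / "clinical.csv",
        output_dir=out / "results",
        background_f=40.0,
        background_b=40.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# quantify


def _masks_for(
    f_sub: np.ndarray,
    b_sub: np.ndarray,
    method: str,
    settings: masking.ThresholdSettings,
    row,
) -> masking.BinaryMask:
    if method == "manual":
        mf = masking.manual_mask(f_sub, float(row.manual_threshold_f), "F")
        mb = masking.manual_mask(b_sub, float(row.manual_threshold_b), "B")
    elif method == "otsu":
        mf = masking.otsu_mask(f_sub, settings, "F")
        mb = masking.otsu_mask(b_sub, settings, "B")
    elif method == "adaptive":
        mf = masking.adaptive_mask(f_sub, settings, "F")
        mb = masking.adaptive_mask(b_sub, settings, "B")
    else:  # pragma: no cover
        raise ValueError(f"unknown method {method!r}")
    return masking.combine_masks(mf, mb)


def quantify(config: RunConfig) -> pd.DataFrame:
    """Images -> calibrated per-patient, per-region, per-method F/B table.

    Returns a wide table with one row per patient and columns
    ``fb_<region>_<method>`` / ``ln_fb_<region>_<method>``.
    """
    import tifffile

    manifest = read_manifest(config.manifest_path)
    calibrations = read_calibration(config.calibration_path)
    base = Path(config.manifest_path).parent
    out = Path(config.output_dir)
    heat_dir = out / "heatmaps"

    roi_rows = []
    for row in manifest.itertuples():
        if row.session_id not in calibrations:
            raise ValueError(f"session {row.session_id!r} has no calibration record")
        f_file, b_file = base / row.f_path, base / row.b_path
        for p, chan in ((f_file, "F"), (b_file, "B")):
            if not p.exists():
                raise FileNotFoundError(f"ROI {row.roi_id!r}: missing {chan} image {p}")
        f_img = tifffile.imread(f_file).astype(np.float64)
        b_img = tifffile.imread(b_file).astype(np.float64)
        f_sub = quant.subtract_background(f_img, config.background_f)
        b_sub = quant.subtract_background(b_img, config.background_b)
        ratio = quant.fb_image(f_sub, b_sub)
        for method in config.methods:
            mask = _masks_for(f_sub, b_sub, method, config.threshold_settings, row)
            result = quant.roi_mean_fb(
                ratio,
                mask,
                roi_id=str(row.roi_id),
                region_type=str(row.region_type),
                session_id=str(row.session_id),
            )
            result = quant.calibrate(result, calibrations[row.session_id])
            roi_rows.append(
                {
                    "patient_id": row.patient_id,
                    "region_type": result.region_type,
                    "roi_id": result.roi_id,
                    "method": method,
                    "mean_fb": result.mean_fb,
                    "n_pixels": result.n_pixels,
                    "session_id": result.session_id,
                }
            )
            if config.write_heatmaps and method == config.methods[0]:
                heat_dir.mkdir(parents=True, exist_ok=True)
                quant.render_heatmap(ratio, mask, heat_dir / f"{row.roi_id}_{method}.png")
    roi_table = pd.DataFrame(roi_rows)
    write_csv(roi_table, out / "roi_fb.csv")

    patient_rows = {}
    for (pid, region, method), grp in roi_table.groupby(
        ["patient_id", "region_type", "method"], sort=True
    ):
        n_rois = len(grp)
        if n_rois != 3:
            logger.warning(
                "patient %s %s/%s: %d ROI(s) instead of 3", pid, region, method, n_rois
            )
        results = [
            quant.FBResult(
                roi_id=str(r.roi_id),
                region_type=region,
                method=method,
                mean_fb=float(r.mean_fb),
                n_pixels=int(r.n_pixels),
                calibrated=True,
                session_id=str(r.session_id),
            )
            for r in grp.itertuples()
        ]
        fb = quant.aggregate_region(results)
        short = {"tumor_bulk": "bulk", "tumor_stroma_interface": "interface", "far": "far"}[region]
        rec = patient_rows.setdefault(pid, {"patient_id": pid})
        rec[f"fb_{short}_{method}"] = fb
        rec[f"ln_fb_{short}_{method}"] = float(np.log(fb))
    table = pd.DataFrame(sorted(patient_rows.values(), key=lambda r: r["patient_id"]))
    write_csv(table, out / "patient_fb.csv")
    return table


# ---------------------------------------------------------------------------
# analyze


def _km_table(curves: dict[str, survival.SurvivalCurve]) -> pd.DataFrame:
    rows = []
    for label, curve in curves.items():
        for t, s, n, d in zip(
            curve.event_times, curve.survival, curve.at_risk, curve.n_events
        ):
            rows.append(
                {"group": label, "time": t, "survival": s, "at_risk": n, "events": d}
            )
    return pd.DataFrame(rows)


def analyze(patient_table: pd.DataFrame, config: RunConfig) -> dict:
    """Survival analyses on the quantified patient table joined with outcomes."""
    if config.clinical_path is None:
        raise ValueError("analysis requires a clinical table (sodx, mfs_time, event)")
    clinical = pd.read_csv(config.clinical_path)
    df = patient_table.merge(clinical, on="patient_id", how="inner", validate="1:1")
    out = Path(config.output_dir)
    summary: dict = {"n_patients": int(len(df))}

    interface_cols = [c for c in df.columns if c.startswith("ln_fb_interface")]
    n_complete = int(df[interface_cols].notna().all(axis=1).sum()) if interface_cols else 0
    summary["n_with_interface"] = n_complete
    if interface_cols and n_complete < len(df):
        logger.info(
            "%d of %d patients lack an interface region; retained for bulk analyses",
            len(df) - n_complete,
            len(df),
        )

    for method in config.methods:
        for region in ("bulk", "interface"):
            col = f"ln_fb_{region}_{method}"
            if col not in df.columns:
                continue
            sub = df[df[col].notna()]
            if len(sub) < 4:
                logger.warning("skipping %s: fewer than 4 patients", col)
                continue
            key = f"{region}_{method}"
            if config.run_quartile_km:
                assignment, curves = survival.quartile_km_analysis(
                    sub[col], sub["mfs_time"], sub["event"], ids=sub["patient_id"]
                )
                write_csv(_km_table(curves), out / f"km_{key}.csv")
                summary[f"quartile_boundaries_{key}"] = list(assignment.boundaries)
                summary[f"quartile_sizes_{key}"] = list(assignment.group_sizes)
            if config.run_cox and sub["event"].sum() >= 2:
                try:
                    fit = survival.cox_fit(
                        sub["mfs_time"], sub["event"], sub[col], covariate_names=(col,)
                    )
                    summary[f"cox_{key}"] = {
                        "coef": float(fit.coefficients[0]),
                        "se": float(fit.std_errors[0]),
                        "lrt_p": fit.lrt_p,
                    }
                except survival.ConvergenceError as exc:
                    summary[f"cox_{key}"] = {"error": str(exc)}
        if config.run_two_covariate:
            cols = [f"ln_fb_bulk_{method}", f"ln_fb_interface_{method}"]
            if all(c in df.columns for c in cols):
                sub = df[df[cols].notna().all(axis=1)]
                if len(sub) >= 4 and sub["event"].sum() >= 2:
                    try:
                        fit, pvals = survival.two_covariate_cox(
                            sub["mfs_time"], sub["event"], sub[cols[0]], sub[cols[1]]
                        )
                        summary[f"two_covariate_{method}"] = {
                            "coef_bulk": float(fit.coefficients[0]),
                            "coef_interface": float(fit.coefficients[1]),
                            "p_bulk": pvals["ln_fb_bulk"],
                            "p_interface": pvals["ln_fb_interface"],
                        }
                    except survival.ConvergenceError as exc:
                        summary[f"two_covariate_{method}"] = {"error": str(exc)}

    tree_covariates = ["sodx"] + [
        f"ln_fb_{region}_{m}"
        for region in ("bulk", "interface")
        for m in config.methods
        if f"ln_fb_{region}_{m}" in df.columns
    ]
    if config.run_tree:
        sub = df[df[tree_covariates].notna().all(axis=1)]
        if len(sub) >= 4 and sub["event"].sum() >= 2:
            fitted = tree.grow_tree(sub, tree_covariates)
            fitted.to_json(out / "risk_tree.json")
            atomic_write_text(tree.render_tree(fitted) + "\n", out / "risk_tree.txt")
            groups = tree.assign_risk_groups(fitted)
            write_csv(groups, out / "risk_groups.csv")
            summary["tree_n_leaves"] = len(fitted.leaves())
            summary["tree_root_split"] = fitted.split_var

    if config.run_sodx_split and "sodx" in df.columns:
        col = next((c for c in (f"ln_fb_interface_{m}" for m in ("adaptive",) + tuple(config.methods)) if c in df.columns), None)
        if col is not None:
            low, high = survival.sodx_split(df[df[col].notna()])
            for name, grp in (("sodx_low", low), ("sodx_high", high)):
                if len(grp) >= 4 and grp["event"].sum() >= 2:
                    assignment = survival.quartile_assign(grp[col], ids=grp["patient_id"])
                    q1 = survival.q1_vs_rest(assignment)
                    try:
                        fit = survival.cox_fit(
                            grp["mfs_time"], grp["event"], q1.astype(float),
                            covariate_names=("q1_lowest_fb",),
                        )
                        summary[f"{name}_q1_vs_rest_lrt_p"] = fit.lrt_p
                    except (survival.ConvergenceError, ValueError) as exc:
                        summary[f"{name}_q1_vs_rest_lrt_p"] = None
                        logger.warning("%s Q1-vs-rest Cox fit failed: %s", name, exc)
                    curves = {
                        "Q1": survival.km_estimate(
                            grp["mfs_time"][q1], grp["event"][q1]
                        ),
                        "Q2-Q4": survival.km_estimate(
                            grp["mfs_time"][~q1], grp["event"][~q1]
                        ),
                    }
                    write_csv(_km_table(curves), out / f"km_{name}_q1_vs_rest.csv")
                else:
                    summary[f"{name}_q1_vs_rest_lrt_p"] = None

    atomic_write_text(json.dumps(summary, indent=2, sort_keys=True), out / "analysis_summary.json")
    write_csv(df, out / "cohort_table.csv")
    return summary


def run_pipeline(config: RunConfig) -> dict:
    """Full quantify + analyze run."""
    table = quantify(config)
    return analyze(table, config)


def run_demo(output_dir: str | Path, seed: int = 0, n_patients: int = 12) -> dict:
    """Simulate a small synthetic study end-to-end and analyze it."""
    config = simulate_dataset(output_dir, n_patients=n_patients, seed=seed)
    return run_pipeline(config)
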
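"""Readers, writers, configuration and the end-to-end pipeline driver.

File formats: NIfTI-1 for images, tab-separated text for motion traces,
phenotype tables, scores, model summaries and curves, YAML for the pipeline
configuration. All writes are atomic (temporary file in the target directory,
then rename). Volume indices are 0-based internally and 1-based in log
messages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from ._types import BoldRun, ConnectivityResult, GmMask, MotionTrace, SEED_SPECS
from . import cohort_stats, connectivity, trajectories

logger = logging.getLogger("hubreserve")

__all__ = [
    "read_bold",
    "write_bold",
    "read_motion",
    "write_motion",
    "read_mask",
    "write_mask",
    "read_table",
    "write_table",
    "write_scores",
    "read_scores",
    "write_models",
    "write_curves",
    "PipelineConfig",
    "run_pipeline",
    "compute_subject_scores",
]

#: Columns every phenotype table must carry; the remaining SubjectRecord
#: columns (biomarkers, cognition, connectivity) are analysis-dependent.
REQUIRED_TABLE_COLUMNS = ("subject_id", "cohort", "group", "gender", "site_id")

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


def _atomic_write(path: Path, writer) -> None:
    """Write via a temp file in the same directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # keep the target's extension so format-sniffing writers (NIfTI) work
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix="".join(path.suffixes) or ".tmp")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_bold(path, tr: float | None = None, run_id: str | None = None) -> BoldRun:
    """Load a 4D NIfTI run; TR comes from the header unless overridden."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"'{path}' is {data.ndim}D; a BOLD run must be 4D (x,y,z,t)")
    if tr is None:
        header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        if header_tr <= 0:
            raise ValueError(
                f"repetition time absent from the header of '{path}' and no --tr given"
            )
        tr = header_tr
    return BoldRun(data, tr=tr, affine=np.asarray(img.affine), run_id=run_id or Path(path).stem)


def write_bold(run: BoldRun, path) -> None:
    img = nib.Nifti1Image(run.data.astype(np.float64), run.affine)
    zooms = tuple(run.voxel_sizes()) + (run.tr,)
    img.header.set_zooms(zooms)
    _atomic_write(Path(path), lambda tmp: nib.save(img, str(tmp)))


def read_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"'{path}' is {data.ndim}D; masks must be 3D")
    return data > 0


def write_mask(mask: np.ndarray, affine: np.ndarray, path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    _atomic_write(Path(path), lambda tmp: nib.save(img, str(tmp)))


def read_motion(path) -> MotionTrace:
    """Read a 6-column TSV motion trace (translations mm, rotations rad)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"motion file '{path}' is missing columns: {missing}")
    if df[list(MOTION_COLUMNS)].isna().any().any():
        raise ValueError(f"motion file '{path}' contains non-finite values")
    return MotionTrace(
        translations=df[list(MOTION_COLUMNS[:3])].to_numpy(),
        rotations=df[list(MOTION_COLUMNS[3:])].to_numpy(),
    )


def write_motion(motion: MotionTrace, path) -> None:
    df = pd.DataFrame(motion.as_matrix(), columns=list(MOTION_COLUMNS))
    _atomic_write(Path(path), lambda tmp: df.to_csv(tmp, sep="\t", index=False))


def read_table(path, required=REQUIRED_TABLE_COLUMNS) -> pd.DataFrame:
    """Read a phenotype TSV; unknown columns are preserved untouched."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table '{path}' is missing required columns: {missing}")
    return df


def write_table(table: pd.DataFrame, path) -> None:
    _atomic_write(Path(path), lambda tmp: table.to_csv(tmp, sep="\t", index=False))


def write_scores(results: list[ConnectivityResult], path) -> None:
    rows = [
        dict(
            subject_id=r.subject_id,
            seed=r.seed_name,
            score="" if r.score is None else r.score,
            n_positive_voxels=r.n_positive_voxels,
            n_gm_voxels=r.n_gm_voxels,
            censored_fraction=r.censored_fraction,
            excluded=r.excluded,
        )
        for r in results
    ]
    _atomic_write(Path(path), lambda tmp: pd.DataFrame(rows).to_csv(tmp, sep="\t", index=False))


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_models(fits, path) -> None:
    frame = pd.concat([f.to_frame() for f in fits], ignore_index=True)
    _atomic_write(Path(path), lambda tmp: frame.to_csv(tmp, sep="\t", index=False))


def write_curves(curves, path) -> None:
    frame = pd.concat([c.to_frame() for c in curves], ignore_index=True)
    _atomic_write(Path(path), lambda tmp: frame.to_csv(tmp, sep="\t", index=False))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline, with their standard defaults.

    Any override of a default is logged at load time so a run's log records
    every analysis choice.
    """

    cohort: str = "DIAN"
    table_path: str | None = None
    bold_dir: str | None = None
    out_dir: str = "hubreserve_out"
    fd_threshold: float = 0.5
    exclusion_fraction: float = 0.30
    band: tuple[float, float] = (0.01, 0.08)
    fwhm: float = 8.0
    gm_threshold: float = 0.3
    seeds: tuple[str, ...] = ("LFC", "RFC", "OCC", "M1")
    alpha_primary: float = 0.0125
    eyo_plot_range: tuple[float, float] = (-20.0, 10.0)
    min_stratum_n: int = 20
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("band", "eyo_plot_range", "seeds"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        defaults = cls()
        for f in dataclasses.fields(cls):
            if getattr(cfg, f.name) != getattr(defaults, f.name):
                logger.info("config override: %s = %r", f.name, getattr(cfg, f.name))
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# pipeline


def compute_subject_scores(
    run: BoldRun,
    motion: MotionTrace,
    gm: GmMask,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    subject_id: str,
    seeds=("LFC", "RFC", "OCC", "M1"),
    fd_threshold: float = 0.5,
    exclusion_fraction: float = 0.30,
    band: tuple[float, float] = (0.01, 0.08),
    fwhm: float = 8.0,
) -> list[ConnectivityResult]:
    """Smooth, denoise, scrub and score one subject for the given seeds."""
    fd = connectivity.compute_framewise_displacement(motion)
    censor = connectivity.build_censor_mask(
        fd, threshold_mm=fd_threshold, exclusion_fraction=exclusion_fraction
    )
    n_censored = int((~censor.retained).sum())
    if n_censored:
        first = int(np.flatnonzero(~censor.retained)[0]) + 1  # 1-based volume number for logs
        logger.info(
            "subject %s: %d/%d volumes censored (first censored volume %d)",
            subject_id, n_censored, len(censor), first,
        )
    if censor.excluded:
        logger.warning(
            "subject %s excluded: %.1f%% of volumes censored (> %.0f%%)",
            subject_id, 100 * censor.censored_fraction, 100 * exclusion_fraction,
        )
        return [
            ConnectivityResult(
                subject_id=subject_id, seed_name=s, score=None, n_positive_voxels=0,
                n_gm_voxels=0, censored_fraction=censor.censored_fraction, excluded=True,
            )
            for s in seeds
        ]
    smoothed = connectivity.smooth_volumes(run, fwhm)
    cleaned = connectivity.denoise_run(smoothed, motion, wm_mask, csf_mask, band)
    results = []
    for seed in seeds:
        roi = connectivity.make_sphere_roi(SEED_SPECS[seed], run.affine, run.shape3d)
        results.append(
            connectivity.global_connectivity(
                cleaned, roi, gm, censor, subject_id=subject_id, seed_name=seed
            )
        )
    return results


def _stage(name: str, subject: str = ""):
    """Context manager labelling failures with the stage (and subject)."""
    import contextlib

    @contextlib.contextmanager
    def cm():
        try:
            yield
        except Exception as err:
            where = f"stage '{name}'" + (f", subject '{subject}'" if subject else "")
            raise RuntimeError(f"pipeline halted at {where}: {err}") from err

    return cm()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run connectivity scoring, descriptives, reserve models and trajectories.

    Reads the phenotype table (and, when ``bold_dir`` is set, per-subject
    runs named ``bold_<subject_id>.nii.gz`` / ``motion_<subject_id>.tsv``
    plus shared ``gm_mask``/``wm_mask``/``csf_mask`` NIfTIs), computes
    per-seed global connectivity, merges scores into the table, fits the
    moderation and trajectory models, and writes TSV outputs plus a JSON
    report carrying the config hash and an output manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("pipeline start; config hash %s; config %s", config.config_hash(), config.to_dict())
    manifest: list[str] = []
    report: dict = {"config_hash": config.config_hash(), "stages": []}

    try:
        with _stage("read-table"):
            table = read_table(config.table_path)
            cohort = cohort_stats.assert_single_cohort(table)
            if cohort != config.cohort:
                raise ValueError(
                    f"config says cohort '{config.cohort}' but the table contains '{cohort}'"
                )
        report["stages"].append("read-table")

        if config.bold_dir is not None:
            bold_dir = Path(config.bold_dir)
            gm = GmMask(read_mask(bold_dir / "gm_mask.nii.gz"), threshold=config.gm_threshold)
            wm = read_mask(bold_dir / "wm_mask.nii.gz")
            csf = read_mask(bold_dir / "csf_mask.nii.gz")
            all_scores: list[ConnectivityResult] = []
            for sid in table["subject_id"]:
                with _stage("connectivity", sid):
                    run = read_bold(bold_dir / f"bold_{sid}.nii.gz")
                    motion = read_motion(bold_dir / f"motion_{sid}.tsv")
                    all_scores.extend(
                        compute_subject_scores(
                            run, motion, gm, wm, csf, sid,
                            seeds=config.seeds, fd_threshold=config.fd_threshold,
                            exclusion_fraction=config.exclusion_fraction,
                            band=config.band, fwhm=config.fwhm,
                        )
                    )
            write_scores(all_scores, out / "scores.tsv")
            manifest.append("scores.tsv")
            wide = pd.DataFrame(
                [
                    dict(subject_id=r.subject_id, seed=f"conn_{r.seed_name.lower()}", score=r.score)
                    for r in all_scores
                    if not r.excluded
                ]
            ).pivot(index="subject_id", columns="seed", values="score")
            table = table.drop(columns=[c for c in table.columns if c.startswith("conn_")], errors="ignore")
            table = table.merge(wide, on="subject_id", how="inner")
            excluded = {r.subject_id for r in all_scores if r.excluded}
            if excluded:
                logger.warning("excluded subjects dropped from analysis: %s", sorted(excluded))
            report["stages"].append("connectivity")

        with _stage("descriptives"):
            grouping = "group" if cohort == "DIAN" else "abeta_status"
            comps = []
            for var in ("age", "education", "mmse", "lm_delayed", "conn_lfc", "gender"):
                if var in table.columns and table[var].notna().any():
                    c = cohort_stats.group_comparison(table, var, grouping)
                    comps.append(dict(variable=var, test=c.test, statistic=c.statistic, p=c.p))
            pd.DataFrame(comps).pipe(
                lambda df: _atomic_write(out / "descriptives.tsv", lambda tmp: df.to_csv(tmp, sep="\t", index=False))
            )
            manifest.append("descriptives.tsv")
        report["stages"].append("descriptives")

        with _stage("reserve-models"):
            outcomes = ["mmse", "lm_delayed"] + (["adas_recall"] if cohort == "DELCODE" else [])
            severities = ["eyo", "csf_tau"] if cohort == "DIAN" else ["csf_tau"]
            strata = ["MC", "NC"] if cohort == "DIAN" else ["abeta_pos", "abeta_neg"]
            fits, aics = [], []
            for outcome in outcomes:
                if outcome not in table.columns or table[outcome].isna().all():
                    continue
                for severity in severities:
                    for seed in config.seeds:
                        for stratum in strata:
                            fit, cmp_ = cohort_stats.fit_reserve_interaction(
                                table, outcome, severity, stratum,
                                connectivity_seed=seed, min_n=config.min_stratum_n,
                            )
                            fits.append(fit)
                            aics.append(
                                dict(outcome=outcome, severity=severity, seed=seed,
                                     stratum=stratum, aic_full=cmp_.aic_full,
                                     aic_reduced=cmp_.aic_reduced, delta=cmp_.delta)
                            )
            cohort_stats.apply_alpha_gate(fits, primary_alpha=config.alpha_primary)
            for stratum in strata:
                fits.append(cohort_stats.fit_education_model(table, stratum, min_n=config.min_stratum_n))
            fits.append(
                cohort_stats.fit_group_ancova(table, "conn_lfc", grouping=grouping)
            )
            if table["scanner_model"].nunique() > 1:
                fits.append(
                    cohort_stats.fit_group_ancova(table, "conn_lfc", grouping="scanner_model")
                )
            write_models(fits, out / "models.tsv")
            _atomic_write(out / "aic.tsv", lambda tmp: pd.DataFrame(aics).to_csv(tmp, sep="\t", index=False))
            manifest += ["models.tsv", "aic.tsv"]
            report["n_reserve_models"] = len(fits)
        report["stages"].append("reserve-models")

        with _stage("trajectories"):
            axis = "eyo" if cohort == "DIAN" else "csf_tau"
            g1, g2 = ("MC", "NC") if cohort == "DIAN" else ("abeta_pos", "abeta_neg")
            if axis == "eyo":
                grid = np.arange(config.eyo_plot_range[0], config.eyo_plot_range[1] + 0.25, 0.5)
            else:
                ax_vals = trajectories._axis_values(table, axis)
                lo, hi = np.nanpercentile(ax_vals, [2.5, 97.5])
                grid = np.linspace(lo, hi, 61)
            curves = []
            traj_outcomes = ["mmse", "csf_tau", "hippocampal_volume"] + (
                ["pib_suvr"] if cohort == "DIAN" else ["csf_abeta_ratio"]
            )
            for outcome in traj_outcomes:
                if outcome == axis or outcome not in table.columns or table[outcome].isna().all():
                    continue
                interact = outcome == "mmse"
                m1 = trajectories.select_polynomial_model(
                    table, outcome, axis, g1, with_connectivity_interaction=interact,
                    min_n=config.min_stratum_n,
                )
                m2 = trajectories.select_polynomial_model(
                    table, outcome, axis, g2, with_connectivity_interaction=interact,
                    min_n=config.min_stratum_n,
                )
                pooled = trajectories.pooled_outcome_values(table, outcome)
                pooled_sd = float(np.nanstd(pooled, ddof=1))
                curves.append(trajectories.predict_difference_curve(m1, m2, grid, pooled_sd))
                if interact:
                    conn_z = cohort_stats.log_z_transform(
                        table["conn_lfc"].dropna().to_numpy(), "conn_lfc"
                    ).values
                    labels = trajectories.median_split(table["conn_lfc"].dropna().to_numpy())
                    for lab in ("high", "low"):
                        cz = float(conn_z[labels == lab].mean())
                        curves.append(
                            trajectories.predict_difference_curve(
                                m1, m2, grid, pooled_sd, connectivity_z=cz, stratum_label=lab
                            )
                        )
            write_curves(curves, out / "curves.tsv")
            manifest.append("curves.tsv")
            _plot_curves(curves, out / "curves.png")
            manifest.append("curves.png")
        report["stages"].append("trajectories")

        report["manifest"] = manifest
        report["n_subjects"] = int(len(table))
        _atomic_write(out / "report.json", lambda tmp: Path(tmp).write_text(json.dumps(report, indent=2)))
        logger.info("pipeline complete; outputs: %s", manifest)
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()


def _plot_curves(curves, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for c in curves:
        label = c.outcome + ("" if c.connectivity_stratum == "none" else f" ({c.connectivity_stratum} conn)")
        ax.plot(c.axis_grid, c.standardized_difference, label=label)
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("disease-stage axis")
    ax.set_ylabel("standardized group difference (pooled-SD units)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
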
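"""Seedable generators for BOLD-like runs and DIAN/DELCODE-like cohorts.

Every other module in this package is exercised end-to-end on the output of
this one, so the defaults *are* the study conditions: published group sizes,
group means/SDs and effect sizes of the two cohorts (see
:mod:`hubreserve.reference`), the reported standardized moderation effects,
and biomarker trajectories that follow a logistic (sigmoid) course over the
disease-stage axis.

Two generators:

* :func:`simulate_bold_run` — a small 4D run with a planted population of
  voxels coupled to the seed's latent band-limited signal at a controlled
  Pearson correlation, nuisance structure (offset, drift) and Bernoulli
  motion spikes, plus grey-matter / white-matter / CSF masks on the grid.
* :func:`simulate_cohort` — a phenotype table with planted
  severity x connectivity moderation on cognition, group effect sizes under
  the root-mean-square Cohen's d convention, an education-connectivity
  correlation, and lognormal biomarkers whose log-scale means follow a
  sigmoid in estimated years to onset (moment-matched so the published group
  means and SDs are reproduced in expectation).

All generators are pure functions of their parameter set including
``rng_seed``: identical parameters give bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import reference as ref
from ._types import BoldRun, GmMask, MotionTrace, RoiSpec, SEED_SPECS
from .connectivity import bandpass_filter, make_sphere_roi

__all__ = [
    "BoldSimParams",
    "CohortSimParams",
    "simulate_bold_run",
    "simulate_cohort",
    "true_log_difference_curve",
    "dian_default_params",
    "delcode_default_params",
]


# ---------------------------------------------------------------------------
# BOLD simulation


@dataclass(frozen=True)
class BoldSimParams:
    """Parameters of the synthetic resting-state run."""

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 4.0
    n_volumes: int = 160
    tr: float = 2.23
    seed_roi: RoiSpec = SEED_SPECS["LFC"]
    coupled_fraction: float = 0.3
    coupling_rho: float = 0.3
    noise_sd: float = 1.0
    motion_spike_prob: float = 0.05
    spike_magnitude_mm: float = 1.0
    #: world coordinate at the grid centre; defaults to the seed centre so
    #: small grids always contain the requested sphere
    center_mni: tuple[float, float, float] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.coupled_fraction <= 1):
            raise ValueError("coupled_fraction must lie in [0, 1]")
        if not abs(self.coupling_rho) < 1:
            raise ValueError("|coupling_rho| must be < 1")


def _band_limited_noise(rng: np.random.Generator, n_series: int, n_volumes: int, tr: float) -> np.ndarray:
    """Independent rows of unit-variance noise restricted to 0.01-0.08 Hz."""
    white = rng.standard_normal((n_series, n_volumes))
    filt = bandpass_filter(white, tr)
    filt -= filt.mean(axis=-1, keepdims=True)
    sd = filt.std(axis=-1, keepdims=True)
    return filt / np.where(sd > 0, sd, 1.0)


def simulate_bold_run(
    params: BoldSimParams,
) -> tuple[BoldRun, MotionTrace, GmMask, np.ndarray, np.ndarray]:
    """Generate one run plus motion trace and tissue masks.

    The grid is placed in world space so that the requested seed sphere sits
    at its centre. Tissue layout: the outermost voxel layer is CSF, the next
    layer white matter, the interior grey matter. Seed-sphere voxels share a
    latent band-limited signal; a ``coupled_fraction`` of the remaining
    grey-matter voxels is generated as ``rho * s + sqrt(1 - rho^2) * e`` with
    independent band-limited ``e``, giving population seed correlation
    exactly ``coupling_rho``; all other voxels are independent noise. A
    baseline offset and slow linear drift are added (removed again by
    detrending), and the motion trace carries Bernoulli spikes of
    ``spike_magnitude_mm`` on the x-translation.
    """
    rng = np.random.default_rng(params.rng_seed)
    shape = tuple(params.grid_shape)
    if min(shape) < 6:
        raise ValueError("grid too small: each dimension must be >= 6 to host tissue layers")
    v = params.voxel_size_mm
    center = np.asarray(params.center_mni if params.center_mni is not None else params.seed_roi.center_mni)
    affine = np.diag([v, v, v, 1.0])
    affine[:3, 3] = center - v * (np.asarray(shape) - 1) / 2.0

    # tissue shells: CSF outermost, then WM, grey matter inside
    idx = np.indices(shape)
    depth = np.minimum.reduce(
        [idx[d] for d in range(3)] + [shape[d] - 1 - idx[d] for d in range(3)]
    )
    csf_mask = depth == 0
    wm_mask = depth == 1
    gm = GmMask(mask=depth >= 2)

    seed_mask = make_sphere_roi(params.seed_roi, affine, shape)
    if not (seed_mask & gm.mask).any():
        raise ValueError("grid too small to contain the seed sphere within grey matter")

    n_vox = int(np.prod(shape))
    t = params.n_volumes
    latent = _band_limited_noise(rng, 1, t, params.tr)[0]

    flat = np.empty((n_vox, t))
    flat[:] = _band_limited_noise(rng, n_vox, t, params.tr)

    seed_flat = seed_mask.ravel()
    flat[seed_flat] = latent + 0.02 * _band_limited_noise(rng, int(seed_flat.sum()), t, params.tr)

    target_idx = np.flatnonzero(gm.mask.ravel() & ~seed_flat)
    n_coupled = int(round(params.coupled_fraction * target_idx.size))
    coupled = rng.choice(target_idx, size=n_coupled, replace=False)
    rho = params.coupling_rho
    flat[coupled] = rho * latent + np.sqrt(1 - rho**2) * _band_limited_noise(
        rng, n_coupled, t, params.tr
    )

    flat *= params.noise_sd
    drift = rng.uniform(-0.01, 0.01, size=(n_vox, 1)) * np.arange(t)
    flat += 500.0 + drift

    translations = 0.02 * rng.standard_normal((t, 3))
    rotations = 0.0004 * rng.standard_normal((t, 3))
    spikes = rng.random(t) < params.motion_spike_prob
    spikes[0] = False
    translations[spikes, 0] += params.spike_magnitude_mm

    run = BoldRun(flat.reshape(*shape, t), tr=params.tr, affine=affine, run_id=f"sim-{params.rng_seed}")
    motion = MotionTrace(translations=translations, rotations=rotations)
    return run, motion, gm, wm_mask, csf_mask


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class CohortSimParams:
    """Parameters of the synthetic phenotype table.

    ``effects`` maps outcome -> standardized betas (severity, connectivity,
    interaction) planted in the *affected* stratum (mutation carriers /
    amyloid-positives); the unaffected stratum gets weak main effects and no
    interaction. ``group_effect_d`` overrides the published between-group
    effect sizes; ``trajectory_shape`` maps biomarker -> (inflection EYO,
    logistic width in years) for the sigmoid course planted in carriers.
    """

    cohort: str = "DIAN"
    n_per_group: dict = None
    effects: dict = None
    education_connectivity_r: float = 0.25
    group_effect_d: dict = field(default_factory=dict)
    trajectory_shape: dict = field(default_factory=dict)
    gender_beta: float = 0.1
    n_sites: int = 8
    site_sd: float = 0.15
    traj_share: float = 0.6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group is not None:
            if any(n < 2 for n in self.n_per_group.values()):
                raise ValueError("every group needs n >= 2")
        if self.n_sites < 1:
            raise ValueError("need at least 1 site")


def dian_default_params(**overrides) -> CohortSimParams:
    """The DIAN-like study conditions: 74 carriers, 55 non-carrier siblings."""
    base = CohortSimParams(
        cohort="DIAN",
        n_per_group=dict(ref.DIAN_SAMPLE_SIZES),
        effects={
            "mmse": dict(ref.RESERVE_MODEL_EFFECTS[("DIAN", "MC", "mmse")]),
            "lm_delayed": dict(ref.RESERVE_MODEL_EFFECTS[("DIAN", "MC", "lm_delayed")]),
        },
    )
    return replace(base, **overrides)


def delcode_default_params(**overrides) -> CohortSimParams:
    """The DELCODE-like study conditions: 75 amyloid-positive, 41 negative."""
    n = {}
    for stratum, groups in ref.DELCODE_SAMPLE_SIZES.items():
        for g, count in groups.items():
            n[f"{stratum}:{g}"] = count
    base = CohortSimParams(
        cohort="DELCODE",
        n_per_group=n,
        effects={
            "mmse": dict(ref.RESERVE_MODEL_EFFECTS[("DELCODE", "abeta_pos", "mmse")]),
            "lm_delayed": dict(ref.RESERVE_MODEL_EFFECTS[("DELCODE", "abeta_pos", "lm_delayed")]),
            "adas_recall": dict(ref.RESERVE_MODEL_EFFECTS[("DELCODE", "abeta_pos", "adas_recall")]),
        },
    )
    return replace(base, **overrides)


def _rms(s1: float, s2: float) -> float:
    return float(np.sqrt((s1**2 + s2**2) / 2.0))


def _sigmoid_profile(eyo: np.ndarray, e0: float, tau: float) -> tuple[np.ndarray, float, float]:
    """Standardized logistic profile over the realized EYO sample."""
    g = 1.0 / (1.0 + np.exp(-(eyo - e0) / tau))
    g_mean, g_sd = float(g.mean()), float(g.std())
    if g_sd < 1e-12:
        return np.zeros_like(g), g_mean, 1.0
    return (g - g_mean) / g_sd, g_mean, g_sd


def _lognormal_matched(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    profile: np.ndarray | None = None,
    share: float = 0.6,
) -> tuple[np.ndarray, dict]:
    """Lognormal sample with exact first two raw moments and a planted course.

    The exponent is ``c + b * profile + sigma * eps`` where ``profile`` is a
    standardized trajectory (or absent). Given the realized profile values,
    ``c`` and ``sigma`` solve the two moment equations in closed form, so the
    sample matches ``mean`` and ``sd`` in expectation whatever the profile's
    distribution. ``share`` sets the fraction of log-scale SD carried by the
    trajectory; it is reduced automatically if the target SD cannot
    accommodate it.
    """
    s2_total = float(np.log(1.0 + (sd / mean) ** 2))
    if profile is None or not np.any(profile):
        sigma = float(np.sqrt(s2_total))
        c = float(np.log(mean) - s2_total / 2.0)
        x = np.exp(c + sigma * rng.standard_normal(n))
        return x, {"c": c, "b": 0.0, "sigma": sigma}
    b = share * np.sqrt(s2_total)
    while b > 1e-9:
        a1 = float(np.mean(np.exp(b * profile)))
        a2 = float(np.mean(np.exp(2.0 * b * profile)))
        s2 = np.log((mean**2 + sd**2) * a1**2 / (mean**2 * a2))
        if s2 > 1e-10:
            break
        b /= 2.0
    else:
        b, a1, s2 = 0.0, 1.0, s2_total
    sigma = float(np.sqrt(s2))
    c = float(np.log(mean) - np.log(a1) - s2 / 2.0)
    x = np.exp(c + b * profile + sigma * rng.standard_normal(n))
    return x, {"c": c, "b": float(b), "sigma": sigma}


def _normal_matched(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    profile: np.ndarray | None = None,
    share: float = 0.6,
) -> tuple[np.ndarray, dict]:
    """Normal sample with mean/SD matched and an optional planted course."""
    if profile is None or not np.any(profile):
        return mean + sd * rng.standard_normal(n), {"c": mean, "b": 0.0, "sigma": sd}
    b = share * sd
    resid = float(np.sqrt(max(sd**2 - b**2, 1e-12)))
    x = mean + b * profile + resid * rng.standard_normal(n)
    return x, {"c": mean, "b": float(b), "sigma": resid}


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


#: Sigmoid (inflection EYO, width in years) per biomarker, DIAN carriers.
#: Inflection near expected symptom onset, transition spanning roughly two
#: decades, matching the cascading-biomarker course the trajectory models
#: approximate with cubics.
_DIAN_TRAJECTORIES = {
    "csf_tau": (0.0, 6.0),
    "csf_ptau181": (0.0, 6.0),
    "pib_suvr": (0.0, 6.0),
    "hippocampal_volume": (0.0, 5.0),
}

#: Cognition raw scales (unaffected-group mean/SD, affected-group SD) chosen
#: inside the instrument bounds; between-group means then follow from the
#: published d under the RMS convention.
_COGNITION_SCALES = {
    "DIAN": {
        "mmse": dict(ref_mean=25.0, ref_sd=1.0, aff_sd=2.0, d=0.66, bounds=(0, 30)),
        "lm_delayed": dict(ref_mean=12.5, ref_sd=2.5, aff_sd=3.5, d=0.77, bounds=(0, 25)),
    },
    "DELCODE": {
        "mmse": dict(ref_mean=27.5, ref_sd=0.8, aff_sd=1.3, d=0.9, bounds=(0, 30)),
        "lm_delayed": dict(ref_mean=13.0, ref_sd=3.0, aff_sd=3.5, d=0.5, bounds=(0, 25)),
        "adas_recall": dict(ref_mean=6.5, ref_sd=1.1, aff_sd=1.6, d=0.7, bounds=(0, 10)),
    },
}

_NULL_EFFECTS = {"severity": -0.1, "connectivity": 0.1, "interaction": 0.0}


def _plant_cognition(
    rng: np.random.Generator,
    z_sev: np.ndarray,
    z_conn: np.ndarray,
    female: np.ndarray,
    site_effect: np.ndarray,
    betas: dict,
    gender_beta: float,
    site_sd: float,
) -> np.ndarray:
    """Standardized-scale cognition with the planted moderation structure."""
    systematic = (
        betas["severity"] * z_sev
        + betas["connectivity"] * z_conn
        + betas["interaction"] * z_sev * z_conn
        + gender_beta * (female - female.mean())
        + site_effect
    )
    var_sys = float(np.var(systematic))
    resid_sd = float(np.sqrt(max(1.0 - var_sys, 0.05)))
    return systematic + resid_sd * rng.standard_normal(len(z_sev))


def _simulate_dian(params: CohortSimParams, rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    info: dict = {"cohort": "DIAN", "variables": {}, "cognition": {}}
    frames = []
    n_total = sum(params.n_per_group.values())
    # sibling families of size 1-3; kept within carrier group so that the
    # per-stratum family fixed effects stay estimable at these sample sizes
    fam_sizes, fam_groups = [], []
    for group, n in params.n_per_group.items():
        total = 0
        while total < n:
            size = int(min(rng.integers(1, 4), n - total))
            fam_sizes.append(size)
            fam_groups.append(group)
            total += size
    fam_labels = np.repeat([f"F{i:03d}" for i in range(len(fam_sizes))], fam_sizes)
    offset = 0

    site_ids = rng.integers(0, params.n_sites, size=n_total)
    site_effects = params.site_sd * rng.standard_normal(params.n_sites)
    scanners = np.array(["Verio", "Trio", "Prisma"])[site_ids % 3]

    for group in params.n_per_group:
        n = params.n_per_group[group]
        sl = slice(offset, offset + n)
        offset += n
        affected = group == "MC"

        eyo_mean, eyo_sd = ref.DIAN_GROUP_STATS["eyo"][group]
        eyo = np.clip(eyo_mean + eyo_sd * rng.standard_normal(n), -30.0, 15.0)
        onset_age = np.clip(47.3 + 5.0 * rng.standard_normal(n), 35.0, 60.0)
        age = np.clip(eyo + onset_age, 18.0, 70.0)
        female = (rng.random(n) < 0.55).astype(float)

        # connectivity / education via a Gaussian copula
        z1 = rng.standard_normal(n)
        r = params.education_connectivity_r
        z_edu = r * z1 + np.sqrt(1 - r**2) * rng.standard_normal(n)
        z_rfc = 0.6 * z1 + 0.8 * rng.standard_normal(n)

        def group_mean(var: str) -> tuple[float, float]:
            nc_mean, nc_sd = ref.DIAN_GROUP_STATS[var]["NC"]
            mc_sd = ref.DIAN_GROUP_STATS[var]["MC"][1]
            d = params.group_effect_d.get(var, ref.DIAN_EFFECT_SIZES.get(var, 0.0))
            direction = -1.0 if var in ("conn_lfc", "education", "mmse", "lm_delayed") else 1.0
            if affected:
                return nc_mean + direction * d * _rms(mc_sd, nc_sd), mc_sd
            return nc_mean, nc_sd

        conn_mean, conn_sd = group_mean("conn_lfc")
        s2 = np.log(1 + (conn_sd / conn_mean) ** 2)
        conn_lfc = np.exp(np.log(conn_mean) - s2 / 2 + np.sqrt(s2) * z1)
        conn_rfc = np.exp(np.log(conn_mean) - s2 / 2 + np.sqrt(s2) * z_rfc)
        null_mean, null_sd = 0.25, 0.06
        s2n = np.log(1 + (null_sd / null_mean) ** 2)
        conn_occ = np.exp(np.log(null_mean) - s2n / 2 + np.sqrt(s2n) * rng.standard_normal(n))
        conn_m1 = np.exp(np.log(null_mean) - s2n / 2 + np.sqrt(s2n) * rng.standard_normal(n))

        edu_mean, edu_sd = group_mean("education")
        education = np.clip(edu_mean + edu_sd * z_edu, 6.0, 22.0)

        biomarkers = {}
        for var in ("csf_tau", "csf_ptau181", "pib_suvr"):
            mean, sd = group_mean(var)
            if affected:
                e0, tau = params.trajectory_shape.get(var, _DIAN_TRAJECTORIES[var])
                profile, g_mean, g_sd = _sigmoid_profile(eyo, e0, tau)
            else:
                e0 = tau = g_mean = g_sd = None
                profile = None
            vals, gen = _lognormal_matched(rng, n, mean, sd, profile, params.traj_share)
            biomarkers[var] = vals
            info["variables"].setdefault(var, {})[group] = dict(
                gen, kind="lognormal", e0=e0, tau=tau, g_mean=g_mean, g_sd=g_sd,
                mean=mean, sd=sd,
            )
        # hippocampal volume: declining sigmoid, normal scale (mm^3)
        hip_mean, hip_sd = (8200.0, 900.0) if affected else (8800.0, 700.0)
        if affected:
            e0, tau = params.trajectory_shape.get("hippocampal_volume", _DIAN_TRAJECTORIES["hippocampal_volume"])
            profile, g_mean, g_sd = _sigmoid_profile(eyo, e0, tau)
            profile = -profile
        else:
            profile = None
        hippo, gen = _normal_matched(rng, n, hip_mean, hip_sd, profile, params.traj_share)
        info["variables"].setdefault("hippocampal_volume", {})[group] = dict(gen, kind="normal")

        # amyloid ratio: carriers low, non-carriers normal (not cut-off defined in DIAN)
        ratio = np.clip(
            (0.06 if affected else 0.12) + 0.015 * rng.standard_normal(n), 0.01, 0.2
        )

        site = site_ids[sl]
        z_sev = _standardize(eyo)
        z_conn = _standardize(np.log(conn_lfc))
        cognition = {}
        for outcome, scale in _COGNITION_SCALES["DIAN"].items():
            betas = params.effects.get(outcome, _NULL_EFFECTS) if affected else _NULL_EFFECTS
            z_out = _plant_cognition(
                rng, z_sev, z_conn, female, site_effects[site], betas,
                params.gender_beta, params.site_sd,
            )
            d = params.group_effect_d.get(outcome, scale["d"])
            if affected:
                mean = scale["ref_mean"] - d * _rms(scale["aff_sd"], scale["ref_sd"])
                sd = scale["aff_sd"]
            else:
                mean, sd = scale["ref_mean"], scale["ref_sd"]
            cognition[outcome] = np.clip(mean + sd * z_out, *scale["bounds"])
            info["cognition"].setdefault(outcome, {})[group] = dict(
                betas=dict(betas), raw_mean=mean, raw_sd=sd,
                eyo_mean=float(eyo.mean()), eyo_sd=float(eyo.std(ddof=1)),
            )

        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"DIAN{group}{i:03d}" for i in range(n)],
                    "cohort": "DIAN",
                    "group": group,
                    "abeta_status": np.where(ratio < 0.1, "pos", "neg"),
                    "eyo": eyo,
                    "age": age,
                    "gender": np.where(female > 0, "female", "male"),
                    "education": education,
                    "family_id": fam_labels[sl],
                    "site_id": [f"site{s:02d}" for s in site],
                    "scanner_model": scanners[sl],
                    "csf_tau": biomarkers["csf_tau"],
                    "csf_ptau181": biomarkers["csf_ptau181"],
                    "csf_abeta_ratio": ratio,
                    "pib_suvr": biomarkers["pib_suvr"],
                    "hippocampal_volume": hippo,
                    "mmse": cognition["mmse"],
                    "lm_delayed": cognition["lm_delayed"],
                    "adas_recall": np.nan,
                    "conn_lfc": conn_lfc,
                    "conn_rfc": conn_rfc,
                    "conn_occ": conn_occ,
                    "conn_m1": conn_m1,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return table, info


#: DELCODE diagnostic groups per amyloid stratum and severity ordering.
_DELCODE_GROUPS = {"abeta_pos": ("CN", "SCD", "MCI", "ADD"), "abeta_neg": ("CN", "SCD")}


def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, low: float, high: float
) -> np.ndarray:
    out = mean + sd * rng.standard_normal(n)
    bad = (out < low) | (out >= high)
    while bad.any():
        out[bad] = mean + sd * rng.standard_normal(int(bad.sum()))
        bad = (out < low) | (out >= high)
    return out


def _simulate_delcode(params: CohortSimParams, rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    info: dict = {"cohort": "DELCODE", "variables": {}, "cognition": {}}
    frames = []
    subject_counter = 0
    for stratum, groups in _DELCODE_GROUPS.items():
        stats = ref.DELCODE_ABPOS_GROUP_STATS if stratum == "abeta_pos" else ref.DELCODE_ABNEG_GROUP_STATS
        affected = stratum == "abeta_pos"
        stratum_rows = []
        for diag in groups:
            n = params.n_per_group[f"{stratum}:{diag}"]
            age_m, age_s = stats["age"][diag]
            edu_m, edu_s = stats["education"][diag]
            tau_m, tau_s = stats["csf_tau"][diag]
            ptau_m, ptau_s = stats["csf_ptau181"][diag]
            conn_m, conn_s = stats["conn_lfc"][diag]
            ratio_m, ratio_s = stats["csf_abeta_ratio"][diag]

            z1 = rng.standard_normal(n)
            r = params.education_connectivity_r
            z_edu = r * z1 + np.sqrt(1 - r**2) * rng.standard_normal(n)
            s2 = np.log(1 + (conn_s / conn_m) ** 2)
            conn_lfc = np.exp(np.log(conn_m) - s2 / 2 + np.sqrt(s2) * z1)
            conn_rfc = np.exp(
                np.log(conn_m) - s2 / 2 + np.sqrt(s2) * (0.6 * z1 + 0.8 * rng.standard_normal(n))
            )
            s2n = np.log(1 + (0.06 / 0.25) ** 2)
            conn_occ = np.exp(np.log(0.25) - s2n / 2 + np.sqrt(s2n) * rng.standard_normal(n))
            conn_m1 = np.exp(np.log(0.25) - s2n / 2 + np.sqrt(s2n) * rng.standard_normal(n))

            tau, _ = _lognormal_matched(rng, n, tau_m, tau_s)
            ptau, _ = _lognormal_matched(rng, n, ptau_m, ptau_s)
            # amyloid status is defined by the ratio cut-off, so the ratio is
            # drawn truncated on the correct side of 0.1 for the stratum
            if affected:
                ratio = _truncated_normal(rng, n, ratio_m, ratio_s, 0.005, 0.1)
            else:
                ratio = _truncated_normal(rng, n, ratio_m, ratio_s, 0.1, 0.25)

            stratum_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": [f"DEL{subject_counter + i:03d}" for i in range(n)],
                        "cohort": "DELCODE",
                        "group": diag,
                        "abeta_status": "pos" if affected else "neg",
                        "eyo": np.nan,
                        "age": np.clip(age_m + age_s * rng.standard_normal(n), 55.0, 90.0),
                        "gender": np.where(rng.random(n) < 0.55, "female", "male"),
                        "education": np.clip(edu_m + edu_s * z_edu, 6.0, 22.0),
                        "site_id": [f"site{int(s):02d}" for s in rng.integers(0, params.n_sites, n)],
                        "csf_tau": tau,
                        "csf_ptau181": ptau,
                        "csf_abeta_ratio": ratio,
                        "pib_suvr": np.nan,
                        "conn_lfc": conn_lfc,
                        "conn_rfc": conn_rfc,
                        "conn_occ": conn_occ,
                        "conn_m1": conn_m1,
                    }
                )
            )
            subject_counter += n
        sdf = pd.concat(stratum_rows, ignore_index=True)
        sdf["family_id"] = sdf["subject_id"]
        sdf["scanner_model"] = np.array(["Verio", "Trio", "Skyra"])[
            sdf["site_id"].str.slice(4).astype(int) % 3
        ]

        site_effects = params.site_sd * rng.standard_normal(params.n_sites)
        site_idx = sdf["site_id"].str.slice(4).astype(int).to_numpy()
        z_sev = _standardize(np.log(sdf["csf_tau"].to_numpy()))
        z_conn = _standardize(np.log(sdf["conn_lfc"].to_numpy()))
        female = (sdf["gender"] == "female").to_numpy(dtype=float)
        # hippocampal volume declines with tau
        sdf["hippocampal_volume"] = 8500.0 - 400.0 * z_sev + 600.0 * rng.standard_normal(len(sdf))

        for outcome, scale in _COGNITION_SCALES["DELCODE"].items():
            betas = params.effects.get(outcome, _NULL_EFFECTS) if affected else _NULL_EFFECTS
            z_out = _plant_cognition(
                rng, z_sev, z_conn, female, site_effects[site_idx], betas,
                params.gender_beta, params.site_sd,
            )
            mean = scale["ref_mean"] - (scale["d"] * _rms(scale["aff_sd"], scale["ref_sd"]) if affected else 0.0)
            sd = scale["aff_sd"] if affected else scale["ref_sd"]
            sdf[outcome] = np.clip(mean + sd * z_out, *scale["bounds"])
            info["cognition"].setdefault(outcome, {})[stratum] = dict(
                betas=dict(betas), raw_mean=mean, raw_sd=sd
            )
        frames.append(sdf)
    table = pd.concat(frames, ignore_index=True)
    return table, info


def simulate_cohort(params: CohortSimParams, return_info: bool = False):
    """Generate a phenotype table for one cohort.

    Returns the table (and, with ``return_info``, a dictionary of the
    generating constants: log-scale trajectory coefficients per biomarker and
    group, and the cognition betas and raw scales — used by recovery checks
    to compare fitted curves against the true planted course).
    """
    if params.n_per_group is None:
        params = (
            dian_default_params(rng_seed=params.rng_seed)
            if params.cohort == "DIAN"
            else delcode_default_params(rng_seed=params.rng_seed)
        )
    rng = np.random.default_rng(params.rng_seed)
    if params.cohort == "DIAN":
        table, info = _simulate_dian(params, rng)
    elif params.cohort == "DELCODE":
        table, info = _simulate_delcode(params, rng)
    else:
        raise ValueError(f"unknown cohort '{params.cohort}'")
    info["params"] = params
    return (table, info) if return_info else table


def true_log_difference_curve(
    info: dict, table: pd.DataFrame, variable: str, grid
) -> np.ndarray:
    """Generating-model MC-minus-NC difference for a lognormal biomarker.

    Evaluated on the log scale (where the sigmoid is planted) and divided by
    the pooled sample SD of the log values — the same scale on which
    trajectory models fit log-z transformed outcomes.
    """
    grid = np.asarray(grid, dtype=float)
    v1 = info["variables"][variable]["MC"]
    v2 = info["variables"][variable]["NC"]
    g = 1.0 / (1.0 + np.exp(-(grid - v1["e0"]) / v1["tau"]))
    mean1 = v1["c"] + v1["b"] * (g - v1["g_mean"]) / v1["g_sd"]
    mean2 = v2["c"]
    pooled_sd = float(np.log(table[variable].to_numpy(dtype=float)).std(ddof=1))
    return (mean1 - mean2) / pooled_sd
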
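"""Published baseline characteristics of the DIAN and DELCODE samples.

These are the group-level summary statistics (means, SDs, counts and
effect sizes) reported for the two cohorts this package targets: the DIAN
sample of autosomal-dominant Alzheimer's disease mutation carriers (MC) and
non-carrier siblings (NC), and the DELCODE sample of sporadic Alzheimer's
disease spanning cognitively normal (CN), subjective cognitive decline (SCD),
mild cognitive impairment (MCI) and dementia (ADD) groups, stratified by CSF
amyloid status.

They serve two purposes: (i) defaults for the cohort simulator, so synthetic
tables reproduce the published group structure; (ii) inputs for effect-size
and contingency-table recomputation. The group means are mutually consistent
under the root-mean-square Cohen's d convention

    d = |m1 - m2| / sqrt((s1^2 + s2^2) / 2),

which is the convention used throughout this package (see
:func:`hubreserve.cohort_stats.cohens_d`).
"""

from __future__ import annotations

__all__ = [
    "DIAN_GROUP_STATS",
    "DIAN_GENDER_COUNTS",
    "DELCODE_ABPOS_GROUP_STATS",
    "DELCODE_ABPOS_GENDER_COUNTS",
    "DELCODE_ABNEG_GROUP_STATS",
    "DIAN_EFFECT_SIZES",
    "DELCODE_EFFECT_SIZES_ADD_VS_CN",
    "RESERVE_MODEL_EFFECTS",
    "DIAN_SAMPLE_SIZES",
    "DELCODE_SAMPLE_SIZES",
]

#: DIAN baseline sample sizes.
DIAN_SAMPLE_SIZES = {"MC": 74, "NC": 55}

#: DELCODE baseline sample sizes by amyloid stratum and diagnostic group.
DELCODE_SAMPLE_SIZES = {
    "abeta_pos": {"CN": 25, "SCD": 23, "MCI": 14, "ADD": 13},
    "abeta_neg": {"CN": 24, "SCD": 17},
}

#: DIAN per-group mean (SD) of the baseline variables, keyed variable -> group.
DIAN_GROUP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"MC": (37.49, 10.05), "NC": (37.84, 10.31)},
    "education": {"MC": (14.47, 3.2), "NC": (15.51, 2.16)},
    "eyo": {"MC": (-9.82, 11.00), "NC": (-9.61, 11.77)},
    "pib_suvr": {"MC": (2.12, 1.25), "NC": (1.04, 0.05)},
    "csf_tau": {"MC": (110.0, 89.48), "NC": (55.19, 22.2)},
    "csf_ptau181": {"MC": (60.82, 35.58), "NC": (29.77, 9.41)},
    "conn_lfc": {"MC": (0.27, 0.07), "NC": (0.30, 0.07)},
    "lm_delayed": {"MC": (10.08, 6.13), "NC": (13.98, 3.71)},
    "mmse": {"MC": (27.04, 5.1), "NC": (29.45, 1.02)},
}

#: DIAN gender contingency counts (female, male) per group.
DIAN_GENDER_COUNTS = {"MC": (42, 32), "NC": (34, 21)}

#: DELCODE amyloid-positive stratum, mean (SD) keyed variable -> diagnostic group.
DELCODE_ABPOS_GROUP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"CN": (67.76, 5.23), "SCD": (72.26, 4.16), "MCI": (74.64, 5.34), "ADD": (71.31, 6.18)},
    "education": {"CN": (14.64, 2.93), "SCD": (14.87, 3.81), "MCI": (14.71, 3.58), "ADD": (14.00, 3.11)},
    "csf_abeta_ratio": {"CN": (0.08, 0.02), "SCD": (0.08, 0.02), "MCI": (0.06, 0.02), "ADD": (0.04, 0.01)},
    "csf_tau": {"CN": (357.08, 136.91), "SCD": (395.16, 178.58), "MCI": (534.97, 172.61), "ADD": (818.53, 322.62)},
    "csf_ptau181": {"CN": (49.08, 17.06), "SCD": (53.96, 25.89), "MCI": (71.99, 21.37), "ADD": (101.6, 45.58)},
    "conn_lfc": {"CN": (0.23, 0.05), "SCD": (0.25, 0.05), "MCI": (0.23, 0.05), "ADD": (0.22, 0.03)},
    "lm_delayed": {"CN": (14.57, 8.15), "SCD": (12.00, 7.18), "MCI": (10.60, 6.47), "ADD": (6.69, 7.26)},
    "mmse": {"CN": (29.20, 0.96), "SCD": (29.39, 0.78), "MCI": (27.71, 1.68), "ADD": (23.85, 2.82)},
}

#: DELCODE amyloid-positive gender counts (female, male) per diagnostic group.
DELCODE_ABPOS_GENDER_COUNTS = {"CN": (16, 9), "SCD": (10, 13), "MCI": (5, 9), "ADD": (9, 4)}

#: DELCODE amyloid-negative stratum, mean (SD) keyed variable -> group.
DELCODE_ABNEG_GROUP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"CN": (67.29, 4.6), "SCD": (71.06, 5.53)},
    "education": {"CN": (14.54, 2.62), "SCD": (15.35, 3.16)},
    "csf_abeta_ratio": {"CN": (0.12, 0.02), "SCD": (0.12, 0.01)},
    "csf_tau": {"CN": (320.78, 112.02), "SCD": (355.84, 114.32)},
    "csf_ptau181": {"CN": (51.57, 16.28), "SCD": (50.35, 21.1)},
    "conn_lfc": {"CN": (0.25, 0.06), "SCD": (0.23, 0.04)},
    "lm_delayed": {"CN": (16.56, 8.26), "SCD": (9.06, 2.19)},
    "mmse": {"CN": (29.67, 0.76), "SCD": (29.06, 0.9)},
}

#: Published DIAN MC-vs-NC effect sizes (RMS Cohen's d convention).
DIAN_EFFECT_SIZES = {
    "pib_suvr": 1.22,
    "csf_tau": 0.84,
    "csf_ptau181": 1.19,
    "mmse": 0.66,
    "lm_delayed": 0.77,
    "conn_lfc": 0.43,
    "education": 0.38,
}

#: Published DELCODE ADD-vs-CN effect sizes within the amyloid-positive stratum.
DELCODE_EFFECT_SIZES_ADD_VS_CN = {"csf_abeta_ratio": 2.53, "mmse": 2.54}

#: Published standardized coefficients of the reserve moderation models
#: (severity x connectivity interactions on cognition), used as simulator
#: defaults. Keys: (cohort, stratum, outcome) -> dict of standardized betas.
RESERVE_MODEL_EFFECTS = {
    ("DIAN", "MC", "mmse"): {"severity": -0.576, "connectivity": 0.216, "interaction": 0.269},
    ("DIAN", "MC", "lm_delayed"): {"severity": -0.458, "connectivity": 0.047, "interaction": 0.275},
    ("DELCODE", "abeta_pos", "mmse"): {"severity": -0.553, "connectivity": 0.159, "interaction": 0.285},
    ("DELCODE", "abeta_pos", "lm_delayed"): {"severity": -0.327, "connectivity": -0.011, "interaction": 0.336},
    ("DELCODE", "abeta_pos", "adas_recall"): {"severity": -0.35, "connectivity": 0.0, "interaction": 0.289},
}
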
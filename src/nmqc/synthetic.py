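"""Synthetic cohorts for normative-modelling QC.

Generates tabular cohorts with the statistical structure the downstream
analysis assumes: smooth age trends over 45-85 years, skewed / heavy-tailed
phenotype noise, rare multi-class artefact contamination, two noisy visual
raters and a table of quantitative QC descriptors.  No images are
synthesized — only their tabular consequences.

The clean generative law is model-matched: for each IDP a latent value
t = trend(age) + Gaussian noise is drawn and mapped to the phenotype scale
through the inverse sinh-arcsinh warp, so a warped-BLR normative model is
correctly specified and parameter / centile recovery is a meaningful test.
A model-mismatch mode with Student-t latent noise is available to probe
robustness.  Artefact contamination shifts the latent value by a stated
number of residual standard deviations, which is the scale on which the
deviation z-scores operate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .basis import BSplineBasis
from .warp import WarpParams, warp_inverse

__all__ = [
    "ArtefactSpec",
    "CohortSpec",
    "IdpParams",
    "default_idp_names",
    "default_idp_params",
    "generate_cohort",
    "generate_rater_scores",
    "generate_qqc_table",
    "QQC_DESCRIPTORS",
]

METRICS = ("FA", "MD", "ICVF", "ISOVF")
TRACTS = (
    "corpus_callosum",
    "corticospinal_tract_L",
    "corticospinal_tract_R",
    "uncinate_fasciculus_L",
    "uncinate_fasciculus_R",
    "fornix",
)

CATEGORIES = ("acquisition", "processing", "incidental")


def default_idp_names() -> list:
    """The default 24 IDPs: 4 diffusion metrics x 6 white-matter tracts."""
    return [f"{m}_{t}" for m in METRICS for t in TRACTS]


@dataclass(frozen=True)
class IdpParams:
    """Generative law for one IDP.

    ``trend`` holds the B-spline control values of the latent age trend
    (latent scale, one per basis function); ``warp`` maps latent to
    phenotype units; ``noise_scale`` is the latent residual SD.
    """

    warp: WarpParams
    trend: tuple
    noise_scale: float = 1.0

    def __post_init__(self):
        if not self.noise_scale > 0:
            raise ValueError(f"noise_scale must be positive, got {self.noise_scale}")


# Typical phenotype locations/scales: FA and the NODDI volume fractions are
# dimensionless in (0, 1); MD is in units of 1e-3 mm^2/s.  Trends: FA and
# ICVF decline with age, MD and ISOVF increase — the canonical ageing
# pattern in white matter.  Mild skew/tail parameters give the
# non-Gaussian shape the warp is there to absorb.
_METRIC_DEFAULTS = {
    "FA": dict(a0=0.45, b0=0.035, epsilon=-0.2, delta=1.1, slope=-1.0),
    "MD": dict(a0=0.80, b0=0.045, epsilon=0.35, delta=0.9, slope=1.2),
    "ICVF": dict(a0=0.55, b0=0.040, epsilon=0.25, delta=0.95, slope=-0.9),
    "ISOVF": dict(a0=0.15, b0=0.030, epsilon=0.5, delta=0.85, slope=1.0),
}

# small per-tract curvature so trends are smooth but not all linear
_TRACT_CURVE = {
    "corpus_callosum": 0.15,
    "corticospinal_tract_L": 0.05,
    "corticospinal_tract_R": 0.05,
    "uncinate_fasciculus_L": -0.10,
    "uncinate_fasciculus_R": -0.10,
    "fornix": 0.30,
}


def default_idp_params(idp_names=None, n_basis: int = 7) -> dict:
    """Default per-IDP generative parameters keyed by IDP name."""
    idp_names = list(idp_names) if idp_names is not None else default_idp_names()
    params = {}
    u = np.linspace(-1.0, 1.0, n_basis)
    for name in idp_names:
        metric = name.split("_", 1)[0]
        tract = name.split("_", 1)[1] if "_" in name else ""
        d = _METRIC_DEFAULTS.get(metric, _METRIC_DEFAULTS["FA"])
        curve = _TRACT_CURVE.get(tract, 0.0)
        trend = d["slope"] * u + curve * (u**2 - 1.0 / 3.0)
        params[name] = IdpParams(
            warp=WarpParams(a0=d["a0"], b0=d["b0"], epsilon=d["epsilon"], delta=d["delta"]),
            trend=tuple(float(v) for v in trend),
            noise_scale=1.0,
        )
    return params


@dataclass(frozen=True)
class ArtefactSpec:
    """One contamination class.

    ``shift_sd`` displaces the latent IDP value by that many residual SDs
    (either sign) in the affected IDPs only; ``severity_score`` is the
    ground-truth visual severity used to drive the simulated raters.
    """

    category: str
    prevalence: float
    affected_idps: tuple
    shift_sd: float = 10.0
    severity_score: int = 3

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category must be one of {CATEGORIES}, got {self.category!r}"
            )
        if not 0 <= self.prevalence < 0.1:
            raise ValueError(
                f"prevalence must be in [0, 0.1) (rare-event regime), got {self.prevalence}"
            )
        if len(self.affected_idps) == 0:
            raise ValueError("affected_idps must be non-empty")
        if self.severity_score not in (2, 3):
            raise ValueError(f"severity_score must be 2 or 3, got {self.severity_score}")


def default_contamination(idp_names=None) -> list:
    """Default artefact classes mirroring the three error categories.

    Acquisition artefacts hit every metric in two tracts; processing
    errors preferentially hit MD and ISOVF; an incidental finding hits a
    single tract.  Total prevalence ~1.7%.
    """
    idp_names = list(idp_names) if idp_names is not None else default_idp_names()

    def sel(pred):
        return tuple(n for n in idp_names if pred(n))

    acq = sel(lambda n: n.endswith(("corticospinal_tract_L", "corticospinal_tract_R")))
    proc = sel(lambda n: n.startswith(("MD", "ISOVF")))
    inc = sel(lambda n: n.endswith("corpus_callosum"))
    specs = []
    if acq:
        specs.append(ArtefactSpec("acquisition", 0.008, acq, shift_sd=10.0, severity_score=3))
    if proc:
        specs.append(ArtefactSpec("processing", 0.006, proc, shift_sd=-10.0, severity_score=3))
    if inc:
        specs.append(ArtefactSpec("incidental", 0.003, inc, shift_sd=10.0, severity_score=2))
    return specs


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one synthetic cohort."""

    n_subjects: int
    age_range: tuple = (45.0, 85.0)
    idp_names: tuple = field(default_factory=lambda: tuple(default_idp_names()))
    idp_params: dict | None = None  # name -> IdpParams; default_idp_params if None
    contamination: tuple = ()
    rater_reliability: float = 0.9
    latent_noise: str = "gaussian"  # or "student-t" (model-mismatch mode)
    student_df: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"age_range min must be < max, got {self.age_range}")
        if not 0 <= self.rater_reliability <= 1:
            raise ValueError(
                f"rater_reliability must be in [0, 1], got {self.rater_reliability}"
            )
        if self.latent_noise not in ("gaussian", "student-t"):
            raise ValueError(f"unknown latent_noise {self.latent_noise!r}")
        total = sum(a.prevalence for a in self.contamination)
        if total >= 1:
            raise ValueError(f"contamination prevalences sum to {total} >= 1")
        known = set(self.idp_names)
        for a in self.contamination:
            unknown = set(a.affected_idps) - known
            if unknown:
                raise ValueError(f"affected_idps not in idp_names: {sorted(unknown)}")

    def resolved_params(self) -> dict:
        if self.idp_params is not None:
            missing = set(self.idp_names) - set(self.idp_params)
            if missing:
                raise ValueError(f"idp_params missing entries for {sorted(missing)}")
            return self.idp_params
        return default_idp_params(self.idp_names)


def _trend_basis(age_range, n_basis: int) -> BSplineBasis:
    # same clamped-cubic family the normative model uses, on the spec's range
    knots = np.linspace(age_range[0], age_range[1], n_basis - 2)
    return BSplineBasis(knots=tuple(knots), order=4)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table: one row per subject.

    Columns: ``subject_id``, ``age``, ``sex``, one column per IDP,
    ``true_category`` (clean or artefact class), ``true_severity``,
    ``rater1``/``rater2`` visual scores.  Deterministic given the spec.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    params = spec.resolved_params()

    ages = rng.uniform(spec.age_range[0], spec.age_range[1], size=n)
    sex = rng.integers(0, 2, size=n)  # generated but unused as covariate

    # per-subject artefact category (at most one per subject)
    probs = [a.prevalence for a in spec.contamination]
    clean_p = 1.0 - sum(probs)
    cat_idx = rng.choice(len(probs) + 1, size=n, p=[clean_p] + probs)
    categories = np.array(
        ["clean"] + [a.category for a in spec.contamination], dtype=object
    )[cat_idx]
    severity = np.ones(n, dtype=int)
    for j, a in enumerate(spec.contamination, start=1):
        severity[cat_idx == j] = a.severity_score

    n_basis = len(next(iter(params.values())).trend)
    basis = _trend_basis(spec.age_range, n_basis)
    Phi = basis.design_matrix(ages)

    data = {"subject_id": [f"sub-{i:06d}" for i in range(n)], "age": ages, "sex": sex}
    for name in spec.idp_names:
        p = params[name]
        if len(p.trend) != n_basis:
            raise ValueError(f"trend length mismatch for {name}")
        if spec.latent_noise == "gaussian":
            noise = rng.normal(0.0, p.noise_scale, size=n)
        else:
            df = spec.student_df
            scale = p.noise_scale / np.sqrt(df / (df - 2.0))
            noise = rng.standard_t(df, size=n) * scale
        t = Phi @ np.asarray(p.trend) + noise
        for j, a in enumerate(spec.contamination, start=1):
            if name in a.affected_idps:
                hit = cat_idx == j
                t[hit] += a.shift_sd * p.noise_scale
        data[name] = warp_inverse(t, p.warp)

    df = pd.DataFrame(data)
    df["true_category"] = categories
    df["true_severity"] = severity
    r1, r2 = generate_rater_scores(
        severity, spec.rater_reliability, seed=int(rng.integers(2**31))
    )
    df["rater1"] = r1
    df["rater2"] = r2
    return df


def generate_rater_scores(truth, reliability: float, seed: int = 0):
    """Simulate two independent visual raters scoring severity 1-3.

    Each rater reports the true severity with probability ``reliability``;
    otherwise the score is confused to an adjacent severity (random
    direction) and clipped to {1, 3}.  ``reliability=1`` reproduces the
    truth exactly for both raters.
    """
    if not 0 <= reliability <= 1:
        raise ValueError(f"reliability must be in [0, 1], got {reliability}")
    truth = np.asarray(truth, dtype=int)
    if truth.size and not np.all(np.isin(truth, (1, 2, 3))):
        raise ValueError("truth severities must be in {1, 2, 3}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(2):
        agree = rng.random(truth.size) < reliability
        step = rng.choice((-1, 1), size=truth.size)
        scores = np.where(agree, truth, np.clip(truth + step, 1, 3))
        out.append(scores.astype(int))
    return out[0], out[1]


# the 21 quantitative QC descriptors: (name, baseline mean, baseline SD)
QQC_DESCRIPTORS = (
    ("avg_abs_motion", 0.45, 0.15),
    ("avg_rel_motion", 0.25, 0.08),
    ("avg_translation", 0.60, 0.20),
    ("avg_rotation", 0.30, 0.10),
    ("std_translation", 0.20, 0.07),
    ("std_rotation", 0.10, 0.04),
    ("outlier_slices_pct", 0.80, 0.40),
    ("outlier_slices_b1000", 1.50, 0.70),
    ("outlier_slices_b2000", 2.50, 1.00),
    ("snr_b0", 22.0, 3.0),
    ("cnr_b1000", 1.30, 0.20),
    ("cnr_b2000", 0.95, 0.15),
    ("t1_dwi_discrepancy", 0.35, 0.08),
    ("fa_template_discrepancy", 0.30, 0.07),
    ("susceptibility_displacement", 1.10, 0.30),
    ("eddy_displacement", 0.50, 0.15),
    ("brain_coverage_pct", 99.0, 0.50),
    ("dropout_volumes", 1.00, 0.60),
    ("bias_field_rms", 0.12, 0.04),
    ("ghost_ratio", 0.05, 0.015),
    ("tsnr_dwi", 14.0, 2.00),
)

# per-category descriptor shifts, in units of the baseline SD
_QQC_FOOTPRINT = {
    "acquisition": {
        "avg_abs_motion": 3.0,
        "avg_rel_motion": 3.0,
        "outlier_slices_pct": 3.0,
        "outlier_slices_b1000": 2.5,
        "outlier_slices_b2000": 2.5,
        "snr_b0": -3.0,
        "cnr_b1000": -2.0,
        "cnr_b2000": -2.0,
        "brain_coverage_pct": -3.0,
        "dropout_volumes": 3.0,
        "tsnr_dwi": -2.5,
    },
    "processing": {
        "t1_dwi_discrepancy": 3.5,
        "fa_template_discrepancy": 3.5,
        "susceptibility_displacement": 2.0,
        "eddy_displacement": 1.5,
    },
    "incidental": {
        "t1_dwi_discrepancy": 1.5,
        "fa_template_discrepancy": 1.0,
    },
}


def generate_qqc_table(cohort: pd.DataFrame, seed: int = 0, effect_size: float = 1.0) -> pd.DataFrame:
    """Synthesize the 21-descriptor quantitative-QC table for a cohort.

    Clean subjects draw each descriptor from its baseline normal law;
    contaminated subjects receive correlated category-specific shifts
    (acquisition artefacts raise motion and lower SNR, processing errors
    raise registration discrepancies) scaled by ``effect_size``.
    ``effect_size=0`` makes clean and contaminated indistinguishable.
    """
    rng = np.random.default_rng(seed)
    n = len(cohort)
    cats = cohort.get("true_category", pd.Series(["clean"] * n)).to_numpy()
    out = {"subject_id": cohort["subject_id"].to_numpy()}
    for name, mean, sd in QQC_DESCRIPTORS:
        vals = rng.normal(mean, sd, size=n)
        for cat, footprint in _QQC_FOOTPRINT.items():
            shift = footprint.get(name, 0.0)
            if shift:
                vals[cats == cat] += effect_size * shift * sd
        out[name] = vals
    return pd.DataFrame(out)
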
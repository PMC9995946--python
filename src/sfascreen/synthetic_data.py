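"""Three-cohort synthetic data with known structure-function associations.

The generator emulates an ADNI1-like cross-sectional sample of cognitively
normal (CN), MCI and dementia subjects:

* test-score intercepts and total SDs are calibrated to the study cohorts'
  published descriptives (MMSE 29.06/26.91/22.66, etc.);
* within-cohort age slopes equal the published CN slopes, with MCI and
  dementia slopes derived as CN + the published slope-interaction
  coefficients, so global-cognition trends (MMSE, ADAS-13) are flat while
  DSST/TMT trends decline;
* for the converging tests (DSST, TMT-B) the MCI/dementia intercepts are
  derived from the constraint that all three cohort trendlines meet at
  ``convergence_age`` (default 100 years), the behaviour the analyses are
  designed to detect;
* morphometric features are driven by a latent atrophy burden with a
  cohort-specific age trend calibrated to the published GM/TIV slopes,
  plus measurement noise; scores load on the subject-specific morphometric
  deviations through cohort-specific weight vectors — the planted SFA
  "stamps" the classifier has to recognise.

Every score is the sum of a cohort trendline, a weighted morphometric
deviation term scaled by the separation parameter ``delta``, and Gaussian
noise, clipped to the scale bounds.  The weight term is mean-zero given
(cohort, age), so the configured intercepts and slopes are the exact
population values — this is what makes the slope-recovery and convergence
checks sharp.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import COHORTS, Dataset
from .exceptions import UnsupportedOperationError, ValidationError
from .features import default_feature_names
from .scales import SCALES, TESTS

__all__ = [
    "SyntheticConfig",
    "default_config",
    "exchangeable_null_config",
    "noise_free_config",
    "generate_cohorts",
    "planted_truth",
    "AGE_MIDPOINT",
    "COHORT_MEANS",
    "COHORT_SDS",
    "CN_AGE_SLOPES",
    "SLOPE_INTERACTIONS",
    "GM_TIV_SLOPES",
]

# --- published cohort calibration -----------------------------------------

#: Cohort sample sizes of the reference study (CN / MCI / Dementia).
COHORT_SIZES: dict[str, int] = {"CN": 287, "MCI": 646, "Dementia": 369}

#: Cohort mean test scores.
COHORT_MEANS: dict[str, dict[str, float]] = {
    "CN": {"MMSE": 29.06, "ADAS13": 8.73, "RAVLT_imm": 43.2, "TMT_B": 85.03, "DSST": 46.77},
    "MCI": {"MMSE": 26.91, "ADAS13": 18.82, "RAVLT_imm": 29.79, "TMT_B": 128.48, "DSST": 37.37},
    "Dementia": {"MMSE": 22.66, "ADAS13": 30.37, "RAVLT_imm": 21.67, "TMT_B": 200.96, "DSST": 26.05},
}

#: Cohort score standard deviations (total spread, not residual noise).
COHORT_SDS: dict[str, dict[str, float]] = {
    "CN": {"MMSE": 1.09, "ADAS13": 4.14, "RAVLT_imm": 9.76, "TMT_B": 43.18, "DSST": 11.06},
    "MCI": {"MMSE": 2.2, "ADAS13": 6.6, "RAVLT_imm": 8.86, "TMT_B": 72.56, "DSST": 11.1},
    "Dementia": {"MMSE": 3.03, "ADAS13": 8.97, "RAVLT_imm": 7.77, "TMT_B": 88.57, "DSST": 12.41},
}

#: Within-CN age slopes (score units / year).
CN_AGE_SLOPES: dict[str, float] = {
    "MMSE": -0.005,
    "ADAS13": 0.092,
    "RAVLT_imm": -0.174,
    "TMT_B": 2.126,
    "DSST": -0.616,
}

#: Age-by-group slope-interaction coefficients relative to CN (units/year).
SLOPE_INTERACTIONS: dict[str, dict[str, float]] = {
    "MCI": {"MMSE": -0.008, "ADAS13": -0.070, "RAVLT_imm": 0.064, "TMT_B": -1.629, "DSST": 0.477},
    "Dementia": {"MMSE": -0.002, "ADAS13": -0.076, "RAVLT_imm": 0.199, "TMT_B": -2.383, "DSST": 0.943},
}

#: Gray-matter fraction of TIV: decline per year within each cohort (% TIV / yr).
GM_TIV_SLOPES: dict[str, float] = {"CN": -0.153, "MCI": -0.091 , "Dementia": -0.047}

#: Fraction of women per cohort.
FEMALE_FRACTION: dict[str, float] = {"CN": 0.4669, "MCI": 0.3328, "Dementia": 0.4688}

EDUCATION_YEARS: dict[str, tuple[float, float]] = {
    "CN": (16.13, 2.91),
    "MCI": (15.76, 2.99),
    "Dementia": (14.85, 3.21),
}

#: Tests whose cohort trendlines converge late in life.
CONVERGING_TESTS: tuple[str, ...] = ("TMT_B", "DSST")

AGE_RANGE: tuple[float, float] = (55.0, 90.0)
AGE_MIDPOINT: float = 0.5 * (AGE_RANGE[0] + AGE_RANGE[1])

#: Relative feature change per unit of atrophy burden (per % TIV of GM lost).
_ATROPHY_GAIN = 0.05
#: Gray-matter %TIV at the CN age midpoint.
_GM_BASELINE = 31.0
#: Extra GM %TIV already lost at the midpoint, relative to CN.
_ATROPHY_BASE: dict[str, float] = {"CN": 0.0, "MCI": -2.0, "Dementia": -4.0}

# Baseline magnitudes (CN midpoint) for the feature registry.  Volumes are
# % of TIV; thickness mm; area mm^2.  Values are order-of-magnitude
# realistic, which is all the standardised models see.
_SUBCORTICAL_BASELINE = {
    "hippocampus": 0.27,
    "amygdala": 0.11,
    "thalamus": 0.45,
    "putamen": 0.35,
    "caudate": 0.24,
    "pallidum": 0.12,
    "accumbens": 0.035,
    "lateral_ventricle": 1.5,
    "inferior_lateral_ventricle": 0.05,
    "cerebral_white_matter": 30.0,
    "cerebral_cortex": _GM_BASELINE,
}
_CORTICAL_BASELINE = {
    "bankssts": 0.17, "caudalanteriorcingulate": 0.13, "caudalmiddlefrontal": 0.4,
    "cuneus": 0.25, "entorhinal": 0.12, "frontalpole": 0.08, "fusiform": 0.6,
    "inferiorparietal": 0.9, "inferiortemporal": 0.7, "insula": 0.45,
    "isthmuscingulate": 0.17, "lateraloccipital": 0.8, "lateralorbitofrontal": 0.5,
    "lingual": 0.5, "medialorbitofrontal": 0.35, "middletemporal": 0.75,
    "paracentral": 0.25, "parahippocampal": 0.14, "parsopercularis": 0.3,
    "parsorbitalis": 0.15, "parstriangularis": 0.25, "pericalcarine": 0.15,
    "postcentral": 0.65, "posteriorcingulate": 0.25, "precentral": 0.9,
    "precuneus": 0.65, "rostralanteriorcingulate": 0.16, "rostralmiddlefrontal": 1.0,
    "superiorfrontal": 1.5, "superiorparietal": 0.8, "superiortemporal": 0.8,
    "supramarginal": 0.65, "temporalpole": 0.15, "transversetemporal": 0.07,
}
# Atrophy loadings: how strongly a structure tracks the latent burden.
# Negative loadings = the structure grows with atrophy (ventricles).
_VOLUME_LOADING = {
    "hippocampus": 1.0, "amygdala": 0.9, "accumbens": 0.7, "thalamus": 0.5,
    "putamen": 0.5, "caudate": 0.4, "pallidum": 0.3,
    "cerebral_white_matter": 0.4, "cerebral_cortex": 1.0,
    "lateral_ventricle": -1.2, "inferior_lateral_ventricle": -1.5,
    "entorhinal": 1.0, "parahippocampal": 0.9, "middletemporal": 0.8,
    "inferiortemporal": 0.7, "fusiform": 0.7, "precuneus": 0.7,
    "inferiorparietal": 0.7, "posteriorcingulate": 0.6, "supramarginal": 0.6,
    "superiortemporal": 0.6, "temporalpole": 0.7,
}
_DEFAULT_CORTICAL_LOADING = 0.4
_THICKNESS_LOADING = 0.3
_AREA_LOADING = 0.15


def _baseline(name: str) -> float:
    if name.startswith("vol_"):
        key = name[4:]
        return _SUBCORTICAL_BASELINE.get(key, _CORTICAL_BASELINE.get(key, 0.3))
    if name.startswith("thick_"):
        return 2.5
    if name.startswith("area_"):
        return 5000.0 * _CORTICAL_BASELINE.get(name[5:], 0.3)
    raise KeyError(name)


def _loading(name: str) -> float:
    if name.startswith("vol_"):
        return _VOLUME_LOADING.get(name[4:], _DEFAULT_CORTICAL_LOADING)
    if name.startswith("thick_"):
        return _THICKNESS_LOADING
    if name.startswith("area_"):
        return _AREA_LOADING
    raise KeyError(name)


# --- configuration ---------------------------------------------------------


@dataclass
class SyntheticConfig:
    """Full generative specification of the three-cohort simulator.

    ``score_sd`` is the target *total* within-cohort SD; the Gaussian score
    noise gets ``sqrt(1 - feature_signal_fraction)`` of the variance and
    the morphometry-linked term is scaled to supply the rest.  ``separation``
    (the separation delta) multiplies the morphometry-linked term, so delta = 0
    removes the structure-function association entirely.
    """

    n_per_cohort: dict[str, int]
    age_range: tuple[float, float] = AGE_RANGE
    feature_names: tuple[str, ...] = field(default_factory=lambda: tuple(default_feature_names()))
    weight_vectors: dict[tuple[str, str], np.ndarray] = field(default_factory=dict, repr=False)
    score_intercepts: dict[str, dict[str, float]] = field(default_factory=dict)
    score_sd: dict[str, dict[str, float]] = field(default_factory=dict)
    age_slopes: dict[str, dict[str, float]] = field(default_factory=dict)
    convergence_age: float = 100.0
    atrophy_slopes: dict[str, float] = field(default_factory=lambda: dict(GM_TIV_SLOPES))
    atrophy_base: dict[str, float] = field(default_factory=lambda: dict(_ATROPHY_BASE))
    atrophy_noise_sd: float = 1.0
    feature_noise_sd: float = 0.05  # relative (CV) measurement noise
    feature_signal_fraction: float = 0.5
    score_noise_scale: float = 1.0
    separation: float = 1.0  # delta
    female_fraction: dict[str, float] = field(default_factory=lambda: dict(FEMALE_FRACTION))
    education_years: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(EDUCATION_YEARS)
    )
    seed: int = 0

    @property
    def age_midpoint(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])

    def score_noise_sd(self, cohort: str, test: str) -> float:
        """Residual (Gaussian) score noise SD after the variance split."""
        total = self.score_sd[cohort][test]
        return total * np.sqrt(1.0 - self.feature_signal_fraction) * self.score_noise_scale

    def validate(self) -> None:
        for cohort in COHORTS:
            if self.n_per_cohort.get(cohort, 0) < 0:
                raise ValidationError(f"negative cohort size for {cohort}")
            for test in TESTS:
                for table, label in (
                    (self.score_intercepts, "intercept"),
                    (self.score_sd, "sd"),
                    (self.age_slopes, "slope"),
                ):
                    v = table[cohort][test]
                    if not np.isfinite(v):
                        raise ValidationError(f"non-finite {label} for ({cohort}, {test}): {v}")
                if self.score_sd[cohort][test] < 0:
                    raise ValidationError(f"negative score SD for ({cohort}, {test})")
        for scalar in (
            self.atrophy_noise_sd,
            self.feature_noise_sd,
            self.separation,
            self.score_noise_scale,
        ):
            if not np.isfinite(scalar) or scalar < 0:
                raise ValidationError(f"noise/separation parameters must be finite and >= 0, got {scalar}")
        if not 0.0 <= self.feature_signal_fraction < 1.0:
            raise ValidationError("feature_signal_fraction must be in [0, 1)")


def _derive_intercepts(age_slopes: dict[str, dict[str, float]], convergence_age: float) -> dict:
    """Cohort intercepts at the age midpoint.

    Non-converging tests take the published cohort means.  For DSST/TMT the
    CN line is anchored at the CN mean and the MCI/dementia intercepts are
    solved from concurrency of the three trendlines at ``convergence_age``.
    """
    span = convergence_age - AGE_MIDPOINT
    out: dict[str, dict[str, float]] = {c: dict(COHORT_MEANS[c]) for c in COHORTS}
    for test in CONVERGING_TESTS:
        at_conv = COHORT_MEANS["CN"][test] + age_slopes["CN"][test] * span
        for cohort in ("MCI", "Dementia"):
            out[cohort][test] = at_conv - age_slopes[cohort][test] * span
    return out


def default_config(
    n_per_cohort: dict[str, int] | None = None,
    seed: int = 0,
    feature_names=None,
    n_signal_features: int = 15,
) -> SyntheticConfig:
    """The calibrated study conditions.

    Cohort sizes default to the reference study's 287/646/369.  Weight
    vectors (the cohort-specific SFA patterns) are sparse Gaussian vectors
    over a cohort-and-test-specific support, drawn from a fixed internal
    stream so they are part of the configuration, not of the data seed.
    """
    names = tuple(feature_names) if feature_names is not None else tuple(default_feature_names())
    slopes = {"CN": dict(CN_AGE_SLOPES)}
    for cohort in ("MCI", "Dementia"):
        slopes[cohort] = {
            t: CN_AGE_SLOPES[t] + SLOPE_INTERACTIONS[cohort][t] for t in TESTS
        }
    wrng = np.random.default_rng(20240117)  # fixed: weights belong to the config
    weights: dict[tuple[str, str], np.ndarray] = {}
    k = min(n_signal_features, len(names))
    for cohort in COHORTS:
        for test in TESTS:
            w = np.zeros(len(names))
            support = wrng.choice(len(names), size=k, replace=False)
            w[support] = wrng.normal(0.0, 1.0, size=k)
            weights[(cohort, test)] = w
    return SyntheticConfig(
        n_per_cohort=dict(n_per_cohort) if n_per_cohort else dict(COHORT_SIZES),
        feature_names=names,
        weight_vectors=weights,
        score_intercepts=_derive_intercepts(slopes, 100.0),
        score_sd={c: dict(COHORT_SDS[c]) for c in COHORTS},
        age_slopes=slopes,
        seed=seed,
    )


def noise_free_config(config: SyntheticConfig) -> SyntheticConfig:
    """The deterministic limit: no atrophy, measurement or score noise."""
    return dataclasses.replace(
        config, atrophy_noise_sd=0.0, feature_noise_sd=0.0, score_noise_scale=0.0
    )


def exchangeable_null_config(
    n_per_cohort: int = 300, seed: int = 0, feature_names=None
) -> SyntheticConfig:
    """A null world where the three cohorts are identically distributed.

    Every cohort gets the CN intercepts, SDs, slopes and atrophy dynamics
    and the structure-function coupling is switched off (delta = 0); the
    cohort label is then pure convention and any classifier should sit at
    chance.
    """
    cfg = default_config(
        n_per_cohort={c: n_per_cohort for c in COHORTS}, seed=seed, feature_names=feature_names
    )
    cn_int = dict(cfg.score_intercepts["CN"])
    cn_sd = dict(cfg.score_sd["CN"])
    cn_slope = dict(cfg.age_slopes["CN"])
    return dataclasses.replace(
        cfg,
        score_intercepts={c: dict(cn_int) for c in COHORTS},
        score_sd={c: dict(cn_sd) for c in COHORTS},
        age_slopes={c: dict(cn_slope) for c in COHORTS},
        atrophy_slopes={c: GM_TIV_SLOPES["CN"] for c in COHORTS},
        atrophy_base={c: 0.0 for c in COHORTS},
        female_fraction={c: FEMALE_FRACTION["CN"] for c in COHORTS},
        education_years={c: EDUCATION_YEARS["CN"] for c in COHORTS},
        separation=0.0,
    )


# --- generation ------------------------------------------------------------


def _weight_scale(config: SyntheticConfig, cohort: str, test: str, b, g, s) -> float:
    """Scale factor on the raw weight vector hitting the target signal variance.

    The morphometric deviation of feature j is b_j*(gain*l_j*eps_A + cv*eta_j)
    (additive for the GM column), so for weights w the linear term variance
    is (w.g)^2 * sd_A^2 + sum_j (w_j s_j)^2 with g and s precomputed.
    """
    w = config.weight_vectors[(cohort, test)]
    target = config.feature_signal_fraction * config.score_sd[cohort][test] ** 2
    denom = (w @ g) ** 2 * config.atrophy_noise_sd**2 + np.sum((w * s) ** 2)
    if denom <= 0 or target <= 0:
        return 0.0
    return float(np.sqrt(target / denom))


def generate_cohorts(config: SyntheticConfig, seed: int | None = None) -> Dataset:
    """Draw a synthetic three-cohort dataset; bit-reproducible given the seed.

    Per subject: age ~ U(age_range); latent atrophy burden from the
    cohort age trend + Gaussian noise; features from baselines, atrophy
    loadings and measurement noise (clipped at 0); each score from the
    cohort trendline + delta-scaled weighted morphometric deviations +
    Gaussian noise, clipped to the scale bounds.  The generating cohort
    and the noise-free scores are stored as the planted truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    seed_tag = config.seed if seed is None else seed
    names = list(config.feature_names)
    p = len(names)
    b = np.array([_baseline(n) for n in names])
    loads = np.array([_loading(n) for n in names])
    is_gm = np.array([n == "vol_cerebral_cortex" for n in names])
    # sensitivity of each feature to the latent atrophy burden / to noise
    g = np.where(is_gm, 1.0, b * _ATROPHY_GAIN * loads)
    s = b * config.feature_noise_sd
    lo_age, hi_age = config.age_range
    mid = config.age_midpoint

    frames = []
    truths = []
    for cohort in COHORTS:
        n = config.n_per_cohort.get(cohort, 0)
        if n == 0:
            continue
        age = rng.uniform(lo_age, hi_age, size=n)
        d = age - mid
        eps_a = rng.normal(0.0, config.atrophy_noise_sd, size=n)
        burden = config.atrophy_base[cohort] + config.atrophy_slopes[cohort] * d + eps_a
        eta = rng.normal(0.0, 1.0, size=(n, p))
        mean_burden = config.atrophy_base[cohort] + config.atrophy_slopes[cohort] * d
        mult = b[None, :] * (
            1.0
            + _ATROPHY_GAIN * loads[None, :] * burden[:, None]
            + config.feature_noise_sd * eta
        )
        additive = b[None, :] + burden[:, None] + s[None, :] * eta
        feats = np.where(is_gm[None, :], additive, mult)
        mult_mean = b[None, :] * (1.0 + _ATROPHY_GAIN * loads[None, :] * mean_burden[:, None])
        add_mean = b[None, :] + mean_burden[:, None]
        mu = np.where(is_gm[None, :], add_mean, mult_mean)
        deviation = feats - mu  # exactly the eps_A / eta contribution
        feats = np.clip(feats, 0.0, None)

        cols = {
            "subject_id": [f"SYN{seed_tag}-{cohort}-{i:05d}" for i in range(n)],
            "visit_index": np.ones(n, dtype=int),
            "age": age,
            "sex": np.where(rng.random(n) < config.female_fraction[cohort], "F", "M"),
            "education": np.clip(
                rng.normal(*config.education_years[cohort], size=n), 0.0, None
            ),
            "cohort": cohort,
        }
        truth_cols = {"cohort": np.repeat(cohort, n)}
        for test in TESTS:
            scale = SCALES[test]
            w = config.weight_vectors[(cohort, test)] * _weight_scale(
                config, cohort, test, b, g, s
            )
            trend = (
                config.score_intercepts[cohort][test]
                + config.age_slopes[cohort][test] * d
            )
            signal = config.separation * (deviation @ w)
            noise = rng.normal(0.0, 1.0, size=n) * config.score_noise_sd(cohort, test)
            truth_cols[test] = trend + signal
            cols[test] = np.clip(trend + signal + noise, scale.min_score, scale.max_score)
        for j, name in enumerate(names):
            cols[name] = feats[:, j]
        frames.append(pd.DataFrame(cols))
        truths.append(pd.DataFrame(truth_cols))

    frame = pd.concat(frames, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    return Dataset(frame=frame, feature_names=names, provenance="synthetic", truth=truth)


def planted_truth(dataset: Dataset) -> pd.DataFrame:
    """Ground truth of a synthetic dataset: generating cohort + noise-free scores.

    The noise-free scores are pre-clipping trendline + SFA-signal values,
    so observed minus truth is exactly the Gaussian score noise wherever
    clipping did not bind.
    """
    if dataset.provenance != "synthetic" or dataset.truth is None:
        raise UnsupportedOperationError("planted_truth is only defined for synthetic datasets")
    return dataset.truth.copy()
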
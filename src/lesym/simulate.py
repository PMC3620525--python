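"""Synthetic lesion-cohort generator with planted, recoverable effects.

The generator emulates the statistical structure of a cross-sectional
small-vessel-disease cohort on a common analysis grid:

* **Tract atlas** — a few geometric "tracts" (cuboid cores with Gaussian
  probability falloff) standing in for a probabilistic white-matter atlas.
* **WML maps** — per patient, a smooth Gaussian random field is thresholded
  at the per-voxel quantile of a target lesion probability, reproducing
  spatially correlated, confluent white-matter lesions whose prevalence
  peaks centrally.  A log-normal per-patient burden multiplier creates the
  heavy-tailed between-patient spread of total WML volume.  The circular
  (wrap) filtering keeps the field exactly unit-variance everywhere, so the
  marginal per-voxel lesion rate equals the requested probability.
* **LL maps** — sparse small spheres (lacunes, 3-15 mm diameter at 2 mm
  voxels) placed within tract cores or background according to placement
  weights.
* **Cognition** — a latent domain score is a linear model in covariates
  (age, sex, 8-level education, reading score) and the *true* regional
  lesion volumes per tract and class, plus Gaussian noise; raw subtests
  are noisy loadings on the latent, emitted on their native scales with
  lower-better subtests flipped so that larger raw values mean worse
  performance.

Every planted parameter is echoed by :func:`ground_truth` so downstream
stages have a parameter-recovery test surface.  One seed drives a single
root pseudo-random stream which is split deterministically per patient.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy.special import ndtri

from .cohort import LesionCohort
from .grid import VoxelGrid
from .tracts import TractAtlas, binarize_atlas, regional_volumes

__all__ = [
    "TractSpec",
    "WMLFieldParams",
    "LLParams",
    "CovariateParams",
    "LesionEffect",
    "EffectParams",
    "SubtestSpec",
    "SimulationConfig",
    "GroundTruth",
    "default_config",
    "replicate_config",
    "make_synthetic_atlas",
    "simulate_lesions",
    "simulate_cognition",
    "simulate_cohort",
    "ground_truth",
]


# --------------------------------------------------------------------------
# configuration dataclasses


@dataclass(frozen=True)
class TractSpec:
    """Cuboid tract core with Gaussian probability falloff outside it."""

    name: str
    center_vox: tuple[float, float, float]
    half_size_vox: tuple[int, int, int]
    peak: float = 1.0
    decay_vox: float = 2.0

    def core_slices(self, shape: tuple[int, int, int]) -> tuple[slice, slice, slice]:
        lo = [int(round(c - h)) for c, h in zip(self.center_vox, self.half_size_vox)]
        hi = [int(round(c + h)) + 1 for c, h in zip(self.center_vox, self.half_size_vox)]
        if any(l < 0 for l in lo) or any(h > s for h, s in zip(hi, shape)):
            raise ValueError(
                f"tract {self.name!r}: core [{lo}..{hi}) does not fit in grid {shape}"
            )
        return tuple(slice(l, h) for l, h in zip(lo, hi))


@dataclass(frozen=True)
class WMLFieldParams:
    """Smooth-field WML model.

    ``base_prob`` is the per-voxel lesion probability at the prevalence
    peak for a patient with unit burden multiplier; ``smoothness_vox`` is
    the Gaussian correlation scale of the field; ``burden_sigma`` the
    log-SD of the per-patient log-normal (mean-1) burden multiplier;
    ``prevalence_profile`` is "central" (prevalence decays from the grid
    centre, emulating a periventricular-peaked lesion distribution) or
    "uniform".
    """

    base_prob: float = 0.15
    smoothness_vox: float = 1.5
    burden_sigma: float = 0.2
    prevalence_profile: str = "central"

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_prob <= 1.0:
            raise ValueError("base_prob must be in [0, 1]")
        if self.prevalence_profile not in ("central", "uniform"):
            raise ValueError("prevalence_profile must be 'central' or 'uniform'")


@dataclass(frozen=True)
class LLParams:
    """Sparse lacune model: zero-inflated count of small spheres."""

    rate: float = 0.19  # probability a patient has any lacune
    extra_mean: float = 0.5  # Poisson mean of additional lacunes given any
    radius_vox: float = 2.0  # sphere radius in voxels (8 mm diameter at 2 mm)
    tract_weights: dict[str, float] = field(default_factory=dict)
    background_weight: float = 0.4
    wml_correlation: float = 0.0  # latent-normal corr between burden and LL presence

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("LL rate must be in [0, 1]")
        if not -1.0 < self.wml_correlation < 1.0:
            raise ValueError("wml_correlation must be in (-1, 1)")


@dataclass(frozen=True)
class CovariateParams:
    """Covariate marginals (defaults follow an arterial-disease cohort)."""

    age_mean: float = 57.0
    age_sd: float = 9.4
    male_prop: float = 0.82
    education_probs: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.20, 0.15, 0.10, 0.05)
    reading_mean: float = 100.0
    reading_sd: float = 15.0

    def __post_init__(self) -> None:
        if len(self.education_probs) != 8 or abs(sum(self.education_probs) - 1.0) > 1e-8:
            raise ValueError("education_probs must be 8 probabilities summing to 1")


@dataclass(frozen=True)
class LesionEffect:
    """Planted effect: z-score change per ml of regional lesion volume."""

    domain: str
    tract: str
    lesion_class: str
    coef_z_per_ml: float


@dataclass(frozen=True)
class EffectParams:
    """True generating coefficients of the latent domain scores."""

    lesion_effects: tuple[LesionEffect, ...] = ()
    covariate_coefs: dict[str, float] = field(
        default_factory=lambda: {
            "age": -0.030,
            "sex": -0.10,
            "education": 0.080,
            "reading": 0.025,
        }
    )
    noise_sd: float = 0.70


@dataclass(frozen=True)
class SubtestSpec:
    """One raw subtest: loading on its domain latent plus native scaling."""

    name: str
    domain: str
    higher_better: bool = True
    loading: float = 1.0
    noise_sd: float = 0.2
    mean: float = 0.0
    sd: float = 1.0


#: Native scales follow typical cohort values for the nine instruments.
DEFAULT_SUBTESTS: tuple[SubtestSpec, ...] = (
    SubtestSpec("word_learning_immediate", "memory", True, 1.0, 0.2, 40.0, 10.0),
    SubtestSpec("word_learning_delayed", "memory", True, 1.0, 0.2, 8.0, 3.0),
    SubtestSpec("rey_figure_delayed", "memory", True, 1.0, 0.2, 21.0, 6.0),
    SubtestSpec("visual_elevator", "executive", False, 1.0, 0.2, 4.8, 2.4),
    SubtestSpec("brixton_errors", "executive", False, 1.0, 0.2, 18.0, 7.0),
    SubtestSpec("verbal_fluency", "executive", True, 1.0, 0.2, 11.0, 5.0),
    SubtestSpec("digit_span_forward", "speed_attention", True, 1.0, 0.2, 8.0, 2.0),
    SubtestSpec("digit_span_backward", "speed_attention", True, 1.0, 0.2, 6.0, 2.0),
    SubtestSpec("symbol_substitution", "speed_attention", True, 1.0, 0.2, 58.0, 15.0),
)


@dataclass
class SimulationConfig:
    """Full specification of one synthetic cohort."""

    n_patients: int = 516
    grid_shape: tuple[int, int, int] = (48, 48, 24)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tract_specs: tuple[TractSpec, ...] = ()
    wml: WMLFieldParams = field(default_factory=WMLFieldParams)
    ll: LLParams = field(default_factory=LLParams)
    covariates: CovariateParams = field(default_factory=CovariateParams)
    effects: EffectParams = field(default_factory=EffectParams)
    subtests: tuple[SubtestSpec, ...] = DEFAULT_SUBTESTS
    atlas_threshold: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be strictly positive")
        if 2 * self.ll.radius_vox + 1 > min(self.grid_shape):
            raise ValueError("LL radius exceeds the grid extent")
        names = [t.name for t in self.tract_specs]
        if len(set(names)) != len(names):
            raise ValueError("tract names must be unique")
        for t in self.tract_specs:
            t.core_slices(self.grid_shape)  # raises if outside the grid
        for w in self.ll.tract_weights:
            if w not in names:
                raise ValueError(f"LL placement weight refers to unknown tract {w!r}")
        for eff in self.effects.lesion_effects:
            if eff.tract not in names:
                raise ValueError(f"lesion effect refers to unknown tract {eff.tract!r}")

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid(shape=self.grid_shape, voxel_size_mm=self.voxel_size_mm, space="synthetic")

    def subtest_scheme(self) -> dict:
        """Subtest-to-domain scheme matching this configuration's subtests."""
        from .cognition import SubtestRole

        return {s.name: SubtestRole(s.domain, s.higher_better) for s in self.subtests}

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tract_specs"] = [asdict(t) for t in self.tract_specs]
        d["subtests"] = [asdict(s) for s in self.subtests]
        d["effects"] = {
            "lesion_effects": [asdict(e) for e in self.effects.lesion_effects],
            "covariate_coefs": dict(self.effects.covariate_coefs),
            "noise_sd": self.effects.noise_sd,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["tract_specs"] = tuple(
            TractSpec(**{**t, "center_vox": tuple(t["center_vox"]),
                         "half_size_vox": tuple(t["half_size_vox"])})
            for t in d.get("tract_specs", ())
        )
        if "wml" in d:
            d["wml"] = WMLFieldParams(**d["wml"])
        if "ll" in d:
            d["ll"] = LLParams(**d["ll"])
        if "covariates" in d:
            cov = dict(d["covariates"])
            if "education_probs" in cov:
                cov["education_probs"] = tuple(cov["education_probs"])
            d["covariates"] = CovariateParams(**cov)
        if "effects" in d:
            eff = dict(d["effects"])
            eff["lesion_effects"] = tuple(LesionEffect(**e) for e in eff.get("lesion_effects", ()))
            d["effects"] = EffectParams(**eff)
        if "subtests" in d:
            d["subtests"] = tuple(SubtestSpec(**s) for s in d["subtests"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class GroundTruth:
    """The planted parameters of a simulation, for recovery tests."""

    lesion_effects: tuple[LesionEffect, ...]
    covariate_coefs: dict[str, float]
    noise_sd: float
    regional_volumes: pd.DataFrame | None = None

    def effect(self, domain: str, tract: str, lesion_class: str) -> float:
        for e in self.lesion_effects:
            if (e.domain, e.tract, e.lesion_class) == (domain, tract, lesion_class):
                return e.coef_z_per_ml
        return 0.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "lesion_effects": [asdict(e) for e in self.lesion_effects],
            "covariate_coefs": self.covariate_coefs,
            "noise_sd": self.noise_sd,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# --------------------------------------------------------------------------
# default scenarios


def _default_tracts(shape: tuple[int, int, int]) -> tuple[TractSpec, TractSpec]:
    """Two cuboid tracts, left and right of the grid centre.

    The cores are separated and the probability falloff is kept tight
    (decay 0.8 voxels) so that the 0.1-thresholded masks are disjoint
    with a clear gap — overlapping ROI masks would make per-tract
    selection rates uninterpretable in recovery experiments.
    """
    hx = max(1, round(shape[0] * 0.07))
    hy = max(1, round(shape[1] * 0.12))
    hz = max(1, round(shape[2] * 0.12))
    half = (hx, hy, hz)
    a = TractSpec("tract_a", (0.30 * shape[0], 0.5 * shape[1], 0.5 * shape[2]), half,
                  decay_vox=0.8)
    b = TractSpec("tract_b", (0.70 * shape[0], 0.5 * shape[1], 0.5 * shape[2]), half,
                  decay_vox=0.8)
    return a, b


def default_config(
    n_patients: int = 516,
    grid_shape: tuple[int, int, int] = (48, 48, 24),
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Study-scale default scenario: two tracts, planted executive effects.

    Tract A carries a lacunar effect of -3.0 z/ml and a WML effect of
    -1.2 z/ml on the executive domain; tract B is null.  Lacunes fall in
    tract cores (30% each) or background (40%).  Effect sizes and the
    residual noise SD are matched so that the latent executive score has
    variance close to 1 (its natural z-score scale), which keeps the
    planted per-ml coefficients interpretable after sample z-scoring.
    """
    tracts = _default_tracts(tuple(grid_shape))
    effects = EffectParams(
        lesion_effects=(
            LesionEffect("executive", "tract_a", "ll", -3.0),
            LesionEffect("executive", "tract_a", "wml", -1.2),
        )
    )
    ll = LLParams(tract_weights={"tract_a": 0.3, "tract_b": 0.3}, background_weight=0.4)
    cfg = dict(
        n_patients=n_patients,
        grid_shape=tuple(grid_shape),
        tract_specs=tracts,
        effects=effects,
        ll=ll,
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def replicate_config(seed: int, n_patients: int = 300,
                     grid_shape: tuple[int, int, int] = (32, 32, 16),
                     **overrides) -> SimulationConfig:
    """Scaled-down replicate scenario used for Monte-Carlo experiments."""
    return default_config(n_patients=n_patients, grid_shape=grid_shape, seed=seed, **overrides)


# --------------------------------------------------------------------------
# atlas


def make_synthetic_atlas(config: SimulationConfig) -> TractAtlas:
    """Probabilistic atlas: peak probability on each tract core, Gaussian
    falloff with the tract's decay scale outside it."""
    if not config.tract_specs:
        raise ValueError("config has no tract specs")
    probs: dict[str, np.ndarray] = {}
    for spec in config.tract_specs:
        core = np.zeros(config.grid_shape, dtype=bool)
        core[spec.core_slices(config.grid_shape)] = True
        dist = ndimage.distance_transform_edt(~core)
        vol = spec.peak * np.exp(-0.5 * (dist / spec.decay_vox) ** 2)
        vol[core] = spec.peak
        probs[spec.name] = vol
    return TractAtlas(grid=config.grid, probabilities=probs)


# --------------------------------------------------------------------------
# lesions


@lru_cache(maxsize=8)
def _wrap_filter_norm(shape: tuple[int, int, int], sigma: float) -> float:
    """SD of a circularly Gaussian-filtered unit white-noise field."""
    impulse = np.zeros(shape)
    impulse[tuple(s // 2 for s in shape)] = 1.0
    kernel = ndimage.gaussian_filter(impulse, sigma, mode="wrap")
    return float(np.sqrt(np.sum(kernel**2)))


def _smooth_unit_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if sigma <= 0:
        return noise
    field_ = ndimage.gaussian_filter(noise, sigma, mode="wrap")
    return field_ / _wrap_filter_norm(tuple(shape), float(sigma))


def _prevalence_weights(config: SimulationConfig) -> np.ndarray:
    shape = config.grid_shape
    if config.wml.prevalence_profile == "uniform":
        return np.ones(shape)
    axes = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((ax - (s - 1) / 2.0) / (0.4 * s)) ** 2 for ax, s in zip(axes, shape))
    return np.exp(-0.5 * r2)


@lru_cache(maxsize=16)
def _ball_offsets(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    g = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    keep = (g**2).sum(axis=0) <= radius**2
    return np.argwhere(keep) - r


def _patient_ids(n: int) -> tuple[str, ...]:
    width = max(3, len(str(n)))
    return tuple(f"P{i:0{width}d}" for i in range(1, n + 1))


def simulate_lesions(config: SimulationConfig) -> LesionCohort:
    """Generate per-patient binary WML and LL maps.

    WML: per patient, a smooth unit-variance field is compared with the
    per-voxel normal quantile of the target probability
    ``clip(base_prob * burden_multiplier * profile, 0, 0.995)``, so the
    marginal per-voxel lesion rate equals that probability exactly.

    LL: a zero-inflated count of spheres is placed at tract cores or
    background according to the placement weights; spheres may overlap
    (the union is taken).
    """
    n = config.n_patients
    shape = config.grid_shape
    root = np.random.SeedSequence(config.seed)
    ss_shared, ss_patients = root.spawn(2)
    shared_rng = np.random.default_rng(ss_shared)
    patient_seeds = ss_patients.spawn(n)

    # per-patient burden multipliers (log-normal, mean 1) and the latent
    # normal used for optional burden/LL-presence coupling
    sig = config.wml.burden_sigma
    z_burden = shared_rng.standard_normal(n)
    multipliers = np.exp(sig * z_burden - 0.5 * sig**2) if sig > 0 else np.ones(n)

    rho = config.ll.wml_correlation
    z2 = shared_rng.standard_normal(n)
    z_ll = rho * z_burden + np.sqrt(1.0 - rho**2) * z2
    # present iff the latent exceeds the upper-rate quantile: positive rho
    # couples lacune presence to high WML burden
    ll_present = z_ll > ndtri(1.0 - config.ll.rate) if config.ll.rate > 0 else np.zeros(n, bool)
    extra_counts = shared_rng.poisson(config.ll.extra_mean, size=n)
    ll_counts = np.where(ll_present, 1 + extra_counts, 0)

    weights = _prevalence_weights(config)
    offsets = _ball_offsets(float(config.ll.radius_vox))

    # normalised placement distribution over tracts + background
    names = [t.name for t in config.tract_specs]
    w_tracts = [config.ll.tract_weights.get(nm, 0.0) for nm in names]
    w_bg = config.ll.background_weight if (config.ll.background_weight > 0 or not w_tracts) else 0.0
    w_all = np.asarray(w_tracts + [w_bg], dtype=float)
    if w_all.sum() <= 0:
        w_all = np.asarray([0.0] * len(names) + [1.0])
    w_all = w_all / w_all.sum()
    cores = {t.name: t.core_slices(shape) for t in config.tract_specs}
    r = int(np.ceil(config.ll.radius_vox))

    wml = np.zeros((n, *shape), dtype=np.uint8)
    ll = np.zeros((n, *shape), dtype=np.uint8)
    for i in range(n):
        rng = np.random.default_rng(patient_seeds[i])
        field_ = _smooth_unit_field(rng, shape, config.wml.smoothness_vox)
        p = np.clip(config.wml.base_prob * multipliers[i] * weights, 0.0, 0.995)
        with np.errstate(divide="ignore"):
            thr = np.where(p > 0, ndtri(1.0 - np.clip(p, 1e-12, None)), np.inf)
        wml[i] = (field_ > thr).astype(np.uint8)

        for _ in range(int(ll_counts[i])):
            which = rng.choice(len(w_all), p=w_all)
            if which < len(names):
                sl = cores[names[which]]
                center = [rng.integers(s.start, s.stop) for s in sl]
            else:
                center = [rng.integers(r, dim - r) if dim > 2 * r else dim // 2
                          for dim in shape]
            pts = offsets + np.asarray(center)
            keep = np.all((pts >= 0) & (pts < np.asarray(shape)), axis=1)
            pts = pts[keep]
            ll[i][pts[:, 0], pts[:, 1], pts[:, 2]] = 1

    return LesionCohort(grid=config.grid, patient_ids=_patient_ids(n),
                        maps={"wml": wml, "ll": ll})


# --------------------------------------------------------------------------
# cognition


def _domain_latents(
    config: SimulationConfig,
    covariates: pd.DataFrame,
    regional: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Latent domain scores: covariate effects + planted lesion effects + noise."""
    eff = config.effects
    cov_part = np.zeros(len(covariates))
    for name, coef in eff.covariate_coefs.items():
        centred = covariates[name].to_numpy(dtype=float)
        cov_part = cov_part + coef * (centred - centred.mean())
    domains = sorted({s.domain for s in config.subtests})
    out = {}
    for domain in domains:
        lesion_part = np.zeros(len(covariates))
        for e in eff.lesion_effects:
            if e.domain != domain:
                continue
            col = f"{e.lesion_class}_{e.tract}_ml"
            lesion_part = lesion_part + e.coef_z_per_ml * regional[col].to_numpy(dtype=float)
        noise = rng.normal(0.0, eff.noise_sd, size=len(covariates))
        out[domain] = cov_part + lesion_part + noise
    return pd.DataFrame(out, index=covariates.index)


def simulate_cognition(
    config: SimulationConfig,
    cohort: LesionCohort,
    atlas: TractAtlas,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw covariates and raw subtest scores for a simulated cohort.

    Returns ``(covariates, subtests)`` tables keyed by patient_id.  The
    lesion terms use the *true* regional volumes within the atlas masks
    (thresholded at ``config.atlas_threshold``), which is also what the
    analysis pipeline estimates.
    """
    cohort.grid.require_match(atlas.grid, "cohort vs atlas")
    if cohort.n_patients != config.n_patients:
        raise ValueError("cohort size does not match the config")
    root = np.random.SeedSequence(config.seed)
    _, _, ss_cog = root.spawn(3)
    rng = np.random.default_rng(ss_cog)

    cp = config.covariates
    n = config.n_patients
    idx = pd.Index(cohort.patient_ids, name="patient_id")
    covariates = pd.DataFrame(
        {
            "age": rng.normal(cp.age_mean, cp.age_sd, size=n),
            "sex": rng.binomial(1, cp.male_prop, size=n),
            "education": rng.choice(np.arange(1, 9), size=n, p=cp.education_probs),
            "reading": rng.normal(cp.reading_mean, cp.reading_sd, size=n),
        },
        index=idx,
    )

    masks = binarize_atlas(atlas, config.atlas_threshold)
    regional = regional_volumes(cohort, masks)
    latents = _domain_latents(config, covariates, regional, rng)

    subtest_cols = {}
    for spec in config.subtests:
        z = spec.loading * latents[spec.domain].to_numpy()
        if spec.noise_sd > 0:
            z = z + rng.normal(0.0, spec.noise_sd, size=n)
        sign = 1.0 if spec.higher_better else -1.0
        subtest_cols[spec.name] = spec.mean + spec.sd * sign * z
    subtests = pd.DataFrame(subtest_cols, index=idx)
    return covariates, subtests


def ground_truth(config: SimulationConfig) -> GroundTruth:
    """Echo the planted generating parameters of a configuration."""
    return GroundTruth(
        lesion_effects=tuple(config.effects.lesion_effects),
        covariate_coefs=dict(config.effects.covariate_coefs),
        noise_sd=config.effects.noise_sd,
    )


def simulate_cohort(config: SimulationConfig):
    """Generate atlas, lesions, covariates and subtests in one call.

    Returns ``(atlas, cohort, covariates, subtests, truth)`` where the
    ground truth additionally carries the per-patient true regional
    volumes used in the generating model.
    """
    atlas = make_synthetic_atlas(config)
    cohort = simulate_lesions(config)
    covariates, subtests = simulate_cognition(config, cohort, atlas)
    truth = ground_truth(config)
    truth.regional_volumes = regional_volumes(cohort, binarize_atlas(atlas, config.atlas_threshold))
    return atlas, cohort, covariates, subtests, truth
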
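"""Synthetic cohort generation with known ground truth.

Every downstream stage (projection, behavioral scoring, mixed models,
cross-validated prediction, decoding) is exercised on cohorts produced here,
so no external imaging or behavioral data is ever required.

The generative model mirrors the analysis model:

* a basis of K zero-mean, unit-norm, mutually orthogonal "gradient" maps;
* per subject, Look-condition loadings on each gradient and a target shift
  added to them in the Regulate condition; activation maps are the loading
  mixtures plus i.i.d. Gaussian voxel noise (gradients are scaled to unit
  per-voxel RMS inside the mixture so similarity values are independent of
  the voxel count);
* behavioral regulatory success is a linear function of the REALIZED
  gradient shifts (computed by running the actual projection code on the
  generated maps), emotional reactivity, a Gaussian study intercept and a
  Gaussian residual — exactly the structure the mixed model estimates;
* trial-level emotional-state ratings are emitted on heterogeneous,
  study-specific scales (different ranges, one reversed orientation) and
  clipped to the scale bounds;
* daily-life affect prompts (experience sampling) are generated for a subset
  of subjects with a programmable linear link to the Gradient-1 shift.

Identical (config, seed) pairs reproduce byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ActivationMap, AnalysisMask, Condition

__all__ = [
    "GradientBasis",
    "StudySpec",
    "CohortConfig",
    "GroundTruth",
    "SimulatedCohort",
    "TermMapSet",
    "DEFAULT_TERMS",
    "make_gradient_basis",
    "simulate_cohort",
    "make_term_maps",
]

HIGHER_IS_MORE_NEGATIVE = "higher_is_more_negative"
HIGHER_IS_MORE_POSITIVE = "higher_is_more_positive"

#: Synthetic vocabulary of cognitive/affective terms for decoding fixtures,
#: in the style of meta-analytic term sets (25 entries; non-cognitive and
#: anatomical terms such as 'stimulation', 'method', 'cortex', 'gyrus' are
#: deliberately absent).
DEFAULT_TERMS: tuple[str, ...] = (
    "negative emotion", "social cognition", "memory", "imagery", "control",
    "language", "attention", "mental disorder", "cognitive impairment",
    "decision making", "aging", "emotion", "reward", "fear", "pain",
    "working memory", "semantic", "learning", "inhibition", "anticipation",
    "arousal", "autobiographical memory", "theory of mind", "valence",
    "executive function",
)


@dataclass
class GradientBasis:
    """K gradient maps over a common voxel mask (columns of ``maps``)."""

    maps: np.ndarray            # (n_voxels, K)
    mask: AnalysisMask
    explained_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 2:
            raise ValueError("gradient maps must be a (n_voxels, K) array")
        if self.maps.shape[0] != len(self.mask):
            raise ValueError("gradient maps do not match the mask size")
        if self.K < 1:
            raise ValueError("need at least one gradient")

    @property
    def K(self) -> int:
        return self.maps.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.maps.shape[0]

    def is_orthonormal(self, tol: float = 1e-10) -> bool:
        gram = self.maps.T @ self.maps
        if np.max(np.abs(self.maps.mean(axis=0))) > tol:
            return False
        return bool(np.max(np.abs(gram - np.eye(self.K))) < tol)

    @classmethod
    def from_images(cls, gradient_images, mask: AnalysisMask,
                    explained_variance=None) -> "GradientBasis":
        from .io import vectorize
        cols = [vectorize(img, mask) for img in gradient_images]
        ev = None if explained_variance is None else np.asarray(explained_variance, float)
        return cls(maps=np.column_stack(cols), mask=mask, explained_variance=ev)


def make_gradient_basis(
    n_voxels: int, K: int = 5, seed: int = 0,
    grid_shape: tuple[int, int, int] | None = None,
) -> GradientBasis:
    """Zero-mean, unit-norm, mutually orthogonal synthetic gradient maps.

    Built by column-centering a seeded Gaussian matrix and orthonormalizing
    with QR; deterministic given ``seed``.  Requires ``K < n_voxels`` (the
    zero-mean constraint uses one degree of freedom).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K >= n_voxels:
        raise ValueError(
            f"cannot build {K} zero-mean orthogonal maps over {n_voxels} voxels"
        )
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_voxels, K))
    X -= X.mean(axis=0, keepdims=True)
    Q, R = np.linalg.qr(X)
    Q = Q * np.sign(np.diag(R))          # fix QR sign indeterminacy
    Q -= Q.mean(axis=0, keepdims=True)   # re-center (numerically tiny shift)
    Q, _ = np.linalg.qr(Q)
    Q = Q * np.sign(Q[0, :])
    if grid_shape is None:
        grid_shape = (n_voxels, 1, 1)
    if int(np.prod(grid_shape)) != n_voxels:
        raise ValueError("grid_shape does not contain n_voxels voxels")
    mask = AnalysisMask(indices=np.arange(n_voxels), grid_shape=grid_shape,
                        affine=np.eye(4))
    # nominal spectrum mirroring "first five gradients explain ~55%"
    ev = 0.55 * np.ones(K) / K if K else None
    return GradientBasis(maps=Q, mask=mask, explained_variance=ev)


@dataclass(frozen=True)
class StudySpec:
    """One synthetic study: cohort size and its rating scale."""

    study_id: str
    n_subjects: int
    scale_min: float
    scale_max: float
    orientation: str = HIGHER_IS_MORE_NEGATIVE

    def __post_init__(self) -> None:
        if self.scale_max <= self.scale_min:
            raise ValueError("rating scale must have max > min")
        if self.n_subjects < 1:
            raise ValueError("study needs at least one subject")
        if self.orientation not in (HIGHER_IS_MORE_NEGATIVE, HIGHER_IS_MORE_POSITIVE):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.scale_min + self.scale_max)


def _default_studies() -> tuple[StudySpec, ...]:
    # four studies in two sample halves (discovery-like A1/A2,
    # replication-like B1/B2), differing in scale range with one reversed
    # orientation, to exercise normalization and orientation machinery
    return (
        StudySpec("studyA1", 15, 1.0, 9.0, HIGHER_IS_MORE_NEGATIVE),
        StudySpec("studyA2", 15, 0.0, 8.0, HIGHER_IS_MORE_NEGATIVE),
        StudySpec("studyB1", 12, 1.0, 5.0, HIGHER_IS_MORE_POSITIVE),
        StudySpec("studyB2", 8, 1.0, 7.0, HIGHER_IS_MORE_NEGATIVE),
    )


@dataclass
class CohortConfig:
    """Parameters of the synthetic generative model.

    Effects are on the raw rating-unit scale of regulatory success;
    ``true_beta1`` is rating units of success per z-unit of Gradient-1 shift.
    """

    studies: tuple[StudySpec, ...] = field(default_factory=_default_studies)
    n_look_trials: int = 30
    n_regulate_trials: int = 30
    true_beta1: float = 3.0
    true_betas_2to5: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    beta0: float = -0.9
    reactivity_effect: float = 0.3
    study_intercept_sd: float = 0.25
    residual_sd: float = 0.5
    map_noise_sd: float = 1.0
    trial_sd: float = 0.8
    loading_mean: float | Sequence[float] = 0.5
    loading_sd: float = 0.1
    shift_mean: Sequence[float] | None = None   # default set per K at run time
    shift_sd: float = 0.12
    reactivity_offset: float = 0.5   # oriented units above scale midpoint
    reactivity_sd: float = 0.6
    esm_intercept: float = 3.4
    esm_effect: float = 1.19
    esm_noise_sd: float = 0.3
    esm_prompt_sd: float = 0.6
    n_esm_prompts: int = 31
    esm_studies: tuple[str, ...] | None = None  # default: last study only
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("study_intercept_sd", "residual_sd", "map_noise_sd",
                     "trial_sd", "loading_sd", "shift_sd", "reactivity_sd",
                     "esm_noise_sd", "esm_prompt_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_look_trials < 1 or self.n_regulate_trials < 1:
            raise ValueError("trial counts must be >= 1")
        self.studies = tuple(self.studies)

    @property
    def n_subjects(self) -> int:
        return sum(s.n_subjects for s in self.studies)

    @classmethod
    def with_total_n(cls, n_total: int, **overrides) -> "CohortConfig":
        """Default two-study world rescaled to ``n_total`` subjects (60/40)."""
        n_a = max(2, int(round(0.6 * n_total)))
        n_b = max(2, n_total - n_a)
        studies = (
            StudySpec("studyA", n_a, 1.0, 9.0, HIGHER_IS_MORE_NEGATIVE),
            StudySpec("studyB", n_b, 1.0, 5.0, HIGHER_IS_MORE_POSITIVE),
        )
        return cls(studies=studies, **overrides)

    def betas(self, K: int) -> np.ndarray:
        b = np.zeros(K)
        b[0] = self.true_beta1
        extra = np.asarray(self.true_betas_2to5, dtype=float)
        b[1:1 + min(K - 1, extra.size)] = extra[: K - 1]
        return b

    def shift_means(self, K: int) -> np.ndarray:
        if self.shift_mean is not None:
            m = np.asarray(self.shift_mean, dtype=float)
            if m.size != K:
                raise ValueError("shift_mean length must equal K")
            return m
        m = np.full(K, 0.05)
        m[0] = 0.12
        return m

    def loading_means(self, K: int) -> np.ndarray:
        m = np.asarray(self.loading_mean, dtype=float)
        if m.ndim == 0:
            return np.full(K, float(m))
        if m.size != K:
            raise ValueError("loading_mean length must equal K")
        return m


@dataclass
class GroundTruth:
    """Everything the generator knew: stored alongside each cohort."""

    config: CohortConfig
    subject_ids: list[str]
    study_ids: list[str]
    look_loadings: np.ndarray          # (n, K)
    target_shifts: np.ndarray          # (n, K) latent delta added for Regulate
    realized_dG: np.ndarray            # (n, K) from the projection module
    reactivity: np.ndarray             # oriented rating units
    study_intercepts: dict[str, float]
    latent_success: np.ndarray         # raw rating units
    esm_latent_mean: dict[str, float]


@dataclass
class SimulatedCohort:
    """Container bundling all generated artifacts."""

    maps: list[ActivationMap]
    trials: pd.DataFrame
    covariates: pd.DataFrame
    esm: pd.DataFrame
    truth: GroundTruth
    basis: GradientBasis


def _orient_to_scale(oriented: np.ndarray, study: StudySpec) -> np.ndarray:
    """Map oriented ('higher = more negative') values onto the study scale."""
    if study.orientation == HIGHER_IS_MORE_NEGATIVE:
        out = oriented
    else:
        out = (study.scale_min + study.scale_max) - oriented
    return np.clip(out, study.scale_min, study.scale_max)


def simulate_cohort(config: CohortConfig, basis: GradientBasis) -> SimulatedCohort:
    """Generate a full synthetic cohort from ``config`` over ``basis``.

    Behavioral success is driven by the REALIZED gradient shifts — computed
    by projecting the generated maps with the actual projection code — so
    downstream parameter recovery is exact in expectation.
    """
    from .projection import projection_table, shift_table  # lazy: avoids cycle

    rng = np.random.default_rng(config.seed)
    K, V = basis.K, basis.n_voxels
    n = config.n_subjects
    betas = config.betas(K)
    shift_mu = config.shift_means(K)
    load_mu = config.loading_means(K)

    subject_ids: list[str] = []
    study_ids: list[str] = []
    for s in config.studies:
        for j in range(s.n_subjects):
            subject_ids.append(f"{s.study_id}_s{j + 1:03d}")
            study_ids.append(s.study_id)
    study_of = {sid: s for s in config.studies for sid in [s.study_id]}

    # gradients enter the mixture at unit per-voxel RMS so that similarity
    # values do not depend on the voxel count
    G_rms = basis.maps * np.sqrt(V)

    look_w = load_mu + config.loading_sd * rng.standard_normal((n, K))
    delta = shift_mu + config.shift_sd * rng.standard_normal((n, K))
    reg_w = look_w + delta

    maps: list[ActivationMap] = []
    for i, sid in enumerate(subject_ids):
        noise_l = config.map_noise_sd * rng.standard_normal(V)
        noise_r = config.map_noise_sd * rng.standard_normal(V)
        vec_l = G_rms @ look_w[i] + noise_l
        vec_r = G_rms @ reg_w[i] + noise_r
        maps.append(ActivationMap(sid, Condition.LOOK, vec_l, basis.mask))
        maps.append(ActivationMap(sid, Condition.REGULATE, vec_r, basis.mask))
    # realized shifts come from the actual projection pipeline, so behavior
    # generated from them is exactly what the downstream fit estimates
    realized_df = shift_table(projection_table(maps, basis))
    assert list(realized_df["subject_id"]) == subject_ids
    realized = realized_df[[f"dG{k + 1}" for k in range(K)]].to_numpy()

    intercepts = {
        s.study_id: config.study_intercept_sd * rng.standard_normal()
        for s in config.studies
    }
    mids = np.array([study_of[g].midpoint for g in study_ids])
    reactivity = (mids + config.reactivity_offset
                  + config.reactivity_sd * rng.standard_normal(n))
    resid = config.residual_sd * rng.standard_normal(n)
    success = (config.beta0 + realized @ betas
               + config.reactivity_effect * reactivity
               + np.array([intercepts[g] for g in study_ids]) + resid)

    # trial-level ratings on each study's own scale
    trial_rows = []
    for i, sid in enumerate(subject_ids):
        s = study_of[study_ids[i]]
        look_lat = reactivity[i] + config.trial_sd * rng.standard_normal(
            config.n_look_trials)
        reg_lat = (reactivity[i] - success[i]
                   + config.trial_sd * rng.standard_normal(config.n_regulate_trials))
        for r in _orient_to_scale(look_lat, s):
            trial_rows.append((sid, s.study_id, Condition.LOOK.value, float(r),
                               s.scale_min, s.scale_max, s.orientation))
        for r in _orient_to_scale(reg_lat, s):
            trial_rows.append((sid, s.study_id, Condition.REGULATE.value, float(r),
                               s.scale_min, s.scale_max, s.orientation))
    trials = pd.DataFrame(
        trial_rows,
        columns=["subject_id", "study_id", "condition", "rating",
                 "scale_min", "scale_max", "orientation"],
    )

    age = np.round(rng.normal(30.0, 8.0, size=n)).clip(18, 65)
    sex = rng.integers(0, 2, size=n)
    erq_reapp = np.round(rng.normal(26.0, 8.0, size=n)).clip(6, 42)
    erq_supp = np.round(rng.normal(16.0, 5.0, size=n)).clip(4, 28)
    covariates = pd.DataFrame({
        "subject_id": subject_ids,
        "study_id": study_ids,
        "age": age,
        "sex": sex,
        "erq_reappraisal": erq_reapp,
        "erq_suppression": erq_supp,
    })

    # experience sampling for a subset of studies (default: the
    # replication-like second half of the study list)
    if config.esm_studies is not None:
        esm_studies = config.esm_studies
    else:
        half = len(config.studies) // 2
        esm_studies = tuple(s.study_id for s in config.studies[half:])
    esm_rows = []
    esm_latent: dict[str, float] = {}
    for i, sid in enumerate(subject_ids):
        if study_ids[i] not in esm_studies:
            continue
        mean_aff = (config.esm_intercept + config.esm_effect * realized[i, 0]
                    + config.esm_noise_sd * rng.standard_normal())
        esm_latent[sid] = float(mean_aff)
        prompts = mean_aff + config.esm_prompt_sd * rng.standard_normal(
            config.n_esm_prompts)
        for t, r in enumerate(np.clip(prompts, 1.0, 5.0)):
            esm_rows.append((sid, t, float(r)))
    esm = pd.DataFrame(esm_rows, columns=["subject_id", "prompt_time", "rating"])

    truth = GroundTruth(
        config=config, subject_ids=subject_ids, study_ids=study_ids,
        look_loadings=look_w, target_shifts=delta, realized_dG=realized,
        reactivity=reactivity, study_intercepts=intercepts,
        latent_success=success, esm_latent_mean=esm_latent,
    )
    return SimulatedCohort(maps=maps, trials=trials, covariates=covariates,
                           esm=esm, truth=truth, basis=basis)


@dataclass
class TermMapSet:
    """Named term maps over the analysis mask, for meta-analytic decoding."""

    terms: list[str]
    maps: np.ndarray   # (n_voxels, n_terms)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if len(self.terms) != self.maps.shape[1]:
            raise ValueError("term names do not match map count")
        if len(set(t.lower() for t in self.terms)) != len(self.terms):
            raise ValueError("term names must be unique (case-insensitive)")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("term maps must be finite")

    @property
    def n_terms(self) -> int:
        return len(self.terms)


def make_term_maps(
    basis: GradientBasis, n_terms: int = 25, seed: int = 0,
    planted: np.ndarray | None = None, planted_name: str = "planted",
) -> TermMapSet:
    """Seeded random term maps; optionally plant an exact copy of a map."""
    if n_terms < 1:
        raise ValueError("need at least one term")
    rng = np.random.default_rng(seed)
    maps = rng.standard_normal((basis.n_voxels, n_terms))
    names = [DEFAULT_TERMS[i] if i < len(DEFAULT_TERMS) else f"term{i + 1:02d}"
             for i in range(n_terms)]
    if planted is not None:
        planted = np.asarray(planted, dtype=np.float64)
        if planted.size != basis.n_voxels:
            raise ValueError("planted map does not match the mask")
        maps[:, 0] = planted
        names[0] = planted_name
    return TermMapSet(terms=names, maps=maps)


def make_synthetic_atlases(
    mask: AnalysisMask, n_cortical: int = 8, n_subcortical: int = 4,
    cortical_fraction: float = 0.8,
):
    """Toy parcellations over the mask for the region-wise analysis.

    The first ``cortical_fraction`` of mask voxels (in index order) is split
    into ``n_cortical`` contiguous 'cortical' regions, the remainder into
    ``n_subcortical`` 'subcortical' ones.  Labelled synthetic stand-ins for
    real cortical/subcortical atlases; deterministic.
    """
    from .io import RegionAtlas

    n = len(mask)
    n_cort_vox = int(round(cortical_fraction * n))
    grid = np.zeros(int(np.prod(mask.grid_shape)), dtype=np.int64)

    cort = np.zeros_like(grid)
    bounds = np.linspace(0, n_cort_vox, n_cortical + 1).astype(int)
    for rid in range(n_cortical):
        cort[mask.indices[bounds[rid]:bounds[rid + 1]]] = rid + 1
    sub = np.zeros_like(grid)
    bounds = np.linspace(n_cort_vox, n, n_subcortical + 1).astype(int)
    for rid in range(n_subcortical):
        sub[mask.indices[bounds[rid]:bounds[rid + 1]]] = rid + 1

    atlas_c = RegionAtlas(labels=cort.reshape(mask.grid_shape),
                          region_ids=list(range(1, n_cortical + 1)),
                          family="cortical", affine=mask.affine)
    atlas_s = RegionAtlas(labels=sub.reshape(mask.grid_shape),
                          region_ids=list(range(1, n_subcortical + 1)),
                          family="subcortical", affine=mask.affine)
    return atlas_c, atlas_s
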
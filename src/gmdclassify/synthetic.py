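"""Synthetic grey-matter-density (GMD) cohort generator.

Produces per-subject 3D GMD volumes in [0, 1] together with template grey- and
white-matter tissue-probability volumes and a subject table carrying two group
labelings (biotype B1/B2/B3/CON and diagnosis SZ/SAD/BD/CON) plus clinical
outcome columns.  The generator emulates the statistical structure a
voxel-based-morphometry classification analysis assumes:

* a step-wise gradient of group GMD reductions — the B1-like group expresses a
  strong, spatially extensive deficit, B2 an intermediate and more localized
  one, B3 only a modest one;
* a *shared* psychosis-wide deficit pattern next to group-*specific* patterns,
  so that cross-group classifier transfer is non-trivial;
* subject-level offsets (global GMD shifts) and voxel-level Gaussian noise;
* clinical outcomes linearly and group-invariantly linked to each subject's
  expression of the B1-like pattern.

It makes no attempt at realistic neuroanatomy; volumes are smooth bump
functions on a small grid so the grey-matter mask rule has both included and
excluded voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIOTYPE_GROUPS = ("B1", "B2", "B3")
DIAGNOSIS_GROUPS = ("SZ", "SAD", "BD")
CONTROL_GROUP = "CON"

#: Biotype group sizes of the reference cohort (psychosis n=557, controls n=251).
DEFAULT_GROUP_SIZES = {"B1": 150, "B2": 185, "B3": 222, "CON": 251}
#: Diagnosis counts over the same 557 psychosis cases.
DEFAULT_DIAGNOSIS_SIZES = {"SZ": 242, "SAD": 138, "BD": 177}

PRESETS = ("paper_like", "null", "shared_only")


@dataclass(frozen=True)
class EffectPattern:
    """A spatial GMD-reduction pattern.

    Parameters
    ----------
    support
        Flat (C-order) voxel indices where the pattern lives.
    magnitude
        Depth of the GMD reduction applied on the support (GMD units, >= 0).
    profile
        ``"uniform"`` applies ``magnitude`` on every support voxel;
        ``"gaussian-bump"`` tapers it from the support centroid outward.
    """

    support: np.ndarray
    magnitude: float
    profile: str = "uniform"

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=np.intp)
        object.__setattr__(self, "support", support)
        if self.magnitude < 0:
            raise ValueError("effect magnitude must be non-negative")
        if self.profile not in ("uniform", "gaussian-bump"):
            raise ValueError(f"unknown profile {self.profile!r}")

    def validate_grid(self, grid_dims: tuple[int, int, int]) -> None:
        n = int(np.prod(grid_dims))
        if self.support.size and (self.support.min() < 0 or self.support.max() >= n):
            raise ValueError("effect support exceeds the voxel grid")

    def deficit_volume(self, grid_dims: tuple[int, int, int]) -> np.ndarray:
        """Dense 3D array of the GMD reduction this pattern encodes."""
        self.validate_grid(grid_dims)
        flat = np.zeros(int(np.prod(grid_dims)))
        if self.support.size == 0 or self.magnitude == 0:
            return flat.reshape(grid_dims)
        if self.profile == "uniform":
            flat[self.support] = self.magnitude
        else:
            coords = np.column_stack(np.unravel_index(self.support, grid_dims)).astype(float)
            center = coords.mean(axis=0)
            d2 = ((coords - center) ** 2).sum(axis=1)
            sigma2 = max(d2.max(), 1.0) / 4.0
            flat[self.support] = self.magnitude * np.exp(-d2 / (2.0 * sigma2))
        return flat.reshape(grid_dims)


@dataclass(frozen=True)
class ClinicalOutcome:
    """One simulated clinical/biomarker outcome.

    ``outcome = intercept + slope * expression + group_offset + N(0, noise_sd)``
    where ``expression`` is the subject's z-scored B1-pattern expression. The
    slope is identical in every group, making the link group-invariant by
    construction; values go missing completely at random at ``missing_rate``.
    """

    name: str
    intercept: float
    slope: float
    group_offsets: dict = field(default_factory=dict)
    noise_sd: float = 1.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class ClinicalSpec:
    outcomes: tuple = ()


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort.

    The defaults reflect the reference study conditions: Biotype group sizes
    150/185/222/251, GMD baseline 0.5, and effect magnitudes small relative to
    the [0, 1] range so that clipping bias stays negligible.
    """

    grid_dims: tuple = (24, 24, 24)
    voxel_size_mm: float = 2.0
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    shared_effect: EffectPattern | None = None
    specific_effects: dict = field(default_factory=dict)
    shared_scale: dict = field(default_factory=dict)
    subject_sd: float = 0.01
    voxel_sd: float = 0.12
    baseline_mean: float = 0.5
    clinical_spec: ClinicalSpec = field(default_factory=ClinicalSpec)
    diagnosis_sizes: dict = field(default_factory=lambda: dict(DEFAULT_DIAGNOSIS_SIZES))
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_dims) != 3 or any(int(d) <= 0 for d in self.grid_dims):
            raise ValueError("grid_dims must be 3 positive integers")
        object.__setattr__(self, "grid_dims", tuple(int(d) for d in self.grid_dims))
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if not (0.0 < self.baseline_mean < 1.0):
            raise ValueError("baseline_mean must lie in (0, 1)")
        if self.subject_sd < 0 or self.voxel_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        for group, n in self.group_sizes.items():
            if int(n) < 1:
                raise ValueError(f"group {group!r} must have at least one subject")
        if self.shared_effect is not None:
            self.shared_effect.validate_grid(self.grid_dims)
        for pattern in self.specific_effects.values():
            pattern.validate_grid(self.grid_dims)

    @property
    def psychosis_groups(self) -> tuple:
        return tuple(g for g in self.group_sizes if g != CONTROL_GROUP)

    @property
    def n_subjects(self) -> int:
        return int(sum(self.group_sizes.values()))

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff


@dataclass
class SyntheticCohort:
    """A generated cohort: image stack, tissue templates, subject table, truth."""

    images: np.ndarray  # (n_subjects, nx, ny, nz) float32, values in [0, 1]
    gm_prob: np.ndarray
    wm_prob: np.ndarray
    affine: np.ndarray
    subjects: pd.DataFrame  # columns: subject_id, biotype, diagnosis, ...
    spec: CohortSpec

    @property
    def subject_ids(self) -> list:
        return list(self.subjects["subject_id"])

    def image_for(self, subject_id: str) -> np.ndarray:
        idx = self.subjects.index[self.subjects["subject_id"] == subject_id]
        if len(idx) != 1:
            raise KeyError(subject_id)
        return self.images[idx[0]]


# ---------------------------------------------------------------------------
# geometry helpers


def _normalized_coords(grid_dims):
    axes = [np.linspace(-1.0, 1.0, d) for d in grid_dims]
    return np.meshgrid(*axes, indexing="ij")


def _sphere_support(grid_dims, center, radius) -> np.ndarray:
    xx, yy, zz = _normalized_coords(grid_dims)
    r2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2
    return np.flatnonzero((r2 <= radius**2).ravel())


def tissue_probability_volumes(grid_dims) -> tuple[np.ndarray, np.ndarray]:
    """Smooth template grey/white tissue-probability bump functions.

    The grey-matter probability exceeds 0.40 on a contiguous interior ball
    (radius ~0.67 in normalized coordinates); the white-matter probability
    exceeds 0.60 only in a small central core. The standard mask rule
    (gm > 0.40 and wm < 0.60) therefore keeps an interior shell and rejects
    both the exterior and the core.
    """
    xx, yy, zz = _normalized_coords(grid_dims)
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    gm = 0.75 * np.exp(-((r / 0.75) ** 4))
    wm = 0.65 * np.exp(-((r / 0.30) ** 2))
    return gm, wm


# Calibrated preset geometry/magnitudes (normalized coordinates; GMD units).
# Supports are pairwise-disjoint spheres inside the grey-matter shell.
# Magnitudes realize the qualitative accuracy gradient B1 > B2 > B3 with the
# B1 model dominated by its specific pattern (hence specific) and the B2
# model dominated by the shared psychosis pattern (hence non-specific via
# B1 transfer).
_PRESET_GEOMETRY = {
    "shared": {"center": (-0.30, 0.0, 0.0), "radius": 0.26},
    "B1": {"center": (0.30, 0.0, 0.0), "radius": 0.32},
    "B2": {"center": (0.0, 0.45, 0.0), "radius": 0.21},
    "B3": {"center": (0.0, -0.45, 0.0), "radius": 0.15},
}
_PAPER_LIKE_MAGNITUDES = {"shared": 0.045, "B1": 0.036, "B2": 0.012, "B3": 0.011}
_PAPER_LIKE_SHARED_SCALE = {"B1": 1.0, "B2": 1.0, "B3": 0.40}


def make_effect_patterns(
    grid_dims, preset: str = "paper_like"
) -> tuple[EffectPattern, dict, dict]:
    """Build the shared and group-specific effect patterns of a preset.

    Returns ``(shared_effect, specific_effects, shared_scale)``. Under the
    ``paper_like`` preset the group-specific supports and magnitudes are
    ordered B1 > B2 > B3; under ``null`` all magnitudes are zero; under
    ``shared_only`` only the shared pattern is non-zero.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    supports = {
        name: _sphere_support(grid_dims, geo["center"], geo["radius"])
        for name, geo in _PRESET_GEOMETRY.items()
    }
    if preset == "null":
        mags = {name: 0.0 for name in supports}
        scale = {g: 1.0 for g in BIOTYPE_GROUPS}
    elif preset == "shared_only":
        mags = {"shared": _PAPER_LIKE_MAGNITUDES["shared"], "B1": 0.0, "B2": 0.0, "B3": 0.0}
        scale = {g: 1.0 for g in BIOTYPE_GROUPS}
    else:
        mags = dict(_PAPER_LIKE_MAGNITUDES)
        scale = dict(_PAPER_LIKE_SHARED_SCALE)
    shared = EffectPattern(supports["shared"], mags["shared"])
    specific = {
        g: EffectPattern(supports[g], mags[g])
        for g in BIOTYPE_GROUPS
        if preset != "shared_only"
    }
    for pattern in [shared, *specific.values()]:
        pattern.validate_grid(tuple(grid_dims))
    return shared, specific, scale


def default_clinical_spec() -> ClinicalSpec:
    """Six outcomes mirroring the association stage's measure families.

    A reading-score-like premorbid-IQ estimate carries a group-invariant
    negative link to B1-pattern expression; a functioning score (GAF-like)
    carries group offsets but no expression link; the remaining outcomes are
    pure noise. Offsets approximate the reference cohort's group means.
    """
    groups = {"B1": 0.0, "B2": 0.0, "B3": 0.0, "CON": 0.0}
    return ClinicalSpec(
        outcomes=(
            ClinicalOutcome(
                "wrat_like",
                intercept=103.5,
                slope=-5.0,
                group_offsets={"B1": -8.0, "B2": -5.0, "B3": 2.0, "CON": 0.0},
                noise_sd=14.0,
                missing_rate=0.02,
            ),
            ClinicalOutcome(
                "gaf_like",
                intercept=86.6,
                slope=0.0,
                group_offsets={"B1": -37.7, "B2": -33.5, "B3": -30.8, "CON": 0.0},
                noise_sd=10.0,
                missing_rate=0.02,
            ),
            ClinicalOutcome(
                "sfs_like",
                intercept=157.7,
                slope=0.0,
                group_offsets={"B1": -40.3, "B2": -33.3, "B3": -25.7, "CON": 0.0},
                noise_sd=20.0,
                missing_rate=0.15,
            ),
            ClinicalOutcome("iea_pc1", 0.0, 0.0, dict(groups), 1.0, 0.10),
            ClinicalOutcome("spem_pc1", 0.0, 0.0, dict(groups), 1.0, 0.10),
            ClinicalOutcome("spem_pc2", 0.0, 0.0, dict(groups), 1.0, 0.10),
        )
    )


def cohort_spec(
    preset: str = "paper_like",
    grid_dims=(24, 24, 24),
    seed: int = 0,
    group_sizes: dict | None = None,
    **overrides,
) -> CohortSpec:
    """Convenience constructor assembling a :class:`CohortSpec` from a preset."""
    shared, specific, scale = make_effect_patterns(tuple(grid_dims), preset)
    kwargs = dict(
        grid_dims=tuple(grid_dims),
        shared_effect=shared,
        specific_effects=specific,
        shared_scale=scale,
        clinical_spec=default_clinical_spec(),
        seed=seed,
    )
    if group_sizes is not None:
        kwargs["group_sizes"] = dict(group_sizes)
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


# ---------------------------------------------------------------------------
# generation


def _group_deficits(spec: CohortSpec) -> dict:
    """Per-group dense deficit volumes (shared x scale + specific)."""
    zero = np.zeros(spec.grid_dims)
    shared = (
        spec.shared_effect.deficit_volume(spec.grid_dims)
        if spec.shared_effect is not None
        else zero
    )
    deficits = {CONTROL_GROUP: zero}
    for g in spec.psychosis_groups:
        scale = float(spec.shared_scale.get(g, 1.0))
        specific = spec.specific_effects.get(g)
        vol = scale * shared
        if specific is not None:
            vol = vol + specific.deficit_volume(spec.grid_dims)
        deficits[g] = vol
    return deficits


def _assign_diagnoses(spec: CohortSpec, n_psychosis: int, rng) -> np.ndarray:
    sizes = spec.diagnosis_sizes
    total = sum(sizes.values())
    counts = {d: int(round(n * n_psychosis / total)) for d, n in sizes.items()}
    # fix rounding drift deterministically on the largest group
    drift = n_psychosis - sum(counts.values())
    largest = max(sizes, key=lambda d: sizes[d])
    counts[largest] += drift
    labels = np.concatenate([np.repeat(d, c) for d, c in counts.items()])
    return rng.permutation(labels)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort of GMD volumes, tissue templates and a subject table.

    Subject ``i``'s voxel ``v`` is
    ``clip(baseline - deficit_g(v) + offset_i + noise_iv, 0, 1)`` with
    ``offset_i ~ N(0, subject_sd)`` and ``noise_iv ~ N(0, voxel_sd)``.
    Per-subject noise streams are spawned from the master seed, so the same
    seed reproduces the cohort bit-for-bit.
    """
    deficits = _group_deficits(spec)
    if CONTROL_GROUP not in spec.group_sizes:
        raise ValueError("group_sizes must include the control group 'CON'")

    group_labels = []
    for g, n in spec.group_sizes.items():
        group_labels.extend([g] * int(n))
    n_subjects = len(group_labels)

    master = np.random.default_rng([int(spec.seed), 0])
    images = np.empty((n_subjects, *spec.grid_dims), dtype=np.float32)
    for i, g in enumerate(group_labels):
        rng_i = np.random.default_rng([int(spec.seed), 1, i])
        offset = rng_i.normal(0.0, spec.subject_sd) if spec.subject_sd > 0 else 0.0
        noise = (
            rng_i.normal(0.0, spec.voxel_sd, size=spec.grid_dims)
            if spec.voxel_sd > 0
            else 0.0
        )
        vol = spec.baseline_mean - deficits[g] + offset + noise
        images[i] = np.clip(vol, 0.0, 1.0)

    psychosis_mask = np.array([g != CONTROL_GROUP for g in group_labels])
    diagnosis = np.full(n_subjects, CONTROL_GROUP, dtype=object)
    diagnosis[psychosis_mask] = _assign_diagnoses(spec, int(psychosis_mask.sum()), master)

    subjects = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n_subjects)],
            "biotype": group_labels,
            "diagnosis": diagnosis,
        }
    )
    gm_prob, wm_prob = tissue_probability_volumes(spec.grid_dims)
    cohort = SyntheticCohort(
        images=images,
        gm_prob=gm_prob,
        wm_prob=wm_prob,
        affine=spec.affine,
        subjects=subjects,
        spec=spec,
    )
    clinical = generate_clinical(cohort, spec.clinical_spec, b1_pattern_expression(cohort))
    cohort.subjects = subjects.join(clinical.set_index("subject_id"), on="subject_id")
    return cohort


def b1_pattern_support(spec: CohortSpec) -> np.ndarray:
    """Flat voxel indices of the B1-like pattern (shared U B1-specific)."""
    parts = []
    if spec.shared_effect is not None:
        parts.append(spec.shared_effect.support)
    if "B1" in spec.specific_effects:
        parts.append(spec.specific_effects["B1"].support)
    if not parts:
        return np.arange(int(np.prod(spec.grid_dims)))
    return np.unique(np.concatenate(parts))


def b1_pattern_expression(cohort: SyntheticCohort) -> np.ndarray:
    """Z-scored mean GMD shortfall over the B1-like pattern support.

    This is the generator's explicit latent standing in for what a trained
    classifier's evidence tracks: how strongly a subject expresses the
    B1-like deficit pattern.
    """
    support = b1_pattern_support(cohort.spec)
    flat = cohort.images.reshape(cohort.images.shape[0], -1)
    shortfall = cohort.spec.baseline_mean - flat[:, support].mean(axis=1)
    sd = shortfall.std(ddof=1)
    if sd == 0:
        return np.zeros_like(shortfall)
    return (shortfall - shortfall.mean()) / sd


def generate_clinical(
    cohort: SyntheticCohort,
    clinical_spec: ClinicalSpec,
    pattern_expression: np.ndarray,
) -> pd.DataFrame:
    """Simulate the clinical table given per-subject pattern expression."""
    subjects = cohort.subjects
    n = len(subjects)
    if len(pattern_expression) != n:
        raise ValueError("pattern_expression must cover every subject")
    table = {"subject_id": list(subjects["subject_id"])}
    for k, outcome in enumerate(clinical_spec.outcomes):
        rng = np.random.default_rng([int(cohort.spec.seed), 2, k])
        offsets = np.empty(n)
        for i, g in enumerate(subjects["biotype"]):
            if g not in outcome.group_offsets and g != CONTROL_GROUP:
                raise ValueError(f"unknown group label {g!r} for outcome {outcome.name!r}")
            offsets[i] = outcome.group_offsets.get(g, 0.0)
        noise = rng.normal(0.0, outcome.noise_sd, size=n) if outcome.noise_sd > 0 else 0.0
        values = outcome.intercept + outcome.slope * np.asarray(pattern_expression) + offsets + noise
        values = values.astype(float)
        if outcome.missing_rate > 0:
            missing = rng.random(n) < outcome.missing_rate
            values[missing] = np.nan
        table[outcome.name] = values
    return pd.DataFrame(table)


def null_spec(**kwargs) -> CohortSpec:
    """Shortcut for the no-effect preset (all magnitudes zero)."""
    return cohort_spec(preset="null", **kwargs)


def paper_like_spec(**kwargs) -> CohortSpec:
    """Shortcut for the calibrated step-wise-gradient preset."""
    return cohort_spec(preset="paper_like", **kwargs)
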
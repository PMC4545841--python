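"""Synthetic co-registered CT + dual-echo UTE head phantoms.

This module stands in for the tri-modality patient cohort: it produces,
on one voxel grid, a ground-truth 3-class label volume (air / soft
tissue / bone), a CT rendering in Hounsfield units, and a dual-echo UTE
rendering whose tissue clusters mimic the structure seen in clinical
joint histograms — a dominant soft-tissue peak placed at (4,000, 4,000),
a bone cluster with strongly reduced second-echo signal generated by
explicit T2* decay, and an air cluster at background-noise level.

Geometry is a nested-ellipsoid "head": an outer soft-tissue ellipsoid
(scalp), a bone shell of configurable thickness (skull), an inner soft
region (brain), and an optional air cavity (sinus). Geometry is fully
deterministic; only the intensity renderings are stochastic, and they
are reproducible given the seed in the :class:`PhantomSpec`.

Bone echo pairs are generated mechanistically rather than as a free 2D
Gaussian: ``echo1`` is drawn from the bone intensity distribution and
``echo2 = echo1 * exp(-R2 * (TE2 - TE1))`` with a per-voxel relaxation
rate R2 (ms^-1), plus additive acquisition noise. This reproduces the
physical decay mechanism that the R2-map baseline classifier assumes,
which keeps baseline behaviour interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .errors import GeometryError
from .volumes import AIR, BONE, SOFT, DualEchoVolume, ScalarVolume, VoxelGrid

__all__ = [
    "TissueModel",
    "PhantomGeometry",
    "PhantomSpec",
    "PhantomCase",
    "generate_labels",
    "render_ct",
    "render_ute",
    "generate_phantom",
    "generate_cohort",
]


def _as_cov(m) -> np.ndarray:
    cov = np.asarray(m, dtype=float)
    if cov.shape != (2, 2):
        raise ValueError(f"echo covariance must be 2x2, got {cov.shape}")
    if not np.allclose(cov, cov.T):
        raise ValueError("echo covariance must be symmetric")
    if np.any(np.linalg.eigvalsh(cov) < -1e-9):
        raise ValueError("echo covariance must be positive semi-definite")
    return cov


@dataclass(frozen=True)
class TissueModel:
    """Per-class intensity model for CT and dual-echo UTE rendering.

    CT values are class mean + Gaussian noise (HU). Air and soft-tissue
    echo pairs are drawn from 2D Gaussian clusters (a.u.); bone echo
    pairs follow the explicit T2* decay mechanism with a Gaussian
    per-voxel R2 (ms^-1).

    Defaults place the soft-tissue cluster at the canonical (4,000,
    4,000) point and use the standard HU anchors: air -1,000 HU, soft
    tissue ~+30 HU (brain-matter range), cortical bone +1,200 HU (within
    the +700..+3,000 HU reference band).
    """

    # CT, ordered (air, soft, bone); means must be increasing
    ct_mean_hu: tuple[float, float, float] = (-1000.0, 30.0, 1200.0)
    ct_sd_hu: tuple[float, float, float] = (30.0, 40.0, 150.0)
    # 2D echo clusters (a.u.)
    air_echo_mean: tuple[float, float] = (60.0, 60.0)
    air_echo_cov: np.ndarray = field(
        default_factory=lambda: np.diag([30.0**2, 30.0**2])
    )
    soft_echo_mean: tuple[float, float] = (4000.0, 4000.0)
    # soft tissue is a two-component mixture: a sharp core (the distinct
    # main histogram peak) plus a broad correlated tail (partial-volume
    # and tissue-composition spread reaching toward the bone cluster)
    soft_echo_cov: np.ndarray = field(
        default_factory=lambda: np.array(
            [[900.0**2, 0.6 * 900.0 * 900.0], [0.6 * 900.0 * 900.0, 900.0**2]]
        )
    )
    soft_core_fraction: float = 0.45
    soft_core_cov: np.ndarray = field(
        default_factory=lambda: np.diag([250.0**2, 250.0**2])
    )
    # bone: echo1 distribution + per-voxel R2 (ms^-1)
    bone_echo1_mean: float = 2200.0
    bone_echo1_sd: float = 700.0
    bone_r2_mean: float = 0.55
    bone_r2_sd: float = 0.18

    def __post_init__(self) -> None:
        object.__setattr__(self, "air_echo_cov", _as_cov(self.air_echo_cov))
        object.__setattr__(self, "soft_echo_cov", _as_cov(self.soft_echo_cov))
        object.__setattr__(self, "soft_core_cov", _as_cov(self.soft_core_cov))
        if not 0.0 <= self.soft_core_fraction <= 1.0:
            raise ValueError("soft_core_fraction must lie in [0, 1]")
        a, s, b = self.ct_mean_hu
        if not (a < s < b):
            raise ValueError(f"CT means must be ordered air < soft < bone, got {self.ct_mean_hu}")
        if any(sd < 0 for sd in self.ct_sd_hu):
            raise ValueError("CT noise sds must be non-negative")
        if self.bone_echo1_sd < 0 or self.bone_r2_sd < 0:
            raise ValueError("bone spread parameters must be non-negative")
        if self.bone_r2_mean <= 0:
            raise ValueError("bone R2 mean must be positive")

    @property
    def bone_echo2_mean(self) -> float:
        """Noise-free bone echo2 mean for the reference dTE = 1.67 ms."""
        return self.bone_echo1_mean * float(np.exp(-self.bone_r2_mean * 1.67))

    @classmethod
    def noise_free(cls) -> "TissueModel":
        """Point-mass clusters, zero CT noise: each class a single echo pair."""
        return cls(
            ct_sd_hu=(0.0, 0.0, 0.0),
            air_echo_mean=(0.0, 0.0),
            air_echo_cov=np.zeros((2, 2)),
            soft_echo_cov=np.zeros((2, 2)),
            soft_core_cov=np.zeros((2, 2)),
            bone_echo1_mean=2000.0,
            bone_echo1_sd=0.0,
            bone_r2_sd=0.0,
        )

    def with_overlap(self, scale: float) -> "TissueModel":
        """Scale every echo-cluster spread by *scale* (>= 0).

        ``scale > 1`` increases the overlap between the soft-tissue and
        bone clusters, ``scale < 1`` separates them; class means and CT
        parameters are untouched.
        """
        if scale < 0:
            raise ValueError("overlap scale must be non-negative")
        return replace(
            self,
            air_echo_cov=self.air_echo_cov * scale**2,
            soft_echo_cov=self.soft_echo_cov * scale**2,
            soft_core_cov=self.soft_core_cov * scale**2,
            bone_echo1_sd=self.bone_echo1_sd * scale,
            bone_r2_sd=self.bone_r2_sd * scale,
        )


@dataclass(frozen=True)
class PhantomGeometry:
    """Nested-ellipsoid head geometry (all lengths in mm, world frame).

    From outside in: outer soft-tissue ellipsoid (scalp surface), bone
    shell starting ``scalp_thickness_mm`` below it with radial thickness
    ``shell_thickness_mm``, inner soft "brain" region, and an optional
    air cavity inside the brain.
    """

    outer_semiaxes_mm: tuple[float, float, float] = (55.0, 50.0, 55.0)
    scalp_thickness_mm: float = 6.0
    shell_thickness_mm: float = 7.0
    cavity_semiaxes_mm: tuple[float, float, float] | None = (10.0, 10.0, 10.0)
    cavity_center_mm: tuple[float, float, float] = (0.0, 15.0, 0.0)

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.outer_semiaxes_mm):
            raise GeometryError("outer semiaxes must be positive")
        if self.scalp_thickness_mm < 0 or self.shell_thickness_mm <= 0:
            raise GeometryError("scalp/shell thickness must be positive")
        inner = self.brain_semiaxes_mm
        if any(a <= 0 for a in inner):
            raise GeometryError("bone shell leaves no room for the inner soft region")
        if self.cavity_semiaxes_mm is not None and any(
            a < 0 for a in self.cavity_semiaxes_mm
        ):
            raise GeometryError("cavity semiaxes must be non-negative")

    @property
    def shell_outer_semiaxes_mm(self) -> tuple[float, float, float]:
        return tuple(a - self.scalp_thickness_mm for a in self.outer_semiaxes_mm)

    @property
    def brain_semiaxes_mm(self) -> tuple[float, float, float]:
        return tuple(
            a - self.scalp_thickness_mm - self.shell_thickness_mm
            for a in self.outer_semiaxes_mm
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Complete recipe for one phantom: grid, geometry, intensity model,
    noise levels (a.u. for MR, HU for CT) and RNG seed."""

    grid: VoxelGrid = field(
        default_factory=lambda: VoxelGrid.centered((64, 64, 64), (2.0, 2.0, 2.0))
    )
    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)
    tissue_model: TissueModel = field(default_factory=TissueModel)
    noise_echo_sd: tuple[float, float] = (120.0, 120.0)
    noise_ct_sd: float = 30.0
    noise_model: Literal["gaussian", "rician"] = "gaussian"
    te1: float = 0.03
    te2: float = 1.7
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.noise_echo_sd) or self.noise_ct_sd < 0:
            raise GeometryError("noise sds must be non-negative")
        # the bone shell must be at least one voxel thick along each axis
        if self.geometry.shell_thickness_mm < max(self.grid.spacing) - 1e-9:
            raise GeometryError(
                f"bone shell {self.geometry.shell_thickness_mm} mm is thinner than "
                f"the largest voxel spacing {max(self.grid.spacing)} mm"
            )


@dataclass
class PhantomCase:
    """One synthetic patient: ground-truth labels plus CT and UTE renderings."""

    name: str
    labels: ScalarVolume
    ct: ScalarVolume
    ute: DualEchoVolume
    spec: PhantomSpec
    intensity_jitter: tuple[float, float] = (1.0, 1.0)


def _inside(world: np.ndarray, center, semiaxes) -> np.ndarray:
    semi = np.asarray(semiaxes, dtype=float)
    rel = (world - np.asarray(center, dtype=float)) / semi
    return (rel**2).sum(axis=-1) <= 1.0


def generate_labels(spec: PhantomSpec) -> ScalarVolume:
    """Deterministic ground-truth label volume for *spec*.

    Voxel class is decided by point-in-ellipsoid tests on the voxel
    center in world coordinates; the bone shell topologically encloses
    the inner soft region by construction.
    """
    geo = spec.geometry
    world = spec.grid.voxel_centers_world()
    labels = np.full(spec.grid.shape, AIR, dtype=np.int16)
    center = (0.0, 0.0, 0.0)
    labels[_inside(world, center, geo.outer_semiaxes_mm)] = SOFT
    shell_outer = _inside(world, center, geo.shell_outer_semiaxes_mm)
    brain = _inside(world, center, geo.brain_semiaxes_mm)
    labels[shell_outer & ~brain] = BONE
    labels[brain] = SOFT
    if geo.cavity_semiaxes_mm is not None and all(
        a > 0 for a in geo.cavity_semiaxes_mm
    ):
        cavity = _inside(world, geo.cavity_center_mm, geo.cavity_semiaxes_mm)
        labels[cavity & brain] = AIR
    return ScalarVolume(spec.grid, labels, "label")


def render_ct(
    labels: ScalarVolume,
    model: TissueModel,
    noise_sd: float,
    seed: int | np.random.Generator,
) -> ScalarVolume:
    """CT rendering: per-voxel HU = class mean + Gaussian noise."""
    rng = np.random.default_rng(seed)
    means = np.asarray(model.ct_mean_hu)[labels.values]
    hu = means + rng.normal(0.0, noise_sd, size=labels.values.shape)
    return ScalarVolume(labels.grid, hu, "CT")


def _magnitude_noise(
    signal: np.ndarray,
    sd: float,
    rng: np.random.Generator,
    model: Literal["gaussian", "rician"],
) -> np.ndarray:
    if sd == 0:
        return signal.copy()
    if model == "rician":
        # magnitude of complex signal + circular Gaussian noise
        re = signal + rng.normal(0.0, sd, size=signal.shape)
        im = rng.normal(0.0, sd, size=signal.shape)
        return np.hypot(re, im)
    return signal + rng.normal(0.0, sd, size=signal.shape)


def render_ute(
    labels: ScalarVolume,
    model: TissueModel,
    noise_echo_sd: tuple[float, float],
    te1: float,
    te2: float,
    seed: int | np.random.Generator,
    noise_model: Literal["gaussian", "rician"] = "gaussian",
) -> DualEchoVolume:
    """Dual-echo UTE rendering.

    Air and soft-tissue voxels draw their (echo1, echo2) pair from the
    class 2D Gaussian cluster; bone voxels draw echo1 from the bone
    intensity distribution and derive echo2 through exponential T2*
    decay with a per-voxel R2. Acquisition noise is then added to both
    echoes (Gaussian by default, Rician on request) and intensities are
    clamped to be non-negative.
    """
    rng = np.random.default_rng(seed)
    lab = labels.values
    e1 = np.zeros(lab.shape)
    e2 = np.zeros(lab.shape)

    air = lab == AIR
    n_air = int(air.sum())
    if n_air:
        draws = rng.multivariate_normal(model.air_echo_mean, model.air_echo_cov,
                                        size=n_air, method="eigh")
        e1[air], e2[air] = draws[:, 0], draws[:, 1]

    soft = lab == SOFT
    n_soft = int(soft.sum())
    if n_soft:
        # sharp-core / broad-tail mixture for the soft cluster
        core = rng.random(n_soft) < model.soft_core_fraction
        draws = np.empty((n_soft, 2))
        for mask, cov in ((core, model.soft_core_cov), (~core, model.soft_echo_cov)):
            k = int(mask.sum())
            if k:
                draws[mask] = rng.multivariate_normal(
                    model.soft_echo_mean, cov, size=k, method="eigh"
                )
        e1[soft], e2[soft] = draws[:, 0], draws[:, 1]

    bone = lab == BONE
    n_bone = int(bone.sum())
    if n_bone:
        b1 = rng.normal(model.bone_echo1_mean, model.bone_echo1_sd, size=n_bone)
        r2 = rng.normal(model.bone_r2_mean, model.bone_r2_sd, size=n_bone)
        e1[bone] = b1
        e2[bone] = b1 * np.exp(-r2 * (te2 - te1))

    e1 = np.clip(_magnitude_noise(e1, noise_echo_sd[0], rng, noise_model), 0.0, None)
    e2 = np.clip(_magnitude_noise(e2, noise_echo_sd[1], rng, noise_model), 0.0, None)
    return DualEchoVolume(
        ScalarVolume(labels.grid, e1, "MR_echo1"),
        ScalarVolume(labels.grid, e2, "MR_echo2"),
        te1,
        te2,
    )


def generate_phantom(spec: PhantomSpec, name: str = "phantom") -> PhantomCase:
    """Labels + CT + UTE for one spec; bitwise reproducible given the seed."""
    labels = generate_labels(spec)
    ss = np.random.SeedSequence(spec.rng_seed)
    ct_seed, ute_seed = ss.spawn(2)
    ct = render_ct(labels, spec.tissue_model, spec.noise_ct_sd, np.random.default_rng(ct_seed))
    ute = render_ute(
        labels,
        spec.tissue_model,
        spec.noise_echo_sd,
        spec.te1,
        spec.te2,
        np.random.default_rng(ute_seed),
        spec.noise_model,
    )
    return PhantomCase(name, labels, ct, ute, spec)


def generate_cohort(
    n: int,
    base_spec: PhantomSpec | None = None,
    jitter_sd: float = 0.1,
    seed: int = 0,
) -> list[PhantomCase]:
    """Generate *n* independent phantoms with per-case intensity jitter.

    Each case gets an independent rendering seed and a global
    multiplicative scale factor per echo, ``exp(N(0, jitter_sd))``,
    emulating inter-patient receive-gain variation — this is what the
    patient-wise prescaling step has to undo before histograms from
    different cases can be pooled.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    base_spec = base_spec or PhantomSpec()
    master = np.random.default_rng(np.random.SeedSequence(seed))
    cases = []
    for i in range(n):
        case_seed = int(master.integers(0, 2**31 - 1))
        g1, g2 = np.exp(master.normal(0.0, jitter_sd, size=2)) if jitter_sd > 0 else (1.0, 1.0)
        spec = replace(base_spec, rng_seed=case_seed)
        case = generate_phantom(spec, name=f"case{i:02d}")
        case.ute = case.ute.scaled(g1, g2)
        case.intensity_jitter = (float(g1), float(g2))
        cases.append(case)
    return cases
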
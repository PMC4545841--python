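"""Voxel classification of dual-echo volumes: max-posterior and baselines.

Three classifiers are implemented:

* **posterior** — look up each voxel's (echo1, echo2) bin in a trained,
  constrained :class:`~utebone.posterior.PosteriorMap` and assign the
  class with maximum posterior probability. Ties and unreliable bins
  fall back to soft tissue, and the a priori rules are re-checked on
  the actual voxel intensities so no classified voxel can violate them.
* **r2** — the apparent transverse relaxation rate map
  ``R2 = ln(I_TE1 / I_TE2) / (TE2 - TE1)`` (ms^-1; in practice an R2*
  map), thresholded. In dual-echo space a threshold t is the straight
  origin-crossing cut ``e2 = e1 * exp(-t * dTE)``.
* **ndiff** — the normalized difference ``N = (I_TE1 - I_TE2) /
  I_TE2^2``, thresholded; a slightly curved origin-crossing cut.

"Higher than" thresholds are strict. The published operating points are
bone posterior probability 0.5, R2 0.35 ms^-1 and N 5e-4. R2 is kept in
ms^-1 so that 0.35 ms^-1 equals the 350 s^-1 contour of the straight-cut
family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import ConfigurationError, ContractError
from .posterior import PosteriorMap
from .preprocess import BackgroundStats
from .volumes import AIR, BONE, SOFT, DualEchoVolume, ScalarVolume

__all__ = [
    "R2_THRESHOLD_DEFAULT",
    "NDIFF_THRESHOLD_DEFAULT",
    "PROB_THRESHOLD_DEFAULT",
    "R2Map",
    "NormalizedDiffMap",
    "Segmentation",
    "compute_r2_map",
    "compute_ndiff_map",
    "threshold_classify",
    "posterior_classify",
    "boundary_curve",
]

R2_THRESHOLD_DEFAULT = 0.35  # ms^-1
NDIFF_THRESHOLD_DEFAULT = 5e-4  # (a.u.)^-1
PROB_THRESHOLD_DEFAULT = 0.5

#: sentinel for voxels where the map is undefined (non-positive echoes);
#: NaN compares False against any threshold, so sentinel voxels are never bone
SENTINEL = np.nan


@dataclass
class R2Map:
    """Apparent transverse relaxation rates (ms^-1) on the echo grid."""

    values: np.ndarray
    source: DualEchoVolume
    kind: Literal["r2"] = "r2"
    units: str = "ms^-1"
    sentinel_policy: str = "NaN where any echo <= 0; sentinel voxels never bone"


@dataclass
class NormalizedDiffMap:
    """Normalized echo difference N = (e1 - e2) / e2^2 (a.u.^-1)."""

    values: np.ndarray
    source: DualEchoVolume
    kind: Literal["ndiff"] = "ndiff"
    units: str = "a.u.^-1"
    sentinel_policy: str = "NaN where echo2 <= 0; sentinel voxels never bone"


@dataclass
class Segmentation:
    """A classified volume plus optional per-class probabilities."""

    labels: ScalarVolume
    method: Literal["posterior", "r2", "ndiff"]
    params: dict = field(default_factory=dict)
    probabilities: dict[int, ScalarVolume] | None = None

    def bone_mask(self, prob_threshold: float | None = None) -> np.ndarray:
        """Boolean bone mask.

        For the posterior method with probabilities attached, the mask
        is ``P(bone) > prob_threshold`` (default 0.5, the published
        operating point); otherwise it is ``labels == bone``.
        """
        if self.probabilities is not None and BONE in self.probabilities:
            thr = PROB_THRESHOLD_DEFAULT if prob_threshold is None else prob_threshold
            return self.probabilities[BONE].values > thr
        return self.labels.values == BONE


def compute_r2_map(vol: DualEchoVolume) -> R2Map:
    """``R2 = ln(I_TE1 / I_TE2) / (TE2 - TE1)`` in ms^-1.

    Voxels where either echo is non-positive get the NaN sentinel and
    can never be classified as bone. Negative rates (echo2 > echo1) are
    retained — they are physically possible noise outcomes and simply
    fall below any positive threshold.
    """
    if vol.te2 <= vol.te1:
        raise ConfigurationError("need te2 > te1 to form an R2 map")
    e1, e2 = vol.echo1.values, vol.echo2.values
    valid = (e1 > 0) & (e2 > 0)
    out = np.full(e1.shape, SENTINEL)
    out[valid] = np.log(e1[valid] / e2[valid]) / vol.delta_te
    return R2Map(out, vol)


def compute_ndiff_map(vol: DualEchoVolume) -> NormalizedDiffMap:
    """``N = (I_TE1 - I_TE2) / I_TE2^2``; NaN sentinel where echo2 <= 0."""
    e1, e2 = vol.echo1.values, vol.echo2.values
    valid = e2 > 0
    out = np.full(e1.shape, SENTINEL)
    out[valid] = (e1[valid] - e2[valid]) / e2[valid] ** 2
    return NormalizedDiffMap(out, vol)


def threshold_classify(
    map_: R2Map | NormalizedDiffMap,
    threshold: float,
    background_ref: BackgroundStats | None = None,
) -> Segmentation:
    """Baseline classification by thresholding an R2 or N map.

    Bone where the map value is strictly above *threshold* (sentinel
    voxels excluded); air where echo1 lies below the background
    reference level ``mu + 3*sigma`` (skipped when *background_ref* is
    None, e.g. on abstract echo lattices); soft tissue elsewhere. The
    air assignment takes precedence: background-level voxels have
    essentially random echo ratios, so without it the noise floor would
    flood the bone mask.
    """
    if not np.isfinite(threshold):
        raise ConfigurationError("threshold must be finite")
    vol = map_.source
    labels = np.full(vol.grid.shape, SOFT, dtype=np.int16)
    with np.errstate(invalid="ignore"):
        labels[map_.values > threshold] = BONE
    if background_ref is not None:
        labels[vol.echo1.values < background_ref.echo1.reference] = AIR
    return Segmentation(
        labels=ScalarVolume(vol.grid, labels, "label"),
        method=map_.kind,
        params={"threshold": threshold},
    )


def posterior_classify(vol: DualEchoVolume, pmap: PosteriorMap) -> Segmentation:
    """Maximum-posterior classification via lookup table.

    *vol* must be prescaled to the canonical soft-tissue peak and
    *pmap* must have the a priori constraints applied. Each voxel is
    mapped to its echo-pair bin and assigned the class with the highest
    posterior probability there; exact ties and unreliable bins resolve
    to soft tissue. The constraint rules are additionally enforced on
    the voxel's own intensities: a voxel violating a bone rule is never
    bone (its bone probability is moved to soft tissue) and a voxel
    with echo1 + echo2 > 4,000 is never air.
    """
    if not pmap.constrained:
        raise ContractError("posterior map must have prior constraints applied")
    e1, e2 = vol.echo1.values, vol.echo2.values
    i = pmap.binning.index(e1.ravel())
    j = pmap.binning.index(e2.ravel())
    shape = vol.grid.shape

    prob = {c: pmap.probs[c, i, j].reshape(shape).copy() for c in (AIR, SOFT, BONE)}
    reliable = pmap.reliable[i, j].reshape(shape)

    # voxel-level re-check of the a priori rules (bin centers can sit on
    # the other side of a rule boundary than the voxel itself)
    never_bone = (e2 > e1) | (e1 > 8000.0) | (e2 > 5000.0) | (e1 - e2 > 4000.0)
    never_air = e1 + e2 > 4000.0
    prob[SOFT] = prob[SOFT] + np.where(never_bone, prob[BONE], 0.0)
    prob[BONE] = np.where(never_bone, 0.0, prob[BONE])
    prob[SOFT] = prob[SOFT] + np.where(never_air, prob[AIR], 0.0)
    prob[AIR] = np.where(never_air, 0.0, prob[AIR])

    stacked = np.stack([prob[AIR], prob[SOFT], prob[BONE]])
    order = np.argsort(stacked, axis=0)  # ascending; ties keep lower index
    winner = order[-1]
    top = np.take_along_axis(stacked, winner[None], axis=0)[0]
    runner = np.take_along_axis(stacked, order[-2][None], axis=0)[0]
    labels = winner.astype(np.int16)
    labels[top == runner] = SOFT  # exact ties are uncertain -> soft tissue
    labels[~reliable] = SOFT

    prob_vols = {
        c: ScalarVolume(vol.grid, np.clip(prob[c], 0.0, 1.0), "probability")
        for c in (AIR, SOFT, BONE)
    }
    return Segmentation(
        labels=ScalarVolume(vol.grid, labels, "label"),
        method="posterior",
        params={"min_count": pmap.min_count},
        probabilities=prob_vols,
    )


def boundary_curve(
    method: Literal["r2", "ndiff"],
    threshold: float,
    te1: float,
    te2: float,
    e1_range: tuple[float, float],
    n_points: int = 256,
) -> np.ndarray:
    """Decision boundary of a baseline classifier in dual-echo space.

    Returns an ``(n_points, 2)`` array of (e1, e2) points with
    ``map(e1, e2) == threshold``. For ``r2`` this is the straight cut
    ``e2 = e1 * exp(-t * (te2 - te1))`` through the origin; for
    ``ndiff`` the slightly curved cut solving ``t * e2^2 + e2 - e1 = 0``
    (also through the origin).
    """
    lo, hi = e1_range
    if not (0 <= lo < hi):
        raise ConfigurationError("e1 range must be positive and increasing")
    e1 = np.linspace(lo, hi, n_points)
    if method == "r2":
        e2 = e1 * np.exp(-threshold * (te2 - te1))
    elif method == "ndiff":
        if threshold == 0:
            e2 = e1.copy()
        else:
            # stable root of t*e2^2 + e2 - e1 = 0 (no cancellation at small t*e1)
            e2 = 2.0 * e1 / (1.0 + np.sqrt(1.0 + 4.0 * threshold * e1))
    else:
        raise ConfigurationError(f"unknown boundary method {method!r}")
    return np.column_stack([e1, e2])
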
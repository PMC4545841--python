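"""Posterior tissue-probability maps over binned dual-echo space.

The training side of the method: for every (echo1, echo2) pair found in
prescaled data, count how often it corresponded to each CT-derived
tissue class, normalize by the total number of occurrences of that pair
to obtain the posterior probability P(class | echo pair), average the
per-patient maps over the cohort, and impose the a priori constraint
rules on the final map.

Echo pairs are discretized on a fixed lattice (default 50 a.u. bins on
[0, 12,000] per axis) so the posterior is a lookup table. The total
count per bin is clipped to a minimum of 10 when normalizing, which
suppresses outlier echo pairs seen only a handful of times; bins at or
above that count are flagged "reliable". On reliable bins the three
class probabilities sum to 1; on clipped bins they sum to less.

A priori constraint rules (applied to bin centers of the final map, and
re-checked voxelwise at classification time):

* echo1 + echo2 > 4,000  ->  never air (residual misregistration);
* echo2 > echo1          ->  never bone (motion / partial volume);
* echo1 > 8,000, echo2 > 5,000 or echo1 - echo2 > 4,000
                         ->  never bone (interface / metal artifacts).

Probability mass removed by a rule is reassigned to soft tissue — the
fallback class for uncertain regions — so the per-bin mass is conserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ContractError, GeometryError
from .volumes import AIR, BONE, SOFT, DualEchoVolume, ScalarVolume

__all__ = [
    "HistogramBinning",
    "JointHistogramSet",
    "PosteriorMap",
    "accumulate_histograms",
    "mean_ct_map",
    "compute_posterior",
    "average_posteriors",
    "apply_prior_constraints",
    "save_posterior_map",
    "load_posterior_map",
]


@dataclass(frozen=True)
class HistogramBinning:
    """Uniform 2D binning of (echo1, echo2) space.

    Bins are half-open ``[low, high)`` with the final bin closed;
    out-of-range intensities clamp to the edge bins. The same binning is
    used on both axes.
    """

    low: float = 0.0
    high: float = 12000.0
    nbins: int = 240

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ConfigurationError("binning needs low < high")
        if self.nbins < 2:
            raise ConfigurationError("binning needs at least 2 bins")

    @property
    def width(self) -> float:
        return (self.high - self.low) / self.nbins

    @property
    def centers(self) -> np.ndarray:
        return self.low + (np.arange(self.nbins) + 0.5) * self.width

    def index(self, values: np.ndarray) -> np.ndarray:
        """Map intensities to bin indices (clamping out-of-range values)."""
        idx = np.floor((np.asarray(values, dtype=float) - self.low) / self.width)
        return np.clip(idx, 0, self.nbins - 1).astype(np.int64)

    def to_dict(self) -> dict:
        return {"low": self.low, "high": self.high, "nbins": self.nbins}


@dataclass
class JointHistogramSet:
    """Per-class 2D count arrays over binned echo space, plus per-bin CT sums.

    ``counts[c, i, j]`` is the number of voxels of class ``c`` whose
    echo pair fell in bin (i, j); ``ct_sum[i, j]`` accumulates their HU
    values (over all classes) for the mean-CT map.
    """

    binning: HistogramBinning
    counts: np.ndarray  # (3, nbins, nbins) int64
    ct_sum: np.ndarray  # (nbins, nbins) float

    def __post_init__(self) -> None:
        n = self.binning.nbins
        if self.counts.shape != (3, n, n) or self.ct_sum.shape != (n, n):
            raise ConfigurationError("histogram array shapes do not match binning")
        if (self.counts < 0).any():
            raise ConfigurationError("negative histogram counts")

    @property
    def total(self) -> np.ndarray:
        """Per-bin voxel count over all classes."""
        return self.counts.sum(axis=0)

    def merged(self, other: "JointHistogramSet") -> "JointHistogramSet":
        if self.binning != other.binning:
            raise ConfigurationError("cannot merge histograms with different binnings")
        return JointHistogramSet(
            self.binning, self.counts + other.counts, self.ct_sum + other.ct_sum
        )


@dataclass
class PosteriorMap:
    """Lookup table P(class | echo1 bin, echo2 bin) with reliability mask.

    ``probs[c, i, j]`` in [0, 1]; ``reliable[i, j]`` marks bins whose
    training count reached ``min_count``. ``constrained`` records
    whether the a priori rules have been imposed; ``provenance`` carries
    audit metadata (number of cases averaged, per-case scale factors,
    counts of constraint-affected bins, ...).
    """

    binning: HistogramBinning
    probs: np.ndarray  # (3, nbins, nbins)
    reliable: np.ndarray  # (nbins, nbins) bool
    min_count: int = 10
    constrained: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.binning.nbins
        if self.probs.shape != (3, n, n) or self.reliable.shape != (n, n):
            raise ConfigurationError("posterior array shapes do not match binning")
        if self.probs.min() < -1e-12 or self.probs.max() > 1 + 1e-12:
            raise ConfigurationError("posterior probabilities outside [0, 1]")


def accumulate_histograms(
    vol: DualEchoVolume,
    labels: ScalarVolume,
    ct: ScalarVolume,
    binning: HistogramBinning | None = None,
) -> JointHistogramSet:
    """Count, per echo-pair bin, the voxels of each CT tissue class.

    All three inputs must share one grid and *vol* must already be
    prescaled to the canonical soft-tissue peak. Every voxel contributes
    exactly one count to its class array and its HU value to ``ct_sum``,
    so the grand total over bins and classes equals the voxel count.
    """
    binning = binning or HistogramBinning()
    if not (vol.grid.matches(labels.grid) and vol.grid.matches(ct.grid)):
        raise GeometryError("echoes, labels and CT must share one voxel grid")
    n = binning.nbins
    i = binning.index(vol.echo1.values.ravel())
    j = binning.index(vol.echo2.values.ravel())
    lab = labels.values.ravel().astype(np.int64)
    flat = (lab * n + i) * n + j
    counts = np.bincount(flat, minlength=3 * n * n).reshape(3, n, n)
    ct_sum = np.bincount(
        i * n + j, weights=ct.values.ravel().astype(float), minlength=n * n
    ).reshape(n, n)
    return JointHistogramSet(binning, counts, ct_sum)


def mean_ct_map(h: JointHistogramSet) -> np.ndarray:
    """Average HU of all voxels sharing each echo-pair bin.

    Empty bins are NaN (an empty bin is *not* water at 0 HU). The
    +100 HU contour of this map outlines the region dense in bone.
    """
    total = h.total
    out = np.full(total.shape, np.nan)
    np.divide(h.ct_sum, total, out=out, where=total > 0)
    return out


def compute_posterior(h: JointHistogramSet, min_count: int = 10) -> PosteriorMap:
    """Normalize class counts into posterior probabilities.

    ``P(class | bin) = count / max(total, min_count)`` — the denominator
    clip eliminates outlier echo pairs backed by fewer than *min_count*
    voxels. The reliability mask marks bins with ``total >= min_count``;
    callers preferring to exclude sparse bins outright can use it.
    """
    if min_count < 1:
        raise ConfigurationError("min_count must be >= 1")
    total = h.total
    denom = np.maximum(total, min_count).astype(float)
    probs = h.counts.astype(float) / denom
    return PosteriorMap(
        binning=h.binning,
        probs=probs,
        reliable=total >= min_count,
        min_count=min_count,
        provenance={"n_voxels": int(total.sum())},
    )


def average_posteriors(maps: Sequence[PosteriorMap]) -> PosteriorMap:
    """Unweighted elementwise mean of per-patient posterior maps.

    All maps must share one binning and be unconstrained. A bin of the
    averaged map is reliable when it was reliable in at least half of
    the input maps.
    """
    if not maps:
        raise ConfigurationError("need at least one posterior map to average")
    first = maps[0]
    for m in maps[1:]:
        if m.binning != first.binning:
            raise ConfigurationError("posterior maps have mismatched binnings")
    if any(m.constrained for m in maps):
        raise ContractError("cannot average maps after constraints were applied")
    probs = np.mean([m.probs for m in maps], axis=0)
    reliable_votes = np.sum([m.reliable for m in maps], axis=0)
    return PosteriorMap(
        binning=first.binning,
        probs=probs,
        reliable=2 * reliable_votes >= len(maps),
        min_count=first.min_count,
        provenance={"n_maps": len(maps)},
    )


def apply_prior_constraints(pmap: PosteriorMap) -> PosteriorMap:
    """Impose the a priori rules on a (final, averaged) posterior map.

    Evaluated on bin centers; zeroed probability mass is reassigned to
    soft tissue, so each bin keeps its pre-constraint total mass.
    Applying the constraints twice is a contract error.
    """
    if pmap.constrained:
        raise ContractError("prior constraints have already been applied to this map")
    c = pmap.binning.centers
    c1, c2 = c[:, None], c[None, :]
    never_air = c1 + c2 > 4000.0
    never_bone = (c2 > c1) | (c1 > 8000.0) | (c2 > 5000.0) | (c1 - c2 > 4000.0)

    probs = pmap.probs.copy()
    moved_air = np.where(never_air, probs[AIR], 0.0)
    probs[SOFT] += moved_air
    probs[AIR] = np.where(never_air, 0.0, probs[AIR])
    moved_bone = np.where(never_bone, probs[BONE], 0.0)
    probs[SOFT] += moved_bone
    probs[BONE] = np.where(never_bone, 0.0, probs[BONE])
    np.clip(probs, 0.0, 1.0, out=probs)  # guard float overshoot in the reassignment

    provenance = dict(pmap.provenance)
    provenance["constraints"] = {
        "bins_never_air": int(never_air.sum()),
        "bins_never_bone": int(never_bone.sum()),
        "mass_moved_to_soft": float(moved_air.sum() + moved_bone.sum()),
    }
    return PosteriorMap(
        binning=pmap.binning,
        probs=probs,
        reliable=pmap.reliable.copy(),
        min_count=pmap.min_count,
        constrained=True,
        provenance=provenance,
    )


def save_posterior_map(pmap: PosteriorMap, path: str | Path) -> None:
    """Serialize a posterior map to ``.npz`` (arrays + JSON metadata)."""
    meta = {
        "binning": pmap.binning.to_dict(),
        "min_count": pmap.min_count,
        "constrained": pmap.constrained,
        "provenance": pmap.provenance,
    }
    np.savez_compressed(
        path,
        probs=pmap.probs,
        reliable=pmap.reliable,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_posterior_map(path: str | Path) -> PosteriorMap:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        return PosteriorMap(
            binning=HistogramBinning(**meta["binning"]),
            probs=data["probs"],
            reliable=data["reliable"].astype(bool),
            min_count=int(meta["min_count"]),
            constrained=bool(meta["constrained"]),
            provenance=meta.get("provenance", {}),
        )
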
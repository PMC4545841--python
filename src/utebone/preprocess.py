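"""Background-noise estimation and patient-wise echo prescaling.

Two preprocessing steps make echo pairs from different acquisitions
comparable before any histogram is pooled:

1. **Background statistics** — for each echo, the mean and standard
   deviation of the image background. The background is found by a
   two-step rule: seed on voxels whose *first* echo is below a
   threshold (default 1,000 a.u.), then re-estimate inside the interval
   ``(0, mu + 3*sigma)`` of each echo to center the measurement on the
   background peak and reject partial-volume and bone voxels. The
   reference level ``mu + 3*sigma`` is later used to separate air from
   tissue.
2. **Prescaling** — each echo is multiplied by a factor that places the
   detected maximum of the soft-tissue cluster on the canonical point
   (4,000, 4,000) in dual-echo space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EstimationError
from .volumes import DualEchoVolume

__all__ = [
    "CANONICAL_PEAK",
    "EchoBackground",
    "BackgroundStats",
    "ScaleFactors",
    "estimate_background",
    "find_soft_tissue_peak",
    "prescale",
    "PeakBinning",
]

#: canonical location of the soft-tissue histogram peak after prescaling
CANONICAL_PEAK = (4000.0, 4000.0)


@dataclass(frozen=True)
class EchoBackground:
    """Background statistics of one echo (arbitrary units)."""

    mean: float
    sd: float
    count: int

    def __post_init__(self) -> None:
        if self.sd < 0 or self.count <= 0:
            raise EstimationError("background sd must be >= 0 and count > 0")

    @property
    def reference(self) -> float:
        """``mu + 3*sigma`` — the air/tissue reference level."""
        return self.mean + 3.0 * self.sd


@dataclass(frozen=True)
class BackgroundStats:
    echo1: EchoBackground
    echo2: EchoBackground

    def to_dict(self) -> dict:
        return {
            "echo1": {"mean": self.echo1.mean, "sd": self.echo1.sd,
                      "count": self.echo1.count, "reference": self.echo1.reference},
            "echo2": {"mean": self.echo2.mean, "sd": self.echo2.sd,
                      "count": self.echo2.count, "reference": self.echo2.reference},
        }


@dataclass(frozen=True)
class ScaleFactors:
    """Prescaling factors and the soft-tissue peak they were derived from."""

    s1: float
    s2: float
    peak: tuple[float, float]

    def __post_init__(self) -> None:
        if self.s1 <= 0 or self.s2 <= 0:
            raise EstimationError("scale factors must be positive")

    def to_dict(self) -> dict:
        return {"s1": self.s1, "s2": self.s2, "peak": list(self.peak)}


@dataclass(frozen=True)
class PeakBinning:
    """2D histogram used only for soft-tissue peak detection.

    Default: 50 a.u. bins on [0, 12,000] per axis, well below the width
    of any tissue cluster.
    """

    low: float = 0.0
    high: float = 12000.0
    width: float = 50.0

    @property
    def nbins(self) -> int:
        return int(round((self.high - self.low) / self.width))

    @property
    def centers(self) -> np.ndarray:
        return self.low + (np.arange(self.nbins) + 0.5) * self.width


def _two_step_stats(values: np.ndarray, seed_mask: np.ndarray) -> EchoBackground:
    seeded = values[seed_mask]
    mu, sigma = float(seeded.mean()), float(seeded.std())
    refined = seeded[(seeded > 0) & (seeded < mu + 3.0 * sigma)]
    if refined.size == 0:
        # degenerate background (e.g. exactly zero everywhere): keep step 1
        return EchoBackground(mu, sigma, int(seeded.size))
    return EchoBackground(float(refined.mean()), float(refined.std()), int(refined.size))


def estimate_background(
    vol: DualEchoVolume, seed_threshold: float = 1000.0
) -> BackgroundStats:
    """Two-step background estimate on *pre-scaling* intensities.

    Step 1 takes all voxels with ``echo1 < seed_threshold`` and computes
    mean/sd of each echo over them; step 2 recomputes each echo's
    statistics restricted to its own interval ``(0, mu + 3*sigma)``. If
    the refinement interval is empty (an exactly constant background)
    the step-1 statistics are returned.
    """
    seed_mask = vol.echo1.values < seed_threshold
    if not seed_mask.any():
        raise EstimationError(
            f"no voxels with echo1 below the seed threshold {seed_threshold} a.u."
        )
    return BackgroundStats(
        _two_step_stats(vol.echo1.values, seed_mask),
        _two_step_stats(vol.echo2.values, seed_mask),
    )


def find_soft_tissue_peak(
    vol: DualEchoVolume,
    binning: PeakBinning | None = None,
    background: BackgroundStats | None = None,
    smooth_bins: float = 1.5,
) -> tuple[float, float]:
    """Locate the soft-tissue maximum of the joint echo histogram.

    Returns the (echo1, echo2) bin-center with the highest joint count
    over the voxels lying strictly above the background reference level
    ``mu + 3*sigma`` of each echo — the restriction keeps the air peak
    from dominating the search, including the degenerate case of an
    exactly-zero background where the reference level is 0. The count
    histogram is smoothed with a symmetric Gaussian kernel
    (*smooth_bins* bins, 0 disables) before the argmax: the raw
    per-bin counts carry Poisson noise that would let the detected
    maximum wander across the flat top of the soft cluster. Ties break
    to the lexicographically smallest (echo1, then echo2) bin center,
    so the result is deterministic.
    """
    binning = binning or PeakBinning()
    if background is None:
        background = estimate_background(vol)
    e1 = vol.echo1.values.ravel()
    e2 = vol.echo2.values.ravel()
    above = (e1 > background.echo1.reference) & (e2 > background.echo2.reference)
    if not above.any():
        raise EstimationError("no above-background voxels: cannot locate soft-tissue peak")
    edges = np.linspace(binning.low, binning.high, binning.nbins + 1)
    counts, _, _ = np.histogram2d(
        np.clip(e1[above], binning.low, np.nextafter(binning.high, 0)),
        np.clip(e2[above], binning.low, np.nextafter(binning.high, 0)),
        bins=(edges, edges),
    )
    if smooth_bins > 0:
        counts = ndimage.gaussian_filter(counts, sigma=smooth_bins, mode="constant")
    centers = binning.centers
    # argmax on the C-ordered flat array is exactly the lexicographic tie-break
    i, j = np.unravel_index(int(np.argmax(counts)), counts.shape)
    return float(centers[i]), float(centers[j])


def prescale(
    vol: DualEchoVolume, peak: tuple[float, float]
) -> tuple[DualEchoVolume, ScaleFactors]:
    """Multiply each echo so the detected peak maps onto (4,000, 4,000)."""
    p1, p2 = peak
    if p1 <= 0 or p2 <= 0:
        raise EstimationError(f"soft-tissue peak coordinates must be positive, got {peak}")
    s1 = CANONICAL_PEAK[0] / p1
    s2 = CANONICAL_PEAK[1] / p2
    return vol.scaled(s1, s2), ScaleFactors(s1, s2, (float(p1), float(p2)))
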
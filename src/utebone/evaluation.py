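"""Segmentation scoring: Jaccard distance, agreement maps, cohort stats.

The quality measure is the Jaccard distance between the MR-derived and
the CT-derived bone masks, in percent: ``100 * (1 - |A∩B| / |A∪B|)``,
with 0% meaning identical, perfectly aligned masks. Two empty masks are
defined to be in perfect agreement (0%). Cohort comparisons use
two-tailed Welch t-tests (unequal variances).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, GeometryError, StatisticsError
from .volumes import ScalarVolume, VoxelGrid

__all__ = [
    "TN",
    "TP",
    "FP",
    "FN",
    "AGREEMENT_COLORS",
    "EvalReport",
    "jaccard_distance",
    "confusion_counts",
    "agreement_map",
    "agreement_rgb",
    "welch_t_test",
    "cohort_summary",
]

# agreement-map alphabet
TN, TP, FP, FN = 0, 1, 2, 3

#: display colors: green = true positive bone, red = false positive,
#: blue = false negative, black = true negative
AGREEMENT_COLORS = {
    TP: (0, 200, 0),
    FP: (220, 0, 0),
    FN: (0, 0, 220),
    TN: (0, 0, 0),
}


def _as_mask(mask: np.ndarray | ScalarVolume) -> tuple[np.ndarray, VoxelGrid | None]:
    if isinstance(mask, ScalarVolume):
        return mask.values.astype(bool), mask.grid
    return np.asarray(mask).astype(bool), None


def _check_grids(pred, ref) -> tuple[np.ndarray, np.ndarray, VoxelGrid | None]:
    p, gp = _as_mask(pred)
    r, gr = _as_mask(ref)
    if gp is not None and gr is not None and not gp.matches(gr):
        raise GeometryError("prediction and reference masks are on different grids")
    if p.shape != r.shape:
        raise GeometryError(f"mask shapes differ: {p.shape} vs {r.shape}")
    return p, r, gp or gr


def jaccard_distance(pred, ref) -> float:
    """Jaccard distance between two bone masks, in percent.

    ``100 * (1 - |pred ∩ ref| / |pred ∪ ref|)``; 0% for two identical
    masks and, by convention, for two empty ones.
    """
    p, r, _ = _check_grids(pred, ref)
    union = int(np.count_nonzero(p | r))
    if union == 0:
        return 0.0
    inter = int(np.count_nonzero(p & r))
    return 100.0 * (1.0 - inter / union)


def confusion_counts(pred, ref) -> dict[str, int]:
    """TP/FP/FN/TN voxel counts for a bone mask against its reference."""
    p, r, _ = _check_grids(pred, ref)
    return {
        "tp": int(np.count_nonzero(p & r)),
        "fp": int(np.count_nonzero(p & ~r)),
        "fn": int(np.count_nonzero(~p & r)),
        "tn": int(np.count_nonzero(~p & ~r)),
    }


def agreement_map(pred, ref) -> ScalarVolume:
    """Categorical agreement volume: 0=TN, 1=TP, 2=FP, 3=FN."""
    p, r, grid = _check_grids(pred, ref)
    out = np.full(p.shape, TN, dtype=np.int16)
    out[p & r] = TP
    out[p & ~r] = FP
    out[~p & r] = FN
    if grid is None:
        grid = VoxelGrid.centered(p.shape, (1.0, 1.0, 1.0))
    return ScalarVolume(grid, out, "label")


def agreement_rgb(agreement: ScalarVolume, axis: int = 2, index: int | None = None) -> np.ndarray:
    """Render one slice of an agreement map as an RGB uint8 image."""
    vals = agreement.values
    if index is None:
        index = vals.shape[axis] // 2
    sl = np.take(vals, index, axis=axis)
    rgb = np.zeros((*sl.shape, 3), dtype=np.uint8)
    for state, color in AGREEMENT_COLORS.items():
        rgb[sl == state] = color
    return rgb


def welch_t_test(a, b) -> tuple[float, float]:
    """Two-tailed t-test assuming unequal variances (Welch).

    Returns the Welch statistic (with Welch-Satterthwaite degrees of
    freedom) and the two-tailed p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatisticsError("each sample needs at least 2 values")
    if a.var(ddof=1) + b.var(ddof=1) == 0:
        raise StatisticsError("zero combined variance: Welch t-test undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def _summary(values: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "min": float(values.min()),
        "max": float(values.max()),
        "n": int(values.size),
    }


@dataclass
class EvalReport:
    """Per-case Jaccard distances + cohort statistics + pairwise tests.

    ``cases`` is a list of records (case, method, jaccard, tp, fp, fn,
    tn); ``methods`` maps method name to its summary statistics;
    ``tests`` maps "methodA_vs_methodB" to Welch (t, p).
    """

    cases: list[dict] = field(default_factory=list)
    methods: dict[str, dict] = field(default_factory=dict)
    tests: dict[str, dict] = field(default_factory=dict)

    def jaccard_of(self, method: str) -> np.ndarray:
        return np.array(
            [c["jaccard"] for c in self.cases if c["method"] == method], dtype=float
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {"cases": self.cases, "methods": self.methods, "tests": self.tests},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "EvalReport":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            source = Path(source).read_text()
        data = json.loads(source)
        return cls(cases=data["cases"], methods=data["methods"], tests=data["tests"])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.cases).to_csv(path, index=False)


def cohort_summary(
    jaccard_by_method: Mapping[str, Mapping[str, float]],
    confusion_by_method: Mapping[str, Mapping[str, Mapping[str, int]]] | None = None,
    reference_method: str = "posterior",
) -> EvalReport:
    """Summarize per-case Jaccard distances per method across a cohort.

    Every method must cover the same case set. Mean, median, sd
    (n-1 denominator), min and max are reported per method, and the
    *reference_method* is compared against every other method with a
    two-tailed Welch t-test (skipped when fewer than two cases).
    """
    methods = list(jaccard_by_method)
    if not methods:
        raise ConfigurationError("no methods to summarize")
    case_sets = {m: tuple(sorted(jaccard_by_method[m])) for m in methods}
    if len(set(case_sets.values())) != 1:
        raise ConfigurationError(f"methods cover different case sets: {case_sets}")

    report = EvalReport()
    for m in methods:
        for case in sorted(jaccard_by_method[m]):
            rec = {"case": case, "method": m, "jaccard": float(jaccard_by_method[m][case])}
            if confusion_by_method is not None:
                rec.update(confusion_by_method[m][case])
            report.cases.append(rec)
        report.methods[m] = _summary(report.jaccard_of(m))

    if reference_method in methods:
        ref = report.jaccard_of(reference_method)
        for m in methods:
            if m == reference_method or ref.size < 2:
                continue
            try:
                t, p = welch_t_test(ref, report.jaccard_of(m))
            except StatisticsError:
                continue
            report.tests[f"{reference_method}_vs_{m}"] = {"t": t, "p": p}
    return report
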
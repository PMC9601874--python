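"""Symptom-description-domain partition of the dispersion plane and scoring.

The (cur1, cur2) plane is partitioned into rectangles, each associated with
a cardiac condition:

* D0 = (25, 200] x [0, 25]        normal
* D1 = (25, 90]  x (25, +inf)     atrial premature (A.P.)
* D2 = (10, 25]  x [0, +inf)      ventricular abnormal, subdivided into
    D21 = (10, 25] x [0, 50]      V.F.   (ventricular flutter)
    D22 = (10, 25] x [40, 70]     F.V.N. (fusion of ventricular and normal)
    D23 = (10, 25] x [60, +inf)   P.V.C. (premature ventricular contraction)
* D3 = [0, 10) x [0, +inf)        bundle branch block, subdivided into
    D31 = [0, 10) x [0, 140]      L.B.B.B.
    D32 = [0, 10) x [100, +inf)   R.B.B.B.
* D4 = everything else            unclassified

The D2 and D3 sub-boxes overlap on purpose: a point landing in an overlap
gets the coarse label only (the lesion area is known, the exact disease is
not).  Narrower QRS complexes give larger transverse dispersion, so cur1
decreases from normal through ventricular classes to bundle branch block.

The boxes were calibrated on MIT-BIH beats; ``DomainPartition.from_json``
lets a recalibrated partition be loaded without code changes.

Classification quality per coarse class j is scored by

    TPR_j = |Qhat_j & Q_j| / |Q_j|              (sensitivity)
    NRR_j = 1 - |Qhat_j & not-Q_j| / |not-Q_j|  (noise removal rate)
    PPV_j = |Qhat_j & Q_j| / |Qhat_j|           (precision)
    F1_j  = 2 |Qhat_j & Q_j| / (|Q_j| + |Qhat_j|)

where Q_j are the true and Qhat_j the predicted members of class j.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "Interval",
    "Box",
    "DomainPartition",
    "Diagnosis",
    "classify_point",
    "evaluate",
    "COARSE_CLASSES",
    "FINE_CLASSES",
]

COARSE_CLASSES = (
    "normal",
    "atrial_abnormal",
    "ventricular_abnormal",
    "bundle_branch_block",
    "unclassified",
)
FINE_CLASSES = ("N", "A.P.", "V.F.", "F.V.N.", "P.V.C.", "L.B.B.B.", "R.B.B.B.", "none")

INF = math.inf


@dataclass(frozen=True)
class Interval:
    lo: float
    hi: float
    lo_open: bool = False
    hi_open: bool = False

    def __contains__(self, x: float) -> bool:
        above = x > self.lo if self.lo_open else x >= self.lo
        below = x < self.hi if self.hi_open else x <= self.hi
        return above and below


@dataclass(frozen=True)
class Box:
    cur1: Interval
    cur2: Interval

    def __contains__(self, p) -> bool:
        return p[0] in self.cur1 and p[1] in self.cur2


def _box(c1, c2) -> Box:
    return Box(Interval(*c1), Interval(*c2))


#: the printed partition; keys are box names, sub-boxes carry the fine label
DEFAULT_BOXES: dict[str, Box] = {
    "D0": _box((25, 200, True, False), (0, 25, False, False)),
    "D1": _box((25, 90, True, False), (25, INF, True, True)),
    "D2": _box((10, 25, True, False), (0, INF, False, True)),
    "D21": _box((10, 25, True, False), (0, 50, False, False)),
    "D22": _box((10, 25, True, False), (40, 70, False, False)),
    "D23": _box((10, 25, True, False), (60, INF, False, True)),
    "D3": _box((0, 10, False, True), (0, INF, False, True)),
    "D31": _box((0, 10, False, True), (0, 140, False, False)),
    "D32": _box((0, 10, False, True), (100, INF, False, True)),
}

_FINE_OF_BOX = {
    "D0": "N",
    "D1": "A.P.",
    "D21": "V.F.",
    "D22": "F.V.N.",
    "D23": "P.V.C.",
    "D31": "L.B.B.B.",
    "D32": "R.B.B.B.",
}


@dataclass(frozen=True)
class DomainPartition:
    boxes: dict[str, Box]

    @classmethod
    def default(cls) -> "DomainPartition":
        return cls(boxes=dict(DEFAULT_BOXES))

    @classmethod
    def from_json(cls, path: str | Path) -> "DomainPartition":
        """Load boxes from ``{name: {"cur1": [lo, hi, lo_open, hi_open], "cur2": [...]}}``.

        ``null`` (or the string "inf") as a bound means +/- infinity.
        """
        raw = json.loads(Path(path).read_text())
        boxes = {}
        for name, spec in raw.items():
            ivs = []
            for key in ("cur1", "cur2"):
                lo, hi, lo_open, hi_open = spec[key]
                lo = -INF if lo is None else float(lo)
                hi = INF if hi is None or hi == "inf" else float(hi)
                ivs.append(Interval(lo, hi, bool(lo_open), bool(hi_open)))
            boxes[name] = Box(*ivs)
        return cls(boxes=boxes)


@dataclass(frozen=True)
class Diagnosis:
    coarse: str
    fine: str = "none"

    def __post_init__(self) -> None:
        if self.coarse not in COARSE_CLASSES:
            raise ValueError(f"unknown coarse class {self.coarse!r}")
        if self.fine not in FINE_CLASSES:
            raise ValueError(f"unknown fine class {self.fine!r}")


def classify_point(p, partition: DomainPartition | None = None) -> Diagnosis:
    """Diagnosis of one dispersion point by rectangle membership.

    Overlaps of the D2 (resp. D3) sub-boxes yield the coarse ventricular
    (resp. bundle-branch-block) label with ``fine='none'``; any point in no
    box is unclassified.
    """
    boxes = (partition or DomainPartition.default()).boxes
    cur1, cur2 = float(p[0]), float(p[1])
    if not (math.isfinite(cur1) and math.isfinite(cur2)):
        return Diagnosis("unclassified")
    pt = (cur1, cur2)
    if pt in boxes["D0"]:
        return Diagnosis("normal", "N")
    if pt in boxes["D1"]:
        return Diagnosis("atrial_abnormal", "A.P.")
    if pt in boxes["D2"]:
        hits = [n for n in ("D21", "D22", "D23") if pt in boxes[n]]
        if len(hits) == 1:
            return Diagnosis("ventricular_abnormal", _FINE_OF_BOX[hits[0]])
        return Diagnosis("ventricular_abnormal", "none")
    if pt in boxes["D3"]:
        hits = [n for n in ("D31", "D32") if pt in boxes[n]]
        if len(hits) == 1:
            return Diagnosis("bundle_branch_block", _FINE_OF_BOX[hits[0]])
        return Diagnosis("bundle_branch_block", "none")
    return Diagnosis("unclassified")


def evaluate(true_labels, predicted) -> dict:
    """Per-coarse-class TPR/NRR/PPV/F1 (percentages) and confusion counts.

    ``predicted`` may be Diagnosis objects or coarse-label strings.  Metrics
    of a class with no true (resp. predicted) members are reported as None
    rather than 0.
    """
    true_labels = [str(t) for t in true_labels]
    pred = [p.coarse if isinstance(p, Diagnosis) else str(p) for p in predicted]
    if len(true_labels) != len(pred):
        raise ValueError("label sequences differ in length")
    n = len(pred)
    report: dict = {"n": n, "classes": {}, "confusion": {}}
    for j in COARSE_CLASSES:
        for k in COARSE_CLASSES:
            report["confusion"][(j, k)] = sum(
                1 for t, p in zip(true_labels, pred) if t == k and p == j
            )
    for j in COARSE_CLASSES:
        q = sum(1 for t in true_labels if t == j)           # |Q_j|
        qhat = sum(1 for p in pred if p == j)               # |Qhat_j|
        hit = report["confusion"][(j, j)]                   # |Qhat_j & Q_j|
        rest = n - q
        off = qhat - hit                                    # |Qhat_j & not-Q_j|
        cls = {
            "size": q,
            "classified_size": qhat,
            "tpr": None if q == 0 else 100.0 * hit / q,
            "nrr": None if rest == 0 else 100.0 * (1.0 - off / rest),
            "ppv": None if qhat == 0 else 100.0 * hit / qhat,
            "f1": None if q + qhat == 0 else 100.0 * 2.0 * hit / (q + qhat),
        }
        report["classes"][j] = cls
    return report


def metrics_frame(report: dict):
    """Tidy per-class metric table (rows: class; columns: the four scores)."""
    import pandas as pd

    rows = []
    for j, cls in report["classes"].items():
        rows.append(
            {
                "class": j,
                "size": cls["size"],
                "classified_size": cls["classified_size"],
                "TPR": cls["tpr"],
                "NRR": cls["nrr"],
                "PPV": cls["ppv"],
                "F1": cls["f1"],
            }
        )
    return pd.DataFrame(rows).set_index("class")
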
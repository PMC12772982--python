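"""Multi-examiner agreement: consensus maps, pairwise IoU and reference masks.

Consensus maps count, per pixel, the fraction of examiners that marked the
pixel.  Lesion reference masks are obtained by thresholding the consensus map;
healthy reference masks are the plain union of the healthy annotations (made
disjoint from the lesion mask).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CIN_CLASSES",
    "CLASSES",
    "AnnotationSet",
    "ConsensusMap",
    "IoUMatrix",
    "consensus_map",
    "union_cin_masks",
    "pairwise_iou",
    "iou_matrix",
    "threshold_consensus",
    "healthy_union",
]

CIN_CLASSES = ("major", "minor")
CLASSES = CIN_CLASSES + ("healthy",)
#: pseudo-class: union of all lesion classes, irrespective of severity
UNION_CLASS = "cin_union"


@dataclass
class AnnotationSet:
    """One examiner's binary masks for one subject, all in a single frame.

    ``masks`` maps class labels (``major``/``minor``/``healthy``) to boolean
    ``H x W`` arrays; absent classes mean the examiner marked nothing.
    """

    subject_id: str
    examiner_id: str
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    frame: str = "colposcope"

    def __post_init__(self) -> None:
        shapes = set()
        for cls, m in list(self.masks.items()):
            m = np.asarray(m, dtype=bool)
            if m.ndim != 2:
                raise ValueError(f"mask for class {cls!r} is not 2-D")
            self.masks[cls] = m
            shapes.add(m.shape)
        if len(shapes) > 1:
            raise ValueError(f"masks have inconsistent shapes: {shapes}")

    @property
    def shape(self) -> tuple[int, int] | None:
        for m in self.masks.values():
            return m.shape
        return None

    def mask(self, cls: str) -> np.ndarray | None:
        """Mask for a class, or the union of lesion classes for ``cin_union``."""
        if cls == UNION_CLASS:
            parts = [self.masks[c] for c in CIN_CLASSES if c in self.masks]
            if not parts:
                return None
            out = parts[0].copy()
            for p in parts[1:]:
                out |= p
            return out
        return self.masks.get(cls)


@dataclass
class ConsensusMap:
    """Per-pixel fraction of examiners marking the pixel, in multiples of 1/n."""

    values: np.ndarray
    cls: str
    n_examiners: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("consensus map must be 2-D")
        if self.n_examiners < 1:
            raise ValueError("n_examiners must be >= 1")


def consensus_map(masks: Sequence[np.ndarray], cls: str = UNION_CLASS) -> ConsensusMap:
    """Normalized 2-D histogram of annotations: count of marks per pixel / n."""
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    arrs = [np.asarray(m, dtype=bool) for m in masks]
    shape = arrs[0].shape
    for m in arrs:
        if m.shape != shape:
            raise ValueError("masks have different shapes")
    counts = np.zeros(shape, dtype=np.int64)
    for m in arrs:
        counts += m
    return ConsensusMap(values=counts / len(arrs), cls=cls, n_examiners=len(arrs))


def union_cin_masks(sets: Sequence[AnnotationSet]) -> list[np.ndarray]:
    """Per-examiner union-of-lesion-classes masks (empty mask if none marked)."""
    shape = None
    for s in sets:
        if s.shape is not None:
            shape = s.shape
            break
    if shape is None:
        raise ValueError("no annotation set contains any mask")
    out = []
    for s in sets:
        m = s.mask(UNION_CLASS)
        out.append(np.zeros(shape, dtype=bool) if m is None else m)
    return out


def pairwise_iou(a: np.ndarray, b: np.ndarray) -> float | None:
    """Jaccard index |a∩b| / |a∪b|; ``None`` when the union is empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return None
    return np.count_nonzero(a & b) / union


@dataclass
class IoUMatrix:
    """Symmetric E x E matrix of pairwise IoU averaged across subjects.

    Diagonal entries and pairs with no valid subject are NaN; ``n_pairs``
    counts the subjects that contributed to each entry.
    """

    values: np.ndarray
    examiner_ids: list[str]
    cls: str
    n_pairs: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.examiner_ids, columns=self.examiner_ids)


def iou_matrix(
    annotations_by_subject: Mapping[str, Sequence[AnnotationSet]],
    cls: str = UNION_CLASS,
) -> IoUMatrix:
    """Pairwise IoU per subject, averaged over subjects where it is defined.

    Examiners are matched across subjects by ``examiner_id``.  A pair whose
    masks have an empty union on a subject contributes nothing for that
    subject; a pair with no valid subject at all gets a NaN entry.
    """
    examiner_ids: list[str] = []
    for sets in annotations_by_subject.values():
        for s in sets:
            if s.examiner_id not in examiner_ids:
                examiner_ids.append(s.examiner_id)
    n = len(examiner_ids)
    if n < 2:
        raise ValueError("need at least two examiners")
    pos = {e: i for i, e in enumerate(examiner_ids)}
    total = np.zeros((n, n))
    count = np.zeros((n, n), dtype=np.int64)
    for sets in annotations_by_subject.values():
        by_ex = {s.examiner_id: s for s in sets}
        ids = list(by_ex)
        for i, ei in enumerate(ids):
            mi = by_ex[ei].mask(cls)
            if mi is None:
                continue
            for ej in ids[i + 1 :]:
                mj = by_ex[ej].mask(cls)
                if mj is None:
                    continue
                v = pairwise_iou(mi, mj)
                if v is None:
                    continue
                a, b = pos[ei], pos[ej]
                total[a, b] += v
                total[b, a] += v
                count[a, b] += 1
                count[b, a] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    np.fill_diagonal(values, np.nan)  # omitted by convention, trivially 1
    return IoUMatrix(values=values, examiner_ids=examiner_ids, cls=cls, n_pairs=count)


def threshold_consensus(cmap: ConsensusMap, tau: float) -> np.ndarray:
    """Binary mask of pixels whose consensus fraction is >= tau (inclusive)."""
    if not 0 < tau <= 1:
        raise ValueError("tau must be in (0, 1]")
    return cmap.values >= tau - 1e-12


def healthy_union(
    sets: Sequence[AnnotationSet],
    cin_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Union of all healthy annotations, minus the thresholded lesion mask.

    Healthy annotations are kept in their entirety regardless of consensus
    (examiners mark only representative samples of healthy tissue), but any
    pixel also present in ``cin_mask`` is removed so the two reference
    regions stay disjoint.
    """
    if len(sets) == 0:
        raise ValueError("need at least one annotation set")
    shape = None
    for s in sets:
        if s.shape is not None:
            shape = s.shape
            break
    if shape is None:
        raise ValueError("annotation sets contain no masks")
    out = np.zeros(shape, dtype=bool)
    for s in sets:
        m = s.masks.get("healthy")
        if m is not None:
            out |= m
    if cin_mask is not None:
        out &= ~np.asarray(cin_mask, dtype=bool)
    return out
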
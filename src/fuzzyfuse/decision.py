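"""Decision stage: labels, partial volumes, tissue volumes, synthesis.

Turns the fused possibility maps into (1) a hard label map by the
maximum-possibility rule, (2) per-voxel partial-volume fractions by
normalising the possibility degrees, (3) per-tissue volume measurements
and (4) a synthesis image that redistributes the mean functional
activity of each tissue according to the local partial volumes —
giving functional contrast at anatomical resolution.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .fusion import FusedMapSet
from .phantom import TISSUES
from .volume import ImageVolume

__all__ = ["LabelMap", "PartialVolumeSet", "VolumeReport", "label",
           "partial_volumes", "synthesize", "quantify", "BACKGROUND_LABEL",
           "extract_features"]

#: label id used where every tissue possibility is zero
BACKGROUND_LABEL = -1


@dataclasses.dataclass
class LabelMap:
    """Per-voxel tissue ids (canonical tissue order; -1 = background)."""

    labels: np.ndarray
    tissues: tuple[str, ...] = TISSUES
    n_ties: int = 0

    def mask_for(self, tissue: int | str) -> np.ndarray:
        if isinstance(tissue, str):
            tissue = self.tissues.index(tissue)
        return self.labels == tissue


@dataclasses.dataclass
class PartialVolumeSet:
    """Per-tissue mixing fractions; zero everywhere on background."""

    p: dict[str, np.ndarray]
    tissues: tuple[str, ...] = TISSUES

    def stack(self) -> np.ndarray:
        return np.stack([self.p[t] for t in self.tissues])


@dataclasses.dataclass
class VolumeReport:
    """Per-tissue voxel counts and volumes (mm^3).

    Soft volume integrates the partial-volume fractions; hard volume
    counts argmax-labelled voxels. Soft volumes sum to the total
    foreground volume by construction.
    """

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def label(fused: FusedMapSet) -> LabelMap:
    """Maximum-possibility labelling.

    Ties are broken by the fixed tissue priority (canonical order, CSF
    first) and counted; voxels where every possibility is zero become
    background.
    """
    stack = fused.stack()
    labels = np.argmax(stack, axis=0)          # first max wins the tie
    sorted_desc = np.sort(stack, axis=0)
    n_ties = int(((sorted_desc[-1] == sorted_desc[-2]) &
                  (sorted_desc[-1] > 0)).sum())
    background = np.all(stack <= 0, axis=0)
    labels = np.where(background, BACKGROUND_LABEL, labels)
    return LabelMap(labels=labels, tissues=fused.tissues, n_ties=n_ties)


def partial_volumes(fused: FusedMapSet) -> PartialVolumeSet:
    """Normalise possibility degrees into partial-volume fractions:
    p_T(v) = pi_T(v) / sum_i pi_i(v); background voxels get all zeros."""
    stack = fused.stack()
    total = stack.sum(axis=0)
    safe = np.where(total > 0, total, 1.0)
    frac = np.where(total > 0, stack / safe, 0.0)
    return PartialVolumeSet(
        p={t: frac[i] for i, t in enumerate(fused.tissues)},
        tissues=fused.tissues,
    )


def synthesize(fused: FusedMapSet | PartialVolumeSet,
               centroids: np.ndarray) -> ImageVolume:
    """Synthesis image: v = sum_T b_T p_T(v), with b_T the mean
    functional activity of tissue T (the functional-modality cluster
    centroids). Linear in the centroid vector; output values stay
    within [min b, max b] on foreground."""
    pv = fused if isinstance(fused, PartialVolumeSet) else partial_volumes(fused)
    b = np.ravel(np.asarray(centroids, dtype=float))
    if len(b) != len(pv.tissues):
        raise ValueError("one centroid per tissue required")
    data = np.tensordot(b, pv.stack(), axes=(0, 0))
    return ImageVolume(data=data, modality="functional")


def quantify(pv: PartialVolumeSet, labels: LabelMap,
             voxel_size: tuple[float, ...] | float = 1.0) -> VolumeReport:
    """Per-tissue volumetry from fractions and hard labels."""
    vv = float(np.prod(voxel_size)) if np.ndim(voxel_size) else float(voxel_size)
    rows = []
    for i, t in enumerate(pv.tissues):
        frac = pv.p[t]
        hard = int((labels.labels == i).sum())
        rows.append({
            "tissue": t,
            "voxel_count": hard,
            "soft_volume_mm3": float(frac.sum() * vv),
            "hard_volume_mm3": float(hard * vv),
        })
    return VolumeReport(table=pd.DataFrame(rows))


def extract_features(pv: PartialVolumeSet, synthesis: ImageVolume,
                     labels: LabelMap) -> np.ndarray:
    """Subject-level feature vector for classification.

    Default features: per-tissue soft volume fractions (3) plus
    per-tissue mean synthesis intensity (3). Tissues absent from the
    label map contribute a zero mean.
    """
    stack = pv.stack()
    total = stack.sum()
    fractions = stack.reshape(len(pv.tissues), -1).sum(axis=1) / max(total, 1e-30)
    means = []
    for i in range(len(pv.tissues)):
        sel = labels.labels == i
        means.append(float(synthesis.data[sel].mean()) if sel.any() else 0.0)
    return np.concatenate([fractions, means])
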
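"""Possibilistic fusion of per-tissue maps from two modalities.

Each tissue T has one possibility map per modality (anatomical and
functional), with per-voxel degrees in [0, 1]. A context-dependent
conjunctive operator combines them, steered by the agreement

    h = 1 - mean_v |pi1(v) - pi2(v)|

between the two maps: when the sources agree (h near 1) the operators
behave as a renormalised T-norm (conjunction), when they conflict the
operators fall back to a cautious disjunctive behaviour. CSF is the
exception: functional imaging carries no reliable CSF signal, so the
fused CSF map is the anatomical one verbatim.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .phantom import TISSUES

__all__ = ["PossibilityMapSet", "FusedMapSet", "agreement", "fop", "fuse_all",
           "EPS_H"]

#: floor applied to h before it divides a T-norm (h = 0 is otherwise undefined)
EPS_H = 1e-6


@dataclasses.dataclass
class PossibilityMapSet:
    """Per-tissue, per-modality possibility maps on one voxel grid."""

    anat: dict[str, np.ndarray]
    func: dict[str, np.ndarray]
    mask: np.ndarray | None = None
    tissues: tuple[str, ...] = TISSUES

    def __post_init__(self) -> None:
        shapes = {m[t].shape for m in (self.anat, self.func) for t in self.tissues}
        if len(shapes) != 1:
            raise ValueError("all maps must share one voxel grid")
        for maps in (self.anat, self.func):
            for t in self.tissues:
                v = np.asarray(maps[t], dtype=float)
                if v.min() < -1e-12 or v.max() > 1 + 1e-12:
                    raise ValueError("possibility degrees must lie in [0, 1]")
                maps[t] = np.clip(v, 0.0, 1.0)


@dataclasses.dataclass
class FusedMapSet:
    """Fused per-tissue maps plus the per-tissue agreement values."""

    maps: dict[str, np.ndarray]
    operator_id: int
    h_per_tissue: dict[str, float]
    mask: np.ndarray | None = None
    tissues: tuple[str, ...] = TISSUES

    def stack(self) -> np.ndarray:
        """(n_tissues, *grid) array in canonical tissue order."""
        return np.stack([self.maps[t] for t in self.tissues])


def agreement(pi1: np.ndarray, pi2: np.ndarray,
              mask: np.ndarray | None = None) -> float:
    """Agreement h = 1 - mean |pi1 - pi2| over the (masked) grid."""
    pi1 = np.asarray(pi1, dtype=float)
    pi2 = np.asarray(pi2, dtype=float)
    if pi1.shape != pi2.shape:
        raise ValueError("maps must share a grid")
    if mask is not None:
        pi1, pi2 = pi1[mask], pi2[mask]
    if pi1.size == 0:
        raise ValueError("cannot measure agreement on an empty grid")
    return float(1.0 - np.abs(pi1 - pi2).mean())


def fop(k: int, pi1: np.ndarray, pi2: np.ndarray, h: float) -> np.ndarray:
    """Apply context-dependent fusion operator ``k`` (1-4) voxel-wise.

    ``h`` is floored at :data:`EPS_H` before dividing; operators 1, 3
    and 4 can exceed 1 as written (renormalised T-norm when min > h), so
    the result is clamped back into [0, 1]. All four operators are
    symmetric in their map arguments and return the input map exactly
    when the two maps are identical (h = 1).
    """
    if k not in (1, 2, 3, 4):
        raise ValueError("fusion operator id must be in 1..4")
    if not 0.0 <= h <= 1.0:
        raise ValueError("agreement h must lie in [0, 1]")
    pi1 = np.asarray(pi1, dtype=float)
    pi2 = np.asarray(pi2, dtype=float)
    hh = max(h, EPS_H)
    lo = np.minimum(pi1, pi2)
    hi = np.maximum(pi1, pi2)
    if k == 1:
        out = np.maximum(lo / hh, 1.0 - h)
    elif k == 2:
        out = np.minimum(1.0, lo / hh + (1.0 - h))
    elif k == 3:
        out = lo + (1.0 - h)
    else:
        out = np.maximum(lo / hh, np.minimum(hi, 1.0 - h))
    return np.clip(out, 0.0, 1.0)


def fuse_all(maps: PossibilityMapSet, k: int = 4) -> FusedMapSet:
    """Fuse every tissue with operator ``k``; CSF passes through from
    the anatomical modality regardless of the functional map.

    The default operator is FOP4, the variant whose cautious branch
    retains the larger source when the maps conflict.
    """
    fused: dict[str, np.ndarray] = {}
    h_per_tissue: dict[str, float] = {}
    for t in maps.tissues:
        h = agreement(maps.anat[t], maps.func[t], maps.mask)
        h_per_tissue[t] = h
        if t == "CSF":
            fused[t] = np.asarray(maps.anat[t], dtype=float).copy()
        else:
            fused[t] = fop(k, maps.anat[t], maps.func[t], h)
    return FusedMapSet(maps=fused, operator_id=k, h_per_tissue=h_per_tissue,
                       mask=maps.mask, tissues=maps.tissues)
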
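"""Assembly of the final component set after swarm optimization.

The swarm's best mask is distilled into B1, the components it selected in
all three color channels (tri-channel consensus); B2 collects the top-m
components by l2 energy of their projected feature vectors; the final set
is the union B = B1 | B2, applied identically to every channel for
reconstruction.  B2 acts as a completion step: high-energy axes that the
sparsity-penalized swarm dropped in some channel are restored, so the
union can only lower the reconstruction error relative to either part.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rgb2dpca import ProjectionBasis, reconstruct, validate_mask

__all__ = [
    "IndexSet",
    "baseline_topk",
    "consensus_indices",
    "indices_to_mask",
    "l2_rank",
    "reconstruct_selected",
    "union_selection",
]


@dataclass(frozen=True)
class IndexSet:
    """A labelled set of component indices in [0, d)."""

    indices: frozenset[int]
    d: int
    label: str

    def __post_init__(self) -> None:
        bad = [i for i in self.indices if not 0 <= i < self.d]
        if bad:
            raise ValueError(f"indices out of range [0, {self.d}): {sorted(bad)}")

    def sorted(self) -> list[int]:
        return sorted(self.indices)

    def __len__(self) -> int:
        return len(self.indices)


def consensus_indices(gbest: np.ndarray) -> IndexSet:
    """B1: components the swarm selected in all three channels."""
    mask = validate_mask(gbest)
    keep = np.nonzero(mask.sum(axis=1) == 3)[0]
    return IndexSet(frozenset(int(j) for j in keep), d=mask.shape[0], label="B1")


def l2_rank(projections: np.ndarray, m: int) -> IndexSet:
    """B2: indices of the m components with largest l2 energy.

    ``projections`` is either one image's (H, d, 3) coefficient array or a
    stack of them (N, H, d, 3).  The energy of component j is the l2 norm
    of its coefficient column ||Y_j^c||_2, averaged over channels and,
    when a stack is given, over images — one modality-level ranking rather
    than per-image ones.  Ties break toward the lower index; m >= d
    returns every index.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    proj = np.asarray(projections, dtype=np.float64)
    if proj.ndim == 3:
        proj = proj[np.newaxis]
    if proj.ndim != 4 or proj.shape[3] != 3:
        raise ValueError(f"expected (H, d, 3) or (N, H, d, 3), got {proj.shape}")
    d = proj.shape[2]
    norms = np.sqrt(np.einsum("nhjc,nhjc->njc", proj, proj))  # (N, d, 3)
    energy = norms.mean(axis=(0, 2))  # (d,)
    if m >= d:
        return IndexSet(frozenset(range(d)), d=d, label="B2")
    # stable sort on negated energies -> descending with lower index winning ties
    order = np.argsort(-energy, kind="stable")
    return IndexSet(frozenset(int(j) for j in order[:m]), d=d, label="B2")


def union_selection(b1: IndexSet, b2: IndexSet) -> IndexSet:
    """B = B1 | B2."""
    if b1.d != b2.d:
        raise ValueError(f"index sets disagree on d: {b1.d} vs {b2.d}")
    return IndexSet(b1.indices | b2.indices, d=b1.d, label="B")


def baseline_topk(basis: ProjectionBasis, k: int) -> IndexSet:
    """Top-k eigenvalue baseline: since eigenvalues are sorted, {0..k-1}."""
    if not 1 <= k <= basis.dim:
        raise ValueError(f"k must be in [1, {basis.dim}], got {k}")
    return IndexSet(frozenset(range(k)), d=basis.dim, label=f"top{k}")


def indices_to_mask(b: IndexSet) -> np.ndarray:
    """Induce the (d, 3) mask selecting b's components on every channel."""
    mask = np.zeros((b.d, 3), dtype=np.uint8)
    mask[b.sorted(), :] = 1
    return mask


def reconstruct_selected(
    projection: np.ndarray, basis: ProjectionBasis, b: IndexSet
) -> np.ndarray:
    """Reconstruct from an index set (all channels): identical to the mask path."""
    if b.d != basis.dim:
        raise ValueError(f"index set d={b.d} does not match basis dim {basis.dim}")
    return reconstruct(projection, basis, indices_to_mask(b))
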
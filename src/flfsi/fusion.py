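"""Feature-level fusion of conventional and contrast-enhanced reconstructions.

Each modality's training stack is decomposed, its components selected
(either by the swarm pipeline or a fixed top-k eigenvalue cut), and each
image reconstructed from the selected components.  Paired reconstructions
are then blended pixelwise at the CEUS proportion x:

    F = x * ceus + (1 - x) * conv

Because reconstruction is linear in the kept feature vectors, blending the
two reconstructions is the same as blending their features under a shared
basis, so the convex pixel combination realizes feature-level fusion.
Selection runs once per modality on the whole training stack and the
resulting component set is applied to every image of that modality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from . import bpso, rgb2dpca, selection
from .rgb2dpca import ShapeError

__all__ = ["FusionSpec", "ModalityModel", "decompose_select", "fuse", "build_fused_dataset"]

#: Rec. 601 luma weights used for the grayscale baseline
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class FusionSpec:
    """Fusion configuration.

    x is the CEUS proportion in [0, 1]; mode selects the reconstruction
    family (``flfsi`` = swarm-selected RGB components, ``rgb_topk`` /
    ``gray_topk`` = top-k eigenvalue baselines on color / luma images);
    top_k is the baseline cut (160 in the reference configuration);
    selection_m is the size of the l2-energy completion set B2 (100 in the
    reference configuration; small synthetic problems use smaller values).
    """

    x: float = 0.2
    mode: Literal["flfsi", "rgb_topk", "gray_topk"] = "flfsi"
    top_k: int = 160
    selection_m: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.x <= 1.0:
            raise ValueError(f"x must be in [0, 1], got {self.x}")
        if self.mode not in ("flfsi", "rgb_topk", "gray_topk"):
            raise ValueError(f"unknown fusion mode {self.mode!r}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.selection_m < 0:
            raise ValueError("selection_m must be >= 0")


@dataclass
class ModalityModel:
    """Fitted decomposition and component selection for one modality."""

    basis: rgb2dpca.ProjectionBasis
    b1: selection.IndexSet | None
    b2: selection.IndexSet | None
    b: selection.IndexSet
    bpso_result: bpso.BPSOResult | None

    def reconstruct_stack(self, stack: np.ndarray) -> np.ndarray:
        stack = rgb2dpca.as_stack(stack)
        out = np.empty_like(stack)
        for i, img in enumerate(stack):
            proj = rgb2dpca.project(img, self.basis)
            out[i] = selection.reconstruct_selected(proj, self.basis, self.b)
        return out


def fuse(conv_recon: np.ndarray, ceus_recon: np.ndarray, spec: FusionSpec) -> np.ndarray:
    """Convex pixelwise blend F = x*ceus + (1-x)*conv.

    The endpoints are exact: x=0 returns conv_recon and x=1 returns
    ceus_recon without floating-point perturbation.
    """
    conv_recon = np.asarray(conv_recon, dtype=np.float64)
    ceus_recon = np.asarray(ceus_recon, dtype=np.float64)
    if conv_recon.shape != ceus_recon.shape:
        raise ShapeError(
            f"shape mismatch: conv {conv_recon.shape} vs ceus {ceus_recon.shape}"
        )
    if spec.x == 0.0:
        return conv_recon.copy()
    if spec.x == 1.0:
        return ceus_recon.copy()
    return spec.x * ceus_recon + (1.0 - spec.x) * conv_recon


def to_grayscale(stack: np.ndarray) -> np.ndarray:
    """Rec. 601 luma of each image, replicated back over the 3 channels."""
    stack = rgb2dpca.as_stack(stack)
    luma = np.einsum("nhwc,c->nhw", stack, LUMA_WEIGHTS)
    return np.repeat(luma[..., np.newaxis], 3, axis=3)


def decompose_select(
    stack: np.ndarray,
    spec: FusionSpec,
    bpso_config: bpso.BPSOConfig | None = None,
) -> ModalityModel:
    """Fit one modality: basis, then component selection per the fusion mode."""
    stack = rgb2dpca.as_stack(stack)
    basis = rgb2dpca.fit_basis(stack)
    if spec.mode == "flfsi":
        if bpso_config is None:
            bpso_config = bpso.BPSOConfig()
        result = bpso.run(stack, basis, bpso_config)
        b1 = selection.consensus_indices(result.gbest)
        projections = np.stack(
            [rgb2dpca.project(img, basis) for img in stack]
        )
        b2 = selection.l2_rank(projections, min(spec.selection_m, basis.dim))
        b = selection.union_selection(b1, b2)
        return ModalityModel(basis=basis, b1=b1, b2=b2, b=b, bpso_result=result)
    k = min(spec.top_k, basis.dim)
    b = selection.baseline_topk(basis, k)
    return ModalityModel(basis=basis, b1=None, b2=None, b=b, bpso_result=None)


def build_fused_dataset(
    conv_stack: np.ndarray,
    ceus_stack: np.ndarray,
    spec: FusionSpec,
    bpso_config: bpso.BPSOConfig | None = None,
    return_models: bool = False,
):
    """Full fusion pipeline over paired stacks.

    Modes: ``flfsi`` fits basis + swarm selection per modality and fuses
    the B-reconstructions; ``rgb_topk`` fuses top-k RGB reconstructions;
    ``gray_topk`` converts both stacks to luma first (the single-channel
    baseline), then proceeds as top-k.  Returns the fused (N, H, W, 3)
    stack, plus the two fitted :class:`ModalityModel` if requested.
    """
    conv_stack = rgb2dpca.as_stack(conv_stack)
    ceus_stack = rgb2dpca.as_stack(ceus_stack)
    if conv_stack.shape != ceus_stack.shape:
        raise ShapeError(
            f"stacks must be paired 1:1 with equal shapes: "
            f"{conv_stack.shape} vs {ceus_stack.shape}"
        )
    if spec.mode == "gray_topk":
        conv_stack = to_grayscale(conv_stack)
        ceus_stack = to_grayscale(ceus_stack)

    conv_cfg = bpso_config
    ceus_cfg = None
    if bpso_config is not None:
        # independent streams per modality, both derived from the config seed
        conv_cfg = _reseed(bpso_config, offset=0)
        ceus_cfg = _reseed(bpso_config, offset=1)
    conv_model = decompose_select(conv_stack, spec, conv_cfg)
    ceus_model = decompose_select(ceus_stack, spec, ceus_cfg)

    conv_recon = conv_model.reconstruct_stack(conv_stack)
    ceus_recon = ceus_model.reconstruct_stack(ceus_stack)
    fused = np.stack(
        [fuse(c, e, spec) for c, e in zip(conv_recon, ceus_recon)]
    )
    if return_models:
        return fused, conv_model, ceus_model
    return fused


def _reseed(config: bpso.BPSOConfig, offset: int) -> bpso.BPSOConfig:
    from dataclasses import replace

    seed = int(np.random.SeedSequence([config.seed, offset]).generate_state(1)[0] % (2**31))
    return replace(config, seed=seed)
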
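"""End-to-end convenience: masks in, labeled tree and territory map out."""

from __future__ import annotations

import numpy as np

from .arterytree import (
    ArteryTree,
    extract_tree,
    label_generations_and_segments,
    paint_vessel_mask,
    skeletonize_vessels,
)
from .territories import TerritoryMap, estimate_territories
from .volume import LabelVolume

__all__ = ["build_perfusion_model", "parenchyma_mask"]


def parenchyma_mask(
    kidney: LabelVolume, sinus_ucs: LabelVolume, vessels: LabelVolume
) -> LabelVolume:
    """Kidney minus sinus/collecting system minus vessel voxels."""
    kidney.require_aligned(sinus_ucs, "kidney/sinus")
    kidney.require_aligned(vessels, "kidney/vessels")
    m = kidney.binarize() & ~sinus_ucs.binarize() & ~vessels.binarize()
    return kidney.like(m.astype(np.int32))


def build_perfusion_model(
    kidney: LabelVolume,
    sinus_ucs: LabelVolume,
    vessels: LabelVolume,
    root_hint_mm,
    prune_mm: float = 2.0,
    segmental_generation: int = 1,
    metric: str = "euclidean",
) -> tuple[ArteryTree, TerritoryMap]:
    """Run the two-step perfusion model on segmentation masks.

    Step 1: skeletonize the vessels, root the tree at the hilum hint, label
    generations and group branches by segmental ancestor.  Step 2: assign
    every parenchyma voxel to its closest lobar-or-deeper vessel voxel, then
    merge lobar territories through the tree into segmental territories.

    If the tree has no generation beyond the segmental one (shallow
    segmentations), the segmental painting itself seeds the territories and
    the lobar map degenerates to the segmental map.
    """
    skel = skeletonize_vessels(vessels, prune_mm=prune_mm)
    tree = extract_tree(skel, root_hint_mm)
    tree = label_generations_and_segments(tree, segmental_generation)
    parenchyma = parenchyma_mask(kidney, sinus_ucs, vessels)
    if tree.lobar_ids():
        painted = paint_vessel_mask(vessels, tree, level="lobar")
        tmap = estimate_territories(parenchyma, painted, tree, metric=metric)
    else:
        painted = paint_vessel_mask(vessels, tree, level="segmental")
        identity = {int(s): int(s) for s in tree.segment_ids() or [1]}
        tmap = estimate_territories(parenchyma, painted, identity, metric=metric)
    return tree, tmap
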
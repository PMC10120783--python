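"""Data-driven cortical parcellation.

Randomized-SVD compression of the corrected movies, spatial ICA (JADE),
multi-stage z-threshold extraction of contiguous spatial domains,
vessel-pixel removal, and assignment of node identities against a
reference layout, with a rescue path for nodes whose ICs fail the main
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, label as cc_label
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator
from sklearn.utils.extmath import randomized_svd

from ._jade import jade

#: 4-connectivity structuring element for "contiguous".
FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)

#: IC-thresholding constants.
Z_PRIMARY = 3.5
Z_FALLBACK = 2.5
Z_RETHRESH = 1.0
MIN_DOMAIN_PX = 150
MAX_DOMAIN_PX = 5000


@dataclass
class IcMap:
    """One spatial independent component, z-scored over in-mask pixels."""

    weights: np.ndarray  # (H, W)
    ic_index: int
    mouse_id: str = ""


@dataclass
class NodeDomain:
    """A thresholded IC domain serving as one network node."""

    pixels: np.ndarray  # bool (H, W); may be fragmented after vessel removal
    weights: np.ndarray  # (H, W), zero outside pixels
    source_ic_index: int
    node_id: int = -1
    homolog_id: int = -1
    hemisphere: str = "?"

    @property
    def size_px(self) -> int:
        return int(self.pixels.sum())


def svd_compress(movie: np.ndarray, n_components: int = 500,
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Randomized SVD of the frames x pixels movie matrix.

    Returns (U, S, Vt) with Vt rows the spatial components.
    """
    movie = np.asarray(movie)
    if movie.ndim == 3:
        movie = movie.reshape(movie.shape[0], -1)
    if n_components > min(movie.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    U, S, Vt = randomized_svd(movie, n_components=n_components, n_iter=4,
                              random_state=seed)
    return U, S, Vt


def spatial_ica(S: np.ndarray, Vt: np.ndarray, image_shape: tuple[int, int],
                n_ics: int = 100, mask: np.ndarray | None = None,
                seed: int = 0, mouse_id: str = "") -> list[IcMap]:
    """Spatial ICA of the compressed movie: IC maps from JADE unmixing.

    The top ``n_ics`` scaled spatial singular vectors are unmixed by
    fourth-order-cumulant joint diagonalization; each map is z-scored
    over the in-mask pixels and sign-flipped so its maximum-|z| pixel is
    positive.  Deterministic for fixed inputs.
    """
    if n_ics > Vt.shape[0]:
        raise ValueError("n_ics exceeds compression rank")
    Y = S[:n_ics, None] * Vt[:n_ics]  # (n_ics, n_pixels)
    if mask is not None:
        flat_mask = np.asarray(mask, bool).ravel()
        B = jade(Y[:, flat_mask])
        maps_in = B @ Y[:, flat_mask]
        maps = np.zeros((n_ics, Y.shape[1]))
        maps[:, flat_mask] = maps_in
    else:
        flat_mask = np.ones(Y.shape[1], bool)
        B = jade(Y)
        maps = B @ Y
    out = []
    for i in range(n_ics):
        vals = maps[i, flat_mask]
        z = np.zeros(Y.shape[1])
        z[flat_mask] = (vals - vals.mean()) / (vals.std() or 1.0)
        if z[np.abs(z).argmax()] < 0:
            z = -z
        out.append(IcMap(z.reshape(image_shape), i, mouse_id))
    # deterministic ordering: by descending peak |z|
    out.sort(key=lambda ic: -np.abs(ic.weights).max())
    for rank, ic in enumerate(out):
        ic.ic_index = rank
    return out


def _components(mask_img: np.ndarray, min_px: int) -> list[np.ndarray]:
    lab, n = cc_label(mask_img, structure=FOUR_CONN)
    comps = []
    for k in range(1, n + 1):
        comp = lab == k
        if comp.sum() >= min_px:
            comps.append(comp)
    return comps


def threshold_ic(ic: IcMap, min_px: int = MIN_DOMAIN_PX, max_px: int = MAX_DOMAIN_PX,
                 z_primary: float = Z_PRIMARY, z_fallback: float = Z_FALLBACK,
                 z_rethresh: float = Z_RETHRESH) -> list[NodeDomain]:
    """Threshold one z-scored IC into candidate spatial domains.

    In order: (1) zero pixels with z below 3.5 and keep 4-connected
    components of at least 150 pixels; (2) if none survive, re-threshold
    at 2.5; (3) any surviving component larger than 5000 pixels is
    re-z-scored within the component and cut at the new z of 1.0, then
    components re-extracted; (4) every surviving component of at least
    150 pixels becomes its own domain.  An empty list is a valid outcome.
    """
    z = ic.weights
    comps = _components(z >= z_primary, min_px)
    if not comps:
        comps = _components(z >= z_fallback, min_px)
    final: list[np.ndarray] = []
    for comp in comps:
        if comp.sum() > max_px:
            vals = z[comp]
            re_z = (z - vals.mean()) / (vals.std() or 1.0)
            final.extend(_components(comp & (re_z >= z_rethresh), min_px))
        else:
            final.append(comp)
    return [
        NodeDomain(pixels=comp, weights=np.where(comp, z, 0.0),
                   source_ic_index=ic.ic_index)
        for comp in final
    ]


def remove_vessel_pixels(domain: NodeDomain, vessel_mask: np.ndarray) -> NodeDomain | None:
    """Strip blood-vessel pixels from a domain.

    The result may be fragmented (non-contiguous), which is allowed.
    A domain emptied by the vessel mask is discarded (returns None).
    """
    vessel_mask = np.asarray(vessel_mask, bool)
    if vessel_mask.shape != domain.pixels.shape:
        raise ValueError("vessel mask shape mismatch")
    keep = domain.pixels & ~vessel_mask
    if not keep.any():
        warnings.warn(f"domain from IC {domain.source_ic_index} fully covered by vessels; discarded")
        return None
    return NodeDomain(keep, np.where(keep, domain.weights, 0.0), domain.source_ic_index,
                      domain.node_id, domain.homolog_id, domain.hemisphere)


def reject_artifact_domains(domains: list[NodeDomain], vessel_mask: np.ndarray | None,
                            brain_mask: np.ndarray | None,
                            vessel_overlap_max: float = 0.5,
                            border_fraction_max: float = 0.3) -> list[NodeDomain]:
    """Drop artifact-like domains: mostly-vessel domains and domains
    hugging the brain-mask border on a large share of their perimeter."""
    kept = []
    for d in domains:
        if vessel_mask is not None:
            if (d.pixels & vessel_mask).sum() > vessel_overlap_max * d.size_px:
                continue
        if brain_mask is not None:
            interior = d.pixels & ~binary_dilation(~d.pixels, structure=FOUR_CONN)
            perim = d.pixels & ~interior
            touching = perim & binary_dilation(~brain_mask, structure=FOUR_CONN)
            if perim.sum() and touching.sum() > border_fraction_max * perim.sum():
                continue
        kept.append(d)
    return kept


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = (a & b).sum()
    denom = a.sum() + b.sum()
    return 2.0 * inter / denom if denom else 0.0


def reference_footprints(node_maps: np.ndarray, level: float = 0.25) -> np.ndarray:
    """Boolean footprints of reference node weight maps (per-node threshold
    at ``level`` of each map's peak)."""
    peaks = node_maps.reshape(node_maps.shape[0], -1).max(axis=1)
    return node_maps > level * peaks[:, None, None]


def assign_node_ids(domains: list[NodeDomain], reference, min_dice: float = 0.05,
                    level: float = 0.25) -> tuple[list[NodeDomain], list[int]]:
    """Optimal one-to-one matching of candidate domains to reference nodes.

    ``reference`` is a GroundTruthParcellation-like object with
    ``node_maps`` (n_nodes, H, W), ``homolog_pairs`` and ``image_shape``.
    Returns the assigned domains (node_id/homolog/hemisphere filled) and
    the list of unmatched reference node ids.  Ties are broken by the
    optimal assignment itself; among equal-cost assignments the lower
    ic_index wins through the deterministic candidate ordering.
    """
    foots = reference_footprints(reference.node_maps, level)
    n_ref = foots.shape[0]
    domains = sorted(domains, key=lambda d: d.source_ic_index)
    if not domains:
        return [], list(range(1, n_ref + 1))
    dice = np.zeros((len(domains), n_ref))
    for i, d in enumerate(domains):
        for j in range(n_ref):
            dice[i, j] = _dice(d.pixels, foots[j])
    rows, cols = linear_sum_assignment(-dice)
    homolog_of = {}
    for pair_idx, (lid, rid) in enumerate(reference.homolog_pairs, start=1):
        homolog_of[lid] = (pair_idx, "L")
        homolog_of[rid] = (pair_idx, "R")
    midline = reference.image_shape[1] / 2.0
    assigned, matched_ref = [], set()
    for i, j in zip(rows, cols):
        if dice[i, j] <= min_dice:
            continue
        d = domains[i]
        node_id = j + 1
        pair_idx, hemi_ref = homolog_of.get(node_id, (-1, "?"))
        cx = np.argwhere(d.pixels)[:, 1].mean()
        hemi = "L" if cx < midline else "R"
        assigned.append(NodeDomain(d.pixels, d.weights, d.source_ic_index,
                                   node_id, pair_idx, hemi if pair_idx > 0 else hemi_ref))
        matched_ref.add(node_id)
    unmatched = [nid for nid in range(1, n_ref + 1) if nid not in matched_ref]
    assigned.sort(key=lambda d: d.node_id)
    return assigned, unmatched


def rescue_missing_nodes(ics: list[IcMap], unmatched: list[int], reference,
                         min_overlap: float = 0.15, dilate: int = 3,
                         level: float = 0.25, min_px: int = MIN_DOMAIN_PX,
                         max_px: int = MAX_DOMAIN_PX) -> list[NodeDomain]:
    """Recover reference nodes whose ICs failed the main threshold.

    For each unmatched reference node, the raw IC with the highest
    positive-weight mass inside the node's footprint is cropped to a
    dilated footprint and re-thresholded with the 2.5 fallback threshold.
    Nodes with no sufficiently overlapping IC are reported missing.
    """
    foots = reference_footprints(reference.node_maps, level)
    homolog_of = {}
    for pair_idx, (lid, rid) in enumerate(reference.homolog_pairs, start=1):
        homolog_of[lid] = (pair_idx, "L")
        homolog_of[rid] = (pair_idx, "R")
    rescued = []
    for nid in unmatched:
        foot = foots[nid - 1]
        scores = []
        for ic in ics:
            pos = np.clip(ic.weights, 0, None)
            total = pos.sum()
            scores.append((pos[foot].sum() / total) if total > 0 else 0.0)
        best = int(np.argmax(scores))
        if scores[best] < min_overlap:
            warnings.warn(f"reference node {nid}: no IC with sufficient overlap; missing")
            continue
        crop = binary_dilation(foot, iterations=dilate)
        cropped = IcMap(np.where(crop, ics[best].weights, 0.0), ics[best].ic_index)
        cands = threshold_ic(cropped, min_px=min_px, max_px=max_px,
                             z_primary=Z_FALLBACK)
        if not cands:
            warnings.warn(f"reference node {nid}: rescue thresholding empty; missing")
            continue
        cands.sort(key=lambda d: -_dice(d.pixels, foot))
        d = cands[0]
        pair_idx, hemi = homolog_of.get(nid, (-1, "?"))
        rescued.append(NodeDomain(d.pixels, d.weights, d.source_ic_index, nid, pair_idx, hemi))
    return rescued


class IcaParcellation(BaseEstimator):
    """SVD -> spatial ICA -> threshold -> node-assignment parcellation.

    Parameters
    ----------
    n_svd : randomized-SVD compression rank (500 by default).
    n_ics : number of independent components (100 by default).
    min_px, max_px : admissible domain size range in pixels.
    seed : randomized-SVD seed (the ICA itself is deterministic).

    Attributes (after ``fit``)
    --------------------------
    ics_ : list of IcMap
    nodes_ : list of assigned NodeDomain (sorted by node_id)
    missing_nodes_ : reference node ids not recovered for this mouse
    node_table_ : DataFrame (node_id, homolog_id, hemisphere, size_px)
    """

    def __init__(self, n_svd: int = 500, n_ics: int = 100,
                 min_px: int = MIN_DOMAIN_PX, max_px: int = MAX_DOMAIN_PX,
                 min_dice: float = 0.05, seed: int = 0):
        self.n_svd = n_svd
        self.n_ics = n_ics
        self.min_px = min_px
        self.max_px = max_px
        self.min_dice = min_dice
        self.seed = seed

    def fit(self, movie: np.ndarray, reference,
            mask: np.ndarray | None = None,
            vessel_mask: np.ndarray | None = None,
            image_shape: tuple[int, int] | None = None,
            mouse_id: str = "") -> "IcaParcellation":
        movie = np.asarray(movie)
        if movie.ndim == 3:
            image_shape = movie.shape[1:]
            movie = movie.reshape(movie.shape[0], -1)
        if image_shape is None:
            raise ValueError("image_shape required for flat movie input")
        n_svd = min(self.n_svd, min(movie.shape))
        _, S, Vt = svd_compress(movie, n_svd, self.seed)
        self.ics_ = spatial_ica(S, Vt, image_shape, min(self.n_ics, n_svd),
                                mask, self.seed, mouse_id)
        candidates: list[NodeDomain] = []
        for ic in self.ics_:
            candidates.extend(threshold_ic(ic, self.min_px, self.max_px))
        candidates = reject_artifact_domains(candidates, vessel_mask, mask)
        if vessel_mask is not None:
            cleaned = [remove_vessel_pixels(d, vessel_mask) for d in candidates]
            candidates = [d for d in cleaned if d is not None]
        assigned, unmatched = assign_node_ids(candidates, reference, self.min_dice)
        rescued = rescue_missing_nodes(self.ics_, unmatched, reference,
                                       min_px=self.min_px, max_px=self.max_px) \
            if unmatched else []
        if vessel_mask is not None and rescued:
            rescued = [remove_vessel_pixels(d, vessel_mask) for d in rescued]
            rescued = [d for d in rescued if d is not None]
        self.nodes_ = sorted(assigned + rescued, key=lambda d: d.node_id)
        got = {d.node_id for d in self.nodes_}
        self.missing_nodes_ = [nid for nid in range(1, reference.node_maps.shape[0] + 1)
                               if nid not in got]
        self.node_table_ = pd.DataFrame(
            [{"node_id": d.node_id, "homolog_id": d.homolog_id,
              "hemisphere": d.hemisphere, "size_px": d.size_px}
             for d in self.nodes_]
        )
        return self

    def labeled_map(self) -> np.ndarray:
        """Pixel map of node ids (0 = background)."""
        shape = self.nodes_[0].pixels.shape
        out = np.zeros(shape, int)
        for d in self.nodes_:
            out[d.pixels] = d.node_id
        return out
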
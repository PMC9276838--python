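"""Detection of deployed electrode tines in CT-like volumes.

Deployed tines show up as curvilinear metal-density structures; they can
deflect up to ~5 mm from their ideal umbrella positions, so the deployed
geometry must be measured, not assumed.  The detector thresholds at a
metal-range intensity, keeps the connected component containing the tip
seed, skeletonises it, and walks the skeleton from the tip to each branch
endpoint, ordering tines by azimuth about the shaft axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .geometry import ElectrodeSpec, _polyline_distance


class TineDetectionError(RuntimeError):
    pass


@dataclass
class TineDetection:
    tines: List[np.ndarray]          # ordered (k,3) mm polylines, tip first
    n_expected: Optional[int]
    deflections_mm: Optional[np.ndarray] = None   # vs an ideal spec, per tine
    warning: Optional[str] = None

    @property
    def n_detected(self) -> int:
        return len(self.tines)


def detect_tines(volume: np.ndarray, voxel_spacing, tip_seed_mm, *,
                 origin=(0.0, 0.0, 0.0), metal_threshold: float = 1500.0,
                 n_expected: Optional[int] = None,
                 ideal: Optional[ElectrodeSpec] = None,
                 min_tine_length_mm: float = 3.0) -> TineDetection:
    """Extract tine centerlines from a CT-like intensity volume.

    Parameters
    ----------
    volume : (nx, ny, nz) array
        Intensities; metal is above ``metal_threshold``.
    voxel_spacing : float or (3,) sequence, mm
    tip_seed_mm : (3,) point near the electrode tip, in mm
    ideal : optional ElectrodeSpec
        When given, each detected tine is matched to the nearest ideal tine
        by endpoint azimuth and its deflection (max distance from measured
        centerline to the ideal tine polyline) is reported in mm.
    """
    vol = np.asarray(volume, float)
    spacing = np.broadcast_to(np.asarray(voxel_spacing, float), (3,)).copy()
    origin = np.asarray(origin, float)
    seed = np.asarray(tip_seed_mm, float)

    mask = vol > metal_threshold
    if not mask.any():
        raise TineDetectionError(
            f"no metal-range voxels above {metal_threshold}")
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    seed_idx = np.round((seed - origin) / spacing).astype(int)
    seed_idx = np.clip(seed_idx, 0, np.array(vol.shape) - 1)
    lab = labels[tuple(seed_idx)]
    if lab == 0:
        # search a small neighbourhood around the seed
        metal_idx = np.argwhere(mask)
        d = np.linalg.norm((metal_idx - seed_idx) * spacing, axis=1)
        if d.min() > 10.0:
            raise TineDetectionError(
                "no metal-range voxels within 10 mm of the tip seed")
        lab = labels[tuple(metal_idx[np.argmin(d)])]
    comp = labels == lab

    skel = skeletonize(comp)
    if not skel.any():
        skel = comp
    voxels = np.argwhere(skel)
    pos_mm = origin + voxels * spacing

    G = _skeleton_graph(voxels, spacing)
    tip_node = int(np.argmin(np.linalg.norm(pos_mm - seed, axis=1)))
    # path from tip to every endpoint = one candidate tine each
    lengths, paths = nx.single_source_dijkstra(G, tip_node, weight="weight")
    endpoints = [n for n in G.nodes
                 if G.degree[n] == 1 and n != tip_node and n in lengths]
    tines = []
    for ep in sorted(endpoints, key=lambda n: -lengths[n]):
        if lengths[ep] < min_tine_length_mm:
            continue
        tines.append(pos_mm[paths[ep]])
    if not tines:
        raise TineDetectionError("skeleton has no branches long enough "
                                 "to be tines")
    tines = _order_by_azimuth(tines, seed)

    warning = None
    if n_expected is not None and len(tines) < n_expected:
        warning = (f"detected {len(tines)} tines, expected {n_expected}; "
                   f"returning partial result")

    deflections = None
    if ideal is not None:
        deflections = _deflections(tines, ideal)
    return TineDetection(tines=tines, n_expected=n_expected,
                         deflections_mm=deflections, warning=warning)


def _skeleton_graph(voxels: np.ndarray, spacing: np.ndarray) -> nx.Graph:
    """26-connectivity graph over skeleton voxels, edge weight = mm length."""
    index = {tuple(v): i for i, v in enumerate(voxels)}
    G = nx.Graph()
    G.add_nodes_from(range(len(voxels)))
    offsets = [np.array(o) for o in np.ndindex(3, 3, 3)
               if o != (1, 1, 1)]
    for i, v in enumerate(voxels):
        for off in offsets:
            j = index.get(tuple(v + off - 1))
            if j is not None and j > i:
                w = float(np.linalg.norm((off - 1) * spacing))
                G.add_edge(i, j, weight=w)
    return G


def _order_by_azimuth(tines, seed):
    def azimuth(path):
        rel = path[-1] - seed
        return np.arctan2(rel[1], rel[0])
    return sorted(tines, key=azimuth)


def _deflections(tines, ideal: ElectrodeSpec) -> np.ndarray:
    """Per-detected-tine deflection: distance of the measured distal end
    from the nearest ideal tine curve (tines bend most at their tips, and
    the endpoint is insensitive to skeletonisation jitter along the stem)."""
    out = np.empty(len(tines))
    for i, meas in enumerate(tines):
        end = meas[-1][None, :]
        out[i] = min(float(_polyline_distance(end, np.asarray(ref))[0])
                     for ref in ideal.tine_paths)
    return out
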
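"""Needle-level structure analysis of crystallisation fingerprints.

The dendritic pattern is binarised inside ROI 0-90 % of the plate radius,
thinned to a one-pixel skeleton, and decomposed into *needles*: maximal
skeleton paths between nodes (branch points or endpoints).  Three derived
counts carry the analysis weight:

* ``lend`` — number of needle end-points (degree-1 skeleton pixels);
* ``l220`` — number of needles with length in [19.2, 22.0) px;
* ``l250`` — number of needles with length >= 22.0 px.

Lengths accumulate inter-pixel steps (1 for 4-neighbour moves, sqrt(2) for
diagonal moves); widths are the medial-axis estimate (twice the Euclidean
distance transform sampled along the path, averaged per needle).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_local
from skimage.morphology import skeletonize

from .synthesis import FingerprintImage
from .texture import RegionOfInterest, roi_mask

#: defining bin edges of the two named length variables
L220_LO = 19.2
L220_HI = 22.0
N_BINS = 15

STRUCTURE_ROI = RegionOfInterest(0.0, 90.0)


class StructureError(ValueError):
    pass


def length_bin_edges(n_bins: int = N_BINS, lo: float = L220_LO,
                     hi: float = L220_HI) -> np.ndarray:
    """Geometric 15-bin edge vector anchored on the two defining edges.

    All bins share the relative width r = hi/lo of the [19.2, 22) bin:
    the 13 lower-bin edges are e_k = lo * r**(k - 13) ascending to lo,
    followed by the two defining edges and +inf for the open top bin.
    """
    r = hi / lo
    edges = [0.0]
    edges += [lo * r ** (k - (n_bins - 2)) for k in range(1, n_bins - 1)]
    edges += [hi, math.inf]
    return np.asarray(edges)


def bin_names(edges: np.ndarray, prefix: str = "l") -> list:
    """Column names encode the bin's upper edge in tenths of a pixel;
    the open top bin keeps the conventional 250 label."""
    names = []
    for k in range(len(edges) - 2):
        names.append(f"{prefix}{int(round(10 * edges[k + 1])):03d}")
    names.append(f"{prefix}250")
    return names


LENGTH_EDGES = length_bin_edges()
LENGTH_NAMES = bin_names(LENGTH_EDGES)          # ... l192, l220, l250
WIDTH_EDGES = np.concatenate(([0.0], LENGTH_EDGES[1:-1] / 4.0, [math.inf]))
WIDTH_NAMES = bin_names(WIDTH_EDGES, prefix="w")


@dataclass(frozen=True)
class NeedleSegment:
    """Maximal skeleton path between two nodes."""

    path: tuple          # ordered (row, col) pixels
    length: float        # step-sum: 1 per axial move, sqrt(2) per diagonal
    mean_width: float    # 2 x distance-transform, averaged along the path


@dataclass(frozen=True)
class StructureFeatures:
    lend: int
    length_bins: np.ndarray
    width_bins: np.ndarray
    n_segments: int

    def as_row(self, plate_id: "str | None" = None) -> dict:
        row = {} if plate_id is None else {"plate_id": plate_id}
        row["lend"] = self.lend
        row.update(dict(zip(LENGTH_NAMES, (int(c) for c in self.length_bins))))
        row.update(dict(zip(WIDTH_NAMES, (int(c) for c in self.width_bins))))
        return row


def dump_bin_edges(path) -> None:
    """Sidecar provenance file with the exact bin edge vectors."""
    doc = {
        "length_edges": [e if math.isfinite(e) else "inf" for e in LENGTH_EDGES],
        "length_names": LENGTH_NAMES,
        "width_edges": [e if math.isfinite(e) else "inf" for e in WIDTH_EDGES],
        "width_names": WIDTH_NAMES,
        "convention": "right-open [lo, hi) except the top bin",
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def binarise(image: FingerprintImage, roi: RegionOfInterest = STRUCTURE_ROI,
             block_size: "int | None" = None, offset: float = -10.0) -> np.ndarray:
    """Local-threshold foreground map of the needle pattern inside the ROI.

    Adaptive (Gaussian-weighted local mean) thresholding keeps the map
    robust against smooth background gradients such as illumination ramps;
    the default window is plate_radius / 8.  Returns a boolean map; an
    empty foreground produces a warning, not an error.
    """
    if block_size is None:
        block_size = max(int(image.plate_radius / 8), 3)
    if block_size % 2 == 0:
        block_size += 1
    pixels = image.pixels.astype(float)
    thresh = threshold_local(pixels, block_size=block_size, method="gaussian",
                             offset=offset)
    fg = (pixels > thresh) & roi_mask(image, roi)
    if not fg.any():
        warnings.warn("empty foreground: structure features will be zero",
                      stacklevel=2)
    return fg


def skeletonise(binary: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning to a 1-px, 8-connected skeleton."""
    return skeletonize(binary.astype(bool))


_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]


def neighbour_degree(skeleton: np.ndarray) -> np.ndarray:
    """8-neighbour count of every skeleton pixel (0 elsewhere)."""
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    deg = ndimage.convolve(skeleton.astype(int), kernel, mode="constant")
    return np.where(skeleton, deg, 0)


def endpoints(skeleton: np.ndarray) -> np.ndarray:
    """Boolean map of degree-1 skeleton pixels."""
    return neighbour_degree(skeleton) == 1


def decompose_needles(skeleton: np.ndarray,
                      width_map: "np.ndarray | None" = None) -> list:
    """Split the skeleton into maximal node-to-node paths.

    Nodes are pixels whose 8-neighbour degree differs from 2 (endpoints
    and branch points).  Every skeleton edge belongs to exactly one
    segment; branch pixels are shared between segments.  Pure cycles
    (every pixel degree 2) yield one closed segment with no nodes.
    """
    coords = np.argwhere(skeleton)
    pixel_set = set(map(tuple, coords))
    deg = neighbour_degree(skeleton)

    def neighbours(px):
        r, c = px
        return [(r + dr, c + dc) for dr, dc in _NEIGHBOURS
                if (r + dr, c + dc) in pixel_set]

    def step_len(a, b):
        return math.sqrt(2) if (a[0] != b[0] and a[1] != b[1]) else 1.0

    nodes = {tuple(px) for px in coords if deg[tuple(px)] != 2}
    visited_edges = set()
    segments = []

    def trace(start, first):
        """Walk from node `start` through `first` until the next node."""
        path = [start, first]
        length = step_len(start, first)
        visited_edges.add(frozenset((start, first)))
        prev, cur = start, first
        while cur not in nodes:
            nxt = [n for n in neighbours(cur) if n != prev
                   and frozenset((cur, n)) not in visited_edges]
            if not nxt:
                break  # isolated loop end or single-pixel stub
            # prefer continuing away from the previous pixel's other
            # neighbours to avoid cutting corners at diagonal contacts
            n = nxt[0]
            visited_edges.add(frozenset((cur, n)))
            length += step_len(cur, n)
            path.append(n)
            prev, cur = cur, n
        return path, length

    for node in sorted(nodes):
        for nb in neighbours(node):
            if frozenset((node, nb)) in visited_edges:
                continue
            path, length = trace(node, nb)
            segments.append((tuple(path), length))

    # remaining unvisited pixels belong to pure cycles
    in_segment = {px for path, _ in segments for px in path}
    for px in sorted(pixel_set - in_segment - nodes):
        if any(frozenset((px, n)) in visited_edges for n in neighbours(px)):
            continue
        nbs = neighbours(px)
        if not nbs:
            segments.append(((px,), 0.0))
            continue
        path, length = trace(px, nbs[0])
        # close the cycle if it returned adjacent to the start
        if path[-1] != px and px in neighbours(path[-1]):
            length += step_len(path[-1], px)
            visited_edges.add(frozenset((path[-1], px)))
        segments.append((tuple(path), length))

    # isolated single pixels (degree 0) are their own segments
    for node in sorted(nodes):
        if deg[node] == 0:
            segments.append(((node,), 0.0))

    out = []
    for path, length in segments:
        if width_map is not None:
            widths = [2.0 * width_map[px] for px in path]
            mean_width = float(np.mean(widths)) if widths else 0.0
        else:
            mean_width = 1.0
        out.append(NeedleSegment(path=path, length=length, mean_width=mean_width))
    return out


def structure_features(segments: list, skeleton: np.ndarray,
                       min_length: float = 2.0,
                       length_edges: np.ndarray = LENGTH_EDGES,
                       width_edges: np.ndarray = WIDTH_EDGES) -> StructureFeatures:
    """Bin needle lengths and widths; count skeleton endpoints.

    Segments shorter than ``min_length`` px are treated as thinning spurs
    and pruned before binning.  Bins are right-open [lo, hi) except the
    open top bin, so a needle of length exactly 22.0 px counts in l250.
    """
    lend = int(endpoints(skeleton).sum())
    kept = [s for s in segments if s.length >= min_length]
    lengths = np.array([s.length for s in kept], dtype=float)
    widths = np.array([s.mean_width for s in kept], dtype=float)
    # np.digitize with right=False gives right-open bins
    lbins = np.bincount(np.digitize(lengths, length_edges[1:-1]), minlength=N_BINS)
    wbins = np.bincount(np.digitize(widths, width_edges[1:-1]), minlength=N_BINS)
    return StructureFeatures(lend=lend, length_bins=lbins[:N_BINS],
                             width_bins=wbins[:N_BINS], n_segments=len(kept))


def structure_features_for_image(image: FingerprintImage,
                                 roi: RegionOfInterest = STRUCTURE_ROI,
                                 min_length: float = 2.0) -> StructureFeatures:
    """Full chain: binarise, skeletonise, decompose, bin."""
    binary = binarise(image, roi)
    skel = skeletonise(binary)
    width_map = ndimage.distance_transform_edt(binary)
    segments = decompose_needles(skel, width_map=width_map)
    return structure_features(segments, skel, min_length=min_length)
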
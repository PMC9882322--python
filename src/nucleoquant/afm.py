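"""AFM height-map analysis: molecule segmentation, contour tracing, volumes
and bound-protein stoichiometry.

The analysis chain mirrors how tapping-mode AFM images of surface-deposited
DNA are quantified: molecules are segmented by a height threshold above the
mica background, each molecule is reduced to a one-pixel skeleton that is
decomposed at branch points into segments, contour lengths are summed with
(rx, ry, sqrt(rx^2+ry^2)) step weights, and molecular volumes are pixel area
times summed height excess over the background. Comparing mean volumes of
protein-bound and bare DNA against the reference volume of a single protein
complex yields the average number of complexes per binding site:

    n_bound = V_d / (V_p * N_p)

where ``V_d`` is the mean volume difference between bound and bare molecules,
``V_p`` the single-complex volume (from mass and an average protein density,
1.44 g/cm^3 by default) and ``N_p`` the mean number of particles per molecule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology

from .errors import BackgroundEstimationError, ParameterError, PathError

AVOGADRO = 6.02214076e23

__all__ = [
    "HeightMap",
    "MoleculeTrace",
    "ParticleRecord",
    "StoichiometryResult",
    "estimate_background",
    "segment_molecules",
    "skeletonize_and_decompose",
    "contour_length",
    "molecule_volume",
    "detect_bound_particles",
    "protein_reference_volume",
    "bound_trimer_count",
    "summarize_scene",
    "analyze_height_map",
]


@dataclass
class HeightMap:
    """Calibrated 2D topography grid.

    Heights are in nm above an arbitrary zero reference; ``rx``/``ry`` are the
    pixel sizes in nm along columns and rows. Pixel indices are row-major and
    0-based with coordinates taken at pixel centers.
    """

    grid: np.ndarray
    rx: float = 1.0
    ry: float = 1.0
    background: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ParameterError("height map grid must be 2D")
        if not (self.rx > 0 and self.ry > 0):
            raise ParameterError("pixel resolutions rx, ry must be positive")
        if not np.all(np.isfinite(self.grid)):
            raise ParameterError("height map contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass
class MoleculeTrace:
    """One segmented DNA molecule and its skeleton decomposition.

    ``mask`` is cropped to the molecule's bounding box; ``origin`` is the
    (row, col) of that box in the full image. All pixel coordinates stored in
    the other fields are in full-image coordinates.
    """

    molecule_id: int
    mask: np.ndarray
    origin: tuple[int, int]
    boundary: np.ndarray  # ordered (n, 2) pixel list, full-image coords
    skeleton: list[tuple[int, int]] = field(default_factory=list)
    endpoints: list[tuple[int, int]] = field(default_factory=list)
    branch_points: list[tuple[int, int]] = field(default_factory=list)
    segments: list[list[tuple[int, int]]] = field(default_factory=list)
    segment_lengths: list[float] = field(default_factory=list)
    total_contour_length: float = 0.0
    degenerate: bool = False

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    def mask_pixels(self) -> np.ndarray:
        """(n, 2) array of mask pixels in full-image coordinates."""
        rr, cc = np.nonzero(self.mask)
        return np.column_stack([rr + self.origin[0], cc + self.origin[1]])


@dataclass
class ParticleRecord:
    """A detected protein particle on a DNA molecule."""

    particle_id: int
    molecule_id: int
    centroid_nm: tuple[float, float]  # (y, x) in nm
    pixels: np.ndarray  # (n, 2) full-image pixel coords
    volume_nm3: float
    placement_class: str  # "end" | "interstitial"


@dataclass
class StoichiometryResult:
    """Volume-ratio stoichiometry summary."""

    v_d: float  # mean bound-minus-bare volume difference (nm^3)
    v_p: float  # single-complex reference volume (nm^3)
    n_p: float  # mean particles per molecule
    n_bound: float  # complexes per binding site
    density: float | None = None  # g/cm^3 used for v_p, if derived from mass
    mass: float | None = None  # complex mass (Da), if given


# ---------------------------------------------------------------------------
# background and segmentation


def estimate_background(hm: HeightMap, exclude_threshold: float) -> float:
    """Median height of pixels below ``exclude_threshold``.

    The median is robust to the small fraction of molecule-edge pixels that
    leak under the threshold. Requires at least 10% of the image to qualify
    as background.
    """
    low = hm.grid[hm.grid < exclude_threshold]
    if low.size < 0.1 * hm.grid.size:
        raise BackgroundEstimationError(
            f"only {low.size}/{hm.grid.size} pixels below {exclude_threshold} nm; "
            "background estimate would be unreliable"
        )
    return float(np.median(low))


def _ordered_boundary(mask: np.ndarray, origin: tuple[int, int]) -> np.ndarray:
    """Ordered outer-boundary pixel list of a cropped mask (full-image coords)."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return np.zeros((0, 2), dtype=int)
    outer = max(contours, key=lambda c: len(c))
    pts = np.round(outer).astype(int) - 1
    pts[:, 0] = np.clip(pts[:, 0], 0, mask.shape[0] - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, mask.shape[1] - 1)
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
    pts = pts[keep]
    return pts + np.asarray(origin)


def segment_molecules(
    hm: HeightMap,
    h_b: float,
    height_threshold: float = 0.3,
    min_area: int = 30,
) -> list[MoleculeTrace]:
    """Segment molecules as 8-connected components above the height threshold.

    A pixel belongs to a molecule when ``h_p - h_b >= height_threshold``;
    components smaller than ``min_area`` pixels are discarded as noise.
    """
    if height_threshold <= 0:
        raise ParameterError("height_threshold must be positive")
    fg = (hm.grid - h_b) >= height_threshold
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    traces: list[MoleculeTrace] = []
    for lbl, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        crop = labels[sl] == lbl
        if crop.sum() < min_area:
            continue
        origin = (sl[0].start, sl[1].start)
        boundary = _ordered_boundary(crop, origin)
        traces.append(
            MoleculeTrace(
                molecule_id=len(traces),
                mask=crop,
                origin=origin,
                boundary=boundary,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# skeleton decomposition


_ORTHO = ((0, 1), (1, 0))
_DIAG = ((1, 1), (1, -1))


def _skeleton_graph(pixels: set[tuple[int, int]]) -> nx.Graph:
    """8-connectivity graph over skeleton pixels with redundant diagonals removed.

    A diagonal edge is redundant when the two pixels also share an orthogonal
    neighbor; dropping it leaves connectivity intact and keeps tracing paths
    one pixel wide.
    """
    g = nx.Graph()
    g.add_nodes_from(pixels)
    for (r, c) in pixels:
        for dr, dc in _ORTHO + _DIAG:
            q = (r + dr, c + dc)
            if q in pixels:
                g.add_edge((r, c), q)
    for a, b in list(g.edges):
        if abs(a[0] - b[0]) == 1 and abs(a[1] - b[1]) == 1:
            if (a[0], b[1]) in pixels or (b[0], a[1]) in pixels:
                g.remove_edge(a, b)
    return g


def _prune_spurs(g: nx.Graph, min_branch_length: int) -> None:
    """Iteratively remove leaf branches shorter than ``min_branch_length``.

    Only spurs that terminate at a junction are removed; a free-standing path
    (a whole molecule) is never pruned away.
    """
    changed = True
    while changed:
        changed = False
        for leaf in [n for n in g.nodes if g.degree(n) == 1]:
            if leaf not in g or g.degree(leaf) != 1:
                continue
            path = [leaf]
            prev, cur = None, leaf
            while True:
                nbrs = [x for x in g.neighbors(cur) if x != prev]
                if g.degree(cur) >= 3 or not nbrs:
                    break
                prev, cur = cur, nbrs[0]
                if g.degree(cur) >= 3:
                    break
                path.append(cur)
            ends_at_junction = cur in g and g.degree(cur) >= 3
            if ends_at_junction and len(path) < min_branch_length:
                g.remove_nodes_from(path)
                changed = True


def _junction_clusters(g: nx.Graph) -> list[list[tuple[int, int]]]:
    branch = [n for n in g.nodes if g.degree(n) >= 3]
    sub = g.subgraph(branch)
    return [sorted(comp) for comp in nx.connected_components(sub)]


def skeletonize_and_decompose(
    trace: MoleculeTrace,
    rx: float = 1.0,
    ry: float = 1.0,
    min_branch_length: int = 5,
    path_rule: str = "sum",
) -> MoleculeTrace:
    """Populate skeleton, endpoints, branch points, segments and lengths.

    The mask is thinned to a one-pixel skeleton; spurs shorter than
    ``min_branch_length`` pixels are pruned; branch pixels (>= 3 skeleton
    neighbors) that touch each other are merged into a single junction;
    segments are the maximal junction-free paths. ``path_rule`` selects
    whether the molecule's total contour length is the sum of all segments
    (default) or the single longest segment.
    """
    if path_rule not in ("sum", "longest"):
        raise ParameterError("path_rule must be 'sum' or 'longest'")
    if trace.mask.sum() == 0:
        trace.degenerate = True
        return trace
    skel = morphology.skeletonize(trace.mask)
    pixels = {
        (int(r) + trace.origin[0], int(c) + trace.origin[1])
        for r, c in zip(*np.nonzero(skel))
    }
    g = _skeleton_graph(pixels)
    _prune_spurs(g, min_branch_length)
    if g.number_of_nodes() == 0:
        trace.degenerate = True
        trace.skeleton = []
        trace.endpoints = []
        trace.branch_points = []
        trace.segments = []
        trace.segment_lengths = []
        trace.total_contour_length = 0.0
        return trace

    endpoints = [n for n in g.nodes if g.degree(n) == 1]
    clusters = _junction_clusters(g)
    branch_pixels = {p for cl in clusters for p in cl}
    cluster_of = {p: i for i, cl in enumerate(clusters) for p in cl}
    # one representative branch point per junction cluster
    branch_points = []
    for cl in clusters:
        arr = np.asarray(cl, dtype=float)
        centroid = arr.mean(axis=0)
        rep = cl[int(np.argmin(((arr - centroid) ** 2).sum(axis=1)))]
        branch_points.append(rep)

    nodes = set(endpoints) | branch_pixels
    segments: list[list[tuple[int, int]]] = []
    visited: set[frozenset] = set()

    def walk(start, first):
        path = [start, first]
        visited.add(frozenset((start, first)))
        prev, cur = start, first
        while cur not in nodes:
            nxt = [x for x in g.neighbors(cur) if x != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            visited.add(frozenset((prev, cur)))
            path.append(cur)
        return path

    for start in sorted(nodes):
        for nb in sorted(g.neighbors(start)):
            if frozenset((start, nb)) in visited:
                continue
            path = walk(start, nb)
            # drop intra-junction connectors (all pixels in one branch cluster)
            if all(p in branch_pixels for p in path) and len(
                {cluster_of[p] for p in path}
            ) == 1:
                continue
            segments.append(path)
    if not nodes:
        # pure cycle: one closed segment
        start = sorted(g.nodes)[0]
        nb = sorted(g.neighbors(start))[0]
        path = [start, nb]
        visited.add(frozenset((start, nb)))
        prev, cur = start, nb
        while cur != start:
            nxt = [x for x in g.neighbors(cur) if x != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            path.append(cur)
        segments.append(path)

    seg_lengths = [contour_length(np.asarray(p), rx, ry) for p in segments]
    trace.skeleton = sorted(g.nodes)
    trace.endpoints = sorted(endpoints)
    trace.branch_points = sorted(branch_points)
    trace.segments = segments
    trace.segment_lengths = seg_lengths
    if path_rule == "sum":
        trace.total_contour_length = float(sum(seg_lengths))
    else:
        trace.total_contour_length = float(max(seg_lengths)) if seg_lengths else 0.0
    return trace


def contour_length(path: np.ndarray, rx: float, ry: float) -> float:
    """Weighted length of an ordered 8-connected pixel path.

    Horizontal steps contribute rx, vertical steps ry, diagonal steps
    sqrt(rx^2 + ry^2).
    """
    path = np.asarray(path)
    if len(path) < 2:
        return 0.0
    d = np.diff(path, axis=0)
    if np.any(np.abs(d) > 1) or np.any(np.all(d == 0, axis=1)):
        raise PathError("consecutive path pixels must be distinct 8-neighbors")
    diag = np.all(np.abs(d) == 1, axis=1)
    vert = (np.abs(d[:, 0]) == 1) & (d[:, 1] == 0)
    horiz = (d[:, 0] == 0) & (np.abs(d[:, 1]) == 1)
    return float(
        horiz.sum() * rx + vert.sum() * ry + diag.sum() * math.hypot(rx, ry)
    )


# ---------------------------------------------------------------------------
# volumes and particles


def molecule_volume(trace: MoleculeTrace, hm: HeightMap, h_b: float) -> float:
    """Volume in nm^3: pixel area times summed height excess over background.

    The summation region is the molecule's outer boundary filled (holes
    included); negative per-pixel excess is clipped at zero so that noise
    cannot contribute negative volume.
    """
    r0, c0 = trace.origin
    region = ndimage.binary_fill_holes(trace.mask)
    crop = hm.grid[r0 : r0 + trace.mask.shape[0], c0 : c0 + trace.mask.shape[1]]
    excess = np.clip(crop - h_b, 0.0, None)
    return float(hm.rx * hm.ry * excess[region].sum())


def detect_bound_particles(
    hm: HeightMap,
    trace: MoleculeTrace,
    h_b: float,
    particle_height_cutoff: float = 1.2,
    end_distance_cutoff: float = 10.0,
) -> list[ParticleRecord]:
    """Detect protein particles as tall clusters within a molecule's mask.

    Particle pixels are mask pixels with height excess >= the cutoff,
    clustered by 8-connectivity. A particle is classed "end" when its
    excess-weighted centroid lies within ``end_distance_cutoff`` (nm) of a
    skeleton endpoint, else "interstitial".
    """
    r0, c0 = trace.origin
    crop = hm.grid[r0 : r0 + trace.mask.shape[0], c0 : c0 + trace.mask.shape[1]]
    excess = np.clip(crop - h_b, 0.0, None)
    tall = trace.mask & (excess >= particle_height_cutoff)
    labels, n = ndimage.label(tall, structure=np.ones((3, 3), dtype=int))
    records: list[ParticleRecord] = []
    ends = np.asarray(trace.endpoints, dtype=float) if trace.endpoints else None
    for lbl in range(1, n + 1):
        sel = labels == lbl
        rr, cc = np.nonzero(sel)
        w = excess[rr, cc]
        cy = float(((rr + r0) * w).sum() / w.sum()) * hm.ry
        cx = float(((cc + c0) * w).sum() / w.sum()) * hm.rx
        vol = float(hm.rx * hm.ry * w.sum())
        cls = "interstitial"
        if ends is not None and len(ends):
            d = np.hypot((ends[:, 0] * hm.ry) - cy, (ends[:, 1] * hm.rx) - cx)
            if d.min() <= end_distance_cutoff:
                cls = "end"
        records.append(
            ParticleRecord(
                particle_id=len(records),
                molecule_id=trace.molecule_id,
                centroid_nm=(cy, cx),
                pixels=np.column_stack([rr + r0, cc + c0]),
                volume_nm3=vol,
                placement_class=cls,
            )
        )
    return records


def protein_reference_volume(mass_da: float, density: float = 1.44) -> float:
    """Volume (nm^3) of a single complex from its mass and mean protein density.

    V_p = M / (rho * N_A), converted from cm^3 to nm^3 (1 cm^3 = 1e21 nm^3).
    """
    if mass_da <= 0 or density <= 0:
        raise ParameterError("mass and density must be positive")
    return mass_da / (density * AVOGADRO) * 1e21


def bound_trimer_count(v_d: float, v_p: float, n_p: float) -> float:
    """Average number of complexes per binding site: V_d / (V_p * N_p)."""
    if v_p <= 0 or n_p <= 0:
        raise ParameterError("V_p and N_p must be positive")
    if v_d < 0:
        raise ParameterError("V_d must be non-negative")
    return v_d / (v_p * n_p)


# ---------------------------------------------------------------------------
# scene summaries


_NP_BINS = ("0", "1", "2", "3", ">3")


def _np_bin(n: int) -> str:
    return str(n) if n <= 3 else ">3"


def summarize_scene(
    traces: list[MoleculeTrace],
    particles: list[list[ParticleRecord]],
    volumes: list[float],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-molecule table plus a contour-length summary grouped by N_p.

    Returns ``(per_molecule, grouped)``. The grouped table bins molecules by
    particle count into {0, 1, 2, 3, >3} and reports mean +/- SD contour
    length and N per bin.
    """
    rows = []
    for trace, parts, vol in zip(traces, particles, volumes):
        rows.append(
            {
                "molecule_id": trace.molecule_id,
                "contour_length_nm": trace.total_contour_length,
                "volume_nm3": vol,
                "n_particles": len(parts),
                "n_end": sum(p.placement_class == "end" for p in parts),
                "n_interstitial": sum(
                    p.placement_class == "interstitial" for p in parts
                ),
            }
        )
    per_molecule = pd.DataFrame(
        rows,
        columns=[
            "molecule_id",
            "contour_length_nm",
            "volume_nm3",
            "n_particles",
            "n_end",
            "n_interstitial",
        ],
    )
    grows = []
    if len(per_molecule):
        bins = per_molecule["n_particles"].map(_np_bin)
        for b in _NP_BINS:
            sel = per_molecule[bins == b]
            if not len(sel):
                continue
            grows.append(
                {
                    "n_particles_bin": b,
                    "n_molecules": len(sel),
                    "contour_length_mean_nm": sel["contour_length_nm"].mean(),
                    "contour_length_sd_nm": sel["contour_length_nm"].std(ddof=1)
                    if len(sel) > 1
                    else 0.0,
                    "volume_mean_nm3": sel["volume_nm3"].mean(),
                }
            )
    grouped = pd.DataFrame(
        grows,
        columns=[
            "n_particles_bin",
            "n_molecules",
            "contour_length_mean_nm",
            "contour_length_sd_nm",
            "volume_mean_nm3",
        ],
    )
    return per_molecule, grouped


def analyze_height_map(
    hm: HeightMap,
    exclude_threshold: float = 0.5,
    height_threshold: float = 0.3,
    min_area: int = 30,
    min_branch_length: int = 5,
    particle_height_cutoff: float = 1.2,
    end_distance_cutoff: float = 10.0,
    path_rule: str = "sum",
) -> tuple[list[MoleculeTrace], list[list[ParticleRecord]], list[float], float]:
    """Full per-image analysis: background, segmentation, tracing, particles.

    Returns ``(traces, particles_per_molecule, volumes, h_b)``.
    """
    h_b = estimate_background(hm, exclude_threshold)
    traces = segment_molecules(hm, h_b, height_threshold, min_area)
    particles: list[list[ParticleRecord]] = []
    volumes: list[float] = []
    for trace in traces:
        skeletonize_and_decompose(
            trace, hm.rx, hm.ry, min_branch_length, path_rule
        )
        volumes.append(molecule_volume(trace, hm, h_b))
        particles.append(
            detect_bound_particles(
                hm, trace, h_b, particle_height_cutoff, end_distance_cutoff
            )
        )
    return traces, particles, volumes, h_b
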
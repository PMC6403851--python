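"""Synthetic fluorescence micrographs with known ground truth.

Emulates confocal images of protein networks: bright anastomosing
threads on a dark background, dark circular occlusions (starch
granules), and Gaussian detector noise.  Five morphological regimes
mirror the gluten network types:

* ``branched``             — connected, homogeneous thread mesh (type II)
* ``fragmented``           — densely packed, ruptured short threads (type I)
* ``contracted``           — fewer, thicker, shorter threads with large
                             dark occlusions (type III)
* ``dense_agglomerate``    — tight clusters of protein blobs (type IV)
* ``scattered_agglomerate``— few, widely separated blob clusters (type V)

Network regimes are built from a planar graph: nodes on a jittered grid,
Delaunay edges pruned by length and by a random keep fraction, drawn as
ribbons of fixed width.  Fragmentation ruptures an edge by blanking a
gap adjacent to one of its end nodes, so the node loses that incidence
(junctions degrade toward plain threads) while the surviving fragment
gains an open end; the thread-end count never decreases as the
fragmentation rate rises.  Ground truth (junctions, endpoints, drawn
length, components) comes from the generating graph, not from
re-measurement.

All randomness flows from one integer seed through named substreams, so
outputs are byte-identical for identical (spec, seed) and changing one
rate (e.g. fragmentation) keeps the rest of the geometry fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError
from skimage.draw import disk as draw_disk, line as draw_line

from .io import DEFAULT_PIXEL_SIZE_UM, Micrograph

REGIMES = (
    "branched",
    "fragmented",
    "contracted",
    "dense_agglomerate",
    "scattered_agglomerate",
)
NETWORK_REGIMES = frozenset({"branched", "fragmented", "contracted"})
AGENTS = ("GSH", "ASC", "GOX", "TG", "BRN", "IHL")

#: network type each regime is designed to produce
REGIME_TYPE = {
    "branched": "II",
    "fragmented": "I",
    "contracted": "III",
    "dense_agglomerate": "IV",
    "scattered_agglomerate": "V",
}


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic micrograph."""

    regime: str = "branched"
    size_px: int = 512
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    # thread-graph parameters (network regimes)
    n_seeds: int = 90
    thread_width_px: float = 3.0
    edge_keep: float = 0.9
    max_edge_factor: float = 2.0
    fragmentation_rate: float = 0.0
    gap_fraction: float = 0.30
    # agglomerate parameters
    agglomerate_count: int = 0
    blobs_per_cluster: int = 14
    cluster_spread_px: float = 12.0
    blob_radius_px: tuple[float, float] = (2.5, 5.0)
    # occlusions, photometry
    starch_disc_count: int = 3
    starch_radius_px: tuple[float, float] = (8.0, 16.0)
    noise_sd: float = 8.0
    background: int = 25
    foreground: int = 190
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if not 0 <= self.fragmentation_rate <= 1:
            raise ValueError("fragmentation_rate must be in [0, 1]")
        if not 0 <= self.edge_keep <= 1:
            raise ValueError("edge_keep must be in [0, 1]")
        if min(self.n_seeds, self.agglomerate_count, self.starch_disc_count) < 0:
            raise ValueError("counts must be >= 0")
        if not self.foreground > self.background:
            raise ValueError("foreground level must exceed background")
        if self.thread_width_px >= self.size_px / 4:
            raise ValueError("thread width too large for the image")
        if self.size_px < 64:
            raise ValueError("image size below 64 px")


@dataclass(frozen=True)
class GroundTruth:
    """Known geometry of a synthetic image, from the generating graph."""

    n_junctions: int
    n_endpoints: int
    total_drawn_length_um: float
    drawn_width_um: float
    n_components: int
    foreground_fraction: float


# per-regime default parameter overrides (calibrated once; see docs)
_REGIME_DEFAULTS: dict[str, dict] = {
    "branched": {
        "n_seeds": 960,
        "edge_keep": 1.0,
        "max_edge_factor": 1.6,
        "thread_width_px": 3.0,
        "fragmentation_rate": 0.16,
        "gap_fraction": 0.60,
        "starch_disc_count": 12,
        "starch_radius_px": (6.0, 10.0),
    },
    "fragmented": {
        "n_seeds": 360,
        "thread_width_px": 10.0,
        "edge_keep": 1.0,
        "max_edge_factor": 1.8,
        "fragmentation_rate": 0.90,
        "gap_fraction": 0.55,
        "starch_disc_count": 0,
    },
    "contracted": {
        "n_seeds": 680,
        "thread_width_px": 6.0,
        "edge_keep": 0.80,
        "fragmentation_rate": 0.40,
        "gap_fraction": 0.50,
        "starch_disc_count": 12,
        "starch_radius_px": (9.0, 14.0),
    },
    "dense_agglomerate": {
        "agglomerate_count": 104,
        "blobs_per_cluster": 45,
        "cluster_spread_px": 20.0,
        "blob_radius_px": (4.0, 7.0),
        "starch_disc_count": 0,
    },
    "scattered_agglomerate": {
        "agglomerate_count": 16,
        "blobs_per_cluster": 12,
        "cluster_spread_px": 16.0,
        "blob_radius_px": (3.0, 6.0),
        "starch_disc_count": 0,
    },
}


def default_spec(regime: str, seed: int = 0, size_px: int = 512) -> SynthSpec:
    """The calibrated default spec for a morphological regime."""
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    return SynthSpec(regime=regime, seed=seed, size_px=size_px,
                     **_REGIME_DEFAULTS[regime])


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    """Named substreams so one parameter change leaves the rest fixed."""
    root = np.random.SeedSequence(seed)
    names = ("discs", "nodes", "edges", "frag", "agg", "noise")
    return {n: np.random.default_rng(c) for n, c in zip(names, root.spawn(len(names)))}


def _sample_discs(spec: SynthSpec, rng: np.random.Generator):
    centers, radii = [], []
    for _ in range(spec.starch_disc_count):
        r = rng.uniform(*spec.starch_radius_px)
        margin = r + 2
        c = rng.uniform(margin, spec.size_px - margin, size=2)
        centers.append(c)
        radii.append(r)
    return np.asarray(centers).reshape(-1, 2), np.asarray(radii)


def _grid_nodes(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid node positions; low count variance keeps the
    measured junction density stable across seeds."""
    g = max(2, round(math.sqrt(spec.n_seeds)))
    spacing = spec.size_px / g
    jitter = 0.35 * spacing
    margin = spec.thread_width_px + 2
    pts = []
    for i in range(g):
        for j in range(g):
            p = np.array([(i + 0.5) * spacing, (j + 0.5) * spacing])
            p = p + rng.uniform(-jitter, jitter, size=2)
            pts.append(np.clip(p, margin, spec.size_px - 1 - margin))
    return np.asarray(pts)


def _segment_hits_disc(p, q, centers, radii, clearance):
    if len(centers) == 0:
        return False
    t = np.linspace(0.0, 1.0, 24)[:, None]
    samples = p[None, :] * (1 - t) + q[None, :] * t          # (24, 2)
    d = np.linalg.norm(samples[:, None, :] - centers[None, :, :], axis=2)
    return bool((d < radii[None, :] + clearance).any())


def _draw_segments(canvas: np.ndarray, segments) -> None:
    for p, q in segments:
        rr, cc = draw_line(int(round(p[0])), int(round(p[1])),
                           int(round(q[0])), int(round(q[1])))
        canvas[rr, cc] = True


def _ribbon_mask(centerline: np.ndarray, width_px: float) -> np.ndarray:
    if not centerline.any():
        return centerline.copy()
    dist = ndimage.distance_transform_edt(~centerline)
    return dist <= width_px / 2.0


def _network_geometry(spec: SynthSpec, rngs) -> tuple[np.ndarray, GroundTruth, np.ndarray, np.ndarray]:
    disc_centers, disc_radii = _sample_discs(spec, rngs["discs"])
    nodes = _grid_nodes(spec, rngs["nodes"])
    clearance = spec.thread_width_px / 2 + 2
    if len(disc_centers):
        d = np.linalg.norm(nodes[:, None, :] - disc_centers[None, :, :], axis=2)
        nodes = nodes[(d >= disc_radii[None, :] + clearance).all(axis=1)]
    if len(nodes) < 4:
        raise ValueError("too few free nodes to triangulate; shrink the occlusions")
    try:
        tri = Delaunay(nodes)
    except QhullError as exc:  # pragma: no cover - degenerate layouts
        raise ValueError("degenerate node layout") from exc
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = sorted((simplex[a], simplex[(a + 1) % 3]))
            edges.add((i, j))
    edges = sorted(edges)
    spacing = spec.size_px / max(2, round(math.sqrt(spec.n_seeds)))
    max_len = spec.max_edge_factor * spacing
    u_keep = rngs["edges"].random(len(edges))
    kept = []
    for (i, j), u in zip(edges, u_keep):
        if np.linalg.norm(nodes[i] - nodes[j]) > max_len:
            continue
        if u >= spec.edge_keep:
            continue
        if _segment_hits_disc(nodes[i], nodes[j], disc_centers, disc_radii, clearance):
            continue
        kept.append((i, j))

    # restrict to the largest connected piece: stray mesh pockets (e.g.
    # isolated behind occlusions) would otherwise leave debris below the
    # particle filter whose ground truth is ill-defined
    if kept:
        pre = nx.Graph(kept)
        giant = max(nx.connected_components(pre), key=len)
        kept = [e for e in kept if e[0] in giant]

    # rupture draws: a fixed uniform and cut-end choice per edge; exactly
    # round(rate * n_eligible) edges are cut, those with the lowest
    # uniforms (inclusion probability = rate per edge, deterministic
    # total), so raising fragmentation_rate only adds cuts to the same
    # geometry.  Edges whose surviving fragment would hang on a
    # degree-1 node are ineligible: a rupture there would strand a
    # speck-sized piece instead of opening a thread end.
    u_frag = rngs["frag"].random(len(kept))
    cut_at_first = rngs["frag"].random(len(kept)) < 0.5
    kept_degree = np.zeros(len(nodes), dtype=int)
    for i, j in kept:
        kept_degree[i] += 1
        kept_degree[j] += 1
    far_nodes = np.array([(j if at else i)
                          for (i, j), at in zip(kept, cut_at_first)], dtype=int)
    eligible = (kept_degree[far_nodes] >= 2 if len(kept)
                else np.zeros(0, dtype=bool))
    split = np.zeros(len(kept), dtype=bool)
    n_cut = int(round(spec.fragmentation_rate * int(eligible.sum())))
    order = np.argsort(np.where(eligible, u_frag, np.inf))
    split[order[:n_cut]] = True

    canvas = np.zeros((spec.size_px, spec.size_px), dtype=bool)
    segments = []
    total_len_px = 0.0
    degree = np.zeros(len(nodes), dtype=int)      # incidences of drawn threads
    n_fragment_ends = 0
    graph = nx.Graph()
    for (i, j), is_split, at_first in zip(kept, split, cut_at_first):
        p, q = nodes[i], nodes[j]
        length = float(np.linalg.norm(q - p))
        if not is_split:
            segments.append((p, q))
            total_len_px += length
            degree[i] += 1
            degree[j] += 1
            graph.add_edge(i, j)
            continue
        # blank a gap next to the cut node; the fragment keeps the far node
        cut, far = (i, j) if at_first else (j, i)
        gap = min(max(spec.gap_fraction * length, 1.2 * spec.thread_width_px + 3),
                  0.6 * length)
        direction = (nodes[far] - nodes[cut]) / length
        segments.append((nodes[cut] + direction * gap, nodes[far]))
        total_len_px += length - gap
        degree[far] += 1
        n_fragment_ends += 1
    _draw_segments(canvas, segments)
    mask = _ribbon_mask(canvas, spec.thread_width_px)

    graph.add_nodes_from(np.flatnonzero(degree > 0))
    gt = GroundTruth(
        n_junctions=int((degree >= 3).sum()),
        n_endpoints=int((degree == 1).sum()) + n_fragment_ends,
        total_drawn_length_um=total_len_px * spec.pixel_size_um,
        drawn_width_um=spec.thread_width_px * spec.pixel_size_um,
        n_components=nx.number_connected_components(graph) if graph else 0,
        foreground_fraction=float(mask.mean()),
    )
    return mask, gt, disc_centers, disc_radii


def _agglomerate_geometry(spec: SynthSpec, rngs):
    rng = rngs["agg"]
    size = spec.size_px
    min_sep = max(2.0 * spec.cluster_spread_px, size / (spec.agglomerate_count + 1))
    margin = spec.cluster_spread_px + spec.blob_radius_px[1] + 2
    centers: list[np.ndarray] = []
    for _ in range(400 * max(spec.agglomerate_count, 1)):
        if len(centers) == spec.agglomerate_count:
            break
        c = rng.uniform(margin, size - margin, size=2)
        if all(np.linalg.norm(c - o) >= min_sep for o in centers):
            centers.append(c)
    mask = np.zeros((size, size), dtype=bool)
    radii_drawn = []
    for c in centers:
        for _ in range(spec.blobs_per_cluster):
            offset = rng.normal(0.0, spec.cluster_spread_px / 2.0, size=2)
            r = rng.uniform(*spec.blob_radius_px)
            radii_drawn.append(r)
            rr, cc = draw_disk(tuple(np.clip(c + offset, r + 1, size - r - 2)),
                               r, shape=mask.shape)
            mask[rr, cc] = True
    mean_d = 2 * float(np.mean(radii_drawn)) if radii_drawn else 0.0
    gt = GroundTruth(
        n_junctions=0,
        n_endpoints=0,
        total_drawn_length_um=0.0,
        drawn_width_um=mean_d * spec.pixel_size_um,
        n_components=len(centers),
        foreground_fraction=float(mask.mean()),
    )
    disc_centers, disc_radii = _sample_discs(spec, rngs["discs"])
    return mask, gt, disc_centers, disc_radii


def generate_network_image(spec: SynthSpec) -> tuple[Micrograph, GroundTruth]:
    """Render one synthetic micrograph and its ground truth."""
    rngs = _rngs(spec.seed)
    if spec.regime in NETWORK_REGIMES:
        mask, gt, disc_centers, disc_radii = _network_geometry(spec, rngs)
    else:
        mask, gt, disc_centers, disc_radii = _agglomerate_geometry(spec, rngs)

    img = np.full(mask.shape, float(spec.background))
    for c, r in zip(disc_centers, disc_radii):
        rr, cc = draw_disk(tuple(c), r, shape=mask.shape)
        img[rr, cc] = spec.background * 0.35
    img[mask] = spec.foreground
    # mild blur anti-aliases thread and occlusion boundaries alike
    img = ndimage.gaussian_filter(img, sigma=0.8)
    if spec.noise_sd > 0:
        # shot-noise-like scaling: noise_sd applies at the foreground
        # level and shrinks with sqrt(signal) in darker regions
        scale = np.sqrt(np.clip(img, 0.0, None) / spec.foreground)
        img += rngs["noise"].normal(0.0, 1.0, size=img.shape) * spec.noise_sd * scale
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    micro = Micrograph(
        img, pixel_size_um=spec.pixel_size_um,
        source_id=f"{spec.regime}_s{spec.seed}",
    )
    return micro, gt


def _lerp(a: float, b: float, t: float) -> float:
    return a + (b - a) * t


def _interp_network(base: SynthSpec, target: SynthSpec, t: float, **extra) -> SynthSpec:
    """Interpolate the thread-graph fields of two network specs."""
    fields = dict(
        n_seeds=round(_lerp(base.n_seeds, target.n_seeds, t)),
        thread_width_px=_lerp(base.thread_width_px, target.thread_width_px, t),
        edge_keep=_lerp(base.edge_keep, target.edge_keep, t),
        fragmentation_rate=_lerp(base.fragmentation_rate,
                                 target.fragmentation_rate, t),
        starch_disc_count=round(_lerp(base.starch_disc_count,
                                      target.starch_disc_count, t)),
        starch_radius_px=(
            _lerp(base.starch_radius_px[0], target.starch_radius_px[0], t),
            _lerp(base.starch_radius_px[1], target.starch_radius_px[1], t),
        ),
    )
    fields.update(extra)
    return replace(base, **fields)


def generate_dose_series(
    agent: str,
    concentrations: list[float],
    base_spec: SynthSpec | None = None,
    seed: int = 0,
) -> list[tuple[float, Micrograph, GroundTruth]]:
    """Emulate one gluten-modifying agent as a concentration series.

    Concentrations must be strictly ascending with the first equal to 0
    (the unmodified standard).  Spec parameters interpolate with
    concentration so each agent reproduces its qualitative direction:

    * GSH / BRN — rising fragmentation: thread rupture, more open ends,
      thicker fragments, denser packing (lower lacunarity)
    * ASC — contraction: thicker, shorter threads and growing dark
      occlusions
    * GOX — rising cross-linking: denser, more complete mesh
    * TG — mesh densification at low dose, crossing over to dense
      protein agglomerates above half the maximal dose
    * IHL — dilution into scattered agglomerates with rising spread

    The whole series shares the base seed, so dose effects are paired on
    the same underlying geometry.
    """
    if agent not in AGENTS:
        raise ValueError(f"unknown agent {agent!r}; expected one of {AGENTS}")
    if not concentrations:
        raise ValueError("empty concentration list")
    if concentrations[0] != 0:
        raise ValueError("first concentration must be 0 (the standard)")
    if any(b <= a for a, b in zip(concentrations, concentrations[1:])):
        raise ValueError("concentrations must be strictly ascending")
    base = base_spec if base_spec is not None else default_spec("branched", seed=seed)
    cmax = concentrations[-1]
    out = []
    for conc in concentrations:
        t = conc / cmax if cmax > 0 else 0.0
        spec = _agent_spec(agent, base, t)
        micro, gt = generate_network_image(spec)
        micro = Micrograph(
            micro.intensities, micro.pixel_size_um,
            source_id=f"{agent}_c{conc:g}_s{base.seed}",
        )
        out.append((conc, micro, gt))
    return out


def _agent_spec(agent: str, base: SynthSpec, t: float) -> SynthSpec:
    if t == 0.0:
        return base
    size, s = base.size_px, base.seed
    if agent in ("GSH", "BRN"):
        return _interp_network(base, default_spec("fragmented", s, size), t)
    if agent == "ASC":
        return _interp_network(base, default_spec("contracted", s, size), t)
    if agent == "GOX":
        dense = replace(base, edge_keep=1.0, n_seeds=round(base.n_seeds * 1.25),
                        fragmentation_rate=0.05)
        return _interp_network(base, dense, t)
    if agent == "TG":
        if t < 0.5:
            dense = replace(base, edge_keep=min(1.0, base.edge_keep + 0.08),
                            n_seeds=round(base.n_seeds * 1.06),
                            fragmentation_rate=0.7 * base.fragmentation_rate)
            return _interp_network(base, dense, t / 0.5)
        u = (t - 0.5) / 0.5
        agg = default_spec("dense_agglomerate", s, size)
        return replace(agg, cluster_spread_px=_lerp(agg.cluster_spread_px * 1.2,
                                                    agg.cluster_spread_px, u))
    if agent == "IHL":
        agg = default_spec("scattered_agglomerate", base.seed, size)
        return replace(agg, cluster_spread_px=agg.cluster_spread_px * (0.7 + 0.6 * t))
    raise ValueError(agent)
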
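"""Seeded graph-cut segmentation of the vasculature.

The final mask minimizes the binary labeling energy

    E(L) = E_d(L) + k E_s(L)

over foreground/background labels, where the data term sums per-pixel
t-link costs and the smoothness term sums n-link costs over the 8-neighbor
system.  Seeds come from the symmetry-transform stage:

* the skeleton (centerline) of the coarse vasculature is definite
  foreground F_d, a shape prior the cut must keep;
* pixels with VL_Sym > T_h are candidate foreground F_c;
* pixels with VL_Sym < T_l are definite background B_d;
* the rest are candidate background B_c.

Candidate pixels are biased by their normalized distance to the seed sets,
D_F(p) = d_f(p) / (d_f(p) + d_b(p)): t-links are w1 VL_Sym/D_F toward the
preferred terminal and w2 VL_Sym/D_F toward the other, with w1 > 1 > w2 >
0, so candidates near the centerline (small D_F) are strongly pulled to the
foreground.  n-links cost k / (|I(p) - I(q)| + eta), cheap to cut across
intensity edges.  The cut is computed as an exact max-flow on fixed-point
integer capacities, so the max-flow value equals the cut capacity exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Union

import numpy as np
import yaml
from scipy import ndimage, sparse
from scipy.sparse.csgraph import breadth_first_order, maximum_flow
from skimage.morphology import skeletonize

from .hessian_enhance import DEFAULT_C, DEFAULT_SCALES, multiscale_enhance
from .io_fixtures import Image2D
from .nlm_filter import NlmParams, estimate_noise_sigma, nlm_denoise
from .radial_symmetry import (
    CoarseVasculature,
    extract_coarse,
    radial_symmetry_transform,
)

# seed label codes
F_D, F_C, B_C, B_D = 0, 1, 2, 3

#: n-link neighbor offsets generating the 8-neighbor system (each
#: unordered pair appears exactly once).
NEIGHBOR_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class SeedLabeling:
    """Four-class seed map over {F_d, F_c, B_c, B_d} plus the centerline
    shape prior and the two likeness thresholds that induced it."""

    labels: np.ndarray
    centerline: np.ndarray
    t_h: float
    t_l: float

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code


@dataclass
class DistanceMaps:
    """Distances to the definite seed sets and their normalized forms.

    ``d_f``/``d_b`` are minimum distances (pixels) to F_d and B_d;
    D_F = d_f / (d_f + d_b) and D_B = 1 - D_F.
    """

    d_f: np.ndarray
    d_b: np.ndarray
    D_F: np.ndarray
    D_B: np.ndarray


@dataclass
class SegGraph:
    """Pixel-graph capacities: t-links ``u_s``/``u_t`` (source/sink) and
    symmetric n-links per neighbor offset.  ``nlinks[(dr, dc)][r, c]`` is
    the capacity between (r, c) and (r+dr, c+dc); rows/columns where the
    neighbor falls outside the image are zero.  ``inf_cap`` is the finite
    stand-in used for the hard seed constraints."""

    u_s: np.ndarray
    u_t: np.ndarray
    nlinks: dict
    inf_cap: float


@dataclass
class SegmentationResult:
    """Final mask, the energy E(L) of the returned labeling (float
    capacities), and the max-flow value.  ``flow_units``/``capacity_scale``
    expose the solver's exact integer flow and the fixed-point scale
    (flow = flow_units / capacity_scale)."""

    mask: np.ndarray
    energy: float
    flow: float
    flow_units: int = 0
    capacity_scale: float = 1.0


# --------------------------------------------------------------------------
# Seeds and distances
# --------------------------------------------------------------------------

def extract_centerline(coarse: Union[CoarseVasculature, np.ndarray]
                       ) -> np.ndarray:
    """Topology-preserving thinning of the coarse mask to a 1-px skeleton."""
    mask = coarse.mask if isinstance(coarse, CoarseVasculature) else np.asarray(
        coarse, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask, dtype=bool)
    return skeletonize(mask)


def assign_seeds(vl_sym: np.ndarray, centerline: np.ndarray,
                 t_h: float, t_l: float) -> SeedLabeling:
    """Label every pixel: centerline -> F_d; else VL_Sym > T_h -> F_c;
    else VL_Sym < T_l -> B_d; else B_c.  Centerline takes priority."""
    if t_l >= t_h:
        raise ValueError(f"need t_l < t_h, got t_l={t_l}, t_h={t_h}")
    vl_sym = np.asarray(vl_sym, dtype=np.float64)
    centerline = np.asarray(centerline, dtype=bool)
    labels = np.full(vl_sym.shape, B_C, dtype=np.int8)
    labels[vl_sym > t_h] = F_C
    labels[vl_sym < t_l] = B_D
    labels[centerline] = F_D
    return SeedLabeling(labels=labels, centerline=centerline,
                        t_h=float(t_h), t_l=float(t_l))


def seed_distances(seeds: SeedLabeling, metric: str = "euclidean",
                   intensity: Optional[np.ndarray] = None,
                   eps: float = 1e-12) -> DistanceMaps:
    """Minimum distances to the definite seed sets.

    ``euclidean`` uses the exact Euclidean distance transform.
    ``geodesic`` integrates an intensity-contrast cost (1 + 100 |grad I|,
    from the supplied ``intensity``) along 8-connected paths, so distances
    grow faster across edges than through homogeneous regions.
    """
    fg = seeds.mask(F_D)
    bg = seeds.mask(B_D)
    if not fg.any() or not bg.any():
        raise ValueError("both definite seed sets must be nonempty")
    if metric == "euclidean":
        d_f = ndimage.distance_transform_edt(~fg)
        d_b = ndimage.distance_transform_edt(~bg)
    elif metric == "geodesic":
        if intensity is None:
            raise ValueError("geodesic metric requires an intensity image")
        gy, gx = np.gradient(np.asarray(intensity, dtype=np.float64))
        cost = 1.0 + 100.0 * np.hypot(gx, gy)
        d_f = _geodesic(cost, fg)
        d_b = _geodesic(cost, bg)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    total = d_f + d_b
    safe = np.where(total > 0, total, eps)
    D_F = d_f / safe
    return DistanceMaps(d_f=d_f, d_b=d_b, D_F=D_F, D_B=1.0 - D_F)


def _geodesic(cost: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    from skimage.graph import MCP_Geometric

    mcp = MCP_Geometric(cost)
    dist, _ = mcp.find_costs(np.argwhere(seeds))
    return dist


# --------------------------------------------------------------------------
# Graph construction and min-cut
# --------------------------------------------------------------------------

def build_graph(intensity: Union[Image2D, np.ndarray], seeds: SeedLabeling,
                dist: DistanceMaps, vl_sym: np.ndarray,
                w1: float = 2.0, w2: float = 0.5, k: float = 1.0,
                eta: float = 0.01, inf_cap: Optional[float] = None,
                use_db_for_bc: bool = False, eps: float = 1e-12) -> SegGraph:
    """Assemble t-link and n-link capacities.

    t-links: F_d -> (inf, 0); B_d -> (0, inf); F_c -> (w1 V/D, w2 V/D);
    B_c -> (w2 V/D, w1 V/D) with V = VL_Sym(p) and D = D_F(p) (or D_B(p)
    for the B_c rows when ``use_db_for_bc``).  n-links: k / (|I(p) - I(q)|
    + eta) per 8-neighbor pair.  ``inf_cap`` defaults to 1e6 times the
    largest finite capacity, large enough that no minimum cut ever severs a
    seed t-link.
    """
    if not (w1 > 1.0 > w2 > 0.0):
        raise ValueError(f"need w1 > 1 > w2 > 0, got w1={w1}, w2={w2}")
    if eta <= 0 or k <= 0:
        raise ValueError("eta and k must be positive")
    pixels = intensity.pixels if isinstance(intensity, Image2D) else np.asarray(
        intensity, dtype=np.float64)
    vl_sym = np.asarray(vl_sym, dtype=np.float64)
    H, W = pixels.shape

    labels = seeds.labels
    D = np.maximum(dist.D_F, eps)
    D_bc = np.maximum(dist.D_B, eps) if use_db_for_bc else D
    ratio_fc = vl_sym / D
    ratio_bc = vl_sym / D_bc

    u_s = np.zeros((H, W), dtype=np.float64)
    u_t = np.zeros((H, W), dtype=np.float64)
    fc = labels == F_C
    bc = labels == B_C
    u_s[fc] = w1 * ratio_fc[fc]
    u_t[fc] = w2 * ratio_fc[fc]
    u_s[bc] = w2 * ratio_bc[bc]
    u_t[bc] = w1 * ratio_bc[bc]

    nlinks = {}
    for dr, dc in NEIGHBOR_OFFSETS:
        cap = np.zeros((H, W), dtype=np.float64)
        rs = slice(0, H - dr)
        cs = slice(0, W - dc) if dc >= 0 else slice(-dc, W)
        ns = slice(dr, H)
        ncs = slice(dc, W) if dc >= 0 else slice(0, W + dc)
        diff = np.abs(pixels[rs, cs] - pixels[ns, ncs])
        cap[rs, cs] = k / (diff + eta)
        nlinks[(dr, dc)] = cap

    finite_max = max(
        float(u_s.max()), float(u_t.max()),
        max(float(c.max()) for c in nlinks.values()),
    )
    if inf_cap is None:
        inf_cap = 1e6 * finite_max if finite_max > 0 else 1e6
    fd = labels == F_D
    bd = labels == B_D
    u_s[fd] = inf_cap
    u_t[fd] = 0.0
    u_s[bd] = 0.0
    u_t[bd] = inf_cap
    return SegGraph(u_s=u_s, u_t=u_t, nlinks=nlinks, inf_cap=float(inf_cap))


def _finite_max_capacity(graph: SegGraph) -> float:
    caps = [graph.u_s[graph.u_s < graph.inf_cap],
            graph.u_t[graph.u_t < graph.inf_cap]]
    finite = max(
        [float(c.max()) if c.size else 0.0 for c in caps]
        + [float(c.max()) for c in graph.nlinks.values()]
    )
    return finite


def labeling_energy(graph: SegGraph, mask: np.ndarray) -> float:
    """E(L) of a labeling with the graph's float capacities: severed
    t-links (u_t on foreground, u_s on background) plus n-links across the
    boundary, each unordered pair counted once."""
    mask = np.asarray(mask, dtype=bool)
    energy = float(graph.u_t[mask].sum() + graph.u_s[~mask].sum())
    H, W = mask.shape
    for (dr, dc), cap in graph.nlinks.items():
        rs = slice(0, H - dr)
        cs = slice(0, W - dc) if dc >= 0 else slice(-dc, W)
        ns = slice(dr, H)
        ncs = slice(dc, W) if dc >= 0 else slice(0, W + dc)
        cut = mask[rs, cs] != mask[ns, ncs]
        energy += float(cap[rs, cs][cut].sum())
    return energy


#: Integer stand-in for infinite capacity inside the solver; the
#: fixed-point scale is chosen so any achievable flow stays below 2^30,
#: hence no minimum cut can afford to sever an edge of this capacity.
INF_UNITS = 2**31 - 1


def quantize_capacity(caps: np.ndarray, scale: float,
                      inf_cap: Optional[float] = None) -> np.ndarray:
    """Round capacities onto the fixed-point integer grid used by the
    max-flow solver; capacities at ``inf_cap`` map to ``INF_UNITS``."""
    caps = np.asarray(caps, dtype=np.float64)
    q = np.rint(caps * scale).astype(np.int64)
    if inf_cap is not None:
        q = np.where(caps >= inf_cap, np.int64(INF_UNITS), q)
    return q


def _flow_bound(graph: SegGraph) -> float:
    """A finite upper bound on the max flow: the cheaper of the two
    all-seed cuts ({source + F_d} vs {sink + B_d})."""
    fd = graph.u_s >= graph.inf_cap
    bd = graph.u_t >= graph.inf_cap
    b_src = float(graph.u_s[~fd].sum())
    b_snk = float(graph.u_t[~bd].sum())
    H, W = fd.shape
    for (dr, dc), cap in graph.nlinks.items():
        rs = slice(0, H - dr)
        cs = slice(0, W - dc) if dc >= 0 else slice(-dc, W)
        ns = slice(dr, H)
        ncs = slice(dc, W) if dc >= 0 else slice(0, W + dc)
        boundary_f = fd[rs, cs] != fd[ns, ncs]
        boundary_b = bd[rs, cs] != bd[ns, ncs]
        b_src += float(cap[rs, cs][boundary_f].sum())
        b_snk += float(cap[rs, cs][boundary_b].sum())
    return min(b_src, b_snk)


def min_cut_segment(graph: SegGraph) -> SegmentationResult:
    """Exact min-cut via integer max-flow; source side -> foreground.

    Finite capacities are represented in fixed point, scaled so that the
    achievable flow stays below 2^30 (the solver works in 32-bit units);
    seed t-links get ``INF_UNITS``, which no minimum cut can then include.
    The integer flow equals the integer cut capacity exactly.  Pixels
    reachable from the source in the residual graph become foreground; the
    returned ``energy`` re-evaluates E(L) of that labeling with the
    original float capacities.
    """
    H, W = graph.u_s.shape
    n = H * W
    source, sink = n, n + 1

    denom = max(_finite_max_capacity(graph), _flow_bound(graph))
    scale = (2.0**30) / denom if denom > 0 else 1.0

    idx = np.arange(n).reshape(H, W)
    rows_l, cols_l, data_l = [], [], []

    us_q = quantize_capacity(graph.u_s, scale, graph.inf_cap).ravel()
    ut_q = quantize_capacity(graph.u_t, scale, graph.inf_cap).ravel()
    nz = us_q > 0
    rows_l.append(np.full(nz.sum(), source))
    cols_l.append(np.flatnonzero(nz))
    data_l.append(us_q[nz])
    nz = ut_q > 0
    rows_l.append(np.flatnonzero(nz))
    cols_l.append(np.full(nz.sum(), sink))
    data_l.append(ut_q[nz])

    for (dr, dc), cap in graph.nlinks.items():
        rs = slice(0, H - dr)
        cs = slice(0, W - dc) if dc >= 0 else slice(-dc, W)
        ns = slice(dr, H)
        ncs = slice(dc, W) if dc >= 0 else slice(0, W + dc)
        cap_q = quantize_capacity(cap[rs, cs], scale).ravel()
        p = idx[rs, cs].ravel()
        q = idx[ns, ncs].ravel()
        nz = cap_q > 0
        rows_l.extend([p[nz], q[nz]])
        cols_l.extend([q[nz], p[nz]])
        data_l.extend([cap_q[nz], cap_q[nz]])

    capacity = sparse.csr_matrix(
        (np.concatenate(data_l),
         (np.concatenate(rows_l), np.concatenate(cols_l))),
        shape=(n + 2, n + 2), dtype=np.int64)
    result = maximum_flow(capacity, source, sink)

    residual = capacity - result.flow
    residual.data = np.where(residual.data > 0, 1, 0).astype(np.int8)
    residual.eliminate_zeros()
    reachable = breadth_first_order(residual, source, directed=True,
                                    return_predecessors=False)
    mask = np.zeros(n, dtype=bool)
    mask[reachable[reachable < n]] = True
    mask = mask.reshape(H, W)

    energy = labeling_energy(graph, mask)
    return SegmentationResult(
        mask=mask, energy=energy,
        flow=float(result.flow_value) / scale,
        flow_units=int(result.flow_value), capacity_scale=scale,
    )


# --------------------------------------------------------------------------
# End-to-end pipeline
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every tunable of the four-stage pipeline, with working defaults.

    ``None`` values are resolved adaptively at run time: NLM strength ``h``
    from the noise level of the likeness map, ``t_h`` by Otsu's method on
    the positive symmetric likeness, ``t_l`` as half of ``t_h``, and the
    vote normalization ``m_n`` as the accumulator maximum.
    """

    # input
    channel_policy: str = "green"
    # enhancement
    scales: tuple = DEFAULT_SCALES
    c: float = DEFAULT_C
    gamma: float = 2.0
    dark_only: bool = False
    # nonlocal means
    search_radius: int = 7
    patch_radius: int = 2
    h: Optional[float] = None
    h_sigma_factor: float = 10.0
    filter_first: bool = False
    # radial symmetry
    delta_r: float = 1.0
    angle_tol: float = 15.0
    q: float = 2.0
    m_n: Optional[float] = None
    # coarse extraction
    t_h: Optional[float] = None
    erosion_radius: int = 1
    t_num: int = 30
    # graph cut
    t_l: Optional[float] = None
    t_l_factor: float = 0.5
    w1: float = 2.0
    w2: float = 0.5
    k: float = 1.0
    eta: float = 0.01
    metric: str = "euclidean"
    use_db_for_bc: bool = False
    nlink_intensity: str = "nl"  # or "raw"
    inf_cap: Optional[float] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.scales, list):
            cfg.scales = tuple(cfg.scales)
        return cfg

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["scales"] = list(self.scales)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def segment(image: Image2D, config: Optional[PipelineConfig] = None,
            return_stages: bool = False):
    """Run enhancement -> NLM -> symmetry transform -> coarse extraction ->
    seeding -> graph cut on a gray fundus image.

    An FOV mask on the input restricts the segmentation: outside-FOV pixels
    are forced to definite background.  If either definite seed set comes
    out empty (no structure found, or nothing below T_l), the coarse mask
    is returned unchanged with a warning — the graph problem is degenerate.

    With ``return_stages`` a dict of intermediate maps is returned
    alongside the result.
    """
    cfg = config or PipelineConfig()
    gray = image.pixels

    if cfg.filter_first:
        h0 = cfg.h or max(cfg.h_sigma_factor * estimate_noise_sigma(gray), 1e-6)
        params = NlmParams(cfg.search_radius, cfg.patch_radius, h0)
        gray = nlm_denoise(gray, params)

    ss = multiscale_enhance(gray, scales=cfg.scales, c=cfg.c,
                            gamma=cfg.gamma, dark_only=cfg.dark_only)
    vl = ss.vl
    vl_max = float(vl.max())
    if vl_max > 0:
        vl = vl / vl_max  # common [0,1] footing for h, T_h, and t-links

    if cfg.filter_first:
        nl = vl
    else:
        h = cfg.h or max(cfg.h_sigma_factor * estimate_noise_sigma(vl), 1e-6)
        params = NlmParams(cfg.search_radius, cfg.patch_radius, h)
        nl = nlm_denoise(vl, params)

    sym = radial_symmetry_transform(nl, ss.opt_scale, delta_r=cfg.delta_r,
                                    angle_tol=cfg.angle_tol, q=cfg.q,
                                    m_n=cfg.m_n)
    coarse = extract_coarse(sym.vl_sym, t_h=cfg.t_h,
                            erosion_radius=cfg.erosion_radius,
                            t_num=cfg.t_num)
    centerline = extract_centerline(coarse)
    t_h = coarse.t_h if np.isfinite(coarse.t_h) else 1.0
    t_l = cfg.t_l if cfg.t_l is not None else cfg.t_l_factor * t_h

    seeds = assign_seeds(sym.vl_sym, centerline, t_h=t_h, t_l=t_l)
    if image.fov_mask is not None:
        seeds.labels[~image.fov_mask] = B_D
        seeds.centerline &= image.fov_mask
        seeds.labels[seeds.centerline] = F_D

    stages = {
        "gray": gray, "vl": vl, "opt_scale": ss.opt_scale, "nl": nl,
        "accumulator": sym.accumulator, "flag": sym.flag,
        "vl_sym": sym.vl_sym, "coarse": coarse.mask,
        "centerline": centerline, "seeds": seeds,
    }

    fg_ok = (seeds.labels == F_D).any()
    bg_ok = (seeds.labels == B_D).any()
    if not (fg_ok and bg_ok):
        warnings.warn("degenerate seeds (empty F_d or B_d); returning the "
                      "coarse mask without graph-cut refinement")
        result = SegmentationResult(mask=coarse.mask, energy=float("nan"),
                                    flow=float("nan"))
        return (result, stages) if return_stages else result

    dist = seed_distances(seeds, metric=cfg.metric, intensity=nl)
    intensity = nl if cfg.nlink_intensity == "nl" else image.pixels
    graph = build_graph(intensity, seeds, dist, sym.vl_sym,
                        w1=cfg.w1, w2=cfg.w2, k=cfg.k, eta=cfg.eta,
                        inf_cap=cfg.inf_cap, use_db_for_bc=cfg.use_db_for_bc)
    result = min_cut_segment(graph)
    stages["graph"] = graph
    return (result, stages) if return_stages else result
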
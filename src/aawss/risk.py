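"""Clinical binning and joint-criterion rupture-site mapping.

Per-node indices are binned into the ranges used for cohort reporting
(TAWSS 0-0.5 / 0.5-1.0 Pa; OSI 0.20-0.35 / 0.35-0.50; ECAP 0.2-0.8 /
0.8-1.2 / 1.2-1.6 / 1.6-2.0 1/Pa; RRT 18-24 / 24-30), and candidate
rupture sites are the contiguous surface patches where the joint
four-parameter criterion holds simultaneously:

    TAWSS in [0, 0.5] Pa  AND  OSI in [0.35, 0.5]  AND
    ECAP in [1.6, 2.0] 1/Pa  AND  RRT in [24, 30].

Bin intervals are half-open [lo, hi); the topmost bin is closed above
after display clamping, and values beyond the top edge land in the top
bin with an overflow flag (mirroring contour plots whose color scale is
capped).  Patches are maximal edge-connected components of the node mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .mesh import VesselMesh
from .metrics import DISPLAY_MAX, HemodynamicFields

BELOW_RANGE = "below-range"

DEFAULT_BINS = {
    "tawss": [(0.0, 0.5), (0.5, 1.0)],
    "osi": [(0.20, 0.35), (0.35, 0.50)],
    "ecap": [(0.2, 0.8), (0.8, 1.2), (1.2, 1.6), (1.6, 2.0)],
    "rrt": [(18.0, 24.0), (24.0, 30.0)],
}

#: the joint rupture criterion: one bin per parameter
DEFAULT_JOINT = {"tawss": (0.0, 0.5), "osi": (0.35, 0.50),
                 "ecap": (1.6, 2.0), "rrt": (24.0, 30.0)}


def bin_label(lo: float, hi: float) -> str:
    return f"{lo:g}-{hi:g}"


@dataclass(frozen=True)
class RiskThresholds:
    bins: dict = field(default_factory=lambda: dict(DEFAULT_BINS))
    joint: dict = field(default_factory=lambda: dict(DEFAULT_JOINT))

    def __post_init__(self):
        for par, bs in self.bins.items():
            for (a, b) in bs:
                if not b > a:
                    raise ValueError(f"{par}: empty bin ({a}, {b})")
            for (a0, b0), (a1, b1) in zip(bs, bs[1:]):
                if a1 < b0:
                    raise ValueError(f"{par}: overlapping/unordered bins")
        for par, (a, b) in self.joint.items():
            if par not in self.bins or (a, b) not in self.bins[par]:
                raise ValueError(
                    f"joint criterion bin {par} ({a}, {b}) is not one of the "
                    "declared bins")


def bin_parameter(values: np.ndarray, bins: list[tuple]):
    """Assign each value a bin label (half-open [lo, hi), top bin closed).

    Returns (labels, overflow) where ``labels`` holds the bin label,
    ``BELOW_RANGE`` for values under the lowest edge, and ``overflow``
    flags values beyond the top edge (assigned to the top bin, matching
    display clamping).
    """
    v = np.asarray(values, dtype=float)
    labels = np.full(v.shape, BELOW_RANGE, dtype=object)
    overflow = np.zeros(v.shape, dtype=bool)
    for lo, hi in bins:
        labels[(v >= lo) & (v < hi)] = bin_label(lo, hi)
    top_lo, top_hi = bins[-1]
    labels[v >= top_hi] = bin_label(top_lo, top_hi)
    overflow[v > top_hi] = True
    labels[v == top_hi] = bin_label(top_lo, top_hi)  # top bin closed above
    return labels, overflow


def joint_risk_mask(fields: HemodynamicFields,
                    thresholds: RiskThresholds = RiskThresholds()) -> np.ndarray:
    """True where all four criterion conditions hold simultaneously;
    flagged (undefined/infinite) nodes are excluded."""
    j = thresholds.joint

    def in_bin(v, b):
        return (v >= b[0]) & (v <= b[1])

    mask = (in_bin(fields.tawss, j["tawss"]) & in_bin(fields.osi, j["osi"]) &
            in_bin(fields.ecap, j["ecap"]) & in_bin(fields.rrt, j["rrt"]))
    mask &= ~fields.undefined_osi & ~fields.infinite_rrt
    return mask


@dataclass(frozen=True)
class RiskMap:
    mask: np.ndarray
    patches: list          # list of dicts: nodes, area_m2, modal_bins
    dropped: list          # sub-min-area patches, same structure
    patch_id: np.ndarray   # per-node patch index (-1 outside)


def extract_patches(mask: np.ndarray, mesh: VesselMesh,
                    fields: HemodynamicFields | None = None,
                    thresholds: RiskThresholds = RiskThresholds(),
                    min_area: float = 25e-6) -> RiskMap:
    """Maximal edge-connected components of the masked nodes.

    Two masked nodes are connected when they share a mesh edge (vertex-only
    contact never bridges patches).  Patches below ``min_area`` (m^2,
    default 25 mm^2) are reported separately in ``dropped``.  Patches are
    sorted by area descending, ties broken by lowest node index.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (mesh.n_nodes,):
        raise ValueError("mask must align with mesh nodes")
    idx = np.flatnonzero(mask)
    patch_id = np.full(mesh.n_nodes, -1, dtype=int)
    if len(idx) == 0:
        return RiskMap(mask=mask, patches=[], dropped=[], patch_id=patch_id)
    e = mesh.edges()
    keep = mask[e[:, 0]] & mask[e[:, 1]]
    e = e[keep]
    remap = -np.ones(mesh.n_nodes, dtype=int)
    remap[idx] = np.arange(len(idx))
    n = len(idx)
    g = coo_matrix((np.ones(len(e)), (remap[e[:, 0]], remap[e[:, 1]])),
                   shape=(n, n))
    ncomp, lab = connected_components(g, directed=False)
    comps = []
    for c in range(ncomp):
        nodes = idx[lab == c]
        area = float(mesh.node_areas[nodes].sum())
        comps.append({"nodes": nodes, "area_m2": area})
    comps.sort(key=lambda p: (-p["area_m2"], int(p["nodes"].min())))
    patches, dropped = [], []
    for p in comps:
        if fields is not None:
            p["modal_bins"] = roi_summary(fields, p["nodes"], thresholds)
        (patches if p["area_m2"] >= min_area else dropped).append(p)
    for i, p in enumerate(patches):
        patch_id[p["nodes"]] = i
    return RiskMap(mask=mask, patches=patches, dropped=dropped,
                   patch_id=patch_id)


def roi_summary(fields: HemodynamicFields, roi: np.ndarray,
                thresholds: RiskThresholds = RiskThresholds()) -> dict:
    """Area-weighted modal bin of each parameter within a region of
    interest — the single range entry reported per patient and parameter."""
    roi = np.asarray(roi, dtype=int)
    if len(roi) == 0:
        raise ValueError("ROI is empty")
    w = fields.mesh.node_areas[roi]
    out = {}
    for par in ("tawss", "osi", "ecap", "rrt"):
        vals = getattr(fields, par)[roi]
        vals = np.minimum(vals, DISPLAY_MAX[par])  # clamp before binning
        labels, _ = bin_parameter(vals, thresholds.bins[par])
        uniq = sorted(set(labels.tolist()))
        weights = {u: float(w[labels == u].sum()) for u in uniq}
        out[par] = max(uniq, key=lambda u: weights[u])
    return out


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard overlap of two node-index sets."""
    sa, sb = set(np.asarray(a).tolist()), set(np.asarray(b).tolist())
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)
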
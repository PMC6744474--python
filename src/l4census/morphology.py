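"""Neuronal morphology: SWC reading, preprocessing, density maps, morphometrics.

Reconstructions are rooted trees of 3-D points (standard 7-column SWC).
The axis convention follows slice electrophysiology: X is horizontal within
the slice, Y is the slice-depth dimension (the noisiest one, smoothed
during preprocessing), and Z is cortical depth. Two feature representations
are computed per cell: a smoothed 100x100 histogram of points sampled
densely along the neurites, projected on the XZ plane and jointly
normalized across a cohort (the "density map"), and a set of 16 summary
morphometrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import convolve
from scipy.signal import savgol_filter

__all__ = [
    "Morphology",
    "SWCError",
    "read_swc",
    "write_swc",
    "preprocess",
    "density_map",
    "gaussian_kernel_2d",
    "morphometrics",
    "MORPHOMETRIC_NAMES",
]

SOMA = 1

MORPHOMETRIC_NAMES = (
    "n_branch_points",
    "width",
    "depth",
    "height",
    "n_tips",
    "n_stems",
    "total_length",
    "max_neurite_length",
    "max_branch_order",
    "max_segment_length",
    "avg_tortuosity",
    "max_tortuosity",
    "avg_branch_angle",
    "max_branch_angle",
    "avg_path_angle",
    "max_path_angle",
)


class SWCError(ValueError):
    """Raised on malformed SWC content; the message names offending lines/nodes."""


@dataclass
class Morphology:
    """A reconstruction as a node table (id, struct, x, y, z, radius, parent).

    The parent of a root is -1. Node ids are unique; parent references form
    a forest rooted at the soma.
    """

    nodes: pd.DataFrame

    def __post_init__(self):
        df = self.nodes
        required = ["id", "struct", "x", "y", "z", "radius", "parent"]
        if list(df.columns) != required:
            df = df[required]
        ids = df["id"].to_numpy()
        if np.unique(ids).size != ids.size:
            dup = df["id"][df["id"].duplicated()].tolist()
            raise SWCError(f"duplicate node ids: {dup}")
        if not np.all(np.isfinite(df[["x", "y", "z"]].to_numpy())):
            raise SWCError("non-finite coordinates")
        id_set = set(ids.tolist())
        orphans = [
            int(i)
            for i, p in zip(ids, df["parent"])
            if p != -1 and int(p) not in id_set
        ]
        if orphans:
            raise SWCError(f"nodes referencing missing parents: {orphans}")
        self.nodes = df.reset_index(drop=True)
        self._index = {int(i): k for k, i in enumerate(ids)}
        self._children: dict[int, list[int]] = {int(i): [] for i in ids}
        for i, p in zip(ids, df["parent"]):
            if p != -1:
                self._children[int(p)].append(int(i))
        roots = [int(i) for i, p in zip(ids, df["parent"]) if p == -1]
        if not roots:
            raise SWCError("no root node (parent == -1)")
        self.roots = roots
        self._check_acyclic()

    def _check_acyclic(self):
        seen: set[int] = set()
        stack = list(self.roots)
        while stack:
            n = stack.pop()
            if n in seen:
                raise SWCError(f"cycle detected at node {n}")
            seen.add(n)
            stack.extend(self._children[n])
        missing = set(self._index) - seen
        if missing:
            raise SWCError(f"cycle or disconnected loop involving nodes {sorted(missing)}")

    # -- accessors ---------------------------------------------------------

    def xyz(self, node_id: int) -> np.ndarray:
        row = self.nodes.iloc[self._index[node_id]]
        return np.array([row["x"], row["y"], row["z"]], dtype=float)

    def children(self, node_id: int) -> list[int]:
        return self._children[node_id]

    @property
    def root(self) -> int:
        return self.roots[0]

    def soma_position(self) -> np.ndarray:
        soma = self.nodes[self.nodes["struct"] == SOMA]
        if len(soma):
            return soma[["x", "y", "z"]].to_numpy(dtype=float).mean(axis=0)
        return self.xyz(self.root)

    def segments(self) -> list[list[int]]:
        """Decompose into segments: node-id paths between branch points/tips.

        Each segment starts at the root or a branch point and ends at the
        next branch point or tip, inclusive of both endpoints.
        """
        segs = []
        for root in self.roots:
            stack = [(root, c) for c in self._children[root]]
            while stack:
                start, nxt = stack.pop()
                path = [start, nxt]
                while len(self._children[nxt]) == 1:
                    nxt = self._children[nxt][0]
                    path.append(nxt)
                segs.append(path)
                for c in self._children[nxt]:
                    stack.append((nxt, c))
        return segs

    def segment_coords(self) -> list[np.ndarray]:
        xyz = self.nodes[["x", "y", "z"]].to_numpy(dtype=float)
        return [np.array([xyz[self._index[i]] for i in seg]) for seg in self.segments()]


# ---------------------------------------------------------------------------
# SWC I/O


def read_swc(path) -> Morphology:
    """Parse a whitespace-delimited 7-column SWC file with validation."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCError(f"line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                rows.append(
                    (
                        int(parts[0]),
                        int(parts[1]),
                        float(parts[2]),
                        float(parts[3]),
                        float(parts[4]),
                        float(parts[5]),
                        int(parts[6]),
                    )
                )
            except ValueError as exc:
                raise SWCError(f"line {lineno}: {exc}") from None
    if not rows:
        raise SWCError("empty SWC file")
    df = pd.DataFrame(rows, columns=["id", "struct", "x", "y", "z", "radius", "parent"])
    return Morphology(df)


def write_swc(m: Morphology, path) -> None:
    with open(path, "w") as fh:
        for _, r in m.nodes.iterrows():
            fh.write(
                f"{int(r['id'])} {int(r['struct'])} {float(r['x'])!r} {float(r['y'])!r} "
                f"{float(r['z'])!r} {float(r['radius'])!r} {int(r['parent'])}\n"
            )


# ---------------------------------------------------------------------------
# preprocessing


def _resample_polyline(coords: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline to uniform arclength spacing, keeping both endpoints."""
    d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(d)])
    length = arc[-1]
    if length <= spacing:
        return coords[[0, -1]].copy()
    n = int(np.floor(length / spacing))
    s = np.arange(0, (n + 1)) * spacing
    if length - s[-1] > 1e-9:
        s = np.concatenate([s, [length]])
    else:
        s[-1] = length
    out = np.empty((s.size, 3))
    for k in range(3):
        out[:, k] = np.interp(s, arc, coords[:, k])
    return out


def preprocess(
    m: Morphology,
    spacing: float = 1.0,
    window: int = 21,
    polyorder: int = 3,
) -> Morphology:
    """Soma-center, resample neurites to 1 um spacing, smooth Y (slice depth).

    Each segment is resampled to uniform arclength spacing and its Y
    coordinate is filtered with a Savitzky-Golay filter (order 3, window 21,
    shortened for segments with fewer points). Branch-point and tip
    coordinates are pinned so the topology is preserved exactly. Segments
    shorter than one spacing unit are kept as their two endpoints,
    unsmoothed.
    """
    soma = m.soma_position()
    segs = m.segments()
    xyz = {int(i): m.xyz(int(i)) - soma for i in m.nodes["id"]}

    new_rows = []
    next_id = 1
    node_map: dict[int, int] = {}
    root = m.root
    root_row = m.nodes.iloc[m._index[root]]
    new_rows.append((next_id, int(root_row["struct"]), *xyz[root], float(root_row["radius"]), -1))
    node_map[root] = next_id
    next_id += 1

    struct_of = dict(zip(m.nodes["id"].astype(int), m.nodes["struct"].astype(int)))
    radius_of = dict(zip(m.nodes["id"].astype(int), m.nodes["radius"].astype(float)))

    for seg in segs:
        coords = np.array([xyz[i] for i in seg])
        rs = _resample_polyline(coords, spacing)
        if rs.shape[0] > polyorder + 1:
            w = min(window, rs.shape[0] if rs.shape[0] % 2 == 1 else rs.shape[0] - 1)
            if w > polyorder:
                y = savgol_filter(rs[:, 1], w, polyorder, mode="interp")
                rs = rs.copy()
                rs[1:-1, 1] = y[1:-1]  # pin endpoints: branch points stay shared
        start_old, end_old = seg[0], seg[-1]
        parent_new = node_map[start_old]
        struct = struct_of[end_old]
        radius = radius_of[end_old]
        for p in rs[1:-1]:
            new_rows.append((next_id, struct, *p, radius, parent_new))
            parent_new = next_id
            next_id += 1
        new_rows.append((next_id, struct, *rs[-1], radius, parent_new))
        node_map[end_old] = next_id
        next_id += 1

    df = pd.DataFrame(new_rows, columns=["id", "struct", "x", "y", "z", "radius", "parent"])
    return Morphology(df)


# ---------------------------------------------------------------------------
# density maps


def gaussian_kernel_2d(size: int = 11, sigma: float = 2.0) -> np.ndarray:
    """Truncated, unit-mass Gaussian kernel on a size x size bin grid."""
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def _sample_points(m: Morphology, spacing: float) -> np.ndarray:
    pts = []
    for coords in m.segment_coords():
        d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(d)])
        if arc[-1] <= 0:
            pts.append(coords[:1])
            continue
        s = np.arange(0.0, arc[-1] + spacing / 2, spacing)
        out = np.empty((s.size, 3))
        for k in range(3):
            out[:, k] = np.interp(s, arc, coords[:, k])
        pts.append(out)
    if not pts:
        raise ValueError("morphology has no neurites to sample")
    return np.vstack(pts)


def density_map(
    cells: list[Morphology],
    bins: int = 100,
    extent: tuple[float, float] = (-0.1, 1.1),
    sampling: float = 0.1,
    kernel_size: int = 11,
    kernel_sigma: float = 2.0,
    smooth: bool = True,
) -> list[np.ndarray]:
    """Per-cell smoothed XZ density maps with joint normalization.

    Points are sampled every 100 nm along each neurite of every cell; one
    global minimum and maximum over all coordinate values of all cells maps
    the joint cloud into [0, 1] (uniform scale, aspect preserved). Each
    cell's points are projected on the XZ plane, binned into a
    ``bins x bins`` histogram spanning ``extent`` on both axes, and
    convolved with a truncated Gaussian kernel (mass may leak over the map
    border for clouds near the edge).
    """
    if not cells:
        raise ValueError("need at least one cell")
    clouds = [_sample_points(m, sampling) for m in cells]
    allpts = np.vstack(clouds)
    gmin = float(allpts.min())
    gmax = float(allpts.max())
    if gmax <= gmin:
        raise ValueError("degenerate point cloud: cannot normalize")
    kern = gaussian_kernel_2d(kernel_size, kernel_sigma)
    maps = []
    for cloud in clouds:
        norm = (cloud - gmin) / (gmax - gmin)
        h, _, _ = np.histogram2d(
            norm[:, 0], norm[:, 2], bins=bins, range=[list(extent), list(extent)]
        )
        if smooth:
            h = convolve(h, kern, mode="constant", cval=0.0)
        maps.append(h)
    return maps


# ---------------------------------------------------------------------------
# morphometrics


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return np.nan
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def morphometrics(m: Morphology) -> pd.Series:
    """The 16 summary statistics of a (preprocessed) reconstruction.

    Counts: branch points (non-root nodes with >= 2 children), tips, stems
    (children of the root). Extents: width/depth/height along X/Y/Z.
    Lengths: total neurite length, maximal root-to-tip path length, maximal
    segment length. Branch order starts at 0 for stems and increments at
    each branch point. Tortuosity is segment path length over end-to-end
    distance. Branch angles are measured between sibling directions at each
    branch point, path angles between successive steps along the neurite.
    """
    root = m.root
    xyz = m.nodes[["x", "y", "z"]].to_numpy(dtype=float)
    idx = m._index
    ids = m.nodes["id"].astype(int).tolist()

    n_stems = len(m.children(root))
    n_branch = sum(1 for i in ids if i != root and len(m.children(i)) >= 2)
    n_tips = sum(1 for i in ids if i != root and len(m.children(i)) == 0)

    ext = xyz.max(axis=0) - xyz.min(axis=0) if len(ids) > 1 else np.zeros(3)

    segs = m.segments()
    seg_lengths, torts = [], []
    total = 0.0
    for seg in segs:
        coords = np.array([xyz[idx[i]] for i in seg])
        d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        L = float(d.sum())
        seg_lengths.append(L)
        total += L
        chord = float(np.linalg.norm(coords[-1] - coords[0]))
        torts.append(L / chord if chord > 0 else np.nan)

    # root-to-tip path lengths and branch order by traversal
    path_len = {root: 0.0}
    order = {root: 0}
    stack = list(m.children(root))
    for c in stack:
        order[c] = 0
    max_path = 0.0
    max_order = 0
    stack = [(root, c) for c in m.children(root)]
    while stack:
        p, n = stack.pop()
        step = float(np.linalg.norm(xyz[idx[n]] - xyz[idx[p]]))
        path_len[n] = path_len[p] + step
        kids = m.children(n)
        o = order.get(n, order.get(p, 0))
        if len(kids) >= 2:
            for c in kids:
                order[c] = o + 1
            max_order = max(max_order, o + 1)
        else:
            for c in kids:
                order[c] = o
        if not kids:
            max_path = max(max_path, path_len[n])
        stack.extend((n, c) for c in kids)

    branch_angles = []
    for i in ids:
        if i == root:
            continue
        kids = m.children(i)
        if len(kids) >= 2:
            dirs = [xyz[idx[c]] - xyz[idx[i]] for c in kids]
            pair_angles = [
                _angle_deg(dirs[a], dirs[b])
                for a in range(len(dirs))
                for b in range(a + 1, len(dirs))
            ]
            pair_angles = [a for a in pair_angles if not np.isnan(a)]
            if pair_angles:
                branch_angles.append(float(np.mean(pair_angles)))

    parent_of = dict(zip(ids, m.nodes["parent"].astype(int)))
    path_angles = []
    for i in ids:
        p = parent_of[i]
        if p == -1 or p == root:
            continue
        u = xyz[idx[i]] - xyz[idx[p]]
        for c in m.children(i):
            a = _angle_deg(u, xyz[idx[c]] - xyz[idx[i]])
            if not np.isnan(a):
                path_angles.append(a)

    torts_ok = [t for t in torts if not np.isnan(t)]
    values = {
        "n_branch_points": n_branch,
        "width": float(ext[0]),
        "depth": float(ext[1]),
        "height": float(ext[2]),
        "n_tips": n_tips,
        "n_stems": n_stems,
        "total_length": total,
        "max_neurite_length": max_path,
        "max_branch_order": max_order,
        "max_segment_length": max(seg_lengths) if seg_lengths else 0.0,
        "avg_tortuosity": float(np.mean(torts_ok)) if torts_ok else np.nan,
        "max_tortuosity": float(np.max(torts_ok)) if torts_ok else np.nan,
        "avg_branch_angle": float(np.mean(branch_angles)) if branch_angles else np.nan,
        "max_branch_angle": float(np.max(branch_angles)) if branch_angles else np.nan,
        "avg_path_angle": float(np.mean(path_angles)) if path_angles else np.nan,
        "max_path_angle": float(np.max(path_angles)) if path_angles else np.nan,
    }
    return pd.Series(values, index=list(MORPHOMETRIC_NAMES))
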
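"""Cell detection and centerline ("mesh") extraction in physical units.

A frame is thresholded (Otsu), connected components become
:class:`CellMask` objects, and each mask is reduced to a
:class:`CellMesh`: a closed outline polygon plus an ordered centerline
from pole A tip to pole B tip, with cumulative arc length and a local
width (twice the distance-transform value) at every centerline point.
Position 0 of the arc-length coordinate is the geometric pole tip — the
sub-pixel intersection of the extended centerline with the cell outline —
so axial profiles can later be aligned tip-to-tip across cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

__all__ = [
    "CellMask",
    "CellMesh",
    "AxialProfile",
    "segment_frame",
    "extract_mesh",
    "axial_profile",
    "mesh_width",
]


@dataclass
class CellMask:
    """One segmented cell: a 4-connected pixel component."""

    label: int
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) exclusive
    crop: np.ndarray  # bool array of shape (max_row-min_row, max_col-min_col)

    @property
    def area(self) -> int:
        return int(self.crop.sum())

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.crop
        return out

    @property
    def top_left_pixel(self) -> tuple[int, int]:
        rows, cols = np.nonzero(self.crop)
        order = np.lexsort((cols, rows))
        i = order[0]
        return (int(rows[i]) + self.bbox[0], int(cols[i]) + self.bbox[1])


@dataclass
class CellMesh:
    """Outline + centerline coordinate system of one cell (µm)."""

    cell_id: int
    outline: np.ndarray  # (N, 2) closed polygon, columns (x, y) µm
    centerline: np.ndarray  # (M, 2) ordered pole A tip -> pole B tip, µm
    arc_length: np.ndarray  # (M,) cumulative µm, arc_length[0] == 0
    local_width: np.ndarray  # (M,) µm
    pixel_size: float
    degenerate: bool = False

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    @property
    def tip_a(self) -> np.ndarray:
        return self.centerline[0]

    @property
    def tip_b(self) -> np.ndarray:
        return self.centerline[-1]

    def reversed(self) -> "CellMesh":
        """The same mesh with poles A and B relabeled."""
        L = self.length
        return CellMesh(
            self.cell_id,
            self.outline,
            self.centerline[::-1].copy(),
            (L - self.arc_length[::-1]).copy(),
            self.local_width[::-1].copy(),
            self.pixel_size,
            self.degenerate,
        )


@dataclass
class AxialProfile:
    """Intensity sampled along the centerline, µm from the pole A tip."""

    cell_id: int
    channel: str
    positions: np.ndarray  # uniform, positions[0] == 0, last == length
    values: np.ndarray

    @property
    def length(self) -> float:
        return float(self.positions[-1])

    @property
    def step(self) -> float:
        return float(self.positions[1] - self.positions[0])

    def reversed(self) -> "AxialProfile":
        return AxialProfile(
            self.cell_id, self.channel, self.positions.copy(), self.values[::-1].copy()
        )


def segment_frame(
    frame: np.ndarray,
    min_area: int = 80,
    max_area: int | None = None,
    polarity: str = "auto",
) -> list[CellMask]:
    """Otsu threshold + 4-connected components, filtered by area.

    ``polarity`` selects which side of the threshold is foreground:
    "bright" (fluorescence), "dark" (phase contrast) or "auto" (the
    minority side — correct for dilute fields in either modality).
    Masks are relabeled 1..n ordered by their top-most, then left-most
    pixel.  A constant frame yields an empty list.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("segment_frame expects a single-channel 2D raster")
    if frame.max() == frame.min():
        return []
    thr = threshold_otsu(frame)
    bright = frame > thr
    if polarity == "bright":
        fg = bright
    elif polarity == "dark":
        fg = ~bright
    elif polarity == "auto":
        fg = bright if bright.sum() <= bright.size / 2 else ~bright
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    fg = ndimage.binary_fill_holes(fg)
    labels = measure.label(fg, connectivity=1)
    masks: list[CellMask] = []
    for rp in measure.regionprops(labels):
        if rp.area < min_area:
            continue
        if max_area is not None and rp.area > max_area:
            continue
        r0, c0, r1, c1 = rp.bbox
        masks.append(CellMask(label=0, bbox=(r0, c0, r1, c1), crop=rp.image.copy()))
    masks.sort(key=lambda m: m.top_left_pixel)
    for i, m in enumerate(masks):
        m.label = i + 1
    return masks


def _skeleton_longest_path(skel: np.ndarray) -> np.ndarray:
    """Longest geodesic path through an 8-connected skeleton (tree
    diameter by double BFS).  Returns (n, 2) array of (row, col)."""
    pts = np.argwhere(skel)
    if len(pts) == 0:
        return pts
    index = {tuple(p): i for i, p in enumerate(pts)}
    nbr_offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    adj: list[list[int]] = [[] for _ in pts]
    for i, (r, c) in enumerate(pts):
        for dr, dc in nbr_offsets:
            j = index.get((r + dr, c + dc))
            if j is not None:
                adj[i].append(j)

    def bfs(start: int):
        dist = np.full(len(pts), -1, dtype=int)
        parent = np.full(len(pts), -1, dtype=int)
        dist[start] = 0
        queue = [start]
        while queue:
            nxt = []
            for u in queue:
                for v in adj[u]:
                    if dist[v] < 0:
                        dist[v] = dist[u] + 1
                        parent[v] = u
                        nxt.append(v)
            queue = nxt
        far = int(np.argmax(dist))
        return far, dist, parent

    e1, _, _ = bfs(0)
    e2, _, parent = bfs(e1)
    path = [e2]
    while parent[path[-1]] >= 0:
        path.append(int(parent[path[-1]]))
    return pts[np.array(path[::-1])]


def _smooth_path(path: np.ndarray, window: int = 5) -> np.ndarray:
    if len(path) < window:
        return path.astype(float)
    pad = window // 2
    padded = np.vstack([path[:1].repeat(pad, 0), path, path[-1:].repeat(pad, 0)])
    kernel = np.ones(window) / window
    return np.column_stack(
        [np.convolve(padded[:, k], kernel, mode="valid") for k in range(2)]
    )


def _march_to_outline(
    start_rc: np.ndarray, direction_rc: np.ndarray, crop: np.ndarray, max_dist: float
) -> np.ndarray:
    """Sub-pixel point where a ray leaving the mask crosses its outline.

    Marches along ``direction_rc`` (unit, row/col) sampling the mask with
    bilinear interpolation; the 0.5-coverage crossing is refined by
    linear interpolation between the last inside and first outside step.
    """
    step = 0.2
    n = max(2, int(max_dist / step) + 2)
    ts = np.arange(n) * step
    pts = start_rc[None, :] + ts[:, None] * direction_rc[None, :]
    vals = ndimage.map_coordinates(
        crop.astype(np.float64), pts.T, order=1, mode="constant", cval=0.0
    )
    below = np.nonzero(vals < 0.5)[0]
    if len(below) == 0:
        return pts[-1]
    k = below[0]
    if k == 0:
        return start_rc
    v0, v1 = vals[k - 1], vals[k]
    frac = 0.0 if v1 >= v0 else (v0 - 0.5) / (v0 - v1)
    return pts[k - 1] + frac * step * direction_rc


def _chord_widths(path_f: np.ndarray, crop: np.ndarray, max_half_px: float) -> np.ndarray:
    """Transverse chord length (px) of the 0.5-coverage boundary at every
    centerline point: sample the mask along the local normal on both
    sides and linearly interpolate each crossing."""
    tx = np.gradient(path_f[:, 0])
    ty = np.gradient(path_f[:, 1])
    nrm = np.hypot(tx, ty)
    nrm[nrm == 0] = 1.0
    normals = np.column_stack([-ty / nrm, tx / nrm])
    step = 0.2
    m = max(2, int(np.ceil(max_half_px / step)))
    offs = np.arange(m + 1) * step
    out = np.empty(len(path_f))
    field = crop.astype(np.float64)
    for sign in (1.0, -1.0):
        pts = path_f[:, None, :] + sign * offs[None, :, None] * normals[:, None, :]
        vals = ndimage.map_coordinates(
            field, pts.reshape(-1, 2).T, order=1, mode="constant", cval=0.0
        ).reshape(len(path_f), -1)
        half = np.empty(len(path_f))
        for i, v in enumerate(vals):
            below = np.nonzero(v < 0.5)[0]
            if len(below) == 0:
                half[i] = offs[-1]
            elif below[0] == 0:
                half[i] = 0.0
            else:
                k = below[0]
                frac = (v[k - 1] - 0.5) / max(v[k - 1] - v[k], 1e-12)
                half[i] = offs[k - 1] + frac * step
        if sign > 0:
            out = half.copy()
        else:
            out += half
    return out


def extract_mesh(mask: CellMask, pixel_size: float) -> CellMesh:
    """Reduce a mask to an outline + pole-to-pole centerline.

    The centerline is the longest path of the morphological skeleton,
    smoothed and extended along its end tangents to the outline so that
    arc position 0 sits on the pole tip.  Local width is twice the
    Euclidean distance transform, sampled along the centerline.  Blob-like
    masks (skeleton shorter than the cell width) are flagged degenerate
    and fall back to the best-fit-ellipse major axis.
    """
    if mask.area < 20:
        raise ValueError(f"mask of {mask.area} px is too small for a mesh")
    pad = 3
    crop = np.pad(mask.crop, pad)
    # regularize the pixelated (and, with noise, ragged) boundary before
    # building the medial axis: a ragged edge grows skeleton spurs that
    # can hijack the longest path and park a "tip" on the cell side
    crop = ndimage.gaussian_filter(crop.astype(np.float64), 1.0) > 0.5
    if not crop.any():
        crop = np.pad(mask.crop, pad)
    offset_rc = np.array([mask.bbox[0] - pad, mask.bbox[1] - pad], dtype=float)
    edt = ndimage.distance_transform_edt(crop)
    width_guess_px = 2 * edt.max()

    skel = skeletonize(crop)
    path = _skeleton_longest_path(skel)
    from_ellipse = len(path) < 8  # too short for a reliable end tangent
    if from_ellipse:
        rp = measure.regionprops(crop.astype(int))[0]
        theta = rp.orientation  # angle of major axis vs row axis
        centroid = np.array(rp.centroid)
        d = np.array([np.cos(theta), np.sin(theta)])  # (row, col) direction
        reach = rp.axis_major_length / 2 + 3
        tip_a = _march_to_outline(centroid, -d, crop, reach)
        tip_b = _march_to_outline(centroid, d, crop, reach)
        n_mid = max(3, int(np.linalg.norm(tip_b - tip_a)))
        path_f = tip_a[None, :] + np.linspace(0, 1, n_mid)[:, None] * (tip_b - tip_a)
    else:
        path_f = _smooth_path(path.astype(float), window=5)
        # skeleton end pixels wander toward boundary bumps; trim them
        # before estimating the end tangents
        trim = min(3, max(0, (len(path_f) - 8) // 2))
        if trim:
            path_f = path_f[trim:-trim]
        # drop duplicate consecutive points introduced by smoothing
        keep = np.ones(len(path_f), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(path_f, axis=0), axis=1) > 1e-9
        path_f = path_f[keep]
        # extend each end along its tangent to the outline (sub-pixel
        # tip); a longer tangent baseline resists residual end wiggle
        k = min(8, len(path_f) - 1)
        tan_a = path_f[0] - path_f[k]
        tan_a /= np.linalg.norm(tan_a)
        tan_b = path_f[-1] - path_f[-1 - k]
        tan_b /= np.linalg.norm(tan_b)
        reach = width_guess_px + 3
        tip_a = _march_to_outline(path_f[0], tan_a, crop, reach)
        tip_b = _march_to_outline(path_f[-1], tan_b, crop, reach)
        path_f = np.vstack([tip_a, path_f, tip_b])

    # physical coordinates: x = col * ps, y = row * ps
    rc = path_f + offset_rc
    xy = np.column_stack([rc[:, 1], rc[:, 0]]) * pixel_size
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    widths = _chord_widths(path_f, crop, width_guess_px / 2 + 3) * pixel_size
    widths = np.maximum(widths, 1e-6)

    contours = measure.find_contours(crop.astype(float), 0.5)
    contour = max(contours, key=len) + offset_rc
    outline = np.column_stack([contour[:, 1], contour[:, 0]]) * pixel_size

    # blob-like: tip-to-tip length comparable to the width
    degenerate = bool(arc[-1] < 1.15 * widths.max())
    # pole A = endpoint nearer the image origin (deterministic tie-break
    # on x then y handled by strict comparison of squared radii)
    ra = float(xy[0] @ xy[0])
    rb = float(xy[-1] @ xy[-1])
    mesh = CellMesh(
        cell_id=mask.label,
        outline=outline,
        centerline=xy,
        arc_length=arc,
        local_width=widths,
        pixel_size=pixel_size,
        degenerate=degenerate,
    )
    if rb < ra:
        mesh = mesh.reversed()
        mesh.arc_length -= mesh.arc_length[0]
    return mesh


def mesh_width(mesh: CellMesh) -> float:
    """Cell width as the mean local width over the cylindrical mid-cell.

    The averaging window is the central 50% of arc length further
    shrunk to exclude the hemispherical pole caps (one cap radius from
    each tip), so that stubby cells — whose caps reach into the central
    50% — are still measured on the cylinder.  Falls back to the maximum
    local width when no interior window remains (blob-like cells).
    """
    L = mesh.length
    r = 0.55 * float(mesh.local_width.max())
    lo = max(0.25 * L, r)
    hi = min(0.75 * L, L - r)
    sel = (mesh.arc_length >= lo) & (mesh.arc_length <= hi)
    if not sel.any():
        return float(mesh.local_width.max())
    return float(np.mean(mesh.local_width[sel]))


def axial_profile(
    mesh: CellMesh,
    frame: np.ndarray,
    *,
    mask: CellMask | None = None,
    band_halfwidth: float = 0.65,
    step: float | None = None,
    channel: str = "",
) -> AxialProfile:
    """Mean intensity in a transverse band at each arc-length step.

    At every position on a uniform grid covering [0, length], the value
    is the mean of bilinear-interpolated intensities along the local
    normal, out to ``band_halfwidth`` µm on either side of the
    centerline point and restricted to the cell interior when ``mask``
    is given.  The default half-width exceeds any half cell width, so
    the band spans the full transverse section — including the bright
    side walls of an envelope label.  The sample offsets are symmetric
    about the centerline, so relabeling the poles reverses the profile
    (to floating-point accuracy).
    """
    if mesh.degenerate:
        raise ValueError("axial_profile requires a non-degenerate mesh")
    ps = mesh.pixel_size
    if step is None:
        step = ps
    L = mesh.length
    if step > L:
        raise ValueError(f"step {step} µm exceeds cell length {L:.3f} µm")
    n = max(2, int(round(L / step))) + 1
    positions = np.linspace(0.0, L, n)
    cx = np.interp(positions, mesh.arc_length, mesh.centerline[:, 0])
    cy = np.interp(positions, mesh.arc_length, mesh.centerline[:, 1])
    centres_rc = np.column_stack([cy, cx]) / ps  # (n, 2) row,col px
    # unit normals from the local tangent of the resampled centerline
    tx = np.gradient(cx)
    ty = np.gradient(cy)
    norm = np.hypot(tx, ty)
    norm[norm == 0] = 1.0
    # normal in (row, col) = (tx, -ty)/|t| (perpendicular to tangent)
    normals_rc = np.column_stack([tx / norm, -ty / norm])
    spacing = 0.25  # px along the normal
    m = max(1, int(np.ceil(band_halfwidth / ps / spacing)))
    offs = np.concatenate([-np.arange(m, 0, -1), [0], np.arange(1, m + 1)]) * spacing
    pts = centres_rc[:, None, :] + offs[None, :, None] * normals_rc[:, None, :]
    flat = pts.reshape(-1, 2)
    vals = ndimage.map_coordinates(
        np.asarray(frame, dtype=np.float64), flat.T, order=1, mode="nearest"
    ).reshape(n, -1)
    if mask is not None:
        crop = mask.crop.astype(np.float64)
        local = flat - np.array([mask.bbox[0], mask.bbox[1]], dtype=float)
        inside = (
            ndimage.map_coordinates(crop, local.T, order=1, mode="constant", cval=0.0)
            >= 0.5
        ).reshape(n, -1)
    else:
        inside = np.ones(vals.shape, dtype=bool)
    counts = inside.sum(axis=1)
    sums = np.where(inside, vals, 0.0).sum(axis=1)
    values = np.where(counts > 0, sums / np.maximum(counts, 1), vals.mean(axis=1))
    return AxialProfile(
        cell_id=mesh.cell_id,
        channel=channel,
        positions=positions,
        values=values,
    )
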
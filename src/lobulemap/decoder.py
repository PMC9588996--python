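"""Combinatorial-FISH signal segmentation and decoding.

The stage sequence mirrors how multi-round single-molecule FISH stacks are
turned into a transcript table:

1. background-fluorescence correction (Gaussian high-pass per plane);
2. per-plane local-maxima detection, calibrated by iteratively adjusting
   brightness-contrast thresholds until the retained count approaches a
   target of ``slice area (µm²) x 0.5`` maxima per plane;
3. grouping of maxima across adjacent z-slices (z-groups); isolated maxima
   are discarded and each group counts as a single candidate signal whose
   representative is its brightest member — these form a 3D point cloud;
4. iterative-closest-point (ICP) rigid alignment of every round's point
   cloud onto round 1, and rigid resampling of the image stacks with a
   trilinear kernel (in-plane drift only, so the kernel degenerates to
   bilinear per plane);
5. per-pixel intensity profiles over all round x channel images, filtered
   by a brightness-normalised contrast statistic, matched against the
   codebook (used + unused codes) by cosine similarity;
6. grouping of same-ID pixels into connected components, filtered by size,
   internal adjacency and spatial extent; the group's intensity peak is the
   transcript location, cross-checked against raw-image local maxima;
7. specificity estimation from the ratio of calls landing on used versus
   unused (decoy) codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .codebook import Codebook, ImagingConfig
from .rigid import RigidTransform

logger = logging.getLogger(__name__)

__all__ = [
    "DecoderParams",
    "DecodeQC",
    "IcpResult",
    "correct_background",
    "detect_maxima",
    "maxima_target",
    "form_zgroups",
    "icp_align",
    "apply_rigid",
    "decode_pixels",
    "call_transcripts",
    "estimate_specificity",
    "decode_experiment",
]


@dataclass
class DecoderParams:
    """Thresholds and filter settings for the decoding pipeline."""

    maxima_area_factor: float = 0.5  # target maxima per µm² of slice area
    peri_ratio: float = 0.25  # Bperi threshold as a fraction of the Babs threshold
    bisect_iters: int = 30
    target_tolerance: float = 0.10  # accept counts within 10% of target
    background_sigma: float = 10.0  # high-pass scale, px (~10x PSF width)
    zgroup_radius: float = 2.0  # max in-plane distance linking adjacent-z maxima
    min_zgroup: int = 2
    profile_variance_threshold: float = 1.0  # on sum(v^2)/sum(v), brightness units
    min_score: float = 0.7  # cosine score floor for an ID assignment
    min_group_size: int = 3
    min_adjacency: int = 2  # face-adjacent pixel pairs within a group
    min_two_px_dims: int = 2  # dims of {x,y,z} whose extent must be >= 2 px
    raw_maxima_fraction: float = 0.75
    icp_max_iter: int = 50
    icp_tol: float = 1e-4
    icp_trim: float = 0.5  # fraction of best correspondences kept per iteration


@dataclass
class DecodeQC:
    """Specificity estimate from used- versus unused-code call counts."""

    n_used_matches: int
    n_unused_matches: int
    specificity_estimate: float | None
    flagged: bool = False


@dataclass
class IcpResult:
    transform: RigidTransform
    converged: bool
    n_iter: int
    rms: float
    n_inliers: int = 0


# ---------------------------------------------------------------------------
# background and maxima
# ---------------------------------------------------------------------------


def correct_background(stack: np.ndarray, sigma: float = 10.0) -> np.ndarray:
    """Remove large-scale background fluorescence (per-plane high-pass).

    Subtracts a Gaussian-smoothed copy (scale ``sigma`` px, roughly 10x the
    PSF width) from each plane and clips negatives, preserving spot-scale
    structure while flattening slowly varying background.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.size == 0:
        raise ValueError("empty stack")
    out = np.empty_like(stack)
    for z in range(stack.shape[0]):
        bg = ndimage.gaussian_filter(stack[z], sigma)
        out[z] = np.clip(stack[z] - bg, 0, None)
    return out


def maxima_target(slice_area_um2: float, factor: float = 0.5) -> float:
    """Allowed number of maxima per slice: area in µm² times the factor."""
    return slice_area_um2 * factor


_N8 = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float)


def _annulus_footprint(r_in: float, r_out: float) -> np.ndarray:
    r = int(np.ceil(r_out))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = xx**2 + yy**2
    return ((d2 > r_in**2) & (d2 <= r_out**2)).astype(float)


def detect_maxima(
    stack: np.ndarray,
    params: DecoderParams | None = None,
    pixel_size: float = 0.138,
) -> pd.DataFrame:
    """Per-plane local maxima with iteratively calibrated thresholds.

    For each plane, strict 8-neighbourhood local maxima are found and
    annotated with their absolute brightness ``Babs``, local background
    ``Bback`` (mean in a 2-5 px annulus) and periphery brightness ``Bperi``
    (mean of the 8 in-plane neighbours). The thresholds on (Babs - Bback)
    and (Bperi - Bback) are then adjusted by bisection until the retained
    count is within 10% of ``n_planes x slice_area_µm² x factor`` (or the
    iteration cap is reached; the closest threshold wins).

    Returns a DataFrame with columns x, y, z, babs, bback, bperi.
    """
    params = params or DecoderParams()
    stack = np.asarray(stack, dtype=float)
    if stack.size == 0 or stack.ndim != 3:
        return pd.DataFrame(columns=["x", "y", "z", "babs", "bback", "bperi"])
    Z, H, W = stack.shape
    annulus = _annulus_footprint(2.0, 5.0)
    annulus /= annulus.sum()
    rows = []
    for z in range(Z):
        plane = stack[z]
        mx = ndimage.maximum_filter(plane, size=3, mode="constant")
        is_max = (plane == mx) & (plane > 0)
        # plateau tie-break: keep the lowest linear index of each plateau
        if is_max.any():
            ys, xs = np.nonzero(is_max)
            bback = ndimage.correlate(plane, annulus, mode="nearest")[ys, xs]
            bperi = ndimage.correlate(plane, _N8 / 8.0, mode="constant")[ys, xs]
            rows.append(
                pd.DataFrame(
                    {"x": xs, "y": ys, "z": z, "babs": plane[ys, xs],
                     "bback": bback, "bperi": bperi}
                )
            )
    if not rows:
        return pd.DataFrame(columns=["x", "y", "z", "babs", "bback", "bperi"])
    maxima = pd.concat(rows, ignore_index=True)

    target = Z * maxima_target(H * W * pixel_size**2, params.maxima_area_factor)
    c1 = (maxima["babs"] - maxima["bback"]).to_numpy()
    c2 = (maxima["bperi"] - maxima["bback"]).to_numpy()
    if len(maxima) <= target * (1 + params.target_tolerance):
        return maxima.reset_index(drop=True)

    lo, hi = 0.0, float(c1.max())
    best_keep, best_err = None, np.inf
    for _ in range(params.bisect_iters):
        theta = 0.5 * (lo + hi)
        keep = (c1 >= theta) & (c2 >= params.peri_ratio * theta)
        n = int(keep.sum())
        err = abs(n - target)
        if err < best_err:
            best_keep, best_err = keep, err
        if err <= params.target_tolerance * target:
            break
        if n > target:
            lo = theta
        else:
            hi = theta
    return maxima[best_keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# z-groups
# ---------------------------------------------------------------------------


def form_zgroups(
    maxima: pd.DataFrame, radius: float = 2.0, min_size: int = 2
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Chain maxima across adjacent z-slices into z-groups.

    Maxima on consecutive slices within ``radius`` px in-plane are linked;
    connected chains of at least ``min_size`` members form a z-group,
    counted as one candidate signal. Isolated maxima are excluded. The
    representative of each group is its brightest member; the set of
    representatives is the feature point cloud used for round alignment.

    Returns ``(groups, representatives)``.
    """
    if len(maxima) == 0:
        return [], maxima.copy()
    maxima = maxima.reset_index(drop=True)
    n = len(maxima)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    z_vals = maxima["z"].to_numpy()
    by_z = {z: np.nonzero(z_vals == z)[0] for z in np.unique(z_vals)}
    for z, idx in by_z.items():
        nxt = by_z.get(z + 1)
        if nxt is None or len(idx) == 0 or len(nxt) == 0:
            continue
        a = maxima.loc[idx, ["x", "y"]].to_numpy(float)
        b = maxima.loc[nxt, ["x", "y"]].to_numpy(float)
        pairs = cKDTree(a).query_ball_tree(cKDTree(b), r=radius)
        for i, matches in enumerate(pairs):
            for j in matches:
                union(idx[i], nxt[j])

    roots = np.array([find(i) for i in range(n)])
    groups: list[pd.DataFrame] = []
    reps = []
    for root in np.unique(roots):
        members = maxima[roots == root]
        if len(members) < min_size:
            continue
        groups.append(members)
        reps.append(members.loc[members["babs"].idxmax()])
    rep_df = (
        pd.DataFrame(reps).reset_index(drop=True)
        if reps
        else maxima.iloc[0:0].copy()
    )
    return groups, rep_df


# ---------------------------------------------------------------------------
# ICP alignment and rigid resampling
# ---------------------------------------------------------------------------


def _fit_rigid(
    src: np.ndarray, dst: np.ndarray, weights: np.ndarray | None = None
) -> RigidTransform:
    """(Weighted) least-squares rigid fit mapping src onto dst (2D Kabsch)."""
    if weights is None:
        weights = np.ones(len(src))
    w = weights / weights.sum()
    sc, dc = w @ src, w @ dst
    H = (src - sc).T @ ((dst - dc) * w[:, None])
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, d])
    R = Vt.T @ D @ U.T
    t = dc - R @ sc
    return RigidTransform(float(np.arctan2(R[1, 0], R[0, 0])), (float(t[0]), float(t[1])))


def _translation_mode(cloud: np.ndarray, reference: np.ndarray, radius: float = 15.0) -> np.ndarray:
    """Modal displacement vector between the clouds (coarse translation init).

    Histogram of all cloud→reference displacement vectors shorter than
    ``radius``, smoothed, peak taken. Robust to points present in only one
    cloud, which defeats a naive centroid difference.
    """
    pairs = cKDTree(cloud).query_ball_tree(cKDTree(reference), r=radius)
    disps = [reference[j] - cloud[i] for i, js in enumerate(pairs) for j in js]
    if not disps:
        return np.zeros(2)
    disps = np.asarray(disps)
    bins = np.arange(-radius - 0.5, radius + 1.5)
    hist, xe, ye = np.histogram2d(disps[:, 0], disps[:, 1], bins=(bins, bins))
    hist = ndimage.gaussian_filter(hist, 1.0)
    i, j = np.unravel_index(np.argmax(hist), hist.shape)
    return np.array([0.5 * (xe[i] + xe[i + 1]), 0.5 * (ye[j] + ye[j + 1])])


def _translation_mode_transform(cloud: np.ndarray, reference: np.ndarray) -> RigidTransform:
    t0 = _translation_mode(cloud, reference)
    return RigidTransform(0.0, (float(t0[0]), float(t0[1])))


def icp_align(
    cloud: np.ndarray,
    reference: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-4,
    trim: float = 0.8,
    init: RigidTransform | str | None = None,
) -> IcpResult:
    """Estimate the rigid transform mapping ``cloud`` onto ``reference``.

    Classic trimmed ICP: alternate nearest-neighbour correspondence (the
    best ``trim`` fraction by distance is kept, making the fit robust to
    points present in only one cloud) with a closed-form least-squares
    rigid fit, until the mean correspondence distance changes by less than
    ``tol`` or ``max_iter`` is reached. Non-convergence returns the best
    iterate with ``converged=False``.

    ``init`` seeds the first correspondence search: a transform, or
    ``"translation-mode"`` to start from the modal displacement vector
    between the clouds (recommended when the clouds only partially
    overlap, as across imaging rounds).
    """
    cloud = np.asarray(cloud, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if len(cloud) < 3 or len(reference) < 3:
        raise ValueError("ICP needs at least 3 points in each cloud")
    tree = cKDTree(reference)
    if init == "translation-mode":
        starts = [_translation_mode_transform(cloud, reference)]
    elif init is None:
        # drift beyond the typical point spacing traps identity-start ICP
        # in a wrong basin; also try the modal displacement
        starts = [RigidTransform.identity(), _translation_mode_transform(cloud, reference)]
    else:
        starts = [init]

    def refine(transform: RigidTransform) -> RigidTransform:
        # distance-gated iterations: once coarsely aligned, true
        # correspondences separate cleanly from unpaired points, so a
        # shrinking gate replaces the fixed-fraction trim and removes its
        # systematic drag when the clouds only partially overlap
        for gate in (4.0, 3.0, 2.0, 1.5, 1.5, 1.5, 1.5, 1.5):
            moved = transform.apply(cloud)
            dist, idx = tree.query(moved)
            keep = dist < gate
            if keep.sum() < 3:
                return transform
            transform = _fit_rigid(cloud[keep], reference[idx[keep]])
        # IRLS final passes (Tukey biweight): spurious matches inside the
        # gate would otherwise bias the least-squares fit into a slightly
        # shifted equilibrium; reweighting by residual removes them
        for _ in range(5):
            moved = transform.apply(cloud)
            dist, idx = tree.query(moved)
            keep = dist < 1.5
            if keep.sum() < 3:
                break
            r = dist[keep]
            c = max(3.0 * float(np.median(r)), 0.3)
            w = np.clip(1 - (r / c) ** 2, 0, None) ** 2
            if w.sum() <= 0:
                break
            transform = _fit_rigid(cloud[keep], reference[idx[keep]], w)
        return transform

    def score(transform: RigidTransform) -> tuple[int, float]:
        dist, _ = tree.query(transform.apply(cloud))
        inliers = dist < 1.5
        n_in = int(inliers.sum())
        rms = (
            float(np.sqrt(np.mean(dist[inliers] ** 2)))
            if n_in
            else float(np.sqrt(np.mean(np.sort(dist)[: max(3, len(cloud) // 2)] ** 2)))
        )
        return n_in, rms

    best, best_key = None, None
    converged = False
    it = 0
    for start in starts:
        # classic trimmed ICP from the start transform
        transform = start
        prev_mean = np.inf
        run_converged = False
        for it in range(1, max_iter + 1):
            moved = transform.apply(cloud)
            dist, idx = tree.query(moved)
            k = max(3, int(np.ceil(trim * len(cloud))))
            keep = np.argsort(dist)[:k]
            transform = _fit_rigid(cloud[keep], reference[idx[keep]])
            mean_d = float(dist[keep].mean())
            if abs(prev_mean - mean_d) < tol:
                run_converged = True
                break
            prev_mean = mean_d
        # keep the best of {trimmed-then-refined, refined-from-start}
        for cand in (refine(transform), refine(start)):
            n_in, rms = score(cand)
            key = (n_in, -rms)
            if best_key is None or key > best_key:
                best, best_key = (cand, n_in, rms), key
                converged = run_converged
    transform, n_in, rms = best
    if not converged:
        logger.warning("ICP did not converge in %d iterations (rms %.3g)", max_iter, rms)
    return IcpResult(transform, converged, it, rms, n_in)


def apply_rigid(
    stack_or_cloud: np.ndarray, transform: RigidTransform
) -> np.ndarray:
    """Apply a rigid transform to a point cloud (exactly) or image stack.

    Stacks (z, y, x) are resampled with a trilinear interpolation kernel on
    the (x, y, z) grid; since the transform is in-plane the kernel
    degenerates to bilinear per plane. Samples falling outside the field
    are zero.
    """
    arr = np.asarray(stack_or_cloud, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return transform.apply(arr)
    if arr.ndim != 3:
        raise ValueError("expected an (N, 2) cloud or a (z, y, x) stack")
    Z, H, W = arr.shape
    inv = transform.inverse()
    yy, xx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    src = inv.apply(np.column_stack([xx.ravel(), yy.ravel()]))
    sx = np.broadcast_to(src[:, 0].reshape(1, H, W), (Z, H, W))
    sy = np.broadcast_to(src[:, 1].reshape(1, H, W), (Z, H, W))
    sz = np.broadcast_to(np.arange(Z).reshape(Z, 1, 1), (Z, H, W))
    coords = np.stack([sz.ravel(), sy.ravel(), sx.ravel()])
    out = ndimage.map_coordinates(arr, coords, order=1, mode="constant", cval=0.0)
    return out.reshape(Z, H, W)


# ---------------------------------------------------------------------------
# pixel decoding
# ---------------------------------------------------------------------------


def _stack_list(stacks, config: ImagingConfig) -> list[np.ndarray]:
    """Accept a round-major list or a {(round, channel): stack} dict."""
    if isinstance(stacks, dict):
        return [stacks[(r, c)] for r in range(config.rounds) for c in range(config.channels)]
    return list(stacks)


def decode_pixels(
    stacks,
    codebook: Codebook,
    params: DecoderParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign a code ID to every informative pixel.

    Pixel profiles (length rounds x channels, round-major) are rejected if
    their total brightness is zero or their contrast statistic — the second
    raw moment per unit brightness, ``sum(v²)/sum(v)`` — falls below the
    threshold; surviving profiles are matched against used + unused codes
    by cosine similarity and take the argmax ID when the score clears
    ``min_score``. Ties break to the lower code index.

    Returns ``(id_map, score_map)`` of shape (z, y, x); ``id_map`` holds
    row indices into ``codebook.all_codes()`` and -1 for no assignment.
    """
    params = params or DecoderParams()
    config = ImagingConfig(codebook.rounds, codebook.channels, 1)
    arrs = _stack_list(stacks, config)
    if len(arrs) != codebook.n_bits:
        raise ValueError(
            f"got {len(arrs)} stacks for a {codebook.n_bits}-bit codebook"
        )
    V = np.stack([np.asarray(a, dtype=float) for a in arrs])  # (bits, z, y, x)
    bits, Z, H, W = V.shape
    flat = V.reshape(bits, -1)
    total = flat.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        contrast = np.where(total > 0, (flat**2).sum(axis=0) / total, 0.0)
    valid = (total > 0) & (contrast >= params.profile_variance_threshold)

    codes, _, _ = codebook.all_codes()
    codes_n = codes / np.linalg.norm(codes, axis=1, keepdims=True)
    norms = np.linalg.norm(flat, axis=0)
    ids = np.full(flat.shape[1], -1, dtype=np.int32)
    scores = np.zeros(flat.shape[1])
    vi = np.nonzero(valid)[0]
    if len(vi):
        sims = codes_n @ flat[:, vi] / norms[vi]  # (n_codes, n_valid)
        best = np.argmax(sims, axis=0)  # first max -> lowest code index
        best_score = sims[best, np.arange(len(vi))]
        ok = best_score >= params.min_score
        ids[vi[ok]] = best[ok]
        scores[vi] = best_score
    return ids.reshape(Z, H, W), scores.reshape(Z, H, W)


# ---------------------------------------------------------------------------
# transcript calling
# ---------------------------------------------------------------------------

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # face connectivity


def _local_maxima_3d(stack: np.ndarray) -> np.ndarray:
    mx = ndimage.maximum_filter(stack, size=3, mode="constant")
    return (stack == mx) & (stack > 0)


def call_transcripts(
    id_map: np.ndarray,
    stacks,
    codebook: Codebook,
    params: DecoderParams | None = None,
) -> pd.DataFrame:
    """Group same-ID pixels and call one transcript per surviving group.

    Connected components (6-connectivity) of each code ID are filtered by
    group size, number of face-adjacent pixel pairs, and the number of
    {x, y, z} dimensions spanning at least two pixels. A group's transcript
    sits at the peak of its summed on-bit intensity and must coincide
    (within 1 px) with a raw-image local maximum in at least
    ``raw_maxima_fraction`` of the code's on-bit images. The cosine fit to
    the code at the called pixel is recorded as the spot score.

    Decoy (unused-code) calls are kept in the table with ``used=False`` so
    specificity can be estimated downstream.
    """
    params = params or DecoderParams()
    config = ImagingConfig(codebook.rounds, codebook.channels, 1)
    arrs = [np.asarray(a, dtype=float) for a in _stack_list(stacks, config)]
    codes, labels, is_used = codebook.all_codes()
    raw_max = [_local_maxima_3d(a) for a in arrs]

    records = []
    present = np.unique(id_map)
    present = present[present >= 0]
    for code_idx in present:
        code = codes[code_idx]
        on_bits = np.nonzero(code)[0]
        on_sum = np.sum([arrs[b] for b in on_bits], axis=0)
        mask = id_map == code_idx
        lbl, n_comp = ndimage.label(mask, structure=_STRUCT6)
        objects = ndimage.find_objects(lbl)
        for comp in range(1, n_comp + 1):
            sl = objects[comp - 1]
            sub = lbl[sl] == comp
            size = int(sub.sum())
            if size < params.min_group_size:
                continue
            adjacency = sum(
                int(np.logical_and(sub.take(range(1, sub.shape[ax]), axis=ax),
                                   sub.take(range(0, sub.shape[ax] - 1), axis=ax)).sum())
                for ax in range(3)
            )
            if adjacency < params.min_adjacency:
                continue
            extents = [sub.shape[ax] for ax in range(3)]
            if sum(e >= 2 for e in extents) < params.min_two_px_dims:
                continue
            vals = np.where(sub, on_sum[sl], -np.inf)
            zz, yy, xx = np.unravel_index(np.argmax(vals), vals.shape)
            z = zz + sl[0].start
            y = yy + sl[1].start
            x = xx + sl[2].start
            # require a raw local maximum within 1 px in most on-bit images
            z0, z1 = max(0, z - 1), min(id_map.shape[0], z + 2)
            y0, y1 = max(0, y - 1), min(id_map.shape[1], y + 2)
            x0, x1 = max(0, x - 1), min(id_map.shape[2], x + 2)
            n_hit = sum(bool(raw_max[b][z0:z1, y0:y1, x0:x1].any()) for b in on_bits)
            if n_hit < params.raw_maxima_fraction * len(on_bits):
                continue
            profile = np.array([a[z, y, x] for a in arrs])
            pnorm = np.linalg.norm(profile)
            score = float(profile @ code / (pnorm * np.linalg.norm(code))) if pnorm else 0.0
            records.append(
                {
                    "x": float(x),
                    "y": float(y),
                    "z": float(z),
                    "gene": labels[code_idx],
                    "score": score,
                    "used": bool(is_used[code_idx]),
                    "group_size": size,
                }
            )
    spots = pd.DataFrame(
        records, columns=["x", "y", "z", "gene", "score", "used", "group_size"]
    )
    spots = spots.sort_values(["z", "y", "x"], kind="stable").reset_index(drop=True)
    spots.insert(0, "spot_id", [f"spot_{i:06d}" for i in range(len(spots))])
    return spots


def estimate_specificity(spots: pd.DataFrame, codebook: Codebook) -> DecodeQC:
    """Specificity estimate: used calls / (used + unused calls).

    Decoding runs with the unused codes included as decoy targets, so the
    fraction of calls matching a used code estimates the true-positive
    fraction among all calls.
    """
    if len(spots) == 0:
        return DecodeQC(0, 0, None, flagged=True)
    used = spots["gene"].isin(codebook.codes).to_numpy()
    n_used = int(used.sum())
    n_unused = int((~used).sum())
    return DecodeQC(n_used, n_unused, n_used / (n_used + n_unused))


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------


@dataclass
class DecodeResult:
    spots: pd.DataFrame
    transforms: list[RigidTransform]
    qc: DecodeQC
    icp: list[IcpResult] = field(default_factory=list)


def decode_experiment(
    stacks,
    codebook: Codebook,
    params: DecoderParams | None = None,
    imaging: ImagingConfig | None = None,
) -> DecodeResult:
    """Run the full decode: background → maxima → z-groups → ICP → decode.

    ``stacks`` is a {(round, channel): (z, y, x) array} dict or a
    round-major list. Coordinates in the returned spot table are in the
    round-1 reference frame. Only used-code spots appear with their gene
    name; decoy calls are retained (``used=False``) for the QC estimate.
    """
    params = params or DecoderParams()
    imaging = imaging or ImagingConfig(codebook.rounds, codebook.channels)
    arrs = _stack_list(stacks, imaging)
    corrected = [correct_background(a, params.background_sigma) for a in arrs]

    # feature cloud per round (channels merged)
    clouds = []
    for r in range(imaging.rounds):
        reps_r = []
        for c in range(imaging.channels):
            m = detect_maxima(corrected[r * imaging.channels + c], params, imaging.pixel_size)
            _, reps = form_zgroups(m, params.zgroup_radius, params.min_zgroup)
            reps_r.append(reps[["x", "y"]])
        cloud = pd.concat(reps_r, ignore_index=True).to_numpy(float)
        clouds.append(cloud)

    def multistart_align(cloud: np.ndarray, reference: np.ndarray,
                         extra_inits: tuple = ()) -> IcpResult:
        # partial overlap between round clouds makes ICP basin-sensitive:
        # sweep small rotations about the cloud centroid, each followed by
        # the modal displacement toward the reference, and keep the fit
        # with the most inliers
        centroid = cloud.mean(axis=0)
        inits: list = [None, *extra_inits]
        for deg in (-3.0, -2.0, -1.0, 1.0, 2.0, 3.0):
            rot = RigidTransform.from_center_rotation(
                np.deg2rad(deg), (0.0, 0.0), (centroid[0], centroid[1])
            )
            shift = _translation_mode(rot.apply(cloud), reference)
            inits.append(RigidTransform(0.0, (float(shift[0]), float(shift[1]))).compose(rot))
        candidates = [
            icp_align(cloud, reference, max_iter=params.icp_max_iter,
                      tol=params.icp_tol, trim=params.icp_trim, init=init)
            for init in inits
        ]
        return max(candidates, key=lambda c: (c.n_inliers, -c.rms))

    transforms = [RigidTransform.identity()]
    icp_results: list[IcpResult] = []
    for r in range(1, imaging.rounds):
        if len(clouds[r]) < 3 or len(clouds[0]) < 3:
            # too few features to register (empty or near-empty field):
            # assume no drift rather than failing the whole decode
            logger.warning("round %d: <3 feature points, assuming identity drift", r + 1)
            transforms.append(RigidTransform.identity())
            continue
        res = multistart_align(clouds[r], clouds[0])
        icp_results.append(res)
        transforms.append(res.transform)

    # consensus pass: each round sees only a subset of the spots, so the
    # union of confidently registered clouds is a far more complete
    # reference than round 1 alone; weakly registered rounds are re-fit
    # against it
    confident = [
        (r, icp_results[r - 1])
        for r in range(1, imaging.rounds)
        if len(clouds[r]) >= 3
        and icp_results[r - 1].n_inliers >= 0.4 * len(clouds[r])
    ]
    if confident and len(clouds[0]) >= 3:
        for r in range(1, imaging.rounds):
            if len(clouds[r]) < 3:
                continue
            union = np.vstack(
                [clouds[0]]
                + [res.transform.apply(clouds[s]) for s, res in confident if s != r]
            )
            res = multistart_align(clouds[r], union, extra_inits=(transforms[r],))
            if res.n_inliers > icp_results[r - 1].n_inliers:
                icp_results[r - 1] = res
                transforms[r] = res.transform

    aligned = []
    for r in range(imaging.rounds):
        for c in range(imaging.channels):
            a = corrected[r * imaging.channels + c]
            aligned.append(a if transforms[r].is_identity() else apply_rigid(a, transforms[r]))

    id_map, _ = decode_pixels(aligned, codebook, params)
    spots = call_transcripts(id_map, aligned, codebook, params)
    qc = estimate_specificity(spots, codebook)
    return DecodeResult(spots, transforms, qc, icp_results)
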
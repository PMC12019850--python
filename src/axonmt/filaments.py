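"""Filament-network extraction from rendered localization sections.

The extraction chain mirrors established SMLM filament-network extractors:

1. curvilinear enhancement with line/orientation filter transforms (LFT/OFT):
   per pixel, the maximal mean intensity along a rotated line segment and the
   orientation achieving it;
2. Otsu segmentation of the LFT response;
3. skeletonization and junction removal, yielding a pool of minimal linear
   fragments with tip orientations;
4. constraint-based greedy grouping of fragments into composite filaments
   (search cone, orientation/angle/gap-vector limits, curvature bound, no
   fragment reuse, two matching passes).

Default grouping parameters target microtubule arrays rendered at 26 nm pixel
size: maximum curvature 1 rad/um, search angle/radius 60 deg / 40 px, 60 deg
endpoint-orientation and tip-angle limits, 30 deg gap-vector limit, unit
similarity and continuity weights, and a 15 px (390 nm) minimum filament
length for statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

__all__ = [
    "EnhancedImage",
    "FilamentFragment",
    "Filament",
    "GroupingConfig",
    "JoinRecord",
    "GroupingResult",
    "enhance_lft_oft",
    "segment_otsu",
    "thin_ridge",
    "fragment_pool",
    "group_fragments",
    "filter_filaments",
    "extract_filaments",
]


# ---------------------------------------------------------------------------
# enhancement
# ---------------------------------------------------------------------------


@dataclass
class EnhancedImage:
    """Per-pixel maximal line-filter response and the orientation achieving it."""

    lft: np.ndarray
    oft: np.ndarray  # radians in [0, pi); ties resolved toward the smallest angle
    radius_px: int
    n_rotations: int


def _line_offsets(theta: float, radius_px: int) -> np.ndarray:
    """Unique integer (row, col) offsets of a centered scan segment."""
    r = np.arange(-radius_px, radius_px + 1)
    rows = np.round(r * np.sin(theta)).astype(int)
    cols = np.round(r * np.cos(theta)).astype(int)
    return np.unique(np.stack([rows, cols], axis=1), axis=0)


def enhance_lft_oft(image: np.ndarray, radius_px: int = 10, n_rotations: int = 40) -> EnhancedImage:
    """Line and orientation filter transforms of a 2D image.

    For each of ``n_rotations`` orientations theta_k = k*pi/n the response is
    the mean intensity along a centered scan segment of half-length
    ``radius_px``; ``lft`` is the maximum over orientations and ``oft`` the
    argmax (ties break toward the smallest angle).  Elongated structures score
    higher than isolated bright pixels of equal peak value because the mean is
    taken along the whole segment.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    if np.any(image < 0):
        raise ValueError("image must be nonnegative")
    if radius_px >= min(image.shape) / 2:
        raise ValueError(
            f"radius_px={radius_px} too large for image of shape {image.shape}: "
            "must be smaller than half the smallest image dimension"
        )
    thetas = np.arange(n_rotations) * np.pi / n_rotations
    lft = np.full(image.shape, -np.inf)
    oft = np.zeros(image.shape)
    for theta in thetas:
        offsets = _line_offsets(theta, radius_px)
        size = 2 * radius_px + 1
        kernel = np.zeros((size, size))
        kernel[offsets[:, 0] + radius_px, offsets[:, 1] + radius_px] = 1.0
        kernel /= kernel.sum()
        response = ndimage.correlate(image, kernel, mode="reflect")
        better = response > lft + 1e-12  # strict: ties keep the smaller angle
        lft[better] = response[better]
        oft[better] = theta
    return EnhancedImage(lft=lft, oft=oft, radius_px=radius_px, n_rotations=n_rotations)


def segment_otsu(lft: np.ndarray) -> np.ndarray:
    """Binary mask from Otsu's threshold on a 256-bin histogram.

    The threshold maximizes the inter-class variance; the mask is
    ``lft > threshold``.  A constant image yields an empty mask with a
    warning rather than an exception.
    """
    lft = np.asarray(lft, dtype=float)
    if np.ptp(lft) == 0:
        warnings.warn("constant image: Otsu threshold undefined, returning empty mask")
        return np.zeros(lft.shape, dtype=bool)
    threshold = threshold_otsu(lft, nbins=256)
    return lft > threshold


# ---------------------------------------------------------------------------
# fragment pool
# ---------------------------------------------------------------------------


@dataclass
class FilamentFragment:
    """An ordered, junction-free 8-connected pixel chain with tip directions.

    ``tip_directions`` holds outward unit vectors (row, col) at the chain
    start and end, estimated from the terminal 5 pixels.
    """

    pixels: np.ndarray  # (n, 2) int, ordered along the chain
    tip_directions: np.ndarray  # (2, 2) float, outward at [start, end]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2:
            raise ValueError("pixels must be an (n, 2) array")

    def __len__(self) -> int:
        return len(self.pixels)

    @property
    def tip_positions(self) -> np.ndarray:
        return np.stack([self.pixels[0], self.pixels[-1]]).astype(float)


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(int), _NEIGHBOR_KERNEL, mode="constant")


#: circular ring order of the 8-neighborhood: N, NE, E, SE, S, SW, W, NW
_RING_OFFSETS = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


def _branch_points(skel: np.ndarray) -> np.ndarray:
    """Skeleton pixels where >= 3 distinct branches meet.

    Uses the crossing number (0 -> 1 transitions around the 8-neighbor ring):
    endpoints have 1, simple curve pixels 2 (including staircase corners,
    which a raw neighbor count would misclassify), branch points >= 3.
    """
    padded = np.pad(skel, 1).astype(np.int8)
    ring = np.stack(
        [padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc] for dr, dc in _RING_OFFSETS]
    )
    nxt = np.roll(ring, -1, axis=0)
    crossings = ((ring == 0) & (nxt == 1)).sum(axis=0)
    return skel & (crossings >= 3)


#: pixels used to estimate tip tangents at chain ends
_TIP_FIT_PX = 5


def _tip_direction(chain: np.ndarray, at_start: bool) -> np.ndarray:
    """Outward unit vector at a chain tip from the terminal <= 5 pixels."""
    k = min(_TIP_FIT_PX, len(chain))
    seg = chain[:k] if at_start else chain[-k:]
    tip = seg[0] if at_start else seg[-1]
    inner = seg[-1] if at_start else seg[0]
    if k == 1:
        return np.array([0.0, 1.0])
    seg = seg.astype(float)
    centered = seg - seg.mean(axis=0)
    # principal direction of the terminal pixels
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    outward = tip.astype(float) - inner.astype(float)
    if np.dot(direction, outward) < 0:
        direction = -direction
    norm = np.linalg.norm(direction)
    if norm == 0:  # degenerate: fall back to the chord
        direction = outward / max(np.linalg.norm(outward), 1e-12)
        return direction
    return direction / norm


def _order_chain(component_pixels: np.ndarray) -> np.ndarray:
    """Order the pixels of a simple 8-connected path from one end to the other."""
    pix = [tuple(p) for p in component_pixels]
    pixset = set(pix)

    def neighbors(p):
        return [
            (p[0] + dr, p[1] + dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr or dc) and (p[0] + dr, p[1] + dc) in pixset
        ]

    endpoints = sorted(p for p in pix if len(neighbors(p)) <= 1)
    start = endpoints[0] if endpoints else min(pix)  # closed loop: break deterministically
    chain = [start]
    visited = {start}
    current = start
    while True:
        nxt = [n for n in neighbors(current) if n not in visited]
        if not nxt:
            break
        # prefer 4-connected continuation for a canonical walk
        nxt.sort(key=lambda n: (abs(n[0] - current[0]) + abs(n[1] - current[1]), n))
        current = nxt[0]
        chain.append(current)
        visited.add(current)
    return np.array(chain, dtype=int)


def thin_ridge(enhanced: EnhancedImage, mask: np.ndarray) -> np.ndarray:
    """Non-maximum suppression of the LFT across the local filament direction.

    Keeps a mask pixel only when its LFT response is not exceeded by either
    neighbor along the direction perpendicular to the local orientation
    (OFT).  This suppresses the broad lateral halo of the line filter around
    each filament, leaving a 1-2 px ridge centered on the filament so that
    skeletonization does not pick up halo structure.
    """
    lft, oft = enhanced.lft, enhanced.oft
    rows, cols = np.indices(lft.shape)
    # orientation theta points along the filament; perpendicular offset
    pr = np.rint(np.cos(oft)).astype(int)
    pc = np.rint(-np.sin(oft)).astype(int)
    r_plus = np.clip(rows + pr, 0, lft.shape[0] - 1)
    c_plus = np.clip(cols + pc, 0, lft.shape[1] - 1)
    r_minus = np.clip(rows - pr, 0, lft.shape[0] - 1)
    c_minus = np.clip(cols - pc, 0, lft.shape[1] - 1)
    keep = (lft >= lft[r_plus, c_plus]) & (lft >= lft[r_minus, c_minus])
    return np.asarray(mask, dtype=bool) & keep


def _prune_spurs(skel: np.ndarray, max_spur_px: int) -> np.ndarray:
    """Remove short endpoint-terminated side branches from a skeleton.

    A spur is a branch of at most ``max_spur_px`` pixels running from an
    endpoint to a branch point; spurs arise from boundary bumps of the
    enhanced ridge, and deleting them (rather than cutting at their branch
    points later) keeps the main line intact.  Iterates until stable.
    """
    skel = skel.copy()
    while True:
        branch = _branch_points(skel)
        if not branch.any():
            return skel
        pixset = {tuple(p) for p in np.argwhere(skel)}
        branchset = {tuple(p) for p in np.argwhere(branch)}
        endpoints = [p for p in pixset if sum(
            (p[0] + dr, p[1] + dc) in pixset for dr, dc in _RING_OFFSETS) == 1]
        removed_any = False
        for end in endpoints:
            walk = [end]
            prev = None
            current = end
            hit_branch = False
            while len(walk) <= max_spur_px:
                nxt = [
                    (current[0] + dr, current[1] + dc)
                    for dr, dc in _RING_OFFSETS
                    if (current[0] + dr, current[1] + dc) in pixset
                    and (current[0] + dr, current[1] + dc) != prev
                    and (current[0] + dr, current[1] + dc) not in walk
                ]
                if any(n in branchset for n in nxt):
                    hit_branch = True
                    break
                if len(nxt) != 1:
                    break
                prev = current
                current = nxt[0]
                walk.append(current)
            if hit_branch:
                for p in walk:
                    skel[p] = False
                    pixset.discard(p)
                removed_any = True
        if not removed_any:
            return skel


def fragment_pool(
    mask: np.ndarray,
    junction_clear_radius_px: int = 1,
    min_fragment_px: int = 5,
    max_spur_px: int = 4,
) -> list[FilamentFragment]:
    """Skeletonize a mask and split it at junctions into linear fragments.

    Junction pixels (>= 3 skeleton neighbors in 8-connectivity) are removed
    together with a small local area around each connection
    (``junction_clear_radius_px`` = 1 clears the 8-neighborhood, which
    guarantees the remaining chains are disconnected at 3- and 4-valent
    crossings).  Chains shorter than ``min_fragment_px`` are discarded as
    skeletonization spurs (side branches of the enhanced ridge, not
    filament signal).  Remaining chains are returned ordered, with tip
    directions estimated from the terminal 5 pixels.  An empty mask yields
    an empty pool.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    skel = skeletonize(mask)
    if max_spur_px > 0:
        skel = _prune_spurs(skel, max_spur_px)
    # iteratively clear junctions until no branch points remain
    while True:
        junctions = _branch_points(skel)
        if not junctions.any():
            break
        size = 2 * junction_clear_radius_px + 1
        cleared = ndimage.binary_dilation(junctions, structure=np.ones((size, size), dtype=bool))
        skel = skel & ~cleared
    labels, n_labels = ndimage.label(skel, structure=np.ones((3, 3), dtype=int))
    fragments = []
    for lab in range(1, n_labels + 1):
        coords = np.argwhere(labels == lab)
        if len(coords) < max(2, min_fragment_px):
            continue
        chain = _order_chain(coords)
        if len(chain) < len(coords):
            # walk did not cover the component (residual branch): drop extras
            chain = chain
        tips = np.stack([_tip_direction(chain, True), _tip_direction(chain, False)])
        fragments.append(FilamentFragment(pixels=chain, tip_directions=tips))
    # deterministic order: by first pixel
    fragments.sort(key=lambda f: tuple(f.pixels[0]))
    return fragments


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------


@dataclass
class GroupingConfig:
    """Hard constraints and score weights for fragment grouping."""

    pixel_size_nm: float = 26.0
    max_curvature_rad_per_um: float = 1.0
    search_angle_deg: float = 60.0
    search_radius_px: float = 40.0
    max_endpoint_orientation_diff_deg: float = 60.0
    max_angle_diff_deg: float = 60.0
    max_gap_vector_angle_deg: float = 30.0
    weight_similarity: float = 1.0
    weight_continuity: float = 1.0
    allow_overlap: bool = False
    n_iterations: int = 2
    min_filament_length_px: float = 15.0

    def __post_init__(self) -> None:
        for name in (
            "search_angle_deg",
            "max_endpoint_orientation_diff_deg",
            "max_angle_diff_deg",
            "max_gap_vector_angle_deg",
        ):
            v = getattr(self, name)
            if not 0 < v <= 180:
                raise ValueError(f"{name} must be in (0, 180], got {v}")
        if self.min_filament_length_px <= 0:
            raise ValueError("min_filament_length_px must be > 0")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")


@dataclass
class Filament:
    """A traced filament polyline in physical coordinates."""

    points_nm: np.ndarray  # (n, 2) float, ordered (row, col) * pixel size
    composite: bool = False
    n_fragments: int = 1

    def __post_init__(self) -> None:
        self.points_nm = np.asarray(self.points_nm, dtype=float)
        if len(self.points_nm) < 2:
            raise ValueError("a filament needs at least 2 points")

    @property
    def contour_length_um(self) -> float:
        steps = np.linalg.norm(np.diff(self.points_nm, axis=0), axis=1)
        return float(steps.sum() / 1000.0)

    @property
    def end_to_end_um(self) -> float:
        return float(np.linalg.norm(self.points_nm[-1] - self.points_nm[0]) / 1000.0)

    @property
    def straightness(self) -> float:
        contour = self.contour_length_um
        if contour == 0:
            raise ValueError("zero-length filament has undefined straightness")
        return min(self.end_to_end_um / contour, 1.0)


@dataclass
class JoinRecord:
    """Constraint values of one accepted tip-to-tip join (for auditing)."""

    gap_px: float
    gap_vector_angle_deg: float  # max over the two tips
    tip_angle_diff_deg: float
    endpoint_orientation_diff_deg: float
    curvature_rad_per_um: float
    score: float


@dataclass
class GroupingResult:
    filaments: list[Filament]
    joins: list[JoinRecord] = field(default_factory=list)


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _line_angle_diff(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two undirected orientations in degrees, in [0, 90]."""
    a = _angle_between(u, v)
    return min(a, 180.0 - a)


@dataclass
class _Chain:
    points: np.ndarray  # ordered (n, 2) float px
    n_fragments: int

    def tip_dir(self, end: int) -> np.ndarray:
        return _tip_direction(np.round(self.points).astype(int), at_start=(end == 0))

    def tip_pos(self, end: int) -> np.ndarray:
        return self.points[0] if end == 0 else self.points[-1]


def _evaluate_pair(a: _Chain, ea: int, b: _Chain, eb: int, cfg: GroupingConfig):
    """Check all hard constraints for joining tip ``ea`` of ``a`` to ``eb`` of ``b``.

    Returns (score, JoinRecord) or None when any constraint fails.
    """
    pa, pb = a.tip_pos(ea), b.tip_pos(eb)
    gap = pb - pa
    gap_len = float(np.linalg.norm(gap))
    if gap_len == 0 or gap_len > cfg.search_radius_px:
        return None
    da, db = a.tip_dir(ea), b.tip_dir(eb)
    # candidate partner must lie inside the search cone of the propagating tip
    if _angle_between(gap, da) > cfg.search_angle_deg:
        return None
    gap_angle = max(_angle_between(gap, da), _angle_between(-gap, db))
    if gap_angle > cfg.max_gap_vector_angle_deg:
        return None
    tip_diff = _angle_between(da, -db)
    if tip_diff > cfg.max_angle_diff_deg:
        return None
    orient_diff = _line_angle_diff(da, db)
    if orient_diff > cfg.max_endpoint_orientation_diff_deg:
        return None
    # curvature implied by the join: total turn between the tip tangents over
    # the arc traversed (gap plus the two 5 px terminal windows the tangents
    # were estimated from); a chord-circle estimate would be hypersensitive
    # to tip-direction noise at junction-removal-scale gaps
    turn_rad = np.radians(tip_diff)
    arc_um = (gap_len + 2 * _TIP_FIT_PX) * cfg.pixel_size_nm / 1000.0
    curvature = turn_rad / arc_um
    if curvature > cfg.max_curvature_rad_per_um:
        return None
    score = cfg.weight_similarity * (1.0 - tip_diff / cfg.max_angle_diff_deg) + cfg.weight_continuity * (
        1.0 - gap_len / cfg.search_radius_px
    )
    return score, JoinRecord(
        gap_px=gap_len,
        gap_vector_angle_deg=gap_angle,
        tip_angle_diff_deg=tip_diff,
        endpoint_orientation_diff_deg=orient_diff,
        curvature_rad_per_um=curvature,
        score=score,
    )


def _merge(a: _Chain, ea: int, b: _Chain, eb: int) -> _Chain:
    """Concatenate two chains joined tip-to-tip, preserving order."""
    pa = a.points if ea == 1 else a.points[::-1]
    pb = b.points if eb == 0 else b.points[::-1]
    return _Chain(points=np.vstack([pa, pb]), n_fragments=a.n_fragments + b.n_fragments)


def group_fragments(
    pool: list[FilamentFragment],
    config: GroupingConfig | None = None,
) -> GroupingResult:
    """Group fragments into composite filaments under the hard constraints.

    Candidate joins must satisfy every constraint (search radius/cone,
    gap-vector angle, tip-angle difference, endpoint orientation difference,
    implied curvature); surviving candidates are scored by a convex
    combination of angle similarity and gap continuity and accepted greedily
    best-first with each tip used at most once per pass (fragment overlap is
    not allowed).  The matching pass runs ``config.n_iterations`` times with
    tips re-estimated after each pass.  All resulting filaments are returned;
    apply :func:`filter_filaments` for the minimum-length statistics cut.
    """
    cfg = config or GroupingConfig()
    chains = [_Chain(points=f.pixels.astype(float), n_fragments=1) for f in pool]
    joins: list[JoinRecord] = []
    for _ in range(cfg.n_iterations):
        chains, joined = _matching_to_fixed_point(chains, cfg, joins)
        if not joined:
            break
    filaments = [
        Filament(
            points_nm=c.points * cfg.pixel_size_nm,
            composite=c.n_fragments > 1,
            n_fragments=c.n_fragments,
        )
        for c in chains
        if len(c.points) >= 2
    ]
    return GroupingResult(filaments=filaments, joins=joins)


def _matching_to_fixed_point(
    chains: list[_Chain], cfg: GroupingConfig, joins: list[JoinRecord]
) -> tuple[list[_Chain], bool]:
    """Repeat greedy matching rounds until no further join is accepted.

    Within each round every tip is used at most once; merged chains
    re-estimate their tip tangents before the next round, so long filaments
    chopped into many fragments re-assemble without an a-priori bound on the
    fragment count.
    """
    any_join = False
    while True:
        candidates = []
        for i, a in enumerate(chains):
            for j, b in enumerate(chains):
                if i >= j:
                    continue
                for ea in (0, 1):
                    for eb in (0, 1):
                        hit = _evaluate_pair(a, ea, b, eb, cfg)
                        if hit is not None:
                            candidates.append((hit[0], i, ea, j, eb, hit[1]))
        # greedy best-score-first; deterministic tie-break by indices
        candidates.sort(key=lambda c: (-c[0], c[1], c[3], c[2], c[4]))
        used_tips: set[tuple[int, int]] = set()
        merges: list[tuple[int, int, int, int, JoinRecord]] = []
        for score, i, ea, j, eb, record in candidates:
            if (i, ea) in used_tips or (j, eb) in used_tips:
                continue
            used_tips.add((i, ea))
            used_tips.add((j, eb))
            merges.append((i, ea, j, eb, record))
        if not merges:
            break
        # apply merges via union of chain indices; one merge per tip means each
        # chain can gain at most one partner per end, forming simple paths
        parent = list(range(len(chains)))
        merged_map: dict[int, _Chain] = {i: c for i, c in enumerate(chains)}

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, ea, j, eb, record in merges:
            ri, rj = find(i), find(j)
            if ri == rj:  # would close a loop; skip
                continue
            ca, cb = merged_map[ri], merged_map[rj]
            # locate which ends of the merged chains correspond to the original tips
            tip_a = chains[i].tip_pos(ea)
            tip_b = chains[j].tip_pos(eb)
            ea_m = 0 if np.array_equal(ca.points[0], tip_a) else 1
            eb_m = 0 if np.array_equal(cb.points[0], tip_b) else 1
            if not np.array_equal(ca.tip_pos(ea_m), tip_a) or not np.array_equal(cb.tip_pos(eb_m), tip_b):
                continue  # tip consumed by an earlier merge this pass
            new = _merge(ca, ea_m, cb, eb_m)
            parent[rj] = ri
            merged_map[ri] = new
            del merged_map[rj]
            joins.append(record)
            any_join = True
        new_chains = [merged_map[find(i)] for i in sorted({find(i) for i in range(len(chains))})]
        if len(new_chains) == len(chains):
            return new_chains, any_join
        chains = new_chains
    return chains, any_join


def filter_filaments(filaments: list[Filament], config: GroupingConfig | None = None) -> list[Filament]:
    """Apply the minimum-length cut (default 15 px = 390 nm) for statistics."""
    cfg = config or GroupingConfig()
    min_um = cfg.min_filament_length_px * cfg.pixel_size_nm / 1000.0
    return [f for f in filaments if f.contour_length_um >= min_um]


def extract_filaments(
    section: np.ndarray,
    config: GroupingConfig | None = None,
    radius_px: int = 10,
    n_rotations: int = 40,
    apply_min_length: bool = True,
) -> GroupingResult:
    """Full extraction chain from a 2D section to retained filaments.

    enhance (LFT/OFT) -> Otsu segmentation, with a second Otsu pass
    restricted to the first mask to separate the on-ridge response from the
    lateral filter halo -> orientation-based non-maximum suppression ->
    fragment pool -> constraint grouping -> minimum-length cut.
    """
    cfg = config or GroupingConfig()
    enhanced = enhance_lft_oft(section, radius_px=radius_px, n_rotations=n_rotations)
    mask = segment_otsu(enhanced.lft)
    if mask.any() and np.ptp(enhanced.lft[mask]) > 0:
        threshold2 = threshold_otsu(enhanced.lft[mask], nbins=256)
        mask = mask & (enhanced.lft > threshold2)
    ridge = thin_ridge(enhanced, mask)
    pool = fragment_pool(ridge)
    result = group_fragments(pool, cfg)
    if apply_min_length:
        result = GroupingResult(filaments=filter_filaments(result.filaments, cfg), joins=result.joins)
    return result
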
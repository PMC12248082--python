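"""Seeded synthetic-data generators.

Every generator is a pure function of its parameters and seed: identical
inputs give bit-identical outputs.  The generators emulate the statistical
structure of the study's imaging and electrophysiology data -- planar
radially symmetric starburst amacrine cell (SAC) arbors, hard-core soma
mosaics, von Mises-modulated Poisson directional spiking, two-band inner
plexiform layer (IPL) lamination profiles, and distally biased synaptic
puncta -- so every downstream analysis is testable without external data.

Arbor growth model
------------------
Each of ``n_primary`` trunks is a biased random walk from the soma outward
to ``target_radius``.  While a trunk grows it spawns side branches as a
Poisson process at ``branch_rate`` per micrometre of trunk; side branches
grow outward with the same walk but do not branch further.  This
single-generation scheme makes the expected branch-point count exactly
``branch_rate x total trunk length`` -- linear in the rate -- so doubling
the branch rate doubles branching density while leaving the dendritic field
area (set by the trunks) unchanged, the phenotype contrast the package is
designed to exercise.  A recursive bifurcation process would instead grow
exponentially with ``branch_rate x target_radius`` and could not hold field
area and branch count independent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import GenerationError, ParameterError
from .types import (
    DENDRITE,
    SOMA,
    Arbor,
    DirectionalResponseSet,
    LaminationProfile,
    PointPattern,
    PunctaSet,
)

SOMA_RADIUS_UM = 4.5  # typical SAC soma radius

# Side-branch length is drawn uniformly in this fraction range of target_radius.
_SIDE_LEN_FRAC = (0.10, 0.30)
# Hypertrophic primary trunks carry a proximal diameter drawn in this range (um).
_HYPERTROPHIC_DIAM_RANGE = (1.2, 2.0)


# --------------------------------------------------------------------------
# parameter records
# --------------------------------------------------------------------------

@dataclass
class ArborGenParams:
    """Parameters of the synthetic SAC arbor generator.

    ``branch_rate`` is expected bifurcations per micrometre of trunk;
    ``radial_bias`` in [0, 1] weighs outward growth against isotropic
    wander (1 = perfectly radial spokes); ``caliber_taper`` is the
    (proximal, distal) dendrite diameter in micrometres; ``hypertrophic``
    gives exactly one primary trunk a proximal diameter above 1 um.
    """

    n_primary: int = 4
    target_radius: float = 150.0
    branch_rate: float = 0.03
    step_len: float = 1.0
    radial_bias: float = 0.8
    caliber_taper: tuple[float, float] = (0.8, 0.3)
    hypertrophic: bool = False
    z_jitter_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_primary < 1:
            raise ParameterError("n_primary must be >= 1")
        if self.target_radius <= 0:
            raise ParameterError("target_radius must be > 0")
        if self.branch_rate < 0:
            raise ParameterError("branch_rate must be >= 0")
        if self.step_len <= 0:
            raise ParameterError("step_len must be > 0")
        if not 0 <= self.radial_bias <= 1:
            raise ParameterError("radial_bias must be in [0, 1]")
        if self.z_jitter_sd < 0:
            raise ParameterError("z_jitter_sd must be >= 0")
        if min(self.caliber_taper) <= 0:
            raise ParameterError("caliber_taper diameters must be > 0")


@dataclass
class MosaicGenParams:
    """Hard-core (exclusion zone) soma mosaic parameters; ``dmin = 0`` is CSR."""

    n_points: int = 100
    window: tuple[float, float] = (300.0, 300.0)
    dmin: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 0:
            raise ParameterError("n_points must be >= 0")
        if min(self.window) <= 0:
            raise ParameterError("window dimensions must be > 0")
        if self.dmin < 0:
            raise ParameterError("dmin must be >= 0")


@dataclass
class MEAGenParams:
    """Von Mises-modulated Poisson spiking over evenly spaced directions.

    Direction-selective (DS) units fire at
    ``baseline_rate + ds_amplitude * exp(kappa * (cos(theta - mu) - 1))``
    spikes/s with a preferred direction ``mu`` drawn uniformly from the
    direction set; non-DS units fire at ``baseline_rate`` in every
    direction.  Counts per epoch are Poisson at the rate times
    ``epoch_dur``.
    """

    n_units: int = 100
    frac_ds: float = 0.3
    baseline_rate: float = 2.0
    ds_amplitude: float = 20.0
    kappa: float = 4.0
    n_directions: int = 12
    n_epochs: int = 5
    epoch_dur: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 0:
            raise ParameterError("n_units must be >= 0")
        if not 0 <= self.frac_ds <= 1:
            raise ParameterError("frac_ds must be in [0, 1]")
        if self.baseline_rate < 0 or self.ds_amplitude < 0:
            raise ParameterError("rates must be >= 0")
        if self.kappa < 0:
            raise ParameterError("kappa must be >= 0")
        if self.n_directions < 2 or self.n_directions % 2:
            raise ParameterError("n_directions must be even and >= 2")
        if self.n_epochs < 1:
            raise ParameterError("n_epochs must be >= 1")
        if self.epoch_dur <= 0:
            raise ParameterError("epoch_dur must be > 0")


# --------------------------------------------------------------------------
# arbor generation
# --------------------------------------------------------------------------

def _walk(rng: np.random.Generator, start_xy: np.ndarray, direction: np.ndarray,
          max_path_len: float, target_radius: float, step_len: float,
          radial_bias: float, z_jitter_sd: float) -> np.ndarray:
    """Biased outward random walk in the xy plane with per-node z jitter.

    Returns the (k, 3) node positions (excluding the start point).  Stops
    when the path length budget is exhausted or the radius reaches
    ``target_radius`` (the final node is clipped onto that radius).
    """
    pts = []
    pos = start_xy.astype(float).copy()
    d = direction / np.linalg.norm(direction)
    n_steps = max(1, int(round(max_path_len / step_len)))
    for _ in range(n_steps):
        r = np.linalg.norm(pos)
        radial = pos / r if r > 1e-9 else d
        if radial_bias < 1.0:
            ang = rng.uniform(0.0, 2.0 * math.pi)
            noise = np.array([math.cos(ang), math.sin(ang)])
            v = radial_bias * radial + (1.0 - radial_bias) * noise
            nv = np.linalg.norm(v)
            d = v / nv if nv > 1e-9 else radial
        else:
            d = radial
        pos = pos + step_len * d
        rr = np.linalg.norm(pos)
        clipped = False
        if rr >= target_radius:
            pos = pos * (target_radius / rr)
            clipped = True
        z = rng.normal(0.0, z_jitter_sd) if z_jitter_sd > 0 else 0.0
        pts.append((pos[0], pos[1], z))
        if clipped:
            break
    return np.array(pts, dtype=float).reshape(-1, 3)


def gen_arbor(params: ArborGenParams) -> Arbor:
    """Generate one synthetic SAC arbor as a rooted SWC-style tree.

    The root node is the soma at the origin; primary trunks leave it at
    evenly spaced angles.  Dendrite diameters taper linearly from the
    proximal to the distal value of ``caliber_taper`` over the radius; if
    ``hypertrophic``, exactly one trunk instead carries a proximal-half
    diameter drawn in (1.2, 2.0) um, tapering to the distal value beyond.
    """
    p = params
    rng = np.random.default_rng(p.seed)

    xyz = [np.zeros(3)]
    parent = [-1]
    radius = [SOMA_RADIUS_UM]
    ntype = [SOMA]

    prox_d, dist_d = p.caliber_taper

    def taper_diam(r: float) -> float:
        f = min(max(r / p.target_radius, 0.0), 1.0)
        return prox_d + (dist_d - prox_d) * f

    base_rot = rng.uniform(0.0, 2.0 * math.pi)
    hyper_primary = int(rng.integers(p.n_primary)) if p.hypertrophic else -1
    hyper_diam = float(rng.uniform(*_HYPERTROPHIC_DIAM_RANGE)) if p.hypertrophic else 0.0
    p_branch = min(p.branch_rate * p.step_len, 1.0)
    # trunks rarely need more than ~4x the radius in path length
    trunk_budget = 4.0 * p.target_radius

    def add_node(pos: np.ndarray, parent_idx: int, diam: float) -> int:
        xyz.append(np.asarray(pos, dtype=float))
        parent.append(parent_idx)
        radius.append(diam / 2.0)
        ntype.append(DENDRITE)
        return len(xyz) - 1

    for i in range(p.n_primary):
        phi = base_rot + 2.0 * math.pi * i / p.n_primary
        d0 = np.array([math.cos(phi), math.sin(phi)])
        trunk_pts = _walk(rng, np.zeros(2), d0, trunk_budget, p.target_radius,
                          p.step_len, p.radial_bias, p.z_jitter_sd)
        n_trunk = len(trunk_pts)
        spawn_sites: list[tuple[int, np.ndarray]] = []
        prev = 0  # soma
        for k, pt in enumerate(trunk_pts):
            r = float(np.linalg.norm(pt[:2]))
            if i == hyper_primary:
                if k < n_trunk / 2:
                    diam = hyper_diam
                else:
                    # taper from the hypertrophic caliber down to the distal value
                    f = (k - n_trunk / 2) / max(n_trunk / 2, 1)
                    diam = hyper_diam + (dist_d - hyper_diam) * f
            else:
                diam = taper_diam(r)
            idx = add_node(pt, prev, diam)
            # Poisson side-branch spawning along the trunk; never on the tip,
            # so a spawned node always has two children (continuation + side)
            if k < n_trunk - 1 and p_branch > 0 and rng.random() < p_branch:
                spawn_sites.append((idx, pt))
            prev = idx

        for site_idx, site_pt in spawn_sites:
            r0 = float(np.linalg.norm(site_pt[:2]))
            if r0 >= p.target_radius - p.step_len:
                continue
            radial = site_pt[:2] / max(r0, 1e-9)
            ang = rng.uniform(math.radians(30), math.radians(70)) * rng.choice([-1.0, 1.0])
            c, s = math.cos(ang), math.sin(ang)
            d_side = np.array([c * radial[0] - s * radial[1],
                               s * radial[0] + c * radial[1]])
            side_len = rng.uniform(*_SIDE_LEN_FRAC) * p.target_radius
            side_pts = _walk(rng, site_pt[:2].copy(), d_side, side_len,
                             p.target_radius, p.step_len, p.radial_bias, p.z_jitter_sd)
            prev = site_idx
            for pt in side_pts:
                r = float(np.linalg.norm(pt[:2]))
                prev = add_node(pt, prev, taper_diam(r))

    n = len(xyz)
    return Arbor(
        ids=np.arange(1, n + 1),
        parent_index=np.array(parent),
        xyz=np.vstack(xyz),
        radius=np.array(radius),
        node_type=np.array(ntype),
    )


# Qualitative genotype presets: the conditional knockout doubles branch density
# and usually carries a single hypertrophic primary dendrite; magnitudes mirror
# the direction of the reported effects, not their exact values.
GENOTYPE_PRESETS: dict[str, dict] = {
    "control": dict(n_primary=4, target_radius=150.0, branch_rate=0.32,
                    step_len=1.0, radial_bias=0.8, caliber_taper=(0.8, 0.3),
                    z_jitter_sd=0.3, hypertrophic_prob=0.0),
    "pten_cko": dict(n_primary=4, target_radius=150.0, branch_rate=0.64,
                     step_len=1.0, radial_bias=0.8, caliber_taper=(0.8, 0.3),
                     z_jitter_sd=0.3, hypertrophic_prob=0.8),
}


# --------------------------------------------------------------------------
# mosaic generation
# --------------------------------------------------------------------------

def gen_mosaic(params: MosaicGenParams) -> PointPattern:
    """Generate a soma mosaic: CSR when ``dmin = 0``, hard-core otherwise.

    Hard-core placement uses random sequential addition (dart throwing) with
    restarts.  Densities beyond the dart-throwing jamming limit fall back to
    a jittered hexagonal lattice whose spacing still respects ``dmin``; if
    even the lattice cannot fit ``n_points``, a :class:`GenerationError` is
    raised naming ``dmin`` and ``n_points``.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    w, h = p.window
    window = (0.0, 0.0, w, h)
    if p.n_points == 0:
        return PointPattern(np.empty((0, 2)), window)
    if p.dmin == 0:
        pts = np.column_stack([rng.uniform(0, w, p.n_points),
                               rng.uniform(0, h, p.n_points)])
        return PointPattern(pts, window)

    attempts_per_point = 2000
    cell = p.dmin  # bucket grid: only 3x3 neighbouring cells can conflict
    for _restart in range(5):
        placed: list[tuple[float, float]] = []
        grid: dict[tuple[int, int], list[tuple[float, float]]] = {}
        ok = True
        for _ in range(p.n_points):
            for _try in range(attempts_per_point):
                cx, cy = rng.uniform(0, w), rng.uniform(0, h)
                gx, gy = int(cx / cell), int(cy / cell)
                clear = True
                for nx in range(gx - 1, gx + 2):
                    for ny in range(gy - 1, gy + 2):
                        for qx, qy in grid.get((nx, ny), ()):
                            if (cx - qx) ** 2 + (cy - qy) ** 2 < p.dmin ** 2:
                                clear = False
                                break
                        if not clear:
                            break
                    if not clear:
                        break
                if clear:
                    placed.append((cx, cy))
                    grid.setdefault((gx, gy), []).append((cx, cy))
                    break
            else:
                ok = False
                break
        if ok:
            return PointPattern(np.array(placed), window)

    # Jittered hexagonal lattice fallback for packings dart throwing cannot reach.
    pts = _hex_lattice_mosaic(rng, p.n_points, w, h, p.dmin)
    if pts is None:
        raise GenerationError(
            f"cannot place n_points={p.n_points} at dmin={p.dmin} in a "
            f"{w:g} x {h:g} window"
        )
    return PointPattern(pts, window)


def _hex_lattice_mosaic(rng: np.random.Generator, n: int, w: float, h: float,
                        dmin: float) -> np.ndarray | None:
    # spacing giving slightly more than n sites on a hex lattice over the window
    s = math.sqrt(2.0 * w * h / (math.sqrt(3.0) * n)) * 0.98
    if s < dmin:
        return None
    jitter = (s - dmin) / 2.0
    row_h = s * math.sqrt(3.0) / 2.0
    pts = []
    y, row = jitter, 0
    while y <= h - jitter:
        x0 = jitter + (s / 2.0 if row % 2 else 0.0)
        x = x0
        while x <= w - jitter:
            pts.append((x, y))
            x += s
        y += row_h
        row += 1
    if len(pts) < n:
        return None
    pts = np.asarray(pts, dtype=float)
    keep = rng.choice(len(pts), size=n, replace=False)
    out = pts[keep] + rng.uniform(-jitter / math.sqrt(2.0), jitter / math.sqrt(2.0),
                                  size=(n, 2))
    return np.clip(out, [0.0, 0.0], [w, h])


# --------------------------------------------------------------------------
# MEA responses and layout
# --------------------------------------------------------------------------

def gen_mea_responses(params: MEAGenParams) -> DirectionalResponseSet:
    """Simulate per-epoch spike counts of sorted units to moving stimuli.

    Ground-truth DS labels are attached to the returned set so classifier
    recovery can be scored.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    directions = np.arange(p.n_directions) * (360.0 / p.n_directions)
    theta = np.deg2rad(directions)

    n_ds = int(round(p.frac_ds * p.n_units))
    is_ds = np.zeros(p.n_units, dtype=bool)
    if n_ds:
        is_ds[rng.choice(p.n_units, size=n_ds, replace=False)] = True

    counts = []
    for u in range(p.n_units):
        if is_ds[u]:
            mu = theta[rng.integers(p.n_directions)]
            rate = p.baseline_rate + p.ds_amplitude * np.exp(
                p.kappa * (np.cos(theta - mu) - 1.0)
            )
        else:
            rate = np.full(p.n_directions, p.baseline_rate)
        lam = p.epoch_dur * rate
        counts.append(rng.poisson(lam, size=(p.n_epochs, p.n_directions)))

    return DirectionalResponseSet(
        directions_deg=directions,
        epoch_dur_s=p.epoch_dur,
        unit_ids=[f"unit{u:04d}" for u in range(p.n_units)],
        counts=counts,
        ground_truth_ds=list(map(bool, is_ds)),
    )


def gen_mea_layout(pitch: float = 60.0, electrode_side: float = 21.0,
                   span: float = 3800.0) -> tuple[np.ndarray, int]:
    """Square high-density MEA grid: electrode centers and total site count.

    Rows are the largest ``k`` with ``(k - 1) * pitch + electrode_side``
    within the span; the quoted span of a commercial array is nominal, so a
    row may overhang it by up to 5% of the pitch (a 64 x 64 array at 60 um
    pitch with 21 um electrodes spans 3801 um, quoted as 3.8 mm).
    """
    if pitch <= 0:
        raise ParameterError("pitch must be > 0")
    if span < electrode_side:
        raise ParameterError("span must be >= electrode_side")
    k = int(math.floor((span - electrode_side) / pitch + 0.05)) + 1
    start = electrode_side / 2.0
    coords = start + pitch * np.arange(k)
    gx, gy = np.meshgrid(coords, coords, indexing="xy")
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    return centers, k * k


# --------------------------------------------------------------------------
# lamination profiles
# --------------------------------------------------------------------------

def gen_lamination(band_centers=(0.3, 0.7), band_sd: float = 0.05,
                   weights=(1.0, 1.0), noise_sd: float = 0.0,
                   n_samples: int = 200, seed: int = 0) -> LaminationProfile:
    """Sample a synthetic IPL intensity-vs-depth profile.

    The signal is a sum of Gaussian bands at the given normalized depths
    (the two SAC strata default to 0.3 and 0.7); additive Gaussian noise is
    truncated so intensities never go below zero.
    """
    band_centers = np.asarray(band_centers, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if len(band_centers) != len(weights):
        raise ParameterError("band_centers and weights length mismatch")
    if len(band_centers) and (band_centers.min() < 0 or band_centers.max() > 1):
        raise ParameterError("band centers must lie in [0, 1]")
    if len(weights) and weights.min() < 0:
        raise ParameterError("weights must be >= 0")
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")

    rng = np.random.default_rng(seed)
    depths = np.linspace(0.0, 1.0, n_samples)
    signal = np.zeros_like(depths)
    for c, wgt in zip(band_centers, weights):
        signal += wgt * np.exp(-0.5 * ((depths - c) / band_sd) ** 2)
    if noise_sd > 0:
        signal = np.clip(signal + rng.normal(0.0, noise_sd, n_samples), 0.0, None)
    if signal.sum() == 0:
        warnings.warn("degenerate lamination profile: zero intensity everywhere")
    return LaminationProfile(depths, signal)


# --------------------------------------------------------------------------
# synaptic puncta
# --------------------------------------------------------------------------

def gen_puncta(arbor: Arbor, n: int = 150, inner_boundary: float = 2.0 / 3.0,
               diam_mean: float = 0.8, diam_sd: float = 0.1,
               seed: int = 0) -> PunctaSet:
    """Place synaptic puncta on an arbor's dendrites, distally restricted.

    Locations are drawn uniformly over dendritic length, rejecting positions
    with normalized soma distance below ``inner_boundary`` (2/3 emulates
    output sites compartmentalized to the outer third of the arbor).
    Diameters are truncated-normal above zero; volume is the equivalent
    sphere ``(pi/6) d^3``.
    """
    if not 0 <= inner_boundary < 1:
        raise ParameterError("inner_boundary must be in [0, 1)")
    if n < 0:
        raise ParameterError("n must be >= 0")
    rng = np.random.default_rng(seed)

    parent_idx, child_idx = arbor.dendrite_segments()
    if len(child_idx) == 0:
        raise GenerationError("arbor has no dendrite segments")
    soma = arbor.soma_center
    extent = arbor.radial_extent
    a = arbor.xyz[parent_idx]
    b = arbor.xyz[child_idx]
    seg_len = np.linalg.norm(b - a, axis=1)
    # segments with any chance of exceeding the boundary
    far = np.maximum(np.linalg.norm(a - soma, axis=1),
                     np.linalg.norm(b - soma, axis=1)) / extent
    if not np.any(far >= inner_boundary):
        raise GenerationError(
            f"no dendrite beyond inner_boundary={inner_boundary:g}"
        )
    w = seg_len.copy()
    w[far < inner_boundary] = 0.0
    w = w / w.sum()

    pts = []
    budget = 200 * max(n, 1)
    while len(pts) < n and budget > 0:
        k = int(rng.choice(len(seg_len), p=w))
        t = rng.random()
        pos = a[k] + t * (b[k] - a[k])
        if np.linalg.norm(pos - soma) / extent >= inner_boundary:
            pts.append(pos)
        budget -= 1
    if len(pts) < n:
        raise GenerationError("could not place puncta beyond inner_boundary")

    if diam_sd > 0:
        lo = (0.0 - diam_mean) / diam_sd
        diam = sps.truncnorm.rvs(lo, np.inf, loc=diam_mean, scale=diam_sd,
                                 size=n, random_state=rng)
    else:
        diam = np.full(n, diam_mean)
    volumes = (math.pi / 6.0) * diam ** 3
    xyz = np.vstack(pts) if n else np.empty((0, 3))
    return PunctaSet(xyz, volumes, soma, extent)
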
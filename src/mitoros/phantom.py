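"""Synthetic voxel phantom of a local brain-tissue volume.

A 16 x 17 x 19 um parallelepiped holds 26 non-overlapping bodies
standing in for neuronal/glial somata and processes: two central spheres
of radius 3.1 um (the glutamate-stimulated, high-H2O2-production cells)
and 24 surrounding rounded-box superellipsoids (exponent 6) arranged on
a jittered 3 x 3 x 3 lattice.  The surrounding bodies are scaled
iteratively until the analytic cell volume fraction reaches 0.60; the
two central spheres alone occupy 4.8% of the box.  Inter-body gaps are
kept at or above one voxel (0.25 um) -- far wider than the ~8 nm
interstitial clefts of real neuropil, a deliberate resolution compromise
recorded in the package documentation.

Coordinates are centred: x in [-8, 8], y in [-8.5, 8.5],
z in [-9.5, 9.5] um.  The central axis used for concentration profiles
is the line y = -5 um, z = 0, running along x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhantomConfig",
    "Body",
    "Phantom",
    "generate_phantom",
    "LABEL_ISF",
    "LABEL_CELL",
    "LABEL_HIGH",
    "superellipsoid_volume",
]

LABEL_ISF = 0
LABEL_CELL = 1
LABEL_HIGH = 2


@dataclass(frozen=True)
class PhantomConfig:
    domain_um: tuple[float, float, float] = (16.0, 17.0, 19.0)
    voxel_um: float = 0.25
    n_bodies: int = 26
    n_high: int = 2
    central_radius_um: float = 3.1
    central_offset_um: float = 3.35   # +-z placement of the two spheres
    target_cell_fraction: float = 0.60
    fraction_tol: float = 0.01
    gap_um: float = 0.25              # minimum inter-surface gap (one voxel)
    jitter_um: float = 0.1
    exponent: float = 6.0             # superellipsoid shape exponent
    axis_y_um: float = -5.0           # central-axis height (Fig-8 style)

    def __post_init__(self) -> None:
        nx, ny, nz = (d / self.voxel_um for d in self.domain_um)
        for n in (nx, ny, nz):
            if abs(n - round(n)) > 1e-9:
                raise ValueError("voxel size must divide the domain exactly")


def superellipsoid_volume(a: float, b: float, c: float, n: float) -> float:
    """Closed-form volume of |x/a|^n + |y/b|^n + |z/c|^n <= 1."""
    g = math.gamma(1.0 + 1.0 / n)
    return 8.0 * a * b * c * g ** 3 / math.gamma(1.0 + 3.0 / n)


@dataclass
class Body:
    kind: str                  # "sphere" | "superellipsoid"
    center: np.ndarray
    semiaxes: np.ndarray       # (r, r, r) for spheres
    label: int
    exponent: float = 2.0

    @property
    def volume(self) -> float:
        a, b, c = self.semiaxes
        if self.kind == "sphere":
            return 4.0 / 3.0 * math.pi * a * b * c
        return superellipsoid_volume(a, b, c, self.exponent)

    def inside(self, x, y, z):
        """Boolean mask of points inside the body (broadcasting)."""
        a, b, c = self.semiaxes
        n = 2.0 if self.kind == "sphere" else self.exponent
        u = (np.abs(x - self.center[0]) / a) ** n
        v = (np.abs(y - self.center[1]) / b) ** n
        w = (np.abs(z - self.center[2]) / c) ** n
        return u + v + w <= 1.0


@dataclass
class Phantom:
    config: PhantomConfig
    bodies: list[Body]
    labels: np.ndarray            # (nx, ny, nz) uint8
    voxel_um: float
    origin_um: np.ndarray         # coordinate of the corner of voxel (0,0,0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def cell_fraction_analytic(self) -> float:
        box = np.prod(self.config.domain_um)
        return sum(b.volume for b in self.bodies) / box

    @property
    def high_fraction_analytic(self) -> float:
        box = np.prod(self.config.domain_um)
        return sum(b.volume for b in self.bodies
                   if b.label == LABEL_HIGH) / box

    def voxel_centers(self):
        """1-D coordinate arrays of voxel centres along each axis (um)."""
        h = self.voxel_um
        return tuple(
            self.origin_um[i] + h * (np.arange(self.shape[i]) + 0.5)
            for i in range(3))

    def initial_concentration(self, c_cell_nM: float = 10.0,
                              c_isf_nM: float = 5.0) -> np.ndarray:
        c = np.full(self.shape, c_isf_nM, dtype=float)
        c[self.labels != LABEL_ISF] = c_cell_nM
        return c

    def mean_initial_concentration(self, c_cell_nM: float = 10.0,
                                   c_isf_nM: float = 5.0) -> float:
        """Volume-weighted mean using the analytic cell fraction."""
        f = self.cell_fraction_analytic
        return f * c_cell_nM + (1.0 - f) * c_isf_nM

    def axis_points(self):
        """Voxel-resolution sample points along the central axis (um)."""
        xs = self.voxel_centers()[0]
        y = np.full_like(xs, self.config.axis_y_um)
        z = np.zeros_like(xs)
        return xs, y, z


def _lattice_bodies(cfg: PhantomConfig, rng: np.random.Generator):
    lx, ly, lz = cfg.domain_um
    cx, cy, cz = lx / 3.0, ly / 3.0, lz / 3.0
    # cap so that two worst-jittered neighbours keep a full gap between them
    cap0 = np.array([(cx - cfg.gap_um) / 2.0 - cfg.jitter_um,
                     (cy - cfg.gap_um) / 2.0 - cfg.jitter_um,
                     (cz - cfg.gap_um) / 2.0 - cfg.jitter_um])
    bodies: list[Body] = []
    caps: list[np.ndarray] = []
    # the two glutamate-stimulated bodies sit on the central axis
    # (y = axis_y, z = 0), which therefore penetrates them; they replace
    # the lattice row the axis runs through and are surrounded by the
    # remaining 24 bodies
    for dx in (-1.0, 1.0):
        bodies.append(Body("sphere",
                           np.array([dx * cfg.central_offset_um,
                                     cfg.axis_y_um, 0.0]),
                           np.full(3, cfg.central_radius_um), LABEL_HIGH))
        caps.append(np.full(3, cfg.central_radius_um))
    axis_j = 0 if cfg.axis_y_um < -cy / 2 else 1
    for i in range(3):
        for j in range(3):
            for k in range(3):
                if j == axis_j and k == 1:
                    continue  # row occupied by the two central spheres
                center = np.array([(i - 1) * cx, (j - 1) * cy, (k - 1) * cz])
                center = center + rng.uniform(-cfg.jitter_um, cfg.jitter_um, 3)
                cap = cap0.copy()
                if j == 1 and k == 1 and axis_j == 0:
                    # row facing the spheres across y: cap the y semi-axis
                    # so the rounded-box corner clears the spherical bulge
                    cap[1] = min(cap[1], 1.8)
                semi = cap * rng.uniform(0.94, 0.97, 3)
                bodies.append(Body("superellipsoid", center, semi,
                                   LABEL_CELL, cfg.exponent))
                caps.append(cap)
    return bodies, caps


def _scale_to_fraction(cfg: PhantomConfig, bodies: list[Body],
                       caps: list[np.ndarray], max_iter: int = 60) -> None:
    """Iteratively rescale the surrounding bodies to the target fraction."""
    box = float(np.prod(cfg.domain_um))
    target_vol = cfg.target_cell_fraction * box
    v_high = sum(b.volume for b in bodies if b.label == LABEL_HIGH)
    for _ in range(max_iter):
        v_sur = sum(b.volume for b in bodies if b.label == LABEL_CELL)
        s = ((target_vol - v_high) / v_sur) ** (1.0 / 3.0)
        s = float(np.clip(s, 0.9, 1.03))  # approach the caps gradually
        all_capped = True
        for b, cap in zip(bodies, caps):
            if b.label != LABEL_CELL:
                continue
            new = np.minimum(b.semiaxes * s, cap)
            all_capped &= bool(np.all(new >= cap - 1e-12))
            b.semiaxes = new
        frac = sum(b.volume for b in bodies) / box
        if abs(frac - cfg.target_cell_fraction) < cfg.fraction_tol / 5.0:
            return
        if s > 1.0 and all_capped:
            break  # cannot grow further
    frac = sum(b.volume for b in bodies) / box
    if abs(frac - cfg.target_cell_fraction) > cfg.fraction_tol:
        raise RuntimeError(
            f"could not reach cell fraction {cfg.target_cell_fraction} "
            f"(got {frac:.4f}); loosen gap/jitter settings")


def _voxelize(cfg: PhantomConfig, bodies: list[Body]):
    h = cfg.voxel_um
    shape = tuple(int(round(d / h)) for d in cfg.domain_um)
    origin = -np.asarray(cfg.domain_um) / 2.0
    xs = origin[0] + h * (np.arange(shape[0]) + 0.5)
    ys = origin[1] + h * (np.arange(shape[1]) + 0.5)
    zs = origin[2] + h * (np.arange(shape[2]) + 0.5)
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]
    labels = np.zeros(shape, dtype=np.uint8)
    claimed = np.zeros(shape, dtype=bool)
    for body in bodies:
        mask = body.inside(X, Y, Z)
        if np.any(mask & claimed):
            raise RuntimeError(f"bodies overlap at the voxel level ({body.kind})")
        claimed |= mask
        labels[mask] = body.label
    return labels, origin


def _check_gaps(bodies: list[Body], gap: float, n_test: int = 2000,
                rng: np.random.Generator | None = None) -> None:
    """Surface-sample check that no two bodies come closer than ``gap``."""
    rng = rng or np.random.default_rng(0)
    pts = []
    for body in bodies:
        u = rng.normal(size=(n_test, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        if body.kind == "sphere":
            surf = body.center + u * body.semiaxes
        else:
            n = body.exponent
            norm = (np.abs(u) ** n).sum(axis=1) ** (1.0 / n)
            surf = body.center + (u / norm[:, None]) * body.semiaxes
        pts.append(surf)
    for i, body in enumerate(bodies):
        a, b, c = body.semiaxes
        n = 2.0 if body.kind == "sphere" else body.exponent
        for j, other_pts in enumerate(pts):
            if i == j:
                continue
            d = other_pts - body.center
            val = ((np.abs(d[:, 0]) / (a + gap)) ** n
                   + (np.abs(d[:, 1]) / (b + gap)) ** n
                   + (np.abs(d[:, 2]) / (c + gap)) ** n)
            if np.any(val < 1.0):
                return (i, j)
    return None


def generate_phantom(config: PhantomConfig | None = None,
                     seed: int = 0) -> Phantom:
    """Build the 26-body voxel phantom, deterministic for a given seed.

    The two central spheres are fixed; the 24 surrounding bodies are
    jittered by the seeded RNG and rescaled until the analytic cell
    volume fraction is 0.60 within tolerance, with at least one voxel of
    interstitial fluid between any two surfaces.
    """
    cfg = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    bodies, caps = _lattice_bodies(cfg, rng)
    for attempt in range(40):
        _scale_to_fraction(cfg, bodies, caps)
        pair = _check_gaps(bodies, cfg.gap_um * 0.999,
                           rng=np.random.default_rng(seed + 1))
        if pair is None:
            break
        # tighten the caps of the offending surrounding bodies and retry
        shrunk = False
        for idx in pair:
            if bodies[idx].label == LABEL_CELL:
                caps[idx] = caps[idx] * 0.98
                bodies[idx].semiaxes = np.minimum(bodies[idx].semiaxes,
                                                  caps[idx])
                shrunk = True
        if not shrunk:  # pragma: no cover
            raise RuntimeError(f"central bodies {pair} violate the gap")
    else:  # pragma: no cover
        raise RuntimeError("could not resolve inter-body gaps")
    labels, origin = _voxelize(cfg, bodies)
    phantom = Phantom(cfg, bodies, labels, cfg.voxel_um, origin)
    n_high = sum(1 for b in bodies if b.label == LABEL_HIGH)
    if len(bodies) != cfg.n_bodies or n_high != cfg.n_high:
        raise RuntimeError("body catalogue inconsistent")
    return phantom
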
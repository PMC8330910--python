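"""Hydrogen-peroxide transport in the tissue phantom.

Solves the linear reaction-convection-diffusion problem

    dc/dt = div(D grad c) - u . grad c + J(x)

on the phantom's uniform voxel grid with a finite-volume 7-point
diffusion stencil and first-order upwind convection along +x (the
interstitial-fluid bulk flow direction).  Production J is positive
inside cell bodies (a higher rate in the two glutamate-stimulated
central bodies) and zero in the interstitial fluid; consumption is
already folded into the net production rates.

Boundary conditions: the inflow face (x = 0) carries a Danckwerts
total-flux condition against the interstitial concentration, the
outflow face (x = L) has zero diffusive flux (purely convective
outflow), and the four lateral faces hold a fixed interstitial
concentration.

Concentrations are in nM, lengths in um, time in s; the printed SI
parameters are converted on construction.  Time stepping is implicit
Euler (unconditionally stable; no CFL restriction), with a direct
sparse solve reused across steps of equal size; the steady state is
available from a single linear solve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, bicgstab, spilu

from .constants import um_per_min_to_nm_per_s
from .phantom import LABEL_CELL, LABEL_HIGH, Phantom

__all__ = ["PdeParams", "Operator", "FieldState", "assemble_operator",
           "solve_transient", "steady_state", "axis_profile"]


@dataclass(frozen=True)
class PdeParams:
    """Transport and production parameters (printed values)."""

    d_m2_s: float = 1.83e-9          # H2O2 diffusion coefficient
    u_isf_m_s: float = 5.0e-7        # ISF bulk flow speed, along +x
    j_normal_um_min: float = 5.05    # production in normal cell bodies
    j_high_um_min: float = 106.0     # glutamate-stimulated production
    c0_cell_nM: float = 10.0
    c0_isf_nM: float = 5.0

    def __post_init__(self) -> None:
        for f in ("d_m2_s", "u_isf_m_s", "j_normal_um_min",
                  "j_high_um_min", "c0_cell_nM", "c0_isf_nM"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    @property
    def d_um2_s(self) -> float:
        return self.d_m2_s * 1e12

    @property
    def u_um_s(self) -> float:
        return self.u_isf_m_s * 1e6

    @property
    def j_normal_nM_s(self) -> float:
        return um_per_min_to_nm_per_s(self.j_normal_um_min)

    @property
    def j_high_nM_s(self) -> float:
        return um_per_min_to_nm_per_s(self.j_high_um_min)


@dataclass
class FieldState:
    """Concentration field (nM) on the phantom grid at one time."""

    concentration: np.ndarray
    time: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.concentration)):
            raise ValueError("concentration field contains non-finite values")


class Operator:
    """Discrete spatial operator: dc/dt = A c + b."""

    def __init__(self, phantom: Phantom, params: PdeParams,
                 lateral_bcs: dict | None = None):
        """``lateral_bcs`` optionally overrides the four non-flow faces:
        keys ``y0, y1, z0, z1`` map to a Dirichlet value or ``None`` for a
        no-flux face (default: all Dirichlet at the ISF concentration)."""
        self.phantom = phantom
        self.params = params
        self.shape = phantom.shape
        self.h = phantom.voxel_um
        self.n = int(np.prod(self.shape))
        c_isf = params.c0_isf_nM
        self.lateral_bcs = {"y0": c_isf, "y1": c_isf,
                            "z0": c_isf, "z1": c_isf}
        if lateral_bcs:
            self.lateral_bcs.update(lateral_bcs)
        self._assemble()
        self._lu_cache: dict[float, object] = {}

    # --- assembly ----------------------------------------------------------

    def _assemble(self) -> None:
        nx, ny, nz = self.shape
        h = self.h
        D = self.params.d_um2_s
        u = self.params.u_um_s
        c_isf = self.params.c0_isf_nM
        kd = D / h ** 2
        ka = u / h
        self.peclet = u * h / D
        if self.peclet > 2.0:  # pragma: no cover
            warnings.warn(f"cell Peclet number {self.peclet:.2f} > 2; "
                          "upwind convection will be diffusive")

        n = self.n
        idx = np.arange(n).reshape(self.shape)
        diag = np.zeros(n)
        b = np.zeros(n)
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []

        def couple(i, j, w):
            rows.append(i.ravel())
            cols.append(j.ravel())
            vals.append(np.full(i.size, w))

        # diffusion between x-neighbours
        i, j = idx[:-1, :, :], idx[1:, :, :]
        couple(i, j, kd); couple(j, i, kd)
        np.add.at(diag, i.ravel(), -kd)
        np.add.at(diag, j.ravel(), -kd)
        # upwind convection along +x: the interior face between i and i+1
        # carries u*c_i, leaving cell i and entering cell i+1
        np.add.at(diag, i.ravel(), -ka)
        couple(j, i, ka)
        # y-neighbours (diffusion only)
        i, j = idx[:, :-1, :], idx[:, 1:, :]
        couple(i, j, kd); couple(j, i, kd)
        np.add.at(diag, i.ravel(), -kd)
        np.add.at(diag, j.ravel(), -kd)
        # z-neighbours
        i, j = idx[:, :, :-1], idx[:, :, 1:]
        couple(i, j, kd); couple(j, i, kd)
        np.add.at(diag, i.ravel(), -kd)
        np.add.at(diag, j.ravel(), -kd)

        # inflow face x = 0: Danckwerts -- the total (advective + diffusive)
        # flux through the face equals the convective influx u*c_isf
        west = idx[0, :, :].ravel()
        b[west] += ka * c_isf
        # outflow face x = L: zero diffusive flux, purely convective u*c
        east = idx[-1, :, :].ravel()
        np.add.at(diag, east, -ka)

        # lateral faces (y and z extremes): Dirichlet ghost at half-cell
        # distance, or no-flux where the value is None
        faces = {"y0": idx[:, 0, :], "y1": idx[:, -1, :],
                 "z0": idx[:, :, 0], "z1": idx[:, :, -1]}
        for key, face in faces.items():
            c_face = self.lateral_bcs[key]
            if c_face is None:
                continue
            f = face.ravel()
            np.add.at(diag, f, -2.0 * kd)
            b[f] += 2.0 * kd * c_face

        rows.append(np.arange(n)); cols.append(np.arange(n)); vals.append(diag)
        self.A = sparse.csr_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n))

        # sources
        src = np.zeros(self.shape)
        src[self.phantom.labels == LABEL_CELL] = self.params.j_normal_nM_s
        src[self.phantom.labels == LABEL_HIGH] = self.params.j_high_nM_s
        self.source = src
        self.b = b + src.ravel()

    # --- linear algebra -----------------------------------------------------

    def rhs(self, c: np.ndarray) -> np.ndarray:
        return (self.A @ c.ravel() + self.b).reshape(self.shape)

    def _stepper(self, dt: float):
        """Implicit-Euler matrix and Jacobi preconditioner for one dt."""
        key = round(dt, 12)
        if key not in self._lu_cache:
            M = (sparse.identity(self.n, format="csr") - dt * self.A).tocsr()
            dinv = 1.0 / M.diagonal()
            self._lu_cache[key] = (M, LinearOperator(
                M.shape, lambda x, dinv=dinv: dinv * x))
        return self._lu_cache[key]

    def step(self, c: np.ndarray, dt: float, rtol: float = 1e-11
             ) -> np.ndarray:
        """One implicit-Euler step (warm-started BiCGStab, Jacobi prec)."""
        M, prec = self._stepper(dt)
        rhs = c.ravel() + dt * self.b
        x, code = bicgstab(M, rhs, x0=c.ravel(), M=prec, rtol=rtol,
                           atol=rtol * float(np.linalg.norm(rhs)),
                           maxiter=5000)
        if code != 0:  # pragma: no cover
            raise RuntimeError(f"implicit step solver failed (code {code})")
        return x.reshape(self.shape)

    def steady(self, rtol: float = 1e-10) -> np.ndarray:
        """Steady solve A c = -b (ILU-preconditioned BiCGStab)."""
        ilu = spilu(self.A.tocsc(), drop_tol=1e-4, fill_factor=8)
        prec = LinearOperator(self.A.shape, ilu.solve)
        rhs = -self.b
        x0 = np.full(self.n, self.params.c0_isf_nM)
        x, code = bicgstab(self.A, rhs, x0=x0, M=prec, rtol=rtol,
                           atol=rtol * float(np.linalg.norm(rhs)),
                           maxiter=5000)
        if code != 0:  # pragma: no cover
            raise RuntimeError(f"steady solver failed (code {code})")
        return x.reshape(self.shape)

    # --- diagnostics --------------------------------------------------------

    def boundary_fluxes(self, c: np.ndarray) -> dict[str, float]:
        """Net boundary fluxes (nM um^3 / s), computed from face formulas."""
        h = self.h
        D = self.params.d_um2_s
        u = self.params.u_um_s
        c_isf = self.params.c0_isf_nM
        area = h * h
        cf = np.asarray(c).reshape(self.shape)
        inflow = u * c_isf * area * cf.shape[1] * cf.shape[2]
        outflow = -u * area * float(cf[-1].sum())
        lateral = 0.0
        slabs = {"y0": cf[:, 0, :], "y1": cf[:, -1, :],
                 "z0": cf[:, :, 0], "z1": cf[:, :, -1]}
        for key, sl in slabs.items():
            c_face = self.lateral_bcs[key]
            if c_face is None:
                continue
            lateral += 2.0 * D / h * area * float((c_face - sl).sum())
        return {"inflow": inflow, "outflow": outflow, "lateral": lateral}

    def mass_balance_residual(self, c0: np.ndarray, c1: np.ndarray,
                              dt: float) -> float:
        """Relative closure error of one implicit step's mass balance."""
        h3 = self.h ** 3
        change = (c1.sum() - c0.sum()) * h3
        fluxes = self.boundary_fluxes(c1)
        sources = float(self.source.sum()) * h3
        expected = dt * (sources + sum(fluxes.values()))
        scale = max(abs(change), abs(expected), 1e-30)
        return abs(change - expected) / scale


def assemble_operator(phantom: Phantom, params: PdeParams | None = None,
                      lateral_bcs: dict | None = None) -> Operator:
    """Build the finite-volume operator for a phantom geometry."""
    return Operator(phantom, params or PdeParams(), lateral_bcs)


def solve_transient(op: Operator, init: FieldState,
                    report_times: list[float],
                    dt_max: float = 2e-3,
                    track_axis: Phantom | None = None
                    ) -> tuple[list[FieldState], dict]:
    """Implicit-Euler evolution, reporting the field at requested times.

    Steps never exceed ``dt_max`` (accuracy, not stability); the LU
    factorisation is reused across equal steps.  If ``track_axis`` is
    given, the running maximum of the central-axis profile (and its
    time) is recorded every step.
    """
    times = sorted(set(float(t) for t in report_times))
    c = np.array(init.concentration, dtype=float)
    t = init.time
    out: list[FieldState] = []
    info = {"axis_max": -np.inf, "axis_max_time": t, "global_max": -np.inf}

    def track():
        info["global_max"] = max(info["global_max"], float(c.max()))
        if track_axis is not None:
            prof = axis_profile(FieldState(c, t), track_axis)[1]
            m = float(prof.max())
            if m > info["axis_max"]:
                info["axis_max"] = m
                info["axis_max_time"] = t

    track()
    if times and times[0] <= t:
        out.append(FieldState(c.copy(), t))
        times = [tt for tt in times if tt > t]
    for target in times:
        while t < target - 1e-12:
            dt = min(dt_max, target - t)
            c = op.step(c, dt)
            t += dt
            track()
        out.append(FieldState(c.copy(), t))
    return out, info


def steady_state(op: Operator) -> FieldState:
    """Steady solution of the linear problem (single direct solve)."""
    return FieldState(op.steady(), np.inf)


def axis_profile(field: FieldState, phantom: Phantom):
    """Concentration along the central axis by trilinear interpolation.

    Returns ``(x_um, c_nM)`` sampled at voxel resolution along the line
    y = axis_y, z = 0.  Interpolation is exact for fields linear in the
    coordinates.
    """
    from scipy.ndimage import map_coordinates

    xs, ys, zs = phantom.axis_points()
    h = phantom.voxel_um
    o = phantom.origin_um
    # voxel-index coordinates of the sample points (centres at i + 0.5)
    ci = (xs - o[0]) / h - 0.5
    cj = (ys - o[1]) / h - 0.5
    ck = (zs - o[2]) / h - 0.5
    prof = map_coordinates(field.concentration, np.vstack([ci, cj, ck]),
                           order=1, mode="nearest")
    return xs, prof
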
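"""2-D finite-element EIT forward solver on an elliptical arm phantom.

The arm cross-section is an outer ellipse (muscle) containing two smaller
ellipses (ulna and radius, low conductivity).  The quasi-static forward
problem div(sigma grad u) = 0 is discretised with linear (P1) triangles;
current is injected through a gap-model electrode pair (uniform current
density over a boundary arc) and boundary voltages are read differentially
between passive electrode pairs.  The 30 kHz excitation of the real
hardware is represented only by its RMS amplitude: the solver is
real-valued and per-unit-depth (2-D), so absolute voltages are amplitudes
up to the implicit out-of-plane thickness.

Default tissue conductivities: muscle 0.5448 S/m, bone 0.02043 S/m;
default drive current 300 uA RMS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import Delaunay

from .protocols import ElectrodeRing, MeasurementSchedule, build_ring

__all__ = [
    "SIGMA_MUSCLE",
    "SIGMA_BONE",
    "Ellipse",
    "Mesh",
    "ArmPhantom",
    "DriveCurrent",
    "ForwardSolution",
    "ellipse_mesh",
    "build_phantom",
    "default_phantom",
    "phantom_from_config",
    "solve_forward",
    "measure",
    "excitation_switch_steps",
    "current_density",
    "dissipated_power",
    "solution_to_frame",
]

SIGMA_MUSCLE = 0.5448  # S/m, arm muscle
SIGMA_BONE = 0.02043  # S/m, arm bone

#: mesh edge-length targets (mm): ``fine`` ~2500 elements for physics
#: checks, ``coarse`` ~650 elements for dataset simulation.
MESH_H_FINE = 1.6
MESH_H_COARSE = 3.2


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned-then-rotated ellipse: center, semi-axes (mm), rotation."""

    cx: float
    cy: float
    ra: float
    rb: float
    angle: float = 0.0

    @property
    def degenerate(self) -> bool:
        return self.ra <= 0.0 or self.rb <= 0.0

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.degenerate:
            return np.zeros(np.shape(x), dtype=bool)
        c, s = np.cos(self.angle), np.sin(self.angle)
        dx, dy = x - self.cx, y - self.cy
        u = c * dx + s * dy
        v = -s * dx + c * dy
        return (u / self.ra) ** 2 + (v / self.rb) ** 2 <= 1.0

    def boundary_points(self, n: int = 64) -> np.ndarray:
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        u, v = self.ra * np.cos(t), self.rb * np.sin(t)
        c, s = np.cos(self.angle), np.sin(self.angle)
        return np.column_stack(
            [self.cx + c * u - s * v, self.cy + s * u + c * v]
        )


@dataclass
class Mesh:
    """Conforming triangulation with precomputed P1 assembly data."""

    nodes: np.ndarray  # (N, 2)
    tris: np.ndarray  # (M, 3)
    boundary_nodes: np.ndarray  # indices of outer-boundary nodes
    boundary_theta: np.ndarray  # parametric angle of each boundary node
    areas: np.ndarray = field(init=False)
    centroids: np.ndarray = field(init=False)
    _ke: np.ndarray = field(init=False)  # (M, 3, 3) unit-sigma stiffness
    _rows: np.ndarray = field(init=False)
    _cols: np.ndarray = field(init=False)
    _grads: np.ndarray = field(init=False)  # (M, 2, 3) basis gradients

    def __post_init__(self) -> None:
        p = self.nodes[self.tris]  # (M, 3, 2)
        x, y = p[..., 0], p[..., 1]
        # b_i = y_j - y_k, c_i = x_k - x_j (cyclic)
        b = np.stack(
            [x[:, 1] * 0 + y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]],
            axis=1,
        )
        c = np.stack(
            [x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1
        )
        det = b[:, 0] * c[:, 1] - b[:, 1] * c[:, 0]
        area2 = x[:, 0] * b[:, 0] + x[:, 1] * b[:, 1] + x[:, 2] * b[:, 2]
        self.areas = 0.5 * np.abs(area2)
        if np.any(self.areas <= 1e-12):
            raise ValueError("degenerate (zero-area) mesh element")
        self.centroids = p.mean(axis=1)
        ke = (
            b[:, :, None] * b[:, None, :] + c[:, :, None] * c[:, None, :]
        ) / (4.0 * self.areas)[:, None, None]
        self._ke = ke
        self._rows = np.repeat(self.tris, 3, axis=1).reshape(-1)
        self._cols = np.tile(self.tris, (1, 3)).reshape(-1)
        self._grads = np.stack([b, c], axis=1) / (2.0 * self.areas)[:, None, None]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tris)

    def assemble(self, sigma: np.ndarray) -> sp.csr_matrix:
        """Stiffness matrix for element conductivities ``sigma`` (M,)."""
        data = (sigma[:, None, None] * self._ke).reshape(-1)
        a = sp.coo_matrix(
            (data, (self._rows, self._cols)), shape=(self.n_nodes, self.n_nodes)
        )
        return a.tocsr()


def ellipse_mesh(a: float, b: float, h: float) -> Mesh:
    """Unstructured triangulation of an ellipse with semi-axes a, b.

    Points are laid out on concentric rings in normalised (unit-disk)
    coordinates, Delaunay-triangulated there for quality, and the nodes
    mapped affinely to the ellipse.  ``h`` is the target edge length in
    the same units as the axes.  Boundary nodes carry their parametric
    angle, used to attach electrode arcs.
    """
    if a <= 0 or b <= 0 or h <= 0:
        raise ValueError("ellipse axes and edge length must be positive")
    # Ramanujan perimeter approximation
    lam = ((a - b) / (a + b)) ** 2
    perim = np.pi * (a + b) * (1 + 3 * lam / (10 + np.sqrt(4 - 3 * lam)))
    # multiple of 8 so boundary nodes land symmetrically under the
    # electrode positions of the 8-ring
    n_b = max(48, 8 * int(round(perim / h / 8)))
    n_rings = max(3, int(round(min(a, b) / h)))
    pts = [np.zeros((1, 2))]
    ring_counts = []
    for k in range(1, n_rings + 1):
        r = k / n_rings
        n_k = max(6, int(round(n_b * r)))
        if k == n_rings:
            n_k = n_b
        # offset alternate rings for better triangle shapes
        t = 2.0 * np.pi * (np.arange(n_k) + 0.5 * (k % 2)) / n_k
        if k == n_rings:
            t = 2.0 * np.pi * np.arange(n_k) / n_k
        pts.append(np.column_stack([r * np.cos(t), r * np.sin(t)]))
        ring_counts.append(n_k)
    unit = np.vstack(pts)
    tri = Delaunay(unit)
    nodes = unit * np.array([a, b])
    n_total = len(unit)
    boundary = np.arange(n_total - n_b, n_total)
    theta = np.mod(np.arctan2(unit[boundary, 1], unit[boundary, 0]), 2 * np.pi)
    return Mesh(
        nodes=nodes,
        tris=tri.simplices.copy(),
        boundary_nodes=boundary,
        boundary_theta=theta,
    )


@dataclass
class ArmPhantom:
    """Arm cross-section phantom: geometry, mesh and conductivity field."""

    outer: Ellipse
    bones: tuple[Ellipse, ...]
    sigma_muscle: float
    sigma_bone: float
    mesh: Mesh
    ring: ElectrodeRing
    electrode_width: float  # arc half-width is width/2, in parametric rad
    element_sigma: np.ndarray  # (M,) baseline conductivity per element
    bone_mask: np.ndarray  # (M,) bool

    def region_mask(self, cx: float, cy: float, radius: float) -> np.ndarray:
        """Elements whose centroid lies in a circular muscle sub-region."""
        d2 = (self.mesh.centroids[:, 0] - cx) ** 2 + (
            self.mesh.centroids[:, 1] - cy
        ) ** 2
        return (d2 <= radius**2) & ~self.bone_mask

    def electrode_node_weights(
        self, k: int, rotation: float = 0.0
    ) -> tuple[np.ndarray, np.ndarray]:
        """Boundary nodes under electrode ``k`` and their current-sharing
        weights (gap model: uniform density over the arc, so weights are
        proportional to each node's share of the arc).  ``rotation``
        rotates the whole ring, emulating re-worn electrodes."""
        center = self.ring.angles[k] + rotation
        theta = self.mesh.boundary_theta
        d = np.abs(np.mod(theta - center + np.pi, 2 * np.pi) - np.pi)
        sel = d <= self.electrode_width / 2.0
        if not np.any(sel):  # arc narrower than node spacing
            sel = d == d.min()
        idx = self.mesh.boundary_nodes[sel]
        w = np.ones(len(idx))
        return idx, w / w.sum()


def _check_geometry(outer: Ellipse, bones: Sequence[Ellipse]) -> None:
    live = [bn for bn in bones if not bn.degenerate]
    for bn in live:
        bp = bn.boundary_points(128)
        if not np.all(outer.contains(bp[:, 0], bp[:, 1])):
            raise ValueError(f"bone ellipse {bn} is not strictly inside the arm")
    for i in range(len(live)):
        for j in range(i + 1, len(live)):
            bp = live[i].boundary_points(128)
            if np.any(live[j].contains(bp[:, 0], bp[:, 1])) or live[j].contains(
                np.array(live[i].cx), np.array(live[i].cy)
            ):
                raise ValueError("bone ellipses overlap")


def build_phantom(
    outer: Ellipse = Ellipse(0.0, 0.0, 40.0, 30.0),
    bones: Sequence[Ellipse] = (
        Ellipse(-14.0, 4.0, 7.0, 5.0, angle=0.35),
        Ellipse(13.0, 2.0, 6.0, 4.5, angle=-0.35),
    ),
    sigma_muscle: float = SIGMA_MUSCLE,
    sigma_bone: float = SIGMA_BONE,
    mesh_h: float = MESH_H_FINE,
    n_electrodes: int = 8,
    electrode_width: float | None = None,
) -> ArmPhantom:
    """Mesh the arm phantom and assign element conductivities.

    Elements whose centroid lies inside a bone ellipse get ``sigma_bone``,
    all others ``sigma_muscle``.  Bones with zero semi-axes are treated as
    absent (homogeneous phantom).  The electrode arc width defaults to a
    quarter of the inter-electrode spacing.
    """
    if sigma_muscle <= 0 or sigma_bone <= 0:
        raise ValueError("conductivities must be positive")
    bones = tuple(bones)
    _check_geometry(outer, bones)
    mesh = ellipse_mesh(outer.ra, outer.rb, mesh_h)
    ring = build_ring(n_electrodes)
    if electrode_width is None:
        electrode_width = ring.spacing / 4.0
    cx, cy = mesh.centroids[:, 0], mesh.centroids[:, 1]
    bone_mask = np.zeros(mesh.n_elements, dtype=bool)
    for bn in bones:
        bone_mask |= bn.contains(cx, cy)
    sigma = np.where(bone_mask, sigma_bone, sigma_muscle)
    return ArmPhantom(
        outer=outer,
        bones=bones,
        sigma_muscle=sigma_muscle,
        sigma_bone=sigma_bone,
        mesh=mesh,
        ring=ring,
        electrode_width=electrode_width,
        element_sigma=sigma,
        bone_mask=bone_mask,
    )


def default_phantom(mesh_h: float = MESH_H_FINE) -> ArmPhantom:
    """The reference arm phantom at the requested mesh resolution."""
    return build_phantom(mesh_h=mesh_h)


def phantom_from_config(config: Mapping) -> ArmPhantom:
    """Build a phantom from a plain dict (e.g. parsed JSON/YAML).

    Recognised keys: outer {cx, cy, ra, rb, angle}, bones [..same..],
    sigma_muscle, sigma_bone, mesh_h, n_electrodes, electrode_width.
    """
    kwargs: dict = {}
    if "outer" in config:
        kwargs["outer"] = Ellipse(**config["outer"])
    if "bones" in config:
        kwargs["bones"] = tuple(Ellipse(**b) for b in config["bones"])
    for key in ("sigma_muscle", "sigma_bone", "mesh_h", "n_electrodes", "electrode_width"):
        if key in config:
            kwargs[key] = config[key]
    return build_phantom(**kwargs)


@dataclass(frozen=True)
class DriveCurrent:
    """Excitation current: RMS amplitude (A) and nominal frequency (Hz).

    The frequency is metadata only; the solver is quasi-static."""

    amplitude: float = 3.0e-4
    frequency: float = 30.0e3

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("current amplitude must be positive")


@dataclass
class ForwardSolution:
    """Node potentials plus differential boundary-voltage readout."""

    phantom: ArmPhantom
    node_potentials: np.ndarray
    excitation: tuple[int, int]
    ring_rotation: float = 0.0

    def electrode_potential(self, k: int) -> float:
        idx, w = self.phantom.electrode_node_weights(k, self.ring_rotation)
        return float(w @ self.node_potentials[idx])

    def boundary_voltage(self, pair: tuple[int, int]) -> float:
        """Signed differential potential between two electrodes."""
        return self.electrode_potential(pair[0]) - self.electrode_potential(pair[1])


def _grounded_solve(a: sp.csr_matrix, f: np.ndarray, ground: int) -> np.ndarray:
    a = a.tolil()
    a[ground, :] = 0.0
    a[:, ground] = 0.0
    a[ground, ground] = 1.0
    f = f.copy()
    f[ground] = 0.0
    return spla.spsolve(a.tocsr(), f)


def _ground_node(phantom: ArmPhantom) -> int:
    # reference at the boundary node opposite electrode A; differential
    # measurements cancel the reference so the exact choice is immaterial
    theta = phantom.mesh.boundary_theta
    far = np.argmin(np.abs(np.mod(theta - np.pi + np.pi, 2 * np.pi) - np.pi))
    return int(phantom.mesh.boundary_nodes[far])


def solve_forward(
    phantom: ArmPhantom,
    excitation: tuple[int, int],
    current: DriveCurrent = DriveCurrent(),
    sigma: np.ndarray | None = None,
    ring_rotation: float = 0.0,
) -> ForwardSolution:
    """Solve div(sigma grad u) = 0 with +I/-I injected at an electrode pair.

    ``sigma`` overrides the phantom's baseline element conductivities
    (used for time-varying gestures).  Current conservation holds exactly:
    the nodal load sums to zero before grounding.
    """
    if excitation[0] == excitation[1]:
        raise ValueError("excitation electrodes must be distinct")
    sig = phantom.element_sigma if sigma is None else np.asarray(sigma, dtype=float)
    if sig.shape != (phantom.mesh.n_elements,):
        raise ValueError("sigma must have one value per mesh element")
    if np.any(sig <= 0):
        raise ValueError("element conductivities must stay positive")
    a = phantom.mesh.assemble(sig)
    f = np.zeros(phantom.mesh.n_nodes)
    ia, wa = phantom.electrode_node_weights(excitation[0], ring_rotation)
    ib, wb = phantom.electrode_node_weights(excitation[1], ring_rotation)
    np.add.at(f, ia, current.amplitude * wa)
    np.add.at(f, ib, -current.amplitude * wb)
    u = _grounded_solve(a, f, _ground_node(phantom))
    if not np.all(np.isfinite(u)):
        raise RuntimeError("forward solve produced non-finite potentials")
    return ForwardSolution(
        phantom=phantom, node_potentials=u, excitation=excitation,
        ring_rotation=ring_rotation,
    )


def measure(
    schedule: MeasurementSchedule,
    phantom_at: "Callable[[int], np.ndarray] | ArmPhantom",
    current: DriveCurrent = DriveCurrent(),
    phantom: ArmPhantom | None = None,
    ring_rotation: "float | Callable[[int], float]" = 0.0,
) -> np.ndarray:
    """Run a measurement schedule over an evolving phantom.

    ``phantom_at`` is either a static :class:`ArmPhantom` or a callable
    ``time_index -> element sigma array`` on the mesh of ``phantom``.
    ``ring_rotation`` may likewise be a callable of the time index (a
    ring that shifts relative to the tissue during the gesture).  Returns
    one voltage amplitude (absolute differential potential, emulating RMS
    magnitude detection) per schedule step, in step order.  Consecutive
    steps sharing the same excitation and phantom state reuse a solve.
    """
    if isinstance(phantom_at, ArmPhantom):
        phantom = phantom_at
        sigma_at = lambda t: phantom.element_sigma  # noqa: E731
    else:
        if phantom is None:
            raise ValueError("phantom required when phantom_at is a callable")
        sigma_at = phantom_at
    rot_at = ring_rotation if callable(ring_rotation) else (lambda t: ring_rotation)
    out = np.empty(len(schedule))
    last_key: tuple | None = None
    sol: ForwardSolution | None = None
    last_sigma: np.ndarray | None = None
    for exc, meas, t in schedule:
        try:
            sig = np.asarray(sigma_at(t), dtype=float)
        except Exception as err:
            raise ValueError(f"phantom state unavailable at time index {t}") from err
        rot = float(rot_at(t))
        if (
            sol is None
            or (exc, rot) != last_key
            or last_sigma is None
            or not np.array_equal(sig, last_sigma)
        ):
            sol = solve_forward(
                phantom, exc, current, sigma=sig, ring_rotation=rot
            )
            last_key, last_sigma = (exc, rot), sig
        out[t] = abs(sol.boundary_voltage(meas))
    return out


def excitation_switch_steps(schedule: MeasurementSchedule) -> np.ndarray:
    """Boolean mask of steps at which the excitation pair differs from the
    previous step's (the first step counts: the source has just switched
    on).  At these steps the constant-current source and the RMS detector
    are still settling while the load impedance changes, so real readings
    carry a transient error; cyclic excitation has one such step per
    block, fixed excitation only the first step."""
    mask = np.zeros(len(schedule), dtype=bool)
    prev: tuple | None = None
    for exc, _, t in schedule:
        mask[t] = exc != prev
        prev = exc
    return mask


def current_density(phantom: ArmPhantom, solution: ForwardSolution) -> np.ndarray:
    """Per-element current density magnitude |sigma grad u|."""
    u = solution.node_potentials[phantom.mesh.tris]  # (M, 3)
    g = np.einsum("mdi,mi->md", phantom.mesh._grads, u)  # (M, 2)
    return phantom.element_sigma * np.linalg.norm(g, axis=1)


def dissipated_power(
    phantom: ArmPhantom, solution: ForwardSolution, sigma: np.ndarray | None = None
) -> float:
    """Total ohmic power sum_e sigma_e |grad u|^2 A_e (per unit depth)."""
    sig = phantom.element_sigma if sigma is None else sigma
    u = solution.node_potentials[phantom.mesh.tris]
    g = np.einsum("mdi,mi->md", phantom.mesh._grads, u)
    return float(np.sum(sig * np.sum(g**2, axis=1) * phantom.mesh.areas))


def solution_to_frame(solution: ForwardSolution) -> pd.DataFrame:
    """Node table (x, y, potential) for external visualisation."""
    nodes = solution.phantom.mesh.nodes
    return pd.DataFrame(
        {"x": nodes[:, 0], "y": nodes[:, 1], "potential": solution.node_potentials}
    )
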
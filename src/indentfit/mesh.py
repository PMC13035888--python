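"""Structured axisymmetric meshes for the flat-punch indentation problem.

The sample is a cylinder of radius ``R_s`` and height ``H`` indented on its
top face by a rigid flat-ended cylindrical punch of radius ``a``.  Because
geometry, loading and frictionless contact are all axisymmetric, the domain
is the rectangle ``[0, R_s] x [0, H]`` in (r, z), discretised into 4-node
quadrilaterals with an element edge placed exactly at ``r = a`` so the punch
edge is captured by the mesh.  Optional geometric grading refines toward the
punch edge ``(r = a, z = H)`` where the contact-pressure singularity lives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AxisymMesh", "build_mesh", "graded_coords"]


def graded_coords(lo: float, hi: float, n: int, grading: float, refine_at: str) -> np.ndarray:
    """n+1 coordinates over [lo, hi] with geometrically graded element sizes.

    ``grading`` is the ratio of the largest to the smallest element size;
    ``refine_at`` ("lo" or "hi") selects the end that gets the small elements.
    """
    if n < 1:
        raise ValueError("need at least one element")
    if grading < 1.0:
        raise ValueError("grading factor must be >= 1")
    if n == 1 or grading == 1.0:
        return np.linspace(lo, hi, n + 1)
    q = grading ** (-1.0 / (n - 1))
    sizes = q ** np.arange(n)  # decreasing sizes toward the far end
    if refine_at == "lo":
        sizes = sizes[::-1]
    elif refine_at != "hi":
        raise ValueError("refine_at must be 'lo' or 'hi'")
    x = np.concatenate([[0.0], np.cumsum(sizes)])
    return lo + (hi - lo) * x / x[-1]


@dataclass(frozen=True)
class AxisymMesh:
    """Structured quadrilateral mesh of the axisymmetric sample section."""

    nodes: np.ndarray  # (n_nodes, 2) -- (r, z), mm
    elems: np.ndarray  # (n_elems, 4) node ids, counterclockwise
    bottom: np.ndarray  # node ids with z = 0
    axis: np.ndarray  # node ids with r = 0
    top_contact: np.ndarray  # node ids with z = H, r <= a
    top_free: np.ndarray  # node ids with z = H, r > a
    R_s: float
    H: float
    a: float

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    @property
    def top(self) -> np.ndarray:
        return np.concatenate([self.top_contact, self.top_free])


def build_mesh(
    R_s: float = 10.0,
    H: float = 10.0,
    a: float = 2.5,
    n_r: int = 40,
    n_z: int = 40,
    grading: float = 3.0,
) -> AxisymMesh:
    """Build a graded structured mesh with a mesh line at the punch edge.

    ``n_r`` radial elements are split between ``[0, a]`` and ``[a, R_s]`` in
    proportion to their widths (at least one element each); ``n_z`` elements
    span the height.  Grading refines toward ``r = a`` from both sides and
    toward the indented face ``z = H``.
    """
    if not (0.0 < a < R_s) or H <= 0.0:
        raise ValueError("invalid geometry: need 0 < a < R_s and H > 0")
    if n_r < 2 or n_z < 2:
        raise ValueError("need n_r >= 2 and n_z >= 2")
    n_in = min(max(1, round(n_r * a / R_s)), n_r - 1)
    n_out = n_r - n_in
    r = np.concatenate(
        [
            graded_coords(0.0, a, n_in, grading, refine_at="hi"),
            graded_coords(a, R_s, n_out, grading, refine_at="lo")[1:],
        ]
    )
    z = graded_coords(0.0, H, n_z, grading, refine_at="hi")

    rr, zz = np.meshgrid(r, z)  # rows: z levels
    nodes = np.column_stack([rr.ravel(), zz.ravel()])
    nrp = n_r + 1

    ir, iz = np.meshgrid(np.arange(n_r), np.arange(n_z), indexing="ij")
    n0 = iz * nrp + ir
    elems = np.column_stack(
        [n0.ravel(), (n0 + 1).ravel(), (n0 + 1 + nrp).ravel(), (n0 + nrp).ravel()]
    )

    tol = 1e-9 * max(R_s, H)
    ids = np.arange(nodes.shape[0])
    bottom = ids[np.abs(nodes[:, 1]) < tol]
    axis_ = ids[np.abs(nodes[:, 0]) < tol]
    top = ids[np.abs(nodes[:, 1] - H) < tol]
    top_contact = top[nodes[top, 0] <= a + tol]
    top_free = top[nodes[top, 0] > a + tol]
    return AxisymMesh(nodes, elems, bottom, axis_, top_contact, top_free, R_s, H, a)
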
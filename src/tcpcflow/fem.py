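"""Shared piecewise-linear (P1) finite-element machinery.

Dimension-agnostic helpers used by both the incompressible-flow solver and
the scalar (dye) transport solver: shape-function gradients, element metric
tensors for stabilization parameters, quadrature rules, and COO assembly of
element matrices.
"""
from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["P1Basis", "assemble_csr"]


# degree-2 quadrature on the reference simplex (barycentric weights)
_TRI_QP = np.array([[2 / 3, 1 / 6, 1 / 6],
                    [1 / 6, 2 / 3, 1 / 6],
                    [1 / 6, 1 / 6, 2 / 3]])
_TRI_QW = np.array([1 / 3, 1 / 3, 1 / 3])

_TET_A, _TET_B = 0.5854101966249685, 0.1381966011250105
_TET_QP = np.array([[_TET_A, _TET_B, _TET_B, _TET_B],
                    [_TET_B, _TET_A, _TET_B, _TET_B],
                    [_TET_B, _TET_B, _TET_A, _TET_B],
                    [_TET_B, _TET_B, _TET_B, _TET_A]])
_TET_QW = np.array([0.25, 0.25, 0.25, 0.25])


class P1Basis:
    """Precomputed per-element data for P1 assembly on a simplicial mesh.

    Attributes
    ----------
    grads : (n_cells, dim+1, dim) shape-function gradients (constant per cell)
    vols : (n_cells,) cell measures
    metric : (n_cells, dim, dim) covariant element metric G = J^-T J^-1 of the
        reference-to-physical map, the tensor entering the stabilization
        parameter tau = (4/dt^2 + v.G.v + C_I nu^2 G:G)^(-1/2).
    qp_shape : (n_qp, dim+1) shape-function values at quadrature points
    qw : (n_qp,) quadrature weights (summing to 1; multiply by vols)
    """

    def __init__(self, nodes: np.ndarray, cells: np.ndarray):
        self.nodes = nodes
        self.cells = cells
        self.dim = d = nodes.shape[1]
        p = nodes[cells]
        e = p[:, 1:, :] - p[:, :1, :]            # (m, d, d) edge matrix J^T
        det = np.linalg.det(e)
        if np.any(det <= 0):
            raise ValueError("mesh contains inverted or degenerate cells")
        self.vols = det / (2.0 if d == 2 else 6.0)
        einv = np.linalg.inv(e)                   # (m, d, d) = J^-T
        # gradient of barycentric coords: lambda_k (k=1..d) rows of J^-1
        gl = np.swapaxes(einv, 1, 2)              # J^-1, rows d(xi_k)/dx
        grads = np.empty((cells.shape[0], d + 1, d))
        grads[:, 1:, :] = gl
        grads[:, 0, :] = -gl.sum(axis=1)
        self.grads = grads
        # metric G_ij = sum_k dxi_k/dx_i dxi_k/dx_j
        self.metric = np.einsum("mki,mkj->mij", gl, gl)
        self.qp_shape = _TRI_QP if d == 2 else _TET_QP
        self.qw = _TRI_QW if d == 2 else _TET_QW

    def interpolate(self, nodal: np.ndarray) -> np.ndarray:
        """Values of a nodal field at quadrature points, (m, n_qp, ...)."""
        vals = nodal[self.cells]                  # (m, d+1, ...)
        return np.einsum("qa,ma...->mq...", self.qp_shape, vals)

    def gradient(self, nodal: np.ndarray) -> np.ndarray:
        """Constant per-cell gradient of a nodal field.

        For scalar input (n_nodes,) returns (m, dim); for vector input
        (n_nodes, k) returns (m, k, dim) with [m, i, j] = d f_i / d x_j.
        """
        vals = nodal[self.cells]
        if vals.ndim == 2:
            return np.einsum("ma,mad->md", vals, self.grads)
        return np.einsum("mai,mad->mid", vals, self.grads)

    def lumped_mass(self) -> np.ndarray:
        """Row-sum lumped mass vector (n_nodes,)."""
        m = np.zeros(self.nodes.shape[0])
        np.add.at(m, self.cells.ravel(),
                  np.repeat(self.vols / (self.dim + 1), self.dim + 1))
        return m


def assemble_csr(cells: np.ndarray, elem_mats: np.ndarray, n_dof: int,
                 dof_map=None) -> sp.csr_matrix:
    """Assemble per-element dense blocks into a global CSR matrix.

    ``elem_mats`` is (m, a, b) with a == b == number of local dofs;
    ``dof_map`` maps (cells) -> local-to-global dof arrays of shape (m, a).
    When None, cells themselves are the dof indices (scalar problems).
    """
    gdof = cells if dof_map is None else dof_map
    m, a, b = elem_mats.shape
    rows = np.repeat(gdof, b, axis=1).ravel()
    cols = np.tile(gdof, (1, a)).ravel()
    A = sp.coo_matrix((elem_mats.ravel(), (rows, cols)), shape=(n_dof, n_dof))
    return A.tocsr()
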
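"""Penalized spline bases and constraint projectors.

One-dimensional thin plate regression splines (TPRS): the full thin-plate
spline on k knots, f(x) = sum_i delta_i |x - x_i|^3 + a + b x with side
conditions T' delta = 0 (T = [1, x] at the knots), has wiggliness penalty
delta' E delta where E_ij = |x_i - x_j|^3. The low-rank version keeps the
leading ``basis_dim - 2`` eigenvectors of E (restricted to the side-condition
space) and appends the penalty-free affine null space, so straight lines are
never penalized.

The constraint machinery removes a chosen span — {constant} or
{constant, linear} — from a basis by reparameterizing onto the orthogonal
complement (uniform inner product over the basis's own evaluation points).
Removing the linear span from the intensity-weight smoother is what makes
the functional histogram term identifiable jointly with the volume smooth:
mean intensity is a linear functional of the histogram, so any affine
component of the weight function duplicates the volume term.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SplineBasis",
    "ConstraintProjector",
    "build_tprs",
    "remove_span",
    "sum_to_zero",
    "functional_design_row",
]


def _tps_kernel(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """|x - x'|^3 radial kernel matrix (conditionally PSD of order 2)."""
    return np.abs(x[:, None] - knots[None, :]) ** 3


@dataclass
class SplineBasis:
    """A low-rank penalized spline basis.

    ``evaluate(x)`` returns the n × q design matrix; ``penalty`` is the
    q × q PSD wiggliness penalty. ``points`` are the evaluation points the
    basis was built from (knots for an unconstrained TPRS); constraints are
    defined relative to these points. ``coef_map`` carries any
    reparameterization applied by constraints so that penalties stay
    congruent.
    """

    knots: np.ndarray
    basis_dim: int
    radial_map: np.ndarray  # k × r: maps kernel columns into reduced basis
    penalty: np.ndarray  # q × q
    points: np.ndarray  # evaluation points defining inner products
    nullspace_dim: int
    coef_map: np.ndarray | None = None  # q_raw × q after constraint absorption
    projector: "ConstraintProjector | None" = None
    x_scale: tuple[float, float] = (0.0, 1.0)

    @property
    def q(self) -> int:
        return self.basis_dim if self.coef_map is None else self.coef_map.shape[1]

    def _raw_design(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo, scale = self.x_scale
        xs = (x - lo) / scale
        ks = (self.knots - lo) / scale
        radial = _tps_kernel(xs, ks) @ self.radial_map
        return np.column_stack([radial, np.ones_like(xs), xs])

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        if not np.all(np.isfinite(x)):
            raise ValueError("evaluation points must be finite")
        B = self._raw_design(np.asarray(x, dtype=float))
        return B if self.coef_map is None else B @ self.coef_map


@dataclass
class ConstraintProjector:
    """Orthogonal projector removing a function span from a basis.

    ``P`` acts on function values at the basis's evaluation points
    (uniform inner product); ``span`` holds the removed functions'
    values at those points, column-wise.
    """

    span: np.ndarray  # m × s
    P: np.ndarray  # m × m, idempotent

    def __call__(self, values: np.ndarray) -> np.ndarray:
        return self.P @ values


def build_tprs(points: np.ndarray, basis_dim: int, max_knots: int = 200) -> SplineBasis:
    """Build a 1-d thin plate regression spline basis.

    ``points`` are the values of the index variable the smooth is a
    function of (data values or histogram-bin representatives). Knots are
    the distinct points, thinned to quantiles when there are more than
    ``max_knots``. The eigen-reduction keeps the ``basis_dim - 2`` leading
    penalized directions; the affine null space (constant + linear, in the
    penalty's kernel) is appended unpenalized.
    """
    x = np.unique(np.asarray(points, dtype=float))
    if basis_dim < 3:
        raise ValueError("basis_dim must be at least 3")
    if x.size < basis_dim:
        raise ValueError(
            f"basis_dim={basis_dim} exceeds the {x.size} distinct points available"
        )
    if x.size > max_knots:
        qs = np.linspace(0, 1, max_knots)
        x = np.unique(np.quantile(x, qs))
    lo, hi = float(x[0]), float(x[-1])
    scale = hi - lo if hi > lo else 1.0
    xs = (x - lo) / scale

    k = xs.size
    E = _tps_kernel(xs, xs)
    T = np.column_stack([np.ones(k), xs])
    # restrict delta to the side-condition space T' delta = 0
    Q, _ = np.linalg.qr(T, mode="complete")
    Z = Q[:, 2:]  # k × (k-2)
    Ez = Z.T @ E @ Z
    Ez = 0.5 * (Ez + Ez.T)
    evals, evecs = np.linalg.eigh(Ez)  # conditionally PD => positive here
    order = np.argsort(evals)[::-1]
    r = basis_dim - 2
    U = evecs[:, order[:r]]
    D = evals[order[:r]]
    radial_map = Z @ U  # k × r; penalty in these coords is diag(D)
    S = np.zeros((basis_dim, basis_dim))
    S[:r, :r] = np.diag(D)
    basis = SplineBasis(
        knots=x,
        basis_dim=basis_dim,
        radial_map=radial_map,
        penalty=S,
        points=np.asarray(points, dtype=float),
        nullspace_dim=2,
        x_scale=(lo, scale),
    )
    return basis


def _span_matrix(points: np.ndarray, span: tuple[str, ...]) -> np.ndarray:
    cols = []
    for name in span:
        if name == "constant":
            cols.append(np.ones_like(points))
        elif name == "linear":
            cols.append(points.astype(float))
        else:
            raise ValueError(f"unknown span function {name!r}")
    return np.column_stack(cols)


def remove_span(basis: SplineBasis, span: tuple[str, ...] = ("constant", "linear")) -> SplineBasis:
    """Constrain a basis so fitted functions are orthogonal to ``span``.

    Orthogonality is with respect to the uniform inner product over the
    basis's own evaluation points. The coefficient space is reparameterized
    onto the null space of the constraints, so the returned basis has
    ``len(span)`` fewer columns and a congruently transformed penalty.
    Applying the operation twice is a no-op.
    """
    pts = np.asarray(basis.points, dtype=float)
    A = _span_matrix(pts, span)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("span is rank-deficient at the evaluation points")
    B = basis.evaluate(pts)  # m × q
    C = A.T @ B  # s × q
    if np.allclose(C, 0, atol=1e-9 * max(1.0, np.abs(B).max()) * np.abs(A).max()):
        return basis  # already orthogonal to the span: idempotence
    # null space of C
    _, sv, Vt = np.linalg.svd(C, full_matrices=True)
    rank = int(np.sum(sv > sv[0] * 1e-12)) if sv.size else 0
    Zc = Vt[rank:].T  # q × (q - s)
    S_new = Zc.T @ basis.penalty @ Zc
    S_new = 0.5 * (S_new + S_new.T)
    coef_map = Zc if basis.coef_map is None else basis.coef_map @ Zc
    # the explicit m x m projector is only materialized for small point sets
    # (e.g. histogram-bin representatives); constraints over large data
    # vectors are absorbed through the reparameterization alone
    P = None
    if A.shape[0] <= 2000:
        AtA = A.T @ A
        P = np.eye(A.shape[0]) - A @ np.linalg.solve(AtA, A.T)
    null_lost = sum(1 for name in span if name in ("constant", "linear"))
    return replace(
        basis,
        penalty=S_new,
        coef_map=coef_map,
        nullspace_dim=max(basis.nullspace_dim - null_lost, 0),
        projector=ConstraintProjector(span=A, P=P) if P is not None else None,
    )


def sum_to_zero(basis: SplineBasis, at_points: np.ndarray) -> SplineBasis:
    """Standard identifiability constraint: fitted values sum to zero over
    ``at_points`` (the data). The linear component is retained."""
    b = replace(basis, points=np.asarray(at_points, dtype=float))
    constrained = remove_span(b, ("constant",))
    return constrained


def functional_design_row(rel_freq: np.ndarray, basis: SplineBasis, z: np.ndarray) -> np.ndarray:
    """Design row of the functional histogram term.

    Returns r with r @ beta = sum_k w(z_k) p_k where w = basis functions
    combined by beta. ``z`` must be the bin representatives the basis was
    built on.
    """
    z = np.asarray(z, dtype=float)
    if basis.points.shape != z.shape or not np.allclose(basis.points, z):
        raise ValueError("histogram bins do not match the basis evaluation points")
    p = np.asarray(rel_freq, dtype=float)
    if p.shape != z.shape:
        raise ValueError("rel_freq length does not match bins")
    return p @ basis.evaluate(z)


# ---------------------------------------------------------------------------
# serialization (JSON header + npz payload written next to it)


def save_basis(basis: SplineBasis, path_json, path_npz) -> None:
    header = {
        "basis_dim": basis.basis_dim,
        "nullspace_dim": basis.nullspace_dim,
        "x_scale": list(basis.x_scale),
        "constrained": basis.coef_map is not None,
    }
    with open(path_json, "w") as fh:
        json.dump(header, fh, indent=1)
    arrays = {
        "knots": basis.knots,
        "radial_map": basis.radial_map,
        "penalty": basis.penalty,
        "points": basis.points,
    }
    if basis.coef_map is not None:
        arrays["coef_map"] = basis.coef_map
    if basis.projector is not None:
        arrays["proj_span"] = basis.projector.span
        arrays["proj_P"] = basis.projector.P
    np.savez(path_npz, **arrays)


def load_basis(path_json, path_npz) -> SplineBasis:
    with open(path_json) as fh:
        header = json.load(fh)
    data = np.load(path_npz)
    proj = None
    if "proj_P" in data:
        proj = ConstraintProjector(span=data["proj_span"], P=data["proj_P"])
    return SplineBasis(
        knots=data["knots"],
        basis_dim=int(header["basis_dim"]),
        radial_map=data["radial_map"],
        penalty=data["penalty"],
        points=data["points"],
        nullspace_dim=int(header["nullspace_dim"]),
        coef_map=data["coef_map"] if "coef_map" in data else None,
        projector=proj,
        x_scale=tuple(header["x_scale"]),
    )
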
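"""Vectorized closest-point-on-triangle queries.

Implements the standard region classification (Ericson, Real-Time Collision
Detection ch. 5.1.5) over paired arrays: query point i is tested against
triangle i. All inputs are (n, 3) float64 arrays.
"""

from __future__ import annotations

import numpy as np


def closest_point_on_triangles(
    p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> np.ndarray:
    """Closest point to ``p[i]`` on triangle ``(a[i], b[i], c[i])``.

    Degenerate (zero-area) triangles fall back to the closest vertex/edge
    result of the same formulas; no special casing is required because the
    barycentric clamps below remain finite for collinear inputs.
    """
    p = np.asarray(p, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)

    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex region A
    m = (d1 <= 0.0) & (d2 <= 0.0)
    out[m] = a[m]
    done |= m

    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)

    # vertex region B
    m = ~done & (d3 >= 0.0) & (d4 <= d3)
    out[m] = b[m]
    done |= m

    # edge region AB
    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0.0) & (d1 >= 0.0) & (d3 <= 0.0)
    denom = d1 - d3
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0.0, d1 / denom, 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m

    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    # vertex region C
    m = ~done & (d6 >= 0.0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge region AC
    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0.0) & (d2 >= 0.0) & (d6 <= 0.0)
    denom = d2 - d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom != 0.0, d2 / denom, 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m

    # edge region BC
    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0.0) & ((d4 - d3) >= 0.0) & ((d5 - d6) >= 0.0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom != 0.0, (d4 - d3) / denom, 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0.0, vb / denom, 1.0 / 3.0)
        w = np.where(denom != 0.0, vc / denom, 1.0 / 3.0)
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


def triangle_normals(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Unit normals of triangles; zero vector for degenerate triangles."""
    n = np.cross(b - a, c - a)
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = np.where(norm > 0.0, n / norm, 0.0)
    return unit


def triangle_areas(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=-1)
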
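"""Dipole forward solutions in layered spherical volume conductors.

The default engine is the classical multilayer-sphere series: the potential
of a current dipole inside concentric conductor shells expanded in Legendre
harmonics, with per-degree radial transfer coefficients fixed by potential
and normal-current continuity at every interface and zero normal current at
the scalp.  The series handles any conductivity contrast (including the
~1/79 skull contrast) and converges geometrically in ``(b / r_inner)^n``
for a dipole at distance ``b`` from the center.

The boundary-element solver on triangulated surfaces lives in
:mod:`earfield.bem`; both engines plug into :func:`compute_leadfield`.

Units: positions in meters, dipole moments in A*m, potentials in volts.
Lead-field columns are stored for a unit moment of 1 A*m; the analysis
scales them by the configured source amplitude (1 nA*m by default, so that
reported channel amplitudes are naturally expressed in nV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .head import CorticalSurface, ElectrodeMontage, ShellModel, VolumeGrid

__all__ = [
    "Dipole",
    "LeadField",
    "potential_infinite",
    "potential_sphere",
    "apply_average_reference",
    "compute_leadfield",
]

N_MAX_DEFAULT = 200


@dataclass(frozen=True)
class Dipole:
    """Current dipole: position (m) and moment (A*m)."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(3)
        )
        object.__setattr__(
            self, "moment", np.asarray(self.moment, dtype=float).reshape(3)
        )
        if not np.all(np.isfinite(self.position)) or not np.all(
            np.isfinite(self.moment)
        ):
            raise ValueError("dipole position and moment must be finite")


def potential_infinite(
    dipole: Dipole, sigma: float, points: np.ndarray
) -> np.ndarray:
    """Infinite homogeneous medium: ``V = m . (r - r0) / (4 pi sigma |r - r0|^3)``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = pts - dipole.position
    r3 = np.linalg.norm(d, axis=1) ** 3
    if np.any(r3 == 0):
        raise ValueError("potential evaluated at the source point")
    return (d @ dipole.moment) / (4.0 * np.pi * sigma * r3)


# ---------------------------------------------------------------------------
# multilayer sphere series


@lru_cache(maxsize=32)
def _transfer_coefficients(
    radii: tuple[float, ...], sigmas: tuple[float, ...], n_max: int
) -> np.ndarray:
    """Per-degree transfer factor ``t[n]`` mapping the source expansion
    (normalized to its value at the innermost interface) to the scalp
    harmonic amplitude.

    For each degree n the potential in shell k is ``A_k (r / r_k)^n +
    B_k (r_k / r)^(n+1)`` (basis normalized at the shell's outer radius
    ``r_k`` to keep the linear system well scaled); the innermost shell
    additionally carries the dipole's singular ``1 / r^(n+1)`` term with
    unit value at ``r_1``.  Continuity of V and of sigma dV/dr at every
    interface plus zero normal current at the scalp closes the system.
    For a homogeneous sphere this reduces to ``t[n] = (2n + 1) / n``.
    """
    N = len(radii)
    out = np.empty(n_max + 1)
    out[0] = 0.0
    for n in range(1, n_max + 1):
        if N == 1:
            out[n] = (2.0 * n + 1.0) / n
            continue
        # unknowns: A_1, (A_2, B_2), ..., (A_N, B_N)  -> size 2N - 1
        m = 2 * N - 1
        M = np.zeros((m, m))
        rhs = np.zeros(m)

        def col_A(k):  # index of A_k
            return 0 if k == 1 else 2 * (k - 1) - 1

        def col_B(k):  # index of B_k (k >= 2)
            return 2 * (k - 1)

        row = 0
        for k in range(1, N):
            rk, rk1 = radii[k - 1], radii[k]
            # value and sigma-weighted derivative of each basis at r = r_k
            # shell k side (basis normalized at its own outer radius r_k)
            # shell k+1 side (basis normalized at r_{k+1})
            a_in_v, a_in_d = 1.0, n / rk
            b_in_v, b_in_d = 1.0, -(n + 1.0) / rk
            ra = (rk / rk1) ** n
            rb = (rk1 / rk) ** (n + 1)
            a_out_v, a_out_d = ra, n / rk * ra
            b_out_v, b_out_d = rb, -(n + 1.0) / rk * rb
            # source term (innermost shell only): unit value at r_1
            s_v = (radii[0] / rk) ** (n + 1)
            s_d = -(n + 1.0) / rk * s_v
            # potential continuity
            M[row, col_A(k)] += a_in_v
            if k >= 2:
                M[row, col_B(k)] += b_in_v
            M[row, col_A(k + 1)] -= a_out_v
            M[row, col_B(k + 1)] -= b_out_v
            if k == 1:
                rhs[row] = -s_v
            row += 1
            # normal-current continuity
            si, so = sigmas[k - 1], sigmas[k]
            M[row, col_A(k)] += si * a_in_d
            if k >= 2:
                M[row, col_B(k)] += si * b_in_d
            M[row, col_A(k + 1)] -= so * a_out_d
            M[row, col_B(k + 1)] -= so * b_out_d
            if k == 1:
                rhs[row] = -si * s_d
            row += 1
        # outer boundary: zero normal current at r_N
        R = radii[-1]
        M[row, col_A(N)] = n / R
        M[row, col_B(N)] = -(n + 1.0) / R
        if N == 1:  # pragma: no cover - handled analytically above
            rhs[row] = (n + 1.0) / R
        sol = np.linalg.solve(M, rhs)
        out[n] = sol[col_A(N)] + sol[col_B(N)]  # scalp value, r_N basis = 1
    return out


def _dipole_frame(dipole: Dipole, center: np.ndarray):
    """Rotate into the frame with z along the dipole offset and x along the
    tangential moment component; returns (b, m_r, m_t, zhat, xhat)."""
    b_vec = dipole.position - center
    b = float(np.linalg.norm(b_vec))
    if b > 1e-12:
        zhat = b_vec / b
    else:
        b = 0.0
        mn = np.linalg.norm(dipole.moment)
        zhat = (
            dipole.moment / mn if mn > 0 else np.array([0.0, 0.0, 1.0])
        )
    m_r = float(dipole.moment @ zhat)
    t_vec = dipole.moment - m_r * zhat
    m_t = float(np.linalg.norm(t_vec))
    if m_t > 1e-18 * max(1.0, np.linalg.norm(dipole.moment)):
        xhat = t_vec / m_t
    else:
        m_t = 0.0
        tmp = np.array([1.0, 0.0, 0.0])
        if abs(zhat @ tmp) > 0.9:
            tmp = np.array([0.0, 1.0, 0.0])
        xhat = tmp - (tmp @ zhat) * zhat
        xhat /= np.linalg.norm(xhat)
    return b, m_r, m_t, zhat, xhat


def potential_sphere(
    dipole: Dipole,
    shell: ShellModel,
    surface_points: np.ndarray,
    tol: float = 1e-6,
    n_max: int = N_MAX_DEFAULT,
) -> np.ndarray:
    """Scalp potential of a dipole in a concentric multilayer sphere.

    Truncated Legendre / associated-Legendre series; terms are accumulated
    until the last term's relative contribution falls below ``tol`` at
    every point (hard cap ``n_max``).  For a centered dipole only the n=1
    term survives and the homogeneous-sphere closed form
    ``3 |m| cos(theta) / (4 pi sigma R^2)`` is recovered exactly.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    pts = np.atleast_2d(np.asarray(surface_points, dtype=float))
    b, m_r, m_t, zhat, xhat = _dipole_frame(dipole, shell.center)
    r1 = shell.inner_radius
    if b >= r1:
        raise ValueError(
            f"dipole at radius {b:.4f} m is not inside the innermost shell "
            f"({r1:.4f} m)"
        )
    yhat = np.cross(zhat, xhat)
    d = pts - shell.center
    rr = np.linalg.norm(d, axis=1)
    u = d / rr[:, None]
    ct = np.clip(u @ zhat, -1.0, 1.0)
    st = np.sqrt(1.0 - ct**2)
    cphi = np.where(st > 1e-15, (u @ xhat) / np.where(st > 1e-15, st, 1.0), 0.0)

    t = _transfer_coefficients(shell.radii, shell.conductivities, n_max)
    sigma1 = shell.conductivities[0]
    pref = 1.0 / (4.0 * np.pi * sigma1 * r1**2)
    x = b / r1  # geometric decay ratio of successive terms

    V = np.zeros(len(pts))
    # Legendre recurrences, P^1 in the positive (no Condon-Shortley) convention
    P_nm1 = np.ones_like(ct)  # P_0
    P_n = ct.copy()  # P_1
    P1_nm1 = np.zeros_like(ct)  # P^1_0
    P1_n = st.copy()  # P^1_1
    xpow = 1.0  # x^(n-1)
    for n in range(1, n_max + 1):
        term = pref * t[n] * xpow * (n * m_r * P_n + m_t * P1_n * cphi)
        V += term
        scale = np.max(np.abs(V))
        # stop when the geometric bound on the remaining tail (successive
        # terms shrink roughly by x = b / r_inner) drops below tol
        if (
            n >= 2
            and scale > 0
            and np.max(np.abs(term)) * x / max(1.0 - x, 1e-3) < tol * scale
        ):
            return V
        if b == 0.0:
            return V  # only n = 1 contributes
        # advance recurrences to degree n+1
        P_np1 = ((2 * n + 1) * ct * P_n - n * P_nm1) / (n + 1)
        P1_np1 = ((2 * n + 1) * ct * P1_n - (n + 1) * P1_nm1) / n
        P_nm1, P_n = P_n, P_np1
        P1_nm1, P1_n = P1_n, P1_np1
        xpow *= x
    raise RuntimeError(
        f"sphere series did not converge within {n_max} terms "
        f"(dipole eccentricity {b / r1:.3f})"
    )


def apply_average_reference(potentials: np.ndarray) -> np.ndarray:
    """Subtract the mean across channels (axis 0).  Bipolar differences are
    invariant under this re-referencing."""
    v = np.asarray(potentials, dtype=float)
    if v.shape[0] < 2:
        raise ValueError("average reference needs at least 2 channels")
    return v - v.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# lead fields


@dataclass(frozen=True)
class LeadField:
    """Average-referenced channels x source-components matrix, volts per A*m.

    Column ``j`` holds the scalp potentials of a unit dipole at
    ``source_positions[j]`` with moment direction ``source_orientations[j]``.
    """

    matrix: np.ndarray
    channel_labels: tuple[str, ...]
    source_positions: np.ndarray
    source_orientations: np.ndarray
    reference_tag: str = "average"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(
            self, "source_positions",
            np.asarray(self.source_positions, dtype=float).reshape(-1, 3),
        )
        object.__setattr__(
            self, "source_orientations",
            np.asarray(self.source_orientations, dtype=float).reshape(-1, 3),
        )
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        if m.shape != (len(self.channel_labels), len(self.source_positions)):
            raise ValueError("lead-field shape inconsistent with descriptors")
        if self.reference_tag not in ("raw", "average"):
            raise ValueError(f"unknown reference_tag {self.reference_tag!r}")
        if self.reference_tag == "average" and m.size:
            colmax = np.abs(m).max(axis=0)
            colmax[colmax == 0] = 1.0
            if np.max(np.abs(m.sum(axis=0)) / colmax) > 1e-12:
                raise ValueError("average-referenced columns must sum to 0")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


_UNIT_XYZ = np.eye(3)


def compute_leadfield(
    montage: ElectrodeMontage,
    sources: VolumeGrid | CorticalSurface,
    shell_or_bem,
    orientation_mode: str = "surface_normal",
    method: str = "sphere",
    tol: float = 1e-6,
) -> LeadField:
    """Assemble the average-referenced lead field for a montage.

    ``orientation_mode='unconstrained'`` produces three columns per source
    (unit moments along x, y, z); ``'surface_normal'`` one column per cortex
    vertex with the moment along the outward normal.  ``method`` selects the
    sphere-series engine (``shell_or_bem`` is a :class:`ShellModel`) or the
    boundary-element engine (a :class:`~earfield.bem.BemOperator`).
    """
    if orientation_mode not in ("unconstrained", "surface_normal"):
        raise ValueError(f"unknown orientation_mode {orientation_mode!r}")
    if method not in ("sphere", "bem"):
        raise ValueError(f"unknown method {method!r}")
    if orientation_mode == "surface_normal":
        if not isinstance(sources, CorticalSurface):
            raise TypeError("surface_normal mode needs a CorticalSurface")
        positions = sources.mesh.vertices
        orientations = sources.normals
    else:
        if isinstance(sources, CorticalSurface):
            positions = np.repeat(sources.mesh.vertices, 3, axis=0)
        else:
            positions = np.repeat(sources.points, 3, axis=0)
        orientations = np.tile(_UNIT_XYZ, (len(positions) // 3, 1))

    if method == "sphere":
        shell: ShellModel = shell_or_bem
        inner = shell.inner_radius
        rad = np.linalg.norm(positions - shell.center, axis=1)
        bad = np.flatnonzero(rad >= inner)
        if len(bad):
            raise ValueError(
                f"source {bad[0]} at radius {rad[bad[0]]:.4f} m lies outside "
                f"the innermost shell ({inner:.4f} m)"
            )
        solve = lambda dip: potential_sphere(dip, shell, montage.positions, tol=tol)
    else:
        from .bem import bem_potential

        solve = lambda dip: bem_potential(shell_or_bem, dip, montage.positions)

    cols = np.empty((montage.n_electrodes, len(positions)))
    for j, (p, o) in enumerate(zip(positions, orientations)):
        cols[:, j] = solve(Dipole(p, o))
    cols = apply_average_reference(cols)
    return LeadField(cols, montage.labels, positions, orientations, "average")
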
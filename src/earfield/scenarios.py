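"""Single-dipole demonstrations of the source-sensor relationship.

Three sweeps show how the signal seen by an around-ear montage depends on
source orientation, position and depth: a dipole near the ear-grid center
is (1) rotated between the grid-normal, anterior and dorsal directions,
(2) displaced anteriorly/dorsally at fixed orientation, and (3) pushed
medially into the head at fixed (dorsal) orientation.  Each run reports
the electrode potentials (average-referenced within the montage) and the
amplitudes of the named horizontal and vertical bipolar channels, in nV
for a 1 nA*m source.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .forward import Dipole, apply_average_reference, potential_sphere
from .head import ElectrodeMontage, ShellModel, SyntheticHead, VolumeGrid

__all__ = [
    "DEFAULT_BIPOLAR_CHANNELS",
    "grid_center_dipole",
    "grid_orientations",
    "run_orientation_sweep",
    "run_position_sweep",
    "run_depth_sweep",
]

log = logging.getLogger(__name__)

#: Named single bipolar channels of the left around-ear grid: one
#: predominantly horizontal pair across the ear and one vertical pair
#: behind it (the vertical pair spans the larger distance because the
#: C-ellipse is taller than it is wide).
DEFAULT_BIPOLAR_CHANNELS = {
    "horizontal": ("L1", "L4b"),
    "vertical": ("L3", "L6"),
}


def grid_center_dipole(grid: VolumeGrid, montage: ElectrodeMontage) -> np.ndarray:
    """The volume-grid point closest to the montage's electrode centroid
    (ties resolved to the lowest grid index)."""
    if grid.n_points == 0:
        raise ValueError("empty volume grid")
    centroid = montage.positions.mean(axis=0)
    d = np.linalg.norm(grid.points - centroid, axis=1)
    return grid.points[int(np.argmin(d))].copy()


def grid_orientations(montage: ElectrodeMontage) -> dict[str, np.ndarray]:
    """Orthonormal source-orientation triplet adapted to an ear grid.

    ``normal``: least-squares best-fit plane normal of the electrode
    positions, signed to point toward the electrodes (out of the head);
    ``anterior`` and ``dorsal``: in-plane directions aligned with +x and +z.
    """
    pos = montage.positions
    if len(pos) < 3:
        raise ValueError("need at least 3 electrodes to fit a plane")
    centered = pos - pos.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-12 * s[0]:
        raise ValueError("electrodes are collinear; plane is degenerate")
    normal = vt[2]
    if normal @ pos.mean(axis=0) < 0:
        normal = -normal
    anterior = np.array([1.0, 0.0, 0.0])
    anterior = anterior - (anterior @ normal) * normal
    anterior /= np.linalg.norm(anterior)
    dorsal = np.array([0.0, 0.0, 1.0])
    dorsal = dorsal - (dorsal @ normal) * normal - (dorsal @ anterior) * anterior
    dorsal /= np.linalg.norm(dorsal)
    return {"normal": normal, "anterior": anterior, "dorsal": dorsal}


def _run_conditions(
    shell: ShellModel,
    montage: ElectrodeMontage,
    conditions: list[tuple[str, np.ndarray, np.ndarray]],
    bipolar_channels: dict[str, tuple[str, str]],
    amplitude: float,
    tol: float,
) -> pd.DataFrame:
    rows = []
    for name, pos, ori in conditions:
        v = potential_sphere(Dipole(pos, ori * amplitude), shell, montage.positions, tol=tol)
        v = apply_average_reference(v)
        row = {"condition": name}
        row.update({f"x_{a}": p for a, p in zip("xyz", pos)})
        row.update(
            {lab: vi * 1e9 for lab, vi in zip(montage.labels, v)}
        )
        for cname, (a, b) in bipolar_channels.items():
            row[f"amp_nV_{cname}"] = abs(
                v[montage.index(a)] - v[montage.index(b)]
            ) * 1e9
        d = np.linalg.norm(montage.positions - pos, axis=1)
        row["mean_electrode_distance_m"] = d.mean()
        rows.append(row)
    return pd.DataFrame(rows)


def run_orientation_sweep(
    head: SyntheticHead,
    montage: ElectrodeMontage | None = None,
    bipolar_channels: dict[str, tuple[str, str]] | None = None,
    amplitude: float = 1e-9,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Dipole at the grid point nearest the ear-grid centroid, oriented
    along the grid normal, anterior and dorsal directions in turn."""
    montage = montage if montage is not None else head.grid_left
    bipolar_channels = bipolar_channels or DEFAULT_BIPOLAR_CHANNELS
    pos = grid_center_dipole(head.grid, montage)
    ori = grid_orientations(montage)
    conditions = [(k, pos, ori[k]) for k in ("normal", "anterior", "dorsal")]
    return _run_conditions(
        head.shell, montage, conditions, bipolar_channels, amplitude, tol
    )


def _clip_shift(
    pos: np.ndarray, shift_vec: np.ndarray, shell: ShellModel, margin: float
) -> np.ndarray:
    """Shrink a displacement so the dipole stays ``margin`` inside the
    innermost shell; logs a warning when clipping occurs."""
    rmax = shell.inner_radius - margin
    target = pos + shift_vec
    if np.linalg.norm(target - shell.center) <= rmax:
        return target
    # largest t in (0, 1] with |pos + t*shift - center| = rmax
    p = pos - shell.center
    s = shift_vec
    a = s @ s
    b = 2.0 * p @ s
    c = p @ p - rmax**2
    disc = b**2 - 4 * a * c
    if disc < 0 or a == 0:
        raise ValueError("shifted dipole cannot be kept inside the brain")
    t = (-b + np.sqrt(disc)) / (2 * a)
    if t <= 0:
        raise ValueError("shifted dipole cannot be kept inside the brain")
    t = min(t, 1.0)
    log.warning(
        "shift clipped to %.1f%% (%.1f mm) to stay inside the innermost shell",
        100 * t,
        1e3 * t * np.linalg.norm(s),
    )
    return pos + t * s


def run_position_sweep(
    head: SyntheticHead,
    montage: ElectrodeMontage | None = None,
    bipolar_channels: dict[str, tuple[str, str]] | None = None,
    shift: float = 0.045,
    amplitude: float = 1e-9,
    tol: float = 1e-6,
    clip_margin: float = 0.005,
) -> pd.DataFrame:
    """Anteriorly oriented dipole at the grid center, then displaced by
    ``shift`` anteriorly and dorsally (displacements that would leave the
    brain are clipped to the largest feasible shift, with a warning)."""
    montage = montage if montage is not None else head.grid_left
    bipolar_channels = bipolar_channels or DEFAULT_BIPOLAR_CHANNELS
    base = grid_center_dipole(head.grid, montage)
    ori = grid_orientations(montage)["anterior"]
    conditions = [("centered", base, ori)]
    for name, direction in (
        ("anterior", np.array([1.0, 0.0, 0.0])),
        ("dorsal", np.array([0.0, 0.0, 1.0])),
    ):
        pos = _clip_shift(base, shift * direction, head.shell, clip_margin)
        conditions.append((name, pos, ori))
    return _run_conditions(
        head.shell, montage, conditions, bipolar_channels, amplitude, tol
    )


def run_depth_sweep(
    head: SyntheticHead,
    montage: ElectrodeMontage | None = None,
    bipolar_channels: dict[str, tuple[str, str]] | None = None,
    depths: tuple[float, ...] = (0.0, 0.015, 0.03),
    amplitude: float = 1e-9,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Dorsally oriented dipole at the grid center, moved medially (toward
    the head center) by each depth offset."""
    montage = montage if montage is not None else head.grid_left
    bipolar_channels = bipolar_channels or DEFAULT_BIPOLAR_CHANNELS
    base = grid_center_dipole(head.grid, montage)
    ori = grid_orientations(montage)["dorsal"]
    medial = head.shell.center - base
    nm = np.linalg.norm(medial)
    if nm == 0:
        raise ValueError("grid-center dipole coincides with the head center")
    medial = medial / nm
    conditions = []
    for d in depths:
        pos = base + d * medial
        if np.linalg.norm(pos - head.shell.center) >= head.shell.inner_radius:
            raise ValueError(f"depth offset {d} m pushes the dipole outside the brain")
        conditions.append((f"depth_{d * 100:g}cm", pos, ori))
    return _run_conditions(
        head.shell, montage, conditions, bipolar_channels, amplitude, tol
    )
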
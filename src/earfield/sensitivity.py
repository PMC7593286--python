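"""Ear-EEG vs cap sensitivity analysis.

For every source (a cortex patch or a single dipole) and every montage, the
analysis searches all unordered electrode pairs for the bipolar channel
with the largest amplitude; the ear montage's best amplitude relative to
the cap's defines the percentage signal loss (negative loss = gain).
Bipolar amplitudes are reference-invariant, so the exhaustive pair search
is the natural montage-level sensitivity measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forward import LeadField
from .head import CorticalSurface, ElectrodeMontage, Parcellation

__all__ = [
    "PairSet",
    "PairHistogram",
    "SurfaceMapResult",
    "enumerate_pairs",
    "best_pair_amplitude",
    "patch_potentials",
    "signal_loss_percent",
    "run_patch_analysis",
    "summarize_losses",
    "best_pair_histogram",
    "whole_surface_map",
]

#: Sources whose best cap amplitude falls below this fraction of the cap's
#: maximum over all sources are flagged uninformative: all their bipolar
#: amplitudes are near zero and loss ratios become meaningless.
UNINFORMATIVE_FRACTION = 1e-3


@dataclass(frozen=True)
class PairSet:
    """All unordered electrode pairs of a montage, lexicographic by index."""

    pairs: np.ndarray  # (n_pairs, 2) int
    labels: tuple[str, ...]

    def __post_init__(self):
        p = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        object.__setattr__(self, "pairs", p)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if len(p) != n * (n - 1) // 2:
            raise ValueError("pair count must be C(n, 2)")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_labels(self, k: int) -> tuple[str, str]:
        i, j = self.pairs[k]
        return self.labels[i], self.labels[j]


def enumerate_pairs(montage: ElectrodeMontage) -> PairSet:
    """All unordered electrode pairs: C(n, 2) of them (190 for 20
    electrodes, 8128 for 128)."""
    n = montage.n_electrodes
    if n < 2:
        raise ValueError("need at least 2 electrodes to form a pair")
    i, j = np.triu_indices(n, k=1)
    return PairSet(np.column_stack([i, j]), montage.labels)


def best_pair_amplitude(
    channel_potentials: np.ndarray, pairs: PairSet
) -> tuple[tuple[int, int], float]:
    """The pair maximizing ``|V_i - V_j|``; ties go to the first pair in
    lexicographic order."""
    v = np.asarray(channel_potentials, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite channel potentials")
    if pairs.n_pairs == 0:
        raise ValueError("empty pair set")
    amps = np.abs(v[pairs.pairs[:, 0]] - v[pairs.pairs[:, 1]])
    k = int(np.argmax(amps))
    return (int(pairs.pairs[k, 0]), int(pairs.pairs[k, 1])), float(amps[k])


def _pair_amplitude_matrix(matrix: np.ndarray, pairs: PairSet) -> np.ndarray:
    """(n_pairs, n_sources) bipolar amplitudes from a channels x sources array."""
    return np.abs(matrix[pairs.pairs[:, 0]] - matrix[pairs.pairs[:, 1]])


def patch_potentials(
    leadfield: LeadField,
    parcellation: Parcellation,
    patch_id: int,
    amplitude: float = 1e-9,
) -> np.ndarray:
    """Channel potentials of a patch source: the coherent sum of the
    patch's vertex dipoles, each at ``amplitude`` (A*m) along its outward
    normal.  Requires a surface-normal lead field (one column per vertex)."""
    if leadfield.n_columns != len(parcellation.patch_id):
        raise ValueError(
            "lead field is not surface-normal over the parcellated cortex"
        )
    verts = parcellation.vertices_of(patch_id)
    if len(verts) == 0:
        raise KeyError(f"patch {patch_id} is empty")
    return leadfield.matrix[:, verts].sum(axis=1) * amplitude


def signal_loss_percent(ear_amplitude: float, cap_amplitude: float) -> float:
    """``100 * (1 - ear / cap)``; negative values are signal gain."""
    if cap_amplitude <= 0:
        raise ValueError("cap amplitude must be positive (reference undefined)")
    return 100.0 * (1.0 - ear_amplitude / cap_amplitude)


def run_patch_analysis(
    leadfield_cap: LeadField,
    leadfield_ear: LeadField,
    parcellation: Parcellation,
    bipolar_channels: dict[str, tuple[str, str]] | None = None,
    amplitude: float = 1e-9,
) -> pd.DataFrame:
    """Per-patch sensitivity table.

    For every patch: best cap pair and amplitude, best ear pair and
    amplitude, percentage loss, and the loss of each named single bipolar
    channel (e.g. the horizontal and vertical around-ear channels).
    Amplitudes are reported in nV for the given source amplitude
    (default 1 nA*m per vertex).
    """
    if leadfield_cap.n_columns != leadfield_ear.n_columns:
        raise ValueError("lead fields must share one source space")
    cap_labels = leadfield_cap.channel_labels
    ear_labels = leadfield_ear.channel_labels
    cap_pairs = enumerate_pairs(
        ElectrodeMontage(cap_labels, np.zeros((len(cap_labels), 3)))
    )
    ear_pairs = enumerate_pairs(
        ElectrodeMontage(ear_labels, np.zeros((len(ear_labels), 3)))
    )
    named = dict(bipolar_channels or {})
    named_idx = {
        name: (ear_labels.index(a), ear_labels.index(b))
        for name, (a, b) in named.items()
    }

    rows = []
    n_patches = parcellation.n_patches
    v_cap_all = np.column_stack(
        [
            patch_potentials(leadfield_cap, parcellation, p, amplitude)
            for p in range(n_patches)
        ]
    )
    v_ear_all = np.column_stack(
        [
            patch_potentials(leadfield_ear, parcellation, p, amplitude)
            for p in range(n_patches)
        ]
    )
    cap_amp = _pair_amplitude_matrix(v_cap_all, cap_pairs)
    ear_amp = _pair_amplitude_matrix(v_ear_all, ear_pairs)
    cap_best = cap_amp.max(axis=0)
    cap_arg = cap_amp.argmax(axis=0)
    ear_best = ear_amp.max(axis=0)
    ear_arg = ear_amp.argmax(axis=0)
    informative = cap_best >= UNINFORMATIVE_FRACTION * cap_best.max()
    for p in range(n_patches):
        ci, cj = cap_pairs.pairs[cap_arg[p]]
        ei, ej = ear_pairs.pairs[ear_arg[p]]
        row = {
            "patch_id": p,
            "area_cm2": parcellation.patch_areas[p],
            "cap_pair": f"{cap_labels[ci]}-{cap_labels[cj]}",
            "cap_amp_nV": cap_best[p] * 1e9,
            "ear_pair": f"{ear_labels[ei]}-{ear_labels[ej]}",
            "ear_pair_idx": (int(ei), int(ej)),
            "ear_amp_nV": ear_best[p] * 1e9,
            "loss_pct": signal_loss_percent(ear_best[p], cap_best[p]),
            "uninformative": not informative[p],
        }
        for name, (i, j) in named_idx.items():
            a = abs(v_ear_all[i, p] - v_ear_all[j, p])
            row[f"amp_nV_{name}"] = a * 1e9
            row[f"loss_pct_{name}"] = signal_loss_percent(a, cap_best[p])
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_losses(table: pd.DataFrame) -> pd.DataFrame:
    """Mean / SD / min / max of the percentage loss per montage and per
    named bipolar channel, across all patches."""
    cols = ["loss_pct"] + [
        c for c in table.columns if c.startswith("loss_pct_")
    ]
    out = []
    for c in cols:
        v = table[c].to_numpy()
        out.append(
            {
                "channel": "ear_grid" if c == "loss_pct" else c[len("loss_pct_"):],
                "mean": v.mean(),
                "sd": v.std(ddof=1),
                "min": v.min(),
                "max": v.max(),
            }
        )
    return pd.DataFrame(out)


@dataclass(frozen=True)
class PairHistogram:
    """How often each electrode pair won the best-amplitude search."""

    counts: np.ndarray  # (n, n) symmetric, zero diagonal
    labels: tuple[str, ...]
    inclusion_rule: str

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "labels", tuple(self.labels))
        if c.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts shape mismatch")
        if np.any(np.diag(c) != 0) or not np.array_equal(c, c.T):
            raise ValueError("counts must be symmetric with zero diagonal")

    @property
    def total(self) -> int:
        return int(self.counts.sum() // 2)


def best_pair_histogram(
    results: pd.DataFrame,
    montage: ElectrodeMontage,
    inclusion: str = "loss_below_mean",
) -> PairHistogram:
    """Histogram of winning ear pairs over the included patches.

    The default inclusion rule keeps only patches whose loss is below the
    mean loss over all patches: for high-loss patches every bipolar
    amplitude is near zero and the identity of the 'best' pair is
    uninformative.
    """
    if inclusion == "loss_below_mean":
        mask = results["loss_pct"] < results["loss_pct"].mean()
    elif inclusion == "all":
        mask = np.ones(len(results), dtype=bool)
    else:
        raise ValueError(f"unknown inclusion rule {inclusion!r}")
    n = montage.n_electrodes
    counts = np.zeros((n, n), dtype=np.int64)
    included = results[mask]
    if len(included) == 0:
        import logging

        logging.getLogger(__name__).warning(
            "no patch passes the inclusion rule; histogram is empty"
        )
    for i, j in included["ear_pair_idx"]:
        counts[i, j] += 1
        counts[j, i] += 1
    return PairHistogram(counts, montage.labels, inclusion)


@dataclass(frozen=True)
class SurfaceMapResult:
    """Per-vertex sensitivity map and the gain summary."""

    cap_amp_nV: np.ndarray
    ear_amp_nV: np.ndarray
    loss_pct: np.ndarray
    uninformative: np.ndarray
    n_gain: int
    gain_fraction: float
    gain_mean: float
    gain_sd: float
    gain_min: float
    gain_max: float

    def gain_summary(self) -> dict:
        return {
            "n_gain": self.n_gain,
            "n_vertices": len(self.loss_pct),
            "gain_fraction_pct": 100.0 * self.gain_fraction,
            "gain_mean_pct": self.gain_mean,
            "gain_sd_pct": self.gain_sd,
            "gain_min_pct": self.gain_min,
            "gain_max_pct": self.gain_max,
        }


def whole_surface_map(
    leadfield_cap: LeadField,
    leadfield_ear: LeadField,
    surface: CorticalSurface,
    amplitude: float = 1e-9,
) -> SurfaceMapResult:
    """Single-dipole sensitivity map over every cortex vertex.

    Each vertex is activated alone (one dipole along its normal at
    ``amplitude``); the best bipolar amplitude of each montage maps the
    percentage loss at that vertex.  Vertices where the ear montage beats
    the cap carry negative loss (gain); the gain magnitudes are summarized.
    """
    if (
        leadfield_cap.n_columns != surface.n_vertices
        or leadfield_ear.n_columns != surface.n_vertices
    ):
        raise ValueError("lead fields must have one column per cortex vertex")
    cap_pairs = enumerate_pairs(
        ElectrodeMontage(
            leadfield_cap.channel_labels,
            np.zeros((len(leadfield_cap.channel_labels), 3)),
        )
    )
    ear_pairs = enumerate_pairs(
        ElectrodeMontage(
            leadfield_ear.channel_labels,
            np.zeros((len(leadfield_ear.channel_labels), 3)),
        )
    )
    cap_best = _pair_amplitude_matrix(
        leadfield_cap.matrix * amplitude, cap_pairs
    ).max(axis=0)
    ear_best = _pair_amplitude_matrix(
        leadfield_ear.matrix * amplitude, ear_pairs
    ).max(axis=0)
    loss = 100.0 * (1.0 - ear_best / cap_best)
    uninformative = cap_best < UNINFORMATIVE_FRACTION * cap_best.max()
    gains = -loss[loss < 0]
    n_gain = int(len(gains))
    return SurfaceMapResult(
        cap_amp_nV=cap_best * 1e9,
        ear_amp_nV=ear_best * 1e9,
        loss_pct=loss,
        uninformative=uninformative,
        n_gain=n_gain,
        gain_fraction=n_gain / len(loss),
        gain_mean=float(gains.mean()) if n_gain else 0.0,
        gain_sd=float(gains.std(ddof=1)) if n_gain > 1 else 0.0,
        gain_min=float(gains.min()) if n_gain else 0.0,
        gain_max=float(gains.max()) if n_gain else 0.0,
    )
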
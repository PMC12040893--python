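"""Synthetic resting-state voxel time series with planted brain states.

Real resting-state fMRI shows piecewise-stationary "states": during a state a
subset of independent-component (IC) modules is coherently active, giving high
within-module amplitude correlation and (optionally) cross-module
anticorrelation, while the remaining voxels carry unstructured noise.  This
module generates analysis-ready voxel x frame matrices with exactly that
structure plus the ground truth needed for parameter-recovery tests, and small
benchmark graphs with known analytic properties for the flow solver.

The signal model for a voxel i belonging to IC c at frame t in state S is

    x_i(t) = s * sqrt(q) * g_S(t) + sqrt(1 - q) * eps_i(t)

where g_S is the state's shared unit-variance AR(1) latent, s the sign of the
state's coupling for c, q the within-module signal share, and eps_i i.i.d.
noise.  Two voxels in ICs coupled with signs s1, s2 in the same state then
have expected Pearson correlation s1*s2*q over stationary windows, so q is
directly the planted (anti)correlation level.  Voxels with zero coupling and
unclassified voxels are pure noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_ICS",
    "SyntheticConfig",
    "GroundTruth",
    "VoxelTimeSeries",
    "generate_state_sequence",
    "generate_voxel_timeseries",
    "generate_benchmark_graph",
    "planted_transition_windows",
]

#: IC labels used throughout, in display order (resting-state networks plus
#: cerebellum / vermis and the catch-all class).
CANONICAL_ICS = (
    "DMN", "SN", "DAN", "CEN", "SMN", "AN", "VN",
    "L_Cbl", "R_Cbl", "Vermis", "unclassified",
)

UNCLASSIFIED = "unclassified"

# Each default state couples one large (dominant) module with one small
# satellite, so the dominant IC makes up >= 0.8 of the active set; SMN and
# the unclassified remainder stay quiescent throughout.
_DEFAULT_IC_SPEC = (("DMN", 60), ("SN", 14), ("DAN", 12), ("CEN", 50),
                    ("SMN", 45), ("AN", 12), ("VN", 55))
_DEFAULT_COUPLING = (
    {"DMN": 1.0, "SN": 1.0},
    {"VN": 1.0, "AN": 1.0},
    {"CEN": 1.0, "DAN": 1.0},
)


class ConfigurationError(ValueError):
    """Raised when a synthetic configuration violates its invariants."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic run.

    Defaults are the desk-scale conditions used by the recovery tests:
    300 voxels x 600 frames at TR 0.72 s, three states separated by two
    boundaries, within-module signal share 0.75 (above the 0.65 positive
    edge threshold), and purely positive couplings so that anticorrelation
    stays diffuse (below the 0.5 unsigned-negative threshold).
    """

    n_voxels: int = 300
    n_frames: int = 600
    tr_seconds: float = 0.72
    ic_spec: tuple[tuple[str, int], ...] = _DEFAULT_IC_SPEC
    n_states: int = 3
    state_boundaries: tuple[int, ...] = (200, 400)
    state_coupling: tuple[Mapping[str, float], ...] = _DEFAULT_COUPLING
    within_signal_share: float = 0.75
    noise_sd: float = 1.0
    ar_coeff: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_voxels < 1 or self.n_frames < 2:
            raise ConfigurationError("need at least 1 voxel and 2 frames")
        labelled = sum(n for _, n in self.ic_spec)
        if labelled > self.n_voxels:
            raise ConfigurationError(
                f"ic_spec assigns {labelled} voxels but only {self.n_voxels} exist"
            )
        if any(n < 1 for _, n in self.ic_spec):
            raise ConfigurationError("every IC must contain at least one voxel")
        names = [name for name, _ in self.ic_spec]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate IC name in ic_spec")
        if UNCLASSIFIED in names:
            raise ConfigurationError(f"'{UNCLASSIFIED}' is reserved")
        if len(self.state_boundaries) != self.n_states - 1:
            raise ConfigurationError(
                f"{self.n_states} states need {self.n_states - 1} boundaries, "
                f"got {len(self.state_boundaries)}"
            )
        bounds = list(self.state_boundaries)
        if bounds != sorted(set(bounds)):
            raise ConfigurationError("state_boundaries must be strictly increasing")
        if bounds and (bounds[0] <= 0 or bounds[-1] >= self.n_frames):
            raise ConfigurationError("state_boundaries must lie strictly inside (0, n_frames)")
        if len(self.state_coupling) != self.n_states:
            raise ConfigurationError("state_coupling must have one map per state")
        known = set(names)
        for k, coupling in enumerate(self.state_coupling):
            unknown = set(coupling) - known
            if unknown:
                raise ConfigurationError(f"state {k} couples unknown ICs {sorted(unknown)}")
        if not 0.0 < self.within_signal_share < 1.0:
            raise ConfigurationError("within_signal_share must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")

    @property
    def ic_labels(self) -> np.ndarray:
        """Per-voxel IC label, ICs in spec order then 'unclassified'."""
        labels = np.full(self.n_voxels, UNCLASSIFIED, dtype=object)
        i = 0
        for name, count in self.ic_spec:
            labels[i : i + count] = name
            i += count
        return labels


@dataclass(frozen=True)
class VoxelTimeSeries:
    """Voxel x frame signal matrix with lattice coordinates and TR."""

    data: np.ndarray            # (n_voxels, n_frames)
    tr_seconds: float
    coords: np.ndarray          # (n_voxels, 3) integer lattice positions
    voxel_ids: np.ndarray       # (n_voxels,) stable integer ids

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (voxels x frames)")
        if self.coords.shape != (self.data.shape[0], 3):
            raise ValueError("coords must be (n_voxels, 3)")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    # -- plain-text / NIfTI round trips -------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.data, index=self.voxel_ids)
        df.index.name = "voxel_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, tr_seconds: float,
                 coords: np.ndarray | None = None) -> "VoxelTimeSeries":
        df = pd.read_csv(path, sep="\t", index_col=0)
        data = df.to_numpy(dtype=float)
        ids = df.index.to_numpy(dtype=int)
        if coords is None:
            coords = lattice_coords(len(ids))
        return cls(data=data, tr_seconds=tr_seconds, coords=coords, voxel_ids=ids)

    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        shape = self.coords.max(axis=0) + 1
        vol = np.zeros((*shape, self.n_frames), dtype=np.float32)
        x, y, z = self.coords.T
        vol[x, y, z, :] = self.data
        affine = np.eye(4)
        img = nib.Nifti1Image(vol, affine)
        img.header.set_zooms((1.0, 1.0, 1.0, self.tr_seconds))
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, mask_path: str | Path | None = None,
                   tr_seconds: float | None = None) -> "VoxelTimeSeries":
        import nibabel as nib

        img = nib.load(str(path))
        vol = np.asarray(img.dataobj, dtype=float)
        if vol.ndim != 4:
            raise ValueError("expected a 4-D NIfTI volume")
        if mask_path is not None:
            mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
        else:
            mask = vol.any(axis=3)
        coords = np.argwhere(mask)
        data = vol[mask]
        if tr_seconds is None:
            tr_seconds = float(img.header.get_zooms()[3])
        return cls(
            data=data,
            tr_seconds=tr_seconds,
            coords=coords,
            voxel_ids=np.arange(data.shape[0]),
        )


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: per-frame state ids, voxel labels, active ICs."""

    state_sequence: np.ndarray                    # (n_frames,) int state ids
    ic_labels: np.ndarray                         # (n_voxels,) str
    active_ics_per_state: tuple[Mapping[str, float], ...]
    state_boundaries: tuple[int, ...]

    def planted_transition_windows(self, n_frames: int, window_frames: int,
                                   shift_frames: int) -> list[int]:
        return planted_transition_windows(
            self.state_boundaries, n_frames, window_frames, shift_frames
        )

    def labels_to_tsv(self, path: str | Path, coords: np.ndarray) -> None:
        df = pd.DataFrame({
            "voxel_id": np.arange(len(self.ic_labels)),
            "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
            "ic_name": self.ic_labels,
        })
        df.to_csv(path, sep="\t", index=False)

    def states_to_json(self, path: str | Path) -> None:
        payload = {
            "state_sequence": [int(s) for s in self.state_sequence],
            "state_boundaries": [int(b) for b in self.state_boundaries],
            "active_ics_per_state": [dict(m) for m in self.active_ics_per_state],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def lattice_coords(n_voxels: int) -> np.ndarray:
    """Pack voxels into a cubic integer lattice (synthetic stand-in for MNI)."""
    side = int(np.ceil(n_voxels ** (1 / 3)))
    grid = np.stack(np.meshgrid(*(np.arange(side),) * 3, indexing="ij"), axis=-1)
    return grid.reshape(-1, 3)[:n_voxels]


def generate_state_sequence(cfg: SyntheticConfig) -> np.ndarray:
    """Piecewise-constant per-frame state ids with changes at the boundaries."""
    seq = np.zeros(cfg.n_frames, dtype=int)
    for state, start in enumerate(cfg.state_boundaries, start=1):
        seq[start:] = state
    return seq


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) path."""
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * np.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + innov[t - 1]
    return x


def generate_voxel_timeseries(
    cfg: SyntheticConfig,
) -> tuple[VoxelTimeSeries, GroundTruth]:
    """Generate the planted-state series and its ground truth.

    All randomness flows from ``cfg.seed`` through a single generator, so the
    output is bit-identical across calls with the same configuration.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = cfg.ic_labels
    states = generate_state_sequence(cfg)

    # One shared latent per state, read by all its active ICs (signed).
    latents = np.stack([_ar1(rng, cfg.n_frames, cfg.ar_coeff)
                        for _ in range(cfg.n_states)])
    shared = latents[states, np.arange(cfg.n_frames)]  # the live latent per frame

    q = cfg.within_signal_share
    noise = rng.standard_normal((cfg.n_voxels, cfg.n_frames)) * cfg.noise_sd
    data = np.sqrt(1.0 - q) * noise

    # Per-frame signed coupling for each voxel's IC in the current state.
    sign = np.zeros((cfg.n_voxels, cfg.n_frames))
    for k, coupling in enumerate(cfg.state_coupling):
        frames = states == k
        for name, coeff in coupling.items():
            if coeff == 0:
                continue
            voxels = labels == name
            sign[np.ix_(voxels, frames)] = np.sign(coeff)
    data += sign * np.sqrt(q) * shared[None, :]

    ts = VoxelTimeSeries(
        data=data,
        tr_seconds=cfg.tr_seconds,
        coords=lattice_coords(cfg.n_voxels),
        voxel_ids=np.arange(cfg.n_voxels),
    )
    truth = GroundTruth(
        state_sequence=states,
        ic_labels=labels,
        active_ics_per_state=tuple(dict(m) for m in cfg.state_coupling),
        state_boundaries=tuple(cfg.state_boundaries),
    )
    return ts, truth


def planted_transition_windows(
    boundaries: Sequence[int], n_frames: int, window_frames: int, shift_frames: int
) -> list[int]:
    """Window index whose center frame is nearest each state boundary.

    Windows are half-open ``[i*shift, i*shift + window)``; the planted
    transition is attributed to the single window whose center is closest to
    the boundary, which gives recovery tests an unambiguous +/- tolerance.
    """
    n_windows = (n_frames - window_frames) // shift_frames + 1
    centers = np.arange(n_windows) * shift_frames + (window_frames - 1) / 2.0
    return [int(np.argmin(np.abs(centers - b))) for b in boundaries]


def generate_benchmark_graph(
    kind: str, n: int, param: float | None = None, seed: int = 0
) -> nx.Graph:
    """Small graphs with known analytic properties (weights 1, unit lengths).

    Kinds: ``complete``, ``cycle``, ``regular`` (param = degree), ``tree``
    (random), ``erdos_renyi`` (param = edge probability), ``scale_free``
    (Barabasi-Albert, param = m).
    """
    if kind == "cycle" and n < 3:
        raise ValueError("a cycle needs n >= 3")
    if kind == "complete":
        g = nx.complete_graph(n)
    elif kind == "cycle":
        g = nx.cycle_graph(n)
    elif kind == "regular":
        if param is None:
            raise ValueError("regular graphs need param = degree")
        g = nx.random_regular_graph(int(param), n, seed=seed)
    elif kind == "tree":
        g = nx.random_labeled_tree(n, seed=seed)
    elif kind == "erdos_renyi":
        if param is None:
            raise ValueError("erdos_renyi needs param = edge probability")
        g = nx.erdos_renyi_graph(n, float(param), seed=seed)
    elif kind == "scale_free":
        if param is None:
            raise ValueError("scale_free needs param = m (edges per new node)")
        g = nx.barabasi_albert_graph(n, int(param), seed=seed)
    else:
        raise ValueError(f"unknown benchmark graph kind {kind!r}")
    nx.set_edge_attributes(g, 1.0, "weight")
    nx.set_edge_attributes(g, 1.0, "length")
    return g
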
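"""In-memory containers for T1rho mapping data and HDF5 / NIfTI persistence.

The quantitative T1rho experiment acquires one k-space data set per
spin-lock time (the "contrast" dimension).  Three real-valued parameter
maps describe the object: the proton-density-weighted baseline ``S0``,
the rotating-frame relaxation time ``T1rho`` (ms) and a phase map
``theta`` (radians).  The magnitude image at spin-lock time TSL_c is
``S0 * exp(-TSL_c / T1rho)`` pixel-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

__all__ = [
    "ParameterMaps",
    "AcquisitionProtocol",
    "SamplingSchedule",
    "KSpaceData",
    "ContrastImageSeries",
    "save_kspace_h5",
    "load_kspace_h5",
    "save_maps_nifti",
]


@dataclass
class ParameterMaps:
    """The three unknown maps of the mono-exponential spin-lock signal model.

    Parameters
    ----------
    s0 : ndarray, shape (ny, nx)
        Non-negative baseline intensity (signal at TSL = 0), arbitrary units.
    t1rho : ndarray, shape (ny, nx)
        Rotating-frame relaxation time in milliseconds, strictly positive.
    phase : ndarray, shape (ny, nx)
        Image phase in radians (unwrapped; no range restriction).
    """

    s0: np.ndarray
    t1rho: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        self.s0 = np.asarray(self.s0, dtype=float)
        self.t1rho = np.asarray(self.t1rho, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if not (self.s0.shape == self.t1rho.shape == self.phase.shape):
            raise ValueError("s0, t1rho and phase must share one shape")
        if np.any(self.s0 < 0):
            raise ValueError("s0 must be non-negative")
        if np.any(self.t1rho <= 0):
            raise ValueError("t1rho must be strictly positive")
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase must be finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.s0.shape

    def copy(self) -> "ParameterMaps":
        return ParameterMaps(self.s0.copy(), self.t1rho.copy(), self.phase.copy())

    @classmethod
    def unchecked(cls, s0: np.ndarray, t1rho: np.ndarray,
                  phase: np.ndarray) -> "ParameterMaps":
        """Bypass validation (used for transient extrapolated iterates that
        may leave the feasible box)."""
        obj = object.__new__(cls)
        obj.s0 = np.asarray(s0, dtype=float)
        obj.t1rho = np.asarray(t1rho, dtype=float)
        obj.phase = np.asarray(phase, dtype=float)
        return obj


@dataclass
class AcquisitionProtocol:
    """Spin-lock time vector and sampling geometry of one experiment.

    ``tsl`` is in milliseconds, non-negative and strictly increasing with at
    least one positive entry; ``af`` is the acceleration factor (fully sampled
    data points divided by points actually used, >= 1).
    """

    tsl: np.ndarray
    matrix_size: int
    scheme: str = "radial"
    af: float = 1.0

    def __post_init__(self) -> None:
        self.tsl = np.asarray(self.tsl, dtype=float)
        if self.tsl.ndim != 1 or self.tsl.size < 1:
            raise ValueError("tsl must be a 1-D vector")
        if np.any(self.tsl < 0):
            raise ValueError("spin-lock times must be non-negative")
        if np.any(np.diff(self.tsl) <= 0):
            raise ValueError("spin-lock times must be strictly increasing")
        if not np.any(self.tsl > 0):
            raise ValueError("at least one spin-lock time must be positive")
        if self.scheme not in ("radial", "cartesian"):
            raise ValueError(f"unknown sampling scheme {self.scheme!r}")
        if self.af < 1:
            raise ValueError("acceleration factor must be >= 1")
        self.matrix_size = int(self.matrix_size)

    @property
    def n_contrasts(self) -> int:
        return int(self.tsl.size)


@dataclass
class SamplingSchedule:
    """Per-contrast k-space sample locations.

    Radial: ``spoke_angles`` holds one array of spoke angles (radians) per
    contrast and ``spoke_indices`` the indices of those spokes in the parent
    golden-angle sequence; readout coordinates are regenerated from
    ``n_readout``.  Cartesian: ``rows`` holds one array of 0-based phase-encode
    row indices per contrast.  Trajectory units are cycles/FOV in [-0.5, 0.5).
    """

    scheme: str
    matrix_size: int
    spoke_angles: list[np.ndarray] | None = None
    spoke_indices: list[np.ndarray] | None = None
    n_readout: int = 0
    rows: list[np.ndarray] | None = None
    seed: int | None = None

    @property
    def n_contrasts(self) -> int:
        blocks = self.spoke_angles if self.scheme == "radial" else self.rows
        return len(blocks)

    def samples_per_contrast(self) -> list[int]:
        if self.scheme == "radial":
            return [len(a) * self.n_readout for a in self.spoke_angles]
        return [len(r) * self.matrix_size for r in self.rows]

    def trajectory(self, contrast: int) -> np.ndarray:
        """(M, 2) array of (kx, ky) coordinates for one contrast (radial only)."""
        if self.scheme != "radial":
            raise ValueError("trajectory is defined for radial schedules only")
        angles = self.spoke_angles[contrast]
        radii = (np.arange(self.n_readout) - self.n_readout // 2) / self.n_readout
        kx = np.outer(np.cos(angles), radii).ravel()
        ky = np.outer(np.sin(angles), radii).ravel()
        return np.stack([kx, ky], axis=-1)

    def row_mask(self, contrast: int) -> np.ndarray:
        """Boolean mask over phase-encode rows for one contrast (cartesian)."""
        if self.scheme != "cartesian":
            raise ValueError("row_mask is defined for cartesian schedules only")
        mask = np.zeros(self.matrix_size, dtype=bool)
        mask[self.rows[contrast]] = True
        return mask


@dataclass
class KSpaceData:
    """Complex multi-contrast k-space samples with their schedule and protocol.

    ``samples`` has shape (C, M): one block of M complex samples per spin-lock
    contrast.  ``noise_sigma`` records the total complex noise standard
    deviation actually applied by the simulator (0 for noiseless data).
    """

    samples: np.ndarray
    schedule: SamplingSchedule
    protocol: AcquisitionProtocol
    noise_sigma: float = 0.0
    noise_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 2:
            raise ValueError("samples must have shape (n_contrasts, n_samples)")
        if self.samples.shape[0] != self.protocol.n_contrasts:
            raise ValueError("sample blocks inconsistent with protocol")
        per_contrast = self.schedule.samples_per_contrast()
        if any(m != self.samples.shape[1] for m in per_contrast):
            raise ValueError("sample blocks inconsistent with schedule")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("k-space samples must be finite")


@dataclass
class ContrastImageSeries:
    """Complex per-contrast images u_c (the compressed-sensing unknown)."""

    images: np.ndarray  # (C, ny, nx) complex
    tsl: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=complex)
        if self.images.ndim != 3 or self.images.shape[0] < 1:
            raise ValueError("images must have shape (C, ny, nx) with C >= 1")
        if self.tsl is not None:
            self.tsl = np.asarray(self.tsl, dtype=float)
            if self.tsl.size != self.images.shape[0]:
                raise ValueError("tsl length must match contrast count")

    @property
    def n_contrasts(self) -> int:
        return self.images.shape[0]

    @property
    def magnitudes(self) -> np.ndarray:
        return np.abs(self.images)


# ---------------------------------------------------------------------------
# Persistence


def save_kspace_h5(path: str | Path, data: KSpaceData,
                   truth: ParameterMaps | None = None) -> None:
    """Write k-space data (and optionally the ground-truth maps) to HDF5."""
    sched = data.schedule
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=data.samples)
        f.create_dataset("tsl_ms", data=data.protocol.tsl)
        if sched.scheme == "radial":
            traj = np.stack([sched.trajectory(c)
                             for c in range(sched.n_contrasts)])
            f.create_dataset("trajectory", data=traj)
            f.create_dataset(
                "spoke_indices",
                data=np.stack([np.asarray(s) for s in sched.spoke_indices]))
            f.attrs["n_readout"] = sched.n_readout
        else:
            mask = np.stack([sched.row_mask(c).astype(np.uint8)
                             for c in range(sched.n_contrasts)])
            f.create_dataset("row_mask", data=mask)
        f.attrs["matrix_size"] = data.protocol.matrix_size
        f.attrs["scheme"] = sched.scheme
        f.attrs["af"] = data.protocol.af
        f.attrs["noise_fraction"] = data.noise_fraction
        f.attrs["noise_sigma"] = data.noise_sigma
        f.attrs["seed"] = -1 if data.seed is None else data.seed
        if truth is not None:
            g = f.create_group("truth")
            g.create_dataset("s0", data=truth.s0)
            g.create_dataset("t1rho", data=truth.t1rho)
            g.create_dataset("phase", data=truth.phase)


def load_kspace_h5(path: str | Path) -> tuple[KSpaceData, ParameterMaps | None]:
    """Read a k-space container written by :func:`save_kspace_h5`."""
    with h5py.File(path, "r") as f:
        scheme = f.attrs["scheme"]
        n = int(f.attrs["matrix_size"])
        tsl = f["tsl_ms"][()]
        samples = f["samples"][()]
        af = float(f.attrs["af"])
        if scheme == "radial":
            idx = f["spoke_indices"][()]
            n_readout = int(f.attrs["n_readout"])
            traj = f["trajectory"][()]
            angles = [np.arctan2(t[n_readout - 1, 1], t[n_readout - 1, 0])
                      for t in traj]
            # recover per-spoke angles from the stored trajectory blocks
            spoke_angles = []
            for t in traj:
                per = t.reshape(-1, n_readout, 2)
                # use an off-centre readout sample to read the angle back
                ref = per[:, -1, :]
                spoke_angles.append(np.arctan2(ref[:, 1], ref[:, 0]) % np.pi)
            sched = SamplingSchedule("radial", n,
                                     spoke_angles=spoke_angles,
                                     spoke_indices=[np.asarray(i) for i in idx],
                                     n_readout=n_readout)
        else:
            mask = f["row_mask"][()].astype(bool)
            rows = [np.flatnonzero(m) for m in mask]
            sched = SamplingSchedule("cartesian", n, rows=rows)
        seed = int(f.attrs["seed"])
        data = KSpaceData(
            samples=samples,
            schedule=sched,
            protocol=AcquisitionProtocol(tsl=tsl, matrix_size=n,
                                         scheme=scheme, af=af),
            noise_sigma=float(f.attrs["noise_sigma"]),
            noise_fraction=float(f.attrs["noise_fraction"]),
            seed=None if seed < 0 else seed,
        )
        truth = None
        if "truth" in f:
            truth = ParameterMaps(f["truth/s0"][()], f["truth/t1rho"][()],
                                  f["truth/phase"][()])
    return data, truth


def save_maps_nifti(path: str | Path, maps: ParameterMaps) -> None:
    """Write the three parameter maps as one NIfTI volume per map stack."""
    vol = np.stack([maps.s0, maps.t1rho, maps.phase], axis=-1)
    nib.save(nib.Nifti1Image(vol.astype(np.float32), np.eye(4)), str(path))
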
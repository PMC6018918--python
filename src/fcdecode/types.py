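"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class BoldSeries:
    """One subject's 4D BOLD signal grid.

    Parameters
    ----------
    data
        4D array, shape ``(x, y, z, t)``, arbitrary signal units.
    voxel_size_mm
        Physical voxel dimensions along x, y, z in millimetres.
    tr_seconds
        Repetition time (sampling interval of the time axis) in seconds.
    brain_mask
        3D boolean array of in-brain voxels, same spatial shape as ``data``.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    tr_seconds: float
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D (x, y, z, t); got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("BOLD series needs at least 2 timepoints")
        if self.brain_mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"brain_mask shape {self.brain_mask.shape} does not match "
                f"spatial shape {self.data.shape[:3]}"
            )
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be 3 positive reals")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        """Copy of this series with ``data`` replaced (metadata preserved)."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class NuisanceSet:
    """Nuisance regressors for one subject: ventricular signal + motion traces.

    ``ventricular_signal`` is the mean BOLD time course within a reference
    ventricular mask; ``motion_traces`` are the six rigid-body motion
    parameters, one row per retained volume.
    """

    ventricular_signal: np.ndarray
    motion_traces: np.ndarray
    include_intercept: bool = True

    def __post_init__(self) -> None:
        self.ventricular_signal = np.asarray(self.ventricular_signal, dtype=float).ravel()
        self.motion_traces = np.asarray(self.motion_traces, dtype=float)
        if self.motion_traces.ndim != 2 or self.motion_traces.shape[1] != 6:
            raise ValueError(f"motion_traces must be t x 6; got {self.motion_traces.shape}")
        if self.motion_traces.shape[0] != self.ventricular_signal.shape[0]:
            raise ValueError("ventricular signal and motion traces disagree on length")

    @property
    def n_timepoints(self) -> int:
        return self.motion_traces.shape[0]

    def design_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Stack regressors into a design matrix with column names."""
        cols = [self.ventricular_signal[:, None], self.motion_traces]
        names = ["ventricular"] + [f"motion_{i}" for i in range(6)]
        if self.include_intercept:
            cols.insert(0, np.ones((self.n_timepoints, 1)))
            names.insert(0, "intercept")
        return np.hstack(cols), names

    def trimmed(self, n_trim: int) -> "NuisanceSet":
        return NuisanceSet(
            ventricular_signal=self.ventricular_signal[n_trim:],
            motion_traces=self.motion_traces[n_trim:],
            include_intercept=self.include_intercept,
        )


@dataclass
class Parcellation:
    """Integer label volume tying voxels to named regions.

    ``labels`` holds region label 0 for background and 1..K for regions;
    ``region_table`` maps each label to a region name.
    """

    labels: np.ndarray
    region_table: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("parcellation labels must be integers")
        if self.region_table is None:
            present = sorted(int(v) for v in np.unique(self.labels) if v != 0)
            self.region_table = pd.DataFrame(
                {"label": present, "name": [f"region_{v}" for v in present]}
            )

    @property
    def region_labels(self) -> list[int]:
        return [int(v) for v in self.region_table["label"]]

    def mask_of(self, label: int) -> np.ndarray:
        if label not in self.region_labels:
            raise KeyError(f"region label {label} not in parcellation")
        return self.labels == label


@dataclass
class ConnectivityMap:
    """Per-subject 3D map of correlation-derived values.

    ``metric`` is ``"r"`` for Pearson correlations or ``"fisher_z"`` after the
    variance-stabilizing transform. Values are defined only inside ``mask``.
    """

    values: np.ndarray
    metric: str
    subject_id: str
    seed_name: str = "global"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.metric not in ("r", "fisher_z"):
            raise ValueError(f"metric must be 'r' or 'fisher_z'; got {self.metric!r}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")


@dataclass
class SeedSpec:
    """A named seed region: boolean voxel mask, possibly bilateral."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"seed {self.name!r} has an empty mask")
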
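"""Domain containers shared across the pipeline.

The analysis operates on per-subject component time courses (the temporal
signals of ICA-derived resting-state components), windowed functional
network connectivity (FNC) vectors, a clustered state model, and per-subject
temporal state metrics.  Containers are thin dataclasses around numpy arrays
and pandas frames; validation happens at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical resting-state network labels.
NETWORKS = ("DMN", "VN", "SMN", "LFPN", "RFPN", "DAN", "VAN", "AN")


@dataclass
class ComponentTimecourses:
    """One subject's time x component signal matrix.

    Parameters
    ----------
    subject_id : str
    data : ndarray, shape (T, C)
        Component time courses, arbitrary signal units.
    tr_seconds : float
        Repetition time (sampling interval) in seconds.
    component_labels : list of str, length C
    network_map : dict
        component label -> network name; every component must be mapped.
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    component_labels: list[str]
    network_map: dict[str, str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (time x component) matrix")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 time points")
        if self.data.shape[1] != len(self.component_labels):
            raise ValueError(
                f"{self.data.shape[1]} columns but "
                f"{len(self.component_labels)} component labels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time courses contain non-finite values")
        missing = [c for c in self.component_labels if c not in self.network_map]
        if missing:
            raise ValueError(f"components without a network mapping: {missing}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]

    def networks(self) -> list[str]:
        """Network label per column, in column order."""
        return [self.network_map[c] for c in self.component_labels]

    def with_data(self, data: np.ndarray) -> "ComponentTimecourses":
        """Copy of this object with a new data matrix of the same shape."""
        return ComponentTimecourses(
            self.subject_id, data, self.tr_seconds,
            list(self.component_labels), dict(self.network_map),
        )


def pair_labels(component_labels: list[str]) -> list[str]:
    """Upper-triangle (i<j, row-major) pair labels for a component list."""
    C = len(component_labels)
    return [
        f"{component_labels[i]}--{component_labels[j]}"
        for i in range(C) for j in range(i + 1, C)
    ]


@dataclass
class FNCMatrix:
    """C x C symmetric Fisher-z connectivity matrix with a zero diagonal.

    ``networks`` optionally records the network label of each component
    (column order); the network-level group contrast requires it.
    """

    subject_id: str
    values: np.ndarray
    component_labels: list[str]
    networks: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        C = len(self.component_labels)
        if self.values.shape != (C, C):
            raise ValueError("values must be C x C")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("FNC matrix must be symmetric")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FNC matrix has non-finite entries")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be exactly 0")

    @property
    def pair_labels(self) -> list[str]:
        return pair_labels(self.component_labels)

    def upper(self) -> np.ndarray:
        """Vectorized upper triangle (i<j, row-major), length C*(C-1)/2."""
        iu = np.triu_indices(len(self.component_labels), k=1)
        return self.values[iu]


@dataclass
class WindowedFNC:
    """Per-subject sequence of vectorized windowed connectivity estimates.

    ``windows`` is N_w x P with P = C*(C-1)/2 Fisher-z values per window
    (upper triangle, row-major); ``window_starts`` holds the 0-based index
    of each window's first sample (windows are half-open ``[s, s+L)``).
    """

    subject_id: str
    windows: np.ndarray
    window_starts: np.ndarray
    component_labels: list[str]

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.window_starts = np.asarray(self.window_starts, dtype=int)
        C = len(self.component_labels)
        if self.windows.shape[1] != C * (C - 1) // 2:
            raise ValueError("window row length must be C*(C-1)/2")
        if self.windows.shape[0] != self.window_starts.shape[0]:
            raise ValueError("one start index per window required")
        if not np.all(np.isfinite(self.windows)):
            raise ValueError("windowed FNC has non-finite entries")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def pair_labels(self) -> list[str]:
        return pair_labels(self.component_labels)


@dataclass
class StateModel:
    """Result of k-means clustering of all subjects' windowed FNC vectors.

    States are indexed 1..k in descending order of overall occupancy.
    """

    k: int
    centroids: np.ndarray              # k x P
    assignments: dict[str, np.ndarray]  # subject_id -> (N_w,) ints in 1..k
    distance: str
    replicate_costs: list[float]
    seed: int
    pair_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape[0] != self.k:
            raise ValueError("need one centroid per state")
        for sid, a in self.assignments.items():
            a = np.asarray(a, dtype=int)
            if a.min() < 1 or a.max() > self.k:
                raise ValueError(f"assignments for {sid} outside 1..k")
            self.assignments[sid] = a

    @property
    def best_cost(self) -> float:
        return min(self.replicate_costs)


@dataclass
class TemporalMetrics:
    """Per-subject temporal properties of a state sequence.

    fraction_of_time : length-k proportions (sum to 1)
    mean_dwell : length-k mean contiguous run lengths, in windows
    n_transitions : number of window-to-window state changes
    """

    subject_id: str
    fraction_of_time: np.ndarray
    mean_dwell: np.ndarray
    n_transitions: int

    def __post_init__(self) -> None:
        self.fraction_of_time = np.asarray(self.fraction_of_time, dtype=float)
        self.mean_dwell = np.asarray(self.mean_dwell, dtype=float)
        if abs(self.fraction_of_time.sum() - 1.0) > 1e-12:
            raise ValueError("fractions of time must sum to 1")
        if self.n_transitions < 0:
            raise ValueError("n_transitions must be nonnegative")


def validate_clinical(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical/demographic table (one row per subject).

    Required columns: subject_id, group (PACG/HC), age, sex (M/F),
    education.  Ophthalmic measures (IOP, RNFLT, VA, duration, cup-to-disc
    ratios) are optional and may contain missing values.
    """
    required = {"subject_id", "group", "age", "sex", "education"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    if table["subject_id"].duplicated().any():
        dups = table.loc[table["subject_id"].duplicated(), "subject_id"]
        raise ValueError(f"duplicate subject ids: {list(dups)}")
    bad_group = set(table["group"]) - {"PACG", "HC"}
    if bad_group:
        raise ValueError(f"unknown group labels: {sorted(bad_group)}")
    bad_sex = set(table["sex"]) - {"M", "F"}
    if bad_sex:
        raise ValueError(f"unknown sex codes: {sorted(bad_sex)}")
    return table
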
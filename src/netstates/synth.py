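"""Synthetic cohort generator with Markov state-switching dynamics.

The generator emulates the statistical structure the downstream analysis
assumes: each subject's component time courses are drawn from a hidden
Markov chain over ``k`` connectivity states, each state being a distinct
C x C signal covariance; patients and controls differ in their chains'
stationary occupancy (by default the state-3 contrast: patients 0.10 vs
controls 0.22); and clinical covariates are coupled to true connectivity
attributes through Gaussian-copula rank reordering, which leaves the
clinical marginals exactly as specified.

Cohort defaults mirror the study design this pipeline targets: 34 patients
and 33 controls, 16 components grouped into 8 resting-state networks, 230
retained volumes at TR = 2 s, and 4 states.

Observations within a dwell are i.i.d. Gaussian draws from the state's
covariance (an optional AR(1) coefficient adds temporal smoothness for
robustness experiments).  A single global seed expands into independent
per-subject seeds through counter-keyed seed sequences, so any subject can
be regenerated in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import compute_metrics
from .types import ComponentTimecourses, TemporalMetrics, validate_clinical

__all__ = [
    "StateSpec", "CohortSpec", "GroundTruth", "DEFAULT_COMPONENTS",
    "make_state_covariances", "simulate_subject", "simulate_cohort",
    "stationary_distribution", "transition_matrix_for", "window_states",
]

log = logging.getLogger(__name__)

#: Component label -> network, mirroring an 8-network, 16-component parcellation.
DEFAULT_COMPONENTS = {
    "IC03": "DMN", "IC06": "DMN", "IC08": "DMN", "IC16": "DMN",
    "IC05": "VN", "IC09": "VN", "IC17": "VN", "IC21": "VN",
    "IC11": "SMN", "IC19": "SMN",
    "IC10": "LFPN", "IC07": "RFPN",
    "IC14": "DAN", "IC15": "DAN",
    "IC13": "VAN", "IC12": "AN",
}

#: Default stationary occupancies (states 1..4) for each group.  The
#: state-3 entries plant the headline occupancy contrast 0.10 vs 0.22.
PATIENT_OCCUPANCY = (0.45, 0.19, 0.10, 0.26)
CONTROL_OCCUPANCY = (0.46 / 0.99, 0.17 / 0.99, 0.22 / 0.99, 0.14 / 0.99)

#: Group-specific clinical marginals: mean, SD per variable.
CLINICAL_MARGINALS = {
    "PACG": {"age": (53.12, 11.75), "education": (9.44, 2.76),
             "IOP": (27.34, 9.24), "RNFLT": (86.77, 24.96),
             "VA": (0.53, 0.31), "ACD_ratio": (0.67, 0.15),
             "VCD_ratio": (0.64, 0.18)},
    "HC": {"age": (52.85, 10.61), "education": (9.91, 2.70),
           "IOP": (15.49, 2.01), "RNFLT": (117.27, 8.95),
           "VA": (1.10, 0.21), "ACD_ratio": (0.46, 0.11),
           "VCD_ratio": (0.49, 0.08)},
}


@dataclass
class StateSpec:
    """One connectivity state: a symmetric positive-definite signal covariance."""

    state_id: int
    covariance: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        self.covariance = np.asarray(self.covariance, dtype=float)
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError(f"state {self.state_id}: covariance not symmetric")
        eigvals = np.linalg.eigvalsh(self.covariance)
        if eigvals.min() <= 0:
            raise ValueError(f"state {self.state_id}: covariance not positive-definite")


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic transition matrix."""
    vals, vecs = np.linalg.eig(P.T)
    idx = np.argmin(np.abs(vals - 1.0))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def transition_matrix_for(occupancy, switch_rate: float = 0.05) -> np.ndarray:
    """Transition matrix with the given stationary occupancy.

    With probability ``switch_rate`` the chain redraws its state from the
    occupancy distribution, otherwise it stays; the stationary distribution
    is exactly ``occupancy`` and mean dwell in state j is
    ``1 / (switch_rate * (1 - occupancy_j))`` steps.
    """
    pi = np.asarray(occupancy, float)
    if abs(pi.sum() - 1.0) > 1e-9 or np.any(pi < 0):
        raise ValueError("occupancy must be a probability vector")
    pi = pi / pi.sum()
    k = pi.size
    return (1 - switch_rate) * np.eye(k) + switch_rate * np.tile(pi, (k, 1))


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort."""

    n_patients: int = 34
    n_controls: int = 33
    n_components: int = 16
    n_timepoints: int = 230
    tr_seconds: float = 2.0
    k_states: int = 4
    transition_matrix_patient: np.ndarray | None = None
    transition_matrix_control: np.ndarray | None = None
    switch_rate: float = 0.05
    within_strength: float = 0.6
    between_strength: float = 0.35
    clinical_coupling: list[tuple[str, str, float]] = field(
        default_factory=lambda: [("IOP", "fraction_state3", -0.578)])
    ar_coefficient: float = 0.0
    min_window_length: int = 48
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_states < 2 and self.k_states != 1:
            raise ValueError("k_states must be >= 1")
        if self.transition_matrix_patient is None:
            occ = PATIENT_OCCUPANCY if self.k_states == 4 else \
                np.ones(self.k_states) / self.k_states
            self.transition_matrix_patient = transition_matrix_for(
                occ, self.switch_rate)
        if self.transition_matrix_control is None:
            occ = CONTROL_OCCUPANCY if self.k_states == 4 else \
                np.ones(self.k_states) / self.k_states
            self.transition_matrix_control = transition_matrix_for(
                occ, self.switch_rate)
        for name in ("transition_matrix_patient", "transition_matrix_control"):
            P = np.asarray(getattr(self, name), float)
            if P.shape != (self.k_states, self.k_states):
                raise ValueError(f"{name} must be k x k")
            if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12) or np.any(P < 0):
                raise ValueError(f"{name} rows must sum to 1")
            setattr(self, name, P)
        if self.n_timepoints < self.min_window_length:
            raise ValueError("n_timepoints shorter than the analysis window")
        for _, _, rho in self.clinical_coupling:
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"coupling strength {rho} outside [-1, 1]")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("AR coefficient must lie in [0, 1)")


def recovery_spec(seed: int = 0, **overrides) -> "CohortSpec":
    """Cohort spec for the well-separated state-recovery regime.

    Same cohort dimensions as the default, but with slower state switching
    (switch rate 0.01, mean dwell roughly 100-180 TRs) and stronger
    between-network coupling contrasts, so that most analysis windows
    sample a single, clearly identifiable state.  This is the validation regime for
    clustering-recovery experiments; the default spec's faster switching
    emulates the transition counts observed in resting scans.
    """
    kwargs = {"switch_rate": 0.01, "between_strength": 0.5, "seed": seed}
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


@dataclass
class GroundTruth:
    """Generator-side truth for recovery tests."""

    state_sequences: dict[str, np.ndarray]
    true_metrics: dict[str, TemporalMetrics]
    group_effects: dict[str, float]
    seed: int


def _nearest_spd(M: np.ndarray, floor: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Eigenvalue-clipped symmetric repair; returns (matrix, was_repaired)."""
    sym = (M + M.T) / 2
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() > 0:
        return sym, False
    vals = np.clip(vals, floor, None)
    return vecs @ np.diag(vals) @ vecs.T, True


def _block_pattern(state_index: int, nblocks: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Within-block factors and between-block coupling signs for one state.

    The first four states follow deterministic archetypes of resting-state
    connectivity regimes: sparse (weak everywhere), strongly and globally
    connected, partial (half the blocks engaged), and modular (positive
    within a module of blocks, negative across modules).  Additional
    states get random patterns.
    """
    within = np.ones(nblocks)
    between = np.zeros((nblocks, nblocks))
    half = nblocks // 2
    if state_index == 0:          # sparse
        within[:] = 0.1
    elif state_index == 1:        # strong global connectivity
        between[:, :] = 1.0
    elif state_index == 2:        # partial: even blocks engaged, odd blocks
        within[1::2] = 0.3        # damped and anticoupled to the engaged set;
        for p in range(nblocks):  # one-factor-consistent (+1/-0.8 loadings)
            for q in range(p + 1, nblocks):
                if p % 2 == 0 and q % 2 == 0:
                    between[p, q] = between[q, p] = 1.0
                elif p % 2 == 1 and q % 2 == 1:
                    between[p, q] = between[q, p] = 0.64
                else:
                    between[p, q] = between[q, p] = -0.8
    elif state_index == 3:        # modular: two anticorrelated modules
        between[:half, :half] = 1.0
        between[half:, half:] = 1.0
        between[:half, half:] = -1.0
        between[half:, :half] = -1.0
    else:                         # extra states: random pattern
        within = rng.uniform(0.3, 1.0, nblocks)
        signs = rng.choice([-1.0, 0.0, 1.0], size=(nblocks, nblocks))
        between = np.triu(signs, 1) + np.triu(signs, 1).T
    np.fill_diagonal(between, 0.0)
    return within, between


def make_state_covariances(C: int, k: int, network_blocks,
                           within_strength: float = 0.6,
                           between_strength: float = 0.35,
                           seed: int = 0) -> list[StateSpec]:
    """Build k distinct SPD covariances with block (network) structure.

    ``network_blocks`` is a partition of the component indices 0..C-1.
    State ``s`` sets within-block correlations to ``within_strength`` times
    a state-specific factor and between-block correlations to
    ``between_strength`` times a state-specific sign pattern; the first
    four states realize sparse, strongly connected, partial, and modular
    connectivity archetypes.  Non-positive-definite drafts are repaired by
    eigenvalue clipping (logged); an irreparable state is a hard error.
    """
    if not (0 <= within_strength < 1 and 0 <= between_strength < 1):
        raise ValueError("strengths must lie in [0, 1)")
    flat = sorted(i for b in network_blocks for i in b)
    if flat != list(range(C)):
        raise ValueError("network_blocks must partition components 0..C-1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0B]))
    nblocks = len(network_blocks)
    states: list[StateSpec] = []
    for s in range(k):
        wfac, bpat = _block_pattern(s, nblocks, rng)
        R = np.eye(C)
        for bi, block in enumerate(network_blocks):
            for ai in range(len(block)):
                for ci in range(ai + 1, len(block)):
                    a, b = block[ai], block[ci]
                    R[a, b] = R[b, a] = within_strength * wfac[bi]
        for p in range(nblocks):
            for q in range(p + 1, nblocks):
                if bpat[p, q] != 0:
                    val = between_strength * bpat[p, q]
                    for a in network_blocks[p]:
                        for b in network_blocks[q]:
                            R[a, b] = R[b, a] = val
        cov, repaired = _nearest_spd(R)
        if repaired:
            log.info("state %d covariance repaired to nearest SPD", s + 1)
        eigmin = np.linalg.eigvalsh(cov).min()
        if eigmin <= 0:
            raise ValueError(f"state {s + 1}: covariance not SPD after repair")
        states.append(StateSpec(state_id=s + 1, covariance=cov,
                                description=f"synthetic state {s + 1}"))
    # distinctness: pairwise L1 separation of vectorized upper triangles
    iu = np.triu_indices(C, k=1)
    for i in range(k):
        for j in range(i + 1, k):
            sep = np.abs(states[i].covariance[iu] - states[j].covariance[iu]).sum()
            if sep == 0:
                raise ValueError(
                    f"states {i + 1} and {j + 1} are identical; increase "
                    "within/between strengths or change the seed")
    return states


def _component_labels(C: int) -> tuple[list[str], dict[str, str]]:
    if C == 16:
        labels = list(DEFAULT_COMPONENTS)
        return labels, dict(DEFAULT_COMPONENTS)
    labels = [f"IC{i + 1:02d}" for i in range(C)]
    nets = ("DMN", "VN", "SMN", "LFPN", "RFPN", "DAN", "VAN", "AN")
    return labels, {lab: nets[i % len(nets)] for i, lab in enumerate(labels)}


def default_network_blocks(C: int) -> list[list[int]]:
    """Partition of 0..C-1 into network blocks matching the default labels."""
    labels, nmap = _component_labels(C)
    blocks: dict[str, list[int]] = {}
    for idx, lab in enumerate(labels):
        blocks.setdefault(nmap[lab], []).append(idx)
    return list(blocks.values())


def simulate_subject(spec: CohortSpec, states: list[StateSpec], group: str,
                     subject_seed, subject_id: str | None = None
                     ) -> tuple[ComponentTimecourses, np.ndarray]:
    """One subject's time courses plus the hidden state path (length T).

    The state path is sampled from the group's Markov chain started at its
    stationary distribution; observations are Gaussian draws from the
    current state's covariance, optionally AR(1)-smoothed.
    """
    if group not in ("PACG", "HC"):
        raise ValueError("group must be 'PACG' or 'HC'")
    P = (spec.transition_matrix_patient if group == "PACG"
         else spec.transition_matrix_control)
    rng = np.random.default_rng(subject_seed)
    k = spec.k_states
    T, C = spec.n_timepoints, spec.n_components
    pi = stationary_distribution(P)
    cum = P.cumsum(axis=1)
    u = rng.random(T)
    path = np.empty(T, dtype=int)
    path[0] = np.searchsorted(pi.cumsum(), u[0]) + 1
    for t in range(1, T):
        path[t] = np.searchsorted(cum[path[t - 1] - 1], u[t]) + 1
    chols = {st.state_id: np.linalg.cholesky(st.covariance) for st in states}
    innov = rng.standard_normal((T, C))
    data = np.empty((T, C))
    for sid_state, L in chols.items():
        idx = path == sid_state
        if idx.any():
            data[idx] = innov[idx] @ L.T
    phi = spec.ar_coefficient
    if phi > 0:
        scale = np.sqrt(1.0 - phi ** 2)
        prev = np.zeros(C)
        for t in range(T):
            data[t] = phi * prev + scale * data[t]
            prev = data[t]
    labels, nmap = _component_labels(C)
    tc = ComponentTimecourses(
        subject_id=subject_id or "sub", data=data, tr_seconds=spec.tr_seconds,
        component_labels=labels, network_map=nmap)
    return tc, path


def window_states(path: np.ndarray, window_length: int, step: int = 1,
                  weights: np.ndarray | None = None) -> np.ndarray:
    """True state per sliding window.

    With ``weights`` (e.g. the analysis taper), the label is the state with
    the largest weighted occupancy inside the window — the state that
    window's connectivity estimate mostly reflects; without weights, the
    hidden state at the window center.
    """
    T = path.size
    starts = np.arange(0, T - window_length + 1, step)
    if weights is None:
        return path[starts + window_length // 2]
    w = np.asarray(weights, float)
    if w.size != window_length:
        raise ValueError("weights length must equal window_length")
    k = int(path.max())
    out = np.empty(starts.size, dtype=int)
    onehot = np.zeros((T, k))
    onehot[np.arange(T), path - 1] = 1.0
    for i, s in enumerate(starts):
        out[i] = int(np.argmax(w @ onehot[s:s + window_length])) + 1
    return out


def _copula_reorder(values: np.ndarray, attribute: np.ndarray, rho: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Reorder ``values`` so their ranks correlate ~rho with ``attribute``.

    Gaussian copula: latent z2 = rho*z1 + sqrt(1-rho^2)*noise where z1 is
    the normal score of the attribute's rank; the sorted marginal values
    are then assigned in the rank order of z2, leaving marginals intact.
    """
    n = values.size
    ranks = sps.rankdata(attribute, method="average")
    z1 = sps.norm.ppf(ranks / (n + 1))
    z2 = rho * z1 + np.sqrt(max(0.0, 1 - rho ** 2)) * rng.standard_normal(n)
    ranks = np.argsort(np.argsort(z2))  # 0-based rank of each latent score
    return np.sort(values)[ranks]


def _attribute_vector(attr: str, metrics: list[TemporalMetrics]) -> np.ndarray:
    if attr == "n_transitions":
        return np.array([float(m.n_transitions) for m in metrics])
    kind, _, state = attr.partition("_state")
    j = int(state) - 1
    if kind == "fraction":
        return np.array([m.fraction_of_time[j] for m in metrics])
    if kind == "dwell":
        return np.array([m.mean_dwell[j] for m in metrics])
    raise ValueError(f"unknown coupling attribute: {attr!r}")


def simulate_cohort(spec: CohortSpec, states: list[StateSpec] | None = None
                    ) -> tuple[list[ComponentTimecourses], pd.DataFrame, GroundTruth]:
    """Generate a full cohort: time courses, clinical table, ground truth.

    Patients come first (``P001``...), controls after (``C001``...).  The
    clinical table reproduces the configured group marginals exactly in
    distribution; requested couplings are planted within the patient group
    by copula rank reordering against the true connectivity attribute.
    """
    if states is None:
        states = make_state_covariances(
            spec.n_components, spec.k_states,
            default_network_blocks(spec.n_components),
            within_strength=spec.within_strength,
            between_strength=spec.between_strength,
            seed=spec.seed)
    tcs: list[ComponentTimecourses] = []
    paths: dict[str, np.ndarray] = {}
    truths: dict[str, TemporalMetrics] = {}
    roster = ([("PACG", f"P{i + 1:03d}") for i in range(spec.n_patients)]
              + [("HC", f"C{i + 1:03d}") for i in range(spec.n_controls)])
    for idx, (group, sid) in enumerate(roster):
        sseed = np.random.SeedSequence([spec.seed, 1, idx])
        tc, path = simulate_subject(spec, states, group, sseed, subject_id=sid)
        tcs.append(tc)
        paths[sid] = path
        truths[sid] = compute_metrics(sid, path, spec.k_states)

    clinical = _simulate_clinical(spec, roster, truths)
    pi_p = stationary_distribution(spec.transition_matrix_patient)
    pi_c = stationary_distribution(spec.transition_matrix_control)
    effects = {f"occupancy_diff_state{j + 1}": float(pi_p[j] - pi_c[j])
               for j in range(spec.k_states)}
    gt = GroundTruth(state_sequences=paths, true_metrics=truths,
                     group_effects=effects, seed=spec.seed)
    return tcs, clinical, gt


def _simulate_clinical(spec: CohortSpec, roster, truths) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    rows = []
    for group, sid in roster:
        marg = CLINICAL_MARGINALS[group]
        row = {"subject_id": sid, "group": group}
        for var, (mu, sd) in marg.items():
            row[var] = rng.normal(mu, sd)
        row["education"] = max(0.0, row["education"])
        row["VA"] = max(0.01, row["VA"])
        rows.append(row)
    df = pd.DataFrame(rows)
    # sex: male fractions matched to the emulated cohort (16/34 and 16/33)
    for group, frac in (("PACG", 16 / 34), ("HC", 16 / 33)):
        idx = df.index[df["group"] == group]
        n_male = int(round(len(idx) * frac))
        sexes = np.array(["M"] * n_male + ["F"] * (len(idx) - n_male))
        rng.shuffle(sexes)
        df.loc[idx, "sex"] = sexes
    # disease duration: heavy-tailed lognormal for patients only, matched to
    # a median of ~0.49 y and IQR 0.08-2.25 y, clipped at 20 y
    pat_idx = df.index[df["group"] == "PACG"]
    mu, sigma = np.log(0.49), np.log(2.25 / 0.08) / (2 * 0.6745)
    df["duration"] = np.nan
    df.loc[pat_idx, "duration"] = np.minimum(
        rng.lognormal(mu, sigma, size=len(pat_idx)), 20.0)
    # plant requested clinical couplings within the patient group
    pat_ids = [sid for g, sid in roster if g == "PACG"]
    pat_metrics = [truths[sid] for sid in pat_ids]
    for var, attr, rho in spec.clinical_coupling:
        if rho == 0 or not pat_ids:
            continue
        if "_state" in attr and int(attr.rpartition("_state")[2]) > spec.k_states:
            log.warning("coupling %s -> %s skipped: state beyond k=%d",
                        var, attr, spec.k_states)
            continue
        target = _attribute_vector(attr, pat_metrics)
        vals = df.loc[pat_idx, var].to_numpy(float)
        df.loc[pat_idx, var] = _copula_reorder(vals, target, rho, rng)
    return validate_clinical(df)
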
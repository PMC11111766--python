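"""Readers/writers and run configuration.

On-disk dialect (plain text only):

* one TSV per subject under ``timecourses/`` — rows = time, columns =
  components, header = component labels;
* ``network_map.json`` — sidecar with the component->network mapping and
  the TR in seconds;
* ``clinical.csv`` — one row per subject;
* ``ground_truth.json`` — generator truth for synthetic cohorts.

Window indexing is 0-based and half-open (``[s, s+L)``) everywhere.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import ComponentTimecourses, validate_clinical

__all__ = ["RunConfig", "read_timecourses", "write_timecourses",
           "read_cohort", "write_cohort", "read_clinical", "write_clinical"]


@dataclasses.dataclass
class RunConfig:
    """Every tunable of every stage, with the analysis defaults.

    Defaults reproduce the reference analysis settings: 3rd-order detrend,
    robust despike, 0.15 Hz low-pass, a 30-TR window tapered by a
    sigma = 3 TR Gaussian sliding in steps of 1 TR, k = 4 states from
    150 k-means repetitions (cityblock distance, <=500 iterations), and
    BH-FDR at alpha = 0.05.
    """

    # conditioning
    detrend_order: int = 3
    do_detrend: bool = True
    do_despike: bool = True
    despike_z: float = 4.0
    do_lowpass: bool = True
    cutoff_hz: float = 0.15
    # dFNC
    window_width: int = 30
    window_sigma: float = 3.0
    window_step: int = 1
    crop_to_width: bool = False
    fisher_windows: bool = True
    k_states: int = 4
    kmeans_reps: int = 150
    kmeans_max_iter: int = 500
    # statistics
    fdr_alpha: float = 0.05
    dwell_absent_policy: str = "zero"
    covariates: tuple = ("age", "sex", "education")
    # reproducibility
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(d["covariates"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_timecourses(tc: ComponentTimecourses, path: str | Path) -> None:
    """Write one subject's time x component matrix as headered TSV."""
    df = pd.DataFrame(tc.data, columns=tc.component_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_timecourses(path: str | Path, network_map: dict[str, str],
                     tr_seconds: float,
                     subject_id: str | None = None) -> ComponentTimecourses:
    """Read a subject TSV; errors name the offending row/column."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path.name}: malformed TSV ({exc})") from exc
    for col in df.columns:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"{path.name}: non-numeric cell at row {bad[0] + 2}, "
                f"column {col!r}")
    unmapped = [c for c in df.columns if c not in network_map]
    if unmapped:
        raise ValueError(f"{path.name}: components without a network "
                         f"mapping: {unmapped}")
    return ComponentTimecourses(
        subject_id=subject_id or path.stem, data=df.to_numpy(float),
        tr_seconds=tr_seconds, component_labels=list(df.columns),
        network_map=network_map)


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    return validate_clinical(pd.read_csv(path))


def write_cohort(out_dir: str | Path, tcs, clinical, ground_truth=None) -> None:
    """Write a cohort directory: subject TSVs, sidecar, clinical, truth."""
    out = Path(out_dir)
    (out / "timecourses").mkdir(parents=True, exist_ok=True)
    for tc in tcs:
        write_timecourses(tc, out / "timecourses" / f"{tc.subject_id}.tsv")
    sidecar = {"tr_seconds": tcs[0].tr_seconds,
               "network_map": tcs[0].network_map}
    (out / "network_map.json").write_text(json.dumps(sidecar, indent=2))
    write_clinical(clinical, out / "clinical.csv")
    if ground_truth is not None:
        payload = {
            "seed": ground_truth.seed,
            "group_effects": ground_truth.group_effects,
            "state_sequences": {sid: seq.tolist()
                                for sid, seq in ground_truth.state_sequences.items()},
        }
        (out / "ground_truth.json").write_text(json.dumps(payload))


def read_cohort(in_dir: str | Path) -> tuple[list[ComponentTimecourses], pd.DataFrame]:
    """Read a cohort directory written by :func:`write_cohort`."""
    root = Path(in_dir)
    sidecar = json.loads((root / "network_map.json").read_text())
    clinical = read_clinical(root / "clinical.csv")
    tcs = []
    for sid in clinical["subject_id"]:
        tcs.append(read_timecourses(
            root / "timecourses" / f"{sid}.tsv",
            network_map=sidecar["network_map"],
            tr_seconds=sidecar["tr_seconds"], subject_id=sid))
    return tcs, clinical
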
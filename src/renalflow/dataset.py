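"""Datasheet format, dataset assembly, and patient-grouped splitting.

The datasheet is the study's tabular representation: one row per signal with
``patient_id,label,site,t0001..t1000`` — 1000 velocity values (cm/s) on the
common 0.1–2.5 s grid. Each patient appears at most twice, once per class.

Splitting is patient-grouped by default: the two signals of one patient are
correlated (same session, operator, machine), so both always land on the
same side of the 80/20 split and in the same cross-validation fold. This is
stricter than a signal-level split; a signal-level option is retained for
replication studies.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .digitize import GRID_POINTS, LABELS, ResampledSignal
from .errors import ConfigurationError, DataError

VELOCITY_COLUMNS = [f"t{i:04d}" for i in range(1, GRID_POINTS + 1)]
META_COLUMNS = ["patient_id", "label", "site"]


def signal_id(patient_id: str, label: str) -> str:
    """Unique per-signal identifier (a patient has one signal per class)."""
    return f"{patient_id}|{label}"


@dataclass
class Datasheet:
    """Validated wrapper around the one-row-per-signal velocity table."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.frame.columns)
        expected = META_COLUMNS + VELOCITY_COLUMNS
        if cols != expected:
            if len(cols) != len(expected):
                raise DataError(
                    f"datasheet has {len(cols)} columns, expected {len(expected)} "
                    f"({len(VELOCITY_COLUMNS)} velocity columns)"
                )
            raise DataError("datasheet columns do not match the expected schema")
        bad = ~self.frame["label"].isin(LABELS)
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise DataError(f"unknown label {self.frame['label'].iloc[row]!r} at row {row}")
        dup = self.frame.duplicated(subset=["patient_id", "label"])
        if dup.any():
            row = int(np.argmax(dup.to_numpy()))
            raise DataError(
                f"duplicate (patient_id, label) pair at row {row}: "
                f"{self.frame['patient_id'].iloc[row]!r}"
            )
        vel = self.frame[VELOCITY_COLUMNS].to_numpy(dtype=float)
        if not np.all(np.isfinite(vel)):
            raise DataError("non-finite velocity value in datasheet")

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_signals(cls, signals: list[ResampledSignal]) -> "Datasheet":
        rows = {
            "patient_id": [s.patient_id for s in signals],
            "label": [s.label for s in signals],
            "site": [s.site for s in signals],
        }
        vel = np.stack([s.velocities for s in signals])
        frame = pd.DataFrame(rows)
        frame = pd.concat([frame, pd.DataFrame(vel, columns=VELOCITY_COLUMNS)], axis=1)
        return cls(frame=frame)

    def velocities(self) -> np.ndarray:
        """(n_signals, 1000) float array of velocities."""
        return self.frame[VELOCITY_COLUMNS].to_numpy(dtype=float)

    def labels01(self) -> np.ndarray:
        """Binary labels with ARAS (positive class) = 1."""
        return (self.frame["label"] == "ARAS").to_numpy(dtype=int)

    def signal_ids(self) -> list[str]:
        return [
            signal_id(p, l) for p, l in zip(self.frame["patient_id"], self.frame["label"])
        ]

    def patients(self) -> list[str]:
        """Unique patient ids in first-appearance order."""
        return list(dict.fromkeys(self.frame["patient_id"]))

    def subset_by_patients(self, patient_ids) -> "Datasheet":
        wanted = set(patient_ids)
        mask = self.frame["patient_id"].isin(wanted)
        return Datasheet(frame=self.frame.loc[mask].reset_index(drop=True))

    def subset_by_signal_ids(self, ids) -> "Datasheet":
        wanted = set(ids)
        mask = [sid in wanted for sid in self.signal_ids()]
        return Datasheet(frame=self.frame.loc[mask].reset_index(drop=True))

    def checksum(self) -> str:
        """SHA-256 of the serialized rows — used to audit test-set integrity."""
        payload = self.frame.to_csv(index=False).encode()
        return hashlib.sha256(payload).hexdigest()


def write_datasheet(ds: Datasheet, path: str | Path) -> None:
    """Write the datasheet CSV (UTF-8, full-precision decimal velocities)."""
    ds.frame.to_csv(path, index=False)


def load_datasheet(path: str | Path) -> Datasheet:
    """Load and validate a datasheet CSV; the round trip is lossless."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"datasheet file not found: {path}")
    frame = pd.read_csv(path, comment="#", float_precision="round_trip", dtype={"patient_id": str})
    return Datasheet(frame=frame)


@dataclass(frozen=True)
class SplitAssignment:
    """Train/test partition at both the patient and signal level."""

    train_patients: tuple[str, ...]
    test_patients: tuple[str, ...]
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fraction: float

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise DataError("train and test signal ids overlap")
        if set(self.train_patients) & set(self.test_patients):
            raise DataError("a patient appears on both sides of the split")


def split_train_test(
    ds: Datasheet,
    fraction: float = 0.2,
    seed: int = 0,
    group_by_patient: bool = True,
) -> SplitAssignment:
    """80/20-style train/test split, grouped by patient.

    ``fraction`` is the test share of patients (nearest integer count).
    Because every patient contributes one signal per class, grouping
    preserves the exact 50/50 class balance on both sides.
    """
    if not (0 < fraction < 1):
        raise ConfigurationError(f"fraction must lie in (0, 1), got {fraction}")
    patients = ds.patients()
    if len(patients) < 5:
        raise DataError(f"need at least 5 patients to split, got {len(patients)}")
    rng = np.random.default_rng(seed)
    if group_by_patient:
        order = list(np.array(patients)[rng.permutation(len(patients))])
        n_test = int(np.floor(len(patients) * fraction + 0.5))
        test_p = sorted(order[:n_test])
        train_p = sorted(order[n_test:])
        id_map: dict[str, list[str]] = {p: [] for p in patients}
        for sid, pid in zip(ds.signal_ids(), ds.frame["patient_id"]):
            id_map[pid].append(sid)
        train_ids = tuple(sid for p in train_p for sid in id_map[p])
        test_ids = tuple(sid for p in test_p for sid in id_map[p])
    else:
        sids = ds.signal_ids()
        order = [sids[i] for i in rng.permutation(len(sids))]
        n_test = int(np.floor(len(sids) * fraction + 0.5))
        test_ids = tuple(sorted(order[:n_test]))
        train_ids = tuple(sorted(order[n_test:]))
        train_p = sorted({sid.split("|")[0] for sid in train_ids})
        test_p = sorted({sid.split("|")[0] for sid in test_ids})
    return SplitAssignment(
        train_patients=tuple(train_p),
        test_patients=tuple(test_p),
        train_ids=train_ids,
        test_ids=test_ids,
        fraction=fraction,
    )


def make_folds(train_patients, k: int = 5, seed: int = 0) -> list[list[str]]:
    """Partition training patients into ``k`` validation folds.

    Folds are disjoint, cover the training set, and differ in size by at
    most one patient; remainders go to the lowest-indexed folds. Both of a
    patient's signals stay in the same fold.
    """
    if k < 2:
        raise ConfigurationError(f"k must be >= 2, got {k}")
    patients = list(train_patients)
    if len(patients) < k:
        raise DataError(f"need at least k={k} patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    base, rem = divmod(len(order), k)
    folds: list[list[str]] = []
    start = 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        folds.append(sorted(order[start : start + size]))
        start += size
    return folds


def fold_signal_ids(ds: Datasheet, fold_patients) -> list[str]:
    """Expand a fold's patient list into its signal ids (datasheet order)."""
    wanted = set(fold_patients)
    return [sid for sid, pid in zip(ds.signal_ids(), ds.frame["patient_id"]) if pid in wanted]


def write_split(split: SplitAssignment, path: str | Path, provenance: str = "") -> None:
    """Serialize a split as an audit CSV (signal_id, role)."""
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        fh.write("signal_id,role\n")
        for sid in split.train_ids:
            fh.write(f"{sid},train\n")
        for sid in split.test_ids:
            fh.write(f"{sid},test\n")


def load_split(path: str | Path, fraction: float = 0.2) -> SplitAssignment:
    df = pd.read_csv(path, comment="#")
    train_ids = tuple(df.loc[df["role"] == "train", "signal_id"])
    test_ids = tuple(df.loc[df["role"] == "test", "signal_id"])
    return SplitAssignment(
        train_patients=tuple(sorted({s.split("|")[0] for s in train_ids})),
        test_patients=tuple(sorted({s.split("|")[0] for s in test_ids})),
        train_ids=train_ids,
        test_ids=test_ids,
        fraction=fraction,
    )
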
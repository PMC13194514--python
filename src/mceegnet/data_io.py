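"""Typed containers and on-disk formats for subject metadata and epoched EEG.

The package works with three in-memory containers:

* :class:`SubjectRecord` — one row of a cohort metadata table (diagnostic
  group, sex, PHQ-9 severity score 0–27).
* :class:`EpochSet` — the cue-locked epochs of one subject under one
  emotional cue condition, shaped ``[trials, channels, samples]`` in
  microvolts.
* :class:`CueTripletBatch` — aligned (happy, fear, sad) epoch triplets: the
  unit of input consumed by the three-branch network.

On disk, epochs live either in a self-describing HDF5 container (datasets
``data``; attrs ``fs``, ``cue``, ``subject_id``, ``t0``) or in EEGLAB
epoched ``.set`` files (read-only, via :mod:`mne`). Metadata tables are
CSV/TSV with case-insensitive headers ``id``, ``type``, ``gender``,
``PHQ-9``. The 53-subject metadata table of the MODMA dot-probe dataset is
packaged as ``data/modma_subjects.csv`` and used as the canonical test
input for metadata operations.

Channels are positional indices ``0..C-1``; montages are not modelled.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "Sex",
    "Cue",
    "SubjectRecord",
    "EpochSet",
    "CueTripletBatch",
    "SchemaError",
    "ValidationError",
    "FormatError",
    "load_subject_table",
    "packaged_subject_table",
    "load_epochs",
    "save_epochs",
    "concatenate_triplets",
]

PHQ9_MIN, PHQ9_MAX = 0, 27


class SchemaError(ValueError):
    """A tabular input is missing a required column."""


class ValidationError(ValueError):
    """An input violates a container invariant."""


class FormatError(ValueError):
    """An on-disk format is unknown or malformed."""


class Group(str, Enum):
    MDD = "MDD"
    HC = "HC"

    @property
    def label(self) -> int:
        """Class label: healthy controls are 0, depressed patients 1."""
        return 0 if self is Group.HC else 1


class Sex(str, Enum):
    F = "F"
    M = "M"


class Cue(str, Enum):
    """The three dot-probe cue conditions: happy-, fear-, sad-neutral pairs."""

    hcue = "hcue"
    fcue = "fcue"
    scue = "scue"


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: int
    group: Group
    sex: Sex
    phq9: int

    def __post_init__(self) -> None:
        if self.subject_id <= 0:
            raise ValidationError(f"subject_id must be positive, got {self.subject_id}")
        if not (PHQ9_MIN <= self.phq9 <= PHQ9_MAX):
            raise ValidationError(
                f"subject {self.subject_id}: PHQ-9 score {self.phq9} outside "
                f"[{PHQ9_MIN}, {PHQ9_MAX}]"
            )

    @property
    def label(self) -> int:
        return self.group.label


@dataclass
class EpochSet:
    """Cue-locked epochs for one subject and one cue condition.

    data : float array [n_trials, n_channels, n_samples], microvolts
    fs : sampling rate in Hz
    cue : which cue condition the epochs are locked to
    subject_id : owning subject
    t0 : epoch start in seconds relative to the event (negative = pre-stimulus)
    """

    data: np.ndarray
    fs: float
    cue: Cue
    subject_id: int
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(
                f"epoch data must be [trials, channels, samples], got ndim={self.data.ndim}"
            )
        self.cue = Cue(self.cue)
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("epoch data contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the event."""
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class CueTripletBatch:
    """Aligned (happy, fear, sad) epoch triplets forming model input samples.

    Each of the three arrays is [n, C, T]; triplet i pairs the i-th trial of
    each cue for one subject. ``labels_class`` holds 0 (HC) / 1 (MDD);
    ``labels_score`` the PHQ-9 regression target (may be on the raw 0–27
    scale or normalized — the training code tracks which).
    """

    x_happy: np.ndarray
    x_fear: np.ndarray
    x_sad: np.ndarray
    labels_class: np.ndarray
    labels_score: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.x_happy, self.x_fear, self.x_sad)}
        if len(shapes) != 1:
            raise ValidationError(f"cue arrays differ in shape: {sorted(shapes)}")
        n = self.x_happy.shape[0]
        for name in ("labels_class", "labels_score", "subject_ids"):
            v = np.asarray(getattr(self, name))
            if v.shape != (n,):
                raise ValidationError(f"{name} must have length {n}, got {v.shape}")
            setattr(self, name, v)

    @property
    def n(self) -> int:
        return self.x_happy.shape[0]

    def subset(self, idx: np.ndarray) -> "CueTripletBatch":
        return CueTripletBatch(
            self.x_happy[idx], self.x_fear[idx], self.x_sad[idx],
            self.labels_class[idx], self.labels_score[idx], self.subject_ids[idx],
        )


def concatenate_triplets(batches: Sequence[CueTripletBatch]) -> CueTripletBatch:
    """Stack several triplet batches (e.g. all training subjects of a fold)."""
    if not batches:
        raise ValidationError("cannot concatenate zero batches")
    return CueTripletBatch(
        np.concatenate([b.x_happy for b in batches]),
        np.concatenate([b.x_fear for b in batches]),
        np.concatenate([b.x_sad for b in batches]),
        np.concatenate([b.labels_class for b in batches]),
        np.concatenate([b.labels_score for b in batches]),
        np.concatenate([b.subject_ids for b in batches]),
    )


# ---------------------------------------------------------------------------
# Subject metadata tables
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = {"id", "type", "gender", "phq-9"}


def load_subject_table(path: str | Path, format: str = "csv") -> list[SubjectRecord]:
    """Read a subject metadata table (CSV or TSV) into records.

    Columns ``id``, ``type`` (MDD/HC), ``gender`` (F/M) and ``PHQ-9`` are
    matched case-insensitively; row order is preserved and every row is
    validated against the PHQ-9 scale bounds.
    """
    path = Path(path)
    if format not in ("csv", "tsv"):
        raise FormatError(f"unknown table format {format!r} (expected csv or tsv)")
    df = pd.read_csv(path, sep="," if format == "csv" else "\t")
    colmap = {c.strip().lower(): c for c in df.columns}
    missing = _REQUIRED_COLUMNS - set(colmap)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                SubjectRecord(
                    subject_id=int(row[colmap["id"]]),
                    group=Group(str(row[colmap["type"]]).strip().upper()),
                    sex=Sex(str(row[colmap["gender"]]).strip().upper()),
                    phq9=int(row[colmap["phq-9"]]),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
    return records


def packaged_subject_table() -> list[SubjectRecord]:
    """The packaged 53-subject MODMA cohort metadata table."""
    res = importlib.resources.files("mceegnet.data") / "modma_subjects.csv"
    with importlib.resources.as_file(res) as p:
        return load_subject_table(p, "csv")


# ---------------------------------------------------------------------------
# Epoched EEG containers
# ---------------------------------------------------------------------------

def save_epochs(es: EpochSet, path: str | Path, format: str = "hdf5") -> None:
    """Write an :class:`EpochSet` to disk (HDF5; data stored float32)."""
    if format != "hdf5":
        raise FormatError(f"unsupported write format {format!r} (only hdf5 writes)")
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=es.data.astype(np.float32))
        d.attrs["units"] = "uV"
        f.attrs["fs"] = float(es.fs)
        f.attrs["cue"] = es.cue.value
        f.attrs["subject_id"] = int(es.subject_id)
        f.attrs["t0"] = float(es.t0)


def load_epochs(path: str | Path, format: str = "hdf5", cue: Cue | str | None = None) -> EpochSet:
    """Read epoched EEG from HDF5 or an EEGLAB epoched ``.set`` file.

    Data are returned as [trials, channels, samples] regardless of on-disk
    layout. For ``.set`` files (which carry no cue/subject attributes) pass
    ``cue`` explicitly; the subject id defaults to 0.
    """
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            if "data" not in f:
                raise FormatError(f"{path}: no 'data' dataset")
            data = f["data"][()]
            if data.ndim != 3:
                raise ValidationError(f"{path}: data must be 3-D, got {data.shape}")
            return EpochSet(
                data=data,
                fs=float(f.attrs["fs"]),
                cue=Cue(str(f.attrs["cue"])),
                subject_id=int(f.attrs["subject_id"]),
                t0=float(f.attrs["t0"]),
            )
    if format == "eeglab_set":
        import mne

        epochs = mne.io.read_epochs_eeglab(str(path), verbose="error")
        data = epochs.get_data(copy=True) * 1e6  # mne uses Volts; we keep microvolts
        return EpochSet(
            data=data,
            fs=float(epochs.info["sfreq"]),
            cue=Cue(cue) if cue is not None else Cue.hcue,
            subject_id=0,
            t0=float(epochs.tmin),
        )
    raise FormatError(f"unknown epoch format {format!r} (expected hdf5 or eeglab_set)")


def write_synthetic_eeglab_set(es: EpochSet, path: str | Path) -> None:
    """Write a minimal synthetic EEGLAB epoched ``.set`` file (test fixture).

    Produces the classic MAT dialect with just enough of the EEG struct
    (data, srate, chanlocs, per-epoch events) for standard readers. Intended
    for round-trip tests of :func:`load_epochs`, not for EEGLAB workflows.
    """
    import scipy.io as sio

    n_tr, n_ch, n_pt = es.data.shape
    chanlocs = np.zeros((n_ch,), dtype=[("labels", object), ("X", object),
                                        ("Y", object), ("Z", object)])
    for i in range(n_ch):
        chanlocs[i] = (f"E{i + 1}", [], [], [])
    event = np.zeros((n_tr,), dtype=[("type", object), ("latency", object),
                                     ("epoch", object)])
    epoch = np.zeros((n_tr,), dtype=[("event", object), ("eventtype", object),
                                     ("eventlatency", object)])
    lock = int(round(-es.t0 * es.fs))  # sample index of the event within the epoch
    for i in range(n_tr):
        event[i] = (es.cue.value, i * n_pt + lock + 1, i + 1)
        epoch[i] = (i + 1, es.cue.value, 0.0)
    eeg = dict(
        data=es.data.astype(np.float32).transpose(1, 2, 0),  # (nbchan, pnts, trials)
        srate=float(es.fs), nbchan=float(n_ch), pnts=float(n_pt),
        trials=float(n_tr), xmin=float(es.t0),
        xmax=float(es.t0 + (n_pt - 1) / es.fs),
        setname="synthetic", chanlocs=chanlocs, event=event, epoch=epoch,
        icawinv=[], icasphere=[], icaweights=[], icaact=[],
        times=np.arange(n_pt) / es.fs + es.t0, ref="averef",
    )
    sio.savemat(str(path), dict(EEG=eeg), appendmat=False)
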
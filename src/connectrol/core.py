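"""Data model and I/O for parcellations, connectomes and subject manifests.

A structural connectome is a symmetric, non-negative, zero-diagonal weighted
adjacency matrix over an anatomical parcellation.  Edge weights are
tractography streamline counts; no thresholding is applied anywhere in this
package.  All downstream metrics require the validation contract enforced
here: symmetry, zero diagonal, non-negativity and a single connected
component.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

SYMMETRY_TOL = 1e-9

HEMISPHERES = ("left", "right", "midline")
PARCEL_CLASSES = ("cortical", "subcortical", "thalamic", "brainstem")
GROUPS = ("control", "resective", "vns")
OUTCOMES = ("seizure_free", "not_seizure_free", "responder", "non_responder", "none")


class ConnectomeError(ValueError):
    """Raised when a connectome file or matrix violates the data contract."""


class ManifestError(ValueError):
    """Raised when a subject manifest row cannot be parsed."""


@dataclass(frozen=True)
class ParcelInfo:
    """One grey-matter parcel: integer id, label, hemisphere and tissue class."""

    id: int
    label: str
    hemisphere: str
    klass: str
    tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if self.klass not in PARCEL_CLASSES:
            raise ValueError(f"unknown parcel class {self.klass!r}")


class Parcellation:
    """Ordered collection of parcels with contiguous 0-based ids.

    Provides vectorised views (hemisphere codes, class masks) used heavily by
    the metric and simulation modules.
    """

    def __init__(self, parcels: Sequence[ParcelInfo]):
        ids = [p.id for p in parcels]
        if ids != list(range(len(parcels))):
            raise ValueError("parcel ids must be contiguous 0..N-1 in order")
        self.parcels: tuple[ParcelInfo, ...] = tuple(parcels)
        self.hemisphere = np.array([p.hemisphere for p in parcels])
        self.klass = np.array([p.klass for p in parcels])

    def __len__(self) -> int:
        return len(self.parcels)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Parcellation) and self.parcels == other.parcels

    @property
    def n_parcels(self) -> int:
        return len(self.parcels)

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.parcels]

    def mask(self, klass: str | None = None, hemisphere: str | None = None,
             tag: str | None = None) -> np.ndarray:
        """Boolean parcel mask filtered by class, hemisphere and/or tag."""
        m = np.ones(len(self), dtype=bool)
        if klass is not None:
            m &= self.klass == klass
        if hemisphere is not None:
            m &= self.hemisphere == hemisphere
        if tag is not None:
            m &= np.array([tag in p.tags for p in self.parcels])
        return m

    @property
    def cortical(self) -> np.ndarray:
        return self.mask(klass="cortical")

    @property
    def thalamic(self) -> np.ndarray:
        return self.mask(klass="thalamic")

    def subset(self, keep: np.ndarray) -> "Parcellation":
        """New parcellation from a boolean keep-mask; ids are renumbered."""
        kept = [p for p, k in zip(self.parcels, keep) if k]
        return Parcellation([
            ParcelInfo(i, p.label, p.hemisphere, p.klass, p.tags)
            for i, p in enumerate(kept)
        ])

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"id": p.id, "label": p.label, "hemisphere": p.hemisphere,
             "class": p.klass, "tags": ";".join(sorted(p.tags))}
            for p in self.parcels
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Parcellation":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        parcels = [
            ParcelInfo(int(r["id"]), str(r["label"]), str(r["hemisphere"]),
                       str(r["class"]),
                       frozenset(t for t in str(r["tags"]).split(";") if t))
            for _, r in df.iterrows()
        ]
        return cls(parcels)


@dataclass
class Connectome:
    """Symmetric non-negative weighted adjacency matrix bound to a parcellation."""

    weights: np.ndarray
    parcellation: Parcellation
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def copy(self) -> "Connectome":
        return Connectome(self.weights.copy(), self.parcellation,
                          self.subject_id, copy.deepcopy(self.meta))

    def upper_triangle(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the strict upper triangle."""
        return np.triu_indices(self.n, k=1)


@dataclass
class ValidationReport:
    passed: bool
    failures: list[dict] = field(default_factory=list)


@dataclass
class SubjectRecord:
    """Manifest row: group membership, demographics, outcome and resection."""

    subject_id: str
    group: str
    age: float
    sex: str
    fsiq_class: str
    outcome: str = "none"
    resected_parcels: frozenset[int] = frozenset()
    connectome_path: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ManifestError(f"unknown group token {self.group!r}")
        if self.outcome not in OUTCOMES:
            raise ManifestError(f"unknown outcome token {self.outcome!r}")
        if self.resected_parcels and self.group != "resective":
            raise ManifestError(
                f"subject {self.subject_id}: resected parcels given for "
                f"non-resective group {self.group!r}")


def validate_connectome(C: Connectome) -> ValidationReport:
    """Check symmetry, zero diagonal, non-negativity and connectedness.

    Reports all violations rather than raising; ``passed`` is true iff the
    failure list is empty.
    """
    W = C.weights
    failures: list[dict] = []
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        return ValidationReport(False, [{"check": "shape", "value": W.shape}])
    asym = np.abs(W - W.T)
    if asym.max() > SYMMETRY_TOL:
        i, j = np.unravel_index(np.argmax(asym), W.shape)
        failures.append({"check": "asymmetry", "indices": (int(i), int(j)),
                         "value": float(asym[i, j])})
    diag = np.abs(np.diag(W))
    if diag.max() > 0:
        failures.append({"check": "nonzero diagonal",
                         "indices": np.nonzero(diag)[0].tolist()})
    if W.min() < 0:
        i, j = np.unravel_index(np.argmin(W), W.shape)
        failures.append({"check": "negative weight", "indices": (int(i), int(j)),
                         "value": float(W[i, j])})
    n_comp, _ = connected_components(csr_matrix(W != 0), directed=False)
    if n_comp != 1:
        failures.append({"check": "disconnected", "value": int(n_comp)})
    return ValidationReport(not failures, failures)


def _read_dense(path: str | Path) -> np.ndarray:
    """Read a dense numeric matrix, accepting headered or headerless CSV/TSV."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    head = pd.read_csv(path, sep=sep, header=None, nrows=1)
    has_header = head.iloc[0].apply(
        lambda v: isinstance(v, str) and not _is_number(v)).any()
    if has_header:
        df = pd.read_csv(path, sep=sep, header=0, index_col=0)
    else:
        df = pd.read_csv(path, sep=sep, header=None)
    return df.to_numpy(dtype=float)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def load_connectome(path: str | Path, parcellation: Parcellation,
                    subject_id: str | None = None) -> Connectome:
    """Read a dense connectivity matrix and enforce the data contract.

    Symmetrises only within an absolute tolerance of 1e-9; forces a nonzero
    diagonal to zero (recorded in ``meta['forced_zero_diagonal']``).
    """
    W = _read_dense(path)
    n = parcellation.n_parcels
    if W.shape != (n, n):
        raise ConnectomeError(
            f"shape error: matrix is {W.shape}, parcellation has {n} parcels")
    if W.min() < 0:
        raise ConnectomeError(f"negative weight: min entry {W.min()}")
    asym = np.abs(W - W.T).max()
    if asym > SYMMETRY_TOL:
        raise ConnectomeError(f"asymmetry error: max |W - W.T| = {asym}")
    W = (W + W.T) / 2.0
    meta: dict = {}
    if np.abs(np.diag(W)).max() > 0:
        meta["forced_zero_diagonal"] = np.nonzero(np.diag(W))[0].tolist()
        np.fill_diagonal(W, 0.0)
    sid = subject_id if subject_id is not None else Path(path).stem
    return Connectome(W, parcellation, sid, meta)


def write_connectome(C: Connectome, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    np.savetxt(path, C.weights, delimiter=sep, fmt="%.12g")


MANIFEST_COLUMNS = ["subject_id", "group", "age", "sex", "fsiq_class",
                    "outcome", "resected_parcels", "connectome_path"]


def load_manifest(path: str | Path,
                  parcellation: Parcellation | None = None) -> list[SubjectRecord]:
    """Parse a subject manifest CSV/TSV into validated records."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ManifestError(f"manifest missing columns: {sorted(missing)}")
    records = []
    for r in df.itertuples(index=False):
        resected = frozenset(int(t) for t in r.resected_parcels.split(";") if t)
        if parcellation is not None:
            bad = [i for i in resected if not 0 <= i < parcellation.n_parcels]
            if bad:
                raise ManifestError(
                    f"subject {r.subject_id}: resected parcel ids out of range: {bad}")
        records.append(SubjectRecord(
            subject_id=r.subject_id, group=r.group, age=float(r.age),
            sex=r.sex, fsiq_class=r.fsiq_class,
            outcome=r.outcome or "none", resected_parcels=resected,
            connectome_path=r.connectome_path))
    return records


def write_manifest(records: Iterable[SubjectRecord], path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    rows = [{
        "subject_id": r.subject_id, "group": r.group, "age": r.age,
        "sex": r.sex, "fsiq_class": r.fsiq_class, "outcome": r.outcome,
        "resected_parcels": ";".join(str(i) for i in sorted(r.resected_parcels)),
        "connectome_path": r.connectome_path,
    } for r in records]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep=sep, index=False)
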
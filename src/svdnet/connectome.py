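"""Structural connectivity matrices from streamline records.

A subject's white-matter network is summarised as a weighted, undirected
graph over a fixed cortical/subcortical parcellation.  The weight of the
edge between two regions is the sum of inverse streamline lengths over
all streamlines terminating in that region pair, multiplied by a
per-subject seed-density scale factor; summing inverse lengths corrects
the linear bias of deterministic tractography toward long fibers.  Edges
weaker than a threshold (conventionally 1, in scaled mm^-1 units) are
pruned as likely false positives.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Parcellation",
    "StreamlineSet",
    "StreamlineRecord",
    "ConnectivityMatrix",
    "DEFAULT_PARCELLATION",
    "build_connectivity_matrix",
    "read_edge_list",
    "write_edge_list",
    "read_parcellation",
    "write_parcellation",
]

# AAL single-subject atlas, cerebrum only (90 regions; cerebellum excluded).
# Left/right homologues interleaved in standard atlas order.
_AAL90_STEMS = [
    "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
    "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri",
    "Frontal_Inf_Orb", "Rolandic_Oper", "Supp_Motor_Area", "Olfactory",
    "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Insula",
    "Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post", "Hippocampus",
    "ParaHippocampal", "Amygdala", "Calcarine", "Cuneus", "Lingual",
    "Occipital_Sup", "Occipital_Mid", "Occipital_Inf", "Fusiform",
    "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
    "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
    "Pallidum", "Thalamus", "Heschl", "Temporal_Sup",
    "Temporal_Pole_Sup", "Temporal_Mid", "Temporal_Pole_Mid",
    "Temporal_Inf",
]
AAL90_LABELS: tuple[str, ...] = tuple(
    f"{stem}_{side}" for stem in _AAL90_STEMS for side in ("L", "R")
)

# Literature-based rich club: bilateral superior frontal gyrus, precuneus,
# superior parietal gyrus and insula.
DEFAULT_RICH_CLUB: tuple[str, ...] = (
    "Frontal_Sup_L", "Frontal_Sup_R",
    "Precuneus_L", "Precuneus_R",
    "Parietal_Sup_L", "Parietal_Sup_R",
    "Insula_L", "Insula_R",
)


@dataclass(frozen=True)
class Parcellation:
    """Ordered region labels plus the a-priori rich-club subset.

    Parameters
    ----------
    labels
        Unique region names; their order fixes the row/column order of
        every connectivity matrix built against this parcellation.
    rich_club_labels
        Subset of ``labels`` designated as rich-club (hub) regions.
    """

    labels: tuple[str, ...]
    rich_club_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "rich_club_labels", tuple(self.rich_club_labels))
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("parcellation labels must be unique")
        missing = set(self.rich_club_labels) - set(self.labels)
        if missing:
            raise ValueError(f"rich-club labels not in parcellation: {sorted(missing)}")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown region label: {label!r}") from None

    @property
    def rich_club_indices(self) -> np.ndarray:
        return np.array([self.labels.index(l) for l in self.rich_club_labels], dtype=int)

    @property
    def rich_club_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_regions, dtype=bool)
        mask[self.rich_club_indices] = True
        return mask


#: 90-region AAL cerebrum parcellation with the 8-node literature rich club.
DEFAULT_PARCELLATION = Parcellation(AAL90_LABELS, DEFAULT_RICH_CLUB)


@dataclass(frozen=True)
class StreamlineRecord:
    region_a: str
    region_b: str
    length_mm: float


@dataclass
class StreamlineSet:
    """Endpoint-pair streamline records for one subject and wave.

    ``scale`` is the per-subject seed-density correction factor (seeds per
    square millimetre are an acquisition property; only the resulting
    constant is carried here, default 1).
    """

    records: list[StreamlineRecord]
    scale: float = 1.0
    subject_id: str = ""
    wave: str = "baseline"

    def __post_init__(self) -> None:
        self.records = [
            r if isinstance(r, StreamlineRecord) else StreamlineRecord(*r)
            for r in self.records
        ]
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        for i, rec in enumerate(self.records):
            if rec.region_a == rec.region_b:
                raise ValueError(f"record {i}: self-loop on region {rec.region_a!r}")
            if not rec.length_mm > 0:
                raise ValueError(
                    f"record {i}: streamline length must be positive, got {rec.length_mm}"
                )


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative weighted adjacency over a parcellation.

    ``weights[i, j]`` holds the (scaled) sum of inverse streamline lengths
    between regions i and j, in mm^-1; the diagonal is zero and every
    surviving weight is at least ``threshold_applied``.
    """

    weights: np.ndarray
    parcellation: Parcellation
    threshold_applied: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = self.parcellation.n_regions
        if w.shape != (n, n):
            raise ValueError(f"weights shape {w.shape} != ({n}, {n})")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.parcellation.n_regions

    def edge_count(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def copy(self) -> "ConnectivityMatrix":
        return ConnectivityMatrix(
            self.weights.copy(), self.parcellation, self.threshold_applied
        )


def build_connectivity_matrix(
    streamlines: StreamlineSet,
    parcellation: Parcellation,
    threshold: float = 1.0,
) -> ConnectivityMatrix:
    """Aggregate streamline records into a thresholded weighted matrix.

    The weight of region pair (i, j) is ``scale * sum(1/length)`` over all
    records joining i and j.  Weights below ``threshold`` are set to zero
    afterwards; pass ``threshold=0`` for the raw matrix.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be nonnegative, got {threshold}")
    n = parcellation.n_regions
    index = {label: i for i, label in enumerate(parcellation.labels)}
    w = np.zeros((n, n), dtype=float)
    for k, rec in enumerate(streamlines.records):
        try:
            i, j = index[rec.region_a], index[rec.region_b]
        except KeyError as exc:
            raise ValueError(
                f"record {k}: unknown region label {exc.args[0]!r}"
            ) from None
        w[i, j] += 1.0 / rec.length_mm
        w[j, i] += 1.0 / rec.length_mm
    w *= streamlines.scale
    w[w < threshold] = 0.0
    return ConnectivityMatrix(w, parcellation, threshold_applied=threshold)


def apply_threshold(matrix: ConnectivityMatrix, threshold: float) -> ConnectivityMatrix:
    """Zero out weights below ``threshold`` (idempotent, monotone)."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    w = matrix.weights.copy()
    w[w < threshold] = 0.0
    return ConnectivityMatrix(
        w, matrix.parcellation, threshold_applied=max(threshold, matrix.threshold_applied)
    )


def write_edge_list(matrix: ConnectivityMatrix, path) -> None:
    """Write a TSV edge list: one row per undirected edge, labels in
    lexicographic order, header ``region_a  region_b  weight``."""
    labels = matrix.parcellation.labels
    iu, ju = np.nonzero(np.triu(matrix.weights, k=1))
    rows = []
    for i, j in zip(iu.tolist(), ju.tolist()):
        a, b = sorted((labels[i], labels[j]))
        rows.append((a, b, matrix.weights[i, j]))
    rows.sort()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["region_a", "region_b", "weight"])
        for a, b, w in rows:
            writer.writerow([a, b, repr(float(w))])


def read_edge_list(path, parcellation: Parcellation) -> ConnectivityMatrix:
    """Read a TSV edge list into a symmetric matrix.

    Unlisted region pairs get weight 0.  A pair listed twice with
    inconsistent weights is an error; duplicated consistent rows are
    accepted.
    """
    n = parcellation.n_regions
    index = {label: i for i, label in enumerate(parcellation.labels)}
    w = np.zeros((n, n), dtype=float)
    seen: dict[tuple[int, int], float] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != ["region_a", "region_b", "weight"]:
            raise ValueError(f"{path}: expected header 'region_a\\tregion_b\\tweight'")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise ValueError(f"{path}:{lineno}: malformed row {row!r}")
            a, b, wt_str = row[0], row[1], row[2]
            try:
                wt = float(wt_str)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric weight {wt_str!r}") from None
            if a not in index:
                raise ValueError(f"{path}:{lineno}: unknown region label {a!r}")
            if b not in index:
                raise ValueError(f"{path}:{lineno}: unknown region label {b!r}")
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-loop on {a!r}")
            if wt < 0:
                raise ValueError(f"{path}:{lineno}: negative weight {wt}")
            i, j = sorted((index[a], index[b]))
            if (i, j) in seen and seen[(i, j)] != wt:
                raise ValueError(
                    f"{path}:{lineno}: inconsistent duplicate edge "
                    f"({a}, {b}): {seen[(i, j)]} vs {wt}"
                )
            seen[(i, j)] = wt
            w[i, j] = w[j, i] = wt
    return ConnectivityMatrix(w, parcellation)


def write_parcellation(parcellation: Parcellation, path) -> None:
    """Write a parcellation as a two-column CSV (label, rich_club 0/1)."""
    rich = set(parcellation.rich_club_labels)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["label", "rich_club"])
        for label in parcellation.labels:
            writer.writerow([label, int(label in rich)])


def read_parcellation(path) -> Parcellation:
    """Read a two-column CSV (label, rich_club 0/1) parcellation."""
    labels: list[str] = []
    rich: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["label", "rich_club"]:
            raise ValueError(f"{path}: expected header 'label,rich_club'")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: malformed row {row!r}")
            labels.append(row[0])
            if row[1].strip() not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: rich_club flag must be 0 or 1")
            if row[1].strip() == "1":
                rich.append(row[0])
    return Parcellation(tuple(labels), tuple(rich))
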
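"""Audit external LRR motif predictions against the winding profile.

If a list of predicted repeat-motif start residues R_1 < ... < R_k is
consistent with the solenoid geometry, the structure winds exactly once
around its core between consecutive starts, so the running differences
w(R_j) - w(R_{j-1}) should all equal 1.  The discrepancy

    D(R_1, ..., R_k) = sum_{j=2..k} (w(R_j) - w(R_{j-1}) - 1)^2

quantifies departure from that ideal: duplicated predictions push a
difference toward 0, missed repeats push one toward 2, and both inflate D.
Differences below 0.5 are flagged as duplicates, above 1.5 as missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .geometry import WindingProfile
from .structure_io import ResidueLabel

logger = logging.getLogger(__name__)

DUPLICATE_THRESHOLD = 0.5
MISSING_THRESHOLD = 1.5


@dataclass(frozen=True)
class MotifTable:
    """Ordered start residues of predicted LxxLxL motifs (author numbering)."""

    starts: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.starts, dtype=int)
        object.__setattr__(self, "starts", arr)
        if arr.ndim != 1:
            raise ValueError("starts must be one-dimensional")
        if np.any(np.diff(arr) < 0):
            raise ValueError("starts must be sorted")

    def __len__(self) -> int:
        return len(self.starts)


@dataclass(frozen=True)
class DiscrepancyReport:
    """Winding values at predicted motif starts and the discrepancy statistic."""

    w_at_starts: np.ndarray
    running_diffs: np.ndarray
    discrepancy: float
    duplicate_flags: tuple[int, ...]  # indices j (into starts) with diff < 0.5
    missing_flags: tuple[int, ...]  # indices j with diff > 1.5

    def to_dict(self) -> dict:
        return {
            "w_at_starts": [float(v) for v in self.w_at_starts],
            "running_diffs": [float(v) for v in self.running_diffs],
            "discrepancy": float(self.discrepancy),
            "duplicate_flags": list(self.duplicate_flags),
            "missing_flags": list(self.missing_flags),
        }


def evaluate_motifs(
    w: WindingProfile | np.ndarray,
    motifs: MotifTable,
    labels: Optional[Sequence[ResidueLabel]] = None,
    duplicate_threshold: float = DUPLICATE_THRESHOLD,
    missing_threshold: float = MISSING_THRESHOLD,
) -> DiscrepancyReport:
    """Score a motif-start table against the winding profile.

    With ``labels`` (the residue labels aligned to the profile) motif starts
    are interpreted as author residue numbers; otherwise they are 0-based
    profile indices.  At least two motifs are required.
    """
    arr = np.asarray(w.w if hasattr(w, "w") else w, dtype=float)
    if len(motifs) < 2:
        raise ValueError("at least two motif starts are needed to form differences")
    if labels is not None:
        lookup = {(lab.number, lab.icode): i for i, lab in enumerate(labels)}
        try:
            idx = np.array([lookup[(int(r), "")] for r in motifs.starts])
        except KeyError as exc:
            raise LookupError(
                f"motif start residue {exc.args[0][0]} not present in the structure"
            ) from exc
    else:
        idx = motifs.starts
        if idx.min() < 0 or idx.max() >= len(arr):
            raise LookupError(
                f"motif index out of range [0, {len(arr) - 1}]: "
                f"{idx.min()}..{idx.max()}"
            )
    w_at = arr[idx]
    diffs = np.diff(w_at)
    discrepancy = float(np.sum((diffs - 1.0) ** 2))
    duplicates = tuple(int(j + 1) for j in np.nonzero(diffs < duplicate_threshold)[0])
    missing = tuple(int(j + 1) for j in np.nonzero(diffs > missing_threshold)[0])
    return DiscrepancyReport(
        w_at_starts=w_at,
        running_diffs=diffs,
        discrepancy=discrepancy,
        duplicate_flags=duplicates,
        missing_flags=missing,
    )


def read_motif_table(path: str | Path) -> MotifTable:
    """Read motif start residues from a plain list or TSV (first column).

    Lines starting with ``#`` are skipped; an optional single non-numeric
    header row is tolerated in TSV-style files.  Unsorted inputs are sorted
    with a warning; duplicates are kept (they are exactly what the
    discrepancy statistic must catch).
    """
    path = Path(path)
    values: list[int] = []
    rows = [
        line.strip() for line in path.read_text().splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    for i, row in enumerate(rows):
        token = row.split("\t")[0].split()[0]
        try:
            values.append(int(token))
        except ValueError:
            if i == 0:  # tolerated header row
                continue
            raise ValueError(f"non-numeric motif row {i + 1} in {path}: {row!r}")
    if not values:
        raise ValueError(f"no motif starts found in {path}")
    arr = np.array(values, dtype=int)
    if np.any(np.diff(arr) < 0):
        logger.warning("motif table %s was unsorted; sorting", path)
        arr = np.sort(arr)
    if len(np.unique(arr)) != len(arr):
        logger.warning("motif table %s contains duplicate starts (kept)", path)
    return MotifTable(starts=arr, source=str(path))
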
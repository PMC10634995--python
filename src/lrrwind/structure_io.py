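"""Read protein backbones and write annotation records.

A structure file (PDB or mmCIF) is reduced to its ordered Cα trace — a 3D
space curve, one point per residue — which is all the downstream winding
machinery needs.  Annotations come back out as GFF3, TSV or JSON on the
residue axis (1-based closed intervals, author numbering).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import ChainNotFoundError, StructureFormatError

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("LRR_domain", "repeat_unit", "anomaly_region")


class ResidueLabel(NamedTuple):
    """Author-facing residue identity: chain id, residue number, insertion code."""

    chain: str
    number: int
    icode: str = ""


@dataclass(frozen=True)
class BackboneCurve:
    """Ordered Cα positions of one chain.

    Attributes
    ----------
    points : (n, 3) float array, Å
    residue_labels : tuple of ResidueLabel, parallel to ``points``
    source_id : provenance string (file path, accession, "synthetic:...")
    """

    points: np.ndarray
    residue_labels: tuple[ResidueLabel, ...]
    source_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "residue_labels", tuple(self.residue_labels))
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("backbone coordinates must be finite")
        if len(pts) != len(self.residue_labels):
            raise ValueError("points and residue_labels must have equal length")
        keys = [(lab.number, lab.icode) for lab in self.residue_labels]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValueError("residue labels must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    def index_of(self, number: int, icode: str = "") -> int:
        """Positional index of the residue with the given author number."""
        for i, lab in enumerate(self.residue_labels):
            if lab.number == number and lab.icode == icode:
                return i
        raise ChainNotFoundError(
            f"residue {number}{icode} not found in {self.source_id or 'curve'}"
        )


@dataclass
class AnnotationRecord:
    """One annotated feature on the residue axis (closed interval)."""

    feature_kind: str
    start: ResidueLabel
    end: ResidueLabel
    score: float = 0.0
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        self.start = ResidueLabel(*self.start)
        self.end = ResidueLabel(*self.end)
        if (self.start.number, self.start.icode) > (self.end.number, self.end.icode):
            raise ValueError("feature start must not exceed end")


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc identifier order
    return min(atoms, key=lambda a: (-a.occ, a.altloc))


def _chain_ca_points(chain: gemmi.Chain) -> tuple[list[list[float]], list[ResidueLabel]]:
    points: list[list[float]] = []
    labels: list[ResidueLabel] = []
    for residue in chain:
        if residue.is_water():
            continue
        cas = [a for a in residue if a.name == "CA" and a.element.name == "C"]
        if not cas:
            continue
        atom = _pick_altloc(cas)
        points.append([atom.pos.x, atom.pos.y, atom.pos.z])
        labels.append(
            ResidueLabel(chain.name, residue.seqid.num, residue.seqid.icode.strip())
        )
    return points, labels


def read_backbone(
    path: str | Path,
    chain: str = "auto",
    *,
    min_length: int | None = None,
) -> BackboneCurve:
    """Read the Cα trace of one chain from a PDB or mmCIF file.

    ``chain="auto"`` selects the first chain that carries Cα atoms.  Altlocs
    keep the highest-occupancy conformer (ties by altloc id).  Residue-number
    gaps are kept contiguous in array space and logged as warnings.  Passing
    ``min_length`` (e.g. 50 for LRR annotation) turns short traces into a
    validation error.
    """
    path = Path(path)
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(structure) == 0:
        raise StructureFormatError(f"{path} contains no models")
    model = structure[0]

    selected = None
    if chain == "auto":
        for ch in model:
            pts, labs = _chain_ca_points(ch)
            if pts:
                selected = (ch.name, pts, labs)
                break
        if selected is None:
            raise StructureFormatError(f"{path} contains no Cα atoms")
    else:
        names = [ch.name for ch in model]
        if chain not in names:
            raise ChainNotFoundError(
                f"chain {chain!r} not in {path}; available chains: {names}"
            )
        ch = model[chain]
        pts, labs = _chain_ca_points(ch)
        if not pts:
            raise StructureFormatError(f"chain {chain!r} of {path} has no Cα atoms")
        selected = (chain, pts, labs)

    name, pts, labs = selected
    for a, b in zip(labs, labs[1:]):
        if b.number > a.number + 1:
            logger.warning(
                "residue numbering gap %d -> %d in %s chain %s (curve kept contiguous)",
                a.number, b.number, path.name, name,
            )
    if min_length is not None and len(pts) < min_length:
        raise ValueError(
            f"{path} chain {name}: only {len(pts)} Cα atoms, "
            f"need at least {min_length} for LRR annotation"
        )
    return BackboneCurve(np.array(pts, dtype=float), tuple(labs), source_id=str(path))


# ---------------------------------------------------------------------------
# annotation output


def _gff3_escape(value: str) -> str:
    return (
        str(value)
        .replace("%", "%25")
        .replace(";", "%3B")
        .replace("=", "%3D")
        .replace(",", "%2C")
        .replace("\t", "%09")
        .replace("\n", "%0A")
    )


def _records_frame(records: Sequence[AnnotationRecord]) -> pd.DataFrame:
    rows = [
        {
            "feature_kind": r.feature_kind,
            "chain": r.start.chain,
            "start": r.start.number,
            "start_icode": r.start.icode,
            "end": r.end.number,
            "end_icode": r.end.icode,
            "score": r.score,
            "attributes": json.dumps(r.attributes, sort_keys=True),
        }
        for r in records
    ]
    columns = [
        "feature_kind", "chain", "start", "start_icode",
        "end", "end_icode", "score", "attributes",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_annotations(
    records: Sequence[AnnotationRecord],
    path: str | Path,
    format: str = "GFF3",
) -> None:
    """Write annotation records as GFF3, TSV or JSON.

    GFF3 uses 1-based closed intervals on the residue axis (columns 4-5 are
    author residue numbers).  TSV and JSON round-trip losslessly through
    :func:`read_annotations`.
    """
    path = Path(path)
    fmt = format.upper()
    if fmt == "GFF3":
        lines = ["##gff-version 3"]
        for i, r in enumerate(records):
            attrs = {"ID": f"{r.feature_kind}_{i}", **r.attributes}
            attr_str = ";".join(
                f"{_gff3_escape(k)}={_gff3_escape(v)}" for k, v in attrs.items()
            )
            lines.append(
                "\t".join(
                    [
                        r.start.chain or ".",
                        "lrrwind",
                        r.feature_kind,
                        str(r.start.number),
                        str(r.end.number),
                        f"{r.score:.6g}",
                        ".",
                        ".",
                        attr_str,
                    ]
                )
            )
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "TSV":
        _records_frame(records).to_csv(path, sep="\t", index=False)
    elif fmt == "JSON":
        payload = [
            {
                "feature_kind": r.feature_kind,
                "start": list(r.start),
                "end": list(r.end),
                "score": r.score,
                "attributes": r.attributes,
            }
            for r in records
        ]
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise ValueError(f"unknown annotation format {format!r}")


def read_annotations(path: str | Path, format: str) -> list[AnnotationRecord]:
    """Read back TSV or JSON annotation files written by :func:`write_annotations`."""
    path = Path(path)
    fmt = format.upper()
    if fmt == "TSV":
        frame = pd.read_csv(
            path, sep="\t", dtype={"start_icode": str, "end_icode": str},
            keep_default_na=False,
        )
        return [
            AnnotationRecord(
                feature_kind=row["feature_kind"],
                start=ResidueLabel(str(row["chain"]), int(row["start"]), row["start_icode"]),
                end=ResidueLabel(str(row["chain"]), int(row["end"]), row["end_icode"]),
                score=float(row["score"]),
                attributes=json.loads(row["attributes"]),
            )
            for _, row in frame.iterrows()
        ]
    if fmt == "JSON":
        payload = json.loads(path.read_text())
        return [
            AnnotationRecord(
                feature_kind=item["feature_kind"],
                start=ResidueLabel(item["start"][0], int(item["start"][1]), item["start"][2]),
                end=ResidueLabel(item["end"][0], int(item["end"][1]), item["end"][2]),
                score=float(item["score"]),
                attributes=item["attributes"],
            )
            for item in payload
        ]
    raise ValueError(f"unknown annotation format {format!r}")
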
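"""Enzyme → (vitamin, role) annotation model and loader.

The synthesis/downstream (S/D) analysis hinges on a curated map from gene
families or EC identifiers to the B vitamin they act on and their role:

* ``S`` — synthesis / upstream of the colonically absorbed vitamin form,
* ``D`` — downstream utilization (the enzyme consumes the vitamin),
* ``T`` — transport.

Roles follow the colonic-absorption convention: the thiamine
pyrophosphokinase that produces TPP counts as upstream because TPP is the
form absorbed in the colon, and the bacterial pantothenate and pyridoxal
kinases are kept upstream because host lumenal phosphatases readily
dephosphorylate their products back to absorbable forms.  The bundled demo
annotation encodes these rules; users supply their full curated table
through :func:`load_annotation`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

VITAMINS = ("B1", "B2", "B3", "B5", "B6", "B7", "B9", "B12")
ROLES = ("S", "D", "T")

_EC_RE = re.compile(r"^EC (?:[0-9]+|-)\.(?:[0-9]+|-)\.(?:[0-9]+|-)\.(?:[0-9n]+|-)$")

REQUIRED_COLUMNS = ["feature_id", "vitamin", "role", "note"]


@dataclass(frozen=True)
class VitaminAnnotationRecord:
    feature_id: str
    vitamin: str
    role: str
    note: str = ""


@dataclass
class VitaminAnnotationTable:
    """Validated collection of annotation records."""

    records: list[VitaminAnnotationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            if not rec.feature_id:
                raise ValueError("empty feature_id")
            if rec.vitamin not in VITAMINS:
                raise ValueError(f"unknown vitamin code {rec.vitamin!r}")
            if rec.role not in ROLES:
                raise ValueError(f"unknown role code {rec.role!r}")
            key = (rec.feature_id, rec.vitamin)
            if key in seen:
                raise ValueError(f"duplicate (feature_id, vitamin) pair {key}")
            seen.add(key)

    @property
    def vitamins_covered(self) -> set[str]:
        return {r.vitamin for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.feature_id, r.vitamin, r.role, r.note) for r in self.records],
            columns=REQUIRED_COLUMNS,
        )

    def by_role(self, vitamin: str, role: str) -> list[str]:
        """Feature IDs annotated (vitamin, role)."""
        return [r.feature_id for r in self.records if r.vitamin == vitamin and r.role == role]

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_annotation(path: str | Path) -> VitaminAnnotationTable:
    """Load and validate an annotation TSV.

    The file must carry the header ``feature_id  vitamin  role  note``
    (tab-separated).  Vitamin codes outside B1–B12, role codes outside
    S/D/T, malformed EC strings, and duplicated (feature_id, vitamin)
    pairs are refused with the offending line numbers (1-based, counting
    the header as line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file missing columns: {missing}")

    errors: list[str] = []
    seen: dict[tuple[str, str], int] = {}
    records: list[VitaminAnnotationRecord] = []
    for i, row in df.iterrows():
        line = int(i) + 2  # header is line 1
        fid, vit, role, note = (row[c].strip() for c in REQUIRED_COLUMNS)
        if not fid:
            errors.append(f"line {line}: empty feature_id")
            continue
        if vit not in VITAMINS:
            errors.append(f"line {line}: unknown vitamin {vit!r}")
            continue
        if role not in ROLES:
            errors.append(f"line {line}: unknown role {role!r}")
            continue
        if fid.startswith("EC ") and not _EC_RE.match(fid):
            errors.append(f"line {line}: malformed EC identifier {fid!r}")
            continue
        key = (fid, vit)
        if key in seen:
            errors.append(f"line {line}: duplicate of line {seen[key]} for {key}")
            continue
        seen[key] = line
        records.append(VitaminAnnotationRecord(fid, vit, role, note))
    if errors:
        raise ValueError("invalid annotation file:\n" + "\n".join(errors))
    return VitaminAnnotationTable(records)


def builtin_demo_annotation() -> VitaminAnnotationTable:
    """Small bundled annotation covering all 8 B vitamins.

    Every vitamin carries at least one S and one D record; B1 and B12 also
    carry T (transport) records.  It encodes the colonic-form rules (TPP
    kinase upstream; pantothenate/pyridoxal kinases upstream) and is the
    default annotation for the synthetic cohort.
    """
    ref = resources.files("fibervit").joinpath("data/demo_annotation.tsv")
    with resources.as_file(ref) as p:
        return load_annotation(p)
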
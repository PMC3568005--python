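"""Canonical data model for binary-mixture property datasets.

A data point is one experimental measurement on a binary liquid mixture: the
two component structures, the molar fraction of the majority component, the
property name, the measured value, its unit, and a provenance string. The
storage convention follows the mixture-upload dialect of online QSPR
databases:

* the first component is always the one with the largest molar fraction, so
  the stored fraction ``x1`` lies in [0.5, 1];
* rows uploaded with a fraction below 0.5 are swapped and the complement to 1
  is stored, which collapses (A, f, B) and (B, 1-f, A) onto one key and makes
  duplicate detection trivial;
* the minority fraction is never stored; it is always ``1 - x1``;
* a pure compound is a degenerate mixture with ``x1 == 1`` and no second
  component.

Structure strings are canonicalized through an injectable backend (default:
RDKit canonical SMILES), so two different SMILES spellings of one compound
compare equal.
"""

from __future__ import annotations

import math
from collections.abc import Callable, Iterable, Mapping
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import (
    AugmentationError,
    ConfigError,
    DomainError,
    IncompleteRecordError,
    SchemaError,
    StructureError,
)

# A canonicalizer maps a structure string to a canonical structure string and
# must be deterministic and idempotent.
Canonicalizer = Callable[[str], str]

#: Default tolerance on molar fractions when matching duplicates; experimental
#: fractions are reported to at most 4 decimals.
FRACTION_TOLERANCE = 1e-6

#: Class labels for the concentration-independent boiling-behavior endpoint.
ZEOTROPE, AZEOTROPE = 0.0, 1.0


def rdkit_canonical_smiles(structure: str) -> str:
    """Canonical SMILES via RDKit. Raises :class:`StructureError` on parse failure."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(structure, sanitize=True)
    if mol is None:
        raise StructureError(f"unparsable SMILES: {structure!r}")
    return Chem.MolToSmiles(mol)


def identity_canonicalizer(structure: str) -> str:
    """Pass-through canonicalizer for opaque compound tokens (synthetic data)."""
    s = structure.strip()
    if not s:
        raise StructureError("empty structure string")
    return s


@dataclass(frozen=True, order=True)
class CompoundRef:
    """A compound identified by its canonical structure string.

    Equality and ordering consider only ``structure``; ``external_id`` and
    ``name`` are display metadata.
    """

    structure: str
    external_id: Optional[str] = field(default=None, compare=False)
    name: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.structure:
            raise StructureError("CompoundRef requires a non-empty structure")


@dataclass(frozen=True)
class MixtureRecord:
    """One experimental data point on a binary mixture (or a pure compound).

    ``x1`` is the molar fraction of ``component1`` and lies in [0.5, 1]; the
    second fraction is derived (``x2 == 1 - x1``) and never stored. A pure
    compound has ``x1 == 1`` and ``component2 is None``.
    """

    component1: CompoundRef
    component2: Optional[CompoundRef]
    x1: float
    property: str
    value: float
    unit: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not (0.5 <= self.x1 <= 1.0):
            raise DomainError(f"x1 must lie in [0.5, 1], got {self.x1}")
        if self.x1 == 1.0:
            if self.component2 is not None:
                raise DomainError("pure record (x1 == 1) must not carry a second component")
        elif self.component2 is None:
            raise IncompleteRecordError("mixture record with x1 < 1 requires a second component")
        if self.x1 == 0.5 and self.component2 is not None:
            if not (self.component1.structure <= self.component2.structure):
                raise DomainError(
                    "equimolar record must order components lexicographically by structure"
                )

    @property
    def x2(self) -> float:
        return 1.0 - self.x1

    @property
    def is_pure(self) -> bool:
        return self.component2 is None

    def pair_key(self) -> tuple[str, ...]:
        """Unordered mixture identity: sorted component structures."""
        if self.component2 is None:
            return (self.component1.structure,)
        return tuple(sorted((self.component1.structure, self.component2.structure)))

    def compounds(self) -> tuple[CompoundRef, ...]:
        if self.component2 is None:
            return (self.component1,)
        return (self.component1, self.component2)


@dataclass
class MixtureDataset:
    """An ordered collection of records sharing one property.

    ``concentration_dependent`` marks endpoints measured across compositions
    (density, bubble temperature: several records per mixture); concentration-
    independent endpoints (azeotrope/zeotrope) carry one record per mixture.
    """

    records: list[MixtureRecord]
    property: str
    endpoint_kind: str = "regression"  # or "classification"
    concentration_dependent: bool = True

    def __post_init__(self) -> None:
        if self.endpoint_kind not in ("regression", "classification"):
            raise ConfigError(f"unknown endpoint_kind: {self.endpoint_kind!r}")
        for r in self.records:
            if r.property != self.property:
                raise ConfigError(
                    f"record property {r.property!r} differs from dataset property "
                    f"{self.property!r}"
                )
        if not self.concentration_dependent:
            seen: dict[tuple[str, ...], int] = {}
            for i, r in enumerate(self.records):
                if r.is_pure:
                    continue
                k = r.pair_key()
                if k in seen:
                    raise ConfigError(
                        f"concentration-independent dataset has two records for pair {k} "
                        f"(rows {seen[k]} and {i})"
                    )
                seen[k] = i

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MixtureDataset):
            return NotImplemented
        return (
            self.records == other.records
            and self.property == other.property
            and self.endpoint_kind == other.endpoint_kind
            and self.concentration_dependent == other.concentration_dependent
        )

    def compounds(self) -> list[CompoundRef]:
        """Distinct compounds in order of first appearance."""
        seen: dict[CompoundRef, None] = {}
        for r in self.records:
            for c in r.compounds():
                seen.setdefault(c, None)
        return list(seen)

    def pairs(self) -> list[tuple[str, ...]]:
        """Distinct unordered pair keys (pure keys included) in first-appearance order."""
        seen: dict[tuple[str, ...], None] = {}
        for r in self.records:
            seen.setdefault(r.pair_key(), None)
        return list(seen)


# ---------------------------------------------------------------------------
# Row canonicalization


def _get(row: Mapping[str, object], *names: str) -> object:
    """Case-insensitive column lookup; empty strings and NaN count as absent."""
    lowered = {str(k).strip().lower(): v for k, v in row.items()}
    for n in names:
        v = lowered.get(n.lower())
        if v is None:
            continue
        if isinstance(v, float) and math.isnan(v):
            continue
        if isinstance(v, str) and not v.strip():
            continue
        return v
    return None


def canonicalize_record(
    raw_row: Mapping[str, object],
    canonicalizer: Canonicalizer = rdkit_canonical_smiles,
) -> MixtureRecord:
    """Turn one upload-dialect row into a canonical :class:`MixtureRecord`.

    The fraction column holds the molar fraction of the first structure as
    uploaded; when it is below 0.5 the components are interchanged and the
    complement to 1 is stored. Equimolar rows (f == 0.5) are ordered by
    lexicographic canonical structure so the stored key is deterministic.
    """
    s1 = _get(raw_row, "SMILES1", "MOL1", "STRUCTURE1")
    if s1 is None:
        raise IncompleteRecordError(f"row lacks a first-component structure: {dict(raw_row)!r}")
    frac = _get(raw_row, "MOLAR_FRACTION", "X1", "FRACTION")
    if frac is None:
        raise IncompleteRecordError(f"row lacks a molar fraction: {dict(raw_row)!r}")
    try:
        f = float(frac)  # type: ignore[arg-type]
    except (TypeError, ValueError) as e:
        raise DomainError(f"molar fraction {frac!r} is not a number") from e
    if not (0.0 < f <= 1.0):
        raise DomainError(f"molar fraction must lie in (0, 1], got {f}")

    raw_value = _get(raw_row, "VALUE")
    if raw_value is None:
        raise IncompleteRecordError(f"row lacks a VALUE: {dict(raw_row)!r}")
    try:
        value = float(raw_value)  # type: ignore[arg-type]
    except (TypeError, ValueError) as e:
        raise DomainError(f"value {raw_value!r} is not a number") from e

    prop = str(_get(raw_row, "PROPERTY") or "")
    unit = str(_get(raw_row, "UNIT") or "")
    source = str(_get(raw_row, "SOURCE") or "")

    c1 = CompoundRef(canonicalizer(str(s1)))

    s2 = _get(raw_row, "SMILES2", "MOL2", "MOLID2", "STRUCTURE2")
    if f == 1.0:
        return MixtureRecord(c1, None, 1.0, prop, value, unit, source)
    if s2 is None:
        raise IncompleteRecordError(
            f"mixture row with fraction {f} < 1 lacks a second component: {dict(raw_row)!r}"
        )
    name2 = _get(raw_row, "NAME2")
    c2 = CompoundRef(canonicalizer(str(s2)), name=str(name2) if name2 is not None else None)

    if f < 0.5 or (f == 0.5 and c2.structure < c1.structure):
        c1, c2 = c2, c1
        f = 1.0 - f
    return MixtureRecord(c1, c2, f, prop, value, unit, source)


# ---------------------------------------------------------------------------
# Duplicate detection


@dataclass(frozen=True)
class DuplicateGroup:
    """A maximal set of mutually duplicated records.

    ``pair`` is the unordered mixture key; ``record_indices`` point into the
    dataset's record list.
    """

    pair: tuple[str, ...]
    record_indices: tuple[int, ...]


def detect_duplicates(
    dataset: MixtureDataset,
    value_tolerance: float = 0.0,
    fraction_tolerance: float = FRACTION_TOLERANCE,
    level: str = "mixture",
) -> list[DuplicateGroup]:
    """Find duplicated measurements in a canonicalized dataset.

    Two records are duplicates when they concern the same unordered component
    pair and property, their majority fractions agree within
    ``fraction_tolerance``, and their values agree within ``value_tolerance``
    (units must match exactly). Groups are maximal under the transitive
    closure of this relation.

    ``level='record'`` returns one group per cluster of matching records;
    ``level='mixture'`` (default) merges all duplicated records of one pair
    into a single group, which matches how duplicate audits are reported (a
    duplicated composition series counts once, not once per composition).
    """
    if level not in ("record", "mixture"):
        raise ConfigError(f"unknown duplicate level: {level!r}")

    buckets: dict[tuple[tuple[str, ...], str], list[int]] = {}
    for i, r in enumerate(dataset.records):
        buckets.setdefault((r.pair_key(), r.property), []).append(i)

    parent: dict[int, int] = {}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for idxs in buckets.values():
        for i in idxs:
            parent[i] = i
        for a_pos, i in enumerate(idxs):
            ri = dataset.records[i]
            for j in idxs[a_pos + 1 :]:
                rj = dataset.records[j]
                if ri.unit != rj.unit:
                    raise ConfigError(
                        f"records of pair {ri.pair_key()} carry mismatched units "
                        f"({ri.unit!r} vs {rj.unit!r}); convert before deduplication"
                    )
                if (
                    abs(ri.x1 - rj.x1) <= fraction_tolerance
                    and abs(ri.value - rj.value) <= value_tolerance
                ):
                    union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in parent:
        clusters.setdefault(find(i), []).append(i)

    groups: list[DuplicateGroup] = []
    if level == "record":
        for members in clusters.values():
            if len(members) >= 2:
                members.sort()
                groups.append(
                    DuplicateGroup(dataset.records[members[0]].pair_key(), tuple(members))
                )
    else:
        by_pair: dict[tuple[str, ...], list[int]] = {}
        for members in clusters.values():
            if len(members) >= 2:
                key = dataset.records[members[0]].pair_key()
                by_pair.setdefault(key, []).extend(members)
        for key, members in by_pair.items():
            members.sort()
            groups.append(DuplicateGroup(key, tuple(members)))
    groups.sort(key=lambda g: g.record_indices)
    return groups


# ---------------------------------------------------------------------------
# Pure-compound augmentation


def augment_with_pure_compounds(
    dataset: MixtureDataset,
    pure_values: Mapping[CompoundRef, float] | str | None = None,
) -> MixtureDataset:
    """Ensure every compound of the dataset also appears as a pure (x1 = 1) record.

    Mixture QSPR training requires each constituent to be present on its own at
    least once so descriptor calculation and compounds-out grouping are well
    defined. ``pure_values`` is either a mapping compound -> pure property
    value (regression) or the string policy ``'zeotrope'`` (classification:
    pure compounds cannot form an azeotrope with themselves, so they receive
    the zeotrope label). Idempotent: compounds already present as pure records
    are left untouched.
    """
    present = {r.component1 for r in dataset.records if r.is_pure}
    missing = [c for c in dataset.compounds() if c not in present]
    if not missing:
        return dataset

    added: list[MixtureRecord] = []
    if pure_values == "zeotrope":
        if dataset.endpoint_kind != "classification":
            raise AugmentationError("the zeotrope policy applies to classification datasets only")
        for c in missing:
            added.append(MixtureRecord(c, None, 1.0, dataset.property, ZEOTROPE))
    else:
        if pure_values is None:
            pure_values = {}
        unknown = [c for c in missing if c not in pure_values]
        if unknown:
            names = ", ".join(c.structure for c in unknown)
            raise AugmentationError(
                f"no pure value supplied for {len(unknown)} compound(s): {names}"
            )
        for c in missing:
            added.append(MixtureRecord(c, None, 1.0, dataset.property, float(pure_values[c])))

    return replace(dataset, records=list(dataset.records) + added)


# ---------------------------------------------------------------------------
# I/O in the upload dialect

_MANDATORY = ("MOLAR_FRACTION", "PROPERTY", "VALUE")
_STRUCT1 = ("SMILES1", "MOL1")
_STRUCT2 = ("SMILES2", "MOL2", "MOLID2")


def _read_structure_file(ref: str, base: Path) -> str:
    """Resolve a MOL/SDF file reference to a SMILES string (first molecule)."""
    from rdkit import Chem

    path = Path(ref)
    if not path.is_absolute():
        path = base / path
    if not path.exists():
        raise StructureError(f"structure file not found: {ref}")
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for mol in supplier:
        if mol is not None:
            return Chem.MolToSmiles(mol)
    raise StructureError(f"no parsable molecule in structure file: {ref}")


def read_dataset(
    path: str | Path,
    format: str | None = None,
    property_name: str | None = None,
    endpoint_kind: str = "regression",
    concentration_dependent: bool = True,
    canonicalizer: Canonicalizer = rdkit_canonical_smiles,
) -> MixtureDataset:
    """Read a mixture dataset from a CSV or XLSX file in the upload dialect.

    Mandatory columns: a structure column (SMILES1 or MOL1), MOLAR_FRACTION,
    PROPERTY, VALUE; optional: SMILES2/MOL2/MOLID2, NAME2, UNIT, SOURCE. MOL
    columns hold paths to SDF/MOL files (first molecule used). Row-level
    failures are collected and reported together with their row numbers.
    """
    path = Path(path)
    fmt = format or ("xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv")
    if fmt == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
    elif fmt == "xlsx":
        df = pd.read_excel(path)
    else:
        raise ConfigError(f"unknown dataset format: {fmt!r}")

    cols = {str(c).strip().upper() for c in df.columns}
    for c in _MANDATORY:
        if c not in cols:
            raise SchemaError(f"missing mandatory column: {c}")
    if not cols & set(_STRUCT1):
        raise SchemaError("missing mandatory structure column: SMILES1 (or MOL1)")

    base = path.parent

    def canon(s: str) -> str:
        if s.lower().endswith((".sdf", ".mol")):
            return _read_structure_file(s, base)  # already canonical SMILES
        return canonicalizer(s)

    records: list[MixtureRecord] = []
    failures: list[str] = []
    for i, row in enumerate(df.to_dict(orient="records")):
        try:
            records.append(canonicalize_record(row, canonicalizer=canon))
        except Exception as e:  # noqa: BLE001 - collected and re-raised below
            failures.append(f"row {i + 2}: {e}")  # +2: header line + 1-based
    if failures:
        raise SchemaError(
            f"{len(failures)} row(s) failed to parse:\n" + "\n".join(failures)
        )
    if not records:
        raise SchemaError(f"no records in {path}")

    prop = property_name or records[0].property
    return MixtureDataset(
        records=records,
        property=prop,
        endpoint_kind=endpoint_kind,
        concentration_dependent=concentration_dependent,
    )


def dataset_to_frame(dataset: MixtureDataset) -> pd.DataFrame:
    """Upload-dialect table view of a dataset (floats kept at full precision)."""
    rows = []
    for r in dataset.records:
        rows.append(
            {
                "SMILES1": r.component1.structure,
                "MOLAR_FRACTION": r.x1,
                "SMILES2": r.component2.structure if r.component2 else "",
                "NAME2": (r.component2.name or "") if r.component2 else "",
                "PROPERTY": r.property,
                "VALUE": r.value,
                "UNIT": r.unit,
                "SOURCE": r.source,
            }
        )
    return pd.DataFrame(rows)


def write_dataset(dataset: MixtureDataset, path: str | Path, format: str | None = None) -> None:
    """Write a dataset in the upload dialect (CSV or XLSX); round-trip stable."""
    path = Path(path)
    fmt = format or ("xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv")
    df = dataset_to_frame(dataset)
    if fmt == "csv":
        df.to_csv(path, index=False)  # pandas writes shortest round-trip floats
    elif fmt == "xlsx":
        df.to_excel(path, index=False)
    else:
        raise ConfigError(f"unknown dataset format: {fmt!r}")
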
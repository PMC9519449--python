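"""The name registry: registration state machine, priority and protologues.

Entries move through a small state machine::

    draft -> provisionally_accepted -> valid
    draft | provisionally_accepted -> rejected

with no transitions out of ``valid`` or ``rejected``.  Two validation paths
exist: path 1 (preregistration before the effective publication; the entry
becomes valid on the date its DOI is recorded, which is the name's priority
date) and path 2 (intake of already-published names, including *Candidatus*
names; curator acceptance marks the priority date and the provisional
designation is dropped).

Priority follows the earliest-valid-name rule: among competing names for one
taxon the earliest priority date wins.  Names validated under the culture
based code (ICNP) participate with their own priority dates but never
displace an earlier name validated here.

The registry serializes to schema-versioned JSON with ISO-8601 dates.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Union

from .nomenclature import (
    NameFinding,
    Rank,
    Severity,
    TaxonName,
    check_name,
    homonym_key,
)
from .qc import QCReport

__all__ = [
    "TypeKind",
    "EntryStatus",
    "TypeDesignation",
    "RegistryEntry",
    "ExternalName",
    "Registry",
    "RegistryError",
    "StateError",
    "SchemaError",
    "register_draft",
    "attach_doi",
    "validate_path2",
    "reject_entry",
    "resolve_priority",
    "render_protologue",
    "export_json",
    "import_json",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1.0"

#: Plain-text rendering of the superscript marker flagging a nomenclatural
#: type whose own type is a DNA sequence.
TS_MARKER = "^Ts"


class RegistryError(ValueError):
    """A registration precondition failed (homonym, QC, rank/type mismatch)."""


class StateError(RegistryError):
    """An operation was applied to an entry in the wrong state."""


class SchemaError(ValueError):
    """A registry JSON document violates the schema."""


class TypeKind(str, Enum):
    GENOME_ASSEMBLY = "genome_assembly"
    SPECIES_REF = "species_ref"
    GENUS_REF = "genus_ref"


class EntryStatus(str, Enum):
    DRAFT = "draft"
    PROVISIONALLY_ACCEPTED = "provisionally_accepted"
    VALID = "valid"
    REJECTED = "rejected"


#: Allowed transitions of the registration state machine.
TRANSITIONS: dict[EntryStatus, frozenset[EntryStatus]] = {
    EntryStatus.DRAFT: frozenset(
        {EntryStatus.PROVISIONALLY_ACCEPTED, EntryStatus.REJECTED}
    ),
    EntryStatus.PROVISIONALLY_ACCEPTED: frozenset(
        {EntryStatus.VALID, EntryStatus.REJECTED}
    ),
    EntryStatus.VALID: frozenset(),
    EntryStatus.REJECTED: frozenset(),
}

#: Which type-designation kind each rank requires.
RANK_TYPE_KIND: dict[Rank, TypeKind] = {
    Rank.SPECIES: TypeKind.GENOME_ASSEMBLY,
    Rank.SUBSPECIES: TypeKind.GENOME_ASSEMBLY,
    Rank.GENUS: TypeKind.SPECIES_REF,
    Rank.FAMILY: TypeKind.GENUS_REF,
    Rank.ORDER: TypeKind.GENUS_REF,
    Rank.CLASS: TypeKind.GENUS_REF,
    Rank.PHYLUM: TypeKind.GENUS_REF,
}

_DOI_RE = re.compile(r"^10\.\S+/\S+$")


@dataclass(frozen=True)
class TypeDesignation:
    """The nomenclatural type anchoring a name.

    Species and subspecies are typified by a genome assembly (INSDC
    accession); a genus by one of its species; ranks above genus by a genus.
    ``is_ts`` marks a type species whose own type is a DNA sequence, rendered
    with the superscript-Ts convention.
    """

    kind: TypeKind
    accession: Optional[str] = None
    ref_entry_id: Optional[str] = None
    is_ts: bool = False

    def __post_init__(self) -> None:
        if self.kind is TypeKind.GENOME_ASSEMBLY and not self.accession:
            raise RegistryError("genome_assembly type needs an accession")
        if self.kind is not TypeKind.GENOME_ASSEMBLY and not self.ref_entry_id:
            raise RegistryError(f"{self.kind.value} type needs a ref_entry_id")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "accession": self.accession,
            "ref_entry_id": self.ref_entry_id,
            "is_ts": self.is_ts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TypeDesignation":
        return cls(
            kind=TypeKind(d["kind"]),
            accession=d.get("accession"),
            ref_entry_id=d.get("ref_entry_id"),
            is_ts=bool(d.get("is_ts", False)),
        )


@dataclass(frozen=True)
class RegistryEntry:
    entry_id: str
    name: TaxonName
    type: TypeDesignation
    status: EntryStatus
    path: int
    created_date: _dt.date
    doi: Optional[str] = None
    priority_date: Optional[_dt.date] = None
    description: Optional[str] = None
    qc: Optional[QCReport] = None
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.path not in (1, 2):
            raise RegistryError(f"path must be 1 or 2, got {self.path}")
        if self.status is EntryStatus.VALID and self.priority_date is None:
            raise RegistryError("a valid entry must carry a priority date")
        if self.status is EntryStatus.VALID and self.path == 1 and not self.doi:
            raise RegistryError("a valid path-1 entry must carry a DOI")

    def to_dict(self) -> dict:
        return {
            "entry_id": self.entry_id,
            "name": self.name.to_dict(),
            "type": self.type.to_dict(),
            "status": self.status.value,
            "path": self.path,
            "created_date": self.created_date.isoformat(),
            "doi": self.doi,
            "priority_date": (
                self.priority_date.isoformat() if self.priority_date else None
            ),
            "description": self.description,
            "qc": self.qc.to_dict() if self.qc else None,
            "notes": list(self.notes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegistryEntry":
        return cls(
            entry_id=d["entry_id"],
            name=TaxonName.from_dict(d["name"]),
            type=TypeDesignation.from_dict(d["type"]),
            status=EntryStatus(d["status"]),
            path=int(d["path"]),
            created_date=_dt.date.fromisoformat(d["created_date"]),
            doi=d.get("doi"),
            priority_date=(
                _dt.date.fromisoformat(d["priority_date"])
                if d.get("priority_date")
                else None
            ),
            description=d.get("description"),
            qc=QCReport.from_dict(d["qc"]) if d.get("qc") else None,
            notes=tuple(d.get("notes", [])),
        )


@dataclass(frozen=True)
class ExternalName:
    """A name validated under the culture-based code (ICNP), participating
    in priority with its own date."""

    name_key: str
    priority_date: _dt.date
    source: str = "ICNP"

    def to_dict(self) -> dict:
        return {
            "name_key": self.name_key,
            "priority_date": self.priority_date.isoformat(),
            "source": self.source,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExternalName":
        return cls(
            name_key=d["name_key"],
            priority_date=_dt.date.fromisoformat(d["priority_date"]),
            source=d.get("source", "ICNP"),
        )


class Registry:
    """Id-indexed collection of entries plus external (ICNP) names.

    Invariants maintained after every mutation: unique entry ids, and at most
    one valid entry per homonym key.  Rejected entries keep their records as
    an audit trail but free their homonym key.
    """

    def __init__(
        self,
        entries: Iterable[RegistryEntry] = (),
        external_names: Iterable[ExternalName] = (),
    ) -> None:
        self.entries: dict[str, RegistryEntry] = {}
        self.external_names: list[ExternalName] = list(external_names)
        for e in entries:
            if e.entry_id in self.entries:
                raise RegistryError(f"duplicate entry_id {e.entry_id!r}")
            self.entries[e.entry_id] = e
        self._check_homonym_invariant()

    # -- invariants ------------------------------------------------------

    def _check_homonym_invariant(self) -> None:
        seen: dict[str, str] = {}
        for e in self.entries.values():
            if e.status is EntryStatus.REJECTED:
                continue
            key = homonym_key(e.name)
            if key in seen:
                raise RegistryError(
                    f"homonym invariant violated: entries {seen[key]!r} and "
                    f"{e.entry_id!r} share key {key!r}"
                )
            seen[key] = e.entry_id

    def active_keys(self) -> dict[str, str]:
        """Homonym keys of non-rejected entries, mapped to entry ids."""
        return {
            homonym_key(e.name): e.entry_id
            for e in self.entries.values()
            if e.status is not EntryStatus.REJECTED
        }

    def external_keys(self) -> set[str]:
        return {x.name_key for x in self.external_names}

    def _next_id(self) -> str:
        return f"seqcode-{len(self.entries) + 1:06d}"

    def get(self, entry_id: str) -> RegistryEntry:
        try:
            return self.entries[entry_id]
        except KeyError:
            raise RegistryError(f"no entry {entry_id!r}") from None

    def _transition(self, entry: RegistryEntry, new: RegistryEntry) -> RegistryEntry:
        if new.status is not entry.status and new.status not in TRANSITIONS[entry.status]:
            raise StateError(
                f"illegal transition {entry.status.value} -> {new.status.value} "
                f"for {entry.entry_id!r}"
            )
        self.entries[entry.entry_id] = new
        self._check_homonym_invariant()
        return new

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Registry):
            return NotImplemented
        return (
            self.entries == other.entries
            and self.external_names == other.external_names
        )

    def __len__(self) -> int:
        return len(self.entries)


# -- operations ----------------------------------------------------------


def register_draft(
    registry: Registry,
    name: TaxonName,
    type_designation: TypeDesignation,
    created_date: _dt.date,
    path: int = 1,
    qc: Optional[QCReport] = None,
    description: Optional[str] = None,
    entry_id: Optional[str] = None,
) -> RegistryEntry:
    """Register a proposal, promoting it to provisionally-accepted when every
    automated check passes.

    Preconditions enforced: the name carries no error-severity findings; the
    type kind matches the rank; referenced type entries exist; for species
    and subspecies the genome QC report must mark the genome eligible as a
    type; the name must not collide with a non-rejected entry or an external
    (ICNP) name.
    """
    errors = [f for f in check_name(name) if f.severity is Severity.ERROR]
    if errors:
        raise RegistryError(
            "name fails nomenclature checks: "
            + "; ".join(f"{f.code}: {f.message}" for f in errors)
        )

    expected_kind = RANK_TYPE_KIND[name.rank]
    if type_designation.kind is not expected_kind:
        raise RegistryError(
            f"a {name.rank.value} must be typified by {expected_kind.value}, "
            f"got {type_designation.kind.value}"
        )
    if type_designation.ref_entry_id is not None:
        if type_designation.ref_entry_id not in registry.entries:
            raise RegistryError(
                f"referenced type entry {type_designation.ref_entry_id!r} "
                "does not exist"
            )

    if name.rank in (Rank.SPECIES, Rank.SUBSPECIES):
        if qc is None or not qc.eligible_as_type:
            raise RegistryError(
                "type genome is not eligible: QC report missing or failing "
                "required checks"
            )

    key = homonym_key(name)
    if key in registry.active_keys():
        raise RegistryError(
            f"homonym: {name.full_name!r} collides with registered entry "
            f"{registry.active_keys()[key]!r}"
        )
    if key in registry.external_keys():
        raise RegistryError(
            f"homonym: {name.full_name!r} collides with an ICNP name"
        )

    entry = RegistryEntry(
        entry_id=entry_id or registry._next_id(),
        name=name,
        type=type_designation,
        status=EntryStatus.DRAFT,
        path=path,
        created_date=created_date,
        qc=qc,
        description=description,
    )
    if entry.entry_id in registry.entries:
        raise RegistryError(f"duplicate entry_id {entry.entry_id!r}")
    registry.entries[entry.entry_id] = entry
    # every automated precondition passed above, so promote immediately
    entry = registry._transition(
        entry, replace(entry, status=EntryStatus.PROVISIONALLY_ACCEPTED)
    )
    return entry


def attach_doi(
    registry: Registry, entry_id: str, doi: str, entry_date: _dt.date
) -> RegistryEntry:
    """Complete a path-1 registration: recording the effective publication's
    DOI makes the entry valid and sets its priority date to the recording
    date."""
    entry = registry.get(entry_id)
    if entry.path != 1:
        raise StateError(f"attach_doi applies to path-1 entries, not path {entry.path}")
    if entry.status is not EntryStatus.PROVISIONALLY_ACCEPTED:
        raise StateError(
            f"attach_doi requires a provisionally accepted entry, "
            f"{entry_id!r} is {entry.status.value}"
        )
    if not _DOI_RE.match(doi):
        raise RegistryError(f"malformed DOI {doi!r} (expected '10.<prefix>/<suffix>')")
    return registry._transition(
        entry,
        replace(entry, status=EntryStatus.VALID, doi=doi, priority_date=entry_date),
    )


def validate_path2(
    registry: Registry, entry_id: str, acceptance_date: _dt.date
) -> RegistryEntry:
    """Complete a path-2 registration: curator acceptance makes the entry
    valid with the acceptance date as priority date.  The rendered name of a
    formerly provisional (*Candidatus*) name omits the designation."""
    entry = registry.get(entry_id)
    if entry.path != 2:
        raise StateError(
            f"validate_path2 applies to path-2 entries, not path {entry.path}"
        )
    if entry.status is not EntryStatus.PROVISIONALLY_ACCEPTED:
        raise StateError(
            f"validate_path2 requires a provisionally accepted entry, "
            f"{entry_id!r} is {entry.status.value}"
        )
    return registry._transition(
        entry,
        replace(entry, status=EntryStatus.VALID, priority_date=acceptance_date),
    )


def reject_entry(registry: Registry, entry_id: str, reason: str) -> RegistryEntry:
    """Reject a draft or provisionally accepted entry, freeing its homonym
    key while keeping the record as an audit trail."""
    entry = registry.get(entry_id)
    if entry.status in (EntryStatus.VALID, EntryStatus.REJECTED):
        raise StateError(f"cannot reject an entry in state {entry.status.value}")
    return registry._transition(
        entry,
        replace(entry, status=EntryStatus.REJECTED, notes=entry.notes + (reason,)),
    )


@dataclass(frozen=True)
class PriorityRecord:
    """One competitor in a priority resolution: either a registry entry or an
    external (ICNP) name."""

    label: str
    priority_date: _dt.date
    source: str  # "SeqCode" or "ICNP"
    entry_id: Optional[str] = None


def resolve_priority(
    records: Iterable[Union[RegistryEntry, ExternalName, PriorityRecord]],
    registry: Optional[Registry] = None,
) -> list[PriorityRecord]:
    """Order competing names for one taxon by priority.

    Records are sorted ascending by priority date; the first is the correct
    name.  ICNP names compete with their own dates but on a date tie the
    name validated here is kept first, so an ICNP name never displaces an
    equal-or-later name.  Ties within one source are broken by ascending
    label with a curator-review note implied.  The result is independent of
    input order.
    """
    normalized: list[PriorityRecord] = []
    for rec in records:
        if isinstance(rec, PriorityRecord):
            normalized.append(rec)
        elif isinstance(rec, RegistryEntry):
            if rec.priority_date is None:
                raise RegistryError(
                    f"entry {rec.entry_id!r} has no priority date; "
                    "only valid entries can compete for priority"
                )
            normalized.append(
                PriorityRecord(
                    label=rec.name.full_name,
                    priority_date=rec.priority_date,
                    source="SeqCode",
                    entry_id=rec.entry_id,
                )
            )
        elif isinstance(rec, ExternalName):
            normalized.append(
                PriorityRecord(
                    label=rec.name_key,
                    priority_date=rec.priority_date,
                    source=rec.source,
                )
            )
        else:  # pragma: no cover - defensive
            raise TypeError(f"cannot resolve priority of {type(rec).__name__}")
    if not normalized:
        raise RegistryError("no records to resolve")
    return sorted(
        normalized,
        key=lambda r: (r.priority_date, 0 if r.source == "SeqCode" else 1, r.label),
    )


# -- protologue ----------------------------------------------------------

_RANK_TYPE_SENTENCE = {
    TypeKind.GENOME_ASSEMBLY: (
        "The genome available under the assembly accession number "
        "({accession}{ts}) is the designated nomenclatural type for the "
        "{rank}."
    ),
    TypeKind.SPECIES_REF: (
        "The nomenclatural type of the {rank} is {ref_name}{ts}."
    ),
    TypeKind.GENUS_REF: (
        "The nomenclatural type of the {rank} is the genus {ref_name}{ts}."
    ),
}


def render_protologue(registry: Registry, entry_id: str) -> str:
    """Render the protologue text of a provisionally accepted or valid entry.

    Blocks, separated by blank lines: the name line with its etymology; the
    free-text description when present; and the type-designation sentence
    naming the genome accession (species/subspecies) or the type taxon
    (higher ranks), with the plain-text ``^Ts`` marker when the type species'
    own type is a DNA sequence.
    """
    entry = registry.get(entry_id)
    if entry.status not in (EntryStatus.PROVISIONALLY_ACCEPTED, EntryStatus.VALID):
        raise StateError(
            f"protologues are rendered for provisionally accepted or valid "
            f"entries; {entry_id!r} is {entry.status.value}"
        )

    name_line = entry.name.full_name
    if entry.type.is_ts and entry.name.rank in (Rank.SPECIES, Rank.SUBSPECIES):
        name_line += TS_MARKER
    if entry.name.etymology:
        name_line += f" ({entry.name.etymology})"

    ts = TS_MARKER if entry.type.is_ts else ""
    if entry.type.kind is TypeKind.GENOME_ASSEMBLY:
        type_sentence = _RANK_TYPE_SENTENCE[entry.type.kind].format(
            accession=entry.type.accession, ts=ts, rank=entry.name.rank.value
        )
    else:
        if entry.type.ref_entry_id is None:
            raise RegistryError(f"entry {entry_id!r} lacks a type designation")
        ref = registry.get(entry.type.ref_entry_id)
        type_sentence = _RANK_TYPE_SENTENCE[entry.type.kind].format(
            ref_name=ref.name.full_name, ts=ts, rank=entry.name.rank.value
        )

    blocks = [name_line]
    if entry.description:
        blocks.append(entry.description)
    blocks.append(type_sentence)
    return "\n\n".join(blocks)


# -- JSON ----------------------------------------------------------------


def export_json(registry: Registry, path: Union[str, Path]) -> None:
    """Write the registry as schema-versioned JSON (ISO-8601 dates)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "entries": [e.to_dict() for e in registry.entries.values()],
        "external_names": [x.to_dict() for x in registry.external_names],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


_ALLOWED_STATUS = {s.value for s in EntryStatus}
_ALLOWED_RANK = {r.value for r in Rank}
_ALLOWED_KIND = {k.value for k in TypeKind}


def _validate_document(doc: dict) -> None:
    problems: list[str] = []
    if not isinstance(doc, dict):
        raise SchemaError("registry document must be a JSON object")
    if doc.get("schema_version") != SCHEMA_VERSION:
        problems.append(
            f"schema_version: expected {SCHEMA_VERSION!r}, "
            f"got {doc.get('schema_version')!r}"
        )
    for i, e in enumerate(doc.get("entries", [])):
        where = f"entries[{i}]"
        for key in ("entry_id", "name", "type", "status", "path", "created_date"):
            if key not in e:
                problems.append(f"{where}.{key}: missing")
        if e.get("status") not in _ALLOWED_STATUS:
            problems.append(f"{where}.status: unknown value {e.get('status')!r}")
        name = e.get("name", {})
        if name.get("rank") not in _ALLOWED_RANK:
            problems.append(f"{where}.name.rank: unknown value {name.get('rank')!r}")
        td = e.get("type", {})
        if td.get("kind") not in _ALLOWED_KIND:
            problems.append(f"{where}.type.kind: unknown value {td.get('kind')!r}")
        for key in ("created_date", "priority_date"):
            val = e.get(key)
            if val is not None:
                try:
                    _dt.date.fromisoformat(val)
                except (TypeError, ValueError):
                    problems.append(f"{where}.{key}: not an ISO date: {val!r}")
    for i, x in enumerate(doc.get("external_names", [])):
        where = f"external_names[{i}]"
        for key in ("name_key", "priority_date"):
            if key not in x:
                problems.append(f"{where}.{key}: missing")
    if problems:
        raise SchemaError("; ".join(problems))


def import_json(path: Union[str, Path]) -> Registry:
    """Load a registry JSON document, validating it against the schema and
    listing every offending field on failure."""
    doc = json.loads(Path(path).read_text())
    _validate_document(doc)
    entries = [RegistryEntry.from_dict(e) for e in doc.get("entries", [])]
    external = [ExternalName.from_dict(x) for x in doc.get("external_names", [])]
    return Registry(entries=entries, external_names=external)
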
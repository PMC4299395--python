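"""Append-only gene registry with event-sourced lifecycle semantics.

The registry issues locus identifiers sequentially per chromosome (one
shared counter across all object types), and records every mutation —
creation, merge, split, relocation from the unanchored chromosome-00 bin,
structural-edit version bumps, sequence-variant allocation, synonym
additions — as an immutable :class:`AnnotationEvent`.  Identifiers are
never reused: a chromosome counter only advances, and a retired record
keeps its history and points at its successor.

The event log is the source of truth.  Every public mutation first builds
an event, then applies it through the same pure ``_apply`` dispatch used by
:meth:`Registry.replay`, so replaying the log from an empty registry
reproduces the live state exactly.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

from .locus_id import (
    MAX_CHROMOSOME,
    MAX_NUMERIC_CODE,
    LocusID,
    ObjectType,
    format_locus_id,
    parse_locus_id,
    split_variant,
)

__all__ = [
    "RegistryError",
    "CapacityError",
    "UnknownGeneError",
    "RetiredGeneError",
    "RuleViolation",
    "SynonymKind",
    "SynonymNote",
    "SynonymEntry",
    "EventType",
    "AnnotationEvent",
    "GeneStatus",
    "GeneRecord",
    "Registry",
]


class RegistryError(Exception):
    """Base class for registry rule violations."""


class CapacityError(RegistryError):
    """A chromosome's 5-digit numbering space (99,999 codes) is exhausted."""


class UnknownGeneError(RegistryError):
    """The identifier has never been issued by this registry."""


class RetiredGeneError(RegistryError):
    """The operation requires an active record but the identifier is retired."""


class RuleViolation(RegistryError):
    """Any other lifecycle rule violation (self-merge, duplicate synonym...)."""


class SynonymKind(enum.Enum):
    SYMBOL = "symbol"
    FULL_NAME = "full_name"
    LOCUS_ID = "locus_id"
    LEGACY_ID = "legacy_id"


class SynonymNote(enum.Enum):
    NONE = "none"
    OBSOLETE = "obsolete"
    INCORRECT = "incorrect"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class SynonymEntry:
    """A historical or alternative name kept alongside a gene's main name.

    ``note`` flags problematic synonyms (a name used for several genes is
    ``ambiguous``, a misattributed one ``incorrect``, a superseded one
    ``obsolete``); ``reference`` holds a bibliographic token (DOI, PubMed
    id) documenting where the synonym was used.
    """

    name: str
    kind: SynonymKind
    note: SynonymNote = SynonymNote.NONE
    note_text: str = ""
    reference: Optional[str] = None

    def key(self) -> Tuple[str, str]:
        return (self.name.lower(), self.kind.value)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind.value,
            "note": self.note.value,
            "note_text": self.note_text,
            "reference": self.reference,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SynonymEntry":
        return cls(
            name=d["name"],
            kind=SynonymKind(d["kind"]),
            note=SynonymNote(d.get("note", "none")),
            note_text=d.get("note_text", ""),
            reference=d.get("reference"),
        )


class EventType(enum.Enum):
    CREATE = "create"
    MERGE = "merge"
    SPLIT = "split"
    RELOCATE = "relocate"
    STRUCTURAL_EDIT = "structural_edit"
    RENAME = "rename"
    SYNONYM_ADDED = "synonym_added"
    VARIANT_ALLOCATED = "variant_allocated"
    RETIRE = "retire"


@dataclass(frozen=True)
class AnnotationEvent:
    """One immutable entry of the registry's history.

    Events are never deleted or modified; ``sequence_number`` is strictly
    increasing within a registry.  ``payload`` carries everything needed to
    re-apply the event during replay.
    """

    sequence_number: int
    event_type: EventType
    subject: str  # canonical locus-ID string
    payload: dict
    actor: str = "curator"

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema": 1,
                "seq": self.sequence_number,
                "type": self.event_type.value,
                "subject": self.subject,
                "payload": self.payload,
                "actor": self.actor,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, line: str) -> "AnnotationEvent":
        d = json.loads(line)
        return cls(
            sequence_number=d["seq"],
            event_type=EventType(d["type"]),
            subject=d["subject"],
            payload=d["payload"],
            actor=d.get("actor", "curator"),
        )


class GeneStatus(enum.Enum):
    ACTIVE = "active"
    RETIRED = "retired"


@dataclass
class GeneRecord:
    """Current state of one locus: identity, status, names and synonyms."""

    locus_id: LocusID
    status: GeneStatus = GeneStatus.ACTIVE
    version: int = 1
    symbol: Optional[str] = None
    full_name: Optional[str] = None
    curation_label: Optional[str] = None
    synonyms: List[SynonymEntry] = field(default_factory=list)
    variants: List[str] = field(default_factory=list)
    successor: Optional[LocusID] = None

    def has_synonym(self, name: str, kind: SynonymKind) -> bool:
        key = (name.lower(), kind.value)
        return any(s.key() == key for s in self.synonyms)


class Registry:
    """The per-genome gene registry.

    State lives in ``records`` (keyed by the base locus identifier) and
    per-chromosome ``counters`` (highest numeric code ever issued); both are
    pure projections of ``event_log``.
    """

    def __init__(self, taxon: str = "VITVI") -> None:
        self.taxon = taxon.upper()
        self.records: Dict[LocusID, GeneRecord] = {}
        self.event_log: List[AnnotationEvent] = []
        self.counters: Dict[int, int] = {}

    # -- queries ---------------------------------------------------------

    def get(self, locus: LocusID) -> GeneRecord:
        rec = self.records.get(locus.base)
        if rec is None:
            raise UnknownGeneError(f"{format_locus_id(locus)} was never issued")
        return rec

    def _get_active(self, locus: LocusID) -> GeneRecord:
        rec = self.get(locus)
        if rec.status is not GeneStatus.ACTIVE:
            raise RetiredGeneError(f"{format_locus_id(locus)} is retired")
        return rec

    def resolve(self, locus: LocusID) -> GeneRecord:
        """Follow successor links from a (possibly retired) identifier to
        its terminal record."""
        rec = self.get(locus)
        seen = {rec.locus_id}
        while rec.successor is not None:
            rec = self.get(rec.successor)
            if rec.locus_id in seen:  # defensive; construction forbids cycles
                raise RuleViolation("successor cycle detected")
            seen.add(rec.locus_id)
        return rec

    def current_version(self, locus: LocusID) -> int:
        """Version implied when the identifier carries no version suffix."""
        return self.get(locus).version

    def get_history(self, locus: LocusID) -> List[AnnotationEvent]:
        """All events touching the identifier, in sequence order; retired
        identifiers remain fully retrievable."""
        self.get(locus)  # raises UnknownGeneError if never issued
        key = format_locus_id(locus.base)
        out = []
        for ev in self.event_log:
            if ev.subject == key or key in ev.payload.get("related", []):
                out.append(ev)
        return out

    # -- event plumbing --------------------------------------------------

    def _emit(self, event_type: EventType, subject: LocusID, payload: dict,
              actor: str) -> AnnotationEvent:
        ev = AnnotationEvent(
            sequence_number=len(self.event_log) + 1,
            event_type=event_type,
            subject=format_locus_id(subject.base),
            payload=payload,
            actor=actor,
        )
        self._apply(ev)
        return ev

    def _apply(self, ev: AnnotationEvent) -> None:
        """Pure state transition used by both live mutation and replay."""
        subject = parse_locus_id(ev.subject)
        handler = {
            EventType.CREATE: self._apply_create,
            EventType.MERGE: self._apply_merge,
            EventType.SPLIT: self._apply_split,
            EventType.RELOCATE: self._apply_relocate,
            EventType.STRUCTURAL_EDIT: self._apply_structural_edit,
            EventType.RENAME: self._apply_rename,
            EventType.SYNONYM_ADDED: self._apply_synonym_added,
            EventType.VARIANT_ALLOCATED: self._apply_variant_allocated,
            EventType.RETIRE: self._apply_retire,
        }[ev.event_type]
        handler(subject, ev.payload)
        self.event_log.append(ev)

    def _apply_create(self, subject: LocusID, payload: dict) -> None:
        self.records[subject] = GeneRecord(locus_id=subject)
        chrom = subject.chromosome
        self.counters[chrom] = max(self.counters.get(chrom, 0), subject.numeric_code)

    def _apply_merge(self, subject: LocusID, payload: dict) -> None:
        discarded = parse_locus_id(payload["discarded"])
        survivor = self.records[subject]
        old = self.records[discarded]
        old.status = GeneStatus.RETIRED
        old.successor = subject
        survivor.synonyms.append(
            SynonymEntry(format_locus_id(discarded), SynonymKind.LOCUS_ID,
                         SynonymNote.OBSOLETE, "merged into this locus")
        )
        survivor.version += 1

    def _apply_split(self, subject: LocusID, payload: dict) -> None:
        original = self.records[subject]
        original.version += 1
        for text in payload["new_ids"]:
            self._apply_create(parse_locus_id(text), {})

    def _apply_relocate(self, subject: LocusID, payload: dict) -> None:
        new_id = parse_locus_id(payload["new_id"])
        old = self.records[subject]
        old.status = GeneStatus.RETIRED
        old.successor = new_id
        new_rec = GeneRecord(locus_id=new_id)
        new_rec.symbol = old.symbol
        new_rec.full_name = old.full_name
        new_rec.curation_label = old.curation_label
        new_rec.synonyms = list(old.synonyms)
        new_rec.synonyms.append(
            SynonymEntry(format_locus_id(subject), SynonymKind.LOCUS_ID,
                         SynonymNote.OBSOLETE, "relocated")
        )
        self.records[new_id] = new_rec
        chrom = new_id.chromosome
        self.counters[chrom] = max(self.counters.get(chrom, 0), new_id.numeric_code)

    def _apply_structural_edit(self, subject: LocusID, payload: dict) -> None:
        self.records[subject].version += 1

    def _apply_rename(self, subject: LocusID, payload: dict) -> None:
        rec = self.records[subject]
        if payload.get("keep_old_as_synonym") and rec.symbol:
            rec.synonyms.append(
                SynonymEntry(rec.symbol, SynonymKind.SYMBOL, SynonymNote.OBSOLETE)
            )
        rec.symbol = payload.get("symbol", rec.symbol)
        rec.full_name = payload.get("full_name", rec.full_name)
        if "curation_label" in payload:
            rec.curation_label = payload["curation_label"]

    def _apply_synonym_added(self, subject: LocusID, payload: dict) -> None:
        self.records[subject].synonyms.append(
            SynonymEntry.from_dict(payload["entry"])
        )

    def _apply_variant_allocated(self, subject: LocusID, payload: dict) -> None:
        self.records[subject].variants.append(payload["token"])

    def _apply_retire(self, subject: LocusID, payload: dict) -> None:
        rec = self.records[subject]
        rec.status = GeneStatus.RETIRED
        if payload.get("successor"):
            rec.successor = parse_locus_id(payload["successor"])

    # -- lifecycle operations -------------------------------------------

    def _next_id(self, chromosome: int, object_type: ObjectType) -> LocusID:
        if not 0 <= chromosome <= MAX_CHROMOSOME:
            raise RuleViolation(f"chromosome {chromosome} outside 00-{MAX_CHROMOSOME}")
        counter = self.counters.get(chromosome, 0)
        if counter >= MAX_NUMERIC_CODE:
            raise CapacityError(
                f"chromosome {chromosome:02d} has exhausted its numbering "
                f"space (up to {MAX_NUMERIC_CODE:,} codes)"
            )
        return LocusID(self.taxon, chromosome, object_type, counter + 1)

    def create_gene(self, chromosome: int,
                    object_type: ObjectType = ObjectType.GENE,
                    actor: str = "curator") -> LocusID:
        """Issue the next available identifier on a chromosome (+1, no gaps)."""
        new_id = self._next_id(chromosome, object_type)
        self._emit(EventType.CREATE, new_id, {}, actor)
        return new_id

    def merge_genes(self, survivor: LocusID, discarded: LocusID,
                    actor: str = "curator") -> GeneRecord:
        """Concatenate two gene models: one identifier survives (version
        bumped), the other is retired and kept as a synonym of the survivor."""
        if survivor.base == discarded.base:
            raise RuleViolation("cannot merge a gene with itself")
        surv = self._get_active(survivor)
        disc = self._get_active(discarded)
        if surv.locus_id.chromosome != disc.locus_id.chromosome:
            raise RuleViolation(
                "cross-chromosome merge is not allowed; relocate first"
            )
        if surv.locus_id.object_type is not disc.locus_id.object_type:
            raise RuleViolation("cannot merge objects of different types")
        self._emit(
            EventType.MERGE, survivor,
            {"discarded": format_locus_id(discarded.base),
             "related": [format_locus_id(discarded.base)]},
            actor,
        )
        return surv

    def split_gene(self, locus: LocusID, n_new: int = 1,
                   actor: str = "curator") -> List[LocusID]:
        """Split a gene model: the original keeps its identifier (version
        bumped); each additional model receives a fresh identifier."""
        if n_new < 1:
            raise RuleViolation("a split must produce at least one new model")
        rec = self._get_active(locus)
        new_ids = []
        chrom = rec.locus_id.chromosome
        counter = self.counters.get(chrom, 0)
        for i in range(n_new):
            if counter + 1 + i > MAX_NUMERIC_CODE:
                raise CapacityError(
                    f"chromosome {chrom:02d} has exhausted its numbering space"
                )
            new_ids.append(LocusID(self.taxon, chrom,
                                   rec.locus_id.object_type, counter + 1 + i))
        self._emit(
            EventType.SPLIT, locus,
            {"new_ids": [format_locus_id(i) for i in new_ids],
             "related": [format_locus_id(i) for i in new_ids]},
            actor,
        )
        return new_ids

    def relocate_gene(self, locus: LocusID, new_chromosome: int,
                      actor: str = "curator") -> LocusID:
        """Move a gene to another chromosome (typically out of the
        unanchored chromosome-00 bin once its scaffold is placed): a fresh
        identifier is issued there, the old one is retired and stored as a
        synonym.  A same-chromosome relocation is rejected — a scaffold
        re-orientation changes nothing."""
        rec = self._get_active(locus)
        if new_chromosome == rec.locus_id.chromosome:
            raise RuleViolation(
                "relocation to the same chromosome changes nothing"
            )
        new_id = self._next_id(new_chromosome, rec.locus_id.object_type)
        self._emit(
            EventType.RELOCATE, locus,
            {"new_id": format_locus_id(new_id),
             "related": [format_locus_id(new_id)]},
            actor,
        )
        return new_id

    def bump_version(self, locus: LocusID, actor: str = "curator") -> int:
        """Record a structural edit: the version increments by exactly 1."""
        rec = self._get_active(locus)
        self._emit(EventType.STRUCTURAL_EDIT, locus,
                   {"from": rec.version, "to": rec.version + 1}, actor)
        return rec.version

    def allocate_variant(self, locus: LocusID, allele_code: str,
                         splice_index: Optional[int] = None,
                         cultivar_prefix: Optional[str] = None,
                         actor: str = "curator") -> str:
        """Register a sequence-variant token (cultivar prefix + allele
        letter(s) + optional splice digit) for a locus; tokens are unique
        per locus and splice digits require a transcript or protein object."""
        rec = self._get_active(locus)
        token = f"{cultivar_prefix or ''}{allele_code}"
        if splice_index is not None:
            if not rec.locus_id.object_type.allows_splice_variant:
                raise RuleViolation(
                    "splice variants are admissible only on object types "
                    "'t' and 'p'"
                )
            token += str(splice_index)
        letters, digits = split_variant(token)
        if not token or letters + digits != token:
            raise RuleViolation(f"malformed variant token {token!r}")
        if token in rec.variants:
            raise RuleViolation(
                f"variant token {token!r} already allocated on "
                f"{format_locus_id(locus)}"
            )
        self._emit(EventType.VARIANT_ALLOCATED, locus, {"token": token}, actor)
        return token

    def add_synonym(self, locus: LocusID, entry: SynonymEntry,
                    actor: str = "curator") -> GeneRecord:
        """Append a synonym; (name, kind) pairs are unique per gene,
        case-insensitively on the name."""
        rec = self._get_active(locus)
        if rec.has_synonym(entry.name, entry.kind):
            raise RuleViolation(
                f"synonym ({entry.name!r}, {entry.kind.value}) already "
                f"present on {format_locus_id(locus)}"
            )
        self._emit(EventType.SYNONYM_ADDED, locus,
                   {"entry": entry.to_dict()}, actor)
        return rec

    def set_names(self, locus: LocusID, symbol: Optional[str] = None,
                  full_name: Optional[str] = None,
                  curation_label: Optional[str] = None,
                  keep_old_as_synonym: bool = False,
                  actor: str = "curator") -> GeneRecord:
        rec = self._get_active(locus)
        payload: dict = {"keep_old_as_synonym": keep_old_as_synonym}
        if symbol is not None:
            payload["symbol"] = symbol
        if full_name is not None:
            payload["full_name"] = full_name
        if curation_label is not None:
            payload["curation_label"] = curation_label
        self._emit(EventType.RENAME, locus, payload, actor)
        return rec

    # -- replay and persistence -----------------------------------------

    @classmethod
    def replay(cls, events: Iterable[AnnotationEvent],
               taxon: str = "VITVI") -> "Registry":
        """Rebuild a registry from its event log alone."""
        reg = cls(taxon=taxon)
        for ev in events:
            reg._apply(ev)
        return reg

    def state_snapshot(self) -> dict:
        """A canonical, comparison-friendly projection of the full state."""
        return {
            "taxon": self.taxon,
            "counters": {str(k): v for k, v in sorted(self.counters.items())},
            "records": {
                format_locus_id(k): {
                    "status": r.status.value,
                    "version": r.version,
                    "symbol": r.symbol,
                    "full_name": r.full_name,
                    "curation_label": r.curation_label,
                    "synonyms": [s.to_dict() for s in r.synonyms],
                    "variants": list(r.variants),
                    "successor": (format_locus_id(r.successor)
                                  if r.successor else None),
                }
                for k, r in sorted(self.records.items(),
                                   key=lambda kv: kv[0].sort_key())
            },
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Registry):
            return NotImplemented
        return self.state_snapshot() == other.state_snapshot()

    def save(self, directory: str | Path) -> None:
        """Persist as registry.tsv + synonyms.tsv + events.jsonl."""
        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows, syn_rows = [], []
        for key, rec in sorted(self.records.items(),
                               key=lambda kv: kv[0].sort_key()):
            rid = format_locus_id(key)
            rows.append({
                "id": rid,
                "status": rec.status.value,
                "version": rec.version,
                "symbol": rec.symbol or "",
                "full_name": rec.full_name or "",
                "curation_label": rec.curation_label or "",
                "variants": ",".join(rec.variants),
                "successor": format_locus_id(rec.successor) if rec.successor else "",
            })
            for syn in rec.synonyms:
                syn_rows.append({
                    "id": rid,
                    "name": syn.name,
                    "kind": syn.kind.value,
                    "note": syn.note.value,
                    "note_text": syn.note_text,
                    "reference": syn.reference or "",
                })
        pd.DataFrame(rows, columns=["id", "status", "version", "symbol",
                                    "full_name", "curation_label", "variants",
                                    "successor"]
                     ).to_csv(directory / "registry.tsv", sep="\t", index=False)
        pd.DataFrame(syn_rows, columns=["id", "name", "kind", "note",
                                        "note_text", "reference"]
                     ).to_csv(directory / "synonyms.tsv", sep="\t", index=False)
        with open(directory / "events.jsonl", "w") as fh:
            for ev in self.event_log:
                fh.write(ev.to_json() + "\n")

    @classmethod
    def load(cls, directory: str | Path, taxon: str = "VITVI") -> "Registry":
        """Load by replaying events.jsonl (the source of truth)."""
        directory = Path(directory)
        events = []
        with open(directory / "events.jsonl") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    events.append(AnnotationEvent.from_json(line))
        return cls.replay(events, taxon=taxon)
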
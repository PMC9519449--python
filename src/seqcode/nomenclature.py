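"""Parsing and checking of proposed prokaryotic names.

Covers the automated prechecks a registration portal runs before a name is
accepted: orthography (Latin letters, capitalization, part lengths), rank
suffixes (family ``-aceae``, order ``-ales``, class ``-ia``, phylum
``-ota``), binomial formation, removal of the provisional *Candidatus*
designation, and homonym keys for collision detection.  Latin grammar and
gender agreement are deliberately not validated — that remains a human
curator's task; etymology is stored verbatim and only checked for presence
where a caller requires it.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Optional

__all__ = [
    "Rank",
    "TaxonName",
    "NameFinding",
    "Severity",
    "NameError_",
    "parse_name",
    "strip_candidatus",
    "check_orthography",
    "check_rank_suffix",
    "check_name",
    "homonym_key",
    "render_name",
    "damerau_levenshtein",
    "orthographic_variants",
    "RESERVED_SUFFIXES",
]


class Rank(str, Enum):
    SPECIES = "species"
    SUBSPECIES = "subspecies"
    GENUS = "genus"
    FAMILY = "family"
    ORDER = "order"
    CLASS = "class"
    PHYLUM = "phylum"


#: Standard rank suffixes; genus names should avoid all of them.
RESERVED_SUFFIXES: dict[Rank, str] = {
    Rank.FAMILY: "aceae",
    Rank.ORDER: "ales",
    Rank.CLASS: "ia",
    Rank.PHYLUM: "ota",
}

_PART_COUNT = {
    Rank.SPECIES: 2,
    Rank.SUBSPECIES: 3,
    Rank.GENUS: 1,
    Rank.FAMILY: 1,
    Rank.ORDER: 1,
    Rank.CLASS: 1,
    Rank.PHYLUM: 1,
}


class Severity(str, Enum):
    ERROR = "error"      # blocks registration
    WARNING = "warning"  # advisory


@dataclass(frozen=True)
class NameFinding:
    code: str
    severity: Severity
    message: str


class NameError_(ValueError):
    """Raised when a raw string cannot be parsed as a name at the given rank."""


@dataclass(frozen=True)
class TaxonName:
    """A parsed name with its rank.

    ``genus_part`` holds the single part for genus and higher ranks, and the
    genus portion of binomials/trinomials.  ``full_name`` is the canonical
    plain-text rendering (no markup, no *Candidatus* prefix).
    """

    rank: Rank
    genus_part: str
    epithet: Optional[str] = None
    subepithet: Optional[str] = None
    etymology: Optional[str] = None
    was_candidatus: bool = False

    @property
    def full_name(self) -> str:
        return render_name(self)

    def to_dict(self) -> dict:
        return {
            "rank": self.rank.value,
            "genus_part": self.genus_part,
            "epithet": self.epithet,
            "subepithet": self.subepithet,
            "etymology": self.etymology,
            "was_candidatus": self.was_candidatus,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaxonName":
        return cls(
            rank=Rank(d["rank"]),
            genus_part=d["genus_part"],
            epithet=d.get("epithet"),
            subepithet=d.get("subepithet"),
            etymology=d.get("etymology"),
            was_candidatus=bool(d.get("was_candidatus", False)),
        )


_MARKUP = re.compile(r"[*_\"'‘’“”]")
_CANDIDATUS = re.compile(r"^(?:candidatus|ca\.)\s+", re.IGNORECASE)


def _normalize(raw: str) -> str:
    text = _MARKUP.sub("", raw)
    return " ".join(text.split())


def strip_candidatus(raw: str) -> tuple[str, bool]:
    """Remove a leading *Candidatus* designation (or the ``Ca.``
    abbreviation) together with surrounding markup.  Idempotent."""
    text = _normalize(raw)
    was = False
    while True:
        stripped = _CANDIDATUS.sub("", text, count=1)
        if stripped == text:
            return text, was
        text, was = stripped, True


def parse_name(raw: str, rank: Rank, etymology: Optional[str] = None) -> TaxonName:
    """Parse a raw name string at the given rank.

    Whitespace is normalized and italic/quote markup stripped; a leading
    *Candidatus* designation is removed and recorded on the result.  A
    ``subsp.`` connector in trinomials is accepted and dropped.  The part
    count must match the rank (two for species, three for subspecies, one
    otherwise).
    """
    if not raw or not raw.strip():
        raise NameError_("empty name")
    text, was_ca = strip_candidatus(raw)
    if not text:
        raise NameError_("name is empty after normalization")
    parts = [p for p in text.split(" ") if p not in ("subsp.", "subsp", "ssp.")]
    expected = _PART_COUNT[rank]
    if len(parts) != expected:
        raise NameError_(
            f"a {rank.value} name must have {expected} part(s); "
            f"got {len(parts)} in {text!r}"
        )
    genus_part, epithet, subepithet = parts[0], None, None
    if rank in (Rank.SPECIES, Rank.SUBSPECIES):
        epithet = parts[1]
    if rank is Rank.SUBSPECIES:
        subepithet = parts[2]
    return TaxonName(
        rank=rank,
        genus_part=genus_part,
        epithet=epithet,
        subepithet=subepithet,
        etymology=etymology,
        was_candidatus=was_ca,
    )


def render_name(name: TaxonName) -> str:
    """Canonical plain-text rendering (the *Candidatus* prefix is never
    re-added: validation drops the provisional designation)."""
    if name.rank is Rank.SUBSPECIES:
        return f"{name.genus_part} {name.epithet} subsp. {name.subepithet}"
    if name.rank is Rank.SPECIES:
        return f"{name.genus_part} {name.epithet}"
    return name.genus_part


_GENUS_RE = re.compile(r"^[A-Z][a-z]+$")
_EPITHET_RE = re.compile(r"^[a-z]+(?:-[a-z]+)*$")


def check_orthography(name: TaxonName) -> list[NameFinding]:
    """Orthographic findings: Latin letters only, capitalized genus part,
    lowercase epithets (internal hyphens allowed in epithets only), and a
    minimum part length of two letters."""
    findings: list[NameFinding] = []

    def letters_only(part: str, allow_hyphen: bool) -> bool:
        pattern = r"^[A-Za-z-]+$" if allow_hyphen else r"^[A-Za-z]+$"
        if not re.match(pattern, part):
            return False
        if allow_hyphen and (part.startswith("-") or part.endswith("-") or "--" in part):
            return False
        return True

    def check_part(part: str, label: str, is_epithet: bool) -> None:
        core = part.replace("-", "") if is_epithet else part
        if not letters_only(part, allow_hyphen=is_epithet):
            findings.append(
                NameFinding(
                    "ORTHO_CHARSET", Severity.ERROR,
                    f"{label} {part!r} contains characters outside Latin letters",
                )
            )
        if len(core) < 2:
            findings.append(
                NameFinding(
                    "ORTHO_LENGTH", Severity.ERROR,
                    f"{label} {part!r} is shorter than two letters",
                )
            )

    check_part(name.genus_part, "genus part", is_epithet=False)
    if re.match(r"^[A-Za-z]+$", name.genus_part) and not _GENUS_RE.match(name.genus_part):
        findings.append(
            NameFinding(
                "ORTHO_CAPITALIZATION", Severity.ERROR,
                f"genus part {name.genus_part!r} must be capitalized "
                "(single leading capital, rest lowercase)",
            )
        )
    for part, label in ((name.epithet, "epithet"), (name.subepithet, "subspecies epithet")):
        if part is None:
            continue
        check_part(part, label, is_epithet=True)
        if re.match(r"^[A-Za-z-]+$", part) and not _EPITHET_RE.match(part):
            findings.append(
                NameFinding(
                    "ORTHO_CASE", Severity.ERROR,
                    f"{label} {part!r} must be all lowercase",
                )
            )
    return findings


def check_rank_suffix(name: TaxonName) -> list[NameFinding]:
    """Suffix findings: ranks above genus must carry their standard suffix;
    a genus ending in a reserved suffix draws a warning; species epithets are
    unconstrained."""
    findings: list[NameFinding] = []
    part = name.genus_part
    if name.rank in RESERVED_SUFFIXES:
        suffix = RESERVED_SUFFIXES[name.rank]
        if not part.lower().endswith(suffix):
            findings.append(
                NameFinding(
                    "SUFFIX_MISMATCH", Severity.ERROR,
                    f"{name.rank.value} name {part!r} must end in -{suffix}",
                )
            )
    elif name.rank is Rank.GENUS:
        for rank, suffix in RESERVED_SUFFIXES.items():
            if part.lower().endswith(suffix):
                findings.append(
                    NameFinding(
                        "SUFFIX_RESERVED", Severity.WARNING,
                        f"genus name {part!r} ends in -{suffix}, "
                        f"reserved for rank {rank.value}",
                    )
                )
                break
    return findings


def check_name(name: TaxonName) -> list[NameFinding]:
    """All checks, in stable order."""
    return check_orthography(name) + check_rank_suffix(name)


def homonym_key(name: TaxonName | str) -> str:
    """Canonical collision key: casefolded full name with markup removed and
    whitespace collapsed.  Two names are homonyms iff their keys are equal."""
    text = name if isinstance(name, str) else name.full_name
    return _normalize(text).casefold()


def damerau_levenshtein(a: str, b: str) -> int:
    """Edit distance counting insertions, deletions, substitutions and
    adjacent transpositions (optimal string alignment variant)."""
    la, lb = len(a), len(b)
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1 and j > 1
                and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]
            ):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        prev2, prev = prev, cur
    return prev[lb]


def orthographic_variants(
    name: TaxonName | str, candidates: Iterable[str], max_distance: int = 2
) -> list[tuple[str, int]]:
    """Advisory near-miss report: candidate keys within a small edit distance
    of the query key (potential minor orthographic variants for curator
    review; nothing is merged automatically)."""
    key = homonym_key(name) if not isinstance(name, str) else homonym_key(name)
    hits = []
    for cand in candidates:
        ck = homonym_key(cand)
        if ck == key:
            continue
        d = damerau_levenshtein(key, ck)
        if d <= max_distance:
            hits.append((cand, d))
    return sorted(hits, key=lambda t: (t[1], t[0]))
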
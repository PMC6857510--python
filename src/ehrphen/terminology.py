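"""Clinical code lists: representation, search, classification and I/O.

Phenotyping algorithms for UK linked EHR sources are built on curated lists
of controlled-terminology codes.  Five terminologies are in play: Read terms
(primary-care diagnoses and symptoms), ICD-9/ICD-10 (causes of death and
hospital diagnoses), OPCS-4 (surgical procedures) and drug codes
(prescriptions).  Each code on a list is classified by clinicians into one
of three non-overlapping categories describing what a record of that code
says about disease status:

``prevalent``
    the condition pre-dates the record (e.g. "history of heart failure");
``possible``
    suggestive but not diagnostic (e.g. "heart failure monitoring");
``incident``
    a new diagnosis, optionally sub-classified into disease subtypes.

This module provides the code-list container, pattern search over a term
dictionary, reconciliation of two independent clinician annotations, and a
diff-friendly metadata-bearing text format for dissemination.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field

from .errors import (
    CoverageMismatchError,
    DuplicateEntryError,
    FormatError,
    InvalidArgumentError,
)

TERMINOLOGIES = frozenset({"READ", "ICD9", "ICD10", "OPCS4", "DRUG"})
CATEGORIES = frozenset({"prevalent", "possible", "incident"})

#: Mandatory keys in a code-list file header, in canonical order.
METADATA_KEYS = ("name", "version", "authors", "timestamp", "terminology")


@dataclass(frozen=True, order=True)
class TermCode:
    """A single code in a controlled clinical terminology."""

    terminology: str
    code: str
    description: str = field(default="", compare=False)

    def __post_init__(self):
        if not self.code:
            raise InvalidArgumentError("TermCode.code must be non-empty")
        if self.terminology not in TERMINOLOGIES:
            raise InvalidArgumentError(
                f"unknown terminology {self.terminology!r}; "
                f"expected one of {sorted(TERMINOLOGIES)}"
            )


@dataclass(frozen=True)
class CodeListEntry:
    """A term together with its clinical category and optional subtype."""

    term: TermCode
    category: str
    subtype: str | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise InvalidArgumentError(
                f"category {self.category!r} not in {sorted(CATEGORIES)}"
            )


@dataclass
class CodeList:
    """A versioned, metadata-bearing, ordered collection of code entries.

    The unit of phenotype curation: one list per terminology, grouped into a
    phenotype by a manifest.  Metadata carries provenance (name, version,
    authors, timestamp, terminology); every entry must share the metadata
    terminology and codes must be unique.
    """

    metadata: dict[str, str]
    entries: list[CodeListEntry]

    def __post_init__(self):
        for key in METADATA_KEYS:
            if not self.metadata.get(key):
                raise FormatError(f"missing or empty metadata key {key!r}")
        term_system = self.metadata["terminology"]
        if term_system not in TERMINOLOGIES:
            raise InvalidArgumentError(f"unknown terminology {term_system!r}")
        seen: set[str] = set()
        for entry in self.entries:
            if entry.term.terminology != term_system:
                raise InvalidArgumentError(
                    f"entry {entry.term.code} has terminology "
                    f"{entry.term.terminology}, list is {term_system}"
                )
            if entry.term.code in seen:
                raise DuplicateEntryError(
                    f"duplicate code {entry.term.code!r}"
                )
            seen.add(entry.term.code)

    @property
    def codes(self) -> list[str]:
        return [e.term.code for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CodeList):
            return NotImplemented
        return self.metadata == other.metadata and self.entries == other.entries


@dataclass
class AnnotationSet:
    """One clinician's independent category assignment over a term set."""

    annotator: str
    mapping: dict[TermCode, str]

    def __post_init__(self):
        bad = {c for c in self.mapping.values() if c not in CATEGORIES}
        if bad:
            raise InvalidArgumentError(
                f"annotation categories {sorted(bad)} not in {sorted(CATEGORIES)}"
            )


def search_terms(
    dictionary,
    patterns,
    whole_word: bool = False,
) -> list[TermCode]:
    """Find dictionary terms whose description matches any search pattern.

    Search strategies for a phenotype start from clinician-supplied disease
    terms and synonyms; each pattern is matched case-insensitively against
    term descriptions, either as a plain substring (default) or at word
    boundaries (``whole_word=True``).

    Parameters
    ----------
    dictionary : iterable of TermCode
    patterns : list of str
        Search strings, e.g. ``["heart failure", "LVF", "cardiac failure"]``.
    whole_word : bool
        Require pattern to match at word boundaries.

    Returns
    -------
    list of TermCode, deterministically ordered by (terminology, code).
    """
    patterns = list(patterns)
    if not patterns:
        raise InvalidArgumentError("patterns must be a non-empty list")
    if whole_word:
        regexes = [
            re.compile(r"\b" + re.escape(p) + r"\b", re.IGNORECASE)
            for p in patterns
        ]
        matches = lambda desc: any(r.search(desc) for r in regexes)  # noqa: E731
    else:
        lowered = [p.lower() for p in patterns]
        matches = lambda desc: any(p in desc.lower() for p in lowered)  # noqa: E731

    hits = {t for t in dictionary if matches(t.description)}
    return sorted(hits, key=lambda t: (t.terminology, t.code))


def merge_annotations(
    a: AnnotationSet, b: AnnotationSet
) -> tuple[dict[TermCode, str], list[TermCode]]:
    """Reconcile two independent clinician annotations of the same terms.

    Terms on which both annotators agree enter the consensus mapping; the
    rest are returned as a disagreement list for third-party adjudication.
    Consensus and disagreements partition the term set.
    """
    terms_a, terms_b = set(a.mapping), set(b.mapping)
    if terms_a != terms_b:
        diff = sorted(terms_a ^ terms_b)
        raise CoverageMismatchError(
            f"annotation sets cover different terms ({len(diff)} differ)",
            symmetric_difference=diff,
        )
    consensus = {t: c for t, c in a.mapping.items() if b.mapping[t] == c}
    disagreements = sorted(t for t in terms_a if t not in consensus)
    return consensus, disagreements


# ---------------------------------------------------------------------------
# On-disk format: "#key: value" header lines for the five mandatory metadata
# keys, then a tab-delimited table with columns code, description, category,
# subtype.  UTF-8, diff-friendly, one terminology per file.
# ---------------------------------------------------------------------------

_COLUMNS = ("code", "description", "category", "subtype")


def write_codelist(codelist: CodeList, path) -> None:
    """Serialize a CodeList to its metadata-bearing text format."""
    buf = io.StringIO()
    for key in METADATA_KEYS:
        buf.write(f"#{key}: {codelist.metadata[key]}\n")
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(_COLUMNS)
    for entry in codelist.entries:
        writer.writerow(
            [
                entry.term.code,
                entry.term.description,
                entry.category,
                entry.subtype or "",
            ]
        )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def read_codelist(path) -> CodeList:
    """Parse a code-list file; inverse of :func:`write_codelist`."""
    metadata: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if ":" not in line:
                raise FormatError(f"malformed header line: {line!r}")
            key, _, value = line[1:].partition(":")
            metadata[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    for key in METADATA_KEYS:
        if key not in metadata:
            raise FormatError(f"missing mandatory metadata key {key!r}")

    body = lines[body_start:]
    if not body or body[0].split("\t") != list(_COLUMNS):
        raise FormatError(
            f"expected column header {list(_COLUMNS)} after metadata block"
        )
    term_system = metadata["terminology"]
    entries: list[CodeListEntry] = []
    for row in csv.reader(body[1:], delimiter="\t"):
        if not row or (len(row) == 1 and not row[0]):
            continue
        if len(row) != len(_COLUMNS):
            raise FormatError(f"expected {len(_COLUMNS)} columns, got {row!r}")
        code, description, category, subtype = row
        entries.append(
            CodeListEntry(
                term=TermCode(term_system, code, description),
                category=category,
                subtype=subtype or None,
            )
        )
    return CodeList(metadata=metadata, entries=entries)


def with_version(codelist: CodeList, version: str) -> CodeList:
    """Return a copy of the list stamped with a new version."""
    meta = dict(codelist.metadata)
    meta["version"] = version
    return CodeList(metadata=meta, entries=list(codelist.entries))
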
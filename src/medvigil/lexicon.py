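"""Antidepressant lexicon and drug-mention matching.

The packaged lexicon maps generic antidepressant names (plus an
illustrative, non-exhaustive subset of brand names) to the four major
drug families: SNRIs, SSRIs, tricyclics and tetracyclics. Mention
matching is case-insensitive on word boundaries with longest-match
priority, so a brand name that contains a generic as a substring is
reported once, as the brand.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ValidationError

FAMILIES = frozenset({"SNRI", "SSRI", "tricyclic", "tetracyclic", "other"})

_BUILTIN = "antidepressants.tsv"


@dataclass(frozen=True)
class DrugRecord:
    """One generic drug with its brand names and family label."""

    generic_name: str
    brand_names: frozenset
    family: str

    def __post_init__(self):
        if not self.generic_name:
            raise ValidationError("generic_name must be non-empty")
        if self.family not in FAMILIES:
            raise ValidationError(
                f"unknown family {self.family!r} for {self.generic_name!r}; "
                f"expected one of {sorted(FAMILIES)}"
            )


@dataclass(frozen=True)
class DrugMention:
    """A verbatim lexicon hit inside one post's text.

    ``char_span`` is a 0-based, half-open ``(start, stop)`` interval into
    the original (un-lowercased) text.
    """

    post_id: object
    matched_term: str
    generic_name: str
    char_span: tuple


def _builtin_path() -> Path:
    return Path(str(resources.files("medvigil.data").joinpath(_BUILTIN)))


def _records_from_rows(rows: Iterable[dict]) -> list:
    records = []
    seen = set()
    for row in rows:
        generic = str(row.get("generic", "")).strip().lower()
        if not generic:
            raise ValidationError("row with empty generic name")
        if generic in seen:
            raise ValidationError(f"duplicate generic name {generic!r}")
        seen.add(generic)
        brands_raw = row.get("brands", "") or ""
        if isinstance(brands_raw, str):
            brands = [b.strip().lower() for b in brands_raw.split("|") if b.strip()]
        else:
            brands = [str(b).strip().lower() for b in brands_raw if str(b).strip()]
        family = str(row.get("family", "") or "other").strip()
        records.append(
            DrugRecord(
                generic_name=generic,
                brand_names=frozenset(brands),
                family=family,
            )
        )
    return records


def load_lexicon(path=None) -> list:
    """Load drug records from TSV/JSON, or the packaged lexicon if ``path`` is None.

    TSV columns: ``generic``, ``brands`` (pipe-separated), ``family``.
    The JSON dialect is a list of objects with the same keys.

    Raises
    ------
    ValidationError
        On duplicate generic names or a family label outside the closed set.
    """
    p = _builtin_path() if path is None else Path(path)
    text = p.read_text(encoding="utf-8")
    if p.suffix.lower() == ".json":
        rows = json.loads(text) if text.strip() else []
        return _records_from_rows(rows)

    rows = []
    header = None
    for line in text.splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            header = [f.strip().lower() for f in fields]
            continue
        fields += [""] * (len(header) - len(fields))
        rows.append(dict(zip(header, fields)))
    return _records_from_rows(rows)


def term_index(lexicon: Sequence[DrugRecord]) -> dict:
    """Map every matchable lowercase term (generic or brand) to its generic."""
    index = {}
    for rec in lexicon:
        index[rec.generic_name] = rec.generic_name
        for brand in rec.brand_names:
            index.setdefault(brand, rec.generic_name)
    return index


@lru_cache(maxsize=32)
def _mention_pattern(terms: tuple) -> re.Pattern:
    # longest-first alternation makes the regex prefer the longest term
    # starting at a given position (brand containing a generic wins)
    ordered = sorted(terms, key=lambda t: (-len(t), t))
    alt = "|".join(re.escape(t) for t in ordered)
    return re.compile(rf"(?<![0-9A-Za-z])({alt})(?![0-9A-Za-z])", re.IGNORECASE)


def match_mentions(text: str, lexicon: Sequence[DrugRecord], post_id=None) -> list:
    """Find every lexicon term mentioned in ``text`` on word boundaries.

    Returns one :class:`DrugMention` per non-overlapping occurrence; no
    match yields an empty list.
    """
    index = term_index(lexicon)
    if not index:
        return []
    pattern = _mention_pattern(tuple(sorted(index)))
    mentions = []
    for m in pattern.finditer(text):
        term = m.group(1)
        mentions.append(
            DrugMention(
                post_id=post_id,
                matched_term=term,
                generic_name=index[term.lower()],
                char_span=(m.start(1), m.end(1)),
            )
        )
    return mentions
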
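"""ICD-10 cause-of-death taxonomy.

Cause categories are defined by ranges of ICD-10 code *stems* — the letter
plus two-digit prefix (``I63.9`` is matched as ``I63``).  A range such as
``V01-Y98`` is a lexicographic span across letter blocks; a bare letter
``S`` expands to ``S00-S99``.  Categories may overlap (intentional self-harm
X60-X84 also falls inside the external-causes span V01-Y98), and a death may
therefore belong to several labels; each label is analysed as its own count
series.

The built-in taxonomy covers the main- and sub-categories used in
cause-specific heat-mortality analyses of South Korean vital statistics:
all-cause, external/accidental causes, cardiovascular, respiratory,
endocrine, mental and behavioural, digestive, nervous, genitourinary and
haematological disease groups, plus their common subcategories.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

from .exceptions import ParseError

__all__ = [
    "CauseCategory",
    "parse_icd10_ranges",
    "assign_cause",
    "code_stem",
    "all_stems",
    "BUILTIN_TAXONOMY",
    "read_taxonomy",
    "write_taxonomy",
]

_STEM_RE = re.compile(r"^([A-Z])([0-9]{2})")
_TOKEN_RE = re.compile(
    r"^(?P<l1>[A-Z])(?P<d1>[0-9]{2})?(?:-(?P<l2>[A-Z])(?P<d2>[0-9]{2}))?$"
)


def code_stem(code: str) -> int:
    """Return the integer key of an ICD-10 code's letter+two-digit stem.

    The key orders stems lexicographically: ``A00`` -> 0, ``Z99`` -> 2599.
    Sub-decimal characters (``I63.9``, ``S72.0``) are ignored.
    """
    m = _STEM_RE.match(code.strip().upper())
    if not m:
        raise ParseError(f"not a valid ICD-10 code: {code!r}")
    return (ord(m.group(1)) - ord("A")) * 100 + int(m.group(2))


def _stem_str(key: int) -> str:
    return chr(ord("A") + key // 100) + f"{key % 100:02d}"


def parse_icd10_ranges(text: str) -> tuple[tuple[int, int], ...]:
    """Parse a comma-separated ICD-10 range expression into stem intervals.

    Accepted tokens: ``X`` (bare letter, expands to X00-X99), ``Xnn``
    (degenerate interval), ``Xnn-Ymm`` (lexicographic span).  Returns
    ``(start_key, end_key)`` pairs, inclusive on both ends.

    >>> parse_icd10_ranges("I20-I25")
    ((820, 825),)
    """
    intervals: list[tuple[int, int]] = []
    for raw in text.split(","):
        token = raw.strip().upper()
        if not token:
            raise ParseError(f"empty token in range expression {text!r}")
        m = _TOKEN_RE.match(token)
        if not m:
            raise ParseError(f"malformed ICD-10 range token: {token!r}")
        l1, d1, l2, d2 = m.group("l1", "d1", "l2", "d2")
        if l2 is not None:
            if d1 is None:
                raise ParseError(f"malformed ICD-10 range token: {token!r}")
            start = (ord(l1) - ord("A")) * 100 + int(d1)
            end = (ord(l2) - ord("A")) * 100 + int(d2)
        elif d1 is not None:
            start = end = (ord(l1) - ord("A")) * 100 + int(d1)
        else:  # bare letter
            start = (ord(l1) - ord("A")) * 100
            end = start + 99
        if start > end:
            raise ParseError(f"inverted ICD-10 range: {token!r}")
        intervals.append((start, end))
    return tuple(intervals)


def format_ranges(intervals: tuple[tuple[int, int], ...]) -> str:
    """Inverse of :func:`parse_icd10_ranges` (canonical text form)."""
    parts = []
    for start, end in intervals:
        if start == end:
            parts.append(_stem_str(start))
        elif start % 100 == 0 and end == start + 99:
            parts.append(_stem_str(start)[0])
        else:
            parts.append(f"{_stem_str(start)}-{_stem_str(end)}")
    return ",".join(parts)


@dataclass(frozen=True)
class CauseCategory:
    """A cause-of-death label with its ICD-10 stem ranges.

    Parameters
    ----------
    label : str
        Human-readable cause name, used as the column name of its daily
        count series.
    ranges : tuple of (int, int)
        Inclusive stem-key intervals; see :func:`parse_icd10_ranges`.
    parent : str or None
        Label of the enclosing main category, if any.
    """

    label: str
    ranges: tuple[tuple[int, int], ...] = field(default=())
    parent: str | None = None

    @classmethod
    def from_expression(
        cls, label: str, expression: str, parent: str | None = None
    ) -> "CauseCategory":
        return cls(label=label, ranges=parse_icd10_ranges(expression), parent=parent)

    def __contains__(self, code: str) -> bool:
        key = code_stem(code)
        return any(lo <= key <= hi for lo, hi in self.ranges)

    @property
    def expression(self) -> str:
        return format_ranges(self.ranges)


def assign_cause(code: str, taxonomy: list[CauseCategory]) -> list[str]:
    """Return the labels of every category containing ``code``.

    Overlap is expected: a self-harm death (X60-X84) matches both the
    self-harm subcategory and the wider external-causes span.  A code
    outside every range returns an empty list.
    """
    return [cat.label for cat in taxonomy if code in cat]


def all_stems() -> list[str]:
    """All 2,600 letter+two-digit ICD-10 stems, A00..Z99 in order."""
    return [_stem_str(k) for k in range(2600)]


def _cat(label: str, expr: str, parent: str | None = None) -> CauseCategory:
    return CauseCategory.from_expression(label, expr, parent)


#: Main- and sub-category cause taxonomy for the cause-specific analysis.
#: "All cause" spans every stem.  Self-harm is grouped (for presentation)
#: under mental and behavioural disorders although its codes sit in the
#: external-causes block.
BUILTIN_TAXONOMY: list[CauseCategory] = [
    _cat("All cause", "A00-Z99"),
    _cat("Accidental causes", "S,T,V01-Y98"),
    _cat("Transport accidents", "V01-V99", "Accidental causes"),
    _cat("All cardiovascular", "I00-I99"),
    _cat("Ischemic heart disease", "I20-I25", "All cardiovascular"),
    _cat("Hypertensive diseases", "I10-I15", "All cardiovascular"),
    _cat("Heart failure", "I50", "All cardiovascular"),
    _cat("Myocardial infarction", "I20-I23", "All cardiovascular"),
    _cat("Stroke, Cerebrovascular diseases", "I60-I69", "All cardiovascular"),
    _cat("Chronic ischemic heart disease", "I05-I09", "All cardiovascular"),
    _cat("Sudden death", "I46", "All cardiovascular"),
    _cat("Respiratory system", "J00-J99"),
    _cat("Asthma", "J45-J46", "Respiratory system"),
    _cat("COPD", "J40-J44", "Respiratory system"),
    _cat("Pneumonia", "J09-J22", "Respiratory system"),
    _cat("Endocrine, nutritional and metabolic diseases", "E00-E99"),
    _cat("Diabetes mellitus", "E10-E14", "Endocrine, nutritional and metabolic diseases"),
    _cat("Mental and behavioral disorders", "F00-F99"),
    _cat("Organic mental disorders", "F00-F09", "Mental and behavioral disorders"),
    _cat(
        "Psychoactive substance use disorders",
        "F10-F19",
        "Mental and behavioral disorders",
    ),
    _cat("Schizophrenia", "F20", "Mental and behavioral disorders"),
    _cat("Self-harm", "X60-X84", "Mental and behavioral disorders"),
    _cat("Diseases of the digestive system", "K00-K93"),
    _cat("Diseases of the nervous system", "G00-G99"),
    _cat("Diseases of the genitourinary system", "N00-N99"),
    _cat("Diseases of the blood and immune mechanism", "D50-D89"),
]


def read_taxonomy(path: str | Path) -> list[CauseCategory]:
    """Read a taxonomy CSV with columns label,icd10_ranges,parent."""
    cats: list[CauseCategory] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            parent = (row.get("parent") or "").strip() or None
            cats.append(
                CauseCategory.from_expression(
                    row["label"].strip(), row["icd10_ranges"], parent
                )
            )
    return cats


def write_taxonomy(taxonomy: list[CauseCategory], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "icd10_ranges", "parent"])
        for cat in taxonomy:
            writer.writerow([cat.label, cat.expression, cat.parent or ""])
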
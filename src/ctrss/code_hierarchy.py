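"""Hierarchy levels of mono-hierarchical diagnosis/procedure catalogues.

ICD-10-style diagnosis codes ("L40.4") and OPS-style procedure codes
("5-121.1") sit in mono-hierarchical catalogues.  Two coarsenings are
supported:

* **category level** (third hierarchy level): the syntactic prefix — three
  characters for diagnosis codes (``L40.4 -> L40``), four for procedure
  codes, chapter digit + hyphen + two digits (``5-121.1 -> 5-12``);
* **block level** (second hierarchy level): a labelled inclusive range of
  categories (``L40 -> L40…L45``, ``5-12 -> 5-08…5-16``).  Block ranges are
  catalogue content, not syntax, so they come from an explicit
  :class:`BlockMap` file.

Category extraction needs no catalogue; block mapping factors through the
category level.  A category not covered by any range falls back to itself
(with a warning) unless strict mode is on — coarsening must never drop a
code silently.
"""

from __future__ import annotations

import csv
import enum
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .cohort_io import CodeSystem, normalize_code

BLOCK_SEP = "…"


class AggregationLevel(str, enum.Enum):
    NONE = "none"
    CATEGORY = "category"
    BLOCK = "block"


class CodeMappingError(ValueError):
    """Code cannot be mapped at the requested hierarchy level."""


class BlockMapError(ValueError):
    """Invalid block-range map (overlap, misordered range, bad syntax)."""


_DX_CATEGORY = re.compile(r"^[A-Z][0-9]{2}")
_DX_CHAPTER = re.compile(r"^[A-Z]$")
_PROC_CATEGORY = re.compile(r"^[0-9]-[0-9]{2}")
_PROC_CHAPTER = re.compile(r"^[0-9]$")


def category_of(code: str, system: CodeSystem) -> str:
    """Reduce a code to its category (third hierarchy level).

    Purely syntactic: diagnosis categories are the first three characters
    (letter + two digits), procedure categories the first four (chapter
    digit, hyphen, two digits).  Codes already at or above category level
    are returned unchanged.
    """
    code = normalize_code(code)
    if system is CodeSystem.DIAGNOSIS:
        if _DX_CATEGORY.match(code):
            return code[:3]
        if _DX_CHAPTER.match(code):
            return code
    else:
        if _PROC_CATEGORY.match(code):
            return code[:4]
        if _PROC_CHAPTER.match(code):
            return code
    raise CodeMappingError(f"cannot derive {system.value} category from code {code!r}")


def category_sort_key(category: str, system: CodeSystem) -> tuple:
    """Ordering key for category codes within a system.

    Letter then two-digit number for diagnosis codes; chapter digit then
    two-digit number for procedure codes.  Plain lexicographic comparison
    would fail on mixed-width numerics, hence the parsed key.
    """
    if system is CodeSystem.DIAGNOSIS:
        m = re.fullmatch(r"([A-Z])([0-9]{2})", category)
        if not m:
            raise CodeMappingError(f"not a diagnosis category code: {category!r}")
        return (m.group(1), int(m.group(2)))
    m = re.fullmatch(r"([0-9])-([0-9]{2})", category)
    if not m:
        raise CodeMappingError(f"not a procedure category code: {category!r}")
    return (int(m.group(1)), int(m.group(2)))


@dataclass(frozen=True)
class BlockRange:
    """Inclusive range of category codes forming one catalogue block."""

    system: CodeSystem
    start: str
    end: str
    label: str = ""

    @property
    def name(self) -> str:
        """Canonical attribute rendering, e.g. ``L40…L45``."""
        return f"{self.start}{BLOCK_SEP}{self.end}"

    def contains(self, category: str) -> bool:
        key = category_sort_key(category, self.system)
        return (
            category_sort_key(self.start, self.system)
            <= key
            <= category_sort_key(self.end, self.system)
        )


@dataclass
class BlockMap:
    """Per-system ordered, non-overlapping block ranges."""

    ranges: dict[CodeSystem, list[BlockRange]] = field(default_factory=dict)

    def add(self, rng: BlockRange) -> None:
        start_key = category_sort_key(rng.start, rng.system)
        end_key = category_sort_key(rng.end, rng.system)
        if start_key > end_key:
            raise BlockMapError(f"range start after end: {rng.start}..{rng.end}")
        existing = self.ranges.setdefault(rng.system, [])
        for other in existing:
            if start_key <= category_sort_key(other.end, rng.system) and category_sort_key(
                other.start, rng.system
            ) <= end_key:
                raise BlockMapError(
                    f"overlapping {rng.system.value} ranges: "
                    f"{other.start}..{other.end} and {rng.start}..{rng.end}"
                )
        existing.append(rng)
        existing.sort(key=lambda r: category_sort_key(r.start, r.system))

    def lookup(self, category: str, system: CodeSystem) -> BlockRange | None:
        for rng in self.ranges.get(system, ()):
            if rng.contains(category):
                return rng
        return None


def block_of(
    code: str,
    system: CodeSystem,
    block_map: BlockMap,
    strict: bool = False,
) -> str:
    """Reduce a code to its block (second hierarchy level) rendering.

    Factors through :func:`category_of`.  A category outside every range
    falls back to itself with a warning; with ``strict=True`` it is an error.
    """
    category = category_of(code, system)
    rng = block_map.lookup(category, system)
    if rng is not None:
        return rng.name
    if strict:
        raise CodeMappingError(
            f"no block range covers {system.value} category {category!r}"
        )
    warnings.warn(
        f"no block range covers {system.value} category {category!r}; "
        "falling back to category level",
        stacklevel=2,
    )
    return category


def load_block_map(path: str | Path, dialect: str | None = None) -> BlockMap:
    """Load a block map from delimited text: system, range_start, range_end, label."""
    with open(path, newline="", encoding="utf-8") as fh:
        sample = fh.read(8192)
        fh.seek(0)
        if dialect is None:
            delim = "\t" if sample.count("\t") >= sample.count(",") else ","
        else:
            delim = {"comma": ",", "tab": "\t", ",": ",", "\t": "\t"}[dialect]
        reader = csv.DictReader(fh, delimiter=delim)
        required = ("system", "range_start", "range_end", "label")
        have = set(reader.fieldnames or ())
        for col in required:
            if col not in have:
                raise BlockMapError(f"{path}: missing required column {col!r}")
        bmap = BlockMap()
        for i, row in enumerate(reader, start=2):
            try:
                system = CodeSystem((row["system"] or "").strip().lower())
            except ValueError:
                raise BlockMapError(f"{path}:{i}: unknown system {row['system']!r}") from None
            try:
                bmap.add(
                    BlockRange(
                        system,
                        normalize_code(row["range_start"] or ""),
                        normalize_code(row["range_end"] or ""),
                        (row["label"] or "").strip(),
                    )
                )
            except (BlockMapError, CodeMappingError) as exc:
                raise BlockMapError(f"{path}:{i}: {exc}") from None
    return bmap


def write_block_map(block_map: BlockMap, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["system", "range_start", "range_end", "label"])
        for system in CodeSystem:
            for rng in block_map.ranges.get(system, ()):
                w.writerow([system.value, rng.start, rng.end, rng.label])


def demo_block_map() -> BlockMap:
    """Small demonstration map: eye-surgery and papulosquamous blocks plus
    pregnancy-chapter ranges — enough to exercise both code systems."""
    bmap = BlockMap()
    for system, start, end, label in [
        (CodeSystem.DIAGNOSIS, "L40", "L45", "Papulosquamous disorders"),
        (CodeSystem.DIAGNOSIS, "O20", "O29", "Maternal disorders related to pregnancy"),
        (CodeSystem.DIAGNOSIS, "O85", "O99", "Complications of the puerperium"),
        (CodeSystem.PROCEDURE, "5-08", "5-16", "Eye surgery"),
        (CodeSystem.PROCEDURE, "5-72", "5-75", "Obstetric procedures"),
    ]:
        bmap.add(BlockRange(system, start, end, label))
    return bmap
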
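"""Ordered torsion-pattern hierarchy.

A torsion library is an ordered list of SMARTS patterns, each describing a
four-atom dihedral motif via atom maps 1-4.  The order encodes match
priority: when a central bond matches several patterns, only the
highest-priority (lowest rank) one claims it.  Patterns are grouped into
hierarchy classes named after the elements of the central (map-2/map-3)
bond -- C-C, C-O, C-S, N-C, S-N, S-S -- plus a general G-G fallback class.

The central bond of every pattern must be constrained to be a single,
non-ring bond (acyclic rotatable bonds are the only bonds for which a
torsional-angle distribution is meaningful here).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from rdkit import Chem

HIERARCHY_CLASSES = ("C-C", "C-O", "C-S", "N-C", "S-N", "S-S", "G-G")

_SYMBOL_TO_Z = {"C": 6, "N": 7, "O": 8, "S": 16}


class LibraryError(ValueError):
    """Raised when a torsion library or one of its patterns is invalid."""


def normalize_class(label: str) -> str:
    """Map a hierarchy-class label onto its canonical ASCII form (e.g. ``C-C``).

    Accepts en-dashes and surrounding whitespace so labels copied from
    documents round-trip.
    """
    return label.strip().replace("–", "-").replace("—", "-")


@dataclass(frozen=True)
class TorsionPattern:
    """One SMARTS torsion motif in the hierarchy."""

    pattern_id: str
    smarts: str
    order_index: int
    hierarchy_class: str
    query: Chem.Mol | None = field(default=None, compare=False, repr=False)

    def with_query(self) -> "TorsionPattern":
        """Return a copy with the parsed RDKit query molecule attached."""
        if self.query is not None:
            return self
        q = Chem.MolFromSmarts(self.smarts)
        return TorsionPattern(
            self.pattern_id, self.smarts, self.order_index,
            self.hierarchy_class, q,
        )

    def map_indices(self) -> dict[int, int]:
        """Atom-map number -> query atom index for the parsed SMARTS."""
        q = self.with_query().query
        if q is None:
            raise LibraryError(f"pattern {self.pattern_id!r}: SMARTS does not parse")
        return {a.GetAtomMapNum(): a.GetIdx() for a in q.GetAtoms() if a.GetAtomMapNum()}


@dataclass(frozen=True)
class ValidationReport:
    pattern_id: str
    valid: bool
    reasons: tuple[str, ...]


def _central_bond_constrained(query: Chem.Mol, idx2: int, idx3: int) -> bool:
    """True if the query bond between map-2 and map-3 atoms requires a
    single, non-ring bond.

    The check inspects RDKit's query description tree: it must assert
    ``BondOrder 1`` positively, assert ``BondInRing`` negatively, and contain
    no disjunction (a plain/default SMARTS bond is 'single or aromatic' and
    therefore under-constrained).
    """
    bond = query.GetBondBetweenAtoms(idx2, idx3)
    if bond is None:
        return False
    desc = bond.DescribeQuery()
    tokens = [line.strip().split() for line in desc.splitlines() if line.strip()]
    has_single = any(t[0] == "BondOrder" and t[1] == "1" and t[2] == "=" for t in tokens if len(t) >= 3)
    has_not_ring = any(t[0] == "BondInRing" and "!=" in t for t in tokens)
    has_or = any(t[0] == "BondOr" for t in tokens)
    return has_single and has_not_ring and not has_or


def validate_pattern(pattern: TorsionPattern) -> ValidationReport:
    """Check a single pattern against the hierarchy's structural rules.

    Violations collected (none raise):

    * SMARTS must parse.
    * ``N_lp`` lone-pair SMARTS extensions are not supported and rejected.
    * Exactly the four atom maps 1,2,3,4 must be present (patterns that map
      only three atoms do not define a dihedral).
    * The central (map-2/map-3) bond must be constrained single + non-ring.
    * The hierarchy class must be known, and for element-specific classes
      the central atoms' element symbols must match the declared class
      where the SMARTS determines them (the G-G fallback class is exempt).
    """
    reasons: list[str] = []
    cls = normalize_class(pattern.hierarchy_class)
    if cls not in HIERARCHY_CLASSES:
        reasons.append(f"unknown hierarchy class {pattern.hierarchy_class!r}")
    if "N_lp" in pattern.smarts:
        reasons.append("N_lp SMARTS extension not supported")
        return ValidationReport(pattern.pattern_id, False, tuple(reasons))
    p = pattern.with_query()
    if p.query is None:
        reasons.append("SMARTS does not parse")
        return ValidationReport(pattern.pattern_id, False, tuple(reasons))
    maps = sorted(a.GetAtomMapNum() for a in p.query.GetAtoms() if a.GetAtomMapNum())
    if maps != [1, 2, 3, 4]:
        if len(maps) == 3:
            reasons.append("three mapped atoms only; four required")
        else:
            reasons.append(f"atom maps {maps} != [1, 2, 3, 4]")
    else:
        idx = p.map_indices()
        if not _central_bond_constrained(p.query, idx[2], idx[3]):
            reasons.append("central bond unconstrained (must be single and non-ring)")
        if cls in HIERARCHY_CLASSES and cls != "G-G":
            want = sorted(_SYMBOL_TO_Z[s] for s in cls.split("-"))
            got = [p.query.GetAtomWithIdx(idx[2]).GetAtomicNum(),
                   p.query.GetAtomWithIdx(idx[3]).GetAtomicNum()]
            if all(z > 0 for z in got) and sorted(got) != want:
                reasons.append(
                    f"central bond elements do not match class {cls}"
                )
    return ValidationReport(pattern.pattern_id, not reasons, tuple(reasons))


class TorsionLibrary:
    """An ordered, validated sequence of :class:`TorsionPattern`.

    Iteration order is by ``order_index`` (ascending), which defines the
    first-match priority used during extraction.
    """

    def __init__(self, patterns: Iterable[TorsionPattern]):
        pats = sorted(patterns, key=lambda p: p.order_index)
        ranks = [p.order_index for p in pats]
        if len(set(ranks)) != len(ranks):
            dupes = sorted({r for r in ranks if ranks.count(r) > 1})
            raise LibraryError(f"duplicate order_index values: {dupes}")
        ids = [p.pattern_id for p in pats]
        if len(set(ids)) != len(ids):
            raise LibraryError("duplicate pattern_id values")
        self._patterns: tuple[TorsionPattern, ...] = tuple(p.with_query() for p in pats)

    def __iter__(self) -> Iterator[TorsionPattern]:
        return iter(self._patterns)

    def __len__(self) -> int:
        return len(self._patterns)

    def __getitem__(self, i: int) -> TorsionPattern:
        return self._patterns[i]

    def get(self, pattern_id: str) -> TorsionPattern:
        for p in self._patterns:
            if p.pattern_id == pattern_id:
                return p
        raise KeyError(pattern_id)

    @property
    def metadata(self) -> dict:
        counts = Counter(normalize_class(p.hierarchy_class) for p in self._patterns)
        return {
            "n_patterns": len(self._patterns),
            "class_counts": {c: counts.get(c, 0) for c in HIERARCHY_CLASSES},
        }


def load_library(
    records: Sequence[tuple],
    on_invalid: str = "raise",
) -> TorsionLibrary:
    """Build a library from ``(smarts, hierarchy_class, rank)`` records.

    A fourth element, if present, is taken as the pattern id; otherwise ids
    are synthesized from the rank.  Every pattern is validated; with
    ``on_invalid='raise'`` the first violation aborts with the pattern named,
    with ``'skip'`` invalid patterns are silently dropped (useful when
    loading an external file containing e.g. unsupported SMARTS extensions).
    """
    if on_invalid not in ("raise", "skip"):
        raise ValueError("on_invalid must be 'raise' or 'skip'")
    patterns: list[TorsionPattern] = []
    for rec in records:
        if len(rec) == 3:
            smarts, cls, rank = rec
            pid = f"T{int(rank):04d}"
        else:
            smarts, cls, rank, pid = rec[:4]
        pat = TorsionPattern(str(pid), str(smarts), int(rank), normalize_class(str(cls)))
        report = validate_pattern(pat)
        if not report.valid:
            if on_invalid == "raise":
                raise LibraryError(
                    f"pattern {pat.pattern_id!r} invalid: " + "; ".join(report.reasons)
                )
            continue
        patterns.append(pat)
    return TorsionLibrary(patterns)


def filter_library(
    library: TorsionLibrary,
    match_counts: Mapping[str, int],
    min_matches: int = 50,
    drop_classes: frozenset[str] | set[str] = frozenset({"G-G"}),
) -> TorsionLibrary:
    """Drop under-populated patterns and whole hierarchy classes.

    A pattern survives if its match count (0 when absent from
    ``match_counts``) is at least ``min_matches`` and its class is not in
    ``drop_classes``.  Relative order among survivors is preserved, so
    filtering commutes with first-match extraction semantics.
    """
    drop = {normalize_class(c) for c in drop_classes}
    keep = [
        p for p in library
        if match_counts.get(p.pattern_id, 0) >= min_matches
        and normalize_class(p.hierarchy_class) not in drop
    ]
    return TorsionLibrary(keep)


# -- delimited-file round trip ------------------------------------------------
#
# Format: UTF-8 text, one pattern per line, tab- (or multi-space-)separated
# columns  rank  class  smarts  [pattern_id];  '#' starts a comment.

def read_library(path: str | Path, on_invalid: str = "raise") -> TorsionLibrary:
    records = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"\t+| {2,}", line)
        if len(parts) < 3:
            raise LibraryError(f"{path}:{lineno}: expected 'rank class smarts [id]'")
        rank, cls, smarts = parts[0], parts[1], parts[2]
        rec = (smarts, cls, int(rank)) if len(parts) == 3 else (smarts, cls, int(rank), parts[3])
        records.append(rec)
    return load_library(records, on_invalid=on_invalid)


def write_library(library: TorsionLibrary, path: str | Path) -> None:
    lines = ["# rank\tclass\tsmarts\tpattern_id"]
    for p in library:
        lines.append(f"{p.order_index}\t{p.hierarchy_class}\t{p.smarts}\t{p.pattern_id}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def fixture_library() -> TorsionLibrary:
    """The small bundled library: published motif SMARTS plus synthetic
    fillers covering every hierarchy class (see ``data/fixture_library.tsv``)."""
    ref = resources.files("torsionprofiles.data").joinpath("fixture_library.tsv")
    with resources.as_file(ref) as path:
        return read_library(path)
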
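"""Hierarchical classification trees for ICD-10 and ATC codes.

Both coding systems are rooted trees: ICD-10 descends chapter -> block ->
3-character category -> subcategory, ATC descends through its five levels
(1, 3, 4, 5 and 7 characters).  Every non-root node is a candidate "cut"
for the tree-based scan statistic: the set of codes at or below the node.

The module also implements the two preprocessing rules applied to event
streams before scanning:

* granularity masking -- registry extracts often deliver some chapters
  only at a coarsened level (e.g. eye diseases at chapter level, most ATC
  classes truncated to five characters); :func:`apply_mask` coarsens a
  raw code according to a configurable rule set;
* chapter exclusion -- chapters judged unrelated to the research question
  (injuries S00-T98, external causes V01-Y98, contact factors Z00-Z99 by
  default) are dropped wholesale.

Codes are normalised on ingestion by upper-casing and stripping dots, so
the dotted ("H66.0") and the Swedish dot-free ("H660") dialects coincide.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

__all__ = [
    "ClassificationSystem",
    "TreeNode",
    "ClassificationTree",
    "Cut",
    "MaskRule",
    "MaskRuleSet",
    "TreeStructureError",
    "UnknownCodeError",
    "normalize_code",
    "build_tree",
    "read_dictionary",
    "write_dictionary",
    "enumerate_cuts",
    "apply_mask",
    "mask_events",
    "exclude_chapters",
    "DEFAULT_EXCLUDED_CHAPTERS",
    "default_icd10_mask_rules",
    "default_atc_mask_rules",
]


class ClassificationSystem(str, Enum):
    """The two supported coding systems."""

    ICD10 = "ICD10"
    ATC = "ATC"


class TreeStructureError(ValueError):
    """Raised when a code dictionary does not describe a valid rooted tree."""


class UnknownCodeError(KeyError):
    """Raised when a code cannot be resolved on the tree at any granularity."""


_DASHES = re.compile(r"[–—-]")  # en dash, em dash, hyphen


def normalize_code(code: str) -> str:
    """Upper-case, strip whitespace and remove dots from a raw code."""
    return str(code).strip().upper().replace(".", "")


def _split_range(code: str) -> tuple[str, str]:
    """Split a range code such as ``"H65–H75"`` into its endpoints.

    A plain code is treated as the degenerate range [code, code].
    """
    parts = [p for p in _DASHES.split(code) if p]
    if len(parts) == 2 and len(parts[0]) == len(parts[1]):
        return parts[0], parts[1]
    return code, code


@dataclass(frozen=True)
class TreeNode:
    code: str
    parent_code: Optional[str]
    label: str = ""
    level: str = ""


@dataclass(frozen=True)
class Cut:
    """A candidate cluster: a tree node together with the leaves beneath it."""

    node_code: str
    leaves: frozenset[str]


class ClassificationTree:
    """A validated rooted hierarchy of ICD-10 or ATC codes.

    Construction checks that codes are unique, that exactly one root
    exists, that every parent reference resolves, and that every node is
    reachable from the root (which rules out cycles).
    """

    def __init__(self, system: ClassificationSystem, nodes: Iterable[TreeNode]):
        self.system = ClassificationSystem(system)
        self._nodes: dict[str, TreeNode] = {}
        self._children: dict[str, list[str]] = {}
        roots: list[str] = []
        for node in nodes:
            if node.code in self._nodes:
                raise TreeStructureError(f"duplicate code {node.code!r}")
            self._nodes[node.code] = node
            self._children.setdefault(node.code, [])
            if node.parent_code is None:
                roots.append(node.code)
        if len(roots) != 1:
            raise TreeStructureError(
                f"expected exactly one root, found {len(roots)}: {roots!r}"
            )
        self.root = roots[0]
        for node in self._nodes.values():
            if node.parent_code is None:
                continue
            if node.parent_code not in self._nodes:
                raise TreeStructureError(
                    f"node {node.code!r} references absent parent {node.parent_code!r}"
                )
            self._children[node.parent_code].append(node.code)
        for kids in self._children.values():
            kids.sort()
        # reachability from the root doubles as the cycle check
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            code = stack.pop()
            if code in seen:
                raise TreeStructureError(f"cycle detected at {code!r}")
            seen.add(code)
            stack.extend(self._children[code])
        if len(seen) != len(self._nodes):
            orphans = sorted(set(self._nodes) - seen)
            raise TreeStructureError(f"nodes unreachable from root: {orphans!r}")
        self._leaves_cache: dict[str, frozenset[str]] = {}

    # -- basic queries ---------------------------------------------------
    def __contains__(self, code: str) -> bool:
        return code in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, code: str) -> TreeNode:
        try:
            return self._nodes[code]
        except KeyError:
            raise UnknownCodeError(code) from None

    def children(self, code: str) -> list[str]:
        return list(self._children[code])

    def is_leaf(self, code: str) -> bool:
        return not self._children[code]

    def ancestors(self, code: str, include_self: bool = True) -> list[str]:
        """Path from ``code`` up to (but excluding) the root."""
        out = []
        cur: Optional[str] = code if include_self else self.node(code).parent_code
        while cur is not None and cur != self.root:
            out.append(cur)
            cur = self.node(cur).parent_code
        return out

    def descendants(self, code: str, include_self: bool = True) -> list[str]:
        out = [code] if include_self else []
        stack = self.children(code)
        while stack:
            c = stack.pop()
            out.append(c)
            stack.extend(self._children[c])
        return out

    def leaves_under(self, code: str) -> frozenset[str]:
        cached = self._leaves_cache.get(code)
        if cached is not None:
            return cached
        kids = self._children[self.node(code).code]
        if not kids:
            leaves = frozenset([code])
        else:
            leaves = frozenset().union(*(self.leaves_under(k) for k in kids))
        self._leaves_cache[code] = leaves
        return leaves

    @property
    def leaf_codes(self) -> list[str]:
        return sorted(c for c in self._nodes if self.is_leaf(c))

    def nodes_at_level(self, level: str) -> list[str]:
        return sorted(c for c, n in self._nodes.items() if n.level == level)

    def iter_preorder(self) -> Iterator[str]:
        """Depth-first preorder with lexicographically sorted siblings."""
        stack = list(reversed(self._children[self.root]))
        while stack:
            code = stack.pop()
            yield code
            stack.extend(reversed(self._children[code]))

    # -- resolution ------------------------------------------------------
    def resolve(self, code: str) -> Optional[str]:
        """Resolve a (normalised) code to a tree node, trying truncations.

        A code absent from the tree is matched against range nodes
        (blocks/chapters such as ``"H65–H75"``) on its 3-character stem,
        then against prefix truncations, so raw subcategory codes land on
        whichever granularity the tree carries.  Returns ``None`` when
        nothing matches.
        """
        if code in self._nodes:
            return code
        # prefix truncations (ATC levels, ICD category from subcategory)
        for cut_len in range(len(code) - 1, 2, -1):
            if code[:cut_len] in self._nodes:
                return code[:cut_len]
        # range containment on the 3-character stem
        stem = code[:3]
        best: Optional[str] = None
        best_span = None
        for node_code in self._nodes:
            lo, hi = _split_range(node_code)
            if lo == hi or len(lo) != 3:
                continue
            if lo <= stem <= hi:
                span = (hi, lo)
                if best is None or span < best_span:  # narrowest range wins
                    best, best_span = node_code, span
        return best


def build_tree(
    dictionary_table: pd.DataFrame, system: ClassificationSystem
) -> ClassificationTree:
    """Build a validated :class:`ClassificationTree` from a code dictionary.

    ``dictionary_table`` needs columns ``code``, ``parent`` and optionally
    ``label`` and ``level``; the root row has an empty/missing parent.
    """
    required = {"code", "parent"}
    missing = required - set(dictionary_table.columns)
    if missing:
        raise TreeStructureError(f"dictionary table missing columns {sorted(missing)}")
    nodes = []
    for row in dictionary_table.itertuples(index=False):
        parent = getattr(row, "parent")
        parent = None if (pd.isna(parent) or str(parent).strip() == "") else str(parent)
        nodes.append(
            TreeNode(
                code=str(row.code),
                parent_code=parent,
                label=str(getattr(row, "label", "") or ""),
                level=str(getattr(row, "level", "") or ""),
            )
        )
    return ClassificationTree(system, nodes)


def read_dictionary(path) -> pd.DataFrame:
    """Read a TSV code dictionary with columns (code, parent, label, level)."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).replace(
        {"": None}
    )


def write_dictionary(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def enumerate_cuts(tree: ClassificationTree) -> list[Cut]:
    """One cut per non-root node, in depth-first code-lexicographic order."""
    return [Cut(code, tree.leaves_under(code)) for code in tree.iter_preorder()]


# ---------------------------------------------------------------------------
# Granularity masking
# ---------------------------------------------------------------------------

_GRANULARITIES = ("chapter", "block", "category", "atc5", "full")


@dataclass(frozen=True)
class MaskRule:
    """Coarsen codes whose 3-character stem (ICD) or first letter (ATC)
    falls in ``[lo, hi]`` to the given target granularity."""

    lo: str
    hi: str
    granularity: str

    def __post_init__(self):
        if self.granularity not in _GRANULARITIES:
            raise ValueError(f"unknown granularity {self.granularity!r}")
        if self.lo > self.hi:
            raise ValueError(f"inverted range {self.lo!r}-{self.hi!r}")

    def matches(self, code: str) -> bool:
        key = code[: len(self.lo)]
        return self.lo <= key <= self.hi


@dataclass
class MaskRuleSet:
    rules: Sequence[MaskRule] = field(default_factory=tuple)

    def __post_init__(self):
        for i, a in enumerate(self.rules):
            for b in self.rules[i + 1 :]:
                if len(a.lo) == len(b.lo) and not (a.hi < b.lo or b.hi < a.lo):
                    raise ValueError(f"overlapping mask rules {a} / {b}")

    def match(self, code: str) -> Optional[MaskRule]:
        for rule in self.rules:
            if rule.matches(code):
                return rule
        return None


def default_icd10_mask_rules() -> MaskRuleSet:
    """Masking applied to the ICD-10 stream by default.

    Eye diseases (H00-H59) and perinatal conditions (P00-P96) arrive at
    chapter level only; congenital malformations (Q00-Q99) at block
    level; ear diseases (H60-H95) at 3-character category level.  All
    other chapters pass through at full granularity.
    """
    return MaskRuleSet(
        (
            MaskRule("H00", "H59", "chapter"),
            MaskRule("P00", "P96", "chapter"),
            MaskRule("Q00", "Q99", "block"),
            MaskRule("H60", "H95", "category"),
        )
    )


def default_atc_mask_rules() -> MaskRuleSet:
    """Default ATC masking: anti-infectives (class J) keep full 7-character
    detail; classes A, B, C, G, H, L, M, N are truncated to 5 characters;
    the incompletely characterised classes D, P, R, S, V are coarsened to
    3-character therapeutic subgroups."""
    return MaskRuleSet(
        (
            MaskRule("J", "J", "full"),
            MaskRule("A", "C", "atc5"),
            MaskRule("G", "H", "atc5"),
            MaskRule("L", "N", "atc5"),
            MaskRule("D", "D", "category"),
            MaskRule("P", "P", "category"),
            MaskRule("R", "S", "category"),
            MaskRule("V", "V", "category"),
        )
    )


def _level_node_containing(
    tree: ClassificationTree, stem: str, level: str
) -> Optional[str]:
    for node_code in tree.nodes_at_level(level):
        lo, hi = _split_range(node_code)
        if len(lo) != 3:
            continue
        if lo <= stem <= hi:
            return node_code
    return None


def apply_mask(
    code: str,
    system: ClassificationSystem,
    rules: MaskRuleSet,
    tree: ClassificationTree,
) -> str:
    """Coarsen ``code`` per the first matching rule and resolve it on the tree.

    Codes matching no rule pass through unchanged (but must resolve on
    the tree).  Raises :class:`UnknownCodeError` when the coarsened code
    cannot be located even at chapter level.
    """
    norm = normalize_code(code)
    rule = rules.match(norm)
    target: str
    if rule is None or rule.granularity == "full":
        target = norm
    elif rule.granularity == "category":
        target = norm[:3]
    elif rule.granularity == "atc5":
        target = norm[:5]
    else:  # chapter / block: map onto the tree's range node
        node = _level_node_containing(tree, norm[:3], rule.granularity)
        if node is None:
            raise UnknownCodeError(
                f"{code!r}: no {rule.granularity}-level node covers it"
            )
        return node
    resolved = tree.resolve(target)
    if resolved is None:
        raise UnknownCodeError(f"{code!r} (as {target!r}) not on the {system} tree")
    return resolved


def mask_events(
    events: pd.DataFrame,
    system: ClassificationSystem,
    rules: MaskRuleSet,
    tree: ClassificationTree,
    code_column: str = "code",
) -> tuple[pd.DataFrame, int]:
    """Apply :func:`apply_mask` to an event table; unknown codes are dropped.

    Returns the masked table and the number of dropped events.
    """
    cache: dict[str, Optional[str]] = {}

    def _mask(raw: str) -> Optional[str]:
        if raw not in cache:
            try:
                cache[raw] = apply_mask(raw, system, rules, tree)
            except UnknownCodeError:
                cache[raw] = None
        return cache[raw]

    masked = events[code_column].map(_mask)
    keep = masked.notna()
    out = events.loc[keep].copy()
    out[code_column] = masked[keep]
    return out, int((~keep).sum())


#: ICD-10 chapters excluded from all hospital-visit analyses: injuries and
#: poisoning (S00–T98), external causes (V01–Y98) and factors influencing
#: health status / contact with services (Z00–Z99).
DEFAULT_EXCLUDED_CHAPTERS: tuple[tuple[str, str], ...] = (
    ("S00", "T98"),
    ("V01", "Y98"),
    ("Z00", "Z99"),
)


def exclude_chapters(
    events: pd.DataFrame,
    excluded: Sequence[tuple[str, str]] = DEFAULT_EXCLUDED_CHAPTERS,
    code_column: str = "code",
) -> tuple[pd.DataFrame, int]:
    """Drop events whose ICD chapter falls in an excluded range.

    Returns the filtered table and the number of removed events.
    """
    if events.empty:
        return events.copy(), 0
    stems = events[code_column].map(lambda c: normalize_code(c)[:3])
    drop = pd.Series(False, index=events.index)
    for lo, hi in excluded:
        drop |= (stems >= lo) & (stems <= hi)
    return events.loc[~drop].copy(), int(drop.sum())
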
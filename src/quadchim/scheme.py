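"""Multiplexing schemes and chimera classification.

A quaddRAD-style experiment tags every sample with four barcodes: a fixed
pair of *inner* inline tags (one at the start of read 1, one at the start of
read 2) identifying the sample within its pool, and a combination of *outer*
index tags identifying the pool ("multiplexed group") on the lane. Because
inner tags are used in fixed pairs, any read whose observed inner-tag
combination was never used in its group is an artifact — a chimera or a
misassigned molecule — and the mismatch between design and observation can be
classified:

* GENUINE  — the combination is one of the group's fixed pairs.
* TYPE_I   — both tags are used in the group, but never in this pairing.
* TYPE_II  — exactly one of the two tags is used in the group.
* TYPE_III — neither tag is used in the group and the combination is not a
  fixed pair anywhere in the scheme.
* TYPE_IV  — neither tag is used in the group, but the combination *is* a
  fixed pair used in some other group: an intact molecule carrying the wrong
  outer index (e.g. an index hop). In a group that uses every fixed pair,
  such molecules are indistinguishable from genuine reads.

Types II-IV are only observable in groups that use fewer than all fixed
pairs; detectability is an emergent property of the rules, not special-cased.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd
import yaml


class SchemeError(ValueError):
    """Structurally invalid scheme definition."""


class UnknownTagError(KeyError):
    """A tag label/sequence absent from the scheme (barcode-list mismatch)."""


class ChimeraClass(str, Enum):
    GENUINE = "genuine"
    TYPE_I = "type_I"
    TYPE_II = "type_II"
    TYPE_III = "type_III"
    TYPE_IV = "type_IV"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CHIMERA_CLASSES = tuple(ChimeraClass)


@dataclass(frozen=True)
class BarcodeTag:
    """An inline tag: a short fixed-length ACGT word plus a label."""

    label: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence or any(b not in "ACGT" for b in self.sequence):
            raise SchemeError(f"tag {self.label!r}: sequence must be ACGT only")


@dataclass(frozen=True)
class InnerPair:
    """A fixed (read1-side, read2-side) pair of inner tags."""

    i5: BarcodeTag
    i7: BarcodeTag

    @property
    def labels(self) -> tuple[str, str]:
        return (self.i5.label, self.i7.label)


@dataclass(frozen=True)
class MultiplexGroup:
    """Samples sharing one outer-index combination, one inner pair each."""

    group_id: str
    outer_combo: tuple[str, str]
    inner_pairs: tuple[InnerPair, ...]
    library_id: str

    def __post_init__(self) -> None:
        if len(set(p.labels for p in self.inner_pairs)) != len(self.inner_pairs):
            raise SchemeError(f"group {self.group_id}: duplicate inner pairs")
        if not self.inner_pairs:
            raise SchemeError(f"group {self.group_id}: needs >= 1 inner pair")

    @property
    def n_samples(self) -> int:
        return len(self.inner_pairs)

    @property
    def i5_labels(self) -> frozenset[str]:
        return frozenset(p.i5.label for p in self.inner_pairs)

    @property
    def i7_labels(self) -> frozenset[str]:
        return frozenset(p.i7.label for p in self.inner_pairs)

    @property
    def pair_labels(self) -> frozenset[tuple[str, str]]:
        return frozenset(p.labels for p in self.inner_pairs)


class LibraryType(str, Enum):
    A = "A"  # indexing PCR on each sample individually: sequencing artifacts only
    B = "B"  # indexing PCR on the pooled group: PCR + sequencing artifacts


@dataclass(frozen=True)
class LibraryDesign:
    library_id: str
    library_type: LibraryType
    groups: tuple[MultiplexGroup, ...]

    def __post_init__(self) -> None:
        combos = [g.outer_combo for g in self.groups]
        if len(set(combos)) != len(combos):
            raise SchemeError(f"library {self.library_id}: duplicate outer combos")


@dataclass(frozen=True)
class ExperimentScheme:
    """The whole design: libraries -> groups -> fixed inner pairs."""

    libraries: tuple[LibraryDesign, ...]
    global_pairs: tuple[InnerPair, ...]
    outer_tags: tuple[str, ...] = ()
    tag_length: int = 8

    def __post_init__(self) -> None:
        tags = [p.i5 for p in self.global_pairs] + [p.i7 for p in self.global_pairs]
        if len({t.label for t in tags}) != len(tags):
            raise SchemeError("every tag in global_pairs must have a distinct label")
        if len({t.sequence for t in tags}) != len(tags):
            raise SchemeError("every tag in global_pairs must have a distinct sequence")
        for t in tags:
            if len(t.sequence) != self.tag_length:
                raise SchemeError(
                    f"tag {t.label}: length {len(t.sequence)} != declared "
                    f"tag_length {self.tag_length}"
                )
        global_labels = {p.labels for p in self.global_pairs}
        seen_group_ids: set[str] = set()
        for lib in self.libraries:
            for g in lib.groups:
                if g.group_id in seen_group_ids:
                    raise SchemeError(f"duplicate group id {g.group_id}")
                seen_group_ids.add(g.group_id)
                if not g.pair_labels <= global_labels:
                    raise SchemeError(
                        f"group {g.group_id}: pairs not a subset of global pairs"
                    )

    # -- lookups -----------------------------------------------------------

    @property
    def i5_tags(self) -> dict[str, BarcodeTag]:
        return {p.i5.label: p.i5 for p in self.global_pairs}

    @property
    def i7_tags(self) -> dict[str, BarcodeTag]:
        return {p.i7.label: p.i7 for p in self.global_pairs}

    @property
    def pair_labels(self) -> frozenset[tuple[str, str]]:
        return frozenset(p.labels for p in self.global_pairs)

    def groups(self) -> list[MultiplexGroup]:
        return [g for lib in self.libraries for g in lib.groups]

    def group(self, group_id: str) -> MultiplexGroup:
        for lib in self.libraries:
            for g in lib.groups:
                if g.group_id == group_id:
                    return g
        raise SchemeError(f"unknown group {group_id!r}")

    def library(self, library_id: str) -> LibraryDesign:
        for lib in self.libraries:
            if lib.library_id == library_id:
                return lib
        raise SchemeError(f"unknown library {library_id!r}")

    def library_of_group(self, group_id: str) -> LibraryDesign:
        for lib in self.libraries:
            if any(g.group_id == group_id for g in lib.groups):
                return lib
        raise SchemeError(f"unknown group {group_id!r}")

    def groups_using_pair(self, pair_labels: tuple[str, str]) -> list[MultiplexGroup]:
        return [g for g in self.groups() if pair_labels in g.pair_labels]


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_combination(
    i5_label: str,
    i7_label: str,
    group: MultiplexGroup,
    scheme: ExperimentScheme,
) -> ChimeraClass:
    """Classify one observed (i5, i7) inner-tag combination within ``group``."""
    if i5_label not in scheme.i5_tags:
        raise UnknownTagError(f"unknown i5 tag {i5_label!r}: not in scheme")
    if i7_label not in scheme.i7_tags:
        raise UnknownTagError(f"unknown i7 tag {i7_label!r}: not in scheme")
    combo = (i5_label, i7_label)
    if combo in group.pair_labels:
        return ChimeraClass.GENUINE
    i5_used = i5_label in group.i5_labels
    i7_used = i7_label in group.i7_labels
    if i5_used and i7_used:
        return ChimeraClass.TYPE_I
    if i5_used or i7_used:
        return ChimeraClass.TYPE_II
    if combo in scheme.pair_labels and any(
        combo in g.pair_labels for g in scheme.groups() if g.group_id != group.group_id
    ):
        return ChimeraClass.TYPE_IV
    return ChimeraClass.TYPE_III


def enumerate_group_combinations(
    group: MultiplexGroup, scheme: ExperimentScheme
) -> pd.DataFrame:
    """All P x P ordered (i5, i7) combinations of the scheme, classified.

    P is the number of global fixed pairs; the returned frame has exactly
    P*P rows with columns ``i5``, ``i7``, ``chimera_class``.
    """
    rows = [
        (i5, i7, classify_combination(i5, i7, group, scheme))
        for i5 in scheme.i5_tags
        for i7 in scheme.i7_tags
    ]
    return pd.DataFrame(rows, columns=["i5", "i7", "chimera_class"])


def detectable_types(
    group: MultiplexGroup, scheme: ExperimentScheme
) -> set[ChimeraClass]:
    """The set of classes occurring among the group's enumerated combinations."""
    table = enumerate_group_combinations(group, scheme)
    return set(table["chimera_class"])


def count_type_iv_cases(scheme: ExperimentScheme) -> tuple[int, int]:
    """(pos_chimIV, total_chimIV) case counts for the type-IV estimator.

    A *case* is a (group g, fixed pair p) with p used in at least one group
    other than g: a molecule of pair p index-hopped into g would land there as
    a type-IV chimera (identifiable iff neither of p's tags is used in g,
    otherwise misassigned). ``pos_chimIV`` counts all cases, ``total_chimIV``
    the identifiable subset.
    """
    pos = total = 0
    groups = scheme.groups()
    for g in groups:
        for p in scheme.global_pairs:
            used_elsewhere = any(
                p.labels in other.pair_labels
                for other in groups
                if other.group_id != g.group_id
            )
            if not used_elsewhere:
                continue
            pos += 1
            if (
                classify_combination(p.i5.label, p.i7.label, g, scheme)
                is ChimeraClass.TYPE_IV
            ):
                total += 1
    return pos, total


def audit_scheme(scheme: ExperimentScheme) -> dict:
    """Design-derived counts: group totals, detectability, combination space."""
    groups = scheme.groups()
    n_pairs = len(scheme.global_pairs)
    type_i_only = type_iv_detectable = 0
    for g in groups:
        det = detectable_types(g, scheme)
        if det <= {ChimeraClass.GENUINE, ChimeraClass.TYPE_I}:
            type_i_only += 1
        if ChimeraClass.TYPE_IV in det:
            type_iv_detectable += 1
    combos = n_pairs * n_pairs
    pct_chimeric = 100.0 * (combos - n_pairs) / combos if combos else float("nan")
    pos, total = count_type_iv_cases(scheme)
    return {
        "n_libraries": len(scheme.libraries),
        "n_groups": len(groups),
        "n_samples": sum(g.n_samples for g in groups),
        "n_inner_pairs": n_pairs,
        "n_inner_tags": 2 * n_pairs,
        "n_outer_tags": len(scheme.outer_tags),
        "n_tag_combinations": 2 * n_pairs * len(scheme.outer_tags),
        "combinations_per_full_group": combos,
        "pct_chimeric_combinations_full_group": round(pct_chimeric, 1),
        "n_groups_type_i_only": type_i_only,
        "n_groups_type_iv_detectable": type_iv_detectable,
        "pos_chimIV_cases": pos,
        "total_chimIV_cases": total,
    }


# ---------------------------------------------------------------------------
# Reference designs
# ---------------------------------------------------------------------------

# 18 inner-tag sequences produced by barcodes.design_tag_set(18, seed=20220627):
# synthetic stand-ins with the published design properties (8 nt, pairwise
# Levenshtein distance >= 4, GC 40-60%, max run 2, no SbfI/MseI reconstruction).
INNER_TAG_SEQUENCES: tuple[str, ...] = (
    "CTGTAACG", "AATTCGGC", "TGCACTGA", "ACGGATCA", "ACTGTGTG", "CGTACTAG",
    "GATAGCAC", "ATACGTCG", "GCCATGTA", "GTTCAAGC", "AACGGTAC", "TTGAGCCA",
    "AGGTTGGA", "CAGTAGTC", "AGCCTAAC", "CTACGAAC", "GTCCTACA", "GTATGCGA",
)

OUTER_TAG_LABELS: tuple[str, ...] = tuple(f"O{i}" for i in range(1, 9))

# Group sizes per library: four type-A libraries and three type-B libraries.
_TYPE_A_SIZES = (9, 9, 9, 9, 9, 9, 9, 9, 8, 6)
_TYPE_B_BASE = (9, 9, 9, 9, 9, 9, 9, 9, 8, 8, 8)
_PAPER_LIBRARIES: tuple[tuple[str, LibraryType, tuple[int, ...]], ...] = (
    ("A-1", LibraryType.A, _TYPE_A_SIZES),
    ("A-2", LibraryType.A, _TYPE_A_SIZES),
    ("A-3", LibraryType.A, _TYPE_A_SIZES),
    ("A-4", LibraryType.A, _TYPE_A_SIZES),
    ("B-1", LibraryType.B, _TYPE_B_BASE + (4,)),
    ("B-2", LibraryType.B, _TYPE_B_BASE + (3,)),
    ("B-3", LibraryType.B, _TYPE_B_BASE),
)


def _default_pairs(n: int = 9, sequences: tuple[str, ...] = INNER_TAG_SEQUENCES
                   ) -> tuple[InnerPair, ...]:
    if len(sequences) < 2 * n:
        raise SchemeError(f"need {2 * n} tag sequences, got {len(sequences)}")
    return tuple(
        InnerPair(
            BarcodeTag(f"i5-{k + 1}", sequences[k]),
            BarcodeTag(f"i7-{k + 1}", sequences[n + k]),
        )
        for k in range(n)
    )


def build_paper_scheme() -> ExperimentScheme:
    """The reference 7-library design: 639 samples in 75 multiplexed groups.

    Nine global fixed inner pairs; each group of n samples uses the first n
    pairs. Four type-A libraries of 10 groups (8x9 + 8 + 6 samples) and three
    type-B libraries (8x9 + 3x8, plus one extra group of 4 in B-1 and of 3 in
    B-2). Outer combos are labels drawn combinatorially from 8 outer tags;
    they serve only to identify groups within a library.
    """
    pairs = _default_pairs(9)
    outer_combos = list(itertools.product(OUTER_TAG_LABELS, repeat=2))
    libraries = []
    for lib_id, lib_type, sizes in _PAPER_LIBRARIES:
        groups = tuple(
            MultiplexGroup(
                group_id=f"{lib_id}-g{i + 1:02d}",
                outer_combo=outer_combos[i],
                inner_pairs=pairs[:size],
                library_id=lib_id,
            )
            for i, size in enumerate(sizes)
        )
        libraries.append(LibraryDesign(lib_id, lib_type, groups))
    return ExperimentScheme(
        libraries=tuple(libraries),
        global_pairs=pairs,
        outer_tags=OUTER_TAG_LABELS,
        tag_length=8,
    )


def build_three_group_scheme() -> ExperimentScheme:
    """A minimal three-group demonstration design.

    Four fixed pairs labelled Aa..Dd. Group 1 uses all four, group 2 uses
    {Aa, Bb}, group 3 uses {Cc, Dd} — so 'Ab' in group 1 is a type-I chimera,
    and in group 2 'Bc' is type II, 'Cd' type III and 'Dd' type IV.
    """
    labels = ["A", "B", "C", "D"]
    pairs = tuple(
        InnerPair(
            BarcodeTag(up, INNER_TAG_SEQUENCES[k]),
            BarcodeTag(up.lower(), INNER_TAG_SEQUENCES[4 + k]),
        )
        for k, up in enumerate(labels)
    )
    groups = (
        MultiplexGroup("mg1", ("O1", "O2"), pairs, "demo"),
        MultiplexGroup("mg2", ("O3", "O4"), pairs[:2], "demo"),
        MultiplexGroup("mg3", ("O5", "O6"), pairs[2:], "demo"),
    )
    return ExperimentScheme(
        libraries=(LibraryDesign("demo", LibraryType.B, groups),),
        global_pairs=pairs,
        outer_tags=("O1", "O2", "O3", "O4", "O5", "O6"),
        tag_length=8,
    )


# ---------------------------------------------------------------------------
# Scheme files
# ---------------------------------------------------------------------------


def write_scheme(scheme: ExperimentScheme, path: str | Path) -> None:
    doc = {
        "tag_length": scheme.tag_length,
        "outer_tags": list(scheme.outer_tags),
        "pairs": [
            {
                "i5": {"label": p.i5.label, "sequence": p.i5.sequence},
                "i7": {"label": p.i7.label, "sequence": p.i7.sequence},
            }
            for p in scheme.global_pairs
        ],
        "libraries": [
            {
                "id": lib.library_id,
                "type": lib.library_type.value,
                "groups": [
                    {
                        "id": g.group_id,
                        "outer_combo": list(g.outer_combo),
                        "pairs": [list(p.labels) for p in g.inner_pairs],
                    }
                    for g in lib.groups
                ],
            }
            for lib in scheme.libraries
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_scheme(path: str | Path) -> ExperimentScheme:
    """Read a scheme file, validating invariants; errors name the element."""
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - passthrough
        raise SchemeError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemeError(f"{path}: expected a mapping at top level")
    try:
        pairs = tuple(
            InnerPair(
                BarcodeTag(p["i5"]["label"], p["i5"]["sequence"]),
                BarcodeTag(p["i7"]["label"], p["i7"]["sequence"]),
            )
            for p in doc["pairs"]
        )
        by_labels = {p.labels: p for p in pairs}
        libraries = []
        for lib in doc["libraries"]:
            groups = []
            for g in lib["groups"]:
                try:
                    inner = tuple(by_labels[tuple(lbls)] for lbls in g["pairs"])
                except KeyError as exc:
                    raise SchemeError(
                        f"{path}: group {g.get('id')}: unknown pair {exc}"
                    ) from exc
                groups.append(
                    MultiplexGroup(
                        group_id=str(g["id"]),
                        outer_combo=tuple(g["outer_combo"]),
                        inner_pairs=inner,
                        library_id=str(lib["id"]),
                    )
                )
            libraries.append(
                LibraryDesign(
                    str(lib["id"]), LibraryType(lib["type"]), tuple(groups)
                )
            )
    except (KeyError, TypeError) as exc:
        raise SchemeError(f"{path}: malformed scheme: {exc}") from exc
    return ExperimentScheme(
        libraries=tuple(libraries),
        global_pairs=pairs,
        outer_tags=tuple(doc.get("outer_tags", ())),
        tag_length=int(doc.get("tag_length", len(pairs[0].i5.sequence))),
    )
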
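"""Design and validation of inline barcode tag sets.

Tags are short fixed-length DNA words used as inline sample barcodes. A usable
set keeps every pair of tags at a minimum Levenshtein distance (so that
sequencing errors cannot silently convert one tag into another), keeps GC
content moderate, avoids homopolymer runs and self-complementary words, and
avoids words that reconstruct the library's restriction sites when placed in
their adapter context.

The designer is a greedy filtered search over random candidate words: a
candidate is accepted iff it passes the per-tag filters and sits at or above
the minimum distance from every previously accepted tag. This mirrors how
edit-distance tag sets are built in practice; it makes no claim of maximality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

DNA_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Restriction sites for the SbfI / MseI double digest.
SBFI_SITE = "CCTGCAGG"
MSEI_SITE = "TTAA"

# Adapter context immediately flanking an inner tag on each side: the ligated
# restriction-site remnants. Used to detect tags that reconstruct a full site.
DEFAULT_FLANKS = (("", "TGCAGG"), ("", "TAA"))


class BarcodeError(ValueError):
    """Invalid barcode input (non-DNA characters, empty sets, ...)."""


def _check_dna(seq: str, *, name: str = "sequence") -> None:
    if not seq or any(b not in DNA_ALPHABET for b in seq):
        raise BarcodeError(f"{name} {seq!r} is not a non-empty ACGT string")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """GC content as an exact fraction in [0, 1]."""
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def levenshtein_distance(a: str, b: str) -> int:
    """Unit-cost edit distance between two DNA words.

    Raises :class:`BarcodeError` on non-ACGT input.
    """
    _check_dna(a, name="a")
    _check_dna(b, name="b")
    if a == b:
        return 0
    # Two-row dynamic programme.
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@dataclass(frozen=True)
class TagConstraints:
    """Filters a tag set must satisfy.

    length        tag length in nt
    min_distance  minimum pairwise Levenshtein distance within the set
    gc_min/gc_max allowed GC content, in percent, compared exactly
    max_run       longest allowed run of identical adjacent bases
    forbidden_sites  motifs (restriction sites) that must not appear when the
                  tag is embedded in its adapter flanks
    flanks        ((left, right), ...) fixed adapter context per side; each
                  context is checked independently
    """

    length: int = 8
    min_distance: int = 4
    gc_min: float = 40.0
    gc_max: float = 60.0
    max_run: int = 2
    forbidden_sites: tuple[str, ...] = (SBFI_SITE, MSEI_SITE)
    flanks: tuple[tuple[str, str], ...] = DEFAULT_FLANKS

    def __post_init__(self) -> None:
        if not (0 <= self.gc_min <= self.gc_max <= 100):
            raise BarcodeError("need 0 <= gc_min <= gc_max <= 100")
        if self.min_distance < 1:
            raise BarcodeError("min_distance must be >= 1")


def validate_tag(sequence: str, constraints: TagConstraints | None = None) -> list[str]:
    """Return the list of violation codes for one tag (empty iff it passes).

    Codes: ``length``, ``alphabet``, ``gc``, ``homopolymer``,
    ``self_complementary``, ``forbidden_site:<motif>``.
    """
    c = constraints or TagConstraints()
    violations: list[str] = []
    if any(b not in DNA_ALPHABET for b in sequence) or not sequence:
        return ["alphabet"]
    if len(sequence) != c.length:
        violations.append("length")
    gc = gc_fraction(sequence) * 100
    if not (c.gc_min <= gc <= c.gc_max):
        violations.append("gc")
    if max_homopolymer_run(sequence) > c.max_run:
        violations.append("homopolymer")
    if reverse_complement(sequence) == sequence:
        violations.append("self_complementary")
    for left, right in c.flanks:
        context = left + sequence + right
        for site in c.forbidden_sites:
            if site in context:
                code = f"forbidden_site:{site}"
                if code not in violations:
                    violations.append(code)
    return violations


@dataclass
class TagSetReport:
    """Validation report for a whole tag set."""

    per_tag: dict[str, list[str]] = field(default_factory=dict)
    close_pairs: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.close_pairs and not any(self.per_tag.values())


def validate_tag_set(
    sequences: Sequence[str], constraints: TagConstraints | None = None
) -> TagSetReport:
    """Per-tag filters plus every unordered pair below the minimum distance."""
    c = constraints or TagConstraints()
    if len(sequences) < 1:
        raise BarcodeError("need at least one tag")
    report = TagSetReport()
    for seq in sequences:
        report.per_tag[seq] = validate_tag(seq, c)
    for i, a in enumerate(sequences):
        for b in sequences[i + 1 :]:
            d = levenshtein_distance(a, b)
            if d < c.min_distance:
                report.close_pairs.append((a, b, d))
    return report


def design_tag_set(
    n: int,
    constraints: TagConstraints | None = None,
    seed: int = 0,
    candidate_budget: int = 1_000_000,
) -> list[str]:
    """Greedy design of ``n`` tags satisfying ``constraints``.

    Random candidate words are streamed from a seeded generator; a candidate
    is kept iff it passes :func:`validate_tag` and has Levenshtein distance
    >= ``min_distance`` to every tag kept so far. Deterministic given ``seed``.

    Raises :class:`BarcodeError` ("design infeasible") if the budget runs out,
    reporting how many tags were reached.
    """
    if n < 1:
        raise BarcodeError("n must be >= 1")
    c = constraints or TagConstraints()
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    bases = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)
    for _ in range(candidate_budget):
        word = bases[rng.integers(0, 4, size=c.length)].tobytes().decode()
        if validate_tag(word, c):
            continue
        if any(levenshtein_distance(word, t) < c.min_distance for t in accepted):
            continue
        accepted.append(word)
        if len(accepted) == n:
            return accepted
    raise BarcodeError(
        f"design infeasible: reached {len(accepted)} of {n} tags "
        f"within a budget of {candidate_budget} candidates"
    )


def read_tag_list(path: str | Path) -> dict[str, str]:
    """Read a tag list: two-column text (label, sequence) or FASTA.

    Returns an ordered mapping label -> sequence.
    """
    path = Path(path)
    text = path.read_text()
    tags: dict[str, str] = {}
    if text.lstrip().startswith(">"):
        from Bio import SeqIO

        for rec in SeqIO.parse(str(path), "fasta"):
            tags[rec.id] = str(rec.seq).upper()
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise BarcodeError(f"{path}:{lineno}: expected 'label sequence'")
            label, seq = fields
            tags[label] = seq.upper()
    for label, seq in tags.items():
        _check_dna(seq, name=f"tag {label}")
    return tags


def write_tag_list(tags: dict[str, str], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{label}\t{seq}\n" for label, seq in tags.items())
    )


def pairwise_distances(sequences: Iterable[str]) -> dict[tuple[str, str], int]:
    seqs = list(sequences)
    return {
        (a, b): levenshtein_distance(a, b)
        for i, a in enumerate(seqs)
        for b in seqs[i + 1 :]
    }
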
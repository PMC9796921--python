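"""FASTQ processing: clone removal, quality filtering, demultiplexing.

The processing order follows the standard Stacks-style pipeline: PCR
duplicates are removed first (while reads still carry their inline tag and
degenerate VBBN tag), then reads are demultiplexed on the inner tags with
mismatch rescue, quality-filtered, stripped of tag+VBBN and truncated.

Demultiplexing deliberately bins reads into *every* ordered (i5, i7) tag
combination — used or not — because the unused combinations are what measures
chimera formation downstream.

Tag rescue uses Hamming (substitution-only) distance: inline tags sit at a
fixed position with a fixed length, so insertions/deletions cannot occur
without shifting the whole read. An observed tag is assigned to the unique
known tag at minimal distance d <= k; ties at the minimal distance are
*ambiguous* and the read is discarded, never guessed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scheme import BarcodeTag, ExperimentScheme
from .simulate import R1_REMNANT, R2_REMNANT, ReadPair

VBBN_LEN = 4


class ReadError(ValueError):
    """Malformed read or invalid demultiplexing input."""


@dataclass(frozen=True)
class DemuxParams:
    """Demultiplexing and filtering settings.

    max_mismatch             tags rescued up to this Hamming distance (0-4 in
                             the reference protocol; any value >= 0 accepted)
    truncate_len             retained read length after tag+VBBN removal
    drop_uncalled            discard reads with N in the payload
    quality_window_fraction  sliding-window length as a fraction of the payload
    quality_threshold        minimum mean Phred inside every window
    honor_chastity           discard reads flagged by the purity filter
    check_remnant            verify the restriction-site remnant (<=1 mismatch)
    """

    max_mismatch: int = 0
    truncate_len: int = 136
    drop_uncalled: bool = True
    quality_window_fraction: float = 0.15
    quality_threshold: float = 10.0
    honor_chastity: bool = True
    check_remnant: bool = False

    def __post_init__(self) -> None:
        if self.max_mismatch < 0:
            raise ReadError("max_mismatch must be >= 0")
        if self.truncate_len < 1:
            raise ReadError("truncate_len must be >= 1")


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_paired_fastq(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    """Load a pair of (optionally gzipped) FASTQ files.

    The pass-filter flag is taken from an Illumina-style comment
    (``<mate>:<Y|N>:...``, Y = failing); absent comments mean passing.
    """
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    pairs = []
    with _open_text(path1) as f1, _open_text(path2) as f2:
        for (t1, s1, q1), (t2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            id1 = t1.split()[0]
            if id1 != t2.split()[0]:
                raise ReadError(f"mate id mismatch: {t1!r} vs {t2!r}")
            fields1 = t1.split()
            pf = True
            if len(fields1) > 1:
                parts = fields1[1].split(":")
                if len(parts) >= 2 and parts[1] == "Y":
                    pf = False
            pairs.append(ReadPair(id1, s1.upper(), q1, s2.upper(), q2, pf))
    return pairs


# ---------------------------------------------------------------------------
# Clone (PCR-duplicate) removal
# ---------------------------------------------------------------------------


def remove_clones(
    pairs: Iterable[ReadPair], tag_len: int = 8, vbbn_len: int = VBBN_LEN
) -> tuple[list[ReadPair], int]:
    """Drop pairs whose full mate1+mate2 sequences were already seen.

    Identical template *and* identical VBBN on both mates marks a PCR
    duplicate; the first occurrence is kept and input order preserved.
    """
    seen: set[tuple[str, str]] = set()
    kept: list[ReadPair] = []
    n_removed = 0
    min_len = tag_len + vbbn_len
    for rp in pairs:
        if len(rp.seq1) < min_len or len(rp.seq2) < min_len:
            raise ReadError(f"read {rp.id}: mate shorter than tag+VBBN ({min_len})")
        key = (rp.seq1, rp.seq2)
        if key in seen:
            n_removed += 1
        else:
            seen.add(key)
            kept.append(rp)
    return kept, n_removed


# ---------------------------------------------------------------------------
# Tag matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TagMatch:
    status: str  # "matched" | "none" | "ambiguous"
    tag: BarcodeTag | None
    distance: int | None


def hamming_distance(a: str, b: str) -> int:
    """Positional mismatch count; N never matches anything."""
    if len(a) != len(b):
        raise ReadError("hamming_distance requires equal lengths")
    return sum(x != y or x == "N" for x, y in zip(a, b))


def match_tag(observed: str, tags: Sequence[BarcodeTag], k: int) -> TagMatch:
    """Assign ``observed`` to the unique tag at minimal Hamming distance <= k."""
    if not tags:
        raise ReadError("empty tag list")
    if len(observed) != len(tags[0].sequence):
        raise ReadError(
            f"observed length {len(observed)} != tag length {len(tags[0].sequence)}"
        )
    dists = [hamming_distance(observed, t.sequence) for t in tags]
    dmin = min(dists)
    if dmin > k:
        return TagMatch("none", None, None)
    if dists.count(dmin) > 1:
        return TagMatch("ambiguous", None, dmin)
    return TagMatch("matched", tags[dists.index(dmin)], dmin)


# ---------------------------------------------------------------------------
# Quality filtering
# ---------------------------------------------------------------------------


def _window_len(n: int, fraction: float) -> int:
    return max(1, int(round(fraction * n)))


def quality_filter(
    pair: ReadPair, params: DemuxParams, payload_start: int = 0
) -> tuple[bool, str | None]:
    """Pass/fail one pair; the reason is one of
    ``chastity``, ``uncalled``, ``low_quality`` (None when passing).

    ``payload_start`` excludes the tag+VBBN prefix from the uncalled-base and
    window checks, mirroring how rescue-capable demultiplexers treat barcode
    bases separately from the read body.
    """
    if params.honor_chastity and not pair.pass_filter:
        return False, "chastity"
    for seq, qual in ((pair.seq1, pair.qual1), (pair.seq2, pair.qual2)):
        if len(seq) != len(qual):
            raise ReadError(f"read {pair.id}: sequence/quality length mismatch")
        body = seq[payload_start:]
        if params.drop_uncalled and "N" in body:
            return False, "uncalled"
        phred = np.frombuffer(qual[payload_start:].encode(), dtype=np.uint8) - 33
        if (phred < 0).any() or (phred > 93).any():
            raise ReadError(f"read {pair.id}: quality not Phred-33 encoded")
        w = _window_len(len(phred), params.quality_window_fraction)
        if len(phred) >= w:
            cs = np.concatenate([[0], np.cumsum(phred)])
            means = (cs[w:] - cs[:-w]) / w
            if (means < params.quality_threshold).any():
                return False, "low_quality"
    return True, None


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------


@dataclass
class DemuxResult:
    """Counts and (optionally) binned reads for one group at one rescue level."""

    group_id: str
    mismatch_level: int
    counts: pd.DataFrame  # group_id, i5, i7, mismatch_level, count
    discards: dict[str, int]
    n_input: int
    n_retained: int
    bins: dict[tuple[str, str], list[ReadPair]] = field(default_factory=dict)


def _tag_matrix(tags: Sequence[BarcodeTag]) -> np.ndarray:
    return np.frombuffer(
        "".join(t.sequence for t in tags).encode(), dtype=np.uint8
    ).reshape(len(tags), -1)


_DISCARD_REASONS = (
    "chastity", "tag_none", "tag_ambiguous", "uncalled", "low_quality", "remnant"
)


@lru_cache(maxsize=65536)
def _qual_window_ok(qual: str, fraction: float, threshold: float) -> bool:
    phred = np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int64) - 33
    if (phred < 0).any() or (phred > 93).any():
        raise ReadError("quality not Phred-33 encoded")
    w = _window_len(len(phred), fraction)
    if len(phred) < w:
        return True
    cs = np.concatenate([[0], np.cumsum(phred)])
    means = (cs[w:] - cs[:-w]) / w
    return not (means < threshold).any()


def _quality_reasons(
    pairs: Sequence[ReadPair], params: DemuxParams, strip: int
) -> np.ndarray:
    """Per-read quality failure reason index (-1 = pass).

    0=chastity, 3=uncalled, 4=low_quality, 5=remnant in _DISCARD_REASONS
    order. Window means are cached per distinct quality string, which makes
    the common simulated case (one shared profile) O(1).
    """
    out = np.full(len(pairs), -1, dtype=np.int8)
    check_n = params.drop_uncalled
    for i, p in enumerate(pairs):
        if len(p.seq1) != len(p.qual1) or len(p.seq2) != len(p.qual2):
            raise ReadError(f"read {p.id}: sequence/quality length mismatch")
        if params.honor_chastity and not p.pass_filter:
            out[i] = 0
        elif check_n and ("N" in p.seq1[strip:] or "N" in p.seq2[strip:]):
            out[i] = 3
        elif not (
            _qual_window_ok(
                p.qual1[strip:], params.quality_window_fraction,
                params.quality_threshold,
            )
            and _qual_window_ok(
                p.qual2[strip:], params.quality_window_fraction,
                params.quality_threshold,
            )
        ):
            out[i] = 4
        elif params.check_remnant and not (
            hamming_distance(p.seq1[strip : strip + len(R1_REMNANT)], R1_REMNANT)
            <= 1
            and hamming_distance(p.seq2[strip : strip + len(R2_REMNANT)], R2_REMNANT)
            <= 1
        ):
            out[i] = 5
    return out


@dataclass
class _Assignment:
    """k-independent per-read demultiplexing state for one group."""

    a5: np.ndarray  # argmin tag index per mate (valid when not tied)
    d5: np.ndarray  # minimal distance per mate
    tie5: np.ndarray
    a7: np.ndarray
    d7: np.ndarray
    tie7: np.ndarray
    qreason: np.ndarray  # -1 pass / index into _DISCARD_REASONS


def _assign(pairs, scheme, params) -> _Assignment:
    i5_tags = list(scheme.i5_tags.values())
    i7_tags = list(scheme.i7_tags.values())
    L = scheme.tag_length
    for p in pairs:
        if len(p.seq1) < L + VBBN_LEN or len(p.seq2) < L + VBBN_LEN:
            raise ReadError(f"read {p.id}: mate shorter than tag+VBBN")
    a5, d5, tie5 = _min_distances(pairs, 1, i5_tags, L)
    a7, d7, tie7 = _min_distances(pairs, 2, i7_tags, L)
    qreason = _quality_reasons(pairs, params, L + VBBN_LEN)
    return _Assignment(a5, d5, tie5, a7, d7, tie7, qreason)


def _min_distances(pairs, mate, tags, tag_len):
    obs = np.frombuffer(
        "".join((p.seq1 if mate == 1 else p.seq2)[:tag_len] for p in pairs).encode(),
        dtype=np.uint8,
    ).reshape(len(pairs), tag_len)
    tag_mat = _tag_matrix(tags)
    mism = (obs[:, None, :] != tag_mat[None, :, :]) | (obs[:, None, :] == ord("N"))
    dists = mism.sum(axis=2)
    dmin = dists.min(axis=1)
    ties = (dists == dmin[:, None]).sum(axis=1) > 1
    return dists.argmin(axis=1), dmin, ties


def _result_at_level(
    pairs, scheme, group_id, asg: _Assignment, params: DemuxParams,
    k: int, keep_reads: bool,
) -> DemuxResult:
    i5_labels = list(scheme.i5_tags)
    i7_labels = list(scheme.i7_tags)
    n5, n7 = len(i5_labels), len(i7_labels)
    none = (asg.d5 > k) | (asg.d7 > k)
    amb = ~none & ((asg.tie5 & (asg.d5 <= k)) | (asg.tie7 & (asg.d7 <= k)))
    matched = ~none & ~amb
    retained = matched & (asg.qreason < 0)
    discards = {r: 0 for r in _DISCARD_REASONS}
    discards["tag_none"] = int(none.sum()) if len(pairs) else 0
    discards["tag_ambiguous"] = int(amb.sum()) if len(pairs) else 0
    if len(pairs):
        qfail = asg.qreason[matched & (asg.qreason >= 0)]
        for idx, count in zip(*np.unique(qfail, return_counts=True)):
            discards[_DISCARD_REASONS[idx]] = int(count)
        combo_idx = asg.a5 * n7 + asg.a7
        hist = np.bincount(combo_idx[retained], minlength=n5 * n7)
    else:
        hist = np.zeros(n5 * n7, dtype=int)
    counts = pd.DataFrame(
        {
            "group_id": group_id,
            "i5": np.repeat(i5_labels, n7),
            "i7": np.tile(i7_labels, n5),
            "mismatch_level": k,
            "count": hist.astype(int),
        }
    )
    bins: dict[tuple[str, str], list[ReadPair]] = {}
    if keep_reads and len(pairs):
        strip = scheme.tag_length + VBBN_LEN
        t = params.truncate_len
        for i in np.nonzero(retained)[0]:
            p = pairs[i]
            combo = (i5_labels[asg.a5[i]], i7_labels[asg.a7[i]])
            bins.setdefault(combo, []).append(
                ReadPair(
                    p.id,
                    p.seq1[strip:][:t], p.qual1[strip:][:t],
                    p.seq2[strip:][:t], p.qual2[strip:][:t],
                    p.pass_filter,
                )
            )
    return DemuxResult(
        group_id=group_id,
        mismatch_level=k,
        counts=counts,
        discards=discards,
        n_input=len(pairs),
        n_retained=int(retained.sum()) if len(pairs) else 0,
        bins=bins,
    )


def demultiplex_group(
    pairs: Sequence[ReadPair],
    scheme: ExperimentScheme,
    group_id: str,
    params: DemuxParams,
    keep_reads: bool = False,
) -> DemuxResult:
    """Demultiplex one group's reads over *all* ordered tag combinations.

    A pair is retained iff both mates match a tag uniquely within
    ``params.max_mismatch`` and the pair passes the quality filter; retained
    reads are stripped of tag+VBBN and truncated to ``truncate_len``.
    Discards are logged by reason and satisfy
    ``n_retained + sum(discards) == n_input``.
    """
    scheme.group(group_id)  # raises SchemeError if unknown
    asg = _assign(list(pairs), scheme, params)
    return _result_at_level(
        list(pairs), scheme, group_id, asg, params, params.max_mismatch, keep_reads
    )


def demultiplex_group_levels(
    pairs: Sequence[ReadPair],
    scheme: ExperimentScheme,
    group_id: str,
    params: DemuxParams,
    levels: Sequence[int],
) -> dict[int, DemuxResult]:
    """One group demultiplexed at several rescue levels in a single pass.

    Tag distances and quality outcomes are k-independent, so the per-level
    results are sliced from one assignment; identical to running
    :func:`demultiplex_group` once per level.
    """
    scheme.group(group_id)
    pairs = list(pairs)
    asg = _assign(pairs, scheme, params)
    return {
        k: _result_at_level(pairs, scheme, group_id, asg, params, k, False)
        for k in levels
    }


def demultiplex_run(
    reads_by_group: dict[str, Sequence[ReadPair]],
    scheme: ExperimentScheme,
    params: DemuxParams,
) -> tuple[pd.DataFrame, dict[str, DemuxResult]]:
    """Demultiplex every group; returns the concatenated count table."""
    results = {
        gid: demultiplex_group(list(pairs), scheme, gid, params)
        for gid, pairs in reads_by_group.items()
    }
    counts = pd.concat([r.counts for r in results.values()], ignore_index=True)
    return counts, results


def demultiplex_run_levels(
    reads_by_group: dict[str, Sequence[ReadPair]],
    scheme: ExperimentScheme,
    params: DemuxParams,
    levels: Sequence[int],
) -> tuple[dict[int, pd.DataFrame], dict[int, dict[str, DemuxResult]]]:
    """All groups at all rescue levels, sharing the per-group assignment."""
    per_group = {
        gid: demultiplex_group_levels(pairs, scheme, gid, params, levels)
        for gid, pairs in reads_by_group.items()
    }
    counts_by_level = {
        k: pd.concat(
            [per_group[g][k].counts for g in per_group], ignore_index=True
        )
        for k in levels
    }
    results_by_level = {
        k: {g: per_group[g][k] for g in per_group} for k in levels
    }
    return counts_by_level, results_by_level


def write_demux_bins(
    result: DemuxResult, outdir: str | Path, compress: bool = True
) -> dict[tuple[str, str], tuple[str, str]]:
    """Write per-combination FASTQ files named ``group.i5-i7.<mate>.fq[.gz]``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".fq.gz" if compress else ".fq"
    opener = (lambda p: gzip.open(p, "wt")) if compress else (lambda p: open(p, "w"))
    written = {}
    for (i5, i7), reads in sorted(result.bins.items()):
        p1 = outdir / f"{result.group_id}.{i5}-{i7}.1{suffix}"
        p2 = outdir / f"{result.group_id}.{i5}-{i7}.2{suffix}"
        with opener(p1) as f1, opener(p2) as f2:
            for rp in reads:
                f1.write(f"@{rp.id} 1\n{rp.seq1}\n+\n{rp.qual1}\n")
                f2.write(f"@{rp.id} 2\n{rp.seq2}\n+\n{rp.qual2}\n")
        written[(i5, i7)] = (str(p1), str(p2))
    return written
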
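"""Synthetic paired-end read generator with per-read ground truth.

Emulates the raw material a sequencing centre would deliver for a
combinatorially barcoded RAD-seq experiment: one pair of FASTQ streams per
multiplexed group, already split by outer index. Each read pair starts with
an 8-nt inline tag, a 4-nt degenerate VBBN tag (IUPAC V=ACG, B=CGT, N=ACGT)
and the restriction-site remnant, followed by random genomic insert.

Artifact events, drawn per template at configurable rates:

* ``pcr_duplicate`` — an extra copy of an emitted molecule, sharing both
  VBBN tags and the full template (only sequencing errors differ).
* ``pcr_chimera``  — read2 identity (tag, VBBN, insert) taken from another
  sample of the same multiplexed group; only in type-B libraries, where the
  indexing PCR runs on the pooled group.
* ``seq_chimera``  — read2 identity taken from any template on the same
  lane (library), emulating chimera formation during cluster generation.
* ``index_hop``    — the intact pair is emitted in a uniformly chosen other
  group of the same library.
* ``junk``         — a cluster whose sequence is arbitrary DNA (adapter
  dimer / contaminant); its "tag" regions are not barcodes at all.

Inserts are i.i.d. uniform DNA: with no reference genome the downstream
detection operates on barcodes only, so genomic realism is irrelevant here.
Insert length is drawn per template but must be at least the read length, so
reads never run into adapter on the 3' end.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .scheme import ExperimentScheme, LibraryType

R1_REMNANT = "TGCAG"  # SbfI overhang remnant at the start of read 1
R2_REMNANT = "TAA"  # MseI remnant at the start of read 2

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate("ACGTN")}
# IUPAC degenerate positions of the VBBN tag, as allowed base codes.
_VBBN_CHOICES = (
    np.array([0, 1, 2]),  # V: A C G
    np.array([1, 2, 3]),  # B: C G T
    np.array([1, 2, 3]),  # B
    np.array([0, 1, 2, 3]),  # N
)

EVENTS = ("genuine", "pcr_duplicate", "pcr_chimera", "seq_chimera", "index_hop", "junk")


class SimulationError(ValueError):
    """Invalid simulation parameters."""


@dataclass(frozen=True)
class SimParams:
    """Generator settings; all rates are per-read probabilities in [0, 1]."""

    reads_per_sample: int = 200
    insert_len: tuple[int, int] = (200, 400)
    read_len: int = 150
    dup_rate: float = 0.10
    pcr_chimera_rate: float = 0.005
    seq_chimera_rate: float = 0.005
    index_hop_rate: float = 0.002
    junk_rate: float = 0.001
    error_rate: float = 0.001
    uncalled_rate: float = 0.0
    chastity_fail_rate: float = 0.0
    base_phred: int = 37
    tail_fraction: float = 0.0
    tail_phred: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {
            "dup_rate": self.dup_rate,
            "pcr_chimera_rate": self.pcr_chimera_rate,
            "seq_chimera_rate": self.seq_chimera_rate,
            "index_hop_rate": self.index_hop_rate,
            "junk_rate": self.junk_rate,
            "error_rate": self.error_rate,
            "uncalled_rate": self.uncalled_rate,
            "chastity_fail_rate": self.chastity_fail_rate,
        }
        for name, value in rates.items():
            if not (0.0 <= value <= 1.0):
                raise SimulationError(f"{name}={value} outside [0, 1]")
        event_sum = (
            self.pcr_chimera_rate
            + self.seq_chimera_rate
            + self.index_hop_rate
            + self.junk_rate
        )
        if event_sum > 1.0:
            raise SimulationError("event rates sum to more than 1")
        if self.insert_len[0] > self.insert_len[1]:
            raise SimulationError("insert_len range inverted")
        if self.insert_len[0] < self.read_len:
            raise SimulationError(
                "insert_len minimum must be >= read_len (no 3' read-through model)"
            )

    def min_read_len(self, tag_len: int) -> int:
        return tag_len + 4 + len(R1_REMNANT) + 1


@dataclass(frozen=True)
class ReadPair:
    """One emitted paired read; layout [tag][VBBN][remnant][insert] per mate."""

    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    pass_filter: bool = True


@dataclass
class SimulatedRun:
    """In-memory result of one simulation: reads per group plus ground truth."""

    scheme: ExperimentScheme
    params: SimParams
    reads_by_group: dict[str, list[ReadPair]]
    truth: pd.DataFrame  # one row per emitted read

    @property
    def n_reads(self) -> int:
        return sum(len(v) for v in self.reads_by_group.values())


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _quality_string(params: SimParams) -> str:
    qual = np.full(params.read_len, params.base_phred, dtype=int)
    tail = int(round(params.tail_fraction * params.read_len))
    if tail > 0:
        qual[-tail:] = params.tail_phred
    return "".join(chr(33 + q) for q in qual)


def draw_vbbn(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """(n, 4) matrix of VBBN base codes drawn per the IUPAC degeneracies."""
    cols = [choices[rng.integers(0, len(choices), size=n)] for choices in _VBBN_CHOICES]
    return np.stack(cols, axis=1)


def apply_sequencing_errors(
    seq: str, error_rate: float, uncalled_rate: float, rng: np.random.Generator
) -> str:
    """Independently substitute each base (to a *different* base) with
    probability ``error_rate``, then overwrite with N at ``uncalled_rate``."""
    if not (0 <= error_rate <= 1 and 0 <= uncalled_rate <= 1):
        raise SimulationError("rates outside [0, 1]")
    codes = np.array([_CODE[b] for b in seq], dtype=np.uint8)
    _mutate_codes(codes, error_rate, uncalled_rate, rng)
    return _decode(codes)


def _mutate_codes(
    codes: np.ndarray, error_rate: float, uncalled_rate: float,
    rng: np.random.Generator,
) -> None:
    """In-place substitution + uncalled-base model on a base-code array."""
    if error_rate > 0:
        mask = rng.random(codes.shape) < error_rate
        n = int(mask.sum())
        if n:
            codes[mask] = (codes[mask] + rng.integers(1, 4, size=n)) % 4
    if uncalled_rate > 0:
        mask = rng.random(codes.shape) < uncalled_rate
        codes[mask] = 4


def build_read_pair(
    read_id: str,
    i5_seq: str,
    i7_seq: str,
    insert: str,
    vbbn1: str,
    vbbn2: str,
    read_len: int = 150,
    base_phred: int = 37,
    tail_fraction: float = 0.0,
    tail_phred: int = 20,
) -> ReadPair:
    """Assemble one error-free pair from its components.

    Mate 1 reads the i5 tag, first VBBN, SbfI remnant and the insert's
    forward strand; mate 2 reads the i7 tag, second VBBN, MseI remnant and
    the reverse complement of the insert. Both are truncated to ``read_len``.
    """
    if len(insert) < 1:
        raise SimulationError("insert must be non-empty")
    comp = str.maketrans("ACGTN", "TGCAN")
    m1 = (i5_seq + vbbn1 + R1_REMNANT + insert)[:read_len]
    m2 = (i7_seq + vbbn2 + R2_REMNANT + insert.translate(comp)[::-1])[:read_len]
    params = SimParams(
        read_len=read_len, base_phred=base_phred,
        tail_fraction=tail_fraction, tail_phred=tail_phred,
        insert_len=(max(read_len, len(insert)), max(read_len, len(insert))),
    )
    qual = _quality_string(params)
    return ReadPair(read_id, m1, qual[: len(m1)], m2, qual[: len(m2)])


# ---------------------------------------------------------------------------
# Whole-experiment generator
# ---------------------------------------------------------------------------


def simulate_experiment(scheme: ExperimentScheme, params: SimParams) -> SimulatedRun:
    """Generate every library of ``scheme`` under ``params``.

    Deterministic given ``params.seed``. Every emitted read has exactly one
    truth row recording its event, emitting group, apparent inner tags and
    parent sample(s).
    """
    if params.read_len < params.min_read_len(scheme.tag_length):
        raise SimulationError(
            f"read_len {params.read_len} too short for tag length "
            f"{scheme.tag_length} + VBBN + remnant"
        )
    rng = np.random.default_rng(params.seed)
    reads_by_group: dict[str, list[ReadPair]] = {
        g.group_id: [] for g in scheme.groups()
    }
    truth_frames = []
    counter = 0
    for lib in scheme.libraries:
        counter = _simulate_library(
            scheme, lib, params, rng, reads_by_group, truth_frames, counter
        )
    truth = pd.concat(truth_frames, ignore_index=True)
    return SimulatedRun(scheme, params, reads_by_group, truth)


def _simulate_library(scheme, lib, params, rng, reads_by_group, truth_frames, counter):
    R = params.reads_per_sample
    tag_len = scheme.tag_length
    groups = list(lib.groups)
    # Template bookkeeping: templates laid out sample by sample, group by group.
    sample_ids: list[str] = []
    sample_group: list[int] = []  # group index per sample
    i5_codes, i7_codes = [], []
    for gi, g in enumerate(groups):
        for pair in g.inner_pairs:
            sample_ids.append(f"{g.group_id}/{pair.i5.label}-{pair.i7.label}")
            sample_group.append(gi)
            i5_codes.append([_CODE[b] for b in pair.i5.sequence])
            i7_codes.append([_CODE[b] for b in pair.i7.sequence])
    S = len(sample_ids)
    T = S * R
    sample_of = np.repeat(np.arange(S), R)  # template -> sample
    group_of = np.asarray(sample_group)[sample_of]  # template -> group index
    i5_codes = np.asarray(i5_codes, dtype=np.uint8)
    i7_codes = np.asarray(i7_codes, dtype=np.uint8)

    # Template material.
    lmax = params.insert_len[1]
    inserts = rng.integers(0, 4, size=(T, lmax), dtype=np.uint8)
    ins_len = rng.integers(params.insert_len[0], params.insert_len[1] + 1, size=T)
    vbbn1 = draw_vbbn(rng, T)
    vbbn2 = draw_vbbn(rng, T)

    # Event assignment (mutually exclusive per template).
    p_pcr = params.pcr_chimera_rate if lib.library_type is LibraryType.B else 0.0
    u = rng.random(T)
    edges = np.cumsum([p_pcr, params.seq_chimera_rate,
                       params.index_hop_rate, params.junk_rate])
    event_idx = np.searchsorted(edges, u, side="right")  # 0..3 events, 4 genuine
    event_names = np.array(["pcr_chimera", "seq_chimera", "index_hop",
                            "junk", "genuine"])

    src1 = np.arange(T)
    src2 = np.arange(T)
    emit_group = group_of.copy()
    is_junk = event_idx == 3
    partner_sample = np.full(T, -1)

    # Sample->template ranges per group, for partner draws.
    group_samples = [
        [s for s in range(S) if sample_group[s] == gi] for gi in range(len(groups))
    ]
    # pcr_chimera: partner drawn within the same group, since type-B pools are
    # per multiplexed group and the indexing PCR runs on the pool.
    for t in np.nonzero(event_idx == 0)[0]:
        own_s = sample_of[t]
        others = [s for s in group_samples[group_of[t]] if s != own_s]
        if not others:
            event_idx[t] = 4  # single-sample group: no partner available
            continue
        ps = others[rng.integers(0, len(others))]
        src2[t] = ps * R + rng.integers(0, R)
        partner_sample[t] = ps
    for t in np.nonzero(event_idx == 1)[0]:  # seq_chimera: partner lane-wide
        t2 = int(rng.integers(0, T - 1))
        if t2 >= t:
            t2 += 1
        src2[t] = t2
        partner_sample[t] = sample_of[t2]
    n_groups = len(groups)
    for t in np.nonzero(event_idx == 2)[0]:  # index_hop: intact pair, other group
        if n_groups < 2:
            event_idx[t] = 4
            continue
        g2 = int(rng.integers(0, n_groups - 1))
        if g2 >= group_of[t]:
            g2 += 1
        emit_group[t] = g2

    # Duplicates: one extra copy of an emitted molecule at dup_rate.
    dup_of = np.nonzero(rng.random(T) < params.dup_rate)[0]

    primary_event = event_names[event_idx]
    all_src1 = np.concatenate([src1, src1[dup_of]])
    all_src2 = np.concatenate([src2, src2[dup_of]])
    all_group = np.concatenate([emit_group, emit_group[dup_of]])
    all_junk = np.concatenate([is_junk, is_junk[dup_of]])
    all_event = np.concatenate(
        [primary_event, np.full(len(dup_of), "pcr_duplicate")]
    )
    all_partner = np.concatenate([partner_sample, np.full(len(dup_of), -1)])
    N = len(all_src1)

    # Sequence assembly.
    n1 = params.read_len - tag_len - 4 - len(R1_REMNANT)
    n2 = params.read_len - tag_len - 4 - len(R2_REMNANT)
    m1 = np.empty((N, params.read_len), dtype=np.uint8)
    m2 = np.empty((N, params.read_len), dtype=np.uint8)
    m1[:, :tag_len] = i5_codes[sample_of[all_src1]]
    m1[:, tag_len : tag_len + 4] = vbbn1[all_src1]
    m1[:, tag_len + 4 : tag_len + 4 + len(R1_REMNANT)] = [
        _CODE[b] for b in R1_REMNANT
    ]
    m1[:, tag_len + 4 + len(R1_REMNANT) :] = inserts[all_src1, :n1]
    m2[:, :tag_len] = i7_codes[sample_of[all_src2]]
    m2[:, tag_len : tag_len + 4] = vbbn2[all_src2]
    m2[:, tag_len + 4 : tag_len + 4 + len(R2_REMNANT)] = [
        _CODE[b] for b in R2_REMNANT
    ]
    # Mate 2 reads the reverse-complement strand from the insert's far end.
    rc_cols = ins_len[all_src2, None] - 1 - np.arange(n2)[None, :]
    m2[:, tag_len + 4 + len(R2_REMNANT) :] = 3 - np.take_along_axis(
        inserts[all_src2], rc_cols, axis=1
    )
    junk_rows = np.nonzero(all_junk)[0]
    if len(junk_rows):
        m1[junk_rows] = rng.integers(0, 4, size=(len(junk_rows), params.read_len))
        m2[junk_rows] = rng.integers(0, 4, size=(len(junk_rows), params.read_len))

    _mutate_codes(m1, params.error_rate, params.uncalled_rate, rng)
    _mutate_codes(m2, params.error_rate, params.uncalled_rate, rng)
    pass_filter = rng.random(N) >= params.chastity_fail_rate

    # Emit, grouped; primaries precede duplicates within each group stream.
    qual = _quality_string(params)
    b1 = _BASES[m1].tobytes()
    b2 = _BASES[m2].tobytes()
    L = params.read_len
    ids = [f"R{counter + i:08d}" for i in range(N)]
    sample_pair_i5 = {}
    sample_pair_i7 = {}
    for gi, g in enumerate(groups):
        for pair in g.inner_pairs:
            sid = f"{g.group_id}/{pair.i5.label}-{pair.i7.label}"
            sample_pair_i5[sid] = pair.i5.label
            sample_pair_i7[sid] = pair.i7.label

    order = np.argsort(all_group, kind="stable")
    truth_rows = {
        "read_id": [], "library_id": [], "emitted_group": [],
        "apparent_i5": [], "apparent_i7": [], "event": [], "parent_samples": [],
    }
    for i in order:
        i = int(i)
        gid = groups[all_group[i]].group_id
        rp = ReadPair(
            id=ids[i],
            seq1=b1[i * L : (i + 1) * L].decode(),
            qual1=qual,
            seq2=b2[i * L : (i + 1) * L].decode(),
            qual2=qual,
            pass_filter=bool(pass_filter[i]),
        )
        reads_by_group[gid].append(rp)
        s1 = sample_ids[sample_of[all_src1[i]]]
        s2 = sample_ids[sample_of[all_src2[i]]]
        if all_junk[i]:
            a5 = a7 = "*"
            parents = ""
        else:
            a5 = sample_pair_i5[s1]
            a7 = sample_pair_i7[s2]
            if all_event[i] in ("pcr_chimera", "seq_chimera"):
                parents = f"{s1}+{s2}"
            else:
                parents = s1
        truth_rows["read_id"].append(ids[i])
        truth_rows["library_id"].append(lib.library_id)
        truth_rows["emitted_group"].append(gid)
        truth_rows["apparent_i5"].append(a5)
        truth_rows["apparent_i7"].append(a7)
        truth_rows["event"].append(str(all_event[i]))
        truth_rows["parent_samples"].append(parents)
    truth_frames.append(pd.DataFrame(truth_rows))
    return counter + N


# ---------------------------------------------------------------------------
# On-disk interface
# ---------------------------------------------------------------------------


def write_run(run: SimulatedRun, outdir: str | Path, compress: bool = True) -> dict:
    """Write per-group paired FASTQ, the truth table (TSV) and a manifest.

    Returns the manifest dict. FASTQ headers are Illumina-style, carrying the
    read id, mate number and the pass-filter flag (``Y`` = filtered out).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".fq.gz" if compress else ".fq"
    opener = (lambda p: gzip.open(p, "wt")) if compress else (lambda p: open(p, "w"))
    files: dict[str, tuple[str, str]] = {}
    for g in run.scheme.groups():
        pairs = run.reads_by_group.get(g.group_id, [])
        outer = "+".join(g.outer_combo)
        p1 = outdir / f"{g.group_id}.1{suffix}"
        p2 = outdir / f"{g.group_id}.2{suffix}"
        with opener(p1) as f1, opener(p2) as f2:
            for rp in pairs:
                flag = "N" if rp.pass_filter else "Y"
                f1.write(f"@{rp.id} 1:{flag}:0:{outer}\n{rp.seq1}\n+\n{rp.qual1}\n")
                f2.write(f"@{rp.id} 2:{flag}:0:{outer}\n{rp.seq2}\n+\n{rp.qual2}\n")
        files[g.group_id] = (str(p1), str(p2))
    truth_path = outdir / "truth.tsv"
    run.truth.to_csv(truth_path, sep="\t", index=False)
    manifest = {
        "params": asdict(run.params),
        "n_reads": run.n_reads,
        "groups": files,
        "truth": str(truth_path),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
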
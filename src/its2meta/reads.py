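"""Paired-end read processing: primer screening, merging, quality
filtering, dereplication and de novo chimera flagging."""

from __future__ import annotations

from collections import Counter, defaultdict
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from ._seq import expected_errors, hamming, revcomp, seq_to_bytes


@dataclass
class ReadPair:
    """One raw paired-end read."""

    id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: str
    rev_qual: str
    sample: str

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(
            self.rev_qual
        ):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")


@dataclass
class MergedRead:
    id: str
    sequence: str
    qual: str
    sample: str
    amplicon_group: str
    abundance: int = 1


@dataclass
class DerepSeq:
    """A unique sequence with its summed copy count and provenance."""

    sequence: str
    abundance: int
    member_ids: list[str] = field(default_factory=list)
    sample_counts: dict[str, int] = field(default_factory=dict)
    amplicon_group: str = ""

    def __post_init__(self) -> None:
        if self.sample_counts and sum(self.sample_counts.values()) != self.abundance:
            raise ValueError("sample_counts must sum to abundance")


# ---------------------------------------------------------------------------
# Primer screening / demultiplexing into amplicon pools
# ---------------------------------------------------------------------------


def _primer_mismatches(read: str, primer: str) -> int:
    if len(read) < len(primer):
        return len(primer)  # incomplete primer counts as all-mismatch
    return hamming(read[: len(primer)], primer)


def screen_and_split(
    pairs: Sequence[ReadPair],
    primer_table: Mapping[str, tuple[str, str]],
    max_primer_mismatch: int = 1,
) -> dict[str, list[ReadPair]]:
    """Assign each pair to an amplicon pool by its primer tags.

    Both orientations are tried; a pair whose forward mate carries the
    reverse primer is re-oriented (mates swapped) so every retained read
    starts 5'->3' at the forward primer.  Primers are stripped from
    retained reads.  Pairs matching no primer system within tolerance go
    to ``discarded``.
    """
    if not primer_table:
        raise ValueError("primer table is empty")
    out: dict[str, list[ReadPair]] = {g: [] for g in primer_table}
    out["discarded"] = []
    for pair in pairs:
        placed = False
        for group, (fwd_primer, rev_primer) in primer_table.items():
            for fseq, rseq, fq, rq in (
                (pair.fwd_seq, pair.rev_seq, pair.fwd_qual, pair.rev_qual),
                (pair.rev_seq, pair.fwd_seq, pair.rev_qual, pair.fwd_qual),
            ):
                if (
                    _primer_mismatches(fseq, fwd_primer) <= max_primer_mismatch
                    and _primer_mismatches(rseq, rev_primer) <= max_primer_mismatch
                ):
                    out[group].append(
                        ReadPair(
                            id=pair.id,
                            fwd_seq=fseq[len(fwd_primer) :],
                            rev_seq=rseq[len(rev_primer) :],
                            fwd_qual=fq[len(fwd_primer) :],
                            rev_qual=rq[len(rev_primer) :],
                            sample=pair.sample,
                        )
                    )
                    placed = True
                    break
            if placed:
                break
        if not placed:
            out["discarded"].append(pair)
    total = sum(len(v) for v in out.values())
    if total != len(pairs):
        raise AssertionError("screen_and_split lost reads")
    return out


# ---------------------------------------------------------------------------
# Pair merging
# ---------------------------------------------------------------------------


def merge_pairs(
    pair: ReadPair,
    min_overlap: int = 10,
    max_overlap_mismatch_frac: float = 0.1,
    amplicon_group: str = "",
) -> MergedRead | None:
    """Merge mates at the best ungapped overlap, or reject.

    All overlap lengths from ``min_overlap`` up to the shorter mate are
    scanned; the feasible overlap (mismatch fraction within tolerance)
    with the most matching bases wins, longer overlaps breaking ties.
    At overlap mismatches the higher-quality base and its quality are
    retained; at agreeing positions the higher quality is kept.
    """
    if min_overlap < 1 or not 0.0 <= max_overlap_mismatch_frac <= 1.0:
        raise ValueError("invalid merge parameters")
    fwd, rc_rev = pair.fwd_seq, revcomp(pair.rev_seq)
    rc_qual = pair.rev_qual[::-1]
    lf, lr = len(fwd), len(rc_rev)
    if min(lf, lr) < min_overlap:
        return None

    # Relative shift d: fwd[i] pairs with rc_rev[i - d].  d >= 0 is the
    # normal "innie" layout; d < 0 is read-through into the opposite
    # primer ("outie"), where the dangling ends are adapter sequence and
    # only the overlap consensus is kept.
    fb, rb = seq_to_bytes(fwd), seq_to_bytes(rc_rev)
    best: tuple[int, int, int] | None = None  # (matches, overlap, shift)
    for d in range(-(lr - min_overlap), lf - min_overlap + 1):
        fstart = max(0, d)
        rstart = max(0, -d)
        o = min(lf - fstart, lr - rstart)
        if o < min_overlap:
            continue
        matches = int((fb[fstart : fstart + o] == rb[rstart : rstart + o]).sum())
        if o - matches > max_overlap_mismatch_frac * o:
            continue
        key = (matches, o, d)
        if best is None or key > best:
            best = key
    if best is None:
        return None

    _, o, d = best
    fstart, rstart = max(0, d), max(0, -d)
    head_seq, head_qual = fwd[:fstart], pair.fwd_qual[:fstart]
    tail_seq, tail_qual = rc_rev[rstart + o :], rc_qual[rstart + o :]
    mid_seq = []
    mid_qual = []
    for i in range(o):
        b1, q1 = fwd[fstart + i], pair.fwd_qual[fstart + i]
        b2, q2 = rc_rev[rstart + i], rc_qual[rstart + i]
        if b1 == b2:
            better_b, better_q = b1, max(q1, q2)
        elif q1 >= q2:
            better_b, better_q = b1, q1
        else:
            better_b, better_q = b2, q2
        mid_seq.append(better_b)
        mid_qual.append(better_q)
    return MergedRead(
        id=pair.id,
        sequence=head_seq + "".join(mid_seq) + tail_seq,
        qual=head_qual + "".join(mid_qual) + tail_qual,
        sample=pair.sample,
        amplicon_group=amplicon_group,
    )


def merge_pool(
    pairs: Sequence[ReadPair],
    amplicon_group: str,
    min_overlap: int = 10,
    max_overlap_mismatch_frac: float = 0.1,
) -> tuple[list[MergedRead], list[ReadPair]]:
    """Merge a pool of pairs, memoizing identical (seq, qual) mate pairs."""
    cache: dict[tuple[str, str, str, str], tuple[str, str] | None] = {}
    merged: list[MergedRead] = []
    rejected: list[ReadPair] = []
    for pair in pairs:
        key = (pair.fwd_seq, pair.rev_seq, pair.fwd_qual, pair.rev_qual)
        if key in cache:
            hit = cache[key]
            if hit is None:
                rejected.append(pair)
            else:
                merged.append(
                    MergedRead(pair.id, hit[0], hit[1], pair.sample, amplicon_group)
                )
            continue
        result = merge_pairs(pair, min_overlap, max_overlap_mismatch_frac, amplicon_group)
        if result is None:
            cache[key] = None
            rejected.append(pair)
        else:
            cache[key] = (result.sequence, result.qual)
            merged.append(result)
    return merged, rejected


# ---------------------------------------------------------------------------
# Quality filtering
# ---------------------------------------------------------------------------


def quality_filter(read: MergedRead, min_len: int = 200, max_ee: float = 1.0) -> bool:
    """Keep iff length > min_len and expected errors < max_ee (both strict)."""
    if len(read.sequence) <= min_len:
        return False
    return expected_errors(read.qual) < max_ee


def filter_pool(
    reads: Sequence[MergedRead], min_len: int = 200, max_ee: float = 1.0
) -> tuple[list[MergedRead], list[MergedRead]]:
    ee_cache: dict[str, float] = {}
    kept, discarded = [], []
    for read in reads:
        if len(read.sequence) <= min_len:
            discarded.append(read)
            continue
        ee = ee_cache.get(read.qual)
        if ee is None:
            ee = expected_errors(read.qual)
            ee_cache[read.qual] = ee
        (kept if ee < max_ee else discarded).append(read)
    return kept, discarded


# ---------------------------------------------------------------------------
# Dereplication
# ---------------------------------------------------------------------------


def dereplicate(reads: Sequence[MergedRead]) -> list[DerepSeq]:
    """Collapse identical sequences, sorted by decreasing abundance
    (ties broken lexicographically by sequence)."""
    abundance: Counter[str] = Counter()
    members: dict[str, list[str]] = defaultdict(list)
    samples: dict[str, Counter] = defaultdict(Counter)
    groups: dict[str, str] = {}
    for read in reads:
        abundance[read.sequence] += read.abundance
        members[read.sequence].append(read.id)
        samples[read.sequence][read.sample] += read.abundance
        groups.setdefault(read.sequence, read.amplicon_group)
    out = [
        DerepSeq(
            sequence=seq,
            abundance=abundance[seq],
            member_ids=members[seq],
            sample_counts=dict(samples[seq]),
            amplicon_group=groups[seq],
        )
        for seq in abundance
    ]
    out.sort(key=lambda d: (-d.abundance, d.sequence))
    return out


# ---------------------------------------------------------------------------
# De novo chimera detection
# ---------------------------------------------------------------------------


def _match_profile(candidate: np.ndarray, parent: str) -> np.ndarray:
    """Boolean per-position match of a parent against the candidate;
    positions beyond the parent's length count as mismatches."""
    pb = seq_to_bytes(parent)
    n = len(candidate)
    out = np.zeros(n, dtype=bool)
    m = min(n, len(pb))
    out[:m] = candidate[:m] == pb[:m]
    return out


def detect_chimeras_denovo(
    dereps: Sequence[DerepSeq],
    min_parent_fold: float = 2.0,
    min_improvement: float = 0.02,
    k_top_parents: int = 20,
    min_chimera_identity: float = 0.99,
) -> list[bool]:
    """Flag candidates explainable as a single-crossover of two parents.

    Parents must each be at least ``min_parent_fold`` times more abundant
    than the candidate (only the ``k_top_parents`` most abundant
    qualify), and the best two-parent model must beat the best single
    parent by ``min_improvement`` identity.  Ungapped model: parents are
    compared position-wise against the candidate.

    ``min_chimera_identity`` is an absolute floor on the two-parent
    model: a genuine crossover reproduces the candidate (nearly)
    perfectly, while maximizing over many parent pairs and breakpoints
    on honest sequences tops out well below 1 — without the floor that
    maximum alone generates false positives.
    """
    flags = [False] * len(dereps)
    for i, cand in enumerate(dereps):
        parents = [
            d for d in dereps[:i] if d.abundance >= min_parent_fold * cand.abundance
        ][:k_top_parents]
        if len(parents) < 2:
            continue
        cb = seq_to_bytes(cand.sequence)
        n = len(cb)
        profiles = np.array([_match_profile(cb, p.sequence) for p in parents])
        prefix = np.concatenate(
            [np.zeros((len(parents), 1), dtype=int), np.cumsum(profiles, axis=1)],
            axis=1,
        )  # prefix[p, b] = matches of parent p over candidate[:b]
        totals = prefix[:, -1]
        best_single = totals.max() / n
        if best_single >= 1.0:
            continue  # identical to a parent: never chimeric
        best_chimera = 0.0
        suffix = totals[:, None] - prefix  # matches of each parent over candidate[b:]
        for a in range(len(parents)):
            # crossover at b: left from parent a, right from parent c != a
            combined = prefix[a][None, 1:n] + suffix[:, 1:n]
            combined[a, :] = -1  # two distinct parents required
            score = combined.max() / n
            best_chimera = max(best_chimera, score)
        if (
            best_chimera >= min_chimera_identity
            and best_chimera - best_single >= min_improvement
        ):
            flags[i] = True
    return flags
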
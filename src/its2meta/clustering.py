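"""ITS2 core extraction, greedy centroid OTU clustering, abundance
flooring, and clone co-clustering."""

from __future__ import annotations

from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

from Bio import Align

from ._seq import hamming
from .reads import DerepSeq

REJECT_MOTIF_5P_MISSING = "motif_5p_missing"
REJECT_MOTIF_3P_MISSING = "motif_3p_missing"
REJECT_MOTIF_OVERLAP = "motif_overlap"


@dataclass
class OTU:
    id: str
    centroid: str
    members: list[tuple[DerepSeq, float]]
    sample_counts: dict[str, int] = field(default_factory=dict)
    total_reads: int = 0
    has_clone_member: bool = False
    amplicon_group: str = ""


# ---------------------------------------------------------------------------
# ITS2 core extraction (motif-proxy trimmer)
# ---------------------------------------------------------------------------


def _best_motif_hit(seq: str, motif: str, max_mismatch: int) -> tuple[int, int] | None:
    """(start, mismatches) of the best motif window, leftmost on ties."""
    m = len(motif)
    best: tuple[int, int] | None = None
    for start in range(len(seq) - m + 1):
        mm = hamming(seq[start : start + m], motif)
        if mm <= max_mismatch and (best is None or mm < best[1]):
            best = (start, mm)
            if mm == 0:
                break
    return best


def extract_its2(
    seq: str, motif_5p: str, motif_3p: str, max_motif_mismatch: int = 1
) -> tuple[str | None, str | None]:
    """Trim to the core strictly between the two conserved flank motifs.

    Returns ``(core, None)`` on success or ``(None, reason)`` when a
    motif is absent within tolerance or the motif hits overlap.
    """
    hit5 = _best_motif_hit(seq, motif_5p, max_motif_mismatch)
    if hit5 is None:
        return None, REJECT_MOTIF_5P_MISSING
    end5 = hit5[0] + len(motif_5p)
    hit3 = _best_motif_hit(seq[end5:], motif_3p, max_motif_mismatch)
    if hit3 is None:
        # a 3' motif overlapping the 5' hit is a distinct failure mode
        if _best_motif_hit(seq, motif_3p, max_motif_mismatch) is not None:
            return None, REJECT_MOTIF_OVERLAP
        return None, REJECT_MOTIF_3P_MISSING
    start3 = end5 + hit3[0]
    return seq[end5:start3], None


# ---------------------------------------------------------------------------
# Pairwise identity (global, end-gap free)
# ---------------------------------------------------------------------------

#: blastn-flavored scoring; terminal gaps are free so short/long pairs
#: are compared over their overlap.
_IDENTITY_ALIGNER = Align.PairwiseAligner()
_IDENTITY_ALIGNER.mode = "global"
_IDENTITY_ALIGNER.match_score = 2
_IDENTITY_ALIGNER.mismatch_score = -3
_IDENTITY_ALIGNER.open_gap_score = -7
_IDENTITY_ALIGNER.extend_gap_score = -2
_IDENTITY_ALIGNER.end_insertion_score = 0.0
_IDENTITY_ALIGNER.end_deletion_score = 0.0


def pairwise_identity(a: str, b: str) -> float:
    """Matching columns / alignment length, terminal gaps excluded.

    The alignment length is floored at the shorter sequence length so
    that degenerate overlap alignments of unrelated pairs (where the
    score optimum is a few-base overlap) cannot inflate identity.
    """
    if not a or not b:
        return 0.0
    if a == b:
        return 1.0
    if len(a) == len(b):
        matches = sum(x == y for x, y in zip(a, b))
        # gapless regime: with few substitutions an indel pair (two gap
        # opens) can never beat mismatches under this scoring
        if matches / len(a) >= 0.9:
            return matches / len(a)
    alignment = _IDENTITY_ALIGNER.align(a, b)[0]
    t, q = alignment[0], alignment[1]
    # trim terminal gap columns (end gaps are free, not part of the overlap)
    start = 0
    end = len(t)
    while start < end and (t[start] == "-" or q[start] == "-"):
        start += 1
    while end > start and (t[end - 1] == "-" or q[end - 1] == "-"):
        end -= 1
    if start >= end:
        return 0.0
    matches = sum(x == y and x != "-" for x, y in zip(t[start:end], q[start:end]))
    length = max(end - start, min(len(a), len(b)))
    return matches / length


# ---------------------------------------------------------------------------
# Greedy centroid clustering
# ---------------------------------------------------------------------------

_PRESCREEN_K = 8


def _kmer_set(seq: str, k: int = _PRESCREEN_K) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _prescreen_pass(
    kmers_a: set[str], kmers_b: set[str], len_a: int, len_b: int
) -> bool:
    """Cheap necessary condition for identity >= ~0.97.

    Two sequences at >= 97% identity over their overlap share the bulk
    of their k-mers (each edit destroys at most k of them); unrelated
    pairs share almost none.  A generous 40% cutoff cannot reject a
    true above-threshold pair but skips the vast majority of alignments.
    """
    m = min(len_a, len_b) - _PRESCREEN_K + 1
    if m <= 0:
        return True
    return len(kmers_a & kmers_b) >= 0.4 * m


def cluster_otus(
    dereps_sorted: Sequence[DerepSeq], identity_threshold: float = 0.97
) -> list[OTU]:
    """Greedy abundance-ordered centroid clustering.

    Every sequence is compared against ALL existing centroids (the
    exhaustive maxaccepts/maxrejects=0 regime) and joins the most
    similar centroid at or above the threshold; equally similar
    centroids resolve to the earlier-founded (more abundant) one.
    Output OTU ids are ranks of descending total read count.

    Centroid comparisons failing the k-mer prescreen are far below the
    threshold and are not aligned; they can affect neither membership
    nor the argmax over above-threshold centroids.
    """
    centroids: list[str] = []
    centroid_kmers: list[set[str]] = []
    clusters: list[list[tuple[DerepSeq, float]]] = []
    for derep in dereps_sorted:
        kmers = _kmer_set(derep.sequence)
        best_idx, best_identity = -1, -1.0
        for idx, centroid in enumerate(centroids):
            if not _prescreen_pass(
                kmers, centroid_kmers[idx], len(derep.sequence), len(centroid)
            ):
                continue
            identity = pairwise_identity(derep.sequence, centroid)
            if identity > best_identity:
                best_idx, best_identity = idx, identity
        if best_idx >= 0 and best_identity >= identity_threshold:
            clusters[best_idx].append((derep, best_identity))
        else:
            centroids.append(derep.sequence)
            centroid_kmers.append(kmers)
            clusters.append([(derep, 1.0)])

    otus: list[OTU] = []
    for centroid, members in zip(centroids, clusters):
        sample_counts: Counter[str] = Counter()
        group_votes: Counter[str] = Counter()
        for derep, _ in members:
            sample_counts.update(derep.sample_counts)
            group_votes[derep.amplicon_group] += derep.abundance
        otus.append(
            OTU(
                id="",
                centroid=centroid,
                members=members,
                sample_counts=dict(sample_counts),
                total_reads=sum(d.abundance for d, _ in members),
                amplicon_group=group_votes.most_common(1)[0][0] if group_votes else "",
            )
        )
    otus.sort(key=lambda o: (-o.total_reads, o.centroid))
    for rank, otu in enumerate(otus, start=1):
        otu.id = f"OTU_{rank:04d}"
    return otus


def filter_low_abundance(
    otus: Sequence[OTU],
    initial_read_total: int,
    floor_fraction: float = 0.00005,
) -> tuple[list[OTU], list[OTU]]:
    """Drop OTUs below the relative-abundance floor.

    The floor is ``floor_fraction`` of the initial (raw) read count of
    the run; removed OTUs are returned, not reassigned.
    """
    if not 0.0 <= floor_fraction <= 1.0:
        raise ValueError("floor_fraction must be in [0, 1]")
    floor = floor_fraction * initial_read_total
    kept = [o for o in otus if o.total_reads >= floor]
    removed = [o for o in otus if o.total_reads < floor]
    return kept, removed


def cocluster_clones(
    otus: Sequence[OTU],
    clone_seqs: Mapping[str, str],
    identity_threshold: float = 0.97,
) -> tuple[list[str], dict[str, list[str]]]:
    """Assign ITS2-trimmed clone sequences to existing OTU centroids.

    Clones matching a centroid at or above the threshold flag that OTU
    as mixed (``has_clone_member``); clones matching none are greedily
    clustered among themselves into clone-only clusters.  OTU read
    counts are unchanged — clones carry no abundance.

    Returns (assignment log lines, clone-only clusters keyed by their
    founding clone id).
    """
    assignments: list[str] = []
    unassigned: list[tuple[str, str]] = []
    for clone_id in sorted(clone_seqs):
        seq = clone_seqs[clone_id]
        best_otu, best_identity = None, -1.0
        for otu in otus:
            identity = pairwise_identity(seq, otu.centroid)
            if identity > best_identity:
                best_otu, best_identity = otu, identity
        if best_otu is not None and best_identity >= identity_threshold:
            best_otu.has_clone_member = True
            assignments.append(f"{clone_id}\t{best_otu.id}\t{best_identity:.4f}")
        else:
            unassigned.append((clone_id, seq))

    clone_only: dict[str, list[str]] = {}
    centroids: list[tuple[str, str]] = []
    for clone_id, seq in unassigned:
        best_key, best_identity = None, -1.0
        for key, centroid in centroids:
            identity = pairwise_identity(seq, centroid)
            if identity > best_identity:
                best_key, best_identity = key, identity
        if best_key is not None and best_identity >= identity_threshold:
            clone_only[best_key].append(clone_id)
        else:
            centroids.append((clone_id, seq))
            clone_only[clone_id] = [clone_id]
    return assignments, clone_only
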
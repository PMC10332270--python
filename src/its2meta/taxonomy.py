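"""Normalized bit scores, local alignment hit tables, consensus
taxonomic assignment, identity-class calling and site-overlap
classification.

The similarity currency throughout is the normalized bit score (NB):
the local-alignment bit score divided by the reference (subject)
sequence length.  Under default blastn scoring a full-length perfect
match of a ~228 bp reference tops out at NB = 1.81.
"""

from __future__ import annotations

import math
from collections import defaultdict
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

from Bio import Align

RANK_LADDER = ("genotype", "species", "genus", "order", "class")
#: lineage tuples are ordered class -> genotype
_LINEAGE_INDEX = {"class": 0, "order": 1, "genus": 2, "species": 3, "genotype": 4}

GENOTYPE_NB = 1.81
SPECIES_NB = 1.75
NB_TOLERANCE = 0.005

TARGET_CLASSES = frozenset(
    {"Chlorophyceae", "Trebouxiophyceae", "Ulvophyceae", "Xanthophyceae"}
)

BLAST_TABULAR_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "slen",
    "qcovs", "stitle",
]


@dataclass(frozen=True)
class ScoringParams:
    """blastn default megablast-style scoring with Karlin-Altschul stats."""

    reward: int = 2
    penalty: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    lam: float = 0.625
    k: float = 0.41


DEFAULT_SCORING = ScoringParams()


@dataclass
class BlastHit:
    query_id: str
    subject_id: str
    subject_length: int
    percent_identity: float
    alignment_length: int
    bit_score: float
    e_value: float
    query_coverage: float
    lineage: tuple[str, ...] = ()
    raw_label: str = ""

    def __post_init__(self) -> None:
        if self.bit_score < 0:
            raise ValueError("bit_score must be >= 0")
        if self.subject_length <= 0:
            raise ValueError("subject_length must be > 0")


@dataclass
class TaxonomyCall:
    otu_id: str
    label: str
    assigned_rank: str | None
    best_nb: float
    identity_class: str = "unidentified"
    is_target: bool = True
    support: dict[str, float] = field(default_factory=dict)
    lineage_class: str | None = None  # class-rank consensus, for composition


@dataclass
class OverlapCall:
    otu_id: str
    presence: str  # groupA_only | groupB_only | shared
    shared_breakdown: str  # genotype_identity | species_level | reference_independent | none

    def __post_init__(self) -> None:
        if (self.shared_breakdown == "none") != (self.presence != "shared"):
            raise ValueError("shared_breakdown must be 'none' iff presence is not 'shared'")


# ---------------------------------------------------------------------------
# Normalized bit score
# ---------------------------------------------------------------------------


def normalize_bitscore(hit: BlastHit) -> float:
    """NB = bit score / reference (subject) length."""
    if hit.subject_length <= 0:
        raise ValueError("subject_length must be positive")
    return hit.bit_score / hit.subject_length


def bits_from_raw(raw_score: float, scoring: ScoringParams = DEFAULT_SCORING) -> float:
    """Karlin-Altschul bit score: (lambda*S - ln K) / ln 2."""
    return (scoring.lam * raw_score - math.log(scoring.k)) / math.log(2.0)


# ---------------------------------------------------------------------------
# Local alignment producing blast-like hits
# ---------------------------------------------------------------------------


def _make_local_aligner(scoring: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.reward
    aligner.mismatch_score = scoring.penalty
    # BLAST gap of length k costs open + k*extend
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


_LOCAL_ALIGNERS: dict[ScoringParams, Align.PairwiseAligner] = {}


def align_local(
    query: str,
    reference: str,
    query_id: str = "query",
    subject_id: str = "subject",
    scoring: ScoringParams = DEFAULT_SCORING,
    min_bit_score: float = 30.0,
    lineage: tuple[str, ...] = (),
    raw_label: str = "",
) -> BlastHit | None:
    """Best local alignment as a blast-like hit, or None below the floor."""
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    aligner = _LOCAL_ALIGNERS.get(scoring)
    if aligner is None:
        aligner = _make_local_aligner(scoring)
        _LOCAL_ALIGNERS[scoring] = aligner
    raw = aligner.score(query, reference)
    if raw <= 0:
        return None
    bits = bits_from_raw(raw, scoring)
    if bits < min_bit_score:
        return None
    alignment = aligner.align(query, reference)[0]
    q_aln, s_aln = alignment[0], alignment[1]
    matches = sum(a == b and a != "-" for a, b in zip(q_aln, s_aln))
    aln_len = len(q_aln)
    (q_start, q_end) = alignment.aligned[0][0][0], alignment.aligned[0][-1][1]
    e_value = scoring.k * len(query) * len(reference) * math.exp(-scoring.lam * raw)
    return BlastHit(
        query_id=query_id,
        subject_id=subject_id,
        subject_length=len(reference),
        percent_identity=100.0 * matches / aln_len if aln_len else 0.0,
        alignment_length=aln_len,
        bit_score=bits,
        e_value=e_value,
        query_coverage=100.0 * (q_end - q_start) / len(query),
        lineage=lineage,
        raw_label=raw_label,
    )


def build_hit_table(
    query_id: str,
    query: str,
    references: Sequence[tuple[str, str, tuple[str, ...], str]],
    n_recorded: int = 50,
    scoring: ScoringParams = DEFAULT_SCORING,
    min_bit_score: float = 30.0,
) -> list[BlastHit]:
    """Align one query against (id, seq, lineage, raw_label) references;
    return the top ``n_recorded`` hits by decreasing bit score."""
    hits = []
    for subject_id, seq, lineage, raw_label in references:
        hit = align_local(
            query, seq,
            query_id=query_id, subject_id=subject_id,
            scoring=scoring, min_bit_score=min_bit_score,
            lineage=lineage, raw_label=raw_label,
        )
        if hit is not None:
            hits.append(hit)
    hits.sort(key=lambda h: (-h.bit_score, h.subject_id))
    return hits[:n_recorded]


# ---------------------------------------------------------------------------
# Consensus assignment
# ---------------------------------------------------------------------------


def _label_at_rank(hit: BlastHit, rank: str) -> str | None:
    idx = _LINEAGE_INDEX[rank]
    if len(hit.lineage) > idx:
        return hit.lineage[idx]
    return None


def consensus_assign(
    hits: Sequence[BlastHit],
    otu_id: str = "",
    n_consensus: int = 10,
    n_recorded: int = 50,
    target_classes: frozenset[str] | set[str] = TARGET_CLASSES,
    genotype_threshold: float = GENOTYPE_NB,
    species_threshold: float = SPECIES_NB,
    nb_tolerance: float = NB_TOLERANCE,
) -> TaxonomyCall:
    """Consensus taxonomic label from a recorded hit table.

    Candidacy is decided over the top ``n_consensus`` hits: at each rank,
    from most specific upward, the label with the highest bit-score sum
    is the candidate.  Genotype/species-rank candidates must be backed
    by a best-hit NB in the corresponding band; failing that the call
    falls back to genus ("<genus> sp."), then to "unidentified <order>"
    and "unidentified <class>".

    Non-target suppression is evaluated over all ``n_recorded`` hits:
    hits whose lineage is absent or outside the target classes are
    excluded from candidacy when the summed bit score of target-class
    hits exceeds the non-target sum; otherwise the OTU is called
    non-target with the dominant foreign label.
    """
    recorded = sorted(hits, key=lambda h: -h.bit_score)[:n_recorded]
    if not recorded:
        return TaxonomyCall(
            otu_id=otu_id, label="no_hit", assigned_rank=None,
            best_nb=0.0, identity_class="unidentified", is_target=False,
        )

    def is_target_hit(hit: BlastHit) -> bool:
        return bool(hit.lineage) and hit.lineage[0] in target_classes

    target_sum = sum(h.bit_score for h in recorded if is_target_hit(h))
    nontarget_sum = sum(h.bit_score for h in recorded if not is_target_hit(h))
    if target_sum <= nontarget_sum and nontarget_sum > 0:
        foreign: dict[str, float] = defaultdict(float)
        for h in recorded:
            if not is_target_hit(h):
                foreign[h.raw_label or h.subject_id] += h.bit_score
        label = min(foreign, key=lambda k: (-foreign[k], k))
        best_nb = max(normalize_bitscore(h) for h in recorded)
        return TaxonomyCall(
            otu_id=otu_id, label=label, assigned_rank=None,
            best_nb=best_nb,
            identity_class=classify_identity(
                best_nb, genotype_threshold, species_threshold, nb_tolerance
            ),
            is_target=False, support=dict(foreign),
        )

    retained = [h for h in recorded if is_target_hit(h)]
    top = retained[:n_consensus]
    best_nb = max(normalize_bitscore(h) for h in retained)
    identity_class = classify_identity(
        best_nb, genotype_threshold, species_threshold, nb_tolerance
    )

    def candidate_at(rank: str) -> tuple[str, dict[str, float], float] | None:
        support: dict[str, float] = defaultdict(float)
        best_single: dict[str, float] = defaultdict(float)
        best_label_nb: dict[str, float] = defaultdict(float)
        for h in top:
            label = _label_at_rank(h, rank)
            if label is None:
                continue
            support[label] += h.bit_score
            best_single[label] = max(best_single[label], h.bit_score)
            best_label_nb[label] = max(best_label_nb[label], normalize_bitscore(h))
        if not support:
            return None
        # ties: highest sum, then highest single best bit score, then name
        label = min(
            support, key=lambda k: (-support[k], -best_single[k], k)
        )
        return label, dict(support), best_label_nb[label]

    class_result = candidate_at("class")
    lineage_class = class_result[0] if class_result else None

    for rank in RANK_LADDER:
        result = candidate_at(rank)
        if result is None:
            continue
        label, support, label_nb = result
        if rank == "genotype":
            if label_nb >= genotype_threshold - nb_tolerance:
                return TaxonomyCall(
                    otu_id, label, rank, best_nb, identity_class, True, support,
                    lineage_class,
                )
        elif rank == "species":
            if label_nb >= species_threshold:
                return TaxonomyCall(
                    otu_id, label, rank, best_nb, identity_class, True, support,
                    lineage_class,
                )
        elif rank == "genus":
            return TaxonomyCall(
                otu_id, f"{label} sp.", rank, best_nb, identity_class, True,
                support, lineage_class,
            )
        else:
            return TaxonomyCall(
                otu_id, f"unidentified {label}", rank, best_nb,
                identity_class, True, support, lineage_class,
            )
    return TaxonomyCall(
        otu_id=otu_id, label="no_hit", assigned_rank=None,
        best_nb=best_nb, identity_class=identity_class, is_target=False,
    )


def classify_identity(
    best_nb: float,
    genotype_threshold: float = GENOTYPE_NB,
    species_threshold: float = SPECIES_NB,
    nb_tolerance: float = NB_TOLERANCE,
) -> str:
    """genotype / species / unidentified from the best-hit NB.

    The genotype ceiling "NB = 1.81" is operationalized as
    NB >= 1.81 - tolerance since bit scores shift slightly with length.
    """
    if best_nb >= genotype_threshold - nb_tolerance:
        return "genotype"
    if species_threshold <= best_nb < genotype_threshold - nb_tolerance:
        return "species"
    return "unidentified"


# ---------------------------------------------------------------------------
# Site-overlap classification
# ---------------------------------------------------------------------------

_BREAKDOWN = {
    "genotype": "genotype_identity",
    "species": "species_level",
    "unidentified": "reference_independent",
}


def classify_overlap(
    otu_table: "pd.DataFrame",
    calls: Mapping[str, TaxonomyCall],
    group_map: Mapping[str, str],
) -> tuple[list[OverlapCall], dict]:
    """Classify each OTU's presence across the two site groups.

    ``group_map`` sends each sample to groupA_north, groupA_south or
    groupB_reference; the two groupA sub-parts together form groupA.
    Shared OTUs are broken down by identity class, and the summary also
    counts shared OTUs present in both groupA sub-parts and per-class
    overlap.
    """
    for sample in otu_table.columns:
        if sample not in group_map:
            raise KeyError(f"sample {sample!r} missing from group map")
    a_north = [s for s in otu_table.columns if group_map[s] == "groupA_north"]
    a_south = [s for s in otu_table.columns if group_map[s] == "groupA_south"]
    group_a = a_north + a_south
    group_b = [s for s in otu_table.columns if group_map[s] == "groupB_reference"]

    overlap_calls: list[OverlapCall] = []
    summary: dict = {
        "groupA_only": 0, "groupB_only": 0, "shared": 0,
        "shared_breakdown": {
            "genotype_identity": 0, "species_level": 0, "reference_independent": 0,
        },
        "shared_in_both_subparts": 0,
        "per_class_overlap": defaultdict(lambda: {"groupA": 0, "shared": 0}),
    }
    for otu_id, row in otu_table.iterrows():
        in_a = bool((row[group_a] > 0).any()) if group_a else False
        in_b = bool((row[group_b] > 0).any()) if group_b else False
        if not in_a and not in_b:
            continue
        call = calls.get(otu_id)
        cls = call.lineage_class if call is not None else None
        if in_a and in_b:
            presence = "shared"
            breakdown = _BREAKDOWN[call.identity_class if call else "unidentified"]
        else:
            presence = "groupA_only" if in_a else "groupB_only"
            breakdown = "none"
        overlap_calls.append(OverlapCall(otu_id, presence, breakdown))
        summary[presence] += 1
        if cls is not None and in_a:
            summary["per_class_overlap"][cls]["groupA"] += 1
        if presence == "shared":
            if cls is not None:
                summary["per_class_overlap"][cls]["shared"] += 1
            summary["shared_breakdown"][breakdown] += 1
            north_hit = bool((row[a_north] > 0).any()) if a_north else False
            south_hit = bool((row[a_south] > 0).any()) if a_south else False
            if north_hit and south_hit:
                summary["shared_in_both_subparts"] += 1
    summary["per_class_overlap"] = dict(summary["per_class_overlap"])
    summary["groupA_total"] = summary["groupA_only"] + summary["shared"]
    summary["groupB_total"] = summary["groupB_only"] + summary["shared"]
    return overlap_calls, summary


# ---------------------------------------------------------------------------
# Percentage summaries of overlap / identity-class count tables
# ---------------------------------------------------------------------------


def percent(part: float, whole: float, ndigits: int = 1) -> float:
    """Presentation-layer percentage, rounded only here."""
    if whole == 0:
        return float("nan")
    return round(100.0 * part / whole, ndigits)


def overlap_percentages(summary: Mapping) -> dict[str, float]:
    """Headline overlap percentages from a classify_overlap summary."""
    shared = summary["shared"]
    return {
        "shared_of_groupA": percent(shared, summary["groupA_total"]),
        "shared_of_groupB": percent(shared, summary["groupB_total"]),
        "genotype_identity_of_shared": percent(
            summary["shared_breakdown"]["genotype_identity"], shared
        ),
        "species_level_of_shared": percent(
            summary["shared_breakdown"]["species_level"], shared
        ),
        "reference_independent_of_shared": percent(
            summary["shared_breakdown"]["reference_independent"], shared
        ),
        "shared_in_both_subparts_of_shared": percent(
            summary["shared_in_both_subparts"], shared
        ),
    }


def identity_class_percentages(calls: Sequence[TaxonomyCall]) -> dict[str, float]:
    """Identity-class fractions over the target (algal) OTUs."""
    algal = [c for c in calls if c.is_target]
    n = len(algal)
    n_genotype = sum(c.identity_class == "genotype" for c in algal)
    n_species = sum(c.identity_class == "species" for c in algal)
    return {
        "n_algal": n,
        "genotype_pct": percent(n_genotype, n),
        "species_pct": percent(n_species, n),
        "unambiguous_pct": percent(n_genotype + n_species, n),
    }


# ---------------------------------------------------------------------------
# BLAST tabular I/O
# ---------------------------------------------------------------------------


def read_blast_tabular(path, lineage_map: Mapping[str, tuple[str, ...]] | None = None):
    """Parse a 15-column outfmt-6-style TSV into hits grouped by query."""
    tables: dict[str, list[BlastHit]] = defaultdict(list)
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < len(BLAST_TABULAR_COLUMNS):
                raise ValueError(f"expected {len(BLAST_TABULAR_COLUMNS)} columns, got {len(f)}")
            lineage = tuple(lineage_map.get(f[1], ())) if lineage_map else ()
            tables[f[0]].append(
                BlastHit(
                    query_id=f[0], subject_id=f[1],
                    percent_identity=float(f[2]), alignment_length=int(f[3]),
                    e_value=float(f[10]), bit_score=float(f[11]),
                    subject_length=int(f[12]), query_coverage=float(f[13]),
                    raw_label=f[14], lineage=lineage,
                )
            )
    for hits in tables.values():
        hits.sort(key=lambda h: (-h.bit_score, h.subject_id))
    return dict(tables)


def write_blast_tabular(tables: Mapping[str, Sequence[BlastHit]], path) -> None:
    with open(path, "w") as fh:
        for query_id in tables:
            for h in tables[query_id]:
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            h.query_id, h.subject_id,
                            f"{h.percent_identity:.3f}", h.alignment_length,
                            0, 0, 0, 0, 0, 0,
                            f"{h.e_value:.3g}", f"{h.bit_score:.1f}",
                            h.subject_length, f"{h.query_coverage:.0f}",
                            h.raw_label or h.subject_id,
                        )
                    )
                    + "\n"
                )
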
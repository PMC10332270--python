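"""Synthetic amplicon data with known ground truth.

Generates a hierarchical reference database (class > order > genus >
species > genotype) with controlled pairwise divergence bands, site
communities with a controlled shared-genotype fraction between two site
groups, and error-bearing paired-end reads with primer tags, chimeras and
an off-target minority — everything the downstream pipeline assumes,
plus per-read truth tables for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from ._seq import error_rate_to_phred, qual_string, revcomp

logger = logging.getLogger(__name__)

RANKS = ("class", "order", "genus", "species", "genotype")

DEFAULT_CLASSES = (
    "Chlorophyceae",
    "Trebouxiophyceae",
    "Ulvophyceae",
    "Xanthophyceae",
)

#: Conserved flanks embedded around every ITS2 core; proxies for the
#: 5.8S / 28S rRNA ends that delimit the spacer in real amplicons.
MOTIF_5P = "TCGATGAAGAACGCAGCG"
MOTIF_3P = "CACGCCTGTCTGAGGGTC"

#: Fixed 20-mer primer tags, one pair per amplicon system.  The xantho
#: system targets Xanthophyceae, the green system the other three classes.
PRIMERS: dict[str, tuple[str, str]] = {
    "green": ("ACGGTCTAGCATCGTGGAAC", "TGCAGTTCACGAGGCATTCC"),
    "xantho": ("GTTACCGAGTCTTGACCGGA", "CCTAGAACGTTGCAGTCACG"),
}

#: Tag carried by off-target (non-algal) reads; never matches a primer.
OFFTARGET_TAG = "TTTTTGGGGGAAAAACCCCC"

XANTHO_CLASS = "Xanthophyceae"

MISLABELS = ("uncultured fungus clone", "uncultured eukaryote", "Diptera sp.")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class DivergenceSpecError(ValueError):
    """Raised for impossible divergence band combinations."""


@dataclass(frozen=True)
class TaxonNode:
    """One node of the synthetic taxonomy."""

    name: str
    rank: str
    parent: str | None
    lineage: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")


@dataclass(frozen=True)
class ReferenceRecord:
    """A reference sequence: conserved flank + ITS2 core + conserved flank."""

    id: str
    taxon: TaxonNode
    sequence: str
    core: str
    mislabeled_as: str | None = None

    @property
    def lineage(self) -> tuple[str, ...]:
        return self.taxon.lineage


@dataclass(frozen=True)
class DivergenceSpec:
    """Target pairwise-divergence bands for each taxonomic split.

    Bands are (low, high) fractions of differing ITS2-core positions for
    sequence pairs whose most recent shared node sits at that level.
    Inner bands must not exceed outer bands.
    """

    genotype: tuple[float, float] = (0.006, 0.018)
    species: tuple[float, float] = (0.05, 0.12)
    genus: tuple[float, float] = (0.18, 0.28)

    def __post_init__(self) -> None:
        for name in ("genotype", "species", "genus"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi < 0.75):
                raise DivergenceSpecError(
                    f"{name} band ({lo}, {hi}) is not an ordered pair in [0, 0.75)"
                )
        if self.genotype[1] > self.species[0]:
            raise DivergenceSpecError("genotype band must lie below the species band")
        if self.species[1] > self.genus[0]:
            raise DivergenceSpecError("species band must lie below the genus band")
        # each level's sampling target is the band minus the downstream
        # contribution (see build_reference_db); that subtraction needs
        # band widths that do not shrink towards the root
        if self._width("species") < self._width("genotype") or self._width(
            "genus"
        ) < self._width("species"):
            raise DivergenceSpecError("band widths must not shrink towards the root")

    def _width(self, name: str) -> float:
        lo, hi = getattr(self, name)
        return hi - lo

    def sampling_band(self, level: str) -> tuple[float, float]:
        """Mutation-target band for one level, downstream-compensated.

        Sibling records split at a level diverge by the level's own
        mutations plus the mutations each lineage accumulates below the
        split.  Subtracting the downstream band endpoint-wise makes the
        REALIZED pairwise divergence land in the requested band:
        species pairs carry one genotype-band contribution, genus pairs
        one species-band sampling contribution plus genotype.
        """
        if level == "genotype":
            return self.genotype
        if level == "species":
            return (
                self.species[0] - self.genotype[0],
                self.species[1] - self.genotype[1],
            )
        if level == "genus":
            return (self.genus[0] - self.species[0], self.genus[1] - self.species[1])
        raise ValueError(f"no band for level {level!r}")


@dataclass
class CommunityProfile:
    """Expected genotype read counts for one sampling site."""

    site: str
    group: str
    abundances: dict[str, int]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.abundances.values()):
            raise ValueError("abundances must be non-negative")
        if sum(self.abundances.values()) <= 0:
            raise ValueError(f"site {self.site}: per-site total must be > 0")


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one emitted read pair."""

    read_id: str
    genotype: str
    site: str
    amplicon_group: str  # green | xantho | offtarget
    is_chimera: bool = False
    parent_ids: tuple[str, str] | None = None


@dataclass
class SimulatedRun:
    """Read pairs plus their complete truth table."""

    pairs: list  # list[reads.ReadPair]; untyped to avoid a module cycle
    truth: list[TruthRow]
    skipped: list[str] = field(default_factory=list)

    def truth_by_id(self) -> dict[str, TruthRow]:
        return {row.read_id: row for row in self.truth}


# ---------------------------------------------------------------------------
# Reference database
# ---------------------------------------------------------------------------


def _random_core(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(_BASES, size=length)


def _mutate(
    rng: np.random.Generator, seq: np.ndarray, positions: np.ndarray
) -> np.ndarray:
    """Substitute each given position with a different random base."""
    out = seq.copy()
    for pos in positions:
        choices = _BASES[_BASES != out[pos]]
        out[pos] = rng.choice(choices)
    return out


def _diverge_children(
    rng: np.random.Generator,
    parent: np.ndarray,
    n_children: int,
    band: tuple[float, float],
) -> list[np.ndarray]:
    """Children of one node, mutated at disjoint position sets.

    Disjoint sets make the realized pairwise divergence between siblings
    exactly m_i + m_j differing positions, so the requested band is hit
    without stochastic slack at this level.
    """
    length = len(parent)
    target = rng.uniform(*band)
    # ceil keeps the realized sibling divergence (2m/length) at or above
    # the band floor even after integer rounding
    m = int(np.ceil(target * length / 2.0))
    if n_children * m > length:
        raise DivergenceSpecError(
            f"band {band} needs {n_children * m} mutated positions "
            f"but the core is only {length} bp"
        )
    pool = rng.permutation(length)
    children = []
    for i in range(n_children):
        positions = pool[i * m : (i + 1) * m]
        children.append(_mutate(rng, parent, positions))
    return children


def build_reference_db(
    n_genera_per_class: int = 3,
    n_species_per_genus: int = 2,
    n_genotypes_per_species: int = 2,
    divergence_spec: DivergenceSpec | None = None,
    seed: int = 0,
    classes: Sequence[str] = DEFAULT_CLASSES,
    core_length_range: tuple[int, int] = (174, 295),
    core_length_mean: float = 228.0,
    core_length_sd: float = 28.0,
    mislabeled_fraction: float = 0.0,
) -> list[ReferenceRecord]:
    """Generate the reference database for a nested taxonomy.

    Each class gets one ITS2 core length (substitution-only evolution
    preserves length along a lineage) drawn around ``core_length_mean``
    and clipped to ``core_length_range``.  A ``mislabeled_fraction`` of
    records is tagged with a foreign label (e.g. "uncultured fungus")
    without altering the sequence, mimicking misannotated database
    entries.
    """
    spec = divergence_spec or DivergenceSpec()
    if not 0.0 <= mislabeled_fraction <= 1.0:
        raise ValueError("mislabeled_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records: list[ReferenceRecord] = []
    acc = 0
    for ci, cls in enumerate(classes):
        length = int(
            np.clip(
                round(rng.normal(core_length_mean, core_length_sd)),
                *core_length_range,
            )
        )
        class_root = _random_core(rng, length)
        order = f"{cls[:-4]}ales"  # Chlorophyceae -> Chlorophyales
        genus_cores = _diverge_children(
            rng, class_root, n_genera_per_class, spec.sampling_band("genus")
        )
        for gi, genus_core in enumerate(genus_cores):
            genus = f"{cls[:4]}genus_{gi + 1}"
            species_cores = _diverge_children(
                rng, genus_core, n_species_per_genus, spec.sampling_band("species")
            )
            for si, species_core in enumerate(species_cores):
                species = f"{genus}_sp{si + 1}"
                if n_genotypes_per_species == 1 or spec.genotype == (0.0, 0.0):
                    genotype_cores = [species_core.copy()] * n_genotypes_per_species
                else:
                    genotype_cores = _diverge_children(
                        rng, species_core, n_genotypes_per_species, spec.genotype
                    )
                for ti, genotype_core in enumerate(genotype_cores):
                    genotype = f"{species}_gt{ti + 1}"
                    acc += 1
                    node = TaxonNode(
                        name=genotype,
                        rank="genotype",
                        parent=species,
                        lineage=(cls, order, genus, species, genotype),
                    )
                    core = genotype_core.tobytes().decode("ascii")
                    records.append(
                        ReferenceRecord(
                            id=f"SYN{acc:06d}",
                            taxon=node,
                            sequence=MOTIF_5P + core + MOTIF_3P,
                            core=core,
                        )
                    )
    if mislabeled_fraction > 0:
        n_mis = round(mislabeled_fraction * len(records))
        idx = rng.choice(len(records), size=n_mis, replace=False)
        for j, i in enumerate(sorted(idx)):
            records[i] = dataclasses.replace(
                records[i], mislabeled_as=MISLABELS[j % len(MISLABELS)]
            )
    return records


def taxonomy_table(records: Iterable[ReferenceRecord]) -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for rec in records:
        cls, order, genus, species, genotype = rec.lineage
        rows.append(
            {
                "id": rec.id,
                "class": cls,
                "order": order,
                "genus": genus,
                "species": species,
                "genotype": genotype,
                "mislabeled_as": rec.mislabeled_as or "",
            }
        )
    return pd.DataFrame(rows)


def write_reference_fasta(records: Iterable[ReferenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id} {';'.join(rec.lineage)}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# Communities
# ---------------------------------------------------------------------------

DEFAULT_SITES: dict[str, int] = {
    "groupA_north": 4,
    "groupA_south": 3,
    "groupB_reference": 1,
}


def simulate_communities(
    refdb: Sequence[ReferenceRecord],
    n_sites_per_group: Mapping[str, int] | None = None,
    shared_fraction: float = 0.35,
    seed: int = 0,
    reads_per_site: int = 50_000,
    lognormal_sigma: float = 1.0,
    group_b_pool_fraction: float = 0.5,
) -> list[CommunityProfile]:
    """Site communities with a controlled groupA/groupB genotype overlap.

    A pool fraction of all genotypes is assigned to groupB; of those,
    ``shared_fraction`` also occur in groupA, which additionally holds
    every genotype outside the groupB pool.  The realized count of
    genotypes present in both groups is therefore
    ``round(shared_fraction * |groupB pool|)`` exactly.  Per-site
    abundances are log-normal, converted to integer expected read counts
    by a multinomial draw of ``reads_per_site``.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    sites_per_group = dict(n_sites_per_group or DEFAULT_SITES)
    rng = np.random.default_rng(seed)
    genotypes = sorted({rec.taxon.name for rec in refdb})
    n = len(genotypes)
    n_b = max(1, round(group_b_pool_fraction * n))
    order = rng.permutation(n)
    pool_b = [genotypes[i] for i in sorted(order[:n_b])]
    rest = [genotypes[i] for i in sorted(order[n_b:])]
    n_shared = round(shared_fraction * n_b)
    shared_idx = rng.choice(n_b, size=n_shared, replace=False)
    shared = [pool_b[i] for i in sorted(shared_idx)]
    pool_a = sorted(rest + shared)

    profiles: list[CommunityProfile] = []
    for group in sorted(sites_per_group):
        members = pool_b if group == "groupB_reference" else pool_a
        for s in range(sites_per_group[group]):
            site = f"{group}_s{s + 1}"
            weights = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=len(members))
            counts = rng.multinomial(reads_per_site, weights / weights.sum())
            profiles.append(
                CommunityProfile(
                    site=site,
                    group=group,
                    abundances={g: int(c) for g, c in zip(members, counts)},
                )
            )
    return profiles


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


def _amplicon(record: ReferenceRecord, group: str) -> str:
    fwd, rev = PRIMERS[group]
    return fwd + record.sequence + revcomp(rev)


def amplicon_group_for(record: ReferenceRecord) -> str:
    return "xantho" if record.lineage[0] == XANTHO_CLASS else "green"


def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for pos in hits:
        choices = _BASES[_BASES != arr[pos]]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _read_pair_from_amplicon(
    amplicon: str, read_len: int
) -> tuple[str, str]:
    fwd = amplicon[:read_len]
    rev = revcomp(amplicon)[:read_len]
    return fwd, rev


def simulate_reads(
    profiles: Sequence[CommunityProfile],
    refdb: Sequence[ReferenceRecord],
    error_rate: float = 0.001,
    chimera_rate: float = 0.0,
    offtarget_fraction: float = 0.0,
    read_len: int = 250,
    seed: int = 0,
    min_merge_span: int = 20,
) -> SimulatedRun:
    """Emit primer-tagged paired-end reads plus a complete truth table.

    Chimeras are single-crossover recombinants of two parent amplicons
    from the same site and primer system, with a uniform breakpoint in
    the reference portion.  Off-target reads carry a non-primer tag and a
    random insert.  Quality strings are constant at the Phred score
    implied by ``error_rate``.  Records whose amplicon exceeds the
    mergeable span (2*read_len - min_merge_span) are skipped with a
    warning, emulating clone-only long sequences.
    """
    from .reads import ReadPair  # deferred: avoids an import cycle

    rng = np.random.default_rng(seed)
    by_genotype = {rec.taxon.name: rec for rec in refdb}
    q = error_rate_to_phred(error_rate)
    max_span = 2 * read_len - min_merge_span

    pairs: list[ReadPair] = []
    truth: list[TruthRow] = []
    skipped: list[str] = []
    counter = 0

    for profile in profiles:
        site_records = [
            (g, by_genotype[g]) for g in sorted(profile.abundances) if profile.abundances[g] > 0
        ]
        usable = []
        for g, rec in site_records:
            if len(_amplicon(rec, amplicon_group_for(rec))) > max_span:
                if rec.id not in skipped:
                    skipped.append(rec.id)
                    logger.warning(
                        "record %s (%s): amplicon longer than mergeable span, skipped",
                        rec.id,
                        g,
                    )
                continue
            usable.append((g, rec))
        by_group: dict[str, list[ReferenceRecord]] = {}
        for _, rec in usable:
            by_group.setdefault(amplicon_group_for(rec), []).append(rec)

        fast = error_rate == 0 and chimera_rate == 0 and offtarget_fraction == 0
        for g, rec in usable:
            count = profile.abundances[g]
            group = amplicon_group_for(rec)
            amp = _amplicon(rec, group)
            if fast:
                fwd, rev = _read_pair_from_amplicon(amp, read_len)
                fq, rq = qual_string(q, len(fwd)), qual_string(q, len(rev))
                swap = rng.random(count) < 0.5
                for i in range(count):
                    counter += 1
                    rid = f"read_{counter:08d}"
                    if swap[i]:
                        pairs.append(ReadPair(rid, rev, fwd, rq, fq, profile.site))
                    else:
                        pairs.append(ReadPair(rid, fwd, rev, fq, rq, profile.site))
                    truth.append(TruthRow(rid, g, profile.site, group))
                continue

            is_chim = rng.random(count) < chimera_rate
            is_off = rng.random(count) < offtarget_fraction
            swap = rng.random(count) < 0.5
            group_mates = [r for r in by_group[group] if r.id != rec.id]
            for i in range(count):
                counter += 1
                rid = f"read_{counter:08d}"
                if is_off[i]:
                    insert_len = rng.integers(180, 260)
                    insert = rng.choice(_BASES, size=insert_len).tobytes().decode()
                    read_amp = OFFTARGET_TAG + insert + OFFTARGET_TAG
                    row = TruthRow(rid, "offtarget", profile.site, "offtarget")
                elif is_chim[i] and group_mates:
                    mate = group_mates[rng.integers(len(group_mates))]
                    amp2 = _amplicon(mate, group)
                    limit = min(len(amp), len(amp2))
                    bp = int(rng.integers(30, limit - 30))
                    read_amp = amp[:bp] + amp2[bp:]
                    row = TruthRow(
                        rid,
                        g,
                        profile.site,
                        group,
                        is_chimera=True,
                        parent_ids=(rec.id, mate.id),
                    )
                else:
                    read_amp = amp
                    row = TruthRow(rid, g, profile.site, group)
                fwd, rev = _read_pair_from_amplicon(read_amp, read_len)
                fwd = _apply_errors(rng, fwd, error_rate)
                rev = _apply_errors(rng, rev, error_rate)
                fq, rq = qual_string(q, len(fwd)), qual_string(q, len(rev))
                if swap[i]:
                    fwd, rev, fq, rq = rev, fwd, rq, fq
                pairs.append(ReadPair(rid, fwd, rev, fq, rq, profile.site))
                truth.append(row)

    if len(pairs) != len(truth):
        raise AssertionError("read/truth conservation violated")
    return SimulatedRun(pairs=pairs, truth=truth, skipped=skipped)


def write_fastq_pair(pairs, fwd_path, rev_path) -> None:
    with open(fwd_path, "w") as f1, open(rev_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id} 1:N:0 sample={p.sample}\n{p.fwd_seq}\n+\n{p.fwd_qual}\n")
            f2.write(f"@{p.id} 2:N:0 sample={p.sample}\n{p.rev_seq}\n+\n{p.rev_qual}\n")


def write_truth_table(truth: Sequence[TruthRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tgenotype\tsite\tamplicon_group\tis_chimera\tparent_ids\n")
        for row in truth:
            parents = ",".join(row.parent_ids) if row.parent_ids else ""
            fh.write(
                f"{row.read_id}\t{row.genotype}\t{row.site}\t{row.amplicon_group}"
                f"\t{int(row.is_chimera)}\t{parents}\n"
            )
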
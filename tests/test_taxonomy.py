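import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from its2meta.taxonomy import (
    DEFAULT_SCORING,
    BlastHit,
    align_local,
    bits_from_raw,
    build_hit_table,
    classify_identity,
    classify_overlap,
    consensus_assign,
    normalize_bitscore,
    overlap_percentages,
    percent,
    read_blast_tabular,
    write_blast_tabular,
)

BASES = list("ACGT")


def mk_hit(
    bit_score,
    subject_length=228,
    lineage=(),
    raw_label="",
    subject_id="ref1",
    query_id="q1",
):
    return BlastHit(
        query_id=query_id,
        subject_id=subject_id,
        subject_length=subject_length,
        percent_identity=99.0,
        alignment_length=subject_length,
        bit_score=bit_score,
        e_value=1e-50,
        query_coverage=100.0,
        lineage=lineage,
        raw_label=raw_label,
    )


# ---------------------------------------------------------------------------
# NB
# ---------------------------------------------------------------------------


class TestNormalizeBitscore:
    def test_ceiling_228bp(self):
        assert round(normalize_bitscore(mk_hit(412.5, 228)), 2) == 1.81

    def test_zero_bits(self):
        assert normalize_bitscore(mk_hit(0.0, 228)) == 0.0

    def test_half(self):
        assert normalize_bitscore(mk_hit(200.0, 400)) == pytest.approx(0.5)

    def test_invalid_subject_length(self):
        with pytest.raises(ValueError):
            mk_hit(100.0, 0)


# ---------------------------------------------------------------------------
# local alignment vs a quadratic affine-gap DP oracle
# ---------------------------------------------------------------------------


def local_align_oracle(query, ref, scoring=DEFAULT_SCORING):
    """Textbook Gotoh local alignment, quadratic, pure Python."""
    n, m = len(query), len(ref)
    go = scoring.gap_open + scoring.gap_extend  # first gap base
    ge = scoring.gap_extend
    NEG = -(10**9)
    best = 0
    h_prev = [0] * (m + 1)
    e_prev = [NEG] * (m + 1)
    for i in range(1, n + 1):
        h_cur = [0] * (m + 1)
        e_cur = [NEG] * (m + 1)
        f = NEG
        for j in range(1, m + 1):
            s = scoring.reward if query[i - 1] == ref[j - 1] else scoring.penalty
            e_cur[j] = max(h_prev[j] - go, e_prev[j] - ge)
            f = max(h_cur[j - 1] - go, f - ge)
            h = max(0, h_prev[j - 1] + s, e_cur[j], f)
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, e_prev = h_cur, e_cur
    return best


def raw_from_bits(bits, scoring=DEFAULT_SCORING):
    return (bits * math.log(2) + math.log(scoring.k)) / scoring.lam


class TestAlignLocal:
    def test_perfect_self_match_228(self, rng):
        seq = "".join(rng.choice(BASES, 228))
        hit = align_local(seq, seq)
        assert hit is not None
        # closed form: raw = 2*228, bits = (lambda*S - ln K)/ln 2
        assert hit.bit_score == pytest.approx(bits_from_raw(456), abs=1e-9)
        assert round(normalize_bitscore(hit), 2) == 1.81
        assert hit.percent_identity == pytest.approx(100.0)
        assert hit.query_coverage == pytest.approx(100.0)

    def test_zero_similarity_omitted(self):
        assert align_local("A" * 100, "C" * 100) is None

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_local("", "ACGT")

    def test_matches_dp_oracle_randomized(self):
        rng = np.random.default_rng(99)
        checked = 0
        for _ in range(50):
            la, lb = int(rng.integers(30, 150)), int(rng.integers(30, 150))
            a = "".join(rng.choice(BASES, la))
            if rng.random() < 0.5:
                # related pair: mutate + indel
                b = list(a)
                for i in range(len(b)):
                    if rng.random() < 0.1:
                        b[i] = BASES[int(rng.integers(4))]
                b = "".join(b)[: int(rng.integers(20, la + 1))]
            else:
                b = "".join(rng.choice(BASES, lb))
            expected_raw = local_align_oracle(a, b)
            hit = align_local(a, b, min_bit_score=0.0)
            if hit is None:
                assert expected_raw <= 0
            else:
                assert raw_from_bits(hit.bit_score) == pytest.approx(
                    expected_raw, abs=1e-6
                )
                checked += 1
        assert checked >= 20


# ---------------------------------------------------------------------------
# consensus assignment
# ---------------------------------------------------------------------------

LINEAGE_ULVO = ("Ulvophyceae", "Ulvophyales", "Planophila", "Planophila_sp1", "P_gt1")


def planophila_table():
    """21 foreign 'uncultured fungus' hits + 29 Ulvophyceae hits where
    Planophila has the top within-class bit-score sum but best NB < 1.5."""
    hits = []
    for i in range(21):
        hits.append(
            mk_hit(300 - i, lineage=(), raw_label="uncultured fungus",
                   subject_id=f"fun{i}")
        )
    for i in range(10):  # Planophila: highest within-class sum
        hits.append(
            mk_hit(
                320 - i, subject_length=228,
                lineage=("Ulvophyceae", "Ulvophyales", "Planophila",
                         f"Planophila_sp{i % 2 + 1}"),
                subject_id=f"plano{i}",
            )
        )
    for i in range(19):
        hits.append(
            mk_hit(
                250 - i, subject_length=228,
                lineage=("Ulvophyceae", "Ulvophyales", f"OtherUlvo{i % 4}"),
                subject_id=f"ulvo{i}",
            )
        )
    return sorted(hits, key=lambda h: -h.bit_score)


class TestConsensusAssign:
    def test_foreign_hits_outcompeted_genus_assigned(self):
        hits = planophila_table()
        # NB of the best hit is 320/228 = 1.40 < 1.5: below the species band
        call = consensus_assign(hits, otu_id="OTU_0006")
        assert call.is_target
        assert call.assigned_rank == "genus"
        assert call.label == "Planophila sp."
        assert call.best_nb < 1.5
        assert call.identity_class == "unidentified"

    def test_foreign_hits_win_when_sum_larger(self):
        hits = [
            mk_hit(500 - i, lineage=(), raw_label="uncultured fungus",
                   subject_id=f"f{i}")
            for i in range(30)
        ] + [
            mk_hit(100, lineage=LINEAGE_ULVO[:3], subject_id="u1"),
        ]
        call = consensus_assign(hits)
        assert not call.is_target
        assert call.label == "uncultured fungus"
        assert call.assigned_rank is None

    def test_all_hits_one_species_high_nb(self):
        lineage = ("Trebouxiophyceae", "Trebouxiales", "Elliptochloris",
                   "E_subsphaerica")
        hits = [
            mk_hit(410.4 - i, subject_length=228, lineage=lineage,
                   subject_id=f"r{i}")
            for i in range(10)
        ]
        call = consensus_assign(hits)
        # best NB = 1.80: species band, species rank
        assert call.assigned_rank == "species"
        assert call.label == "E_subsphaerica"
        assert call.identity_class == "species"

    def test_genotype_rank_at_ceiling(self):
        lineage = LINEAGE_ULVO
        hits = [mk_hit(412.5, subject_length=228, lineage=lineage)]
        call = consensus_assign(hits)
        assert call.assigned_rank == "genotype"
        assert call.label == "P_gt1"
        assert call.identity_class == "genotype"

    def test_empty_hits(self):
        call = consensus_assign([], otu_id="x")
        assert call.label == "no_hit"
        assert call.identity_class == "unidentified"
        assert not call.is_target

    def test_class_only_lineage_falls_back_to_unidentified_class(self):
        hits = [
            mk_hit(200 - i, lineage=("Xanthophyceae",), subject_id=f"x{i}")
            for i in range(5)
        ]
        call = consensus_assign(hits)
        assert call.assigned_rank == "class"
        assert call.label == "unidentified Xanthophyceae"

    def test_order_fallback(self):
        hits = [
            mk_hit(200 - i, lineage=("Chlorophyceae", "Chlamydomonadales"),
                   subject_id=f"c{i}")
            for i in range(5)
        ]
        call = consensus_assign(hits)
        assert call.assigned_rank == "order"
        assert call.label == "unidentified Chlamydomonadales"


# --- randomized oracle ------------------------------------------------------

RANKS = ("genotype", "species", "genus", "order", "class")
_IDX = {"class": 0, "order": 1, "genus": 2, "species": 3, "genotype": 4}


def consensus_oracle(hits, n_consensus=10, n_recorded=50,
                     target_classes=("Chlorophyceae", "Trebouxiophyceae",
                                     "Ulvophyceae", "Xanthophyceae")):
    """Plain re-statement of the decision rules by brute enumeration."""
    recorded = sorted(hits, key=lambda h: -h.bit_score)[:n_recorded]
    if not recorded:
        return ("no_hit", None)
    is_target = lambda h: bool(h.lineage) and h.lineage[0] in target_classes
    t_sum = sum(h.bit_score for h in recorded if is_target(h))
    f_sum = sum(h.bit_score for h in recorded if not is_target(h))
    if t_sum <= f_sum and f_sum > 0:
        sums = {}
        for h in recorded:
            if not is_target(h):
                key = h.raw_label or h.subject_id
                sums[key] = sums.get(key, 0) + h.bit_score
        label = max(sorted(sums), key=lambda k: sums[k])
        return (label, None)
    top = [h for h in recorded if is_target(h)][:n_consensus]
    for rank in RANKS:
        idx = _IDX[rank]
        entries = {}
        for h in top:
            if len(h.lineage) > idx:
                lab = h.lineage[idx]
                e = entries.setdefault(lab, {"sum": 0.0, "best": 0.0, "nb": 0.0})
                e["sum"] += h.bit_score
                e["best"] = max(e["best"], h.bit_score)
                e["nb"] = max(e["nb"], h.bit_score / h.subject_length)
        if not entries:
            continue
        label = min(entries, key=lambda k: (-entries[k]["sum"],
                                            -entries[k]["best"], k))
        nb = entries[label]["nb"]
        if rank == "genotype" and nb >= 1.805:
            return (label, rank)
        if rank == "species" and nb >= 1.75:
            return (label, rank)
        if rank == "genus":
            return (f"{label} sp.", rank)
        if rank in ("order", "class"):
            return (f"unidentified {label}", rank)
    return ("no_hit", None)


def random_hit_table(rng):
    classes = ["Chlorophyceae", "Trebouxiophyceae", "Ulvophyceae",
               "Xanthophyceae", None]
    hits = []
    for i in range(int(rng.integers(1, 31))):
        cls = classes[int(rng.integers(len(classes)))]
        if cls is None:
            lineage = ()
            raw = "uncultured fungus" if rng.random() < 0.5 else "Diptera sp."
        else:
            depth = int(rng.integers(1, 6))
            lineage = tuple(
                f"{cls[:4]}_{r}{int(rng.integers(3))}" for r in RANKS[::-1][:depth]
            )
            lineage = (cls,) + lineage[1:]
            raw = ""
        hits.append(
            mk_hit(
                float(rng.integers(50, 460)),
                subject_length=int(rng.integers(174, 296)),
                lineage=lineage,
                raw_label=raw,
                subject_id=f"s{i}",
            )
        )
    return hits


class TestConsensusOracleEquivalence:
    def test_randomized(self):
        rng = np.random.default_rng(4242)
        for _ in range(300):
            hits = random_hit_table(rng)
            call = consensus_assign(hits)
            label, rank = consensus_oracle(hits)
            assert (call.label, call.assigned_rank) == (label, rank)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        hits = random_hit_table(rng)
        call1 = consensus_assign(hits)
        order = rng.permutation(len(hits))
        call2 = consensus_assign([hits[i] for i in order])
        assert (call1.label, call1.assigned_rank) == (call2.label, call2.assigned_rank)


# ---------------------------------------------------------------------------
# identity classes
# ---------------------------------------------------------------------------


class TestClassifyIdentity:
    @pytest.mark.parametrize(
        "nb,expected",
        [
            (1.81, "genotype"),
            (1.806, "genotype"),
            (1.80, "species"),
            (1.76, "species"),
            (1.75, "species"),
            (1.73, "unidentified"),
            (0.0, "unidentified"),
        ],
    )
    def test_examples(self, nb, expected):
        assert classify_identity(nb) == expected

    @given(st.floats(0.0, 2.0))
    @settings(max_examples=200, deadline=None)
    def test_partition(self, nb):
        classes = [classify_identity(nb)]
        assert classes[0] in {"genotype", "species", "unidentified"}
        # exactly one class matches
        assert (
            sum(
                [
                    nb >= 1.805,
                    1.75 <= nb < 1.805,
                    nb < 1.75,
                ]
            )
            == 1
        )


# ---------------------------------------------------------------------------
# overlap classification
# ---------------------------------------------------------------------------


def mk_call(otu_id, identity_class="genotype", cls="Chlorophyceae"):
    from its2meta.taxonomy import TaxonomyCall

    return TaxonomyCall(
        otu_id=otu_id, label="x", assigned_rank="genotype", best_nb=1.81,
        identity_class=identity_class, lineage_class=cls,
    )


class TestClassifyOverlap:
    def table(self):
        return pd.DataFrame(
            {
                "an1": [5, 0, 3, 1],
                "as1": [2, 0, 0, 1],
                "b1": [0, 4, 2, 1],
            },
            index=["o1", "o2", "o3", "o4"],
        )

    def group_map(self):
        return {"an1": "groupA_north", "as1": "groupA_south", "b1": "groupB_reference"}

    def test_presence_classes(self):
        calls = {o: mk_call(o) for o in ["o1", "o2", "o3", "o4"]}
        overlap_calls, summary = classify_overlap(self.table(), calls, self.group_map())
        by_id = {c.otu_id: c for c in overlap_calls}
        assert by_id["o1"].presence == "groupA_only"
        assert by_id["o2"].presence == "groupB_only"
        assert by_id["o3"].presence == "shared"
        assert by_id["o4"].presence == "shared"
        assert summary["shared"] == 2
        assert summary["groupA_total"] == 3
        assert summary["groupB_total"] == 3
        # o4 is present in both groupA sub-parts, o3 only in the north
        assert summary["shared_in_both_subparts"] == 1

    def test_breakdown_follows_identity_class(self):
        calls = {
            "o1": mk_call("o1"),
            "o2": mk_call("o2"),
            "o3": mk_call("o3", "species"),
            "o4": mk_call("o4", "unidentified"),
        }
        overlap_calls, summary = classify_overlap(self.table(), calls, self.group_map())
        assert summary["shared_breakdown"] == {
            "genotype_identity": 0,
            "species_level": 1,
            "reference_independent": 1,
        }
        for c in overlap_calls:
            assert (c.shared_breakdown == "none") == (c.presence != "shared")

    def test_missing_sample_raises(self):
        calls = {o: mk_call(o) for o in ["o1", "o2", "o3", "o4"]}
        with pytest.raises(KeyError):
            classify_overlap(self.table(), calls, {"an1": "groupA_north"})

    def test_printed_count_percentages(self):
        # 830 groupA / 214 groupB / 75 shared
        summary = {
            "shared": 75,
            "groupA_total": 830,
            "groupB_total": 214,
            "shared_breakdown": {
                "genotype_identity": 24,
                "species_level": 21,
                "reference_independent": 30,
            },
            "shared_in_both_subparts": 36,
        }
        pct = overlap_percentages(summary)
        assert pct["shared_of_groupA"] == 9.0
        assert pct["shared_of_groupB"] == 35.0
        assert pct["genotype_identity_of_shared"] == 32.0
        assert pct["shared_in_both_subparts_of_shared"] == 48.0


# ---------------------------------------------------------------------------
# blast tabular I/O
# ---------------------------------------------------------------------------


class TestBlastTabularIO:
    def test_round_trip(self, tmp_path, small_db):
        refs = [
            (r.id, r.core, r.lineage, r.taxon.name) for r in small_db[:6]
        ]
        table = {"q1": build_hit_table("q1", small_db[0].core, refs)}
        path = tmp_path / "blastout.tsv"
        write_blast_tabular(table, path)
        lineage_map = {r.id: r.lineage for r in small_db}
        back = read_blast_tabular(path, lineage_map)
        assert list(back) == ["q1"]
        assert len(back["q1"]) == len(table["q1"])
        for orig, rt in zip(table["q1"], back["q1"]):
            assert rt.subject_id == orig.subject_id
            assert rt.bit_score == pytest.approx(orig.bit_score, abs=0.05)
            assert rt.subject_length == orig.subject_length
            assert rt.lineage == orig.lineage

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("q1\tref1\t99.0\n")
        with pytest.raises(ValueError):
            read_blast_tabular(path)


def test_percent_rounding():
    assert percent(830, 848) == 97.9
    assert percent(1, 0) != percent(1, 0)  # NaN for empty denominators
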
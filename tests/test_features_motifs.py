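"""Degron/structure/PTM features: motif finders vs naive regex oracles,
SEG vs direct entropy tables, heuristics on constructed sequences, and
reader-backend substitutability."""

import math
import re
from collections import Counter

import numpy as np
import pytest

from conftest import random_sequence
from shortprot.features_core import KYTE_DOOLITTLE
from shortprot.features_motifs import (RESIDUE_MASS, Backends, DboxReader,
                                       IupredReader, PsipredReader,
                                       PtmTableReader, Region, SignalPReader,
                                       TmhmmReader, count_ptm_sites,
                                       extract_features, find_dbox,
                                       find_ken_box, find_lcr, find_pest,
                                       nterm_onehot, pest_score,
                                       predict_disorder,
                                       predict_secondary_structure,
                                       predict_signal_peptide, predict_tm,
                                       window_entropy)
from shortprot.seqio import ALPHABET, SCHEMA, ProteinRecord, ValidationError

AA_IDX = {a: i for i, a in enumerate(ALPHABET)}


class TestKenBox:
    @pytest.mark.parametrize("seq,exists", [
        ("KENAAAN", 1), ("KENAAAD", 1), ("KENAAAQ", 0), ("AKENXXXN".replace("X", "G"), 1),
    ])
    def test_examples(self, seq, exists):
        assert find_ken_box(seq)[0] == exists

    def test_matches_naive_regex_scan(self, rng):
        for _ in range(30):
            seq = random_sequence(rng, 200)
            _, hits = find_ken_box(seq)
            naive = [i for i in range(len(seq) - 6)
                     if seq[i:i + 3] == "KEN" and seq[i + 6] in "ND"]
            assert [h.start for h in hits] == naive


class TestDbox:
    def test_examples(self):
        scores = find_dbox("RAALGG")
        assert scores[2] > 0  # cyclin-B-style RxxLG core at position 0
        assert np.all(find_dbox("GGGGGG") == 0.0)
        assert np.all(find_dbox("A" * 100) == 0.0)

    def test_counts_match_naive_scan(self, rng):
        for _ in range(20):
            seq = random_sequence(rng, 200)
            scores = find_dbox(seq)
            rxxl = [i for i in range(len(seq) - 3)
                    if seq[i] == "R" and seq[i + 3] == "L"]
            assert scores[3] == len(rxxl)  # securin = bare core
            cb = sum(1 for i in rxxl if i + 4 < len(seq) and seq[i + 4] == "G")
            assert scores[2] == cb


class TestPest:
    def test_constructed_candidate_found(self):
        _, feats = find_pest("K" + "PESTSEDEDSPT" + "R")
        assert feats[0] >= 1

    def test_no_pest_without_required_residues(self):
        _, feats = find_pest("K" + "A" * 12 + "R")
        assert np.all(feats == 0.0)

    def test_score_matches_hand_formula(self):
        """Independent evaluation of the documented mass-fraction formula."""
        seg = "PESTSEDEDSPTQG"  # fixed 14-residue candidate
        total = sum(RESIDUE_MASS[c] for c in seg)
        depst = sum(RESIDUE_MASS[c] for c in seg if c in "DEPST")
        depst -= RESIDUE_MASS["D"] + RESIDUE_MASS["P"] + RESIDUE_MASS["S"]
        hi = sum(10 * KYTE_DOOLITTLE[c] + 45 for c in seg) / len(seg)
        expected = 0.55 * (100 * depst / total) - 0.5 * hi
        assert pest_score(seg) == pytest.approx(expected, abs=1e-12)
        regions, feats = find_pest("K" + seg + "R")
        assert feats[2] == pytest.approx(expected)
        assert feats[3] == pytest.approx((1 + 15) / 2 / 16)  # midpoint / L

    def test_regions_respect_invariants(self, rng):
        for _ in range(20):
            seq = random_sequence(rng, 300)
            regions, feats = find_pest(seq)
            for a, b in zip(regions, regions[1:]):
                assert a.end <= b.start
            if regions:
                assert feats[1] == max(len(r) for r in regions)


def entropy_table(seq, window=12):
    """Independent per-window Shannon entropy computation."""
    out = []
    for i in range(len(seq) - window + 1):
        counts = Counter(seq[i:i + window])
        out.append(-sum(k / window * math.log2(k / window)
                        for k in counts.values()))
    return out


class TestLcr:
    def test_homopolymer_is_one_full_lcr(self):
        regions, feats = find_lcr("A" * 50)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 50)
        assert window_entropy("A" * 12) == 0.0

    def test_maximally_mixed_has_none(self):
        seq = "".join(ALPHABET[i % 20] for i in range(50))
        regions, feats = find_lcr(seq)
        assert feats[1] == 0.0
        assert min(entropy_table(seq)) > 2.5  # oracle: all windows complex

    def test_two_blocks_give_two_lcrs(self, rng):
        mixed = "".join(ALPHABET[i % 20] for i in range(30))
        seq = "A" * 30 + mixed + "Q" * 30
        regions, feats = find_lcr(seq)
        assert feats[1] == 2.0

    def test_calls_match_entropy_oracle(self, rng):
        """Region membership reproduces the seed-and-extend rule applied to
        an independently computed entropy table."""
        for _ in range(10):
            seq = ("".join(rng.choice(list("AQ"), size=25)) +
                   random_sequence(rng, 40) +
                   "S" * int(rng.integers(0, 25)))
            regions, _ = find_lcr(seq)
            ent = entropy_table(seq)
            seeds = [i for i, h in enumerate(ent) if h <= 2.2]
            expected = set()
            for s in seeds:
                lo = s
                while lo > 0 and ent[lo - 1] <= 2.5:
                    lo -= 1
                hi = s
                while hi + 1 < len(ent) and ent[hi + 1] <= 2.5:
                    hi += 1
                expected.update(range(lo, hi + 12))
            got = set()
            for r in regions:
                got.update(range(r.start, r.end))
            assert got == expected

    def test_total_length_is_region_sum(self, rng):
        for _ in range(10):
            seq = random_sequence(rng, 120, alphabet="ASQQL")
            regions, feats = find_lcr(seq)
            assert feats[0] == sum(len(r) for r in regions)
            assert feats[2] == (max(len(r) for r in regions) if regions else 0)


class TestNterm:
    def test_onehot(self):
        v = nterm_onehot("MKKK")
        assert v[AA_IDX["M"]] == 1.0 and v.sum() == 1.0
        assert nterm_onehot("RKKK")[AA_IDX["R"]] == 1.0


class TestSignalPeptide:
    def test_constructed_positive(self):
        assert predict_signal_peptide("MK" + "L" * 10 + "SDQERTNNDSQQ" * 4) == 1

    def test_acidic_n_region_fails(self):
        assert predict_signal_peptide("MDDDDDDDDDD" + "L" * 20) == 0

    def test_no_h_region_fails(self):
        assert predict_signal_peptide("MKNQSTDDEQ" * 8) == 0


class TestTm:
    def test_hydrophobic_stretch_found(self):
        exists, total, regions = predict_tm("DQNS" * 5 + "I" * 30 + "DQNS" * 5)
        assert exists == 1 and total >= 19

    def test_hydrophilic_has_none(self):
        assert predict_tm("D" * 60)[:2] == (0, 0)

    def test_two_stretches_sum(self):
        spacer = "DQNSDQNSDQNSDQNSDQNSDQNS"
        seq = spacer + "L" * 25 + spacer + "L" * 25 + spacer
        exists, total, regions = predict_tm(seq)
        assert exists == 1 and len(regions) == 2
        # boundary windows can extend each mark by <= 6 residues per side
        assert 50 <= total <= 74

    def test_matches_window_mean_oracle(self, rng):
        """Covered positions = union of qualifying 19-windows (oracle scan)."""
        for _ in range(10):
            seq = random_sequence(rng, 150, alphabet="LIVDFQNSA")
            _, _, regions = predict_tm(seq)
            kd = [KYTE_DOOLITTLE[c] for c in seq]
            covered = set()
            for i in range(len(seq) - 18):
                if sum(kd[i:i + 19]) / 19 >= 1.6:
                    covered.update(range(i, i + 19))
            expected = set()
            runs = sorted(covered)
            run = []
            for p in runs:
                if run and p != run[-1] + 1:
                    if len(run) >= 19:
                        expected.update(run)
                    run = []
                run.append(p)
            if len(run) >= 19:
                expected.update(run)
            got = set()
            for r in regions:
                got.update(range(r.start, r.end))
            assert got == expected


class TestSecondaryStructure:
    def test_fractions_sum_to_one(self, rng):
        for _ in range(10):
            ss = predict_secondary_structure(random_sequence(rng, 80))
            assert ss.sum() == pytest.approx(1.0)

    def test_poly_proline_is_coil(self):
        ss = predict_secondary_structure("P" * 30)
        assert ss[2] == max(ss)

    def test_ss2_reader(self, tmp_path):
        p = tmp_path / "x.ss2"
        rows = [f"{i+1} A H 0.1 0.8 0.1" for i in range(10)] + \
               [f"{i+11} G C 0.8 0.1 0.1" for i in range(10)]
        p.write_text("# PSIPRED VFORMAT\n\n" + "\n".join(rows) + "\n")
        reader = PsipredReader()
        reader.add_ss2("p1", p)
        assert np.allclose(reader.get("p1"), [0.5, 0.0, 0.5])

    def test_horiz_reader(self, tmp_path):
        p = tmp_path / "x.horiz"
        p.write_text("Conf: 999\nPred: HHHHH\n  AA: MKENL\n\nPred: CCCCC\n")
        reader = PsipredReader()
        reader.add_horiz("p1", p)
        assert np.allclose(reader.get("p1"), [0.5, 0.0, 0.5])

    def test_malformed_ss2_names_line(self, tmp_path):
        p = tmp_path / "bad.ss2"
        p.write_text("1 A\n")
        reader = PsipredReader()
        with pytest.raises(ValidationError, match="line 1"):
            reader.add_ss2("p1", p)


class TestDisorder:
    def test_disorder_promoting_sequence_found(self):
        feats, regions = predict_disorder("E" * 30 + "S" * 30)
        assert feats[0] >= 1

    def test_order_promoting_sequence_clean(self):
        feats, _ = predict_disorder("I" * 30 + "V" * 30)
        assert np.all(feats == 0.0)

    def test_iupred_reader_thresholds_at_half(self, tmp_path):
        p = tmp_path / "x.iupred"
        lines = [f"{i+1} E 0.9" for i in range(35)] + \
                [f"{i+36} I 0.1" for i in range(35)]
        p.write_text("# IUPred\n" + "\n".join(lines) + "\n")
        reader = IupredReader()
        reader.add("p1", p)
        feats, regions = predict_disorder("E" * 35 + "I" * 35, backend=reader,
                                          record_id="p1")
        assert feats[0] == 1 and feats[1] == 35
        assert regions[0].score == pytest.approx(0.9)


class TestPtm:
    @pytest.mark.parametrize("seq,slot,count", [
        ("NAS", 4, 1),   # N-glyc sequon N-x-S
        ("NPS", 4, 0),   # P forbidden at x
        ("WAAW", 3, 1),  # C-glyc W-x-x-W
        ("ASPA", 0, 1),  # phospho-S via SP context
        ("RAASAA", 0, 1),  # phospho-S via RxxS context
    ])
    def test_sequon_examples(self, seq, slot, count):
        assert count_ptm_sites(seq)[slot] == count

    def test_sequon_oracle_nglyc(self, rng):
        for _ in range(20):
            seq = random_sequence(rng, 150)
            naive = len(re.findall(r"(?=(N[^P][ST]))", seq))
            assert count_ptm_sites(seq)[4] == naive


class TestFullVector:
    def test_length_and_determinism(self, rng):
        rec = ProteinRecord("p", random_sequence(rng, 200))
        v1 = extract_features(rec)
        v2 = extract_features(rec)
        assert len(v1.values) == 776
        assert np.array_equal(v1.values, v2.values)

    def test_degenerate_single_residue(self):
        v = extract_features(ProteinRecord("m", "M"))
        assert np.all(np.isfinite(v.values))
        assert v["N_M"] == 1.0

    def test_reader_backends_change_only_their_slots(self, tmp_path, rng):
        seq = random_sequence(rng, 120)
        rec = ProteinRecord("p1", seq)
        sp_file = tmp_path / "signalp.txt"
        sp_file.write_text("# SignalP short\np1 0.9 Y\n")
        base = extract_features(rec)
        swapped = extract_features(rec, Backends(sp=SignalPReader(sp_file)))
        diff = np.flatnonzero(base.values != swapped.values)
        assert set(diff) <= {SCHEMA.index("SP")}
        assert swapped["SP"] == 1.0

    def test_tmhmm_reader_backend(self, tmp_path):
        seq = "D" * 80
        rec = ProteinRecord("p1", seq)
        tm_file = tmp_path / "tmhmm.txt"
        tm_file.write_text("p1 TMhelix 11 35\n")
        v = extract_features(rec, Backends(tm=TmhmmReader(tm_file)))
        assert v["TM"] == 1.0
        assert v["TM_len."] == pytest.approx(25 / 80)

    def test_missing_backend_record_names_id(self, tmp_path):
        tm_file = tmp_path / "tmhmm.txt"
        tm_file.write_text("other TMhelix 1 20\n")
        with pytest.raises(ValidationError, match="p1"):
            extract_features(ProteinRecord("p1", "M" * 40),
                             Backends(tm=TmhmmReader(tm_file)))

    def test_ptm_and_dbox_readers(self, tmp_path):
        rec = ProteinRecord("p1", "G" * 50)
        ptm_file = tmp_path / "ptm.tsv"
        ptm_file.write_text("p1 3 Phos_S\np1 9 Phos_S\np1 12 Nglyc\n")
        dbox_file = tmp_path / "dbox.tsv"
        dbox_file.write_text("p1 1 0 2 0\n")
        v = extract_features(rec, Backends(ptm=PtmTableReader(ptm_file),
                                           dbox=DboxReader(dbox_file)))
        assert v["Phos_S"] == pytest.approx(2 / 50)
        assert v["Nglyc"] == pytest.approx(1 / 50)
        assert v["D_g"] == pytest.approx(1 / 50)
        assert v["D_cB"] == pytest.approx(2 / 50)


class TestRegion:
    def test_bounds_validated(self):
        with pytest.raises(ValidationError):
            Region("TM", 5, 5)

    def test_render_is_one_based_inclusive(self):
        assert Region("PEST", 0, 10, 6.5).render().startswith("PEST 1-10")
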
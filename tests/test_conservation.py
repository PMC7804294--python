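"""Conservation under the 80% rule, aromatic tracking, pi interactions."""

import numpy as np
import pytest

from riboarch.contacts import AtomRecord, InterfaceContact, StructureAtoms
from riboarch.conservation import (PiCutoffs, aromatic_acquisitions,
                                   classify_pi_interactions,
                                   conservation_profile,
                                   distant_aromatic_approaches,
                                   interface_conservation)
from riboarch.synthetic import MsaSpec, make_msa


class TestConservationProfile:
    def test_identical_sequences_all_strict(self):
        p = conservation_profile(["MKLV"] * 10)
        assert all(c.strict_conserved for c in p.columns)
        assert all(c.identity_fraction == 1.0 for c in p.columns)

    def test_seven_phe_two_tyr_one_lys(self):
        p = conservation_profile(["F"] * 7 + ["Y"] * 2 + ["K"])
        c = p.columns[0]
        assert c.identity_fraction == pytest.approx(0.7)
        assert not c.strict_conserved
        assert c.top_class == "aromatic"
        assert c.class_fraction == pytest.approx(0.9)
        assert c.similar_conserved

    def test_gaps_count_in_denominator(self):
        # 80% identity among non-gap rows but half the rows are gapped
        p = conservation_profile(["F"] * 4 + ["Y"] + ["-"] * 5)
        assert p.columns[0].identity_fraction == pytest.approx(0.4)
        assert not p.columns[0].strict_conserved
        assert not p.columns[0].similar_conserved

    def test_all_gap_column_flagged_never_conserved(self):
        p = conservation_profile(["-A", "-A", "-A"])
        assert p.columns[0].all_gap
        assert not p.columns[0].strict_conserved

    def test_strict_implies_similar(self):
        m = make_msa(MsaSpec(seed=9))
        for seqs in (m.sequences_a, m.sequences_e):
            p = conservation_profile(seqs)
            for c in p.columns:
                if c.strict_conserved:
                    assert c.similar_conserved

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            conservation_profile(["AAA", "AA"])
        with pytest.raises(ValueError):
            conservation_profile(["AAA"])

    def test_invariant_under_reordering_and_duplication(self):
        seqs = ["FYKA", "FYKC", "FWKA", "LYKA", "FYRA"]
        base = conservation_profile(seqs)
        perm = conservation_profile(seqs[::-1])
        dup = conservation_profile(seqs + seqs)
        for i in range(4):
            assert base.columns[i].identity_fraction == pytest.approx(
                perm.columns[i].identity_fraction)
            assert base.columns[i].identity_fraction == pytest.approx(
                dup.columns[i].identity_fraction)

    def test_planted_strict_columns_recovered_exactly(self, msa_fixture):
        p = conservation_profile(msa_fixture.sequences_e)
        t = msa_fixture.truth
        planted = set(t["strict_columns"]) | set(t["ancient_aromatic_columns"]) \
            | set(t["new_aromatic_columns"]) | set(t["strengthened_columns"])
        assert set(p.strict_columns()) == planted

    def test_read_from_fasta_file(self, tmp_path, msa_fixture):
        pa, pe = msa_fixture.write(tmp_path)
        assert len(conservation_profile(pe)) == len(msa_fixture.sequences_e[0])


def _contact(res_a, res_b):
    return InterfaceContact("A", "B", 100.0,
                            [(r, 1.0) for r in res_a],
                            [(r, 1.0) for r in res_b])


class TestInterfaceConservation:
    def profiles(self, pattern):
        # one column per residue; 'S'->strict, 's'->similar only, '.'->neither
        seqs = []
        for k in range(10):
            row = []
            for ch in pattern:
                if ch == "S":
                    row.append("W")
                elif ch == "s":
                    row.append("F" if k < 5 else "Y")   # class-only conserved
                else:
                    row.append("ACDEGIKLMN"[k])
            seqs.append("".join(row))
        return conservation_profile(seqs)

    def test_all_strict_gives_one(self):
        prof = self.profiles("SSSS")
        seq_map = {("A", str(i + 1)): i for i in range(4)}
        r = interface_conservation(_contact(["1", "2"], []), {"A": prof},
                                   seq_map)
        assert r.fraction_strict_a == 1.0

    def test_none_conserved_gives_zero(self):
        prof = self.profiles("....")
        seq_map = {("A", str(i + 1)): i for i in range(4)}
        r = interface_conservation(_contact(["1", "2"], []), {"A": prof},
                                   seq_map)
        assert r.fraction_strict_a == 0.0 and r.fraction_similar_a == 0.0

    def test_planted_three_of_five(self):
        prof = self.profiles("SSS..")
        seq_map = {("A", str(i + 1)): i for i in range(5)}
        r = interface_conservation(_contact(["1", "2", "3", "4", "5"], []),
                                   {"A": prof}, seq_map)
        assert r.fraction_strict_a == pytest.approx(0.6)

    def test_unmappable_residue_listed_and_excluded(self):
        prof = self.profiles("SS")
        seq_map = {("A", "1"): 0}
        r = interface_conservation(_contact(["1", "99"], []), {"A": prof},
                                   seq_map)
        assert r.unmapped == [("A", "99")]
        assert r.fraction_strict_a == 1.0   # over the mappable residue only

    def test_monotone_as_columns_flip_conserved(self):
        seq_map = {("A", str(i + 1)): i for i in range(5)}
        fracs = []
        for n_cons in range(6):
            prof = self.profiles("S" * n_cons + "." * (5 - n_cons))
            r = interface_conservation(
                _contact(["1", "2", "3", "4", "5"], []), {"A": prof}, seq_map)
            fracs.append(r.fraction_strict_a)
        assert fracs == sorted(fracs)


class TestAromaticAcquisitions:
    def test_identical_profiles_have_no_new(self, msa_fixture):
        p = conservation_profile(msa_fixture.sequences_e)
        acq = aromatic_acquisitions(p, p)
        assert all(x.status != "new_in_E" for x in acq)

    def test_planted_acquisitions_recovered_exactly(self, msa_fixture):
        pa = conservation_profile(msa_fixture.sequences_a)
        pe = conservation_profile(msa_fixture.sequences_e)
        acq = aromatic_acquisitions(pa, pe, msa_fixture.column_map)
        by_status = {}
        for x in acq:
            by_status.setdefault(x.status, []).append(x.column_e)
        t = msa_fixture.truth
        assert sorted(by_status["new_in_E"]) == t["new_aromatic_columns"]
        assert sorted(by_status["ancient"]) == t["ancient_aromatic_columns"]
        assert sorted(by_status["strengthened_similar_to_strict"]) == \
            t["strengthened_columns"]

    def test_new_interface_flag(self, msa_fixture):
        pa = conservation_profile(msa_fixture.sequences_a)
        pe = conservation_profile(msa_fixture.sequences_e)
        target = msa_fixture.truth["new_aromatic_columns"][0]
        acq = aromatic_acquisitions(pa, pe, msa_fixture.column_map,
                                    new_interface_columns_e={target})
        flagged = [x.column_e for x in acq if x.at_new_interface]
        assert flagged == [target]

    def test_length_mismatch_without_map_raises(self):
        p1 = conservation_profile(["FF", "FF", "FF"])
        p2 = conservation_profile(["FFF", "FFF", "FFF"])
        with pytest.raises(ValueError, match="cross_map"):
            aromatic_acquisitions(p1, p2)


def phe_ring(chain, resnum, center, resname="PHE"):
    offsets = {"CG": (-1.4, 0.7, 0), "CD1": (-0.7, -0.6, 0),
               "CD2": (-0.7, 1.9, 0), "CE1": (0.7, -0.6, 0),
               "CE2": (0.7, 1.9, 0), "CZ": (1.4, 0.7, 0)}
    c = np.asarray(center, dtype=float) - np.mean(list(offsets.values()),
                                                  axis=0)
    return [AtomRecord(chain, resnum, "", resname, n, "C",
                       tuple(c + np.asarray(o)), 1.7)
            for n, o in offsets.items()]


def single_atom(chain, resnum, resname, atom_name, pos):
    return [AtomRecord(chain, resnum, "", resname, atom_name, "C",
                       tuple(pos), 1.7)]


def struct(*chains_atoms):
    chains = {}
    for a in [x for grp in chains_atoms for x in grp]:
        chains.setdefault(a.chain_id, []).append(a)
    return StructureAtoms(chains)


class TestPiInteractions:
    def test_lone_aromatic_has_no_partners(self):
        out = classify_pi_interactions(struct(phe_ring("A", 1, (0, 0, 0))))
        assert out == []

    def test_arg_guanidinium_at_4p5_is_cation_pi(self):
        st = struct(phe_ring("A", 1, (0, 0, 0)),
                    single_atom("B", 5, "ARG", "CZ", (0, 0, 4.5)))
        out = classify_pi_interactions(st)
        assert len(out) == 1
        assert out[0].interaction_class == "cation_pi"
        assert out[0].centroid_distance == pytest.approx(4.5)
        assert not out[0].intramolecular

    def test_phe_phe_at_5_is_pi_pi_reported_once(self):
        st = struct(phe_ring("A", 1, (0, 0, 0)), phe_ring("A", 7, (0, 0, 5.0)))
        out = classify_pi_interactions(st)
        pi = [x for x in out if x.interaction_class == "pi_pi"]
        assert len(pi) == 1
        assert pi[0].centroid_distance == pytest.approx(5.0)
        assert pi[0].intramolecular
        assert pi[0].aromatic[1] <= pi[0].partner[1]   # deterministic order

    def test_glu_beyond_cutoff_ignored(self):
        st = struct(phe_ring("A", 1, (0, 0, 0)),
                    single_atom("B", 5, "GLU", "CD", (0, 0, 6.5)))
        assert classify_pi_interactions(st) == []
        near = struct(phe_ring("A", 1, (0, 0, 0)),
                      single_atom("B", 5, "GLU", "CD", (0, 0, 5.0)))
        assert classify_pi_interactions(near)[0].interaction_class == "anion_pi"

    def test_incomplete_ring_skipped(self):
        ring = phe_ring("A", 1, (0, 0, 0))[:-1]   # missing CZ
        st = struct(ring, single_atom("B", 5, "ARG", "CZ", (0, 0, 4.0)))
        assert classify_pi_interactions(st) == []

    def test_custom_cutoffs_respected(self):
        st = struct(phe_ring("A", 1, (0, 0, 0)),
                    single_atom("B", 5, "ARG", "CZ", (0, 0, 4.5)))
        tight = classify_pi_interactions(st, cutoffs=PiCutoffs(cation_pi=4.0))
        assert tight == []


def test_distant_approach_scan_reports_10A_motif():
    st = struct(phe_ring("A", 10, (0, 0, 0)), phe_ring("B", 20, (9.0, 0, 0)))
    hits = distant_aromatic_approaches(st, "A", "B", max_dist=10.0)
    assert len(hits) == 1
    assert hits[0]["centroid_distance"] == pytest.approx(9.0)
    none = distant_aromatic_approaches(st, "A", "B", max_dist=8.0)
    assert none == []
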
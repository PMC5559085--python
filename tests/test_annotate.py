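"""Gene assignment, CDR3 extraction, junction decomposition, error collapse."""

import numpy as np
import pandas as pd
import pytest

from oracles import sw_score
from vdjprof import annotate as an
from vdjprof import germline as gl
from vdjprof import simulate as sim


@pytest.fixture(scope="module")
def trb_annotator(trb_db):
    return an.Annotator(trb_db)


class TestAssignVJ:
    def test_exact_containment_identity_one(self, trb_db, trb_annotator):
        v, j = trb_db.v_genes[3], trb_db.j_genes[2]
        read = v.sequence[150:] + j.sequence
        av, aj = trb_annotator.assign_vj(read)
        assert av.gene_name == v.gene_name and av.identity == 1.0
        assert aj.gene_name == j.gene_name and aj.identity == 1.0
        assert av.ref_end == len(v.sequence)
        assert aj.ref_start == 1

    def test_error_free_simulation_recovers_truth(self, trb_run, clonotype_map):
        total = correct = 0
        for r in trb_run["rearrangements"]:
            for ann in clonotype_map.get(r.clonotype_id, []):
                total += 1
                correct += (
                    ann.v is not None and ann.j is not None
                    and ann.v.gene_name == r.v_gene
                    and ann.j.gene_name == r.j_gene
                )
        assert total > 0
        assert correct / total >= 0.99

    def test_score_tie_prefers_lexicographic_and_flags(self, trb_db):
        # two identical V genes under different names force an exact tie
        v = trb_db.v_genes[0]
        twin = gl.GermlineGene("TRBV0twin", "TRB", "V", v.sequence,
                               functional=True, anchor_pos=v.anchor_pos)
        db = gl.GermlineDatabase(
            "TRB", v_genes=[v, twin], d_genes=trb_db.d_genes,
            j_genes=trb_db.j_genes,
        )
        annotator = an.Annotator(db)
        read = v.sequence[150:] + trb_db.j_genes[0].sequence
        av, _ = annotator.assign_vj(read)
        assert av.gene_name == min(v.gene_name, "TRBV0twin")
        assert av.tie

    def test_junk_read_unassigned(self, trb_annotator):
        rng = np.random.default_rng(5)
        read = "".join("ACGT"[i] for i in rng.integers(0, 4, 160))
        ann = trb_annotator.annotate("junk", read)
        assert ann.status.startswith("unassigned")

    def test_best_gene_and_score_agree_with_dp_oracle(self, trb_run, trb_db):
        """SW assignment (with prescreen) equals an exhaustive DP oracle."""
        aligner = an.SegmentAligner(trb_db.v_genes, k=11, prescreen_top=8)
        reads = [m.sequence for m in trb_run["merged"][:100]]
        for read in reads:
            best = aligner.best(read)
            oracle = max(
                ((sw_score(read, g.sequence), g.gene_name) for g in trb_db.v_genes),
                key=lambda t: (t[0], [-ord(c) for c in t[1]]),
            )
            assert best.score == oracle[0]
            assert best.gene_name == oracle[1]


class TestExtractCDR3:
    def test_constructed_motif_example(self):
        # V ends ...TGT GCC AGC AGC; J carries TTT GGC CAA GGG
        v_seq = "GGAGTCAGTCCAGGTACCTGGCTCCAGAAGGGCCTGAAATTCACCGGAGTC" * 6
        v_seq = v_seq[: 3 * (len(v_seq) // 3)]
        v_seq = v_seq[:-12] + "TGTGCCAGCAGC"
        j_seq = "TTAGGGACTTTTGGCCAAGGGACCACGGTCACCGTCTCC"
        (v,) = gl.filter_functional(
            [gl.GermlineGene("TRBV9", "TRB", "V", v_seq)], "V"
        )
        (j,) = gl.filter_functional(
            [gl.GermlineGene("TRBJ9", "TRB", "J", j_seq)], "J"
        )
        db = gl.GermlineDatabase("TRB", v_genes=[v], j_genes=[j])
        annotator = an.Annotator(db)
        read = v_seq + j_seq  # junction-free joint
        ann = annotator.annotate("r", read)
        assert ann.cdr3_nt == "TGTGCCAGCAGC" + "TTAGGGACT" + "TTT"
        assert ann.cdr3_aa == "CASSLGTF"
        assert ann.productive

    def test_v_alignment_missing_anchor_gives_no_cdr3(self, trb_db, trb_annotator):
        v, j = trb_db.v_genes[0], trb_db.j_genes[0]
        # read stops 40 nt before the V end: anchor codon absent
        read = v.sequence[100 : len(v.sequence) - 40] + j.sequence
        ann = trb_annotator.annotate("r", read)
        assert ann.status in ("no_cdr3", "unassigned_j")

    def test_simulation_cdr3_recovery(self, trb_run, clonotype_map):
        total = correct = 0
        for r in trb_run["rearrangements"]:
            for ann in clonotype_map.get(r.clonotype_id, []):
                total += 1
                correct += ann.cdr3_nt == r.cdr3_nt
        assert correct / total >= 0.99


class TestClassifyProductive:
    def _annotate_null_junction(self, db, insert):
        cfg = sim.SimulationConfig(
            locus=db.locus, n_clonotypes=1, deletion_mean=0, insertion_mean=0,
            per_base_error_rate=0, n_rate=0, seed=1,
        )
        (r,) = sim.simulate_repertoire(cfg, db)
        return r

    def test_in_frame_no_stop_is_productive(self, trb_run, clonotype_map):
        db = trb_run["db"]
        for r in trb_run["rearrangements"]:
            if len(r.cdr3_nt) % 3 != 0:
                continue
            for ann in clonotype_map.get(r.clonotype_id, []):
                if ann.productive:
                    assert len(ann.cdr3_nt) % 3 == 0
                    assert ann.cdr3_aa.startswith("C")
                    assert ann.cdr3_aa[-1] in "FW"
                    assert "*" not in ann.cdr3_aa

    def test_out_of_frame_reason(self, trb_run, clonotype_map):
        seen = False
        for r in trb_run["rearrangements"]:
            if len(r.cdr3_nt) % 3 == 0:
                continue
            for ann in clonotype_map.get(r.clonotype_id, []):
                if ann.status == "ok":
                    assert not ann.productive
                    assert ann.productive_reason == "out_of_frame"
                    seen = True
        assert seen

    def test_stop_codon_reason(self, trb_run, clonotype_map):
        from Bio.Seq import Seq

        seen = False
        for r in trb_run["rearrangements"]:
            if len(r.cdr3_nt) % 3 != 0:
                continue
            if "*" not in str(Seq(r.cdr3_nt).translate()):
                continue
            for ann in clonotype_map.get(r.clonotype_id, []):
                if ann.status == "ok":
                    assert ann.productive_reason == "stop_codon"
                    seen = True
        assert seen


class TestJunctionDecomposition:
    def test_null_junction_all_zero(self, trb_db):
        db = gl.GermlineDatabase(
            "TRB", v_genes=trb_db.v_genes[:1], d_genes=trb_db.d_genes[:1],
            j_genes=trb_db.j_genes[:1],
        )
        cfg = sim.SimulationConfig(
            locus="TRB", n_clonotypes=1, deletion_mean=0, insertion_mean=0,
            per_base_error_rate=0, n_rate=0, seed=2,
        )
        (r,) = sim.simulate_repertoire(cfg, db)
        ann = an.Annotator(db).annotate("r", r.full_sequence)
        assert (ann.del_3v, ann.del_5d, ann.del_3d, ann.del_5j) == (0, 0, 0, 0)
        assert ann.ins_vd == "" and ann.ins_dj == ""
        assert ann.d.gene_name == r.d_gene

    def test_simulated_sections_recovered(self, trb_run, clonotype_map):
        total = correct = 0
        for r in trb_run["rearrangements"]:
            for ann in clonotype_map.get(r.clonotype_id, []):
                total += 1
                d_name = ann.d.gene_name if ann.d else None
                correct += (
                    ann.del_3v == r.del_3v and ann.del_5j == r.del_5j
                    and d_name == r.d_gene
                    and (ann.del_5d or 0) == r.del_5d
                    and (ann.del_3d or 0) == r.del_3d
                    and (ann.ins_vd or "") == r.ins_vd
                    and (ann.ins_dj or "") == r.ins_dj
                )
        assert correct / total >= 0.99

    def test_junction_reconstruction_invariant(self, trb_run, clonotype_map):
        """Assembled sections reproduce the read span between V and J."""
        db = trb_run["db"]
        for r in trb_run["rearrangements"][:100]:
            for ann in clonotype_map.get(r.clonotype_id, []):
                if ann.status != "ok":
                    continue
                v_len = len(db.get(ann.v.gene_name).sequence)
                gap = ann.ins_vd
                if ann.d is not None:
                    d = db.get(ann.d.gene_name)
                    gap = (
                        ann.ins_vd
                        + d.sequence[ann.del_5d : len(d.sequence) - ann.del_3d]
                        + ann.ins_dj
                    )
                j_head = db.get(ann.j.gene_name).sequence[ann.del_5j :]
                v_tail = db.get(ann.v.gene_name).sequence[: v_len - ann.del_3v]
                seq = next(
                    m.sequence for m in trb_run["merged"]
                    if m.read_id == ann.read_id
                )
                assert seq.endswith(gap + j_head)
                assert v_tail.endswith(seq[: len(seq) - len(gap + j_head)])

    def test_light_chain_reports_only_vj_insertion(self, igk_db, tmp_path):
        cfg = sim.SimulationConfig.for_locus(
            "IGK", n_clonotypes=20, seed=41, shm_rate_per_nt=0.0,
            per_base_error_rate=0.0, n_rate=0.0,
        )
        rearr = sim.simulate_repertoire(cfg, igk_db)
        annotator = an.Annotator(igk_db)
        for r in rearr[:10]:
            ann = annotator.annotate("r", r.full_sequence)
            assert ann.ins_vd is None and ann.ins_dj is None
            assert ann.del_5d is None and ann.del_3d is None
            assert ann.ins_vj == r.ins_vj


class TestSplitIGKL:
    def test_self_identification(self, igk_db, igl_db):
        igk_ann, igl_ann = an.Annotator(igk_db), an.Annotator(igl_db)
        cfg_k = sim.SimulationConfig.for_locus(
            "IGK", n_clonotypes=60, seed=43, shm_rate_per_nt=0.0,
            per_base_error_rate=0.0, n_rate=0.0,
        )
        cfg_l = sim.SimulationConfig.for_locus(
            "IGL", n_clonotypes=60, seed=44, shm_rate_per_nt=0.0,
            per_base_error_rate=0.0, n_rate=0.0,
        )
        correct = total = 0
        for r in sim.simulate_repertoire(cfg_k, igk_db):
            total += 1
            correct += an.split_igkl(r.full_sequence[-180:], igk_ann, igl_ann) == "IGK"
        for r in sim.simulate_repertoire(cfg_l, igl_db):
            total += 1
            correct += an.split_igkl(r.full_sequence[-180:], igk_ann, igl_ann) == "IGL"
        assert correct / total >= 0.99

    def test_equal_scores_unresolved(self, igk_db, igl_db):
        # the same sequence presented as both databases' best hit
        shared = igk_db.v_genes[0]
        twin = gl.GermlineGene("IGLVtwin", "IGL", "V", shared.sequence,
                               functional=True, anchor_pos=shared.anchor_pos)
        igl_twin = gl.GermlineDatabase("IGL", v_genes=[twin],
                                       j_genes=igl_db.j_genes)
        igk_one = gl.GermlineDatabase("IGK", v_genes=[shared],
                                      j_genes=igk_db.j_genes)
        read = shared.sequence[150:]
        assert an.split_igkl(read, igk_one, igl_twin) == "unresolved"


class TestCollapseErrors:
    @staticmethod
    def _frame(rows):
        return pd.DataFrame(
            rows, columns=["cdr3_nt", "v_gene", "j_gene", "read_count"]
        )

    def test_small_neighbor_absorbed(self):
        df = self._frame([
            ("TGTGCCAGCTTT", "V1", "J1", 1000),
            ("TGTGCCAGCTTA", "V1", "J1", 5),
        ])
        out = an.collapse_errors(df)
        assert len(out) == 1
        assert out.iloc[0].read_count == 1005

    def test_ratio_guard_keeps_both(self):
        df = self._frame([
            ("TGTGCCAGCTTT", "V1", "J1", 1000),
            ("TGTGCCAGCTTA", "V1", "J1", 900),
        ])
        out = an.collapse_errors(df)
        assert sorted(out.read_count) == [900, 1000]

    def test_different_v_never_merged(self):
        df = self._frame([
            ("TGTGCCAGCTTT", "V1", "J1", 1000),
            ("TGTGCCAGCTTT", "V2", "J1", 1),
        ])
        out = an.collapse_errors(df)
        assert len(out) == 2

    def test_two_mismatches_not_merged_at_default_distance(self):
        df = self._frame([
            ("TGTGCCAGCTTT", "V1", "J1", 1000),
            ("TGTGCCAGCAAT", "V1", "J1", 2),
        ])
        assert len(an.collapse_errors(df)) == 2

    def test_applied_once_largest_first(self):
        # chain A(10000) <- B(50) <- C(1): B is not small enough for A at
        # ratio 0.01 x 10000 = 100 -> B absorbed? 50 <= 100: yes. C joins A's
        # pile only if within 1 mismatch of A.
        df = self._frame([
            ("AAAAAA", "V1", "J1", 10000),
            ("AAAAAT", "V1", "J1", 50),
            ("AAAATT", "V1", "J1", 1),
        ])
        out = an.collapse_errors(df)
        assert out.iloc[0].read_count == 10050
        assert list(out.cdr3_nt) == ["AAAAAA", "AAAATT"]
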
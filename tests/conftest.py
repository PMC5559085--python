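"""Shared fixtures: small synthetic databases and simulated repertoires."""

from __future__ import annotations

import pytest

from vdjprof import annotate as an
from vdjprof import preprocess as pp
from vdjprof import simulate as sim


@pytest.fixture(scope="session")
def trb_db():
    """Small functional TRB database (10 V, 2 D, 5 J)."""
    return sim.synthetic_database("TRB", n_v=10, n_d=2, n_j=5, seed=1)


@pytest.fixture(scope="session")
def igk_db():
    return sim.synthetic_database("IGK", n_v=8, n_j=3, seed=2)


@pytest.fixture(scope="session")
def igl_db():
    return sim.synthetic_database("IGL", n_v=8, n_j=3, seed=3)


@pytest.fixture(scope="session")
def igh_db():
    return sim.synthetic_database("IGH", n_v=8, n_d=4, n_j=4, seed=4)


def simulate_to_annotations(db, config, tmp_path, annotation_config=None):
    """Simulate, emit reads, preprocess and annotate; returns all artifacts."""
    rearrangements = sim.simulate_repertoire(config, db)
    fq1, fq2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
    sim.emit_reads(rearrangements, config, fq1, fq2)
    merged, qc = pp.process_pairs(pp.read_pairs(fq1, fq2))
    annotations, summary = an.annotate_repertoire(merged, db, annotation_config)
    return rearrangements, merged, qc, annotations, summary


@pytest.fixture(scope="session")
def trb_run(trb_db, tmp_path_factory):
    """Error-free, SHM-free TRB run: 400 clonotypes, fixed seed."""
    config = sim.SimulationConfig.for_locus(
        "TRB", n_clonotypes=400, seed=7, per_base_error_rate=0.0, n_rate=0.0
    )
    tmp = tmp_path_factory.mktemp("trb_run")
    rearr, merged, qc, annotations, summary = simulate_to_annotations(
        trb_db, config, tmp
    )
    return {
        "db": trb_db, "config": config, "rearrangements": rearr,
        "merged": merged, "qc": qc, "annotations": annotations,
        "summary": summary,
    }


@pytest.fixture(scope="session")
def clonotype_map(trb_run):
    """clonotype_id -> list of annotations of its unique merged sequences."""
    by_clono: dict[int, list] = {}
    for ann in trb_run["annotations"]:
        cid = int(ann.read_id.split("_")[0].removeprefix("clono"))
        by_clono.setdefault(cid, []).append(ann)
    return by_clono
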
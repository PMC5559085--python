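"""End-to-end orchestration: preprocess -> annotate -> statistics.

The driver mirrors a standard repertoire-sequencing run: paired FASTQ in,
per-stage TSV outputs and a machine-readable run summary (counts at every
filtering stage) out.  SHM profiling runs for BCR loci only.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import annotate as an
from . import diversity as dv
from . import germline as gl
from . import preprocess as pp
from . import repstats as rs
from . import shm as sh

logger = logging.getLogger(__name__)


def run_pipeline(
    db: gl.GermlineDatabase,
    fastq1: str | Path,
    fastq2: str | Path,
    out_dir: str | Path,
    seed: int = 0,
    diversity_unit: str = "nt",
    collapse: bool = True,
    annotation_config: an.AnnotationConfig | None = None,
    min_mean_q: float = pp.DEFAULT_MIN_MEAN_Q,
    max_n_frac: float = pp.DEFAULT_MAX_N_FRAC,
    min_overlap: int = pp.DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = pp.DEFAULT_MAX_MISMATCH_RATE,
) -> dict:
    """Run the full analysis for one locus; returns the run summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    locus = db.locus

    merged, qc = pp.process_pairs(
        pp.read_pairs(fastq1, fastq2),
        min_mean_q=min_mean_q, max_n_frac=max_n_frac,
        min_overlap=min_overlap, max_mismatch_rate=max_mismatch_rate,
    )
    pp.write_qc_report(qc, out / "qc_report.tsv")
    pp.write_merged_fasta(merged, out / "merged.fasta")
    logger.info("preprocess: %s", qc)

    annotations, ann_summary = an.annotate_repertoire(merged, db, annotation_config)
    an.annotations_to_frame(annotations).to_csv(
        out / "annotations.tsv", sep="\t", index=False
    )
    logger.info("annotate: %s", ann_summary)

    summary = {
        "locus": locus,
        "raw_pairs": qc["reads_in"],
        "qc_passed": qc["merged"] + qc["unmerged"],
        "merged": qc["merged"],
        "assigned": ann_summary["reads_in"] - ann_summary["unassigned"],
        "productive": ann_summary["productive"],
        "qc": qc,
        "annotation": ann_summary,
    }

    try:
        table = rs.RepertoireTable.from_annotations(
            an.annotations_to_frame(annotations), locus=locus
        )
    except rs.EmptyTableError:
        logger.warning("no productive clonotypes; statistics skipped")
        summary["distinct_cdr3_nt"] = 0
        (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
        return summary
    if collapse:
        cfg = annotation_config or an.AnnotationConfig()
        table = rs.RepertoireTable(
            locus=locus,
            data=an.collapse_errors(
                table.data, cfg.collapse_max_dist, cfg.collapse_ratio
            ),
        )
    table.data.to_csv(out / "clonotypes.tsv", sep="\t", index=False)
    summary["distinct_cdr3_nt"] = int(table.data["cdr3_nt"].nunique())

    for axis in ("V", "J", "VJ"):
        rs.write_stat_tsv(
            rs.usage_frequencies(table, axis), out / f"usage_{axis.lower()}.tsv",
            name="frequency",
        )
    rs.write_stat_tsv(
        rs.cdr3_length_distribution(table, "aa"), out / "cdr3_length_aa.tsv",
        name="fraction",
    )
    rs.write_stat_tsv(rs.rank_abundance(table), out / "rank_abundance.tsv")
    rs.write_stat_tsv(rs.aa_composition(table), out / "aa_composition.tsv",
                      name="frequency")
    ann_frame = an.annotations_to_frame(annotations)
    for section, hist in rs.junction_indel_distributions(ann_frame, locus).items():
        rs.write_stat_tsv(hist, out / f"junction_{section}.tsv", name="fraction")
    ins = rs.inserted_nt_composition(ann_frame)
    if ins is not None:
        rs.write_stat_tsv(ins, out / "inserted_nt_composition.tsv", name="frequency")

    div = dv.diversity_summary(table, unit=diversity_unit)
    curve = dv.rarefaction(table, unit=diversity_unit, seed=seed)
    curve.to_frame().to_csv(out / "rarefaction.tsv", sep="\t", index=False)
    summary["diversity"] = div

    if locus.startswith("IG"):
        profiles = sh.build_profiles(annotations, db)
        if profiles:
            rates = {
                "overall_nt": sh.overall_rate(profiles, "nt"),
                "overall_aa": sh.overall_rate(profiles, "aa"),
                "per_gene_nt": sh.per_gene_rate(profiles, "nt"),
            }
            summary["shm"] = rates
            hotspot_rows, poly_rows = [], []
            for gene, prof in sorted(profiles.items()):
                prof.to_frame().to_csv(
                    out / f"shm_profile_{gene.replace('/', '_')}.tsv",
                    sep="\t", index=False,
                )
                hot, excluded = sh.call_hotspots(prof)
                hotspot_rows += [
                    {"gene": gene, "position": p, "kind": "hotspot"} for p in hot
                ] + [
                    {"gene": gene, "position": p, "kind": "low_coverage"}
                    for p in excluded
                ]
                poly_rows += [vars(c) for c in sh.detect_polymorphic_sites(prof)]
            import pandas as pd

            pd.DataFrame(hotspot_rows).to_csv(out / "shm_hotspots.tsv", sep="\t", index=False)
            pd.DataFrame(poly_rows).to_csv(out / "shm_polymorphic.tsv", sep="\t", index=False)
            spectrum = sh.substitution_spectrum(profiles, "nt")
            if spectrum is not None:
                rs.write_stat_tsv(spectrum, out / "shm_spectrum_nt.tsv", name="frequency")

    (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
    return summary
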
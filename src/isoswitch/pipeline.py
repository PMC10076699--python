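"""End-to-end study pipeline over the synthetic fixture.

Runs: fixture generation -> index construction (isoform-specific classes +
separate common class, and a standard whole-gene index) -> per-sample
read assignment and CPM -> per-age profiles -> switch/masking report,
trajectory-recovery correlations and sigmoid-midpoint refit.  Everything
downstream (tests, analysis drivers, the acceptance script, the CLI demo)
calls into this module rather than re-orchestrating the stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_models import ExonClassification
from .profiles import (
    PcaResult,
    SwitchReport,
    fit_late_plateau,
    pca_explained_variance,
    spearman,
    switch_report,
)
from .quantify import (
    AMBIGUOUS,
    UNASSIGNED,
    CountTable,
    FeatureIndex,
    assign_batch,
    build_feature_index,
    build_whole_gene_index,
    quantify_sample,
)
from .gene_models import SequenceRecord, classify_exons, extract_feature_sequences
from .synthetic import (
    SimulationConfig,
    StudyFixture,
    analytic_crossing,
    make_study_fixture,
    trajectory_value,
)

DEFAULT_K = 21
WHOLE_GENE = "whole_gene"


def build_panel_index(fixture: StudyFixture, k: int = DEFAULT_K) -> FeatureIndex:
    """Index with one class per target isoform's specific exons, a separate
    common class, and one class per housekeeping transcript."""
    cls = classify_exons(fixture.gene)
    by_class: dict[str, list] = {}
    seen = set()
    for t in fixture.gene.transcripts:
        for e in t.exons:
            key = (e.interval.chrom, e.interval.start, e.interval.end)
            if key in seen:
                continue
            seen.add(key)
            by_class.setdefault(cls.labels[key], []).append((e.exon_id, [e.interval]))
    class_records = {
        label: extract_feature_sequences(fixture.genome, feats)
        for label, feats in by_class.items()
    }
    for tid, seq in fixture.transcripts.items():
        if tid.startswith("Hk"):
            class_records[tid.split(".")[0]] = [SequenceRecord(tid, seq)]
    return build_feature_index(
        class_records, k, common_classes=[ExonClassification.COMMON]
    )


def quantify_fixture(
    fixture: StudyFixture,
    index: FeatureIndex,
    min_hits: int = 2,
) -> tuple[CountTable, dict[str, np.ndarray]]:
    """Assign every sample's reads against one index."""
    rows = {}
    assignments = {}
    for sample_id in fixture.samples.index:
        batch = fixture.reads[sample_id]
        codes = assign_batch(batch.seqs, index, min_hits)
        assignments[sample_id] = codes
        row = {c: int((codes == i).sum()) for i, c in enumerate(index.classes)}
        row[AMBIGUOUS] = int((codes == -1).sum())
        row[UNASSIGNED] = int((codes == -2).sum())
        row["library_size"] = len(batch)
        rows[sample_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    lib = frame.pop("library_size")
    return CountTable(frame, lib), assignments


def cross_isoform_misassignments(
    fixture: StudyFixture,
    assignments: dict[str, np.ndarray],
    index: FeatureIndex,
) -> int:
    """Reads assigned to one isoform class whose true source is the other
    isoform's transcript (brute-force check against the truth table)."""
    iso1_pos = index.classes.index("iso1")
    iso2_pos = index.classes.index("iso2")
    tids = fixture.target_transcript_ids
    bad = 0
    for sample_id, codes in assignments.items():
        truth = fixture.truth[sample_id]
        src = np.array(truth.transcript_order)[truth.source_transcript]
        bad += int(((codes == iso1_pos) & (src == tids[1])).sum())
        bad += int(((codes == iso2_pos) & (src == tids[0])).sum())
    return bad


@dataclass
class StudyResult:
    fixture: StudyFixture
    panel_index: FeatureIndex
    counts: CountTable  # panel classes + whole_gene column merged
    assignments: dict[str, np.ndarray]
    cpm: pd.DataFrame  # features x samples
    age_means: pd.DataFrame  # ages x {iso1, iso2, whole_gene} estimated cpm means
    true_means: pd.DataFrame  # ages x {iso1, iso2} true trajectory values
    report: SwitchReport
    recovery: dict[str, float]  # Spearman estimated-vs-true per isoform
    analytic_crossing_t: float | None
    t50_fit: tuple[float, float, float]  # (A, t50, slope) refit on iso1 means
    pca: PcaResult

    @property
    def ages(self) -> pd.DataFrame:
        return (
            self.fixture.samples[["age_label", "age_t"]]
            .drop_duplicates()
            .set_index("age_label", drop=False)
        )


def run_study(
    config: SimulationConfig | None = None,
    k: int = DEFAULT_K,
    min_hits: int = 2,
) -> StudyResult:
    """Run the whole pipeline on a fresh synthetic study."""
    fixture = make_study_fixture(config)
    panel = build_panel_index(fixture, k)
    whole = build_whole_gene_index(fixture.gene, fixture.genome, k)

    counts, assignments = quantify_fixture(fixture, panel, min_hits)
    counts_whole, _ = quantify_fixture(fixture, whole, min_hits)
    merged = counts.counts.copy()
    merged[WHOLE_GENE] = counts_whole.counts[fixture.gene.gene_id]
    table = CountTable(merged, counts.library_size)

    feature_classes = [c for c in merged.columns if c not in (AMBIGUOUS, UNASSIGNED)]
    cpm = table.cpm_matrix(feature_classes)

    ages = (
        fixture.samples[["age_label", "age_t"]]
        .drop_duplicates()
        .set_index("age_label", drop=False)
    )
    sample_age = fixture.samples["age_label"]
    age_means = (
        cpm.T.groupby(sample_age)
        .mean()
        .reindex(ages.index)[["iso1", "iso2", WHOLE_GENE]]
    )
    true_means = pd.DataFrame(
        {
            iso: [
                trajectory_value(fixture.trajectories[iso], t)
                for t in ages["age_t"]
            ]
            for iso in ("iso1", "iso2")
        },
        index=ages.index,
    )

    report = switch_report(
        ages,
        age_means["iso1"],
        age_means["iso2"],
        age_means[WHOLE_GENE],
        true_means["iso1"],
        true_means["iso2"],
    )
    recovery = {
        iso: spearman(age_means[iso], true_means[iso]) for iso in ("iso1", "iso2")
    }
    t_lo = float(ages["age_t"].min())
    t_hi = float(ages["age_t"].max())
    crossing = analytic_crossing(
        fixture.trajectories["iso1"], fixture.trajectories["iso2"], t_lo, t_hi
    )
    t50 = fit_late_plateau(ages["age_t"], age_means["iso1"])
    pca = pca_explained_variance(cpm)

    return StudyResult(
        fixture=fixture,
        panel_index=panel,
        counts=table,
        assignments=assignments,
        cpm=cpm,
        age_means=age_means,
        true_means=true_means,
        report=report,
        recovery=recovery,
        analytic_crossing_t=crossing,
        t50_fit=t50,
        pca=pca,
    )


def crossing_age_step_error(result: StudyResult) -> int | None:
    """|detected crossing age index - index of the age nearest the analytic
    crossing| in panel steps; None if either crossing is undefined."""
    if result.report.crossing_age_t is None or result.analytic_crossing_t is None:
        return None
    ages_t = result.ages["age_t"].to_numpy(dtype=float)
    detected = int(np.argmin(np.abs(ages_t - result.report.crossing_age_t)))
    nearest = int(np.argmin(np.abs(ages_t - result.analytic_crossing_t)))
    return abs(detected - nearest)
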
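"""Quantify isoform-specific, common and whole-gene reads per sample.

Re-runs the seeded study end to end: builds the isoform-resolved k-mer index
(iso1/iso2 specific exon classes + separate common class) and the standard
whole-gene index, assigns every read, and writes counts, the CPM matrix and
the per-age estimated/true trajectory means.
"""

from pathlib import Path

from isoswitch.io_utils import write_tsv
from isoswitch.pipeline import run_study
from isoswitch.synthetic import SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 7
DEPTH = 20_000


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    result = run_study(SimulationConfig(reads_per_sample=DEPTH, seed=SEED))

    counts = result.counts.counts.copy()
    counts["library_size"] = result.counts.library_size
    write_tsv(RESULTS / "counts.tsv", counts, seed=SEED, k=21, min_hits=2)
    write_tsv(RESULTS / "cpm_matrix.tsv", result.cpm, unit="cpm", seed=SEED)
    write_tsv(RESULTS / "age_means.tsv", result.age_means, seed=SEED)
    write_tsv(RESULTS / "true_means.tsv", result.true_means, seed=SEED)

    assigned = counts[["iso1", "iso2", "common"]].to_numpy().sum()
    print(f"assigned {assigned:,} target-gene reads across "
          f"{len(counts)} samples (ambiguous: {counts['ambiguous'].sum()}, "
          f"unassigned incl. non-target: {counts['unassigned'].sum():,})")
    print("trajectory recovery (Spearman estimated vs true): "
          f"iso1 {result.recovery['iso1']:.3f}, iso2 {result.recovery['iso2']:.3f}")
    print(f"wrote counts.tsv, cpm_matrix.tsv, age_means.tsv, true_means.tsv")


if __name__ == "__main__":
    main()
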
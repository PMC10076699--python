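"""Generate the synthetic developmental study and record its design.

Emits the toy two-isoform gene annotation, the sample sheet (12 ages from
E14 to P60, 3 replicates each) and the per-sample true transcript-abundance
fractions.  Reads are regenerated deterministically by later steps from the
same seed, so no FASTQ is stored here.
"""

from pathlib import Path

import pandas as pd

from isoswitch.io_utils import write_tsv
from isoswitch.synthetic import SimulationConfig, make_study_fixture

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 7
DEPTH = 20_000  # reads per sample for the desk-scale analysis chain


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    config = SimulationConfig(reads_per_sample=DEPTH, seed=SEED)
    fixture = make_study_fixture(config)

    (RESULTS / "annotation.gtf").write_text(fixture.gtf_text)
    write_tsv(RESULTS / "samples.tsv", fixture.samples, index=False, seed=SEED)
    rows = [
        {"sample": sid, "transcript": tid, "true_fraction": frac}
        for sid in fixture.samples.index
        for tid, frac in fixture.truth[sid].fractions.items()
    ]
    write_tsv(
        RESULTS / "truth_fractions.tsv", pd.DataFrame(rows), index=False, seed=SEED
    )

    n_reads = sum(len(fixture.reads[s]) for s in fixture.samples.index)
    print(f"study: {len(fixture.samples)} samples over {len(config.ages)} ages, "
          f"{n_reads:,} reads total")
    print(f"target gene: {len(fixture.gene.transcripts)} isoforms; "
          f"specific 5' exons per isoform: 4 (iso1) + 1 (iso2), 6 shared exons")
    print(f"wrote annotation.gtf, samples.tsv, truth_fractions.tsv to {RESULTS}")


if __name__ == "__main__":
    main()
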
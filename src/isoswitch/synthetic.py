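"""Synthetic study generator: toy genome, biphasic trajectories, reads.

Emulates the design of a developmental RNA-seq time course over the mouse
retina: a target gene with two promoter isoforms whose transcripts share 3'
exons but differ in their 5' exons (four specific exons for the TRβ1-like
isoform, one for the TRβ2-like isoform, with the specific exons separated
from the shared exons by a > 6 kb intron), plus constant housekeeping genes.
Expression follows parametric trajectories over ordered developmental ages —
an early embryonic peak that declines postnatally (TRβ2-like) against a
postnatal sigmoidal rise to a plateau (TRβ1-like).  Counts are
negative-binomially overdispersed around the expected proportions; reads are
uniform-start, fixed-length, single-end with optional substitution errors.

Ages are mapped to numeric day positions with embryonic days negative
relative to birth (E14 -> -5, E17 -> -2, P1 -> 1, ... P60 -> 60).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_models import GeneModel, parse_gene_annotation

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: default developmental panel: (age label, numeric position in days, birth = 0).
#: Dense over the perinatal switch window, where the trajectories change
#: fastest, with three maintenance ages (P21, P30, P60) covering the adult
#: plateau; consecutive expected values outside the plateau group differ by
#: more than the replicate noise, so rank-based trajectory recovery is
#: well-posed on this panel.
DEFAULT_AGES: tuple[tuple[str, float], ...] = (
    ("E14", -5.0),
    ("E17", -2.0),
    ("P1", 1.0),
    ("P2", 2.0),
    ("P3", 3.0),
    ("P5", 5.0),
    ("P7", 7.0),
    ("P9", 9.0),
    ("P11", 11.0),
    ("P21", 21.0),
    ("P30", 30.0),
    ("P60", 60.0),
)


@dataclass(frozen=True)
class TrajectorySpec:
    """Parametric expected-expression trajectory (cpm-scale units).

    shapes: ``early_peak`` — Gaussian bump A*exp(-(t-t0)^2/(2 sigma^2));
    ``late_plateau`` — sigmoid A/(1+exp(-(t-t50)/slope)); ``constant`` — A.
    """

    shape: str
    amplitude: float
    t0: float | None = None
    sigma: float | None = None
    t50: float | None = None
    slope: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("early_peak", "late_plateau", "constant"):
            raise ValueError(f"unknown trajectory shape {self.shape!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.shape == "early_peak" and (self.sigma is None or self.sigma <= 0):
            raise ValueError("early_peak requires sigma > 0")
        if self.shape == "late_plateau" and (self.slope is None or self.slope <= 0):
            raise ValueError("late_plateau requires slope > 0")


def trajectory_value(spec: TrajectorySpec, t: float | np.ndarray) -> float | np.ndarray:
    t = np.asarray(t, dtype=float)
    if spec.shape == "early_peak":
        val = spec.amplitude * np.exp(-((t - spec.t0) ** 2) / (2 * spec.sigma**2))
    elif spec.shape == "late_plateau":
        from scipy.special import expit

        val = spec.amplitude * expit((t - spec.t50) / spec.slope)
    else:
        val = np.full_like(t, spec.amplitude, dtype=float)
    return val if val.ndim else float(val)


@dataclass
class SimulationConfig:
    ages: Sequence[tuple[str, float]] = DEFAULT_AGES
    replicates: int = 3
    reads_per_sample: int = 200_000
    read_length: int = 50
    error_rate: float = 0.002
    dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error rate must be in [0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class ReadBatch:
    """Fixed-length reads packed as a (n, L) uint8 ASCII array."""

    seqs: np.ndarray
    ids: list[str]

    def __len__(self) -> int:
        return self.seqs.shape[0]

    def iter_records(self):
        qual = "I" * self.seqs.shape[1]  # constant Phred 40
        for i, rid in enumerate(self.ids):
            yield rid, self.seqs[i].tobytes().decode("ascii"), qual

    def to_fastq(self, handle) -> None:
        for rid, seq, qual in self.iter_records():
            handle.write(f"@{rid}\n{seq}\n+\n{qual}\n")


@dataclass
class SampleTruth:
    """Per-sample ground truth: abundance fractions and per-read sources."""

    fractions: pd.Series  # transcript -> true read fraction (sums to 1)
    source_transcript: np.ndarray  # per read, index into transcript order
    source_position: np.ndarray  # per read, 0-based start in transcript
    transcript_order: list[str]


def simulate_sample_counts(
    expected: np.ndarray,
    lengths: np.ndarray,
    depth: int,
    dispersion: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw per-transcript read totals.

    Mean count is depth * expected_t * length_t / sum(expected * length)
    (expression is molar, so read yield scales with transcript length).
    Counts are negative binomial with variance m + dispersion * m^2;
    dispersion 0 reduces to Poisson.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    expected = np.asarray(expected, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if (expected < 0).any():
        raise ValueError("expected expression must be >= 0")
    weight = expected * lengths
    total = weight.sum()
    if total == 0:
        return np.zeros_like(expected, dtype=np.int64)
    mean = depth * weight / total
    counts = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    if dispersion == 0:
        counts[pos] = rng.poisson(mean[pos])
    else:
        n = 1.0 / dispersion
        p = n / (n + mean[pos])
        counts[pos] = rng.negative_binomial(n, p)
    return counts


def simulate_reads(
    transcripts: Mapping[str, str],
    counts: Mapping[str, int],
    read_length: int,
    error_rate: float,
    rng: np.random.Generator | int,
    id_prefix: str = "read",
) -> tuple[ReadBatch, SampleTruth]:
    """Emit fixed-length reads with uniform start positions.

    Per-base substitution errors occur at ``error_rate`` (the erroneous base
    is drawn uniformly from the other three).  The truth table records each
    read's source transcript and start.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    order = list(transcripts)
    for tid in order:
        if counts.get(tid, 0) > 0 and len(transcripts[tid]) < read_length:
            raise ValueError(
                f"transcript {tid} (length {len(transcripts[tid])}) shorter "
                f"than read length {read_length}"
            )
    n_total = int(sum(counts.get(tid, 0) for tid in order))
    seqs = np.empty((n_total, read_length), dtype=np.uint8)
    src_t = np.empty(n_total, dtype=np.int64)
    src_p = np.empty(n_total, dtype=np.int64)
    row = 0
    for t_idx, tid in enumerate(order):
        n = int(counts.get(tid, 0))
        if n == 0:
            continue
        tarr = np.frombuffer(transcripts[tid].encode("ascii"), dtype=np.uint8)
        starts = rng.integers(0, len(tarr) - read_length + 1, size=n)
        seqs[row : row + n] = tarr[starts[:, None] + np.arange(read_length)]
        src_t[row : row + n] = t_idx
        src_p[row : row + n] = starts
        row += n
    if error_rate > 0 and n_total > 0:
        err = rng.random((n_total, read_length)) < error_rate
        n_err = int(err.sum())
        if n_err:
            # replace with a uniformly chosen *different* base
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            cur = seqs[err]
            code = np.zeros(n_err, dtype=np.uint8)
            for b, c in zip(b"CGT", (1, 2, 3)):
                code[cur == b] = c
            seqs[err] = BASES[(code + shift) % 4]
    weight = np.array([counts.get(tid, 0) for tid in order], dtype=float)
    fractions = weight / weight.sum() if weight.sum() else weight
    ids = [f"{id_prefix}_{i}" for i in range(n_total)]
    truth = SampleTruth(
        pd.Series(fractions, index=order), src_t, src_p, order
    )
    return ReadBatch(seqs, ids), truth


# ---------------------------------------------------------------------------
# Study fixture: toy genome + annotation + per-sample reads
# ---------------------------------------------------------------------------

#: default trajectories: isoform 2 peaks embryonically and declines steeply
#: after birth; isoform 1 rises postnatally (sigmoid midpoint P8, so ~90% of
#: plateau by P15) and stays high into adulthood.
DEFAULT_TRAJECTORIES: dict[str, TrajectorySpec] = {
    "iso1": TrajectorySpec("late_plateau", amplitude=60.0, t50=8.0, slope=3.0),
    "iso2": TrajectorySpec("early_peak", amplitude=100.0, t0=-5.0, sigma=6.0),
}

N_HOUSEKEEPING = 5
HOUSEKEEPING_AMPLITUDE = 200.0


@dataclass
class StudyFixture:
    genome: dict[str, str]
    gtf_text: str
    gene: GeneModel
    transcripts: dict[str, str]  # sense-strand spliced sequences
    samples: pd.DataFrame  # sample_id, age_label, age_t, replicate
    reads: dict[str, ReadBatch]
    truth: dict[str, SampleTruth]
    trajectories: dict[str, TrajectorySpec]
    config: SimulationConfig

    @property
    def target_transcript_ids(self) -> tuple[str, str]:
        return ("Tgene.iso1", "Tgene.iso2")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _make_target_gene(rng: np.random.Generator) -> tuple[str, list[str]]:
    """Genome sequence for chrT plus GTF lines for the two-isoform gene.

    Layout (plus strand): four isoform-1-specific exons (two coding, two
    non-coding, 110 bp each), one isoform-2-specific exon (440 bp), a 6.2 kb
    intron, then six shared exons (150 bp each).  Both isoforms therefore
    carry 440 specific bases and identical 1340 nt spliced lengths.
    """
    iso1_exons = [(1000 + 400 * i, 1000 + 400 * i + 110) for i in range(4)]
    iso2_exon = (3500, 3940)
    common_start = iso2_exon[1] + 6200  # > 6 kb intron before shared exons
    common_exons = [
        (common_start + 350 * i, common_start + 350 * i + 150) for i in range(6)
    ]
    chrom_len = common_exons[-1][1] + 500
    seq = _random_seq(rng, chrom_len)

    lines = []

    def exon_line(start0, end0, tid, iso, eid, coding=True):
        attrs = (
            f'gene_id "Tgene"; transcript_id "{tid}"; isoform "{iso}"; '
            f'exon_id "{eid}"; coding "{"true" if coding else "false"}";'
        )
        return f"chrT\tisoswitch\texon\t{start0 + 1}\t{end0}\t.\t+\t.\t{attrs}"

    for i, (s, e) in enumerate(iso1_exons):
        lines.append(
            exon_line(s, e, "Tgene.iso1", "iso1", f"iso1.e{i + 1}", coding=i >= 2)
        )
    for i, (s, e) in enumerate(common_exons):
        lines.append(exon_line(s, e, "Tgene.iso1", "iso1", f"common.e{i + 1}"))
    lines.append(exon_line(*iso2_exon, "Tgene.iso2", "iso2", "iso2.e1"))
    for i, (s, e) in enumerate(common_exons):
        lines.append(exon_line(s, e, "Tgene.iso2", "iso2", f"common.e{i + 1}"))
    return seq, lines


def _make_housekeeping(rng: np.random.Generator, n: int) -> tuple[str, list[str]]:
    """n single-transcript two-exon genes on chrH, 600 nt spliced each."""
    lines = []
    pos = 200
    for g in range(n):
        exons = [(pos, pos + 300), (pos + 500, pos + 800)]
        gid = f"Hk{g + 1}"
        for i, (s, e) in enumerate(exons):
            attrs = (
                f'gene_id "{gid}"; transcript_id "{gid}.t1"; '
                f'exon_id "{gid}.e{i + 1}";'
            )
            lines.append(f"chrH\tisoswitch\texon\t{s + 1}\t{e}\t.\t+\t.\t{attrs}")
        pos += 1200
    chrom_len = pos + 200
    seq = _random_seq(rng, chrom_len)
    return seq, lines


def _spliced(genome: Mapping[str, str], gene: GeneModel) -> dict[str, str]:
    out = {}
    for t in gene.transcripts:
        out[t.transcript_id] = "".join(
            genome[e.interval.chrom][e.interval.start : e.interval.end]
            for e in t.exons
        )
    return out


def make_study_fixture(config: SimulationConfig | None = None) -> StudyFixture:
    """Generate the full toy study: genome, GTF, per-sample reads, truth.

    Deterministic for a fixed config seed.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)

    chrT, target_lines = _make_target_gene(rng)
    chrH, hk_lines = _make_housekeeping(rng, N_HOUSEKEEPING)
    genome = {"chrT": chrT, "chrH": chrH}
    gtf_text = "\n".join(target_lines + hk_lines) + "\n"

    models = {g.gene_id: g for g in parse_gene_annotation(gtf_text)}
    target = models["Tgene"]
    transcripts: dict[str, str] = {}
    for g in models.values():
        transcripts.update(_spliced(genome, g))

    trajectories = dict(DEFAULT_TRAJECTORIES)
    specs: dict[str, TrajectorySpec] = {
        "Tgene.iso1": trajectories["iso1"],
        "Tgene.iso2": trajectories["iso2"],
    }
    for g in range(N_HOUSEKEEPING):
        specs[f"Hk{g + 1}.t1"] = TrajectorySpec("constant", HOUSEKEEPING_AMPLITUDE)

    order = list(transcripts)
    lengths = np.array([len(transcripts[t]) for t in order], dtype=float)

    rows = []
    reads: dict[str, ReadBatch] = {}
    truth: dict[str, SampleTruth] = {}
    for age_label, t in config.ages:
        for rep in range(1, config.replicates + 1):
            sample_id = f"{age_label}_r{rep}"
            expected = np.array(
                [trajectory_value(specs[tid], t) for tid in order], dtype=float
            )
            counts_arr = simulate_sample_counts(
                expected, lengths, config.reads_per_sample, config.dispersion, rng
            )
            counts = dict(zip(order, (int(c) for c in counts_arr)))
            batch, tr = simulate_reads(
                transcripts,
                counts,
                config.read_length,
                config.error_rate,
                rng,
                id_prefix=sample_id,
            )
            rows.append(
                {
                    "sample_id": sample_id,
                    "age_label": age_label,
                    "age_t": t,
                    "replicate": rep,
                }
            )
            reads[sample_id] = batch
            truth[sample_id] = tr

    samples = pd.DataFrame(rows).set_index("sample_id", drop=False)
    return StudyFixture(
        genome=genome,
        gtf_text=gtf_text,
        gene=target,
        transcripts=transcripts,
        samples=samples,
        reads=reads,
        truth=truth,
        trajectories=trajectories,
        config=config,
    )


def analytic_crossing(
    spec_rising: TrajectorySpec,
    spec_falling: TrajectorySpec,
    t_min: float,
    t_max: float,
) -> float | None:
    """Age at which the rising trajectory first overtakes the falling one.

    Solved on the continuous true curves by bisection; None if no sign change
    in [t_min, t_max].
    """
    from scipy.optimize import brentq

    def diff(t):
        return trajectory_value(spec_rising, t) - trajectory_value(spec_falling, t)

    grid = np.linspace(t_min, t_max, 512)
    vals = np.array([diff(t) for t in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        return None
    i = sign_change[0]
    return float(brentq(diff, grid[i], grid[i + 1]))
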
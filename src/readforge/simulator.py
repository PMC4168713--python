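"""Read sampling, error injection and dataset generation.

Reads are produced in two stages, mirroring the training side: first a raw
read of uniform (intermediate) length is sampled from the genome database —
genome chosen by abundance, start uniform over valid positions, strand
equiprobable — then the raw read is *realized*: trimmed from the 3' end to
a length drawn from the empirical length distribution, given a quality
string from the Markov chain, and walked base by base injecting
substitution, insertion and deletion errors at the modelled per-position
rates.  Erroneous bases have their chain quality overridden by the
quality-error model.  Every injected event is recorded, so each read's
ground truth (source genome, coordinates, strand, events) is exact.

Deletions consume extra template so the realized read keeps its sampled
length: the length distribution is a trained model, not a side effect of
the error process.  All randomness flows through one generator in a fixed
draw order, making whole datasets byte-reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .error_models import BASES, ErrorRateModel, QualityErrorModel, default_error_prob
from .io_formats import AbundanceProfile, SequenceRecord, write_reads
from .quality_length_models import (
    LengthDistribution,
    QualityMarkovModel,
    sample_length,
    sample_quality_string,
)

__all__ = [
    "SimulationError",
    "SimulatedRead",
    "SimulationConfig",
    "sample_raw_read",
    "realize_read",
    "generate_pair",
    "generate_dataset",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: transition partner of each base
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
#: the two transversion targets of each base, in fixed order
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


class SimulationError(RuntimeError):
    """Raised on unsatisfiable sampling setups (bad profile, tiny genomes...)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulatedRead:
    """A simulated read with full provenance.

    ``start``/``end`` are 0-based half-open genome coordinates; strand '+'
    means the error-free read equals the genome slice, '-' its reverse
    complement.  ``events`` records each injected error as
    (read_position 0-based, kind in {sub, ins, del}, from_base, to_base).
    """

    id: str
    sequence: str
    qualities: Optional[list[int]]
    genome_id: str
    start: int
    end: int
    strand: str
    events: list[tuple[int, str, str, str]] = field(default_factory=list)

    @property
    def n_sub(self) -> int:
        return sum(1 for e in self.events if e[1] == "sub")

    @property
    def n_ins(self) -> int:
        return sum(1 for e in self.events if e[1] == "ins")

    @property
    def n_del(self) -> int:
        return sum(1 for e in self.events if e[1] == "del")


@dataclass
class SimulationConfig:
    n_reads: int
    seed: int = 0
    paired: bool = False
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    uniform_len: Optional[int] = None  # default: length-model support_max
    error_mode: str = "trained"  # or "default"
    run_tag: str = "sim"
    allow_n: bool = False
    max_retries: int = 50

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.error_mode not in ("trained", "default"):
            raise ValueError(f"unknown error_mode {self.error_mode!r}")


# ---------------------------------------------------------------------------
# Raw read sampling
# ---------------------------------------------------------------------------

class _CommunitySampler:
    """Pre-validated genome lookup + cumulative-abundance sampling."""

    def __init__(self, db: Sequence[SequenceRecord], profile: AbundanceProfile):
        by_id = {rec.id: rec for rec in db}
        missing = [g for g in profile.ids if g not in by_id]
        if missing:
            raise SimulationError(
                f"abundance profile references genome(s) absent from the "
                f"database: {missing[:5]}"
            )
        self.genomes = [by_id[g] for g in profile.ids]
        self.cum = np.cumsum(profile.abundances)
        self.cum[-1] = 1.0

    def draw_genome(self, rng: np.random.Generator) -> SequenceRecord:
        i = int(np.searchsorted(self.cum, rng.random(), side="right"))
        return self.genomes[min(i, len(self.genomes) - 1)]


def sample_raw_read(
    db: Sequence[SequenceRecord],
    profile: AbundanceProfile,
    uniform_len: int,
    rng: np.random.Generator,
    *,
    allow_n: bool = False,
    max_retries: int = 50,
    _sampler: Optional[_CommunitySampler] = None,
) -> SimulatedRead:
    """Sample one error-free uniform-length read from the community.

    Draw order: genome, start, strand.  Reads overlapping N in the genome
    are resampled up to ``max_retries`` times unless ``allow_n``.  A genome
    shorter than ``uniform_len`` caps the read at the genome length.
    """
    sampler = _sampler or _CommunitySampler(db, profile)
    for _ in range(max_retries + 1):
        genome = sampler.draw_genome(rng)
        glen = len(genome.sequence)
        take = min(uniform_len, glen)
        start = int(rng.integers(0, glen - take + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        slice_ = genome.sequence[start : start + take]
        if "N" in slice_ and not allow_n:
            continue
        seq = slice_ if strand == "+" else reverse_complement(slice_)
        return SimulatedRead(
            id="",
            sequence=seq,
            qualities=None,
            genome_id=genome.id,
            start=start,
            end=start + take,
            strand=strand,
        )
    raise SimulationError(
        f"could not sample an N-free read in {max_retries} retries; "
        "pass allow_n=True or clean the database"
    )


# ---------------------------------------------------------------------------
# Realization: trim, qualities, error injection
# ---------------------------------------------------------------------------

def realize_read(
    raw: SimulatedRead,
    lengths: LengthDistribution,
    qmodel: QualityMarkovModel,
    emodel: Optional[ErrorRateModel],
    qerr: Optional[QualityErrorModel],
    rng: np.random.Generator,
    *,
    default_mode: bool = False,
) -> SimulatedRead:
    """Turn a raw uniform-length read into a final variable-length read.

    Steps: (1) draw the target length p and keep the raw read's first p
    bases (5' end; 3' bases are the low-quality end worth trimming);
    (2) sample a length-p quality string from the Markov chain; (3) walk
    positions 1..p injecting errors.  At each position the current template
    base b substitutes with probability ``sub_rate(b, i)``; otherwise an
    indel occurs with ``indel_rate(i)``, split into insertion vs deletion
    by the ins:del ratio.  Substitution targets are the transition partner
    with probability titv, else one of the two transversions equiprobably.
    Substituted and inserted bases take the quality-error model's quality;
    in default mode the chain quality is kept and the per-position error
    probability is Phred-implied, split equally across the three classes.

    Deletions skip a template base and consume further template to keep
    length p, shortening the read only if the raw slice runs out.
    """
    p = sample_length(lengths, rng)
    template = raw.sequence
    if p > len(template):
        p = len(template)  # genome-capped raw read: truncate the target
    quals = sample_quality_string(qmodel, p, rng)

    if default_mode:
        return _realize_default(raw, template, p, quals, rng)
    if emodel is None or qerr is None:
        raise ValueError("trained mode requires both error models")

    sub_m, indel_a, frac_a = emodel.rate_arrays(max(p, 1))
    base_row = {b: sub_m[j] for j, b in enumerate(BASES)}
    titv = emodel.titv

    out = []
    out_q = []
    events = []
    t = 0
    i = 0
    u = rng.random(p)
    n_template = len(template)
    while i < p and t < n_template:
        b = template[t]
        pos1 = i + 1
        x = u[i]
        r_sub = base_row[b][pos1] if b != "N" else 0.0
        r_indel = indel_a[pos1]
        if x < r_sub:
            new = _substitute(b, titv, rng)
            out.append(new)
            out_q.append(qerr.predict(new, pos1))
            events.append((i, "sub", b, new))
            t += 1
        elif x < r_sub + r_indel:
            if rng.random() < frac_a[pos1]:
                ins = BASES[int(rng.integers(0, 4))]
                out.append(ins)
                out_q.append(qerr.predict(ins, pos1))
                events.append((i, "ins", "-", ins))
                # template not consumed; downstream bases shift right
            else:
                events.append((i, "del", b, "-"))
                t += 1
                u[i] = rng.random()  # fresh draw for the retried position
                continue
        else:
            out.append(b)
            out_q.append(quals[i])
            t += 1
        i += 1
    return _finish(raw, out, out_q, events, t)


def _realize_default(raw, template, p, quals, rng):
    """Default (quality-implied) error mode of :func:`realize_read`."""
    out = []
    out_q = []
    events = []
    t = 0
    i = 0
    u = rng.random(p)
    n_template = len(template)
    while i < p and t < n_template:
        b = template[t]
        p_each = default_error_prob(quals[i]) / 3.0
        x = u[i]
        if x < p_each:  # substitution, uniform among the three other bases
            k = int(rng.integers(0, 3))
            others = [c for c in BASES if c != b] if b != "N" else list(BASES[:3])
            new = others[k]
            out.append(new)
            out_q.append(quals[i])
            events.append((i, "sub", b, new))
            t += 1
        elif x < 2 * p_each:  # insertion
            ins = BASES[int(rng.integers(0, 4))]
            out.append(ins)
            out_q.append(quals[i])
            events.append((i, "ins", "-", ins))
        elif x < 3 * p_each:  # deletion
            events.append((i, "del", b, "-"))
            t += 1
            u[i] = rng.random()
            continue
        else:
            out.append(b)
            out_q.append(quals[i])
            t += 1
        i += 1
    return _finish(raw, out, out_q, events, t)


def _finish(raw, out, out_q, events, consumed):
    if raw.strand == "+":
        start, end = raw.start, raw.start + consumed
    else:
        start, end = raw.end - consumed, raw.end
    return SimulatedRead(
        id=raw.id,
        sequence="".join(out),
        qualities=out_q,
        genome_id=raw.genome_id,
        start=start,
        end=end,
        strand=raw.strand,
        events=events,
    )


def _substitute(base: str, titv: float, rng: np.random.Generator) -> str:
    if rng.random() < titv:
        return _TRANSITION[base]
    pair = _TRANSVERSIONS[base]
    return pair[0] if rng.random() < 0.5 else pair[1]


# ---------------------------------------------------------------------------
# Paired-end
# ---------------------------------------------------------------------------

def generate_pair(
    db: Sequence[SequenceRecord],
    profile: AbundanceProfile,
    config: SimulationConfig,
    lengths: LengthDistribution,
    qmodel: QualityMarkovModel,
    emodel: Optional[ErrorRateModel],
    qerr: Optional[QualityErrorModel],
    rng: np.random.Generator,
    uniform_len: int,
    *,
    _sampler: Optional[_CommunitySampler] = None,
) -> tuple[SimulatedRead, SimulatedRead]:
    """Sample one read pair from a Normal(insert_mean, insert_sd) fragment.

    Mate 1 reads inward from the fragment's 5' end on the fragment strand;
    mate 2 reads inward from the 3' end on the opposite strand.  The
    fragment length is clamped to [uniform_len, genome length]; genomes too
    short for a full-length mate are resampled up to the retry bound.
    """
    sampler = _sampler or _CommunitySampler(db, profile)
    genome = None
    for _ in range(config.max_retries + 1):
        candidate = sampler.draw_genome(rng)
        if len(candidate.sequence) >= uniform_len:
            genome = candidate
            break
    if genome is None:
        raise SimulationError(
            f"no genome of length >= {uniform_len} drawn in "
            f"{config.max_retries} retries"
        )
    glen = len(genome.sequence)
    frag = int(round(rng.normal(config.insert_mean, config.insert_sd)))
    frag = max(uniform_len, min(frag, glen))
    start = int(rng.integers(0, glen - frag + 1))
    frag_strand = "+" if rng.random() < 0.5 else "-"
    m = uniform_len

    five = genome.sequence[start : start + m]
    three = genome.sequence[start + frag - m : start + frag]
    if frag_strand == "+":
        raw1 = SimulatedRead("", five, None, genome.id, start, start + m, "+")
        raw2 = SimulatedRead(
            "", reverse_complement(three), None, genome.id,
            start + frag - m, start + frag, "-",
        )
    else:
        raw1 = SimulatedRead(
            "", reverse_complement(three), None, genome.id,
            start + frag - m, start + frag, "-",
        )
        raw2 = SimulatedRead("", five, None, genome.id, start, start + m, "+")

    default_mode = config.error_mode == "default"
    read1 = realize_read(raw1, lengths, qmodel, emodel, qerr, rng, default_mode=default_mode)
    read2 = realize_read(raw2, lengths, qmodel, emodel, qerr, rng, default_mode=default_mode)
    return read1, read2


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def simulate_reads(
    db: Sequence[SequenceRecord],
    profile: AbundanceProfile,
    config: SimulationConfig,
    lengths: LengthDistribution,
    qmodel: QualityMarkovModel,
    emodel: Optional[ErrorRateModel] = None,
    qerr: Optional[QualityErrorModel] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Yield ``config.n_reads`` realized reads (or mate tuples when paired)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    uniform_len = config.uniform_len or lengths.support_max
    sampler = _CommunitySampler(db, profile)
    default_mode = config.error_mode == "default"
    if not default_mode and (emodel is None or qerr is None):
        raise SimulationError("error_mode='trained' requires trained error models")
    if config.paired:
        n_pairs = (config.n_reads + 1) // 2
        for serial in range(n_pairs):
            r1, r2 = generate_pair(
                db, profile, config, lengths, qmodel, emodel, qerr, rng,
                uniform_len, _sampler=sampler,
            )
            r1.id = f"{config.run_tag}.{serial}/1"
            r2.id = f"{config.run_tag}.{serial}/2"
            yield r1, r2
    else:
        for serial in range(config.n_reads):
            raw = sample_raw_read(
                db, profile, uniform_len, rng,
                allow_n=config.allow_n, max_retries=config.max_retries,
                _sampler=sampler,
            )
            read = realize_read(
                raw, lengths, qmodel, emodel, qerr, rng, default_mode=default_mode
            )
            read.id = f"{config.run_tag}.{serial}"
            yield read


def generate_dataset(
    db: Sequence[SequenceRecord],
    profile: AbundanceProfile,
    config: SimulationConfig,
    lengths: LengthDistribution,
    qmodel: QualityMarkovModel,
    emodel: Optional[ErrorRateModel] = None,
    qerr: Optional[QualityErrorModel] = None,
    out_prefix: str = "simulated",
) -> dict[str, str]:
    """Simulate a dataset and write FASTQ + ground-truth files.

    Single-end: ``<prefix>.fastq``; paired: ``<prefix>_1.fastq`` and
    ``<prefix>_2.fastq``.  Ground truth goes to ``<prefix>.truth.tsv``.
    Fully deterministic given ``config.seed``.  Returns the written paths.
    """
    rng = np.random.default_rng(config.seed)
    stream = simulate_reads(db, profile, config, lengths, qmodel, emodel, qerr, rng)
    if config.paired:
        pairs = list(stream)
        paths = {
            "fastq_1": f"{out_prefix}_1.fastq",
            "fastq_2": f"{out_prefix}_2.fastq",
            "truth": f"{out_prefix}.truth.tsv",
        }
        write_reads([r1 for r1, _ in pairs], paths["fastq_1"], paths["truth"] + ".m1")
        write_reads([r2 for _, r2 in pairs], paths["fastq_2"], paths["truth"] + ".m2")
        _merge_truth(paths["truth"], paths["truth"] + ".m1", paths["truth"] + ".m2")
        return paths
    paths = {"fastq": f"{out_prefix}.fastq", "truth": f"{out_prefix}.truth.tsv"}
    write_reads(stream, paths["fastq"], paths["truth"])
    return paths


def _merge_truth(out_path: str, path1: str, path2: str) -> None:
    """Interleave the two mate truth files so a pair's rows are adjacent."""
    import os

    from .io_formats import TRUTH_COLUMNS, _atomic_open

    with open(path1) as h1, open(path2) as h2, _atomic_open(out_path) as out:
        out.write("\t".join(TRUTH_COLUMNS) + "\n")
        rows1 = h1.readlines()[1:]
        rows2 = h2.readlines()[1:]
        for a, b in zip(rows1, rows2):
            out.write(a)
            out.write(b)
    os.unlink(path1)
    os.unlink(path2)
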
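"""Deterministic synthetic data for training and validating every model.

The generator emulates the *inputs* the simulator is trained on: random
genomes, a training FASTQ whose read lengths follow a chosen pmf and whose
qualities follow an explicit position-dependent Markov chain, with
substitution and indel errors planted at known exponential rates inside
groups of artifactual duplicate reads (identical prefixes), plus a
taxonomy-annotated hit table with known intended LCA outcomes.  Because
every planted truth is returned (and serializable) alongside the data, the
estimators can be validated against ground truth with no external
downloads.

Genomes are i.i.d. uniform over A,C,G,T: the trained models are
sequence-composition-agnostic apart from the transition/transversion
balance, which the planted substitution classes exercise directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io_formats import HitRecord, SequenceRecord

__all__ = [
    "FixtureSpec",
    "FixtureTruth",
    "make_genomes",
    "make_training_reads",
    "make_hit_table",
    "default_quality_chain",
]

BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


def default_quality_chain(
    q_start: int = 38,
    drift: float = -0.08,
    spread: int = 2,
    max_len: int = 200,
    q_min: int = 2,
    q_max: int = 40,
) -> dict[tuple[int, int], dict[int, float]]:
    """An explicit, realistically drifting quality transition table.

    Qualities start near ``q_start`` and drift down along the read (the
    3'-decay seen on real instruments), moving at most ``spread`` units per
    step.  Returned as {(position_prev, q_prev): {q_next: prob}} including
    the (0, 0) start-sentinel context.
    """
    chain: dict[tuple[int, int], dict[int, float]] = {
        (0, 0): {q_start: 0.6, q_start - 1: 0.25, q_start - 2: 0.15}
    }
    for i in range(max_len):
        for q in range(q_min, q_max + 1):
            center = q + drift
            steps = np.arange(-spread, spread + 1)
            w = np.exp(-((q + steps - center) ** 2) / 2.0)
            targets = np.clip(q + steps, q_min, q_max)
            probs: dict[int, float] = {}
            for t, wt in zip(targets.tolist(), (w / w.sum()).tolist()):
                probs[t] = probs.get(t, 0.0) + wt
            chain[(i, q)] = probs
    return chain


@dataclass
class FixtureSpec:
    """Controls for the synthetic data generator; all pmfs sum to 1."""

    n_genomes: int = 2
    genome_len: int = 10_000
    length_pmf: dict[int, float] = field(
        default_factory=lambda: {80: 0.2, 100: 0.5, 120: 0.3}
    )
    quality_chain: Optional[dict] = None  # default_quality_chain() when None
    planted_sub: tuple[float, float] = (0.005, 0.0)  # alpha, beta per position
    planted_indel: tuple[float, float] = (0.002, 0.0)
    planted_ins_fraction: float = 0.5
    planted_titv: float = 0.5
    n_reads: int = 2_000
    duplication_fraction: float = 0.5
    bin_multiplicity: int = 25
    prefix_len: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.length_pmf.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"length_pmf sums to {total}, expected 1")
        if min(self.length_pmf) < self.prefix_len:
            raise ValueError("all read lengths must cover the duplicate prefix")

    def chain(self) -> dict:
        if self.quality_chain is None:
            self.quality_chain = default_quality_chain(
                max_len=max(self.length_pmf) + 1
            )
        return self.quality_chain

    def sub_rate(self, pos1: int) -> float:
        a, b = self.planted_sub
        return min(1.0, a * np.exp(b * pos1))

    def indel_rate(self, pos1: int) -> float:
        a, b = self.planted_indel
        return min(1.0, a * np.exp(b * pos1))


@dataclass
class FixtureTruth:
    """Planted ground truth serialized alongside every fixture."""

    spec_seed: int
    length_pmf: dict[int, float]
    planted_sub: tuple[float, float]
    planted_indel: tuple[float, float]
    planted_ins_fraction: float
    planted_titv: float
    n_duplicate_bins: int
    intended_assignments: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        from .io_formats import _atomic_open

        payload = {
            "spec_seed": self.spec_seed,
            "length_pmf": {str(k): v for k, v in self.length_pmf.items()},
            "planted_sub": list(self.planted_sub),
            "planted_indel": list(self.planted_indel),
            "planted_ins_fraction": self.planted_ins_fraction,
            "planted_titv": self.planted_titv,
            "n_duplicate_bins": self.n_duplicate_bins,
            "intended_assignments": self.intended_assignments,
        }
        with _atomic_open(path) as handle:
            json.dump(payload, handle, indent=1)
            handle.write("\n")


def make_genomes(spec: FixtureSpec, rng: np.random.Generator) -> list[SequenceRecord]:
    """i.i.d. uniform-base genomes, ids g0001..; byte-reproducible per seed."""
    if spec.genome_len < 1:
        raise ValueError("genome_len must be >= 1")
    genomes = []
    for k in range(spec.n_genomes):
        bases = rng.integers(0, 4, size=spec.genome_len)
        seq = "".join(BASES[b] for b in bases)
        genomes.append(SequenceRecord(id=f"g{k + 1:04d}", sequence=seq))
    return genomes


def make_training_reads(
    spec: FixtureSpec, rng: np.random.Generator
) -> tuple[list[SequenceRecord], FixtureTruth]:
    """Training FASTQ records with planted errors and duplicate structure.

    A ``duplication_fraction`` share of the reads comes in groups of
    ``bin_multiplicity`` copies of a common template (identical error-free
    prefix), so the duplicate-binning estimator has material to work with;
    the rest are singletons.  Substitutions and indels are planted beyond
    the prefix at the spec's exponential rates — inside duplicate groups
    only, so the planted rate is exactly what within-bin disagreement
    should recover.  Qualities are sampled from the explicit chain.
    """
    chain = spec.chain()
    sampler = _ChainSampler(chain, rng)
    lengths = sorted(spec.length_pmf)
    length_p = np.array([spec.length_pmf[k] for k in lengths])
    support_max = lengths[-1]

    n_dup = int(round(spec.n_reads * spec.duplication_fraction))
    n_bins = n_dup // spec.bin_multiplicity
    n_singletons = spec.n_reads - n_bins * spec.bin_multiplicity

    reads: list[SequenceRecord] = []
    serial = 0
    for _ in range(n_bins):
        template = "".join(
            BASES[b] for b in rng.integers(0, 4, size=support_max)
        )
        for _ in range(spec.bin_multiplicity):
            L = int(rng.choice(lengths, p=length_p))
            seq = _plant_errors(template[:L], spec, rng)
            reads.append(
                SequenceRecord(
                    id=f"fx{serial:06d}",
                    sequence=seq,
                    qualities=sampler.sample(len(seq)),
                )
            )
            serial += 1
    for _ in range(n_singletons):
        L = int(rng.choice(lengths, p=length_p))
        seq = "".join(BASES[b] for b in rng.integers(0, 4, size=L))
        reads.append(
            SequenceRecord(
                id=f"fx{serial:06d}",
                sequence=seq,
                qualities=sampler.sample(L),
            )
        )
        serial += 1
    truth = FixtureTruth(
        spec_seed=spec.seed,
        length_pmf=dict(spec.length_pmf),
        planted_sub=spec.planted_sub,
        planted_indel=spec.planted_indel,
        planted_ins_fraction=spec.planted_ins_fraction,
        planted_titv=spec.planted_titv,
        n_duplicate_bins=n_bins,
    )
    return reads, truth


def _plant_errors(template: str, spec: FixtureSpec, rng: np.random.Generator) -> str:
    """Apply the planted error process to one duplicate-group member.

    Positions within the prefix stay error-free (so group members share an
    identical prefix by construction); beyond it each position substitutes
    with the planted rate, else suffers an indel with the planted indel
    rate.  Planted events mirror the simulator's: transitions with
    probability titv, insertions of uniform bases, deletions consuming
    template (final length may drift by the few planted indels).
    """
    out = list(template[: spec.prefix_len])
    t = spec.prefix_len
    i = spec.prefix_len
    n = len(template)
    while t < n:
        b = template[t]
        pos1 = i + 1
        x = rng.random()
        if x < spec.sub_rate(pos1):
            if rng.random() < spec.planted_titv:
                out.append(_TRANSITION[b])
            else:
                pair = _TRANSVERSIONS[b]
                out.append(pair[0] if rng.random() < 0.5 else pair[1])
            t += 1
        elif x < spec.sub_rate(pos1) + spec.indel_rate(pos1):
            if rng.random() < spec.planted_ins_fraction:
                out.append(BASES[int(rng.integers(0, 4))])
                # template base not consumed; it will be emitted next
            else:
                t += 1  # deletion: skip the template base
                continue
        else:
            out.append(b)
            t += 1
        i += 1
    return "".join(out)


class _ChainSampler:
    """Samples quality strings from an explicit transition table."""

    def __init__(self, chain: dict, rng: np.random.Generator):
        self.rng = rng
        self.compiled = {}
        for ctx, probs in chain.items():
            vals = np.array(sorted(probs), dtype=np.int64)
            p = np.array([probs[v] for v in vals], dtype=float)
            cum = np.cumsum(p / p.sum())
            cum[-1] = 1.0
            self.compiled[ctx] = (vals, cum)
        self.fallback_q = int(
            max(chain[(0, 0)], key=lambda q: chain[(0, 0)][q])
        )

    def sample(self, length: int) -> list[int]:
        out = []
        q_prev = 0
        for i in range(length):
            ctx = self.compiled.get((i, q_prev))
            if ctx is None:
                out.append(self.fallback_q)
                q_prev = self.fallback_q
                continue
            vals, cum = ctx
            q = int(vals[np.searchsorted(cum, self.rng.random(), side="right")])
            out.append(q)
            q_prev = q
        return out


def make_hit_table(
    rng: np.random.Generator,
    n_queries: int = 30,
    neighborhood: float = 0.9,
) -> tuple[list[HitRecord], dict[str, list[str]]]:
    """Hit records with known intended LCA outcomes under ``neighborhood``.

    Three scenario families are cycled: (a) a clearly best hit whose
    competitors fall outside the score neighborhood (intended assignment =
    the best hit's full lineage); (b) two equal-score hits diverging at the
    species rank (intended = shared genus-level prefix); (c) equal-score
    hits with disjoint lineages (intended = root, the empty lineage).
    Returns (hits, {query_id: intended_lineage}).
    """
    base = ["Bacteria", "Proteobacteria", "Gammaproteobacteria",
            "Enterobacterales", "Enterobacteriaceae", "Escherichia",
            "Escherichia coli"]
    alt_species = base[:5] + ["Salmonella", "Salmonella enterica"]
    disjoint = ["Archaea", "Euryarchaeota", "Methanococci",
                "Methanococcales", "Methanococcaceae", "Methanococcus",
                "Methanococcus maripaludis"]
    hits: list[HitRecord] = []
    intended: dict[str, list[str]] = {}
    for k in range(n_queries):
        qid = f"q{k:04d}"
        top = float(rng.uniform(80, 200))
        scenario = k % 3
        if scenario == 0:
            low = top * neighborhood * float(rng.uniform(0.7, 0.98))
            hits.append(HitRecord(qid, top, list(base)))
            hits.append(HitRecord(qid, low, list(alt_species)))
            intended[qid] = list(base)
        elif scenario == 1:
            hits.append(HitRecord(qid, top, list(base)))
            hits.append(HitRecord(qid, top, list(alt_species)))
            intended[qid] = base[:5]
        else:
            hits.append(HitRecord(qid, top, list(base)))
            hits.append(HitRecord(qid, top, list(disjoint)))
            intended[qid] = []
    return hits, intended
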
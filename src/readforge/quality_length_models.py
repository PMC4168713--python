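"""Empirical read-length distribution and position-dependent quality chain.

Both models are non-parametric and learned directly from a training FASTQ:

* the read-length distribution is the exact empirical pmf of training read
  lengths (no smoothing);
* quality strings follow a position-dependent first-order Markov chain —
  the quality at position i is drawn from the empirical conditional
  distribution P(q_i | q_{i-1}, i-1), with a sentinel q_0 = 0 so that the
  first position uses the empirical distribution of first-position
  qualities.

Sampling must be total: a requested read may be longer than any training
read, or wander into a (position, previous-quality) context never observed.
Unseen contexts fall back, in order, to (same position, marginal over the
previous quality), then (nearest smaller observed position, same previous
quality), then the global quality marginal.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .io_formats import SequenceRecord

__all__ = [
    "LengthDistribution",
    "QualityMarkovModel",
    "train_length_distribution",
    "train_quality_markov",
    "sample_length",
    "sample_quality_string",
    "save_quality_model",
    "load_quality_model",
    "save_length_model",
    "load_length_model",
]

QUALITY_MODEL_SCHEMA = "readforge-quality-model/1"
LENGTH_MODEL_SCHEMA = "readforge-length-model/1"

#: Sentinel "previous quality" for the first read position.
SENTINEL_Q = 0


@dataclass
class LengthDistribution:
    """Empirical pmf over read lengths (bp)."""

    pmf: dict[int, float]
    _lengths: np.ndarray = field(init=False, repr=False, compare=False)
    _cum: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.pmf:
            raise ValueError("empty length pmf")
        if any(length < 1 for length in self.pmf):
            raise ValueError("read lengths must be >= 1")
        total = sum(self.pmf.values())
        if abs(total - 1.0) > 1e-9:
            self.pmf = {k: v / total for k, v in self.pmf.items()}
        items = sorted(self.pmf.items())
        self._lengths = np.array([k for k, _ in items], dtype=np.int64)
        self._cum = np.cumsum([v for _, v in items])
        self._cum[-1] = 1.0

    @property
    def support_max(self) -> int:
        return int(self._lengths[-1])


def train_length_distribution(reads: Iterable[SequenceRecord]) -> LengthDistribution:
    """Exact empirical length frequencies of the training reads."""
    counts: dict[int, int] = {}
    total = 0
    for read in reads:
        counts[len(read.sequence)] = counts.get(len(read.sequence), 0) + 1
        total += 1
    if total == 0:
        raise ValueError("cannot train a length distribution on zero reads")
    return LengthDistribution(pmf={k: v / total for k, v in counts.items()})


def sample_length(dist: LengthDistribution, rng: np.random.Generator) -> int:
    """One draw from the empirical length pmf (inverse-cdf)."""
    i = int(np.searchsorted(dist._cum, rng.random(), side="right"))
    return int(dist._lengths[min(i, len(dist._lengths) - 1)])


@dataclass
class QualityMarkovModel:
    """Position-dependent first-order Markov chain over Phred qualities.

    ``transitions[(i_prev, q_prev)]`` maps the next quality to its observed
    count; ``i_prev`` is the 0-based index of the previous position (0 with
    ``q_prev == 0`` denotes the start sentinel).  Count tables rather than
    probabilities are stored so retrained models can be compared
    observation-for-observation.
    """

    transitions: dict[tuple[int, int], dict[int, int]]
    q_min: int = 0
    q_max: int = 41
    _compiled: dict = field(default_factory=dict, repr=False, compare=False)
    _pos_marginal: dict = field(default_factory=dict, repr=False, compare=False)
    _global: Optional[tuple] = field(default=None, repr=False, compare=False)
    _positions_by_q: dict = field(default_factory=dict, repr=False, compare=False)

    def conditional(self, i_prev: int, q_prev: int) -> dict[int, float]:
        """P(q_i | q_prev, i_prev) as a dict, or {} if the context is unseen."""
        table = self.transitions.get((i_prev, q_prev))
        if not table:
            return {}
        total = sum(table.values())
        return {q: c / total for q, c in table.items()}

    def context_observations(self, i_prev: int, q_prev: int) -> int:
        return sum(self.transitions.get((i_prev, q_prev), {}).values())

    # -- sampling machinery -------------------------------------------------

    def _compile(self) -> None:
        if self._compiled:
            return
        pos_counts: dict[int, dict[int, int]] = {}
        glob: dict[int, int] = {}
        for (i_prev, q_prev), table in self.transitions.items():
            vals = np.array(sorted(table), dtype=np.int64)
            cnts = np.array([table[v] for v in vals], dtype=float)
            cum = np.cumsum(cnts / cnts.sum())
            cum[-1] = 1.0
            self._compiled[(i_prev, q_prev)] = (vals, cum)
            self._positions_by_q.setdefault(q_prev, set()).add(i_prev)
            pc = pos_counts.setdefault(i_prev, {})
            for v, c in table.items():
                pc[v] = pc.get(v, 0) + c
                glob[v] = glob.get(v, 0) + c
        for i_prev, table in pos_counts.items():
            vals = np.array(sorted(table), dtype=np.int64)
            cnts = np.array([table[v] for v in vals], dtype=float)
            cum = np.cumsum(cnts / cnts.sum())
            cum[-1] = 1.0
            self._pos_marginal[i_prev] = (vals, cum)
        vals = np.array(sorted(glob), dtype=np.int64)
        cnts = np.array([glob[v] for v in vals], dtype=float)
        cum = np.cumsum(cnts / cnts.sum())
        cum[-1] = 1.0
        self._global = (vals, cum)
        self._positions_by_q = {
            q: sorted(ps) for q, ps in self._positions_by_q.items()
        }

    def _lookup(self, i_prev: int, q_prev: int):
        """Resolve a context through the fallback hierarchy."""
        ctx = self._compiled.get((i_prev, q_prev))
        if ctx is not None:
            return ctx
        ctx = self._pos_marginal.get(i_prev)
        if ctx is not None:
            return ctx
        positions = self._positions_by_q.get(q_prev)
        if positions:
            k = bisect.bisect_left(positions, i_prev) - 1
            if k >= 0:
                return self._compiled[(positions[k], q_prev)]
        return self._global

    def to_dict(self) -> dict:
        return {
            "q_min": self.q_min,
            "q_max": self.q_max,
            "transitions": {
                f"{i} {q}": {str(v): c for v, c in sorted(table.items())}
                for (i, q), table in sorted(self.transitions.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QualityMarkovModel":
        transitions = {}
        for key, table in d["transitions"].items():
            i, q = key.split()
            transitions[(int(i), int(q))] = {int(v): c for v, c in table.items()}
        return cls(transitions=transitions, q_min=d["q_min"], q_max=d["q_max"])


def train_quality_markov(
    reads: Iterable[SequenceRecord],
    q_min: int = 0,
    q_max: int = 41,
) -> QualityMarkovModel:
    """Count (position, previous-quality) -> next-quality transitions.

    Encoded-key vectorisation keeps training linear-time over tens of
    millions of bases.
    """
    span = q_max + 1
    chunks = []
    n_reads = 0
    for read in reads:
        if read.qualities is None:
            raise ValueError(f"read {read.id!r} carries no qualities")
        n_reads += 1
        q = np.asarray(read.qualities, dtype=np.int64)
        if q.min() < q_min or q.max() > q_max:
            raise ValueError(
                f"read {read.id!r}: quality outside [{q_min}, {q_max}]; "
                "pass a wider q_range"
            )
        prev = np.concatenate(([SENTINEL_Q], q[:-1]))
        pos = np.arange(len(q), dtype=np.int64)
        chunks.append((pos * span + prev) * span + q)
    if n_reads == 0:
        raise ValueError("cannot train a quality model on zero reads")
    keys, counts = np.unique(np.concatenate(chunks), return_counts=True)
    transitions: dict[tuple[int, int], dict[int, int]] = {}
    for key, count in zip(keys.tolist(), counts.tolist()):
        q_next = key % span
        key //= span
        q_prev = key % span
        i_prev = key // span
        transitions.setdefault((i_prev, q_prev), {})[q_next] = count
    return QualityMarkovModel(transitions=transitions, q_min=q_min, q_max=q_max)


def sample_quality_string(
    model: QualityMarkovModel,
    length: int,
    rng: np.random.Generator,
) -> list[int]:
    """Sample one quality string of the requested length from the chain.

    Point-mass contexts are emitted without consuming randomness, so a
    deterministic chain reproduces its training string exactly and cheaply.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    model._compile()
    out = [0] * length
    q_prev = SENTINEL_Q
    lookup = model._lookup
    random = rng.random
    for i in range(length):
        vals, cum = lookup(i, q_prev)
        if len(vals) == 1:
            q = int(vals[0])
        else:
            q = int(vals[np.searchsorted(cum, random(), side="right")])
        out[i] = q
        q_prev = q
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_quality_model(path, model: QualityMarkovModel, metadata: Optional[dict] = None) -> None:
    from .io_formats import _atomic_open

    payload = {
        "schema": QUALITY_MODEL_SCHEMA,
        "model": model.to_dict(),
        "metadata": metadata or {},
    }
    with _atomic_open(path) as handle:
        json.dump(payload, handle)
        handle.write("\n")


def load_quality_model(path) -> QualityMarkovModel:
    with open(path) as handle:
        payload = json.load(handle)
    if payload.get("schema") != QUALITY_MODEL_SCHEMA:
        raise ValueError(f"{path}: not a quality model file")
    return QualityMarkovModel.from_dict(payload["model"])


def save_length_model(path, dist: LengthDistribution, metadata: Optional[dict] = None) -> None:
    from .io_formats import _atomic_open

    payload = {
        "schema": LENGTH_MODEL_SCHEMA,
        "pmf": {str(k): v for k, v in sorted(dist.pmf.items())},
        "metadata": metadata or {},
    }
    with _atomic_open(path) as handle:
        json.dump(payload, handle)
        handle.write("\n")


def load_length_model(path) -> LengthDistribution:
    with open(path) as handle:
        payload = json.load(handle)
    if payload.get("schema") != LENGTH_MODEL_SCHEMA:
        raise ValueError(f"{path}: not a length model file")
    return LengthDistribution(pmf={int(k): v for k, v in payload["pmf"].items()})
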
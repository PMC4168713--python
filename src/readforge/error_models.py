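"""Reference-free error-rate and quality-error model estimation.

The estimator exploits *artifactual duplicate reads*: reads that begin at
the same template position and are therefore identical apart from
sequencing errors.  Reads sharing an identical prefix (default 50 bp) are
binned; each bin's consensus stands in for the (unknown) template, and
within-bin disagreement beyond the prefix yields per-position substitution
and insertion/deletion counts without any reference genome.

Raw per-position rates are then smoothed by exponential regression
``rate(i) = alpha * exp(beta * i)`` (log-linear least squares), which also
extrapolates rates to read positions deeper than any bin covers.  Alongside
the rates the estimator records the insertion:deletion split, the
transition:transversion balance of substitutions, and — for the
quality-error model — the mean quality score of erroneous base calls per
position, smoothed by a per-nucleotide quadratic
``q(i) = a_s * i**2 + b_s * i + c_s``.

A lightweight default model is also provided for use without training data:
the per-base error probability is taken directly from the Phred quality of
the simulated position, split equally between substitutions, insertions and
deletions.

Positions are 0-based read coordinates in the raw count arrays and 1-based
in all fitted formulas and reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
from Bio import Align

from .io_formats import SequenceRecord

__all__ = [
    "ModelError",
    "AlignerParams",
    "PrefixBin",
    "BinningResult",
    "RawErrorCounts",
    "ErrorRateModel",
    "QualityErrorModel",
    "bin_by_prefix",
    "consensus",
    "count_errors",
    "fit_exponential",
    "fit_quality_error",
    "fit_error_rate_model",
    "quality_error_observations",
    "default_error_prob",
    "default_class_probs",
    "train_error_model",
    "save_error_model",
    "load_error_model",
    "is_transition",
]

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_CODE["N"] = 4
_BYTE_CODE = np.full(256, 4, dtype=np.uint8)
for _b, _i in _CODE.items():
    _BYTE_CODE[ord(_b)] = _i

_PURINES = frozenset("AG")

DEFAULT_PREFIX_LEN = 50
DEFAULT_MIN_BIN_SIZE = 20


class ModelError(ValueError):
    """Raised when a model cannot be estimated from the given data."""


def is_transition(a: str, b: str) -> bool:
    """True when a<->b is purine<->purine or pyrimidine<->pyrimidine."""
    return (a in _PURINES) == (b in _PURINES)


# ---------------------------------------------------------------------------
# Binning and consensus
# ---------------------------------------------------------------------------

@dataclass
class PrefixBin:
    """Reads sharing an identical prefix, presumed artifactual duplicates."""

    prefix: str
    members: list[SequenceRecord]
    consensus: Optional[str] = None


@dataclass
class BinningResult:
    bins: list[PrefixBin]
    n_reads: int
    n_too_short: int
    n_unbinned: int  # reads in below-threshold prefix groups


def bin_by_prefix(
    reads: Iterable[SequenceRecord],
    prefix_len: int = DEFAULT_PREFIX_LEN,
    min_bin_size: int = DEFAULT_MIN_BIN_SIZE,
) -> BinningResult:
    """Group reads by identical ``prefix_len``-bp prefix.

    Reads shorter than the prefix are skipped and counted.  Only prefix
    groups with at least ``min_bin_size`` members become bins; bins are
    sorted by prefix for determinism.  Zero qualifying bins is fatal —
    the training set then carries no usable duplicate structure.
    """
    if prefix_len < 1:
        raise ValueError(f"prefix_len must be >= 1, got {prefix_len}")
    groups: dict[str, list[SequenceRecord]] = {}
    n_reads = 0
    n_short = 0
    for read in reads:
        n_reads += 1
        if len(read.sequence) < prefix_len:
            n_short += 1
            continue
        groups.setdefault(read.sequence[:prefix_len], []).append(read)
    bins = [
        PrefixBin(prefix=prefix, members=members)
        for prefix, members in sorted(groups.items())
        if len(members) >= min_bin_size
    ]
    n_binned = sum(len(b.members) for b in bins)
    if not bins:
        raise ModelError(
            f"no prefix bin reached min_bin_size={min_bin_size} "
            f"({n_reads} reads, {n_short} shorter than prefix_len={prefix_len}); "
            "the training set lacks artifactual duplicates — lower --min-bin "
            "or supply a larger/rawer read sample"
        )
    return BinningResult(
        bins=bins,
        n_reads=n_reads,
        n_too_short=n_short,
        n_unbinned=n_reads - n_short - n_binned,
    )


def consensus(bin: PrefixBin, members: Optional[Sequence[SequenceRecord]] = None) -> str:
    """Per-column plurality base over the bin members.

    The consensus spans the longest member; at each column only members long
    enough to cover it vote.  Ties break by fixed base order A < C < G < T
    (N loses to any concrete base).  ``members`` restricts the voter set
    (used internally to re-vote without indel-shifted members) but the
    consensus always spans the full bin.
    """
    max_len = max(len(m.sequence) for m in bin.members)
    voters = bin.members if members is None else members
    if not voters:
        voters = bin.members
    counts = np.zeros((max_len, 5), dtype=np.int64)
    for member in voters:
        codes = _encode(member.sequence)
        np.add.at(counts[: len(codes)], (np.arange(len(codes)), codes), 1)
    # argmax over A,C,G,T,N in that order implements the tie-break;
    # columns past every voter fall back to the longest member's base
    best = counts.argmax(axis=1)
    covered = counts.sum(axis=1) > 0
    longest = max(bin.members, key=lambda m: len(m.sequence))
    chars = [
        "ACGTN"[c] if ok else longest.sequence[j]
        for j, (c, ok) in enumerate(zip(best, covered))
    ]
    cons = "".join(chars)
    bin.consensus = cons
    return cons


# ---------------------------------------------------------------------------
# Error counting
# ---------------------------------------------------------------------------

@dataclass
class AlignerParams:
    """Needleman-Wunsch scores for member-vs-consensus alignment."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


@dataclass
class RawErrorCounts:
    """Per-position error tallies pooled over all bins.

    Arrays are indexed by 0-based read position; the second axis, where
    present, is the base in A,C,G,T order.  ``sub_count`` is keyed by the
    erroneous (read) base; ``tmpl_sub_count``/``cov_by_base`` are keyed by
    the consensus (template) base so that conditional per-nucleotide rates
    can be formed.  Prefix positions are excluded by construction.
    """

    sub_count: np.ndarray
    tmpl_sub_count: np.ndarray
    coverage: np.ndarray
    cov_by_base: np.ndarray
    ins_count: np.ndarray
    del_count: np.ndarray
    err_qual_sum: np.ndarray
    err_qual_n: np.ndarray
    transition_count: int = 0
    transversion_count: int = 0
    n_members: int = 0
    prefix_len: int = DEFAULT_PREFIX_LEN

    @property
    def indel_count(self) -> np.ndarray:
        return self.ins_count + self.del_count

    @classmethod
    def empty(cls, length: int, prefix_len: int) -> "RawErrorCounts":
        return cls(
            sub_count=np.zeros((length, 4), dtype=np.int64),
            tmpl_sub_count=np.zeros((length, 4), dtype=np.int64),
            coverage=np.zeros(length, dtype=np.int64),
            cov_by_base=np.zeros((length, 4), dtype=np.int64),
            ins_count=np.zeros(length, dtype=np.int64),
            del_count=np.zeros(length, dtype=np.int64),
            err_qual_sum=np.zeros((length, 4), dtype=float),
            err_qual_n=np.zeros((length, 4), dtype=np.int64),
            prefix_len=prefix_len,
        )


def count_errors(
    bins: Sequence[PrefixBin],
    aligner_params: Optional[AlignerParams] = None,
    min_column_coverage: int = 5,
) -> RawErrorCounts:
    """Align every bin member to its consensus and tally errors.

    Aligned columns beyond the prefix contribute: a mismatch increments the
    substitution count at that read position for the erroneous (read) base
    and the transition/transversion tally; a gap in the consensus is an
    insertion; a gap in the read is a deletion; coverage is incremented for
    every member base aligned at a position.  The quality score of every
    erroneous base (substituted or inserted) is accumulated for the
    quality-error model.

    Members identical in implied alignment to the diagonal (no indels) are
    counted by direct column comparison; only indel-bearing members incur a
    full Needleman-Wunsch alignment (free end gaps absorb length variation
    among members, which reflects read-length spread, not deletions).

    Within each bin, columns reached by fewer than ``min_column_coverage``
    members are skipped: with so few voters the consensus is not a reliable
    template (a single indel-shifted member can tie or flip the plurality),
    so disagreement there measures consensus noise, not sequencing error.

    The consensus is refined in two passes: members whose best alignment
    needs a gap are identified against the initial all-member consensus,
    and the consensus is then re-voted without them.  An indel early in a
    member shifts all its downstream bases, turning its diagonal votes into
    correlated noise; excluding those voters stops rare plurality flips
    that would charge every correct member with a phantom substitution.
    """
    if not bins:
        raise ValueError("no bins to count errors from")
    params = aligner_params or AlignerParams()
    prefix_len = len(bins[0].prefix)
    max_len = max(max(len(m.sequence) for m in b.members) for b in bins)
    counts = RawErrorCounts.empty(max_len, prefix_len)
    aligner = _make_aligner(params)
    for bin in bins:
        cons = bin.consensus if bin.consensus is not None else consensus(bin)
        clean = [m for m in bin.members if _is_diagonal(m, cons)]
        if len(clean) < len(bin.members):
            cons = consensus(bin, members=clean)
        cons_codes = _encode(cons)
        voters = np.zeros(len(cons), dtype=np.int64)
        for member in bin.members:
            voters[: len(member.sequence)] += 1
        usable = voters >= min_column_coverage
        for member in bin.members:
            counts.n_members += 1
            _count_member(counts, member, cons, cons_codes, prefix_len, aligner, usable)
    return counts


def _is_diagonal(member: SequenceRecord, cons: str) -> bool:
    """True when the member's optimal alignment to the consensus is gap-free."""
    codes = _encode(member.sequence)
    span = _encode(cons)[: len(codes)]
    hamming = int(((codes != span) & (codes < 4) & (span < 4)).sum())
    if hamming == 0:
        return True
    d = edlib.align(member.sequence, cons, mode="SHW", task="distance")["editDistance"]
    return d >= hamming


def _count_member(counts, member, cons, cons_codes, prefix_len, aligner, usable):
    seq = member.sequence
    codes = _encode(seq)
    n = len(codes)
    span = cons_codes[:n]
    mismatch = np.flatnonzero((codes != span) & (codes < 4) & (span < 4))
    mismatch = mismatch[mismatch >= prefix_len]
    if len(mismatch) == 0:
        _add_diagonal(counts, member, codes, span, mismatch, prefix_len, usable)
        return
    # diagonal alignment is optimal iff edit distance equals the hamming
    # distance; otherwise the member carries indels and needs a real DP.
    d = edlib.align(seq, cons, mode="SHW", task="distance")["editDistance"]
    hamming = int(((codes != span) & (codes < 4) & (span < 4)).sum())
    if d >= hamming:
        _add_diagonal(counts, member, codes, span, mismatch, prefix_len, usable)
    else:
        _add_aligned(counts, member, cons, prefix_len, aligner, usable)


def _add_diagonal(counts, member, codes, span, mismatch, prefix_len, usable):
    valid = np.flatnonzero(
        (codes[prefix_len:] < 4) & (span[prefix_len:] < 4) & usable[prefix_len : len(codes)]
    ) + prefix_len
    counts.coverage[valid] += 1
    np.add.at(counts.cov_by_base, (valid, span[valid]), 1)
    if len(mismatch) == 0:
        return
    mismatch = mismatch[usable[mismatch]]
    np.add.at(counts.sub_count, (mismatch, codes[mismatch]), 1)
    np.add.at(counts.tmpl_sub_count, (mismatch, span[mismatch]), 1)
    quals = member.qualities
    for i in mismatch:
        a, b = BASES[span[i]], BASES[codes[i]]
        if is_transition(a, b):
            counts.transition_count += 1
        else:
            counts.transversion_count += 1
        if quals is not None:
            counts.err_qual_sum[i, codes[i]] += quals[i]
            counts.err_qual_n[i, codes[i]] += 1


def _add_aligned(counts, member, cons, prefix_len, aligner, usable):
    alignment = aligner.align(cons, member.sequence)[0]
    tgt, qry = str(alignment[0]), str(alignment[1])
    quals = member.qualities
    n = len(member.sequence)
    pos = 0  # read position
    for tc, qc in zip(tgt, qry):
        if qc == "-":
            # gap in read: a deletion, unless it is a free end gap past the
            # member's last base
            if prefix_len <= pos < n and usable[pos]:
                counts.del_count[pos] += 1
            continue
        if pos >= len(usable) or not usable[pos]:
            pos += 1
            continue
        if tc == "-":
            if pos >= prefix_len and qc != "N":
                counts.ins_count[pos] += 1
                counts.coverage[pos] += 1
                counts.err_qual_sum[pos, _CODE[qc]] += (
                    quals[pos] if quals is not None else 0
                )
                counts.err_qual_n[pos, _CODE[qc]] += quals is not None
        elif pos >= prefix_len and qc != "N" and tc != "N":
            counts.coverage[pos] += 1
            counts.cov_by_base[pos, _CODE[tc]] += 1
            if qc != tc:
                counts.sub_count[pos, _CODE[qc]] += 1
                counts.tmpl_sub_count[pos, _CODE[tc]] += 1
                if is_transition(tc, qc):
                    counts.transition_count += 1
                else:
                    counts.transversion_count += 1
                if quals is not None:
                    counts.err_qual_sum[pos, _CODE[qc]] += quals[pos]
                    counts.err_qual_n[pos, _CODE[qc]] += 1
        pos += 1


def _make_aligner(params: AlignerParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap
    aligner.extend_gap_score = params.gap
    # free right end gaps: members are prefixes of the template of varying
    # length, so trailing length difference is not a deletion
    aligner.open_right_insertion_score = 0
    aligner.extend_right_insertion_score = 0
    aligner.open_right_deletion_score = 0
    aligner.extend_right_deletion_score = 0
    return aligner


def _encode(seq: str) -> np.ndarray:
    return _BYTE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

def fit_exponential(
    points: Sequence[tuple[float, float]],
    weights: Optional[Sequence[float]] = None,
) -> tuple[float, float]:
    """Least-squares fit of ``rate(i) = alpha * exp(beta * i)``.

    The fit is linear in log space: ``ln(rate) = ln(alpha) + beta * i``.
    Zero-rate points are excluded (their log is undefined; a pseudocount
    would bias alpha).  Requires at least 3 positive points.

    ``weights``, when given, are per-point inverse-variance weights for the
    log-rate (for a binomial rate estimate the variance of the log is
    roughly 1/(error count), so the observed counts are the natural
    weights; positions whose rate rests on a couple of events then no
    longer swamp the regression).
    """
    if weights is None:
        weights = [1.0] * len(points)
    if len(weights) != len(points):
        raise ValueError("weights must match points")
    kept = [(x, r, w) for (x, r), w in zip(points, weights) if r > 0 and w > 0]
    if len(kept) < 3:
        raise ModelError(
            f"exponential fit needs >= 3 positive-rate points, got {len(kept)}"
        )
    x = np.array([k[0] for k in kept], dtype=float)
    y = np.log(np.array([k[1] for k in kept], dtype=float))
    w = np.sqrt(np.array([k[2] for k in kept], dtype=float))  # polyfit wants sqrt
    beta, log_alpha = np.polyfit(x, y, 1, w=w)
    return float(np.exp(log_alpha)), float(beta)


@dataclass
class QualityErrorModel:
    """Quadratic position -> quality map for erroneous base calls.

    ``coeffs[s] = (a_s, b_s, c_s)`` so an erroneous call of base s at
    1-based position i receives quality
    ``clamp(round(a_s * i**2 + b_s * i + c_s))``.
    """

    coeffs: dict[str, tuple[float, float, float]]
    q_min: int = 0
    q_max: int = 41

    def predict(self, base: str, position: int) -> int:
        a, b, c = self.coeffs[base]
        q = a * position * position + b * position + c
        return int(min(self.q_max, max(self.q_min, round(q))))

    def to_dict(self) -> dict:
        return {
            "coeffs": {b: list(co) for b, co in self.coeffs.items()},
            "q_min": self.q_min,
            "q_max": self.q_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QualityErrorModel":
        return cls(
            coeffs={b: tuple(co) for b, co in d["coeffs"].items()},
            q_min=d["q_min"],
            q_max=d["q_max"],
        )


def fit_quality_error(
    observations: Sequence[tuple[int, str, float]],
    q_min: int = 0,
    q_max: int = 41,
    min_positions: int = 3,
) -> QualityErrorModel:
    """Per-nucleotide quadratic fit of mean erroneous-call quality vs position.

    ``observations`` are (1-based position, nucleotide, mean quality).  A
    nucleotide observed at fewer than ``min_positions`` distinct positions
    inherits the pooled all-nucleotide fit.  No observations at all is fatal
    (callers fall back to the default error model).
    """
    if not observations:
        raise ModelError("no erroneous-base quality observations to fit")
    pooled_pts = [(p, q) for p, _, q in observations]
    pooled = _polyfit2(pooled_pts)
    coeffs: dict[str, tuple[float, float, float]] = {}
    for base in BASES:
        pts = [(p, q) for p, b, q in observations if b == base]
        if len({p for p, _ in pts}) >= min_positions:
            coeffs[base] = _polyfit2(pts)
        else:
            coeffs[base] = pooled
    return QualityErrorModel(coeffs=coeffs, q_min=q_min, q_max=q_max)


def _polyfit2(points: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    x = np.array([p for p, _ in points], dtype=float)
    y = np.array([q for _, q in points], dtype=float)
    if len({float(v) for v in x}) >= 3:
        a, b, c = np.polyfit(x, y, 2)
    elif len({float(v) for v in x}) == 2:
        b, c = np.polyfit(x, y, 1)
        a = 0.0
    else:
        a, b, c = 0.0, 0.0, float(y.mean())
    return float(a), float(b), float(c)


# ---------------------------------------------------------------------------
# Error-rate model
# ---------------------------------------------------------------------------

@dataclass
class ErrorRateModel:
    """Smoothed per-position error rates driving error injection.

    ``sub_params[b] = (alpha_b, beta_b)`` gives the substitution rate of a
    template base b at 1-based position i as ``alpha_b * exp(beta_b * i)``,
    clamped to [0, 1]; ``sub_pooled`` is the all-base fit, ``indel_params``
    the combined insertion+deletion rate.  ``ins_ratio_by_pos`` holds the
    per-position share of indels that are insertions where enough indels
    were observed; elsewhere ``ins_ratio_global`` applies.  ``titv`` is the
    probability that a substitution is a transition.
    """

    sub_params: dict[str, tuple[float, float]]
    sub_pooled: tuple[float, float]
    indel_params: tuple[float, float]
    ins_ratio_by_pos: dict[int, float] = field(default_factory=dict)
    ins_ratio_global: float = 0.5
    titv: float = 0.5
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def sub_rate(self, base: str, position: int) -> float:
        alpha, beta = self.sub_params[base]
        return float(min(1.0, max(0.0, alpha * np.exp(beta * position))))

    def indel_rate(self, position: int) -> float:
        alpha, beta = self.indel_params
        return float(min(1.0, max(0.0, alpha * np.exp(beta * position))))

    def ins_fraction(self, position: int) -> float:
        return self.ins_ratio_by_pos.get(position, self.ins_ratio_global)

    # vectorised lookups used by the simulator inner loop
    def rate_arrays(self, max_pos: int):
        """(sub[4, max_pos+1], indel[max_pos+1], ins_frac[max_pos+1]) arrays
        indexed by 1-based position (index 0 unused)."""
        key = max_pos
        if key not in self._cache:
            pos = np.arange(max_pos + 1, dtype=float)
            sub = np.empty((4, max_pos + 1))
            for j, b in enumerate(BASES):
                alpha, beta = self.sub_params[b]
                sub[j] = np.clip(alpha * np.exp(beta * pos), 0.0, 1.0)
            ia, ib = self.indel_params
            indel = np.clip(ia * np.exp(ib * pos), 0.0, 1.0)
            frac = np.full(max_pos + 1, self.ins_ratio_global)
            for p, f in self.ins_ratio_by_pos.items():
                if 0 <= p <= max_pos:
                    frac[p] = f
            self._cache[key] = (sub, indel, frac)
        return self._cache[key]

    def to_dict(self) -> dict:
        return {
            "sub_params": {b: list(p) for b, p in self.sub_params.items()},
            "sub_pooled": list(self.sub_pooled),
            "indel_params": list(self.indel_params),
            "ins_ratio_by_pos": {str(k): v for k, v in self.ins_ratio_by_pos.items()},
            "ins_ratio_global": self.ins_ratio_global,
            "titv": self.titv,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ErrorRateModel":
        return cls(
            sub_params={b: tuple(p) for b, p in d["sub_params"].items()},
            sub_pooled=tuple(d["sub_pooled"]),
            indel_params=tuple(d["indel_params"]),
            ins_ratio_by_pos={int(k): v for k, v in d["ins_ratio_by_pos"].items()},
            ins_ratio_global=d["ins_ratio_global"],
            titv=d["titv"],
        )


def fit_error_rate_model(
    counts: RawErrorCounts,
    min_indel_per_pos: int = 10,
    default_ins_fraction: float = 0.5,
    min_fit_coverage: int = 10,
) -> ErrorRateModel:
    """Turn raw tallies into smoothed exponential rate curves.

    Substitution curves are fitted per template nucleotide (rate of a
    miscall given the true base); nucleotides with too few positive-rate
    positions inherit the pooled fit, and if even the pooled exponential is
    unfittable a constant rate (mean of observed) is used.  Positions with
    pooled coverage below ``min_fit_coverage`` contribute no regression
    point (a rate ratioed over a handful of observations is mostly noise
    and, in log space, can dominate the fit).  Regression positions are
    1-based.
    """
    cov_idx = np.flatnonzero(counts.coverage >= min_fit_coverage)
    if len(cov_idx) == 0:
        cov_idx = np.flatnonzero(counts.coverage > 0)
    sub_total = counts.sub_count.sum(axis=1)

    def _points(num, den, idx):
        # (position, rate) plus event-count weights for the log-space fit
        pts = [(int(i) + 1, num[i] / den[i]) for i in idx if den[i] > 0]
        wts = [float(num[i]) for i in idx if den[i] > 0]
        return pts, wts

    pooled_pts, pooled_w = _points(sub_total, counts.coverage, cov_idx)
    sub_pooled = _fit_or_constant(pooled_pts, pooled_w)
    sub_params: dict[str, tuple[float, float]] = {}
    for j, base in enumerate(BASES):
        pts, wts = _points(counts.tmpl_sub_count[:, j], counts.cov_by_base[:, j], cov_idx)
        try:
            sub_params[base] = fit_exponential(pts, wts)
        except ModelError:
            sub_params[base] = sub_pooled

    indel_pts, indel_w = _points(counts.indel_count, counts.coverage, cov_idx)
    indel_params = _fit_or_constant(indel_pts, indel_w)

    trans, tv = counts.transition_count, counts.transversion_count
    titv = trans / (trans + tv) if (trans + tv) > 0 else 0.5

    ins_total = int(counts.ins_count.sum())
    indel_total = int(counts.indel_count.sum())
    global_ratio = ins_total / indel_total if indel_total > 0 else default_ins_fraction
    by_pos = {
        int(i) + 1: counts.ins_count[i] / counts.indel_count[i]
        for i in np.flatnonzero(counts.indel_count >= min_indel_per_pos)
    }
    return ErrorRateModel(
        sub_params=sub_params,
        sub_pooled=sub_pooled,
        indel_params=indel_params,
        ins_ratio_by_pos=by_pos,
        ins_ratio_global=global_ratio,
        titv=titv,
    )


def _fit_or_constant(points, weights=None) -> tuple[float, float]:
    try:
        return fit_exponential(points, weights)
    except ModelError:
        rates = [r for _, r in points]
        return (float(np.mean(rates)) if rates else 0.0, 0.0)


def quality_error_observations(
    counts: RawErrorCounts,
) -> list[tuple[int, str, float]]:
    """(1-based position, base, mean quality) for every erroneous-call cell."""
    obs = []
    idx = np.argwhere(counts.err_qual_n > 0)
    for i, j in idx:
        obs.append(
            (int(i) + 1, BASES[j], float(counts.err_qual_sum[i, j] / counts.err_qual_n[i, j]))
        )
    return obs


# ---------------------------------------------------------------------------
# Lightweight default model
# ---------------------------------------------------------------------------

def default_error_prob(q: float) -> float:
    """Total per-base error probability implied by Phred quality q."""
    if q < 0:
        raise ValueError(f"quality must be >= 0, got {q}")
    return 10.0 ** (-q / 10.0)


def default_class_probs(q: float) -> tuple[float, float, float]:
    """Equal substitution/insertion/deletion split of the Phred error prob."""
    p = default_error_prob(q) / 3.0
    return p, p, p


# ---------------------------------------------------------------------------
# Training glue + serialization
# ---------------------------------------------------------------------------

ERROR_MODEL_SCHEMA = "readforge-error-model/1"


def train_error_model(
    reads: Iterable[SequenceRecord],
    prefix_len: int = DEFAULT_PREFIX_LEN,
    min_bin_size: int = DEFAULT_MIN_BIN_SIZE,
    q_min: int = 0,
    q_max: int = 41,
    aligner_params: Optional[AlignerParams] = None,
) -> tuple[ErrorRateModel, QualityErrorModel, dict]:
    """Full training pipeline: bin, consensus, count, regress.

    Returns the error-rate model, the quality-error model and an info dict
    (read/bin tallies) for logging.  If no erroneous base ever carried a
    quality score the quality-error model degenerates to a constant q_max
    curve (no evidence that errors score lower).
    """
    binning = bin_by_prefix(reads, prefix_len=prefix_len, min_bin_size=min_bin_size)
    for bin in binning.bins:
        consensus(bin)
    counts = count_errors(binning.bins, aligner_params)
    emodel = fit_error_rate_model(counts)
    obs = quality_error_observations(counts)
    try:
        qerr = fit_quality_error(obs, q_min=q_min, q_max=q_max)
    except ModelError:
        qerr = QualityErrorModel(
            coeffs={b: (0.0, 0.0, float(q_max)) for b in BASES},
            q_min=q_min,
            q_max=q_max,
        )
    info = {
        "n_reads": binning.n_reads,
        "n_too_short": binning.n_too_short,
        "n_unbinned": binning.n_unbinned,
        "n_bins": len(binning.bins),
        "n_members": counts.n_members,
        "transition_count": counts.transition_count,
        "transversion_count": counts.transversion_count,
    }
    return emodel, qerr, info


def save_error_model(
    path,
    emodel: ErrorRateModel,
    qerr: QualityErrorModel,
    metadata: Optional[dict] = None,
) -> None:
    from .io_formats import _atomic_open

    payload = {
        "schema": ERROR_MODEL_SCHEMA,
        "error_rate": emodel.to_dict(),
        "quality_error": qerr.to_dict(),
        "metadata": metadata or {},
    }
    with _atomic_open(path) as handle:
        json.dump(payload, handle, indent=1)
        handle.write("\n")


def load_error_model(path) -> tuple[ErrorRateModel, QualityErrorModel, dict]:
    with open(path) as handle:
        payload = json.load(handle)
    if payload.get("schema") != ERROR_MODEL_SCHEMA:
        raise ModelError(
            f"{path}: unexpected schema {payload.get('schema')!r}, "
            f"wanted {ERROR_MODEL_SCHEMA!r}"
        )
    return (
        ErrorRateModel.from_dict(payload["error_rate"]),
        QualityErrorModel.from_dict(payload["quality_error"]),
        payload.get("metadata", {}),
    )
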
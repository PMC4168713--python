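# Methods

`readforge` simulates whole-genome-shotgun sequencing reads whose lengths,
quality strings and errors imitate a user-supplied sample of real reads.
Nothing about the instrument is hard-coded: every distribution is learned
non-parametrically from the training FASTQ, which is what lets the same
code emulate Illumina-like fixed-length runs and Ion Torrent/454-like
runs with long, ragged length distributions and decaying quality tails.

## Models

### Read lengths

The length model is the exact empirical probability mass function of
training read lengths — no smoothing, no parametric family. Simulated
lengths are i.i.d. draws from it. Real instruments can produce multimodal,
skewed length distributions that a normal or uniform fit misrepresents;
the empirical pmf reproduces them by construction. The cost is that
lengths never seen in training are never generated.

### Quality strings

Quality scores follow a position-dependent first-order Markov chain: the
quality at position i is drawn from the empirical conditional distribution
P(q_i | q_{i−1}, i−1), with a sentinel q_0 = 0 so the first position uses
the empirical distribution of first-position qualities. Conditioning on
the previous score captures the run-to-run autocorrelation of quality
traces; conditioning on the position captures the systematic 3′ decay.

Sampling must be total, so unseen contexts fall back in a fixed order:
(same position, marginal over the previous quality) → (nearest smaller
observed position, same previous quality) → global marginal. Positions
and qualities are not binned; with small training sets, deep-position
contexts are sparse and the fallback hierarchy carries them.

### Error rates (reference-free)

Per-position error rates are estimated without any reference genome by
exploiting artifactual duplicate reads: reads sharing an identical 50 bp
prefix (configurable) are binned, each bin's per-column plurality
consensus stands in for the unknown template, and within-bin disagreement
beyond the prefix is tallied as substitutions (by both the erroneous read
base and the consensus base), insertions and deletions. Members whose
best alignment to the consensus is gap-free are counted by direct column
comparison; members carrying indels are globally aligned
(match/mismatch/gap = +1/−1/−2, free right end gaps so that read-length
spread is not charged as deletions).

Two guards keep the estimator unbiased in the presence of indels:

* columns reached by fewer than `min_column_coverage = 5` members in a bin
  are not counted — with 2–4 voters, one indel-shifted member can tie or
  flip the plurality, charging every correct member a phantom
  substitution;
* the consensus is re-voted after excluding indel-bearing members, whose
  diagonal votes downstream of the indel are correlated noise.

Raw per-position rates are smoothed by exponential regression
`rate(i) = alpha·exp(beta·i)`, fitted by least squares in log space with
each point weighted by its error count (≈ the inverse variance of the log
rate). Zero-rate positions are excluded rather than pseudocounted —
a pseudocount would bias alpha — and positions with pooled coverage below
10 contribute no point. The exponential form extrapolates rates to read
positions deeper than any bin covers, where rates typically rise.
Substitution curves are fitted per template nucleotide (probability of a
miscall given the true base), falling back to the pooled curve when a
nucleotide has fewer than three positive-rate positions, and to a constant
(mean observed rate) if even the pooled exponential is unfittable.
Alongside the curves the model stores the transition fraction of
substitutions (ti/tv), and the insertion share of indels — per position
where at least 10 indels were observed, else a global pooled ratio
(default 0.5 when no indels were seen).

### Quality of erroneous calls

Erroneous base calls score systematically lower than correct ones. The
quality-error model records the mean quality of erroneous bases per
(position, nucleotide) during error counting and fits a per-nucleotide
quadratic q(i) = a_s·i² + b_s·i + c_s. Predictions are clamped to the
configured quality range and rounded. Nucleotides observed at fewer than
three distinct positions inherit the pooled all-nucleotide fit. During
simulation this model overrides the Markov-chain quality at substituted
and inserted bases.

### Default error model

Without training data, the per-base error probability is taken directly
from the Phred quality of the position, 10^(−q/10), split equally between
substitution, insertion and deletion; the chain quality is kept for
erroneous bases. This is deliberately crude — it ignores the empirical
excess of indels on some platforms — but is exactly calibrated to the
generated quality string.

### Community composition

Two profile generators. The parametric route assigns the rank-r genome an
abundance proportional to r^(−gamma), with presets gamma = 1.5 (low
complexity: few dominant species), 1.0 (medium) and 0.5 (high: no dominant
species), all user-overridable; these defaults are this package's choice
of a plausible rank-abundance decay, not fitted constants. The homology
route consumes a pre-computed hit table (query, bit score, root-first
lineage): per query, hits scoring at least `neighborhood` (default 0.9) of
that query's best bit score are kept, the assignment is the lowest common
ancestor (longest common prefix) of the kept lineages, and species-level
assignments (lineage deeper than rank index 6, or a terminal `s__` tag)
are counted into the profile; shallower assignments are dropped and the
drop count reported. Whether "neighborhood" should be a fraction or an
absolute bit-score delta is a genuinely open choice; fraction was chosen
and is a flag.

## Simulation

Reads are produced in two stages. A raw read of uniform intermediate
length (default: the length model's support maximum) is sampled — genome
by abundance, start uniform over valid positions, strand equiprobable,
reads overlapping N resampled up to a retry bound. The raw read is then
realized: trimmed from the 3′ end to a length drawn from the length model
(3′ trimming keeps the 5′ end, matching where sequencers degrade), given
a Markov quality string, and walked position by position. At 1-based
position i with current template base b, a substitution occurs with
probability rate_b(i); otherwise an indel with the combined indel rate,
split by the insertion fraction. Substitution targets are the transition
partner with probability ti/tv, else one of the two transversions
equiprobably. Insertions add a uniform random base without consuming
template; deletions skip a template base and consume further template so
the read keeps its sampled length — the length distribution is a trained
model, not a side effect of the error process. If the template runs out
(only possible when the raw read had no slack), the read is shortened and
the final deletion is recorded one past the read end. Every event is
recorded as (read position, kind, from-base, to-base), making the ground
truth exact: undoing the events reproduces the oriented genome slice
byte for byte, which the test suite asserts for every simulated read.

Paired-end mode draws a fragment length from Normal(insert mean, sd)
(defaults 500/50), clamped to [uniform length, genome length]; mate 1
reads inward from the fragment 5′ end on the fragment strand, mate 2 from
the 3′ end on the opposite strand.

All randomness flows through a single NumPy generator in a fixed draw
order (genome, start, strand; then per-read length, qualities, error
walk), so datasets are byte-reproducible from a seed.

## Synthetic data generator

The fixture generator emulates the *training inputs*: uniform-random
genomes; a training FASTQ whose lengths follow a chosen pmf and whose
qualities follow an explicit drifting Markov chain; duplicate-read groups
(default: half the reads, in groups of 25 sharing an error-free 50 bp
prefix) with substitutions and indels planted at known exponential rates
beyond the prefix; and hit tables with known intended LCA outcomes.
Planted truth is returned and serializable alongside the data.

What it does not emulate, and hence what passing tests do not show:
genome base composition bias (fixture genomes are i.i.d. uniform — the
models are composition-agnostic except ti/tv, which the planted
substitution classes exercise directly), homopolymer-specific indel
processes, GC bias, chimeras, and quality–error coupling in the training
data (planted errors carry chain qualities). Closure and recovery results
on fixtures demonstrate estimator correctness, not fidelity to any
particular instrument.

## Numerical and test choices

* Quality range defaults to [0, 41]; Phred+33 encoding by default with
  +64 behind a flag.
* Consensus ties break by fixed base order A < C < G < T; N loses to any
  concrete base.
* Binomial/Poisson acceptance bands are 99% intervals at the stated n.
  Per-position 3-SE recovery checks allow up to 3 excursions across the
  ~70 checked positions: at 3 SE, chance alone produces occasional
  excursions (expected ~0.2 per run), while four or more would be
  evidence of bias (probability < 1e-4 under an unbiased estimator).
  The smoothed rate curve must sit inside the per-position 3-SE band
  everywhere and within 15% of the planted curve.
* Markov-closure TV comparisons use contexts with ≥500 observations on
  both the training and resample sides; one-sided filtering leaves the
  comparison dominated by estimation noise rather than model mismatch.
* Problem sizes: estimator-recovery fixtures use 20,000 training reads
  (~800 duplicate bins); quality-model closure trains on 10,000 reads and
  resamples 100,000 strings; the end-to-end closure simulates 100,000
  reads from a 400 bp genome (short on purpose, so simulated reads form
  duplicate bins and the error model can be retrained reference-free);
  calibration checks use 10^5 bases (trained model) and 10^7 bases
  (default model). The acceptance script uses 50,000 strings and 2×10^6
  bases for the same measurements.

## Known limitations

* The error estimator needs artifactual duplicates; libraries that were
  deduplicated upstream cannot be trained on (the binning step fails with
  guidance rather than returning a vacuous model).
* Exponential extrapolation beyond the deepest covered position is an
  assumption; real tail behavior may differ.
* ti/tv is a single global ratio, not position-dependent.
* Lengths are sampled independently of genome and quality; any real
  correlation between read length and quality decay is not reproduced.
* Indel placement within homopolymers is ambiguous; counts are assigned
  at the alignment's chosen column (substitutions preferred over gaps on
  ties), which can smear per-position indel rates by ±1 position.
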
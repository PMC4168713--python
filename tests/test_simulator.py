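import numpy as np
import pytest

from conftest import reconstruct_template
from readforge import (
    AbundanceProfile,
    ErrorRateModel,
    QualityErrorModel,
    SequenceRecord,
    SimulationConfig,
    SimulationError,
)
from readforge import quality_length_models as qlm
from readforge import simulator as sim
from readforge.error_models import BASES


def flat_error_model(sub=0.0, indel=0.0, titv=0.5, ins_fraction=0.5):
    return ErrorRateModel(
        sub_params={b: (sub, 0.0) for b in BASES},
        sub_pooled=(sub, 0.0),
        indel_params=(indel, 0.0),
        ins_ratio_global=ins_fraction,
        titv=titv,
    )


def flat_quality_error(q=12):
    return QualityErrorModel(coeffs={b: (0.0, 0.0, float(q)) for b in BASES})


def flat_qmodel(q=38, max_len=300):
    # a chain that deterministically emits q everywhere
    transitions = {(0, 0): {q: 10}}
    for i in range(max_len):
        transitions[(i, q)] = {q: 10}
    return qlm.QualityMarkovModel(transitions=transitions)


def random_genome(rng, n, gid="g1"):
    return SequenceRecord(id=gid, sequence="".join("ACGT"[b] for b in rng.integers(0, 4, n)))


class TestSampleRawRead:
    def test_start_positions_uniform(self):
        rng = np.random.default_rng(0)
        genome = random_genome(rng, 1000)
        profile = AbundanceProfile(entries=[("g1", 1.0)])
        starts = [
            sim.sample_raw_read([genome], profile, 400, rng).start
            for _ in range(10_000)
        ]
        # uniform on [0, 600]: 99% CI for the mean at n=10,000
        assert abs(np.mean(starts) - 300) < 2.576 * (600 / np.sqrt(12)) / 100

    def test_abundance_respected(self):
        rng = np.random.default_rng(1)
        db = [random_genome(rng, 2000, "A"), random_genome(rng, 2000, "B")]
        profile = AbundanceProfile(entries=[("A", 0.75), ("B", 0.25)])
        n_a = sum(
            sim.sample_raw_read(db, profile, 100, rng).genome_id == "A"
            for _ in range(10_000)
        )
        assert 7388 <= n_a <= 7612  # 99% binomial CI

    def test_short_genome_caps_read(self):
        rng = np.random.default_rng(2)
        genome = random_genome(rng, 120)
        profile = AbundanceProfile(entries=[("g1", 1.0)])
        read = sim.sample_raw_read([genome], profile, 400, rng)
        assert len(read.sequence) == 120
        assert (read.start, read.end) == (0, 120)

    def test_missing_genome_fatal(self):
        rng = np.random.default_rng(3)
        genome = random_genome(rng, 100)
        profile = AbundanceProfile(entries=[("nope", 1.0)])
        with pytest.raises(SimulationError, match="nope"):
            sim.sample_raw_read([genome], profile, 50, rng)

    def test_minus_strand_is_reverse_complement(self):
        rng = np.random.default_rng(4)
        genome = random_genome(rng, 300)
        profile = AbundanceProfile(entries=[("g1", 1.0)])
        for _ in range(20):
            read = sim.sample_raw_read([genome], profile, 80, rng)
            slice_ = genome.sequence[read.start : read.end]
            expected = slice_ if read.strand == "+" else sim.reverse_complement(slice_)
            assert read.sequence == expected


class TestRealizeRead:
    def _raw(self, rng, glen=500, ulen=200):
        genome = random_genome(rng, glen)
        profile = AbundanceProfile(entries=[("g1", 1.0)])
        return genome, sim.sample_raw_read([genome], profile, ulen, rng)

    def test_null_error_model_is_identity(self):
        rng = np.random.default_rng(5)
        genome, raw = self._raw(rng)
        lengths = qlm.LengthDistribution(pmf={150: 1.0})
        read = sim.realize_read(
            raw, lengths, flat_qmodel(), flat_error_model(), flat_quality_error(), rng
        )
        assert read.events == []
        assert read.sequence == raw.sequence[:150]
        assert read.qualities == [38] * 150
        slice_ = genome.sequence[read.start : read.end]
        oriented = slice_ if read.strand == "+" else sim.reverse_complement(slice_)
        assert read.sequence == oriented

    def test_forced_substitution_transition_and_quality_override(self):
        rng = np.random.default_rng(6)
        _, raw = self._raw(rng)
        lengths = qlm.LengthDistribution(pmf={100: 1.0})
        read = sim.realize_read(
            raw, lengths, flat_qmodel(),
            flat_error_model(sub=1.0, titv=1.0),  # every base substitutes
            flat_quality_error(q=12), rng,
        )
        assert read.n_sub == 100
        trans = {"A": "G", "G": "A", "C": "T", "T": "C"}
        for (pos, kind, fb, tb), ch, q in zip(read.events, read.sequence, read.qualities):
            assert kind == "sub"
            assert tb == trans[fb]  # titv=1: always the transition partner
            assert ch == tb
            assert q == 12  # overridden by the quality-error model

    def test_deletions_preserve_target_length(self):
        rng = np.random.default_rng(7)
        _, raw = self._raw(rng, ulen=200)
        lengths = qlm.LengthDistribution(pmf={120: 1.0})
        read = sim.realize_read(
            raw, lengths, flat_qmodel(),
            flat_error_model(indel=0.05, ins_fraction=0.0),
            flat_quality_error(), rng,
        )
        assert len(read.sequence) == 120
        assert read.n_del > 0
        # consumed template = emitted bases + deletions
        assert read.end - read.start == 120 + read.n_del

    def test_calibrated_substitution_rate(self):
        rng = np.random.default_rng(8)
        genome = random_genome(rng, 5000)
        profile = AbundanceProfile(entries=[("g1", 1.0)])
        lengths = qlm.LengthDistribution(pmf={100: 1.0})
        emodel = flat_error_model(sub=0.01)
        total = subs = 0
        for _ in range(1000):
            raw = sim.sample_raw_read([genome], profile, 100, rng)
            read = sim.realize_read(
                raw, lengths, flat_qmodel(), emodel, flat_quality_error(), rng
            )
            total += len(read.sequence)
            subs += read.n_sub
        p = subs / total  # 100,000 bases
        assert abs(p - 0.01) < 2.576 * np.sqrt(0.01 * 0.99 / total)

    def test_round_trip_conservation(self):
        rng = np.random.default_rng(9)
        genome = random_genome(rng, 2000)
        profile = AbundanceProfile(entries=[("g1", 1.0)])
        lengths = qlm.LengthDistribution(pmf={90: 0.5, 130: 0.5})
        emodel = flat_error_model(sub=0.01, indel=0.01)
        for _ in range(300):
            raw = sim.sample_raw_read([genome], profile, 150, rng)
            read = sim.realize_read(
                raw, lengths, flat_qmodel(), emodel, flat_quality_error(), rng
            )
            slice_ = genome.sequence[read.start : read.end]
            oriented = slice_ if read.strand == "+" else sim.reverse_complement(slice_)
            assert reconstruct_template(read) == oriented


class TestGeneratePair:
    def test_error_free_pair_coordinates(self):
        rng = np.random.default_rng(10)
        genome = random_genome(rng, 3000)
        profile = AbundanceProfile(entries=[("g1", 1.0)])
        lengths = qlm.LengthDistribution(pmf={100: 1.0})
        config = SimulationConfig(
            n_reads=2, paired=True, insert_mean=500, insert_sd=0
        )
        for _ in range(20):
            r1, r2 = sim.generate_pair(
                [genome], profile, config, lengths, flat_qmodel(),
                flat_error_model(), flat_quality_error(), rng, uniform_len=100,
            )
            assert {r1.strand, r2.strand} == {"+", "-"}
            fwd, rev = (r1, r2) if r1.strand == "+" else (r2, r1)
            # insert_sd=0: fragment exactly 500
            assert rev.end - fwd.start == 500
            assert fwd.sequence == genome.sequence[fwd.start : fwd.end]
            assert rev.sequence == sim.reverse_complement(
                genome.sequence[rev.start : rev.end]
            )

    def test_too_short_genomes_fatal(self):
        rng = np.random.default_rng(11)
        genome = random_genome(rng, 60)
        profile = AbundanceProfile(entries=[("g1", 1.0)])
        lengths = qlm.LengthDistribution(pmf={100: 1.0})
        config = SimulationConfig(n_reads=2, paired=True, max_retries=3)
        with pytest.raises(SimulationError):
            sim.generate_pair(
                [genome], profile, config, lengths, flat_qmodel(),
                flat_error_model(), flat_quality_error(), rng, uniform_len=100,
            )


class TestGenerateDataset:
    def test_same_seed_byte_identical(self, tmp_path):
        rng = np.random.default_rng(12)
        db = [random_genome(rng, 1000, "A"), random_genome(rng, 1000, "B")]
        profile = AbundanceProfile(entries=[("A", 0.6), ("B", 0.4)])
        lengths = qlm.LengthDistribution(pmf={80: 0.5, 100: 0.5})
        outputs = []
        for run in ("x", "y"):
            config = SimulationConfig(n_reads=100, seed=42)
            paths = sim.generate_dataset(
                db, profile, config, lengths, flat_qmodel(),
                flat_error_model(sub=0.02, indel=0.01), flat_quality_error(),
                out_prefix=str(tmp_path / run),
            )
            outputs.append(
                (open(paths["fastq"]).read(), open(paths["truth"]).read())
            )
        assert outputs[0][0] == outputs[1][0]
        assert outputs[0][1] == outputs[1][1]

    def test_truth_counts_match_abundance(self, tmp_path):
        rng = np.random.default_rng(13)
        db = [random_genome(rng, 1500, "A"), random_genome(rng, 1500, "B")]
        profile = AbundanceProfile(entries=[("A", 0.75), ("B", 0.25)])
        lengths = qlm.LengthDistribution(pmf={80: 1.0})
        config = SimulationConfig(n_reads=10_000, seed=5)
        reads = list(
            sim.simulate_reads(
                db, profile, config, lengths, flat_qmodel(),
                flat_error_model(), flat_quality_error(),
            )
        )
        n_a = sum(r.genome_id == "A" for r in reads)
        assert 7388 <= n_a <= 7612  # 99% binomial CI around 7500


class TestClosure:
    """Train on synthetic reads, simulate, retrain on the simulation: the
    retrained models must match the generating ones (the natural check for
    a trained simulator)."""

    def test_end_to_end_model_recovery(self):
        from readforge import error_models as em

        gen_sub = (0.004, 0.012)
        rng = np.random.default_rng(20)
        genome = random_genome(rng, 400)
        profile = AbundanceProfile(entries=[("g1", 1.0)])
        lengths = qlm.LengthDistribution(pmf={110: 0.3, 140: 0.4, 160: 0.3})
        # quality chain with genuine position-dependent drift
        from readforge.fixtures import FixtureSpec, make_training_reads

        spec = FixtureSpec(
            n_reads=1500, seed=21, length_pmf={110: 0.3, 140: 0.4, 160: 0.3},
            planted_sub=(0.0, 0.0), planted_indel=(0.0, 0.0),
        )
        train_reads, _ = make_training_reads(spec, np.random.default_rng(21))
        qmodel = qlm.train_quality_markov(train_reads)
        emodel = ErrorRateModel(
            sub_params={b: gen_sub for b in BASES},
            sub_pooled=gen_sub,
            indel_params=(0.0, 0.0),
            titv=0.5,
        )
        config = SimulationConfig(n_reads=100_000, seed=22)
        reads = [
            SequenceRecord(id=r.id, sequence=r.sequence, qualities=r.qualities)
            for r in sim.simulate_reads(
                [genome], profile, config, lengths, qmodel, emodel,
                flat_quality_error(q=15),
            )
        ]
        # length closure: TV distance between pmfs
        dist2 = qlm.train_length_distribution(reads)
        tv = 0.5 * sum(
            abs(lengths.pmf.get(k, 0) - dist2.pmf.get(k, 0))
            for k in set(lengths.pmf) | set(dist2.pmf)
        )
        assert tv <= 0.02
        # per-position mean quality within 1 Phred unit
        qm2 = qlm.train_quality_markov(reads)
        for i in range(0, 160, 10):
            m1 = _mean_next_quality(qmodel, i)
            m2 = _mean_next_quality(qm2, i)
            if m1 is not None and m2 is not None:
                assert abs(m1 - m2) <= 1.0
        # substitution-curve closure via duplicate-read retraining
        binning = em.bin_by_prefix(reads)
        counts = em.count_errors(binning.bins)
        refit = em.fit_error_rate_model(counts)
        assert abs(refit.sub_pooled[0] / gen_sub[0] - 1) < 0.15
        assert abs(refit.sub_pooled[1] / gen_sub[1] - 1) < 0.15


def _mean_next_quality(model, i_prev):
    tables = [
        t for (i, _), t in model.transitions.items() if i == i_prev
    ]
    total = sum(sum(t.values()) for t in tables)
    if total < 1000:
        return None
    return (
        sum(q * c for t in tables for q, c in t.items()) / total
    )
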
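import numpy as np
import pytest

from readforge import error_models as em
from readforge.io_formats import SequenceRecord


def rec(i, seq, q=30):
    return SequenceRecord(id=f"r{i}", sequence=seq, qualities=[q] * len(seq))


def random_seq(rng, n):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=n))


class TestBinByPrefix:
    def test_threshold_counting(self):
        rng = np.random.default_rng(0)
        prefix = random_seq(rng, 50)
        reads = [rec(i, prefix + random_seq(rng, 30)) for i in range(25)]
        reads += [rec(100 + i, random_seq(rng, 80)) for i in range(5)]
        result = em.bin_by_prefix(reads, min_bin_size=20)
        assert len(result.bins) == 1
        assert len(result.bins[0].members) == 25

    def test_min_bin_boundary(self):
        rng = np.random.default_rng(1)
        p, q = random_seq(rng, 50), random_seq(rng, 50)
        reads = [rec(0, p + "A"), rec(1, p + "C"), rec(2, q + "G")]
        result = em.bin_by_prefix(reads, min_bin_size=2)
        assert len(result.bins) == 1
        assert result.bins[0].prefix == min(p, q, key=lambda s: (s != p, s))
        assert result.bins[0].prefix == p
        assert len(result.bins[0].members) == 2

    def test_all_too_short_fatal_with_count(self):
        reads = [rec(i, "ACGT" * 10) for i in range(40)]  # length 40 < 50
        with pytest.raises(em.ModelError, match="40"):
            em.bin_by_prefix(reads, prefix_len=50)


class TestConsensus:
    def _bin(self, seqs):
        return em.PrefixBin(prefix=seqs[0][:50], members=[rec(i, s) for i, s in enumerate(seqs)])

    def test_unanimous(self):
        rng = np.random.default_rng(2)
        s = random_seq(rng, 80)
        assert em.consensus(self._bin([s] * 20)) == s

    def test_majority_wins(self):
        rng = np.random.default_rng(3)
        s = random_seq(rng, 80)
        s = s[:60] + "A" + s[61:]
        variant = s[:60] + "G" + s[61:]
        cons = em.consensus(self._bin([s] * 20 + [variant]))
        assert cons[60] == "A"

    def test_tie_breaks_alphabetically(self):
        rng = np.random.default_rng(4)
        base = random_seq(rng, 60)
        seqs = [base[:55] + c + base[56:] for c in "AACC"]
        assert em.consensus(self._bin(seqs))[55] == "A"


class TestCountErrors:
    def _make_bin(self, rng, n=21, length=100):
        tpl = random_seq(rng, length)
        members = [rec(i, tpl) for i in range(n)]
        return tpl, members

    def test_single_substitution_counted(self):
        rng = np.random.default_rng(5)
        tpl, members = self._make_bin(rng)
        tpl60 = "A"
        tpl = tpl[:60] + tpl60 + tpl[61:]
        members = [rec(i, tpl) for i in range(20)]
        mutated = tpl[:60] + "G" + tpl[61:]
        members.append(rec(20, mutated, q=17))
        bin = em.PrefixBin(prefix=tpl[:50], members=members)
        counts = em.count_errors([bin])
        g = em.BASES.index("G")
        assert counts.sub_count[60][g] == 1
        assert counts.coverage[60] == 21
        assert counts.sub_count.sum() == 1
        # A->G is a transition
        assert counts.transition_count == 1
        assert counts.transversion_count == 0
        # the erroneous base's quality is recorded for the quality-error fit
        assert counts.err_qual_n[60][g] == 1
        assert counts.err_qual_sum[60][g] == 17

    def test_single_deletion_counted(self):
        rng = np.random.default_rng(6)
        tpl = random_seq(rng, 100)
        # make the deletion locally unambiguous
        tpl = tpl[:69] + "ACG" + tpl[72:]
        members = [rec(i, tpl) for i in range(20)]
        members.append(rec(20, tpl[:70] + tpl[71:]))
        bin = em.PrefixBin(prefix=tpl[:50], members=members)
        counts = em.count_errors([bin])
        assert counts.del_count[70] == 1
        assert counts.del_count.sum() == 1
        assert counts.ins_count.sum() == 0
        assert counts.sub_count.sum() == 0

    def test_single_insertion_counted(self):
        rng = np.random.default_rng(7)
        tpl = random_seq(rng, 100)
        tpl = tpl[:69] + "ACG" + tpl[72:]
        members = [rec(i, tpl) for i in range(20)]
        members.append(rec(20, tpl[:70] + "T" + tpl[70:]))
        bin = em.PrefixBin(prefix=tpl[:50], members=members)
        counts = em.count_errors([bin])
        assert counts.ins_count.sum() == 1
        assert counts.del_count.sum() == 0
        assert counts.indel_count.sum() == 1


class TestFitExponential:
    def test_noiseless_data_recovered_exactly(self):
        pts = [(i, 0.002 * np.exp(0.015 * i)) for i in range(1, 101)]
        alpha, beta = em.fit_exponential(pts)
        assert alpha == pytest.approx(0.002, abs=1e-9)
        assert beta == pytest.approx(0.015, abs=1e-9)

    def test_constant_rate_gives_zero_slope(self):
        alpha, beta = em.fit_exponential([(i, 0.01) for i in range(1, 50)])
        assert alpha == pytest.approx(0.01, abs=1e-9)
        assert beta == pytest.approx(0.0, abs=1e-9)

    def test_too_few_positive_points(self):
        with pytest.raises(em.ModelError):
            em.fit_exponential([(1, 0.1), (2, 0.2), (3, 0.0), (4, 0.0)])


class TestFitQualityError:
    def test_noiseless_quadratic_recovered(self):
        obs = [(i, "G", -0.0002 * i * i + 0.01 * i + 38) for i in range(1, 100)]
        model = em.fit_quality_error(obs)
        a, b, c = model.coeffs["G"]
        assert a == pytest.approx(-0.0002, abs=1e-9)
        assert b == pytest.approx(0.01, abs=1e-9)
        assert c == pytest.approx(38, abs=1e-9)

    def test_prediction_clamped_to_range(self):
        model = em.QualityErrorModel(
            coeffs={b: (0.0, 0.1, 40.0) for b in em.BASES}, q_min=0, q_max=41
        )
        assert model.predict("A", 57) == 41  # 0.1*57 + 40 = 45.7 clamps

    def test_sparse_base_inherits_pooled_fit(self):
        obs = [(i, "A", 30.0 + i) for i in range(1, 20)]
        obs += [(1, "T", 10.0), (2, "T", 12.0)]  # only 2 positions for T
        model = em.fit_quality_error(obs)
        assert model.coeffs["T"] == model.coeffs["C"]  # both fall back to pooled

    def test_no_observations_fatal(self):
        with pytest.raises(em.ModelError):
            em.fit_quality_error([])


@pytest.mark.parametrize("q,total", [(10, 0.1), (0, 1.0), (30, 0.001)])
def test_default_error_prob_is_phred(q, total):
    assert em.default_error_prob(q) == pytest.approx(total)
    assert em.default_class_probs(q)[0] == pytest.approx(total / 3)


class TestPlantedRateRecovery:
    """Estimator consistency on synthetic duplicate bins with a known
    planted substitution rate: within-bin disagreement, pooled over bins,
    must recover the planted rate position by position."""

    def test_constant_rate_within_three_se(self):
        rng = np.random.default_rng(12)
        rate = 0.008
        bins = []
        for _ in range(40):
            tpl = random_seq(rng, 100)
            members = []
            for i in range(30):
                bases = list(tpl)
                for pos in range(50, 100):
                    if rng.random() < rate:
                        bases[pos] = "ACGT"[
                            ("ACGT".index(bases[pos]) + 1 + int(rng.integers(0, 3))) % 4
                        ]
                members.append(rec(i, "".join(bases)))
            bins.append(em.PrefixBin(prefix=tpl[:50], members=members))
        counts = em.count_errors(bins)
        cov = counts.coverage[50:100]
        sub = counts.sub_count.sum(axis=1)[50:100]
        assert (cov == 1200).all()
        se = np.sqrt(rate * (1 - rate) / cov)
        z = np.abs(sub / cov - rate) / se
        # individual positions fluctuate; demand no more violations of the
        # 3-SE band than chance plausibly allows across 50 positions
        assert (z > 3).sum() <= 2
        assert abs(sub.sum() / cov.sum() - rate) < 3 * np.sqrt(
            rate * (1 - rate) / cov.sum()
        )
        model = em.fit_error_rate_model(counts)
        pos = np.arange(51, 101)
        curve = model.sub_pooled[0] * np.exp(model.sub_pooled[1] * pos)
        assert np.abs(curve / rate - 1).max() < 0.15
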
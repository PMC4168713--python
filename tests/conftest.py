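import numpy as np
import pytest

from readforge import FixtureSpec, make_genomes, make_training_reads


@pytest.fixture(scope="session")
def small_fixture():
    """A modest training corpus with planted constant error rates."""
    spec = FixtureSpec(n_reads=2000, seed=11)
    rng = np.random.default_rng(spec.seed)
    genomes = make_genomes(spec, rng)
    reads, truth = make_training_reads(spec, rng)
    return spec, genomes, reads, truth


def reconstruct_template(read):
    """Undo a simulated read's recorded events, recovering the oriented
    genome slice it was drawn from (the round-trip oracle)."""
    dels = {}
    subs = {}
    inss = set()
    for pos, kind, from_base, to_base in read.events:
        if kind == "del":
            dels.setdefault(pos, []).append(from_base)
        elif kind == "sub":
            subs[pos] = from_base
        else:
            inss.add(pos)
    out = []
    for i, ch in enumerate(read.sequence):
        out.extend(dels.get(i, []))
        if i in inss:
            continue
        out.append(subs.get(i, ch))
    # deletions that exhausted the template are recorded one past the end
    out.extend(dels.get(len(read.sequence), []))
    return "".join(out)
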
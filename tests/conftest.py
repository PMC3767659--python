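import numpy as np
import pytest

from nestkin import simulate as sim


@pytest.fixture(scope="session")
def panel7():
    """Seven microsatellite-like loci with 4-13 alleles each."""
    return sim.make_locus_panel(7, (4, 13), seed=1)


@pytest.fixture(scope="session")
def study_colonies(panel7):
    """40 monogynous colonies with mixed paternity, hidden truth attached."""
    rng = np.random.default_rng(11)
    kdist = [1] + [2] * 5 + [3] * 8 + [4] * 4 + [5] * 3
    colonies = []
    for i in range(40):
        k = int(rng.choice(kdist))
        counts = rng.multinomial(20 - k, np.ones(k) / k) + 1
        spec = sim.ColonySpec(n_workers=20, contributions=tuple(int(c) for c in counts))
        colonies.append(
            sim.simulate_colony(panel7, spec, seed=int(rng.integers(2**31)),
                                colony_id=f"N{i + 1:03d}")
        )
    return colonies


def multinomial_colony_spec(rng, n_workers, shares, **kwargs):
    """ColonySpec with father counts drawn iid per offspring (multinomial).

    With iid assignment the probability two nestmates share a father equals
    sum(shares^2) exactly, which the closed-form relatedness expectations
    assume.
    """
    counts = rng.multinomial(n_workers + kwargs.get("n_alate_females", 0),
                             np.asarray(shares, dtype=float))
    counts = tuple(int(c) for c in counts if c > 0)
    return sim.ColonySpec(n_workers=n_workers, contributions=counts, **kwargs)
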
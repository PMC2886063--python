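import numpy as np
import pytest

from paralogpace.synthetic_data import TrioSimConfig, simulate_trio_set


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_trio_set():
    """20 simulated trios under the recovery-test branch parameters."""
    cfg = TrioSimConfig(
        n_trios=20, n_codons=300,
        branch_dS={"OA": 0.09, "OB": 0.09, "OC": 0.32},
        branch_omega={"OA": 0.08, "OB": 0.21, "OC": 0.09},
        seed=42,
    )
    trios, truth = simulate_trio_set(cfg)
    return cfg, trios, truth


def random_codon_seq(rng, n_codons, no_stop=True):
    from paralogpace._codon_tables import SENSE_CODONS, ALL_CODONS
    pool = SENSE_CODONS if no_stop else tuple(ALL_CODONS)
    return "".join(rng.choice(pool, size=n_codons))


def diverged_pair(rng, n_codons, n_mut):
    """A sense-codon sequence and a copy carrying n_mut random single-base
    changes that keep every codon sense (moderate, unsaturated divergence)."""
    from paralogpace._codon_tables import CODON_INDEX
    s1 = random_codon_seq(rng, n_codons)
    s = list(s1)
    done = 0
    while done < n_mut:
        i = int(rng.integers(len(s)))
        old = s[i]
        s[i] = str(rng.choice([b for b in "ACGT" if b != old]))
        start = 3 * (i // 3)
        if "".join(s[start:start + 3]) in CODON_INDEX:
            done += 1
        else:
            s[i] = old
    return s1, "".join(s)
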
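import numpy as np
import pytest

from latentscan.sequence import NucleotideSequence, from_codes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_seq(residues: str, id: str = "test") -> NucleotideSequence:
    return NucleotideSequence(id, residues)


@pytest.fixture
def latent_array_factory():
    """Tandem array of a random unit, degraded by substitutions and indels."""

    def factory(period, copies, subs_rate=1.0, indel_rate=0.05, seed=0):
        from latentscan.simulate import ImplantSpec, random_consensus, _mutate_array

        rng = np.random.default_rng(seed)
        spec = ImplantSpec(
            consensus=random_consensus(period, rng),
            copies=copies,
            substitution_rate=subs_rate,
            indel_rate=indel_rate,
            background_length=period * copies + 10,
            seed=seed,
        )
        arr, *_ = _mutate_array(spec, np.random.default_rng(seed + 1))
        return from_codes(arr, id=f"p{period}s{seed}")

    return factory
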
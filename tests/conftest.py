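import numpy as np
import pytest

from mippi.records import ImpactLabel, MutationEvent
from mippi.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_event(
    event_id="e1",
    seq="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQ",
    position=10,
    alt_aa="A",
    partner="MSERADLVFFHGGNASTWLWRSLLPYMEAAGYRCIAPDLPGHGDSAG",
    label=ImpactLabel.DECREASING,
    **kwargs,
):
    return MutationEvent(
        event_id=event_id,
        mut_protein_id=f"mp-{event_id}",
        mut_protein_seq=seq,
        position=position,
        ref_aa=seq[position - 1],
        alt_aa=alt_aa,
        partner_id=f"pp-{event_id}",
        partner_seq=partner,
        label=label,
        **kwargs,
    )


@pytest.fixture
def simple_event():
    return make_event()


@pytest.fixture(scope="session")
def small_dataset():
    events, truths = generate_dataset(GeneratorConfig(n_events=60, seed=21))
    return events, truths


@pytest.fixture(scope="session")
def tiny_model():
    """A deliberately small model reused by structural tests."""
    from mippi.network import MIPPIModel, ModelConfig

    cfg = ModelConfig(
        d_model=32, d_embed=8, n_heads=4, ffn_width=32,
        n_encoder_blocks_per_branch=1, resblock_filters=32,
        partner_len=128, dropout=0.1, seed=7,
    )
    return MIPPIModel(cfg)
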
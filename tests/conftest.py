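import pytest

from trialchain import trial_simulator
from trialchain.core_ledger import Chain, append_transaction
from trialchain.trial_simulator import TRIAL_START


@pytest.fixture
def default_scenario():
    return trial_simulator.generate_trial_fixture()


@pytest.fixture
def replayed_chain(default_scenario, tmp_path):
    """Default 4-subject trial replayed onto a temporary store."""
    return trial_simulator.replay(default_scenario, tmp_path / "chain.jsonl")


@pytest.fixture
def make_chain(tmp_path):
    """Factory for plain chains of n generated transactions."""

    def _make(n_blocks: int, payload_size: int = 64, store_name: str | None = None):
        store = tmp_path / store_name if store_name else None
        chain = Chain.initialize("TRIAL-TEST", TRIAL_START, store)
        for i in range(n_blocks):
            append_transaction(
                chain, "SPONSOR", "REGULATOR", f"doc_{i}.txt",
                bytes((i + j) % 256 for j in range(payload_size)),
                False, TRIAL_START,
            )
        return chain

    return _make
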
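import numpy as np
import pytest

from ngffkit.chunk_store import MemoryStore
from ngffkit.synthesize import FixtureSpec, make_plate_fixture, write_image_fixture


class CountingStore(MemoryStore):
    """MemoryStore that logs every get() so tests can assert laziness."""

    def __init__(self):
        super().__init__()
        self.get_log = []

    def get(self, key):
        self.get_log.append(key)
        return super().get(key)


@pytest.fixture
def store():
    return MemoryStore()


@pytest.fixture
def counting_store():
    return CountingStore()


@pytest.fixture
def image_fixture(store):
    """A clean labelled-blob image fixture at 'img'; returns (store, truth)."""
    truth = write_image_fixture(store, "img",
                                FixtureSpec(seed=7, shape=(1, 2, 2, 64, 64)))
    return store, truth


@pytest.fixture
def plate_fixture(store):
    """A clean 2x3 plate fixture at 'plate'."""
    make_plate_fixture(FixtureSpec(seed=7, shape=(1, 1, 1, 48, 48)),
                       store, "plate")
    return store
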
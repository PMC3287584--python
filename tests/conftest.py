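import pytest

from protrack import Store, access, synth


@pytest.fixture
def store(tmp_path):
    """Empty store with two registered users and one project."""
    s = Store(tmp_path / "store.db")
    access.register_user(s, "gloria", "pw-g", "Gloria")
    access.register_user(s, "herbert", "pw-h", "Herbert")
    s.create_project("SmProteome", "S. mansoni 2D study", "gloria")
    s.add_member(1, "herbert", "RESEARCHER")
    yield s
    s.close()


@pytest.fixture
def demo_store(tmp_path):
    """The worked provenance example (ids 1, 100, 146, 174, 101, 148)."""
    s = Store(tmp_path / "demo.db")
    synth.make_demo_store(s, seed=0)
    yield s
    s.close()


def fresh_store(tmp_path, name="s"):
    """Helper for tests that need many independent stores."""
    root = tmp_path / name
    root.mkdir(parents=True, exist_ok=True)
    return Store(root / "store.db")
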
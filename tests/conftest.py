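import pytest
from hypothesis import settings
from hypothesis import strategies as st

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from multiorder import PathCollection, ToySpec, toy_collection, toy_topology


@pytest.fixture
def toy():
    """Five-path toy collection, every path observed 10 times (m=50)."""
    return toy_collection()


@pytest.fixture
def toy_top():
    return toy_topology()


@pytest.fixture
def order3_instance():
    """Start-terminal dependency instance: frequencies (10, 50, 0, 0, 50)."""
    return toy_collection(ToySpec((10, 50, 0, 0, 50)))


# -- hypothesis strategies --------------------------------------------------

labels = st.sampled_from(["a", "b", "c", "d", "e"])
path_nodes = st.lists(labels, min_size=1, max_size=6).map(tuple)


@st.composite
def collections(draw, min_paths=1, max_paths=8, max_count=5):
    """Small random path collections over a 5-node alphabet."""
    pairs = draw(
        st.lists(
            st.tuples(path_nodes, st.integers(1, max_count)),
            min_size=min_paths,
            max_size=max_paths,
        )
    )
    col = PathCollection()
    for nodes, count in pairs:
        col.add(nodes, count)
    return col
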
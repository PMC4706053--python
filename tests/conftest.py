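import random

import pytest

from hetnetkit.core import HetNet, default_metagraph
from hetnetkit.fixtures import FixtureSpec, generate


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """One seeded synthetic resource directory shared by the session."""
    d = tmp_path_factory.mktemp("resources")
    manifest = generate(FixtureSpec(seed=1), d)
    return d, manifest


def random_hetnet(rng: random.Random, n_per_kind: int = 8, n_edges: int = 40) -> HetNet:
    """A random valid hetnet over the default metagraph."""
    mg = default_metagraph()
    net = HetNet(mg)
    ids: dict[str, list[str]] = {}
    for kind in sorted(mg.node_kinds):
        ids[kind] = [f"{kind[:2].upper()}:{i}" for i in range(n_per_kind)]
        for nid in ids[kind]:
            net.add_node(nid, kind)
    ekinds = sorted(mg.edge_kinds)
    for _ in range(n_edges):
        ek = mg.edge_kinds[rng.choice(ekinds)]
        u = rng.choice(ids[ek.endpoint_a])
        v = rng.choice(ids[ek.endpoint_b])
        net.add_edge(u, v, ek.name, weight=rng.randint(1, 9))
    return net
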
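import io
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from glite.graph import parse_gfa

G1_GFA = """S\t1\tGAT
S\t2\tA
S\t3\tC
S\t4\tTACA
L\t1\t+\t2\t+\t0M
L\t1\t+\t3\t+\t0M
L\t2\t+\t4\t+\t0M
L\t3\t+\t4\t+\t0M
P\tH1\t1+,2+,4+\t*
P\tH2\t1+,3+,4+\t*
"""


@pytest.fixture
def g1():
    """The running SNP-bubble fixture: GAT -> (A|C) -> TACA, two haplotypes."""
    return parse_gfa(io.StringIO(G1_GFA))


@pytest.fixture
def g1_text():
    return G1_GFA


def make_sim_graph(seed, backbone=600, n_hap=4, snv=0.02, indel=0.008,
                   inv=0.0, dup=0.0, max_indel=15):
    from glite.sim import GraphSimParams, simulate_graph

    return simulate_graph(
        GraphSimParams(
            backbone_length=backbone,
            n_haplotypes=n_hap,
            snv_bubble_rate=snv,
            indel_bubble_rate=indel,
            inversion_rate=inv,
            tandem_duplication_rate=dup,
            max_indel_length=max_indel,
            seed=seed,
        )
    )


try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "ci",
        deadline=None,
        derandomize=True,
        max_examples=25,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass
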
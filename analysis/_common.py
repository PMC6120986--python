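"""Shared helpers for the numbered analysis scripts: fixture location,
per-region preprocessing and network construction at the study parameters."""

from pathlib import Path

from coexdiff import network, preprocess, simulate

ROOT = Path(__file__).resolve().parent.parent
FIXTURE_DIR = ROOT / "results" / "fixture"
RESULTS = ROOT / "results"

REGIONS = ("SH", "CeA", "PL")

# fixture-scale analysis parameters (module size 150 -> min cluster 30)
MIN_CLUSTER_SIZE = 30
N_PERMUTATIONS = 200


def load_fixture():
    """Read the three-region fixture written by 01_simulate_fixtures.py."""
    if not FIXTURE_DIR.exists():
        raise SystemExit("run analysis/01_simulate_fixtures.py first")
    out = {}
    for region in REGIONS:
        out[region] = simulate.read_fixture(FIXTURE_DIR / region)
    return out


def preprocess_region(counts):
    filtered = preprocess.filter_by_cpm(counts, threshold=1.0)
    return filtered, preprocess.upper_quartile_normalize(filtered)


def network_region(expr, beta=6.0):
    adj_full = network.adjacency(expr, beta=beta)
    adj = network.cull_network(adj_full, mode="cumulative", fraction=0.8)
    partition = network.detect_modules(
        adj, cut_height=0.9995, min_cluster_size=MIN_CLUSTER_SIZE, deep_split=4
    )
    profile = network.intramodular_connectivity(adj, partition)
    return adj_full, adj, partition, profile
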
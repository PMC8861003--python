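import numpy as np
import pytest

from sxjunction import (
    SimConfig,
    call_junction,
    simulate_reads,
    synthetic_switch_region,
)

# fixed fixture seeds: fixtures must be byte-stable across runs
REF_SEED = 777
SIM_SEED = 20240615


@pytest.fixture(scope="session")
def switch_refs():
    """Synthetic repeat-rich switch-region stand-ins (donor ~2 kb, acceptor
    ~1.5 kb) sharing the AGCT-family motif vocabulary, so that junctional
    microhomologies up to 13+ nt are realizable."""
    rng = np.random.default_rng(REF_SEED)
    donor = synthetic_switch_region("Smu_syn", "donor", 2000, rng)
    acceptor = synthetic_switch_region("sigma_delta_syn", "acceptor", 1500, rng)
    return donor, acceptor


@pytest.fixture(scope="session")
def mixed_dataset(switch_refs):
    """Error-free simulated library mixing blunt, microhomology (0-13 nt) and
    insertion (up to 6 nt) junctions, with the corresponding calls."""
    donor, acceptor = switch_refs
    cfg = SimConfig(
        n_reads=150,
        read_length=300,
        mh_distribution={r: 1 / 14 for r in range(14)},
        insertion_distribution={k: 1 / 7 for k in range(7)},
        mutation_rate=0.0,
        seq_error_rate=0.0,
        seed=SIM_SEED,
    )
    reads, truths, _ = simulate_reads(cfg, donor, acceptor)
    calls = [call_junction(r, donor, acceptor) for r in reads]
    return reads, truths, calls
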
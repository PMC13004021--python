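import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

RECOVERY_K0 = 1.2
RECOVERY_LEVELS = (0.5, 1.0, 1.5, 2.0, 2.5)


@pytest.fixture(scope="session")
def recovery_library():
    """Deep pooled-library simulation shared by the recovery/calibration tests.

    200 overabundance genes on the log10 o grid (0.5 .. 2.5, 40 genes per
    level, all arrest times inside the 0-12 h window at k0 = 1.2/h) mixed
    with 1000 no-effect genes (the flat reference population that makes the
    library normalization identifiable), depth 1e6 reads per timepoint.
    """
    from kodep.synth import SimConfig, TrueGene, simulate_tfnseq
    from kodep.tfnseq import fit_library

    truth = [
        TrueGene(f"over{i:04d}", True, "overabundance", float(lvl), 10.0)
        for i, lvl in enumerate(np.repeat(RECOVERY_LEVELS, 40))
    ]
    truth += [TrueGene(f"flat{i:04d}", False, "no_effect", 0.0, 10.0) for i in range(1000)]
    cfg = SimConfig(k0=RECOVERY_K0, depth=1_000_000, n_genes=len(truth), seed=7)
    counts = simulate_tfnseq(truth, cfg)
    result = fit_library(counts, k0=RECOVERY_K0)
    return truth, result


@pytest.fixture(scope="session")
def noise_free_colonies():
    """Noise-free microcolonies over o_true in {2, 4, 8, 16, 32}."""
    from kodep.synth import SimConfig, simulate_microcolony

    k0 = 1.0
    out = {}
    for o in (2.0, 4.0, 8.0, 16.0, 32.0):
        cfg = SimConfig(k0=k0, partition_cv=0.0, seed=3)
        out[o] = simulate_microcolony(o, k0, cfg, t_max=np.log(o) / k0 + 2.0)
    return k0, out


@pytest.fixture(scope="session")
def noisy_colonies():
    """Microcolonies with partition_cv = 0.05 over the same o_true grid."""
    from kodep.synth import SimConfig, simulate_microcolony

    k0 = 1.0
    out = {}
    for o in (2.0, 4.0, 8.0, 16.0, 32.0):
        cfg = SimConfig(k0=k0, partition_cv=0.05, seed=3)
        out[o] = simulate_microcolony(o, k0, cfg, t_max=np.log(o) / k0 + 2.0)
    return k0, out
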
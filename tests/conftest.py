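import pytest
from hypothesis import HealthCheck, settings

from mirturn import SimConfig, compute_frequencies, generate_reference, quantify_reads
from mirturn.reference import HairpinRecord, MatureAnnotation, Reference
from mirturn.synthdata import add_spikein_counts, simulate_timecourse_reads

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_sim():
    """A 20-hairpin, 1e5-depth time course with spike-ins."""
    cfg = SimConfig(n_hairpins=20, depth=1e5, seed=3)
    ref, spikes, truth = generate_reference(cfg)
    sim = add_spikein_counts(simulate_timecourse_reads(ref, truth, cfg),
                             spikes, cfg)
    return cfg, ref, spikes, truth, sim


@pytest.fixture(scope="session")
def small_fm(small_sim):
    _, ref, _, _, sim = small_sim
    counts = quantify_reads(sim.counts, ref)
    return counts, compute_frequencies(counts, sim.samples)


@pytest.fixture
def toy_reference():
    """One handcrafted two-arm hairpin with known coordinates."""
    m5p = "TGAGGTAGTAGGTTGTATAGTT"          # 22 nt
    m3p = "CTATACAATCTACTGTCTTTCC"          # 22 nt
    loop = "GGGTTTGGGTTTGGGT"               # 16 nt
    seq = "ACGTAC" + m5p + loop + m3p + "TGCATG"
    hp = HairpinRecord("hp-toy", seq, {
        "5p": MatureAnnotation("toy-5p", "5p", 6, 28),
        "3p": MatureAnnotation("toy-3p", "3p", 44, 66),
    })
    return Reference([hp])
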
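import pytest

from telofuseq.simulate import (FusionSimConfig, SimGenomeConfig, SimPanelConfig,
                                build_subtelomere_panel, build_toy_genome,
                                render_amplicon_reads, simulate_fusion_events)


@pytest.fixture(scope="session")
def panel():
    return build_subtelomere_panel(SimPanelConfig(seed=11))


@pytest.fixture(scope="session")
def genome():
    return build_toy_genome(SimGenomeConfig(seed=11))


@pytest.fixture(scope="session")
def called_sample():
    """One fully simulated and called sample shared across caller tests."""
    from telofuseq.caller import call_sample

    panel = build_subtelomere_panel(SimPanelConfig(seed=23))
    genome = build_toy_genome(SimGenomeConfig(seed=23))
    events = simulate_fusion_events(
        panel, genome, FusionSimConfig(n_events=40, seed=23))
    r1, r2, truth = render_amplicon_reads(events, panel, genome, seed=23)
    panel.genome = genome
    calls, failures = call_sample(r1, r2, panel)
    return panel, genome, events, r1, r2, calls, failures
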
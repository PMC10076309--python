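import numpy as np
import pytest

from ampseek import (
    PlantedVariant,
    SampleSheet,
    SimulationConfig,
    build_default_panel,
    make_sample_sheet,
    marker_site,
    simulate_pool,
)


@pytest.fixture(scope="session")
def panel():
    return build_default_panel()


@pytest.fixture(scope="session")
def sheet6(panel):
    """Six samples over two pools with distance-3 barcodes."""
    return make_sample_sheet(6, 2, seed=42)


@pytest.fixture(scope="session")
def kdr_variant(panel):
    """The vgsc L958F substitution on the default panel."""
    amp, pos, ref, alt = marker_site(panel, panel.marker("L958F"))
    return PlantedVariant(amp, pos, ref, alt, 0.5)


def simulate_pools(panel, sheet, planted, out_dir, reads_mean=100.0,
                   error=0.0, seed=0, amplicons=None, quality=(37, 12, 0.0)):
    """Simulate every pool of a sheet into ``out_dir``; returns per-pool sims."""
    amplicons = amplicons if amplicons is not None else panel.amplicons
    sims = {}
    for k, pool in enumerate(sheet.pools):
        sub = SampleSheet([r for r in sheet.rows if r[3] == pool])
        cfg = SimulationConfig(
            n_samples=len(sub.rows), amplicons=amplicons,
            planted_variants=planted, reads_per_amplicon_mean=reads_mean,
            base_error_rate=error, quality_model=quality,
            seed=seed * 1009 + k + 1,
        )
        sims[pool] = simulate_pool(cfg, sub, out_dir)
    return sims


@pytest.fixture(scope="session")
def clean_pool(tmp_path_factory, panel, sheet6, kdr_variant):
    """Error-free two-pool simulation over two amplicons with a planted het
    variant, demultiplexed once for the whole session."""
    from ampseek import demultiplex_pool

    out = tmp_path_factory.mktemp("clean_pool")
    amps = [panel.get(kdr_variant.amplicon), panel.get("Rdl1")]
    sims = simulate_pools(panel, sheet6, [kdr_variant], out / "reads",
                          reads_mean=120.0, error=0.0, seed=7, amplicons=amps)
    demux_dir = out / "demux"
    reports = {}
    results = {}
    for pool, sim in sims.items():
        sub = SampleSheet([r for r in sheet6.rows if r[3] == pool])
        res, rep = demultiplex_pool(sim.r1_path, sim.r2_path, sub, panel,
                                    out_dir=demux_dir)
        reports[pool] = rep
        results[pool] = res
    return {"sims": sims, "demux_dir": demux_dir, "reports": reports,
            "results": results, "amplicons": amps}
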
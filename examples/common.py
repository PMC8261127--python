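"""Shared reduced cohort used by the example scripts (fast to generate)."""

from afcerna import SimulationConfig


def example_config(**overrides) -> SimulationConfig:
    base = dict(
        n_samples_per_group={"SR/SR": 12, "AF/SR": 16, "AF/AF": 20},
        n_genes=400,
        n_lncrna=40,
        n_modules=4,
        module_size=45,
        # effects sized for clear recovery at this small sample count
        trait_module_effects={
            1: ("susceptibility", 1.6),
            2: ("persistence", 2.2),
        },
        # nuisance effects are per-gene, so at a few hundred genes they must
        # be larger than at study scale for the surrogate variables to pick
        # the batch/depth factors ahead of the module factors
        batch_effect_sd=2.0,
        depth_effect_sd=1.0,
        n_mirnas=250,
        pairs_per_module=5,
        hub_partner_count=4,
        n_seed_genes=8,
        layer2_random_edges=120,
        layer2_planted_edges=50,
        hub_layer2_seed_edges=3,
        n_test_per_group={"SR/SR": 10, "AF/AF": 10},
        n_gene_sets=8,
        rng_seed=5,
    )
    base.update(overrides)
    return SimulationConfig(**base)
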
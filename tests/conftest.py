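import pytest

from srna_census.sim import SimConfig, build_genome

SMALL_CHROMS = {"2R": 220_000, "2L": 160_000, "3L": 160_000, "X": 120_000}


def small_config(**overrides) -> SimConfig:
    """Desk-scale-within-desk-scale generator config for unit tests."""
    base = dict(
        seed=42,
        chromosomes=dict(SMALL_CHROMS),
        n_reads=4000,
        clusters=[("2R", 100_000, 17.7), ("3L", 0, 3.3)],
        n_hairpins=6,
        n_trna=8,
        n_rrna=4,
        n_mrna=8,
        te_multi_families_per_class=1,
        te_copies_per_multi_family=3,
        te_single_background={"LTR": 4, "non-LTR": 3, "DNA": 2},
        te_single_per_cluster={"LTR": 1, "non-LTR": 1, "DNA": 1},
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_bundle():
    """One shared small genome bundle for fast unit tests."""
    return build_genome(small_config())
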
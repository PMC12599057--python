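import pytest

from pansv_atlas.synthetic import CohortConfig, simulate_cohort, simulate_reference

COHORT_SEED = 11


def sparse_config() -> CohortConfig:
    """A small, sparse cohort: planted features well separated so that the
    filter/merge/TE recovery properties can be checked against truth."""
    return CohortConfig(
        n_shared=250,
        n_ecotype_specific=120,
        n_private=80,
        n_genes=300,
        chromosomes=(("A01", 4_000_000, "A"), ("C01", 4_000_000, "C")),
        n_false_positives=40,
        n_deletion_segments=6,
        n_duplication_segments=3,
        n_hotspot_windows=4,
        spurious_per_segment=2,
    )


@pytest.fixture(scope="session")
def small_cohort():
    cc = sparse_config()
    ref = simulate_reference(cc, COHORT_SEED)
    return simulate_cohort(ref, cc, COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    from pansv_atlas.synthetic import write_cohort

    out = tmp_path_factory.mktemp("cohort") / "data"
    write_cohort(small_cohort, str(out))
    return out
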
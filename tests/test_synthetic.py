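import numpy as np
import pytest

from sfdkit import (
    CascadeStep,
    StepKind,
    SyntheticConfig,
    build_reference,
    generate_proteomes,
    generate_survival,
    run_cascade,
)


def run_sfd(world):
    """disease − healthy union, then intersect the function reference."""
    refs = {
        "healthy": build_reference(world.healthy_sources),
        "function": world.function_reference,
    }
    steps = [
        CascadeStep(StepKind.SUBTRACT, "healthy"),
        CascadeStep(StepKind.INTERSECT, "function"),
    ]
    return run_cascade(world.disease, steps, refs)


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticConfig(seed=1, n_scaffold=-1)
    with pytest.raises(ValueError):
        SyntheticConfig(seed=1, dropout=1.5)
    with pytest.raises(ValueError):
        SyntheticConfig(seed=1, n_sources=0)


def test_seed_determinism_byte_identical():
    config = SyntheticConfig(seed=5, n_scaffold=80, n_sources=3, dropout=0.2,
                             n_disease_unique=30, n_patients=40)
    w1, w2 = generate_proteomes(config), generate_proteomes(config)
    assert w1.disease.members == w2.disease.members
    assert [s.proteins.members for s in w1.healthy_sources] == [
        s.proteins.members for s in w2.healthy_sources
    ]
    assert w1.expression.equals(w2.expression)
    assert w1.clinical.equals(w2.clinical)


def test_truth_labels_partition_universe(small_world):
    truth = small_world.truth
    labeled = (
        truth["scaffold"] | truth["source_specific"] | truth["disease_unique"]
    )
    assert truth["scaffold"] & truth["disease_unique"] == frozenset()
    assert truth["scaffold"] & truth["source_specific"] == frozenset()
    assert truth["function_positive"] <= truth["disease_unique"]
    universe = small_world.disease.members | frozenset().union(
        *(s.proteins.members for s in small_world.healthy_sources)
    )
    assert universe <= labeled


def test_noiseless_world_gives_exact_recovery(small_world):
    assert small_world.config.dropout == 0
    report = run_sfd(small_world)
    assert set(report.final_members) == {
        p.value for p in small_world.truth["function_positive"]
    }


def test_no_disease_unique_means_empty_final_set():
    config = SyntheticConfig(seed=3, n_scaffold=50, n_sources=3,
                             n_disease_unique=0, n_patients=0)
    world = generate_proteomes(config, with_survival=False)
    assert run_sfd(world).final_members == []


def test_scaffold_dropout_shrinks_healthy_sources():
    config = SyntheticConfig(seed=9, n_scaffold=500, n_sources=4, dropout=0.3,
                             n_source_specific=0, n_disease_unique=0, n_patients=0)
    world = generate_proteomes(config, with_survival=False)
    sizes = [len(s.proteins) for s in world.healthy_sources]
    assert all(250 < s < 450 for s in sizes)  # ~500*0.7 = 350 per source


def test_scaffold_leakage_matches_binomial_expectation():
    """With 2 sources at 10% dropout, ~1000·0.01 scaffold ids leak through."""
    leaks = []
    for seed in range(30):
        config = SyntheticConfig(seed=seed, n_scaffold=1000, n_sources=2,
                                 dropout=0.1, n_source_specific=0,
                                 n_disease_unique=0, n_patients=0)
        world = generate_proteomes(config, with_survival=False)
        healthy = build_reference(world.healthy_sources)
        leaked = world.disease.members - healthy.members
        leaks.append(len(leaked & world.truth["scaffold"]))
    mean = np.mean(leaks)
    sd = np.sqrt(1000 * 0.01 * 0.99)
    assert abs(mean - 10.0) <= 3 * sd / np.sqrt(len(leaks))


def test_survival_censoring_calibration_and_zero_case():
    config = SyntheticConfig(seed=21, n_patients=400, censoring=0.0,
                             frac_dfs_missing=0.0)
    _, clinical = generate_survival(config)
    assert (clinical["os_event"] == 1).all()

    config = SyntheticConfig(seed=21, n_patients=400, censoring=0.3)
    _, clinical = generate_survival(config)
    frac = 1 - clinical["os_event"].mean()
    assert abs(frac - 0.3) < 0.07


def test_dfs_missingness_is_joint():
    config = SyntheticConfig(seed=2, n_patients=200, frac_dfs_missing=0.25)
    _, clinical = generate_survival(config)
    missing_t = clinical["dfs_time"].isna()
    missing_e = clinical["dfs_event"].isna()
    assert (missing_t == missing_e).all()
    assert 0.1 < missing_t.mean() < 0.4


def test_expression_transform_recovers_latent_exactly():
    """log2(x+1) of the stored expression is an affine image of the latent."""
    config = SyntheticConfig(seed=13, n_patients=50, n_null_genes=1)
    expr, _ = generate_survival(config)
    logged = np.log2(expr.loc["HAZARD00001"].to_numpy() + 1.0)
    assert logged.std() == pytest.approx(1.0, abs=0.35)  # latent is N(0,1)
    assert logged.mean() == pytest.approx(8.0, abs=0.5)
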
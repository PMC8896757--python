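"""Proteome profiles: pooled frequencies, UPGMA, PCA, trait regressions."""

import numpy as np
import pytest

from thermoenv import (
    InvariantError,
    OrganismMeta,
    ProteomeProfile,
    TESequence,
    fraction_most_stable,
    kingdom_slope_test,
    pca_decompose,
    proteome_te_frequencies,
    regress_pc_vs_trait,
    trait_regression,
    upgma_cluster,
)

META = OrganismMeta("org", "bacteria")


def make_profile(freq, oid="org", kingdom="bacteria", **meta_kwargs):
    return ProteomeProfile(oid, np.asarray(freq, dtype=float),
                           OrganismMeta(oid, kingdom, **meta_kwargs))


# ---------------------------------------------------------------------------
# frequencies

def test_single_protein_frequencies():
    seq = TESequence("p", [4, 4, 5, 5], [1, 1, 1, 1])
    profile = proteome_te_frequencies([seq], META)
    assert np.allclose(profile.native_freq, [0, 0, 0, .5, .5, 0, 0, 0])
    assert np.allclose(profile.denatured_freq, [1, 0, 0, 0, 0, 0, 0, 0])
    assert profile.n_proteins == 1 and profile.n_residues == 4


def test_pooling_weights_by_length_not_by_protein(rng):
    short = TESequence("a", [1], [1])
    long = TESequence("b", [8, 8, 8], [1, 1, 1])
    pooled = proteome_te_frequencies([short, long], META)
    # 1 residue of TE1 and 3 of TE8 out of 4 total
    assert np.allclose(pooled.native_freq, [0.25, 0, 0, 0, 0, 0, 0, 0.75])
    averaged = proteome_te_frequencies([short, long], META, mode="mean")
    assert np.allclose(averaged.native_freq, [0.5, 0, 0, 0, 0, 0, 0, 0.5])
    # pooled result equals a direct residue tally
    labels = np.concatenate([short.native_labels, long.native_labels])
    direct = np.bincount(labels, minlength=9)[1:] / labels.size
    assert np.allclose(pooled.native_freq, direct)


def test_empty_proteome_rejected():
    with pytest.raises(InvariantError):
        proteome_te_frequencies([], META)


def test_profile_normalization_enforced():
    with pytest.raises(InvariantError):
        ProteomeProfile("x", np.full(8, 0.2), META)


# ---------------------------------------------------------------------------
# UPGMA

def textbook_upgma_cophenetic(dist):
    """Quadratic-time UPGMA: average linkage over explicit cluster lists."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    d = {frozenset((i, j)): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        pair = min(d, key=d.get)
        a, b = tuple(pair)
        height = d[pair]
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = height
        merged = clusters[a] + clusters[b]
        del clusters[a], clusters[b]
        new_d = {}
        for key, value in d.items():
            if a in key or b in key:
                continue
            new_d[key] = value
        for c, members in clusters.items():
            total = sum(dist[i, j] for i in merged for j in members)
            new_d[frozenset((next_id, c))] = total / (len(merged) * len(members))
        clusters[next_id] = merged
        d = new_d
        next_id += 1
    return coph


def test_two_profiles_join_at_half_distance():
    p1 = make_profile([1, 0, 0, 0, 0, 0, 0, 0], "a")
    p2 = make_profile([0, 1, 0, 0, 0, 0, 0, 0], "b")
    tree = upgma_cluster([p1, p2])
    distance = np.sqrt(2.0)
    assert tree.linkage_matrix[0, 2] == pytest.approx(distance)
    newick = tree.to_newick()
    # each leaf sits at depth = half the pair distance
    assert f"{distance / 2:.10g}" in newick
    assert tree.cophenetic_matrix()[0, 1] == pytest.approx(distance)


def test_identical_pair_joins_first_at_zero_height():
    freq = np.array([0.1, 0.1, 0.1, 0.2, 0.2, 0.1, 0.1, 0.1])
    other = np.array([0.3, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
    tree = upgma_cluster([
        make_profile(freq, "a"), make_profile(other, "b"), make_profile(freq, "c"),
    ])
    first = tree.linkage_matrix[0]
    assert {int(first[0]), int(first[1])} == {0, 2}
    assert first[2] == pytest.approx(0.0)


def test_cophenetic_matches_textbook_oracle(rng):
    from scipy.spatial.distance import pdist, squareform

    freqs = rng.dirichlet(np.ones(8), size=6)
    profiles = [make_profile(f, f"o{i}") for i, f in enumerate(freqs)]
    tree = upgma_cluster(profiles)
    dist = squareform(pdist(freqs))
    expected = textbook_upgma_cophenetic(dist)
    assert np.allclose(tree.cophenetic_matrix(), expected, atol=1e-12)


def test_ultrametricity(rng):
    freqs = rng.dirichlet(np.ones(8) * 3, size=9)
    profiles = [make_profile(f, f"o{i}") for i, f in enumerate(freqs)]
    coph = upgma_cluster(profiles).cophenetic_matrix()
    n = coph.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                top = sorted([coph[i, j], coph[i, k], coph[j, k]])
                assert top[2] - top[1] <= 1e-9


def test_duplicate_ids_rejected():
    p = make_profile(np.full(8, 0.125), "same")
    q = make_profile(np.ones(8) / 8, "same")
    with pytest.raises(InvariantError, match="same"):
        upgma_cluster([p, q])


# ---------------------------------------------------------------------------
# PCA

def test_identical_profiles_zero_variance_error():
    profiles = [make_profile(np.full(8, 0.125), f"o{i}") for i in range(4)]
    with pytest.raises(InvariantError, match="variance"):
        pca_decompose(profiles)


def test_rank_one_variation_explained_by_first_component(rng):
    base = np.full(8, 0.125)
    direction = np.array([1, -1, 0, 0, 0, 0, 0, 0]) / np.sqrt(2)
    profiles = [make_profile(base + t * direction * 0.05, f"o{i}")
                for i, t in enumerate(rng.uniform(-1, 1, size=10))]
    result = pca_decompose(profiles, n_components=3)
    assert result.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)
    assert abs(result.loadings[0] @ direction) == pytest.approx(1.0, abs=1e-8)


def test_eigenvalues_match_direct_covariance_eigensolve(rng):
    freqs = rng.dirichlet(np.ones(8) * 5, size=20)
    profiles = [make_profile(f, f"o{i}") for i, f in enumerate(freqs)]
    result = pca_decompose(profiles)
    eigenvalues = np.sort(np.linalg.eigvalsh(np.cov(freqs.T)))[::-1]
    assert np.allclose(result.explained_variance, eigenvalues[:result.n_components],
                       atol=1e-12)
    # compositional closure: rank <= 7, trailing eigenvalue ~ 0
    assert result.explained_variance[-1] == pytest.approx(0.0, abs=1e-12)
    assert result.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)


def test_full_rank_reconstruction_and_orthonormal_loadings(rng):
    freqs = rng.dirichlet(np.ones(8) * 5, size=15)
    profiles = [make_profile(f, f"o{i}") for i, f in enumerate(freqs)]
    result = pca_decompose(profiles)
    assert np.max(np.abs(result.reconstruct() - freqs)) < 1e-8
    gram = result.loadings @ result.loadings.T
    assert np.allclose(gram, np.eye(result.n_components), atol=1e-8)
    # sign convention: the largest-|entry| of each loading is positive
    for component in result.loadings:
        assert component[np.argmax(np.abs(component))] > 0


def test_concatenated_native_denatured_pca(small_proteome_profiles):
    result = pca_decompose(small_proteome_profiles, states="both", n_components=4)
    assert result.loadings.shape == (4, 16)


# ---------------------------------------------------------------------------
# traits

def test_fraction_most_stable_configurable():
    uniform = make_profile(np.full(8, 0.125), "u")
    assert fraction_most_stable(uniform) == pytest.approx(0.125)
    assert fraction_most_stable(uniform, stable_envs=(7, 8)) == pytest.approx(0.25)
    top = make_profile([0, 0, 0, 0, 0, 0, 0, 1.0], "t")
    assert fraction_most_stable(top) == pytest.approx(1.0)


def test_perfect_linear_trait_gives_unit_correlation(rng):
    scores = rng.normal(size=30)
    reg = trait_regression(scores, 2.5 * scores - 1.0)
    assert reg.pearson_r == pytest.approx(1.0)
    assert reg.slope == pytest.approx(2.5)
    assert reg.p_value < 1e-30


def test_null_calibration_small(rng):
    """Type-I error of the zero-slope test is near its nominal 5% level."""
    hits = sum(
        trait_regression(rng.normal(size=200), rng.normal(size=200)).p_value < 0.05
        for _ in range(200)
    )
    assert 0.02 <= hits / 200 <= 0.09


def test_planted_slope_recovered_within_three_stderr(rng):
    x = rng.normal(size=100)
    y = 0.4 * x + rng.normal(scale=0.5, size=100)
    reg = trait_regression(x, y)
    assert abs(reg.slope - 0.4) <= 3 * reg.stderr


def test_regress_pc_vs_trait_drops_missing(small_proteome_profiles):
    profiles = list(small_proteome_profiles)
    # strip the trait from a third of the organisms
    stripped = [
        ProteomeProfile(p.organism_id, p.native_freq,
                        OrganismMeta(p.organism_id, p.meta.kingdom),
                        denatured_freq=p.denatured_freq,
                        n_proteins=p.n_proteins, n_residues=p.n_residues)
        if i % 3 == 0 else p
        for i, p in enumerate(profiles)
    ]
    result = pca_decompose(stripped)
    reg = regress_pc_vs_trait(result, stripped, "growth_temp", pc_index=1)
    assert reg.n_dropped == len([i for i in range(len(profiles)) if i % 3 == 0])
    assert reg.n == len(profiles) - reg.n_dropped


def test_trait_recovery_on_planted_axis():
    """Noiseless trait on rank-1 compositional variation: |r| ~ 1 on PC1."""
    from thermoenv.simulate import GeneratorConfig, gen_proteome_set
    from thermoenv.profile import proteome_te_frequencies
    from thermoenv import annotate_protein

    config = GeneratorConfig(seed=21, n_organisms_per_kingdom=4, n_proteins=6,
                             length_range=(800, 1000), kingdom_tilt=0.0,
                             axis_spread=0.06, growth_temp_noise_sd=0.0,
                             disorder_noise_sd=0.0, td_scatter_sd=0.5)
    dataset = gen_proteome_set(config)
    profiles = []
    for organism in dataset.organisms:
        te_seqs = [annotate_protein(t, dataset.centers) for t in organism.td_tables]
        profiles.append(proteome_te_frequencies(te_seqs, organism.meta))
    result = pca_decompose(profiles)
    reg = regress_pc_vs_trait(result, profiles, "disorder_fraction", pc_index=1)
    # finite proteins add multinomial noise around the planted axis
    assert abs(reg.pearson_r) > 0.97
    assert np.sign(reg.slope) == np.sign(
        dataset.truth["disorder_fraction"]["slope"]
        * (result.loadings[0] @ dataset.truth["disorder_fraction"]["contrast"])
    )


# ---------------------------------------------------------------------------
# kingdom slopes

def _two_kingdom_profiles(rng, slope_b, slope_e, n=60, noise=0.3):
    profiles, traits = [], []
    base = np.full(8, 0.125)
    direction = np.zeros(8)
    direction[0], direction[7] = 1 / np.sqrt(2), -1 / np.sqrt(2)
    for i in range(n):
        kingdom = "bacteria" if i < n // 2 else "eukaryote"
        t = rng.uniform(-1, 1)
        freq = base + 0.05 * t * direction
        slope = slope_b if kingdom == "bacteria" else slope_e
        trait = slope * t + rng.normal(scale=noise)
        profiles.append(make_profile(freq, f"o{i}", kingdom, growth_temp=trait))
    return profiles


def test_single_kingdom_errors():
    profiles = [
        make_profile(np.random.default_rng(i).dirichlet(np.ones(8)), f"o{i}",
                     growth_temp=float(i))
        for i in range(6)
    ]
    result = pca_decompose(profiles)
    with pytest.raises(InvariantError, match="regress_pc_vs_trait"):
        kingdom_slope_test(result, profiles, "growth_temp", 1)


def test_interaction_detected_for_different_slopes(rng):
    detected = 0
    for rep in range(40):
        profiles = _two_kingdom_profiles(rng, slope_b=1.0, slope_e=0.2)
        result = pca_decompose(profiles)
        kt = kingdom_slope_test(result, profiles, "growth_temp", 1)
        if kt.interaction_p_value < 0.05:
            detected += 1
        assert set(kt.slopes) == {"bacteria", "eukaryote"}
    assert detected >= 36  # >= 90% power


def test_interaction_null_controlled(rng):
    false_hits = 0
    for rep in range(40):
        profiles = _two_kingdom_profiles(rng, slope_b=0.8, slope_e=0.8)
        result = pca_decompose(profiles)
        kt = kingdom_slope_test(result, profiles, "growth_temp", 1)
        if kt.interaction_p_value < 0.05:
            false_hits += 1
    assert false_hits <= 4  # non-significant in >= 90% of replicates
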
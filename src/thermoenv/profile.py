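"""Proteome-level TE usage: frequency vectors, clustering, PCA, trait models.

A proteome is summarised by the 8-vector of native TE frequencies, pooled over
all residues of all proteins (``T_n / sum_n T_n``).  Proteomes are compared by
UPGMA clustering on Euclidean distance, decomposed by PCA on mean-centered
frequency vectors, and principal-component scores are regressed against
organism traits (optimal growth temperature, intrinsic disorder fraction, or
the proteome's most-stable-TE fraction), optionally with per-kingdom slopes.

Because frequency vectors sum to 1 (compositional closure) the covariance of
the 8 native frequencies has rank at most 7; the trailing eigenvalue is zero
and at most 7 meaningful components exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage, to_tree
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from sklearn.decomposition import PCA

from .assign import te_counts
from .containers import N_ENVIRONMENTS, OrganismMeta, ProteomeProfile
from .errors import InvariantError

__all__ = [
    "proteome_te_frequencies",
    "upgma_cluster",
    "UPGMATree",
    "pca_decompose",
    "PCAResult",
    "fraction_most_stable",
    "trait_regression",
    "regress_pc_vs_trait",
    "TraitRegression",
    "kingdom_slope_test",
    "KingdomSlopeTest",
]


def proteome_te_frequencies(te_seqs, meta: OrganismMeta, mode: str = "pooled") -> ProteomeProfile:
    """TE frequency vector of one proteome.

    ``mode="pooled"`` (default) divides pooled residue counts over all
    proteins by the total residue count, so long proteins weigh more;
    ``mode="mean"`` averages per-protein frequency vectors instead.
    """
    te_seqs = list(te_seqs)
    if not te_seqs:
        raise InvariantError(f"{meta.organism_id}: proteome must contain at least one protein")
    native_counts = np.zeros(N_ENVIRONMENTS)
    denatured_counts = np.zeros(N_ENVIRONMENTS)
    native_mean = np.zeros(N_ENVIRONMENTS)
    denatured_mean = np.zeros(N_ENVIRONMENTS)
    n_residues = 0
    for seq in te_seqs:
        n, d = te_counts(seq)
        native_counts += n
        denatured_counts += d
        native_mean += n / len(seq)
        denatured_mean += d / len(seq)
        n_residues += len(seq)
    if mode == "pooled":
        native_freq = native_counts / n_residues
        denatured_freq = denatured_counts / n_residues
    elif mode == "mean":
        native_freq = native_mean / len(te_seqs)
        denatured_freq = denatured_mean / len(te_seqs)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ProteomeProfile(
        meta.organism_id, native_freq, meta, denatured_freq=denatured_freq,
        n_proteins=len(te_seqs), n_residues=n_residues,
    )


# ---------------------------------------------------------------------------
# UPGMA clustering

@dataclass
class UPGMATree:
    """Rooted ultrametric tree from UPGMA on Euclidean distances.

    Node height is half the UPGMA average pairwise distance between the two
    joined clusters, so every leaf sits at the same depth below an internal
    node and the cophenetic distance between two leaves equals the full
    average distance at their join.
    """

    ids: list[str]
    linkage_matrix: np.ndarray

    def cophenetic_matrix(self) -> np.ndarray:
        """Square matrix of cophenetic distances, ordered like ``ids``."""
        return squareform(cophenet(self.linkage_matrix))

    def to_newick(self) -> str:
        root = to_tree(self.linkage_matrix)

        def render(node) -> tuple[str, float]:
            if node.is_leaf():
                return self.ids[node.id], 0.0
            left, hl = render(node.left)
            right, hr = render(node.right)
            height = node.dist / 2.0
            return f"({left}:{height - hl:.10g},{right}:{height - hr:.10g})", height

        text, _ = render(root)
        return text + ";"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def upgma_cluster(profiles, state: str = "native") -> UPGMATree:
    """UPGMA agglomerative clustering of proteome TE frequency vectors."""
    profiles = list(profiles)
    if len(profiles) < 2:
        raise InvariantError("UPGMA requires at least 2 profiles")
    ids = [p.organism_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InvariantError(f"duplicate organism ids: {dupes}")
    X = _frequency_matrix(profiles, state)
    Z = linkage(pdist(X, metric="euclidean"), method="average")
    return UPGMATree(ids=ids, linkage_matrix=Z)


def _frequency_matrix(profiles, states: str) -> np.ndarray:
    native = np.array([p.native_freq for p in profiles])
    if states == "native":
        return native
    if states in ("both", "native+denatured"):
        if any(p.denatured_freq is None for p in profiles):
            raise InvariantError("denatured frequencies missing for at least one profile")
        denatured = np.array([p.denatured_freq for p in profiles])
        return np.hstack([native, denatured])
    raise ValueError(f"unknown states selector {states!r}")


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAResult:
    """Principal-component decomposition of proteome TE usage.

    Columns are mean-centered but not variance-scaled.  Each loading vector is
    oriented so its largest-magnitude entry is positive (PCA signs are
    otherwise arbitrary).  With all components retained the scores reproduce
    the centered data exactly.
    """

    loadings: np.ndarray  # (k, n_features)
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    center: np.ndarray
    scores: np.ndarray  # (n_samples, k)
    organism_ids: list[str]
    states: str

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Data reconstructed from the retained components."""
        return self.scores @ self.loadings + self.center

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=self.organism_ids,
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        )

    def plot_scores(self, profiles=None, ax=None, pc_x: int = 1, pc_y: int = 2):
        """Scatter two PC scores, colored by kingdom when profiles are given."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.scores[:, pc_x - 1]
        y = self.scores[:, pc_y - 1]
        if profiles is not None:
            kingdoms = np.array([p.meta.kingdom for p in profiles])
            for kingdom in sorted(set(kingdoms)):
                mask = kingdoms == kingdom
                ax.scatter(x[mask], y[mask], label=kingdom, s=14)
            ax.legend()
        else:
            ax.scatter(x, y, s=14)
        ax.set_xlabel(f"PC{pc_x} ({self.explained_variance_ratio[pc_x - 1]:.1%})")
        ax.set_ylabel(f"PC{pc_y} ({self.explained_variance_ratio[pc_y - 1]:.1%})")
        return ax


def pca_decompose(profiles, states: str = "native", n_components: int | None = None) -> PCAResult:
    """PCA of proteome TE frequency vectors (mean-centered, unscaled).

    ``states`` selects the native 8-vectors or the concatenated 16-vector
    including denatured frequencies.  The default retains every component
    (min(n_features, n_samples - 1)); compositional closure leaves the
    trailing eigenvalue at zero, which is tolerated, not an error.
    """
    profiles = list(profiles)
    if len(profiles) < 3:
        raise InvariantError("PCA requires at least 3 profiles")
    X = _frequency_matrix(profiles, states)
    max_components = min(X.shape[1], len(profiles) - 1)
    if n_components is None:
        n_components = max_components
    if not 0 < n_components <= max_components:
        raise InvariantError(
            f"n_components must lie in 1..{max_components} for {len(profiles)} profiles"
        )
    total_variance = np.var(X, axis=0, ddof=1).sum()
    if total_variance < 1e-15:
        raise InvariantError("profiles have zero total variance; PCA is undefined")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.copy()
    # orient each component so its largest-|entry| is positive
    for i in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    return PCAResult(
        loadings=loadings,
        explained_variance=model.explained_variance_.copy(),
        explained_variance_ratio=model.explained_variance_ratio_.copy(),
        center=model.mean_.copy(),
        scores=scores,
        organism_ids=[p.organism_id for p in profiles],
        states=states,
    )


# ---------------------------------------------------------------------------
# Traits and regressions

def fraction_most_stable(profile: ProteomeProfile, stable_envs=(8,)) -> float:
    """Fraction of residues in the "most stable" native TEs (default {TE8})."""
    idx = [int(e) - 1 for e in stable_envs]
    if any(i < 0 or i >= N_ENVIRONMENTS for i in idx):
        raise InvariantError("stable_envs must be a subset of 1..8")
    return float(profile.native_freq[idx].sum())


@dataclass(frozen=True)
class TraitRegression:
    """Ordinary least-squares fit of a trait against one PC score."""

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int
    stderr: float
    trait: str = ""
    pc_index: int = 0
    n_dropped: int = 0

    def __post_init__(self):
        if abs(self.pearson_r) > 1 + 1e-12:
            raise InvariantError("|pearson_r| must not exceed 1")
        if not 0.0 <= self.p_value <= 1.0:
            raise InvariantError("p_value must lie in [0, 1]")
        if self.n < 3:
            raise InvariantError("regression requires n >= 3")


def trait_regression(scores, traits, trait: str = "", pc_index: int = 0,
                     n_dropped: int = 0) -> TraitRegression:
    """OLS of trait on score: slope, intercept, Pearson r, two-sided p."""
    scores = np.asarray(scores, dtype=float)
    traits = np.asarray(traits, dtype=float)
    if scores.size != traits.size:
        raise InvariantError("scores and traits must have equal length")
    if scores.size < 3:
        raise InvariantError("regression requires at least 3 organisms with the trait")
    res = stats.linregress(scores, traits)
    return TraitRegression(
        slope=float(res.slope), intercept=float(res.intercept),
        pearson_r=float(np.clip(res.rvalue, -1.0, 1.0)),
        p_value=float(res.pvalue), n=int(scores.size), stderr=float(res.stderr),
        trait=trait, pc_index=pc_index, n_dropped=n_dropped,
    )


def _trait_values(profiles, trait: str, stable_envs=(8,)) -> np.ndarray:
    if trait == "growth_temp":
        vals = [p.meta.growth_temp for p in profiles]
    elif trait == "disorder_fraction":
        vals = [p.meta.disorder_fraction for p in profiles]
    elif trait == "fraction_most_stable":
        vals = [fraction_most_stable(p, stable_envs) for p in profiles]
    else:
        raise ValueError(f"unknown trait {trait!r}")
    return np.array([np.nan if v is None else float(v) for v in vals])


def regress_pc_vs_trait(pca: PCAResult, profiles, trait: str, pc_index: int,
                        stable_envs=(8,)) -> TraitRegression:
    """Regress a trait on the scores of one principal component (1-based).

    Organisms missing the trait are dropped and counted in ``n_dropped``.
    """
    profiles = list(profiles)
    if len(profiles) != pca.scores.shape[0]:
        raise InvariantError("profiles and PCA scores are misaligned")
    if not 1 <= pc_index <= pca.n_components:
        raise InvariantError(f"pc_index must lie in 1..{pca.n_components}")
    y = _trait_values(profiles, trait, stable_envs)
    mask = np.isfinite(y)
    if not mask.any():
        raise InvariantError(f"no organism carries trait {trait!r}")
    x = pca.scores[mask, pc_index - 1]
    return trait_regression(x, y[mask], trait=trait, pc_index=pc_index,
                            n_dropped=int((~mask).sum()))


@dataclass(frozen=True)
class KingdomSlopeTest:
    """ANCOVA with a kingdom-by-score interaction.

    ``interaction_p_value`` is the F-test of the full interaction model
    against the common-slope model; ``slopes`` holds each kingdom's own OLS
    slope.
    """

    slopes: dict
    interaction_p_value: float
    n_per_kingdom: dict
    trait: str = ""
    pc_index: int = 0


def kingdom_slope_test(pca: PCAResult, profiles, trait: str, pc_index: int,
                       stable_envs=(8,)) -> KingdomSlopeTest:
    """Test whether kingdoms share a common trait-vs-score slope."""
    import statsmodels.formula.api as smf

    profiles = list(profiles)
    y = _trait_values(profiles, trait, stable_envs)
    mask = np.isfinite(y)
    df = pd.DataFrame({
        "score": pca.scores[mask, pc_index - 1],
        "trait": y[mask],
        "kingdom": [p.meta.kingdom for i, p in enumerate(profiles) if mask[i]],
    })
    counts = df.groupby("kingdom").size()
    counts = counts[counts >= 3]
    if len(counts) < 2:
        raise InvariantError(
            "kingdom slope test requires >= 2 kingdoms with >= 3 trait-bearing "
            "organisms each; use regress_pc_vs_trait for a single kingdom"
        )
    df = df[df["kingdom"].isin(counts.index)]
    full = smf.ols("trait ~ score * C(kingdom)", data=df).fit()
    reduced = smf.ols("trait ~ score + C(kingdom)", data=df).fit()
    f_stat, p_value, _ = full.compare_f_test(reduced)
    slopes = {
        kingdom: trait_regression(sub["score"], sub["trait"]).slope
        for kingdom, sub in df.groupby("kingdom")
    }
    return KingdomSlopeTest(
        slopes=slopes, interaction_p_value=float(p_value),
        n_per_kingdom={k: int(v) for k, v in counts.items()},
        trait=trait, pc_index=pc_index,
    )
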
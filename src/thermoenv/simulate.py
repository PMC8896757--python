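"""Synthetic-data generators with known ground truth for every pipeline stage.

These generators emulate the statistical structure the analysis assumes:
per-residue TD vectors scattered isotropically around well-separated TE
cluster centers; proteomes whose TE usage follows kingdom-specific Dirichlet
distributions tilted along a stability gradient and a hydrophobicity-proxy
gradient; organism traits that are linear functions of planted frequency
contrasts plus Gaussian noise; secondary-structure labels sampled with
planted conditional enrichments; and stability records whose experimental dG
values come from a known additive model plus noise.  Every generator is
deterministic under a fixed seed and returns its ground truth alongside the
data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (
    N_ENVIRONMENTS,
    OrganismMeta,
    SSAnnotation,
    StabilityParams,
    StabilityRecord,
    TDTable,
    TECenterTable,
    TESequence,
)
from .errors import InvariantError
from .stability import predict_dG

__all__ = [
    "GeneratorConfig",
    "BASE_COMPOSITION",
    "STABILITY_GRADIENT",
    "HYDRO_GRADIENT",
    "default_stability_truth",
    "gen_center_table",
    "gen_protein_td",
    "gen_proteome_set",
    "SyntheticOrganism",
    "SyntheticProteomeSet",
    "gen_ss_labels",
    "planted_cell_conditional",
    "gen_stability_records",
]

#: Baseline native TE usage: peaked at the median-stability environments TE4
#: and TE5 (each >20% of a proteome, at least about twice any other TE) with
#: the extremes TE1 and TE8 rarest.
BASE_COMPOSITION = np.array([0.04, 0.075, 0.12, 0.24, 0.23, 0.115, 0.115, 0.065])

_k = np.arange(N_ENVIRONMENTS, dtype=float)
#: Unit-norm, zero-sum contrast increasing with environment stability rank.
STABILITY_GRADIENT = (_k - _k.mean()) / np.linalg.norm(_k - _k.mean())
_h = np.array([1.0, 0.5, 0.0, -0.5, -0.5, 0.0, 0.5, 1.0])
_h -= _h.mean()
#: Unit-norm, zero-sum contrast loading on the stability extremes, used as a
#: hydrophobicity proxy independent of the stability gradient.
HYDRO_GRADIENT = _h / np.linalg.norm(_h)

#: Kingdom tilt directions (coefficients on the two gradients).  Eukaryotes
#: sit apart from bacteria and archaea, archaea between the other two along
#: the hydrophobicity axis.
KINGDOM_TILTS = {
    "bacteria": (-1.0, 0.3),
    "archaea": (0.2, 1.0),
    "eukaryote": (1.0, -0.8),
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def default_stability_truth() -> StabilityParams:
    """Ground-truth parameters used by the stability-record generator.

    Weights decrease with stability rank so compositions enriched in stable
    TEs predict negative (stable) dG; the mean weight level offsets the
    uniform R*T*ln(20) per-residue entropic penalty so that structured
    proteins land clearly below zero and disordered ones above.
    """
    k = np.arange(1, N_ENVIRONMENTS + 1, dtype=float)
    return StabilityParams(
        w_native=3.69 - 0.45 * (k - 4.5),
        w_denatured=3.69 - 0.30 * (k - 4.5),
        z=20.0,
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for all synthetic generators.

    The defaults define the desk-scale analogue of the full study: three
    kingdoms of 30 organisms, ~25 proteins of 60-160 residues each, TE
    centers separated by 10 kJ/mol under the assignment metric with 1 kJ/mol
    isotropic TD scatter, kingdom compositions drawn from Dirichlet
    distributions with distinct means, and traits linear in frequency
    contrasts with Gaussian noise.
    """

    seed: int = 0
    kingdoms: tuple = ("bacteria", "archaea", "eukaryote")
    n_organisms_per_kingdom: int = 30
    n_proteins: int = 25
    length_range: tuple = (60, 160)
    center_separation: float = 10.0  # kJ/mol, minimum pairwise weighted-L1 gap
    td_scatter_sd: float = 1.0  # kJ/mol
    dirichlet_precision: float = 600.0
    kingdom_tilt: float = 0.05
    axis_spread: float = 0.0  # >0: rank-1 compositional variation along STABILITY_GRADIENT
    growth_temp_base: float = 34.0
    growth_temp_slope: float = 150.0  # degC per unit of HYDRO_GRADIENT . freq
    growth_temp_noise_sd: float = 2.0
    disorder_base: float = 0.18
    disorder_slope: float = 1.5  # per unit of STABILITY_GRADIENT . freq
    disorder_noise_sd: float = 0.015
    enrichment_matrix: np.ndarray | None = None
    ss_base_probs: tuple = (0.35, 0.22, 0.18, 0.25)  # helix, strand, turn, coil
    stability_noise_sd: float = 2.0

    def __post_init__(self):
        if self.td_scatter_sd < 0:
            raise InvariantError("td_scatter_sd must be nonnegative")
        if self.center_separation <= 0:
            raise InvariantError("center_separation must be positive")


def default_enrichment_matrix() -> np.ndarray:
    """Planted 4x8 log-enrichment pattern: helix/strand favored in stable TEs,
    turn/coil in unstable ones."""
    grad = (np.arange(1, 9) - 4.5) / 3.5
    return np.log(2.0) * np.outer([1.0, 0.8, -1.0, -0.8], grad)


# ---------------------------------------------------------------------------
# TE centers and per-protein TD tables

def gen_center_table(config: GeneratorConfig | None = None) -> TECenterTable:
    """Well-separated synthetic TE cluster centers.

    Native dG means decrease strictly with the environment index (TE1 least
    stable, TE8 most stable) and every coordinate trends monotonically, so
    the pairwise weighted-Manhattan separation grows linearly with index
    distance and is at least ``center_separation`` by construction (verified
    exhaustively).
    """
    config = config or GeneratorConfig()
    s = config.center_separation
    k = np.arange(N_ENVIRONMENTS, dtype=float)
    native = np.column_stack([
        12.0 - s * k,          # dG: +12 down to -58 at s=10
        10.0 - 0.4 * s * k,    # apolar enthalpy
        -20.0 + 0.3 * s * k,   # polar enthalpy
        15.0 - 0.2 * s * k,    # TdS_conf (weighted x3 in the metric)
    ])
    denatured = np.column_stack([
        8.0 - 0.8 * s * k,
        -15.0 + 0.35 * s * k,
        5.0 - 0.3 * s * k,
        25.0 - 0.25 * s * k,
    ])
    table = TECenterTable(native, denatured)
    for centers, weights in (
        (table.native_centers, table.native_term_weights),
        (table.denatured_centers, table.denatured_term_weights),
    ):
        diff = np.abs(centers[:, None, :] - centers[None, :, :]) @ weights
        off = diff[~np.eye(N_ENVIRONMENTS, dtype=bool)]
        if off.min() < s:
            raise InvariantError(
                f"requested separation {s} kJ/mol is infeasible "
                f"(achieved {off.min():.3f})"
            )
    return table


def _sample_td(labels: np.ndarray, centers: np.ndarray, sd: float,
               rng: np.random.Generator) -> np.ndarray:
    base = centers[labels - 1]
    if sd == 0:
        return base.copy()
    return base + rng.normal(0.0, sd, size=base.shape)


def gen_protein_td(length: int, centers: TECenterTable,
                   config: GeneratorConfig | None = None,
                   true_native=None, true_denatured=None,
                   rng: np.random.Generator | None = None,
                   protein_id: str = "synthetic") -> tuple[TDTable, TESequence]:
    """One protein's TD table: per-residue center plus isotropic Gaussian
    scatter, with the ground-truth TE labels returned alongside."""
    config = config or GeneratorConfig()
    if length < 1:
        raise InvariantError("length must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if true_native is None:
        true_native = rng.choice(np.arange(1, 9), size=length, p=BASE_COMPOSITION)
    else:
        true_native = np.asarray(true_native, dtype=int)
    if true_denatured is None:
        true_denatured = rng.choice(np.arange(1, 9), size=length, p=BASE_COMPOSITION)
    else:
        true_denatured = np.asarray(true_denatured, dtype=int)
    native_td = _sample_td(true_native, centers.native_centers, config.td_scatter_sd, rng)
    denatured_td = _sample_td(true_denatured, centers.denatured_centers,
                              config.td_scatter_sd, rng)
    sequence = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    table = TDTable.from_arrays(protein_id, sequence, native_td, denatured_td)
    truth = TESequence(protein_id, true_native, true_denatured)
    return table, truth


# ---------------------------------------------------------------------------
# Whole proteome sets

@dataclass
class SyntheticOrganism:
    meta: OrganismMeta
    target_freq: np.ndarray  # the organism's true native TE composition
    td_tables: list
    true_te: list  # ground-truth TESequence per protein


@dataclass
class SyntheticProteomeSet:
    organisms: list
    centers: TECenterTable
    truth: dict

    @property
    def metas(self) -> list:
        return [o.meta for o in self.organisms]


def kingdom_mean_composition(kingdom: str, config: GeneratorConfig) -> np.ndarray:
    a1, a2 = KINGDOM_TILTS[kingdom]
    mean = BASE_COMPOSITION + config.kingdom_tilt * (
        a1 * STABILITY_GRADIENT + a2 * HYDRO_GRADIENT
    )
    mean = np.clip(mean, 5e-3, None)
    return mean / mean.sum()


def gen_proteome_set(config: GeneratorConfig | None = None,
                     centers: TECenterTable | None = None,
                     emit_td: bool = True) -> SyntheticProteomeSet:
    """Kingdom-structured synthetic proteomes with planted traits.

    Each organism draws a target native TE composition from its kingdom's
    Dirichlet (or, when ``axis_spread`` > 0, varies along the stability
    gradient only, giving rank-1 compositional variation).  Proteins sample
    residue labels from the target composition; TD tables add Gaussian
    scatter around the centers.  Growth temperature and disorder fraction are
    planted linear functions of frequency contrasts plus noise; the planted
    slopes are recorded in ``truth``.  ``emit_td=False`` skips TD sampling
    and returns ground-truth TE sequences only (fast path).
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    if centers is None:
        centers = gen_center_table(config)
    organisms = []
    kingdom_means = {k: kingdom_mean_composition(k, config) for k in config.kingdoms}
    envs = np.arange(1, 9)
    for kingdom in config.kingdoms:
        mean = kingdom_means[kingdom]
        for i in range(config.n_organisms_per_kingdom):
            oid = f"{kingdom}_{i:02d}"
            if config.axis_spread > 0:
                t = rng.uniform(-1.0, 1.0)
                p = mean + t * config.axis_spread * STABILITY_GRADIENT
                p = np.clip(p, 1e-6, None)
                p = p / p.sum()
            else:
                p = rng.dirichlet(mean * config.dirichlet_precision)
            growth_temp = (
                config.growth_temp_base
                + config.growth_temp_slope * float(HYDRO_GRADIENT @ p)
                + rng.normal(0.0, config.growth_temp_noise_sd)
            )
            disorder = (
                config.disorder_base
                + config.disorder_slope * float(STABILITY_GRADIENT @ p)
                + rng.normal(0.0, config.disorder_noise_sd)
            )
            meta = OrganismMeta(
                oid, kingdom, growth_temp=float(growth_temp),
                disorder_fraction=float(np.clip(disorder, 0.0, 1.0)),
            )
            tables: list = []
            true_te: list = []
            lo, hi = config.length_range
            for j in range(config.n_proteins):
                length = int(rng.integers(lo, hi + 1))
                native = rng.choice(envs, size=length, p=p)
                denatured = rng.choice(envs, size=length, p=BASE_COMPOSITION)
                pid = f"{oid}_p{j:03d}"
                if emit_td:
                    table, truth_seq = gen_protein_td(
                        length, centers, config,
                        true_native=native, true_denatured=denatured,
                        rng=rng, protein_id=pid,
                    )
                    tables.append(table)
                else:
                    truth_seq = TESequence(pid, native, denatured)
                true_te.append(truth_seq)
            organisms.append(SyntheticOrganism(meta, p, tables, true_te))
    truth = {
        "kingdom_means": kingdom_means,
        "growth_temp": {
            "contrast": HYDRO_GRADIENT.copy(),
            "slope": config.growth_temp_slope,
            "intercept": config.growth_temp_base,
            "noise_sd": config.growth_temp_noise_sd,
        },
        "disorder_fraction": {
            "contrast": STABILITY_GRADIENT.copy(),
            "slope": config.disorder_slope,
            "intercept": config.disorder_base,
            "noise_sd": config.disorder_noise_sd,
        },
    }
    return SyntheticProteomeSet(organisms=organisms, centers=centers, truth=truth)


# ---------------------------------------------------------------------------
# Secondary-structure labels

def _conditional_from_enrichment(enrichment: np.ndarray, base: np.ndarray) -> np.ndarray:
    enrichment = np.asarray(enrichment, dtype=float)
    if enrichment.shape != (4, N_ENVIRONMENTS):
        raise InvariantError("enrichment matrix must be 4 x 8")
    raw = base[:, None] * np.exp(enrichment)
    norms = raw.sum(axis=0)
    if not np.all(np.isfinite(norms)) or np.any(norms <= 0):
        raise InvariantError("enrichment matrix yields non-normalizable conditionals")
    return raw / norms


def gen_ss_labels(te_seq: TESequence, enrichment_matrix=None,
                  config: GeneratorConfig | None = None,
                  conditional=None,
                  rng: np.random.Generator | None = None) -> tuple[SSAnnotation, dict]:
    """Sample per-residue DSSP codes with planted TE-conditional class odds.

    Classes are drawn from P(class | TE) proportional to
    base_probs * exp(enrichment); an explicit 4x8 ``conditional`` matrix
    overrides this.  Returns the annotation and a truth dict holding the
    conditional matrix actually used.
    """
    config = config or GeneratorConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    base = np.asarray(config.ss_base_probs, dtype=float)
    if conditional is not None:
        conditional = np.asarray(conditional, dtype=float)
        if conditional.shape != (4, N_ENVIRONMENTS) or np.any(conditional < 0):
            raise InvariantError("conditional must be a nonnegative 4 x 8 matrix")
        sums = conditional.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise InvariantError("conditional columns must each sum to 1")
    else:
        if enrichment_matrix is None:
            enrichment_matrix = (config.enrichment_matrix
                                 if config.enrichment_matrix is not None
                                 else default_enrichment_matrix())
        conditional = _conditional_from_enrichment(enrichment_matrix, base)
    # representative DSSP code per class: helix->H, strand->E, turn->T, coil->'-'
    codes = np.array(["H", "E", "T", "-"])
    labels = te_seq.native_labels - 1
    u = rng.random(len(te_seq))
    cum = np.cumsum(conditional, axis=0)  # (4, 8)
    idx = (u[:, None] > cum[:, labels].T).sum(axis=1)
    out = codes[idx]
    annotation = SSAnnotation(te_seq.protein_id, "".join(out))
    return annotation, {"conditional": conditional, "base_probs": base}


def planted_cell_conditional(te_probs, class_index: int = 0, te_index: int = 8,
                             log_enrichment: float = float(np.log(2.0)),
                             target_marginal: float = 0.2,
                             base=(0.35, 0.22, 0.18, 0.25)) -> np.ndarray:
    """Conditional class matrix whose realized log-odds at one cell is exact.

    Constructs P(class | TE) so that, with TE labels drawn from ``te_probs``,
    the marginal class probability equals ``target_marginal`` and
    P(class | TE = te_index) = exp(log_enrichment) * marginal - i.e. the
    planted cell's population log-odds is exactly ``log_enrichment``.  The
    remaining probability mass in each column is split over the other classes
    in proportion to ``base``.
    """
    te_probs = np.asarray(te_probs, dtype=float)
    p_k0 = float(te_probs[te_index - 1])
    q = float(np.exp(log_enrichment)) * target_marginal  # P(class | planted TE)
    if not 0 < q < 1:
        raise InvariantError("planted conditional probability must lie in (0, 1)")
    q_other = (target_marginal - p_k0 * q) / (1.0 - p_k0)
    if not 0 < q_other < 1:
        raise InvariantError(
            "infeasible planting: adjust target_marginal or the TE probabilities"
        )
    base = np.asarray(base, dtype=float)
    others = np.delete(np.arange(4), class_index)
    rest = base[others] / base[others].sum()
    conditional = np.empty((4, N_ENVIRONMENTS))
    for k in range(N_ENVIRONMENTS):
        cls_p = q if (k + 1) == te_index else q_other
        conditional[class_index, k] = cls_p
        conditional[others, k] = (1.0 - cls_p) * rest
    return conditional


# ---------------------------------------------------------------------------
# Stability records

#: Class tilt applied to BASE_COMPOSITION: structured proteins are enriched
#: in high-stability TEs, disordered ones in low-stability TEs.
_CLASS_TILT = 0.25


def _class_composition(class_label: str, state: str) -> np.ndarray:
    k = np.arange(1, N_ENVIRONMENTS + 1, dtype=float)
    sign = 1.0 if class_label == "structured" else -1.0
    strength = _CLASS_TILT if state == "native" else 0.7 * _CLASS_TILT
    mean = BASE_COMPOSITION * np.exp(sign * strength * (k - 4.5))
    return mean / mean.sum()


def gen_stability_records(n: int, stability_truth: StabilityParams | None = None,
                          noise_sd: float | None = None,
                          length_range: tuple = (50, 400),
                          config: GeneratorConfig | None = None,
                          class_labels=None,
                          length_matched_pairs: bool = False,
                          composition_precision: float = 60.0,
                          rng: np.random.Generator | None = None
                          ) -> tuple[list, StabilityParams]:
    """Synthetic stability records with dG from a known additive model.

    ``class_labels`` fixes each record's class ("structured"/"disordered");
    by default roughly 5 in 6 records are structured, echoing the mix of
    globular and disordered proteins in a typical training table.  With
    ``length_matched_pairs`` the generator emits n structured/disordered
    pairs of identical length (2n records).  Returns the records and the
    ground-truth parameters.
    """
    if n < 1:
        raise InvariantError("n must be >= 1")
    config = config or GeneratorConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth = stability_truth or default_stability_truth()
    if noise_sd is None:
        noise_sd = config.stability_noise_sd
    lo, hi = length_range
    records: list[StabilityRecord] = []

    def make_record(pid: str, class_label: str, length: int) -> StabilityRecord:
        nat_comp = rng.dirichlet(_class_composition(class_label, "native")
                                 * composition_precision)
        den_comp = rng.dirichlet(_class_composition(class_label, "denatured")
                                 * composition_precision)
        native = rng.multinomial(length, nat_comp)
        denatured = rng.multinomial(length, den_comp)
        record = StabilityRecord(pid, native, denatured, length, class_label=class_label)
        dg = predict_dG(record, truth) + rng.normal(0.0, noise_sd)
        return StabilityRecord(pid, native, denatured, length, dG_exp=dg,
                               class_label=class_label)

    if length_matched_pairs:
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            records.append(make_record(f"struct_{i:03d}", "structured", length))
            records.append(make_record(f"idp_{i:03d}", "disordered", length))
    else:
        if class_labels is None:
            n_disordered = max(1, round(n / 6)) if n >= 6 else 0
            class_labels = (["structured"] * (n - n_disordered)
                            + ["disordered"] * n_disordered)
        for i, label in enumerate(class_labels):
            length = int(rng.integers(lo, hi + 1))
            records.append(make_record(f"{label[:6]}_{i:03d}", label, length))
    return records, truth
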
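"""Per-protein profile comparisons: hydropathy windows and TE-delta tracks.

Sliding-window means are centered; at the termini the window shrinks
symmetrically (half-width limited by the distance to the nearer end) rather
than padding.  TE deltas are signed environment-index differences
(mutant - wild type) and are therefore antisymmetric under swapping the pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .containers import TESequence
from .errors import InvariantError

__all__ = [
    "KYTE_DOOLITTLE",
    "sliding_window_mean",
    "hydropathy_profile",
    "te_delta_profile",
    "DeltaProfile",
    "substitution_effect_distribution",
    "SubstitutionEffectSummary",
]


def sliding_window_mean(values, window: int) -> np.ndarray:
    """Centered moving average with symmetrically shrinking terminal windows.

    At position i the half-width is min(window//2, i, L-1-i), so the window is
    always centered on i and never extends past either terminus.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if window % 2 != 1 or window < 1:
        raise InvariantError(f"window length must be odd and positive, got {window}")
    if window > n:
        raise InvariantError(f"window length {window} exceeds sequence length {n}")
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


def hydropathy_profile(seq: str, scale: dict | None = None, window: int = 17) -> np.ndarray:
    """Windowed hydropathy of an amino-acid sequence.

    The default scale is Kyte-Doolittle; any per-residue dictionary may be
    substituted.  Unknown residues raise an error naming the position.
    """
    if scale is None:
        scale = KYTE_DOOLITTLE
    values = np.empty(len(seq))
    for i, aa in enumerate(seq):
        try:
            values[i] = scale[aa]
        except KeyError:
            raise InvariantError(
                f"residue {aa!r} at position {i + 1} is not in the hydropathy scale"
            ) from None
    return sliding_window_mean(values, window)


@dataclass
class DeltaProfile:
    """Positionwise signed TE change between a wild-type/mutant pair."""

    positions: np.ndarray  # 1-based
    raw_delta: np.ndarray  # environment steps, mutant - wild type
    window_mean: np.ndarray | None = None


def te_delta_profile(wt: TESequence, mut: TESequence, window: int | None = None,
                     state: str = "native") -> DeltaProfile:
    """Signed per-position TE difference (mutant - wild type).

    ``window`` adds a centered moving-average track with the same shrinking
    terminal convention as :func:`hydropathy_profile`.
    """
    if len(wt) != len(mut):
        raise InvariantError(
            f"wild-type and mutant TE sequences differ in length ({len(wt)} vs {len(mut)})"
        )
    if state == "native":
        delta = mut.native_labels.astype(int) - wt.native_labels.astype(int)
    elif state == "denatured":
        delta = mut.denatured_labels.astype(int) - wt.denatured_labels.astype(int)
    else:
        raise ValueError(f"unknown state {state!r}")
    window_mean = None if window is None else sliding_window_mean(delta, window)
    return DeltaProfile(
        positions=np.arange(1, len(wt) + 1),
        raw_delta=delta.astype(float),
        window_mean=window_mean,
    )


@dataclass
class SubstitutionEffectSummary:
    """Pooled distribution of per-pair signed environment changes."""

    mean: float
    variance: float  # population variance (ddof=0)
    histogram: dict  # effect value -> count
    effects: np.ndarray
    n_pairs: int


def substitution_effect_distribution(pairs, flank: int = 3,
                                     state: str = "native") -> SubstitutionEffectSummary:
    """Distribution of substitution consequences over wild-type/mutant pairs.

    Each pair contributes the sum of signed TE changes over the mutated
    position plus/minus ``flank`` residues (clipped at the termini) - local
    stability changes induced by a substitution often land on the neighbors
    of the mutated site rather than the site itself.
    """
    pairs = list(pairs)
    if not pairs:
        raise InvariantError("at least one wild-type/mutant pair is required")
    effects = np.empty(len(pairs))
    for idx, (wt, mut, position) in enumerate(pairs):
        profile = te_delta_profile(wt, mut, state=state)
        if not 1 <= position <= len(wt):
            raise InvariantError(
                f"pair {idx}: mutated position {position} outside 1..{len(wt)}"
            )
        lo = max(0, position - 1 - flank)
        hi = min(len(wt), position + flank)
        effects[idx] = profile.raw_delta[lo:hi].sum()
    values, counts = np.unique(effects, return_counts=True)
    return SubstitutionEffectSummary(
        mean=float(effects.mean()),
        variance=float(effects.var(ddof=0)),
        histogram={float(v): int(c) for v, c in zip(values, counts)},
        effects=effects,
        n_pairs=len(pairs),
    )
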
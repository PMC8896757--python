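"""Log-odds enrichment of secondary-structure classes within native TEs.

For class j and environment k the score is the pointwise mutual information

    score[j][k] = ln( P(j|k) / P(j) ) = ln( N * N_jk / (N_j * N_k) ),

evaluated over the 4 x 8 joint count table of DSSP-derived classes (helix =
H/G/I, strand = E/B, turn = T/S, coil = everything else) against native TE
labels.  Cells with a zero class or environment marginal are undefined (NaN);
a zero joint count with positive marginals scores -inf.  An optional
Haldane-style +0.5 pseudocount is available for small samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import N_ENVIRONMENTS, SS_CLASSES, dssp_class
from .errors import InvariantError

__all__ = ["group_dssp", "log_odds", "LogOddsMatrix", "SS_CLASSES"]

_CLASS_INDEX = {c: i for i, c in enumerate(SS_CLASSES)}


def group_dssp(code: str) -> str:
    """Coarse class of one DSSP code; unrecognised codes fall through to coil."""
    return dssp_class(code)


@dataclass
class LogOddsMatrix:
    """4 x 8 enrichment scores (natural-log units) with their count table."""

    scores: np.ndarray  # (4, 8), NaN where undefined
    counts: np.ndarray  # (4, 8) joint counts
    n_total: int
    class_totals: np.ndarray  # (4,)
    te_totals: np.ndarray  # (8,)
    classes: tuple = SS_CLASSES
    pseudocount: float = 0.0

    @classmethod
    def from_counts(cls, counts, pseudocount: float = 0.0) -> "LogOddsMatrix":
        """Evaluate the score for an explicit joint count table."""
        counts = np.asarray(counts, dtype=float)
        if counts.shape != (len(SS_CLASSES), N_ENVIRONMENTS):
            raise InvariantError("joint count table must be 4 x 8")
        if np.any(counts < 0):
            raise InvariantError("counts must be nonnegative")
        n_j = counts.sum(axis=1)
        n_k = counts.sum(axis=0)
        n = counts.sum()
        work = counts + pseudocount
        wj = work.sum(axis=1)
        wk = work.sum(axis=0)
        wn = work.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = np.log(wn * work / np.outer(wj, wk))
        if pseudocount == 0.0:
            undefined = (n_j[:, None] == 0) | (n_k[None, :] == 0)
            scores = np.where(undefined, np.nan, scores)
        return cls(
            scores=scores, counts=counts.astype(int), n_total=int(n),
            class_totals=n_j.astype(int), te_totals=n_k.astype(int),
            pseudocount=pseudocount,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=list(self.classes),
            columns=[f"TE{k}" for k in range(1, N_ENVIRONMENTS + 1)],
        )


def _class_indices(ss) -> np.ndarray:
    out = np.empty(len(ss), dtype=int)
    for i, label in enumerate(ss):
        if label in _CLASS_INDEX:
            out[i] = _CLASS_INDEX[label]
        elif isinstance(label, str) and len(label) == 1:
            out[i] = _CLASS_INDEX[dssp_class(label)]
        else:
            raise InvariantError(f"unrecognised secondary-structure label {label!r}")
    return out


def log_odds(ss, te, pseudocount: float = 0.0) -> LogOddsMatrix:
    """Log-odds matrix from aligned secondary-structure and native TE labels.

    ``ss`` may hold raw single-character DSSP codes or class names; ``te``
    holds integers 1..8.  The two tracks must be aligned and equal length.
    """
    te = np.asarray(te, dtype=int)
    if len(ss) != te.size:
        raise InvariantError(
            f"secondary-structure and TE tracks differ in length ({len(ss)} vs {te.size})"
        )
    if te.size == 0:
        raise InvariantError("labels must be nonempty")
    if te.min() < 1 or te.max() > N_ENVIRONMENTS:
        raise InvariantError("TE labels must lie in 1..8")
    j = _class_indices(ss)
    counts = np.zeros((len(SS_CLASSES), N_ENVIRONMENTS), dtype=int)
    np.add.at(counts, (j, te - 1), 1)
    return LogOddsMatrix.from_counts(counts, pseudocount=pseudocount)
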
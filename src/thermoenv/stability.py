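"""Additive TE model of global protein stability.

The predicted stability of a protein of length L with native TE counts NTE_i
and denatured TE counts DTE_j is

    dG = sum_i w_native[i] * NTE_i + sum_j w_denatured[j] * DTE_j
         - L * R * T * ln(Z),

in kJ/mol at T = 298.15 K, with Z the effective number of unfolded-state
conformations per residue.  More negative dG means more stable; proteins with
predicted dG above a threshold (default 0) are classified as intrinsically
disordered.

Identifiability
---------------
Because the counts obey sum_i NTE_i = sum_j DTE_j = L, shifting
w_native -> w_native + a, w_denatured -> w_denatured + b and
ln Z -> ln Z + (a + b)/(R*T) changes no prediction.  The expression is linear
in the weights and in ln Z, so fitting is an exact linear least-squares
problem with this two-parameter gauge freedom.  The default fit is
unconstrained and returns the deterministic minimum-norm solution, reporting
the design rank; ``gauge_fix=True`` pins mean(w_native) = mean(w_denatured)
= 0, which makes ln Z identifiable and parameters comparable across fits.
Fit quality should always be judged on predictions, which are gauge
invariant, never on raw parameters in the unconstrained gauge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .assign import te_counts
from .containers import (
    GAS_CONSTANT,
    N_ENVIRONMENTS,
    STANDARD_TEMPERATURE,
    StabilityParams,
    StabilityRecord,
    TESequence,
)
from .errors import InvariantError

__all__ = [
    "featurize",
    "predict_dG",
    "AdditiveStabilityModel",
    "StabilityFit",
    "fit_model",
    "loo_bootstrap",
    "LOOResult",
    "classify_structured",
]


def featurize(te_seq: TESequence, dG_exp: float | None = None,
              class_label: str | None = None) -> StabilityRecord:
    """TE count features of one protein."""
    native, denatured = te_counts(te_seq)
    return StabilityRecord(
        te_seq.protein_id, native, denatured, len(te_seq),
        dG_exp=dG_exp, class_label=class_label,
    )


def predict_dG(record: StabilityRecord, params: StabilityParams) -> float:
    """Predicted global stability in kJ/mol (more negative = more stable)."""
    if not params.z > 0:
        raise InvariantError(f"Z must be positive, got {params.z}")
    return float(
        record.native_counts @ params.w_native
        + record.denatured_counts @ params.w_denatured
        - record.length * params.rt * params.ln_z
    )


def _count_matrix(records) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([
        np.concatenate([r.native_counts, r.denatured_counts]) for r in records
    ], dtype=float)
    lengths = np.array([r.length for r in records], dtype=float)
    return X, lengths


def _predict_many(records, params: StabilityParams) -> np.ndarray:
    X, lengths = _count_matrix(records)
    w = np.concatenate([params.w_native, params.w_denatured])
    return X @ w - lengths * params.rt * params.ln_z


# mean-zero basis: columns of B span {w in R^8 : sum(w) = 0}
_B = np.vstack([np.eye(7), -np.ones((1, 7))])


@dataclass
class StabilityFit:
    """Results of a least-squares fit of the additive stability expression."""

    params: StabilityParams
    fitted: np.ndarray
    residuals: np.ndarray
    ssr: float
    rank: int
    n_obs: int
    gauge_fixed: bool
    fixed_z: float | None = None
    degenerate: bool = False

    @property
    def rmse(self) -> float:
        return float(np.sqrt(np.mean(self.residuals ** 2)))

    def predict(self, records) -> np.ndarray:
        return _predict_many(records, self.params)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Additive TE stability model",
            "=" * 44,
            f"n observations      {self.n_obs}",
            f"design rank         {self.rank}",
            f"gauge fixed         {self.gauge_fixed}",
            f"SSR (kJ/mol)^2      {self.ssr:.6g}",
            f"RMSE (kJ/mol)       {self.rmse:.6g}",
            f"Z (conf/residue)    {p.z:.6g}",
            f"R*T*ln(Z) (kJ/mol)  {p.rt * p.ln_z:.6g}",
            "",
            "TE   w_native   w_denatured  (kJ/mol per residue)",
        ]
        for k in range(N_ENVIRONMENTS):
            lines.append(f"{k + 1:>2}   {p.w_native[k]:>9.4f}   {p.w_denatured[k]:>10.4f}")
        if not self.gauge_fixed:
            lines.append("")
            lines.append(
                "note: unconstrained weights and Z share a gauge freedom; "
                "compare predictions, not raw parameters"
            )
        return "\n".join(lines)


class AdditiveStabilityModel:
    """Model object binding stability records with experimental dG values.

    ``fit`` solves the linear least-squares problem exactly;
    ``loo_bootstrap`` refits leaving each record out in turn and averages the
    fold parameters (weights elementwise, Z through its logarithm).
    """

    def __init__(self, records, min_records: int = 3):
        self.records = [r for r in records if r.dG_exp is not None]
        if len(self.records) < min_records:
            raise InvariantError(
                f"fitting requires at least {min_records} records with experimental dG, "
                f"got {len(self.records)}"
            )
        self.y = np.array([r.dG_exp for r in self.records], dtype=float)

    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "AdditiveStabilityModel":
        """Build from a dataframe with n1..n8, d1..d8, length, dG_exp columns."""
        records = []
        for _, row in df.iterrows():
            records.append(StabilityRecord(
                protein_id=str(row.get("protein_id", f"p{_}")),
                native_counts=[int(row[f"n{k}"]) for k in range(1, 9)],
                denatured_counts=[int(row[f"d{k}"]) for k in range(1, 9)],
                length=int(row["length"]),
                dG_exp=float(row["dG_exp"]),
            ))
        return cls(records, **kwargs)

    def fit(self, gauge_fix: bool = False, fixed_z: float | None = None,
            temperature: float = STANDARD_TEMPERATURE) -> StabilityFit:
        X, lengths = _count_matrix(self.records)
        rt = GAS_CONSTANT * temperature
        if fixed_z is not None:
            if not fixed_z > 0:
                raise InvariantError("fixed_z must be positive")
            design = X
            target = self.y + rt * np.log(fixed_z) * lengths
        elif gauge_fix:
            design = np.hstack([
                X[:, :8] @ _B, X[:, 8:] @ _B, (-rt * lengths)[:, None]
            ])
            target = self.y
        else:
            design = np.hstack([X, (-rt * lengths)[:, None]])
            target = self.y
        theta, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
        degenerate = rank < min(design.shape)
        if degenerate and not gauge_fix and fixed_z is None:
            # expected: the gauge freedom always leaves the 17-column design
            # rank-deficient; only warn when even the identifiable part is short
            if rank < 15 and len(self.records) >= 15:
                warnings.warn(
                    "stability design is rank-deficient beyond the gauge freedom; "
                    "minimum-norm (pseudo-inverse) weights returned",
                    stacklevel=2,
                )
        elif degenerate:
            warnings.warn(
                "degenerate stability design; minimum-norm (pseudo-inverse) "
                "weights returned",
                stacklevel=2,
            )
        if fixed_z is not None:
            w = theta
            ln_z = float(np.log(fixed_z))
        elif gauge_fix:
            w = np.concatenate([_B @ theta[:7], _B @ theta[7:14]])
            ln_z = float(theta[14])
        else:
            w = theta[:16]
            ln_z = float(theta[16])
        params = StabilityParams(
            w_native=w[:8], w_denatured=w[8:], z=float(np.exp(ln_z)),
            temperature=temperature,
        )
        fitted = _predict_many(self.records, params)
        residuals = self.y - fitted
        return StabilityFit(
            params=params, fitted=fitted, residuals=residuals,
            ssr=float(residuals @ residuals), rank=int(rank),
            n_obs=len(self.records), gauge_fixed=gauge_fix, fixed_z=fixed_z,
            degenerate=bool(degenerate),
        )

    def loo_bootstrap(self, **fit_kwargs) -> "LOOResult":
        n = len(self.records)
        if n < 4:
            raise InvariantError("leave-one-out bootstrapping requires at least 4 records")
        folds: list[StabilityFit | None] = []
        heldout = np.full(n, np.nan)
        failed: list[int] = []
        for i in range(n):
            subset = self.records[:i] + self.records[i + 1:]
            try:
                fit = AdditiveStabilityModel(subset).fit(**fit_kwargs)
            except (InvariantError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"fold {i} failed to converge: {exc}", stacklevel=2)
                folds.append(None)
                failed.append(i)
                continue
            folds.append(fit)
            heldout[i] = fit.predict([self.records[i]])[0]
        ok = [f for f in folds if f is not None]
        if not ok:
            raise InvariantError("every leave-one-out fold failed")
        temperature = ok[0].params.temperature
        averaged = StabilityParams(
            w_native=np.mean([f.params.w_native for f in ok], axis=0),
            w_denatured=np.mean([f.params.w_denatured for f in ok], axis=0),
            z=float(np.exp(np.mean([f.params.ln_z for f in ok]))),
            temperature=temperature,
        )
        mask = np.isfinite(heldout)
        heldout_residuals = self.y[mask] - heldout[mask]
        return LOOResult(
            fold_results=folds, averaged=averaged,
            heldout_predictions=heldout,
            heldout_rmse=float(np.sqrt(np.mean(heldout_residuals ** 2))),
            failed_folds=failed,
        )


@dataclass
class LOOResult:
    """Per-fold fits, their held-out predictions, and the averaged parameters."""

    fold_results: list
    averaged: StabilityParams
    heldout_predictions: np.ndarray
    heldout_rmse: float
    failed_folds: list = field(default_factory=list)


def fit_model(records, gauge_fix: bool = False, fixed_z: float | None = None,
              min_records: int = 3) -> StabilityFit:
    """Fit the additive stability expression to records with experimental dG."""
    return AdditiveStabilityModel(records, min_records=min_records).fit(
        gauge_fix=gauge_fix, fixed_z=fixed_z
    )


def loo_bootstrap(records, **fit_kwargs) -> LOOResult:
    """Leave-one-out bootstrapping: n fits, fold i excluding record i."""
    return AdditiveStabilityModel(records).loo_bootstrap(**fit_kwargs)


def classify_structured(dG_pred: float, threshold: float = 0.0) -> str:
    """Classify by predicted stability: above the threshold means disordered."""
    if not np.isfinite(dG_pred) or not np.isfinite(threshold):
        raise InvariantError("classification requires finite inputs")
    return "disordered" if dG_pred > threshold else "structured"
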
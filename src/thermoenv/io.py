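"""Readers and writers for the tabular and sequence formats the pipeline uses.

Dialects
--------
TD tables are tab-separated with header
``position aa dG_N dHap_N dHpol_N TdS_N dG_D dHap_D dHpol_D TdS_D`` and
energies in kJ/mol printed to 3 decimals.  TE tracks are FASTA-like, two
records per protein (``id|native`` and ``id|denatured``) whose bodies are
digit strings over 1..8.  Center tables are TSV with columns
``state env dG dHap dHpol TdS``.  Organism metadata is TSV with columns
``organism_id kingdom growth_temp disorder_fraction``; blank trait cells mean
"absent" and are never imputed.  All readers reject malformed input with an
error naming the file and line rather than repairing it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .containers import (
    KCAL_TO_KJ,
    N_ENVIRONMENTS,
    OrganismMeta,
    ProteomeProfile,
    StabilityParams,
    StabilityRecord,
    TDTable,
    TECenterTable,
    TESequence,
)
from .errors import FormatError, InvariantError

TD_COLUMNS = [
    "position", "aa",
    "dG_N", "dHap_N", "dHpol_N", "TdS_N",
    "dG_D", "dHap_D", "dHpol_D", "TdS_D",
]

META_COLUMNS = ["organism_id", "kingdom", "growth_temp", "disorder_fraction"]


# ---------------------------------------------------------------------------
# FASTA sequences

def read_fasta(path) -> list[tuple[str, str]]:
    """Read amino-acid sequences; uppercased, file order preserved."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FormatError("FASTA record with empty header", path=path)
        if not seq:
            raise FormatError(f"FASTA record {rec.id!r} has an empty sequence", path=path)
        records.append((rec.id, seq))
    return records


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n{seq}\n")


# ---------------------------------------------------------------------------
# TD tables

def read_td_table(path, protein_id: str | None = None) -> TDTable:
    """Read one protein's per-residue TD table (see module docstring dialect)."""
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise FormatError(f"unreadable TD table: {exc}", path=path) from exc
    if list(df.columns) != TD_COLUMNS:
        raise FormatError(
            f"TD table header must be {TD_COLUMNS}, got {list(df.columns)}",
            path=path, line=1,
        )
    if len(df) == 0:
        raise FormatError("TD table contains no residues", path=path)
    for col in TD_COLUMNS:
        if col == "aa":
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy())[0]
        if bad.size:
            raise FormatError(
                f"non-numeric value {df[col].iloc[bad[0]]!r} in column {col}",
                path=path, line=int(bad[0]) + 2,
            )
        df[col] = vals
    positions = df["position"].to_numpy()
    expected = np.arange(1, len(df) + 1)
    mism = np.nonzero(positions != expected)[0]
    if mism.size:
        raise FormatError(
            f"positions must be consecutive 1..L; expected {expected[mism[0]]}, "
            f"got {int(positions[mism[0]])}",
            path=path, line=int(mism[0]) + 2,
        )
    native = df[["dG_N", "dHap_N", "dHpol_N", "TdS_N"]].to_numpy(dtype=float)
    denatured = df[["dG_D", "dHap_D", "dHpol_D", "TdS_D"]].to_numpy(dtype=float)
    if not (np.all(np.isfinite(native)) and np.all(np.isfinite(denatured))):
        raise FormatError("TD table contains non-finite energies", path=path)
    return TDTable.from_arrays(protein_id, "".join(df["aa"]), native, denatured)


def write_td_table(table: TDTable, path) -> None:
    """Write a TD table; energies printed in kJ/mol to 3 decimals."""
    native = table.native_matrix
    denatured = table.denatured_matrix
    with open(path, "w") as fh:
        fh.write("\t".join(TD_COLUMNS) + "\n")
        for i, res in enumerate(table.residues):
            energies = np.concatenate([native[i], denatured[i]])
            fh.write(
                f"{res.position}\t{res.amino_acid}\t"
                + "\t".join(f"{e:.3f}" for e in energies)
                + "\n"
            )


# ---------------------------------------------------------------------------
# TE tracks (FASTA-like, digit bodies)

def write_te_sequence(te_seq: TESequence, path_or_handle) -> None:
    """Write one protein's TE tracks as two FASTA-like records of digits 1-8."""
    native = "".join(str(l) for l in te_seq.native_labels)
    denatured = "".join(str(l) for l in te_seq.denatured_labels)
    text = (
        f">{te_seq.protein_id}|native\n{native}\n"
        f">{te_seq.protein_id}|denatured\n{denatured}\n"
    )
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text)
    else:
        with open(path_or_handle, "w") as fh:
            fh.write(text)


def write_te_sequences(te_seqs, path) -> None:
    with open(path, "w") as fh:
        for seq in te_seqs:
            write_te_sequence(seq, fh)


def read_te_sequences(path) -> list[TESequence]:
    """Read TE tracks written by :func:`write_te_sequence`; order preserved."""
    tracks: dict[str, dict[str, np.ndarray]] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise FormatError(
                f"TE record id {rec.id!r} must be '<protein_id>|native' or "
                "'<protein_id>|denatured'", path=path,
            )
        protein_id, state = rec.id.rsplit("|", 1)
        body = str(rec.seq)
        if not body or not set(body) <= set("12345678"):
            raise FormatError(
                f"TE track for {rec.id!r} must be a nonempty string of digits 1-8",
                path=path,
            )
        if protein_id not in tracks:
            tracks[protein_id] = {}
            order.append(protein_id)
        tracks[protein_id][state] = np.array([int(c) for c in body])
    out = []
    for pid in order:
        t = tracks[pid]
        if set(t) != {"native", "denatured"}:
            raise FormatError(
                f"protein {pid!r} must have exactly a native and a denatured track",
                path=path,
            )
        out.append(TESequence(pid, t["native"], t["denatured"]))
    return out


# ---------------------------------------------------------------------------
# Organism metadata

def read_metadata_table(path) -> list[OrganismMeta]:
    """Read organism metadata; kingdoms normalised to lowercase."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in META_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise FormatError(f"metadata table lacks required columns {missing}", path=path, line=1)
    metas = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        kingdom = str(row["kingdom"]).strip().lower()
        try:
            meta = OrganismMeta(
                organism_id=str(row["organism_id"]).strip(),
                kingdom=kingdom,
                growth_temp=_optional_float(row.get("growth_temp"), path, line, "growth_temp"),
                disorder_fraction=_optional_float(
                    row.get("disorder_fraction"), path, line, "disorder_fraction"
                ),
            )
        except InvariantError as exc:
            raise FormatError(str(exc), path=path, line=line) from exc
        metas.append(meta)
    return metas


def _optional_float(value, path, line, name) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if s == "" or s.lower() in ("na", "nan"):
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise FormatError(f"non-numeric {name}: {s!r}", path=path, line=line) from exc


def write_metadata_table(metas, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(META_COLUMNS) + "\n")
        for m in metas:
            gt = "" if m.growth_temp is None else f"{m.growth_temp:g}"
            df_ = "" if m.disorder_fraction is None else f"{m.disorder_fraction:g}"
            fh.write(f"{m.organism_id}\t{m.kingdom}\t{gt}\t{df_}\n")


# ---------------------------------------------------------------------------
# TE center tables

def read_center_table(path, units: str = "kJ/mol",
                      native_term_weights=None, denatured_term_weights=None) -> TECenterTable:
    """Read the 16 TE cluster centers.

    ``units`` declares the file's energy unit ("kJ/mol" or "kcal/mol");
    kcal/mol values are converted on load so assignment always runs in kJ/mol.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = ["state", "env", "dG", "dHap", "dHpol", "TdS"]
    if list(df.columns) != required:
        raise FormatError(f"center table header must be {required}", path=path, line=1)
    if units == "kJ/mol":
        factor = 1.0
    elif units == "kcal/mol":
        factor = KCAL_TO_KJ
    else:
        raise FormatError(f"unknown energy unit {units!r}", path=path)
    centers = {}
    for state in ("N", "D"):
        sub = df[df["state"] == state].sort_values("env")
        if list(sub["env"]) != list(range(1, N_ENVIRONMENTS + 1)):
            raise FormatError(
                f"center table must contain environments 1..8 for state {state}", path=path
            )
        centers[state] = sub[["dG", "dHap", "dHpol", "TdS"]].to_numpy(dtype=float) * factor
    kwargs = {}
    if native_term_weights is not None:
        kwargs["native_term_weights"] = native_term_weights
    if denatured_term_weights is not None:
        kwargs["denatured_term_weights"] = denatured_term_weights
    return TECenterTable(centers["N"], centers["D"], **kwargs)


def write_center_table(centers: TECenterTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("state\tenv\tdG\tdHap\tdHpol\tTdS\n")
        for state, mat in (("N", centers.native_centers), ("D", centers.denatured_centers)):
            for k in range(N_ENVIRONMENTS):
                fh.write(
                    f"{state}\t{k + 1}\t" + "\t".join(f"{v:.4f}" for v in mat[k]) + "\n"
                )


# ---------------------------------------------------------------------------
# Proteome profiles

def write_profiles_table(profiles, path) -> None:
    cols = (["organism_id", "kingdom"]
            + [f"nfreq{k}" for k in range(1, 9)]
            + [f"dfreq{k}" for k in range(1, 9)]
            + ["n_proteins", "n_residues"])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for p in profiles:
            dfreq = p.denatured_freq if p.denatured_freq is not None else [np.nan] * 8
            row = ([p.organism_id, p.meta.kingdom]
                   + [f"{v:.12f}" for v in p.native_freq]
                   + [("" if np.isnan(v) else f"{v:.12f}") for v in np.asarray(dfreq, dtype=float)]
                   + [str(p.n_proteins), str(p.n_residues)])
            fh.write("\t".join(row) + "\n")


def read_profiles_table(path, metas=None) -> list[ProteomeProfile]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta_by_id = {m.organism_id: m for m in (metas or [])}
    profiles = []
    for _, row in df.iterrows():
        oid = str(row["organism_id"])
        meta = meta_by_id.get(oid) or OrganismMeta(oid, str(row["kingdom"]))
        nfreq = np.array([row[f"nfreq{k}"] for k in range(1, 9)], dtype=float)
        dfreq = np.array([row[f"dfreq{k}"] for k in range(1, 9)], dtype=float)
        profiles.append(ProteomeProfile(
            oid, nfreq, meta,
            denatured_freq=None if np.any(np.isnan(dfreq)) else dfreq,
            n_proteins=int(row["n_proteins"]), n_residues=int(row["n_residues"]),
        ))
    return profiles


# ---------------------------------------------------------------------------
# Stability records and fitted parameters

STABILITY_COLUMNS = (["protein_id"]
                     + [f"n{k}" for k in range(1, 9)]
                     + [f"d{k}" for k in range(1, 9)]
                     + ["length", "dG_exp", "class"])


def read_stability_records(path) -> list[StabilityRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != STABILITY_COLUMNS:
        raise FormatError(f"stability table header must be {STABILITY_COLUMNS}",
                          path=path, line=1)
    records = []
    for idx, row in df.iterrows():
        dg = row["dG_exp"]
        cls = row["class"]
        try:
            records.append(StabilityRecord(
                protein_id=str(row["protein_id"]),
                native_counts=[int(row[f"n{k}"]) for k in range(1, 9)],
                denatured_counts=[int(row[f"d{k}"]) for k in range(1, 9)],
                length=int(row["length"]),
                dG_exp=None if pd.isna(dg) else float(dg),
                class_label=None if pd.isna(cls) else str(cls),
            ))
        except (InvariantError, ValueError) as exc:
            raise FormatError(str(exc), path=path, line=int(idx) + 2) from exc
    return records


def write_stability_records(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(STABILITY_COLUMNS) + "\n")
        for r in records:
            dg = "" if r.dG_exp is None else f"{r.dG_exp:.4f}"
            cls = "" if r.class_label is None else r.class_label
            fh.write("\t".join(
                [r.protein_id]
                + [str(c) for c in r.native_counts]
                + [str(c) for c in r.denatured_counts]
                + [str(r.length), dg, cls]
            ) + "\n")


def save_stability_params(params: StabilityParams, path, provenance: dict | None = None) -> None:
    payload = params.to_dict()
    payload["provenance"] = provenance or {}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_stability_params(path) -> StabilityParams:
    with open(path) as fh:
        return StabilityParams.from_dict(json.load(fh))
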
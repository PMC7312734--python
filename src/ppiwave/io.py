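"""File formats and dataset filters.

Formats: FASTA for sequences; tab-separated pair lists
(``id_a  id_b  label``, label 1 = interacting); feature matrices as
TSV (one row per protein: id + 600 feature columns) or Parquet, both
carrying a layout-version marker that readers verify.

Dataset filters mirror the benchmark construction rules: sequences
shorter than 64 residues or longer than 1200 are dropped (closed
interval [64, 1200] kept), and pairs touching a dropped protein are
dropped with them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from ppiwave import LAYOUT_VERSION
from ppiwave.exceptions import InvalidInputError, ParseError
from ppiwave.pairs import PairRecord, label_from_int
from ppiwave.wavelets import (
    MAX_SEQUENCE_LENGTH,
    MIN_SEQUENCE_LENGTH,
    N_FEATURES,
    ProteinFeatureVector,
)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[tuple[str, str]]:
    """Ordered (id, sequence) records; wrapped lines joined.

    Duplicate ids and sequence data before the first header are
    rejected with the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ParseError("sequence data before first FASTA header",
                                 path=path, line=lineno)
            break
    records = []
    seen = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate sequence id {rec.id!r}", path=path)
        seen[rec.id] = True
        records.append((rec.id, str(rec.seq)))
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(records, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for pid, seq in records:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# length filters


@dataclass(frozen=True)
class FilterReport:
    """Audit of a length-filter pass."""

    kept_ids: tuple[str, ...]
    dropped: tuple[tuple[str, str], ...] = ()        # (id, reason)
    dropped_pairs: tuple[tuple[str, str, str], ...] = ()  # (id_a, id_b, reason)


def filter_by_length(
    records,
    min_len: int = MIN_SEQUENCE_LENGTH,
    max_len: int = MAX_SEQUENCE_LENGTH,
    pairs: list[PairRecord] | None = None,
):
    """Keep sequences with min_len <= L <= max_len (closed interval).

    Returns ``(kept_records, kept_pairs, report)``; ``kept_pairs`` is
    None when no pair list was given.  Pairs referencing a dropped
    protein are dropped and reported.
    """
    kept, dropped = [], []
    for pid, seq in records:
        L = len(seq)
        if L < min_len:
            dropped.append((pid, f"length {L} < {min_len}"))
        elif L > max_len:
            dropped.append((pid, f"length {L} > {max_len}"))
        else:
            kept.append((pid, seq))
    kept_ids = {pid for pid, _ in kept}
    kept_pairs = None
    dropped_pairs = []
    if pairs is not None:
        kept_pairs = []
        for p in pairs:
            missing = [x for x in (p.id_a, p.id_b) if x not in kept_ids]
            if missing:
                dropped_pairs.append(
                    (p.id_a, p.id_b, f"dropped protein(s): {', '.join(missing)}")
                )
            else:
                kept_pairs.append(p)
    report = FilterReport(
        kept_ids=tuple(pid for pid, _ in kept),
        dropped=tuple(dropped),
        dropped_pairs=tuple(dropped_pairs),
    )
    return kept, kept_pairs, report


# ---------------------------------------------------------------------------
# pair lists


def read_pairs(path) -> list[PairRecord]:
    """Tab-separated ``id_a  id_b  label`` with label 1|0; header optional."""
    path = Path(path)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:2] == ["id_a", "id_b"]:
                continue
            if len(parts) < 3:
                raise ParseError("expected 3 tab-separated columns",
                                 path=path, line=lineno)
            try:
                label = label_from_int(int(parts[2]))
            except (ValueError, InvalidInputError):
                raise ParseError(f"label must be 0 or 1, got {parts[2]!r}",
                                 path=path, line=lineno) from None
            out.append(PairRecord(id_a=parts[0], id_b=parts[1], label=label))
    return out


def write_pairs(pairs, path, origins=None) -> None:
    """Write a pair list; optional ``origins`` adds an fwd|bwd audit column."""
    with open(path, "w") as fh:
        cols = "id_a\tid_b\tlabel"
        if origins is not None:
            cols += "\torigin"
        fh.write(cols + "\n")
        for i, p in enumerate(pairs):
            row = f"{p.id_a}\t{p.id_b}\t{1 if p.interacting else 0}"
            if origins is not None:
                row += f"\t{origins[i]}"
            fh.write(row + "\n")


# ---------------------------------------------------------------------------
# feature matrices

_FEATURE_COLUMNS = [f"f{i:03d}" for i in range(N_FEATURES)]
_LAYOUT_KEY = "ppiwave_layout"


def write_features(features: list[ProteinFeatureVector], path) -> None:
    """One row per protein: id + 600 feature columns.

    ``.parquet`` writes the binary columnar form; anything else writes
    TSV with a layout-version comment header.
    """
    path = Path(path)
    df = pd.DataFrame(
        np.stack([f.values for f in features]), columns=_FEATURE_COLUMNS
    )
    df.insert(0, "protein_id", [f.protein_id for f in features])
    if path.suffix == ".parquet":
        df.attrs[_LAYOUT_KEY] = LAYOUT_VERSION
        import pyarrow, pyarrow.parquet  # noqa: F401
        table = pyarrow.Table.from_pandas(df, preserve_index=False)
        table = table.replace_schema_metadata(
            {**(table.schema.metadata or {}),
             _LAYOUT_KEY.encode(): LAYOUT_VERSION.encode()}
        )
        pyarrow.parquet.write_table(table, path)
    else:
        with open(path, "w") as fh:
            fh.write(f"# {_LAYOUT_KEY}={LAYOUT_VERSION}\n")
            df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_features(path) -> dict[str, ProteinFeatureVector]:
    """Read a feature matrix; rejects layout-version mismatches."""
    path = Path(path)
    if path.suffix == ".parquet":
        import pyarrow.parquet
        table = pyarrow.parquet.read_table(path)
        meta = table.schema.metadata or {}
        version = meta.get(_LAYOUT_KEY.encode(), b"").decode()
        df = table.to_pandas()
    else:
        with open(path) as fh:
            first = fh.readline().strip()
        if not first.startswith(f"# {_LAYOUT_KEY}="):
            raise ParseError("missing layout-version header", path=path, line=1)
        version = first.split("=", 1)[1]
        df = pd.read_csv(path, sep="\t", comment="#")
    if version != LAYOUT_VERSION:
        raise ParseError(
            f"feature layout {version!r} does not match reader {LAYOUT_VERSION!r}",
            path=path,
        )
    missing = [c for c in _FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing feature columns (first: {missing[0]})",
                         path=path)
    return {
        str(row["protein_id"]): ProteinFeatureVector(
            protein_id=str(row["protein_id"]),
            values=row[_FEATURE_COLUMNS].to_numpy(dtype=float),
        )
        for _, row in df.iterrows()
    }


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """Paths and bounds of one pipeline run."""

    fasta: Path | None = None
    pairs: Path | None = None
    features: Path | None = None
    model: Path | None = None
    report: Path | None = None
    min_len: int = MIN_SEQUENCE_LENGTH
    max_len: int = MAX_SEQUENCE_LENGTH
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.min_len <= self.max_len):
            raise InvalidInputError(
                f"bad length bounds [{self.min_len}, {self.max_len}]"
            )
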
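"""Readers and writers for the tabular and interval inputs.

All tabular formats are delimited text with a header (tab or comma,
auto-detected).  Interval files are BED-like: 0-based half-open,
tab-separated ``chrom  start  end  type``, header optional.  Gestational age
is stored internally in weeks; a ``gestational_age_days`` column (or the
``ga_in_days`` flag) triggers division by 7 at read time.  The preterm flag
is always derived from gestational age, never read from a file.
"""

from __future__ import annotations

import csv
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    GESTATIONAL_AGE_RANGE,
    CONSEQUENCES,
    DeNovoMutation,
    ExpressionMatrix,
    GeneAnnotation,
    GenomicInterval,
    ReplicationTimingTrack,
    TrioRecord,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

#: Canonical mapping from raw structural-variant type labels ("loss",
#: "gain", ...) to the two svtypes used throughout.
DEFAULT_SVTYPE_MAP = {
    "deletion": "deletion",
    "loss": "deletion",
    "duplication": "duplication",
    "gain": "duplication",
}


class FormatError(ValueError):
    """A file does not match the documented layout."""


def _read_table(path) -> pd.DataFrame:
    # sep=None sniffs tab vs comma; engine="python" is required for that.
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def _numeric(df: pd.DataFrame, column: str, path) -> np.ndarray:
    raw = df[column]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & (raw.str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        # +2: one for the header line, one for 1-based line numbering.
        raise FormatError(
            f"{path}: non-numeric value {raw.iloc[row]!r} in column "
            f"{column!r} at line {row + 2}"
        )
    return out.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Trios


def read_trios(path, ga_in_days: bool | None = None) -> list[TrioRecord]:
    """Read a trio table (family_id, paternal_age, maternal_age, GA).

    Gestational age is accepted in weeks (column ``gestational_age``) or in
    days (column ``gestational_age_days``, or ``ga_in_days=True``), converted
    by dividing by 7.  Values outside 20-45 weeks are rejected.
    """
    df = _read_table(path)
    ga_col = "gestational_age"
    if "gestational_age_days" in df.columns and "gestational_age" not in df.columns:
        ga_col = "gestational_age_days"
        if ga_in_days is None:
            ga_in_days = True
    _require_columns(df, ["family_id", "paternal_age", "maternal_age", ga_col], path)
    pat = _numeric(df, "paternal_age", path)
    mat = _numeric(df, "maternal_age", path)
    ga = _numeric(df, ga_col, path)
    if ga_in_days:
        ga = ga / 7.0
    lo, hi = GESTATIONAL_AGE_RANGE
    records = []
    for i, fam in enumerate(df["family_id"]):
        if not lo <= ga[i] <= hi:
            raise FormatError(
                f"{path}: gestational age {ga[i]:g} weeks out of range "
                f"[{lo:g}, {hi:g}] at line {i + 2}"
            )
        records.append(
            TrioRecord(
                family_id=str(fam),
                paternal_age=float(pat[i]),
                maternal_age=float(mat[i]),
                gestational_age=float(ga[i]),
            )
        )
    return records


def write_trios(records: Iterable[TrioRecord], path) -> None:
    rows = [
        {
            "family_id": r.family_id,
            "paternal_age": r.paternal_age,
            "maternal_age": r.maternal_age,
            "gestational_age": r.gestational_age,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Mutations


_OPTIONAL_MUTATION_COLUMNS = ("consequence", "cadd_phred", "gene", "parental_origin")


def read_mutations(path) -> list[DeNovoMutation]:
    """Read a de novo mutation table; no filtering happens at read time.

    ``consequence``, ``cadd_phred``, ``gene`` and ``parental_origin`` columns
    are optional.  Unknown consequence labels degrade to ``other`` with a
    logged warning so partially annotated inputs remain usable.
    """
    df = _read_table(path)
    _require_columns(df, ["subject_id", "chrom", "pos", "ref", "alt", "variant_class"], path)
    pos = _numeric(df, "pos", path)
    if not np.all(pos == np.floor(pos)):
        row = int(np.flatnonzero(pos != np.floor(pos))[0])
        raise FormatError(f"{path}: non-integer position at line {row + 2}")
    cadd = _numeric(df, "cadd_phred", path) if "cadd_phred" in df.columns else None
    unknown_consequences: set[str] = set()
    records = []
    for i in range(len(df)):
        consequence = "other"
        if "consequence" in df.columns:
            raw = df["consequence"].iloc[i].strip().lower()
            if raw in CONSEQUENCES:
                consequence = raw
            elif raw:
                unknown_consequences.add(raw)
        origin = "unknown"
        if "parental_origin" in df.columns:
            raw = df["parental_origin"].iloc[i].strip().lower()
            if raw in ("paternal", "maternal"):
                origin = raw
        gene = None
        if "gene" in df.columns:
            raw = df["gene"].iloc[i].strip()
            gene = raw.upper() or None
        c = None
        if cadd is not None and not math.isnan(cadd[i]):
            c = float(cadd[i])
        try:
            records.append(
                DeNovoMutation(
                    subject_id=str(df["subject_id"].iloc[i]),
                    chrom=df["chrom"].iloc[i],
                    pos=int(pos[i]),
                    ref=df["ref"].iloc[i].strip().upper(),
                    alt=df["alt"].iloc[i].strip().upper(),
                    variant_class=df["variant_class"].iloc[i].strip(),
                    consequence=consequence,
                    cadd_phred=c,
                    gene=gene,
                    parental_origin=origin,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
    if unknown_consequences:
        logger.warning(
            "%s: %d unknown consequence label(s) mapped to 'other': %s",
            path,
            len(unknown_consequences),
            ", ".join(sorted(unknown_consequences)),
        )
    return records


def write_mutations(records: Iterable[DeNovoMutation], path) -> None:
    rows = [
        {
            "subject_id": m.subject_id,
            "chrom": m.chrom,
            "pos": m.pos,
            "ref": m.ref,
            "alt": m.alt,
            "variant_class": m.variant_class,
            "consequence": m.consequence,
            "cadd_phred": "" if m.cadd_phred is None else m.cadd_phred,
            "gene": m.gene or "",
            "parental_origin": m.parental_origin,
        }
        for m in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene annotations


def read_gene_annotations(path) -> list[GeneAnnotation]:
    """Read a per-gene annotation table.

    Columns: ``gene`` (required); ``cnv_intolerance``, ``del_intolerance``,
    ``dup_intolerance`` (optional, blank = unscored); ``viability`` (optional,
    default ``unknown``); ``phenotype_terms`` (optional, ``;``-separated).
    """
    df = _read_table(path)
    _require_columns(df, ["gene"], path)
    scores = {}
    for col in ("cnv_intolerance", "del_intolerance", "dup_intolerance"):
        if col in df.columns:
            vals = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
            scores[col] = vals.to_numpy(dtype=float)
    records = []
    for i in range(len(df)):
        viability = "unknown"
        if "viability" in df.columns:
            raw = df["viability"].iloc[i].strip().lower()
            viability = raw if raw else "unknown"
        terms: frozenset[str] = frozenset()
        if "phenotype_terms" in df.columns:
            raw = df["phenotype_terms"].iloc[i].strip()
            if raw:
                terms = frozenset(t.strip() for t in raw.split(";") if t.strip())
        try:
            records.append(
                GeneAnnotation(
                    gene=df["gene"].iloc[i].strip().upper(),
                    cnv_intolerance=float(scores["cnv_intolerance"][i]) if "cnv_intolerance" in scores else float("nan"),
                    del_intolerance=float(scores["del_intolerance"][i]) if "del_intolerance" in scores else float("nan"),
                    dup_intolerance=float(scores["dup_intolerance"][i]) if "dup_intolerance" in scores else float("nan"),
                    viability=viability,
                    phenotype_terms=terms,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
    return records


def write_gene_annotations(records: Iterable[GeneAnnotation], path) -> None:
    def fmt(x: float) -> object:
        return "" if math.isnan(x) else x

    rows = [
        {
            "gene": g.gene,
            "cnv_intolerance": fmt(g.cnv_intolerance),
            "del_intolerance": fmt(g.del_intolerance),
            "dup_intolerance": fmt(g.dup_intolerance),
            "viability": g.viability,
            "phenotype_terms": ";".join(sorted(g.phenotype_terms)),
        }
        for g in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression matrices


def read_expression(path) -> ExpressionMatrix:
    """Read a gene x stage matrix whose header tags stages as ``label:epoch``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    epochs = {}
    stages = []
    for col in df.columns:
        if ":" not in col:
            raise FormatError(f"{path}: stage header {col!r} lacks an ':epoch' tag")
        label, epoch = col.rsplit(":", 1)
        stages.append(label)
        epochs[label] = epoch
    df.columns = stages
    df.index = [str(g).strip().upper() for g in df.index]
    return ExpressionMatrix(df.astype(float), epochs)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.columns = [f"{s}:{matrix.epochs[s]}" for s in df.columns]
    df.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Intervals


def _read_bedlike(path, n_fields: int) -> list[list[str]]:
    rows = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < n_fields:
                raise FormatError(f"{path}: line {lineno}: expected {n_fields} fields")
            # A header line is tolerated: second field non-numeric.
            if lineno == 1:
                try:
                    float(fields[1])
                except ValueError:
                    continue
            rows.append([lineno, *fields[:n_fields]])
    return rows


def read_intervals(path, svtype_map: Mapping[str, str] | None = None) -> list[GenomicInterval]:
    """Read a BED-like interval file (chrom, start, end, type).

    Coordinates are 0-based half-open.  Raw type labels are canonicalized via
    ``svtype_map`` (default: deletion/loss -> deletion, duplication/gain ->
    duplication); rows with unmapped types are dropped and counted in a
    logged message.
    """
    svtype_map = DEFAULT_SVTYPE_MAP if svtype_map is None else dict(svtype_map)
    intervals = []
    dropped = 0
    for lineno, chrom, start, end, rawtype in _read_bedlike(path, 4):
        try:
            s, e = int(start), int(end)
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: bad coordinates") from exc
        svtype = svtype_map.get(rawtype.strip().lower())
        if svtype is None:
            dropped += 1
            continue
        try:
            intervals.append(GenomicInterval(chrom=chrom, start=s, end=e, svtype=svtype))
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    if dropped:
        logger.info("%s: dropped %d row(s) with unmapped sv types", path, dropped)
    return intervals


def write_intervals(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for iv in intervals:
            w.writerow([iv.chrom, iv.start, iv.end, iv.svtype])


def read_timing_track(path) -> ReplicationTimingTrack:
    """Read a bedGraph-like replication-timing track (chrom, start, end, value)."""
    segments = []
    for lineno, chrom, start, end, value in _read_bedlike(path, 4):
        try:
            segments.append((chrom, int(start), int(end), float(value)))
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: bad segment") from exc
    return ReplicationTimingTrack(segments)


def read_gene_regions(path) -> pd.DataFrame:
    """Read gene coordinates (chrom, start, end, gene), 0-based half-open."""
    rows = []
    for _lineno, chrom, start, end, gene in _read_bedlike(path, 4):
        rows.append(
            {
                "chrom": normalize_chrom(chrom),
                "start": int(start),
                "end": int(end),
                "gene": gene.strip().upper(),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def write_gene_regions(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)
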
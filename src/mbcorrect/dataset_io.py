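"""Reading, writing, merging and augmenting single-point-mutation tables.

A mutation table has one row per single-point mutation: wild-type and
mutant residue, position, optional structure/chain identifiers, the
experimental stability change ddG (kcal/mol), and the base predictor's
score — either per-state scores (S_w, S_m) or a precomputed delta.

The canonical file dialect is UTF-8 CSV with a header row and columns
``id, structure_id, chain, position, wt, mut, ddg_exp, score_wt,
score_mut, score_delta``.  Other dialects are handled through a
:class:`ColumnMap`, including a compact mutation-string column
("A123V").  Positions are stored verbatim in the convention of the
source file — the model never uses them numerically.

The ddG sign convention is deliberately NOT normalized here: the
convention label travels as free text in dataset metadata, and fitting
is convention-agnostic because the model is linear.  Silently flipping
signs is the classic source of ddG-benchmark bugs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
import re
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd

from .errors import (
    DuplicateKeyError,
    FormatError,
    RecordError,
)
from .scales import validate_residue

logger = logging.getLogger(__name__)

#: Tolerance for the consistency check between score_delta and
#: score_mut - score_wt, in method units.
SCORE_CONSISTENCY_TOL = 1e-6

_MUTSTR_RE = re.compile(r"^\s*([A-Za-z])\s*(-?\d+)\s*([A-Za-z])\s*$")

CANONICAL_COLUMNS = (
    "id",
    "structure_id",
    "chain",
    "position",
    "wt",
    "mut",
    "ddg_exp",
    "score_wt",
    "score_mut",
    "score_delta",
)


@dataclass(frozen=True)
class MutationRecord:
    """One single-point mutation with experiment and base-method scores.

    ``score_delta`` is the base method's direct prediction S_m - S_w in
    its own units; per-state scores may be carried instead or as well.
    When all three score fields are present they must be mutually
    consistent to within :data:`SCORE_CONSISTENCY_TOL`.
    """

    record_id: str
    wt_aa: str
    mut_aa: str
    position: Optional[int] = None
    structure_id: Optional[str] = None
    chain: Optional[str] = None
    ddg_exp: Optional[float] = None
    score_wt: Optional[float] = None
    score_mut: Optional[float] = None
    score_delta: Optional[float] = None
    is_complement: bool = False

    def __post_init__(self):
        object.__setattr__(self, "wt_aa", validate_residue(self.wt_aa))
        object.__setattr__(self, "mut_aa", validate_residue(self.mut_aa))
        if (
            self.score_wt is not None
            and self.score_mut is not None
            and self.score_delta is not None
        ):
            implied = self.score_mut - self.score_wt
            if abs(self.score_delta - implied) > SCORE_CONSISTENCY_TOL:
                raise RecordError(
                    f"record {self.record_id!r}: score_delta={self.score_delta} "
                    f"inconsistent with score_mut-score_wt={implied}"
                )

    @property
    def key(self) -> tuple:
        """Identity key for merging: (structure_id, chain, position, wt, mut)."""
        return (self.structure_id, self.chain, self.position, self.wt_aa, self.mut_aa)

    def delta_score(self) -> Optional[float]:
        """The usable score delta: explicit if present, else S_m - S_w."""
        if self.score_delta is not None:
            return self.score_delta
        if self.score_wt is not None and self.score_mut is not None:
            return self.score_mut - self.score_wt
        return None

    def complement(self) -> "MutationRecord":
        """The antisymmetric complement: residues swapped, ddG and score delta negated.

        Per-state scores are swapped; the explicit delta is negated (the
        base method is not re-run on a mutant structure — an
        approximation appropriate to the retrofit setting, where only
        direct predictions exist).  Applying ``complement`` twice
        restores the original record apart from the provenance flag.
        """
        return dataclasses.replace(
            self,
            record_id=(
                self.record_id[: -len("_inv")]
                if self.is_complement and self.record_id.endswith("_inv")
                else self.record_id + "_inv"
            ),
            wt_aa=self.mut_aa,
            mut_aa=self.wt_aa,
            ddg_exp=None if self.ddg_exp is None else -self.ddg_exp,
            score_wt=self.score_mut,
            score_mut=self.score_wt,
            score_delta=None if self.score_delta is None else -self.score_delta,
            is_complement=not self.is_complement,
        )


@dataclass
class ParseReport:
    """Summary of a table parse: rows read, rows rejected and why."""

    n_read: int = 0
    n_rejected: int = 0
    rejections: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class MutationDataset:
    """Ordered collection of mutation records with free-text metadata.

    ``meta`` carries the base method's name, the ddG sign-convention
    label (stored, never interpreted) and a source label.
    """

    records: list[MutationRecord] = field(default_factory=list)
    meta: dict = field(default_factory=dict)
    parse_report: Optional[ParseReport] = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MutationRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def to_dataframe(self) -> pd.DataFrame:
        """Canonical-dialect DataFrame (one row per record, fixed columns)."""
        rows = [
            {
                "id": r.record_id,
                "structure_id": r.structure_id,
                "chain": r.chain,
                "position": r.position,
                "wt": r.wt_aa,
                "mut": r.mut_aa,
                "ddg_exp": r.ddg_exp,
                "score_wt": r.score_wt,
                "score_mut": r.score_mut,
                "score_delta": r.score_delta,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


@dataclass(frozen=True)
class ColumnMap:
    """Maps logical fields to column names of a concrete file dialect.

    Either ``mutation`` (compact string, e.g. "A123V") or the triple
    ``wt``/``mut``/``position`` must be provided.  Unset optional fields
    are simply absent from the parsed records.
    """

    mutation: Optional[str] = None
    wt: Optional[str] = "wt"
    mut: Optional[str] = "mut"
    position: Optional[str] = "position"
    id: Optional[str] = "id"
    structure_id: Optional[str] = "structure_id"
    chain: Optional[str] = "chain"
    ddg: Optional[str] = "ddg_exp"
    score_wt: Optional[str] = "score_wt"
    score_mut: Optional[str] = "score_mut"
    score_delta: Optional[str] = "score_delta"


CANONICAL_MAP = ColumnMap()


def parse_mutation_string(s: str) -> tuple[str, int, str]:
    """Parse a compact mutation string like "A123V" into (wt, position, mut)."""
    m = _MUTSTR_RE.match(s)
    if not m:
        raise RecordError(f"unparseable mutation string {s!r} (expected e.g. 'A123V')")
    wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
    return validate_residue(wt), pos, validate_residue(mut)


def _opt_float(value) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def _opt_str(value) -> Optional[str]:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    return s or None


def read_mutation_table(
    path,
    column_map: ColumnMap = CANONICAL_MAP,
    sep: Optional[str] = None,
    strict: bool = True,
    meta: Optional[dict] = None,
) -> MutationDataset:
    """Read a CSV/TSV mutation table into a validated dataset.

    ``sep`` defaults to tab for ``.tsv`` files and comma otherwise.
    In strict mode (default) any invalid row aborts the read with a
    :class:`RecordError` naming the offending rows; in lenient mode
    invalid rows are skipped, logged, and counted in the parse report.
    Training on silently dropped rows changes coefficients, hence the
    strict default.

    Raises
    ------
    FormatError
        A column named in the map and required (mutation identity) is
        absent from the file.
    """
    p = Path(path)
    if sep is None:
        sep = "\t" if p.suffix.lower() in (".tsv", ".tab") else ","
    try:
        # round_trip float parsing so read -> write -> read is lossless
        df = pd.read_csv(p, sep=sep, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse {p}: {exc}") from exc

    cm = column_map
    if cm.mutation is not None:
        required = [cm.mutation]
    else:
        required = [c for c in (cm.wt, cm.mut) if c is not None]
        if not required:
            raise FormatError("column map must define either 'mutation' or 'wt'/'mut'")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{p}: missing required column(s): {', '.join(missing)}")

    def col(name):
        return name if (name is not None and name in df.columns) else None

    report = ParseReport(n_read=len(df))
    records: list[MutationRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        try:
            if cm.mutation is not None:
                wt, pos, mut = parse_mutation_string(str(row_d[cm.mutation]))
            else:
                wt = str(row_d[cm.wt])
                mut = str(row_d[cm.mut])
                pos_raw = row_d.get(col(cm.position)) if col(cm.position) else None
                pos = None if pos_raw is None or (
                    isinstance(pos_raw, float) and math.isnan(pos_raw)
                ) else int(pos_raw)
            rec = MutationRecord(
                record_id=_opt_str(row_d.get(col(cm.id))) or f"row{i + 1}",
                wt_aa=wt,
                mut_aa=mut,
                position=pos,
                structure_id=_opt_str(row_d.get(col(cm.structure_id))) if col(cm.structure_id) else None,
                chain=_opt_str(row_d.get(col(cm.chain))) if col(cm.chain) else None,
                ddg_exp=_opt_float(row_d.get(col(cm.ddg))) if col(cm.ddg) else None,
                score_wt=_opt_float(row_d.get(col(cm.score_wt))) if col(cm.score_wt) else None,
                score_mut=_opt_float(row_d.get(col(cm.score_mut))) if col(cm.score_mut) else None,
                score_delta=_opt_float(row_d.get(col(cm.score_delta))) if col(cm.score_delta) else None,
            )
        except Exception as exc:
            report.n_rejected += 1
            report.rejections.append((i + 1, str(exc)))
            continue
        records.append(rec)

    if report.n_rejected and strict:
        detail = "; ".join(f"row {r}: {why}" for r, why in report.rejections[:10])
        raise RecordError(
            f"{p}: {report.n_rejected} invalid row(s) in strict mode: {detail}",
            rows=report.rejections,
        )
    if report.n_rejected:
        logger.warning(
            "%s: skipped %d invalid row(s) in lenient mode", p, report.n_rejected
        )
    logger.info("read %d records from %s (%d rejected)", len(records), p, report.n_rejected)
    ds = MutationDataset(records=records, meta=dict(meta or {}), parse_report=report)
    ds.meta.setdefault("source", str(p))
    return ds


def _atomic_write_text(path, text: str) -> None:
    p = Path(path)
    fd, tmp = tempfile.mkstemp(dir=p.parent or ".", prefix=p.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
        os.replace(tmp, p)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_mutation_table(ds: MutationDataset, path) -> None:
    """Write a dataset in the canonical CSV dialect (atomically).

    Floats are rendered with ``repr`` so that read -> write -> read is
    lossless.
    """
    df = ds.to_dataframe()
    text = df.to_csv(index=False, float_format=lambda x: repr(float(x)))
    _atomic_write_text(path, text)


def merge_datasets(
    primary: MutationDataset,
    secondary: MutationDataset,
    strict: bool = True,
) -> MutationDataset:
    """Union of two datasets with primary precedence on key collisions.

    Records are keyed by (structure_id, chain, position, wt, mut).  When
    the same mutation appears in both inputs, the record from
    ``primary`` is kept — the rule used to assemble a merged training
    set from two source benchmarks where the primary source's ddG value
    takes precedence.  A merge report (kept/overridden counts) lands in
    the output metadata.

    Duplicate keys *within* one input raise :class:`DuplicateKeyError`
    in strict mode; in lenient mode the first occurrence is kept with a
    warning.
    """

    def dedup(ds: MutationDataset, label: str) -> dict:
        out: dict = {}
        for rec in ds.records:
            if rec.key in out:
                if strict:
                    raise DuplicateKeyError(
                        f"duplicate key {rec.key} within {label} dataset"
                    )
                logger.warning("duplicate key %s in %s: keeping first", rec.key, label)
                continue
            out[rec.key] = rec
        return out

    prim = dedup(primary, "primary")
    sec = dedup(secondary, "secondary")

    overridden = sum(1 for k in sec if k in prim)
    merged = list(prim.values()) + [r for k, r in sec.items() if k not in prim]
    meta = {
        **secondary.meta,
        **primary.meta,
        "merge_report": {
            "n_primary": len(prim),
            "n_secondary": len(sec),
            "n_overridden_by_primary": overridden,
            "n_merged": len(merged),
        },
    }
    logger.info(
        "merged %d + %d records -> %d (%d secondary overridden)",
        len(prim), len(sec), len(merged), overridden,
    )
    return MutationDataset(records=merged, meta=meta)


def augment_antisymmetric(ds: MutationDataset) -> MutationDataset:
    """Append the antisymmetric complement of every record.

    For each mutation w->m with experimental ddG, adds the reverse
    mutation m->w with negated ddG (scores swapped, score delta
    negated).  Output size is exactly twice the input; complements are
    flagged in the record's provenance field.

    Raises
    ------
    RecordError
        Any input record lacking ``ddg_exp``.
    """
    missing = [r.record_id for r in ds.records if r.ddg_exp is None]
    if missing:
        raise RecordError(
            f"cannot augment: {len(missing)} record(s) lack ddg_exp "
            f"(first: {missing[:5]})"
        )
    out = list(ds.records) + [r.complement() for r in ds.records]
    meta = {**ds.meta, "augmented": True}
    return MutationDataset(records=out, meta=meta)


# -- model (de)serialization -------------------------------------------------

MODEL_SCHEMA_VERSION = 1


def save_model(model, path) -> None:
    """Serialize a fitted correction model to JSON (atomically).

    The document keys residue coefficients by one-letter code, so
    coefficient order is self-describing.  Floats round-trip exactly
    (JSON uses ``repr``).
    """
    doc = model.to_json_dict()
    doc["schema_version"] = MODEL_SCHEMA_VERSION
    _atomic_write_text(path, json.dumps(doc, indent=2, sort_keys=True) + "\n")


def load_model(path):
    """Load a model saved by :func:`save_model`.

    Raises :class:`FormatError` on truncated/invalid JSON or a schema
    version this code does not understand.
    """
    from .core import MBCModel  # deferred: core depends on this module

    p = Path(path)
    try:
        doc = json.loads(p.read_text(encoding="utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise FormatError(f"{p}: not a valid model file: {exc}") from exc
    if not isinstance(doc, dict):
        raise FormatError(f"{p}: model document must be a JSON object")
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise FormatError(
            f"{p}: unsupported model schema_version {version!r} "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    try:
        return MBCModel.from_json_dict(doc)
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{p}: malformed model document: {exc}") from exc
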
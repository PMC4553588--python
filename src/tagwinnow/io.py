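"""Readers and writers for the pipeline's tabular interchange formats.

Three small TSV dialects cover every external file:

* annotation TSV — one row per assembled contig with its top-hit annotation
  (``contig_id, length_bp, accession, gene_name, species, evalue,
  pct_coverage``);
* alignment TSV — one row per read-to-contig hit (``read_id, treatment,
  contig_id``); a read that hits several contigs occupies several rows;
* count TSV — a contig x treatment matrix of non-negative integer tag counts
  (``contig_id`` plus one column per treatment, control first).

SAM is accepted as an alternative alignment dialect via pysam; only
``(QNAME, RNAME)`` and the unmapped flag are consulted, so any aligner's
output can be fed in.

All readers validate strictly and raise :class:`~tagwinnow.errors.FormatError`
naming the offending row rather than silently repairing it.  Comma
thousands-separators (``1,969``) are accepted in numeric cells on read —
published tables print them — and are never written.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError

ANNOTATION_COLUMNS = [
    "contig_id",
    "length_bp",
    "accession",
    "gene_name",
    "species",
    "evalue",
    "pct_coverage",
]

ALIGNMENT_COLUMNS = ["read_id", "treatment", "contig_id"]

_EVALUE_RE = re.compile(r"^([0-9]*\.?[0-9]+)?[eE]([+-]?[0-9]+)$")


@dataclass(frozen=True)
class ContigRecord:
    """One assembled contig with its annotation and BLAST e-value."""

    contig_id: str
    length_bp: int
    accession: str | None
    gene_name: str = ""
    species: str = ""
    evalue: float = math.inf
    pct_coverage: int = 0


@dataclass
class AlignmentRecord:
    """One read: its treatment label and the set of contigs it hit."""

    read_id: str
    treatment: str
    contig_ids: set[str] = field(default_factory=set)


def parse_evalue(text: str) -> float:
    """Parse a BLAST e-value string, including the mantissa-less dialect.

    Accepts plain decimals (``0``, ``1e-50``), scientific notation with any
    case (``3E-88``), and the bare-exponent form some reports print
    (``E-68`` meaning ``1e-68``).
    """
    s = str(text).strip()
    if not s:
        raise FormatError("empty e-value")
    m = _EVALUE_RE.match(s)
    if m:
        mantissa = float(m.group(1)) if m.group(1) else 1.0
        value = mantissa * 10.0 ** int(m.group(2))
    else:
        try:
            value = float(s)
        except ValueError:
            raise FormatError(f"unparseable e-value {text!r}") from None
    if value < 0:
        raise FormatError(f"negative e-value {text!r}")
    return value


def _strip_thousands(cell: str) -> str:
    return cell.replace(",", "") if isinstance(cell, str) else cell


def _to_int(cell, *, what: str, row: object) -> int:
    raw = _strip_thousands(cell)
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise FormatError(f"non-numeric {what} {cell!r} in row {row}") from None
    if not float(value).is_integer():
        raise FormatError(f"non-integer {what} {cell!r} in row {row}")
    if value < 0:
        raise FormatError(f"negative {what} {cell!r} in row {row}")
    return int(value)


def read_annotation(path) -> pd.DataFrame:
    """Read a contig annotation table.

    Returns a DataFrame with :data:`ANNOTATION_COLUMNS`; ``accession`` is
    ``None`` for unannotated contigs, ``evalue`` is a float.  Duplicate
    contig ids and unparseable cells raise :class:`FormatError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation file {path} lacks columns {missing}")
    df = df[ANNOTATION_COLUMNS].copy()
    dupes = df["contig_id"][df["contig_id"].duplicated()]
    if len(dupes):
        raise FormatError(f"duplicate contig_id {dupes.iloc[0]!r} in {path}")
    out = pd.DataFrame(
        {
            "contig_id": df["contig_id"],
            "length_bp": [
                _to_int(v, what="length_bp", row=i) for i, v in df["length_bp"].items()
            ],
            "accession": [a if a.strip() else None for a in df["accession"]],
            "gene_name": df["gene_name"],
            "species": df["species"],
            "evalue": [
                _parse_evalue_row(v, i) for i, v in df["evalue"].items()
            ],
            "pct_coverage": [
                _to_int(v, what="pct_coverage", row=i) for i, v in df["pct_coverage"].items()
            ],
        }
    )
    bad_len = out["length_bp"] < 1
    if bad_len.any():
        raise FormatError(f"length_bp < 1 in row {out.index[bad_len][0]}")
    return out


def _parse_evalue_row(value: str, row: object) -> float:
    try:
        return parse_evalue(value)
    except FormatError as exc:
        raise FormatError(f"{exc} (row {row})") from None


def write_annotation(annotations: pd.DataFrame, path) -> None:
    annotations[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def contig_records(annotations: pd.DataFrame) -> list[ContigRecord]:
    """Materialise an annotation frame as :class:`ContigRecord` objects."""
    return [
        ContigRecord(
            contig_id=r.contig_id,
            length_bp=int(r.length_bp),
            accession=r.accession,
            gene_name=r.gene_name,
            species=r.species,
            evalue=float(r.evalue),
            pct_coverage=int(r.pct_coverage),
        )
        for r in annotations.itertuples(index=False)
    ]


def read_alignments(
    path,
    dialect: str = "tsv",
    treatments: list[str] | None = None,
    treatment: str | None = None,
) -> pd.DataFrame:
    """Read read-to-contig alignments as a hit table.

    Parameters
    ----------
    dialect
        ``"tsv"`` for the canonical 3-column table, ``"sam"`` for SAM input.
    treatments
        Declared treatment labels; rows with any other label raise
        :class:`FormatError`.
    treatment
        For SAM files without read groups: the label applied to every read.

    Returns a DataFrame with :data:`ALIGNMENT_COLUMNS`, one row per
    read-contig hit.  For SAM input, unmapped records are skipped and their
    count is attached as ``df.attrs["n_unmapped_skipped"]``.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in ALIGNMENT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"alignment file {path} lacks columns {missing}")
        df = df[ALIGNMENT_COLUMNS].copy()
    elif dialect == "sam":
        df = _read_sam(path, treatment=treatment)
    else:
        raise FormatError(f"unknown alignment dialect {dialect!r}")
    if treatments is not None:
        unknown = set(df["treatment"]) - set(treatments)
        if unknown:
            raise FormatError(f"unknown treatment label(s) {sorted(unknown)} in {path}")
    return df


def _read_sam(path, treatment: str | None) -> pd.DataFrame:
    import pysam

    rows = []
    skipped = 0
    rg_sample: dict[str, str] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rg in sam.header.to_dict().get("RG", []):
            rg_sample[rg.get("ID", "")] = rg.get("SM", rg.get("ID", ""))
        for rec in sam:
            if rec.is_unmapped:
                skipped += 1
                continue
            if treatment is not None:
                label = treatment
            else:
                try:
                    label = rg_sample.get(rec.get_tag("RG"))
                except KeyError:
                    label = None
                if label is None:
                    raise FormatError(
                        f"SAM record {rec.query_name} has no usable treatment label; "
                        "pass treatment= or add read groups"
                    )
            rows.append((rec.query_name, label, rec.reference_name))
    df = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    df.attrs["n_unmapped_skipped"] = skipped
    return df


def write_alignments(alignments: pd.DataFrame, path) -> None:
    alignments[ALIGNMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def alignment_records(alignments: pd.DataFrame) -> list[AlignmentRecord]:
    """Merge hit rows into one record per read (union of contigs hit).

    Rows sharing a ``read_id`` must share a treatment label; a read listed
    under two treatments raises :class:`FormatError`.
    """
    records: dict[str, AlignmentRecord] = {}
    for row in alignments.itertuples(index=False):
        rec = records.get(row.read_id)
        if rec is None:
            records[row.read_id] = AlignmentRecord(
                row.read_id, row.treatment, {row.contig_id}
            )
        else:
            if rec.treatment != row.treatment:
                raise FormatError(
                    f"read {row.read_id!r} appears under treatments "
                    f"{rec.treatment!r} and {row.treatment!r}"
                )
            rec.contig_ids.add(row.contig_id)
    return list(records.values())


def read_counts(path) -> pd.DataFrame:
    """Read a contig x treatment count matrix.

    The first column is ``contig_id`` (becomes the index); every other
    column is a treatment in file order (control first by convention).
    Cells must be non-negative integers; comma thousands-separators are
    accepted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "contig_id":
        raise FormatError(f"count file {path} must start with a contig_id column")
    if df.shape[1] < 2:
        raise FormatError(f"count file {path} has no treatment columns")
    dupes = df["contig_id"][df["contig_id"].duplicated()]
    if len(dupes):
        raise FormatError(f"duplicate contig_id {dupes.iloc[0]!r} in {path}")
    out = df.set_index("contig_id")
    for col in out.columns:
        out[col] = [
            _to_int(v, what=f"count ({col})", row=i) for i, v in out[col].items()
        ]
    return out.astype("int64")


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=True, index_label="contig_id")


def validate_counts(counts: pd.DataFrame) -> None:
    """Check CountMatrix invariants: unique rows, integer cells, all >= 0."""
    if counts.index.duplicated().any():
        raise FormatError("duplicate contig ids in count matrix")
    if counts.isna().any().any():
        raise FormatError("missing cells in count matrix")
    if not all(pd.api.types.is_integer_dtype(t) for t in counts.dtypes):
        raise FormatError("count matrix cells must be integers")
    if (counts < 0).any().any():
        raise FormatError("negative counts in count matrix")


def write_fasta(contigs: pd.DataFrame, path, sequences: dict[str, str] | None = None) -> None:
    """Write contig ids (and optional sequences) as FASTA.

    Synthetic catalogues carry no real sequence; a run of ``N`` of the
    annotated length is emitted so the file remains a valid FASTA.
    """
    with open(path, "w") as fh:
        for row in contigs.itertuples(index=False):
            seq = (sequences or {}).get(row.contig_id) or "N" * int(row.length_bp)
            fh.write(f">{row.contig_id}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
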
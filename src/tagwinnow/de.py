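"""Semi-quantitative fold-change differential expression on tag counts.

Expression is compared between conditions as a plain ratio of tag counts
(optionally per-million normalised first).  Two conventions are fixed by the
published worked examples this pipeline reproduces:

* zero-floor denominator — ``fold_change(n, d) = n / max(d, 1)``, so a
  transcript absent from the control (0 tags) but seen 19 times under
  elicitation reports a 19.0-fold induction rather than infinity; a zero
  numerator reports 0;
* report rounding — half-up, one decimal for ratios >= 1 and two decimals
  for ratios < 1 (down-regulation), computed exactly from the integer
  counts via ``decimal`` so printed values never suffer binary-float
  artefacts.

Regulation calls use an inclusive three-fold rule: ``up`` iff fold >=
threshold, ``down`` iff fold <= 1/threshold, else ``ns``.  Records whose
annotation e-value is not strictly below the cutoff (default 1e-5) are
flagged and excluded from summaries.  No replicate-based statistics are
computed: the method is a pure fold-change rule on pooled tag counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal, localcontext

import pandas as pd

from .errors import ConsistencyError, ParameterError

REGULATION_UP = "up"
REGULATION_DOWN = "down"
REGULATION_NS = "ns"


@dataclass(frozen=True)
class ComparisonSpec:
    """A numerator-vs-denominator treatment comparison."""

    numerator: str
    denominator: str

    def __post_init__(self):
        if self.numerator == self.denominator:
            raise ParameterError("comparison: numerator and denominator must differ")

    @property
    def label(self) -> str:
        return f"{self.numerator}_vs_{self.denominator}"


def default_comparisons(treatments) -> list[ComparisonSpec]:
    """Each elicited treatment vs control, then all ordered elicited pairs.

    For (control, bacterial, fungal) this yields bacterial/control,
    fungal/control, fungal/bacterial and bacterial/fungal — the four
    comparisons whose up/down tallies a three-condition elicitation study
    reports.
    """
    treatments = list(treatments)
    control, elicited = treatments[0], treatments[1:]
    specs = [ComparisonSpec(t, control) for t in elicited]
    specs += [ComparisonSpec(b, a) for a in elicited for b in elicited if a != b]
    return specs


def normalize(counts: pd.DataFrame, mode: str = "none") -> pd.DataFrame:
    """Scale a count matrix; ``per_million`` scales each column to 1e6 total."""
    if mode == "none":
        return counts.copy()
    if mode == "per_million":
        totals = counts.sum(axis=0)
        zero = totals[totals == 0]
        if len(zero):
            raise ParameterError(
                f"normalize: column(s) {list(zero.index)} sum to zero; per-million undefined"
            )
        return counts / totals * 1e6
    raise ParameterError(f"normalize: unknown mode {mode!r}")


def fold_change(numerator: float, denominator: float) -> float:
    """Tag-count ratio with the zero-floor denominator convention."""
    if numerator < 0 or denominator < 0:
        raise ConsistencyError("fold_change: counts must be non-negative")
    if numerator == 0:
        return 0.0
    return numerator / max(denominator, 1.0)


def report_decimals(fc: float) -> int:
    """Decimals used when printing a fold change: 1 for >= 1, 2 below 1."""
    return 1 if fc >= 1.0 else 2


def round_half_up(value, decimals: int) -> float:
    """Decimal ROUND_HALF_UP at the given precision.

    Floats go through their shortest repr, which recovers the intended
    decimal value of a count ratio (e.g. 166/40 -> "4.15" -> 4.2).
    """
    d = value if isinstance(value, Decimal) else Decimal(repr(float(value)))
    q = Decimal(1).scaleb(-decimals)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def rounded_fold_change(
    numerator: int, denominator: int, decimals: int | None = None
) -> float:
    """Report-rounded fold change computed exactly from integer counts."""
    fc = fold_change(numerator, denominator)
    if decimals is None:
        decimals = report_decimals(fc)
    if numerator == 0:
        return 0.0
    with localcontext() as ctx:
        ctx.prec = 40
        exact = Decimal(int(numerator)) / Decimal(int(max(denominator, 1)))
        return round_half_up(exact, decimals)


def format_fold(numerator: int, denominator: int) -> str:
    """Printed form of a fold change ("0" for an absent transcript)."""
    if numerator == 0:
        return "0"
    fc = fold_change(numerator, denominator)
    decimals = report_decimals(fc)
    return f"{rounded_fold_change(numerator, denominator, decimals):.{decimals}f}"


def classify(fc: float, fc_threshold: float = 3.0) -> str:
    """Three-fold regulation call: inclusive at both boundaries."""
    if fc_threshold <= 1.0:
        raise ParameterError("fc_threshold: must be > 1")
    if fc < 0:
        raise ConsistencyError("classify: fold change must be >= 0")
    if fc >= fc_threshold:
        return REGULATION_UP
    if fc <= 1.0 / fc_threshold:
        return REGULATION_DOWN
    return REGULATION_NS


def evalue_filter(records: pd.DataFrame, cutoff: float = 1e-5) -> pd.DataFrame:
    """Set ``passes_evalue`` (strict ``evalue < cutoff``) on a record frame."""
    out = records.copy()
    out["passes_evalue"] = out["evalue"] < cutoff
    return out


def de_table(
    counts: pd.DataFrame,
    annotations: pd.DataFrame,
    comparisons: list[ComparisonSpec] | None = None,
    fc_threshold: float = 3.0,
    evalue_cutoff: float = 1e-5,
    normalize_mode: str = "none",
) -> pd.DataFrame:
    """Build the per-contig differential-expression record table.

    One row per contig in ``counts`` with its counts, per-comparison fold
    change (``fc_<num>_vs_<den>``) and regulation call
    (``reg_<num>_vs_<den>``), annotation fields and the e-value flag.
    """
    if comparisons is None:
        comparisons = default_comparisons(counts.columns)
    for spec in comparisons:
        for t in (spec.numerator, spec.denominator):
            if t not in counts.columns:
                raise ConsistencyError(f"comparison treatment {t!r} not in count matrix")
    values = normalize(counts, normalize_mode)
    ann = annotations.set_index("contig_id")
    table = counts.copy()
    for spec in comparisons:
        fc = [
            fold_change(n, d)
            for n, d in zip(values[spec.numerator], values[spec.denominator])
        ]
        table[f"fc_{spec.label}"] = fc
        table[f"reg_{spec.label}"] = [classify(v, fc_threshold) for v in fc]
    for col in ("gene_name", "species", "length_bp", "pct_coverage", "evalue"):
        table[col] = ann[col].reindex(table.index)
    table = evalue_filter(table, evalue_cutoff)
    return table


def summarize(
    records: pd.DataFrame, comparisons: list[ComparisonSpec] | None = None
) -> pd.DataFrame:
    """Per-comparison up/down tallies over records passing the e-value filter."""
    if comparisons is None:
        labels = [
            c[len("reg_"):] for c in records.columns if c.startswith("reg_")
        ]
    else:
        labels = [spec.label for spec in comparisons]
    passing = records[records["passes_evalue"]] if "passes_evalue" in records else records
    rows = []
    for label in labels:
        reg = passing[f"reg_{label}"]
        rows.append(
            {
                "comparison": label,
                "n_up": int((reg == REGULATION_UP).sum()),
                "n_down": int((reg == REGULATION_DOWN).sum()),
            }
        )
    return pd.DataFrame(rows)
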
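"""Annotation-group construction, group-unique read filtering, and tallying.

Contigs sharing a top-hit accession form an *annotation group*: the unit
within which reads must map uniquely and within which winnowing later
operates.  A read is kept only if the set of groups touched by its hits has
size exactly one — reads touching two or more groups (plausibly shared or
conserved sequence) and reads hitting only unannotated contigs are dropped,
each tallied under its own reason.  Retained reads are tallied into the
contig x treatment count matrix; a read hitting several contigs of its one
group increments every one of them (no fractional assignment).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConsistencyError


@dataclass(frozen=True)
class FilterTally:
    """Partition of the read set by filtering outcome."""

    total: int
    retained: int
    excluded_multi_group: int
    excluded_no_group: int

    def __post_init__(self):
        if self.retained + self.excluded_multi_group + self.excluded_no_group != self.total:
            raise ConsistencyError("filter tally does not partition the read set")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reason": ["retained", "multi_group", "no_group", "total"],
                "reads": [
                    self.retained,
                    self.excluded_multi_group,
                    self.excluded_no_group,
                    self.total,
                ],
            }
        )


def group_by_accession(annotations: pd.DataFrame) -> tuple[dict[str, set[str]], int]:
    """Group contig ids by accession.

    Returns ``(groups, n_unannotated)``; contigs with no accession form no
    group and are counted instead.
    """
    annotated = annotations[annotations["accession"].notna()]
    groups = {
        acc: set(sub["contig_id"])
        for acc, sub in annotated.groupby("accession", sort=True)
    }
    return groups, int(len(annotations) - len(annotated))


def filter_unique_group_reads(
    alignments: pd.DataFrame,
    groups: dict[str, set[str]],
    known_contigs: set[str] | None = None,
) -> tuple[pd.DataFrame, FilterTally]:
    """Retain reads whose hits fall within one and only one annotation group.

    Parameters
    ----------
    alignments
        Hit table (``read_id, treatment, contig_id``), one row per hit.
    groups
        Accession -> contig-id sets from :func:`group_by_accession`.
    known_contigs
        Full contig universe; hits outside it raise
        :class:`ConsistencyError`.  When omitted, every aligned contig not
        in a group is treated as unannotated.

    Returns the retained hit rows and a :class:`FilterTally`.
    """
    contig_to_acc = {c: acc for acc, members in groups.items() for c in members}
    if known_contigs is not None:
        unknown = set(alignments["contig_id"]) - set(known_contigs)
        if unknown:
            raise ConsistencyError(
                f"alignments reference unknown contig id(s), e.g. {sorted(unknown)[:3]}"
            )
    if alignments.empty:
        return alignments.copy(), FilterTally(0, 0, 0, 0)

    acc = alignments["contig_id"].map(contig_to_acc)
    per_read = pd.DataFrame({"read_id": alignments["read_id"], "acc": acc})
    n_groups = per_read.groupby("read_id", sort=False)["acc"].nunique(dropna=True)

    total = int(n_groups.size)
    retained_ids = n_groups.index[n_groups == 1]
    no_group = int((n_groups == 0).sum())
    multi = int((n_groups > 1).sum())
    retained = alignments[alignments["read_id"].isin(set(retained_ids))].copy()
    tally = FilterTally(total, total - no_group - multi, multi, no_group)
    return retained, tally


def tally_counts(
    retained: pd.DataFrame,
    groups: dict[str, set[str]],
    treatments: list[str] | tuple[str, ...],
) -> pd.DataFrame:
    """Tally retained hits into a contig x treatment count matrix.

    Every grouped contig appears as a row (zero-filled when unhit);
    hits on unannotated contigs attract no counts.
    """
    grouped_contigs = sorted(c for members in groups.values() for c in members)
    index = pd.Index(grouped_contigs, name="contig_id")
    matrix = pd.DataFrame(0, index=index, columns=list(treatments), dtype="int64")
    if retained.empty:
        return matrix
    hits = retained[retained["contig_id"].isin(set(grouped_contigs))]
    stray = set(hits["treatment"]) - set(treatments)
    if stray:
        raise ConsistencyError(f"treatment(s) {sorted(stray)} not in declared treatments")
    pivot = (
        hits.groupby(["contig_id", "treatment"], sort=False)
        .size()
        .unstack(fill_value=0)
        .reindex(index=index, columns=list(treatments), fill_value=0)
    )
    return pivot.astype("int64")


def filter_and_tally(
    annotations: pd.DataFrame,
    alignments: pd.DataFrame,
    treatments: list[str] | tuple[str, ...],
) -> tuple[pd.DataFrame, FilterTally, dict[str, set[str]], int]:
    """Convenience composition: group, filter, tally.

    Returns ``(counts, tally, groups, n_unannotated_contigs)``.
    """
    groups, n_unannotated = group_by_accession(annotations)
    retained, tally = filter_unique_group_reads(
        alignments, groups, known_contigs=set(annotations["contig_id"])
    )
    counts = tally_counts(retained, groups, treatments)
    return counts, tally, groups, n_unannotated
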
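"""End-to-end driver: filter -> tally -> winnow -> fold change -> summarise.

A run is a pure function of its inputs and :class:`RunConfig`: repeated
runs write byte-identical outputs.  Every stage's product is written under
the output directory so any number in the final report can be recomputed
from the intermediates, and the run log records one line per stage with
its input/output record counts (the same kind of stage tallies a
transcriptome study reports: reads excluded by group-ambiguity, contigs
collapsed by winnowing, assemblies up/down per comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import de as de_mod
from . import io as io_mod
from .errors import ConsistencyError, ParameterError
from .grouping import FilterTally, filter_and_tally
from .winnow import WinnowResult, winnow_all

DE_TABLE_COLUMNS_DOC = (
    "section, gene_id, contig_id, counts per treatment with fold-change "
    "columns after each elicited treatment, then length, coverage, species "
    "and e-value — mirroring the layout of published tag-count tables"
)


@dataclass(frozen=True)
class RunConfig:
    """Serialisable parameter record for one pipeline run."""

    annotations: str
    out_dir: str
    alignments: str | None = None
    counts: str | None = None
    treatments: tuple[str, ...] = ("control", "bacterial", "fungal")
    r_threshold: float = 0.8
    fc_threshold: float = 3.0
    evalue_cutoff: float = 1e-5
    normalize: str = "none"
    seed: int = 0

    def validate(self) -> None:
        if not (-1.0 < self.r_threshold <= 1.0):
            raise ParameterError("r_threshold: must be in (-1, 1]")
        if self.fc_threshold <= 1.0:
            raise ParameterError("fc_threshold: must be > 1")
        if self.evalue_cutoff <= 0:
            raise ParameterError("evalue_cutoff: must be > 0")
        if self.normalize not in ("none", "per_million"):
            raise ParameterError(f"normalize: unknown mode {self.normalize!r}")
        if len(self.treatments) < 2:
            raise ParameterError("treatments: need control plus at least one elicitation")
        if self.alignments is None and self.counts is None:
            raise ParameterError("alignments: either alignments or counts must be given")

    @property
    def control(self) -> str:
        return self.treatments[0]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "treatments" in data:
            data["treatments"] = tuple(data["treatments"])
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class PipelineResult:
    """Bundle of every stage's product."""

    counts_raw: pd.DataFrame
    tally: FilterTally | None
    winnow: WinnowResult
    de: pd.DataFrame
    summary: pd.DataFrame
    log: list[str] = field(default_factory=list)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline and write all stage outputs.

    Stage order: read inputs -> group & filter reads -> tally counts ->
    winnow -> normalise -> fold change -> classify -> e-value filter ->
    summarise.  Any stage error aborts with the stage name prefixed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config: {config}"]

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    annotations = stage("read_annotation", io_mod.read_annotation, config.annotations)
    log.append(f"read_annotation: {len(annotations)} contigs")

    tally = None
    if config.counts is not None:
        counts = stage("read_counts", io_mod.read_counts, config.counts)
        missing = [t for t in config.treatments if t not in counts.columns]
        if missing:
            raise ConsistencyError(f"[stage read_counts] treatments {missing} not in matrix")
        counts = counts[list(config.treatments)]
        log.append(f"read_counts: {len(counts)} contigs x {counts.shape[1]} treatments")
    else:
        alignments = stage(
            "read_alignments",
            io_mod.read_alignments,
            config.alignments,
            treatments=list(config.treatments),
        )
        log.append(f"read_alignments: {len(alignments)} hits")
        counts, tally, groups, n_unannotated = stage(
            "filter_and_tally", filter_and_tally, annotations, alignments, config.treatments
        )
        log.append(
            "filter_unique_group_reads: "
            f"{tally.retained} retained, {tally.excluded_multi_group} multi-group, "
            f"{tally.excluded_no_group} no-group of {tally.total} reads "
            f"({n_unannotated} unannotated contigs formed no group)"
        )
        tally.as_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
    io_mod.write_counts(counts, out / "counts_raw.tsv")

    if config.counts is not None:
        # counts supplied directly: winnow whatever grouped contigs the matrix covers
        from .grouping import group_by_accession

        groups, _ = group_by_accession(annotations)
        groups = {
            acc: members & set(counts.index)
            for acc, members in groups.items()
            if members & set(counts.index)
        }

    result = stage("winnow", winnow_all, groups, counts, config.r_threshold)
    log.append(
        f"winnow: {len(counts)} contigs -> {result.n_survivors} survivors "
        f"({len(result.ledger)} collapsed) at r >= {config.r_threshold}"
    )
    io_mod.write_counts(result.counts, out / "counts_winnowed.tsv")
    result.ledger_frame().to_csv(out / "winnow_ledger.tsv", sep="\t", index=False)

    comparisons = de_mod.default_comparisons(config.treatments)
    table = stage(
        "differential_expression",
        de_mod.de_table,
        result.counts,
        annotations,
        comparisons=comparisons,
        fc_threshold=config.fc_threshold,
        evalue_cutoff=config.evalue_cutoff,
        normalize_mode=config.normalize,
    )
    log.append(f"differential_expression: {len(table)} records, {len(comparisons)} comparisons")
    summary = de_mod.summarize(table, comparisons)
    log.append(
        "summarize: "
        + "; ".join(
            f"{r.comparison}: {r.n_up} up / {r.n_down} down"
            for r in summary.itertuples(index=False)
        )
    )
    write_de_table(table, out / "de_table.tsv", treatments=config.treatments)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    config.to_yaml(out / "run_config.yaml")
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return PipelineResult(
        counts_raw=counts, tally=tally, winnow=result, de=table, summary=summary, log=log
    )


def write_de_table(records: pd.DataFrame, path, treatments=None) -> None:
    """Write the differential-expression report.

    Column order mirrors the published layout — gene, contig, control
    count, then each elicited treatment's count and report-rounded fold
    change, then contig length, coverage, species and e-value.  Rows are
    restricted to records passing the e-value filter and regulated in at
    least one vs-control comparison, split into an up section followed by
    a down section (a ``section`` column keeps the file a clean TSV).
    """
    if treatments is None:
        raise ParameterError("treatments: must be supplied to write_de_table")
    treatments = list(treatments)
    control, elicited = treatments[0], treatments[1:]
    vs_control = [f"{t}_vs_{control}" for t in elicited]

    passing = (
        records[records["passes_evalue"]] if "passes_evalue" in records.columns else records
    )
    out_rows = []
    for contig_id, row in passing.iterrows():
        regs = [row[f"reg_{label}"] for label in vs_control]
        if de_mod.REGULATION_UP in regs:
            section = "up-regulated"
        elif de_mod.REGULATION_DOWN in regs:
            section = "down-regulated"
        else:
            continue
        rec = {"section": section, "gene_id": row.get("gene_name", ""), "contig_id": contig_id,
               control: int(row[control])}
        for t, label in zip(elicited, vs_control):
            rec[t] = int(row[t])
            rec[f"{t}_fold_change"] = de_mod.format_fold(int(row[t]), int(row[control]))
        rec.update(
            {
                "length_bp": row.get("length_bp", ""),
                "pct_coverage": row.get("pct_coverage", ""),
                "species": row.get("species", ""),
                "evalue": row.get("evalue", ""),
            }
        )
        out_rows.append(rec)

    columns = (
        ["section", "gene_id", "contig_id", control]
        + [c for t in elicited for c in (t, f"{t}_fold_change")]
        + ["length_bp", "pct_coverage", "species", "evalue"]
    )
    frame = pd.DataFrame(out_rows, columns=columns)
    order = {"up-regulated": 0, "down-regulated": 1}
    if len(frame):
        frame = frame.sort_values(
            ["section", "gene_id"], key=lambda s: s.map(order) if s.name == "section" else s
        )
    frame.to_csv(path, sep="\t", index=False)


def taxonomy_tally(annotations: pd.DataFrame, taxon_map: dict[str, str]) -> pd.DataFrame:
    """Tally contigs per caller-supplied taxon label, descending.

    ``taxon_map`` maps contig ids to taxon labels (taxonomic resolution of
    BLAST hits is upstream of this artifact); unmapped contigs are counted
    under ``"unassigned"``.
    """
    labels = annotations["contig_id"].map(lambda c: taxon_map.get(c, "unassigned"))
    tally = labels.value_counts()
    return pd.DataFrame({"taxon": tally.index, "n_contigs": tally.to_numpy()})
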
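"""Ground-truthed simulator for redundant de novo transcriptome tag counts.

The generator emulates the statistical structure a winnowing + fold-change
pipeline has to cope with when the reference is a fragmented de novo
assembly of an immune-elicited insect transcriptome:

* each underlying transcript is annotated with one accession and assembles
  into one or more contig *fragments* sharing that accession (an annotation
  group);
* fragments inherit the parent transcript's expression profile across
  treatments, times a fragment-specific abundance weight and an optional
  per-treatment lognormal perturbation (``fragment_corr_noise``) that tunes
  the within-group profile correlation — at zero noise every group collapses
  to one survivor, at large noise none do;
* the design has one control plus elicited treatments (control is always the
  first label); per elicited treatment a fraction of transcripts is up- or
  down-regulated by ``effect_fold``;
* tag counts are Poisson at ``dispersion=0`` and gamma-mixed Poisson
  (negative binomial, variance ``mu + dispersion * mu**2``) otherwise;
* a tunable fraction of simulated reads aligns to contigs in more than one
  annotation group, exercising the group-uniqueness read filter;
* contig lengths are lognormal, floored at 101 bp, calibrated so that the
  default catalogue reproduces the ~391 bp median / ~765 bp mean of a short
  42-base-tag Velvet/Oases assembly.

All randomness flows from one root seed through ``numpy``'s
``SeedSequence``; identical parameters give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParameterError

DEFAULT_TREATMENTS = ("control", "bacterial", "fungal")

# lognormal length parameters solved from median 391 bp and mean 765 bp:
# exp(mu) = 391, exp(mu + s^2/2) = 765  =>  s = sqrt(2 ln(765/391))
LENGTH_LOG_MEAN = math.log(391.0)
LENGTH_LOG_SD = math.sqrt(2.0 * math.log(765.0 / 391.0))
MIN_CONTIG_LENGTH = 101


@dataclass(frozen=True)
class FragmentDist:
    """Distribution of contig fragments per transcript (support >= 1).

    ``kind="constant"`` gives exactly ``int(value)`` fragments;
    ``kind="shifted_poisson"`` gives ``1 + Poisson(value - 1)`` so the mean
    is ``value``.
    """

    kind: str = "shifted_poisson"
    value: float = 4.7

    def validate(self) -> None:
        if self.kind not in ("constant", "shifted_poisson"):
            raise ParameterError(f"fragments_per_transcript.kind: unknown kind {self.kind!r}")
        if self.value < 1:
            raise ParameterError("fragments_per_transcript.value: must be >= 1")
        if self.kind == "constant" and self.value != int(self.value):
            raise ParameterError("fragments_per_transcript.value: constant count must be integral")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "constant":
            return np.full(n, int(self.value), dtype=int)
        return 1 + rng.poisson(self.value - 1.0, size=n)


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one synthetic dataset.

    Defaults encode the three-condition elicitation design (control first,
    then bacterial and fungal cell-wall elicitations) at a depth that puts
    per-contig tag counts in the tens-to-thousands range of the published
    tables.  ``frac_up``/``frac_down`` apply per elicited treatment.
    """

    n_transcripts: int = 1000
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    mean_log_expression: float = 0.0
    sd_log_expression: float = 1.0
    frac_up: float = 0.05
    frac_down: float = 0.05
    effect_fold: float = 5.0
    fragments_per_transcript: FragmentDist = field(default_factory=FragmentDist)
    fragment_corr_noise: float = 0.25
    depth_per_treatment: float = 100_000.0
    dispersion: float = 0.1
    frac_ambiguous_reads: float = 0.2
    length_log_mean: float = LENGTH_LOG_MEAN
    length_log_sd: float = LENGTH_LOG_SD
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts < 1:
            raise ParameterError("n_transcripts: must be >= 1")
        if len(self.treatments) < 2:
            raise ParameterError("treatments: need at least a control and one elicitation")
        if len(set(self.treatments)) != len(self.treatments):
            raise ParameterError("treatments: labels must be unique")
        if self.sd_log_expression <= 0:
            raise ParameterError("sd_log_expression: must be > 0")
        for name in ("frac_up", "frac_down", "frac_ambiguous_reads"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}: must be in [0, 1]")
        if self.frac_up + self.frac_down > 1.0:
            raise ParameterError("frac_up: frac_up + frac_down must be <= 1")
        if self.effect_fold < 3.0:
            raise ParameterError("effect_fold: must be >= 3")
        if self.fragment_corr_noise < 0:
            raise ParameterError("fragment_corr_noise: must be >= 0")
        if self.depth_per_treatment < 0:
            raise ParameterError("depth_per_treatment: must be >= 0")
        if self.dispersion < 0:
            raise ParameterError("dispersion: must be >= 0")
        if self.length_log_sd <= 0:
            raise ParameterError("length_log_sd: must be > 0")
        self.fragments_per_transcript.validate()

    @property
    def control(self) -> str:
        return self.treatments[0]

    def with_seed(self, seed: int) -> "SimulationParams":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """What the generator knows and downstream stages must recover.

    ``transcripts`` is indexed by transcript accession and carries the true
    per-treatment expression plus a ``reg_<treatment>`` regulation class
    (``up``/``down``/``null``) per elicited treatment.  ``contig_map`` maps
    every generated contig to its parent accession with its fragment weight.
    ``contig_expression`` is the per-contig expected expression used for
    count sampling.  ``ambiguous_read_ids`` is populated by
    :func:`simulate_alignments`.
    """

    transcripts: pd.DataFrame
    contig_map: pd.DataFrame
    contig_expression: pd.DataFrame
    treatments: tuple[str, ...]
    ambiguous_read_ids: set[str] = field(default_factory=set)

    def regulation(self, treatment: str) -> pd.Series:
        return self.transcripts[f"reg_{treatment}"]


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_catalogue(params: SimulationParams) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a redundant annotated contig catalogue plus its ground truth.

    Returns ``(annotation frame, GroundTruth)``.  The annotation frame has
    the columns of the annotation TSV dialect; contigs from the same
    transcript share an accession.
    """
    params.validate()
    rng = _streams(params.seed, 3)[0]
    n = params.n_transcripts
    treatments = list(params.treatments)
    elicited = treatments[1:]

    accessions = np.array([f"GB{i:06d}" for i in range(n)])
    base = rng.lognormal(params.mean_log_expression, params.sd_log_expression, size=n)

    expr = {params.control: base}
    reg: dict[str, np.ndarray] = {}
    n_up = int(round(params.frac_up * n))
    n_down = int(round(params.frac_down * n))
    for t in elicited:
        classes = np.full(n, "null", dtype=object)
        perm = rng.permutation(n)
        classes[perm[:n_up]] = "up"
        classes[perm[n_up : n_up + n_down]] = "down"
        fold = np.where(
            classes == "up",
            params.effect_fold,
            np.where(classes == "down", 1.0 / params.effect_fold, 1.0),
        )
        expr[t] = base * fold
        reg[t] = classes

    n_frags = params.fragments_per_transcript.sample(n, rng)
    parent = np.repeat(np.arange(n), n_frags)
    n_contigs = parent.size
    frag_index = np.concatenate([np.arange(k) for k in n_frags])
    contig_ids = np.array(
        [f"{accessions[p]}.frag{j + 1}" for p, j in zip(parent, frag_index)]
    )

    # fragment abundance weights give distinct within-group totals;
    # the per-treatment perturbation de-correlates within-group profiles
    weights = rng.lognormal(0.0, 0.5, size=n_contigs)
    contig_expr = np.empty((n_contigs, len(treatments)))
    for j, t in enumerate(treatments):
        noise = (
            rng.lognormal(0.0, params.fragment_corr_noise, size=n_contigs)
            if params.fragment_corr_noise > 0
            else 1.0
        )
        contig_expr[:, j] = expr[t][parent] * weights * noise

    lengths = np.maximum(
        np.rint(rng.lognormal(params.length_log_mean, params.length_log_sd, size=n_contigs)),
        MIN_CONTIG_LENGTH,
    ).astype(int)
    evalues = 10.0 ** rng.uniform(-150.0, -6.0, size=n_contigs)
    coverage = rng.integers(20, 101, size=n_contigs)

    annotation = pd.DataFrame(
        {
            "contig_id": contig_ids,
            "length_bp": lengths,
            "accession": accessions[parent],
            "gene_name": [f"gene_{p:05d}" for p in parent],
            "species": "Heliothis virescens",
            "evalue": evalues,
            "pct_coverage": coverage,
        }
    )

    transcripts = pd.DataFrame(
        {"accession": accessions, **{f"expr_{t}": expr[t] for t in treatments}}
    ).set_index("accession")
    for t in elicited:
        transcripts[f"reg_{t}"] = reg[t]

    truth = GroundTruth(
        transcripts=transcripts,
        contig_map=pd.DataFrame(
            {"contig_id": contig_ids, "accession": accessions[parent], "weight": weights}
        ),
        contig_expression=pd.DataFrame(
            contig_expr, index=pd.Index(contig_ids, name="contig_id"), columns=treatments
        ),
        treatments=params.treatments,
    )
    return annotation, truth


def _scale(truth: GroundTruth, params: SimulationParams) -> float:
    """Tags per unit expression.

    One scale factor, anchored to the control column, is shared by all
    treatments so that the expected count ratio of a DE transcript equals
    its true expression fold exactly.
    """
    total = truth.contig_expression[params.control].sum()
    if total == 0:
        return 0.0
    return params.depth_per_treatment / total


def _sample_counts(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu)
    lam = np.zeros_like(mu)
    positive = mu > 0
    # gamma-mixed Poisson: var = mu + dispersion * mu^2
    lam[positive] = rng.gamma(1.0 / dispersion, dispersion * mu[positive])
    return rng.poisson(lam)


def simulate_counts(
    contigs: pd.DataFrame, truth: GroundTruth, params: SimulationParams
) -> pd.DataFrame:
    """Draw a contig x treatment tag-count matrix directly (no read level).

    Cell expectations are the true contig expression scaled so the control
    column totals ``depth_per_treatment``; noise is Poisson or gamma-mixed
    Poisson per :attr:`SimulationParams.dispersion`.
    """
    params.validate()
    rng = _streams(params.seed, 3)[2]
    lam = _scale(truth, params)
    mu = truth.contig_expression[list(params.treatments)].to_numpy() * lam
    counts = _sample_counts(mu, params.dispersion, rng)
    return pd.DataFrame(
        counts, index=truth.contig_expression.index.copy(), columns=list(params.treatments)
    ).astype("int64")


def simulate_alignments(
    contigs: pd.DataFrame, truth: GroundTruth, params: SimulationParams
) -> pd.DataFrame:
    """Generate a read-level hit table (``read_id, treatment, contig_id``).

    Each read carries one primary contig drawn with probability proportional
    to contig expression; a fraction ``frac_ambiguous_reads`` of reads gains
    one extra hit on a contig from a *different* annotation group, making
    the read span two groups.  Ambiguous read ids are recorded in
    ``truth.ambiguous_read_ids``.
    """
    params.validate()
    rng = _streams(params.seed, 3)[1]
    lam = _scale(truth, params)
    contig_index = truth.contig_expression.index.to_numpy()
    accession_of = truth.contig_map.set_index("contig_id")["accession"]
    acc_arr = accession_of.loc[contig_index].to_numpy()

    frames = []
    truth.ambiguous_read_ids = set()
    for t in params.treatments:
        mu = truth.contig_expression[t].to_numpy() * lam
        per_contig = _sample_counts(mu, params.dispersion, rng)
        n_reads = int(per_contig.sum())
        if n_reads == 0:
            continue
        primary = np.repeat(np.arange(len(contig_index)), per_contig)
        read_ids = np.array([f"{t}:{i}" for i in range(n_reads)])
        rows = pd.DataFrame(
            {"read_id": read_ids, "treatment": t, "contig_id": contig_index[primary]}
        )
        frames.append(rows)

        if params.frac_ambiguous_reads > 0 and len(set(acc_arr)) > 1:
            ambiguous = rng.random(n_reads) < params.frac_ambiguous_reads
            idx = np.flatnonzero(ambiguous)
            if idx.size:
                extra = rng.integers(0, len(contig_index), size=idx.size)
                # re-draw any extra hit that landed in the read's own group
                same = acc_arr[extra] == acc_arr[primary[idx]]
                while same.any():
                    extra[same] = rng.integers(0, len(contig_index), size=int(same.sum()))
                    same = acc_arr[extra] == acc_arr[primary[idx]]
                frames.append(
                    pd.DataFrame(
                        {
                            "read_id": read_ids[idx],
                            "treatment": t,
                            "contig_id": contig_index[extra],
                        }
                    )
                )
                truth.ambiguous_read_ids.update(read_ids[idx])

    if not frames:
        return pd.DataFrame(columns=["read_id", "treatment", "contig_id"])
    return pd.concat(frames, ignore_index=True)


def write_ground_truth(truth: GroundTruth, transcripts_path, contig_map_path) -> None:
    """Persist the ground truth as two TSVs (transcript table, contig map)."""
    truth.transcripts.to_csv(transcripts_path, sep="\t")
    truth.contig_map.to_csv(contig_map_path, sep="\t", index=False)
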
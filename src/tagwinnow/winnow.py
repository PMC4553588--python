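"""Recursive correlation-based winnowing of redundant contigs.

A de novo assembly of short tags splinters one transcript into several
contig fragments that share an annotation accession and, being pieces of
the same mRNA, show near-identical expression profiles across treatments.
Winnowing removes that redundancy: within each annotation group, whenever
two contigs' per-treatment count profiles correlate at ``r >= r_threshold``
(default 0.8, inclusive), the member with the greater total number of hits
is retained and the other is dropped, recursively, until every survivor has
a distinct combination of annotation and expression.

The order of collapses can matter when correlations chain (A~B, B~C but not
A~C), so a canonical deterministic order is imposed: the highest-r pair is
collapsed first, ties broken by larger combined hit total and then by
lexicographic contig-id pair; within a pair, a hit-total tie drops the
lexicographically larger id.  Identical inputs therefore yield identical
ledgers regardless of row order.

Correlation is plain Pearson product-moment on raw counts.  Profiles with
zero variance make Pearson undefined: two *identical* profiles are treated
as r = 1 (they are redundant by any reading), otherwise the undefined value
never reaches the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ParameterError


@dataclass(frozen=True)
class ExpressionProfile:
    """One contig's ordered per-treatment counts (control first)."""

    contig_id: str
    counts: tuple[float, ...]

    @property
    def total_hits(self) -> float:
        return sum(self.counts)


@dataclass
class GroupWinnow:
    """Winnowing outcome for one annotation group."""

    survivors: list[str]
    ledger: list[tuple[str, str, float]]  # (dropped_id, absorbed_by_id, r)
    rounds: int


@dataclass
class WinnowResult:
    """Survivors and collapse ledger over all groups.

    ``ledger`` maps each dropped contig to ``(absorbed_by, r at collapse)``;
    following it always terminates at a survivor (it is acyclic by
    construction).
    """

    survivors: dict[str, list[str]]
    ledger: dict[str, tuple[str, float]]
    rounds: dict[str, int]
    counts: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_survivors(self) -> int:
        return sum(len(v) for v in self.survivors.values())

    def resolve(self, contig_id: str) -> str:
        """Follow the ledger from a dropped contig to its surviving representative."""
        seen = set()
        while contig_id in self.ledger:
            if contig_id in seen:
                raise ConsistencyError(f"cyclic ledger at {contig_id!r}")
            seen.add(contig_id)
            contig_id = self.ledger[contig_id][0]
        return contig_id

    def ledger_frame(self) -> pd.DataFrame:
        rows = sorted(self.ledger.items())
        return pd.DataFrame(
            {
                "dropped_id": [d for d, _ in rows],
                "absorbed_by_id": [k for _, (k, _r) in rows],
                "r_at_collapse": [r for _, (_k, r) in rows],
            }
        )


def pearson_r(a, b) -> float | None:
    """Pearson product-moment correlation of two equal-length count vectors.

    Returns ``None`` (undefined) when either vector has zero variance,
    except that two identical vectors give 1.0.  Vectors must have length
    >= 2.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ConsistencyError(f"profile length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ConsistencyError("profiles need at least two treatments")
    if np.array_equal(x, y):
        return 1.0
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(dx @ dx)
    sy = float(dy @ dy)
    if sx == 0.0 or sy == 0.0:
        return None
    r = float(dx @ dy) / math.sqrt(sx * sy)
    return max(-1.0, min(1.0, r))


def _pair_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise Pearson r with the zero-variance convention.

    Undefined entries are encoded as ``-inf`` so they never reach any
    threshold in (-1, 1].
    """
    n = X.shape[0]
    centered = X - X.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", centered, centered)
    R = np.full((n, n), -np.inf)
    ok = ss > 0
    if ok.any():
        C = centered[ok] @ centered[ok].T
        denom = np.sqrt(np.outer(ss[ok], ss[ok]))
        R[np.ix_(ok, ok)] = np.clip(C / denom, -1.0, 1.0)
    # identical profiles correlate at 1 by convention, variance or not
    for i in range(n):
        for j in range(i + 1, n):
            if np.array_equal(X[i], X[j]):
                R[i, j] = R[j, i] = 1.0
    np.fill_diagonal(R, 1.0)
    return R


def _validate_threshold(r_threshold: float) -> None:
    if not (-1.0 < r_threshold <= 1.0):
        raise ParameterError("r_threshold: must be in (-1, 1]")


def winnow_group(profiles: pd.DataFrame, r_threshold: float = 0.8) -> GroupWinnow:
    """Winnow one annotation group.

    ``profiles`` is a contig x treatment count frame for the group's
    members.  Greedy collapse: while any pair correlates at or above the
    threshold, collapse the maximal-r pair (ties: larger combined hit
    total, then lexicographic id pair), dropping the lower-hit member
    (tie: lexicographically larger id).
    """
    _validate_threshold(r_threshold)
    if profiles.index.duplicated().any():
        raise ConsistencyError("duplicate contig ids in group profiles")
    order = np.argsort(profiles.index.to_numpy())
    ids = profiles.index.to_numpy()[order]
    X = profiles.to_numpy(dtype=float)[order]
    totals = X.sum(axis=1)
    n = len(ids)
    if n == 1:
        return GroupWinnow(survivors=[str(ids[0])], ledger=[], rounds=0)

    R = _pair_matrix(X)
    active = list(range(n))
    ledger: list[tuple[str, str, float]] = []
    rounds = 0
    while True:
        best = None  # (r, combined_total, i, j); ids already lexicographic by index
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                r = R[i, j]
                if r < r_threshold:
                    continue
                combined = totals[i] + totals[j]
                if (
                    best is None
                    or r > best[0]
                    or (r == best[0] and combined > best[1])
                    or (r == best[0] and combined == best[1] and (ids[i], ids[j]) < (ids[best[2]], ids[best[3]]))
                ):
                    best = (r, combined, i, j)
        if best is None:
            break
        r, _, i, j = best
        # keep the member with more hits; tie -> keep the lexicographically smaller id
        if totals[i] > totals[j] or (totals[i] == totals[j] and ids[i] < ids[j]):
            keep, drop = i, j
        else:
            keep, drop = j, i
        ledger.append((str(ids[drop]), str(ids[keep]), float(r)))
        active.remove(drop)
        rounds += 1

    return GroupWinnow(survivors=[str(ids[i]) for i in active], ledger=ledger, rounds=rounds)


def winnow_all(
    groups: dict[str, set[str]],
    counts: pd.DataFrame,
    r_threshold: float = 0.8,
) -> WinnowResult:
    """Winnow every annotation group independently.

    ``counts`` must cover every grouped contig; the returned matrix is the
    input restricted to survivors (survivors keep their own counts — the
    retained member is kept, dropped members are not summed in).
    """
    _validate_threshold(r_threshold)
    survivors: dict[str, list[str]] = {}
    ledger: dict[str, tuple[str, float]] = {}
    rounds: dict[str, int] = {}
    for acc in sorted(groups):
        members = sorted(groups[acc])
        missing = [m for m in members if m not in counts.index]
        if missing:
            raise ConsistencyError(
                f"group {acc!r} member(s) missing from count matrix: {missing[:3]}"
            )
        gw = winnow_group(counts.loc[members], r_threshold=r_threshold)
        survivors[acc] = gw.survivors
        rounds[acc] = gw.rounds
        for dropped, kept, r in gw.ledger:
            ledger[dropped] = (kept, r)
    keep = set().union(*survivors.values()) if survivors else set()
    winnowed = counts.loc[[c for c in counts.index if c in keep]].copy()
    return WinnowResult(survivors=survivors, ledger=ledger, rounds=rounds, counts=winnowed)
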
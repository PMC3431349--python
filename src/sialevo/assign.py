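"""Subfamily assignment by reciprocal best hit and subgroup-specific residues.

Assignment follows the reciprocal-best-hit (RBH) scheme used for ortholog
and subfamily calling: a query inherits the subgroup label of its top-scoring
reference only if it is, reciprocally, that reference's top-scoring query.
Smith-Waterman local alignment under BLOSUM62 with affine gaps (open 11,
extend 1 — the protein-BLAST defaults) provides the similarity ranking.

Subgroup-specific residues are operationalised as alignment columns where the
modal residue of the in-group reaches a high within-group frequency while
staying rare outside — the frequency-contrast idea behind subfamily logos.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .alignment import AA20, GAP, Alignment, AlignmentError, build_coordinate_map


@dataclass(frozen=True)
class ScoreParams:
    """Local-alignment scoring: substitution matrix and affine gap penalties."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")


@dataclass(frozen=True)
class Assignment:
    query_id: str
    subgroup: str          # "unassigned" when the best hit is not mutual
    best_ref: str
    mutual: bool
    score: float


@dataclass(frozen=True)
class SpecificResidueCall:
    column: int
    ref_coordinate: int | None  # residue number on the in-group reference
    subgroup: str
    residue: str
    freq_in: float
    freq_out: float


def _make_aligner(params: ScoreParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix_name)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def pairwise_score(a: str, b: str, params: ScoreParams | None = None) -> float:
    """Best Smith-Waterman local alignment score of two ungapped sequences."""
    if not a or not b:
        raise AlignmentError("pairwise_score requires non-empty sequences")
    if GAP in a or GAP in b:
        raise AlignmentError("pairwise_score requires ungapped sequences")
    return float(_make_aligner(params or ScoreParams()).score(a, b))


def score_matrix(queries: Mapping[str, str], references: Mapping[str, str],
                 params: ScoreParams | None = None) -> pd.DataFrame:
    """All query x reference local-alignment scores (rows = queries)."""
    aligner = _make_aligner(params or ScoreParams())
    cache: dict[tuple[str, str], float] = {}
    rows = {}
    for qid, q in queries.items():
        row = []
        for rid, r in references.items():
            # local-alignment scores are symmetric; compute each pair once
            key = (qid, rid) if qid <= rid else (rid, qid)
            mirrored = (qid in references and rid in queries
                        and references[qid] == q and queries[rid] == r)
            if mirrored and key in cache:
                row.append(cache[key])
                continue
            s = float(aligner.score(q, r))
            if mirrored:
                cache[key] = s
            row.append(s)
        rows[qid] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(references))


def _argmax_lexicographic(series: pd.Series) -> str:
    """Index of the maximum; ties broken by lexicographically first id."""
    best = series.max()
    winners = sorted(series.index[series == best])
    if len(winners) > 1:
        warnings.warn(f"score tie between {winners}; keeping {winners[0]}")
    return winners[0]


def rbh_assign(queries: Mapping[str, str],
               references: Mapping[str, str],
               ref_labels: Mapping[str, str],
               params: ScoreParams | None = None) -> list[Assignment]:
    """Reciprocal-best-hit subgroup assignment.

    Parameters
    ----------
    queries, references
        id -> ungapped sequence.  The two sets may overlap; a self pair
        (same id in both) is excluded from the reciprocity check.
    ref_labels
        reference id -> subgroup label.
    """
    missing = set(references) - set(ref_labels)
    if missing:
        raise AlignmentError(f"references without labels: {sorted(missing)}")
    S = score_matrix(queries, references, params)
    out = []
    for qid in queries:
        row = S.loc[qid].drop(labels=[qid], errors="ignore")
        if row.empty:
            raise AlignmentError(f"no references to score {qid!r} against")
        best_ref = _argmax_lexicographic(row)
        # reciprocal direction: is qid the best query for best_ref?
        col = S[best_ref].drop(labels=[best_ref], errors="ignore")
        best_query = _argmax_lexicographic(col)
        mutual = best_query == qid
        out.append(Assignment(
            query_id=qid,
            subgroup=ref_labels[best_ref] if mutual else "unassigned",
            best_ref=best_ref,
            mutual=mutual,
            score=float(row[best_ref]),
        ))
    return out


def subfamily_specific_residues(aln: Alignment,
                                group_in: Sequence[str],
                                group_out: Sequence[str],
                                in_threshold: float = 0.7,
                                out_threshold: float = 0.2,
                                subgroup: str = "",
                                ref_id: str | None = None) -> list[SpecificResidueCall]:
    """Columns where the in-group's modal residue is frequent inside and rare
    outside.

    The modal non-gap, unambiguous residue of ``group_in`` at each column is
    called specific iff its in-group frequency >= ``in_threshold`` and its
    out-group frequency <= ``out_threshold`` (denominators = group sizes, so
    gaps depress frequencies).  ``ref_id`` (a member of the in-group, e.g. the
    human sequence) adds reference residue coordinates to the calls.
    """
    gi, go = list(group_in), list(group_out)
    if not gi or not go:
        raise AlignmentError("both groups must be non-empty")
    if set(gi) & set(go):
        raise AlignmentError("groups must be disjoint")
    if not 0 <= out_threshold <= in_threshold <= 1:
        raise AlignmentError("need 0 <= out_threshold <= in_threshold <= 1")
    cmap = build_coordinate_map(aln, ref_id) if ref_id else None
    rows_in = [aln.row(i) for i in gi]
    rows_out = [aln.row(i) for i in go]
    calls = []
    for c in range(1, aln.n_cols + 1):
        j = c - 1
        col_in = [r[j] for r in rows_in if r[j] in AA20]
        if not col_in:
            continue
        counts: dict[str, int] = {}
        for ch in col_in:
            counts[ch] = counts.get(ch, 0) + 1
        residue = max(sorted(counts), key=counts.get)
        freq_in = counts[residue] / len(gi)
        if freq_in < in_threshold:
            continue
        freq_out = sum(1 for r in rows_out if r[j] == residue) / len(go)
        if freq_out > out_threshold:
            continue
        calls.append(SpecificResidueCall(
            column=c,
            ref_coordinate=cmap.to_residue(c) if cmap else None,
            subgroup=subgroup,
            residue=residue,
            freq_in=freq_in,
            freq_out=freq_out,
        ))
    return calls


#: the family comparison scheme: NEU1 and NEU5 each against NEU2+3+4
#: pooled; NEU2, NEU3 and NEU4 each against the other two pooled.
LOGO_COMPARISON_SCHEME: Mapping[str, tuple[str, ...]] = {
    "NEU1": ("NEU2", "NEU3", "NEU4"),
    "NEU5": ("NEU2", "NEU3", "NEU4"),
    "NEU2": ("NEU3", "NEU4"),
    "NEU3": ("NEU2", "NEU4"),
    "NEU4": ("NEU2", "NEU3"),
}


def specific_residues_all_subgroups(aln: Alignment,
                                    in_threshold: float = 0.7,
                                    out_threshold: float = 0.2,
                                    ref_ids: Mapping[str, str] | None = None
                                    ) -> list[SpecificResidueCall]:
    """Run the subgroup-vs-pooled-others comparisons for all five subfamilies."""
    calls = []
    for sub, others in LOGO_COMPARISON_SCHEME.items():
        gi = aln.subgroup_ids(sub)
        go = [i for o in others for i in aln.subgroup_ids(o)]
        if not gi or not go:
            continue
        calls.extend(subfamily_specific_residues(
            aln, gi, go, in_threshold, out_threshold, subgroup=sub,
            ref_id=(ref_ids or {}).get(sub),
        ))
    return calls
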
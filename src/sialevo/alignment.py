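"""Alignment data model, standard-format I/O and coordinate maps.

The central container is :class:`Alignment`: an ordered set of equal-length
gapped protein sequences with per-sequence subgroup (NEU1..NEU5) and
taxonomic-group metadata.  Residue coordinates are 1-based throughout, and
:class:`CoordinateMap` translates between per-sequence residue numbering and
global alignment columns — the convention used to report positions on a
reference sequence such as human NEU2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO

GAP = "-"
AMBIGUOUS = frozenset("XBZJUO*")
AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")
VALID_CHARS = AA20 | AMBIGUOUS | {GAP}

SUBGROUPS = ("NEU1", "NEU2", "NEU3", "NEU4", "NEU5")
TAXON_GROUPS = ("mammals", "vertebrates", "deuterostomes", "early_metazoa")
UNKNOWN = "unknown"

#: taxon nesting used for the hierarchical conservation tests:
#: mammals are vertebrates are deuterostomes; early metazoans are outside.
_TAXON_NESTING = {
    "mammals": ("mammals", "vertebrates", "deuterostomes"),
    "vertebrates": ("vertebrates", "deuterostomes"),
    "deuterostomes": ("deuterostomes",),
    "early_metazoa": ("early_metazoa",),
}


class AlignmentError(ValueError):
    """Raised for malformed alignments or metadata."""


@dataclass(frozen=True)
class SeqMeta:
    """Per-sequence annotation: sialidase subgroup and taxonomic group."""

    subgroup: str = UNKNOWN
    taxon_group: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.subgroup not in SUBGROUPS and self.subgroup != UNKNOWN:
            raise AlignmentError(
                f"unknown subgroup {self.subgroup!r}; valid: "
                f"{', '.join(SUBGROUPS)} or {UNKNOWN!r}"
            )
        if self.taxon_group not in TAXON_GROUPS and self.taxon_group != UNKNOWN:
            raise AlignmentError(
                f"unknown taxon_group {self.taxon_group!r}; valid: "
                f"{', '.join(TAXON_GROUPS)} or {UNKNOWN!r}"
            )

    def in_taxon(self, group: str) -> bool:
        """Nested membership: a mammal counts as vertebrate and deuterostome."""
        if self.taxon_group == UNKNOWN:
            return False
        return group in _TAXON_NESTING[self.taxon_group]


@dataclass
class Alignment:
    """Equal-length labelled protein alignment with per-sequence metadata."""

    ids: list[str]
    seqs: list[str]
    metadata: dict[str, SeqMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ids:
            raise AlignmentError("alignment has no sequences")
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            dup = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dup}")
        L = len(self.seqs[0])
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != L:
                raise AlignmentError(
                    f"ragged alignment: {sid!r} has length {len(s)}, expected {L}"
                )
            bad = set(s) - VALID_CHARS
            if bad:
                raise AlignmentError(
                    f"invalid characters {sorted(bad)} in {sid!r} "
                    "(gap must be '-', '.' is rejected)"
                )
        for sid in self.metadata:
            if sid not in self._index():
                raise AlignmentError(f"metadata id {sid!r} not in alignment")

    def _index(self) -> dict[str, int]:
        return {sid: i for i, sid in enumerate(self.ids)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.seqs[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.seqs[self._index()[seq_id]]
        except KeyError:
            raise AlignmentError(f"unknown sequence id {seq_id!r}") from None

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def meta(self, seq_id: str) -> SeqMeta:
        return self.metadata.get(seq_id, SeqMeta())

    def column(self, col: int) -> str:
        """1-based alignment column as a string over sequences, input order."""
        self._check_col(col)
        j = col - 1
        return "".join(s[j] for s in self.seqs)

    def _check_col(self, col: int) -> None:
        if not 1 <= col <= self.n_cols:
            raise AlignmentError(
                f"column {col} out of range 1..{self.n_cols}"
            )

    def subgroup_ids(self, subgroup: str) -> list[str]:
        return [i for i in self.ids if self.meta(i).subgroup == subgroup]

    def taxon_ids(self, group: str) -> list[str]:
        """Ids belonging to a (nested) taxonomic group."""
        return [i for i in self.ids if self.meta(i).in_taxon(group)]

    def subset(self, keep_ids: Sequence[str]) -> "Alignment":
        keep = list(keep_ids)
        idx = self._index()
        missing = [i for i in keep if i not in idx]
        if missing:
            raise AlignmentError(f"unknown ids in subset: {missing}")
        return Alignment(
            ids=keep,
            seqs=[self.seqs[idx[i]] for i in keep],
            metadata={i: self.metadata[i] for i in keep if i in self.metadata},
        )

    def take_columns(self, cols: Sequence[int]) -> "Alignment":
        """New alignment restricted to the given 1-based columns, in order."""
        for c in cols:
            self._check_col(c)
        js = [c - 1 for c in cols]
        return Alignment(
            ids=list(self.ids),
            seqs=["".join(s[j] for j in js) for s in self.seqs],
            metadata=dict(self.metadata),
        )

    # -- coverage ----------------------------------------------------------
    def site_coverage(self, column: int) -> float:
        """Fraction of sequences with an unambiguous residue at the column.

        Gaps and ambiguity letters (X, B, Z, ...) both count as missing.
        """
        self._check_col(column)
        col = self.column(column)
        ok = sum(1 for c in col if c in AA20)
        return ok / self.n_seqs

    def filter_columns(self, min_coverage: float, strict: bool = False) -> list[int]:
        """1-based columns whose coverage exceeds (strict) or meets the threshold."""
        if not 0.0 <= min_coverage <= 1.0:
            raise AlignmentError("min_coverage must be in [0, 1]")
        out = []
        for c in range(1, self.n_cols + 1):
            cov = self.site_coverage(c)
            if (cov > min_coverage) if strict else (cov >= min_coverage):
                out.append(c)
        return out


@dataclass(frozen=True)
class CoordinateMap:
    """Bijection between 1-based residue numbers of one sequence and columns."""

    seq_id: str
    col_of_residue: Mapping[int, int]
    residue_of_col: Mapping[int, int]

    def __len__(self) -> int:
        return len(self.col_of_residue)

    def to_column(self, residue: int) -> int:
        try:
            return self.col_of_residue[residue]
        except KeyError:
            raise AlignmentError(
                f"{self.seq_id!r} has no residue {residue} "
                f"(ungapped length {len(self)})"
            ) from None

    def to_residue(self, column: int) -> int | None:
        """Residue at an alignment column, or None at a gap column."""
        return self.residue_of_col.get(column)


def build_coordinate_map(aln: Alignment, seq_id: str) -> CoordinateMap:
    """Map the n-th non-gap character of a row to residue number n."""
    row = aln.row(seq_id)
    col_of, res_of = {}, {}
    n = 0
    for j, ch in enumerate(row, start=1):
        if ch != GAP:
            n += 1
            col_of[n] = j
            res_of[j] = n
    return CoordinateMap(seq_id=seq_id, col_of_residue=col_of, residue_of_col=res_of)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path, metadata: Mapping[str, SeqMeta] | None = None) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Sequences are upper-cased; '.' gaps are rejected (only '-' is accepted)
    so that mixed gap dialects fail loudly rather than silently.
    """
    path = Path(path)
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment(ids=ids, seqs=seqs, metadata=dict(metadata or {}))


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_metadata(path: str | Path, aln: Alignment | None = None) -> dict[str, SeqMeta]:
    """Read the tab-separated metadata table (header: id/subgroup/taxon_group).

    Rows for ids absent from the alignment (when one is given) are skipped
    with a warning; unknown subgroup or taxon tokens are hard errors.
    """
    path = Path(path)
    meta: dict[str, SeqMeta] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["id", "subgroup", "taxon_group"]
        if [h.strip().lower() for h in header[:3]] != expected:
            raise AlignmentError(
                f"metadata header must start with {expected}, got {header}"
            )
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise AlignmentError(f"{path}:{ln}: expected 3 columns")
            sid, sub, tax = (p.strip() for p in parts[:3])
            if aln is not None and sid not in set(aln.ids):
                warnings.warn(f"metadata id {sid!r} not in alignment; skipped")
                continue
            meta[sid] = SeqMeta(subgroup=sub or UNKNOWN, taxon_group=tax or UNKNOWN)
    return meta


def write_metadata(meta: Mapping[str, SeqMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsubgroup\ttaxon_group\n")
        for sid, m in meta.items():
            fh.write(f"{sid}\t{m.subgroup}\t{m.taxon_group}\n")


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a newick tree; malformed input raises."""
    try:
        return dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises various parse errors
        raise AlignmentError(f"malformed newick in {path}: {exc}") from exc


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    """Write newick with branch lengths at 6-decimal precision."""
    s = tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".6f",
    )
    with open(path, "w") as fh:
        fh.write(s)


def write_table(rows: Iterable[Mapping[str, object]], path: str | Path,
                columns: Sequence[str] | None = None) -> None:
    """Write a list of dict rows as a TSV with a header line."""
    rows = list(rows)
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for r in rows:
            fh.write("\t".join(str(r.get(c, "")) for c in columns) + "\n")
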
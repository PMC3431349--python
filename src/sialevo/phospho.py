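"""Conservation statistics for predicted phosphorylation sites.

Predicted phospho-sites (from an upstream predictor such as NetPhos) are
given per protein as (id, residue position, residue) with residue in {S,T,Y}.
Each site is mapped to its global alignment column; equivalent positions
across proteins collapse to one column.  A column counts as phosphorylatable
in a sequence if any of Ser, Thr or Tyr occurs there, regardless of which
residue was predicted.

Global conservation of a column is tested one-sided against the alignment-wide
S/T/Y background frequency with an exact binomial test; subgroup- and
taxon-specific conservation with two-sided Fisher exact tests on 2x2 tables
(group vs rest, phosphorylatable vs not).  All p-values are Bonferroni
corrected within their test family, and flags are raised only for columns
that are both significant and >=60% (or >=90%) conserved in some group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import AA20, Alignment, AlignmentError, build_coordinate_map

PHOSPHO_RESIDUES = frozenset("STY")


@dataclass(frozen=True)
class PhosphoSite:
    seq_id: str
    residue_pos: int  # 1-based on the ungapped sequence
    residue: str

    def __post_init__(self) -> None:
        if self.residue not in PHOSPHO_RESIDUES:
            raise AlignmentError(
                f"{self.seq_id}:{self.residue_pos}: residue must be S, T or Y"
            )


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows group/rest, cols phospho/non-phospho."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise AlignmentError("contingency counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def read_phospho_sites(path) -> list[PhosphoSite]:
    """Read a TSV of (seq_id, position, residue) with header."""
    sites = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip().lower() for h in header[:3]] != ["seq_id", "position", "residue"]:
            raise AlignmentError(
                "phospho site table header must be: seq_id<TAB>position<TAB>residue"
            )
        for line in fh:
            if not line.strip():
                continue
            sid, pos, res = line.rstrip("\n").split("\t")[:3]
            sites.append(PhosphoSite(sid, int(pos), res.strip().upper()))
    return sites


def write_phospho_sites(sites: Sequence[PhosphoSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tposition\tresidue\n")
        for s in sites:
            fh.write(f"{s.seq_id}\t{s.residue_pos}\t{s.residue}\n")


def map_sites_to_columns(sites: Sequence[PhosphoSite], aln: Alignment) -> list[int]:
    """Distinct ascending alignment columns carrying at least one site.

    Each site is validated against its sequence: the named residue must occur
    at the stated ungapped position.
    """
    cmaps = {}
    cols = set()
    for s in sites:
        if s.seq_id not in cmaps:
            cmaps[s.seq_id] = build_coordinate_map(aln, s.seq_id)
        actual = aln.ungapped(s.seq_id)[s.residue_pos - 1:s.residue_pos]
        if actual != s.residue:
            raise AlignmentError(
                f"site {s.seq_id} {s.residue}{s.residue_pos}: sequence has "
                f"{actual or 'nothing'} at that position"
            )
        cols.add(cmaps[s.seq_id].to_column(s.residue_pos))
    return sorted(cols)


def background_frequency(aln: Alignment) -> tuple[float, int]:
    """(S/T/Y frequency, total residues) over all non-gap cells of the alignment.

    Ambiguity letters count in the denominator of neither: they are excluded
    from both the S/T/Y count and the total.
    """
    total = 0
    sty = 0
    for s in aln.seqs:
        for ch in s:
            if ch in AA20:
                total += 1
                if ch in PHOSPHO_RESIDUES:
                    sty += 1
    if total == 0:
        return 0.0, 0
    return sty / total, total


def column_conservation(aln: Alignment, column: int, group: Sequence[str]) -> float:
    """Percent of group sequences with S, T or Y at the column.

    Gaps and ambiguity codes count in the denominator but never the numerator.
    """
    group = list(group)
    if not group:
        raise AlignmentError("empty group")
    aln._check_col(column)
    j = column - 1
    hits = sum(1 for sid in group if aln.row(sid)[j] in PHOSPHO_RESIDUES)
    return 100.0 * hits / len(group)


def binomial_conservation_test(k: int, N: int, p: float) -> float:
    """One-sided upper-tail exact binomial p-value, P(X >= k), X ~ Bin(N, p)."""
    if not 0 <= k <= N:
        raise AlignmentError("need 0 <= k <= N")
    if not 0.0 < p < 1.0:
        raise AlignmentError("background p must be strictly between 0 and 1")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, N, p))


def fisher_exact_2x2(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value by the point-probability rule."""
    return float(stats.fisher_exact(t.as_array(), alternative="two-sided")[1])


def build_group_contingency(aln: Alignment, column: int,
                            group: Sequence[str], complement: Sequence[str],
                            drop_gaps: bool = False) -> ContingencyTable2x2:
    """2x2 table at a column: (group, rest) x (phosphorylatable, not).

    In the default faithful mode gaps and ambiguity letters count as
    non-phosphorylatable; ``drop_gaps=True`` removes them from the table
    instead (non-gap denominators).
    """
    group, complement = list(group), list(complement)
    if not group or not complement:
        raise AlignmentError("group and complement must be non-empty")
    if set(group) & set(complement):
        raise AlignmentError("group and complement must be disjoint")
    aln._check_col(column)
    j = column - 1

    def counts(ids: Sequence[str]) -> tuple[int, int]:
        phos = non = 0
        for sid in ids:
            ch = aln.row(sid)[j]
            if ch in PHOSPHO_RESIDUES:
                phos += 1
            elif drop_gaps and ch not in AA20:
                continue
            else:
                non += 1
        return phos, non

    a, b = counts(group)
    c, d = counts(complement)
    return ContingencyTable2x2(a, b, c, d)


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Multiply each p-value by the family size (default len(p_values)), cap at 1."""
    ps = list(p_values)
    if any(not 0.0 <= p <= 1.0 for p in ps):
        raise AlignmentError("p-values must lie in [0, 1]")
    mm = len(ps) if m is None else m
    return [min(1.0, p * mm) for p in ps]


# ---------------------------------------------------------------------------
# Whole-table driver
# ---------------------------------------------------------------------------

def compute_column_stats(aln: Alignment, columns: Sequence[int],
                         alpha: float = 0.01,
                         cons60: float = 60.0, cons90: float = 90.0,
                         faithful_n: bool = True,
                         drop_gaps_in_fisher: bool = False) -> pd.DataFrame:
    """Per-column conservation statistics and significance flags.

    Parameters
    ----------
    columns
        Distinct 1-based alignment columns to test (typically the output of
        :func:`map_sites_to_columns`).
    faithful_n
        When True, the binomial N is the number of sequences (gaps count as
        non-phosphorylatable); otherwise N is the column's non-gap count.

    Returns a frame indexed by column with conservation percentages per
    group, raw and Bonferroni-corrected p-values (family size = number of
    tested columns, separately per grouping scheme) and the significance
    flags: ``global60``/``global90`` (binomial) and ``specific_<group>``
    (Fisher) for each subgroup and taxon group present in the metadata.
    """
    columns = sorted(set(columns))
    if not columns:
        return pd.DataFrame()
    p_bg, total = background_frequency(aln)
    if not 0.0 < p_bg < 1.0:
        raise AlignmentError("degenerate S/T/Y background frequency")
    m = len(columns)
    all_ids = list(aln.ids)

    subgroups = [s for s in ("NEU1", "NEU2", "NEU3", "NEU4", "NEU5")
                 if aln.subgroup_ids(s)]
    taxa = [t for t in ("mammals", "vertebrates", "deuterostomes", "early_metazoa")
            if aln.taxon_ids(t)]

    rows = []
    for c in columns:
        j = c - 1
        col = [aln.row(sid)[j] for sid in all_ids]
        k = sum(1 for ch in col if ch in PHOSPHO_RESIDUES)
        N = len(all_ids) if faithful_n else sum(1 for ch in col if ch in AA20)
        row: dict[str, object] = {
            "column": c, "k": k, "N": N,
            "conservation_global": column_conservation(aln, c, all_ids),
            "p_binomial_raw": binomial_conservation_test(k, N, p_bg),
        }
        for sub in subgroups:
            ids = aln.subgroup_ids(sub)
            rest = [i for i in all_ids if i not in set(ids)]
            row[f"conservation_{sub}"] = column_conservation(aln, c, ids)
            t = build_group_contingency(aln, c, ids, rest, drop_gaps=drop_gaps_in_fisher)
            row[f"p_fisher_{sub}_raw"] = fisher_exact_2x2(t)
        for tx in taxa:
            ids = aln.taxon_ids(tx)
            rest = [i for i in all_ids if i not in set(ids)]
            if not rest:
                continue
            row[f"conservation_{tx}"] = column_conservation(aln, c, ids)
            t = build_group_contingency(aln, c, ids, rest, drop_gaps=drop_gaps_in_fisher)
            row[f"p_fisher_{tx}_raw"] = fisher_exact_2x2(t)
        rows.append(row)

    df = pd.DataFrame(rows).set_index("column")
    df["p_binomial_corrected"] = bonferroni(df["p_binomial_raw"], m)
    for g in subgroups + taxa:
        col_name = f"p_fisher_{g}_raw"
        if col_name in df:
            df[f"p_fisher_{g}_corrected"] = bonferroni(df[col_name], m)

    sig_global = df["p_binomial_corrected"] < alpha
    df["global60"] = sig_global & (df["conservation_global"] >= cons60)
    df["global90"] = sig_global & (df["conservation_global"] >= cons90)
    for g in subgroups + taxa:
        pc = f"p_fisher_{g}_corrected"
        if pc in df:
            df[f"specific_{g}"] = (df[pc] < alpha) & (df[f"conservation_{g}"] >= cons60)
    return df


def classify_sites(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Summary flags per column from :func:`compute_column_stats` output.

    Adds ``subgroup_specific``/``taxon_specific``: significantly conserved
    (>=60%) in exactly the groups listed, with globally conserved columns
    (global60) excluded from the "only in specific groups" calls.
    """
    if stats_df.empty:
        return stats_df
    df = stats_df.copy()
    sub_cols = [c for c in df.columns
                if c.startswith("specific_NEU")]
    tax_cols = [c for c in df.columns
                if c.startswith("specific_") and not c.startswith("specific_NEU")]

    def joined(row, cols):
        names = [c.removeprefix("specific_") for c in cols if row[c]]
        return ",".join(names)

    df["subgroup_specific"] = df.apply(lambda r: joined(r, sub_cols), axis=1)
    df["taxon_specific"] = df.apply(lambda r: joined(r, tax_cols), axis=1)
    df["subgroup_only"] = (df["subgroup_specific"] != "") & ~df["global60"]
    df["taxon_only"] = (df["taxon_specific"] != "") & ~df["global60"]
    return df


def conservation_heatmap_matrix(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Columns x groups conservation-% matrix for heatmap plotting."""
    cols = [c for c in stats_df.columns if c.startswith("conservation_")]
    out = stats_df[cols].copy()
    out.columns = [c.removeprefix("conservation_") for c in cols]
    return out
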
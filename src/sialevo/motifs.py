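"""Sialidase sequence features: Asp-boxes, N-terminal motif, catalytic
residues, active-site loop lengths and exon-junction mapping.

Sialidases fold as a six-bladed beta-propeller.  Two short signatures mark
the family: the Asp-box repeat S-x-D-x-G-x-x-(W/F) on loops connecting
propeller strands, and an N-terminal (T/F)-Y-R-(I/V)-P motif.  Six residues
are essential for catalysis (an arginine triad, a Tyr/Glu nucleophile pair
and an aspartate acid/base); here they default to the human NEU2 positions
R21, D46, E218, R237, R304, Y334.  Loops around the catalytic crevice vary
in length between subfamilies and are measured relative to a reference
sequence, counting insertions between the aligned reference flanks.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .alignment import GAP, Alignment, AlignmentError, CoordinateMap, build_coordinate_map

#: residue-level regular expressions for the family signatures
MOTIF_PATTERNS: Mapping[str, str] = {
    "aspbox": r"S.D.G..[WF]",
    "nterm": r"[TF]YR[IV]P",
}

#: catalytic residues in human NEU2 numbering (residue -> amino acid)
CATALYTIC_RESIDUES_NEU2: Mapping[int, str] = {
    21: "R", 46: "D", 218: "E", 237: "R", 304: "R", 334: "Y",
}


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    pattern_name: str
    start: int  # 1-based residue span on the ungapped sequence
    end: int
    matched_text: str


@dataclass(frozen=True)
class LoopDefinition:
    """A loop named by its position on the reference (human NEU2) sequence."""

    name: str
    ref_start: int
    ref_end: int

    def __post_init__(self) -> None:
        if self.ref_start > self.ref_end:
            raise ValueError(f"{self.name}: ref_start > ref_end")


#: the nine active-site loops plus the overlapping Loop 0 variant, in human
#: NEU2 coordinates; both Loop 0 and Loop 1 are kept as configured defaults.
DEFAULT_LOOPS: tuple[LoopDefinition, ...] = (
    LoopDefinition("Loop 0", 16, 18),
    LoopDefinition("Loop 1", 15, 18),
    LoopDefinition("Loop 2", 42, 49),
    LoopDefinition("Loop 3", 107, 122),
    LoopDefinition("Loop 4", 183, 190),
    LoopDefinition("Loop 5", 238, 243),
    LoopDefinition("Loop 6", 261, 274),
    LoopDefinition("Loop 7", 299, 306),
    LoopDefinition("Loop 8", 329, 332),
    LoopDefinition("Loop 9", 357, 359),
)


@dataclass(frozen=True)
class ExonStructure:
    """Exon-exon junction positions in 1-based protein coordinates."""

    seq_id: str
    junctions: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.junctions, self.junctions[1:])):
            raise ValueError(f"{self.seq_id}: junctions must be strictly ascending")
        if any(j < 1 for j in self.junctions):
            raise ValueError(f"{self.seq_id}: junctions must be >= 1")

    @property
    def n_exons(self) -> int:
        return len(self.junctions) + 1


def scan_motif(seq: str, pattern_name: str) -> list[MotifHit]:
    """All (possibly overlapping) matches of a family signature, left to right.

    The sequence must be ungapped; de-gap aligned rows first.
    """
    if GAP in seq:
        raise AlignmentError("scan_motif requires an ungapped sequence")
    try:
        pat = MOTIF_PATTERNS[pattern_name]
    except KeyError:
        raise ValueError(
            f"unknown pattern {pattern_name!r}; valid: {sorted(MOTIF_PATTERNS)}"
        ) from None
    hits = []
    # lookahead so that overlapping matches at distinct starts are all found
    for m in re.finditer(f"(?=({pat}))", seq):
        text = m.group(1)
        start = m.start() + 1
        hits.append(MotifHit("", pattern_name, start, start + len(text) - 1, text))
    return hits


def scan_alignment_motifs(aln: Alignment, pattern_name: str,
                          ids: Sequence[str] | None = None) -> list[MotifHit]:
    """Scan each (ungapped) sequence; hits carry their seq_id."""
    out = []
    for sid in (ids if ids is not None else aln.ids):
        for h in scan_motif(aln.ungapped(sid), pattern_name):
            out.append(MotifHit(sid, h.pattern_name, h.start, h.end, h.matched_text))
    return out


def _hit_column_span(aln: Alignment, hit: MotifHit,
                     cmap: CoordinateMap) -> tuple[int, int]:
    return cmap.to_column(hit.start), cmap.to_column(hit.end)


def cluster_motif_locations(aln: Alignment, hits: Sequence[MotifHit]) -> list[list[MotifHit]]:
    """Group hits whose alignment-column spans overlap by >= 1 column.

    Single-linkage over the interval overlap graph, returned in ascending
    order of cluster start column.
    """
    spans = []
    cmaps = {}
    for h in hits:
        if h.seq_id not in cmaps:
            cmaps[h.seq_id] = build_coordinate_map(aln, h.seq_id)
        spans.append((_hit_column_span(aln, h, cmaps[h.seq_id]), h))
    spans.sort(key=lambda t: t[0])
    clusters: list[tuple[list[int], list[MotifHit]]] = []
    for (s, e), h in spans:
        if clusters and s <= clusters[-1][0][1]:
            clusters[-1][0][1] = max(clusters[-1][0][1], e)
            clusters[-1][1].append(h)
        else:
            clusters.append(([s, e], [h]))
    return [members for _span, members in clusters]


def aspbox_conservation(aln: Alignment, subgroup: str) -> pd.DataFrame:
    """Per aligned Asp-box location, the fraction of subgroup sequences with
    an intact motif there.

    Returns a frame with columns start_col/end_col/n_with_motif/fraction,
    one row per clustered motif location, ascending by column.
    """
    ids = aln.subgroup_ids(subgroup)
    if not ids:
        raise AlignmentError(f"subgroup {subgroup!r} is empty")
    hits = scan_alignment_motifs(aln, "aspbox", ids=ids)
    rows = []
    cmaps = {sid: build_coordinate_map(aln, sid) for sid in ids}
    for members in cluster_motif_locations(aln, hits):
        cols = [_hit_column_span(aln, h, cmaps[h.seq_id]) for h in members]
        start = min(s for s, _ in cols)
        end = max(e for _, e in cols)
        n = len({h.seq_id for h in members})
        rows.append({
            "start_col": start, "end_col": end,
            "n_with_motif": n, "fraction": n / len(ids),
        })
    return pd.DataFrame(rows, columns=["start_col", "end_col", "n_with_motif", "fraction"])


def check_catalytic_residues(aln: Alignment, ref_id: str,
                             ref_positions: Sequence[int]) -> pd.DataFrame:
    """Identity of each sequence to the reference at catalytic positions.

    A cell is True iff the sequence carries the reference's amino acid in the
    alignment column of that reference residue (strict identity, as complete
    conservation is the expectation for these sites).
    """
    cmap = build_coordinate_map(aln, ref_id)
    ref_row = aln.row(ref_id)
    cols, expected = [], []
    for pos in ref_positions:
        c = cmap.to_column(pos)
        cols.append(c)
        expected.append(ref_row[c - 1])
    data = {}
    for sid in aln.ids:
        row = aln.row(sid)
        data[sid] = [row[c - 1] == e for c, e in zip(cols, expected)]
    return pd.DataFrame.from_dict(data, orient="index", columns=list(ref_positions))


def loop_lengths(aln: Alignment, ref_id: str,
                 loops: Sequence[LoopDefinition] = DEFAULT_LOOPS) -> pd.DataFrame:
    """Loop length per sequence: non-gap residues strictly between the aligned
    flanking reference residues, so insertions inside the loop are counted.

    For a loop at the reference terminus (no flanking residue) the span falls
    back to the loop's own reference columns, with a warning.
    """
    cmap = build_coordinate_map(aln, ref_id)
    ref_len = len(cmap)
    spans = {}
    for lp in loops:
        if lp.ref_start < 1 or lp.ref_end > ref_len:
            raise AlignmentError(
                f"{lp.name}: span {lp.ref_start}-{lp.ref_end} outside "
                f"reference (length {ref_len})"
            )
        if lp.ref_start == 1 or lp.ref_end == ref_len:
            warnings.warn(
                f"{lp.name} touches the reference terminus; "
                "using its own columns instead of flanks"
            )
            spans[lp.name] = (cmap.to_column(lp.ref_start), cmap.to_column(lp.ref_end))
        else:
            spans[lp.name] = (
                cmap.to_column(lp.ref_start - 1) + 1,
                cmap.to_column(lp.ref_end + 1) - 1,
            )
    data = {}
    for sid in aln.ids:
        row = aln.row(sid)
        data[sid] = [
            sum(1 for ch in row[s - 1:e] if ch != GAP)
            for s, e in (spans[lp.name] for lp in loops)
        ]
    return pd.DataFrame.from_dict(data, orient="index", columns=[lp.name for lp in loops])


def mean_loop_lengths_by_subgroup(aln: Alignment, ref_id: str,
                                  loops: Sequence[LoopDefinition] = DEFAULT_LOOPS) -> pd.DataFrame:
    """Mean loop length per subgroup (rows) and loop (columns)."""
    lengths = loop_lengths(aln, ref_id, loops)
    sub = pd.Series({sid: aln.meta(sid).subgroup for sid in aln.ids})
    return lengths.groupby(sub).mean()


def map_exon_junctions(ex: ExonStructure, cmap: CoordinateMap) -> list[int]:
    """Map junction residues to alignment columns (ascending)."""
    cols = []
    for j in ex.junctions:
        if j > len(cmap):
            raise AlignmentError(
                f"{ex.seq_id}: junction {j} beyond ungapped length {len(cmap)}"
            )
        cols.append(cmap.to_column(j))
    return cols


def read_exon_table(path) -> list[ExonStructure]:
    """Read a TSV of (id, comma-separated junction residues)."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip().lower() for h in header[:2]] != ["id", "junctions"]:
            raise AlignmentError("exon table header must be: id<TAB>junctions")
        for line in fh:
            if not line.strip():
                continue
            sid, js = line.rstrip("\n").split("\t")[:2]
            junctions = tuple(int(x) for x in js.split(",") if x.strip()) if js.strip() else ()
            out.append(ExonStructure(seq_id=sid, junctions=junctions))
    return out


def write_exon_table(structures: Sequence[ExonStructure], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tjunctions\n")
        for ex in structures:
            fh.write(f"{ex.seq_id}\t{','.join(map(str, ex.junctions))}\n")
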
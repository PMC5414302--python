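"""Category assignment and per-miRNA counting of clean small-RNA reads.

Reads are first screened against contaminating ncRNA classes (rRNA, tRNA,
snRNA, snoRNA, scRNA, srpRNA, in that priority order) by exact substring
match — a short read is a fragment of a longer ncRNA, so substring matching
mirrors the BLAST screen of a standard pipeline.  Surviving reads are then
compared near-full-length to the mature miRNA reference, allowing up to two
substitutions and two nucleotides of terminal length slack; everything else
is left unannotated.  Each unique read lands in exactly one category.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from . import constants as C
from .preprocess import CleanReadSet

__all__ = [
    "MatchResult",
    "load_fasta",
    "match_known_mirnas",
    "classify_reads",
    "build_count_table",
    "annotate_libraries",
]

CATEGORY_ORDER = C.CONTAMINANT_CLASSES + ("mirna", "unannotated")


def load_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate reference id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


@dataclass
class MatchResult:
    """Outcome of matching one library's unique reads to mature miRNAs."""

    counts: dict  # mirna_id -> reads assigned (multiplicity-weighted)
    assignment: dict  # read sequence -> (mirna_id, mismatches)
    ambiguous: int  # reads whose best hit was tied between >= 2 miRNAs
    unassigned: dict  # read sequence -> multiplicity

    @property
    def total_assigned(self) -> int:
        return sum(self.counts.values())


def _mismatches(read: str, ref: str) -> int:
    """Ungapped mismatch count over the common prefix of read and reference."""
    return sum(a != b for a, b in zip(read, ref))


def match_known_mirnas(
    reads: CleanReadSet | Mapping[str, int],
    mature: Mapping[str, str],
    max_mismatches: int = 2,
) -> MatchResult:
    """Assign unique reads to the closest mature miRNA.

    A read is comparable to a reference when their lengths differ by at most
    2 nt; mismatches are counted ungapped over the common prefix.  The read
    goes to the reference with the fewest mismatches (<= ``max_mismatches``);
    ties are broken toward the lexicographically smallest miRNA id and
    counted in ``ambiguous``.
    """
    if not mature:
        raise ValueError("empty mature miRNA reference")
    if not 0 <= max_mismatches <= 2:
        raise ValueError("max_mismatches must be 0, 1 or 2")
    counts = reads.counts if isinstance(reads, CleanReadSet) else reads

    exact: dict[str, list] = {}
    by_id = sorted(mature.items())
    for mid, seq in by_id:
        exact.setdefault(seq, []).append(mid)

    assigned_counts = {mid: 0 for mid, _ in by_id}
    assignment: dict = {}
    unassigned: dict = {}
    ambiguous = 0
    for read, mult in counts.items():
        hits = exact.get(read)
        if hits:
            best_id, best_mm, tied = hits[0], 0, len(hits) > 1
        else:
            best_id, best_mm, tied = None, max_mismatches + 1, False
            for mid, ref in by_id:
                if abs(len(read) - len(ref)) > 2:
                    continue
                mm = _mismatches(read, ref)
                if mm < best_mm:
                    best_id, best_mm, tied = mid, mm, False
                elif mm == best_mm and best_id is not None:
                    tied = True
        if best_id is not None and best_mm <= max_mismatches:
            assigned_counts[best_id] += mult
            assignment[read] = (best_id, best_mm)
            if tied:
                ambiguous += mult
        else:
            unassigned[read] = mult
    return MatchResult(
        counts=assigned_counts,
        assignment=assignment,
        ambiguous=ambiguous,
        unassigned=unassigned,
    )


def _contaminant_screen(
    counts: Mapping[str, int],
    contaminants: Mapping[str, Mapping[str, str]],
) -> tuple[dict, dict]:
    """Split reads into contaminant classes (priority order) vs the rest."""
    haystacks = {
        cls: "\n".join(contaminants[cls].values())
        for cls in C.CONTAMINANT_CLASSES
        if cls in contaminants and contaminants[cls]
    }
    by_class: dict = {cls: {} for cls in haystacks}
    remainder: dict = {}
    for read, mult in counts.items():
        for cls, hay in haystacks.items():
            if read in hay:
                by_class[cls][read] = mult
                break
        else:
            remainder[read] = mult
    return by_class, remainder


def classify_reads(
    reads: CleanReadSet | Mapping[str, int],
    contaminants: Mapping[str, Mapping[str, str]],
    match: MatchResult | None = None,
) -> pd.DataFrame:
    """Tabulate unique/total/proportion per small-RNA category.

    Contaminant classes take priority over the miRNA assignment in
    ``match``; reads in neither are ``unannotated``.  Returns a DataFrame
    indexed by category with columns ``unique_sequences``, ``total_reads``
    and ``proportion``; proportions sum to 1 over a non-empty read set.
    """
    counts = reads.counts if isinstance(reads, CleanReadSet) else reads
    by_class, remainder = _contaminant_screen(counts, contaminants)
    matched = match.assignment if match is not None else {}

    rows = []
    for cls in C.CONTAMINANT_CLASSES:
        sub = by_class.get(cls, {})
        rows.append((cls, len(sub), sum(sub.values())))
    mir = {r: m for r, m in remainder.items() if r in matched}
    rows.append(("mirna", len(mir), sum(mir.values())))
    un = {r: m for r, m in remainder.items() if r not in matched}
    rows.append(("unannotated", len(un), sum(un.values())))

    df = pd.DataFrame(rows, columns=["category", "unique_sequences", "total_reads"])
    df = df.set_index("category")
    total = df["total_reads"].sum()
    df["proportion"] = df["total_reads"] / total if total else 0.0
    return df


def build_count_table(
    match1: MatchResult,
    match2: MatchResult,
    n1: int,
    n2: int,
    mature: Mapping[str, str],
) -> pd.DataFrame:
    """Combine per-library match results into a miRNA x library count table.

    The table carries the clean-read totals as ``attrs["N1"]`` /
    ``attrs["N2"]`` — the normalization denominators downstream.  Every
    reference miRNA is present, including zero rows.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    ids = sorted(mature)
    df = pd.DataFrame(
        {
            "count_1": [int(match1.counts.get(m, 0)) for m in ids],
            "count_2": [int(match2.counts.get(m, 0)) for m in ids],
        },
        index=pd.Index(ids, name="mirna_id"),
    )
    df.attrs["N1"] = int(n1)
    df.attrs["N2"] = int(n2)
    return df


def annotate_libraries(
    clean1: CleanReadSet,
    clean2: CleanReadSet,
    mature: Mapping[str, str],
    contaminants: Mapping[str, Mapping[str, str]] | None = None,
    max_mismatches: int = 2,
):
    """Full annotation of two libraries: screen, match, count, summarize.

    Returns ``(count_table, summary1, summary2)``.  Contaminant screening
    happens before miRNA matching, so contaminant-derived reads never enter
    the count table.
    """
    contaminants = contaminants or {}
    results = []
    for crs in (clean1, clean2):
        _by_class, remainder = _contaminant_screen(crs.counts, contaminants)
        match = match_known_mirnas(remainder, mature, max_mismatches)
        summary = classify_reads(crs, contaminants, match)
        results.append((match, summary))
    (m1, s1), (m2, s2) = results
    table = build_count_table(
        m1, m2, clean1.total_clean_reads, clean2.total_clean_reads, mature
    )
    return table, s1, s2


def write_count_table_tsv(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# N1={table.attrs['N1']}\tN2={table.attrs['N2']}\n")
        table.to_csv(fh, sep="\t")


def read_count_table_tsv(path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("count table must start with '# N1=..\\tN2=..'")
        meta = dict(
            kv.split("=", 1) for kv in header.lstrip("# ").strip().split("\t")
        )
        df = pd.read_csv(fh, sep="\t", index_col="mirna_id")
    df.attrs["N1"] = int(meta["N1"])
    df.attrs["N2"] = int(meta["N2"])
    return df
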
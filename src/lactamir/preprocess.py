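"""Raw-read cleaning for single-end small-RNA libraries.

Six removal rules are applied to every read, in a fixed order; a read is
charged to the first rule it violates and surviving reads are 3'-adapter
trimmed and collapsed to unique sequences with multiplicities:

1. low quality           — more than half the bases below Phred 20
2. adapter5_contaminant  — read starts with >= 12 nt of the 5' adapter
3. no_adapter3           — the 3' adapter seed (first 8 nt) never occurs
4. poly_a                — trimmed insert is >= 80% A
5. no_insert             — trimmed insert is empty
6. too_short             — trimmed insert shorter than 18 nt

A seventh ledger class, ``overlong``, removes inserts longer than 30 nt and
enforces the upper end of the gel size selection.  The surviving total is
the library's clean-read count N, the denominator of reads-per-million
normalization downstream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import constants as C

__all__ = ["CleanParams", "CleanReadSet", "clean_reads", "length_distribution"]


@dataclass(frozen=True)
class CleanParams:
    """Tunable thresholds behind the named cleaning rules."""

    low_quality_phred: int = C.LOW_QUALITY_PHRED
    low_quality_max_fraction: float = C.LOW_QUALITY_MAX_FRACTION
    adapter5_min_prefix: int = C.ADAPTER5_MIN_PREFIX
    adapter3_min_prefix: int = C.ADAPTER3_MIN_PREFIX
    poly_a_fraction: float = C.POLY_A_FRACTION
    min_insert_len: int = C.MIN_INSERT_LEN
    max_insert_len: int = C.MAX_INSERT_LEN
    phred_offset: int = C.PHRED_OFFSET


@dataclass
class CleanReadSet:
    """Unique clean inserts with multiplicities plus the removal ledger."""

    counts: Counter = field(default_factory=Counter)
    ledger: dict = field(default_factory=dict)
    n_raw: int = 0

    @property
    def total_clean_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def n_removed(self) -> int:
        return sum(self.ledger.values())

    def check_conservation(self) -> None:
        if self.total_clean_reads + self.n_removed != self.n_raw:
            raise AssertionError(
                "read conservation violated: "
                f"{self.total_clean_reads} clean + {self.n_removed} removed "
                f"!= {self.n_raw} raw"
            )

    def write_collapsed_fasta(self, path) -> None:
        """Write unique inserts as ``>seq_<i>_x<multiplicity>`` records."""
        with open(path, "w") as fh:
            for i, (seq, mult) in enumerate(
                sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
            ):
                fh.write(f">seq_{i}_x{mult}\n{seq}\n")

    def write_ledger_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("rule\treads_removed\n")
            for rule in C.RULE_ORDER:
                fh.write(f"{rule}\t{self.ledger.get(rule, 0)}\n")
            fh.write(f"clean\t{self.total_clean_reads}\n")


def _iter_records(source) -> Iterator[tuple[str, str]]:
    """Yield (sequence, quality) pairs from a FASTQ path or an iterable."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            index = 0
            try:
                for _title, seq, qual in FastqGeneralIterator(fh):
                    yield seq.upper(), qual
                    index += 1
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record at index {index}: {exc}")
    else:
        for seq, qual in source:
            yield seq.upper(), qual


def _low_quality_table(threshold_phred: int, offset: int) -> bytes:
    cut = offset + threshold_phred
    return bytes(1 if i < cut else 0 for i in range(256))


def clean_reads(
    source,
    adapter_3p: str = C.DEFAULT_ADAPTER_3P,
    adapter_5p: str = C.DEFAULT_ADAPTER_5P,
    params: CleanParams | None = None,
) -> CleanReadSet:
    """Apply the removal rules to raw reads and collapse the survivors.

    Parameters
    ----------
    source
        Path to a FASTQ file (Sanger/Phred+33) or an iterable of
        ``(sequence, quality)`` string pairs.
    adapter_3p, adapter_5p
        Ligated adapter sequences; both must be non-empty.
    params
        Threshold overrides; defaults follow the module constants.
    """
    if not adapter_3p or not adapter_5p:
        raise ValueError("adapters must be non-empty")
    p = params or CleanParams()
    if len(adapter_3p) < p.adapter3_min_prefix:
        raise ValueError("3' adapter shorter than its match seed")

    a3_seed = adapter_3p[: p.adapter3_min_prefix]
    a5_prefix = adapter_5p[: p.adapter5_min_prefix]
    lowq = _low_quality_table(p.low_quality_phred, p.phred_offset)
    frac_low = p.low_quality_max_fraction
    frac_a = p.poly_a_fraction
    min_len, max_len = p.min_insert_len, p.max_insert_len

    counts: Counter = Counter()
    ledger = {rule: 0 for rule in C.RULE_ORDER}
    n_raw = 0
    for seq, qual in _iter_records(source):
        n_raw += 1
        if qual.encode().translate(lowq).count(1) > frac_low * len(qual):
            ledger[C.RULE_LOW_QUALITY] += 1
            continue
        if seq.startswith(a5_prefix):
            ledger[C.RULE_ADAPTER5] += 1
            continue
        pos = seq.find(a3_seed)
        if pos < 0:
            ledger[C.RULE_NO_ADAPTER3] += 1
            continue
        insert = seq[:pos]
        if insert and insert.count("A") >= frac_a * len(insert):
            ledger[C.RULE_POLY_A] += 1
            continue
        if pos == 0:
            ledger[C.RULE_NO_INSERT] += 1
            continue
        if pos < min_len:
            ledger[C.RULE_TOO_SHORT] += 1
            continue
        if pos > max_len:
            ledger[C.RULE_OVERLONG] += 1
            continue
        counts[insert] += 1

    result = CleanReadSet(counts=counts, ledger=ledger, n_raw=n_raw)
    result.check_conservation()
    return result


def length_distribution(reads: CleanReadSet | Mapping[str, int]) -> dict[int, float]:
    """Multiplicity-weighted insert-length proportions of a clean read set.

    Returns a mapping length -> proportion over the observed lengths; the
    proportions sum to 1.  Raises on an empty read set.
    """
    counts = reads.counts if isinstance(reads, CleanReadSet) else reads
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty read set has no length distribution")
    hist: Counter = Counter()
    for seq, mult in counts.items():
        hist[len(seq)] += mult
    return {length: hist[length] / total for length in sorted(hist)}


def write_length_distribution_tsv(dist: Mapping[int, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("length\tproportion\n")
        for length in sorted(dist):
            fh.write(f"{length}\t{dist[length]:.6f}\n")
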
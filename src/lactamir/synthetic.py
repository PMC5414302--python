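"""Ground-truth simulator for a two-library small-RNA sequencing experiment.

The generator emulates the structure of a pooled two-condition small-RNA
experiment (condition 1 vs condition 2, one library each): mature miRNA
inserts of 18-25 nt whose length distribution peaks at a configurable mode
(22 nt by default), a heavy-tailed log-normal abundance profile in which a
handful of miRNAs dominate the library, contaminating fragments of longer
ncRNAs (rRNA, tRNA, snRNA, snoRNA, scRNA, srpRNA), and junk reads built so
that each one is removed by exactly one named cleaning rule.  Differential
expression is planted as per-miRNA log2 effects applied to the library-2
expectation; realized counts are Poisson.

Everything is driven by a single integer seed and is byte-for-byte
reproducible.  Truth (per-miRNA counts, per-read categories, planted
effects) is returned separately from the reads; read identifiers carry no
truth information.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import constants as C

__all__ = [
    "SimConfig",
    "References",
    "TruthTable",
    "generate_references",
    "generate_libraries",
    "generate_annotation_and_targets",
    "simulate_experiment",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# miRNA insert-length weights relative to the modal length: the mode takes
# roughly a third of the mass, neighbouring lengths fall off quickly.  This
# mirrors the sharply peaked Dicer-product length profile of real libraries.
_LENGTH_OFFSET_WEIGHTS = {
    -4: 0.04, -3: 0.06, -2: 0.10, -1: 0.14, 0: 0.32, 1: 0.14, 2: 0.10, 3: 0.10,
}

DEFAULT_CONTAMINANT_FRACTIONS = {
    "rRNA": 0.05, "tRNA": 0.03, "snRNA": 0.01,
    "snoRNA": 0.01, "scRNA": 0.005, "srpRNA": 0.005,
}
DEFAULT_JUNK_FRACTIONS = {
    C.RULE_LOW_QUALITY: 0.02,
    C.RULE_ADAPTER5: 0.01,
    C.RULE_NO_ADAPTER3: 0.02,
    C.RULE_POLY_A: 0.01,
    C.RULE_NO_INSERT: 0.01,
    C.RULE_TOO_SHORT: 0.02,
}

_MAX_REJECTION_ATTEMPTS = 10_000


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated two-library experiment."""

    seed: int = 0
    n_mirnas: int = 100
    n_reads_per_library: int = 100_000
    length_mode: int = 22
    abundance_dispersion: float = 1.5
    planted_de: tuple = ()  # ((mirna_id, log2 effect on library 2), ...)
    contaminant_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTAMINANT_FRACTIONS)
    )
    junk_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_JUNK_FRACTIONS)
    )
    adapter_3p: str = C.DEFAULT_ADAPTER_3P
    adapter_5p: str = C.DEFAULT_ADAPTER_5P
    n_contaminants_per_class: int = 5

    def __post_init__(self):
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas must be >= 1")
        if not (C.MIN_INSERT_LEN <= self.length_mode <= C.MAX_INSERT_LEN):
            raise ValueError("length_mode must lie in [18, 30]")
        fracs = list(self.contaminant_fractions.values()) + list(
            self.junk_fractions.values()
        )
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("category fractions must be in [0,1] and sum to <= 1")
        unknown = set(self.junk_fractions) - set(C.RULE_ORDER)
        if unknown:
            raise ValueError(f"unknown junk classes: {sorted(unknown)}")
        if not self.adapter_3p or not self.adapter_5p:
            raise ValueError("adapters must be non-empty")

    def mirna_ids(self) -> list[str]:
        return [f"syn-mir-{i:04d}" for i in range(self.n_mirnas)]


@dataclass
class References:
    """Simulated mature-miRNA and contaminant ncRNA reference sets."""

    mirnas: dict  # id -> sequence (18-25 nt)
    contaminants: dict  # class -> {id -> sequence (>= 30 nt)}

    def write_fastas(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        mature = outdir / "mature.fa"
        _write_fasta(mature, self.mirnas)
        paths["mature"] = mature
        for cls, seqs in self.contaminants.items():
            p = outdir / f"contaminant_{cls}.fa"
            _write_fasta(p, seqs)
            paths[cls] = p
        return paths


@dataclass
class TruthTable:
    """Ground truth for one simulated experiment.

    ``mirna_counts`` maps miRNA id -> (reads in library 1, reads in library
    2, planted log2 effect on library 2).  ``read_categories`` holds, per
    library, the category of every emitted read in emission order; read i of
    library k is named ``r<i>`` in the FASTQ output.
    """

    mirna_counts: dict
    read_categories: tuple  # (list for library 1, list for library 2)

    def category_counts(self, library: int) -> dict:
        out: dict = {}
        for cat in self.read_categories[library - 1]:
            out[cat] = out.get(cat, 0) + 1
        return out

    def junk_counts(self, library: int) -> dict:
        counts = self.category_counts(library)
        return {rule: counts.get(rule, 0) for rule in C.RULE_ORDER}

    def n_reads(self, library: int) -> int:
        return len(self.read_categories[library - 1])

    def to_json(self, path) -> None:
        payload = {
            "mirna_counts": {
                mid: list(v) for mid, v in sorted(self.mirna_counts.items())
            },
            "read_categories": [list(self.read_categories[0]),
                                list(self.read_categories[1])],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            mirna_counts={k: tuple(v) for k, v in payload["mirna_counts"].items()},
            read_categories=(payload["read_categories"][0],
                             payload["read_categories"][1]),
        )


def _write_fasta(path, records: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n{records[name]}\n")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _forbidden_insert(seq: str, cfg: SimConfig) -> bool:
    """True when a legitimate insert would trip a cleaning rule by chance."""
    if cfg.adapter_3p[: C.ADAPTER3_MIN_PREFIX] in seq:
        return True
    if seq.startswith(cfg.adapter_5p[: C.ADAPTER5_MIN_PREFIX]):
        return True
    if seq and seq.count("A") >= C.POLY_A_FRACTION * len(seq):
        return True
    return False


def _sample_insert(rng, length: int, cfg: SimConfig) -> str:
    for _ in range(_MAX_REJECTION_ATTEMPTS):
        seq = _random_seq(rng, length)
        if not _forbidden_insert(seq, cfg):
            return seq
    raise RuntimeError("rejection sampling budget exhausted for insert")


def _mirna_window_clash(candidate: str, mirnas: Mapping[str, str]) -> bool:
    """True when any window of ``candidate`` could pass for a known miRNA.

    The annotation step compares a read to a mature miRNA over their common
    prefix with <= 2 mismatches and <= 2 nt length slack, so the weakest
    window that could match a miRNA of length L is the (L-2)-mer prefix.
    """
    for mir in mirnas.values():
        k = len(mir) - 2
        probe = mir[:k]
        for start in range(len(candidate) - k + 1):
            window = candidate[start : start + k]
            mism = sum(a != b for a, b in zip(window, probe))
            if mism <= 2:
                return True
    return False


def generate_references(config: SimConfig) -> References:
    """Draw mature miRNA and contaminant ncRNA reference sequences.

    miRNAs are 18-25 nt with unique ids and a length profile peaked at
    ``length_mode``; contaminants are 60-120 nt and rejection-sampled so no
    18-25 nt window of any contaminant is within 2 mismatches of a miRNA,
    guaranteeing clean category separation downstream.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = 18, 25
    offsets = sorted(_LENGTH_OFFSET_WEIGHTS)
    lengths_pool = [min(hi, max(lo, config.length_mode + o)) for o in offsets]
    weights = np.array([_LENGTH_OFFSET_WEIGHTS[o] for o in offsets])
    weights = weights / weights.sum()

    mirnas: dict = {}
    seen = set()
    for i, mid in enumerate(config.mirna_ids()):
        # record 0 anchors the modal length so the most abundant miRNA can
        # be placed there by generate_libraries
        length = (
            min(hi, max(lo, config.length_mode))
            if i == 0
            else int(rng.choice(lengths_pool, p=weights))
        )
        for _ in range(_MAX_REJECTION_ATTEMPTS):
            seq = _sample_insert(rng, length, config)
            if seq not in seen:
                break
        else:
            raise RuntimeError("could not draw a unique miRNA sequence")
        seen.add(seq)
        mirnas[mid] = seq

    contaminants: dict = {}
    for cls in C.CONTAMINANT_CLASSES:
        records = {}
        for j in range(config.n_contaminants_per_class):
            length = int(rng.integers(60, 121))
            for _ in range(_MAX_REJECTION_ATTEMPTS):
                seq = _random_seq(rng, length)
                if config.adapter_3p[: C.ADAPTER3_MIN_PREFIX] in seq:
                    continue
                if not _mirna_window_clash(seq, mirnas):
                    break
            else:
                raise RuntimeError(
                    f"rejection sampling budget exhausted for {cls} reference"
                )
            records[f"syn-{cls}-{j:02d}"] = seq
        contaminants[cls] = records
    return References(mirnas=mirnas, contaminants=contaminants)


def _abundance_profile(rng, config: SimConfig, refs: References) -> np.ndarray:
    """Log-normal relative abundances; the top miRNA sits at the modal length."""
    w = rng.lognormal(mean=0.0, sigma=config.abundance_dispersion,
                      size=config.n_mirnas)
    ids = config.mirna_ids()
    top = int(np.argmax(w))
    if len(refs.mirnas[ids[top]]) != config.length_mode:
        # swap the largest weight onto the anchored modal-length miRNA
        w[0], w[top] = w[top], w[0]
    return w / w.sum()


def _contaminant_window(rng, refs: References, cls: str, cfg: SimConfig) -> str:
    seqs = list(refs.contaminants[cls].values())
    for _ in range(_MAX_REJECTION_ATTEMPTS):
        ref = seqs[int(rng.integers(len(seqs)))]
        length = int(rng.integers(18, 26))
        start = int(rng.integers(0, len(ref) - length + 1))
        window = ref[start : start + length]
        if not _forbidden_insert(window, cfg):
            return window
    raise RuntimeError("rejection sampling budget exhausted for contaminant window")


def _junk_read(rng, rule: str, cfg: SimConfig) -> tuple[str, str]:
    """Construct one junk read removed by exactly the named rule."""
    a3 = cfg.adapter_3p
    if rule == C.RULE_LOW_QUALITY:
        insert = _sample_insert(rng, int(rng.integers(18, 26)), cfg)
        seq = insert + a3
        n_low = int(math.floor(0.6 * len(seq)))
        qual = "+" * n_low + "I" * (len(seq) - n_low)  # Phred 10 over 60%
        return seq, qual
    if rule == C.RULE_ADAPTER5:
        insert = _sample_insert(rng, int(rng.integers(18, 26)), cfg)
        seq = cfg.adapter_5p + insert + a3
        return seq, "I" * len(seq)
    if rule == C.RULE_NO_ADAPTER3:
        seq = _sample_insert(rng, 30, cfg)  # no adapter appended
        return seq, "I" * len(seq)
    if rule == C.RULE_POLY_A:
        length = int(rng.integers(18, 26))
        n_other = int(rng.integers(0, int(length * (1 - C.POLY_A_FRACTION)) + 1))
        tail = "".join(rng.choice(np.frombuffer(b"CGT", dtype="S1"),
                                  size=n_other).tobytes().decode())
        seq = "A" * (length - n_other) + tail + a3
        return seq, "I" * len(seq)
    if rule == C.RULE_NO_INSERT:
        seq = a3
        return seq, "I" * len(seq)
    if rule == C.RULE_TOO_SHORT:
        insert = _sample_insert(rng, int(rng.integers(8, C.MIN_INSERT_LEN)), cfg)
        seq = insert + a3
        return seq, "I" * len(seq)
    if rule == C.RULE_OVERLONG:
        insert = _sample_insert(rng, int(rng.integers(31, 40)), cfg)
        seq = insert + a3
        return seq, "I" * len(seq)
    raise ValueError(f"unknown junk rule {rule!r}")


def generate_libraries(
    config: SimConfig,
    refs: References,
    outdir=None,
):
    """Generate both read libraries and the accompanying truth table.

    Returns ``(records1, records2, truth)`` where each ``records`` is a list
    of ``(sequence, quality)`` pairs in emission order.  When ``outdir`` is
    given the libraries are additionally written as ``lib1.fastq`` /
    ``lib2.fastq`` with sequential read ids ``r<i>``.
    """
    if not refs.mirnas:
        raise ValueError("empty miRNA reference set")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ids = config.mirna_ids()
    profile = _abundance_profile(rng, config, refs)
    effects = dict(config.planted_de)
    unknown = set(effects) - set(ids)
    if unknown:
        raise ValueError(f"planted_de names unknown miRNAs: {sorted(unknown)}")

    n = config.n_reads_per_library
    n_junk = {r: int(round(f * n)) for r, f in config.junk_fractions.items()}
    n_cont = {c: int(round(f * n)) for c, f in config.contaminant_fractions.items()}
    n_legit = n - sum(n_junk.values()) - sum(n_cont.values())
    if n_legit <= 0:
        raise ValueError("junk and contaminant fractions leave no legitimate reads")

    lam1 = profile * n_legit
    lam2 = lam1 * np.array([2.0 ** effects.get(m, 0.0) for m in ids])
    counts1 = rng.poisson(lam1)
    counts2 = rng.poisson(lam2)

    mirna_counts = {
        m: (int(counts1[i]), int(counts2[i]), float(effects.get(m, 0.0)))
        for i, m in enumerate(ids)
    }

    libraries = []
    categories = []
    for lib_counts in (counts1, counts2):
        recs: list = []
        cats: list = []
        for i, m in enumerate(ids):
            seq = refs.mirnas[m] + config.adapter_3p
            qual = "I" * len(seq)
            c = int(lib_counts[i])
            recs.extend([(seq, qual)] * c)
            cats.extend(["mirna"] * c)
        for cls, k in n_cont.items():
            for _ in range(k):
                seq = _contaminant_window(rng, refs, cls, config) + config.adapter_3p
                recs.append((seq, "I" * len(seq)))
                cats.append(cls)
        for rule, k in n_junk.items():
            for _ in range(k):
                recs.append(_junk_read(rng, rule, config))
                cats.append(rule)
        order = rng.permutation(len(recs))
        libraries.append([recs[j] for j in order])
        categories.append([cats[j] for j in order])

    truth = TruthTable(mirna_counts=mirna_counts,
                       read_categories=(categories[0], categories[1]))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for k, recs in enumerate(libraries, start=1):
            with open(outdir / f"lib{k}.fastq", "w") as fh:
                fh.writelines(
                    f"@r{i}\n{seq}\n+\n{qual}\n"
                    for i, (seq, qual) in enumerate(recs)
                )
        truth.to_json(outdir / "truth.json")
    return libraries[0], libraries[1], truth


def generate_annotation_and_targets(
    config: SimConfig,
    n_genes: int = 400,
    n_terms: int = 25,
    mean_targets: float = 3.0,
    n_samples_per_group: int = 3,
    n_replicates: int = 3,
    ct_noise_sd: float = 0.2,
    n_assays: int = 10,
    outdir=None,
):
    """Generate a GMT term file, a miRNA->target table, and a qPCR Ct table.

    Returns ``(terms, targets, ct_table, truth)`` where ``terms`` maps term
    id -> gene list, ``targets`` is a list of (mirna_id, gene_id) pairs, the
    Ct table is a list of (sample, group, assay, ct) rows with reference
    assay "18S" present in every sample, and ``truth`` records term sizes,
    per-miRNA target counts and the true log2 expression ratios
    (condition 1 over condition 2) behind the Ct values.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    genes = [f"gene-{i:04d}" for i in range(n_genes)]

    terms: dict = {}
    for t in range(n_terms):
        size = int(rng.integers(10, max(11, n_genes // 6)))
        members = rng.choice(n_genes, size=size, replace=False)
        terms[f"TERM:{t:04d}"] = sorted(genes[g] for g in members)

    targets: list = []
    effects = dict(config.planted_de)
    for m in config.mirna_ids():
        k = 1 + int(rng.poisson(mean_targets))
        chosen = rng.choice(n_genes, size=min(k, n_genes), replace=False)
        targets.extend((m, genes[g]) for g in sorted(chosen))

    # qPCR truth: relative expression of condition 1 vs condition 2 equals
    # 2^(-effect) because planted effects scale the library-2 expectation.
    assay_ids = config.mirna_ids()[: min(n_assays, config.n_mirnas)]
    true_log2_ratio = {m: -effects.get(m, 0.0) for m in assay_ids}
    ct_rows: list = []
    base_ct = {m: float(rng.uniform(20, 30)) for m in assay_ids}
    ref_ct = 12.0
    for group_idx, group in enumerate(("condition1", "condition2")):
        for s in range(n_samples_per_group):
            sample = f"{group}_s{s}"
            for m in assay_ids:
                # condition1 carries the full ratio relative to condition2:
                # higher expression -> proportionally lower Ct
                true_ct = base_ct[m] + (0.0 if group_idx else -true_log2_ratio[m])
                for _ in range(n_replicates):
                    ct = true_ct + float(rng.normal(0.0, ct_noise_sd))
                    ct_rows.append((sample, group, m, round(ct, 4)))
            for _ in range(n_replicates):
                ct = ref_ct + float(rng.normal(0.0, ct_noise_sd))
                ct_rows.append((sample, group, "18S", round(ct, 4)))

    truth = {
        "term_sizes": {t: len(g) for t, g in terms.items()},
        "target_counts": {},
        "true_log2_ratio": true_log2_ratio,
    }
    for m, _g in targets:
        truth["target_counts"][m] = truth["target_counts"].get(m, 0) + 1

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "annotation.gmt", "w") as fh:
            for t in terms:
                fh.write(t + "\tsynthetic\t" + "\t".join(terms[t]) + "\n")
        with open(outdir / "targets.tsv", "w") as fh:
            fh.write("mirna_id\tgene_id\n")
            for m, g in targets:
                fh.write(f"{m}\t{g}\n")
        with open(outdir / "ct.tsv", "w") as fh:
            fh.write("sample\tgroup\tassay\tct\n")
            for row in ct_rows:
                fh.write("\t".join(str(v) for v in row) + "\n")
        with open(outdir / "sim_truth_extras.json", "w") as fh:
            json.dump(truth, fh)
    return terms, targets, ct_rows, truth


def simulate_experiment(config: SimConfig, outdir=None):
    """References + libraries + annotation tables in one call."""
    refs = generate_references(config)
    if outdir is not None:
        refs.write_fastas(outdir)
    lib1, lib2, truth = generate_libraries(config, refs, outdir=outdir)
    terms, targets, ct_rows, extras = generate_annotation_and_targets(
        config, outdir=outdir
    )
    return {
        "references": refs,
        "lib1": lib1,
        "lib2": lib2,
        "truth": truth,
        "terms": terms,
        "targets": targets,
        "ct_rows": ct_rows,
        "extras": extras,
    }
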
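"""End-to-end convenience drivers: simulate -> clean -> annotate -> test."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import annotate, diffexpr, preprocess, synthetic

__all__ = ["PipelineResult", "run_from_fastq", "run_synthetic"]


@dataclass
class PipelineResult:
    clean1: preprocess.CleanReadSet
    clean2: preprocess.CleanReadSet
    count_table: pd.DataFrame
    summary1: pd.DataFrame
    summary2: pd.DataFrame
    de: pd.DataFrame


def run_from_fastq(
    fastq1,
    fastq2,
    mature,
    contaminants=None,
    adapter_3p=None,
    adapter_5p=None,
    max_mismatches: int = 2,
    clean_params: preprocess.CleanParams | None = None,
    de_params: diffexpr.DEParams | None = None,
) -> PipelineResult:
    """Clean two libraries, annotate them and run differential expression.

    ``fastq1`` / ``fastq2`` are FASTQ paths or iterables of (sequence,
    quality) pairs; ``mature`` and ``contaminants`` are id->sequence
    mappings (``contaminants`` keyed by ncRNA class) or FASTA paths.
    """
    from . import constants as C

    adapter_3p = adapter_3p or C.DEFAULT_ADAPTER_3P
    adapter_5p = adapter_5p or C.DEFAULT_ADAPTER_5P
    if isinstance(mature, (str, bytes)) or hasattr(mature, "__fspath__"):
        mature = annotate.load_fasta(mature)
    if contaminants:
        contaminants = {
            cls: (
                annotate.load_fasta(v)
                if isinstance(v, (str, bytes)) or hasattr(v, "__fspath__")
                else v
            )
            for cls, v in contaminants.items()
        }

    clean1 = preprocess.clean_reads(fastq1, adapter_3p, adapter_5p, clean_params)
    clean2 = preprocess.clean_reads(fastq2, adapter_3p, adapter_5p, clean_params)
    table, s1, s2 = annotate.annotate_libraries(
        clean1, clean2, mature, contaminants, max_mismatches
    )
    de = diffexpr.run_de(table, de_params)
    return PipelineResult(clean1, clean2, table, s1, s2, de)


def run_synthetic(
    config: synthetic.SimConfig,
    de_params: diffexpr.DEParams | None = None,
):
    """Simulate a full experiment and analyze it; returns (result, truth).

    The libraries are passed through the same cleaning/annotation/DE path
    as real FASTQ input, only held in memory instead of on disk.
    """
    refs = synthetic.generate_references(config)
    lib1, lib2, truth = synthetic.generate_libraries(config, refs)
    result = run_from_fastq(
        lib1,
        lib2,
        refs.mirnas,
        refs.contaminants,
        adapter_3p=config.adapter_3p,
        adapter_5p=config.adapter_5p,
        de_params=de_params,
    )
    return result, truth
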
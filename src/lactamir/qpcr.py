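"""Relative quantification of miRNA expression from stem-loop RT-qPCR.

Implements the comparative-Ct (2^-ddCt) method: technical replicates are
averaged on the Ct scale, each sample's target Ct is normalized against the
reference assay (18S rRNA by default) to give dCt, group means of dCt are
contrasted against a calibrator group, and relative expression is
2^-(ddCt).  Between-group significance per assay is a two-sample t-test on
the per-sample dCt values.  A concordance check compares qPCR direction
against the sequencing-based differential-expression calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import STATUS_DOWN, STATUS_UP

__all__ = ["read_ct_tsv", "ddct", "relative_expression_table", "concordance"]

REFERENCE_ASSAY = "18S"


def read_ct_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "group", "assay", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def _delta_ct(
    table: pd.DataFrame, assay: str, reference: str
) -> pd.DataFrame:
    """Per-sample dCt = mean Ct(assay) - mean Ct(reference)."""
    means = (
        table[table["assay"].isin((assay, reference))]
        .groupby(["group", "sample", "assay"])["ct"]
        .mean()
        .unstack("assay")
    )
    if assay not in means.columns:
        raise ValueError(f"assay {assay!r} absent from Ct table")
    if reference not in means.columns or means[reference].isna().any():
        bad = (
            means.index.get_level_values("sample").tolist()
            if reference not in means.columns
            else means[means[reference].isna()].index.get_level_values("sample").tolist()
        )
        raise ValueError(f"reference assay {reference!r} missing for samples {bad}")
    out = (means[assay] - means[reference]).dropna().rename("delta_ct")
    return out.reset_index()


def ddct(
    table: pd.DataFrame,
    assay: str,
    calibrator_group: str,
    reference: str = REFERENCE_ASSAY,
) -> dict[str, float]:
    """Relative expression 2^-(ddCt) of one assay per group.

    ddCt contrasts each group's mean dCt against the calibrator group,
    whose own relative expression is exactly 1.
    """
    d = _delta_ct(table, assay, reference)
    groups = d.groupby("group")["delta_ct"].mean()
    if calibrator_group not in groups.index:
        raise ValueError(f"calibrator group {calibrator_group!r} not present")
    return {
        group: float(2.0 ** -(groups[group] - groups[calibrator_group]))
        for group in groups.index
    }


def relative_expression_table(
    table: pd.DataFrame,
    calibrator_group: str,
    reference: str = REFERENCE_ASSAY,
    assays=None,
) -> pd.DataFrame:
    """Per-assay relative expression of the non-calibrator group plus a
    two-sample t-test on per-sample dCt values.

    Returns a DataFrame indexed by assay with columns ``ratio`` (relative
    expression of the test group vs the calibrator), ``log2_ratio`` and
    ``p_value``.
    """
    if assays is None:
        assays = [a for a in table["assay"].unique() if a != reference]
    rows = []
    for assay in assays:
        d = _delta_ct(table, assay, reference)
        rel = ddct(table, assay, calibrator_group, reference)
        test_groups = [g for g in rel if g != calibrator_group]
        if len(test_groups) != 1:
            raise ValueError("expected exactly one non-calibrator group")
        test = test_groups[0]
        a = d.loc[d["group"] == test, "delta_ct"]
        b = d.loc[d["group"] == calibrator_group, "delta_ct"]
        if len(a) > 1 and len(b) > 1:
            p = float(stats.ttest_ind(a, b).pvalue)
        else:
            p = float("nan")
        rows.append((assay, rel[test], float(np.log2(rel[test])), p))
    return pd.DataFrame(
        rows, columns=["assay", "ratio", "log2_ratio", "p_value"]
    ).set_index("assay")


def concordance(
    qpcr: pd.DataFrame,
    de_results: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Direction agreement between qPCR ratios and sequencing DE calls.

    An assay is concordant when a significant qPCR ratio > 1 meets an "up"
    call, a significant ratio < 1 meets a "down" call, or neither platform
    calls the miRNA differential.  The overall agreement fraction is in
    ``attrs["fraction_concordant"]``.
    """
    shared = qpcr.index.intersection(de_results.index)
    if shared.empty:
        raise ValueError("no shared miRNA ids between qPCR and DE results")
    rows = []
    for m in shared:
        ratio = float(qpcr.at[m, "ratio"])
        qpcr_sig = (
            bool(qpcr.at[m, "p_value"] < alpha)
            if not np.isnan(qpcr.at[m, "p_value"])
            else False
        )
        status = de_results.at[m, "status"]
        agree = (
            (qpcr_sig and ratio > 1 and status == STATUS_UP)
            or (qpcr_sig and ratio < 1 and status == STATUS_DOWN)
            or (not qpcr_sig and status not in (STATUS_UP, STATUS_DOWN))
        )
        rows.append((m, ratio, qpcr_sig, status, agree))
    df = pd.DataFrame(
        rows, columns=["mirna_id", "ratio", "qpcr_significant", "status", "concordant"]
    ).set_index("mirna_id")
    df.attrs["fraction_concordant"] = float(df["concordant"].mean())
    return df
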
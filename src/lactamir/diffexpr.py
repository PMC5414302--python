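"""Exact count-based differential expression between two pooled libraries.

The design is one sequencing library per condition with no replicates, so
significance comes from an exact test on the raw counts: conditional on the
count x observed in library 1, the count in library 2 under the null of
equal underlying abundance follows

    p(y | x) = (N2/N1)^y * (x+y)! / (x! * y! * (1 + N2/N1)^(x+y+1)),

where N1 and N2 are the clean-read totals of the two libraries.  The lower
tail C = sum_{y' <= y} p(y'|x) and upper tail D = sum_{y' >= y} p(y'|x)
both include the observed point; the two-sided p-value doubles the smaller
tail and caps at 1.  Everything is evaluated in log space with log-gamma.

Expression levels are reported as normalized expression (NE), reads per
million clean reads.  miRNAs with NE below 3 in both libraries are excluded
before testing; zero NE values among the survivors are replaced by 0.001 so
the log2 fold change NE1/NE2 is always defined.  A miRNA is called up
(down) when log2fc > 1 (< -1) with p < 0.05 and FDR < 0.05; FDR is
Benjamini-Hochberg over the tested miRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEParams",
    "normalize",
    "apply_ne_rules",
    "fold_change",
    "ac_pvalue",
    "bh_fdr",
    "run_de",
]

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_UNCHANGED = "unchanged"
STATUS_EXCLUDED = "excluded_low_NE"


@dataclass(frozen=True)
class DEParams:
    """Thresholds of the differential-expression call."""

    alpha: float = 0.05  # p-value threshold
    fdr_alpha: float = 0.05  # FDR threshold
    lfc: float = 1.0  # |log2 fold change| threshold (fold change 2)
    min_ne: float = 3.0  # NE floor: excluded when below in both libraries
    zero_substitute: float = 0.001  # replaces NE values of exactly zero
    sided: str = "two"  # "two" or "one"


def normalize(x: float, total: int) -> float:
    """Normalized expression: reads-per-million of the library total."""
    if total <= 0:
        raise ValueError("library total must be positive")
    if x < 0:
        raise ValueError("count must be non-negative")
    return x / total * 1e6


def apply_ne_rules(
    ne1: float,
    ne2: float,
    min_ne: float = 3.0,
    zero_substitute: float = 0.001,
) -> tuple[float, float, bool]:
    """Exclusion and zero-substitution rules on a pair of NE values.

    ``keep`` is False when both pre-substitution values are below ``min_ne``;
    zeros are replaced by ``zero_substitute`` so ratios stay finite.
    """
    if ne1 < 0 or ne2 < 0:
        raise ValueError("NE values must be non-negative")
    keep = not (ne1 < min_ne and ne2 < min_ne)
    out1 = ne1 if ne1 > 0 else zero_substitute
    out2 = ne2 if ne2 > 0 else zero_substitute
    return out1, out2, keep


def fold_change(ne1: float, ne2: float) -> float:
    """log2 of the library-1 over library-2 normalized expression."""
    if ne1 <= 0 or ne2 <= 0:
        raise ValueError("fold change requires positive NE values")
    return float(np.log2(ne1) - np.log2(ne2))


def _log_pmf_terms(x: int, y_hi: int, log_r: float) -> np.ndarray:
    """log p(y'|x) for y' = 0..y_hi, with r = N2/N1."""
    ys = np.arange(y_hi + 1)
    log1pr = np.logaddexp(0.0, log_r)  # log(1 + r)
    return (
        ys * log_r
        + gammaln(x + ys + 1)
        - gammaln(x + 1)
        - gammaln(ys + 1)
        - (x + ys + 1) * log1pr
    )


def ac_pvalue(x: int, y: int, n1: int, n2: int, sided: str = "two") -> float:
    """Exact two-library p-value for counts (x, y) at depths (N1, N2).

    ``sided="two"`` doubles the smaller of the two tails (both tails
    include the observed y) and caps at 1; ``sided="one"`` returns the
    smaller tail itself.
    """
    for name, v in (("x", x), ("y", y)):
        if v != int(v) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    x, y = int(x), int(y)

    log_r = float(np.log(n2) - np.log(n1))
    terms = _log_pmf_terms(x, y, log_r)
    # tails accumulated from the small end (logsumexp is order-stable)
    lower = float(np.exp(logsumexp(terms)))
    pmf = float(np.exp(terms[-1]))
    upper = 1.0 - (lower - pmf)
    lower = min(lower, 1.0)
    upper = min(max(upper, pmf), 1.0)
    tail = min(lower, upper)
    if sided == "one":
        return tail
    return min(1.0, 2.0 * tail)


def ac_tails(x: int, y: int, n1: int, n2: int) -> tuple[float, float, float]:
    """(lower tail C, upper tail D, pmf at y) — both tails include y."""
    log_r = float(np.log(n2) - np.log(n1))
    terms = _log_pmf_terms(int(x), int(y), log_r)
    lower = float(np.exp(logsumexp(terms)))
    pmf = float(np.exp(terms[-1]))
    upper = 1.0 - (lower - pmf)
    return min(lower, 1.0), min(max(upper, pmf), 1.0), pmf


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_de(table: pd.DataFrame, params: DEParams | None = None) -> pd.DataFrame:
    """Full differential-expression analysis of a miRNA count table.

    ``table`` is indexed by miRNA id with integer columns ``count_1`` and
    ``count_2`` and library totals in ``attrs["N1"]`` / ``attrs["N2"]``.
    Returns one row per miRNA with NE values, log2 fold change, p, FDR and
    status (up / down / unchanged / excluded_low_NE), sorted by p then
    |log2fc| descending; excluded miRNAs carry NaN p and FDR.
    """
    params = params or DEParams()
    n1, n2 = int(table.attrs["N1"]), int(table.attrs["N2"])
    rows = []
    for mirna_id, row in table.iterrows():
        x, y = int(row["count_1"]), int(row["count_2"])
        ne1_raw, ne2_raw = normalize(x, n1), normalize(y, n2)
        ne1, ne2, keep = apply_ne_rules(
            ne1_raw, ne2_raw, params.min_ne, params.zero_substitute
        )
        lfc = fold_change(ne1, ne2)
        rows.append((mirna_id, x, y, ne1, ne2, lfc, keep))
    df = pd.DataFrame(
        rows, columns=["mirna_id", "x", "y", "NE1", "NE2", "log2fc", "kept"]
    ).set_index("mirna_id")

    kept = df.index[df["kept"]]
    pvals = np.array(
        [ac_pvalue(df.at[m, "x"], df.at[m, "y"], n1, n2, params.sided) for m in kept]
    )
    fdrs = bh_fdr(pvals)
    df["p_value"] = np.nan
    df["fdr"] = np.nan
    df.loc[kept, "p_value"] = pvals
    df.loc[kept, "fdr"] = fdrs

    def status(row):
        if not row["kept"]:
            return STATUS_EXCLUDED
        significant = row["p_value"] < params.alpha and row["fdr"] < params.fdr_alpha
        if significant and row["log2fc"] > params.lfc:
            return STATUS_UP
        if significant and row["log2fc"] < -params.lfc:
            return STATUS_DOWN
        return STATUS_UNCHANGED

    df["status"] = df.apply(status, axis=1)
    df = df.drop(columns="kept")
    order = df.assign(_abs=df["log2fc"].abs()).sort_values(
        ["p_value", "_abs"], ascending=[True, False], na_position="last"
    )
    df = df.loc[order.index]
    df.attrs["N1"], df.attrs["N2"] = n1, n2
    return df
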
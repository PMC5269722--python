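"""Result-table and QQ serialization."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .burden import GeneResult

RESULT_COLUMNS = [
    "gene_name", "gene_id", "ex_mut", "ex_len", "bg_mut", "bg_len",
    "pval", "qval", "ex_mut_rate", "bg_mut_rate", "ratio", "stratum",
]


def results_frame(results: list[GeneResult]) -> pd.DataFrame:
    """Tabulate gene results; lengths are position-genomes, rates per kb."""
    rows = [
        {
            "gene_name": r.gene_name, "gene_id": r.gene_id,
            "ex_mut": r.M, "ex_len": r.N, "bg_mut": r.m, "bg_len": r.n,
            "pval": r.pval, "qval": r.qval,
            "ex_mut_rate": r.ex_rate, "bg_mut_rate": r.bg_rate,
            "ratio": r.ratio, "stratum": r.stratum,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results_tsv(results: list[GeneResult], path) -> None:
    results_frame(results).to_csv(path, sep="\t", index=False, float_format="%.6g",
                                  na_rep="NA")


def qq_points(pvals) -> np.ndarray:
    """(-log10 expected, -log10 observed) pairs for a QQ plot.

    Observed p-values are sorted ascending and paired with uniform expected
    quantiles i/(n+1); the result is invariant to the input order.
    """
    p = np.sort(np.asarray(pvals, dtype=float))
    n = p.size
    if n == 0:
        return np.empty((0, 2))
    expected = np.arange(1, n + 1) / (n + 1)
    with np.errstate(divide="ignore"):
        return np.column_stack([-np.log10(expected), -np.log10(p)])


def write_qq_tsv(pvals, path) -> None:
    pts = qq_points(pvals)
    pd.DataFrame(pts, columns=["expected_neglog10_p", "observed_neglog10_p"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
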
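"""Probe-level two-group differential expression.

Fold change is the difference of group means on the log2 scale (positive
group minus negative group); the default significance test is the two-sided
Welch unequal-variance t-test. Raw p-values drive the 0.05 filter, mirroring
standard microarray practice for this cohort size; Benjamini–Hochberg
q-values are computed and reported alongside but do not gate the filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import BinaryContrast


@dataclass(frozen=True)
class DEResult:
    probe_id: str
    fc: float            # log2 mean difference, positive minus negative group
    p: float
    q: float = float("nan")
    gene: str | None = None
    chromosome: str | None = None
    cytoband: str | None = None


def _welch_p(x: np.ndarray, y: np.ndarray, equal_var: bool = False) -> np.ndarray:
    """Vectorized two-sided t-test p per row; degenerate zero-variance rows
    get p=1 when the means agree and p=0 when they differ."""
    res = stats.ttest_ind(x, y, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        same = np.isclose(x[degenerate].mean(axis=1), y[degenerate].mean(axis=1))
        p[degenerate] = np.where(same, 1.0, 0.0)
    return p


def probe_de(
    matrix: pd.DataFrame,
    contrast: BinaryContrast,
    annotation: pd.DataFrame | None = None,
    equal_var: bool = False,
) -> list[DEResult]:
    """Per-probe differential expression between the contrast's two groups.

    Each group must contain at least 2 samples. ``equal_var=True`` switches
    from Welch's to the pooled-variance Student t-test.
    """
    if contrast.n_positive < 2 or contrast.n_negative < 2:
        raise ValueError(
            f"each group needs >=2 samples, got {contrast.n_positive} vs {contrast.n_negative}"
        )
    missing = [s for s in contrast.samples if s not in matrix.columns]
    if missing:
        raise ValueError(f"contrast samples absent from matrix: {missing[:5]}")
    pos = matrix[list(contrast.positive)].to_numpy(dtype=float)
    neg = matrix[list(contrast.negative)].to_numpy(dtype=float)
    fc = pos.mean(axis=1) - neg.mean(axis=1)
    p = _welch_p(pos, neg, equal_var=equal_var)
    q = multipletests(p, method="fdr_bh")[1]

    results = []
    for i, probe in enumerate(matrix.index):
        gene = chrom = band = None
        if annotation is not None and probe in annotation.index:
            row = annotation.loc[probe]
            gene = row.get("gene")
            chrom = row.get("chromosome")
            band = row.get("cytoband")
        results.append(
            DEResult(
                probe_id=str(probe), fc=float(fc[i]), p=float(p[i]), q=float(q[i]),
                gene=gene, chromosome=chrom, cytoband=band,
            )
        )
    return results


def filter_de(
    results: list[DEResult],
    p_threshold: float = 0.05,
    gene_list: set[str] | list[str] | None = None,
) -> list[DEResult]:
    """Keep probes with p < threshold, optionally intersect with a curated
    gene list (stand-in for a disease-focused annotation filter), and order
    by ascending p."""
    kept = [r for r in results if r.p < p_threshold]
    if gene_list is not None:
        genes = set(gene_list)
        kept = [r for r in kept if r.gene in genes]
    return sorted(kept, key=lambda r: (r.p, r.probe_id))


def chromosome_distribution(
    results: list[DEResult], annotation: pd.DataFrame | None = None
) -> dict[str, float]:
    """Percentage of unique differentially expressed genes per chromosome.

    Genes without a chromosome assignment are pooled under ``"NA"``.
    Percentages sum to 100 over all bins (empty input gives an empty map).
    """
    gene_chrom: dict[str, str] = {}
    for r in results:
        gene = r.gene if r.gene is not None else r.probe_id
        chrom = r.chromosome
        if chrom is None and annotation is not None and r.probe_id in annotation.index:
            chrom = annotation.loc[r.probe_id, "chromosome"]
        gene_chrom[gene] = str(chrom) if chrom is not None and not pd.isna(chrom) else "NA"
    if not gene_chrom:
        return {}
    counts = pd.Series(list(gene_chrom.values())).value_counts()
    return (100.0 * counts / counts.sum()).to_dict()


def de_table(results: list[DEResult]) -> pd.DataFrame:
    """Results as a DataFrame with columns probe_id, gene, FC, p, q, chromosome, cytoband."""
    return pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in results],
            "gene": [r.gene for r in results],
            "FC": [r.fc for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "chromosome": [r.chromosome for r in results],
            "cytoband": [r.cytoband for r in results],
        }
    )


def write_de(results: list[DEResult], path) -> None:
    de_table(results).to_csv(path, sep="\t", index=False)
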
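"""CNA <-> expression integration.

Tests whether recurrent copy-number events alter the expression of the genes
they cover, by contrasting carriers of a region in the positive response
group against non-carriers in the negative group. The expectation under a
simple dosage model is that losses depress expression of covered genes while
gains and LOH leave it unchanged.
"""

from __future__ import annotations

from typing import NamedTuple

import pandas as pd

from .cna import RegionCallMatrix
from .diffexpr import DEResult, probe_de
from .io import BinaryContrast

MIN_GROUP = 2


def genes_in_region(
    region, probe_annotation: pd.DataFrame, unique_genes: bool = False
) -> list[str]:
    """Probes (or unique gene symbols) whose annotated interval overlaps the
    region, with 1-based inclusive overlap semantics.

    ``region`` is anything with chrom/start/end attributes or a
    (chrom, start, end) tuple.
    """
    if hasattr(region, "chrom"):
        chrom, start, end = region.chrom, region.start, region.end
    else:
        chrom, start, end = region
    ann = probe_annotation
    if "start" not in ann.columns or "end" not in ann.columns:
        raise ValueError("probe annotation lacks start/end coordinates")
    located = ann.dropna(subset=["start", "end"])
    hit = located[
        (located["chromosome"].astype(str) == str(chrom))
        & (located["start"] <= end)
        & (located["end"] >= start)
    ]
    if unique_genes:
        return sorted(hit["gene"].astype(str).unique())
    return sorted(hit.index.astype(str))


def carrier_contrast(
    matrix: pd.DataFrame,
    region_index: int,
    call_matrix: RegionCallMatrix,
    contrast: BinaryContrast,
    probe_annotation: pd.DataFrame,
) -> list[DEResult]:
    """Differential expression of a region's covered probes between
    positive-group carriers and negative-group non-carriers.

    ``region_index`` selects the row of ``call_matrix.regions`` under test.
    Samples outside the contrast are ignored; each side needs at least
    two samples.
    """
    region = call_matrix.regions.iloc[region_index]
    calls = dict(zip(call_matrix.samples, call_matrix.calls[region_index]))
    carriers = tuple(
        s for s in contrast.positive if s in calls and calls[s] and s in matrix.columns
    )
    non_carriers = tuple(
        s for s in contrast.negative if s in calls and not calls[s] and s in matrix.columns
    )
    label = f"{region['chrom']}:{region['start']}-{region['end']} ({region['event']})"
    if len(carriers) < MIN_GROUP or len(non_carriers) < MIN_GROUP:
        raise ValueError(
            f"region {label}: need >= {MIN_GROUP} carriers in {contrast.name_positive} "
            f"and >= {MIN_GROUP} non-carriers in {contrast.name_negative}, "
            f"got {len(carriers)} / {len(non_carriers)}"
        )
    probes = genes_in_region(
        (region["chrom"], region["start"], region["end"]), probe_annotation
    )
    probes = [p for p in probes if p in matrix.index]
    if not probes:
        return []
    sub = matrix.loc[probes]
    local = BinaryContrast(
        positive=carriers, negative=non_carriers,
        name_positive=f"{contrast.name_positive}+carrier",
        name_negative=f"{contrast.name_negative}+non-carrier",
    )
    return probe_de(sub, local, annotation=probe_annotation)


class DeregulationSummary(NamedTuple):
    """Fraction of covered genes moving in ``direction`` and, of those, the
    fraction significant at the p threshold. Both None when input is empty."""

    fraction_direction: float | None
    fraction_significant: float | None


def fraction_deregulated(
    results: list[DEResult],
    p_threshold: float = 0.05,
    direction: str = "down",
    by_gene: bool = True,
) -> DeregulationSummary:
    """Summarize dosage-consistent deregulation of a region's genes.

    With ``direction="down"``: the fraction of covered genes with negative
    fold change, and among those the fraction with p below the threshold.
    ``by_gene=False`` counts probes instead of unique gene symbols (a gene
    counts as moved/significant if any of its probes is).
    """
    if not results:
        return DeregulationSummary(None, None)
    if direction == "down":
        moved = lambda r: r.fc < 0
    elif direction == "up":
        moved = lambda r: r.fc > 0
    else:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if by_gene:
        units: dict[str, list[DEResult]] = {}
        for r in results:
            units.setdefault(r.gene if r.gene is not None else r.probe_id, []).append(r)
        groups = list(units.values())
    else:
        groups = [[r] for r in results]
    n = len(groups)
    moved_groups = [g for g in groups if any(moved(r) for r in g)]
    n_moved = len(moved_groups)
    n_sig = sum(
        1 for g in moved_groups if any(moved(r) and r.p < p_threshold for r in g)
    )
    return DeregulationSummary(
        fraction_direction=n_moved / n,
        fraction_significant=(n_sig / n_moved) if n_moved else None,
    )
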
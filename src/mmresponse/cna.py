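"""Cohort-level copy-number-alteration comparison between response groups.

Per event type (gain / loss / LOH) the genome is broken at the union of all
segment endpoints into atomic regions, each sample is scored present/absent
per atomic region, and per-region carrier frequencies of the two response
groups are compared with a two-sided Fisher exact test (probability-mass
rule) plus Benjamini–Hochberg FDR across all regions of all event types
jointly. Two named threshold presets select significant regions:

* ``broad``:      p < 0.05 and >= 25 percentage-point frequency differential
* ``stringent``:  p < 0.01 and >= 10 percentage-point frequency differential
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .io import BinaryContrast, SEGMENT_EVENTS, validate_segments

PRESETS = {
    "broad": {"p_threshold": 0.05, "diff_threshold_pct": 25.0},
    "stringent": {"p_threshold": 0.01, "diff_threshold_pct": 10.0},
}


# ---------------------------------------------------------------------------
# atomic regionization
# ---------------------------------------------------------------------------

@dataclass
class RegionCallMatrix:
    """Atomic regions x samples presence indicators.

    ``regions`` has columns chrom, start, end, event (1-based inclusive);
    ``calls`` is a boolean (n_regions, n_samples) array aligned with
    ``samples``.
    """

    regions: pd.DataFrame
    calls: np.ndarray
    samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.regions), len(self.samples)):
            raise ValueError("calls shape does not match regions x samples")


def regionize(segments: pd.DataFrame, samples) -> RegionCallMatrix:
    """Break segments into atomic regions and score presence per sample.

    Per event type and chromosome, cut points are the union of all segment
    start positions and end+1 positions; atomic regions are the resulting
    intervals restricted to genome covered by at least one segment. Because
    every segment boundary is a cut point, a segment either fully covers an
    atomic region or misses it entirely, so presence is well defined.
    """
    segments = validate_segments(segments)
    samples = tuple(str(s) for s in samples)
    sample_pos = {s: i for i, s in enumerate(samples)}
    region_rows = []
    call_rows = []
    for event in SEGMENT_EVENTS:
        ev = segments[segments["event"] == event]
        for chrom in sorted(ev["chrom"].unique()):
            sub = ev[ev["chrom"] == chrom]
            cuts = np.unique(np.r_[sub["start"].to_numpy(), sub["end"].to_numpy() + 1])
            starts, ends = cuts[:-1], cuts[1:] - 1
            seg_start = sub["start"].to_numpy()
            seg_end = sub["end"].to_numpy()
            seg_sample = sub["sample_id"].to_numpy()
            for a, b in zip(starts, ends):
                covering = (seg_start <= a) & (seg_end >= b)
                if not covering.any():
                    continue
                row = np.zeros(len(samples), dtype=bool)
                for s in seg_sample[covering]:
                    if s in sample_pos:
                        row[sample_pos[s]] = True
                region_rows.append((chrom, int(a), int(b), event))
                call_rows.append(row)
    regions = pd.DataFrame(region_rows, columns=["chrom", "start", "end", "event"])
    calls = (
        np.array(call_rows, dtype=bool)
        if call_rows
        else np.zeros((0, len(samples)), dtype=bool)
    )
    return RegionCallMatrix(regions=regions, calls=calls, samples=samples)


# ---------------------------------------------------------------------------
# Fisher exact test (two-sided, probability-mass rule)
# ---------------------------------------------------------------------------

def _log_hypergeom_pmf(k: np.ndarray, n1: int, n2: int, m: int) -> np.ndarray:
    """log P(K = k) for K ~ Hypergeometric(row margin n1, row margin n2,
    column margin m): tables [[k, n1-k], [m-k, n2-(m-k)]]."""
    return (
        gammaln(n1 + 1) - gammaln(k + 1) - gammaln(n1 - k + 1)
        + gammaln(n2 + 1) - gammaln(m - k + 1) - gammaln(n2 - (m - k) + 1)
        - (gammaln(n1 + n2 + 1) - gammaln(m + 1) - gammaln(n1 + n2 - m + 1))
    )


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums the hypergeometric probability of every table with the observed
    margins whose probability does not exceed that of the observed table
    (relative slack 1e-7 on the comparison). Computed in floating point via
    log-gamma. Degenerate all-zero margins give p = 1.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError(f"counts must be non-negative integers, got {(a, b, c, d)}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n1, n2, m = a + b, c + d, a + c
    if n1 == 0 or n2 == 0 or m == 0 or (b + d) == 0:
        return 1.0
    lo, hi = max(0, m - n2), min(m, n1)
    k = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(k, n1, n2, m)
    logp_obs = float(logp[a - lo])
    include = logp <= logp_obs + np.log1p(1e-7)
    return float(min(1.0, np.exp(logp[include]).sum()))


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionComparison:
    chrom: str
    start: int
    end: int
    event: str
    n_pos: int
    n_neg: int
    count_pos: int
    count_neg: int
    freq_pos: float      # percent
    freq_neg: float      # percent
    p: float
    q: float = float("nan")

    @property
    def differential(self) -> float:
        """Absolute frequency difference in percentage points."""
        return abs(self.freq_pos - self.freq_neg)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def compare_groups(
    call_matrix: RegionCallMatrix,
    contrast: BinaryContrast,
    fdr_scope: str = "joint",
) -> list[RegionComparison]:
    """Per-region frequency comparison between the contrast's groups.

    Group denominators are the samples of each group present in the call
    matrix (samples without any call data are excluded). The BH q-values are
    computed jointly across all event types by default
    (``fdr_scope="per-event"`` adjusts within each event type separately).
    """
    sample_idx = {s: i for i, s in enumerate(call_matrix.samples)}
    pos = [sample_idx[s] for s in contrast.positive if s in sample_idx]
    neg = [sample_idx[s] for s in contrast.negative if s in sample_idx]
    if not pos or not neg:
        raise ValueError("both contrast groups must have samples with call data")
    n_pos, n_neg = len(pos), len(neg)

    results = []
    for i, region in call_matrix.regions.iterrows():
        row = call_matrix.calls[i]
        a = int(row[pos].sum())
        c = int(row[neg].sum())
        p = fisher_exact_two_sided(a, n_pos - a, c, n_neg - c)
        results.append(
            RegionComparison(
                chrom=str(region["chrom"]), start=int(region["start"]),
                end=int(region["end"]), event=str(region["event"]),
                n_pos=n_pos, n_neg=n_neg, count_pos=a, count_neg=c,
                freq_pos=100.0 * a / n_pos, freq_neg=100.0 * c / n_neg, p=p,
            )
        )
    if not results:
        return []
    if fdr_scope == "joint":
        groups = {None: list(range(len(results)))}
    elif fdr_scope == "per-event":
        groups = {}
        for i, r in enumerate(results):
            groups.setdefault(r.event, []).append(i)
    else:
        raise ValueError(f"fdr_scope must be 'joint' or 'per-event', got {fdr_scope!r}")
    q = np.empty(len(results))
    for idxs in groups.values():
        q[idxs] = multipletests([results[i].p for i in idxs], method="fdr_bh")[1]
    return [
        RegionComparison(**{**r.__dict__, "q": float(qi)}) for r, qi in zip(results, q)
    ]


def filter_comparisons(
    results: list[RegionComparison],
    p_threshold: float | None = None,
    diff_threshold_pct: float | None = None,
    preset: str | None = None,
) -> list[RegionComparison]:
    """Keep regions with p below and frequency differential at or above the
    thresholds; ``preset`` selects the named configuration ``"broad"``
    (p<0.05, 25 pp) or ``"stringent"`` (p<0.01, 10 pp)."""
    if preset is not None:
        cfg = PRESETS[preset]
        p_threshold = cfg["p_threshold"]
        diff_threshold_pct = cfg["diff_threshold_pct"]
    if p_threshold is None or diff_threshold_pct is None:
        raise ValueError("provide p_threshold and diff_threshold_pct, or a preset")
    return [
        r for r in results
        if r.p < p_threshold and r.differential >= diff_threshold_pct
    ]


def comparison_table(
    results: list[RegionComparison],
    probe_annotation: pd.DataFrame | None = None,
    decimal: str = ".",
) -> pd.DataFrame:
    """Tabulate comparisons in the reporting layout (event, location, length,
    group frequencies to 3 decimals, p, q, covered genes).

    ``decimal=","`` renders frequencies with a comma separator, matching
    European-style published tables.
    """
    from .integration import genes_in_region  # local import, avoids cycle

    rows = []
    for r in results:
        genes = ""
        if probe_annotation is not None:
            found = genes_in_region(
                (r.chrom, r.start, r.end), probe_annotation, unique_genes=True
            )
            genes = ", ".join(found)

        def fmt(x: float) -> str:
            s = f"{x:.3f}"
            return s.replace(".", ",") if decimal == "," else s

        rows.append(
            {
                "event": r.event, "chrom": r.chrom, "start": r.start, "end": r.end,
                "length_bp": r.length, "freq_pos_pct": fmt(r.freq_pos),
                "freq_neg_pct": fmt(r.freq_neg), "p": r.p, "q": r.q, "genes": genes,
            }
        )
    return pd.DataFrame(rows)


def write_comparisons(results, path, probe_annotation=None, decimal=".") -> None:
    comparison_table(results, probe_annotation, decimal).to_csv(path, sep="\t", index=False)
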
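"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes: a cohort
of ~118 patients with the observed response-category distribution
(CR 15 / nCR 14 / VGPR 40 / PR 42 / SD 7 at the defaults), a planted
low-dimensional class-discriminative probe set with class-specific
covariance in the positive (CR) class, a background of uninformative probes,
planted copy-number regions with distinct carrier frequencies per response
group, and a dosage coupling that lowers expression of genes inside deleted
regions in carriers (gains and LOH leave expression untouched by default).

Everything is deterministic given (config, seed): each operation derives its
own random stream from the seed with a fixed stream key, so the ops can be
called independently and still reproduce bit-identically.

The ground-truth record (informative probes, true class laws, a Monte-Carlo
estimate of the Bayes accuracy, per-sample carrier status, the generated
probe annotation) is what parameter-recovery tests compare against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import RESPONSE_CATEGORIES, SEGMENT_COLUMNS

DEFAULT_PROPORTIONS = {"CR": 0.127, "nCR": 0.118, "VGPR": 0.339, "PR": 0.356, "SD": 0.059}

# fixed stream keys so each op owns an independent substream of the seed
_STREAM_LABELS, _STREAM_EXPR, _STREAM_BAYES, _STREAM_CNA = 1, 2, 3, 5

N_BAYES_MC = 100_000


class ConfigError(ValueError):
    """The synthetic configuration violates an invariant."""


@dataclass(frozen=True)
class PlantedRegion:
    """A copy-number region planted with group-specific carrier frequencies.

    ``carrier_freq`` maps a response category to its carrier fraction; the
    special key ``"other"`` covers any category not listed explicitly.
    ``member_genes`` are the gene symbols placed inside the region, through
    which the dosage coupling acts.
    """

    chrom: str
    start: int
    end: int
    event: str
    carrier_freq: dict
    member_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigError(f"region {self.chrom}:{self.start}-{self.end} has start > end")
        if self.event not in ("gain", "loss", "LOH"):
            raise ConfigError(f"unknown event {self.event!r}")
        for group, f in self.carrier_freq.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"carrier frequency {f} for {group!r} outside [0, 1]")

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.event}"

    def frequency_for(self, category: str) -> float:
        if category in self.carrier_freq:
            return self.carrier_freq[category]
        if "other" in self.carrier_freq:
            return self.carrier_freq["other"]
        raise ConfigError(
            f"region {self.name}: no carrier frequency for group {category!r} "
            "and no 'other' fallback"
        )


def default_regions() -> tuple[PlantedRegion, ...]:
    """One recurrent deletion (the dosage-coupled one, with the 0.60-vs-0.19
    carrier split reported for the most CR-associated loss) and one gain with
    no expression coupling."""
    return (
        PlantedRegion(
            chrom="chr1", start=93_000_000, end=94_372_892, event="loss",
            carrier_freq={"CR": 0.60, "other": 0.19},
            member_genes=tuple(f"LG{i:03d}" for i in range(1, 17)),
        ),
        PlantedRegion(
            chrom="chr3", start=170_000_000, end=170_001_318, event="gain",
            carrier_freq={"CR": 0.467, "other": 0.111},
            member_genes=("GG001",),
        ),
    )


@dataclass
class SyntheticConfig:
    """Parameters of the stated synthetic world.

    Units: expression quantities are log2 intensities; ``mean_shift`` is the
    per-probe mean displacement of the positive class, ``within_class_sd``
    the common within-class standard deviation, ``class_cov_distortion`` the
    equicorrelation of the positive class's informative probes (0 = same law
    as background), ``dosage_effect`` the log2 drop per deleted copy.
    """

    n_samples: int = 118
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    n_probes: int = 5000
    n_informative: int = 5
    mean_shift: float = 1.0
    within_class_sd: float = 1.0
    class_cov_distortion: float = 0.5
    baseline_range: tuple[float, float] = (4.0, 14.0)
    cna_regions: tuple[PlantedRegion, ...] = field(default_factory=default_regions)
    dosage_effect: float = 0.8
    coupled_events: tuple[str, ...] = ("loss",)
    noise_segments_per_sample: int = 0
    positive_category: str = "CR"
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        # published category percentages are rounded to one decimal and sum to
        # 0.999; accept that rounding slack and renormalize, reject anything worse
        if abs(total - 1.0) > 5e-3:
            raise ConfigError(f"class proportions sum to {total}, not 1")
        self.class_proportions = {k: v / total for k, v in self.class_proportions.items()}
        unknown = set(self.class_proportions) - set(RESPONSE_CATEGORIES)
        if unknown:
            raise ConfigError(f"unknown response categories {sorted(unknown)}")
        if self.n_informative > self.n_probes:
            raise ConfigError("n_informative exceeds n_probes")
        if self.within_class_sd <= 0:
            raise ConfigError("within_class_sd must be > 0")
        if self.class_cov_distortion < 0:
            raise ConfigError("class_cov_distortion must be >= 0")
        if self.baseline_range[0] > self.baseline_range[1]:
            raise ConfigError("baseline_range is inverted")
        if self.n_samples < len(self.class_proportions):
            raise ConfigError("need at least one sample per category")


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the generator for parameter-recovery tests."""

    informative_probe_ids: tuple[str, ...] = ()
    shift_signs: tuple[int, ...] = ()
    class_means: dict = field(default_factory=dict)      # 'positive'/'background'
    class_covs: dict = field(default_factory=dict)
    bayes_accuracy: float | None = None
    carrier_status: pd.DataFrame | None = None           # regions x samples bool
    probe_annotation: pd.DataFrame | None = None
    member_probe_map: dict = field(default_factory=dict)  # gene symbol -> probe id


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def _largest_remainder(proportions: dict, n: int) -> dict:
    cats = list(proportions)
    exact = np.array([proportions[c] * n for c in cats])
    counts = np.floor(exact).astype(int)
    remainders = exact - counts
    short = n - counts.sum()
    for idx in sorted(range(len(cats)), key=lambda i: (-remainders[i], i))[:short]:
        counts[idx] += 1
    return dict(zip(cats, counts.tolist()))


def generate_labels(config: SyntheticConfig) -> pd.Series:
    """Response categories per sample: deterministic largest-remainder counts
    (the defaults yield exactly 15/14/40/42/7 at n=118), order shuffled by
    the seed."""
    counts = _largest_remainder(config.class_proportions, config.n_samples)
    labels = np.array([c for cat, k in counts.items() for c in [cat] * k])
    rng = np.random.default_rng([_STREAM_LABELS, config.seed])
    rng.shuffle(labels)
    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    return pd.Series(labels, index=pd.Index(sample_ids, name="sample_id"), name="response")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _positive_class_cov(config: SyntheticConfig) -> np.ndarray:
    """Equicorrelated covariance of the informative probes in the positive
    class; correlation = class_cov_distortion, clipped below 1 to stay
    positive-definite."""
    d = config.n_informative
    rho = min(config.class_cov_distortion, 0.95)
    sd2 = config.within_class_sd**2
    return sd2 * ((1.0 - rho) * np.eye(d) + rho * np.ones((d, d)))


def _true_bayes_accuracy(config: SyntheticConfig, mu_pos, mu_neg, cov_pos, cov_neg) -> float:
    """Monte-Carlo estimate of the accuracy of the true equal-prior QDA rule
    on fresh points drawn from the generating laws (half per class)."""
    d = len(mu_pos)
    if d == 0:
        return 0.5
    rng = np.random.default_rng([_STREAM_BAYES, config.seed])
    n_half = N_BAYES_MC // 2
    Xp = rng.multivariate_normal(mu_pos, cov_pos, size=n_half, method="cholesky")
    Xn = rng.multivariate_normal(mu_neg, cov_neg, size=n_half, method="cholesky")

    def g(X, mu, cov):
        sign, logdet = np.linalg.slogdet(cov)
        diff = X - mu
        return -0.5 * logdet - 0.5 * np.einsum(
            "ij,jk,ik->i", diff, np.linalg.inv(cov), diff
        )

    correct_pos = (g(Xp, mu_pos, cov_pos) >= g(Xp, mu_neg, cov_neg)).mean()
    correct_neg = (g(Xn, mu_pos, cov_pos) < g(Xn, mu_neg, cov_neg)).mean()
    return float((correct_pos + correct_neg) / 2.0)


def _build_probe_annotation(
    config: SyntheticConfig, probe_ids: list[str], informative: np.ndarray
) -> tuple[pd.DataFrame, dict]:
    """Assign gene symbols and coordinates; member genes of planted regions
    claim the first non-informative probes and sit inside their region,
    everything else goes to filler coordinates away from the planted loci."""
    genes = [f"G{i + 1:05d}" for i in range(config.n_probes)]
    chroms = [f"chr{(i % 22) + 1}" for i in range(config.n_probes)]
    starts = [500_000_000 + (i // 22) * 10_000 + 1 for i in range(config.n_probes)]
    ends = [s + 2_000 - 1 for s in starts]
    cytobands = ["synthetic"] * config.n_probes

    informative_set = set(informative.tolist())
    available = (i for i in range(config.n_probes) if i not in informative_set)
    member_probe_map: dict[str, str] = {}
    for region in config.cna_regions:
        span = region.end - region.start + 1
        width = max(1, span // (len(region.member_genes) + 1)) if region.member_genes else 1
        for j, gene in enumerate(region.member_genes):
            try:
                idx = next(available)
            except StopIteration:
                warnings.warn(f"not enough probes to place member gene {gene}")
                break
            genes[idx] = gene
            chroms[idx] = region.chrom
            g_start = region.start + j * width
            starts[idx] = g_start
            ends[idx] = min(region.end, g_start + max(0, width - 1))
            member_probe_map[gene] = probe_ids[idx]
    annotation = pd.DataFrame(
        {"gene": genes, "chromosome": chroms, "cytoband": cytobands,
         "start": starts, "end": ends},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return annotation, member_probe_map


def generate_expression(
    config: SyntheticConfig, labels: pd.Series
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw the log2 expression matrix and record the ground truth.

    Background probes follow one shared per-probe normal law (baseline
    uniform in ``baseline_range``, sd ``within_class_sd``) in every class.
    The informative probes are drawn class-conditionally: positive-class
    means are shifted by ``mean_shift`` with alternating signs (+,-,+,...)
    and the probes are equicorrelated by ``class_cov_distortion``; the other
    classes share the background law.
    """
    if len(labels) != config.n_samples:
        raise ConfigError(f"labels length {len(labels)} != n_samples {config.n_samples}")
    rng = np.random.default_rng([_STREAM_EXPR, config.seed])
    probe_ids = [f"P{i + 1:05d}" for i in range(config.n_probes)]
    informative = np.sort(
        rng.choice(config.n_probes, size=config.n_informative, replace=False)
    )
    baselines = rng.uniform(*config.baseline_range, size=config.n_probes)
    values = baselines[:, None] + config.within_class_sd * rng.standard_normal(
        (config.n_probes, config.n_samples)
    )

    signs = np.array([1 if i % 2 == 0 else -1 for i in range(config.n_informative)])
    mu_neg = baselines[informative]
    mu_pos = mu_neg + signs * config.mean_shift
    cov_neg = config.within_class_sd**2 * np.eye(config.n_informative)
    cov_pos = _positive_class_cov(config)

    pos_mask = (labels == config.positive_category).to_numpy()
    n_pos = int(pos_mask.sum())
    if config.n_informative > 0 and n_pos > 0:
        values[np.ix_(informative, pos_mask)] = rng.multivariate_normal(
            mu_pos, cov_pos, size=n_pos, method="cholesky"
        ).T

    matrix = pd.DataFrame(
        values, index=pd.Index(probe_ids, name="probe_id"), columns=labels.index
    )
    annotation, member_probe_map = _build_probe_annotation(config, probe_ids, informative)
    truth = SyntheticTruth(
        informative_probe_ids=tuple(probe_ids[i] for i in informative),
        shift_signs=tuple(int(s) for s in signs),
        class_means={"positive": mu_pos, "background": mu_neg},
        class_covs={"positive": cov_pos, "background": cov_neg},
        bayes_accuracy=_true_bayes_accuracy(config, mu_pos, mu_neg, cov_pos, cov_neg),
        probe_annotation=annotation,
        member_probe_map=member_probe_map,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# copy-number segments
# ---------------------------------------------------------------------------

def generate_cna(
    config: SyntheticConfig, labels: pd.Series, truth: SyntheticTruth | None = None
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw per-sample carrier status for every planted region and emit the
    corresponding segment table; updates (or creates) the truth record's
    carrier matrix. Non-carriers get no overlapping segment of that event
    type; optional uniform background noise segments land far from the
    planted loci."""
    if truth is None:
        truth = SyntheticTruth()
    rng = np.random.default_rng([_STREAM_CNA, config.seed])
    rows = []
    carrier = pd.DataFrame(
        False,
        index=pd.Index([r.name for r in config.cna_regions], name="region"),
        columns=labels.index,
    )
    for region in config.cna_regions:
        freqs = labels.map(region.frequency_for).to_numpy(dtype=float)
        draws = rng.random(len(labels)) < freqs
        for sample, hit in zip(labels.index, draws):
            if hit:
                rows.append((sample, region.chrom, region.start, region.end, region.event))
        carrier.loc[region.name] = draws
    for sample in labels.index:
        for _ in range(config.noise_segments_per_sample):
            chrom = f"chr{rng.integers(1, 23)}"
            start = int(rng.integers(600_000_000, 700_000_000))
            length = int(rng.integers(10_000, 1_000_000))
            event = ("gain", "loss", "LOH")[rng.integers(0, 3)]
            rows.append((sample, chrom, start, start + length, event))
    segments = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    truth.carrier_status = carrier
    return segments, truth


def couple_expression_to_cna(
    matrix: pd.DataFrame,
    segments: pd.DataFrame,
    truth: SyntheticTruth,
    config: SyntheticConfig,
) -> pd.DataFrame:
    """Apply the dosage model: carriers of a coupled (by default, loss)
    region have the expression of its member-gene probes lowered by
    ``dosage_effect``. Other samples and events are untouched; a member gene
    with no mapped probe raises a warning and is skipped."""
    out = matrix.copy()
    if truth.carrier_status is None:
        return out
    for region in config.cna_regions:
        if region.event not in config.coupled_events:
            continue
        carriers = truth.carrier_status.loc[region.name]
        carrier_samples = [s for s in carriers.index[carriers] if s in out.columns]
        if not carrier_samples:
            continue
        for gene in region.member_genes:
            probe = truth.member_probe_map.get(gene)
            if probe is None or probe not in out.index:
                warnings.warn(f"member gene {gene} has no mapped probe; skipped")
                continue
            out.loc[probe, carrier_samples] -= config.dosage_effect
    return out


# ---------------------------------------------------------------------------
# one-call cohort
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    labels: pd.Series
    expression: pd.DataFrame
    segments: pd.DataFrame
    annotation: pd.DataFrame
    truth: SyntheticTruth


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Labels -> expression -> CNA -> dosage coupling, in one call."""
    labels = generate_labels(config)
    matrix, truth = generate_expression(config, labels)
    segments, truth = generate_cna(config, labels, truth)
    matrix = couple_expression_to_cna(matrix, segments, truth, config)
    return SyntheticCohort(
        config=config, labels=labels, expression=matrix,
        segments=segments, annotation=truth.probe_annotation, truth=truth,
    )
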
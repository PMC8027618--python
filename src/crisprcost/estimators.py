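"""Diversity, self-targeting and fitness statistics.

Alpha diversity (observed variants, bias-corrected Chao1, Shannon, Simpson,
Simpson evenness) with hypergeometric rarefaction; the PAM-ratio estimator of
the fraction of cells carrying a lethal self-targeting spacer; and selection
coefficients from pairwise competition counts.

The self-targeting estimator exists because canonical-PAM self-targeting
spacers are autoimmune and purged before they can be sequenced, so their
frequency cannot be read off the data directly. Non-canonical-PAM
self-targeters are (nearly) harmless and remain observable. Assuming PAM class
is assigned at acquisition independently of the target, the canonical:
non-canonical ratio rho among *phage*-targeting spacers estimates the same
ratio at acquisition, and

    f_cells = f_self_nc * rho

estimates the fraction of cells that acquired a canonical (lethal)
self-targeting spacer, where f_self_nc is the read fraction in arrays with a
non-canonical self-targeting spacer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .spacers import SpacerRecord

__all__ = [
    "chao1",
    "shannon",
    "simpson",
    "simpson_evenness",
    "observed_variants",
    "rarefaction_curve",
    "SelfTargetEstimate",
    "estimate_self_targeting",
    "CompetitionCount",
    "selection_coefficient",
    "relative_fitness",
    "bootstrap_ci",
]

METRICS: dict[str, "callable"] = {}


class EstimatorError(ValueError):
    pass


def _counts(x) -> np.ndarray:
    c = np.asarray(x, dtype=float)
    if c.ndim != 1:
        raise EstimatorError("counts must be a 1-D vector")
    if (c < 0).any():
        raise EstimatorError("counts must be non-negative")
    if c.sum() <= 0:
        raise EstimatorError("counts must contain at least one positive value")
    return c


def _metric(fn):
    METRICS[fn.__name__] = fn
    return fn


@_metric
def observed_variants(counts) -> float:
    """Number of variants with non-zero count."""
    return float((_counts(counts) > 0).sum())


@_metric
def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1*(F1-1) / (2*(F2+1))."""
    c = _counts(counts)
    s_obs = (c > 0).sum()
    f1 = (c == 1).sum()
    f2 = (c == 2).sum()
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


@_metric
def shannon(counts, base: float = math.e) -> float:
    """Shannon diversity -sum p_i log p_i over positive frequencies."""
    c = _counts(counts)
    p = c[c > 0] / c.sum()
    return float(-(p * np.log(p)).sum() / math.log(base))


@_metric
def simpson(counts) -> float:
    """Simpson diversity 1 - sum p_i^2."""
    c = _counts(counts)
    p = c / c.sum()
    return float(1.0 - (p ** 2).sum())


@_metric
def simpson_evenness(counts) -> float:
    """Inverse-Simpson evenness (1 / sum p_i^2) / S_obs."""
    c = _counts(counts)
    p = c / c.sum()
    return float(1.0 / (p ** 2).sum() / (c > 0).sum())


def rarefaction_curve(table, depths, reps: int = 33, metric="chao1",
                      seed: int | None = None):
    """Mean diversity at fixed subsampling depths, per sample.

    For every sample (column of the clusters x samples table) and every depth
    not exceeding the sample total, ``reps`` subsamples are drawn *without
    replacement* (multivariate hypergeometric) and the metric is averaged.
    Depths exceeding the sample total yield the full-sample (plug-in) value
    and are flagged in the ``saturated`` column of the result.

    Returns a tidy DataFrame (sample, depth, mean, sd, saturated).
    """
    import pandas as pd

    if hasattr(table, "empty") and table.empty:
        raise EstimatorError("empty abundance table")
    if reps < 1:
        raise EstimatorError("reps must be >= 1")
    depths = [int(x) for x in depths]
    if any(x <= 0 for x in depths):
        raise EstimatorError("depths must be positive")
    fn = METRICS[metric] if isinstance(metric, str) else metric
    rng = np.random.default_rng(seed)
    rows = []
    for sample in table.columns:
        col = np.asarray(table[sample], dtype=np.int64)
        total = int(col.sum())
        for depth in depths:
            if depth >= total:
                val = fn(col)
                rows.append(dict(sample=sample, depth=depth, mean=val, sd=0.0,
                                 saturated=True))
                continue
            vals = [fn(rng.multivariate_hypergeometric(col, depth))
                    for _ in range(reps)]
            rows.append(dict(sample=sample, depth=depth,
                             mean=float(np.mean(vals)), sd=float(np.std(vals)),
                             saturated=False))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SelfTargetEstimate:
    """Components of the PAM-ratio self-targeting estimate."""

    rho_hat: float        # canonical:non-canonical ratio among phage-targeting spacers
    f_self_nc: float      # read fraction in non-canonical self-targeting arrays
    f_self_cells: float   # estimated fraction of cells with a lethal self-target
    n_phage_canonical: int
    n_phage_noncanonical: int
    reads_self_noncanonical: int
    reads_total: int


def estimate_self_targeting(records: list[SpacerRecord],
                            rho_from: str = "types") -> SelfTargetEstimate:
    """Estimate the fraction of cells carrying a canonical-PAM self-targeting
    spacer from classified spacer records.

    rho is computed from distinct spacer types by default (``rho_from="types"``,
    less distorted by post-acquisition selection on read counts) or from reads
    (``rho_from="reads"``).
    """
    if rho_from not in ("types", "reads"):
        raise EstimatorError(f"rho_from must be 'types' or 'reads', got {rho_from!r}")
    phage = [r for r in records if r.target == "phage"]
    can = [r for r in phage if r.pam == "canonical"]
    noncan = [r for r in phage if r.pam == "non-canonical"]
    if not can or not noncan:
        raise EstimatorError(
            "need at least one phage-targeting spacer of each PAM class "
            f"(canonical={len(can)}, non-canonical={len(noncan)})")
    reads_total = sum(r.count for r in records)
    if reads_total <= 0:
        raise EstimatorError("zero total reads")
    if rho_from == "types":
        rho_hat = len(can) / len(noncan)
    else:
        num = sum(r.count for r in can)
        den = sum(r.count for r in noncan)
        if den == 0:
            raise EstimatorError("zero reads in non-canonical phage spacers")
        rho_hat = num / den
    reads_self_nc = sum(r.count for r in records
                        if r.target == "host" and r.pam == "non-canonical")
    f_self_nc = reads_self_nc / reads_total
    return SelfTargetEstimate(
        rho_hat=rho_hat,
        f_self_nc=f_self_nc,
        f_self_cells=f_self_nc * rho_hat,
        n_phage_canonical=len(can),
        n_phage_noncanonical=len(noncan),
        reads_self_noncanonical=reads_self_nc,
        reads_total=reads_total,
    )


@dataclass(frozen=True)
class CompetitionCount:
    """Blue/white colony counts from a pairwise competition assay."""

    marked_t0: int
    unmarked_t0: int
    marked_end: int
    unmarked_end: int
    days: float

    def __post_init__(self):
        for name in ("marked_t0", "unmarked_t0", "marked_end", "unmarked_end"):
            if getattr(self, name) < 0:
                raise EstimatorError(f"{name} must be >= 0")
        if self.marked_t0 + self.unmarked_t0 == 0 or self.marked_end + self.unmarked_end == 0:
            raise EstimatorError("each timepoint needs at least one colony")
        if self.days < 0:
            raise EstimatorError("days must be >= 0")


def _logit_fraction(marked: int, unmarked: int, pseudocount: float) -> float:
    m = marked + pseudocount
    u = unmarked + pseudocount
    if m == 0 or u == 0:
        raise EstimatorError(
            "zero colony count gives an infinite logit; consider pseudocount=0.5")
    return math.log(m / u)


def selection_coefficient(counts: CompetitionCount, focal: str = "marked",
                          pseudocount: float = 0.0) -> float:
    """Per-day selection coefficient of the focal strain.

    s = [logit(x_end) - logit(x_0)] / days, with x the focal-strain colony
    fraction. Zero counts raise unless a pseudocount (e.g. 0.5) is supplied.
    """
    if focal not in ("marked", "unmarked"):
        raise EstimatorError(f"focal must be 'marked' or 'unmarked', got {focal!r}")
    if counts.days == 0:
        raise EstimatorError("cannot estimate a per-day coefficient over 0 days")
    l0 = _logit_fraction(counts.marked_t0, counts.unmarked_t0, pseudocount)
    l1 = _logit_fraction(counts.marked_end, counts.unmarked_end, pseudocount)
    s = (l1 - l0) / counts.days
    return s if focal == "marked" else -s


def relative_fitness(counts: CompetitionCount, focal: str = "marked",
                     pseudocount: float = 0.0) -> float:
    """Relative fitness reported as 1 + s per day (frequency data only)."""
    return 1.0 + selection_coefficient(counts, focal, pseudocount)


def bootstrap_ci(values, stat=np.mean, n_boot: int = 1000, alpha: float = 0.05,
                 seed: int | None = None) -> tuple[float, float]:
    """Seeded percentile bootstrap confidence interval for a statistic."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EstimatorError("cannot bootstrap an empty sample")
    rng = np.random.default_rng(seed)
    boots = [stat(rng.choice(values, size=values.size, replace=True))
             for _ in range(n_boot)]
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
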
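"""Synthetic data generators for every pipeline input.

The generators emulate the statistical structure of the study system:

* spacer acquisition under primed adaptation -- protospacer positions fall off
  around the priming site, PAM class is assigned at a fixed canonical:
  non-canonical ratio independent of the target, a small fraction of
  acquisitions hit the host genome, and canonical-PAM self-targeters are
  purged by selection before sequencing;
* blue/white competition counts drawn binomially around a logit-linear
  frequency trajectory with a fixed per-day selection coefficient;
* negative-binomial host + phage RNA-seq counts with an early/middle/late
  phage transcriptional programme and attenuated phage expression in
  CRISPR-immune hosts;
* phenotype counts of streak-tested clones (24 per sample) drawn
  multinomially from genotype frequencies.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import CompetitionCount
from .spacers import SpacerRecord

__all__ = [
    "SpacerSimParams",
    "ExprSimParams",
    "generate_spacer_dataset",
    "generate_competition_counts",
    "generate_expression_dataset",
    "sample_clone_phenotypes",
    "PhenotypeCounts",
    "spacer_records_to_tsv",
    "ExpressionMatrix",
]


class SimulationError(ValueError):
    pass


def _check(cond: bool, field_name: str, msg: str):
    if not cond:
        raise SimulationError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class SpacerSimParams:
    """Conditions of the spacer-acquisition simulation.

    Defaults reproduce the study's stated conditions: the priming site at
    phage genome position 27847, and a canonical-PAM self-targeting cell
    fraction of 0.0068% (frac_self * rho / (1 + rho) with rho = 2).
    """

    n_events: int = 10_000
    frac_self: float = 1.02e-4
    pam_canonical_ratio: float = 2.0
    selection_against_self_canonical: float = 0.05
    read_depth: int = 1_000_000
    priming_center: int = 27_847
    priming_spread: float = 2_000.0
    genome_length: int = 36_415
    host_genome_length: int = 6_537_648
    spacer_length: int = 32
    seed: int = 0

    def __post_init__(self):
        _check(self.n_events >= 1, "n_events", "must be >= 1")
        _check(math.isfinite(self.frac_self) and 0.0 <= self.frac_self <= 1.0,
               "frac_self", "must lie in [0, 1]")
        _check(math.isfinite(self.pam_canonical_ratio) and self.pam_canonical_ratio > 0,
               "pam_canonical_ratio", "must be > 0")
        _check(0.0 <= self.selection_against_self_canonical <= 1.0,
               "selection_against_self_canonical", "must lie in [0, 1]")
        _check(self.read_depth >= self.n_events, "read_depth",
               "must be >= n_events")
        _check(self.priming_spread > 0, "priming_spread", "must be > 0")
        _check(0 <= self.priming_center < self.genome_length, "priming_center",
               "must lie on the genome")
        _check(self.spacer_length >= 15, "spacer_length", "must be >= 15")


def _random_unique_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    bases = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out), length))
        for row in block:
            s = "".join(bases[row])
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


def _discrete_laplace_positions(rng: np.random.Generator, n: int, center: int,
                                spread: float, genome_length: int) -> np.ndarray:
    """Discretised Laplace kernel around the priming site, truncated to the
    genome by resampling."""
    pos = np.empty(n, dtype=np.int64)
    todo = np.arange(n)
    while todo.size:
        draw = np.rint(rng.laplace(center, spread, size=todo.size)).astype(np.int64)
        ok = (draw >= 0) & (draw < genome_length)
        pos[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return pos


def generate_spacer_dataset(params: SpacerSimParams,
                            sample: str = "sim") -> list[SpacerRecord]:
    """Simulate spacer-acquisition events and their sequenced read counts.

    Each event yields a distinct spacer targeting the host with probability
    ``frac_self`` (else the phage), with a canonical PAM with probability
    rho/(1+rho). Phage protospacer coordinates follow the priming-centred
    Laplace kernel. Canonical-PAM self-targeters have their expected abundance
    multiplied by the survival factor before ``read_depth`` reads are drawn
    multinomially. Events drawing zero reads are unobserved and dropped.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_events
    is_self = rng.random(n) < params.frac_self
    p_can = params.pam_canonical_ratio / (1.0 + params.pam_canonical_ratio)
    is_can = rng.random(n) < p_can
    phage_pos = _discrete_laplace_positions(
        rng, n, params.priming_center, params.priming_spread, params.genome_length)
    host_pos = rng.integers(0, params.host_genome_length, size=n)
    seqs = _random_unique_seqs(rng, n, params.spacer_length)

    weights = np.ones(n)
    weights[is_self & is_can] *= params.selection_against_self_canonical
    probs = weights / weights.sum()
    counts = rng.multinomial(params.read_depth, probs)

    records = []
    for i in range(n):
        if counts[i] == 0:
            continue
        records.append(SpacerRecord(
            sequence=seqs[i],
            target="host" if is_self[i] else "phage",
            pam="canonical" if is_can[i] else "non-canonical",
            coordinate=int(host_pos[i] if is_self[i] else phage_pos[i]),
            strand="+",
            count=int(counts[i]),
            sample=sample,
            spacer_id=f"sp{i:06d}",
        ))
    return records


def spacer_records_to_tsv(records: list[SpacerRecord], path) -> None:
    pd.DataFrame([dict(spacer_id=r.spacer_id, sequence=r.sequence, target=r.target,
                       pam=r.pam, coordinate=r.coordinate, strand=r.strand,
                       count=r.count, sample=r.sample) for r in records]
                 ).to_csv(path, sep="\t", index=False)


def generate_competition_counts(s_true: float, x0: float = 0.5, days: float = 3.0,
                                colonies: int = 200, seed: int = 0) -> CompetitionCount:
    """Simulate a blue/white competition: the marked strain starts at fraction
    x0 and its log-odds drift at ``s_true`` per day; ``colonies`` colonies are
    scored at T0 and at the end."""
    if not 0.0 < x0 < 1.0:
        raise SimulationError(f"x0={x0!r} is degenerate; must lie strictly in (0, 1)")
    if colonies <= 0:
        raise SimulationError("colonies must be > 0")
    if days < 0:
        raise SimulationError("days must be >= 0")
    rng = np.random.default_rng(seed)
    logit_end = math.log(x0 / (1 - x0)) + s_true * days
    x_end = 1.0 / (1.0 + math.exp(-logit_end))
    m0 = int(rng.binomial(colonies, x0))
    m1 = int(rng.binomial(colonies, x_end))
    return CompetitionCount(marked_t0=m0, unmarked_t0=colonies - m0,
                            marked_end=m1, unmarked_end=colonies - m1, days=days)


@dataclass(frozen=True)
class PhenotypeCounts:
    """Streak-test phenotype counts for one sample of clones."""

    sensitive: int
    crispr: int
    surface_mutant: int

    @property
    def total(self) -> int:
        return self.sensitive + self.crispr + self.surface_mutant


def sample_clone_phenotypes(freqs, n_clones: int = 24,
                            seed: int | None = 0) -> PhenotypeCounts:
    """Multinomial sample of (sensitive, CRISPR-immune, surface mutant)
    phenotypes among ``n_clones`` streak-tested clones."""
    f = np.asarray(freqs, dtype=float)
    if f.shape != (3,):
        raise SimulationError("freqs must have exactly 3 entries")
    if (f < 0).any():
        raise SimulationError(f"negative frequency in {freqs!r}")
    if abs(f.sum() - 1.0) > 1e-9:
        raise SimulationError(f"frequencies sum to {f.sum()!r}, not 1")
    if n_clones < 1:
        raise SimulationError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    s, c, m = rng.multinomial(n_clones, f / f.sum())
    return PhenotypeCounts(sensitive=int(s), crispr=int(c), surface_mutant=int(m))


# ---------------------------------------------------------------------------
# expression

GENOTYPES = ("WT", "BIM2", "BIM2-uninfected")

#: Relative expression of each temporal class at 0/35/60/120 min post infection.
PROGRAMME_SHAPES = {
    "early": (0.02, 1.00, 0.45, 0.20),
    "middle": (0.01, 0.30, 1.00, 0.50),
    "late": (0.01, 0.08, 0.40, 1.00),
}


@dataclass(frozen=True)
class ExprSimParams:
    """Conditions of the RNA-seq count simulation.

    Five replicates per genotype group at 0/35/60/120 min post infection;
    phage expression in infected CRISPR-immune (BIM2) hosts is divided by
    ``phage_attenuation`` (default 5, the study's observed fold difference);
    uninfected controls have zero expected phage counts.
    """

    n_host_genes: int = 200
    n_phage_genes: int = 51
    timepoints: tuple[int, ...] = (0, 35, 60, 120)
    n_replicates: int = 5
    phage_attenuation: float = 5.0
    nb_dispersion: float = 0.05
    library_size: float = 1e6
    phage_peak_fraction: float = 0.05
    programme: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        _check(self.n_host_genes >= 1, "n_host_genes", "must be >= 1")
        _check(self.n_phage_genes >= 1, "n_phage_genes", "must be >= 1")
        _check(self.n_replicates >= 1, "n_replicates", "must be >= 1")
        _check(self.phage_attenuation >= 1.0, "phage_attenuation", "must be >= 1")
        _check(self.nb_dispersion >= 0.0, "nb_dispersion", "must be >= 0")
        _check(self.library_size > 0, "library_size", "must be > 0")
        _check(0.0 < self.phage_peak_fraction < 1.0, "phage_peak_fraction",
               "must lie in (0, 1)")
        _check(all(b > a for a, b in zip(self.timepoints, self.timepoints[1:])),
               "timepoints", "must be strictly increasing")
        if self.programme is not None:
            _check(len(self.programme) == self.n_phage_genes, "programme",
                   f"needs one class per phage gene ({self.n_phage_genes})")
            bad = set(self.programme) - set(PROGRAMME_SHAPES)
            _check(not bad, "programme", f"unknown classes {sorted(bad)}")

    def gene_programme(self) -> tuple[str, ...]:
        """Early/middle/late class per phage gene (round-robin by default)."""
        if self.programme is not None:
            return self.programme
        classes = tuple(PROGRAMME_SHAPES)
        return tuple(classes[i % 3] for i in range(self.n_phage_genes))


@dataclass
class ExpressionMatrix:
    """Gene x sample counts plus gene origin and sample metadata.

    ``counts``: DataFrame indexed by gene id with one column per sample.
    ``gene_origin``: Series mapping gene id -> "host" | "phage".
    ``samples``: DataFrame with columns sample, genotype, minutes, replicate.
    """

    counts: pd.DataFrame
    gene_origin: pd.Series
    samples: pd.DataFrame

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise SimulationError("negative counts")
        missing = set(self.counts.columns) - set(self.samples["sample"])
        if missing:
            raise SimulationError(f"samples lacking metadata: {sorted(missing)}")
        missing_genes = set(self.counts.index) - set(self.gene_origin.index)
        if missing_genes:
            raise SimulationError(f"genes lacking origin: {sorted(missing_genes)[:5]}")

    def write_tsv(self, counts_path, samples_path, origin_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        self.samples.to_csv(samples_path, sep="\t", index=False)
        if origin_path is not None:
            self.gene_origin.rename("origin").to_frame().to_csv(origin_path, sep="\t")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2; Poisson in
    the dispersion -> 0 limit; exactly zero where the mean is zero."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(mean[pos])
        return out
    size = 1.0 / dispersion
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def generate_expression_dataset(params: ExprSimParams) -> ExpressionMatrix:
    """Simulate the infection time-course count matrix.

    Host genes get lognormal baseline means shared across groups and
    timepoints. Phage genes follow their temporal class profile in infected
    WT; infected BIM2 means are those divided by ``phage_attenuation``;
    uninfected controls have zero phage means. At the peak of infection phage
    reads make up about ``phage_peak_fraction`` of the WT library.
    """
    rng = np.random.default_rng(params.seed)
    host_genes = [f"host_{i:04d}" for i in range(params.n_host_genes)]
    phage_genes = [f"phage_{i:03d}" for i in range(params.n_phage_genes)]
    programme = params.gene_programme()

    host_weights = rng.lognormal(0.0, 1.0, size=params.n_host_genes)
    host_means = host_weights / host_weights.sum() * params.library_size

    phage_weights = rng.lognormal(0.0, 0.5, size=params.n_phage_genes)
    shapes = np.array([PROGRAMME_SHAPES[c] for c in programme])  # genes x times
    profile = shapes * phage_weights[:, None]
    # scale so the largest per-timepoint phage total is phage_peak_fraction
    # of the library in infected WT
    peak_total = profile.sum(axis=0).max()
    profile *= params.phage_peak_fraction * params.library_size / peak_total

    columns, meta = [], []
    data = []
    for genotype in GENOTYPES:
        infected = genotype != "BIM2-uninfected"
        atten = params.phage_attenuation if genotype == "BIM2" else 1.0
        for t_idx, minutes in enumerate(params.timepoints):
            for rep in range(1, params.n_replicates + 1):
                name = f"{genotype}_t{minutes}_r{rep}"
                phage_mean = profile[:, t_idx] / atten if infected else np.zeros(params.n_phage_genes)
                mean = np.concatenate([host_means, phage_mean])
                data.append(_nb_draw(rng, mean, params.nb_dispersion))
                columns.append(name)
                meta.append(dict(sample=name, genotype=genotype,
                                 minutes=minutes, replicate=rep))
    counts = pd.DataFrame(np.column_stack(data), index=host_genes + phage_genes,
                          columns=columns)
    counts.index.name = "gene"
    origin = pd.Series(["host"] * params.n_host_genes + ["phage"] * params.n_phage_genes,
                       index=counts.index, name="origin")
    return ExpressionMatrix(counts=counts, gene_origin=origin,
                            samples=pd.DataFrame(meta))
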
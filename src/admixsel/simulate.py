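"""Forward simulation of three-way admixed cohorts under selection.

The simulated scenario mimics a recently admixed Latin American population:
three differentiated source populations (Amerindian, European and African
proxies) contribute haplotypes in a single founding pulse (default
50% / 45% / 5%), followed by 20 generations of random mating over a 3 Mb
region split into three segments by two recombination hotspots. The
mid-section carries alleles under positive selection whenever their ancestry
matches ``selected_ancestry`` (the African proxy by default): a haplotype
whose mid-section is of the selected ancestry is sampled as a parent with
relative weight 1 + s (haploid viability selection). Crossovers occur only at
the two hotspot boundaries, so each haplotype is an ancestry-atomic triple of
segments and ground-truth local ancestry is exact by construction.

Source panels come from a Balding–Nichols allele-frequency hierarchy (per-SNP
population frequencies drawn around a shared ancestral frequency with a
per-population drift parameter F) combined with a founder-mosaic copying
process that induces linkage disequilibrium decaying with map distance.

Phasing switch errors are injected by, at each heterozygous site scanned left
to right, crossing over the two haplotypes of an individual with a fixed
probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import ANCESTRIES, HaplotypePanel, PanelError, make_markers


class SimInputError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the admixture-under-selection simulation.

    Defaults are the full-scale conditions: a 50,000-haplotype admixed pool,
    50/45/5% Amerindian/European/African contributions, 20 generations, a
    3 Mb region at 1000 SNPs/cM and 1 cM/Mb, two hotspots with per-generation
    crossover probability 0.2, a 0.5 Mb selected mid-section, 1,000 cohort
    diplotypes and 200 training haplotypes per source population.
    ``reduced()`` gives the documented desk-scale variant (5,000-haplotype
    pool, 600 markers).
    """

    n_pool: int = 50_000
    admix_proportions: tuple[float, float, float] = (0.50, 0.45, 0.05)
    generations: int = 20
    region_length: int = 3_000_000
    hotspot_probs: tuple[float, float] = (0.2, 0.2)
    selection_coefficient: float = 0.05
    selected_ancestry: int = 2            # African proxy
    midsection_length: int = 500_000
    snp_density: float = 1000.0           # SNPs per cM
    cm_per_mb: float = 1.0
    n_cohort_diplotypes: int = 1000
    n_training_haps_per_pop: int = 200
    differentiation: tuple[float, float, float] = (0.25, 0.15, 0.15)
    n_panel_haps_per_pop: int = 600       # training set-aside + founder pool
    seed: int | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.admix_proportions) - 1.0) > 1e-8:
            raise SimInputError("admix_proportions must sum to 1")
        if not all(0 <= p <= 0.5 for p in self.hotspot_probs):
            raise SimInputError("hotspot_probs must be in [0, 0.5]")
        if self.selection_coefficient < 0:
            raise SimInputError("selection_coefficient must be >= 0")
        for name in ("n_pool", "generations", "region_length", "midsection_length",
                     "n_cohort_diplotypes", "n_training_haps_per_pop",
                     "n_panel_haps_per_pop"):
            if getattr(self, name) <= 0:
                raise SimInputError(f"{name} must be positive")
        if self.n_pool % 2:
            raise SimInputError("n_pool must be even")
        if self.midsection_length >= self.region_length:
            raise SimInputError("mid-section must be shorter than the region")
        if not 0 <= self.selected_ancestry < 3:
            raise SimInputError("selected_ancestry must index one of 3 populations")

    @property
    def n_markers(self) -> int:
        return int(round(self.region_length / 1e6 * self.cm_per_mb * self.snp_density))

    @property
    def boundaries_bp(self) -> tuple[float, float]:
        """Hotspot positions: the mid-section is centered in the region."""
        a = (self.region_length - self.midsection_length) / 2.0
        return a, a + self.midsection_length

    def segment_of_markers(self, markers: pd.DataFrame) -> np.ndarray:
        a, b = self.boundaries_bp
        bp = markers["bp"].to_numpy()
        return np.where(bp <= a, 0, np.where(bp <= b, 1, 2)).astype(np.int8)

    @classmethod
    def reduced(cls, **overrides) -> "SimConfig":
        """Desk-scale conditions: 5,000-haplotype pool, 600 markers."""
        base = dict(n_pool=5000, snp_density=200.0, n_cohort_diplotypes=200)
        base.update(overrides)
        return cls(**base)


@dataclass
class SourcePanels:
    panels: tuple[HaplotypePanel, HaplotypePanel, HaplotypePanel]
    pop_freqs: np.ndarray            # (3, n_markers) Balding–Nichols draws
    ancestral_freqs: np.ndarray      # (n_markers,)
    differentiation: tuple[float, float, float]

    def __post_init__(self) -> None:
        m0 = self.panels[0].markers["bp"].to_numpy()
        for p in self.panels[1:]:
            if not np.array_equal(p.markers["bp"].to_numpy(), m0):
                raise PanelError("source panels must share one marker grid")

    @property
    def markers(self) -> pd.DataFrame:
        return self.panels[0].markers


def generate_source_panels(n_markers: int, n_haps_per_pop: int,
                           differentiation: tuple[float, float, float] | float,
                           seed: int | np.random.Generator | None = None,
                           markers: pd.DataFrame | None = None,
                           region_length: int | None = None,
                           cm_per_mb: float = 1.0,
                           n_founders: int = 64,
                           mosaic_switch_rate: float = 1000.0,
                           copy_error: float = 0.002) -> SourcePanels:
    """Three differentiated source panels over one marker grid.

    Per SNP, an ancestral frequency is drawn Uniform(0.1, 0.9) and each
    population's frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) — the
    Balding–Nichols model, whose F is approximately the population's Fst to
    the ancestral pool. Haplotypes are mosaics of ``n_founders`` founder
    haplotypes (founders drawn site-wise Bernoulli at the population
    frequency), switching founders per marker interval with probability
    1 - exp(-rate * d) for map distance d in Morgans, plus a small per-site
    copy error; this yields LD that decays with map distance.
    """
    if n_markers < 2:
        raise SimInputError("n_markers must be >= 2")
    if n_haps_per_pop < 1 or n_founders < 2:
        raise SimInputError("panel sizes must be positive")
    if np.isscalar(differentiation):
        differentiation = (float(differentiation),) * 3
    if not all(0 < f < 1 for f in differentiation):
        raise SimInputError("differentiation parameters must be in (0,1)")
    rng = np.random.default_rng(seed)
    if markers is None:
        region_length = region_length or n_markers * 1000
        markers = make_markers(n_markers, region_length, cm_per_mb)
    if len(markers) != n_markers:
        raise SimInputError("marker table size disagrees with n_markers")

    p_anc = rng.uniform(0.1, 0.9, size=n_markers)
    pop_freqs = np.empty((3, n_markers))
    for k, f in enumerate(differentiation):
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        pop_freqs[k] = rng.beta(a, b)

    d_morgan = np.diff(markers["cm"].to_numpy()) / 100.0
    switch_p = 1.0 - np.exp(-mosaic_switch_rate * d_morgan)
    panels = []
    for k in range(3):
        founders = (rng.random((n_founders, n_markers)) < pop_freqs[k]).astype(np.int8)
        # founder index path per haplotype: Markov switches along the map
        idx = np.empty((n_haps_per_pop, n_markers), dtype=np.int64)
        idx[:, 0] = rng.integers(n_founders, size=n_haps_per_pop)
        switches = rng.random((n_haps_per_pop, n_markers - 1)) < switch_p
        jumps = rng.integers(n_founders, size=(n_haps_per_pop, n_markers - 1))
        for m in range(1, n_markers):
            idx[:, m] = np.where(switches[:, m - 1], jumps[:, m - 1], idx[:, m - 1])
        alleles = founders[idx, np.arange(n_markers)]
        flip = rng.random(alleles.shape) < copy_error
        alleles = np.where(flip, 1 - alleles, alleles)
        panels.append(HaplotypePanel(
            alleles, markers,
            sample_ids=[f"{ANCESTRIES[k]}_h{i}" for i in range(n_haps_per_pop)],
            population=ANCESTRIES[k]))
    return SourcePanels(tuple(panels), pop_freqs, p_anc, tuple(differentiation))


def hudson_fst(freq_a: np.ndarray, freq_b: np.ndarray,
               n_a: int, n_b: int) -> float:
    """Hudson's Fst estimator averaged over SNPs (ratio of averages)."""
    pa, pb = np.asarray(freq_a, float), np.asarray(freq_b, float)
    num = (pa - pb) ** 2 - pa * (1 - pa) / (n_a - 1) - pb * (1 - pb) / (n_b - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    return float(num.sum() / den.sum())


@dataclass
class AdmixedCohort:
    """Sampled admixed haplotypes with exact per-segment ancestry truth."""

    haplotypes: np.ndarray            # (2*n_diplotypes, n_markers) in {0,1}
    truth_ancestry: np.ndarray        # (2*n_diplotypes, 3) segment ancestry labels
    markers: pd.DataFrame
    pairing: np.ndarray               # (n_diplotypes, 2) haplotype row indices
    marker_segment: np.ndarray        # (n_markers,) segment index 0/1/2
    pool_segment_freqs: np.ndarray    # (3 segments, 3 ancestries) final pool freqs
    config: SimConfig = None
    seed: int | None = None

    @property
    def n_diplotypes(self) -> int:
        return self.pairing.shape[0]

    def panel(self) -> HaplotypePanel:
        ids = [f"ind{i}_h{j}" for i in range(self.n_diplotypes) for j in (0, 1)]
        return HaplotypePanel(self.haplotypes, self.markers, sample_ids=ids)

    def truth_dosage_per_marker(self, ancestry: int) -> np.ndarray:
        """True per-marker average diploid dosage of ``ancestry`` in the cohort."""
        anc_per_marker = self.truth_ancestry[:, self.marker_segment]  # (H, M)
        return 2.0 * (anc_per_marker == ancestry).mean(axis=0)

    def truth_dosage_field(self) -> np.ndarray:
        """(n_diplotypes, n_markers, 3) true diploid ancestry dosages."""
        anc = self.truth_ancestry[:, self.marker_segment]             # (H, M)
        onehot = (anc[:, :, None] == np.arange(3)).astype(np.float64)
        return onehot[self.pairing[:, 0]] + onehot[self.pairing[:, 1]]


def selected_frequency_trajectory(p0: float, s: float, n: int,
                                  pool_size: int | None = None
                                  ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic haploid trajectory p' = p(1+s)/(1+ps) and, if a finite
    pool size is given, the standard error accumulated from per-generation
    binomial resampling of the pool (propagated through the recursion's local
    growth factor)."""
    p = np.empty(n + 1)
    var = np.zeros(n + 1)
    p[0] = p0
    for t in range(n):
        g = (1 + s) / (1 + p[t] * s) ** 2          # d p_{t+1} / d p_t
        p[t + 1] = p[t] * (1 + s) / (1 + p[t] * s)
        if pool_size:
            var[t + 1] = var[t] * g * g + p[t + 1] * (1 - p[t + 1]) / pool_size
    return p, np.sqrt(var)


def simulate_admixture(panels: SourcePanels, config: SimConfig,
                       rng: np.random.Generator | None = None) -> AdmixedCohort:
    """One-pulse admixture followed by ``generations`` of weighted resampling.

    Generation 0 draws ``n_pool`` haplotypes from the three panels with the
    admixture proportions. Each later generation repeats ``n_pool / 2`` times:
    draw two haplotypes with replacement (weight 1 + s when a haplotype's
    mid-section ancestry is the selected one), cross them over independently
    at each hotspot with its configured probability, and emit both
    recombinants. Because crossovers happen only at the two boundaries, a
    haplotype is tracked as (source population, panel row) per segment and
    alleles are materialized only for the final cohort sample, which is drawn
    without replacement and paired consecutively into diplotypes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    markers = panels.markers
    seg_of_marker = config.segment_of_markers(markers)
    if len({int(s) for s in seg_of_marker}) < 3:
        raise SimInputError("marker grid does not cover all three segments")
    for p in panels.panels:
        if p.n_haplotypes == 0:
            raise SimInputError("empty source panel")

    n_pool, n_half = config.n_pool, config.n_pool // 2
    props = np.asarray(config.admix_proportions)
    s = config.selection_coefficient
    sel = config.selected_ancestry

    pop0 = rng.choice(3, size=n_pool, p=props).astype(np.int8)
    seg_pop = np.repeat(pop0[:, None], 3, axis=1)           # (n_pool, 3)
    seg_src = np.empty((n_pool, 3), dtype=np.int64)
    for k in range(3):
        n_k = int((pop0 == k).sum())
        seg_src[pop0 == k] = rng.integers(
            panels.panels[k].n_haplotypes, size=n_k)[:, None]

    p1, p2 = config.hotspot_probs
    for _ in range(config.generations):
        w = np.where(seg_pop[:, 1] == sel, 1.0 + s, 1.0)
        parents = rng.choice(n_pool, size=(n_half, 2), p=w / w.sum())
        x1 = rng.random(n_half) < p1
        x2 = rng.random(n_half) < p2
        # source-parent indicator per segment: cumulative XOR of crossovers
        c = np.empty((n_half, 3), dtype=np.intp)
        c[:, 0] = 0
        c[:, 1] = x1
        c[:, 2] = x1 ^ x2
        rows = np.arange(n_half)[:, None]
        pa = parents[rows, c]                               # (n_half, 3)
        pb = parents[rows, 1 - c]
        cols = np.arange(3)
        seg_pop = np.concatenate([seg_pop[pa, cols], seg_pop[pb, cols]])
        seg_src = np.concatenate([seg_src[pa, cols], seg_src[pb, cols]])

    pool_segment_freqs = np.stack(
        [(seg_pop == k).mean(axis=0) for k in range(3)], axis=1)  # (seg, anc)

    n_out = 2 * config.n_cohort_diplotypes
    if n_out > n_pool:
        raise SimInputError("cohort larger than the admixed pool")
    take = rng.choice(n_pool, size=n_out, replace=False)
    out_pop, out_src = seg_pop[take], seg_src[take]

    alleles = np.empty((n_out, len(markers)), dtype=np.int8)
    for seg in range(3):
        m_idx = np.flatnonzero(seg_of_marker == seg)
        for k in range(3):
            rows_k = np.flatnonzero(out_pop[:, seg] == k)
            if rows_k.size:
                alleles[np.ix_(rows_k, m_idx)] = \
                    panels.panels[k].alleles[np.ix_(out_src[rows_k, seg], m_idx)]
    pairing = np.arange(n_out).reshape(-1, 2)
    return AdmixedCohort(alleles, out_pop, markers, pairing, seg_of_marker,
                         pool_segment_freqs, config, config.seed)


def inject_switch_errors(haplotypes: np.ndarray, pairing: np.ndarray,
                         rate: float,
                         seed: int | np.random.Generator | None = None
                         ) -> np.ndarray:
    """Phasing switch errors: scanning markers left to right, each
    heterozygous site of a diplotype independently initiates, with probability
    ``rate``, a swap of the two haplotype suffixes from that site onward.
    Unphased genotypes are unchanged at every site."""
    if not 0.0 <= rate <= 1.0:
        raise SimInputError("rate must be in [0,1]")
    haplotypes = np.asarray(haplotypes)
    pairing = np.asarray(pairing)
    if pairing.ndim != 2 or pairing.shape[1] != 2:
        raise SimInputError("pairing must be (n_diplotypes, 2) haplotype indices")
    used = pairing.ravel()
    if len(np.unique(used)) != used.size:
        raise SimInputError("haplotypes must be paired uniquely")
    rng = np.random.default_rng(seed)
    out = haplotypes.copy()
    h1, h2 = out[pairing[:, 0]], out[pairing[:, 1]]
    het = h1 != h2
    init = het & (rng.random(h1.shape) < rate)
    swapped = np.cumsum(init, axis=1) % 2 == 1       # swap state incl. this site
    n1 = np.where(swapped, h2, h1)
    n2 = np.where(swapped, h1, h2)
    out[pairing[:, 0]] = n1
    out[pairing[:, 1]] = n2
    return out


@dataclass
class PhaseErrorConfig:
    """Switch-error rates: cohort and Amerindian-proxy training panels phase
    worse (2%) than the European/African-proxy panels (1%)."""

    cohort_rate: float = 0.02
    training_rates: tuple[float, float, float] = (0.02, 0.01, 0.01)

    def __post_init__(self) -> None:
        rates = (self.cohort_rate, *self.training_rates)
        if not all(0.0 <= r <= 1.0 for r in rates):
            raise SimInputError("switch-error rates must be in [0,1]")


@dataclass
class SimulatedStudy:
    training: tuple[HaplotypePanel, HaplotypePanel, HaplotypePanel]
    cohort: AdmixedCohort
    source: SourcePanels
    config: SimConfig


def simulate_study(config: SimConfig,
                   phase_errors: PhaseErrorConfig | None = None) -> SimulatedStudy:
    """End-to-end generator: source panels, training set-aside, admixture
    under selection, cohort sampling, and optional switch-error injection."""
    rng = np.random.default_rng(config.seed)
    markers = make_markers(config.n_markers, config.region_length, config.cm_per_mb)
    source = generate_source_panels(
        config.n_markers, config.n_panel_haps_per_pop, config.differentiation,
        seed=rng, markers=markers)
    n_t = config.n_training_haps_per_pop
    if n_t >= config.n_panel_haps_per_pop:
        raise SimInputError("training set-aside exhausts the source panels")
    training, founders = [], []
    for k, p in enumerate(source.panels):
        training.append(HaplotypePanel(p.alleles[:n_t], p.markers,
                                       sample_ids=p.sample_ids[:n_t],
                                       population=p.population))
        founders.append(HaplotypePanel(p.alleles[n_t:], p.markers,
                                       sample_ids=p.sample_ids[n_t:],
                                       population=p.population))
    founder_panels = SourcePanels(tuple(founders), source.pop_freqs,
                                  source.ancestral_freqs, source.differentiation)
    cohort = simulate_admixture(founder_panels, config, rng=rng)

    if phase_errors is not None:
        cohort.haplotypes = inject_switch_errors(
            cohort.haplotypes, cohort.pairing, phase_errors.cohort_rate, seed=rng)
        for k, t in enumerate(training):
            pairing = np.arange(t.n_haplotypes - t.n_haplotypes % 2).reshape(-1, 2)
            t.alleles = inject_switch_errors(
                t.alleles, pairing, phase_errors.training_rates[k], seed=rng)
    return SimulatedStudy(tuple(training), cohort, source, config)
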
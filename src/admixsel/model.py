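"""Two-layer haplotype-cluster model for local ancestry inference.

The latent state at each marker is a pair (s, j): an upper-layer cluster s
representing an ancestral population and a lower-layer cluster j representing
a contemporary haplotype group within that ancestry. Along the chromosome the
upper state switches between ancestries at a rate set by the number of
admixture generations g and the genetic map (per-interval switch probability
1 - exp(-g d) for map distance d in Morgans, landing on an ancestry drawn
from the individual's admixture proportions); conditional on no ancestry
switch, the lower state switches among that ancestry's clusters at a faster
fixed rate. Emissions are Bernoulli: cluster j carries an allele-1 frequency
theta_mj at marker m.

The model is fitted by EM. The theta update supports differential sample
weights: training haplotypes (whose ancestry is pinned) receive weight w_t
and cohort samples weight w_c, so an arbitrarily large cohort can be
down-weighted without corrupting the ancestral allele-frequency estimates —
and when a training panel is absent, that ancestry's clusters are learned
from the cohort alone, the common weight cancelling out of the update. This
is what lets the model run with one training population missing, or with no
labels at all (structure mode).

Diplotype input is handled exactly: the chain runs over ordered pairs of
lower clusters with phase integrated out of the emissions.

Per-individual ancestry dosages are posterior ancestry probabilities summed
over a haplotype's clusters ([0, 1] per haplotype, [0, 2] per diplotype),
averaged over several independent EM restarts after aligning cluster labels
across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dosage import DosageField
from .panel import ANCESTRIES, GenotypePanel, HaplotypePanel, PanelError

logger = logging.getLogger(__name__)


class ModelInputError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Settings of the two-layer model and its EM fit.

    ``weight_cohort=None`` resolves to 0.1 * min(1, n_training_haps /
    n_cohort_rows) so the training panels dominate the allele-frequency
    estimates of the anchored clusters (w_t >> w_c); with no training panels
    the common cohort weight cancels out of the theta update.
    """

    n_upper: int = 3
    n_lower: int = 15
    admix_generations: float = 20.0
    em_steps: int = 20
    em_runs: int = 10
    weight_training: float = 1.0
    weight_cohort: float | None = None
    mode: str = "auto"                  # supervised | partial | structure | auto
    lambda_lower: float = 100.0         # lower-layer switch rate per Morgan
    theta_floor: float = 1e-4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_upper < 2:
            raise ModelInputError("need at least 2 upper clusters")
        if self.n_lower < self.n_upper:
            raise ModelInputError("need at least one lower cluster per ancestry")
        if self.weight_training < 0 or (self.weight_cohort or 0) < 0:
            raise ModelInputError("weights must be non-negative")
        if self.weight_training == 0 and self.weight_cohort == 0:
            raise ModelInputError("weights must not both be zero")
        if self.mode not in ("auto", "supervised", "partial", "structure"):
            raise ModelInputError(f"unknown mode {self.mode!r}")


def split_clusters(n_lower: int, n_upper: int) -> np.ndarray:
    """Assign lower clusters to ancestries as evenly as possible (15 -> 5/5/5)."""
    counts = np.full(n_upper, n_lower // n_upper)
    counts[: n_lower % n_upper] += 1
    return np.repeat(np.arange(n_upper), counts)


@dataclass
class TwoLayerParams:
    """Parameter collection of the two-layer model.

    The object handed to :func:`e_step` plays the role of the previous
    iteration's estimates (the conditioning collection), and the M-step
    produces the next one.
    """

    theta: np.ndarray                # (n_markers, n_lower) in [0,1]
    cluster_ancestry: np.ndarray     # (n_lower,) upper-cluster index per cluster
    upper_switch: np.ndarray         # (n_markers-1,) ancestry switch prob per interval
    lower_switch: np.ndarray         # (n_markers-1,) cluster switch prob per interval
    admix_prop: np.ndarray           # (n_rows, n_upper), rows sum to 1

    def __post_init__(self) -> None:
        if np.any(self.theta < 0) or np.any(self.theta > 1):
            raise ModelInputError("theta must be in [0,1]")
        for p, name in ((self.upper_switch, "upper_switch"),
                        (self.lower_switch, "lower_switch")):
            if np.any(p < 0) or np.any(p > 1):
                raise ModelInputError(f"{name} must be in [0,1]")
        if not np.allclose(self.admix_prop.sum(axis=1), 1.0, atol=1e-6):
            raise ModelInputError("admixture proportions must sum to 1 per row")

    @property
    def n_upper(self) -> int:
        return self.admix_prop.shape[1]

    @property
    def n_lower(self) -> int:
        return self.theta.shape[1]

    def cluster_prior_weights(self) -> np.ndarray:
        """Within-ancestry lower-cluster weights (uniform within each ancestry)."""
        counts = np.bincount(self.cluster_ancestry, minlength=self.n_upper)
        return 1.0 / counts[self.cluster_ancestry]


def switch_probs(cm: np.ndarray, rate: float) -> np.ndarray:
    """Per-interval switch probability 1 - exp(-rate * d), d in Morgans."""
    d = np.diff(np.asarray(cm, dtype=np.float64)) / 100.0
    return 1.0 - np.exp(-rate * d)


@dataclass
class PosteriorField:
    """E-step output for one batch of rows (haplotypes or diplotypes)."""

    q: np.ndarray                    # (n_rows, n_markers, n_lower) cluster marginals
    ancestry: np.ndarray             # (n_rows, n_markers, n_upper), sums to ploidy
    loglik: np.ndarray               # (n_rows,)
    upper_counts: np.ndarray         # (n_rows, n_upper) expected ancestry-draw counts
    n_emit: np.ndarray               # (n_rows, n_markers, n_lower) emission exposures
    y_emit: np.ndarray               # expected allele-1 emissions per cluster
    ploidy: int = 1


def _prepare(params: TwoLayerParams, n_rows: int):
    anc = params.cluster_ancestry
    wvec = params.cluster_prior_weights()
    G = np.zeros((params.n_lower, params.n_upper))
    G[np.arange(params.n_lower), anc] = 1.0
    return anc, wvec, G


def e_step(params: TwoLayerParams, alleles: np.ndarray) -> PosteriorField:
    """Exact forward–backward over the layered chain for haplotype rows.

    ``alleles`` is (n_rows, n_markers) with values {0, 1} and -1 for missing
    (missing sites contribute a unit emission and are excluded from the
    theta-update exposures). Rows correspond 1:1 to rows of
    ``params.admix_prop``.
    """
    H = np.asarray(alleles)
    n, M = H.shape
    C = params.n_lower
    if M != params.theta.shape[0]:
        raise ModelInputError("marker count mismatch between params and data")
    if params.admix_prop.shape[0] != n:
        raise ModelInputError("admix_prop rows must match data rows")
    anc, wvec, G = _prepare(params, n)
    pi = params.admix_prop
    pstar = pi[:, anc] * wvec                      # (n, C) stationary state prior
    u, v = params.upper_switch, params.lower_switch
    theta = params.theta

    # Emission likelihoods, unit at missing sites.
    obs = H >= 0
    E = np.where((H == 1)[:, :, None], theta[None, :, :], 1.0 - theta[None, :, :])
    E[~obs] = 1.0

    alpha = np.empty((n, M, C))
    scale = np.empty((n, M))
    a = pstar * E[:, 0]
    scale[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / scale[:, 0][:, None]
    for m in range(1, M):
        am = alpha[:, m - 1]
        group = am @ G                              # (n, S) ancestry mass
        spread = group[:, anc] * wvec               # redistribute within ancestry
        pred = (1 - u[m - 1]) * ((1 - v[m - 1]) * am + v[m - 1] * spread) \
            + u[m - 1] * pstar                      # alpha rows sum to 1
        a = pred * E[:, m]
        scale[:, m] = a.sum(axis=1)
        alpha[:, m] = a / scale[:, m][:, None]

    beta = np.empty((n, M, C))
    beta[:, M - 1] = 1.0
    jump = np.zeros((n, params.n_upper))
    for m in range(M - 2, -1, -1):
        x = E[:, m + 1] * beta[:, m + 1]
        dot = (x * pstar).sum(axis=1)
        gsum = (x * wvec) @ G
        within = gsum[:, anc]
        beta[:, m] = ((1 - u[m]) * ((1 - v[m]) * x + v[m] * within)
                      + u[m] * dot[:, None]) / scale[:, m + 1][:, None]
        # expected mass through the ancestry-redraw branch of this interval
        jmass = (u[m] / scale[:, m + 1])[:, None] * pstar * x
        jump += jmass @ G

    q = alpha * beta
    q /= q.sum(axis=2, keepdims=True)
    ancestry = q @ G
    loglik = np.log(scale).sum(axis=1)
    upper_counts = ancestry[:, 0] + jump            # init draw + redraws

    n_emit = np.where(obs[:, :, None], q, 0.0)
    y_emit = np.where((H == 1)[:, :, None], q, 0.0)
    return PosteriorField(q, ancestry, loglik, upper_counts, n_emit, y_emit, 1)


def _apply_trans(A: np.ndarray, axis: int, u: float, v: float,
                 pstar: np.ndarray, wvec: np.ndarray, anc: np.ndarray,
                 G: np.ndarray) -> np.ndarray:
    """Forward transition of one chain of the product state, A is (n, C, C)."""
    if axis == 1:
        group = np.einsum("ncd,cs->nsd", A, G)
        spread = group[:, anc, :] * wvec[None, :, None]
        tot = A.sum(axis=1)
        jump = u * pstar[:, :, None] * tot[:, None, :]
        return (1 - u) * ((1 - v) * A + v * spread) + jump
    group = np.einsum("ncd,ds->ncs", A, G)
    spread = group[:, :, anc] * wvec[None, None, :]
    tot = A.sum(axis=2)
    jump = u * pstar[:, None, :] * tot[:, :, None]
    return (1 - u) * ((1 - v) * A + v * spread) + jump


def _apply_trans_back(X: np.ndarray, axis: int, u: float, v: float,
                      pstar: np.ndarray, wvec: np.ndarray, anc: np.ndarray,
                      G: np.ndarray) -> np.ndarray:
    """Backward operator (sum over the arrival state) of one chain."""
    if axis == 1:
        dot = np.einsum("ncd,nc->nd", X, pstar)
        gsum = np.einsum("ncd,c,cs->nsd", X, wvec, G)
        within = gsum[:, anc, :]
        return (1 - u) * ((1 - v) * X + v * within) + u * dot[:, None, :]
    dot = np.einsum("ncd,nd->nc", X, pstar)
    gsum = np.einsum("ncd,d,ds->ncs", X, wvec, G)
    within = gsum[:, :, anc]
    return (1 - u) * ((1 - v) * X + v * within) + u * dot[:, :, None]


def e_step_diploid(params: TwoLayerParams, genotypes: np.ndarray) -> PosteriorField:
    """Forward–backward over ordered lower-cluster pairs for diplotype rows.

    ``genotypes`` is (n_rows, n_markers) with values {0, 1, 2} and NaN for
    missing. Phase is integrated out of the emissions; heterozygous sites
    split their expected allele-1 emission between the two slots by the
    posterior odds theta_j (1 - theta_k) : (1 - theta_j) theta_k.
    """
    Gm = np.asarray(genotypes, dtype=np.float64)
    n, M = Gm.shape
    C = params.n_lower
    if M != params.theta.shape[0]:
        raise ModelInputError("marker count mismatch between params and data")
    if params.admix_prop.shape[0] != n:
        raise ModelInputError("admix_prop rows must match data rows")
    anc, wvec, G = _prepare(params, n)
    pi = params.admix_prop
    pstar = pi[:, anc] * wvec
    u, v = params.upper_switch, params.lower_switch
    theta = params.theta

    missing = np.isnan(Gm)
    g_int = np.where(missing, 0, Gm).astype(np.intp)

    def emission(m: int) -> np.ndarray:
        th = theta[m]
        e0 = np.outer(1 - th, 1 - th)
        e1 = np.outer(th, 1 - th) + np.outer(1 - th, th)
        e2 = np.outer(th, th)
        E3 = np.stack([e0, e1, e2])
        Em = E3[g_int[:, m]]
        Em[missing[:, m]] = 1.0
        return Em

    init = pstar[:, :, None] * pstar[:, None, :]
    alpha = np.empty((n, M, C, C))
    scale = np.empty((n, M))
    a = init * emission(0)
    scale[:, 0] = a.sum(axis=(1, 2))
    alpha[:, 0] = a / scale[:, 0][:, None, None]
    for m in range(1, M):
        pred = _apply_trans(alpha[:, m - 1], 1, u[m - 1], v[m - 1],
                            pstar, wvec, anc, G)
        pred = _apply_trans(pred, 2, u[m - 1], v[m - 1], pstar, wvec, anc, G)
        a = pred * emission(m)
        scale[:, m] = a.sum(axis=(1, 2))
        alpha[:, m] = a / scale[:, m][:, None, None]

    beta_next = np.ones((n, C, C))
    q1 = np.empty((n, M, C))
    q2 = np.empty((n, M, C))
    y1 = np.zeros((n, M, C))
    y2 = np.zeros((n, M, C))

    def slot_stats(m: int, Q: np.ndarray) -> None:
        q1[:, m] = Q.sum(axis=2)
        q2[:, m] = Q.sum(axis=1)
        th = theta[m]
        den = np.outer(th, 1 - th) + np.outer(1 - th, th)
        with np.errstate(invalid="ignore", divide="ignore"):
            R1 = np.where(den > 0, np.outer(th, 1 - th) / np.where(den == 0, 1, den),
                          0.5)
        het = (g_int[:, m] == 1) & ~missing[:, m]
        hom2 = (g_int[:, m] == 2) & ~missing[:, m]
        if het.any():
            y1[het, m] = (Q[het] * R1).sum(axis=2)
            y2[het, m] = (Q[het] * (1.0 - R1)).sum(axis=1)
        if hom2.any():
            y1[hom2, m] = q1[hom2, m]
            y2[hom2, m] = q2[hom2, m]

    Q = alpha[:, M - 1] * beta_next
    Q /= Q.sum(axis=(1, 2), keepdims=True)
    slot_stats(M - 1, Q)
    for m in range(M - 2, -1, -1):
        x = emission(m + 1) * beta_next
        b = _apply_trans_back(x, 1, u[m], v[m], pstar, wvec, anc, G)
        b = _apply_trans_back(b, 2, u[m], v[m], pstar, wvec, anc, G)
        beta_next = b / scale[:, m + 1][:, None, None]
        Q = alpha[:, m] * beta_next
        Q /= Q.sum(axis=(1, 2), keepdims=True)
        slot_stats(m, Q)

    q = q1 + q2
    ancestry = q @ G
    loglik = np.log(scale).sum(axis=1)
    # occupancy approximation for the admixture-proportion update
    upper_counts = ancestry.mean(axis=1) / 2.0
    obs3 = ~missing[:, :, None]
    n_emit = np.where(obs3, q, 0.0)
    y_emit = np.where(obs3, y1 + y2, 0.0)
    return PosteriorField(q / 2.0, ancestry, loglik, upper_counts,
                          n_emit, y_emit, 2)


def update_theta(posteriors: np.ndarray, alleles: np.ndarray,
                 weights: np.ndarray, prev_theta: np.ndarray | None = None,
                 floor: float = 1e-4) -> np.ndarray:
    """Weighted M-step update of the cluster allele frequencies.

    ``posteriors`` is (n_rows, n_markers, n_lower) of normalized cluster
    marginals, ``alleles`` (n_rows, n_markers) in {0, 1} (-1 = missing), and
    ``weights`` one non-negative weight per row (training vs cohort). Weights
    are normalized by their maximum, so a common weight cancels exactly:
    with equal weights the update is bit-identical to the unweighted
    estimator. Clusters with zero weighted exposure at a marker keep
    ``prev_theta`` (with a logged warning); the result is clamped to
    [floor, 1 - floor].
    """
    q = np.asarray(posteriors, dtype=np.float64)
    h = np.asarray(alleles)
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (q.shape[0],):
        raise ModelInputError("need one weight per row")
    if np.any(w < 0) or w.max() == 0:
        raise ModelInputError("weights must be non-negative with a positive max")
    w = w / w.max()
    wq = w[:, None, None] * q
    num = (wq * (h == 1)[:, :, None]).sum(axis=0)
    den = (wq * (h >= 0)[:, :, None]).sum(axis=0)
    empty = den <= 0.0
    if empty.any():
        if prev_theta is None:
            raise ModelInputError("unoccupied cluster and no previous theta to keep")
        logger.warning("%d unoccupied (marker, cluster) cells: keeping previous theta",
                       int(empty.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = num / np.where(empty, 1.0, den)
    if prev_theta is not None:
        t = np.where(empty, prev_theta, t)
    elif empty.any():  # pragma: no cover - guarded above
        t = np.where(empty, 0.5, t)
    return np.clip(t, floor, 1.0 - floor)


def theta_from_counts(n_list, y_list, w_list, prev_theta, floor):
    """Theta update from pre-reduced emission exposures of several batches."""
    wmax = max(w_list)
    num = sum((w / wmax) * y.sum(axis=0) for w, y in zip(w_list, y_list))
    den = sum((w / wmax) * n.sum(axis=0) for w, n in zip(w_list, n_list))
    empty = den <= 0.0
    if empty.any():
        logger.warning("%d unoccupied (marker, cluster) cells: keeping previous theta",
                       int(empty.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = num / np.where(empty, 1.0, den)
    t = np.where(empty, prev_theta, t)
    return np.clip(t, floor, 1.0 - floor)


def align_labels(runs: list[np.ndarray], anchors=()) -> list[np.ndarray]:
    """Permutations aligning ancestry labels across EM runs.

    Ancestries backed by a training panel (``anchors``) are fixed by
    construction; the remaining labels of each run are matched to run 0 by
    greedily maximizing the correlation of the dosage fields. Returns one
    permutation per run such that ``run[..., perm]`` is aligned with run 0.
    """
    if len(runs) < 2:
        return [np.arange(runs[0].shape[-1])] if runs else []
    S = runs[0].shape[-1]
    for r in runs[1:]:
        if r.shape != runs[0].shape:
            raise ModelInputError("runs must have identical shapes")
    anchors = set(int(a) for a in anchors)
    free = [a for a in range(S) if a not in anchors]
    ref = runs[0]
    perms = [np.arange(S)]
    for r in runs[1:]:
        perm = np.arange(S)
        if free:
            corr = np.zeros((len(free), len(free)))
            for i, a in enumerate(free):
                x = ref[..., a].ravel()
                for j, b in enumerate(free):
                    y = r[..., b].ravel()
                    if x.std() == 0 or y.std() == 0:
                        logger.warning("constant dosage field during label "
                                       "alignment; ties broken by run order")
                        c = 0.0
                    else:
                        c = float(np.corrcoef(x, y)[0, 1])
                    corr[i, j] = c
            remaining_i = list(range(len(free)))
            remaining_j = list(range(len(free)))
            while remaining_i:
                sub = corr[np.ix_(remaining_i, remaining_j)]
                k = int(np.argmax(sub))
                i, j = remaining_i[k // len(remaining_j)], \
                    remaining_j[k % len(remaining_j)]
                perm[free[i]] = free[j]
                remaining_i.remove(i)
                remaining_j.remove(j)
        perms.append(perm)
    return perms


@dataclass
class FitResult:
    """Run-averaged dosages plus per-run diagnostics."""

    dosage: DosageField                  # cohort, run-averaged, aligned
    params: TwoLayerParams               # final parameters of the last run
    run_dosages: list = field(default_factory=list)
    permutations: list = field(default_factory=list)
    loglik_traces: list = field(default_factory=list)  # weighted loglik per step
    admix_prop: np.ndarray | None = None               # cohort rows, averaged
    anchors: tuple = ()


def _init_theta(rng: np.random.Generator, cluster_anc: np.ndarray,
                train_freqs: dict[int, np.ndarray], M: int,
                floor: float) -> np.ndarray:
    C = len(cluster_anc)
    theta = rng.uniform(0.2, 0.8, size=(M, C))
    for j in range(C):
        a = int(cluster_anc[j])
        if a in train_freqs:
            theta[:, j] = 0.7 * train_freqs[a] + 0.3 * theta[:, j]
    return np.clip(theta, floor, 1.0 - floor)


def fit(training_panels, cohort, config: ModelConfig,
        pair_haplotypes: bool = True) -> FitResult:
    """Fit the two-layer model and return run-averaged ancestry dosages.

    ``training_panels`` is a sequence of up to ``n_upper`` HaplotypePanels
    indexed by ancestry, with ``None`` for an absent panel (an empty sequence
    or all-None is structure mode). ``cohort`` is a HaplotypePanel (phased) or
    a GenotypePanel (unphased; exact product-state chain). Each of
    ``config.em_runs`` restarts draws its own theta initialization, runs
    ``config.em_steps`` EM iterations with the weighted theta update, and
    yields a cohort dosage field; fields are label-aligned across runs and
    averaged.
    """
    S = config.n_upper
    training = list(training_panels) if training_panels is not None else []
    training += [None] * (S - len(training))
    if len(training) != S:
        raise ModelInputError("more training panels than upper clusters")
    diploid = isinstance(cohort, GenotypePanel)
    markers = cohort.markers
    M = cohort.n_markers
    cm = markers["cm"].to_numpy()

    train_alleles, train_anc = [], []
    train_freqs: dict[int, np.ndarray] = {}
    for a, p in enumerate(training):
        if p is None:
            continue
        if p.n_markers != M or not np.array_equal(
                p.markers["bp"].to_numpy(), markers["bp"].to_numpy()):
            raise PanelError("training panel marker grid differs from cohort")
        train_alleles.append(p.alleles)
        train_anc.extend([a] * p.n_haplotypes)
        train_freqs[a] = p.allele_frequencies()
    n_train = len(train_anc)
    anchors = tuple(sorted(train_freqs))
    if cohort.n_markers == 0 or (cohort.genotypes.shape[0] == 0 if diploid
                                 else cohort.alleles.shape[0] == 0):
        raise ModelInputError("empty cohort")

    if diploid:
        coh_data = cohort.genotypes
        n_coh_rows = cohort.n_individuals
    else:
        coh_data = cohort.alleles.astype(np.int8)
        n_coh_rows = cohort.n_haplotypes
        if pair_haplotypes and n_coh_rows % 2:
            raise ModelInputError("odd cohort haplotype count cannot be paired")

    w_t = config.weight_training
    w_c = config.weight_cohort
    if w_c is None:
        # training must dominate the anchored clusters' theta (w_t >> w_c):
        # the cohort contributes at most ~10% of the training panels' mass.
        w_c = 0.1 * min(1.0, n_train / n_coh_rows) if n_train else 1.0

    cluster_anc = split_clusters(config.n_lower, S)
    u = switch_probs(cm, config.admix_generations)
    v = switch_probs(cm, config.lambda_lower)

    pi_train = np.zeros((n_train, S))
    if n_train:
        pi_train[np.arange(n_train), train_anc] = 1.0
        train_mat = np.concatenate(train_alleles, axis=0)

    master = np.random.default_rng(config.seed)
    run_seeds = master.integers(2**31 - 1, size=config.em_runs)

    run_dosages, traces = [], []
    params = None
    for run in range(config.em_runs):
        rng = np.random.default_rng(run_seeds[run])
        theta = _init_theta(rng, cluster_anc, train_freqs, M, config.theta_floor)
        pi_coh = np.full((n_coh_rows, S), 1.0 / S)
        trace = []
        post_c = post_t = None
        for _ in range(config.em_steps):
            pi_all = np.concatenate([pi_train, pi_coh]) if n_train else pi_coh
            params = TwoLayerParams(theta, cluster_anc, u, v, pi_all)
            if n_train:
                params_t = TwoLayerParams(theta, cluster_anc, u, v, pi_train)
                post_t = e_step(params_t, train_mat)
            params_c = TwoLayerParams(theta, cluster_anc, u, v, pi_coh)
            post_c = (e_step_diploid(params_c, coh_data) if diploid
                      else e_step(params_c, coh_data))
            ll = w_c * post_c.loglik.sum()
            if n_train:
                ll += w_t * post_t.loglik.sum()
            trace.append(ll)
            # M-step
            if n_train:
                theta = theta_from_counts(
                    [post_t.n_emit, post_c.n_emit],
                    [post_t.y_emit, post_c.y_emit],
                    [w_t, w_c], theta, config.theta_floor)
            else:
                theta = update_theta(post_c.q, coh_data, np.full(n_coh_rows, w_c),
                                     theta, config.theta_floor) if not diploid \
                    else theta_from_counts([post_c.n_emit], [post_c.y_emit],
                                           [w_c], theta, config.theta_floor)
            counts = post_c.upper_counts + 0.01
            pi_coh = counts / counts.sum(axis=1, keepdims=True)
        # final posteriors under the final parameters
        params_c = TwoLayerParams(theta, cluster_anc, u, v, pi_coh)
        post_c = (e_step_diploid(params_c, coh_data) if diploid
                  else e_step(params_c, coh_data))
        pi_all = np.concatenate([pi_train, pi_coh]) if n_train else pi_coh
        params = TwoLayerParams(theta, cluster_anc, u, v, pi_all)
        traces.append(trace)

        dos = post_c.ancestry                           # (rows, M, S)
        if not diploid and pair_haplotypes:
            dos = dos[0::2] + dos[1::2]
        run_dosages.append(dos)

    low = config.theta_floor
    final_pi = params.admix_prop[-n_coh_rows:] if n_train else params.admix_prop
    for a in range(S):
        if a not in train_freqs and final_pi[:, a].mean() < max(low, 1e-3):
            logger.warning("ancestry %d has no training panel and a negligible "
                           "cohort component; dosages may be unidentifiable", a)

    perms = align_labels(run_dosages, anchors)
    aligned = [d[..., p] for d, p in zip(run_dosages, perms)]
    mean_dos = np.mean(aligned, axis=0)
    ploidy = 2 if (diploid or pair_haplotypes) else 1
    names = ANCESTRIES if S == 3 else tuple(f"anc{k}" for k in range(S))
    ids = (cohort.sample_ids if diploid or not pair_haplotypes
           else [f"ind{i}" for i in range(mean_dos.shape[0])])
    dosage = DosageField(mean_dos, markers, list(ids), names, ploidy)
    return FitResult(dosage, params, run_dosages, perms, traces,
                     admix_prop=mean_dos.mean(axis=1) / ploidy, anchors=anchors)
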
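"""Synthetic genotypes and phenotypes for a small-Ne cattle-like population.

A forward Wright–Fisher simulator (biallelic markers, Haldane recombination,
allele-flip mutation) produces a haplotype pool whose linkage disequilibrium
mimics a closed beef-cattle breed with effective population size around 30.
Diploid cohorts are drawn from the final-generation pool, trait architectures
are imposed as additive QTL effects (a few large QTLs plus polygenes for a
carcass-weight-like trait; small-effect polygenes only for a marbling-like
ordinal trait), and phenotypes carry market/year factors and linear plus
quadratic age covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in dosage matrices.
MISSING: int = -1


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the forward Wright–Fisher simulation.

    Defaults emulate the study population: 29 autosomes of roughly 86 Mb
    (a ~2.5 Gbp genome) carrying ~40,000 chip markers, an effective size of
    30 diploids, and enough generations of random mating for drift to build
    the elevated long-range LD characteristic of a small closed breed.
    """

    n_chromosomes: int = 29
    chrom_length_bp: int = 86_000_000
    n_markers_total: int = 40_000
    effective_size: int = 30
    n_generations: int = 10
    ancestral_size: int = 150
    ancestral_generations: int = 100
    expansion_size: int = 400
    expansion_generations: int = 6
    mutation_rate: float = 2e-3
    recomb_rate_cm_per_mb: float = 1.0
    founder_maf_low: float = 0.35
    founder_maf_high: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effective_size < 2:
            raise ValueError("effective_size must be >= 2")
        if self.ancestral_size < 2 or self.ancestral_generations < 0:
            raise ValueError("invalid ancestral phase")
        if self.expansion_size < 2 or self.expansion_generations < 0:
            raise ValueError("invalid expansion phase")
        if self.n_markers_total < self.n_chromosomes:
            raise ValueError("need at least one marker per chromosome")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.recomb_rate_cm_per_mb < 0:
            raise ValueError("recombination rate must be non-negative")
        if self.n_chromosomes < 1 or self.chrom_length_bp < 2:
            raise ValueError("invalid genome dimensions")


@dataclass(frozen=True)
class MarkerMap:
    """Per-marker chromosome and physical position, sorted.

    Positions are strictly increasing within a chromosome and marker ids are
    unique; both are enforced at construction.
    """

    marker_id: np.ndarray  # str array
    chromosome: np.ndarray  # int array, 1-based
    position_bp: np.ndarray  # int array

    def __post_init__(self) -> None:
        n = len(self.marker_id)
        if not (len(self.chromosome) == len(self.position_bp) == n):
            raise ValueError("marker map columns must have equal length")
        if len(np.unique(self.marker_id)) != n:
            raise ValueError("marker ids must be unique")
        chrom = np.asarray(self.chromosome)
        pos = np.asarray(self.position_bp)
        order_key = chrom.astype(np.int64) * (pos.max(initial=0) + 1) + pos
        if n and not np.all(np.diff(order_key) > 0):
            raise ValueError(
                "markers must be sorted by (chromosome, position) with "
                "strictly increasing positions within a chromosome"
            )

    def __len__(self) -> int:
        return len(self.marker_id)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chromosome)

    def chrom_slice(self, chrom: int) -> slice:
        """Contiguous index range of markers on one chromosome."""
        lo, hi = np.searchsorted(self.chromosome, [chrom, chrom + 1])
        return slice(int(lo), int(hi))

    def subset(self, indices: np.ndarray) -> "MarkerMap":
        idx = np.asarray(indices)
        return MarkerMap(
            marker_id=self.marker_id[idx],
            chromosome=self.chromosome[idx],
            position_bp=self.position_bp[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chromosome": self.chromosome,
                "position_bp": self.position_bp,
            }
        )


@dataclass
class GenotypeMatrix:
    """Individuals × markers minor-allele dosages with missing support.

    Dosages are 0/1/2 counts of the minor allele (as polarized at build
    time) or :data:`MISSING`. ``orientation`` records, per marker, whether
    the counted allele is the flip of the haplotype panel's allele-1 coding,
    so that independently sampled cohorts can share a coding.
    """

    dosages: np.ndarray  # (n, m) int16
    individual_ids: list[str]
    orientation: np.ndarray | None = None  # bool per marker, True = flipped

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x markers)")
        if len(self.individual_ids) != self.dosages.shape[0]:
            raise ValueError("individual_ids length must match rows")
        valid = np.isin(self.dosages, [0, 1, 2, MISSING])
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or MISSING")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def subset_markers(self, indices: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(indices)
        orient = None if self.orientation is None else self.orientation[idx]
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            individual_ids=list(self.individual_ids),
            orientation=orient,
        )

    def copy(self) -> "GenotypeMatrix":
        orient = None if self.orientation is None else self.orientation.copy()
        return GenotypeMatrix(
            dosages=self.dosages.copy(),
            individual_ids=list(self.individual_ids),
            orientation=orient,
        )


@dataclass(frozen=True)
class HaplotypePanel:
    """Final-generation haplotypes (2·Ne × markers, allele codes 0/1)."""

    haplotypes: np.ndarray  # (2*Ne, m) uint8
    marker_map: MarkerMap

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def allele1_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


@dataclass(frozen=True)
class QTLModel:
    """Additive trait architecture: QTL marker indices and effects."""

    qtl_marker_indices: np.ndarray
    effects: np.ndarray
    architecture_label: str = "polygenic_only"

    def __post_init__(self) -> None:
        idx = np.asarray(self.qtl_marker_indices)
        eff = np.asarray(self.effects, dtype=float)
        if len(idx) != len(eff):
            raise ValueError("indices and effects must have equal length")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("QTL indices must be unique")
        object.__setattr__(self, "qtl_marker_indices", idx.astype(np.int64))
        object.__setattr__(self, "effects", eff)

    @property
    def n_qtl(self) -> int:
        return len(self.effects)


@dataclass(frozen=True)
class LiabilityThresholds:
    """Ascending cut points on the liability scale (K-1 values for K categories)."""

    tau: np.ndarray

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        if tau.ndim != 1 or len(tau) < 1:
            raise ValueError("need at least one threshold")
        if not np.all(np.diff(tau) > 0):
            raise ValueError("thresholds must be strictly increasing")
        object.__setattr__(self, "tau", tau)

    @property
    def n_categories(self) -> int:
        return len(self.tau) + 1


@dataclass(frozen=True)
class CovariateDesign:
    """Fixed-effect structure of the phenotype model.

    Two slaughter markets and ten slaughter years by default, with linear and
    quadratic age-at-slaughter covariates over the observed 15.3–43.0 month
    range. Effect sizes are in trait units.
    """

    n_markets: int = 2
    n_years: int = 10
    market_effect_sd: float = 5.0
    year_effect_sd: float = 5.0
    age_linear: float = 1.0
    age_quadratic: float = -0.01
    age_range: tuple[float, float] = (15.3, 43.0)
    intercept: float = 0.0


# Right-heavy, mildly bimodal 12-category score distribution of the
# marbling-like trait (most carcasses score mid-to-high, few score 1).
DEFAULT_MARBLING_PROBS: np.ndarray = np.array(
    [0.02, 0.05, 0.07, 0.07, 0.06, 0.06, 0.07, 0.09, 0.12, 0.14, 0.14, 0.11]
)


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------


def _unique_sorted_positions(rng: np.random.Generator, k: int, length: int) -> np.ndarray:
    """k distinct uniform positions in [1, length], sorted."""
    if k > length:
        raise ValueError("more markers than base pairs on a chromosome")
    pos = np.unique(rng.integers(1, length + 1, size=k))
    while len(pos) < k:
        extra = rng.integers(1, length + 1, size=k - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return pos


def _random_marker_map(cfg: SimConfig, rng: np.random.Generator) -> MarkerMap:
    """Markers placed uniformly at random, chromosome chosen by length share."""
    chrom_of = rng.integers(1, cfg.n_chromosomes + 1, size=cfg.n_markers_total)
    counts = np.bincount(chrom_of, minlength=cfg.n_chromosomes + 1)[1:]
    empty = np.flatnonzero(counts == 0) + 1
    if len(empty):
        warnings.warn(
            f"{len(empty)} chromosome(s) received no markers and were dropped",
            stacklevel=3,
        )
    chroms, positions = [], []
    for c in range(1, cfg.n_chromosomes + 1):
        k = counts[c - 1]
        if k == 0:
            continue
        pos = _unique_sorted_positions(rng, int(k), cfg.chrom_length_bp)
        chroms.append(np.full(k, c, dtype=np.int64))
        positions.append(pos.astype(np.int64))
    chromosome = np.concatenate(chroms)
    position = np.concatenate(positions)
    ids = np.array([f"snp{i:06d}" for i in range(len(chromosome))])
    return MarkerMap(marker_id=ids, chromosome=chromosome, position_bp=position)


def _recombine(
    rng: np.random.Generator,
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    chrom_starts: np.ndarray,
    chrom_pos_morgans: list[np.ndarray],
    chrom_len_morgans: float,
) -> np.ndarray:
    """One gamete from a diploid parent under the Haldane (no-interference) model.

    Crossover counts are Poisson with mean equal to the chromosome's map
    length in Morgans; crossover positions are uniform. Each chromosome
    starts from a random parental haplotype.
    """
    gamete = np.empty_like(hap_a)
    for c, pos_m in enumerate(chrom_pos_morgans):
        lo = chrom_starts[c]
        hi = chrom_starts[c + 1]
        start = rng.integers(0, 2)
        n_x = rng.poisson(chrom_len_morgans) if chrom_len_morgans > 0 else 0
        if n_x == 0:
            src = hap_a if start == 0 else hap_b
            gamete[lo:hi] = src[lo:hi]
            continue
        xs = np.sort(rng.uniform(0.0, chrom_len_morgans, size=n_x))
        seg = np.searchsorted(xs, pos_m)
        use_b = (start + seg) % 2 == 1
        gamete[lo:hi] = np.where(use_b, hap_b[lo:hi], hap_a[lo:hi])
    return gamete


def simulate_haplotypes(cfg: SimConfig) -> tuple[HaplotypePanel, MarkerMap]:
    """Evolve haplotypes by Wright–Fisher resampling and return the final pool.

    Three demographic phases mimic a closed breed whose effective size
    declined while its census stayed large: an ancestral phase of
    ``ancestral_size`` diploids for ``ancestral_generations`` generations
    establishes short-range LD that decays with distance; a bottleneck phase
    of ``effective_size`` diploids for ``n_generations`` generations inflates
    long-range LD by drift; and an expansion phase of ``expansion_size``
    diploids for ``expansion_generations`` generations diversifies the
    haplotype pool the study cohort is drawn from (a small breeding nucleus
    feeding a large slaughter population). Founder allele frequencies are
    drawn uniformly between
    ``founder_maf_low`` and ``founder_maf_high`` per locus; each generation
    forms offspring from two distinct random parents with Haldane-model
    recombination at ``recomb_rate_cm_per_mb`` and allele-flip mutation at
    ``mutation_rate`` per locus per gamete.
    """
    rng = np.random.default_rng(cfg.seed)
    mmap = _random_marker_map(cfg, rng)
    m = len(mmap)

    # chromosome bookkeeping in map (Morgan) coordinates
    present = np.unique(mmap.chromosome)
    chrom_starts = np.searchsorted(mmap.chromosome, np.append(present, present[-1] + 1))
    morgans_per_bp = cfg.recomb_rate_cm_per_mb / 100.0 / 1e6
    chrom_len_m = cfg.chrom_length_bp * morgans_per_bp
    chrom_pos_m = [
        mmap.position_bp[chrom_starts[c] : chrom_starts[c + 1]] * morgans_per_bp
        for c in range(len(present))
    ]

    def evolve(haps: np.ndarray, n_offspring: int, n_gens: int) -> np.ndarray:
        for _ in range(n_gens):
            n_parents = haps.shape[0] // 2
            new = np.empty((2 * n_offspring, m), dtype=np.uint8)
            for i in range(n_offspring):
                pa, pb = rng.choice(n_parents, size=2, replace=False)
                for j, parent in enumerate((pa, pb)):
                    gamete = _recombine(
                        rng,
                        haps[2 * parent],
                        haps[2 * parent + 1],
                        chrom_starts,
                        chrom_pos_m,
                        chrom_len_m,
                    )
                    if cfg.mutation_rate > 0:
                        n_mut = rng.binomial(m, cfg.mutation_rate)
                        if n_mut:
                            at = rng.choice(m, size=n_mut, replace=False)
                            gamete[at] ^= 1
                    new[2 * i + j] = gamete
            haps = new
        return haps

    founder_freq = rng.uniform(cfg.founder_maf_low, cfg.founder_maf_high, size=m)
    haps = (rng.random((2 * cfg.ancestral_size, m)) < founder_freq).astype(np.uint8)
    haps = evolve(haps, cfg.ancestral_size, cfg.ancestral_generations)
    # bottleneck: the first generation at the reduced size samples parents
    # from the full ancestral pool
    haps = evolve(haps, cfg.effective_size, cfg.n_generations)
    haps = evolve(haps, cfg.expansion_size, cfg.expansion_generations)

    return HaplotypePanel(haplotypes=haps, marker_map=mmap), mmap


def sample_genotypes(
    panel: HaplotypePanel,
    n_individuals: int,
    seed: int,
    orientation: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Draw diploid individuals from the haplotype pool.

    Each individual receives two haplotypes drawn without replacement (the
    pair is distinct; different individuals may reuse haplotypes). Dosages
    are then polarized to count the minor allele: if ``orientation`` is
    given it is applied as-is (so a second cohort can share the coding of a
    first); otherwise the allele with cohort frequency > 0.5 is flipped.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if panel.n_haplotypes < 2:
        raise ValueError("panel must contain at least 2 haplotypes")
    rng = np.random.default_rng(seed)
    n_hap = panel.n_haplotypes
    rows = np.empty((n_individuals, panel.haplotypes.shape[1]), dtype=np.int16)
    for i in range(n_individuals):
        a, b = rng.choice(n_hap, size=2, replace=False)
        rows[i] = panel.haplotypes[a].astype(np.int16) + panel.haplotypes[b]
    if orientation is None:
        freq = rows.mean(axis=0) / 2.0
        orientation = freq > 0.5
    else:
        orientation = np.asarray(orientation, dtype=bool)
        if len(orientation) != rows.shape[1]:
            raise ValueError("orientation length must match marker count")
    rows[:, orientation] = 2 - rows[:, orientation]
    ids = [f"ind{i:05d}" for i in range(n_individuals)]
    return GenotypeMatrix(dosages=rows, individual_ids=ids, orientation=orientation)


# ---------------------------------------------------------------------------
# Trait architecture and phenotypes
# ---------------------------------------------------------------------------


def extended_ld_strength(
    G: GenotypeMatrix,
    mmap: MarkerMap,
    min_mb: float = 0.3,
    max_mb: float = 3.0,
    max_neighbors: int = 15,
    seed: int = 0,
) -> np.ndarray:
    """Per-marker mean r² with markers 0.3–3 Mb away (extended-LD score).

    High scores mark loci inside long haplotype blocks — the kind of region
    where major carcass-trait QTLs were mappable by GWAS and remain well
    tagged even by sparse equally-spaced panels. Neighbour sets larger than
    ``max_neighbors`` are subsampled for speed.
    """
    dos = G.dosages.astype(float)
    if (dos < 0).any():
        raise ValueError("genotypes must be complete")
    centered = dos - dos.mean(axis=0)
    sd = centered.std(axis=0)
    n, m = dos.shape
    pos = mmap.position_bp.astype(float)
    chrom = mmap.chromosome
    rng = np.random.default_rng(seed)
    strength = np.zeros(m)
    for j in range(m):
        if sd[j] == 0:
            continue
        gap = np.abs(pos - pos[j])
        near = np.flatnonzero(
            (chrom == chrom[j]) & (gap > min_mb * 1e6) & (gap < max_mb * 1e6)
        )
        near = near[sd[near] > 0]
        if len(near) == 0:
            continue
        if len(near) > max_neighbors:
            near = rng.choice(near, size=max_neighbors, replace=False)
        r = (centered[:, j] @ centered[:, near]) / (n * sd[j] * sd[near])
        strength[j] = float(np.mean(r * r))
    return strength


def assign_qtl_effects(
    mmap: MarkerMap,
    n_large: int,
    n_small: int,
    large_sd: float,
    small_sd: float,
    seed: int,
    placement: str = "uniform",
    genotypes: GenotypeMatrix | None = None,
) -> QTLModel:
    """Choose QTL positions and draw effects from zero-mean normals.

    ``n_large`` QTLs get effects with SD ``large_sd`` (the carcass-weight-like
    preset uses three such loci), ``n_small`` get SD ``small_sd``; the
    marbling-like preset uses ``n_large=0`` (small-effect polygenes only).

    With the default ``placement='uniform'`` all positions are drawn
    uniformly without replacement. ``placement='extended_ld'`` instead pins
    the large QTLs to the strongest extended-LD marker per chromosome (see
    :func:`extended_ld_strength`; requires ``genotypes``), emulating
    GWAS-ascertained major QTLs that sit in long haplotype blocks; small
    QTLs stay uniform.
    """
    if large_sd < 0 or small_sd < 0:
        raise ValueError("effect SDs must be non-negative")
    if placement not in ("uniform", "extended_ld"):
        raise ValueError("placement must be 'uniform' or 'extended_ld'")
    n_qtl = n_large + n_small
    if n_qtl > len(mmap):
        raise ValueError("more QTLs requested than markers available")
    rng = np.random.default_rng(seed)

    if placement == "extended_ld" and n_large > 0:
        if genotypes is None:
            raise ValueError("extended_ld placement requires genotypes")
        strength = extended_ld_strength(genotypes, mmap)
        order = np.argsort(strength)[::-1]
        large_idx: list[int] = []
        used_chroms: set[int] = set()
        for j in order:  # one block per chromosome first, then next-best
            c = int(mmap.chromosome[j])
            if c in used_chroms and len(used_chroms) < len(mmap.chromosomes):
                continue
            large_idx.append(int(j))
            used_chroms.add(c)
            if len(large_idx) == n_large:
                break
        large = np.array(large_idx, dtype=np.int64)
        pool = np.setdiff1d(np.arange(len(mmap)), large)
        small = rng.choice(pool, size=n_small, replace=False) if n_small else np.array([], int)
        idx = np.concatenate([large, small]).astype(np.int64)
    else:
        idx = (
            rng.choice(len(mmap), size=n_qtl, replace=False)
            if n_qtl
            else np.array([], int)
        )
    effects = np.concatenate(
        [
            rng.normal(0.0, large_sd, size=n_large),
            rng.normal(0.0, small_sd, size=n_small),
        ]
    )
    label = "mixed_large_plus_polygenic" if n_large > 0 else "polygenic_only"
    return QTLModel(qtl_marker_indices=idx, effects=effects, architecture_label=label)


def true_breeding_values(G: GenotypeMatrix, qtl: QTLModel) -> np.ndarray:
    """Additive genetic values g_i = sum_q effect_q (dosage_iq - 2 p_q)."""
    if qtl.n_qtl == 0:
        return np.zeros(G.n_individuals)
    dos = G.dosages[:, qtl.qtl_marker_indices].astype(float)
    if (dos == MISSING).any():
        raise ValueError("QTL genotypes must be complete")
    p = dos.mean(axis=0) / 2.0
    return (dos - 2.0 * p) @ qtl.effects


def simulate_phenotypes(
    G: GenotypeMatrix,
    qtl: QTLModel,
    design: CovariateDesign,
    target_h2: float,
    seed: int,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Phenotypes y = fixed effects + g + e with empirical heritability control.

    The residual variance is set so that var(g)/(var(g)+sigma_e^2) equals
    ``target_h2`` for the realized sample variance of the true breeding
    values g. Returns the phenotype table (id, value, market, year,
    age_months) and the vector of true breeding values.
    """
    if not 0.0 < target_h2 < 1.0:
        raise ValueError("target_h2 must be in (0, 1)")
    g = true_breeding_values(G, qtl)
    var_g = g.var()
    if var_g <= 0:
        raise ValueError("zero genetic variance but target_h2 > 0")
    rng = np.random.default_rng(seed)
    n = G.n_individuals

    sigma_e2 = var_g * (1.0 - target_h2) / target_h2
    e = rng.normal(0.0, np.sqrt(sigma_e2), size=n)

    market = rng.integers(0, design.n_markets, size=n)
    year = rng.integers(0, design.n_years, size=n)
    market_eff = rng.normal(0.0, design.market_effect_sd, size=design.n_markets)
    year_eff = rng.normal(0.0, design.year_effect_sd, size=design.n_years)
    age = rng.uniform(design.age_range[0], design.age_range[1], size=n)

    fixed = (
        design.intercept
        + market_eff[market]
        + year_eff[year]
        + design.age_linear * age
        + design.age_quadratic * age**2
    )
    y = fixed + g + e

    table = pd.DataFrame(
        {
            "individual_id": G.individual_ids,
            "value": y,
            "market": [f"M{k + 1}" for k in market],
            "year": [f"Y{k + 1}" for k in year],
            "age_months": age,
        }
    )
    return table, g


def discretize_liability(
    liability: np.ndarray, thresholds: LiabilityThresholds
) -> np.ndarray:
    """Map liabilities to ordinal scores 1..K.

    A liability exactly equal to a threshold goes to the upper category.
    """
    x = np.asarray(liability, dtype=float)
    return 1 + np.searchsorted(thresholds.tau, x, side="right").astype(np.int64)


def thresholds_from_probs(
    liability: np.ndarray, probs: np.ndarray
) -> LiabilityThresholds:
    """Empirical-quantile cut points reproducing target category proportions.

    Ensures strictly increasing thresholds by nudging ties by a tiny epsilon.
    """
    probs = np.asarray(probs, dtype=float)
    if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("probs must be non-negative and sum to 1")
    cum = np.cumsum(probs)[:-1]
    tau = np.quantile(np.asarray(liability, float), cum)
    eps = 1e-9 * max(1.0, np.ptp(tau))
    for i in range(1, len(tau)):
        if tau[i] <= tau[i - 1]:
            tau[i] = tau[i - 1] + eps
    return LiabilityThresholds(tau=tau)


def mask_genotypes(G: GenotypeMatrix, missing_rate: float, seed: int) -> GenotypeMatrix:
    """Set each entry to missing independently with probability ``missing_rate``."""
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    out = G.copy()
    if missing_rate > 0.0:
        rng = np.random.default_rng(seed)
        mask = rng.random(out.dosages.shape) < missing_rate
        out.dosages[mask] = MISSING
    return out
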
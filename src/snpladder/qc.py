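"""SNP quality control: MAF and call-rate filters, exact HWE test, gap filling.

Markers are retained when MAF and call rate exceed their thresholds
(strict inequalities), the Hardy–Weinberg exact-test p-value exceeds its
threshold, and the marker has position information. Missing calls on the
retained markers are then filled by one of three simple schemes; with only a
few percent missing, the genomic relationship matrix is insensitive to the
choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .simdata import GenotypeMatrix, MarkerMap

FILL_METHODS = ("hwe_draw", "locus_mode", "neighbor_conditional")


@dataclass(frozen=True)
class QCConfig:
    """Filter thresholds and the gap-filling scheme."""

    maf_min: float = 0.01
    call_rate_min: float = 0.95
    hwe_p_min: float = 0.001
    fill_method: str = "hwe_draw"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fill_method not in FILL_METHODS:
            raise ValueError(f"unknown fill method {self.fill_method!r}")


@dataclass(frozen=True)
class QCReport:
    """Marker accounting for one filtering pass.

    Removal counts follow the fixed reporting precedence
    no-position → call-rate → MAF → HWE, so they partition the removed set.
    """

    n_input: int
    n_removed_no_position: int
    n_removed_callrate: int
    n_removed_maf: int
    n_removed_hwe: int
    n_retained: int
    n_filled: int = 0

    def __post_init__(self) -> None:
        total = (
            self.n_removed_no_position
            + self.n_removed_callrate
            + self.n_removed_maf
            + self.n_removed_hwe
            + self.n_retained
        )
        if total != self.n_input:
            raise ValueError("QCReport counts do not partition the input")


def compute_maf(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker minor-allele frequency among non-missing calls.

    Returns ``(maf, defined)`` where ``defined`` is False for all-missing
    markers (their MAF entry is NaN; such markers fail the call-rate filter
    anyway).
    """
    miss = G.missing_mask
    n_obs = (~miss).sum(axis=0)
    total = np.where(miss, 0, G.dosages).sum(axis=0)
    defined = n_obs > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(defined, total / (2.0 * np.maximum(n_obs, 1)), np.nan)
    maf = np.where(defined, np.minimum(freq, 1.0 - freq), np.nan)
    return maf, defined


def _hwe_log_pmf(het: np.ndarray, n: int, n_a: int) -> np.ndarray:
    """Log of the Levene–Haldane conditional pmf of the heterozygote count."""
    n_aa = (n_a - het) // 2
    n_bb = n - n_aa - het
    n_b = 2 * n - n_a
    return (
        gammaln(n + 1)
        - gammaln(n_aa + 1)
        - gammaln(het + 1)
        - gammaln(n_bb + 1)
        + het * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )


def hwe_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact two-sided Hardy–Weinberg test (Levene–Haldane).

    Conditions on the allele counts and sums the probabilities of all
    heterozygote counts whose conditional probability does not exceed that of
    the observed count. Monomorphic markers return 1 by convention.
    """
    if min(n_hom_minor, n_het, n_hom_major) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_minor + n_het + n_hom_major
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_hom_minor + n_het  # minor-allele count
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    # heterozygote support: same parity as n_a, bounded by both allele counts
    hets = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    logp = _hwe_log_pmf(hets, n, n_a)
    logp -= logp.max()
    pmf = np.exp(logp)
    pmf /= pmf.sum()
    p_obs = pmf[np.searchsorted(hets, n_het)]
    # probability-mass ordering with a tolerance against float ties
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-12)].sum()))


def hwe_test_chisq(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """One-df chi-square HWE test (sanity cross-check for large counts)."""
    n = n_hom_minor + n_het + n_hom_major
    if n < 1:
        raise ValueError("need at least one genotype")
    p = (2 * n_hom_minor + n_het) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_hom_minor, n_het, n_hom_major], dtype=float)
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, df=1))


def genotype_counts(G: GenotypeMatrix) -> np.ndarray:
    """(markers, 3) counts of dosages 2 (minor hom), 1 (het), 0 (major hom)."""
    counts = np.empty((G.n_markers, 3), dtype=np.int64)
    counts[:, 0] = (G.dosages == 2).sum(axis=0)
    counts[:, 1] = (G.dosages == 1).sum(axis=0)
    counts[:, 2] = (G.dosages == 0).sum(axis=0)
    return counts


def apply_filters(
    G: GenotypeMatrix,
    mmap: MarkerMap,
    cfg: QCConfig,
) -> tuple[GenotypeMatrix, MarkerMap, QCReport]:
    """Retain markers passing position, call-rate, MAF and HWE criteria."""
    if G.n_markers != len(mmap):
        raise ValueError("genotype matrix and marker map are misaligned")
    n_input = G.n_markers

    has_pos = (mmap.chromosome >= 1) & (mmap.position_bp >= 0)
    call_rate = 1.0 - G.missing_mask.mean(axis=0)
    maf, defined = compute_maf(G)

    pass_call = call_rate > cfg.call_rate_min
    pass_maf = defined & (maf > cfg.maf_min)

    hwe_p = np.ones(n_input)
    counts = genotype_counts(G)
    # HWE evaluated only where it can still decide the outcome
    need = has_pos & pass_call & pass_maf
    for j in np.flatnonzero(need):
        hwe_p[j] = hwe_test(*counts[j])
    pass_hwe = hwe_p > cfg.hwe_p_min

    keep = has_pos & pass_call & pass_maf & pass_hwe
    if not keep.any():
        raise ValueError("no markers survive the QC filters")

    # reporting precedence: no-position, call-rate, MAF, HWE
    rm_pos = ~has_pos
    rm_call = has_pos & ~pass_call
    rm_maf = has_pos & pass_call & ~pass_maf
    rm_hwe = has_pos & pass_call & pass_maf & ~pass_hwe

    report = QCReport(
        n_input=n_input,
        n_removed_no_position=int(rm_pos.sum()),
        n_removed_callrate=int(rm_call.sum()),
        n_removed_maf=int(rm_maf.sum()),
        n_removed_hwe=int(rm_hwe.sum()),
        n_retained=int(keep.sum()),
    )
    idx = np.flatnonzero(keep)
    return G.subset_markers(idx), mmap.subset(idx), report


def fill_missing(
    G: GenotypeMatrix,
    cfg: QCConfig,
    mmap: MarkerMap | None = None,
) -> GenotypeMatrix:
    """Replace missing calls so the matrix is complete; never touches observed calls.

    ``hwe_draw`` samples from the per-locus Hardy–Weinberg genotype
    probabilities; ``locus_mode`` takes the most frequent genotype (ties to
    the smaller dosage); ``neighbor_conditional`` takes the modal genotype
    given the nearest non-missing flanking marker's genotype, from the
    empirical complete-case table, falling back to the locus mode. The
    marker map is required only to respect chromosome boundaries and bp
    distances for ``neighbor_conditional``; without it, column order is used.
    """
    out = G.copy()
    miss = out.missing_mask
    if not miss.any():
        return out
    rng = np.random.default_rng(cfg.seed)

    dos = out.dosages
    n, m = dos.shape

    maf, defined = compute_maf(G)
    # locus modes (complete cases), tie-break toward smaller dosage
    counts = np.stack(
        [(dos == 0).sum(axis=0), (dos == 1).sum(axis=0), (dos == 2).sum(axis=0)],
        axis=1,
    )
    locus_mode = counts.argmax(axis=1).astype(np.int16)

    if cfg.fill_method == "locus_mode":
        for j in np.flatnonzero(miss.any(axis=0)):
            dos[miss[:, j], j] = locus_mode[j]
        return out

    if cfg.fill_method == "hwe_draw":
        for j in np.flatnonzero(miss.any(axis=0)):
            p = maf[j] if defined[j] else 0.0
            probs = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
            rows = np.flatnonzero(miss[:, j])
            dos[rows, j] = rng.choice(3, size=len(rows), p=probs).astype(np.int16)
        return out

    # neighbor_conditional
    if mmap is not None and len(mmap) != m:
        raise ValueError("marker map does not match genotype columns")
    chrom = mmap.chromosome if mmap is not None else np.ones(m, dtype=np.int64)
    pos = mmap.position_bp if mmap is not None else np.arange(m, dtype=np.int64)

    cond_tables: dict[tuple[int, int], np.ndarray] = {}

    def conditional_mode(j: int, k: int) -> np.ndarray:
        """mode of dosage_j given dosage_k, from complete cases; -1 if cell empty."""
        key = (j, k)
        if key not in cond_tables:
            both = ~miss[:, j] & ~miss[:, k]
            table = np.full(3, -1, dtype=np.int16)
            dj, dk = dos[both, j], dos[both, k]
            for gk in range(3):
                sel = dj[dk == gk]
                if len(sel):
                    table[gk] = np.bincount(sel, minlength=3).argmax()
            cond_tables[key] = table
        return cond_tables[key]

    for j in np.flatnonzero(miss.any(axis=0)):
        same = np.flatnonzero((chrom == chrom[j]) & (np.arange(m) != j))
        order = same[np.argsort(np.abs(pos[same] - pos[j]), kind="stable")]
        for i in np.flatnonzero(miss[:, j]):
            filled = locus_mode[j]
            for k in order:
                if not miss[i, k]:
                    mode = conditional_mode(j, int(k))[dos[i, k]]
                    if mode >= 0:
                        filled = mode
                    break
            dos[i, j] = filled
    return out
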
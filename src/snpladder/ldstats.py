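"""Linkage disequilibrium between adjacent SNPs from unphased genotypes.

r² for a pair of loci is D² / (p_A(1-p_A) p_B(1-p_B)) with D the gametic
disequilibrium of the maximum-likelihood haplotype frequencies. Since chip
genotypes are unphased, haplotype frequencies are estimated by a two-locus EM
over the nine genotype classes: only double heterozygotes are phase-ambiguous
and are split by the current coupling/repulsion odds each iteration. Only
within-chromosome adjacent pairs are computed (all-pairs LD is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import MISSING, GenotypeMatrix, MarkerMap

EM_TOL = 1e-10
EM_MAX_ITER = 1000

#: bin edges (Mb) used for the distance-binned LD summary
DEFAULT_BIN_EDGES_MB = (0.0, 0.1, 0.2, 0.5, 1.0)


@dataclass
class LDSummary:
    """Adjacent-pair r² and distance d, with aggregate accessors.

    ``pairs`` has one row per converged within-chromosome adjacent pair:
    columns chromosome, pos1_bp, pos2_bp, d_mb, r2.
    """

    pairs: pd.DataFrame
    n_dropped: int = 0

    @property
    def mean_r2(self) -> float:
        return float(self.pairs["r2"].mean())

    @property
    def sd_r2(self) -> float:
        return float(self.pairs["r2"].std(ddof=1))

    @property
    def mean_d_mb(self) -> float:
        return float(self.pairs["d_mb"].mean())

    @property
    def sd_d_mb(self) -> float:
        return float(self.pairs["d_mb"].std(ddof=1))

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# Two-locus EM, vectorized over pairs
# ---------------------------------------------------------------------------


def _pair_genotype_counts(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """3x3 table of joint dosage counts over complete cases."""
    ok = (d1 != MISSING) & (d2 != MISSING)
    idx = d1[ok] * 3 + d2[ok]
    return np.bincount(idx, minlength=9).reshape(3, 3).astype(float)


def _em_from_counts(
    counts: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """EM haplotype frequencies for a stack of 3x3 genotype tables.

    counts: (P, 3, 3) with counts[p, a, b] the number of individuals with
    dosage a at locus 1 and b at locus 2. Returns (freqs (P,4) in order
    AB, Ab, aB, ab where A/B are the counted alleles; D; r2; converged).
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim == 2:
        c = c[None]
    n = c.sum(axis=(1, 2))
    if np.any(n < 1):
        raise ValueError("each pair needs at least one complete case")
    two_n = 2.0 * n

    p_a = (2 * c[:, 2, :].sum(axis=1) + c[:, 1, :].sum(axis=1)) / two_n
    p_b = (2 * c[:, :, 2].sum(axis=1) + c[:, :, 1].sum(axis=1)) / two_n
    if np.any((p_a <= 0) | (p_a >= 1) | (p_b <= 0) | (p_b >= 1)):
        raise ValueError("both loci must be polymorphic among complete cases")

    # unambiguous haplotype contributions (everything except double hets)
    base_ab = 2 * c[:, 2, 2] + c[:, 2, 1] + c[:, 1, 2]  # AB
    base_aB_ = 2 * c[:, 2, 0] + c[:, 2, 1] + c[:, 1, 0]  # Ab
    base_rB = 2 * c[:, 0, 2] + c[:, 0, 1] + c[:, 1, 2]  # aB
    base_rb = 2 * c[:, 0, 0] + c[:, 0, 1] + c[:, 1, 0]  # ab
    dh = c[:, 1, 1]  # double heterozygotes: AB/ab or Ab/aB

    f = np.stack(
        [p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)],
        axis=1,
    )
    converged = np.zeros(len(c), dtype=bool)
    for _ in range(EM_MAX_ITER):
        coup = f[:, 0] * f[:, 3]
        rep = f[:, 1] * f[:, 2]
        tot = coup + rep
        w = np.where(tot > 0, coup / np.where(tot > 0, tot, 1.0), 0.5)
        new = np.stack(
            [
                base_ab + w * dh,
                base_aB_ + (1 - w) * dh,
                base_rB + (1 - w) * dh,
                base_rb + w * dh,
            ],
            axis=1,
        ) / two_n[:, None]
        delta = np.abs(new - f).max(axis=1)
        f = new
        converged |= delta < EM_TOL
        if converged.all():
            break

    D = f[:, 0] - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = np.clip(D * D / denom, 0.0, 1.0)
    return f, D, r2, converged


@dataclass(frozen=True)
class PairLD:
    """EM result for one pair of loci."""

    freqs: np.ndarray  # f_AB, f_Ab, f_aB, f_ab
    D: float
    r2: float
    converged: bool


def em_haplotype_freqs(d1: np.ndarray, d2: np.ndarray) -> PairLD:
    """Maximum-likelihood haplotype frequencies for one pair of loci.

    ``d1``/``d2`` are dosage vectors (0/1/2, missing allowed and dropped).
    A and B denote the counted (minor) alleles at the two loci.
    """
    counts = _pair_genotype_counts(np.asarray(d1), np.asarray(d2))
    f, D, r2, conv = _em_from_counts(counts[None])
    return PairLD(freqs=f[0], D=float(D[0]), r2=float(r2[0]), converged=bool(conv[0]))


def composite_r2(d1: np.ndarray, d2: np.ndarray) -> float:
    """Squared Pearson correlation of dosages (cross-check estimator)."""
    ok = (np.asarray(d1) != MISSING) & (np.asarray(d2) != MISSING)
    r = np.corrcoef(d1[ok], d2[ok])[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# Adjacent-pair summaries
# ---------------------------------------------------------------------------


def adjacent_r2(
    G: GenotypeMatrix,
    mmap: MarkerMap,
    estimator: str = "em",
) -> LDSummary:
    """r² and distance for every within-chromosome adjacent marker pair.

    Pairs with a monomorphic locus or (for the EM estimator) a non-converged
    EM are dropped and counted in ``n_dropped``. A chromosome with fewer than
    two markers contributes no pairs.
    """
    if estimator not in ("em", "composite"):
        raise ValueError("estimator must be 'em' or 'composite'")
    if G.n_markers != len(mmap):
        raise ValueError("genotype matrix and marker map are misaligned")

    left_idx: list[int] = []
    for c in mmap.chromosomes:
        s = mmap.chrom_slice(int(c))
        if s.stop - s.start >= 2:
            left_idx.extend(range(s.start, s.stop - 1))
    left = np.array(left_idx, dtype=np.int64)
    if len(left) == 0:
        return LDSummary(
            pairs=pd.DataFrame(
                columns=["chromosome", "pos1_bp", "pos2_bp", "d_mb", "r2"]
            ),
            n_dropped=0,
        )
    right = left + 1

    dos = G.dosages
    # polymorphism among complete cases, per pair
    counts = np.empty((len(left), 3, 3))
    for i, (a, b) in enumerate(zip(left, right)):
        counts[i] = _pair_genotype_counts(dos[:, a], dos[:, b])
    two_n = 2.0 * counts.sum(axis=(1, 2))
    p1 = (2 * counts[:, 2, :].sum(axis=1) + counts[:, 1, :].sum(axis=1)) / two_n
    p2 = (2 * counts[:, :, 2].sum(axis=1) + counts[:, :, 1].sum(axis=1)) / two_n
    poly = (p1 > 0) & (p1 < 1) & (p2 > 0) & (p2 < 1) & (two_n > 0)

    r2 = np.full(len(left), np.nan)
    keep = poly.copy()
    if estimator == "em":
        if poly.any():
            _, _, r2_em, conv = _em_from_counts(counts[poly])
            r2[poly] = r2_em
            keep[np.flatnonzero(poly)[~conv]] = False
    else:
        for i in np.flatnonzero(poly):
            r2[i] = composite_r2(dos[:, left[i]], dos[:, right[i]])

    d_mb = (mmap.position_bp[right] - mmap.position_bp[left]) / 1e6
    pairs = pd.DataFrame(
        {
            "chromosome": mmap.chromosome[left][keep],
            "pos1_bp": mmap.position_bp[left][keep],
            "pos2_bp": mmap.position_bp[right][keep],
            "d_mb": d_mb[keep],
            "r2": r2[keep],
        }
    ).reset_index(drop=True)
    return LDSummary(pairs=pairs, n_dropped=int((~keep).sum()))


def bin_summary(
    summary: LDSummary,
    bin_edges_mb=DEFAULT_BIN_EDGES_MB,
    r2_threshold: float = 0.3,
) -> pd.DataFrame:
    """Per-distance-bin mean r², fraction above threshold, and pair counts.

    Bins are half-open [lo, hi); pairs at or beyond the last edge land in an
    overflow bin. Empty bins report NaN for the mean and fraction.
    """
    edges = np.asarray(bin_edges_mb, dtype=float)
    if len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("need >= 2 strictly ascending bin edges")
    d = summary.pairs["d_mb"].to_numpy()
    r2 = summary.pairs["r2"].to_numpy()
    which = np.digitize(d, edges)  # 0 = below first edge, len(edges) = overflow

    rows = []
    bounds = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    bounds.append((edges[-1], np.inf))
    for b, (lo, hi) in enumerate(bounds, start=1):
        sel = which == b
        n = int(sel.sum())
        rows.append(
            {
                "lo_mb": lo,
                "hi_mb": hi,
                "n_pairs": n,
                "mean_r2": float(r2[sel].mean()) if n else np.nan,
                f"frac_r2_gt_{r2_threshold}": float((r2[sel] > r2_threshold).mean())
                if n
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def cumulative_summary(
    summary: LDSummary,
    upper_edges_mb=(0.1, 0.2, 0.5, 1.0),
    r2_threshold: float = 0.3,
) -> pd.DataFrame:
    """Mean r² and fraction above threshold over cumulative ranges [0, x)."""
    d = summary.pairs["d_mb"].to_numpy()
    r2 = summary.pairs["r2"].to_numpy()
    rows = []
    for hi in upper_edges_mb:
        sel = d < hi
        n = int(sel.sum())
        rows.append(
            {
                "hi_mb": hi,
                "n_pairs": n,
                "mean_r2": float(r2[sel].mean()) if n else np.nan,
                f"frac_r2_gt_{r2_threshold}": float((r2[sel] > r2_threshold).mean())
                if n
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def write_ld_tsv(summary: LDSummary, path) -> None:
    summary.pairs.to_csv(path, sep="\t", index=False)
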
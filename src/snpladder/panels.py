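"""Equally-spaced SNP panels and the VanRaden genomic relationship matrix.

The study ladder selects from 100 to 30,000 equally-spaced SNPs, or all
available SNPs, and builds one G matrix per panel:

    G = (M - 2P)(M - 2P)' / (2 * sum_i p_i (1 - p_i)) + jitter * I

where M holds minor-allele dosages, P repeats the per-marker minor-allele
frequency p_i, and a small diagonal jitter keeps G positive definite.
Panels are compared to the full-density G via Pearson correlations of the
diagonal (r_D), strictly-upper-triangle (r_N) and all (r_A) elements.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import GenotypeMatrix, MarkerMap

#: Panel sizes used throughout the study, sparsest to densest.
STUDY_LADDER: tuple = (100, 200, 500, 1000, 2000, 4000, 6000, 8000, 10000, 20000, 30000, "all")


@dataclass(frozen=True)
class PanelSpec:
    """A marker subset: requested size and the selected (sorted) indices."""

    target_count: int | str
    selected_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.selected_indices, dtype=np.int64)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("panel indices must be unique")
        if len(idx) and not np.all(np.diff(idx) > 0):
            raise ValueError("panel indices must be sorted")
        object.__setattr__(self, "selected_indices", idx)

    @property
    def size(self) -> int:
        return len(self.selected_indices)


@dataclass(frozen=True)
class GRMatrix:
    """Symmetric genomic relationship matrix with its provenance."""

    values: np.ndarray
    panel: PanelSpec
    jitter: float
    allele_freqs_used: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        object.__setattr__(self, "values", v)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class GRMComparison:
    """Correlations of a panel G with the full-density G."""

    r_D: float  # diagonal elements
    r_N: float  # strictly-upper-triangle elements
    r_A: float  # all elements (full flattened matrix)


# ---------------------------------------------------------------------------
# Panel selection
# ---------------------------------------------------------------------------


def _largest_remainder_allocation(
    spans: np.ndarray, caps: np.ndarray, k: int
) -> np.ndarray:
    """Allocate k picks across chromosomes proportional to span.

    Each chromosome gets at least one pick when k allows it, never more than
    its marker count; leftovers go to the largest fractional remainders.
    """
    c = len(spans)
    weights = spans.astype(float)
    if weights.sum() <= 0:
        weights = np.ones(c)
    quota = k * weights / weights.sum()
    floor_min = 1 if k >= c else 0
    alloc = np.clip(np.floor(quota).astype(int), floor_min, caps)
    remainder = quota - np.floor(quota)
    # redistribute until the total matches k
    while alloc.sum() < k:
        room = alloc < caps
        if not room.any():
            break
        j = np.flatnonzero(room)[np.argmax(remainder[room])]
        alloc[j] += 1
        remainder[j] = -1.0
    while alloc.sum() > k:
        shrinkable = alloc > floor_min
        j = np.flatnonzero(shrinkable)[np.argmin(remainder[shrinkable])]
        alloc[j] -= 1
        remainder[j] = 2.0
    return alloc


def _nearest_unused(pos: np.ndarray, grid_point: float, used: np.ndarray) -> int:
    """Index of the nearest-by-bp unused marker; distance ties break low."""
    dist = np.abs(pos - grid_point)
    dist[used] = np.inf
    best = np.min(dist)
    candidates = np.flatnonzero(dist == best)
    return int(candidates[0])  # positions ascending, so first = lower position


def select_equally_spaced(mmap: MarkerMap, k: int) -> PanelSpec:
    """Pick k markers approximately uniform in physical position.

    Picks are allocated per chromosome proportional to the chromosome's
    marker span (largest-remainder rounding, at least one per chromosome
    when k allows). Within a chromosome, k_c grid points are placed
    endpoint-inclusive across the marker span and each grid point takes the
    nearest marker by bp; distance ties break toward the lower position and
    an already-taken marker is replaced by the nearest unused one.
    """
    m = len(mmap)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > m:
        raise ValueError(f"requested {k} markers but only {m} available")
    if k == m:
        return PanelSpec(target_count=k, selected_indices=np.arange(m))

    chroms = mmap.chromosomes
    slices = [mmap.chrom_slice(int(c)) for c in chroms]
    spans = np.array(
        [
            mmap.position_bp[s].max() - mmap.position_bp[s].min() if s.stop > s.start else 0
            for s in slices
        ],
        dtype=np.int64,
    )
    caps = np.array([s.stop - s.start for s in slices])
    alloc = _largest_remainder_allocation(spans, caps, k)

    chosen: list[int] = []
    for s, k_c in zip(slices, alloc):
        if k_c == 0:
            continue
        pos = mmap.position_bp[s].astype(float)
        grid = np.linspace(pos[0], pos[-1], int(k_c))
        used = np.zeros(len(pos), dtype=bool)
        for gp in grid:
            j = _nearest_unused(pos, gp, used)
            used[j] = True
            chosen.append(s.start + j)
    return PanelSpec(target_count=k, selected_indices=np.sort(np.array(chosen)))


def full_panel(mmap: MarkerMap) -> PanelSpec:
    return PanelSpec(target_count="all", selected_indices=np.arange(len(mmap)))


def make_ladder(mmap: MarkerMap, sizes=STUDY_LADDER) -> list[PanelSpec]:
    """Panels for every ladder size not exceeding the available marker count."""
    out = []
    for size in sizes:
        if size == "all":
            out.append(full_panel(mmap))
        elif size <= len(mmap):
            out.append(select_equally_spaced(mmap, int(size)))
    return out


# ---------------------------------------------------------------------------
# Genomic relationship matrix
# ---------------------------------------------------------------------------


def build_grm(
    G: GenotypeMatrix,
    panel: PanelSpec | None = None,
    jitter: float = 1e-4,
) -> GRMatrix:
    """VanRaden G on the panel's markers, frequencies from the analyzed cohort."""
    if panel is None:
        panel = PanelSpec(
            target_count="all", selected_indices=np.arange(G.n_markers)
        )
    if panel.size == 0:
        raise ValueError("panel is empty")
    dos = G.dosages[:, panel.selected_indices].astype(float)
    if (dos < 0).any():
        raise ValueError("genotypes must be complete (no missing) to build G")
    p = dos.mean(axis=0) / 2.0
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError(
            "monomorphic marker in panel; filter markers before building G"
        )
    Z = dos - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    values = (Z @ Z.T) / denom
    values[np.diag_indices_from(values)] += jitter
    values = (values + values.T) / 2.0  # exact symmetry
    return GRMatrix(values=values, panel=panel, jitter=jitter, allele_freqs_used=p)


def grm_correlation(sub: GRMatrix, full: GRMatrix) -> GRMComparison:
    """Pearson correlations of the sub-panel G with the full-density G."""
    a, b = sub.values, full.values
    if a.shape != b.shape:
        raise ValueError("G matrices must have identical dimensions")
    iu = np.triu_indices_from(a, k=1)
    return GRMComparison(
        r_D=float(np.corrcoef(np.diag(a), np.diag(b))[0, 1]),
        r_N=float(np.corrcoef(a[iu], b[iu])[0, 1]),
        r_A=float(np.corrcoef(a.ravel(), b.ravel())[0, 1]),
    )


# ---------------------------------------------------------------------------
# Plain-text persistence
# ---------------------------------------------------------------------------


def write_grm_ijv(grm: GRMatrix, ids: list[str], path: str | Path) -> None:
    """Lower triangle (including diagonal) as a 3-column TSV (id_i, id_j, value)."""
    n = grm.n_individuals
    il, jl = np.tril_indices(n)
    pd.DataFrame(
        {
            "id_i": np.asarray(ids)[il],
            "id_j": np.asarray(ids)[jl],
            "value": grm.values[il, jl],
        }
    ).to_csv(path, sep="\t", index=False)


def write_panel_markers(panel: PanelSpec, mmap: MarkerMap, path: str | Path) -> None:
    """Selected marker ids, one per line."""
    Path(path).write_text(
        "\n".join(mmap.marker_id[panel.selected_indices]) + "\n"
    )


def read_panel_markers(path: str | Path, mmap: MarkerMap) -> PanelSpec:
    wanted = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    lookup = {mid: i for i, mid in enumerate(mmap.marker_id)}
    idx = np.sort(np.array([lookup[mid] for mid in wanted], dtype=np.int64))
    return PanelSpec(target_count=len(idx), selected_indices=idx)
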
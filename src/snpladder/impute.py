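"""Low-to-high-density genotype prediction from a reference cohort.

A deliberately transparent stand-in for haplotype-based imputation: each
untyped marker is predicted from the single typed flanking marker that is
most correlated with it in the reference cohort, via the empirical
conditional modal genotype. The interface accepts externally imputed
matrices, so a real phasing/imputation tool can be swapped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panels import PanelSpec
from .simdata import MISSING, GenotypeMatrix, MarkerMap


@dataclass(frozen=True)
class ReferencePanel:
    """Complete high-density genotypes of individuals disjoint from the study set."""

    genotypes: GenotypeMatrix
    marker_map: MarkerMap

    def __post_init__(self) -> None:
        if self.genotypes.missing_mask.any():
            raise ValueError("reference genotypes must be complete")
        if self.genotypes.n_markers != len(self.marker_map):
            raise ValueError("reference matrix and map are misaligned")


@dataclass
class ImputationResult:
    """Full-density imputed genotypes plus per-marker provenance."""

    imputed: GenotypeMatrix
    untyped_indices: np.ndarray
    predictor_indices: np.ndarray  # flanking marker used per untyped marker (-1 = none)


def _conditional_mode_table(ref_target: np.ndarray, ref_flank: np.ndarray) -> np.ndarray:
    """table[g] = modal target dosage among reference animals with flank dosage g."""
    table = np.full(3, -1, dtype=np.int16)
    for gk in range(3):
        sel = ref_target[ref_flank == gk]
        if len(sel):
            table[gk] = np.bincount(sel, minlength=3).argmax()
    return table


def naive_impute(
    low: GenotypeMatrix,
    panel: PanelSpec,
    ref: ReferencePanel,
) -> ImputationResult:
    """Predict untyped high-density genotypes from a low-density panel.

    ``low`` holds the study cohort's genotypes at ``panel`` markers (indices
    into the reference marker map). For each untyped marker the typed
    flanking marker with the larger absolute dosage correlation in the
    reference is chosen; the imputed call is the reference's modal genotype
    conditional on the study animal's genotype at that flanking marker,
    falling back to the reference marker mode for empty cells or markers
    with no typed neighbour on their chromosome.
    """
    m_full = len(ref.marker_map)
    typed = panel.selected_indices
    if low.n_markers != len(typed):
        raise ValueError("low-density matrix does not match the panel")
    if low.missing_mask.any():
        raise ValueError("low-density genotypes must be complete")
    if typed.max(initial=-1) >= m_full:
        raise ValueError("panel indices exceed the reference marker set")

    n = low.n_individuals
    out = np.full((n, m_full), MISSING, dtype=np.int16)
    out[:, typed] = low.dosages
    untyped = np.setdiff1d(np.arange(m_full), typed)
    predictors = np.full(len(untyped), -1, dtype=np.int64)

    ref_dos = ref.genotypes.dosages
    chrom = ref.marker_map.chromosome
    pos = ref.marker_map.position_bp
    typed_mask = np.zeros(m_full, dtype=bool)
    typed_mask[typed] = True
    ref_modes = np.array(
        [np.bincount(ref_dos[:, j], minlength=3).argmax() for j in range(m_full)],
        dtype=np.int16,
    )

    warned = False
    for u_i, j in enumerate(untyped):
        same = typed[chrom[typed] == chrom[j]]
        if len(same) == 0:
            if not warned:
                warnings.warn(
                    "untyped marker with no typed marker on its chromosome; "
                    "falling back to reference marker mode",
                    stacklevel=2,
                )
                warned = True
            out[:, j] = ref_modes[j]
            continue
        # typed flanking markers: nearest on each side, by bp
        below = same[pos[same] < pos[j]]
        above = same[pos[same] > pos[j]]
        candidates = []
        if len(below):
            candidates.append(below[np.argmax(pos[below])])
        if len(above):
            candidates.append(above[np.argmin(pos[above])])
        target = ref_dos[:, j].astype(np.int64)
        best_k, best_abs_r = candidates[0], -1.0
        for k in candidates:
            flank = ref_dos[:, k].astype(np.int64)
            if flank.std() == 0 or target.std() == 0:
                abs_r = 0.0
            else:
                abs_r = abs(float(np.corrcoef(target, flank)[0, 1]))
            if abs_r > best_abs_r:
                best_abs_r, best_k = abs_r, k
        predictors[u_i] = best_k
        table = _conditional_mode_table(target, ref_dos[:, best_k].astype(np.int64))
        filled = table[out[:, best_k]]
        filled[filled < 0] = ref_modes[j]
        out[:, j] = filled

    return ImputationResult(
        imputed=GenotypeMatrix(
            dosages=out,
            individual_ids=list(low.individual_ids),
            orientation=low.orientation if low.orientation is not None else None,
        ),
        untyped_indices=untyped,
        predictor_indices=predictors,
    )


def imputation_accuracy(
    truth: GenotypeMatrix,
    imputed: GenotypeMatrix,
    scored_markers: np.ndarray,
) -> tuple[float, pd.DataFrame]:
    """Percent of exactly-correct calls on the scored (untyped) markers.

    Returns the overall concordance percentage and a per-individual table;
    the per-individual accuracies' mean ± SD mirror how imputation accuracy
    is usually reported.
    """
    scored = np.asarray(scored_markers, dtype=np.int64)
    if len(scored) == 0:
        raise ValueError("scored marker set is empty")
    if truth.dosages.shape != imputed.dosages.shape:
        raise ValueError("truth and imputed matrices must align")
    t = truth.dosages[:, scored]
    p = imputed.dosages[:, scored]
    correct = t == p
    overall = 100.0 * correct.mean()
    per_ind = pd.DataFrame(
        {
            "individual_id": truth.individual_ids,
            "accuracy_pct": 100.0 * correct.mean(axis=1),
        }
    )
    return float(overall), per_ind
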
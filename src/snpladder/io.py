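"""Plain-text readers and writers: PLINK PED/MAP, dosage/phenotype/truth TSV.

PED rows are ``fid iid pat mat sex phe`` followed by two allele columns per
marker. Alleles are coded ``A`` (major) / ``B`` (minor) so that the dosage is
the count of ``B``; a missing call is ``0 0``. MAP rows are
``chromosome marker_id cm position_bp`` with 1-based physical positions.
All writers are paired with readers and round-trip exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import MISSING, GenotypeMatrix, MarkerMap, QTLModel


# ---------------------------------------------------------------------------
# PED / MAP
# ---------------------------------------------------------------------------


def write_map(mmap: MarkerMap, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chromosome": mmap.chromosome,
            "marker_id": mmap.marker_id,
            "cm": 0,
            "position_bp": mmap.position_bp,
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_map(path: str | Path) -> MarkerMap:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "marker_id", "cm", "position_bp"],
    )
    return MarkerMap(
        marker_id=df["marker_id"].astype(str).to_numpy(),
        chromosome=df["chromosome"].to_numpy(np.int64),
        position_bp=df["position_bp"].to_numpy(np.int64),
    )


_DOSAGE_TO_ALLELES = {0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B"), MISSING: ("0", "0")}


def write_ped(G: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iid in enumerate(G.individual_ids):
            row = G.dosages[i]
            fields = ["FAM", iid, "0", "0", "0", "-9"]
            for d in row:
                a1, a2 = _DOSAGE_TO_ALLELES[int(d)]
                fields.append(a1)
                fields.append(a2)
            fh.write(" ".join(fields) + "\n")


def read_ped(path: str | Path) -> GenotypeMatrix:
    ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            ids.append(parts[1])
            alleles = parts[6:]
            if len(alleles) % 2:
                raise ValueError("odd number of allele columns in PED row")
            a1 = np.array(alleles[0::2])
            a2 = np.array(alleles[1::2])
            dos = (a1 == "B").astype(np.int16) + (a2 == "B").astype(np.int16)
            miss = (a1 == "0") | (a2 == "0")
            dos[miss] = MISSING
            rows.append(dos)
    return GenotypeMatrix(dosages=np.array(rows, dtype=np.int16), individual_ids=ids)


def write_ped_map(
    G: GenotypeMatrix, mmap: MarkerMap, prefix: str | Path
) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` and ``<prefix>.map``; returns both paths."""
    if G.n_markers != len(mmap):
        raise ValueError("genotype columns and marker map length differ")
    prefix = Path(prefix)
    ped, mp = prefix.with_suffix(".ped"), prefix.with_suffix(".map")
    write_ped(G, ped)
    write_map(mmap, mp)
    return ped, mp


def read_ped_map(prefix: str | Path) -> tuple[GenotypeMatrix, MarkerMap]:
    prefix = Path(prefix)
    G = read_ped(prefix.with_suffix(".ped"))
    mmap = read_map(prefix.with_suffix(".map"))
    if G.n_markers != len(mmap):
        raise ValueError("PED and MAP disagree on marker count")
    return G, mmap


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def write_dosage_tsv(G: GenotypeMatrix, mmap: MarkerMap, path: str | Path) -> None:
    """Dosage matrix as TSV: one row per individual, one column per marker id."""
    df = pd.DataFrame(G.dosages, index=G.individual_ids, columns=mmap.marker_id)
    df.index.name = "individual_id"
    df.to_csv(path, sep="\t")


def read_dosage_tsv(path: str | Path) -> tuple[GenotypeMatrix, np.ndarray]:
    """Returns the matrix and the marker-id header (map stored separately)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return (
        GenotypeMatrix(
            dosages=df.to_numpy(np.int16),
            individual_ids=[str(i) for i in df.index],
        ),
        df.columns.to_numpy(str),
    )


PHENOTYPE_COLUMNS = ["individual_id", "value", "market", "year", "age_months"]


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.loc[:, PHENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"market": str, "year": str})
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file lacks columns: {sorted(missing)}")
    return df


def write_truth(
    true_bv: np.ndarray,
    individual_ids: list[str],
    qtl: QTLModel,
    mmap: MarkerMap,
    bv_path: str | Path,
    qtl_path: str | Path,
) -> None:
    """Sidecar files: per-individual true breeding values and the QTL table."""
    pd.DataFrame({"individual_id": individual_ids, "true_bv": true_bv}).to_csv(
        bv_path, sep="\t", index=False
    )
    idx = qtl.qtl_marker_indices
    pd.DataFrame(
        {
            "marker_id": mmap.marker_id[idx],
            "chromosome": mmap.chromosome[idx],
            "position_bp": mmap.position_bp[idx],
            "effect": qtl.effects,
        }
    ).to_csv(qtl_path, sep="\t", index=False)


def read_truth_bv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
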
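"""Cross-density evaluation: the panel ladder, GEBV comparisons, pipeline driver.

Runs the whole study on synthetic data: simulate a small-Ne population and
two traits (a carcass-weight-like continuous trait with a few large QTLs plus
polygenes, and a marbling-like 12-category ordinal trait with small QTLs
only), apply SNP QC, then walk a ladder of equally-spaced panels computing LD
summaries, G-matrix correlations, Gibbs variance components, and the
correlation/regression of each panel's GEBVs on the full-density GEBVs.
Optional imputation arms rebuild the full panel from a low-density panel via
a reference cohort before fitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ldstats, qc
from .bayes import (
    ChainConfig,
    PosteriorSummary,
    PriorConfig,
    _GrmEigen,
    build_design,
    gibbs_model1,
    gibbs_model2,
)
from .impute import ReferencePanel, imputation_accuracy, naive_impute
from .panels import (
    STUDY_LADDER,
    build_grm,
    full_panel,
    grm_correlation,
    select_equally_spaced,
)
from .simdata import (
    DEFAULT_MARBLING_PROBS,
    CovariateDesign,
    GenotypeMatrix,
    SimConfig,
    assign_qtl_effects,
    discretize_liability,
    mask_genotypes,
    sample_genotypes,
    simulate_haplotypes,
    simulate_phenotypes,
    thresholds_from_probs,
)


# ---------------------------------------------------------------------------
# Pairwise comparison statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GEBVComparison:
    """Agreement of a sparse panel's GEBVs with the full-density GEBVs."""

    correlation: float
    regression_slope: float  # sparse GEBVs regressed on full-density GEBVs


def gebv_compare(sub_gebv: np.ndarray, full_gebv: np.ndarray) -> GEBVComparison:
    """Pearson correlation and OLS slope (sub regressed on full)."""
    sub = np.asarray(sub_gebv, float)
    full = np.asarray(full_gebv, float)
    if sub.shape != full.shape or sub.ndim != 1:
        raise ValueError("GEBV vectors must be aligned 1-D arrays")
    if len(sub) < 3:
        raise ValueError("need at least 3 animals")
    if sub.std() == 0 or full.std() == 0:
        raise ValueError("zero-variance GEBV vector")
    r = float(np.corrcoef(sub, full)[0, 1])
    slope = float(np.cov(sub, full, ddof=1)[0, 1] / full.var(ddof=1))
    return GEBVComparison(correlation=r, regression_slope=slope)


def variance_explained_percent(
    sub: PosteriorSummary, full: PosteriorSummary
) -> dict[str, float]:
    """100 x (sub posterior mean / full posterior mean) per variance component."""
    out: dict[str, float] = {}
    for key in ("sigma_e2", "sigma_g2", "sigma_p2"):
        if key not in sub.mean or key not in full.mean:
            continue
        denom = full.mean[key]
        out[key] = 100.0 * sub.mean[key] / denom if denom != 0 else float("nan")
    return out


def cross_panel_statistics(table: pd.DataFrame) -> dict[str, float]:
    """Aggregates across the ladder rows.

    Correlation between r_N and the panel's mean adjacent r², plus, for each
    trait column pair present, correlations between mean r² and the posterior
    variance components. Requires at least 3 rows with defined r_N.
    """
    sub = table.dropna(subset=["r_N", "mean_r2"])
    if len(sub) < 3:
        raise ValueError("need at least 3 ladder rows with r_N defined")
    out = {
        "corr_rN_mean_r2": float(np.corrcoef(sub["r_N"], sub["mean_r2"])[0, 1])
    }
    for col in table.columns:
        if col.endswith("_sigma_e2") or col.endswith("_sigma_g2"):
            rows = table.dropna(subset=[col, "mean_r2"])
            if len(rows) >= 3:
                out[f"corr_mean_r2_{col}"] = float(
                    np.corrcoef(rows["mean_r2"], rows[col])[0, 1]
                )
    return out


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitConfig:
    """Genetic architecture and measurement model of one simulated trait."""

    name: str
    kind: str  # "continuous" | "ordinal"
    n_large_qtl: int
    n_small_qtl: int
    large_effect_sd: float
    small_effect_sd: float
    target_h2: float
    category_probs: tuple | None = None  # ordinal only
    qtl_placement: str = "uniform"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "ordinal"):
            raise ValueError("trait kind must be 'continuous' or 'ordinal'")


def default_traits() -> tuple[TraitConfig, TraitConfig]:
    """The study's two carcass traits.

    Carcass weight: moderate heritability with three large-effect QTLs on a
    polygenic background. Marbling score: higher heritability, small-effect
    QTLs only, observed as a 12-category ordinal score.
    """
    cw = TraitConfig(
        name="carcass_weight",
        kind="continuous",
        n_large_qtl=3,
        n_small_qtl=300,
        large_effect_sd=12.0,
        small_effect_sd=1.0,
        target_h2=0.55,
        qtl_placement="extended_ld",
    )
    ms = TraitConfig(
        name="marbling_score",
        kind="ordinal",
        n_large_qtl=0,
        n_small_qtl=300,
        large_effect_sd=0.0,
        small_effect_sd=1.0,
        target_h2=0.68,
        category_probs=tuple(DEFAULT_MARBLING_PROBS),
    )
    return cw, ms


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end study configuration; defaults mirror the study design.

    The default sizes (872 study animals, 494 reference animals, the full
    12-step ladder, 110k-iteration chains) are the study's own conditions and
    are expensive; tests and examples pass scaled-down configs.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    n_animals: int = 872
    n_reference: int = 494
    missing_rate: float = 0.02
    qc: qc.QCConfig = field(default_factory=qc.QCConfig)
    covariates: CovariateDesign = field(default_factory=CovariateDesign)
    traits: tuple[TraitConfig, ...] = field(default_factory=default_traits)
    ladder: tuple = STUDY_LADDER
    chain: ChainConfig = field(default_factory=ChainConfig)
    prior: PriorConfig = field(default_factory=PriorConfig)
    fit_model2: bool = True
    model2_max_panel: int = 2000
    impute_panels: tuple = (4000, 10000)
    seed: int = 0


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a single YAML document.

    Top-level keys mirror the PipelineConfig fields; the nested ``sim``,
    ``qc``, ``covariates``, ``chain``, ``prior`` mappings mirror their
    dataclasses, and ``traits`` is a list of TraitConfig mappings. Unknown
    keys raise immediately rather than being ignored.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}

    def build(cls, data):
        if data is None:
            return cls()
        valid = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
        return cls(**data)

    kwargs: dict = {}
    for key, cls in (
        ("sim", SimConfig),
        ("qc", qc.QCConfig),
        ("covariates", CovariateDesign),
        ("chain", ChainConfig),
        ("prior", PriorConfig),
    ):
        if key in raw:
            kwargs[key] = build(cls, raw.pop(key))
    if "traits" in raw:
        kwargs["traits"] = tuple(build(TraitConfig, t) for t in raw.pop("traits"))
    for key in ("ladder", "impute_panels"):
        if key in raw:
            kwargs[key] = tuple(raw.pop(key))
    allowed = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs.update(raw)
    return PipelineConfig(**kwargs)


@dataclass
class LadderResult:
    """One row per panel plus full-density baseline and cross-panel aggregates.

    ``gebv`` maps each trait to an individuals × panels table of posterior-mean
    GEBVs (the scatter-plot data behind the correlation/slope columns).
    """

    table: pd.DataFrame
    cross_stats: dict[str, float]
    qc_report: qc.QCReport
    imputation: pd.DataFrame | None = None
    gebv: dict[str, pd.DataFrame] | None = None


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


def _fit_traits(
    trait_data: dict,
    grm,
    eigen,
    chain: ChainConfig,
    prior: PriorConfig,
    fit_model2: bool,
    seed: int,
) -> dict[str, PosteriorSummary]:
    """Model-1 fit per trait (on the observed scale) and, for ordinal traits
    when requested, model-2 fits on the binary and categorical codings."""
    fits: dict[str, PosteriorSummary] = {}
    for k, (tname, td) in enumerate(trait_data.items()):
        cc = ChainConfig(
            n_iter=chain.n_iter,
            burn_in=chain.burn_in,
            thin=chain.thin,
            seed=(seed + 1009 * k) % (2**31 - 1),
            fixed_variances=chain.fixed_variances,
        )
        fits[tname] = gibbs_model1(
            td["y"], td["design"], grm, cc, prior, eigen=eigen
        )
        if fit_model2 and td["kind"] == "ordinal":
            for mode in ("binary", "ordinal"):
                cc2 = ChainConfig(
                    n_iter=chain.n_iter,
                    burn_in=chain.burn_in,
                    thin=chain.thin,
                    seed=(seed + 1009 * k + 13 + (mode == "ordinal")) % (2**31 - 1),
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fits[f"{tname}__{mode}"] = gibbs_model2(
                        td["scores"], td["design"], grm, cc2, mode=mode,
                        binary_split=td["binary_split"], prior=prior, eigen=eigen,
                    )
    return fits


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> LadderResult:
    """Execute the full study on synthetic data; deterministic given the seed.

    Stages: simulate haplotypes → sample/mask the study cohort → QC and gap
    filling → simulate traits → for each ladder panel: equally-spaced
    selection, adjacent-pair LD, G matrix and comparison with the full G,
    Gibbs fits and GEBV comparison → optional imputation arms → tables,
    run manifest and figures.
    """
    base = config.seed

    # --- simulate and QC -------------------------------------------------
    sim_cfg = config.sim if config.sim.seed == base else _with_seed(config.sim, base)
    hap_panel, _ = simulate_haplotypes(sim_cfg)
    study_raw = sample_genotypes(hap_panel, config.n_animals, seed=base + 1)
    masked = mask_genotypes(study_raw, config.missing_rate, seed=base + 2)
    qc_cfg = config.qc if config.qc.seed == base + 3 else _with_seed(config.qc, base + 3)
    G_f, mmap_f, report = qc.apply_filters(masked, hap_panel.marker_map, qc_cfg)
    G = qc.fill_missing(G_f, qc_cfg, mmap_f)

    # --- traits -----------------------------------------------------------
    trait_data: dict[str, dict] = {}
    for k, tc in enumerate(config.traits):
        qtl = assign_qtl_effects(
            mmap_f,
            tc.n_large_qtl,
            tc.n_small_qtl,
            tc.large_effect_sd,
            tc.small_effect_sd,
            seed=base + 10 + k,
            placement=tc.qtl_placement,
            genotypes=G,
        )
        phenos, g_true = simulate_phenotypes(
            G, qtl, config.covariates, tc.target_h2, seed=base + 20 + k
        )
        entry: dict = {"qtl": qtl, "true_bv": g_true, "kind": tc.kind}
        if tc.kind == "ordinal":
            probs = np.asarray(tc.category_probs, float)
            thresholds = thresholds_from_probs(phenos["value"].to_numpy(), probs)
            scores = discretize_liability(phenos["value"].to_numpy(), thresholds)
            obs = phenos.assign(value=scores.astype(float))
            entry["scores"] = scores
            entry["binary_split"] = 6
        else:
            obs = phenos
        design, y = build_design(obs)
        entry["design"], entry["y"], entry["phenos"] = design, y, obs
        trait_data[tc.name] = entry

    # --- full-density baseline -------------------------------------------
    pfull = full_panel(mmap_f)
    grm_full = build_grm(G, pfull)
    eig_full = _GrmEigen(grm_full)
    ld_full = ldstats.adjacent_r2(G, mmap_f)
    fits_full = _fit_traits(
        trait_data, grm_full, eig_full, config.chain, config.prior,
        config.fit_model2 and _as_size(pfull.size) <= config.model2_max_panel,
        seed=base + 100,
    )

    # --- ladder ------------------------------------------------------------
    sub_sizes = [s for s in config.ladder if s != "all" and s < len(mmap_f)]
    rows: list[dict] = []
    gebv_columns: dict[str, dict[str, np.ndarray]] = {}
    for s_i, size in enumerate(sorted(set(sub_sizes))):
        panel = select_equally_spaced(mmap_f, int(size))
        row, panel_gebvs = _evaluate_panel(
            label=str(size),
            panel=panel,
            G=G,
            mmap=mmap_f,
            trait_data=trait_data,
            fits_full=fits_full,
            grm_full=grm_full,
            config=config,
            seed=base + 200 + 7 * s_i,
        )
        rows.append(row)
        for tname, vec in panel_gebvs.items():
            gebv_columns.setdefault(tname, {})[str(size)] = vec
    rows.append(
        _baseline_row(
            label="all", ld=ld_full, grm=grm_full, fits=fits_full,
            fits_full=fits_full, trait_data=trait_data,
        )
    )
    for tname in trait_data:
        gebv_columns.setdefault(tname, {})["all"] = fits_full[tname].gebv
    gebv_tables = {
        tname: pd.DataFrame(cols, index=G.individual_ids).rename_axis(
            "individual_id"
        )
        for tname, cols in gebv_columns.items()
    }
    table = pd.DataFrame(rows)

    cross = cross_panel_statistics(table)

    # --- imputation arms ----------------------------------------------------
    imput_df = None
    imp_sizes = [s for s in config.impute_panels if s < len(mmap_f)]
    if imp_sizes and config.n_reference >= 2:
        ref_G = sample_genotypes(
            hap_panel, config.n_reference, seed=base + 4,
            orientation=study_raw.orientation,
        )
        ref_G = ref_G.subset_markers(
            np.flatnonzero(np.isin(hap_panel.marker_map.marker_id, mmap_f.marker_id))
        )
        ref = ReferencePanel(genotypes=ref_G, marker_map=mmap_f)
        imp_rows = []
        for s_i, size in enumerate(imp_sizes):
            panel = select_equally_spaced(mmap_f, int(size))
            low = G.subset_markers(panel.selected_indices)
            result = naive_impute(low, panel, ref)
            acc, per_ind = imputation_accuracy(G, result.imputed, result.untyped_indices)
            # mode-imputed columns can go monomorphic; G is built on the rest
            dos = result.imputed.dosages
            poly = (dos.min(axis=0) != dos.max(axis=0))
            from .panels import PanelSpec

            grm_imp = build_grm(
                result.imputed,
                PanelSpec(target_count="all", selected_indices=np.flatnonzero(poly)),
            )
            eig_imp = _GrmEigen(grm_imp)
            fits_imp = _fit_traits(
                trait_data, grm_imp, eig_imp, config.chain, config.prior,
                fit_model2=False, seed=base + 300 + 7 * s_i,
            )
            row = {
                "panel": f"imp_{size}",
                "accuracy_pct": acc,
                "accuracy_sd_pct": float(per_ind["accuracy_pct"].std(ddof=1)),
                "grm_r_A": grm_correlation(grm_imp, grm_full).r_A,
            }
            for tname in trait_data:
                fit = fits_imp[tname]
                cmp_ = gebv_compare(fit.gebv, fits_full[tname].gebv)
                row[f"{tname}_sigma_g2"] = fit.mean["sigma_g2"]
                row[f"{tname}_ratio"] = fit.mean["ratio"]
                row[f"{tname}_gebv_corr"] = cmp_.correlation
                row[f"{tname}_gebv_slope"] = cmp_.regression_slope
            imp_rows.append(row)
        imput_df = pd.DataFrame(imp_rows)

    result = LadderResult(
        table=table,
        cross_stats=cross,
        qc_report=report,
        imputation=imput_df,
        gebv=gebv_tables,
    )
    if outdir is not None:
        _write_outputs(result, config, Path(outdir), ld_full)
    return result


def _as_size(v) -> int:
    return int(v) if not isinstance(v, str) else 10**9


def _with_seed(cfg, seed: int):
    from dataclasses import replace

    return replace(cfg, seed=seed)


def _evaluate_panel(
    label: str,
    panel,
    G: GenotypeMatrix,
    mmap,
    trait_data: dict,
    fits_full: dict,
    grm_full,
    config: PipelineConfig,
    seed: int,
) -> dict:
    sub_G = G.subset_markers(panel.selected_indices)
    sub_map = mmap.subset(panel.selected_indices)
    ld = ldstats.adjacent_r2(sub_G, sub_map)
    grm = build_grm(G, panel)
    eig = _GrmEigen(grm)
    comp = grm_correlation(grm, grm_full)
    fit2 = config.fit_model2 and panel.size <= config.model2_max_panel
    fits = _fit_traits(
        trait_data, grm, eig, config.chain, config.prior, fit2, seed=seed
    )
    row = {
        "panel": label,
        "n_markers": panel.size,
        "mean_r2": ld.mean_r2,
        "sd_r2": ld.sd_r2,
        "mean_d_mb": ld.mean_d_mb,
        "sd_d_mb": ld.sd_d_mb,
        "r_D": comp.r_D,
        "r_N": comp.r_N,
        "r_A": comp.r_A,
    }
    _add_fit_columns(row, fits, fits_full, trait_data)
    return row, {tname: fits[tname].gebv for tname in trait_data}


def _baseline_row(label, ld, grm, fits, fits_full, trait_data) -> dict:
    row = {
        "panel": label,
        "n_markers": grm.panel.size,
        "mean_r2": ld.mean_r2,
        "sd_r2": ld.sd_r2,
        "mean_d_mb": ld.mean_d_mb,
        "sd_d_mb": ld.sd_d_mb,
        "r_D": 1.0,
        "r_N": 1.0,
        "r_A": 1.0,
    }
    _add_fit_columns(row, fits, fits_full, trait_data)
    return row


def _add_fit_columns(row, fits, fits_full, trait_data) -> None:
    for tname in trait_data:
        fit = fits[tname]
        full = fits_full[tname]
        pct = variance_explained_percent(fit, full)
        cmp_ = gebv_compare(fit.gebv, full.gebv)
        row[f"{tname}_sigma_e2"] = fit.mean["sigma_e2"]
        row[f"{tname}_sigma_g2"] = fit.mean["sigma_g2"]
        row[f"{tname}_sigma_p2"] = fit.mean["sigma_p2"]
        row[f"{tname}_ratio"] = fit.mean["ratio"]
        row[f"{tname}_pct_sigma_g2"] = pct.get("sigma_g2", float("nan"))
        row[f"{tname}_pct_sigma_p2"] = pct.get("sigma_p2", float("nan"))
        row[f"{tname}_gebv_corr"] = cmp_.correlation
        row[f"{tname}_gebv_slope"] = cmp_.regression_slope
        for mode in ("binary", "ordinal"):
            key = f"{tname}__{mode}"
            if key in fits:
                row[f"{tname}_model2_{mode}_ratio"] = fits[key].mean["ratio"]
                row[f"{tname}_model2_{mode}_converged"] = fits[key].converged


def _write_outputs(result: LadderResult, config: PipelineConfig, outdir: Path, ld_full) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(outdir / "ladder.tsv", sep="\t", index=False)
    if result.imputation is not None:
        result.imputation.to_csv(outdir / "imputation.tsv", sep="\t", index=False)
    manifest = {
        "seed": config.seed,
        "n_animals": config.n_animals,
        "ladder": [str(s) for s in config.ladder],
        "chain": {
            "n_iter": config.chain.n_iter,
            "burn_in": config.chain.burn_in,
            "thin": config.chain.thin,
        },
        "qc": result.qc_report.__dict__,
        "cross_stats": result.cross_stats,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    binned = ldstats.bin_summary(ld_full)
    binned.to_csv(outdir / "ld_bins.tsv", sep="\t", index=False)

    if result.gebv:
        for tname, df in result.gebv.items():
            df.to_csv(outdir / f"gebv_{tname}.tsv", sep="\t")
        # sparse-vs-full GEBV scatter for the sparsest panel of each trait
        fig, axes = plt.subplots(
            1, len(result.gebv), figsize=(4.2 * len(result.gebv), 4), squeeze=False
        )
        for ax, (tname, df) in zip(axes[0], result.gebv.items()):
            sparse_col = df.columns[0]
            ax.scatter(df["all"], df[sparse_col], s=8, alpha=0.6)
            lim = [df["all"].min(), df["all"].max()]
            ax.plot(lim, lim, "k--", lw=0.8)
            ax.set_xlabel("GEBV, all SNPs")
            ax.set_ylabel(f"GEBV, {sparse_col} SNPs")
            ax.set_title(tname)
        fig.tight_layout()
        fig.savefig(outdir / "gebv_scatter.png", dpi=120)
        plt.close(fig)

    # LD decay (adjacent-pair r2 against distance)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ld_full.pairs["d_mb"], ld_full.pairs["r2"], s=3, alpha=0.2, color="gray")
    mids = (binned["lo_mb"] + binned["hi_mb"].replace(np.inf, np.nan)) / 2
    ax.plot(mids, binned["mean_r2"], "ko-")
    ax.set_xlabel("distance between adjacent SNPs (Mb)")
    ax.set_ylabel("r$^2$")
    fig.tight_layout()
    fig.savefig(outdir / "ld_decay.png", dpi=120)
    plt.close(fig)

    # G-matrix correlations across the ladder
    sub = result.table[result.table["panel"] != "all"]
    fig, ax = plt.subplots(figsize=(5, 4))
    for col, mk in (("r_D", "o"), ("r_N", "^"), ("r_A", "s")):
        ax.plot(sub["n_markers"], sub[col], mk + "-", label=col)
    ax.set_xscale("log")
    ax.set_xlabel("number of SNPs")
    ax.set_ylabel("correlation with full-density G")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "grm_correlations.png", dpi=120)
    plt.close(fig)

    # variance proportions across the ladder
    fig, ax = plt.subplots(figsize=(5, 4))
    for tc in config.traits:
        ax.plot(
            sub["n_markers"], sub[f"{tc.name}_pct_sigma_g2"], "o-", label=tc.name
        )
    ax.set_xscale("log")
    ax.set_xlabel("number of SNPs")
    ax.set_ylabel("% of full-density genetic variance")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "variance_explained.png", dpi=120)
    plt.close(fig)
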
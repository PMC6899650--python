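"""Niche/neutral classification and end-to-end orchestration.

The biological reading of the fitted models: complete spatial randomness
and pure dispersal limitation (Thomas / double Thomas clustering) imply
neutral community assembly — no taxon is responding to its local
environment or to other taxa.  Habitat association (a heterogeneous
Poisson background, with or without superimposed clustering) and spatial
segregation imply niche processes, as do non-independent interspecific
distributions.

:func:`run_pipeline` glues the stages together for a batch of surfaces:
erosion-bias screening, abundance filtering, the per-taxon model ladder,
pairwise toroidal-shift tests on a rectangular sub-window, per-surface
summaries, and the standard plots.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .bias import fit_erosion_models, select_erosion_model
from .bivariate import BivariateResult, toroidal_shift_test
from .clusters import DoubleThomasParams, FittedModel, ThomasParams, fit_protocol, mean_cluster_size
from .config import AnalysisConfig
from .errors import SppaError
from .geometry import (
    BedSurfaceMap,
    extract_rect_subwindow,
    filter_analysis_taxa,
    largest_inscribed_rectangle,
    read_surface_map,
)

log = logging.getLogger("sppa")

#: the model → assembly-process mapping (total over all model kinds)
UNIVARIATE_PROCESS = {
    "CSR": "neutral",
    "TC": "neutral",
    "DTC": "neutral",
    "HP": "niche",
    "ITC": "niche",
    "SEGREGATED": "niche",
}


@dataclass(frozen=True)
class ClassificationResult:
    """Per-taxon or per-pair verdict with its supporting evidence."""

    subject: str | tuple[str, str]
    best_model: FittedModel | BivariateResult
    process: str  # neutral | niche
    rationale: str


def classify_univariate(fit: FittedModel) -> ClassificationResult:
    """Map a univariate best-fit model to a neutral/niche verdict."""
    process = UNIVARIATE_PROCESS[fit.kind]
    return ClassificationResult(
        subject="",
        best_model=fit,
        process=process,
        rationale=f"univariate:{fit.kind}->{process}",
    )


def classify_bivariate(result: BivariateResult) -> ClassificationResult:
    """Independent pairs are neutral; any non-independence is a niche signal."""
    process = "neutral" if result.independent else "niche"
    tag = "independent" if result.independent else result.direction
    return ClassificationResult(
        subject=(result.taxon_a, result.taxon_b),
        best_model=result,
        process=process,
        rationale=f"bivariate:{tag}->{process}",
    )


@dataclass
class SurfaceSummary:
    """Per-surface tallies of model kinds and assembly-process verdicts."""

    surface: str
    model_counts: dict[str, int] = field(default_factory=dict)
    neutral_univariate: int = 0
    niche_univariate: int = 0
    bivariate_independent: int = 0
    bivariate_nonindependent: int = 0

    @property
    def model_proportions(self) -> dict[str, float]:
        total = sum(self.model_counts.values())
        if total == 0:
            return {}
        return {k: v / total for k, v in self.model_counts.items()}


def summarize_surface(
    surface: str,
    univariate: list[ClassificationResult],
    bivariate: list[ClassificationResult] | None = None,
) -> SurfaceSummary:
    out = SurfaceSummary(surface=surface)
    for c in univariate:
        kind = c.best_model.kind
        out.model_counts[kind] = out.model_counts.get(kind, 0) + 1
        if c.process == "neutral":
            out.neutral_univariate += 1
        else:
            out.niche_univariate += 1
    for c in bivariate or []:
        if c.process == "neutral":
            out.bivariate_independent += 1
        else:
            out.bivariate_nonindependent += 1
    return out


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------


def _fit_row(surface: str, taxon: str, fit: FittedModel) -> dict:
    row: dict = {
        "surface": surface,
        "taxon": taxon,
        "n": fit.n_points,
        "model": fit.kind,
        "fit_basis": fit.fit_basis or "",
        "sigma_m": np.nan,
        "rho_per_m2": np.nan,
        "mean_cluster_size": np.nan,
    }
    p = fit.params
    if isinstance(p, ThomasParams):
        row.update(sigma_m=p.sigma, rho_per_m2=p.rho, mean_cluster_size=mean_cluster_size(p))
    elif isinstance(p, DoubleThomasParams):
        row.update(
            sigma_m=p.small_sigma,
            rho_per_m2=p.large.lambda_total,
            mean_cluster_size=p.small_mu,
        )
    for kind in ("CSR", "HP", "TC", "DTC", "ITC", "SEGREGATED"):
        cand = fit.candidates.get(kind)
        row[f"pd_pcf_{kind}"] = cand.p_d_pcf if cand else np.nan
        row[f"pd_nn_{kind}"] = cand.p_d_nn if cand else np.nan
    return row


def _bias_table(surface_map: BedSurfaceMap, anchor) -> pd.DataFrame:
    fits = fit_erosion_models(surface_map.coords(), surface_map.window, anchor)
    best, adopted = select_erosion_model(fits)
    rows = []
    for f in fits:
        rows.append(
            {
                "surface": surface_map.surface_name,
                "model_kind": f.model_kind,
                "intercept": f.intercept,
                "slope": f.slope,
                "logLik": f.log_likelihood,
                "AIC": f.aic,
                "dAIC": f.aic - fits[0].aic,
                "adopted": adopted and f.model_kind == best.model_kind,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _child_seeds(seed, n: int) -> list[np.random.Generator]:
    if isinstance(seed, np.random.Generator):
        return seed.spawn(n)
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def analyse_surface(
    surface_map: BedSurfaceMap,
    config: AnalysisConfig,
    seed=None,
    abundance_threshold: int = 30,
    anchor: tuple[float, float] | None = None,
    run_bivariate: bool = True,
) -> dict:
    """Run the full univariate + bivariate analysis of one surface."""
    t0 = time.perf_counter()
    name = surface_map.surface_name
    anchor = anchor if anchor is not None else surface_map.window.bounds[:2]
    bias_df = _bias_table(surface_map, anchor)
    filtered, filter_report = filter_analysis_taxa(surface_map, abundance_threshold)
    taxa = sorted(filtered.taxon_counts())
    rngs = _child_seeds(seed, len(taxa) + 1)

    fits: dict[str, FittedModel] = {}
    classes: list[ClassificationResult] = []
    fit_rows = []
    for taxon, rng in zip(taxa, rngs):
        try:
            fit = fit_protocol(filtered.coords(taxon), filtered.window, config, seed=rng)
        except SppaError as e:
            log.warning("surface %s taxon %s: %s", name, taxon, e)
            continue
        fits[taxon] = fit
        c = classify_univariate(fit)
        classes.append(
            ClassificationResult(taxon, fit, c.process, c.rationale)
        )
        fit_rows.append(_fit_row(name, taxon, fit))
        log.info("surface %s taxon %s -> %s (%.1fs)", name, taxon, fit.kind,
                 time.perf_counter() - t0)

    bi_results: list[BivariateResult] = []
    bi_classes: list[ClassificationResult] = []
    if run_bivariate and len(fits) >= 2:
        rect = largest_inscribed_rectangle(filtered.window)
        clipped = extract_rect_subwindow(filtered, rect)
        rng = rngs[-1]
        for ta, tb in combinations(sorted(fits), 2):
            pa, pb = clipped.coords(ta), clipped.coords(tb)
            if len(pa) == 0 or len(pb) == 0:
                continue
            res = toroidal_shift_test(
                pa, pb, clipped.window, config.grid,
                n_sims=config.n_sims, rank=config.envelope_rank_scaled,
                seed=rng, taxon_a=ta, taxon_b=tb,
            )
            bi_results.append(res)
            bi_classes.append(classify_bivariate(res))

    bi_rows = [
        {
            "surface": name,
            "taxon_a": r.taxon_a,
            "taxon_b": r.taxon_b,
            "n_a": r.n_a,
            "n_b": r.n_b,
            "independent": r.independent,
            "direction": r.direction,
            "density_change_pct": r.density_change_pct,
            "excursions": ";".join(f"{a:.3f}-{b:.3f}" for a, b, _ in r.envelope.excursions),
        }
        for r in bi_results
    ]
    summary = summarize_surface(name, classes, bi_classes)
    return {
        "surface": name,
        "bias": bias_df,
        "filter_report": filter_report,
        "fits": fits,
        "fit_table": pd.DataFrame(fit_rows),
        "univariate_classes": classes,
        "bivariate": bi_results,
        "bivariate_table": pd.DataFrame(bi_rows),
        "summary": summary,
        "elapsed_s": time.perf_counter() - t0,
    }


def run_pipeline(
    map_paths: list[str | Path],
    config: AnalysisConfig | None = None,
    out_dir: str | Path = "sppa_out",
    seed: int | None = None,
    abundance_threshold: int = 30,
    make_plots: bool = True,
) -> dict:
    """Analyse a batch of surface maps and write the report bundle.

    Writes, per run: ``bias_report.csv``, ``fit_table.csv`` (the per-taxon
    model table), ``bivariate_table.csv``, ``surface_summary.csv`` and —
    unless ``make_plots`` is false — PCF/envelope figures per surface.
    A stage failure on one surface is logged and does not abort the rest.
    Deterministic for a fixed seed and config.
    """
    config = config or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = {}
    seeds = np.random.SeedSequence(seed).spawn(len(map_paths))
    for path, ss in zip(map_paths, seeds):
        try:
            smap = path if isinstance(path, BedSurfaceMap) else read_surface_map(path)
            results[smap.surface_name] = analyse_surface(
                smap, config, seed=np.random.default_rng(ss),
                abundance_threshold=abundance_threshold,
            )
        except Exception as e:  # keep going: report per-surface failures
            log.error("surface %s failed: %s", path, e)
            results[str(path)] = {"error": str(e)}

    ok = {k: v for k, v in results.items() if "error" not in v}
    _concat(ok, "bias").to_csv(out / "bias_report.csv", index=False, float_format="%.6g")
    _concat(ok, "fit_table").to_csv(out / "fit_table.csv", index=False, float_format="%.6g")
    _concat(ok, "bivariate_table").to_csv(
        out / "bivariate_table.csv", index=False, float_format="%.6g"
    )
    summary_rows = []
    for name, res in ok.items():
        s: SurfaceSummary = res["summary"]
        row = {
            "surface": name,
            "neutral_univariate": s.neutral_univariate,
            "niche_univariate": s.niche_univariate,
            "bivariate_independent": s.bivariate_independent,
            "bivariate_nonindependent": s.bivariate_nonindependent,
        }
        for kind in UNIVARIATE_PROCESS:
            row[f"prop_{kind}"] = s.model_proportions.get(kind, 0.0)
        summary_rows.append(row)
    pd.DataFrame(summary_rows).to_csv(
        out / "surface_summary.csv", index=False, float_format="%.6g"
    )
    if make_plots:
        for name, res in ok.items():
            plot_surface(res, out)
        plot_model_proportions(ok, out / "model_proportions.png")
    return results


def _concat(results: dict, key: str) -> pd.DataFrame:
    frames = [v[key] for v in results.values() if isinstance(v.get(key), pd.DataFrame)]
    frames = [f for f in frames if len(f)]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


# ---------------------------------------------------------------------------
# Plots (side artefacts; the tables are the product)
# ---------------------------------------------------------------------------


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_surface(result: dict, out_dir: Path) -> None:
    """PCF curves with CSR envelopes for every analysed taxon (one panel each)."""
    plt = _mpl()
    fits: dict[str, FittedModel] = result["fits"]
    if not fits:
        return
    fig, axes = plt.subplots(
        1, len(fits), figsize=(4 * len(fits), 3.2), squeeze=False, sharey=False
    )
    for ax, (taxon, fit) in zip(axes[0], sorted(fits.items())):
        cand = fit.candidates.get("CSR")
        env = cand.envelope if cand else None
        if env is not None:
            ax.fill_between(env.observed.r, env.lo, env.hi, color="0.85", label="CSR envelope")
            obs = env.observed
            neutral = UNIVARIATE_PROCESS[fit.kind] == "neutral"
            ax.plot(obs.r, obs.values, color="C0", ls="-" if neutral else "--",
                    label=f"observed ({fit.kind})")
        ax.axhline(1.0, color="k", lw=0.8)
        ax.set_xlabel("r (m)")
        ax.set_ylabel("g(r)")
        ax.set_title(taxon, fontsize=9)
        ax.legend(fontsize=7)
    fig.suptitle(result["surface"])
    fig.tight_layout()
    fig.savefig(out_dir / f"pcf_{result['surface']}.png", dpi=120)
    plt.close(fig)

    if len(result.get("bivariate", [])):
        fig, axes = plt.subplots(
            1, len(result["bivariate"]), figsize=(4 * len(result["bivariate"]), 3.2),
            squeeze=False,
        )
        for ax, r in zip(axes[0], result["bivariate"]):
            env = r.envelope
            ax.fill_between(env.observed.r, env.lo, env.hi, color="0.85")
            ax.plot(env.observed.r, env.observed.values, color="C3")
            ax.axhline(1.0, color="k", lw=0.8)
            ax.set_title(f"{r.taxon_a} × {r.taxon_b}\n{r.direction}", fontsize=8)
            ax.set_xlabel("r (m)")
            ax.set_ylabel("g12(r)")
        fig.tight_layout()
        fig.savefig(out_dir / f"bivariate_{result['surface']}.png", dpi=120)
        plt.close(fig)


def plot_model_proportions(results: dict, path: Path) -> None:
    """Stacked bar chart of best-fit model proportions per surface."""
    plt = _mpl()
    kinds = ["CSR", "TC", "DTC", "HP", "ITC", "SEGREGATED"]
    colors = {"CSR": "#2166ac", "TC": "#4393c3", "DTC": "#92c5de",
              "HP": "#d6604d", "ITC": "#b2182b", "SEGREGATED": "#67001f"}
    names = list(results)
    fig, ax = plt.subplots(figsize=(1.2 * max(len(names), 3) + 2, 3.5))
    bottoms = np.zeros(len(names))
    for kind in kinds:
        vals = np.array(
            [results[n]["summary"].model_proportions.get(kind, 0.0) for n in names]
        )
        ax.bar(names, vals, bottom=bottoms, label=kind, color=colors[kind])
        bottoms += vals
    ax.set_ylabel("proportion of taxa")
    ax.legend(fontsize=7, ncol=3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
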
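"""Figure helpers: difference-density, twin scatter, and ordered straddle
plots. Figures are presentation-only; nothing downstream reads them."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .concordance import straddle_analysis
from .data_model import AnalysisConfig, Cohort


def difference_density_plot(cohorts: Sequence[Cohort], config: AnalysisConfig,
                            ax=None, scale: str = "raw"):
    """Superimposed densities of absolute twin-twin differences."""
    from .severity import difference_summary
    if ax is None:
        _, ax = plt.subplots()
    for cohort in cohorts:
        s = difference_summary(cohort, scale, config)
        centers = (s.bin_edges[:-1] + s.bin_edges[1:]) / 2.0
        ax.plot(centers, s.bin_density, label=f"{cohort.label} (n={s.n_pairs})")
    ax.set_xlabel(f"|twin 1 - twin 2| ({scale} score points)")
    ax.set_ylabel("density")
    ax.legend()
    return ax


def twin_scatter_plot(cohort: Cohort, config: AnalysisConfig, ax=None):
    """Twin-1 vs twin-2 T-scores with the clinical threshold marked."""
    if ax is None:
        _, ax = plt.subplots()
    x = [p.score_t1 for p in cohort]
    y = [p.score_t2 for p in cohort]
    ax.scatter(x, y, s=12, alpha=0.6)
    thr = config.clinical_threshold
    ax.axvline(thr, ls="--", lw=0.8, color="grey")
    ax.axhline(thr, ls="--", lw=0.8, color="grey")
    ax.set_xlabel("twin 1 (T)")
    ax.set_ylabel("twin 2 (T)")
    ax.set_title(cohort.label)
    return ax


def straddle_plot(cohort: Cohort, config: AnalysisConfig, ax=None):
    """Pairs in ascending order of the lower twin's T-score, with the
    clinical threshold and the subthreshold floor drawn."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    result = straddle_analysis(cohort, config)
    idx = np.arange(len(result.ordered_pairs))
    lower = [r["lower"] for r in result.ordered_pairs]
    upper = [r["upper"] for r in result.ordered_pairs]
    ax.vlines(idx, lower, upper, lw=0.8, color="grey")
    ax.scatter(idx, lower, s=10, label="lower-scoring twin")
    ax.scatter(idx, upper, s=10, label="co-twin")
    ax.axhline(config.clinical_threshold, ls="--", color="red",
               label=f"clinical threshold ({config.clinical_threshold:g}T)")
    ax.axhline(config.subthreshold_floor, ls=":", color="orange",
               label=f"subthreshold floor ({config.subthreshold_floor:g}T)")
    ax.set_xlabel("pairs, ascending by lower twin's T-score")
    ax.set_ylabel("SRS T-score")
    ax.legend(fontsize=7)
    return ax


def save_figures(cohorts: Sequence[Cohort], config: AnalysisConfig,
                 outdir: str | Path, fmt: str = "svg") -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots()
    difference_density_plot(cohorts, config, ax=ax)
    path = outdir / f"difference_density.{fmt}"
    fig.savefig(path)
    plt.close(fig)
    written.append(path)

    for cohort in cohorts:
        fig, ax = plt.subplots()
        twin_scatter_plot(cohort, config, ax=ax)
        path = outdir / f"scatter_{cohort.label}.{fmt}"
        fig.savefig(path)
        plt.close(fig)
        written.append(path)

        fig, ax = plt.subplots(figsize=(8, 4))
        straddle_plot(cohort, config, ax=ax)
        path = outdir / f"straddle_{cohort.label}.{fmt}"
        fig.savefig(path)
        plt.close(fig)
        written.append(path)
    return written
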
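"""End-to-end glue: synthetic cohort → per-cell fits → cohort report.

The measurement chain mirrors the experimental protocol: per cell and
condition, trajectories are reduced to an ensemble MSD curve on the lag grid
k·dt (k = 1..10), fitted to MSD = 2nK_αΔt^α, and the fluorescence image is
reduced to its footprint intensity CV.  The assembled records then run the
paired statistics.
"""

from __future__ import annotations

import numpy as np

from diffent import llps, tracking
from diffent.cohort import CellRecord, CohortReport, run_cohort_analysis
from diffent.synth import SyntheticCohort


def records_from_cohort(cohort_data: SyntheticCohort, k_max: int = 10,
                        n_dims: int = 2) -> list[CellRecord]:
    """Fit every synthetic cell-condition and assemble analysis records."""
    records = []
    for cell in cohort_data.cells:
        curve = tracking.compute_msd(cell.trajectories, k_max=k_max,
                                     dt_frame=cohort_data.spec.dt_frame)
        fit = tracking.fit_power_law(curve, n_dims=n_dims)
        homog = None
        if cell.image is not None:
            homog = llps.compute_cv(cell.image, cell.mask)
        records.append(CellRecord(cell_id=cell.cell_id,
                                  condition=cell.condition, diffusion=fit,
                                  homogeneity=homog))
    return records


def analyze_cohort(cohort_data: SyntheticCohort, k_max: int = 10,
                   bh_correct: bool = False) -> CohortReport:
    """Run the full pipeline on a generated cohort."""
    records = records_from_cohort(cohort_data, k_max=k_max)
    return run_cohort_analysis(records, dt_eval=cohort_data.spec.dt_eval,
                               bh_correct=bh_correct)


def plot_cohort_report(records: list[CellRecord], report: CohortReport,
                       out_dir) -> list[str]:
    """Write summary figures (MSD-style parameter panels) to ``out_dir``.

    Produces per-arm scatter panels for α vs K_α, CV vs K_α / α / α_work,
    CV vs entropy, and paired before/after strip plots for K_α, α and
    entropy.  Returns the written file paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arms = {"active": [r for r in records if r.condition == "active"],
            "depleted": [r for r in records if r.condition == "depleted"]}
    written = []

    def scatter(ax, xs, ys, xlabel, ylabel, title):
        ax.scatter(xs, ys, s=25)
        ax.set_xlabel(xlabel)
        ax.set_ylabel(ylabel)
        ax.set_title(title, fontsize=9)

    fig, axes = plt.subplots(2, 3, figsize=(11, 6.5))
    for row, (arm, cells) in enumerate(arms.items()):
        k = [r.diffusion.k_alpha for r in cells]
        a = [r.diffusion.alpha for r in cells]
        cv = [r.homogeneity.cv for r in cells if r.homogeneity]
        scatter(axes[row, 0], k, a, "K_alpha (um^2/s^a)", "alpha",
                f"alpha vs K_alpha ({arm})")
        if cv:
            scatter(axes[row, 1], k, cv, "K_alpha", "CV",
                    f"CV vs K_alpha ({arm})")
            s = [r.thermo.entropy for r in cells if r.thermo]
            scatter(axes[row, 2], s, cv, "entropy (nats)", "CV",
                    f"CV vs entropy ({arm})")
    fig.tight_layout()
    p = out_dir / "scatter_panels.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(str(p))

    paired_ids = sorted({r.cell_id for r in arms["active"]}
                        & {r.cell_id for r in arms["depleted"]})
    if paired_ids:
        by = {(r.cell_id, r.condition): r for r in records}
        fig, axes = plt.subplots(1, 3, figsize=(10, 3.2))
        for ax, (name, get) in zip(axes, (
                ("K_alpha", lambda r: r.diffusion.k_alpha),
                ("alpha", lambda r: r.diffusion.alpha),
                ("entropy", lambda r: r.thermo.entropy if r.thermo else np.nan))):
            for cid in paired_ids:
                pre = get(by[(cid, "active")])
                post = get(by[(cid, "depleted")])
                ax.plot([0, 1], [pre, post], "o-", alpha=0.6, ms=3)
            ax.set_xticks([0, 1], ["active", "depleted"])
            ax.set_title(name, fontsize=9)
        fig.tight_layout()
        p = out_dir / "paired_comparison.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(str(p))

    (out_dir / "report.md").write_text(report.to_markdown())
    report.to_json(out_dir / "report.json")
    written += [str(out_dir / "report.md"), str(out_dir / "report.json")]
    return written
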
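"""Paired active / ATP-depleted cohort statistics.

The paired design measures each cell twice — active (untreated) and after
ATP depletion — and asks:

* paired t-tests: are K_α, α and entropy larger in the active arm?
* per-arm power-law regressions: is α negatively related to K_α in the
  depleted (equilibrium) arm, as constant-energy level sets predict?
* work decomposition: fit the elastic regression α_e = a·K_α^b on the
  depleted arm, predict α_e for active cells, α_work = α − α_e;
* homogeneity couplings: is the intensity CV (the LLPS proxy) negatively
  related to K_α, α_work and entropy in the active arm only?

All regressions are log-log least squares (power-law form); significance is
judged at p ≤ 0.05 with no multiple-testing correction by default, matching
common practice for a single pre-registered panel (a Benjamini–Hochberg
option exists behind a flag).  Direction expectations are reported as
booleans alongside the underlying effects and p-values — they summarize the
synthetic cohort, they do not prove biology.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from diffent.llps import HomogeneityResult
from diffent.thermo import ElasticRegression, ThermoState, fit_elastic_regression, thermo_state
from diffent.tracking import DiffusionFit

logger = logging.getLogger(__name__)

SIGNIFICANCE = 0.05


@dataclass
class CellRecord:
    """One cell in one condition, fully analyzed."""

    cell_id: str
    condition: str                     # "active" | "depleted"
    diffusion: DiffusionFit
    thermo: ThermoState | None = None
    homogeneity: HomogeneityResult | None = None


@dataclass
class PairedTestResult:
    """Two-sided Student's t-test on paired differences (post − pre)."""

    statistic: float
    p_value: float
    mean_difference: float
    n: int
    degenerate: bool = False


def paired_compare(pre, post) -> PairedTestResult:
    """Paired two-sample t-test of matched measurements.

    ``pre`` and ``post`` must be equal-length (≥ 3) sequences matched by
    cell.  Zero-variance differences make the t statistic undefined; such
    input is returned flagged ``degenerate`` with NaN statistics.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.size != post.size:
        raise ValueError("pre and post must have equal length")
    if pre.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = post - pre
    if np.allclose(diff.std(ddof=1), 0.0):
        logger.warning("zero-variance paired differences: degenerate t-test")
        return PairedTestResult(float("nan"), float("nan"),
                                float(diff.mean()), int(pre.size),
                                degenerate=True)
    t = diff.mean() / (diff.std(ddof=1) / np.sqrt(diff.size))
    p = 2.0 * stats.t.sf(abs(t), df=diff.size - 1)
    return PairedTestResult(float(t), float(p), float(diff.mean()),
                            int(pre.size))


@dataclass
class PowerRegression:
    """Log-log least-squares fit y = a·x^b with slope p-value."""

    a: float
    b: float
    p_value: float
    n: int
    n_excluded: int = 0

    @property
    def significant_negative(self) -> bool:
        return self.b < 0 and self.p_value <= SIGNIFICANCE


def regress_power(x, y) -> PowerRegression:
    """Power-law regression y = a·x^b by least squares on ln x, ln y.

    Non-positive (x, y) pairs cannot enter the log-log fit; they are
    excluded and counted in ``n_excluded``.  Fewer than 3 usable pairs is an
    error.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    ok = (x > 0) & (y > 0)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("excluding %d non-positive pair(s) from log-log "
                    "regression", n_excluded)
    if ok.sum() < 3:
        raise ValueError("need at least 3 positive pairs")
    res = stats.linregress(np.log(x[ok]), np.log(y[ok]))
    return PowerRegression(a=float(np.exp(res.intercept)), b=float(res.slope),
                           p_value=float(res.pvalue), n=int(ok.sum()),
                           n_excluded=n_excluded)


def regress_exponential(x, y) -> PowerRegression:
    """Exponential regression y = a·e^{b·x} by least squares on x, ln y.

    Used for couplings to entropy, which (being a differential entropy) can
    be negative and cannot enter a log-log fit.  Since entropy = ¼ + ¼·ln E,
    an exponential fit in entropy is exactly a power-law fit in energy, with
    an identical slope p-value.  Non-positive y values are excluded.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    ok = y > 0
    n_excluded = int((~ok).sum())
    if ok.sum() < 3:
        raise ValueError("need at least 3 pairs with positive y")
    res = stats.linregress(x[ok], np.log(y[ok]))
    return PowerRegression(a=float(np.exp(res.intercept)), b=float(res.slope),
                           p_value=float(res.pvalue), n=int(ok.sum()),
                           n_excluded=n_excluded)


@dataclass
class CohortReport:
    """Assembled paired tests, regressions, and direction expectations."""

    n_pairs: int
    n_active: int
    n_depleted: int
    paired_tests: dict[str, PairedTestResult]
    regressions: dict[str, PowerRegression]
    elastic_regression: ElasticRegression | None
    expectations: dict[str, bool]
    adjusted_p: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_active": self.n_active,
            "n_depleted": self.n_depleted,
            "paired_tests": {k: vars(v) for k, v in self.paired_tests.items()},
            "regressions": {k: vars(v) for k, v in self.regressions.items()},
            "elastic_regression": (vars(self.elastic_regression)
                                   if self.elastic_regression else None),
            "expectations": self.expectations,
            "adjusted_p": self.adjusted_p,
        }

    def to_json(self, path) -> None:
        from pathlib import Path
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def to_markdown(self) -> str:
        lines = [f"# Cohort report ({self.n_pairs} paired cells; "
                 f"{self.n_active} active, {self.n_depleted} depleted)", ""]
        lines.append("## Paired t-tests (active − depleted)")
        for name, t in self.paired_tests.items():
            tag = " (degenerate)" if t.degenerate else ""
            lines.append(f"- {name}: mean diff {t.mean_difference:+.4g}, "
                         f"t = {t.statistic:.3g}, p = {t.p_value:.3g}{tag}")
        lines.append("")
        lines.append("## Power-law regressions y = a·x^b")
        for name, r in self.regressions.items():
            excl = f", {r.n_excluded} excluded" if r.n_excluded else ""
            lines.append(f"- {name}: b = {r.b:+.3g}, p = {r.p_value:.3g} "
                         f"(n = {r.n}{excl})")
        if self.elastic_regression is not None:
            e = self.elastic_regression
            lines.append("")
            lines.append(f"## Elastic regression (depleted arm): "
                         f"alpha_e = {e.a:.3g}·K^{e.b:+.3g} "
                         f"(p = {e.p_value:.3g}, n = {e.n})")
        lines.append("")
        lines.append("## Direction expectations")
        for name, ok in self.expectations.items():
            lines.append(f"- {name}: {'yes' if ok else 'no'}")
        return "\n".join(lines)


def _benjamini_hochberg(pvals: dict[str, float]) -> dict[str, float]:
    names = list(pvals)
    p = np.array([pvals[n] for n in names])
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return {n: float(a) for n, a in zip(names, adj)}


def _try_regress(name: str, x, y, out: dict, func=regress_power) -> None:
    try:
        out[name] = func(x, y)
    except ValueError as err:
        logger.warning("regression %s skipped: %s", name, err)


def run_cohort_analysis(records: list[CellRecord], dt_eval: float = 3.0,
                        bh_correct: bool = False) -> CohortReport:
    """Full paired-cohort analysis.

    Fits the elastic regression on the depleted arm, recomputes each
    record's thermo state (decomposing active-arm α into α_e + α_work with
    that regression), runs the paired t-tests on the cell_id intersection of
    the two arms, and computes the per-arm power-law regressions.  Supports
    partially paired cohorts: unpaired cells are excluded from the paired
    tests (with a log message) but still enter the per-arm regressions; the
    report states the overlap.  Fewer than 3 pairs disables the paired tests
    (single-arm degraded mode) — the per-arm regressions are still produced.
    """
    active = {r.cell_id: r for r in records if r.condition == "active"}
    depleted = {r.cell_id: r for r in records if r.condition == "depleted"}
    if len(active) + len(depleted) != len(records):
        raise ValueError("conditions must be 'active' or 'depleted', one "
                         "record per cell per condition")

    reg = None
    if len(depleted) >= 3:
        reg = fit_elastic_regression(
            [r.diffusion.k_alpha for r in depleted.values()],
            [r.diffusion.alpha for r in depleted.values()])

    # depleted cells evaluated with their own-arm regression give
    # alpha_work ~ 0 up to residuals, a useful self-consistency readout
    for r in records:
        r.thermo = thermo_state(r.diffusion.k_alpha, r.diffusion.alpha,
                                dt=dt_eval, reg=reg)

    paired_ids = sorted(set(active) & set(depleted))
    unpaired = (set(active) | set(depleted)) - set(paired_ids)
    if unpaired:
        logger.info("%d unpaired cell(s) excluded from paired tests: %s",
                    len(unpaired), sorted(unpaired))

    paired_tests: dict[str, PairedTestResult] = {}
    if len(paired_ids) >= 3:
        for name, get in (("k_alpha", lambda r: r.diffusion.k_alpha),
                          ("alpha", lambda r: r.diffusion.alpha),
                          ("entropy", lambda r: r.thermo.entropy)):
            paired_tests[name] = paired_compare(
                [get(depleted[c]) for c in paired_ids],
                [get(active[c]) for c in paired_ids])
    else:
        logger.warning("fewer than 3 pairs: paired tests skipped")

    regressions: dict[str, PowerRegression] = {}
    for arm_name, arm in (("active", active), ("depleted", depleted)):
        cells = list(arm.values())
        if len(cells) < 3:
            continue
        k = [r.diffusion.k_alpha for r in cells]
        a = [r.diffusion.alpha for r in cells]
        s = [r.thermo.entropy for r in cells]
        _try_regress(f"alpha_vs_k_{arm_name}", k, a, regressions)
        if all(r.homogeneity is not None for r in cells):
            cv = [r.homogeneity.cv for r in cells]
            _try_regress(f"cv_vs_k_{arm_name}", k, cv, regressions)
            _try_regress(f"cv_vs_alpha_{arm_name}", a, cv, regressions)
            _try_regress(f"cv_vs_entropy_{arm_name}", s, cv, regressions,
                         func=regress_exponential)
            if arm_name == "active" and reg is not None:
                aw = [r.thermo.alpha_work for r in cells]
                # log-log form: cells with non-positive alpha_work excluded
                _try_regress("cv_vs_alpha_work_active", aw, cv, regressions)

    expectations: dict[str, bool] = {}
    if paired_tests:
        for name in ("k_alpha", "alpha", "entropy"):
            t = paired_tests[name]
            expectations[f"active_{name}_larger"] = bool(
                (not t.degenerate) and t.mean_difference > 0
                and t.p_value <= SIGNIFICANCE)
    if "alpha_vs_k_depleted" in regressions:
        expectations["negative_alpha_k_relation_depleted"] = \
            regressions["alpha_vs_k_depleted"].significant_negative
    active_neg = [f"cv_vs_{v}_active" for v in ("k", "alpha_work", "entropy")]
    depleted_null = [f"cv_vs_{v}_depleted" for v in ("k", "entropy")]
    if all(n in regressions for n in active_neg + depleted_null):
        expectations["cv_couplings_negative_active_only"] = bool(
            all(regressions[n].significant_negative for n in active_neg)
            and not any(regressions[n].significant_negative
                        for n in depleted_null))

    adjusted = {}
    if bh_correct and regressions:
        adjusted = _benjamini_hochberg(
            {k: v.p_value for k, v in regressions.items()})

    return CohortReport(n_pairs=len(paired_ids), n_active=len(active),
                        n_depleted=len(depleted), paired_tests=paired_tests,
                        regressions=regressions, elastic_regression=reg,
                        expectations=expectations, adjusted_p=adjusted)
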
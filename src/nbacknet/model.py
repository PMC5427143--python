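"""Group-level analysis as a fitted-model interface.

:class:`NBackNetworkModel` holds the cohort data (trial-wise ROI power
or precomputed connectivity, plus behavior) together with the analysis
configuration; :meth:`NBackNetworkModel.fit` runs the full pipeline -
connectivity, sparsity sweep, graph metrics, surrogate normalization,
sparsity integration, paired statistics, FDR screening and
brain-behavior correlations - and returns a
:class:`NBackNetworkResults` carrying the estimates, their test
statistics and a text ``summary()``.

Two analysis profiles are built in: ``"full"`` mirrors the reference
protocol (sparsity 10-50% in 1% steps, 100 surrogates per network);
``"fast"`` thins this to 5% steps and 20 surrogates for simulation
studies where thousands of networks are analyzed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .metrics import GLOBAL_METRIC_NAMES, betweenness_centrality, global_metrics
from .network import (
    BANDS,
    CONDITIONS,
    ConnectivityMatrix,
    SparsityGrid,
    pearson_connectivity,
    sweep_sparsity,
)
from .nulls import normalized_small_world_metrics, surrogate_ensemble
from .stats import (
    MetricCurve,
    bh_fdr,
    integrate_over_sparsity,
    paired_t_test,
    pearson_correlation_with_p,
)
from .synthetic import SyntheticCohort

__all__ = ["PROFILES", "NBackNetworkModel", "NBackNetworkResults",
           "run_group_pipeline"]

PROFILES = {
    "full": {"sparsity_step": 0.01, "n_surrogates": 100, "swap_factor": 10},
    "fast": {"sparsity_step": 0.05, "n_surrogates": 20, "swap_factor": 5},
}

_BEHAVIOR_VARS = ("rt_target_ms", "rt_nontarget_ms",
                  "acc_target", "acc_nontarget")


@dataclass
class _Cell:
    """One (subject, condition, band) connectivity matrix."""

    subject_id: str
    condition: str
    band: str
    connectivity: ConnectivityMatrix


class NBackNetworkModel:
    """Band-specific network comparison between 0-back and 2-back.

    Parameters
    ----------
    cohort
        A :class:`~nbacknet.synthetic.SyntheticCohort` or a cohort
        directory (``sub-*/{0back,2back}/{theta,alpha}_power.tsv`` plus
        ``behavior.tsv``).
    profile
        ``"full"`` or ``"fast"``; sets the sparsity grid and surrogate
        count unless overridden explicitly.
    ranking
        Edge ranking for proportional thresholding, ``"absolute"``
        (default) or ``"signed"``.
    rt_mode
        Which reaction time enters the brain-behavior correlations:
        ``"combined"`` (mean of target and non-target, default),
        ``"target"`` or ``"nontarget"``.
    """

    def __init__(
        self,
        cohort,
        *,
        profile: str = "full",
        grid: SparsityGrid | None = None,
        n_surrogates: int | None = None,
        ranking: str = "absolute",
        swap_factor: int | None = None,
        surrogate_connectivity: str = "final",
        global_alpha: float = 0.05,
        nodal_alpha: float = 0.01,
        fdr_q: float = 0.05,
        gamma_threshold: float = 1.5,
        lambda_tolerance: float = 0.15,
        rt_mode: str = "combined",
        include_nodal: bool = True,
        include_behavior: bool = True,
    ) -> None:
        if profile not in PROFILES:
            raise ValueError(f"unknown profile {profile!r}")
        if rt_mode not in ("combined", "target", "nontarget"):
            raise ValueError(f"unknown rt_mode {rt_mode!r}")
        spec = PROFILES[profile]
        self.profile = profile
        self.grid = grid or SparsityGrid.from_step(step=spec["sparsity_step"])
        self.n_surrogates = n_surrogates or spec["n_surrogates"]
        self.ranking = ranking
        self.swap_factor = swap_factor or spec["swap_factor"]
        self.surrogate_connectivity = surrogate_connectivity
        self.global_alpha = global_alpha
        self.nodal_alpha = nodal_alpha
        self.fdr_q = fdr_q
        self.gamma_threshold = gamma_threshold
        self.lambda_tolerance = lambda_tolerance
        self.rt_mode = rt_mode
        self.include_nodal = include_nodal
        self.include_behavior = include_behavior
        self._cells, self.behavior, self.subject_ids = self._ingest(cohort)
        if self.behavior is None or self.behavior.empty:
            self.include_behavior = False

    # ------------------------------------------------------------------
    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort, **kwargs):
        return cls(cohort, **kwargs)

    @classmethod
    def from_directory(cls, path: str | Path, **kwargs):
        return cls(Path(path), **kwargs)

    # ------------------------------------------------------------------
    @staticmethod
    def _ingest(cohort):
        if isinstance(cohort, (str, Path)):
            cohort = SyntheticCohort.from_directory(cohort)
        if not isinstance(cohort, SyntheticCohort):
            raise TypeError(
                "cohort must be a SyntheticCohort or a cohort directory"
            )
        cells: dict[tuple, _Cell] = {}
        incomplete = []
        for sub in cohort.subjects:
            missing = [
                (c, b)
                for c in CONDITIONS
                for b in BANDS
                if (c, b) not in sub.power
            ]
            if missing:
                incomplete.append((sub.subject_id, missing))
                continue
            for c in CONDITIONS:
                for b in BANDS:
                    cm = pearson_connectivity(sub.power[(c, b)])
                    cells[(sub.subject_id, c, b)] = _Cell(
                        sub.subject_id, c, b, cm
                    )
        if incomplete:
            raise ValueError(
                f"incomplete condition x band data for subjects: {incomplete}"
            )
        subject_ids = [s.subject_id for s in cohort.subjects]
        if len(subject_ids) < 3:
            raise ValueError("at least 3 complete subjects are required")
        return cells, cohort.behavior_frame(), subject_ids

    # ------------------------------------------------------------------
    def _cell_curves(self, cell: _Cell, seed: int):
        """Global metric curves and integrated nodal betweenness."""
        ensemble = sweep_sparsity(cell.connectivity, self.grid, self.ranking)
        n_grid = len(self.grid)
        curves = {name: np.empty(n_grid) for name in GLOBAL_METRIC_NAMES}
        n_rois = cell.connectivity.n_rois
        nodal = np.empty((n_grid, n_rois)) if self.include_nodal else None
        rng = substream(seed, cell.subject_id, cell.condition, cell.band,
                        "surrogates")
        for k, net in enumerate(ensemble.networks):
            gm = global_metrics(net)
            if not np.isfinite(gm.L):
                raise ValueError(
                    "disconnected network at sparsity "
                    f"{net.sparsity} for {cell.subject_id}/"
                    f"{cell.condition}/{cell.band}; path-based metrics "
                    "are undefined"
                )
            surr = surrogate_ensemble(
                net, self.n_surrogates, rng,
                swap_factor=self.swap_factor,
                connectivity=self.surrogate_connectivity,
            )
            norm = normalized_small_world_metrics(
                gm, surr, self.gamma_threshold, self.lambda_tolerance
            )
            curves["C"][k] = gm.C
            curves["L"][k] = gm.L
            curves["gamma"][k] = norm.gamma
            curves["lambda"][k] = norm.lambda_
            curves["sigma"][k] = norm.sigma
            curves["E_local"][k] = gm.E_local
            curves["E_global"][k] = gm.E_global
            if nodal is not None:
                nodal[k] = betweenness_centrality(net)
        if nodal is None:
            nodal_int = None
        else:
            nodal_int = np.trapezoid(nodal, self.grid.values, axis=0)
        return curves, nodal_int

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0, verbose: bool = False) -> "NBackNetworkResults":
        """Run the pipeline and return the fitted results object."""
        grid_values = self.grid.values
        curve_rows, int_rows, nodal_rows = [], [], []
        roi_labels: list[str] | None = None
        for key in sorted(self._cells):
            cell = self._cells[key]
            curves, nodal_int = self._cell_curves(cell, seed)
            if roi_labels is None:
                roi_labels = list(cell.connectivity.roi_labels)
            for name in GLOBAL_METRIC_NAMES:
                for s, v in zip(grid_values, curves[name]):
                    curve_rows.append(
                        (cell.subject_id, cell.condition, cell.band,
                         name, s, v)
                    )
                integrated = integrate_over_sparsity(
                    MetricCurve(name, grid_values, curves[name],
                                cell.subject_id, cell.condition, cell.band)
                )
                int_rows.append(
                    (cell.subject_id, cell.condition, cell.band, name,
                     integrated.value)
                )
            if nodal_int is not None:
                for roi, v in zip(roi_labels, nodal_int):
                    nodal_rows.append(
                        (cell.subject_id, cell.condition, cell.band, roi, v)
                    )
            if verbose:
                print(f"processed {key}")
        curves_df = pd.DataFrame(
            curve_rows,
            columns=["subject", "condition", "band", "metric", "sparsity",
                     "value"],
        )
        integrated_df = pd.DataFrame(
            int_rows,
            columns=["subject", "condition", "band", "metric", "value"],
        )
        nodal_df = pd.DataFrame(
            nodal_rows,
            columns=["subject", "condition", "band", "roi", "value"],
        )
        global_tests = self._global_tests(integrated_df)
        nodal_tests = self._nodal_tests(nodal_df) if self.include_nodal \
            else _empty_nodal_tests()
        if self.include_behavior:
            behavior_tests = self._behavior_tests()
            correlations = self._correlations(integrated_df, nodal_df,
                                              global_tests, nodal_tests)
        else:
            behavior_tests = pd.DataFrame(
                columns=["variable", "mean_0back", "sd_0back", "mean_2back",
                         "sd_2back", "t", "df", "p"]
            )
            correlations = pd.DataFrame(
                columns=["band", "metric", "behavioral_variable",
                         "r", "n", "p"]
            )
        return NBackNetworkResults(
            model=self,
            seed=seed,
            curves=curves_df,
            integrated=integrated_df,
            nodal_integrated=nodal_df,
            global_tests=global_tests,
            nodal_tests=nodal_tests,
            behavior_tests=behavior_tests,
            correlations=correlations,
            roi_labels=roi_labels or [],
        )

    # ------------------------------------------------------------------
    def _paired_wide(self, df: pd.DataFrame, key: str) -> pd.DataFrame:
        """0-back/2-back columns per (band, key, subject), one reshape."""
        wide = df.set_index(["band", key, "subject", "condition"])["value"] \
            .unstack("condition")
        return wide

    def _global_tests(self, integrated: pd.DataFrame) -> pd.DataFrame:
        wide = self._paired_wide(integrated, "metric")
        rows = []
        for band in BANDS:
            for metric in GLOBAL_METRIC_NAMES:
                sub = wide.loc[(band, metric)].loc[self.subject_ids]
                res = paired_t_test(sub["0back"], sub["2back"], metric)
                rows.append(
                    {"band": band, "metric": metric, "t": res.t,
                     "df": res.df, "p": res.p, "mean_diff": res.mean_diff,
                     "significant": res.p < self.global_alpha}
                )
        return pd.DataFrame(rows)

    def _nodal_tests(self, nodal: pd.DataFrame) -> pd.DataFrame:
        wide = self._paired_wide(nodal, "roi")
        frames = []
        for band in BANDS:
            sub = wide.loc[band]
            rois = sub.index.get_level_values("roi").unique()
            rows = []
            for roi in rois:
                grp = sub.loc[roi].loc[self.subject_ids]
                res = paired_t_test(grp["0back"], grp["2back"], roi)
                rows.append(
                    {"band": band, "roi": roi, "t": res.t, "df": res.df,
                     "p": res.p, "mean_diff": res.mean_diff}
                )
            frame = pd.DataFrame(rows)
            fdr = bh_fdr(frame["p"].to_numpy(), self.fdr_q)
            frame["significant"] = frame["p"] < self.nodal_alpha
            frame["fdr_significant"] = fdr.rejected
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)

    def _behavior_tests(self) -> pd.DataFrame:
        rows = []
        beh = self.behavior.set_index(["subject", "condition"])
        for var in _BEHAVIOR_VARS:
            a = beh.loc[[(s, "0back") for s in self.subject_ids], var]
            b = beh.loc[[(s, "2back") for s in self.subject_ids], var]
            res = paired_t_test(a.to_numpy(), b.to_numpy(), var)
            rows.append(
                {"variable": var, "mean_0back": float(a.mean()),
                 "sd_0back": float(a.std(ddof=1)),
                 "mean_2back": float(b.mean()),
                 "sd_2back": float(b.std(ddof=1)),
                 "t": res.t, "df": res.df, "p": res.p}
            )
        return pd.DataFrame(rows)

    def _pooled_behavior(self) -> pd.DataFrame:
        """Subject x condition behavioral observations (n = 2 subjects)."""
        beh = self.behavior.copy()
        if self.rt_mode == "combined":
            beh["rt"] = (beh["rt_target_ms"] + beh["rt_nontarget_ms"]) / 2.0
        elif self.rt_mode == "target":
            beh["rt"] = beh["rt_target_ms"]
        else:
            beh["rt"] = beh["rt_nontarget_ms"]
        beh["accuracy"] = (beh["acc_target"] + beh["acc_nontarget"]) / 2.0
        return beh.set_index(["subject", "condition"])[["rt", "accuracy"]]

    def _correlations(self, integrated, nodal, global_tests,
                      nodal_tests) -> pd.DataFrame:
        """Behavior correlations, gated on a significant group difference.

        Only metrics (global, at ``global_alpha``) and regions (nodal,
        at ``nodal_alpha`` uncorrected) whose 0-back/2-back contrast is
        significant enter; observations are pooled over subject x
        condition.
        """
        pooled = self._pooled_behavior()
        index = [(s, c) for s in self.subject_ids for c in CONDITIONS]
        rows = []

        def correlate(values: pd.Series, band: str, metric: str):
            x = values.loc[index].to_numpy()
            for var in ("rt", "accuracy"):
                y = pooled.loc[index, var].to_numpy()
                res = pearson_correlation_with_p(x, y)
                rows.append(
                    {"band": band, "metric": metric,
                     "behavioral_variable": var, "r": res.r, "n": res.n,
                     "p": res.p}
                )

        for _, test in global_tests[global_tests.significant].iterrows():
            sub = integrated[(integrated.band == test.band)
                             & (integrated.metric == test.metric)]
            correlate(sub.set_index(["subject", "condition"])["value"],
                      test.band, test.metric)
        for _, test in nodal_tests[nodal_tests.significant].iterrows():
            sub = nodal[(nodal.band == test.band) & (nodal.roi == test.roi)]
            correlate(sub.set_index(["subject", "condition"])["value"],
                      test.band, f"betweenness[{test.roi}]")
        return pd.DataFrame(
            rows, columns=["band", "metric", "behavioral_variable",
                           "r", "n", "p"]
        )

    # ------------------------------------------------------------------
    def config_echo(self) -> dict:
        return {
            "profile": self.profile,
            "sparsity_grid": [float(s) for s in self.grid.values],
            "n_surrogates": self.n_surrogates,
            "ranking": self.ranking,
            "swap_factor": self.swap_factor,
            "surrogate_connectivity": self.surrogate_connectivity,
            "global_alpha": self.global_alpha,
            "nodal_alpha": self.nodal_alpha,
            "fdr_q": self.fdr_q,
            "gamma_threshold": self.gamma_threshold,
            "lambda_tolerance": self.lambda_tolerance,
            "rt_mode": self.rt_mode,
            "n_subjects": len(self.subject_ids),
        }


@dataclass
class NBackNetworkResults:
    """Everything the fitted group analysis produced."""

    model: NBackNetworkModel
    seed: int
    curves: pd.DataFrame
    integrated: pd.DataFrame
    nodal_integrated: pd.DataFrame
    global_tests: pd.DataFrame
    nodal_tests: pd.DataFrame
    behavior_tests: pd.DataFrame
    correlations: pd.DataFrame
    roi_labels: list[str]

    # ------------------------------------------------------------------
    def summary(self) -> str:
        lines = []
        m = self.model
        lines.append("Band-specific functional network comparison "
                     "(0-back vs 2-back)")
        lines.append("=" * 66)
        lines.append(
            f"subjects: {len(m.subject_ids)}   profile: {m.profile}   "
            f"grid: {m.grid.values[0]:.2f}-{m.grid.values[-1]:.2f} "
            f"({len(m.grid)} points)   surrogates: {m.n_surrogates}   "
            f"seed: {self.seed}"
        )
        lines.append("")
        lines.append("Behavioral manipulation check (paired t, "
                     f"df={len(m.subject_ids) - 1})")
        lines.append("-" * 66)
        for _, r in self.behavior_tests.iterrows():
            lines.append(
                f"  {r.variable:<16} 0-back {r.mean_0back:8.2f} +/- "
                f"{r.sd_0back:6.2f}   2-back {r.mean_2back:8.2f} +/- "
                f"{r.sd_2back:6.2f}   t={r.t:7.2f}  p={r.p:.3g}"
            )
        for band in BANDS:
            lines.append("")
            lines.append(f"Integrated global metrics, {band} band "
                         f"(paired t, alpha={m.global_alpha})")
            lines.append("-" * 66)
            sub = self.global_tests[self.global_tests.band == band]
            for _, r in sub.iterrows():
                star = " *" if r.significant else ""
                lines.append(
                    f"  {r.metric:<9} t={r.t:7.3f}  p={r.p:7.4f}  "
                    f"diff(2b-0b)={r.mean_diff:+.4f}{star}"
                )
            nd = self.nodal_tests[(self.nodal_tests.band == band)
                                  & self.nodal_tests.significant]
            if len(nd):
                lines.append(f"  betweenness, p<{m.nodal_alpha} "
                             "(+ = FDR-significant):")
                for _, r in nd.iterrows():
                    mark = "+" if r.fdr_significant else " "
                    lines.append(
                        f"    {mark} {r.roi:<12} t={r.t:7.3f}  p={r.p:.4f}"
                    )
            else:
                lines.append(f"  no regions at p<{m.nodal_alpha}")
        lines.append("")
        lines.append("Brain-behavior correlations "
                     "(pooled subject x condition)")
        lines.append("-" * 66)
        if len(self.correlations):
            for _, r in self.correlations.iterrows():
                lines.append(
                    f"  {r.band:<6} {r.metric:<22} ~ "
                    f"{r.behavioral_variable:<9} r={r.r:+.3f}  "
                    f"p={r.p:.3f}  n={r.n}"
                )
        else:
            lines.append("  (no metric passed the significance gate)")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def save(self, outdir: str | Path) -> Path:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.global_tests.to_csv(out / "global_stats.tsv", sep="\t",
                                 index=False)
        self.nodal_tests.to_csv(out / "nodal_stats.tsv", sep="\t",
                                index=False)
        self.behavior_tests.to_csv(out / "behavior_stats.tsv", sep="\t",
                                   index=False)
        self.correlations.to_csv(out / "correlations.tsv", sep="\t",
                                 index=False)
        self.integrated.to_csv(out / "integrated_metrics.tsv", sep="\t",
                               index=False)
        self.nodal_integrated.to_csv(out / "integrated_betweenness.tsv",
                                     sep="\t", index=False)
        self.curves.to_csv(out / "metric_curves.tsv", sep="\t", index=False)
        report = {
            "config": self.model.config_echo(),
            "seed": self.seed,
            "summary": self.summary(),
        }
        (out / "report.json").write_text(json.dumps(report, indent=2))
        return out

    # ------------------------------------------------------------------
    def plot_metric_curves(self, metric: str, band: str, ax=None):
        """Mean +/- SD of one metric across sparsity, per condition."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sub = self.curves[(self.curves.metric == metric)
                          & (self.curves.band == band)]
        for condition in CONDITIONS:
            g = sub[sub.condition == condition].groupby("sparsity")["value"]
            mean, sd = g.mean(), g.std(ddof=1)
            ax.errorbar(mean.index, mean.to_numpy(), yerr=sd.to_numpy(),
                        label=condition, capsize=2)
        ax.set_xlabel("sparsity")
        ax.set_ylabel(metric)
        ax.set_title(f"{metric}, {band} band")
        ax.legend()
        return ax

    def plot_integrated(self, band: str, ax=None):
        """Bar chart of integrated global metrics per condition."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sub = self.integrated[self.integrated.band == band]
        width = 0.38
        x = np.arange(len(GLOBAL_METRIC_NAMES))
        for k, condition in enumerate(CONDITIONS):
            g = sub[sub.condition == condition].groupby("metric")["value"]
            mean = g.mean().loc[list(GLOBAL_METRIC_NAMES)]
            sem = (g.std(ddof=1) / np.sqrt(g.count())) \
                .loc[list(GLOBAL_METRIC_NAMES)]
            ax.bar(x + (k - 0.5) * width, mean.to_numpy(), width,
                   yerr=sem.to_numpy(), label=condition, capsize=2)
        ax.set_xticks(x, GLOBAL_METRIC_NAMES)
        ax.set_ylabel("integrated value")
        ax.set_title(f"integrated global metrics, {band} band")
        ax.legend()
        return ax


def _empty_nodal_tests() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["band", "roi", "t", "df", "p", "mean_diff",
                 "significant", "fdr_significant"]
    )


def run_group_pipeline(cohort, seed: int = 0,
                       **kwargs) -> NBackNetworkResults:
    """One-call convenience wrapper: build the model and fit it."""
    return NBackNetworkModel(cohort, **kwargs).fit(seed=seed)
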
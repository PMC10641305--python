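"""Variance-decomposition synchrony statistics.

Built on the four-component random-effects survival model: the intra-class
correlation coefficient (ICC) per species-by-stream combination,

    ICC[j,s] = (s2_t + s2_j + s2_s) / (s2_t + s2_j + s2_s + s2_js),

the synchronous variance contributed by an environmental covariate
(s2_cov = variance over intervals of beta * x_t) with its share of
synchronous variation s2_cov / (s2_cov + s2_t), and pairwise Pearson
correlations of the posterior-mean survival series within and between
streams.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .inference import PosteriorSamples, DICResult, summarize_survival_series


def plug_in_icc(sigma2_t, sigma2_j, sigma2_s, sigma2_js) -> float:
    """ICC from point estimates of the four variance components."""
    shared = float(sigma2_t) + float(sigma2_j) + float(sigma2_s)
    total = shared + float(sigma2_js)
    if total == 0:
        warnings.warn("all variance components zero: ICC degenerate, set to 1",
                      stacklevel=2)
        return 1.0
    return shared / total


@dataclasses.dataclass(eq=False)
class ICCTable:
    """Posterior-summary ICC per (species, stream), plus the per-draw array."""

    table: pd.DataFrame  # species, stream, mean, lower, upper, plug_in
    draws: np.ndarray    # (N, J, S)


def compute_icc(sigma2_t, sigma2_j, sigma2_s, sigma2_js,
                species_labels, stream_labels, level: float = 0.95) -> ICCTable:
    """Per-draw ICC summarized by posterior mean and percentile CRI.

    Inputs are aligned draw arrays: sigma2_t (N,), sigma2_j (N, J),
    sigma2_s (N, S), sigma2_js (N, J, S).  A draw where all four components
    are zero gets ICC 1 with a warning (no variance to partition).  The
    ``plug_in`` column applies the formula to the posterior-mean variances.
    """
    s2t = np.asarray(sigma2_t, float)
    s2j = np.asarray(sigma2_j, float)
    s2s = np.asarray(sigma2_s, float)
    s2js = np.asarray(sigma2_js, float)
    shared = s2t[:, None, None] + s2j[:, :, None] + s2s[:, None, :]
    total = shared + s2js
    degenerate = total == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} draws with zero total variance: "
                      f"ICC set to 1", stacklevel=2)
    icc = np.where(degenerate, 1.0, shared / np.where(degenerate, 1.0, total))
    alpha = (1 - level) / 2
    lo, hi = np.quantile(icc, [alpha, 1 - alpha], axis=0)
    mean = icc.mean(axis=0)
    rows = []
    for j, sp in enumerate(species_labels):
        for s, st in enumerate(stream_labels):
            rows.append({
                "species": sp, "stream": st,
                "mean": mean[j, s], "lower": lo[j, s], "upper": hi[j, s],
                "plug_in": plug_in_icc(s2t.mean(), s2j[:, j].mean(),
                                       s2s[:, s].mean(), s2js[:, j, s].mean()),
            })
    return ICCTable(table=pd.DataFrame(rows), draws=icc)


def icc_from_samples(samples: PosteriorSamples, level: float = 0.95) -> ICCTable:
    """ICC table straight from a random-effects model fit."""
    if not samples.spec.uses_random_effects:
        raise ValueError("ICC needs a random-effects model fit")
    return compute_icc(samples.flat("sigma2_t"), samples.flat("sigma2_j"),
                       samples.flat("sigma2_s"), samples.flat("sigma2_js"),
                       samples.species_labels, samples.stream_labels, level)


def covariate_variance(beta_draws, x, ddof: int = 1) -> np.ndarray:
    """Per-draw variance over intervals of beta * x_t (sigma2_cov draws)."""
    beta = np.asarray(beta_draws, float).reshape(-1)
    x = np.asarray(x, float)
    return np.array([np.var(b * x, ddof=ddof) for b in beta])


@dataclasses.dataclass(eq=False)
class CovariateContribution:
    """sigma2_cov draws and the covariate's share of synchronous variation."""

    sigma2_cov: np.ndarray
    proportion: np.ndarray
    summary: dict  # posterior mean + CRI for both quantities

    def to_json(self) -> str:
        return json.dumps(self.summary, indent=2)


def synchrony_proportion(sigma2_cov, sigma2_t,
                         level: float = 0.95) -> CovariateContribution:
    """Per-draw sigma2_cov / (sigma2_cov + sigma2_t), posterior-summarized."""
    s2c = np.asarray(sigma2_cov, float).reshape(-1)
    s2t = np.asarray(sigma2_t, float).reshape(-1)
    if s2c.shape != s2t.shape:
        raise ValueError("sigma2_cov and sigma2_t draws must be aligned")
    denom = s2c + s2t
    zero = denom == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} draws with sigma2_cov + sigma2_t = 0: "
                      f"proportion set to 0", stacklevel=2)
    prop = np.where(zero, 0.0, s2c / np.where(zero, 1.0, denom))
    alpha = (1 - level) / 2

    def summ(v):
        lo, hi = np.quantile(v, [alpha, 1 - alpha])
        return {"mean": float(v.mean()), "lower": float(lo), "upper": float(hi)}

    return CovariateContribution(sigma2_cov=s2c, proportion=prop,
                                 summary={"sigma2_cov": summ(s2c),
                                          "proportion": summ(prop)})


def pairwise_correlations(series: pd.DataFrame) -> pd.DataFrame:
    """Pearson r of survival series for every within-stream species pair and
    every between-stream conspecific pair.

    ``series`` is the posterior-mean survival table (columns species,
    stream, interval, mean).  Two-sided p-values use the t distribution
    with n-2 degrees of freedom.  A constant series yields an undefined r:
    the row is kept with NaN and flagged.
    """
    wide = series.pivot_table(index="interval", columns=["species", "stream"],
                              values="mean", sort=False)
    species = list(dict.fromkeys(series["species"]))
    streams = list(dict.fromkeys(series["stream"]))
    pairs = []
    for st in streams:  # within-stream interspecific
        for a in range(len(species)):
            for b in range(a + 1, len(species)):
                pairs.append((f"{species[a]} vs {species[b]} ({st})",
                              (species[a], st), (species[b], st),
                              "within-stream interspecific"))
    for sp in species:  # between-stream conspecific
        for a in range(len(streams)):
            for b in range(a + 1, len(streams)):
                pairs.append((f"{sp} ({streams[a]}) vs {sp} ({streams[b]})",
                              (sp, streams[a]), (sp, streams[b]),
                              "between-stream conspecific"))
    rows = []
    for label, key_a, key_b, klass in pairs:
        if key_a not in wide.columns or key_b not in wide.columns:
            continue  # combination absent from the series table
        u = wide[key_a].to_numpy()
        v = wide[key_b].to_numpy()
        if np.std(u) == 0 or np.std(v) == 0:
            warnings.warn(f"constant survival series in pair {label}: "
                          f"correlation undefined", stacklevel=2)
            rows.append({"pair": label, "class": klass, "r": np.nan,
                         "p_value": np.nan, "undefined": True})
            continue
        res = stats.pearsonr(u, v)
        rows.append({"pair": label, "class": klass, "r": float(res.statistic),
                     "p_value": float(res.pvalue), "undefined": False})
    return pd.DataFrame(rows)


@dataclasses.dataclass(eq=False)
class SynchronyReport:
    """Bundle of the synchrony analysis outputs (Table-style artifacts)."""

    icc: pd.DataFrame
    correlations: pd.DataFrame
    contribution: dict | None
    dic: pd.DataFrame | None

    def to_markdown(self) -> str:
        lines = ["# Synchrony report", "",
                 "## Intra-class correlation coefficients (posterior mean, 95% CRI)",
                 "", self.icc.round(3).to_markdown(index=False), ""]
        if self.correlations is not None and len(self.correlations):
            lines += ["## Pairwise Pearson correlations of survival series", "",
                      self.correlations.round(3).to_markdown(index=False), ""]
        if self.contribution is not None:
            c = self.contribution
            lines += ["## Covariate contribution to synchronous variation", ""]
            lines += [f"- sigma2_cov: {c['sigma2_cov']['mean']:.3f} "
                      f"({c['sigma2_cov']['lower']:.3f}, {c['sigma2_cov']['upper']:.3f})"]
            lines += [f"- proportion sigma2_cov/(sigma2_cov+sigma2_t): "
                      f"{c['proportion']['mean']:.3f} "
                      f"({c['proportion']['lower']:.3f}, {c['proportion']['upper']:.3f})"]
            lines += [""]
        if self.dic is not None and len(self.dic):
            lines += ["## Model comparison (DIC)", "",
                      self.dic.round(1).to_markdown(index=False), ""]
        lines += ["Note: the final survival interval is confounded with final-"
                  "occasion detection in any CJS model; treat the last interval "
                  "with caution.", ""]
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        import pathlib
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.icc.to_csv(out / "icc.csv", index=False)
        (self.correlations if self.correlations is not None else pd.DataFrame()
         ).to_csv(out / "correlations.csv", index=False)
        (out / "contribution.json").write_text(
            json.dumps(self.contribution or {}, indent=2))
        (self.dic if self.dic is not None else pd.DataFrame()
         ).to_csv(out / "dic.csv", index=False)
        (out / "report.md").write_text(self.to_markdown())

    @classmethod
    def load(cls, in_dir) -> "SynchronyReport":
        import pathlib
        src = pathlib.Path(in_dir)
        contribution = json.loads((src / "contribution.json").read_text())
        dic = pd.read_csv(src / "dic.csv")
        return cls(icc=pd.read_csv(src / "icc.csv"),
                   correlations=pd.read_csv(src / "correlations.csv"),
                   contribution=contribution or None,
                   dic=dic if len(dic) else None)


def build_synchrony_report(icc: ICCTable,
                           contribution: CovariateContribution | None,
                           correlations: pd.DataFrame | None,
                           dic_set: dict | None = None) -> SynchronyReport:
    """Assemble the report from one consistent run's pieces.

    ``dic_set`` maps model labels (e.g. 'intercept_only',
    'random_effects', 'random_effects_plus_covariate') to DICResult.
    """
    dic_df = None
    if dic_set:
        dic_df = pd.DataFrame([
            {"model": k, "mean_deviance": v.mean_deviance, "p_d": v.p_d,
             "dic": v.dic}
            for k, v in dic_set.items()]).sort_values("dic").reset_index(drop=True)
    return SynchronyReport(
        icc=icc.table,
        correlations=correlations if correlations is not None else pd.DataFrame(),
        contribution=contribution.summary if contribution is not None else None,
        dic=dic_df)


def survival_series_for_correlation(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior-mean survival series used by the correlation analysis."""
    return summarize_survival_series(samples)
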
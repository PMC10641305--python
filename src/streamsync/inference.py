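"""Posterior sampling, convergence diagnostics, DIC and survival summaries.

The sampler draws from the posterior proportional to (marginalized CJS
likelihood x diffuse priors) for any model variant.  Per-draw deviance
(-2 log-likelihood, conditional on the random effects) is recorded for
DIC.  Convergence is assessed with the split-chain Gelman-Rubin potential
scale reduction factor, with the conventional R-hat < 1.1 pass mark.
"""

from __future__ import annotations

import dataclasses
import json
import math
import re
import warnings

import numpy as np
import pandas as pd

from . import _kernels
from .cjs import ModelSpec
from .data_model import CaptureHistoryMatrix


@dataclasses.dataclass(frozen=True)
class MCMCSettings:
    """Desk-scale defaults; the study-scale equivalent (3 x 250k, thin 10)
    is available by overriding fields."""

    chains: int = 3
    iterations: int = 4000
    burn_in: int = 1000
    thin: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.chains < 2:
            raise ValueError("need >= 2 chains for R-hat")

    @property
    def n_store(self) -> int:
        return -(-(self.iterations - self.burn_in) // self.thin)

    @classmethod
    def synchrony_default(cls, seed: int = 0) -> "MCMCSettings":
        """Longer desk-scale run for the hierarchical synchrony models,
        whose random effects mix more slowly than the covariate models
        (the same reason the field analyses run their synchrony models
        longer)."""
        return cls(chains=3, iterations=20000, burn_in=5000, thin=5, seed=seed)


@dataclasses.dataclass(eq=False)
class PosteriorSamples:
    """Named posterior draws with shape (chains, draws, *param shape).

    Keys: mu (J,S), beta (NB,), eps1 (T-1,), eps2 (J,T-1), eps3 (S,T-1),
    eps4 (J,S,T-1), sigma2_t (), sigma2_j (J,), sigma2_s (S,),
    sigma2_js (J,S), p (J,S,T-1); plus per-draw deviance.
    """

    params: dict
    deviance: np.ndarray
    spec: ModelSpec
    species_labels: tuple
    stream_labels: tuple
    n_days: np.ndarray
    x: np.ndarray | None
    settings: MCMCSettings
    model_data: dict | None = None

    @property
    def n_chains(self) -> int:
        return self.deviance.shape[0]

    @property
    def n_draws(self) -> int:
        return self.deviance.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """Draws pooled over chains: shape (chains*draws, *param shape)."""
        a = self.params[name]
        return a.reshape((-1,) + a.shape[2:])

    def active_names(self) -> list:
        """Parameter keys actually sampled under this model variant."""
        names = ["mu", "p"]
        if self.spec.uses_covariate:
            names.append("beta")
        if self.spec.uses_random_effects:
            names += ["eps1", "eps2", "eps3", "eps4",
                      "sigma2_t", "sigma2_j", "sigma2_s", "sigma2_js"]
        return names

    def iter_scalars(self):
        """Yield (label, (chains, draws) array) for every sampled scalar."""
        for name in self.active_names():
            a = self.params[name]
            shape = a.shape[2:]
            if shape == ():
                yield name, a
                continue
            for idx in np.ndindex(*shape):
                label = name + "[" + ",".join(str(i) for i in idx) + "]"
                yield label, a[(slice(None), slice(None)) + idx]
        yield "deviance", self.deviance

    # -- persistence ----------------------------------------------------

    def save(self, out_dir) -> None:
        """Write long-format draws CSV plus a JSON run manifest."""
        import pathlib
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frames = []
        C, D = self.n_chains, self.n_draws
        chain_col = np.repeat(np.arange(1, C + 1), D)
        iter_col = np.tile(np.arange(1, D + 1), C)
        for label, arr in self.iter_scalars():
            frames.append(pd.DataFrame({
                "chain": chain_col, "iteration": iter_col,
                "parameter": label, "value": arr.reshape(-1)}))
        pd.concat(frames, ignore_index=True).to_csv(out / "draws.csv", index=False)
        meta = {
            "variant": self.spec.variant,
            "covariate": self.spec.covariate,
            "scaling_mode": self.spec.scaling_mode,
            "priors": dataclasses.asdict(self.spec.priors),
            "species_labels": list(self.species_labels),
            "stream_labels": list(self.stream_labels),
            "n_days": [int(v) for v in self.n_days],
            "x": None if self.x is None else [float(v) for v in self.x],
            "settings": dataclasses.asdict(self.settings),
        }
        (out / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, in_dir) -> "PosteriorSamples":
        import pathlib
        from .cjs import PriorSpec
        src = pathlib.Path(in_dir)
        meta = json.loads((src / "meta.json").read_text())
        spec = ModelSpec(variant=meta["variant"], covariate=meta["covariate"],
                         scaling_mode=meta["scaling_mode"],
                         priors=PriorSpec(**meta["priors"]))
        settings = MCMCSettings(**meta["settings"])
        draws = pd.read_csv(src / "draws.csv")
        C = int(draws["chain"].max())
        D = int(draws["iteration"].max())
        J = len(meta["species_labels"])
        S = len(meta["stream_labels"])
        Tm1 = len(meta["n_days"])
        shapes = {"mu": (J, S), "beta": (J if spec.beta_per_species else 1,),
                  "eps1": (Tm1,), "eps2": (J, Tm1), "eps3": (S, Tm1),
                  "eps4": (J, S, Tm1), "sigma2_t": (), "sigma2_j": (J,),
                  "sigma2_s": (S,), "sigma2_js": (J, S), "p": (J, S, Tm1)}
        params = {k: np.zeros((C, D) + v) for k, v in shapes.items()}
        deviance = np.zeros((C, D))
        pat = re.compile(r"^(\w+)(?:\[([\d,]+)\])?$")
        for label, sub in draws.groupby("parameter", sort=False):
            name, idx = pat.match(label).groups()
            vals = sub.sort_values(["chain", "iteration"])["value"].to_numpy()
            block = vals.reshape(C, D)
            if name == "deviance":
                deviance = block
            else:
                key = () if idx is None else tuple(int(i) for i in idx.split(","))
                params[name][(slice(None), slice(None)) + key] = block
        return cls(params=params, deviance=deviance, spec=spec,
                   species_labels=tuple(meta["species_labels"]),
                   stream_labels=tuple(meta["stream_labels"]),
                   n_days=np.asarray(meta["n_days"]),
                   x=None if meta["x"] is None else np.asarray(meta["x"]),
                   settings=settings)


def _empirical_p_init(matrix: CaptureHistoryMatrix) -> np.ndarray:
    """Per-group per-occasion recapture fraction (marked animals recaptured
    over marked animals at risk), clipped to (0.05, 0.9)."""
    T = matrix.n_occasions
    G = matrix.index.n_groups
    g_codes = matrix.group_codes()
    fc = matrix.individuals["first_capture"].to_numpy()
    p0 = np.full((G, T - 1), 0.3)
    for g in range(G):
        sel = g_codes == g
        if sel.sum() == 0:
            continue
        y = matrix.detections[sel]
        f = fc[sel]
        for t in range(1, T):
            at_risk = (f <= t).sum()  # marked before occasion t+1 (1-based)
            if at_risk > 0:
                p0[g, t - 1] = np.clip(y[f <= t, t].sum() / at_risk, 0.05, 0.9)
    return p0


def sample_posterior(matrix: CaptureHistoryMatrix, spec: ModelSpec,
                     x: np.ndarray | None = None, calendar=None,
                     settings: MCMCSettings | None = None) -> PosteriorSamples:
    """MCMC draws from the posterior of the requested model variant.

    ``x`` is the standardized per-interval covariate vector (required by
    covariate variants).  Draws are reproducible given ``settings.seed``.
    """
    from .cjs import build_marray

    settings = settings or MCMCSettings()
    cal = calendar if calendar is not None else matrix.calendar
    n_days = cal.n_days.astype(float)
    J, S = matrix.index.n_species, matrix.index.n_streams
    Tm1 = cal.n_occasions - 1
    if spec.uses_covariate:
        if x is None:
            raise ValueError("covariate variant requires a covariate vector x")
        x = np.asarray(x, dtype=float)
        if x.shape != (Tm1,):
            raise ValueError(f"x must have length T-1 = {Tm1}")
        beta_mode = 2 if spec.beta_per_species else 1
    else:
        x = None
        beta_mode = 0
    NB = J if beta_mode == 2 else 1
    use_eps = 1 if spec.uses_random_effects else 0
    nd_exp = (n_days / 60.0 if spec.scaling_mode == "baseline60"
              else np.ones(Tm1))

    m, never = build_marray(matrix)
    gj = np.repeat(np.arange(J), S).astype(np.int64)
    gs = np.tile(np.arange(S), J).astype(np.int64)
    p_init = _empirical_p_init(matrix)
    x_arr = x if x is not None else np.zeros(Tm1)

    C, D = settings.chains, settings.n_store
    pr = spec.priors

    for attempt in range(3):
        ss = np.random.SeedSequence([settings.seed, attempt])
        chain_seeds = (ss.generate_state(C, dtype=np.uint32) % (2 ** 31 - 1)).astype(np.int64)
        jitter = 0.1 * (1 + attempt)  # disperse inits on retry
        out = {k: np.zeros((C, D) + shp) for k, shp in {
            "mu": (J, S), "beta": (NB,), "eps1": (Tm1,), "eps2": (J, Tm1),
            "eps3": (S, Tm1), "eps4": (J, S, Tm1), "sigma2_t": (),
            "sigma2_j": (J,), "sigma2_s": (S,), "sigma2_js": (J, S),
            "p": (J, S, Tm1)}.items()}
        deviance = np.zeros((C, D))
        for c in range(C):
            bufs = {k: np.zeros((D,) + shp) for k, shp in {
                "mu": (J * S,), "beta": (NB,), "eps1": (Tm1,),
                "eps2": (J, Tm1), "eps3": (S, Tm1), "eps4": (J, S, Tm1),
                "s2t": (), "s2j": (J,), "s2s": (S,), "s2js": (J, S),
                "p": (J * S, Tm1), "dev": ()}.items()}
            stored = _kernels.run_chain(
                m, never, gj, gs, nd_exp, x_arr, beta_mode, use_eps,
                pr.mu_sd, pr.beta_sd, pr.sd_upper, p_init,
                settings.iterations, settings.burn_in, settings.thin,
                int(chain_seeds[c]), jitter,
                bufs["mu"], bufs["beta"], bufs["eps1"], bufs["eps2"],
                bufs["eps3"], bufs["eps4"], bufs["s2t"], bufs["s2j"],
                bufs["s2s"], bufs["s2js"], bufs["p"], bufs["dev"])
            if stored != D:
                raise RuntimeError("sampler stored an unexpected draw count")
            out["mu"][c] = bufs["mu"].reshape(D, J, S)
            out["beta"][c] = bufs["beta"]
            out["eps1"][c] = bufs["eps1"]
            out["eps2"][c] = bufs["eps2"]
            out["eps3"][c] = bufs["eps3"]
            out["eps4"][c] = bufs["eps4"]
            out["sigma2_t"][c] = bufs["s2t"]
            out["sigma2_j"][c] = bufs["s2j"]
            out["sigma2_s"][c] = bufs["s2s"]
            out["sigma2_js"][c] = bufs["s2js"]
            out["p"][c] = bufs["p"].reshape(D, J, S, Tm1)
            deviance[c] = bufs["dev"]
        finite = np.isfinite(deviance).all() and all(
            np.isfinite(v).all() for v in out.values())
        if finite:
            return PosteriorSamples(
                params=out, deviance=deviance, spec=spec,
                species_labels=matrix.index.species_labels,
                stream_labels=matrix.index.stream_labels,
                n_days=cal.n_days, x=x, settings=settings,
                model_data={"m": m, "never": never, "gj": gj, "gs": gs,
                            "nd_exp": nd_exp, "beta_mode": beta_mode})
    raise RuntimeError("non-finite posterior after 3 re-initializations")


# ---------------------------------------------------------------------------
# Diagnostics


@dataclasses.dataclass(eq=False)
class ConvergenceReport:
    table: pd.DataFrame  # parameter, rhat, degenerate flag
    threshold: float
    passed: bool

    def worst(self) -> pd.DataFrame:
        return self.table.sort_values("rhat", ascending=False).head(10)


def _split_rhat(x: np.ndarray):
    """Split-chain Gelman-Rubin statistic for one scalar; (C, D) input."""
    C, D = x.shape
    half = D // 2
    if half < 2:
        raise ValueError("need at least 4 draws per chain for split R-hat")
    parts = np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)
    W = parts.var(axis=1, ddof=1).mean()
    if W == 0:
        return 1.0, True
    means = parts.mean(axis=1)
    B = half * means.var(ddof=1)
    var_plus = (half - 1) / half * W + B / half
    return float(math.sqrt(var_plus / W)), False


def compute_rhat(samples: PosteriorSamples,
                 threshold: float = 1.1) -> ConvergenceReport:
    """Split-chain R-hat per sampled scalar; pass iff all below threshold."""
    rows = []
    for label, arr in samples.iter_scalars():
        rhat, degenerate = _split_rhat(arr)
        if degenerate:
            warnings.warn(f"zero-variance parameter {label}: R-hat undefined, "
                          f"reported as 1", stacklevel=2)
        rows.append({"parameter": label, "rhat": rhat, "degenerate": degenerate})
    table = pd.DataFrame(rows)
    return ConvergenceReport(table=table, threshold=threshold,
                             passed=bool((table["rhat"] < threshold).all()))


@dataclasses.dataclass(frozen=True)
class DICResult:
    mean_deviance: float
    p_d: float
    dic: float
    pd_method: str


def compute_dic(samples: PosteriorSamples,
                pd_method: str = "variance") -> DICResult:
    """Deviance information criterion DIC = mean deviance + pD.

    pd_method 'variance' uses pD = var(deviance)/2 (the estimator of the
    BUGS/JAGS lineage); 'mean_diff' uses pD = Dbar - D(posterior mean),
    which needs the in-memory model data and can be negative.  Deviance is
    conditional on the random effects.
    """
    dev = samples.deviance.reshape(-1)
    if dev.size < 2:
        raise ValueError("DIC needs at least 2 draws")
    dbar = float(dev.mean())
    if pd_method == "variance":
        p_d = float(dev.var(ddof=1) / 2.0)
    elif pd_method == "mean_diff":
        if samples.model_data is None:
            raise ValueError("mean_diff pD needs in-memory model data; "
                             "refit or use pd_method='variance'")
        p_d = dbar - _deviance_at_means(samples)
    else:
        raise ValueError(f"unknown pd_method {pd_method!r}")
    return DICResult(mean_deviance=dbar, p_d=p_d, dic=dbar + p_d,
                     pd_method=pd_method)


def _deviance_at_means(samples: PosteriorSamples) -> float:
    md = samples.model_data
    eta = _eta_draws(samples, use_means=True)  # (J, S, Tm1)
    phi = _phi_from_eta(eta, md["nd_exp"])
    J, S, Tm1 = eta.shape
    pbar = samples.flat("p").mean(axis=0)
    ll = _kernels.marray_loglik(md["m"], md["never"],
                                np.ascontiguousarray(phi.reshape(J * S, Tm1)),
                                np.ascontiguousarray(pbar.reshape(J * S, Tm1)))
    return float(-2.0 * ll)


def significance_from_cri(draws, level: float = 0.95):
    """Percentile credible interval; significant iff it excludes zero."""
    d = np.asarray(draws, dtype=float).reshape(-1)
    if d.size < 100:
        raise ValueError("need at least 100 draws for a stable CRI")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(d, [alpha, 1.0 - alpha])
    significant = bool(lo > 0 or hi < 0)
    return significant, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Posterior survival series


def _eta_draws(samples: PosteriorSamples, use_means: bool = False) -> np.ndarray:
    """Linear predictor per draw: (N, J, S, Tm1), or (J, S, Tm1) of means."""
    spec = samples.spec
    Tm1 = len(samples.n_days)

    def get(name):
        a = samples.flat(name)
        return a.mean(axis=0) if use_means else a

    mu = get("mu")  # (..., J, S)
    eta = mu[..., None] * np.ones(Tm1)
    if spec.uses_covariate:
        beta = get("beta")
        x = samples.x
        if spec.beta_per_species:
            bx = beta[..., :, None] * x  # (..., J, Tm1)
            eta = eta + bx[..., :, None, :]
        else:
            bx = beta[..., 0, None] * x  # (..., Tm1)
            eta = eta + bx[..., None, None, :]
    if spec.uses_random_effects:
        eta = (eta + get("eps1")[..., None, None, :]
               + get("eps2")[..., :, None, :]
               + get("eps3")[..., None, :, :]
               + get("eps4"))
    return eta


def _phi_from_eta(eta: np.ndarray, nd_exp: np.ndarray) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-eta))
    return np.clip(s ** nd_exp, 1e-12, 1 - 1e-12)


def survival60_draws(samples: PosteriorSamples) -> np.ndarray:
    """Per-draw 60-day survival (N, J, S, T-1) under the fit's scaling mode."""
    eta = _eta_draws(samples)
    s = 1.0 / (1.0 + np.exp(-eta))
    if samples.spec.scaling_mode == "posthoc":
        s = s ** (60.0 / samples.n_days.astype(float))
    return s


def summarize_survival_series(samples: PosteriorSamples,
                              level: float = 0.95) -> pd.DataFrame:
    """Posterior mean and CRI of 60-day survival per species, stream, interval."""
    s60 = survival60_draws(samples)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(s60, [alpha, 1.0 - alpha], axis=0)
    mean = s60.mean(axis=0)
    rows = []
    for j, sp in enumerate(samples.species_labels):
        for s, st in enumerate(samples.stream_labels):
            for t in range(s60.shape[-1]):
                rows.append({"species": sp, "stream": st, "interval": t + 1,
                             "mean": mean[j, s, t], "lower": lo[j, s, t],
                             "upper": hi[j, s, t]})
    return pd.DataFrame(rows)
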
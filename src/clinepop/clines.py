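"""Allele-frequency cline fitting along a one-dimensional transect.

The cline is the hybrid-zone sigmoid

    p(x) = pMin + (pMax - pMin) / (1 + exp(-4 (x - c) / w)),

parameterized so the width ``w`` is the inverse-maximum-slope width: the
slope at the center ``c`` equals (pMax - pMin) / w, which makes fitted
widths directly comparable across loci in km. Optional exponential tails
(Szymura-Barton form) replace the sigmoid beyond c ± delta on each side,
decaying at rate 4 tau / w and continuous at the junction.

Four models (fixed/free frequency scaling x no tails/tails at both ends)
plus a flat null are fitted per locus to population allele counts by a
binomial likelihood; fitting is random-walk Metropolis, model choice is by
small-sample AICc, and a locus shows a *significant cline* when a non-null
model wins and its log-likelihood clears the configured cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_EPS = 1e-9


# ---------------------------------------------------------------------------
# model family
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClineModelSpec:
    """One member of the cline model family."""

    scaling: str  # 'fixed' | 'free'
    tails: str    # 'none' | 'both'

    def __post_init__(self) -> None:
        if self.scaling not in ("fixed", "free"):
            raise ValueError("scaling must be 'fixed' or 'free'")
        if self.tails not in ("none", "both"):
            raise ValueError("tails must be 'none' or 'both'")

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["center", "width"]
        if self.scaling == "free":
            names += ["p_min", "p_max"]
        if self.tails == "both":
            names += ["delta_l", "tau_l", "delta_r", "tau_r"]
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def name(self) -> str:
        return f"{self.scaling}_{'notails' if self.tails == 'none' else 'tails'}"


MODEL_FAMILY: tuple[ClineModelSpec, ...] = (
    ClineModelSpec("fixed", "none"),
    ClineModelSpec("free", "none"),
    ClineModelSpec("fixed", "both"),
    ClineModelSpec("free", "both"),
)


def cline_frequency(params: dict[str, float], spec: ClineModelSpec,
                    x: np.ndarray | float, p_min: float | None = None,
                    p_max: float | None = None) -> np.ndarray:
    """Expected counted-allele frequency at transect position(s) x (km).

    For ``fixed`` scaling pass the pinned ``p_min``/``p_max`` (the observed
    extreme population frequencies); for ``free`` scaling they live in
    ``params``.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("transect positions must be finite")
    c, w = params["center"], params["width"]
    if w <= 0:
        raise ValueError("width must be > 0")
    if spec.scaling == "free":
        p_min, p_max = params["p_min"], params["p_max"]
    if p_min is None or p_max is None:
        raise ValueError("fixed scaling requires p_min and p_max")
    s = 1.0 / (1.0 + np.exp(np.clip(-4.0 * (x - c) / w, -700, 700)))
    if spec.tails == "both":
        dl, tl = params["delta_l"], params["tau_l"]
        dr, tr = params["delta_r"], params["tau_r"]
        s_l = 1.0 / (1.0 + np.exp(np.clip(4.0 * dl / w, -700, 700)))
        s_r = 1.0 / (1.0 + np.exp(np.clip(-4.0 * dr / w, -700, 700)))
        left = x < c - dl
        right = x > c + dr
        s = np.where(left, s_l * np.exp(np.clip(4.0 * tl * (x - (c - dl)) / w, -700, 0)), s)
        s = np.where(right, 1.0 - (1.0 - s_r) * np.exp(np.clip(-4.0 * tr * (x - (c + dr)) / w, -700, 0)), s)
    return p_min + (p_max - p_min) * s


def cline_loglik(params: dict[str, float], spec: ClineModelSpec,
                 p_hat: np.ndarray, n_alleles: np.ndarray, x: np.ndarray,
                 p_min: float | None = None, p_max: float | None = None) -> float:
    """Binomial log-likelihood of population allele counts under the cline.

    Allele counts are recovered as k = round(p_hat * n); the predicted
    frequency is clamped to [1e-9, 1 - 1e-9]. Populations with n = 0 are
    skipped.
    """
    ok = np.asarray(n_alleles) > 0
    n = np.asarray(n_alleles, dtype=float)[ok]
    k = np.round(np.asarray(p_hat, dtype=float)[ok] * n)
    mu = np.clip(cline_frequency(params, spec, np.asarray(x, dtype=float)[ok],
                                 p_min=p_min, p_max=p_max), _EPS, 1 - _EPS)
    return float(np.sum(k * np.log(mu) + (n - k) * np.log(1 - mu)))


def null_loglik(p_hat: np.ndarray, n_alleles: np.ndarray) -> tuple[float, float]:
    """(pooled frequency, lnL) of the flat one-parameter null model."""
    ok = np.asarray(n_alleles) > 0
    n = np.asarray(n_alleles, dtype=float)[ok]
    k = np.round(np.asarray(p_hat, dtype=float)[ok] * n)
    p0 = float(np.clip(k.sum() / n.sum(), _EPS, 1 - _EPS))
    lnl = float(np.sum(k * np.log(p0) + (n - k) * np.log(1 - p0)))
    return p0, lnl


def saturated_loglik(p_hat: np.ndarray, n_alleles: np.ndarray) -> float:
    """lnL of the saturated model (one free frequency per population)."""
    ok = np.asarray(n_alleles) > 0
    n = np.asarray(n_alleles, dtype=float)[ok]
    k = np.round(np.asarray(p_hat, dtype=float)[ok] * n)
    mu = np.clip(k / n, _EPS, 1 - _EPS)
    return float(np.sum(k * np.log(mu) + (n - k) * np.log(1 - mu)))


def aicc(lnl: float, k: int, n: int) -> float:
    """Small-sample AICc = -2 lnL + 2k + 2k(k+1)/(n - k - 1); NaN if n <= k + 1."""
    if n - k - 1 <= 0:
        return np.nan
    return -2.0 * lnl + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# MCMC fit
# ---------------------------------------------------------------------------

@dataclass
class ClineFitResults:
    """Results of one locus x one model MCMC fit."""

    locus: str
    spec: ClineModelSpec | None     # None for the closed-form null
    params: dict[str, float]        # maximum-lnL point of the trace
    loglik: float
    aicc: float
    trace_quantiles: pd.DataFrame   # per-parameter posterior quantiles
    seed: int
    iterations: int
    burn_in: int
    acceptance_rate: float
    pinned: tuple[float, float] | None = None  # (p_min, p_max) for fixed scaling

    def summary(self) -> str:
        name = self.spec.name if self.spec else "null"
        lines = [f"Cline fit: locus {self.locus}, model {name}",
                 f"  lnL = {self.loglik:.4f}  AICc = {self.aicc:.4f}  "
                 f"accept = {self.acceptance_rate:.2f}"]
        for k, v in self.params.items():
            lines.append(f"  {k} = {v:.4g}")
        return "\n".join(lines)


@dataclass
class _Prior:
    lo: float
    hi: float
    log_scale: bool = False


class ClineModel:
    """Per-locus cline model over population allele frequencies.

    Parameters
    ----------
    p_hat, n_alleles, x
        Population allele frequencies, allele sample sizes (2 x diploids)
        and transect positions in km from the origin.
    spec
        Model family member; ``None`` fits the flat null in closed form.
    """

    def __init__(self, p_hat, n_alleles, x, spec: ClineModelSpec | None,
                 locus: str = ""):
        self.p_hat = np.asarray(p_hat, dtype=float)
        self.n = np.asarray(n_alleles, dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.spec = spec
        self.locus = locus
        ok = self.n > 0
        if ok.sum() < 3:
            raise ValueError("need >= 3 populations with defined frequencies")
        self.span = float(self.x[ok].max() - self.x[ok].min())
        if self.span <= 0:
            raise ValueError("transect span must be positive")
        self.n_pops = int(ok.sum())
        if spec is not None and spec.scaling == "fixed":
            obs = self.p_hat[ok]
            self.pinned = (float(np.min(obs)), float(np.max(obs)))
        else:
            self.pinned = None
        # precomputed per-population data for the MCMC inner loop
        self._n_ok = self.n[ok]
        self._k_ok = np.round(self.p_hat[ok] * self._n_ok)
        self._x_ok = self.x[ok]

    def _lnl(self, params: dict[str, float]) -> float:
        pmin, pmax = (self.pinned if self.pinned else (None, None))
        mu = np.clip(cline_frequency(params, self.spec, self._x_ok,
                                     p_min=pmin, p_max=pmax), _EPS, 1 - _EPS)
        return float(np.sum(self._k_ok * np.log(mu)
                            + (self._n_ok - self._k_ok) * np.log(1 - mu)))

    def _priors(self) -> dict[str, _Prior]:
        lo_x = float(self.x.min()) - 0.5 * self.span
        hi_x = float(self.x.max()) + 0.5 * self.span
        pri = {
            "center": _Prior(lo_x, hi_x),
            "width": _Prior(1.0, 10.0 * self.span, log_scale=True),
        }
        if self.spec.scaling == "free":
            pri["p_min"] = _Prior(0.0, 1.0)
            pri["p_max"] = _Prior(0.0, 1.0)
        if self.spec.tails == "both":
            pri["delta_l"] = _Prior(0.0, self.span)
            pri["tau_l"] = _Prior(1e-3, 1.0)
            pri["delta_r"] = _Prior(0.0, self.span)
            pri["tau_r"] = _Prior(1e-3, 1.0)
        return pri

    def _init_params(self, rng: np.random.Generator, pri) -> dict[str, float]:
        ok = self.n > 0
        params = {
            "center": float(np.median(self.x[ok])),
            "width": float(self.span / 2.0),
        }
        if self.spec.scaling == "free":
            params["p_min"] = float(np.clip(self.p_hat[ok].min(), 0.001, 0.999))
            params["p_max"] = float(np.clip(self.p_hat[ok].max(), params["p_min"] + 1e-3, 1.0))
        if self.spec.tails == "both":
            params.update(delta_l=self.span / 4, tau_l=0.5,
                          delta_r=self.span / 4, tau_r=0.5)
        return params

    def fit(self, iterations: int = 100_000, burn_in: int = 10_000,
            seed: int = 0) -> ClineFitResults:
        """Random-walk Metropolis; returns the trace's maximum-lnL point.

        Proposals are Gaussian per parameter (width on the log scale);
        moves outside the prior box or violating p_min < p_max are rejected.
        AICc uses the number of populations with data as the sample size.
        """
        if self.spec is None:
            return self._fit_null(seed, iterations, burn_in)
        rng = np.random.default_rng(seed)
        pri = self._priors()
        names = list(self.spec.param_names)
        params = self._init_params(rng, pri)
        steps = {
            "center": 0.05 * self.span, "width": 0.15,
            "p_min": 0.05, "p_max": 0.05,
            "delta_l": 0.05 * self.span, "tau_l": 0.05,
            "delta_r": 0.05 * self.span, "tau_r": 0.05,
        }
        lnl = self._lnl(params)
        best, best_lnl = dict(params), lnl
        total = iterations + burn_in
        trace = np.empty((iterations, len(names)))
        accepts = 0
        for it in range(total):
            name = names[it % len(names)]
            prop = dict(params)
            p = pri[name]
            if p.log_scale:
                val = np.exp(np.log(params[name]) + steps[name] * rng.standard_normal())
            else:
                val = params[name] + steps[name] * rng.standard_normal()
            prop[name] = val
            ok = p.lo <= val <= p.hi
            if ok and self.spec.scaling == "free":
                ok = prop["p_min"] < prop["p_max"]
            if ok:
                lnl_prop = self._lnl(prop)
                if np.log(rng.random()) < lnl_prop - lnl:
                    params, lnl = prop, lnl_prop
                    accepts += 1
                    if lnl > best_lnl:
                        best, best_lnl = dict(params), lnl
            if it >= burn_in:
                trace[it - burn_in] = [params[nm] for nm in names]
        qs = np.quantile(trace, [0.025, 0.25, 0.5, 0.75, 0.975], axis=0)
        tq = pd.DataFrame(qs.T, index=names,
                          columns=["q2.5", "q25", "q50", "q75", "q97.5"])
        a = aicc(best_lnl, self.spec.n_params, self.n_pops)
        return ClineFitResults(
            locus=self.locus, spec=self.spec, params=best, loglik=best_lnl,
            aicc=a, trace_quantiles=tq, seed=seed, iterations=iterations,
            burn_in=burn_in, acceptance_rate=accepts / total, pinned=self.pinned)

    def _fit_null(self, seed: int, iterations: int, burn_in: int) -> ClineFitResults:
        p0, lnl = null_loglik(self.p_hat, self.n)
        tq = pd.DataFrame([[p0] * 5], index=["p0"],
                          columns=["q2.5", "q25", "q50", "q75", "q97.5"])
        return ClineFitResults(
            locus=self.locus, spec=None, params={"p0": p0}, loglik=lnl,
            aicc=aicc(lnl, 1, self.n_pops), trace_quantiles=tq, seed=seed,
            iterations=iterations, burn_in=burn_in, acceptance_rate=1.0)


def fit_cline_mcmc(p_hat, n_alleles, x, spec: ClineModelSpec,
                   iterations: int = 100_000, burn_in: int = 10_000,
                   seed: int = 0, locus: str = "") -> ClineFitResults:
    """Functional wrapper over :class:`ClineModel`.fit for one model."""
    return ClineModel(p_hat, n_alleles, x, spec, locus=locus).fit(
        iterations=iterations, burn_in=burn_in, seed=seed)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

@dataclass
class ClineSelection:
    """Best model per locus with the significant-cline flag."""

    locus: str
    best_model: str            # model name or 'null'
    loglik: float
    aicc: float
    significant: bool          # non-null best AND lnL clears the cutoff
    width_km: float | None
    center_km: float | None
    all_aicc: dict[str, float] = field(default_factory=dict)


def select_cline_model(fits: list[ClineFitResults], null_fit: ClineFitResults,
                       lnl_cutoff: float = -10.0,
                       cutoff_mode: str = "saturated",
                       saturated_lnl: float | None = None) -> ClineSelection:
    """AICc model choice followed by the log-likelihood cutoff.

    ``cutoff_mode`` fixes what the cutoff is compared against:

    * ``'saturated'`` (default) — lnL relative to the saturated fit (one
      free frequency per population); a deviance-scale goodness-of-fit that
      is 0 for a perfect fit regardless of allele sample sizes, so a fixed
      cutoff like -10 is meaningful at any n.
    * ``'absolute'`` — the raw binomial lnL, whose scale grows with total
      allele counts (a perfect fit at 12 populations x 40 alleles sits near
      -140), making a fixed cutoff sample-size dependent.
    * ``'delta'`` — lnL relative to the flat null fit.

    Width and center are reported only for significant loci.
    """
    candidates = [f for f in fits if np.isfinite(f.aicc)] + [null_fit]
    if not any(np.isfinite(f.aicc) for f in candidates):
        raise ValueError(f"locus {null_fit.locus!r}: no model has a defined AICc")
    best = min(candidates, key=lambda f: f.aicc)
    non_null = best.spec is not None
    if cutoff_mode == "absolute":
        clears = best.loglik > lnl_cutoff
    elif cutoff_mode == "delta":
        clears = (best.loglik - null_fit.loglik) > lnl_cutoff
    elif cutoff_mode == "saturated":
        if saturated_lnl is None:
            raise ValueError("cutoff_mode='saturated' needs saturated_lnl")
        clears = (best.loglik - saturated_lnl) > lnl_cutoff
    else:
        raise ValueError("cutoff_mode must be 'absolute', 'delta' or 'saturated'")
    sig = bool(non_null and clears)
    return ClineSelection(
        locus=best.locus,
        best_model=best.spec.name if non_null else "null",
        loglik=best.loglik, aicc=best.aicc, significant=sig,
        width_km=best.params.get("width") if sig else None,
        center_km=best.params.get("center") if sig else None,
        all_aicc={(f.spec.name if f.spec else "null"): f.aicc for f in candidates},
    )


def fit_locus(p_hat, n_alleles, x, locus: str = "",
              specs: tuple[ClineModelSpec, ...] = MODEL_FAMILY,
              iterations: int = 100_000, burn_in: int = 10_000, seed: int = 0,
              lnl_cutoff: float = -10.0, cutoff_mode: str = "saturated",
              ) -> tuple[ClineSelection, list[ClineFitResults]]:
    """Fit the full model family plus null for one locus and select."""
    null_fit = ClineModel(p_hat, n_alleles, x, None, locus=locus).fit(seed=seed)
    fits = []
    for m, spec in enumerate(specs):
        fits.append(fit_cline_mcmc(p_hat, n_alleles, x, spec,
                                   iterations=iterations, burn_in=burn_in,
                                   seed=seed + 7919 * (m + 1), locus=locus))
    sel = select_cline_model(fits, null_fit, lnl_cutoff=lnl_cutoff,
                             cutoff_mode=cutoff_mode,
                             saturated_lnl=saturated_loglik(p_hat, n_alleles))
    return sel, fits


# ---------------------------------------------------------------------------
# Welch two-sample t-test
# ---------------------------------------------------------------------------

@dataclass
class WelchResult:
    t: float
    df: float
    p: float


def welch_t_test(sample_a, sample_b) -> WelchResult:
    """Welch unequal-variance t-test with Satterthwaite df, two-sided."""
    from scipy import stats as sps

    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need size >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return WelchResult(t=0.0, df=float(a.size + b.size - 2), p=1.0)
        raise ValueError("both samples have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))
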
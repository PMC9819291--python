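"""Synthetic longitudinal scleroderma cohorts for the fatigue analyses.

The study data behind the fatigue MCID analyses are not publicly
available, so every downstream stage (anchor classification, ROC cutoff
selection, random-forest screening, logistic models, power) is exercised
on cohorts drawn from this generator.  The generator emulates the
statistical structure the analysis assumes:

* cross-sectional marginals of the clinical covariates approximating the
  published cohort description (e.g. ILD prevalence 0.606, disease
  duration mean 10.5 y / SD 7.6 y, 55% diffuse subtype);
* a latent true fatigue change ``L`` on the FACIT-FS scale, drawn from a
  three-component mixture (worsened / unchanged / improved with default
  weights 44/65/35 of 144) whose direction is biased by baseline
  covariates through a two-stage logistic model (e.g. ILD raises the
  worsening odds by a configurable log-odds, default ln 3.197);
* an observed FACIT-FS change = ``L`` + measurement noise, rounded and
  clipped to the 0-52 instrument range;
* two anchor instruments (VAS Fatigue, SF36-MCS) whose observed changes
  are monotone transforms of ``L`` plus independent noise, calibrated at
  generation time so the Spearman correlation between observed FACIT-FS
  change and observed oriented anchor change hits ``anchor_correlation``;
* one-year changes of the candidate change-predictors (FACIT-EWB,
  SF36-PCS, CHFS, Hgb, albumin, UCLA GIT 2.0, pinch strength, rEUSTAR-AI)
  coupled to ``L`` with signs consistent with the predictor analyses;
* HAQ-DI generated as a noisy monotone transform of CHFS (rank
  correlation ~0.85) to exercise the collinearity-exclusion rule.

``latent_true_change`` is retained in the returned frame for recovery
tests only; :func:`write_cohort` drops it so pipeline stages cannot
consume it, and :func:`truth_table` exports it separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit, ndtr, ndtri

__all__ = [
    "CohortSpec",
    "CohortError",
    "generate_cohort",
    "truth_table",
    "write_cohort",
    "read_cohort",
    "INSTRUMENT_RANGES",
    "LONGITUDINAL_COLUMNS",
    "STATIC_COLUMNS",
]


class CohortError(ValueError):
    """Invalid cohort specification."""


#: Admissible range per longitudinal measure (used for clipping + checks).
INSTRUMENT_RANGES: dict[str, tuple[float, float]] = {
    "facit_fs": (0, 52),
    "vas_fatigue": (0, 100),
    "sf36_vt": (0, 100),
    "sf36_mcs": (0, 100),
    "sf36_pcs": (0, 100),
    "facit_ewb": (0, 24),
    "ucla_git": (0, 3),
    "chfs": (0, 90),
    "haq_di": (0, 3),
    "reustar_ai": (0, 10),
    "hgb": (60, 200),
    "albumin": (20, 60),
    "pinch_n": (0, 200),
}

LONGITUDINAL_COLUMNS = tuple(INSTRUMENT_RANGES)
STATIC_COLUMNS = ("sex_female", "age_years", "dcssc", "duration_years",
                  "ild", "mrss")


def _default_marginals() -> dict[str, Any]:
    # Disease-duration log-normal parameters solve mean 10.5, SD 7.6.
    sigma2 = math.log(1.0 + (7.6 / 10.5) ** 2)
    return {
        "female_prevalence": 0.863,
        "age_mean": 55.8, "age_sd": 13.0,
        "dcssc_prevalence": 0.55,
        "duration_lognorm": (math.log(10.5) - sigma2 / 2.0, math.sqrt(sigma2)),
        "ild_prevalence": 0.606,
        "mrss_gamma": (1.5, 3.0), "mrss_dcssc_gamma": (1.5, 4.0),
        "reustar_lognorm": (0.916, 0.815),      # median 2.5, IQR ~1.3-3.9
        "chfs_zero_fraction": 0.27,
        "chfs_lognorm": (2.2, 0.9),             # nonzero part, median ~9
        "haq_noise_sd": 2.0,                     # on the CHFS scale
        "ucla_git_lognorm": (-1.6, 1.0),        # median ~0.2
        "hgb": (131.0, 11.0),
        "albumin": (43.6, 3.2),
        "pinch_n": (61.0, 19.0),
        "facit_fs_base": (36.5, 10.5),
        "vas_fatigue_base_beta": (0.55, 1.15),  # median ~24, heavy right tail
        "sf36_vt_base": (55.0, 20.0),
        "sf36_mcs_base_beta": (1.8, 1.0),       # median ~68, left skew
        "sf36_pcs_base": (40.0, 10.0),
        "facit_ewb_base": (18.5, 4.0),
    }


def _default_effects() -> dict[str, dict[str, float]]:
    # Per-unit log-odds of the two direction stages; signs/magnitudes follow
    # the published baseline predictor models (worsened- and improved-vs-rest).
    return {
        "worsening": {
            "ild": math.log(3.197),
            "reustar_ai": math.log(0.825),
            "chfs": math.log(0.982),
            "duration_years": math.log(1.027),
            "mrss": math.log(0.901),
        },
        "improvement": {
            "ild": math.log(0.602),
            "reustar_ai": math.log(1.374),
            "chfs": math.log(1.037),
            "duration_years": math.log(0.916),
            "mrss": math.log(0.924),
        },
    }


# Coupling of each change-predictor's one-year change to the latent fatigue
# change L: fu = base + slope*L + sd*noise, rounded to `decimals` (or to the
# nearest `step`), then clipped to the instrument range.  Signs match the
# direction of the published change-predictor effects (e.g. emotional
# well-being and physical condition improve together with fatigue, GI
# symptoms and hand disability move against it).
_CHANGE_COUPLINGS: dict[str, tuple[float, float, float]] = {
    # column: (slope per FACIT point, noise SD, rounding step)
    "sf36_vt": (1.3, 9.0, 5.0),
    "facit_ewb": (0.35, 2.2, 1.0),
    "sf36_pcs": (0.8, 5.0, 0.1),
    "chfs": (-0.8, 5.0, 1.0),
    "ucla_git": (-0.03, 0.30, 0.01),
    "hgb": (0.4, 6.0, 1.0),
    "albumin": (0.10, 2.0, 0.1),
    "pinch_n": (0.6, 8.0, 0.1),
    "reustar_ai": (-0.10, 1.0, 0.1),
}

_STAGES = ("covariates", "direction", "latent", "observation",
           "anchor_vas", "anchor_mcs", "changes")


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the conditions the fatigue analyses assume: 144
    followed patients, worsened/unchanged/improved mixture weights
    44/65/35, a true MCID pair of (-3, +4) FACIT-FS points, anchor rank
    correlation 0.6, and covariate effects on the change direction taken
    from the published predictor models.
    """

    n_patients: int = 144
    seed: int = 0
    mixture_weights: tuple[float, float, float] = (44 / 144, 65 / 144, 35 / 144)
    latent_change_sd: float | None = None  # None: solve scale from the weights
    obs_noise_sd: float = 0.75         # FACIT-FS measurement noise SD
    anchor_correlation: float = 0.6
    anchor_label_noise: float = 0.25   # latent-scale width of anchor labelling
    anchor_relabel_fraction: float = 0.05  # gross anchor errors (label-corrupting)
    anchor_bin_offsets: tuple[float, float] = (0.5, 0.0)  # worsen, improve
    true_mcid_worsen: float = -3.0
    true_mcid_improve: float = 4.0
    vas_anchor_mcid: float = 10.0      # mm, per direction
    mcs_anchor_mcid: float = 5.0       # points, per direction
    covariate_marginals: dict[str, Any] = field(default_factory=_default_marginals)
    effect_spec: dict[str, dict[str, float]] = field(default_factory=_default_effects)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise CohortError("n_patients must be >= 1")
        if not 0.0 < self.anchor_correlation < 1.0:
            raise CohortError("anchor_correlation must be in (0, 1)")
        if not (self.true_mcid_worsen < 0.0 < self.true_mcid_improve):
            raise CohortError("need true_mcid_worsen < 0 < true_mcid_improve")
        w = np.asarray(self.mixture_weights, dtype=float)
        if w.shape != (3,) or np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
            raise CohortError("mixture_weights must be 3 positive values summing to 1")
        for par in ("obs_noise_sd", "vas_anchor_mcid", "mcs_anchor_mcid"):
            if getattr(self, par) <= 0:
                raise CohortError(f"{par} must be positive")
        if self.latent_change_sd is not None and self.latent_change_sd <= 0:
            raise CohortError("latent_change_sd must be positive")

    def latent_distribution(self) -> tuple[float, float]:
        """Location and scale of the latent-change normal.

        The three mixture components are the slices of one
        ``Normal(mu, sigma)`` cut at the true MCID thresholds, so the
        marginal latent density is smooth across them (the property that
        lets the anchor-based ROC cutoff land on the true threshold).
        With ``latent_change_sd=None`` both parameters are solved so the
        region masses equal ``mixture_weights``; with an explicit scale
        only the location is solved, to match the worsening weight.
        """
        w_worsen, w_stable, _ = self.mixture_weights
        z1 = float(ndtri(w_worsen))
        z2 = float(ndtri(w_worsen + w_stable))
        if self.latent_change_sd is None:
            sigma = (self.true_mcid_improve - self.true_mcid_worsen) / (z2 - z1)
        else:
            sigma = self.latent_change_sd
        mu = self.true_mcid_worsen - sigma * z1
        return mu, sigma


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept such that mean(expit(a + eta)) == target (Newton)."""
    a = float(logit(target))
    for _ in range(60):
        p = expit(a + eta)
        err = p.mean() - target
        if abs(err) < 1e-12:
            break
        a -= err / max(float((p * (1 - p)).mean()), 1e-10)
    return a


def _round_step(x: np.ndarray, step: float) -> np.ndarray:
    return np.round(x / step) * step


def _haq_from_chfs(chfs_like: np.ndarray) -> np.ndarray:
    """Deterministic monotone map from the CHFS scale onto HAQ-DI 0-3."""
    haq = 0.9 * np.sqrt(np.maximum(chfs_like, 0.0) / 10.0)
    return np.clip(np.round(haq * 8.0) / 8.0, 0.0, 3.0)


def _anchor_latent_threshold(thr: float, mu0: float, sigma0: float,
                             obs_sd: float, w: float,
                             bin_offset: float = 0.5) -> float:
    """Latent value the anchor MCID must map to for unbiased ROC recovery.

    The Youden-maximizing cutoff of a ROC sits where the positive-class
    and negative-class densities of the observed change are equal, i.e.
    where P(anchor-labeled changed | observed change) equals the label
    prevalence.  With a normal latent change N(mu0, sigma0), measurement
    noise ``obs_sd`` (plus integer rounding) and anchor label noise of
    width ``w`` on the latent scale, that condition is met at the true
    threshold ``thr`` exactly when the anchor labels patients beyond the
    latent point returned here (closed form: both sides of the condition
    are normal probabilities linear in the threshold).  Without this
    alignment the estimand of the anchor-based procedure would differ
    from the generator's truth and no estimator could recover the pair.
    """
    sig_eff2 = obs_sd ** 2 + 1.0 / 12.0        # + variance of rounding
    shrink = sigma0 ** 2 / (sigma0 ** 2 + sig_eff2)
    tau2 = shrink * sig_eff2
    # Change scores are integers, so the candidate cutoffs bin them; the
    # density-equality point belongs a fraction of a point inside the
    # threshold, which makes the threshold's own bin the strict Youden
    # argmax instead of tying with its outer neighbour.  The offset that
    # equalizes the discrete Youden gaps on both sides of the peak
    # depends on the positive-class prevalence (lower prevalence calls
    # for a smaller offset).
    thr_adj = thr - bin_offset * math.copysign(1.0, thr)
    m_thr = shrink * thr_adj + (1.0 - shrink) * mu0
    s_marg = math.sqrt(sigma0 ** 2 + w ** 2)
    s_post = math.sqrt(tau2 + w ** 2)
    return (m_thr * s_marg - mu0 * s_post) / (s_marg - s_post)


def _bisect_decreasing(fn, target: float, lo: float = 0.0, hi: float = 1.0,
                       iters: int = 40) -> float:
    """Largest argument keeping a decreasing ``fn`` above ``target``."""
    if fn(lo) <= target:
        return lo
    if fn(hi) > target:
        return hi
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if fn(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one synthetic cohort; deterministic given ``spec.seed``.

    Returns a frame with one row per patient: static covariates, the
    baseline (``*_base``) and 12-month (``*_fu``) value of every
    longitudinal measure, and the hidden ``latent_true_change``.  Frame
    ``attrs`` record the spec, the realized anchor correlations and the
    fraction of values affected by range clipping.
    """
    spec.validate()
    n = spec.n_patients
    m = spec.covariate_marginals
    ss = np.random.SeedSequence(spec.seed & 0x7FFFFFFF)
    rng = {name: np.random.default_rng(child)
           for name, child in zip(_STAGES, ss.spawn(len(_STAGES)))}
    clip_frac: dict[str, float] = {}

    # --- static covariates and baselines -------------------------------
    c = rng["covariates"]
    female = c.random(n) < m["female_prevalence"]
    age = np.round(np.clip(c.normal(m["age_mean"], m["age_sd"], n), 18, 90), 1)
    dcssc = c.random(n) < m["dcssc_prevalence"]
    mu_d, sd_d = m["duration_lognorm"]
    duration = np.round(np.clip(c.lognormal(mu_d, sd_d, n), 0.2, 45.0), 1)
    ild = c.random(n) < m["ild_prevalence"]
    k1, t1 = m["mrss_gamma"]
    k2, t2 = m["mrss_dcssc_gamma"]
    mrss = np.rint(np.clip(c.gamma(k1, t1, n) + np.where(dcssc, c.gamma(k2, t2, n), 0.0),
                           0, 51))
    mu_r, sd_r = m["reustar_lognorm"]
    reustar = np.round(np.clip(c.lognormal(mu_r, sd_r, n), 0, 10), 1)
    mu_c, sd_c = m["chfs_lognorm"]
    chfs = np.where(c.random(n) < m["chfs_zero_fraction"], 0.0,
                    np.rint(np.clip(c.lognormal(mu_c, sd_c, n), 0, 90)))
    haq = _haq_from_chfs(chfs + c.normal(0.0, m["haq_noise_sd"], n))
    mu_g, sd_g = m["ucla_git_lognorm"]
    git = np.round(np.clip(c.lognormal(mu_g, sd_g, n), 0, 3), 2)
    hgb = np.rint(np.clip(c.normal(*m["hgb"], n), *INSTRUMENT_RANGES["hgb"]))
    albumin = np.round(np.clip(c.normal(*m["albumin"], n),
                               *INSTRUMENT_RANGES["albumin"]), 1)
    pinch = np.round(np.clip(c.normal(*m["pinch_n"], n), 5, 200), 1)
    facit_base = np.rint(np.clip(c.normal(*m["facit_fs_base"], n), 0, 52))
    a_v, b_v = m["vas_fatigue_base_beta"]
    vas_base = np.rint(100.0 * c.beta(a_v, b_v, n))
    vt_base = _round_step(np.clip(c.normal(*m["sf36_vt_base"], n), 0, 100), 5.0)
    a_m, b_m = m["sf36_mcs_base_beta"]
    mcs_base = np.round(100.0 * c.beta(a_m, b_m, n), 1)
    pcs_base = np.round(np.clip(c.normal(*m["sf36_pcs_base"], n), 0, 100), 1)
    ewb_base = np.rint(np.clip(c.normal(*m["facit_ewb_base"], n), 0, 24))

    covariates = {
        "ild": ild.astype(float), "reustar_ai": reustar, "chfs": chfs,
        "duration_years": duration, "mrss": mrss, "haq_di": haq,
        "age_years": age, "sex_female": female.astype(float),
        "dcssc": dcssc.astype(float),
    }

    # --- change direction: two-stage conditional logit ------------------
    d = rng["direction"]
    w_worsen, w_stable, w_improve = spec.mixture_weights

    def linpred(effects: dict[str, float]) -> np.ndarray:
        eta = np.zeros(n)
        for name, beta in effects.items():
            x = covariates[name]
            eta += beta * (x - x.mean())
        return eta

    eta_w = linpred(spec.effect_spec.get("worsening", {}))
    a_w = _solve_intercept(eta_w, w_worsen)
    worsen = d.random(n) < expit(a_w + eta_w)
    eta_i = linpred(spec.effect_spec.get("improvement", {}))
    improve = np.zeros(n, dtype=bool)
    rest = ~worsen
    if rest.any():
        target = min(w_improve / (1.0 - w_worsen), 0.999)
        a_i = _solve_intercept(eta_i[rest], target)
        improve[rest] = d.random(int(rest.sum())) < expit(a_i + eta_i[rest])

    # --- latent true change: truncated slices of one smooth normal ------
    l = rng["latent"]
    mu0, sigma0 = spec.latent_distribution()
    L = np.empty(n)
    stable = ~(worsen | improve)
    q_w = ndtr((spec.true_mcid_worsen - mu0) / sigma0)
    q_i = ndtr((spec.true_mcid_improve - mu0) / sigma0)
    u = l.random(n)
    L[worsen] = mu0 + sigma0 * ndtri(u[worsen] * q_w)
    L[stable] = mu0 + sigma0 * ndtri(q_w + u[stable] * (q_i - q_w))
    L[improve] = mu0 + sigma0 * ndtri(q_i + u[improve] * (1.0 - q_i))

    # --- observed FACIT-FS change ---------------------------------------
    o = rng["observation"]
    raw_fu = facit_base + L + o.normal(0.0, spec.obs_noise_sd, n)
    clip_frac["facit_fs"] = float(np.mean((raw_fu < 0) | (raw_fu > 52)))
    facit_fu = np.rint(np.clip(raw_fu, 0, 52))
    delta_facit = facit_fu - facit_base

    # --- anchors ---------------------------------------------------------
    # The anchor error has three parts.  (i) Threshold noise of width
    # ``anchor_label_noise`` (latent scale): genuine smearing of who the
    # anchor calls changed.  (ii) A fixed fraction of gross errors:
    # patients whose anchor value is an independent draw from the
    # marginal, i.e. completely-at-random label corruption -- which
    # scales the Youden curve without moving its argmax.  (iii)
    # Category-preserving magnitude scrambling: anchor values exchanged
    # among patients the anchor placed in the same worsened / unchanged /
    # improved category, calibrated by bisection so the rank correlation
    # between observed target and anchor changes hits
    # ``anchor_correlation`` (the dichotomizing ROC never sees these
    # magnitudes, so the recovery estimand is untouched).  The transform
    # maps the anchor MCID onto the latent point solving the
    # density-equality condition, keeping the population Youden cutoff at
    # the true MCID pair.
    w_lab = spec.anchor_label_noise
    ls_w = _anchor_latent_threshold(spec.true_mcid_worsen, mu0, sigma0,
                                    spec.obs_noise_sd, w_lab,
                                    bin_offset=spec.anchor_bin_offsets[0])
    ls_i = _anchor_latent_threshold(spec.true_mcid_improve, mu0, sigma0,
                                    spec.obs_noise_sd, w_lab,
                                    bin_offset=spec.anchor_bin_offsets[1])
    realized: dict[str, float] = {}
    s_marginal = math.sqrt(sigma0 ** 2 + w_lab ** 2)

    def make_anchor(stream: np.random.Generator, anchor_mcid: float, observe):
        slope_w = anchor_mcid / abs(ls_w)
        slope_i = anchor_mcid / ls_i
        lat_noisy = L + w_lab * stream.normal(0.0, 1.0, n)
        lat_indep = mu0 + s_marginal * stream.normal(0.0, 1.0, n)
        u_relabel = stream.random(n)
        u_scramble = stream.random(n)
        shuffle_key = stream.random(n)

        def oriented(frac: float, lam: float) -> np.ndarray:
            out = np.where(u_relabel < lam, lat_indep, lat_noisy)
            category = np.where(out <= ls_w, -1, np.where(out >= ls_i, 1, 0))
            chosen = u_scramble < frac
            for cat in (-1, 0, 1):
                members = np.flatnonzero(chosen & (category == cat))
                if members.size > 1:
                    out[members] = out[members][np.argsort(shuffle_key[members])]
            return np.where(out < 0, out * slope_w, out * slope_i)

        def rho_of(frac: float, lam: float) -> float:
            return float(stats.spearmanr(
                delta_facit, observe(oriented(frac, lam))).statistic)

        # stage 1: category-preserving scrambling; stage 2 (only if the
        # category structure alone still correlates above target): more
        # completely-at-random replacement
        lam = spec.anchor_relabel_fraction
        frac = _bisect_decreasing(lambda f: rho_of(f, lam),
                                  spec.anchor_correlation)
        if frac >= 1.0 and rho_of(1.0, lam) > spec.anchor_correlation:
            lam = _bisect_decreasing(lambda la: rho_of(1.0, la),
                                     spec.anchor_correlation,
                                     lo=lam, hi=1.0)
        raw = oriented(frac, lam)
        obs = observe(raw)
        rho = float(stats.spearmanr(delta_facit, obs).statistic)
        return obs, rho, raw

    def observe_vas(oriented: np.ndarray) -> np.ndarray:
        fu = np.rint(np.clip(vas_base - oriented, 0, 100))  # VAS: higher = worse
        return vas_base - fu

    obs_vas, realized["vas_fatigue"], raw_vas = make_anchor(
        rng["anchor_vas"], spec.vas_anchor_mcid, observe_vas)
    vas_fu = vas_base - obs_vas
    clip_frac["vas_fatigue"] = float(np.mean(
        ((vas_base - raw_vas) < 0) | ((vas_base - raw_vas) > 100)))

    def observe_mcs(oriented: np.ndarray) -> np.ndarray:
        fu = np.round(np.clip(mcs_base + oriented, 0, 100), 1)
        return fu - mcs_base

    obs_mcs, realized["sf36_mcs"], raw_mcs = make_anchor(
        rng["anchor_mcs"], spec.mcs_anchor_mcid, observe_mcs)
    mcs_fu = mcs_base + obs_mcs
    clip_frac["sf36_mcs"] = float(np.mean(
        ((mcs_base + raw_mcs) < 0) | ((mcs_base + raw_mcs) > 100)))

    # --- one-year changes of the candidate change-predictors ------------
    gch = rng["changes"]
    bases = {
        "sf36_vt": vt_base, "facit_ewb": ewb_base, "sf36_pcs": pcs_base,
        "chfs": chfs, "ucla_git": git, "hgb": hgb, "albumin": albumin,
        "pinch_n": pinch, "reustar_ai": reustar,
    }
    fus: dict[str, np.ndarray] = {}
    for col, (slope, sd, step) in _CHANGE_COUPLINGS.items():
        lo_r, hi_r = INSTRUMENT_RANGES[col]
        raw = bases[col] + slope * L + gch.normal(0.0, sd, n)
        clip_frac[col] = float(np.mean((raw < lo_r) | (raw > hi_r)))
        fus[col] = _round_step(np.clip(raw, lo_r, hi_r), step)
    haq_fu = _haq_from_chfs(fus["chfs"] + gch.normal(0.0, m["haq_noise_sd"], n))

    frame = pd.DataFrame({
        "patient_id": [f"P{i + 1:04d}" for i in range(n)],
        "sex_female": female.astype(int),
        "age_years": age,
        "dcssc": dcssc.astype(int),
        "duration_years": duration,
        "ild": ild.astype(int),
        "mrss": mrss.astype(int),
        "facit_fs_base": facit_base.astype(int),
        "facit_fs_fu": facit_fu.astype(int),
        "vas_fatigue_base": vas_base.astype(int),
        "vas_fatigue_fu": vas_fu.astype(int),
        "sf36_vt_base": vt_base,
        "sf36_vt_fu": fus["sf36_vt"],
        "sf36_mcs_base": mcs_base,
        "sf36_mcs_fu": np.round(mcs_fu, 1),
        "sf36_pcs_base": pcs_base,
        "sf36_pcs_fu": fus["sf36_pcs"],
        "facit_ewb_base": ewb_base.astype(int),
        "facit_ewb_fu": fus["facit_ewb"].astype(int),
        "ucla_git_base": git,
        "ucla_git_fu": fus["ucla_git"],
        "chfs_base": chfs.astype(int),
        "chfs_fu": fus["chfs"].astype(int),
        "haq_di_base": haq,
        "haq_di_fu": haq_fu,
        "reustar_ai_base": reustar,
        "reustar_ai_fu": fus["reustar_ai"],
        "hgb_base": hgb.astype(int),
        "hgb_fu": fus["hgb"].astype(int),
        "albumin_base": albumin,
        "albumin_fu": fus["albumin"],
        "pinch_n_base": pinch,
        "pinch_n_fu": fus["pinch_n"],
        "latent_true_change": L,
    })
    frame.attrs["spec"] = asdict(spec)
    frame.attrs["realized_anchor_correlation"] = realized
    frame.attrs["clipping_fraction"] = clip_frac
    return frame


def truth_table(cohort: pd.DataFrame,
                true_mcid_worsen: float | None = None,
                true_mcid_improve: float | None = None) -> pd.DataFrame:
    """Ground-truth change direction per patient, from the latent change.

    A patient is ``worsened`` when ``latent_true_change <= true_mcid_worsen``,
    ``improved`` when ``>= true_mcid_improve`` (both thresholds inclusive),
    else ``unchanged``.  Intended for recovery tests only.
    """
    if "latent_true_change" not in cohort.columns:
        raise CohortError("cohort lacks the latent_true_change column")
    spec = cohort.attrs.get("spec", {})
    tw = spec.get("true_mcid_worsen") if true_mcid_worsen is None else true_mcid_worsen
    ti = spec.get("true_mcid_improve") if true_mcid_improve is None else true_mcid_improve
    if tw is None or ti is None:
        raise CohortError("true MCID thresholds unavailable: pass them explicitly")
    L = cohort["latent_true_change"].to_numpy()
    label = np.where(L <= tw, "worsened",
                     np.where(L >= ti, "improved", "unchanged"))
    return pd.DataFrame({"patient_id": cohort["patient_id"],
                         "true_direction": label})


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write the cohort as CSV, dropping the hidden latent change column."""
    public = cohort.drop(columns=["latent_true_change"], errors="ignore")
    public.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
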
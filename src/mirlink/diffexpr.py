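"""Two-group negative-binomial differential expression for count matrices.

The engine follows the standard RNA-seq decision surface — log2 fold change
plus Benjamini-Hochberg FDR — with a self-contained statistical core:

* counts-per-million (CPM) computation and low-expression filtering
  (a feature is kept when at least ``cpm_frac`` of samples reach
  ``cpm_min`` CPM; the usual "10 CPM in at least half the samples" rule
  for miRNA data);
* trimmed-mean-of-log-ratio (TMM-style) normalization factors;
* per-feature NB dispersions by method of moments, shrunk toward the
  median dispersion with a prior weight of 10 degrees of freedom;
* a likelihood-ratio test of group-specific versus shared NB means at the
  feature's dispersion, referred to chi-square with 1 df;
* BH adjustment and threshold classification into up / down / ns.

An optional latent-factor step (residual SVD of group-centred log-CPM with
permutation-based factor-count selection) stands in for surrogate-variable
batch adjustment: fitted factor contributions are absorbed into the
per-feature log-mean offsets before testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CountMatrix, SampleSheet, DE_COLUMNS

__all__ = [
    "DEConfig",
    "NormFactors",
    "cpm",
    "filter_low_expression",
    "norm_factors",
    "estimate_dispersions",
    "nb_test",
    "bh_adjust",
    "classify",
    "estimate_latent_factors",
    "run_de",
]


@dataclass
class DEConfig:
    """Thresholds and tuning constants for the DE stage.

    ``lfc_threshold`` is in log2 units; a feature is called up (down) only
    when its |log2FC| exceeds it AND both p thresholds hold. ``prior_count``
    is added to group mean CPM before the fold-change ratio only — it never
    enters the likelihood.
    """

    lfc_threshold: float = 2.0
    p_threshold: float = 0.01
    fdr_threshold: float = 0.01
    cpm_min: float = 10.0
    cpm_frac: float = 0.5
    prior_count: float = 0.5
    n_latent: int | None = None  # None = no latent factors; use "auto" in run_de

    def __post_init__(self) -> None:
        if min(self.lfc_threshold, self.p_threshold, self.fdr_threshold) <= 0:
            raise ValueError("thresholds must be strictly positive")
        if not (0 < self.cpm_frac <= 1):
            raise ValueError("cpm_frac must lie in (0, 1]")


@dataclass
class NormFactors:
    """Per-sample scale factors with geometric mean 1.

    Effective library size = raw library size x factor.
    """

    factors: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")
        logf = np.log(self.factors.to_numpy(dtype=float))
        if abs(logf.mean()) > 1e-9:
            raise ValueError("factors must have geometric mean 1")

    @classmethod
    def unit(cls, sample_ids) -> "NormFactors":
        return cls(pd.Series(1.0, index=list(sample_ids)))

    def effective_sizes(self, matrix: CountMatrix) -> pd.Series:
        lib = matrix.library_sizes().astype(float)
        return lib * self.factors.reindex(matrix.sample_ids)


def cpm(matrix: CountMatrix, norm: NormFactors | None = None) -> pd.DataFrame:
    """Counts per million over effective library sizes."""
    if norm is None:
        norm = NormFactors.unit(matrix.sample_ids)
    eff = norm.effective_sizes(matrix)
    zero = eff.index[eff == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s) {list(zero)[:5]}")
    return matrix.counts / eff.to_numpy() * 1e6


def filter_low_expression(matrix: CountMatrix, cfg: DEConfig,
                          norm: NormFactors | None = None) -> CountMatrix:
    """Keep features with >= ``cpm_min`` CPM in at least
    ``ceil(cpm_frac * n_samples)`` samples."""
    c = cpm(matrix, norm)
    need = int(np.ceil(cfg.cpm_frac * len(matrix.sample_ids)))
    keep = (c >= cfg.cpm_min).sum(axis=1) >= need
    return CountMatrix(matrix.counts.loc[keep], matrix.feature_class)


def norm_factors(matrix: CountMatrix, m_trim: float = 0.30,
                 a_trim: float = 0.05) -> NormFactors:
    """Trimmed-mean-of-log-ratio normalization factors.

    The reference is the sample whose upper-quartile CPM is closest to the
    mean upper quartile. For every sample, log2 abundance ratios (M) against
    the reference are trimmed by ``m_trim`` on each tail after discarding
    the ``a_trim`` tails of average log abundance (A); the factor is 2 to
    the trimmed mean M. Factors are rescaled to geometric mean 1, so a pure
    depth difference between samples yields unit factors.
    """
    if len(matrix.sample_ids) < 2:
        raise ValueError("normalization requires at least 2 samples")
    counts = matrix.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = [s for s, L in zip(matrix.sample_ids, lib) if L == 0]
        raise ValueError(f"zero library size for sample(s) {bad[:5]}")
    rel = counts / lib  # relative abundance per sample

    uq = np.quantile(rel * 1e6, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    logf = np.zeros(len(lib))
    for s in range(len(lib)):
        if s == ref:
            continue
        both = (counts[:, s] > 0) & (counts[:, ref] > 0)
        if not both.any():
            warnings.warn(
                f"sample {matrix.sample_ids[s]!r} shares no expressed feature "
                "with the reference; factor set to 1",
                stacklevel=2,
            )
            continue
        m = np.log2(rel[both, s] / rel[both, ref])
        a = 0.5 * np.log2(rel[both, s] * rel[both, ref])
        lo_a, hi_a = np.quantile(a, [a_trim, 1 - a_trim])
        keep_a = (a >= lo_a) & (a <= hi_a)
        m = m[keep_a]
        if m.size == 0:
            continue
        lo_m, hi_m = np.quantile(m, [m_trim, 1 - m_trim])
        kept = m[(m >= lo_m) & (m <= hi_m)]
        if kept.size == 0:
            continue
        logf[s] = kept.mean()
    logf -= logf.mean()  # geometric mean 1
    return NormFactors(pd.Series(np.exp2(logf), index=matrix.sample_ids))


# ---------------------------------------------------------------------------
# NB dispersion and likelihood-ratio test
# ---------------------------------------------------------------------------

PRIOR_DF = 10.0  # shrinkage prior weight for the common dispersion


def _group_masks(matrix: CountMatrix, sheet: SampleSheet) -> dict[str, np.ndarray]:
    cols = pd.Index(matrix.sample_ids)
    return {
        g: cols.isin(sheet.samples_in(g)) for g in ("tumor", "normal")
    }


def estimate_dispersions(matrix: CountMatrix, sheet: SampleSheet,
                         norm: NormFactors | None = None) -> pd.Series:
    """Per-feature NB dispersion phi (variance = mu + phi mu^2).

    Method of moments on depth-scaled counts within each group, pooled by
    within-group degrees of freedom, floored at zero, then shrunk toward
    the median raw dispersion with prior weight ``PRIOR_DF``:
    ``phi = w * median + (1 - w) * phi_raw``, ``w = PRIOR_DF / (PRIOR_DF + df)``.
    """
    sheet.check_against(matrix)
    if norm is None:
        norm = NormFactors.unit(matrix.sample_ids)
    eff = norm.effective_sizes(matrix).to_numpy(dtype=float)
    counts = matrix.counts.to_numpy(dtype=float)
    scale = eff.mean() / eff  # bring samples to a common depth
    z = counts * scale

    masks = _group_masks(matrix, sheet)
    num = np.zeros(counts.shape[0])
    df_total = 0.0
    for mask in masks.values():
        zg = z[:, mask]
        n = mask.sum()
        if n < 2:
            raise ValueError("need at least 2 samples per group")
        m = zg.mean(axis=1)
        v = zg.var(axis=1, ddof=1)
        # E var(z) ~ mu * mean(scale) + phi * mu^2 within the group
        shot = m * scale[mask].mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_g = np.where(m > 0, (v - shot) / np.maximum(m, 1e-300) ** 2, 0.0)
        num += (n - 1) * phi_g
        df_total += n - 1
    raw = np.maximum(0.0, num / df_total)
    common = float(np.median(raw))
    w = PRIOR_DF / (PRIOR_DF + df_total)
    shrunk = w * common + (1 - w) * raw
    return pd.Series(shrunk, index=matrix.feature_ids)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-feature NB log-likelihood summed over samples, dropping terms
    that do not depend on mu. phi = 0 falls back to Poisson."""
    phi = phi[:, None]
    out = np.zeros_like(mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        pois = phi == 0
        ylogmu = np.where(y > 0, y * np.log(np.maximum(mu, 1e-300)), 0.0)
        out = np.where(pois, ylogmu - mu, 0.0)
        r = np.where(pois, 1.0, 1.0 / np.maximum(phi, 1e-300))
        nb = ylogmu - (y + r) * np.log(mu + r)
        out = np.where(pois, out, nb)
    return out.sum(axis=1)


def _fit_nb_mean(y: np.ndarray, offsets: np.ndarray, phi: np.ndarray,
                 n_iter: int = 60) -> np.ndarray:
    """Newton fit of the shared NB rate q (mu = q * offset) per feature,
    vectorized over features. Returns the F-vector of fitted q."""
    tot = y.sum(axis=1)
    off = offsets.sum(axis=1)
    q = tot / off  # Poisson MLE; exact when phi = 0
    pos = tot > 0
    beta = np.where(pos, np.log(np.maximum(q, 1e-300)), -np.inf)
    r = 1.0 / np.maximum(phi, 1e-300)
    pois = phi == 0
    for _ in range(n_iter):
        mu = np.exp(beta[:, None]) * offsets
        with np.errstate(invalid="ignore", over="ignore"):
            score_nb = (y - (y + r[:, None]) * mu / (mu + r[:, None])).sum(axis=1)
            info_nb = (mu * r[:, None] / (mu + r[:, None])).sum(axis=1)
        score = np.where(pois, 0.0, score_nb)  # Poisson MLE is closed-form
        info = np.where(pois, 1.0, info_nb)
        step = np.where(pos & ~pois, score / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -5, 5)
        beta = beta + np.where(np.isfinite(beta), step, 0.0)
        if np.abs(step).max(initial=0.0) < 1e-12:
            break
    return np.where(pos, np.exp(beta), 0.0)


def nb_test(matrix: CountMatrix, sheet: SampleSheet,
            norm: NormFactors | None = None,
            dispersions: pd.Series | None = None,
            cfg: DEConfig | None = None,
            latent: pd.DataFrame | None = None) -> pd.DataFrame:
    """Two-group NB likelihood-ratio test; returns a classified DE table.

    Per feature: ``log2fc = log2((mean tumor CPM + prior) / (mean normal
    CPM + prior))``; the p-value compares group-specific to shared NB means
    at the feature's dispersion via chi-square(1); BH adjustment runs over
    all tested features. If ``latent`` (samples x k factor scores) is
    given, each feature's fitted factor contribution is folded into its
    offsets before testing.
    """
    cfg = cfg or DEConfig()
    sheet.check_against(matrix)
    if norm is None:
        norm = NormFactors.unit(matrix.sample_ids)
    eff = norm.effective_sizes(matrix).to_numpy(dtype=float)
    y = matrix.counts.to_numpy(dtype=float)
    if dispersions is None:
        dispersions = estimate_dispersions(matrix, sheet, norm)
    phi = dispersions.reindex(matrix.feature_ids).to_numpy(dtype=float)

    offsets = np.broadcast_to(eff, y.shape).copy()
    if latent is not None and latent.shape[1] > 0:
        offsets = offsets * _latent_offset_adjustment(matrix, sheet, norm, latent)

    masks = _group_masks(matrix, sheet)
    q_null = _fit_nb_mean(y, offsets, phi)
    ll_null = _nb_loglik(y, q_null[:, None] * offsets, phi)
    ll_alt = np.zeros_like(ll_null)
    for mask in masks.values():
        qg = _fit_nb_mean(y[:, mask], offsets[:, mask], phi)
        ll_alt += _nb_loglik(y[:, mask], qg[:, None] * offsets[:, mask], phi)
    stat = np.maximum(0.0, 2.0 * (ll_alt - ll_null))
    p_raw = stats.chi2.sf(stat, df=1)
    p_raw[stat == 0] = 1.0

    c = y / eff * 1e6
    mean_t = c[:, masks["tumor"]].mean(axis=1)
    mean_n = c[:, masks["normal"]].mean(axis=1)
    log2fc = np.log2(mean_t + cfg.prior_count) - np.log2(mean_n + cfg.prior_count)

    table = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
            "direction": "ns",
        }
    )
    table, _ = classify(table, cfg)
    return table


def _latent_offset_adjustment(matrix: CountMatrix, sheet: SampleSheet,
                              norm: NormFactors, latent: pd.DataFrame) -> np.ndarray:
    """Per-feature multiplicative offset 2^(fitted factor contribution)."""
    logcpm = np.log2(cpm(matrix, norm).to_numpy() + 1.0)
    centred = _group_centre(logcpm, matrix, sheet)
    F = latent.reindex(matrix.sample_ids).to_numpy(dtype=float)  # S x k
    # per-feature OLS: coef = centred @ F (F orthonormal columns from SVD)
    coef, *_ = np.linalg.lstsq(F, centred.T, rcond=None)
    fitted = (F @ coef).T  # F x S, log2 scale
    return np.exp2(fitted)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``q_(i) = min_{j >= i} (m / j) p_(j)``, clipped at 1; ties in the sort
    are broken by input index (stable).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def classify(table: pd.DataFrame, cfg: DEConfig | None = None
             ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Set the direction call per record and return summary counts.

    up: log2fc > T and p_raw < p_threshold and p_adj < fdr_threshold;
    down: log2fc < -T under the same p rules; otherwise ns.
    """
    cfg = cfg or DEConfig()
    t = table.copy()
    sig = (t["p_raw"] < cfg.p_threshold) & (t["p_adj"] < cfg.fdr_threshold)
    up = sig & (t["log2fc"] > cfg.lfc_threshold)
    down = sig & (t["log2fc"] < -cfg.lfc_threshold)
    t["direction"] = np.select([up, down], ["up", "down"], default="ns")
    return t, {"n_up": int(up.sum()), "n_down": int(down.sum())}


# ---------------------------------------------------------------------------
# latent factors (simplified surrogate-variable step)
# ---------------------------------------------------------------------------

def _group_centre(logcpm: np.ndarray, matrix: CountMatrix,
                  sheet: SampleSheet) -> np.ndarray:
    centred = logcpm.copy()
    for mask in _group_masks(matrix, sheet).values():
        centred[:, mask] -= centred[:, mask].mean(axis=1, keepdims=True)
    return centred


def estimate_latent_factors(matrix: CountMatrix, sheet: SampleSheet,
                            k: int | None = None,
                            norm: NormFactors | None = None,
                            n_perm: int = 20,
                            seed: int = 0) -> pd.DataFrame:
    """Latent expression factors from residual SVD, for use as covariates.

    The group-mean-centred log2(CPM+1) matrix is decomposed by SVD; factor
    scores (right singular vectors) capture structured variation not
    explained by the tumor/normal contrast, e.g. batch. When ``k`` is not
    given it is chosen by parallel analysis: each singular value must
    exceed the 95th percentile of the matching singular value across
    ``n_perm`` independent row-wise permutations of the residual matrix,
    counted from the top until the first failure.

    Returns a samples x k DataFrame (columns ``LF1..LFk``); k may be 0.
    """
    sheet.check_against(matrix, min_per_group=2)
    n_samples = len(matrix.sample_ids)
    if n_samples < 4:
        raise ValueError("latent-factor estimation requires at least 4 samples")
    if k is not None and k >= n_samples - 2:
        raise ValueError(f"k={k} must be below n_samples - 2 = {n_samples - 2}")
    if norm is None:
        norm = NormFactors.unit(matrix.sample_ids)
    logcpm = np.log2(cpm(matrix, norm).to_numpy() + 1.0)
    resid = _group_centre(logcpm, matrix, sheet)

    u, s, vt = np.linalg.svd(resid, full_matrices=False)
    k_max = n_samples - 3
    if k is None:
        rng = np.random.default_rng(seed)
        null_s = np.empty((n_perm, s.size))
        for b in range(n_perm):
            # permute each raw row independently (breaks sample structure,
            # keeps per-feature marginals), then apply the same group
            # centring so the null matches the observed rank deficiency
            idx = rng.random(logcpm.shape).argsort(axis=1)
            perm = _group_centre(
                np.take_along_axis(logcpm, idx, axis=1), matrix, sheet
            )
            null_s[b] = np.linalg.svd(perm, compute_uv=False)
        thresh = np.quantile(null_s, 0.95, axis=0)
        k = 0
        for i in range(min(k_max, s.size)):
            if s[i] > thresh[i]:
                k += 1
            else:
                break
    k = min(k, k_max)
    factors = vt[:k].T  # samples x k, orthonormal
    return pd.DataFrame(
        factors, index=matrix.sample_ids, columns=[f"LF{i+1}" for i in range(k)]
    )


def run_de(matrix: CountMatrix, sheet: SampleSheet, cfg: DEConfig | None = None,
           apply_cpm_filter: bool | None = None,
           latent: str | int | None = None,
           seed: int = 0) -> pd.DataFrame:
    """Convenience front door: normalize, optionally filter and adjust for
    latent factors, test, classify.

    ``apply_cpm_filter`` defaults to True for miRNA matrices and False for
    mRNA. ``latent`` may be None (off), an integer k, or ``"auto"``.
    """
    cfg = cfg or DEConfig()
    if apply_cpm_filter is None:
        apply_cpm_filter = matrix.feature_class == "mirna"
    nf = norm_factors(matrix)
    if apply_cpm_filter:
        matrix = filter_low_expression(matrix, cfg, nf)
        nf = NormFactors(nf.factors.reindex(matrix.sample_ids))
    lat = None
    if latent == "auto":
        lat = estimate_latent_factors(matrix, sheet, None, nf, seed=seed)
    elif isinstance(latent, int) and latent > 0:
        lat = estimate_latent_factors(matrix, sheet, latent, nf, seed=seed)
    if lat is not None and lat.shape[1] == 0:
        lat = None
    return nb_test(matrix, sheet, nf, None, cfg, lat)
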
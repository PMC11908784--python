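"""Likelihood-ratio somatic variant calling against a pooled background.

For every (site, alt, test sample) the observed variant rate in the test
sample is compared with the site's background error model by a one-sided
likelihood-ratio test:

* null — one shared error rate across background samples and the test
  sample, with the site's plug-in overdispersion;
* alternative — a separate rate for the test sample, shared dispersion.

``lambda = 2 * (loglik_alt - loglik_null)`` is referred to chi-square with
one degree of freedom; the one-sided p-value is half the tail when the test
rate exceeds the background rate and 1 otherwise.  p-values are adjusted by
Benjamini-Hochberg within each cell-type batch and calls retained at a
configurable q cutoff.

Rate estimates are effective-depth-weighted quasi-likelihood estimates
evaluated under the exact beta-binomial likelihood, which makes the scalar
and the vectorized batched path identical and fast enough for cohort-scale
matrices (see ``lrt_one_sample`` and ``call_variants``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln, gammaln

from .errormodel import (
    MU_FLOOR,
    RHO_FLOOR,
    _RHO_BINOMIAL_SWITCH,
    _validate_counts,
    rho_moment_estimate,
)

__all__ = [
    "BackgroundDesign",
    "LrtResult",
    "bh_adjust",
    "call_variants",
    "lrt_one_sample",
    "DEFAULT_DESIGN",
]

_P_FLOOR = 1e-300

#: Baseline overdispersion imposed on every site.  Sparse background counts
#: cannot reveal small but real between-sample dispersion, and assuming a
#: pure binomial there makes deep-tail p-values anti-conservative; a floor
#: of 1e-4 matches typical targeted deep-sequencing panels.
DEFAULT_RHO_MIN = 1e-4


class ConfigurationError(ValueError):
    """Raised when the background design cannot be satisfied."""


@dataclass(frozen=True)
class BackgroundDesign:
    """Mapping from each test cell type to the cell types pooled as background.

    The default mirrors a four-population sort: each population is tested
    against the union of the other non-blood populations.
    """

    pools: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_POOLS)
    )

    def __post_init__(self) -> None:
        for test, pool in self.pools.items():
            if test in pool:
                raise ConfigurationError(
                    f"cell type {test!r} is a member of its own background pool"
                )

    def background_for(self, cell_type: str) -> tuple[str, ...]:
        try:
            return tuple(self.pools[cell_type])
        except KeyError:
            raise ConfigurationError(f"no background pool for cell type {cell_type!r}")


DEFAULT_POOLS: dict[str, tuple[str, ...]] = {
    "microglia": ("neuron", "glia"),
    "glia": ("neuron", "microglia"),
    "neuron": ("microglia", "glia"),
    "blood": ("neuron", "glia"),
}

DEFAULT_DESIGN = BackgroundDesign()


@dataclass(frozen=True)
class LrtResult:
    """One likelihood-ratio comparison of a test sample against background."""

    mu_hat_test: float
    mu_hat_background: float
    rho: float
    lam: float
    p: float
    degenerate_coverage: bool = False
    site_id: str | None = None
    alt: str | None = None
    sample_id: str | None = None
    q: float | None = None


def _bb_loglik_terms(x, n, mu, rho):
    """Vectorized beta-binomial log pmf; broadcasts all arguments.

    Unlike :func:`mosaicall.errormodel.beta_binomial_loglik` this accepts
    per-element ``mu``/``rho`` arrays and skips domain validation — callers
    guarantee the domain.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    mu = np.asarray(mu, dtype=float)
    rho = np.asarray(rho, dtype=float)
    x, n, mu, rho = np.broadcast_arrays(x, n, mu, rho)
    out = np.zeros(x.shape, dtype=float)

    bino = rho <= _RHO_BINOMIAL_SWITCH
    if np.any(bino):
        out[bino] = stats.binom.logpmf(x[bino], n[bino], mu[bino])
    bb = ~bino
    if np.any(bb):
        s = 1.0 / rho[bb] - 1.0
        a = mu[bb] * s
        b = (1.0 - mu[bb]) * s
        xb, nb = x[bb], n[bb]
        out[bb] = (
            gammaln(nb + 1)
            - gammaln(xb + 1)
            - gammaln(nb - xb + 1)
            + betaln(xb + a, nb - xb + b)
            - betaln(a, b)
        )
    return np.where(n == 0, 0.0, out)


def lrt_one_sample(
    x_test, n_test, xs_bg, ns_bg, *,
    rho: float | None = None, rho_min: float = DEFAULT_RHO_MIN,
) -> LrtResult:
    """One-sided LRT of a single test sample against the pooled background.

    ``rho`` defaults to the moment estimate across the background samples
    (never below ``rho_min``); the same dispersion is used in both nested
    models so the alternative has exactly one extra free parameter.  A test
    sample with zero depth is reported with ``p = 1`` and the
    ``degenerate_coverage`` flag, never as an exception.
    """
    xs_bg, ns_bg = _validate_counts(xs_bg, ns_bg)
    if len(xs_bg) != len(ns_bg) or len(xs_bg) < 2 or np.count_nonzero(ns_bg) < 2:
        raise ConfigurationError("background must contain >= 2 samples with positive depth")
    x_test = float(x_test)
    n_test = float(n_test)
    _validate_counts(x_test, n_test)

    if rho is None:
        rho = max(rho_moment_estimate(xs_bg, ns_bg), rho_min)
    rho = float(min(max(rho, RHO_FLOOR), 1.0 - 1e-6))

    if n_test == 0:
        mu_bg = _weighted_mu(xs_bg, ns_bg, rho)
        return LrtResult(MU_FLOOR, mu_bg, rho, 0.0, 1.0, degenerate_coverage=True)

    x_all = np.append(xs_bg, x_test)
    n_all = np.append(ns_bg, n_test)
    mu_null = _weighted_mu(x_all, n_all, rho)
    mu_bg = _weighted_mu(xs_bg, ns_bg, rho)
    mu_test = _weighted_mu(np.array([x_test]), np.array([n_test]), rho)

    ll_null = float(np.sum(_bb_loglik_terms(x_all, n_all, mu_null, rho)))
    ll_alt = float(np.sum(_bb_loglik_terms(xs_bg, ns_bg, mu_bg, rho))) + float(
        _bb_loglik_terms(x_test, n_test, mu_test, rho)
    )
    lam = max(0.0, 2.0 * (ll_alt - ll_null))
    if mu_test > mu_bg:
        p = max(0.5 * float(stats.chi2.sf(lam, df=1)), _P_FLOOR)
    else:
        p = 1.0
    return LrtResult(mu_test, mu_bg, rho, lam, p)


def _weighted_mu(x: np.ndarray, n: np.ndarray, rho) -> float | np.ndarray:
    w = 1.0 / (1.0 + np.maximum(n - 1.0, 0.0) * rho)
    num = np.sum(x * w, axis=-1)
    den = np.sum(n * w, axis=-1)
    mu = np.divide(num, den, out=np.full(np.shape(num), MU_FLOOR, dtype=float), where=den > 0)
    return np.clip(mu, MU_FLOOR, 1.0 - MU_FLOOR) if np.ndim(mu) else float(
        min(max(mu, MU_FLOOR), 1.0 - MU_FLOOR)
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def _pivot_counts(pileups: pd.DataFrame):
    """Long pileup table -> site-by-sample alt/depth matrices (strand-combined)."""
    df = pileups.assign(
        alt_n=pileups["alt_fwd"] + pileups["alt_rev"],
        depth_n=pileups["depth_fwd"] + pileups["depth_rev"],
    )
    alt = df.pivot_table(index="site_id", columns="sample_id", values="alt_n", fill_value=0)
    depth = df.pivot_table(index="site_id", columns="sample_id", values="depth_n", fill_value=0)
    depth = depth.loc[alt.index, alt.columns]
    return alt, depth


def call_variants(
    pileups: pd.DataFrame,
    metadata: pd.DataFrame,
    design: BackgroundDesign = DEFAULT_DESIGN,
    q_cutoff: float = 0.01,
    *,
    cell_types: list[str] | None = None,
    keep_all_tests: bool = False,
    rho_min: float = DEFAULT_RHO_MIN,
) -> pd.DataFrame:
    """Run the LRT for every (site, alt, test sample) and keep q <= cutoff.

    Tests are batched per test cell type: the background pool is shared by
    all test samples of that cell type and the BH family is the full set of
    (site, sample) tests performed within the batch.  The returned call
    table carries the test-sample rate estimate as ``vaf`` plus both strand
    counts, tagged ``caller="error_model"``.  With ``keep_all_tests`` every
    test is returned regardless of q (used for calibration checks).
    """
    alt_m, depth_m = _pivot_counts(pileups)
    site_info = (
        pileups[["site_id", "chrom", "pos", "ref", "alt"]]
        .drop_duplicates("site_id")
        .set_index("site_id")
    )
    ctype = metadata.set_index("sample_id")["cell_type"]
    samples = [s for s in alt_m.columns]
    missing = [s for s in samples if s not in ctype.index]
    if missing:
        raise ConfigurationError(f"samples without metadata: {missing[:5]}")

    targets = cell_types if cell_types is not None else sorted(
        set(ctype.loc[samples]) & set(design.pools)
    )
    rows: list[pd.DataFrame] = []
    for ct in targets:
        pool = design.background_for(ct)
        bg_samples = [s for s in samples if ctype[s] in pool]
        test_samples = [s for s in samples if ctype[s] == ct]
        if len(bg_samples) < 2:
            raise ConfigurationError(
                f"background pool for cell type {ct!r} has {len(bg_samples)} samples (need >= 2)"
            )
        if not test_samples:
            continue
        batch = _call_batch(
            alt_m, depth_m, bg_samples, test_samples,
            q_cutoff if not keep_all_tests else None, rho_min,
        )
        if batch is not None:
            rows.append(batch)

    if not rows:
        cols = [
            "site_id", "chrom", "pos", "ref", "alt", "sample_id", "vaf",
            "alt_reads", "depth", "alt_fwd", "alt_rev", "lambda", "p", "q", "caller",
        ]
        return pd.DataFrame(columns=cols)

    calls = pd.concat(rows, ignore_index=True)
    calls = calls.join(site_info, on="site_id")
    strand = (
        pileups.set_index(["site_id", "sample_id"])[["alt_fwd", "alt_rev"]]
    )
    calls = calls.join(strand, on=["site_id", "sample_id"])
    calls["caller"] = "error_model"
    calls = calls[
        [
            "site_id", "chrom", "pos", "ref", "alt", "sample_id", "vaf",
            "alt_reads", "depth", "alt_fwd", "alt_rev", "lambda", "p", "q", "caller",
        ]
    ]
    return calls.sort_values(["chrom", "pos", "sample_id"], kind="mergesort").reset_index(drop=True)


def _call_batch(alt_m, depth_m, bg_samples, test_samples, q_cutoff,
                rho_min=DEFAULT_RHO_MIN):
    """Vectorized batch LRT; numerically identical to lrt_one_sample."""
    xb = alt_m[bg_samples].to_numpy(dtype=float)      # (sites, n_bg)
    nb = depth_m[bg_samples].to_numpy(dtype=float)
    xt = alt_m[test_samples].to_numpy(dtype=float)    # (sites, n_test)
    nt = depth_m[test_samples].to_numpy(dtype=float)
    n_sites, n_test = xt.shape

    rho = np.maximum(_rho_mom_rows(xb, nb), rho_min)   # (sites,)
    w_b = 1.0 / (1.0 + np.maximum(nb - 1.0, 0.0) * rho[:, None])
    swx = np.sum(xb * w_b, axis=1)
    swn = np.sum(nb * w_b, axis=1)
    mu_bg = np.where(swn > 0, swx / np.maximum(swn, 1e-300), MU_FLOOR)
    mu_bg = np.clip(mu_bg, MU_FLOOR, 1.0 - MU_FLOOR)

    with np.errstate(divide="ignore", invalid="ignore"):
        mu_test = np.where(nt > 0, xt / np.maximum(nt, 1e-300), MU_FLOOR)
    mu_test = np.clip(mu_test, MU_FLOOR, 1.0 - MU_FLOOR)

    p = np.ones((n_sites, n_test))
    lam = np.zeros((n_sites, n_test))
    # only an excess over the background can produce p < 1
    mask = (xt > 0) & (mu_test > mu_bg[:, None]) & (nt > 0)
    if np.any(mask):
        sites_idx, test_idx = np.nonzero(mask)
        rho_k = rho[sites_idx]
        xt_k = xt[mask]
        nt_k = nt[mask]
        w_t = 1.0 / (1.0 + np.maximum(nt_k - 1.0, 0.0) * rho_k)
        mu_null = (swx[sites_idx] + xt_k * w_t) / np.maximum(
            swn[sites_idx] + nt_k * w_t, 1e-300
        )
        mu_null = np.clip(mu_null, MU_FLOOR, 1.0 - MU_FLOOR)

        xb_k = xb[sites_idx]                            # (k, n_bg)
        nb_k = nb[sites_idx]
        ll_bg_null = np.sum(
            _bb_loglik_terms(xb_k, nb_k, mu_null[:, None], rho_k[:, None]), axis=1
        )
        ll_bg_alt = np.sum(
            _bb_loglik_terms(xb_k, nb_k, mu_bg[sites_idx, None], rho_k[:, None]), axis=1
        )
        ll_t_null = _bb_loglik_terms(xt_k, nt_k, mu_null, rho_k)
        ll_t_alt = _bb_loglik_terms(xt_k, nt_k, mu_test[mask], rho_k)
        lam_k = np.maximum(0.0, 2.0 * (ll_bg_alt + ll_t_alt - ll_bg_null - ll_t_null))
        lam[mask] = lam_k
        p[mask] = np.maximum(0.5 * stats.chi2.sf(lam_k, df=1), _P_FLOOR)

    q = bh_adjust(p.ravel()).reshape(p.shape)
    keep = np.ones_like(p, dtype=bool) if q_cutoff is None else (q <= q_cutoff)
    if not np.any(keep):
        return None
    si, ti = np.nonzero(keep)
    return pd.DataFrame(
        {
            "site_id": alt_m.index.to_numpy()[si],
            "sample_id": np.asarray(test_samples, dtype=object)[ti],
            "vaf": mu_test[keep],
            "alt_reads": xt[keep].astype(int),
            "depth": nt[keep].astype(int),
            "lambda": lam[keep],
            "p": p[keep],
            "q": q[keep],
        }
    )


def _rho_mom_rows(xb: np.ndarray, nb: np.ndarray) -> np.ndarray:
    """Row-wise Kleinman moment estimate of rho (sites x samples input)."""
    pos = nb > 0
    k = pos.sum(axis=1).astype(float)
    ntot = nb.sum(axis=1)
    xtot = xb.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_hat = np.where(ntot > 0, xtot / np.maximum(ntot, 1e-300), 0.0)
        p_i = np.where(pos, xb / np.maximum(nb, 1e-300), 0.0)
        s = np.sum(np.where(pos, nb * (p_i - p_hat[:, None]) ** 2, 0.0), axis=1)
        denom = ntot - np.sum(nb**2, axis=1) / np.maximum(ntot, 1e-300) - (k - 1.0)
        pq = p_hat * (1.0 - p_hat)
        rho = np.where(
            (pq > 0) & (denom > 0) & (k >= 2),
            (s / np.maximum(pq, 1e-300) - (k - 1.0)) / np.maximum(denom, 1e-300),
            RHO_FLOOR,
        )
    return np.clip(rho, RHO_FLOOR, 1.0 - 1e-6)
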
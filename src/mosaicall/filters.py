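"""Post-calling filter cascade and call-set merging.

Each call is annotated with every filter flag it fails; the retained set is
exactly the set with no flags, and flag computation is independent of
evaluation order.  Coordinates are 1-based fully closed throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilterConfig",
    "FILTER_NAMES",
    "pooled_vaf",
    "near_indel",
    "apply_filters",
    "merge_callsets",
    "DataIntegrityError",
]

FILTER_NAMES = (
    "germline",
    "low_coverage",
    "high_vaf",
    "low_vaf",
    "few_alt_reads",
    "strand",
    "near_indel",
    "common_population_allele",
    "fdr",
)


class DataIntegrityError(ValueError):
    pass


@dataclass(frozen=True)
class FilterConfig:
    germline_pooled_vaf_max: float = 0.20
    min_coverage: int = 50
    max_vaf: float = 0.35
    min_vaf: float = 0.003
    min_alt_reads: int = 4
    require_both_strands: bool = True
    indel_window: int = 10
    pop_af_max: float = 0.01
    q_max: float = 0.01
    germline_by_donor: bool = False     # pool the 20% germline rule per donor
    flag_high_background: bool = False  # stand-in for manual curation of noisy sites

    def __post_init__(self) -> None:
        if not (0.0 < self.min_vaf < self.max_vaf <= 1.0):
            raise ValueError("require 0 < min_vaf < max_vaf <= 1")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.indel_window < 0:
            raise ValueError("indel_window must be >= 0")


def pooled_vaf(pileups: pd.DataFrame, site_id: str) -> float:
    """Alt reads over depth summed across *all* samples at one site."""
    sub = pileups.loc[pileups["site_id"] == site_id]
    if sub.empty:
        raise KeyError(site_id)
    depth = float((sub["depth_fwd"] + sub["depth_rev"]).sum())
    if depth == 0:
        return 0.0
    return float((sub["alt_fwd"] + sub["alt_rev"]).sum()) / depth


def _pooled_vaf_by_site(pileups: pd.DataFrame, by: list[str] | None = None) -> pd.Series:
    keys = ["site_id"] + (by or [])
    g = pileups.assign(
        alt_n=pileups["alt_fwd"] + pileups["alt_rev"],
        depth_n=pileups["depth_fwd"] + pileups["depth_rev"],
    ).groupby(keys)[["alt_n", "depth_n"]].sum()
    return (g["alt_n"] / g["depth_n"].replace(0, np.nan)).fillna(0.0)


def near_indel(pos: int, indel_sites, window: int) -> bool:
    """True iff an indel lies within ``window`` bp (inclusive) on the contig."""
    arr = np.asarray(sorted(indel_sites), dtype=float)
    if arr.size == 0:
        return False
    i = np.searchsorted(arr, pos)
    best = np.inf
    if i < arr.size:
        best = min(best, abs(arr[i] - pos))
    if i > 0:
        best = min(best, abs(arr[i - 1] - pos))
    return bool(best <= window)


def apply_filters(
    callset: pd.DataFrame,
    pileups: pd.DataFrame,
    config: FilterConfig = FilterConfig(),
    pop_af: pd.DataFrame | None = None,
    indel_sites: pd.DataFrame | None = None,
    *,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Annotate calls with failed-filter flags and a ``retained`` column.

    ``pop_af`` has columns (chrom, pos, ref, alt, af); missing entries count
    as allele frequency 0.  ``indel_sites`` has columns (chrom, pos).  The
    per-donor germline option needs ``metadata`` to map samples to donors.
    """
    calls = callset.copy().reset_index(drop=True)
    if calls.empty:
        calls["filter_flags"] = pd.Series(dtype=str)
        calls["retained"] = pd.Series(dtype=bool)
        return calls

    unknown = set(calls["site_id"]) - set(pileups["site_id"])
    if unknown:
        raise KeyError(f"calls reference sites absent from pileups: {sorted(unknown)[:5]}")

    flags = pd.DataFrame(False, index=calls.index, columns=list(FILTER_NAMES))

    if config.germline_by_donor:
        if metadata is None:
            raise ValueError("germline_by_donor requires sample metadata")
        donor_of = metadata.set_index("sample_id")["donor_id"]
        pv = _pooled_vaf_by_site(
            pileups.assign(donor_id=pileups["sample_id"].map(donor_of)), by=["donor_id"]
        )
        key = pd.MultiIndex.from_arrays(
            [calls["site_id"], calls["sample_id"].map(donor_of)]
        )
        site_vaf = pd.Series(pv.reindex(key).to_numpy(), index=calls.index).fillna(0.0)
    else:
        pv = _pooled_vaf_by_site(pileups)
        site_vaf = pd.Series(
            pv.reindex(calls["site_id"]).to_numpy(), index=calls.index
        ).fillna(0.0)
    flags["germline"] = site_vaf > config.germline_pooled_vaf_max

    depth = calls["depth"].astype(float)
    alt_reads = (
        calls["alt_reads"].astype(float)
        if "alt_reads" in calls
        else (calls["alt_fwd"] + calls["alt_rev"]).astype(float)
    )
    vaf = calls["vaf"].astype(float)
    flags["low_coverage"] = depth < config.min_coverage
    flags["high_vaf"] = vaf > config.max_vaf
    flags["low_vaf"] = vaf < config.min_vaf
    flags["few_alt_reads"] = alt_reads < config.min_alt_reads
    if config.require_both_strands:
        flags["strand"] = (calls["alt_fwd"] < 1) | (calls["alt_rev"] < 1)

    if indel_sites is not None and len(indel_sites):
        by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in indel_sites.groupby("chrom")}
        flags["near_indel"] = [
            near_indel(p, by_chrom.get(c, ()), config.indel_window)
            for c, p in zip(calls["chrom"], calls["pos"])
        ]

    if pop_af is not None and len(pop_af):
        af_map = pop_af.set_index(["chrom", "pos", "ref", "alt"])["af"]
        key = pd.MultiIndex.from_frame(calls[["chrom", "pos", "ref", "alt"]])
        af = pd.Series(af_map.reindex(key).to_numpy(), index=calls.index).fillna(0.0)
        flags["common_population_allele"] = af >= config.pop_af_max

    if "q" in calls:
        q = calls["q"].astype(float)
        flags["fdr"] = q.notna() & (q > config.q_max)

    if config.flag_high_background:
        noisy = _high_background_sites(pileups, config)
        calls["high_background"] = calls["site_id"].isin(noisy)

    calls["filter_flags"] = [
        ";".join(n for n in FILTER_NAMES if row[n]) for _, row in flags.iterrows()
    ]
    calls["retained"] = ~flags.any(axis=1)
    if config.flag_high_background:
        calls["retained"] &= ~calls["high_background"]
    return calls


def _high_background_sites(pileups: pd.DataFrame, config: FilterConfig) -> set[str]:
    """Sites where >= 50% of samples show VAF in [0.02, germline threshold)."""
    df = pileups.assign(
        vaf=(pileups["alt_fwd"] + pileups["alt_rev"])
        / (pileups["depth_fwd"] + pileups["depth_rev"]).replace(0, np.nan)
    )
    noisy = (df["vaf"] >= 0.02) & (df["vaf"] < config.germline_pooled_vaf_max)
    frac = noisy.groupby(df["site_id"]).mean()
    return set(frac.index[frac >= 0.5])


_MERGE_KEY = ["sample_id", "chrom", "pos", "ref", "alt"]


def merge_callsets(a: pd.DataFrame, b: pd.DataFrame, labels: tuple[str, str] = ("A", "B")) -> pd.DataFrame:
    """Union of two call sets on (sample, chrom, pos, ref, alt).

    Per-call statistics come from caller ``a`` where both called; the
    ``provenance`` column is one of the two labels or ``"both"``.
    """
    la, lb = labels
    a = a.copy().reset_index(drop=True)
    b = b.copy().reset_index(drop=True)
    for df, name in ((a, la), (b, lb)):
        if df.duplicated(_MERGE_KEY).any():
            raise DataIntegrityError(f"duplicate call keys in call set {name}")

    posa = a[["sample_id", "chrom", "pos", "ref"]].drop_duplicates()
    posb = b[["sample_id", "chrom", "pos", "ref"]].drop_duplicates()
    both = posa.merge(posb, on=["sample_id", "chrom", "pos"], suffixes=("_a", "_b"))
    bad = both[both["ref_a"] != both["ref_b"]]
    if len(bad):
        r = bad.iloc[0]
        raise DataIntegrityError(
            f"conflicting ref alleles at {r.chrom}:{r.pos} ({r.ref_a} vs {r.ref_b})"
        )

    a_keys = pd.MultiIndex.from_frame(a[_MERGE_KEY])
    b_keys = pd.MultiIndex.from_frame(b[_MERGE_KEY])
    in_both = a_keys.isin(b_keys)
    a["provenance"] = np.where(in_both, "both", la)
    b_only = b.loc[~b_keys.isin(a_keys)].copy()
    b_only["provenance"] = lb
    merged = pd.concat([a, b_only], ignore_index=True, sort=False)
    return merged.sort_values(_MERGE_KEY, kind="mergesort").reset_index(drop=True)
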
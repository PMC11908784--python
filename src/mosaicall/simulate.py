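"""Synthetic deep-targeted-sequencing cohorts with planted truth.

Generates per-site per-strand allele-count pileups for a case/control
cohort of donors with several sorted cell populations each, a site-level
beta-distributed background error profile, germline heterozygous sites
shared within a donor, and somatic clones planted in designated cell types
with an arm-specific carrier probability.  Everything is reproducible from
a single seed and emitted as plain TSV-compatible data frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "CohortBundle",
    "simulate_error_profile",
    "simulate_pileups",
    "plant_clones",
    "simulate_cohort",
]

_BASES = np.array(["A", "C", "G", "T"])


class InvalidParameterError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    n_donors_case: int = 8
    n_donors_control: int = 8
    cell_types: tuple[str, ...] = ("microglia", "neuron", "glia", "blood")
    samples_per_donor: int = 1          # per cell type
    n_sites: int = 500
    panel_footprint_mb: float = 3.43
    mean_depth: float = 1100.0
    depth_dispersion: float = 0.12      # NB variance = m + disp * m^2; 0 => constant depth
    error_prior_mean: float = 1e-3
    error_prior_dispersion: float = 0.2
    error_site_rho: float = 1e-4        # within-site between-sample overdispersion
    germline_het_fraction: float = 0.01
    clone_vaf_range: tuple[float, float] = (0.01, 0.10)
    clones_per_carrier: tuple[int, int] = (1, 3)
    carrier_prob_case: float = 0.5
    carrier_prob_control: float = 0.1
    pathogenic_prob: float = 0.7
    clone_cell_type: str | None = "microglia"
    age_range: tuple[float, float] = (55.0, 95.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise InvalidParameterError("n_sites must be >= 1")
        if not (0.0 < self.error_prior_mean <= 0.01):
            raise InvalidParameterError("error_prior_mean must be in (0, 0.01]")
        for name in ("carrier_prob_case", "carrier_prob_control", "germline_het_fraction",
                     "pathogenic_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidParameterError(f"{name}={v} outside [0, 1]")
        lo, hi = self.clone_vaf_range
        if not (0.0 < lo <= hi <= 1.0):
            raise InvalidParameterError(f"clone_vaf_range {self.clone_vaf_range} invalid")
        if self.panel_footprint_mb <= 0:
            raise InvalidParameterError("panel_footprint_mb must be > 0")
        if self.depth_dispersion < 0 or self.error_prior_dispersion < 0:
            raise InvalidParameterError("dispersions must be >= 0")
        if self.clone_cell_type is not None and self.clone_cell_type not in self.cell_types:
            raise InvalidParameterError(
                f"clone_cell_type {self.clone_cell_type!r} not in cell_types"
            )


@dataclass(frozen=True)
class CohortBundle:
    """Self-consistent simulated cohort: counts, truth and metadata."""

    pileups: pd.DataFrame
    truth: pd.DataFrame
    metadata: pd.DataFrame
    sites: pd.DataFrame
    pathogenicity: pd.DataFrame
    config: SimulationConfig


def simulate_error_profile(
    n_sites: int, prior_mean: float, prior_dispersion: float, seed: int
) -> np.ndarray:
    """Per-site background error rates drawn from a beta prior.

    The prior has mean ``prior_mean`` and shape ``a + b = 1/d - 1`` for
    dispersion ``d``; ``d -> 0`` collapses to a point mass at the mean.
    """
    if n_sites < 1:
        raise InvalidParameterError("n_sites must be >= 1")
    if not (0.0 < prior_mean <= 0.01):
        raise InvalidParameterError("prior_mean must be in (0, 0.01]")
    if prior_dispersion < 0:
        raise InvalidParameterError("prior_dispersion must be >= 0")
    if prior_dispersion < 1e-8:
        return np.full(n_sites, prior_mean)
    rng = np.random.default_rng(seed)
    s = 1.0 / prior_dispersion - 1.0
    if s <= 0:
        raise InvalidParameterError("prior_dispersion must be < 1")
    rates = rng.beta(prior_mean * s, (1.0 - prior_mean) * s, size=n_sites)
    return np.clip(rates, 1e-12, 1.0 - 1e-12)


def _donor_frame(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    donors = [f"case{i + 1:03d}" for i in range(config.n_donors_case)] + [
        f"ctrl{i + 1:03d}" for i in range(config.n_donors_control)
    ]
    status = ["case"] * config.n_donors_case + ["control"] * config.n_donors_control
    ages = rng.uniform(*config.age_range, size=len(donors))
    sexes = rng.choice(["F", "M"], size=len(donors))
    return pd.DataFrame(
        {"donor_id": donors, "status": status, "age": np.round(ages, 1), "sex": sexes}
    )


def sample_table(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Deterministic sample sheet: one row per donor x cell type x replicate."""
    rng = rng or np.random.default_rng(config.seed)
    donors = _donor_frame(config, rng)
    regions = ["cortex", "hippocampus"]
    rows = []
    for _, d in donors.iterrows():
        for ct in config.cell_types:
            for k in range(config.samples_per_donor):
                rows.append(
                    {
                        "sample_id": f"{d.donor_id}:{ct}:{k + 1}",
                        "donor_id": d.donor_id,
                        "cell_type": ct,
                        "region": "blood" if ct == "blood" else regions[k % len(regions)],
                        "age": d.age,
                        "sex": d.sex,
                        "status": d.status,
                        "panel_mb": config.panel_footprint_mb,
                    }
                )
    return pd.DataFrame(rows)


def site_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_sites
    n_genes = max(1, min(48, n))
    per_gene = math.ceil(n / n_genes)
    idx = np.arange(n)
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    return pd.DataFrame(
        {
            "site_id": [f"S{i + 1:06d}" for i in idx],
            "chrom": np.where(idx < n / 2, "chr1", "chr2"),
            "pos": (1000 + 25 * idx).astype(int),
            "ref": _BASES[ref_i],
            "alt": _BASES[alt_i],
            "gene": [f"G{(i // per_gene) + 1:03d}" for i in idx],
        }
    )


def simulate_pileups(
    error_profile: np.ndarray,
    config: SimulationConfig,
    *,
    seed: int | None = None,
    samples: pd.DataFrame | None = None,
    sites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Background-only pileups: depth ~ NB around the mean, alt ~ beta-binomial.

    Strand assignment is sampling without replacement (hypergeometric), so
    per-strand alt counts never exceed per-strand depth.
    """
    error_profile = np.asarray(error_profile, dtype=float)
    if len(error_profile) != config.n_sites:
        raise InvalidParameterError("error profile length must equal n_sites")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if samples is None:
        samples = sample_table(config, np.random.default_rng(config.seed))
    if sites is None:
        sites = site_table(config, np.random.default_rng(config.seed + 1))

    n_sites, n_samples = config.n_sites, len(samples)
    m = config.mean_depth
    if config.depth_dispersion < 1e-12:
        depth = np.full((n_sites, n_samples), int(round(m)), dtype=np.int64)
    else:
        size = 1.0 / config.depth_dispersion
        depth = rng.negative_binomial(size, size / (size + m), size=(n_sites, n_samples))

    e = error_profile[:, None]
    rho = config.error_site_rho
    if rho < 1e-8:
        p = np.broadcast_to(e, (n_sites, n_samples))
    else:
        s = 1.0 / rho - 1.0
        a = np.clip(e * s, 1e-12, None)
        b = np.clip((1.0 - e) * s, 1e-12, None)
        p = rng.beta(a, b, size=(n_sites, n_samples))
    p = np.where(e == 0.0, 0.0, p)
    alt = rng.binomial(depth, p)

    return _assemble_pileups(depth, alt, samples, sites, rng)


def _assemble_pileups(depth, alt, samples, sites, rng) -> pd.DataFrame:
    n_sites, n_samples = depth.shape
    depth_fwd = rng.binomial(depth, 0.5)
    alt_fwd = rng.hypergeometric(
        np.maximum(depth_fwd, 0), np.maximum(depth - depth_fwd, 0), alt
    )
    long = pd.DataFrame(
        {
            "site_id": np.repeat(sites["site_id"].to_numpy(), n_samples),
            "chrom": np.repeat(sites["chrom"].to_numpy(), n_samples),
            "pos": np.repeat(sites["pos"].to_numpy(), n_samples),
            "ref": np.repeat(sites["ref"].to_numpy(), n_samples),
            "alt": np.repeat(sites["alt"].to_numpy(), n_samples),
            "sample_id": np.tile(samples["sample_id"].to_numpy(), n_sites),
            "depth_fwd": depth_fwd.ravel(),
            "depth_rev": (depth - depth_fwd).ravel(),
            "alt_fwd": alt_fwd.ravel(),
            "alt_rev": (alt - alt_fwd).ravel(),
        }
    )
    return long


def plant_clones(
    pileups: pd.DataFrame,
    config: SimulationConfig,
    seed: int,
    *,
    samples: pd.DataFrame | None = None,
    sites: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant germline heterozygous sites and somatic clones into pileups.

    Clone alt counts *replace* the background draw with a binomial at the
    target VAF, so the expected VAF is exact.  Returns the modified pileups
    and a truth table covering every insertion.
    """
    rng = np.random.default_rng(seed)
    if samples is None:
        samples = sample_table(config, np.random.default_rng(config.seed))
    if sites is None:
        sites = site_table(config, np.random.default_rng(config.seed + 1))
    lo, hi = config.clone_vaf_range
    if hi > 1.0:
        raise InvalidParameterError("clone VAF above 1")

    pil = pileups.copy()
    pil["_row"] = np.arange(len(pil))
    by_key = pil.set_index(["site_id", "sample_id"])["_row"]
    site_lookup = sites.set_index("site_id")
    donors = samples.drop_duplicates("donor_id")[["donor_id", "status"]]

    n_germ = int(round(config.germline_het_fraction * config.n_sites))
    truth_rows: list[dict] = []
    edits: list[tuple[np.ndarray, float]] = []  # (row indices, target vaf)
    used_sites: set[str] = set()

    # germline hets are drawn from one shared polymorphic-site pool (as real
    # SNPs are); each donor is heterozygous at a random subset of the pool,
    # and somatic clones are never planted inside the pool
    germ_pool = (
        rng.choice(sites["site_id"].to_numpy(), size=n_germ, replace=False)
        if n_germ > 0
        else np.array([], dtype=object)
    )

    for _, d in donors.iterrows():
        donor_samples = samples.loc[samples["donor_id"] == d.donor_id, "sample_id"]
        if n_germ > 0:
            het = rng.random(n_germ) < 0.5
            if not het.any():
                het[rng.integers(0, n_germ)] = True
            germ_sites = germ_pool[het]
            for sid in germ_sites:
                rows = by_key.loc[[(sid, s) for s in donor_samples]].to_numpy()
                edits.append((rows, 0.5))
                truth_rows.append(
                    _truth_row(d.donor_id, donor_samples, sid, site_lookup, 0.5,
                               "germline_het", False, "all")
                )

        p_carrier = (
            config.carrier_prob_case if d.status == "case" else config.carrier_prob_control
        )
        if rng.random() >= p_carrier:
            continue
        k_lo, k_hi = config.clones_per_carrier
        n_clones = int(rng.integers(k_lo, k_hi + 1))
        blocked = used_sites | set(germ_pool)
        pool = sites.loc[~sites["site_id"].isin(blocked), "site_id"].to_numpy()
        n_clones = min(n_clones, len(pool))
        clone_sites = rng.choice(pool, size=n_clones, replace=False)
        for sid in clone_sites:
            used_sites.add(sid)
            vaf = float(rng.uniform(lo, hi))
            ct = config.clone_cell_type or str(rng.choice(list(config.cell_types)))
            carrier_samples = samples.loc[
                (samples["donor_id"] == d.donor_id) & (samples["cell_type"] == ct),
                "sample_id",
            ]
            rows = by_key.loc[[(sid, s) for s in carrier_samples]].to_numpy()
            edits.append((rows, vaf))
            pathogenic = bool(rng.random() < config.pathogenic_prob)
            truth_rows.append(
                _truth_row(d.donor_id, carrier_samples, sid, site_lookup, vaf,
                           "somatic_clone", pathogenic, ct)
            )

    if edits:
        rows = np.concatenate([r for r, _ in edits])
        vafs = np.concatenate([np.full(len(r), v) for r, v in edits])
        depth = (pil["depth_fwd"].to_numpy() + pil["depth_rev"].to_numpy())[rows]
        new_alt = rng.binomial(depth, vafs)
        dfwd = pil["depth_fwd"].to_numpy()[rows]
        new_alt_fwd = rng.hypergeometric(dfwd, depth - dfwd, new_alt)
        pil.loc[pil.index[rows], "alt_fwd"] = new_alt_fwd
        pil.loc[pil.index[rows], "alt_rev"] = new_alt - new_alt_fwd

    truth = pd.DataFrame(
        truth_rows,
        columns=["donor_id", "sample_ids", "site_id", "chrom", "pos", "ref", "alt",
                 "gene", "true_vaf", "category", "pathogenic_flag", "cell_type"],
    )
    return pil.drop(columns="_row"), truth


def _truth_row(donor_id, sample_ids, site_id, site_lookup, vaf, category, pathogenic, ct):
    info = site_lookup.loc[site_id]
    return {
        "donor_id": donor_id,
        "sample_ids": ",".join(sample_ids),
        "site_id": site_id,
        "chrom": info["chrom"],
        "pos": int(info["pos"]),
        "ref": info["ref"],
        "alt": info["alt"],
        "gene": info["gene"],
        "true_vaf": vaf,
        "category": category,
        "pathogenic_flag": pathogenic,
        "cell_type": ct,
    }


def _pathogenicity_table(truth: pd.DataFrame, sites: pd.DataFrame,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Annotation rows for planted pathogenic clones plus benign decoys."""
    rows = []
    for _, t in truth.iterrows():
        if t.category != "somatic_clone":
            continue
        label = "Pathogenic" if t.pathogenic_flag else "Benign"
        onco = "Oncogenic" if (t.pathogenic_flag and rng.random() < 0.5) else ""
        rows.append(
            {
                "gene": t.gene,
                "protein_change": f"p.X{int(t.pos) % 997}Y",
                "chrom": t.chrom,
                "pos": int(t.pos),
                "ref": t.ref,
                "alt": t.alt,
                "clinvar_label": label,
                "oncokb_label": onco,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "protein_change", "chrom", "pos", "ref", "alt",
                 "clinvar_label", "oncokb_label"],
    ).drop_duplicates(["chrom", "pos", "ref", "alt"])


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Full bundle: metadata, background pileups with planted truth, annotations."""
    if config.n_donors_case == 0 and config.n_donors_control == 0:
        raise ConfigurationError("need at least one donor in one arm")
    root = np.random.SeedSequence(config.seed)
    s_meta, s_sites, s_err, s_pile, s_plant, s_annot = [
        int(s.generate_state(1)[0]) for s in root.spawn(6)
    ]
    samples = sample_table(config, np.random.default_rng(s_meta))
    sites = site_table(config, np.random.default_rng(s_sites))
    profile = simulate_error_profile(
        config.n_sites, config.error_prior_mean, config.error_prior_dispersion, s_err
    )
    pileups = simulate_pileups(profile, config, seed=s_pile, samples=samples, sites=sites)
    pileups, truth = plant_clones(pileups, config, s_plant, samples=samples, sites=sites)
    patho = _pathogenicity_table(truth, sites, np.random.default_rng(s_annot))
    return CohortBundle(pileups, truth, samples, sites, patho, config)
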
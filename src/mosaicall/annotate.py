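"""Pathogenicity classification, gene-set tagging and mutational burden.

Burden is defined as retained somatic SNVs per megabase of sequenced
footprint, computed per sample and averaged per donor within a cell type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PathogenicityTable",
    "GeneSetCatalog",
    "PanelDefinition",
    "classify_pathogenic",
    "classify_candidate_deleterious",
    "assign_gene_sets",
    "annotate_calls",
    "sample_burden",
    "burden_table",
    "donor_burden",
    "CLASSICAL_MAPK_GENES",
    "default_catalog",
]

P_SNV = "P_SNV"
NOT_CLASSIFIED = "not_classified"

_CLINVAR_PATHOGENIC = {"pathogenic", "likely_pathogenic"}
_ONCOKB_PATHOGENIC = {"oncogenic", "likely_oncogenic", "predicted_oncogenic"}

#: RASopathy gene set used to tag classical MAPK-pathway variants.
CLASSICAL_MAPK_GENES = frozenset(
    {
        "BRAF", "CBL", "KRAS", "MAP2K1", "NF1", "PTPN11", "SOS1", "RIT1",
        "SHOC2", "NRAS", "RAF1", "RASA1", "HRAS", "MAP2K2", "SPRED1",
    }
)


def _norm_label(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    return str(value).strip().lower().replace(" ", "_").replace("-", "_")


@dataclass(frozen=True)
class PanelDefinition:
    name: str
    genes: tuple[str, ...]
    footprint_mb: float

    def __post_init__(self) -> None:
        if self.footprint_mb <= 0:
            raise ValueError("footprint_mb must be > 0")


class PathogenicityTable:
    """ClinVar/OncoKB-style labels keyed by (gene, protein change) with a
    genomic (chrom, pos, ref, alt) fallback."""

    def __init__(self, table: pd.DataFrame):
        self._df = table.copy()
        self._by_protein = {}
        self._by_genomic = {}
        for _, r in table.iterrows():
            labels = (_norm_label(r.get("clinvar_label")), _norm_label(r.get("oncokb_label")))
            gene = str(r.get("gene", "")).upper()
            pc = str(r.get("protein_change", "") or "")
            if gene and pc:
                self._by_protein[(gene, pc)] = labels
            if not pd.isna(r.get("pos", np.nan)):
                self._by_genomic[(r["chrom"], int(r["pos"]), r["ref"], r["alt"])] = labels

    def lookup(self, variant) -> tuple[str, str] | None:
        gene = str(variant.get("gene", "")).upper()
        pc = str(variant.get("protein_change", "") or "")
        hit = self._by_protein.get((gene, pc))
        if hit is not None:
            return hit
        try:
            key = (variant["chrom"], int(variant["pos"]), variant["ref"], variant["alt"])
        except (KeyError, TypeError, ValueError):
            return None
        return self._by_genomic.get(key)


def classify_pathogenic(variant, table: PathogenicityTable) -> str:
    """``P_SNV`` iff ClinVar says (likely) pathogenic OR OncoKB says
    (likely/predicted) oncogenic; case-insensitive; unknowns pass through."""
    hit = table.lookup(variant)
    if hit is None:
        return NOT_CLASSIFIED
    clinvar, oncokb = hit
    if clinvar in _CLINVAR_PATHOGENIC or oncokb in _ONCOKB_PATHOGENIC:
        return P_SNV
    return NOT_CLASSIFIED


def classify_candidate_deleterious(scores) -> bool:
    """Consensus deleteriousness: all four predictors must agree.

    polyphen in {possibly_damaging, probably_damaging} AND sift deleterious
    AND cadd_msc high AND fathmm pathogenic; any missing predictor => False.
    """
    polyphen = _norm_label(scores.get("polyphen"))
    sift = _norm_label(scores.get("sift"))
    cadd = _norm_label(scores.get("cadd_msc"))
    fathmm = _norm_label(scores.get("fathmm"))
    return (
        polyphen in {"possibly_damaging", "probably_damaging"}
        and sift == "deleterious"
        and cadd == "high"
        and fathmm == "pathogenic"
    )


class GeneSetCatalog:
    """Named gene sets with uppercase, deduplicated symbols."""

    def __init__(self, sets: dict[str, set[str] | frozenset[str] | list[str]]):
        self.sets = {name: frozenset(g.upper() for g in genes) for name, genes in sets.items()}

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCatalog":
        sets = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 3:
                    sets[parts[0]] = set(parts[2:])
        return cls(sets)


def default_catalog() -> GeneSetCatalog:
    return GeneSetCatalog({"classical_MAPK": set(CLASSICAL_MAPK_GENES)})


def assign_gene_sets(variant, catalog: GeneSetCatalog) -> set[str]:
    gene = str(variant.get("gene", "")).upper()
    return {name for name, members in catalog.sets.items() if gene in members}


def annotate_calls(
    calls: pd.DataFrame,
    table: PathogenicityTable,
    catalog: GeneSetCatalog | None = None,
    sites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Add ``gene`` (from the site table), ``pathogenicity`` and ``gene_sets``."""
    out = calls.copy()
    if sites is not None and "gene" not in out.columns:
        out = out.join(sites.set_index("site_id")["gene"], on="site_id")
    out["pathogenicity"] = [
        classify_pathogenic(row, table) for row in out.to_dict("records")
    ]
    if catalog is not None:
        out["gene_sets"] = [
            ";".join(sorted(assign_gene_sets(row, catalog)))
            for row in out.to_dict("records")
        ]
    return out


def sample_burden(
    callset: pd.DataFrame,
    footprint_mb: float,
    *,
    sample_id: str | None = None,
    cell_type: str | None = None,
    subset: str = "all_SNV",
    selector=None,
) -> dict:
    """Burden record for one sample: retained calls / footprint in Mb."""
    if footprint_mb <= 0:
        raise ValueError("footprint_mb must be > 0")
    calls = callset
    if "retained" in calls.columns:
        calls = calls.loc[calls["retained"]]
    if sample_id is not None:
        calls = calls.loc[calls["sample_id"] == sample_id]
    if selector is not None:
        calls = calls.loc[calls.apply(selector, axis=1)] if len(calls) else calls
    n = int(len(calls))
    return {
        "sample_id": sample_id,
        "cell_type": cell_type,
        "n_variants": n,
        "footprint_mb": footprint_mb,
        "burden": n / footprint_mb,
        "subset": subset,
    }


def burden_table(
    calls: pd.DataFrame,
    metadata: pd.DataFrame,
    *,
    subset: str = "all_SNV",
    pathogenic_only: bool = False,
    gene_list: set[str] | None = None,
) -> pd.DataFrame:
    """Per-sample burden for every sample in the metadata (zeros included)."""
    df = calls
    if "retained" in df.columns:
        df = df.loc[df["retained"]]
    if pathogenic_only:
        df = df.loc[df["pathogenicity"] == P_SNV]
    if gene_list is not None:
        genes = {g.upper() for g in gene_list}
        df = df.loc[df["gene"].astype(str).str.upper().isin(genes)]
    counts = df.groupby("sample_id").size()
    meta = metadata.set_index("sample_id")
    n = counts.reindex(meta.index).fillna(0).astype(int)
    out = pd.DataFrame(
        {
            "sample_id": meta.index,
            "donor_id": meta["donor_id"].to_numpy(),
            "cell_type": meta["cell_type"].to_numpy(),
            "status": meta["status"].to_numpy(),
            "age": meta["age"].to_numpy(),
            "sex": meta["sex"].to_numpy(),
            "n_variants": n.to_numpy(),
            "footprint_mb": meta["panel_mb"].to_numpy(),
            "subset": subset,
        }
    ).reset_index(drop=True)
    if (out["footprint_mb"] <= 0).any():
        raise ValueError("footprint_mb must be > 0 for every sample")
    out["burden"] = out["n_variants"] / out["footprint_mb"]
    return out


def donor_burden(records: pd.DataFrame) -> pd.DataFrame:
    """Mean sample burden within (donor, cell type, subset); empty groups absent."""
    if records.empty:
        return records.copy()
    keys = ["donor_id", "cell_type", "subset"]
    extra = [c for c in ("status", "age", "sex") if c in records.columns]
    agg = {"burden": ("burden", "mean"), "n_samples": ("burden", "size")}
    for c in extra:
        agg[c] = (c, "first")
    return records.groupby(keys, as_index=False).agg(**agg)
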
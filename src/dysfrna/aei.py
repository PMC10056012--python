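"""Allele-expression-imbalance (AEI) estimation and cis/trans phasing.

A heterozygous SNV in cis with the sample's sole decay-triggering PTV is
depleted to a lesser-allele fraction of about (1-e)/(2-e) ≈ 25% by
nonsense-mediated decay; a consistent ~75:25 ratio across SNVs therefore
phases candidate variants in trans without parental sequencing.  Biallelic
PTV samples return to ~50:50 (both transcripts decayed) and cannot be phased
this way.  Same-region read-backed phasing covers the remaining cases: two
variants covered by the same read pairs are in trans when only the two
single-alt haplotypes are observed, and in cis when the double-alt (and
double-ref) haplotypes dominate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genemodel import (
    ContractError,
    GeneModel,
    Variant,
    locate,
    nmd_triggering,
)

__all__ = [
    "AEIConfig",
    "AEIResult",
    "PhaseCall",
    "allele_fraction",
    "relative_abundance",
    "aggregate_aei",
    "phase_by_aei",
    "phase_by_same_region",
    "aei_table",
]

SNV_CLASSES = {"synonymous", "missense", "nonsense"}
INDEL_CLASSES = {"frameshift_indel", "inframe_indel"}


@dataclass
class AEIConfig:
    """Thresholds for AEI aggregation and trans calling (all configurable;
    the published pattern reports no cutoffs, these separate the closed-form
    regimes at default depth)."""

    min_depth: int = 20
    min_snvs: int = 3
    lesser_band: tuple[float, float] = (0.15, 0.35)
    max_sd: float = 0.10
    escape_window: int = 50


@dataclass
class AEIResult:
    sample_id: str
    per_variant_lesser: dict[str, float] = field(default_factory=dict)
    mean_fraction_A: Optional[float] = None
    mean_fraction_B: Optional[float] = None
    sd_fraction: Optional[float] = None
    mean_lesser: Optional[float] = None
    sd_lesser: Optional[float] = None
    n_informative_snvs: int = 0
    relative_abundance: Optional[float] = None
    allele_abundance_A: Optional[float] = None
    allele_abundance_B: Optional[float] = None
    ptv_count: int = 0
    ptv_ids: tuple[str, ...] = ()
    partner_ids: tuple[str, ...] = ()
    flags: set[str] = field(default_factory=set)

    def to_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "n_informative_snvs": self.n_informative_snvs,
            "mean_fraction_A": self.mean_fraction_A,
            "mean_fraction_B": self.mean_fraction_B,
            "mean_lesser": self.mean_lesser,
            "sd_lesser": self.sd_lesser,
            "relative_abundance": self.relative_abundance,
            "allele_abundance_A": self.allele_abundance_A,
            "allele_abundance_B": self.allele_abundance_B,
            "ptv_count": self.ptv_count,
            "flags": ",".join(sorted(self.flags)),
        }


@dataclass
class PhaseCall:
    pair: tuple[str, str]
    call: str       # trans / cis / indeterminate
    method: str     # aei / same_region_reads / external
    rationale: str

    def to_row(self) -> dict:
        return {
            "variant_1": self.pair[0], "variant_2": self.pair[1],
            "call": self.call, "method": self.method, "rationale": self.rationale,
        }


def allele_fraction(ref_count: int, alt_count: int) -> tuple[float, float]:
    """Alt-allele fraction and lesser-allele fraction at one site."""
    depth = ref_count + alt_count
    if depth < 1:
        raise ContractError("allele_fraction needs at least one read")
    alt = alt_count / depth
    return alt, min(alt, 1.0 - alt)


def relative_abundance(
    sample_gene: float,
    sample_panel: float,
    controls: Sequence[tuple[float, float]],
) -> float:
    """Gene abundance relative to controls, panel-total normalized.

    The gene's read total is taken as a share of the sample's whole panel
    total (targeted-panel normalization), then divided by the control mean of
    the same statistic.
    """
    if not controls:
        raise ContractError("at least one control sample is required")
    ctrl = [g / p for g, p in controls]
    m = float(np.mean(ctrl))
    if m <= 0:
        raise ContractError("control mean abundance is zero")
    return (sample_gene / sample_panel) / m


def _variant_from_row(row: Mapping) -> Variant:
    return Variant(
        row["variant_id"].split(":")[-1] if ":" in str(row["variant_id"]) else row["variant_id"],
        row["v_class"],
        zygosity=row.get("zygosity", "het"),
        allele=row.get("allele") or None,
        is_ptv=bool(row["is_ptv"]) if "is_ptv" in row else None,
    )


def aggregate_aei(
    records: pd.DataFrame,
    variants: pd.DataFrame,
    model: GeneModel,
    cfg: Optional[AEIConfig] = None,
    gene_abundance: Optional[tuple[float, float]] = None,
    controls: Optional[Sequence[tuple[float, float]]] = None,
) -> AEIResult:
    """Aggregate one sample's allele counts into an AEI summary.

    Informative sites are heterozygous substitution SNVs in constitutively
    included exons passing the depth filter; indels and variable-exon sites
    are flagged and excluded (they follow the pattern with less accuracy).
    Orientation assigns each site's alt fraction to its haplotype so that
    mean_fraction_A + mean_fraction_B = 1.
    """
    cfg = cfg or AEIConfig()
    if records.empty:
        raise ContractError("no allele-count records supplied")
    sample_id = str(records["sample_id"].iloc[0])
    res = AEIResult(sample_id=sample_id)

    vinfo = {str(r["variant_id"]): r for _, r in variants.iterrows()}
    frac_A: list[float] = []
    lessers: list[float] = []
    for _, rec in records.iterrows():
        vid = str(rec["variant_id"])
        row = vinfo.get(vid)
        if row is None:
            continue
        v = _variant_from_row(row)
        depth = int(rec["ref_count"]) + int(rec["alt_count"])
        if depth < cfg.min_depth:
            res.flags.add("low_depth")
            continue
        alt, lesser = allele_fraction(int(rec["ref_count"]), int(rec["alt_count"]))
        if v.zygosity == "hom":
            continue
        if v.v_class in INDEL_CLASSES:
            res.flags.add("indel_site")
            continue
        if v.v_class not in SNV_CLASSES:
            continue
        _, in_variable = locate(v, model)
        if in_variable:
            res.flags.add("variable_exon_site")
            continue
        res.per_variant_lesser[vid] = lesser
        lessers.append(lesser)
        hap = row.get("allele") or ""
        if hap == "A":
            frac_A.append(alt)
        elif hap == "B":
            frac_A.append(1.0 - alt)

    res.n_informative_snvs = len(lessers)
    if lessers:
        res.mean_lesser = float(np.mean(lessers))
        res.sd_lesser = float(np.std(lessers, ddof=1)) if len(lessers) > 1 else 0.0
    if frac_A:
        res.mean_fraction_A = float(np.mean(frac_A))
        res.mean_fraction_B = 1.0 - res.mean_fraction_A
        res.sd_fraction = float(np.std(frac_A, ddof=1)) if len(frac_A) > 1 else 0.0
    if res.sd_lesser is not None and res.sd_lesser > cfg.max_sd:
        res.flags.add("inconsistent")

    # decay-triggering PTV count (a homozygous PTV counts for both haplotypes)
    ptv_ids, partners = [], []
    n_trig = 0
    for vid, row in vinfo.items():
        v = _variant_from_row(row)
        if v.is_ptv:
            try:
                trig = nmd_triggering(v, model, cfg.escape_window)
            except Exception:
                continue
            if trig:
                n_trig += 2 if v.zygosity == "hom" else 1
                ptv_ids.append(vid)
            else:
                res.flags.add("last_exon_ptv")
                ptv_ids.append(vid)
        elif ":mkr" not in vid:
            partners.append(vid)
    res.ptv_count = min(n_trig, 2)
    res.ptv_ids = tuple(ptv_ids)
    res.partner_ids = tuple(partners)

    if gene_abundance is not None and controls:
        res.relative_abundance = relative_abundance(
            gene_abundance[0], gene_abundance[1], controls
        )
        if res.mean_fraction_A is not None:
            res.allele_abundance_A = res.mean_fraction_A * res.relative_abundance
            res.allele_abundance_B = res.mean_fraction_B * res.relative_abundance
    return res


def phase_by_aei(aei: AEIResult, cfg: Optional[AEIConfig] = None) -> PhaseCall:
    """Call trans phase from a one-PTV allele-imbalance pattern.

    trans requires exactly one decay-triggering PTV, enough informative SNVs,
    a mean lesser fraction inside the expected decay band, consistency across
    sites, and no disqualifying flag; anything else is indeterminate with the
    reason recorded.
    """
    cfg = cfg or AEIConfig()
    ptv = aei.ptv_ids[0] if aei.ptv_ids else "?"
    partner = aei.partner_ids[0] if aei.partner_ids else "?"
    pair = (ptv, partner)

    def indet(reason: str) -> PhaseCall:
        return PhaseCall(pair, "indeterminate", "aei", reason)

    if aei.ptv_count == 0:
        return indet("no decay-triggering PTV: no imbalance expected")
    if aei.ptv_count >= 2:
        return indet("biallelic PTVs: both transcripts decay, ratio returns to ~0.5")
    if "last_exon_ptv" in aei.flags:
        return indet("PTV in the last exon / escape window may not trigger decay")
    if aei.n_informative_snvs < cfg.min_snvs:
        return indet(
            f"only {aei.n_informative_snvs} informative SNVs (< {cfg.min_snvs})"
        )
    if "inconsistent" in aei.flags or (aei.sd_lesser or 0.0) > cfg.max_sd:
        return indet("allele ratios inconsistent across SNVs")
    lo, hi = cfg.lesser_band
    if not (lo <= aei.mean_lesser <= hi):
        return indet(
            f"mean lesser fraction {aei.mean_lesser:.2f} outside decay band "
            f"[{lo:.2f}, {hi:.2f}]"
        )
    return PhaseCall(
        pair, "trans", "aei",
        f"one decay-triggering PTV with consistent lesser fraction "
        f"{aei.mean_lesser:.2f} over {aei.n_informative_snvs} SNVs",
    )


def phase_by_same_region(
    pair_counts: Mapping[str, int],
    pair: tuple[str, str] = ("v1", "v2"),
    min_pairs: int = 10,
    noise_share: float = 0.05,
    support_share: float = 0.2,
    require_ref_pairs: bool = True,
) -> PhaseCall:
    """Phase two variants covered by the same read pairs.

    ``pair_counts`` maps the four two-site haplotypes RR/RA/AR/AA to read
    counts.  trans: both single-alt haplotypes well supported and double
    ref/alt within noise (no reference haplotype spans both sites).  cis:
    double-alt (and, for het sites, double-ref) dominate with single-alt
    pairs within noise.
    """
    counts = {k: int(pair_counts.get(k, 0)) for k in ("RR", "RA", "AR", "AA")}
    if any(c < 0 for c in counts.values()):
        raise ContractError("pair counts must be non-negative")
    total = sum(counts.values())
    if total < min_pairs:
        return PhaseCall(
            pair, "indeterminate", "same_region_reads",
            f"only {total} read pairs (< {min_pairs})",
        )
    s = {k: c / total for k, c in counts.items()}
    if (
        s["RA"] >= support_share
        and s["AR"] >= support_share
        and s["RR"] + s["AA"] <= noise_share
    ):
        return PhaseCall(
            pair, "trans", "same_region_reads",
            "only single-alt haplotypes observed; no read carries both or neither",
        )
    cis_support = s["AA"] >= support_share and (
        not require_ref_pairs or s["RR"] >= support_share
    )
    if cis_support and s["RA"] + s["AR"] <= noise_share:
        return PhaseCall(
            pair, "cis", "same_region_reads",
            "both variants observed on the same read pairs",
        )
    return PhaseCall(
        pair, "indeterminate", "same_region_reads",
        "mixed two-site haplotypes: no clean cis or trans signal",
    )


def aei_table(
    allele_counts: pd.DataFrame,
    variants: pd.DataFrame,
    model: GeneModel,
    cfg: Optional[AEIConfig] = None,
    gene_abundance: Optional[pd.DataFrame] = None,
    control_ids: Iterable[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame, list[AEIResult]]:
    """Run AEI + phasing across a cohort table; returns (aei, phase, results)."""
    cfg = cfg or AEIConfig()
    control_ids = set(control_ids)
    controls: list[tuple[float, float]] = []
    ab_of: dict[str, tuple[float, float]] = {}
    if gene_abundance is not None:
        for _, r in gene_abundance.iterrows():
            pair = (float(r["gene_count"]), float(r["panel_count"]))
            ab_of[str(r["sample_id"])] = pair
            if str(r["sample_id"]) in control_ids:
                controls.append(pair)
    rows, prows, results = [], [], []
    for sid, recs in allele_counts.groupby("sample_id", sort=True):
        vs = variants[variants["sample_id"] == sid]
        res = aggregate_aei(
            recs, vs, model, cfg,
            gene_abundance=ab_of.get(str(sid)),
            controls=controls or None,
        )
        call = phase_by_aei(res, cfg)
        results.append(res)
        rows.append(res.to_row())
        prows.append({"sample_id": sid, **call.to_row()})
    return pd.DataFrame(rows), pd.DataFrame(prows), results
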
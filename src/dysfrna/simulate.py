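"""Synthetic cohort generator for blood RNA-Seq count data in a recessive
muscular-dystrophy gene.

The generator emits the count tables all downstream inference consumes —
allele counts at heterozygous sites, splice-junction counts, gene/panel
totals, per-exon relative coverage, and haplotype-resolved read pairs — under
a transcript-mixture model of nonsense-mediated decay (NMD):

* each haplotype contributes weight 1/2;
* an isoform that carries a decay-triggering premature termination codon
  survives with probability ``1 - e`` (``e`` = decay efficiency, default 2/3
  so that the cis lesser-allele fraction is (1-e)/(2-e) = 0.25);
* allele counts are binomial at Poisson depths; junction reads are Poisson
  around the surviving isoform mixture at each boundary.

Samples are built from named genotype archetypes (one-PTV, biallelic-PTV,
last-exon PTV, leaky splice, homozygous splice, intragenic deletion or
duplication, same-exon trans pair, ...) mirroring the case types a
diagnostic cohort presents.  Every sample carries a first-class truth record
so recovery tests never reverse-engineer the sampler.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .genemodel import (
    ContractError,
    GeneModel,
    Haplotype,
    Variant,
    frame_consequence,
    load_default_model,
    nmd_triggering,
)

__all__ = [
    "SimConfig",
    "SpliceTruth",
    "SampleData",
    "CohortData",
    "expected_lesser_fraction",
    "expected_abundance",
    "simulate_sample",
    "simulate_cohort",
    "build_archetype",
    "ARCHETYPES",
    "DEFAULT_COHORT",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """Study conditions for the generator.

    ``nmd_efficiency`` is the per-transcript decay probability for an isoform
    with a premature termination codon; 2/3 reproduces the ~75:25
    greater:lesser allele ratio seen at heterozygous SNVs in one-PTV samples.
    Depths are expected read counts (Poisson means) per site / per junction.
    ``leaky_aberrant_fraction`` / ``leaky_missense_fraction`` are *observed*
    transcript shares for the leaky-splice archetype (aberrantly spliced vs
    normally spliced variant-bearing transcripts).
    """

    nmd_efficiency: float = 2.0 / 3.0
    depth_per_site: float = 500.0
    n_het_snvs: int = 8
    junction_depth: float = 200.0
    gene_depth: float = 20000.0
    panel_depth: float = 1_000_000.0
    pair_depth: float = 30.0
    seed: int = 0
    leaky_aberrant_fraction: float = 0.28
    leaky_missense_fraction: float = 0.16
    exon_ratio_noise_sd: float = 0.03

    def __post_init__(self) -> None:
        if not 0.0 <= self.nmd_efficiency <= 1.0:
            raise ContractError("nmd_efficiency must be in [0,1]")
        for name in ("depth_per_site", "junction_depth", "gene_depth", "panel_depth"):
            if getattr(self, name) < 1:
                raise ContractError(f"{name} must be >= 1")
        if self.n_het_snvs < 0:
            raise ContractError("n_het_snvs must be >= 0")
        for name in ("leaky_aberrant_fraction", "leaky_missense_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ContractError(f"{name} must be in [0,1]")
        if self.leaky_aberrant_fraction + self.leaky_missense_fraction > 1.0:
            raise ContractError("leaky fractions must sum to <= 1")


def expected_lesser_fraction(e: float) -> float:
    """Closed-form lesser-allele fraction at a het SNV in cis with the sole
    decay-triggering PTV: (1-e)/(2-e)."""
    if not 0.0 <= e <= 1.0:
        raise ContractError("decay efficiency must be in [0,1]")
    return (1.0 - e) / (2.0 - e)


def expected_abundance(n_triggering_haps: int, e: float) -> float:
    """Expected gene abundance relative to control for 0/1/2 decay-triggering
    haplotypes: 1, (2-e)/2, 1-e."""
    if not 0.0 <= e <= 1.0:
        raise ContractError("decay efficiency must be in [0,1]")
    if n_triggering_haps not in (0, 1, 2):
        raise ContractError("n_triggering_haps must be 0, 1 or 2")
    return {0: 1.0, 1: (2.0 - e) / 2.0, 2: 1.0 - e}[n_triggering_haps]


# ---------------------------------------------------------------------------
# splice-event truth


@dataclass
class SpliceTruth:
    """A simulated aberrant isoform on one haplotype (or both)."""

    name: str
    kind: str                      # exon_skip / exon_extension / cryptic_site / back_junction
    hap: str                       # "A", "B" or "both"
    fraction: float                # of that haplotype's transcripts
    donor: str                     # serialized transcript coordinate
    acceptor: str
    removed_exons: tuple[int, ...] = ()
    duplicated_exons: tuple[int, ...] = ()
    replaced_boundaries: tuple[tuple[int, int], ...] = ()
    frame: str = "frameshift"
    nmd: bool = True               # isoform is decayed with probability e

    def to_dict(self) -> dict:
        return {
            "name": self.name, "kind": self.kind, "hap": self.hap,
            "fraction": self.fraction, "donor": self.donor, "acceptor": self.acceptor,
            "removed_exons": list(self.removed_exons),
            "duplicated_exons": list(self.duplicated_exons),
            "frame": self.frame, "nmd": self.nmd,
        }


@dataclass
class _LeakyTruth:
    variant_id: str
    aberrant_fraction: float       # observed share of transcripts with the event
    missense_fraction: float       # observed share carrying the normally spliced variant


@dataclass
class SampleData:
    sample_id: str
    allele_counts: pd.DataFrame
    junctions: pd.DataFrame
    variants: pd.DataFrame
    gene_abundance: pd.DataFrame
    exon_abundance: pd.DataFrame
    pair_reads: Optional[pd.DataFrame]
    truth: dict


# ---------------------------------------------------------------------------
# core sampler


def _isoforms(hapA: Haplotype, hapB: Haplotype, events: Sequence[SpliceTruth],
              model: GeneModel, e: float) -> list[dict]:
    """Surviving transcript mixture: one dict per isoform with abundance weight."""
    iso = []
    for hap in (hapA, hapB):
        trig = any(
            v.v_class in ("nonsense", "frameshift_indel") and v.is_ptv
            and nmd_triggering(v, model)
            for v in hap.variants
        )
        own = [ev for ev in events if ev.hap in (hap.allele_id, "both")]
        canon_frac = 1.0 - sum(ev.fraction for ev in own)
        if canon_frac < -1e-9:
            raise ContractError(
                f"isoform fractions on haplotype {hap.allele_id} exceed 1"
            )
        canon_frac = max(canon_frac, 0.0)
        iso.append({
            "hap": hap.allele_id, "event": None,
            "weight": 0.5 * canon_frac * (1.0 - e * trig),
        })
        for ev in own:
            survive = (1.0 - e) if ev.nmd else 1.0
            iso.append({
                "hap": hap.allele_id, "event": ev,
                "weight": 0.5 * ev.fraction * survive,
            })
    return iso


def _exon_inclusion(iso: list[dict], exon_id: int, model: GeneModel) -> dict[str, float]:
    """Per-haplotype abundance of transcripts containing a given exon."""
    phi = model.inclusion_fraction(exon_id)
    out = {"A": 0.0, "B": 0.0}
    for it in iso:
        ev = it["event"]
        if ev is not None and exon_id in ev.removed_exons:
            continue
        mult = 2.0 if (ev is not None and exon_id in ev.duplicated_exons) else 1.0
        out[it["hap"]] += it["weight"] * phi * mult
    return out


def _junction_shares(iso: list[dict], model: GeneModel) -> dict[tuple[str, str], float]:
    """Expected read share at every junction implied by the isoform mixture."""
    shares: dict[tuple[str, str], float] = {}

    def add(donor: str, acceptor: str, w: float) -> None:
        if w > 0:
            shares[(donor, acceptor)] = shares.get((donor, acceptor), 0.0) + w

    exons = model.exons
    for it in iso:
        ev = it["event"]
        w = it["weight"]
        if w <= 0:
            continue
        replaced = set(ev.replaced_boundaries) if ev is not None else set()
        removed = set(ev.removed_exons) if ev is not None else set()
        dup = set(ev.duplicated_exons) if ev is not None else set()
        for a, b in zip(exons, exons[1:]):
            pair = (a.exon_id, b.exon_id)
            if pair in replaced or a.exon_id in removed or b.exon_id in removed:
                continue
            phi_a = model.inclusion_fraction(a.exon_id)
            phi_b = model.inclusion_fraction(b.exon_id)
            mult = 2.0 if (a.exon_id in dup and b.exon_id in dup) else 1.0
            add(str(a.end), str(b.start), w * phi_a * phi_b * mult)
            # a variable exon is skipped in the complementary share
            if phi_b < 1.0:
                idx = model.exon_index(b.exon_id)
                if idx + 1 < len(exons):
                    nxt = exons[idx + 1]
                    add(str(a.end), str(nxt.start), w * (1.0 - phi_b))
        if ev is not None:
            add(ev.donor, ev.acceptor, w)
    return shares


def simulate_sample(
    hapA: Haplotype,
    hapB: Haplotype,
    model: GeneModel,
    cfg: SimConfig,
    *,
    sample_id: str = "S1",
    events: Sequence[SpliceTruth] = (),
    e: Optional[float] = None,
    leaky: Optional[_LeakyTruth] = None,
    marker_exons: Optional[Sequence[int]] = None,
    pair_truth: Optional[tuple[str, str, str]] = None,
    archetype: str = "custom",
    flags: Sequence[str] = (),
    rng: Optional[np.random.Generator] = None,
) -> SampleData:
    """Draw one sample's count tables from the transcript-mixture model."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    e = cfg.nmd_efficiency if e is None else e
    if not 0.0 <= e <= 1.0:
        raise ContractError("decay efficiency must be in [0,1]")
    iso = _isoforms(hapA, hapB, events, model, e)
    total_abundance = sum(it["weight"] for it in iso)

    # --- markers: benign het SNVs used as phase-informative sites ----------
    hap_of: dict[str, str] = {}
    site_variants: list[Variant] = []
    allowed = (
        [model.exon(x) for x in marker_exons]
        if marker_exons is not None
        else [ex for ex in model.exons if ex.exon_id not in model.variable_exons]
    )
    bases = np.concatenate([np.arange(ex.start, ex.end + 1) for ex in allowed])
    taken = {v.position.base for h in (hapA, hapB) for v in h.variants}
    bases = bases[~np.isin(bases, list(taken))]
    n_mk = min(cfg.n_het_snvs, len(bases))
    marker_pos = np.sort(rng.choice(bases, size=n_mk, replace=False))
    for i, pos in enumerate(marker_pos):
        hap = "A" if rng.random() < 0.5 else "B"
        mv = Variant(f"c.{int(pos)}A>G", "synonymous", zygosity="het", allele=hap)
        mv.id = f"{sample_id}:mkr{i}:{mv.id}"
        site_variants.append(mv)
        hap_of[mv.id] = hap
    for hap in (hapA, hapB):
        for v in hap.variants:
            if v not in [x for x in site_variants]:
                site_variants.append(v)
                hap_of[v.id] = hap.allele_id

    # --- allele counts -----------------------------------------------------
    ac_rows = []
    for v in site_variants:
        try:
            ex = model.exon_containing(v.position.base)
        except Exception:
            continue  # deep intronic: no pile-up site
        if v.position.offset != 0:
            continue
        incl = _exon_inclusion(iso, ex.exon_id, model)
        denom = incl["A"] + incl["B"]
        if leaky is not None and v.id == leaky.variant_id:
            # observed-share parameterization: the site's exon is removed by
            # the aberrant event, so site depth covers normally spliced
            # transcripts only
            depth_mean = cfg.depth_per_site * (1.0 - leaky.aberrant_fraction)
            p_alt = leaky.missense_fraction / (1.0 - leaky.aberrant_fraction)
        elif denom <= 0:
            continue
        else:
            depth_mean = cfg.depth_per_site * denom
            if v.zygosity == "hom":
                p_alt = 1.0
            else:
                p_alt = incl[hap_of[v.id]] / denom
        depth = int(rng.poisson(depth_mean))
        if depth < 1:
            continue
        alt = int(rng.binomial(depth, min(max(p_alt, 0.0), 1.0)))
        ac_rows.append((sample_id, v.id, depth - alt, alt))
    allele_counts = pd.DataFrame(
        ac_rows, columns=["sample_id", "variant_id", "ref_count", "alt_count"]
    )

    # --- junction counts ----------------------------------------------------
    if leaky is not None:
        # observed shares directly define the locus mixture
        f = leaky.aberrant_fraction
        ev = events[0]
        shares = _junction_shares(iso, model)
        for pair in ev.replaced_boundaries:
            d = str(model.exon(pair[0]).end)
            a = str(model.exon(pair[1]).start)
            shares[(d, a)] = 1.0 - f
        shares[(ev.donor, ev.acceptor)] = f
    else:
        shares = _junction_shares(iso, model)
    canonical = {(str(d), str(a)) for d, a in model.canonical_junctions()}
    j_rows = []
    for (donor, acceptor), share in sorted(shares.items(), key=lambda kv: kv[0]):
        reads = int(rng.poisson(cfg.junction_depth * share))
        if reads > 0:
            j_rows.append(
                (sample_id, donor, acceptor, reads, (donor, acceptor) in canonical)
            )
    junctions = pd.DataFrame(
        j_rows, columns=["sample_id", "donor", "acceptor", "reads", "canonical"]
    )

    # --- gene / panel totals ------------------------------------------------
    gene_count = int(rng.poisson(cfg.gene_depth * total_abundance))
    panel_count = int(rng.poisson(cfg.panel_depth))
    gene_abundance = pd.DataFrame(
        [(sample_id, gene_count, panel_count)],
        columns=["sample_id", "gene_count", "panel_count"],
    )

    # --- per-exon relative coverage (median-normalized, vs diploid control) -
    raw = {}
    for ex in model.exons:
        incl = _exon_inclusion(iso, ex.exon_id, model)
        ctrl = model.inclusion_fraction(ex.exon_id)  # diploid control coverage
        raw[ex.exon_id] = (incl["A"] + incl["B"]) / ctrl
    med = float(np.median(list(raw.values())))
    ea_rows = []
    for ex in model.exons:
        noise = float(np.exp(rng.normal(0.0, cfg.exon_ratio_noise_sd)))
        ea_rows.append((sample_id, ex.exon_id, round(raw[ex.exon_id] / med * noise, 4)))
    exon_abundance = pd.DataFrame(ea_rows, columns=["sample_id", "exon_id", "ratio"])

    # --- haplotype-resolved read pairs over two sites -----------------------
    pair_reads = None
    if pair_truth is not None:
        v1, v2, phase = pair_truth
        # error-free by design: in the regime being emulated no
        # phase-discordant read pairs were observed at these loci
        if phase == "trans":
            probs = [0.0, 0.5, 0.5, 0.0]
        else:  # cis
            probs = [0.5, 0.0, 0.0, 0.5]
        total = max(int(rng.poisson(cfg.pair_depth)), 1)
        rr, ra, ar, aa = rng.multinomial(total, probs)
        pair_reads = pd.DataFrame(
            [(sample_id, v1, v2, int(rr), int(ra), int(ar), int(aa))],
            columns=["sample_id", "variant_1", "variant_2", "RR", "RA", "AR", "AA"],
        )

    # --- variant table ------------------------------------------------------
    v_rows = []
    for v in site_variants:
        v_rows.append((
            sample_id, v.id, v.v_class, v.zygosity, hap_of.get(v.id, ""),
            bool(v.is_ptv),
        ))
    variants = pd.DataFrame(
        v_rows,
        columns=["sample_id", "variant_id", "v_class", "zygosity", "allele", "is_ptv"],
    )

    n_trig = sum(
        1 for hap in (hapA, hapB)
        if any(
            v.v_class in ("nonsense", "frameshift_indel") and v.is_ptv
            and nmd_triggering(v, model)
            for v in hap.variants
        )
    )
    truth = {
        "sample_id": sample_id,
        "archetype": archetype,
        "e": e,
        "n_triggering_haps": n_trig,
        "expected_abundance": expected_abundance(n_trig, e),
        "expected_lesser": expected_lesser_fraction(e) if n_trig == 1 else 0.5,
        "markers": {m: hap_of[m] for m in hap_of},
        "events": [ev.to_dict() for ev in events],
        "leaky": (
            {"variant_id": leaky.variant_id,
             "aberrant_fraction": leaky.aberrant_fraction,
             "missense_fraction": leaky.missense_fraction}
            if leaky is not None else None
        ),
        "phase": pair_truth[2] if pair_truth else None,
        "flags": list(flags),
    }
    return SampleData(
        sample_id, allele_counts, junctions, variants,
        gene_abundance, exon_abundance, pair_reads, truth,
    )


# ---------------------------------------------------------------------------
# genotype archetypes


def _skip_event(model: GeneModel, exons: tuple[int, ...], hap: str,
                fraction: float, name: str, nmd: Optional[bool] = None,
                kind: str = "exon_skip") -> SpliceTruth:
    first, last = exons[0], exons[-1]
    donor = str(model.exon(first - 1).end)
    acceptor = str(model.exon(last + 1).start)
    span = sum(model.exon(x).length for x in exons)
    frame = frame_consequence(span, "deletion")
    if nmd is None:
        nmd = frame == "frameshift"
    replaced = tuple((x - 1, x) for x in exons) + ((last, last + 1),)
    return SpliceTruth(
        name=name, kind=kind, hap=hap, fraction=fraction,
        donor=donor, acceptor=acceptor, removed_exons=exons,
        replaced_boundaries=replaced, frame=frame, nmd=nmd,
    )


def build_archetype(name: str, model: GeneModel, cfg: SimConfig) -> dict:
    """Keyword arguments for :func:`simulate_sample` for a named archetype."""
    A, B = Haplotype("A"), Haplotype("B")
    kw: dict = {"archetype": name}

    if name == "control":
        pass
    elif name in ("one_ptv", "off_model"):
        A.variants.append(Variant("c.757C>T", "nonsense", allele="A"))
        B.variants.append(Variant("c.1004G>C", "missense", allele="B"))
        if name == "off_model":
            kw["flags"] = ["indeterminate_truth"]
            kw["e"] = "draw_off_model"  # resolved by the caller with its rng
    elif name in ("two_ptv", "biallelic_ptv"):
        A.variants.append(Variant("c.757C>T", "nonsense", allele="A"))
        B.variants.append(Variant("c.5022delT", "frameshift_indel", allele="B"))
    elif name == "last_exon_ptv":
        A.variants.append(Variant("c.6216delC", "frameshift_indel", allele="A"))
        B.variants.append(Variant("c.1004G>C", "missense", allele="B"))
        kw["flags"] = ["phase_unknowable"]
    elif name == "exon17_only":
        A.variants.append(Variant("c.757C>T", "nonsense", allele="A"))
        B.variants.append(Variant("c.1500A>G", "missense", allele="B"))
        kw["marker_exons"] = [17]
    elif name == "leaky":
        lv = Variant("c.4794G>T", "missense", allele="A")
        A.variants.append(lv)
        f_ab = cfg.leaky_aberrant_fraction
        ev = _skip_event(model, (43,), "both", f_ab, "leaky_skip_exon43", nmd=False)
        kw["events"] = [ev]
        kw["leaky"] = _LeakyTruth(lv.id, f_ab, cfg.leaky_missense_fraction)
    elif name == "het_splice":
        sv = Variant("c.2810+1G>A", "splice_site", allele="A", is_ptv=True)
        A.variants.append(sv)
        B.variants.append(Variant("c.1004G>C", "missense", allele="B"))
        kw["events"] = [_skip_event(model, (26,), "A", 1.0, "skip_exon26")]
    elif name == "hom_splice":
        sv = Variant("c.5429G>A", "splice_site", zygosity="hom", allele="A", is_ptv=True)
        A.variants.append(sv)
        B.variants.append(sv)
        kw["events"] = [_skip_event(model, (47,), "both", 1.0, "skip_exon47")]
    elif name == "cnv_del":
        # genomic deletion of exons 25-29 on haplotype A; the causal DNA
        # variant is absent from the variant table (that is the point)
        B.variants.append(Variant("c.1004G>C", "missense", allele="B"))
        kw["events"] = [_skip_event(model, (25, 26, 27, 28, 29), "A", 1.0,
                                    "del_exons25_29", kind="multi_exon_skip")]
    elif name == "cnv_dup":
        B.variants.append(Variant("c.1004G>C", "missense", allele="B"))
        dup = tuple(range(10, 36))
        kw["events"] = [SpliceTruth(
            name="dup_exons10_35", kind="back_junction", hap="A", fraction=1.0,
            donor=str(model.exon(35).end), acceptor=str(model.exon(10).start),
            duplicated_exons=dup,
            frame=frame_consequence(sum(model.exon(x).length for x in dup), "insertion"),
            nmd=False,
        )]
    elif name == "same_exon_trans":
        v1 = Variant("c.2200G>A", "missense", allele="A")
        v2 = Variant("c.2250C>T", "nonsense", allele="B")
        A.variants.append(v1)
        B.variants.append(v2)
        kw["pair_truth"] = (v1.id, v2.id, "trans")
    elif name == "same_transcript_cis":
        v1 = Variant("c.3444T>A", "nonsense", allele="A")
        v2 = Variant("c.3445G>A", "missense", allele="A")
        A.variants.extend([v1, v2])
        kw["pair_truth"] = (v1.id, v2.id, "cis")
    else:
        raise ContractError(f"unknown genotype archetype {name!r}")
    kw["hapA"], kw["hapB"] = A, B
    return kw


ARCHETYPES = (
    "control", "one_ptv", "two_ptv", "biallelic_ptv", "last_exon_ptv",
    "exon17_only", "off_model", "leaky", "het_splice", "hom_splice",
    "cnv_del", "cnv_dup", "same_exon_trans", "same_transcript_cis",
)

# default cohort: the case mix the analysis is designed around
DEFAULT_COHORT = [
    {"archetype": "control", "n": 15},
    {"archetype": "one_ptv", "n": 12},
    {"archetype": "two_ptv", "n": 5},
    {"archetype": "last_exon_ptv", "n": 1},
    {"archetype": "exon17_only", "n": 2},
    {"archetype": "off_model", "n": 1},
    {"archetype": "leaky", "n": 2},
    {"archetype": "het_splice", "n": 6},
    {"archetype": "hom_splice", "n": 3},
    {"archetype": "cnv_del", "n": 2},
    {"archetype": "cnv_dup", "n": 1},
    {"archetype": "same_exon_trans", "n": 2},
    {"archetype": "same_transcript_cis", "n": 1},
]


@dataclass
class CohortData:
    samples: list[SampleData]
    allele_counts: pd.DataFrame
    junctions: pd.DataFrame
    variants: pd.DataFrame
    gene_abundance: pd.DataFrame
    exon_abundance: pd.DataFrame
    pair_reads: pd.DataFrame
    truth: list[dict]


def simulate_cohort(
    spec: Optional[Sequence[dict] | str | Path] = None,
    cfg: Optional[SimConfig] = None,
    model: Optional[GeneModel] = None,
    outdir: Optional[str | Path] = None,
) -> CohortData:
    """Simulate a cohort from a spec of archetype rows; optionally write TSVs.

    ``spec`` rows are ``{"archetype": name, "n": count}`` (or a YAML file of
    such rows).  Sample seeds derive deterministically from ``cfg.seed`` so a
    fixed seed gives byte-identical output files.
    """
    cfg = cfg or SimConfig()
    model = model or load_default_model()
    if spec is None:
        spec = DEFAULT_COHORT
    elif isinstance(spec, (str, Path)):
        with open(spec) as fh:
            spec = yaml.safe_load(fh)
    samples: list[SampleData] = []
    idx = 0
    for row in spec:
        name = row["archetype"]
        for k in range(int(row.get("n", 1))):
            rng = np.random.default_rng([cfg.seed, idx])
            kw = build_archetype(name, model, cfg)
            if kw.get("e") == "draw_off_model":
                # an inexplicable deviator: decay far weaker than the model assumes
                kw["e"] = float(rng.uniform(0.0, 0.15))
            sid = row.get("sample_id", f"{name}_{k:03d}")
            samples.append(
                simulate_sample(
                    kw.pop("hapA"), kw.pop("hapB"), model, cfg,
                    sample_id=sid, rng=rng, **kw,
                )
            )
            idx += 1

    def cat(attr: str) -> pd.DataFrame:
        frames = [getattr(s, attr) for s in samples if getattr(s, attr) is not None]
        if not frames:
            return pd.DataFrame()
        return pd.concat(frames, ignore_index=True)

    cohort = CohortData(
        samples=samples,
        allele_counts=cat("allele_counts"),
        junctions=cat("junctions"),
        variants=cat("variants"),
        gene_abundance=cat("gene_abundance"),
        exon_abundance=cat("exon_abundance"),
        pair_reads=cat("pair_reads"),
        truth=[s.truth for s in samples],
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for attr in ("allele_counts", "junctions", "variants",
                     "gene_abundance", "exon_abundance", "pair_reads"):
            getattr(cohort, attr).to_csv(outdir / f"{attr}.tsv", sep="\t", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(cohort.truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return cohort
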
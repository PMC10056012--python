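"""Allele-fraction estimation, AEI aggregation, and phase calling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dysfrna.aei import (
    AEIConfig,
    AEIResult,
    aei_table,
    aggregate_aei,
    allele_fraction,
    phase_by_aei,
    phase_by_same_region,
    relative_abundance,
)
from dysfrna.genemodel import ContractError
from dysfrna.simulate import SimConfig, simulate_cohort


@pytest.mark.parametrize(
    "ref, alt, lesser",
    [(75, 25, 0.25), (50, 50, 0.5), (30, 10, 0.25)],
)
def test_allele_fraction(ref, alt, lesser):
    frac, less = allele_fraction(ref, alt)
    assert frac == pytest.approx(alt / (ref + alt))
    assert less == pytest.approx(lesser)


def test_allele_fraction_contract():
    with pytest.raises(ContractError):
        allele_fraction(0, 0)


class TestRelativeAbundance:
    def test_equal_to_control_mean(self):
        assert relative_abundance(100, 10_000, [(100, 10_000)]) == pytest.approx(1.0)

    def test_one_ptv_sample(self, model):
        cfg = SimConfig(seed=4)
        cohort = simulate_cohort(
            [{"archetype": "control", "n": 6}, {"archetype": "one_ptv", "n": 1}],
            cfg, model,
        )
        ab = cohort.gene_abundance.set_index("sample_id")
        controls = [
            (r["gene_count"], r["panel_count"])
            for sid, r in ab.iterrows() if sid.startswith("control")
        ]
        r = ab.loc["one_ptv_000"]
        rel = relative_abundance(r["gene_count"], r["panel_count"], controls)
        assert rel == pytest.approx(2 / 3, abs=0.05)

    def test_biallelic_sample(self, model):
        cfg = SimConfig(seed=4)
        cohort = simulate_cohort(
            [{"archetype": "control", "n": 6}, {"archetype": "two_ptv", "n": 1}],
            cfg, model,
        )
        ab = cohort.gene_abundance.set_index("sample_id")
        controls = [
            (r["gene_count"], r["panel_count"])
            for sid, r in ab.iterrows() if sid.startswith("control")
        ]
        r = ab.loc["two_ptv_000"]
        rel = relative_abundance(r["gene_count"], r["panel_count"], controls)
        assert rel == pytest.approx(1 / 3, abs=0.05)

    def test_requires_controls(self):
        with pytest.raises(ContractError):
            relative_abundance(100, 1000, [])


def _records(sample="s", **sites):
    rows = [
        {"sample_id": sample, "variant_id": vid, "ref_count": r, "alt_count": a}
        for vid, (r, a) in sites.items()
    ]
    return pd.DataFrame(rows)


def _variants(sample="s", **info):
    rows = []
    for vid, (vclass, allele) in info.items():
        rows.append({
            "sample_id": sample, "variant_id": vid, "v_class": vclass,
            "zygosity": "het", "allele": allele,
            "is_ptv": vclass in ("nonsense", "frameshift_indel"),
        })
    return pd.DataFrame(rows)


class TestAggregate:
    def test_one_ptv_pattern(self, model):
        recs = _records(
            ptv=(300, 100), m1=(310, 95), m2=(105, 290), m3=(290, 102),
        )
        recs["variant_id"] = ["c.757C>T", "c.1900A>G", "c.2400A>G", "c.3300A>G"]
        vs = _variants(**{
            "c.757C>T": ("nonsense", "A"),
            "c.1900A>G": ("synonymous", "A"),
            "c.2400A>G": ("synonymous", "B"),
            "c.3300A>G": ("synonymous", "A"),
        })
        res = aggregate_aei(recs, vs, model)
        assert res.n_informative_snvs == 4
        assert res.mean_lesser == pytest.approx(0.25, abs=0.02)
        assert res.ptv_count == 1
        assert res.mean_fraction_A + res.mean_fraction_B == pytest.approx(1.0)
        assert not res.flags

    def test_variable_exon_site_excluded(self, model):
        recs = _records(**{"c.1500A>G": (60, 40)})
        vs = _variants(**{"c.1500A>G": ("synonymous", "B")})  # exon 17
        res = aggregate_aei(recs, vs, model)
        assert res.n_informative_snvs == 0
        assert "variable_exon_site" in res.flags

    def test_indel_and_low_depth_flags(self, model):
        recs = _records(**{"c.5022delT": (200, 80), "c.2000A>G": (8, 4)})
        vs = _variants(**{
            "c.5022delT": ("frameshift_indel", "B"),
            "c.2000A>G": ("synonymous", "A"),
        })
        res = aggregate_aei(recs, vs, model)
        assert {"indel_site", "low_depth"} <= res.flags
        assert res.n_informative_snvs == 0

    def test_biallelic_lesser_near_half(self, model):
        recs = _records(**{"c.757C>T": (100, 95), "c.2000A>G": (98, 103)})
        vs = _variants(**{
            "c.757C>T": ("nonsense", "A"),
            "c.2000A>G": ("synonymous", "B"),
        })
        vs2 = pd.concat([vs, _variants(**{"c.5022delT": ("frameshift_indel", "B")})])
        res = aggregate_aei(recs, vs2, model)
        assert res.ptv_count == 2
        assert res.mean_lesser == pytest.approx(0.5, abs=0.05)


class TestPhaseByAei:
    def _res(self, **kw):
        base = dict(
            sample_id="s", mean_lesser=0.24, sd_lesser=0.03,
            n_informative_snvs=8, ptv_count=1,
            ptv_ids=("ptv",), partner_ids=("vus",),
        )
        base.update(kw)
        return AEIResult(**base)

    def test_clean_one_ptv_is_trans(self):
        assert phase_by_aei(self._res()).call == "trans"

    def test_biallelic_is_indeterminate(self):
        call = phase_by_aei(self._res(ptv_count=2, mean_lesser=0.5))
        assert call.call == "indeterminate"
        assert "biallelic" in call.rationale.lower()

    def test_last_exon_flag_blocks(self):
        call = phase_by_aei(self._res(flags={"last_exon_ptv"}))
        assert call.call == "indeterminate"

    def test_off_model_fraction_blocks(self):
        call = phase_by_aei(self._res(mean_lesser=0.46))
        assert call.call == "indeterminate"
        assert "outside" in call.rationale

    def test_too_few_snvs_blocks(self):
        assert phase_by_aei(self._res(n_informative_snvs=2)).call == "indeterminate"

    def test_inconsistent_blocks(self):
        assert phase_by_aei(self._res(sd_lesser=0.2)).call == "indeterminate"


def _oracle_same_region(c, min_pairs=10, noise=0.05, support=0.2):
    """Independent re-derivation: a phase hypothesis is accepted when its
    predicted two-site haplotypes are well supported and all others are noise."""
    total = sum(c.values())
    if total < min_pairs:
        return "indeterminate"
    hypotheses = {
        "trans": (("RA", "AR"), ("RR", "AA")),
        "cis": (("AA", "RR"), ("RA", "AR")),
    }
    accepted = [
        name for name, (req, forb) in hypotheses.items()
        if all(c[r] >= support * total for r in req)
        and sum(c[f] for f in forb) <= noise * total
    ]
    return accepted[0] if len(accepted) == 1 else "indeterminate"


class TestSameRegionPhasing:
    @pytest.mark.parametrize(
        "counts, expect",
        [
            ({"RR": 0, "RA": 12, "AR": 15, "AA": 0}, "trans"),
            ({"RR": 20, "RA": 0, "AR": 0, "AA": 18}, "cis"),
            ({"RR": 10, "RA": 9, "AR": 11, "AA": 8}, "indeterminate"),
            ({"RR": 2, "RA": 3, "AR": 1, "AA": 0}, "indeterminate"),  # low depth
        ],
    )
    def test_examples(self, counts, expect):
        assert phase_by_same_region(counts).call == expect

    def test_low_depth_rationale(self):
        call = phase_by_same_region({"RR": 1, "RA": 2, "AR": 2, "AA": 0})
        assert "read pairs" in call.rationale

    def test_matches_enumeration_oracle(self):
        """Agreement with the brute-force oracle on all tables with total <= 30."""
        checked = 0
        for total in range(0, 31):
            for rr, ra, ar in itertools.product(range(total + 1), repeat=3):
                aa = total - rr - ra - ar
                if aa < 0:
                    continue
                c = {"RR": rr, "RA": ra, "AR": ar, "AA": aa}
                assert phase_by_same_region(c).call == _oracle_same_region(c), c
                checked += 1
        assert checked > 5000


class TestCohortIntegration:
    def test_trans_rate_and_false_positives(self, model):
        cfg = SimConfig(seed=9)
        spec = [
            {"archetype": "one_ptv", "n": 30},
            {"archetype": "control", "n": 10},
            {"archetype": "two_ptv", "n": 10},
        ]
        cohort = simulate_cohort(spec, cfg, model)
        _, phase_df, _ = aei_table(cohort.allele_counts, cohort.variants, model)
        phase_df = phase_df.set_index("sample_id")
        one = phase_df[phase_df.index.str.startswith("one_ptv")]
        assert (one["call"] == "trans").mean() >= 0.95
        rest = phase_df[~phase_df.index.str.startswith("one_ptv")]
        assert (rest["call"] == "trans").sum() == 0

    def test_fraction_sum_invariant(self, model):
        cfg = SimConfig(seed=10)
        cohort = simulate_cohort([{"archetype": "one_ptv", "n": 5}], cfg, model)
        aei_df, _, results = aei_table(cohort.allele_counts, cohort.variants, model)
        for r in results:
            assert r.mean_fraction_A + r.mean_fraction_B == pytest.approx(1.0)

    def test_same_region_archetypes_phase_correctly(self, model):
        cfg = SimConfig(seed=12, pair_depth=40)
        cohort = simulate_cohort(
            [{"archetype": "same_exon_trans", "n": 3},
             {"archetype": "same_transcript_cis", "n": 3}],
            cfg, model,
        )
        for _, row in cohort.pair_reads.iterrows():
            counts = {k: row[k] for k in ("RR", "RA", "AR", "AA")}
            call = phase_by_same_region(counts, (row["variant_1"], row["variant_2"]))
            expect = "trans" if str(row["sample_id"]).startswith("same_exon") else "cis"
            assert call.call == expect
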